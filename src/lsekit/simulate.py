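"""Synthetic inputs with the statistical structure the analysis assumes.

The generators stand in for the study's derived data products: an
18-taxon two-suborder ultrametric tree about 250 My deep, thousands of
gene families whose per-species counts evolved under a linear
birth-death process with rates of order 0.002 events/gene/My, trait
vectors drawn from the BM/OU regime models, and candidate categories with
planted enrichment.  Everything is a pure function of its parameters and
a seed.

What the generators do NOT emulate: sequencing and assembly artifacts
(isoform collapse in transcriptomes, annotation errors beyond the optional
tip-error smear), correlation of rates across families, and lineage
effects outside the two-regime painting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import BACKGROUND, CategoryAssignment, FamilyCountTable
from .gainloss import BDParams, _TreeIndex, _alpha_beta, _simulate_rows
from .trees import PaintedTree, paint_regimes, read_newick

__all__ = [
    "SimulationConfig",
    "ADEPHAGA_TIPS",
    "POLYPHAGA_TIPS",
    "fixture_tree",
    "fixture_clade_map",
    "random_tree",
    "simulate_count_table",
    "simulate_trait",
    "simulate_family_gillespie",
    "plant_categories",
]

# Table-1-style five-letter short names for the 9 + 9 sampled taxa.
ADEPHAGA_TIPS = (
    "CHYBR", "CFRIG", "EAURE", "NCLAV", "HFLUV", "CLATE", "SWRAS", "DINEU", "GMARI",
)
POLYPHAGA_TIPS = (
    "ACURT", "AGLAB", "APLAN", "DPOND", "LDECE", "LTESS", "MVIOL", "OTAUR", "TCAST",
)

# Node ages (My) are synthesized: both suborder crowns at 220 with the same
# multiset of internal node ages, so within-clade node-age distributions match.
_FIXTURE_NEWICK = (
    "("
    "((DINEU:60,GMARI:60):160,(((CFRIG:70,EAURE:70):30,CHYBR:100):80,"
    "((NCLAV:120,HFLUV:120):40,(CLATE:90,SWRAS:90):70):20):40):30,"
    "((ACURT:160,OTAUR:160):60,(APLAN:180,((TCAST:60,MVIOL:60):60,"
    "((AGLAB:90,LDECE:90):10,(DPOND:70,LTESS:70):30):20):60):40):30"
    ");"
)


@dataclass
class SimulationConfig:
    """Default study conditions for end-to-end synthetic runs.

    Counts: 2000 families under gain 0.002 / loss 0.0018 events/gene/My on
    a 250 My two-clade tree with root sizes uniform on 1..3 — real
    orthology tables are dominated by low-copy families ("single-copy
    control"), so ancestral families are small.  Traits: OU pull alpha
    0.02/My (phenotypic half-life ~35 My) with diffusion 0.1 per My;
    planted expanded families pull towards per-regime optima of 6.5 vs 19
    genes, the size contrast of observed adaptive carboxylesterase
    expansions.  Categories: eight candidate sets sized like the
    annotation table's, with a background positive rate near 0.9%.
    """

    seed: int = 0
    n_families: int = 2000
    lambda_: float = 0.002
    mu: float = 0.0018
    root_size_max: int = 3
    tree_depth: float = 250.0
    tips_per_group: int = 9
    alpha: float = 0.02
    sigma2: float = 0.1
    theta_base: float = 6.5
    theta_expanded: float = 19.0
    background_positive_rate: float = 0.009
    category_spec: list[tuple[str, int, float]] = field(
        default_factory=lambda: [
            ("UGT", 4, 0.009),
            ("P450", 22, 0.05),
            ("CE", 19, 0.16),
            ("GST", 6, 0.5),
            ("SER", 4, 0.009),
            ("CYS", 7, 0.14),
            ("ABC", 28, 0.009),
            ("GH", 1, 0.009),
        ]
    )


def fixture_clade_map() -> dict[str, frozenset[str]]:
    return {"A": frozenset(ADEPHAGA_TIPS), "P": frozenset(POLYPHAGA_TIPS)}


def fixture_tree() -> PaintedTree:
    """Deterministic 18-tip two-suborder tree, 250 My deep, painted A/P/R."""
    ptree = read_newick(_FIXTURE_NEWICK)
    return paint_regimes(ptree, fixture_clade_map(), root_regime="R")


def _yule_clade(n_tips: int, rng: np.random.Generator) -> tuple[list, float]:
    """Pure-birth (rate 1) clade: returns (merge events, crown duration).

    Events are (time, lineage_index_split) with lineage bookkeeping done by
    the caller via a simple growing list.
    """
    # represent the growing tree as a list of "open" lineage slots; each
    # split replaces one slot by an internal node with two child slots.
    t = 0.0
    events = []
    k = 1
    while k < n_tips:
        t += rng.exponential(1.0 / k)
        events.append((t, int(rng.integers(0, k))))
        k += 1
    t_end = t + rng.exponential(1.0 / k)
    return events, t_end


def _clade_newick(labels: list[str], rng: np.random.Generator) -> tuple[str, float]:
    """Seeded pure-birth clade over ``labels``; returns (newick, crown depth)."""
    n = len(labels)
    if n == 1:
        return labels[0], 0.0
    events, t_end = _yule_clade(n, rng)
    # build nested structure: nodes are dicts {birth: t, children: []} or tips
    root = {"birth": 0.0, "children": None}
    open_slots = [root]
    for t, idx in events:
        slot = open_slots[idx]
        slot["birth_split"] = t
        a = {"birth": t, "children": None}
        b = {"birth": t, "children": None}
        slot["children"] = [a, b]
        open_slots[idx] = a
        open_slots.append(b)
    perm = rng.permutation(n)
    for slot, j in zip(open_slots, perm):
        slot["label"] = labels[int(j)]

    def render(node, parent_birth: float) -> str:
        if node["children"] is None:
            return f"{node['label']}:{t_end - node['birth']:.17g}"
        t_split = node["birth_split"]
        inner = ",".join(render(c, t_split) for c in node["children"])
        return f"({inner}):{t_split - node['birth']:.17g}"

    # root of the clade subtree: render without its own stem
    if root["children"] is None:
        return root["label"], t_end
    t_split = root["birth_split"]
    inner = ",".join(render(c, t_split) for c in root["children"])
    # crown begins at the first split; depth below crown is t_end - t_split
    return f"({inner})", t_end - t_split


def random_tree(
    tips_per_group: int = 9,
    depth: float = 250.0,
    seed: int = 0,
    crown_fraction: float = 0.88,
) -> PaintedTree:
    """Seeded random two-clade tree: a pure-birth topology per clade, both
    crowns rescaled to ``crown_fraction * depth``, joined at the root.
    """
    if tips_per_group < 2:
        raise ValueError("tips_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    labels_a = [f"A{i:02d}" for i in range(tips_per_group)]
    labels_p = [f"P{i:02d}" for i in range(tips_per_group)]
    crown = crown_fraction * depth
    stem = depth - crown
    parts = []
    for labels in (labels_a, labels_p):
        nwk, cd = _clade_newick(labels, rng)
        sub = read_newick(nwk + ";")
        # rescale crown depth to the target
        factor = crown / cd
        for edge in sub.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        import io

        buf = io.StringIO()
        sub.tree.write(file=buf, schema="newick", unquoted_underscores=True,
                       suppress_rooting=True, real_value_format_specifier=".17g")
        parts.append(buf.getvalue().strip().rstrip(";"))
    newick = f"({parts[0]}:{stem:.17g},{parts[1]}:{stem:.17g});"
    ptree = read_newick(newick)
    return paint_regimes(
        ptree,
        {"A": frozenset(labels_a), "P": frozenset(labels_p)},
        root_regime="R",
    )


def simulate_count_table(
    ptree: PaintedTree,
    params: BDParams,
    n_families: int,
    root_dist: tuple[str, int] = ("uniform", 3),
    seed: int = 0,
) -> FamilyCountTable:
    """Gene-count table sampled under the linear birth-death process.

    Each family draws a root size (``("uniform", m)`` for uniform 1..m or
    ``("fixed", s)``), then every branch draws the child count from the
    exact per-lineage offspring law of the process (no state truncation).
    """
    rng = np.random.default_rng(seed)
    kind, value = root_dist
    if kind == "uniform":
        roots = rng.integers(1, int(value) + 1, n_families)
    elif kind == "fixed":
        roots = np.full(n_families, int(value))
    else:
        raise ValueError(f"unknown root distribution {kind!r}")
    tidx = _TreeIndex(ptree)
    rows = _simulate_rows(tidx, params, roots, rng)
    fam_ids = [f"FAM{i + 1:05d}" for i in range(n_families)]
    return FamilyCountTable(fam_ids, list(tidx.tip_order), rows)


def simulate_trait(
    ptree: PaintedTree,
    model: str,
    params: dict,
    seed: int = 0,
    root_state: float | None = None,
) -> dict[str, float]:
    """One trait vector simulated root-to-tips under a BM or OU model.

    ``params``: ``sigma2`` (scalar or per-regime), plus ``alpha`` and
    ``theta`` (per-regime optima) for OU models.  BM draws Gaussian
    increments with variance sigma^2 * branch length; OU uses the exact
    transition N(theta + (x - theta) e^(-a l), sigma^2 (1 - e^(-2 a l)) / (2 a)).
    The root state defaults to 0 for BM and the mean optimum for OU.
    """
    rng = np.random.default_rng(seed)
    regimes = ptree.edge_regimes()
    is_ou = model.startswith("OU")
    sigma2 = params["sigma2"]
    s2 = (lambda r: float(sigma2[r]) if isinstance(sigma2, dict) else float(sigma2))
    if is_ou:
        alpha = float(params["alpha"])
        theta = params["theta"]
        th = (lambda r: float(theta[r]) if isinstance(theta, dict) else float(theta))
        if root_state is None:
            vals = list(theta.values()) if isinstance(theta, dict) else [theta]
            root_state = float(np.mean(vals))
    elif root_state is None:
        root_state = 0.0
    x: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is None:
            x[id(node)] = float(root_state)
        else:
            parent = x[id(node.parent_node)]
            ell = float(node.edge.length)
            reg = regimes[node]
            sig = s2(reg)
            if is_ou and alpha > 0:
                decay = np.exp(-alpha * ell)
                mean = th(reg) + (parent - th(reg)) * decay
                var = sig * (1 - decay * decay) / (2 * alpha)
            else:
                mean = parent
                var = sig * ell
            x[id(node)] = mean + (np.sqrt(var) * rng.standard_normal() if var > 0 else 0.0)
        if node.is_leaf():
            out[node.taxon.label] = x[id(node)]
    return out


def simulate_family_gillespie(
    params: BDParams, s0: int, t: float, rng: np.random.Generator
) -> int:
    """Event-by-event birth-death simulation (independent oracle for the
    offspring-law sampler and the transition probabilities)."""
    s = int(s0)
    clock = 0.0
    while s > 0:
        rate = s * (params.lambda_ + params.mu)
        clock += rng.exponential(1.0 / rate)
        if clock >= t:
            break
        if rng.random() < params.lambda_ / (params.lambda_ + params.mu):
            s += 1
        else:
            s -= 1
    return s


def plant_categories(
    n_background: int,
    background_positive_rate: float,
    category_spec: list[tuple[str, int, float]],
    seed: int = 0,
) -> tuple[dict[str, bool], CategoryAssignment]:
    """Bernoulli positives for a background set and planted categories.

    Returns (family_id -> positive flag, category assignment); background
    families are named ``BG#####`` and category families ``<NAME>-###``.
    """
    rng = np.random.default_rng(seed)
    if not 0 <= background_positive_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    flags: dict[str, bool] = {}
    mapping: dict[str, str] = {}
    for i in range(n_background):
        flags[f"BG{i + 1:05d}"] = bool(rng.random() < background_positive_rate)
    for name, n, rate in category_spec:
        if not 0 <= rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        for j in range(n):
            fam = f"{name}-{j + 1:03d}"
            flags[fam] = bool(rng.random() < rate)
            mapping[fam] = name
    return flags, CategoryAssignment(mapping)
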