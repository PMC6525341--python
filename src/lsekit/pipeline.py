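"""End-to-end orchestration of the adaptive-expansion analysis.

Stage order follows the inference logic: families must span both clades
(filter), global gain/loss rates are estimated and compared (single vs
distinct), per-family Monte-Carlo p-values screen for families with
significantly variable gene content, only screened families enter the
five-model BM/OU comparison, positive calls are split by direction
(which regime holds the larger optimum), and category enrichment is
evaluated per direction against the full analyzed background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .counts import (
    BACKGROUND,
    CategoryAssignment,
    FamilyCountTable,
    filter_shared_families,
    read_count_table,
    write_results,
)
from .enrichment import BackgroundResults, bh_adjust, permutation_enrichment
from .gainloss import (
    BDFit,
    family_p_values,
    fit_global_rates,
    likelihood_ratio_test,
    summarize_node_changes,
    table_log_likelihoods,
)
from .regimes import MODELS, fit_all_models, group_means, select_model
from .trees import PaintedTree, paint_regimes, read_newick, validate_ultrametric

__all__ = ["RunConfig", "ReportBundle", "analyze", "run_pipeline", "load_groups"]


@dataclass
class RunConfig:
    """File paths, thresholds and sampling sizes for one pipeline run."""

    tree: str
    counts: str
    groups: str                      # YAML: {root_regime: R, clades: {A: [...], P: [...]}}
    out_dir: str
    candidates: str | None = None    # TSV: family_id <tab> category
    p_threshold: float = 0.01
    n_sim: int = 1000
    n_draws: int = 100_000
    seed: int = 0
    epsilon: float = 0.0
    n_starts: int = 5
    root_prior_max: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.n_draws < 1 or self.n_sim < 1:
            raise ValueError("n_draws and n_sim must be >= 1")


@dataclass
class ReportBundle:
    fit_single: BDFit
    fit_distinct: BDFit
    lrt: tuple[float, float]
    family_frame: pd.DataFrame       # family_id, lnL, p_value, significant, category
    selection_frame: pd.DataFrame    # Table-3-like per screened family
    enrichment_frame: pd.DataFrame   # Table-4-like per regime x category
    node_frame: pd.DataFrame         # node_id, scope, n_expanding, n_contracting
    provenance: dict[str, Any] = field(default_factory=dict)

    def positives(self, direction: str) -> list[str]:
        sel = self.selection_frame
        mask = sel["positive"] & (sel["direction"] == direction)
        return sel.loc[mask, "family_id"].tolist()

    def summary_text(self) -> str:
        lines = [
            "lsekit run summary",
            f"version: {_version}",
        ]
        for key, val in self.provenance.items():
            lines.append(f"{key}: {val}")
        lines += [
            f"lambda_single: {self.fit_single.params.lambda_:.6g}",
            f"lnL_single: {self.fit_single.lnL:.6f}",
            f"lambda_distinct: {self.fit_distinct.params.lambda_:.6g}",
            f"mu_distinct: {self.fit_distinct.params.mu:.6g}",
            f"lnL_distinct: {self.fit_distinct.lnL:.6f}",
            f"lrt_statistic: {self.lrt[0]:.6f}",
            f"lrt_p: {self.lrt[1]:.6g}",
            f"n_families: {len(self.family_frame)}",
            f"n_significant: {int(self.family_frame['significant'].sum())}",
            f"n_positive: {int(self.selection_frame['positive'].sum()) if len(self.selection_frame) else 0}",
        ]
        return "\n".join(lines) + "\n"

    def to_tables(self) -> dict[str, pd.DataFrame | str]:
        return {
            "families": self.family_frame,
            "selection": self.selection_frame,
            "enrichment": self.enrichment_frame,
            "node_changes": self.node_frame,
            "summary": self.summary_text(),
        }


def load_groups(path: str) -> tuple[dict[str, frozenset[str]], str]:
    """Read a regime painting config: clades plus the root regime label."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    clades = {k: frozenset(v) for k, v in data["clades"].items()}
    return clades, str(data.get("root_regime", "R"))


def analyze(
    table: FamilyCountTable,
    ptree: PaintedTree,
    clade_map: dict[str, frozenset[str]] | None = None,
    root_regime: str = "R",
    assignment: CategoryAssignment | None = None,
    p_threshold: float = 0.01,
    n_sim: int = 1000,
    n_draws: int = 100_000,
    seed: int = 0,
    epsilon: float = 0.0,
    n_starts: int = 5,
    node_summaries: bool = True,
    root_prior_max: int | None = None,
) -> ReportBundle:
    """Run the full three-stage analysis on in-memory inputs.

    Regime model fits are restricted to families whose Monte-Carlo
    gain/loss p-value falls below ``p_threshold``; enrichment is computed
    per direction against the entire analyzed background.  Deterministic
    given the seed.
    """
    if clade_map is None:
        if not ptree.is_painted:
            raise ValueError("tree is unpainted and no clade_map was given")
        clade_map = dict(ptree.clade_map)
    else:
        ptree = paint_regimes(ptree, clade_map, root_regime=root_regime)
    validate_ultrametric(ptree)
    if assignment is None:
        assignment = CategoryAssignment({})
    group_map = {
        tip: regime for regime, tips in clade_map.items() for tip in tips
    }
    table = filter_shared_families(table, group_map)

    fit_single = fit_global_rates(
        table, ptree, "single_rate", epsilon=epsilon, seed=seed,
        root_prior_max=root_prior_max,
    )
    fit_distinct = fit_global_rates(
        table, ptree, "distinct_rates", epsilon=epsilon, seed=seed,
        root_prior_max=root_prior_max,
    )
    lrt = likelihood_ratio_test(fit_single, fit_distinct)

    lnls = table_log_likelihoods(ptree, table, fit_distinct.params)
    pvals = family_p_values(
        table, ptree, fit_distinct, n_sim=n_sim, seed=seed + 1,
        root_prior_max=root_prior_max,
    )
    family_frame = pd.DataFrame(
        {
            "family_id": table.family_ids,
            "lnL": lnls,
            "p_value": [pvals[f] for f in table.family_ids],
            "significant": [pvals[f] < p_threshold for f in table.family_ids],
            "category": [assignment.category_of(f) for f in table.family_ids],
        }
    )

    screened = family_frame.loc[family_frame["significant"], "family_id"].tolist()
    sel_rows = []
    for fam in screened:
        trait = {s: float(c) for s, c in table.row(fam).items()}
        fits = fit_all_models(trait, ptree, n_starts=n_starts)
        means = group_means(trait, clade_map)
        call = select_model(fits, means, family_id=fam)
        row = {"family_id": fam, "category": assignment.category_of(fam)}
        for m in MODELS:
            row[f"aicc_{m}"] = fits[m].aicc
        row.update(
            best_h0=call.best_h0[0],
            best_h1=call.best_h1[0],
            delta_aicc=call.delta_aicc,
            positive=call.positive,
            direction=call.direction or "",
        )
        for regime in sorted(clade_map):
            row[f"mean_{regime}"] = means[regime]
        sel_rows.append(row)
    sel_cols = (
        ["family_id", "category"]
        + [f"aicc_{m}" for m in MODELS]
        + ["best_h0", "best_h1", "delta_aicc", "positive", "direction"]
        + [f"mean_{r}" for r in sorted(clade_map)]
    )
    selection_frame = pd.DataFrame(sel_rows, columns=sel_cols)

    # enrichment per direction, against the full analyzed background
    categories = sorted(
        {c for c in assignment.mapping.values()}
    )
    analyzed = set(table.family_ids)
    enr_rows = []
    for di, direction in enumerate(sorted(clade_map)):
        pos = set(selection_frame.loc[
            selection_frame["positive"]
            & (selection_frame["direction"] == direction),
            "family_id",
        ])
        background = BackgroundResults(total=len(analyzed), positives=len(pos))
        cat_nk = []
        for cat in categories:
            fams = [f for f in assignment.families_in(cat) if f in analyzed]
            cat_nk.append((len(fams), len([f for f in fams if f in pos])))
        if categories:
            p_raw = permutation_enrichment(
                background, cat_nk, n_draws=n_draws, seed=seed + 2 + di
            )
            fdr = bh_adjust(p_raw)
        else:
            p_raw, fdr = [], np.array([])
        for cat, (n, k), p, q in zip(categories, cat_nk, p_raw, fdr):
            enr_rows.append(
                {
                    "direction": direction,
                    "category": cat,
                    "n_category": n,
                    "k_positive": k,
                    "p_raw": p,
                    "fdr": q,
                    "background": f"{len(pos)}/{len(analyzed)}",
                }
            )
    enrichment_frame = pd.DataFrame(
        enr_rows,
        columns=[
            "direction", "category", "n_category", "k_positive",
            "p_raw", "fdr", "background",
        ],
    )

    node_rows = []
    if node_summaries:
        candidate_fams = {f for f in analyzed if assignment.category_of(f) != BACKGROUND}
        for scope, subset in (("all", None), ("candidates", candidate_fams)):
            if subset is not None and not subset:
                continue
            for s in summarize_node_changes(
                table, ptree, fit_distinct.params, only_families=subset
            ):
                node_rows.append(
                    {
                        "scope": scope,
                        "node_id": s.node_id,
                        "n_expanding": s.n_expanding,
                        "n_contracting": s.n_contracting,
                    }
                )
    node_frame = pd.DataFrame(
        node_rows, columns=["scope", "node_id", "n_expanding", "n_contracting"]
    )

    provenance = {
        "seed": seed,
        "p_threshold": p_threshold,
        "n_sim": n_sim,
        "n_draws": n_draws,
        "epsilon": epsilon,
        "n_starts": n_starts,
    }
    return ReportBundle(
        fit_single=fit_single,
        fit_distinct=fit_distinct,
        lrt=lrt,
        family_frame=family_frame,
        selection_frame=selection_frame,
        enrichment_frame=enrichment_frame,
        node_frame=node_frame,
        provenance=provenance,
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """File-based front end: read inputs, analyze, write the report tables."""
    ptree = read_newick(config.tree)
    table = read_count_table(config.counts)
    clade_map, root_regime = load_groups(config.groups)
    assignment = None
    if config.candidates:
        cand = pd.read_csv(config.candidates, sep="\t", dtype=str)
        if not {"family_id", "category"} <= set(cand.columns):
            raise ValueError("candidates file needs family_id and category columns")
        assignment = CategoryAssignment(
            dict(zip(cand["family_id"], cand["category"]))
        )
    bundle = analyze(
        table,
        ptree,
        clade_map=clade_map,
        root_regime=root_regime,
        assignment=assignment,
        p_threshold=config.p_threshold,
        n_sim=config.n_sim,
        n_draws=config.n_draws,
        seed=config.seed,
        epsilon=config.epsilon,
        n_starts=config.n_starts,
        root_prior_max=config.root_prior_max,
    )
    write_results(bundle.to_tables(), config.out_dir)
    return bundle
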