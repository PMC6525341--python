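"""Ultrametric species trees with selective-regime paintings.

The tree is the scaffold for every stage of the analysis: gene gain/loss
likelihoods integrate birth-death transition probabilities along its
branches, and the trait models (BM/OU) build their covariance structure
from shared root-to-tip path lengths.  Branch lengths are in millions of
years (My).

A :class:`PaintedTree` is a rooted ultrametric tree in which every tip is
assigned to exactly one *regime* (a contiguous clade sharing model
parameters, e.g. a beetle suborder) and the root carries its own regime
label.  Edge regimes are derived from the tip partition: every edge whose
descendant tips all belong to one clade — including the clade's stem edge —
carries that clade's label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PaintedTree",
    "read_newick",
    "write_newick",
    "validate_ultrametric",
    "prune_tree",
    "scale_tree_depth",
    "paint_regimes",
    "tree_vcv",
]


class TreeError(ValueError):
    """Raised for malformed, non-ultrametric or inconsistently painted trees."""


@dataclass
class PaintedTree:
    """Rooted tree (branch lengths in My) with an optional regime painting.

    Parameters
    ----------
    tree:
        The underlying :class:`dendropy.Tree`; treated as rooted.
    clade_map:
        Mapping ``regime label -> frozenset of tip labels``.  Empty until
        :func:`paint_regimes` is applied.  Clades must be disjoint,
        monophyletic, and jointly cover all tips.
    root_regime:
        Label attached to the root node itself (the painting convention
        places the regime switch on each clade's stem edge, so the root
        node is the only point carrying this label).
    """

    tree: dendropy.Tree
    clade_map: dict[str, frozenset[str]] = field(default_factory=dict)
    root_regime: str | None = None

    # -- basic queries -------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def is_painted(self) -> bool:
        return bool(self.clade_map)

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance of every node from the root."""
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                bl = node.edge.length
                if bl is None:
                    raise TreeError(f"edge above {describe_node(node)} has no length")
                depths[node] = depths[node.parent_node] + bl
        return depths

    def regime_of_tip(self, label: str) -> str:
        for regime, tips in self.clade_map.items():
            if label in tips:
                return regime
        raise TreeError(f"tip {label!r} not covered by the regime painting")

    def edge_regimes(self) -> dict[dendropy.Node, str]:
        """Regime per edge, keyed by the edge's head (child) node.

        Every edge lies inside exactly one painted clade (the stem edge of
        a clade inherits the clade's regime); the root node is not an edge
        and carries :attr:`root_regime` separately.
        """
        if not self.is_painted:
            raise TreeError("tree is not painted with regimes")
        regimes: dict[dendropy.Node, str] = {}
        # postorder: regime of an edge = regime shared by all descendant tips
        tipsets: dict[dendropy.Node, frozenset[str]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[node] = frozenset([node.taxon.label])
            else:
                tipsets[node] = frozenset().union(
                    *(tipsets[c] for c in node.child_nodes())
                )
            if node.parent_node is None:
                continue
            for regime, tips in self.clade_map.items():
                if tipsets[node] <= tips:
                    regimes[node] = regime
                    break
            else:
                raise TreeError(
                    f"edge above {describe_node(node)} spans multiple regimes; "
                    "painting is not contiguous"
                )
        return regimes

    def copy(self) -> "PaintedTree":
        return PaintedTree(
            tree=self.tree.clone(depth=1),
            clade_map=dict(self.clade_map),
            root_regime=self.root_regime,
        )


def describe_node(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    tips = [lf.taxon.label for lf in node.leaf_iter()]
    return "mrca(" + ",".join(sorted(tips)[:3]) + ("..." if len(tips) > 3 else "") + ")"


# ---------------------------------------------------------------------------
# I/O


def read_newick(source: str) -> PaintedTree:
    """Parse a newick string (or path to a newick file) into a PaintedTree.

    Labels are preserved verbatim (no underscore munging); support values on
    internal nodes are tolerated and ignored; branch lengths are required
    downstream but not at parse time.  Regimes are left unset.
    """
    text = source
    if "(" not in source:  # a path, not newick data
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc
    tree.is_rooted = True
    return PaintedTree(tree=tree)


def write_newick(ptree: PaintedTree) -> str:
    """Serialize to newick with branch lengths; regimes are not embedded."""
    out = io.StringIO()
    ptree.tree.write(
        file=out,
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    return out.getvalue().strip() + "\n"


# ---------------------------------------------------------------------------
# Validation and manipulation


def validate_ultrametric(ptree: PaintedTree, rel_tol: float = 1e-6) -> float:
    """Check all tips are equidistant from the root; return that depth (My).

    Deviations up to ``rel_tol`` times the maximum depth are accepted
    (inclusive), which absorbs rounding introduced by newick serialization
    of time-calibrated trees.
    """
    depths = ptree.node_depths()
    tip_depths = {
        lf.taxon.label: depths[lf] for lf in ptree.tree.leaf_node_iter()
    }
    dmax = max(tip_depths.values())
    if dmax <= 0:
        raise TreeError("tree has zero depth")
    if dmax - min(tip_depths.values()) > rel_tol * dmax:
        med = float(np.median(list(tip_depths.values())))
        bad = {
            label: d
            for label, d in tip_depths.items()
            if abs(d - med) > rel_tol * dmax
        }
        worst = sorted(bad, key=lambda k: abs(bad[k] - med), reverse=True)
        raise TreeError(
            "tree is not ultrametric at relative tolerance "
            f"{rel_tol:g}; offending tips: "
            + ", ".join(f"{t} (depth {bad[t]:.6g} vs {med:.6g})" for t in worst)
        )
    return float(np.mean(list(tip_depths.values())))


def prune_tree(ptree: PaintedTree, keep: set[str]) -> PaintedTree:
    """Induced subtree on ``keep``; unifurcations suppressed, lengths summed.

    Tip depths (and hence ultrametricity) are preserved.  A painting, if
    present, is restricted to the kept tips; regimes emptied by the pruning
    are dropped.
    """
    keep = set(keep)
    tips = set(ptree.tip_labels)
    unknown = keep - tips
    if unknown:
        raise TreeError(f"unknown tips in keep set: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least two tips to keep")
    new = ptree.tree.extract_tree_with_taxa_labels(labels=keep)
    new.is_rooted = True
    clade_map = {
        regime: frozenset(t for t in tipset if t in keep)
        for regime, tipset in ptree.clade_map.items()
    }
    clade_map = {r: s for r, s in clade_map.items() if s}
    return PaintedTree(tree=new, clade_map=clade_map, root_regime=ptree.root_regime)


def scale_tree_depth(ptree: PaintedTree, target_depth: float) -> PaintedTree:
    """Rescale all branch lengths so the root-to-tip depth equals ``target_depth``.

    Used to pin a relative chronogram to an absolute age (e.g. a ~250 My
    crown group).  The input must already be ultrametric.
    """
    if target_depth <= 0:
        raise TreeError("target depth must be positive")
    depth = validate_ultrametric(ptree)
    factor = target_depth / depth
    out = ptree.copy()
    for edge in out.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return out


def paint_regimes(
    ptree: PaintedTree,
    clade_map: dict[str, set[str] | frozenset[str]],
    root_regime: str,
) -> PaintedTree:
    """Assign a regime to every edge by declaring monophyletic tip groups.

    ``clade_map`` maps each regime label to its tip set; the sets must be
    disjoint, jointly cover all tips, and each be monophyletic.  Each
    clade's stem edge inherits the clade's regime (the regime switch is
    placed at the stem); the root node itself receives ``root_regime``.
    """
    tips = set(ptree.tip_labels)
    seen: set[str] = set()
    fmap: dict[str, frozenset[str]] = {}
    for regime, tipset in clade_map.items():
        tipset = frozenset(tipset)
        if tipset & seen:
            raise TreeError(f"regime {regime!r} overlaps another regime's tips")
        unknown = tipset - tips
        if unknown:
            raise TreeError(f"regime {regime!r} lists unknown tips {sorted(unknown)}")
        seen |= tipset
        fmap[regime] = tipset
    if seen != tips:
        raise TreeError(f"painting does not cover tips {sorted(tips - seen)}")
    taxa = ptree.tree.taxon_namespace
    for regime, tipset in fmap.items():
        if len(tipset) == len(tips):
            continue  # whole tree: trivially monophyletic
        mrca = ptree.tree.mrca(taxa=[taxa.get_taxon(t) for t in tipset])
        clade_tips = {lf.taxon.label for lf in mrca.leaf_iter()}
        if clade_tips != set(tipset):
            raise TreeError(
                f"regime {regime!r} is not monophyletic: its mrca also contains "
                f"{sorted(clade_tips - set(tipset))}"
            )
    out = ptree.copy()
    out.clade_map = fmap
    out.root_regime = root_regime
    out.edge_regimes()  # raises if painting is not contiguous
    return out


def tree_vcv(ptree: PaintedTree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion base covariance: shared root-to-tip path lengths.

    Returns ``(tip_labels, V)`` where ``V[i, j]`` is the depth of the MRCA
    of tips i and j (My) and the diagonal is the root depth.  Symmetric and
    positive semi-definite by construction.
    """
    depths = ptree.node_depths()
    leaves = list(ptree.tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    # For each internal node: pairs of tips whose MRCA is exactly that node
    # are pairs drawn from different child subtrees.
    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in ptree.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[node]]
            V[index[node], index[node]] = depths[node]
            continue
        children = node.child_nodes()
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = tipsets[children[a]]
                ib = tipsets[children[b]]
                for i in ia:
                    V[i, ib] = depths[node]
                    V[ib, i] = depths[node]
        tipsets[node] = [i for c in children for i in tipsets[c]]
    return labels, V
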