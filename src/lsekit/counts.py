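"""Gene-family count tables, annotation tables and the two input filters.

The central observable of the whole analysis is the family-by-species
matrix of gene counts (one row per orthologous group, one column per
taxon).  Two filters defined here shape the analysis set:

* :func:`filter_shared_families` keeps only families with at least one
  gene in *both* of two species groups (e.g. both sampled suborders), so
  that every retained family has an evolutionary history traceable to the
  groups' last common ancestor.
* :func:`select_candidate_ogs` assigns families to candidate functional
  categories (detoxification/digestion enzyme families and transporters)
  from a pre-computed annotation table, using per-category identifier sets
  (Pfam/InterPro/GO accessions) combined with case-insensitive keyword
  matches on sequence-cluster names.  Both kinds of evidence are required
  on the same gene for an assignment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_ORDER",
    "DEFAULT_CATEGORY_RULES",
    "FamilyCountTable",
    "CategoryRule",
    "AnnotationRecord",
    "AnnotationTable",
    "CategoryAssignment",
    "read_count_table",
    "write_count_table",
    "read_annotation_table",
    "filter_shared_families",
    "select_candidate_ogs",
    "write_results",
]

BACKGROUND = "background"

# Canonical candidate-category order used to break assignment ties: the
# detoxification/digestion gene families screened for adaptive expansion.
CATEGORY_ORDER = ("UGT", "P450", "CE", "GST", "SER", "CYS", "ABC", "GH")


class CountTableError(ValueError):
    """Raised for malformed count or annotation tables."""


@dataclass
class FamilyCountTable:
    """Families x species matrix of non-negative integer gene counts."""

    family_ids: list[str]
    species_ids: list[str]
    counts: np.ndarray  # (n_families, n_species) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.family_ids), len(self.species_ids)):
            raise CountTableError("counts shape does not match id lists")
        if len(set(self.family_ids)) != len(self.family_ids):
            raise CountTableError("duplicate family ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise CountTableError("duplicate species ids")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise CountTableError(
                f"negative count at family {self.family_ids[i]!r}, "
                f"species {self.species_ids[j]!r}"
            )

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.family_ids, name="family_id"),
            columns=self.species_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FamilyCountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def row(self, family_id: str) -> dict[str, int]:
        i = self.family_ids.index(family_id)
        return dict(zip(self.species_ids, self.counts[i]))

    def subset(self, family_ids: list[str]) -> "FamilyCountTable":
        idx = {f: i for i, f in enumerate(self.family_ids)}
        rows = [idx[f] for f in family_ids]
        return FamilyCountTable(list(family_ids), list(self.species_ids),
                                self.counts[rows])

    def reorder_species(self, species_ids: list[str]) -> "FamilyCountTable":
        if set(species_ids) != set(self.species_ids):
            raise CountTableError("species sets differ; cannot reorder")
        cols = [self.species_ids.index(s) for s in species_ids]
        return FamilyCountTable(list(self.family_ids), list(species_ids),
                                self.counts[:, cols])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FamilyCountTable):
            return NotImplemented
        return (
            self.family_ids == other.family_ids
            and self.species_ids == other.species_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class CategoryRule:
    """Selection rule for one candidate category.

    A family joins the category if at least one of its genes carries BOTH
    an accession in ``identifier_set`` (Pfam/InterPro/GO) AND a cluster
    name containing one of ``keyword_patterns`` (case-insensitive
    substring match).
    """

    category_name: str
    identifier_set: frozenset[str]
    keyword_patterns: frozenset[str]

    def __post_init__(self) -> None:
        if not self.identifier_set or not self.keyword_patterns:
            raise CountTableError(
                f"rule {self.category_name!r}: identifiers and keywords "
                "must both be non-empty"
            )


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    family_id: str
    identifier_hits: frozenset[str]
    cluster_name_hits: frozenset[str]


@dataclass
class AnnotationTable:
    records: list[AnnotationRecord]

    def validate_against(self, table: FamilyCountTable) -> None:
        known = set(table.family_ids)
        for rec in self.records:
            if rec.family_id not in known:
                raise CountTableError(
                    f"annotation references unknown family {rec.family_id!r}"
                )


@dataclass
class CategoryAssignment:
    """family_id -> category name; unmapped families are background."""

    mapping: dict[str, str] = field(default_factory=dict)

    def category_of(self, family_id: str) -> str:
        return self.mapping.get(family_id, BACKGROUND)

    def families_in(self, category: str) -> list[str]:
        return sorted(f for f, c in self.mapping.items() if c == category)


# ---------------------------------------------------------------------------
# Readers / writers


def read_count_table(path: str | os.PathLike) -> FamilyCountTable:
    """Read a TSV count matrix: header of species labels, first column the
    family id.  A leading "Desc" column (a common dialect carrying free-text
    family descriptions) is tolerated and dropped.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise CountTableError(f"{path}: need a family-id column plus species")
    cols = list(df.columns)
    drop = [c for c in cols[:2] if c.strip().lower() in ("desc", "description")]
    fam_col = next(c for c in cols if c not in drop)
    species = [c for c in cols if c != fam_col and c not in drop]
    fam_ids = df[fam_col].astype(str).tolist()
    mat = np.zeros((len(fam_ids), len(species)), dtype=np.int64)
    for j, sp in enumerate(species):
        for i, raw in enumerate(df[sp]):
            try:
                v = int(str(raw).strip())
            except (TypeError, ValueError):
                raise CountTableError(
                    f"{path}: non-integer count {raw!r} at family "
                    f"{fam_ids[i]!r}, species {sp!r}"
                ) from None
            if v < 0:
                raise CountTableError(
                    f"{path}: negative count at family {fam_ids[i]!r}, "
                    f"species {sp!r}"
                )
            mat[i, j] = v
    return FamilyCountTable(fam_ids, species, mat)


def write_count_table(table: FamilyCountTable, path: str | os.PathLike) -> None:
    table.to_frame().to_csv(path, sep="\t")


def read_annotation_table(path: str | os.PathLike) -> AnnotationTable:
    """Read a gene annotation TSV with columns gene_id, family_id,
    identifiers (comma/; separated accessions), cluster_names
    (';'-separated cluster name strings).  Empty cells mean no hits.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    required = {"gene_id", "family_id", "identifiers", "cluster_names"}
    missing = required - set(df.columns)
    if missing:
        raise CountTableError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, r in df.iterrows():
        idents = frozenset(
            tok.strip() for tok in str(r["identifiers"]).replace(",", ";").split(";")
            if tok.strip()
        )
        names = frozenset(
            tok.strip() for tok in str(r["cluster_names"]).split(";") if tok.strip()
        )
        records.append(AnnotationRecord(r["gene_id"], r["family_id"], idents, names))
    return AnnotationTable(records)


# ---------------------------------------------------------------------------
# Filters


def filter_shared_families(
    table: FamilyCountTable, group_map: dict[str, str]
) -> FamilyCountTable:
    """Keep families with at least one gene in each of the two groups.

    ``group_map`` maps every species to one of exactly two group labels.
    Families whose genes are confined to a single group (or absent
    entirely) are removed; row order is preserved.  Idempotent.
    """
    missing = [s for s in table.species_ids if s not in group_map]
    if missing:
        raise CountTableError(f"group_map missing species {missing}")
    groups = sorted(set(group_map[s] for s in table.species_ids))
    if len(groups) != 2:
        raise CountTableError(f"expected exactly two groups, got {groups}")
    masks = [
        np.array([group_map[s] == g for s in table.species_ids]) for g in groups
    ]
    keep = (table.counts[:, masks[0]].sum(axis=1) >= 1) & (
        table.counts[:, masks[1]].sum(axis=1) >= 1
    )
    fam = [f for f, k in zip(table.family_ids, keep) if k]
    return FamilyCountTable(fam, list(table.species_ids), table.counts[keep])


def _gene_matches(rec: AnnotationRecord, rule: CategoryRule) -> bool:
    if not (rec.identifier_hits & rule.identifier_set):
        return False
    names = [n.lower() for n in rec.cluster_name_hits]
    return any(pat.lower() in n for pat in rule.keyword_patterns for n in names)


def select_candidate_ogs(
    annotations: AnnotationTable, rules: list[CategoryRule]
) -> CategoryAssignment:
    """Assign families to candidate categories by the two-evidence rule.

    A family is assigned to a category iff at least one of its genes has
    both an identifier hit in the category's identifier set and a cluster
    name containing one of its keywords.  If a family satisfies several
    rules it is assigned the category with the most matching genes; any
    remaining tie resolves by the canonical :data:`CATEGORY_ORDER` (other
    category names sort alphabetically after it), so the outcome is
    deterministic and invariant both to the order of ``rules`` and to the
    row order of the annotation table.
    """
    names = [r.category_name for r in rules]
    if len(set(names)) != len(names):
        raise CountTableError("category rule names must be distinct")
    per_family: dict[str, dict[str, int]] = {}
    for rec in annotations.records:
        for rule in rules:
            if _gene_matches(rec, rule):
                per_family.setdefault(rec.family_id, {}).setdefault(
                    rule.category_name, 0
                )
                per_family[rec.family_id][rule.category_name] += 1
    canon = {name: i for i, name in enumerate(CATEGORY_ORDER)}

    def tie_key(name: str):
        return canon.get(name, len(CATEGORY_ORDER)), name

    mapping = {}
    for fam, hits in per_family.items():
        best = sorted(hits, key=lambda c: (-hits[c],) + tie_key(c))[0]
        mapping[fam] = best
    return CategoryAssignment(mapping)


#: Selection rules for the eight candidate detoxification/digestion
#: categories: Pfam/InterPro/GO accessions plus UniRef cluster-name
#: keywords.  Both kinds of evidence are required on the same gene.
DEFAULT_CATEGORY_RULES: list[CategoryRule] = [
    CategoryRule("UGT", frozenset({"PF00201"}),
                 frozenset({"UDP glucuronosyltransferase",
                            "UDP glycosyltransferase"})),
    CategoryRule("P450", frozenset({"PF00067"}),
                 frozenset({"Cytochrome P450"})),
    CategoryRule("CE", frozenset({"PF02230", "PF00135"}),
                 frozenset({"carboxylesterase", "carboxylic ester hydrolase"})),
    CategoryRule("GST", frozenset({"PF00043", "PF02798"}),
                 frozenset({"Glutathione S-transferase"})),
    CategoryRule("SER", frozenset({"PF00450", "PF12146", "PF05577",
                                   "GO:0008236"}),
                 frozenset({"Serine protease", "Serine peptidase"})),
    CategoryRule("CYS", frozenset({"PF00112"}),
                 frozenset({"cysteine protease", "cystein protease", "Papain"})),
    CategoryRule("ABC", frozenset({"PF00005", "PF00664"}),
                 frozenset({"ABC"})),
    CategoryRule("GH", frozenset({"IPR000334", "IPR000743", "IPR001360",
                                  "IPR001547"}),
                 frozenset({"Glycoside hydrolase"})),
]


# ---------------------------------------------------------------------------
# Result output


def write_results(bundle: dict[str, pd.DataFrame | str], out_dir: str) -> list[str]:
    """Write result tables as TSV plus the run summary as structured text.

    ``bundle`` maps a result name to either a DataFrame (written as
    ``<name>.tsv`` with a deterministic column order — the frame's own) or
    a string (written as ``<name>.txt``).  Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name in sorted(bundle):
        obj = bundle[name]
        if isinstance(obj, pd.DataFrame):
            path = os.path.join(out_dir, f"{name}.tsv")
            obj.to_csv(path, sep="\t", index=False)
        else:
            path = os.path.join(out_dir, f"{name}.txt")
            with open(path, "w") as fh:
                fh.write(str(obj))
                if not str(obj).endswith("\n"):
                    fh.write("\n")
        paths.append(path)
    return paths
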