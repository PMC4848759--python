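"""Cross-atlas concordance of two independent gene classifications.

Two atlases (e.g. a tissue panel profiled by two consortia) rarely share an
identical tissue vocabulary — one may profile "brain" as a single tissue where
the other has cerebellum, cortex and pituitary — so per-tissue comparisons go
through a many-to-many :class:`TissueMapping`.

Three comparisons are provided, all restricted to the gene ids present in both
classifications:

* a 6x6 category cross-tabulation;
* the overlap of "expressed in all tissues" calls (and, for genes called
  expressed-in-all by only one atlas, how the other atlas classified them);
* per-tissue agreement of tissue-enriched calls: a gene enriched in tissue t
  of atlas A agrees ("both") when atlas B elevates it in a mapped partner
  tissue, by default under any of the three elevated categories
  (``mode="elevated"``), or only when B also calls it tissue-enriched there
  (``mode="strict"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .classify import (
    CATEGORIES,
    ELEVATED_CATEGORIES,
    EXPRESSED_IN_ALL,
    TISSUE_ENRICHED,
    GeneClassification,
)
from .errors import ConfigurationError, InputError, MappingError
from .expression_io import write_table

__all__ = [
    "TissueMapping",
    "ConcordanceResult",
    "intersect_genes",
    "category_crosstab",
    "expressed_in_all_overlap",
    "elevated_overlap",
    "elevated_tissue_agreement",
    "compare",
    "read_mapping",
]

UNMAPPED = "unmapped"


@dataclass
class TissueMapping:
    """Many-to-many pairs (tissue in A, tissue in B)."""

    pairs: list[tuple[str, str]]

    @classmethod
    def identity(cls, tissues: Iterable[str]) -> "TissueMapping":
        return cls([(t, t) for t in tissues])

    def partners_of_a(self, tissue_a: str) -> set[str]:
        return {b for a, b in self.pairs if a == tissue_a}

    def partners_of_b(self, tissue_b: str) -> set[str]:
        return {a for a, b in self.pairs if b == tissue_b}

    def transpose(self) -> "TissueMapping":
        return TissueMapping([(b, a) for a, b in self.pairs])

    def validate(self, tissues_a: set[str], tissues_b: set[str]) -> None:
        bad_a = {a for a, _ in self.pairs} - tissues_a
        bad_b = {b for _, b in self.pairs} - tissues_b
        if bad_a or bad_b:
            raise MappingError(
                f"mapping references unknown tissues: A={sorted(bad_a)}, B={sorted(bad_b)}"
            )


def read_mapping(path: str | Path) -> TissueMapping:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MappingError(f"{path}: mapping needs tissue_a and tissue_b columns")
    return TissueMapping([(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])])


def _index(classes: Sequence[GeneClassification], label: str) -> dict[str, GeneClassification]:
    idx: dict[str, GeneClassification] = {}
    for rec in classes:
        if rec.gene_id in idx:
            raise InputError(f"duplicate gene id {rec.gene_id!r} in classification {label}")
        idx[rec.gene_id] = rec
    return idx


def intersect_genes(
    a: Sequence[GeneClassification], b: Sequence[GeneClassification]
) -> list[str]:
    """Gene ids classified in both atlases, sorted lexicographically."""
    return sorted(set(_index(a, "A")) & set(_index(b, "B")))


def category_crosstab(
    a: Sequence[GeneClassification],
    b: Sequence[GeneClassification],
    shared: Sequence[str] | None = None,
) -> pd.DataFrame:
    """6x6 count matrix: rows are A's categories, columns B's."""
    ia, ib = _index(a, "A"), _index(b, "B")
    if shared is None:
        shared = sorted(set(ia) & set(ib))
    tab = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES), dtype=int)
    for g in shared:
        tab.loc[ia[g].category, ib[g].category] += 1
    tab.index.name = "category_a"
    tab.columns.name = "category_b"
    return tab


def _status_overlap(
    ia: dict[str, GeneClassification],
    ib: dict[str, GeneClassification],
    shared: Sequence[str],
    in_status,
) -> dict:
    both = only_a = only_b = 0
    by_cat_a = {c: 0 for c in CATEGORIES}  # B's category for genes only in A's set
    by_cat_b = {c: 0 for c in CATEGORIES}
    for g in shared:
        sa, sb = in_status(ia[g]), in_status(ib[g])
        if sa and sb:
            both += 1
        elif sa:
            only_a += 1
            by_cat_a[ib[g].category] += 1
        elif sb:
            only_b += 1
            by_cat_b[ia[g].category] += 1
    return {
        "both": both,
        "only_a": only_a,
        "only_b": only_b,
        "only_a_by_other_category": by_cat_a,
        "only_b_by_other_category": by_cat_b,
    }


def expressed_in_all_overlap(
    a: Sequence[GeneClassification],
    b: Sequence[GeneClassification],
    shared: Sequence[str] | None = None,
) -> dict:
    """Overlap of expressed-in-all calls, with the discordant genes broken down
    by the category the other atlas assigned them."""
    ia, ib = _index(a, "A"), _index(b, "B")
    if shared is None:
        shared = sorted(set(ia) & set(ib))
    return _status_overlap(ia, ib, shared, lambda r: r.category == EXPRESSED_IN_ALL)


def elevated_overlap(
    a: Sequence[GeneClassification],
    b: Sequence[GeneClassification],
    shared: Sequence[str] | None = None,
) -> dict:
    """Overlap of tissue-elevated calls (any of the three elevated categories)."""
    ia, ib = _index(a, "A"), _index(b, "B")
    if shared is None:
        shared = sorted(set(ia) & set(ib))
    return _status_overlap(ia, ib, shared, lambda r: r.category in ELEVATED_CATEGORIES)


def _is_elevated_in(rec: GeneClassification, tissues: set[str], mode: str) -> bool:
    if mode == "strict":
        return rec.category == TISSUE_ENRICHED and bool(set(rec.elevated_tissues) & tissues)
    return rec.category in ELEVATED_CATEGORIES and bool(set(rec.elevated_tissues) & tissues)


def elevated_tissue_agreement(
    a: Sequence[GeneClassification],
    b: Sequence[GeneClassification],
    mapping: TissueMapping,
    mode: str = "elevated",
) -> pd.DataFrame:
    """Per-tissue agreement of tissue-enriched calls between the two atlases.

    For each gene tissue-enriched in A at tissue t, the call counts as "both"
    for t's group when B elevates the gene in a mapped partner of t, otherwise
    as "only_a"; symmetrically, a gene tissue-enriched in B at u contributes
    to the A-side tissue(s) mapped to u.  Tissue groups are keyed by the
    A-side label; enriched calls in tissues absent from the mapping accumulate
    under an ``unmapped`` row.  A gene enriched in several tissues contributes
    to each of their groups.
    """
    if mode not in ("elevated", "strict"):
        raise ConfigurationError(f"unknown agreement mode {mode!r}")
    ia, ib = _index(a, "A"), _index(b, "B")
    shared = sorted(set(ia) & set(ib))
    rows: dict[str, dict[str, int]] = {}

    def bump(tissue: str, key: str) -> None:
        row = rows.setdefault(tissue, {"both": 0, "only_a": 0, "only_b": 0})
        row[key] += 1

    for g in shared:
        ra, rb = ia[g], ib[g]
        if ra.category == TISSUE_ENRICHED:
            for t in ra.elevated_tissues:
                partners = mapping.partners_of_a(t)
                if not partners:
                    bump(UNMAPPED, "only_a")
                elif _is_elevated_in(rb, partners, mode):
                    bump(t, "both")
                else:
                    bump(t, "only_a")
        if rb.category == TISSUE_ENRICHED:
            for u in rb.elevated_tissues:
                groups = mapping.partners_of_b(u)
                if not groups:
                    bump(UNMAPPED, "only_b")
                    continue
                key = "both" if _is_elevated_in(ra, groups, mode) else "only_b"
                for t in sorted(groups):
                    bump(t, key)

    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if df.empty:
        df = pd.DataFrame(columns=["both", "only_a", "only_b"], dtype=int)
    df.index.name = "tissue"
    return df


@dataclass
class ConcordanceResult:
    """Bundle of all cross-atlas comparisons on the shared gene universe."""

    shared_gene_count: int
    category_crosstab: pd.DataFrame
    expressed_in_all_overlap: dict
    elevated_overlap: dict
    per_tissue_elevated: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: str | Path, prefix: str = "concordance") -> None:
        outdir = Path(outdir)
        self.category_crosstab.to_csv(outdir / f"{prefix}_crosstab.tsv", sep="\t")
        rows = [
            {"tissue": t, **{k: int(v) for k, v in row.items()}}
            for t, row in self.per_tissue_elevated.iterrows()
        ]
        if rows:
            write_table(rows, outdir / f"{prefix}_per_tissue.tsv")
        else:
            write_table(
                pd.DataFrame(columns=["tissue", "both", "only_a", "only_b"]),
                outdir / f"{prefix}_per_tissue.tsv",
            )
        overlap_rows = []
        for name, ov in (
            ("expressed_in_all", self.expressed_in_all_overlap),
            ("elevated", self.elevated_overlap),
        ):
            overlap_rows.append(
                {
                    "status": name,
                    "both": ov["both"],
                    "only_a": ov["only_a"],
                    "only_b": ov["only_b"],
                }
            )
        write_table(overlap_rows, outdir / f"{prefix}_overlap.tsv")


def compare(
    a: Sequence[GeneClassification],
    b: Sequence[GeneClassification],
    mapping: TissueMapping | None = None,
    mode: str = "elevated",
) -> ConcordanceResult:
    """Run all concordance comparisons; with no mapping, tissue labels are
    matched by identity."""
    shared = intersect_genes(a, b)
    ia, ib = _index(a, "A"), _index(b, "B")
    if mapping is None:
        tissues = {t for r in list(a) + list(b) for t in r.elevated_tissues}
        mapping = TissueMapping.identity(sorted(tissues))
    return ConcordanceResult(
        shared_gene_count=len(shared),
        category_crosstab=category_crosstab(a, b, shared),
        expressed_in_all_overlap=expressed_in_all_overlap(a, b, shared),
        elevated_overlap=elevated_overlap(a, b, shared),
        per_tissue_elevated=elevated_tissue_agreement(a, b, mapping, mode=mode),
    )
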