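"""Six-category tissue-specificity classification of protein-coding genes.

Every gene is assigned exactly one category from its per-tissue FPKM profile,
using a detection cutoff (default 0.5 FPKM) and a fold factor (default 5):

* ``tissue_enriched`` — at least fivefold higher FPKM in one tissue than in
  every other tissue;
* ``group_enriched`` — mean FPKM over a group of 2-7 tissues at least fivefold
  above every tissue outside the group;
* ``enhanced`` — at least fivefold higher FPKM in some tissue than the
  average across all tissues, without meeting either criterion above;
* ``expressed_in_all`` — detected (>= cutoff) in every tissue;
* ``mixed`` — detected in some tissues only, meeting no elevation criterion;
* ``not_detected`` — below the cutoff everywhere.

Rules are evaluated in that order and the first match wins, which makes the
categories mutually exclusive and the classification a partition.  All fold
comparisons are multiplicative (``x >= fold * reference``) so a zero
reference is well defined; reported fold scores guard the denominator at
``cutoff / fold``.

The group search only ever inspects the top-k tissues by value for each group
size k: the top-k set simultaneously maximizes the group mean, minimizes the
maximum outside the group, and, if its smallest member is below the cutoff,
no other size-k subset can clear the cutoff either.  Checking top-k per k is
therefore equivalent to exhaustive search over all tissue subsets (a property
the test suite verifies against brute-force enumeration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, MatrixValueError
from .expression_io import ExpressionMatrix, write_table

__all__ = [
    "CATEGORIES",
    "ELEVATED_CATEGORIES",
    "ClassifierParams",
    "GeneClassification",
    "ClassificationSummary",
    "classify_gene",
    "classify_matrix",
    "summarize",
    "summary_from_counts",
    "write_classifications",
    "read_classifications",
    "write_summary",
]

TISSUE_ENRICHED = "tissue_enriched"
GROUP_ENRICHED = "group_enriched"
ENHANCED = "enhanced"
EXPRESSED_IN_ALL = "expressed_in_all"
MIXED = "mixed"
NOT_DETECTED = "not_detected"

#: Canonical category order used in every summary and cross-tabulation.
CATEGORIES: tuple[str, ...] = (
    TISSUE_ENRICHED,
    GROUP_ENRICHED,
    ENHANCED,
    EXPRESSED_IN_ALL,
    MIXED,
    NOT_DETECTED,
)

#: The three categories whose union the atlas literature calls "elevated".
ELEVATED_CATEGORIES: tuple[str, ...] = (TISSUE_ENRICHED, GROUP_ENRICHED, ENHANCED)

#: Human-readable rule labels, mirrored in the summary table.
CATEGORY_DEFINITIONS: dict[str, str] = {
    TISSUE_ENRICHED: "At least fivefold higher FPKM in one tissue than in all other tissues",
    GROUP_ENRICHED: "At least fivefold higher mean FPKM in a group of tissues than outside it",
    ENHANCED: "At least fivefold higher FPKM in a tissue than the average over all tissues",
    EXPRESSED_IN_ALL: "Detected in all tissues",
    MIXED: "Detected in some but not all tissues, no elevation criterion met",
    NOT_DETECTED: "Below the detection cutoff in every tissue",
}


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds driving the classification.

    cutoff
        FPKM detection threshold; a gene is "detected" in a tissue when its
        value is >= cutoff.  Default 0.5 FPKM.
    fold
        Enrichment factor for all three elevated rules.  Default 5.
    group_min, group_max
        Smallest and largest group size considered by the group-enriched
        search.  Defaults 2 and 7.
    """

    cutoff: float = 0.5
    fold: float = 5.0
    group_min: int = 2
    group_max: int = 7

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ConfigurationError("cutoff must be non-negative")
        if self.fold <= 1:
            raise ConfigurationError("fold must exceed 1")
        if not (2 <= self.group_min <= self.group_max):
            raise ConfigurationError("need 2 <= group_min <= group_max")


@dataclass
class GeneClassification:
    """Category call for one gene.

    ``elevated_tissues`` is non-empty only for the three elevated categories
    (exactly one tissue for tissue_enriched, the smallest satisfying group for
    group_enriched, every qualifying tissue for enhanced), sorted
    lexicographically.  ``fold_score`` is the rule's achieved fold ratio with
    the denominator guarded at ``cutoff / fold``; it is 0.0 for non-elevated
    categories.  ``n_detected`` counts tissues at or above the cutoff.
    """

    gene_id: str
    category: str
    elevated_tissues: tuple[str, ...] = ()
    fold_score: float = 0.0
    n_detected: int = 0


def _guarded_ratio(numerator: float, reference: float, params: ClassifierParams) -> float:
    denom = max(params.cutoff / params.fold, reference)
    if denom == 0.0:
        return float("inf") if numerator > 0 else 0.0
    return float(numerator / denom)


def classify_gene(
    values,
    tissues,
    params: ClassifierParams | None = None,
    gene_id: str = "gene",
) -> GeneClassification:
    """Classify one gene from its per-tissue FPKM vector.

    ``values`` and ``tissues`` are parallel sequences; ties in the descending
    value sort are broken lexicographically by tissue label so the result does
    not depend on column order.
    """
    params = params or ClassifierParams()
    v = np.asarray(values, dtype=float)
    tissues = [str(t) for t in tissues]
    n = v.size
    if n < 2:
        raise ConfigurationError("classification needs at least 2 tissues")
    if len(tissues) != n:
        raise ConfigurationError("values and tissues have different lengths")
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise MatrixValueError(f"gene {gene_id!r}: values must be finite and non-negative")
    cutoff, fold = params.cutoff, params.fold
    # a "group" must leave at least one tissue outside it
    group_max = min(params.group_max, n - 1)
    n_detected = int(np.count_nonzero(v >= cutoff))

    # (1) not detected anywhere
    if bool(np.all(v < cutoff)):
        return GeneClassification(gene_id, NOT_DETECTED, (), 0.0, n_detected)

    order = sorted(range(n), key=lambda i: (-v[i], tissues[i]))
    sv = v[order]

    # (2) tissue enriched: only the top tissue can be fold-above all others
    top, second = sv[0], sv[1]
    if top >= cutoff and top >= fold * second:
        return GeneClassification(
            gene_id,
            TISSUE_ENRICHED,
            (tissues[order[0]],),
            _guarded_ratio(top, second, params),
            n_detected,
        )

    # (3) group enriched: smallest k whose top-k tissues all clear the cutoff
    # and whose mean is fold-above everything outside the group
    for k in range(params.group_min, group_max + 1):
        group = sv[:k]
        rest_max = sv[k]
        if group[-1] >= cutoff and group.mean() >= fold * rest_max:
            members = tuple(sorted(tissues[i] for i in order[:k]))
            return GeneClassification(
                gene_id,
                GROUP_ENRICHED,
                members,
                _guarded_ratio(float(group.mean()), float(rest_max), params),
                n_detected,
            )

    # (4) enhanced: fold-above the mean over all tissues (candidate included)
    mean_all = float(v.mean())
    enhanced_mask = (v >= cutoff) & (v >= fold * mean_all)
    if enhanced_mask.any():
        members = tuple(sorted(tissues[i] for i in np.flatnonzero(enhanced_mask)))
        return GeneClassification(
            gene_id,
            ENHANCED,
            members,
            _guarded_ratio(float(v[enhanced_mask].max()), mean_all, params),
            n_detected,
        )

    # (5) detected everywhere
    if n_detected == n:
        return GeneClassification(gene_id, EXPRESSED_IN_ALL, (), 0.0, n_detected)

    # (6) everything else, including single-tissue sub-fivefold genes
    return GeneClassification(gene_id, MIXED, (), 0.0, n_detected)


def classify_matrix(
    m: ExpressionMatrix, params: ClassifierParams | None = None
) -> list[GeneClassification]:
    """Classify every gene of an expression matrix, in input gene order."""
    params = params or ClassifierParams()
    tissues = m.tissue_ids
    values = m.values.to_numpy()
    return [
        classify_gene(values[i], tissues, params, gene_id=g)
        for i, g in enumerate(m.gene_ids)
    ]


@dataclass
class ClassificationSummary:
    """Per-category counts, integer percentages, and per-tissue elevated counts."""

    counts: dict[str, int]
    total: int
    total_elevated: int
    percentages: dict[str, int]
    per_tissue: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "definition": [CATEGORY_DEFINITIONS[c] for c in CATEGORIES],
                "count": [self.counts[c] for c in CATEGORIES],
                "percent": [self.percentages[c] for c in CATEGORIES],
            }
        )


def _round_percent(count: int, total: int) -> int:
    # round half away from zero; round() would round half to even
    return int(np.floor(100.0 * count / total + 0.5))


def summary_from_counts(counts: dict[str, int]) -> ClassificationSummary:
    """Build a summary from per-category gene counts alone.

    Useful for checking published per-category tallies: totals, the elevated
    total, and rounded percentages follow arithmetically from the six counts.
    """
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
    full = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    total = sum(full.values())
    if total == 0:
        raise ConfigurationError("cannot summarize zero genes")
    elevated = sum(full[c] for c in ELEVATED_CATEGORIES)
    pct = {c: _round_percent(full[c], total) for c in CATEGORIES}
    return ClassificationSummary(full, total, elevated, pct)


def summarize(classes: list[GeneClassification]) -> ClassificationSummary:
    """Summarize a classification: category counts and per-tissue elevated counts.

    A gene contributes to the per-tissue count of every tissue in its elevated
    set (a group-enriched gene is counted once per member tissue).
    """
    if not classes:
        raise ConfigurationError("cannot summarize an empty classification")
    counts = {c: 0 for c in CATEGORIES}
    per_tissue: dict[str, dict[str, int]] = {}
    for rec in classes:
        counts[rec.category] += 1
        if rec.category in ELEVATED_CATEGORIES:
            for t in rec.elevated_tissues:
                row = per_tissue.setdefault(t, {c: 0 for c in ELEVATED_CATEGORIES})
                row[rec.category] += 1
    summary = summary_from_counts(counts)
    if per_tissue:
        pt = pd.DataFrame.from_dict(per_tissue, orient="index").sort_index()
        pt = pt[list(ELEVATED_CATEGORIES)]
        pt.index.name = "tissue"
        summary.per_tissue = pt
    return summary


# ---------------------------------------------------------------------------
# TSV round trip for classification results


def write_classifications(classes: list[GeneClassification], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "category": r.category,
            "elevated_tissues": ";".join(r.elevated_tissues),
            "fold_score": r.fold_score,
            "n_detected": r.n_detected,
        }
        for r in classes
    ]
    if rows:
        write_table(rows, path)
    else:
        write_table(
            pd.DataFrame(
                columns=["gene_id", "category", "elevated_tissues", "fold_score", "n_detected"]
            ),
            path,
        )


def read_classifications(path: str | Path) -> list[GeneClassification]:
    df = pd.read_csv(
        Path(path), sep="\t", dtype={"gene_id": str, "elevated_tissues": str}
    )
    required = {"gene_id", "category", "elevated_tissues", "fold_score", "n_detected"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    out = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if row.category not in CATEGORIES:
            raise FormatError(f"{path}: line {lineno}: unknown category {row.category!r}")
        ts = row.elevated_tissues
        elevated = tuple(ts.split(";")) if isinstance(ts, str) and ts else ()
        out.append(
            GeneClassification(
                str(row.gene_id), row.category, elevated, float(row.fold_score), int(row.n_detected)
            )
        )
    return out


def write_summary(summary: ClassificationSummary, path: str | Path) -> None:
    write_table(summary.to_frame(), path)
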