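"""Interindividual variation of gene expression within a tissue.

For a tissue with several biological replicates, each gene's coefficient of
variation (CV = sample standard deviation / mean, across replicates) measures
how much its expression varies between individuals.  Genes detected in all
tissues ("housekeeping"-like genes) are expected to vary less between
individuals than genes with restricted expression; :func:`cv_shift_test`
quantifies that shift with a two-sided Mann-Whitney U test between the CV
distributions of the two groups.

CVs are computed on FPKM for genes whose tissue mean clears the detection
cutoff — the ratio sd/mean is numerically unstable near zero, and genes not
detected in a tissue carry no interindividual signal there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import EXPRESSED_IN_ALL, ClassifierParams, GeneClassification
from .errors import ConfigurationError, MappingError, StatisticsError
from .expression_io import SampleManifest, SampleMatrix, write_table

__all__ = ["CVRecord", "CVComparison", "gene_cv", "cv_shift_test", "write_cv_records", "write_cv_comparisons"]


@dataclass
class CVRecord:
    """Replicate statistics for one gene in one tissue.

    ``sd`` is the n-1 (sample) standard deviation: the replicates are a sample
    of individuals, not the population.
    """

    gene_id: str
    tissue: str
    mean: float
    sd: float
    cv: float
    n_samples: int


@dataclass
class CVComparison:
    """Mann-Whitney comparison of CV distributions, expressed-in-all vs rest."""

    tissue: str
    n_expressed_in_all: int
    n_other: int
    statistic: float
    p_value: float
    median_cv_expressed_in_all: float
    median_cv_other: float

    @property
    def expressed_in_all_lower(self) -> bool:
        """True when the expressed-in-all group has the lower median CV."""
        return self.median_cv_expressed_in_all < self.median_cv_other


def gene_cv(
    m: SampleMatrix,
    manifest: SampleManifest,
    tissue: str,
    params: ClassifierParams | None = None,
    min_replicates: int = 3,
) -> list[CVRecord]:
    """Per-gene CV across the biological replicates of one tissue.

    Only genes whose tissue mean is at or above the detection cutoff are
    reported.  Requires at least ``min_replicates`` samples for the tissue.
    """
    params = params or ClassifierParams()
    if tissue not in set(manifest.entries.values()):
        raise MappingError(f"tissue {tissue!r} not present in manifest")
    samples = [s for s in m.sample_ids if manifest.entries.get(s) == tissue]
    if len(samples) < min_replicates:
        raise ConfigurationError(
            f"tissue {tissue!r} has {len(samples)} replicate(s); need at least {min_replicates}"
        )
    sub = m.values[samples].to_numpy()
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    keep = means >= max(params.cutoff, np.finfo(float).tiny)
    records = []
    for i in np.flatnonzero(keep):
        records.append(
            CVRecord(
                gene_id=m.gene_ids[i],
                tissue=tissue,
                mean=float(means[i]),
                sd=float(sds[i]),
                cv=float(sds[i] / means[i]),
                n_samples=len(samples),
            )
        )
    return records


def cv_shift_test(
    classes: Sequence[GeneClassification], cvs: Sequence[CVRecord]
) -> CVComparison:
    """Test whether expressed-in-all genes have a shifted CV distribution.

    Partitions the CV records by whether the gene is classified
    expressed-in-all, then compares the two CV samples with a two-sided
    Mann-Whitney U (normal approximation with tie correction for large
    samples).  The direction of any shift is exposed via
    :attr:`CVComparison.expressed_in_all_lower`.
    """
    category = {r.gene_id: r.category for r in classes}
    eia, other = [], []
    for rec in cvs:
        cat = category.get(rec.gene_id)
        if cat is None:
            continue
        (eia if cat == EXPRESSED_IN_ALL else other).append(rec.cv)
    if len(eia) < 2 or len(other) < 2:
        raise StatisticsError(
            f"need at least 2 genes per group (expressed_in_all={len(eia)}, other={len(other)})"
        )
    res = stats.mannwhitneyu(eia, other, alternative="two-sided")
    tissue = cvs[0].tissue if cvs else ""
    return CVComparison(
        tissue=tissue,
        n_expressed_in_all=len(eia),
        n_other=len(other),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_cv_expressed_in_all=float(np.median(eia)),
        median_cv_other=float(np.median(other)),
    )


def write_cv_records(records: Sequence[CVRecord], path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "tissue": r.tissue,
            "mean": r.mean,
            "sd": r.sd,
            "cv": r.cv,
            "n_samples": r.n_samples,
        }
        for r in records
    ]
    if rows:
        write_table(rows, path)
    else:
        write_table(pd.DataFrame(columns=["gene_id", "tissue", "mean", "sd", "cv", "n_samples"]), path)


def write_cv_comparisons(comparisons: Sequence[CVComparison], path) -> None:
    write_table(
        [
            {
                "tissue": c.tissue,
                "n_expressed_in_all": c.n_expressed_in_all,
                "n_other": c.n_other,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "median_cv_expressed_in_all": c.median_cv_expressed_in_all,
                "median_cv_other": c.median_cv_other,
                "expressed_in_all_lower": c.expressed_in_all_lower,
            }
            for c in comparisons
        ],
        path,
    )
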