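"""Synthetic expression atlases with planted category structure.

The generator emulates the object the classifier consumes in production — a
gene x tissue x replicate FPKM atlas — with a known ("planted") category for
every gene, so the whole pipeline can be exercised and scored without any
external download.

For each gene a tissue-level mean vector is constructed according to its
planted category, built so that, at the tissue-mean level, the category rules
hold with a comfortable margin (``planted_fold``, default 10, against the
downstream fold of 5) and no *other* rule fires:

* ``expressed_in_all`` — a gene-level log-normal baseline times per-tissue
  factors in [1, 2]; a max/min ratio of at most 2 cannot trip any fivefold
  rule;
* ``tissue_enriched`` — one tissue at ``planted_fold`` times the maximum of an
  expressed-in-all-style background;
* ``group_enriched`` — a random group of ``group_min``..``group_max`` tissues
  at ``planted_fold`` times the background maximum (with jitter up to 1.2x,
  small enough that no sub-group satisfies the rule on its own);
* ``enhanced`` — the three-level pattern one high tissue / ``group_max``
  moderate tissues / the rest low: the moderates block both the enriched rule
  and every group of size <= ``group_max``, while the high tissue still clears
  fold x the overall mean;
* ``mixed`` — a random proper subset (>= 2) of tissues just above the cutoff
  (1.05-1.5x) with the rest just below it (0.35-0.5x), which provably violates
  every elevation rule for any subset size;
* ``not_detected`` — all tissues uniform below ``sub_cutoff_ceiling``.

Replicates are the tissue mean times LogNormal(0, sigma) noise, where sigma is
chosen so the multiplicative noise has the requested coefficient of variation:
the "housekeeping" level (default 0.1) for expressed-in-all genes and the
"restricted" level (default 0.4) for everything else, planting the lower
interindividual variation of ubiquitously expressed genes.

Randomness is reproducible: a single seed drives one master stream for the
category assignment, and per-gene substreams are spawned deterministically so
draws do not depend on gene order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CATEGORIES, ELEVATED_CATEGORIES, GeneClassification
from .errors import ConfigurationError, InputError
from .expression_io import SampleManifest, SampleMatrix

__all__ = ["SyntheticSpec", "TruthTable", "generate_atlas", "recovery_report"]

# Table-2-like default mix: fractions of genes per category in a real atlas
# (tissue_enriched, group_enriched, enhanced, expressed_in_all, mixed,
# not_detected), normalized from per-category gene counts out of 18,684.
DEFAULT_PROPORTIONS: tuple[float, ...] = tuple(
    c / 18684.0 for c in (2359, 1208, 3227, 8385, 2484, 1021)
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic atlas.

    Defaults mirror a human-scale atlas: 32 tissues, a category mix matching
    the published atlas proportions, a planted fold of 10 against the
    classifier's 5, and replicate noise of CV 0.1 for ubiquitous genes versus
    0.4 for the rest.
    """

    n_genes: int = 2000
    n_tissues: int = 32
    replicates_per_tissue: int = 8
    category_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    planted_fold: float = 10.0
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    noise_cv_housekeeping: float = 0.1
    noise_cv_restricted: float = 0.4
    sub_cutoff_ceiling: float = 0.25
    seed: int = 0
    # classifier-side constants the construction must respect
    cutoff: float = 0.5
    fold: float = 5.0
    group_min: int = 2
    group_max: int = 7

    def __post_init__(self) -> None:
        props = tuple(float(p) for p in self.category_proportions)
        if len(props) != len(CATEGORIES):
            raise ConfigurationError(f"need {len(CATEGORIES)} category proportions")
        if any(p < 0 for p in props):
            raise ConfigurationError("category proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError("category proportions must sum to 1")
        self.category_proportions = props
        if self.planted_fold <= self.fold:
            raise ConfigurationError("planted_fold must exceed the classifier fold")
        if min(self.noise_cv_housekeeping, self.noise_cv_restricted) < 0:
            raise ConfigurationError("noise CVs must be non-negative")
        if not (0 < self.sub_cutoff_ceiling < self.cutoff):
            raise ConfigurationError("sub_cutoff_ceiling must lie in (0, cutoff)")
        if self.n_genes < 1 or self.replicates_per_tissue < 1:
            raise ConfigurationError("need at least one gene and one replicate")
        if self.n_tissues < self.group_max + 2:
            raise ConfigurationError(
                f"need at least group_max + 2 = {self.group_max + 2} tissues "
                "so group-enriched genes leave a tissue outside every group"
            )
        if self.category_proportions[CATEGORIES.index("enhanced")] > 0:
            # enhanced needs one high + group_max moderate + enough low tissues
            if self.n_tissues <= self.fold + self.group_max:
                raise ConfigurationError(
                    "enhanced-category genes need n_tissues > fold + group_max "
                    f"({self.fold + self.group_max:.0f}); got {self.n_tissues}"
                )


@dataclass
class TruthTable:
    """Planted category labels: one row per gene."""

    frame: pd.DataFrame  # columns: gene_id, true_category, true_elevated_tissues

    def categories(self) -> pd.Series:
        return self.frame.set_index("gene_id")["true_category"]


def _counts_from_proportions(n: int, props: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment so counts sum exactly to n."""
    raw = [n * p for p in props]
    base = [math.floor(x) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(props)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def _baseline(rng: np.random.Generator, spec: SyntheticSpec) -> float:
    return max(
        float(rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd)), spec.cutoff
    )


def _housekeeping_vector(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    base = _baseline(rng, spec)
    return base * rng.uniform(1.0, 2.0, spec.n_tissues)


def _gene_means(
    category: str, rng: np.random.Generator, spec: SyntheticSpec
) -> tuple[np.ndarray, list[int]]:
    """Tissue-mean vector and the planted elevated tissue indices."""
    n = spec.n_tissues
    if category == "not_detected":
        return rng.uniform(0.0, spec.sub_cutoff_ceiling, n), []

    if category == "expressed_in_all":
        return _housekeeping_vector(rng, spec), []

    if category == "tissue_enriched":
        v = _housekeeping_vector(rng, spec)
        t = int(rng.integers(n))
        v[t] = spec.planted_fold * np.delete(v, t).max()
        return v, [t]

    if category == "group_enriched":
        v = _housekeeping_vector(rng, spec)
        size = int(rng.integers(spec.group_min, spec.group_max + 1))
        members = rng.choice(n, size=size, replace=False)
        bg_max = np.delete(v, members).max()
        v[members] = spec.planted_fold * bg_max * rng.uniform(1.0, 1.2, size)
        return v, sorted(int(i) for i in members)

    if category == "enhanced":
        # one high tissue, group_max equal moderates, the rest low
        perm = rng.permutation(n)
        high, moderates, lows = perm[0], perm[1 : 1 + spec.group_max], perm[1 + spec.group_max :]
        low_vals = rng.uniform(0.0, spec.sub_cutoff_ceiling, lows.size)
        s_low = float(low_vals.sum())
        # floor the moderate level so the enhanced window below is non-empty
        slack = spec.n_tissues - spec.fold - spec.group_max
        m_level = max(_baseline(rng, spec), 2.0 * s_low / slack)
        lower = spec.fold * (spec.group_max * m_level + s_low) / (n - spec.fold)
        upper = spec.fold * m_level  # strictly below: enriched must not fire
        if n > spec.planted_fold:
            target = (
                spec.planted_fold
                * (spec.group_max * m_level + s_low)
                / (n - spec.planted_fold)
            )
        else:
            target = math.sqrt(lower * upper)
        if not (lower < upper):
            raise ConfigurationError("enhanced construction infeasible for this spec")
        h = target if lower < target < upper else math.sqrt(lower * upper)
        v = np.empty(n)
        v[high] = h
        v[moderates] = m_level
        v[lows] = low_vals
        elevated = [
            int(i) for i in np.flatnonzero((v >= spec.cutoff) & (v >= spec.fold * v.mean()))
        ]
        return v, elevated

    if category == "mixed":
        size = int(rng.integers(2, n))  # proper subset, >= 2 detected
        detected = rng.choice(n, size=size, replace=False)
        v = spec.cutoff * rng.uniform(0.35, 0.5, n)
        v[detected] = spec.cutoff * rng.uniform(1.05, 1.5, size)
        return v, []

    raise ConfigurationError(f"unknown category {category!r}")


def generate_atlas(spec: SyntheticSpec) -> tuple[SampleMatrix, SampleManifest, TruthTable]:
    """Generate a replicate-level atlas with planted per-gene categories.

    Returns the raw sample matrix, its sample->tissue manifest, and the truth
    table of planted categories and elevated tissues.  Deterministic given
    ``spec`` (including its seed).
    """
    n_t, n_r = spec.n_tissues, spec.replicates_per_tissue
    width = len(str(n_t))
    tissues = [f"tissue{str(i + 1).zfill(width)}" for i in range(n_t)]
    samples = [f"{t}_r{j + 1}" for t in tissues for j in range(n_r)]
    manifest = SampleManifest({s: s.rsplit("_", 1)[0] for s in samples})

    counts = _counts_from_proportions(spec.n_genes, spec.category_proportions)
    labels = [c for c, k in zip(CATEGORIES, counts) for _ in range(k)]

    root = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(root.spawn(1)[0])
    master.shuffle(labels)
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_genes + 1)[1:]

    sigma_hk = math.sqrt(math.log1p(spec.noise_cv_housekeeping**2))
    sigma_re = math.sqrt(math.log1p(spec.noise_cv_restricted**2))

    gene_width = len(str(spec.n_genes))
    gene_ids = [f"G{str(i + 1).zfill(gene_width)}" for i in range(spec.n_genes)]
    data = np.empty((spec.n_genes, n_t * n_r))
    truth_rows = []
    for i, (gid, cat) in enumerate(zip(gene_ids, labels)):
        rng = np.random.default_rng(child_seeds[i])
        means, elevated = _gene_means(cat, rng, spec)
        sigma = sigma_hk if cat == "expressed_in_all" else sigma_re
        if sigma > 0:
            noise = rng.lognormal(0.0, sigma, size=(n_t, n_r))
        else:
            noise = np.ones((n_t, n_r))
        data[i] = (means[:, None] * noise).ravel()
        truth_rows.append(
            {
                "gene_id": gid,
                "true_category": cat,
                "true_elevated_tissues": ";".join(tissues[t] for t in elevated),
            }
        )

    matrix = SampleMatrix(pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"), columns=samples))
    return matrix, manifest, TruthTable(pd.DataFrame(truth_rows))


def recovery_report(
    truth: TruthTable, classes: list[GeneClassification]
) -> dict:
    """Score a classification against the planted truth.

    Returns overall accuracy, per-category accuracy, and the full confusion
    matrix (rows: true category, columns: assigned category).
    """
    assigned = pd.Series(
        {r.gene_id: r.category for r in classes}, name="assigned"
    )
    true_cat = truth.categories()
    if len(assigned) != len(classes):
        raise InputError("duplicate gene ids in classification")
    if set(assigned.index) != set(true_cat.index):
        raise InputError("classification and truth cover different gene sets")
    assigned = assigned.reindex(true_cat.index)
    confusion = pd.crosstab(true_cat, assigned).reindex(
        index=list(CATEGORIES), columns=list(CATEGORIES), fill_value=0
    )
    confusion.index.name = "true_category"
    confusion.columns.name = "assigned_category"
    per_category = {}
    for c in CATEGORIES:
        n_true = int(confusion.loc[c].sum())
        per_category[c] = float(confusion.loc[c, c] / n_true) if n_true else float("nan")
    overall = float((assigned == true_cat).mean())
    return {
        "overall_accuracy": overall,
        "per_category_accuracy": per_category,
        "confusion": confusion,
        "n_genes": int(len(true_cat)),
    }
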