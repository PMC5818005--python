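"""Library-level quality filters and stage-wise PCA outlier screening.

Filters mirror standard single-cell RNA-seq practice for plate-based
libraries: a minimum mapped-read depth of 500,000, a gene-body coverage
bias ratio (reads over the 3' half of gene bodies divided by reads over
the 5' half, percentile bins 50-100 vs 1-49) capped at 2, and a robust
per-stage outlier screen on the first two principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "LibraryStats",
    "filter_min_reads",
    "coverage_bias_ratio",
    "filter_bias",
    "pca_outlier_screen",
    "read_libstats",
    "write_libstats",
    "qc_report",
]

MIN_MAPPED_READS = 500_000
MAX_BIAS_RATIO = 2.0


@dataclass
class LibraryStats:
    """Per-library sequencing metrics.

    ``coverage_percentile_mass`` is a 100-vector giving the fraction of
    reads falling into each gene-length percentile bin (5' to 3');
    non-negative and summing to 1.
    """

    cell_id: str
    mapped_reads: int
    coverage_percentile_mass: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.coverage_percentile_mass, dtype=float)
        if cov.shape != (100,):
            raise ValidationError("coverage vector must have 100 bins")
        if (cov < 0).any():
            raise ValidationError("coverage vector must be non-negative")
        if cov.sum() > 0 and abs(cov.sum() - 1.0) > 1e-6:
            raise ValidationError("coverage vector must sum to 1")
        self.coverage_percentile_mass = cov
        if self.mapped_reads < 0:
            raise ValidationError("mapped_reads must be non-negative")


def filter_min_reads(stats, threshold: int = MIN_MAPPED_READS):
    """Partition libraries into (kept, removed) by mapped-read depth.

    Libraries with fewer than ``threshold`` mapped reads are removed;
    a library at exactly the threshold is kept.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    kept = [s.cell_id for s in stats if s.mapped_reads >= threshold]
    removed = [s.cell_id for s in stats if s.mapped_reads < threshold]
    return kept, removed


def coverage_bias_ratio(stats: LibraryStats) -> float:
    """3'-half / 5'-half coverage ratio.

    Ratio of total mass in percentile bins 50..100 (1-based; 51 bins) to
    mass in bins 1..49.  A uniform profile gives 51/49.  Returns +inf
    when the 5' half carries no reads.
    """
    cov = stats.coverage_percentile_mass
    if cov.sum() == 0:
        raise ValidationError(f"{stats.cell_id}: all-zero coverage vector")
    num = cov[49:].sum()   # bins 50..100
    den = cov[:49].sum()   # bins 1..49
    if den == 0:
        return np.inf
    return float(num / den)


def filter_bias(stats, max_ratio: float = MAX_BIAS_RATIO):
    """Partition libraries into (kept, removed) by coverage bias.

    A ratio strictly greater than ``max_ratio`` removes the library;
    exactly ``max_ratio`` is kept.
    """
    if max_ratio <= 0:
        raise ValidationError("max_ratio must be positive")
    kept, removed = [], []
    for s in stats:
        (removed if coverage_bias_ratio(s) > max_ratio else kept).append(s.cell_id)
    return kept, removed


def pca_outlier_screen(m: ExpressionMatrix, ann: pd.DataFrame, k_mads: float = 5.0) -> list[str]:
    """Flag per-stage outliers on PC1/PC2 by a median +/- k*MAD rule.

    Within each stage group of >= 3 cells, a centred PCA is computed and
    cells whose PC1 or PC2 score deviates from the group median by more
    than ``k_mads`` median absolute deviations are flagged.  Stages with
    fewer than 3 cells are skipped with a warning.  Deterministic given
    input order.
    """
    flagged: list[str] = []
    by_cell_stage = dict(zip(ann["cell_id"], ann["stage"]))
    stages = pd.unique(ann["stage"])
    for stage in stages:
        cells = [c for c in m.cell_ids if by_cell_stage.get(c) == stage]
        if len(cells) < 3:
            warnings.warn(f"stage {stage!r} has fewer than 3 cells; outlier screen skipped")
            continue
        x = m.data[cells].values.T.astype(float)       # cells x genes
        x = x - x.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        scores = u[:, :2] * s[:2]
        for comp in range(min(2, scores.shape[1])):
            v = scores[:, comp]
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            thresh = k_mads * mad
            if not np.isfinite(thresh):
                continue
            for c, val in zip(cells, v):
                if abs(val - med) > thresh and c not in flagged:
                    flagged.append(c)
    return flagged


# ---------------------------------------------------------------------------
# plumbing
# ---------------------------------------------------------------------------

def write_libstats(stats, path: str) -> None:
    rows = [
        {"cell_id": s.cell_id, "mapped_reads": s.mapped_reads,
         **{f"cov_{i + 1}": v for i, v in enumerate(s.coverage_percentile_mass)}}
        for s in stats
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_libstats(path: str) -> list[LibraryStats]:
    df = pd.read_csv(path, sep="\t")
    cov_cols = [f"cov_{i + 1}" for i in range(100)]
    return [
        LibraryStats(cell_id=str(r["cell_id"]), mapped_reads=int(r["mapped_reads"]),
                     coverage_percentile_mass=r[cov_cols].values.astype(float))
        for _, r in df.iterrows()
    ]


def qc_report(stats, matrix: ExpressionMatrix | None = None,
              ann: pd.DataFrame | None = None,
              min_reads: int = MIN_MAPPED_READS,
              max_ratio: float = MAX_BIAS_RATIO,
              k_mads: float = 5.0) -> pd.DataFrame:
    """Per-cell pass/fail table with reasons (depth -> bias -> PCA screen)."""
    _, low_depth = filter_min_reads(stats, min_reads)
    _, biased = filter_bias(stats, max_ratio)
    low_depth, biased = set(low_depth), set(biased)
    pca_flagged: set[str] = set()
    if matrix is not None and ann is not None:
        survivors = [c for c in matrix.cell_ids if c not in low_depth and c not in biased]
        sub = matrix.subset_cells(survivors)
        sub_ann = ann[ann["cell_id"].isin(survivors)]
        pca_flagged = set(pca_outlier_screen(sub, sub_ann, k_mads=k_mads))
    rows = []
    for s in stats:
        reasons = []
        if s.cell_id in low_depth:
            reasons.append("low_depth")
        if s.cell_id in biased:
            reasons.append("coverage_bias")
        if s.cell_id in pca_flagged:
            reasons.append("pca_outlier")
        rows.append({"cell_id": s.cell_id, "pass": not reasons,
                     "reasons": ";".join(reasons) if reasons else "."})
    return pd.DataFrame(rows)
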