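"""Mean-CV^2 variable-gene selection and cross-study intersection.

Per gene, the squared coefficient of variation (sample variance divided
by squared mean) is computed on the raw FPKM scale and plotted against
the mean of log2(FPKM+1); a local quadratic trend captures the expected
mean-dispersion relationship and a residual above it flags genuinely
variable genes.  Thresholds on both axes (mean log2 FPKM and log10 CV^2)
select the variable set.  When several studies are analysed together,
variable genes are selected per study and intersected, retaining only
features variable in every dataset — the cross-study comparability step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "VariableGeneSet",
    "compute_variability",
    "select_variable_genes",
    "intersect_variable_genes",
    "per_study_variable_genes",
]


@dataclass
class VariableGeneSet:
    gene_ids: set[str]
    thresholds: tuple[float, float]            # (min_mean_log2, min_log_cv2)
    source: str = ""
    per_source_thresholds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)


def _local_poly_trend(x: np.ndarray, y: np.ndarray, span: float = 0.3,
                      degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights (loess-style).

    For each point, the nearest ``span`` fraction of points by |x - x0|
    supports a weighted degree-2 fit evaluated at x0.  Falls back to
    lower degree when the local design is singular.
    """
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    fitted = np.empty(n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for idx in range(n):
        x0 = x[idx]
        # nearest k points in sorted x
        pos = np.searchsorted(xs, x0)
        lo, hi = pos, pos
        while hi - lo < k:
            if lo == 0:
                hi = k
                break
            if hi == n:
                lo = n - k
                break
            if x0 - xs[lo - 1] <= xs[hi] - x0:
                lo -= 1
            else:
                hi += 1
        xi, yi = xs[lo:hi], ys[lo:hi]
        d = np.abs(xi - x0)
        dmax = d.max()
        w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
        w = np.maximum(w, 1e-12)
        max_deg = min(degree, len(np.unique(xi)) - 1)
        if max_deg < 1:
            fitted[idx] = np.average(yi, weights=w)
            continue
        for deg in range(max_deg, -1, -1):
            try:
                coefs = np.polyfit(xi - x0, yi, deg, w=np.sqrt(w))
                fitted[idx] = coefs[-1]
                break
            except np.linalg.LinAlgError:
                continue
        else:  # pragma: no cover
            fitted[idx] = np.average(yi, weights=w)
    return fitted


def compute_variability(m: ExpressionMatrix, span: float = 0.3) -> pd.DataFrame:
    """Per-gene mean log2(FPKM+1), log10 CV^2 and trend residual.

    CV^2 is computed on the raw FPKM scale with sample variance (ddof=1);
    genes with zero mean or zero variance are dropped (their log CV^2 is
    undefined).  ``trend_residual`` is log10 CV^2 minus a local quadratic
    trend fitted against mean log2 FPKM.
    """
    if m.unit != "FPKM":
        raise ValidationError(f"compute_variability expects FPKM input, got {m.unit}")
    if m.n_cells < 2:
        raise ValidationError("variance undefined for a single cell")
    raw = m.values.astype(float)
    mean_raw = raw.mean(axis=1)
    var_raw = raw.var(axis=1, ddof=1)
    mean_log2 = np.log2(raw + 1.0).mean(axis=1)
    keep = (mean_raw > 0) & (var_raw > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = var_raw[keep] / mean_raw[keep] ** 2
    df = pd.DataFrame(
        {
            "gene_id": np.asarray(m.gene_ids)[keep],
            "mean_log2_fpkm": mean_log2[keep],
            "log_cv2": np.log10(cv2),
        }
    )
    df["trend_residual"] = df["log_cv2"].values - _local_poly_trend(
        df["mean_log2_fpkm"].values, df["log_cv2"].values, span=span
    )
    return df.set_index("gene_id", drop=False)


def select_variable_genes(variability: pd.DataFrame, min_mean_log2: float = 2.0,
                          min_log_cv2: float = 0.5, use_residual: bool = False,
                          source: str = "") -> VariableGeneSet:
    """Select genes with mean log2 FPKM and log10 CV^2 strictly above thresholds.

    With ``use_residual``, genes must additionally sit above the fitted
    mean-CV^2 trend (positive residual).
    """
    sel = (variability["mean_log2_fpkm"] > min_mean_log2) & (variability["log_cv2"] > min_log_cv2)
    if use_residual:
        sel &= variability["trend_residual"] > 0
    return VariableGeneSet(
        gene_ids=set(variability.loc[sel, "gene_id"]),
        thresholds=(min_mean_log2, min_log_cv2),
        source=source,
        per_source_thresholds={source: (min_mean_log2, min_log_cv2)} if source else {},
    )


def intersect_variable_genes(sets) -> VariableGeneSet:
    """Intersection of per-study variable-gene sets (commutative, associative)."""
    sets = list(sets)
    if len(sets) < 2:
        raise ValidationError("need at least two sets to intersect")
    genes = set(sets[0].gene_ids)
    per_source = {}
    for s in sets:
        genes &= s.gene_ids
        per_source.update(s.per_source_thresholds or {s.source: s.thresholds})
    if not genes:
        warnings.warn("variable-gene intersection is empty; downstream PCA needs >= 2 genes")
    return VariableGeneSet(
        gene_ids=genes,
        thresholds=sets[0].thresholds,
        source=" & ".join(s.source or "?" for s in sets),
        per_source_thresholds=per_source,
    )


def per_study_variable_genes(m: ExpressionMatrix, ann: pd.DataFrame,
                             min_mean_log2: float = 2.0, min_log_cv2: float = 0.5,
                             use_residual: bool = False) -> dict[str, VariableGeneSet]:
    """Variable genes selected independently within each study."""
    out: dict[str, VariableGeneSet] = {}
    for study, grp in ann.groupby("study", sort=True):
        cells = [c for c in grp["cell_id"] if c in set(m.cell_ids)]
        if len(cells) < 2:
            warnings.warn(f"study {study!r} has fewer than 2 cells; skipped")
            continue
        v = compute_variability(m.subset_cells(cells))
        out[study] = select_variable_genes(v, min_mean_log2, min_log_cv2,
                                           use_residual=use_residual, source=str(study))
    return out
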