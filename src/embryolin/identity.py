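"""Fractional identity of query transcriptomes against embryonic stages.

A stage signature matrix S (genes x stages, per-stage mean expression)
represents the reference time course.  The fractional identity of a
query transcriptome x is the solution of the convex quadratic programme

    minimise ||S f - x||^2   subject to  f >= 0,  sum(f) = 1,

solved exactly by an active-set method with a KKT optimality
certificate.  The per-stage weights f express the query as a mixture of
stage signatures; the residual norm measures unexplained signal.

Differential expression between sample groups uses a two-sided Wilcoxon
rank-sum test with Benjamini-Hochberg adjustment — a deterministic,
assumption-light substitute for error-model-based single-cell DE
methods; significance thresholds (adjusted P and absolute log2 fold
change) are parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "StageSignature",
    "FractionalIdentityResult",
    "build_signature",
    "fractional_identity",
    "fractional_identities",
    "kkt_residual",
    "de_genes_ranksum",
    "correlation_to_stages",
]


@dataclass
class StageSignature:
    """Per-stage mean expression (genes x stages) on a linear scale."""

    matrix: pd.DataFrame
    unit: str = "FPKM"

    @property
    def stages(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class FractionalIdentityResult:
    sample_id: str
    fractions: pd.Series               # indexed by stage, sums to 1
    residual_norm: float
    non_unique: bool = False


def build_signature(m: ExpressionMatrix, ann: pd.DataFrame, stages) -> StageSignature:
    """Arithmetic per-stage mean expression on the matrix's unit scale."""
    by_cell = dict(zip(ann["cell_id"], ann["stage"]))
    cols = {}
    for s in stages:
        cells = [c for c in m.cell_ids if by_cell.get(c) == s]
        if not cells:
            warnings.warn(f"stage {s!r} has no cells; excluded from signature")
            continue
        cols[s] = m.data[cells].mean(axis=1)
    if not cols:
        raise ValidationError("no stages with cells")
    return StageSignature(matrix=pd.DataFrame(cols), unit=m.unit)


# ---------------------------------------------------------------------------
# simplex-constrained least squares (active set)
# ---------------------------------------------------------------------------

def _solve_free(S: np.ndarray, x: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Equality-constrained LS on the free coordinates (sum = 1) via KKT."""
    Sf = S[:, free]
    k = Sf.shape[1]
    G = 2.0 * Sf.T @ Sf
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = G
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * Sf.T @ x, [1.0]])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    return sol[:k]


def _simplex_lsq(S: np.ndarray, x: np.ndarray, tol: float = 1e-12,
                 max_iter: int = 500) -> np.ndarray:
    """Global optimum of min ||S f - x||^2 s.t. f >= 0, sum f = 1.

    Primal active-set method: start from the barycentre, solve the
    equality-constrained problem on the free set, step toward it along a
    feasible direction clamping variables that hit zero, and release
    clamped variables with negative reduced gradient until the KKT
    conditions hold.  The problem is convex, so the certificate implies
    global optimality.
    """
    k = S.shape[1]
    f = np.full(k, 1.0 / k)
    active = np.zeros(k, dtype=bool)
    for _ in range(max_iter):
        free = ~active
        sol = np.zeros(k)
        sol[free] = _solve_free(S, x, free)
        if (sol[free] >= -tol).all():
            f = np.where(free, np.maximum(sol, 0.0), 0.0)
            f /= f.sum()
            # dual feasibility on the clamped set
            g = 2.0 * S.T @ (S @ f - x)
            lam = float(np.mean(g[free]))
            mu = g - lam
            viol = np.where(active & (mu < -1e-9))[0]
            if viol.size == 0:
                return f
            active[viol[np.argmin(mu[viol])]] = False
            continue
        # step from f toward sol until a free variable hits zero
        direction = sol - f
        direction[active] = 0.0
        blocking = np.where(free & (direction < -tol) & (f > 0))[0]
        if blocking.size == 0:
            alpha = 1.0
        else:
            steps = f[blocking] / -direction[blocking]
            alpha = min(1.0, float(steps.min()))
        f = f + alpha * direction
        f = np.maximum(f, 0.0)
        newly = np.where(free & (f <= tol))[0]
        if newly.size == 0 and alpha >= 1.0:
            continue
        for j in newly:
            if active.sum() < k - 1:
                active[j] = True
                f[j] = 0.0
        f /= f.sum()
    warnings.warn("active-set iteration limit reached; returning best feasible point")
    return f


def kkt_residual(S: np.ndarray, x: np.ndarray, f: np.ndarray) -> float:
    """Scale-relative KKT violation at f (0 certifies global optimality).

    Stationarity and dual-feasibility violations are normalised by the
    gradient magnitude so the certificate is meaningful regardless of
    the expression scale; primal violations are absolute.
    """
    g = 2.0 * S.T @ (S @ f - x)
    free = f > 1e-10
    if free.sum() == 0:
        return np.inf
    scale = 1.0 + float(np.abs(g).max())
    lam = float(np.mean(g[free]))
    stationarity = float(np.abs(g[free] - lam).max()) / scale
    dual = max(0.0, float(np.max(lam - g[~free], initial=0.0))) / scale
    primal = max(abs(f.sum() - 1.0), float(max(0.0, -f.min())))
    return max(stationarity, dual, primal)


def fractional_identity(sig: StageSignature, query, sample_id: str = "query",
                        genes=None) -> FractionalIdentityResult:
    """Simplex-constrained least-squares weights of a query over stages.

    ``query`` is a gene-indexed Series (or array aligned to the
    signature rows); deconvolution operates on the signature's linear
    scale.  Flags non-uniqueness when two stage columns are identical
    within 1e-9.
    """
    mat = sig.matrix
    if genes is not None:
        mat = mat.loc[[g for g in genes if g in mat.index]]
    if isinstance(query, pd.Series):
        common = [g for g in mat.index if g in query.index]
        if len(common) < len(mat.index):
            mat = mat.loc[common]
        x = query.loc[mat.index].values.astype(float)
    else:
        x = np.asarray(query, dtype=float)
        if x.shape[0] != mat.shape[0]:
            raise ValidationError("query length does not match signature rows")
    if mat.shape[1] < 2:
        raise ValidationError("need at least 2 stages")
    S = mat.values.astype(float)
    non_unique = False
    for i in range(S.shape[1]):
        for j in range(i + 1, S.shape[1]):
            if np.allclose(S[:, i], S[:, j], atol=1e-9):
                non_unique = True
    if non_unique:
        warnings.warn("two stage signatures are numerically identical; "
                      "fractions are not unique")
    f = _simplex_lsq(S, x)
    res = float(np.linalg.norm(S @ f - x))
    return FractionalIdentityResult(
        sample_id=sample_id,
        fractions=pd.Series(f, index=mat.columns),
        residual_norm=res,
        non_unique=non_unique,
    )


def fractional_identities(sig: StageSignature, queries: pd.DataFrame,
                          genes=None) -> pd.DataFrame:
    """Fractional identity per column of a gene x sample query matrix."""
    rows = []
    for sample in queries.columns:
        r = fractional_identity(sig, queries[sample], sample_id=sample, genes=genes)
        rows.append({"sample_id": sample, **r.fractions.to_dict(),
                     "residual": r.residual_norm})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential expression (rank-sum substitute) and stage correlation
# ---------------------------------------------------------------------------

def de_genes_ranksum(m: ExpressionMatrix, group_a, group_b, alpha: float = 0.001,
                     min_abs_lfc: float = 1.5) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE with Benjamini-Hochberg adjustment.

    Log2 fold changes are computed from group means with a pseudocount
    of 1 on the linear scale.  ``significant`` marks genes with adjusted
    P below ``alpha`` and |log2 FC| above ``min_abs_lfc``.  All-tied
    genes get P = 1.  The exact (tie-free) null distribution is used for
    small comparisons, the normal approximation otherwise.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("need at least 3 cells per group")
    if m.unit == "log2FPKM":
        lin = 2.0 ** m.data - 1.0
    else:
        lin = m.data
    a = lin[group_a].values.astype(float)
    b = lin[group_b].values.astype(float)
    n_small = (len(group_a) + len(group_b)) <= 30
    pvals = np.empty(m.n_genes)
    for i in range(m.n_genes):
        xa, xb = a[i], b[i]
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            pvals[i] = 1.0
            continue
        method = "exact" if n_small else "asymptotic"
        pvals[i] = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                            method=method).pvalue
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    lfc = np.log2(a.mean(axis=1) + 1.0) - np.log2(b.mean(axis=1) + 1.0)
    out = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "adjusted_p": adj,
        }
    )
    out["significant"] = (out["adjusted_p"] < alpha) & (out["log2_fold_change"].abs() > min_abs_lfc)
    return out.set_index("gene_id", drop=False)


def correlation_to_stages(sig: StageSignature, query: pd.Series, genes) -> pd.Series:
    """Pearson correlation (log2 scale) between a query and each stage.

    Restricted to the given gene subset (>= 3 genes); stages whose
    restricted signature has zero variance give NaN.
    """
    genes = [g for g in genes if g in sig.matrix.index and g in query.index]
    if len(genes) < 3:
        raise ValidationError("need at least 3 genes for stage correlation")
    q = np.log2(query.loc[genes].values.astype(float) + 1.0)
    out = {}
    for s in sig.stages:
        v = np.log2(sig.matrix.loc[genes, s].values.astype(float) + 1.0)
        if np.std(v) == 0 or np.std(q) == 0:
            out[s] = np.nan
        else:
            out[s] = float(np.corrcoef(q, v)[0, 1])
    return pd.Series(out, name="pearson_r")
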