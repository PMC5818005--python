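"""Post-hoc lineage assignment for blastocyst cells.

The workflow mirrors marker-based re-classification of pooled embryo
data: PCA on a small high-confidence marker panel, extraction of the
late inner cell mass by clustering cells on the principal component
tracking POU5F1 expression, labelling of EPI / PrE / intermediate groups
by the NANOG:PDGFRA expression ratio, and a diffusion-map pseudotime to
resolve the early ICM among E5 cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse
import scipy.sparse.csgraph
import scipy.spatial.distance
import scipy.stats

from .core import ExpressionMatrix, MarkerPanel, ValidationError

__all__ = [
    "Embedding",
    "pca",
    "hierarchical_clusters",
    "extract_pou5f1_classes",
    "ratio_classify",
    "assign_late_icm",
    "diffusion_pseudotime",
    "find_early_icm",
    "classify_blastocyst",
]


@dataclass
class Embedding:
    """PCA embedding: per-cell coordinates plus per-gene loadings."""

    cell_ids: list[str]
    gene_ids: list[str]
    coordinates: np.ndarray          # cells x components
    component_loadings: np.ndarray   # genes x components
    variance_explained: np.ndarray   # per-component fraction

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def pca(m: ExpressionMatrix, genes=None, n_components: int | None = None,
        center: bool = True, scale: bool = False) -> Embedding:
    """Exact PCA of the per-gene centred expression matrix.

    Centring is per gene without unit-variance scaling by default, so
    expression magnitude contributes to the components; ``scale`` turns
    on standardisation.  Component signs are fixed so that the largest-
    magnitude loading of each component is positive.
    """
    if genes is not None:
        genes = [g for g in genes if g in set(m.gene_ids)]
        if len(genes) < 2:
            raise ValidationError("PCA needs at least 2 genes present in the matrix")
        m = m.subset_genes(genes)
    x = m.values.T.astype(float)             # cells x genes
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    k = min(x.shape)
    if n_components is not None:
        k = min(k, n_components)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(k):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    total = (s ** 2).sum()
    ve = (s ** 2) / total if total > 0 else np.zeros(k)
    return Embedding(
        cell_ids=m.cell_ids,
        gene_ids=m.gene_ids,
        coordinates=u * s,
        component_loadings=vt.T,
        variance_explained=ve,
    )


def _coords_and_cells(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, Embedding):
        return np.asarray(x.coordinates, dtype=float), list(x.cell_ids)
    if isinstance(x, ExpressionMatrix):
        return x.values.T.astype(float), x.cell_ids
    raise TypeError("expected an Embedding or ExpressionMatrix")


def hierarchical_clusters(x, k: int) -> dict[str, int]:
    """Average-linkage agglomerative clustering (Euclidean), cut to k groups.

    Cells are processed in lexicographic cell_id order so that distance
    ties break deterministically.  Cluster labels are integers starting
    at 1, renumbered by order of first appearance.
    """
    coords, cells = _coords_and_cells(x)
    if k < 1 or k > len(cells):
        raise ValidationError(f"k={k} out of range for {len(cells)} cells")
    order = np.argsort(np.asarray(cells, dtype=object))
    coords = coords[order]
    cells = [cells[i] for i in order]
    if len(cells) == 1:
        return {cells[0]: 1}
    z = sch.linkage(coords, method="average", metric="euclidean")
    labels = sch.fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for c, lab in zip(cells, labels):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[c] = relabel[lab]
    return out


def extract_pou5f1_classes(m: ExpressionMatrix, embedding: Embedding,
                           pou5f1_gene: str = "POU5F1", n_classes: int = 3,
                           component: int | str = 3) -> dict[str, str]:
    """Cluster cells on one principal component and label by POU5F1 level.

    Cells are clustered 1-D (Euclidean, average linkage) on the chosen
    component into ``n_classes`` groups, labelled high/medium/low by
    descending mean POU5F1 log2 expression.  ``component`` is 1-based;
    ``"auto"`` picks the component (among the first five) whose
    coordinate correlates most with POU5F1 — the data-driven analogue of
    identifying the POU5F1-tracking component by inspection — and
    ``"supervised"`` clusters on POU5F1 denoised through the embedding
    subspace (its least-squares fit on the leading components), which is
    robust when no single axis tracks POU5F1.  Ties in group means break
    by group size (larger group -> lower class).
    """
    if pou5f1_gene not in set(m.gene_ids):
        raise ValidationError(f"{pou5f1_gene} not present in the matrix")
    pou = m.data.loc[pou5f1_gene, embedding.cell_ids].values.astype(float)
    if component == "supervised":
        k = min(5, embedding.n_components)
        design = np.column_stack([np.ones(len(pou)), embedding.coordinates[:, :k]])
        beta, *_ = np.linalg.lstsq(design, pou, rcond=None)
        comp = None
        coord_1d = design @ beta
    elif component == "auto":
        best, best_cor = 0, -1.0
        for c in range(min(5, embedding.n_components)):
            v = embedding.coordinates[:, c]
            if v.std() == 0 or pou.std() == 0:
                continue
            cor = abs(np.corrcoef(v, pou)[0, 1])
            if cor > best_cor:
                best, best_cor = c, cor
        comp = best
    else:
        if embedding.n_components < component:
            raise ValidationError(f"embedding has fewer than {component} components")
        comp = int(component) - 1
    coord = (coord_1d if comp is None else embedding.coordinates[:, comp]).reshape(-1, 1)
    fake = Embedding(embedding.cell_ids, [], coord, np.zeros((0, 1)), np.ones(1))
    n_classes = min(n_classes, len(embedding.cell_ids))
    clusters = hierarchical_clusters(fake, n_classes)

    if pou.std() == 0:
        warnings.warn("POU5F1 is constant across cells; class labels are arbitrary")
    level_names = {3: ["high", "medium", "low"], 2: ["high", "low"], 1: ["high"]}.get(
        n_classes, [f"class{i + 1}" for i in range(n_classes)]
    )
    pou_by_cell = dict(zip(embedding.cell_ids, pou))
    groups: dict[int, list[str]] = {}
    for c, lab in clusters.items():
        groups.setdefault(lab, []).append(c)
    # descending POU5F1 mean; ties -> larger group ranks lower (later)
    ranked = sorted(
        groups.items(),
        key=lambda kv: (-float(np.mean([pou_by_cell[c] for c in kv[1]])), len(kv[1])),
    )
    out: dict[str, str] = {}
    for name, (_, members) in zip(level_names, ranked):
        for c in members:
            out[c] = name
    return out


def ratio_classify(m: ExpressionMatrix, cells=None, nanog: str = "NANOG",
                   pdgfra: str = "PDGFRA", tau: float = 1.0) -> pd.DataFrame:
    """EPI / PrE / intermediate calls from the NANOG:PDGFRA log-ratio.

    r = log2 expression of NANOG minus that of PDGFRA; EPI if r > tau,
    PrE if r < -tau, intermediate otherwise.  Antisymmetric: swapping
    the two genes swaps EPI and PrE calls exactly.
    """
    present = set(m.gene_ids)
    for g in (nanog, pdgfra):
        if g not in present:
            raise ValidationError(f"{g} not present in the matrix")
    if cells is None:
        cells = m.cell_ids
    cells = list(cells)
    r = (m.data.loc[nanog, cells] - m.data.loc[pdgfra, cells]).values.astype(float)
    call = np.where(r > tau, "EPI", np.where(r < -tau, "PrE", "intermediate"))
    return pd.DataFrame({"cell_id": cells, "ratio_nanog_pdgfra": r, "call": call})


def assign_late_icm(m: ExpressionMatrix, ann: pd.DataFrame, panel: MarkerPanel,
                    pou5f1_classes: dict[str, str], tau: float = 1.0,
                    nanog: str = "NANOG", pdgfra: str = "PDGFRA") -> pd.DataFrame:
    """Classify late-ICM cells into EPI / PrE / intermediate.

    Restricted to POU5F1-high and -medium cells, clustered (k=3, average
    linkage) on marker-panel PCA coordinates; the cluster with highest
    mean NANOG:PDGFRA ratio becomes EPI, the lowest PrE.  The middle
    cluster is intermediate unless its mean ratio itself clears the
    per-cell rule (mean r > tau -> EPI, mean r < -tau -> PrE), which
    guards against a mature-lineage chunk being forced into the
    intermediate slot.  Returns one row per input cell; cells outside
    the high/medium classes are ``unassigned``.
    """
    retained = [c for c in m.cell_ids if pou5f1_classes.get(c) in ("high", "medium")]
    rows = []
    if len(retained) < 3:
        for c in m.cell_ids:
            rows.append({"cell_id": c, "call": "unassigned",
                         "ratio_nanog_pdgfra": np.nan,
                         "pou5f1_class": pou5f1_classes.get(c, "NA")})
        return pd.DataFrame(rows)
    sub = m.subset_cells(retained)
    ratios = ratio_classify(sub, nanog=nanog, pdgfra=pdgfra, tau=tau)
    ratio_by_cell = dict(zip(ratios["cell_id"], ratios["ratio_nanog_pdgfra"]))
    emb = pca(sub, genes=panel.genes)
    if np.allclose(emb.variance_explained, 0):
        clusters = {c: 1 for c in retained}
    else:
        clusters = hierarchical_clusters(emb, k=min(3, len(retained)))
    groups: dict[int, list[str]] = {}
    for c, lab in clusters.items():
        groups.setdefault(lab, []).append(c)
    mean_ratio = {lab: float(np.mean([ratio_by_cell[c] for c in mem]))
                  for lab, mem in groups.items()}
    ranked = sorted(mean_ratio, key=lambda lab: -mean_ratio[lab])
    if len(ranked) == 3:
        mid = mean_ratio[ranked[1]]
        mid_label = "EPI" if mid > tau else ("PrE" if mid < -tau else "intermediate")
        label_of = {ranked[0]: "EPI", ranked[1]: mid_label, ranked[2]: "PrE"}
    elif len(ranked) == 2:
        label_of = {ranked[0]: "EPI", ranked[1]: "PrE"}
    else:
        label_of = {ranked[0]: "intermediate"}
    call_by_cell = {c: label_of[lab] for lab, mem in groups.items() for c in mem}
    for c in m.cell_ids:
        rows.append({
            "cell_id": c,
            "call": call_by_cell.get(c, "unassigned"),
            "ratio_nanog_pdgfra": ratio_by_cell.get(c, np.nan),
            "pou5f1_class": pou5f1_classes.get(c, "NA"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diffusion pseudotime
# ---------------------------------------------------------------------------

def _knn_indices(d: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbours per row, excluding self even under zero-distance ties."""
    n = d.shape[0]
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        order = [j for j in np.argsort(d[i], kind="stable") if j != i]
        out[i] = order[:k]
    return out


def _diffusion_order(x: np.ndarray, n_neighbors: int) -> np.ndarray:
    """First non-trivial right eigenvector of the kNN Gaussian transition matrix."""
    n = x.shape[0]
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x))
    nn_idx = _knn_indices(d, n_neighbors)
    sigma = d[np.arange(n), nn_idx[:, -1]]
    sigma[sigma == 0] = 1e-12
    w = np.zeros((n, n))
    for i in range(n):
        for j in nn_idx[i]:
            w[i, j] = np.exp(-d[i, j] ** 2 / (sigma[i] * sigma[j]))
    w = np.maximum(w, w.T)                    # symmetrise on the union of edges
    rowsum = w.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    p = w / rowsum[:, None]
    vals, vecs = np.linalg.eig(p)
    order = np.argsort(-vals.real)
    v = vecs[:, order[1]].real                # first non-trivial eigenvector
    return v


def diffusion_pseudotime(m: ExpressionMatrix, genes=None, n_neighbors: int = 15,
                         ann: pd.DataFrame | None = None,
                         root_cells=None) -> pd.Series:
    """Diffusion-map pseudotime in [0, 1] for each cell.

    A Gaussian kernel on the k-nearest-neighbour graph (local bandwidth =
    distance to the ``n_neighbors``-th neighbour) defines a transition
    matrix; pseudotime is the rank-normalised coordinate along its first
    non-trivial right eigenvector, oriented so the root group has
    minimal mean pseudotime.  The root defaults to cells of the earliest
    embryonic day in ``ann``; disconnected graph components are processed
    separately with a warning.
    """
    if genes is not None:
        m = m.subset_genes([g for g in genes if g in set(m.gene_ids)])
    cells = m.cell_ids
    n = len(cells)
    if n < n_neighbors + 1:
        raise ValidationError(f"need at least {n_neighbors + 1} cells")
    x = m.values.T.astype(float)

    if root_cells is None and ann is not None:
        sub = ann[ann["cell_id"].isin(cells)]
        days = [d for d in sub["embryonic_day"].unique() if str(d).startswith("E")]
        if days:
            earliest = sorted(days)[0]
            root_cells = list(sub.loc[sub["embryonic_day"] == earliest, "cell_id"])
    root_set = set(root_cells or [])

    # connectivity on the symmetrised kNN graph
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x))
    nn_idx = _knn_indices(d, n_neighbors)
    adj = scipy.sparse.lil_matrix((n, n))
    for i in range(n):
        adj[i, nn_idx[i]] = 1
    adj = adj.maximum(adj.T)
    n_comp, comp = scipy.sparse.csgraph.connected_components(adj.tocsr(), directed=False)
    if n_comp > 1:
        warnings.warn(f"kNN graph has {n_comp} components; pseudotime computed per component")

    pt = np.empty(n)
    for c in range(n_comp):
        idx = np.where(comp == c)[0]
        if len(idx) == 1:
            pt[idx] = 0.0
            continue
        k = min(n_neighbors, len(idx) - 1)
        v = _diffusion_order(x[idx], k)
        # quantise relative to the coordinate range so numerically equal
        # cells (e.g. duplicated columns) receive tied ranks
        span = v.max() - v.min()
        vq = np.round((v - v.min()) / span, 6) if span > 0 else np.zeros_like(v)
        ranks = scipy.stats.rankdata(vq, method="average") - 1.0
        ranks = ranks / max(len(idx) - 1, 1)
        roots = [i for i, g in enumerate(idx) if cells[g] in root_set]
        if roots and np.mean(ranks[roots]) > np.median(ranks):
            ranks = 1.0 - ranks
        pt[idx] = ranks
    return pd.Series(pt, index=cells, name="pseudotime")


def find_early_icm(m: ExpressionMatrix, ann: pd.DataFrame, markers_early,
                   k: int = 3, n_neighbors: int = 15,
                   genes=None) -> set[str]:
    """Consensus early-ICM set among E5 cells.

    The lowest-pseudotime hierarchical cluster (k groups on expression)
    is intersected with cells whose mean log2 expression of the early
    markers exceeds the E5 median.  Pseudotime is oriented so that
    marker-high cells sit early.  Returns an empty set (with a warning)
    if no E5 cells or no consensus.
    """
    present = set(m.gene_ids)
    missing = [g for g in markers_early if g not in present]
    if missing:
        raise ValidationError(f"early markers absent from matrix: {missing}")
    e5 = [c for c in ann.loc[ann["embryonic_day"] == "E5", "cell_id"] if c in set(m.cell_ids)]
    if not e5:
        return set()
    sub = m.subset_cells(e5)
    score = sub.data.loc[list(markers_early)].mean(axis=0)
    high = set(score.index[score > score.median()])
    roots = list(score.sort_values(ascending=False).index[: max(len(e5) // 4, 1)])
    pt = diffusion_pseudotime(sub, genes=genes, n_neighbors=min(n_neighbors, len(e5) - 1),
                              root_cells=roots)
    clusters = hierarchical_clusters(sub if genes is None else sub.subset_genes(genes),
                                     k=min(k, len(e5)))
    groups: dict[int, list[str]] = {}
    for c, lab in clusters.items():
        groups.setdefault(lab, []).append(c)
    low_lab = min(groups, key=lambda lab: float(np.mean([pt[c] for c in groups[lab]])))
    consensus = set(groups[low_lab]) & high
    if not consensus:
        warnings.warn("early-ICM consensus set is empty")
    return consensus


# ---------------------------------------------------------------------------
# end-to-end blastocyst classification
# ---------------------------------------------------------------------------

def classify_blastocyst(m: ExpressionMatrix, ann: pd.DataFrame,
                        panel: MarkerPanel | None = None,
                        pou5f1_gene: str = "POU5F1", tau: float = 1.0,
                        component: int | str = "supervised") -> pd.DataFrame:
    """Full late-blastocyst workflow: TE extraction then EPI/PrE/intermediate.

    Variable genes are selected per study and intersected; PCA on that
    set provides the embedding on which POU5F1 high/medium/low classes
    are extracted (the component tracking POU5F1 is chosen by
    correlation).  The low class is called TE; the remaining ICM cells
    are clustered on marker-panel PCA and labelled by NANOG:PDGFRA
    ratio.  Accepts FPKM or log2FPKM input.
    """
    from .core import default_marker_panel, inverse_log_transform, log_transform
    from .hvg import intersect_variable_genes, per_study_variable_genes

    panel = panel or default_marker_panel()
    if m.unit == "log2FPKM":
        m_fpkm = inverse_log_transform(m)
    else:
        m_fpkm, m = m, log_transform(m)
    sets = per_study_variable_genes(m_fpkm, ann)
    hvg_genes: list[str] = []
    if len(sets) >= 2:
        hvg_genes = sorted(intersect_variable_genes(list(sets.values())).gene_ids)
    elif len(sets) == 1:
        hvg_genes = sorted(next(iter(sets.values())).gene_ids)
    if len(hvg_genes) < 3:
        hvg_genes = panel.genes
    emb = pca(m, genes=hvg_genes)
    classes = extract_pou5f1_classes(m, emb, pou5f1_gene=pou5f1_gene, component=component)
    calls = assign_late_icm(m, ann, panel, classes, tau=tau)
    calls.loc[calls["cell_id"].map(lambda c: classes.get(c) == "low"), "call"] = "TE"
    return calls
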