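"""Weighted co-expression network modules, eigengenes and hub genes.

The construction follows the WGCNA recipe: soft-thresholded adjacency
a_ij = |cor(g_i, g_j)|^beta (unsigned, beta = 10 by default), the
topological overlap measure (TOM) as similarity, average-linkage
clustering of 1 - TOM with a static-height tree cut (minimum module
size 50), module eigengenes as first principal components of the
standardised member submatrix, eigengene-correlation merging of similar
modules (dissimilarity threshold 0.35) and per-module hub genes ranked
by intramodular connectivity (top 50).

The tree cut is a deliberately simplified, deterministic stand-in for
Dynamic Tree Cut: the cut height descends from 0.99 of the tallest
merge in steps of 0.01 until the partition into groups of at least
``min_size`` genes is stable across one step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance
import networkx as nx

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "GeneModuleSet",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "hub_genes",
    "build_modules",
    "hub_network",
]


@dataclass
class GeneModuleSet:
    """Gene -> module assignment with eigengenes, connectivity and hubs."""

    assignment: dict[str, int]                 # 0 = unassigned
    eigengenes: dict[int, np.ndarray] = field(default_factory=dict)
    connectivity: dict[str, float] = field(default_factory=dict)
    hubs: dict[int, list[str]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted({m for m in self.assignment.values() if m != 0})

    def members(self, module: int) -> list[str]:
        return [g for g, m in self.assignment.items() if m == module]


def adjacency(m: ExpressionMatrix, genes=None, beta: float = 10.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |pearson|^beta with unit diagonal."""
    if m.n_cells < 3:
        raise ValidationError("adjacency needs at least 3 cells")
    if genes is not None:
        m = m.subset_genes([g for g in genes if g in set(m.gene_ids)])
    x = m.values.astype(float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        dropped = [g for g, s in zip(m.gene_ids, sd) if s == 0]
        warnings.warn(f"dropping {len(dropped)} zero-variance genes from the network")
        m = m.subset_genes([g for g, s in zip(m.gene_ids, sd) if s > 0])
        x = m.values.astype(float)
    cor = np.corrcoef(x)
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=m.gene_ids, columns=m.gene_ids)


def tom_similarity(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency with unit diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i the connectivity excluding the diagonal; TOM_ii = 1.
    """
    av = a.values.astype(float)
    if not np.allclose(av, av.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    n = av.shape[0]
    off = av - np.eye(n)                         # zero the diagonal
    k = off.sum(axis=1)
    shared = off @ off                           # sum over u != i, j includes u=j/i terms?
    # remove contributions where u == i or u == j: off[i,i] = 0 already,
    # but off @ off includes u=j (a_ij * a_jj=0) and u=i likewise, so none remain
    num = shared + off
    den = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=a.index, columns=a.columns)


def detect_modules(dissim: pd.DataFrame, min_size: int = 50) -> dict[str, int]:
    """Preliminary module assignment by a static-height cut of the TOM tree.

    Returns gene -> module id (0 for unassigned); modules are numbered
    by decreasing size, ties broken by the lexicographically smallest
    member gene.
    """
    genes = list(dissim.index)
    n = len(genes)
    if n < min_size:
        warnings.warn(f"only {n} genes for min_size={min_size}; all unassigned")
        return {g: 0 for g in genes}
    d = dissim.values.astype(float)
    condensed = scipy.spatial.distance.squareform((d + d.T) / 2.0, checks=False)
    z = sch.linkage(condensed, method="average")
    hmax = z[:, 2].max()
    if hmax == 0:
        return _number_modules(genes, [genes] if n >= min_size else [])

    def groups_at(frac: float) -> list[frozenset]:
        labels = sch.fcluster(z, t=frac * hmax, criterion="distance")
        out: dict[int, set] = {}
        for g, lab in zip(genes, labels):
            out.setdefault(lab, set()).add(g)
        return sorted((frozenset(s) for s in out.values() if len(s) >= min_size),
                      key=lambda s: (-len(s), sorted(s)[0]))

    prev = groups_at(0.99)
    frac = 0.98
    while frac > 0:
        cur = groups_at(frac)
        if cur == prev:
            break
        prev = cur
        frac = round(frac - 0.01, 10)
    return _number_modules(genes, [sorted(s) for s in prev])


def _number_modules(genes, module_lists) -> dict[str, int]:
    assignment = {g: 0 for g in genes}
    ordered = sorted(module_lists, key=lambda mem: (-len(mem), mem[0] if mem else ""))
    for i, mem in enumerate(ordered, start=1):
        for g in mem:
            assignment[g] = i
    return assignment


def module_eigengene(m: ExpressionMatrix, members) -> np.ndarray:
    """First principal component of the standardised member x cell submatrix.

    Unit-norm cell-length vector, oriented so the mean correlation with
    member genes is positive.
    """
    members = list(members)
    if len(members) < 2:
        raise ValidationError("eigengene needs at least 2 member genes")
    x = m.data.loc[members].values.astype(float)
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValidationError("all member genes are constant")
    keep = sd > 0
    x = x[keep]
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    e = vt[0]
    e = e / np.linalg.norm(e)
    cors = [np.corrcoef(e, row)[0, 1] for row in x]
    if np.mean(cors) < 0:
        e = -e
    return e


def merge_modules(m: ExpressionMatrix, assignment: dict[str, int],
                  threshold: float = 0.35) -> GeneModuleSet:
    """Iteratively merge modules with eigengene dissimilarity below threshold.

    Dissimilarity is 1 - pearson(eigengene_a, eigengene_b); the closest
    qualifying pair merges first and eigengenes are recomputed after
    each merge.  Never increases the module count; idempotent on its own
    output.
    """
    assignment = dict(assignment)
    while True:
        mods = sorted({v for v in assignment.values() if v != 0})
        if len(mods) < 2:
            break
        eig = {mod: module_eigengene(m, [g for g, v in assignment.items() if v == mod])
               for mod in mods}
        best, best_d = None, np.inf
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                dis = 1.0 - float(np.corrcoef(eig[a], eig[b])[0, 1])
                if dis < best_d:
                    best, best_d = (a, b), dis
        if best is None or best_d >= threshold:
            break
        a, b = best
        for g, v in assignment.items():
            if v == b:
                assignment[g] = a
    # renumber contiguously by size
    module_lists = [sorted(g for g, v in assignment.items() if v == mod)
                    for mod in sorted({v for v in assignment.values() if v != 0})]
    assignment = _number_modules(list(assignment), module_lists)
    gms = GeneModuleSet(assignment=assignment, params={"merge_threshold": threshold})
    for mod in gms.module_ids:
        gms.eigengenes[mod] = module_eigengene(m, gms.members(mod))
    return gms


def hub_genes(gms: GeneModuleSet, h: int = 50) -> dict[int, list[str]]:
    """Top-h genes per module by descending intramodular connectivity.

    Ties break lexicographically on gene id; requires ``connectivity``
    to be populated (see :func:`build_modules`).
    """
    hubs: dict[int, list[str]] = {}
    for mod in gms.module_ids:
        mem = gms.members(mod)
        ranked = sorted(mem, key=lambda g: (-gms.connectivity.get(g, 0.0), g))
        hubs[mod] = ranked[: max(h, 0)]
    return hubs


def build_modules(m: ExpressionMatrix, genes=None, beta: float = 10.0,
                  min_size: int = 50, merge_threshold: float = 0.35,
                  h: int = 50) -> GeneModuleSet:
    """Full module pipeline: adjacency -> TOM -> detect -> merge -> hubs."""
    a = adjacency(m, genes=genes, beta=beta)
    tom = tom_similarity(a)
    prelim = detect_modules(1.0 - tom, min_size=min_size)
    gms = merge_modules(m.subset_genes(list(a.index)), prelim, threshold=merge_threshold)
    av = a.values
    pos = {g: i for i, g in enumerate(a.index)}
    for g, mod in gms.assignment.items():
        if mod == 0:
            gms.connectivity[g] = 0.0
            continue
        others = [pos[o] for o in gms.members(mod) if o != g]
        gms.connectivity[g] = float(av[pos[g], others].sum())
    gms.hubs = hub_genes(gms, h=h)
    gms.params.update({"beta": beta, "min_size": min_size,
                       "merge_threshold": merge_threshold, "h": h})
    return gms


def hub_network(gms: GeneModuleSet, a: pd.DataFrame, min_weight: float = 0.0) -> nx.Graph:
    """Graph over hub genes with adjacency edge weights (per module)."""
    g = nx.Graph()
    for mod, hub_list in gms.hubs.items():
        for gene in hub_list:
            g.add_node(gene, module=mod)
        for i, gi in enumerate(hub_list):
            for gj in hub_list[i + 1:]:
                w = float(a.loc[gi, gj])
                if w > min_weight:
                    g.add_edge(gi, gj, weight=w, module=mod)
    return g
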