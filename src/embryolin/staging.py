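"""Self-organising stage maps and stage / early / late lineage markers.

Per-gene mean FPKM profiles across the ordered pre-implantation stages
(zygote, 4-cell, 8-cell, morula, early ICM, EPI, PrE) are summarised as
cross-stage Z-scores.  A batch-trained 30x30 hexagonal self-organising
map arranges genes by profile shape; stage-specific gene lists use a
Z > 1.5 rule (genes below 1.5 in every stage form the background
universe).  Late lineage markers require a transcriptional contribution
above 75% in the lineage stage and at least 10 FPKM there; early markers
require 75% contribution summed over the 8-cell -> morula -> early ICM
-> lineage path, a four-fold induction between lineages, and 10 FPKM in
at least one path-relevant stage.  "Transcriptional contribution" of a
gene at a stage is its share of the gene's total cross-stage mean FPKM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, STAGE_ORDER, ValidationError

__all__ = [
    "StageProfileTable",
    "SomGrid",
    "stage_profiles",
    "train_som",
    "quantisation_error",
    "stage_specific_genes",
    "late_lineage_markers",
    "early_lineage_markers",
]

#: pseudo-floor on FPKM means when computing fold changes (negligible
#: against the 10 FPKM expression floor)
FC_EPSILON = 0.01


@dataclass
class StageProfileTable:
    """Per-gene per-stage mean FPKM and cross-stage Z-scores."""

    means: pd.DataFrame        # genes x ordered stages, mean FPKM
    zscores: pd.DataFrame      # genes with nonzero cross-stage variance only

    @property
    def stages(self) -> list[str]:
        return list(self.means.columns)


def stage_profiles(m: ExpressionMatrix, ann: pd.DataFrame,
                   stages=STAGE_ORDER) -> StageProfileTable:
    """Mean FPKM per stage and per-gene Z-scores across the stage axis.

    Stages without cells are excluded with a warning; genes constant
    across stages are excluded from the Z-score table (their Z is
    undefined).  Z-scores use the sample standard deviation, so each
    retained gene has mean 0 and SD 1 across stages.
    """
    if m.unit != "FPKM":
        raise ValidationError(f"stage_profiles expects FPKM input, got {m.unit}")
    by_cell = dict(zip(ann["cell_id"], ann["stage"]))
    cols = {}
    for s in stages:
        cells = [c for c in m.cell_ids if by_cell.get(c) == s]
        if not cells:
            warnings.warn(f"stage {s!r} has no cells; excluded from profiles")
            continue
        cols[s] = m.data[cells].mean(axis=1)
    means = pd.DataFrame(cols)
    sd = means.std(axis=1, ddof=1)
    # a relative floor keeps float noise on constant genes out of the Z table
    keep = sd > 1e-9 * (means.abs().mean(axis=1) + 1.0)
    z = means.loc[keep].sub(means.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return StageProfileTable(means=means, zscores=z)


# ---------------------------------------------------------------------------
# self-organising map
# ---------------------------------------------------------------------------

@dataclass
class SomGrid:
    """Hexagonally arranged SOM with a batch training schedule."""

    width: int = 30
    height: int = 30
    epochs: int = 100
    seed: int = 0
    codebook: np.ndarray | None = None         # (width*height) x features

    def unit_positions(self) -> np.ndarray:
        """Cartesian coordinates of the hexagonal grid units (odd rows offset)."""
        pos = np.empty((self.height * self.width, 2))
        for r in range(self.height):
            for c in range(self.width):
                pos[r * self.width + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2)
        return pos


def _bmu(codebook: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Best-matching unit index for each row of x (Euclidean)."""
    d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def train_som(profiles: StageProfileTable, grid: SomGrid | None = None,
              features: str = "zscore") -> tuple[SomGrid, pd.Series]:
    """Batch-train a SOM on per-gene stage profiles; map genes to units.

    The codebook is initialised on the plane of the first two principal
    components of the feature matrix (deterministic); each epoch assigns
    every gene to its best-matching unit and moves codebook vectors
    toward the Gaussian-neighbourhood-weighted mean of their genes.  The
    neighbourhood radius decays linearly from max(width, height)/2 to 1.
    Features are cross-stage Z-scores by default (``features="raw"``
    uses the mean-FPKM profiles directly).
    """
    grid = grid or SomGrid()
    feats = profiles.zscores if features == "zscore" else profiles.means
    if len(feats) == 0:
        raise ValidationError("no genes with defined profiles to train on")
    x = feats.values.astype(float)
    n_units = grid.width * grid.height
    pos = grid.unit_positions()

    # PCA-plane initialisation
    mu = x.mean(axis=0)
    xc = x - mu
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    n_feat = x.shape[1]
    pc = vt[:2] if vt.shape[0] >= 2 else np.vstack([vt[0], np.zeros(n_feat)])
    sd = s[:2] / np.sqrt(max(len(x) - 1, 1))
    if len(sd) < 2:
        sd = np.array([sd[0], 0.0])
    gx = (pos[:, 0] / max(grid.width - 1, 1) - 0.5) * 2.0
    gy = (pos[:, 1] / max(pos[:, 1].max(), 1e-12) - 0.5) * 2.0
    codebook = mu + np.outer(gx * sd[0], pc[0]) + np.outer(gy * sd[1], pc[1])

    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    r0, r1 = max(grid.width, grid.height) / 2.0, 1.0
    for epoch in range(grid.epochs):
        radius = r0 + (r1 - r0) * (epoch / max(grid.epochs - 1, 1))
        bmu = _bmu(codebook, x)
        influence = np.exp(-grid_d2[:, bmu] / (2.0 * radius ** 2))  # units x genes
        weights = influence.sum(axis=1)
        target = influence @ x
        nz = weights > 1e-12
        codebook[nz] = target[nz] / weights[nz, None]
    grid.codebook = codebook
    bmu = _bmu(codebook, x)
    return grid, pd.Series(bmu, index=feats.index, name="bmu")


def quantisation_error(grid: SomGrid, profiles: StageProfileTable,
                       features: str = "zscore") -> float:
    """Mean Euclidean distance of each gene to its best-matching unit."""
    feats = profiles.zscores if features == "zscore" else profiles.means
    x = feats.values.astype(float)
    bmu = _bmu(grid.codebook, x)
    return float(np.linalg.norm(x - grid.codebook[bmu], axis=1).mean())


# ---------------------------------------------------------------------------
# marker rules
# ---------------------------------------------------------------------------

def stage_specific_genes(profiles: StageProfileTable,
                         z_threshold: float = 1.5):
    """Genes with Z > threshold per stage, plus the background universe.

    A gene is assigned to every stage where its Z-score exceeds the
    threshold; genes below the threshold in all stages form the
    universe used as background for enrichment analyses.
    """
    by_stage: dict[str, list[str]] = {s: [] for s in profiles.zscores.columns}
    z = profiles.zscores
    for s in z.columns:
        by_stage[s] = list(z.index[z[s] > z_threshold])
    universe = list(z.index[(z < z_threshold).all(axis=1)])
    return by_stage, universe


def _contributions(means: pd.DataFrame) -> pd.DataFrame:
    """Per-gene share of total cross-stage mean FPKM (rows sum to 1)."""
    total = means.sum(axis=1)
    keep = total > 0
    return means.loc[keep].div(total[keep], axis=0)


def late_lineage_markers(profiles: StageProfileTable, lineage: str,
                         contrib: float = 0.75, min_fpkm: float = 10.0) -> list[str]:
    """Late EPI or PrE markers: contribution > 75% in the lineage, >= 10 FPKM."""
    if lineage not in ("EPI", "PrE"):
        raise ValidationError("lineage must be EPI or PrE")
    if lineage not in profiles.means.columns:
        raise ValidationError(f"profiles lack the {lineage} stage")
    c = _contributions(profiles.means)
    means = profiles.means.loc[c.index]
    sel = (c[lineage] > contrib) & (means[lineage] >= min_fpkm)
    return sorted(c.index[sel])


def early_lineage_markers(profiles: StageProfileTable, lineage: str,
                          contrib: float = 0.75, min_fc: float = 4.0,
                          min_fpkm: float = 10.0) -> list[str]:
    """Early lineage markers along the 8-cell -> morula -> early ICM path.

    Requires: summed contribution over {8cell, morula, earlyICM, lineage}
    above ``contrib``; fold change of at least ``min_fc`` between the two
    late lineages (with a small pseudo-floor); and >= ``min_fpkm`` mean
    FPKM in at least one of the five relevant stages.
    """
    if lineage not in ("EPI", "PrE"):
        raise ValidationError("lineage must be EPI or PrE")
    other = "PrE" if lineage == "EPI" else "EPI"
    path = ["8cell", "morula", "earlyICM", lineage]
    needed = set(path + [other])
    missing = needed - set(profiles.means.columns)
    if missing:
        raise ValidationError(f"profiles lack stages: {sorted(missing)}")
    c = _contributions(profiles.means)
    means = profiles.means.loc[c.index]
    path_contrib = c[path].sum(axis=1)
    fc = (means[lineage] + FC_EPSILON) / (means[other] + FC_EPSILON)
    floor = (means[["8cell", "morula", "earlyICM", "EPI", "PrE"]] >= min_fpkm).any(axis=1)
    sel = (path_contrib > contrib) & (fc >= min_fc) & floor
    return sorted(c.index[sel])
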