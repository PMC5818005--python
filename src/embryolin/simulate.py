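"""Synthetic multi-study embryo-like expression data with known ground truth.

The generator emulates the structure of the pooled human pre-implantation
single-cell compendium: several "studies" with distinct batch and dropout
characteristics, developmental stages from zygote to late blastocyst,
mature EPI/PrE/TE lineages plus EPI-PrE intermediates, a 12-gene marker
panel with mutually exclusive mature-lineage expression, POU5F1 dynamics
(broad early expression, restriction to the ICM in the late blastocyst),
and per-library mapped-read totals and gene-body coverage profiles for
QC testing.

Expression model: per-cell log2 means are given by per-stage programs;
a per-(gene, study) multiplicative log-normal batch factor, per-entry
Gaussian noise on the log2 scale and optional per-gene extra dispersion
are added; FPKM = max(2**x - 1, 0); per-study Bernoulli dropout then
zeroes entries.  Intermediates are convex combinations of the EPI and
PrE programs with per-cell weight ~ Uniform(0.3, 0.7).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    MarkerPanel,
    ValidationError,
    default_marker_panel,
    make_annotation,
)
from .qc import LibraryStats

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "LibraryStatsTruth",
    "simulate_dataset",
    "simulate_library_stats",
    "plant_module_blocks",
    "default_config",
    "late_blastocyst_config",
    "hvg_config",
    "e5_config",
    "module_config",
    "simulate_psc_queries",
    "EARLY_ICM_MARKERS",
]

#: early-ICM markers planted by the default configs (primate early-ICM genes)
EARLY_ICM_MARKERS = ["ESRRB", "ATG2A", "MAGEA4", "NANOGNB", "PRAMEF17"]

_STAGE_DAY = {
    "zygote": "E3", "4cell": "E3", "8cell": "E3", "morula": "E4",
    "earlyICM": "E5", "EPI": "E6", "PrE": "E6", "TE": "E6",
    "intermediate": "E6", "PSC": "culture",
}

_MARKER_ON = 12.0   # log2 scale
_MARKER_OFF = 0.0


@dataclass
class SimulationConfig:
    """Full description of a synthetic dataset; builders below construct them."""

    n_genes: int
    stages: list[tuple[str, int]]              # ordered (stage, n_cells)
    programs: pd.DataFrame                     # gene x stage mean log2 expression
    marker_panel: MarkerPanel | None = None
    pou5f1_profile: dict[str, float] | None = None
    n_studies: int = 1
    batch_scale_sd: float = 0.0
    dropout_rates: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.0
    intermediate_fraction: float = 0.0
    seed: int = 0
    gene_roles: dict[str, dict] = field(default_factory=dict)
    extra_dispersion: dict[str, float] = field(default_factory=dict)
    # gene -> (study index, in-study mean log2, in-study extra sd)
    study_dispersed: dict[str, tuple[int, float, float]] = field(default_factory=dict)
    # (ordered member gene list, within-block target correlation, first-gene loading boost)
    module_blocks: list[tuple[list[str], float, float]] = field(default_factory=list)
    stage_day: dict[str, str] = field(default_factory=lambda: dict(_STAGE_DAY))

    def __post_init__(self) -> None:
        if len(self.dropout_rates) != self.n_studies:
            raise ValidationError("need one dropout rate per study")
        if any(not (0.0 <= d <= 1.0) for d in self.dropout_rates):
            raise ValidationError("dropout rates must be in [0, 1]")
        if any(n < 0 for _, n in self.stages):
            raise ValidationError("stage cell counts must be >= 0")
        if self.batch_scale_sd < 0 or self.noise_sd < 0:
            raise ValidationError("scale parameters must be non-negative")
        if not (0.0 <= self.intermediate_fraction <= 1.0):
            raise ValidationError("intermediate_fraction must be in [0, 1]")
        if self.marker_panel is not None:
            prog = self.programs
            for gene, lin in self.marker_panel.entries:
                if gene not in prog.index:
                    continue
                others = [s for s, _ in self.stages
                          if s in ("EPI", "PrE", "TE") and s != lin and s in prog.columns]
                if lin in prog.columns and others:
                    on = prog.loc[gene, lin]
                    if any(prog.loc[gene, o] >= on for o in others):
                        raise ValidationError(
                            f"marker {gene}: off-state mean must be strictly below on-state"
                        )

    @property
    def total_cells(self) -> int:
        return sum(n for _, n in self.stages)


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated dataset."""

    labels: dict[str, str]                     # cell_id -> true stage/lineage
    roles: dict[str, dict]                     # gene_id -> planted roles
    study_of_cell: dict[str, int]
    dropout_fraction: dict[int, float]
    intermediate_weights: dict[str, float] = field(default_factory=dict)
    module_factors: dict[int, np.ndarray] = field(default_factory=dict)

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r.get("role") == role]


@dataclass
class LibraryStatsTruth:
    stats: list[LibraryStats]
    bad_depth_ids: set[str]
    biased_ids: set[str]


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _cell_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for stage, n in config.stages:
        for j in range(n):
            study = i % config.n_studies
            rows.append((f"S{study + 1}_{stage}_{j:03d}", stage, study))
            i += 1
    return pd.DataFrame(rows, columns=["cell_id", "stage", "study"])


def simulate_dataset(config: SimulationConfig):
    """Simulate (ExpressionMatrix [FPKM], annotation, SyntheticTruth).

    Deterministic given ``config.seed``; the annotation carries the true
    stage in ``lineage_label``.
    """
    if config.total_cells == 0:
        raise ValidationError("configuration has zero total cells")
    rng = np.random.default_rng(config.seed)
    cells = _cell_table(config)
    genes = list(config.programs.index)
    n_g, n_c = len(genes), len(cells)
    gene_pos = {g: i for i, g in enumerate(genes)}

    prog = np.empty((n_g, n_c))
    inter_w: dict[str, float] = {}
    prog_by_stage = {s: config.programs[s].values for s in config.programs.columns}
    for j, (cid, stage, study) in enumerate(cells.itertuples(index=False)):
        if stage == "intermediate":
            w = rng.uniform(0.3, 0.7)
            inter_w[cid] = w
            prog[:, j] = w * prog_by_stage["EPI"] + (1.0 - w) * prog_by_stage["PrE"]
        else:
            prog[:, j] = prog_by_stage[stage]

    batch = (rng.normal(0.0, config.batch_scale_sd, size=(n_g, config.n_studies))
             if config.batch_scale_sd > 0 else np.zeros((n_g, config.n_studies)))
    study_of_col = cells["study"].values
    x = prog + batch[:, study_of_col]

    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=(n_g, n_c))
    for g, sd in config.extra_dispersion.items():
        if sd > 0:
            x[gene_pos[g]] += rng.normal(0.0, sd, size=n_c)
    for g, (study, mu, sd) in config.study_dispersed.items():
        in_study = study_of_col == study
        x[gene_pos[g], in_study] = mu + rng.normal(0.0, sd, size=int(in_study.sum()))

    module_factors: dict[int, np.ndarray] = {}
    for b, (members, within_cor, boost) in enumerate(config.module_blocks):
        f = rng.normal(0.0, 1.0, size=n_c)
        module_factors[b] = f
        if within_cor >= 1.0:
            # affine copies of the factor: overwrite noise entirely
            for i, g in enumerate(members):
                load = config.noise_sd if config.noise_sd > 0 else 1.0
                if i == 0:
                    load *= boost
                x[gene_pos[g]] = prog[gene_pos[g]] + load * f
        else:
            sigma = config.noise_sd if config.noise_sd > 0 else 1.0
            load = sigma * np.sqrt(within_cor / (1.0 - within_cor))
            for i, g in enumerate(members):
                x[gene_pos[g]] += (load * boost if i == 0 else load) * f

    fpkm = np.maximum(2.0 ** x - 1.0, 0.0)

    dropout_fraction: dict[int, float] = {}
    for s in range(config.n_studies):
        d = config.dropout_rates[s]
        in_study = study_of_col == s
        if d > 0:
            mask = rng.random(size=(n_g, int(in_study.sum()))) < d
            sub = fpkm[:, in_study]
            sub[mask] = 0.0
            fpkm[:, in_study] = sub
            dropout_fraction[s] = float(mask.mean())
        else:
            dropout_fraction[s] = 0.0

    matrix = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=cells["cell_id"]), "FPKM")
    ann = make_annotation(
        cells["cell_id"],
        study=[f"study{s + 1}" for s in cells["study"]],
        embryonic_day=[config.stage_day.get(s, "unknown") for s in cells["stage"]],
        stage=list(cells["stage"]),
        collection="whole_embryo",
        lineage_label=list(cells["stage"]),
    )
    truth = SyntheticTruth(
        labels=dict(zip(cells["cell_id"], cells["stage"])),
        roles=dict(config.gene_roles),
        study_of_cell=dict(zip(cells["cell_id"], cells["study"].astype(int))),
        dropout_fraction=dropout_fraction,
        intermediate_weights=inter_w,
        module_factors=module_factors,
    )
    return matrix, ann, truth


# ---------------------------------------------------------------------------
# QC fixtures
# ---------------------------------------------------------------------------

def _coverage_with_ratio(rng: np.random.Generator, ratio: float) -> np.ndarray:
    """100-bin gene-body coverage mass with an exact 3'-half/5'-half ratio.

    Bins 50..100 (1-based) carry ratio/(1+ratio) of the mass, bins 1..49
    the rest, with random proportions inside each half.
    """
    lo = rng.random(49) + 0.05
    hi = rng.random(51) + 0.05
    lo *= (1.0 / (1.0 + ratio)) / lo.sum()
    hi *= (ratio / (1.0 + ratio)) / hi.sum()
    return np.concatenate([lo, hi])


def simulate_library_stats(config: SimulationConfig, n_bad_depth: int, n_biased: int,
                           planted_bias_ratio: float = 2.5,
                           depth_threshold: int = 500_000) -> LibraryStatsTruth:
    """Per-library mapped reads and coverage with planted QC failures.

    Exactly ``n_bad_depth`` libraries fall below the read-depth floor and
    exactly ``n_biased`` get a coverage ratio of ``planted_bias_ratio``;
    all other libraries pass both filters with >= 10% margin.
    """
    cells = list(_cell_table(config)["cell_id"])
    if n_bad_depth + n_biased > len(cells):
        raise ValidationError("more planted failures than libraries")
    rng = np.random.default_rng(config.seed + 1)
    flagged = list(rng.choice(len(cells), size=n_bad_depth + n_biased, replace=False))
    bad_depth = {cells[i] for i in flagged[:n_bad_depth]}
    biased = {cells[i] for i in flagged[n_bad_depth:]}
    stats = []
    for cid in cells:
        if cid in bad_depth:
            reads = int(rng.integers(50_000, int(0.9 * depth_threshold)))
            cov = _coverage_with_ratio(rng, rng.uniform(0.9, 1.8))
        elif cid in biased:
            reads = int(rng.integers(2 * depth_threshold, 10 * depth_threshold))
            cov = _coverage_with_ratio(rng, planted_bias_ratio)
        else:
            reads = int(rng.integers(int(1.1 * depth_threshold), 10 * depth_threshold))
            cov = _coverage_with_ratio(rng, rng.uniform(0.9, 1.8))
        stats.append(LibraryStats(cell_id=cid, mapped_reads=reads, coverage_percentile_mass=cov))
    return LibraryStatsTruth(stats=stats, bad_depth_ids=bad_depth, biased_ids=biased)


# ---------------------------------------------------------------------------
# module-block planting
# ---------------------------------------------------------------------------

def plant_module_blocks(config: SimulationConfig, block_sizes: list[int],
                        within_cor: float, boost_first: float = 1.0) -> SimulationConfig:
    """Return a config in which blocks of genes share a latent factor.

    Genes inside a block have pairwise expected correlation close to
    ``within_cor``; genes in different blocks are uncorrelated.  Blocks
    are carved from background genes in order; ``boost_first`` scales the
    factor loading of the first gene of each block (a planted hub).
    """
    if not block_sizes:
        return config
    if within_cor <= 0 or within_cor > 1:
        raise ValidationError("within_cor must be in (0, 1]")
    if sum(block_sizes) > config.n_genes:
        raise ValidationError("blocks exceed the number of genes")
    used = {g for members, _, _ in config.module_blocks for g in members}
    free = [g for g, r in config.gene_roles.items()
            if r.get("role") == "background" and g not in used]
    if sum(block_sizes) > len(free):
        raise ValidationError("not enough background genes for the requested blocks")
    roles = {g: dict(r) for g, r in config.gene_roles.items()}
    blocks = list(config.module_blocks)
    programs = config.programs.copy()
    pos = 0
    for b, size in enumerate(block_sizes, start=len(config.module_blocks)):
        members = free[pos:pos + size]
        pos += size
        blocks.append((members, within_cor, boost_first))
        for g in members:
            roles[g] = {**roles.get(g, {}), "role": "module", "module": b}
            # block genes are well-detected so the zero clip on the FPKM
            # scale does not truncate the shared-factor signal
            programs.loc[g] = np.maximum(programs.loc[g], 8.0)
    return dataclasses.replace(config, module_blocks=blocks, gene_roles=roles,
                               programs=programs)


# ---------------------------------------------------------------------------
# configuration builders: these defaults ARE the study conditions
# ---------------------------------------------------------------------------

def _background(n: int, rng: np.random.Generator) -> pd.Series:
    ids = [f"G{i + 1:04d}" for i in range(n)]
    return pd.Series(rng.uniform(1.0, 8.0, size=n), index=ids)


_LATE_EPI = ["NODAL", "LEFTY2", "WNT3"]
_LATE_PRE = ["RSPO3", "APOA1", "FOXA2"]
_EARLY_EPI = ["ARGFX", "PRDM14", "DPPA2"]
_EARLY_PRE = ["LAMA1", "HNF4A", "MARCKS"]
_POU5F1_PROFILE = {
    "zygote": 6.0, "4cell": 6.0, "8cell": 7.0, "morula": 7.0,
    "earlyICM": 7.0, "EPI": 8.0, "PrE": 5.0, "TE": 1.0,
}


def _named_gene_programs(stage_names: list[str]) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Programs and roles for the named marker/flavour genes."""
    panel = default_marker_panel()
    roles: dict[str, dict] = {}
    rows: dict[str, dict[str, float]] = {}

    def set_gene(g, role, level_by_stage, **extra):
        rows[g] = {s: level_by_stage.get(s, 0.0) for s in stage_names}
        roles[g] = {"role": role, **extra}

    set_gene("POU5F1", "pou5f1", {s: v for s, v in _POU5F1_PROFILE.items() if s in stage_names})
    for gene, lin in panel.entries:
        levels = {lin: _MARKER_ON}
        # early-ICM co-expression of the two ICM specifiers at mid level
        if gene in ("NANOG", "GATA6") and "earlyICM" in stage_names:
            levels["earlyICM"] = 5.0
        set_gene(gene, "marker", levels, lineage=lin)
    for g in EARLY_ICM_MARKERS:
        if "earlyICM" in stage_names:
            set_gene(g, "early_icm_marker", {"earlyICM": 10.0})
    lv20 = np.log2(21.0)   # exactly 20 FPKM
    lv15 = np.log2(16.0)   # exactly 15 FPKM
    for g in _LATE_EPI:
        set_gene(g, "late_lineage_marker", {"EPI": lv20}, lineage="EPI")
    for g in _LATE_PRE:
        set_gene(g, "late_lineage_marker", {"PrE": lv20}, lineage="PrE")
    path = ["8cell", "morula", "earlyICM"]
    for g in _EARLY_EPI:
        set_gene(g, "early_lineage_marker",
                 {s: lv15 for s in path + ["EPI"] if s in stage_names}, lineage="EPI")
    for g in _EARLY_PRE:
        set_gene(g, "early_lineage_marker",
                 {s: lv15 for s in path + ["PrE"] if s in stage_names}, lineage="PrE")
    te_genes = ["DAB2", "TEAD3", "KRT18"] + [f"TEP{i:03d}" for i in range(4, 31)]
    for g in te_genes:
        if "TE" in stage_names:
            set_gene(g, "te_program", {"TE": 10.0})
    df = pd.DataFrame.from_dict(rows, orient="index")[stage_names]
    return df, roles


def _assemble(stage_counts: list[tuple[str, int]], n_genes: int, seed: int,
              n_studies: int, dropout_rates, batch_scale_sd: float, noise_sd: float,
              with_named: bool = True, variable_mode: str | None = None,
              n_variable: int = 100, include_study_noise: bool = False,
              intermediate_fraction: float = 0.0) -> SimulationConfig:
    rng = np.random.default_rng(seed + 1000)
    stage_names = [s for s, _ in stage_counts if s != "intermediate"]
    parts, roles = [], {}
    extra_dispersion: dict[str, float] = {}
    study_dispersed: dict[str, tuple[int, float, float]] = {}

    if with_named:
        named, named_roles = _named_gene_programs(stage_names)
        parts.append(named)
        roles.update(named_roles)

    if variable_mode == "dispersed":
        ids = [f"HVG{i + 1:04d}" for i in range(n_variable)]
        parts.append(pd.DataFrame(5.5, index=ids, columns=stage_names))
        for g in ids:
            roles[g] = {"role": "variable"}
            extra_dispersion[g] = 3.0
    elif variable_mode == "lineage":
        ids = [f"HVG{i + 1:04d}" for i in range(n_variable)]
        lineages = [s for s in stage_names if s in ("EPI", "PrE", "TE", "earlyICM")]
        df = pd.DataFrame(2.0, index=ids, columns=stage_names)
        for g in ids:
            on = lineages[int(rng.integers(len(lineages)))]
            df.loc[g, on] = 8.0
            roles[g] = {"role": "variable", "on_stage": on}
            extra_dispersion[g] = 1.2
        parts.append(df)
    elif variable_mode == "stage_run":
        ids = [f"HVG{i + 1:04d}" for i in range(n_variable)]
        df = pd.DataFrame(2.0, index=ids, columns=stage_names)
        for g in ids:
            run = int(rng.integers(1, 4))
            start = int(rng.integers(0, max(1, len(stage_names) - run)))
            on = stage_names[start:start + run]
            df.loc[g, on] = 8.0
            roles[g] = {"role": "variable", "on_stage": tuple(on)}
            extra_dispersion[g] = 1.2
        parts.append(df)

    if include_study_noise:
        # protocol-specific genes: strongly detected in one study only,
        # near-silent elsewhere (emulates library-construction bias)
        sdg = []
        for s in range(n_studies):
            for i in range(60):
                g = f"SDG_S{s + 1}_{i + 1:02d}"
                sdg.append(g)
                roles[g] = {"role": "study_dispersed", "study": s}
                study_dispersed[g] = (s, 9.0, 2.5)
        parts.append(pd.DataFrame(2.0, index=sdg, columns=stage_names))

    # stage-specific planted genes for staging tests
    if with_named:
        flavours = {"8cell": "LEUTX", "morula": "ZNF296"}
        for s in stage_names:
            names = [f"STG_{s}_{i}" for i in (1, 2, 3)]
            if s in flavours:
                names[0] = flavours[s]
            for g in names:
                parts.append(pd.DataFrame(
                    {c: [np.log2(21.0) if c == s else 0.0] for c in stage_names}, index=[g]))
                roles[g] = {"role": "stage_specific", "stage": s}

    n_named = sum(len(p) for p in parts)
    n_bg = max(n_genes - n_named, 0)
    bg = _background(n_bg, rng)
    parts.append(pd.DataFrame({s: bg for s in stage_names}))
    for g in bg.index:
        roles[g] = {"role": "background"}

    programs = pd.concat(parts)
    return SimulationConfig(
        n_genes=len(programs),
        stages=list(stage_counts),
        programs=programs,
        marker_panel=default_marker_panel() if with_named else None,
        pou5f1_profile=dict(_POU5F1_PROFILE) if with_named else None,
        n_studies=n_studies,
        batch_scale_sd=batch_scale_sd,
        dropout_rates=tuple(dropout_rates),
        noise_sd=noise_sd,
        intermediate_fraction=intermediate_fraction,
        seed=seed,
        gene_roles=roles,
        extra_dispersion=extra_dispersion,
        study_dispersed=study_dispersed,
    )


def noise_free(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with all stochastic effects switched off.

    Cells then express their stage programs exactly (the noise-free
    limit used for deterministic marker-rule checks).
    """
    return dataclasses.replace(
        config,
        noise_sd=0.0,
        batch_scale_sd=0.0,
        dropout_rates=(0.0,) * config.n_studies,
        extra_dispersion={},
        study_dispersed={},
    )


def default_config(seed: int = 0) -> SimulationConfig:
    """Full zygote-to-late-blastocyst time course: 300 cells, 3 studies."""
    stage_counts = [
        ("zygote", 20), ("4cell", 20), ("8cell", 30), ("morula", 30),
        ("earlyICM", 40), ("EPI", 50), ("PrE", 50), ("TE", 60),
    ]
    return _assemble(stage_counts, n_genes=2000, seed=seed, n_studies=3,
                     dropout_rates=(0.1, 0.3, 0.2), batch_scale_sd=0.3,
                     noise_sd=0.5, variable_mode="stage_run")


def late_blastocyst_config(seed: int = 0) -> SimulationConfig:
    """Late blastocyst only: EPI/PrE/TE plus 10% planted intermediates, 300 cells."""
    stage_counts = [("EPI", 80), ("PrE", 80), ("TE", 110), ("intermediate", 30)]
    return _assemble(stage_counts, n_genes=2000, seed=seed, n_studies=3,
                     dropout_rates=(0.1, 0.3, 0.2), batch_scale_sd=0.3,
                     noise_sd=0.5, variable_mode="lineage",
                     include_study_noise=True, intermediate_fraction=0.1)


def hvg_config(seed: int = 0, n_variable: int = 100) -> SimulationConfig:
    """Stage-free fixture for variable-gene selection: 100 planted among 2000."""
    return _assemble([("morula", 300)], n_genes=2000, seed=seed, n_studies=3,
                     dropout_rates=(0.1, 0.3, 0.2), batch_scale_sd=0.3,
                     noise_sd=0.5, with_named=False, variable_mode="dispersed",
                     n_variable=n_variable)


def e5_config(seed: int = 0) -> SimulationConfig:
    """Early blastocyst mixture: 45 early-ICM among 300 E5 cells."""
    stage_counts = [("earlyICM", 45), ("EPI", 130), ("PrE", 125)]
    cfg = _assemble(stage_counts, n_genes=2000, seed=seed, n_studies=1,
                    dropout_rates=(0.1,), batch_scale_sd=0.0, noise_sd=0.5,
                    variable_mode="lineage")
    cfg.stage_day = {s: "E5" for s, _ in stage_counts}
    return cfg


def module_config(n_cells: int = 200, seed: int = 0, n_genes: int = 2000) -> SimulationConfig:
    """Single-stage, dropout-free fixture for co-expression module planting."""
    return _assemble([("morula", n_cells)], n_genes=n_genes, seed=seed, n_studies=1,
                     dropout_rates=(0.0,), batch_scale_sd=0.0, noise_sd=0.5,
                     with_named=False, variable_mode=None)


def simulate_psc_queries(config: SimulationConfig, seed: int = 0,
                         noise_sd: float = 0.3) -> pd.DataFrame:
    """Synthetic PSC query transcriptomes against a time-course config.

    ``naive`` follows the EPI program; ``conventional`` is a mixed
    program (part EPI, part spread over earlier stages plus an offset),
    emulating cultures that have diverged from the pre-implantation
    epiblast.  Returns a gene x sample FPKM DataFrame.
    """
    rng = np.random.default_rng(seed + 77)
    prog = config.programs
    naive = prog["EPI"].values + rng.normal(0.0, noise_sd, size=len(prog))
    mix = (0.35 * prog["EPI"].values + 0.25 * prog["morula"].values
           + 0.25 * prog["8cell"].values + 0.15 * prog["4cell"].values)
    conventional = mix + rng.normal(0.0, noise_sd, size=len(prog)) + 0.5
    out = pd.DataFrame(
        {
            "naive_PSC": np.maximum(2.0 ** naive - 1.0, 0.0),
            "conventional_PSC": np.maximum(2.0 ** conventional - 1.0, 0.0),
        },
        index=prog.index,
    )
    return out
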