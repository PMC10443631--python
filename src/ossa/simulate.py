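"""Synthetic multi-bone scRNA-seq cohorts with planted ground truth.

The generator emulates the statistical structure the downstream statistics
assume: per-gene lognormal baseline abundances, lognormal library sizes,
negative-binomial UMI counts, cell-type marker genes, a fixed expected
mitochondrial share, simulated doublet scores, and multiplicative planted
effects — region × cell-type × condition expression shifts and
ligand-receptor pair elevations — whose identities are returned as ground
truth for recovery testing.

The count for cell *i*, gene *g* is drawn NB(mean = L_i · μ_g · m_tg · 2^Δ,
size = r) where L_i is the cell's library-size factor, μ_g the baseline
relative abundance, m_tg the marker multiplier of the cell's type and Δ the
sum of the planted log2 fold changes that apply to (region, type,
condition, gene).  Doublets are sums of two random singlet profiles from
the same sample and carry a doublet score above 0.1; singlets score below.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CONDITIONS, CellMatrix, infer_tissue_class
from ._utils import logger

PAPER_REGIONS = (
    "calvaria",
    "scapula",
    "humerus",
    "vertebra",
    "pelvis",
    "femur",
    "meninges",
    "brain",
)
PAPER_CELL_TYPES = ("neutrophils", "monocytes", "b_cells", "progenitors", "erythroid")

# Real mouse gene symbols embedded in the preset gene vocabulary so that the
# bundled ligand-receptor database and the inflammation gene sets resolve
# against simulated cohorts.
_NAMED_GENES_LR = (
    "Pecam1", "Cd177", "Cd74", "Mif", "Il1b", "Adrb2", "Ccl4", "Ccr5",
    "Cxcl2", "Dpp4", "Cd28", "Cd86", "Cxcl12", "Cxcr4", "Tnf", "Tnfrsf1a",
    "Il6", "Il6ra", "Csf1", "Csf1r", "Kitl", "Kit", "Ccl2", "Ccr2",
    "Cxcl1", "Cxcr2", "Tgfb1", "Tgfbr1", "Il10", "Il10ra", "Ccl5", "Ccr1",
    "Vcam1", "Itga4", "Icam1", "Itgb2", "Sele", "Selplg", "Cx3cl1", "Cx3cr1",
    "Flt3l", "Flt3", "Angpt1", "Tek", "Jag1", "Notch1", "Dll1", "Notch2",
    "Vegfa", "Kdr", "Il7", "Il7r", "Ccl19", "Ccr7", "Cd40lg", "Cd40",
    "Fasl", "Fas", "Lgals9", "Havcr2", "Cd44", "Il18r1", "Il1r1", "Il4ra",
    "Ifngr1", "Il11ra1",
)
_NAMED_GENES_INFLAM = (
    "Il1a", "Ifng", "Il11", "Il7d", "Il7f", "Il18",
    "Il1rn", "Il4", "Il12a", "Il13",
)


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    The defaults are the study-scale conditions used throughout the test
    suite; :func:`design_from_paper` returns the full 8-region preset.
    """

    n_regions: int = 6
    n_conditions: int = 3
    n_cell_types: int = 3
    cells_per_sample: int = 300
    n_genes: int = 1000
    n_mito_genes: int = 20
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 10.0
    gene_varying_dispersion: bool = False
    dispersion_log_sd: float = 0.3
    libsize_log_mean: float = math.log(2500.0)
    libsize_log_sd: float = 0.35
    marker_genes_per_type: int = 20
    marker_fold: float = 8.0
    mito_share: float = 0.05
    doublet_fraction: float = 0.05
    seed: int = 0
    region_labels: Sequence[str] | None = None
    condition_labels: Sequence[str] | None = None
    cell_type_labels: Sequence[str] | None = None
    gene_names: Sequence[str] | None = None
    # per-gene baseline relative abundance pins, as multiples of the mean
    # gene abundance (e.g. {"Il6": 0.01} makes Il6 a rare transcript whose
    # expressing fraction sits below the LR testability floor until planted
    # up in one region — the structure behind region-unique interactions)
    pinned_rel_abundance: Mapping[str, float] | None = None

    def resolved_regions(self) -> list[str]:
        if self.region_labels is not None:
            return list(self.region_labels)
        return [f"region_{i}" for i in range(self.n_regions)]

    def resolved_conditions(self) -> list[str]:
        if self.condition_labels is not None:
            return list(self.condition_labels)
        return list(CONDITIONS[: self.n_conditions])

    def resolved_cell_types(self) -> list[str]:
        if self.cell_type_labels is not None:
            return list(self.cell_type_labels)
        return [f"type_{i}" for i in range(self.n_cell_types)]

    def validate(self) -> "SimulationConfig":
        if min(self.n_regions, self.n_conditions, self.n_cell_types) < 1:
            raise ValueError("region/condition/cell-type counts must be >= 1")
        if self.cells_per_sample < 1 or self.n_genes < 1:
            raise ValueError("cells_per_sample and n_genes must be >= 1")
        if not (0 <= self.n_mito_genes < self.n_genes):
            raise ValueError("n_mito_genes must be in [0, n_genes)")
        if self.nb_dispersion <= 0 or self.marker_fold <= 0:
            raise ValueError("nb_dispersion and marker_fold must be positive")
        for name in ("mito_share", "doublet_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0,1]")
        if len(self.resolved_regions()) != self.n_regions:
            raise ValueError("region_labels length must equal n_regions")
        if len(self.resolved_conditions()) != self.n_conditions:
            raise ValueError("condition_labels length must equal n_conditions")
        if len(self.resolved_cell_types()) != self.n_cell_types:
            raise ValueError("cell_type_labels length must equal n_cell_types")
        return self


@dataclasses.dataclass
class PlantedEffect:
    """A multiplicative 2^log2_fold shift of one gene in one region,
    restricted to one cell type and/or condition ("all" = unrestricted)."""

    gene_id: str
    region: str
    cell_type: str = "all"
    condition: str = "all"
    log2_fold: float = 1.0


@dataclasses.dataclass
class PlantedLRPair:
    """A ligand-receptor pair elevated `fold`-fold in one region: the ligand
    in the sender cell type and the receptor in the receiver cell type."""

    ligand: str
    receptor: str
    sender_type: str
    receiver_type: str
    region: str
    fold: float = 4.0


@dataclasses.dataclass
class GroundTruth:
    planted_effects: list
    planted_lr: list
    true_cell_type: pd.Series
    true_doublet: pd.Series


def _gene_ids(config: SimulationConfig) -> list[str]:
    names = []
    named = list(config.gene_names or ())
    n_regular = config.n_genes - config.n_mito_genes
    if len(named) > n_regular:
        raise ValueError("more gene_names than non-mitochondrial genes")
    names.extend(f"mt-g{i:04d}" for i in range(config.n_mito_genes))
    names.extend(named)
    names.extend(f"g{i:04d}" for i in range(n_regular - len(named)))
    return names


def simulate_cohort(
    config: SimulationConfig,
    effects: Sequence[PlantedEffect] = (),
    lr_pairs: Sequence[PlantedLRPair] = (),
) -> tuple[CellMatrix, GroundTruth]:
    """Draw one cohort.  Identical (config, effects, lr_pairs) gives
    bit-identical output: all randomness flows through one seeded PCG64."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = config.resolved_regions()
    conditions = config.resolved_conditions()
    cell_types = config.resolved_cell_types()
    gene_ids = _gene_ids(config)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    n_genes = config.n_genes

    # planted ids must resolve before any random draw
    for eff in effects:
        _check_effect(eff, gene_index, regions, cell_types, conditions)
    for pair in lr_pairs:
        if pair.ligand == pair.receptor:
            raise ValueError(f"LR pair with identical ligand and receptor {pair.ligand!r}")
        for g in (pair.ligand, pair.receptor):
            if g not in gene_index:
                raise ValueError(f"planted LR gene {g!r} not in cohort")
        if pair.region not in regions:
            raise ValueError(f"planted LR region {pair.region!r} not in design")
        for t in (pair.sender_type, pair.receiver_type):
            if t not in cell_types:
                raise ValueError(f"planted LR cell type {t!r} not in design")
        if pair.fold <= 0:
            raise ValueError("LR fold must be positive")

    # LR elevations reduce to per-(region, type, gene) multiplicative effects
    all_effects = list(effects)
    for pair in lr_pairs:
        lf = math.log2(pair.fold)
        all_effects.append(
            PlantedEffect(pair.ligand, pair.region, pair.sender_type, "all", lf)
        )
        all_effects.append(
            PlantedEffect(pair.receptor, pair.region, pair.receiver_type, "all", lf)
        )

    # baseline relative abundances, mito share pinned at config.mito_share
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    for g, mult in (config.pinned_rel_abundance or {}).items():
        if g not in gene_index:
            raise ValueError(f"pinned gene {g!r} not in cohort")
        if mult <= 0:
            raise ValueError("pinned relative abundance must be positive")
        base[gene_index[g]] = mult * base.mean()
    n_mito = config.n_mito_genes
    if n_mito > 0 and config.mito_share > 0:
        s_m, s_o = base[:n_mito].sum(), base[n_mito:].sum()
        base[:n_mito] *= (config.mito_share / (1.0 - config.mito_share)) * s_o / s_m
    mu = base / base.sum()

    # marker multipliers per cell type: disjoint blocks of non-mito genes
    type_mult = np.ones((len(cell_types), n_genes))
    mk = config.marker_genes_per_type
    for t in range(len(cell_types)):
        lo = n_mito + t * mk
        hi = min(lo + mk, n_genes)
        if lo < hi:
            type_mult[t, lo:hi] = config.marker_fold

    if config.gene_varying_dispersion:
        disp = rng.lognormal(math.log(config.nb_dispersion), config.dispersion_log_sd, n_genes)
    else:
        disp = np.full(n_genes, float(config.nb_dispersion))

    blocks, cell_rows, type_series, doublet_series = [], [], [], []
    for region in regions:
        for condition in conditions:
            sample_id = f"{region}_{condition}"
            n = config.cells_per_sample
            types = rng.integers(0, len(cell_types), size=n)
            libs = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n)
            mult = _effect_multipliers(
                all_effects, region, condition, cell_types, gene_index, n_genes
            )
            mean = libs[:, None] * (mu[None, :] * type_mult[types] * mult[types])
            counts = rng.negative_binomial(disp[None, :], disp[None, :] / (disp[None, :] + mean))
            n_dbl = int(round(config.doublet_fraction * n))
            if n_dbl > 0:
                pa = rng.integers(0, n, size=n_dbl)
                pb = (pa + 1 + rng.integers(0, n - 1, size=n_dbl)) % n
                dbl_counts = counts[pa] + counts[pb]
                counts = np.vstack([counts, dbl_counts])
            scores = np.concatenate(
                [rng.uniform(0.0, 0.1, n), 1.0 - rng.uniform(0.0, 0.9, n_dbl)]
            )
            blocks.append(sp.csr_matrix(counts))
            for j in range(n + n_dbl):
                is_dbl = j >= n
                t_idx = types[pa[j - n]] if is_dbl else types[j]
                cell_rows.append(
                    {
                        "cell_id": f"{sample_id}_c{j:05d}",
                        "region": region,
                        "condition": condition,
                        "cell_type": cell_types[t_idx],
                        "sample_id": sample_id,
                        "tissue_class": infer_tissue_class(region),
                        "doublet_score": scores[j],
                    }
                )
                type_series.append(cell_types[t_idx])
                doublet_series.append(is_dbl)

    counts = sp.csr_matrix(sp.vstack(blocks, format="csr"), dtype=np.int64)
    cells = pd.DataFrame(cell_rows)
    genes = pd.DataFrame(
        {"gene_id": gene_ids, "is_mito": [i < n_mito for i in range(n_genes)]}
    )
    cohort = CellMatrix(counts, cells, genes).validate()
    truth = GroundTruth(
        planted_effects=list(effects),
        planted_lr=list(lr_pairs),
        true_cell_type=pd.Series(type_series, name="true_cell_type"),
        true_doublet=pd.Series(doublet_series, name="true_doublet"),
    )
    return cohort, truth


def _check_effect(eff, gene_index, regions, cell_types, conditions) -> None:
    if eff.gene_id not in gene_index:
        raise ValueError(f"planted gene {eff.gene_id!r} not in cohort")
    if eff.region not in regions:
        raise ValueError(f"planted region {eff.region!r} not in design")
    if eff.cell_type != "all" and eff.cell_type not in cell_types:
        raise ValueError(f"planted cell type {eff.cell_type!r} not in design")
    if eff.condition != "all" and eff.condition not in conditions:
        raise ValueError(f"planted condition {eff.condition!r} not in design")
    if not np.isfinite(eff.log2_fold):
        raise ValueError("planted log2_fold must be finite")


def _effect_multipliers(effects, region, condition, cell_types, gene_index, n_genes):
    """Per-cell-type gene multipliers for one (region, condition) sample."""
    mult = np.ones((len(cell_types), n_genes))
    for eff in effects:
        if eff.region != region:
            continue
        if eff.condition not in ("all", condition):
            continue
        g = gene_index[eff.gene_id]
        factor = 2.0 ** eff.log2_fold
        if eff.cell_type == "all":
            mult[:, g] *= factor
        else:
            mult[cell_types.index(eff.cell_type), g] *= factor
    return mult


def null_cohort(config: SimulationConfig) -> tuple[CellMatrix, GroundTruth]:
    """A cohort with no planted effects — the permutation-test calibration
    substrate."""
    return simulate_cohort(config, (), ())


def spike_doublets(cohort: CellMatrix, fraction: float, seed: int) -> CellMatrix:
    """Append synthetic doublets (pairwise cell sums) with doublet scores in
    (0.1, 1]; original cells are untouched."""
    if not (0.0 <= fraction < 0.5):
        raise ValueError("doublet fraction must be in [0, 0.5)")
    n = cohort.n_cells
    n_add = int(round(fraction * n))
    if n_add == 0:
        return cohort
    rng = np.random.default_rng(seed)
    pa = rng.integers(0, n, size=n_add)
    pb = (pa + 1 + rng.integers(0, n - 1, size=n_add)) % n
    extra = sp.csr_matrix(cohort.counts[pa] + cohort.counts[pb])
    new_cells = cohort.cells.iloc[pa].copy().reset_index(drop=True)
    new_cells["cell_id"] = [f"doublet_{i:05d}" for i in range(n_add)]
    new_cells["doublet_score"] = 1.0 - rng.uniform(0.0, 0.9, n_add)
    counts = sp.csr_matrix(sp.vstack([cohort.counts, extra], format="csr"))
    cells = pd.concat([cohort.cells, new_cells], ignore_index=True)
    out = CellMatrix(counts, cells, cohort.genes.copy())
    return out.validate()


def design_from_paper() -> SimulationConfig:
    """The full study design: three flat bones (calvaria, scapula, pelvis),
    two long bones (humerus, femur), one irregular bone (vertebra), plus
    meninges (dura) and brain; naive / sham / MCAo conditions; five coarse
    cell types.  ≈5,000 singlets at the default cells_per_sample."""
    named = tuple(dict.fromkeys(_NAMED_GENES_LR + _NAMED_GENES_INFLAM))
    cfg = SimulationConfig(
        n_regions=len(PAPER_REGIONS),
        n_conditions=3,
        n_cell_types=len(PAPER_CELL_TYPES),
        cells_per_sample=210,
        n_genes=1200,
        n_mito_genes=20,
        region_labels=PAPER_REGIONS,
        condition_labels=CONDITIONS,
        cell_type_labels=PAPER_CELL_TYPES,
        gene_names=named,
    )
    return cfg.validate()
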