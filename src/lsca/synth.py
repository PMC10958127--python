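"""Synthetic data generation for the whole pipeline.

Generates every input the analysis needs, with the statistical structure
the downstream methods assume:

* sorted reference profiles: a shared log2 baseline with one disjoint
  marker block per cell type elevated by a fixed log2 fold change, plus
  i.i.d. Gaussian noise;
* mixing fractions: i.i.d. Dirichlet rows on the simplex;
* pseudo-bulk cohorts: per-type median profiles (linear scale) mixed by the
  fraction matrix — so deconvolution has exact ground truth;
* survival outcomes: exponential proportional-hazards times driven by a
  linear predictor on the true fractions, with uniform censoring calibrated
  to a target censoring rate;
* gene sets with planted group-wise expression shifts for enrichment tests.

Every generator is a pure function of its arguments and a seed: identical
inputs give bit-identical outputs.  The cohort generator derives stage
seeds from a single master seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .deconv import FractionMatrix
from .io import HEMATO_CELL_TYPES, CellTypeLabels, ExpressionMatrix, GeneSetCollection, SurvivalTable

__all__ = [
    "SyntheticDesign",
    "SyntheticCohort",
    "simulate_reference_profiles",
    "simulate_fraction_matrix",
    "make_pseudobulk",
    "simulate_survival_from_fractions",
    "plant_gene_set_signal",
    "simulate_cohort",
    "lsc_like_gene_sets",
]

# fixed offsets for stage seeds derived from the master seed
_SEED_PROFILES, _SEED_FRACTIONS, _SEED_SURVIVAL = 11, 23, 37
_SEED_MOD = 2**31


@dataclass(frozen=True)
class SyntheticDesign:
    """Knobs of the synthetic study.

    Defaults mirror the reference/pseudo-bulk setting the pipeline is built
    for: 9 hematopoietic cell types, 50 planted markers per type at a log2
    fold change of 2, 4 sorted replicates per type with 0.25 log2-units of
    noise, and 100 Dirichlet(1) mixtures.
    """

    n_genes: int = 1000
    cell_types: tuple[str, ...] = HEMATO_CELL_TYPES
    markers_per_type: int = 50
    marker_log2fc: float = 2.0
    replicates_per_type: int = 4
    noise_sd: float = 0.25
    dirichlet_alpha: float | tuple[float, ...] = 1.0
    n_mixtures: int = 100
    baseline_log2: float = 5.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("marker blocks would overlap: markers_per_type * n_types > n_genes")
        for name in ("n_genes", "markers_per_type", "replicates_per_type", "n_mixtures"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.marker_log2fc < 0 or self.noise_sd < 0:
            raise ValueError("marker_log2fc and noise_sd must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def marker_block(self, cell_type: str) -> list[str]:
        """The disjoint block of planted marker genes for one cell type."""
        k = self.cell_types.index(cell_type)
        lo = k * self.markers_per_type
        return self.gene_ids[lo: lo + self.markers_per_type]


@dataclass
class SyntheticCohort:
    """A complete simulated cohort with its generating truth."""

    bulk: ExpressionMatrix            # linear scale
    true_fractions: FractionMatrix
    survival: SurvivalTable
    truth_coefficients: dict[str, float]
    censor_rate: float
    profiles: ExpressionMatrix = None  # log2-scale sorted reference profiles
    labels: CellTypeLabels = None

    def __post_init__(self) -> None:
        ids = self.bulk.sample_ids
        assert ids == self.true_fractions.sample_ids == self.survival.sample_ids


def simulate_reference_profiles(design: SyntheticDesign) -> tuple[ExpressionMatrix, CellTypeLabels]:
    """Simulate cell-type-sorted log2 expression profiles.

    Each cell type gets ``replicates_per_type`` samples; its marker block is
    elevated by ``marker_log2fc`` over a baseline shared by all cell types
    (per-gene levels drawn N(baseline_log2, baseline_sd), as real genes have
    heterogeneous constitutive expression); Gaussian noise with sd
    ``noise_sd`` is added i.i.d.
    """
    rng = np.random.default_rng((design.seed + _SEED_PROFILES) % _SEED_MOD)
    genes = design.gene_ids
    n_types = len(design.cell_types)
    cols, labels = [], {}
    base = design.baseline_log2 + rng.normal(0.0, design.baseline_sd, design.n_genes)
    matrix = np.empty((design.n_genes, n_types * design.replicates_per_type))
    j = 0
    for k, ct in enumerate(design.cell_types):
        mean = base.copy()
        lo = k * design.markers_per_type
        mean[lo: lo + design.markers_per_type] += design.marker_log2fc
        for r in range(design.replicates_per_type):
            sid = f"{ct}_rep{r}"
            noise = rng.normal(0.0, design.noise_sd, design.n_genes) if design.noise_sd > 0 else 0.0
            matrix[:, j] = mean + noise
            cols.append(sid)
            labels[sid] = ct
            j += 1
    expr = ExpressionMatrix(pd.DataFrame(matrix, index=genes, columns=cols), scale="log2")
    return expr, CellTypeLabels(labels, cell_types=design.cell_types)


def simulate_fraction_matrix(
    n_samples: int,
    cell_types=HEMATO_CELL_TYPES,
    alpha: float | tuple[float, ...] = 1.0,
    seed: int = 0,
) -> FractionMatrix:
    """Draw i.i.d. Dirichlet(alpha) mixing-fraction rows."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), (len(cell_types),))
    if (alpha_vec <= 0).any():
        raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(alpha_vec, size=n_samples)
    index = [f"S{i:04d}" for i in range(n_samples)]
    return FractionMatrix(pd.DataFrame(rows, index=index, columns=list(cell_types)))


def celltype_medians(profiles: ExpressionMatrix, labels: CellTypeLabels) -> pd.DataFrame:
    """Per-gene, per-cell-type median expression in linear scale."""
    linear = profiles.to_linear()
    cols = {}
    for ct in labels.present_types():
        samples = labels.samples_of(ct)
        cols[ct] = linear.values[samples].median(axis=1)
    return pd.DataFrame(cols)


def make_pseudobulk(
    profiles: ExpressionMatrix,
    labels: CellTypeLabels,
    fractions: FractionMatrix,
) -> ExpressionMatrix:
    """Mix per-type median profiles by known fractions into pseudo-bulk.

    Per-gene medians are taken within each cell type (linear scale), then
    each output sample is the fraction-weighted sum of the type medians:
    ``bulk = M @ F.T``.
    """
    missing = set(fractions.cell_types) - set(labels.present_types())
    if missing:
        raise ValueError(f"fraction cell types absent from labels: {sorted(missing)}")
    M = celltype_medians(profiles, labels)[fractions.cell_types]
    bulk = M.to_numpy() @ fractions.values.to_numpy().T
    return ExpressionMatrix(
        pd.DataFrame(bulk, index=M.index, columns=fractions.sample_ids), scale="linear"
    )


def simulate_survival_from_fractions(
    fractions: FractionMatrix,
    coefficients,
    baseline_scale: float = 1000.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    time_unit: str = "days",
) -> SurvivalTable:
    """Exponential proportional-hazards event times from true fractions.

    The linear predictor is ``eta = sum_c beta_c * F_c``; event times are
    Exp(rate = exp(eta) / baseline_scale).  Censoring times are uniform on
    [0, c] with c solved on the realised sample so the censored proportion
    matches ``censor_rate``; ``censor_rate = 0`` observes every event.
    """
    coef = dict(getattr(coefficients, "coefficients", coefficients))
    if not coef:
        raise ValueError("empty coefficient vector")
    missing = set(coef) - set(fractions.cell_types)
    if missing:
        raise ValueError(f"coefficient names absent from fractions: {sorted(missing)}")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    F = fractions.values
    eta = sum(beta * F[ct].to_numpy(dtype=float) for ct, beta in coef.items())
    rate = np.exp(eta) / baseline_scale
    t_event = rng.exponential(1.0 / rate)
    if censor_rate == 0:
        time, event = t_event, np.ones(len(t_event), dtype=int)
    else:
        u = rng.uniform(size=len(t_event))

        def censored_frac(c):
            return float(np.mean(t_event > c * u)) - censor_rate

        hi = float(t_event.max()) * 2
        while censored_frac(hi) > 0:
            hi *= 2
        c = scipy.optimize.brentq(censored_frac, 1e-9, hi, xtol=1e-9)
        t_cens = c * u
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    df = pd.DataFrame({"time": time, "event": event}, index=fractions.sample_ids)
    return SurvivalTable(df, time_unit=time_unit)


def plant_gene_set_signal(
    bulk: ExpressionMatrix,
    groups: pd.Series | dict,
    gene_set: list[str],
    delta: float,
    target_group=None,
) -> ExpressionMatrix:
    """Shift a gene set by +delta (log2 units) in one sample group only.

    ``groups`` maps sample id -> group label; ``target_group`` picks the
    group that receives the shift (default: the first label encountered).
    On a linear-scale matrix the shift multiplies by ``2**delta``.
    """
    groups = pd.Series(groups)
    unknown = set(gene_set) - set(bulk.gene_ids)
    if unknown:
        raise ValueError(f"genes not in matrix: {sorted(unknown)[:5]}")
    if target_group is None:
        target_group = groups.iloc[0]
    target_samples = [s for s in bulk.sample_ids if groups.get(s) == target_group]
    values = bulk.values.copy()
    if bulk.scale == "log2":
        values.loc[gene_set, target_samples] += delta
    else:
        values.loc[gene_set, target_samples] *= 2.0 ** delta
    return ExpressionMatrix(values, scale=bulk.scale)


def lsc_like_gene_sets(design: SyntheticDesign, set_size: int = 40,
                       n_sets: int = 6) -> GeneSetCollection:
    """Disjoint gene sets drawn from the non-marker baseline genes.

    Stand-ins for LSC-program gene sets (up/down pairs); signal is planted
    separately with :func:`plant_gene_set_signal`.
    """
    pool = design.gene_ids[design.markers_per_type * len(design.cell_types):]
    if n_sets * set_size > len(pool):
        raise ValueError("not enough baseline genes for the requested gene sets")
    sets = {}
    for i in range(n_sets):
        direction = "UP" if i % 2 == 0 else "DN"
        name = f"SYNTH_LSC_SET{i // 2 + 1}_{direction}"
        genes = pool[i * set_size: (i + 1) * set_size]
        sets[name] = (f"synthetic LSC-like set {i}", list(genes))
    return GeneSetCollection(sets)


def simulate_cohort(
    design: SyntheticDesign = SyntheticDesign(),
    coefficients: dict[str, float] | None = None,
    baseline_scale: float = 1000.0,
    censor_rate: float = 0.3,
) -> SyntheticCohort:
    """One-call cohort: profiles -> fractions -> pseudo-bulk -> survival.

    ``coefficients`` default to the published five-cell-type prognostic
    weights, so simulated survival depends on the latent fractions the way
    the fitted score assumes.
    """
    if coefficients is None:
        from .model import PUBLISHED_COEFFICIENTS
        coefficients = dict(PUBLISHED_COEFFICIENTS)
    profiles, labels = simulate_reference_profiles(design)
    fractions = simulate_fraction_matrix(
        design.n_mixtures, design.cell_types, design.dirichlet_alpha,
        seed=(design.seed + _SEED_FRACTIONS) % _SEED_MOD,
    )
    bulk = make_pseudobulk(profiles, labels, fractions)
    survival = simulate_survival_from_fractions(
        fractions, coefficients, baseline_scale=baseline_scale,
        censor_rate=censor_rate, seed=(design.seed + _SEED_SURVIVAL) % _SEED_MOD,
    )
    return SyntheticCohort(
        bulk=bulk, true_fractions=fractions, survival=survival,
        truth_coefficients=dict(coefficients), censor_rate=censor_rate,
        profiles=profiles, labels=labels,
    )
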