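"""Synthetic multi-cohort methylation data with known ground truth.

The generator emulates the statistical structure a case/control methylation
EWAS assumes, so every downstream stage (normalization, deconvolution,
per-probe regression, replication, coregulation modules, mediation, and
endophenotype models) can be exercised and checked against planted truth:

* beta values arise from a logit-normal model: a per-probe baseline plus
  block-latent, group, covariate and noise terms on the logit (M-value)
  scale, pushed through the inverse logit;
* group effects are planted on the logit scale but *specified* on the beta
  scale (the delta a per-probe regression should recover); the logit shift
  is delta divided by the cohort-average derivative of the inverse logit,
  applied symmetrically (+/- half to cases/controls) so the realized
  beta-scale difference matches delta to third order;
* correlated probe blocks share a standard-normal latent factor with
  loading sqrt(rho), giving within-block correlation rho on the logit scale;
* samples are mixtures of pure cell-type profiles whose composition differs
  by diagnosis group — the classic cell-composition confound that the
  deconvolution covariates must absorb;
* one designated block is the *mediator*: its latent factor drives the
  outcome (morning cortisol) with coefficient gamma, and selected ROI BOLD
  eigenvariates through a monotone (hence Kendall-detectable) transform.

One global seed governs everything; per-cohort sub-streams are spawned from
it so cohorts are independent but jointly reproducible, while the probe
architecture (baselines, causal set, blocks, cell profiles) is shared across
cohorts — replication analyses need a common probe namespace with common
causal loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_io import BetaMatrix, CellReference, ProbeManifest, SampleTable

__all__ = [
    "ModuleBlock",
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_study",
    "generate_intensity_pair",
    "default_manifest",
]

#: ROI labels mirroring a bilateral fear-circuit region set.
ROI_LABELS = (
    "amygdala_left",
    "amygdala_right",
    "hippocampus_left",
    "hippocampus_right",
    "insula_left",
    "insula_right",
    "rostral_acc_left",
    "rostral_acc_right",
    "vmpfc_left",
    "vmpfc_right",
)


@dataclass(frozen=True)
class ModuleBlock:
    """A planted coregulated probe block: ``size`` probes sharing a latent
    factor with within-block logit-scale correlation ``rho``."""

    size: int
    rho: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("block size must be >= 2")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort (or a multi-cohort study).

    Defaults mirror a desk-scale version of a blood EWAS: three cohorts of
    500/100/400 samples, 5,000 probes of which 96 carry a planted diagnosis
    effect, one 50-probe mediator block inside the causal set, six blood
    cell types with a diagnosis-dependent composition shift, and morning
    cortisol driven by the mediator block's latent factor.
    """

    n_samples: int = 500
    n_probes: int = 5000
    n_causal: int = 96
    #: beta-scale effect magnitudes drawn uniformly from this range
    delta_range: tuple[float, float] = (0.01, 0.05)
    #: fraction of causal probes with negative (hypomethylation) effects
    frac_negative: float = 0.7
    #: explicit per-causal-probe effects; overrides delta_range when given
    deltas: np.ndarray | None = None
    module_blocks: tuple[ModuleBlock, ...] = (ModuleBlock(50, 0.9),)
    #: blocks are carved out of the causal probe set (the replicated-hit
    #: geometry: the coregulated module sits inside the associated probes)
    blocks_within_causal: bool = True
    mediator_block: int = 0
    gamma: float = -4.0
    sigma_out: float = 8.0
    cortisol_baseline: float = 12.0
    n_cell_types: int = 6
    #: Dirichlet concentration of control-group compositions
    composition_alpha: tuple[float, ...] = (12.0, 6.0, 4.0, 3.0, 2.0, 1.0)
    #: per-type multiplier applied to the Dirichlet alpha for cases; None
    #: switches the composition confound off
    composition_shift: tuple[float, ...] | None = (1.5, 0.6, 1.0, 1.3, 0.7, 1.0)
    #: fraction of probes that strongly discriminate cell types
    frac_discriminating: float = 0.05
    #: Beta concentration of type profiles around the probe baseline
    #: (discriminating / background probes)
    profile_concentration: tuple[float, float] = (15.0, 500.0)
    case_fraction: float = 0.5
    #: logit-scale residual noise standard deviation
    noise_sd: float = 0.3
    #: fraction of probes with nuisance covariate (age/sex/smoking) effects
    frac_covariate_probes: float = 0.10
    covariate_effect_sd: float = 0.02
    #: smoking score correlates with diagnosis (comorbidity); set False to
    #: simulate smoking independent of diagnosis for sensitivity analyses
    smoking_comorbid: bool = True
    #: ROI eigenvariates coupled to the mediator latent, and the coupling
    bold_coupled_rois: tuple[str, ...] = ("amygdala_right",)
    bold_coupling: float = 0.45
    #: right-hippocampus volume coupling to the mediator latent (mm^3 / SD)
    volume_coupling: float = 150.0
    #: per-cohort multiplier on the planted effects (cross-cohort attenuation)
    effect_scale: float = 1.0
    cohort_sizes: tuple[int, ...] = (500, 100, 400)
    cohort_effect_scales: tuple[float, ...] = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_causal > self.n_probes:
            raise ValueError("n_causal cannot exceed n_probes")
        lo, hi = self.delta_range
        if not (-1 < lo <= hi < 1):
            raise ValueError("delta_range must lie inside (-1, 1)")
        if self.deltas is not None:
            d = np.asarray(self.deltas, dtype=float)
            if d.shape != (self.n_causal,):
                raise ValueError("deltas must have length n_causal")
            if (np.abs(d) >= 1).any():
                raise ValueError("deltas must lie in (-1, 1)")
        if sum(b.size for b in self.module_blocks) > (
            self.n_causal if self.blocks_within_causal else self.n_probes
        ):
            raise ValueError("module blocks do not fit in the probe set")
        if len(self.composition_alpha) != self.n_cell_types:
            raise ValueError("composition_alpha length must equal n_cell_types")
        if self.composition_shift is not None and len(self.composition_shift) != self.n_cell_types:
            raise ValueError("composition_shift length must equal n_cell_types")
        if self.module_blocks and not 0 <= self.mediator_block < len(self.module_blocks):
            raise ValueError("mediator_block index out of range")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each synthetic cohort."""

    causal_probes: pd.Index
    deltas: pd.Series  # beta-scale effect per causal probe
    block_membership: pd.Series  # probe -> block index (-1 = none)
    mediator_block: int
    mediator_latent: pd.Series  # per-sample latent factor of the mediator block
    true_proportions: pd.DataFrame  # samples x cell types
    gamma: float
    sigma_out: float


@dataclass
class _ProbeArchitecture:
    """Probe-level parameters shared by every cohort of a study."""

    probe_ids: pd.Index
    baseline_logit: np.ndarray
    causal_idx: np.ndarray
    deltas: np.ndarray
    block_of: np.ndarray  # -1 for non-block probes
    profiles: pd.DataFrame  # cell types x probes
    cov_effects: dict[str, np.ndarray]  # per-covariate logit effects per probe
    design_type: np.ndarray  # "I"/"II" per probe


def _build_architecture(config: SimulationConfig, rng: np.random.Generator) -> _ProbeArchitecture:
    p = config.n_probes
    probe_ids = pd.Index([f"cg{j:08d}" for j in range(p)], name="probe_id")

    # Baselines: bimodal like a real array, but causal/block probes sit in the
    # intermediate-methylation range where beta-scale group differences of a
    # few percent are representable.
    comp = rng.choice(3, size=p, p=[0.3, 0.4, 0.3])
    base = np.where(
        comp == 0,
        rng.beta(1.5, 8.0, size=p),
        np.where(comp == 1, rng.beta(5.0, 5.0, size=p), rng.beta(8.0, 1.5, size=p)),
    )

    causal_idx = rng.choice(p, size=config.n_causal, replace=False)
    base[causal_idx] = rng.beta(5.0, 5.0, size=config.n_causal)
    if config.deltas is not None:
        deltas = np.asarray(config.deltas, dtype=float).copy()
    else:
        mags = rng.uniform(*config.delta_range, size=config.n_causal)
        signs = np.where(rng.random(config.n_causal) < config.frac_negative, -1.0, 1.0)
        deltas = mags * signs

    block_of = np.full(p, -1, dtype=int)
    pool = causal_idx if config.blocks_within_causal else np.arange(p)
    pool = rng.permutation(pool)
    start = 0
    for b, blk in enumerate(config.module_blocks):
        block_of[pool[start : start + blk.size]] = b
        start += blk.size

    base = np.clip(base, 1e-3, 1 - 1e-3)
    baseline_logit = logit(base)

    kappa_strong, kappa_weak = config.profile_concentration
    discr = rng.random(p) < config.frac_discriminating
    kappa = np.where(discr, kappa_strong, kappa_weak)
    prof = rng.beta(
        np.tile(base * kappa, (config.n_cell_types, 1)),
        np.tile((1 - base) * kappa, (config.n_cell_types, 1)),
    )
    profiles = pd.DataFrame(
        prof,
        index=pd.Index([f"cell{c}" for c in range(config.n_cell_types)], name="cell_type"),
        columns=probe_ids,
    )

    cov_effects = {}
    for cov in ("age", "sex", "smoking_score"):
        eff = np.zeros(p)
        hit = rng.random(p) < config.frac_covariate_probes
        eff[hit] = rng.normal(0.0, config.covariate_effect_sd, size=hit.sum())
        cov_effects[cov] = eff

    design_type = np.where(rng.random(p) < 0.7, "II", "I")
    return _ProbeArchitecture(
        probe_ids, baseline_logit, causal_idx, deltas, block_of, profiles, cov_effects, design_type
    )


def _sample_cohort(
    config: SimulationConfig,
    arch: _ProbeArchitecture,
    n: int,
    cohort_id: str,
    effect_scale: float,
    rng: np.random.Generator,
) -> tuple[BetaMatrix, SampleTable, GroundTruth]:
    p = config.n_probes
    sample_ids = pd.Index([f"{cohort_id}_s{i:04d}" for i in range(n)], name="sample_id")

    diagnosis = (rng.random(n) < config.case_fraction).astype(float)
    age = np.clip(rng.normal(45.0, 12.0, size=n), 21.0, 75.0)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    ancestry = rng.choice(["EUR", "AFR", "AMR"], size=n, p=[0.5, 0.35, 0.15])
    if config.smoking_comorbid:
        smoking = rng.poisson(1.0 + 3.0 * diagnosis).astype(float)
    else:
        smoking = rng.poisson(2.0, size=n).astype(float)
    drinks_per_day = np.where(
        diagnosis == 1, rng.gamma(6.0, 1.5, size=n), rng.gamma(1.2, 0.6, size=n)
    )
    years_drinking = np.round(rng.uniform(3.0, 35.0, size=n), 1)
    units_per_week = drinks_per_day * 7.0 * rng.lognormal(0.0, 0.15, size=n)
    pack_years = smoking * rng.uniform(0.0, 2.5, size=n)

    # cell compositions: Dirichlet, with case alphas rescaled (the confound)
    alpha0 = np.asarray(config.composition_alpha, dtype=float)
    if config.composition_shift is None:
        alphas = np.tile(alpha0, (n, 1))
    else:
        shift = np.asarray(config.composition_shift, dtype=float)
        alphas = np.where(diagnosis[:, None] == 1, alpha0 * shift, alpha0)
    props = np.vstack([rng.dirichlet(a) for a in alphas])
    true_props = pd.DataFrame(
        props, index=sample_ids, columns=arch.profiles.index
    )

    # sample-level logit deviations: block latents, idiosyncratic noise,
    # nuisance covariate effects (shared by every cell type of a sample)
    n_blocks = len(config.module_blocks)
    latents = rng.normal(size=(n, n_blocks)) if n_blocks else np.empty((n, 0))
    z = rng.normal(size=(n, p))
    for b, blk in enumerate(config.module_blocks):
        members = arch.block_of == b
        z[:, members] = (
            np.sqrt(blk.rho) * latents[:, [b]]
            + np.sqrt(1.0 - blk.rho) * z[:, members]
        )
    dev = config.noise_sd * z
    age_z = (age - age.mean()) / age.std()
    sex_num = (sex == "M").astype(float)
    dev += np.outer(age_z, arch.cov_effects["age"])
    dev += np.outer(sex_num, arch.cov_effects["sex"])
    dev += np.outer(smoking, arch.cov_effects["smoking_score"])

    # each pure cell type carries the deviation on its own logit scale, and
    # the sample's beta is the proportion-weighted mixture — so beta is
    # *linear* in the true proportions and the composition confound is
    # removable by the linear covariate adjustment the analysis applies
    logit_prof = logit(np.clip(arch.profiles.to_numpy(), 1e-4, 1 - 1e-4))
    deriv = np.zeros((n, p))
    for c in range(config.n_cell_types):
        pr = expit(dev + logit_prof[c][None, :])
        deriv += props[:, [c]] * pr * (1 - pr)

    # plant group effects: beta-scale delta -> logit shift via the cohort
    # average derivative, applied +/- half so the realized difference is delta
    d_avg = deriv.mean(axis=0)
    shift_m = np.zeros(p)
    shift_m[arch.causal_idx] = effect_scale * arch.deltas / d_avg[arch.causal_idx]
    dev = dev + np.outer(diagnosis - 0.5, shift_m)

    beta = np.zeros((n, p))
    for c in range(config.n_cell_types):
        beta += props[:, [c]] * expit(dev + logit_prof[c][None, :])
    matrix = BetaMatrix(pd.DataFrame(beta.T, index=arch.probe_ids, columns=sample_ids))

    med_latent = (
        latents[:, config.mediator_block]
        if n_blocks
        else np.zeros(n)
    )
    cortisol = (
        config.cortisol_baseline
        + config.gamma * med_latent
        + 0.04 * (age - age.mean())
        + 0.8 * sex_num
        + rng.normal(0.0, config.sigma_out, size=n)
    )

    table = pd.DataFrame(
        {
            "cohort_id": cohort_id,
            "diagnosis": diagnosis,
            "units_per_week": units_per_week,
            "age": np.round(age, 1),
            "sex": sex,
            "ancestry": ancestry,
            "smoking_score": smoking,
            "pack_years": np.round(pack_years, 2),
            "drinks_per_day": np.round(drinks_per_day, 2),
            "years_drinking": years_drinking,
            "cortisol": cortisol,
            "tissue": "blood",
        },
        index=sample_ids,
    )
    # BOLD eigenvariates: coupled ROIs get a monotone transform of the
    # mediator latent (cube-enriched, so strictly monotone) plus noise
    for roi in ROI_LABELS:
        noise = rng.normal(0.0, 1.0, size=n)
        if roi in config.bold_coupled_rois and n_blocks:
            g = med_latent + 0.25 * med_latent**3
            g = (g - g.mean()) / g.std()
            table[f"roi_bold_{roi}"] = config.bold_coupling * g + np.sqrt(
                1 - config.bold_coupling**2
            ) * noise
        else:
            table[f"roi_bold_{roi}"] = noise
    hip_base = rng.normal(4100.0, 320.0, size=n) - 6.0 * (age - age.mean())
    table["hippocampus_left"] = np.round(hip_base + rng.normal(0, 120, size=n), 1)
    table["hippocampus_right"] = np.round(
        hip_base + config.volume_coupling * med_latent + rng.normal(0, 120, size=n), 1
    )

    truth = GroundTruth(
        causal_probes=arch.probe_ids[arch.causal_idx],
        deltas=pd.Series(
            effect_scale * arch.deltas, index=arch.probe_ids[arch.causal_idx]
        ),
        block_membership=pd.Series(arch.block_of, index=arch.probe_ids),
        mediator_block=config.mediator_block,
        mediator_latent=pd.Series(med_latent, index=sample_ids),
        true_proportions=true_props,
        gamma=config.gamma,
        sigma_out=config.sigma_out,
    )
    return matrix, SampleTable(table), truth


def generate_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, SampleTable, CellReference, GroundTruth]:
    """Generate one cohort under ``config``; identical configs (including the
    seed) give byte-identical outputs."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    arch_ss, cohort_ss = ss.spawn(2)
    arch = _build_architecture(config, np.random.default_rng(arch_ss))
    matrix, table, truth = _sample_cohort(
        config,
        arch,
        config.n_samples,
        "c0",
        config.effect_scale,
        np.random.default_rng(cohort_ss),
    )
    return matrix, table, CellReference(arch.profiles), truth


def generate_study(
    config: SimulationConfig,
) -> tuple[list[tuple[BetaMatrix, SampleTable, GroundTruth]], CellReference]:
    """Generate a multi-cohort study sharing one probe architecture.

    Cohort sizes and per-cohort effect scales come from
    ``config.cohort_sizes`` / ``config.cohort_effect_scales``; each cohort
    draws its samples from an independent sub-stream spawned from the global
    seed.
    """
    config.validate()
    if len(config.cohort_effect_scales) != len(config.cohort_sizes):
        raise ValueError("cohort_effect_scales must match cohort_sizes in length")
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(1 + len(config.cohort_sizes))
    arch = _build_architecture(config, np.random.default_rng(streams[0]))
    cohorts = []
    for k, (n, scale) in enumerate(zip(config.cohort_sizes, config.cohort_effect_scales)):
        cohorts.append(
            _sample_cohort(
                config, arch, n, f"c{k}", scale, np.random.default_rng(streams[k + 1])
            )
        )
    return cohorts, CellReference(arch.profiles)


def default_manifest(
    probe_ids: Sequence[str],
    design_type: Sequence[str] | None = None,
    cross_reactive: Sequence[bool] | None = None,
    qc_fail: Sequence[bool] | None = None,
    seed: int = 0,
) -> ProbeManifest:
    """Build a probe manifest for a synthetic probe set.

    When flags are not supplied, design types are drawn 70% type II (the
    array's approximate mix) and QC flags are all clear.
    """
    n = len(probe_ids)
    rng = np.random.default_rng(seed)
    if design_type is None:
        design_type = np.where(rng.random(n) < 0.7, "II", "I")
    data = pd.DataFrame(
        {
            "gene_symbols": [""] * n,
            "design_type": list(design_type),
            "cross_reactive": list(cross_reactive) if cross_reactive is not None else False,
            "qc_fail": list(qc_fail) if qc_fail is not None else False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeManifest(data)


def generate_intensity_pair(
    matrix: BetaMatrix,
    design_types: pd.Series,
    depth: float = 4000.0,
    type2_scale: float = 2.0,
    noise_sd_frac: float = 0.0,
    offset: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Invert beta values into methylated/unmethylated intensity matrices.

    Per probe j with beta b and total depth D_j: M = s_j * D_j * b and
    U = s_j * D_j * (1 - b) - offset adjustments, where s_j is 1 for type I
    probes and ``type2_scale`` for type II — so the between-design scale
    correction downstream has real work to do.  Multiplicative Gaussian
    noise with sd ``noise_sd_frac`` of the signal is added when requested.
    With zero noise and zero offset, ``compute_beta(M, U, 0)`` reproduces
    the input betas exactly.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    beta = matrix.values
    dt = design_types.reindex(matrix.probe_ids).to_numpy()
    scale = np.where(dt == "II", type2_scale, 1.0)[:, None]
    total = depth * scale
    m_sig = total * beta + offset * 0.0
    u_sig = total * (1.0 - beta)
    if noise_sd_frac > 0:
        m_sig = m_sig + rng.normal(0.0, noise_sd_frac * depth, size=beta.shape) * scale
        u_sig = u_sig + rng.normal(0.0, noise_sd_frac * depth, size=beta.shape) * scale
    m_sig = np.clip(m_sig, 0.0, None)
    u_sig = np.clip(u_sig, 0.0, None)
    meth = pd.DataFrame(m_sig, index=matrix.probe_ids, columns=matrix.sample_ids)
    unmeth = pd.DataFrame(u_sig, index=matrix.probe_ids, columns=matrix.sample_ids)
    return meth, unmeth
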