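"""Synthetic tracer kinetics, voxel phantoms and lesion cohorts.

Every downstream stage of the quantitation chain is testable against known
ground truth through this module:

* a bolus-shaped plasma input function drives a two-tissue irreversible
  compartment model (striatum: trapping rate k3 > 0) or its one-tissue
  reduction (cerebellum reference: k3 = 0);
* an exact-identity constructor builds tissue curves that satisfy the Patlak
  relation to machine precision, so slope/intercept recovery can be checked
  without any modelling error;
* a 4D voxel phantom with an integer label mask exercises VOI extraction;
* a cohort generator emulates a unilateral 6-OHDA dose-response study:
  dose-dependent lesion severity with large inter-animal scatter at
  intermediate doses, striatal dopamine-plus-metabolite asymmetry linearly
  linked to the K_i asymmetry, and methamphetamine-induced rotation counts
  whose common logarithm falls linearly with the K_i asymmetry.

All randomness flows through one ``numpy`` Generator seeded from the config,
so identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .patlak import cumulative_trapezoid_from_origin
from .tac import FramingScheme, TimeActivityCurve

__all__ = [
    "BolusShape",
    "PlasmaCurve",
    "KineticParams",
    "LinkParams",
    "CohortConfig",
    "AnimalRecord",
    "Phantom4D",
    "DEFAULT_BOLUS",
    "REFERENCE_KINETICS",
    "STRIATUM_K1",
    "STRIATUM_K2",
    "simulate_input_function",
    "simulate_tissue_tac",
    "construct_patlak_exact_tac",
    "striatal_params_for_ki",
    "simulate_cohort",
    "default_brain_mask",
    "generate_phantom",
]


# ---------------------------------------------------------------------------
# Plasma input
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BolusShape:
    """Parameters of the analytic bolus input A*t*exp(-lam1*t) + B*exp(-lam2*t).

    The first term is the fast first-pass peak, the second the slow
    terminal clearance of parent tracer from plasma.  Units: A in
    kBq/mL/min, B in kBq/mL, rates in 1/min.
    """

    A: float = 300.0
    lam1: float = 4.0
    B: float = 30.0
    lam2: float = 0.025

    def __post_init__(self) -> None:
        if min(self.A, self.lam1, self.B, self.lam2) < 0:
            raise ValueError("bolus shape parameters must be non-negative")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.A * t * np.exp(-self.lam1 * t) + self.B * (
            -np.expm1(-self.lam1 * t)
        ) * np.exp(-self.lam2 * t)


#: Default plasma input: peaks near 0.25 min, terminal half-life ~28 min.
DEFAULT_BOLUS = BolusShape()


@dataclass(frozen=True)
class PlasmaCurve:
    """Sampled plasma activity concentration (kBq/mL) at given minutes.

    If the analytic ``shape`` is attached the curve evaluates exactly at any
    time; otherwise it interpolates linearly through (0, 0) and its samples.
    """

    times: np.ndarray
    values: np.ndarray
    shape: BolusShape | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(v < 0):
            raise ValueError("plasma activity must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def concentration(self, t):
        """Plasma concentration at arbitrary times (minutes)."""
        if self.shape is not None:
            return self.shape(t)
        return np.interp(
            np.asarray(t, dtype=float),
            np.concatenate([[0.0], self.times]),
            np.concatenate([[0.0], self.values]),
        )


def simulate_input_function(shape: BolusShape, times) -> PlasmaCurve:
    """Evaluate a bolus input at the given times (minutes).

    Deterministic; a bolus rises from zero at t=0 and decays
    multi-exponentially.
    """
    t = np.asarray(times, dtype=float)
    if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
        raise ValueError("times must be non-negative and strictly increasing")
    return PlasmaCurve(times=t, values=shape(t), shape=shape)


# ---------------------------------------------------------------------------
# Compartment model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the irreversible two-tissue model.

    K1 (mL/min/g): plasma-to-tissue transfer; k2 (1/min): tissue-to-plasma
    washout; k3 (1/min): irreversible trapping (0 for the reference tissue).
    The net influx macro-parameter is ``ki_true`` = K1*k3/(k2+k3).
    """

    K1: float
    k2: float
    k3: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be non-negative")

    @property
    def ki_true(self) -> float:
        denom = self.k2 + self.k3
        return self.K1 * self.k3 / denom if denom > 0 else 0.0


#: Cerebellar reference kinetics: no trapping, distribution volume K1/k2 = 1.
REFERENCE_KINETICS = KineticParams(K1=0.5, k2=0.5, k3=0.0)

#: Striatal transfer/washout defaults; k3 is solved per animal from target K_i.
#: k2 = 0.4/min keeps the free compartment equilibrated well before the 10-min
#: start of the Patlak window even for severely lesioned (small-k3) tissue.
STRIATUM_K1 = 0.4
STRIATUM_K2 = 0.4


def striatal_params_for_ki(
    ki: float, K1: float = STRIATUM_K1, k2: float = STRIATUM_K2
) -> KineticParams:
    """Kinetic parameters whose influx macro-parameter equals ``ki``.

    Solves K1*k3/(k2+k3) = ki for k3; requires 0 < ki < K1.
    """
    if not 0 < ki < K1:
        raise ValueError(f"target ki must lie in (0, K1={K1})")
    return KineticParams(K1=K1, k2=k2, k3=ki * k2 / (K1 - ki))


def simulate_tissue_tac(
    plasma: PlasmaCurve,
    params: KineticParams,
    scheme: FramingScheme,
    region: str = "",
) -> TimeActivityCurve:
    """Frame-averaged tissue activity from the two-tissue irreversible model.

    Solves
        C_free' = K1*Cp(t) - (k2+k3)*C_free,
        C_trap' = k3*C_free,
    and returns, per frame, the time-average of C_free + C_trap over the frame
    (what a scanner histogram measures), not a mid-point sample.  With k3 = 0
    the model reduces to the one-tissue reference model.  Simulated
    concentrations represent decay-corrected tracer amounts.
    """
    edges = scheme.edges_min
    K1, k2, k3 = params.K1, params.k2, params.k3

    def rhs(t, y):
        cp = float(plasma.concentration(t))
        cf = y[0]
        return (K1 * cp - (k2 + k3) * cf, k3 * cf, cf + y[1])

    # third state accumulates the running integral of total tissue activity
    sol = solve_ivp(
        rhs,
        (0.0, edges[-1]),
        (0.0, 0.0, 0.0),
        t_eval=edges,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - LSODA is robust for this linear system
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    frame_means = np.diff(sol.y[2]) / scheme.durations_min
    frame_means = np.clip(frame_means, 0.0, None)
    return TimeActivityCurve(scheme, frame_means, decay_corrected=True, region=region)


def construct_patlak_exact_tac(
    reference: TimeActivityCurve, ki: float, v: float
) -> TimeActivityCurve:
    """Tissue TAC satisfying the Patlak identity exactly on the frame grid.

    Builds C_T(t) = ki * int_0^t C_ref(u) du + v * C_ref(t), with the running
    integral computed by the same mid-time trapezoid rule the Patlak transform
    uses — so fitting the output against ``reference`` over any window
    recovers (ki, v) to numerical precision.
    """
    ref = reference.values
    if np.any(ref <= 0):
        raise ValueError("reference TAC must be strictly positive")
    cum = cumulative_trapezoid_from_origin(reference.mid_times_min, ref)
    return TimeActivityCurve(
        reference.scheme,
        ki * cum + v * ref,
        decay_corrected=reference.decay_corrected,
        region="patlak_exact",
    )


# ---------------------------------------------------------------------------
# Lesion cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkParams:
    """Linear link y = slope * x + intercept + N(0, noise_sd)."""

    slope: float
    intercept: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    def mean(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def _default_group_sizes() -> dict[int, int]:
    # PET arm of the study design: 3 sham controls, 6 per 6-OHDA dose.
    return {0: 3, 7: 6, 14: 6, 28: 6}


def _default_severity_mean() -> dict[int, float]:
    return {0: 1.0, 7: 0.70, 14: 0.55, 28: 0.32}


def _default_severity_sd() -> dict[int, float]:
    # wide scatter at the intermediate doses, tight at 0 and 28 ug
    return {0: 0.02, 7: 0.20, 14: 0.20, 28: 0.04}


@dataclass
class CohortConfig:
    """Generative parameters of a unilateral 6-OHDA lesion cohort.

    ``severity_mean``/``severity_sd`` give, per dose (μg), the truncated-normal
    distribution on (0, 1] of the residual ipsilateral influx fraction
    s = K_i(ipsi)/K_i(contra).  ``da_link`` maps the K_i R/L percentage to the
    dopamine-plus-metabolites R/L percentage; ``rot_link`` maps it to log10 of
    the rotation count per 90 min.  Doses listed in ``control_doses`` draw
    rotations from a low-mean Poisson instead of the log-linear link, because
    unlesioned animals rotate negligibly.
    """

    group_sizes: dict[int, int] = field(default_factory=_default_group_sizes)
    ki_contra_mean: float = 16.2e-3  # 1/min; intact-side influx constant
    ki_contra_sd: float = 0.25e-3
    severity_mean: dict[int, float] = field(default_factory=_default_severity_mean)
    severity_sd: dict[int, float] = field(default_factory=_default_severity_sd)
    da_contra_mean: float = 75.0  # nmol/g tissue, DA + DOPAC + HVA
    da_contra_sd: float = 8.0
    da_link: LinkParams = field(default_factory=lambda: LinkParams(1.2, -20.0, 8.0))
    rot_link: LinkParams = field(default_factory=lambda: LinkParams(-0.035, 4.0, 1.0))
    control_rotation_mean: float = 3.0
    control_doses: tuple[int, ...] = (0,)
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("at least one dose group is required")
        for dose, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group size for dose {dose} ug must be >= 1")
            if dose not in self.severity_mean or dose not in self.severity_sd:
                raise ValueError(f"no severity model for dose {dose} ug")
            m = self.severity_mean[dose]
            if not 0 < m <= 1:
                raise ValueError(f"severity mean for dose {dose} ug must be in (0, 1]")
            if self.severity_sd[dose] < 0:
                raise ValueError("severity SD must be non-negative")
        if min(self.ki_contra_sd, self.da_contra_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if self.ki_contra_mean <= 0 or self.da_contra_mean <= 0:
            raise ValueError("contralateral means must be positive")
        if self.control_rotation_mean < 0:
            raise ValueError("control rotation mean must be non-negative")


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's measured triplet: bilateral K_i, monoamines, rotations."""

    animal_id: str
    dose_ug: int
    ki_ipsi: float
    ki_contra: float
    da_ipsi: float
    da_contra: float
    rotations: int

    def __post_init__(self) -> None:
        if self.ki_ipsi <= 0 or self.ki_contra <= 0:
            raise ValueError("K_i values must be positive")
        if self.da_ipsi < 0 or self.da_contra < 0:
            raise ValueError("monoamine levels must be non-negative")
        if self.rotations < 0:
            raise ValueError("rotation count must be non-negative")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sampled normal truncated to (lo, hi]; deterministic given rng."""
    if sd == 0:
        if not lo < mean <= hi:
            raise ValueError(f"degenerate truncated normal at {mean} outside ({lo}, {hi}]")
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling did not converge")


def simulate_cohort(config: CohortConfig) -> list[AnimalRecord]:
    """Draw a full lesion cohort with the configured correlation structure.

    Per animal: the intact-side K_i is drawn around its configured mean; the
    residual fraction s comes from the dose group's truncated normal on
    (0, 1]; K_i(ipsi) = s * K_i(contra).  The monoamine R/L percentage is the
    linear ``da_link`` applied to 100*s plus noise, clipped to (0, 100]; the
    rotation count is round(10**(rot_link(100*s) + noise)) for lesioned
    groups and Poisson(control_rotation_mean) for control doses.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[AnimalRecord] = []
    for dose in sorted(config.group_sizes):
        n = config.group_sizes[dose]
        for i in range(n):
            ki_contra = _truncated_normal(
                rng, config.ki_contra_mean, config.ki_contra_sd, 0.0, np.inf
            )
            s = _truncated_normal(
                rng, config.severity_mean[dose], config.severity_sd[dose], 0.0, 1.0
            )
            da_contra = _truncated_normal(
                rng, config.da_contra_mean, config.da_contra_sd, 0.0, np.inf
            )
            da_pct = config.da_link.mean(100.0 * s)
            if config.da_link.noise_sd > 0:
                da_pct += rng.normal(0.0, config.da_link.noise_sd)
            da_pct = float(np.clip(da_pct, 0.1, 100.0))
            if dose in config.control_doses:
                rotations = int(rng.poisson(config.control_rotation_mean))
            else:
                log_rot = config.rot_link.mean(100.0 * s)
                if config.rot_link.noise_sd > 0:
                    log_rot += rng.normal(0.0, config.rot_link.noise_sd)
                rotations = int(round(10.0 ** float(log_rot)))
            records.append(
                AnimalRecord(
                    animal_id=f"d{dose:02d}a{i + 1:02d}",
                    dose_ug=dose,
                    ki_ipsi=s * ki_contra,
                    ki_contra=ki_contra,
                    da_ipsi=da_pct / 100.0 * da_contra,
                    da_contra=da_contra,
                    rotations=rotations,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Voxel phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Phantom4D:
    """4D activity volume plus integer label mask on a common grid.

    Labels: 0 background, 1 left striatum, 2 right striatum, 3 cerebellum.
    ``frames`` has shape (nx, ny, nz, n_frames); ``spacing_mm`` is isotropic
    per-axis voxel size.
    """

    frames: np.ndarray
    mask: np.ndarray
    scheme: FramingScheme
    spacing_mm: tuple[float, float, float] = (1.2, 1.2, 1.2)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        m = np.asarray(self.mask)
        if f.ndim != 4 or m.ndim != 3 or f.shape[:3] != m.shape:
            raise ValueError("frames must be 4D and mask 3D on the same grid")
        if f.shape[3] != self.scheme.n_frames:
            raise ValueError("frame count does not match framing scheme")
        if np.any(f < 0):
            raise ValueError("activity must be non-negative")
        if not np.issubdtype(m.dtype, np.integer):
            raise ValueError("mask must be an integer array")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "mask", m)

    @property
    def labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.mask) if v != 0)


def default_brain_mask(shape: tuple[int, int, int] = (24, 24, 18)) -> np.ndarray:
    """Toy rat-brain label mask: two striatal boxes and a caudal cerebellum."""
    nx, ny, nz = shape
    if min(shape) < 12:
        raise ValueError("mask grid must be at least 12 voxels per axis")
    mask = np.zeros(shape, dtype=np.int16)
    zlo, zhi = nz // 3, 2 * nz // 3
    ylo, yhi = ny // 4, ny // 2
    mask[2 : nx // 2 - 2, ylo:yhi, zlo:zhi] = 1  # left striatum
    mask[nx // 2 + 2 : nx - 2, ylo:yhi, zlo:zhi] = 2  # right striatum
    mask[nx // 4 : 3 * nx // 4, 3 * ny // 4 : ny - 1, zlo:zhi] = 3  # cerebellum
    return mask


def generate_phantom(
    scheme: FramingScheme,
    tacs: dict[int, TimeActivityCurve],
    noise_cv: float = 0.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
    spacing_mm: tuple[float, float, float] = (1.2, 1.2, 1.2),
) -> Phantom4D:
    """Fill each labelled region with its TAC plus frame-length-scaled noise.

    Voxel noise is zero-mean Gaussian with SD = noise_cv * value / sqrt(w_f),
    where w_f = frame duration / mean frame duration — shorter frames collect
    fewer counts and are proportionally noisier, mimicking count statistics
    without projection-space simulation.  Negative draws are clipped to zero;
    background stays zero.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if mask is None:
        mask = default_brain_mask()
    labels = sorted(int(v) for v in np.unique(mask) if v != 0)
    missing = [lab for lab in labels if lab not in tacs]
    if missing:
        raise ValueError(f"no TAC supplied for mask labels {missing}")
    for lab, tac in tacs.items():
        if tac.scheme != scheme:
            raise ValueError(f"TAC for label {lab} does not match the framing scheme")
    rng = np.random.default_rng(seed)
    nt = scheme.n_frames
    frames = np.zeros(mask.shape + (nt,), dtype=float)
    w = scheme.durations_min / scheme.durations_min.mean()
    for lab in labels:
        sel = mask == lab
        nvox = int(sel.sum())
        vals = np.broadcast_to(tacs[lab].values, (nvox, nt)).copy()
        if noise_cv > 0:
            sd = noise_cv * vals / np.sqrt(w)
            vals = vals + rng.normal(0.0, 1.0, size=vals.shape) * sd
        frames[sel] = np.clip(vals, 0.0, None)
    return Phantom4D(frames=frames, mask=np.asarray(mask), scheme=scheme,
                     spacing_mm=spacing_mm)
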