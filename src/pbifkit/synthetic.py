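"""Synthetic dynamic FDG-PET data: schedules, tissue curves, populations, phantoms.

The generator emulates a cohort of oncological subjects scanned with a
65-min dynamic protocol on a long axial field-of-view scanner:

* arterial input functions with Feng's shape and log-normal inter-subject
  variability on amplitudes and eigenvalues, uniform arrival delays;
* an image-derived input function (IDIF) equal to the true AIF sampled on
  the frame schedule (optionally with noise) — the eroded-aorta IDIF is
  treated as ground truth, so no partial-volume model is applied;
* tumor and gray-matter tissue curves from the irreversible two-tissue
  compartment model (2TCM, k4=0), whose net influx is
  ``Ki = K1*k3/(k2+k3)``;
* optional small 4D phantoms for voxel-wise parametric analysis.

Noise is zero-mean Gaussian with variance proportional to value over frame
duration (the usual decay-corrected dynamic-PET heuristic), controlled by a
single scalar level; stored values are clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .input_function import (
    FengParams,
    POPULATION_PBIF_PARAMS,
    SampledCurve,
    feng_cumint,
    feng_eval,
)

__all__ = [
    "FrameSchedule",
    "KineticParams",
    "PopulationConfig",
    "SubjectDataset",
    "PhantomRegion",
    "default_schedule",
    "simulate_tissue_tac",
    "generate_population",
    "generate_phantom",
]

#: (count, duration seconds) blocks of the 62-frame, 65-min acquisition.
DEFAULT_FRAME_BLOCKS = ((2, 10), (30, 2), (4, 10), (8, 30), (4, 60), (5, 120), (9, 300))


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping reconstruction frames, in seconds."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.start_s, dtype=float)
        d = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", s)
        object.__setattr__(self, "duration_s", d)
        if s.shape != d.shape or s.ndim != 1 or s.size == 0:
            raise ValueError("start_s and duration_s must be equal-length 1-D arrays")
        if np.any(d <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(s[1:], s[:-1] + d[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def total_seconds(self) -> float:
        return float(self.start_s[-1] + self.duration_s[-1] - self.start_s[0])

    @property
    def start_min(self) -> np.ndarray:
        return self.start_s / 60.0

    @property
    def end_min(self) -> np.ndarray:
        return (self.start_s + self.duration_s) / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        return (self.start_s + 0.5 * self.duration_s) / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0

    def empty_curve(self, value, label: str = "") -> SampledCurve:
        return SampledCurve(self.start_min, self.end_min, np.asarray(value, float), label)


def default_schedule() -> FrameSchedule:
    """The 62-frame clinical schedule: 2×10, 30×2, 4×10, 8×30, 4×60, 5×120, 9×300 s."""
    durations = np.concatenate([np.full(n, float(d)) for n, d in DEFAULT_FRAME_BLOCKS])
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


@dataclass(frozen=True)
class KineticParams:
    """Irreversible 2TCM microparameters.

    K1 (ml·g⁻¹·min⁻¹) and k2, k3 (min⁻¹) govern exchange between plasma and
    the two tissue compartments; vB is the fractional blood volume.  The
    implied net influx rate is ``Ki = K1*k3/(k2+k3)``.
    """

    K1: float
    k2: float
    k3: float
    vB: float = 0.0

    def __post_init__(self):
        if self.K1 <= 0:
            raise ValueError(f"K1 must be positive, got {self.K1}")
        if self.k2 <= 0:
            raise ValueError(f"k2 must be positive, got {self.k2}")
        if self.k3 < 0:
            raise ValueError(f"k3 must be nonnegative, got {self.k3}")
        if not (0 <= self.vB < 1):
            raise ValueError(f"vB must lie in [0, 1), got {self.vB}")

    @property
    def ki(self) -> float:
        """Net influx rate K1*k3/(k2+k3), ml·g⁻¹·min⁻¹."""
        return self.K1 * self.k3 / (self.k2 + self.k3)

    def to_dict(self) -> dict:
        return {"K1": self.K1, "k2": self.k2, "k3": self.k3, "vB": self.vB}


def _conv_exp_with_exp(A: float, lam: float, beta: float, tp: np.ndarray) -> np.ndarray:
    """Closed form of (A e^{-lam t}) * e^{-beta t} (convolution) at shifted times."""
    if abs(beta - lam) < 1e-10:
        return A * tp * np.exp(-lam * tp)
    return A * (np.exp(-lam * tp) - np.exp(-beta * tp)) / (beta - lam)


def _conv_lin_with_exp(A: float, lam: float, beta: float, tp: np.ndarray) -> np.ndarray:
    """Closed form of (A t e^{-lam t}) * e^{-beta t} at shifted times."""
    mu = lam - beta
    if abs(mu) < 1e-8:
        return A * 0.5 * tp**2 * np.exp(-beta * tp)
    return A * (np.exp(-beta * tp) - (1.0 + mu * tp) * np.exp(-lam * tp)) / mu**2


def _feng_conv_exp(aif: FengParams, beta: float, t: np.ndarray) -> np.ndarray:
    """Convolution of the Feng curve with e^{-beta t}, delay-aware."""
    tp = np.maximum(np.asarray(t, float) - aif.tau, 0.0)
    out = _conv_lin_with_exp(aif.A1, aif.lam1, beta, tp)
    out += _conv_exp_with_exp(-(aif.A2 + aif.A3), aif.lam1, beta, tp)
    out += _conv_exp_with_exp(aif.A2, aif.lam2, beta, tp)
    out += _conv_exp_with_exp(aif.A3, aif.lam3, beta, tp)
    return out


def tissue_concentration(aif: FengParams, kp: KineticParams, t) -> np.ndarray:
    """Measured tissue concentration of the irreversible 2TCM at times ``t``.

    Uses the closed-form convolution of the Feng input with the impulse
    response ``K1*(k3/(k2+k3) + k2/(k2+k3) e^{-(k2+k3)t})`` and mixes in
    fractional blood volume: ``(1-vB)*Ct + vB*Cp``.
    """
    beta = kp.k2 + kp.k3
    if beta <= 0:
        raise ValueError("k2 + k3 must be positive")
    t = np.asarray(t, dtype=float)
    ct = kp.ki * feng_cumint(aif, t) + (kp.K1 * kp.k2 / beta) * _feng_conv_exp(aif, beta, t)
    return (1.0 - kp.vB) * ct + kp.vB * feng_eval(aif, t)


def simulate_tissue_tac(
    aif: FengParams, kp: KineticParams, schedule: FrameSchedule, label: str = "tissue"
) -> SampledCurve:
    """Noiseless tissue time-activity curve sampled at frame mid-times."""
    values = tissue_concentration(aif, kp, schedule.mid_min)
    return SampledCurve(schedule.start_min, schedule.end_min, values, label)


@dataclass(frozen=True)
class UniformPrior:
    """Per-parameter uniform prior box for kinetic microparameters."""

    K1: tuple[float, float]
    k2: tuple[float, float]
    k3: tuple[float, float]
    vB: tuple[float, float]

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "vB"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid prior bounds for {name}: ({lo}, {hi})")

    def draw(self, rng: np.random.Generator) -> KineticParams:
        return KineticParams(
            K1=float(rng.uniform(*self.K1)),
            k2=float(rng.uniform(*self.k2)),
            k3=float(rng.uniform(*self.k3)),
            vB=float(rng.uniform(*self.vB)),
        )


# FDG-literature prior boxes used by the default population.
TUMOR_PRIOR = UniformPrior(K1=(0.05, 0.3), k2=(0.1, 0.5), k3=(0.02, 0.15), vB=(0.02, 0.1))
GRAY_MATTER_PRIOR = UniformPrior(
    K1=(0.09, 0.11), k2=(0.135, 0.165), k3=(0.063, 0.077), vB=(0.036, 0.044)
)


@dataclass(frozen=True)
class PopulationConfig:
    """Study conditions for the synthetic cohort.

    ``feng_mean`` is the population mean input-function shape in normalized
    (unit-AUC) units; ``amplitude_scale`` converts it to kBq/ml so that the
    mean full-curve AUC is ~550 kBq·min/ml.  ``cv`` is the log-normal
    coefficient of variation applied multiplicatively to the amplitudes and
    eigenvalues; the arrival delay is uniform over ``delay_range``.
    ``noise_level`` scales a Gaussian noise model with
    sd = level*sqrt(value/frame-duration-min).
    """

    feng_mean: FengParams = POPULATION_PBIF_PARAMS
    amplitude_scale: float = 550.0
    cv: float = 0.1
    delay_range: tuple[float, float] = (0.4, 1.0)
    tumor_prior: UniformPrior = TUMOR_PRIOR
    gray_matter_prior: UniformPrior = GRAY_MATTER_PRIOR
    n_tumors: int = 4
    noise_level: float = 0.2
    idif_noise: bool = True

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.noise_level < 0:
            raise ValueError("noise_level must be nonnegative")
        lo, hi = self.delay_range
        if not 0 <= lo <= hi:
            raise ValueError(f"invalid delay range ({lo}, {hi})")
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")


@dataclass
class SubjectDataset:
    """One synthetic subject: true AIF, sampled IDIF and labeled ROI curves."""

    subject_id: str
    true_aif: FengParams
    idif: SampledCurve
    roi_tacs: dict[str, tuple[SampledCurve, KineticParams]]
    schedule: FrameSchedule
    seed: int

    @property
    def labels(self) -> list[str]:
        return list(self.roi_tacs)

    def tac(self, label: str) -> SampledCurve:
        return self.roi_tacs[label][0]

    def true_ki(self, label: str) -> float:
        return self.roi_tacs[label][1].ki


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean log-normal multiplicative factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _add_frame_noise(
    values: np.ndarray, duration_min: np.ndarray, level: float, rng: np.random.Generator
) -> np.ndarray:
    if level == 0:
        return values
    sd = level * np.sqrt(np.maximum(values, 0.0) / duration_min)
    return np.maximum(values + rng.normal(0.0, 1.0, values.shape) * sd, 0.0)


def draw_subject_aif(config: PopulationConfig, rng: np.random.Generator) -> FengParams:
    """Draw one subject's true AIF from the population model."""
    m = config.feng_mean
    f = _lognormal_factor(rng, config.cv, 6)
    tau = float(rng.uniform(*config.delay_range))
    return FengParams(
        tau=tau,
        A1=m.A1 * config.amplitude_scale * f[0],
        A2=m.A2 * config.amplitude_scale * f[1],
        A3=m.A3 * config.amplitude_scale * f[2],
        lam1=m.lam1 * f[3],
        lam2=m.lam2 * f[4],
        lam3=m.lam3 * f[5],
    )


def generate_population(
    n: int,
    config: PopulationConfig | None = None,
    seed: int = 0,
    schedule: FrameSchedule | None = None,
    id_prefix: str = "sub",
) -> list[SubjectDataset]:
    """Generate ``n`` synthetic subjects; subject ``i`` uses seed ``seed + i``.

    Deterministic given ``seed``.  With ``cv=0``, ``noise_level=0`` and a
    degenerate delay range every subject is identical to the population
    mean forward model (kinetic ROI parameters are still drawn from their
    priors per subject).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or PopulationConfig()
    schedule = schedule or default_schedule()
    dur_min = schedule.duration_min
    subjects = []
    for i in range(n):
        sub_seed = seed + i
        rng = np.random.default_rng(sub_seed)
        aif = draw_subject_aif(config, rng)
        idif_vals = feng_eval(aif, schedule.mid_min)
        if config.idif_noise:
            idif_vals = _add_frame_noise(idif_vals, dur_min, config.noise_level, rng)
        idif = SampledCurve(schedule.start_min, schedule.end_min, idif_vals, "IDIF")
        rois: dict[str, tuple[SampledCurve, KineticParams]] = {}
        for j in range(config.n_tumors):
            kp = config.tumor_prior.draw(rng)
            vals = tissue_concentration(aif, kp, schedule.mid_min)
            vals = _add_frame_noise(vals, dur_min, config.noise_level, rng)
            label = f"tumor_{j + 1}"
            rois[label] = (SampledCurve(schedule.start_min, schedule.end_min, vals, label), kp)
        kp = config.gray_matter_prior.draw(rng)
        vals = tissue_concentration(aif, kp, schedule.mid_min)
        vals = _add_frame_noise(vals, dur_min, config.noise_level, rng)
        rois["gray_matter"] = (
            SampledCurve(schedule.start_min, schedule.end_min, vals, "gray_matter"),
            kp,
        )
        subjects.append(
            SubjectDataset(
                subject_id=f"{id_prefix}{i:03d}",
                true_aif=aif,
                idif=idif,
                roi_tacs=rois,
                schedule=schedule,
                seed=sub_seed,
            )
        )
    return subjects


@dataclass(frozen=True)
class PhantomRegion:
    """A spherical region of a digital phantom: blood pool or 2TCM tissue."""

    label: int
    center: tuple[float, float, float]  # fractional coordinates in (0, 1)
    radius: float  # fraction of the smallest dimension
    kinetics: KineticParams | None = None  # None means blood pool

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError("region labels must be positive (0 is background)")
        if not all(0 < c < 1 for c in self.center):
            raise ValueError("region centers must be fractional coordinates in (0, 1)")
        if self.radius <= 0:
            raise ValueError("region radius must be positive")


DEFAULT_PHANTOM_LAYOUT = (
    PhantomRegion(label=1, center=(0.5, 0.5, 0.3), radius=0.12, kinetics=None),  # blood
    PhantomRegion(label=2, center=(0.3, 0.3, 0.6), radius=0.1,
                  kinetics=KineticParams(0.15, 0.3, 0.08, 0.05)),  # tumor
    PhantomRegion(label=3, center=(0.7, 0.6, 0.7), radius=0.1,
                  kinetics=KineticParams(0.1, 0.15, 0.07, 0.04)),  # gray matter
)

#: faint uptake assigned to background voxels
BACKGROUND_KINETICS = KineticParams(K1=0.01, k2=0.2, k3=0.002, vB=0.01)


def generate_phantom(
    subject: SubjectDataset,
    dims: tuple[int, int, int] = (32, 32, 32),
    layout: tuple[PhantomRegion, ...] = DEFAULT_PHANTOM_LAYOUT,
    seed: int = 0,
    noise_level: float = 0.0,
):
    """Build a 4D digital phantom (x, y, z, frame) plus integer label map.

    Every voxel of a region carries that region's forward-model TAC; blood
    regions carry the subject's AIF sampled on the schedule; background
    (label 0) has near-zero uptake.  Optional iid Gaussian frame noise uses
    the same variance model as the TAC generator.

    Returns
    -------
    (volume, labels, region_truth) where ``region_truth`` maps each region
    label to ``{"ki", "vB"}`` ground truth (Ki is NaN for the blood pool).
    The expected Patlak slope of a region's voxels is ``(1 - vB) * ki``
    because the measured signal mixes in fractional blood volume.
    """
    dims = tuple(int(d) for d in dims)
    if min(dims) < 8:
        raise ValueError(f"dims too small to place regions, got {dims}")
    schedule = subject.schedule
    mids = schedule.mid_min
    n_t = schedule.n_frames

    labels = np.zeros(dims, dtype=np.int16)
    grids = np.meshgrid(*(np.arange(d) + 0.5 for d in dims), indexing="ij")
    scale = min(dims)
    for region in layout:
        cx = [c * d for c, d in zip(region.center, dims)]
        r_vox = region.radius * scale
        if r_vox < 1.0:
            raise ValueError(f"dims {dims} too small: region {region.label} is sub-voxel")
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, cx))
        inside = dist2 <= r_vox**2
        if labels[inside].any():
            raise ValueError(f"region {region.label} overlaps an earlier region")
        labels[inside] = region.label

    region_tacs = {0: tissue_concentration(subject.true_aif, BACKGROUND_KINETICS, mids)}
    region_truth = {0: {"ki": BACKGROUND_KINETICS.ki, "vB": BACKGROUND_KINETICS.vB}}
    for region in layout:
        if region.kinetics is None:
            region_tacs[region.label] = feng_eval(subject.true_aif, mids)
            region_truth[region.label] = {"ki": float("nan"), "vB": 1.0}
        else:
            region_tacs[region.label] = tissue_concentration(
                subject.true_aif, region.kinetics, mids
            )
            region_truth[region.label] = {
                "ki": region.kinetics.ki,
                "vB": region.kinetics.vB,
            }

    volume = np.empty(dims + (n_t,), dtype=float)
    for lab, tac in region_tacs.items():
        volume[labels == lab] = tac
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        sd = noise_level * np.sqrt(np.maximum(volume, 0.0) / schedule.duration_min)
        volume = np.maximum(volume + rng.normal(0.0, 1.0, volume.shape) * sd, 0.0)
    return volume, labels, region_truth
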