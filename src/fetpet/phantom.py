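"""Synthetic dynamic-PET phantoms and synthetic biomarker cohorts.

The phantom is a desk-scale stand-in for a 40-min dynamic FET acquisition:
a spherical "brain" of uniform background uptake containing one ellipsoidal
lesion whose time-activity curve follows a two-rate kinetic model that spans
the three curve shapes seen clinically (descending, plateau, ascending).
Frames are noisier when shorter, mimicking count statistics across the mixed
5-s-to-5-min frame schedule.

The cohort generators produce patient-level biomarker tables (TBRmax,
TBRmean, TTP, TAC score, IDH status, outcome) for exercising the statistics
layer, plus a deterministic 44-patient reference table whose marginal counts
match a typical recurrent-glioma FET referral series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .images import DynamicSeries, FrameSchedule, VoiMask

__all__ = [
    "LesionKinetics",
    "PhantomTruth",
    "CLASS_KINETICS",
    "make_frame_schedule",
    "lesion_tac_model",
    "simulate_dynamic_series",
    "simulate_noisy_tac",
    "GroupSpec",
    "DEFAULT_GROUP_PARAMS",
    "generate_cohort",
    "reference_cohort",
]

#: sd of a frame of this duration equals ``noise_sd``; shorter frames are noisier
REF_FRAME_DURATION_S = 5.0


def make_frame_schedule() -> FrameSchedule:
    """Return the default 35-frame, 2400-s dynamic schedule."""
    return FrameSchedule.default()


@dataclass(frozen=True)
class LesionKinetics:
    """Two-rate lesion kinetics: saturating wash-in times exponential washout.

    ``SUV(t) = scale * (1 - exp(-wash_in_rate*t)) * exp(-wash_out_rate*t)``
    with ``scale`` chosen so the maximum over the 40-min acquisition equals
    ``amplitude``.  ``wash_out_rate = 0`` gives a monotone ascending curve;
    a small washout gives a plateau; a large washout an early peak with a
    clear descent.

    Attributes
    ----------
    amplitude : float
        Peak SUV over the acquisition (> 0).
    wash_in_rate : float
        1/min (> 0).
    wash_out_rate : float
        1/min (>= 0).
    intended_class : str
        One of ``descending``, ``plateau``, ``ascending`` (bookkeeping for
        recovery tests; not used by the model itself).
    """

    amplitude: float
    wash_in_rate: float
    wash_out_rate: float
    intended_class: str = "descending"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.wash_in_rate <= 0:
            raise ValueError("wash_in_rate must be > 0")
        if self.wash_out_rate < 0:
            raise ValueError("wash_out_rate must be >= 0")

    def peak_time_min(self, acquisition_end: float = 40.0) -> float:
        """Analytic peak time of the unclipped model, capped at the acquisition end.

        For ``wash_out_rate > 0`` the derivative vanishes at
        ``t* = ln(1 + wash_in/wash_out) / wash_in``; a washout-free curve
        peaks at the end of the acquisition.
        """
        if self.wash_out_rate == 0:
            return float(acquisition_end)
        t_star = math.log1p(self.wash_in_rate / self.wash_out_rate) / self.wash_in_rate
        return float(min(t_star, acquisition_end))


#: default kinetics for the three curve-shape classes (SUV amplitude 3.0)
CLASS_KINETICS: dict[str, LesionKinetics] = {
    "descending": LesionKinetics(3.0, 0.5, 0.01, "descending"),
    "plateau": LesionKinetics(3.0, 0.5, 0.0012, "plateau"),
    "ascending": LesionKinetics(3.0, 0.06, 0.0, "ascending"),
}


def lesion_tac_model(
    kinetics: LesionKinetics, times_min: np.ndarray, acquisition_end: float = 40.0
) -> np.ndarray:
    """Noise-free lesion SUV at the given times (minutes).

    The curve is rescaled so its maximum over ``[0, acquisition_end]`` equals
    ``kinetics.amplitude``; SUV(0) = 0.
    """
    t = np.asarray(times_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.ndim == 1 and t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    def shape(u):
        return (1.0 - np.exp(-kinetics.wash_in_rate * u)) * np.exp(-kinetics.wash_out_rate * u)

    peak_val = shape(kinetics.peak_time_min(acquisition_end))
    return kinetics.amplitude * shape(t) / peak_val


@dataclass
class PhantomTruth:
    """Ground truth attached to a simulated series, for recovery tests."""

    lesion_mask: VoiMask
    brain_mask: VoiMask
    background_suv: float
    lesion_tac_true: np.ndarray  # noise-free SUV per frame
    kinetics: LesionKinetics

    def __post_init__(self) -> None:
        self.lesion_tac_true = np.asarray(self.lesion_tac_true, dtype=float)
        if np.any(self.lesion_tac_true < 0):
            raise ValueError("lesion_tac_true must be >= 0")


def _ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    center_vox: np.ndarray,
    radii_mm: np.ndarray,
    voxel_size: np.ndarray,
) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    d = [
        ((idx[a] - center_vox[a]) * voxel_size[a] / radii_mm[a]) ** 2
        for a in range(3)
    ]
    return d[0] + d[1] + d[2] <= 1.0


def simulate_dynamic_series(
    kinetics: LesionKinetics,
    background_suv: float = 1.0,
    noise_sd: float = 0.0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    *,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    schedule: FrameSchedule | None = None,
    lesion_radii_mm: tuple[float, float, float] = (10.0, 10.0, 10.0),
    lesion_offset_frac: float = 0.25,
    brain_radius_frac: float = 0.45,
    ref_duration_s: float = REF_FRAME_DURATION_S,
) -> tuple[DynamicSeries, PhantomTruth]:
    """Simulate one dynamic series with a single lesion in a uniform brain.

    The brain is a sphere of radius ``brain_radius_frac`` times the smallest
    grid extent, centred on the grid; outside it the image is zero.  The
    lesion is an axis-aligned ellipsoid displaced from the brain centre along
    +x by ``lesion_offset_frac`` of the x extent (i.e. into the "right"
    hemisphere).  Background voxels hold ``background_suv`` in every frame;
    lesion voxels follow :func:`lesion_tac_model` sampled at frame mid-times.
    Zero-mean Gaussian noise with per-frame sd
    ``noise_sd * sqrt(ref_duration_s / frame_duration)`` is added inside the
    brain and the result is clipped at 0.  Fully reproducible given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if background_suv <= 0:
        raise ValueError("background_suv must be > 0")
    schedule = schedule or FrameSchedule.default()
    vs = np.asarray(voxel_size, float)
    radii = np.asarray(lesion_radii_mm, float)
    extent_mm = np.asarray(grid_shape, float) * vs
    brain_radius_mm = brain_radius_frac * extent_mm.min()
    center_vox = (np.asarray(grid_shape, float) - 1) / 2.0
    lesion_center = center_vox.copy()
    lesion_center[0] += lesion_offset_frac * grid_shape[0]
    if np.linalg.norm((lesion_center - center_vox) * vs) + radii.max() > brain_radius_mm:
        raise ValueError("lesion does not fit inside the brain volume on this grid")

    idx = np.indices(grid_shape, dtype=float)
    r2 = sum(((idx[a] - center_vox[a]) * vs[a]) ** 2 for a in range(3))
    brain = r2 <= brain_radius_mm**2
    lesion = _ellipsoid_mask(grid_shape, lesion_center, radii, vs)
    lesion &= brain

    tac_true = lesion_tac_model(kinetics, schedule.mid_times_min)
    n_frames = schedule.n_frames
    voxels = np.zeros((n_frames,) + tuple(grid_shape), dtype=float)
    voxels[:, brain] = background_suv
    voxels[:, lesion] = tac_true[:, None]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame_sd = noise_sd * np.sqrt(ref_duration_s / schedule.frame_duration)
        for f in range(n_frames):
            voxels[f][brain] += rng.normal(0.0, frame_sd[f], size=int(brain.sum()))
        np.clip(voxels, 0.0, None, out=voxels)

    series = DynamicSeries(voxels, schedule, tuple(vs))
    truth = PhantomTruth(
        lesion_mask=VoiMask(lesion, kind="lesion_truth"),
        brain_mask=VoiMask(brain, kind="brain"),
        background_suv=float(background_suv),
        lesion_tac_true=tac_true,
        kinetics=kinetics,
    )
    return series, truth


def simulate_noisy_tac(
    kinetics: LesionKinetics,
    noise_sd: float,
    seed: int,
    schedule: FrameSchedule | None = None,
    ref_duration_s: float = REF_FRAME_DURATION_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one noisy lesion TAC (times_min, suv) without building a volume.

    Uses the same frame-duration-scaled noise model as
    :func:`simulate_dynamic_series`; values are clipped at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    schedule = schedule or FrameSchedule.default()
    t = schedule.mid_times_min
    suv = lesion_tac_model(kinetics, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame_sd = noise_sd * np.sqrt(ref_duration_s / schedule.frame_duration)
        suv = np.clip(suv + rng.normal(0.0, frame_sd), 0.0, None)
    return t, suv


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution of one (IDH, outcome) patient group.

    Continuous biomarkers are truncated normals ``(mean, sd, low, high)``;
    the TAC score is categorical over {-1, 0, 1}; ``p_empty_contour`` is the
    probability that the auto-contour is empty (TBRmean recorded as 0).
    """

    tbr_max: tuple[float, float, float, float]
    tbr_mean: tuple[float, float, float, float]
    ttp: tuple[float, float, float, float]
    score_probs: tuple[float, float, float]  # P(score = -1), P(0), P(1)
    p_empty_contour: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tbr_max", "tbr_mean", "ttp"):
            mean, sd, lo, hi = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name}: sd must be > 0")
            if hi <= lo:
                raise ValueError(f"{name}: empty truncation support")
        p = np.asarray(self.score_probs, float)
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("score_probs must be non-negative and sum to 1")
        if not 0 <= self.p_empty_contour < 1:
            raise ValueError("p_empty_contour must be in [0, 1)")


#: group location parameters anchored to the reference clinical summaries
DEFAULT_GROUP_PARAMS: dict[tuple[str, str], GroupSpec] = {
    ("mutant", "TP"): GroupSpec(
        tbr_max=(4.2, 1.0, 1.0, 9.0),
        tbr_mean=(2.2, 0.45, 1.6, 4.0),
        ttp=(30.0, 9.0, 1.0, 40.0),
        score_probs=(0.50, 0.30, 0.20),
        p_empty_contour=0.03,
    ),
    ("mutant", "TRC"): GroupSpec(
        tbr_max=(2.6, 0.7, 1.0, 9.0),
        tbr_mean=(1.8, 0.30, 1.6, 4.0),
        ttp=(30.0, 9.0, 1.0, 40.0),
        score_probs=(0.15, 0.25, 0.60),
        p_empty_contour=0.15,
    ),
    ("wildtype", "TP"): GroupSpec(
        tbr_max=(4.0, 1.0, 1.0, 9.0),
        tbr_mean=(2.1, 0.45, 1.6, 4.0),
        ttp=(22.0, 9.0, 1.0, 40.0),
        score_probs=(0.50, 0.30, 0.20),
        p_empty_contour=0.03,
    ),
    ("wildtype", "TRC"): GroupSpec(
        tbr_max=(2.7, 0.7, 1.0, 9.0),
        tbr_mean=(1.8, 0.30, 1.6, 4.0),
        ttp=(36.0, 5.0, 1.0, 40.0),
        score_probs=(0.15, 0.25, 0.60),
        p_empty_contour=0.15,
    ),
}

COHORT_COLUMNS = [
    "patient_id",
    "idh",
    "outcome",
    "sex",
    "tbr_max",
    "tbr_mean",
    "ttp_min",
    "tac_score",
]


def _truncnorm_rvs(spec: tuple[float, float, float, float], size: int, rng) -> np.ndarray:
    mean, sd, lo, hi = spec
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    group_params: dict[tuple[str, str], GroupSpec] | None = None,
    n_per_group: dict[tuple[str, str], int] | int = 50,
    seed: int = 0,
    male_fraction: float = 0.6,
) -> pd.DataFrame:
    """Sample a synthetic biomarker cohort table.

    Parameters
    ----------
    group_params : mapping (idh, outcome) -> GroupSpec, optional
        Defaults to :data:`DEFAULT_GROUP_PARAMS`.
    n_per_group : int or mapping
        Patients per group; a group mapped to 0 is absent from the output.
    seed : int
        Seeds all sampling; identical seeds give identical tables.

    Returns
    -------
    DataFrame with the cohort CSV schema
    ``patient_id,idh,outcome,sex,tbr_max,tbr_mean,ttp_min,tac_score``.
    """
    group_params = DEFAULT_GROUP_PARAMS if group_params is None else group_params
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in group_params}
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for (idh, outcome), spec in group_params.items():
        n = int(n_per_group.get((idh, outcome), 0))
        if n < 0:
            raise ValueError("n_per_group must be >= 0")
        if n == 0:
            continue
        tbr_max = _truncnorm_rvs(spec.tbr_max, n, rng)
        tbr_mean = _truncnorm_rvs(spec.tbr_mean, n, rng)
        empty = rng.random(n) < spec.p_empty_contour
        tbr_mean[empty] = 0.0
        ttp = _truncnorm_rvs(spec.ttp, n, rng)
        score = rng.choice([-1, 0, 1], size=n, p=spec.score_probs)
        sex = np.where(rng.random(n) < male_fraction, "male", "female")
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"S{offset + i + 1:04d}" for i in range(n)],
                    "idh": idh,
                    "outcome": outcome,
                    "sex": sex,
                    "tbr_max": tbr_max,
                    "tbr_mean": tbr_mean,
                    "ttp_min": ttp,
                    "tac_score": score,
                }
            )
        )
        offset += n
    if not frames:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


# deterministic placeholder biomarkers per (idh, outcome): values sit inside
# the observed group ranges and respect the score/TTP coherence rules
_FIXTURE_PLACEHOLDERS = {
    ("mutant", "TP"): dict(tbr_max=4.25, tbr_mean=2.45, ttp_min=20.0, tac_score=-1),
    ("mutant", "TRC"): dict(tbr_max=3.0, tbr_mean=1.9, ttp_min=40.0, tac_score=1),
    ("wildtype", "TP"): dict(tbr_max=4.55, tbr_mean=2.35, ttp_min=20.0, tac_score=-1),
    ("wildtype", "TRC"): dict(tbr_max=2.9, tbr_mean=1.8, ttp_min=40.0, tac_score=1),
}

# (idh, outcome, n, n_male): 44 patients, 26 IDHm (7 TRC), 18 IDHwt (5 TRC),
# 27 male / 17 female
_FIXTURE_GROUPS = [
    ("mutant", "TP", 19, 12),
    ("mutant", "TRC", 7, 4),
    ("wildtype", "TP", 13, 8),
    ("wildtype", "TRC", 5, 3),
]


def reference_cohort() -> pd.DataFrame:
    """Deterministic 44-patient reference table with realistic marginal counts.

    The composition mirrors a recurrent-glioma FET-PET referral series:
    26 IDH-mutant patients (7 with treatment-related changes, 19 with true
    progression), 18 IDH-wildtype (5 TRC, 13 TP), 27 male / 17 female.
    Biomarker columns hold deterministic placeholder values inside the
    plausible group ranges and are flagged ``measured = False``: the table
    supports count/proportion analyses, not biomarker inference.
    """
    rows = []
    pid = 0
    for idh, outcome, n, n_male in _FIXTURE_GROUPS:
        ph = _FIXTURE_PLACEHOLDERS[(idh, outcome)]
        for i in range(n):
            pid += 1
            rows.append(
                {
                    "patient_id": f"R{pid:04d}",
                    "idh": idh,
                    "outcome": outcome,
                    "sex": "male" if i < n_male else "female",
                    "measured": False,
                    **ph,
                }
            )
    return pd.DataFrame(rows)[COHORT_COLUMNS + ["measured"]]
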