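"""Synthetic cohort generator for surface-vs-bone spinal profile studies.

Emulates the measurement structure of a lateral-lying MRI + 3D surface-scan
protocol on healthy adults: a T1-L5 spinous-process chain with thoracic
kyphosis, lumbar lordosis and a mild coronal deviation; skin fiducial markers
displaced posteriorly from the spinous processes by a BMI-dependent adipose
offset with a left-lateral bias; and surface-scan markers equal to the
fiducials plus a smooth postural-misalignment field and repositioning noise.
Designated subjects carry duplicate observer-selection sessions for
reliability analysis.

Coordinate convention (fixed project-wide, millimetres):
+z cephalad, +y posterior, +x subject-left.

All randomness flows from one master seed through per-subject, per-stage
seed sequences, so adding a subject never perturbs earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from .stats import bmi_and_class, classify_bmi

# ---------------------------------------------------------------------------
# Labels and sources
# ---------------------------------------------------------------------------

THORACIC_LABELS = tuple(f"T{i}" for i in range(1, 13))
LUMBAR_LABELS = tuple(f"L{i}" for i in range(1, 6))
VERTEBRAL_LABELS = THORACIC_LABELS + LUMBAR_LABELS  # cephalad -> caudad
AUXILIARY_LABELS = ("C7", "PSIS_L", "PSIS_R")
VALID_LABELS = frozenset(VERTEBRAL_LABELS) | frozenset(AUXILIARY_LABELS)

SOURCE_MRI_SPINOUS = "MRI_SPINOUS"
SOURCE_MRI_FIDUCIAL = "MRI_FIDUCIAL"
SOURCE_SCAN_MARKER = "SCAN_MARKER"
VALID_SOURCES = (SOURCE_MRI_SPINOUS, SOURCE_MRI_FIDUCIAL, SOURCE_SCAN_MARKER)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectDemographics:
    """One subject's demographics; BMI and its class are derived."""

    subject_id: str
    gender: str  # 'F' or 'M'
    age: int  # years
    height_m: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.gender not in ("F", "M"):
            raise ValueError(f"gender must be 'F' or 'M', got {self.gender!r}")
        if self.height_m <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")

    @property
    def bmi(self) -> float:
        return self.weight_kg / self.height_m**2

    @property
    def bmi_class(self) -> str:
        return classify_bmi(self.bmi)


@dataclass
class LandmarkSet:
    """Labeled 3D points for one subject, source and selection session.

    ``labels`` and ``coords`` (n, 3) are index-aligned and ordered cephalad to
    caudad over the vertebral chain, auxiliary labels last.
    """

    subject_id: str
    source: str
    labels: list[str]
    coords: np.ndarray  # (n, 3) mm: x subject-left, y posterior, z cephalad
    session: int = 1
    frame: str = "mri"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.labels)} labels"
            )
        self.validate()

    def validate(self) -> None:
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        unknown = [lb for lb in self.labels if lb not in VALID_LABELS]
        if unknown:
            raise ValueError(f"unknown labels {unknown}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels within a landmark set")
        # monotonicity is a property of the anatomical convention; a set still
        # expressed in its scanner's own frame may be arbitrarily oriented
        vz = self.vertebral_z()
        if self.frame == "mri" and vz.size >= 2 and not np.all(np.diff(vz) < 0):
            raise ValueError(
                "vertebral z coordinates must decrease strictly from T1 to L5"
            )

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"label {label!r} missing from {self.source} set of "
                f"subject {self.subject_id}"
            ) from None

    def point(self, label: str) -> np.ndarray:
        return self.coords[self.index_of(label)]

    def has_label(self, label: str) -> bool:
        return label in self.labels

    def vertebral_labels(self) -> list[str]:
        return [lb for lb in self.labels if lb in VERTEBRAL_LABELS]

    def vertebral_coords(self) -> np.ndarray:
        idx = [i for i, lb in enumerate(self.labels) if lb in VERTEBRAL_LABELS]
        return self.coords[idx]

    def vertebral_z(self) -> np.ndarray:
        return self.vertebral_coords()[:, 2]

    def copy(self) -> "LandmarkSet":
        return replace(self, labels=list(self.labels), coords=self.coords.copy())


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

def default_spacing() -> dict[str, float]:
    """Inter-spinous gap (mm) above each level: thoracic 27, lumbar 33
    (T1-L5 chain length 462 mm). Keys are the caudal level of each gap."""
    spacing = {lb: 27.0 for lb in VERTEBRAL_LABELS[1:12]}  # T2..T12
    spacing.update({lb: 33.0 for lb in LUMBAR_LABELS})  # L1..L5
    return spacing


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a 50-subject healthy-adult cohort lying laterally:
    BMI ~ truncated normal (22.82, 3.22) on [16, 31]; posterior skin-marker
    offsets growing ~0.9 mm per BMI unit over a 1.5 mm intercept; a 5.17 mm
    mean left-lateral marker bias (SD 2.83 mm); a smooth quadratic postural
    misalignment between scan and MRI (8 mm lateral, 2 mm antero-posterior);
    and 0.5 mm isotropic observer re-selection noise.
    """

    n_subjects: int = 50
    seed: int = 0

    # skeleton geometry
    vertebral_spacing_mm: Mapping[str, float] = field(default_factory=default_spacing)
    kyphosis_amplitude_mm: float = 28.0
    lordosis_amplitude_mm: float = 20.0
    inflection_level: str = "T12"
    coronal_amplitude_mm: float = 6.0

    # adipose / skin marker offsets
    adipose_intercept_mm: float = 1.5
    adipose_slope_mm_per_bmi: float = 0.9
    adipose_noise_sd_mm: float = 1.5
    lateral_bias_mean_mm: float = 5.17
    lateral_bias_sd_mm: float = 2.83
    #: Gaussian-kernel correlation length (mm) of the per-level offset noise
    #: along the spine; adipose thickness varies smoothly, so neighbouring
    #: levels share most of their offset deviation. 0 gives independent draws.
    offset_correlation_length_mm: float = 250.0

    # scan-vs-MRI posture misalignment
    posture_amplitude_lateral_mm: float = 8.0
    posture_amplitude_ap_mm: float = 2.0
    reposition_noise_sd_mm: float = 1.0

    # observer re-selection
    observer_noise_sd_mm: float = 0.5
    reliability_subjects: tuple[int, ...] = (4, 42)  # 0-based indices

    # demographics
    female_fraction: float = 0.5
    age_mean: float = 23.48
    age_sd: float = 2.79
    age_range: tuple[int, int] = (18, 35)
    bmi_mean: float = 22.82
    bmi_sd: float = 3.22
    bmi_bounds: tuple[float, float] = (16.0, 31.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for lb, gap in self.vertebral_spacing_mm.items():
            if gap <= 0:
                raise ValueError(f"spacing above {lb} must be positive, got {gap}")
        missing = [lb for lb in VERTEBRAL_LABELS[1:] if lb not in self.vertebral_spacing_mm]
        if missing:
            raise ValueError(f"spacing table missing levels {missing}")
        for name in (
            "adipose_noise_sd_mm",
            "lateral_bias_sd_mm",
            "reposition_noise_sd_mm",
            "observer_noise_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.inflection_level not in VERTEBRAL_LABELS:
            raise ValueError(f"unknown inflection level {self.inflection_level!r}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")

    # -- config file round-trip -------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("reliability_subjects", "age_range", "bmi_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _stage_rng(config_seed: int, subject_index: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config_seed, subject_index, stage])
    )


def subject_stage_seed(config_seed: int, subject_index: int, stage: int) -> int:
    """Deterministic per-subject, per-stage integer seed below 2^31."""
    ss = np.random.SeedSequence([config_seed, subject_index, stage])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Skeleton shape
# ---------------------------------------------------------------------------

def vertebral_z_positions(config: GeneratorConfig) -> np.ndarray:
    """Cephalo-caudal coordinate of each level, T1 first, L5 = 0 mm."""
    gaps = np.array(
        [config.vertebral_spacing_mm[lb] for lb in VERTEBRAL_LABELS[1:]], dtype=float
    )
    z = np.concatenate([[0.0], np.cumsum(gaps[::-1])])[::-1]  # T1 highest
    return z


def double_arc_shape(
    z: np.ndarray, thoracic_amp_mm: float, lumbar_amp_mm: float, inflection_level: str
) -> np.polynomial.Polynomial:
    """Quintic double-arc spinal shape with the configured apex amplitudes.

    Determined by six Hermite conditions: value +thoracic_amp and zero slope
    at the thoracic apex (T7 station), value -lumbar_amp and zero slope at
    the lumbar apex (L3 station), zero at the inflection level and at T1.
    Used for the sagittal kyphosis/lordosis curve (posterior +y, so the
    kyphotic bow is positive and the lordotic bow negative) and, at small
    amplitude, for the mild coronal S-deviation.
    """
    idx = {lb: i for i, lb in enumerate(VERTEBRAL_LABELS)}
    z_apex_t = z[idx["T7"]]
    z_apex_l = z[idx["L3"]]
    z_inf = z[idx[inflection_level]]
    z_t1 = z[idx["T1"]]
    # scale to [-1, 1] for conditioning
    lo, hi = z.min(), z.max()
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0

    def u(zz: float) -> float:
        return (zz - mid) / half

    deg = 5
    rows, rhs = [], []
    for zz, val in ((z_apex_t, thoracic_amp_mm), (z_apex_l, -lumbar_amp_mm),
                    (z_inf, 0.0), (z_t1, 0.0)):
        rows.append([u(zz) ** k for k in range(deg + 1)])
        rhs.append(val)
    for zz in (z_apex_t, z_apex_l):  # zero slope at both apices
        rows.append([k * u(zz) ** (k - 1) if k else 0.0 for k in range(deg + 1)])
        rhs.append(0.0)
    coef = np.linalg.solve(np.array(rows), np.array(rhs))
    return np.polynomial.Polynomial(coef, domain=[lo, hi], window=[-1, 1])


#: Lumbar-to-thoracic amplitude ratio of the coronal S-deviation.
CORONAL_LUMBAR_RATIO = 0.6


def coronal_shape(z: np.ndarray, amplitude_mm: float, sign: float = 1.0) -> np.ndarray:
    """Mild coronal S-deviation: a double arc with the configured amplitude
    at the thoracic apex and a 0.6-fraction counter-bow at the lumbar apex,
    its side chosen by ``sign``. Varying curvature along the chain mimics a
    postural lateral-flexion curve rather than a constant-curvature bow."""
    if amplitude_mm == 0:
        return np.zeros_like(z)
    poly = double_arc_shape(z, amplitude_mm, CORONAL_LUMBAR_RATIO * amplitude_mm, "T12")
    return sign * poly(z)


def posture_basis(z: np.ndarray) -> np.ndarray:
    """Quadratic misalignment basis orthogonal to rigid trends.

    t^2 orthogonalised against {1, t} over the stations and normalised to
    unit maximum absolute value, so a rigid (translation + small rotation)
    alignment absorbs essentially none of the applied field.
    """
    lo, hi = z.min(), z.max()
    t = (z - lo) / (hi - lo)
    basis = np.column_stack([np.ones_like(t), t])
    q = t**2
    q = q - basis @ np.linalg.lstsq(basis, q, rcond=None)[0]
    return q / np.max(np.abs(q))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def generate_spine_centerline(
    subject: SubjectDemographics, config: GeneratorConfig, rng_seed: int
) -> LandmarkSet:
    """Spinous-process chain T1-L5 (17 labeled points) for one subject.

    The skeletal curve is deterministic given the config (the rng only picks
    the coronal deviation side), so subjects differ through their soft-tissue
    offsets rather than their bony shape.
    """
    config.validate()
    rng = np.random.default_rng(rng_seed)
    z = vertebral_z_positions(config)
    sag = double_arc_shape(
        z, config.kyphosis_amplitude_mm, config.lordosis_amplitude_mm,
        config.inflection_level,
    )
    y = sag(z)
    side = 1.0 if rng.random() < 0.5 else -1.0
    x = coronal_shape(z, config.coronal_amplitude_mm, sign=side)
    coords = np.column_stack([x, y, z])
    return LandmarkSet(
        subject_id=subject.subject_id,
        source=SOURCE_MRI_SPINOUS,
        labels=list(VERTEBRAL_LABELS),
        coords=coords,
    )


#: Fiducial posterior offsets are truncated at this floor so skin markers are
#: strictly posterior to the spinous processes.
MIN_POSTERIOR_OFFSET_MM = 0.1


def correlated_level_noise(
    rng: np.random.Generator, z: np.ndarray, sd: float, length_mm: float
) -> np.ndarray:
    """Zero-mean Gaussian noise at each level with marginal SD ``sd`` and
    squared-exponential correlation along z (length 0 = independent draws).

    The marginal distribution at every level is exactly N(0, sd^2) whatever
    the correlation length, so pooled-offset statistics are unaffected by it.
    """
    if sd == 0:
        return np.zeros_like(z)
    if length_mm <= 0:
        return rng.normal(0.0, sd, size=z.size)
    dz = z[:, None] - z[None, :]
    cov = sd**2 * np.exp(-0.5 * (dz / length_mm) ** 2)
    cov[np.diag_indices_from(cov)] += (1e-6 * sd) ** 2
    return np.linalg.cholesky(cov) @ rng.standard_normal(z.size)


def generate_fiducials(
    spine: LandmarkSet,
    subject: SubjectDemographics,
    config: GeneratorConfig,
    rng_seed: int,
) -> LandmarkSet:
    """Skin fiducial markers over each spinous process.

    Per level: posterior offset = intercept + slope * BMI + noise, truncated
    strictly positive; lateral offset = bias mean + noise with +x =
    subject-left. The per-level noise has the configured marginal SD but is
    spatially correlated along the spine (adipose thickness varies smoothly).
    Adds PSIS_L / PSIS_R pelvic markers used downstream to orient the
    anatomical frame.
    """
    missing = [lb for lb in VERTEBRAL_LABELS if not spine.has_label(lb)]
    if missing:
        raise ValueError(f"spine set missing vertebral labels {missing}")
    rng = np.random.default_rng(rng_seed)
    n = len(VERTEBRAL_LABELS)
    vz = np.array([spine.point(lb)[2] for lb in VERTEBRAL_LABELS])
    ell = config.offset_correlation_length_mm
    posterior = (
        config.adipose_intercept_mm
        + config.adipose_slope_mm_per_bmi * subject.bmi
        + correlated_level_noise(rng, vz, config.adipose_noise_sd_mm, ell)
    )
    posterior = np.maximum(posterior, MIN_POSTERIOR_OFFSET_MM)
    lateral = config.lateral_bias_mean_mm + correlated_level_noise(
        rng, vz, config.lateral_bias_sd_mm, ell
    )

    base = np.vstack([spine.point(lb) for lb in VERTEBRAL_LABELS])
    coords = base + np.column_stack([lateral, posterior, np.zeros(n)])

    # pelvic skin markers caudal to L5, at the same adipose depth
    skin_depth = config.adipose_intercept_mm + config.adipose_slope_mm_per_bmi * subject.bmi
    l5 = spine.point("L5")
    psis_l = l5 + np.array([40.0, skin_depth, -60.0])
    psis_r = l5 + np.array([-40.0, skin_depth, -60.0])

    return LandmarkSet(
        subject_id=spine.subject_id,
        source=SOURCE_MRI_FIDUCIAL,
        labels=list(VERTEBRAL_LABELS) + ["PSIS_L", "PSIS_R"],
        coords=np.vstack([coords, psis_l, psis_r]),
    )


def generate_scan_markers(
    fiducials: LandmarkSet, config: GeneratorConfig, rng_seed: int
) -> LandmarkSet:
    """Surface-scan markers: fiducials plus a smooth postural-misalignment
    field and isotropic repositioning noise.

    The field is a quadratic in z (orthogonal to rigid trends, unit-max
    basis) applied to the lateral and antero-posterior axes with per-subject
    random signs and the configured amplitudes; amplitude 0 and noise 0
    reproduce the fiducials exactly.
    """
    missing = [lb for lb in VERTEBRAL_LABELS if not fiducials.has_label(lb)]
    if missing:
        raise ValueError(f"fiducial set missing vertebral labels {missing}")
    rng = np.random.default_rng(rng_seed)
    coords = fiducials.coords.copy()
    vz = fiducials.vertebral_z()
    basis = posture_basis(vz)
    # evaluate the same quadratic at every label (incl. auxiliary) via refit
    qfit = np.polynomial.Polynomial.fit(vz, basis, deg=2)
    h = qfit(coords[:, 2])
    sign_x = 1.0 if rng.random() < 0.5 else -1.0
    sign_y = 1.0 if rng.random() < 0.5 else -1.0
    coords[:, 0] += sign_x * config.posture_amplitude_lateral_mm * h
    coords[:, 1] += sign_y * config.posture_amplitude_ap_mm * h
    coords += rng.normal(0.0, config.reposition_noise_sd_mm, size=coords.shape)
    return LandmarkSet(
        subject_id=fiducials.subject_id,
        source=SOURCE_SCAN_MARKER,
        labels=list(fiducials.labels),
        coords=coords,
        frame="scan",
    )


def _observer_session(
    base: LandmarkSet, config: GeneratorConfig, rng: np.random.Generator
) -> LandmarkSet:
    noisy = base.copy()
    noisy.coords = noisy.coords + rng.normal(
        0.0, config.observer_noise_sd_mm, size=noisy.coords.shape
    )
    noisy.session = 2
    return noisy


def _sample_demographics(config: GeneratorConfig, index: int) -> SubjectDemographics:
    from scipy.stats import truncnorm

    rng = _stage_rng(config.seed, index, 0)
    # deterministic low-discrepancy assignment: independent of n_subjects, so
    # growing the cohort never flips an earlier subject's gender, while any
    # prefix matches the configured fraction as closely as possible
    f = config.female_fraction
    gender = "F" if np.floor((index + 1) * f) > np.floor(index * f) else "M"
    age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)),
                      config.age_range[0], config.age_range[1]))
    lo, hi = config.bmi_bounds
    a = (lo - config.bmi_mean) / config.bmi_sd
    b = (hi - config.bmi_mean) / config.bmi_sd
    bmi = float(truncnorm.rvs(a, b, loc=config.bmi_mean, scale=config.bmi_sd,
                              random_state=rng))
    height = float(np.clip(
        rng.normal(1.63 if gender == "F" else 1.75, 0.06), 1.45, 2.00
    ))
    weight = bmi * height**2
    return SubjectDemographics(
        subject_id=f"S{index + 1:03d}", gender=gender, age=age,
        height_m=height, weight_kg=weight,
    )


def generate_subject(
    config: GeneratorConfig, index: int
) -> tuple[SubjectDemographics, list[LandmarkSet]]:
    """All landmark sets for subject ``index`` (pure, keyed by master seed)."""
    demo = _sample_demographics(config, index)
    spine = generate_spine_centerline(
        demo, config, subject_stage_seed(config.seed, index, 1)
    )
    fiducials = generate_fiducials(
        spine, demo, config, subject_stage_seed(config.seed, index, 2)
    )
    scan = generate_scan_markers(
        fiducials, config, subject_stage_seed(config.seed, index, 3)
    )
    sets = [spine, fiducials, scan]
    if index in config.reliability_subjects:
        rng = _stage_rng(config.seed, index, 4)
        sets.append(_observer_session(spine, config, rng))
        sets.append(_observer_session(fiducials, config, rng))
    return demo, sets


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[SubjectDemographics], list[LandmarkSet]]:
    """A full cohort: demographics and landmark sets for every subject,
    including session-2 duplicates for the designated reliability subjects.

    Pure and deterministic: identical (config, seed) reproduce the cohort
    byte for byte.
    """
    config.validate()
    demographics: list[SubjectDemographics] = []
    landmark_sets: list[LandmarkSet] = []
    for i in range(config.n_subjects):
        demo, sets = generate_subject(config, i)
        demographics.append(demo)
        landmark_sets.extend(sets)
    return demographics, landmark_sets
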