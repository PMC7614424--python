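"""Synthetic brain-PET phantom cohort with dose-fraction degradations.

Clinical low-dose PET studies rate reconstructions on three ordinal metrics
— global quality rating (GQR), pattern recognition (PR) and diagnostic
confidence (DC), each on a 0–3 scale in 0.5 steps — at count fractions
between 0.5% and 100% of a full acquisition.  The real scored scans behind
such studies are not shareable, so this module builds a stand-in cohort
with the same observable structure:

* brain-like activity phantoms (head ellipsoid, cortical shell > white
  matter > ventricles, zero outside the head);
* dose reduction by image-space Poisson thinning at a chosen count
  fraction, plus fraction-dependent Gaussian smoothing so that lower
  fractions are both noisier and blurrier, as low-count reconstructions
  are;
* min–max normalisation of each degraded volume to [0, 1];
* clinician-like scores: a monotone map from log10 of the
  weight-standardised dose to the 0–3 scale, with Gaussian rater noise,
  0.5-step quantisation and clipping.  Slope-to-noise ratios are largest
  for GQR, so the GQR–dose correlation dominates, as it does for real
  readers.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "FRACTIONS",
    "QUALITY_CATEGORIES",
    "AnatomyParams",
    "ActivityVolume",
    "ClinicalScores",
    "ScoreModelParams",
    "DoseFraction",
    "PatientRecord",
    "generate_phantom",
    "simulate_dose_fraction",
    "normalize_volume",
    "assign_scores",
    "make_cohort",
    "save_cohort",
    "load_cohort",
]

#: The seven simulated count fractions (0.5% … 100%).
FRACTIONS: tuple[float, ...] = (0.005, 0.01, 0.05, 0.10, 0.25, 0.50, 1.0)

#: Dose groupings used to shorten clinical reading sessions.
QUALITY_CATEGORIES: dict[str, tuple[float, ...]] = {
    "low": (0.005, 0.01),
    "medium": (0.05, 0.10),
    "high": (0.25, 0.50, 1.0),
}

METRICS = ("gqr", "pr", "dc")

#: Default expected total counts of a full (100%) acquisition.
DEFAULT_FULL_COUNTS = 200_000_000


@dataclass(frozen=True)
class AnatomyParams:
    """Geometry and relative uptake of the phantom head.

    Semi-axes are fractions of the corresponding full array dimension, so
    the head scales with the grid.  Uptakes are relative activity
    concentrations (cortex is the reference at 1.0).
    """

    semiaxes: tuple[float, float, float] = (0.40, 0.42, 0.38)
    cortex_uptake: float = 1.0
    white_uptake: float = 0.35
    ventricle_uptake: float = 0.10
    white_radius: float = 0.70  # normalised ellipsoid radius of the white-matter core
    ventricle_semiaxes: tuple[float, float, float] = (0.10, 0.22, 0.14)
    ventricle_offset: float = 0.16  # lateral offset of each ventricle, normalised
    texture_amplitude: float = 0.06  # SD of the smooth multiplicative texture field
    texture_sigma: float = 2.0  # smoothing of the texture field, voxels


@dataclass
class ActivityVolume:
    """Ground-truth tracer distribution on a voxel grid."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("activity volume must be 3-D")
        if np.any(v < 0):
            raise ValueError("activity must be nonnegative")
        if not np.any(v > 0):
            raise ValueError("activity must have at least one positive voxel")
        self.voxels = v


@dataclass(frozen=True)
class ClinicalScores:
    """One reader's (GQR, PR, DC) triple on the 0–3 half-point grid."""

    gqr: float
    pr: float
    dc: float

    def __post_init__(self):
        for name, value in self.as_dict().items():
            if not (0.0 <= value <= 3.0) or (round(value * 2) != value * 2):
                raise ValueError(f"{name}={value} is not a multiple of 0.5 in [0, 3]")

    def as_dict(self) -> dict[str, float]:
        return {"gqr": self.gqr, "pr": self.pr, "dc": self.dc}


@dataclass(frozen=True)
class ScoreModelParams:
    """Monotone log-dose → score model with rater noise.

    ``score = clip(quantise(slope * log10(fraction * full_counts / weight)
    + intercept + noise, 0.5), 0, 3)``.  Defaults place a 75 kg patient's
    100% scan near the top of the scale and its 0.5% scan near the bottom,
    with GQR carrying the highest slope-to-noise ratio.
    """

    slopes: dict[str, float] = field(
        default_factory=lambda: {"gqr": 1.30, "pr": 1.05, "dc": 0.95}
    )
    intercepts: dict[str, float] = field(
        default_factory=lambda: {"gqr": -5.36, "pr": -3.85, "dc": -3.31}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"gqr": 0.25, "pr": 0.40, "dc": 0.45}
    )
    between_patient_sd: float = 0.15
    step: float = 0.5

    def __post_init__(self):
        if any(s <= 0 for s in self.slopes.values()):
            raise ValueError("score-model slopes must be positive")
        ratio = {m: self.slopes[m] / max(self.noise_sd[m], 1e-12) for m in METRICS}
        if max(ratio, key=ratio.get) != "gqr":
            raise ValueError("GQR must have the highest slope-to-noise ratio")


@dataclass
class DoseFraction:
    """One degraded reconstruction of a patient at a given count fraction."""

    fraction: float
    volume: np.ndarray  # normalised to [0, 1]
    scores: ClinicalScores


@dataclass
class PatientRecord:
    patient_id: str
    weight_kg: float
    full_counts: int
    fractions: list[DoseFraction]
    seed: int

    def __post_init__(self):
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        shapes = {f.volume.shape for f in self.fractions}
        if len(shapes) > 1:
            raise ValueError("all fractions of one patient must share a volume shape")


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------


def _ellipsoid_radius(shape: tuple[int, int, int], center, semiaxes_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes_vox):
        r2 = r2 + ((g - c) / a) ** 2
    return np.sqrt(r2)


def generate_phantom(
    seed: int,
    shape: tuple[int, int, int] = (96, 96, 64),
    anatomy: AnatomyParams | None = None,
) -> ActivityVolume:
    """Generate a brain-like activity phantom.

    The head is an ellipsoid centred in the grid; within it a cortical
    shell surrounds a white-matter core that contains two low-uptake
    ventricles.  A smooth multiplicative texture field (seeded) makes
    repeated patients non-identical; outside the head the activity is
    exactly zero.
    """
    anatomy = anatomy or AnatomyParams()
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 32 for s in shape):
        raise ValueError(f"shape must be 3-D with every dimension >= 32, got {shape}")
    for name in ("cortex_uptake", "white_uptake", "ventricle_uptake"):
        if getattr(anatomy, name) <= 0:
            raise ValueError(f"{name} must be positive")

    rng = np.random.default_rng(seed)
    center = tuple((s - 1) / 2.0 for s in shape)
    semiaxes_vox = tuple(f * s for f, s in zip(anatomy.semiaxes, shape))
    r = _ellipsoid_radius(shape, center, semiaxes_vox)

    vol = np.zeros(shape, dtype=np.float64)
    head = r <= 1.0
    vol[head] = anatomy.cortex_uptake
    vol[r <= anatomy.white_radius] = anatomy.white_uptake

    # two lateral ventricles inside the white-matter core
    vsemi = tuple(f * s for f, s in zip(anatomy.ventricle_semiaxes, shape))
    for sign in (-1.0, 1.0):
        vc = (
            center[0] + sign * anatomy.ventricle_offset * shape[0],
            center[1],
            center[2],
        )
        rv = _ellipsoid_radius(shape, vc, vsemi)
        vol[(rv <= 1.0) & head] = anatomy.ventricle_uptake

    if anatomy.texture_amplitude > 0:
        noise = gaussian_filter(rng.standard_normal(shape), anatomy.texture_sigma)
        noise *= anatomy.texture_amplitude / max(noise.std(), 1e-12)
        vol[head] *= np.clip(1.0 + noise[head], 0.05, None)

    return ActivityVolume(voxels=vol)


# ---------------------------------------------------------------------------
# Dose-fraction simulation
# ---------------------------------------------------------------------------


def _smoothing_sigma(fraction: float) -> float:
    """Resolution loss at low counts: sigma grows as the fraction shrinks."""
    return 0.6 + 0.55 * (-np.log10(fraction))


def simulate_dose_fraction(
    activity: ActivityVolume | np.ndarray,
    full_counts: int,
    fraction: float,
    seed: int,
) -> np.ndarray:
    """Simulate a low-count acquisition by Poisson thinning in image space.

    Each voxel draws an independent Poisson count with mean
    ``fraction * full_counts * activity / activity.sum()`` and the result
    is smoothed with a Gaussian whose width grows as the fraction shrinks,
    emulating the noise increase and resolution loss of low-count
    reconstructions.  The expected total equals ``fraction * full_counts``.
    """
    vox = activity.voxels if isinstance(activity, ActivityVolume) else np.asarray(activity)
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if full_counts <= 0:
        raise ValueError("full_counts must be positive")
    total = vox.sum()
    if total <= 0:
        raise ValueError("activity has no support (all-zero volume)")

    rng = np.random.default_rng(seed)
    lam = vox * (fraction * full_counts / total)
    counts = rng.poisson(lam).astype(np.float64)
    return gaussian_filter(counts, _smoothing_sigma(fraction), mode="constant")


def normalize_volume(counts: np.ndarray) -> np.ndarray:
    """Scale a count volume to [0, 1] by its maximum (max maps exactly to 1)."""
    counts = np.asarray(counts, dtype=np.float64)
    peak = counts.max()
    if peak <= 0:
        raise ValueError("cannot normalise a volume with no positive voxel")
    return counts / peak


# ---------------------------------------------------------------------------
# Clinician-like scoring
# ---------------------------------------------------------------------------


def _quantise_half_up(x: float, step: float) -> float:
    """Round to the nearest multiple of ``step``; exact halves round up."""
    return float(np.floor(x / step + 0.5) * step)


def assign_scores(
    fraction: float,
    weight_kg: float,
    params: ScoreModelParams | None = None,
    seed: int = 0,
    full_counts: int = DEFAULT_FULL_COUNTS,
    patient_offset: dict[str, float] | None = None,
) -> ClinicalScores:
    """Draw one reader's (GQR, PR, DC) triple for a reconstruction.

    The latent score is linear in log10 of the weight-standardised dose
    ``fraction * full_counts / weight_kg``; rater noise is Gaussian, the
    result is quantised to the 0.5 grid (halves round up) and clipped to
    [0, 3].  ``patient_offset`` shifts the latent score per metric to model
    between-patient variation in how scannable a head is.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    params = params or ScoreModelParams()
    rng = np.random.default_rng(seed)
    dose_per_kg = fraction * full_counts / weight_kg
    x = np.log10(dose_per_kg)
    values = {}
    for metric in METRICS:
        latent = params.slopes[metric] * x + params.intercepts[metric]
        if patient_offset:
            latent += patient_offset.get(metric, 0.0)
        if params.noise_sd[metric] > 0:
            latent += rng.normal(0.0, params.noise_sd[metric])
        values[metric] = float(np.clip(_quantise_half_up(latent, params.step), 0.0, 3.0))
    return ClinicalScores(**values)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def _select_fractions(k: int, rng: np.random.Generator) -> list[float]:
    if k >= len(FRACTIONS):
        return list(FRACTIONS)
    if k == 3:
        # one fraction per quality category, mirroring shortened reading sessions
        return sorted(float(rng.choice(group)) for group in QUALITY_CATEGORIES.values())
    return sorted(float(f) for f in rng.choice(FRACTIONS, size=k, replace=False))


def _jitter_anatomy(anatomy: AnatomyParams, rng: np.random.Generator) -> AnatomyParams:
    scale = lambda v, rel: v * (1.0 + rng.uniform(-rel, rel))
    return replace(
        anatomy,
        semiaxes=tuple(scale(a, 0.05) for a in anatomy.semiaxes),
        white_uptake=scale(anatomy.white_uptake, 0.10),
        ventricle_uptake=scale(anatomy.ventricle_uptake, 0.10),
        white_radius=scale(anatomy.white_radius, 0.03),
    )


def make_cohort(
    n_patients: int,
    fractions_per_patient: int = 3,
    seed: int = 0,
    shape: tuple[int, int, int] = (96, 96, 64),
    anatomy: AnatomyParams | None = None,
    score_params: ScoreModelParams | None = None,
    id_prefix: str = "P",
) -> list[PatientRecord]:
    """Generate a scored phantom cohort.

    Per patient: a weight drawn from a truncated Normal(75, 10) on
    [45, 120] kg, a full-count total, a jittered anatomy, and
    ``fractions_per_patient`` degraded + normalised volumes each carrying
    a ClinicalScores triple.  Fully deterministic given ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    anatomy = anatomy or AnatomyParams()
    score_params = score_params or ScoreModelParams()
    master = np.random.SeedSequence(seed)
    records = []
    for i, child in enumerate(master.spawn(n_patients)):
        sub = child.generate_state(4) % (2**31)
        rng = np.random.default_rng(int(sub[0]))
        weight = float(rng.normal(75.0, 10.0))
        while not (45.0 <= weight <= 120.0):
            weight = float(rng.normal(75.0, 10.0))
        full_counts = int(np.clip(rng.normal(DEFAULT_FULL_COUNTS, 0.15 * DEFAULT_FULL_COUNTS), 5e7, None))
        offset = {m: float(rng.normal(0.0, score_params.between_patient_sd)) for m in METRICS}
        phantom = generate_phantom(int(sub[1]), shape=shape, anatomy=_jitter_anatomy(anatomy, rng))
        fractions = []
        for j, frac in enumerate(_select_fractions(fractions_per_patient, rng)):
            counts = simulate_dose_fraction(phantom, full_counts, frac, int(sub[2]) + j)
            volume = normalize_volume(counts).astype(np.float32)
            scores = assign_scores(
                frac,
                weight,
                params=score_params,
                seed=int(sub[3]) + j,
                full_counts=full_counts,
                patient_offset=offset,
            )
            fractions.append(DoseFraction(fraction=frac, volume=volume, scores=scores))
        records.append(
            PatientRecord(
                patient_id=f"{id_prefix}{i + 1:02d}",
                weight_kg=weight,
                full_counts=full_counts,
                fractions=fractions,
                seed=int(sub[0]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Cohort I/O: NIfTI volumes + CSV manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["patient_id", "weight_kg", "full_counts", "fraction", "volume_path", "gqr", "pr", "dc", "seed"]


def save_cohort(records: list[PatientRecord], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for df in rec.fractions:
            name = f"{rec.patient_id}_f{df.fraction:g}.nii.gz"
            nib.save(nib.Nifti1Image(df.volume.astype(np.float32), np.eye(4)), out_dir / name)
            rows.append(
                dict(
                    patient_id=rec.patient_id,
                    weight_kg=rec.weight_kg,
                    full_counts=rec.full_counts,
                    fraction=df.fraction,
                    volume_path=name,
                    **df.scores.as_dict(),
                    seed=rec.seed,
                )
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> list[PatientRecord]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    records = []
    for pid, group in table.groupby("patient_id", sort=False):
        fractions = []
        for _, row in group.sort_values("fraction").iterrows():
            vol = np.asarray(nib.load(base / row["volume_path"]).get_fdata(), dtype=np.float32)
            scores = ClinicalScores(gqr=row["gqr"], pr=row["pr"], dc=row["dc"])
            fractions.append(DoseFraction(fraction=float(row["fraction"]), volume=vol, scores=scores))
        first = group.iloc[0]
        records.append(
            PatientRecord(
                patient_id=str(pid),
                weight_kg=float(first["weight_kg"]),
                full_counts=int(first["full_counts"]),
                fractions=fractions,
                seed=int(first["seed"]),
            )
        )
    return records
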