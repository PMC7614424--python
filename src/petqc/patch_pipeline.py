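"""Extraction, background thresholding and balanced sampling of 2-D patches.

A normalised volume is sliced along the three anatomical planes
(transverse, sagittal, coronal); square windows are drawn uniformly over
(plane, slice, corner).  A candidate is rejected as background when its
mean pixel value falls below one-eighth of the whole-volume mean — the
rule used when masking brain from background in FDG PET.  From the
surviving candidates an equal number is sampled per plane (without
replacement on distinct windows), so every reconstruction contributes a
plane-balanced patch set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PLANES",
    "Patch",
    "PatchSet",
    "feasible_patch_size",
    "extract_candidates",
    "passes_background_threshold",
    "sample_balanced",
    "extract_patch_set",
    "to_three_channel",
    "save_patch_set",
    "load_patch_set",
]

PLANES = ("transverse", "sagittal", "coronal")

# in-plane axes of each plane for a volume indexed (x, y, z)
_PLANE_AXES = {"transverse": (0, 1), "sagittal": (1, 2), "coronal": (0, 2)}
_SLICE_AXIS = {"transverse": 2, "sagittal": 0, "coronal": 1}


@dataclass
class Patch:
    """A single square window from one anatomical plane."""

    pixels: np.ndarray
    plane: str
    slice_index: int
    corner: tuple[int, int]
    patient_id: str | None = None
    fraction: float | None = None

    @property
    def key(self) -> tuple:
        return (self.plane, self.slice_index, self.corner)


@dataclass
class PatchSet:
    patches: list[Patch] = field(default_factory=list)

    def __len__(self):
        return len(self.patches)

    @property
    def per_plane_counts(self) -> dict[str, int]:
        counts = {p: 0 for p in PLANES}
        for patch in self.patches:
            counts[patch.plane] += 1
        return counts

    def to_array(self) -> np.ndarray:
        """Stack as (n, size, size) float32."""
        return np.stack([p.pixels for p in self.patches]).astype(np.float32)


def feasible_patch_size(shape: tuple[int, int, int], requested: int) -> int:
    """Largest usable patch size <= requested, valid in all three planes.

    When the requested size does not fit the volume (desk-scale grids are
    smaller than clinical 344-voxel grids), it is reduced to the largest
    feasible multiple of 16 and a warning is logged.
    """
    limit = min(shape)
    if requested <= limit:
        return requested
    reduced = (limit // 16) * 16
    if reduced < 16:
        raise ValueError(f"no feasible patch size for volume shape {shape}")
    logger.warning(
        "patch size %d does not fit volume shape %s; reduced to %d", requested, shape, reduced
    )
    return reduced


def _slice_patch(volume: np.ndarray, plane: str, slice_index: int, corner, size: int) -> np.ndarray:
    r, c = corner
    if plane == "transverse":
        return volume[r : r + size, c : c + size, slice_index]
    if plane == "sagittal":
        return volume[slice_index, r : r + size, c : c + size]
    if plane == "coronal":
        return volume[r : r + size, slice_index, c : c + size]
    raise ValueError(f"unknown plane {plane!r}")


def _draw_candidates(
    volume: np.ndarray,
    n: int,
    size: int,
    rng: np.random.Generator,
    planes: tuple[str, ...],
    patient_id=None,
    fraction=None,
) -> list[Patch]:
    shape = volume.shape
    out = []
    plane_idx = rng.integers(0, len(planes), size=n)
    for i in range(n):
        plane = planes[plane_idx[i]]
        a0, a1 = _PLANE_AXES[plane]
        sl = int(rng.integers(0, shape[_SLICE_AXIS[plane]]))
        r = int(rng.integers(0, shape[a0] - size + 1))
        c = int(rng.integers(0, shape[a1] - size + 1))
        out.append(
            Patch(
                pixels=np.ascontiguousarray(_slice_patch(volume, plane, sl, (r, c), size)),
                plane=plane,
                slice_index=sl,
                corner=(r, c),
                patient_id=patient_id,
                fraction=fraction,
            )
        )
    return out


def extract_candidates(
    volume: np.ndarray,
    n: int = 1000,
    size: int = 80,
    seed: int = 0,
    patient_id: str | None = None,
    fraction: float | None = None,
) -> list[Patch]:
    """Draw ``n`` candidate patches uniformly over (plane, slice, corner).

    The plane is chosen uniformly among transverse, sagittal and coronal;
    candidates are drawn with replacement (two may coincide) and always
    lie fully inside the volume.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must be 3-D")
    if size > min(volume.shape):
        raise ValueError(
            f"patch size {size} exceeds the smallest volume dimension {min(volume.shape)}; "
            "use feasible_patch_size() first"
        )
    rng = np.random.default_rng(seed)
    return _draw_candidates(volume, n, size, rng, PLANES, patient_id, fraction)


def passes_background_threshold(patch: Patch | np.ndarray, volume_mean: float) -> bool:
    """True iff the patch mean is at least one-eighth of the volume mean.

    Equality survives: only patches strictly below the threshold are
    rejected as background.
    """
    if volume_mean <= 0:
        raise ValueError("volume mean must be positive")
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    return float(pixels.mean()) >= volume_mean / 8.0


def sample_balanced(
    candidates: list[Patch],
    per_plane: int = 100,
    seed: int = 0,
    redraw=None,
    max_attempts_factor: int = 50,
) -> PatchSet:
    """Sample ``per_plane`` distinct surviving patches from each plane.

    Sampling is uniform without replacement over distinct (plane, slice,
    corner) windows.  If a plane has fewer survivors than ``per_plane``
    and a ``redraw(plane, n_needed)`` callback is given, fresh candidates
    are drawn for that plane until filled, bounded at
    ``max_attempts_factor * per_plane`` redraw batches; otherwise the
    shortfall is an error naming the plane.
    """
    if per_plane == 0:
        return PatchSet([])
    rng = np.random.default_rng(seed)
    by_plane: dict[str, dict[tuple, Patch]] = {p: {} for p in PLANES}
    for patch in candidates:
        by_plane[patch.plane].setdefault(patch.key, patch)

    selected: list[Patch] = []
    for plane in PLANES:
        pool = by_plane[plane]
        attempts = 0
        while len(pool) < per_plane:
            if redraw is None:
                raise RuntimeError(
                    f"plane {plane!r}: only {len(pool)} surviving candidates for "
                    f"per_plane={per_plane} and no redraw source"
                )
            attempts += 1
            if attempts > max_attempts_factor * per_plane:
                raise RuntimeError(
                    f"plane {plane!r}: could not reach {per_plane} foreground patches "
                    f"after {attempts - 1} redraw batches"
                )
            for patch in redraw(plane, per_plane - len(pool)):
                pool.setdefault(patch.key, patch)
        keys = sorted(pool)
        if len(keys) == per_plane:
            chosen = keys
        else:
            chosen = [keys[i] for i in rng.choice(len(keys), size=per_plane, replace=False)]
        selected.extend(pool[k] for k in chosen)
    return PatchSet(selected)


def extract_patch_set(
    volume: np.ndarray,
    per_plane: int = 100,
    size: int = 80,
    n_candidates: int | None = None,
    seed: int = 0,
    patient_id: str | None = None,
    fraction: float | None = None,
) -> PatchSet:
    """Full per-volume pipeline: candidates → background threshold → balance.

    ``size`` is auto-reduced when it does not fit the volume.  The default
    candidate count follows the 1000-candidates-for-100-per-plane ratio
    and scales with ``per_plane``.
    """
    volume = np.asarray(volume)
    size = feasible_patch_size(volume.shape, size)
    if n_candidates is None:
        n_candidates = max(10 * per_plane, 30)
    vol_mean = float(volume.mean())
    if vol_mean <= 0:
        raise ValueError("volume has no signal; cannot threshold patches")
    rng = np.random.default_rng(seed)

    candidates = _draw_candidates(
        volume, n_candidates, size, rng, PLANES, patient_id, fraction
    )
    survivors = [p for p in candidates if passes_background_threshold(p, vol_mean)]

    def redraw(plane: str, n_needed: int) -> list[Patch]:
        fresh = _draw_candidates(
            volume, max(4 * n_needed, 16), size, rng, (plane,), patient_id, fraction
        )
        return [p for p in fresh if passes_background_threshold(p, vol_mean)]

    return sample_balanced(
        survivors, per_plane=per_plane, seed=int(rng.integers(2**31)), redraw=redraw
    )


def to_three_channel(patch: Patch | np.ndarray) -> np.ndarray:
    """Replicate a grayscale patch into three identical channels (3, h, w)."""
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    if pixels.ndim != 2:
        raise ValueError("patch must be single-channel 2-D")
    return np.repeat(pixels[None, :, :], 3, axis=0)


def _sibling(path: Path, suffix: str) -> Path:
    # append the suffix: stems may contain dots (e.g. fraction 0.05)
    name = path.name
    for known in (".npz", ".csv"):
        if name.endswith(known):
            name = name[: -len(known)]
    return path.with_name(name + suffix)


def save_patch_set(patch_set: PatchSet, path: str | Path) -> None:
    """Write pixels to an .npz container plus a CSV provenance index."""
    path = Path(path)
    np.savez_compressed(_sibling(path, ".npz"), pixels=patch_set.to_array())
    pd.DataFrame(
        [
            dict(
                patient_id=p.patient_id,
                fraction=p.fraction,
                plane=p.plane,
                slice_index=p.slice_index,
                row=p.corner[0],
                col=p.corner[1],
            )
            for p in patch_set.patches
        ]
    ).to_csv(_sibling(path, ".csv"), index=False)


def load_patch_set(path: str | Path) -> PatchSet:
    path = Path(path)
    pixels = np.load(_sibling(path, ".npz"))["pixels"]
    index = pd.read_csv(_sibling(path, ".csv"))
    patches = [
        Patch(
            pixels=pixels[i],
            plane=row["plane"],
            slice_index=int(row["slice_index"]),
            corner=(int(row["row"]), int(row["col"])),
            patient_id=None if pd.isna(row["patient_id"]) else str(row["patient_id"]),
            fraction=None if pd.isna(row["fraction"]) else float(row["fraction"]),
        )
        for i, row in index.iterrows()
    ]
    return PatchSet(patches)
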