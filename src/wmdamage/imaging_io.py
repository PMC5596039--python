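"""Volume and mask I/O with geometric-consistency checks.

All downstream computation assumes the sequences of one scanning session are
already co-registered onto a common voxel grid (registration is an upstream
concern, typically FSL-FLIRT).  This module enforces that assumption at load
time: volumes must share the exact grid shape, and affines must agree within
a small per-element tolerance.

Masks are voxel-binary.  Probabilistic tissue maps (e.g. a partial-volume
white-matter map) are binarised at a configurable threshold, 0.5 by default.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "MultiSequenceScan",
    "TissueMaskSet",
    "GridMismatchError",
    "MaskInvariantError",
    "read_scan",
    "read_masks",
    "write_volume",
    "write_result",
    "read_result",
]

#: maximum allowed per-element difference between affines of co-registered files
AFFINE_TOL = 1e-3

#: binarisation threshold for probabilistic mask inputs
DEFAULT_MASK_THRESHOLD = 0.5


class GridMismatchError(ValueError):
    """Volumes that must share a grid do not."""


class MaskInvariantError(ValueError):
    """A tissue-mask set violates its partition/containment invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MultiSequenceScan:
    """Co-registered structural MRI volumes of one subject at one timepoint.

    FLAIR is mandatory; T1-, T2- and T2*-weighted volumes are optional.
    ``voxel_dims`` are the voxel edge lengths in mm, taken from the FLAIR
    header when loaded from disk.
    """

    flair: np.ndarray
    t1w: np.ndarray | None = None
    t2w: np.ndarray | None = None
    t2star: np.ndarray | None = None
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.flair = np.asarray(self.flair, dtype=float)
        if self.flair.ndim != 3:
            raise ValueError(f"FLAIR must be 3-D, got shape {self.flair.shape}")
        if not np.all(np.isfinite(self.flair)):
            raise ValueError("FLAIR contains non-finite values")
        vd = tuple(float(v) for v in self.voxel_dims)
        if len(vd) != 3 or any(v <= 0 for v in vd):
            raise ValueError(f"voxel_dims must be three positive lengths, got {self.voxel_dims}")
        self.voxel_dims = vd
        for name in ("t1w", "t2w", "t2star"):
            vol = getattr(self, name)
            if vol is None:
                continue
            vol = np.asarray(vol, dtype=float)
            if vol.shape != self.flair.shape:
                raise GridMismatchError(
                    f"{name} shape {vol.shape} differs from FLAIR shape {self.flair.shape}"
                )
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, vol)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flair.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))

    def channels(self) -> dict[str, np.ndarray]:
        """Present sequences, keyed by name, FLAIR first."""
        out = {"flair": self.flair}
        for name in ("t1w", "t2w", "t2star"):
            vol = getattr(self, name)
            if vol is not None:
                out[name] = vol
        return out


@dataclass
class TissueMaskSet:
    """Binary tissue masks on the scan grid.

    ``icv`` (intracranial volume) bounds everything; ``nawm`` and
    ``wmh_total`` are disjoint and contained in it.  When the intense /
    less-intense WMH subdivision is available the two sub-masks partition
    ``wmh_total``.  ``exclusion`` marks voxels (stroke lesions, artefacts)
    removed from all tissue compartments upstream.
    """

    icv: np.ndarray
    nawm: np.ndarray
    wmh_total: np.ndarray
    wmh_intense: np.ndarray | None = None
    wmh_less_intense: np.ndarray | None = None
    exclusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.validate()

    def _as_bool(self, arr: np.ndarray, name: str) -> np.ndarray:
        arr = np.asarray(arr)
        if arr.ndim != 3:
            raise ValueError(f"mask {name!r} must be 3-D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask {name!r} is not binary (values {uniq[:5]}...)")
        return arr.astype(bool)

    def validate(self) -> "TissueMaskSet":
        """Coerce to boolean and enforce the partition invariants.

        Idempotent: validating an already-valid set changes nothing.
        Raises :class:`MaskInvariantError` with voxel counts on violation.
        """
        self.icv = self._as_bool(self.icv, "icv")
        shape = self.icv.shape
        for name in ("nawm", "wmh_total", "wmh_intense", "wmh_less_intense", "exclusion"):
            m = getattr(self, name)
            if m is None:
                continue
            m = self._as_bool(m, name)
            if m.shape != shape:
                raise GridMismatchError(f"mask {name!r} shape {m.shape} != icv shape {shape}")
            setattr(self, name, m)

        overlap = int(np.sum(self.nawm & self.wmh_total))
        if overlap:
            raise MaskInvariantError(f"nawm and wmh_total overlap in {overlap} voxels")
        outside = int(np.sum((self.nawm | self.wmh_total) & ~self.icv))
        if outside:
            raise MaskInvariantError(f"{outside} tissue voxels fall outside the ICV mask")
        if (self.wmh_intense is None) != (self.wmh_less_intense is None):
            raise MaskInvariantError(
                "wmh_intense and wmh_less_intense must be given together or not at all"
            )
        if self.wmh_intense is not None and self.wmh_less_intense is not None:
            both = int(np.sum(self.wmh_intense & self.wmh_less_intense))
            if both:
                raise MaskInvariantError(
                    f"intense and less-intense WMH overlap in {both} voxels"
                )
            union = self.wmh_intense | self.wmh_less_intense
            missing = int(np.sum(self.wmh_total & ~union))
            extra = int(np.sum(union & ~self.wmh_total))
            if missing or extra:
                raise MaskInvariantError(
                    "intense ∪ less-intense must equal wmh_total "
                    f"({missing} uncovered, {extra} outside total)"
                )
        if self.exclusion is not None:
            bad = int(np.sum(self.exclusion & (self.nawm | self.wmh_total)))
            if bad:
                raise MaskInvariantError(
                    f"exclusion mask intersects tissue compartments in {bad} voxels"
                )
        return self


# ---------------------------------------------------------------------------
# NIfTI reading / writing
# ---------------------------------------------------------------------------

def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine, dtype=float), zooms


def _check_congruent(ref_name: str, ref_shape, ref_affine, name: str, shape, affine) -> list[str]:
    problems = []
    if shape != ref_shape:
        problems.append(f"{name}: shape {shape} != {ref_name} shape {ref_shape}")
    elif np.max(np.abs(affine - ref_affine)) > AFFINE_TOL:
        problems.append(
            f"{name}: affine differs from {ref_name} by "
            f"{np.max(np.abs(affine - ref_affine)):.2e} (> {AFFINE_TOL})"
        )
    return problems


def read_scan(
    paths: Mapping[str, str | Path],
    subject_id: str = "",
    timepoint: str = "",
) -> MultiSequenceScan:
    """Load a co-registered multi-sequence scan from NIfTI files.

    Parameters
    ----------
    paths
        Mapping with mandatory key ``"flair"`` and optional keys ``"t1w"``,
        ``"t2w"``, ``"t2star"``.
    """
    if "flair" not in paths:
        raise ValueError("FLAIR is mandatory: paths must contain key 'flair'")
    unknown = set(paths) - {"flair", "t1w", "t2w", "t2star"}
    if unknown:
        raise ValueError(f"unknown sequence keys: {sorted(unknown)}")

    flair, ref_affine, zooms = _load_nifti(paths["flair"])
    volumes: dict[str, np.ndarray | None] = {"t1w": None, "t2w": None, "t2star": None}
    problems: list[str] = []
    for name in ("t1w", "t2w", "t2star"):
        if name not in paths:
            continue
        data, affine, _ = _load_nifti(paths[name])
        problems += _check_congruent("flair", flair.shape, ref_affine, name, data.shape, affine)
        volumes[name] = data
    if problems:
        raise GridMismatchError("scan volumes are not congruent:\n  " + "\n  ".join(problems))
    return MultiSequenceScan(
        flair=flair, voxel_dims=zooms, subject_id=subject_id, timepoint=timepoint, **volumes
    )


def read_masks(
    paths: Mapping[str, str | Path],
    threshold: float = DEFAULT_MASK_THRESHOLD,
) -> TissueMaskSet:
    """Load and validate a tissue-mask set from NIfTI files.

    Inputs may be probabilistic; they are binarised at ``threshold`` before
    validation.  Keys: ``icv``, ``nawm``, ``wmh_total`` (required),
    ``wmh_intense``, ``wmh_less_intense``, ``exclusion`` (optional).
    """
    required = {"icv", "nawm", "wmh_total"}
    missing = required - set(paths)
    if missing:
        raise ValueError(f"missing required mask paths: {sorted(missing)}")
    loaded: dict[str, np.ndarray] = {}
    ref_shape = ref_affine = None
    problems: list[str] = []
    for name in ("icv", "nawm", "wmh_total", "wmh_intense", "wmh_less_intense", "exclusion"):
        if name not in paths:
            continue
        data, affine, _ = _load_nifti(paths[name])
        if ref_shape is None:
            ref_shape, ref_affine = data.shape, affine
        else:
            problems += _check_congruent("icv", ref_shape, ref_affine, name, data.shape, affine)
        loaded[name] = (data > threshold).astype(bool)
    if problems:
        raise GridMismatchError("mask volumes are not congruent:\n  " + "\n  ".join(problems))
    return TissueMaskSet(**loaded)


def write_volume(
    data: np.ndarray,
    path: str | Path,
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a 3-D array as NIfTI-1 with a diagonal affine from voxel_dims."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(voxel_dims) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Result serialisation
# ---------------------------------------------------------------------------

def _result_to_dict(result) -> dict:
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        d = dataclasses.asdict(result)
    elif isinstance(result, Mapping):
        d = dict(result)
    else:
        raise TypeError(f"cannot serialise result of type {type(result).__name__}")
    for k, v in d.items():
        if isinstance(v, np.generic):
            d[k] = v.item()
    return d


def write_result(result, path: str | Path, format: str = "json") -> None:
    """Serialise a result record (dataclass or mapping) to JSON or CSV.

    Every field is written; numeric zeros serialise as ``0``, never null.
    The written file round-trips through :func:`read_result` to full float
    precision.
    """
    d = _result_to_dict(result)
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")
    elif format == "csv":
        # JSON-encode each cell so None/bool/number round-trip typed
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(d.keys())
            writer.writerow([json.dumps(v) for v in d.values()])
    else:
        raise ValueError(f"unknown format {format!r} (expected 'json' or 'csv')")


def read_result(path: str | Path, format: str = "json") -> dict:
    """Read back a record written by :func:`write_result`."""
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    if format == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if len(rows) != 2:
            raise ValueError(f"expected header + one data row in {path}")
        out = {}
        for key, raw in zip(rows[0], rows[1]):
            try:
                out[key] = json.loads(raw)
            except (json.JSONDecodeError, TypeError):
                out[key] = raw
        return out
    raise ValueError(f"unknown format {format!r}")
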