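"""Synthetic multi-sequence brain phantoms with ground truth.

The phantom is a nested-ellipsoid brain: an intracranial ellipsoid whose
outer shell is cortex, whose interior is white matter, with a central
ventricular ellipsoid of CSF.  Ellipsoidal WMH lesions are placed inside
the white matter, split into an *intense* and a *less-intense* compartment
whose FLAIR means sit ``k_intense`` and ``k_less`` NAWM standard deviations
above the NAWM mean — mirroring the operational definition of WMH as signal
at least 3 SD above normal-appearing white matter.

Because every tissue has a known mean and the truth masks delimit the
compartments exactly, the expected WM damage metric is available in closed
form, making the whole downstream pipeline testable without any image data.

Simplifications (deliberate, documented): noise is additive Gaussian rather
than Rician; tissue interiors are homogeneous (no texture, no partial
volume); T1/T2/T2* channels use fixed per-tissue intensity lookup tables so
the colour-fusion segmentation path is exercisable — they are not claimed
physiologically calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import MultiSequenceScan, TissueMaskSet
from .metric import voxels_to_ml

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "LesionPlacementError",
    "generate_phantom",
    "expected_metric",
    "SECONDARY_TISSUE_MEANS",
]


class LesionPlacementError(RuntimeError):
    """Could not place the requested lesions without overlap."""


#: Per-tissue means (arbitrary units, 8-bit-like scale) for the secondary
#: sequences.  Chosen for plausible qualitative contrast only: CSF bright on
#: T2W and dark on T1W, lesions T1-hypointense and T2-hyperintense.
SECONDARY_TISSUE_MEANS: dict[str, dict[str, float]] = {
    "t1w": {"background": 0.0, "csf": 20.0, "cortex": 120.0, "nawm": 150.0,
            "wmh_less": 120.0, "wmh_intense": 105.0},
    "t2w": {"background": 0.0, "csf": 230.0, "cortex": 140.0, "nawm": 100.0,
            "wmh_less": 160.0, "wmh_intense": 200.0},
    "t2star": {"background": 0.0, "csf": 200.0, "cortex": 130.0, "nawm": 110.0,
               "wmh_less": 150.0, "wmh_intense": 175.0},
}


@dataclass
class PhantomSpec:
    """Ground-truth parameters of a synthetic scan.

    FLAIR lesion means are ``mu_nawm + k·sd_nawm``; ``sd_nawm`` is the
    nominal NAWM standard deviation that defines lesion contrast, while
    ``noise_sd`` is the additive Gaussian image noise actually applied
    (``noise_sd = 0`` gives exactly piecewise-constant images, so the
    measured metric equals the closed-form expectation to rounding).
    Defaults put the NAWM mean at 59% of the ceiling (within the 50–75%
    windowing convention for T2-based sequences) and image SNR
    (``mu_nawm/noise_sd``) at 20.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mu_nawm: float = 150.0
    sd_nawm: float = 15.0
    csf_mu: float = 30.0
    cortex_mu: float = 170.0
    k_intense: float = 6.0
    k_less: float = 3.0
    n_lesions: int = 8
    lesion_radius_range: tuple[float, float] = (2.0, 5.0)
    noise_sd: float = 7.5
    seed: int = 0
    imax: float = 255.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be three ints >= 16")
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        if self.k_less < 3:
            raise ValueError(
                f"k_less must be >= 3 (WMH are defined at least 3 SD above NAWM), got {self.k_less}"
            )
        if self.k_intense <= self.k_less:
            raise ValueError("k_intense must exceed k_less")
        if self.mu_nawm > (2.0 / 3.0) * self.imax:
            raise ValueError(
                f"mu_nawm {self.mu_nawm} exceeds 2/3 of imax {self.imax}; "
                "good T2-based contrast requires I_NAWM <= (2/3)*Imax"
            )
        for name in ("mu_nawm", "csf_mu", "cortex_mu"):
            v = getattr(self, name)
            if not (0 <= v <= self.imax):
                raise ValueError(f"{name}={v} outside [0, imax={self.imax}]")
        if self.sd_nawm < 0 or self.noise_sd < 0:
            raise ValueError("sd_nawm and noise_sd must be non-negative")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be non-negative")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must satisfy 0 < lo <= hi")

    @property
    def mu_wmh_intense(self) -> float:
        return self.mu_nawm + self.k_intense * self.sd_nawm

    @property
    def mu_wmh_less(self) -> float:
        return self.mu_nawm + self.k_less * self.sd_nawm


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    masks: TissueMaskSet
    expected_wm_damage: float
    expected_volumes_ml: dict[str, float]
    cortex: np.ndarray | None = None
    csf: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _tissue_labels(spec: PhantomSpec):
    """Nested-ellipsoid anatomy: ICV > cortex shell > WM > ventricles (CSF)."""
    shape = spec.grid_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    outer = tuple(0.44 * s for s in shape)  # ICV semi-axes
    icv = _ellipsoid_mask(shape, center, outer)
    inner = _ellipsoid_mask(shape, center, tuple(0.82 * a for a in outer))
    cortex = icv & ~inner
    ventricles = _ellipsoid_mask(shape, center, tuple(0.22 * a for a in outer))
    wm = inner & ~ventricles
    return icv, cortex, wm, ventricles


def _place_lesions(spec: PhantomSpec, wm: np.ndarray, rng: np.random.Generator):
    """Place non-overlapping ellipsoidal lesions fully inside the WM region.

    Lesions alternate intense / less-intense by placement order so both
    compartments are populated whenever ``n_lesions >= 2``.
    """
    shape = spec.grid_shape
    intense = np.zeros(shape, dtype=bool)
    less = np.zeros(shape, dtype=bool)
    candidates = np.argwhere(wm)
    max_tries = 200 * max(spec.n_lesions, 1)
    placed = 0
    tries = 0
    while placed < spec.n_lesions:
        if tries >= max_tries:
            raise LesionPlacementError(
                f"placed only {placed}/{spec.n_lesions} lesions after {max_tries} tries; "
                "reduce n_lesions or lesion_radius_range"
            )
        tries += 1
        center = candidates[rng.integers(len(candidates))]
        radii = rng.uniform(*spec.lesion_radius_range, size=3)
        blob = _ellipsoid_mask(shape, center, radii)
        # lesion must sit fully in WM and not touch an existing lesion
        if np.any(blob & ~wm) or np.any(blob & (intense | less)):
            continue
        if placed % 2 == 0:
            intense |= blob
        else:
            less |= blob
        placed += 1
    return intense, less


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _paint(shape, regions: dict[str, np.ndarray], means: dict[str, float]) -> np.ndarray:
    vol = np.full(shape, means["background"], dtype=float)
    for name in ("csf", "cortex", "nawm", "wmh_less", "wmh_intense"):
        vol[regions[name]] = means[name]
    return vol


def generate_phantom(spec: PhantomSpec) -> tuple[MultiSequenceScan, PhantomTruth]:
    """Generate a multi-sequence phantom and its ground truth.

    Deterministic given ``spec.seed``.  Returns the scan (FLAIR, T1W, T2W,
    T2*W) and a :class:`PhantomTruth` whose masks exactly delimit the
    generated compartments and whose ``expected_wm_damage`` is the
    closed-form metric of the noiseless tissue means.
    """
    rng = np.random.default_rng(spec.seed)
    icv, cortex, wm, ventricles = _tissue_labels(spec)
    intense, less = _place_lesions(spec, wm, rng)
    nawm = wm & ~(intense | less)
    regions = {
        "csf": ventricles,
        "cortex": cortex,
        "nawm": nawm,
        "wmh_less": less,
        "wmh_intense": intense,
    }

    flair_means = {
        "background": 0.0,
        "csf": spec.csf_mu,
        "cortex": spec.cortex_mu,
        "nawm": spec.mu_nawm,
        "wmh_less": spec.mu_wmh_less,
        "wmh_intense": spec.mu_wmh_intense,
    }
    shape = spec.grid_shape
    volumes = {"flair": _paint(shape, regions, flair_means)}
    for name, means in SECONDARY_TISSUE_MEANS.items():
        volumes[name] = _paint(shape, regions, means)
    if spec.noise_sd > 0:
        for name in volumes:
            volumes[name] = volumes[name] + rng.normal(0.0, spec.noise_sd, size=shape)

    scan = MultiSequenceScan(
        flair=volumes["flair"],
        t1w=volumes["t1w"],
        t2w=volumes["t2w"],
        t2star=volumes["t2star"],
        voxel_dims=spec.voxel_dims,
        subject_id="phantom",
        timepoint="synthetic",
    )
    masks = TissueMaskSet(
        icv=icv,
        nawm=nawm,
        wmh_total=intense | less,
        wmh_intense=intense,
        wmh_less_intense=less,
    )
    vols_ml = {
        "icv": voxels_to_ml(int(icv.sum()), spec.voxel_dims),
        "cortex": voxels_to_ml(int(cortex.sum()), spec.voxel_dims),
        "csf": voxels_to_ml(int(ventricles.sum()), spec.voxel_dims),
        "nawm": voxels_to_ml(int(nawm.sum()), spec.voxel_dims),
        "wmh_total": voxels_to_ml(int((intense | less).sum()), spec.voxel_dims),
        "wmh_intense": voxels_to_ml(int(intense.sum()), spec.voxel_dims),
        "wmh_less_intense": voxels_to_ml(int(less.sum()), spec.voxel_dims),
    }
    truth = PhantomTruth(
        masks=masks,
        expected_wm_damage=expected_metric(spec, vols_ml),
        expected_volumes_ml=vols_ml,
        cortex=cortex,
        csf=ventricles,
    )
    return scan, truth


def expected_metric(spec: PhantomSpec, truth_volumes: dict[str, float]) -> float:
    """Closed-form WM damage of a phantom from its spec means and volumes.

    The WMH mean is the volume-weighted mean of the intense and less-intense
    compartment means.  Returns 0 when the WMH volume is 0.
    """
    v_int = float(truth_volumes.get("wmh_intense", 0.0))
    v_less = float(truth_volumes.get("wmh_less_intense", 0.0))
    v_wmh = v_int + v_less
    v_nawm = float(truth_volumes["nawm"])
    if v_wmh == 0:
        return 0.0
    if v_nawm <= 0:
        raise ValueError("NAWM volume must be positive")
    i_wmh = (v_int * spec.mu_wmh_intense + v_less * spec.mu_wmh_less) / v_wmh
    contrast = (i_wmh - spec.mu_nawm) / spec.mu_nawm
    proportion = v_wmh / (v_wmh + v_nawm)
    return contrast * proportion
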