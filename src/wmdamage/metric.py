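"""The contrast-weighted white-matter damage metric.

WMH (white-matter hyperintensities) appear bright on FLAIR/T2-weighted MRI.
Raw WMH volume ignores how abnormal the lesion signal actually is, and is
sensitive to segmentation differences in the faint lesion periphery.  The
WM damage metric weights the lesion *proportion* of the tissue where WMH can
occur (brain white matter, i.e. WMH + NAWM) by the relative FLAIR contrast
of the lesions against normal-appearing white matter:

    WM_damage = (I_WMH - I_NAWM) / I_NAWM  *  WMH_vol / (WMH_vol + NAWM_vol)

where I_X is the mean FLAIR (or T2W) intensity over compartment X.  Under
the standard operating conditions — lesion intensity at least 3 NAWM
standard deviations above the NAWM mean, and NAWM mean at most 2/3 of the
intensity ceiling (the usual windowing convention for T2-based sequences) —
the metric takes values in [0, 1].  It is defined as exactly 0 when no WMH
are present, and is invariant to global intensity rescaling (but not to
intensity shifts, since the contrast term is a ratio of means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import GridMismatchError, MultiSequenceScan, TissueMaskSet

__all__ = [
    "IntensityStats",
    "WMDamageResult",
    "LongitudinalChange",
    "intensity_stats",
    "wm_damage",
    "wm_damage_from_masks",
    "pct_icv",
    "volume_change",
    "spatial_change",
    "voxels_to_ml",
]


def voxels_to_ml(n_voxels: int | float, voxel_dims: tuple[float, float, float]) -> float:
    """Volume in millilitres of ``n_voxels`` voxels with edges in mm."""
    return float(n_voxels) * float(np.prod(voxel_dims)) / 1000.0


# ---------------------------------------------------------------------------
# Intensity statistics (the I = sum I_i / n estimator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityStats:
    """First-order intensity statistics of one tissue compartment.

    ``mean`` is the arithmetic mean over the n voxels the compartment
    occupies; ``sd`` is the population standard deviation (ddof=0).
    """

    mean: float
    sd: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("IntensityStats requires at least one voxel")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"inconsistent stats: min {self.min} <= mean {self.mean} <= max {self.max} fails"
            )
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def intensity_stats(volume: np.ndarray, mask: np.ndarray) -> IntensityStats:
    """Mean/SD/min/max/count of ``volume`` within a binary ``mask``.

    Raises on an empty mask: the WMH-absent case is a *metric* decision
    (value 0) and is handled by the caller before statistics are requested.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape:
        raise GridMismatchError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    values = volume[mask]
    if values.size == 0:
        raise ValueError("mask selects no voxels")
    if not np.all(np.isfinite(values)):
        raise ValueError("masked intensities contain non-finite values")
    return IntensityStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        min=float(values.min()),
        max=float(values.max()),
        n=int(values.size),
    )


# ---------------------------------------------------------------------------
# The WM damage metric
# ---------------------------------------------------------------------------

@dataclass
class WMDamageResult:
    """The metric value with its two factors and the volume bookkeeping.

    ``contrast_term`` is (I_WMH − I_NAWM)/I_NAWM; ``proportion_term`` is
    WMHvol/(WMHvol+NAWMvol).  ``valid`` is False when the contrast is
    negative (lesions darker than NAWM — almost certainly a segmentation
    error); the raw negative value is reported rather than clamped so the
    problem stays visible.
    """

    wm_damage: float
    contrast_term: float
    proportion_term: float
    wmh_volume_ml: float
    nawm_volume_ml: float
    icv_ml: float | None = None
    wmh_pct_icv: float | None = None
    wmh_intense_volume_ml: float | None = None
    wmh_less_intense_volume_ml: float | None = None
    sequence_used: str = "FLAIR"
    valid: bool = True


def wm_damage(
    stats_wmh: IntensityStats | None,
    stats_nawm: IntensityStats,
    vol_wmh_ml: float,
    vol_nawm_ml: float,
    sequence_used: str = "FLAIR",
) -> WMDamageResult:
    """Compute the WM damage metric from compartment statistics and volumes.

    Parameters
    ----------
    stats_wmh
        Intensity statistics over the (whole) WMH mask; may be None when
        ``vol_wmh_ml`` is 0, in which case the metric is 0 by definition.
    stats_nawm
        Intensity statistics over the NAWM mask; the mean must be positive.
    vol_wmh_ml, vol_nawm_ml
        Compartment volumes in ml.  NAWM volume must be positive.
    """
    if vol_nawm_ml <= 0:
        raise ValueError("NAWM volume must be positive")
    if vol_wmh_ml < 0:
        raise ValueError("WMH volume cannot be negative")
    if stats_nawm.mean <= 0:
        raise ValueError(
            f"NAWM mean intensity must be positive (got {stats_nawm.mean}); "
            "the contrast ratio is undefined otherwise"
        )

    if vol_wmh_ml == 0:
        # defined as zero in the absence of WMH
        return WMDamageResult(
            wm_damage=0.0,
            contrast_term=0.0,
            proportion_term=0.0,
            wmh_volume_ml=0.0,
            nawm_volume_ml=float(vol_nawm_ml),
            sequence_used=sequence_used,
        )

    if stats_wmh is None:
        raise ValueError("stats_wmh is required when the WMH volume is positive")

    contrast = (stats_wmh.mean - stats_nawm.mean) / stats_nawm.mean
    proportion = vol_wmh_ml / (vol_wmh_ml + vol_nawm_ml)
    value = contrast * proportion
    return WMDamageResult(
        wm_damage=float(value),
        contrast_term=float(contrast),
        proportion_term=float(proportion),
        wmh_volume_ml=float(vol_wmh_ml),
        nawm_volume_ml=float(vol_nawm_ml),
        sequence_used=sequence_used,
        valid=bool(contrast >= 0),
    )


def wm_damage_from_masks(
    scan: MultiSequenceScan,
    masks: TissueMaskSet,
    sequence: str = "flair",
) -> WMDamageResult:
    """End-to-end metric on a scan + validated mask set.

    Intensities are read from ``sequence`` (``"flair"`` default, ``"t2w"``
    optional).  When intense/less-intense compartments are present, I_WMH is
    computed on their union (``wmh_total``), i.e. the volume-weighted mean.
    Masks are used exactly as given; this module never resamples.
    """
    sequence = sequence.lower()
    if sequence not in ("flair", "t2w"):
        raise ValueError("sequence must be 'flair' or 't2w'")
    volume = scan.flair if sequence == "flair" else scan.t2w
    if volume is None:
        raise ValueError("scan has no T2W volume")
    if volume.shape != masks.icv.shape:
        raise GridMismatchError(
            f"scan grid {volume.shape} != mask grid {masks.icv.shape}"
        )

    nawm_stats = intensity_stats(volume, masks.nawm)
    n_wmh = int(masks.wmh_total.sum())
    vol_wmh = voxels_to_ml(n_wmh, scan.voxel_dims)
    vol_nawm = voxels_to_ml(int(masks.nawm.sum()), scan.voxel_dims)
    wmh_stats = intensity_stats(volume, masks.wmh_total) if n_wmh else None

    result = wm_damage(
        wmh_stats, nawm_stats, vol_wmh, vol_nawm,
        sequence_used=sequence.upper().replace("T2W", "T2W"),
    )
    result.icv_ml = voxels_to_ml(int(masks.icv.sum()), scan.voxel_dims)
    result.wmh_pct_icv = pct_icv(result.wmh_volume_ml, result.icv_ml)
    if masks.wmh_intense is not None:
        result.wmh_intense_volume_ml = voxels_to_ml(
            int(masks.wmh_intense.sum()), scan.voxel_dims
        )
        result.wmh_less_intense_volume_ml = voxels_to_ml(
            int(masks.wmh_less_intense.sum()), scan.voxel_dims
        )
    return result


def pct_icv(vol_ml: float, icv_ml: float) -> float:
    """Head-size-normalised volume: 100 · vol / ICV (percent)."""
    if icv_ml <= 0:
        raise ValueError("ICV must be positive")
    if vol_ml < 0:
        raise ValueError("volume cannot be negative")
    if vol_ml > icv_ml:
        import warnings

        warnings.warn(
            f"volume {vol_ml} ml exceeds ICV {icv_ml} ml", stacklevel=2
        )
    return 100.0 * vol_ml / icv_ml


# ---------------------------------------------------------------------------
# Longitudinal change
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalChange:
    """WMH change between two co-registered timepoints.

    ``volume_change_ml`` is the numeric difference of compartment volumes
    (follow-up − baseline).  The spatial fields come from mask subtraction:
    ``new_ml`` is tissue labelled WMH only at follow-up, ``vanished_ml``
    only at baseline, and ``net_spatial_change_ml`` their difference, which
    equals the volume difference of the same two masks exactly.
    """

    volume_change_ml: float
    new_ml: float | None = None
    vanished_ml: float | None = None
    net_spatial_change_ml: float | None = None
    wm_damage_change: float | None = None


def volume_change(baseline_ml: float, followup_ml: float) -> float:
    """Numeric volume change: follow-up minus baseline, in ml."""
    for v in (baseline_ml, followup_ml):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"volumes must be finite and non-negative, got {v}")
    return float(followup_ml) - float(baseline_ml)


def spatial_change(
    mask_baseline: np.ndarray,
    mask_followup: np.ndarray,
    voxel_dims: tuple[float, float, float],
) -> LongitudinalChange:
    """WMH change from subtraction of co-registered baseline/follow-up masks."""
    mask_baseline = np.asarray(mask_baseline).astype(bool)
    mask_followup = np.asarray(mask_followup).astype(bool)
    if mask_baseline.shape != mask_followup.shape:
        raise GridMismatchError(
            f"baseline grid {mask_baseline.shape} != follow-up grid {mask_followup.shape}"
        )
    new = voxels_to_ml(int(np.sum(mask_followup & ~mask_baseline)), voxel_dims)
    vanished = voxels_to_ml(int(np.sum(mask_baseline & ~mask_followup)), voxel_dims)
    vol_change = voxels_to_ml(int(mask_followup.sum()), voxel_dims) - voxels_to_ml(
        int(mask_baseline.sum()), voxel_dims
    )
    return LongitudinalChange(
        volume_change_ml=vol_change,
        new_ml=new,
        vanished_ml=vanished,
        net_spatial_change_ml=new - vanished,
    )
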