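"""NAWM / WMH segmentation by three routes.

1. **Colour fusion + minimum-variance quantisation** ("MCMxxxVI" style):
   two sequences are min-max normalised within the brain mask and mapped to
   the red and green channels of a fused colour image; the fused colours are
   partitioned into k levels by a variance-minimising quantiser (greedy
   optimal binary splits refined by Lloyd iterations); levels are then assigned to
   WM and WMH by a centroid rule — WMH levels are those whose green (FLAIR /
   T2-driven) centroid exceeds the WM level's by a margin, and the
   highest-green level among them is the *intense* compartment.  The original
   method's level selection is operator-guided; the centroid rule here is a
   deterministic stand-in, not claimed equivalent.

2. **Multispectral Gaussian clustering**: a k-component Gaussian mixture
   (EM, diagonal covariances) on the per-voxel feature vectors formed by
   concatenating the normalised brain-extracted sequences; the component
   with the most WM-like profile provides the NAWM prior.

3. **FLAIR histogram thresholding**: WMH are FLAIR voxels at least
   ``k_sd`` NAWM standard deviations above the NAWM mean — the conventional
   operational definition of hyperintensity (default k_sd = 3).  A second
   threshold at ``k_sd_intense`` (default 5) splits intense from
   less-intense lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .imaging_io import GridMismatchError, MultiSequenceScan, TissueMaskSet
from .metric import IntensityStats, intensity_stats

__all__ = [
    "FusedColourImage",
    "QuantisationResult",
    "LevelSelectionRules",
    "GaussianClusterResult",
    "fuse_rg",
    "minimum_variance_quantise",
    "select_tissue_levels",
    "gaussian_cluster",
    "flair_histogram_threshold",
    "split_intense_less",
    "segment_mcmxxxvi",
    "segment_cluster_threshold",
    "dice",
]


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ValueError("volume is constant within the mask; min-max normalisation undefined")
    return (values - lo) / (hi - lo)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(a & b)) / denom


# ---------------------------------------------------------------------------
# Route 1: red-green colour fusion + minimum-variance quantisation
# ---------------------------------------------------------------------------

@dataclass
class FusedColourImage:
    """Two sequences fused into red/green channels within a brain mask.

    Channels are min-max normalised over the mask, so each spans [0, 1]
    within it; voxels outside the mask carry no colour information.
    """

    red: np.ndarray
    green: np.ndarray
    mask: np.ndarray
    source_pair: str = ""

    def colours(self) -> np.ndarray:
        """(n_voxels, 2) array of in-mask RG colours, in mask scan order."""
        return np.column_stack([self.red[self.mask], self.green[self.mask]])


def fuse_rg(
    vol_a: np.ndarray,
    vol_b: np.ndarray,
    brain_mask: np.ndarray,
    source_pair: str = "",
) -> FusedColourImage:
    """Fuse two co-registered volumes into red (vol_a) / green (vol_b).

    Each volume is independently min-max normalised within ``brain_mask``.
    Raises if either volume is constant within the mask (normalisation
    undefined) or if the mask is empty.
    """
    vol_a = np.asarray(vol_a, dtype=float)
    vol_b = np.asarray(vol_b, dtype=float)
    brain_mask = np.asarray(brain_mask).astype(bool)
    if vol_a.shape != vol_b.shape or vol_a.shape != brain_mask.shape:
        raise GridMismatchError("fuse_rg inputs must share one grid")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    red = np.zeros_like(vol_a)
    green = np.zeros_like(vol_b)
    red[brain_mask] = _minmax(vol_a[brain_mask])
    green[brain_mask] = _minmax(vol_b[brain_mask])
    return FusedColourImage(red=red, green=green, mask=brain_mask, source_pair=source_pair)


@dataclass
class QuantisationResult:
    """A k-level partition of the fused RG colours.

    ``labels`` holds the level index (0..k-1) for every in-mask voxel and
    −1 elsewhere; ``centroids`` are the level means in RG space;
    ``within_variance`` is the total within-level sum of squared deviations
    over both channels.
    """

    labels: np.ndarray
    centroids: np.ndarray
    within_variance: float
    mask: np.ndarray

    @property
    def k(self) -> int:
        return len(self.centroids)

    def level_mask(self, level: int) -> np.ndarray:
        return self.labels == level

    def level_counts(self) -> np.ndarray:
        return np.bincount(self.labels[self.mask], minlength=self.k)


def _best_split(pts: np.ndarray):
    """Best axis-aligned variance-minimising split of a point set.

    For each dimension, sort the points and use prefix sums to find the cut
    that minimises the summed within-part SSE.  Returns (sse_reduction,
    dim, threshold) or None when the set has a single distinct point.
    """
    n, d = pts.shape
    total_sse = float(((pts - pts.mean(axis=0)) ** 2).sum())
    best = None
    for dim in range(d):
        order = np.argsort(pts[:, dim], kind="stable")
        s = pts[order]
        vals = s[:, dim]
        csum = np.cumsum(s, axis=0)
        csq = np.cumsum(s**2, axis=0)
        idx = np.arange(1, n)
        # SSE of s[:i] plus SSE of s[i:] for every cut position i
        left = (csq[:-1] - csum[:-1] ** 2 / idx[:, None]).sum(axis=1)
        nr = n - idx
        rsum = csum[-1] - csum[:-1]
        rsq = csq[-1] - csq[:-1]
        right = (rsq - rsum**2 / nr[:, None]).sum(axis=1)
        valid = vals[1:] > vals[:-1]  # cut only between distinct values
        if not valid.any():
            continue
        sse = np.where(valid, left + right, np.inf)
        i = int(np.argmin(sse))
        reduction = total_sse - float(sse[i])
        if best is None or reduction > best[0]:
            best = (reduction, dim, float((vals[i] + vals[i + 1]) / 2.0))
    return best


def _variance_cut(colours: np.ndarray, k: int) -> np.ndarray:
    """Initial centroids by greedy variance-minimising binary splits:
    repeatedly apply, to whichever box offers it, the axis-aligned cut with
    the largest reduction in total within-box SSE."""
    boxes = [np.arange(len(colours))]
    splits = [_best_split(colours)]
    while len(boxes) < k:
        candidates = [i for i, s in enumerate(splits) if s is not None]
        if not candidates:
            raise ValueError("fewer distinct colours than requested levels")
        bi = max(candidates, key=lambda i: splits[i][0])
        idx = boxes[bi]
        _, dim, threshold = splits[bi]
        left = idx[colours[idx, dim] <= threshold]
        right = idx[colours[idx, dim] > threshold]
        boxes[bi] = left
        boxes.append(right)
        splits[bi] = _best_split(colours[left])
        splits.append(_best_split(colours[right]))
    return np.array([colours[b].mean(axis=0) for b in boxes])


def minimum_variance_quantise(
    img: FusedColourImage, k: int, max_iter: int = 100
) -> QuantisationResult:
    """Partition the fused RG colours into k levels of minimum variance.

    Greedy variance-cut initialisation (repeated optimal axis-aligned
    binary splits) followed by Lloyd refinement (assign each colour to its
    nearest centroid, recompute centroids) until the assignment is stable.
    Deterministic: no random initialisation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    colours = img.colours()
    n_distinct = len(np.unique(colours, axis=0))
    if n_distinct < k:
        raise ValueError(
            f"requested {k} levels but the image has only {n_distinct} distinct colours"
        )
    centroids = _variance_cut(colours, k)
    labels = None
    for _ in range(max_iter):
        d2 = ((colours[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            sel = labels == j
            if sel.any():
                centroids[j] = colours[sel].mean(axis=0)
    within = float(((colours - centroids[labels]) ** 2).sum())
    full = np.full(img.mask.shape, -1, dtype=int)
    full[img.mask] = labels
    return QuantisationResult(
        labels=full, centroids=centroids, within_variance=within, mask=img.mask
    )


@dataclass(frozen=True)
class LevelSelectionRules:
    """Centroid rules mapping quantised levels to tissues.

    WM is anchored at the most populous level (white matter dominates the
    brain mask once cortex and extra-axial CSF are excluded); any level
    whose centroid lies within ``margin`` of the anchor in both channels is
    also WM — a variance-minimising quantiser happily splits a large
    homogeneous tissue into near-identical levels, and those fragments must
    be reunited.  WMH levels are those whose green (FLAIR/T2-driven)
    centroid exceeds the anchor's by more than ``margin``; the single
    highest-green WMH level is *intense*, the rest *less intense*.
    """

    margin: float = 0.1


def select_tissue_levels(
    quant: QuantisationResult,
    img: FusedColourImage,
    rules: LevelSelectionRules = LevelSelectionRules(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign quantised levels to (wm, wmh_intense, wmh_less_intense) masks."""
    counts = quant.level_counts()
    if counts.sum() == 0:
        raise ValueError("no level qualifies as WM: quantisation covers no voxels")
    wm_level = int(np.argmax(counts))
    wm_green = quant.centroids[wm_level, 1]
    wmh_levels = [
        j for j in range(quant.k)
        if j != wm_level and quant.centroids[j, 1] > wm_green + rules.margin
    ]
    wm_levels = [
        j for j in range(quant.k)
        if j not in wmh_levels
        and np.max(np.abs(quant.centroids[j] - quant.centroids[wm_level])) <= rules.margin
    ]
    wm = np.isin(quant.labels, wm_levels) & quant.mask
    intense = np.zeros_like(wm)
    less = np.zeros_like(wm)
    if wmh_levels:
        intense_level = max(wmh_levels, key=lambda j: quant.centroids[j, 1])
        intense = quant.level_mask(intense_level)
        for j in wmh_levels:
            if j != intense_level:
                less |= quant.level_mask(j)
    return wm, intense, less


# ---------------------------------------------------------------------------
# Route 2: multispectral Gaussian mixture clustering
# ---------------------------------------------------------------------------

@dataclass
class GaussianClusterResult:
    """EM-fitted Gaussian-mixture tissue classification.

    ``labels`` is the hard assignment (−1 outside the mask); ``posteriors``
    has shape (k, *grid) and sums to 1 over components at every in-mask
    voxel.  ``nawm_label`` designates the component with the most WM-like
    profile; ``nawm_labels`` additionally absorbs components whose mean
    profile is indistinguishable from it (EM over-segments a large
    homogeneous tissue into near-duplicate components); ``nawm_mask`` is
    the hard-assignment mask of that union.
    """

    labels: np.ndarray
    posteriors: np.ndarray
    means: np.ndarray
    weights: np.ndarray
    nawm_label: int
    nawm_labels: tuple[int, ...]
    channel_names: tuple[str, ...]
    mask: np.ndarray

    @property
    def nawm_mask(self) -> np.ndarray:
        return np.isin(self.labels, self.nawm_labels) & self.mask


def gaussian_cluster(
    channels: dict[str, np.ndarray],
    brain_mask: np.ndarray,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    merge_tol: float = 0.1,
) -> GaussianClusterResult:
    """Cluster per-voxel multispectral feature vectors with a k-GMM.

    Each channel is min-max normalised within the mask before stacking.
    Diagonal covariances; ``n_restarts`` k-means-seeded EM starts, keeping
    the best; deterministic given ``seed``.  The NAWM component is the one
    with the highest T1-weighted mean when a ``t1w`` channel is present
    (white matter is T1-bright), otherwise the highest-weight component.
    """
    if not channels:
        raise ValueError("at least one channel is required")
    if k < 2:
        raise ValueError("k must be >= 2")
    brain_mask = np.asarray(brain_mask).astype(bool)
    n_voxels = int(brain_mask.sum())
    if n_voxels < 10 * k:
        raise ValueError(f"mask has {n_voxels} voxels; need at least {10 * k}")
    names = tuple(channels)
    feats = np.column_stack(
        [_minmax(np.asarray(channels[n], dtype=float)[brain_mask]) for n in names]
    )

    gmm = None
    for attempt in range(3):
        candidate = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=n_restarts,
            tol=tol,
            reg_covar=1e-6,
            random_state=seed + attempt,
            max_iter=300,
        ).fit(feats)
        if candidate.converged_ and np.all(candidate.weights_ > 1e-8):
            gmm = candidate
            break
    if gmm is None:
        raise RuntimeError(
            "EM failed to converge without component collapse after 3 restart rounds"
        )

    post = gmm.predict_proba(feats)
    hard = np.argmax(post, axis=1)
    labels = np.full(brain_mask.shape, -1, dtype=int)
    labels[brain_mask] = hard
    posteriors = np.zeros((k,) + brain_mask.shape, dtype=float)
    for j in range(k):
        posteriors[j][brain_mask] = post[:, j]

    if "t1w" in names:
        nawm_label = int(np.argmax(gmm.means_[:, names.index("t1w")]))
    else:
        nawm_label = int(np.argmax(gmm.weights_))
    # reunite components that are near-duplicates of the NAWM profile
    dist = np.max(np.abs(gmm.means_ - gmm.means_[nawm_label]), axis=1)
    nawm_labels = tuple(int(j) for j in np.flatnonzero(dist <= merge_tol))
    return GaussianClusterResult(
        labels=labels,
        posteriors=posteriors,
        means=gmm.means_,
        weights=gmm.weights_,
        nawm_label=nawm_label,
        nawm_labels=nawm_labels,
        channel_names=names,
        mask=brain_mask,
    )


# ---------------------------------------------------------------------------
# Route 3: FLAIR histogram thresholding
# ---------------------------------------------------------------------------

def flair_histogram_threshold(
    flair: np.ndarray,
    brain_mask: np.ndarray,
    nawm_stats: IntensityStats,
    k_sd: float = 3.0,
    exclusion: np.ndarray | None = None,
) -> np.ndarray:
    """WMH mask: in-mask FLAIR voxels at least k_sd NAWM SDs above the mean.

    The comparison is inclusive (≥) except when the margin ``k_sd·SD`` is
    zero — there the threshold degenerates to the NAWM mean itself and an
    inclusive comparison would label all of NAWM as lesion, so a strict
    comparison is used (with a warning; a zero SD almost always means a
    noiseless synthetic input).
    """
    flair = np.asarray(flair, dtype=float)
    brain_mask = np.asarray(brain_mask).astype(bool)
    if flair.shape != brain_mask.shape:
        raise GridMismatchError("flair and brain_mask grids differ")
    threshold = nawm_stats.mean + k_sd * nawm_stats.sd
    if k_sd > 0 and nawm_stats.sd == 0:
        warnings.warn(
            "NAWM SD is 0: the WMH threshold equals the NAWM mean "
            "(noiseless synthetic input?); using a strict comparison",
            stacklevel=2,
        )
    if k_sd * nawm_stats.sd == 0:
        mask = (flair > threshold) & brain_mask
    else:
        mask = (flair >= threshold) & brain_mask
    if exclusion is not None:
        mask &= ~np.asarray(exclusion).astype(bool)
    return mask


def split_intense_less(
    flair: np.ndarray,
    wmh_mask: np.ndarray,
    nawm_stats: IntensityStats,
    k_sd_intense: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a WMH mask at a second threshold mean + k_sd_intense·SD."""
    flair = np.asarray(flair, dtype=float)
    wmh_mask = np.asarray(wmh_mask).astype(bool)
    threshold = nawm_stats.mean + k_sd_intense * nawm_stats.sd
    if k_sd_intense * nawm_stats.sd == 0:
        intense = (flair > threshold) & wmh_mask
    else:
        intense = (flair >= threshold) & wmh_mask
    return intense, wmh_mask & ~intense


# ---------------------------------------------------------------------------
# End-to-end pipelines
# ---------------------------------------------------------------------------

def segment_mcmxxxvi(
    scan: MultiSequenceScan,
    brain_mask: np.ndarray,
    k: int = 4,
    rules: LevelSelectionRules = LevelSelectionRules(),
) -> TissueMaskSet:
    """Colour-fusion segmentation: fuse T2*W (red) with FLAIR (green),
    quantise, select WM/WMH levels.  ``brain_mask`` should already exclude
    the cortex (WMH are sought in brain tissue excluding the cortex)."""
    if scan.t2star is None:
        raise ValueError("the colour-fusion route requires a T2*W volume")
    fused = fuse_rg(scan.t2star, scan.flair, brain_mask, source_pair="T2*+FLAIR")
    quant = minimum_variance_quantise(fused, k)
    wm, intense, less = select_tissue_levels(quant, fused, rules)
    return TissueMaskSet(
        icv=brain_mask,
        nawm=wm,
        wmh_total=intense | less,
        wmh_intense=intense,
        wmh_less_intense=less,
    )


def segment_cluster_threshold(
    scan: MultiSequenceScan,
    brain_mask: np.ndarray,
    k: int = 4,
    k_sd: float = 3.0,
    k_sd_intense: float = 5.0,
    seed: int = 0,
) -> TissueMaskSet:
    """Clustering + thresholding pipeline: a k-class multispectral Gaussian
    mixture provides the NAWM prior; its intensity statistics set the FLAIR
    hyperintensity threshold; NAWM is the prior minus the detected WMH."""
    cluster = gaussian_cluster(scan.channels(), brain_mask, k=k, seed=seed)
    nawm_prior = cluster.nawm_mask
    stats = intensity_stats(scan.flair, nawm_prior)
    wmh = flair_histogram_threshold(scan.flair, brain_mask, stats, k_sd=k_sd)
    intense, less = split_intense_less(scan.flair, wmh, stats, k_sd_intense=k_sd_intense)
    return TissueMaskSet(
        icv=brain_mask,
        nawm=nawm_prior & ~wmh,
        wmh_total=wmh,
        wmh_intense=intense,
        wmh_less_intense=less,
    )
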