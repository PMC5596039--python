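"""Visual-rating scales and their total scores.

Three clinical scales are supported:

* **Fazekas** — WMH burden rated 0–3 separately for periventricular and
  deep white matter; the total is their sum (0–6).
* **Prins** — perceived WMH *change* between two timepoints, −1/0/+1 in
  three periventricular and four deep regions per hemisphere (14 items);
  the total ranges −14..14.
* **SVD score** — one point for each of four small-vessel-disease features
  (WMH burden, lacunes, microbleeds, enlarged perivascular spaces), total
  0–4.  The WMH point is awarded for periventricular Fazekas 3 or deep
  Fazekas ≥ 2 (the Staals 2014 convention, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "FazekasRating",
    "PrinsRating",
    "SVDRating",
    "total_fazekas",
    "total_prins",
    "total_svd",
    "svd_wmh_point",
    "totals_from_table",
    "PRINS_REGIONS",
]

#: Prins item labels: 3 periventricular + 4 deep regions per hemisphere.
PRINS_REGIONS: tuple[str, ...] = tuple(
    f"{side}_{region}"
    for side in ("left", "right")
    for region in (
        "pv_frontal", "pv_bands", "pv_occipital",
        "deep_frontal", "deep_parietal", "deep_temporal", "deep_occipital",
    )
)


@dataclass(frozen=True)
class FazekasRating:
    periventricular: int
    deep: int

    def __post_init__(self) -> None:
        for name in ("periventricular", "deep"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3):
                raise ValueError(f"Fazekas {name} score must be in 0..3, got {v!r}")


@dataclass(frozen=True)
class PrinsRating:
    """Per-region WMH change scores; exactly 14 items, each in {−1, 0, +1}."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != len(PRINS_REGIONS):
            raise ValueError(
                f"Prins rating needs {len(PRINS_REGIONS)} items, got {len(self.items)}"
            )
        for v in self.items:
            if v not in (-1, 0, 1):
                raise ValueError(f"Prins item must be in {{-1,0,1}}, got {v!r}")


@dataclass(frozen=True)
class SVDRating:
    """Binary presence of the four SVD features."""

    wmh: int
    lacunes: int
    microbleeds: int
    perivascular_spaces: int

    def __post_init__(self) -> None:
        for name in ("wmh", "lacunes", "microbleeds", "perivascular_spaces"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"SVD item {name} must be 0 or 1, got {v!r}")


def total_fazekas(r: FazekasRating) -> int:
    """Total Fazekas score: periventricular + deep, range 0–6."""
    return r.periventricular + r.deep


def total_prins(r: PrinsRating) -> int:
    """Total Prins change score: sum of the 14 items, range −14..14."""
    return sum(r.items)


def total_svd(r: SVDRating) -> int:
    """Total SVD burden score: number of features present, range 0–4."""
    return r.wmh + r.lacunes + r.microbleeds + r.perivascular_spaces


def svd_wmh_point(fazekas: FazekasRating, pv_threshold: int = 3, deep_threshold: int = 2) -> int:
    """The WMH item of the SVD score from a Fazekas rating.

    Awarded when periventricular Fazekas reaches ``pv_threshold`` (default
    3) or deep Fazekas reaches ``deep_threshold`` (default 2).
    """
    return int(fazekas.periventricular >= pv_threshold or fazekas.deep >= deep_threshold)


def totals_from_table(df: pd.DataFrame) -> pd.DataFrame:
    """Compute every total score available from a tidy ratings table.

    One row per subject/timepoint.  Recognised columns: ``fazekas_pv`` and
    ``fazekas_deep``; the 14 ``prins_<region>`` columns named after
    :data:`PRINS_REGIONS`; ``svd_wmh``, ``svd_lacunes``, ``svd_microbleeds``,
    ``svd_perivascular_spaces``.  Returns the identifying columns plus one
    column per computable total.
    """
    id_cols = [c for c in ("subject_id", "timepoint") if c in df.columns]
    out = df[id_cols].copy() if id_cols else pd.DataFrame(index=df.index)
    if {"fazekas_pv", "fazekas_deep"} <= set(df.columns):
        out["total_fazekas"] = [
            total_fazekas(FazekasRating(int(pv), int(dp)))
            for pv, dp in zip(df["fazekas_pv"], df["fazekas_deep"])
        ]
    prins_cols = [f"prins_{r}" for r in PRINS_REGIONS]
    if set(prins_cols) <= set(df.columns):
        out["total_prins"] = [
            total_prins(PrinsRating(tuple(int(v) for v in row)))
            for row in df[prins_cols].itertuples(index=False)
        ]
    svd_cols = ["svd_wmh", "svd_lacunes", "svd_microbleeds", "svd_perivascular_spaces"]
    if set(svd_cols) <= set(df.columns):
        out["total_svd"] = [
            total_svd(SVDRating(*(int(v) for v in row)))
            for row in df[svd_cols].itertuples(index=False)
        ]
    if out.shape[1] == len(id_cols):
        raise ValueError(
            "no recognised rating columns found; expected fazekas_pv/fazekas_deep, "
            "prins_<region>, or svd_* columns"
        )
    return out
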