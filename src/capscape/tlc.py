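"""Densitometric normalisation of 2D-TLC spot intensities.

After pyrophosphatase cleavage and radiolabelling, each 5' cap species
appears as one spot per plate.  Spot intensities are background-subtracted
and expressed as a percentage of the total intensity of all quantified
(non-saturated) spots on the same plate, then summarised over replicates.
Spotting origins saturate the detector and are excluded from both numerator
and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TLC_FRACTIONS",
    "SpotMeasurement",
    "normalize_plate",
    "normalize_plates",
    "replicate_summary",
]

#: Gel size-fraction vocabulary (nt) for TLC plates.
TLC_FRACTIONS = ("<50", "50-100", "100-200")

SPOT_COLUMNS = [
    "plate_id",
    "replicate_id",
    "fraction",
    "spot_label",
    "raw_intensity",
    "background",
    "saturated",
]


@dataclass(frozen=True)
class SpotMeasurement:
    """One quantified TLC spot."""

    plate_id: str
    replicate_id: str
    fraction: str
    spot_label: str
    raw_intensity: float
    background: float = 0.0
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.raw_intensity < 0 or self.background < 0:
            raise ValueError("intensities and backgrounds must be non-negative")


def normalize_plate(spots: pd.DataFrame | list[SpotMeasurement]) -> pd.DataFrame:
    """Percentages of total background-subtracted intensity for one plate.

    Saturated spots are excluded entirely; background-subtracted values
    below zero clamp to 0 with a warning.  Raises if nothing positive
    remains on the plate.
    """
    df = _as_frame(spots)
    if df["plate_id"].nunique() > 1:
        raise ValueError("normalize_plate expects spots from a single plate")
    return _normalize_one(df)


def normalize_plates(spots: pd.DataFrame | list[SpotMeasurement]) -> pd.DataFrame:
    """Apply per-plate normalisation across a table of many plates."""
    df = _as_frame(spots)
    parts = [_normalize_one(g) for _, g in df.groupby("plate_id", sort=True)]
    return pd.concat(parts, ignore_index=True)


def _as_frame(spots) -> pd.DataFrame:
    if isinstance(spots, pd.DataFrame):
        df = spots.copy()
    else:
        df = pd.DataFrame([s.__dict__ for s in spots])
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    return df


def _normalize_one(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    quant = df[~df["saturated"].astype(bool)].copy()
    signal = quant["raw_intensity"] - quant["background"]
    if (signal < 0).any():
        neg = quant.loc[signal < 0, "spot_label"].tolist()
        warnings.warn(
            f"plate {df['plate_id'].iloc[0]!r}: negative background-subtracted "
            f"intensity clamped to 0 for spots {neg}",
            stacklevel=3,
        )
    signal = signal.clip(lower=0.0)
    total = signal.sum()
    if total <= 0:
        raise ValueError(
            f"plate {df['plate_id'].iloc[0]!r} has no positive intensity after "
            "background subtraction"
        )
    df["pct"] = np.nan
    df.loc[quant.index, "pct"] = 100.0 * signal / total
    return df.reset_index(drop=True)


def replicate_summary(normalized: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD and replicate count per (fraction, spot).

    The SD uses the n-1 denominator and is 0 for a single replicate; a spot
    missing from some replicates is summarised over the replicates where it
    was measured (absent, not zero).
    """
    quant = normalized.dropna(subset=["pct"])
    g = quant.groupby(["fraction", "spot_label"], sort=True)["pct"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
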