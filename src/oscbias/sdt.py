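"""Signal-detection computations and SOA binning.

In the dichotic 2AFC design the "signal" axis runs left→right: the hit
rate is P(respond R | target R) and the false-alarm rate is
P(respond R | target L).  Sensitivity and criterion follow the standard
equal-variance Gaussian model,

    d' = (z(H_right) - z(FA_left)) / denom        (denom = 2 by default)
    c  = -0.5 * (z(H_right) + z(FA_left))

so positive criterion means a leftward response tendency.  Time courses are
built by pooling trials into contiguous 10-ms SOA bins across the 0.2-1.2 s
target window and computing one (d', c) point per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trials import Dataset

Measure = Literal["sensitivity", "criterion"]


@dataclass(frozen=True)
class RatePair:
    """Hit/false-alarm proportions with the trial counts they came from."""

    hit_right: float
    fa_left: float
    n_right: int
    n_left: int


@dataclass(frozen=True)
class SDTPoint:
    dprime: float
    criterion: float


def corrected_z(p: float, n: int) -> float:
    """Inverse standard-normal of ``p`` after clamping to [1/(2n), 1 - 1/(2n)].

    The clamp keeps z finite for perfect proportions (0 or 1) while
    preserving monotonicity in ``p``.
    """
    if n < 1:
        raise ValueError("rate undefined: no trials in condition")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion out of range: {p}")
    lo = 1.0 / (2.0 * n)
    return float(norm.ppf(np.clip(p, lo, 1.0 - lo)))


def sdt_point(r: RatePair, denom: float = 2.0) -> SDTPoint:
    """Sensitivity and criterion from a hit/false-alarm rate pair."""
    zh = corrected_z(r.hit_right, r.n_right)
    zf = corrected_z(r.fa_left, r.n_left)
    return SDTPoint(dprime=(zh - zf) / denom, criterion=-0.5 * (zh + zf))


@dataclass
class BinnedSeries:
    """SOA-binned time course of d' or criterion.

    Bins are half-open ``[left, right)`` and contiguous over the window;
    ``defined`` flags bins with at least one trial in each target condition.
    Undefined bins carry NaN values and are skipped by downstream fitters.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    n_left: np.ndarray
    n_right: np.ndarray
    defined: np.ndarray
    measure: str
    window: tuple[float, float]
    detrended: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_s": self.bin_centers,
                "value": self.values,
                "n_left": self.n_left,
                "n_right": self.n_right,
                "defined": self.defined,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def _series_from_counts(
    centers: np.ndarray,
    n_r: np.ndarray,
    hit_r: np.ndarray,
    n_l: np.ndarray,
    fa_l: np.ndarray,
    measure: str,
    window: tuple[float, float],
    denom: float,
) -> BinnedSeries:
    """Vectorized bin-wise SDT from per-bin counts (shared with permutation engines)."""
    defined = (n_r > 0) & (n_l > 0)
    zh = np.full(len(centers), np.nan)
    zf = np.full(len(centers), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(defined, hit_r / np.maximum(n_r, 1), np.nan)
        f = np.where(defined, fa_l / np.maximum(n_l, 1), np.nan)
        lo_r = 1.0 / (2.0 * np.maximum(n_r, 1))
        lo_l = 1.0 / (2.0 * np.maximum(n_l, 1))
        zh[defined] = norm.ppf(np.clip(h, lo_r, 1 - lo_r))[defined]
        zf[defined] = norm.ppf(np.clip(f, lo_l, 1 - lo_l))[defined]
    if measure == "sensitivity":
        values = (zh - zf) / denom
    elif measure == "criterion":
        values = -0.5 * (zh + zf)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return BinnedSeries(
        bin_centers=centers,
        values=values,
        n_left=n_l.astype(int),
        n_right=n_r.astype(int),
        defined=defined,
        measure=measure,
        window=window,
    )


def bin_by_soa(
    d: Dataset,
    window: tuple[float, float] = (0.2, 1.2),
    n_bins: int = 100,
    measure: Measure = "criterion",
    denom: float = 2.0,
) -> BinnedSeries:
    """Pool valid trials into SOA bins and compute one SDT point per bin.

    With the defaults this yields one hundred 10-ms bins over the 0.2-1.2 s
    target window.  Bins are half-open, so a trial at SOA 0.205 s falls in
    the first bin (center 0.205 s).
    """
    lo, hi = window
    df = d.valid_trials()
    soa = df["soa_s"].to_numpy(float)
    in_win = (soa >= lo) & (soa < hi)
    soa = soa[in_win]
    stim_r = (df["stim_ear"].to_numpy() == "R")[in_win]
    resp_r = (df["resp_ear"].to_numpy() == "R")[in_win]

    width = (hi - lo) / n_bins
    idx = np.floor((soa - lo) / width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guard float roundoff at the right edge
    centers = lo + width * (np.arange(n_bins) + 0.5)

    n_r = np.bincount(idx, weights=stim_r, minlength=n_bins)
    hit_r = np.bincount(idx, weights=stim_r & resp_r, minlength=n_bins)
    n_l = np.bincount(idx, weights=~stim_r, minlength=n_bins)
    fa_l = np.bincount(idx, weights=(~stim_r) & resp_r, minlength=n_bins)
    return _series_from_counts(centers, n_r, hit_r, n_l, fa_l, measure, window, denom)


def detrend(s: BinnedSeries, order: int | None = 2) -> BinnedSeries:
    """Subtract a least-squares polynomial trend from a binned series.

    Sensitivity time courses carry a slow non-oscillatory drift that is
    removed (default: 2nd-order polynomial) before sinusoid fitting;
    criterion series are analyzed raw (``order=None`` is the identity).
    """
    if order is None:
        return s
    ok = s.defined & np.isfinite(s.values)
    if ok.sum() < order + 2:
        raise ValueError("too few defined bins to detrend")
    t = s.bin_centers[ok]
    y = s.values[ok]
    coef = np.polynomial.polynomial.polyfit(t, y, order)
    resid = np.full_like(s.values, np.nan)
    resid[ok] = y - np.polynomial.polynomial.polyval(t, coef)
    out = replace(s, values=resid, detrended=True)
    return out
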