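"""Discrete cell-cycle staging from DNA and Geminin intensities.

Cells are partitioned by integrated DNA into G1 (2N), S (2N-4N) and G2+M
(4N); the 2N class is subdivided by log-Geminin into early G1 (baseline
reporter) and the G1/S transition (accumulating reporter). Thresholds are
detected automatically from the marginal distributions: density valleys of
a 1-D kernel density estimate between the two largest DNA modes, and the
valley (or a robust baseline-mode + 3*MAD fallback) of log-Geminin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelextrema, find_peaks

__all__ = ["StagingError", "StageThresholds", "detect_thresholds", "assign_stage", "STAGES"]

STAGES = ("G1", "G1/S", "S", "G2+M")

_GRID = 1024
_MIN_CELLS = 500


class StagingError(ValueError):
    pass


@dataclass(frozen=True)
class StageThresholds:
    """DNA cuts flanking the 2N / 4N modes and the log-Geminin cut.

    ``geminin_log_cut`` is ``nan`` when Geminin carries no signal; the 2N
    class is then not subdivided (early G1 and G1/S merged as "G1").
    """

    dna_2n_upper: float
    dna_4n_lower: float
    geminin_log_cut: float

    def __post_init__(self):
        if not (np.isfinite(self.dna_2n_upper) and np.isfinite(self.dna_4n_lower)):
            raise StagingError("DNA thresholds must be finite")
        if self.dna_2n_upper > self.dna_4n_lower:
            raise StagingError("dna_2n_upper must not exceed dna_4n_lower")

    @property
    def geminin_available(self) -> bool:
        return np.isfinite(self.geminin_log_cut)


def _silverman_bw(x: np.ndarray) -> float:
    n = x.size
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(np.std(x), iqr / 1.34) if iqr > 0 else np.std(x)
    return 0.9 * scale * n ** (-0.2)


def _kde_grid(x: np.ndarray, n_grid: int = _GRID):
    """Binned Gaussian KDE with Silverman bandwidth on a regular grid."""
    bw = _silverman_bw(x)
    if bw <= 0:
        raise StagingError("degenerate intensity distribution (zero spread)")
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    grid = np.linspace(lo, hi, n_grid)
    step = grid[1] - grid[0]
    hist, _ = np.histogram(x, bins=n_grid, range=(lo, hi + step))
    dens = gaussian_filter1d(hist.astype(float), bw / step, mode="constant")
    dens /= dens.sum() * step
    return grid, dens


def _two_largest_modes(grid: np.ndarray, dens: np.ndarray, min_prominence: float = 0.012):
    """Indices of the two major modes (left to right), or None if unimodal.

    Modes are local maxima whose prominence exceeds ``min_prominence`` of
    the density maximum, which ignores minor interior bumps (e.g. mid-S
    DNA mass between the 2N and 4N peaks); the outermost two are returned.
    """
    peaks, props = find_peaks(dens, prominence=min_prominence * dens.max())
    if peaks.size < 2:
        return None
    return int(peaks[0]), int(peaks[-1])


def _interior_minima(dens: np.ndarray, i_lo: int, i_hi: int, order: int = 3) -> np.ndarray:
    """Local minima strictly between two mode indices.

    ``order`` sets the comparison window; valleys between the DNA modes are
    broad, so a bandwidth-scaled window suppresses sampling wiggles.
    """
    seg = dens[i_lo : i_hi + 1]
    (mins,) = argrelextrema(seg, np.less_equal, order=order)
    mins = mins[(mins > 0) & (mins < seg.size - 1)]
    if mins.size == 0:
        return np.array([i_lo + int(np.argmin(seg))])
    # collapse flat runs, keep one representative per valley
    keep = [mins[0]]
    for m in mins[1:]:
        if m - keep[-1] > order:
            keep.append(m)
        elif seg[m] < seg[keep[-1]]:
            keep[-1] = m
    return i_lo + np.asarray(keep)


def _dna_cuts(dna: np.ndarray):
    grid, dens = _kde_grid(dna)
    modes = _two_largest_modes(grid, dens)
    if modes is None:
        raise StagingError("cannot resolve 2N/4N: DNA distribution is not bimodal")
    i1, i2 = modes
    order = max(3, int(0.5 * _silverman_bw(dna) / (grid[1] - grid[0])))
    minima = _interior_minima(dens, i1, i2, order=order)
    if minima.size == 1:
        # a mid-S density bump implies a second (possibly shallow) valley
        # toward whichever mode the single minimum does not flank
        m0 = minima[0]
        for a, b, side in ((m0, i2, "hi"), (i1, m0, "lo")):
            if b - a < 3:
                continue
            interior = dens[a + 1 : b]
            bump = a + 1 + int(np.argmax(interior))
            if dens[bump] > 1.05 * dens[m0] and b - bump >= 2:
                other = bump + 1 + int(np.argmin(dens[bump + 1 : b]))
                pair = sorted([m0, other])
                return grid[pair[0]], grid[pair[1]]
        cut = grid[m0]
        return cut, cut
    # several valleys: deepest in each half flanks the corresponding mode;
    # ties (within 1% density) break toward the midpoint of the modes
    mid = (i1 + i2) // 2
    left = minima[minima <= mid]
    right = minima[minima >= mid]

    def deepest(cands, fallback):
        if cands.size == 0:
            return fallback
        d = dens[cands]
        best = d.min()
        tied = cands[d <= best * 1.01]
        return tied[np.argmin(np.abs(tied - mid))]

    lo = deepest(left, minima[0])
    hi = deepest(right, minima[-1])
    if lo > hi:
        lo = hi = minima[np.argmin(dens[minima])]
    return grid[lo], grid[hi]


def _geminin_cut(geminin: np.ndarray) -> float:
    positive = geminin[geminin > 0]
    if positive.size < 0.5 * geminin.size:
        return np.nan
    logg = np.log(positive)
    grid, dens = _kde_grid(logg)
    modes = _two_largest_modes(grid, dens)
    if modes is not None:
        i1, i2 = modes
        low_peak = dens[i1]
        minima = _interior_minima(dens, i1, i2)
        valley = minima[np.argmin(dens[minima])]
        # accept the valley only if it is a real dip below the baseline mode
        if low_peak - dens[valley] >= 0.1 * low_peak:
            return float(grid[valley])
    # shallow valley or single mode: baseline mode + 3 * MAD of the low side
    mode = grid[np.argmax(dens)]
    low = logg[logg <= mode]
    mad = np.median(np.abs(low - np.median(low))) * 1.4826
    if mad == 0:
        return np.nan
    return float(mode + 3.0 * mad)


def detect_thresholds(cells: pd.DataFrame) -> StageThresholds:
    """Detect stage thresholds from the DNA and log-Geminin distributions.

    Requires >= 500 cells and a bimodal DNA distribution; raises
    :class:`StagingError` otherwise. With all-zero (or non-positive)
    Geminin the reporter cut is marked unavailable (``nan``).
    """
    for col in ("dna", "geminin"):
        if col not in cells.columns:
            raise StagingError(f"missing required column {col!r}")
    if len(cells) < _MIN_CELLS:
        raise StagingError(f"need >= {_MIN_CELLS} cells, got {len(cells)}")
    dna = cells["dna"].to_numpy(dtype=float)
    if not np.all(np.isfinite(dna)):
        raise StagingError("non-finite DNA intensities")
    lo, hi = _dna_cuts(dna)
    gem_cut = _geminin_cut(cells["geminin"].to_numpy(dtype=float))
    return StageThresholds(float(lo), float(hi), gem_cut)


def assign_stage(cells: pd.DataFrame, thresholds: StageThresholds) -> pd.DataFrame:
    """Label every cell with exactly one stage; returns a copy with ``stage``.

    DNA rules take precedence: above ``dna_4n_lower`` is G2+M and between
    the cuts is S regardless of Geminin; the 2N class splits at the
    Geminin cut into G1 (early G1) and G1/S.
    """
    for col in ("dna", "geminin"):
        if col not in cells.columns:
            raise StagingError(f"missing required column {col!r}")
    dna = cells["dna"].to_numpy(dtype=float)
    gem = cells["geminin"].to_numpy(dtype=float)
    stage = np.full(len(cells), "S", dtype=object)
    is_2n = dna <= thresholds.dna_2n_upper
    is_4n = dna >= thresholds.dna_4n_lower
    stage[is_4n] = "G2+M"
    if thresholds.geminin_available:
        with np.errstate(divide="ignore"):
            high_gem = np.log(np.maximum(gem, 1e-300)) > thresholds.geminin_log_cut
        stage[is_2n & ~is_4n & high_gem] = "G1/S"
        stage[is_2n & ~is_4n & ~high_gem] = "G1"
    else:
        stage[is_2n & ~is_4n] = "G1"
    out = cells.copy()
    out["stage"] = stage
    return out
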