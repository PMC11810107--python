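"""Growth-rate and cell-cycle-length inference from bulk and track data.

Bulk estimators operate on time courses of cell counts and mean sizes:
the cell-cycle length is tau = ln(2)/alpha, where alpha comes from a
least-squares exponential fit N_t = N_0 * exp(alpha * t) (performed in
log space: count noise is multiplicative); the per-cell mass accumulation
rate is nu_t = (1/N_t) dM_t/dt with M_t = mean size x count and the
derivative by central differences.

Track estimators operate on single-cell nuclear-area time series from
live imaging: the growth rate is the first derivative of the
moving-average-smoothed area (central differences), with the first and
last six frames of each cycle discarded (nuclear envelope breakdown and
reformation corrupt the area there). Only cells tracked from one division
to the next ("complete") enter any summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthError",
    "GrowthFit",
    "fit_cycle_length",
    "bulk_growth_rate",
    "track_growth_rate",
    "tracks_growth_table",
    "align_tracks",
    "phase_durations",
    "percentile_growth_compare",
]

DEFAULT_SMOOTH_WINDOW = 5  # frames (~75 min at 15-min sampling)
DEFAULT_TRIM = 6  # frames dropped at each end of a cycle


class GrowthError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthFit:
    """Exponential proliferation fit: alpha (1/h), tau = ln2/alpha (h)."""

    alpha: float
    tau: float
    alpha_ci: tuple[float, float]
    alpha_se: float
    n_points: int
    diagnostic: str = ""


def _check_bulk(bulk: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    for col in ("time_h", "cell_count"):
        if col not in bulk.columns:
            raise GrowthError(f"missing required column {col!r}")
    b = bulk.sort_values("time_h")
    t = b["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise GrowthError("timepoints must be strictly increasing")
    if len(b) < min_points:
        raise GrowthError(f"need >= {min_points} timepoints, got {len(b)}")
    if np.any(b["cell_count"].to_numpy(dtype=float) <= 0):
        raise GrowthError("cell counts must be positive")
    return b


def fit_cycle_length(bulk: pd.DataFrame) -> GrowthFit:
    """Cell-cycle length from exponential growth of cell counts.

    alpha is the slope of log N_t on t; tau = ln2/alpha. A non-positive
    alpha leaves tau undefined (NaN) with a diagnostic message.
    """
    b = _check_bulk(bulk)
    t = b["time_h"].to_numpy(dtype=float)
    logn = np.log(b["cell_count"].to_numpy(dtype=float))
    res = stats.linregress(t, logn)
    alpha = float(res.slope)
    se = float(res.stderr) if np.isfinite(res.stderr) else np.nan
    tcrit = stats.t.ppf(0.975, len(b) - 2) if len(b) > 2 else np.nan
    ci = (alpha - tcrit * se, alpha + tcrit * se) if np.isfinite(se) else (np.nan, np.nan)
    if alpha <= 0:
        return GrowthFit(
            alpha=alpha, tau=np.nan, alpha_ci=ci, alpha_se=se, n_points=len(b),
            diagnostic="non-positive proliferation rate; cycle length undefined",
        )
    return GrowthFit(alpha=alpha, tau=float(np.log(2.0) / alpha), alpha_ci=ci,
                     alpha_se=se, n_points=len(b))


def bulk_growth_rate(bulk: pd.DataFrame) -> pd.DataFrame:
    """Per-cell bulk mass accumulation rate nu_t = (1/N_t) dM_t/dt.

    M_t = mean size x cell count; dM/dt by central differences with
    one-sided differences at the ends. Returns the input timepoints with
    ``bulk_mass`` and ``nu`` columns (a.u./h per cell).
    """
    b = _check_bulk(bulk)
    if "mean_size" not in b.columns:
        raise GrowthError("missing required column 'mean_size'")
    t = b["time_h"].to_numpy(dtype=float)
    n = b["cell_count"].to_numpy(dtype=float)
    mass = b["mean_size"].to_numpy(dtype=float) * n
    dmdt = np.gradient(mass, t)
    out = b.copy()
    out["bulk_mass"] = mass
    out["nu"] = dmdt / n
    return out


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")[pad : pad + x.size]
    return sm


def track_growth_rate(
    track: pd.DataFrame,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    trim: int = DEFAULT_TRIM,
) -> pd.DataFrame:
    """Per-frame growth rate of one track (a.u. nuclear area per hour).

    Moving-average smoothing then central-difference derivative; the
    first and last ``trim`` frames are excluded from the result. Raises
    :class:`GrowthError` for incomplete or too-short tracks.
    """
    t = track["time_h"].to_numpy(dtype=float)
    a = track["nuclear_area"].to_numpy(dtype=float)
    if "complete" in track.columns and not bool(track["complete"].iloc[0]):
        raise GrowthError("track excluded: not tracked from division to division")
    if t.size <= 2 * trim + smooth_window:
        raise GrowthError(
            f"track excluded: length {t.size} <= 2*trim + window "
            f"({2 * trim + smooth_window})"
        )
    sm = _moving_average(a, smooth_window)
    rate = np.gradient(sm, t)
    keep = slice(trim, t.size - trim if trim > 0 else t.size)
    out = pd.DataFrame({"time_h": t[keep], "area_smooth": sm[keep], "growth_rate": rate[keep]})
    for col in ("track_id", "birth_time_h", "g1s_time_h", "division_time_h"):
        if col in track.columns:
            out[col] = track[col].iloc[0]
    return out


def tracks_growth_table(
    tracks: pd.DataFrame,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    trim: int = DEFAULT_TRIM,
) -> pd.DataFrame:
    """Concatenated per-frame growth rates for all usable complete tracks.

    Tracks failing the completeness or length preconditions are skipped
    (their ids and reasons are attached as ``.attrs['excluded']``).
    """
    frames, excluded = [], []
    for tid, g in tracks.groupby("track_id"):
        try:
            frames.append(track_growth_rate(g, smooth_window, trim))
        except GrowthError as e:
            excluded.append((tid, str(e)))
    if not frames:
        raise GrowthError("no usable tracks after filtering")
    out = pd.concat(frames, ignore_index=True)
    out.attrs["excluded"] = excluded
    return out


def align_tracks(
    tracks: pd.DataFrame, anchor: str = "birth", min_tracks: int = 10
) -> pd.DataFrame:
    """Mean +- 95% CI nuclear-area curve over tracks aligned at an anchor.

    ``anchor`` is ``"birth"`` or ``"g1s"``; each track's time axis is
    shifted so the anchor sits at zero, curves are averaged on the common
    frame grid, and grid points supported by fewer than ``min_tracks``
    tracks are masked out. Tracks without a defined anchor are dropped
    (listed in ``.attrs['dropped']``).
    """
    col = {"birth": "birth_time_h", "g1s": "g1s_time_h"}.get(anchor)
    if col is None:
        raise GrowthError(f"unknown anchor {anchor!r} (use 'birth' or 'g1s')")
    pieces, dropped = [], []
    for tid, g in tracks.groupby("track_id"):
        t0 = g[col].iloc[0]
        if not np.isfinite(t0):
            dropped.append(tid)
            continue
        shifted = g[["time_h", "nuclear_area"]].copy()
        shifted["aligned_time_h"] = g["time_h"] - t0
        pieces.append(shifted)
    if not pieces:
        raise GrowthError(f"no tracks with a defined {anchor} anchor")
    cat = pd.concat(pieces, ignore_index=True)
    # snap to the frame grid to avoid float jitter
    dt = np.median(np.diff(np.sort(cat["time_h"].unique())))
    cat["aligned_time_h"] = np.round(cat["aligned_time_h"] / dt) * dt
    g = cat.groupby("aligned_time_h")["nuclear_area"]
    stat = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
    stat = stat[stat["n"] >= min_tracks]
    tcrit = stats.t.ppf(0.975, np.maximum(stat["n"] - 1, 1))
    half = tcrit * stat["sd"] / np.sqrt(stat["n"])
    out = pd.DataFrame(
        {
            "aligned_time_h": stat.index.to_numpy(),
            "mean": stat["mean"].to_numpy(),
            "ci_low": (stat["mean"] - half).to_numpy(),
            "ci_high": (stat["mean"] + half).to_numpy(),
            "n": stat["n"].to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["dropped"] = dropped
    return out


def _mean_ci(x: np.ndarray):
    m = float(np.mean(x))
    if x.size < 2:
        return m, np.nan, np.nan
    half = stats.t.ppf(0.975, x.size - 1) * np.std(x, ddof=1) / np.sqrt(x.size)
    return m, m - half, m + half


def phase_durations(tracks: pd.DataFrame, other: pd.DataFrame | None = None) -> dict:
    """G1 and whole-cycle duration statistics, optionally versus a second arm.

    G1 = G1/S transition minus birth; cycle = division minus birth; only
    complete tracks with a defined G1/S time contribute. With ``other``
    given, Welch two-sample t-tests compare the arms.
    """

    def durations(df):
        lm = df.drop_duplicates("track_id")
        lm = lm[lm["complete"] & np.isfinite(lm["g1s_time_h"])]
        if lm.empty:
            raise GrowthError("no complete tracks with a G1/S time")
        g1 = (lm["g1s_time_h"] - lm["birth_time_h"]).to_numpy(dtype=float)
        cyc = (lm["division_time_h"] - lm["birth_time_h"]).to_numpy(dtype=float)
        return g1, cyc

    g1, cyc = durations(tracks)
    out = {
        "g1_mean": _mean_ci(g1)[0],
        "g1_ci": _mean_ci(g1)[1:],
        "cycle_mean": _mean_ci(cyc)[0],
        "cycle_ci": _mean_ci(cyc)[1:],
        "n_tracks": int(g1.size),
    }
    if other is not None:
        g1b, cycb = durations(other)
        welch_g1 = stats.ttest_ind(g1b, g1, equal_var=False)
        welch_cyc = stats.ttest_ind(cycb, cyc, equal_var=False)
        diff = g1b.mean() - g1.mean()
        se = np.sqrt(np.var(g1, ddof=1) / g1.size + np.var(g1b, ddof=1) / g1b.size)
        dof = welch_g1.df
        half = stats.t.ppf(0.975, dof) * se
        out.update(
            {
                "g1_mean_other": float(g1b.mean()),
                "cycle_mean_other": float(cycb.mean()),
                "g1_diff": float(diff),
                "g1_diff_ci": (float(diff - half), float(diff + half)),
                "g1_p_value": float(welch_g1.pvalue),
                "cycle_p_value": float(welch_cyc.pvalue),
                "n_tracks_other": int(g1b.size),
            }
        )
    return out


def percentile_growth_compare(
    tracks: pd.DataFrame,
    size_percentiles: tuple[float, float] = (20.0, 80.0),
    split: str = "whole",
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    trim: int = DEFAULT_TRIM,
) -> dict:
    """Mean trimmed growth rate of small versus large cells.

    Tracks are classified by birth size (first-frame nuclear area):
    "small" at or below the low percentile, "large" at or above the high
    one. ``split`` restricts the averaged frames to before ("pre_g1s") or
    after ("post_g1s") each track's G1/S transition, or uses the whole
    cycle. Reports per-class means and the Welch CI of the difference
    (large minus small).
    """
    if split not in ("whole", "pre_g1s", "post_g1s"):
        raise GrowthError(f"unknown split {split!r}")
    rates = tracks_growth_table(tracks, smooth_window, trim)
    birth_size = tracks.sort_values("time_h").groupby("track_id")["nuclear_area"].first()
    lo_cut, hi_cut = np.percentile(birth_size, list(size_percentiles))
    small_ids = set(birth_size[birth_size <= lo_cut].index)
    large_ids = set(birth_size[birth_size >= hi_cut].index)

    def class_rates(ids):
        vals = []
        for tid in ids:
            sub = rates[rates["track_id"] == tid]
            if sub.empty:
                continue
            if split == "pre_g1s":
                sub = sub[sub["time_h"] < sub["g1s_time_h"]]
            elif split == "post_g1s":
                sub = sub[sub["time_h"] >= sub["g1s_time_h"]]
            if len(sub):
                vals.append(sub["growth_rate"].mean())
        return np.asarray(vals, dtype=float)

    small = class_rates(small_ids)
    large = class_rates(large_ids)
    if small.size == 0 or large.size == 0:
        raise GrowthError("empty size class after trimming")
    diff = float(large.mean() - small.mean())
    se = np.sqrt(np.var(large, ddof=1) / large.size + np.var(small, ddof=1) / small.size)
    dof = stats.ttest_ind(large, small, equal_var=False).df
    half = stats.t.ppf(0.975, dof) * se
    return {
        "split": split,
        "small_mean_rate": float(small.mean()),
        "large_mean_rate": float(large.mean()),
        "difference": diff,
        "difference_ci": (float(diff - half), float(diff + half)),
        "n_small": int(small.size),
        "n_large": int(large.size),
    }
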