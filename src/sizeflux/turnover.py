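"""Proteasome-flux statistics from fixed-cell feature tables.

The central quantity is ΔK48-polyUb — the clearance rate of K48-linked
polyubiquitinated protein, measured as the excess K48-polyUb accumulated
during a 30-minute proteasome blockade (carfilzomib, CFZ): for every pair
of a +CFZ and a -CFZ well of the same condition, the difference of the
well-level central K48 intensities. Replicate wells (not cells) are the
independent units throughout; confidence intervals are t-based over the
cross pairs with an effective sample size of min(n_plus, n_minus), or
bootstrap over wells where ratios are involved.

Satellite analyses: fold-change scaling of ΔK48 against cell size between
a perturbed and a control arm (with a one-sided bootstrap test for
superlinearity, i.e. degradation rising faster than size); decomposition
into nascent (CHX-sensitive) and long-lived shares; cycloheximide-chase
size-loss slopes for small (20th percentile) versus large (80th
percentile) cells; ordinary least-squares marker-versus-size fits; and the
deviation of the G1/S stage from the linear ΔK48-size trend of the other
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TurnoverError",
    "TurnoverResult",
    "ScalingFit",
    "well_summaries",
    "delta_k48",
    "scaling_analysis",
    "chx_decomposition",
    "chx_chase_slopes",
    "marker_size_fit",
    "g1s_deviation",
]

STAGE_ORDER = ("G1", "G1/S", "S", "G2+M")


class TurnoverError(ValueError):
    pass


@dataclass
class TurnoverResult:
    """ΔK48 estimate for one condition x stage, with replicate-well detail."""

    condition: str
    stage: str  # "all" for the unstratified estimate
    delta_k48: float
    ci_low: float
    ci_high: float
    n_pairs: int
    median_size: float
    fold_delta_vs_control: float = np.nan
    fold_size_vs_control: float = np.nan
    # well-level summaries retained for bootstrap resampling
    wells_plus: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    wells_minus: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    sizes_plus: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    sizes_minus: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


@dataclass(frozen=True)
class ScalingFit:
    """Marker-size regression and/or fold-change scaling summary."""

    slope: float
    intercept: float
    pearson_r: float
    excess_ratio: float = np.nan
    superlinear_p: float = np.nan
    fold_delta: float = np.nan
    fold_size: float = np.nan


def _centre(x: np.ndarray, how: str) -> float:
    if how == "median":
        return float(np.median(x))
    if how == "mean":
        return float(np.mean(x))
    raise ValueError(f"unknown centre {how!r}")


def well_summaries(
    cells: pd.DataFrame, value: str = "k48", centre: str = "median"
) -> pd.DataFrame:
    """Per-well central value of ``value`` and of cell size.

    Cells within a well are correlated (shared staining, shared history),
    so all inference downstream operates on these well-level units.
    """
    if value not in cells.columns:
        raise TurnoverError(f"missing required column {value!r}")
    g = cells.groupby("well_id", observed=True)
    out = pd.DataFrame(
        {
            "value": g[value].median() if centre == "median" else g[value].mean(),
            "size_se": g["size_se"].median(),
            "n_cells": g.size(),
        }
    )
    for meta in ("condition", "cfz_flag", "chx_flag", "fixation_time_h"):
        if meta in cells.columns:
            first = g[meta].first()
            if not g[meta].nunique().le(1).all():
                raise TurnoverError(f"well metadata column {meta!r} is not constant per well")
            out[meta] = first
    return out.reset_index()


def _pair_estimate(plus: np.ndarray, minus: np.ndarray):
    """Cross-pair ΔK48: mean over all (+CFZ, -CFZ) pair differences.

    The cross-pair mean equals the difference of arm means; the CI uses
    the t distribution over pair values with effective n = min(arm sizes)
    (cross pairs reuse wells and are not independent).
    """
    pairs = plus[:, None] - minus[None, :]
    vals = pairs.ravel()
    est = float(vals.mean())
    n_eff = min(plus.size, minus.size)
    if n_eff < 2:
        return est, np.nan, np.nan, vals.size
    se = float(vals.std(ddof=1) / np.sqrt(n_eff))
    t = stats.t.ppf(0.975, n_eff - 1)
    return est, est - t * se, est + t * se, vals.size


def delta_k48(
    cells: pd.DataFrame,
    per_stage: bool = False,
    centre: str = "median",
    value: str = "k48",
) -> list[TurnoverResult]:
    """ΔK48 estimates from a table containing both CFZ arms.

    The table must hold exactly one condition and fixation time, with
    ``cfz_flag`` marking the blocked arm. With ``per_stage`` the estimate
    is additionally computed within each stage label (requires a
    ``stage`` column). Single-pair designs return an undefined (NaN) CI.
    """
    for col in ("cfz_flag", "well_id", "condition"):
        if col not in cells.columns:
            raise TurnoverError(f"missing required column {col!r}")
    conditions = cells["condition"].unique()
    if conditions.size != 1:
        raise TurnoverError(
            f"expected a single condition per ΔK48 computation, got {sorted(conditions)}"
        )
    if "fixation_time_h" in cells.columns and cells["fixation_time_h"].nunique() > 1:
        raise TurnoverError("mixed fixation times in ΔK48 computation")
    condition = str(conditions[0])

    def one(sub: pd.DataFrame, stage: str) -> TurnoverResult:
        w = well_summaries(sub, value=value, centre=centre)
        plus = w.loc[w["cfz_flag"], "value"].to_numpy(dtype=float)
        minus = w.loc[~w["cfz_flag"], "value"].to_numpy(dtype=float)
        if plus.size < 1 or minus.size < 1:
            raise TurnoverError(
                f"need at least one well in each CFZ arm (stage {stage!r}); "
                f"got +{plus.size}/-{minus.size}"
            )
        est, lo, hi, n_pairs = _pair_estimate(plus, minus)
        sizes_p = w.loc[w["cfz_flag"], "size_se"].to_numpy(dtype=float)
        sizes_m = w.loc[~w["cfz_flag"], "size_se"].to_numpy(dtype=float)
        return TurnoverResult(
            condition=condition,
            stage=stage,
            delta_k48=est,
            ci_low=lo,
            ci_high=hi,
            n_pairs=n_pairs,
            median_size=float(np.median(np.concatenate([sizes_p, sizes_m]))),
            wells_plus=plus,
            wells_minus=minus,
            sizes_plus=sizes_p,
            sizes_minus=sizes_m,
        )

    results = [one(cells, "all")]
    if per_stage:
        if "stage" not in cells.columns:
            raise TurnoverError("per_stage requires a 'stage' column (run staging first)")
        for stage in STAGE_ORDER:
            sub = cells[cells["stage"] == stage]
            if len(sub):
                results.append(one(sub, stage))
    return results


def _match_stages(control, perturbed):
    ctrl = {r.stage: r for r in control}
    pert = {r.stage: r for r in perturbed}
    shared = [s for s in ctrl if s in pert]
    if not shared:
        raise TurnoverError("no matching stages between control and perturbed results")
    return [(ctrl[s], pert[s]) for s in shared]


def scaling_analysis(
    control: list[TurnoverResult],
    perturbed: list[TurnoverResult],
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> ScalingFit:
    """Fold-change scaling of ΔK48 versus cell size, with superlinearity test.

    ``fold_delta`` (perturbed/control ΔK48) and ``fold_size`` (median SE)
    are averaged over the matched stages; ``excess_ratio`` is their ratio
    (1 = proportional scaling). ``superlinear_p`` is the one-sided
    bootstrap probability (resampling wells within each arm) that the
    excess ratio is <= 1, i.e. the p-value of the superlinearity claim.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    matched = _match_stages(control, perturbed)

    def folds(sampler=None):
        fd, fs = [], []
        for c, p in matched:
            if sampler is None:
                cp, cm, pp, pm = c.wells_plus, c.wells_minus, p.wells_plus, p.wells_minus
                csz = np.concatenate([c.sizes_plus, c.sizes_minus])
                psz = np.concatenate([p.sizes_plus, p.sizes_minus])
            else:
                cp, cm, pp, pm = (sampler(x) for x in (c.wells_plus, c.wells_minus, p.wells_plus, p.wells_minus))
                csz = sampler(np.concatenate([c.sizes_plus, c.sizes_minus]))
                psz = sampler(np.concatenate([p.sizes_plus, p.sizes_minus]))
            dc = cp.mean() - cm.mean()
            dp = pp.mean() - pm.mean()
            if dc <= 0 or dp <= 0:
                return None
            fd.append(dp / dc)
            fs.append(np.median(psz) / np.median(csz))
        return float(np.mean(fd)), float(np.mean(fs))

    point = folds()
    if point is None:
        raise TurnoverError("non-positive ΔK48 fold; scaling analysis undefined")
    fold_delta, fold_size = point
    if fold_size <= 0:
        raise TurnoverError("non-positive size fold; scaling analysis undefined")
    excess = fold_delta / fold_size

    def sampler(x):
        return x[rng.integers(0, x.size, x.size)]

    boot = []
    for _ in range(n_boot):
        f = folds(sampler)
        if f is not None:
            boot.append(f[0] / f[1])
    boot = np.asarray(boot)
    # one-sided bootstrap p for H0: excess_ratio <= 1
    p = float((np.sum(boot <= 1.0) + 1) / (boot.size + 1)) if boot.size else np.nan
    return ScalingFit(
        slope=np.nan,
        intercept=np.nan,
        pearson_r=np.nan,
        excess_ratio=excess,
        superlinear_p=p,
        fold_delta=fold_delta,
        fold_size=fold_size,
    )


def chx_decomposition(
    delta_without_chx: TurnoverResult, delta_with_chx: TurnoverResult
) -> dict:
    """Nascent versus long-lived shares of the K48 flux.

    CHX halts synthesis, so the CHX-sensitive part of ΔK48 reflects
    degradation of nascent protein: nascent share = (Δ_without − Δ_with)
    / Δ_without, clipped to [0, 1] (flagged when clipping applied).
    """
    if (
        delta_without_chx.condition != delta_with_chx.condition
        or delta_without_chx.stage != delta_with_chx.stage
    ):
        raise TurnoverError("CHX decomposition requires matching condition and stage")
    d0 = delta_without_chx.delta_k48
    d1 = delta_with_chx.delta_k48
    if d0 <= 0:
        return {
            "condition": delta_without_chx.condition,
            "stage": delta_without_chx.stage,
            "nascent_share": np.nan,
            "long_lived_share": np.nan,
            "clipped": False,
            "defined": False,
        }
    raw = (d0 - d1) / d0
    share = float(np.clip(raw, 0.0, 1.0))
    return {
        "condition": delta_without_chx.condition,
        "stage": delta_without_chx.stage,
        "nascent_share": share,
        "long_lived_share": 1.0 - share,
        "clipped": bool(raw != share),
        "defined": True,
    }


def chx_chase_slopes(
    snapshots: pd.DataFrame,
    size_percentiles: tuple[float, float] = (20.0, 80.0),
    per_stage: bool = True,
) -> pd.DataFrame:
    """Size-loss rates of small versus large cells in a CHX chase.

    ``snapshots`` holds cells fixed at several chase times
    (``fixation_time_h``). Within each stage and timepoint, the median SE
    of cells below the low percentile ("small") and above the high
    percentile ("large") is expressed as a fraction of that class's median
    at time 0; the loss rate is the least-squares slope of this fraction
    over chase time (per hour; -0.01 = 1% of initial size lost per hour).
    """
    lo_p, hi_p = size_percentiles
    times = np.sort(snapshots["fixation_time_h"].unique())
    if times.size < 3:
        raise TurnoverError(f"need >= 3 chase timepoints, got {times.size}")
    groups = (
        [(s, snapshots[snapshots["stage"] == s]) for s in STAGE_ORDER
         if (snapshots.get("stage") == s).any()]
        if per_stage and "stage" in snapshots.columns
        else [("all", snapshots)]
    )
    if not groups:
        raise TurnoverError("no staged cells for the chase analysis")
    rows = []
    for stage, sub in groups:
        for label, pick in (("small", "low"), ("large", "high")):
            fracs = []
            ref = None
            for t in times:
                at = sub[sub["fixation_time_h"] == t]["size_se"].to_numpy(dtype=float)
                if at.size == 0:
                    raise TurnoverError(f"empty percentile class at t={t} (stage {stage})")
                cut_lo, cut_hi = np.percentile(at, [lo_p, hi_p])
                cls = at[at <= cut_lo] if pick == "low" else at[at >= cut_hi]
                if cls.size == 0:
                    raise TurnoverError(f"empty percentile class at t={t} (stage {stage})")
                med = np.median(cls)
                if ref is None:
                    ref = med
                fracs.append(med / ref)
            slope = float(np.polyfit(times, np.asarray(fracs), 1)[0])
            rows.append(
                {"stage": stage, "size_class": label, "loss_rate_per_h": slope,
                 "n_timepoints": times.size}
            )
    return pd.DataFrame(rows)


def marker_size_fit(cells: pd.DataFrame, marker: str) -> ScalingFit:
    """OLS fit of a marker on cell size (SE) with the Pearson correlation.

    Negative marker values are permitted (background-subtracted signals);
    a degenerate size distribution raises.
    """
    if marker not in cells.columns:
        raise TurnoverError(f"missing required column {marker!r}")
    if len(cells) < 100:
        raise TurnoverError(f"need >= 100 cells for a marker fit, got {len(cells)}")
    x = cells["size_se"].to_numpy(dtype=float)
    y = cells[marker].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise TurnoverError("non-finite values in marker fit")
    if np.std(x) == 0:
        raise TurnoverError("zero size variance; marker fit undefined")
    res = stats.linregress(x, y)
    return ScalingFit(slope=float(res.slope), intercept=float(res.intercept),
                      pearson_r=float(res.rvalue))


def g1s_deviation(
    results: list[TurnoverResult],
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Deviation of the G1/S stage from the ΔK48-size trend of other stages.

    Fits ΔK48 against median size on {G1, S, G2+M} and reports the G1/S
    residual (observed minus predicted) with a bootstrap CI (resampling
    wells within each stage). A positive residual with a CI excluding zero
    indicates G1/S degradation hyperactivity beyond what size predicts.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    by_stage = {r.stage: r for r in results}
    trend_stages = [s for s in ("G1", "S", "G2+M") if s in by_stage]
    if len(trend_stages) < 3:
        raise TurnoverError("need all of G1, S and G2+M to fit the stage-wise trend")
    if "G1/S" not in by_stage:
        raise TurnoverError("no G1/S stage present")

    def residual(sampler=None):
        xs, ys = [], []
        for s in trend_stages + ["G1/S"]:
            r = by_stage[s]
            if sampler is None:
                plus, minus = r.wells_plus, r.wells_minus
                sizes = np.concatenate([r.sizes_plus, r.sizes_minus])
            else:
                plus, minus = sampler(r.wells_plus), sampler(r.wells_minus)
                sizes = sampler(np.concatenate([r.sizes_plus, r.sizes_minus]))
            xs.append(np.median(sizes))
            ys.append(plus.mean() - minus.mean())
        coef = np.polyfit(xs[:-1], ys[:-1], 1)
        return ys[-1] - np.polyval(coef, xs[-1])

    obs = float(residual())

    def sampler(x):
        return x[rng.integers(0, x.size, x.size)]

    boot = np.array([residual(sampler) for _ in range(n_boot)])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {
        "residual": obs,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "excludes_zero": bool(lo > 0 or hi < 0),
        "n_boot": n_boot,
    }
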