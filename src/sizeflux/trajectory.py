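"""Continuous cell-cycle axis from the DNA x log-Geminin density ridge.

An asynchronous population traces a characteristic arc in the plane of DNA
content versus log Geminin: early-G1 cells sit at the (2N, baseline) mode,
the G1/S transition climbs in Geminin at constant DNA, S sweeps from 2N to
4N, and G2+M accumulates further Geminin at 4N. :func:`fit_ridge` extracts
this arc as a polyline following the local maxima of a 2-D kernel density
estimate (steepest-ascent ridge walk from the global mode, extended in both
directions, followed by a short principal-curve refinement).
:func:`project_cells` assigns each cell the normalized arc-length ``ell``
in [0, 1] of its nearest point on the curve; ``ell`` orders cells by
average cycle progression but is not wall-clock time.

Channels are z-scored before any distance or density computation: DNA and
Geminin are on arbitrary, unequal scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = ["RidgeError", "TrajectoryCurve", "fit_ridge", "project_cells", "ell_size_heatmap"]

_MIN_CELLS = 2000


class RidgeError(ValueError):
    pass


@dataclass(frozen=True)
class TrajectoryCurve:
    """Ordered ridge polyline with its arc-length parameterization.

    ``points`` are in the original (dna, log-geminin) units; ``ell`` is the
    normalized arc length in [0, 1] computed in z-scored channel units,
    anchored at the early-G1 mode (0) and the 4N / high-Geminin end (1).
    ``center``/``scale`` record the z-scoring used for projections.
    """

    points: np.ndarray  # (n, 2) dna, log-geminin
    ell: np.ndarray  # (n,)
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    scale: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        ell = np.asarray(self.ell, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] != ell.size:
            raise RidgeError("points must be (n, 2) with matching ell")
        if pts.shape[0] < 2:
            raise RidgeError("curve needs at least two points")
        if np.any(np.diff(ell) <= 0):
            raise RidgeError("ell must be strictly increasing")

    @property
    def z_points(self) -> np.ndarray:
        return (self.points - self.center) / self.scale


def _features(cells: pd.DataFrame) -> np.ndarray:
    dna = cells["dna"].to_numpy(dtype=float)
    gem = cells["geminin"].to_numpy(dtype=float)
    if np.any(dna <= 0) or np.any(gem <= 0):
        raise RidgeError("both channels must be positive")
    return np.column_stack([dna, np.log(gem)])


def _density_grid(z: np.ndarray, n_grid: int):
    """Binned 2-D Gaussian KDE (Silverman bandwidth per channel) on a grid."""
    n = z.shape[0]
    bw = 1.06 * n ** (-1.0 / 6.0)  # z-scored channels: unit variance
    lo = z.min(axis=0) - 3 * bw
    hi = z.max(axis=0) + 3 * bw
    step = (hi - lo) / (n_grid - 1)
    hist, _, _ = np.histogram2d(
        z[:, 0], z[:, 1], bins=n_grid, range=[[lo[0], hi[0] + step[0]], [lo[1], hi[1] + step[1]]]
    )
    dens = gaussian_filter(hist, sigma=bw / step, mode="constant")
    return dens, lo, step, bw


def _interp(dens: np.ndarray, lo, step, pts: np.ndarray) -> np.ndarray:
    coords = ((pts - lo) / step).T
    return map_coordinates(dens, coords, order=1, mode="constant", cval=0.0)


def _grad(dens, lo, step, pts, eps):
    """Central-difference density gradient at arbitrary points."""
    out = np.zeros_like(pts)
    for k in range(2):
        d = np.zeros(2)
        d[k] = eps
        out[:, k] = (_interp(dens, lo, step, pts + d) - _interp(dens, lo, step, pts - d)) / (
            2 * eps
        )
    return out


def _walk(
    dens,
    lo,
    step,
    start,
    direction,
    bw,
    floor,
    support,
    max_turn_deg=55.0,
    max_steps=600,
):
    """Ridge walk: step along the current direction, then pull the point to
    the density maximum on the perpendicular segment (+- 1.5 bandwidths).

    ``support(p)`` reports how many cells lie within 1.5 bandwidths of a
    point; the walk stops once it leaves the data support (sparse tails)
    or the density falls below ``floor``.
    """
    h = 0.5 * bw
    pts = []
    p = start.copy()
    d = direction / np.linalg.norm(direction)
    offsets = np.linspace(-1.5 * bw, 1.5 * bw, 25)
    max_turn = np.deg2rad(max_turn_deg)
    n_capped = 0
    for _ in range(max_steps):
        cand = p + h * d
        perp = np.array([-d[1], d[0]])
        line = cand[None, :] + offsets[:, None] * perp[None, :]
        vals = _interp(dens, lo, step, line)
        k = int(np.argmax(vals))
        off = offsets[k]
        if 0 < k < offsets.size - 1:
            # parabolic sub-step refinement of the perpendicular maximum
            denom = vals[k - 1] - 2 * vals[k] + vals[k + 1]
            if denom < 0:
                off += 0.5 * (vals[k - 1] - vals[k + 1]) / denom * (offsets[1] - offsets[0])
        best = cand + off * perp
        if vals.max() < floor or not support(best):
            break
        new_d = best - p
        norm = np.linalg.norm(new_d)
        if norm < 1e-12:
            break
        new_d = new_d / norm
        angle = np.arccos(np.clip(np.dot(new_d, d), -1.0, 1.0))
        if angle > max_turn:
            # limit the turn; if the ridge truly bends away, the support
            # criterion terminates the walk on the next iterations
            n_capped += 1
            w = max_turn / angle
            blend = (1 - w) * d + w * new_d
            new_d = blend / np.linalg.norm(blend)
            best = p + h * new_d
        # a U-turn at the ridge end would retrace the curve: stop when the
        # walk re-enters territory it traced more than a few steps ago
        if len(pts) > 6:
            prior = np.asarray(pts[:-6])
            if np.min(np.einsum("ij,ij->i", prior - best, prior - best)) < (0.9 * h) ** 2:
                break
        pts.append(best)
        d = new_d
        p = best
    return pts, n_capped


def _ridge_anisotropy(dens, lo, step, pts, bw) -> float:
    """Median ratio of along-track to transverse density curvature.

    Near zero on a genuine ridge (density flat along, sharply peaked
    across); near one inside an isotropic blob.
    """
    if pts.shape[0] < 3:
        return 1.0
    eps = 0.5 * bw
    tang = np.diff(pts, axis=0)
    tang = tang / np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    mids = 0.5 * (pts[:-1] + pts[1:])
    perp = np.column_stack([-tang[:, 1], tang[:, 0]])
    f0 = _interp(dens, lo, step, mids)

    def second(direction):
        fp = _interp(dens, lo, step, mids + eps * direction)
        fm = _interp(dens, lo, step, mids - eps * direction)
        return fp - 2 * f0 + fm

    f_tt = second(tang)
    f_nn = second(perp)
    valid = f_nn < 0
    if valid.sum() < 3:
        return 1.0
    ratios = np.clip(f_tt[valid] / f_nn[valid], 0.0, 2.0)
    return float(np.median(ratios))


def _candidate_starts(dens, lo, step, bw, n_max: int = 3):
    """Grid positions of the strongest well-separated density modes."""
    from scipy.ndimage import maximum_filter

    size = max(3, int(np.ceil(bw / step.min())))
    local_max = (dens == maximum_filter(dens, size=size)) & (dens > 0.05 * dens.max())
    ij = np.argwhere(local_max)
    order = np.argsort(dens[local_max])[::-1]
    starts = []
    for k in order:
        # sub-grid refinement: density-weighted centroid of the local patch
        i, j = ij[k]
        w = max(2, size // 2)
        sl = (slice(max(i - w, 0), i + w + 1), slice(max(j - w, 0), j + w + 1))
        patch = dens[sl]
        gi, gj = np.mgrid[sl]
        mass = patch.sum()
        pos = np.array([(gi * patch).sum(), (gj * patch).sum()]) / mass
        p = lo + pos * step
        if all(np.linalg.norm(p - q) > 2 * bw for q in starts):
            starts.append(p)
        if len(starts) == n_max:
            break
    return starts


def _initial_direction(dens, lo, step, start, bw):
    """Direction of the densest ray leaving the start point.

    The global mode can sit at an *endpoint* of the trajectory, where the
    local covariance of the mode's own noise cloud is uninformative; the
    ridge continuation is the direction along which the density decays
    slowest.
    """
    thetas = np.linspace(0.0, 2 * np.pi, 36, endpoint=False)
    dirs = np.column_stack([np.cos(thetas), np.sin(thetas)])
    radii = np.array([1.0, 2.0, 3.0]) * bw
    probe = start[None, None, :] + radii[None, :, None] * dirs[:, None, :]
    vals = _interp(dens, lo, step, probe.reshape(-1, 2)).reshape(len(thetas), len(radii))
    score = vals.mean(axis=1)
    return dirs[int(np.argmax(score))]


def _resample(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        return points
    n = max(int(np.round(total / spacing)), 2)
    targets = np.linspace(0.0, total, n + 1)
    out = np.column_stack(
        [np.interp(targets, arc, points[:, k]) for k in range(2)]
    )
    return out


def _refine(points: np.ndarray, z: np.ndarray, bw: float, n_iter: int = 6) -> np.ndarray:
    """Principal-curve refinement: local average of the data points that
    project to each vertex's neighborhood, blended with the current vertex."""
    pts = points.copy()
    for _ in range(n_iter):
        ell = _arc_length(pts)
        cell_ell = _project_to_polyline(z, pts, ell)[0]
        new_pts = pts.copy()
        width = 0.05
        for i in range(pts.shape[0]):
            m = np.abs(cell_ell - ell[i]) < width
            if m.sum() >= 10:
                new_pts[i] = 0.5 * pts[i] + 0.5 * z[m].mean(axis=0)
        # light smoothing of the polyline itself
        new_pts[1:-1] = 0.25 * new_pts[:-2] + 0.5 * new_pts[1:-1] + 0.25 * new_pts[2:]
        pts = new_pts
    return pts


def _arc_length(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    ell = np.concatenate([[0.0], np.cumsum(seg)])
    total = ell[-1]
    if total <= 0:
        raise RidgeError("degenerate curve with zero length")
    return ell / total


def fit_ridge(cells: pd.DataFrame, n_grid: int = 200, density_floor: float = 0.01) -> TrajectoryCurve:
    """Extract the average cell-cycle trajectory as a density-ridge polyline.

    Raises :class:`RidgeError` for degenerate inputs: fewer than 2,000
    cells, non-positive channels, or a distribution without an extended
    ridge (e.g. a rotationally symmetric blob). ``density_floor`` is the
    fraction of the peak density below which the walk stops.
    """
    if len(cells) < _MIN_CELLS:
        raise RidgeError(f"need >= {_MIN_CELLS} cells, got {len(cells)}")
    x = _features(cells)
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    if np.any(scale <= 0):
        raise RidgeError("zero variance in a channel")
    z = (x - center) / scale
    dens, lo, step, bw = _density_grid(z, n_grid)
    floor = density_floor * dens.max()

    # data-support criterion for walk termination (leaves sparse tails)
    min_support = max(5, int(0.0025 * z.shape[0]))
    r2 = (1.5 * bw) ** 2

    def support_count(p):
        return int(np.sum(np.einsum("ij,ij->i", z - p, z - p) < r2))

    def support(p):
        return support_count(p) >= min_support

    # the global mode may sit at an endpoint of the arc, where its own
    # noise cloud hides the ridge direction; trace from the strongest few
    # modes and keep the longest ridge
    best = None
    for start in _candidate_starts(dens, lo, step, bw):
        d0 = _initial_direction(dens, lo, step, start, bw)
        fwd, cap_f = _walk(dens, lo, step, start, d0, bw, floor, support)
        bwd, cap_b = _walk(dens, lo, step, start, -d0, bw, floor, support)
        pts = np.array(list(reversed(bwd)) + [start] + fwd)
        n_steps = len(fwd) + len(bwd)
        cap_frac = (cap_f + cap_b) / n_steps if n_steps else 1.0
        if pts.shape[0] < 2:
            continue
        extent = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2).max()
        if best is None or extent > best[1]:
            best = (pts, extent, cap_frac)
    if best is None or best[0].shape[0] < 5:
        raise RidgeError("no simple ridge: traced curve is degenerate")
    pts, extent, cap_frac = best
    if cap_frac > 0.3:
        raise RidgeError(
            "no simple ridge: walk keeps turning back on itself "
            "(rotationally symmetric or disconnected density; try a larger bandwidth)"
        )
    if extent < 4 * bw:
        raise RidgeError(
            "no simple ridge: traced extent is below the bandwidth scale "
            "(rotationally symmetric or disconnected density; try a larger bandwidth)"
        )
    if _ridge_anisotropy(dens, lo, step, pts, bw) > 0.35:
        raise RidgeError(
            "no simple ridge: density curvature along the walk matches the "
            "transverse curvature (rotationally symmetric density)"
        )
    # canonical vertex layout before refinement: decouples the polyline
    # from the walk's step phase and the grid resolution
    pts = _resample(pts, 0.4 * bw)
    pts = _refine(pts, z, bw)
    pts = _resample(pts, 0.4 * bw)
    # drop near-duplicate vertices so that ell is strictly increasing
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    pts = pts[keep]

    # trim end overruns into sparse noise tails: drop terminal vertices with
    # weak data support relative to the curve's typical support
    supports = np.array([support_count(p) for p in pts])
    cut = 0.3 * np.percentile(supports, 75)
    i_lo, i_hi = 0, pts.shape[0] - 1
    while i_lo < i_hi - 3 and supports[i_lo] < cut:
        i_lo += 1
    while i_hi > i_lo + 3 and supports[i_hi] < cut:
        i_hi -= 1
    pts = pts[i_lo : i_hi + 1]

    # anchor the endpoints at the outermost density modes when the modes
    # bracket the curve (the cycle arc runs mode-to-mode); this pins the
    # arc-length normalization against grid-resolution changes
    candidates = _candidate_starts(dens, lo, step, bw)
    if len(candidates) >= 2:
        sep = np.array(
            [[np.linalg.norm(a - b) for b in candidates] for a in candidates]
        )
        i, j = np.unravel_index(np.argmax(sep), sep.shape)
        ends = [candidates[i], candidates[j]]
        n_pts = pts.shape[0]
        idx = sorted(
            int(np.argmin(np.linalg.norm(pts - e, axis=1))) for e in ends
        )
        near = all(
            np.linalg.norm(pts[k] - e) < 2 * bw
            for k, e in zip(idx, sorted(ends, key=lambda e: np.argmin(np.linalg.norm(pts - e, axis=1))))
        )
        terminal = idx[0] < 0.3 * n_pts and idx[1] > 0.7 * n_pts
        if near and terminal and idx[1] - idx[0] >= 2:
            pts = pts[idx[0] : idx[1] + 1]
            # pin the terminal vertices to the (sub-grid) mode positions so
            # the ell origin and scale do not depend on the walk's endpoints
            by_dist = sorted(ends, key=lambda e: np.linalg.norm(pts[0] - e))
            pts[0], pts[-1] = by_dist[0], by_dist[1]
    else:
        # no bracketing modes: trim to where the data mass projects
        ell = _arc_length(pts)
        cell_ell = _project_to_polyline(z, pts, ell)[0]
        lo_q, hi_q = np.quantile(cell_ell, [0.005, 0.995])
        keep = (ell >= lo_q - 1e-12) & (ell <= hi_q + 1e-12)
        if keep.sum() >= 2:
            pts = pts[keep]

    # orient: ell = 0 at the early-G1 end (low DNA, low Geminin)
    if np.sum(pts[0]) > np.sum(pts[-1]):
        pts = pts[::-1]
    ell = _arc_length(pts)
    return TrajectoryCurve(points=pts * scale + center, ell=ell, center=center, scale=scale)


def _project_to_polyline(z: np.ndarray, verts: np.ndarray, ell: np.ndarray):
    """Nearest point on the polyline for each row of ``z``.

    Returns (ell_values, distances). Ties between segments resolve to the
    smaller arc length (segments are scanned in increasing ell and only a
    strictly smaller distance replaces the incumbent).
    """
    a = verts[:-1]
    b = verts[1:]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2 = np.where(ab2 == 0, 1e-300, ab2)
    best_d2 = np.full(z.shape[0], np.inf)
    best_ell = np.zeros(z.shape[0])
    seg_ell = np.diff(ell)
    for i in range(a.shape[0]):
        t = np.clip(((z - a[i]) @ ab[i]) / ab2[i], 0.0, 1.0)
        proj = a[i] + t[:, None] * ab[i]
        d2 = np.einsum("ij,ij->i", z - proj, z - proj)
        closer = d2 < best_d2 - 1e-15
        best_d2[closer] = d2[closer]
        best_ell[closer] = ell[i] + t[closer] * seg_ell[i]
    return best_ell, np.sqrt(best_d2)


def project_cells(curve: TrajectoryCurve, cells: pd.DataFrame) -> pd.DataFrame:
    """Project cells onto the trajectory; adds ``ell`` and ``ell_distance``.

    Distances are computed in the curve's z-scored channel units; the
    reported distance supports QC of poorly fitting cells.
    """
    x = _features(cells)
    z = (x - curve.center) / curve.scale
    ell, dist = _project_to_polyline(z, curve.z_points, curve.ell)
    out = cells.copy()
    out["ell"] = ell
    out["ell_distance"] = dist
    return out


def ell_size_heatmap(
    cells: pd.DataFrame,
    feature: str,
    normalize_by_size: bool = False,
    n_ell_bins: int = 12,
    n_size_bins: int = 12,
    min_cells_per_bin: int = 20,
) -> pd.DataFrame:
    """Joint (ell, size) density with a per-bin mean of ``feature``.

    Size bins are logarithmic (cell size spans a twofold-plus range);
    ``normalize_by_size`` divides the feature per cell by its SE size
    before averaging (flux per unit mass). Bins with fewer than
    ``min_cells_per_bin`` cells report NaN for the statistic. Returns a
    long-format table (ell_bin, size_bin, bin centers, density, stat).
    """
    for col in ("ell", "size_se", feature):
        if col not in cells.columns:
            raise ValueError(f"missing required column {col!r}")
    df = cells[["ell", "size_se", feature]].dropna()
    if df.empty:
        raise ValueError("no finite cells for the heatmap")
    vals = df[feature].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite values in feature {feature!r}")
    if normalize_by_size:
        vals = vals / df["size_se"].to_numpy(dtype=float)
    ell_edges = np.linspace(0.0, 1.0, n_ell_bins + 1)
    log_size = np.log(df["size_se"].to_numpy(dtype=float))
    size_edges = np.linspace(log_size.min(), log_size.max() + 1e-9, n_size_bins + 1)
    i = np.clip(np.digitize(df["ell"], ell_edges) - 1, 0, n_ell_bins - 1)
    j = np.clip(np.digitize(log_size, size_edges) - 1, 0, n_size_bins - 1)
    count = np.zeros((n_ell_bins, n_size_bins))
    total = np.zeros((n_ell_bins, n_size_bins))
    np.add.at(count, (i, j), 1)
    np.add.at(total, (i, j), vals)
    with np.errstate(invalid="ignore"):
        stat = np.where(count >= min_cells_per_bin, total / np.maximum(count, 1), np.nan)
    density = count / count.sum()
    ii, jj = np.meshgrid(np.arange(n_ell_bins), np.arange(n_size_bins), indexing="ij")
    return pd.DataFrame(
        {
            "ell_bin": ii.ravel(),
            "size_bin": jj.ravel(),
            "ell_center": 0.5 * (ell_edges[ii] + ell_edges[ii + 1]).ravel(),
            "log_size_center": 0.5 * (size_edges[jj] + size_edges[jj + 1]).ravel(),
            "density": density.ravel(),
            "stat": stat.ravel(),
            "n_cells": count.ravel().astype(int),
        }
    )
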