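"""Agent-based generative model of single-cell growth, division and turnover.

The simulator stands in for a fixed-cell high-content imaging experiment on
an asynchronously proliferating epithelial population. Each cell carries a
mass ``M`` (total protein, measured by SE staining), a cell-cycle phase with
DNA and Geminin reporter dynamics, and a K48-polyubiquitin pool ``U`` fed by
the proteasome flux. Per unit mass, the degradation flux is

    d(M) = d0 * (M / M_target)^beta * (1 + gain * A)

where ``beta`` is the compensation exponent (``beta = 0``: flux exactly
proportional to mass) and ``A`` is a low-pass-filtered relative size excess
modelling the *delayed* activation of compensatory degradation in oversized
cells. Mass evolves as ``dM/dt = [s - d(M)] * M`` (exponential-Euler
integration, exact for constant rates).

Cell-cycle structure: G1 exit follows a size-checkpoint hazard
``lambda(M) = k * max(0, M/M_target - theta)`` (small cells wait longer);
the G1/S, S and G2+M phases are Gamma-distributed timers. Division halves
mass with asymmetry noise. A configured G1-duration multiplier ``m`` is
applied as an exact time dilation of the exit process: the hazard is
evaluated at ``M_birth * (M / M_birth)^(1/m)`` and divided by ``m``, which
scales the realized G1 duration by ``m`` for exponentially growing cells.

Three emitters produce the canonical tables: :func:`simulate_snapshot`
(per-cell feature tables with replicate-well structure and optional CFZ /
CHX pre-fixation windows), :func:`simulate_tracks` (time-lapse nuclear-area
and Geminin series with landmark times) and :func:`simulate_bulk` (cell
counts and mean sizes over a treatment time course). All include ground
truth columns (``true_*``) for testing.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Perturbation, SimConfig

__all__ = [
    "SimulationError",
    "CellState",
    "PHASES",
    "step_cell",
    "degradation_flux",
    "simulate_snapshot",
    "simulate_k48_experiment",
    "simulate_tracks",
    "simulate_bulk",
    "exponential_counts",
    "simulate_chx_chase",
]

# phase codes; labels match the staging vocabulary
G1, G1S, S, G2M = 0, 1, 2, 3
PHASES = ("G1", "G1/S", "S", "G2+M")
_PHASE_CODE = {name: i for i, name in enumerate(PHASES)}

_AREA_SCALE = 300.0  # a.u.; nuclear area at target mass
_MV151_SCALE = 0.1  # active-proteasome signal per unit mass
_MV151_BACKGROUND_SD = 2.0  # additive noise after background subtraction


class SimulationError(RuntimeError):
    pass


@dataclass
class CellState:
    """State of a single simulated cell (scalar convenience wrapper)."""

    mass: float
    phase: str = "G1"
    phase_age: float = 0.0
    dna: float = 100.0
    geminin: float = 3.0
    k48_pool: float = 0.0
    mass_at_birth: float | None = None
    activation: float = 0.0
    phase_duration: float = np.inf


@dataclass(frozen=True)
class _Pars:
    """Per-condition resolved rate parameters."""

    s: float
    d0: float
    beta: float
    gain: float
    t_act: float
    target: float
    k_chk: float
    theta: float
    m_g1: float
    g1s_mean: float
    s_mean: float
    g2m_mean: float
    dur_cv: float
    asym_cv: float
    gem_rate: float
    gem_k_on: float
    gem_sat: float
    gem_base: float
    k_turn: float
    f_nascent: float
    g1s_boost: float
    g1_boost: float
    comp_g1_only: bool
    clearance: float
    growth_mult: float
    synthesis_mult: float
    dna_2n: float
    ramp_a: float


def _resolve(cfg: SimConfig, condition: str) -> _Pars:
    cfg.validate()
    p: Perturbation = cfg.condition(condition)

    def override(value, default):
        return default if value is None else value

    return _Pars(
        s=cfg.synthesis_rate_per_mass,
        d0=cfg.basal_degradation_per_mass,
        beta=override(p.compensation_exponent, cfg.compensation_exponent),
        gain=override(p.activation_gain, cfg.activation_gain),
        t_act=cfg.activation_time_h,
        target=cfg.target_size * p.target_size_mult,
        k_chk=cfg.g1_checkpoint_strength,
        theta=cfg.g1_size_threshold,
        m_g1=p.g1_duration_mult,
        g1s_mean=cfg.g1s_duration_h * p.g1s_duration_mult,
        s_mean=cfg.s_duration_h * p.s_duration_mult,
        g2m_mean=cfg.g2m_duration_h * p.g2m_duration_mult,
        dur_cv=cfg.phase_duration_cv,
        asym_cv=cfg.division_asymmetry_cv,
        gem_rate=cfg.geminin_rate,
        gem_k_on=cfg.geminin_onset_rate,
        gem_sat=cfg.geminin_onset_sat,
        gem_base=cfg.geminin_baseline,
        k_turn=cfg.k48_pool_turnover,
        f_nascent=override(p.nascent_fraction, cfg.nascent_fraction),
        g1s_boost=override(p.g1s_degradation_boost, cfg.g1s_degradation_boost),
        g1_boost=p.g1_degradation_boost,
        comp_g1_only=p.compensation_g1_only,
        clearance=p.clearance_mult,
        growth_mult=p.growth_mult,
        synthesis_mult=p.synthesis_mult,
        dna_2n=cfg.dna_2n,
        ramp_a=cfg.dna_ramp_sharpness,
    )


def _gamma_durations(rng: np.random.Generator, mean: float, cv: float, size: int):
    """Gamma-distributed timer durations with the requested mean and CV."""
    if cv <= 0:
        return np.full(size, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size)


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def _dna_ramp(u: np.ndarray, a: float) -> np.ndarray:
    """S-phase replication progress in [0, 1] as a function of phase fraction.

    Fast near entry and exit, slow mid-S, so that the DNA histogram keeps
    well-separated 2N/4N shoulders (atanh-shaped ramp; ``a`` sets sharpness).
    """
    w = np.clip(2.0 * np.asarray(u, dtype=float) - 1.0, -1.0, 1.0)
    return 0.5 * (1.0 + np.arctanh(w * np.tanh(a)) / a)


def _true_dna(state: dict, pars: _Pars) -> np.ndarray:
    dna = np.full(state["M"].shape, pars.dna_2n)
    in_s = state["phase"] == S
    if in_s.any():
        u = state["age"][in_s] / state["dur"][in_s]
        dna[in_s] = pars.dna_2n * (1.0 + _dna_ramp(u, pars.ramp_a))
    dna[state["phase"] == G2M] = 2.0 * pars.dna_2n
    return dna


def _per_mass_deg(state: dict, pars: _Pars, chx: bool = False) -> np.ndarray:
    """Degradation flux per unit mass for every cell in the state."""
    rel = state["M"] / pars.target
    size_factor = rel**pars.beta * (1.0 + pars.gain * state["A"])
    if pars.comp_g1_only:
        size_factor = np.where(state["phase"] <= G1S, size_factor, 1.0)
    d = pars.d0 * pars.clearance * size_factor
    d = np.where(state["phase"] == G1S, d * pars.g1s_boost, d)
    if pars.g1_boost != 1.0:
        d = np.where(state["phase"] <= G1S, d * pars.g1_boost, d)
    if chx:
        d = d * (1.0 - pars.f_nascent)
    return d


def degradation_flux(
    mass, cfg: SimConfig, condition: str = "control", phase: str = "G1", activation=0.0
):
    """Instantaneous proteasome flux (a.u./h) for a cell of the given mass."""
    pars = _resolve(cfg, condition)
    mass = np.asarray(mass, dtype=float)
    per_mass = (
        pars.d0
        * pars.clearance
        * (mass / pars.target) ** pars.beta
        * (1.0 + pars.gain * np.asarray(activation))
    )
    if phase == "G1/S":
        per_mass = per_mass * pars.g1s_boost
    if phase in ("G1", "G1/S"):
        per_mass = per_mass * pars.g1_boost
    return pars.growth_mult * per_mass * mass


_CHECK_FIELDS = ("M", "U", "gem", "A")


def _check_finite(state: dict) -> None:
    for name in _CHECK_FIELDS:
        if not np.all(np.isfinite(state[name])):
            raise SimulationError(f"non-finite value in simulation field {name!r}")


def _new_state(mass: np.ndarray, pars: _Pars, t0: float = 0.0) -> dict:
    n = mass.size
    return {
        "M": mass.astype(float).copy(),
        "M_birth": mass.astype(float).copy(),
        "U": pars.growth_mult * pars.clearance * pars.d0 * mass / pars.k_turn,
        "A": np.zeros(n),
        "gem": np.full(n, pars.gem_base),
        "phase": np.zeros(n, dtype=np.int8),
        "age": np.zeros(n),
        "dur": np.full(n, np.inf),
        "birth_t": np.full(n, t0),
        "g1s_t": np.full(n, np.nan),
        "div_t": np.full(n, np.nan),
        "aha": np.zeros(n),
        "cfz_excess": np.zeros(n),
        "t": t0,
    }


def _step(
    state: dict,
    pars: _Pars,
    dt: float,
    rng: np.random.Generator,
    *,
    cfz: bool = False,
    chx: bool = False,
    aha_on: bool = False,
    branch: bool = False,
    freeze_divided: bool = False,
) -> None:
    """Advance all cells by one Euler step of length ``dt`` (hours).

    ``branch`` appends the second daughter at division (growing population);
    ``freeze_divided`` stops updating cells whose division was recorded
    (used for single-cycle tracks).
    """
    M = state["M"]
    n = M.size
    alive = ~np.isfinite(state["div_t"]) if freeze_divided else np.ones(n, bool)

    rel = M / pars.target
    per_mass_deg = _per_mass_deg(state, pars, chx=chx)
    per_mass_syn = 0.0 if chx else pars.s * pars.synthesis_mult

    syn_flux = pars.growth_mult * per_mass_syn * M
    deg_flux = pars.growth_mult * per_mass_deg * M
    if cfz:
        # proteasome blocked: no clearance of mass nor of the K48 pool
        net_per_mass = pars.growth_mult * per_mass_syn
        new_U = state["U"] + deg_flux * dt
        state["cfz_excess"] = np.where(
            alive, state.get("cfz_excess", 0.0) + deg_flux * dt, state.get("cfz_excess", 0.0)
        )
    else:
        net_per_mass = pars.growth_mult * (per_mass_syn - per_mass_deg)
        # exact relaxation toward flux/k_turn for piecewise-constant flux
        decay = np.exp(-pars.k_turn * dt)
        new_U = state["U"] * decay + (deg_flux / pars.k_turn) * (1.0 - decay)

    state["M"] = np.where(alive, M * np.exp(net_per_mass * dt), M)
    state["U"] = np.where(alive, new_U, state["U"])
    state["A"] = np.where(
        alive,
        state["A"] + (np.maximum(rel - 1.0, 0.0) - state["A"]) * (dt / pars.t_act),
        state["A"],
    )
    gem = state["gem"]
    onset = pars.gem_k_on * gem * np.maximum(1.0 - gem / pars.gem_sat, 0.0)
    linear = np.where(state["phase"] >= S, pars.gem_rate, 0.0)
    state["gem"] = np.where(
        alive & (state["phase"] >= G1S), gem + (onset + linear) * dt, gem
    )
    if aha_on:
        state["aha"] = np.where(alive, state["aha"] + syn_flux * dt, state["aha"])
    state["age"] = np.where(alive, state["age"] + dt, state["age"])
    state["t"] += dt
    t = state["t"]

    if chx:
        # protein synthesis is required for cycle progression (cyclin
        # turnover): CHX arrests phase transitions
        return

    # --- G1 exit: size-checkpoint hazard with exact duration dilation ---
    in_g1 = alive & (state["phase"] == G1)
    if in_g1.any():
        m = pars.m_g1
        if m == 1.0:
            m_eff = state["M"]
        else:
            mb = state["M_birth"]
            m_eff = mb * (state["M"] / mb) ** (1.0 / m)
        lam = pars.k_chk * np.maximum(m_eff / pars.target - pars.theta, 0.0)
        p_exit = -np.expm1(-lam * dt / m)
        exiting = in_g1 & (rng.random(n) < p_exit)
        n_exit = int(exiting.sum())
        if n_exit:
            state["phase"][exiting] = G1S
            state["age"][exiting] = 0.0
            state["dur"][exiting] = _gamma_durations(rng, pars.g1s_mean, pars.dur_cv, n_exit)
            state["g1s_t"][exiting] = t

    # --- timer phases ---
    for code, nxt, mean in ((G1S, S, pars.s_mean), (S, G2M, pars.g2m_mean)):
        done = alive & (state["phase"] == code) & (state["age"] >= state["dur"])
        n_done = int(done.sum())
        if n_done:
            state["phase"][done] = nxt
            state["age"][done] = 0.0
            state["dur"][done] = _gamma_durations(rng, mean, pars.dur_cv, n_done)

    # --- division ---
    dividing = alive & (state["phase"] == G2M) & (state["age"] >= state["dur"])
    n_div = int(dividing.sum())
    if n_div:
        state["div_t"][dividing] = t
        if not freeze_divided:
            frac = 0.5 * (1.0 + pars.asym_cv * rng.standard_normal(n_div))
            frac = np.clip(frac, 0.2, 0.8)
            m_mother = state["M"][dividing]
            u_mother = state["U"][dividing]
            if branch:
                sib = {
                    "M": m_mother * (1.0 - frac),
                    "M_birth": m_mother * (1.0 - frac),
                    "U": u_mother * (1.0 - frac),
                    "A": state["A"][dividing].copy(),
                    "gem": np.full(n_div, pars.gem_base),
                    "phase": np.zeros(n_div, dtype=np.int8),
                    "age": np.zeros(n_div),
                    "dur": np.full(n_div, np.inf),
                    "birth_t": np.full(n_div, t),
                    "g1s_t": np.full(n_div, np.nan),
                    "div_t": np.full(n_div, np.nan),
                    "aha": np.zeros(n_div),
                    "cfz_excess": np.zeros(n_div),
                }
            state["M"][dividing] = m_mother * frac
            state["M_birth"][dividing] = m_mother * frac
            state["U"][dividing] = u_mother * frac
            state["gem"][dividing] = pars.gem_base
            state["phase"][dividing] = G1
            state["age"][dividing] = 0.0
            state["dur"][dividing] = np.inf
            state["birth_t"][dividing] = t
            state["g1s_t"][dividing] = np.nan
            state["div_t"][dividing] = np.nan
            state["aha"][dividing] = 0.0
            state["cfz_excess"][dividing] = 0.0
            if branch:
                for key, arr in sib.items():
                    state[key] = np.concatenate([state[key], arr])


def step_cell(
    state: CellState,
    cfg: SimConfig,
    dt: float,
    condition: str = "control",
    rng: np.random.Generator | None = None,
    cfz: bool = False,
    chx: bool = False,
) -> CellState:
    """Advance a single cell by one integration step of ``dt`` hours."""
    if dt > 0.1:
        raise ValueError(f"dt must be <= 0.1 h, got {dt}")
    pars = _resolve(cfg, condition)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not np.isfinite(state.mass) or state.mass <= 0:
        raise SimulationError("non-finite or non-positive value in field 'mass'")
    vec = _new_state(np.array([state.mass]), pars)
    vec["phase"][0] = _PHASE_CODE[state.phase]
    vec["age"][0] = state.phase_age
    vec["gem"][0] = state.geminin
    vec["U"][0] = state.k48_pool
    vec["A"][0] = state.activation
    vec["dur"][0] = state.phase_duration
    vec["M_birth"][0] = (
        state.mass if state.mass_at_birth is None else state.mass_at_birth
    )
    _step(vec, pars, dt, rng, cfz=cfz, chx=chx)
    _check_finite(vec)
    return CellState(
        mass=float(vec["M"][0]),
        phase=PHASES[int(vec["phase"][0])],
        phase_age=float(vec["age"][0]),
        dna=float(_true_dna(vec, pars)[0]),
        geminin=float(vec["gem"][0]),
        k48_pool=float(vec["U"][0]),
        mass_at_birth=float(vec["M_birth"][0]),
        activation=float(vec["A"][0]),
        phase_duration=float(vec["dur"][0]),
    )


def _seed_rng(cfg: SimConfig, condition: str, *key: int) -> np.random.Generator:
    tag = zlib.crc32(condition.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(tag, *key)))


def _init_asynchronous(
    n: int, cfg: SimConfig, pars: _Pars, rng: np.random.Generator
) -> dict:
    """Desynchronized initial population, to be refined by burn-in."""
    g = max(pars.growth_mult * (pars.s * pars.synthesis_mult - pars.clearance * pars.d0), 1e-3)
    t_cycle = np.log(2.0) / g
    t_g1 = max(t_cycle - (pars.g1s_mean + pars.s_mean + pars.g2m_mean), 0.5)
    newborn = (
        cfg.newborn_size_frac
        * pars.target
        * _lognoise(rng, cfg.newborn_size_cv, n)
    )
    elapsed = rng.random(n) * t_cycle
    state = _new_state(newborn, pars)
    state["M"] = newborn * np.exp(g * elapsed)
    bounds = np.array([t_g1, t_g1 + pars.g1s_mean, t_g1 + pars.g1s_mean + pars.s_mean])
    phase = np.searchsorted(bounds, elapsed).astype(np.int8)
    state["phase"] = phase
    offsets = np.concatenate([[0.0], bounds])
    state["age"] = elapsed - offsets[phase]
    means = np.array([np.inf, pars.g1s_mean, pars.s_mean, pars.g2m_mean])
    timer = phase > G1
    if timer.any():
        draw = _gamma_durations(rng, 1.0, pars.dur_cv, int(timer.sum()))
        state["dur"][timer] = np.maximum(
            means[phase[timer]] * draw, state["age"][timer] + 0.1
        )
    since_g1s = np.maximum(elapsed - t_g1, 0.0)
    ratio = pars.gem_sat / pars.gem_base - 1.0
    logistic = pars.gem_sat / (1.0 + ratio * np.exp(-pars.gem_k_on * since_g1s))
    state["gem"] = np.where(
        phase >= G1S,
        logistic + pars.gem_rate * np.maximum(elapsed - t_g1 - pars.g1s_mean, 0.0),
        pars.gem_base,
    )
    state["U"] = pars.growth_mult * pars.clearance * pars.d0 * state["M"] / pars.k_turn
    state["birth_t"] = -elapsed
    return state


def _segment_flags(treat_h: float, cfg: SimConfig, cfz: bool, chx: bool):
    """Breakpoints of the treatment span with the active pre-fixation windows."""
    events = {treat_h}
    cfz_start = treat_h - cfg.cfz_block_min / 60.0 if cfz else np.inf
    chx_start = treat_h - cfg.chx_block_h if chx else np.inf
    aha_start = treat_h - cfg.aha_pulse_h
    for t in (cfz_start, chx_start, aha_start):
        if 0.0 < t < treat_h:
            events.add(t)
    cuts = sorted(events)
    segments = []
    t0 = 0.0
    for t1 in cuts:
        mid = 0.5 * (t0 + t1)
        segments.append(
            (t1 - t0, dict(cfz=mid >= cfz_start, chx=mid >= chx_start, aha_on=mid >= aha_start))
        )
        t0 = t1
    return segments


def simulate_snapshot(
    cfg: SimConfig,
    condition: str = "control",
    treat_h: float = 24.0,
    cfz: bool = False,
    chx: bool = False,
) -> pd.DataFrame:
    """Simulate one arm (n_wells replicate wells) of a fixed-cell experiment.

    The population is burned in under control conditions, switched to the
    perturbation for ``treat_h`` hours, exposed to the AHA pulse and the
    optional CHX / CFZ pre-fixation windows, then "fixed": every intensity
    is read out with multiplicative lognormal staining noise on top of a
    per-well staining effect. Returns a CellRecord table with ``true_*``
    ground-truth sidecar columns.
    """
    if cfg.cells_per_well < 50:
        raise ValueError(
            "cells_per_well must be >= 50 (density estimation downstream is "
            f"undefined for sparser wells), got {cfg.cells_per_well}"
        )
    pars = _resolve(cfg, condition)
    control = _resolve(cfg, "control")
    dt = cfg.dt_h
    # all wells of the arm advance as one vectorized population; the
    # replicate-well structure (ids, per-well staining effects) is applied
    # at read-out
    rng = _seed_rng(cfg, condition, int(cfz), int(chx), int(round(treat_h * 60)))
    n_total = cfg.n_wells * cfg.cells_per_well
    state = _init_asynchronous(n_total, cfg, control, rng)
    for _ in range(int(round(cfg.burn_in_h / dt))):
        _step(state, control, dt, rng)
    _check_finite(state)
    for hours, flags in _segment_flags(treat_h, cfg, cfz, chx):
        for _ in range(int(round(hours / dt))):
            _step(state, pars, dt, rng, **flags)
        _check_finite(state)
    return _read_out(state, pars, cfg, rng, condition, treat_h, cfz, chx)


def _cycle_position(state, pars) -> np.ndarray:
    """Position along the canonical (average) cell cycle, in hours.

    In a sizer model elapsed age is not a clean progression coordinate
    (G1 length varies with birth size by design), so the ground truth for
    pseudo-time checks is the position a cell's state corresponds to on
    the average cycle: mass-growth progress within G1, then scaled phase
    fractions through G1/S, S and G2+M.
    """
    g = max(pars.growth_mult * (pars.s * pars.synthesis_mult - pars.clearance * pars.d0), 1e-6)
    t_cycle = np.log(2.0) / g
    t_g1 = max(t_cycle - (pars.g1s_mean + pars.s_mean + pars.g2m_mean), 0.5)
    pos = np.zeros(state["M"].size)
    phase = state["phase"]
    in_g1 = phase == G1
    growth = np.log(np.maximum(state["M"] / state["M_birth"], 1.0)) / np.log(2.0)
    pos[in_g1] = t_g1 * np.clip(growth[in_g1] / (g * t_g1 / np.log(2.0)), 0.0, 1.0)
    frac = np.clip(state["age"] / np.where(np.isfinite(state["dur"]), state["dur"], 1.0), 0, 1)
    pos[phase == G1S] = t_g1 + frac[phase == G1S] * pars.g1s_mean
    pos[phase == S] = t_g1 + pars.g1s_mean + frac[phase == S] * pars.s_mean
    pos[phase == G2M] = (
        t_g1 + pars.g1s_mean + pars.s_mean + frac[phase == G2M] * pars.g2m_mean
    )
    return pos


def _read_out(state, pars, cfg, rng, condition, treat_h, cfz, chx):
    n = state["M"].size
    cpw = cfg.cells_per_well
    n_wells = n // cpw
    cv = cfg.staining_noise_cv

    def well_effect():
        # one multiplicative staining factor per well per channel
        return np.repeat(_lognoise(rng, cfg.well_effect_cv, n_wells), cpw)

    dna_true = _true_dna(state, pars)
    gem_true = state["gem"]
    mass = state["M"]
    active = pars.clearance > 0
    mv_true = _MV151_SCALE * mass * active
    deg_flux = pars.growth_mult * _per_mass_deg(state, pars) * mass
    stub = f"{condition}|t{treat_h:g}|cfz{int(cfz)}|chx{int(chx)}"
    well_ids = np.repeat([f"{stub}|w{w:02d}" for w in range(n_wells)], cpw)
    cell_ids = [f"{wid}:{i % cpw}" for i, wid in enumerate(well_ids)]
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "well_id": well_ids,
            "condition": condition,
            "fixation_time_h": float(treat_h),
            "cfz_flag": bool(cfz),
            "chx_flag": bool(chx),
            "dna": dna_true * well_effect() * _lognoise(rng, cv, n),
            "geminin": gem_true * well_effect() * _lognoise(rng, cv, n),
            "size_se": mass * well_effect() * _lognoise(rng, cv, n),
            "aha": state["aha"] * well_effect() * _lognoise(rng, cv, n),
            "k48": state["U"] * well_effect() * _lognoise(rng, cv, n),
            "mv151": mv_true * _lognoise(rng, cv, n)
            + rng.normal(0.0, _MV151_BACKGROUND_SD, n),
            "true_phase": [PHASES[c] for c in state["phase"]],
            "true_mass": mass,
            "true_dna": dna_true,
            "true_geminin": gem_true,
            "true_deg_flux": deg_flux,
            "true_cycle_age": state["t"] - state["birth_t"],
            "true_cycle_pos": _cycle_position(state, pars),
            "true_cfz_excess": state["cfz_excess"],
        }
    )


def simulate_k48_experiment(
    cfg: SimConfig,
    conditions: tuple[str, ...] = ("control",),
    treat_h: float = 24.0,
    chx: bool = False,
) -> pd.DataFrame:
    """Paired +/-CFZ arms for each condition (the ΔK48 well-pair design)."""
    frames = []
    for condition in conditions:
        for cfz in (False, True):
            frames.append(simulate_snapshot(cfg, condition, treat_h, cfz=cfz, chx=chx))
    return pd.concat(frames, ignore_index=True)


def simulate_tracks(
    cfg: SimConfig,
    condition: str = "control",
    n_tracks: int = 100,
    t_max_h: float = 80.0,
) -> pd.DataFrame:
    """Time-lapse tracks of newborn cells followed until their next division.

    Birth sizes are sampled from a fixed newborn distribution shared across
    conditions (the first tracked cycle starts from mothers grown before the
    perturbation took effect). Emits one row per retained frame with the
    nuclear-area proxy ``area ∝ (M / M_target)^(2/3)`` plus noise, and the
    landmark birth / G1-S / division times.
    """
    pars = _resolve(cfg, condition)
    rng = _seed_rng(cfg, condition, 7, n_tracks)
    dt = cfg.dt_h
    frame_h = cfg.frame_interval_min / 60.0
    steps_per_frame = int(round(frame_h / dt))
    if abs(steps_per_frame * dt - frame_h) > 1e-9:
        raise ValueError("frame_interval_min must be a multiple of the time step")
    newborn = (
        cfg.newborn_size_frac * pars.target * _lognoise(rng, cfg.newborn_size_cv, n_tracks)
    )
    state = _new_state(newborn, pars)
    n_frames = int(np.floor(t_max_h / frame_h)) + 1
    rows_t, rows_area, rows_gem, rows_id, rows_mass = [], [], [], [], []
    ids = np.arange(n_tracks)
    for f in range(n_frames):
        t = f * frame_h
        live = ~np.isfinite(state["div_t"])
        if f > 0:
            for _ in range(steps_per_frame):
                _step(state, pars, dt, rng, freeze_divided=True)
            _check_finite(state)
            # cells that divided during this interval contribute their final frame
            live = live  # recorded below for cells live at frame start
        idx = np.nonzero(live)[0]
        if idx.size == 0:
            break
        area_true = _AREA_SCALE * (state["M"][idx] / pars.target) ** (2.0 / 3.0)
        rows_t.append(np.full(idx.size, t))
        rows_area.append(area_true * _lognoise(rng, cfg.area_noise_cv, idx.size))
        rows_gem.append(state["gem"][idx] * _lognoise(rng, cfg.area_noise_cv, idx.size))
        rows_id.append(ids[idx])
        rows_mass.append(state["M"][idx])
    df = pd.DataFrame(
        {
            "track_id": np.concatenate(rows_id),
            "time_h": np.concatenate(rows_t),
            "nuclear_area": np.concatenate(rows_area),
            "geminin": np.concatenate(rows_gem),
            "true_mass": np.concatenate(rows_mass),
        }
    )
    landmarks = pd.DataFrame(
        {
            "track_id": ids,
            "birth_time_h": 0.0,
            "g1s_time_h": state["g1s_t"],
            "division_time_h": state["div_t"],
            "complete": np.isfinite(state["div_t"]),
        }
    )
    df = df.merge(landmarks, on="track_id")
    df["condition"] = condition
    return df.sort_values(["track_id", "time_h"], ignore_index=True)


def simulate_bulk(
    cfg: SimConfig,
    condition: str = "control",
    timepoints=(0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0),
) -> pd.DataFrame:
    """Bulk time course: cell counts and mean sizes at fixation times.

    Burn-in runs at constant population size; from t = 0 the population
    branches (both daughters kept) under the condition, so counts grow
    exponentially at the per-capita division rate. ``true_nu`` records the
    ground-truth per-cell mass accumulation rate (1/N) dM_total/dt.
    """
    timepoints = np.asarray(sorted(timepoints), dtype=float)
    if timepoints.size < 1 or timepoints[0] < 0:
        raise ValueError("timepoints must be non-negative")
    pars = _resolve(cfg, condition)
    control = _resolve(cfg, "control")
    rng = _seed_rng(cfg, condition, 11, timepoints.size)
    dt = cfg.dt_h
    state = _init_asynchronous(max(cfg.cells_per_well, 200), cfg, control, rng)
    for _ in range(int(round(cfg.burn_in_h / dt))):
        _step(state, control, dt, rng)
    _check_finite(state)
    records = []

    def record(t):
        n = state["M"].size
        mass = state["M"]
        net_flux = (
            pars.growth_mult
            * (pars.s * pars.synthesis_mult - _per_mass_deg(state, pars))
            * mass
        )
        count = n * _lognoise(rng, cfg.count_noise_cv, 1)[0]
        records.append(
            {
                "time_h": t,
                "cell_count": count,
                "mean_size": float(np.mean(mass * _lognoise(rng, cfg.staining_noise_cv, n))),
                "true_count": n,
                "true_mean_mass": float(mass.mean()),
                "true_nu": float(net_flux.mean()),
            }
        )

    t = 0.0
    for target_t in timepoints:
        while t < target_t - 1e-9:
            _step(state, pars, dt, rng, branch=True)
            t += dt
        _check_finite(state)
        record(target_t)
    df = pd.DataFrame.from_records(records)
    df["condition"] = condition
    return df


def exponential_counts(
    tau_h: float,
    timepoints,
    n0: float = 1000.0,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Closed-form exponential proliferation counts (BulkTimepoint table).

    A convenience generator for estimator calibration: counts follow
    ``N(t) = n0 * 2^(t / tau)`` with optional lognormal measurement noise.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    counts = n0 * 2.0 ** (timepoints / tau_h) * _lognoise(rng, noise_cv, timepoints.size)
    return pd.DataFrame(
        {"time_h": timepoints, "cell_count": counts, "mean_size": np.full(timepoints.size, 1.0)}
    )


def simulate_chx_chase(
    cfg: SimConfig,
    condition: str = "control",
    chase_times=(0.0, 1.5, 3.0, 6.0, 9.0),
    treat_h: float = 24.0,
) -> pd.DataFrame:
    """Cycloheximide-chase snapshots: synthesis halted for the last
    ``chase`` hours before fixation, one table per chase time, with
    ``fixation_time_h`` recording the chase duration."""
    frames = []
    for chase in chase_times:
        c = cfg.replace(chx_block_h=max(chase, 1e-6))
        snap = simulate_snapshot(c, condition, treat_h, cfz=False, chx=chase > 0)
        snap["fixation_time_h"] = float(chase)
        snap["well_id"] = snap["well_id"] + f"|chase{chase:g}"
        frames.append(snap)
    return pd.concat(frames, ignore_index=True)
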