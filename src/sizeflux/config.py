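"""Simulation and pipeline configuration.

`SimConfig` is the full generative parameterization of the synthetic
imaging experiment: single-cell growth and degradation rates, cell-cycle
structure, reporter dynamics, staining noise, plate layout, and the named
drug perturbation arms. Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = ["Perturbation", "SimConfig", "default_perturbations"]


@dataclass(frozen=True)
class Perturbation:
    """Multipliers a condition applies on top of the control parameterization.

    ``None`` for the optional overrides means "inherit the config default".
    ``growth_mult`` scales the *net* specific growth rate (synthesis minus
    degradation), so a planted value is recovered exactly by the track
    estimators; ``synthesis_mult`` scales synthesis only (an mTOR-inhibitor
    style perturbation).
    """

    g1_duration_mult: float = 1.0
    g1s_duration_mult: float = 1.0
    s_duration_mult: float = 1.0
    g2m_duration_mult: float = 1.0
    synthesis_mult: float = 1.0
    growth_mult: float = 1.0
    target_size_mult: float = 1.0
    clearance_mult: float = 1.0
    compensation_exponent: Optional[float] = None
    activation_gain: Optional[float] = None
    g1s_degradation_boost: Optional[float] = None
    g1_degradation_boost: float = 1.0  # extra clearance in G1 and G1/S phases
    compensation_g1_only: bool = False  # size-dependent clearance confined to G1/G1-S
    nascent_fraction: Optional[float] = None


def default_perturbations() -> dict[str, Perturbation]:
    """Named perturbation arms emulating the drug treatments of the assay.

    - ``CDK2i``: longer G1 (x1.32) with compensatory degradation (higher
      compensation exponent plus delayed activation of clearance).
    - ``CDK46i``: reprogrammed, larger target size without compensation.
    - ``barasertib`` / ``JNJ``: G2/M and S phase delays with compensation.
    - ``bortezomib``: proteasome fully inhibited (clearance zeroed).
    - ``mTORi``: proportional reduction of protein synthesis.
    """
    return {
        "control": Perturbation(),
        "CDK2i": Perturbation(
            g1_duration_mult=1.32, compensation_exponent=0.8, activation_gain=6.0
        ),
        "CDK46i": Perturbation(target_size_mult=1.40),
        "barasertib": Perturbation(
            g2m_duration_mult=2.5, compensation_exponent=0.8, activation_gain=6.0
        ),
        "JNJ": Perturbation(
            s_duration_mult=1.6, compensation_exponent=0.8, activation_gain=6.0
        ),
        "bortezomib": Perturbation(clearance_mult=0.0),
        "mTORi": Perturbation(synthesis_mult=0.7),
    }


@dataclass(frozen=True)
class SimConfig:
    """Generative parameterization of the synthetic high-content experiment.

    Rates are per hour, sizes/intensities in arbitrary units (a.u.).
    The degradation flux per unit mass is
    ``basal_degradation_per_mass * (M / target)^beta * (1 + gain * A)``
    where ``A`` is a low-pass-filtered relative size excess (the delayed
    activation of compensatory degradation) and ``beta`` the compensation
    exponent; ``beta = 0`` and ``gain = 0`` give flux exactly proportional
    to mass.
    """

    # growth / degradation
    synthesis_rate_per_mass: float = 0.0472  # 1/h
    basal_degradation_per_mass: float = 0.015  # 1/h
    compensation_exponent: float = 0.3  # beta >= 0
    target_size: float = 1000.0  # a.u. (SE scale)
    activation_gain: float = 0.0  # dimensionless
    activation_time_h: float = 14.0  # h, lag of compensatory activation

    # cell cycle structure
    g1_checkpoint_strength: float = 1.2  # 1/h per unit relative size excess
    g1_size_threshold: float = 0.65  # theta, fraction of target size
    g1s_duration_h: float = 1.3  # mean, h
    s_duration_h: float = 6.2  # mean, h
    g2m_duration_h: float = 3.0  # mean, h
    phase_duration_cv: float = 0.12
    division_asymmetry_cv: float = 0.04

    # reporters and noise
    staining_noise_cv: float = 0.06
    area_noise_cv: float = 0.05
    geminin_rate: float = 12.0  # a.u./h linear accumulation in S and G2+M
    geminin_onset_rate: float = 8.0  # 1/h, switch-like exponential onset at G1/S
    geminin_onset_sat: float = 22.0  # a.u., saturation of the onset burst
    geminin_baseline: float = 3.0  # a.u.
    dna_2n: float = 100.0  # a.u.
    dna_ramp_sharpness: float = 2.5  # S-phase 2N->4N ramp shape
    k48_pool_turnover: float = 6.0  # 1/h (pool half-life ~7 min)
    nascent_fraction: float = 0.4  # CHX-sensitive share of degradation
    g1s_degradation_boost: float = 1.4  # G1/S degradation hyperactivity

    # assay windows
    cfz_block_min: float = 30.0  # proteasome blockade before fixation
    chx_block_h: float = 3.0  # CHX pre-fixation window
    aha_pulse_h: float = 3.0  # AHA labeling pulse

    # plate / sampling structure
    n_wells: int = 9
    cells_per_well: int = 300
    well_effect_cv: float = 0.02  # well-to-well staining variation
    count_noise_cv: float = 0.0  # measurement noise on bulk counts
    frame_interval_min: float = 15.0
    newborn_size_frac: float = 0.57  # mean newborn size / target size
    newborn_size_cv: float = 0.12
    burn_in_h: float = 30.0
    dt_h: float = 0.05
    seed: int = 0

    perturbations: Mapping[str, Perturbation] = field(
        default_factory=default_perturbations
    )

    def validate(self) -> None:
        """Raise ``ValueError`` on an inconsistent parameterization."""
        nonneg = (
            "synthesis_rate_per_mass",
            "basal_degradation_per_mass",
            "compensation_exponent",
            "activation_gain",
            "g1_checkpoint_strength",
            "phase_duration_cv",
            "division_asymmetry_cv",
            "staining_noise_cv",
            "area_noise_cv",
            "well_effect_cv",
            "count_noise_cv",
            "nascent_fraction",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        positive = (
            "target_size",
            "g1s_duration_h",
            "s_duration_h",
            "g2m_duration_h",
            "cfz_block_min",
            "dt_h",
            "k48_pool_turnover",
            "frame_interval_min",
            "activation_time_h",
            "dna_2n",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.dt_h > 0.1:
            raise ValueError(f"dt_h must be <= 0.1 h, got {self.dt_h}")
        if self.nascent_fraction > 1:
            raise ValueError("nascent_fraction must be in [0, 1]")
        if self.n_wells < 1 or self.cells_per_well < 1:
            raise ValueError("n_wells and cells_per_well must be >= 1")

    def condition(self, name: str) -> Perturbation:
        """Look up a perturbation arm; 'control' is always defined."""
        if name == "control" and name not in self.perturbations:
            return Perturbation()
        try:
            return self.perturbations[name]
        except KeyError:
            known = ", ".join(sorted(self.perturbations))
            raise KeyError(f"unknown condition {name!r}; known: {known}") from None

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)
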