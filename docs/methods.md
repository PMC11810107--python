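# Methods

`sizeflux` analyses size-dependent compensatory growth in proliferating
mammalian cells: the observation that cells forced to overgrow (e.g. by a
low-dose CDK2 inhibitor that prolongs G1) later slow their mass
accumulation, and that this slowdown is carried by a superlinear increase
in proteasome-mediated protein degradation rather than by reduced protein
synthesis. The package contains (i) estimators for the quantities such a
study measures and (ii) a generative model of the underlying single-cell
biology that produces feature tables with known ground truth, so every
estimator can be validated by recovery of planted effects.

## Generative model (`sizeflux.simulate`)

Each cell carries a protein mass `M` (a.u., measured in the assay by
integrated succinimidyl-ester intensity), a cell-cycle phase with reporter
states, a K48-polyubiquitin pool `U`, and a slow "activation" variable
`A`.

**Growth law.** `dM/dt = [s − d(M)] · M` with synthesis rate per unit
mass `s` (default 0.0472 /h) and degradation per unit mass

    d(M) = d0 · (M / M_target)^β · (1 + gain · A),

`d0 = 0.015 /h`, target size `M_target = 1000 a.u.`. The compensation
exponent `β` makes large cells degrade disproportionately (β = 0: flux
exactly proportional to mass; control default β = 0.3, compensating arms
0.8). `A` is a low-pass filter (time constant 14 h) of the relative size
excess `max(0, M/M_target − 1)`; with a positive `gain` it implements the
*delayed* activation of degradation seen in compensating cells: an
instantaneous size-dependent rate constant alone cannot produce a ~30%
flux increase at a ~3% size increase, whereas a slow activation variable
that integrates the transient overgrowth can, and it also reproduces the
observed latency (flux near control at 1–8 h of treatment, elevated at
24 h). Integration is exponential-Euler at `dt = 0.05 h` (exact for
constant rates, first-order for state-dependent ones). Whether
compensation acts on the degradation rate constant (as modelled) or on
ubiquitination supply is not distinguishable from these data; the model
exposes it on the rate constant only.

**Cell cycle.** G1 exit is a size checkpoint: hazard
`λ(M) = k · max(0, M/M_target − θ)` with `k = 1.2 /h`, `θ = 0.65`, so
small newborns wait longer in G1. G1/S, S and G2+M are Gamma-distributed
timers (means 1.3, 6.2, 3.0 h; CV 0.12). Division halves mass with 4%
asymmetry noise. At stationarity this yields a ~21.5 h cycle with a
~11 h G1 and a stable newborn-size CV of ≈ 0.12 — the checkpoint and the
β > 0 compensation together make the lineage birth-size map mean
reverting. A configured G1-duration multiplier `m` (the CDK2-inhibitor
arm uses 1.32, i.e. +32%) is applied as an exact time dilation of the
exit process: the hazard is evaluated at `M_birth (M/M_birth)^{1/m}` and
divided by `m`, which multiplies the realized G1 duration by exactly `m`
for exponentially growing cells (verified to ratio 1.319 at n = 20,000).
With β > 0 the sizer feedback compounds the extension slightly, as it
should biologically.

**Reporters and readouts.**
- DNA: 2N (100 a.u.) in G1/G1-S, ramping to 4N through S along an
  atanh-shaped profile (fast at the S borders, slow mid-S, sharpness 2.5)
  so the DNA histogram keeps clean 2N/4N shoulders; 4N in G2+M.
- Geminin: baseline 3 a.u. in G1; at the G1/S transition a switch-like
  logistic onset (rate 8 /h, saturation 22 a.u. — APC/C inactivation is
  fast), then linear accumulation (12 a.u./h) through S and G2+M; reset
  at division.
- K48 pool: `dU/dt = flux − k_turn · U` with `k_turn = 6 /h` (pool
  half-life ~7 min, realistic for proteasome substrates), solved with the
  exact exponential update. Under carfilzomib (CFZ) clearance is frozen
  and the pool accumulates the integral of the flux; the planted 30-min
  excess is recorded per cell as ground truth. A slow pool would make the
  ΔK48 assay itself ~3% biased (the pool lags a growing flux), which the
  fast turnover removes.
- Nuclear area (tracks): `area ∝ (M/M_target)^{2/3}` with 5% frame
  noise; area is a 2-D section of a volume-like mass, and the exact
  exponent is immaterial to the estimators tested.
- AHA: integral of the synthesis flux over a 3-h pulse; MV151 (active
  proteasome): proportional to `M`, zeroed under bortezomib, with
  additive background noise (values may be negative after background
  subtraction).
- Staining noise: multiplicative lognormal, CV 6% per channel, plus a 2%
  per-well staining effect. Replicate wells of one arm are simulated as
  one vectorized population and split into wells at read-out.
- CHX (cycloheximide): zeroes synthesis, removes the nascent
  (CHX-sensitive) share of the degradation flux (default 40%), and
  arrests phase transitions (cycle progression requires translation).

**Perturbation arms** are multiplier sets on phase durations, synthesis,
net growth, target size and clearance: `CDK2i` (G1 ×1.32, β = 0.8,
activation gain 12), `CDK46i` (target size ×1.4, no compensation),
`barasertib`-like (G2+M ×2.5) and `JNJ`-like (S ×1.6) delays with
compensation, `bortezomib` (clearance 0), `mTORi` (synthesis ×0.7).
Custom arms can plant isolated effects (a pure growth multiplier, a pure
G1 dilation, a G1-confined compensation) for recovery tests.

**Emitters.** `simulate_snapshot` (fixed-cell CellRecord tables with
±CFZ/±CHX windows applied in the stated pre-fixation order),
`simulate_tracks` (per-frame area/Geminin at 15-min intervals with
birth, G1/S and division landmarks; birth sizes drawn from a fixed
newborn distribution shared across conditions, as in the first imaged
cycle after treatment onset), `simulate_bulk` (counts and mean sizes over
a treatment course; burn-in at constant N, then both daughters kept so
counts grow at the per-capita division rate), and `simulate_chx_chase`
(snapshots at chase times 0, 1.5, 3, 6, 9 h). All include `true_*`
ground-truth columns.

## Staging (`sizeflux.staging`)

Cells are partitioned by integrated DNA into G1 (2N), S (2N–4N) and G2+M
(4N), and the 2N class is split by log-Geminin into early G1 and the
G1/S transition. Thresholds come from 1-D binned KDEs (Silverman
bandwidth): the two outermost density modes with prominence ≥ 1.2% of
the peak are the 2N and 4N modes (prominence ignores the mid-S bump);
the cuts are the deepest valleys flanking each mode (coincident when the
distribution has a single interior valley, e.g. two clean Gaussians;
ties within 1% density break toward the mode midpoint; a single valley
with a clear interior bump triggers an explicit search for the second,
shallower valley). The Geminin cut is the log-scale valley between the
baseline mode and the accumulating population, falling back to
baseline-mode + 3×MAD when the valley is shallower than 10% of the
baseline peak. All thresholds are scale-equivariant by construction.
Mitotic cells are not separated from G2 (G2+M), matching the assay's
DNA-only resolution. With all-zero Geminin the 2N class is left merged
as "G1".

## Cell-cycle pseudo-time (`sizeflux.trajectory`)

An asynchronous population traces an arc in the (DNA, log Geminin) plane.
`fit_ridge` z-scores both channels (their scales are arbitrary and
unequal), builds a 2-D binned KDE (grid 200×200, Silverman bandwidth),
and walks the density ridge: starting from each of the strongest modes
(sub-grid refined), an initial direction is chosen as the densest ray,
then steps of half a bandwidth are pulled to the parabolic-refined
density maximum on the perpendicular segment, with a 55° per-step turn
cap, termination on loss of data support or density, and a stop when the
walk re-enters already-traced territory (U-turn guard). The longest
traced ridge is kept, resampled at uniform arc length, refined by three
principal-curve iterations (local data averaging), and anchored: when
two modes bracket the curve its endpoints are pinned to them (the
early-G1 mode is ℓ = 0, the 4N/high-Geminin end ℓ = 1). Degenerate
inputs (blobs) are rejected by three tests: walk length below the
bandwidth scale, persistent turn-cap saturation, and Hessian anisotropy
(median along-track/transverse curvature ratio > 0.35 means no ridge;
measured ≈ 0.5 for an isotropic blob vs 0.01–0.22 for true ridges).

`project_cells` assigns each cell the normalized arc length of its
nearest point on the polyline (z-scored units; ties resolve to the
smaller ℓ; distances reported for QC). ℓ orders cells by average cycle
progression — it is *not* wall-clock time, and phase durations are not
proportional to ℓ spans. Accordingly, pseudo-time quality is scored
against the canonical cycle position (mass-growth progress within G1,
scaled phase fractions after), not elapsed age: in a sizer model elapsed
age is confounded by intrinsic G1-duration variability, which caps the
rank correlation near 0.7 even for a perfect axis.

`ell_size_heatmap` bins cells on (ℓ, log size), reports the joint
density and a per-bin feature mean (optionally per unit size), masking
bins with fewer than 20 cells.

Known limitations: curve geometry is stable under grid refinement (95%
of arc-length labels shift < 0.02 when the grid is doubled), but
cell-level ℓ near the dense early-G1 endpoint can shift up to ~0.03 —
projection against a curve endpoint is intrinsically less stable; and
the KDE ridge is biased inward at high curvature by about one bandwidth
(the usual smoothing bias), so curve accuracy is asserted at the
bandwidth scale, not at grid resolution.

## Turnover statistics (`sizeflux.turnover`)

ΔK48-polyUb is the clearance rate of K48-linked polyubiquitinated
protein: the excess K48 signal accumulated during a 30-min proteasome
blockade, computed as the difference of well-level central K48 values
over every (+CFZ, −CFZ) well pair of a condition. Wells, not cells, are
the independent units (cells share staining and history). The central
estimate is the cross-pair mean (identical to the difference of arm
means); the CI is t-based over the pair values with effective
n = min(arm sizes) — cross pairs reuse wells, and the correction keeps
the CI from being anti-conservative. The within-well centre is the
median by default (robust to segmentation outliers) with the mean
exposed; recovery benchmarks use the mean, whose estimand is exactly the
planted mean flux.

`scaling_analysis` compares a perturbed arm with control: fold change in
ΔK48 against fold change in median size, their ratio (the *excess
ratio*; 1 = proportional scaling), and a one-sided bootstrap test
(resampling wells) for superlinearity. The bootstrap is preferred over a
delta-method normal approximation because well counts are small and
ratio distributions skewed. `g1s_deviation` fits ΔK48 against median
size on {G1, S, G2+M} and reports the G1/S residual with a well-bootstrap
CI — positive with a CI excluding zero under G1/S degradation
hyperactivity. `chx_decomposition` splits the flux into nascent
(CHX-sensitive) and long-lived shares; the measured share exceeds the
planted fraction by a small, predictable drift (the CHX-arrested arm
shrinks slightly over the window while the untreated steady-state arm
does not). `chx_chase_slopes` computes, per stage and timepoint, median
sizes of the sub-20th and supra-80th size percentiles as fractions of
the time-0 class median, and their least-squares loss rates.
`marker_size_fit` is an OLS of a marker on size with the Pearson r
(negative values allowed: background-subtracted signals).

## Growth inference (`sizeflux.growth`)

From bulk time courses: `fit_cycle_length` fits `log N_t` on `t`
(unweighted least squares in log space — count noise is multiplicative)
giving `α` and `τ = ln 2/α` (τ undefined with a diagnostic when
α ≤ 0); `bulk_growth_rate` forms `M_t = mean size × count` and
`ν_t = (1/N_t) dM/dt` by central differences (one-sided at the ends).

From tracks: growth rate is the central-difference derivative of the
moving-average-smoothed nuclear area (window 5 frames ≈ 75 min), with
the first and last 6 frames of each cycle discarded (nuclear envelope
breakdown/reformation) and only division-to-division tracks used. The
smoothing window of the original live-imaging analysis is not
documented; sensitivity across windows {3, 5, 9} is a one-line loop for
the user and is not resolved here. `align_tracks` averages tracks
anchored at birth or at the G1/S transition (grid points with < 10
tracks masked); `phase_durations` compares G1 and cycle lengths between
arms by Welch t-tests (variances differ between arms by design);
`percentile_growth_compare` contrasts mean trimmed growth rates of
small (≤20th birth-size percentile) versus large (≥80th) cells before or
after G1/S. Comparisons stay in nuclear-area units throughout; they are
never converted to mass.

## What the benchmarks do and do not show

The recovery tests (`tests/test_acceptance.py`, `scripts/acceptance.py`)
plant known effects under the defaults above and demand recovery at
stated tolerances: τ to machine precision without noise and < 2% mean
error at 5% count noise (7 timepoints, 100 seeds); the planted ΔK48
excess inside the estimator CI in ≥ 95% of 200 runs (9+9 wells);
superlinearity power ≥ 90% at the compensating arm and type-I ≤ 10% at a
proportional arm (100 runs each, α = 0.05); projection equal to a
brute-force nearest-point oracle and pseudo-time rank correlation > 0.9
on noiseless data; staging agreement ≥ 90% at default noise; the planted
−21% growth multiplier within 3% and the +32% G1 extension within its CI
over 100 tracks; and a planted ×1.4 G1/S flux boost detected while null
runs cover zero ≥ 90% of the time. Problem sizes (cells per well,
burn-in, run counts) are chosen so the full suite runs on a laptop-class
budget; they are stated in each test.

Passing these benchmarks shows the estimators are correct against this
generative model. Real imaging data differ in ways the model does not
emulate: segmentation errors and doublets, spatial/illumination
artifacts, density-dependent growth, cell death, non-lognormal staining
tails, and reporter silencing. The pipeline's robustness choices
(medians within wells, well-level inference, masked sparse bins) address
some of these, but parameter values recovered from real data should be
validated against orthogonal measurements.
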