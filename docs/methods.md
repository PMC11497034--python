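# Methods

## Conical-pore blockade model

The nanopipette tip is a truncated cone: local radius `r(x) = r_p + x·tanα`
at depth `x` into the pipette, filled with electrolyte of conductivity `κ`.
A translocating oligomer is modelled as a cylinder with the fixed aspect
ratio `L_o = 2 r_o`, coaxial with the pore and seated at the tip (`x = 0`),
where the cone is narrowest and the blockade maximal — only the maximal
depth `ΔI_max` of each pulse is analysed, so the axial position is not a
free parameter. The particle's excess resistance is the difference between
the annular channel `r_o < r < r(x)` and the open cone over the particle
length (the integral in the README); in series with the open-pore resistance
`1/G` it gives

    ΔI_max/I₀ = R_max / (1/G + R_max)  ∈ [0, 1).

This form is bounded, vanishes with the particle and is strictly increasing
in `r_o`, which guarantees a unique inversion. Assumptions: the particle is
coaxial (no off-axis or tilted orientations), singly occupying the sensing
zone, and surface-charge corrections to the conductance are neglected.

*Numerics.* The integral has the closed form
`[atanh(r_o/u)/r_o − 1/u]` evaluated between `u = r_p` and
`u = r_p + 2 r_o tanα` (up to the `1/(κπ tanα)` prefactor). For
`r_o < 0.1 r_p` the two terms cancel catastrophically in floating point, so
the implementation switches to the series
`Σ_k r_o^{2k}/(2k+1) (u₀^{−(2k+1)} − u₁^{−(2k+1)})` (8 terms, relative
truncation error < 1e-16 at the branch point). Both branches are tested
against adaptive quadrature of the raw integrand to 1e-6 relative error.
Inversion is bisection on `r_o ∈ [1e-3, 0.99 r_p]` nm to 1e-4 nm; blockades
above the value at `0.99 r_p` raise a saturation error that quotes the
bound. Units are nm, S/m and nS throughout; with these choices the integral
is numerically in GΩ and `1/G` (nS⁻¹) likewise, so no conversion constants
appear.

*Tip sizing.* `r_p = (G/κ)(1/(π tanα) + 1/4)`: the cone-body resistance
`1/(κπ r_p tanα)` in series with the access resistance `1/(4 κ r_p)` at the
mouth, inverted for `r_p`. `G/κ` in nS/(S/m) is directly nm.

*Detectability.* Oligomer diameters between `r_p` and `2 r_p` are reported
as the detection window: smaller particles fall below the noise floor,
larger ones cannot enter the tip. A set of pipettes of different diameters
tiles a wide volume range.

## Event detection

Traces are low-passed with a zero-phase (forward–backward) order-1
Butterworth filter at 20 kHz (0.1 × Nyquist at the 200 kHz acquisition
rate). The baseline is an order-1 Savitzky–Golay smooth; because a linear
least-squares fit evaluated at the centre of a symmetric window equals the
window mean, it is computed as an O(N) centred moving average with
linear-fit edge windows — algebraically identical to the direct O(N·W)
filter, which is intractable at the default window of 50 001 samples
(0.25 s at 200 kHz, chosen ≫ any event duration so drift is tracked but
events are not absorbed). The noise scale is `σ = 1.4826 × MAD` of the
baseline residual, robust to event contamination.

Events are maximal runs deviating beyond `k·σ` (default `k = 4`) in the
blockade direction — toward zero current, inferred from the baseline sign
and overridable — extended outward to the nearest 1σ crossing, merged
across gaps ≤ 5 samples, and discarded below 2 samples duration. `I₀` for
`ΔI/I₀` is the baseline at the event peak, robust to drift. On
20 kHz-filtered Gaussian noise a 4σ threshold still yields a few short
false-positive runs per second because the filtered noise is correlated
over ~10 samples; analyses that require a clean event list should raise the
minimum duration to a fraction of the expected dwell time (the recovery
tests use 0.2 ms against 1 ms pulses). Sub-state fitting, CUSUM/HMM
segmentation and dwell-time physics are out of scope.

## Burst analysis

Photon traces are binned at 10 ms. The baseline level and σ are estimated
in two passes (median + MAD, second pass on sub-threshold bins only), with
σ floored at `sqrt(level)` — the Poisson shot-noise scale — so sparse
traces with zero MAD still get a finite threshold. Bursts are runs above
`baseline + 4σ`, extended to the return to the baseline level ("peak
base"), with single-bin gaps merged (blinking tolerance). Each burst
reports peak intensity, base duration and area (photons above baseline);
per-trace summaries give bursts s⁻¹ and a dwell-time histogram on 20
log-spaced bins per decade over 0.01–100 s (out-of-range dwell times are
clipped into the outer bins so histogram mass equals burst count).

Dwell times are classified against the bead calibration: 0.1–1 s ↔
100–200 nm, 1–10 s ↔ 350–500 nm; a fibril-like class covers [0.05, 0.1) s —
the sub-0.1 s dwell of isolated 150–250 nm fibrils — kept disjoint from the
bead classes. Burst intensity is deliberately not used for sizing (it
confounds ThT load, conformation and trajectory); only the dwell time is
interpreted.

## Kinetics

Each replicate ThT curve is fitted separately with the four-parameter
Boltzmann sigmoid (evaluated through the logistic function for
overflow-free arithmetic); T50 values are then averaged per condition —
pooling replicates before fitting is available but not the default. The
slope parameter `τ` is essential: without it the exponent is dimensionally
inconsistent and 10-min-sampled data cannot be fitted. Initialisation uses
the first/last time-quartile means for the plateaus, the half-range
crossing for T50 and span/10 for τ; a fit is rejected as degenerate when
the first/last-quartile intensity ranges overlap (no transition) or the
fitted T50 leaves the observed span. `I_i` is not constrained to be
non-negative. Seeding efficiency is `100 (T50_ctrl − T50_seed)/T50_ctrl`,
reported raw and rounded to the nearest integer percent. Mechanistic
rate-law fitting (nucleation/elongation constants) is out of scope.

## Synthetic data

The generators define the conditions under which the pipeline is
validated; all are bit-reproducible from their seed.

*Current traces* — baseline `I₀ = G·V` (−500 mV default) plus linear and
sinusoidal drift plus white Gaussian noise; events are rectangular pulses at
Poisson arrival times with depths from the forward pore model and
log-normal (or log-uniform) volumes and dwell times; a causal 4-pole 10 kHz
Bessel filter emulates the acquisition electronics and rounds pulse edges.
Real traces additionally show 1/f noise, capacitive transients and
non-rectangular pulse shapes, so recovery results bound performance under
idealised event shapes only.

*Photon traces* — Euler–Maruyama Brownian motion (step = bin/10) of one
particle per requested diameter in a periodic box, detection probability
`exp(−2(x²+y²)/w_xy² − 2z²/w_z²)`, Poisson counts per bin. Defaults:
T = 298.15 K, η = 0.89 mPa·s (water), box 20 µm. The waists default to
w_xy = 2 µm, w_z = 6 µm with peak rate 1e6 photons/s on a 1e3 photons/s
background: with Stokes–Einstein diffusion these place 100–200 nm beads at
~0.5–0.8 s mean burst duration, inside the calibration decade, and keep
mean dwell strictly increasing over 100/200/350/500 nm. (A
diffraction-limited ~300 nm waist would give ~5 ms transits for 100 nm
beads — three orders below the calibrated decade — so the effective
detection region of the calibrated instrument is evidently much larger than
the optical waist; the simulation models that effective region directly.)
Triplet blinking, bleaching and flow are not modelled.

*Kinetics* — the Boltzmann curve sampled every 10 min with additive
Gaussian noise (default σ = 3 a.u. on a 100 a.u. amplitude, i.e. 3%);
`t_max` must exceed `T50 + 4τ` so both plateaus are sampled.

## Validation problem sizes

End-to-end event recovery runs on 8 s of 200 kHz trace at ~8 events/s with
volumes log-uniform in [1e2, 1e4] nm³ and noise set so the smallest event
has SNR 8 (recovery ≥ 90%, median volume error ≤ 15%). The bead
calibration uses 4 particles × 3600 s per diameter; T50 recovery uses 50
replicates at 3% noise. Smaller sizes are used in unit tests where only
qualitative behaviour is asserted.

## Known limitations

The pore model ignores electroosmosis, electrophoretic capture bias and
surface conductance; volumes assume the fixed 2:1 cylindrical aspect ratio,
so elongated fibrils are systematically mis-sized. Burst durations from the
simulation depend on the chosen effective confocal volume, so the bead
calibration is reproduced qualitatively (ordering and decade placement),
not as absolute dwell values. Event dwell times carry no physical transport
model and should not be interpreted kinetically.
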