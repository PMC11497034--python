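# rtfast

Single-molecule analysis of amyloid-β (Aβ42) secondary nucleation. During
the lag phase of amyloid aggregation, seeds catalyse the formation of
oligomers that bulk thioflavin-T (ThT) fluorescence cannot resolve. This
package implements the analysis chain of a combined nanopipette / confocal
single-molecule assay for mapping those oligomers:

* **Nanopipette resistive pulses → oligomer volumes.** A conical nanopipette
  (tip radius `r_p`, half-cone angle `α`, electrolyte conductivity `κ`, open
  conductance `G`) detects oligomers as transient current blockades. An
  oligomer is modelled as a cylinder of radius `r_o` and length `L_o = 2 r_o`
  seated at the tip; the excess resistance of the annular channel it leaves,

  `R_max = ∫₀^{L_o} [ 1/(κπ((r_p + x·tanα)² − r_o²)) − 1/(κπ(r_p + x·tanα)²) ] dx`,

  yields the relative blockade `ΔI_max/I₀ = R_max / (G⁻¹ + R_max)`. The map
  is strictly monotone in `r_o`, so each measured blockade inverts to a
  unique volume `V = 2π r_o³` and size `2 r_o`. The tip radius itself is
  estimated from `r_p = (G/κ)(1/(π tanα) + 1/4)` (cone plus access
  resistance), and only oligomers with diameters between the pipette radius
  and diameter are detectable.
* **Event detection.** Traces (200 kHz, −500 mV) are low-passed with a
  zero-phase 20 kHz order-1 Butterworth filter, baseline-corrected with an
  order-1 Savitzky–Golay smooth, and thresholded at 4σ (robust MAD-based σ),
  with boundary extension, merging and minimum-duration rules; each event
  reports `Δt`, `ΔI` and `ΔI/I₀`.
* **Confocal fluorescence bursts.** ThT-positive aggregates crossing the
  confocal volume give photon bursts in 10 ms-binned traces; bursts are
  detected at 4σ over a robust Poisson baseline, characterised by peak
  intensity, base duration and area, summarised as bursts s⁻¹ and a
  log-binned dwell-time histogram, and classified against the latex-bead
  dwell calibration (0.1–1 s ↔ 100–200 nm, 1–10 s ↔ 350–500 nm).
* **Aggregation kinetics.** ThT microplate curves are fitted with the
  Boltzmann sigmoid `I(t) = I_f + (I_i − I_f)/(1 + exp((t − T50)/τ))`;
  seeding efficiency is the percent T50 reduction versus the unseeded
  control.
* **Synthetic data.** Seeded generators produce current traces (square
  pulses from the forward pore model on a noisy drifting baseline, optional
  10 kHz Bessel acquisition filter), photon traces (Brownian motion through
  a 3D-Gaussian confocal volume with Stokes–Einstein diffusion
  `D = k_B T/(3πηd)`, Poisson counting) and noisy Boltzmann kinetics — each
  with a ground-truth table, so every stage is validated end to end.

## Worked example

```python
import numpy as np
from rtfast import *

geom = PipetteGeometry(tip_radius_nm=15.0, half_cone_angle_rad=0.1,
                       conductivity_S_per_m=8.6, open_conductance_nS=37.7)
print("detectability window (nm):", detectability_window(geom))

pop = OligomerPopulation(components=(
    OligomerComponent(volume_median_nm3=2000.0, rate_per_s=5.0, volume_log_sd=0.4),))
trace, truth = simulate_current_trace(geom, pop, duration_s=5.0,
                                      noise_sigma_pA=8.0, drift_pA_per_s=2.0,
                                      drift_sine_amp_pA=10.0, seed=1)
filtered = lowpass_filter(trace)
baseline = estimate_baseline(filtered, window=50_001)
events = detect_events(filtered, baseline)
print(f"injected {int(truth['injected'].sum())} events, detected {len(events)}")
result = events_to_volume_map(events, geom, incubation_time_min=30.0)
print(result.table[["start_s", "dwell_s", "rel_blockade", "volume_nm3", "size_nm"]]
      .head(3).round(4))
```

prints

```
detectability window (nm): (15.0, 30.0)
injected 26 events, detected 26
   start_s  dwell_s  rel_blockade  volume_nm3  size_nm
0   0.0257   0.0008        0.0175   1954.3615  13.5510
1   0.3710   0.0011        0.0171   1911.5436  13.4513
2   0.4664   0.0013        0.0164   1841.9864  13.2861
```

i.e. all 26 injected translocations of a ~2000 nm³ oligomer population are
recovered, and inverting their relative blockades (~1.7 %) through the
conical-pore model returns volumes within a few percent of the injected
median — oligomer sizes of ~13.5 nm, inside the (15, 30) nm detection window
of this pipette. Kinetics work the same way:

```python
fit = fit_boltzmann(simulate_kinetics(T50_min=630.0, tau_min=40.0,
                                      noise_sigma=3.0, seed=2))
print(f"T50 = {fit.T50_min:.1f} min, tau = {fit.tau_min:.1f} min")
# T50 = 630.6 min, tau = 41.8 min
```

A control fitted at T50 = 630 min against a seeded condition at 427 min
gives `percent_t50_reduction(...) = 32%` — the seeding efficiency of
fragmented growth-phase seeds.

The same pipeline is scriptable from a shell:

```sh
rtfast simulate-trace --seed 1 --out run1
rtfast detect-events run1/trace.tsv --out run1
rtfast invert-volumes run1/events.csv --out run1
rtfast report run1 --out summary
```

Every command writes its resolved configuration next to its outputs;
re-running with the same config and seed is byte-identical.

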