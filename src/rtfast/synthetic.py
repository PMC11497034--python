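"""Synthetic data generators for the three experimental channels.

Every analysis stage in this package was designed against instrument output
(ionic-current traces, binned photon counts, microplate ThT kinetics).  The
generators here produce inputs with the same statistical structure together
with a ground-truth record per injected feature, so detection and inversion
can be validated end to end:

* ``simulate_current_trace`` — square translocation pulses on a noisy,
  drifting baseline, with depths computed from the conical-pore forward
  model, optionally smoothed by the 10 kHz acquisition Bessel filter.
* ``simulate_photon_trace`` — particles performing Brownian motion through a
  3D-Gaussian confocal volume with Stokes-Einstein diffusion, Poisson photon
  statistics per 10 ms bin.
* ``simulate_kinetics`` — Boltzmann-sigmoid ThT curves with additive
  Gaussian noise.

All generators are bit-reproducible from their ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.constants import k as BOLTZMANN_J_PER_K

from .event_detection import CurrentTrace, TranslocationEvent
from .burst_analysis import PhotonTrace
from .kinetics import KineticTrace, boltzmann
from .pore_model import (
    CylindricalOligomer,
    PipetteGeometry,
    relative_blockade,
)

__all__ = [
    "OligomerComponent",
    "OligomerPopulation",
    "ConfocalSetup",
    "simulate_current_trace",
    "simulate_photon_trace",
    "simulate_kinetics",
    "stokes_einstein_diffusion",
    "match_events",
]


@dataclass(frozen=True)
class OligomerComponent:
    """One log-normal oligomer population component.

    Volumes are log-normal around ``volume_median_nm3`` (sigma of ln V =
    ``volume_log_sd``) or, with ``volume_distribution="loguniform"``,
    log-uniform over ``volume_range_nm3``; translocation dwell times are
    log-normal around ``dwell_median_s``; events arrive as a Poisson process
    at ``rate_per_s``.
    """

    volume_median_nm3: float
    volume_log_sd: float = 0.5
    rate_per_s: float = 1.0
    dwell_median_s: float = 1e-3
    dwell_log_sd: float = 0.3
    volume_distribution: str = "lognormal"
    volume_range_nm3: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.volume_median_nm3 <= 0 or self.dwell_median_s <= 0:
            raise ValueError("medians must be > 0")
        if self.rate_per_s < 0:
            raise ValueError("rate must be >= 0")
        if self.volume_distribution not in ("lognormal", "loguniform"):
            raise ValueError("volume_distribution must be lognormal or loguniform")
        if self.volume_distribution == "loguniform":
            if self.volume_range_nm3 is None or not (
                0 < self.volume_range_nm3[0] < self.volume_range_nm3[1]
            ):
                raise ValueError("loguniform needs volume_range_nm3 = (low, high)")

    def sample_volumes(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.volume_distribution == "loguniform":
            lo, hi = self.volume_range_nm3
            return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        return np.exp(rng.normal(np.log(self.volume_median_nm3), self.volume_log_sd, size=n))


@dataclass(frozen=True)
class OligomerPopulation:
    """Mixture of oligomer components present in the pipette reservoir."""

    components: tuple[OligomerComponent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))


@dataclass(frozen=True)
class ConfocalSetup:
    """Confocal detection volume and photophysics parameters.

    The detection volume is a 3D Gaussian with lateral waist ``waist_xy_nm``
    and axial waist ``waist_z_nm``; the waists are chosen so that 100-200 nm
    beads produce dwell times in the 0.1-1 s decade, matching the bead
    calibration of the setup.  Emission at the focus is ``peak_rate_per_s``
    on a flat ``background_rate_per_s``.  Temperature and viscosity feed the
    Stokes-Einstein diffusion coefficient.
    """

    waist_xy_nm: float = 2000.0
    waist_z_nm: float = 6000.0
    peak_rate_per_s: float = 1.0e6
    background_rate_per_s: float = 1.0e3
    temperature_K: float = 298.15
    viscosity_Pa_s: float = 8.9e-4
    box_nm: float = 20_000.0
    n_particles: int = 3

    def __post_init__(self) -> None:
        for name in (
            "waist_xy_nm",
            "waist_z_nm",
            "peak_rate_per_s",
            "background_rate_per_s",
            "temperature_K",
            "viscosity_Pa_s",
            "box_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.waist_z_nm < self.waist_xy_nm:
            raise ValueError("axial waist must be >= lateral waist")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")


def stokes_einstein_diffusion(
    diameter_nm: float, temperature_K: float = 298.15, viscosity_Pa_s: float = 8.9e-4
) -> float:
    """Stokes-Einstein diffusion coefficient D = k_B T / (3 pi eta d), in nm^2/s."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    d_m2_per_s = BOLTZMANN_J_PER_K * temperature_K / (
        3.0 * np.pi * viscosity_Pa_s * diameter_nm * 1e-9
    )
    return d_m2_per_s * 1e18  # m^2/s -> nm^2/s


def simulate_current_trace(
    geom: PipetteGeometry,
    pop: OligomerPopulation,
    duration_s: float,
    noise_sigma_pA: float,
    sampling_rate_Hz: float = 200_000.0,
    applied_voltage_mV: float = -500.0,
    drift_pA_per_s: float = 0.0,
    drift_sine_amp_pA: float = 0.0,
    drift_sine_freq_Hz: float = 0.1,
    bessel_cutoff_Hz: float | None = 10_000.0,
    incubation_time_min: float = 0.0,
    overlap_warn_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[CurrentTrace, pd.DataFrame]:
    """Simulate a nanopipette current trace with ground-truth events.

    The open-pore baseline is ``I0 = G * V`` (nS * mV = pA) plus a linear and
    a sinusoidal drift term plus white Gaussian noise.  For each population
    component, events arrive at Poisson times; each event is a rectangular
    pulse whose depth is the forward-model relative blockade of the sampled
    volume times the local baseline magnitude, pointing toward zero current,
    and whose width is drawn from the component's dwell distribution.  If
    ``bessel_cutoff_Hz`` is set, the assembled trace is passed through a
    causal 4-pole low-pass Bessel filter emulating the acquisition
    electronics.

    Returns the trace and a ground-truth table with one row per injected
    event (``t_start_s, dwell_s, volume_nm3, r_o_nm, rel_blockade,
    depth_pA, injected``); volumes too large for the pore are recorded with
    ``injected = False`` and skipped with a warning.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if noise_sigma_pA < 0:
        raise ValueError("noise_sigma_pA must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_Hz))
    t = np.arange(n) / sampling_rate_Hz
    i0 = geom.open_conductance_nS * applied_voltage_mV  # pA
    baseline = (
        i0
        + drift_pA_per_s * t
        + drift_sine_amp_pA * np.sin(2.0 * np.pi * drift_sine_freq_Hz * t)
    )
    current = baseline + rng.normal(0.0, noise_sigma_pA, size=n)

    toward_zero = -np.sign(i0) if i0 != 0 else -1.0
    ro_ceiling = 0.99 * geom.tip_radius_nm
    records = []
    occupied = np.zeros(n, dtype=bool)
    for comp in pop.components:
        n_events = rng.poisson(comp.rate_per_s * duration_s)
        starts = rng.uniform(0.0, duration_s, size=n_events)
        volumes = comp.sample_volumes(rng, n_events)
        dwells = np.exp(
            rng.normal(np.log(comp.dwell_median_s), comp.dwell_log_sd, size=n_events)
        )
        for t0, vol, dw in zip(starts, volumes, dwells):
            olig = CylindricalOligomer.from_volume(vol)
            feasible = olig.radius_nm < ro_ceiling
            rel = relative_blockade(geom, olig) if feasible else np.nan
            s = int(t0 * sampling_rate_Hz)
            e = min(n, s + max(1, int(round(dw * sampling_rate_Hz))))
            depth = np.nan
            if feasible and s < n:
                depth = rel * np.abs(baseline[s])
                current[s:e] += toward_zero * depth
                occupied[s:e] = True
            records.append(
                {
                    "t_start_s": t0,
                    "dwell_s": dw,
                    "volume_nm3": vol,
                    "r_o_nm": olig.radius_nm,
                    "rel_blockade": rel,
                    "depth_pA": depth,
                    "injected": bool(feasible and s < n),
                }
            )
    truth = pd.DataFrame(
        records,
        columns=[
            "t_start_s",
            "dwell_s",
            "volume_nm3",
            "r_o_nm",
            "rel_blockade",
            "depth_pA",
            "injected",
        ],
    ).sort_values("t_start_s", ignore_index=True) if records else pd.DataFrame(
        columns=[
            "t_start_s",
            "dwell_s",
            "volume_nm3",
            "r_o_nm",
            "rel_blockade",
            "depth_pA",
            "injected",
        ]
    )
    n_skipped = int((~truth["injected"]).sum()) if len(truth) else 0
    if n_skipped:
        warnings.warn(
            f"{n_skipped} sampled volumes exceeded the pore and were not injected",
            stacklevel=2,
        )
    if len(truth):
        expected = truth.loc[truth["injected"], "dwell_s"].sum() * sampling_rate_Hz
        if expected > 0:
            overlap = 1.0 - occupied.sum() / min(expected, n)
            if overlap > overlap_warn_fraction:
                warnings.warn(
                    f"event overlap fraction {overlap:.2f} exceeds "
                    f"{overlap_warn_fraction}",
                    stacklevel=2,
                )
    if bessel_cutoff_Hz is not None:
        sos = signal.bessel(
            4, bessel_cutoff_Hz, btype="low", fs=sampling_rate_Hz, output="sos"
        )
        current = signal.sosfilt(sos, current - current[0]) + current[0]
    trace = CurrentTrace(
        current_pA=current,
        sampling_rate_Hz=sampling_rate_Hz,
        applied_voltage_mV=applied_voltage_mV,
        incubation_time_min=incubation_time_min,
        geometry=geom,
    )
    return trace, truth


def simulate_photon_trace(
    setup: ConfocalSetup,
    diameters_nm: list[float],
    duration_s: float,
    bin_width_s: float = 0.010,
    substeps: int = 10,
    incubation_time_min: float = 0.0,
    seed: int = 0,
) -> tuple[PhotonTrace, pd.DataFrame]:
    """Simulate a binned photon-count trace from diffusing fluorescent particles.

    One particle per entry of ``diameters_nm`` performs 3D Brownian motion
    (Euler-Maruyama with ``substeps`` sub-steps per bin, step <= bin/10) in a
    periodic cubic box of side ``setup.box_nm`` centred on the confocal
    volume.  The instantaneous emission rate is

        background + sum_i peak * exp(-2 (x_i^2+y_i^2)/w_xy^2 - 2 z_i^2/w_z^2)

    and counts per bin are Poisson with the time-integrated rate.

    Returns the trace and a ground-truth table with one row per particle
    in-waist transit interval (``particle, diameter_nm, D_nm2_per_s,
    t_enter_s, t_exit_s``).
    """
    if duration_s <= 0 or bin_width_s <= 0:
        raise ValueError("duration and bin width must be > 0")
    if substeps < 10:
        substeps = 10  # enforce step <= bin_width / 10
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration_s / bin_width_s))
    n_steps = n_bins * substeps
    dt = bin_width_s / substeps
    diameters = np.asarray(diameters_nm, dtype=float)
    n_part = diameters.size
    box = setup.box_nm

    rate_per_bin = np.full(n_bins, setup.background_rate_per_s * bin_width_s)
    transits: list[dict] = []
    d_coeffs = np.array(
        [
            stokes_einstein_diffusion(d, setup.temperature_K, setup.viscosity_Pa_s)
            for d in diameters
        ]
    )
    if n_part:
        step_sigma = np.sqrt(2.0 * d_coeffs * dt)  # per-axis, nm
        if np.any(3.0 * step_sigma > box / 4.0):
            raise ValueError(
                "diffusion step too large for the box; increase substeps or box size"
            )
        # positions: cumulative Gaussian steps, wrapped into [-box/2, box/2)
        for p in range(n_part):
            steps = rng.normal(0.0, step_sigma[p], size=(n_steps, 3))
            start = rng.uniform(-box / 2.0, box / 2.0, size=3)
            pos = np.mod(start + np.cumsum(steps, axis=0) + box / 2.0, box) - box / 2.0
            g = np.exp(
                -2.0 * (pos[:, 0] ** 2 + pos[:, 1] ** 2) / setup.waist_xy_nm**2
                - 2.0 * pos[:, 2] ** 2 / setup.waist_z_nm**2
            )
            rate_per_bin += (
                setup.peak_rate_per_s * g.reshape(n_bins, substeps).sum(axis=1) * dt
            )
            inside = g > np.exp(-2.0)  # within one waist surface
            edges = np.diff(np.concatenate(([0], inside.view(np.int8), [0])))
            for s, e in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1) - 1):
                transits.append(
                    {
                        "particle": p,
                        "diameter_nm": float(diameters[p]),
                        "D_nm2_per_s": float(d_coeffs[p]),
                        "t_enter_s": s * dt,
                        "t_exit_s": (e + 1) * dt,
                    }
                )
    counts = rng.poisson(rate_per_bin)
    trace = PhotonTrace(
        counts=counts, bin_width_s=bin_width_s, incubation_time_min=incubation_time_min
    )
    truth = pd.DataFrame(
        transits,
        columns=["particle", "diameter_nm", "D_nm2_per_s", "t_enter_s", "t_exit_s"],
    )
    return trace, truth


def simulate_kinetics(
    I_i: float = 0.0,
    I_f: float = 100.0,
    T50_min: float = 630.0,
    tau_min: float = 40.0,
    noise_sigma: float = 3.0,
    t_max_min: float = 1200.0,
    interval_min: float = 10.0,
    condition: str = "control",
    replicate: int = 0,
    seed: int = 0,
) -> KineticTrace:
    """Simulate a ThT kinetic trace: Boltzmann curve plus Gaussian noise.

    Sampled every ``interval_min`` (the microplate reader cadence) from 0 to
    ``t_max_min``, which must exceed ``T50 + 4 tau`` so the plateau is
    reached.
    """
    if t_max_min <= T50_min + 4.0 * tau_min:
        raise ValueError(
            f"t_max_min = {t_max_min} must exceed T50 + 4 tau = "
            f"{T50_min + 4.0 * tau_min}"
        )
    if interval_min <= 0:
        raise ValueError("interval_min must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max_min + 0.5 * interval_min, interval_min)
    y = boltzmann(t, I_i, I_f, T50_min, tau_min)
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=t.size)
    return KineticTrace(time_min=t, intensity=y, condition=condition, replicate=replicate)


def match_events(
    truth: pd.DataFrame,
    events: list[TranslocationEvent],
    tolerance_s: float = 2e-3,
) -> pd.DataFrame:
    """Match detected events to injected ground-truth events by start time.

    Greedy nearest-neighbour matching within ``tolerance_s``; each truth row
    and each detected event is used at most once.  Returns the injected
    truth table with columns ``detected`` (bool), ``detected_rel_blockade``
    and ``detected_dwell_s`` appended (NaN where unmatched).
    """
    out = truth.loc[truth["injected"]].reset_index(drop=True).copy()
    out["detected"] = False
    out["detected_rel_blockade"] = np.nan
    out["detected_dwell_s"] = np.nan
    if not len(out) or not events:
        return out
    ev_starts = np.array([ev.start_time_s for ev in events])
    used = np.zeros(len(events), dtype=bool)
    for i, t0 in enumerate(out["t_start_s"].to_numpy()):
        dist = np.abs(ev_starts - t0)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= tolerance_s:
            used[j] = True
            out.loc[i, "detected"] = True
            out.loc[i, "detected_rel_blockade"] = events[j].relative_blockade
            out.loc[i, "detected_dwell_s"] = events[j].dwell_s
    return out
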