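"""Boltzmann-sigmoid fitting of ThT aggregation kinetics.

Amyloid aggregation followed by thioflavin-T fluorescence is sigmoidal: a lag
phase, a growth phase and a plateau.  Each kinetic trace is fitted with the
Boltzmann equation

    I(t) = I_f + (I_i - I_f) / (1 + exp((t - T50) / tau)),

where ``I_i`` and ``I_f`` are the initial and plateau fluorescence levels,
``T50`` the half-transition time and ``tau`` the transition width.  Seeding
efficiency is quantified as the percent reduction of T50 relative to an
unseeded control, and replicate fits are aggregated per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.special import expit

__all__ = [
    "KineticTrace",
    "BoltzmannFit",
    "FitDegenerateError",
    "boltzmann",
    "fit_boltzmann",
    "percent_t50_reduction",
    "T50Reduction",
    "summarize_conditions",
]


class FitDegenerateError(ValueError):
    """The trace shows no resolvable sigmoidal transition."""


def boltzmann(t, I_i: float, I_f: float, T50: float, tau: float):
    """Boltzmann sigmoid I(t) = I_f + (I_i - I_f) / (1 + exp((t - T50)/tau)).

    Evaluated through the logistic function for overflow-free arithmetic far
    from the transition.
    """
    z = (np.asarray(t, dtype=float) - T50) / tau
    return I_f + (I_i - I_f) * expit(-z)


@dataclass
class KineticTrace:
    """One ThT kinetic trace (time in min, intensity in a.u.)."""

    time_min: np.ndarray
    intensity: np.ndarray
    condition: str = "control"
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_min.size != self.intensity.size:
            raise ValueError("time and intensity must have the same length")
        if self.time_min.size < 8:
            raise ValueError("kinetic trace needs at least 8 points")
        if not np.all(np.diff(self.time_min) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann parameters with uncertainties and residual RMS."""

    I_i: float
    I_f: float
    T50_min: float
    tau_min: float
    residual_rms: float
    stderr: dict = field(default_factory=dict)
    condition: str = ""
    replicate: int = 0

    def predict(self, t):
        return boltzmann(t, self.I_i, self.I_f, self.T50_min, self.tau_min)


def _transition_check(intensity: np.ndarray) -> None:
    """Require non-overlapping first/last-quartile intensity ranges."""
    q = max(2, intensity.size // 4)
    first, last = intensity[:q], intensity[-q:]
    lo = (first.min(), first.max())
    hi = (last.min(), last.max())
    if not (lo[1] < hi[0] or hi[1] < lo[0]):
        raise FitDegenerateError(
            "no sigmoidal transition: first- and last-quartile intensity ranges overlap"
        )


def fit_boltzmann(trace: KineticTrace) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a kinetic trace.

    Initialisation: ``I_i`` = mean of the first time quartile, ``I_f`` = mean
    of the last, ``T50`` = time of the half-range crossing, ``tau`` = time
    span / 10.  Converged to 1e-8 relative tolerance.  Decreasing traces
    (``I_i > I_f``) are fitted symmetrically.

    Raises :class:`FitDegenerateError` if the trace does not span both
    plateaus or the fitted midpoint falls outside the observed time span.
    """
    t, y = trace.time_min, trace.intensity
    _transition_check(y)

    q = max(2, t.size // 4)
    i_i0 = float(y[:q].mean())
    i_f0 = float(y[-q:].mean())
    half = 0.5 * (i_i0 + i_f0)
    rising = i_f0 >= i_i0
    crossed = y >= half if rising else y <= half
    t50_0 = float(t[np.argmax(crossed)]) if crossed.any() else float(t[t.size // 2])
    tau0 = (t[-1] - t[0]) / 10.0

    with warnings.catch_warnings():
        # noiseless traces legitimately yield a singular covariance;
        # stderr is reported as NaN in that case
        warnings.simplefilter("ignore", category=OptimizeWarning)
        popt, pcov = curve_fit(
            boltzmann,
            t,
            y,
            p0=[i_i0, i_f0, t50_0, tau0],
            maxfev=20_000,
            xtol=1e-8,
            ftol=1e-8,
        )
    i_i, i_f, t50, tau = (float(v) for v in popt)
    if tau < 0:  # sign convention: tau > 0, orientation carried by I_i vs I_f
        tau = -tau
        i_i, i_f = i_f, i_i
    if not t[0] <= t50 <= t[-1]:
        raise FitDegenerateError(
            f"fitted T50 = {t50:.1f} min lies outside the observed span "
            f"[{t[0]:.0f}, {t[-1]:.0f}] min"
        )
    resid = y - boltzmann(t, i_i, i_f, t50, tau)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    return BoltzmannFit(
        I_i=i_i,
        I_f=i_f,
        T50_min=t50,
        tau_min=tau,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        stderr={
            "I_i": float(perr[0]),
            "I_f": float(perr[1]),
            "T50_min": float(perr[2]),
            "tau_min": float(perr[3]),
        },
        condition=trace.condition,
        replicate=trace.replicate,
    )


class T50Reduction(NamedTuple):
    """Percent T50 reduction of a seeded condition vs its control."""

    percent: float
    percent_rounded: int


def percent_t50_reduction(control: BoltzmannFit, seeded: BoltzmannFit) -> T50Reduction:
    """Seeding efficiency: 100 * (T50_control - T50_seeded) / T50_control.

    Returned both raw and rounded to the nearest integer percent.
    """
    if control.T50_min <= 0:
        raise ValueError("control T50 must be > 0")
    pct = 100.0 * (control.T50_min - seeded.T50_min) / control.T50_min
    return T50Reduction(percent=pct, percent_rounded=int(round(pct)))


def summarize_conditions(fits: Iterable[BoltzmannFit]) -> pd.DataFrame:
    """Per-condition mean and standard deviation of T50 across replicates.

    Columns: ``condition, n_replicates, T50_mean_min, T50_sd_min,
    single_replicate``.  Conditions with a single replicate report sd = 0
    and are flagged; empty groups are omitted with a warning.
    """
    groups: dict[str, list[float]] = {}
    for fit in fits:
        groups.setdefault(fit.condition or "unlabelled", []).append(fit.T50_min)
    rows = []
    for condition, t50s in groups.items():
        if not t50s:
            warnings.warn(f"condition {condition!r} has no fits; omitted", stacklevel=2)
            continue
        single = len(t50s) == 1
        rows.append(
            {
                "condition": condition,
                "n_replicates": len(t50s),
                "T50_mean_min": float(np.mean(t50s)),
                "T50_sd_min": 0.0 if single else float(np.std(t50s, ddof=1)),
                "single_replicate": single,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "n_replicates",
            "T50_mean_min",
            "T50_sd_min",
            "single_replicate",
        ],
    )
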