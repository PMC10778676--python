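"""RVA digestogram kinetics and pasting-curve metrics.

Two kinds of Rapid Visco Analyser traces are handled.  A *digestogram* is
the apparent-viscosity decay recorded after alpha-amylase addition to a
gelatinised slurry; it is modelled as first-order decay

    mu(t) = mu_inf + (mu_0 - mu_inf) * exp(-k t)

whose kinetic constant k_RVA (min^-1) proxies starch digestibility.  A
*pasting* trace is the heat-hold-cool run from which peak viscosity
(VPEAK), final viscosity, setback (SB = final - VPEAK) and a surrogate
pasting/gelatinization temperature are read.

cP and mPa.s are treated as identical units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ViscosityTrace",
    "DigestogramFit",
    "PastingProfile",
    "fit_digestogram",
    "pasting_metrics",
    "detect_pasting_temperature",
]


@dataclass(frozen=True)
class ViscosityTrace:
    """A viscosity-vs-time trace, optionally with a temperature channel.

    For digestograms ``t`` is minutes from enzyme addition; for pasting
    traces minutes from run start with ``temperature`` in deg C.
    """

    variety: str
    t: np.ndarray
    viscosity: np.ndarray
    temperature: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.viscosity, dtype=float)
        order = np.argsort(t)
        t, v = t[order], v[order]
        temp = self.temperature
        if temp is not None:
            temp = np.asarray(temp, dtype=float)[order]
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "viscosity", v)
        object.__setattr__(self, "temperature", temp)
        if t.size < 5:
            raise ValueError("trace needs at least 5 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must contain no duplicate times")
        if np.any(v < 0):
            raise ValueError("viscosity must be non-negative")
        if temp is not None and temp.size != t.size:
            raise ValueError("temperature channel length mismatch")


@dataclass(frozen=True)
class DigestogramFit:
    variety: str
    mu0: float
    mu_inf: float
    k_rva: float
    rss: float = 0.0
    converged: bool = True
    identifiable: bool = True

    def predict(self, t):
        return self.mu_inf + (self.mu0 - self.mu_inf) * np.exp(
            -self.k_rva * np.asarray(t, dtype=float)
        )


@dataclass(frozen=True)
class PastingProfile:
    variety: str
    vpeak: float
    final_viscosity: float
    setback: float
    tg_surrogate: float | None = None


def _dig_residuals(p, t, v):
    mu0, mu_inf, k = p
    return mu_inf + (mu0 - mu_inf) * np.exp(-k * t) - v


def _dig_jacobian(p, t, v):
    mu0, mu_inf, k = p
    e = np.exp(-k * t)
    return np.column_stack([e, 1.0 - e, -(mu0 - mu_inf) * t * e])


def fit_digestogram(trace: ViscosityTrace) -> DigestogramFit:
    """Least-squares fit of the first-order digestogram decay.

    Initialises mu0 from the first reading, mu_inf from the last and k = 1,
    with a log-grid restart on non-convergence.  A constant trace leaves k
    unidentifiable; the fit then reports mu0 = mu_inf = mean with
    ``identifiable=False``.
    """
    t, v = trace.t, trace.viscosity
    if np.ptp(v) == 0:
        return DigestogramFit(
            variety=trace.variety, mu0=float(v[0]), mu_inf=float(v[0]),
            k_rva=1.0, rss=0.0, converged=True, identifiable=False,
        )
    lower = np.array([0.0, 0.0, 1e-6])
    upper = np.array([np.inf, np.inf, 1e3])

    def solve(x0):
        return least_squares(
            _dig_residuals, np.clip(x0, lower, upper), jac=_dig_jacobian,
            args=(t, v), bounds=(lower, upper), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )

    best = solve(np.array([v[0], v[-1], 1.0]))
    sst = 0.5 * float(np.sum((v - v.mean()) ** 2))
    if not best.success or best.cost > max(0.5 * sst, 1e-12):
        for k0 in np.geomspace(1e-2, 50.0, 10):
            for frac in np.linspace(0.0, 1.0, 10):
                x0 = np.array([v.max(), frac * v.min() + 1e-3, k0])
                res = solve(x0)
                if res.cost < best.cost:
                    best = res
        if not best.success:
            warnings.warn(
                f"digestogram fit for {trace.variety!r} did not converge",
                RuntimeWarning, stacklevel=2,
            )
    mu0, mu_inf, k = best.x
    return DigestogramFit(
        variety=trace.variety, mu0=float(mu0), mu_inf=float(mu_inf),
        k_rva=float(k), rss=float(2.0 * best.cost), converged=bool(best.success),
    )


def pasting_metrics(
    trace: ViscosityTrace, heating_window: tuple[float, float] | None = None
) -> PastingProfile:
    """Peak viscosity, final viscosity and setback from a pasting trace.

    ``heating_window`` bounds (minutes) the heating/holding phase searched
    for VPEAK.  When the trace carries a temperature channel the default
    window runs to the end of the maximum-temperature hold (so the cooling
    rise never masquerades as the peak); otherwise the whole trace is used.
    Setback is final minus peak and may legitimately be negative for traces
    with no cooling rise.
    """
    if heating_window is None:
        if trace.temperature is not None:
            hold_end = int(np.flatnonzero(
                trace.temperature >= trace.temperature.max() - 1e-9
            )[-1])
            heating_window = (float(trace.t[0]), float(trace.t[hold_end]))
        else:
            heating_window = (float(trace.t[0]), float(trace.t[-1]))
    lo, hi = heating_window
    mask = (trace.t >= lo) & (trace.t <= hi)
    if not np.any(mask):
        raise ValueError("heating window contains no trace points")
    vpeak = float(np.max(trace.viscosity[mask]))
    final = float(trace.viscosity[-1])
    tg = None
    if trace.temperature is not None:
        tg = detect_pasting_temperature(trace)
    return PastingProfile(
        variety=trace.variety, vpeak=vpeak, final_viscosity=final,
        setback=final - vpeak, tg_surrogate=tg,
    )


def detect_pasting_temperature(
    trace: ViscosityTrace, threshold: float | None = None
) -> float | None:
    """Surrogate pasting/gelatinization temperature from viscosity onset.

    Returns the temperature at which viscosity first exceeds the pre-ramp
    baseline median plus ``threshold`` (cP) during the heating ramp, with
    linear interpolation between samples.  The default threshold is 5% of
    the trace maximum above baseline.  Returns None (with a warning) if the
    threshold is never crossed.
    """
    if trace.temperature is None:
        raise ValueError("trace has no temperature channel")
    temp, visc, t = trace.temperature, trace.viscosity, trace.t
    dT = np.diff(temp)
    ramp = np.flatnonzero(dT > 1e-9)
    if ramp.size == 0:
        warnings.warn(
            f"trace {trace.variety!r} has no heating ramp", RuntimeWarning,
            stacklevel=2,
        )
        return None
    ramp_start = int(ramp[0])
    ramp_end = int(np.argmax(temp))
    baseline = float(np.median(visc[: ramp_start + 1]))
    if threshold is None:
        threshold = 0.05 * (float(np.max(visc)) - baseline)
        if threshold <= 0:  # flat trace: no gelatinization response
            warnings.warn(
                f"trace {trace.variety!r} shows no viscosity rise",
                RuntimeWarning, stacklevel=2,
            )
            return None
    elif threshold <= 0:
        return float(temp[ramp_start])
    level = baseline + threshold
    seg = slice(ramp_start, ramp_end + 1)
    above = np.flatnonzero(visc[seg] > level)
    if above.size == 0:
        warnings.warn(
            f"trace {trace.variety!r} never exceeds the onset threshold",
            RuntimeWarning, stacklevel=2,
        )
        return None
    i = ramp_start + int(above[0])
    if i == ramp_start or visc[i] == visc[i - 1]:
        return float(temp[i])
    frac = (level - visc[i - 1]) / (visc[i] - visc[i - 1])
    return float(temp[i - 1] + frac * (temp[i] - temp[i - 1]))
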