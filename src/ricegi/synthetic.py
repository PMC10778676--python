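"""Seeded synthetic rice-panel generator.

Emulates the data structure of a multi-variety rice quality study: a panel
of varieties spread over commercial types, each with

* a starch-hydrolysis time course following first-order kinetics with
  type-dependent (C_inf, k) plus additive Gaussian measurement noise, and a
  glucose reference curve with higher (C_inf, k) than any variety;
* an RVA digestogram (exponential viscosity decay after enzyme addition);
* an RVA pasting trace with a heat-hold-cool temperature program, a single
  interior viscosity peak and a final cooling rise (setback);
* raw cooking measurements (12 g uncooked rice) and grain biometry;
* a 16-variable per-variety parameter table drawn through a Gaussian copula
  with a configurable target correlation matrix, shifted/scaled to
  per-type means and pooled SDs.

All generators are deterministic in (config, seed); each output family uses
an independent RNG stream so results do not depend on call order.

The latent table draw is *not* truncated at physical bounds (a variable
with mean close to 0, like RS in the high-GI types, can dip slightly
negative): truncation would bias the correlation structure the generator
contracts to deliver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    GLUCOSE_REFERENCE_KINETICS,
    VARIABLES,
    GeneratorConfig,
)
from .kinetics import EGI_INTERCEPT, EGI_SLOPE, HydrolysisCurve, hydrolysis_model

__all__ = [
    "RawMeasurements",
    "nearest_psd_correlation",
    "generate_variety_table",
    "generate_hydrolysis_curves",
    "generate_raw_measurements",
    "cinf_for_target_egi",
]

_STREAM_TABLE = 1
_STREAM_CURVES = 2
_STREAM_RAW = 3

#: digestogram sampling: 5 min at 4 s intervals after enzyme addition
_DIGESTO_T = np.arange(0, 5.0 + 1e-9, 1.0 / 15.0)


@dataclass(frozen=True)
class RawMeasurements:
    """Raw synthetic measurement tables (one pass of the bench work).

    ``cooking``: per-variety raw cooking weights/volumes.
    ``biometry``: per-variety grain length/width (mm).
    ``pasting``: long trace table (variety, time_min, temperature_C,
    viscosity_cP).  ``digestograms``: long trace table (variety, time_min,
    viscosity_cP), t = 0 at enzyme addition.
    """

    cooking: pd.DataFrame
    biometry: pd.DataFrame
    pasting: pd.DataFrame
    digestograms: pd.DataFrame


def nearest_psd_correlation(matrix: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Repair an indefinite correlation matrix by eigenvalue clipping.

    Negative eigenvalues are clipped to ``eig_floor`` and the diagonal is
    renormalised to 1.  Matrices assembled from rounded published
    coefficients are frequently slightly indefinite; a warning is issued
    when a repair actually changes the matrix.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    w, q = np.linalg.eigh(m)
    if w.min() >= 0:
        return m
    warnings.warn(
        f"target correlation is indefinite (min eigenvalue {w.min():.3g}); "
        "clipping to nearest PSD",
        RuntimeWarning,
        stacklevel=2,
    )
    w = np.clip(w, eig_floor, None)
    repaired = (q * w) @ q.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def generate_variety_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw the 16-variable per-variety parameter table.

    A multivariate-normal latent sample with the (PSD-repaired) target
    correlation is shifted and scaled variable-by-variable to the
    configured per-type means and pooled SDs.  Returns one row per variety
    with columns ``variety``, ``type`` and the 16 variables.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_TABLE])
    corr = nearest_psd_correlation(cfg.target_correlation)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    z = rng.standard_normal((cfg.n_varieties, len(VARIABLES))) @ chol.T
    sds = np.array([cfg.pooled_sds[v] for v in VARIABLES])
    types = cfg.variety_types()
    means = np.array(
        [[cfg.type_means[t][v] for v in VARIABLES] for t in types]
    )
    values = means + z * sds
    out = pd.DataFrame(values, columns=list(VARIABLES))
    out.insert(0, "type", types)
    out.insert(0, "variety", cfg.variety_names())
    return out


def _reference_auc(tf: float = 240.0) -> float:
    cinf, k = GLUCOSE_REFERENCE_KINETICS
    return cinf * tf + (cinf / k) * (np.exp(-k * tf) - 1.0)


def cinf_for_target_egi(egi: float, k: float, tf: float = 240.0) -> float:
    """Invert the AUC -> HI -> eGI chain: the C_inf giving ``egi`` at fixed k."""
    hi = (egi - EGI_INTERCEPT) / EGI_SLOPE
    auc_target = hi / 100.0 * _reference_auc(tf)
    denom = tf + (np.exp(-k * tf) - 1.0) / k
    return float(np.clip(auc_target / denom, 1.0, 119.0))


def generate_hydrolysis_curves(
    cfg: GeneratorConfig, variety_table: pd.DataFrame | None = None
) -> tuple[dict[str, HydrolysisCurve], HydrolysisCurve]:
    """Synthetic starch-hydrolysis time courses plus a glucose reference.

    Without a ``variety_table`` every variety uses its commercial type's
    (C_inf, k); with one, per-variety C_inf is solved from the table's eGI
    (at the type's k) so that curve-derived and table eGI agree up to
    noise.  Noise is i.i.d. Gaussian (sd ``cfg.noise_sd`` percentage
    points) truncated below at 0 and applied at t > 0 only — the t = 0
    reading is definitionally zero hydrolysis.

    With ``cfg.replicates > 1`` keys become ``"<variety>#r<j>"``.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_CURVES])
    t = np.asarray(cfg.timepoints, dtype=float)
    names = cfg.variety_names()
    types = cfg.variety_types()
    if variety_table is not None:
        egi_by_variety = dict(zip(variety_table["variety"], variety_table["eGI"]))
    curves: dict[str, HydrolysisCurve] = {}

    def make(name: str, cinf: float, k: float) -> HydrolysisCurve:
        c = np.asarray(hydrolysis_model(t, cinf, k), dtype=float)
        if cfg.noise_sd > 0:
            noise = rng.normal(0.0, cfg.noise_sd, size=t.size)
            noise[t == 0] = 0.0
            c = np.clip(c + noise, 0.0, None)
        return HydrolysisCurve(variety=name, t=t.copy(), C=c)

    for name, typ in zip(names, types):
        cinf, k = cfg.per_type_kinetics[typ]
        if variety_table is not None:
            cinf = cinf_for_target_egi(egi_by_variety[name], k)
        for rep in range(cfg.replicates):
            key = name if cfg.replicates == 1 else f"{name}#r{rep + 1}"
            curves[key] = make(key, cinf, k)
    reference = make("glucose", *GLUCOSE_REFERENCE_KINETICS)
    return curves, reference


def _pasting_trace(
    tg: float, vpeak: float, setback: float, baseline: float = 60.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One noiseless pasting trace (t, temperature, viscosity).

    Temperature program: 1 min at 50 C, heat to 95 C at 10 C/min, hold
    2.5 min, cool to 50 C at 10 C/min, 0.5 min final hold.  Viscosity is
    piecewise raised-cosine: flat baseline until the ramp crosses the
    gelatinization temperature, a rise to VPEAK completed 0.8 min later, a
    shear-thinning decay to a trough during the 95 C hold, then a cooling
    (retrogradation) rise to final = VPEAK + SB.
    """
    step = 1.0 / 15.0  # 4 s
    t_ramp_end = 1.0 + 4.5
    t_hold_end = t_ramp_end + 2.5
    t_cool_end = t_hold_end + 4.5
    t_end = t_cool_end + 0.5
    t = np.arange(0.0, t_end + 1e-9, step)

    temp = np.empty_like(t)
    temp[t <= 1.0] = 50.0
    m = (t > 1.0) & (t <= t_ramp_end)
    temp[m] = 50.0 + 10.0 * (t[m] - 1.0)
    m = (t > t_ramp_end) & (t <= t_hold_end)
    temp[m] = 95.0
    m = (t > t_hold_end) & (t <= t_cool_end)
    temp[m] = 95.0 - 10.0 * (t[m] - t_hold_end)
    temp[t > t_cool_end] = 50.0

    tg = float(np.clip(tg, 52.0, 93.0))
    vpeak = max(vpeak, baseline + 200.0)
    final = max(vpeak + setback, 10.0)
    trough = 0.72 * vpeak
    t_onset = 1.0 + (tg - 50.0) / 10.0
    t_peak = min(t_onset + 0.8, t_hold_end - 0.4)

    def cosine(x, x0, x1, y0, y1):
        f = np.clip((x - x0) / (x1 - x0), 0.0, 1.0)
        return y0 + (y1 - y0) * 0.5 * (1.0 - np.cos(np.pi * f))

    visc = np.full_like(t, baseline)
    m = (t >= t_onset) & (t <= t_peak)
    visc[m] = cosine(t[m], t_onset, t_peak, baseline, vpeak)
    m = (t > t_peak) & (t <= t_hold_end)
    visc[m] = cosine(t[m], t_peak, t_hold_end, vpeak, trough)
    m = t > t_hold_end
    visc[m] = cosine(t[m], t_hold_end, t_end, trough, final)
    return t, temp, visc


def generate_raw_measurements(
    cfg: GeneratorConfig, variety_table: pd.DataFrame | None = None
) -> RawMeasurements:
    """Synthetic raw cooking, biometry, pasting and digestogram tables.

    Per-variety true values of WUp/VER/SL, Tg/VPEAK/SB and k_RVA come from
    ``variety_table`` when given (so downstream analyses reproduce the
    table's correlation structure), otherwise from the per-type means.
    Cooking measurements are consistent with 12 g of uncooked rice; pasting
    traces are noiseless by construction (they contract to a single
    interior peak); digestograms are exact first-order decays plus Gaussian
    noise of sd ``cfg.rva_noise_sd``.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_RAW])
    names = cfg.variety_names()
    types = cfg.variety_types()
    if variety_table is None:
        tm = cfg.type_means
        truth = pd.DataFrame({
            "variety": names,
            **{v: [tm[t][v] for t in types] for v in ("WUp", "VER", "SL", "Tg", "VPEAK", "SB", "k_RVA")},
        })
    else:
        truth = variety_table[["variety", "WUp", "VER", "SL", "Tg", "VPEAK", "SB", "k_RVA"]]
    truth = truth.set_index("variety")

    # --- cooking: invert WUp/VER/SL from 12 g uncooked rice, 120 g water
    uncooked_mass, uncooked_vol, w2 = 12.0, 15.0, 20.0
    cooking = pd.DataFrame({
        "variety": names,
        "uncooked_mass_g": uncooked_mass,
        "cooked_mass_g": uncooked_mass * (1.0 + truth.loc[names, "WUp"].to_numpy() / 100.0),
        "uncooked_volume_mL": uncooked_vol,
        "cooked_volume_mL": uncooked_vol * truth.loc[names, "VER"].to_numpy(),
        "W2_g": w2,
        "W1_g": w2 + np.clip(truth.loc[names, "SL"].to_numpy(), 0.0, None) * uncooked_mass / 100.0,
        "aliquot_volume_mL": 50.0,
        "total_water_g": 120.0,
    })

    # --- biometry: type-typical grain dimensions (mm) + measurement noise
    dims = {
        "Long A": (6.6, 2.8),
        "Short grain": (5.0, 2.8),
        "Long B": (6.9, 2.1),
        "Medium grain": (5.6, 2.4),
        "Basmati": (6.9, 1.9),
        "European Aromatic": (6.3, 2.6),
    }
    length = np.array([dims.get(t, (6.0, 2.5))[0] for t in types])
    width = np.array([dims.get(t, (6.0, 2.5))[1] for t in types])
    biometry = pd.DataFrame({
        "variety": names,
        "length_mm": np.clip(length + rng.normal(0, 0.08, len(names)), 3.0, None),
        "width_mm": np.clip(width + rng.normal(0, 0.05, len(names)), 1.0, None),
    })

    # --- pasting traces (noiseless; single interior peak by construction)
    pasting_frames = []
    for name in names:
        t, temp, visc = _pasting_trace(
            truth.loc[name, "Tg"], truth.loc[name, "VPEAK"], truth.loc[name, "SB"]
        )
        pasting_frames.append(pd.DataFrame({
            "variety": name, "time_min": t,
            "temperature_C": temp, "viscosity_cP": visc,
        }))
    pasting = pd.concat(pasting_frames, ignore_index=True)

    # --- digestograms: first-order decay + noise, t = 0 at enzyme addition
    digesto_frames = []
    for name in names:
        mu0 = 1900.0 + rng.normal(0.0, 100.0)
        mu_inf = max(200.0 + rng.normal(0.0, 20.0), 10.0)
        k = max(float(truth.loc[name, "k_RVA"]), 0.05)
        visc = mu_inf + (mu0 - mu_inf) * np.exp(-k * _DIGESTO_T)
        if cfg.rva_noise_sd > 0:
            visc = visc + rng.normal(0.0, cfg.rva_noise_sd, _DIGESTO_T.size)
        digesto_frames.append(pd.DataFrame({
            "variety": name, "time_min": _DIGESTO_T,
            "viscosity_cP": np.clip(visc, 0.0, None),
        }))
    digestograms = pd.concat(digesto_frames, ignore_index=True)

    return RawMeasurements(
        cooking=cooking, biometry=biometry,
        pasting=pasting, digestograms=digestograms,
    )
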