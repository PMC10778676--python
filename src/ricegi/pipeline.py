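"""End-to-end orchestration: simulate or ingest, analyse, summarise.

``run_all`` drives the full chain — hydrolysis-kinetics fitting and eGI
estimation, Englyst fractions, digestogram and pasting analysis, cooking
parameters and biometric classification, assembly of the 16-variable
variety table, then the statistical layer (Tukey letters, correlation
screen, PCA) — and writes every stage output plus a run manifest as plain
CSV/JSON.  Two runs with the same configuration and seed produce identical
numeric output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import VARIABLES, GeneratorConfig
from .cooking import CookingMeasurement, GrainBiometry, classify_commercial_type, cooking_parameters
from .io import read_curves_csv, read_traces_csv, write_csv, write_curves_csv, write_traces_csv
from .kinetics import HydrolysisCurve, estimate_gi, fit_hydrolysis, starch_fractions
from .rva import ViscosityTrace, fit_digestogram, pasting_metrics
from .stats import GroupComparison, CorrelationReport, PCAResult, compare_groups, correlation_report, pca
from .synthetic import generate_hydrolysis_curves, generate_raw_measurements, generate_variety_table

__all__ = [
    "RunConfig",
    "RunResult",
    "analyze_digestion",
    "analyze_traces",
    "analyze_cooking",
    "assemble_variety_table",
    "traces_from_frames",
    "run_all",
]

log = logging.getLogger("ricegi")

#: columns the digestion stage must contribute to the variety table
_DIGESTION_COLS = ["eGI", "RDS", "SDS", "RS", "TS"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is ``simulate`` (generator-driven, ``seed`` required) or
    ``ingest`` (reads ``curves``/``traces``/``cooking``/``biometry``/
    ``composition`` CSV paths from ``inputs``).  ``rs_mode`` selects whether
    RS is passed through from an independent measurement (``measured``,
    composition column ``RS``) or derived from the digestion curve as
    TS - digested(120 min) (``derived``).
    """

    mode: str = "simulate"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    inputs: dict[str, str] = field(default_factory=dict)
    t0: float = 0.0
    tf: float = 240.0
    alpha: float = 0.05
    rs_mode: str = "measured"
    scale_sl_to_total_water: bool = False
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.rs_mode not in ("measured", "derived"):
            raise ValueError("rs_mode must be 'measured' or 'derived'")
        if self.mode == "ingest":
            required = {"curves", "traces", "cooking", "biometry", "composition"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"ingest mode missing input paths: {sorted(missing)}")
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"input {key!r}: {p} does not exist")
        if self.mode == "simulate":
            self.generator = GeneratorConfig(**{
                **self.generator.__dict__, "seed": self.seed,
            }) if self.generator.seed != self.seed else self.generator

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen:
            cfg.generator = GeneratorConfig(**{**gen, "seed": cfg.seed})
        return cfg


@dataclass
class RunResult:
    variety_table: pd.DataFrame
    digestion: pd.DataFrame
    rva: pd.DataFrame
    cooking: pd.DataFrame
    comparison: GroupComparison
    correlation: CorrelationReport
    pca: PCAResult
    manifest: dict[str, Any]


def analyze_digestion(
    curves: dict[str, HydrolysisCurve],
    reference: HydrolysisCurve,
    composition: pd.DataFrame,
    t0: float = 0.0,
    tf: float = 240.0,
    rs_mode: str = "measured",
) -> pd.DataFrame:
    """Kinetic fits, eGI and Englyst fractions for every curve.

    ``composition`` must carry ``variety`` and ``TS`` columns (and ``RS``
    when ``rs_mode='measured'``).  Replicate curves keyed
    ``"<variety>#r<j>"`` are analysed separately and averaged per variety.
    """
    comp = composition.set_index("variety")
    ref_fit = fit_hydrolysis(reference, t0=t0, tf=tf)
    rows = []
    for key, curve in curves.items():
        variety = key.split("#r")[0]
        if variety not in comp.index:
            raise KeyError(f"composition table has no row for variety {variety!r}")
        fit = fit_hydrolysis(curve, t0=t0, tf=tf)
        gi = estimate_gi(fit, ref_fit)
        measured_rs = None
        if rs_mode == "measured":
            if "RS" not in comp.columns:
                raise KeyError("rs_mode='measured' needs an RS composition column")
            measured_rs = float(comp.loc[variety, "RS"])
        frac = starch_fractions(
            curve, TS=float(comp.loc[variety, "TS"]),
            measured_RS=measured_rs, fit=fit,
        )
        rows.append({
            "variety": variety, "C_inf": fit.C_inf, "k": fit.k, "rss": fit.rss,
            "converged": fit.converged, "AUC": gi.AUC, "HI": gi.HI, "eGI": gi.eGI,
            "RDS": frac.RDS, "SDS": frac.SDS, "RS": frac.RS, "TS": frac.TS,
            "rs_mode": frac.rs_mode,
        })
        if not fit.converged:
            log.warning("hydrolysis fit did not converge for %s", key)
    df = pd.DataFrame(rows)
    numeric = df.columns.drop(["variety", "rs_mode", "converged"])
    agg = df.groupby("variety", sort=False).agg(
        {**{c: "mean" for c in numeric}, "converged": "all", "rs_mode": "first"}
    )
    return agg.reset_index()


def analyze_traces(
    pasting: dict[str, ViscosityTrace], digestograms: dict[str, ViscosityTrace]
) -> pd.DataFrame:
    """Pasting metrics (VPEAK, SB, surrogate Tg) and digestogram kinetics."""
    rows = []
    for variety in sorted(set(pasting) | set(digestograms)):
        row: dict[str, Any] = {"variety": variety}
        if variety in pasting:
            prof = pasting_metrics(pasting[variety])
            row.update(VPEAK=prof.vpeak, final_viscosity=prof.final_viscosity,
                       SB=prof.setback, Tg=prof.tg_surrogate)
        if variety in digestograms:
            fit = fit_digestogram(digestograms[variety])
            row.update(mu0=fit.mu0, mu_inf=fit.mu_inf, k_RVA=fit.k_rva,
                       k_identifiable=fit.identifiable)
            if not fit.converged:
                log.warning("digestogram fit did not converge for %s", variety)
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cooking(
    cooking: pd.DataFrame,
    biometry: pd.DataFrame,
    scale_sl_to_total_water: bool = False,
) -> pd.DataFrame:
    """Cooking parameters plus a biometric commercial-type assignment."""
    rows = []
    for rec in cooking.itertuples(index=False):
        m = CookingMeasurement(
            variety=rec.variety,
            uncooked_mass=rec.uncooked_mass_g,
            cooked_mass=rec.cooked_mass_g,
            uncooked_volume=rec.uncooked_volume_mL,
            cooked_volume=rec.cooked_volume_mL,
            aliquot_dry_with_container_W1=rec.W1_g,
            empty_container_W2=rec.W2_g,
            aliquot_volume=getattr(rec, "aliquot_volume_mL", 50.0),
            total_water=getattr(rec, "total_water_g", 120.0),
        )
        cp = cooking_parameters(m, scale_sl_to_total_water=scale_sl_to_total_water)
        rows.append({"variety": cp.variety, "WUp": cp.WUp, "VER": cp.VER, "SL": cp.SL})
    out = pd.DataFrame(rows)
    bio = biometry.copy()
    bio["type_from_biometry"] = [
        classify_commercial_type(GrainBiometry(r.variety, r.length_mm, r.width_mm))
        for r in bio.itertuples(index=False)
    ]
    return out.merge(bio[["variety", "type_from_biometry"]], on="variety", how="left")


def assemble_variety_table(
    digestion: pd.DataFrame,
    rva: pd.DataFrame,
    cooking: pd.DataFrame,
    composition: pd.DataFrame,
) -> pd.DataFrame:
    """Join stage outputs into the 16-variable per-variety table.

    Every variety must appear in the digestion output (the anchor stage);
    gaps contributed by other stages are retained as missing values with a
    logged warning.  Column order is fixed to the canonical variable list.
    """
    if digestion.empty:
        raise ValueError("digestion output is empty; nothing to assemble")
    for name, df in (("digestion", digestion), ("rva", rva),
                     ("cooking", cooking), ("composition", composition)):
        if df["variety"].duplicated().any():
            dupes = df.loc[df["variety"].duplicated(), "variety"].tolist()
            raise ValueError(f"duplicate variety keys in {name} output: {dupes}")
    base = composition[["variety", "type", "AMYL", "FAT", "FIBER", "PRTD"]]
    table = (
        digestion[["variety"] + _DIGESTION_COLS]
        .merge(base, on="variety", how="left")
        .merge(rva[["variety", "k_RVA", "Tg", "VPEAK", "SB"]], on="variety", how="left")
        .merge(cooking[["variety", "WUp", "VER", "SL"]], on="variety", how="left")
    )
    missing = table[list(VARIABLES)].isna()
    if missing.any().any():
        for variety, row in missing.set_axis(table["variety"]).iterrows():
            gaps = list(row[row].index)
            if gaps:
                log.warning("variety %s has missing values: %s", variety, gaps)
    return table[["variety", "type", *VARIABLES]]


def run_all(cfg: RunConfig) -> RunResult:
    """Run the full pipeline and (optionally) write the report bundle."""
    if cfg.mode == "simulate":
        truth = generate_variety_table(cfg.generator)
        curves, reference = generate_hydrolysis_curves(cfg.generator, truth)
        raw = generate_raw_measurements(cfg.generator, truth)
        composition = truth[["variety", "type", "AMYL", "FAT", "FIBER", "PRTD", "TS", "RS"]]
        cooking_df, biometry_df = raw.cooking, raw.biometry
        pasting, digesto = traces_from_frames(raw.pasting, raw.digestograms)
    else:
        curves, reference = read_curves_csv(cfg.inputs["curves"])
        if reference is None:
            raise ValueError("curves CSV has no 'glucose' reference rows")
        pasting, digesto = read_traces_csv(cfg.inputs["traces"])
        cooking_df = pd.read_csv(cfg.inputs["cooking"])
        biometry_df = pd.read_csv(cfg.inputs["biometry"])
        composition = pd.read_csv(cfg.inputs["composition"])

    digestion = analyze_digestion(
        curves, reference, composition, t0=cfg.t0, tf=cfg.tf, rs_mode=cfg.rs_mode
    )
    rva_df = analyze_traces(pasting, digesto)
    cook_df = analyze_cooking(
        cooking_df, biometry_df, scale_sl_to_total_water=cfg.scale_sl_to_total_water
    )
    table = assemble_variety_table(digestion, rva_df, cook_df, composition)

    comparison = compare_groups(table, alpha=cfg.alpha)
    correlation = correlation_report(table, alpha=cfg.alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pca_res = pca(table)

    manifest = {
        "version": __version__,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "t0": cfg.t0, "tf": cfg.tf, "alpha": cfg.alpha,
        "rs_mode": cfg.rs_mode,
        "scale_sl_to_total_water": cfg.scale_sl_to_total_water,
        "n_varieties": int(len(table)),
        "rows": {
            "digestion": int(len(digestion)), "rva": int(len(rva_df)),
            "cooking": int(len(cook_df)), "variety_table": int(len(table)),
        },
    }
    result = RunResult(
        variety_table=table, digestion=digestion, rva=rva_df, cooking=cook_df,
        comparison=comparison, correlation=correlation, pca=pca_res,
        manifest=manifest,
    )
    if cfg.outdir is not None:
        _write_bundle(cfg, result, curves, reference, pasting, digesto,
                      cooking_df, biometry_df)
    return result


def traces_from_frames(
    pasting: pd.DataFrame, digesto: pd.DataFrame
) -> tuple[dict[str, ViscosityTrace], dict[str, ViscosityTrace]]:
    """Build ViscosityTrace maps from long-format pasting/digestogram tables."""
    p = {
        str(name): ViscosityTrace(
            variety=str(name), t=sub["time_min"].to_numpy(float),
            viscosity=sub["viscosity_cP"].to_numpy(float),
            temperature=sub["temperature_C"].to_numpy(float),
        )
        for name, sub in pasting.groupby("variety", sort=False)
    }
    d = {
        str(name): ViscosityTrace(
            variety=str(name), t=sub["time_min"].to_numpy(float),
            viscosity=sub["viscosity_cP"].to_numpy(float),
        )
        for name, sub in digesto.groupby("variety", sort=False)
    }
    return p, d


def _write_bundle(cfg, result, curves, reference, pasting, digesto,
                  cooking_df, biometry_df) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_csv(result.variety_table, out / "variety_table.csv")
    write_csv(result.digestion, out / "digestion.csv")
    write_csv(result.rva, out / "rva.csv")
    write_csv(result.cooking, out / "cooking_params.csv")
    write_csv(result.comparison.summary.reset_index(), out / "group_summary.csv")
    write_csv(result.comparison.anova.reset_index(), out / "anova.csv")
    corr_long = (
        result.correlation.r.stack().rename("r").to_frame()
        .join(result.correlation.p.stack().rename("p"))
        .join(result.correlation.significant.stack().rename("significant"))
        .reset_index(names=["var1", "var2"])
    )
    write_csv(corr_long[corr_long["var1"] < corr_long["var2"]], out / "correlations.csv")
    write_csv(result.pca.loadings.reset_index(names="variable"), out / "pca_loadings.csv")
    write_csv(result.pca.scores.reset_index(names="variety"), out / "pca_scores.csv")
    write_csv(
        pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(result.pca.variance_ratio.size)],
            "variance_fraction": result.pca.variance_ratio,
        }),
        out / "pca_variance.csv",
    )
    if cfg.mode == "simulate":
        write_curves_csv(curves, out / "curves.csv", reference=reference)
        pasting_df = pd.concat([
            pd.DataFrame({"variety": tr.variety, "time_min": tr.t,
                          "temperature_C": tr.temperature, "viscosity_cP": tr.viscosity})
            for tr in pasting.values()
        ], ignore_index=True)
        digesto_df = pd.concat([
            pd.DataFrame({"variety": tr.variety, "time_min": tr.t,
                          "viscosity_cP": tr.viscosity})
            for tr in digesto.values()
        ], ignore_index=True)
        write_traces_csv(pasting_df, digesto_df, out / "traces.csv")
        write_csv(cooking_df, out / "cooking_raw.csv")
        write_csv(biometry_df, out / "biometry.csv")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
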