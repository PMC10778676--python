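"""Configuration objects and panel defaults.

The default values describe a 22-variety brown-rice panel spread over six
commercial types (Long A, Short grain, Long B, Medium grain, Basmati,
European Aromatic).  Per-type means for the 16 analysis variables sit in the
ranges reported for such panels; the default correlation structure is built
from a small latent-factor model so that it is positive semi-definite by
construction while reproducing the strong published associations
(r(RS, eGI) = -0.90, r(Tg, eGI) = -0.90, r(SB, eGI) = -0.70,
r(FIBER, PRTD) = 0.70, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VARIABLES",
    "GeneratorConfig",
    "ConfigError",
    "default_type_counts",
    "default_type_means",
    "default_pooled_sds",
    "default_type_kinetics",
    "default_correlation",
    "GLUCOSE_REFERENCE_KINETICS",
]

#: The 16 per-variety analysis variables, in fixed display order.
VARIABLES: tuple[str, ...] = (
    "eGI", "RDS", "SDS", "RS", "TS", "k_RVA", "AMYL", "FAT",
    "FIBER", "PRTD", "Tg", "VPEAK", "SB", "WUp", "VER", "SL",
)

#: Glucose reference hydrolysis kinetics (C_inf %, k min^-1).  Glucose is
#: fully and rapidly available, so both parameters exceed any rice variety.
GLUCOSE_REFERENCE_KINETICS: tuple[float, float] = (100.0, 0.35)


class ConfigError(ValueError):
    """A generator configuration field failed validation."""


def default_type_counts() -> dict[str, int]:
    """Commercial-type composition of the default 22-variety panel."""
    return {
        "Long A": 11,
        "Short grain": 3,
        "Long B": 3,
        "Medium grain": 2,
        "Basmati": 2,
        "European Aromatic": 1,
    }


def default_type_kinetics() -> dict[str, tuple[float, float]]:
    """Per-type first-order hydrolysis parameters (C_inf %, k min^-1).

    Derived by inverting the AUC -> HI -> eGI chain from typical per-type
    eGI means (68-76) against the glucose reference, so that noiseless
    synthetic panels land in the published eGI range.
    """
    return {
        "Long A": (76.1, 0.023),
        "Short grain": (77.1, 0.023),
        "Long B": (66.2, 0.019),
        "Medium grain": (78.2, 0.025),
        "Basmati": (64.5, 0.020),
        "European Aromatic": (75.8, 0.023),
    }


def default_type_means() -> dict[str, dict[str, float]]:
    """Per-type means of the 16 analysis variables (units as in VARIABLES).

    eGI in GI units; starch fractions and composition in % dry matter;
    k_RVA in min^-1; Tg in deg C; VPEAK/SB in cP; WUp and SL in %, VER a ratio.
    """
    rows = {
        "Long A":            (74.33, 24.52, 30.76, 0.43, 62.88, 2.26, 19.66, 2.89, 1.30, 7.89, 66.24, 2202.1, 718.5, 187.3, 3.88, 5.72),
        "Short grain":       (74.79, 23.86, 33.08, 0.32, 64.35, 2.36, 22.19, 3.05, 1.42, 8.29, 64.93, 2112.8, 961.8, 206.4, 4.08, 6.26),
        "Long B":            (68.44, 15.89, 29.44, 4.28, 63.93, 2.07, 27.46, 3.07, 1.45, 8.05, 73.37, 1687.3, 2295.8, 201.2, 4.06, 6.21),
        "Medium grain":      (75.88, 23.95, 34.69, 0.11, 65.67, 2.29, 20.65, 2.96, 1.12, 7.00, 63.81, 2454.0, 718.5, 224.2, 3.93, 7.50),
        "Basmati":           (68.10, 17.24, 27.73, 2.57, 59.25, 2.76, 19.93, 2.62, 1.94, 9.09, 72.53, 1655.8, 2318.3, 246.9, 4.66, 4.94),
        "European Aromatic": (74.17, 24.43, 33.14, 0.22, 61.60, 2.47, 18.31, 2.73, 1.30, 8.57, 65.80, 2537.0, 262.0, 283.9, 3.51, 4.18),
    }
    return {t: dict(zip(VARIABLES, v)) for t, v in rows.items()}


def default_pooled_sds() -> dict[str, float]:
    """Pooled within-type standard deviations for the 16 variables."""
    vals = (2.0, 3.5, 3.0, 1.0, 2.7, 0.17, 3.6, 0.17,
            0.20, 0.70, 1.9, 400.0, 480.0, 16.0, 0.25, 0.80)
    return dict(zip(VARIABLES, vals))


def _factor_loadings() -> np.ndarray:
    """Loadings of the 16 variables on three latent factors.

    Factor 1: starch digestibility (drives eGI, RDS, RS, Tg, SB).
    Factor 2: protein/fibre composition (FIBER, PRTD, TS, WUp, SL).
    Factor 3: retrogradation / expansion (AMYL, VPEAK, SB, VER).
    Cross-products reproduce the strong published pairwise correlations.
    """
    lam = {
        "eGI":   (0.95, 0.0, 0.0),
        "RDS":   (0.95, 0.0, 0.0),
        "SDS":   (0.30, 0.0, 0.0),
        "RS":    (-0.9474, 0.0, 0.0),
        "TS":    (0.0, -0.8367, 0.0),
        "k_RVA": (0.30, 0.0, 0.0),
        "AMYL":  (-0.20, 0.0, 0.70),
        "FAT":   (0.0, 0.0, 0.0),
        "FIBER": (0.0, 0.8367, 0.0),
        "PRTD":  (0.0, 0.8367, 0.0),
        "Tg":    (-0.9474, 0.0, 0.0),
        "VPEAK": (0.25, 0.0, -0.75),
        "SB":    (-0.7368, 0.0, 0.65),
        "WUp":   (0.0, 0.7171, 0.0),
        "VER":   (-0.30, 0.0, 0.74),
        "SL":    (0.0, -0.7171, 0.0),
    }
    return np.array([lam[v] for v in VARIABLES])


def default_correlation() -> np.ndarray:
    """Default 16x16 target correlation matrix (PSD by construction)."""
    lam = _factor_loadings()
    r = lam @ lam.T
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic rice-panel generator.

    Parameters
    ----------
    n_varieties
        Number of varieties in the panel.
    type_counts
        Commercial-type name -> number of varieties; must sum to
        ``n_varieties``.
    per_type_kinetics
        Type -> (C_inf %, k min^-1) first-order hydrolysis parameters.
    timepoints
        Hydrolysis sampling times in minutes; strictly increasing, first 0.
    noise_sd
        SD of additive Gaussian noise on hydrolysis curves, percentage
        points (truncated below at 0 after adding).
    rva_noise_sd
        SD of additive Gaussian noise on digestogram viscosity, cP.
    replicates
        Hydrolysis-assay replicates per variety.
    target_correlation
        16x16 target correlation over :data:`VARIABLES`.
    type_means, pooled_sds
        Location/scale used to map latent normals onto variable units.
    seed
        Base RNG seed.
    """

    n_varieties: int = 22
    type_counts: dict[str, int] = field(default_factory=default_type_counts)
    per_type_kinetics: dict[str, tuple[float, float]] = field(default_factory=default_type_kinetics)
    timepoints: tuple[float, ...] = (0.0, 20.0, 60.0, 120.0, 180.0, 240.0)
    noise_sd: float = 1.5
    rva_noise_sd: float = 15.0
    replicates: int = 1
    target_correlation: np.ndarray = field(default_factory=default_correlation)
    type_means: dict[str, dict[str, float]] = field(default_factory=default_type_means)
    pooled_sds: dict[str, float] = field(default_factory=default_pooled_sds)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_varieties < 1:
            raise ConfigError("n_varieties must be >= 1")
        if sum(self.type_counts.values()) != self.n_varieties:
            raise ConfigError(
                "type_counts must sum to n_varieties "
                f"(got {sum(self.type_counts.values())} != {self.n_varieties})"
            )
        if any(c < 1 for c in self.type_counts.values()):
            raise ConfigError("type_counts entries must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.rva_noise_sd < 0:
            raise ConfigError("rva_noise_sd must be >= 0")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ConfigError("timepoints must be strictly increasing and start at 0")
        for typ in self.type_counts:
            if typ not in self.per_type_kinetics:
                raise ConfigError(f"per_type_kinetics missing entry for type {typ!r}")
            if typ not in self.type_means:
                raise ConfigError(f"type_means missing entry for type {typ!r}")
        c = np.asarray(self.target_correlation, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ConfigError("target_correlation must be a square matrix")
        if c.shape[0] != len(VARIABLES):
            raise ConfigError(
                f"target_correlation must be {len(VARIABLES)}x{len(VARIABLES)}"
            )
        if not np.allclose(c, c.T, atol=1e-10):
            raise ConfigError("target_correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ConfigError("target_correlation must have unit diagonal")

    def variety_names(self) -> list[str]:
        """Deterministic variety identifiers, grouped by type."""
        names = []
        for typ, count in self.type_counts.items():
            tag = "".join(w[0] for w in typ.split()).upper()
            for i in range(count):
                names.append(f"{tag}{i + 1:02d}")
        return names

    def variety_types(self) -> list[str]:
        return [t for t, c in self.type_counts.items() for _ in range(c)]
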