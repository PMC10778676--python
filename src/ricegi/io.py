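"""Tidy-CSV readers and writers for curves, traces and result tables.

All files are UTF-8, "." decimal separator.  Curves are long format
(variety, time_min, value); RVA traces are long format with a ``phase``
column (``pasting`` carries a temperature channel, ``digestogram`` does
not).  Floating-point outputs are written at 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import HydrolysisCurve
from .rva import ViscosityTrace

__all__ = [
    "FLOAT_FORMAT",
    "write_csv",
    "write_curves_csv",
    "read_curves_csv",
    "write_traces_csv",
    "read_traces_csv",
]

FLOAT_FORMAT = "%.6g"
REFERENCE_NAME = "glucose"


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def curves_to_frame(
    curves: dict[str, HydrolysisCurve], reference: HydrolysisCurve | None = None
) -> pd.DataFrame:
    items = list(curves.values()) + ([reference] if reference is not None else [])
    return pd.concat(
        [
            pd.DataFrame({"variety": c.variety, "time_min": c.t, "value": c.C})
            for c in items
        ],
        ignore_index=True,
    )


def write_curves_csv(
    curves: dict[str, HydrolysisCurve],
    path: str | Path,
    reference: HydrolysisCurve | None = None,
) -> None:
    write_csv(curves_to_frame(curves, reference), path)


def read_curves_csv(
    path: str | Path, reference_name: str = REFERENCE_NAME
) -> tuple[dict[str, HydrolysisCurve], HydrolysisCurve | None]:
    """Read long-format curves; a row set named ``glucose`` becomes the reference."""
    df = pd.read_csv(path)
    curves: dict[str, HydrolysisCurve] = {}
    reference = None
    for name, sub in df.groupby("variety", sort=False):
        sub = sub.sort_values("time_min")
        curve = HydrolysisCurve(
            variety=str(name),
            t=sub["time_min"].to_numpy(float),
            C=sub["value"].to_numpy(float),
        )
        if str(name) == reference_name:
            reference = curve
        else:
            curves[str(name)] = curve
    return curves, reference


def write_traces_csv(
    pasting: pd.DataFrame, digestograms: pd.DataFrame, path: str | Path
) -> None:
    p = pasting.assign(phase="pasting")
    d = digestograms.assign(phase="digestogram", temperature_C=np.nan)
    cols = ["variety", "phase", "time_min", "temperature_C", "viscosity_cP"]
    write_csv(pd.concat([p[cols], d[cols]], ignore_index=True), path)


def read_traces_csv(
    path: str | Path,
) -> tuple[dict[str, ViscosityTrace], dict[str, ViscosityTrace]]:
    """Read a combined trace CSV into (pasting, digestogram) trace maps."""
    df = pd.read_csv(path)
    pasting: dict[str, ViscosityTrace] = {}
    digesto: dict[str, ViscosityTrace] = {}
    for (name, phase), sub in df.groupby(["variety", "phase"], sort=False):
        sub = sub.sort_values("time_min")
        if phase == "pasting":
            pasting[str(name)] = ViscosityTrace(
                variety=str(name),
                t=sub["time_min"].to_numpy(float),
                viscosity=sub["viscosity_cP"].to_numpy(float),
                temperature=sub["temperature_C"].to_numpy(float),
            )
        else:
            digesto[str(name)] = ViscosityTrace(
                variety=str(name),
                t=sub["time_min"].to_numpy(float),
                viscosity=sub["viscosity_cP"].to_numpy(float),
            )
    return pasting, digesto
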