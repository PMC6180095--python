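"""CSV / YAML readers and writers for the package's file dialects.

Time-series CSVs carry a ``time_s`` column plus three channel columns
(``ax,ay,az`` for linear acceleration, ``alx,aly,alz`` for angular
acceleration, ``wx,wy,wz`` for angular velocity).  Material curves are
``strain,stress_pa`` tables; a material YAML block reads either a curve file
or the parametric family.  Kinematics tables use the tidy per-(age,
direction) dialect of :mod:`playfall.age_analysis`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .age_analysis import validate_table
from .errors import InvalidParameterError
from .signal_metrics import TriaxSignal, UniformSignal
from .surface_model import HystereticMaterial, MaterialCurve
from .tissue_metrics import ElementField

__all__ = [
    "TRIAX_COLUMNS",
    "read_triax_csv",
    "write_triax_csv",
    "read_material_csv",
    "write_material_csv",
    "load_material_config",
    "read_kinematics_table",
    "write_kinematics_table",
    "read_element_field",
    "write_element_field",
]

TRIAX_COLUMNS = {
    "lin": ("ax", "ay", "az"),
    "ang_acc": ("alx", "aly", "alz"),
    "ang_vel": ("wx", "wy", "wz"),
}
_DEFAULT_UNIT = {"lin": "g", "ang_acc": "rad_s2", "ang_vel": "rad_s"}


def read_triax_csv(path: str | Path, kind: str = "lin", unit: str | None = None) -> TriaxSignal:
    """Read a triaxial time-series CSV; the grid must be uniform."""
    if kind not in TRIAX_COLUMNS:
        raise InvalidParameterError(f"unknown time-series kind {kind!r}")
    df = pd.read_csv(path)
    cols = TRIAX_COLUMNS[kind]
    missing = [c for c in ("time_s", *cols) if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidParameterError(f"{path}: need at least two samples")
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-12):
        raise InvalidParameterError(f"{path}: time grid is not uniform")
    unit = unit or _DEFAULT_UNIT[kind]
    return TriaxSignal.from_arrays(
        float(t[0]), dt, df[cols[0]], df[cols[1]], df[cols[2]], unit=unit
    )


def write_triax_csv(path: str | Path, tri: TriaxSignal, kind: str = "lin") -> None:
    cols = TRIAX_COLUMNS[kind]
    pd.DataFrame(
        {
            "time_s": tri.x.times,
            cols[0]: tri.x.samples,
            cols[1]: tri.y.samples,
            cols[2]: tri.z.samples,
        }
    ).to_csv(path, index=False)


def write_signal_csv(path: str | Path, sig: UniformSignal, column: str = "a") -> None:
    """Write a scalar time series (e.g. a drop acceleration trace)."""
    pd.DataFrame({"time_s": sig.times, column: sig.samples}).to_csv(path, index=False)


def read_material_csv(path: str | Path) -> MaterialCurve:
    df = pd.read_csv(path)
    for col in ("strain", "stress_pa"):
        if col not in df.columns:
            raise InvalidParameterError(f"{path}: missing column {col!r}")
    return MaterialCurve(df["strain"].to_numpy(float), df["stress_pa"].to_numpy(float))


def write_material_csv(path: str | Path, curve: MaterialCurve) -> None:
    pd.DataFrame({"strain": curve.strain, "stress_pa": curve.stress}).to_csv(path, index=False)


def load_material_config(source: str | Path | Mapping) -> HystereticMaterial:
    """Build a material from a YAML file or an equivalent mapping.

    Schema::

        curve: {file: curve.csv} | {parametric: {e1: ..., e3: ...}}
        hu: 0.5        # optional
        shape: 2.0     # optional
        scale: 1.0     # optional
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
        base = Path(".")
    else:
        path = Path(source)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, Mapping):
            raise InvalidParameterError(f"{path}: material config must be a mapping")
        cfg = dict(cfg)
        base = path.parent
    curve_cfg = cfg.get("curve", {"parametric": {}})
    if "file" in curve_cfg:
        curve = read_material_csv(base / curve_cfg["file"])
    elif "parametric" in curve_cfg:
        par = curve_cfg["parametric"] or {}
        kwargs = {k: float(par[k]) for k in ("e1", "e3") if k in par}
        curve = MaterialCurve.parametric(**kwargs)
    else:
        raise InvalidParameterError("material curve config needs 'file' or 'parametric'")
    return HystereticMaterial(
        curve,
        hu=float(cfg.get("hu", 0.5)),
        shape=float(cfg.get("shape", 2.0)),
        scale=float(cfg.get("scale", 1.0)),
    )


def read_kinematics_table(path: str | Path) -> pd.DataFrame:
    return validate_table(pd.read_csv(path))


def write_kinematics_table(path: str | Path, table: pd.DataFrame) -> None:
    validate_table(table).to_csv(path, index=False)


def read_element_field(path: str | Path) -> ElementField:
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise InvalidParameterError(f"{path}: missing column 'value'")
    return ElementField(df["value"].to_numpy(float))


def write_element_field(path: str | Path, field: ElementField) -> None:
    pd.DataFrame(
        {"element_id": np.arange(field.element_count), "value": field.values}
    ).to_csv(path, index=False)
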