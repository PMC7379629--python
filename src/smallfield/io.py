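"""Readers and writers for dose maps, measurement tables and fitted curves.

Dose maps travel either as single-channel TIFF (16-bit integer or float)
with the pixel pitch in a YAML/JSON sidecar, or as whitespace-delimited
text grids whose first line is ``spacing_x spacing_y`` in mm.  Tables are
delimited text with a header row; fitted parameters are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .correction import CorrectionCurveParams
from .errors import ConfigError
from .geometry import DoseMap2D
from .output_factors import OutputFactorCurve, SauerWilbertParams
from .volume import DetectorGeometry

__all__ = [
    "read_dose_map",
    "write_dose_map",
    "read_text_grid",
    "write_text_grid",
    "read_measurements",
    "write_table",
    "write_curve_json",
    "read_curve_json",
    "write_correction_json",
    "read_correction_json",
    "load_detector_table",
    "read_clr_file",
    "write_clr_file",
]

_SHAPE_WORDS = {"circular": "circular", "circle": "circular", "disk": "circular",
                "square": "square"}

_UINT16_MAX_DOSE = 10.0  # Gy mapped onto the 16-bit range when writing


def write_dose_map(path: str | Path, dose_map: DoseMap2D) -> None:
    """Write a dose map as float32 TIFF plus a YAML sidecar with the pitch."""
    path = Path(path)
    tifffile.imwrite(path, dose_map.values.astype(np.float32))
    sidecar = {
        "spacing_x_mm": float(dose_map.spacing_x),
        "spacing_y_mm": float(dose_map.spacing_y),
        "origin_mm": [float(dose_map.origin[0]), float(dose_map.origin[1])],
        "unit": "Gy",
    }
    path.with_suffix(path.suffix + ".yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=False))


def read_dose_map(path: str | Path, spacing: tuple[float, float] | None = None
                  ) -> DoseMap2D:
    """Read a TIFF dose map; pitch from the sidecar unless given explicitly.

    16-bit integer images are rescaled to the sidecar's ``max_dose_gy``
    (default 10 Gy full scale); float images are taken as Gy directly.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ConfigError("dose map TIFF must be single-channel 2D")
    origin = None
    max_dose = _UINT16_MAX_DOSE
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    meta = {}
    if sidecar_path.exists():
        meta = yaml.safe_load(sidecar_path.read_text()) or {}
    if spacing is None:
        try:
            spacing = (float(meta["spacing_x_mm"]), float(meta["spacing_y_mm"]))
        except KeyError:
            raise ConfigError(
                f"no pixel pitch: sidecar {sidecar_path.name} missing or "
                "incomplete and no --spacing given") from None
    if "origin_mm" in meta:
        origin = tuple(float(v) for v in meta["origin_mm"])
    max_dose = float(meta.get("max_dose_gy", max_dose))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) * (max_dose / np.iinfo(arr.dtype).max)
    else:
        arr = arr.astype(float)
    return DoseMap2D(values=arr, spacing_x=spacing[0], spacing_y=spacing[1],
                     origin=origin)


def write_text_grid(path: str | Path, dose_map: DoseMap2D) -> None:
    """Write a dose grid as text: header line ``spacing_x spacing_y`` (mm)."""
    with open(path, "w") as fh:
        fh.write(f"{dose_map.spacing_x:.6g} {dose_map.spacing_y:.6g}\n")
        np.savetxt(fh, dose_map.values, fmt="%.8g")


def read_text_grid(path: str | Path) -> DoseMap2D:
    """Read a delimited-text dose grid with a one-line pitch header."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ConfigError("text grid header must be 'spacing_x spacing_y'")
        sx, sy = float(header[0]), float(header[1])
        values = np.loadtxt(fh)
    return DoseMap2D(values=values, spacing_x=sx, spacing_y=sy)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement table (CSV with header row).

    Required columns: linac, energy, filter, detector, nominal_field,
    repeat_index, ch1.  Optional: ch2, session_position.
    """
    df = pd.read_csv(path)
    required = {"linac", "energy", "filter", "detector", "nominal_field",
                "repeat_index", "ch1"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"measurement table missing columns: {sorted(missing)}")
    return df


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_curve_json(path: str | Path, curve: OutputFactorCurve) -> None:
    p = curve.params
    payload = {
        "model": "sauer-wilbert",
        "beam": curve.beam,
        "params": {"p_inf": p.p_inf, "n": p.n, "l": p.l,
                   "s_inf": p.s_inf, "b": p.b},
        "normalization": curve.normalization,
        "n_bootstrap": len(curve.ensemble),
        "ensemble": [q.as_array().tolist() for q in curve.ensemble],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_curve_json(path: str | Path) -> OutputFactorCurve:
    payload = json.loads(Path(path).read_text())
    p = payload["params"]
    params = SauerWilbertParams(p["p_inf"], p["n"], p["l"], p["s_inf"], p["b"])
    ensemble = tuple(SauerWilbertParams(*row)
                     for row in payload.get("ensemble", []))
    return OutputFactorCurve(params=params, beam=payload.get("beam", ""),
                             ensemble=ensemble)


def write_correction_json(path: str | Path,
                          curves: dict[str, CorrectionCurveParams]) -> None:
    payload = {
        name: {"a": c.a, "b": c.b, "c": c.c, "d": c.d}
        for name, c in curves.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_correction_json(path: str | Path) -> dict[str, CorrectionCurveParams]:
    payload = json.loads(Path(path).read_text())
    return {name: CorrectionCurveParams(v["a"], v["b"], v["c"], v["d"])
            for name, v in payload.items()}


def load_detector_table(path: str | Path) -> list[DetectorGeometry]:
    """Load detector geometries from CSV columns name, shape, dimension_mm.

    ``shape`` accepts circular/circle/disk (dimension = radius) or square
    (dimension = side).  The equal-area square side is computed on load.
    """
    df = pd.read_csv(path)
    required = {"name", "shape", "dimension_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"detector table missing columns: {sorted(missing)}")
    geoms = []
    for _, row in df.iterrows():
        word = str(row["shape"]).strip().lower()
        if word not in _SHAPE_WORDS:
            raise ConfigError(f"unknown detector shape keyword {row['shape']!r}")
        geoms.append(DetectorGeometry(name=str(row["name"]).strip(),
                                      shape=_SHAPE_WORDS[word],
                                      dimension=float(row["dimension_mm"])))
    return geoms


def write_clr_file(path: str | Path, clr_map: dict) -> None:
    """CLR calibrations keyed by 'linac|energy|filter'."""
    Path(path).write_text(yaml.safe_dump(
        {k: float(v) for k, v in clr_map.items()}, sort_keys=True))


def read_clr_file(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return {str(k): float(v) for k, v in data.items()}
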