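"""End-to-end orchestration: field sizing -> volume averaging -> signal
reduction -> output-factor fit -> correction factors -> comparisons.

The stages are plain functions over in-memory objects so each is usable on
its own; ``analyze_campaign`` chains them for one beam and
``run_full_pipeline`` binds them to files on disk.  Uncertainty of a mean
reading is its standard error; uncertainties combine in quadrature
downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beams, io
from .correction import (CorrectionCurveParams, SignalRatio,
                         fit_correction_curve, output_correction_factor)
from .errors import CoverageError, FitError
from .geometry import DoseMap2D, measure_field
from .output_factors import (CorrectedReading, OutputFactorCurve,
                             correct_film_reading, fit_output_factor_curve,
                             tabulate_output_factors)
from .scintillator import cross_normalization, normalize_w1
from .volume import (DEFAULT_KVOL_THRESHOLD, BivariateGaussianFit,
                     DetectorGeometry, fit_central_gaussian, kvol_closed_form)

__all__ = [
    "BeamContext",
    "RunConfig",
    "PipelineResult",
    "size_fields",
    "kvol_table",
    "reduce_readings",
    "corrected_reference_readings",
    "correction_factor_table",
    "analyze_campaign",
    "run_full_pipeline",
]

log = logging.getLogger(__name__)

REFERENCE_FIELD_CM = beams.REFERENCE_FIELD_CM


@dataclass(frozen=True)
class BeamContext:
    """One (linac, energy, filtration) combination."""

    linac: str
    energy_mv: int
    filtration: str  # "WFF" | "FFF"

    def __post_init__(self) -> None:
        if self.filtration not in ("WFF", "FFF"):
            raise ValueError("filtration must be 'WFF' or 'FFF'")

    @property
    def beam_label(self) -> str:
        return f"{self.energy_mv} MV {self.filtration}"


@dataclass
class RunConfig:
    """File-level configuration for a disk-based run."""

    dose_map_paths: dict[float, Path]
    readings_path: Path
    beam: BeamContext
    out_dir: Path
    detector_table_path: Path | None = None
    clr: float | None = None
    kvol_threshold: float = DEFAULT_KVOL_THRESHOLD
    seed: int = 0
    n_bootstrap: int = 500
    min_field_cm: float = 0.8

    def __post_init__(self) -> None:
        for p in [self.readings_path, *self.dose_map_paths.values()]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass(frozen=True)
class PipelineResult:
    """All tables and curves produced for one beam."""

    field_sizes: pd.DataFrame
    gaussian_fits: dict[float, BivariateGaussianFit]
    kvol: pd.DataFrame
    ratios: pd.DataFrame
    epsilon_bar: float
    omega_curve: OutputFactorCurve
    omega_table: pd.DataFrame
    k_table: pd.DataFrame
    k_curves: dict[str, CorrectionCurveParams]
    k_points: dict[str, pd.DataFrame] = dc_field(default_factory=dict)


def size_fields(dose_maps: dict[float, DoseMap2D]) -> pd.DataFrame:
    """Measure FWHM field sizes for every nominal field's dose map."""
    rows = []
    for nominal in sorted(dose_maps):
        fs, center, (roi_mean, roi_sd) = measure_field(dose_maps[nominal])
        rows.append({"nominal_field": nominal, "A_cm": fs.A, "B_cm": fs.B,
                     "s_clin_cm": fs.s_clin, "center_x_mm": center[0],
                     "center_y_mm": center[1], "roi_dose_gy": roi_mean,
                     "roi_sd_gy": roi_sd})
    return pd.DataFrame(rows)


def central_gaussian_fits(dose_maps: dict[float, DoseMap2D],
                          field_sizes: pd.DataFrame
                          ) -> dict[float, BivariateGaussianFit]:
    """Bivariate Gaussian fit of each map's central 3 mm x 3 mm region."""
    centers = field_sizes.set_index("nominal_field")
    fits: dict[float, BivariateGaussianFit | None] = {}
    for nominal in sorted(dose_maps):
        c = centers.loc[nominal]
        try:
            fits[nominal] = fit_central_gaussian(
                dose_maps[nominal], (c["center_x_mm"], c["center_y_mm"]),
                field_label=str(nominal))
        except FitError:
            # flat central region (large field): no volume averaging
            log.info("central region flat at %s cm: k_vol taken as 1", nominal)
            fits[nominal] = None
    return fits


def kvol_table(gaussian_fits: dict[float, BivariateGaussianFit],
               detectors: list[DetectorGeometry],
               field_sizes: pd.DataFrame | None = None,
               energy_label: str = "") -> pd.DataFrame:
    """Volume-averaging factors for every detector at every fitted field."""
    s_map = {}
    if field_sizes is not None:
        s_map = dict(zip(field_sizes["nominal_field"], field_sizes["s_clin_cm"]))
    rows = []
    for nominal in sorted(gaussian_fits):
        fit = gaussian_fits[nominal]
        for geom in detectors:
            rows.append({
                "energy": energy_label,
                "nominal_field": nominal,
                "s_clin_cm": s_map.get(nominal, nominal),
                "detector": geom.name,
                "d_mm": geom.equivalent_side_d,
                "b_mm": fit.b if fit is not None else np.nan,
                "c_mm": fit.c if fit is not None else np.nan,
                "k_vol": (kvol_closed_form(geom.equivalent_side_d, fit)
                          if fit is not None else 1.0),
            })
    return pd.DataFrame(rows)


def _session_mean(df: pd.DataFrame, clr: float | None) -> tuple[float, float, int]:
    """Mean, 1-SD and count of (Cerenkov-corrected) readings.

    The quoted uncertainty is the sample SD of the repeated readings — the
    conservative single-measurement convention used in dosimetry uncertainty
    tables — not the standard error of the mean.
    """
    if "ch2" in df.columns and df["ch2"].notna().any():
        if clr is None:
            raise CoverageError("two-channel readings need a CLR calibration")
        sig = df["ch1"].to_numpy(float) - clr * df["ch2"].to_numpy(float)
    else:
        sig = df["ch1"].to_numpy(float)
    n = sig.size
    mean = float(sig.mean())
    sd = float(sig.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def reduce_readings(readings: pd.DataFrame, detector: str,
                    clr: float | None = None) -> pd.DataFrame:
    """Per-field mean signal ratios M_clin/M_ref for one detector.

    The reference reading is the mean over all reference-field sessions
    (pre and post where present).  Ratio uncertainty combines the standard
    errors of both means in quadrature.
    """
    df = readings[readings["detector"] == detector]
    if df.empty:
        raise CoverageError(f"no readings for detector {detector!r}")
    ref = df[df["nominal_field"] == REFERENCE_FIELD_CM]
    if ref.empty:
        raise CoverageError(
            f"missing 10 cm reference-field readings for {detector!r}")
    m_ref, se_ref, _ = _session_mean(ref, clr)
    rows = []
    for nominal, grp in df.groupby("nominal_field"):
        m, se, n = _session_mean(grp, clr)
        ratio = m / m_ref
        rel = np.sqrt((se / m) ** 2 + (se_ref / m_ref) ** 2) if m > 0 else 0.0
        rows.append({"detector": detector, "nominal_field": float(nominal),
                     "ratio": ratio, "sd": abs(ratio) * rel, "n": n})
    return pd.DataFrame(rows).sort_values("nominal_field", ignore_index=True)


def corrected_reference_readings(film_ratios: pd.DataFrame,
                                 w1_ratios: pd.DataFrame,
                                 kvol: pd.DataFrame,
                                 field_sizes: pd.DataFrame,
                                 kvol_threshold: float = DEFAULT_KVOL_THRESHOLD,
                                 beam: str = ""
                                 ) -> tuple[list[CorrectedReading], float]:
    """Volume-averaging-corrected, cross-normalized reference-detector points.

    Film ratios are multiplied by the film-ROI k_vol, scintillator ratios
    by the scintillator k_vol; corrections below ``kvol_threshold`` are
    skipped (logged).  The scintillator series is then divided by the mean
    scintillator/film ratio over the common fields (epsilon-bar).
    Returns the pooled points and epsilon-bar.
    """
    s_map = dict(zip(field_sizes["nominal_field"], field_sizes["s_clin_cm"]))

    def kv(detector: str, nominal: float) -> float:
        sel = kvol[(kvol["detector"] == detector)
                   & (kvol["nominal_field"] == nominal)]
        if sel.empty:
            return 1.0
        k = float(sel["k_vol"].iloc[0])
        if k - 1.0 <= kvol_threshold:
            log.info("k_vol %.5f below threshold for %s at %s cm: skipped",
                     k, detector, nominal)
            return 1.0
        log.info("applying k_vol %.5f for %s at %s cm", k, detector, nominal)
        return k

    film = film_ratios.set_index("nominal_field")
    w1 = w1_ratios.set_index("nominal_field")
    common = sorted(set(film.index) & set(w1.index))
    film_corr = {f: correct_film_reading(float(film.loc[f, "ratio"]),
                                         kv("EBT3 ROI", f)) for f in common}
    w1_corr_raw = {f: float(w1.loc[f, "ratio"]) * kv("W1 PSD", f)
                   for f in common}
    eps = cross_normalization([w1_corr_raw[f] for f in common],
                              [film_corr[f] for f in common])
    points: list[CorrectedReading] = []
    for f in common:
        s = float(s_map.get(f, f))
        points.append(CorrectedReading(
            s_clin=s, detector="EBT3", value=film_corr[f],
            sd=float(film.loc[f, "sd"]) * kv("EBT3 ROI", f), beam=beam))
        points.append(CorrectedReading(
            s_clin=s, detector="W1",
            value=normalize_w1(float(w1.loc[f, "ratio"]), kv("W1 PSD", f), eps),
            sd=float(w1.loc[f, "sd"]) * kv("W1 PSD", f) / eps, beam=beam))
    return points, eps


def correction_factor_table(curve: OutputFactorCurve, ratios: pd.DataFrame,
                            field_sizes: pd.DataFrame, beam: str = ""
                            ) -> pd.DataFrame:
    """Discrete output correction factors k = Omega/ratio for one detector."""
    s_map = dict(zip(field_sizes["nominal_field"], field_sizes["s_clin_cm"]))
    rows = []
    for _, row in ratios.iterrows():
        s = float(s_map.get(row["nominal_field"], row["nominal_field"]))
        omega = float(curve(s))
        omega_sd = float(curve.sd(s))
        sr = SignalRatio(s_clin=s, detector=str(row["detector"]),
                         ratio=float(row["ratio"]), sd=float(row["sd"]),
                         beam=beam)
        k, k_sd = output_correction_factor(omega, sr, omega_sd=omega_sd)
        rows.append({"detector": sr.detector,
                     "nominal_field": float(row["nominal_field"]),
                     "s_clin": s, "k": k, "sd": k_sd})
    return pd.DataFrame(rows)


def analyze_campaign(dose_maps: dict[float, DoseMap2D],
                     readings: pd.DataFrame,
                     solid_state: list[DetectorGeometry] | None = None,
                     clr: float | None = None,
                     kvol_threshold: float = DEFAULT_KVOL_THRESHOLD,
                     seed: int = 0, n_bootstrap: int = 500,
                     min_field_cm: float = 0.8,
                     beam: str = "") -> PipelineResult:
    """Run the full analysis for one beam on in-memory inputs.

    ``readings`` must contain detectors "EBT3" and "W1" (reference) and may
    contain any solid-state detectors listed in ``solid_state``.
    """
    if REFERENCE_FIELD_CM not in dose_maps:
        raise CoverageError("missing dose map for the 10 cm reference field")
    field_sizes = size_fields(dose_maps)
    gfits = central_gaussian_fits(dose_maps, field_sizes)
    if solid_state is None:
        present = set(readings["detector"].unique()) - {"EBT3", "W1"}
        solid_state = [g for g in beams.DETECTORS if g.name in present]
    all_geoms = [beams.detector("EBT3 ROI"), beams.detector("W1 PSD"),
                 *solid_state]
    kvol = kvol_table(gfits, all_geoms, field_sizes, energy_label=beam)

    film_ratios = reduce_readings(readings, "EBT3")
    w1_ratios = reduce_readings(readings, "W1", clr=clr)
    points, eps = corrected_reference_readings(
        film_ratios, w1_ratios, kvol, field_sizes,
        kvol_threshold=kvol_threshold, beam=beam)
    curve = fit_output_factor_curve(points, seed=seed,
                                    n_bootstrap=n_bootstrap, beam=beam)
    omega_table = tabulate_output_factors(
        curve, field_sizes["s_clin_cm"].tolist(),
        nominal=field_sizes["nominal_field"].tolist())

    k_frames, k_curves, k_points = [], {}, {}
    ratio_frames = [film_ratios, w1_ratios]
    for geom in solid_state:
        det_ratios = reduce_readings(readings, geom.name)
        ratio_frames.append(det_ratios)
        ktab = correction_factor_table(curve, det_ratios, field_sizes,
                                       beam=beam)
        k_frames.append(ktab)
        pts = ktab.rename(columns={"s_clin": "s_clin"})[["s_clin", "k", "sd"]]
        try:
            k_curves[geom.name], k_points[geom.name] = fit_correction_curve(
                pts, min_field_cm=min_field_cm, seed=seed)
        except CoverageError:
            log.warning("too few fields to fit k(S) for %s", geom.name)
    k_table = (pd.concat(k_frames, ignore_index=True) if k_frames
               else pd.DataFrame(columns=["detector", "nominal_field",
                                          "s_clin", "k", "sd"]))
    ratios = pd.concat(ratio_frames, ignore_index=True)
    return PipelineResult(field_sizes=field_sizes, gaussian_fits=gfits,
                          kvol=kvol, ratios=ratios, epsilon_bar=eps,
                          omega_curve=curve, omega_table=omega_table,
                          k_table=k_table, k_curves=k_curves,
                          k_points=k_points)


def run_full_pipeline(config: RunConfig) -> PipelineResult:
    """Disk-based run: read inputs, analyze, persist every intermediate table."""
    dose_maps = {}
    for nominal, path in config.dose_map_paths.items():
        path = Path(path)
        if path.suffix in (".tif", ".tiff"):
            dose_maps[float(nominal)] = io.read_dose_map(path)
        else:
            dose_maps[float(nominal)] = io.read_text_grid(path)
    readings = io.read_measurements(config.readings_path)
    solid_state = None
    if config.detector_table_path is not None:
        solid_state = io.load_detector_table(config.detector_table_path)
    log.info("pipeline start: beam=%s seed=%d kvol_threshold=%g",
             config.beam.beam_label, config.seed, config.kvol_threshold)
    result = analyze_campaign(
        dose_maps, readings, solid_state=solid_state, clr=config.clr,
        kvol_threshold=config.kvol_threshold, seed=config.seed,
        n_bootstrap=config.n_bootstrap, min_field_cm=config.min_field_cm,
        beam=config.beam.beam_label)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(out / "field_sizes.csv", result.field_sizes)
    io.write_table(out / "kvol.csv", result.kvol)
    io.write_table(out / "ratios.csv", result.ratios)
    io.write_table(out / "output_factors.csv", result.omega_table)
    io.write_table(out / "correction_factors.csv", result.k_table)
    io.write_curve_json(out / "omega_curve.json", result.omega_curve)
    io.write_correction_json(out / "k_curves.json", result.k_curves)
    (out / "run_info.json").write_text(json.dumps({
        "beam": config.beam.beam_label, "linac": config.beam.linac,
        "seed": config.seed, "n_bootstrap": config.n_bootstrap,
        "kvol_threshold": config.kvol_threshold,
        "epsilon_bar": result.epsilon_bar,
    }, indent=1))
    return result
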