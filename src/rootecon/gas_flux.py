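"""Chamber CO2 traces and total root respiration flux.

Root respiration of an excised root system is measured by sealing the roots
in a small chamber plumbed to an infrared gas analyzer and recording the
chamber CO2 molar fraction once per second.  After an initial equilibration
transient (the *dead band*), CO2 accumulates linearly and the flux follows
from the ideal gas law:

    F = P * V / (R * T) * dC/dt

with ``F`` in nmol CO2 s^-1, ``P`` the chamber pressure (kPa), ``V`` the
chamber volume corrected for the volume displaced by the roots (converted
ml -> L), ``R`` the gas constant (L kPa K^-1 mol^-1), ``T`` the air
temperature (K) and ``dC/dt`` the OLS slope of the water-corrected CO2
molar fraction (µmol mol^-1 s^-1) over the retained observation window.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_SPLIT = re.compile(r"[,\s]+")


@dataclass(frozen=True)
class ChamberConfig:
    """Physical constants of the respiration chamber and the fit window.

    Defaults: 19 ml chamber at 28 degC (301.15 K) and standard pressure,
    slope fitted over the inclusive 20-90 s window (20 s dead band).
    """

    chamber_volume_ml: float = 19.0
    pressure_kPa: float = 101.325
    temperature_K: float = 301.15
    gas_constant: float = 8.31446  # L kPa K^-1 mol^-1
    dead_band_s: float = 20.0
    window_end_s: float = 90.0

    def __post_init__(self) -> None:
        if self.chamber_volume_ml <= 0:
            raise ValueError("chamber volume must be positive")
        if self.pressure_kPa <= 0 or self.temperature_K <= 0:
            raise ValueError("pressure and temperature must be positive")
        if self.gas_constant <= 0:
            raise ValueError("gas constant must be positive")
        if not self.dead_band_s < self.window_end_s:
            raise ValueError("dead_band_s must be smaller than window_end_s")


@dataclass
class GasTrace:
    """One chamber recording: CO2 molar fraction vs time for one sample."""

    sample_id: str
    time_s: np.ndarray
    co2_umol_mol: np.ndarray
    h2o_mmol_mol: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.co2_umol_mol = np.asarray(self.co2_umol_mol, dtype=float)
        if self.time_s.shape != self.co2_umol_mol.shape:
            raise ValueError("time and CO2 arrays must have equal length")
        if self.time_s.size < 2:
            raise ValueError(
                f"trace {self.sample_id!r}: need at least 2 readings"
            )
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError(f"trace {self.sample_id!r}: time not strictly increasing")
        if not np.all(np.isfinite(self.co2_umol_mol)) or np.any(self.co2_umol_mol <= 0):
            raise ValueError(f"trace {self.sample_id!r}: CO2 values must be finite and > 0")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class FluxResult:
    sample_id: str
    flux_nmol_s: float
    slope_umol_mol_s: float
    r_squared: float
    n_points: int
    corrected_volume_ml: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("flux needs at least 2 fitted points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


def read_gas_trace(path: str | Path) -> GasTrace:
    """Parse one plain-text chamber trace.

    Dialect: optional leading header lines (starting with '#' or containing
    non-numeric tokens), then whitespace- or comma-delimited columns
    ``time_s  co2_umol_mol  [h2o_mmol_mol]``.  The sample id is the filename
    stem (barcode convention).  Unparseable rows after the first data row
    are skipped with a logged warning; fewer than two valid rows is an error.
    """
    path = Path(path)
    times: list[float] = []
    co2: list[float] = []
    h2o: list[float] = []
    seen_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in _SPLIT.split(line) if t]
            try:
                vals = [float(t) for t in tokens[:3]]
                if len(vals) < 2:
                    raise ValueError("need at least two columns")
            except ValueError:
                if seen_data:
                    log.warning("%s:%d: skipping unparseable row %r", path, lineno, line)
                continue  # header line before any data, or bad row
            seen_data = True
            times.append(vals[0])
            co2.append(vals[1])
            h2o.append(vals[2] if len(vals) > 2 else math.nan)
    if len(times) < 2:
        raise ValueError(f"gas trace file {path} contains fewer than 2 valid rows")
    h2o_arr = np.asarray(h2o)
    return GasTrace(
        sample_id=path.stem,
        time_s=np.asarray(times),
        co2_umol_mol=np.asarray(co2),
        h2o_mmol_mol=None if np.all(np.isnan(h2o_arr)) else h2o_arr,
    )


def estimate_slope(
    trace: GasTrace, dead_band_s: float = 20.0, window_end_s: float = 90.0
) -> tuple[float, float, int]:
    """OLS slope of CO2 on time over the inclusive [dead_band, window_end] window.

    Returns ``(slope_umol_mol_s, r_squared, n_points)``.
    """
    mask = (trace.time_s >= dead_band_s) & (trace.time_s <= window_end_s)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(
            f"trace {trace.sample_id!r}: fewer than 2 readings in "
            f"[{dead_band_s}, {window_end_s}] s"
        )
    fit = stats.linregress(trace.time_s[mask], trace.co2_umol_mol[mask])
    r2 = float(fit.rvalue**2)
    if math.isnan(r2):  # flat trace: zero variance in CO2
        r2 = 0.0
    return float(fit.slope), min(r2, 1.0), n


def corrected_chamber_volume(chamber_volume_ml: float, root_volume_mm3: float) -> float:
    """Chamber volume minus the volume displaced by the root sample (ml)."""
    if root_volume_mm3 < 0:
        raise ValueError("root volume must be non-negative")
    root_ml = root_volume_mm3 / 1000.0
    if root_ml >= chamber_volume_ml:
        raise ValueError(
            f"root volume {root_volume_mm3} mm3 >= chamber volume "
            f"{chamber_volume_ml} ml: physically impossible"
        )
    return chamber_volume_ml - root_ml


def compute_flux(
    slope_umol_mol_s: float, chamber: ChamberConfig, corrected_volume_ml: float
) -> float:
    """Ideal-gas conversion of a concentration slope to a molar flux (nmol s^-1).

    F = P·V/(R·T) · dC/dt, with V in litres; the µmol mol^-1 -> mol fraction
    (1e-6) and mol -> nmol (1e9) conversions combine to a factor 1e3.
    """
    if not math.isfinite(slope_umol_mol_s):
        raise ValueError("slope must be finite")
    moles = chamber.pressure_kPa * (corrected_volume_ml / 1000.0) / (
        chamber.gas_constant * chamber.temperature_K
    )
    return moles * slope_umol_mol_s * 1e3


def _volume_lookup(root_volume_table: Mapping[str, float] | pd.DataFrame) -> dict[str, float]:
    if isinstance(root_volume_table, pd.DataFrame):
        if "sample_id" in root_volume_table.columns:
            return dict(
                zip(
                    root_volume_table["sample_id"].astype(str),
                    root_volume_table["root_volume_mm3"].astype(float),
                )
            )
        return {str(k): float(v) for k, v in root_volume_table.iloc[:, 0].items()}
    return {str(k): float(v) for k, v in root_volume_table.items()}


def batch_flux(
    trace_dir: str | Path,
    root_volume_table: Mapping[str, float] | pd.DataFrame,
    chamber: ChamberConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute one :class:`FluxResult` per trace file in a directory.

    ``root_volume_table`` maps barcode -> total root volume (mm3) used for
    the chamber-volume correction; a data frame may additionally carry a
    ``pressure_kPa`` column to override the chamber pressure per sample.
    Per-sample failures (malformed file, missing barcode, bad window) are
    collected into a rejects table rather than aborting the batch.
    Returns ``(results, rejects)`` data frames.
    """
    chamber = chamber or ChamberConfig()
    pressures: dict[str, float] = {}
    if isinstance(root_volume_table, pd.DataFrame) and "pressure_kPa" in root_volume_table.columns:
        pressures = dict(
            zip(root_volume_table["sample_id"].astype(str),
                root_volume_table["pressure_kPa"].astype(float))
        )
    trace_dir = Path(trace_dir)
    files = sorted(trace_dir.glob("*.txt"))
    if not files:
        raise ValueError(f"no trace files (*.txt) found in {trace_dir}")
    volumes = _volume_lookup(root_volume_table)

    rows: list[dict] = []
    rejects: list[dict] = []
    for path in files:
        sample_id = path.stem
        try:
            if sample_id not in volumes:
                raise KeyError(f"barcode {sample_id!r} missing from root volume table")
            trace = read_gas_trace(path)
            slope, r2, n = estimate_slope(trace, chamber.dead_band_s, chamber.window_end_s)
            vol = corrected_chamber_volume(chamber.chamber_volume_ml, volumes[sample_id])
            sample_chamber = chamber
            if sample_id in pressures:
                sample_chamber = ChamberConfig(
                    chamber_volume_ml=chamber.chamber_volume_ml,
                    pressure_kPa=pressures[sample_id],
                    temperature_K=chamber.temperature_K,
                    gas_constant=chamber.gas_constant,
                    dead_band_s=chamber.dead_band_s,
                    window_end_s=chamber.window_end_s,
                )
            flux = compute_flux(slope, sample_chamber, vol)
            if flux < 0:
                log.warning("sample %s: negative flux %.4g nmol/s (kept, flagged)", sample_id, flux)
            rows.append(
                dict(
                    sample_id=sample_id,
                    slope_umol_mol_s=slope,
                    r_squared=r2,
                    n_points=n,
                    corrected_volume_ml=vol,
                    flux_nmol_s=flux,
                    negative_flux=flux < 0,
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-sample failures are data QC
            rejects.append(dict(sample_id=sample_id, file=str(path), reason=str(exc)))
    results = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "slope_umol_mol_s",
            "r_squared",
            "n_points",
            "corrected_volume_ml",
            "flux_nmol_s",
            "negative_flux",
        ],
    )
    rejects_df = pd.DataFrame(rejects, columns=["sample_id", "file", "reason"])
    return results, rejects_df
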