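"""Reading and writing the standard formats the pipeline touches.

ANDI/AIA chromatograms (.CDF, netCDF-3 classic with the ANDI-MS variable
conventions: ``mass_values`` / ``intensity_values`` flattened across scans,
``scan_index`` giving each scan's offset, ``scan_acquisition_time`` in
seconds), NIST MSP text spectral libraries, and CSV/JSON for feature tables
and model summaries.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import netcdf_file

from .datatypes import FeatureTable, SpectrumRecord, ThreeWayArray

__all__ = [
    "ChromatogramRun",
    "CdfFormatError",
    "read_cdf_run",
    "write_cdf_run",
    "bin_to_tensor",
    "read_msp",
    "write_msp",
    "write_feature_table",
    "read_feature_table",
    "write_json_summary",
]

logger = logging.getLogger(__name__)

_MANDATORY_VARS = (
    "mass_values",
    "intensity_values",
    "scan_index",
    "scan_acquisition_time",
)


class CdfFormatError(ValueError):
    """Raised when a .CDF file violates the ANDI-MS variable conventions."""


@dataclass
class ChromatogramRun:
    """One GC-MS run as per-scan centroided peak lists.

    ``mz[i]`` and ``intensity[i]`` are the (possibly empty) peak arrays of
    scan ``i``; ``scan_times`` is in seconds.
    """

    scan_times: np.ndarray
    mz: list[np.ndarray]
    intensity: list[np.ndarray]
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return len(self.scan_times)

    def tic(self) -> np.ndarray:
        return np.array([float(v.sum()) if v.size else 0.0 for v in self.intensity])


def read_cdf_run(path: str | Path) -> ChromatogramRun:
    """Read one ANDI/AIA .CDF chromatographic run.

    Raises
    ------
    CdfFormatError
        If a mandatory ANDI variable is missing or the scan index is
        inconsistent with the flattened point arrays.
    """
    path = Path(path)
    with netcdf_file(str(path), "r", mmap=False) as nc:
        for name in _MANDATORY_VARS:
            if name not in nc.variables:
                raise CdfFormatError(
                    f"{path.name}: mandatory ANDI variable {name!r} is missing"
                )
        mass = np.asarray(nc.variables["mass_values"][:], dtype=float)
        inten = np.asarray(nc.variables["intensity_values"][:], dtype=float)
        index = np.asarray(nc.variables["scan_index"][:], dtype=np.int64)
        times = np.asarray(nc.variables["scan_acquisition_time"][:], dtype=float)

    if mass.shape != inten.shape:
        raise CdfFormatError(
            f"{path.name}: mass_values and intensity_values lengths differ"
        )
    if len(index) != len(times):
        raise CdfFormatError(
            f"{path.name}: scan_index and scan_acquisition_time lengths differ"
        )
    if np.any(np.diff(index) < 0) or (len(index) and index[0] != 0):
        raise CdfFormatError(f"{path.name}: scan_index is not a valid offset array")
    if len(index) and index[-1] > len(mass):
        raise CdfFormatError(
            f"{path.name}: scan_index points beyond mass_values "
            f"({index[-1]} > {len(mass)})"
        )
    if np.any(inten < 0):
        raise CdfFormatError(f"{path.name}: negative intensities")

    bounds = np.append(index, len(mass))
    mz_lists = [mass[bounds[i] : bounds[i + 1]] for i in range(len(index))]
    it_lists = [inten[bounds[i] : bounds[i + 1]] for i in range(len(index))]
    return ChromatogramRun(
        scan_times=times, mz=mz_lists, intensity=it_lists, sample_id=path.stem
    )


def write_cdf_run(run: ChromatogramRun, path: str | Path) -> None:
    """Write a run as an ANDI/AIA .CDF (netCDF-3 classic) file."""
    path = Path(path)
    mass = np.concatenate([m for m in run.mz]) if run.mz else np.empty(0)
    inten = np.concatenate([v for v in run.intensity]) if run.intensity else np.empty(0)
    index = np.cumsum([0] + [len(m) for m in run.mz[:-1]]).astype(np.int32)
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", run.n_scans)
        nc.createDimension("point_number", max(len(mass), 1))
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = run.scan_times
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = index
        v = nc.createVariable("point_count", "i", ("scan_number",))
        v[:] = np.array([len(m) for m in run.mz], dtype=np.int32)
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[: len(mass)] = mass
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[: len(inten)] = inten
        v = nc.createVariable("total_intensity", "d", ("scan_number",))
        v[:] = run.tic()


def tensor_to_runs(tensor: ThreeWayArray) -> list[ChromatogramRun]:
    """Expand a binned cube back into per-sample centroided runs (nonzero bins)."""
    runs = []
    mz = np.asarray(tensor.mz_axis, dtype=float)
    for k in range(tensor.n_samples):
        mz_lists, it_lists = [], []
        for j in range(tensor.n_rt):
            row = tensor.data[k, j]
            nz = np.nonzero(row)[0]
            mz_lists.append(mz[nz])
            it_lists.append(row[nz])
        runs.append(
            ChromatogramRun(
                scan_times=tensor.rt_axis.copy(),
                mz=mz_lists,
                intensity=it_lists,
                sample_id=str(tensor.sample_ids[k]),
            )
        )
    return runs


def bin_to_tensor(
    runs: list[ChromatogramRun],
    mz_lo: int = 40,
    mz_hi: int = 650,
    rt_grid: np.ndarray | None = None,
    channel_tag: str = "TMS",
) -> ThreeWayArray:
    """Bin centroided runs onto a common (RT scans x integer m/z) grid.

    Each raw ion contributes its full intensity to exactly one integer bin
    (nearest-integer rule, inclusive bounds ``[mz_lo, mz_hi]``); in-range
    TIC is conserved exactly. If ``rt_grid`` (scan times, seconds) is not
    given, the first run's scan times truncated to the shortest run are
    used; runs are linearly interpolated per bin onto the grid, and a run
    that does not span the grid raises instead of extrapolating.
    """
    if not runs:
        raise ValueError("no runs supplied")
    if rt_grid is None:
        n = min(r.n_scans for r in runs)
        rt_grid = runs[0].scan_times[:n].copy()
    rt_grid = np.asarray(rt_grid, dtype=float)
    mz_axis = np.arange(int(mz_lo), int(mz_hi) + 1)
    n_mz = len(mz_axis)
    data = np.zeros((len(runs), len(rt_grid), n_mz))
    for k, run in enumerate(runs):
        if run.scan_times[0] > rt_grid[0] + 1e-9 or run.scan_times[-1] < rt_grid[-1] - 1e-9:
            raise ValueError(
                f"run {run.sample_id or k} does not span the requested RT grid"
            )
        mat = np.zeros((run.n_scans, n_mz))
        for j in range(run.n_scans):
            if run.mz[j].size == 0:
                continue
            bins = np.rint(run.mz[j]).astype(int) - int(mz_lo)
            ok = (bins >= 0) & (bins < n_mz)
            np.add.at(mat[j], bins[ok], run.intensity[j][ok])
        if run.n_scans == len(rt_grid) and np.allclose(run.scan_times, rt_grid):
            data[k] = mat
        else:
            for m in range(n_mz):
                data[k, :, m] = np.interp(rt_grid, run.scan_times, mat[:, m])
    return ThreeWayArray(
        data=data,
        rt_axis=rt_grid,
        mz_axis=mz_axis,
        sample_ids=[r.sample_id or f"S{k:03d}" for k, r in enumerate(runs)],
        channel_tag=channel_tag,
    )


# ---------------------------------------------------------------------------
# MSP spectral libraries


def write_msp(
    spectra: list[SpectrumRecord], path: str | Path, base_peak: float = 999.0
) -> int:
    """Write records in the NIST MSP text dialect; returns records written.

    Peak lists are canonicalized (sorted ascending by m/z) and base-peak
    normalized. Records with empty peak lists are skipped with a warning.
    """
    path = Path(path)
    written = 0
    with open(path, "w") as fh:
        for rec in spectra:
            if rec.mz.size == 0:
                warnings.warn(f"MSP record {rec.name!r} has no peaks; skipped")
                logger.warning("MSP record %r has no peaks; skipped", rec.name)
                continue
            norm = rec.normalized(base_peak)
            fh.write(f"Name: {norm.name}\n")
            fh.write(f"Num Peaks: {len(norm.mz)}\n")
            for m, v in zip(norm.mz, norm.intensity):
                fh.write(f"{m:g} {v:g}\n")
            fh.write("\n")
            written += 1
    return written


def read_msp(path: str | Path) -> list[SpectrumRecord]:
    """Parse an MSP library written by :func:`write_msp` (or NIST-style text)."""
    records: list[SpectrumRecord] = []
    name, peaks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if name is not None and peaks:
                    mz, it = map(np.array, zip(*peaks))
                    records.append(SpectrumRecord(name, mz, it))
                name, peaks = None, []
                continue
            low = line.lower()
            if low.startswith("name:"):
                name = line.split(":", 1)[1].strip()
            elif low.startswith("num peaks:") or ":" in line.split(" ")[0]:
                continue
            else:
                parts = line.replace(";", " ").split()
                for i in range(0, len(parts) - 1, 2):
                    peaks.append((float(parts[i]), float(parts[i + 1])))
    if name is not None and peaks:
        mz, it = map(np.array, zip(*peaks))
        records.append(SpectrumRecord(name, mz, it))
    return records


# ---------------------------------------------------------------------------
# Feature tables and summaries


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write values and provenance as a CSV pair (``<path>`` and
    ``<path stem>.provenance.csv``)."""
    path = Path(path)
    df = table.values.copy()
    if table.creatinine is not None:
        df.insert(0, "creatinine", np.asarray(table.creatinine))
    df.to_csv(path, index_label="sample_id")
    table.provenance.to_csv(path.with_suffix(".provenance.csv"), index_label="compound")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, index_col="sample_id")
    creat = None
    if "creatinine" in df.columns:
        creat = df.pop("creatinine")
    prov_path = path.with_suffix(".provenance.csv")
    prov = (
        pd.read_csv(prov_path, index_col="compound")
        if prov_path.exists()
        else pd.DataFrame(index=df.columns)
    )
    return FeatureTable(values=df, provenance=prov, creatinine=creat)


def write_json_summary(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
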