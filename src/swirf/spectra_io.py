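"""Reading and writing SWIR absorbance spectra and study metadata tables.

Spectra travel as plain CSV in one of two dialects:

``long``
    one row per scan x wavelength, columns
    ``specimen_id, species, treatment_cycle, collection_day, scan_replicate,
    wavelength_nm, absorbance``;
``wide``
    one row per scan, the five identifying columns followed by one
    absorbance column per wavelength, headed by the wavelength in nm.

Both dialects are validated against a :class:`WavelengthGrid` inferred from
the file itself: every scan must carry exactly ``n_points`` finite
absorbance values on a strictly increasing, evenly spaced grid.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "CollectionDay",
    "ScanSpectrum",
    "DEFAULT_GRID",
    "LONG_COLUMNS",
    "ID_COLUMNS",
    "read_spectra_table",
    "write_spectra_table",
    "load_fixture_metadata",
    "load_fixture_f",
    "SPECIES",
]

#: The eleven taxa of the field study (Culex pipiens and Cx. restuans are
#: pooled as a complex because females are not reliably separable).
SPECIES = (
    "Ae. cinereus",
    "Ae. vexans",
    "An. punctipennis",
    "An. quadrimaculatus",
    "Cq. perturbans",
    "Cs. melanura",
    "Cx. pipiens/restuans",
    "Oc. abserratus",
    "Oc. canadensis",
    "Oc. excrucians",
    "Ps. ferox",
)

ID_COLUMNS = [
    "specimen_id",
    "species",
    "treatment_cycle",
    "collection_day",
    "scan_replicate",
]
LONG_COLUMNS = ID_COLUMNS + ["wavelength_nm", "absorbance"]


class CollectionDay(str, enum.Enum):
    """Collection-day class relative to the adulticide application.

    PRE is one day before treatment; POST_D1 and POST_D2 are one and two
    days after.  The enum is closed: any other token in an input file is a
    hard error.
    """

    PRE = "PRE"
    POST_D1 = "POST_D1"
    POST_D2 = "POST_D2"

    @classmethod
    def parse(cls, token: str) -> "CollectionDay":
        try:
            return cls(str(token).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown collection_day token {token!r}; "
                f"expected one of {[d.value for d in cls]}"
            ) from None


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength axis shared by every scan of an analysis.

    The default matches the study spectrometer: 228 points at 3.5 nm
    resolution.  The instrument's exact endpoints are not published, so the
    start wavelength is configurable; 900 nm places the span inside the
    shortwave-infrared window and covers the 1210/1450 nm water bands.
    """

    start_nm: float = 900.0
    step_nm: float = 3.5
    n_points: int = 228

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("grid needs at least one point")
        if self.step_nm <= 0:
            raise ValueError("grid step must be positive (strictly increasing)")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def from_wavelengths(cls, wavelengths: Sequence[float]) -> "WavelengthGrid":
        w = np.asarray(wavelengths, dtype=float)
        if w.size < 1:
            raise ValueError("empty wavelength axis")
        if w.size == 1:
            return cls(start_nm=float(w[0]), step_nm=3.5, n_points=1)
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("wavelengths must be evenly spaced")
        return cls(start_nm=float(w[0]), step_nm=float(steps[0]), n_points=int(w.size))


#: 228 points at 3.5 nm starting at 900 nm.
DEFAULT_GRID = WavelengthGrid()


@dataclass
class ScanSpectrum:
    """One scan's absorbance vector plus its specimen/cohort labels."""

    specimen_id: str
    species: str
    treatment_cycle: int
    collection_day: CollectionDay
    scan_replicate: int
    absorbance: np.ndarray
    grid: WavelengthGrid = field(default=DEFAULT_GRID)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.collection_day = CollectionDay.parse(
            self.collection_day.value
            if isinstance(self.collection_day, CollectionDay)
            else self.collection_day
        )
        if self.absorbance.ndim != 1:
            raise ValueError("absorbance must be a 1-D vector")
        if self.absorbance.size != self.grid.n_points:
            raise ValueError(
                f"scan {self.specimen_id!r} rep {self.scan_replicate} has "
                f"{self.absorbance.size} absorbance values, grid expects "
                f"{self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError(
                f"scan {self.specimen_id!r} rep {self.scan_replicate} "
                "contains non-finite absorbance values"
            )
        if self.scan_replicate < 1:
            raise ValueError("scan_replicate must be >= 1")

    def sort_key(self) -> tuple:
        return (self.species, self.specimen_id, self.scan_replicate)


def _scan_sort_key(scan: ScanSpectrum) -> tuple:
    return scan.sort_key()


def read_spectra_table(path: str | Path, dialect: str = "long") -> list[ScanSpectrum]:
    """Read a spectra CSV in the given dialect into :class:`ScanSpectrum` records.

    The wavelength grid is inferred from the wavelength column (long) or the
    wavelength-named column headers (wide) and validated; every scan must
    cover the full grid.  Malformed files fail loudly: a non-numeric
    absorbance cell reports its row number, a ragged scan names the
    specimen, and an unrecognised collection-day token is rejected.
    """
    path = Path(path)
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(
        path,
        dtype={"specimen_id": str, "species": str},
        float_precision="round_trip",
    )
    if dialect == "long":
        return _parse_long(df, path)
    return _parse_wide(df, path)


def _numeric_or_die(series: pd.Series, label: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(series, errors="coerce")
    bad = values.isna() & series.notna() | series.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path.name}: non-numeric {label} value at row {row}")
    return values.to_numpy(dtype=float)


def _parse_long(df: pd.DataFrame, path: Path) -> list[ScanSpectrum]:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: long dialect missing columns {missing}")
    df = df.copy()
    df["absorbance"] = _numeric_or_die(df["absorbance"], "absorbance", path)
    df["wavelength_nm"] = _numeric_or_die(df["wavelength_nm"], "wavelength_nm", path)
    grid = WavelengthGrid.from_wavelengths(np.sort(df["wavelength_nm"].unique()))
    scans: list[ScanSpectrum] = []
    for key, chunk in df.groupby(ID_COLUMNS, sort=False):
        specimen_id, species, cycle, day, rep = key
        chunk = chunk.sort_values("wavelength_nm")
        if len(chunk) != grid.n_points or not np.allclose(
            chunk["wavelength_nm"].to_numpy(), grid.wavelengths, atol=1e-6
        ):
            raise ValueError(
                f"{path.name}: ragged scan for specimen {specimen_id!r} "
                f"replicate {rep}: {len(chunk)} points, grid has {grid.n_points}"
            )
        scans.append(
            ScanSpectrum(
                specimen_id=str(specimen_id),
                species=str(species),
                treatment_cycle=int(cycle),
                collection_day=CollectionDay.parse(day),
                scan_replicate=int(rep),
                absorbance=chunk["absorbance"].to_numpy(),
                grid=grid,
            )
        )
    scans.sort(key=_scan_sort_key)
    return scans


def _parse_wide(df: pd.DataFrame, path: Path) -> list[ScanSpectrum]:
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: wide dialect missing columns {missing}")
    wl_cols = [c for c in df.columns if c not in ID_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(
            f"{path.name}: wide dialect absorbance columns must be wavelengths: {exc}"
        ) from None
    order = np.argsort(wavelengths)
    wl_cols = [wl_cols[i] for i in order]
    grid = WavelengthGrid.from_wavelengths(wavelengths[order])
    scans: list[ScanSpectrum] = []
    for idx, row in df.iterrows():
        values = pd.to_numeric(row[wl_cols], errors="coerce")
        if values.isna().any():
            raise ValueError(
                f"{path.name}: non-numeric absorbance value at row {int(idx) + 2}"
            )
        scans.append(
            ScanSpectrum(
                specimen_id=str(row["specimen_id"]),
                species=str(row["species"]),
                treatment_cycle=int(row["treatment_cycle"]),
                collection_day=CollectionDay.parse(row["collection_day"]),
                scan_replicate=int(row["scan_replicate"]),
                absorbance=values.to_numpy(dtype=float),
                grid=grid,
            )
        )
    scans.sort(key=_scan_sort_key)
    return scans


def write_spectra_table(
    scans: Iterable[ScanSpectrum], path: str | Path, dialect: str = "long"
) -> Path:
    """Write scans as CSV in the given dialect.

    Rows are emitted in a deterministic order (species, specimen, replicate,
    wavelength) so that identical inputs give byte-identical files; the
    output re-reads to the same records via :func:`read_spectra_table`.
    """
    scans = sorted(scans, key=_scan_sort_key)
    if not scans:
        raise ValueError("cannot write an empty scan collection")
    grid = scans[0].grid
    if any(s.grid != grid for s in scans):
        raise ValueError("scans mix wavelength grids; one grid per file")
    path = Path(path)
    if dialect == "long":
        frames = []
        w = grid.wavelengths
        for s in scans:
            frames.append(
                pd.DataFrame(
                    {
                        "specimen_id": s.specimen_id,
                        "species": s.species,
                        "treatment_cycle": s.treatment_cycle,
                        "collection_day": s.collection_day.value,
                        "scan_replicate": s.scan_replicate,
                        "wavelength_nm": w,
                        "absorbance": s.absorbance,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    elif dialect == "wide":
        records = []
        wl_names = [repr(float(x)) for x in grid.wavelengths]
        for s in scans:
            rec = {
                "specimen_id": s.specimen_id,
                "species": s.species,
                "treatment_cycle": s.treatment_cycle,
                "collection_day": s.collection_day.value,
                "scan_replicate": s.scan_replicate,
            }
            rec.update(dict(zip(wl_names, s.absorbance)))
            records.append(rec)
        pd.DataFrame.from_records(records).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _data_path(name: str):
    return resources.files("swirf.data").joinpath(name)


def load_fixture_metadata() -> pd.DataFrame:
    """Study metadata: abundance and scanning totals by collection day,
    preservation time, ambient scanning conditions, larval habitat,
    voltinism and average maximum flight distance for the 11 taxa.

    Returned as a DataFrame indexed by species.  ``max_flight_km`` is NaN
    for the two species without a published dispersal range.  The
    ``published_group`` column carries the study's A-D trend classification
    for cross-checking the classifier.
    """
    with resources.as_file(_data_path("field_metadata.csv")) as p:
        df = pd.read_csv(p)
    df = df.set_index("species")
    if len(df) != 11:
        raise ValueError("metadata fixture must have 11 species rows")
    for day in ("pre", "post_d1", "post_d2"):
        bad = df[f"abundance_{day}"] < df[f"scanned_{day}"]
        if bad.any():
            # one published cell (Cs. melanura POST d1: 109 scanned of 108
            # trapped) breaks the expected ordering; surface, don't reject
            warnings.warn(
                f"scanned exceeds abundance ({day}) for {list(df.index[bad])}",
                stacklevel=2,
            )
    return df


def load_fixture_f() -> pd.DataFrame:
    """Published cohort outlier fractions f by species and collection-day
    class (PRE, POST d1, POST d2, POST d1+d2), indexed by species."""
    with resources.as_file(_data_path("cohort_f.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("species")
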