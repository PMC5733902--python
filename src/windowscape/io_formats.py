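"""Readers and writers for genotype tables, rasters, pairwise matrices and the
run configuration.

Conventions
-----------
* Missing allele calls are canonically stored as ``0`` (the GenePop sentinel);
  a locus is missing for an individual when both of its alleles are 0.
* Coordinates are WGS84 decimal degrees; all ground distances downstream are
  great-circle (haversine, R = 6371 km).
* Pairwise matrices are written as labeled square TSV files.
"""
from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: canonical in-memory missing allele marker
MISSING = 0

_RESERVED_CSV_COLUMNS = ("individual_id", "deme_id", "lon", "lat", "year", "cluster_label")


# ---------------------------------------------------------------------------
# GenotypeTable
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenotypeTable:
    """Diploid genotype calls with per-individual metadata.

    Attributes
    ----------
    individual_id : list of unique individual labels (length n).
    deme_id : deme label per individual.
    lon, lat : WGS84 coordinates per individual (NaN when unknown).
    loci : ordered locus names (length L).
    calls : int array of shape (n, L, 2); allele identifiers, 0 = missing.
    year : optional collection year per individual (NaN allowed).
    cluster_label : optional externally supplied cluster per individual.
    """

    individual_id: list[str]
    deme_id: list[str]
    lon: np.ndarray
    lat: np.ndarray
    loci: list[str]
    calls: np.ndarray
    year: np.ndarray | None = None
    cluster_label: list[str] | None = None

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n = len(self.individual_id)
        if len(set(self.individual_id)) != n:
            raise ValueError("duplicate individual_id")
        if self.calls.shape != (n, len(self.loci), 2):
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        finite = np.isfinite(self.lat) & np.isfinite(self.lon)
        if np.any(np.abs(self.lat[finite]) > 90) or np.any(np.abs(self.lon[finite]) > 180):
            raise ValueError("coordinates out of WGS84 bounds")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean array, True where the locus is missing."""
        return np.all(self.calls == MISSING, axis=2)

    def subset(self, ids: Sequence[str]) -> "GenotypeTable":
        """Row subset preserving the order of `ids`."""
        pos = {iid: k for k, iid in enumerate(self.individual_id)}
        idx = [pos[i] for i in ids]
        return GenotypeTable(
            individual_id=[self.individual_id[i] for i in idx],
            deme_id=[self.deme_id[i] for i in idx],
            lon=self.lon[idx],
            lat=self.lat[idx],
            loci=list(self.loci),
            calls=self.calls[idx],
            year=None if self.year is None else self.year[idx],
            cluster_label=None if self.cluster_label is None
            else [self.cluster_label[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-ish CSV representation (one 'a/b' column per locus)."""
        data = {
            "individual_id": self.individual_id,
            "deme_id": self.deme_id,
            "lon": self.lon,
            "lat": self.lat,
        }
        if self.year is not None:
            data["year"] = self.year
        if self.cluster_label is not None:
            data["cluster_label"] = self.cluster_label
        df = pd.DataFrame(data)
        miss = self.missing_mask()
        for j, locus in enumerate(self.loci):
            col = [
                "" if miss[i, j] else f"{self.calls[i, j, 0]}/{self.calls[i, j, 1]}"
                for i in range(self.n_individuals)
            ]
            df[locus] = col
        return df


def _parse_csv_call(text: str, line_no: int, locus: str) -> tuple[int, int]:
    text = text.strip()
    if text in ("", "NA", "0/0", "0"):
        return (MISSING, MISSING)
    parts = re.split(r"[/:|]", text)
    if len(parts) != 2:
        raise ValueError(
            f"line {line_no}: locus {locus!r}: expected 2 alleles, got {len(parts)} ({text!r})"
        )
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(f"line {line_no}: locus {locus!r}: non-integer allele in {text!r}") from exc
    if a == MISSING or b == MISSING:
        return (MISSING, MISSING)
    return (a, b)


def read_genotypes(path: str | Path, format: str = "csv") -> GenotypeTable:
    """Read a genotype table from CSV or GenePop.

    CSV dialect: columns ``individual_id, deme_id, lon, lat[, year]
    [, cluster_label]`` followed by one column per locus containing
    ``"120/124"`` style calls (empty cell = missing).

    GenePop dialect: title line, locus names (one per line or comma
    separated), ``Pop`` blocks; alleles in 2- or 3-digit fixed width,
    ``00``/``000`` = missing. Each ``Pop`` block becomes one deme, labeled by
    the per-line prefix before the comma; coordinates are NaN.
    """
    path = Path(path)
    if format == "csv":
        return _read_genotypes_csv(path)
    if format == "genepop":
        return _read_genotypes_genepop(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_csv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("individual_id", "deme_id", "lon", "lat"):
        if col not in df.columns:
            raise ValueError(f"CSV genotype file missing required column {col!r}")
    loci = [c for c in df.columns if c not in _RESERVED_CSV_COLUMNS]
    if not loci:
        raise ValueError("no locus columns found")
    ids = df["individual_id"].tolist()
    if len(set(ids)) != len(ids):
        dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate individual_id {dup!r}")
    n = len(df)
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for i, text in enumerate(df[locus]):
            calls[i, j] = _parse_csv_call(text, i + 2, locus)  # +2: header + 1-based
    lon = pd.to_numeric(df["lon"], errors="coerce").to_numpy()
    lat = pd.to_numeric(df["lat"], errors="coerce").to_numpy()
    year = None
    if "year" in df.columns:
        year = pd.to_numeric(df["year"], errors="coerce").to_numpy()
    cluster = df["cluster_label"].tolist() if "cluster_label" in df.columns else None
    return GenotypeTable(ids, df["deme_id"].tolist(), lon, lat, loci, calls,
                         year=year, cluster_label=cluster)


def _read_genotypes_genepop(path: Path) -> GenotypeTable:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("truncated GenePop file")
    # locus names: either one comma-separated line or one name per line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if not loci:
        raise ValueError("no loci declared in GenePop file")
    ids: list[str] = []
    demes: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    counter = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ValueError(f"line {i}: GenePop individual line lacks a comma")
        label, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"line {i}: expected {len(loci)} locus fields, got {len(tokens)}")
        row = []
        for tok, locus in zip(tokens, loci):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(f"line {i}: malformed allele field {tok!r} at {locus}")
            w = len(tok) // 2
            a, b = int(tok[:w]), int(tok[w:])
            if a == 0 or b == 0:
                a = b = MISSING
            row.append((a, b))
        counter += 1
        ids.append(f"{label.strip() or 'ind'}_{counter}")
        demes.append(label.strip() or f"pop{pop_idx}")
        rows.append(row)
    if not rows:
        raise ValueError("GenePop file contains no individuals")
    n = len(rows)
    calls = np.array(rows, dtype=np.int64).reshape(n, len(loci), 2)
    nan = np.full(n, np.nan)
    return GenotypeTable(ids, demes, nan.copy(), nan.copy(), loci, calls)


def write_genotypes_csv(table: GenotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raster
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Raster:
    """Regular grid raster. `data` is float64 with NaN for NoData.

    The geotransform follows the ESRI ASCII convention: (xllcorner,
    yllcorner) is the lower-left corner of the lower-left cell and `cellsize`
    is the square cell edge, in the same units as the coordinates
    (decimal degrees here).
    """

    data: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0
    units: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not (self.cellsize > 0):
            raise ValueError("cellsize must be > 0")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols); row 0 is the top."""
        xs = self.xllcorner + (np.arange(self.n_cols) + 0.5) * self.cellsize
        ys = self.yllcorner + (np.arange(self.n_rows)[::-1] + 0.5) * self.cellsize
        lon, lat = np.meshgrid(xs, ys)
        return lon, lat

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; may be out of bounds."""
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        row = self.n_rows - 1 - int(np.floor((lat - self.yllcorner) / self.cellsize))
        return row, col

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)


def read_raster(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc/.txt) or GeoTIFF (.tif/.tiff)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt", ".grd", ""):
        return _read_ascii_grid(path)
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {path.suffix!r}")


def write_raster(raster: Raster, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt", ".grd", ""):
        _write_ascii_grid(raster, path)
    elif suffix in (".tif", ".tiff"):
        _write_geotiff(raster, path)
    else:
        raise ValueError(f"unknown raster format {path.suffix!r}")


def _read_ascii_grid(path: Path) -> Raster:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in ("ncols", "nrows", "xllcorner", "yllcorner",
                                          "xllcenter", "yllcenter", "cellsize",
                                          "nodata_value"):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"ESRI ASCII grid missing header field {req!r}")
    cellsize = header["cellsize"]
    if cellsize <= 0:
        raise ValueError("cellsize must be positive")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # llcenter variant
        xll = header["xllcenter"] - cellsize / 2.0
        yll = header["yllcenter"] - cellsize / 2.0
    values = np.loadtxt(data_lines).reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    return Raster(values, xll, yll, cellsize, nodata=nodata)


def _write_ascii_grid(raster: Raster, path: Path) -> None:
    out = raster.data.copy()
    out[~np.isfinite(out)] = raster.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {float(raster.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(raster.yllcorner)!r}\n")
        fh.write(f"cellsize {float(raster.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(raster.nodata)!r}\n")
        for row in out:
            # repr of a Python float is the shortest exact round-trip form
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path: Path) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = page.tags
        scale = tags.get("ModelPixelScaleTag")
        tiepoint = tags.get("ModelTiepointTag")
        if scale is None or tiepoint is None:
            raise ValueError("GeoTIFF lacks geotransform tags")
        sx, sy = scale.value[0], scale.value[1]
        if sx <= 0 or sy <= 0:
            raise ValueError("cellsize must be positive")
        # tiepoint maps raster (0,0) upper-left corner to model space
        x0, y_top = tiepoint.value[3], tiepoint.value[4]
        nodata_tag = tags.get("GDAL_NODATA")
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0
        data[data == nodata] = np.nan
        nrows = data.shape[0]
        return Raster(data, x0, y_top - nrows * sy, sx, nodata=nodata)


def _write_geotiff(raster: Raster, path: Path) -> None:
    import tifffile

    out = raster.data.copy()
    out[~np.isfinite(out)] = raster.nodata
    y_top = raster.yllcorner + raster.n_rows * raster.cellsize
    extratags = [
        (33550, "d", 3, (raster.cellsize, raster.cellsize, 0.0)),  # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, raster.xllcorner, y_top, 0.0)),  # ModelTiepoint
        (42113, "s", 0, str(raster.nodata)),  # GDAL_NODATA
    ]
    tifffile.imwrite(path, out, extratags=extratags)


# ---------------------------------------------------------------------------
# Pairwise matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    """Write a labeled square symmetric matrix as TSV."""
    matrix = np.asarray(matrix, dtype=float)
    _check_square_symmetric(matrix, labels)
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ValueError("matrix row and column labels disagree")
    matrix = df.to_numpy(dtype=float)
    _check_square_symmetric(matrix, labels)
    return matrix, labels


def _check_square_symmetric(matrix: np.ndarray, labels: Sequence[str]) -> None:
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix must be square with matching labels")
    finite = np.isfinite(matrix)
    if not np.array_equal(finite, finite.T) or not np.allclose(
            matrix[finite & finite.T].reshape(-1),
            matrix.T[finite & finite.T].reshape(-1), rtol=1e-12, atol=1e-12):
        raise ValueError("matrix is not symmetric")
    if not np.allclose(np.diag(matrix), 0.0, atol=1e-12):
        raise ValueError("matrix diagonal is not zero")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Configuration of a multi-scale, multi-site analysis run."""

    scenarios: list[str] = dataclasses.field(default_factory=lambda: ["T", "E", "Pr", "Pc"])
    diameter_min_km: float = 220.0
    diameter_max_km: float = 1000.0
    diameter_step_km: float = 20.0
    n_permutations: int = 999
    alpha: float = 0.05
    min_demes: int = 3
    seed: int = 0
    connectivity: int = 8
    idw_power: float = 2.0
    idw_k: int = 12
    variogram_lag_km: float = 50.0
    support_band_km: tuple[float, float] = (220.0, 600.0)
    commonality: bool = False

    def __post_init__(self):
        if self.diameter_min_km > self.diameter_max_km:
            raise ValueError("diameter_min_km > diameter_max_km")
        if self.diameter_step_km <= 0:
            raise ValueError("diameter_step_km must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def diameters_km(self) -> np.ndarray:
        n = int(round((self.diameter_max_km - self.diameter_min_km) / self.diameter_step_km)) + 1
        return self.diameter_min_km + self.diameter_step_km * np.arange(n)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "support_band_km" in raw:
            raw["support_band_km"] = tuple(raw["support_band_km"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["support_band_km"] = list(d["support_band_km"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
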