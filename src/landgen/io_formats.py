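"""File formats and shared data model for the landscape-genetics pipeline.

Defines the four containers every stage exchanges — diploid microsatellite
genotypes (:class:`GenotypeTable`), georeferenced grids (:class:`RasterSurface`),
symmetric pairwise matrices (:class:`PairwiseMatrix`) and site coordinates
(:class:`PointSet`) — together with readers/writers for the plain-text formats
the field uses: Genepop, STRUCTURE, ESRI ASCII grid and labelled CSV matrices.
"""

from __future__ import annotations

import csv
import importlib.resources
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # sentinel allele code for an untyped gene copy


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes with one population label per individual.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` holding integer allele
    identifiers (microsatellite repeat sizes); both entries are ``MISSING``
    when the individual was not typed at that locus.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci x 2"
            )
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label required per individual")
        # a call is either missing entirely or has two typed alleles
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing genotype call encountered")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def pop_names(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.populations])
        return np.nonzero(mask)[0]

    def n_per_pop(self) -> dict[str, int]:
        return {p: len(self.pop_indices(p)) for p in self.pop_names()}

    def n_msat(self) -> dict[str, float]:
        """Per-population mean number of typed individuals across loci."""
        typed = self.calls[:, :, 0] != MISSING  # (n_ind, n_loci)
        out = {}
        for p in self.pop_names():
            idx = self.pop_indices(p)
            out[p] = float(typed[idx].sum(axis=0).mean())
        return out

    def subset(self, populations: list[str] | None = None,
               loci: list[str] | None = None) -> "GenotypeTable":
        ind_idx = np.arange(self.n_individuals)
        if populations is not None:
            keep = set(populations)
            ind_idx = np.array([i for i in ind_idx if self.populations[i] in keep])
        loc_idx = np.arange(self.n_loci)
        if loci is not None:
            name_to_i = {l: i for i, l in enumerate(self.loci)}
            missing = [l for l in loci if l not in name_to_i]
            if missing:
                raise KeyError(f"unknown loci: {missing}")
            loc_idx = np.array([name_to_i[l] for l in loci])
        return GenotypeTable(
            [self.individuals[i] for i in ind_idx],
            [self.populations[i] for i in ind_idx],
            [self.loci[i] for i in loc_idx],
            self.calls[np.ix_(ind_idx, loc_idx)],
        )

    def drop_loci(self, excluded: list[str]) -> "GenotypeTable":
        keep = [l for l in self.loci if l not in set(excluded)]
        return self.subset(loci=keep)


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a Genepop file (2- or 3-digit allele codes, whitespace or comma
    separated locus list). Allele code 0 means missing."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("genepop file too short")
    # line 0 is a free title; locus names follow until the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no POP separator found")
    if not loci:
        raise ValueError("no locus names declared")

    individuals: list[str] = []
    populations: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    pop_no = 0
    block_count = 0
    while i < len(lines):
        line = lines[i]
        if line.strip().upper() == "POP":
            if pop_no > 0 and block_count == 0:
                raise ValueError(f"empty POP block before line {i + 1}")
            pop_no += 1
            block_count = 0
            i += 1
            continue
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise ValueError(f"line {i + 1}: missing ',' separator in individual line")
        ident, genostr = line.split(",", 1)
        fields = genostr.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"line {i + 1}: {len(fields)} genotype fields for {len(loci)} declared loci"
            )
        row = []
        for f in fields:
            if len(f) == 4:
                a, b = int(f[:2]), int(f[2:])
            elif len(f) == 6:
                a, b = int(f[:3]), int(f[3:])
            else:
                raise ValueError(f"line {i + 1}: genotype field '{f}' is not 4 or 6 digits")
            if a == 0 or b == 0:
                a = b = MISSING
            row.append((a, b))
        individuals.append(ident.strip())
        populations.append(f"pop{pop_no}")
        calls.append(row)
        block_count += 1
        i += 1
    if pop_no == 0:
        raise ValueError("no POP blocks found")
    if block_count == 0:
        raise ValueError("trailing empty POP block")
    return GenotypeTable(individuals, populations, loci, np.array(calls))


def write_genepop(gt: GenotypeTable, path: str | Path, title: str = "landgen export") -> None:
    """Write 3-digit Genepop; missing calls become 000000."""
    if gt.n_individuals == 0 or gt.n_loci == 0:
        raise ValueError("cannot write an empty genotype table")
    valid = gt.calls[gt.calls != MISSING]
    if valid.size and (valid.max() > 999 or valid.min() < 0):
        raise ValueError("allele identifiers must fit in 3 digits")
    out = [title]
    out.extend(gt.loci)
    current_pop = None
    for i in range(gt.n_individuals):
        if gt.populations[i] != current_pop:
            out.append("POP")
            current_pop = gt.populations[i]
        fields = []
        for l in range(gt.n_loci):
            a, b = gt.calls[i, l]
            if a == MISSING:
                fields.append("000000")
            else:
                fields.append(f"{a:03d}{b:03d}")
        out.append(f"{gt.individuals[i]} , " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")


def write_structure_file(gt: GenotypeTable, path: str | Path) -> None:
    """STRUCTURE plain-text export: two rows per individual (one allele per
    row/locus cell), column 2 an integer population code, missing coded -9."""
    popcode = {p: k + 1 for k, p in enumerate(gt.pop_names())}
    rows = []
    for i in range(gt.n_individuals):
        for copy in range(2):
            cells = [gt.individuals[i].replace(" ", "_"), str(popcode[gt.populations[i]])]
            for l in range(gt.n_loci):
                a = gt.calls[i, l, copy]
                cells.append("-9" if a == MISSING else str(a))
            rows.append("\t".join(cells))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

@dataclass
class RasterSurface:
    """A georeferenced numeric grid. ``values[0, 0]`` is the north-west cell;
    NODATA cells are stored as NaN. ``origin`` is the lower-left corner."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if np.isinf(self.values).any():
            raise ValueError("raster contains non-finite (inf) values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        x0, y0 = self.origin
        return (x0, x0 + self.n_cols * self.cell_size,
                y0, y0 + self.n_rows * self.cell_size)

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map a coordinate to (row, col); row 0 is the northernmost row."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((y - y0) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) falls outside the raster extent")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def copy_with(self, values: np.ndarray) -> "RasterSurface":
        return RasterSurface(values, self.cell_size, self.origin, self.nodata)


def read_ascii_grid(path: str | Path) -> RasterSurface:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize header)."""
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and re.fullmatch(r"[A-Za-z_]+", parts[0]):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"missing header field {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    rows = []
    for line in text[i:]:
        if line.strip():
            vals = [float(v) for v in line.split()]
            if len(vals) != ncols:
                raise ValueError(
                    f"row with {len(vals)} values does not match ncols={ncols}"
                )
            rows.append(vals)
    if len(rows) != nrows:
        raise ValueError(f"{len(rows)} data rows do not match nrows={nrows}")
    values = np.array(rows, dtype=float)
    values[values == nodata] = np.nan
    return RasterSurface(values, header["cellsize"],
                         (header["xllcorner"], header["yllcorner"]), nodata)


def write_ascii_grid(r: RasterSurface, path: str | Path) -> None:
    out = [
        f"ncols {r.n_cols}",
        f"nrows {r.n_rows}",
        f"xllcorner {r.origin[0]:.6g}",
        f"yllcorner {r.origin[1]:.6g}",
        f"cellsize {r.cell_size:.6g}",
        f"NODATA_value {r.nodata:.6g}",
    ]
    vals = np.where(np.isnan(r.values), r.nodata, r.values)
    for row in vals:
        out.append(" ".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# pairwise matrices
# ---------------------------------------------------------------------------

@dataclass
class PairwiseMatrix:
    """Symmetric labelled matrix of pairwise distances or differentiation."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix dimension does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix is not symmetric within 1e-12")

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def reorder(self, labels: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def read_matrix_csv(path: str | Path) -> PairwiseMatrix:
    """Read a labelled square CSV matrix. If only one triangle is filled
    (other cells blank), the filled triangle is mirrored; a fully filled but
    asymmetric matrix (|a_ij - a_ji| > 1e-9) is rejected."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    labels = [c.strip() for c in rows[0][1:]]
    n = len(labels)
    body = rows[1:]
    if len(body) != n or any(len(r) != n + 1 for r in body):
        raise ValueError("matrix body is not square")
    row_labels = [r[0].strip() for r in body]
    if row_labels != labels:
        raise ValueError("row labels do not match column labels")
    M = np.full((n, n), np.nan)
    for i, r in enumerate(body):
        for j, cell in enumerate(r[1:]):
            cell = cell.strip()
            if cell not in ("", "--", "NA"):
                M[i, j] = float(cell)
    np.fill_diagonal(M, np.where(np.isnan(np.diag(M)), 0.0, np.diag(M)))
    both = ~np.isnan(M) & ~np.isnan(M.T)
    if np.nanmax(np.abs(np.where(both, M - M.T, 0.0))) > 1e-9:
        raise ValueError("matrix is asymmetric beyond 1e-9")
    # mirror whichever triangle is present
    M = np.where(np.isnan(M), M.T, M)
    if np.isnan(M).any():
        raise ValueError("matrix has cells missing from both triangles")
    M = 0.5 * (M + M.T)  # remove <=1e-9 asymmetry
    return PairwiseMatrix(labels, M)


def write_matrix_csv(m: PairwiseMatrix, path: str | Path, fmt: str = "%.6g") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + m.labels)
        for i, lab in enumerate(m.labels):
            w.writerow([lab] + [fmt % v for v in m.values[i]])


def write_dual_triangle_csv(upper: PairwiseMatrix, lower: PairwiseMatrix,
                            path: str | Path, fmt: str = "%.3f") -> None:
    """Publication-style layout: one statistic above the diagonal, another
    below (e.g. Jost's D above, theta below)."""
    if upper.labels != lower.labels:
        raise ValueError("label mismatch between triangles")
    n = upper.n
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + upper.labels)
        for i in range(n):
            row = [upper.labels[i]]
            for j in range(n):
                if i == j:
                    row.append("--")
                elif j > i:
                    row.append(fmt % upper.values[i, j])
                else:
                    row.append(fmt % lower.values[i, j])
            w.writerow(row)


# ---------------------------------------------------------------------------
# points
# ---------------------------------------------------------------------------

@dataclass
class PointSet:
    """Named site coordinates in the raster's coordinate system."""

    labels: list[str]
    coordinates: np.ndarray  # (n, 2) x, y
    elevations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.labels), 2):
            raise ValueError("coordinates must be (n_labels, 2)")
        if self.elevations is not None:
            self.elevations = np.asarray(self.elevations, dtype=float)
            if self.elevations.shape != (len(self.labels),):
                raise ValueError("elevations must match label count")

    @property
    def n(self) -> int:
        return len(self.labels)

    def euclidean_matrix(self) -> PairwiseMatrix:
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return PairwiseMatrix(list(self.labels), np.sqrt((d ** 2).sum(axis=2)))

    def check_inside(self, raster: RasterSurface) -> None:
        for lab, (x, y) in zip(self.labels, self.coordinates):
            raster.point_to_cell(x, y)  # raises when outside


def read_points_csv(path: str | Path) -> PointSet:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    lab = df[cols.get("label", df.columns[0])].astype(str).tolist()
    xy = df[[cols["x"], cols["y"]]].to_numpy(float)
    elev = df[cols["elevation"]].to_numpy(float) if "elevation" in cols else None
    return PointSet(lab, xy, elev)


def write_points_csv(pts: PointSet, path: str | Path) -> None:
    df = pd.DataFrame({"label": pts.labels,
                       "x": pts.coordinates[:, 0], "y": pts.coordinates[:, 1]})
    if pts.elevations is not None:
        df["elevation"] = pts.elevations
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bundled study fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("landgen.data").joinpath(name)

def load_gecko_fst() -> PairwiseMatrix:
    """Published pairwise multilocus theta for the 12 leaf-toed gecko sites."""
    with importlib.resources.as_file(_data_path("gecko_fst.csv")) as p:
        return read_matrix_csv(p)

def load_gecko_dest() -> PairwiseMatrix:
    """Published pairwise Jost's D for the 12 leaf-toed gecko sites."""
    with importlib.resources.as_file(_data_path("gecko_dest.csv")) as p:
        return read_matrix_csv(p)

def load_gecko_sites() -> pd.DataFrame:
    """Published per-site diversity summary (elevation, n, H_O, H_E, richness)."""
    with importlib.resources.as_file(_data_path("gecko_sites.csv")) as p:
        return pd.read_csv(p)
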