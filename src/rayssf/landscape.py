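"""Gridded environmental covariates.

A :class:`Landscape` holds K named covariate layers on a shared regular
grid.  Storage is row-major with the origin at the lower-left corner; cells
are half-open ``[x0, x0 + Δs) × [y0, y0 + Δs)`` so every point belongs to
exactly one cell and a point on a shared edge belongs to the upper/right
cell.  ``grain`` is the cell edge Δs in meters; Δs² is the spatial grain
that appears in the residence-time selection function.

On-disk format is the ESRI ASCII grid (plain text), one file per layer,
optionally tied together by a YAML sidecar mapping layer names to files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage


class LandscapeError(ValueError):
    pass


@dataclass
class Landscape:
    """Named covariate layers on a common regular grid.

    Layers are 2-D float arrays indexed ``[row, col]`` with row 0 the
    bottom (southernmost) row.
    """

    layers: dict[str, np.ndarray]
    origin: tuple[float, float]
    grain: float
    crs: str | None = None
    standardization: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.grain <= 0:
            raise LandscapeError("grain must be positive")
        if not self.layers:
            raise LandscapeError("landscape needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise LandscapeError(f"layers have mismatched shapes: {shapes}")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def nrow(self) -> int:
        return self.shape[0]

    @property
    def ncol(self) -> int:
        return self.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        x0, y0 = self.origin
        return (x0, x0 + self.ncol * self.grain, y0, y0 + self.nrow * self.grain)

    def cell_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) with an out-of-bounds mask.

        Half-open convention: col = floor((x − x0)/Δs); a point on the
        right/top outer edge is out of bounds.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x0, y0 = self.origin
        col = np.floor((pts[:, 0] - x0) / self.grain).astype(int)
        row = np.floor((pts[:, 1] - y0) / self.grain).astype(int)
        oob = (col < 0) | (col >= self.ncol) | (row < 0) | (row >= self.nrow)
        return row, col, oob

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x-centers (ncol,) and y-centers (nrow,)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncol) + 0.5) * self.grain
        ys = y0 + (np.arange(self.nrow) + 0.5) * self.grain
        return xs, ys

    def stack(self) -> np.ndarray:
        """Layers as one (nrow, ncol, K) array in name order."""
        return np.stack([self.layers[k] for k in self.names], axis=-1)


def extract_covariates(
    landscape: Landscape, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate vectors w(s) at points by containing-cell lookup.

    Returns
    -------
    values : ndarray, shape (n_points, K)
        One row per point, NaN where out of bounds or the cell is NoData.
    missing : ndarray of bool, shape (n_points,)
        True where the point fell outside the extent or hit a NaN cell.
        Policy (drop, redraw, error) is the caller's.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    row, col, oob = landscape.cell_index(pts)
    k = len(landscape.names)
    values = np.full((len(pts), k), np.nan)
    inb = ~oob
    if inb.any():
        for j, name in enumerate(landscape.names):
            values[inb, j] = landscape.layers[name][row[inb], col[inb]]
    missing = oob | np.isnan(values).any(axis=1)
    return values, missing


def standardize(landscape: Landscape) -> Landscape:
    """Z-score every layer, recording (mean, sd) for back-transformation."""
    record: dict[str, tuple[float, float]] = {}
    new_layers: dict[str, np.ndarray] = {}
    for name, arr in landscape.layers.items():
        mu = float(np.nanmean(arr))
        sd = float(np.nanstd(arr))
        if not np.isfinite(sd) or sd == 0:
            raise LandscapeError(f"layer {name!r} has zero variance; cannot standardize")
        new_layers[name] = (arr - mu) / sd
        record[name] = (mu, sd)
    return Landscape(
        layers=new_layers,
        origin=landscape.origin,
        grain=landscape.grain,
        crs=landscape.crs,
        standardization=record,
    )


# ---------------------------------------------------------------------------
# synthetic landscapes

def _gradient_layer(nrow: int, ncol: int, axis: str) -> np.ndarray:
    if axis == "x":
        return np.tile(np.linspace(0.0, 1.0, ncol), (nrow, 1))
    if axis == "y":
        return np.tile(np.linspace(0.0, 1.0, nrow)[:, None], (1, ncol))
    raise LandscapeError(f"gradient axis must be 'x' or 'y', got {axis!r}")


def _smooth_layer(nrow: int, ncol: int, sigma_cells: float, rng) -> np.ndarray:
    noise = rng.standard_normal((nrow, ncol))
    return ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="wrap")


def _checkerboard_layer(nrow: int, ncol: int, period: int) -> np.ndarray:
    r = np.arange(nrow)[:, None] // period
    c = np.arange(ncol)[None, :] // period
    return ((r + c) % 2).astype(float)


def simulate_landscape(
    nrow: int,
    ncol: int,
    grain: float,
    layer_spec: dict[str, dict],
    seed: int | np.random.Generator | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    standardize_layers: bool = False,
) -> Landscape:
    """Generate a reproducible synthetic landscape.

    ``layer_spec`` maps layer names to generator specs:

    - ``{"kind": "gradient", "axis": "x" | "y"}`` — linear ramp 0..1
    - ``{"kind": "smooth", "sigma_cells": s}`` — Gaussian-smoothed white
      noise (kernel width in cells controls spatial autocorrelation)
    - ``{"kind": "checkerboard", "period": p}`` — alternating 0/1 blocks
    """
    if nrow <= 0 or ncol <= 0:
        raise LandscapeError("nrow and ncol must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    layers: dict[str, np.ndarray] = {}
    for name, spec in layer_spec.items():
        kind = spec.get("kind")
        if kind == "gradient":
            layers[name] = _gradient_layer(nrow, ncol, spec.get("axis", "x"))
        elif kind == "smooth":
            layers[name] = _smooth_layer(nrow, ncol, float(spec.get("sigma_cells", 3.0)), rng)
        elif kind == "checkerboard":
            layers[name] = _checkerboard_layer(nrow, ncol, int(spec.get("period", 4)))
        else:
            raise LandscapeError(f"unknown layer kind {kind!r} for layer {name!r}")
    scape = Landscape(layers=layers, origin=origin, grain=grain)
    return standardize(scape) if standardize_layers else scape


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_NODATA = -9999.0


def write_ascii_grid(array: np.ndarray, origin: tuple[float, float], grain: float, path) -> None:
    """Write one layer as an ESRI ASCII grid (rows written top to bottom)."""
    arr = np.asarray(array, dtype=float)
    out = np.where(np.isnan(arr), _NODATA, arr)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        f"xllcorner {origin[0]:.10g}\n"
        f"yllcorner {origin[1]:.10g}\n"
        f"cellsize {grain:.10g}\n"
        f"NODATA_value {_NODATA:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.17g")


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read an ESRI ASCII grid -> (array row0=bottom, origin, grain)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        body = np.loadtxt(fh, ndmin=2)
    ncols = int(header.get("ncols", body.shape[1]))
    nrows = int(header.get("nrows", body.shape[0]))
    if body.shape != (nrows, ncols):
        raise LandscapeError(f"grid body {body.shape} does not match header ({nrows}, {ncols})")
    if "xllcenter" in header or "yllcenter" in header:
        raise LandscapeError("cell-center referenced grids are not supported")
    nodata = header.get("nodata_value")
    arr = body[::-1].copy()
    if nodata is not None:
        arr[arr == nodata] = np.nan
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return arr, origin, float(header.get("cellsize", 1.0))


def save_landscape(landscape: Landscape, directory) -> Path:
    """Write all layers plus a YAML sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"grain": landscape.grain, "origin": list(landscape.origin),
            "crs": landscape.crs, "layers": {}}
    for name in landscape.names:
        fname = f"{name}.asc"
        write_ascii_grid(landscape.layers[name], landscape.origin, landscape.grain,
                         directory / fname)
        meta["layers"][name] = fname
    if landscape.standardization:
        meta["standardization"] = {
            k: [float(m), float(s)] for k, (m, s) in landscape.standardization.items()
        }
    sidecar = directory / "landscape.yaml"
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
    return sidecar


def load_landscape(source) -> Landscape:
    """Load a landscape from a YAML sidecar (or a directory containing one)."""
    source = Path(source)
    sidecar = source / "landscape.yaml" if source.is_dir() else source
    meta = yaml.safe_load(sidecar.read_text())
    layers: dict[str, np.ndarray] = {}
    origin = tuple(meta["origin"])
    grain = float(meta["grain"])
    for name, fname in meta["layers"].items():
        arr, lorigin, lgrain = read_ascii_grid(sidecar.parent / fname)
        if abs(lgrain - grain) > 1e-9 * grain or not np.allclose(lorigin, origin):
            raise LandscapeError(f"layer {name!r} georeferencing disagrees with sidecar")
        layers[name] = arr
    std = meta.get("standardization")
    return Landscape(
        layers=layers,
        origin=origin,  # type: ignore[arg-type]
        grain=grain,
        crs=meta.get("crs"),
        standardization={k: (v[0], v[1]) for k, v in std.items()} if std else None,
    )
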