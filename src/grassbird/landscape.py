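"""Raster land-cover landscapes.

A landscape is a small rectangular grid of 30-m pixels, each carrying one of
three land-cover classes (grassland, agriculture, forest), together with the
annual-cycle role the grid plays for a migratory grassland bird (breeding
ground, migratory stopover, or wintering ground).  The default grid is
40 x 40 = 1600 pixels, i.e. 1.44 km^2.

Grids are generated by drawing every pixel independently from a cover
distribution (the output of the landowner choice model), and are interrogated
through composition summaries, Moore-neighborhood counts, and a one-hectare
"patch" quality window.  Grids round-trip through the plain-text ESRI ASCII
raster format.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "LandCover",
    "LandscapeRole",
    "CoverDistribution",
    "Landscape",
    "generate_landscape",
    "composition",
    "neighborhood_counts",
    "patch_quality",
    "read_ascii_grid",
    "write_ascii_grid",
]

DEFAULT_PIXEL_SIZE_M = 30.0
DEFAULT_N_ROWS = 40
DEFAULT_N_COLS = 40

#: side of the square window standing in for the one-hectare forage patch.
#: 3 x 3 pixels of 30 m = 0.81 ha, the closest odd-sided square to 1 ha.
PATCH_WINDOW = 3

_NODATA = -9999


class LandCover(enum.IntEnum):
    """The three land-cover classes a pixel can hold.

    Integer codes double as the on-disk raster codes.
    """

    GRASSLAND = 1
    AGRICULTURE = 2
    FOREST = 3


class LandscapeRole(enum.Enum):
    """Which phase of the annual cycle a landscape serves."""

    BREEDING = "breeding"
    STOPOVER = "stopover"
    WINTERING = "wintering"


@dataclass(frozen=True)
class CoverDistribution:
    """Per-pixel probabilities of each land-cover class.

    Probabilities must be in [0, 1] and sum to 1 (within 1e-9).
    """

    p_grassland: float
    p_agriculture: float
    p_forest: float

    def __post_init__(self) -> None:
        for name in ("p_grassland", "p_agriculture", "p_forest"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0) or not np.isfinite(p):
                raise ValueError(
                    f"cover probability {name}={p!r} is outside [0, 1]"
                )
        total = self.p_grassland + self.p_agriculture + self.p_forest
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"cover probabilities must sum to 1, got {total!r} "
                f"(p_grassland={self.p_grassland}, "
                f"p_agriculture={self.p_agriculture}, p_forest={self.p_forest})"
            )

    def as_array(self) -> np.ndarray:
        """Probabilities ordered as (GRASSLAND, AGRICULTURE, FOREST)."""
        return np.array([self.p_grassland, self.p_agriculture, self.p_forest])

    @classmethod
    def from_array(cls, p: np.ndarray) -> "CoverDistribution":
        return cls(float(p[0]), float(p[1]), float(p[2]))


@dataclass
class Landscape:
    """A rectangular grid of land-cover codes with a fixed pixel size.

    Parameters
    ----------
    grid : ndarray of int
        2-D array of :class:`LandCover` codes, indexed (row, col), 0-based.
    pixel_size_m : float
        Pixel edge length in meters (default 30).
    role : LandscapeRole
        Annual-cycle role of this landscape.
    label : str
        Free-text label carried through to output files.
    """

    grid: np.ndarray
    role: LandscapeRole
    pixel_size_m: float = DEFAULT_PIXEL_SIZE_M
    label: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("landscape grid must be a non-empty 2-D array")
        codes = {int(c) for c in LandCover}
        present = set(np.unique(g).tolist())
        if not present <= codes:
            raise ValueError(
                f"grid holds invalid land-cover codes {sorted(present - codes)}"
            )
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        self.grid = g.astype(np.int8)
        if not isinstance(self.role, LandscapeRole):
            raise TypeError(f"role must be a LandscapeRole, got {self.role!r}")

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.grid.size

    @property
    def area_km2(self) -> float:
        """Total area in km^2 (1.44 for the default 40x40 grid of 30-m pixels)."""
        return self.n_pixels * self.pixel_size_m**2 / 1e6

    def mask(self, cover: LandCover) -> np.ndarray:
        """Boolean mask of pixels holding ``cover``."""
        return self.grid == int(cover)

    def value_map(self, by_cover: Mapping[LandCover, float]) -> np.ndarray:
        """Per-pixel float array looking each pixel's cover up in ``by_cover``."""
        lut = np.zeros(max(int(c) for c in LandCover) + 1)
        for c in LandCover:
            lut[int(c)] = float(by_cover[c])
        return lut[self.grid]


def generate_landscape(
    dist: CoverDistribution,
    n_rows: int = DEFAULT_N_ROWS,
    n_cols: int = DEFAULT_N_COLS,
    role: LandscapeRole = LandscapeRole.BREEDING,
    seed: Union[int, np.random.SeedSequence, None] = None,
    pixel_size_m: float = DEFAULT_PIXEL_SIZE_M,
    label: str = "",
) -> Landscape:
    """Draw every pixel independently from a cover distribution.

    A single RNG stream is consumed in row-major order, so a fixed seed and
    identical arguments reproduce the grid bit-for-bit.

    Parameters
    ----------
    dist : CoverDistribution
        Per-pixel probabilities of grassland / agriculture / forest.
    n_rows, n_cols : int
        Grid dimensions (>= 1 each).
    role : LandscapeRole
        Annual-cycle role recorded on the landscape.
    seed : int, SeedSequence or None
        Seed for the pixel draws.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must each be >= 1")
    rng = np.random.default_rng(seed)
    # inverse-CDF draw from a single uniform field, filled row-major
    u = rng.random(size=(n_rows, n_cols))
    thresholds = np.cumsum(dist.as_array())
    grid = np.full((n_rows, n_cols), int(LandCover.FOREST), dtype=np.int8)
    grid[u < thresholds[1]] = int(LandCover.AGRICULTURE)
    grid[u < thresholds[0]] = int(LandCover.GRASSLAND)
    return Landscape(
        grid=grid, role=role, pixel_size_m=pixel_size_m, label=label
    )


def composition(ls: Landscape) -> dict[LandCover, float]:
    """Proportion of pixels in each cover class; proportions sum to 1."""
    n = ls.n_pixels
    return {c: float(np.count_nonzero(ls.grid == int(c))) / n for c in LandCover}


def _check_focal(ls: Landscape, row: int, col: int) -> None:
    if not (0 <= row < ls.n_rows and 0 <= col < ls.n_cols):
        raise IndexError(
            f"focal pixel ({row}, {col}) outside {ls.n_rows}x{ls.n_cols} grid"
        )


def neighborhood_counts(
    ls: Landscape, row: int, col: int, radius: int = 1
) -> dict[LandCover, int]:
    """Cover counts in the Moore neighborhood of a focal pixel.

    Counts cells within Chebyshev distance <= ``radius`` of (row, col),
    excluding the focal pixel itself; cells beyond the grid edge are simply
    omitted, so totals shrink at edges and corners.
    """
    _check_focal(ls, row, col)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r0, r1 = max(0, row - radius), min(ls.n_rows, row + radius + 1)
    c0, c1 = max(0, col - radius), min(ls.n_cols, col + radius + 1)
    window = ls.grid[r0:r1, c0:c1]
    counts = {c: int(np.count_nonzero(window == int(c))) for c in LandCover}
    counts[LandCover(int(ls.grid[row, col]))] -= 1
    return counts


def patch_quality(
    ls: Landscape,
    row: int,
    col: int,
    quality_by_cover: Mapping[LandCover, float],
) -> float:
    """Mean cover quality over the one-hectare patch around a focal pixel.

    The patch is the 3x3 window (edge-truncated) centered on the pixel,
    including the pixel itself.  With qualities in [0, 1] the result is in
    [0, 1].
    """
    _check_focal(ls, row, col)
    half = PATCH_WINDOW // 2
    r0, r1 = max(0, row - half), min(ls.n_rows, row + half + 1)
    c0, c1 = max(0, col - half), min(ls.n_cols, col + half + 1)
    values = ls.value_map(quality_by_cover)[r0:r1, c0:c1]
    return float(values.mean())


# ---------------------------------------------------------------------------
# vectorized window summaries used by the population model

_ONES3 = np.ones((PATCH_WINDOW, PATCH_WINDOW))


def neighbor_mean(values: np.ndarray) -> np.ndarray:
    """Mean of the radius-1 Moore neighborhood of every pixel, focal excluded.

    Edge-truncated: border pixels average over their existing neighbors only.
    """
    values = np.asarray(values, dtype=float)
    sums = convolve2d(values, _ONES3, mode="same")
    counts = convolve2d(np.ones_like(values), _ONES3, mode="same")
    return (sums - values) / (counts - 1.0)


def patch_mean(values: np.ndarray) -> np.ndarray:
    """Mean over the edge-truncated 3x3 window of every pixel, focal included."""
    values = np.asarray(values, dtype=float)
    sums = convolve2d(values, _ONES3, mode="same")
    counts = convolve2d(np.ones_like(values), _ONES3, mode="same")
    return sums / counts


# ---------------------------------------------------------------------------
# plain-text raster I/O (ESRI ASCII grid dialect)


def write_ascii_grid(ls: Landscape, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write a landscape as a single-band ESRI ASCII grid.

    Integer codes follow :class:`LandCover` (1 grassland, 2 agriculture,
    3 forest).  The writer emits a canonical layout so write -> read -> write
    round-trips bit-exactly.
    """
    lines = [
        f"ncols {ls.n_cols}",
        f"nrows {ls.n_rows}",
        "xllcorner 0.0",
        "yllcorner 0.0",
        f"cellsize {ls.pixel_size_m:g}",
        f"NODATA_value {_NODATA}",
    ]
    for row in ls.grid:
        lines.append(" ".join(str(int(v)) for v in row))
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


def read_ascii_grid(
    path: Union[str, Path],
    role: LandscapeRole = LandscapeRole.BREEDING,
    label: str = "",
) -> Landscape:
    """Read a landscape from an ESRI ASCII grid file."""
    text = Path(path).read_text(encoding="utf-8")
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            rows.append([int(v) for v in parts])
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: missing ncols/nrows header")
    grid = np.array(rows, dtype=np.int8)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return Landscape(
        grid=grid,
        role=role,
        pixel_size_m=header.get("cellsize", DEFAULT_PIXEL_SIZE_M),
        label=label,
    )
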