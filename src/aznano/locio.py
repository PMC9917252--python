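"""Localization-table and mask I/O.

Localization tables are whitespace-delimited text in the rapidSTORM
dialect: one localization per row with x/y coordinates in nanometres,
an acquisition frame index and a fitted spot intensity in camera A/D
counts.  Two header styles are tolerated: a plain line of column names
(``x y frame intensity``) and the attribute-style XML header rapidSTORM
itself writes (``# <field identifier="Position-0-0" ...>``).

Masks are single-channel 8-bit TIFF images of the epifluorescence
bouton channel, used downstream to separate synaptic from
extrasynaptic regions.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LocalizationTable",
    "DensityMatrix",
    "EpiImage",
    "FormatError",
    "read_localizations",
    "write_localizations",
    "render_density_matrix",
    "read_mask_image",
    "write_mask_image",
]

#: default spot-intensity cutoff in camera A/D counts; spots at or
#: below this are discarded at read time.
DEFAULT_INTENSITY_MIN = 12000.0


class FormatError(ValueError):
    """Raised when a localization file or mask cannot be interpreted."""


@dataclass
class LocalizationTable:
    """Point set for one measurement: x/y in nm, frame index, intensity.

    The universal currency of the pipeline; every analysis stage
    consumes or produces one of these.
    """

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray
    intensity: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.x.size
        if self.frame is None:
            self.frame = np.zeros(n, dtype=np.int64)
        self.frame = np.asarray(self.frame, dtype=np.int64)
        if self.intensity is None:
            self.intensity = np.full(n, np.inf)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.y.size == n and self.frame.size == n and self.intensity.size == n):
            raise ValueError("all columns must have equal length")
        if n and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in nm."""
        return np.column_stack([self.x, self.y])

    def select(self, idx) -> "LocalizationTable":
        """Row subset (boolean mask or integer indices), order preserved."""
        return LocalizationTable(
            self.x[idx], self.y[idx], self.frame[idx], self.intensity[idx], self.source_id
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "frame": self.frame, "intensity": self.intensity}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source_id: str = "") -> "LocalizationTable":
        return cls(
            df["x"].to_numpy(float),
            df["y"].to_numpy(float),
            df["frame"].to_numpy() if "frame" in df else None,
            df["intensity"].to_numpy(float) if "intensity" in df else None,
            source_id,
        )

    @classmethod
    def empty(cls, source_id: str = "") -> "LocalizationTable":
        z = np.empty(0)
        return cls(z, z, np.empty(0, np.int64), z, source_id)


@dataclass
class DensityMatrix:
    """2D localization count grid (row = y bin, column = x bin)."""

    counts: np.ndarray
    bin_size: float
    origin: tuple[float, float] = (0.0, 0.0)


@dataclass
class EpiImage:
    """8-bit single-channel epifluorescence image used as a bouton mask."""

    pixels: np.ndarray
    pixel_size: float = 126.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise FormatError(
                f"mask must be 8-bit (got dtype {self.pixels.dtype}); refusing to rescale"
            )
        if self.pixels.ndim != 2:
            raise FormatError(
                f"mask must be single-channel 2D (got shape {self.pixels.shape})"
            )


# rapidSTORM attribute-style header: map field identifiers to our names
_RAPIDSTORM_FIELDS = {
    "Position-0-0": "x",
    "Position-1-0": "y",
    "ImageNumber-0-0": "frame",
    "Amplitude-0-0": "intensity",
}
# plain-name header aliases (case-insensitive)
_NAME_ALIASES = {
    "x": "x", "x[nm]": "x", "pos_x": "x", "x_nm": "x",
    "y": "y", "y[nm]": "y", "pos_y": "y", "y_nm": "y",
    "frame": "frame", "t": "frame", "imagenumber": "frame",
    "intensity": "intensity", "amplitude": "intensity", "adc": "intensity",
}


def _parse_header(line: str) -> list[str | None]:
    """Return per-column names (None for columns we do not use)."""
    if "<field" in line:
        cols: list[str | None] = []
        for m in re.finditer(r'identifier="([^"]+)"', line):
            cols.append(_RAPIDSTORM_FIELDS.get(m.group(1)))
        return cols
    tokens = line.lstrip("#").split()
    return [_NAME_ALIASES.get(tok.lower()) for tok in tokens]


def read_localizations(
    path, intensity_min: float = DEFAULT_INTENSITY_MIN
) -> LocalizationTable:
    """Read a rapidSTORM-dialect localization table.

    Rows with ``intensity <= intensity_min`` are dropped at read time
    (only spots whose A/D count exceeds the threshold are analyzed);
    pass ``intensity_min=0`` or ``-inf`` to keep everything a generator
    with positive intensities produced.  Row order is preserved.

    Raises
    ------
    FormatError
        If the header lacks an x or y column, or a data row fails to
        parse.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return LocalizationTable.empty(source_id=path.stem)

    header = lines[0]
    first_is_header = "<field" in header or not _is_numeric_row(header)
    if first_is_header:
        cols = _parse_header(header)
        data_lines = lines[1:]
    else:
        # headerless: assume canonical column order
        cols = ["x", "y", "frame", "intensity"]
        data_lines = lines
    for required in ("x", "y"):
        if required not in cols:
            raise FormatError(f"missing required column: {required}")
    if not data_lines:
        return LocalizationTable.empty(source_id=path.stem)

    try:
        data = np.loadtxt(io.StringIO("\n".join(data_lines)), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"unparseable data row in {path.name}: {exc}") from None
    if data.shape[1] < len([c for c in cols if c is not None]):
        # tolerate extra declared fields beyond actual columns
        cols = cols[: data.shape[1]]
    if data.shape[1] < 2:
        raise FormatError("need at least two numeric columns (x, y)")

    def col(name):
        for i, c in enumerate(cols):
            if c == name and i < data.shape[1]:
                return data[:, i]
        return None

    table = LocalizationTable(
        col("x"), col("y"), col("frame"), col("intensity"), source_id=path.stem
    )
    keep = table.intensity > intensity_min
    return table.select(keep)


def _is_numeric_row(line: str) -> bool:
    try:
        [float(tok) for tok in line.split()]
        return True
    except ValueError:
        return False


def write_localizations(table: LocalizationTable, path) -> None:
    """Write a table in the plain-name dialect (round-trips with read)."""
    df = table.to_dataframe()
    with open(path, "w") as fh:
        fh.write("x y frame intensity\n")
        df.to_csv(fh, sep=" ", header=False, index=False, float_format="%.6f")


def render_density_matrix(locs: LocalizationTable, bin_size: float) -> DensityMatrix:
    """Bin localizations into a count grid with half-open bins.

    ``counts[i, j]`` counts points with
    ``x0 + j*b <= x < x0 + (j+1)*b`` and likewise for y; every
    localization lands in exactly one bin, so the total is conserved.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(locs) == 0:
        return DensityMatrix(np.zeros((0, 0), dtype=np.int64), bin_size)
    x0 = np.floor(locs.x.min() / bin_size) * bin_size
    y0 = np.floor(locs.y.min() / bin_size) * bin_size
    jx = np.floor((locs.x - x0) / bin_size).astype(np.int64)
    iy = np.floor((locs.y - y0) / bin_size).astype(np.int64)
    counts = np.zeros((iy.max() + 1, jx.max() + 1), dtype=np.int64)
    np.add.at(counts, (iy, jx), 1)
    return DensityMatrix(counts, bin_size, (float(x0), float(y0)))


def read_mask_image(path, pixel_size: float = 126.0) -> EpiImage:
    """Load an 8-bit single-channel TIFF mask.

    Anything that is not already 2D uint8 raises :class:`FormatError`
    rather than being silently converted.
    """
    pixels = tifffile.imread(path)
    return EpiImage(pixels, pixel_size)


def write_mask_image(img: EpiImage, path) -> None:
    tifffile.imwrite(path, img.pixels)
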