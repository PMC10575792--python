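"""NanoSIMS ion-count image handling.

An acquisition yields, per ion species, a short stack of raster layers of
per-pixel secondary-ion counts.  Layers are registered to a reference layer
(by convention the second) with integer shifts maximizing cross-correlation
and then summed; downstream quantification works on the summed image.
Coordinates are 0-based, row-major, origin top-left; rasters are square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "IonImage",
    "AlignedStack",
    "IonImageFormatError",
    "AlignmentBoundaryError",
    "read_ion_image",
    "write_ion_image",
    "align_layers",
    "sum_layers",
    "pixel_resolution",
    "cell_isotope_ratio",
    "shift_int",
    "NATURAL_CA46_FRACTION_PCT",
    "NATURAL_CA40_FRACTION_PCT",
    "natural_abundance_permil",
    "enrichment_ceiling_permil",
]

#: natural isotopic abundances of calcium, percent of all Ca atoms
NATURAL_CA46_FRACTION_PCT = 0.004
NATURAL_CA40_FRACTION_PCT = 96.94


class IonImageFormatError(ValueError):
    pass


class AlignmentBoundaryError(RuntimeError):
    """Best shift sits on the search boundary — likely mis-registration."""


@dataclass
class IonImage:
    """Layered count image for one ion species."""

    species: str
    layers: np.ndarray  # (n_layers, h, w) non-negative integer counts
    raster_um: float = 40.0

    def __post_init__(self) -> None:
        layers = np.asarray(self.layers)
        if layers.ndim == 2:
            layers = layers[None]
        if layers.ndim != 3:
            raise IonImageFormatError("layers must be a (n, h, w) stack")
        if not np.issubdtype(layers.dtype, np.integer):
            if not np.allclose(layers, np.round(layers)):
                raise IonImageFormatError("counts must be integers")
            layers = np.round(layers).astype(np.int64)
        if np.any(layers < 0):
            raise IonImageFormatError("counts must be non-negative")
        if not self.raster_um > 0:
            raise ValueError("raster_um must be positive")
        self.layers = layers

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers.shape[1:]

    @property
    def pixels(self) -> int:
        return self.layers.shape[1]

    @property
    def nm_per_px(self) -> float:
        return pixel_resolution(self.raster_um, self.pixels)


@dataclass
class AlignedStack:
    """Registered layer stack: per-layer shifts plus the summed image."""

    shifts: list[tuple[int, int]]
    layers: np.ndarray
    summed: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.summed = self.layers.sum(axis=0)


def _parse_text_block(lines: list[str], row0: int) -> np.ndarray:
    rows = []
    width = None
    for i, line in enumerate(lines):
        parts = line.split()
        try:
            vals = [int(v) for v in parts]
        except ValueError as exc:
            raise IonImageFormatError(
                f"non-numeric entry at row {row0 + i}: {exc}") from None
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise IonImageFormatError(
                f"ragged row {row0 + i}: {len(vals)} columns, expected {width}")
        for j, v in enumerate(vals):
            if v < 0:
                raise IonImageFormatError(
                    f"negative count at row {row0 + i}, col {j}")
        rows.append(vals)
    return np.array(rows, dtype=np.int64)


def read_ion_image(
    path: str | Path,
    format: str | None = None,
    species: str = "",
    raster_um: float = 40.0,
) -> IonImage:
    """Read an ion image from a text matrix or (multi-page) TIFF.

    Text dialect: whitespace-separated integers, layers stacked in one file
    separated by blank lines (or a single layer per file).
    """
    path = Path(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "text"
    if format == "tiff":
        import tifffile

        arr = tifffile.imread(path)
        return IonImage(species=species or path.stem, layers=arr,
                        raster_um=raster_um)
    text = path.read_text()
    blocks: list[list[str]] = [[]]
    starts = [1]
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            blocks[-1].append(line)
        elif blocks[-1]:
            blocks.append([])
            starts.append(lineno + 1)
    if blocks and not blocks[-1]:
        blocks.pop()
        starts.pop()
    if not blocks:
        raise IonImageFormatError(f"{path}: no data")
    layers = [_parse_text_block(b, s) for b, s in zip(blocks, starts)]
    shapes = {l.shape for l in layers}
    if len(shapes) > 1:
        raise IonImageFormatError(f"{path}: layers differ in shape: {shapes}")
    return IonImage(species=species or path.stem, layers=np.stack(layers),
                    raster_um=raster_um)


def write_ion_image(img: IonImage, path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "text"
    if format == "tiff":
        import tifffile

        tifffile.imwrite(path, img.layers.astype(np.uint32),
                         photometric="minisblack")
        return
    with open(path, "w") as fh:
        for k, layer in enumerate(img.layers):
            if k:
                fh.write("\n")
            for row in layer:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def shift_int(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate by whole pixels with zero fill: out[i, j] = arr[i-dr, j-dc]."""
    out = np.zeros_like(arr)
    h, w = arr.shape
    rs = slice(max(dr, 0), h + min(dr, 0))
    cs = slice(max(dc, 0), w + min(dc, 0))
    rs_src = slice(max(-dr, 0), h + min(-dr, 0))
    cs_src = slice(max(-dc, 0), w + min(-dc, 0))
    out[rs, cs] = arr[rs_src, cs_src]
    return out


def _best_shift(ref: np.ndarray, layer: np.ndarray, radius: int) -> tuple[int, int]:
    """Integer (dr, dc) maximizing the raw cross-correlation
    sum_ij ref[i, j] * layer[i + dr, j + dc] within the search radius."""
    best, best_val = (0, 0), -np.inf
    ref = ref.astype(float)
    layer = layer.astype(float)
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            # overlap of ref[i,j] with layer[i+dr, j+dc]
            moved = shift_int(layer, -dr, -dc)
            val = float(np.sum(ref * moved))
            if val > best_val:
                best_val, best = val, (dr, dc)
    return best


def align_layers(img: IonImage, reference_index: int = 1,
                 search_radius: int = 10) -> AlignedStack:
    """Register all layers to the reference layer (the second by default).

    Shifts are whole pixels chosen to maximize cross-correlation with the
    reference within ``search_radius``; shifted layers are zero-filled at
    the borders and summed.  A best shift on the search boundary raises
    :class:`AlignmentBoundaryError` since the true displacement may lie
    outside the searched window.
    """
    if img.n_layers < 2:
        raise ValueError("alignment needs at least two layers")
    if not 0 <= reference_index < img.n_layers:
        raise ValueError(f"reference_index {reference_index} out of range")
    ref = img.layers[reference_index]
    if ref.size == 0:
        raise ValueError("empty layers")
    shifts: list[tuple[int, int]] = []
    aligned = []
    for k in range(img.n_layers):
        if k == reference_index:
            shifts.append((0, 0))
            aligned.append(img.layers[k].copy())
            continue
        dr, dc = _best_shift(ref, img.layers[k], search_radius)
        if max(abs(dr), abs(dc)) >= search_radius:
            raise AlignmentBoundaryError(
                f"layer {k}: best shift ({dr}, {dc}) on search boundary "
                f"(radius {search_radius})")
        shifts.append((dr, dc))
        aligned.append(shift_int(img.layers[k], -dr, -dc))
    return AlignedStack(shifts=shifts, layers=np.stack(aligned))


def sum_layers(aligned: AlignedStack) -> np.ndarray:
    """Elementwise sum of the registered layers."""
    if aligned.layers.ndim != 3:
        raise ValueError("aligned stack must be (n, h, w)")
    return aligned.layers.sum(axis=0)


def pixel_resolution(raster_um: float, pixels: int) -> float:
    """Physical pixel size in nm/px for a square raster.

    E.g. a 40 um raster at 256 px gives 156.25 nm/px.
    """
    if not raster_um > 0:
        raise ValueError("raster_um must be positive")
    if not (isinstance(pixels, (int, np.integer)) and pixels > 0):
        raise ValueError("pixels must be a positive integer")
    return 1000.0 * raster_um / pixels


def cell_isotope_ratio(img46: np.ndarray, img40: np.ndarray,
                       mask: np.ndarray) -> tuple[float, dict]:
    """Per-cell 46Ca/40Ca ratio in per mil over a cell-area mask.

    Computed as 1000 * mean(46Ca) / mean(40Ca) over the masked pixels.
    Because single 46Ca counts can inflate the ratio at low count totals,
    the per-cell total 46Ca and 40Ca counts are returned alongside so that
    downstream statistics can weight or flag low-count cells.
    """
    img46 = np.asarray(img46)
    img40 = np.asarray(img40)
    mask = np.asarray(mask).astype(bool)
    if not (img46.shape == img40.shape == mask.shape):
        raise ValueError("images and mask must share one shape")
    if not mask.any():
        raise ValueError("mask is empty")
    m40 = float(img40[mask].mean())
    if m40 <= 0:
        raise ZeroDivisionError("mean 40Ca over mask is not positive")
    m46 = float(img46[mask].mean())
    ratio = 1000.0 * m46 / m40
    return ratio, {"total_46": float(img46[mask].sum()),
                   "total_40": float(img40[mask].sum()),
                   "n_pixels": int(mask.sum())}


def natural_abundance_permil() -> float:
    """46Ca/40Ca at natural isotopic abundance, in per mil (~0.0413)."""
    return 1000.0 * NATURAL_CA46_FRACTION_PCT / NATURAL_CA40_FRACTION_PCT


def enrichment_ceiling_permil(source_ca46_fraction: float = 0.05) -> float:
    """Maximum achievable enrichment for a labeled Ca source.

    A carbonate source containing 5% 46Ca caps the attainable per-cell
    enrichment at 1000 * 0.05 = 50 per mil (46Ca fraction convention).
    """
    if not 0 < source_ca46_fraction <= 1:
        raise ValueError("source fraction must be in (0, 1]")
    return 1000.0 * source_ca46_fraction
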