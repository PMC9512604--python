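"""Reading and writing images and lesion annotations.

Images are held as :class:`GrayImage` — an 8-bit, top-left-origin raster.
Annotations follow the MIAS dialect: one whitespace-separated record per
image (``id tissue class [severity] [x y radius]``) with lesion centers
given in a bottom-left-origin coordinate system, which is converted to the
internal (row, col) convention at read time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "GrayImage",
    "GroundTruthLump",
    "FormatError",
    "AnnotationParseError",
    "read_image",
    "read_annotations",
    "write_mask",
]


class FormatError(ValueError):
    """Raised for unreadable or unsupported image files."""


class AnnotationParseError(ValueError):
    """Raised when an annotation record cannot be parsed."""


@dataclass
class GrayImage:
    """2-D 8-bit intensity raster, origin top-left, 0-based (row, col)."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError("GrayImage requires a 2-D array")
        if self.pixels.dtype != np.uint8:
            arr = self.pixels
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GroundTruthLump:
    """A reference lesion: a circle in top-left-origin pixel coordinates."""

    image_id: str
    center: tuple[int, int]  # (row, col)
    radius: float
    severity: str | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("lump radius must be positive")


def read_image(path: str | Path) -> GrayImage:
    """Read a single-channel PGM (P2/P5) or PNG image.

    16-bit sources are rescaled linearly onto [0, 255] and rounded half-up,
    because the whole histogram machinery is defined on 256 gray levels.
    Multi-channel images are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".pgm":
        return read_pgm(path)  # maxval-aware; Pillow does not rescale maxval != 255
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # Pillow raises several unrelated types
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: multi-channel ({mode}) images are not supported")
    if arr.dtype == np.uint8:
        pixels = arr
    else:
        arr = arr.astype(np.int64)
        maxval = 65535 if arr.max() > 255 else 255
        pixels = arr.astype(np.uint8) if maxval == 255 else _rescale_to_u8(arr, maxval)
    return GrayImage(pixels=pixels, source_id=path.stem)


def _rescale_to_u8(arr: np.ndarray, maxval: int) -> np.ndarray:
    return np.floor(arr.astype(np.float64) * 255.0 / maxval + 0.5).astype(np.uint8)


def read_pgm(path: str | Path) -> GrayImage:
    """Read a PGM file (P2 ascii or P5 binary) without relying on Pillow.

    Kept as an explicit reader because MIAS-style archives mix dialects and
    some P2 writers use maxval < 255, which must rescale rather than clip.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        data = fh.read()
    tokens, pos = [], 0
    while len(tokens) < 4 and pos < len(data):
        end = data.find(b"\n", pos)
        end = len(data) if end == -1 else end
        line = data[pos:end].split(b"#", 1)[0]
        tokens.extend(line.split())
        pos = end + 1
    if len(tokens) < 4 or tokens[0] not in (b"P2", b"P5"):
        raise FormatError(f"{path}: not a P2/P5 PGM file")
    magic = tokens[0]
    try:
        width, height, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    except ValueError as exc:
        raise FormatError(f"{path}: bad PGM header") from exc
    if magic == b"P2":
        values = data[pos:].split()
        if len(values) < width * height:
            raise FormatError(f"{path}: truncated P2 data")
        arr = np.array(values[: width * height], dtype=np.int64).reshape(height, width)
    else:
        itemsize = 2 if maxval > 255 else 1
        raw = data[pos : pos + width * height * itemsize]
        if len(raw) < width * height * itemsize:
            raise FormatError(f"{path}: truncated P5 data")
        dtype = ">u2" if itemsize == 2 else np.uint8
        arr = np.frombuffer(raw, dtype=dtype).reshape(height, width).astype(np.int64)
    if arr.min() < 0 or arr.max() > maxval:
        raise FormatError(f"{path}: sample values exceed maxval")
    pixels = arr.astype(np.uint8) if maxval == 255 else _rescale_to_u8(arr, maxval)
    return GrayImage(pixels=pixels, source_id=path.stem)


def write_pgm(image: GrayImage | np.ndarray, path: str | Path, ascii_format: bool = False) -> None:
    """Write an 8-bit PGM (binary P5, or ascii P2 when requested)."""
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.uint8)
    h, w = arr.shape
    path = Path(path)
    if ascii_format:
        lines = [f"P2\n{w} {h}\n255\n"]
        lines.extend(" ".join(str(v) for v in row) + "\n" for row in arr)
        path.write_text("".join(lines))
    else:
        with open(path, "wb") as fh:
            fh.write(f"P5\n{w} {h}\n255\n".encode())
            fh.write(arr.tobytes())


def read_annotations(path: str | Path, image_height: int) -> list[GroundTruthLump]:
    """Parse a MIAS-style annotation file.

    Records without x/y/radius (normal images, or abnormalities without a
    marked circle) contribute no lump. The dialect's bottom-left-origin y is
    converted to a top-left row: ``row = image_height - 1 - y``.
    """
    lumps: list[GroundTruthLump] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 3:
            raise AnnotationParseError(f"line {lineno}: expected at least 3 fields: {raw!r}")
        image_id = fields[0]
        severity = None
        rest = fields[3:]
        if rest and not _is_number(rest[0]):
            severity = rest[0]
            rest = rest[1:]
        if not rest:
            continue  # normal record, no circle
        if len(rest) != 3:
            raise AnnotationParseError(f"line {lineno}: expected 'x y radius', got {rest!r}")
        try:
            x, y, radius = (float(v) for v in rest)
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: non-numeric circle field in {raw!r}") from exc
        row = image_height - 1 - int(round(y))
        col = int(round(x))
        if not (0 <= row < image_height) or col < 0:
            raise AnnotationParseError(f"line {lineno}: center outside image bounds")
        lumps.append(GroundTruthLump(image_id=image_id, center=(row, col), radius=radius, severity=severity))
    return lumps


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255, background 0)."""
    arr = (np.asarray(mask).astype(bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")
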