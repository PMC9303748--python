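"""Channel-stack I/O and the five-spot field sampler.

A :class:`ChannelStack` bundles the registered single-channel 8-bit images of
one microscope field (``dapi`` is the nuclear channel; ``green``/``red`` are
immunofluorescence markers; ``myhc`` is the cytoplasmic myotube stain).
Stacks are stored on disk as one grayscale TIFF per channel, named
``<coating>_<day>_w<well>_f<field>_<channel>.tif``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

from .errors import FormatError, GeometryError

log = logging.getLogger(__name__)

#: Channel names with a fixed meaning throughout the package.
KNOWN_CHANNELS = ("dapi", "green", "red", "myhc")

_FILENAME_RE = re.compile(
    r"(?P<coating>[^_]+)_(?P<day>\d+)_w(?P<well>\d+)_f(?P<field>\d+)_(?P<channel>[a-z]+)\.tiff?$"
)


@dataclass(frozen=True)
class Provenance:
    """Condition labels identifying where a field came from."""

    coating: str
    day: int
    well: int
    field: int

    def stem(self) -> str:
        return f"{self.coating}_{self.day}_w{self.well}_f{self.field}"


@dataclass
class ChannelStack:
    """Named 8-bit channels of one field, all with identical shape."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    provenance: Provenance | None = None
    _shape: tuple[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("a ChannelStack needs at least one channel")
        shapes = {name: img.shape for name, img in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise FormatError(f"channel shapes differ: {shapes}")
        for name, img in self.channels.items():
            if img.ndim != 2:
                raise FormatError(f"channel {name!r} is not a 2-D image")
            if img.dtype != np.uint8:
                raise FormatError(
                    f"channel {name!r} has dtype {img.dtype}, expected uint8 "
                    "(use read_stack(..., allow_conversion=True) to down-convert)"
                )
        self._shape = next(iter(shapes.values()))

    @property
    def shape(self) -> tuple[int, int]:
        return self._shape

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def _to_uint8(plane: np.ndarray, *, allow_conversion: bool) -> np.ndarray:
    if plane.dtype == np.uint8:
        return plane
    if not allow_conversion:
        raise FormatError(f"plane has dtype {plane.dtype}, expected 8-bit")
    info = np.iinfo(plane.dtype) if np.issubdtype(plane.dtype, np.integer) else None
    if info is None:
        raise FormatError(f"cannot safely convert dtype {plane.dtype} to uint8")
    log.warning("down-converting %s plane to uint8 (full-range rescale)", plane.dtype)
    scaled = plane.astype(np.float64) * (255.0 / info.max)
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def parse_field_filename(path: str | Path) -> tuple[Provenance, str]:
    """Extract (provenance, channel) from a canonical field filename."""
    m = _FILENAME_RE.search(Path(path).name)
    if m is None:
        raise FormatError(f"cannot parse field filename {Path(path).name!r}")
    prov = Provenance(
        coating=m["coating"], day=int(m["day"]), well=int(m["well"]), field=int(m["field"])
    )
    return prov, m["channel"]


def read_stack(
    source: Mapping[str, str | Path] | Sequence[str | Path] | str | Path,
    *,
    channel_names: Sequence[str] | None = None,
    pixel_size_um: float = 1.0,
    allow_conversion: bool = False,
    require_dapi: bool = True,
) -> ChannelStack:
    """Read a channel stack from per-channel TIFFs or one multi-page TIFF.

    ``source`` may be a mapping ``{channel: path}``, a list of paths whose
    names end in ``_<channel>.tif``, or a single multi-page TIFF (then
    ``channel_names`` gives one name per page).
    """
    provenance = None
    if isinstance(source, Mapping):
        planes = {name: tifffile.imread(str(p)) for name, p in source.items()}
    elif isinstance(source, (str, Path)):
        pages = tifffile.imread(str(source))
        if pages.ndim == 2:
            pages = pages[None]
        if channel_names is None or len(channel_names) != len(pages):
            raise FormatError("multi-page input needs channel_names, one per page")
        planes = {name: page for name, page in zip(channel_names, pages)}
    else:
        planes = {}
        for p in source:
            prov, channel = parse_field_filename(p)
            provenance = provenance or prov
            planes[channel] = tifffile.imread(str(p))
    planes = {k: _to_uint8(np.asarray(v), allow_conversion=allow_conversion) for k, v in planes.items()}
    if require_dapi and "dapi" not in planes:
        raise FormatError(f"required 'dapi' channel missing (got {sorted(planes)})")
    return ChannelStack(channels=planes, pixel_size_um=pixel_size_um, provenance=provenance)


def write_stack(stack: ChannelStack, out_dir: str | Path, stem: str | None = None) -> list[Path]:
    """Write one grayscale TIFF per channel; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stem is None:
        if stack.provenance is None:
            raise FormatError("write_stack needs a stem or a stack with provenance")
        stem = stack.provenance.stem()
    paths = []
    for name, img in stack.channels.items():
        path = out_dir / f"{stem}_{name}.tif"
        tifffile.imwrite(str(path), img)
        paths.append(path)
    return paths


def split_channels(stack: ChannelStack) -> dict[str, np.ndarray]:
    """Return the independent single-channel images (copies, pixel-identical)."""
    return {name: img.copy() for name, img in stack.channels.items()}


def sample_fields(well_image: ChannelStack, field_size: int) -> list[ChannelStack]:
    """Crop five standardized fields from a whole-well image.

    Fields are centered at the well center and one field-size above, below,
    left and right of it, in that order; the five crops are pairwise disjoint.
    """
    h, w = well_image.shape
    if field_size <= 0:
        raise GeometryError("field_size must be positive")
    if h < 3 * field_size or w < 3 * field_size:
        raise GeometryError(
            f"well image {h}x{w} too small for five disjoint {field_size}-px fields"
        )
    cr, cc = h // 2, w // 2
    centers = [
        (cr, cc),
        (cr - field_size, cc),
        (cr + field_size, cc),
        (cr, cc - field_size),
        (cr, cc + field_size),
    ]
    half = field_size // 2
    crops = []
    for i, (r, c) in enumerate(centers):
        r0, c0 = r - half, c - half
        sub = {
            name: img[r0 : r0 + field_size, c0 : c0 + field_size].copy()
            for name, img in well_image.channels.items()
        }
        prov = well_image.provenance
        if prov is not None:
            prov = Provenance(prov.coating, prov.day, prov.well, i)
        crops.append(
            ChannelStack(channels=sub, pixel_size_um=well_image.pixel_size_um, provenance=prov)
        )
    return crops


def find_field_files(directory: str | Path) -> dict[Provenance, dict[str, Path]]:
    """Group canonical per-channel TIFFs in a directory by field provenance."""
    groups: dict[Provenance, dict[str, Path]] = {}
    for path in sorted(Path(directory).glob("*.tif")):
        try:
            prov, channel = parse_field_filename(path)
        except FormatError:
            continue
        groups.setdefault(prov, {})[channel] = path
    return groups
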