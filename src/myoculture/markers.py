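"""Per-nucleus marker calling, myotube recognition, and per-field counts.

A nucleus is called positive for a marker channel when at least one
size-filtered marker segment intersects its region (a stricter full
containment rule is available behind a switch). A myotube is an
MyHC-positive component that contains the centroids of at least two
retained nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigError, DataError
from .io import ChannelStack, Provenance
from .segmentation import (
    MAX_SEGMENT_AREA,
    MIN_SEGMENT_AREA,
    NucleusSegment,
    isodata_threshold,
    segment_nuclei,
)

_STRUCT8 = np.ones((3, 3), dtype=bool)

#: Quantification modes and the channels each requires.
MODE_CHANNELS = {
    "pax7-myod": ("dapi", "green", "red"),
    "myog-myod": ("dapi", "green", "red"),
    "myhc": ("dapi", "myhc"),
    "all": ("dapi", "green", "red", "myhc"),
}


@dataclass
class NucleusPhenotype:
    nucleus_label: int
    green_positive: bool = False
    red_positive: bool = False
    in_myotube: bool = False

    @property
    def double_positive(self) -> bool:
        return self.green_positive and self.red_positive


@dataclass
class MyotubeRecord:
    myotube_label: int
    area_px: int
    member_nuclei: list[int]


@dataclass
class FieldQuantification:
    """Per-field counts feeding the index formulas."""

    n_nuclei: int = 0
    n_green: int = 0
    n_red: int = 0
    n_double: int = 0
    n_myotubes: int = 0
    n_nuclei_in_myotubes: int = 0
    provenance: Provenance | None = None

    def __post_init__(self) -> None:
        if self.n_double > min(self.n_green, self.n_red):
            raise DataError("n_double exceeds a marginal marker count")
        if self.n_nuclei_in_myotubes > self.n_nuclei:
            raise DataError("n_nuclei_in_myotubes exceeds n_nuclei")


def detect_marker_segments(
    channel_image: np.ndarray,
    min_area: int = MIN_SEGMENT_AREA,
    max_area: int = MAX_SEGMENT_AREA,
    *,
    min_contrast: float = 0.0,
) -> np.ndarray:
    """Labeled marker segments: IsoData threshold, 8-connected components,
    inclusive size filter. Border segments are retained (only nuclei are
    border-filtered)."""
    mask = isodata_threshold(channel_image, min_contrast=min_contrast)
    labels, _ = ndi.label(mask.mask, structure=_STRUCT8)
    if labels.max() == 0:
        return labels
    areas = np.bincount(labels.ravel())
    bad = (areas < min_area) | (areas > max_area)
    bad[0] = False
    if bad.any():
        labels[bad[labels]] = 0
    return labels


def assign_markers(
    nuclei: list[NucleusSegment],
    green_segments: np.ndarray | None,
    red_segments: np.ndarray | None,
    *,
    rule: str = "intersection",
) -> list[NucleusPhenotype]:
    """Call per-nucleus marker positivity from labeled marker segments.

    ``rule='intersection'``: positive iff >= 1 marker-segment pixel falls
    inside the nucleus region. ``rule='containment'``: positive iff some
    marker segment lies entirely inside the nucleus region.
    """
    if rule not in ("intersection", "containment"):
        raise ConfigError(f"unknown marker rule {rule!r}")
    labels_seen = [n.label for n in nuclei]
    if len(set(labels_seen)) != len(labels_seen):
        raise DataError("duplicate nucleus labels")

    phenotypes = [NucleusPhenotype(nucleus_label=n.label) for n in nuclei]

    for attr, seg_labels in (("green_positive", green_segments), ("red_positive", red_segments)):
        if seg_labels is None or seg_labels.max() == 0:
            continue
        if rule == "intersection":
            for nuc, ph in zip(nuclei, phenotypes):
                if (seg_labels[nuc.coords[:, 0], nuc.coords[:, 1]] > 0).any():
                    setattr(ph, attr, True)
        else:
            # a segment is contained in a nucleus iff all its pixels carry
            # that nucleus's label in the rasterized nucleus image
            nuc_img = np.zeros(seg_labels.shape, dtype=np.int64)
            for nuc in nuclei:
                nuc_img[nuc.coords[:, 0], nuc.coords[:, 1]] = nuc.label
            by_label = {n.label: ph for n, ph in zip(nuclei, phenotypes)}
            for seg_slice, seg_id in zip(
                ndi.find_objects(seg_labels), range(1, seg_labels.max() + 1)
            ):
                if seg_slice is None:
                    continue
                seg_mask = seg_labels[seg_slice] == seg_id
                under = nuc_img[seg_slice][seg_mask]
                first = under[0]
                if first != 0 and (under == first).all():
                    setattr(by_label[int(first)], attr, True)
    return phenotypes


def detect_myotubes(
    myhc_image: np.ndarray,
    nuclei: list[NucleusSegment],
    *,
    min_myotube_area: int = 300,
    min_contrast: float = 0.0,
) -> list[MyotubeRecord]:
    """Myotubes: MyHC components of sufficient area containing >= 2 retained
    nucleus centroids. Each nucleus belongs to at most one component (the one
    its centroid falls in)."""
    mask = isodata_threshold(myhc_image, min_contrast=min_contrast)
    labels, n_comp = ndi.label(mask.mask, structure=_STRUCT8)
    if n_comp == 0:
        return []
    areas = np.bincount(labels.ravel())
    members: dict[int, list[int]] = {}
    for nuc in nuclei:
        r = int(round(nuc.centroid[0]))
        c = int(round(nuc.centroid[1]))
        r = min(max(r, 0), labels.shape[0] - 1)
        c = min(max(c, 0), labels.shape[1] - 1)
        comp = int(labels[r, c])
        if comp > 0 and areas[comp] >= min_myotube_area:
            members.setdefault(comp, []).append(nuc.label)
    return [
        MyotubeRecord(myotube_label=comp, area_px=int(areas[comp]), member_nuclei=sorted(ids))
        for comp, ids in sorted(members.items())
        if len(ids) >= 2
    ]


def quantify_field(
    stack: ChannelStack,
    mode: str = "all",
    *,
    rule: str = "intersection",
    min_area: int = MIN_SEGMENT_AREA,
    max_area: int = MAX_SEGMENT_AREA,
    exclude_border: bool = True,
    min_myotube_area: int = 300,
    min_seed_distance: int = 5,
    min_contrast: float = 16.0,
) -> FieldQuantification:
    """Run the full per-field pipeline for one staining mode.

    ``min_contrast`` suppresses foreground detection in channels that carry
    nothing but noise (the converged IsoData class means must differ by at
    least this much).
    """
    if mode not in MODE_CHANNELS:
        raise ConfigError(f"unknown mode {mode!r}; choose from {sorted(MODE_CHANNELS)}")
    required = MODE_CHANNELS[mode]
    missing = [ch for ch in required if ch not in stack]
    if missing:
        raise ConfigError(f"mode {mode!r} requires channels {missing} not present in stack")

    nuclei, _ = segment_nuclei(
        stack["dapi"],
        min_area=min_area,
        max_area=max_area,
        exclude_border=exclude_border,
        min_seed_distance=min_seed_distance,
        min_contrast=min_contrast,
    )
    q = FieldQuantification(n_nuclei=len(nuclei), provenance=stack.provenance)

    if "green" in required and "red" in required:
        green_segs = detect_marker_segments(
            stack["green"], min_area, max_area, min_contrast=min_contrast
        )
        red_segs = detect_marker_segments(
            stack["red"], min_area, max_area, min_contrast=min_contrast
        )
        phenotypes = assign_markers(nuclei, green_segs, red_segs, rule=rule)
        q.n_green = sum(p.green_positive for p in phenotypes)
        q.n_red = sum(p.red_positive for p in phenotypes)
        q.n_double = sum(p.double_positive for p in phenotypes)

    if "myhc" in required:
        tubes = detect_myotubes(
            stack["myhc"],
            nuclei,
            min_myotube_area=min_myotube_area,
            min_contrast=min_contrast,
        )
        q.n_myotubes = len(tubes)
        q.n_nuclei_in_myotubes = sum(len(t.member_nuclei) for t in tubes)
    return q
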