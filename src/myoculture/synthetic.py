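"""Synthetic fluorescence fields of cultured myoblasts with full ground truth.

Each generated field mimics a 10x-magnification multi-channel 8-bit
micrograph: round DAPI-stained nuclei (~10 um diameter at 1 um/px, so
segment areas land inside the 15-230 px acceptance window), nuclear
green/red marker signal co-located with marker-positive nuclei, and
elongated MyHC-positive myotubes each overlapping at least two nuclei.
Gaussian blur and additive read noise are applied before 8-bit
quantization. The generator records every object it places, so the
downstream pipeline can be validated against exact per-field truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from .errors import ParameterError, PlacementError
from .io import ChannelStack, Provenance, write_stack

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one simulated field.

    ``n_nuclei`` is the total nucleus count, including nuclei belonging to
    myotubes. Marker states are drawn per nucleus from a joint law with
    marginals ``p_green``/``p_red`` and joint ``p_double`` (so a target
    index double/marginal can be dialed in exactly).
    """

    n_nuclei: int = 150
    shape: tuple[int, int] = (512, 512)
    nucleus_diameter_um: float = 10.0
    nucleus_diameter_sd_um: float = 1.0
    pixel_size_um: float = 1.0
    p_green: float = 0.0
    p_red: float = 0.0
    p_double: float = 0.0
    n_myotubes: int = 0
    nuclei_per_myotube_min: int = 2
    nuclei_per_myotube_max: int = 4
    myotube_length_px: tuple[float, float] = (60.0, 200.0)
    myotube_width_px: tuple[float, float] = (10.0, 20.0)
    min_nucleus_spacing_px: float = 11.0
    border_margin_px: int = 12
    noise_sd: float = 6.0
    blur_sigma_px: float = 1.0
    background_level: float = 8.0
    dapi_intensity: float = 185.0
    marker_intensity: float = 165.0
    myhc_intensity: float = 145.0
    render_myhc: bool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_nuclei", "n_myotubes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ParameterError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("p_green", "p_red", "p_double"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.p_double > min(self.p_green, self.p_red) + 1e-12:
            raise ParameterError(
                f"p_double ({self.p_double}) exceeds a marginal "
                f"(p_green={self.p_green}, p_red={self.p_red})"
            )
        if self.pixel_size_um <= 0:
            raise ParameterError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.nuclei_per_myotube_min < 2:
            raise ParameterError("nuclei_per_myotube_min must be >= 2")
        if self.nuclei_per_myotube_max < self.nuclei_per_myotube_min:
            raise ParameterError("nuclei_per_myotube_max < nuclei_per_myotube_min")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ParameterError("noise_sd and blur_sigma_px must be >= 0")

    @property
    def include_myhc(self) -> bool:
        if self.render_myhc is not None:
            return self.render_myhc
        return self.n_myotubes > 0


@dataclass
class NucleusTruth:
    id: int
    row: float
    col: float
    radius_px: float
    area_px: int
    green: bool
    red: bool
    myotube_id: int | None = None

    @property
    def double(self) -> bool:
        return self.green and self.red


@dataclass
class MyotubeTruth:
    id: int
    area_px: int
    member_ids: list[int]


@dataclass
class TrueIndices:
    """Index formulas applied to the true per-nucleus states (no imaging)."""

    proliferation: float | None
    differentiation: float | None
    fusion: float | None
    myotube_count: int


@dataclass
class GroundTruth:
    nuclei: list[NucleusTruth] = dc_field(default_factory=list)
    myotubes: list[MyotubeTruth] = dc_field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    @property
    def n_green(self) -> int:
        return sum(n.green for n in self.nuclei)

    @property
    def n_red(self) -> int:
        return sum(n.red for n in self.nuclei)

    @property
    def n_double(self) -> int:
        return sum(n.double for n in self.nuclei)

    @property
    def n_in_myotubes(self) -> int:
        return sum(n.myotube_id is not None for n in self.nuclei)

    @property
    def indices(self) -> TrueIndices:
        def ratio(num: int, den: int) -> float | None:
            return 100.0 * num / den if den > 0 else None

        return TrueIndices(
            proliferation=ratio(self.n_double, self.n_green),
            differentiation=ratio(self.n_double, self.n_red),
            fusion=ratio(self.n_in_myotubes, self.n_nuclei),
            myotube_count=len(self.myotubes),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nucleus_id": n.id,
                    "row": n.row,
                    "col": n.col,
                    "area_px": n.area_px,
                    "green": n.green,
                    "red": n.red,
                    "myotube_id": -1 if n.myotube_id is None else n.myotube_id,
                }
                for n in self.nuclei
            ],
            columns=["nucleus_id", "row", "col", "area_px", "green", "red", "myotube_id"],
        )


def _capsule_mask(
    shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray, width: float
) -> np.ndarray:
    """Boolean mask of a stadium (segment dilated by width/2)."""
    half = width / 2.0
    r0 = int(max(0, np.floor(min(p0[0], p1[0]) - half - 1)))
    r1 = int(min(shape[0], np.ceil(max(p0[0], p1[0]) + half + 2)))
    c0 = int(max(0, np.floor(min(p0[1], p1[1]) - half - 1)))
    c1 = int(min(shape[1], np.ceil(max(p0[1], p1[1]) + half + 2)))
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d = p1 - p0
    length2 = float(d @ d)
    vr, vc = rr - p0[0], cc - p0[1]
    if length2 == 0:
        dist2 = vr**2 + vc**2
    else:
        t = np.clip((vr * d[0] + vc * d[1]) / length2, 0.0, 1.0)
        dist2 = (vr - t * d[0]) ** 2 + (vc - t * d[1]) ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = dist2 <= half**2
    return mask


def _sample_radius(params: SceneParams, rng: np.random.Generator) -> float:
    d_um = rng.normal(params.nucleus_diameter_um, params.nucleus_diameter_sd_um)
    d_um = float(np.clip(d_um, 6.0, 16.0))  # keeps areas inside [15, 230] px
    return d_um / 2.0 / params.pixel_size_um


def _draw_marker_states(
    n: int, params: SceneParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Joint green/red states from a single uniform per nucleus.

    Partitioning [0,1) as [0, p_double) -> both, [p_double, p_green) ->
    green only, [p_green, p_green + p_red - p_double) -> red only makes the
    green count monotone in p_green for a fixed draw.
    """
    u = rng.random(n)
    green = u < params.p_green
    red_only_hi = params.p_green + params.p_red - params.p_double
    red = (u < params.p_double) | ((u >= params.p_green) & (u < red_only_hi))
    return green, red


def generate_field(params: SceneParams) -> tuple[ChannelStack, GroundTruth]:
    """Render one field and its exact ground truth.

    Identical params (including seed) give bit-identical output. Raises
    :class:`PlacementError` if the requested objects cannot be placed under
    the spacing rules (too dense a scene for the field size).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    margin = params.border_margin_px
    spacing = params.min_nucleus_spacing_px

    truth = GroundTruth()
    myhc_mask = np.zeros((h, w), dtype=bool)
    # exclusion zone keeping free-nucleus centroids out of (and clear of) tubes
    myhc_exclusion = np.zeros((h, w), dtype=bool)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tube_member_counts: list[int] = []

    # -- myotube placement -------------------------------------------------
    if params.n_myotubes > 0:
        tube_member_counts = list(
            rng.integers(
                params.nuclei_per_myotube_min,
                params.nuclei_per_myotube_max + 1,
                size=params.n_myotubes,
            )
        )
        if sum(tube_member_counts) > params.n_nuclei:
            raise ParameterError(
                "myotube membership exceeds n_nuclei: "
                f"{sum(tube_member_counts)} > {params.n_nuclei}"
            )
        gap = int(np.ceil(spacing))  # clearance between neighboring tubes
        for tube_id, k in enumerate(tube_member_counts):
            end_inset = 10.0
            needed = (k - 1) * (spacing + 3.0) + 2 * end_inset
            lo = max(params.myotube_length_px[0], needed)
            hi = max(params.myotube_length_px[1], lo)
            placed = False
            for _ in range(4000):
                length = rng.uniform(lo, hi)
                width = rng.uniform(*params.myotube_width_px)
                theta = rng.uniform(0.0, np.pi)
                direction = np.array([np.sin(theta), np.cos(theta)])
                center = np.array(
                    [
                        rng.uniform(margin + length / 2, h - margin - length / 2)
                        if h - 2 * margin > length
                        else h / 2,
                        rng.uniform(margin + length / 2, w - margin - length / 2)
                        if w - 2 * margin > length
                        else w / 2,
                    ]
                )
                p0 = center - direction * length / 2
                p1 = center + direction * length / 2
                half = width / 2 + 1
                pts = np.array([p0, p1])
                if (
                    (pts - half < margin).any()
                    or (pts[:, 0] + half > h - margin).any()
                    or (pts[:, 1] + half > w - margin).any()
                ):
                    continue
                cand = _capsule_mask((h, w), p0, p1, width)
                if (cand & myhc_exclusion).any():
                    continue
                myhc_mask |= cand
                dil = ndi.binary_dilation(cand, structure=_STRUCT8, iterations=gap)
                myhc_exclusion |= dil
                # member nuclei along the tube axis, spaced for watershed
                span = length - 2 * end_inset
                base = np.linspace(0.0, 1.0, k)
                jitter = rng.uniform(-0.15, 0.15, size=k) / max(k - 1, 1)
                ts = np.clip(base + jitter, 0.0, 1.0)
                axis0 = p0 + direction * end_inset
                for t in ts:
                    pos = axis0 + direction * span * t
                    centers.append((float(pos[0]), float(pos[1])))
                    radii.append(_sample_radius(params, rng))
                    truth.nuclei.append(
                        NucleusTruth(
                            id=len(truth.nuclei),
                            row=float(pos[0]),
                            col=float(pos[1]),
                            radius_px=radii[-1],
                            area_px=0,
                            green=False,
                            red=False,
                            myotube_id=tube_id,
                        )
                    )
                truth.myotubes.append(
                    MyotubeTruth(id=tube_id, area_px=int(cand.sum()), member_ids=[])
                )
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place myotube {tube_id + 1}/{params.n_myotubes}; "
                    "reduce n_myotubes or enlarge the field"
                )
        for nuc in truth.nuclei:
            if nuc.myotube_id is not None:
                truth.myotubes[nuc.myotube_id].member_ids.append(nuc.id)

    # -- free nuclei -------------------------------------------------------
    n_free = params.n_nuclei - len(truth.nuclei)
    center_arr = np.array(centers, dtype=float).reshape(-1, 2)
    for _ in range(n_free):
        placed = False
        for _ in range(4000):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if myhc_exclusion[int(r), int(c)]:
                continue
            if center_arr.size:
                d2 = (center_arr[:, 0] - r) ** 2 + (center_arr[:, 1] - c) ** 2
                if d2.min() < spacing**2:
                    continue
            centers.append((r, c))
            center_arr = np.vstack([center_arr, [r, c]])
            radii.append(_sample_radius(params, rng))
            truth.nuclei.append(
                NucleusTruth(
                    id=len(truth.nuclei),
                    row=float(r),
                    col=float(c),
                    radius_px=radii[-1],
                    area_px=0,
                    green=False,
                    red=False,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {len(truth.nuclei) + 1}/{params.n_nuclei}; "
                "reduce density or enlarge the field"
            )

    # -- marker states -----------------------------------------------------
    green, red = _draw_marker_states(len(truth.nuclei), params, rng)
    for nuc, g, r in zip(truth.nuclei, green, red):
        nuc.green = bool(g)
        nuc.red = bool(r)

    # -- rendering ---------------------------------------------------------
    bg = params.background_level
    dapi = np.full((h, w), bg, dtype=np.float64)
    green_ch = np.full((h, w), bg, dtype=np.float64)
    red_ch = np.full((h, w), bg, dtype=np.float64)
    myhc_ch = np.full((h, w), bg, dtype=np.float64)

    for nuc in truth.nuclei:
        rr, cc = draw_disk((nuc.row, nuc.col), nuc.radius_px, shape=(h, w))
        nuc.area_px = len(rr)
        dapi[rr, cc] = np.maximum(dapi[rr, cc], params.dapi_intensity)
        if nuc.green:
            green_ch[rr, cc] = np.maximum(green_ch[rr, cc], params.marker_intensity)
        if nuc.red:
            red_ch[rr, cc] = np.maximum(red_ch[rr, cc], params.marker_intensity)
    myhc_ch[myhc_mask] = params.myhc_intensity

    channels = {"dapi": dapi, "green": green_ch, "red": red_ch}
    if params.include_myhc:
        channels["myhc"] = myhc_ch

    rendered: dict[str, np.ndarray] = {}
    for name in channels:  # fixed order -> deterministic noise draws
        img = channels[name]
        if params.blur_sigma_px > 0:
            img = ndi.gaussian_filter(img, sigma=params.blur_sigma_px)
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        rendered[name] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stack = ChannelStack(channels=rendered, pixel_size_um=params.pixel_size_um)
    return stack, truth


# ---------------------------------------------------------------------------
# calibration helpers


def calibrate_marker_probs(
    target_pct: float, p_denominator: float = 0.55, denominator: str = "green"
) -> dict[str, float]:
    """SceneParams overrides making the true double/denominator ratio equal
    ``target_pct`` in expectation.

    ``denominator`` selects which marginal carries the index denominator
    ('green' for the proliferation-style Pax7 denominator, 'red' for the
    differentiation-style MyoD denominator).
    """
    if not 0 <= target_pct <= 100:
        raise ParameterError("target_pct must be in [0, 100]")
    p_double = target_pct / 100.0 * p_denominator
    other = min(1.0, p_double + 0.25)
    if denominator == "green":
        return {"p_green": p_denominator, "p_red": other, "p_double": p_double}
    if denominator == "red":
        return {"p_red": p_denominator, "p_green": other, "p_double": p_double}
    raise ParameterError(f"unknown denominator {denominator!r}")


def calibrate_fusion(
    target_pct: float, n_nuclei: int, nuclei_per_myotube: int = 3
) -> dict[str, int]:
    """SceneParams overrides placing myotubes so that the true fused-nucleus
    fraction is as close as possible to ``target_pct``."""
    if not 0 <= target_pct <= 100:
        raise ParameterError("target_pct must be in [0, 100]")
    n_tubes = int(round(target_pct / 100.0 * n_nuclei / nuclei_per_myotube))
    return {
        "n_myotubes": n_tubes,
        "nuclei_per_myotube_min": nuclei_per_myotube,
        "nuclei_per_myotube_max": nuclei_per_myotube,
        # shorter tubes keep dense high-fusion scenes placeable
        "myotube_length_px": (60.0, 120.0),
    }


# ---------------------------------------------------------------------------
# study generation


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a simulated study: coatings x days x wells x fields."""

    coatings: tuple[str, ...] = ("matrigel", "fibrin", "fibrin-lec", "lec")
    days: tuple[int, ...] = (1, 5, 7, 9)
    wells_per_condition: int = 3
    fields_per_well: int = 5

    @property
    def n_fields(self) -> int:
        return (
            len(self.coatings) * len(self.days) * self.wells_per_condition * self.fields_per_well
        )


def field_seed(master_seed: int, coating_index: int, day: int, well: int, field: int) -> int:
    """Deterministic per-field seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), coating_index, day, well, field])
    return int(ss.generate_state(1)[0])


def generate_study(
    design: StudyDesign,
    base_params: SceneParams,
    out_dir: str | Path,
    *,
    seed: int = 0,
    condition_overrides: Mapping[tuple[str, int], Mapping[str, object]] | None = None,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Render a full study to disk; returns the manifest table.

    One TIFF per channel per field plus one ground-truth CSV per field,
    named by condition; a ``manifest.csv`` at the root enumerates fields.
    ``condition_overrides`` maps (coating, day) to SceneParams overrides so
    each condition can have its own generating truth.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"output directory {out_dir} is not empty; pass overwrite=True"
            )
    out_dir.mkdir(parents=True, exist_ok=True)
    condition_overrides = condition_overrides or {}

    rows = []
    for ci, coating in enumerate(design.coatings):
        for day in design.days:
            overrides = dict(condition_overrides.get((coating, day), {}))
            for well in range(1, design.wells_per_condition + 1):
                for fld in range(1, design.fields_per_well + 1):
                    fseed = field_seed(seed, ci, day, well, fld)
                    params = dataclasses.replace(base_params, seed=fseed, **overrides)
                    stack, truth = generate_field(params)
                    prov = Provenance(coating=coating, day=day, well=well, field=fld)
                    stack.provenance = prov
                    write_stack(stack, out_dir)
                    truth_path = out_dir / f"{prov.stem()}_truth.csv"
                    truth.to_frame().to_csv(truth_path, index=False)
                    rows.append(
                        {
                            "coating": coating,
                            "day": day,
                            "well": well,
                            "field": fld,
                            "stem": prov.stem(),
                            "n_channels": len(stack.channels),
                            "seed": fseed,
                        }
                    )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
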