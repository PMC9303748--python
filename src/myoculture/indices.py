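"""Proliferation, differentiation and fusion indices, and well aggregation.

Proliferation index = 100 * (Pax7+MyoD+ double positives) / (Pax7+);
differentiation index = 100 * (MyoD+MyoG+ double positives) / (MyoD+);
fusion index = 100 * (nuclei inside myotubes) / (all nuclei). An index with
a zero denominator is undefined and propagates as a missing value, never 0.

Wells pool their fields by summing counts and applying the formula once
(not by averaging per-field ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConsistencyError, DataError
from .markers import FieldQuantification


@dataclass
class IndexRecord:
    coating: str
    day: int
    well: int
    proliferation_index_pct: float | None
    differentiation_index_pct: float | None
    fusion_index_pct: float | None
    myotube_count: int


def _ratio_pct(numerator: int, denominator: int, what: str) -> float | None:
    if numerator < 0 or denominator < 0:
        raise ConsistencyError(f"{what}: negative count")
    if numerator > denominator:
        raise ConsistencyError(f"{what}: numerator {numerator} > denominator {denominator}")
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator


def proliferation_index(n_double: int, n_pax7: int) -> float | None:
    """Percentage of Pax7-positive nuclei that are also MyoD-positive."""
    return _ratio_pct(n_double, n_pax7, "proliferation index")


def differentiation_index(n_double: int, n_myod: int) -> float | None:
    """Percentage of MyoD-positive nuclei that are also MyoG-positive."""
    return _ratio_pct(n_double, n_myod, "differentiation index")


def fusion_index(n_in_myotubes: int, n_total: int) -> float | None:
    """Percentage of all nuclei located inside myotubes."""
    return _ratio_pct(n_in_myotubes, n_total, "fusion index")


def aggregate_well(
    fields: list[FieldQuantification],
    *,
    mode: str = "all",
    pooling: str = "pooled",
) -> IndexRecord:
    """Combine one well's fields into a single IndexRecord.

    ``pooling='pooled'`` (default) sums counts across fields and applies
    each index formula once; ``pooling='mean'`` averages per-field indices
    (ignoring fields where an index is undefined). ``mode`` names which
    staining the well carries; it only affects which denominator the
    double-positive count is divided by (green for 'pax7-myod', red for
    'myog-myod').
    """
    if not fields:
        raise DataError("aggregate_well needs at least one field")
    if pooling not in ("pooled", "mean"):
        raise DataError(f"unknown pooling rule {pooling!r}")
    provs = {
        (f.provenance.coating, f.provenance.day, f.provenance.well)
        for f in fields
        if f.provenance is not None
    }
    if len(provs) > 1:
        raise DataError(f"fields from multiple wells pooled together: {sorted(provs)}")
    coating, day, well = provs.pop() if provs else ("?", 0, 0)

    if pooling == "pooled":
        tot = FieldQuantification(
            n_nuclei=sum(f.n_nuclei for f in fields),
            n_green=sum(f.n_green for f in fields),
            n_red=sum(f.n_red for f in fields),
            n_double=sum(f.n_double for f in fields),
            n_myotubes=sum(f.n_myotubes for f in fields),
            n_nuclei_in_myotubes=sum(f.n_nuclei_in_myotubes for f in fields),
        )
        prolif = proliferation_index(tot.n_double, tot.n_green)
        diff = differentiation_index(tot.n_double, tot.n_red)
        fus = fusion_index(tot.n_nuclei_in_myotubes, tot.n_nuclei)
        n_tubes = tot.n_myotubes
    else:
        def mean_of(values: list[float | None]) -> float | None:
            defined = [v for v in values if v is not None]
            return sum(defined) / len(defined) if defined else None

        prolif = mean_of([proliferation_index(f.n_double, f.n_green) for f in fields])
        diff = mean_of([differentiation_index(f.n_double, f.n_red) for f in fields])
        fus = mean_of([fusion_index(f.n_nuclei_in_myotubes, f.n_nuclei) for f in fields])
        n_tubes = round(sum(f.n_myotubes for f in fields) / len(fields))

    if mode == "myog-myod":
        prolif = None  # green channel is MyoG here; Pax7 ratio meaningless
    elif mode == "pax7-myod":
        diff = None

    return IndexRecord(
        coating=coating,
        day=day,
        well=well,
        proliferation_index_pct=prolif,
        differentiation_index_pct=diff,
        fusion_index_pct=fus,
        myotube_count=n_tubes,
    )


def build_analysis_table(
    quantifications: list[FieldQuantification],
    *,
    mode: str = "all",
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Group per-field counts by (coating, day, well) and emit the tidy
    per-well analysis table consumed by the statistics layer."""
    groups: dict[tuple[str, int, int], list[FieldQuantification]] = {}
    for q in quantifications:
        if q.provenance is None:
            raise DataError("cannot build analysis table from fields without provenance")
        key = (q.provenance.coating, q.provenance.day, q.provenance.well)
        groups.setdefault(key, []).append(q)
    records = [
        aggregate_well(fields, mode=mode, pooling=pooling) for _, fields in sorted(groups.items())
    ]
    return pd.DataFrame(
        [
            {
                "coating": r.coating,
                "day": r.day,
                "well": r.well,
                "proliferation_index_pct": r.proliferation_index_pct,
                "differentiation_index_pct": r.differentiation_index_pct,
                "fusion_index_pct": r.fusion_index_pct,
                "myotube_count": r.myotube_count,
            }
            for r in records
        ]
    )
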