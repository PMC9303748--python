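"""Run configuration: YAML-backed parameters for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

#: Outcomes the statistics stage knows, with the quantification mode that
#: produces each and whether day 1 is excluded from its regression.
OUTCOME_SPECS: dict[str, dict[str, Any]] = {
    "proliferation_index_pct": {"mode": "pax7-myod", "exclude_day1": False},
    "differentiation_index_pct": {"mode": "myog-myod", "exclude_day1": True},
    "fusion_index_pct": {"mode": "myhc", "exclude_day1": False},
    "myotube_count": {"mode": "myhc", "exclude_day1": True},
}


@dataclass
class RunConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    coatings: list[str] = field(
        default_factory=lambda: ["matrigel", "fibrin", "fibrin-lec", "lec"]
    )
    days: list[int] = field(default_factory=lambda: [1, 5, 7, 9])
    wells: int = 3
    fields: int = 5
    scene: dict[str, Any] = field(default_factory=dict)
    #: mode -> coating -> day -> calibration mapping. Marker modes take
    #: {index_pct, p_denominator}; the myhc mode takes
    #: {fusion_pct, nuclei_per_myotube}.
    modes: dict[str, dict[str, dict[int, dict[str, Any]]]] = field(default_factory=dict)
    #: per-mode SceneParams overrides applied on top of ``scene``
    mode_scene: dict[str, dict[str, Any]] = field(default_factory=dict)
    marker_rule: str = "intersection"
    min_area: int = 15
    max_area: int = 230
    exclude_border: bool = True
    min_myotube_area: int = 300
    min_contrast: float = 16.0
    reference: str = "matrigel"
    pooling: str = "pooled"
    overwrite: bool = False

    def validate(self) -> None:
        if self.reference not in self.coatings:
            raise ConfigError(
                f"stats reference coating {self.reference!r} is not among {self.coatings}"
            )
        if self.marker_rule not in ("intersection", "containment"):
            raise ConfigError(f"unknown marker_rule {self.marker_rule!r}")
        if self.min_area > self.max_area:
            raise ConfigError("min_area > max_area")
        for mode, by_coating in self.modes.items():
            if mode not in ("pax7-myod", "myog-myod", "myhc"):
                raise ConfigError(f"unknown quantification mode {mode!r}")
            for coating in by_coating:
                if coating not in self.coatings:
                    raise ConfigError(
                        f"mode {mode!r} calibrates unknown coating {coating!r}"
                    )

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        # YAML mapping keys may arrive as strings; normalize day keys to int
        cfg.days = [int(d) for d in cfg.days]
        cfg.modes = {
            mode: {
                coating: {int(day): dict(cal) for day, cal in by_day.items()}
                for coating, by_day in by_coating.items()
            }
            for mode, by_coating in cfg.modes.items()
        }
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def demo_config(
    out_dir: str = "runs/demo",
    *,
    seed: int = 0,
    wells: int = 3,
    fields: int = 5,
    n_nuclei: int = 120,
) -> RunConfig:
    """A self-contained study configuration whose generating truths follow
    the broad trends of a coating-comparison experiment (matrigel strongest,
    fibrin weakest, fibrin-lec close to matrigel late)."""
    coatings = ["matrigel", "fibrin", "fibrin-lec", "lec"]
    days = [1, 5, 7, 9]
    prolif = {
        "matrigel": {1: 30.8, 5: 38.0, 7: 45.0, 9: 52.0},
        "fibrin": {1: 10.0, 5: 12.0, 7: 15.0, 9: 18.0},
        "fibrin-lec": {1: 22.5, 5: 30.0, 7: 38.0, 9: 45.0},
        "lec": {1: 25.0, 5: 30.0, 7: 35.0, 9: 40.0},
    }
    diff = {
        "matrigel": {1: 2.0, 5: 40.1, 7: 27.1, 9: 25.0},
        "fibrin": {1: 1.0, 5: 10.0, 7: 12.0, 9: 12.0},
        "fibrin-lec": {1: 2.0, 5: 28.7, 7: 32.8, 9: 25.0},
        "lec": {1: 1.0, 5: 15.0, 7: 15.0, 9: 14.0},
    }
    fusion = {
        "matrigel": {1: 0.0, 5: 60.0, 7: 40.0, 9: 25.5},
        "fibrin": {1: 0.0, 5: 5.0, 7: 8.0, 9: 12.0},
        "fibrin-lec": {1: 0.0, 5: 15.0, 7: 20.0, 9: 26.9},
        "lec": {1: 0.0, 5: 3.0, 7: 4.0, 9: 5.0},
    }
    modes: dict[str, dict[str, dict[int, dict[str, Any]]]] = {
        "pax7-myod": {
            c: {d: {"index_pct": v, "p_denominator": 0.55} for d, v in by_day.items()}
            for c, by_day in prolif.items()
        },
        "myog-myod": {
            c: {d: {"index_pct": v, "p_denominator": 0.60} for d, v in by_day.items()}
            for c, by_day in diff.items()
        },
        "myhc": {
            c: {d: {"fusion_pct": v, "nuclei_per_myotube": 3} for d, v in by_day.items()}
            for c, by_day in fusion.items()
        },
    }
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        coatings=coatings,
        days=days,
        wells=wells,
        fields=fields,
        scene={"n_nuclei": n_nuclei, "shape": [420, 420]},
        mode_scene={"myhc": {"n_nuclei": min(n_nuclei, 100), "shape": [512, 512]}},
        modes=modes,
    )
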