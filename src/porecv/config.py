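"""Run configuration: one YAML document bundling every tunable of the
pipeline, so a run's parameters are auditable in a single place.

Defaults are the package defaults throughout (cylinder radius 1.2 nm,
switching threshold 0.95 at rate 20, umbrella force constant 5000 kJ/mol,
flat-bottom 1000 kJ mol^-1 nm^-2 with 2.5 nm half width, 310 K, 17 slices of
0.25 nm on [-2.125, 2.125] nm, quadratic fit for CV <= 0.5 and linear fit
for CV >= 1.2).  Loading echoes the fully resolved configuration.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml

from .cv_fullpath import CVParams
from .cv_rapid import BiasSpec
from .pore_state import SliceSpec
from .toy_md import SimulationSettings

__all__ = ["RunConfig"]


@dataclass
class WindowLayout:
    lo: float = -0.100
    hi: float = 2.175
    spacing: Optional[float] = 0.035
    count: Optional[int] = None


@dataclass
class FitRanges:
    quadratic_cv_max: float = 0.5
    linear_cv_min: float = 1.2


@dataclass
class RunConfig:
    """Aggregated run configuration (see module docstring for defaults)."""

    structures: List[str] = field(default_factory=list)
    series: List[str] = field(default_factory=list)
    output_dir: str = "."
    cv: CVParams = field(default_factory=CVParams)
    slices: SliceSpec = field(default_factory=SliceSpec)
    biases: List[BiasSpec] = field(default_factory=lambda: [
        BiasSpec(kind="harmonic", kappa=5000.0),
        BiasSpec(kind="flat_bottom", k_fb=1000.0, half_width=2.5),
    ])
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    windows: WindowLayout = field(default_factory=WindowLayout)
    fit: FitRanges = field(default_factory=FitRanges)
    report_units: str = "pN"

    def validate_paths(self) -> None:
        """Every referenced input path must exist at load time."""
        for p in [*self.structures, *self.series]:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["slices"]["interval"] = list(self.slices.interval)
        for b in d["biases"]:
            b.pop("schedule", None)  # callables are not serialisable
        return d

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path, check_paths: bool = True) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cv_kwargs = dict(raw.get("cv", {}))
        if "boundary_exponents" in cv_kwargs:
            cv_kwargs["boundary_exponents"] = tuple(
                cv_kwargs["boundary_exponents"])
        slice_kwargs = dict(raw.get("slices", {}))
        if "interval" in slice_kwargs:
            slice_kwargs["interval"] = tuple(slice_kwargs["interval"])
        kwargs = dict(
            structures=raw.get("structures", []),
            series=raw.get("series", []),
            output_dir=raw.get("output_dir", "."),
            cv=CVParams(**cv_kwargs),
            slices=SliceSpec(**slice_kwargs),
            simulation=SimulationSettings(**raw.get("simulation", {})),
            windows=WindowLayout(**raw.get("windows", {})),
            fit=FitRanges(**raw.get("fit", {})),
            report_units=raw.get("report_units", "pN"),
        )
        if "biases" in raw:
            kwargs["biases"] = [BiasSpec(**b) for b in raw["biases"]]
        cfg = cls(**kwargs)
        if check_paths:
            cfg.validate_paths()
        return cfg
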