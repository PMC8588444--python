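"""YAML pipeline configuration, validated at load time."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .recording import DEFAULT_BANDS, BandSpec
from .synthetic import CohortSpec, CouplingEntry


@dataclass
class PipelineConfig:
    bands: list[str] = field(default_factory=lambda: [b.name for b in DEFAULT_BANDS])
    custom_bands: dict = field(default_factory=dict)   # name -> [f_lo, f_hi]
    method: str = "circ_corr"
    window_s: float | None = None
    overlap_s: float = 0.0
    som_grid: tuple[int, int] = (8, 8)
    som_seed: int = 7
    som_iter_per_sample: int = 500
    cv_k: int = 5
    cv_seed: int = 0
    permutation_B: int = 0
    fdr_alpha: float = 0.05
    display_alpha: float = 0.01
    simulate: dict | None = None   # CohortSpec fields; alternative to input_dir
    input_dir: str | None = None

    def band_specs(self) -> list[BandSpec]:
        out = []
        for name in self.bands:
            if name in self.custom_bands:
                lo, hi = self.custom_bands[name]
                out.append(BandSpec(name, float(lo), float(hi)))
            else:
                out.append(next(b for b in DEFAULT_BANDS if b.name == name))
        return out

    def cohort_spec(self) -> CohortSpec:
        if self.simulate is None:
            raise ValueError("configuration has no 'simulate' section")
        sim = dict(self.simulate)
        for key in ("coupling_control", "coupling_case"):
            if key in sim:
                sim[key] = tuple(
                    CouplingEntry(e[0], (int(e[1][0]), int(e[1][1])), float(e[2]))
                    for e in sim[key]
                )
        return CohortSpec(**sim)

    def validate(self) -> None:
        if self.method not in ("plv", "circ_corr"):
            raise ValueError(f"unknown connectivity method {self.method!r}")
        if self.cv_k != 0 and self.cv_k < 2:
            raise ValueError("cv_k must be 0 (disabled) or >= 2")
        if not (0 < self.fdr_alpha < 1) or not (0 < self.display_alpha < 1):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.window_s is not None and self.overlap_s >= self.window_s:
            raise ValueError("overlap_s must be smaller than window_s")
        specs = self.band_specs()
        if self.simulate is not None:
            cs = self.cohort_spec()
            for b in specs:
                b.validate_fs(cs.fs)
        if self.simulate is None and self.input_dir is None:
            raise ValueError("need either 'simulate' or 'input_dir'")

    def manifest_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "som_grid" in raw:
        raw["som_grid"] = tuple(raw["som_grid"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
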