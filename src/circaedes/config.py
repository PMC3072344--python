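"""Run configuration: one YAML file drives the whole pipeline.

Every stochastic stage carries an explicit seed; a config round-trips
through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # synthetic dataset
    n_probes_dup2: int = 1000
    n_probes_dup3: int = 0
    n_probes_dup4: int = 0
    n_spike: int = 50
    frac_rhythmic: float = 0.5
    amplitude: float = 1.0
    noise_sd: float = 0.5
    baseline: float = 0.0
    seed: int = 7

    # design
    reference_hour: float = 24.0
    first_sample_hour: float = 72.0
    last_sample_hour: float = 104.0
    sampling_interval: float = 4.0
    n_replicates: int = 2

    # preprocessing
    background_floor: float = 1.0
    average_technical: bool = False

    # conditioning
    smoothing_window: int = 7
    smoothing_degree: int = 3
    smoothing_circular: bool = True
    smooth_for_tests: bool = False
    smooth_for_continuum: bool = True

    # tests
    alpha: float = 0.05
    period_hours: float = 24.0
    pt_max_perm: int = 100
    pt_n_series: int = 2
    fdr: bool = False

    # continuum
    frame_g: int = 5
    frame_pt: int = 3
    frame_autocorr: int = 3

    # heatmap
    heatmap_scale: float | None = None

    def sample_hours(self) -> tuple[float, ...]:
        h = self.first_sample_hour
        out = []
        while h <= self.last_sample_hour + 1e-9:
            out.append(float(h))
            h += self.sampling_interval
        return tuple(out)

    def frames(self) -> dict[str, int]:
        return {"g": self.frame_g, "pt": self.frame_pt, "autocorr": self.frame_autocorr}


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
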