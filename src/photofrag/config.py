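"""Run configuration: defaults, validation and YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of one campaign.

    Defaults mirror the reference protocol: 450 K thermal sampling,
    photon grid 12–16 eV in 0.5 eV steps, 10 ps constant-energy runs with
    a 0.5 fs step, 4 Å fragmentation criterion and a 0.1 eV total-energy
    filter.  The trajectory count defaults to a desk-scale 50 (the
    reference-scale value is 1000); every field is overridable.
    """

    variant: str = "2TU-like"
    temperature_K: float = 450.0
    nvt_duration_ps: float = 20.0
    nve_duration_ps: float = 10.0
    dt_fs: float = 0.5
    photon_grid_eV: list[float] = field(
        default_factory=lambda: [12.0 + 0.5 * k for k in range(9)])
    n_trajectories: int = 50
    cutoff_A: float = 4.0
    filter_tol_eV: float = 0.1
    sample_stride: int = 10
    nvt_sample_interval_fs: float = 100.0
    base_seed: int = 1
    output_dir: str = "photofrag_out"

    def __post_init__(self) -> None:
        errors = []
        if self.variant not in ("2TU-like", "4TU-like"):
            errors.append(f"variant: unknown {self.variant!r}")
        for name in ("temperature_K",):
            if getattr(self, name) < 0:
                errors.append(f"{name}: must be non-negative")
        for name in ("nvt_duration_ps", "nve_duration_ps", "dt_fs",
                     "cutoff_A", "nvt_sample_interval_fs"):
            if getattr(self, name) <= 0:
                errors.append(f"{name}: must be positive")
        if self.filter_tol_eV < 0:
            errors.append("filter_tol_eV: must be non-negative")
        if self.n_trajectories < 1:
            errors.append("n_trajectories: must be at least 1")
        if self.sample_stride < 1:
            errors.append("sample_stride: must be at least 1")
        if not self.photon_grid_eV:
            errors.append("photon_grid_eV: must be non-empty")
        elif sorted(self.photon_grid_eV) != list(self.photon_grid_eV):
            errors.append("photon_grid_eV: must be sorted ascending")
        if self.base_seed < 0 or self.base_seed >= 2**31:
            errors.append("base_seed: must be in [0, 2^31)")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)
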