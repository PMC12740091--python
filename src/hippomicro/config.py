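"""Run configuration: a single structured YAML file with a top-level seed."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "demo_config"]

DEFAULT_SEED = 20250101


@dataclass
class RunConfig:
    seed: int = DEFAULT_SEED
    output_dir: str = "hippomicro_out"
    # phantom / cohort simulation
    phantom_shape: tuple = (12, 12, 12)
    n_subjects: int = 6
    snr: float = 50.0
    # acquisition protocol
    delta_small: float = 8.0
    delta_big: float = 19.0
    directions_per_shell: int | None = 6  # None = full 32/64 protocol
    bvals_path: str | None = None
    bvecs_path: str | None = None
    # super-resolution
    sr_factor: int = 2
    sr_kernel: int = 5
    sr_patch: int = 3
    sr_h_series: tuple = (1.0, 2.0, 4.0, 6.0, 8.0, 16.0)
    # SANDI inversion
    n_train: int = 2000
    n_trees: int = 30
    train_snr: float | None = 50.0
    # DKI
    dki_b_max: float = 3.5
    # statistics
    stats_model: str = "M3"
    alpha: float = 0.05
    # injected age effects: param -> [target_r, noise_sd]
    age_effects: dict = field(default_factory=lambda: {
        "f_soma": [-0.5, 0.05],
        "r_soma": [-0.4, 0.6],
        "f_extra": [0.5, 0.05],
    })

    def validate(self) -> None:
        for p in (self.bvals_path, self.bvecs_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.seed is None:
            raise ValueError("a seed is required")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    for name in ("phantom_shape", "sr_h_series"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    cfg.validate()
    return cfg


def demo_config(output_dir: str = "hippomicro_out", seed: int = DEFAULT_SEED) -> RunConfig:
    """A desk-scale configuration exercising the full pipeline."""
    return RunConfig(seed=seed, output_dir=output_dir)
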