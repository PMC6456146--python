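"""Study configuration: YAML-backed description of a full synthetic study."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


@dataclass
class KernelConfig:
    seed: int = 7
    n_modes: int = 160
    decay_rate: float = 1.0
    coupling_strength: float = 0.7


@dataclass
class CalibrationConfig:
    M: int = 100  # number of calibration spots (perfect square for the lattice)
    spot_width: float = 0.04
    beta: float = float(np.pi / 2)
    gamma: float | None = float(np.pi)
    noise_sigma: float = 0.0
    sensor_points: int = 2048
    sensor_seed: int = 11


@dataclass
class ReconstructionConfig:
    basis: str = "fourier"  # fourier | spot | wavelet
    K: int = 100
    method: str = "l1"
    lam: float = 0.005
    lam_relative: bool = True
    noise_sigma: float = 0.0


@dataclass
class PhantomConfig:
    categories: list = field(default_factory=lambda: [2, 5])  # 1-based category index
    areas_per_class: int = 3
    subimages_per_area: int = 3
    seed: int = 101


@dataclass
class StudyConfig:
    """Everything needed to rerun a study bit-identically."""

    grid_side: int = 64
    kernel: KernelConfig = field(default_factory=KernelConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    phantoms: PhantomConfig = field(default_factory=PhantomConfig)
    output_dir: str = "study_output"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def full_window(cls) -> "StudyConfig":
        """Study sized so the recovered spectrum spans the feature window.

        K = 400 Fourier coefficients per polarization (20 x 20, the full
        [-10, 10) window of the decay feature) recovered from a dense
        25 x 25 spot calibration; slower than the default smoke-scale
        configuration but the recovered features track the ground-truth
        phantom features closely.
        """
        return cls(
            grid_side=64,
            kernel=KernelConfig(seed=7, n_modes=800, decay_rate=1.0, coupling_strength=0.7),
            calibration=CalibrationConfig(M=625, spot_width=0.025),
            reconstruction=ReconstructionConfig(K=400, method="l1", lam=0.005),
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        kwargs = dict(raw)
        for name, sub in (
            ("kernel", KernelConfig),
            ("calibration", CalibrationConfig),
            ("reconstruction", ReconstructionConfig),
            ("phantoms", PhantomConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)
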