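"""Run configuration: every tunable parameter of the architecture in one place.

A :class:`Config` is a flat dataclass so it can round-trip through YAML and be
written verbatim next to each run's outputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class Config:
    # --- synthetic session -------------------------------------------------
    image_size: int = 128          # square frame side, pixels
    n_avatars: int = 12            # partner count of the default benchmark
    frames_per_partner: int = 300  # raw frames per partner block
    noise_level: float = 0.02      # additive Gaussian pixel noise (sigma)
    learning_stride: int = 10      # keep 1/stride frames for learning

    # --- visual front-end --------------------------------------------------
    dog_sigma1: float = 1.0        # DOG narrow Gaussian, pixels
    dog_sigma2: float = 2.0        # DOG wide Gaussian, pixels
    n_focus_points: int = 20       # local views extracted per frame
    suppression_radius: int = 6    # Chebyshev non-max suppression, pixels
    lp_r_max: float = 56.0         # outer log-polar radius, pixels
    lp_n_rings: int = 16
    lp_n_angles: int = 16

    # --- visual-feature (VF) prototype network -----------------------------
    gamma: float = 0.96            # vigilance (recruitment threshold)
    epsilon: float = 0.1           # prototype long-term-averaging rate

    # --- conditioning and readout ------------------------------------------
    lms_rate: float = 0.3          # Widrow-Hoff learning rate
    stm_decay: float = 0.7         # leaky-integrator decay of the STM

    # --- novelty detector --------------------------------------------------
    novelty_window: int = 5        # sliding window of the mean error E(t)
    novelty_smoothing: float = 0.6 # EMA coefficient of V = smooth(-dE/dt)
    novelty_threshold: float = 0.01   # |V| crossing that fires an event
    novelty_refractory: int = 15   # frames during which no new event fires
    # which prediction-error stream drives event detection:
    #   "error"   - person-pathway self-prediction error vs the running belief
    #   "posture" - posture-prediction (MISP) error
    #   "recruit" - VF recruitment rate (outliers in the visual-feature stream)
    #   "both"    - "error" OR "recruit"
    novelty_channel: str = "error"

    # --- recognition test battery ------------------------------------------
    n_test_images: int = 100       # images per partner per condition
    n_postures: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must be in [0, 1)")
        if not (0.0 <= self.stm_decay < 1.0):
            raise ValueError("stm_decay must be in [0, 1)")
        if self.novelty_channel not in ("error", "posture", "recruit", "both"):
            raise ValueError("novelty_channel must be 'error', 'posture', 'recruit' or 'both'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
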