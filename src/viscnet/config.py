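"""Run configuration: validated parameters, YAML round-trip, profiles.

A ``RunConfig`` gathers every tunable of the pipeline.  Two scale
profiles are provided: ``full`` reproduces the complete study
(H = 15 network, 2100-point material grid — hours to days of compute)
and ``desk`` is the scaled-down profile used for desk-scale validation
(H = 8, the stiff/viscous corner of the grid where the drag exponent
alone controls the outcome).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclasses.dataclass
class RunConfig:
    # lattice
    H: int = 8
    ell: float = 1.1
    sigma: float = 1.0
    mass: float = 1.0
    k: float = 800.0
    # drag
    gamma: float = 80.0
    alpha: float = 1.0
    v_eps: float = 1e-8
    # indenter
    sigma_s: float = 11.0
    epsilon: float = 1.0
    xi: float = 400.0
    # protocol
    delta_max: float = 0.8
    tau_l: float = 16.0
    dwell_time: float = 32.0
    dt: float | None = None
    sample_stride: int = 100
    early_stop: bool = False
    # sweep grid
    k_values: list = dataclasses.field(default_factory=lambda: [800.0, 1000.0])
    gamma_values: list = dataclasses.field(default_factory=lambda: [80.0, 100.0])
    alpha_values: list = dataclasses.field(
        default_factory=lambda: [round(0.05 * i, 4) for i in range(21)])
    # run management
    seed: int = 0
    profile: str = "desk"
    out_dir: str = "viscnet_out"

    def __post_init__(self) -> None:
        checks = [
            ("H", self.H >= 1), ("ell", self.ell > 0), ("sigma", self.sigma > 0),
            ("mass", self.mass > 0), ("k", self.k > 0), ("gamma", self.gamma >= 0),
            ("alpha", self.alpha >= 0), ("sigma_s", self.sigma_s > self.sigma),
            ("epsilon", self.epsilon > 0), ("xi", self.xi >= 1),
            ("delta_max", self.delta_max > 0), ("tau_l", self.tau_l > 0),
            ("dwell_time", self.dwell_time >= 0),
            ("sample_stride", self.sample_stride >= 1),
            ("alpha_values", all(a >= 0 for a in self.alpha_values)),
            ("k_values", all(k > 0 for k in self.k_values)),
            ("gamma_values", all(g > 0 for g in self.gamma_values)),
            ("profile", self.profile in ("desk", "full")),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"invalid configuration value(s) for: {', '.join(bad)}")

    # ------------------------------------------------------------ views
    def network_kwargs(self) -> dict:
        return {"H": self.H, "ell": self.ell, "sigma": self.sigma,
                "k": self.k, "mass": self.mass}

    def protocol(self):
        from .indentation import IndentationProtocol
        return IndentationProtocol(
            delta_max=self.delta_max, tau_l=self.tau_l,
            dwell_time=self.dwell_time, dt=self.dt,
            sample_stride=self.sample_stride, early_stop=self.early_stop)

    def drag(self):
        from .dynamics import DragLaw
        return DragLaw(gamma=self.gamma, alpha=self.alpha, v_eps=self.v_eps)

    def indenter(self):
        from .dynamics import Indenter
        return Indenter(diameter=self.sigma_s, epsilon=self.epsilon, xi=self.xi)

    def grid(self):
        from .classify import SweepGrid
        return SweepGrid(k_values=tuple(self.k_values),
                         gamma_values=tuple(self.gamma_values),
                         alpha_values=tuple(self.alpha_values), seed=self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


FULL_OVERRIDES = {
    "H": 15,
    "delta_max": 0.8,
    "k_values": [float(k) for k in range(100, 1001, 100)],
    "gamma_values": [float(g) for g in range(10, 101, 10)],
    "profile": "full",
}


def load_config(path: str | Path | None = None, profile: str | None = None,
                **overrides) -> RunConfig:
    """Load and validate a YAML config; defaults fill missing keys.

    An empty or absent file yields the full default (desk-profile)
    configuration.  Unknown keys are rejected with their key path.
    ``profile='full'`` applies the full-scale overrides before any
    explicit keys from the file.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded)}")
        data = loaded
    profile = profile or data.get("profile") or "desk"
    merged: dict = {}
    if profile == "full":
        merged.update(FULL_OVERRIDES)
    merged.update(data)
    merged.update(overrides)
    merged["profile"] = profile
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(merged) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        return RunConfig(**merged)
    except TypeError as e:
        raise ValueError(str(e)) from e


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = cfg.to_dict()
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
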