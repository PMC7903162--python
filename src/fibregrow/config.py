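"""Run configuration: growth-region, morphology and algorithm parameters.

All lengths are micrometres; the growth region is the axis-aligned box
``[0, L] x [0, L] x [0, L]`` (right-handed frame, primary bundle axis = z).

Parameters outside the ranges the method has been exercised in trigger a
``UserWarning`` rather than an error — extreme values are legitimate but
the stochastic growth is not validated there.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "BundleSpec",
    "FibreSeed",
    "GrowthConfig",
    "MechanismFlags",
    "load_config",
    "save_config",
]


class ParameterError(ValueError):
    """An input parameter violates a hard precondition."""


#: entry face identifiers -> (axis index, face coordinate is 0 side?)
_FACES = {
    "x-": (0, True),
    "x+": (0, False),
    "y-": (1, True),
    "y+": (1, False),
    "z-": (2, True),
    "z+": (2, False),
}

# ranges the algorithm has been exercised in; outside -> warning
_PRACTICAL = {
    "region_size": (0.0, 50.0),
    "target_density": (0.0, 0.8),
    "radius_mean": (0.5, 2.0),
    "radius_std": (0.0, 0.5),
    "watson_kappa": (4.0, 100.0),
    "esag_concentration": (2.0, 10.0),
    "cost_weight": (0.0, 0.5),
    "collapse_initial": (1.0, 5.0),
    "collapse_increment": (1.0, 5.0),
    "n_added": (0, 5000),
    "n_nodes": (4, 10_000_000),
}


@dataclass
class BundleSpec:
    """One fibre bundle: mean direction, entry face and overrides."""

    bundle_index: int = 0
    mean_direction: tuple = (0.0, 0.0, 1.0)
    entry_face: str | None = None  # derived from mean_direction when None
    target_density: float | None = None
    dispersion_model: str | None = None
    watson_kappa: float | None = None
    esag_mu: tuple | None = None
    esag_gamma: tuple | None = None

    def __post_init__(self):
        d = np.asarray(self.mean_direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ParameterError("bundle mean_direction must be non-zero")
        if abs(norm - 1.0) > 1e-9:
            d = d / norm
        self.mean_direction = tuple(float(x) for x in d)
        if self.entry_face is None:
            axis = int(np.argmax(np.abs(d)))
            self.entry_face = "xyz"[axis] + ("-" if d[axis] > 0 else "+")
        if self.entry_face not in _FACES:
            raise ParameterError(f"unknown entry face {self.entry_face!r}")

    @property
    def face_axis(self) -> int:
        return _FACES[self.entry_face][0]

    @property
    def face_origin_side(self) -> bool:
        return _FACES[self.entry_face][1]


@dataclass
class FibreSeed:
    """Start/target pair defining one fibre before growth."""

    start_point: np.ndarray
    target_point: np.ndarray
    target_diameter: float
    bundle_index: int

    def __post_init__(self):
        self.start_point = np.asarray(self.start_point, dtype=float)
        self.target_point = np.asarray(self.target_point, dtype=float)
        if self.target_diameter <= 0:
            raise ParameterError("target diameter d0 must be positive")
        if np.allclose(self.start_point, self.target_point):
            raise ParameterError("start and target coincide")


@dataclass
class MechanismFlags:
    """Independently togglable growth mechanisms (for ablation studies)."""

    collapse: bool = True
    dynamic_network: bool = True
    fasciculation: bool = True
    global_optimisation: bool = True

    @classmethod
    def minimal(cls) -> "MechanismFlags":
        """Chemoattraction-only growth: every optional mechanism off."""
        return cls(False, False, False, False)

    @classmethod
    def all(cls) -> "MechanismFlags":
        return cls(True, True, True, True)

    @classmethod
    def only(cls, name: str) -> "MechanismFlags":
        flags = cls.minimal()
        if not hasattr(flags, name):
            raise ParameterError(f"unknown mechanism {name!r}")
        setattr(flags, name, True)
        return flags


@dataclass
class GrowthConfig:
    """All user parameters of one phantom-generation run."""

    region_size: tuple = (10.0, 10.0, 10.0)  # L, um
    target_density: float = 0.75  # rho
    radius_mean: float = 0.5  # mu_r, um
    radius_std: float = 0.1  # sigma_r, um
    dispersion_model: str = "parallel"  # parallel | watson | esag
    watson_kappa: float = 8.0
    esag_mu: tuple = (0.0, 0.0, 5.0)  # norm acts as concentration
    esag_gamma: tuple = (0.0, 0.0)
    n_nodes: int = 200_000  # N
    cost_weight: float = 0.2  # f
    collapse_initial: float = 2.0  # g0, um
    collapse_increment: float = 5.0  # delta, um
    collapse_max_attempts: int = 5
    n_added: int = 2500  # dynamic nodes per grown fibre
    bundles: list = field(default_factory=lambda: [BundleSpec()])
    master_seed: int = 0
    # numerical knobs (defaults documented in docs/methods.md)
    radius_floor_fraction: float = 0.1
    node_padding: float | None = None  # default 2 * radius_mean
    direction_cost: str = "additive"  # additive | product, see cost_direction

    def __post_init__(self):
        self.region_size = tuple(float(x) for x in np.asarray(self.region_size, dtype=float))
        if len(self.region_size) != 3 or any(x <= 0 for x in self.region_size):
            raise ParameterError("region_size must be a positive 3-vector")
        if not (0.0 <= self.target_density <= 1.0):
            raise ParameterError("target_density rho must lie in [0, 1]")
        if self.radius_mean <= 0:
            raise ParameterError("radius_mean mu_r must be positive")
        if self.radius_std < 0:
            raise ParameterError("radius_std sigma_r must be non-negative")
        if self.dispersion_model not in ("parallel", "watson", "esag"):
            raise ParameterError(f"unknown dispersion model {self.dispersion_model!r}")
        if self.dispersion_model == "watson" and self.watson_kappa <= 0:
            raise ParameterError("watson_kappa must be positive")
        self.esag_mu = tuple(float(x) for x in self.esag_mu)
        self.esag_gamma = tuple(float(x) for x in self.esag_gamma)
        if self.dispersion_model == "esag" and np.linalg.norm(self.esag_mu) == 0:
            raise ParameterError("esag_mu must be non-zero")
        if self.n_nodes < 4:
            raise ParameterError("n_nodes must be >= 4 to triangulate")
        if self.cost_weight < 0 or self.cost_weight > 1:
            raise ParameterError("cost_weight f must lie in [0, 1]")
        if self.collapse_max_attempts < 0 or self.n_added < 0:
            raise ParameterError("collapse_max_attempts and n_added must be non-negative")
        if self.direction_cost not in ("additive", "product"):
            raise ParameterError("direction_cost must be 'additive' or 'product'")
        bundles = []
        for b in self.bundles:
            bundles.append(b if isinstance(b, BundleSpec) else BundleSpec(**b))
        self.bundles = bundles
        if len({b.bundle_index for b in self.bundles}) != len(self.bundles):
            raise ParameterError("bundle indices must be unique")
        if self.node_padding is None:
            self.node_padding = 2.0 * self.radius_mean
        self._warn_practical()

    def _warn_practical(self):
        checks = [
            ("region_size", max(self.region_size)),
            ("target_density", self.target_density),
            ("radius_mean", self.radius_mean),
            ("radius_std", self.radius_std),
            ("cost_weight", self.cost_weight),
            ("collapse_initial", self.collapse_initial),
            ("collapse_increment", self.collapse_increment),
            ("n_added", self.n_added),
            ("n_nodes", self.n_nodes),
        ]
        if self.dispersion_model == "watson":
            checks.append(("watson_kappa", self.watson_kappa))
        if self.dispersion_model == "esag":
            checks.append(("esag_concentration", float(np.linalg.norm(self.esag_mu))))
        for name, value in checks:
            lo, hi = _PRACTICAL[name]
            if not (lo <= value <= hi):
                warnings.warn(
                    f"{name}={value} outside the exercised range [{lo}, {hi}]; "
                    "results are not validated there",
                    stacklevel=3,
                )

    # bundle-resolved accessors -------------------------------------------
    def bundle_density(self, b: BundleSpec) -> float:
        return self.target_density if b.target_density is None else b.target_density

    def bundle_dispersion(self, b: BundleSpec) -> tuple:
        model = b.dispersion_model or self.dispersion_model
        kappa = b.watson_kappa if b.watson_kappa is not None else self.watson_kappa
        mu = b.esag_mu if b.esag_mu is not None else self.esag_mu
        gamma = b.esag_gamma if b.esag_gamma is not None else self.esag_gamma
        return model, kappa, mu, gamma

    # serialisation --------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bundles"] = [dataclasses.asdict(b) for b in self.bundles]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> GrowthConfig:
    """Load a GrowthConfig from a YAML or JSON file (keys = field names)."""
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} did not parse to a mapping")
    return GrowthConfig.from_dict(data)


def save_config(config: GrowthConfig, path) -> None:
    path = str(path)
    data = config.to_dict()
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)
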