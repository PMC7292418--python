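"""Configuration schema, validation and YAML loading.

All durations are stored in simulation cycles; one cycle maps to one second.
Keys ending in ``_h`` in a YAML file are converted to cycles on load.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError

SECONDS_PER_CYCLE = 1
CYCLES_PER_HOUR = 3600
DOSE_CAP_OBJECTS = 100_000
#: objects per mg/kg; 600 mg/kg maps to the 100,000-object cap
OBJECTS_PER_MGKG = 500.0 / 3.0

RELEASE_MODES = ("NECROTIC_ONLY", "MITOD", "NONMD", "DUAL")
DUAL_SEMANTICS = ("sum", "both")


def _check_range(name: str, rng: tuple[int, int], minimum: int = 1) -> tuple[int, int]:
    lo, hi = int(rng[0]), int(rng[1])
    if lo > hi or lo < minimum:
        raise ConfigurationError(f"{name}: invalid integer range [{lo}, {hi}]")
    return lo, hi


@dataclass
class LayerSpec:
    """Sampling ranges (inclusive) for one layer of Sinusoid Segments."""

    n_nodes: tuple[int, int]
    core_length: tuple[int, int]
    circumference: tuple[int, int]

    def validate(self, label: str) -> None:
        _check_range(f"{label}.n_nodes", self.n_nodes)
        _check_range(f"{label}.core_length", self.core_length)
        _check_range(f"{label}.circumference", self.circumference)


@dataclass
class LobuleConfig:
    """Monte Carlo sampling ranges for one vLobule graph."""

    layers: list[LayerSpec]
    hepatocyte_occupancy: float = 0.90
    ec_occupancy: float = 0.99
    fanout: tuple[int, int] = (1, 3)
    n_lobules_per_liver: int = 12

    def validate(self) -> None:
        if len(self.layers) != 3:
            raise ConfigurationError("LobuleConfig requires exactly 3 layers")
        for i, layer in enumerate(self.layers, 1):
            layer.validate(f"layer{i}")
        # biomimetic constraint: layer 2 can never hold fewer SSs than layer 3
        if self.layers[1].n_nodes[0] < self.layers[2].n_nodes[1]:
            raise ConfigurationError(
                "layer 2 node-count range must dominate layer 3 "
                f"(got {self.layers[1].n_nodes} vs {self.layers[2].n_nodes})"
            )
        for name, occ in (("hepatocyte_occupancy", self.hepatocyte_occupancy), ("ec_occupancy", self.ec_occupancy)):
            if not 0.0 < occ <= 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1], got {occ}")
        _check_range("fanout", self.fanout)
        if self.n_lobules_per_liver < 1:
            raise ConfigurationError("n_lobules_per_liver must be >= 1")


@dataclass
class BandConfig:
    """Lobular band definitions on the dPV/dCV axes (inclusive ranges).

    The periportal band is a dPV prefix, the pericentral band a dCV prefix,
    and the mid-zonal band a dPV interval.  Bands need not cover every
    position; a vHPC outside every band is labelled ``none``.
    """

    pp_dpv: tuple[int, int] = (1, 4)
    mz_dpv: tuple[int, int] = (11, 15)
    pc_dcv: tuple[int, int] = (1, 4)

    def validate(self) -> None:
        pp = _check_range("pp_dpv", self.pp_dpv)
        mz = _check_range("mz_dpv", self.mz_dpv)
        _check_range("pc_dcv", self.pc_dcv)
        if pp[1] >= mz[0]:
            raise ConfigurationError("pp_dpv and mz_dpv ranges overlap")


@dataclass
class FlowParams:
    """Stochastic movement parameters for mobile Compound objects."""

    dose_transfer_fraction: float = 0.005
    downstream_bias: float = 0.5
    p_enter_cell: float = 0.1
    p_exit_cell: float = 0.05
    ec_bind_prob: float = 0.05
    ec_release_prob: float = 0.05
    vhpc_bind_prob: float = 0.05
    vhpc_release_prob: float = 0.05
    marker_fraction: float = 0.10

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"flow.{f.name} must be in [0, 1], got {v}")


def _as_knots(knots) -> list[tuple[float, float]]:
    out = [(float(z), float(v)) for z, v in knots]
    if len(out) < 2:
        raise ConfigurationError("a gradient needs at least two knots")
    zs = [z for z, _ in out]
    if zs != sorted(zs) or zs[0] != 0.0 or zs[-1] != 1.0:
        raise ConfigurationError(f"gradient knots must span z in [0, 1] in order, got {zs}")
    return out


@dataclass
class GradientSet:
    """Piecewise-linear periportal-to-pericentral gradients.

    Each gradient is a list of ``(z, value)`` knots with ``z = 0`` at the
    portal and ``z = 1`` at the central vein.  Monotonicity directions are
    validated: metabolism and NAPQI probability rise toward the central
    vein, the GSH depletion threshold and mitochondrial-damage mitigation
    fall, and non-mitochondrial-damage mitigation rises.
    """

    p_metabolism: list = field(default_factory=lambda: [(0.0, 0.004), (0.6, 0.015), (0.85, 0.055), (1.0, 0.12)])
    p_napqi: list = field(default_factory=lambda: [(0.0, 0.02), (0.45, 0.16), (0.7, 0.35), (0.87, 0.7), (1.0, 0.85)])
    gsh_threshold: list = field(default_factory=lambda: [(0.0, 12.0), (0.45, 3.8), (0.7, 3.6), (0.87, 3.0), (1.0, 2.0)])
    p_mitigate_mitod: list = field(default_factory=lambda: [(0.0, 0.01), (0.45, 0.0015), (1.0, 0.0005)])
    p_mitigate_nonmd: list = field(default_factory=lambda: [(0.0, 0.0005), (1.0, 0.01)])
    p_mito_fraction: float = 0.5

    _DIRECTIONS = {
        "p_metabolism": +1,
        "p_napqi": +1,
        "gsh_threshold": -1,
        "p_mitigate_mitod": -1,
        "p_mitigate_nonmd": +1,
    }
    _PROBABILITIES = ("p_metabolism", "p_napqi", "p_mitigate_mitod", "p_mitigate_nonmd")

    def validate(self) -> None:
        for name, direction in self._DIRECTIONS.items():
            knots = _as_knots(getattr(self, name))
            setattr(self, name, knots)
            vals = [v for _, v in knots]
            diffs = np.diff(vals) * direction
            if np.any(diffs < 0):
                kind = "increase" if direction > 0 else "decrease"
                raise ConfigurationError(f"gradient {name} must {kind} from PP to PC, got values {vals}")
            if name in self._PROBABILITIES and not all(0.0 <= v <= 1.0 for v in vals):
                raise ConfigurationError(f"gradient {name} values must be probabilities in [0, 1]")
            if name == "gsh_threshold" and any(v < 0 for v in vals):
                raise ConfigurationError("gsh_threshold values must be non-negative")
        if not 0.0 <= self.p_mito_fraction <= 1.0:
            raise ConfigurationError("p_mito_fraction must be in [0, 1]")

    def evaluate(self, name: str, z: np.ndarray) -> np.ndarray:
        knots = getattr(self, name)
        xs = np.array([k[0] for k in knots])
        ys = np.array([k[1] for k in knots])
        return np.interp(np.asarray(z, dtype=float), xs, ys)


@dataclass
class FutileCycleConfig:
    """Optional reversible APAP <-> p-aminophenol interconversion."""

    enabled: bool = False
    forward_prob: float = 0.0
    reverse_prob: float = 0.0

    def validate(self) -> None:
        for name in ("forward_prob", "reverse_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"futile_cycle.{name} must be in [0, 1]")


@dataclass
class MechanismConfig:
    """ALT-release mechanism variant and its thresholds and lag distributions."""

    release_mode: str = "MITOD"
    dual_semantics: str = "sum"
    leakage_threshold: int = 1
    necrosis_threshold: int = 4
    napqi_removal_prob: float = 0.5
    amplification_range: tuple[int, int] = (3, 6)
    leak_lag_cycles: tuple[int, int] = (2700, 18000)
    death_delay_cycles: tuple[int, int] = (7200, 21600)
    exlt_shift_cycles: int = 0
    alt_initial: int = 5
    futile_cycle: FutileCycleConfig = field(default_factory=FutileCycleConfig)

    def validate(self) -> None:
        if self.release_mode not in RELEASE_MODES:
            raise ConfigurationError(f"release_mode must be one of {RELEASE_MODES}, got {self.release_mode!r}")
        if self.dual_semantics not in DUAL_SEMANTICS:
            raise ConfigurationError(f"dual_semantics must be one of {DUAL_SEMANTICS}")
        for name in ("leakage_threshold", "necrosis_threshold", "alt_initial"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.napqi_removal_prob <= 1.0:
            raise ConfigurationError("napqi_removal_prob must be in [0, 1]")
        _check_range("amplification_range", self.amplification_range, minimum=0)
        for name in ("leak_lag_cycles", "death_delay_cycles"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ConfigurationError(f"{name}: require 0 < Min < Max, got [{lo}, {hi})")
        if self.exlt_shift_cycles < 0:
            raise ConfigurationError("exlt_shift_cycles must be >= 0")
        if self.leak_lag_cycles[0] >= self.death_delay_cycles[0]:
            raise ConfigurationError(
                "minimum ALT-leakage lag must be below the minimum death delay "
                f"(got {self.leak_lag_cycles[0]} >= {self.death_delay_cycles[0]})"
            )
        self.futile_cycle.validate()


@dataclass
class VExperimentConfig:
    """Everything needed to run one virtual experiment."""

    lobule: LobuleConfig
    bands: BandConfig
    flow: FlowParams
    gradients: GradientSet
    mechanism: MechanismConfig
    dose_objects: int = 50_000
    duration_cycles: int = 21_600
    n_trials: int = 12
    n_lobules: int = 12
    master_seed: int = 7
    measure_every: int = 1
    ledger_check_every: int = 600

    def validate(self) -> None:
        self.lobule.validate()
        self.bands.validate()
        self.flow.validate()
        self.gradients.validate()
        self.mechanism.validate()
        if not 0 <= self.dose_objects <= DOSE_CAP_OBJECTS:
            raise ConfigurationError(f"dose_objects must be in [0, {DOSE_CAP_OBJECTS}], got {self.dose_objects}")
        if self.duration_cycles < 1:
            raise ConfigurationError("duration_cycles must be >= 1")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.n_lobules < 1:
            raise ConfigurationError("n_lobules must be >= 1")
        if self.measure_every < 1 or self.ledger_check_every < 1:
            raise ConfigurationError("measure_every and ledger_check_every must be >= 1")

    def copy(self) -> "VExperimentConfig":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def dose_objects_from_mgkg(mgkg: float) -> int:
    """Map a wet-lab dose in mg/kg to discrete APAP objects (linear, capped).

    150 / 300 / 600 mg/kg map to 25,000 / 50,000 / 100,000 objects.
    """
    if mgkg < 0:
        raise ConfigurationError("dose must be non-negative")
    objects = round(mgkg * OBJECTS_PER_MGKG)
    if objects > DOSE_CAP_OBJECTS:
        raise ConfigurationError(f"dose of {objects} objects exceeds the {DOSE_CAP_OBJECTS}-object cap")
    return objects


def _tuple2(v) -> tuple[int, int]:
    return (int(v[0]), int(v[1]))


def _hours_to_cycles(value: float) -> int:
    return int(round(float(value) * CYCLES_PER_HOUR))


def _convert_hour_keys(d: dict) -> dict:
    """Rewrite ``*_h`` keys to their ``*_cycles`` equivalents."""
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = _convert_hour_keys(v)
        elif k.endswith("_h"):
            base = k[:-2] + "_cycles"
            out[base] = [_hours_to_cycles(x) for x in v] if isinstance(v, (list, tuple)) else _hours_to_cycles(v)
        else:
            out[k] = v
    return out


def config_from_dict(raw: dict) -> VExperimentConfig:
    raw = _convert_hour_keys(raw)
    lob = raw.get("lobule", {})
    layers = [
        LayerSpec(_tuple2(ls["n_nodes"]), _tuple2(ls["core_length"]), _tuple2(ls["circumference"]))
        for ls in lob["layers"]
    ]
    lobule = LobuleConfig(
        layers=layers,
        hepatocyte_occupancy=float(lob.get("hepatocyte_occupancy", 0.90)),
        ec_occupancy=float(lob.get("ec_occupancy", 0.99)),
        fanout=_tuple2(lob.get("fanout", (1, 3))),
        n_lobules_per_liver=int(lob.get("n_lobules_per_liver", 12)),
    )
    b = raw.get("bands", {})
    bands = BandConfig(
        pp_dpv=_tuple2(b.get("pp_dpv", (1, 4))),
        mz_dpv=_tuple2(b.get("mz_dpv", (11, 14))),
        pc_dcv=_tuple2(b.get("pc_dcv", (1, 4))),
    )
    flow = FlowParams(**{k: float(v) for k, v in raw.get("flow", {}).items()})
    g = dict(raw.get("gradients", {}))
    grad_kwargs = {}
    for name in ("p_metabolism", "p_napqi", "gsh_threshold", "p_mitigate_mitod", "p_mitigate_nonmd"):
        if name in g:
            grad_kwargs[name] = [(float(z), float(v)) for z, v in g[name]]
    if "p_mito_fraction" in g:
        grad_kwargs["p_mito_fraction"] = float(g["p_mito_fraction"])
    gradients = GradientSet(**grad_kwargs)
    m = dict(raw.get("mechanism", {}))
    fc = m.pop("futile_cycle", {})
    mech = MechanismConfig(
        release_mode=str(m.get("release_mode", "MITOD")).upper(),
        dual_semantics=str(m.get("dual_semantics", "sum")),
        leakage_threshold=int(m.get("leakage_threshold", 1)),
        necrosis_threshold=int(m.get("necrosis_threshold", 4)),
        napqi_removal_prob=float(m.get("napqi_removal_prob", 0.5)),
        amplification_range=_tuple2(m.get("amplification_range", (3, 6))),
        leak_lag_cycles=_tuple2(m.get("leak_lag_cycles", (2700, 18000))),
        death_delay_cycles=_tuple2(m.get("death_delay_cycles", (7200, 21600))),
        exlt_shift_cycles=int(m.get("exlt_shift_cycles", 0)),
        alt_initial=int(m.get("alt_initial", 5)),
        futile_cycle=FutileCycleConfig(
            enabled=bool(fc.get("enabled", False)),
            forward_prob=float(fc.get("forward_prob", 0.0)),
            reverse_prob=float(fc.get("reverse_prob", 0.0)),
        ),
    )
    e = dict(raw.get("experiment", {}))
    if "dose_mgkg" in e:
        e["dose_objects"] = dose_objects_from_mgkg(float(e.pop("dose_mgkg")))
    cfg = VExperimentConfig(
        lobule=lobule,
        bands=bands,
        flow=flow,
        gradients=gradients,
        mechanism=mech,
        dose_objects=int(e.get("dose_objects", 50_000)),
        duration_cycles=int(e.get("duration_cycles", 21_600)),
        n_trials=int(e.get("n_trials", 12)),
        n_lobules=int(e.get("n_lobules", 12)),
        master_seed=int(e.get("master_seed", 7)),
        measure_every=int(e.get("measure_every", 1)),
        ledger_check_every=int(e.get("ledger_check_every", 600)),
    )
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> VExperimentConfig:
    """Load and validate a YAML experiment configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: not a mapping")
    return config_from_dict(raw)


def default_config() -> VExperimentConfig:
    """The shipped, calibrated default configuration."""
    text = resources.files("vliver").joinpath("defaults.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))
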