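"""Deterministic fixture generation: every module is testable without
external data.

Three fixture kinds are supported:

* ``tiny_lobule`` -- a degenerate 3-node chain lobule (one SS per layer,
  unit core length) for transport unit tests;
* ``single_vhpc`` -- a scripted NAPQI arrival schedule feeding both the
  event-kernel simulator and the exhaustive Markov-chain oracle;
* ``synthetic_plasma_table`` -- 18 synthetic animals measured once each at
  3, 4.5 or 6 h, generated from the individualized scaling model with
  known skew factors (for delta-recovery tests).  These are synthetic
  stand-ins with the structure of a per-animal plasma-ALT table; no real
  animal data are packaged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import BandConfig, LayerSpec, LobuleConfig
from .errors import ConfigurationError
from .lobule import compute_zonal_positions, sample_lobule_graph
from .rng import single_stream
from .scaling import ScalingParams

FIXTURE_KINDS = ("tiny_lobule", "single_vhpc", "synthetic_plasma_table")

PLASMA_TIMES_H = (3.0, 4.5, 6.0)


def tiny_lobule_config(core_length: int = 1, circumference: int = 2) -> LobuleConfig:
    """A degenerate lobule: one SS per layer, fixed dimensions."""
    layer = lambda: LayerSpec((1, 1), (core_length, core_length), (circumference, circumference))  # noqa: E731
    return LobuleConfig(layers=[layer(), layer(), layer()], n_lobules_per_liver=1)


def tiny_band_config() -> BandConfig:
    return BandConfig(pp_dpv=(1, 1), mz_dpv=(2, 2), pc_dcv=(1, 1))


def reference_body_alt_curve(times_h: np.ndarray, plateau: float = 600.0, t50_h: float = 2.5, tau_h: float = 0.8) -> np.ndarray:
    """A synthetic logistic Body-ALT reference curve (objects vs hours)."""
    times_h = np.asarray(times_h, dtype=float)
    return plateau / (1.0 + np.exp(-(times_h - t50_h) / tau_h))


def synthetic_plasma_table(
    seed: int,
    n_animals: int = 18,
    delta_mode: str = "lognormal",
    delta_sigma: float = 0.3,
    scaling: ScalingParams | None = None,
):
    """Generate ``(table, deltas, reference)`` from the individualized model.

    Each animal is assigned one measurement time (3/4.5/6 h round-robin)
    and a skew factor delta_i (unit, or lognormal(0, sigma^2)); its plasma
    value is ``delta_i * S * X_t`` with ``X_t`` from the synthetic logistic
    reference curve.
    """
    if delta_mode not in ("lognormal", "unit"):
        raise ConfigurationError("delta_mode must be 'lognormal' or 'unit'")
    scaling = scaling or ScalingParams()
    rng = single_stream(seed)
    times = np.array([PLASMA_TIMES_H[i % len(PLASMA_TIMES_H)] for i in range(n_animals)])
    if delta_mode == "unit":
        deltas = np.ones(n_animals)
    else:
        deltas = rng.lognormal(mean=0.0, sigma=delta_sigma, size=n_animals)
    x = reference_body_alt_curve(times)
    y = deltas * scaling.s * x
    table = pd.DataFrame(
        {"animal_id": [f"m{i + 1:02d}" for i in range(n_animals)], "time_h": times, "alt_iu_ml": y}
    )
    reference = pd.DataFrame({"time_h": np.array(PLASMA_TIMES_H), "body_alt": reference_body_alt_curve(np.array(PLASMA_TIMES_H))})
    return table, deltas, reference


def single_vhpc_schedule(seed: int, n_arrivals: int = 3, arrival_cycle: int = 0) -> pd.DataFrame:
    """Scripted NAPQI arrival schedule for the single-cell oracle test."""
    if n_arrivals < 1:
        raise ConfigurationError("schedule needs at least one arrival")
    return pd.DataFrame({"cycle": [arrival_cycle], "napqi_arrivals": [n_arrivals]})


def generate_fixture(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write the requested fixture files; returns the created paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "tiny_lobule":
        graph = compute_zonal_positions(sample_lobule_graph(tiny_lobule_config(), seed))
        path = out_dir / "tiny_lobule.json"
        path.write_text(graph.to_json())
        written.append(path)
    elif kind == "single_vhpc":
        path = out_dir / "single_vhpc_schedule.csv"
        single_vhpc_schedule(seed).to_csv(path, index=False)
        written.append(path)
    elif kind == "synthetic_plasma_table":
        table, deltas, reference = synthetic_plasma_table(seed)
        for name, df in (
            ("synthetic_plasma_table.csv", table),
            ("synthetic_plasma_reference.csv", reference),
            ("synthetic_plasma_deltas.csv", pd.DataFrame({"animal_id": table["animal_id"], "delta": deltas})),
        ):
            path = out_dir / name
            df.to_csv(path, index=False)
            written.append(path)
    else:
        raise ConfigurationError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    return written
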