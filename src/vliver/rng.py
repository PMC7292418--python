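"""Named random-number substreams.

Each trial owns five independent PCG64 generators keyed by what they drive:

* ``structure``   -- lobule-graph sampling and cell placement
* ``disposition`` -- dosing, extracellular percolation and cell exchange of
                     APAP/G/S, binder events, metabolism
* ``damage``      -- NAPQI removal, damage amplification, mitigation,
                     necrosis triggering and death-delay draws
* ``release``     -- ALT-leakage scheduling draws and extracellular ALT
                     movement
* ``marker``      -- movement of the inert Marker internal standard

Keeping these streams separate guarantees that changing the ALT-release
mechanism or any of its parameters leaves the APAP disposition and damage
trajectories bit-identical, and that the Marker body-accumulation curve is
invariant to mechanism parameters at a fixed structure seed.
"""

from __future__ import annotations

import numpy as np

STREAM_NAMES = ("structure", "disposition", "damage", "release", "marker")


def stream_generators(seed: int, names: tuple[str, ...] = STREAM_NAMES) -> dict[str, np.random.Generator]:
    """Return independent generators for ``names``, derived from ``seed``.

    Substreams are derived with fixed ``spawn_key`` indices so the mapping
    from name to stream never depends on call order.
    """
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return {
        name: np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(i,))))
        for i, name in enumerate(names)
    }


def single_stream(seed: int, index: int = 0) -> np.random.Generator:
    """One generator on the same keying scheme (used by fixtures/calibration)."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy=int(seed), spawn_key=(100 + index,))))
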