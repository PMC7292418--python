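"""Exhaustive Markov-chain oracle for the single-vHPC necrosis chain.

Computes the exact distribution of the necrosis-trigger cycle for one vHPC
holding ``n0`` NAPQI at t=0, with an integer GSH counter ``g``, per-cycle
removal probability ``q``, all damage batches mitochondrial with sizes
(n+1) uniform on {4..7}, a necrosis threshold of 4 (strict), and no
mitigation or further arrivals.

State: (remaining NAPQI, remaining GSH, flag) where ``flag`` records that
exactly one size-4 batch exists (MitoD == 4, not yet over the threshold).
Within a cycle, ``r ~ Binomial(k, q)`` removals occur; the GSH counter
absorbs removals first, and each surplus removal creates one batch:

* two or more batches in one cycle always cross the threshold (>= 8 MitoD);
* one batch crosses iff its size >= 5 (probability 3/4) or the flag is set;
* a single size-4 batch on a clean state sets the flag.

This mirrors the event kernels' semantics but is computed by enumeration,
independent of the simulation code.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom


def trigger_time_distribution(n0: int, g: int, q: float = 0.5, t_max: int = 80) -> np.ndarray:
    """P(necrosis triggered at cycle t) for t = 1..t_max (index 0 unused).

    The returned array has length t_max + 1; ``out[0]`` is the probability
    the chain never triggers within the horizon (including true never).
    """
    states: dict[tuple[int, int, bool], float] = {(n0, g, False): 1.0}
    out = np.zeros(t_max + 1)
    for t in range(1, t_max + 1):
        nxt: dict[tuple[int, int, bool], float] = {}
        for (k, gsh, flag), p in states.items():
            if k == 0:
                nxt[(k, gsh, flag)] = nxt.get((k, gsh, flag), 0.0) + p
                continue
            pmf = binom.pmf(np.arange(k + 1), k, q)
            for r in range(k + 1):
                pr = p * pmf[r]
                if pr == 0.0:
                    continue
                consumed = min(r, gsh)
                d = r - consumed
                k2, g2 = k - r, gsh - consumed
                if d == 0:
                    key = (k2, g2, flag)
                    nxt[key] = nxt.get(key, 0.0) + pr
                elif d >= 2 or flag:
                    out[t] += pr
                else:  # exactly one batch on a clean state
                    out[t] += pr * 0.75  # batch size >= 5
                    key = (k2, g2, True)
                    nxt[key] = nxt.get(key, 0.0) + pr * 0.25
        states = nxt
    out[0] = sum(states.values())
    return out


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())
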