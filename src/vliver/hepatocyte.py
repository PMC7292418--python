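"""Per-vHPC event logic: metabolism, GSH depletion, damage, necrosis and
the four ALT-externalization mechanisms.

State is held as a structure-of-arrays (:class:`HepatocyteArray`) over all
vHPCs in a liver so every event kernel is vectorised.  Each kernel maps to
one discrete, probabilistic event class evaluated once per simulation cycle:

* APAP metabolism: each free intracellular APAP is metabolised with a
  zone-dependent probability; the metabolite is NAPQI with a zone-dependent
  probability, otherwise G or S with equal probability.
* NAPQI removal: each NAPQI is removed with a fixed per-cycle probability.
  While the GSH counter is positive a removal decrements it by 1.0 and is
  harmless; once the counter reaches zero every further removal creates
  ``n + 1`` Damage Products of one type (MitoD or nonMD), with ``n`` drawn
  uniformly from the configured integer amplification range.
* Damage mitigation: at most one MitoD and one nonMD removal event per
  vHPC per cycle, with opposing zonal gradients.
* Necrosis: MitoD strictly above the Necrosis Threshold triggers necrosis;
  after a uniformly sampled death delay the vHPC turns Necrotic and
  externalizes all remaining ALT with zero delay.  Necrotic is absorbing; a
  Necrotic vHPC performs no further events.
* ALT leakage: damage above the Leakage Threshold (per the configured
  release mode) makes a vHPC Leakage-Triggered; while triggered and
  unscheduled ALT remains it schedules one lagged release per cycle, and
  scheduled releases fire at their due cycle iff the ALT counter is still
  positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GradientSet, MechanismConfig

MAX_ALT = 8  # pending-release slots per vHPC; alt_initial may not exceed this


@dataclass
class HepatocyteArray:
    """Structure-of-arrays state for a population of vHPCs."""

    z: np.ndarray  # normalised zonal coordinate in [0, 1]
    slot: np.ndarray  # axial lattice slot of each vHPC
    band: np.ndarray  # band code (lobule.BAND_*)
    lobule: np.ndarray

    # zone-resolved event probabilities / initial values
    p_met: np.ndarray
    p_napqi: np.ndarray
    p_mit_mito: np.ndarray
    p_mit_non: np.ndarray
    p_mito_fraction: float

    # compound counters
    apap_free: np.ndarray
    apap_bound: np.ndarray
    g: np.ndarray
    s: np.ndarray
    napqi: np.ndarray
    pap: np.ndarray  # p-aminophenol (futile-cycle option)
    gsh: np.ndarray  # real-valued depletion counter, monotone non-increasing
    mitod: np.ndarray
    nonmd: np.ndarray

    # ALT bookkeeping
    alt_counter: np.ndarray
    pending_due: np.ndarray  # (n, MAX_ALT) due cycles, -1 when unused
    pending_count: np.ndarray
    scheduled_ever: np.ndarray

    # state flags and first-event times (-1 = never)
    leak_triggered: np.ndarray
    leak_ever: np.ndarray
    necrosis_triggered: np.ndarray
    necrotic: np.ndarray
    necrotic_due: np.ndarray
    t_gsh_depleted: np.ndarray
    t_leak: np.ndarray
    t_necrosis: np.ndarray
    t_necrotic: np.ndarray

    alt_initial: int = 5

    @property
    def n(self) -> int:
        return len(self.z)

    @classmethod
    def create(
        cls,
        z: np.ndarray,
        gradients: GradientSet,
        mech: MechanismConfig,
        slot: np.ndarray | None = None,
        band: np.ndarray | None = None,
        lobule: np.ndarray | None = None,
    ) -> "HepatocyteArray":
        z = np.asarray(z, dtype=float)
        n = len(z)
        if mech.alt_initial > MAX_ALT:
            raise ValueError(f"alt_initial may not exceed {MAX_ALT}")
        zeros = lambda: np.zeros(n, dtype=np.int64)  # noqa: E731
        return cls(
            z=z,
            slot=zeros() if slot is None else np.asarray(slot, dtype=np.int64),
            band=zeros() if band is None else np.asarray(band, dtype=np.int64),
            lobule=zeros() if lobule is None else np.asarray(lobule, dtype=np.int64),
            p_met=gradients.evaluate("p_metabolism", z),
            p_napqi=gradients.evaluate("p_napqi", z),
            p_mit_mito=gradients.evaluate("p_mitigate_mitod", z),
            p_mit_non=gradients.evaluate("p_mitigate_nonmd", z),
            p_mito_fraction=gradients.p_mito_fraction,
            apap_free=zeros(),
            apap_bound=zeros(),
            g=zeros(),
            s=zeros(),
            napqi=zeros(),
            pap=zeros(),
            gsh=gradients.evaluate("gsh_threshold", z).astype(float),
            mitod=zeros(),
            nonmd=zeros(),
            alt_counter=np.full(n, mech.alt_initial, dtype=np.int64),
            pending_due=np.full((n, MAX_ALT), -1, dtype=np.int64),
            pending_count=zeros(),
            scheduled_ever=zeros(),
            leak_triggered=np.zeros(n, dtype=bool),
            leak_ever=np.zeros(n, dtype=bool),
            necrosis_triggered=np.zeros(n, dtype=bool),
            necrotic=np.zeros(n, dtype=bool),
            necrotic_due=np.full(n, -1, dtype=np.int64),
            t_gsh_depleted=np.full(n, -1, dtype=np.int64),
            t_leak=np.full(n, -1, dtype=np.int64),
            t_necrosis=np.full(n, -1, dtype=np.int64),
            t_necrotic=np.full(n, -1, dtype=np.int64),
            alt_initial=mech.alt_initial,
        )

    def alt_released(self) -> np.ndarray:
        """Per-vHPC ALT externalized so far (counter identity)."""
        return self.alt_initial - self.alt_counter


def metabolize_step(h: HepatocyteArray, rng: np.random.Generator) -> dict:
    """Metabolise free intracellular APAP into NAPQI, G or S."""
    idx = np.nonzero((h.apap_free > 0) & ~h.necrotic)[0]
    if len(idx) == 0:
        return {"metabolized": 0, "napqi": 0, "g": 0, "s": 0}
    met = rng.binomial(h.apap_free[idx], h.p_met[idx])
    nap = rng.binomial(met, h.p_napqi[idx])
    rest = met - nap
    gnew = rng.binomial(rest, 0.5)
    snew = rest - gnew
    h.apap_free[idx] -= met
    h.napqi[idx] += nap
    h.g[idx] += gnew
    h.s[idx] += snew
    return {
        "metabolized": int(met.sum()),
        "napqi": int(nap.sum()),
        "g": int(gnew.sum()),
        "s": int(snew.sum()),
    }


def napqi_removal_step(h: HepatocyteArray, cfg: MechanismConfig, t: int, rng: np.random.Generator) -> dict:
    """Remove NAPQI; deplete GSH first, then create amplified damage."""
    idx = np.nonzero((h.napqi > 0) & ~h.necrotic)[0]
    out = {"removed": 0, "depleted_idx": np.empty(0, dtype=np.int64), "mitod_created": 0, "nonmd_created": 0}
    if len(idx) == 0:
        return out
    rem = rng.binomial(h.napqi[idx], cfg.napqi_removal_prob)
    gsh = h.gsh[idx]
    capacity = np.ceil(gsh).astype(np.int64)  # removals the counter can still absorb
    consumed = np.minimum(rem, capacity)
    damage_removals = rem - consumed
    new_gsh = np.maximum(gsh - rem, 0.0)
    newly_depleted = (gsh > 0) & (new_gsh == 0)
    h.gsh[idx] = new_gsh
    h.napqi[idx] -= rem
    dep_idx = idx[newly_depleted]
    h.t_gsh_depleted[dep_idx] = t
    out["removed"] = int(rem.sum())
    out["depleted_idx"] = dep_idx

    dmg_rows = idx[damage_removals > 0]
    if len(dmg_rows):
        reps = np.repeat(dmg_rows, damage_removals[damage_removals > 0])
        n_lo, n_hi = cfg.amplification_range
        sizes = rng.integers(n_lo, n_hi + 1, size=len(reps)) + 1
        is_mito = rng.random(len(reps)) < h.p_mito_fraction
        np.add.at(h.mitod, reps[is_mito], sizes[is_mito])
        np.add.at(h.nonmd, reps[~is_mito], sizes[~is_mito])
        out["mitod_created"] = int(sizes[is_mito].sum())
        out["nonmd_created"] = int(sizes[~is_mito].sum())
    return out


def mitigation_step(h: HepatocyteArray, rng: np.random.Generator) -> dict:
    """At most one MitoD and one nonMD removal event per vHPC per cycle."""
    events = 0
    mitigated_idx = []
    for counts, prob in ((h.mitod, h.p_mit_mito), (h.nonmd, h.p_mit_non)):
        idx = np.nonzero((counts > 0) & ~h.necrotic)[0]
        if len(idx) == 0:
            continue
        hit = rng.random(len(idx)) < prob[idx]
        counts[idx[hit]] -= 1
        events += int(hit.sum())
        mitigated_idx.append(idx[hit])
    return {
        "mitigation_events": events,
        "idx": np.concatenate(mitigated_idx) if mitigated_idx else np.empty(0, dtype=np.int64),
    }


def necrosis_step(h: HepatocyteArray, cfg: MechanismConfig, t: int, rng: np.random.Generator) -> dict:
    """Trigger necrosis on MitoD excess; complete it after the death delay.

    The trigger test is strict (``mitod > necrosis_threshold``).  At the due
    cycle all remaining ALT is externalized with zero delay and the vHPC
    becomes Necrotic (absorbing).
    Returns indices and amounts of externalized ALT for the transport layer.
    """
    new = np.nonzero(~h.necrosis_triggered & ~h.necrotic & (h.mitod > cfg.necrosis_threshold))[0]
    if len(new):
        lo, hi = cfg.death_delay_cycles
        delay = rng.integers(lo, hi, size=len(new)) + cfg.exlt_shift_cycles
        h.necrosis_triggered[new] = True
        h.necrotic_due[new] = t + delay
        h.t_necrosis[new] = t

    due = np.nonzero(h.necrosis_triggered & ~h.necrotic & (h.necrotic_due == t))[0]
    released = h.alt_counter[due].copy()
    h.alt_counter[due] = 0
    h.necrotic[due] = True
    h.t_necrotic[due] = t
    return {"triggered_idx": new, "necrotic_idx": due, "released": released}


def _leakage_metric(h: HepatocyteArray, cfg: MechanismConfig) -> np.ndarray:
    mode = cfg.release_mode
    if mode == "MITOD":
        return h.mitod > cfg.leakage_threshold
    if mode == "NONMD":
        return h.nonmd > cfg.leakage_threshold
    if mode == "DUAL":
        if cfg.dual_semantics == "sum":
            return (h.mitod + h.nonmd) > cfg.leakage_threshold
        return (h.mitod > cfg.leakage_threshold) & (h.nonmd > cfg.leakage_threshold)
    raise ValueError(f"unexpected release mode {mode!r}")


def leakage_step(h: HepatocyteArray, cfg: MechanismConfig, t: int, rng: np.random.Generator) -> dict:
    """Evaluate leakage triggering, fire due releases, schedule new ones.

    No-op for the Necrotic-only mechanism.  A vHPC whose damage falls back
    below the threshold loses its Leakage-Triggered state but already
    scheduled releases persist and still fire.
    """
    out = {
        "new_triggered_idx": np.empty(0, dtype=np.int64),
        "released_idx": np.empty(0, dtype=np.int64),
        "released": np.empty(0, dtype=np.int64),
        "scheduled_idx": np.empty(0, dtype=np.int64),
    }
    if cfg.release_mode == "NECROTIC_ONLY":
        return out

    trig = _leakage_metric(h, cfg) & ~h.necrotic
    new_ever = trig & ~h.leak_ever
    h.leak_triggered = trig
    h.leak_ever |= trig
    new_idx = np.nonzero(new_ever)[0]
    h.t_leak[new_idx] = t
    out["new_triggered_idx"] = new_idx

    # fire releases that are due this cycle
    rows = np.nonzero(h.pending_count > 0)[0]
    if len(rows):
        hits = (h.pending_due[rows, :] == t).sum(axis=1)
        fired = hits > 0
        frows = rows[fired]
        if len(frows):
            released = np.minimum(hits[fired], h.alt_counter[frows])
            h.alt_counter[frows] -= released
            h.pending_count[frows] -= hits[fired]
            keep = released > 0
            out["released_idx"] = frows[keep]
            out["released"] = released[keep]

    # schedule at most one new release per triggered vHPC per cycle
    can = np.nonzero(h.leak_triggered & (h.alt_counter - h.pending_count > 0))[0]
    if len(can):
        lo, hi = cfg.leak_lag_cycles
        lag = rng.integers(lo, hi, size=len(can)) + cfg.exlt_shift_cycles
        h.pending_due[can, h.scheduled_ever[can]] = t + lag
        h.scheduled_ever[can] += 1
        h.pending_count[can] += 1
        out["scheduled_idx"] = can
    return out


def futile_cycle_step(h: HepatocyteArray, cfg: MechanismConfig, rng: np.random.Generator) -> dict:
    """Optional reversible APAP <-> p-aminophenol interconversion."""
    fc = cfg.futile_cycle
    if not fc.enabled:
        return {"forward": 0, "reverse": 0}
    idx_f = np.nonzero((h.apap_free > 0) & ~h.necrotic)[0]
    fwd = rng.binomial(h.apap_free[idx_f], fc.forward_prob) if len(idx_f) else np.empty(0, dtype=np.int64)
    idx_r = np.nonzero((h.pap > 0) & ~h.necrotic)[0]
    rev = rng.binomial(h.pap[idx_r], fc.reverse_prob) if len(idx_r) else np.empty(0, dtype=np.int64)
    h.apap_free[idx_f] -= fwd
    h.pap[idx_f] += fwd
    h.pap[idx_r] -= rev
    h.apap_free[idx_r] += rev
    return {"forward": int(np.sum(fwd)), "reverse": int(np.sum(rev))}
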