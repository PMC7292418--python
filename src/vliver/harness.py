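"""Assemble virtual Mice and run Monte Carlo virtual experiments.

A *trial* is one seeded execution: a Mouse (Body + sampled vLobule variants
+ Dose) advanced through ``duration_cycles`` one-second cycles.  A
*vExperiment* is a set of trials whose measurements are aggregated.
Measurement agents record amounts and cumulative event counts at the end
of every cycle (optionally thinned); object-conservation ledgers are
verified during the run and any violation is a hard failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hepatocyte as hp
from . import transport as tr
from .config import VExperimentConfig
from .errors import SimulationInvariantError
from .lobule import BAND_PP, BAND_MZ, BAND_PC, compute_zonal_positions, sample_lobule_graph
from .rng import stream_generators

AMOUNT_SERIES = ("APAP", "NAPQI", "G", "S", "MitoD", "nonMD")
EVENT_SERIES = (
    "gsh_depleted",
    "mitigation",
    "leak_triggered",
    "alt_scheduled",
    "alt_released",
    "necrosis_triggered",
    "necrotic",
)
SCOPES = ("liver", "PP", "MZ", "PC")  # column order of banded series


def _band_tally(bands: np.ndarray, idx: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """(liver, PP, MZ, PC) totals for events at vHPC indices ``idx``."""
    out = np.zeros(4, dtype=np.int64)
    if len(idx) == 0:
        return out
    w = weights if weights is not None else np.ones(len(idx), dtype=np.int64)
    out[0] = w.sum()
    b = bands[idx]
    for col, code in ((1, BAND_PP), (2, BAND_MZ), (3, BAND_PC)):
        sel = b == code
        if sel.any():
            out[col] = w[sel].sum()
    return out


@dataclass
class MeasurementLog:
    """Per-cycle measurements of one trial.

    ``amounts[name]`` and ``ex_alt`` are (n_records, 4) arrays over scopes
    (whole liver, PP, MZ, PC); ``events[name]`` are cumulative counts with
    the same layout; ``body[kind]`` is the mean per-lobule Body amount.
    """

    cycles: np.ndarray
    body: dict
    amounts: dict
    ex_alt: np.ndarray
    events: dict
    n_vhpc: int
    band_sizes: dict

    def to_frame(self):
        import pandas as pd

        data = {"cycle": self.cycles}
        for kind, series in self.body.items():
            data[f"body_{kind}"] = series
        for name, arr in self.amounts.items():
            for ci, scope in enumerate(SCOPES):
                data[f"{name}_{scope}"] = arr[:, ci]
        for ci, scope in enumerate(SCOPES):
            data[f"exALT_{scope}"] = self.ex_alt[:, ci]
        for name, arr in self.events.items():
            for ci, scope in enumerate(SCOPES):
                data[f"cum_{name}_{scope}"] = arr[:, ci]
        return pd.DataFrame(data)


@dataclass
class TrialResult:
    seed: int
    log: MeasurementLog
    # per-vHPC first-event times (-1 = never) and metadata
    t_gsh_depleted: np.ndarray
    t_leak: np.ndarray
    t_necrosis: np.ndarray
    t_necrotic: np.ndarray
    vhpc_band: np.ndarray
    vhpc_zone: np.ndarray
    vhpc_lobule: np.ndarray
    alt_released_per_vhpc: np.ndarray
    marker_curve: np.ndarray  # mean body Marker per recorded cycle
    transport_trace: list = field(default_factory=list)

    @property
    def n_vhpc(self) -> int:
        return len(self.vhpc_band)

    def event_ledger_frame(self):
        """Per-vHPC first-event times as a long-form DataFrame."""
        import pandas as pd

        from .lobule import BAND_LABELS

        rows = []
        for event, times in (
            ("GSH_DEPLETED", self.t_gsh_depleted),
            ("LEAK_TRIGGERED", self.t_leak),
            ("NECROSIS_TRIGGERED", self.t_necrosis),
            ("NECROTIC", self.t_necrotic),
        ):
            idx = np.nonzero(times >= 0)[0]
            for i in idx:
                rows.append((int(times[i]), int(i), event, BAND_LABELS[int(self.vhpc_band[i])]))
        return pd.DataFrame(rows, columns=["cycle", "vhpc", "event", "band"]).sort_values(
            ["cycle", "vhpc"], kind="stable", ignore_index=True
        )


class _Ledger:
    """Per-kind object-conservation bookkeeping, checked during the run."""

    def __init__(self, state: tr.TransportState, hep: hp.HepatocyteArray, marker_objects: int):
        self.marker_total = marker_objects * state.lattice.n_lobules
        self.apap_total = state.initial_dose * state.lattice.n_lobules
        self.alt_total = hep.alt_initial * hep.n
        self.metabolized = 0
        self.g_created = 0
        self.s_created = 0
        self.napqi_created = 0
        self.napqi_removed = 0
        self.damage_created = 0
        self.damage_mitigated = 0

    def check(self, state: tr.TransportState, hep: hp.HepatocyteArray, cycle: int) -> None:
        def fail(kind, expect, got):
            raise SimulationInvariantError(
                f"cycle {cycle}: {kind} ledger does not close (expected {expect}, got {got})"
            )

        m = state.mobile
        apap = (
            int(state.body_reservoir["APAP"].sum() + state.body["APAP"].sum())
            + int(m["APAP"].sum() + state.ec_bound.sum() + state.cv["APAP"].sum())
            + int(hep.apap_free.sum() + hep.apap_bound.sum() + hep.pap.sum())
            + self.metabolized
        )
        if apap != self.apap_total:
            fail("APAP", self.apap_total, apap)
        for kind, created, intra in (("G", self.g_created, hep.g), ("S", self.s_created, hep.s)):
            tot = int(state.body[kind].sum() + m[kind].sum() + state.cv[kind].sum() + intra.sum())
            if tot != created:
                fail(kind, created, tot)
        napqi = int(hep.napqi.sum()) + self.napqi_removed
        if napqi != self.napqi_created:
            fail("NAPQI", self.napqi_created, napqi)
        alt = int(hep.alt_counter.sum() + m["ALT"].sum() + state.cv["ALT"].sum() + state.body["ALT"].sum())
        if alt != self.alt_total:
            fail("ALT", self.alt_total, alt)
        marker = int(
            state.body_reservoir["Marker"].sum()
            + state.body["Marker"].sum()
            + m["Marker"].sum()
            + state.cv["Marker"].sum()
        )
        if marker != self.marker_total:
            fail("Marker", self.marker_total, marker)
        dmg = int(hep.mitod.sum() + hep.nonmd.sum()) + self.damage_mitigated
        if dmg != self.damage_created:
            fail("damage", self.damage_created, dmg)


def build_liver(cfg: VExperimentConfig, rng_structure: np.random.Generator):
    """Sample ``n_lobules`` variant graphs and flatten them to a lattice."""
    graphs = []
    for _ in range(cfg.n_lobules):
        g = sample_lobule_graph(cfg.lobule, rng_structure)
        compute_zonal_positions(g)
        graphs.append(g)
    lattice = tr.LiverLattice.build(graphs, cfg.bands)
    return graphs, lattice


def measure_cycle(hep: hp.HepatocyteArray, state: tr.TransportState) -> dict:
    """One end-of-cycle measurement record (amounts by scope)."""
    lat = state.lattice
    bands = hep.band
    record = {"body": {}, "amounts": {}, "ex_alt": None}
    # per-kind accumulated Body pool; the un-infused APAP dose reservoir is
    # reported separately so accumulation curves stay monotone
    for kind in tr.MOBILE_KINDS:
        record["body"][kind] = float(state.body[kind].mean())
    record["body"]["APAP_reservoir"] = float(state.body_reservoir["APAP"].mean())
    intr = {
        "APAP": hep.apap_free + hep.apap_bound,
        "NAPQI": hep.napqi,
        "G": hep.g,
        "S": hep.s,
        "MitoD": hep.mitod,
        "nonMD": hep.nonmd,
    }
    for name, counts in intr.items():
        row = np.zeros(4, dtype=np.int64)
        row[0] = counts.sum()
        sums = np.bincount(bands, weights=counts, minlength=4)
        row[1], row[2], row[3] = int(sums[BAND_PP]), int(sums[BAND_MZ]), int(sums[BAND_PC])
        record["amounts"][name] = row
    alt = state.mobile["ALT"]
    row = np.zeros(4, dtype=np.int64)
    row[0] = alt.sum()
    sums = np.bincount(lat.slot_band, weights=alt, minlength=4)
    row[1], row[2], row[3] = int(sums[BAND_PP]), int(sums[BAND_MZ]), int(sums[BAND_PC])
    record["ex_alt"] = row
    return record


def run_trial(cfg: VExperimentConfig, trial_seed: int, trace_every: int | None = None) -> TrialResult:
    """Run one seeded execution; deterministic given config and seed.

    ``trace_every`` optionally records a sparse per-slot transport snapshot
    (cycle, lobule, slot, kind, count) every N cycles; off by default as it
    is costly.
    """
    cfg.validate()
    streams = stream_generators(trial_seed)
    _, lattice = build_liver(cfg, streams["structure"])
    hep = hp.HepatocyteArray.create(
        z=lattice.vhpc_z,
        gradients=cfg.gradients,
        mech=cfg.mechanism,
        slot=lattice.slot_of_vhpc,
        band=lattice.vhpc_band,
        lobule=lattice.vhpc_lobule,
    )
    marker_objects = int(round(cfg.dose_objects * cfg.flow.marker_fraction))
    state = tr.TransportState.create(lattice, cfg.dose_objects, marker_objects)
    ledger = _Ledger(state, hep, marker_objects)

    cum = {name: np.zeros(4, dtype=np.int64) for name in EVENT_SERIES}
    rec_cycles, rec_body, rec_amounts, rec_exalt, rec_events = [], [], [], [], []
    trace_rows: list[tuple] = []

    mech = cfg.mechanism
    flow = cfg.flow
    d_rng, dmg_rng, rel_rng, mk_rng = (
        streams["disposition"],
        streams["damage"],
        streams["release"],
        streams["marker"],
    )

    intracellular_phases = ("metabolize", "napqi", "mitigate")
    for t in range(1, cfg.duration_cycles + 1):
        tr.dose_step(state, flow, d_rng, kind="APAP")
        tr.dose_step(state, flow, mk_rng, kind="Marker")
        tr.percolate_step(state, flow, d_rng, kinds=("APAP", "G", "S"))
        tr.percolate_step(state, flow, rel_rng, kinds=("ALT",))
        tr.percolate_step(state, flow, mk_rng, kinds=("Marker",))
        tr.cell_exchange_step(state, hep, flow, d_rng)

        # the order of intracellular event classes is re-randomized each cycle
        for phase in dmg_rng.permutation(len(intracellular_phases)):
            name = intracellular_phases[phase]
            if name == "metabolize":
                ev = hp.metabolize_step(hep, d_rng)
                ledger.metabolized += ev["metabolized"]
                ledger.g_created += ev["g"]
                ledger.s_created += ev["s"]
                ledger.napqi_created += ev["napqi"]
            elif name == "napqi":
                ev = hp.napqi_removal_step(hep, mech, t, dmg_rng)
                ledger.napqi_removed += ev["removed"]
                ledger.damage_created += ev["mitod_created"] + ev["nonmd_created"]
                cum["gsh_depleted"] += _band_tally(hep.band, ev["depleted_idx"])
            else:
                ev = hp.mitigation_step(hep, dmg_rng)
                ledger.damage_mitigated += ev["mitigation_events"]
                cum["mitigation"] += _band_tally(hep.band, ev["idx"])
        if mech.futile_cycle.enabled:
            hp.futile_cycle_step(hep, mech, d_rng)

        ev = hp.necrosis_step(hep, mech, t, dmg_rng)
        cum["necrosis_triggered"] += _band_tally(hep.band, ev["triggered_idx"])
        cum["necrotic"] += _band_tally(hep.band, ev["necrotic_idx"])
        if len(ev["necrotic_idx"]):
            released = ev["released"]
            np.add.at(state.mobile["ALT"], hep.slot[ev["necrotic_idx"]], released)
            cum["alt_released"] += _band_tally(hep.band, ev["necrotic_idx"], released)

        ev = hp.leakage_step(hep, mech, t, rel_rng)
        cum["leak_triggered"] += _band_tally(hep.band, ev["new_triggered_idx"])
        cum["alt_scheduled"] += _band_tally(hep.band, ev["scheduled_idx"])
        if len(ev["released_idx"]):
            np.add.at(state.mobile["ALT"], hep.slot[ev["released_idx"]], ev["released"])
            cum["alt_released"] += _band_tally(hep.band, ev["released_idx"], ev["released"])

        tr.cv_collect_step(state)

        if t % cfg.measure_every == 0 or t == cfg.duration_cycles:
            rec = measure_cycle(hep, state)
            rec_cycles.append(t)
            rec_body.append(rec["body"])
            rec_amounts.append(rec["amounts"])
            rec_exalt.append(rec["ex_alt"])
            rec_events.append({k: v.copy() for k, v in cum.items()})
        if trace_every and t % trace_every == 0:
            for kind, pool in state.mobile.items():
                nz = np.nonzero(pool)[0]
                for s in nz:
                    trace_rows.append((t, int(lattice.lobule_of_slot[s]), int(s), kind, int(pool[s])))
        if t % cfg.ledger_check_every == 0 or t == cfg.duration_cycles:
            ledger.check(state, hep, t)

    body = {
        kind: np.array([r[kind] for r in rec_body]) for kind in tr.MOBILE_KINDS + ("APAP_reservoir",)
    }
    amounts = {
        name: np.stack([r[name] for r in rec_amounts]) for name in AMOUNT_SERIES
    }
    events = {name: np.stack([r[name] for r in rec_events]) for name in EVENT_SERIES}
    band_sizes = {
        "PP": int((hep.band == BAND_PP).sum()),
        "MZ": int((hep.band == BAND_MZ).sum()),
        "PC": int((hep.band == BAND_PC).sum()),
    }
    log = MeasurementLog(
        cycles=np.array(rec_cycles),
        body=body,
        amounts=amounts,
        ex_alt=np.stack(rec_exalt),
        events=events,
        n_vhpc=hep.n,
        band_sizes=band_sizes,
    )
    return TrialResult(
        seed=trial_seed,
        transport_trace=trace_rows,
        log=log,
        t_gsh_depleted=hep.t_gsh_depleted,
        t_leak=hep.t_leak,
        t_necrosis=hep.t_necrosis,
        t_necrotic=hep.t_necrotic,
        vhpc_band=hep.band.copy(),
        vhpc_zone=hep.z.copy(),
        vhpc_lobule=hep.lobule.copy(),
        alt_released_per_vhpc=hep.alt_released(),
        marker_curve=body["Marker"],
    )


@dataclass
class VExperimentResult:
    """Aggregate of a set of Monte Carlo trials."""

    config_hash: str
    trial_seeds: list
    trials: list
    cycles: np.ndarray = field(init=False)
    body_alt_mean: np.ndarray = field(init=False)
    body_alt_sd: np.ndarray = field(init=False)
    body_alt_min: np.ndarray = field(init=False)
    body_alt_max: np.ndarray = field(init=False)

    def __post_init__(self):
        self.cycles = self.trials[0].log.cycles
        stack = np.stack([t.log.body["ALT"] for t in self.trials])
        self.body_alt_mean = stack.mean(axis=0)
        self.body_alt_sd = stack.std(axis=0, ddof=1) if len(self.trials) > 1 else np.zeros(stack.shape[1])
        self.body_alt_min = stack.min(axis=0)
        self.body_alt_max = stack.max(axis=0)

    def body_series(self, kind: str) -> dict:
        stack = np.stack([t.log.body[kind] for t in self.trials])
        return {
            "mean": stack.mean(axis=0),
            "sd": stack.std(axis=0, ddof=1) if len(self.trials) > 1 else np.zeros(stack.shape[1]),
            "min": stack.min(axis=0),
            "max": stack.max(axis=0),
        }

    def pooled_event_times(self, event: str, band: str | None = None) -> np.ndarray:
        """Event times (cycles) pooled across trials; band-restricted if given."""
        attr = {
            "gsh_depleted": "t_gsh_depleted",
            "leak_triggered": "t_leak",
            "necrosis_triggered": "t_necrosis",
            "necrotic": "t_necrotic",
        }[event]
        code = {"PP": BAND_PP, "MZ": BAND_MZ, "PC": BAND_PC}.get(band)
        out = []
        for trial in self.trials:
            times = getattr(trial, attr)
            mask = times >= 0
            if code is not None:
                mask &= trial.vhpc_band == code
            out.append(times[mask])
        return np.concatenate(out)

    def band_fraction_by(self, event: str, cycle: int, band: str) -> float:
        """Mean across trials of the fraction of band vHPCs with the event by ``cycle``."""
        attr = {
            "gsh_depleted": "t_gsh_depleted",
            "leak_triggered": "t_leak",
            "necrosis_triggered": "t_necrosis",
            "necrotic": "t_necrotic",
        }[event]
        code = {"PP": BAND_PP, "MZ": BAND_MZ, "PC": BAND_PC}[band]
        fracs = []
        for trial in self.trials:
            times = getattr(trial, attr)
            sel = trial.vhpc_band == code
            if sel.any():
                fracs.append(((times[sel] >= 0) & (times[sel] <= cycle)).mean())
        return float(np.mean(fracs))


def trial_seeds(cfg: VExperimentConfig) -> list[int]:
    return [cfg.master_seed + i for i in range(cfg.n_trials)]


def run_vexperiment(cfg: VExperimentConfig) -> VExperimentResult:
    """Run ``cfg.n_trials`` seeded trials and aggregate their measurements."""
    cfg.validate()
    seeds = trial_seeds(cfg)
    trials = [run_trial(cfg, s) for s in seeds]
    return VExperimentResult(config_hash=cfg.config_hash(), trial_seeds=seeds, trials=trials)
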