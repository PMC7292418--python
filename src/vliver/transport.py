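"""Compound movement through the lobule lattice.

The quasi-3D Sinusoid Segments are flattened to axial *slots* (one slot per
Core grid position per SS; the sampled circumference sets how many cell
positions a slot holds).  Mobile Compound objects are integer counts per
slot and per kind.  Each cycle a compound takes at most one step toward the
central vein with probability ``downstream_bias``; objects leaving the last
slot of a layer-3 SS enter the CV and are moved to Mouse Body the same
cycle.  Objects leaving the last slot of an upstream SS are split across
its downstream SSs.

Non-specific binding is represented by vEC binders (extracellular APAP)
and intracellular vHPC binders; bound objects are immobile for the cycle.
The Marker internal standard is extracellular-only, non-binding and
non-metabolised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DOSE_CAP_OBJECTS, FlowParams
from .errors import ConfigurationError
from .hepatocyte import HepatocyteArray
from .lobule import BAND_NONE, LobuleGraph, assign_bands

MOBILE_KINDS = ("APAP", "G", "S", "ALT", "Marker")
#: kinds that may cross cell membranes (Marker and extracellular pools only)
MEMBRANE_CROSSING = {"APAP": True, "G": True, "S": True, "ALT": True, "Marker": False}


@dataclass
class LiverLattice:
    """Static flattened geometry for one or more sampled lobules."""

    n_slots: int
    n_lobules: int
    lobule_of_slot: np.ndarray
    next_slot: np.ndarray  # within-SS successor, -1 at the SS outlet
    slot_band: np.ndarray
    slot_z: np.ndarray
    slot_has_ec: np.ndarray
    # SS outlet routing
    node_last_slot: np.ndarray  # (n_nodes,)
    node_lobule: np.ndarray
    node_terminal: np.ndarray  # bool: outlet drains to CV
    node_out_slots: list  # per node: array of downstream entry slots
    max_fanout: int
    # PV inflow
    entry_slots: list  # per lobule: entry slots of layer-1 SSs
    # vHPC placement (vHPCs sorted by slot)
    slot_of_vhpc: np.ndarray
    slot_vhpc_start: np.ndarray
    slot_vhpc_count: np.ndarray
    vhpc_z: np.ndarray
    vhpc_band: np.ndarray
    vhpc_lobule: np.ndarray
    vhpc_dpv: np.ndarray
    vhpc_dcv: np.ndarray

    @property
    def n_vhpc(self) -> int:
        return len(self.slot_of_vhpc)

    @classmethod
    def build(cls, graphs: list[LobuleGraph], band_config) -> "LiverLattice":
        slot_lobule, nxt, slot_band, slot_z, slot_ec = [], [], [], [], []
        node_last, node_lob, node_term, node_out = [], [], [], []
        entry_slots: list[list[int]] = []
        svhpc, vz, vband, vlob, vdpv, vdcv = [], [], [], [], [], []
        slot_base = 0
        node_base = 0
        for li, graph in enumerate(graphs):
            if not graph.dpv:
                raise ConfigurationError("graphs must have zonal positions computed")
            codes = assign_bands(graph, band_config)
            node_slot0 = {}
            entry = []
            vptr = 0
            for ss in graph.nodes:
                s0 = slot_base
                node_slot0[ss.node_id] = s0
                L = ss.core_length
                for j in range(L):
                    slot_lobule.append(li)
                    nxt.append(s0 + j + 1 if j < L - 1 else -1)
                    slot_ec.append(ss.ec_per_pos[j] > 0)
                    slot_z.append(graph.zone[ss.node_id][j])
                slot_base += L
                if ss.layer == 1:
                    entry.append(s0)
            # per-slot band = band of a vHPC at that axial position
            for ss in graph.nodes:
                dpv = graph.dpv[ss.node_id]
                dcv = graph.dcv[ss.node_id]
                b = np.full(ss.core_length, BAND_NONE, dtype=np.int8)
                bc = band_config
                b[(dpv >= bc.pp_dpv[0]) & (dpv <= bc.pp_dpv[1])] = 1
                b[(dpv >= bc.mz_dpv[0]) & (dpv <= bc.mz_dpv[1])] = 2
                b[(dcv >= bc.pc_dcv[0]) & (dcv <= bc.pc_dcv[1])] = 3
                slot_band.extend(b.tolist())
                # vHPC placement for this SS
                s0 = node_slot0[ss.node_id]
                for j in range(ss.core_length):
                    c = int(ss.vhpc_per_pos[j])
                    if c:
                        svhpc.extend([s0 + j] * c)
                        vz.extend([graph.zone[ss.node_id][j]] * c)
                        vdpv.extend([int(dpv[j])] * c)
                        vdcv.extend([int(dcv[j])] * c)
                n_in_ss = int(ss.vhpc_per_pos.sum())
                vband.extend(codes[vptr : vptr + n_in_ss].tolist())
                vlob.extend([li] * n_in_ss)
                vptr += n_in_ss
            for ss in graph.nodes:
                node_last.append(node_slot0[ss.node_id] + ss.core_length - 1)
                node_lob.append(li)
                node_term.append(ss.layer == 3)
                outs = [node_slot0[v] for u, v in graph.edges if u == ss.node_id]
                node_out.append(np.array(outs, dtype=np.int64))
            entry_slots.append(np.array(entry, dtype=np.int64))
            node_base += len(graph.nodes)

        slot_of_vhpc = np.array(svhpc, dtype=np.int64)
        n_slots = slot_base
        counts = np.bincount(slot_of_vhpc, minlength=n_slots).astype(np.int64)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        return cls(
            n_slots=n_slots,
            n_lobules=len(graphs),
            lobule_of_slot=np.array(slot_lobule, dtype=np.int64),
            next_slot=np.array(nxt, dtype=np.int64),
            slot_band=np.array(slot_band, dtype=np.int8),
            slot_z=np.array(slot_z, dtype=float),
            slot_has_ec=np.array(slot_ec, dtype=bool),
            node_last_slot=np.array(node_last, dtype=np.int64),
            node_lobule=np.array(node_lob, dtype=np.int64),
            node_terminal=np.array(node_term, dtype=bool),
            node_out_slots=node_out,
            max_fanout=max((len(o) for o in node_out), default=0),
            entry_slots=entry_slots,
            slot_of_vhpc=slot_of_vhpc,
            slot_vhpc_start=starts,
            slot_vhpc_count=counts,
            vhpc_z=np.array(vz, dtype=float),
            vhpc_band=np.array(vband, dtype=np.int64),
            vhpc_lobule=np.array(vlob, dtype=np.int64),
            vhpc_dpv=np.array(vdpv, dtype=np.int64),
            vhpc_dcv=np.array(vdcv, dtype=np.int64),
        )


@dataclass
class TransportState:
    """Mutable per-cycle compound pools."""

    lattice: LiverLattice
    mobile: dict = field(default_factory=dict)  # kind -> (n_slots,) counts
    ec_bound: np.ndarray | None = None  # APAP bound to vEC binders
    body_reservoir: dict = field(default_factory=dict)  # kind -> (n_lobules,) un-infused dose
    body: dict = field(default_factory=dict)  # kind -> (n_lobules,) returned/accumulated
    cv: dict = field(default_factory=dict)  # kind -> (n_lobules,) arrived this cycle
    initial_dose: int = 0

    @classmethod
    def create(cls, lattice: LiverLattice, dose_objects: int, marker_objects: int) -> "TransportState":
        if dose_objects > DOSE_CAP_OBJECTS:
            raise ConfigurationError(f"APAP doses are limited to {DOSE_CAP_OBJECTS} objects, got {dose_objects}")
        if dose_objects < 0 or marker_objects < 0:
            raise ConfigurationError("dose must be non-negative")
        nl = lattice.n_lobules
        st = cls(lattice=lattice, initial_dose=int(dose_objects))
        for kind in MOBILE_KINDS:
            st.mobile[kind] = np.zeros(lattice.n_slots, dtype=np.int64)
            st.body[kind] = np.zeros(nl, dtype=np.int64)
            st.cv[kind] = np.zeros(nl, dtype=np.int64)
            st.body_reservoir[kind] = np.zeros(nl, dtype=np.int64)
        st.ec_bound = np.zeros(lattice.n_slots, dtype=np.int64)
        # every lobule variant is a self-contained replicate of whole-liver
        # flow, so each receives the full dose
        st.body_reservoir["APAP"][:] = dose_objects
        st.body_reservoir["Marker"][:] = marker_objects
        return st

    def body_total(self, kind: str) -> np.ndarray:
        """Per-lobule Body amount (reservoir plus returned pool)."""
        return self.body_reservoir[kind] + self.body[kind]


def dose_step(state: TransportState, params: FlowParams, rng: np.random.Generator, kind: str = "APAP") -> int:
    """Transfer a binomially thinned fraction of Body ``kind`` to the PV.

    Objects entering the PV are spread across the entry slots of layer-1
    SSs.  Cumulative transfer can never exceed the administered dose.
    """
    lat = state.lattice
    reservoir = state.body_reservoir[kind]
    total = 0
    for li in range(lat.n_lobules):
        n = int(reservoir[li])
        if n == 0:
            continue
        moved = int(rng.binomial(n, params.dose_transfer_fraction))
        if moved == 0:
            continue
        reservoir[li] -= moved
        split = rng.multinomial(moved, np.full(len(lat.entry_slots[li]), 1.0 / len(lat.entry_slots[li])))
        np.add.at(state.mobile[kind], lat.entry_slots[li], split)
        total += moved
    return total


def percolate_step(
    state: TransportState,
    params: FlowParams,
    rng: np.random.Generator,
    kinds: tuple[str, ...] = ("APAP", "G", "S"),
) -> None:
    """Advance mobile compounds at most one grid step toward the CV.

    Per-kind counts are conserved: every object either holds, advances
    within its SS, moves to a downstream SS, or enters the CV pool.
    """
    lat = state.lattice
    internal = lat.next_slot >= 0
    for kind in kinds:
        pool = state.mobile[kind]
        if pool.sum() == 0:
            continue
        moving = rng.binomial(pool, params.downstream_bias)
        new = pool - moving
        # advance within SS (next_slot is injective on internal slots)
        new[lat.next_slot[internal]] += moving[internal]
        # SS outlets
        out = moving[lat.node_last_slot]
        term = lat.node_terminal
        if out[term].any():
            np.add.at(state.cv[kind], lat.node_lobule[term], out[term])
        rem = out.copy()
        rem[term] = 0
        active = np.nonzero(rem > 0)[0]
        for nd in active:  # few nodes have outgoing movers in any one cycle
            outs = lat.node_out_slots[nd]
            split = rng.multinomial(int(rem[nd]), np.full(len(outs), 1.0 / len(outs)))
            new[outs] += split
        state.mobile[kind] = new


def cell_exchange_step(
    state: TransportState,
    hep: HepatocyteArray,
    params: FlowParams,
    rng: np.random.Generator,
) -> None:
    """Mediate Compound entry to and exit from Cells, and binder events.

    Only membrane-crossing kinds enter vHPCs (APAP is the only extracellular
    kind taken up; G, S and ALT originate inside and only exit).  Necrotic
    vHPCs perform no exchange.  vEC binders bind and release extracellular
    APAP; vHPC binders bind and release intracellular APAP.  Bound objects
    are immobile for the cycle.
    """
    lat = state.lattice

    # vEC binders: extracellular APAP only
    apap = state.mobile["APAP"]
    slots = np.nonzero((apap > 0) & lat.slot_has_ec)[0]
    if len(slots):
        bound = rng.binomial(apap[slots], params.ec_bind_prob)
        apap[slots] -= bound
        state.ec_bound[slots] += bound
    slots = np.nonzero(state.ec_bound > 0)[0]
    if len(slots):
        rel = rng.binomial(state.ec_bound[slots], params.ec_release_prob)
        state.ec_bound[slots] -= rel
        apap[slots] += rel

    # entry: extracellular APAP into a random vHPC of its slot
    slots = np.nonzero((apap > 0) & (lat.slot_vhpc_count > 0))[0]
    if len(slots):
        entering = rng.binomial(apap[slots], params.p_enter_cell)
        nz = entering > 0
        if nz.any():
            src = np.repeat(slots[nz], entering[nz])
            target = lat.slot_vhpc_start[src] + rng.integers(0, lat.slot_vhpc_count[src])
            ok = ~hep.necrotic[target]  # necrotic cells refuse entry
            apap_taken = np.bincount(src[ok], minlength=lat.n_slots)
            apap -= apap_taken
            np.add.at(hep.apap_free, target[ok], 1)

    # vHPC binders (intracellular APAP)
    idx = np.nonzero((hep.apap_free > 0) & ~hep.necrotic)[0]
    if len(idx):
        b = rng.binomial(hep.apap_free[idx], params.vhpc_bind_prob)
        hep.apap_free[idx] -= b
        hep.apap_bound[idx] += b
    idx = np.nonzero((hep.apap_bound > 0) & ~hep.necrotic)[0]
    if len(idx):
        r = rng.binomial(hep.apap_bound[idx], params.vhpc_release_prob)
        hep.apap_bound[idx] -= r
        hep.apap_free[idx] += r

    # exit of free intracellular compounds back to the slot pool
    for kind, counts in (("APAP", hep.apap_free), ("G", hep.g), ("S", hep.s)):
        idx = np.nonzero((counts > 0) & ~hep.necrotic)[0]
        if len(idx):
            ex = rng.binomial(counts[idx], params.p_exit_cell)
            counts[idx] -= ex
            np.add.at(state.mobile[kind], hep.slot[idx], ex)


def cv_collect_step(state: TransportState) -> dict:
    """Move everything that reached the CV this cycle into Mouse Body."""
    arrived = {}
    for kind in MOBILE_KINDS:
        cv = state.cv[kind]
        if cv.any():
            state.body[kind] += cv
            arrived[kind] = int(cv.sum())
            cv[:] = 0
    return arrived
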