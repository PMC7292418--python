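"""Monte Carlo sampling of vLobule graphs and zonal position metrics.

A vLobule is a three-layer directed acyclic graph of Sinusoid Segments
(SSs).  Flow runs from the portal vein (PV) through layers 1..3 to the
central vein (CV).  Each SS is a quasi-3D cylinder collapsed here to a
1-D chain of axial Core grid positions; the sampled circumference sets how
many cell slots each axial position holds.  Virtual hepatocytes (vHPCs)
occupy 90% of hepatocyte slots by default.

Zonal position of a vHPC is summarised by two 1-based graph distances:

* ``dPV`` -- axial position plus the rounded mean core length of upstream
  layers, in Core grid points;
* ``dCV`` -- the symmetric distance from the central vein.

The normalised zonal coordinate ``z = dPV / (dPV + dCV)`` is the argument
of all periportal-to-pericentral gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import BandConfig, LobuleConfig
from .errors import ConfigurationError, StructuralError
from .rng import single_stream

BAND_NONE, BAND_PP, BAND_MZ, BAND_PC = 0, 1, 2, 3
BAND_LABELS = {BAND_NONE: "none", BAND_PP: "PP", BAND_MZ: "MZ", BAND_PC: "PC"}


@dataclass
class SinusoidSegment:
    """One sampled SS: a node of the lobule graph."""

    node_id: int
    layer: int  # 1..3
    core_length: int
    circumference: int
    vhpc_per_pos: np.ndarray  # (core_length,) occupied hepatocyte slots
    ec_per_pos: np.ndarray  # (core_length,) occupied endothelial slots

    @property
    def n_vhpc(self) -> int:
        return int(self.vhpc_per_pos.sum())


@dataclass
class LobuleGraph:
    """A sampled vLobule: SS nodes, directed PV->CV edges, zonal metrics."""

    nodes: list[SinusoidSegment]
    edges: list[tuple[int, int]]  # directed SS -> SS links (layer k -> k+1)
    layer_mean_core: np.ndarray  # (3,) realised mean core length per layer
    # populated by compute_zonal_positions()
    dpv: dict[int, np.ndarray] = field(default_factory=dict)  # node -> (L,) per axial position
    dcv: dict[int, np.ndarray] = field(default_factory=dict)
    zone: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_vhpc(self) -> int:
        return sum(ss.n_vhpc for ss in self.nodes)

    def out_neighbors(self, node_id: int) -> list[int]:
        return [v for u, v in self.edges if u == node_id]

    def vhpc_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-vHPC arrays ``(node_id, dpv, dcv, zone)`` in a fixed order.

        Requires zonal positions to be populated.
        """
        if not self.dpv:
            raise StructuralError("zonal positions not computed; call compute_zonal_positions first")
        nodes, dpvs, dcvs, zs = [], [], [], []
        for ss in self.nodes:
            counts = ss.vhpc_per_pos
            nodes.append(np.full(counts.sum(), ss.node_id, dtype=np.int32))
            dpvs.append(np.repeat(self.dpv[ss.node_id], counts))
            dcvs.append(np.repeat(self.dcv[ss.node_id], counts))
            zs.append(np.repeat(self.zone[ss.node_id], counts))
        return (
            np.concatenate(nodes),
            np.concatenate(dpvs),
            np.concatenate(dcvs),
            np.concatenate(zs),
        )

    def to_json(self) -> str:
        """Canonical JSON serialisation (byte-stable for a fixed seed)."""
        payload = {
            "nodes": [
                {
                    "id": ss.node_id,
                    "layer": ss.layer,
                    "core_length": ss.core_length,
                    "circumference": ss.circumference,
                    "vhpc_per_pos": ss.vhpc_per_pos.tolist(),
                    "ec_per_pos": ss.ec_per_pos.tolist(),
                    "dpv": self.dpv.get(ss.node_id, np.array([])).tolist(),
                    "dcv": self.dcv.get(ss.node_id, np.array([])).tolist(),
                }
                for ss in self.nodes
            ],
            "edges": sorted(self.edges),
            "layer_mean_core": self.layer_mean_core.tolist(),
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    def to_networkx(self):
        """Export to a networkx DiGraph (with PV/CV pseudo-nodes)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_node("PV")
        g.add_node("CV")
        for ss in self.nodes:
            g.add_node(ss.node_id, layer=ss.layer, core_length=ss.core_length, circumference=ss.circumference)
            if ss.layer == 1:
                g.add_edge("PV", ss.node_id)
            if ss.layer == 3:
                g.add_edge(ss.node_id, "CV")
        g.add_edges_from(self.edges)
        return g


def _sample_layer_nodes(rng: np.random.Generator, config: LobuleConfig) -> list[int]:
    counts = [int(rng.integers(lo, hi + 1)) for lo, hi in (ls.n_nodes for ls in config.layers)]
    # enforce the biomimetic layer-2 >= layer-3 ordering on the realised draw
    counts[2] = min(counts[2], counts[1])
    return counts


def sample_lobule_graph(config: LobuleConfig, seed: int | np.random.Generator) -> LobuleGraph:
    """Sample one vLobule graph; identical seeds give identical graphs.

    All SS dimensions are drawn fresh on every call.  The returned graph is
    acyclic by construction (edges only run layer ``k`` to ``k+1``) and every
    node is reachable from PV and reaches CV.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else single_stream(seed)

    layer_counts = _sample_layer_nodes(rng, config)
    nodes: list[SinusoidSegment] = []
    node_layers: list[list[int]] = [[], [], []]
    nid = 0
    for li, (n_nodes, spec) in enumerate(zip(layer_counts, config.layers)):
        for _ in range(n_nodes):
            L = int(rng.integers(spec.core_length[0], spec.core_length[1] + 1))
            C = int(rng.integers(spec.circumference[0], spec.circumference[1] + 1))
            n_occ = int(round(config.hepatocyte_occupancy * L * C))
            vhpc_per_pos = rng.multivariate_hypergeometric([C] * L, n_occ).astype(np.int32)
            n_ec = int(round(config.ec_occupancy * L * C))
            ec_per_pos = rng.multivariate_hypergeometric([C] * L, n_ec).astype(np.int32)
            nodes.append(SinusoidSegment(nid, li + 1, L, C, vhpc_per_pos, ec_per_pos))
            node_layers[li].append(nid)
            nid += 1

    # layer k -> k+1 edges: sampled fan-out, then patch uncovered targets
    edges: list[tuple[int, int]] = []
    flo, fhi = config.fanout
    for li in (0, 1):
        downstream = node_layers[li + 1]
        covered: set[int] = set()
        for u in node_layers[li]:
            f = int(rng.integers(flo, fhi + 1))
            targets = rng.choice(downstream, size=min(f, len(downstream)), replace=False)
            for v in targets:
                edges.append((u, int(v)))
                covered.add(int(v))
        for v in downstream:
            if v not in covered:
                u = int(rng.choice(node_layers[li]))
                edges.append((u, v))

    layer_mean_core = np.array(
        [np.mean([nodes[i].core_length for i in node_layers[li]]) for li in range(3)]
    )
    graph = LobuleGraph(nodes=nodes, edges=sorted(set(edges)), layer_mean_core=layer_mean_core)
    _check_structure(graph)
    return graph


def _check_structure(graph: LobuleGraph) -> None:
    by_layer: dict[int, int] = {}
    for ss in graph.nodes:
        by_layer[ss.layer] = by_layer.get(ss.layer, 0) + 1
    if by_layer.get(2, 0) < by_layer.get(3, 0):
        raise StructuralError("sampled graph has more layer-3 than layer-2 SSs")
    for u, v in graph.edges:
        if graph.nodes[v].layer != graph.nodes[u].layer + 1:
            raise StructuralError(f"edge {u}->{v} does not run to the next layer")
    has_out = {u for u, _ in graph.edges}
    has_in = {v for _, v in graph.edges}
    for ss in graph.nodes:
        if ss.layer < 3 and ss.node_id not in has_out:
            raise StructuralError(f"node {ss.node_id} (layer {ss.layer}) cannot reach CV")
        if ss.layer > 1 and ss.node_id not in has_in:
            raise StructuralError(f"node {ss.node_id} (layer {ss.layer}) unreachable from PV")


def compute_zonal_positions(graph: LobuleGraph) -> LobuleGraph:
    """Populate per-position dPV, dCV and the normalised zone in-place.

    dPV of an axial position ``j`` (1-based) in layer ``k`` is
    ``round(sum of mean core lengths of layers < k) + j``; dCV is the mirror
    image using downstream layers.  The two distance distributions are
    therefore computed independently, as upstream and downstream layer
    compositions differ.
    """
    mean = graph.layer_mean_core
    up_offset = {1: 0, 2: int(round(mean[0])), 3: int(round(mean[0] + mean[1]))}
    down_offset = {1: int(round(mean[1] + mean[2])), 2: int(round(mean[2])), 3: 0}
    for ss in graph.nodes:
        j = np.arange(1, ss.core_length + 1)
        dpv = up_offset[ss.layer] + j
        dcv = down_offset[ss.layer] + (ss.core_length - j + 1)
        graph.dpv[ss.node_id] = dpv.astype(np.int32)
        graph.dcv[ss.node_id] = dcv.astype(np.int32)
        graph.zone[ss.node_id] = dpv / (dpv + dcv)
    return graph


def assign_bands(graph: LobuleGraph, bands: BandConfig) -> np.ndarray:
    """Label every vHPC with a band code (``BAND_PP/MZ/PC/NONE``).

    Labels are deterministic given the graph and band configuration; a vHPC
    matching more than one band is a configuration error.
    """
    bands.validate()
    _, dpv, dcv, _ = graph.vhpc_table()
    pp = (dpv >= bands.pp_dpv[0]) & (dpv <= bands.pp_dpv[1])
    mz = (dpv >= bands.mz_dpv[0]) & (dpv <= bands.mz_dpv[1])
    pc = (dcv >= bands.pc_dcv[0]) & (dcv <= bands.pc_dcv[1])
    overlap = (pp.astype(int) + mz.astype(int) + pc.astype(int)) > 1
    if overlap.any():
        raise ConfigurationError("band ranges overlap on this graph (a vHPC matched two bands)")
    out = np.full(dpv.shape, BAND_NONE, dtype=np.int8)
    out[pp] = BAND_PP
    out[mz] = BAND_MZ
    out[pc] = BAND_PC
    return out


@dataclass
class StructureSummary:
    """Across-graph means of lobule structure statistics."""

    n_graphs: int
    mean_total_vhpc: float
    frac_dpv_1_14: float  # fraction of vHPCs at dPV positions 1..14
    frac_dcv_1_12: float  # fraction at dCV 1..12, excluding the dPV display set
    band_means: dict[str, float]
    dpv_position_means: dict[int, float]
    dcv_position_means: dict[int, float]

    @property
    def display_fraction(self) -> float:
        return self.frac_dpv_1_14 + self.frac_dcv_1_12

    def to_frame(self):
        import pandas as pd

        rows = [("dPV", p, m) for p, m in sorted(self.dpv_position_means.items())]
        rows += [("dCV", p, m) for p, m in sorted(self.dcv_position_means.items())]
        return pd.DataFrame(rows, columns=["axis", "position", "mean_count"])


def structure_summary(graphs: list[LobuleGraph], bands: BandConfig) -> StructureSummary:
    """Summarise mean vHPC counts per position and band over sampled graphs."""
    if not graphs:
        raise ConfigurationError("structure_summary requires at least one graph")
    totals, fr_dpv, fr_dcv = [], [], []
    band_counts = {"PP": [], "MZ": [], "PC": []}
    dpv_hist: dict[int, list] = {}
    dcv_hist: dict[int, list] = {}
    for graph in graphs:
        if not graph.dpv:
            compute_zonal_positions(graph)
        _, dpv, dcv, _ = graph.vhpc_table()
        total = len(dpv)
        totals.append(total)
        in_dpv_set = dpv <= 14
        in_dcv_set = (dcv <= 12) & ~in_dpv_set
        fr_dpv.append(in_dpv_set.mean())
        fr_dcv.append(in_dcv_set.mean())
        codes = assign_bands(graph, bands)
        for label, code in (("PP", BAND_PP), ("MZ", BAND_MZ), ("PC", BAND_PC)):
            band_counts[label].append(int((codes == code).sum()))
        for p in range(1, 15):
            dpv_hist.setdefault(p, []).append(int((dpv == p).sum()))
        for p in range(1, 13):
            dcv_hist.setdefault(p, []).append(int(((dcv == p) & ~in_dpv_set).sum()))
    return StructureSummary(
        n_graphs=len(graphs),
        mean_total_vhpc=float(np.mean(totals)),
        frac_dpv_1_14=float(np.mean(fr_dpv)),
        frac_dcv_1_12=float(np.mean(fr_dcv)),
        band_means={k: float(np.mean(v)) for k, v in band_counts.items()},
        dpv_position_means={p: float(np.mean(v)) for p, v in dpv_hist.items()},
        dcv_position_means={p: float(np.mean(v)) for p, v in dcv_hist.items()},
    )
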