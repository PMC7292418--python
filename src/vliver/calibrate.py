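"""Automated structural calibration (a stand-in for manual refinement cycles).

``calibrate`` searches a bounded space of structural configuration values
for the candidate minimising the weighted relative error against target
lobule statistics (mean vHPCs per lobule, position fractions, band counts).
The search is a seeded random scan; if the input configuration already
meets every target within its tolerance it is returned unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .config import VExperimentConfig
from .errors import ConfigurationError
from .lobule import compute_zonal_positions, sample_lobule_graph, structure_summary
from .rng import single_stream

#: measured-statistic extractors keyed by target name
_METRICS = {
    "mean_total_vhpc": lambda s: s.mean_total_vhpc,
    "frac_dpv_1_14_pct": lambda s: 100.0 * s.frac_dpv_1_14,
    "frac_dcv_1_12_pct": lambda s: 100.0 * s.frac_dcv_1_12,
    "band_pp": lambda s: s.band_means["PP"],
    "band_mz": lambda s: s.band_means["MZ"],
    "band_pc": lambda s: s.band_means["PC"],
}

DEFAULT_TARGETS = {
    "mean_total_vhpc": {"value": 16165.0, "weight": 1.0, "tol": 0.05},
    "frac_dpv_1_14_pct": {"value": 85.3, "weight": 1.0, "tol": 0.035},
    "frac_dcv_1_12_pct": {"value": 14.1, "weight": 1.0, "tol": 0.20},
    "band_pp": {"value": 4772.0, "weight": 1.0, "tol": 0.10},
    "band_mz": {"value": 1721.0, "weight": 1.0, "tol": 0.10},
    "band_pc": {"value": 906.0, "weight": 1.0, "tol": 0.10},
}


@dataclass
class CalibrationResult:
    config: VExperimentConfig
    residuals: dict
    score: float
    n_evaluated: int
    changed: bool
    search_log: list = field(default_factory=list)


def _get_path(cfg: VExperimentConfig, path: str):
    obj = cfg
    for part in path.split("."):
        if "[" in part:
            name, idx = part[:-1].split("[")
            obj = getattr(obj, name)[int(idx)]
        else:
            obj = getattr(obj, part)
    return obj


def _set_path(cfg: VExperimentConfig, path: str, value) -> None:
    parts = path.split(".")
    obj = cfg
    for part in parts[:-1]:
        if "[" in part:
            name, idx = part[:-1].split("[")
            obj = getattr(obj, name)[int(idx)]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    if "[" in last:
        name, idx = last[:-1].split("[")
        getattr(obj, name)[int(idx)] = value
    else:
        setattr(obj, last, value)


def _evaluate(cfg: VExperimentConfig, targets: dict, n_graphs: int, seed: int) -> tuple[dict, float]:
    rng = single_stream(seed, index=7)
    graphs = [compute_zonal_positions(sample_lobule_graph(cfg.lobule, rng)) for _ in range(n_graphs)]
    summary = structure_summary(graphs, cfg.bands)
    residuals = {}
    score = 0.0
    for name, spec in targets.items():
        measured = _METRICS[name](summary)
        rel = abs(measured - spec["value"]) / abs(spec["value"])
        residuals[name] = {"measured": measured, "target": spec["value"], "rel_error": rel}
        score += spec.get("weight", 1.0) * rel**2
    return residuals, score


def _within_tolerance(residuals: dict, targets: dict) -> bool:
    return all(residuals[name]["rel_error"] <= spec.get("tol", 0.05) for name, spec in targets.items())


def calibrate(
    base_config: VExperimentConfig,
    targets: dict | None = None,
    search_space: dict | None = None,
    n_candidates: int = 30,
    n_graphs: int = 20,
    seed: int = 0,
) -> CalibrationResult:
    """Search ``search_space`` for the structural config best matching ``targets``.

    ``search_space`` maps dotted attribute paths (e.g.
    ``"lobule.layers[0].circumference"``) to lists of candidate values.
    Candidates violating configuration invariants (for example the layer
    node-count ordering) are rejected during the search.  With no search
    space, the base configuration is simply evaluated.
    """
    targets = dict(targets or DEFAULT_TARGETS)
    unknown = set(targets) - set(_METRICS)
    if unknown:
        raise ConfigurationError(f"unknown calibration targets: {sorted(unknown)}")

    base_res, base_score = _evaluate(base_config, targets, n_graphs, seed)
    log = [{"candidate": "base", "score": base_score}]
    if _within_tolerance(base_res, targets) or not search_space:
        return CalibrationResult(base_config, base_res, base_score, 1, changed=False, search_log=log)

    rng = single_stream(seed, index=8)
    paths = sorted(search_space)
    combos = list(itertools.product(*(range(len(search_space[p])) for p in paths)))
    if len(combos) > n_candidates:
        pick = rng.choice(len(combos), size=n_candidates, replace=False)
        combos = [combos[i] for i in pick]

    best_cfg, best_res, best_score = base_config, base_res, base_score
    n_eval = 1
    for combo in combos:
        cand = base_config.copy()
        for path, ci in zip(paths, combo):
            _set_path(cand, path, search_space[path][ci])
        try:
            cand.validate()
        except ConfigurationError:
            log.append({"candidate": dict(zip(paths, combo)), "score": None, "rejected": True})
            continue
        res, score = _evaluate(cand, targets, n_graphs, seed)
        n_eval += 1
        log.append({"candidate": dict(zip(paths, combo)), "score": score})
        if score < best_score:
            best_cfg, best_res, best_score = cand, res, score
    return CalibrationResult(
        best_cfg, best_res, best_score, n_eval, changed=best_cfg is not base_config, search_log=log
    )
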