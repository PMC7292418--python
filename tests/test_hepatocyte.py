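"""Per-vHPC event kernels: metabolism, GSH/damage, mitigation, necrosis,
leakage and the release-mode truth table."""

import numpy as np
import pytest

from vliver.config import GradientSet, MechanismConfig
from vliver.hepatocyte import (
    HepatocyteArray,
    futile_cycle_step,
    leakage_step,
    metabolize_step,
    mitigation_step,
    napqi_removal_step,
    necrosis_step,
)


def make_cells(
    n=1,
    z=0.5,
    gsh=2.0,
    p_met=1.0,
    p_napqi=1.0,
    p_mit_mito=0.0,
    p_mit_non=0.0,
    p_mito_fraction=1.0,
    **mech_kwargs,
):
    grads = GradientSet(
        p_metabolism=[(0.0, p_met), (1.0, p_met)],
        p_napqi=[(0.0, p_napqi), (1.0, p_napqi)],
        gsh_threshold=[(0.0, gsh), (1.0, gsh)],
        p_mitigate_mitod=[(0.0, p_mit_mito), (1.0, p_mit_mito)],
        p_mitigate_nonmd=[(0.0, p_mit_non), (1.0, p_mit_non)],
        p_mito_fraction=p_mito_fraction,
    )
    grads.validate()
    fc = mech_kwargs.pop("futile_cycle", None)
    if isinstance(fc, dict):
        from vliver.config import FutileCycleConfig

        mech_kwargs["futile_cycle"] = FutileCycleConfig(**fc)
    mech = MechanismConfig(**mech_kwargs)
    mech.validate()
    h = HepatocyteArray.create(z=np.full(n, z), gradients=grads, mech=mech)
    return h, mech


def test_deterministic_metabolism_to_napqi(rng):
    h, _ = make_cells(p_met=1.0, p_napqi=1.0)
    h.apap_free[:] = 1
    metabolize_step(h, rng)
    assert h.napqi[0] == 1 and h.apap_free[0] == 0


def test_non_napqi_metabolites_split_equally(rng):
    h, _ = make_cells(n=2000, p_met=1.0, p_napqi=0.0)
    h.apap_free[:] = 10
    ev = metabolize_step(h, rng)
    assert ev["napqi"] == 0
    ratio = ev["g"] / ev["s"]
    assert 0.95 < ratio < 1.05
    assert ev["g"] + ev["s"] == 20000  # APAP conserved into exactly one product


def test_default_gradients_monotone(cfg_default):
    g = cfg_default.gradients
    assert g.evaluate("p_metabolism", 1.0) > g.evaluate("p_metabolism", 0.0)
    assert g.evaluate("p_napqi", 1.0) > g.evaluate("p_napqi", 0.0)
    assert g.evaluate("gsh_threshold", 1.0) < g.evaluate("gsh_threshold", 0.0)
    assert g.evaluate("p_mitigate_mitod", 0.0) > g.evaluate("p_mitigate_mitod", 1.0)
    assert g.evaluate("p_mitigate_nonmd", 1.0) > g.evaluate("p_mitigate_nonmd", 0.0)


def test_napqi_removal_depletes_gsh_before_damage(rng):
    h, mech = make_cells(gsh=2.0, napqi_removal_prob=1.0)
    h.napqi[:] = 1
    napqi_removal_step(h, mech, t=1, rng=rng)
    assert h.gsh[0] == 1.0 and h.mitod[0] == 0 and h.nonmd[0] == 0


def test_post_depletion_removal_creates_amplified_products(rng):
    h, mech = make_cells(n=4000, gsh=0.0, napqi_removal_prob=1.0, p_mito_fraction=1.0)
    h.gsh[:] = 0.0
    h.napqi[:] = 1
    ev = napqi_removal_step(h, mech, t=1, rng=rng)
    batch = h.mitod
    assert batch.min() >= 4 and batch.max() <= 7  # (n+1) with n ~ U{3..6}
    # all four sizes occur and are roughly uniform
    counts = np.bincount(batch, minlength=8)[4:8]
    assert (counts > 0).all()
    assert ev["mitod_created"] == batch.sum()


def test_removal_probability_is_half_per_cycle(rng):
    h, mech = make_cells(n=5000, gsh=0.0)
    h.gsh[:] = 0.0
    h.napqi[:] = 1
    napqi_removal_step(h, mech, t=1, rng=rng)
    removed_frac = (h.napqi == 0).mean()
    assert abs(removed_frac - 0.5) < 0.03


def test_fractional_gsh_counter_absorbs_partial_removal(rng):
    h, mech = make_cells(gsh=1.5, napqi_removal_prob=1.0)
    h.napqi[:] = 2
    napqi_removal_step(h, mech, t=1, rng=rng)
    # both removals consumed by the counter (1.5 -> 0), no damage yet
    assert h.gsh[0] == 0.0 and h.mitod[0] + h.nonmd[0] == 0
    assert h.t_gsh_depleted[0] == 1


def test_mitigation_removes_at_most_one_per_type_per_cycle(rng):
    h, _ = make_cells(p_mit_mito=1.0, p_mit_non=1.0)
    h.mitod[:] = 3
    h.nonmd[:] = 2
    mitigation_step(h, rng)
    assert h.mitod[0] == 2 and h.nonmd[0] == 1


def test_mitigation_probability_zero_is_noop(rng):
    h, _ = make_cells(p_mit_mito=0.0, p_mit_non=0.0)
    h.mitod[:] = 5
    for _ in range(10):
        mitigation_step(h, rng)
    assert h.mitod[0] == 5


def test_necrosis_trigger_is_strict_inequality(rng):
    h, mech = make_cells()
    h.mitod[:] = 4  # equal to the threshold: must NOT trigger
    necrosis_step(h, mech, t=1, rng=rng)
    assert not h.necrosis_triggered[0]
    h.mitod[:] = 5
    ev = necrosis_step(h, mech, t=2, rng=rng)
    assert h.necrosis_triggered[0] and len(ev["triggered_idx"]) == 1
    delay = h.necrotic_due[0] - 2
    assert 7200 <= delay < 21600


def test_necrotic_transition_externalizes_all_remaining_alt(rng):
    h, mech = make_cells(death_delay_cycles=(5, 6), leak_lag_cycles=(2, 4))
    h.mitod[:] = 9
    h.alt_counter[:] = 3
    necrosis_step(h, mech, t=1, rng=rng)
    due = int(h.necrotic_due[0])
    for t in range(2, due):
        necrosis_step(h, mech, t=t, rng=rng)
        assert not h.necrotic[0]
    ev = necrosis_step(h, mech, t=due, rng=rng)
    assert h.necrotic[0] and h.alt_counter[0] == 0
    assert list(ev["released"]) == [3]
    # absorbing: a necrotic vHPC never re-triggers or releases again
    ev2 = necrosis_step(h, mech, t=due + 1, rng=rng)
    assert len(ev2["necrotic_idx"]) == 0


@pytest.mark.parametrize(
    "mode,dual,mitod,nonmd,expected",
    [
        ("MITOD", "sum", 2, 0, True),
        ("MITOD", "sum", 0, 10, False),
        ("NONMD", "sum", 10, 0, False),
        ("NONMD", "sum", 0, 2, True),
        ("DUAL", "sum", 1, 1, True),
        ("DUAL", "both", 1, 1, False),
        ("DUAL", "both", 2, 2, True),
        ("NECROTIC_ONLY", "sum", 50, 50, False),
    ],
)
def test_leakage_trigger_truth_table(mode, dual, mitod, nonmd, expected, rng):
    h, mech = make_cells(release_mode=mode, dual_semantics=dual, leakage_threshold=1)
    h.mitod[:] = mitod
    h.nonmd[:] = nonmd
    ev = leakage_step(h, mech, t=1, rng=rng)
    assert bool(h.leak_triggered[0]) is expected
    assert (len(ev["new_triggered_idx"]) == 1) is expected


def test_leakage_schedules_one_release_per_cycle_and_decrements_counter(rng):
    h, mech = make_cells(release_mode="MITOD", leak_lag_cycles=(3, 4), death_delay_cycles=(4000, 4001))
    h.mitod[:] = 10
    for t in range(1, 3):
        leakage_step(h, mech, t=t, rng=rng)
    assert h.scheduled_ever[0] == 2  # one new schedule per cycle while triggered
    # all lags are exactly 3 cycles here, so releases fire at t+3
    released = 0
    for t in range(3, 12):
        ev = leakage_step(h, mech, t=t, rng=rng)
        released += int(ev["released"].sum())
    assert h.alt_counter[0] == 5 - released
    assert released == h.alt_released()[0]
    assert h.scheduled_ever[0] <= 5  # bounded by initial ALT


def test_leakage_trigger_clears_when_damage_mitigated(rng):
    h, mech = make_cells(release_mode="MITOD", leak_lag_cycles=(50, 51), death_delay_cycles=(400, 401))
    h.mitod[:] = 2
    leakage_step(h, mech, t=1, rng=rng)
    assert h.leak_triggered[0]
    h.mitod[:] = 0  # damage fell back below the threshold
    leakage_step(h, mech, t=2, rng=rng)
    assert not h.leak_triggered[0]
    assert h.pending_count[0] == 1  # the already-scheduled release persists
    fired = 0
    for t in range(3, 60):
        fired += int(leakage_step(h, mech, t=t, rng=rng)["released"].sum())
    assert fired == 1  # ... and still fires despite the cleared trigger


def test_scheduled_release_noop_after_necrosis(rng):
    """Releases scheduled before death fire as no-ops once the counter is 0."""
    h, mech = make_cells(release_mode="MITOD", leak_lag_cycles=(10, 11), death_delay_cycles=(12, 13))
    h.mitod[:] = 9
    necrosis_step(h, mech, t=1, rng=rng)
    leakage_step(h, mech, t=1, rng=rng)  # schedules a release for t=11
    due = int(h.necrotic_due[0])
    for t in range(2, due + 1):
        necrosis_step(h, mech, t=t, rng=rng)
    assert h.necrotic[0] and h.alt_counter[0] == 0
    total = sum(int(leakage_step(h, mech, t=t, rng=rng)["released"].sum()) for t in range(due + 1, due + 40))
    assert total == 0


def test_alt_identity_holds_under_mixed_releases(rng):
    """released + counter == initial ALT for every vHPC at all times."""
    h, mech = make_cells(n=300, gsh=0.0, release_mode="MITOD", leak_lag_cycles=(2, 30), death_delay_cycles=(40, 80))
    h.gsh[:] = 0.0
    h.napqi[:] = 6
    for t in range(1, 200):
        napqi_removal_step(h, mech, t=t, rng=rng)
        ev_n = necrosis_step(h, mech, t=t, rng=rng)
        ev_l = leakage_step(h, mech, t=t, rng=rng)
        assert np.all(h.alt_counter >= 0) and np.all(h.alt_counter <= 5)
    assert np.all(h.alt_released() + h.alt_counter == 5)


def test_degenerate_full_mitigation_prevents_necrosis(rng):
    """Mitigation prob 1 with damage influx <= 1 per cycle never triggers."""
    h, mech = make_cells(p_mit_mito=1.0, p_mit_non=1.0)
    for t in range(1, 500):
        h.mitod += 1  # damage influx of one product per cycle
        mitigation_step(h, rng)
        necrosis_step(h, mech, t=t, rng=rng)
    assert not h.necrosis_triggered[0]


def test_futile_cycle_disabled_and_conserving(rng):
    h, mech = make_cells()
    h.apap_free[:] = 2
    futile_cycle_step(h, mech, rng)
    assert h.apap_free[0] == 2 and h.pap[0] == 0  # disabled: no-op
    h2, mech2 = make_cells(futile_cycle={"enabled": True, "forward_prob": 1.0, "reverse_prob": 0.0})
    h2.apap_free[:] = 2
    futile_cycle_step(h2, mech2, rng)
    assert h2.apap_free[0] == 0 and h2.pap[0] == 2


def test_futile_cycle_zero_probs_noop(rng):
    h, mech = make_cells(futile_cycle={"enabled": True, "forward_prob": 0.0, "reverse_prob": 0.0})
    h.apap_free[:] = 3
    futile_cycle_step(h, mech, rng)
    assert h.apap_free[0] == 3 and h.pap[0] == 0
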