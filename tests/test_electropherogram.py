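"""Peak simulation, dropout model, decoding and concentration balancing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtplex.electropherogram import (DecodeConfigurationError, DropoutModel,
                                     Peak, PeakTable, decode_peaks,
                                     dropout_probability,
                                     rebalance_concentrations, simulate_peaks)
from mtplex.phylogeny import ANCESTRAL, CONFLICT, DERIVED, MISSING, profile_for

INF = float("inf")


# ---------------------------------------------------------------------------
# dropout model

def test_detection_probability_is_half_at_c50():
    model = DropoutModel(c50=2000.0, slope=4.0)
    assert dropout_probability(2000.0, model) == pytest.approx(0.5)


def test_detection_probability_saturates():
    model = DropoutModel()
    assert dropout_probability(1e12, model) > 0.999
    assert dropout_probability(INF, model) == 1.0
    assert dropout_probability(0.0, model) == 0.0


def test_detection_probability_near_complete_at_dilution_study_copies(panel):
    # ~28,000 copies/uL (the 1:100 dilution point) must give a near
    # complete profile: >0.95 per assay under the default model
    model = DropoutModel()
    for assay in panel:
        assert dropout_probability(28278.0, model, assay) > 0.95


def test_detection_probability_monotone_in_copies():
    model = DropoutModel()
    grid = [0, 10, 100, 1000, 2000, 10_000, 1e6, INF]
    probs = [dropout_probability(c, model) for c in grid]
    assert probs == sorted(probs)


def test_negative_copies_rejected():
    with pytest.raises(ValueError):
        dropout_probability(-1.0, DropoutModel())


# ---------------------------------------------------------------------------
# simulation

def test_noiseless_full_detection_hits_target_height(panel, tree):
    profile = profile_for("A2", tree, panel)
    table = simulate_peaks(profile, panel, copies=INF, noise_cv=0.0, seed=3)
    assert len(table.peaks) == 26
    assert all(p.height == panel.target_rfu for p in table.peaks)
    sizes = sorted(p.size for p in table.peaks)
    assert sizes[0] >= 32 and sizes[-1] <= 80


def test_simulated_peaks_decode_back_to_the_profile(panel, tree):
    profile = profile_for("C1d1", tree, panel)
    table = simulate_peaks(profile, panel, copies=INF, noise_cv=0.0, seed=3)
    assert decode_peaks(table, panel).profile.states == profile.states


def test_missing_states_emit_no_peak(panel, tree):
    profile = profile_for("M", tree, panel)
    profile.states[493] = MISSING
    table = simulate_peaks(profile, panel, copies=INF, noise_cv=0.0, seed=3)
    assert len(table.peaks) == 25


def test_conflict_state_emits_both_allele_peaks(panel, tree):
    profile = profile_for("M", tree, panel)
    profile.states[6755] = CONFLICT
    table = simulate_peaks(profile, panel, copies=INF, noise_cv=0.0, seed=3)
    at_52 = [p for p in table.peaks
             if p.size == 52 and p.dye in ("red", "yellow")]
    assert sorted(p.dye for p in at_52) == ["red", "yellow"]
    assert all(p.height == panel.target_rfu / 2 for p in at_52)
    assert decode_peaks(table, panel).profile.states[6755] == CONFLICT


def test_seed_is_mandatory_and_reproducible(panel, tree):
    profile = profile_for("B2", tree, panel)
    with pytest.raises(ValueError, match="seed"):
        simulate_peaks(profile, panel, copies=1000.0)
    t1 = simulate_peaks(profile, panel, copies=1000.0, seed=11)
    t2 = simulate_peaks(profile, panel, copies=1000.0, seed=11)
    assert t1.peaks == t2.peaks


def test_mean_peak_count_at_c50_matches_binomial_oracle(panel, tree):
    # at c50 each of the 26 assays is an independent p=0.5 detection, so
    # the count is Binomial(26, 0.5): mean 13, SE of the 1000-rep mean
    # sqrt(26*0.25/1000)
    model = DropoutModel()
    profile = profile_for("B2", tree, panel)
    counts = [
        len(simulate_peaks(profile, panel, copies=model.c50, model=model,
                           seed=s).peaks)
        for s in range(1000)
    ]
    se = math.sqrt(26 * 0.25 / 1000)
    assert abs(np.mean(counts) - 13.0) < 3 * se


# ---------------------------------------------------------------------------
# decoding

def test_decode_assigns_peak_to_size_dye_bin(panel):
    table = PeakTable("s", [Peak(dye="blue", size=80.2, height=2900.0)])
    profile = decode_peaks(table, panel).profile
    assert profile.states[12007] == ANCESTRAL  # G is the blue allele at 80 nt
    assert profile.states[493] == MISSING


def test_decode_discards_peaks_at_or_below_floor(panel):
    table = PeakTable("s", [Peak(dye="red", size=52.0, height=40.0)])
    assert decode_peaks(table, panel).profile.states[6755] == MISSING
    # the floor is strict: exactly 50 rfu is still insufficient
    table = PeakTable("s", [Peak(dye="red", size=52.0, height=50.0)])
    assert decode_peaks(table, panel).profile.states[6755] == MISSING
    table = PeakTable("s", [Peak(dye="red", size=52.0, height=50.5)])
    assert decode_peaks(table, panel).profile.states[6755] == DERIVED


def test_decode_both_alleles_is_conflict(panel):
    table = PeakTable("s", [Peak(dye="yellow", size=52.0, height=900.0),
                            Peak(dye="red", size=52.0, height=800.0)])
    assert decode_peaks(table, panel).profile.states[6755] == CONFLICT


def test_decode_reports_off_panel_peaks(panel):
    table = PeakTable("s", [Peak(dye="blue", size=46.0, height=900.0)])
    result = decode_peaks(table, panel)
    assert len(result.off_panel) == 1
    assert all(st == MISSING for st in result.profile.states.values())


def test_decode_ignores_size_standard(panel):
    table = PeakTable("s", [Peak(dye="orange", size=80.0, height=5000.0)])
    result = decode_peaks(table, panel)
    assert result.off_panel == []
    assert all(st == MISSING for st in result.profile.states.values())


def test_decode_same_bin_twice_keeps_higher_and_warns(panel):
    table = PeakTable("s", [Peak(dye="blue", size=79.8, height=700.0),
                            Peak(dye="blue", size=80.3, height=900.0)])
    result = decode_peaks(table, panel)
    assert result.profile.states[12007] == ANCESTRAL
    assert result.warnings


def test_decode_overlapping_tolerance_is_configuration_error(panel):
    table = PeakTable("s", [])
    with pytest.raises(DecodeConfigurationError):
        decode_peaks(table, panel, size_tolerance=2.0)


def test_raising_floor_never_creates_observations(panel, tree):
    profile = profile_for("B2b", tree, panel)
    table = simulate_peaks(profile, panel, copies=3000.0, noise_cv=0.6, seed=5)
    observed_prev = None
    for floor in (0.0, 50.0, 500.0, 2000.0, 10_000.0):
        profile_now = decode_peaks(table, panel, min_rfu=floor).profile
        observed = {s for s, st in profile_now.states.items() if st != MISSING}
        if observed_prev is not None:
            assert observed <= observed_prev
        observed_prev = observed


# ---------------------------------------------------------------------------
# balancing

def test_rebalance_fixed_point_and_inverse_rule():
    plan = rebalance_concentrations({1: 3000.0, 2: 6000.0}, {1: 0.025, 2: 0.030})
    by_site = {e.site_id: e for e in plan.entries}
    assert by_site[1].adjusted_conc == pytest.approx(0.025)
    assert by_site[1].pct_diff_from_target == pytest.approx(0.0)
    assert by_site[2].adjusted_conc == pytest.approx(0.015)
    assert by_site[2].pct_diff_from_target == pytest.approx(100.0)


def test_rebalance_doubles_failed_assay():
    plan = rebalance_concentrations({7: 0.0}, {7: 0.017})
    assert plan.entries[0].adjusted_conc == pytest.approx(0.034)


def test_rebalance_rejects_non_positive_concentration():
    with pytest.raises(ValueError):
        rebalance_concentrations({1: 100.0}, {1: 0.0})


@settings(derandomize=True, max_examples=50)
@given(
    obs=st.floats(min_value=0.0, max_value=50_000.0),
    conc=st.floats(min_value=1e-4, max_value=0.05),
)
def test_rebalance_output_always_within_bounds(obs, conc):
    plan = rebalance_concentrations({1: obs}, {1: conc}, floor=0.001, cap=0.1)
    adjusted = plan.entries[0].adjusted_conc
    assert 0.0 < adjusted <= 0.1
    if obs > 0:  # the doubling rule for failed assays is not floor-clamped
        assert adjusted >= 0.001


def test_iterated_rebalancing_converges_under_linear_response(panel):
    # expected height proportional to concentration, assay-specific gain
    rng = np.random.default_rng(0)
    gains = {a.site_id: float(rng.uniform(2e4, 4e5)) for a in panel}
    conc = {a.site_id: a.pcr_conc for a in panel}
    for iteration in range(5):
        observed = {s: gains[s] * conc[s] for s in conc}
        if all(abs(h - 3000.0) / 3000.0 <= 0.05 for h in observed.values()):
            break
        conc = rebalance_concentrations(observed, conc, floor=1e-6, cap=10.0).as_conc()
    observed = {s: gains[s] * conc[s] for s in conc}
    assert all(abs(h - 3000.0) / 3000.0 <= 0.05 for h in observed.values())
    assert iteration <= 4
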