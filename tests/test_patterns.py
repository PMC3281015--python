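"""Activity patterns across treatments and cross-panel conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtlact.model import ActivityPattern, QTLHit, bits_from_index, pattern_index
from qtlact.patterns import (
    cross_population_conservation,
    enumerate_patterns,
    lrs_across_conditions,
    make_activity_pattern,
    nearest_marker,
    summarize_patterns,
)
from qtlact.simulate import (
    PlantedEffect,
    make_marker_map,
    plant_traits,
    simulate_ri_genotypes,
)


def test_lxs_threshold_example_gives_bits_1100():
    pat = make_activity_pattern(np.array([30.0, 25.0, 10.0, 5.0]), threshold=24.0)
    assert pat is not None
    assert pat.bits == (1, 1, 0, 0)
    assert pat.index == 12


def test_threshold_is_strict_inequality():
    pat = make_activity_pattern(np.array([24.0, 30.0, 0.0, 0.0]), threshold=24.0)
    assert pat.bits == (0, 1, 0, 0)


def test_all_below_threshold_yields_no_pattern():
    assert make_activity_pattern(np.zeros(4), threshold=24.0) is None


@pytest.mark.parametrize("n,count", [(4, 15), (1, 1), (3, 7)])
def test_enumerate_patterns_counts(n, count):
    pats = enumerate_patterns(n)
    assert len(pats) == count
    assert len(set(pats)) == count
    assert all(any(b) for b in pats)


def test_enumerate_patterns_rejects_nonpositive():
    with pytest.raises(ValueError):
        enumerate_patterns(0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(bits=st.lists(st.integers(0, 1), min_size=1, max_size=8))
def test_pattern_index_bijective(bits):
    idx = pattern_index(bits)
    assert 0 <= idx < 2 ** len(bits)
    assert bits_from_index(idx, len(bits)) == tuple(bits)


def test_nearest_marker_and_tie_break():
    mm = pd.DataFrame(
        {
            "marker": ["a", "b"],
            "chromosome": ["1", "1"],
            "position_mb": [10.0, 20.0],
        }
    )
    assert nearest_marker("1", 14.0, mm) == "a"
    assert nearest_marker("1", 15.0, mm) == "a"  # tie -> lower position
    assert nearest_marker("1", 19.0, mm) == "b"
    with pytest.raises(KeyError):
        nearest_marker("7", 14.0, mm)


def _planted_panel(rng, panel_id="LXS", n_strains=24, pattern=(0, 1, 0, 0),
                   beta=4.0, sigma=1e-3, causal_position=None):
    mm = make_marker_map(12, {"1": 100.0, "2": 80.0}, rng, prefix=panel_id.lower())
    gm = simulate_ri_genotypes(mm, n_strains, 0.02, rng, panel_id=panel_id)
    if causal_position is None:
        # most balanced marker, so both genotype groups are well populated
        n_b = (gm.codes == 1).sum(axis=0)
        marker_row = int(np.argmin(np.abs(n_b - n_strains / 2)))
    else:
        chrom, pos = causal_position
        marker_row = int(
            gm.markers.index[gm.markers["marker"] == nearest_marker(
                chrom, pos, gm.markers
            )][0]
        )
    row = gm.markers.iloc[marker_row]
    eff = PlantedEffect(
        trait_id="T1", panel_id=panel_id, causal_marker_id=row["marker"],
        causal_chromosome=str(row["chromosome"]),
        causal_position_mb=float(row["position_mb"]),
        effect_sizes=tuple(beta * b for b in pattern),
        shared_across_panels=True,
    )
    ann = pd.DataFrame(
        {"kind": ["expression"], "gene_symbol": ["g"],
         "chromosome": [str(row["chromosome"])],
         "position_mb": [float(row["position_mb"])]},
        index=pd.Index(["T1"], name="trait"),
    )
    ts = plant_traits(gm, [eff], ann, sigma=sigma, rng=rng)
    return gm, ts, eff


def test_lrs_across_conditions_reflects_planted_pattern(rng):
    gm, ts, eff = _planted_panel(rng)
    vec = lrs_across_conditions("T1", eff.causal_marker_id, ts, gm)
    assert vec[1] > 100  # essentially noise-free perfect fit in EC
    assert max(vec[0], vec[2], vec[3]) < 10


def test_lrs_across_conditions_constant_trait_is_zero(rng):
    gm, ts, eff = _planted_panel(rng, "Q", pattern=(0, 0, 0, 0), sigma=1e-9)
    vec = lrs_across_conditions("T1", eff.causal_marker_id, ts, gm)
    assert (vec < 10).all()


def test_lrs_vector_invariant_to_strain_column_order(rng):
    gm, ts, eff = _planted_panel(rng, "R", sigma=0.5)
    base = lrs_across_conditions("T1", eff.causal_marker_id, ts, gm)
    shuffled = {
        c: df[list(np.random.default_rng(5).permutation(df.columns))]
        for c, df in ts.values.items()
    }
    ts2 = type(ts)(
        panel_id=ts.panel_id, conditions=ts.conditions, values=shuffled,
        annotations=ts.annotations,
    )
    np.testing.assert_allclose(
        base, lrs_across_conditions("T1", eff.causal_marker_id, ts2, gm)
    )


def test_unknown_trait_raises(rng):
    gm, ts, eff = _planted_panel(rng, "S")
    with pytest.raises(KeyError):
        lrs_across_conditions("nope", eff.causal_marker_id, ts, gm)


def _cross_setup(rng, shared=True):
    gm_a, ts_a, eff_a = _planted_panel(rng, "LXS")
    pattern = (0, 1, 0, 0) if shared else (0, 0, 0, 0)
    # shared causal locus: the BXD copy sits at the marker that
    # nearest-position matching from the LXS hit will select
    gm_b, ts_b, eff_b = _planted_panel(
        rng, "BXD", pattern=pattern,
        causal_position=(eff_a.causal_chromosome, eff_a.causal_position_mb),
    )
    vec = lrs_across_conditions("T1", eff_a.causal_marker_id, ts_a, gm_a)
    pat = make_activity_pattern(
        vec, 24.0, trait_id="T1", marker_id=eff_a.causal_marker_id,
        panel_id="LXS",
    )
    hit = QTLHit(
        trait_id="T1", marker_id=eff_a.causal_marker_id,
        chromosome=eff_a.causal_chromosome,
        position_mb=eff_a.causal_position_mb, lrs=float(np.nanmax(vec)),
        effect_sign=1, n_strains_used=gm_a.n_strains, significant=True,
        panel_id="LXS",
    )
    return hit, pat, ts_b, gm_b


def test_shared_noise_free_effect_is_conserved_with_identical_pattern(rng):
    hit, pat, ts_b, gm_b = _cross_setup(rng, shared=True)
    rec = cross_population_conservation(hit, pat, ts_b, gm_b, 26.0)
    assert rec.conserved_any is True
    assert rec.pattern_identical is True
    assert rec.bits == pat.bits


def test_private_effect_is_not_conserved(rng):
    hit, pat, ts_b, gm_b = _cross_setup(rng, shared=False)
    rec = cross_population_conservation(hit, pat, ts_b, gm_b, 26.0)
    assert rec.conserved_any is False


def test_conservation_threshold_monotone(rng):
    hit, pat, ts_b, gm_b = _cross_setup(rng, shared=True)
    # conserved flags never turn back on as the other panel's threshold rises
    flags = [
        cross_population_conservation(hit, pat, ts_b, gm_b, th).conserved_any
        for th in (5.0, 26.0, 100.0, 400.0)
    ]
    assert flags == sorted(flags, reverse=True)


def test_identical_mode_matches_nearest_on_shared_map(rng):
    gm, ts, eff = _planted_panel(rng, "LXS")
    vec = lrs_across_conditions("T1", eff.causal_marker_id, ts, gm)
    pat = make_activity_pattern(vec, 24.0, trait_id="T1",
                                marker_id=eff.causal_marker_id, panel_id="LXS")
    hit = QTLHit(
        trait_id="T1", marker_id=eff.causal_marker_id,
        chromosome=eff.causal_chromosome,
        position_mb=eff.causal_position_mb, lrs=float(np.nanmax(vec)),
        effect_sign=1, n_strains_used=gm.n_strains, panel_id="LXS",
    )
    a = cross_population_conservation(hit, pat, ts, gm, 24.0, mode="nearest")
    b = cross_population_conservation(hit, pat, ts, gm, 24.0, mode="identical")
    assert a.matched_marker == b.matched_marker == eff.causal_marker_id
    np.testing.assert_allclose(a.lrs_vector, b.lrs_vector)


def test_trait_absent_from_other_panel_gives_missing_record(rng):
    hit, pat, ts_b, gm_b = _cross_setup(rng)
    hit.trait_id = "unknown_trait"
    pat_alien = make_activity_pattern(
        np.array([30.0, 0, 0, 0]), 24.0, trait_id="unknown_trait",
        marker_id=hit.marker_id, panel_id="LXS",
    )
    rec = cross_population_conservation(hit, pat_alien, ts_b, gm_b, 26.0)
    assert rec.conserved_any is None
    assert rec.reason == "trait_absent"


def _pat(bits):
    lrs = np.array([30.0 if b else 0.0 for b in bits])
    return ActivityPattern(
        trait_id="t", marker_id="m", panel_id="p",
        conditions=("SC", "EC", "SR", "ER"), lrs_vector=lrs, threshold=24.0,
    )


def test_summarize_patterns_fractions_and_histogram():
    pats = [
        ("cis", _pat((1, 1, 1, 1))),
        ("cis", _pat((1, 1, 1, 1))),
        ("nonsyntenic_trans", _pat((0, 1, 0, 0))),
        ("nonsyntenic_trans", _pat((0, 0, 1, 0))),
        ("nonsyntenic_trans", _pat((1, 1, 0, 0))),
    ]
    summary = summarize_patterns(pats)
    assert summary.at["cis", "all_conditions_fraction"] == 1.0
    assert summary.at["cis", "treatment_specific_fraction"] == 0.0
    trans = summary.loc["nonsyntenic_trans"]
    assert trans["treatment_specific_fraction"] == pytest.approx(2 / 3)
    hist_cols = [c for c in summary.columns if c.startswith("pattern_")]
    assert len(hist_cols) == 15
    for cls in summary.index:
        assert summary.loc[cls, hist_cols].sum() == pytest.approx(1.0, abs=1e-12)


def test_summarize_patterns_empty_input_rejected():
    with pytest.raises(ValueError):
        summarize_patterns([])
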