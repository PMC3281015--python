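"""The synthetic RI study generator and its planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from qtlact.mapping import compute_lrs, lrs_scan, permutation_fdr
from qtlact.model import CODE_B
from qtlact.simulate import (
    PlantedEffect,
    SimulationConfig,
    count_breakpoints,
    make_marker_map,
    make_two_panel_study,
    plant_traits,
    scaled_config,
    simulate_ri_genotypes,
    step_sharing,
    transition_probability,
)


def two_marker_map(d_mb: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": ["a", "b"],
            "chromosome": ["1", "1"],
            "position_mb": [0.0, d_mb],
        }
    )


def test_transition_probability_limits_and_value():
    assert transition_probability(0.02, 0.0) == 0.0  # complete linkage
    assert transition_probability(0.02, 10.0) == pytest.approx(
        0.5 * (1 - np.exp(-0.4))
    )
    assert transition_probability(0.02, 1e9) == pytest.approx(0.5)


def test_adjacent_marker_discordance_matches_formula(rng):
    """Monte-Carlo cross-check: the fraction of strains discordant between
    two markers 10 Mb apart equals (1 - exp(-2 r d)) / 2."""
    gm = simulate_ri_genotypes(two_marker_map(10.0), 100_000, 0.02, rng)
    discordant = (gm.codes[:, 0] != gm.codes[:, 1]).mean()
    p = transition_probability(0.02, 10.0)
    se = np.sqrt(p * (1 - p) / 100_000)
    assert abs(discordant - p) < 4 * se
    assert p == pytest.approx(0.1648, abs=5e-4)


def test_marginal_allele_frequency_is_half(rng):
    mm = make_marker_map(25, {"1": 100.0, "2": 100.0}, rng)
    gm = simulate_ri_genotypes(mm, 2000, 0.02, rng)
    freq = (gm.codes == CODE_B).mean(axis=0)
    se = np.sqrt(0.25 / 2000)
    assert (np.abs(freq - 0.5) < 3.5 * se).all()


def test_breakpoint_count_scales_linearly_with_rate(rng):
    mm = make_marker_map(50, {"1": 150.0, "2": 150.0}, rng)
    gaps = []
    chroms = mm["chromosome"].to_numpy()
    pos = mm["position_mb"].to_numpy()
    for i in range(1, len(mm)):
        if chroms[i] == chroms[i - 1]:
            gaps.append(pos[i] - pos[i - 1])
    gaps = np.array(gaps)
    for rate in (0.01, 0.02, 0.04):
        expected = 500 * transition_probability(rate, gaps).sum()
        gm = simulate_ri_genotypes(mm, 500, rate, rng)
        observed = count_breakpoints(gm)
        assert observed == pytest.approx(expected, rel=0.10)


def test_generator_is_deterministic_for_fixed_seed():
    a = make_two_panel_study(scaled_config(seed=7))
    b = make_two_panel_study(scaled_config(seed=7))
    for panel in a.genotypes:
        np.testing.assert_array_equal(a.genotypes[panel].codes,
                                      b.genotypes[panel].codes)
        for cond in a.traits[panel].conditions:
            pd.testing.assert_frame_equal(
                a.traits[panel].values[cond], b.traits[panel].values[cond]
            )
    pd.testing.assert_frame_equal(a.snps.table, b.snps.table)
    pd.testing.assert_frame_equal(a.truth_table(), b.truth_table())


def test_empty_marker_map_rejected(rng):
    with pytest.raises(ValueError):
        simulate_ri_genotypes(two_marker_map(5.0).iloc[:0], 10, 0.02, rng)


def _single_effect_traits(gm, pattern, beta, sigma, rng, marker=None):
    marker = marker or gm.markers.at[2, "marker"]
    eff = PlantedEffect(
        trait_id="T1", panel_id=gm.panel_id, causal_marker_id=marker,
        causal_chromosome=str(gm.markers.at[2, "chromosome"]),
        causal_position_mb=float(gm.markers.at[2, "position_mb"]),
        effect_sizes=tuple(beta * b for b in pattern),
        shared_across_panels=False,
    )
    ann = pd.DataFrame(
        {"kind": ["expression"], "gene_symbol": ["g"], "chromosome": ["1"],
         "position_mb": [10.0]},
        index=pd.Index(["T1"], name="trait"),
    )
    return eff, plant_traits(gm, [eff], ann, sigma=sigma, rng=rng)


def test_noise_free_planted_effect_shifts_only_ec_means(rng):
    mm = make_marker_map(10, {"1": 100.0}, rng)
    gm = simulate_ri_genotypes(mm, 20, 0.02, rng)
    eff, ts = _single_effect_traits(gm, (0, 1, 0, 0), beta=1.0, sigma=1e-12, rng=rng)
    carrier = gm.marker_codes(eff.causal_marker_id) == CODE_B
    for cond in ts.conditions:
        vals = ts.values[cond].loc["T1"].to_numpy()
        diff = vals[carrier].mean() - vals[~carrier].mean()
        assert diff == pytest.approx(1.0 if cond == "EC" else 0.0, abs=1e-9)


def test_noise_free_effect_sign_recovered(rng):
    mm = make_marker_map(10, {"1": 100.0}, rng)
    gm = simulate_ri_genotypes(mm, 20, 0.02, rng)
    for beta in (2.0, -2.0):
        eff, ts = _single_effect_traits(gm, (1, 1, 1, 1), beta=beta,
                                        sigma=1e-12, rng=rng)
        codes = gm.marker_codes(eff.causal_marker_id)
        _, sign, _ = compute_lrs(ts.values["SC"].loc["T1"].to_numpy(), codes)
        assert sign == np.sign(beta)


def test_unknown_causal_marker_rejected(rng):
    mm = make_marker_map(10, {"1": 100.0}, rng)
    gm = simulate_ri_genotypes(mm, 20, 0.02, rng)
    eff = PlantedEffect(
        trait_id="T1", panel_id="p", causal_marker_id="nope",
        causal_chromosome="1", causal_position_mb=1.0,
        effect_sizes=(1, 0, 0, 0), shared_across_panels=False,
    )
    ann = pd.DataFrame(
        {"kind": ["expression"], "gene_symbol": [""], "chromosome": ["1"],
         "position_mb": [1.0]},
        index=pd.Index(["T1"], name="trait"),
    )
    with pytest.raises(KeyError):
        plant_traits(gm, [eff], ann, sigma=1.0, rng=rng)


def test_planted_ec_effect_detected_at_study_threshold():
    """beta = 2 sigma on 40 strains: the EC-condition LRS at the causal
    marker clears the panel's own permutation-calibrated 5% threshold in
    at least 95% of replicates."""
    rng = np.random.default_rng(31805)
    chrom_lengths = {str(c): 150.0 for c in range(1, 5)}
    mm = make_marker_map(60, chrom_lengths, rng)
    gm = simulate_ri_genotypes(mm, 40, 0.02, rng)
    null = pd.DataFrame(
        rng.standard_normal((30, 40)),
        index=[f"N{i}" for i in range(30)], columns=gm.strains,
    )
    fdr = permutation_fdr(null, gm, n_perm=300, seed=5, shared_permutation=False)
    theta = fdr.threshold_at_null_rate(0.05)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        j = int(rng.integers(gm.n_markers))
        codes = gm.codes[:, j]
        if min((codes == 0).sum(), (codes == 1).sum()) < 2:
            continue
        y = 2.0 * (codes == CODE_B) + rng.standard_normal(40)
        lrs, _, _ = compute_lrs(y, codes)
        hits += lrs > theta
    assert hits / n_rep >= 0.95


def test_null_study_genome_max_matches_permutation_null():
    """With no planted effects, observed genome-wide maxima are
    distributed like the permutation null (KS test)."""
    from scipy import stats

    rng = np.random.default_rng(404)
    mm = make_marker_map(50, {"1": 120.0, "2": 120.0}, rng)
    gm = simulate_ri_genotypes(mm, 30, 0.02, rng)
    traits = pd.DataFrame(
        rng.standard_normal((200, 30)),
        index=[f"T{i}" for i in range(200)], columns=gm.strains,
    )
    fdr = permutation_fdr(traits, gm, n_perm=200, seed=3,
                          shared_permutation=False)
    observed = np.nanmax(fdr.observed_chrom_max, axis=1)
    permuted = fdr.perm_genome_max[0]  # one full permuted study
    ks = stats.ks_2samp(observed, permuted)
    assert ks.pvalue > 0.01


@pytest.mark.parametrize("inside,expect_shared", [(1.0, True), (0.0, False)])
def test_sharing_function_extremes(inside, expect_shared):
    cfg = scaled_config(
        seed=11,
        sharing=step_sharing([], inside=0.0, outside=inside),
    )
    study = make_two_panel_study(cfg)
    expr = [e for e in study.effects if e.kind == "expression"]
    assert all(e.shared_across_panels == expect_shared for e in expr)
    if expect_shared:
        # every shared effect is planted in both panels with equal sizes
        by_trait = {}
        for e in expr:
            by_trait.setdefault(e.trait_id, []).append(e)
        for group in by_trait.values():
            assert len(group) == 2
            assert group[0].effect_sizes == group[1].effect_sizes
    if expect_shared:
        assert study.snps.table["conserved"].all()
    else:
        assert not study.snps.table["conserved"].any()


def test_intended_pattern_tracks_nonzero_effects():
    eff = PlantedEffect(
        trait_id="t", panel_id="p", causal_marker_id="m",
        causal_chromosome="1", causal_position_mb=0.0,
        effect_sizes=(0.0, 2.0, 0.0, -1.5), shared_across_panels=False,
    )
    assert eff.intended_pattern == (0, 1, 0, 1)


def test_unequal_group_sizes_are_subsets_of_panel():
    cfg = scaled_config(seed=3, unequal_groups=True)
    study = make_two_panel_study(cfg)
    for panel, ts in study.traits.items():
        strains = set(study.genotypes[panel].strains)
        sizes = set()
        for cond in ts.conditions:
            cols = list(ts.values[cond].columns)
            assert set(cols) <= strains
            sizes.add(len(cols))
        assert len(sizes) >= 1  # groups may genuinely differ in size


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(breakpoint_rate=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_expression_traits=5, n_cis=10)
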