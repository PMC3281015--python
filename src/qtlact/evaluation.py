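"""Ground-truth benchmarks of the pipeline on synthetic studies.

These routines run the full method — simulate, scan, call, pattern,
conserve — against the generator's planted truth and summarize how well
it is recovered: null calibration of the permutation thresholds, exact
activity-pattern recovery, the cis-versus-trans treatment-specificity
contrast, eQTL/SNP conservation-track correlation, and candidate-gene
selection in a constructed noise-free region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import classify_eqtl
from .conservation import (
    eqtl_feature_table,
    sliding_conservation_ratio,
    track_correlation,
)
from .mapping import permutation_fdr, scan_all_traits
from .model import ActivityPattern, QTLHit
from .patterns import (
    cross_population_conservation,
    lrs_across_conditions,
    make_activity_pattern,
    summarize_patterns,
)
from .simulate import (
    PlantedEffect,
    SimulationConfig,
    Study,
    make_marker_map,
    make_two_panel_study,
    plant_traits,
    simulate_ri_genotypes,
    step_sharing,
)

#: per-panel LRS thresholds used when benchmarking at the emulated study's
#: fixed significance levels
DEFAULT_THRESHOLDS: dict[int, float] = {0: 24.0, 1: 26.0}


def _panel_thresholds(config: SimulationConfig) -> dict[str, float]:
    return {p: DEFAULT_THRESHOLDS[i] for i, p in enumerate(config.panels)}


def null_calibration(
    seed: int,
    n_studies: int = 100,
    n_traits: int = 25,
    n_strains: int = 30,
    n_markers: int = 120,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> dict:
    """False-hit rate of the permutation-calibrated genome-wide threshold
    on pure-noise studies.

    Each study simulates an RI panel (four ~150 Mb chromosomes) and a
    trait matrix with no planted effects, derives the LRS threshold at
    which a null trait's genome-wide maximum exceeds it with probability
    ``alpha`` from ``n_perm`` shared strain-label permutations, and counts
    how many observed per-trait genome-wide maxima exceed it.  The pooled
    exceedance proportion estimates the realized false-hit rate.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {str(c): 150.0 for c in range(1, 5)}
    n_false = 0
    n_total = 0
    for _ in range(n_studies):
        mm = make_marker_map(n_markers, chrom_lengths, rng)
        gm = simulate_ri_genotypes(mm, n_strains, 0.02, rng)
        traits = pd.DataFrame(
            rng.standard_normal((n_traits, n_strains)),
            index=[f"T{i}" for i in range(n_traits)],
            columns=gm.strains,
        )
        # independent per-trait shuffles: equivalent under the independent
        # null and they pool to a smoother genome-wide max distribution
        fdr = permutation_fdr(
            traits, gm, n_perm=n_perm,
            seed=np.random.default_rng(rng.integers(2**31)),
            shared_permutation=False,
        )
        theta = fdr.threshold_at_null_rate(alpha)
        obs = fdr.observed_chrom_max
        with np.errstate(invalid="ignore"):
            genome_max = np.nanmax(obs, axis=1)
        n_false += int((genome_max > theta).sum())
        n_total += genome_max.size
    rate = n_false / n_total
    half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / n_total)
    return {
        "rate": rate,
        "n_false": n_false,
        "n_total": n_total,
        "alpha": alpha,
        "band": (alpha - half_width, alpha + half_width),
    }


def _significant_patterns(
    study: Study, panel: str, threshold: float
) -> list[tuple[QTLHit, ActivityPattern]]:
    """Union over treatments of significant (trait, marker) chromosome-max
    hits, each with its four-condition activity pattern."""
    gm = study.genotypes[panel]
    ts = study.traits[panel]
    expr = ts.traits_of_kind("expression")
    best: dict[tuple[str, str], QTLHit] = {}
    for cond in ts.conditions:
        table = ts.values[cond].loc[[t for t in expr if t in ts.values[cond].index]]
        for h in scan_all_traits(table, gm, threshold=threshold,
                                 panel_id=panel, condition=cond):
            if not h.significant:
                continue
            key = (h.trait_id, h.marker_id)
            if key not in best or h.lrs > best[key].lrs:
                best[key] = h
    pairs = []
    for (trait, marker), hit in sorted(best.items()):
        vec = lrs_across_conditions(trait, marker, ts, gm)
        pat = make_activity_pattern(
            vec, threshold, trait_id=trait, marker_id=marker,
            panel_id=panel, conditions=ts.conditions,
        )
        if pat is not None:
            hit.eqtl_class = classify_eqtl(
                hit,
                ts.annotations.at[trait, "chromosome"],
                ts.annotations.at[trait, "position_mb"],
            )
            pairs.append((hit, pat))
    return pairs


def recovery_config(seed: int) -> SimulationConfig:
    """Well-powered recovery conditions: 60 strains per panel, planted
    effects of 3 residual standard deviations."""
    return SimulationConfig(
        n_strains=(60, 60),
        n_markers=(300, 350),
        n_expression_traits=45,
        n_cis=15,
        n_syntenic_trans=6,
        n_nonsyntenic_trans=18,
        effect_sizes=(3.0,),
        n_snps=500,
        seed=seed,
    )


def pattern_recovery(
    seed: int,
    n_replicates: int = 50,
    config_factory=recovery_config,
) -> dict:
    """Exact activity-pattern recovery of planted eQTLs, plus the
    cis-versus-trans treatment-specificity contrast.

    Per replicate, every planted expression effect is looked up among the
    significant hits on its causal chromosome; a planted eQTL is
    recovered exactly when the hit's 4-bit pattern equals the intended
    one.  Patterns are also pooled by gene-marker class to compare the
    fraction of treatment-specific (single-condition) patterns between
    non-syntenic trans and cis eQTLs.
    """
    rng = np.random.default_rng(seed)
    n_exact = 0
    n_significant = 0
    pooled: list[tuple[str, ActivityPattern]] = []
    for _ in range(n_replicates):
        config = config_factory(int(rng.integers(2**31)))
        study = make_two_panel_study(config)
        thresholds = _panel_thresholds(config)
        for panel in config.panels:
            pairs = _significant_patterns(study, panel, thresholds[panel])
            pooled.extend((h.eqtl_class, p) for h, p in pairs)
            by_trait_chrom: dict[tuple[str, str], tuple[QTLHit, ActivityPattern]] = {}
            for h, p in pairs:
                key = (h.trait_id, h.chromosome)
                if key not in by_trait_chrom or h.lrs > by_trait_chrom[key][0].lrs:
                    by_trait_chrom[key] = (h, p)
            for eff in study.effects:
                if eff.kind != "expression" or eff.panel_id != panel:
                    continue
                key = (eff.trait_id, eff.causal_chromosome)
                if key not in by_trait_chrom:
                    continue
                n_significant += 1
                _, pat = by_trait_chrom[key]
                if pat.bits == eff.intended_pattern:
                    n_exact += 1
    summary = summarize_patterns(pooled)
    return {
        "exact_fraction": n_exact / n_significant if n_significant else float("nan"),
        "n_significant": n_significant,
        "n_exact": n_exact,
        "class_summary": summary,
        "trans_specific_fraction": float(
            summary.at["nonsyntenic_trans", "treatment_specific_fraction"]
        ) if "nonsyntenic_trans" in summary.index else float("nan"),
        "cis_specific_fraction": float(
            summary.at["cis", "treatment_specific_fraction"]
        ) if "cis" in summary.index else float("nan"),
        "cis_all_conditions_fraction": float(
            summary.at["cis", "all_conditions_fraction"]
        ) if "cis" in summary.index else float("nan"),
    }


def conservation_config(seed: int) -> SimulationConfig:
    """Step-function sharing: causal variants and SNPs shared between the
    panels on chromosome 1 and essentially private elsewhere."""
    chrom_lengths = {"1": 195.0, "2": 182.0, "3": 160.0, "4": 157.0}
    return SimulationConfig(
        n_strains=(31, 30),
        n_markers=(300, 350),
        chrom_lengths=chrom_lengths,
        n_expression_traits=45,
        n_cis=20,
        n_syntenic_trans=5,
        n_nonsyntenic_trans=20,
        effect_sizes=(3.0,),
        sharing=step_sharing([("1", 0.0, 195.0)], inside=0.95, outside=0.05),
        n_snps=2000,
        seed=seed,
    )


def conservation_replicates(
    seed: int,
    n_replicates: int = 50,
    window_mb: float = 50.0,
    step_mb: float = 25.0,
    config_factory=conservation_config,
) -> dict:
    """Correlation between eQTL- and SNP-conservation tracks under
    step-function sharing, across replicate studies.

    The eQTL track is anchored on the second panel's significant eQTLs,
    each flagged conserved when the first panel shows any significant
    treatment at its nearest marker.
    """
    rng = np.random.default_rng(seed)
    correlations = []
    for _ in range(n_replicates):
        config = config_factory(int(rng.integers(2**31)))
        study = make_two_panel_study(config)
        thresholds = _panel_thresholds(config)
        anchor = config.panels[1]
        other = config.panels[0]
        pairs = _significant_patterns(study, anchor, thresholds[anchor])
        records = [
            cross_population_conservation(
                hit, pat, study.traits[other], study.genotypes[other],
                thresholds[other],
            )
            for hit, pat in pairs
        ]
        feats = eqtl_feature_table([h for h, _ in pairs], records)
        if feats.empty:
            correlations.append(float("nan"))
            continue
        track_eqtl = sliding_conservation_ratio(
            feats, config.chrom_lengths, window_mb=window_mb, step_mb=step_mb
        )
        track_snp = sliding_conservation_ratio(
            study.snps.table, config.chrom_lengths,
            window_mb=window_mb, step_mb=step_mb,
        )
        correlations.append(track_correlation(track_eqtl, track_snp))
    arr = np.asarray(correlations)
    return {
        "correlations": arr,
        "n_positive": int(np.nansum(arr > 0)),
        "n_replicates": n_replicates,
        "mean_r": float(np.nanmean(arr)),
    }


# -- constructed candidate-selection region --------------------------------

#: designed genes in the candidate region: (suffix, pattern, shared)
#: the first six satisfy all three selection criteria (silent in SC,
#: active in EC, private to the focal panel); the last six each violate
#: exactly one criterion
CANDIDATE_PLAN: tuple[tuple[str, tuple[int, int, int, int], bool], ...] = (
    ("match1", (0, 1, 0, 0), False),
    ("match2", (0, 1, 1, 0), False),
    ("match3", (0, 1, 0, 1), False),
    ("match4", (0, 1, 1, 1), False),
    ("match5", (0, 1, 0, 0), False),
    ("match6", (0, 1, 1, 0), False),
    ("viol_sc1", (1, 1, 0, 0), False),  # active in the SC control
    ("viol_sc2", (1, 1, 1, 1), False),
    ("viol_ec1", (0, 0, 1, 0), False),  # not active after ethanol alone
    ("viol_ec2", (0, 0, 0, 1), False),
    ("viol_cons1", (0, 1, 0, 0), True),  # conserved in the other panel
    ("viol_cons2", (0, 1, 1, 0), True),
)


def candidate_region_study(
    seed: int = 0,
    beta: float = 6.0,
    sigma: float = 1e-6,
) -> dict:
    """Noise-free constructed region: six genes matching the behavioral
    activity pattern and six violating exactly one criterion each.

    Returns the selected gene list alongside the expected one; with
    ``sigma`` effectively zero the selection should recover exactly the
    six matching genes.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {"3": 160.0}
    panels = {}
    for panel, n_strains, n_markers in (("LXS", 40, 160), ("BXD", 40, 180)):
        mm = make_marker_map(n_markers, chrom_lengths, rng, prefix=panel.lower())
        panels[panel] = simulate_ri_genotypes(mm, n_strains, 0.02, rng,
                                              panel_id=panel)
    focal, other = "LXS", "BXD"
    region = (126.0, 142.0)
    gm = panels[focal]
    in_region = gm.markers[
        (gm.markers["position_mb"] >= region[0])
        & (gm.markers["position_mb"] <= region[1])
    ]
    if len(in_region) < len(CANDIDATE_PLAN):
        # genes may share a causal locus; recycle region markers if sparse
        reps = -(-len(CANDIDATE_PLAN) // len(in_region))
        in_region = pd.concat([in_region] * reps, ignore_index=True)
    effects: dict[str, list[PlantedEffect]] = {focal: [], other: []}
    rows = []
    for k, (suffix, pattern, shared) in enumerate(CANDIDATE_PLAN):
        trait = f"TRc_{suffix}"
        row = in_region.iloc[k]
        sizes = tuple(beta * b for b in pattern)
        effects[focal].append(
            PlantedEffect(
                trait_id=trait, panel_id=focal,
                causal_marker_id=row["marker"],
                causal_chromosome=row["chromosome"],
                causal_position_mb=float(row["position_mb"]),
                effect_sizes=sizes, shared_across_panels=shared,
                eqtl_class="cis", gene_symbol=suffix,
                gene_chromosome=row["chromosome"],
                gene_position_mb=float(row["position_mb"]),
            )
        )
        if shared:
            from .patterns import nearest_marker

            om = nearest_marker(
                row["chromosome"], float(row["position_mb"]),
                panels[other].markers,
            )
            orow = panels[other].markers.set_index("marker").loc[om]
            effects[other].append(
                PlantedEffect(
                    trait_id=trait, panel_id=other, causal_marker_id=om,
                    causal_chromosome=str(orow["chromosome"]),
                    causal_position_mb=float(orow["position_mb"]),
                    effect_sizes=sizes, shared_across_panels=True,
                    eqtl_class="cis",
                )
            )
        rows.append(
            {
                "trait": trait, "kind": "expression", "gene_symbol": suffix,
                "chromosome": row["chromosome"],
                "position_mb": float(row["position_mb"]),
            }
        )
    annotations = pd.DataFrame(rows).set_index("trait")
    thresholds = {focal: 24.0, other: 26.0}
    trait_sets = {}
    for panel in (focal, other):
        trait_sets[panel] = plant_traits(
            panels[panel], effects[panel], annotations, sigma=sigma, rng=rng
        )
    pairs = []
    for eff in effects[focal]:
        vec = lrs_across_conditions(
            eff.trait_id, eff.causal_marker_id, trait_sets[focal], panels[focal]
        )
        pat = make_activity_pattern(
            vec, thresholds[focal], trait_id=eff.trait_id,
            marker_id=eff.causal_marker_id, panel_id=focal,
        )
        assert pat is not None
        hit = QTLHit(
            trait_id=eff.trait_id, marker_id=eff.causal_marker_id,
            chromosome=eff.causal_chromosome,
            position_mb=eff.causal_position_mb,
            lrs=float(np.nanmax(vec)), effect_sign=1,
            n_strains_used=panels[focal].n_strains, significant=True,
            eqtl_class="cis", panel_id=focal,
        )
        rec = cross_population_conservation(
            hit, pat, trait_sets[other], panels[other], thresholds[other]
        )
        pairs.append((pat, rec))
    from .network import select_candidates

    selected = select_candidates(pairs)
    expected = sorted(
        f"TRc_{suffix}" for suffix, pattern, shared in CANDIDATE_PLAN
        if pattern[0] == 0 and pattern[1] == 1 and not shared
    )
    return {
        "selected": selected,
        "expected": expected,
        "pairs": pairs,
        "panels": {p: (panels[p], trait_sets[p]) for p in panels},
    }
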