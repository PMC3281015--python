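"""Synthetic two-panel, four-treatment RI study with planted ground truth.

The generator emulates the structure of a hippocampal eQTL study in two
mouse recombinant inbred families (an LXS-like and a BXD-like panel):

* RI genotypes are two-state Markov chains along each chromosome.  The
  first marker is A or B with probability 1/2 and the transition
  probability between adjacent markers d Mb apart is
  p = (1 - exp(-2 r d)) / 2 with breakpoint rate r per Mb, so linkage
  decays with distance and strains are independent.
* Expression traits are strain means: a per-trait baseline plus additive
  B-allele effects at a planted causal marker whose size varies by
  treatment according to a designed 4-bit activity pattern, plus
  independent Gaussian residual noise per strain x condition.
* Causal variants are shared between panels with a probability that
  depends on genome position (conserved patches), and a genotyped SNP
  panel carries conservation flags drawn from the same sharing function,
  so eQTL- and SNP-conservation tracks are positively related by
  construction.
* Behavioral traits carry planted treatment-specific QTLs (by default
  ethanol-only loci private to one panel, mirroring zero-maze activity
  and open-quadrant phenotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CODE_A,
    CODE_B,
    DEFAULT_CONDITIONS,
    ConditionedTraitSet,
    GenotypeMatrix,
    SNPPanel,
    validate_marker_map,
)
from .patterns import nearest_marker

log = logging.getLogger(__name__)

#: approximate mouse chromosome lengths in Mb
MOUSE_CHROM_LENGTHS_MB: dict[str, float] = {
    "1": 195.0, "2": 182.0, "3": 160.0, "4": 157.0, "5": 152.0,
    "6": 150.0, "7": 145.0, "8": 129.0, "9": 124.0, "10": 131.0,
    "11": 122.0, "12": 120.0, "13": 120.0, "14": 125.0, "15": 104.0,
    "16": 98.0, "17": 95.0, "18": 91.0, "19": 61.0, "X": 169.0,
}

SharingFn = Callable[[str, float], float]


def step_sharing(
    patches: Sequence[tuple[str, float, float]],
    inside: float = 1.0,
    outside: float = 0.0,
) -> SharingFn:
    """Position-dependent sharing probability: ``inside`` within any patch
    (chromosome, start, end), ``outside`` elsewhere."""
    patches = [(str(c), float(a), float(b)) for c, a, b in patches]

    def fn(chromosome: str, position_mb: float) -> float:
        for c, a, b in patches:
            if str(chromosome) == c and a <= position_mb <= b:
                return inside
        return outside

    return fn


#: default conserved patches (distal chr 3 and 4, proximal chr 12) with a
#: low background sharing level elsewhere
DEFAULT_SHARING: SharingFn = step_sharing(
    [("3", 110.0, 160.0), ("4", 120.0, 157.0), ("12", 0.0, 40.0)],
    inside=0.9,
    outside=0.15,
)


@dataclass
class PlantedEffect:
    """Ground truth for one planted QTL.

    ``effect_sizes`` is the additive shift of B-allele strains under each
    condition (trait units); the intended activity pattern has a 1
    exactly where the effect size is nonzero.
    """

    trait_id: str
    panel_id: str
    causal_marker_id: str
    causal_chromosome: str
    causal_position_mb: float
    effect_sizes: tuple[float, float, float, float]
    shared_across_panels: bool
    kind: str = "expression"  # or "behavioral"
    eqtl_class: str | None = None  # designed gene-marker geometry
    gene_symbol: str | None = None
    gene_chromosome: str | None = None
    gene_position_mb: float | None = None

    @property
    def intended_pattern(self) -> tuple[int, ...]:
        return tuple(int(b != 0.0) for b in self.effect_sizes)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated study: two RI panels with 31 and 30
    strains genotyped at 2659 and 3796 markers across the 19 mouse
    autosomes plus X, four treatment conditions, and causal variants
    shared between panels inside designated conserved patches.
    """

    panels: tuple[str, str] = ("LXS", "BXD")
    n_strains: tuple[int, int] = (31, 30)
    n_markers: tuple[int, int] = (2659, 3796)
    chrom_lengths: Mapping[str, float] = field(
        default_factory=lambda: dict(MOUSE_CHROM_LENGTHS_MB)
    )
    breakpoint_rate: float = 0.02  # per Mb
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_expression_traits: int = 200
    n_cis: int = 40
    n_syntenic_trans: int = 15
    n_nonsyntenic_trans: int = 45
    effect_sizes: tuple[float, ...] = (2.0, 3.0)  # multiples of sigma
    sigma: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    sharing: SharingFn = DEFAULT_SHARING
    n_snps: int = 78881
    unequal_groups: bool = False
    behavioral_effect_size: float = 1.5  # multiples of sigma
    seed: int = 0
    # fraction of planted effects that are single-condition, per class;
    # the remainder are active in all four conditions
    treatment_specific_fraction: Mapping[str, float] = field(
        default_factory=lambda: {
            "cis": 0.3,
            "syntenic_trans": 0.5,
            "nonsyntenic_trans": 0.85,
        }
    )

    def __post_init__(self) -> None:
        counts = (
            self.n_expression_traits, self.n_cis, self.n_syntenic_trans,
            self.n_nonsyntenic_trans, self.n_snps, *self.n_strains,
            *self.n_markers,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.breakpoint_rate <= 0:
            raise ValueError("breakpoint rate must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        n_planted = self.n_cis + self.n_syntenic_trans + self.n_nonsyntenic_trans
        if n_planted > self.n_expression_traits:
            raise ValueError("more planted effects than expression traits")


def transition_probability(rate_per_mb: float, distance_mb) -> np.ndarray:
    """Markov transition probability between adjacent markers.

    p = (1 - exp(-2 r d)) / 2, which is 0 at d = 0 (complete linkage) and
    saturates at 1/2 (free recombination) for distant markers.
    """
    d = np.asarray(distance_mb, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * rate_per_mb * d))


def make_marker_map(
    n_markers: int,
    chrom_lengths: Mapping[str, float],
    rng: np.random.Generator,
    prefix: str = "m",
) -> pd.DataFrame:
    """Random marker map: markers allotted to chromosomes proportionally to
    length, positions uniform, ids stable under the sorted order."""
    if n_markers <= 0:
        raise ValueError("need at least one marker")
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    counts = rng.multinomial(n_markers, weights)
    # every chromosome gets at least one marker when possible
    for i in np.flatnonzero(counts == 0):
        if counts.max() > 1:
            counts[np.argmax(counts)] -= 1
            counts[i] += 1
    rows = []
    for ch, k, length in zip(chroms, counts, lengths):
        pos = np.sort(rng.uniform(0.0, length, size=int(k)))
        for p in pos:
            rows.append({"chromosome": str(ch), "position_mb": float(p)})
    mm = pd.DataFrame(rows)
    mm["marker"] = [f"{prefix}_{i:05d}" for i in range(len(mm))]
    mm = validate_marker_map(mm)
    # rename in sorted order so ids are stable and informative
    mm["marker"] = [
        f"{prefix}_{r.chromosome}_{i:04d}" for i, r in enumerate(mm.itertuples())
    ]
    return validate_marker_map(mm)


def simulate_ri_genotypes(
    marker_map: pd.DataFrame,
    n_strains: int,
    breakpoint_rate: float,
    rng: np.random.Generator,
    panel_id: str = "panel",
    strain_prefix: str | None = None,
) -> GenotypeMatrix:
    """Simulate homozygous RI genotypes as per-chromosome Markov chains.

    Each strain's chromosome starts A or B with probability 1/2;
    adjacent markers d Mb apart flip with probability
    (1 - exp(-2 r d)) / 2.  Strains and chromosomes are independent.
    """
    mm = validate_marker_map(marker_map)
    if mm.empty:
        raise ValueError("empty marker map")
    if n_strains <= 0:
        raise ValueError("need at least one strain")
    codes = np.empty((n_strains, len(mm)), dtype=np.int8)
    chroms = mm["chromosome"].to_numpy()
    positions = mm["position_mb"].to_numpy()
    start = 0
    for j in range(1, len(mm) + 1):
        if j < len(mm) and chroms[j] == chroms[start]:
            continue
        pos = positions[start:j]
        p_flip = transition_probability(breakpoint_rate, np.diff(pos))
        block = np.empty((n_strains, j - start), dtype=np.int8)
        block[:, 0] = rng.random(n_strains) < 0.5
        if p_flip.size:
            flips = rng.random((n_strains, p_flip.size)) < p_flip[None, :]
            block[:, 1:] = block[:, [0]] ^ (np.cumsum(flips, axis=1) % 2).astype(np.int8)
        codes[:, start:j] = np.where(block, CODE_B, CODE_A)
        start = j
    prefix = strain_prefix or panel_id
    strains = [f"{prefix}-{i + 1:03d}" for i in range(n_strains)]
    return GenotypeMatrix(
        panel_id=panel_id, strains=strains, markers=mm, codes=codes
    )


def count_breakpoints(gmatrix: GenotypeMatrix) -> int:
    """Total allele switches between adjacent markers, summed over strains
    and chromosomes (missing codes are not expected here)."""
    total = 0
    chroms = gmatrix.markers["chromosome"].to_numpy()
    start = 0
    for j in range(1, gmatrix.n_markers + 1):
        if j < gmatrix.n_markers and chroms[j] == chroms[start]:
            continue
        block = gmatrix.codes[:, start:j]
        total += int((np.diff(block, axis=1) != 0).sum())
        start = j
    return total


def plant_traits(
    gmatrix: GenotypeMatrix,
    effects: Sequence[PlantedEffect],
    annotations: pd.DataFrame,
    sigma: float,
    rng: np.random.Generator,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    strain_subsets: Mapping[str, Sequence[str]] | None = None,
) -> ConditionedTraitSet:
    """Strain-mean trait matrices with planted additive allele effects.

    Trait value of strain s under condition c:
    baseline(trait) + sum over that trait's effects of
    effect_size_c * I[s carries B at the causal marker] + N(0, sigma),
    noise independent per strain x condition.  ``annotations`` lists every
    trait (planted and null); ``strain_subsets`` optionally restricts the
    strain columns per condition (unequal treatment-group sizes).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    traits = list(annotations.index)
    trait_pos = {t: i for i, t in enumerate(traits)}
    for eff in effects:
        if eff.trait_id not in trait_pos:
            raise KeyError(f"effect refers to unknown trait {eff.trait_id!r}")
        gmatrix.marker_column(eff.causal_marker_id)  # raises on unknown marker

    baselines = baseline_mean + baseline_sd * rng.standard_normal(len(traits))
    genetic = {
        c: np.zeros((len(traits), gmatrix.n_strains)) for c in conditions
    }
    for eff in effects:
        carrier = (gmatrix.marker_codes(eff.causal_marker_id) == CODE_B).astype(float)
        t = trait_pos[eff.trait_id]
        for k, c in enumerate(conditions):
            genetic[c][t] += eff.effect_sizes[k] * carrier

    values: dict[str, pd.DataFrame] = {}
    for c in conditions:
        noise = sigma * rng.standard_normal((len(traits), gmatrix.n_strains))
        mat = baselines[:, None] + genetic[c] + noise
        df = pd.DataFrame(mat, index=traits, columns=gmatrix.strains)
        if strain_subsets is not None and c in strain_subsets:
            df = df[list(strain_subsets[c])]
        values[c] = df
    return ConditionedTraitSet(
        panel_id=gmatrix.panel_id,
        conditions=conditions,
        values=values,
        annotations=annotations,
    )


@dataclass
class Study:
    """A complete synthetic two-panel study with ground truth."""

    config: SimulationConfig
    genotypes: dict[str, GenotypeMatrix]
    traits: dict[str, ConditionedTraitSet]
    snps: SNPPanel
    effects: list[PlantedEffect]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for e in self.effects:
            rows.append(
                {
                    "trait": e.trait_id,
                    "panel": e.panel_id,
                    "kind": e.kind,
                    "eqtl_class": e.eqtl_class or "",
                    "causal_marker": e.causal_marker_id,
                    "causal_chromosome": e.causal_chromosome,
                    "causal_position_mb": e.causal_position_mb,
                    "gene_symbol": e.gene_symbol or "",
                    "gene_chromosome": e.gene_chromosome or "",
                    "gene_position_mb": e.gene_position_mb,
                    "pattern": "".join(map(str, e.intended_pattern)),
                    "effect_sizes": ",".join(f"{b if b else 0.0:g}" for b in e.effect_sizes),
                    "shared": e.shared_across_panels,
                }
            )
        return pd.DataFrame(rows)


def _draw_genome_position(
    rng: np.random.Generator, chrom_lengths: Mapping[str, float]
) -> tuple[str, float]:
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms])
    ch = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
    return str(ch), float(rng.uniform(0.0, chrom_lengths[ch]))


def _draw_pattern(
    rng: np.random.Generator, single_fraction: float, n_conditions: int
) -> tuple[int, ...]:
    """Either a single-condition pattern (uniform over conditions) or the
    all-conditions pattern."""
    if rng.random() < single_fraction:
        k = int(rng.integers(n_conditions))
        return tuple(int(i == k) for i in range(n_conditions))
    return tuple(1 for _ in range(n_conditions))


#: default planted behavioral QTLs: (trait, panel index, chromosome,
#: position Mb, activity pattern) — ethanol-only loci on chr 3 and 14 in
#: the first panel, an ethanol-only proximal chr 1 locus plus a
#: non-ethanol distal chr 1 locus in the second panel
DEFAULT_BEHAVIORAL_PLAN: tuple[tuple[str, int, str, float, tuple[int, ...]], ...] = (
    ("ACTCNT", 0, "3", 136.0, (0, 1, 0, 0)),
    ("OPEN", 0, "14", 9.0, (0, 1, 0, 0)),
    ("ACTCNT", 1, "1", 25.0, (0, 1, 0, 0)),
    ("ACTCNT", 1, "1", 160.0, (1, 0, 1, 1)),
)


def design_effects(
    config: SimulationConfig,
    genotypes: Mapping[str, GenotypeMatrix],
    rng: np.random.Generator,
) -> tuple[list[PlantedEffect], dict[str, pd.DataFrame]]:
    """Choose causal markers, gene locations, activity patterns and
    cross-panel sharing for all planted effects; build per-panel trait
    annotations (planted + null expression traits + behavioral traits)."""
    panels = list(config.panels)
    n_cond = len(config.conditions)
    class_plan = (
        ["cis"] * config.n_cis
        + ["syntenic_trans"] * config.n_syntenic_trans
        + ["nonsyntenic_trans"] * config.n_nonsyntenic_trans
    )
    effects: list[PlantedEffect] = []
    gene_rows: list[dict] = []
    n_planted = len(class_plan)

    for idx, cls in enumerate(class_plan):
        trait_id = f"TR{idx + 1:05d}"
        gene = f"Gene{idx + 1:05d}"
        # the causal variant sits at a genotyped marker of the anchor panel
        anchor = panels[int(rng.integers(len(panels)))]
        anchor_row = genotypes[anchor].markers.iloc[
            int(rng.integers(genotypes[anchor].n_markers))
        ]
        chrom = str(anchor_row["chromosome"])
        pos = float(anchor_row["position_mb"])
        share_p = config.sharing(chrom, pos)
        shared = bool(rng.random() < share_p)
        carriers = panels if shared else [anchor]
        pattern = _draw_pattern(
            rng, config.treatment_specific_fraction[cls], n_cond
        )
        beta = float(rng.choice(config.effect_sizes)) * config.sigma
        if rng.random() < 0.5:
            beta = -beta
        # gene location by designed geometry relative to the causal variant
        if cls == "cis":
            gene_chrom = chrom
            gene_pos = float(
                np.clip(pos + rng.uniform(-2.0, 2.0), 0.0,
                        config.chrom_lengths[chrom])
            )
        elif cls == "syntenic_trans":
            gene_chrom = chrom
            length = config.chrom_lengths[chrom]
            for _ in range(100):
                gene_pos = float(rng.uniform(0.0, length))
                if abs(gene_pos - pos) > 12.0:
                    break
        else:
            others = [c for c in config.chrom_lengths if str(c) != chrom]
            gene_chrom = str(others[int(rng.integers(len(others)))])
            gene_pos = float(rng.uniform(0.0, config.chrom_lengths[gene_chrom]))
        gene_rows.append(
            {
                "trait": trait_id,
                "kind": "expression",
                "gene_symbol": gene,
                "chromosome": gene_chrom,
                "position_mb": gene_pos,
            }
        )
        for panel in carriers:
            marker = nearest_marker(chrom, pos, genotypes[panel].markers)
            row = genotypes[panel].markers.set_index("marker").loc[marker]
            effects.append(
                PlantedEffect(
                    trait_id=trait_id,
                    panel_id=panel,
                    causal_marker_id=marker,
                    causal_chromosome=chrom,
                    causal_position_mb=float(row["position_mb"]),
                    effect_sizes=tuple(beta * b for b in pattern),
                    shared_across_panels=shared,
                    kind="expression",
                    eqtl_class=cls,
                    gene_symbol=gene,
                    gene_chromosome=gene_chrom,
                    gene_position_mb=gene_pos,
                )
            )

    # null expression traits with random gene annotations
    for idx in range(n_planted, config.n_expression_traits):
        trait_id = f"TR{idx + 1:05d}"
        chrom, pos = _draw_genome_position(rng, config.chrom_lengths)
        gene_rows.append(
            {
                "trait": trait_id,
                "kind": "expression",
                "gene_symbol": f"Gene{idx + 1:05d}",
                "chromosome": chrom,
                "position_mb": pos,
            }
        )

    behavioral_rows = []
    for trait_id, panel_idx, chrom, pos, pattern in DEFAULT_BEHAVIORAL_PLAN:
        if panel_idx >= len(panels) or str(chrom) not in config.chrom_lengths:
            continue
        panel = panels[panel_idx]
        marker = nearest_marker(chrom, pos, genotypes[panel].markers)
        row = genotypes[panel].markers.set_index("marker").loc[marker]
        beta = config.behavioral_effect_size * config.sigma
        effects.append(
            PlantedEffect(
                trait_id=trait_id,
                panel_id=panel,
                causal_marker_id=marker,
                causal_chromosome=str(chrom),
                causal_position_mb=float(row["position_mb"]),
                effect_sizes=tuple(beta * b for b in pattern),
                shared_across_panels=False,
                kind="behavioral",
            )
        )
        behavioral_rows.append(trait_id)
    for trait_id in dict.fromkeys(t for t, *_ in DEFAULT_BEHAVIORAL_PLAN):
        gene_rows.append(
            {
                "trait": trait_id,
                "kind": "behavioral",
                "gene_symbol": "",
                "chromosome": None,
                "position_mb": np.nan,
            }
        )

    annotations = (
        pd.DataFrame(gene_rows)
        .set_index("trait")[["kind", "gene_symbol", "chromosome", "position_mb"]]
    )
    return effects, {panel: annotations.copy() for panel in panels}


def make_two_panel_study(config: SimulationConfig) -> Study:
    """Generate the full synthetic study: genotypes, traits, SNP panel and
    planted ground truth, deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genotypes: dict[str, GenotypeMatrix] = {}
    for panel, n_strains, n_markers in zip(
        config.panels, config.n_strains, config.n_markers
    ):
        mm = make_marker_map(
            n_markers, config.chrom_lengths, rng, prefix=panel.lower()
        )
        genotypes[panel] = simulate_ri_genotypes(
            mm, n_strains, config.breakpoint_rate, rng, panel_id=panel
        )

    effects, annotations = design_effects(config, genotypes, rng)

    traits: dict[str, ConditionedTraitSet] = {}
    for panel in config.panels:
        gm = genotypes[panel]
        panel_effects = [e for e in effects if e.panel_id == panel]
        subsets = None
        if config.unequal_groups:
            subsets = {}
            for c in config.conditions:
                n_keep = int(rng.integers(max(gm.n_strains - 4, 3), gm.n_strains + 1))
                keep = sorted(
                    rng.choice(gm.n_strains, size=n_keep, replace=False)
                )
                subsets[c] = [gm.strains[i] for i in keep]
        traits[panel] = plant_traits(
            gm,
            panel_effects,
            annotations[panel],
            sigma=config.sigma,
            rng=rng,
            conditions=config.conditions,
            baseline_mean=config.baseline_mean,
            baseline_sd=config.baseline_sd,
            strain_subsets=subsets,
        )

    snp_rows = []
    for _ in range(config.n_snps):
        chrom, pos = _draw_genome_position(rng, config.chrom_lengths)
        conserved = bool(rng.random() < config.sharing(chrom, pos))
        snp_rows.append(
            {"chromosome": chrom, "position_mb": pos, "conserved": conserved}
        )
    snps = SNPPanel(pd.DataFrame(snp_rows))
    return Study(
        config=config, genotypes=genotypes, traits=traits, snps=snps,
        effects=effects,
    )


def scaled_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A desk-scale configuration: full study structure, reduced marker,
    trait and SNP counts so simulations finish quickly."""
    defaults = dict(
        n_strains=(31, 30),
        n_markers=(400, 500),
        n_expression_traits=80,
        n_cis=16,
        n_syntenic_trans=6,
        n_nonsyntenic_trans=18,
        n_snps=4000,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
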