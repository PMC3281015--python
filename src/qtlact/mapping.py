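"""Single-marker likelihood-ratio mapping on RI strain means.

For a biallelic homozygous marker the genetic model is a two-group
Gaussian mean shift.  With N strains used, RSS0 the residual sum of
squares about the grand mean and RSS1 about the two genotype-group
means, the likelihood ratio statistic is

    LRS = N * ln(RSS0 / RSS1) = -N * ln(1 - r^2),

where r is the Pearson correlation between the trait and the {0,1}-coded
genotype, and LOD = LRS / (2 ln 10).  Transcriptome-wide significance is
calibrated by permuting strain labels: one shared shuffle per iteration
is applied to every trait, preserving trait-trait correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import CODE_A, CODE_B, GenotypeMatrix, QTLHit, chrom_sort_key

log = logging.getLogger(__name__)

#: LRS assigned to a perfect within-group fit (RSS1 = 0), flagged as capped
DEFAULT_LRS_CAP: float = 300.0

# reason codes for skipped markers
REASON_GROUP_TOO_SMALL = "group_too_small"
REASON_OK = ""


class UninformativeMarkerError(ValueError):
    """A genotype group has fewer than two usable strains."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


def lrs_scan(
    traits: np.ndarray,
    codes: np.ndarray,
    cap: float = DEFAULT_LRS_CAP,
    min_per_group: int = 2,
) -> dict[str, np.ndarray]:
    """Vectorized LRS of every trait against every marker.

    Parameters
    ----------
    traits
        (n_traits, n_strains) float array; NaN marks a missing strain mean.
    codes
        (n_strains, n_markers) int8 genotype codes.

    Returns a dict of (n_traits, n_markers) arrays: ``lrs`` (NaN where a
    trait-marker pair is unusable), ``sign``, ``n_used``, ``capped`` and
    ``valid``.  Strains missing either the trait or the genotype are
    dropped pairwise per trait-marker combination.
    """
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    g1 = (codes == CODE_B).astype(float)
    g0 = (codes == CODE_A).astype(float)
    called = g0 + g1  # S x M
    observed = np.isfinite(traits)
    x = np.where(observed, traits, 0.0)
    vf = observed.astype(float)

    n = vf @ called
    n1 = vf @ g1
    n0 = n - n1
    s = x @ called
    s1 = x @ g1
    s0 = s - s1
    q = (x * x) @ called

    valid = (n1 >= min_per_group) & (n0 >= min_per_group)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = q - s * s / n
        rss1 = q - s1 * s1 / np.maximum(n1, 1) - s0 * s0 / np.maximum(n0, 1)
        mean_diff = s1 / np.maximum(n1, 1) - s0 / np.maximum(n0, 1)
    rss0 = np.clip(rss0, 0.0, None)
    rss1 = np.clip(rss1, 0.0, None)

    # numerical floor: treat RSS below ~machine precision of the sum of
    # squares as an exact fit
    floor = 1e-12 * np.maximum(q, 1.0)
    perfect = rss1 <= floor
    flat = rss0 <= floor  # constant trait among used strains

    lrs = np.full(n.shape, np.nan)
    ok = valid & ~flat & ~perfect
    with np.errstate(divide="ignore", invalid="ignore"):
        lrs[ok] = n[ok] * np.log(rss0[ok] / rss1[ok])
    lrs[valid & flat] = 0.0
    capped = valid & perfect & ~flat
    lrs[capped] = cap
    lrs[valid] = np.minimum(lrs[valid], cap)
    sign = np.where(valid, np.sign(mean_diff), 0.0).astype(np.int8)
    return {
        "lrs": lrs,
        "sign": sign,
        "n_used": n.astype(int),
        "capped": capped,
        "valid": valid,
    }


def compute_lrs(
    trait_values: Sequence[float] | np.ndarray,
    genotype_codes: Sequence[int] | np.ndarray,
    cap: float = DEFAULT_LRS_CAP,
) -> tuple[float, int, int]:
    """LRS of one trait at one marker.

    Returns ``(lrs, effect_sign, n_used)`` where the sign is that of
    mean(B-allele strains) - mean(A-allele strains).  Raises
    :class:`UninformativeMarkerError` when either genotype group retains
    fewer than two strains after pairwise missing-data removal.
    """
    trait = np.asarray(trait_values, dtype=float)
    codes = np.asarray(genotype_codes)
    if trait.shape != codes.shape:
        raise ValueError("trait and genotype vectors differ in length")
    res = lrs_scan(trait[None, :], codes[:, None].astype(np.int8), cap=cap)
    if not res["valid"][0, 0]:
        raise UninformativeMarkerError(
            REASON_GROUP_TOO_SMALL,
            "fewer than two usable strains in a genotype group",
        )
    return float(res["lrs"][0, 0]), int(res["sign"][0, 0]), int(res["n_used"][0, 0])


def align_traits_to_panel(
    traits: pd.DataFrame, gmatrix: GenotypeMatrix
) -> tuple[np.ndarray, list[str]]:
    """Reorder a traits x strains DataFrame onto the panel's strain order.

    Strains absent from the trait table contribute NaN columns (they are
    dropped pairwise downstream); trait strains unknown to the panel are
    ignored.  Raises when the intersection is empty.
    """
    shared = [s for s in gmatrix.strains if s in traits.columns]
    if not shared:
        raise ValueError(
            f"no strain overlap between trait table and panel {gmatrix.panel_id}"
        )
    aligned = np.full((traits.shape[0], gmatrix.n_strains), np.nan)
    col_of = {s: i for i, s in enumerate(gmatrix.strains)}
    for s in shared:
        aligned[:, col_of[s]] = traits[s].to_numpy(dtype=float)
    return aligned, list(traits.index)


def genome_scan(
    trait_values: pd.Series,
    gmatrix: GenotypeMatrix,
    cap: float = DEFAULT_LRS_CAP,
) -> pd.DataFrame:
    """Per-marker LRS profile of one trait across the whole panel.

    ``trait_values`` is indexed by strain id.  Returns one row per marker
    with columns marker, chromosome, position_mb, lrs, effect_sign,
    n_used, capped, reason; markers skipped for small group sizes carry
    NaN LRS and a reason code.
    """
    table = pd.DataFrame([trait_values])
    aligned, _ = align_traits_to_panel(table, gmatrix)
    res = lrs_scan(aligned, gmatrix.codes, cap=cap)
    out = gmatrix.markers.copy()
    out["lrs"] = res["lrs"][0]
    out["effect_sign"] = res["sign"][0]
    out["n_used"] = res["n_used"][0]
    out["capped"] = res["capped"][0]
    out["reason"] = np.where(res["valid"][0], REASON_OK, REASON_GROUP_TOO_SMALL)
    return out


def chromosome_max_qtls(
    profile: pd.DataFrame,
    trait_id: str,
    threshold: float | None = None,
    panel_id: str | None = None,
    condition: str | None = None,
) -> list[QTLHit]:
    """One QTL per chromosome: the marker with the maximum LRS.

    Ties are broken toward the smallest genomic position (profiles are
    position-sorted, so the first maximum wins).  Chromosomes whose
    markers were all skipped yield no hit and are logged.  When
    ``threshold`` is given the ``significant`` flag is set by strict
    inequality (LRS > threshold).
    """
    if profile.empty:
        raise ValueError("empty LRS profile")
    hits: list[QTLHit] = []
    chroms = sorted(profile["chromosome"].unique(), key=chrom_sort_key)
    for ch in chroms:
        sub = profile[(profile["chromosome"] == ch) & profile["lrs"].notna()]
        if sub.empty:
            log.info("trait %s: chromosome %s has no informative marker", trait_id, ch)
            continue
        row = sub.loc[sub["lrs"].idxmax()]  # idxmax -> first (lowest-position) max
        hits.append(
            QTLHit(
                trait_id=trait_id,
                marker_id=row["marker"],
                chromosome=str(ch),
                position_mb=float(row["position_mb"]),
                lrs=float(row["lrs"]),
                effect_sign=int(row["effect_sign"]),
                n_strains_used=int(row["n_used"]),
                significant=bool(threshold is not None and row["lrs"] > threshold),
                capped=bool(row["capped"]),
                panel_id=panel_id,
                condition=condition,
            )
        )
    return hits


def _chromosome_max_matrix(
    lrs: np.ndarray, chrom_slices: list[tuple[str, slice]]
) -> np.ndarray:
    """(n_traits, n_chromosomes) matrix of per-chromosome maxima (NaN-aware)."""
    cols = []
    with np.errstate(invalid="ignore"):
        for _, sl in chrom_slices:
            block = lrs[:, sl]
            allnan = np.all(np.isnan(block), axis=1)
            m = np.where(allnan, np.nan, np.nanmax(block, axis=1))
            cols.append(m)
    return np.column_stack(cols)


def chromosome_slices(gmatrix: GenotypeMatrix) -> list[tuple[str, slice]]:
    """Contiguous column ranges of each chromosome in the sorted marker map."""
    chroms = gmatrix.markers["chromosome"].to_numpy()
    slices = []
    start = 0
    for j in range(1, len(chroms) + 1):
        if j == len(chroms) or chroms[j] != chroms[start]:
            slices.append((str(chroms[start]), slice(start, j)))
            start = j
    return slices


def scan_all_traits(
    traits: pd.DataFrame,
    gmatrix: GenotypeMatrix,
    threshold: float | None = None,
    panel_id: str | None = None,
    condition: str | None = None,
    cap: float = DEFAULT_LRS_CAP,
) -> list[QTLHit]:
    """Chromosome-maximum QTL hits for every trait in a matrix, vectorized.

    Equivalent to running :func:`genome_scan` + :func:`chromosome_max_qtls`
    per trait, but computed in one pass over the traits x strains matrix.
    """
    aligned, trait_ids = align_traits_to_panel(traits, gmatrix)
    res = lrs_scan(aligned, gmatrix.codes, cap=cap)
    lrs = res["lrs"]
    hits: list[QTLHit] = []
    markers = gmatrix.markers
    for ch, sl in chromosome_slices(gmatrix):
        block = lrs[:, sl]
        finite = np.isfinite(block)
        if not finite.any():
            continue
        # first (lowest-position) index of the maximum per trait
        safe = np.where(finite, block, -np.inf)
        j_rel = np.argmax(safe, axis=1)
        any_ok = finite.any(axis=1)
        for t in np.flatnonzero(any_ok):
            j = sl.start + int(j_rel[t])
            value = float(lrs[t, j])
            hits.append(
                QTLHit(
                    trait_id=trait_ids[t],
                    marker_id=markers.at[j, "marker"],
                    chromosome=str(markers.at[j, "chromosome"]),
                    position_mb=float(markers.at[j, "position_mb"]),
                    lrs=value,
                    effect_sign=int(res["sign"][t, j]),
                    n_strains_used=int(res["n_used"][t, j]),
                    significant=bool(threshold is not None and value > threshold),
                    capped=bool(res["capped"][t, j]),
                    panel_id=panel_id,
                    condition=condition,
                )
            )
    return hits


@dataclass
class FDRTable:
    """Permutation-based FDR estimates over a grid of LRS thresholds.

    ``table`` has columns theta, n_observed, mean_permuted, fdr_raw and
    fdr; ``fdr`` is the raw estimate made non-increasing in theta by a
    cumulative maximum from the right (a noisy dip of the raw curve can
    then never select a too-lenient threshold).  FDR is NaN where no
    observed maximum exceeds theta.
    """

    table: pd.DataFrame
    n_perm: int
    n_traits: int
    observed_chrom_max: np.ndarray  # (n_traits, n_chromosomes)
    perm_genome_max: np.ndarray  # (n_perm, n_traits) genome-wide maxima
    target: float = 0.05
    threshold: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.threshold = self.threshold_at_fdr(self.target)

    def threshold_at_fdr(self, target: float) -> float | None:
        """Smallest grid theta whose (monotone) FDR estimate is <= target."""
        ok = self.table[self.table["fdr"].notna() & (self.table["fdr"] <= target)]
        if ok.empty:
            return None
        return float(ok["theta"].iloc[0])

    def threshold_at_null_rate(self, alpha: float = 0.05) -> float:
        """LRS threshold at which a null trait's genome-wide maximum exceeds
        it with probability ``alpha``.

        Computed as the (1 - alpha) quantile of the pooled permuted
        per-trait genome-wide maxima; this is the genome-wide calibration
        a pure-noise study can be checked against.
        """
        flat = self.perm_genome_max[np.isfinite(self.perm_genome_max)]
        if flat.size == 0:
            raise ValueError("no finite permuted maxima")
        return float(np.quantile(flat, 1.0 - alpha, method="higher"))


def permutation_fdr(
    traits: pd.DataFrame,
    gmatrix: GenotypeMatrix,
    n_perm: int = 1000,
    theta_grid: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
    target: float = 0.05,
    cap: float = DEFAULT_LRS_CAP,
    shared_permutation: bool = True,
) -> FDRTable:
    """Estimate FDR of per-trait chromosome-maximum QTL calls by permutation.

    Each iteration applies one shuffle of strain labels to the trait
    matrix (shared across traits by default, preserving co-expression
    structure) and recomputes every per-trait chromosome maximum.
    FDR(theta) = mean permuted count above theta / observed count above
    theta, NaN where the observed count is zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if theta_grid is None:
        theta_grid = np.arange(5.0, 60.5, 0.5)
    theta = np.asarray(sorted(theta_grid), dtype=float)

    aligned, _ = align_traits_to_panel(traits, gmatrix)
    slices = chromosome_slices(gmatrix)
    obs = _chromosome_max_matrix(
        lrs_scan(aligned, gmatrix.codes, cap=cap)["lrs"], slices
    )
    obs_flat = obs[np.isfinite(obs)]
    n_observed = (obs_flat[None, :] > theta[:, None]).sum(axis=1)

    n_traits, n_strains = aligned.shape
    perm_counts = np.zeros((n_perm, theta.size))
    perm_genome_max = np.full((n_perm, n_traits), np.nan)
    for p in range(n_perm):
        if shared_permutation:
            shuffled = aligned[:, rng.permutation(n_strains)]
        else:
            shuffled = np.empty_like(aligned)
            for t in range(n_traits):
                shuffled[t] = aligned[t, rng.permutation(n_strains)]
        pm = _chromosome_max_matrix(
            lrs_scan(shuffled, gmatrix.codes, cap=cap)["lrs"], slices
        )
        flat = pm[np.isfinite(pm)]
        perm_counts[p] = (flat[None, :] > theta[:, None]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            allnan = np.all(np.isnan(pm), axis=1)
            perm_genome_max[p] = np.where(allnan, np.nan, np.nanmax(pm, axis=1))

    mean_perm = perm_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_raw = np.where(n_observed > 0, mean_perm / n_observed, np.nan)
    # enforce a monotone non-increasing FDR curve: running maximum from the
    # right, so a theta is only reported below target when every larger
    # theta is too (spurious dips of the raw estimate cannot select a
    # too-lenient threshold)
    fdr = fdr_raw.copy()
    finite = np.isfinite(fdr)
    if finite.any():
        vals = fdr[finite]
        fdr[finite] = np.maximum.accumulate(vals[::-1])[::-1]
    table = pd.DataFrame(
        {
            "theta": theta,
            "n_observed": n_observed,
            "mean_permuted": mean_perm,
            "fdr_raw": fdr_raw,
            "fdr": fdr,
        }
    )
    return FDRTable(
        table=table,
        n_perm=n_perm,
        n_traits=n_traits,
        observed_chrom_max=obs,
        perm_genome_max=perm_genome_max,
        target=target,
    )


def genomewide_pvalue(
    trait_values: pd.Series,
    gmatrix: GenotypeMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    cap: float = DEFAULT_LRS_CAP,
) -> tuple[float, QTLHit]:
    """Empirical genome-wide p-value of a (behavioral) trait's best marker.

    p = (1 + #{permutations with max LRS >= observed max}) / (n_perm + 1).
    Returns the p-value together with the genome-wide best hit.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = genome_scan(trait_values, gmatrix, cap=cap)
    usable = profile[profile["lrs"].notna()]
    if usable.empty:
        raise ValueError("no informative marker for trait")
    best = usable.loc[usable["lrs"].idxmax()]
    obs_max = float(best["lrs"])

    table = pd.DataFrame([trait_values])
    aligned, _ = align_traits_to_panel(table, gmatrix)
    n_strains = aligned.shape[1]
    count = 0
    for _ in range(n_perm):
        shuffled = aligned[:, rng.permutation(n_strains)]
        lrs = lrs_scan(shuffled, gmatrix.codes, cap=cap)["lrs"]
        finite = lrs[np.isfinite(lrs)]
        pmax = float(np.max(finite)) if finite.size else -np.inf
        if pmax >= obs_max:
            count += 1
    p = (1 + count) / (n_perm + 1)
    hit = QTLHit(
        trait_id=str(trait_values.name) if trait_values.name is not None else "trait",
        marker_id=best["marker"],
        chromosome=str(best["chromosome"]),
        position_mb=float(best["position_mb"]),
        lrs=obs_max,
        effect_sign=int(best["effect_sign"]),
        n_strains_used=int(best["n_used"]),
        capped=bool(best["capped"]),
    )
    return p, hit
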