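"""QTL activity patterns across treatments and their conservation across panels.

The activity pattern of a QTL is the binary vector recording in which of
the four treatment conditions (SC, EC, SR, ER) the trait-marker LRS
exceeds the panel's significance threshold (strictly).  With four
conditions there are 2^4 - 1 = 15 non-null patterns.  Conservation of a
QTL in the other RI panel is judged at that panel's nearest marker (or,
as a sensitivity mode, only at markers shared by both maps), using the
other panel's own threshold.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .mapping import UninformativeMarkerError, compute_lrs
from .model import (
    ActivityPattern,
    ConditionedTraitSet,
    CrossPanelRecord,
    GenotypeMatrix,
    QTLHit,
    pattern_index,
)

log = logging.getLogger(__name__)


def lrs_across_conditions(
    trait_id: str,
    marker_id: str,
    trait_set: ConditionedTraitSet,
    gmatrix: GenotypeMatrix,
) -> np.ndarray:
    """Per-condition LRS of one trait at one fixed marker.

    Entries are NaN for conditions where the trait is missing or the
    marker is uninformative after missing-data removal.  Raises if the
    trait is absent from every condition.
    """
    codes = gmatrix.marker_codes(marker_id)
    strain_pos = {s: i for i, s in enumerate(gmatrix.strains)}
    out = np.full(len(trait_set.conditions), np.nan)
    present = False
    for k, cond in enumerate(trait_set.conditions):
        df = trait_set.values[cond]
        if trait_id not in df.index:
            continue
        present = True
        row = df.loc[trait_id]
        vals = np.full(gmatrix.n_strains, np.nan)
        for s, v in row.items():
            if s in strain_pos:
                vals[strain_pos[s]] = v
        try:
            lrs, _, _ = compute_lrs(vals, codes)
        except UninformativeMarkerError:
            continue
        out[k] = lrs
    if not present:
        raise KeyError(f"trait {trait_id!r} absent from all conditions")
    return out


def make_activity_pattern(
    lrs_vector: np.ndarray,
    threshold: float,
    trait_id: str = "",
    marker_id: str = "",
    panel_id: str = "",
    conditions: tuple[str, ...] = ("SC", "EC", "SR", "ER"),
) -> ActivityPattern | None:
    """Binary activity pattern of an LRS vector at a panel threshold.

    Significance is strict (LRS > threshold).  Returns None when no
    condition is significant: an all-zero vector is not one of the 15
    patterns.
    """
    pat = ActivityPattern(
        trait_id=trait_id,
        marker_id=marker_id,
        panel_id=panel_id,
        conditions=conditions,
        lrs_vector=np.asarray(lrs_vector, dtype=float),
        threshold=threshold,
    )
    if pat.is_null:
        log.debug("trait %s @ %s: no condition above threshold", trait_id, marker_id)
        return None
    return pat


def enumerate_patterns(n_conditions: int = 4) -> list[tuple[int, ...]]:
    """All non-null binary activity patterns: 2^n - 1 of them."""
    if n_conditions <= 0:
        raise ValueError("need at least one condition")
    pats = [
        bits
        for bits in itertools.product((0, 1), repeat=n_conditions)
        if any(bits)
    ]
    pats.sort(key=pattern_index, reverse=True)
    return pats


def nearest_marker(
    chromosome: str, position_mb: float, marker_map: pd.DataFrame
) -> str:
    """Id of the other panel's marker nearest a genomic position.

    Distance ties break toward the lower position.  Raises ``KeyError``
    when the other map has no marker on that chromosome.
    """
    sub = marker_map[marker_map["chromosome"].astype(str) == str(chromosome)]
    if sub.empty:
        raise KeyError(f"no marker on chromosome {chromosome}")
    pos = sub["position_mb"].to_numpy()
    dist = np.abs(pos - float(position_mb))
    best = np.flatnonzero(dist == dist.min())
    # marker maps are position-sorted, so the first minimum is the lower one
    return str(sub.iloc[best[0]]["marker"])


def cross_population_conservation(
    hit: QTLHit,
    source_pattern: ActivityPattern,
    other_traits: ConditionedTraitSet,
    other_gmatrix: GenotypeMatrix,
    other_threshold: float,
    mode: str = "nearest",
) -> CrossPanelRecord:
    """Judge conservation of one QTL in the other panel.

    ``mode="nearest"`` matches the hit's marker to the other map's
    nearest marker on the same chromosome; ``mode="identical"`` requires
    the same marker id in both maps (sensitivity check).  Conservation
    under a treatment means the other-panel LRS at the matched marker
    exceeds the OTHER panel's threshold; ``conserved_any`` is the OR over
    treatments and ``pattern_identical`` compares full bit vectors.
    """
    if mode not in ("nearest", "identical"):
        raise ValueError(f"unknown matching mode {mode!r}")
    base = dict(
        trait_id=hit.trait_id,
        source_panel=hit.panel_id or "",
        source_marker=hit.marker_id,
        other_panel=other_gmatrix.panel_id,
    )
    if not other_traits.has_trait(hit.trait_id):
        return CrossPanelRecord(
            **base, matched_marker=None, lrs_vector=None, bits=None,
            conserved_any=None, pattern_identical=None, reason="trait_absent",
        )
    if mode == "identical":
        if hit.marker_id not in set(other_gmatrix.markers["marker"]):
            return CrossPanelRecord(
                **base, matched_marker=None, lrs_vector=None, bits=None,
                conserved_any=None, pattern_identical=None,
                reason="marker_not_shared",
            )
        matched = hit.marker_id
    else:
        try:
            matched = nearest_marker(
                hit.chromosome, hit.position_mb, other_gmatrix.markers
            )
        except KeyError:
            log.info(
                "trait %s: chromosome %s absent from panel %s map; skipped",
                hit.trait_id, hit.chromosome, other_gmatrix.panel_id,
            )
            return CrossPanelRecord(
                **base, matched_marker=None, lrs_vector=None, bits=None,
                conserved_any=None, pattern_identical=None,
                reason="chromosome_absent",
            )
    try:
        vec = lrs_across_conditions(hit.trait_id, matched, other_traits, other_gmatrix)
    except KeyError:
        return CrossPanelRecord(
            **base, matched_marker=matched, lrs_vector=None, bits=None,
            conserved_any=None, pattern_identical=None, reason="trait_absent",
        )
    other = ActivityPattern(
        trait_id=hit.trait_id,
        marker_id=matched,
        panel_id=other_gmatrix.panel_id,
        conditions=other_traits.conditions,
        lrs_vector=vec,
        threshold=other_threshold,
    )
    return CrossPanelRecord(
        **base,
        matched_marker=matched,
        lrs_vector=vec,
        bits=other.bits,
        conserved_any=any(other.bits),
        pattern_identical=(other.bits == source_pattern.bits),
    )


def summarize_patterns(
    classified_patterns: list[tuple[str, ActivityPattern]],
    n_conditions: int = 4,
) -> pd.DataFrame:
    """Per-class distribution over the 15 activity patterns.

    Input is (eqtl_class, pattern) pairs.  Returns one row per class with
    a normalized 15-bin histogram (columns ``pattern_1`` .. ``pattern_15``
    summing to 1), the fraction of treatment-specific QTLs (exactly one
    bit), the fraction conserved in all conditions, and the class count.
    Classes present in the index but without patterns get zero rows and
    are flagged ``empty``.
    """
    if not classified_patterns:
        raise ValueError("no patterns to summarize")
    n_bins = 2**n_conditions - 1
    classes = sorted({c for c, _ in classified_patterns})
    rows = []
    for cls in classes:
        pats = [p for c, p in classified_patterns if c == cls]
        hist = np.zeros(n_bins)
        one_bit = 0
        all_bits = 0
        for p in pats:
            if p.is_null:
                continue
            hist[p.index - 1] += 1
            if sum(p.bits) == 1:
                one_bit += 1
            if sum(p.bits) == n_conditions:
                all_bits += 1
        total = hist.sum()
        row = {"eqtl_class": cls, "n": int(total), "empty": total == 0}
        if total > 0:
            hist = hist / total
            row["treatment_specific_fraction"] = one_bit / total
            row["all_conditions_fraction"] = all_bits / total
        else:
            row["treatment_specific_fraction"] = 0.0
            row["all_conditions_fraction"] = 0.0
        for i in range(n_bins):
            row[f"pattern_{i + 1}"] = hist[i]
        rows.append(row)
    return pd.DataFrame(rows).set_index("eqtl_class")
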