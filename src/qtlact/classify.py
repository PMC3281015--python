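"""Geometric classification of eQTLs and the probe-SNP cis filter.

An expression QTL is *cis* when the mapped marker lies within 5 Mb of the
gene's annotated position, *syntenic trans* when marker and gene share a
chromosome but are farther apart, and *non-syntenic trans* when they lie
on different chromosomes.  A hybridization artifact can masquerade as a
cis-eQTL when the probe itself overlaps a segregating SNP: such probes
show apparently higher expression in strains carrying the reference
(B6-like, A-coded) allele in every treatment, and are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import ActivityPattern, QTLHit

log = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW_MB: float = 5.0


def classify_eqtl(
    hit: QTLHit,
    gene_chromosome: str | None,
    gene_position_mb: float | None,
    cis_window_mb: float = DEFAULT_CIS_WINDOW_MB,
) -> str:
    """Class label of one hit given its gene's annotated location.

    The 5 Mb cis boundary is inclusive.  Behavioral traits (no genomic
    location) are ``not_applicable``.
    """
    if gene_chromosome is None or gene_position_mb is None:
        return "not_applicable"
    if str(gene_chromosome) != str(hit.chromosome):
        return "nonsyntenic_trans"
    if abs(float(gene_position_mb) - hit.position_mb) <= cis_window_mb:
        return "cis"
    return "syntenic_trans"


def classify_hits(
    hits: Iterable[QTLHit],
    annotations,
    cis_window_mb: float = DEFAULT_CIS_WINDOW_MB,
) -> list[QTLHit]:
    """Set ``eqtl_class`` on every hit in place (and return the list).

    ``annotations`` is the trait-annotation DataFrame of a
    :class:`~qtlact.model.ConditionedTraitSet` (indexed by trait id with
    ``kind``, ``chromosome``, ``position_mb`` columns).
    """
    out = []
    for h in hits:
        if h.trait_id in annotations.index and (
            annotations.at[h.trait_id, "kind"] == "expression"
        ):
            h.eqtl_class = classify_eqtl(
                h,
                annotations.at[h.trait_id, "chromosome"],
                annotations.at[h.trait_id, "position_mb"],
                cis_window_mb,
            )
        else:
            h.eqtl_class = "not_applicable"
        out.append(h)
    return out


@dataclass
class ProbeSnpFilterResult:
    kept: list[tuple[QTLHit, ActivityPattern]]
    removed: list[tuple[QTLHit, ActivityPattern]]
    missing_flags: list[str] = field(default_factory=list)


def filter_probe_snp_cis(
    hits_with_patterns: Iterable[tuple[QTLHit, ActivityPattern]],
    probe_flags: Mapping[str, bool],
    enabled: bool = True,
) -> ProbeSnpFilterResult:
    """Remove artifact cis-eQTLs caused by SNPs under the probe.

    A hit is removed iff it is cis AND its probe contains a SNP AND its
    effect sign indicates higher expression for A-allele (B6-like)
    carriers (sign = -1 under the B-coded convention) AND its activity
    pattern is significant in all four treatments.  Everything else
    passes; a trait without a probe flag is treated as flag-free and
    logged.  The filter is idempotent.  Set ``enabled=False`` for panels
    whose parental strains lack sequence (no probe-SNP calls available).
    """
    result = ProbeSnpFilterResult(kept=[], removed=[])
    for hit, pattern in hits_with_patterns:
        if not enabled:
            result.kept.append((hit, pattern))
            continue
        if hit.trait_id not in probe_flags:
            result.missing_flags.append(hit.trait_id)
            contains_snp = False
        else:
            contains_snp = bool(probe_flags[hit.trait_id])
        all_conditions = all(b == 1 for b in pattern.bits)
        if (
            hit.eqtl_class == "cis"
            and contains_snp
            and hit.effect_sign == -1
            and all_conditions
        ):
            result.removed.append((hit, pattern))
        else:
            result.kept.append((hit, pattern))
    if result.missing_flags:
        log.info(
            "probe-SNP filter: %d traits had no flag (treated as SNP-free)",
            len(set(result.missing_flags)),
        )
    return result
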