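"""Candidate-gene selection and QTL-activity-pattern correlation networks.

A behavioral QTL region is scored for every trait by an 8-entry LRS
vector: the maximum LRS over markers inside the region, for each of the
two panels x four treatments (LXS-SC, LXS-EC, LXS-SR, LXS-ER, BXD-SC,
BXD-EC, BXD-SR, BXD-ER by default).  Candidate genes are transcripts
whose focal-panel activity pattern matches the behavioral one (silent in
SC, significant in EC, not conserved in the other panel).  The
correlation network connects traits whose 8-vectors are strongly
correlated.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .mapping import lrs_scan
from .model import (
    ActivityPattern,
    ConditionedTraitSet,
    CrossPanelRecord,
    GenotypeMatrix,
    RegionSpec,
)

log = logging.getLogger(__name__)

DEFAULT_PANEL_ORDER: tuple[str, str] = ("LXS", "BXD")
DEFAULT_PREFILTER_LRS: float = 20.0
DEFAULT_INCLUDE_R: float = 0.7
DEFAULT_EDGE_R: float = 0.8
MIN_SHARED_ENTRIES: int = 4


def _region_marker_columns(gmatrix: GenotypeMatrix, region: RegionSpec) -> np.ndarray:
    mm = gmatrix.markers
    mask = (
        (mm["chromosome"].astype(str) == region.chromosome)
        & (mm["position_mb"] >= region.start_mb)
        & (mm["position_mb"] <= region.end_mb)
    )
    return np.flatnonzero(mask.to_numpy())


def region_lrs_vector(
    trait_id: str,
    region: RegionSpec,
    panels: Mapping[str, tuple[GenotypeMatrix, ConditionedTraitSet]],
    panel_order: Sequence[str] = DEFAULT_PANEL_ORDER,
) -> np.ndarray:
    """8-entry region-max LRS vector of one trait (panel-major order).

    Per panel and condition, the maximum LRS over markers inside
    [start, end].  Entries are NaN when the trait is absent from a
    panel/condition or the region holds no marker in that panel's map.
    Raises ``KeyError`` when the trait is unknown to every panel.
    """
    known = False
    out: list[float] = []
    for panel in panel_order:
        gmatrix, trait_set = panels[panel]
        cols = _region_marker_columns(gmatrix, region)
        if trait_set.has_trait(trait_id):
            known = True
        if cols.size == 0 or not trait_set.has_trait(trait_id):
            out.extend([np.nan] * len(trait_set.conditions))
            continue
        codes = gmatrix.codes[:, cols]
        strain_pos = {s: i for i, s in enumerate(gmatrix.strains)}
        for cond in trait_set.conditions:
            df = trait_set.values[cond]
            if trait_id not in df.index:
                out.append(np.nan)
                continue
            vals = np.full(gmatrix.n_strains, np.nan)
            for s, v in df.loc[trait_id].items():
                if s in strain_pos:
                    vals[strain_pos[s]] = v
            lrs = lrs_scan(vals[None, :], codes)["lrs"][0]
            finite = lrs[np.isfinite(lrs)]
            out.append(float(finite.max()) if finite.size else np.nan)
    if not known:
        raise KeyError(f"trait {trait_id!r} unknown to all panels")
    return np.asarray(out)


def pattern_correlation(
    x: np.ndarray, y: np.ndarray, min_shared: int = MIN_SHARED_ENTRIES
) -> float:
    """Pearson correlation of two LRS vectors over shared non-missing
    entries; NaN when fewer than ``min_shared`` remain or either side is
    constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_shared:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def select_candidates(
    region_hits: Iterable[tuple[ActivityPattern, CrossPanelRecord]],
    sc_condition: str = "SC",
    ec_condition: str = "EC",
) -> list[str]:
    """Genes whose eQTL activity pattern matches an ethanol-activated,
    population-private behavioral QTL.

    A trait passes iff, at its focal-panel hit inside the region:
    (1) the SC bit is 0 (no association in the untreated control),
    (2) the EC bit is 1 (significant after ethanol alone), and
    (3) the QTL is not conserved in the other panel (``conserved_any``
    false; a trait with no counterpart cannot be shown conserved and
    passes).  The returned list is sorted, so it is invariant to input
    order.
    """
    selected = set()
    for pattern, record in region_hits:
        conds = list(pattern.conditions)
        i_sc = conds.index(sc_condition)
        i_ec = conds.index(ec_condition)
        if pattern.bits[i_sc] != 0:
            continue
        if pattern.bits[i_ec] != 1:
            continue
        if record.conserved_any:
            continue
        selected.add(pattern.trait_id)
    return sorted(selected)


def build_pattern_network(
    region: RegionSpec,
    panels: Mapping[str, tuple[GenotypeMatrix, ConditionedTraitSet]],
    transcripts: Sequence[str] | None = None,
    prefilter_lrs: float = DEFAULT_PREFILTER_LRS,
    include_r: float = DEFAULT_INCLUDE_R,
    edge_r: float = DEFAULT_EDGE_R,
    panel_order: Sequence[str] = DEFAULT_PANEL_ORDER,
    ethanol_flags: Mapping[str, bool] | None = None,
) -> nx.Graph:
    """QTL-activity-pattern correlation network around one behavioral QTL.

    Transcripts first pass an association prefilter: focal-panel,
    focal-condition region LRS strictly above ``prefilter_lrs``.  A
    passing transcript becomes a node iff the Pearson correlation of its
    8-vector with the phenotype's exceeds ``include_r``; edges connect
    any node pair (phenotype-transcript or transcript-transcript) with
    correlation above ``edge_r``.  Node attributes carry the trait kind,
    the correlation with the phenotype, and an optional ethanol-annotation
    flag; edges carry ``r`` and an ``edge_kind`` column.
    """
    pheno_vec = region_lrs_vector(region.phenotype_id, region, panels, panel_order)

    if transcripts is None:
        _, focal_traits = panels[region.focal_panel]
        transcripts = focal_traits.traits_of_kind("expression")

    focal_idx = list(panel_order).index(region.focal_panel)
    _, focal_set = panels[region.focal_panel]
    cond_idx = list(focal_set.conditions).index(region.focal_condition)
    entry = focal_idx * len(focal_set.conditions) + cond_idx

    vectors: dict[str, np.ndarray] = {}
    for trait in transcripts:
        if trait == region.phenotype_id:
            continue
        try:
            vec = region_lrs_vector(trait, region, panels, panel_order)
        except KeyError:
            continue
        if np.isfinite(vec[entry]) and vec[entry] > prefilter_lrs:
            vectors[trait] = vec
    return network_from_vectors(
        pheno_vec,
        vectors,
        phenotype_id=region.phenotype_id,
        include_r=include_r,
        edge_r=edge_r,
        ethanol_flags=ethanol_flags,
    )


def network_from_vectors(
    phenotype_vector: np.ndarray,
    transcript_vectors: Mapping[str, np.ndarray],
    phenotype_id: str = "phenotype",
    include_r: float = DEFAULT_INCLUDE_R,
    edge_r: float = DEFAULT_EDGE_R,
    ethanol_flags: Mapping[str, bool] | None = None,
) -> nx.Graph:
    """Correlation network over already-computed activity vectors.

    Transcripts become nodes iff their Pearson correlation with the
    phenotype vector exceeds ``include_r``; edges connect any node pair
    with correlation above ``edge_r``.  Raises when the phenotype vector
    is constant (its correlations are undefined).
    """
    pheno_vec = np.asarray(phenotype_vector, dtype=float)
    finite = pheno_vec[np.isfinite(pheno_vec)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise ValueError("phenotype activity vector is constant; correlation undefined")
    flags = ethanol_flags or {}
    graph = nx.Graph()
    graph.add_node(
        phenotype_id,
        kind="phenotype",
        ethanol=bool(flags.get(phenotype_id, False)),
        r_with_phenotype=1.0,
    )
    vectors: dict[str, np.ndarray] = {phenotype_id: pheno_vec}
    for trait, vec in transcript_vectors.items():
        r = pattern_correlation(np.asarray(vec, dtype=float), pheno_vec)
        if not (np.isfinite(r) and r > include_r):
            continue
        graph.add_node(
            trait,
            kind="transcript",
            ethanol=bool(flags.get(trait, False)),
            r_with_phenotype=r,
        )
        vectors[trait] = np.asarray(vec, dtype=float)

    nodes = sorted(vectors)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            r = pattern_correlation(vectors[a], vectors[b])
            if np.isfinite(r) and r > edge_r:
                kinds = {graph.nodes[a]["kind"], graph.nodes[b]["kind"]}
                edge_kind = (
                    "phenotype-transcript" if "phenotype" in kinds
                    else "transcript-transcript"
                )
                graph.add_edge(a, b, r=r, edge_kind=edge_kind)
    return graph


def write_network(graph: nx.Graph, edge_path, graphml_path=None) -> None:
    """Write the network as an edge-list TSV (and optionally GraphML)."""
    import pandas as pd

    rows = [
        {"source": a, "target": b, "r": d["r"], "edge_kind": d["edge_kind"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "edge_kind"]).to_csv(
        edge_path, sep="\t", index=False, float_format="%.6g"
    )
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
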