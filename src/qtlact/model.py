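"""Shared data model for two-panel, multi-treatment QTL studies.

Genotypes of recombinant inbred (RI) strains are homozygous at every
marker, so a panel is fully described by a strains x markers matrix over
three codes: the two parental alleles and "missing" (no-call or residual
heterozygosity).  Expression and behavioral traits are strain means,
measured separately under each treatment condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# genotype codes: A = first parental allele (ISS / C57BL/6J-like),
# B = second parental allele (ILS / DBA/2J-like)
CODE_A: int = 0
CODE_B: int = 1
CODE_MISSING: int = -1

#: fixed treatment order used for every activity-pattern computation:
#: saline control, ethanol, saline+restraint, ethanol+restraint
DEFAULT_CONDITIONS: tuple[str, ...] = ("SC", "EC", "SR", "ER")

#: LRS = LOD * 2 ln 10
LRS_PER_LOD: float = 2.0 * math.log(10.0)

EQTL_CLASSES = ("cis", "syntenic_trans", "nonsyntenic_trans", "not_applicable")


def chrom_sort_key(chromosome: str) -> tuple[int, float, str]:
    """Sorting key placing autosomes 1..19 first (numerically), then X.

    Unrecognized chromosome names sort after X, alphabetically, so the
    ordering is total.
    """
    ch = str(chromosome)
    try:
        return (0, float(int(ch)), "")
    except ValueError:
        if ch.upper() == "X":
            return (1, 0.0, "")
        return (2, 0.0, ch)


def order_chromosomes(chromosomes: Iterable[str]) -> list[str]:
    """Unique chromosome names in canonical output order."""
    return sorted(set(str(c) for c in chromosomes), key=chrom_sort_key)


def validate_marker_map(markers: pd.DataFrame) -> pd.DataFrame:
    """Check and canonicalize a marker map.

    Expects columns ``marker``, ``chromosome``, ``position_mb``.  Returns a
    copy sorted by (chromosome, position) with a fresh integer index.
    Duplicate marker ids or negative positions raise ``ValueError``.
    """
    required = {"marker", "chromosome", "position_mb"}
    missing = required - set(markers.columns)
    if missing:
        raise ValueError(f"marker map lacks columns: {sorted(missing)}")
    mm = markers.copy()
    mm["marker"] = mm["marker"].astype(str)
    mm["chromosome"] = mm["chromosome"].astype(str)
    mm["position_mb"] = mm["position_mb"].astype(float)
    if mm["marker"].duplicated().any():
        dups = mm.loc[mm["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"duplicate marker ids: {dups[:5]}")
    if (mm["position_mb"] < 0).any():
        raise ValueError("marker positions must be non-negative (Mb)")
    key = mm["chromosome"].map(chrom_sort_key)
    mm = (
        mm.assign(_key=key)
        .sort_values(["_key", "position_mb"], kind="mergesort")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    return mm


@dataclass
class GenotypeMatrix:
    """Homozygous genotype codes for one RI panel.

    ``codes`` is a strains x markers int8 array over
    {``CODE_A``, ``CODE_B``, ``CODE_MISSING``}; marker columns follow the
    (chromosome, position)-sorted order of ``markers``.
    """

    panel_id: str
    strains: list[str]
    markers: pd.DataFrame  # columns: marker, chromosome, position_mb
    codes: np.ndarray

    def __post_init__(self) -> None:
        order_before = list(self.markers["marker"].astype(str))
        self.markers = validate_marker_map(self.markers)
        order_after = list(self.markers["marker"])
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.strains), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.strains)} strains x {len(self.markers)} markers"
            )
        if order_after != order_before:
            perm = [order_before.index(m) for m in order_after]
            self.codes = self.codes[:, perm]
        bad = ~np.isin(self.codes, (CODE_A, CODE_B, CODE_MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {A, B, missing}")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain ids")
        self._marker_col = {m: j for j, m in enumerate(self.markers["marker"])}

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_column(self, marker_id: str) -> int:
        try:
            return self._marker_col[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r} in panel {self.panel_id}")

    def marker_codes(self, marker_id: str) -> np.ndarray:
        return self.codes[:, self.marker_column(marker_id)]

    def informative_mask(self, min_per_group: int = 2) -> np.ndarray:
        """Markers where both alleles are carried by >= ``min_per_group`` strains."""
        n_a = (self.codes == CODE_A).sum(axis=0)
        n_b = (self.codes == CODE_B).sum(axis=0)
        return (n_a >= min_per_group) & (n_b >= min_per_group)

    def subset_strains(self, strains: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.strains.index(s) for s in strains]
        return GenotypeMatrix(
            panel_id=self.panel_id,
            strains=list(strains),
            markers=self.markers.copy(),
            codes=self.codes[idx, :].copy(),
        )


@dataclass
class ConditionedTraitSet:
    """Per-condition strain-mean trait matrices plus trait annotations.

    ``values`` maps each condition label to a traits x strains DataFrame;
    group sizes may differ between conditions (the strain columns of each
    condition are a subset of the panel's strains).  ``annotations`` is
    indexed by trait id with columns ``kind`` ("expression"/"behavioral"),
    ``gene_symbol``, ``chromosome``, ``position_mb`` (location columns are
    NaN for behavioral traits).
    """

    panel_id: str
    conditions: tuple[str, ...]
    values: dict[str, pd.DataFrame]
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        missing = [c for c in self.conditions if c not in self.values]
        if missing:
            raise ValueError(f"conditions without trait matrices: {missing}")
        for cond, df in self.values.items():
            if df.index.duplicated().any():
                raise ValueError(f"duplicate trait ids in condition {cond}")
        if "kind" not in self.annotations.columns:
            raise ValueError("annotations need a 'kind' column")

    @property
    def traits(self) -> list[str]:
        return list(self.annotations.index)

    def traits_of_kind(self, kind: str) -> list[str]:
        return list(self.annotations.index[self.annotations["kind"] == kind])

    def trait_values(self, trait_id: str, condition: str) -> pd.Series:
        """Strain means of one trait under one condition (NaN-free entries only)."""
        df = self.values[condition]
        if trait_id not in df.index:
            raise KeyError(f"trait {trait_id!r} absent from condition {condition}")
        return df.loc[trait_id]

    def has_trait(self, trait_id: str) -> bool:
        return trait_id in self.annotations.index


@dataclass
class SNPPanel:
    """SNP positions with a flag marking variants segregating in both panels."""

    table: pd.DataFrame  # columns: chromosome, position_mb, conserved

    def __post_init__(self) -> None:
        required = {"chromosome", "position_mb", "conserved"}
        if missing := required - set(self.table.columns):
            raise ValueError(f"SNP panel lacks columns: {sorted(missing)}")
        t = self.table.copy()
        t["chromosome"] = t["chromosome"].astype(str)
        key = t["chromosome"].map(chrom_sort_key)
        t = (
            t.assign(_key=key)
            .sort_values(["_key", "position_mb"], kind="mergesort")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class QTLHit:
    """One trait-marker association (usually the per-chromosome LRS maximum)."""

    trait_id: str
    marker_id: str
    chromosome: str
    position_mb: float
    lrs: float
    effect_sign: int  # sign of mean(B strains) - mean(A strains); 0 on exact tie
    n_strains_used: int
    significant: bool = False
    eqtl_class: str = "not_applicable"
    capped: bool = False
    panel_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.lrs < 0:
            raise ValueError("LRS must be non-negative")
        if self.eqtl_class not in EQTL_CLASSES:
            raise ValueError(f"unknown eQTL class {self.eqtl_class!r}")

    @property
    def lod(self) -> float:
        return self.lrs / LRS_PER_LOD


def pattern_index(bits: Sequence[int]) -> int:
    """Integer code of a binary activity pattern, first condition = MSB.

    With the (SC, EC, SR, ER) order, ``bits (1,1,0,0) -> 12``.  The all-zero
    vector maps to 0, which is not a valid pattern index (patterns require
    at least one significant condition).
    """
    value = 0
    for b in bits:
        value = (value << 1) | (1 if b else 0)
    return value


def bits_from_index(index: int, n_conditions: int) -> tuple[int, ...]:
    if not 0 <= index < 2**n_conditions:
        raise ValueError("pattern index out of range")
    return tuple((index >> (n_conditions - 1 - i)) & 1 for i in range(n_conditions))


@dataclass
class ActivityPattern:
    """Per-condition LRS vector of one QTL and its binary significance pattern."""

    trait_id: str
    marker_id: str
    panel_id: str
    conditions: tuple[str, ...]
    lrs_vector: np.ndarray  # NaN where the trait is missing from a condition
    threshold: float
    bits: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.lrs_vector = np.asarray(self.lrs_vector, dtype=float)
        if self.lrs_vector.shape != (len(self.conditions),):
            raise ValueError("lrs_vector length must equal number of conditions")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        with np.errstate(invalid="ignore"):
            self.bits = tuple(
                int(v > self.threshold) if np.isfinite(v) else 0
                for v in self.lrs_vector
            )

    @property
    def index(self) -> int:
        return pattern_index(self.bits)

    @property
    def is_null(self) -> bool:
        """True when no condition exceeds the threshold (no activity pattern)."""
        return self.index == 0


@dataclass
class CrossPanelRecord:
    """Conservation of one QTL in the other panel, judged at that panel's
    nearest (or identical) marker with that panel's own LRS threshold."""

    trait_id: str
    source_panel: str
    source_marker: str
    other_panel: str
    matched_marker: str | None
    lrs_vector: np.ndarray | None
    bits: tuple[int, ...] | None
    conserved_any: bool | None  # None when the trait/marker has no counterpart
    pattern_identical: bool | None
    reason: str | None = None


@dataclass
class RegionSpec:
    """A behavioral-QTL support region used for candidate-gene selection."""

    chromosome: str
    start_mb: float
    end_mb: float
    focal_panel: str
    phenotype_id: str
    focal_condition: str = "EC"

    def __post_init__(self) -> None:
        self.chromosome = str(self.chromosome)
        if not self.start_mb < self.end_mb:
            raise ValueError("region start must be below end")

    def contains(self, chromosome: str, position_mb) -> np.ndarray | bool:
        pos = np.asarray(position_mb, dtype=float)
        return (str(chromosome) == self.chromosome) & (
            (pos >= self.start_mb) & (pos <= self.end_mb)
        )
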