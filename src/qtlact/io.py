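"""Readers and writers for the study's text formats.

Genotypes travel in a GeneNetwork-style ``.geno`` dialect: ``#`` comment
lines, ``@key:value`` metadata lines, then a tab-separated table whose
leading columns give chromosome / marker / position (Mb) and whose
remaining columns are one allele code per strain.  Trait matrices are CSV
(traits in rows, strains in columns); QTL hits go to TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    CODE_A,
    CODE_B,
    CODE_MISSING,
    GenotypeMatrix,
    QTLHit,
    chrom_sort_key,
)

log = logging.getLogger(__name__)

#: header names recognized as metadata (non-strain) columns, lower-cased
_META_COLUMNS = {"chr", "chromosome", "locus", "marker", "cm", "mb", "pos", "position"}


@dataclass(frozen=True)
class GenoDialect:
    """Configurable knobs of the ``.geno`` text dialect."""

    comment_prefix: str = "#"
    metadata_prefix: str = "@"
    sep: str = "\t"
    missing_codes: tuple[str, ...] = ("H", "U", "?", "")


def read_geno(
    path: str | Path,
    allele_labels: tuple[str, str] = ("B", "D"),
    panel_id: str | None = None,
    dialect: GenoDialect = GenoDialect(),
) -> GenotypeMatrix:
    """Read a ``.geno`` file into a :class:`GenotypeMatrix`.

    ``allele_labels`` maps the file's two allele codes onto the internal
    (A, B) convention, e.g. ``("B", "D")`` for a C57BL/6J x DBA/2J panel.
    Heterozygous or unknown codes become missing (RI strains are treated
    as homozygous; residual heterozygosity is a no-call) and their count
    is logged.  Markers are returned sorted by (chromosome, position).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[str, str, float, list[str]]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(dialect.comment_prefix):
                continue
            if line.startswith(dialect.metadata_prefix):
                key, _, value = line[len(dialect.metadata_prefix):].partition(":")
                meta[key.strip()] = value.strip()
                continue
            fields = line.split(dialect.sep)
            if header is None:
                header = [f.strip() for f in fields]
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path.name}:{lineno}: row has {len(fields)} fields, "
                    f"header has {len(header)}"
                )
            rows.append((lineno, fields))
    if header is None or not rows:
        raise ValueError(f"{path}: no genotype table found")

    n_meta = 0
    for name in header:
        if name.lower() in _META_COLUMNS:
            n_meta += 1
        else:
            break
    if n_meta < 3:
        raise ValueError(
            f"{path}: expected >=3 leading metadata columns "
            "(chromosome, marker, position), got header "
            f"{header[:4]}"
        )
    meta_names = [h.lower() for h in header[:n_meta]]
    strains = header[n_meta:]
    if not strains:
        raise ValueError(f"{path}: header names no strains")

    def _col(*names: str) -> int:
        for n in names:
            if n in meta_names:
                return meta_names.index(n)
        raise ValueError(f"{path}: none of columns {names} present")

    i_chr = _col("chr", "chromosome")
    i_marker = _col("locus", "marker")
    # prefer a physical Mb column over cM when both are present
    try:
        i_pos = _col("mb", "pos", "position")
    except ValueError:
        i_pos = _col("cm")

    code_a, code_b = allele_labels
    lut = {code_a: CODE_A, code_b: CODE_B}
    markers: list[dict] = []
    codes = np.empty((len(strains), len(rows)), dtype=np.int8)
    n_missing = 0
    for j, (lineno, fields) in enumerate(rows):
        marker = fields[i_marker].strip()
        if marker in seen:
            raise ValueError(f"{path.name}:{lineno}: duplicate marker id {marker!r}")
        seen.add(marker)
        try:
            pos = float(fields[i_pos])
        except ValueError:
            raise ValueError(
                f"{path.name}:{lineno}: non-numeric position {fields[i_pos]!r}"
            )
        markers.append(
            {"marker": marker, "chromosome": fields[i_chr].strip(), "position_mb": pos}
        )
        for i, cell in enumerate(fields[n_meta:]):
            cell = cell.strip()
            code = lut.get(cell)
            if code is None:
                if cell not in dialect.missing_codes:
                    log.warning(
                        "%s:%d: unrecognized code %r treated as missing",
                        path.name, lineno, cell,
                    )
                code = CODE_MISSING
                n_missing += 1
            codes[i, j] = code
    if n_missing:
        log.info("%s: %d genotype cells mapped to missing", path.name, n_missing)
    return GenotypeMatrix(
        panel_id=panel_id or meta.get("name", path.stem),
        strains=list(strains),
        markers=pd.DataFrame(markers),
        codes=codes,
    )


def write_geno(
    gmatrix: GenotypeMatrix,
    path: str | Path,
    allele_labels: tuple[str, str] = ("B", "D"),
    missing_label: str = "U",
    dialect: GenoDialect = GenoDialect(),
) -> None:
    """Write a genotype matrix in the ``.geno`` dialect (round-trips with
    :func:`read_geno`)."""
    path = Path(path)
    lut = {CODE_A: allele_labels[0], CODE_B: allele_labels[1], CODE_MISSING: missing_label}
    with path.open("w") as fh:
        fh.write(f"{dialect.comment_prefix} qtlact genotype file\n")
        fh.write(f"{dialect.metadata_prefix}name:{gmatrix.panel_id}\n")
        fh.write(f"{dialect.metadata_prefix}mat:{allele_labels[0]}\n")
        fh.write(f"{dialect.metadata_prefix}pat:{allele_labels[1]}\n")
        header = ["Chr", "Locus", "Mb"] + list(gmatrix.strains)
        fh.write(dialect.sep.join(header) + "\n")
        for j, row in gmatrix.markers.iterrows():
            cells = [str(row["chromosome"]), row["marker"], f"{row['position_mb']:.6f}"]
            cells += [lut[int(c)] for c in gmatrix.codes[:, j]]
            fh.write(dialect.sep.join(cells) + "\n")


def read_trait_table(path: str | Path, kind: str = "expression") -> pd.DataFrame:
    """Read one condition's trait x strain matrix from CSV.

    The first column holds trait ids, the header strain ids.  Blank cells
    become NaN (missing strain means, not zeros); any other non-numeric
    cell raises with its (trait, strain) coordinates.
    """
    if kind not in ("expression", "behavioral"):
        raise ValueError(f"unknown trait kind {kind!r}")
    path = Path(path)
    try:
        raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trait table")
    if raw.shape[1] == 0:
        raise ValueError(f"{path}: trait table names no strains")
    out = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns, dtype=float)
    for col in raw.columns:
        for trait, cell in raw[col].items():
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                out.at[trait, col] = np.nan
                continue
            try:
                out.at[trait, col] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path.name}: non-numeric value {cell!r} at "
                    f"trait {trait!r}, strain {col!r}"
                )
    out.attrs["kind"] = kind
    return out


def write_trait_table(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, float_format="%.8g")


QTL_TABLE_COLUMNS = [
    "trait", "marker", "chromosome", "position_mb",
    "lrs", "effect_sign", "eqtl_class", "significant",
]


def write_qtl_table(hits: Sequence[QTLHit], path: str | Path) -> None:
    """Write QTL hits as TSV, ordered by (trait, chromosome, position)."""
    rows = [
        {
            "trait": h.trait_id,
            "marker": h.marker_id,
            "chromosome": h.chromosome,
            "position_mb": h.position_mb,
            "lrs": float(f"{h.lrs:.6g}"),
            "effect_sign": h.effect_sign,
            "eqtl_class": h.eqtl_class,
            "significant": int(h.significant),
        }
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=QTL_TABLE_COLUMNS)
    if len(df):
        key = df["chromosome"].astype(str).map(chrom_sort_key)
        df = (
            df.assign(_key=key)
            .sort_values(["trait", "_key", "position_mb"], kind="mergesort")
            .drop(columns="_key")
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_qtl_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(QTL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: QTL table lacks columns {sorted(missing)}")
    return df
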