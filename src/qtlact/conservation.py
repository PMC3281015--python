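"""Sliding-window conservation-ratio tracks along the genome.

Given features (eQTL marker positions or SNPs) each flagged as conserved
across the two RI panels or not, the conservation ratio of a genomic
window is the observed number of conserved features in the window
divided by the number expected from the genome-wide conserved fraction:

    ratio(w) = n_conserved(w) / (n_features(w) * global_fraction).

Windows are half-open [start, start + width) so membership is
unambiguous; the ratio is undefined (NaN) in empty windows.  Parallel
tracks computed for eQTLs and for SNPs can be compared by their Pearson
correlation over shared windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import chrom_sort_key


@dataclass
class ConservationTrack:
    windows: pd.DataFrame  # chromosome, start_mb, end_mb, truncated,
    #                        n_features, n_conserved, expected, ratio
    global_fraction: float
    window_mb: float
    step_mb: float


def sliding_conservation_ratio(
    features: pd.DataFrame,
    chrom_lengths: Mapping[str, float],
    window_mb: float = 50.0,
    step_mb: float = 5.0,
) -> ConservationTrack:
    """Observed/expected conserved-feature ratio in sliding windows.

    ``features`` needs columns ``chromosome``, ``position_mb`` and a
    boolean ``conserved``.  The global conserved fraction is computed
    once over all features genome-wide.  Windows overhanging a
    chromosome end are kept (membership is by position, so they simply
    truncate) and flagged.
    """
    if window_mb <= 0 or step_mb <= 0:
        raise ValueError("window and step must be positive")
    required = {"chromosome", "position_mb", "conserved"}
    if missing := required - set(features.columns):
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")
    if features.empty:
        raise ValueError("no features")
    feats = features.copy()
    feats["chromosome"] = feats["chromosome"].astype(str)
    global_fraction = float(feats["conserved"].astype(bool).mean())

    rows = []
    for ch in sorted(chrom_lengths, key=chrom_sort_key):
        length = float(chrom_lengths[ch])
        sub = feats[feats["chromosome"] == str(ch)]
        pos = sub["position_mb"].to_numpy(dtype=float)
        cons = sub["conserved"].to_numpy(dtype=bool)
        start = 0.0
        while start < length:
            end = start + window_mb
            inside = (pos >= start) & (pos < end)
            n = int(inside.sum())
            n_cons = int(cons[inside].sum())
            expected = n * global_fraction
            ratio = n_cons / expected if expected > 0 else np.nan
            rows.append(
                {
                    "chromosome": str(ch),
                    "start_mb": start,
                    "end_mb": end,
                    "truncated": end > length,
                    "n_features": n,
                    "n_conserved": n_cons,
                    "expected": expected,
                    "ratio": ratio,
                }
            )
            start += step_mb
    return ConservationTrack(
        windows=pd.DataFrame(rows),
        global_fraction=global_fraction,
        window_mb=window_mb,
        step_mb=step_mb,
    )


def track_correlation(
    track_a: ConservationTrack, track_b: ConservationTrack
) -> float:
    """Pearson correlation of two conservation tracks over shared windows.

    Windows are matched on (chromosome, start); windows missing (NaN
    ratio) in either track are excluded.  Returns NaN when fewer than 3
    windows remain or a track is constant over them.
    """
    a = track_a.windows[["chromosome", "start_mb", "ratio"]]
    b = track_b.windows[["chromosome", "start_mb", "ratio"]]
    merged = a.merge(b, on=["chromosome", "start_mb"], suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["ratio_a", "ratio_b"])
    if len(merged) < 3:
        return float("nan")
    x = merged["ratio_a"].to_numpy()
    y = merged["ratio_b"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def eqtl_feature_table(hits, records) -> pd.DataFrame:
    """Feature table (marker position + conserved flag) from QTL hits and
    their cross-panel records, ready for the sliding-window ratio.

    Records with unknown conservation (no counterpart in the other
    panel) are treated as not conserved.
    """
    rows = []
    for hit, rec in zip(hits, records):
        rows.append(
            {
                "chromosome": hit.chromosome,
                "position_mb": hit.position_mb,
                "conserved": bool(rec.conserved_any),
            }
        )
    return pd.DataFrame(rows)


def plot_conservation_tracks(
    track_eqtl: ConservationTrack,
    track_snp: ConservationTrack,
    path,
) -> None:
    """Minimal line plot of the two tracks along a concatenated genome axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0.0
    for ch in sorted(track_eqtl.windows["chromosome"].unique(), key=chrom_sort_key):
        for track, style, label in (
            (track_eqtl, "-", "eQTLs"),
            (track_snp, "--", "SNPs"),
        ):
            sub = track.windows[track.windows["chromosome"] == ch]
            ax.plot(
                sub["start_mb"] + offset,
                sub["ratio"],
                style,
                color="tab:blue" if label == "eQTLs" else "tab:red",
                label=label if offset == 0.0 else None,
            )
        sub = track_eqtl.windows[track_eqtl.windows["chromosome"] == ch]
        offset += float(sub["end_mb"].max()) if len(sub) else 0.0
        ax.axvline(offset, color="0.8", lw=0.5)
    ax.set_xlabel("genome position (Mb, chromosomes concatenated)")
    ax.set_ylabel("conservation ratio")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
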