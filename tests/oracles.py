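"""Independent oracles used to cross-check the package's statistics.

These deliberately avoid the vectorized code paths of the package: the
LRS oracle fits both Gaussian models explicitly and evaluates their
log-likelihoods point by point; the window oracle tests every feature
against every window.
"""

from __future__ import annotations

import math

import numpy as np


def lrs_gaussian_ml_oracle(trait: np.ndarray, codes: np.ndarray) -> float:
    """LRS via explicit maximum-likelihood fits of both Gaussian models.

    Null model: one mean, one variance.  Genetic model: one mean per
    genotype group, shared variance.  Variances are the ML estimates
    (RSS/N); the statistic is twice the log-likelihood difference.
    """
    trait = np.asarray(trait, dtype=float)
    codes = np.asarray(codes)
    keep = np.isfinite(trait) & (codes >= 0)
    y = trait[keep]
    g = codes[keep]
    n = y.size

    def max_loglik(groups: list[np.ndarray]) -> float:
        rss = sum(float(((v - v.mean()) ** 2).sum()) for v in groups)
        sigma2 = rss / n
        if sigma2 == 0:
            return math.inf
        ll = 0.0
        for v in groups:
            mu = v.mean()
            for x in v:
                ll += (
                    -0.5 * math.log(2 * math.pi * sigma2)
                    - (x - mu) ** 2 / (2 * sigma2)
                )
        return ll

    ll0 = max_loglik([y])
    ll1 = max_loglik([y[g == 0], y[g == 1]])
    return 2.0 * (ll1 - ll0)


def lrs_pearson_oracle(trait: np.ndarray, codes: np.ndarray) -> float:
    """LRS via -N ln(1 - r^2) with r the trait-genotype Pearson correlation."""
    trait = np.asarray(trait, dtype=float)
    codes = np.asarray(codes)
    keep = np.isfinite(trait) & (codes >= 0)
    y = trait[keep]
    g = codes[keep].astype(float)
    r = np.corrcoef(y, g)[0, 1]
    return float(-y.size * np.log(1.0 - r * r))


def sliding_ratio_oracle(
    features, chrom_lengths, window_mb: float, step_mb: float
):
    """Every-feature-vs-every-window brute force of the conservation ratio.

    Returns a list of dicts (chromosome, start, n, n_conserved, ratio).
    """
    rows = []
    feats = list(
        features[["chromosome", "position_mb", "conserved"]].itertuples(index=False)
    )
    global_fraction = (
        sum(1 for f in feats if f.conserved) / len(feats) if feats else 0.0
    )
    for ch in sorted(chrom_lengths, key=str):
        start = 0.0
        while start < float(chrom_lengths[ch]):
            n = n_cons = 0
            for f in feats:
                if str(f.chromosome) != str(ch):
                    continue
                if start <= f.position_mb < start + window_mb:
                    n += 1
                    n_cons += bool(f.conserved)
            expected = n * global_fraction
            rows.append(
                {
                    "chromosome": str(ch),
                    "start_mb": start,
                    "n_features": n,
                    "n_conserved": n_cons,
                    "ratio": n_cons / expected if expected > 0 else float("nan"),
                }
            )
            start += step_mb
    return rows
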