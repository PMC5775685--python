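"""Alpha-diversity estimators, rarefaction curves, and Bray-Curtis matrices.

Estimators follow the classic abundance-based definitions used by
community-ecology toolkits for amplicon data:

* ``chao1``: S_obs + F1^2/(2 F2), falling back to S_obs + F1(F1-1)/2 when
  no doubletons exist (F1, F2 = numbers of singleton/doubleton OTUs).
* ``ace``: abundance-based coverage estimator with the conventional
  rare/abundant split at 10 reads and the coefficient of variation
  floored at zero.
* ``goods_coverage``: 1 - F1/N, the estimated fraction of reads drawn
  from already-observed OTUs.
* ``shannon``: -sum p_i ln p_i (natural log).
* ``simpson``: dominance D = sum p_i^2 (set ``dominance=False`` for 1-D).

Rarefaction uses the exact hypergeometric expectation of richness at a
given depth rather than Monte-Carlo resampling. Bray-Curtis matrices are
returned as :class:`skbio.DistanceMatrix`, the container the permutation
statistics consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio import DistanceMatrix

from .otu import OtuTable, relative_abundance

__all__ = [
    "ALPHA_METRICS",
    "chao1",
    "ace",
    "goods_coverage",
    "shannon",
    "simpson",
    "alpha_diversity",
    "alpha_diversity_table",
    "rarefaction_curve",
    "bray_curtis_matrix",
]

ALPHA_METRICS = ("ace", "chao1", "goods_coverage", "shannon", "simpson")


def _clean(counts) -> np.ndarray:
    x = np.asarray(counts)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValueError("negative counts")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("count vector is empty or all zeros")
    return x.astype(np.int64)


def chao1(counts) -> float:
    x = _clean(counts)
    s_obs = x.size
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace(counts, rare_threshold: int = 10) -> float:
    x = _clean(counts)
    rare = x[x <= rare_threshold]
    s_abund = int((x > rare_threshold).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if f1 == n_rare:
        # every rare OTU is a singleton: sample coverage is estimated at
        # zero and ACE is undefined; fall back to Chao1.
        return chao1(counts)
    c_ace = 1.0 - f1 / n_rare
    freqs = np.bincount(rare, minlength=rare_threshold + 1)
    i = np.arange(1, rare_threshold + 1)
    sum_term = float((i * (i - 1) * freqs[1:]).sum())
    gamma2 = max(s_rare / c_ace * sum_term / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def goods_coverage(counts) -> float:
    x = _clean(counts)
    return 1.0 - (x == 1).sum() / x.sum()


def shannon(counts) -> float:
    x = _clean(counts)
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts, dominance: bool = True) -> float:
    x = _clean(counts)
    p = x / x.sum()
    d = float((p * p).sum())
    return d if dominance else 1.0 - d


def alpha_diversity(counts, metric: str) -> float:
    """Dispatch a single alpha-diversity metric by name."""
    funcs = {
        "ace": ace,
        "chao1": chao1,
        "goods_coverage": goods_coverage,
        "shannon": shannon,
        "simpson": simpson,
    }
    if metric not in funcs:
        raise ValueError(f"unknown metric {metric!r}; choose from {ALPHA_METRICS}")
    return float(funcs[metric](counts))


def alpha_diversity_table(table: OtuTable, metrics=ALPHA_METRICS) -> pd.DataFrame:
    """Long-format (sample_id, metric, value) table over all samples."""
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        for metric in metrics:
            rows.append((sid, metric, alpha_diversity(col, metric)))
    return pd.DataFrame(rows, columns=["sample_id", "metric", "value"])


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected richness at each subsampling depth (without replacement).

    E[S(n)] = sum_i [1 - C(N - N_i, n) / C(N, n)], the exact expectation
    of observed richness when n reads are drawn without replacement from
    a sample of N total reads with per-OTU counts N_i. Non-decreasing in
    n, and equal to observed richness at n = N.
    """
    x = _clean(counts)
    n_total = int(x.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    if depths.max() > n_total:
        raise ValueError(f"depth {depths.max()} exceeds sample total {n_total}")
    # log C(N - N_i, n) - log C(N, n), with probability 0 when N - N_i < n
    out = np.empty(depths.shape, dtype=float)
    for k, n in enumerate(depths):
        rem = n_total - x
        ok = rem >= n
        log_miss = np.full(x.shape, -np.inf)
        log_miss[ok] = (
            gammaln(rem[ok] + 1)
            - gammaln(rem[ok] - n + 1)
            - (gammaln(n_total + 1) - gammaln(n_total - n + 1))
        )
        out[k] = float((1.0 - np.exp(log_miss)).sum())
    return out


def bray_curtis_matrix(table: OtuTable, input: str = "relative") -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    BC(x, y) = sum |x_i - y_i| / sum (x_i + y_i), computed on per-sample
    relative abundances (default) or raw counts. Similarity, where a
    plot or decay analysis wants it, is 1 - BC.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    if input == "relative":
        profiles = relative_abundance(table, per="sample").T
    elif input == "counts":
        if (table.sample_totals == 0).any():
            zero = [s for s, t in zip(table.sample_ids, table.sample_totals) if t == 0]
            raise ValueError(f"zero-total sample(s): {zero}")
        profiles = table.counts.T.astype(float)
    else:
        raise ValueError(f"input must be 'relative' or 'counts', got {input!r}")
    condensed = pdist(profiles, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)
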