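"""Permutation statistics on dissimilarity matrices.

ANOSIM contrasts mean ranks of between-group and within-group
dissimilarities; the Mantel test correlates the upper triangles of two
distance matrices under simultaneous row/column permutation. Both use
mid-ranks for ties and the add-one permutation p-value
``(1 + #{permuted >= observed}) / (1 + n_permutations)``, so a p-value
is never exactly zero. For small instances an exact mode enumerates
every permutation, in which case p is the fraction of the full
permutation distribution (identity included) at or above the observed
statistic.

The moving-window analysis quantifies community turnover along an
ordered station sequence: for each consecutive station pair the change
rate is ``100 * (1 - r)`` where r is the correlation (Pearson by
default) of the stations' mean relative-abundance profiles.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .otu import OtuTable, relative_abundance

__all__ = ["PermutationTestResult", "anosim", "mantel", "moving_window"]

_EPS = 1e-12  # float tolerance when counting permuted >= observed


@dataclasses.dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _anosim_stat(ranks: np.ndarray, i: np.ndarray, j: np.ndarray, labels: np.ndarray) -> float:
    within = labels[i] == labels[j]
    n = labels.size
    denom = n * (n - 1) / 4.0
    return float((ranks[~within].mean() - ranks[within].mean()) / denom)


def anosim(
    dm: DistanceMatrix,
    grouping: Mapping[str, str] | Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> PermutationTestResult:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean rank between groups - mean rank within groups) / (n(n-1)/4),
    with ranks taken over all pairwise dissimilarities (mid-ranks for
    ties), so R lies in [-1, 1]; a constant matrix yields R = 0. The
    p-value permutes the group labels.

    `grouping` is either a mapping from sample id to label or a label
    sequence aligned with ``dm.ids``.
    """
    ids = list(dm.ids)
    if isinstance(grouping, Mapping):
        labels = np.asarray([grouping[s] for s in ids])
    else:
        labels = np.asarray(list(grouping))
        if labels.size != len(ids):
            raise ValueError("grouping length does not match the matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least two groups")
    small = [str(u) for u, c in zip(uniq, counts) if c < 2]
    if small:
        raise ValueError(f"group(s) with fewer than two samples: {small}")

    n = len(ids)
    i, j = np.triu_indices(n, k=1)
    ranks = rankdata(dm.condensed_form())
    obs = _anosim_stat(ranks, i, j, labels)

    if exact:
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9 samples")
        stats = [
            _anosim_stat(ranks, i, j, labels[list(perm)])
            for perm in itertools.permutations(range(n))
        ]
        stats = np.asarray(stats)
        p = float((stats >= obs - _EPS).mean())
        return PermutationTestResult(obs, p, len(stats), None, "anosim-exact")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm_labels = labels[rng.permutation(n)]
        if _anosim_stat(ranks, i, j, perm_labels) >= obs - _EPS:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationTestResult(obs, p, n_permutations, seed, "anosim")


def _rank_square(dm: DistanceMatrix) -> np.ndarray:
    """Square symmetric matrix of mid-ranks of the condensed entries."""
    n = dm.shape[0]
    ranks = rankdata(dm.condensed_form())
    out = np.zeros((n, n))
    i, j = np.triu_indices(n, k=1)
    out[i, j] = ranks
    out[j, i] = ranks
    return out


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "spearman",
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    exact: bool = False,
) -> PermutationTestResult:
    """Mantel test of matrix correlation.

    The statistic is the Pearson (or Spearman, via rank transform of the
    upper triangles) correlation between the two condensed matrices; the
    null distribution permutes rows and columns of the second matrix
    simultaneously. ``alternative="greater"`` (default) tests for
    positive association, the usual direction in distance-decay
    analyses; ``"two-sided"`` compares absolute values.
    """
    if list(dm1.ids) != list(dm2.ids):
        raise ValueError("matrices must share the same sample ids in the same order")
    n = dm1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    if method == "spearman":
        a_sq, b_sq = _rank_square(dm1), _rank_square(dm2)
    elif method == "pearson":
        a_sq, b_sq = np.asarray(dm1.data, float), np.asarray(dm2.data, float)
    else:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    i, j = np.triu_indices(n, k=1)
    a = a_sq[i, j]
    if a.std() == 0 or b_sq[i, j].std() == 0:
        raise ValueError("zero-variance distance triangle")
    a = (a - a.mean()) / a.std()

    def corr(perm: Sequence[int]) -> float:
        b = b_sq[np.ix_(perm, perm)][i, j]
        return float((a * (b - b.mean())).mean() / b.std())

    obs = corr(range(n))

    def extreme(x: float) -> bool:
        if alternative == "greater":
            return x >= obs - _EPS
        if alternative == "two-sided":
            return abs(x) >= abs(obs) - _EPS
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")

    if exact:
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8 samples")
        stats = [corr(perm) for perm in itertools.permutations(range(n))]
        p = float(np.mean([extreme(s) for s in stats]))
        return PermutationTestResult(obs, p, math.factorial(n), None, f"mantel-{method}-exact")

    rng = np.random.default_rng(seed)
    hits = sum(extreme(corr(rng.permutation(n))) for _ in range(n_permutations))
    p = (1 + hits) / (1 + n_permutations)
    return PermutationTestResult(obs, p, n_permutations, seed, f"mantel-{method}")


def moving_window(
    table: OtuTable,
    ordered_stations: Sequence[str],
    station_of: Mapping[str, str] | pd.Series,
    method: str = "pearson",
) -> pd.DataFrame:
    """Community change rate between consecutive stations along a river.

    Samples are averaged per station on relative-abundance profiles
    (stations with several samples contribute their mean profile); for
    each consecutive pair in `ordered_stations` (upstream to downstream)
    the change rate is ``100 * (1 - r)`` with r the Pearson (or
    Spearman) correlation of the two profiles. The value is reported
    uncapped, so anticorrelated profiles can exceed 100.
    """
    if isinstance(station_of, pd.Series):
        station_of = station_of.to_dict()
    rel = relative_abundance(table, per="sample")
    profiles: dict[str, np.ndarray] = {}
    for st in ordered_stations:
        cols = [k for k, s in enumerate(table.sample_ids) if station_of.get(s) == st]
        if not cols:
            missing = [
                s for s in ordered_stations
                if not any(station_of.get(x) == s for x in table.sample_ids)
            ]
            raise ValueError(f"station(s) without samples: {missing}")
        profiles[st] = rel[:, cols].mean(axis=1)
    rows = []
    for up, down in zip(ordered_stations, ordered_stations[1:]):
        x, y = profiles[up], profiles[down]
        if method == "spearman":
            x, y = rankdata(x), rankdata(y)
        elif method != "pearson":
            raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((up, down, 100.0 * (1.0 - r)))
    return pd.DataFrame(rows, columns=["upstream_station", "downstream_station", "change_rate"])
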