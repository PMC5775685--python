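"""Sloan neutral community model: fit, prediction band, and partitioning.

The model treats each local community as a fixed-size assembly of N
individuals undergoing a birth-death-immigration process: when an
individual dies it is replaced by an immigrant drawn from the
metacommunity with probability m, or by reproduction of a local
individual with probability 1 - m. At stationarity the local relative
abundance of an OTU with metacommunity relative abundance p follows a
Beta(N m p, N m (1 - p)) distribution, so the probability that the OTU
is *detected* in a community (its frequency of occurrence across
communities) is the upper tail of that Beta beyond the detection limit
d:

    freq(p) = 1 - I_d(N m p, N m (1 - p))

where I is the regularized incomplete beta function. Fitting reduces to
a one-dimensional least-squares problem in m: N is the (equal) number
of reads per sample and d defaults to one read (1/N). OTUs are then
partitioned as occurring **above**, within (**neutral**), or **below**
a binomial confidence band around the predicted frequency.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .otu import OtuTable, occupancy, relative_abundance

__all__ = [
    "NeutralFit",
    "predict_occurrence",
    "fit_immigration_rate",
    "fit_neutral_model",
    "partition_otus",
]


def predict_occurrence(p, N: int, m: float, detection_limit: float):
    """Neutral-model occurrence frequency for mean relative abundance(s) `p`.

    Vectorized over `p`. Degenerate endpoints are exact: p = 0 gives
    frequency 0 and p = 1 gives frequency 1.
    """
    if not 0 < m <= 1:
        raise ValueError(f"m must be in (0, 1], got {m}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if not 0 < detection_limit < 1:
        raise ValueError(f"detection_limit must be in (0, 1), got {detection_limit}")
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("p must lie in [0, 1]")
    a = N * m * p_arr
    b = N * m * (1.0 - p_arr)
    with np.errstate(invalid="ignore"):
        freq = 1.0 - special.betainc(a, b, detection_limit)
    freq = np.where(p_arr == 0, 0.0, freq)
    freq = np.where(p_arr == 1, 1.0, freq)
    return float(freq) if np.isscalar(p) else freq


@dataclasses.dataclass
class NeutralFit:
    """Result of fitting the neutral model to an OTU table.

    ``per_otu`` has one row per fitted OTU: otu_id, mean_rel_abundance,
    observed_frequency, predicted_frequency, ci_lower, ci_upper,
    partition.
    """

    m: float
    N: int
    detection_limit: float
    r_squared: float
    n_samples: int
    per_otu: pd.DataFrame
    confidence: float = 0.95
    ci_method: str = "binomial"

    def partition_percentages(self) -> dict[str, float]:
        frac = self.per_otu["partition"].value_counts(normalize=True)
        return {k: 100.0 * float(frac.get(k, 0.0)) for k in ("above", "neutral", "below")}

    def summary(self) -> dict:
        out = {
            "m": self.m,
            "N": self.N,
            "detection_limit": self.detection_limit,
            "r_squared": self.r_squared,
            "n_otus": int(len(self.per_otu)),
            "n_samples": self.n_samples,
            "confidence": self.confidence,
        }
        for k, v in self.partition_percentages().items():
            out[f"pct_{k}"] = v
        return out

    def write(self, summary_path: str | Path, per_otu_path: str | Path | None = None) -> None:
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        if per_otu_path is not None:
            self.per_otu.to_csv(per_otu_path, sep="\t", index=False, float_format="%.10g")

    def prediction_curve(self, n_points: int = 200) -> pd.DataFrame:
        """Model curve with confidence band on a log-spaced abundance grid."""
        p_obs = self.per_otu["mean_rel_abundance"]
        grid = np.logspace(np.log10(max(p_obs.min(), 1e-9)), np.log10(p_obs.max()), n_points)
        pred = predict_occurrence(grid, self.N, self.m, self.detection_limit)
        lo, hi = _CI_METHODS[self.ci_method](pred, self.n_samples, self.confidence)
        return pd.DataFrame(
            {"mean_rel_abundance": grid, "predicted": pred, "ci_lower": lo, "ci_upper": hi}
        )


def _wilson_interval(p_hat, n: int, confidence: float):
    """Wilson score interval for a binomial proportion (vectorized)."""
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    p_hat = np.asarray(p_hat, dtype=float)
    denom = 1.0 + z * z / n
    center = (p_hat + z * z / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z * z / (4 * n * n)) / denom
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def _binomial_interval(p_pred, n: int, confidence: float):
    """Exact central prediction interval for an observed binomial frequency.

    Bounds are binomial quantiles of X ~ Bin(n, p_pred) divided by n, so
    an observed frequency of exactly 0 or 1 stays inside the band
    whenever that outcome is probable under the model — the behaviour a
    band around occurrence frequencies needs at the extremes, where a
    normal-approximation interval never reaches 0 or 1.
    """
    alpha = 1.0 - confidence
    p_pred = np.asarray(p_pred, dtype=float)
    lo = stats.binom.ppf(alpha / 2.0, n, p_pred) / n
    hi = stats.binom.ppf(1.0 - alpha / 2.0, n, p_pred) / n
    return lo, hi


_CI_METHODS = {"binomial": _binomial_interval, "wilson": _wilson_interval}


def fit_immigration_rate(
    mean_p: np.ndarray, observed_freq: np.ndarray, N: int, detection_limit: float
) -> tuple[float, float, np.ndarray]:
    """Least-squares estimate of m from (abundance, frequency) pairs.

    Minimizes sum_i (obs_i - freq(p_i; m))^2 by bounded scalar search on
    m in (1e-6, 1] to absolute tolerance 1e-8. Returns
    (m_hat, r_squared, predicted frequencies); R^2 = 1 - SS_res/SS_tot
    and may be negative for a fit worse than the mean.
    """
    mean_p = np.asarray(mean_p, float)
    obs = np.asarray(observed_freq, float)

    def sse(m: float) -> float:
        pred = predict_occurrence(mean_p, N, m, detection_limit)
        return float(((obs - pred) ** 2).sum())

    res = optimize.minimize_scalar(
        sse, bounds=(1e-6, 1.0), method="bounded", options={"xatol": 1e-8}
    )
    m_hat = float(res.x)
    pred = predict_occurrence(mean_p, N, m_hat, detection_limit)
    ss_res = float(((obs - pred) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    return m_hat, 1.0 - ss_res / ss_tot, pred


def fit_neutral_model(
    table: OtuTable,
    detection_limit: float | None = None,
    confidence: float = 0.95,
    ci_method: str = "binomial",
) -> NeutralFit:
    """Fit the immigration rate m to an equal-depth OTU table.

    Per OTU, the mean relative abundance across samples is the abscissa
    and the occupancy (fraction of samples where detected) the observed
    frequency. N is the common per-sample read depth and the detection
    limit defaults to a single read, 1/N. m is found by bounded scalar
    least squares on (1e-6, 1] to an absolute tolerance of 1e-8;
    R^2 = 1 - SS_res/SS_tot is reported as-is (it may be negative).
    OTUs absent from every sample are excluded. The per-OTU confidence
    band and above/neutral/below partition are filled in at the stated
    confidence via :func:`partition_otus`.
    """
    depths = table.sample_totals
    if table.n_samples == 0 or depths.max() == 0:
        raise ValueError("table has no reads")
    if depths.min() != depths.max():
        raise ValueError(
            "samples are at unequal depths; subsample to a common depth first "
            f"(depths range {depths.min()}-{depths.max()})"
        )
    N = int(depths[0])
    d = 1.0 / N if detection_limit is None else float(detection_limit)
    mean_p = relative_abundance(table, per="sample").mean(axis=1)
    obs = occupancy(table).to_numpy()
    present = mean_p > 0
    mean_p, obs = mean_p[present], obs[present]
    otu_ids = [o for o, keep in zip(table.otu_ids, present) if keep]
    if len(otu_ids) < 10:
        raise ValueError(f"need at least 10 detected OTUs to fit, got {len(otu_ids)}")
    if np.all(obs == 1.0):
        raise ValueError("degenerate table: every OTU occurs in every sample")

    m_hat, r_squared, pred = fit_immigration_rate(mean_p, obs, N, d)
    per_otu = pd.DataFrame(
        {
            "otu_id": otu_ids,
            "mean_rel_abundance": mean_p,
            "observed_frequency": obs,
            "predicted_frequency": pred,
        }
    )
    fit = NeutralFit(
        m=m_hat,
        N=N,
        detection_limit=d,
        r_squared=r_squared,
        n_samples=table.n_samples,
        per_otu=per_otu,
        confidence=confidence,
        ci_method=ci_method,
    )
    return partition_otus(fit, confidence=confidence, ci_method=ci_method)


def partition_otus(
    fit: NeutralFit, confidence: float = 0.95, ci_method: str | None = None
) -> NeutralFit:
    """Label each OTU above/neutral/below the model's confidence band.

    The band around each predicted frequency is, by default, the exact
    central binomial prediction interval with success probability equal
    to the predicted frequency and n equal to the number of samples
    (``ci_method="binomial"``); a Wilson score interval is available via
    ``ci_method="wilson"``. An OTU is "above" when its observed
    frequency exceeds the upper bound, "below" when under the lower
    bound, and "neutral" otherwise. Returns the fit with
    ci_lower/ci_upper and partition columns (re)computed.
    """
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    ci_method = fit.ci_method if ci_method is None else ci_method
    if ci_method not in _CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(_CI_METHODS)}, got {ci_method!r}")
    per = fit.per_otu.copy()
    lo, hi = _CI_METHODS[ci_method](
        per["predicted_frequency"].to_numpy(), fit.n_samples, confidence
    )
    obs = per["observed_frequency"].to_numpy()
    partition = np.where(obs > hi, "above", np.where(obs < lo, "below", "neutral"))
    per["ci_lower"], per["ci_upper"], per["partition"] = lo, hi, partition
    return dataclasses.replace(fit, per_otu=per, confidence=confidence, ci_method=ci_method)
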