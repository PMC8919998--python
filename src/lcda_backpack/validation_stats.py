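"""Agreement and equivalence statistics for clustered prediction-measurement pairs.

Repeated measurements on the same participant are not independent, so the
bias (mean of predicted - measured) is estimated from a random-intercept
model: the two variance components are estimated by the one-way ANOVA
method of moments and participant means are combined with exact
generalized-least-squares weights n_i / (n_i * tau2 + sigma2).  Interval
estimation uses the cluster (participant-level) percentile bootstrap, and
equivalence is declared by the two one-sided t-test procedure on
participant-level mean differences against limits of +/-10% of the mean
measured rate.  Lin's concordance correlation coefficient summarizes
agreement on the pooled pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ValidationReport",
    "clustered_bias",
    "variance_components",
    "percentile_bootstrap_ci",
    "tost_equivalence",
    "concordance_correlation",
    "mad_outlier_screen",
    "build_validation_report",
]

MAD_SCALE = 1.4826  # consistency constant for normal data


def _check_clusters(ids: np.ndarray) -> np.ndarray:
    ids = np.asarray(ids)
    if ids.size == 0:
        raise ValueError("empty input")
    return ids


def variance_components(values, ids) -> tuple[float, float]:
    """One-way ANOVA method-of-moments estimates (sigma2_within, tau2_between).

    ``tau2`` is clipped at zero.  Closed-form, so it can serve as an oracle
    for the GLS bias weights.
    """
    v = np.asarray(values, dtype=float)
    ids = _check_clusters(ids)
    uniq, inv = np.unique(ids, return_inverse=True)
    k = uniq.size
    n = v.size
    if k < 2:
        raise ValueError("need >= 2 clusters to estimate variance components")
    n_i = np.bincount(inv)
    sums = np.bincount(inv, weights=v)
    means = sums / n_i
    ssw = float(np.sum((v - means[inv]) ** 2))
    msw = ssw / (n - k) if n > k else 0.0
    grand = v.mean()
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    msb = ssb / (k - 1)
    n0 = (n - np.sum(n_i**2) / n) / (k - 1)
    tau2 = max(0.0, (msb - msw) / n0)
    return msw, tau2


def clustered_bias(predicted=None, measured=None, ids=None, *, differences=None):
    """GLS-weighted mean paired difference and the pooled SD of differences.

    Accepts either ``predicted``/``measured`` arrays or precomputed
    ``differences`` (= predicted - measured), plus participant ``ids``.
    Returns ``(bias, bias_sd)`` where ``bias_sd`` is the sample SD of all
    pooled paired differences (the descriptive spread usually quoted next to
    the bias).  With balanced clusters the GLS weights are equal and the
    bias is exactly the mean of participant means.
    """
    if differences is None:
        differences = np.asarray(predicted, dtype=float) - np.asarray(measured, dtype=float)
    d = np.asarray(differences, dtype=float)
    ids = _check_clusters(ids)
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    uniq, inv = np.unique(ids, return_inverse=True)
    bias_sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    if uniq.size < 2:
        warnings.warn(
            "single participant: falling back to the simple mean difference",
            UserWarning,
            stacklevel=2,
        )
        return float(d.mean()), bias_sd
    sigma2, tau2 = variance_components(d, ids)
    n_i = np.bincount(inv)
    means = np.bincount(inv, weights=d) / n_i
    if sigma2 == 0.0 and tau2 == 0.0:
        weights = n_i.astype(float)
    else:
        weights = n_i / (n_i * tau2 + sigma2)
    bias = float(np.sum(weights * means) / np.sum(weights))
    return bias, bias_sd


def _participant_means(values: np.ndarray, ids: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(ids, return_inverse=True)
    n_i = np.bincount(inv)
    return np.bincount(inv, weights=values) / n_i


def percentile_bootstrap_ci(
    values,
    ids,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    level: float = 0.90,
    n_boot: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Cluster percentile bootstrap CI for a statistic of clustered values.

    Participants (clusters) are resampled with replacement; each resampled
    cluster keeps all its observations and is treated as a new cluster.  The
    default statistic is the GLS clustered bias of ``values``.
    Deterministic given ``seed``.
    """
    v = np.asarray(values, dtype=float)
    ids = _check_clusters(ids)
    uniq, inv = np.unique(ids, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need >= 2 participants for a cluster bootstrap")
    if statistic is None:
        statistic = lambda d, g: clustered_bias(differences=d, ids=g)[0]
    cluster_idx = [np.flatnonzero(inv == j) for j in range(k)]
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, k, size=(n_boot, k))
    out = np.empty(n_boot)
    for b in range(n_boot):
        chosen = draws[b]
        idx = np.concatenate([cluster_idx[j] for j in chosen])
        new_ids = np.repeat(np.arange(k), [cluster_idx[j].size for j in chosen])
        out[b] = statistic(v[idx], new_ids)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(out, [alpha, 1.0 - alpha])
    return float(low), float(high)


def tost_equivalence(
    predicted=None,
    measured=None,
    ids=None,
    *,
    differences=None,
    mean_measured: float | None = None,
    limit_fraction: float = 0.10,
    alpha: float = 0.05,
) -> tuple[bool, float, float]:
    """Two one-sided t-tests of equivalence on participant-level mean differences.

    The equivalence limit is ``limit_fraction * mean(measured)``.  The TOST
    p-value is the larger of the two one-sided p-values; the pass verdict
    requires the (1 - 2*alpha) CI of the mean difference — equivalently both
    one-sided tests at ``alpha`` — to lie strictly inside (-delta, +delta).
    Degrees of freedom count participants, honoring the clustering.

    Returns ``(tost_passed, tost_p, equivalence_limit)``.
    """
    if differences is None:
        differences = np.asarray(predicted, dtype=float) - np.asarray(measured, dtype=float)
    d = np.asarray(differences, dtype=float)
    ids = _check_clusters(ids)
    if mean_measured is None:
        if measured is None:
            raise ValueError("provide measured values or mean_measured for the limit")
        mean_measured = float(np.mean(measured))
    delta = limit_fraction * abs(mean_measured)
    if delta <= 0:
        raise ValueError("equivalence limit must be positive")
    pm = _participant_means(d, ids)
    if pm.size < 2:
        if d.size < 2:
            raise ValueError("need >= 2 participants or >= 2 observations")
        warnings.warn(
            "single participant: TOST falls back to observation-level units",
            UserWarning,
            stacklevel=2,
        )
        pm = d
    n = pm.size
    mean = float(pm.mean())
    sd = float(pm.std(ddof=1))
    if sd == 0.0:
        passed = abs(mean) < delta
        return passed, 0.0 if passed else 1.0, delta
    se = sd / np.sqrt(n)
    df = n - 1
    t_lower = (mean + delta) / se  # H0: mean <= -delta
    t_upper = (mean - delta) / se  # H0: mean >= +delta
    p_lower = stats.t.sf(t_lower, df)
    p_upper = stats.t.cdf(t_upper, df)
    tost_p = float(max(p_lower, p_upper))
    half = stats.t.ppf(1.0 - alpha, df) * se
    ci_low, ci_high = mean - half, mean + half
    passed = (-delta < ci_low) and (ci_high < delta)
    return bool(passed), tost_p, delta


def concordance_correlation(predicted, measured) -> float:
    """Lin's concordance correlation coefficient on pooled pairs.

    CCC = 2 cov(p, m) / (var(p) + var(m) + (mean p - mean m)^2) with
    population (1/n) moments.
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    var_p = p.var()
    var_m = m.var()
    if var_p == 0.0 and var_m == 0.0:
        raise ValueError("zero variance in both vectors: CCC undefined")
    cov = np.mean((p - p.mean()) * (m - m.mean()))
    return float(2.0 * cov / (var_p + var_m + (p.mean() - m.mean()) ** 2))


def mad_outlier_screen(values, cutoff: float = 3.0) -> np.ndarray:
    """Median-absolute-deviation outlier mask (True = outlier).

    Flags values whose distance from the median exceeds ``cutoff`` times the
    normal-consistent scaled MAD (1.4826 * MAD).  Never mutates the input.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need >= 3 values for the MAD screen")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0.0:
        if np.all(v == med):
            return np.zeros(v.shape, dtype=bool)
        warnings.warn(
            "MAD is zero with non-identical values: flagging every value off "
            "the median",
            UserWarning,
            stacklevel=2,
        )
        return v != med
    return np.abs(v - med) / (MAD_SCALE * mad) > cutoff


@dataclass(frozen=True)
class ValidationReport:
    """Agreement summary for one set of prediction-measurement pairs."""

    n_pairs: int
    n_participants: int
    bias: float  # W/kg
    bias_sd: float  # W/kg, SD of pooled paired differences
    ci90: tuple[float, float]  # W/kg, cluster bootstrap percentile
    ccc: float
    equivalence_limit: float  # W/kg
    tost_passed: bool
    tost_p: float
    label: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def summary(self) -> str:
        lo, hi = self.ci90
        return (
            f"bias, {self.bias:.2f} ± {self.bias_sd:.2f} W·kg⁻¹; "
            f"90% CI, {lo:.2f} to {hi:.2f} W·kg⁻¹; "
            f"CCC, {self.ccc:.3f}; "
            f"equivalent: {'yes' if self.tost_passed else 'no'} "
            f"(p = {self.tost_p:.4g}, limit ±{self.equivalence_limit:.2f})"
        )


def build_validation_report(
    predicted,
    measured,
    ids,
    limit_fraction: float = 0.10,
    n_boot: int = 10000,
    seed: int | None = None,
    label: str = "",
) -> ValidationReport:
    """Full agreement/equivalence report for clustered paired data."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    ids = _check_clusters(ids)
    d = p - m
    bias, bias_sd = clustered_bias(differences=d, ids=ids)
    n_participants = int(np.unique(ids).size)
    if n_participants >= 2:
        ci = percentile_bootstrap_ci(d, ids, n_boot=n_boot, seed=seed)
    else:
        ci = (bias, bias)
    _, tost_p, delta = tost_equivalence(
        differences=d, ids=ids, mean_measured=float(m.mean()), limit_fraction=limit_fraction
    )
    # the pass verdict applies the stated criterion — the 90% CI (cluster
    # percentile bootstrap) inside the open equivalence interval
    passed = (-delta < ci[0]) and (ci[1] < delta)
    return ValidationReport(
        n_pairs=int(d.size),
        n_participants=n_participants,
        bias=bias,
        bias_sd=bias_sd,
        ci90=(ci[0], ci[1]),
        ccc=concordance_correlation(p, m),
        equivalence_limit=delta,
        tost_passed=passed,
        tost_p=tost_p,
        label=label,
    )
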