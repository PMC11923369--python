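"""The cross-replicate significance protocol and curve-comparison statistics.

The decision rule: two measurement series (e.g. per-domain RMSD traces from
two proteins) are each smoothed with an exponentially weighted moving average
(EWMA, span = 10% of the series length by default), compared with the
two-sample Kolmogorov-Smirnov test, and the comparison is called *significant*
only when every simulation replicate yields D > 0.55 with p < 0.001, and
*insignificant* only when every replicate yields D < 0.45; anything else is
inconclusive.

Caveat documented up front: applying the KS test to EWMA-smoothed series
treats strongly autocorrelated points as independent, so the nominal p-values
are anti-conservative.  The rule is implemented verbatim; an optional
effective-sample-size-corrected p-value is exposed for diagnostics
(:func:`ks_compare` with ``ess_correction=True``) and is off by default.
No multiple-testing correction is applied across comparison grids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EwmaSpec",
    "VerdictRule",
    "Verdict",
    "ewma",
    "snr",
    "ks_compare",
    "effective_sample_size",
    "replicate_verdict",
    "wilcoxon_compare",
    "wilcoxon_replicate_verdict",
    "frechet_distance",
    "EquilibrationCut",
    "suggest_equilibration_cut",
]

SIGNIFICANT = "significant"
INSIGNIFICANT = "insignificant"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class EwmaSpec:
    """Recursive EWMA with alpha = 2/(span+1); span defaults to 10% of length."""

    span: int

    def __post_init__(self) -> None:
        if self.span < 1:
            raise ValueError("span must be >= 1")

    @property
    def alpha(self) -> float:
        return 2.0 / (self.span + 1.0)

    @classmethod
    def fraction_of(cls, n: int, fraction: float = 0.10) -> "EwmaSpec":
        return cls(span=max(1, int(round(fraction * n))))


@dataclass(frozen=True)
class VerdictRule:
    """Thresholds of the cross-replicate significance decision."""

    d_significant: float = 0.55
    d_insignificant: float = 0.45
    p_max: float = 0.001
    require_all_replicates: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_insignificant < self.d_significant <= 1.0):
            raise ValueError("need 0 <= d_insignificant < d_significant <= 1")

    def to_dict(self) -> dict:
        return {"d_significant": self.d_significant,
                "d_insignificant": self.d_insignificant,
                "p_max": self.p_max,
                "require_all_replicates": self.require_all_replicates}


@dataclass(frozen=True)
class Verdict:
    """Outcome of applying a VerdictRule to per-replicate test records."""

    outcome: str                                  # significant|insignificant|inconclusive
    replicates: tuple[tuple[float, float], ...]   # (statistic, p) per replicate
    rule: VerdictRule

    def to_dict(self) -> dict:
        return {"outcome": self.outcome,
                "replicates": [{"D": d, "p": p} for d, p in self.replicates],
                "rule": self.rule.to_dict()}


def ewma(series: Sequence[float] | np.ndarray, spec: EwmaSpec | int) -> np.ndarray:
    """y0 = x0; yt = alpha*xt + (1-alpha)*y(t-1), alpha = 2/(span+1)."""
    if not isinstance(spec, EwmaSpec):
        spec = EwmaSpec(span=int(spec))
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("series must be non-empty")
    return pd.Series(x).ewm(span=spec.span, adjust=False).mean().to_numpy()


def snr(series: Sequence[float] | np.ndarray) -> float:
    """Signal-to-noise ratio: mean / population standard deviation."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("SNR needs at least 2 points")
    mean = float(np.mean(x))
    sd = float(np.std(x))
    if sd == 0.0:
        warnings.warn("zero variance; SNR reported as infinity")
        return math.inf if mean >= 0 else -math.inf
    return mean / sd


def effective_sample_size(series: np.ndarray, max_lag: int | None = None) -> float:
    """n / (1 + 2*sum of positive-prefix autocorrelations) (initial positive
    sequence truncation)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 1.0
    if max_lag is None:
        max_lag = n - 1
    tau = 1.0
    for lag in range(1, max_lag):
        rho = float(np.dot(x[:-lag], x[lag:])) / denom
        if rho <= 0:
            break
        tau += 2.0 * rho
    return max(1.0, n / tau)


def ks_compare(series_a: Sequence[float], series_b: Sequence[float],
               ess_correction: bool = False) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison -> (D, asymptotic p).

    With ``ess_correction=True`` the p-value is recomputed from the same D but
    with each sample size shrunk to its autocorrelation-based effective sample
    size (diagnostic only; the verdict rule uses the uncorrected p).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both series must be non-empty")
    d, p = sps.ks_2samp(a, b, method="asymp")
    if ess_correction:
        na, nb = effective_sample_size(a), effective_sample_size(b)
        en = na * nb / (na + nb)
        p = float(sps.kstwobign.sf(d * (math.sqrt(en) + 0.12 + 0.11 / math.sqrt(en))))
    return float(d), float(p)


def replicate_verdict(pairs: Sequence[tuple[float, float]],
                      rule: VerdictRule = VerdictRule()) -> Verdict:
    """Aggregate per-replicate (D, p) records into the three-way verdict.

    significant  iff every replicate has D > d_significant and p < p_max;
    insignificant iff every replicate has D < d_insignificant;
    inconclusive otherwise.
    """
    if not pairs:
        raise ValueError("at least one replicate record is required")
    records = tuple((float(d), float(p)) for d, p in pairs)
    if all(d > rule.d_significant and p < rule.p_max for d, p in records):
        outcome = SIGNIFICANT
    elif all(d < rule.d_insignificant for d, p in records):
        outcome = INSIGNIFICANT
    else:
        outcome = INCONCLUSIVE
    return Verdict(outcome=outcome, replicates=records, rule=rule)


def wilcoxon_compare(curve_a: Sequence[float], curve_b: Sequence[float],
                     mapping: Sequence[tuple[int, int]] | None = None,
                     p_max: float = 0.001) -> tuple[float, float, str]:
    """Paired Wilcoxon signed-rank comparison of two residue-indexed curves.

    ``mapping`` pairs 0-based positions of A with positions of B (aligned
    residue pairs); identity over the common length when omitted.  Returns
    ``(W, p, verdict)`` where the verdict for this single comparison is
    significant iff p < p_max with a nonzero statistic; all-zero differences
    are insignificant by convention.  Two-sided test.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if mapping is None:
        n = min(a.size, b.size)
        mapping = [(i, i) for i in range(n)]
    if len(mapping) < 10:
        raise ValueError("mapping must pair at least 10 positions")
    ia = np.array([m[0] for m in mapping])
    ib = np.array([m[1] for m in mapping])
    diffs = a[ia] - b[ib]
    if np.all(diffs == 0):
        return 0.0, 1.0, INSIGNIFICANT
    w, p = sps.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided")
    verdict = SIGNIFICANT if (p < p_max and np.any(diffs != 0)) else INSIGNIFICANT
    return float(w), float(p), verdict


def wilcoxon_replicate_verdict(results: Sequence[tuple[float, float, str]],
                               p_max: float = 0.001) -> Verdict:
    """Cross-replicate aggregation of Wilcoxon comparisons.

    significant iff every replicate's comparison is individually significant;
    insignificant iff none is; inconclusive otherwise.
    """
    if not results:
        raise ValueError("at least one replicate record is required")
    flags = [v == SIGNIFICANT for _, _, v in results]
    if all(flags):
        outcome = SIGNIFICANT
    elif not any(flags):
        outcome = INSIGNIFICANT
    else:
        outcome = INCONCLUSIVE
    rule = VerdictRule(p_max=p_max)
    return Verdict(outcome=outcome,
                   replicates=tuple((w, p) for w, p, _ in results), rule=rule)


# ---------------------------------------------------------------------------
# Discrete Frechet distance

def frechet_distance(curve_a: Sequence[float] | np.ndarray,
                     curve_b: Sequence[float] | np.ndarray) -> float:
    """Discrete Frechet ("dog-leash") distance between two sampled curves.

    Accepts 1-D value-only curves (compared on |a_i - b_j|, i.e. unit index
    spacing contributes nothing to the ground distance) or 2-D point arrays
    (Euclidean ground distance).  Dynamic programming over the coupling
    lattice; symmetric; zero for identical curves.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("curves must be non-empty")
    if a.ndim == 1 and b.ndim == 1:
        dist = np.abs(a[:, None] - b[None, :])
    else:
        if a.ndim == 1:
            a = a[:, None]
        if b.ndim == 1:
            b = b[:, None]
        dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    n, m = dist.shape
    dp = np.empty_like(dist)
    dp[0, 0] = dist[0, 0]
    for j in range(1, m):
        dp[0, j] = max(dp[0, j - 1], dist[0, j])
    for i in range(1, n):
        dp[i, 0] = max(dp[i - 1, 0], dist[i, 0])
        row, prev = dp[i], dp[i - 1]
        drow = dist[i]
        for j in range(1, m):
            row[j] = max(drow[j], min(prev[j], row[j - 1], prev[j - 1]))
    return float(dp[-1, -1])


# ---------------------------------------------------------------------------
# Equilibration-cut suggestion

@dataclass(frozen=True)
class EquilibrationCut:
    """Suggested production start frame, or a not-converged flag."""

    frame: int | None
    converged: bool
    slope_tol: float
    window: int


def suggest_equilibration_cut(rmsd_values: Sequence[float] | np.ndarray,
                              spec: EwmaSpec | None = None,
                              slope_tol: float = 1e-4,
                              window: int | None = None) -> EquilibrationCut:
    """First frame from which the EWMA of an RMSD trace has settled.

    The trace is EWMA-smoothed (span = 10% of length by default), then the
    cut is the first index ``i`` such that the least-squares slope of the
    smoothed trace over the leading window ``[i, i + window)`` is at most
    ``slope_tol`` (Angstrom per frame).  Window defaults to 10% of the length.
    A flat trace yields frame 0; a trace that never settles is flagged as not
    converged.
    """
    x = np.asarray(rmsd_values, dtype=float)
    n = x.size
    if window is None:
        window = max(2, int(round(0.10 * n)))
    if n <= window:
        raise ValueError("series must be longer than the window")
    if spec is None:
        spec = EwmaSpec.fraction_of(n)
    smooth = ewma(x, spec)
    t = np.arange(window, dtype=float)
    t_c = t - t.mean()
    denom = float(np.dot(t_c, t_c))
    for i in range(0, n - window + 1):
        seg = smooth[i:i + window]
        slope = float(np.dot(t_c, seg - seg.mean())) / denom
        if slope <= slope_tol:
            return EquilibrationCut(frame=i, converged=True,
                                    slope_tol=slope_tol, window=window)
    return EquilibrationCut(frame=None, converged=False,
                            slope_tol=slope_tol, window=window)
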