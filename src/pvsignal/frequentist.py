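"""Frequentist disproportionality statistics and the likelihood-ratio test.

ROR, PRR and IC are closed-form per-cell statistics with normal-approximation
intervals on the log (respectively log2) scale; an (AE, drug) pair is flagged
when the interval's lower bound clears a cutoff.  The likelihood-ratio-test
method (LRT) scans all AEs for one fixed drug with the maximum of per-AE
binomial log-likelihood ratios and obtains its p-value by Monte Carlo
simulation under the row-margin null, which controls the family-wise error
over AEs.

Array inputs are accepted everywhere a cell count appears, so a whole drug
column is evaluated in one call; the ``TwoByTwo`` wrappers cover the scalar
case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import TwoByTwo, DrugEventTable

__all__ = [
    "IntervalEstimate",
    "LrtResult",
    "ror",
    "prr",
    "ic",
    "ror_arrays",
    "prr_arrays",
    "ic_arrays",
    "lrt_llr",
    "lrt_statistic",
    "lrt_test",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a normal-approximation interval.

    ``sd`` is the standard deviation on the scale the interval is built on
    (log for ROR/PRR, the IC/log2 scale for IC).  ``defined`` is False when a
    zero cell makes the estimate or its variance undefined; an undefined
    estimate never signals.
    """

    point: float
    sd: float
    lower: float
    upper: float
    confidence: float
    defined: bool

    def is_signal(self, cutoff: float) -> bool:
        return bool(self.defined and self.lower > cutoff)


def _z(confidence: float) -> float:
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    return float(stats.norm.ppf(0.5 + confidence / 2.0))


def ror_arrays(n_ij, n_i_dot, n_dot_j, n_dot_dot, confidence: float = 0.95):
    """Reporting odds ratio with CI for vectors of cells.

    ROR = n_ij (n_.. - n_i. - n_.j + n_ij) / ((n_i. - n_ij)(n_.j - n_ij));
    the variance of log ROR is the sum of the four reciprocal cells.  The
    estimate is undefined when any of the four cells is zero.

    Returns ``(point, sd, lower, upper, defined)`` arrays.
    """
    a = np.asarray(n_ij, dtype=float)
    b = np.asarray(n_i_dot, dtype=float) - a
    c = np.asarray(n_dot_j, dtype=float) - a
    d = np.asarray(n_dot_dot, dtype=float) - np.asarray(n_i_dot, dtype=float) - c
    defined = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    z = _z(confidence)
    with np.errstate(divide="ignore", invalid="ignore"):
        point = np.where(defined, a * d / np.where(defined, b * c, 1.0), np.nan)
        sd = np.sqrt(
            np.where(defined, 1.0 / np.where(a > 0, a, 1) + 1.0 / np.where(b > 0, b, 1)
                     + 1.0 / np.where(c > 0, c, 1) + 1.0 / np.where(d > 0, d, 1), np.nan)
        )
        log_point = np.log(point)
        lower = np.exp(log_point - z * sd)
        upper = np.exp(log_point + z * sd)
    return point, sd, lower, upper, defined


def prr_arrays(n_ij, n_i_dot, n_dot_j, n_dot_dot, confidence: float = 0.95):
    """Proportional reporting ratio with CI for vectors of cells.

    PRR = (n_ij / n_i.) / ((n_.j - n_ij) / (n_.. - n_i.)); the variance of
    log PRR is 1/n_ij - 1/n_i. + 1/(n_.j - n_ij) - 1/(n_.. - n_i.).
    Undefined when n_ij = 0, n_i. = 0, n_.j - n_ij = 0 or n_.. = n_i..
    """
    a = np.asarray(n_ij, dtype=float)
    ni = np.asarray(n_i_dot, dtype=float)
    c = np.asarray(n_dot_j, dtype=float) - a
    rest = np.asarray(n_dot_dot, dtype=float) - ni
    defined = (a > 0) & (ni > 0) & (c > 0) & (rest > 0)
    z = _z(confidence)
    with np.errstate(divide="ignore", invalid="ignore"):
        point = np.where(defined, (a / ni) * rest / np.where(c > 0, c, 1.0), np.nan)
        var = (
            1.0 / np.where(a > 0, a, 1)
            - 1.0 / np.where(ni > 0, ni, 1)
            + 1.0 / np.where(c > 0, c, 1)
            - 1.0 / np.where(rest > 0, rest, 1)
        )
        sd = np.sqrt(np.where(defined, var, np.nan))
        log_point = np.log(point)
        lower = np.exp(log_point - z * sd)
        upper = np.exp(log_point + z * sd)
    return point, sd, lower, upper, defined


def ic_arrays(n_ij, n_i_dot, n_dot_j, n_dot_dot, confidence: float = 0.95):
    """Information component with CI for vectors of cells.

    IC = log2(n_ij / E_ij) with E_ij = n_i. n_.j / n_..; the variance on the
    IC scale is (1/ln2)^2 (1/n_ij + 1/n_i. + 1/n_.j).  The interval is
    additive on the IC scale: IC +- z sd.  Undefined when n_ij, n_i. or
    n_.j is zero.
    """
    a = np.asarray(n_ij, dtype=float)
    ni = np.asarray(n_i_dot, dtype=float)
    nj = np.asarray(n_dot_j, dtype=float)
    n = np.asarray(n_dot_dot, dtype=float)
    defined = (a > 0) & (ni > 0) & (nj > 0) & (n > 0)
    z = _z(confidence)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = ni * nj / np.where(n > 0, n, 1.0)
        point = np.where(defined, np.log2(np.where(defined, a / np.where(e > 0, e, 1.0), np.nan)), np.nan)
        sd = np.sqrt(
            1.0 / np.where(a > 0, a, 1)
            + 1.0 / np.where(ni > 0, ni, 1)
            + 1.0 / np.where(nj > 0, nj, 1)
        ) / _LN2
        sd = np.where(defined, sd, np.nan)
        lower = point - z * sd
        upper = point + z * sd
    return point, sd, lower, upper, defined


def _scalar(fn, t: TwoByTwo, confidence: float) -> IntervalEstimate:
    point, sd, lower, upper, defined = (
        np.asarray(v).reshape(()) for v in
        fn(t.n_ij, t.n_i_dot, t.n_dot_j, t.n_dot_dot, confidence)
    )
    return IntervalEstimate(
        point=float(point), sd=float(sd), lower=float(lower), upper=float(upper),
        confidence=confidence, defined=bool(defined),
    )


def ror(t: TwoByTwo, confidence: float = 0.95) -> IntervalEstimate:
    """Reporting odds ratio for one 2x2 table."""
    return _scalar(ror_arrays, t, confidence)


def prr(t: TwoByTwo, confidence: float = 0.95) -> IntervalEstimate:
    """Proportional reporting ratio for one 2x2 table."""
    return _scalar(prr_arrays, t, confidence)


def ic(t: TwoByTwo, confidence: float = 0.95) -> IntervalEstimate:
    """Information component for one 2x2 table."""
    return _scalar(ic_arrays, t, confidence)


# ---------------------------------------------------------------------------
# Likelihood ratio test
# ---------------------------------------------------------------------------

def lrt_llr(n_ij, n_i_dot, n_dot_j: float, n_dot_dot: float) -> np.ndarray:
    """Per-AE log-likelihood-ratio for a fixed drug column.

    For AE i with observed excess (p_hat = n_ij/n_i. > q_hat =
    (n_.j - n_ij)/(n_.. - n_i.)) the statistic is

        n_ij ln(n_ij / E_ij) + (n_.j - n_ij) ln((n_.j - n_ij)/(n_.j - E_ij))

    with E_ij = n_i. n_.j / n_..; AEs without excess contribute 0.  The
    result is always >= 0 (it is n_.j times a binomial Kullback-Leibler
    divergence).
    """
    c = np.atleast_1d(np.asarray(n_ij, dtype=float))
    x = np.atleast_1d(np.asarray(n_i_dot, dtype=float))
    C = float(n_dot_j)
    N = float(n_dot_dot)
    e = x * C / N
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = np.where(x > 0, c / np.where(x > 0, x, 1.0), np.nan)
        q_hat = np.where(N > x, (C - c) / (N - x), np.inf)
        include = (x > 0) & (c > 0) & (p_hat > q_hat)
        t1 = np.where(c > 0, c * np.log(np.where(c > 0, c, 1.0) / np.where(e > 0, e, 1.0)), 0.0)
        rem = C - c
        t2 = np.where(rem > 0, rem * np.log(np.where(rem > 0, rem, 1.0) / np.where(C > e, C - e, 1.0)), 0.0)
    return np.where(include, t1 + t2, 0.0)


@dataclass(frozen=True)
class LrtResult:
    """Maximum-likelihood-ratio scan of one drug column with MC inference.

    ``p_value`` is the global Monte Carlo p-value of the maximum statistic;
    ``per_ae_p`` ranks each AE's own statistic against the same null maximum
    distribution (so the per-AE decisions control the family-wise error and
    the minimum over AEs equals ``p_value``).
    """

    mlr_log: float
    best_ae: str
    p_value: float
    per_ae_llr: Mapping[str, float]
    per_ae_p: Mapping[str, float]
    n_mc: int


def lrt_statistic(
    n_ij,
    n_i_dot,
    n_dot_j: int,
    n_dot_dot: int,
    ae_ids: Sequence[str] | None = None,
) -> tuple[float, str, dict[str, float]]:
    """Observed maximum log likelihood ratio for one drug column.

    Returns ``(mlr_log, best_ae, per_ae_llr)``; ties in the maximum go to
    the smallest AE identifier.
    """
    c = np.atleast_1d(np.asarray(n_ij))
    x = np.atleast_1d(np.asarray(n_i_dot))
    if ae_ids is None:
        ae_ids = [str(i) for i in range(len(c))]
    ids = [str(a) for a in ae_ids]
    if len(ids) != len(c) or len(c) != len(x):
        raise ValueError("n_ij, n_i_dot and ae_ids must have equal length")
    if int(c.sum()) != int(n_dot_j):
        raise ValueError(
            f"column counts sum to {int(c.sum())}, expected n_.j = {n_dot_j}"
        )
    if np.any(c > x):
        raise ValueError("n_ij exceeds its AE margin n_i. for some AE")
    llr = lrt_llr(c, x, n_dot_j, n_dot_dot)
    mlr = float(llr.max()) if llr.size else 0.0
    best = min(ids[i] for i in np.flatnonzero(llr == mlr)) if llr.size else ""
    return mlr, best, dict(zip(ids, llr.tolist()))


def _mc_rank_p(null_max: np.ndarray, values: np.ndarray) -> np.ndarray:
    """p = (1 + #{null max >= value}) / (n_mc + 1), ties counted against."""
    srt = np.sort(null_max)
    n_mc = len(srt)
    n_ge = n_mc - np.searchsorted(srt, values, side="left")
    return (1.0 + n_ge) / (n_mc + 1.0)


def lrt_mc_arrays(
    n_ij,
    n_i_dot,
    n_dot_j: int,
    n_dot_dot: int,
    n_mc: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray]:
    """LLR vector, global MC p-value and per-AE rank p-values for one column.

    Null replicates redistribute the drug's total over AEs as
    Multinomial(n_.j, n_i./n_..) and each replicate is scored by its own
    maximum statistic.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    c = np.atleast_1d(np.asarray(n_ij, dtype=np.int64))
    x = np.atleast_1d(np.asarray(n_i_dot, dtype=float))
    llr = lrt_llr(c, x, n_dot_j, n_dot_dot)
    t_obs = float(llr.max()) if llr.size else 0.0
    p0 = x / x.sum()
    draws = rng.multinomial(int(n_dot_j), p0, size=int(n_mc))
    rep_llr = lrt_llr(draws, x[None, :], n_dot_j, n_dot_dot)
    null_max = rep_llr.max(axis=1)
    p_global = float(_mc_rank_p(null_max, np.asarray([t_obs]))[0])
    per_ae_p = _mc_rank_p(null_max, llr)
    # AEs with no observed excess never signal
    per_ae_p = np.where(llr > 0, per_ae_p, 1.0)
    return llr, p_global, per_ae_p


def lrt_test(
    table: DrugEventTable,
    drug: str,
    n_mc: int = 9999,
    seed: int | np.random.Generator = 0,
) -> LrtResult:
    """Monte Carlo LRT for one drug over all AE terms of a table."""
    c, x, n_j, n = table.column_stats(drug)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    llr, p_global, per_ae_p = lrt_mc_arrays(c, x, n_j, n, n_mc, rng)
    ids = list(table.ae_ids)
    mlr = float(llr.max()) if llr.size else 0.0
    best = min(ids[i] for i in np.flatnonzero(llr == mlr)) if llr.size else ""
    return LrtResult(
        mlr_log=mlr,
        best_ae=best,
        p_value=p_global,
        per_ae_llr=dict(zip(ids, llr.tolist())),
        per_ae_p=dict(zip(ids, per_ae_p.tolist())),
        n_mc=int(n_mc),
    )
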