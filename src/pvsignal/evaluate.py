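"""Operating characteristics of the detectors on simulated data.

Every method except the tree scan is applied twice — once on the PT-level
column and once on the SOC-aggregated column of the target drug — and the
two detection sets are merged; the tree scan evaluates both levels in a
single pass over the hierarchy.  A detected signal is a (level, term) pair,
so a PT flagged at PT level and its SOC flagged at SOC level count as two
detections.

Across replicates the summary reports

* **type I error** — fraction of datasets flagging at least one term that is
  not a true signal,
* **power** — fraction of datasets flagging at least one term of any kind,
* **sensitivity** — mean over the S datasets with >= 1 detection of
  (true positives / true signals),
* **PPV** — mean over the same S datasets of (true positives / detections).

Truth labelling: planted signals live on PT cells; by default
(``pt_and_parent_soc``) a SOC containing at least one true PT also counts as
a true signal, so SOC-level detections induced by real PT signals are scored
as true positives.  ``pt_only`` restricts the truth set to PT cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Level, Method
from .frequentist import ic_arrays, lrt_mc_arrays, prr_arrays, ror_arrays
from .bayes import (
    bcpnn_arrays,
    fit_gps_prior,
    gps_eb05_arrays,
    new_ic_arrays,
    sb_arrays,
)
from .treescan import LeafData, treescan_test
from .simulate import SimDataset, SimConfig, gen_dataset

__all__ = [
    "STANDARD_CUTOFFS",
    "CUTOFF_LADDERS",
    "MergedDetection",
    "PerfSummary",
    "label_truth",
    "detect_all",
    "summarize",
    "run_experiment",
]

#: Standard single cutoffs per method (CI/credible lower bound, EB05 or p-value).
STANDARD_CUTOFFS: dict[Method, float] = {
    Method.ROR: 2.0,
    Method.PRR: 2.0,
    Method.IC: float(np.log2(2.0)),
    Method.LRT: 0.05,
    Method.GPS: 2.0,
    Method.BCPNN: float(np.log2(2.0)),
    Method.NEWIC: 1.0,
    Method.SB: 2.0,
    Method.TREESCAN: 0.05,
}

#: Five-point cutoff ladders used in the simulation benchmark.
CUTOFF_LADDERS: dict[Method, list[float]] = {
    Method.ROR: [1.0, 1.5, 2.0, 2.5, 3.0],
    Method.PRR: [1.0, 1.5, 2.0, 2.5, 3.0],
    Method.IC: [float(np.log2(v)) for v in (1.0, 1.5, 2.0, 2.5, 3.0)],
    Method.LRT: [0.2, 0.1, 0.05, 0.025, 0.01],
    Method.GPS: [1.0, 1.5, 2.0, 2.5, 3.0],
    Method.BCPNN: [float(np.log2(v)) for v in (1.0, 1.5, 2.0, 2.5, 3.0)],
    Method.NEWIC: [1.0],
    Method.SB: [1.0, 1.5, 2.0, 2.5, 3.0],
    Method.TREESCAN: [0.2, 0.1, 0.05, 0.025, 0.01],
}

#: Methods whose decision is "bound greater than cutoff" (vs p-value below).
_BOUND_METHODS = {
    Method.ROR, Method.PRR, Method.IC, Method.GPS, Method.BCPNN,
    Method.NEWIC, Method.SB,
}


@dataclass(frozen=True)
class MergedDetection:
    """PT+SOC merged detections of one method/cutoff on one dataset."""

    detected: frozenset[tuple[Level, str]]
    true_set: frozenset[tuple[Level, str]]

    @property
    def n_detected(self) -> int:
        return len(self.detected)

    @property
    def n_true_positive(self) -> int:
        return len(self.detected & self.true_set)

    @property
    def any_false_positive(self) -> bool:
        return bool(self.detected - self.true_set)


@dataclass(frozen=True)
class PerfSummary:
    """Operating characteristics over a set of replicates."""

    type1: float
    power: float
    sensitivity: float
    ppv: float
    s_detected: int
    n_datasets: int


def label_truth(
    ds: SimDataset, convention: str = "pt_and_parent_soc"
) -> frozenset[tuple[Level, str]]:
    """Truth labels for one dataset under the chosen scoring convention."""
    pts = {(Level.PT, pt) for pt in ds.true_signals_pt}
    if convention == "pt_only":
        return frozenset(pts)
    if convention == "pt_and_parent_soc":
        return frozenset(pts | {(Level.SOC, s) for s in ds.true_signal_socs})
    raise ValueError(f"unknown truth convention {convention!r}")


def _bounds_for_level(
    method: Method,
    stats_tuple: tuple[np.ndarray, np.ndarray, int, int],
    confidence: float,
    sb_alpha: float,
) -> np.ndarray:
    """The per-term decision bound (CI lower bound etc.) for one level."""
    c, x, nj, n = stats_tuple
    if method is Method.ROR:
        _, _, lower, _, defined = ror_arrays(c, x, nj, n, confidence)
        return np.where(defined, lower, -np.inf)
    if method is Method.PRR:
        _, _, lower, _, defined = prr_arrays(c, x, nj, n, confidence)
        return np.where(defined, lower, -np.inf)
    if method is Method.IC:
        _, _, lower, _, defined = ic_arrays(c, x, nj, n, confidence)
        return np.where(defined, lower, -np.inf)
    if method is Method.BCPNN:
        _, _, lower, _ = bcpnn_arrays(c, x, nj, n, confidence)
        return lower
    if method is Method.SB:
        e = x.astype(float) * nj / n
        return sb_arrays(c, e, alpha=sb_alpha)
    if method is Method.NEWIC:
        e = x.astype(float) * nj / n
        _, q025, _ = new_ic_arrays(c, e)
        return q025
    raise ValueError(f"{method} has no closed-form bound")


def detect_all(
    ds: SimDataset,
    methods: Iterable[Method],
    cutoffs: Mapping[Method, Sequence[float]] | None = None,
    mc_reps: int = 9999,
    seed: int | np.random.Generator = 0,
    confidence: float = 0.95,
    sb_alpha: float = 0.5,
    truth_convention: str = "pt_and_parent_soc",
    gps_starts: int = 5,
) -> dict[tuple[Method, float], MergedDetection]:
    """Run methods on one dataset at PT and SOC levels and merge detections.

    Monte Carlo methods (LRT, tree scan) consume ``mc_reps`` null replicates
    from ``seed``; GPS refits its prior on the full matrix at each level and
    requires a full-matrix dataset.
    """
    methods = [Method(m) for m in methods]
    if cutoffs is None:
        cutoffs = {}
    cut_map = {m: list(cutoffs.get(m, [STANDARD_CUTOFFS[m]])) for m in methods}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = label_truth(ds, truth_convention)

    pt_stats = ds.pt_stats()
    soc_stats = ds.soc_stats()
    pt_ids = list(ds.tree.pt_ids)
    soc_ids = list(ds.tree.soc_ids)
    out: dict[tuple[Method, float], MergedDetection] = {}

    for method in methods:
        if method in _BOUND_METHODS and method is not Method.GPS:
            bounds = {
                Level.PT: _bounds_for_level(method, pt_stats, confidence, sb_alpha),
                Level.SOC: _bounds_for_level(method, soc_stats, confidence, sb_alpha),
            }
            for cut in cut_map[method]:
                det = {
                    (Level.PT, pt_ids[i])
                    for i in np.flatnonzero(bounds[Level.PT] > cut)
                } | {
                    (Level.SOC, soc_ids[s])
                    for s in np.flatnonzero(bounds[Level.SOC] > cut)
                }
                out[(method, cut)] = MergedDetection(frozenset(det), truth)
        elif method is Method.GPS:
            if ds.full_counts is None:
                raise ValueError(
                    "GPS requires a full count matrix; generate with full_matrix=True"
                )
            eb05 = {}
            for level, ids, stats_tuple, counts in (
                (Level.PT, pt_ids, pt_stats, ds.full_counts),
                (Level.SOC, soc_ids, soc_stats, ds._soc_membership @ ds.full_counts),
            ):
                c, x, nj, n = stats_tuple
                col_margins = counts.sum(axis=0).astype(float)
                e_full = np.outer(x.astype(float), col_margins) / n
                prior = fit_gps_prior(counts, e_full, starts=gps_starts)
                e_target = x.astype(float) * nj / n
                eb05[level] = gps_eb05_arrays(c, e_target, prior)
            for cut in cut_map[method]:
                det = {
                    (Level.PT, pt_ids[i])
                    for i in np.flatnonzero(eb05[Level.PT] > cut)
                } | {
                    (Level.SOC, soc_ids[s])
                    for s in np.flatnonzero(eb05[Level.SOC] > cut)
                }
                out[(method, cut)] = MergedDetection(frozenset(det), truth)
        elif method is Method.LRT:
            pvals = {}
            for level, stats_tuple in ((Level.PT, pt_stats), (Level.SOC, soc_stats)):
                c, x, nj, n = stats_tuple
                _, _, per_ae_p = lrt_mc_arrays(c, x, nj, n, mc_reps, rng)
                pvals[level] = per_ae_p
            for cut in cut_map[method]:
                det = {
                    (Level.PT, pt_ids[i])
                    for i in np.flatnonzero(pvals[Level.PT] < cut)
                } | {
                    (Level.SOC, soc_ids[s])
                    for s in np.flatnonzero(pvals[Level.SOC] < cut)
                }
                out[(method, cut)] = MergedDetection(frozenset(det), truth)
        elif method is Method.TREESCAN:
            c, x, _, _ = pt_stats
            result = treescan_test(LeafData(c=c, x=x), ds.tree, n_mc=mc_reps, seed=rng)
            for cut in cut_map[method]:
                det = {
                    (cutres.level, cutres.node_id)
                    for cutres in result.all_cuts
                    if cutres.rank_p < cut
                }
                out[(method, cut)] = MergedDetection(frozenset(det), truth)
        else:  # pragma: no cover - enum is exhaustive
            raise ValueError(f"unhandled method {method}")
    return out


def summarize(runs: Sequence[MergedDetection]) -> PerfSummary:
    """Aggregate per-dataset detections into the four operating characteristics.

    Sensitivity and PPV are averaged only over the S datasets with at least
    one detection; when S = 0 they are reported as NaN.  Datasets with no
    true signals contribute NaN to sensitivity (nothing to recover).
    """
    if not runs:
        raise ValueError("need at least one dataset")
    n = len(runs)
    any_fp = sum(r.any_false_positive for r in runs)
    detected_runs = [r for r in runs if r.n_detected > 0]
    s = len(detected_runs)
    if s:
        sens_terms = [
            r.n_true_positive / len(r.true_set) for r in detected_runs if r.true_set
        ]
        sensitivity = float(np.mean(sens_terms)) if sens_terms else float("nan")
        ppv = float(np.mean([r.n_true_positive / r.n_detected for r in detected_runs]))
    else:
        sensitivity = float("nan")
        ppv = float("nan")
    return PerfSummary(
        type1=any_fp / n,
        power=s / n,
        sensitivity=sensitivity,
        ppv=ppv,
        s_detected=s,
        n_datasets=n,
    )


def run_experiment(
    cfg: SimConfig,
    methods: Iterable[Method],
    cutoffs: Mapping[Method, Sequence[float]] | None = None,
    mc_reps: int = 999,
    truth_convention: str = "pt_and_parent_soc",
    confidence: float = 0.95,
    sb_alpha: float = 0.5,
    gps_starts: int = 5,
) -> pd.DataFrame:
    """Simulate ``cfg.n_datasets`` replicates and summarise every method/cutoff.

    Returns one row per (method, cutoff) with the four operating
    characteristics and their binomial Monte Carlo standard errors.
    """
    methods = [Method(m) for m in methods]
    collected: dict[tuple[Method, float], list[MergedDetection]] = {}
    for rep in range(cfg.n_datasets):
        ds = gen_dataset(cfg, rep)
        mc_seed = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), int(rep), 1])
        )
        dets = detect_all(
            ds, methods, cutoffs, mc_reps=mc_reps, seed=mc_seed,
            confidence=confidence, sb_alpha=sb_alpha,
            truth_convention=truth_convention, gps_starts=gps_starts,
        )
        for key, det in dets.items():
            collected.setdefault(key, []).append(det)

    rows = []
    for (method, cut), runs in collected.items():
        perf = summarize(runs)
        n = perf.n_datasets
        rows.append(
            {
                "method": method.value,
                "cutoff": cut,
                "n_total": cfg.n_total,
                "signal_ratio": cfg.signal_ratio,
                "rr_low": cfg.rr_low,
                "rr_high": cfg.rr_high,
                "n_datasets": n,
                "type1": perf.type1,
                "power": perf.power,
                "sensitivity": perf.sensitivity,
                "ppv": perf.ppv,
                "s_detected": perf.s_detected,
                "mc_se_type1": float(np.sqrt(perf.type1 * (1 - perf.type1) / n)),
                "mc_se_power": float(np.sqrt(perf.power * (1 - perf.power) / n)),
            }
        )
    return pd.DataFrame(rows)
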