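"""Tree-based scan statistic over the SOC/PT hierarchy.

The scan evaluates every *simple cut* of the two-level tree — each PT leaf on
its own and each SOC node with all of its leaves — for an excess of the
target drug's reports.  With ``c_i`` the leaf's count for the target drug and
``x_i`` its count over all drugs (totals ``C`` and ``X``), a cut G scores

    LR(G) = c_G ln(c_G / x_G) + (C - c_G) ln((C - c_G) / (X - x_G)),

counted only when the cut's rate exceeds the rest of the tree
(``c_G / x_G > (C - c_G) / (X - x_G)``); the test statistic is the maximum
over cuts.  Inference is by conditional Monte Carlo: null replicates
redistribute C over leaves as Multinomial(C, x_i / X), each replicate is
scored by its own maximum, and the p-value is the rank R/(n_mc + 1).
Scanning all cuts against the same null maximum distribution adjusts for the
multiplicity over tree levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Hierarchy, Level

__all__ = [
    "LeafData",
    "Cut",
    "ScanResult",
    "enumerate_cuts",
    "cut_llr",
    "cut_llr_arrays",
    "treescan_test",
]

#: Statistic value for cuts excluded by the excess indicator.
EXCLUDED = -np.inf


@dataclass(frozen=True)
class LeafData:
    """Per-leaf counts for the scan: target-drug count c_i and all-drug total x_i."""

    c: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=np.int64)
        x = np.asarray(self.x, dtype=np.int64)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "x", x)
        if c.shape != x.shape or c.ndim != 1:
            raise ValueError("c and x must be 1-D arrays of equal length")
        if np.any(c < 0) or np.any(c > x):
            raise ValueError("need 0 <= c_i <= x_i for every leaf")

    @property
    def C(self) -> int:
        return int(self.c.sum())

    @property
    def X(self) -> int:
        return int(self.x.sum())


@dataclass(frozen=True)
class Cut:
    """One evaluated cut: a PT leaf or a SOC node with all its leaves."""

    node_id: str
    level: Level
    leaves: tuple[str, ...]
    c_g: int
    x_g: int
    llr: float
    rank_p: float


@dataclass(frozen=True)
class ScanResult:
    most_likely_cut: Cut | None
    all_cuts: tuple[Cut, ...]
    p_value: float
    n_mc: int
    seed: int


def enumerate_cuts(tree: Hierarchy) -> list[tuple[str, Level, tuple[str, ...]]]:
    """All simple cuts: one per PT leaf, then one per SOC with all its leaves."""
    cuts: list[tuple[str, Level, tuple[str, ...]]] = [
        (pt, Level.PT, (pt,)) for pt in tree.pt_ids
    ]
    children = tree.children()
    cuts.extend((soc, Level.SOC, tuple(children[soc])) for soc in tree.soc_ids)
    return cuts


def cut_llr_arrays(c_g, x_g, C: float, X: float) -> np.ndarray:
    """LR(G) for vectors of cuts; excluded cuts get ``-inf``.

    Convention 0 ln(0/.) = 0.  A cut is excluded when its observed rate does
    not exceed the rest of the tree, including the degenerate whole-tree cut.
    """
    cg = np.asarray(c_g, dtype=float)
    xg = np.asarray(x_g, dtype=float)
    C = float(C)
    X = float(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = np.where(xg > 0, cg / np.where(xg > 0, xg, 1.0), 0.0)
        outside = np.where(X > xg, (C - cg) / (X - xg), np.inf)
        include = (xg > 0) & (X > xg) & (inside > outside)
        t1 = np.where(cg > 0, cg * np.log(inside, where=inside > 0, out=np.ones_like(inside)), 0.0)
        rem = C - cg
        t2 = np.where(rem > 0, rem * np.log(outside, where=outside > 0, out=np.ones_like(outside)), 0.0)
    return np.where(include, t1 + t2, EXCLUDED)


def cut_llr(c_g: int, x_g: int, C: int, X: int) -> float:
    """LR(G) for one cut; ``-inf`` when the excess indicator excludes it."""
    if not (0 <= c_g <= min(x_g, C)) or x_g > X:
        raise ValueError(
            f"invalid cut counts: c_G={c_g}, x_G={x_g}, C={C}, X={X}"
        )
    return float(cut_llr_arrays(np.asarray([c_g]), np.asarray([x_g]), C, X)[0])


def _rank_p(null_max: np.ndarray, values: np.ndarray) -> np.ndarray:
    srt = np.sort(null_max)
    n_ge = len(srt) - np.searchsorted(srt, values, side="left")
    return (1.0 + n_ge) / (len(srt) + 1.0)


def treescan_test(
    leaf_data: LeafData,
    tree: Hierarchy,
    n_mc: int = 9999,
    seed: int | np.random.Generator = 0,
    leaf_order: Sequence[str] | None = None,
) -> ScanResult:
    """Simple-cut tree scan with conditional Monte Carlo inference.

    ``leaf_data`` rows follow ``leaf_order`` (default: ``tree.pt_ids``).
    Ties for the most likely cut go to the smallest node identifier.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    leaves = list(leaf_order) if leaf_order is not None else list(tree.pt_ids)
    if len(leaves) != len(leaf_data.c):
        raise ValueError("leaf_data length does not match the leaf order")
    X = leaf_data.X
    if X == 0:
        raise ValueError("the tree carries no reports (X = 0)")
    C = leaf_data.C

    # canonicalise everything to tree.pt_ids order, so results (including the
    # Monte Carlo stream) are invariant to how the caller ordered the leaves
    pos = {pt: k for k, pt in enumerate(leaves)}
    leaf_perm = np.array([pos[pt] for pt in tree.pt_ids], dtype=np.intp)
    c_leaf = leaf_data.c[leaf_perm]
    x_leaf = leaf_data.x[leaf_perm]
    m = tree.membership_matrix().astype(np.int64)
    c_soc, x_soc = m @ c_leaf, m @ x_leaf
    cg = np.concatenate([c_leaf, c_soc])
    xg = np.concatenate([x_leaf, x_soc])
    llr = cut_llr_arrays(cg, xg, C, X)
    t_obs = llr.max() if llr.size else EXCLUDED

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multinomial(C, x_leaf / X, size=int(n_mc))
    rep_llr_leaf = cut_llr_arrays(draws, x_leaf[None, :], C, X)
    rep_llr_soc = cut_llr_arrays(draws @ m.T, x_soc[None, :], C, X)
    null_max = np.maximum(
        rep_llr_leaf.max(axis=1) if rep_llr_leaf.size else EXCLUDED,
        rep_llr_soc.max(axis=1) if rep_llr_soc.size else EXCLUDED,
    )
    p_value = float(_rank_p(null_max, np.asarray([t_obs]))[0])
    rank_p = _rank_p(null_max, llr)
    rank_p = np.where(np.isfinite(llr), rank_p, 1.0)

    defs = enumerate_cuts(tree)
    cuts = tuple(
        Cut(
            node_id=node,
            level=level,
            leaves=members,
            c_g=int(cg[k]),
            x_g=int(xg[k]),
            llr=float(llr[k]),
            rank_p=float(rank_p[k]),
        )
        for k, (node, level, members) in enumerate(defs)
    )
    best = None
    if np.isfinite(t_obs):
        winners = [cut for cut in cuts if cut.llr == t_obs]
        best = min(winners, key=lambda cut: cut.node_id)
    return ScanResult(
        most_likely_cut=best,
        all_cuts=cuts,
        p_value=p_value,
        n_mc=int(n_mc),
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )
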