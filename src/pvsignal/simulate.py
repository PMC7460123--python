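"""Synthetic spontaneous-reporting data with a planted target-drug signal.

The generator emulates the structure of a national spontaneous-reporting
database summarised as an AE x drug count matrix under a two-level
(SOC -> PT) terminology:

1. AE margins ``n_1., ..., n_I.`` and drug margins ``n_.1, ..., n_.J`` are
   drawn as Multinomial(n_.., u / sum(u)) with independent Uniform(0, 1)
   weights u, giving realistically skewed report totals per term and drug.
2. PTs are assigned uniformly at random to SOCs (every SOC keeps at least
   one PT).
3. For one target drug j*, a fraction of PT cells is selected as true
   signals; each gets a relative reporting rate rr_i ~ Uniform(rr_low,
   rr_high), all other cells have rr_i = 1.  The target column is drawn as
   Multinomial(n_.j*, p) with p_i = rr_i r0 n_i. / n_.., where the baseline
   r0 = 1 / sum_i(rr_i n_i. / n_..) makes the probabilities sum to one.
4. Optionally (``full_matrix``) every other drug column is filled under the
   null, Multinomial(n_.j, n_i. / n_..), and all margins are then recomputed
   from the realised cells — required by detectors that fit a prior over the
   whole matrix.

With ``signal_ratio = 0`` (or rr_low = rr_high = 1) the generator reduces
exactly to the global null used for type I error studies.  Defaults: 300
PTs under 30 SOCs, 500 drugs, total report counts of a few hundred thousand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DrugEventTable, Hierarchy, Level, write_hierarchy, write_pairs

__all__ = ["SimConfig", "SimDataset", "gen_margins", "gen_tree",
           "gen_target_column", "gen_dataset", "write_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation setting.

    ``signal_ratio`` is the fraction of PT cells of the target drug that are
    true signals; their relative reporting rates are drawn from
    Uniform(rr_low, rr_high).
    """

    n_total: int
    n_ae: int = 300
    n_drug: int = 500
    n_soc: int = 30
    signal_ratio: float = 0.0
    rr_low: float = 1.0
    rr_high: float = 1.0
    n_datasets: int = 1000
    seed: int = 0
    full_matrix: bool = False

    def __post_init__(self) -> None:
        if self.n_total < 1 or self.n_ae < 1 or self.n_drug < 1:
            raise ValueError("n_total, n_ae and n_drug must be positive")
        if not 0 <= self.n_soc <= self.n_ae:
            raise ValueError("need 1 <= n_soc <= n_ae")
        if not 0.0 <= self.signal_ratio < 1.0:
            raise ValueError("signal_ratio must be in [0, 1)")
        if self.rr_low > self.rr_high:
            raise ValueError("rr_low must not exceed rr_high")
        if self.signal_ratio > 0 and self.rr_low < 1.0:
            raise ValueError("relative reporting rates of true signals must be >= 1")


@dataclass(frozen=True)
class SimDataset:
    """One generated replicate with its truth labels.

    ``ae_margins``/``drug_margins`` are the *generated* margins; in
    full-matrix mode the accessors below return margins recomputed from the
    realised cells, keeping the 2x2 identities exact for every method.
    """

    config: SimConfig
    replicate: int
    tree: Hierarchy
    ae_margins: np.ndarray
    drug_margins: np.ndarray
    target_index: int
    target_counts: np.ndarray
    true_signal_idx: np.ndarray
    rr: np.ndarray
    r0: float
    full_counts: np.ndarray | None = None
    _soc_membership: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = self.tree.membership_matrix().astype(np.int64)
        object.__setattr__(self, "_soc_membership", m)

    @property
    def target_drug(self) -> str:
        return f"drug{self.target_index + 1:04d}"

    @property
    def drug_ids(self) -> list[str]:
        return [f"drug{j + 1:04d}" for j in range(self.config.n_drug)]

    @property
    def true_signals_pt(self) -> set[str]:
        return {self.tree.pt_ids[i] for i in self.true_signal_idx}

    @property
    def true_signal_socs(self) -> set[str]:
        return {self.tree.parent[pt] for pt in self.true_signals_pt}

    def pt_stats(self) -> tuple[np.ndarray, np.ndarray, int, int]:
        """(n_ij*, n_i., n_.j*, n_..) at PT level, using realised margins
        when the full matrix was generated."""
        if self.full_counts is not None:
            x = self.full_counts.sum(axis=1)
            n = int(self.full_counts.sum())
        else:
            x = self.ae_margins
            n = int(self.config.n_total)
        return self.target_counts, x, int(self.target_counts.sum()), n

    def soc_stats(self) -> tuple[np.ndarray, np.ndarray, int, int]:
        """PT stats aggregated into SOC rows."""
        c, x, cj, n = self.pt_stats()
        m = self._soc_membership
        return m @ c, m @ x, cj, n

    def realized_drug_margins(self) -> np.ndarray:
        if self.full_counts is not None:
            return self.full_counts.sum(axis=0)
        out = self.drug_margins.copy()
        out[self.target_index] = int(self.target_counts.sum())
        return out

    def to_table(self, level: Level = Level.PT) -> DrugEventTable:
        """Full count matrix as a DrugEventTable (full-matrix mode only)."""
        if self.full_counts is None:
            raise ValueError(
                "dataset was generated in target-column mode; "
                "set full_matrix=True for a complete matrix"
            )
        table = DrugEventTable(
            self.full_counts, ae_ids=self.tree.pt_ids, drug_ids=self.drug_ids,
            level=Level.PT,
        )
        if level == Level.PT:
            return table
        from .core import aggregate_to_soc

        return aggregate_to_soc(table, self.tree)


def _rng_for(cfg: SimConfig, replicate: int) -> np.random.Generator:
    # independent, reproducible stream per replicate
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(replicate)]))


def gen_margins(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial AE and drug margins with independent Uniform(0,1) weights."""
    u_ae = rng.uniform(size=cfg.n_ae)
    ae_margins = rng.multinomial(cfg.n_total, u_ae / u_ae.sum())
    u_drug = rng.uniform(size=cfg.n_drug)
    drug_margins = rng.multinomial(cfg.n_total, u_drug / u_drug.sum())
    return ae_margins, drug_margins


def gen_tree(cfg: SimConfig, rng: np.random.Generator) -> Hierarchy:
    """Random SOC assignment of PTs; every SOC receives at least one PT."""
    soc_ids = [f"{(s + 1) * 100}" for s in range(cfg.n_soc)]
    pt_soc = np.empty(cfg.n_ae, dtype=np.int64)
    order = rng.permutation(cfg.n_ae)
    pt_soc[order[: cfg.n_soc]] = np.arange(cfg.n_soc)
    pt_soc[order[cfg.n_soc:]] = rng.integers(0, cfg.n_soc, size=cfg.n_ae - cfg.n_soc)
    pt_ids = [f"{soc_ids[pt_soc[i]]}.{i + 1:04d}" for i in range(cfg.n_ae)]
    parent = dict(zip(pt_ids, (soc_ids[s] for s in pt_soc)))
    return Hierarchy(soc_ids=tuple(soc_ids), pt_ids=tuple(pt_ids), parent=parent)


def gen_target_column(
    cfg: SimConfig,
    ae_margins: np.ndarray,
    n_dot_jstar: int,
    rng: np.random.Generator,
    max_resample: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Draw the target drug's column with planted relative reporting rates.

    Returns ``(counts, true_signal_idx, rr, r0)``; the signal set is
    resampled (up to ``max_resample`` times) in the rare event that a cell
    probability rr_i r0 n_i./n_.. leaves [0, 1].
    """
    n_sig = int(np.floor(cfg.signal_ratio * cfg.n_ae))
    base = ae_margins / ae_margins.sum()
    for _ in range(max_resample):
        rr = np.ones(cfg.n_ae)
        idx = rng.choice(cfg.n_ae, size=n_sig, replace=False) if n_sig else np.empty(0, dtype=np.int64)
        if n_sig:
            rr[idx] = rng.uniform(cfg.rr_low, cfg.rr_high, size=n_sig)
        r0 = 1.0 / float(np.sum(rr * base))
        p = rr * r0 * base
        if np.all((p >= 0) & (p <= 1)):
            counts = rng.multinomial(int(n_dot_jstar), p)
            return counts, np.sort(idx), rr, r0
    raise RuntimeError(
        "could not draw a valid signal configuration after "
        f"{max_resample} attempts"
    )


def gen_dataset(cfg: SimConfig, replicate: int = 0) -> SimDataset:
    """Generate one replicate; (cfg, replicate) fully determines the output."""
    if replicate < 0:
        raise ValueError("replicate index must be >= 0")
    rng = _rng_for(cfg, replicate)
    ae_margins, drug_margins = gen_margins(cfg, rng)
    tree = gen_tree(cfg, rng)
    jstar = int(rng.integers(cfg.n_drug))
    target_counts, true_idx, rr, r0 = gen_target_column(
        cfg, ae_margins, int(drug_margins[jstar]), rng
    )
    full = None
    if cfg.full_matrix:
        p0 = ae_margins / ae_margins.sum()
        full = np.empty((cfg.n_ae, cfg.n_drug), dtype=np.int64)
        other = np.delete(np.arange(cfg.n_drug), jstar)
        full[:, other] = rng.multinomial(drug_margins[other], p0).T
        full[:, jstar] = target_counts
    return SimDataset(
        config=cfg,
        replicate=int(replicate),
        tree=tree,
        ae_margins=ae_margins,
        drug_margins=drug_margins,
        target_index=jstar,
        target_counts=target_counts,
        true_signal_idx=true_idx,
        rr=rr,
        r0=r0,
        full_counts=full,
    )


def write_dataset(ds: SimDataset, out_dir) -> None:
    """Emit one replicate as pair-list, hierarchy and truth TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"rep{ds.replicate:04d}"
    if ds.full_counts is not None:
        write_pairs(ds.to_table(), out / f"{tag}_pairs.tsv")
    else:
        pts = list(ds.tree.pt_ids)
        nz = np.flatnonzero(ds.target_counts)
        pd.DataFrame(
            {
                "drug": ds.target_drug,
                "ae_code": [pts[i] for i in nz],
                "count": ds.target_counts[nz],
            }
        ).to_csv(out / f"{tag}_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"ae_code": pts, "margin": ds.ae_margins}
        ).to_csv(out / f"{tag}_ae_margins.tsv", sep="\t", index=False)
    write_hierarchy(ds.tree, out / f"{tag}_hierarchy.tsv")
    pts = list(ds.tree.pt_ids)
    pd.DataFrame(
        {
            "pt_code": [pts[i] for i in ds.true_signal_idx],
            "rr": ds.rr[ds.true_signal_idx],
        }
    ).to_csv(out / f"{tag}_truth.tsv", sep="\t", index=False)
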