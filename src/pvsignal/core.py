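"""Hierarchical drug--adverse-event count data.

Spontaneous-reporting databases record (drug, adverse event) report pairs.
For disproportionality analysis the reports are summarised as an I x J
matrix of counts ``n_ij`` (AE term i, drug j) at one level of the adverse
event terminology (WHO-ART style: system-organ classes, SOC, containing
preferred terms, PT).  Every detection statistic in this package consumes
the four cells of the 2 x 2 table for one (AE, drug) pair::

                    drug j     all other drugs    total
    AE i            n_ij       n_i. - n_ij        n_i.
    all other AEs   n_.j-n_ij  n_..-n_i.-n_.j+n_ij
    total           n_.j                          n_..

This module holds the count-matrix container, the two-level SOC/PT
hierarchy, 2x2 extraction, SOC aggregation and pair-list file I/O.
Margins are always recomputed from the cells, never stored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Method",
    "Level",
    "TwoByTwo",
    "DrugEventTable",
    "Hierarchy",
    "SignalDecision",
    "WhoArtCode",
    "parse_whoart_code",
    "hierarchy_from_codes",
    "read_pairs",
    "write_pairs",
    "read_hierarchy",
    "write_hierarchy",
    "aggregate_to_soc",
]


class Method(str, Enum):
    """Detection methods implemented in this package."""

    ROR = "ror"
    PRR = "prr"
    IC = "ic"
    LRT = "lrt"
    GPS = "gps"
    BCPNN = "bcpnn"
    NEWIC = "newic"
    SB = "sb"
    TREESCAN = "treescan"


class Level(str, Enum):
    """Hierarchy level of an adverse-event term."""

    PT = "pt"
    SOC = "soc"


@dataclass(frozen=True)
class TwoByTwo:
    """The four margins of the 2x2 table for one (AE, drug) pair.

    Stores ``n_ij`` together with the AE margin ``n_i.``, the drug margin
    ``n_.j`` and the grand total ``n_..``; the remaining cells are derived.
    """

    n_ij: int
    n_i_dot: int
    n_dot_j: int
    n_dot_dot: int

    def __post_init__(self) -> None:
        cells = (self.n_ij, self.n_i_dot, self.n_dot_j, self.n_dot_dot)
        if any(int(c) != c or c < 0 for c in cells):
            raise ValueError(f"2x2 margins must be non-negative integers, got {cells}")
        if self.n_ij > min(self.n_i_dot, self.n_dot_j):
            raise ValueError(
                f"n_ij={self.n_ij} exceeds a margin "
                f"(n_i.={self.n_i_dot}, n_.j={self.n_dot_j})"
            )
        if self.other_cell < 0:
            raise ValueError(
                "inconsistent 2x2 margins: n_.. - n_i. - n_.j + n_ij = "
                f"{self.other_cell} < 0"
            )

    @property
    def ae_other_drugs(self) -> int:
        """AE i under all other drugs, ``n_i. - n_ij``."""
        return self.n_i_dot - self.n_ij

    @property
    def other_aes_drug(self) -> int:
        """All other AEs under drug j, ``n_.j - n_ij``."""
        return self.n_dot_j - self.n_ij

    @property
    def other_cell(self) -> int:
        """All other AEs under all other drugs, ``n_.. - n_i. - n_.j + n_ij``."""
        return self.n_dot_dot - self.n_i_dot - self.n_dot_j + self.n_ij

    @property
    def expected(self) -> float:
        """Expected count ``E_ij = n_i. n_.j / n_..`` under independence."""
        if self.n_dot_dot == 0:
            return 0.0
        return self.n_i_dot * self.n_dot_j / self.n_dot_dot


class DrugEventTable:
    """Dense non-negative count matrix of AE terms (rows) by drugs (columns).

    Parameters
    ----------
    counts
        2-D array-like of non-negative integers, shape (n_ae, n_drug).
    ae_ids, drug_ids
        Ordered unique identifiers for the rows / columns.
    level
        Hierarchy level of the row terms (PT or SOC).
    """

    def __init__(
        self,
        counts,
        ae_ids: Sequence[str],
        drug_ids: Sequence[str],
        level: Level = Level.PT,
    ) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.size and (np.any(counts < 0) or np.any(counts != np.floor(counts))):
            raise ValueError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64)
        self.ae_ids = pd.Index([str(a) for a in ae_ids], name="ae_code")
        self.drug_ids = pd.Index([str(d) for d in drug_ids], name="drug")
        if self.counts.shape != (len(self.ae_ids), len(self.drug_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.ae_ids)} AEs x {len(self.drug_ids)} drugs"
            )
        if not self.ae_ids.is_unique or not self.drug_ids.is_unique:
            raise ValueError("AE and drug identifiers must be unique")
        self.level = Level(level)

    # -- margins (always derived from the cells) -------------------------
    @property
    def ae_margins(self) -> np.ndarray:
        """Row margins n_i. in row order."""
        return self.counts.sum(axis=1)

    @property
    def drug_margins(self) -> np.ndarray:
        """Column margins n_.j in column order."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        """Grand total n_.. ."""
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.ae_ids, columns=self.drug_ids)

    def ae_index(self, ae: str) -> int:
        i = self.ae_ids.get_indexer([str(ae)])[0]
        if i < 0:
            raise KeyError(f"unknown AE term {ae!r}")
        return int(i)

    def drug_index(self, drug: str) -> int:
        j = self.drug_ids.get_indexer([str(drug)])[0]
        if j < 0:
            raise KeyError(f"unknown drug {drug!r}")
        return int(j)

    def two_by_two(self, ae: str, drug: str) -> TwoByTwo:
        """Extract the 2x2 table for one (AE, drug) pair by label."""
        i, j = self.ae_index(ae), self.drug_index(drug)
        return TwoByTwo(
            n_ij=int(self.counts[i, j]),
            n_i_dot=int(self.ae_margins[i]),
            n_dot_j=int(self.drug_margins[j]),
            n_dot_dot=self.total,
        )

    def column_stats(self, drug: str) -> tuple[np.ndarray, np.ndarray, int, int]:
        """Per-AE 2x2 margins for one drug: (n_ij, n_i., n_.j, n_..).

        Returns the drug's full column at once; this is the vector form every
        closed-form statistic consumes.
        """
        j = self.drug_index(drug)
        return (
            self.counts[:, j].copy(),
            self.ae_margins,
            int(self.drug_margins[j]),
            self.total,
        )

    def __repr__(self) -> str:
        return (
            f"DrugEventTable({self.shape[0]} AEs x {self.shape[1]} drugs, "
            f"level={self.level.value}, n_..={self.total})"
        )


@dataclass(frozen=True)
class Hierarchy:
    """Two-level SOC -> PT tree.

    ``parent`` maps every PT identifier to its single SOC parent.  SOC and
    PT order is preserved as given (or first-seen order when derived).
    """

    soc_ids: tuple[str, ...]
    pt_ids: tuple[str, ...]
    parent: Mapping[str, str]

    def __post_init__(self) -> None:
        socs, pts = set(self.soc_ids), set(self.pt_ids)
        if len(socs) != len(self.soc_ids) or len(pts) != len(self.pt_ids):
            raise ValueError("identifiers must be unique within a level")
        missing = pts - set(self.parent)
        if missing:
            raise ValueError(f"PTs without a SOC parent: {sorted(missing)[:5]}")
        bad = {p: s for p, s in self.parent.items() if s not in socs}
        if bad:
            raise ValueError(f"PT parents not in soc_ids: {bad}")
        childless = socs - set(self.parent.values())
        if childless:
            raise ValueError(f"SOCs with no PT children: {sorted(childless)[:5]}")

    @property
    def n_soc(self) -> int:
        return len(self.soc_ids)

    @property
    def n_pt(self) -> int:
        return len(self.pt_ids)

    def children(self) -> dict[str, list[str]]:
        """SOC -> ordered list of PT children."""
        out: dict[str, list[str]] = {s: [] for s in self.soc_ids}
        for pt in self.pt_ids:
            out[self.parent[pt]].append(pt)
        return out

    def membership_matrix(self, pt_order: Sequence[str] | None = None) -> np.ndarray:
        """0/1 matrix M of shape (n_soc, n_pt) with M[s, i] = 1 iff PT i in SOC s.

        Row order follows ``soc_ids``; column order follows ``pt_order``
        (default ``pt_ids``).
        """
        pts = list(pt_order) if pt_order is not None else list(self.pt_ids)
        soc_pos = {s: k for k, s in enumerate(self.soc_ids)}
        m = np.zeros((len(self.soc_ids), len(pts)), dtype=np.int8)
        for i, pt in enumerate(pts):
            try:
                m[soc_pos[self.parent[str(pt)]], i] = 1
            except KeyError:
                raise KeyError(f"PT {pt!r} not present in the hierarchy") from None
        return m


@dataclass(frozen=True)
class SignalDecision:
    """One method's verdict on one term at one hierarchy level.

    ``bound`` is the quantity the cutoff is applied to: a 95% CI/credible
    lower bound (ROR, PRR, IC, BCPNN, sB, new IC), EB05 (GPS), or a
    Monte Carlo p-value (LRT, tree scan).  ``is_signal`` is a pure function
    of (bound, cutoff, direction): p-value methods signal when
    ``bound < cutoff``, all others when ``bound > cutoff``.
    """

    method: Method
    level: Level
    term_id: str
    estimate: float
    bound: float
    cutoff: float
    is_signal: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.method in (Method.LRT, Method.TREESCAN):
            sig = self.bound < self.cutoff
        else:
            sig = self.bound > self.cutoff
        object.__setattr__(self, "is_signal", bool(sig) and np.isfinite(self.bound))


# ---------------------------------------------------------------------------
# WHO-ART style term codes
# ---------------------------------------------------------------------------

class WhoArtCode(NamedTuple):
    """Level-resolved components of a WHO-ART style term code."""

    soc: str
    pt: str | None
    it: str | None

    @property
    def level(self) -> str:
        return "it" if self.it is not None else ("pt" if self.pt is not None else "soc")

    @property
    def dotted(self) -> str:
        return ".".join(seg for seg in self if seg is not None)


_DOTTED = re.compile(r"^\d+(\.\d+){0,2}$")
_UNDERSCORE = re.compile(r"^\d+_\d+$")


def parse_whoart_code(code: str) -> WhoArtCode:
    """Parse a dotted (``100.0001.001``) or underscore (``600_285``) term code.

    Dotted codes carry 1-3 numeric segments (SOC, SOC.PT or SOC.PT.IT);
    the underscore dialect writes a PT as ``SOC_PT``.  The level is inferred
    from the number of segments.
    """
    code = str(code).strip()
    if _UNDERSCORE.match(code):
        soc, pt = code.split("_")
        return WhoArtCode(soc=soc, pt=pt, it=None)
    if not _DOTTED.match(code):
        raise ValueError(
            f"malformed term code {code!r}: expected numeric segments "
            "'SOC', 'SOC.PT', 'SOC.PT.IT' or 'SOC_PT'"
        )
    segs = code.split(".")
    return WhoArtCode(
        soc=segs[0],
        pt=segs[1] if len(segs) > 1 else None,
        it=segs[2] if len(segs) > 2 else None,
    )


def hierarchy_from_codes(pt_codes: Iterable[str]) -> Hierarchy:
    """Build the SOC->PT tree implied by dotted/underscore PT codes.

    Each code must resolve to PT level (two segments); its SOC segment
    becomes the parent.  Order of first appearance is preserved.
    """
    soc_ids: list[str] = []
    pt_ids: list[str] = []
    parent: dict[str, str] = {}
    for raw in pt_codes:
        c = parse_whoart_code(raw)
        if c.pt is None or c.it is not None:
            raise ValueError(f"code {raw!r} is not a PT-level code")
        key = str(raw)
        if key in parent:
            continue
        pt_ids.append(key)
        parent[key] = c.soc
        if c.soc not in soc_ids:
            soc_ids.append(c.soc)
    return Hierarchy(soc_ids=tuple(soc_ids), pt_ids=tuple(pt_ids), parent=parent)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

#: Causality assessment levels dropped by default when a pair list carries a
#: causality column: reports whose relation to the drug cannot be assessed.
DEFAULT_DROP_CAUSALITY = frozenset({"unassessable"})


def read_pairs(
    path,
    dedupe: bool = False,
    sep: str = "\t",
    drop_causality: Iterable[str] | None = DEFAULT_DROP_CAUSALITY,
    level: Level = Level.PT,
) -> DrugEventTable:
    """Read a delimited (drug, ae_code[, count][, causality]) pair list.

    Columns ``drug`` and ``ae_code`` are required; ``count`` defaults to 1
    per row.  With ``dedupe=True`` repeated (drug, ae_code) rows contribute a
    single report in total (the convention of reporting systems where a pair
    re-reported per dose or time is counted once); otherwise counts sum.
    Rows whose ``causality`` value (case-insensitive) is in
    ``drop_causality`` are discarded before tabulation.
    """
    df = pd.read_csv(path, sep=sep, dtype={"drug": str, "ae_code": str})
    required = {"drug", "ae_code"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"pair list must have columns {sorted(required)}; got {list(df.columns)}"
        )
    if df[["drug", "ae_code"]].isna().any().any():
        bad = int(df[["drug", "ae_code"]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"malformed pair-list row at line {bad}: missing field")
    if "causality" in df.columns and drop_causality is not None:
        drop = {str(c).lower() for c in drop_causality}
        df = df[~df["causality"].astype(str).str.lower().isin(drop)]
    if "count" in df.columns:
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any():
            bad = int(counts.isna().idxmax()) + 2
            raise ValueError(f"malformed count at line {bad}")
        if (counts < 0).any():
            bad = int((counts < 0).idxmax()) + 2
            raise ValueError(f"negative count at line {bad}")
        df = df.assign(count=counts.astype(np.int64))
    else:
        df = df.assign(count=1)

    if dedupe:
        cell = df.groupby(["ae_code", "drug"], sort=False)["count"].apply(
            lambda c: int((c > 0).any())
        )
    else:
        cell = df.groupby(["ae_code", "drug"], sort=False)["count"].sum()
    wide = cell.unstack(fill_value=0)
    return DrugEventTable(
        wide.to_numpy(), ae_ids=wide.index, drug_ids=wide.columns, level=level
    )


def write_pairs(table: DrugEventTable, path, sep: str = "\t") -> None:
    """Write a table as a (drug, ae_code, count) pair list (zero cells omitted)."""
    frame = table.to_frame().stack()
    frame = frame[frame > 0].rename("count").reset_index()
    frame[["drug", "ae_code", "count"]].to_csv(path, sep=sep, index=False)


def read_hierarchy(path, sep: str = "\t") -> Hierarchy:
    """Read a two-column ``pt_code<sep>soc_code`` hierarchy file (no header)."""
    df = pd.read_csv(path, sep=sep, header=None, names=["pt", "soc"], dtype=str)
    soc_ids = list(dict.fromkeys(df["soc"]))
    pt_ids = list(dict.fromkeys(df["pt"]))
    parent = dict(zip(df["pt"], df["soc"]))
    return Hierarchy(soc_ids=tuple(soc_ids), pt_ids=tuple(pt_ids), parent=parent)


def write_hierarchy(tree: Hierarchy, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"pt": list(tree.pt_ids), "soc": [tree.parent[p] for p in tree.pt_ids]}
    ).to_csv(path, sep=sep, index=False, header=False)


def aggregate_to_soc(pt_table: DrugEventTable, tree: Hierarchy) -> DrugEventTable:
    """Sum PT rows into their SOC parents; column margins and total are preserved."""
    orphans = [pt for pt in pt_table.ae_ids if pt not in tree.parent]
    if orphans:
        raise KeyError(f"PT terms missing from the hierarchy: {orphans[:10]}")
    m = tree.membership_matrix(pt_order=list(pt_table.ae_ids)).astype(np.int64)
    soc_counts = m @ pt_table.counts
    return DrugEventTable(
        soc_counts, ae_ids=tree.soc_ids, drug_ids=pt_table.drug_ids, level=Level.SOC
    )
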