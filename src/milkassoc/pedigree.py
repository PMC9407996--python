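"""Pedigrees and the additive (numerator) relationship matrix.

The animal model treats the random additive-genetic effect ``u`` as
``u ~ N(0, A * sigma_a^2)`` where ``A`` is the pedigree-based additive
relationship matrix: ``a_ij`` is twice the kinship coefficient between
animals *i* and *j*, and the diagonal is ``1 + F_i`` with ``F_i`` the
inbreeding coefficient.  This module builds ``A`` by the tabular method,
its inverse directly from the pedigree by Henderson's rules (with
inbreeding), and per-animal inbreeding coefficients.

Unknown parents are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["Pedigree", "PedigreeError", "build_A", "build_A_inverse", "inbreeding_coefficients"]

#: tokens accepted as "parent unknown" in pedigree files
MISSING_TOKENS = {"", "0", "NA", "na", "nan", ".", "None"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids)."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip() in MISSING_TOKENS


@dataclass
class Pedigree:
    """Ordered animal/sire/dam records, topologically sorted on construction.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``animal``, ``sire``, ``dam``; unknown parents given as
        empty string / ``0`` / ``NA`` / NaN.  Parents that appear only in
        the sire/dam columns are added as founder records.
    """

    records: pd.DataFrame
    ids: list[str] = field(init=False)
    sire_idx: np.ndarray = field(init=False)
    dam_idx: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        df = self.records.copy()
        df.columns = [c.lower() for c in df.columns]
        if not {"animal", "sire", "dam"}.issubset(df.columns):
            raise PedigreeError("pedigree needs columns animal, sire, dam")
        animals = [str(a) for a in df["animal"]]
        if len(set(animals)) != len(animals):
            dup = pd.Series(animals).value_counts()
            raise PedigreeError(f"duplicate animal id: {dup.index[0]}")
        parents: dict[str, tuple[str | None, str | None]] = {}
        for animal, sire, dam in zip(animals, df["sire"], df["dam"]):
            s = None if _is_missing(sire) else str(sire)
            d = None if _is_missing(dam) else str(dam)
            parents[animal] = (s, d)
        # implicit founders: parents without their own record
        for s, d in list(parents.values()):
            for p in (s, d):
                if p is not None and p not in parents:
                    parents[p] = (None, None)
        graph = nx.DiGraph()
        graph.add_nodes_from(parents)
        for child, (s, d) in parents.items():
            for p in (s, d):
                if p is not None:
                    graph.add_edge(p, child)
        try:
            order = list(nx.topological_sort(graph))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(graph)
            raise PedigreeError(f"pedigree cycle involving animal {cycle[0][0]!r}") from None
        self.ids = order
        pos = {a: i for i, a in enumerate(order)}
        self.sire_idx = np.array(
            [-1 if parents[a][0] is None else pos[parents[a][0]] for a in order], dtype=int
        )
        self.dam_idx = np.array(
            [-1 if parents[a][1] is None else pos[parents[a][1]] for a in order], dtype=int
        )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> list[str]:
        mask = (self.sire_idx < 0) & (self.dam_idx < 0)
        return [a for a, m in zip(self.ids, mask) if m]

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls(df)

    def to_csv(self, path) -> None:
        rows = []
        for i, a in enumerate(self.ids):
            s = self.ids[self.sire_idx[i]] if self.sire_idx[i] >= 0 else ""
            d = self.ids[self.dam_idx[i]] if self.dam_idx[i] >= 0 else ""
            rows.append((a, s, d))
        pd.DataFrame(rows, columns=["animal", "sire", "dam"]).to_csv(path, index=False)

    # -- relationship machinery -------------------------------------------

    def additive_relationship(self) -> pd.DataFrame:
        """Full additive relationship matrix A by the tabular method.

        ``a_ii = 1 + 0.5 * a(sire_i, dam_i)``;
        ``a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))`` for j preceding i.
        """
        n = len(self)
        A = np.zeros((n, n))
        for i in range(n):
            s, d = self.sire_idx[i], self.dam_idx[i]
            if i:
                row = np.zeros(i)
                if s >= 0:
                    row += A[s, :i]
                if d >= 0:
                    row += A[d, :i]
                row *= 0.5
                A[i, :i] = row
                A[:i, i] = row
            A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        return pd.DataFrame(A, index=self.ids, columns=self.ids)

    def inbreeding(self) -> pd.Series:
        """Per-animal inbreeding coefficient F_i = 0.5 * a(sire_i, dam_i)."""
        A = self.additive_relationship().to_numpy()
        return pd.Series(np.diag(A) - 1.0, index=self.ids, name="F")

    def a_inverse(self, as_dataframe: bool = False):
        """Sparse A^-1 assembled directly by Henderson's rules with inbreeding.

        Mendelian-sampling variance per animal:
        ``d_i = 0.5 - 0.25 (F_s + F_d)`` (both parents known),
        ``0.75 - 0.25 F_p`` (one known), ``1`` (none known).
        """
        n = len(self)
        F = self.inbreeding().to_numpy()
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []

        def add(i: int, j: int, v: float) -> None:
            rows.append(i)
            cols.append(j)
            vals.append(v)

        for i in range(n):
            s, d = self.sire_idx[i], self.dam_idx[i]
            if s >= 0 and d >= 0:
                mend = 0.5 - 0.25 * (F[s] + F[d])
            elif s >= 0 or d >= 0:
                p = s if s >= 0 else d
                mend = 0.75 - 0.25 * F[p]
            else:
                mend = 1.0
            alpha = 1.0 / mend
            add(i, i, alpha)
            for p in (s, d):
                if p >= 0:
                    add(i, p, -alpha / 2)
                    add(p, i, -alpha / 2)
            for p in (s, d):
                for q in (s, d):
                    if p >= 0 and q >= 0:
                        add(p, q, alpha / 4)
        Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        if as_dataframe:
            return pd.DataFrame(Ainv.toarray(), index=self.ids, columns=self.ids)
        return Ainv


def build_A(ped: Pedigree) -> pd.DataFrame:
    """Additive relationship matrix (tabular method); see :meth:`Pedigree.additive_relationship`."""
    return ped.additive_relationship()


def build_A_inverse(ped: Pedigree, as_dataframe: bool = True):
    """Inverse of A via Henderson's rules; see :meth:`Pedigree.a_inverse`."""
    return ped.a_inverse(as_dataframe=as_dataframe)


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    """Per-animal inbreeding coefficients; see :meth:`Pedigree.inbreeding`."""
    return ped.inbreeding()
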