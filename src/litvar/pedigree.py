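"""Pedigree container and relationship-matrix algebra.

Implements the numerator relationship matrix A by the tabular method,
per-animal inbreeding coefficients F (diagonal of A minus one), and
Henderson's rules — with the inbreeding adjustment through Mendelian-sampling
variances — for the sparse inverse of A used by the animal models.

The tabular method is O(n^2) in time and memory; that is the right trade-off
for the pedigrees this package produces (a few thousand animals over ten
discrete generations).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
import scipy.sparse as sp
from numba import njit

from .exceptions import PedigreeError

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "line", "generation"]
UNKNOWN = "0"


@njit(cache=True)
def _tabular(sire, dam):
    n = sire.size
    a = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        for i in range(j):
            v = 0.0
            if s >= 0:
                v += 0.5 * a[i, s]
            if d >= 0:
                v += 0.5 * a[i, d]
            a[i, j] = v
            a[j, i] = v
        diag = 1.0
        if s >= 0 and d >= 0:
            diag += 0.5 * a[s, d]
        a[j, j] = diag
    return a


class Pedigree:
    """Ordered pedigree with parent links and per-animal metadata.

    Animals are stored so that parents precede offspring (the input is
    topologically re-ordered if needed). Unknown parents are encoded as
    index -1 (id "0" on file).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame["id"] = frame["id"].astype(str)
        for c in ("sire", "dam"):
            frame[c] = frame[c].astype(str).replace("", UNKNOWN)
        ids = frame["id"].tolist()
        if len(set(ids)) != len(ids):
            dup = frame["id"][frame["id"].duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup!r}")
        known = set(ids)
        for col in ("sire", "dam"):
            for row, parent in zip(frame.index, frame[col]):
                if parent != UNKNOWN and parent not in known:
                    raise PedigreeError(f"unknown {col} id {parent!r} at row {row}")
        frame = self._toposort(frame)
        self.frame = frame.reset_index(drop=True)
        self.ids = self.frame["id"].to_numpy()
        self._index = {a: i for i, a in enumerate(self.ids)}
        self.sire = np.array(
            [self._index.get(s, -1) for s in self.frame["sire"]], dtype=np.int64
        )
        self.dam = np.array(
            [self._index.get(d, -1) for d in self.frame["dam"]], dtype=np.int64
        )
        self._f = None

    @staticmethod
    def _toposort(frame: pd.DataFrame) -> pd.DataFrame:
        g = nx.DiGraph()
        g.add_nodes_from(frame["id"])
        for _, row in frame.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent != UNKNOWN:
                    g.add_edge(parent, row["id"])
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            members = sorted({a for e in cycle for a in e[:2]})
            raise PedigreeError(f"pedigree contains a cycle involving {members}")
        pos = {a: i for i, a in enumerate(order)}
        return frame.iloc[np.argsort([pos[a] for a in frame["id"]])]

    # ------------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[str(a)] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree")

    @property
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficient F per animal."""
        if self._f is None:
            self._f = np.diag(_tabular(self.sire, self.dam)) - 1.0
        return self._f

    def mendelian_variances(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variances d_i in units of sigma_A^2."""
        f = self.inbreeding
        d = np.empty(len(self), dtype=float)
        for i in range(len(self)):
            s, m = self.sire[i], self.dam[i]
            if s >= 0 and m >= 0:
                d[i] = 0.5 - 0.25 * (f[s] + f[m])
            elif s >= 0 or m >= 0:
                p = s if s >= 0 else m
                d[i] = 0.75 - 0.25 * f[p]
            else:
                d[i] = 1.0
        return d


def additive_relationship(pedigree: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method."""
    return _tabular(pedigree.sire, pedigree.dam)


def a_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding adjustment."""
    n = len(pedigree)
    d = pedigree.mendelian_variances()
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, m = pedigree.sire[i], pedigree.dam[i]
        alpha = 1.0 / d[i]
        add(i, i, alpha)
        for p in (s, m):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, m):
            if p >= 0:
                for q in (s, m):
                    if q >= 0:
                        add(p, q, 0.25 * alpha)
    ai = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    ai.sum_duplicates()
    return ai
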