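"""Pedigrees and the additive (numerator) relationship matrix.

This module reads and validates pedigrees, orders them parents-first,
prunes them to a fixed ancestral horizon, and constructs the quantities
the animal model needs: the additive relationship matrix ``A`` (tabular
method, dense, small pedigrees only), per-animal inbreeding coefficients
``F`` (Meuwissen-Luo style path accumulation), and the sparse inverse of
``A`` (Henderson's rules with inbreeding).

Conventions
-----------
* Animal identifiers are opaque strings; unknown parents are coded as an
  empty string or ``"0"`` in files and as ``-1`` internally.
* Unknown parents are treated as unrelated, non-inbred founders; there
  are no unknown-parent groups.
* ``diag(A) = 1 + F`` exactly: both come from the same L-D-L'
  decomposition of A, with Mendelian-sampling variance
  ``d_i = 0.5 - 0.25 (F_sire + F_dam)`` (terms dropped per unknown
  parent), so ``|A| = prod(d_i)``.
"""

from __future__ import annotations

import heapq
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

UNKNOWN = -1

__all__ = [
    "UNKNOWN",
    "PedigreeError",
    "Pedigree",
    "RelationshipStructure",
    "read_pedigree",
    "trace_back",
    "inbreeding",
    "mendelian_variances",
    "build_A",
    "build_A_inverse",
    "relationship_structure",
    "relationship_submatrix",
    "write_a_inverse",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, ...)."""


@dataclass
class Pedigree:
    """A validated, parents-first ordered pedigree.

    Attributes
    ----------
    ids : tuple of str
        Animal identifiers in topological (parents-first) order.
    sire, dam : ndarray of int
        Position of each animal's parent in ``ids``; ``-1`` if unknown.
    input_position : ndarray of int
        Position each animal had in the input record list (auto-added
        founders get positions past the end of the input).
    meta : pandas.DataFrame or None
        Optional per-animal annotations (e.g. generation, sex) attached
        by the synthetic-data generator; aligned with ``ids``.
    """

    ids: tuple
    sire: np.ndarray
    dam: np.ndarray
    input_position: np.ndarray
    meta: pd.DataFrame | None = field(default=None, compare=False)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.ids)

    @property
    def index(self) -> Mapping[str, int]:
        idx = getattr(self, "_index", None)
        if idx is None:
            idx = {a: i for i, a in enumerate(self.ids)}
            object.__setattr__(self, "_index", idx)
        return idx

    def position(self, animal: str) -> int:
        try:
            return self.index[animal]
        except KeyError:
            raise PedigreeError(f"animal id not in pedigree: {animal!r}") from None

    @property
    def is_founder(self) -> np.ndarray:
        """True where both parents are unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        def name(j):
            return "" if j == UNKNOWN else self.ids[j]

        return pd.DataFrame(
            {
                "animal": list(self.ids),
                "sire": [name(j) for j in self.sire],
                "dam": [name(j) for j in self.dam],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    # -- structure -------------------------------------------------------
    def generation_depth(self, base: Iterable[str] | None = None) -> np.ndarray:
        """Meioses separating each animal from a *base* set, tracing upward.

        ``depth[i] = 0`` for base animals and ``k`` for an ancestor whose
        shortest descent path to any base animal has ``k`` meioses.
        Animals that are neither base animals nor their ancestors get
        ``-1``.  Default base: animals that are nobody's parent.
        """
        if base is None:
            is_parent = np.zeros(self.n, dtype=bool)
            for arr in (self.sire, self.dam):
                known = arr[arr != UNKNOWN]
                is_parent[known] = True
            base_idx = np.nonzero(~is_parent)[0]
        else:
            base_idx = np.array([self.position(a) for a in base], dtype=int)
        depth = np.full(self.n, -1, dtype=int)
        depth[base_idx] = 0
        # offspring precede their parents when walking the order backwards
        for i in range(self.n - 1, -1, -1):
            if depth[i] < 0:
                continue
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and (depth[p] < 0 or depth[p] > depth[i] + 1):
                    depth[p] = depth[i] + 1
        return depth

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "Pedigree":
        """Validate and topologically order raw (animal, sire, dam) triples.

        Unknown parents are ``None``, ``""`` or ``"0"``.  Parents that
        appear only as parents are auto-added as founders (with a
        warning).  Duplicate ids and ancestry cycles raise
        :class:`PedigreeError`.
        """
        animals: list[str] = []
        sires: list[str | None] = []
        dams: list[str | None] = []
        seen: set[str] = set()

        def norm(x):
            if x is None:
                return None
            x = str(x).strip()
            return None if x in ("", "0") else x

        for rec in records:
            a, s, d = rec
            a = str(a).strip()
            if not a or a == "0":
                raise PedigreeError("empty animal id in pedigree record")
            if a in seen:
                raise PedigreeError(f"duplicate animal id: {a!r}")
            seen.add(a)
            animals.append(a)
            sires.append(norm(s))
            dams.append(norm(d))

        extra = []
        for plist in (sires, dams):
            for p in plist:
                if p is not None and p not in seen:
                    seen.add(p)
                    extra.append(p)
        if extra:
            warnings.warn(
                f"{len(extra)} parent(s) without their own record were added "
                f"as founders (e.g. {extra[0]!r})",
                stacklevel=2,
            )
            for p in extra:
                animals.append(p)
                sires.append(None)
                dams.append(None)

        n = len(animals)
        pos_in = {a: i for i, a in enumerate(animals)}
        sidx = np.array([UNKNOWN if s is None else pos_in[s] for s in sires])
        didx = np.array([UNKNOWN if d is None else pos_in[d] for d in dams])

        order = _toposort(n, sidx, didx, animals)
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        ids = tuple(animals[i] for i in order)
        new_sire = np.array(
            [UNKNOWN if sidx[i] == UNKNOWN else rank[sidx[i]] for i in order]
        )
        new_dam = np.array(
            [UNKNOWN if didx[i] == UNKNOWN else rank[didx[i]] for i in order]
        )
        return cls(
            ids=ids,
            sire=new_sire,
            dam=new_dam,
            input_position=np.asarray(order, dtype=int),
        )


def _toposort(n: int, sire: np.ndarray, dam: np.ndarray, names: Sequence[str]) -> list:
    """Stable Kahn ordering placing every parent before its offspring."""
    children: list[list[int]] = [[] for _ in range(n)]
    pending = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                children[p].append(i)
                pending[i] += 1
    ready = deque(i for i in range(n) if pending[i] == 0)
    order: list[int] = []
    while ready:
        i = ready.popleft()
        order.append(i)
        for c in children[i]:
            pending[c] -= 1
            if pending[c] == 0:
                ready.append(c)
    if len(order) < n:
        cycle = _find_cycle(n, sire, dam, set(order), names)
        raise PedigreeError("ancestry cycle detected: " + " -> ".join(cycle))
    return order


def _find_cycle(n, sire, dam, placed, names) -> list:
    leftover = next(i for i in range(n) if i not in placed)
    seen_at: dict[int, int] = {}
    path = [leftover]
    cur = leftover
    while cur not in seen_at:
        seen_at[cur] = len(path) - 1
        # follow a parent that is itself unplaced (must exist for a stuck node)
        nxt = None
        for p in (sire[cur], dam[cur]):
            if p != UNKNOWN and p not in placed:
                nxt = p
                break
        path.append(nxt)
        cur = nxt
    cyc = path[seen_at[cur]:]
    return [names[i] for i in cyc]


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with header ``animal,sire,dam``.

    Unknown parents are empty cells or ``"0"``.  See
    :meth:`Pedigree.from_records` for validation behaviour.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["animal", "sire", "dam"]:
        raise PedigreeError(
            f"pedigree file must have header 'animal,sire,dam'; got {list(df.columns)!r}"
        )
    df.columns = cols
    return Pedigree.from_records(df[["animal", "sire", "dam"]].itertuples(index=False))


def trace_back(ped: Pedigree, base: Iterable[str], max_generations: int) -> Pedigree:
    """Prune ``ped`` to *base* animals plus ancestors within a horizon.

    Keeps every animal reachable from ``base`` in at most
    ``max_generations`` meioses tracing upward; parents beyond the
    horizon are recoded unknown.  Tracing an already-traced pedigree at
    the same horizon is a no-op on the animal set.
    """
    if max_generations < 0:
        raise ValueError("max_generations must be >= 0")
    base = list(base)
    depth = ped.generation_depth(base)  # raises on unknown base ids
    keep = np.nonzero((depth >= 0) & (depth <= max_generations))[0]
    keep_set = set(keep.tolist())
    records = []
    for i in keep:
        s = ped.sire[i] if ped.sire[i] in keep_set else UNKNOWN
        d = ped.dam[i] if ped.dam[i] in keep_set else UNKNOWN
        records.append(
            (
                ped.ids[i],
                None if s == UNKNOWN else ped.ids[s],
                None if d == UNKNOWN else ped.ids[d],
            )
        )
    out = Pedigree.from_records(records)
    if ped.meta is not None:
        out.meta = (
            ped.meta.iloc[[ped.position(a) for a in out.ids]].reset_index(drop=True)
        )
    return out


# ---------------------------------------------------------------------------
# Relationship machinery
# ---------------------------------------------------------------------------


@dataclass
class RelationshipStructure:
    """Additive relationships for one pedigree.

    ``A`` is dense and only present for small pedigrees; ``A_inv`` is the
    sparse inverse built from Henderson's rules; ``F`` are inbreeding
    coefficients; ``log_det_A`` is ``log|A| = sum(log d_i)``.
    """

    ids: tuple
    F: np.ndarray
    A: np.ndarray | None = None
    A_inv: sparse.csr_matrix | None = None
    log_det_A: float | None = None

    @property
    def n(self) -> int:
        return len(self.ids)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by Meuwissen-Luo path accumulation.

    Founders and animals with any unknown parent have ``F = 0``.  For the
    rest, ``A_ii = sum_j L_ij^2 d_j`` is accumulated over the ancestor
    paths, and ``F_i = A_ii - 1``.
    """
    F, _ = _inbreeding_and_d(ped)
    return F


def mendelian_variances(ped: Pedigree) -> np.ndarray:
    """Mendelian-sampling variances ``d_i`` of the L-D-L' decomposition."""
    _, D = _inbreeding_and_d(ped)
    return D


def _inbreeding_and_d(ped: Pedigree):
    n = ped.n
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.ones(n)
    for i in range(n):
        si, di = s[i], d[i]
        if si == UNKNOWN and di == UNKNOWN:
            D[i] = 1.0
            continue
        if si == UNKNOWN or di == UNKNOWN:
            known = di if si == UNKNOWN else si
            D[i] = 0.75 - 0.25 * F[known]
            continue
        D[i] = 0.5 - 0.25 * (F[si] + F[di])
        # accumulate A_ii over ancestors, largest index first
        w = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            v = w.pop(j, 0.0)
            if v == 0.0:
                continue
            a_ii += v * v * D[j]
            for p in (s[j], d[j]):
                if p != UNKNOWN:
                    if p not in w:
                        heapq.heappush(heap, -p)
                        w[p] = 0.0
                    w[p] += 0.5 * v
        F[i] = a_ii - 1.0
    return F, D


def build_A(ped: Pedigree, dense_limit: int = 2000) -> RelationshipStructure:
    """Dense numerator relationship matrix by the tabular method.

    ``a(i,j) = 0.5 (a(j, sire_i) + a(j, dam_i))`` for ``j < i`` and
    ``a(i,i) = 1 + 0.5 a(sire_i, dam_i)``, with unknown parents
    contributing zero.  Refuses pedigrees above ``dense_limit``.
    """
    n = ped.n
    if n > dense_limit:
        raise PedigreeError(
            f"pedigree has {n} animals, above the dense limit {dense_limit}; "
            "use build_A_inverse for the sparse route"
        )
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        if i > 0:
            row = np.zeros(i)
            if si != UNKNOWN:
                row += 0.5 * A[:i, si]
            if di != UNKNOWN:
                row += 0.5 * A[:i, di]
            A[i, :i] = row
            A[:i, i] = row
        aii = 1.0
        if si != UNKNOWN and di != UNKNOWN:
            aii += 0.5 * A[si, di]
        A[i, i] = aii
    F = np.diag(A) - 1.0
    _, D = _inbreeding_and_d(ped)
    return RelationshipStructure(
        ids=ped.ids, F=F, A=A, log_det_A=float(np.log(D).sum())
    )


def build_A_inverse(ped: Pedigree) -> RelationshipStructure:
    """Sparse inverse of A from Henderson's rules with inbreeding.

    Each animal contributes ``alpha = 1/d_i`` to at most nine cells:
    ``+alpha`` at (i,i), ``-alpha/2`` at (i,parent), ``+alpha/4`` at
    (parent,parent) and (sire,dam), terms dropped for unknown parents.
    """
    n = ped.n
    F, D = _inbreeding_and_d(ped)
    alpha = 1.0 / D
    s, d = ped.sire, ped.dam
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    i = np.arange(n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(i, i, alpha)
    for p in (s, d):
        k = p != UNKNOWN
        add(i[k], p[k], -0.5 * alpha[k])
        add(p[k], i[k], -0.5 * alpha[k])
        add(p[k], p[k], 0.25 * alpha[k])
    both = (s != UNKNOWN) & (d != UNKNOWN)
    add(s[both], d[both], 0.25 * alpha[both])
    add(d[both], s[both], 0.25 * alpha[both])

    Ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return RelationshipStructure(
        ids=ped.ids, F=F, A_inv=Ainv, log_det_A=float(np.log(D).sum())
    )


def relationship_structure(ped: Pedigree, dense_limit: int = 2000) -> RelationshipStructure:
    """Sparse A-inverse plus, when the pedigree is small enough, dense A."""
    rel = build_A_inverse(ped)
    if ped.n <= dense_limit:
        rel.A = build_A(ped, dense_limit=dense_limit).A
    return rel


def relationship_submatrix(rel: RelationshipStructure, positions: Sequence[int]) -> np.ndarray:
    """Dense block of A for a subset of animals (by pedigree position).

    Uses the stored dense A when available, otherwise solves
    ``A_inv W = E`` column-block-wise with a sparse LU factorisation.
    """
    positions = np.asarray(positions, dtype=int)
    if rel.A is not None:
        return rel.A[np.ix_(positions, positions)]
    if rel.A_inv is None:
        raise ValueError("RelationshipStructure has neither A nor A_inv")
    lu = splu(rel.A_inv.tocsc())
    rhs = np.zeros((rel.n, len(positions)))
    rhs[positions, np.arange(len(positions))] = 1.0
    W = lu.solve(rhs)
    sub = W[positions, :]
    return 0.5 * (sub + sub.T)  # symmetrise away solver round-off


def write_a_inverse(rel: RelationshipStructure, path) -> None:
    """Write A-inverse as 1-based lower-triangle coordinate text (i j value)."""
    if rel.A_inv is None:
        raise ValueError("no A_inv present")
    coo = sparse.tril(rel.A_inv.tocoo())
    with open(path, "w") as fh:
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r + 1} {c + 1} {v:.12g}\n")
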