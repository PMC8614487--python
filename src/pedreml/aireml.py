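"""Average-information REML for pedigree-based animal models.

Fits the variance components of ``y = Xb + Zu + e`` with
``Var(u) = G (x) A`` and ``Var(e) = R (x) I`` for one or two traits, where
``A`` is the numerator relationship matrix.  Because ``u`` is integrated
out, everything is evaluated on the observed records only:

    V = (G (x) A_phi) restricted to observed (animal, trait) pairs + R-blocks

with ``A_phi`` the relationship block among phenotyped animals.  Two
exact evaluation strategies share one interface:

* ``_EigenWorkspace`` - when every phenotyped animal has records for all
  traits, a single symmetric eigendecomposition ``A_phi = U D U'`` turns
  V into independent t x t blocks per eigen-record; each REML iteration
  is then O(n).
* ``_DenseWorkspace`` - arbitrary missing-trait patterns; builds V
  densely on the stacked records (small and medium problems).

Both provide the restricted log-likelihood, its analytic gradient, the
average-information matrix and an exact EM update, so the driver
(`fit`) can take AI steps with step-halving and fall back to EM, using
the relative-change convergence criterion
``C = sum_i (theta_i - theta_i*)^2 / sum_i theta_i^2`` with a default
stopping tolerance of 1e-12.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg

from .design import DesignMatrices
from .pedigree import RelationshipStructure, relationship_submatrix

__all__ = [
    "VarianceComponents",
    "REMLFit",
    "ParameterMap",
    "convergence_criterion",
    "restricted_log_likelihood",
    "em_update",
    "ai_update",
    "fit",
    "fit_constrained",
    "default_start",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VarianceComponents:
    """Additive-genetic (G) and residual (R) covariance matrices, t in {1, 2}."""

    G: np.ndarray
    R: np.ndarray
    traits: tuple | None = None

    def __post_init__(self):
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if self.G.shape != self.R.shape or self.G.shape[0] != self.G.shape[1]:
            raise ValueError("G and R must be square matrices of equal size")
        if not (np.allclose(self.G, self.G.T) and np.allclose(self.R, self.R.T)):
            raise ValueError("G and R must be symmetric")

    @property
    def n_traits(self) -> int:
        return self.G.shape[0]

    @property
    def P(self) -> np.ndarray:
        """Phenotypic covariance matrix G + R."""
        return self.G + self.R

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(self.G.copy(), self.R.copy(), self.traits)


class ParameterMap:
    """Order of the free parameters: unique elements of G, then of R.

    Covariance elements can be excluded (held at zero) for the reduced
    models of the likelihood-ratio tests.
    """

    def __init__(self, n_traits: int, free_genetic_cov: bool = True,
                 free_residual_cov: bool = True):
        self.n_traits = n_traits
        self.entries: list[tuple[str, int, int]] = []
        for mat, free_cov in (("G", free_genetic_cov), ("R", free_residual_cov)):
            for i in range(n_traits):
                for j in range(i, n_traits):
                    if i != j and not free_cov:
                        continue
                    self.entries.append((mat, i, j))

    @property
    def k(self) -> int:
        return len(self.entries)

    def names(self, traits: Sequence[str] | None = None) -> list[str]:
        tn = list(traits) if traits else [str(i) for i in range(self.n_traits)]
        out = []
        for mat, i, j in self.entries:
            kind = "sigma2_g" if mat == "G" else "sigma2_e"
            if i == j:
                out.append(f"{kind}[{tn[i]}]")
            else:
                out.append(f"{'sigma_g' if mat == 'G' else 'sigma_e'}[{tn[i]},{tn[j]}]")
        return out

    def pack(self, G: np.ndarray, R: np.ndarray) -> np.ndarray:
        src = {"G": G, "R": R}
        return np.array([src[m][i, j] for m, i, j in self.entries])

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = self.n_traits
        G = np.zeros((t, t))
        R = np.zeros((t, t))
        dst = {"G": G, "R": R}
        for val, (m, i, j) in zip(theta, self.entries):
            dst[m][i, j] = val
            dst[m][j, i] = val
        return G, R

    def bases(self) -> list[tuple[str, np.ndarray]]:
        """(matrix-name, symmetric derivative basis) per parameter."""
        t = self.n_traits
        out = []
        for m, i, j in self.entries:
            S = np.zeros((t, t))
            S[i, j] = S[j, i] = 1.0
            out.append((m, S))
        return out


def convergence_criterion(theta: np.ndarray, theta_prev: np.ndarray) -> float:
    """Relative squared change ``sum (th - th*)^2 / sum th^2``."""
    theta = np.asarray(theta, dtype=float)
    theta_prev = np.asarray(theta_prev, dtype=float)
    if theta.shape != theta_prev.shape:
        raise ValueError("theta vectors must have the same length")
    denom = float(np.sum(theta**2))
    if denom == 0.0:
        raise ValueError("convergence criterion undefined for all-zero theta")
    return float(np.sum((theta - theta_prev) ** 2) / denom)


# ---------------------------------------------------------------------------
# Workspaces
# ---------------------------------------------------------------------------


class _EigenWorkspace:
    """Complete-record path: A_phi = U D U' turns V block-diagonal."""

    def __init__(self, dm: DesignMatrices, A_phi: np.ndarray,
                 animal_order: np.ndarray, n_pedigree: int):
        t = dm.n_traits
        self.t = t
        self.q = n_pedigree
        d, U = np.linalg.eigh(A_phi)
        self.d = np.clip(d, 0.0, None)
        n = A_phi.shape[0]
        self.n = n
        ytil = np.empty((n, t))
        p_offsets = []
        p_total = 0
        Xs = []
        for k, trait in enumerate(dm.traits):
            blk = dm.block(trait)
            order = np.argsort(blk.animal_index)
            pos_sorted = blk.animal_index[order]
            if not np.array_equal(pos_sorted, animal_order):
                raise ValueError("eigen workspace requires identical animal sets")
            ytil[:, k] = U.T @ blk.y[order]
            Xs.append(U.T @ blk.X[order])
            p_offsets.append(p_total)
            p_total += blk.X.shape[1]
        self.p = p_total
        self.N = n * t
        Xr = np.zeros((n, t, p_total))
        for k in range(t):
            pk = Xs[k].shape[1]
            Xr[:, k, p_offsets[k]:p_offsets[k] + pk] = Xs[k]
        self.Xr = Xr
        self.y = ytil
        self.vp = np.array([np.var(dm.block(tr).y, ddof=1) for tr in dm.traits])
        self.n_records = {tr: dm.block(tr).n_records for tr in dm.traits}

    # -- state -----------------------------------------------------------
    def state(self, G: np.ndarray, R: np.ndarray) -> "_EigenState":
        return _EigenState(self, G, R)


class _EigenState:
    def __init__(self, ws: _EigenWorkspace, G, R):
        self.ws = ws
        self.G = G
        self.R = R
        n, t = ws.n, ws.t
        V = ws.d[:, None, None] * G[None, :, :] + R[None, :, :]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            raise linalg.LinAlgError(
                "V is not positive definite; try bending or better start values"
            ) from None
        self.logdetV = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
        self.Vinv = np.linalg.inv(V)
        B = np.einsum("rts,rsp->rtp", self.Vinv, ws.Xr)
        self.B = B
        M = np.einsum("rtp,rtq->pq", ws.Xr, B)
        self.M = M
        self.cM = linalg.cho_factor(M)
        Viy = np.einsum("rts,rs->rt", self.Vinv, ws.y)
        Xty = np.einsum("rtp,rt->p", B, ws.y)
        beta = linalg.cho_solve(self.cM, Xty)
        self.beta = beta
        self.w = Viy - np.einsum("rtp,p->rt", B, beta)  # = (Py), transformed
        self.yPy = float(np.einsum("rt,rt->", ws.y, self.w))
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            raise linalg.LinAlgError("X'V^-1 X not positive definite")
        self.logdetM = float(logdetM)
        self.logL = -0.5 * (
            self.logdetV + self.logdetM + self.yPy + (ws.N - ws.p) * _LOG2PI
        )

    def _proj(self, f: np.ndarray) -> np.ndarray:
        """Apply P to a stacked (n, t) vector."""
        Vif = np.einsum("rts,rs->rt", self.Vinv, f)
        Xtf = np.einsum("rtp,rt->p", self.B, f)
        return Vif - np.einsum("rtp,p->rt", self.B, linalg.cho_solve(self.cM, Xtf))

    def score_ai(self, pmap: ParameterMap):
        ws = self.ws
        k = pmap.k
        grad = np.empty(k)
        fs = []
        for idx, (mat, S) in enumerate(pmap.bases()):
            c = ws.d if mat == "G" else np.ones(ws.n)
            trV = float(np.einsum("r,rts,st->", c, self.Vinv, S))
            H = np.einsum("r,rtp,ts,rsq->pq", c, self.B, S, self.B, optimize=True)
            trPV = trV - float(np.trace(linalg.cho_solve(self.cM, H)))
            Sw = np.einsum("ts,rs->rt", S, self.w)
            quad = float(np.einsum("r,rt,rt->", c, self.w, Sw))
            grad[idx] = -0.5 * (trPV - quad)
            fs.append(c[:, None] * Sw)
        AI = np.empty((k, k))
        Pf = [self._proj(f) for f in fs]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(np.einsum("rt,rt->", fs[i], Pf[j]))
        return grad, AI

    def em_step(self, pmap: ParameterMap):
        ws = self.ws
        Minv_Bt = np.einsum("pq,rtq->rtp", _chol_inverse(self.cM), self.B)
        Prr = self.Vinv - np.einsum("rtp,rsp->rts", self.B, Minv_Bt)
        T = np.einsum("r,rkl->kl", ws.d, Prr)
        T2 = np.einsum("r,rk,rl->kl", ws.d, self.w, self.w)
        G_new = self.G + self.G @ (T2 - T) @ self.G / ws.q
        e = self.w @ self.R  # R w_r per record (R symmetric)
        Ree = e.T @ e
        Psum = Prr.sum(axis=0)
        R_new = (Ree + ws.n * self.R - self.R @ Psum @ self.R) / ws.n
        return _apply_cov_constraints(G_new, R_new, pmap)


def _chol_inverse(cfac) -> np.ndarray:
    n = cfac[0].shape[0]
    return linalg.cho_solve(cfac, np.eye(n))


class _DenseWorkspace:
    """General path: dense V on the stacked observed records."""

    def __init__(self, dm: DesignMatrices, A_phi: np.ndarray,
                 local_of_position: dict, n_pedigree: int):
        t = dm.n_traits
        self.t = t
        self.q = n_pedigree
        an_parts, tr_parts, y_parts, X_parts = [], [], [], []
        p_total = sum(dm.block(tr).X.shape[1] for tr in dm.traits)
        offset = 0
        for k, trait in enumerate(dm.traits):
            blk = dm.block(trait)
            m = blk.n_records
            an_parts.append(
                np.array([local_of_position[p] for p in blk.animal_index])
            )
            tr_parts.append(np.full(m, k))
            y_parts.append(blk.y)
            Xk = np.zeros((m, p_total))
            Xk[:, offset:offset + blk.X.shape[1]] = blk.X
            offset += blk.X.shape[1]
            X_parts.append(Xk)
        self.an = np.concatenate(an_parts)
        self.tr = np.concatenate(tr_parts)
        self.y = np.concatenate(y_parts)
        self.X = np.vstack(X_parts)
        self.N = len(self.y)
        self.p = p_total
        self.Asub = A_phi[np.ix_(self.an, self.an)]
        self.same = self.an[:, None] == self.an[None, :]
        self.vp = np.array([np.var(dm.block(tr).y, ddof=1) for tr in dm.traits])
        self.n_records = {tr: dm.block(tr).n_records for tr in dm.traits}

    def state(self, G, R):
        return _DenseState(self, G, R)


class _DenseState:
    def __init__(self, ws: _DenseWorkspace, G, R):
        self.ws = ws
        self.G = G
        self.R = R
        tr = ws.tr
        V = G[np.ix_(tr, tr)] * ws.Asub + np.where(ws.same, R[np.ix_(tr, tr)], 0.0)
        self.Rbig = np.where(ws.same, R[np.ix_(tr, tr)], 0.0)
        try:
            c = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            raise linalg.LinAlgError(
                "V is not positive definite; try bending or better start values"
            ) from None
        self.logdetV = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        self.Vinv = linalg.cho_solve(c, np.eye(ws.N))
        B = self.Vinv @ ws.X
        self.B = B
        M = ws.X.T @ B
        self.M = M
        self.cM = linalg.cho_factor(M)
        beta = linalg.cho_solve(self.cM, B.T @ ws.y)
        self.beta = beta
        self.w = self.Vinv @ ws.y - B @ beta
        self.yPy = float(ws.y @ self.w)
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            raise linalg.LinAlgError("X'V^-1 X not positive definite")
        self.logdetM = float(logdetM)
        self.logL = -0.5 * (
            self.logdetV + self.logdetM + self.yPy + (ws.N - ws.p) * _LOG2PI
        )
        self._P = None

    @property
    def P(self) -> np.ndarray:
        if self._P is None:
            self._P = self.Vinv - self.B @ linalg.cho_solve(self.cM, self.B.T)
        return self._P

    def _vi(self, mat: str, S: np.ndarray) -> np.ndarray:
        ws = self.ws
        pat = S[np.ix_(ws.tr, ws.tr)]
        if mat == "G":
            return pat * ws.Asub
        return np.where(ws.same, pat, 0.0)

    def score_ai(self, pmap: ParameterMap):
        k = pmap.k
        grad = np.empty(k)
        fs = []
        P = self.P
        for idx, (mat, S) in enumerate(pmap.bases()):
            Vi = self._vi(mat, S)
            trPV = float(np.sum(P * Vi))
            f = Vi @ self.w
            quad = float(self.w @ f)
            grad[idx] = -0.5 * (trPV - quad)
            fs.append(f)
        AI = np.empty((k, k))
        Pf = [P @ f for f in fs]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(fs[i] @ Pf[j])
        return grad, AI

    def em_step(self, pmap: ParameterMap):
        ws = self.ws
        t = ws.t
        P = self.P
        T = np.empty((t, t))
        T2 = np.empty((t, t))
        rows = [ws.tr == k for k in range(t)]
        for i in range(t):
            for j in range(i, t):
                blkP = P[np.ix_(rows[i], rows[j])]
                blkA = ws.Asub[np.ix_(rows[i], rows[j])]
                T[i, j] = T[j, i] = float(np.sum(blkP * blkA))
                T2[i, j] = T2[j, i] = float(
                    self.w[rows[i]] @ blkA @ self.w[rows[j]]
                )
        G_new = self.G + self.G @ (T2 - T) @ self.G / ws.q
        # residual E-step on the observed patterns
        e = self.Rbig @ self.w
        Cond = self.Rbig - self.Rbig @ P @ self.Rbig
        R_new = np.empty((t, t))
        for i in range(t):
            for j in range(i, t):
                sel = ws.same & np.outer(rows[i], rows[j])
                n_ij = int(np.count_nonzero(sel))
                if n_ij == 0:
                    R_new[i, j] = R_new[j, i] = self.R[i, j]
                    continue
                total = float(np.sum(np.outer(e, e)[sel]) + np.sum(Cond[sel]))
                R_new[i, j] = R_new[j, i] = total / n_ij
        return _apply_cov_constraints(G_new, R_new, pmap)


def _apply_cov_constraints(G, R, pmap: ParameterMap):
    free = {(m, i, j) for m, i, j in pmap.entries}
    t = pmap.n_traits
    for i in range(t):
        for j in range(i + 1, t):
            if ("G", i, j) not in free:
                G[i, j] = G[j, i] = 0.0
            if ("R", i, j) not in free:
                R[i, j] = R[j, i] = 0.0
    return G, R


def build_workspace(dm: DesignMatrices, rel: RelationshipStructure,
                    prefer_eigen: bool = True):
    """Choose the evaluation strategy for one design + relationship pair."""
    positions = np.unique(np.concatenate(
        [dm.block(t).animal_index for t in dm.traits]
    ))
    A_phi = relationship_submatrix(rel, positions)
    local = {int(p): i for i, p in enumerate(positions)}
    complete = all(
        len(dm.block(t).animal_index) == len(positions)
        and len(np.unique(dm.block(t).animal_index)) == len(positions)
        for t in dm.traits
    )
    if complete and prefer_eigen:
        return _EigenWorkspace(dm, A_phi, positions, rel.n)
    return _DenseWorkspace(dm, A_phi, local, rel.n)


# ---------------------------------------------------------------------------
# Public single-step operations
# ---------------------------------------------------------------------------


def restricted_log_likelihood(vc: VarianceComponents, dm: DesignMatrices,
                              rel: RelationshipStructure) -> float:
    """REML log-likelihood (error-contrast likelihood) at the given G, R."""
    ws = build_workspace(dm, rel)
    return ws.state(vc.G, vc.R).logL


def em_update(vc: VarianceComponents, dm: DesignMatrices,
              rel: RelationshipStructure) -> VarianceComponents:
    """One exact EM-REML update; never decreases the restricted logL."""
    ws = build_workspace(dm, rel)
    pmap = ParameterMap(vc.n_traits)
    G, R = ws.state(vc.G, vc.R).em_step(pmap)
    return VarianceComponents(G, R, vc.traits)


def ai_update(vc: VarianceComponents, dm: DesignMatrices,
              rel: RelationshipStructure, max_step_halving: int = 10):
    """One average-information update with step-halving / EM fallback.

    Returns ``(VarianceComponents, AI matrix)`` where the AI matrix is
    evaluated at the *input* parameter values.
    """
    ws = build_workspace(dm, rel)
    pmap = ParameterMap(vc.n_traits)
    state = ws.state(vc.G, vc.R)
    grad, AI = state.score_ai(pmap)
    theta = pmap.pack(vc.G, vc.R)
    theta_new, _, _ = _try_ai_step(ws, pmap, state, theta, grad, AI,
                                   ws.vp, max_step_halving)
    if theta_new is None:
        G, R = state.em_step(pmap)
        warnings.warn("AI step failed to improve the likelihood; EM fallback used")
        return VarianceComponents(G, R, vc.traits), AI
    G, R = pmap.unpack(theta_new)
    return VarianceComponents(G, R, vc.traits), AI


# ---------------------------------------------------------------------------
# Fit driver
# ---------------------------------------------------------------------------


@dataclass
class REMLFit:
    """Converged (or flagged) REML solution.

    ``theta`` holds the free parameters (unique elements of G then R),
    ``theta_cov`` the inverse of the final average-information matrix.
    """

    vc: VarianceComponents
    theta: np.ndarray
    param_names: list
    theta_cov: np.ndarray
    loglik: float
    trace: list
    converged: bool
    n_iterations: int
    boundary: bool
    bent: bool
    pmap: ParameterMap = field(repr=False, default=None)
    n_records: dict = field(default_factory=dict)

    def summary_frame(self):
        import pandas as pd

        se = np.sqrt(np.clip(np.diag(self.theta_cov), 0.0, None))
        return pd.DataFrame(
            {"parameter": self.param_names, "estimate": self.theta, "se": se}
        )


def default_start(dm: DesignMatrices, free_genetic_cov=True,
                  free_residual_cov=True) -> VarianceComponents:
    """Heuristic start: 40% of the phenotypic variance to G, 60% to R."""
    vp = np.array([np.var(dm.block(t).y, ddof=1) for t in dm.traits])
    return VarianceComponents(np.diag(0.4 * vp), np.diag(0.6 * vp), dm.traits)


def _sanitize(G, R, vp, bend_floor=1e-8, var_floor=1e-10):
    """Clip variances to the floor and bend G/R back into the PD cone."""
    boundary = False
    bent = False
    G = G.copy()
    R = R.copy()
    for M_ in (G, R):
        floor = var_floor * vp
        dg = np.diag(M_).copy()
        low = dg < floor
        if low.any():
            boundary = True
            np.fill_diagonal(M_, np.where(low, floor, dg))
    for name, M_ in (("G", G), ("R", R)):
        w_, Q = np.linalg.eigh(M_)
        lo = bend_floor * max(np.trace(M_), 1e-300)
        if w_.min() < lo:
            bent = True
            w_ = np.clip(w_, lo, None)
            M_new = Q @ np.diag(w_) @ Q.T
            if name == "G":
                G = 0.5 * (M_new + M_new.T)
            else:
                R = 0.5 * (M_new + M_new.T)
    return G, R, boundary, bent


def _try_ai_step(ws, pmap, state, theta, grad, AI, vp, max_halving):
    """Propose theta + AI^-1 grad, halving until logL does not decrease."""
    k = pmap.k
    try:
        delta = np.linalg.solve(AI + 1e-12 * np.eye(k) * max(np.trace(AI), 1.0),
                                grad)
    except np.linalg.LinAlgError:
        delta = np.linalg.pinv(AI) @ grad
    for h in range(max_halving + 1):
        cand = theta + delta / (2.0 ** h)
        G, R = pmap.unpack(cand)
        G, R, boundary, bent = _sanitize(G, R, vp)
        try:
            st = ws.state(G, R)
        except linalg.LinAlgError:
            continue
        if st.logL >= state.logL - 1e-10:
            return pmap.pack(G, R), st, (boundary, bent)
    return None, None, (False, False)


def fit(
    dm: DesignMatrices,
    rel: RelationshipStructure,
    start: VarianceComponents | None = None,
    tol: float = 1e-12,
    max_iter: int = 200,
    *,
    free_genetic_cov: bool = True,
    free_residual_cov: bool = True,
    em_warmup: int = 2,
    method: str = "ai",
    max_step_halving: int = 10,
) -> REMLFit:
    """REML fit by the average-information algorithm with EM fallback.

    Parameters
    ----------
    dm, rel
        Design blocks and relationship structure (must refer to the same
        pedigree order).
    start
        Initial (G, R); defaults to a 40/60 split of the per-trait
        phenotypic variance with zero covariances.
    tol
        Stop when ``C = sum (th - th*)^2 / sum th^2 < tol``.
    method
        ``"ai"`` (EM warm-up then AI steps, EM fallback) or ``"em"``
        (pure EM; slow but monotone - used for diagnostics).

    Deterministic given identical inputs and start values.
    """
    ws = build_workspace(dm, rel)
    pmap = ParameterMap(dm.n_traits, free_genetic_cov, free_residual_cov)
    if start is None:
        start = default_start(dm)
    G, R = _apply_cov_constraints(start.G.copy(), start.R.copy(), pmap)
    G, R, boundary_any, bent_any = _sanitize(G, R, ws.vp)
    theta = pmap.pack(G, R)
    state = ws.state(G, R)
    trace: list[dict] = [
        {"iteration": 0, "theta": theta.copy(), "logL": state.logL,
         "C": np.inf, "step": "start"}
    ]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        use_em = method == "em" or it <= em_warmup
        step_name = "em"
        if use_em:
            G_new, R_new = state.em_step(pmap)
            G_new, R_new, bd, bt = _sanitize(G_new, R_new, ws.vp)
            theta_new = pmap.pack(G_new, R_new)
            new_state = ws.state(G_new, R_new)
        else:
            grad, AI = state.score_ai(pmap)
            theta_new, new_state, (bd, bt) = _try_ai_step(
                ws, pmap, state, theta, grad, AI, ws.vp, max_step_halving
            )
            step_name = "ai"
            if theta_new is None:
                G_new, R_new = state.em_step(pmap)
                G_new, R_new, bd, bt = _sanitize(G_new, R_new, ws.vp)
                theta_new = pmap.pack(G_new, R_new)
                new_state = ws.state(G_new, R_new)
                step_name = "em-fallback"
        boundary_any |= bd
        bent_any |= bt
        C = convergence_criterion(theta_new, theta)
        theta = theta_new
        state = new_state
        trace.append({"iteration": it, "theta": theta.copy(),
                      "logL": state.logL, "C": C, "step": step_name})
        if C < tol and not (method == "ai" and it <= em_warmup):
            converged = True
            break
    G, R = pmap.unpack(theta)
    _, AI = state.score_ai(pmap)
    try:
        theta_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        theta_cov = np.linalg.pinv(AI)
    theta_cov = 0.5 * (theta_cov + theta_cov.T)
    return REMLFit(
        vc=VarianceComponents(G, R, dm.traits),
        theta=theta,
        param_names=pmap.names(dm.traits),
        theta_cov=theta_cov,
        loglik=state.logL,
        trace=trace,
        converged=converged,
        n_iterations=it,
        boundary=boundary_any,
        bent=bent_any,
        pmap=pmap,
        n_records=dict(ws.n_records),
    )


def fit_constrained(dm: DesignMatrices, rel: RelationshipStructure,
                    constraint: str, **kwargs) -> REMLFit:
    """Reduced-model fit with covariance parameters fixed at zero.

    ``constraint`` is ``"zero-genetic-cov"`` (G diagonal; the df = 1
    reduced model) or ``"zero-both-cov"`` (G and R diagonal; df = 2).
    """
    if dm.n_traits < 2:
        raise ValueError("covariance constraints require a bivariate model")
    if constraint == "zero-genetic-cov":
        return fit(dm, rel, free_genetic_cov=False, **kwargs)
    if constraint == "zero-both-cov":
        return fit(dm, rel, free_genetic_cov=False, free_residual_cov=False,
                   **kwargs)
    raise ValueError(f"unknown constraint {constraint!r}")
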