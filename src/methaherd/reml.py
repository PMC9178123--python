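"""REML variance components for repeatability animal models.

Model per trait:  ``y = Xb + Za + Wp + e`` with ``var(a) = A s2a``
(``A`` the pedigree numerator relationship matrix), ``var(p) = I s2pe``
(one permanent-environment effect per cow across parities) and
``var(e) = I s2e``.  The restricted likelihood is maximized by
average-information (AI) updates with variances on the log scale, an EM
fallback, and step halving whenever a candidate step does not improve the
restricted log-likelihood.  Bivariate fits share the machinery with 2x2
genetic / permanent-environment / residual blocks and records missing per
trait (residual covariance acts on cow-weeks where both traits are
observed).

All solves go through the mixed-model equations, so the cost per iteration
is one Cholesky factorization of the coefficient matrix; trace terms use
standard MME-inverse identities, e.g. ``tr(P Z A Z') = q/s2a -
tr(Ainv Caa)/s2a^2`` generalized to matrix blocks, and
``P = Rinv - Rinv D Minv D' Rinv`` for residual derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .pedigree import Pedigree, a_inverse, prune, relationship_matrix
from .traits import COVARIATE_COLUMNS, FIXED_EFFECT_COLUMNS, DesignError

__all__ = [
    "MixedModelSpec",
    "VarCompResult",
    "RepeatabilityREML",
    "BivariateREML",
    "fit_reml",
    "fit_bivariate",
    "summarize_ratios",
]


@dataclass
class MixedModelSpec:
    """Model specification for one trait.

    ``mean_only=True`` drops all fixed effects but the mean — the model for
    residual traits (RMeP, RMeC, RFI1, RFI2), whose fixed effects were
    already absorbed during residualization.
    """

    trait: str
    mean_only: bool = False
    fixed_effects: tuple[str, ...] = FIXED_EFFECT_COLUMNS
    covariates: tuple[str, ...] = COVARIATE_COLUMNS


@dataclass
class VarCompResult:
    """(Co)variance components and derived ratios from one REML fit.

    For univariate fits the blocks are 1x1.  ``param_cov`` is the inverse
    average-information matrix over the packed parameter vector (lower
    triangles of G, PE, E in that order); ratio and correlation standard
    errors are first-order delta-method values from it.
    """

    trait_names: tuple[str, ...]
    G: np.ndarray
    PE: np.ndarray
    E: np.ndarray
    param_cov: np.ndarray
    h2: np.ndarray
    pe2: np.ndarray
    repeatability: np.ndarray
    h2_se: np.ndarray
    pe2_se: np.ndarray
    repeatability_se: np.ndarray
    genetic_correlation: float | None = None
    genetic_correlation_se: float | None = None
    phenotypic_correlation: float | None = None
    phenotypic_correlation_se: float | None = None
    converged: bool = False
    n_iter: int = 0
    loglik: float = np.nan
    gradient_norm: float = np.nan
    history: list = field(default_factory=list)

    @property
    def total_variance(self) -> np.ndarray:
        return np.diag(self.G) + np.diag(self.PE) + np.diag(self.E)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trait_names):
            rows.append(
                {
                    "trait": t,
                    "sigma2_a": self.G[i, i],
                    "sigma2_pe": self.PE[i, i],
                    "sigma2_e": self.E[i, i],
                    "h2": self.h2[i],
                    "h2_se": self.h2_se[i],
                    "pe2": self.pe2[i],
                    "pe2_se": self.pe2_se[i],
                    "repeatability": self.repeatability[i],
                    "repeatability_se": self.repeatability_se[i],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter packing: lower triangles of the T x T blocks G, PE, E


def _pack_indices(T: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(T) for j in range(i + 1)]


def _pack(G, PE, E, T):
    ix = _pack_indices(T)
    return np.array(
        [G[i, j] for i, j in ix] + [PE[i, j] for i, j in ix] + [E[i, j] for i, j in ix]
    )


def _unpack(theta, T):
    ix = _pack_indices(T)
    m = len(ix)
    out = []
    for b in range(3):
        M = np.zeros((T, T))
        for k, (i, j) in enumerate(ix):
            M[i, j] = M[j, i] = theta[b * m + k]
        out.append(M)
    return out


def _bend(M: np.ndarray, eps_rel: float = 1e-8) -> np.ndarray:
    """Project a symmetric block to the PD cone (eigenvalue clipping)."""
    w, V = np.linalg.eigh(M)
    floor = eps_rel * max(np.max(np.abs(w)), 1e-12)
    if w.min() >= floor:
        return M
    w = np.clip(w, floor, None)
    return V @ np.diag(w) @ V.T


def _sumdot(Minv: np.ndarray, C: sparse.coo_matrix) -> float:
    """Elementwise sum  sum_kl Minv[k,l] C[k,l]  (Minv symmetric)."""
    return float(np.sum(C.data * Minv[C.row, C.col]))


class _Engine:
    """Stacked-observation AI-REML engine for T traits (T = 1 or 2)."""

    def __init__(
        self,
        ys: list[np.ndarray],
        Xs: list[np.ndarray],
        animal_ix: np.ndarray,
        cow_ix: np.ndarray,
        Ainv: sparse.csr_matrix,
        logdet_A: float,
        A: np.ndarray,
    ):
        self.T = len(ys)
        T = self.T
        n_units = len(animal_ix)
        self.q_a = Ainv.shape[0]
        self.q_pe = int(cow_ix.max()) + 1
        self.logdet_A = logdet_A
        self.Ainv = Ainv.tocoo()
        self.A = A

        obs_mask = [np.isfinite(y) for y in ys]
        self.n_obs_t = [int(m.sum()) for m in obs_mask]
        self.N = int(sum(self.n_obs_t))
        self.P = sum(X.shape[1] for X in Xs)
        K = self.P + T * self.q_a + T * self.q_pe
        self.K = K

        # stacked rows: trait-major
        rows = []
        cols = []
        vals = []
        y_stacked = []
        self.obs_trait = np.empty(self.N, dtype=np.int64)
        self.obs_unit = np.empty(self.N, dtype=np.int64)
        pos = 0
        p_off = 0
        stack_pos = {}  # (t, unit) -> stacked row
        for t in range(T):
            units_t = np.flatnonzero(obs_mask[t])
            X = Xs[t]
            for u in units_t:
                stack_pos[(t, int(u))] = pos
                self.obs_trait[pos] = t
                self.obs_unit[pos] = u
                y_stacked.append(ys[t][u])
                for j in range(X.shape[1]):
                    v = X[u, j]
                    if v != 0.0:
                        rows.append(pos)
                        cols.append(p_off + j)
                        vals.append(v)
                rows.append(pos)
                cols.append(self.P + t * self.q_a + animal_ix[u])
                vals.append(1.0)
                rows.append(pos)
                cols.append(self.P + T * self.q_a + t * self.q_pe + cow_ix[u])
                vals.append(1.0)
                pos += 1
            p_off += X.shape[1]
        self.y = np.asarray(y_stacked)
        self.D = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.N, K), dtype=np.float64
        )

        # observation patterns: for T=2, units with both traits vs single
        if T == 2:
            both_units = np.flatnonzero(obs_mask[0] & obs_mask[1])
            self.pos_b = [
                np.array([stack_pos[(t, int(u))] for u in both_units], dtype=np.int64)
                for t in range(2)
            ]
            only = [
                np.flatnonzero(obs_mask[t] & ~obs_mask[1 - t]) for t in range(2)
            ]
            self.pos_s = [
                np.array([stack_pos[(t, int(u))] for u in only[t]], dtype=np.int64)
                for t in range(2)
            ]
        else:
            self.pos_b = [np.empty(0, dtype=np.int64)] * 1
            self.pos_s = [np.arange(self.N)]
        self.n_both = len(self.pos_b[0]) if T == 2 else 0

        # constant cross-product matrices D_s' D_t restricted to patterns
        D = self.D
        self.cross_b = {}
        if T == 2 and self.n_both:
            Db = [D[self.pos_b[t]] for t in range(2)]
            self.cross_b[(0, 0)] = (Db[0].T @ Db[0]).tocoo()
            self.cross_b[(0, 1)] = (Db[0].T @ Db[1]).tocoo()
            self.cross_b[(1, 1)] = (Db[1].T @ Db[1]).tocoo()
        self.cross_s = []
        for t in range(T if T == 2 else 1):
            Ds = D[self.pos_s[t]]
            self.cross_s.append((Ds.T @ Ds).tocoo())

        self.gen_slice = slice(self.P, self.P + T * self.q_a)
        self.pe_slice = slice(self.P + T * self.q_a, K)
        self.ix = _pack_indices(T)
        self.n_par = 3 * len(self.ix)

    # -- R^{-1} action --------------------------------------------------
    def _apply_rinv(self, v: np.ndarray, E: np.ndarray, Einv: np.ndarray):
        out = np.empty_like(v)
        if self.T == 2:
            if self.n_both:
                b1, b2 = v[self.pos_b[0]], v[self.pos_b[1]]
                out[self.pos_b[0]] = Einv[0, 0] * b1 + Einv[0, 1] * b2
                out[self.pos_b[1]] = Einv[1, 0] * b1 + Einv[1, 1] * b2
            for t in range(2):
                out[self.pos_s[t]] = v[self.pos_s[t]] / E[t, t]
        else:
            out = v / E[0, 0]
        return out

    def _logdet_R(self, E: np.ndarray) -> float:
        if self.T == 1:
            return self.N * np.log(E[0, 0])
        s, ld = np.linalg.slogdet(E)
        if s <= 0:
            raise np.linalg.LinAlgError("residual block not positive definite")
        out = self.n_both * ld
        for t in range(2):
            out += len(self.pos_s[t]) * np.log(E[t, t])
        return float(out)

    # -- coefficient matrix ---------------------------------------------
    def _build_M(self, G, PE, E, Ginv, PEinv, Einv) -> np.ndarray:
        K = self.K
        M = sparse.coo_matrix((K, K))
        if self.T == 2 and self.n_both:
            M = (
                Einv[0, 0] * self.cross_b[(0, 0)]
                + Einv[1, 1] * self.cross_b[(1, 1)]
                + Einv[0, 1] * (self.cross_b[(0, 1)] + self.cross_b[(0, 1)].T)
            )
        for t, C in enumerate(self.cross_s):
            M = M + C / E[t, t]
        M = M.toarray()
        # genetic block: Ginv (x) Ainv
        Ainv = self.Ainv
        for s in range(self.T):
            for t in range(self.T):
                if Ginv[s, t] != 0.0:
                    r0 = self.P + s * self.q_a
                    c0 = self.P + t * self.q_a
                    M[r0 + Ainv.row, c0 + Ainv.col] += Ginv[s, t] * Ainv.data
        # permanent environment: PEinv (x) I
        for s in range(self.T):
            for t in range(self.T):
                if PEinv[s, t] != 0.0:
                    r0 = self.P + self.T * self.q_a + s * self.q_pe
                    c0 = self.P + self.T * self.q_a + t * self.q_pe
                    idx = np.arange(self.q_pe)
                    M[r0 + idx, c0 + idx] += PEinv[s, t]
        return M

    # -- one evaluation --------------------------------------------------
    def evaluate(self, theta: np.ndarray, need_derivs: bool = True) -> dict:
        T = self.T
        G, PE, E = _unpack(theta, T)
        Ginv = np.linalg.inv(G)
        PEinv = np.linalg.inv(PE)
        Einv = np.linalg.inv(E)
        M = self._build_M(G, PE, E, Ginv, PEinv, Einv)
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Rinv_y = self._apply_rinv(self.y, E, Einv)
        rhs = self.D.T @ Rinv_y
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        yPy = float(self.y @ Rinv_y - sol @ rhs)
        sign_G, ld_G = np.linalg.slogdet(G)
        sign_P, ld_P = np.linalg.slogdet(PE)
        if sign_G <= 0 or sign_P <= 0:
            raise np.linalg.LinAlgError("covariance block not positive definite")
        minus2l = (
            self._logdet_R(E)
            + self.q_a * ld_G
            + T * self.logdet_A
            + self.q_pe * ld_P
            + logdet_M
            + yPy
            + (self.N - self.P) * np.log(2.0 * np.pi)
        )
        out = {"theta": theta.copy(), "loglik": -0.5 * minus2l, "sol": sol}
        if not need_derivs:
            return out

        Minv = linalg.cho_solve(cf, np.eye(self.K), check_finite=False)
        Py = self._apply_rinv(self.y - self.D @ sol, E, Einv)
        w = self.D.T @ Py
        t_gen = w[self.gen_slice].reshape(T, self.q_a)
        t_pe = w[self.pe_slice].reshape(T, self.q_pe)
        At = np.array([self.A @ t_gen[t] for t in range(T)])

        # MME-inverse trace building blocks
        trAC = np.zeros((T, T))
        trCpp = np.zeros((T, T))
        Ac = self.Ainv
        for s in range(T):
            for t in range(T):
                blk = Minv[
                    self.P + s * self.q_a : self.P + (s + 1) * self.q_a,
                    self.P + t * self.q_a : self.P + (t + 1) * self.q_a,
                ]
                trAC[s, t] = float(np.sum(Ac.data * blk[Ac.row, Ac.col]))
                pblk = Minv[
                    self.P + T * self.q_a + s * self.q_pe : self.P
                    + T * self.q_a
                    + (s + 1) * self.q_pe,
                    self.P + T * self.q_a + t * self.q_pe : self.P
                    + T * self.q_a
                    + (t + 1) * self.q_pe,
                ]
                trCpp[s, t] = float(np.trace(pblk))
        sd_b = {k: _sumdot(Minv, C) for k, C in self.cross_b.items()}
        sd_s = [_sumdot(Minv, C) for C in self.cross_s]

        ix = self.ix
        m = len(ix)
        F = np.empty((self.N, self.n_par))
        grad = np.empty(self.n_par)

        def basis(i, j):
            J = np.zeros((T, T))
            J[i, j] = J[j, i] = 1.0
            return J

        # genetic parameters
        for k, (i, j) in enumerate(ix):
            J = basis(i, j)
            u = J @ At  # (T, q_a): u_s = sum_t J[s,t] * (A t_gen[t])
            f = np.empty(self.N)
            for t in range(T):
                sel = self.obs_trait == t
                f[sel] = u[t][self.animal_of_obs[sel]]
            F[:, k] = f
            tr = self.q_a * float(np.trace(J @ Ginv)) - float(
                np.sum((Ginv @ J @ Ginv) * trAC)
            )
            grad[k] = -0.5 * (tr - float(Py @ f))

        # permanent-environment parameters
        for k, (i, j) in enumerate(ix):
            J = basis(i, j)
            u = J @ t_pe
            f = np.empty(self.N)
            for t in range(T):
                sel = self.obs_trait == t
                f[sel] = u[t][self.cow_of_obs[sel]]
            F[:, m + k] = f
            tr = self.q_pe * float(np.trace(J @ PEinv)) - float(
                np.sum((PEinv @ J @ PEinv) * trCpp)
            )
            grad[m + k] = -0.5 * (tr - float(Py @ f))

        # residual parameters
        for k, (i, j) in enumerate(ix):
            J = basis(i, j)
            f = np.zeros(self.N)
            if T == 2:
                if self.n_both:
                    b = [Py[self.pos_b[0]], Py[self.pos_b[1]]]
                    f[self.pos_b[0]] = J[0, 0] * b[0] + J[0, 1] * b[1]
                    f[self.pos_b[1]] = J[1, 0] * b[0] + J[1, 1] * b[1]
                if i == j:
                    f[self.pos_s[i]] = Py[self.pos_s[i]]
            else:
                f = Py.copy()
            F[:, 2 * m + k] = f
            # tr(Rinv dR) - tr(Minv D' Rinv dR Rinv D)
            if T == 2:
                tr1 = self.n_both * float(np.trace(Einv @ J))
                if i == j:
                    tr1 += len(self.pos_s[i]) / E[i, i]
                B = Einv @ J @ Einv
                tr2 = 0.0
                if self.n_both:
                    tr2 += B[0, 0] * sd_b[(0, 0)] + B[1, 1] * sd_b[(1, 1)]
                    tr2 += 2.0 * B[0, 1] * sd_b[(0, 1)]
                if i == j:
                    tr2 += sd_s[i] / E[i, i] ** 2
            else:
                tr1 = self.N / E[0, 0]
                tr2 = sd_s[0] / E[0, 0] ** 2
            grad[2 * m + k] = -0.5 * ((tr1 - tr2) - float(Py @ f))

        # average-information matrix: 0.5 F' P F
        RinvF = self._apply_rinv(F, E, Einv)
        rhsF = self.D.T @ RinvF
        solF = linalg.cho_solve(cf, rhsF, check_finite=False)
        PF = self._apply_rinv(F - self.D @ solF, E, Einv)
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)

        # EM sufficient statistics
        uhat = sol[self.gen_slice].reshape(T, self.q_a)
        phat = sol[self.pe_slice].reshape(T, self.q_pe)
        Ainv_csr = sparse.csr_matrix(
            (Ac.data, (Ac.row, Ac.col)), shape=(self.q_a, self.q_a)
        )
        G_em = np.zeros((T, T))
        PE_em = np.zeros((T, T))
        for s in range(T):
            for t in range(T):
                G_em[s, t] = (
                    float(uhat[s] @ (Ainv_csr @ uhat[t])) + trAC[s, t]
                ) / self.q_a
                PE_em[s, t] = (float(phat[s] @ phat[t]) + trCpp[s, t]) / self.q_pe
        ehat = self.y - self.D @ sol
        E_em = np.zeros((T, T))
        if T == 2:
            if self.n_both:
                e1, e2 = ehat[self.pos_b[0]], ehat[self.pos_b[1]]
                E_em[0, 1] = E_em[1, 0] = (
                    float(e1 @ e2) + sd_b[(0, 1)]
                ) / max(self.n_both, 1)
                both_ss = [float(e1 @ e1) + sd_b[(0, 0)], float(e2 @ e2) + sd_b[(1, 1)]]
            else:
                both_ss = [0.0, 0.0]
            for t in range(2):
                es = ehat[self.pos_s[t]]
                E_em[t, t] = (both_ss[t] + float(es @ es) + sd_s[t]) / self.n_obs_t[t]
        else:
            E_em[0, 0] = (float(ehat @ ehat) + sd_s[0]) / self.N
        out.update(
            grad=grad, AI=AI, G_em=G_em, PE_em=PE_em, E_em=E_em, Minv=Minv
        )
        return out

    @property
    def animal_of_obs(self) -> np.ndarray:
        return self._animal_of_obs

    @property
    def cow_of_obs(self) -> np.ndarray:
        return self._cow_of_obs

    def attach_maps(self, animal_ix: np.ndarray, cow_ix: np.ndarray) -> None:
        self._animal_of_obs = animal_ix[self.obs_unit]
        self._cow_of_obs = cow_ix[self.obs_unit]


def _working_jacobian(theta: np.ndarray, T: int) -> np.ndarray:
    """d(theta)/d(working): variances on log scale, covariances natural."""
    ix = _pack_indices(T)
    m = len(ix)
    d = np.ones(len(theta))
    for b in range(3):
        for k, (i, j) in enumerate(ix):
            if i == j:
                d[b * m + k] = theta[b * m + k]
    return np.diag(d)


@dataclass
class _FitControl:
    max_iter: int = 200
    ll_tol: float = 1e-8
    param_tol: float = 1e-6
    method: str = "ai"  # "ai" (with EM fallback) or "em" (pure EM)


def _run_reml(engine: _Engine, theta0: np.ndarray, control: _FitControl):
    T = engine.T
    scale = np.max(np.abs(theta0)) or 1.0
    floor = 1e-10 * scale
    theta = theta0.copy()
    state = engine.evaluate(theta)
    history = [
        {"iter": 0, "loglik": state["loglik"], "theta": theta.copy(), "step": "init"}
    ]
    converged = False
    it = 0
    for it in range(1, control.max_iter + 1):
        if control.method == "em":
            cand = _pack(state["G_em"], state["PE_em"], state["E_em"], T)
            cand = _sanitize(cand, T, floor)
            new_state = engine.evaluate(cand)
            step_kind = "em"
        else:
            Jw = _working_jacobian(theta, T)
            g_w = Jw @ state["grad"]
            AI_w = Jw @ state["AI"] @ Jw
            ridge = 1e-8 * max(np.trace(AI_w) / len(theta), 1e-12)
            try:
                step_w = np.linalg.solve(
                    AI_w + ridge * np.eye(len(theta)), g_w
                )
            except np.linalg.LinAlgError:
                step_w = g_w / max(np.linalg.norm(AI_w), 1.0)
            new_state = None
            step_kind = "ai"
            for halving in range(12):
                w = _to_working(theta, T) + step_w / (2.0**halving)
                cand = _sanitize(_from_working(w, T), T, floor)
                try:
                    trial = engine.evaluate(cand)
                except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
                    continue
                if np.isfinite(trial["loglik"]) and trial["loglik"] >= state[
                    "loglik"
                ] - 1e-10:
                    new_state = trial
                    if halving:
                        step_kind = f"ai/halved{halving}"
                    break
            if new_state is None:
                # EM fallback step
                cand = _sanitize(
                    _pack(state["G_em"], state["PE_em"], state["E_em"], T), T, floor
                )
                try:
                    trial = engine.evaluate(cand)
                    if np.isfinite(trial["loglik"]):
                        new_state = trial
                        step_kind = "em-fallback"
                except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
                    pass
            if new_state is None:
                break  # stalled: no improving step found
        d_ll = new_state["loglik"] - state["loglik"]
        rel = np.max(
            np.abs(new_state["theta"] - theta) / np.maximum(np.abs(theta), floor)
        )
        theta = new_state["theta"]
        state = new_state
        history.append(
            {
                "iter": it,
                "loglik": state["loglik"],
                "theta": theta.copy(),
                "step": step_kind,
            }
        )
        if control.method == "em":
            if abs(d_ll) < control.ll_tol * (1.0 + abs(state["loglik"])):
                converged = True
                break
        elif (
            abs(d_ll) < control.ll_tol * (1.0 + abs(state["loglik"]))
            and rel < control.param_tol
        ):
            converged = True
            break
    return state, converged, it, history


def _to_working(theta, T):
    ix = _pack_indices(T)
    m = len(ix)
    w = theta.copy()
    for b in range(3):
        for k, (i, j) in enumerate(ix):
            if i == j:
                w[b * m + k] = np.log(theta[b * m + k])
    return w


def _from_working(w, T):
    ix = _pack_indices(T)
    m = len(ix)
    theta = w.copy()
    for b in range(3):
        for k, (i, j) in enumerate(ix):
            if i == j:
                # clip so an oversized trial step stays finite; the line
                # search rejects it on the likelihood anyway
                theta[b * m + k] = np.exp(np.clip(w[b * m + k], -200.0, 200.0))
    return theta


def _sanitize(theta, T, floor):
    """Clamp variances at the floor and bend each block to PSD."""
    G, PE, E = _unpack(theta, T)
    out = []
    for M in (G, PE, E):
        M = M.copy()
        for i in range(T):
            M[i, i] = max(M[i, i], floor)
        out.append(_bend(M) if T > 1 else M)
    # residual block must stay invertible
    if T > 1:
        out[2] = _bend(out[2], eps_rel=1e-7)
    return _pack(*out, T)


# ---------------------------------------------------------------------------
# data preparation


def _fixed_design(table: pd.DataFrame, spec: MixedModelSpec) -> np.ndarray:
    if spec.mean_only:
        return np.ones((len(table), 1))
    pieces = [pd.Series(1.0, index=table.index, name="intercept")]
    for col in spec.fixed_effects:
        pieces.append(
            pd.get_dummies(
                table[col].astype("category"),
                prefix=col,
                drop_first=True,
                dtype=float,
            )
        )
    for col in spec.covariates:
        pieces.append(table[col].astype(float))
    X = pd.concat(pieces, axis=1)
    D = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        _, R = np.linalg.qr(D)
        bad = [X.columns[j] for j in range(D.shape[1]) if abs(R[j, j]) < 1e-8]
        raise DesignError(
            "singular fixed-effect design; collinear columns: "
            + ", ".join(map(str, bad or ["<unidentified>"]))
        )
    return D


def _prepare(table: pd.DataFrame, pedigree: Pedigree, specs: list[MixedModelSpec]):
    cows = np.unique(table["cow_id"].to_numpy())
    if len(cows) < 2:
        raise ValueError("need at least 2 cows with records")
    ped = prune(pedigree, cows)
    Ainv, logdet_A = a_inverse(ped)
    A = relationship_matrix(ped).A
    animal_pos = {int(a): i for i, a in enumerate(ped.animal)}
    cow_pos = {int(c): i for i, c in enumerate(cows)}
    animal_ix = np.array(
        [animal_pos[int(c)] for c in table["cow_id"]], dtype=np.int64
    )
    cow_ix = np.array([cow_pos[int(c)] for c in table["cow_id"]], dtype=np.int64)
    ys = [table[s.trait].to_numpy(dtype=float) for s in specs]
    Xs = [_fixed_design(table, s) for s in specs]
    engine = _Engine(ys, Xs, animal_ix, cow_ix, Ainv, logdet_A, A)
    engine.attach_maps(animal_ix, cow_ix)
    return engine, ped


def _start_univariate(table, spec):
    y = table[spec.trait].to_numpy(dtype=float)
    mask = np.isfinite(y)
    X = _fixed_design(table.loc[mask], spec)
    resid = y[mask] - X @ np.linalg.lstsq(X, y[mask], rcond=None)[0]
    v = float(np.var(resid, ddof=X.shape[1]))
    return np.array([v / 3.0, v / 3.0, v / 3.0])


def summarize_ratios(
    sigma2_a: float, sigma2_pe: float, sigma2_e: float, cov: np.ndarray | None = None
) -> dict:
    """Heritability, permanent-environment ratio and repeatability with SEs.

    ``h2 = s2a/total``, ``pe2 = s2pe/total``, ``rep = (s2a+s2pe)/total``;
    standard errors by the first-order delta method from ``cov``, the 3x3
    covariance of (s2a, s2pe, s2e) (typically the inverse AI matrix).
    """
    s = sigma2_a + sigma2_pe + sigma2_e
    if s <= 0:
        raise ValueError("total variance must be positive")
    h2 = sigma2_a / s
    pe2 = sigma2_pe / s
    rep = (sigma2_a + sigma2_pe) / s
    out = {"h2": h2, "pe2": pe2, "repeatability": rep}
    if cov is not None:
        g_h2 = np.array([(s - sigma2_a), -sigma2_a, -sigma2_a]) / s**2
        g_pe2 = np.array([-sigma2_pe, (s - sigma2_pe), -sigma2_pe]) / s**2
        g_rep = np.array([sigma2_e, sigma2_e, -(sigma2_a + sigma2_pe)]) / s**2
        out["h2_se"] = float(np.sqrt(max(g_h2 @ cov @ g_h2, 0.0)))
        out["pe2_se"] = float(np.sqrt(max(g_pe2 @ cov @ g_pe2, 0.0)))
        out["repeatability_se"] = float(np.sqrt(max(g_rep @ cov @ g_rep, 0.0)))
    return out


def _ratio_block(theta, cov, T):
    """Per-trait ratios and delta-method SEs from packed parameters."""
    ix = _pack_indices(T)
    m = len(ix)
    diag_pos = {i: k for k, (i, j) in enumerate(ix) if i == j}
    h2 = np.zeros(T)
    pe2 = np.zeros(T)
    rep = np.zeros(T)
    ses = np.zeros((3, T))
    for t in range(T):
        p = [diag_pos[t], m + diag_pos[t], 2 * m + diag_pos[t]]
        sub = cov[np.ix_(p, p)] if cov is not None else None
        r = summarize_ratios(theta[p[0]], theta[p[1]], theta[p[2]], sub)
        h2[t], pe2[t], rep[t] = r["h2"], r["pe2"], r["repeatability"]
        if sub is not None:
            ses[0, t] = r["h2_se"]
            ses[1, t] = r["pe2_se"]
            ses[2, t] = r["repeatability_se"]
    return h2, pe2, rep, ses


def _correlation_se(num_ix, d1_ix, d2_ix, theta, cov, extra=None):
    """Delta-method SE of c/sqrt(v1 v2) over packed parameters.

    ``num_ix/d1_ix/d2_ix`` are lists of packed indices whose sums form the
    covariance and the two variances (sums of blocks for the phenotypic
    correlation).
    """
    c = sum(theta[k] for k in num_ix)
    v1 = sum(theta[k] for k in d1_ix)
    v2 = sum(theta[k] for k in d2_ix)
    r = c / np.sqrt(v1 * v2)
    g = np.zeros(len(theta))
    for k in num_ix:
        g[k] += 1.0 / np.sqrt(v1 * v2)
    for k in d1_ix:
        g[k] += -0.5 * r / v1
    for k in d2_ix:
        g[k] += -0.5 * r / v2
    se = float(np.sqrt(max(g @ cov @ g, 0.0))) if cov is not None else np.nan
    return float(r), se


def _result_from_state(trait_names, state, AIinv, converged, n_iter, history, T):
    theta = state["theta"]
    G, PE, E = _unpack(theta, T)
    h2, pe2, rep, ses = _ratio_block(theta, AIinv, T)
    res = VarCompResult(
        trait_names=tuple(trait_names),
        G=G,
        PE=PE,
        E=E,
        param_cov=AIinv if AIinv is not None else np.full((len(theta),) * 2, np.nan),
        h2=h2,
        pe2=pe2,
        repeatability=rep,
        h2_se=ses[0],
        pe2_se=ses[1],
        repeatability_se=ses[2],
        converged=converged,
        n_iter=n_iter,
        loglik=state["loglik"],
        gradient_norm=float(np.linalg.norm(state.get("grad", np.nan))),
        history=history,
    )
    if T == 2:
        # packed order: [g11, g21, g22, pe11, pe21, pe22, e11, e21, e22]
        rg, rg_se = _correlation_se([1], [0], [2], theta, AIinv)
        rp, rp_se = _correlation_se(
            [1, 4, 7], [0, 3, 6], [2, 5, 8], theta, AIinv
        )
        res.genetic_correlation = rg
        res.genetic_correlation_se = rg_se
        res.phenotypic_correlation = rp
        res.phenotypic_correlation_se = rp_se
    return res


class RepeatabilityREML:
    """Univariate repeatability animal model fitted by AI-REML.

    sklearn-style estimator: configure in the constructor, call
    :meth:`fit` with a trait table and a pedigree, read fitted attributes
    (``sigma2_a_``, ``h2_``, ``result_`` ...).

    Parameters
    ----------
    trait
        Column of the trait table to analyse.
    mean_only
        Fit mean + additive genetic + permanent environment + residual only
        (the model for residual traits).
    fixed_effects, covariates
        Fixed-effect factors and continuous covariates (ignored when
        ``mean_only``).
    method
        ``"ai"`` (average information with EM fallback) or ``"em"``.
    """

    def __init__(
        self,
        trait: str = "mep",
        mean_only: bool = False,
        fixed_effects: tuple[str, ...] = FIXED_EFFECT_COLUMNS,
        covariates: tuple[str, ...] = COVARIATE_COLUMNS,
        max_iter: int = 200,
        ll_tol: float = 1e-8,
        param_tol: float = 1e-6,
        method: str = "ai",
    ):
        self.trait = trait
        self.mean_only = mean_only
        self.fixed_effects = tuple(fixed_effects)
        self.covariates = tuple(covariates)
        self.max_iter = max_iter
        self.ll_tol = ll_tol
        self.param_tol = param_tol
        self.method = method

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "trait",
                "mean_only",
                "fixed_effects",
                "covariates",
                "max_iter",
                "ll_tol",
                "param_tol",
                "method",
            )
        }

    def set_params(self, **params) -> "RepeatabilityREML":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _spec(self) -> MixedModelSpec:
        return MixedModelSpec(
            trait=self.trait,
            mean_only=self.mean_only,
            fixed_effects=self.fixed_effects,
            covariates=self.covariates,
        )

    def fit(self, X: pd.DataFrame, pedigree: Pedigree) -> "RepeatabilityREML":
        spec = self._spec()
        table = X.loc[np.isfinite(X[spec.trait].to_numpy(dtype=float))]
        counts = table.groupby("cow_id").size()
        if not (counts >= 2).any():
            raise ValueError("need repeated records to separate pe from residual")
        engine, ped = _prepare(table, pedigree, [spec])
        theta0 = _start_univariate(table, spec)
        control = _FitControl(self.max_iter, self.ll_tol, self.param_tol, self.method)
        state, converged, n_iter, history = _run_reml(engine, theta0, control)
        AIinv = None
        if "AI" in state:
            try:
                AIinv = np.linalg.inv(state["AI"])
            except np.linalg.LinAlgError:
                AIinv = np.linalg.pinv(state["AI"])
        self.result_ = _result_from_state(
            [spec.trait], state, AIinv, converged, n_iter, history, 1
        )
        self.pedigree_ = ped
        self.sigma2_a_ = float(self.result_.G[0, 0])
        self.sigma2_pe_ = float(self.result_.PE[0, 0])
        self.sigma2_e_ = float(self.result_.E[0, 0])
        self.h2_ = float(self.result_.h2[0])
        self.pe2_ = float(self.result_.pe2[0])
        self.repeatability_ = float(self.result_.repeatability[0])
        self.h2_se_ = float(self.result_.h2_se[0])
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.loglik_ = float(self.result_.loglik)
        return self


class BivariateREML:
    """Pairwise bivariate repeatability animal model fitted by AI-REML.

    Estimates 2x2 genetic, permanent-environment and residual blocks and
    the genetic/phenotypic correlations between two traits.  Records may be
    missing per trait; the residual covariance applies to cow-weeks where
    both traits are observed.  Starting values come from the univariate
    fits with covariances at half the geometric mean of the variances.
    """

    def __init__(
        self,
        trait_a: str = "ecm",
        trait_b: str = "mep",
        mean_only_a: bool = False,
        mean_only_b: bool = False,
        fixed_effects: tuple[str, ...] = FIXED_EFFECT_COLUMNS,
        covariates: tuple[str, ...] = COVARIATE_COLUMNS,
        max_iter: int = 200,
        ll_tol: float = 1e-8,
        param_tol: float = 1e-6,
    ):
        self.trait_a = trait_a
        self.trait_b = trait_b
        self.mean_only_a = mean_only_a
        self.mean_only_b = mean_only_b
        self.fixed_effects = tuple(fixed_effects)
        self.covariates = tuple(covariates)
        self.max_iter = max_iter
        self.ll_tol = ll_tol
        self.param_tol = param_tol

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "trait_a",
                "trait_b",
                "mean_only_a",
                "mean_only_b",
                "fixed_effects",
                "covariates",
                "max_iter",
                "ll_tol",
                "param_tol",
            )
        }

    def set_params(self, **params) -> "BivariateREML":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, pedigree: Pedigree) -> "BivariateREML":
        specs = [
            MixedModelSpec(
                self.trait_a, self.mean_only_a, self.fixed_effects, self.covariates
            ),
            MixedModelSpec(
                self.trait_b, self.mean_only_b, self.fixed_effects, self.covariates
            ),
        ]
        ya = X[self.trait_a].to_numpy(dtype=float)
        yb = X[self.trait_b].to_numpy(dtype=float)
        table = X.loc[np.isfinite(ya) | np.isfinite(yb)]
        engine, ped = _prepare(table, pedigree, specs)
        starts = []
        for spec in specs:
            uni = RepeatabilityREML(
                trait=spec.trait,
                mean_only=spec.mean_only,
                fixed_effects=self.fixed_effects,
                covariates=self.covariates,
                max_iter=60,
                ll_tol=1e-6,
                param_tol=1e-4,
            ).fit(table, pedigree)
            starts.append(
                (uni.sigma2_a_, uni.sigma2_pe_, uni.sigma2_e_)
            )
        theta0 = []
        for b in range(3):
            v1, v2 = starts[0][b], starts[1][b]
            theta0 += [v1, 0.5 * np.sqrt(v1 * v2), v2]
        theta0 = np.array(theta0)
        control = _FitControl(self.max_iter, self.ll_tol, self.param_tol, "ai")
        state, converged, n_iter, history = _run_reml(engine, theta0, control)
        AIinv = None
        if "AI" in state:
            try:
                AIinv = np.linalg.inv(state["AI"])
            except np.linalg.LinAlgError:
                AIinv = np.linalg.pinv(state["AI"])
        self.result_ = _result_from_state(
            [self.trait_a, self.trait_b], state, AIinv, converged, n_iter, history, 2
        )
        self.pedigree_ = ped
        self.G_ = self.result_.G
        self.PE_ = self.result_.PE
        self.E_ = self.result_.E
        self.genetic_correlation_ = float(self.result_.genetic_correlation)
        self.genetic_correlation_se_ = float(self.result_.genetic_correlation_se)
        self.phenotypic_correlation_ = float(self.result_.phenotypic_correlation)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.loglik_ = float(self.result_.loglik)
        return self


def fit_reml(
    spec: MixedModelSpec, trait_table: pd.DataFrame, pedigree: Pedigree, **kw
) -> VarCompResult:
    """Functional wrapper over :class:`RepeatabilityREML`."""
    est = RepeatabilityREML(
        trait=spec.trait,
        mean_only=spec.mean_only,
        fixed_effects=spec.fixed_effects,
        covariates=spec.covariates,
        **kw,
    )
    return est.fit(trait_table, pedigree).result_


def fit_bivariate(
    spec_a: MixedModelSpec,
    spec_b: MixedModelSpec,
    trait_table: pd.DataFrame,
    pedigree: Pedigree,
    **kw,
) -> VarCompResult:
    """Functional wrapper over :class:`BivariateREML`."""
    est = BivariateREML(
        trait_a=spec_a.trait,
        trait_b=spec_b.trait,
        mean_only_a=spec_a.mean_only,
        mean_only_b=spec_b.mean_only,
        fixed_effects=spec_a.fixed_effects,
        covariates=spec_a.covariates,
        **kw,
    )
    return est.fit(trait_table, pedigree).result_
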