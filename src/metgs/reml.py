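"""Residual maximum likelihood for mixed models with Kronecker genetic terms.

Fits ``y = Xτ + Σ_j Z_j u_j + ε`` where each random term has covariance

* ``θ² I``                      (a scalar design term, e.g. replicate blocks), or
* ``Γ ⊗ K``                     (a genetic term: Γ an s×s trial structure from
  :mod:`metgs.varstruct`, K a symmetric PSD relationship matrix over lines or
  the identity over markers),

and the residual is heterogeneous by trial, ``R = ⊕_t θ_t² I_{n_t}``.

The likelihood is evaluated through the mixed-model equations.  With
``W = [X, Z_1, …, Z_J]`` and ``C = Wᵀ R⁻¹ W + diag(0, G₁⁻¹, …, G_J⁻¹)``,

    -2 l_R = (n - p) log 2π + log|R| + Σ_j log|G_j| + log|C| + yᵀ P y,

which matches the direct multivariate-normal REML likelihood (tested against
a brute-force evaluation).  Genetic terms are pre-rotated by the eigenvectors
of K so that each ``G_j`` becomes ``Γ ⊗ D`` with D diagonal; null eigenvalues
of K are dropped, which implements the pseudo-inverse treatment of singular
relationship matrices.  The exact REML score is assembled from the inverse of
C, and a quasi-Newton search (L-BFGS-B) runs on log-variance / unconstrained-
loading coordinates.  E-BLUPs and their prediction-error variances come from
the solution and inverse blocks of C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy import optimize, stats

from .varstruct import CovStructure

__all__ = [
    "RandomTerm",
    "FittedModel",
    "fit_reml",
    "aic",
    "aic_value",
    "lrt",
    "blup_pev",
    "mean_pairwise_difference_pev",
]

_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e30


@dataclass
class RandomTerm:
    """Specification of one random term.

    ``Z`` is the n×b incidence matrix in original coordinates.  With
    ``structure=None`` the term has scalar covariance θ²I_b (one parameter).
    With a :class:`CovStructure` of s trials, ``b = s·v`` trials-major and the
    covariance is Γ⊗K with ``K`` of dimension v (identity when ``K=None``).
    """

    name: str
    Z: np.ndarray
    structure: CovStructure | None = None
    K: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.structure is not None:
            s = self.structure.s
            if self.Z.shape[1] % s:
                raise ValueError(
                    f"term {self.name!r}: incidence width {self.Z.shape[1]} "
                    f"not a multiple of s={s}"
                )
            v = self.Z.shape[1] // s
            if self.K is not None and self.K.shape != (v, v):
                raise ValueError(
                    f"term {self.name!r}: K has shape {self.K.shape}, expected {(v, v)}"
                )

    @property
    def n_params(self) -> int:
        return 1 if self.structure is None else self.structure.k


@dataclass
class TermResult:
    """Per-term REML output: estimates, BLUPs, and bookkeeping for PEVs."""

    name: str
    structure: CovStructure | None
    x: np.ndarray                      # transformed coordinate estimates
    params: dict[str, float]           # natural-scale named parameters
    blup: np.ndarray                   # E-BLUPs in original coordinates
    sl: slice                          # columns of this term inside C
    rotation: np.ndarray | None        # U_r when a K-eigenrotation was applied
    d: np.ndarray | None               # kept eigenvalues of K
    boundary: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def gamma(self) -> np.ndarray | None:
        return None if self.structure is None else self.structure.gamma(self.x)


@dataclass
class FittedModel:
    """REML fit: estimates, log-likelihood, E-BLUPs, convergence diagnostics."""

    loglik: float
    fixed_effects: np.ndarray
    terms: dict[str, TermResult]
    residual_variances: np.ndarray
    residual_boundary: np.ndarray
    n: int
    rank_X: int
    n_random_params: int
    converged: bool
    n_iter: int
    message: str
    X: np.ndarray
    trial_index: np.ndarray
    _Cinv: np.ndarray | None = None
    _fixed_sl: slice | None = None
    transformed_estimates: np.ndarray | None = None
    vcov_transformed: np.ndarray | None = None
    coord_names: list[str] | None = None

    @property
    def boundary_hit(self) -> bool:
        return bool(
            self.residual_boundary.any()
            or any(t.boundary.any() for t in self.terms.values())
        )

    def summary(self) -> str:
        lines = [
            f"REML log-likelihood: {self.loglik:.4f}  (AIC {aic(self):.4f})",
            f"converged: {self.converged} in {self.n_iter} iterations"
            + ("  [boundary]" if self.boundary_hit else ""),
            "term                      parameter                 estimate",
        ]
        for tr in self.terms.values():
            for k, v in tr.params.items():
                lines.append(f"{tr.name:<25} {k:<25} {v:.6g}")
        for t, rv in enumerate(self.residual_variances):
            flag = " *" if self.residual_boundary[t] else ""
            lines.append(f"{'residual':<25} {'variance_t' + str(t + 1):<25} {rv:.6g}{flag}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# internal machinery


class _Problem:
    """Precomputed quantities for fast repeated likelihood evaluation."""

    def __init__(self, y, X, terms, trial_index):
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.size:
            raise ValueError("X row count does not match y")
        n = y.size
        trial_index = np.asarray(trial_index, dtype=int).ravel()
        if trial_index.size != n:
            raise ValueError("trial_index length does not match y")

        # resolve fixed-effect rank deficiency by QR column pivoting
        q, r, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            keep = np.sort(piv[:rank])
            warnings.warn(
                f"fixed-effect design rank deficient ({X.shape[1]} columns, rank "
                f"{rank}); dropping columns {sorted(set(range(X.shape[1])) - set(keep))}"
            )
            X = X[:, keep]
        if n <= rank:
            raise ValueError("need more observations than fixed-effect rank")

        self.y, self.X, self.n, self.rank_X = y, X, n, rank
        self.trial_index = trial_index
        self.s_resid = int(trial_index.max()) + 1
        self.n_t = np.bincount(trial_index, minlength=self.s_resid)
        if (self.n_t == 0).any():
            raise ValueError("empty residual group")

        # rotate genetic terms by the eigenvectors of K
        self.terms = list(terms)
        blocks = [X]
        self.meta = []  # per-term dict
        col = X.shape[1]
        for tm in self.terms:
            if tm.structure is None:
                Zr, U, d = tm.Z, None, None
                q_j = Zr.shape[1]
            else:
                s = tm.structure.s
                v = tm.Z.shape[1] // s
                if tm.K is None:
                    Zr, U, d = tm.Z, None, np.ones(v)
                else:
                    K = 0.5 * (tm.K + tm.K.T)
                    w, V = sla.eigh(K)
                    keep = w > max(w.max(), 0.0) * 1e-10
                    if not keep.any():
                        raise ValueError(f"term {tm.name!r}: K has no positive eigenvalues")
                    U, d = V[:, keep], w[keep]
                    v_r = U.shape[1]
                    Zr = np.empty((n, s * v_r))
                    for t in range(s):
                        Zr[:, t * v_r : (t + 1) * v_r] = tm.Z[:, t * v : (t + 1) * v] @ U
                q_j = Zr.shape[1]
            blocks.append(Zr)
            self.meta.append({"term": tm, "U": U, "d": d, "sl": slice(col, col + q_j)})
            col += q_j
        self.m = col
        W = np.hstack(blocks)
        self.W = W

        # per-trial cross products
        self.A = np.empty((self.s_resid, self.m, self.m))
        self.b = np.empty((self.s_resid, self.m))
        self.c = np.empty(self.s_resid)
        for t in range(self.s_resid):
            mask = trial_index == t
            Wt = W[mask]
            self.A[t] = Wt.T @ Wt
            self.b[t] = Wt.T @ y[mask]
            self.c[t] = y[mask] @ y[mask]

        self.scale = float(np.var(y))
        if not np.isfinite(self.scale) or self.scale <= 0:
            self.scale = 1.0

        # parameter packing: term coords then residual log-variances
        self.slices = []
        off = 0
        for tm in self.terms:
            k = tm.n_params
            self.slices.append(slice(off, off + k))
            off += k
        self.res_sl = slice(off, off + self.s_resid)
        self.n_par = off + self.s_resid

    # -- parameter helpers ------------------------------------------------
    def initial(self, start: dict[str, np.ndarray] | None = None) -> np.ndarray:
        # equal split of the phenotypic variance across random terms + residual
        share = self.scale / (len(self.terms) + 1)
        x0 = np.empty(self.n_par)
        for tm, sl in zip(self.terms, self.slices):
            if tm.structure is None:
                x0[sl] = np.log(max(share, 1e-8))
            else:
                sc = share
                if tm.K is not None:
                    # put the share on the *line-scale* variance Γ·mean(K_ii)
                    sc = share / max(np.mean(np.diag(tm.K)), 1e-12)
                elif tm.structure is not None:
                    d = self.meta[self.terms.index(tm)]["d"]
                    sc = share / max(np.mean(d), 1e-12)
                x0[sl] = tm.structure.initial(sc)
        x0[self.res_sl] = np.log(max(share, 1e-8))
        if start:
            for name, xs in start.items():
                if name == "residual":
                    x0[self.res_sl] = xs
                    continue
                for tm, sl in zip(self.terms, self.slices):
                    if tm.name == name:
                        x0[sl] = xs
        return x0

    def bounds(self):
        lo = np.log(1e-10 * self.scale)
        hi = np.log(1e8 * self.scale)
        bnds: list[tuple[float | None, float | None]] = []
        for tm in self.terms:
            if tm.structure is None:
                bnds.append((lo, hi))
            else:
                sc = self.scale
                if tm.K is not None:
                    sc = self.scale / max(np.mean(np.diag(tm.K)), 1e-12)
                bnds.extend(tm.structure.bounds(sc))
        bnds.extend([(lo, hi)] * self.s_resid)
        return bnds

    # -- objective --------------------------------------------------------
    def neg2ll_grad(self, x: np.ndarray):
        theta_r = np.exp(x[self.res_sl])
        inv_tr = 1.0 / theta_r

        # assemble C = Σ_t A_t/θ_t² + blockdiag(0, G⁻¹)
        C = np.einsum("t,tij->ij", inv_tr, self.A)
        rhs = inv_tr @ self.b
        yRy = float(inv_tr @ self.c)

        logdetG = 0.0
        g_info = []
        for tm, psl, meta in zip(self.terms, self.slices, self.meta):
            sl = meta["sl"]
            if tm.structure is None:
                th = np.exp(x[psl.start])
                idx = np.arange(sl.start, sl.stop)
                C[idx, idx] += 1.0 / th
                logdetG += (sl.stop - sl.start) * np.log(th)
                g_info.append({"theta": th})
            else:
                st = tm.structure
                G = st.gamma(x[psl])
                Ginv, ld = _safe_inv_logdet(G)
                if Ginv is None:
                    return _BIG, np.zeros(self.n_par)
                d = meta["d"]
                v_r = d.size
                idx = np.arange(v_r)
                for a in range(st.s):
                    for b_ in range(st.s):
                        C[sl.start + a * v_r + idx, sl.start + b_ * v_r + idx] += (
                            Ginv[a, b_] / d
                        )
                logdetG += v_r * ld + st.s * float(np.sum(np.log(d)))
                g_info.append({"Gamma": G, "Ginv": Ginv, "d": d, "v_r": v_r})

        cf = None
        jitter = 0.0
        for _ in range(4):
            try:
                cf, low = sla.cho_factor(
                    C if jitter == 0.0 else C + jitter * np.eye(self.m),
                    lower=True,
                    check_finite=False,
                )
                break
            except sla.LinAlgError:
                base = float(np.mean(np.abs(np.diag(C)))) or 1.0
                jitter = base * 1e-10 if jitter == 0.0 else jitter * 1e4
        if cf is None:
            return _BIG, np.zeros(self.n_par)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf))))
        chat = sla.cho_solve((cf, low), rhs, check_finite=False)
        yPy = yRy - float(rhs @ chat)

        n2l = (
            (self.n - self.rank_X) * _LOG2PI
            + float(self.n_t @ np.log(theta_r))
            + logdetG
            + logdetC
            + yPy
        )

        # gradient pieces need C⁻¹ and residuals
        Cinv = _chol_inverse(cf, low)
        e = self.y - self.W @ chat
        grad = np.empty(self.n_par)

        for tm, psl, meta, gi in zip(self.terms, self.slices, self.meta, g_info):
            sl = meta["sl"]
            u = chat[sl]
            if tm.structure is None:
                th = gi["theta"]
                q_j = sl.stop - sl.start
                tr_c = float(np.trace(Cinv[sl, sl]))
                grad[psl.start] = q_j - (tr_c + float(u @ u)) / th
            else:
                st, Ginv, d, v_r = tm.structure, gi["Ginv"], gi["d"], gi["v_r"]
                s = st.s
                umat = u.reshape(s, v_r)
                w = Ginv @ umat
                S = (w / d) @ w.T
                tmat = np.empty((s, s))
                base = sl.start
                idx = np.arange(v_r)
                for a in range(s):
                    for b_ in range(s):
                        tmat[a, b_] = float(
                            np.sum(Cinv[base + a * v_r + idx, base + b_ * v_r + idx] / d)
                        )
                T = Ginv @ tmat @ Ginv
                dG = st.dgamma(x[psl])
                M = v_r * Ginv - T - S
                grad[psl] = np.einsum("rab,ab->r", dG, M)

        # residual gradient (log scale)
        for t in range(self.s_resid):
            mask = self.trial_index == t
            sse_t = float(e[mask] @ e[mask])
            trCA = float(np.sum(Cinv * self.A[t]))
            grad[self.res_sl.start + t] = self.n_t[t] - (trCA + sse_t) / theta_r[t]

        self._last = {
            "chat": chat,
            "Cinv": Cinv,
            "e": e,
            "theta_r": theta_r,
            "n2l": n2l,
        }
        return n2l, grad


def _safe_inv_logdet(G: np.ndarray):
    """Inverse and log-determinant of a near-PSD matrix, with clamping."""
    try:
        L = sla.cholesky(G, lower=True)
        ld = 2.0 * float(np.sum(np.log(np.diag(L))))
        Ginv = sla.cho_solve((L, True), np.eye(G.shape[0]))
        return Ginv, ld
    except sla.LinAlgError:
        w, V = sla.eigh(G)
        top = max(w.max(), 0.0)
        if top <= 0:
            return None, None
        w = np.clip(w, top * 1e-10, None)
        return (V / w) @ V.T, float(np.sum(np.log(w)))


def _chol_inverse(cf: np.ndarray, low: bool) -> np.ndarray:
    inv, info = sla.lapack.dpotri(cf, lower=low)
    if info != 0:
        raise sla.LinAlgError("dpotri failed")
    # dpotri fills one triangle; the other still holds factor workspace
    if low:
        tri = np.tril(inv)
        return tri + np.tril(inv, -1).T
    tri = np.triu(inv)
    return tri + np.triu(inv, 1).T


# ----------------------------------------------------------------------


def fit_reml(
    y,
    X,
    terms: list[RandomTerm],
    trial_index,
    start: dict[str, np.ndarray] | None = None,
    tol: float = 1e-12,
    max_iter: int = 500,
    compute_vcov: bool = False,
    keep_cinv: bool = True,
) -> FittedModel:
    """Maximize the REML log-likelihood and return estimates and E-BLUPs.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design (full rank enforced by
        pivoting).
    terms
        Random terms; see :class:`RandomTerm`.
    trial_index
        Integer array mapping each observation to its residual group
        (per-trial heterogeneous residual variances).
    start
        Optional warm start: mapping term name → transformed coordinates
        (plus ``"residual"`` → log residual variances), e.g. a previous
        fit's ``terms[name].x``.
    compute_vcov
        Also compute the asymptotic covariance of the transformed variance
        parameters (finite differences of the exact score); enables
        Wald-type intervals.
    """
    prob = _Problem(y, X, terms, trial_index)
    x0 = prob.initial(start)
    bnds = prob.bounds()
    x0 = np.clip(
        x0,
        [b[0] if b[0] is not None else -np.inf for b in bnds],
        [b[1] if b[1] is not None else np.inf for b in bnds],
    )

    # L-BFGS-B with restarts: the REML surface has ridge-like trade-off
    # directions along which the built-in relative-f test can fire early;
    # restarting from the incumbent resets the Hessian approximation and
    # line search, and we stop only when a restart yields no real progress.
    res = None
    x_cur = x0
    n_iter_total = 0
    for _ in range(12):
        step = optimize.minimize(
            prob.neg2ll_grad,
            x_cur,
            jac=True,
            method="L-BFGS-B",
            bounds=bnds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7, "maxcor": 25},
        )
        n_iter_total += int(step.nit)
        if res is not None and res.fun - step.fun < 1e-6:
            if step.fun < res.fun:
                res = step
            break
        res = step
        x_cur = step.x
    res.nit = n_iter_total
    xh = res.x
    n2l, grad = prob.neg2ll_grad(xh)  # refresh cached state at the optimum
    last = prob._last

    converged = bool(res.success) or float(np.max(np.abs(grad))) < 1e-3
    if not converged:
        warnings.warn(f"REML did not converge: {res.message}")

    # unpack
    chat, Cinv = last["chat"], last["Cinv"]
    fixed = chat[: prob.rank_X]
    term_results: dict[str, TermResult] = {}
    n_random = 0
    for tm, psl, meta in zip(prob.terms, prob.slices, prob.meta):
        sl = meta["sl"]
        u = chat[sl]
        xt = xh[psl]
        if tm.structure is None:
            params = {"variance": float(np.exp(xt[0]))}
            blup = u
        else:
            params = tm.structure.param_dict(xt)
            if meta["U"] is not None:
                s = tm.structure.s
                v_r = meta["d"].size
                U = meta["U"]
                blup = np.concatenate(
                    [U @ u[t * v_r : (t + 1) * v_r] for t in range(s)]
                )
            else:
                blup = u
        lo = np.array([b[0] if b[0] is not None else -np.inf for b in bnds[psl]])
        boundary = np.abs(xt - lo) < 1e-6
        term_results[tm.name] = TermResult(
            name=tm.name,
            structure=tm.structure,
            x=xt.copy(),
            params=params,
            blup=blup,
            sl=sl,
            rotation=meta["U"],
            d=meta["d"],
            boundary=boundary,
        )
        n_random += tm.n_params

    res_x = xh[prob.res_sl]
    res_lo = np.array([b[0] for b in bnds[prob.res_sl]])
    n_random += prob.s_resid

    coord_names = []
    for tm in prob.terms:
        if tm.structure is None:
            coord_names.append(f"{tm.name}:log_variance")
        else:
            coord_names.extend(f"{tm.name}:x{i}" for i in range(tm.n_params))
    coord_names.extend(f"residual:log_variance_t{t + 1}" for t in range(prob.s_resid))

    vcov = None
    if compute_vcov:
        vcov = _numeric_vcov(prob, xh)

    fit = FittedModel(
        loglik=-0.5 * n2l,
        fixed_effects=fixed,
        terms=term_results,
        residual_variances=np.exp(res_x),
        residual_boundary=np.abs(res_x - res_lo) < 1e-6,
        n=prob.n,
        rank_X=prob.rank_X,
        n_random_params=n_random,
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
        X=prob.X,
        trial_index=prob.trial_index,
        _Cinv=Cinv if keep_cinv else None,
        _fixed_sl=slice(0, prob.rank_X),
        transformed_estimates=xh.copy(),
        vcov_transformed=vcov,
        coord_names=coord_names,
    )
    return fit


def _numeric_vcov(prob: _Problem, xh: np.ndarray) -> np.ndarray | None:
    """Asymptotic vcov of transformed parameters: 2·H⁻¹ of the -2·loglik."""
    k = prob.n_par
    H = np.empty((k, k))
    h = 1e-4
    for i in range(k):
        xp = xh.copy()
        xp[i] += h
        _, gp = prob.neg2ll_grad(xp)
        xm = xh.copy()
        xm[i] -= h
        _, gm = prob.neg2ll_grad(xm)
        H[i] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        return 2.0 * sla.inv(H)
    except sla.LinAlgError:
        return None


# ----------------------------------------------------------------------
# model comparison


def aic_value(loglik: float, n_random_params: int) -> float:
    """AIC convention for REML model screening: 2·(random parameter count)
    − 2·loglik, fixed-effect count ignored (constant across compared models)."""
    return 2.0 * n_random_params - 2.0 * loglik


def aic(fit: FittedModel) -> float:
    return aic_value(fit.loglik, fit.n_random_params)


def lrt(nested: FittedModel, full: FittedModel) -> tuple[float, int, float]:
    """REML likelihood-ratio test of a nested pair sharing fixed effects.

    Returns (statistic, df, p).  The statistic is clipped at zero; the
    chi-square reference is conservative when the tested parameters are
    variances on their boundary.
    """
    if nested.X.shape != full.X.shape or not np.allclose(nested.X, full.X):
        raise ValueError("REML likelihoods are only comparable for identical fixed effects")
    df = full.n_random_params - nested.n_random_params
    if df < 0:
        raise ValueError("'nested' model has more random parameters than 'full'")
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


# ----------------------------------------------------------------------
# prediction-error variances


def blup_pev(fit: FittedModel, term: str, indices=None) -> np.ndarray:
    """Prediction-error covariance of a term's E-BLUPs (original coordinates).

    ``indices`` optionally selects a subset of effects (after rotation back
    to original coordinates).
    """
    if term not in fit.terms:
        raise KeyError(f"no random term named {term!r} in this fit")
    if fit._Cinv is None:
        raise ValueError("fit was run with keep_cinv=False; PEVs unavailable")
    tr = fit.terms[term]
    P = fit._Cinv[tr.sl, tr.sl]
    if tr.rotation is not None:
        s = tr.structure.s
        v_r = tr.d.size
        U = tr.rotation
        v = U.shape[0]
        out = np.empty((s * v, s * v))
        for a in range(s):
            for b in range(s):
                out[a * v : (a + 1) * v, b * v : (b + 1) * v] = (
                    U @ P[a * v_r : (a + 1) * v_r, b * v_r : (b + 1) * v_r] @ U.T
                )
        P = out
    if indices is not None:
        indices = np.asarray(indices)
        P = P[np.ix_(indices, indices)]
    return P


def mean_pairwise_difference_pev(pev: np.ndarray) -> float:
    """Average over effect pairs of var(ũ_i − ũ_j − (u_i − u_j))."""
    v = pev.shape[0]
    if v < 2:
        raise ValueError("need at least two effects")
    dg = np.diag(pev)
    total = v * dg.sum() + v * dg.sum() - 2.0 * pev.sum()
    # Σ_{i,j} (P_ii + P_jj - 2 P_ij) over ordered pairs incl. i=j (those are 0)
    return float(total / (v * (v - 1)))
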