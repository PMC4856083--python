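"""Trial-by-trial genetic covariance families for MET mixed models.

A genetic random term in a multi-environment-trial (MET) model carries a
covariance of the form ``Gamma ⊗ K`` where ``Gamma`` is an ``s × s`` matrix
over trials and ``K`` is a relationship matrix over lines (or the identity
over markers).  This module defines the parametric families of ``Gamma``
used in genomic selection:

========  =====================================  ===================
form      Gamma(params)                          free parameters
========  =====================================  ===================
single    [θ²]  (s = 1 only)                     1
diag      diag(θ₁², …, θ_s²)                     s
cs        θ² J_s + θ_e² I_s                      2
cs_diag   θ² J_s + diag(θ₁², …, θ_s²)            1 + s
fam0      alias of cs_diag (zero-factor FA)      1 + s
fam1      θ² J_s + λλᵀ [+ diag(ψ₁, …, ψ_s)]      1 + s (ψ ≡ 0) / 1 + 2s
us        L Lᵀ (free symmetric PSD)              s(s+1)/2
========  =====================================  ===================

``J_s`` is the all-ones matrix.  ``cs``/``cs_diag``/``fam1`` decompose the
term into a main effect that is stable across trials (variance ``θ² J_s``)
plus a trial-specific interaction; ``diag`` and ``us`` carry totals only.

Each structure exposes the covariance matrix, its derivatives with respect
to the internal optimisation coordinates (variances on log scale, loadings
and Cholesky off-diagonals unconstrained), and the free-parameter count
used in AIC arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CovStructure", "n_params", "equivalent_forms", "FORMS"]

FORMS = ("single", "diag", "cs", "cs_diag", "fam0", "fam1", "us")

# forms that contain an explicit across-trial main effect θ² J_s
_MAIN_EFFECT_FORMS = ("cs", "cs_diag", "fam0", "fam1")


def n_params(form: str, s: int, psi_zero: bool = True) -> int:
    """Number of free (co)variance parameters of a family at ``s`` trials.

    ``psi_zero`` applies to ``fam1`` only and constrains the specific
    variances to zero (the identifiable parameterisation at s=2).
    """
    form = form.lower()
    if form not in FORMS:
        raise ValueError(f"unknown covariance form {form!r}")
    if form == "single":
        if s != 1:
            raise ValueError("'single' form applies to a single trial only")
        return 1
    if form == "diag":
        return s
    if s < 2:
        raise ValueError(f"form {form!r} requires at least two trials")
    if form == "cs":
        return 2
    if form in ("cs_diag", "fam0"):
        return 1 + s
    if form == "fam1":
        return 1 + s if psi_zero else 1 + 2 * s
    return s * (s + 1) // 2  # us


def equivalent_forms(s: int) -> list[tuple[str, str]]:
    """Pairs of families spanning identical model spaces at ``s`` trials.

    ``fam0`` (zero-factor FA with a main effect) coincides with ``cs_diag``
    at every ``s``.  At s=2 the one-factor model with zero specific
    variances, ``fam1``, has three parameters reproducing any 2×2 PSD
    matrix, hence matches ``us``.
    """
    if s < 2:
        return []
    pairs = [("fam0", "cs_diag")]
    if s == 2:
        pairs.insert(0, ("fam1", "us"))
    return pairs


@dataclass
class CovStructure:
    """A parameterized trial×trial covariance family.

    Parameters are handled on an internal unconstrained scale ``x``:
    variances as logs, factor loadings and Cholesky off-diagonals as-is.
    """

    form: str
    s: int
    psi_zero: bool = True  # fam1 only

    def __post_init__(self) -> None:
        self.form = self.form.lower()
        self.k = n_params(self.form, self.s, self.psi_zero)  # validates

    # ------------------------------------------------------------------
    @property
    def has_main_effect(self) -> bool:
        return self.form in _MAIN_EFFECT_FORMS

    def initial(self, scale: float) -> np.ndarray:
        """Starting coordinates putting roughly ``scale`` on each diagonal."""
        scale = float(max(scale, 1e-8))
        lv = np.log(scale)
        s = self.s
        if self.form in ("single", "diag"):
            return np.full(self.k, lv)
        if self.form == "cs":
            return np.array([lv - np.log(2.0), lv - np.log(2.0)])
        if self.form in ("cs_diag", "fam0"):
            return np.full(self.k, lv - np.log(2.0))
        if self.form == "fam1":
            x = np.empty(self.k)
            x[0] = lv - np.log(2.0)
            x[1 : 1 + s] = np.sqrt(scale / 2.0) * (1.0 + 0.1 * np.arange(s))
            if not self.psi_zero:
                x[1 + s :] = lv - np.log(4.0)
            return x
        # us: Cholesky of scale * I
        x = np.zeros(self.k)
        x[:s] = 0.5 * lv
        return x

    def bounds(self, scale: float) -> list[tuple[float | None, float | None]]:
        """Box bounds on the internal coordinates (log-variances clamped)."""
        scale = float(max(scale, 1e-8))
        lo = np.log(1e-10 * scale)
        hi = np.log(1e4 * scale)
        s = self.s
        if self.form in ("single", "diag", "cs", "cs_diag", "fam0"):
            return [(lo, hi)] * self.k
        if self.form == "fam1":
            b: list[tuple[float | None, float | None]] = [(lo, hi)]
            b += [(None, None)] * s
            if not self.psi_zero:
                b += [(lo, hi)] * s
            return b
        # us: log-diagonal of Cholesky bounded, off-diagonals free
        return [(lo / 2.0, hi / 2.0)] * s + [(None, None)] * (self.k - s)

    # ------------------------------------------------------------------
    def gamma(self, x: np.ndarray) -> np.ndarray:
        """Covariance matrix Γ(x), shape (s, s)."""
        x = np.asarray(x, dtype=float)
        s = self.s
        if self.form in ("single", "diag"):
            return np.diag(np.exp(x))
        if self.form == "cs":
            return np.exp(x[0]) * np.ones((s, s)) + np.exp(x[1]) * np.eye(s)
        if self.form in ("cs_diag", "fam0"):
            return np.exp(x[0]) * np.ones((s, s)) + np.diag(np.exp(x[1:]))
        if self.form == "fam1":
            lam = x[1 : 1 + s]
            g = np.exp(x[0]) * np.ones((s, s)) + np.outer(lam, lam)
            if not self.psi_zero:
                g = g + np.diag(np.exp(x[1 + s :]))
            return g
        L = self._chol(x)
        return L @ L.T

    def dgamma(self, x: np.ndarray) -> np.ndarray:
        """Derivatives dΓ/dx_r, shape (k, s, s), chain rule included."""
        x = np.asarray(x, dtype=float)
        s = self.s
        out = np.zeros((self.k, s, s))
        if self.form in ("single", "diag"):
            for t in range(s):
                out[t, t, t] = np.exp(x[t])
            return out
        if self.form == "cs":
            out[0] = np.exp(x[0]) * np.ones((s, s))
            out[1] = np.exp(x[1]) * np.eye(s)
            return out
        if self.form in ("cs_diag", "fam0"):
            out[0] = np.exp(x[0]) * np.ones((s, s))
            for t in range(s):
                out[1 + t, t, t] = np.exp(x[1 + t])
            return out
        if self.form == "fam1":
            lam = x[1 : 1 + s]
            out[0] = np.exp(x[0]) * np.ones((s, s))
            for t in range(s):
                d = np.zeros((s, s))
                d[t, :] += lam
                d[:, t] += lam
                out[1 + t] = d
            if not self.psi_zero:
                for t in range(s):
                    out[1 + s + t, t, t] = np.exp(x[1 + s + t])
            return out
        # us
        L = self._chol(x)
        r = 0
        for t in range(s):
            E = np.zeros((s, s))
            E[t, t] = L[t, t]  # d L / d log L_tt
            out[r] = E @ L.T + L @ E.T
            r += 1
        for i in range(1, s):
            for j in range(i):
                E = np.zeros((s, s))
                E[i, j] = 1.0
                out[r] = E @ L.T + L @ E.T
                r += 1
        return out

    def _chol(self, x: np.ndarray) -> np.ndarray:
        s = self.s
        L = np.zeros((s, s))
        L[np.diag_indices(s)] = np.exp(x[:s])
        r = s
        for i in range(1, s):
            for j in range(i):
                L[i, j] = x[r]
                r += 1
        return L

    # ------------------------------------------------------------------
    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        """Resolve sign indeterminacies (fam1 loadings reported with λ₁ ≥ 0)."""
        x = np.array(x, dtype=float)
        if self.form == "fam1" and x[1] < 0:
            x[1 : 1 + self.s] *= -1.0
        return x

    def param_dict(self, x: np.ndarray) -> dict[str, float]:
        """Natural-scale named parameters at coordinates ``x``."""
        x = self.canonicalize(np.asarray(x, dtype=float))
        s = self.s
        if self.form == "single":
            return {"variance": float(np.exp(x[0]))}
        if self.form == "diag":
            return {f"variance_t{t + 1}": float(np.exp(x[t])) for t in range(s)}
        if self.form == "cs":
            return {
                "main_variance": float(np.exp(x[0])),
                "specific_variance": float(np.exp(x[1])),
            }
        if self.form in ("cs_diag", "fam0"):
            d = {"main_variance": float(np.exp(x[0]))}
            d.update(
                {f"specific_variance_t{t + 1}": float(np.exp(x[1 + t])) for t in range(s)}
            )
            return d
        if self.form == "fam1":
            d = {"main_variance": float(np.exp(x[0]))}
            d.update({f"loading_t{t + 1}": float(x[1 + t]) for t in range(s)})
            if not self.psi_zero:
                d.update(
                    {
                        f"specific_variance_t{t + 1}": float(np.exp(x[1 + s + t]))
                        for t in range(s)
                    }
                )
            return d
        g = self.gamma(x)
        d = {}
        for i in range(s):
            for j in range(i + 1):
                key = f"variance_t{i + 1}" if i == j else f"covariance_t{i + 1}{j + 1}"
                d[key] = float(g[i, j])
        return d

    def main_gamma(self, x: np.ndarray) -> np.ndarray | None:
        """Covariance of the across-trial main-effect component (θ² J_s).

        ``None`` for forms without a main effect (single/diag/us).
        """
        if not self.has_main_effect:
            return None
        return float(np.exp(np.asarray(x, dtype=float)[0])) * np.ones((self.s, self.s))
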