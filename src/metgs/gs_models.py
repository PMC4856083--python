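"""Phenotypic, standard and partitioned RR-BLUP models for MET data.

The line genetic effect of the single-stage MET model is

    g = (I_s ⊗ M) u_m + u_e ,

with u_m the p marker effects per trial and u_e the residual (non-marker)
genetic effect of each line per trial.  The three genetic models are

* phenotypic:   g = u_e                    (no markers; total genetic value),
* standard:     g = (I_s ⊗ M) u_m         (classical RR-BLUP),
* partitioned:  both terms                 (marker + residual genetic).

When markers outnumber lines, the marker term is fitted on the line
dimension as ``u_g = (I_s ⊗ M) u_m`` with covariance Γ_m ⊗ MMᵀ, and the
marker effects are recovered afterwards by back-solving

    ũ_m = (I_s ⊗ Mᵀ (M Mᵀ)⁻¹) ũ_g ,

with the same transform applied to the main-effect and interaction BLUP
components for the trial covariance families that contain a main effect.
The direct marker-dimension parameterization (covariance Γ_m ⊗ I_p) is
also available and yields the identical likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reml
from .geno_prep import MarkerMatrix
from .met_design import DesignMatrices, MetDataset, ModelSpec, build_design
from .reml import FittedModel, RandomTerm, blup_pev, fit_reml, mean_pairwise_difference_pev
from .varstruct import CovStructure

__all__ = [
    "GeneticModelFit",
    "MarkerEffects",
    "fit_genetic_model",
    "backsolve_marker_effects",
    "predict_gebv",
    "genotypic_values",
    "heritability",
    "marker_variance_proportion",
]

MARKER_TERM = "marker"
LINE_TERM = "lines"


@dataclass
class MarkerEffects:
    """Back-solved marker effects per trial.

    ``total`` is s × p (one effect vector per trial).  For forms with an
    across-trial main effect (cs, cs_diag, fam1), ``main`` (p,) and
    ``interaction`` (s × p) satisfy total_t = main + interaction_t; for
    diag/us forms only totals exist.
    """

    marker_ids: list
    trials: list
    total: np.ndarray
    main: np.ndarray | None = None
    interaction: np.ndarray | None = None
    form: str = ""
    pseudo_inverse: bool = False


@dataclass
class GeneticModelFit:
    """A fitted genetic model plus the context needed for downstream use."""

    base: FittedModel
    spec: ModelSpec
    data: MetDataset
    markers: MarkerMatrix | None
    design: DesignMatrices
    parameterization: str  # 'line' | 'marker' | 'none'
    label: str = ""

    @property
    def loglik(self) -> float:
        return self.base.loglik

    @property
    def aic(self) -> float:
        return reml.aic(self.base)

    def u_g_blups(self) -> np.ndarray | None:
        """Genomic line values per trial (v·s, trials-major), marker models."""
        if self.spec.genetic_model == "phenotypic":
            return None
        if self.parameterization == "line":
            return self.base.terms[MARKER_TERM].blup
        u_m = self.base.terms[MARKER_TERM].blup
        s, v, p = self.data.s, self.data.v, self.markers.p
        out = np.empty(s * v)
        for t in range(s):
            out[t * v : (t + 1) * v] = self.markers.M @ u_m[t * p : (t + 1) * p]
        return out

    def u_e_blups(self) -> np.ndarray | None:
        if LINE_TERM not in self.base.terms:
            return None
        return self.base.terms[LINE_TERM].blup


def _genetic_structure(form: str, s: int, psi_zero: bool) -> CovStructure:
    return CovStructure(form, s, psi_zero=psi_zero)


def _k_matrix(markers: MarkerMatrix, k_scaling) -> np.ndarray:
    """Genomic relationship K = MMᵀ; optional scalings behind a flag."""
    K = markers.relationship()
    if k_scaling in (None, 1, 1.0):
        return K
    if k_scaling == "p":
        return K / markers.p
    if k_scaling == "vanraden":
        q = (markers.M == 0.0).mean(axis=0)  # minor allele frequency per marker
        denom = 2.0 * float(np.sum(q * (1.0 - q)))
        return K / denom
    return K * float(k_scaling)


def fit_genetic_model(
    data: MetDataset,
    spec: ModelSpec,
    markers: MarkerMatrix | None = None,
    parameterization: str = "auto",
    k_scaling=None,
    start: dict | None = None,
    label: str = "",
    **reml_opts,
) -> GeneticModelFit:
    """Assemble the design for ``spec`` and maximize its REML likelihood.

    For marker models, phenotype records of lines without genotypes are
    dropped (with a warning); for the phenotypic model, passing ``markers``
    restricts the fit to genotyped lines, which is how genotypic values for
    cross-validation comparisons are produced.
    """
    gm = spec.genetic_model
    if gm != "phenotypic" and markers is None:
        raise ValueError(f"{gm} model requires a marker matrix")

    if markers is not None:
        genotyped = set(markers.line_ids)
        extra = [l for l in data.lines if l not in genotyped]
        if extra:
            if gm != "phenotypic":
                warnings.warn(
                    f"dropping {len(extra)} lines without genotypes from the {gm} fit"
                )
            data = data.restrict_lines(genotyped)
        markers = markers.select_lines(data.lines)

    dm = build_design(data, spec)
    s, v = data.s, data.v

    terms: list[RandomTerm] = []
    if gm in ("standard", "partitioned"):
        st_m = _genetic_structure(spec.form_um, s, spec.fam1_psi_zero)
        if parameterization == "auto":
            parameterization = "line" if markers.p > v else "line"
        if parameterization == "line":
            K = _k_matrix(markers, k_scaling)
            terms.append(RandomTerm(MARKER_TERM, dm.Z_g, structure=st_m, K=K))
        elif parameterization == "marker":
            p = markers.p
            Zm = np.empty((data.n, s * p))
            for t in range(s):
                Zm[:, t * p : (t + 1) * p] = dm.Z_g[:, t * v : (t + 1) * v] @ markers.M
            terms.append(RandomTerm(MARKER_TERM, Zm, structure=st_m, K=None))
        else:
            raise ValueError(f"unknown parameterization {parameterization!r}")
    else:
        parameterization = "none"
    if gm in ("phenotypic", "partitioned"):
        st_e = _genetic_structure(spec.form_ue, s, spec.fam1_psi_zero)
        terms.append(RandomTerm(LINE_TERM, dm.Z_g, structure=st_e, K=None))
    for name, Z in dm.Z_u:
        terms.append(RandomTerm(name, Z))

    base = fit_reml(data.y, dm.X, terms, dm.trial_index, start=start, **reml_opts)
    return GeneticModelFit(
        base=base,
        spec=spec,
        data=data,
        markers=markers,
        design=dm,
        parameterization=parameterization,
        label=label or _default_label(spec),
    )


def _default_label(spec: ModelSpec) -> str:
    tag = {"phenotypic": "E", "standard": "S", "partitioned": "P"}[spec.genetic_model]
    form = spec.form_um or spec.form_ue or ""
    return f"{tag}_{form.upper()}"


# ----------------------------------------------------------------------
# marker-effect back-solving and prediction


def backsolve_marker_effects(fit: GeneticModelFit) -> MarkerEffects:
    """Recover marker effects from genomic line-value BLUPs.

    Line-dimension fits use ũ_m = Mᵀ(MMᵀ)⁻¹ ũ_g per trial (Moore-Penrose
    pseudo-inverse, flagged, when MMᵀ is singular).  Main and interaction
    components are obtained by projecting ũ_g onto its a-priori independent
    main/interaction parts (cov Γ_main ⊗ K and (Γ−Γ_main) ⊗ K) before the
    same transform.
    """
    if fit.spec.genetic_model == "phenotypic":
        raise ValueError("phenotypic model carries no marker term")
    markers = fit.markers
    s, v, p = fit.data.s, fit.data.v, markers.p
    tr = fit.base.terms[MARKER_TERM]
    st = tr.structure

    if fit.parameterization == "marker":
        u_m = tr.blup.reshape(s, p)
        pseudo = False
    else:
        u_g = tr.blup.reshape(s, v)
        d, U = tr.d, tr.rotation
        pseudo = d.size < v
        if pseudo:
            warnings.warn(
                "MMᵀ is rank deficient; marker effects use its pseudo-inverse "
                "and reproduce ũ_g in projection only"
            )
        # Mᵀ K⁻ x with K = U diag(d) Uᵀ
        B = markers.M.T @ (U / d) @ U.T  # p × v
        u_m = u_g @ B.T

    main = interaction = None
    if st.has_main_effect:
        gamma = st.gamma(tr.x)
        gamma_main = st.main_gamma(tr.x)
        A = gamma_main @ np.linalg.inv(gamma)  # projection of totals onto main part
        if fit.parameterization == "marker":
            uf = A @ tr.blup.reshape(s, p)
        else:
            uf = (A @ u_g) @ B.T
        main = uf.mean(axis=0)  # rows are identical up to round-off
        interaction = u_m - main[None, :]

    return MarkerEffects(
        marker_ids=list(markers.marker_ids),
        trials=list(fit.data.trials),
        total=u_m,
        main=main,
        interaction=interaction,
        form=st.form,
        pseudo_inverse=pseudo,
    )


def predict_gebv(
    effects: MarkerEffects,
    M_new: MarkerMatrix,
    which=("total", None),
    subset: np.ndarray | None = None,
) -> pd.Series:
    """GEBVs of new lines from back-solved effects.

    ``which`` is ('total', trial_label), ('main', None) or ('trial',
    trial_label) — the last picks the per-trial total of a diag/us form,
    which equals ('total', trial).  ``subset`` restricts to a low-density
    random marker subset (indices into the training marker set).
    """
    if list(M_new.marker_ids) != list(effects.marker_ids):
        off = [m for m in M_new.marker_ids if m not in set(effects.marker_ids)]
        raise ValueError(
            f"marker sets differ between training effects and prediction matrix "
            f"(first offenders: {off[:5] if off else 'order mismatch'})"
        )
    kind, trial = which
    if kind == "main":
        if effects.main is None:
            raise ValueError(f"form {effects.form!r} has no main marker effect")
        eff = effects.main
    elif kind in ("total", "trial"):
        t = effects.trials.index(trial)
        eff = effects.total[t]
    else:
        raise ValueError(f"unknown effect choice {kind!r}")
    if subset is not None:
        subset = np.asarray(subset)
        vals = M_new.M[:, subset] @ eff[subset]
    else:
        vals = M_new.M @ eff
    return pd.Series(vals, index=list(M_new.line_ids), name="gebv")


# ----------------------------------------------------------------------
# derived statistics


def genotypic_values(fit: GeneticModelFit, trial) -> pd.Series:
    """Total genetic values (GV) of lines in one trial, from a phenotypic fit."""
    if LINE_TERM not in fit.base.terms:
        raise ValueError("fit has no residual genetic line term")
    t = fit.data.trials.index(trial)
    v = fit.data.v
    u = fit.base.terms[LINE_TERM].blup[t * v : (t + 1) * v]
    return pd.Series(u, index=fit.data.lines, name=f"gv:{trial}")


def heritability(fit: GeneticModelFit, trial) -> float:
    """Generalized (Cullis) heritability of one trial from a phenotypic fit.

    H² = 1 − ā / (2 θ̂²_g,t), with ā the average pairwise prediction-error
    variance of line-effect differences within the trial.
    """
    if fit.spec.genetic_model != "phenotypic":
        raise ValueError("heritability is defined from the phenotypic model")
    t = fit.data.trials.index(trial)
    v = fit.data.v
    tr = fit.base.terms[LINE_TERM]
    g_t = float(tr.gamma()[t, t])
    if tr.boundary.any() and g_t < 1e-8 * float(np.var(fit.data.y)):
        raise ValueError(f"genetic variance of trial {trial!r} at zero boundary; "
                         "heritability undefined")
    pev = blup_pev(fit.base, LINE_TERM, indices=np.arange(t * v, (t + 1) * v))
    a = mean_pairwise_difference_pev(pev)
    h2 = 1.0 - a / (2.0 * g_t)
    return float(np.clip(h2, 0.0, 1.0))


def marker_variance_proportion(
    phenotypic_fit: GeneticModelFit, partitioned_fit: GeneticModelFit, trial
) -> float:
    """Share of total genetic variance captured by markers in one trial.

    Compares the residual-genetic variance of the partitioned fit with the
    total genetic variance of the phenotypic fit (both diag-form, same
    data): proportion = 1 − θ̂²_e,part / θ̂²_g,pheno.
    """
    if phenotypic_fit.spec.genetic_model != "phenotypic":
        raise ValueError("first fit must be phenotypic")
    if partitioned_fit.spec.genetic_model != "partitioned":
        raise ValueError("second fit must be partitioned")
    if phenotypic_fit.data.n != partitioned_fit.data.n:
        raise ValueError("fits must share the same data")
    t = phenotypic_fit.data.trials.index(trial)
    g_pheno = float(phenotypic_fit.base.terms[LINE_TERM].gamma()[t, t])
    g_part = float(partitioned_fit.base.terms[LINE_TERM].gamma()[t, t])
    if g_pheno <= 0:
        raise ValueError("phenotypic genetic variance is zero; proportion undefined")
    return 1.0 - g_part / g_pheno
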