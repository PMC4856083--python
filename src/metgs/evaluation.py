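"""Cross-validated genomic prediction accuracy and low-marker-density sweeps.

Lines are divided as evenly as possible into 10 groups; the CV10, CV20 and
CV40 schemes hold out every combination of 1, 2 or 4 groups as the
validation set (10, 45 and 210 iterations).  Lines common to all trials are
assigned first and keep one group label across every analysis so that
single-trial and MET results are comparable.

In each iteration the genomic-selection model is refitted on the training
lines (all phenotype records of validation lines removed, genotypes kept
for prediction), marker effects are back-solved, and validation GEBVs are
regressed against genotypic values (GVs) from a phenotypic model fitted
once to all genotyped lines.  Predictive ability is the R² of that
GV-on-GEBV regression, accuracy its residual mean square.

The low-density sweep reuses the full-marker training effects, truncating
them to random marker subsets of increasing size (200 resamples per size,
identical subsets across compared models).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geno_prep import MarkerMatrix
from .gs_models import (
    GeneticModelFit,
    backsolve_marker_effects,
    fit_genetic_model,
    predict_gebv,
)
from .met_design import MetDataset, ModelSpec

__all__ = [
    "CvPlan",
    "CvResult",
    "make_groups",
    "run_cv",
    "evaluate_regression",
    "draw_subsets",
    "lowdensity_sweep",
]

SCHEMES = {"CV10": 1, "CV20": 2, "CV40": 4}


@dataclass
class CvPlan:
    """Line → group assignment plus the held-out combinations of a scheme."""

    groups: dict
    scheme: str
    n_groups: int = 10

    @property
    def groups_out(self) -> int:
        return SCHEMES[self.scheme]

    @property
    def iterations(self) -> list[tuple[int, ...]]:
        return list(itertools.combinations(range(self.n_groups), self.groups_out))

    def validation_lines(self, combo) -> list:
        held = set(combo)
        return [l for l, g in self.groups.items() if g in held]


def make_groups(
    lines_by_trial: dict, n_groups: int = 10, seed: int = 0, scheme: str = "CV10"
) -> CvPlan:
    """Randomly divide lines into balanced groups, common lines first.

    Lines present in every trial are shuffled and dealt round-robin; lines
    specific to some trials are then appended one at a time to the currently
    smallest group, keeping overall sizes as even as possible.  Fully
    reproducible from ``seed``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    trial_sets = [set(v) for v in lines_by_trial.values()]
    common = sorted(set.intersection(*trial_sets)) if trial_sets else []
    everyone = sorted(set.union(*trial_sets)) if trial_sets else []
    specific = [l for l in everyone if l not in set(common)]
    if n_groups > len(everyone):
        raise ValueError("more groups than lines")

    groups: dict = {}
    order = list(common)
    rng.shuffle(order)
    for i, line in enumerate(order):
        groups[line] = i % n_groups
    sizes = np.bincount(list(groups.values()), minlength=n_groups)
    order = list(specific)
    rng.shuffle(order)
    for line in order:
        g = int(np.argmin(sizes))
        groups[line] = g
        sizes[g] += 1
    return CvPlan(groups=groups, scheme=scheme, n_groups=n_groups)


def evaluate_regression(gv, gebv) -> dict:
    """OLS of GV on GEBV: predictive ability R², residual MSE, slope.

    MSE uses the regression residual mean square with n−2 degrees of
    freedom.  A zero-variance GEBV leaves slope and R² undefined (NaN).
    """
    gv = np.asarray(gv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if gv.size != gebv.size or gv.size < 3:
        raise ValueError("need at least three paired finite values")
    if not (np.isfinite(gv).all() and np.isfinite(gebv).all()):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(gebv) == 0.0:
        return {"r_squared": np.nan, "mse": np.nan, "slope": np.nan}
    res = stats.linregress(gebv, gv)
    fitted = res.intercept + res.slope * gebv
    sse = float(np.sum((gv - fitted) ** 2))
    return {
        "r_squared": float(res.rvalue**2),
        "mse": sse / (gv.size - 2),
        "slope": float(res.slope),
    }


@dataclass
class CvResult:
    """Per-iteration validation regressions and their aggregates."""

    per_iteration: pd.DataFrame
    scheme: str
    model_label: str
    effect_choice: tuple
    gv_trial: object
    failed_iterations: list = field(default_factory=list)

    def summary(self) -> dict:
        ok = self.per_iteration
        return {
            "r_squared_mean": float(ok["r_squared"].mean()),
            "r_squared_sd": float(ok["r_squared"].std(ddof=1)),
            "mse_mean": float(ok["mse"].mean()),
            "mse_sd": float(ok["mse"].std(ddof=1)),
            "slope_mean": float(ok["slope"].mean()),
            "n_iterations": int(len(ok)),
        }


def _effect_selector(effect_choice: tuple, gv_trial, trials) -> tuple:
    """Resolve ('same'|'opposite'|'total'|'main') into a predict_gebv choice."""
    kind = effect_choice[0]
    if kind == "same":
        return ("total", gv_trial)
    if kind == "opposite":
        others = [t for t in trials if t != gv_trial]
        if len(others) != 1:
            raise ValueError("'opposite' requires exactly two trials")
        return ("total", others[0])
    if kind == "total":
        return ("total", effect_choice[1] if len(effect_choice) > 1 else gv_trial)
    if kind == "main":
        return ("main", None)
    raise ValueError(f"unknown effect choice {kind!r}")


def run_cv(
    data: MetDataset,
    markers: MarkerMatrix,
    spec: ModelSpec,
    plan: CvPlan,
    gv: pd.Series,
    gv_trial,
    effect_choice: tuple = ("same",),
    start: dict | None = None,
    collect_fits: bool = False,
    **fit_opts,
) -> CvResult:
    """Run one cross-validation for one model and one GV/effect comparison.

    ``gv`` must be the genotypic values of all genotyped lines in
    ``gv_trial``, precomputed from a phenotypic model fitted to the full
    data.  ``start`` warm-starts every training fit (typically the full-data
    fit's estimates), which the refits then refine.
    """
    results = []
    failed = []
    fits = []
    for combo in plan.iterations:
        val_lines = [l for l in plan.validation_lines(combo) if l in set(markers.line_ids)]
        train = data.drop_lines(val_lines)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_genetic_model(
                    train, spec, markers=markers, start=start, keep_cinv=False, **fit_opts
                )
            if not fit.base.converged:
                raise RuntimeError("non-convergence")
        except Exception as exc:  # noqa: BLE001 - flagged, never silent
            failed.append((combo, str(exc)))
            continue
        effects = backsolve_marker_effects(fit)
        which = _effect_selector(effect_choice, gv_trial, fit.data.trials)
        # only validation lines observed in the GV trial enter the regression
        lines = [l for l in val_lines if l in gv.index]
        M_val = markers.select_lines(lines)
        gebv = predict_gebv(effects, M_val, which=which)
        metrics = evaluate_regression(gv.loc[lines].to_numpy(), gebv.to_numpy())
        metrics["iteration"] = "+".join(str(g) for g in combo)
        results.append(metrics)
        if collect_fits:
            fits.append((combo, fit, effects, lines))
    per_iter = pd.DataFrame(results)
    out = CvResult(
        per_iteration=per_iter,
        scheme=plan.scheme,
        model_label=spec.genetic_model,
        effect_choice=effect_choice,
        gv_trial=gv_trial,
        failed_iterations=failed,
    )
    if collect_fits:
        out.fits = fits  # type: ignore[attr-defined]
    return out


# ----------------------------------------------------------------------
# low marker density


def draw_subsets(p: int, sizes, n_resamples: int = 200, seed: int = 0) -> dict:
    """Random marker subsets per size, shared across compared models.

    The same (size, resample) → indices mapping must be reused for every
    model/scenario being compared so that differences are attributable to
    the models alone.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for x in sizes:
        if not (1 <= x <= p):
            raise ValueError(f"subset size {x} outside 1..{p}")
        out[x] = [np.sort(rng.choice(p, size=x, replace=False)) for _ in range(n_resamples)]
    return out


def lowdensity_sweep(
    effects,
    M_val: MarkerMatrix,
    gv: pd.Series,
    subsets: dict,
    which: tuple = ("total", None),
) -> pd.DataFrame:
    """Validation metrics for random marker subsets of increasing size.

    Marker effects come from the full-marker training fit and are truncated
    to each subset (not refitted).  Returns one row per size with metrics
    averaged over the resamples.
    """
    lines = [l for l in M_val.line_ids if l in gv.index]
    M_val = M_val.select_lines(lines)
    y = gv.loc[lines].to_numpy()
    rows = []
    for x, idx_list in sorted(subsets.items()):
        r2s, mses, slopes = [], [], []
        for idx in idx_list:
            gebv = predict_gebv(effects, M_val, which=which, subset=idx)
            m = evaluate_regression(y, gebv.to_numpy())
            r2s.append(m["r_squared"])
            mses.append(m["mse"])
            slopes.append(m["slope"])
        rows.append(
            {
                "size": x,
                "r_squared": float(np.nanmean(r2s)),
                "mse": float(np.nanmean(mses)),
                "slope": float(np.nanmean(slopes)),
                "n_resamples": len(idx_list),
            }
        )
    return pd.DataFrame(rows)
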