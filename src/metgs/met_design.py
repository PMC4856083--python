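"""Observation-level MET phenotype data and mixed-model design matrices.

A replicated multi-environment trial (MET) records one response per plot
(pot), indexed by trial, line, replicate block and row/column field
position.  This module holds those records (:class:`MetDataset`), the model
configuration (:class:`ModelSpec`), and builds the fixed and random design
matrices of the single-stage mixed model ``y = Xτ + Z_g g + Z_u u + ε``.

Orderings are fixed once and used everywhere: trials sorted by label,
lines sorted by label, and the line-within-trial incidence ``Z_g`` stored
trials-major (all lines of trial 1, then trial 2, …) so that it conforms
with the Kronecker algebra ``I_s ⊗ M`` of the genetic terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetDataset",
    "ModelSpec",
    "RandomDesignTerm",
    "DesignMatrices",
    "build_design",
    "summarize_raw",
]

REQUIRED_COLUMNS = ("trial", "line", "block", "row", "col", "y")


@dataclass
class MetDataset:
    """Observation-level phenotypes of a replicated row-column MET.

    ``records`` has columns trial, line, block, row, col, y.  Records with
    missing response are dropped at construction (the single-stage model
    operates on observed plots only) and counted in ``n_dropped_missing``.
    """

    records: pd.DataFrame
    trait: str = "response"
    units: str = ""
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        df = self.records
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table lacks required columns: {missing_cols}")
        df = df.copy()
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
        df["y"] = pd.to_numeric(df["y"], errors="coerce")
        n0 = len(df)
        df = df.dropna(subset=["y"]).reset_index(drop=True)
        self.n_dropped_missing += n0 - len(df)
        dup = df.duplicated(subset=["trial", "row", "col"])
        if dup.any():
            bad = df.loc[dup, ["trial", "row", "col"]].iloc[0].tolist()
            raise ValueError(f"duplicate plot coordinate (trial, row, col) = {bad}")
        self.records = df
        self.trials = sorted(df["trial"].unique().tolist())
        self.lines = sorted(df["line"].unique().tolist())

    @property
    def s(self) -> int:
        return len(self.trials)

    @property
    def v(self) -> int:
        return len(self.lines)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_t(self) -> dict:
        return self.records["trial"].value_counts().to_dict()

    @property
    def y(self) -> np.ndarray:
        return self.records["y"].to_numpy(float)

    @property
    def trial_index(self) -> np.ndarray:
        lut = {t: i for i, t in enumerate(self.trials)}
        return self.records["trial"].map(lut).to_numpy(int)

    def restrict_lines(self, keep_lines) -> "MetDataset":
        """Dataset restricted to a subset of lines (e.g. genotyped ones)."""
        keep = set(keep_lines)
        df = self.records[self.records["line"].isin(keep)].reset_index(drop=True)
        return MetDataset(df, trait=self.trait, units=self.units)

    def drop_lines(self, drop_lines) -> "MetDataset":
        drop = set(drop_lines)
        df = self.records[~self.records["line"].isin(drop)].reset_index(drop=True)
        return MetDataset(df, trait=self.trait, units=self.units)


@dataclass(frozen=True)
class RandomDesignTerm:
    """A randomization/design random factor with scalar variance θ²I.

    ``factor`` names a column of the records ('block', 'row', 'col').  With
    ``trial=None`` the factor is fitted trial-specifically: one independent
    scalar-variance term per trial (a replicate-block variance per trial).
    With ``trial`` set, the term applies to that trial only (e.g. a random
    column effect in one year).
    """

    factor: str
    trial: object | None = None


@dataclass
class ModelSpec:
    """Model configuration: fixed terms, random design terms, genetic model.

    ``genetic_model`` is one of 'phenotypic' (line term only), 'standard'
    (marker term only) or 'partitioned' (both).  ``form_um``/``form_ue``
    name the trial covariance family of the marker and residual-genetic
    terms (see :mod:`metgs.varstruct`).
    """

    genetic_model: str = "partitioned"
    form_um: str | None = None
    form_ue: str | None = None
    random_terms: list = field(default_factory=lambda: [RandomDesignTerm("block")])
    fixed_covariates: list = field(default_factory=list)  # e.g. [("lin_row", trial)]
    fam1_psi_zero: bool = True

    def __post_init__(self) -> None:
        gm = self.genetic_model
        if gm not in ("phenotypic", "standard", "partitioned"):
            raise ValueError(f"unknown genetic_model {gm!r}")
        if gm == "phenotypic":
            if self.form_um is not None:
                raise ValueError("phenotypic model takes no marker form (form_um)")
            if self.form_ue is None:
                raise ValueError("phenotypic model requires form_ue")
        elif gm == "standard":
            if self.form_ue is not None:
                raise ValueError("standard model takes no residual genetic form (form_ue)")
            if self.form_um is None:
                raise ValueError("standard model requires form_um")
        else:
            if self.form_um is None or self.form_ue is None:
                raise ValueError("partitioned model requires both form_um and form_ue")

    def validate(self, data: MetDataset) -> None:
        for rt in self.random_terms:
            if rt.factor not in data.records.columns:
                raise ValueError(f"random term factor {rt.factor!r} not in data")
            if rt.trial is not None and rt.trial not in data.trials:
                raise ValueError(f"random term trial {rt.trial!r} not in data")


@dataclass
class DesignMatrices:
    """Fixed and random incidence matrices for one dataset/model pair."""

    X: np.ndarray
    fixed_names: list
    Z_g: np.ndarray                  # n × (v·s), trials-major
    Z_u: list                        # list of (name, n×b incidence)
    trial_index: np.ndarray
    lines: list
    trials: list


def build_design(data: MetDataset, spec: ModelSpec) -> DesignMatrices:
    """Assemble X, Z_g and the scalar-variance design incidences.

    ``Z_g`` columns are trials-major, lines-minor; a line absent from a
    trial keeps a structural zero column in that trial's block so the
    column count is always ``v·s``.
    """
    spec.validate(data)
    df = data.records
    n, s, v = data.n, data.s, data.v
    trial_lut = {t: i for i, t in enumerate(data.trials)}
    line_lut = {l: i for i, l in enumerate(data.lines)}
    ti = df["trial"].map(trial_lut).to_numpy(int)
    li = df["line"].map(line_lut).to_numpy(int)

    # fixed: per-trial intercepts, plus optional centered linear row/col
    X_cols = [np.asarray(ti == t, float) for t in range(s)]
    fixed_names = [f"mean:{t}" for t in data.trials]
    for cov in spec.fixed_covariates:
        kind, trial = cov
        col = {"lin_row": "row", "lin_col": "col"}.get(kind)
        if col is None:
            raise ValueError(f"unknown fixed covariate {kind!r}")
        mask = ti == trial_lut[trial]
        z = np.zeros(n)
        vals = df.loc[mask, col].to_numpy(float)
        z[mask] = vals - vals.mean()
        X_cols.append(z)
        fixed_names.append(f"{kind}:{trial}")
    X = np.column_stack(X_cols)

    # line-within-trial incidence
    Z_g = np.zeros((n, v * s))
    Z_g[np.arange(n), ti * v + li] = 1.0

    # scalar random design terms, expanded per trial
    Z_u = []
    for rt in spec.random_terms:
        target_trials = data.trials if rt.trial is None else [rt.trial]
        for t in target_trials:
            mask = (df["trial"] == t).to_numpy()
            levels = sorted(df.loc[mask, rt.factor].unique().tolist())
            lut = {lv: j for j, lv in enumerate(levels)}
            Z = np.zeros((n, len(levels)))
            rows = np.where(mask)[0]
            for r in rows:
                Z[r, lut[df.at[r, rt.factor]]] = 1.0
            Z_u.append((f"{rt.factor}:{t}", Z))

    return DesignMatrices(
        X=X,
        fixed_names=fixed_names,
        Z_g=Z_g,
        Z_u=Z_u,
        trial_index=ti,
        lines=list(data.lines),
        trials=list(data.trials),
    )


def summarize_raw(data: MetDataset, lines_subset=None):
    """Raw per-trial line means, trial means, and inter-trial correlation.

    Line means average the raw replicate observations.  Trial means and the
    Pearson correlation are computed over ``lines_subset`` (default: all
    lines); the correlation uses lines observed in both of the first two
    trials.
    """
    df = data.records
    if lines_subset is not None:
        df = df[df["line"].isin(set(lines_subset))]
    means = df.groupby(["trial", "line"])["y"].mean().unstack("trial")
    trial_means = means.mean(axis=0)
    corr = None
    if data.s >= 2:
        both = means.dropna(subset=data.trials[:2])
        if len(both) < 2:
            raise ValueError("fewer than two lines common to both trials; correlation undefined")
        a = both[data.trials[0]].to_numpy()
        b = both[data.trials[1]].to_numpy()
        corr = float(np.corrcoef(a, b)[0, 1])
    return {
        "line_means": means,
        "trial_means": trial_means.to_dict(),
        "correlation": corr,
    }
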