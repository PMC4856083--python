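"""Run configuration and model-comparison tables.

``compare_models`` reproduces the full-data model screening workflow:
log-likelihood, random-parameter count and AIC per fitted model (sorted by
AIC), plus likelihood-ratio tests for the nested pairs (standard and
phenotypic models are nested in the partitioned model of the same trial
covariance form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reml
from .gs_models import GeneticModelFit
from .met_design import ModelSpec, RandomDesignTerm

__all__ = ["RunConfig", "compare_models"]


@dataclass
class RunConfig:
    """Parsed run configuration (YAML) for the command-line workflow."""

    phenotypes: Path
    genotypes: Path | None
    spec: ModelSpec
    cv_scheme: str = "CV10"
    seed: int = 0
    out_dir: Path = Path("metgs_out")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        model = raw.get("model", {})
        rts = [
            RandomDesignTerm(d["factor"], d.get("trial"))
            for d in model.get("random_terms", [{"factor": "block"}])
        ]
        spec = ModelSpec(
            genetic_model=model.get("genetic_model", "partitioned"),
            form_um=model.get("form_um"),
            form_ue=model.get("form_ue"),
            random_terms=rts,
            fam1_psi_zero=model.get("fam1_psi_zero", True),
        )
        pheno = Path(raw["phenotypes"])
        geno = Path(raw["genotypes"]) if raw.get("genotypes") else None
        for p in [pheno] + ([geno] if geno else []):
            if not p.exists():
                raise FileNotFoundError(p)
        cv = raw.get("cv", {})
        return cls(
            phenotypes=pheno,
            genotypes=geno,
            spec=spec,
            cv_scheme=cv.get("scheme", "CV10"),
            seed=int(cv.get("seed", raw.get("seed", 0))),
            out_dir=Path(raw.get("out_dir", "metgs_out")),
        )


def _nested(a: GeneticModelFit, b: GeneticModelFit) -> bool:
    """Is fit ``a`` nested in fit ``b``? (same forms, fewer genetic terms)"""
    if b.spec.genetic_model != "partitioned":
        return False
    if a.spec.genetic_model == "standard":
        return a.spec.form_um == b.spec.form_um
    if a.spec.genetic_model == "phenotypic":
        return a.spec.form_ue == b.spec.form_ue
    return False


def compare_models(fits: list[GeneticModelFit]):
    """AIC/log-likelihood comparison table plus nested-pair LRTs.

    All fits must share the data and fixed-effect design (REML likelihoods
    are not comparable otherwise).
    """
    if not fits:
        raise ValueError("no fits to compare")
    X0 = fits[0].base.X
    for f in fits[1:]:
        if f.base.X.shape != X0.shape or not np.allclose(f.base.X, X0):
            raise ValueError("fits have different fixed effects; refusing comparison")
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.label,
                "genetic_model": f.spec.genetic_model,
                "form_um": f.spec.form_um or "",
                "form_ue": f.spec.form_ue or "",
                "loglik": f.base.loglik,
                "n_random_params": f.base.n_random_params,
                "aic": f.aic,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()

    lrt_rows = []
    for a in fits:
        for b in fits:
            if _nested(a, b):
                stat, df, p = reml.lrt(a.base, b.base)
                lrt_rows.append(
                    {"nested": a.label, "full": b.label, "statistic": stat, "df": df, "p": p}
                )
    lrts = pd.DataFrame(lrt_rows)
    return table, lrts
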