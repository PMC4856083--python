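"""Genetic models: parameterization equality, back-solving, heritability."""

import numpy as np
import pandas as pd
import pytest

from metgs.geno_prep import MarkerMatrix
from metgs.met_design import MetDataset, ModelSpec, build_design
from metgs.reml import RandomTerm, _Problem, lrt
from metgs.gs_models import (
    MARKER_TERM,
    backsolve_marker_effects,
    fit_genetic_model,
    genotypic_values,
    heritability,
    marker_variance_proportion,
    predict_gebv,
)
from metgs.varstruct import CovStructure


def _toy_single_trial(seed=2, v=6, reps=2, p=3):
    """One trial, few lines, p <= v markers (tiny enough for exact optima)."""
    rng = np.random.default_rng(seed)
    while True:
        M = rng.choice([0.0, 2.0], size=(v, p))
        if all(np.ptp(M[:, j]) > 0 for j in range(p)) and np.linalg.matrix_rank(M) == p:
            break
    markers = MarkerMatrix(M, [f"L{i}" for i in range(v)], [f"M{j}" for j in range(p)])
    u = rng.normal(0, 0.6, p)
    recs = []
    for i in range(v):
        for rep in range(reps):
            recs.append(
                {
                    "trial": "T1",
                    "line": f"L{i}",
                    "block": f"B{rep}",
                    "row": rep + 1,
                    "col": i + 1,
                    "y": 50.0 + M[i] @ u + rng.normal(0, 1.0),
                }
            )
    return MetDataset(pd.DataFrame(recs)), markers


class TestParameterizations:
    def test_line_and_marker_dimension_fits_agree(self):
        data, markers = _toy_single_trial()
        spec = ModelSpec("standard", form_um="diag", random_terms=[])
        f_line = fit_genetic_model(data, spec, markers=markers, parameterization="line")
        f_mark = fit_genetic_model(data, spec, markers=markers, parameterization="marker")
        assert f_line.loglik == pytest.approx(f_mark.loglik, abs=1e-6)

    def test_partitioned_with_zero_ue_variance_equals_standard(self, tiny_met):
        data, markers, _ = tiny_met
        std = fit_genetic_model(
            data, ModelSpec("standard", form_um="diag"), markers=markers
        )
        # evaluate the partitioned likelihood with u_e variances at the zero
        # boundary and every other parameter at the standard optimum
        dm = build_design(data, ModelSpec("partitioned", form_um="diag", form_ue="diag"))
        K = markers.select_lines(data.lines).relationship()
        terms = [
            RandomTerm("marker", dm.Z_g, structure=CovStructure("diag", 2), K=K),
            RandomTerm("lines", dm.Z_g, structure=CovStructure("diag", 2)),
            RandomTerm("block:T1", dm.Z_u[0][1]),
            RandomTerm("block:T2", dm.Z_u[1][1]),
        ]
        prob = _Problem(data.y, dm.X, terms, dm.trial_index)
        x = np.concatenate(
            [
                std.base.terms["marker"].x,
                np.full(2, np.log(1e-12 * prob.scale)),
                std.base.terms["block:T1"].x,
                std.base.terms["block:T2"].x,
                np.log(std.base.residual_variances),
            ]
        )
        n2l, _ = prob.neg2ll_grad(x)
        assert -0.5 * n2l == pytest.approx(std.loglik, abs=1e-4)

    def test_standard_and_phenotypic_nested_in_partitioned(self, tiny_met):
        data, markers, _ = tiny_met
        std = fit_genetic_model(data, ModelSpec("standard", form_um="diag"), markers=markers)
        pheno = fit_genetic_model(
            data, ModelSpec("phenotypic", form_ue="diag"), markers=markers
        )
        part = fit_genetic_model(
            data, ModelSpec("partitioned", form_um="diag", form_ue="diag"), markers=markers
        )
        for nested in (std, pheno):
            stat, df, p = lrt(nested.base, part.base)
            assert stat >= 0 and df == 2

    def test_k_scaling_leaves_loglik_gebv_invariant_and_rescales_variance(self, tiny_met):
        data, markers, _ = tiny_met
        c = 10.0
        spec = ModelSpec("standard", form_um="diag")
        f1 = fit_genetic_model(data, spec, markers=markers)
        f2 = fit_genetic_model(data, spec, markers=markers, k_scaling=c)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)
        assert np.abs(f1.u_g_blups() - f2.u_g_blups()).max() < 1e-5
        r = f1.base.terms[MARKER_TERM].params["variance_t1"] / f2.base.terms[
            MARKER_TERM
        ].params["variance_t1"]
        assert r == pytest.approx(c, rel=1e-3)

    def test_missing_genotypes_dropped_with_warning(self, tiny_met):
        data, markers, _ = tiny_met
        sub = markers.select_lines(markers.line_ids[:-2])
        with pytest.warns(UserWarning, match="without genotypes"):
            fit = fit_genetic_model(
                data, ModelSpec("standard", form_um="diag"), markers=sub
            )
        assert fit.data.v == data.v - 2


class TestBacksolve:
    def test_backsolve_reproduces_ug_when_k_invertible(self, small_met):
        data, markers, _ = small_met
        fit = fit_genetic_model(
            data, ModelSpec("partitioned", form_um="cs_diag", form_ue="diag"),
            markers=markers,
        )
        eff = backsolve_marker_effects(fit)
        assert not eff.pseudo_inverse
        ug = fit.u_g_blups().reshape(2, data.v)
        rec = eff.total @ fit.markers.M.T
        assert np.abs(rec - ug).max() < 1e-8

    def test_orthogonal_rows_give_scaled_transpose(self):
        # M with orthogonal rows: M Mᵀ = c I, so ũ_m = Mᵀ ũ_g / c
        M = np.array([[2.0, 0.0, 0.0, 2.0], [0.0, 2.0, 2.0, 0.0]])
        c = 8.0
        u_g = np.array([1.5, -0.7])
        expect = M.T @ u_g / c
        assert np.allclose(M @ expect, u_g)

    def test_main_plus_interaction_equals_total(self, tiny_met):
        data, markers, _ = tiny_met
        fit = fit_genetic_model(
            data, ModelSpec("partitioned", form_um="cs_diag", form_ue="cs_diag"),
            markers=markers,
        )
        eff = backsolve_marker_effects(fit)
        assert eff.main is not None
        assert np.abs(eff.main[None, :] + eff.interaction - eff.total).max() < 1e-10

    def test_cs_single_term_matches_explicit_two_term_formulation(self, small_met):
        """A CS genetic term equals a common line term (θ²K) plus a DIAG
        interaction term with equal specific variances — the explicit
        main+interaction formulation of the same model."""
        data, markers, _ = small_met
        dm = build_design(data, ModelSpec("standard", form_um="cs"))
        K = markers.select_lines(data.lines).relationship()
        one = fit_genetic_model(
            data, ModelSpec("standard", form_um="cs"), markers=markers
        )
        v = data.v
        Z_common = dm.Z_g[:, :v] + dm.Z_g[:, v:]
        terms = [
            RandomTerm("main", Z_common, structure=CovStructure("single", 1), K=K),
            RandomTerm("inter", dm.Z_g, structure=CovStructure("diag", 2), K=K),
            RandomTerm("b1", dm.Z_u[0][1]),
            RandomTerm("b2", dm.Z_u[1][1]),
        ]
        prob = _Problem(data.y, dm.X, terms, dm.trial_index)
        # evaluate at the single-term optimum mapped onto the two-term coords
        xm = one.base.terms["marker"].x  # (log θ², log θ_e²)
        x = np.concatenate(
            [
                [xm[0]], [xm[1], xm[1]],
                one.base.terms["block:T1"].x,
                one.base.terms["block:T2"].x,
                np.log(one.base.residual_variances),
            ]
        )
        n2l, _ = prob.neg2ll_grad(x)
        assert -0.5 * n2l == pytest.approx(one.loglik, abs=1e-6)


class TestPredictGebv:
    def test_zero_effects_give_zero_gebv(self, tiny_met):
        data, markers, _ = tiny_met
        fit = fit_genetic_model(
            data, ModelSpec("standard", form_um="diag"), markers=markers
        )
        eff = backsolve_marker_effects(fit)
        eff.total = np.zeros_like(eff.total)
        g = predict_gebv(eff, fit.markers, which=("total", "T1"))
        assert (g == 0).all()

    def test_single_marker_effect(self):
        from metgs.gs_models import MarkerEffects

        eff = MarkerEffects(
            marker_ids=["M0"], trials=["T1"], total=np.array([[0.5]]), form="diag"
        )
        M = MarkerMatrix(np.array([[0.0], [2.0]]), ["a", "b"], ["M0"])
        g = predict_gebv(eff, M, which=("total", "T1"))
        assert g.tolist() == [0.0, 1.0]

    def test_training_lines_full_set_reproduces_ug(self, tiny_met):
        data, markers, _ = tiny_met
        fit = fit_genetic_model(
            data, ModelSpec("standard", form_um="diag"), markers=markers
        )
        eff = backsolve_marker_effects(fit)
        g = predict_gebv(eff, fit.markers, which=("total", "T2"))
        ug = fit.u_g_blups()[data.v :]
        assert np.abs(g.to_numpy() - ug).max() < 1e-8

    def test_marker_mismatch_raises(self, tiny_met):
        data, markers, _ = tiny_met
        fit = fit_genetic_model(
            data, ModelSpec("standard", form_um="diag"), markers=markers
        )
        eff = backsolve_marker_effects(fit)
        M_bad = MarkerMatrix(
            fit.markers.M[:, :-1], list(fit.markers.line_ids),
            list(fit.markers.marker_ids[:-1]),
        )
        with pytest.raises(ValueError, match="marker sets differ"):
            predict_gebv(eff, M_bad, which=("total", "T1"))

    def test_subset_prediction_uses_only_subset(self, tiny_met):
        data, markers, _ = tiny_met
        fit = fit_genetic_model(
            data, ModelSpec("standard", form_um="diag"), markers=markers
        )
        eff = backsolve_marker_effects(fit)
        idx = np.array([0, 2, 5])
        g = predict_gebv(eff, fit.markers, which=("total", "T1"), subset=idx)
        expect = fit.markers.M[:, idx] @ eff.total[0][idx]
        assert np.allclose(g.to_numpy(), expect)


class TestDerivedStatistics:
    def test_heritability_matches_balanced_oneway_closed_form(self, oneway_dataset):
        data, (g, r) = oneway_dataset
        markers = None
        fit = fit_genetic_model(
            data, ModelSpec("phenotypic", form_ue="diag", random_terms=[])
        )
        sg = fit.base.terms["lines"].params["variance_t1"]
        se = fit.base.residual_variances[0]
        h2 = heritability(fit, "T1")
        assert h2 == pytest.approx(r * sg / (r * sg + se), abs=1e-6)

    def test_zero_pev_limit_gives_unit_heritability(self):
        from metgs.reml import mean_pairwise_difference_pev

        assert 1.0 - mean_pairwise_difference_pev(np.zeros((4, 4))) / (2 * 3.0) == 1.0

    def test_marker_variance_proportion_arithmetic(self, small_met):
        data, markers, _ = small_met
        pheno = fit_genetic_model(
            data, ModelSpec("phenotypic", form_ue="diag"), markers=markers
        )
        part = fit_genetic_model(
            data, ModelSpec("partitioned", form_um="diag", form_ue="diag"),
            markers=markers,
        )
        prop = marker_variance_proportion(pheno, part, "T1")
        g_ph = pheno.base.terms["lines"].params["variance_t1"]
        g_pa = part.base.terms["lines"].params["variance_t1"]
        assert prop == pytest.approx(1 - g_pa / g_ph)

    def test_published_proportion_arithmetic(self):
        # variance pairs from the barley height fits round to 0.75 / 0.73
        assert round(1 - 27.67 / 111.65, 2) == 0.75
        assert round(1 - 23.43 / 86.35, 2) == 0.73

    def test_genotypic_values_are_line_blups(self, small_met):
        data, markers, _ = small_met
        pheno = fit_genetic_model(
            data, ModelSpec("phenotypic", form_ue="diag"), markers=markers
        )
        gv = genotypic_values(pheno, "T2")
        assert list(gv.index) == data.lines
        v = data.v
        assert np.allclose(gv.to_numpy(), pheno.base.terms["lines"].blup[v:])
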