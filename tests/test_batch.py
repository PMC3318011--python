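"""Quantile normalization and empirical-Bayes batch correction."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from varray import (
    BatchEffectTruth,
    apply_batch_correction,
    build_virtual_array,
    fit_batch_model,
    generate_multiplatform_study,
    make_programs,
    quantile_normalize,
    reference_anchor_check,
)
from varray.batch import _eb_fixed_point
from varray.synthetic import PlatformSpec

from conftest import make_virtual_array


class TestQuantileNormalize:
    def test_two_sample_hand_example(self):
        v = make_virtual_array(np.array([[1, 4], [2, 5], [3, 6]], dtype=float))
        out = quantile_normalize(v)
        np.testing.assert_allclose(out.values.to_numpy(), [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_samples_unchanged(self, rng):
        col = rng.normal(size=8)
        v = make_virtual_array(np.column_stack([col, col, col]))
        out = quantile_normalize(v)
        np.testing.assert_allclose(out.values.to_numpy(), v.values.to_numpy(), atol=1e-12)

    def test_definitional_oracle_sorted_columns_identical(self, rng):
        v = make_virtual_array(rng.normal(size=(20, 5)))
        out = quantile_normalize(v).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 5):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)

    def test_within_sample_ranks_preserved(self, rng):
        X = rng.normal(size=(30, 4))
        v = make_virtual_array(X)
        out = quantile_normalize(v).values.to_numpy()
        for j in range(4):
            assert (np.argsort(X[:, j], kind="stable") == np.argsort(out[:, j], kind="stable")).all()

    def test_ties_get_mean_of_tied_quantile_values(self):
        v = make_virtual_array(np.array([[1.0, 3.0], [1.0, 4.0], [2.0, 5.0]]))
        out = quantile_normalize(v).values.to_numpy()
        # target distribution = mean of sorted columns = [2, 2.5, 3.5]
        np.testing.assert_allclose(out[:, 1], [2.0, 2.5, 3.5])
        np.testing.assert_allclose(out[:, 0], [2.25, 2.25, 3.5])

    def test_idempotent(self, rng):
        v = make_virtual_array(rng.normal(size=(25, 6)))
        once = quantile_normalize(v)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-12
        )

    def test_constant_sample_permitted(self):
        v = make_virtual_array(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))
        out = quantile_normalize(v).values.to_numpy()
        assert np.allclose(out[:, 0], out[:, 0].mean())


def two_batch_array(rng, n_genes=40, n1=10, n2=12, shift=1.5, scale2=1.0):
    base = rng.normal(7, 1, size=n_genes)
    Y = np.empty((n_genes, n1 + n2))
    Y[:, :n1] = base[:, None] + rng.normal(0, 0.5, (n_genes, n1))
    Y[:, n1:] = base[:, None] + shift + scale2 * rng.normal(0, 0.5, (n_genes, n2))
    return make_virtual_array(Y, batch=["b1"] * n1 + ["b2"] * n2)


class TestFitBatchModel:
    def test_two_batch_standardization_matches_closed_form_oracle(self, rng):
        """No-covariate case: alpha, sigma, gamma_hat, delta_hat by direct formulas."""
        v = two_batch_array(rng)
        model = fit_batch_model(v, covariate_key=None)
        Y = v.values.to_numpy()
        b = v.metadata["batch"].to_numpy()
        n1, n2 = (b == "b1").sum(), (b == "b2").sum()
        m1, m2 = Y[:, b == "b1"].mean(axis=1), Y[:, b == "b2"].mean(axis=1)
        alpha = (n1 * m1 + n2 * m2) / (n1 + n2)
        resid = Y.copy()
        resid[:, b == "b1"] -= m1[:, None]
        resid[:, b == "b2"] -= m2[:, None]
        sigma = np.sqrt((resid**2).mean(axis=1))
        np.testing.assert_allclose(model.alpha.to_numpy(), alpha, atol=1e-8)
        np.testing.assert_allclose(model.sigma.to_numpy(), sigma, atol=1e-8)
        s = (Y - alpha[:, None]) / sigma[:, None]
        np.testing.assert_allclose(
            model.gamma_hat.loc["b1"].to_numpy(), s[:, b == "b1"].mean(axis=1), atol=1e-8
        )
        np.testing.assert_allclose(
            model.delta2_hat.loc["b2"].to_numpy(),
            s[:, b == "b2"].var(axis=1, ddof=1),
            atol=1e-8,
        )

    def test_gamma_star_lies_between_raw_estimate_and_prior_mean(self, rng):
        v = two_batch_array(rng)
        model = fit_batch_model(v, covariate_key=None)
        for b in model.batches:
            g_hat = model.gamma_hat.loc[b].to_numpy()
            g_star = model.gamma_star.loc[b].to_numpy()
            bar = model.hyper[b]["gamma_bar"]
            lo, hi = np.minimum(g_hat, bar), np.maximum(g_hat, bar)
            assert np.all(g_star >= lo - 1e-9) and np.all(g_star <= hi + 1e-9)

    def test_stronger_prior_precision_pulls_gamma_toward_prior_mean(self, rng):
        v = two_batch_array(rng)
        model = fit_batch_model(v, covariate_key=None)
        b = "b1"
        block = ((v.values.to_numpy() - model.alpha.to_numpy()[:, None])
                 / model.sigma.to_numpy()[:, None])[:, (v.metadata["batch"] == b).to_numpy()]
        h = model.hyper[b]
        g_loose, _, _ = _eb_fixed_point(
            block, model.gamma_hat.loc[b].to_numpy(), model.delta2_hat.loc[b].to_numpy(),
            h["gamma_bar"], h["tau2"], h["shape"], h["scale"],
        )
        g_tight, _, _ = _eb_fixed_point(
            block, model.gamma_hat.loc[b].to_numpy(), model.delta2_hat.loc[b].to_numpy(),
            h["gamma_bar"], h["tau2"] / 100.0, h["shape"], h["scale"],
        )
        assert np.all(
            np.abs(g_tight - h["gamma_bar"]) <= np.abs(g_loose - h["gamma_bar"]) + 1e-9
        )

    def test_single_batch_rejected(self, rng):
        v = make_virtual_array(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="two batches"):
            fit_batch_model(v, covariate_key=None)

    def test_batch_with_one_sample_rejected(self, rng):
        v = make_virtual_array(rng.normal(size=(5, 4)), batch=["b1", "b1", "b1", "b2"])
        with pytest.raises(ValueError, match=">=2 samples"):
            fit_batch_model(v, covariate_key=None)

    def test_confounded_covariate_rejected(self, rng):
        v = make_virtual_array(
            rng.normal(size=(5, 6)),
            batch=["b1"] * 3 + ["b2"] * 3,
            cell_type=["t1"] * 3 + ["t2"] * 3,
        )
        with pytest.raises(ValueError, match="confounded"):
            fit_batch_model(v, covariate_key="cell_type")


def recovery_study(seed=0, n_per_group=24, n_genes=200, gamma=(2.0, -2.0), delta=(1.0, 1.0)):
    """Two programs × two batches on one neutral platform, gene-level exact."""
    progs = make_programs(["alpha", "beta"], n_genes=n_genes, markers_per_program=30, seed=99)
    genes = sorted(progs[0].base_level)
    platforms = [PlatformSpec("p1", frozenset(genes), probes_per_gene=1)]
    batches = [
        BatchEffectTruth("b1", gamma=gamma[0], delta=delta[0]),
        BatchEffectTruth("b2", gamma=gamma[1], delta=delta[1]),
    ]
    study = generate_multiplatform_study(
        progs, platforms, batches, n_per_group=n_per_group,
        noise_sd=0.5, probe_sd=0.0, seed=seed,
    )
    v = build_virtual_array(study.probe_matrices, study.annotations, study.metadata)
    return study, v


class TestParameterRecovery:
    def test_gamma_recovered_on_data_scale(self):
        study, v = recovery_study(seed=4)
        model = fit_batch_model(v)
        rec = (model.gamma_star.loc["b1"] * model.sigma).mean()
        assert abs(rec - 2.0) < 0.1
        rec2 = (model.gamma_star.loc["b2"] * model.sigma).mean()
        assert abs(rec2 - (-2.0)) < 0.1

    def test_null_simulation_gamma_near_zero(self):
        study, v = recovery_study(seed=5, n_per_group=49, gamma=(0.0, 0.0))
        model = fit_batch_model(v)
        for b in model.batches:
            assert np.abs((model.gamma_star.loc[b] * model.sigma)).mean() < 0.05

    def test_doubled_noise_sd_recovered_as_variance_ratio(self):
        study, v = recovery_study(seed=6, n_per_group=49, gamma=(0.0, 0.0), delta=(1.0, 2.0))
        model = fit_batch_model(v)
        ratio = (model.delta2_star.loc["b2"] / model.delta2_star.loc["b1"]).mean()
        assert 3.0 < ratio < 5.0


class TestApplyCorrection:
    def test_zero_effect_model_is_identity(self, rng):
        v = two_batch_array(rng)
        model = fit_batch_model(v, covariate_key=None)
        model.gamma_star.iloc[:, :] = 0.0
        model.delta2_star.iloc[:, :] = 1.0
        out = apply_batch_correction(v, model)
        np.testing.assert_allclose(out.values.to_numpy(), v.values.to_numpy(), atol=1e-10)

    def test_batch_mean_difference_shrinks_and_contrast_survives(self):
        study, v = recovery_study(seed=7)
        model = fit_batch_model(v)
        out = apply_batch_correction(v, model)
        b = v.metadata["batch"]
        before = (
            v.values.loc[:, (b == "b1").to_numpy()].mean(axis=1)
            - v.values.loc[:, (b == "b2").to_numpy()].mean(axis=1)
        ).abs().mean()
        after = (
            out.values.loc[:, (b == "b1").to_numpy()].mean(axis=1)
            - out.values.loc[:, (b == "b2").to_numpy()].mean(axis=1)
        ).abs().mean()
        assert after < 0.1 * before
        # biological contrast: program-mean difference on alpha's marker genes
        prog = next(p for p in study.truth["programs"] if p.name == "alpha")
        markers = sorted(prog.marker_genes)
        ct = v.metadata["cell_type"]
        contrast = (
            out.values.loc[markers, (ct == "alpha").to_numpy()].mean(axis=1)
            - out.values.loc[markers, (ct == "beta").to_numpy()].mean(axis=1)
        ).mean()
        assert abs(contrast - 3.0) < 0.3  # truth: +3 log2 marker boost

    def test_unknown_batch_rejected(self, rng):
        v = two_batch_array(rng)
        model = fit_batch_model(v, covariate_key=None)
        v2 = make_virtual_array(v.values.to_numpy(), batch=["b9"] * v.n_samples)
        v2.values.index = v.values.index
        with pytest.raises(ValueError, match="b9"):
            apply_batch_correction(v2, model)

    def test_shapes_and_orders_preserved(self, rng):
        v = two_batch_array(rng)
        out = apply_batch_correction(v, fit_batch_model(v, covariate_key=None))
        assert out.genes == v.genes and out.samples == v.samples


class TestReferenceAnchorCheck:
    def _ref_array(self, rng, shift_b2=0.0):
        n_genes = 30
        base = rng.normal(7, 1, size=n_genes)
        cols, batch, ct = [], [], []
        for b, shift in (("b1", 0.0), ("b2", shift_b2)):
            for k in range(2):
                cols.append(base + shift + rng.normal(0, 0.1, n_genes))
                batch.append(b)
                ct.append("reference")
            for k in range(2):
                cols.append(base + shift + rng.normal(0, 0.1, n_genes) + 1)
                batch.append(b)
                ct.append("x")
        return make_virtual_array(np.column_stack(cols), batch=batch, cell_type=ct)

    def test_identical_references_give_zero_distance_no_flags(self):
        base = np.linspace(5, 9, 10)
        cols = [base, base, base, base]
        v = make_virtual_array(
            np.column_stack(cols),
            batch=["b1", "b1", "b2", "b2"],
            cell_type=["reference"] * 4,
        )
        rep = reference_anchor_check(v)
        assert not rep["any_flagged"]
        for rec in rep["batches"].values():
            assert rec["between"] == pytest.approx(0.0, abs=1e-12)

    def test_uncorrected_shift_is_flagged(self, rng):
        rep = reference_anchor_check(self._ref_array(rng, shift_b2=2.0))
        assert rep["batches"]["b2"]["flagged"]

    def test_corrected_study_not_flagged(self, rng):
        v = self._ref_array(rng, shift_b2=2.0)
        out = apply_batch_correction(v, fit_batch_model(v))
        assert not reference_anchor_check(out)["any_flagged"]

    def test_no_reference_samples_is_error(self, rng):
        v = make_virtual_array(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="reference"):
            reference_anchor_check(v)


class TestAgainstReferenceImplementation:
    def test_matches_sva_combat_on_small_matrix(self, tmp_path, rng):
        """Independent cross-check against the canonical R implementation."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the reference cross-check")
        v = two_batch_array(rng, n_genes=50, n1=8, n2=10)
        model = fit_batch_model(v, covariate_key=None)
        mine = apply_batch_correction(v, model).values
        dat = tmp_path / "dat.tsv"
        v.values.to_csv(dat, sep="\t")
        batches = ",".join(f"'{b}'" for b in v.metadata["batch"])
        script = tmp_path / "combat.R"
        script.write_text(
            "suppressMessages(library(sva))\n"
            f"dat <- as.matrix(read.table('{dat}', sep='\\t', header=TRUE, row.names=1))\n"
            f"batch <- c({batches})\n"
            "out <- ComBat(dat=dat, batch=batch, mod=NULL, par.prior=TRUE)\n"
            f"write.table(out, '{tmp_path / 'theirs.tsv'}', sep='\\t', quote=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        theirs = pd.read_csv(tmp_path / "theirs.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(mine.to_numpy(), theirs.to_numpy(), atol=1e-3)
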