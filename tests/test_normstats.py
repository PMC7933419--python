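"""Normalization, imputation, moderated differential expression, BH FDR."""
from __future__ import annotations

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats, special

from imsischemia import normstats, synthgen
from imsischemia.iodata import StudyDesign
from imsischemia.normstats import (
    ROI,
    STAR_THRESHOLDS,
    bh_adjust,
    estimate_f_prior,
    extract_roi_means,
    fit_moderated_de,
    impute_zeros,
    log2_transform,
    mstus_normalize,
    significance_stars,
    volcano_table,
)
from imsischemia.peakflow import FeatureList, FeatureMatrix


def _matrix(values, tissue=None, sample_id="s", group="control"):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    return FeatureMatrix(
        sample_id=sample_id,
        pixels=[(i, 0) for i in range(n)],
        features=FeatureList(100.0 + np.arange(f), np.ones(f)),
        values=values,
        tissue=None if tissue is None else np.asarray(tissue, dtype=bool),
        group=group,
        timepoint="15min",
    )


class TestMstus:
    def test_tissue_rows_equalized_to_common_total(self):
        m = _matrix([[1, 1], [3, 3], [10, 10]], tissue=[True, True, False])
        out = mstus_normalize(m)
        sums = out.values.sum(axis=1)
        # both tissue pixels end at the tissue-mean total (2+6)/2 = 4
        assert sums[0] == pytest.approx(4.0)
        assert sums[1] == pytest.approx(4.0)
        # off-tissue pixel untouched
        np.testing.assert_array_equal(out.values[2], [10, 10])

    def test_relative_composition_preserved(self, rng):
        vals = rng.lognormal(3, 1, (20, 6))
        out = mstus_normalize(_matrix(vals))
        frac_before = vals / vals.sum(axis=1, keepdims=True)
        frac_after = out.values / out.values.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(frac_before, frac_after, rtol=1e-12)

    def test_zero_signal_pixel_left_unscaled(self):
        m = _matrix([[0, 0], [4, 4]], tissue=[True, True])
        with np.errstate(all="raise"):
            out = mstus_normalize(m)
        np.testing.assert_array_equal(out.values[0], [0, 0])


class TestImpute:
    def test_zeros_replaced_by_fifth_of_feature_minimum(self):
        m = _matrix([[0, 10], [5, 0], [15, 40]],
                    tissue=[True, True, True])
        out = impute_zeros(m)
        assert out.values[0, 0] == pytest.approx(5 / 5)
        assert out.values[1, 1] == pytest.approx(10 / 5)
        # nonzero entries untouched
        assert out.values[2, 0] == 15 and out.values[2, 1] == 40

    def test_never_detected_feature_stays_zero(self):
        m = _matrix([[0.0, 3.0], [0.0, 4.0]], tissue=[True, True])
        out = impute_zeros(m)
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 0.0])

    def test_off_tissue_rows_untouched(self):
        m = _matrix([[0, 1], [2, 3]], tissue=[False, True])
        out = impute_zeros(m)
        np.testing.assert_array_equal(out.values[0], [0, 1])


class TestLog2:
    def test_offset_one_maps_zero_to_zero(self):
        out = log2_transform(_matrix([[0, 3]]))
        np.testing.assert_allclose(out.values, [[0.0, 2.0]])

    def test_negative_rejected(self):
        m = _matrix([[1.0, 2.0]])
        m2 = m
        m2.values[0, 0] = 1.0
        with pytest.raises(ValueError):
            m_bad = _matrix([[1.0, 2.0]])
            m_bad.values[0, 0] = -0.5
            log2_transform(m_bad)


class TestBH:
    def _brute_force(self, p):
        """Literal step-up definition: q_i = min over j>=i of m p_(j)/j."""
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        sorted_p = p[order]
        for rank_i in range(m):
            q[order[rank_i]] = min(
                min(m * sorted_p[j] / (j + 1) for j in range(rank_i, m)), 1.0
            )
        return q

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 26))
            p = rng.random(n)
            np.testing.assert_allclose(bh_adjust(p), self._brute_force(p),
                                       rtol=1e-12)

    def test_matches_brute_force_large(self, rng):
        p = rng.random(1000)
        np.testing.assert_allclose(bh_adjust(p), self._brute_force(p), rtol=1e-12)

    def test_handles_ties_and_extremes(self):
        p = np.array([0.01, 0.01, 1.0, 0.0, 0.5])
        np.testing.assert_allclose(bh_adjust(p), self._brute_force(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, np.nan])

    def test_monotone_in_p(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestPrior:
    def test_moment_match_recovers_known_prior(self, rng):
        # sample variances drawn from the scaled-F model with known d0, s0
        d0, s0_sq, dg, n = 8.0, 2.5, 8, 20000
        s2 = s0_sq * stats.f.rvs(dg, d0, size=n, random_state=42)
        d0_hat, s0_hat = estimate_f_prior(s2, dg)
        assert d0_hat == pytest.approx(d0, rel=0.1)
        assert s0_hat == pytest.approx(s0_sq, rel=0.05)

    def test_trigamma_inverse_roundtrip(self):
        for y in [0.01, 0.5, 3.0, 40.0, 2000.0]:
            x = float(special.polygamma(1, y))
            assert normstats._trigamma_inverse(x) == pytest.approx(y, rel=1e-6)


def _roi_means_frame(rng, n1=5, n2=5, n_feat=40, shift=None):
    ctrl = rng.normal(10, 1, (n1, n_feat))
    isch = rng.normal(10, 1, (n2, n_feat))
    if shift is not None:
        isch = isch + shift
    rows = []
    data = {}
    for i in range(n1):
        data[f"c{i}"] = ctrl[i]
        rows.append((f"c{i}", "control", "15min", i))
    for i in range(n2):
        data[f"i{i}"] = isch[i]
        rows.append((f"i{i}", "ischemic", "15min", i))
    df = pd.DataFrame.from_dict(data, orient="index")
    df.columns = 100.0 + np.arange(n_feat)
    return df, StudyDesign(samples=rows)


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_pooled_t(self, rng):
        df, design = _roi_means_frame(rng)
        de = fit_moderated_de(df, design, prior_df=0.0, prior_var=1.0)
        X = df.to_numpy()
        ctrl, isch = X[:5], X[5:]
        s2 = (ctrl.var(axis=0, ddof=1) * 4 + isch.var(axis=0, ddof=1) * 4) / 8
        t_ref = (isch.mean(axis=0) - ctrl.mean(axis=0)) / np.sqrt(s2 * (2 / 5))
        np.testing.assert_allclose(de.table["t_mod"], t_ref, rtol=1e-10)
        p_ref = 2 * stats.t.sf(np.abs(t_ref), 8)
        np.testing.assert_allclose(de.table["p"], p_ref, rtol=1e-10)

    def test_infinite_prior_shrinks_to_common_variance(self, rng):
        df, design = _roi_means_frame(rng)
        de = fit_moderated_de(df, design, prior_df=1e9, prior_var=2.0)
        np.testing.assert_allclose(de.table["s2_post"], 2.0, rtol=1e-4)

    def test_moderation_shrinks_toward_prior(self, rng):
        df, design = _roi_means_frame(rng)
        de = fit_moderated_de(df, design)
        s2, s2_post = de.table["s2"].to_numpy(), de.table["s2_post"].to_numpy()
        # posterior variances lie between the observed and the prior
        lo = np.minimum(s2, de.s0_sq) - 1e-12
        hi = np.maximum(s2, de.s0_sq) + 1e-12
        assert np.all((s2_post >= lo) & (s2_post <= hi))

    def test_detects_large_shift(self, rng):
        shift = np.zeros(40)
        shift[:5] = 3.0
        df, design = _roi_means_frame(rng, shift=shift)
        de = fit_moderated_de(df, design)
        q = de.table["q"].to_numpy()
        assert np.all(q[:5] < 0.05)
        assert (q[5:] < 0.05).sum() <= 2

    def test_requires_two_samples_per_group(self, rng):
        df, design = _roi_means_frame(rng, n1=1, n2=5)
        with pytest.raises(ValueError, match="2 samples per group"):
            fit_moderated_de(df, design)


def test_moderated_t_matches_limma_reference(tmp_path, rng):
    """Cross-check the empirical-Bayes machinery against the R reference."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript is required for the limma cross-check")
    df, design = _roi_means_frame(rng, n_feat=120)
    de = fit_moderated_de(df, design)
    csv = tmp_path / "m.csv"
    # limma expects features x samples
    df.T.to_csv(csv)
    r_code = textwrap.dedent("""
        suppressMessages(library(limma))
        m <- read.csv("%s", row.names = 1, check.names = FALSE)
        groups <- ifelse(startsWith(colnames(m), "i"), "ischemic", "control")
        design <- model.matrix(~ 0 + factor(groups, c("control", "ischemic")))
        colnames(design) <- c("control", "ischemic")
        fit <- lmFit(as.matrix(m), design)
        fit <- contrasts.fit(fit, makeContrasts(ischemic - control, levels = design))
        fit <- eBayes(fit)
        out <- data.frame(t = fit$t[, 1], p = fit$p.value[, 1],
                          d0 = fit$df.prior, s0 = fit$s2.prior)
        write.csv(out, "%s")
    """ % (csv, tmp_path / "out.csv"))
    script = tmp_path / "limma_ref.R"
    script.write_text(r_code)
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
    np.testing.assert_allclose(de.table["t_mod"], ref["t"], rtol=1e-4)
    np.testing.assert_allclose(de.table["p"], ref["p"], rtol=1e-3)
    assert de.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-3)
    assert de.s0_sq == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-3)


class TestVolcano:
    def test_classification_thresholds(self, rng):
        df, design = _roi_means_frame(rng, n_feat=30,
                                      shift=np.linspace(-3, 3, 30))
        de = fit_moderated_de(df, design)
        v = volcano_table(de, fdr=0.05, fc=1.5)
        gate = np.log2(1.5)
        for _i, row in v.iterrows():
            if row["status"] == "up":
                assert row["q"] < 0.05 and row["log2FC"] >= gate
            elif row["status"] == "down":
                assert row["q"] < 0.05 and row["log2FC"] <= -gate
            else:
                assert row["q"] >= 0.05 or abs(row["log2FC"]) < gate

    def test_significance_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.0004) == "****"
        assert significance_stars(0.2) == ""
        assert sorted(t for t, _s in STAR_THRESHOLDS) == [
            0.0005, 0.001, 0.01, 0.05
        ]


class TestRoiMeans:
    def test_roi_mean_is_pixel_average(self, small_norm, small_spec):
        norm, _gt = small_norm
        rois = synthgen.default_rois(small_spec)
        roi = ROI("ROI1_ischemic", rois["ROI1_ischemic"])
        means = extract_roi_means([norm], roi)
        sel = [i for i, pix in enumerate(norm.pixels)
               if pix in rois["ROI1_ischemic"]]
        np.testing.assert_allclose(
            means.loc[norm.sample_id].to_numpy(),
            norm.values[sel].mean(axis=0),
        )

    def test_roi_outside_grid_rejected(self, small_norm):
        norm, _ = small_norm
        roi = ROI("bad", {(10_000, 3)})
        with pytest.raises(ValueError, match="outside grid"):
            extract_roi_means([norm], roi)
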