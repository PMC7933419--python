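"""Peak picking, consensus list, duplicate merge, extraction, filtering."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imsischemia import peakflow, synthgen
from imsischemia.iodata import ImagingDataset, PixelSpectrum, StudyDesign
from imsischemia.peakflow import (
    FeatureList,
    FeatureMatrix,
    PeakList,
    build_consensus_mzlist,
    extract_feature_matrix,
    filter_features,
    mad_noise,
    merge_duplicate_mz,
    pick_peaks,
)


class TestMadNoise:
    def test_matches_definition(self, rng):
        x = rng.normal(10, 3, 1001)
        med = np.median(x)
        assert mad_noise(x) == pytest.approx(
            1.4826 * np.median(np.abs(x - med))
        )

    def test_estimates_gaussian_sigma(self, rng):
        x = rng.normal(0, 5.0, 100_000)
        assert mad_noise(x) == pytest.approx(5.0, rel=0.02)


class TestPickPeaks:
    def test_local_maxima_with_halfwindow(self):
        mz = np.arange(100.0, 110.0, 1.0)
        inten = np.array([1, 5, 1, 1, 9, 1, 1, 3, 1, 1], dtype=float)
        pl = pick_peaks(PixelSpectrum(0, 0, mz, inten), snr_min=0.0, halfwindow=2)
        assert list(pl.mz) == [101.0, 104.0, 107.0]

    def test_halfwindow_zero_keeps_every_positive_point(self):
        mz = np.array([100.0, 200.0, 300.0])
        inten = np.array([4.0, 0.0, 2.0])
        pl = pick_peaks(PixelSpectrum(0, 0, mz, inten), snr_min=0.0, halfwindow=0)
        assert list(pl.mz) == [100.0, 300.0]

    def test_snr_gate(self):
        rng = np.random.default_rng(0)
        mz = np.linspace(100, 200, 201)
        inten = np.abs(rng.normal(0, 1.0, 201))
        inten[50] = 100.0  # one real peak far above the noise
        pl = pick_peaks(PixelSpectrum(0, 0, mz, inten), snr_min=10.0, halfwindow=2)
        assert mz[50] in pl.mz
        assert np.all(pl.snr >= 10.0)

    def test_empty_spectrum(self):
        pl = pick_peaks(PixelSpectrum(0, 0, np.empty(0), np.empty(0)))
        assert len(pl) == 0


class TestConsensus:
    def _lists(self, centers, jitter, n_lists, rng):
        out = []
        for i in range(n_lists):
            mz = np.sort(centers + rng.uniform(-jitter, jitter, len(centers)))
            out.append(PeakList(i, 0, mz, np.full(len(centers), 10.0),
                                np.full(len(centers), 99.0)))
        return out

    def test_recovers_planted_centers(self, rng):
        centers = np.array([100.0, 150.0, 500.0, 1500.0])
        lists = self._lists(centers, 0.0004, 10, rng)
        fl = build_consensus_mzlist(lists, tolerance_da=0.001, min_frequency=0.5)
        assert len(fl) == 4
        np.testing.assert_allclose(fl.mz, centers, atol=0.0005)

    def test_min_frequency_excludes_rare_peaks(self):
        common = PeakList(0, 0, np.array([100.0]), np.array([5.0]), np.array([9.0]))
        lists = [
            PeakList(i, 0, np.array([100.0, 200.0 + i]), np.array([5.0, 5.0]),
                     np.array([9.0, 9.0]))
            for i in range(1, 5)
        ] + [common] * 0
        # 200+i appear once each (frequency 1/4 < 0.5); 100.0 in all lists
        fl = build_consensus_mzlist(lists, min_frequency=0.5)
        assert list(fl.mz) == [100.0]

    def test_consensus_mz_is_intensity_weighted(self):
        a = PeakList(0, 0, np.array([100.0000]), np.array([1.0]), np.array([9.0]))
        b = PeakList(1, 0, np.array([100.0008]), np.array([3.0]), np.array([9.0]))
        fl = build_consensus_mzlist([a, b], tolerance_da=0.001, min_frequency=0.5)
        assert fl.mz[0] == pytest.approx((100.0 * 1 + 100.0008 * 3) / 4)


class TestMerge:
    def test_known_merge(self):
        fl = FeatureList(np.array([500.0, 500.005, 600.0]),
                         np.array([1.0, 3.0, 1.0]))
        merged = merge_duplicate_mz(fl, merge_ppm=20.0)
        assert len(merged) == 2
        # 500.005 is 10 ppm from 500.0 -> merged, provenance-weighted
        assert merged.mz[0] == pytest.approx((500.0 + 3 * 500.005) / 4)
        assert merged.mz[1] == 600.0

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=100.0, max_value=2000.0,
                      allow_nan=False, allow_infinity=False),
            min_size=1, max_size=40,
        )
    )
    def test_fuzzed_idempotent_and_gap_respecting(self, mzs):
        mz = np.unique(np.asarray(mzs, dtype=float))
        fl = FeatureList(mz, np.ones(mz.size))
        merged = merge_duplicate_mz(fl, merge_ppm=20.0)
        # no two survivors within the merge window
        if len(merged) > 1:
            gaps_ppm = np.diff(merged.mz) / merged.mz[:-1] * 1e6
            assert np.all(gaps_ppm > 20.0)
        # applying the merge again changes nothing
        again = merge_duplicate_mz(merged, merge_ppm=20.0)
        np.testing.assert_array_equal(again.mz, merged.mz)
        np.testing.assert_array_equal(again.provenance, merged.provenance)
        # total provenance is conserved
        assert merged.provenance.sum() == pytest.approx(fl.provenance.sum())


class TestExtraction:
    def _dataset(self):
        pixels = [
            PixelSpectrum(0, 0, np.array([500.0, 500.004, 800.0]),
                          np.array([10.0, 20.0, 5.0])),
            PixelSpectrum(1, 0, np.array([500.011, 800.0]),
                          np.array([7.0, 2.0])),
        ]
        return ImagingDataset(sample_id="s", pixels=pixels)

    def test_window_and_nearest_assignment(self):
        fl = FeatureList(np.array([500.0, 800.0]), np.array([1.0, 1.0]))
        fm = extract_feature_matrix(self._dataset(), fl, extract_ppm=20.0)
        # pixel 0: both 500.0 (0 ppm) and 500.004 (8 ppm) inside the window
        assert fm.values[0, 0] == pytest.approx(30.0)
        # pixel 1: 500.011 is 22 ppm away -> outside
        assert fm.values[1, 0] == 0.0
        assert fm.values[0, 1] == 5.0 and fm.values[1, 1] == 2.0

    def test_each_point_assigned_to_single_nearest_feature(self):
        # two features 12 ppm apart: a point between them goes to the nearer
        fl = FeatureList(np.array([1000.0, 1000.012]), np.array([1.0, 1.0]))
        ds = ImagingDataset(sample_id="s", pixels=[
            PixelSpectrum(0, 0, np.array([1000.004]), np.array([6.0])),
        ])
        fm = extract_feature_matrix(ds, fl, extract_ppm=20.0)
        assert fm.values[0, 0] == 6.0 and fm.values[0, 1] == 0.0

    def test_empty_feature_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_feature_matrix(
                self._dataset(), FeatureList(np.empty(0), np.empty(0))
            )


class TestFilter:
    def _matrices(self, values_by_sample, groups):
        fl = FeatureList(np.array([100.0, 200.0, 300.0]), np.ones(3))
        mats, rows = [], []
        for i, (vals, grp) in enumerate(zip(values_by_sample, groups)):
            sid = f"s{i}"
            mats.append(FeatureMatrix(
                sample_id=sid,
                pixels=[(x, 0) for x in range(len(vals))],
                features=fl,
                values=np.asarray(vals, dtype=float),
                tissue=np.ones(len(vals), dtype=bool),
                group=grp,
                timepoint="15min",
            ))
            rows.append((sid, grp, "15min", i))
        return mats, StudyDesign(samples=rows)

    def test_three_criteria(self):
        # feature 0: abundant everywhere -> kept
        # feature 1: present in only 1/10 pixels -> fails pixel fraction
        # feature 2: present but maximum abundance below threshold -> fails
        base = np.zeros((10, 3))
        base[:, 0] = 30000.0
        base[0, 1] = 25000.0
        base[:, 2] = 19999.0
        mats, design = self._matrices(
            [base] * 6, ["control"] * 3 + ["ischemic"] * 3
        )
        keep, stats = filter_features(mats, design)
        assert list(keep) == [True, False, False]
        assert stats["retained"] == 1
        assert stats["n_input"] == 3

    def test_group_support_criterion(self):
        present = np.zeros((10, 3))
        present[:, 0] = 30000.0
        mats, design = self._matrices(
            [present, present, np.zeros((10, 3)), np.zeros((10, 3)),
             np.zeros((10, 3)), np.zeros((10, 3))],
            ["control"] * 3 + ["ischemic"] * 3,
        )
        # feature 0 present in only 2 control samples < 3 required
        keep, _ = filter_features(mats, design, min_samples_per_group=3)
        assert not keep[0]
        keep, _ = filter_features(mats, design, min_samples_per_group=2)
        assert keep[0]


def test_end_to_end_consensus_recovers_phantom_features():
    """The picker + consensus + merge chain recovers the planted m/z axis."""
    spec = synthgen.PhantomSpec(
        grid=(16, 16), n_features=80, n_de_up=8, n_de_down=8,
        mass_jitter_ppm=3.0, dropout_rate=0.05, seed=31,
    )
    model = synthgen.build_model(spec)
    ds, _ = synthgen.generate_phantom(spec, "s", "control", "none")
    lists = [
        peakflow.pick_peaks(p, snr_min=0.0, halfwindow=0)
        for p in ds.pixels
        if ds.is_tissue(p.x, p.y)  # consensus built over the section itself
    ]
    fl = build_consensus_mzlist(lists, tolerance_da=0.001, min_frequency=0.5)
    fl = merge_duplicate_mz(fl, merge_ppm=20.0)
    ppm = np.array([
        np.min(np.abs(fl.mz - true_mz)) / true_mz * 1e6 for true_mz in model.mz
    ])
    # every planted feature is recovered well inside the 20 ppm extraction
    # window; sub-ppm accuracy holds for the vast majority.  The fixed
    # 0.001 Da grouping tolerance fragments sparse groups at high m/z
    # (3 ppm of 1800 Th is ~5 mDa), which bounds the attainable accuracy.
    assert np.all(ppm < 5.0)
    assert (ppm < 1.0).mean() >= 0.9
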