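"""Voxelwise decomposition, weighted histograms, Gaussian cluster
fitting, assignment, model-order selection and reproducibility."""

import warnings

import numpy as np
import pandas as pd
import pytest

from modespec import spectral
from modespec.clustering import (WeightedHistogram, assign_imfs,
                                 build_histogram, decompose_volume,
                                 fit_clusters, icc, order_selection)
from modespec.decompose import VMDConfig, vmd_decompose
from modespec.series import BOLDSeries
from modespec.synthetic import BrainPhantomConfig, make_brain_phantom, \
    TISSUE_LABELS


def _single_tone_volume(n_vox=10, n_t=128, dt=2.0, seed=0):
    """Tiny volume: one noise-free tone per voxel, distinct frequencies."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.03, 0.22, n_vox)
    t = dt * np.arange(n_t)
    bold = np.zeros((n_vox, 1, 1, n_t))
    for i, f in enumerate(freqs):
        bold[i, 0, 0] = np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    tissue = np.full((n_vox, 1, 1), TISSUE_LABELS["GM"], dtype=np.int16)
    return bold, tissue, freqs, dt


class TestDecomposeVolume:
    def test_single_tone_voxels_top_weight_frequency(self):
        bold, tissue, freqs, dt = _single_tone_volume()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dv = decompose_volume(bold, tissue, dt,
                                  VMDConfig(n_modes=2, alpha=500.0))
        df = 1.0 / (bold.shape[-1] * dt)
        top = dv.table.loc[dv.table.groupby("voxel")["weight"].idxmax()]
        got = top.sort_values("voxel")["freq"].to_numpy()
        assert np.max(np.abs(got - freqs)) < 2 * df

    def test_row_count_and_degenerate_skipping(self):
        bold, tissue, freqs, dt = _single_tone_volume()
        bold[3, 0, 0] = 5.0   # constant voxels (> 10% of the mask)
        bold[7, 0, 0] = -1.0
        with pytest.warns(RuntimeWarning, match="degenerate"):
            dv = decompose_volume(bold, tissue, dt,
                                  VMDConfig(n_modes=2, alpha=500.0))
        assert dv.n_skipped == 2
        assert dv.table["voxel"].nunique() == 8
        assert len(dv.table) == 8 * 2

    def test_voxel_triples_match_direct_recomputation(self):
        bold, tissue, freqs, dt = _single_tone_volume(n_vox=4)
        cfg = VMDConfig(n_modes=2, alpha=500.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dv = decompose_volume(bold, tissue, dt, cfg)
            for v in range(4):
                imfs = vmd_decompose(BOLDSeries(bold[v, 0, 0], dt=dt), cfg)
                specs = imfs.mode_spectra()
                powers = np.array([s.total_power for s in specs])
                coms = np.array([spectral.com_frequency(s) for s in specs])
                rows = dv.table[dv.table["voxel"] == v].sort_values("mode")
                np.testing.assert_allclose(rows["freq"], coms, atol=1e-9)
                np.testing.assert_allclose(rows["power"], powers, rtol=1e-9)
                np.testing.assert_allclose(rows["weight"],
                                           powers / powers.sum(), rtol=1e-9)

    def test_weights_sum_to_one_per_voxel(self, default_pipeline):
        sums = default_pipeline.decomposition.table.groupby("voxel")[
            "weight"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)


class TestHistogram:
    def _table(self, freqs, weights, tissue=2):
        n = len(freqs)
        return pd.DataFrame({
            "voxel": np.arange(n), "i": 0, "j": 0, "k": 0,
            "tissue": tissue, "roi": 0, "mode": 0,
            "freq": freqs, "power": 1.0, "weight": weights})

    def test_single_frequency_single_bin(self, default_pipeline):
        dv = default_pipeline.decomposition
        import dataclasses
        dv2 = dataclasses.replace(
            dv, table=self._table([0.1] * 5, [1.0] * 5))
        hist = build_histogram(dv2, bin_width=0.005)
        assert (hist.mass > 0).sum() == 1
        assert hist.total_mass == pytest.approx(5.0)

    def test_tissue_filters_partition_mass(self, default_pipeline):
        dv = default_pipeline.decomposition
        full = build_histogram(dv)
        gm = build_histogram(dv, tissue=TISSUE_LABELS["GM"])
        wm = build_histogram(dv, tissue=TISSUE_LABELS["WM"])
        csf = build_histogram(dv, tissue=TISSUE_LABELS["CSF"])
        assert gm.total_mass + wm.total_mass + csf.total_mass == \
            pytest.approx(full.total_mass, abs=1e-6)

    def test_mass_equals_contributing_voxels(self, default_pipeline):
        hist = default_pipeline.histogram
        assert hist.total_mass == pytest.approx(hist.n_voxels, abs=1e-6)

    def test_matches_brute_force_accumulation(self, default_pipeline):
        dv = default_pipeline.decomposition
        hist = build_histogram(dv, bin_width=0.005)
        brute = np.zeros_like(hist.mass)
        for _, row in dv.table.dropna(subset=["freq"]).iterrows():
            b = int(row["freq"] / 0.005)
            if b < brute.size:
                brute[b] += row["weight"]
        np.testing.assert_allclose(hist.mass, brute, atol=1e-9)

    def test_empty_selection_rejected(self, default_pipeline):
        with pytest.raises(ValueError):
            build_histogram(default_pipeline.decomposition, tissue=99)


def _hist_from_gaussians(params, bin_width=0.002, f_max=0.25, n=20000,
                         seed=0):
    """Sample a histogram from a Gaussian mixture (mass-weighted)."""
    rng = np.random.default_rng(seed)
    samples = []
    for amp, mu, sd in params:
        samples.append(rng.normal(mu, sd, int(n * amp)))
    samples = np.concatenate(samples)
    edges = bin_width * np.arange(int(np.ceil(f_max / bin_width)) + 1)
    mass, _ = np.histogram(samples, bins=edges)
    return WeightedHistogram(edges=edges, mass=mass.astype(float),
                             n_voxels=n, bin_width=bin_width)


class TestFitClusters:
    def test_single_gaussian_recovery(self):
        hist = _hist_from_gaussians([(1.0, 0.08, 0.01)])
        cl = fit_clusters(hist)
        assert cl.n_clusters == 1
        assert cl.centers[0] == pytest.approx(0.08, abs=0.002)
        width = cl.ranges[0].hi - cl.ranges[0].lo
        assert width == pytest.approx(2 * 1.96 * 0.01, rel=0.1)
        assert cl.labels == ["IMF1"]

    def test_two_gaussian_mixture_vs_moment_oracle(self):
        hist = _hist_from_gaussians([(0.5, 0.03, 0.005), (0.5, 0.20, 0.01)])
        cl = fit_clusters(hist)
        assert cl.n_clusters == 2
        # weighted-moment oracle on the separated halves
        f = hist.centers
        for i, (lo, hi) in enumerate([(0.0, 0.1), (0.1, 0.25)]):
            sel = (f >= lo) & (f < hi)
            mu = np.sum(f[sel] * hist.mass[sel]) / hist.mass[sel].sum()
            assert cl.centers[i] == pytest.approx(mu, abs=0.005)
        assert cl.labels == ["IMF2", "IMF1"]

    def test_default_phantom_four_clusters(self, phantom_pipelines):
        truth = (0.028, 0.080, 0.15, 0.22)
        for cfg, res in phantom_pipelines:
            assert res.clusters.n_clusters == 4
            for got, true in zip(res.clusters.centers, truth):
                assert got == pytest.approx(true, abs=0.01)

    def test_cluster_centers_unbiased_across_seeds(self, phantom_pipelines):
        centers = np.array([res.clusters.centers
                            for _, res in phantom_pipelines])
        mean = centers.mean(axis=0)
        # lowest two clusters: tighter tolerance; highest two: looser
        assert abs(mean[0] - 0.028) < 0.005
        assert abs(mean[1] - 0.080) < 0.005
        assert abs(mean[2] - 0.15) < 0.01
        assert abs(mean[3] - 0.22) < 0.01

    def test_ranges_are_95pct_area_intervals(self):
        hist = _hist_from_gaussians([(1.0, 0.1, 0.015)])
        cl = fit_clusters(hist)
        band = cl.ranges[0]
        np.testing.assert_allclose(
            [band.lo, band.hi],
            [cl.centers[0] - 1.96 * cl.sds[0],
             cl.centers[0] + 1.96 * cl.sds[0]])

    def test_empty_histogram_rejected(self):
        hist = WeightedHistogram(edges=np.arange(11) * 0.025,
                                 mass=np.zeros(10), n_voxels=0,
                                 bin_width=0.025)
        with pytest.raises(ValueError):
            fit_clusters(hist)


class TestAssignIMFs:
    @pytest.fixture(scope="class")
    def clusters(self):
        hist = _hist_from_gaussians([(0.4, 0.03, 0.004), (0.6, 0.15, 0.01)])
        return fit_clusters(hist)

    def _table(self, freqs):
        n = len(freqs)
        return pd.DataFrame({"voxel": np.arange(n), "i": 0, "j": 0, "k": 0,
                             "tissue": 2, "roi": 0, "mode": 0, "freq": freqs,
                             "power": 1.0, "weight": 1.0})

    def test_frequency_at_center_assigned_there(self, clusters):
        out = assign_imfs(self._table(list(clusters.centers)), clusters)
        assert list(out["cluster"]) == [0, 1]

    def test_frequency_outside_all_ranges_unassigned(self, clusters):
        out = assign_imfs(self._table([0.09]), clusters)
        assert out["cluster"].iloc[0] == -1
        assert out["cluster_label"].iloc[0] == "unassigned"

    def test_matches_brute_force_rule_on_random_frequencies(self, clusters):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0, 0.25, 1000)
        out = assign_imfs(self._table(freqs), clusters)
        for f, got in zip(freqs, out["cluster"]):
            candidates = [ci for ci, b in enumerate(clusters.ranges)
                          if b.lo <= f <= b.hi]
            if not candidates:
                expected = -1
            else:
                expected = min(candidates,
                               key=lambda ci: abs(f - clusters.centers[ci]))
            assert got == expected


class TestOrderSelection:
    @pytest.fixture(scope="class")
    def cohort(self):
        subjects = []
        for s in range(2):
            runs = []
            for r in range(2):
                cfg = BrainPhantomConfig(shape=(10, 10, 6), seed=31 + 10 * s + r,
                                         n_frames=160, n_discard=10)
                ph = make_brain_phantom(cfg)
                runs.append((ph.analyzed(), ph.tissue, ph.tr))
            subjects.append(runs)
        return subjects

    def test_recommends_generating_mode_count(self, cohort):
        report = order_selection(cohort, candidate_K=(2, 4, 5, 8),
                                 vmd_config=VMDConfig(alpha=1000.0))
        assert report.recommended_K == 4
        assert set(report.metrics["K"]) == {2, 4, 5, 8}
        assert ((report.metrics["manifestation_pct"] >= 0)
                & (report.metrics["manifestation_pct"] <= 100)).all()

    def test_duplicated_runs_have_unit_correlation(self, cohort):
        dup = [[runs[0], runs[0]] for runs in cohort]
        report = order_selection(dup, candidate_K=(4,),
                                 vmd_config=VMDConfig(alpha=1000.0))
        assert report.metrics["run_correlation"].iloc[0] == \
            pytest.approx(1.0)

    def test_metrics_recomputable_from_per_run_table(self, cohort):
        report = order_selection(cohort, candidate_K=(4,),
                                 vmd_config=VMDConfig(alpha=1000.0))
        per_run = report.per_run
        # independent recomputation of the center-sd metric
        sub = per_run[per_run["K"] == 4]
        counts = sub.groupby(["subject", "run"]).size()
        modal = int(counts.mode().iloc[0])
        templ = [np.sort(sub[(sub["subject"] == s) & (sub["run"] == r)]
                         ["center"].to_numpy())
                 for (s, r) in counts[counts == modal].index]
        template = np.mean(templ, axis=0)
        cols = []
        for (s, r) in counts.index:
            cent = sub[(sub["subject"] == s)
                       & (sub["run"] == r)]["center"].to_numpy()
            matched = np.full(template.size, np.nan)
            used = set()
            for ti in np.argsort(template):
                d = np.abs(cent - template[ti])
                for ci in np.argsort(d):
                    if ci not in used and d[ci] <= 0.02:
                        matched[ti] = cent[ci]
                        used.add(ci)
                        break
            cols.append(matched)
        arr = np.vstack(cols)
        expected = float(np.nanmean(np.nanstd(arr, axis=0)))
        assert report.metrics["center_sd"].iloc[0] == \
            pytest.approx(expected, rel=1e-9)

    def test_too_few_subjects_rejected(self, cohort):
        with pytest.raises(ValueError):
            order_selection(cohort[:1], candidate_K=(4,))


class TestICC:
    def test_identical_vectors_give_one(self):
        x = np.array([0.02, 0.08, 0.15, 0.22, 0.05])
        assert icc(x, x) == pytest.approx(1.0)

    def test_variance_components_match_closed_form(self):
        rng = np.random.default_rng(6)
        n = 400
        subj = rng.normal(0, 3.0, n)       # between-subject variance 9
        x1 = subj + rng.normal(0, 1.0, n)  # within variance 1
        x2 = subj + rng.normal(0, 1.0, n)
        val = icc(x1, x2)
        assert val == pytest.approx(0.9, abs=0.03)

    def test_reversed_run_non_positive(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.normal(0, 3.0, 20))
        assert icc(x, x[::-1]) <= 0

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        x1 = rng.normal(0, 1, 12)
        x2 = x1 + rng.normal(0, 0.5, 12)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(12), 2),
            "raters": np.repeat(["a", "b"], 12),
            "score": np.concatenate([x1, x2])})
        ref = pingouin.intraclass_corr(df, targets="targets",
                                       raters="raters", ratings="score")
        ref_val = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]),
                          "ICC"].iloc[0]
        assert icc(x1, x2) == pytest.approx(ref_val, abs=1e-9)

    def test_constant_data_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(icc(np.ones(5), np.ones(5)))

    def test_phantom_run_pairs_highly_reproducible(self, phantom_pipelines):
        """Cluster centers from repeated phantom 'sessions' (seed pairs as
        subjects) agree with near-unit intraclass correlation."""
        centers = np.array([res.clusters.centers
                            for _, res in phantom_pipelines])
        # treat alternating seeds as run1/run2 of 5 subjects, pooled clusters
        run1 = centers[0::2].ravel()
        run2 = centers[1::2].ravel()
        assert icc(run1, run2) > 0.95
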