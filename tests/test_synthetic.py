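import math

import numpy as np
import pandas as pd
import pytest

from nitrosip.errors import ValidationError
from nitrosip import kinetics as kin
from nitrosip import sip
from nitrosip import synthetic as syn
from nitrosip.io import incubations_to_frame, rois_to_frame


def scenario(**kw):
    defaults = dict(true_rate=1.0, ambient_substrate=0.0, tracer_added=100.0,
                    tracer_purity=1.0, noise_sd=0.0,
                    timepoints=[0, 12, 24.0], seed=0)
    defaults.update(kw)
    return syn.IncubationScenario(**defaults)


class TestGenIncubation:
    def test_noiseless_line(self):
        series = syn.gen_incubation(scenario())[0]
        assert np.allclose(series.product_15N_nM, [0.0, 0.5, 1.0])

    def test_labeling_fraction_applied(self):
        s = scenario(ambient_substrate=100.0, tracer_purity=0.98)
        series = syn.gen_incubation(s)[0]
        # f = 100*0.98/200 = 0.49
        assert np.allclose(series.product_15N_nM, 0.49 * np.array([0, 0.5, 1.0]))

    def test_null_model_slopes_centered_on_zero(self):
        slopes = []
        for seed in range(300):
            series = syn.gen_incubation(
                scenario(true_rate=0.0, noise_sd=0.1,
                         timepoints=[0, 3, 6, 12, 24], seed=seed))[0]
            slopes.append(kin.fit_slope(series).slope)
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(mean) < 3 * se

    def test_determinism_byte_identical(self):
        s = scenario(noise_sd=0.2, seed=7, n_replicates=3)
        a = incubations_to_frame(syn.gen_incubation(s)).to_csv(sep="\t")
        b = incubations_to_frame(syn.gen_incubation(s)).to_csv(sep="\t")
        assert a.encode() == b.encode()

    def test_truncation_flagged(self):
        s = scenario(true_rate=0.0, noise_sd=5.0, seed=1,
                     timepoints=list(range(0, 25, 3)))
        series = syn.gen_incubation(s)[0]
        assert np.all(series.product_15N_nM >= 0)
        assert series.truth["truncated"].any()

    def test_leak_adds_combined_series(self):
        series = syn.gen_incubation(
            scenario(urea_to_ammonium_leak_rate=0.5))[0]
        assert series.combined_15N_nM is not None
        # combined = nitrite + leak-derived ammonium
        assert np.allclose(series.combined_15N_nM - series.product_15N_nM,
                           0.5 * np.array([0, 0.5, 1.0]))

    def test_invalid_scenarios(self):
        with pytest.raises(ValidationError):
            scenario(timepoints=[0, 12])
        with pytest.raises(ValidationError):
            scenario(noise_sd=-1)
        with pytest.raises(ValidationError):
            scenario(true_rate=-1)
        with pytest.raises(ValidationError):
            scenario(tracer_purity=0.0)

    def test_recovery_monte_carlo(self):
        # estimator bias < 2 SE over replicates; first sample late enough
        # that zero-truncation of the noise never triggers
        s = scenario(true_rate=2.0, noise_sd=0.05,
                     timepoints=[3, 6, 12, 18, 24], n_replicates=300, seed=5)
        rates = [kin.estimate_rate(x, noise_sd=0.05).rate
                 for x in syn.gen_incubation(s)]
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(mean - 2.0) < 2 * se


class TestGenCells:
    def test_background_distribution(self):
        scen = syn.CellPopulationScenario(
            n_cells=0, n_background_cells=100, true_ape_mean=0.0,
            true_ape_sd=0.0, mean_total_counts_per_plane=5000,
            n_planes=20, seed=0)
        rois = syn.gen_cells(scen)
        assert len(rois) == 100
        assert all(r.truth["is_background"] for r in rois)
        ratios = [sip.accumulate_ratio(r) for r in rois]
        assert np.mean(ratios) == pytest.approx(3.7e-3, rel=0.05)

    def test_zero_ape_cells_sit_at_natural_abundance(self):
        scen = syn.CellPopulationScenario(
            n_cells=200, true_ape_mean=0.0, true_ape_sd=0.0,
            mean_total_counts_per_plane=5000, n_planes=20, seed=1)
        ratios = [sip.accumulate_ratio(r) for r in syn.gen_cells(scen)]
        assert np.mean(ratios) == pytest.approx(3.7e-3, rel=0.02)

    def test_high_counts_recover_ape_within_3_sigma(self):
        scen = syn.CellPopulationScenario(
            n_cells=1000, true_ape_mean=3.0, true_ape_sd=0.0,
            mean_total_counts_per_plane=5000, n_planes=30, seed=2)
        ctx = sip.SipContext()
        n_ok = 0
        for roi in syn.gen_cells(scen):
            ratio = sip.accumulate_ratio(roi)
            sigma = ratio * sip.poisson_relative_error(roi)
            true_ratio = roi.truth["true_ratio"]
            if abs(ratio - true_ratio) < 3 * sigma:
                n_ok += 1
        assert n_ok >= 990

    def test_determinism(self):
        scen = syn.CellPopulationScenario(
            n_cells=5, true_ape_mean=1.0, true_ape_sd=0.5,
            mean_total_counts_per_plane=1000, seed=9)
        a = rois_to_frame(syn.gen_cells(scen))
        b = rois_to_frame(syn.gen_cells(scen))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid(self):
        with pytest.raises(ValidationError):
            syn.CellPopulationScenario(n_cells=1, true_ape_mean=1,
                                       true_ape_sd=0,
                                       mean_total_counts_per_plane=0)
        with pytest.raises(ValidationError):
            syn.CellPopulationScenario(n_cells=1, true_ape_mean=1,
                                       true_ape_sd=0,
                                       mean_total_counts_per_plane=10,
                                       n_planes=0)


class TestGenHits:
    def test_all_true_all_accepted(self):
        from nitrosip import genes
        scen = syn.HitTableScenario(
            n_true=50, n_false=0,
            custom_score_true=(200.0, 0.0), global_score_true=(150.0, 0.0),
            identity_true=(95.0, 0.0), seed=0)
        custom, glob, truth = syn.gen_hits(scen)
        cls = genes.bsr_classify(custom, glob)
        assert cls["accepted"].all()

    def test_all_false_all_rejected(self):
        from nitrosip import genes
        scen = syn.HitTableScenario(
            n_true=0, n_false=50,
            custom_score_false=(150.0, 0.0), global_score_false=(300.0, 0.0),
            identity_false=(95.0, 0.0), seed=0)
        custom, glob, _ = syn.gen_hits(scen)
        cls = genes.bsr_classify(custom, glob)
        assert not cls["accepted"].any()

    def test_precision_recall_match_threshold_oracle(self):
        from nitrosip import genes
        scen = syn.HitTableScenario(n_true=200, n_false=100, seed=3,
                                    p_global_hit=0.9)
        custom, glob, truth = syn.gen_hits(scen)
        cls = genes.bsr_classify(custom, glob).set_index("read_id")
        gbest = glob.groupby("qseqid")["bitscore"].max()
        for row in custom.itertuples():
            g = gbest.get(row.qseqid)
            bsr_ok = True if g is None else (row.bitscore / g) >= 0.9
            expected = (row.bitscore >= 100 and row.pident >= 90 and bsr_ok)
            assert bool(cls.loc[row.qseqid, "accepted"]) == expected

    def test_truth_labels_recorded(self):
        scen = syn.HitTableScenario(n_true=7, n_false=3, seed=1)
        _, _, truth = syn.gen_hits(scen)
        assert truth["is_true"].sum() == 7
        assert len(truth) == 10


class TestGenNutrients:
    def test_zero_spread_equals_median(self):
        cfg = {"R": syn.RegionNutrientConfig(
            median_ammonium_nM=100.0, median_urea_nM=50.0, sigma=0.0,
            ammonium_lod_nM=1.0, urea_lod_nM=1.0, n_samples=10)}
        df = syn.gen_nutrients(cfg, seed=0)
        assert (df["ammonium_nM"] == 100.0).all()
        assert (df["urea_nM"] == 50.0).all()

    def test_equal_medians_symmetric_fraction(self):
        cfg = {"R": syn.RegionNutrientConfig(
            median_ammonium_nM=100.0, median_urea_nM=100.0, sigma=0.5,
            ammonium_lod_nM=0.001, urea_lod_nM=0.001, n_samples=5000)}
        df = syn.gen_nutrients(cfg, seed=1)
        frac = df["truth_urea_nM"] / (df["truth_urea_nM"]
                                      + df["truth_ammonium_nM"])
        assert frac.mean() == pytest.approx(0.5, abs=0.01)

    def test_below_detection_fraction_nonzero(self):
        # median barely above the LOD: a sizable share must be censored
        cfg = {"BS": syn.RegionNutrientConfig(
            median_ammonium_nM=51.0, median_urea_nM=130.0, sigma=0.6,
            ammonium_lod_nM=42.7, urea_lod_nM=27.6, n_samples=2000)}
        df = syn.gen_nutrients(cfg, seed=2)
        share = df["ammonium_below_lod"].mean()
        assert 0.1 < share < 0.9
        # censored values are stored at the LOD
        assert (df.loc[df["ammonium_below_lod"], "ammonium_nM"] == 42.7).all()

    def test_median_recovery(self):
        df = syn.gen_nutrients(seed=3)
        ag = df[df["region"] == "Angola_Gyre"]
        med = ag["truth_urea_nM"].median()
        assert med == pytest.approx(52.0, rel=0.35)

    def test_stream_independence(self):
        # adding a generator draw elsewhere must not change this table
        a = syn.gen_nutrients(seed=4)
        _ = syn.gen_cells(syn.CellPopulationScenario(
            n_cells=3, true_ape_mean=1, true_ape_sd=0,
            mean_total_counts_per_plane=100, seed=4))
        b = syn.gen_nutrients(seed=4)
        pd.testing.assert_frame_equal(a, b)
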