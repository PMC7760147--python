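"""Generator contracts: determinism, planted truth, null behaviour, calibration."""

import numpy as np
import pandas as pd
import pytest

from mirtargetome import filter_probes, normalize_to_rpm, quantile_normalize
from mirtargetome.seedscan import scan_transcript, seed_patterns
from mirtargetome.synthetic import (
    GfpSimConfig,
    LuciferaseSimConfig,
    RipChipSimConfig,
    SmallRnaSimConfig,
    TranscriptomeSimConfig,
    simulate_gfp_assay,
    simulate_luciferase,
    simulate_ripchip_dataset,
    simulate_smallrna_counts,
    simulate_transcriptome,
)


class TestDeterminism:
    def test_smallrna_counts_identical_for_same_seed(self):
        a, ta = simulate_smallrna_counts(SmallRnaSimConfig(seed=5))
        b, tb = simulate_smallrna_counts(SmallRnaSimConfig(seed=5))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert ta.de_mirnas == tb.de_mirnas
        c, _ = simulate_smallrna_counts(SmallRnaSimConfig(seed=6))
        assert not a.counts.equals(c.counts)

    def test_ripchip_identical_for_same_seed(self):
        a, _ = simulate_ripchip_dataset(
            RipChipSimConfig(n_probes=100, n_targets=10, seed=5)
        )
        b, _ = simulate_ripchip_dataset(
            RipChipSimConfig(n_probes=100, n_targets=10, seed=5)
        )
        pd.testing.assert_frame_equal(a.signal, b.signal)
        pd.testing.assert_frame_equal(a.present, b.present)

    def test_transcriptome_identical_for_same_seed(self, mir378a):
        cfg = TranscriptomeSimConfig(
            n_transcripts=5, planted_sites=[("8mer", "3UTR")], seed=5
        )
        a, ta = simulate_transcriptome(cfg, mir378a)
        b, tb = simulate_transcriptome(cfg, mir378a)
        assert {k: v.sequence for k, v in a.items()} == {
            k: v.sequence for k, v in b.items()
        }
        assert ta.site_positions == tb.site_positions

    def test_gfp_and_luciferase_identical_for_same_seed(self):
        a, _ = simulate_gfp_assay(GfpSimConfig(seed=5))
        b, _ = simulate_gfp_assay(GfpSimConfig(seed=5))
        assert all(
            np.array_equal(x.pct_gfp, y.pct_gfp) for x, y in zip(a, b)
        )
        la = simulate_luciferase(LuciferaseSimConfig(seed=5))
        lb = simulate_luciferase(LuciferaseSimConfig(seed=5))
        pd.testing.assert_frame_equal(la, lb)


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            SmallRnaSimConfig(n_mirnas=0)
        with pytest.raises(ValueError):
            SmallRnaSimConfig(n_de=10, n_mirnas=5)
        with pytest.raises(ValueError):
            SmallRnaSimConfig(dispersion=0.0)
        with pytest.raises(ValueError):
            RipChipSimConfig(frac_absent=1.2)
        with pytest.raises(ValueError, match="invert"):
            RipChipSimConfig(target_ip_log2_effect=-1.0)
        with pytest.raises(ValueError):
            TranscriptomeSimConfig(length_range=(40, 100))
        with pytest.raises(ValueError):
            LuciferaseSimConfig(n_replicates=1)


class TestSmallRnaGenerator:
    def test_null_case_no_planted_truth(self):
        cm, truth = simulate_smallrna_counts(
            SmallRnaSimConfig(n_mirnas=200, n_de=0, seed=1)
        )
        assert truth.de_mirnas == {}
        nm = normalize_to_rpm(cm)
        g = nm.groups
        logfc = np.log2(
            (nm.rpm.loc[:, g == "BL"].mean(axis=1) + 1)
            / (nm.rpm.loc[:, g == "GCB"].mean(axis=1) + 1)
        )
        # group means differ only by sampling noise
        assert abs(logfc.mean()) < 0.2

    def test_counts_are_nonnegative_integers(self):
        cm, _ = simulate_smallrna_counts(SmallRnaSimConfig(n_mirnas=100, seed=2))
        vals = cm.counts.to_numpy()
        assert (vals >= 0).all() and np.allclose(vals, vals.astype(int))

    def test_planted_truth_resolvable(self):
        cm, truth = simulate_smallrna_counts(SmallRnaSimConfig(seed=3))
        assert set(truth.de_mirnas) <= set(cm.counts.index)
        assert len(truth.de_mirnas) == 50

    def test_planted_log2fc_recovered_on_rpm_scale(self):
        # Monte-Carlo check against the generator's own expectation: the mean
        # measured log2FC of the planted set stays within +-0.3 of the target
        means = []
        for seed in range(20):
            cm, truth = simulate_smallrna_counts(
                SmallRnaSimConfig(
                    n_mirnas=500, n_de=50, de_log2fc=2.0, n_per_group=(4, 3),
                    library_size_mean=2e6, seed=seed,
                )
            )
            nm = normalize_to_rpm(cm)
            g = nm.groups
            de = list(truth.de_mirnas)
            m1 = nm.rpm.loc[de, g == "BL"].mean(axis=1)
            m2 = nm.rpm.loc[de, g == "GCB"].mean(axis=1)
            means.append(float(np.log2(m1 / m2).mean()))
        assert abs(np.mean(means) - 2.0) < 0.3


class TestRipChipGenerator:
    def test_null_case_fc_near_one(self):
        cfg = RipChipSimConfig(n_probes=500, n_targets=0, seed=3)
        ds, truth = simulate_ripchip_dataset(cfg)
        assert truth.target_probes == {}
        from mirtargetome import compute_enrichment

        et = compute_enrichment(ds)
        tab = et.table
        num = tab[tab["condition"] == cfg.condition_high].set_index("probe")["ratio"]
        den = tab[tab["condition"] == cfg.condition_low].set_index("probe")["ratio"]
        assert abs(np.log2(num / den).mean()) < 0.05

    def test_all_absent_filters_everything(self):
        ds, _ = simulate_ripchip_dataset(
            RipChipSimConfig(n_probes=200, n_targets=0, frac_absent=1.0, seed=1)
        )
        assert filter_probes(quantile_normalize(ds)).retained == []

    def test_signals_positive_and_flags_planted(self):
        cfg = RipChipSimConfig(n_probes=400, frac_absent=0.1, seed=8, n_targets=20)
        ds, truth = simulate_ripchip_dataset(cfg)
        assert (ds.signal.to_numpy() > 0).all()
        for p in truth.absent_probes:
            assert not ds.present.loc[p].all()  # absent in >=1 sample
        for p in truth.inconsistent_probes:
            ratios = []
            for (_c, _f), grp in ds.samples.groupby(["condition", "fraction"]):
                sub = ds.signal.loc[p, list(grp.index)]
                ratios.append(sub.max() / sub.min())
            assert max(ratios) >= 2.0  # duplicate ratio >=2 in some pair

    def test_planted_targets_exceed_fc_two_before_filtering(self):
        # generator expectation, 20 seeds: >=90% of planted targets show a
        # cross-condition IP/T fold change above 2 before any noise filtering
        from mirtargetome import compute_enrichment

        fractions = []
        for seed in range(20):
            cfg = RipChipSimConfig(
                n_probes=2000, n_targets=100, target_ip_log2_effect=2.0,
                baseline_sd=0.2, replicate_sd=0.1, seed=seed,
            )
            ds, truth = simulate_ripchip_dataset(cfg)
            et = compute_enrichment(ds, floor_condition=cfg.condition_low)
            tab = et.table
            num = tab[tab["condition"] == cfg.condition_high].set_index("probe")
            den = tab[tab["condition"] == cfg.condition_low].set_index("probe")
            fc = num["ratio"] / den["floored_ratio"]
            fractions.append(float((fc[list(truth.target_probes)] > 2.0).mean()))
        assert min(fractions) >= 0.9


class TestTranscriptomeGenerator:
    REQUESTS = [
        ("8mer", "3UTR"),
        ("7mer-m8", "CDS"),
        ("7mer-A1", "5UTR"),
        ("8mer", "noncoding"),
        ("7mer-m8", "3UTR"),
    ]

    def test_pattern_present_at_recorded_coordinate(self, mir378a):
        txs, truth = simulate_transcriptome(
            TranscriptomeSimConfig(n_transcripts=8, planted_sites=self.REQUESTS,
                                   seed=4),
            mir378a,
        )
        patterns = seed_patterns(mir378a)
        for tx_id, pos, site_type, _region in truth.site_positions:
            pat = patterns.pattern(site_type)
            assert txs[tx_id].sequence[pos : pos + len(pat)] == pat

    def test_noncoding_request_makes_noncoding_transcript(self, mir378a):
        txs, truth = simulate_transcriptome(
            TranscriptomeSimConfig(
                n_transcripts=2, planted_sites=[("8mer", "noncoding")], seed=2
            ),
            mir378a,
        )
        assert txs["tx0000"].noncoding
        assert truth.site_positions[0][3] == "3UTR"  # reporting convention

    def test_scanner_recovers_planted_sites_exactly(self, mir378a):
        patterns = seed_patterns(mir378a)
        for seed in range(5):
            txs, truth = simulate_transcriptome(
                TranscriptomeSimConfig(
                    n_transcripts=8, planted_sites=self.REQUESTS, seed=100 + seed
                ),
                mir378a,
            )
            for tx_id, pos, site_type, region in truth.site_positions:
                matches = scan_transcript(txs[tx_id], patterns)
                assert any(
                    m.start == pos and m.site_type == site_type and m.region == region
                    for m in matches
                )

    def test_scan_is_superset_of_planted_and_equals_oracle(self, mir378a):
        from test_seedscan import naive_scan

        patterns = seed_patterns(mir378a)
        txs, truth = simulate_transcriptome(
            TranscriptomeSimConfig(n_transcripts=8, planted_sites=self.REQUESTS,
                                   seed=7),
            mir378a,
        )
        planted = {(t, p) for t, p, _s, _r in truth.site_positions}
        found = set()
        for tx in txs.values():
            matches = scan_transcript(tx, patterns)
            got = sorted((m.start, m.site_type) for m in matches)
            assert got == naive_scan(tx.sequence, patterns)
            found |= {(tx.id, m.start) for m in matches}
        assert planted <= found

    def test_too_many_requests_rejected(self):
        with pytest.raises(ValueError, match="transcript"):
            TranscriptomeSimConfig(n_transcripts=1,
                                   planted_sites=[("8mer", "CDS")] * 2)


class TestGfpGenerator:
    def test_noiseless_exact_exponential(self):
        cfg = GfpSimConfig(
            slope_diffs={"x": -0.1}, replicate_intercept_sd=0.0, noise_sd=0.0,
            seed=0,
        )
        series, _ = simulate_gfp_assay(cfg)
        t = np.asarray(cfg.days, float) - cfg.days[0]
        for s in series:
            slope = cfg.control_slope + (cfg.slope_diffs.get(s.construct, 0.0))
            assert np.allclose(s.pct_gfp, cfg.baseline_pct * np.exp(slope * t))

    def test_truth_records_slope_differences(self):
        cfg = GfpSimConfig(slope_diffs={"a": -0.2, "b": -0.05}, seed=1)
        _, truth = simulate_gfp_assay(cfg)
        assert truth.gfp_slope_diff == {"a": -0.2, "b": -0.05}

    def test_strong_slope_difference_detected(self):
        # power check: slope difference -0.2/day at small noise gives
        # interaction p < 0.001 in >=95% of 100 seeds
        from mirtargetome import fit_growth_mixed_model

        hits = 0
        for seed in range(100):
            cfg = GfpSimConfig(
                slope_diffs={"x": -0.2}, noise_sd=0.02,
                replicate_intercept_sd=0.02, seed=2000 + seed,
            )
            series, _ = simulate_gfp_assay(cfg)
            fit = fit_growth_mixed_model(series, cfg.reference_construct)
            hits += fit.interaction["x"][2] < 0.001
        assert hits >= 95


class TestLuciferaseGenerator:
    def test_one_value_per_replicate_after_averaging(self):
        from mirtargetome import rl_fl_ratios

        df = simulate_luciferase(LuciferaseSimConfig(n_replicates=3, seed=0))
        for arm in ("control", "mimic"):
            assert len(rl_fl_ratios(df[df["arm"] == arm])) == 3

    def test_suppression_scales_rl_only_in_experimental_arm(self):
        df = simulate_luciferase(
            LuciferaseSimConfig(suppression=0.25, duplicate_cv=0.0,
                                replicate_sd=0.0, seed=0)
        )
        ctrl = df[df["arm"] == "control"]
        mimic = df[df["arm"] == "mimic"]
        assert np.allclose(mimic["RL"].to_numpy(), 0.25 * ctrl["RL"].to_numpy())
        assert np.allclose(mimic["FL"].to_numpy(), ctrl["FL"].to_numpy())
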