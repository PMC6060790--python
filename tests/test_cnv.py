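"""CNV pipeline: log2 ratios, binning, baseline, segmentation, event calls, export."""

import numpy as np
import pandas as pd
import pytest

from methyldx.array_model import ProbeManifest, SampleIntensities, build_reference
from methyldx.cnv import (
    BinConfig,
    BinProfile,
    EventThresholds,
    Segment,
    bin_profile,
    build_bins,
    call_events,
    export_igv,
    export_seg,
    fit_baseline,
    probe_log2,
    read_igv,
    segment_profile,
)
from methyldx.synthetic import CopyNumberTruth, simulate_tumor


def _profile_from_values(values, chrom="1", sample_id="s"):
    n = len(values)
    bins = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, list) else [chrom] * n,
            "start": np.arange(n) * 1000,
            "end": np.arange(1, n + 1) * 1000,
            "probe_count": 10,
            "log2_value": np.asarray(values, float),
        }
    )
    return BinProfile(sample_id, bins)


class TestProbeLog2:
    def test_panel_member_is_near_zero(self, manifest, panel):
        lr = probe_log2(panel.samples[0], panel)
        ok = ~np.isnan(lr)
        assert np.mean(np.abs(lr[ok])) < 0.1
        assert abs(np.median(lr[ok])) < 0.02

    def test_doubled_sample_shifts_by_one_after_scaling_off(self, manifest, panel):
        s = panel.samples[0]
        doubled = SampleIntensities("x2", s.manifest, s.meth * 2, s.unmeth * 2)
        lr1 = probe_log2(s, panel, scaling="none")
        lr2 = probe_log2(doubled, panel, scaling="none")
        ok = ~np.isnan(lr1)
        np.testing.assert_allclose(lr2[ok], lr1[ok] + 1.0, atol=1e-9)

    def test_median_match_scaling_removes_global_factor(self, manifest, panel):
        s = panel.samples[0]
        doubled = SampleIntensities("x2", s.manifest, s.meth * 2, s.unmeth * 2)
        np.testing.assert_allclose(
            probe_log2(doubled, panel)[~np.isnan(probe_log2(s, panel))],
            probe_log2(s, panel)[~np.isnan(probe_log2(s, panel))],
            atol=1e-9,
        )

    def test_matches_loop_oracle(self, rng):
        man = ProbeManifest(
            np.array([f"p{i}" for i in range(50)], dtype=object),
            np.array(["1"] * 50, dtype=object),
            np.arange(50) * 100,
        )
        samples = [
            SampleIntensities(f"r{k}", man, rng.uniform(100, 200, 50), rng.uniform(100, 200, 50))
            for k in range(3)
        ]
        panel = build_reference(samples)
        s = SampleIntensities("t", man, rng.uniform(100, 200, 50), rng.uniform(100, 200, 50))
        lr = probe_log2(s, panel)
        comb = s.meth + s.unmeth
        scale = np.median(panel.per_probe_reference) / np.median(comb)
        oracle = [np.log2(scale * comb[i] / panel.per_probe_reference[i]) for i in range(50)]
        np.testing.assert_allclose(lr, oracle, atol=1e-12)


class TestBuildBins:
    def test_small_manifest_partition_oracle(self):
        # 10 probes on one chromosome, min 5 per bin, target 2 -> 2 bins of 5
        man = ProbeManifest(
            np.array([f"p{i}" for i in range(10)], dtype=object),
            np.array(["1"] * 10, dtype=object),
            np.arange(10) * 1000,
        )
        scheme = build_bins(man, BinConfig(target_bins=2, min_probes=5))
        assert len(scheme) == 2
        assert list(scheme.bins["probe_count"]) == [5, 5]
        assert scheme.bins["end"].iloc[0] <= scheme.bins["start"].iloc[1] + 1

    def test_empty_manifest_gives_no_bins(self):
        man = ProbeManifest(
            np.array([], dtype=object), np.array([], dtype=object), np.array([], dtype=int)
        )
        assert len(build_bins(man, BinConfig(target_bins=10, min_probes=2))) == 0

    def test_bins_never_cross_chromosomes_and_are_ordered(self, manifest):
        scheme = build_bins(manifest, BinConfig(target_bins=300, min_probes=10))
        bins = scheme.bins
        for c, grp in bins.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert np.all(starts[1:] >= ends[:-1])
        assert (bins["probe_count"] >= 10).all()

    def test_target_count_reached_when_supply_allows(self, manifest):
        scheme = build_bins(manifest, BinConfig(target_bins=800, min_probes=10))
        assert len(scheme) == 800

    def test_min_probe_cap_binds_on_scarce_chromosome(self):
        man = ProbeManifest(
            np.array([f"p{i}" for i in range(12)], dtype=object),
            np.array(["1"] * 12, dtype=object),
            np.arange(12) * 1000,
        )
        scheme = build_bins(man, BinConfig(target_bins=10, min_probes=5))
        assert len(scheme) == 2  # floor(12 / 5)


class TestBinProfile:
    def test_median_aggregation_against_sort_and_pick_oracle(self, rng):
        man = ProbeManifest(
            np.array([f"p{i}" for i in range(30)], dtype=object),
            np.array(["1"] * 30, dtype=object),
            np.arange(30) * 1000,
        )
        scheme = build_bins(man, BinConfig(target_bins=3, min_probes=10))
        values = rng.normal(0, 1, 30)
        prof = bin_profile("s", values, scheme)
        for b in range(3):
            member = values[scheme.probe_bin == b]
            assert prof.values[b] == pytest.approx(np.median(member))

    def test_all_zero_probes_give_zero_bins(self):
        man = ProbeManifest(
            np.array([f"p{i}" for i in range(20)], dtype=object),
            np.array(["1"] * 20, dtype=object),
            np.arange(20) * 1000,
        )
        scheme = build_bins(man, BinConfig(target_bins=2, min_probes=5))
        prof = bin_profile("s", np.zeros(20), scheme)
        assert np.all(prof.values == 0)


class TestFitBaseline:
    def test_degenerate_profile(self):
        prof = _profile_from_values([0.3] * 20)
        assert fit_baseline(prof) == pytest.approx(0.3, abs=1e-9)

    def test_majority_value_wins(self):
        prof = _profile_from_values([0.0] * 6 + [1.0] * 4)
        assert fit_baseline(prof) == pytest.approx(0.0, abs=1e-6)

    def test_matches_exhaustive_grid_oracle(self, rng):
        for _ in range(20):
            values = rng.normal(0.2, 0.5, 50)
            prof = _profile_from_values(values)
            b = fit_baseline(prof, grid_step=0.01)
            grid = np.arange(values.min(), values.max() + 0.005, 0.01)
            mads = np.array([np.median(np.abs(values - g)) for g in grid])
            best = mads.min()
            # returned candidate achieves the optimal MAD on the same grid
            assert np.median(np.abs(values - b)) <= best + 1e-12

    def test_translation_equivariance(self, rng):
        values = rng.normal(0, 0.3, 60)
        p1 = _profile_from_values(values)
        p2 = _profile_from_values(values + 0.7)
        b1, b2 = fit_baseline(p1), fit_baseline(p2)
        assert b2 - b1 == pytest.approx(0.7, abs=0.002)
        np.testing.assert_allclose(p1.baselined(), p2.baselined(), atol=0.004)


class TestSegmentation:
    def test_flat_profile_one_segment_per_chromosome(self):
        chroms = ["1"] * 40 + ["2"] * 40
        prof = _profile_from_values([0.0] * 80, chrom=chroms)
        prof.baseline = 0.0
        segs = segment_profile(prof, seed=0)
        assert len(segs) == 2
        assert {s.chromosome for s in segs} == {"1", "2"}
        assert all(s.mean_log2 == pytest.approx(0.0) for s in segs)

    def test_step_breakpoint_recovered_within_two_bins(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(1, 0.1, 100)])
        prof = _profile_from_values(x)
        prof.baseline = 0.0
        segs = segment_profile(prof, seed=1)
        boundaries = sorted(s.start // 1000 for s in segs)[1:]
        assert any(abs(b - 100) <= 2 for b in boundaries)

    def test_pure_noise_rarely_splits(self, rng):
        no_split = 0
        reps = 40
        for r in range(reps):
            x = rng.normal(0, 0.1, 120)
            prof = _profile_from_values(x)
            prof.baseline = 0.0
            segs = segment_profile(prof, alpha=0.01, seed=100 + r)
            no_split += len(segs) == 1
        assert no_split / reps >= 0.95

    def test_segment_means_conserve_member_bins(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 50), rng.normal(0.8, 0.05, 30)])
        prof = _profile_from_values(x)
        prof.baseline = 0.0
        segs = segment_profile(prof, seed=2)
        v = prof.baselined()
        for s in segs:
            members = v[(np.arange(80) * 1000 >= s.start) & (np.arange(80) * 1000 < s.end)]
            assert s.mean_log2 == pytest.approx(np.mean(members), abs=1e-9)
            assert s.n_bins == members.size

    def test_requires_fitted_baseline(self):
        prof = _profile_from_values([0.0] * 20)
        with pytest.raises(ValueError, match="baseline"):
            segment_profile(prof)


class TestCallEvents:
    def _seg(self, chrom, start, end, n_bins, mean):
        return Segment(chrom, start, end, n_bins, mean)

    def test_flat_genome_gives_no_events(self, highlight_genes):
        segs = [self._seg("1", 0, 240_000_000, 60, 0.01)]
        assert call_events(segs, highlight_genes) == []

    def test_focal_amplification_at_egfr(self, highlight_genes):
        segs = [
            self._seg("7", 0, 54_000_000, 20, 0.0),
            self._seg("7", 54_000_000, 56_000_000, 2, 1.5),
            self._seg("7", 56_000_000, 159_000_000, 30, 0.0),
        ]
        events = call_events(segs, highlight_genes)
        assert len(events) == 1
        assert events[0].kind == "amplification"
        assert "EGFR" in events[0].gene

    def test_focal_homozygous_deletion_at_cdkn2ab(self, highlight_genes):
        segs = [self._seg("9", 21_900_000, 22_100_000, 1, -1.2)]
        events = call_events(segs, highlight_genes)
        assert [e.kind for e in events] == ["homozygous_deletion"]
        assert "CDKN2A/B" in events[0].gene

    def test_arm_scale_deviation_is_gain_or_loss(self, highlight_genes):
        segs = [
            self._seg("7", 0, 159_000_000, 40, 0.3),
            self._seg("10", 0, 135_000_000, 35, -0.2),
        ]
        kinds = {e.kind for e in call_events(segs, highlight_genes)}
        assert kinds == {"gain", "loss"}

    def test_broad_high_segment_is_gain_not_amplification(self, highlight_genes):
        segs = [self._seg("7", 0, 80_000_000, 20, 0.9)]
        assert [e.kind for e in call_events(segs, highlight_genes)] == ["gain"]

    def test_unknown_required_genes_raise(self, highlight_genes):
        with pytest.raises(ValueError, match="NOPE1"):
            call_events([], highlight_genes, required_genes=["EGFR", "NOPE1"])

    def test_translation_equivariance_of_calls(self, manifest, panel, scheme):
        # shifting all probe log2 values changes the baseline, not the calls
        truth = CopyNumberTruth(segments=[("7", 0, 159_138_663, 4)], purity=1.0)
        t = simulate_tumor(truth, manifest, noise_sd=0.05, seed=5)
        lr = probe_log2(t, panel)
        from methyldx.cnv import bin_profile as bp, load_highlight_genes

        genes = load_highlight_genes()
        p1 = bp("a", lr, scheme)
        p2 = bp("b", lr + 0.5, scheme)
        b1, b2 = fit_baseline(p1), fit_baseline(p2)
        assert b2 - b1 == pytest.approx(0.5, abs=0.002)
        e1 = call_events(segment_profile(p1, seed=6), genes)
        e2 = call_events(segment_profile(p2, seed=6), genes)
        assert [(e.kind, e.chromosome) for e in e1] == [(e.kind, e.chromosome) for e in e2]


class TestExport:
    def test_igv_round_trip_reproduces_bin_values(self, tmp_path, rng):
        prof = _profile_from_values(rng.normal(0, 0.2, 25))
        path = tmp_path / "t.igv"
        export_igv(prof, path)
        df = read_igv(path)
        assert list(df.columns) == ["Chromosome", "Start", "End", "Feature", "s"]
        np.testing.assert_allclose(df["s"].to_numpy(), prof.values, atol=5e-7)

    def test_single_bin_profile_one_data_row(self, tmp_path):
        prof = _profile_from_values([0.1])
        path = tmp_path / "one.igv"
        export_igv(prof, path)
        assert len(path.read_text().strip().splitlines()) == 2

    def test_rows_grouped_by_chromosome(self, tmp_path):
        chroms = ["1"] * 5 + ["2"] * 5
        prof = _profile_from_values(np.arange(10) / 10, chrom=chroms)
        export_igv(prof, tmp_path / "two.igv")
        df = read_igv(tmp_path / "two.igv")
        assert list(df["Chromosome"]) == chroms

    def test_seg_format_columns(self, tmp_path):
        segs = [Segment("1", 0, 1000, 5, 0.2)]
        export_seg(segs, "s1", tmp_path / "a.seg")
        header = (tmp_path / "a.seg").read_text().splitlines()[0].split("\t")
        assert header == ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
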