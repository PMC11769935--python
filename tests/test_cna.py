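"""Binned CNA calling, cross-caller intersection, and recurrence filtering."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from canfrag import cna
from canfrag.cna import (CALLER_A, CALLER_B, CNACallSet, CallerThresholds,
                         ConsensusConfig, PanelOfNormals, bin_reads, call_states,
                         correct_bias, intersect_callsets, read_ichorcna_seg,
                         read_wisecondorx_bed, recurrence_filter)
from canfrag.synth import CNASpike, SyntheticCNAConfig, generate_cna_cohort

TOY_GENOME = {"chrA": 5_000_000, "chrB": 2_500_000}


def callset(sample, caller, rows):
    return CNACallSet(sample, caller,
                      pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


class TestBinReads:
    def test_no_reads_all_zero(self):
        bins, rejected = bin_reads({}, TOY_GENOME)
        assert rejected == 0
        assert (bins["count"] == 0).all()
        assert len(bins) == 10 + 5

    def test_position_bin_assignment(self):
        bins, _ = bin_reads({"chrA": np.array([750_000])}, TOY_GENOME)
        hit = bins[(bins["chrom"] == "chrA") & (bins["count"] > 0)]
        assert list(hit["start"]) == [500_000]

    def test_bin_widths_uniform(self):
        genome = {"chrC": 1_234_567}
        bins, _ = bin_reads({}, genome)
        widths = bins["end"] - bins["start"]
        assert (widths[:-1] == 500_000).all()
        assert widths.iloc[-1] == 1_234_567 % 500_000

    def test_out_of_bounds_rejected(self):
        bins, rejected = bin_reads({"chrA": np.array([-5, 10, 6_000_000]),
                                    "chrZ": np.array([1])}, TOY_GENOME)
        assert rejected == 3
        assert bins["count"].sum() == 1


def _flat_panel(n=8, n_bins=50, mean=5000.0, gc=None, seed=0):
    rng = np.random.default_rng(seed)
    grid = pd.DataFrame({"chrom": "chrA", "start": np.arange(n_bins) * 500_000,
                         "end": (np.arange(n_bins) + 1) * 500_000})
    # GC shuffled so genomic segments are not confounded with the GC trend
    gc = rng.permutation(np.linspace(0.3, 0.55, n_bins)) if gc is None else gc
    samples = []
    for _ in range(n):
        df = grid.copy()
        df["gc"] = gc
        df["mappability"] = 0.99
        df["count"] = rng.poisson(mean, n_bins)
        samples.append(df)
    return samples


class TestBiasCorrection:
    def test_sample_matching_panel_is_neutral(self):
        normals = _flat_panel(n=10, seed=1)
        panel = PanelOfNormals.build(normals)
        sample = normals[0].copy()
        sample["count"] = np.round(panel.median).astype(int)
        corrected = correct_bias(sample, panel)
        ok = ~corrected.masked
        assert np.abs(corrected.ratio[ok]).max() < 0.05
        assert np.abs(corrected.z[ok]).max() < 1.5

    def test_gc_function_variance_reduced(self):
        """Counts that are an exact smooth function of GC lose that variance
        after the LOESS correction."""
        normals = _flat_panel(n=10, seed=2)
        panel = PanelOfNormals.build(normals)
        sample = normals[0].copy()
        gc = sample["gc"].to_numpy()
        sample["count"] = np.round(5000 * (0.7 + 1.2 * np.exp(
            -0.5 * ((gc - 0.42) / 0.08) ** 2))).astype(int)
        pre = np.log2(sample["count"].to_numpy() / panel.median)
        corrected = correct_bias(sample, panel)
        ok = ~corrected.masked
        assert corrected.ratio[ok].var() <= pre[ok].var()

    def test_masked_bins_never_called(self):
        normals = _flat_panel(n=6, seed=3)
        panel = PanelOfNormals.build(normals)
        sample = normals[0].copy()
        sample.loc[5, "mappability"] = 0.5
        sample.loc[5, "count"] = 10 * int(panel.median[5])  # huge aberration
        corrected = correct_bias(sample, panel)
        calls = call_states(corrected, CallerThresholds("x", 2.0, 0.1))
        masked_bin = (sample.loc[5, "start"], sample.loc[5, "end"])
        for _, r in calls.calls.iterrows():
            assert not (r["start"] < masked_bin[1] and r["end"] > masked_bin[0])

    def test_all_masked_rejected(self):
        normals = _flat_panel(n=4, seed=4)
        panel = PanelOfNormals.build(normals)
        sample = normals[0].copy()
        sample["mappability"] = 0.1
        with pytest.raises(ValueError, match="masked"):
            correct_bias(sample, panel)


class TestCallStates:
    def test_neutral_input_empty(self):
        normals = _flat_panel(n=10, seed=5)
        panel = PanelOfNormals.build(normals)
        corrected = correct_bias(normals[1], panel)
        assert len(call_states(corrected, CALLER_A).calls) == 0

    def test_spike_recovered_with_reciprocal_overlap(self):
        """A spiked 10-bin copy-ratio-1.5 segment yields one gain interval with
        >=80% reciprocal overlap against truth."""
        config = SyntheticCNAConfig(seed=6, low_mappability_fraction=0.0,
                                    spikes=(CNASpike("chr2", 5_000_000, 10_000_000,
                                                     1.5, 8),))
        cohort = generate_cna_cohort(config)
        panel = PanelOfNormals.build([cohort.bins[s] for s in cohort.normal_ids])
        carrier = cohort.truth.iloc[0]["carriers"].split(",")[0]
        corrected = correct_bias(cohort.bins[carrier], panel, carrier)
        calls = call_states(corrected, CALLER_A)
        gains = calls.intervals("gain")
        assert len(gains) == 1
        chrom, s, e = gains[0]
        assert chrom == "chr2"
        overlap = min(e, 10_000_000) - max(s, 5_000_000)
        assert overlap / 5_000_000 >= 0.8
        assert overlap / (e - s) >= 0.8

    def test_two_presets_overlap_but_differ_on_soft_spike(self):
        """A marginal spike is called wider by the looser preset."""
        normals = _flat_panel(n=20, n_bins=60, seed=7)
        panel = PanelOfNormals.build(normals)
        sample = normals[0].copy()
        lift = np.ones(60)
        lift[20:30] = 1.30
        lift[19] = lift[30] = 1.22  # shoulders only the looser preset keeps
        sample["count"] = np.round(panel.median * lift).astype(int)
        corrected = correct_bias(sample, panel)
        strict = call_states(corrected, CallerThresholds("a", 6.0, 0.30))
        loose = call_states(corrected, CallerThresholds("b", 3.0, 0.15))
        both = intersect_callsets(strict, loose)
        assert len(strict.calls) > 0 and len(loose.calls) > 0
        strict_bp = (strict.calls["end"] - strict.calls["start"]).sum()
        loose_bp = (loose.calls["end"] - loose.calls["start"]).sum()
        common_bp = (both.calls["end"] - both.calls["start"]).sum()
        assert loose_bp > strict_bp
        assert common_bp == strict_bp


def brute_force_intersection(a_rows, b_rows, genome, state):
    """Per-base oracle on a toy genome."""
    out = {}
    for chrom, length in genome.items():
        cover_a = np.zeros(length, dtype=bool)
        cover_b = np.zeros(length, dtype=bool)
        for c, s, e, st_ in a_rows:
            if c == chrom and st_ == state:
                cover_a[s:e] = True
        for c, s, e, st_ in b_rows:
            if c == chrom and st_ == state:
                cover_b[s:e] = True
        out[chrom] = cover_a & cover_b
    return out


class TestIntersect:
    def test_worked_interval_example(self):
        a = callset("s", "a", [("chr1", 0, 1_000_000, "gain")])
        b = callset("s", "b", [("chr1", 500_000, 1_500_000, "gain")])
        result = intersect_callsets(a, b)
        assert result.intervals("gain") == [("chr1", 500_000, 1_000_000)]

    def test_disjoint_and_idempotent_and_commutative(self):
        a = callset("s", "a", [("chr1", 0, 100, "gain"), ("chr1", 300, 400, "loss")])
        b = callset("s", "b", [("chr1", 150, 250, "gain")])
        assert len(intersect_callsets(a, b).calls) == 0
        same = intersect_callsets(a, a)
        assert same.calls[["chrom", "start", "end", "state"]].equals(
            a.calls[["chrom", "start", "end", "state"]])
        ab = intersect_callsets(a, b).calls
        ba = intersect_callsets(b, a).calls
        assert ab.equals(ba)

    def test_matches_per_base_oracle(self):
        genome = {"c1": 1000, "c2": 600}
        rng = np.random.default_rng(9)
        for _ in range(10):
            def random_rows():
                rows = []
                for chrom, length in genome.items():
                    for state in ("gain", "loss"):
                        cuts = np.sort(rng.choice(length, 4, replace=False))
                        rows.append((chrom, int(cuts[0]), int(cuts[1]), state))
                        rows.append((chrom, int(cuts[2]), int(cuts[3]) + 1, state))
                return [r for r in rows if r[1] < r[2]]
            ra, rb = random_rows(), random_rows()
            result = intersect_callsets(callset("s", "a", ra), callset("s", "b", rb))
            for state in ("gain", "loss"):
                expected = brute_force_intersection(ra, rb, genome, state)
                got = {c: np.zeros(l, dtype=bool) for c, l in genome.items()}
                for c, s, e in result.intervals(state):
                    got[c][s:e] = True
                for chrom in genome:
                    assert (got[chrom] == expected[chrom]).all()

    def test_agrees_with_bedtools(self, tmp_path):
        """Independent semantics check against bedtools intersect."""
        a = callset("s", "a", [("chr1", 0, 1_000_000, "gain"),
                               ("chr1", 2_000_000, 3_000_000, "gain")])
        b = callset("s", "b", [("chr1", 500_000, 2_500_000, "gain")])
        pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
        for cs, p in ((a, pa), (b, pb)):
            cna.write_calls_bed(cs.calls, p)
        out = subprocess.run(["bedtools", "intersect", "-a", pa, "-b", pb],
                             capture_output=True, text=True, check=True).stdout
        expected = sorted(tuple(line.split("\t")[:3])
                          for line in out.strip().splitlines())
        got = sorted((c, str(s), str(e))
                     for c, s, e in intersect_callsets(a, b).intervals("gain"))
        assert got == expected

    def test_sample_mismatch_rejected(self):
        a = callset("s1", "a", [("chr1", 0, 100, "gain")])
        b = callset("s2", "b", [("chr1", 0, 100, "gain")])
        with pytest.raises(ValueError, match="sample mismatch"):
            intersect_callsets(a, b)


def _grid(genome, width=500_000):
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length, width)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": np.minimum(starts + width, length)}))
    return pd.concat(rows, ignore_index=True)


class TestRecurrence:
    def test_threshold_boundary(self):
        """Present in 7 of 21 samples -> retained; 6 of 21 -> dropped."""
        genome = {"chr1": 5_000_000}
        grid = _grid(genome)
        region_a = ("chr1", 0, 1_000_000, "gain")       # 7 carriers
        region_b = ("chr1", 3_000_000, 4_000_000, "gain")  # 6 carriers
        callsets = []
        for i in range(21):
            rows = []
            if i < 7:
                rows.append(region_a)
            if i < 6:
                rows.append(region_b)
            callsets.append(callset(f"s{i}", "c", rows))
        result = recurrence_filter(callsets, grid, ConsensusConfig(7, 21))
        kept = result.regions
        assert len(kept) == 1
        assert (kept.iloc[0]["start"], kept.iloc[0]["end"]) == (0, 1_000_000)
        assert result.chromosomes == {"gain": ["chr1"], "loss": []}

    def test_universal_region_retained(self):
        genome = {"chr1": 2_000_000}
        callsets = [callset(f"s{i}", "c", [("chr1", 0, 500_000, "loss")])
                    for i in range(5)]
        result = recurrence_filter(callsets, _grid(genome), ConsensusConfig(5, 5))
        assert result.chromosomes["loss"] == ["chr1"]

    def test_counts_match_brute_force_tally(self):
        genome = {"c1": 3_000_000, "c2": 2_000_000}
        grid = _grid(genome)
        rng = np.random.default_rng(13)
        callsets = []
        all_rows = []
        for i in range(9):
            rows = []
            for chrom, length in genome.items():
                for state in ("gain", "loss"):
                    if rng.random() < 0.6:
                        s = int(rng.integers(0, length - 500_000))
                        e = int(rng.integers(s + 1, length))
                        rows.append((chrom, s, e, state))
            callsets.append(callset(f"s{i}", "c", rows))
            all_rows.append(rows)
        result = recurrence_filter(callsets, grid, ConsensusConfig(3, 9))
        for _, bin_row in result.per_bin_counts.iterrows():
            for state, col in (("gain", "gain_count"), ("loss", "loss_count")):
                tally = sum(
                    any(c == bin_row["chrom"] and s < bin_row["end"]
                        and e > bin_row["start"] and st_ == state
                        for c, s, e, st_ in rows)
                    for rows in all_rows)
                assert bin_row[col] == tally

    def test_regions_sorted_disjoint_per_state(self):
        genome = {"c1": 4_000_000}
        callsets = [callset(f"s{i}", "c",
                            [("c1", 0, 1_500_000, "gain"),
                             ("c1", 2_500_000, 4_000_000, "gain")])
                    for i in range(4)]
        result = recurrence_filter(callsets, _grid(genome), ConsensusConfig(3, 4))
        gains = result.regions[result.regions["state"] == "gain"]
        starts, ends = list(gains["start"]), list(gains["end"])
        assert starts == sorted(starts)
        assert all(e <= s for e, s in zip(ends, starts[1:]))

    def test_null_cohort_specific(self):
        """Without spikes the two-preset consensus makes no calls in most runs."""
        clean = 0
        for seed in range(3):
            cohort = generate_cna_cohort(SyntheticCNAConfig(seed=100 + seed,
                                                            spikes=()))
            panel = PanelOfNormals.build(
                [cohort.bins[s] for s in cohort.normal_ids])
            n_calls = 0
            for sid in cohort.tumor_ids:
                corrected = correct_bias(cohort.bins[sid], panel, sid)
                n_calls += len(intersect_callsets(
                    call_states(corrected, CALLER_A),
                    call_states(corrected, CALLER_B)).calls)
            clean += n_calls == 0
        assert clean >= 2


class TestAdapters:
    def test_ichorcna_seg_roundtrip(self, tmp_path):
        seg = tmp_path / "s.seg"
        seg.write_text(
            "ID\tchrom\tstart\tend\tnum.mark\tseg.median.logR\tcall\n"
            "dog1\tchr5\t1\t1000000\t2\t0.6\tGAIN\n"
            "dog1\tchr5\t2000001\t3000000\t2\t-0.7\tHETD\n"
            "dog1\tchr6\t1\t500000\t1\t0.0\tNEUT\n")
        cs = read_ichorcna_seg(seg)
        assert cs.intervals("gain") == [("chr5", 0, 1_000_000)]
        assert cs.intervals("loss") == [("chr5", 2_000_000, 3_000_000)]

    def test_wisecondorx_bed_roundtrip(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t0\t1500000\tgain\nchr2\t500000\t1000000\tloss\n")
        cs = read_wisecondorx_bed(bed, "dog2")
        assert cs.intervals("gain") == [("chr1", 0, 1_500_000)]
        assert cs.intervals("loss") == [("chr2", 500_000, 1_000_000)]

    def test_consensus_runs_on_adapter_output(self, tmp_path):
        seg = tmp_path / "s.seg"
        seg.write_text("ID\tchrom\tstart\tend\tnum.mark\tseg.median.logR\tcall\n"
                       "d\tchr1\t1\t1000000\t2\t0.6\tGAIN\n")
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t250000\t1500000\tgain\n")
        a = read_ichorcna_seg(seg, "d")
        b = read_wisecondorx_bed(bed, "d")
        assert intersect_callsets(a, b).intervals("gain") \
            == [("chr1", 250_000, 1_000_000)]
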