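"""Aberration calling, penetrance accounting and recurrent-region extraction."""

import numpy as np
import pandas as pd
import pytest

from mircna import (call_segments, cytoband_penetrance, genes_in_regions,
                    recurrent_regions)
from mircna.cna import RecurrentRegionSet
from mircna.io import (CytobandMap, Locus, ProbeRatioTrack, SegmentCall,
                       ValidationError)

from conftest import SEED
from oracles import brute_penetrance, brute_runs


def track(ratios, chroms=None, sample="s1", spacing=100):
    n = len(ratios)
    chroms = chroms or ["1"] * n
    pos = []
    counter = {}
    for c in chroms:
        counter[c] = counter.get(c, 0) + 1
        pos.append(counter[c] * spacing)
    return ProbeRatioTrack(sample_id=sample, probes=pd.DataFrame(
        {"chrom": chroms, "position": pos, "log2_ratio": ratios}))


def band_map(rows):
    return CytobandMap(pd.DataFrame(rows, columns=["chrom", "start", "stop",
                                                   "band"]))


def seg(sample, chrom, start, stop, direction, n=10):
    mean = 0.5 if direction == "gain" else -0.5
    return SegmentCall(sample_id=sample, chrom=chrom, start=start, stop=stop,
                       direction=direction, mean_log2_ratio=mean, n_probes=n)


class TestCallSegments:
    def test_uniform_gain_run(self):
        calls = call_segments(track([0.5] * 10))
        assert len(calls) == 1
        c = calls[0]
        assert (c.direction, c.n_probes) == ("gain", 10)
        assert c.mean_log2_ratio == pytest.approx(0.5)

    def test_three_probe_run_not_called(self):
        # aberration filter: a run needs more than 3 probes
        calls = call_segments(track([0.0, 0.5, 0.5, 0.5, 0.0, 0.0]))
        assert calls == []

    def test_adjacent_gain_and_loss_split(self):
        calls = call_segments(track([0.5] * 5 + [-0.5] * 5))
        assert [c.direction for c in calls] == ["gain", "loss"]
        assert calls[0].stop <= calls[1].start

    def test_runs_do_not_cross_chromosomes(self):
        calls = call_segments(track([0.5] * 4, chroms=["1"] * 2 + ["2"] * 2))
        assert calls == []

    def test_threshold_is_strict(self):
        calls = call_segments(track([0.25] * 10 + [-0.25] * 10))
        assert calls == []

    def test_unsorted_probes_rejected(self):
        t = ProbeRatioTrack.__new__(ProbeRatioTrack)
        t.sample_id = "s1"
        t.probes = pd.DataFrame({"chrom": ["1", "1"], "position": [200, 100],
                                 "log2_ratio": [0.5, 0.5]})
        with pytest.raises(ValidationError):
            call_segments(t)

    def test_matches_run_enumeration_oracle(self):
        rng = np.random.default_rng(SEED)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            ratios = rng.choice([-0.5, 0.0, 0.5], size=n,
                                p=[0.3, 0.4, 0.3])
            chroms = [str(c) for c in np.sort(rng.integers(1, 4, size=n))]
            t = track(list(ratios), chroms=chroms)
            calls = call_segments(t)
            expected = brute_runs(np.sign(ratios).astype(int), chroms, 4)
            assert len(calls) == len(expected)
            for call, (i, j, sign) in zip(calls, expected):
                assert call.n_probes == j - i + 1
                assert call.direction == ("gain" if sign == 1 else "loss")
                assert call.start == t.probes["position"].iloc[i]
                assert call.stop == t.probes["position"].iloc[j] + 1


class TestPenetrance:
    BANDS = [("1", 0, 1000, "p1"), ("1", 1000, 2000, "q1"),
             ("2", 0, 1500, "q1")]

    def test_fraction_arithmetic(self):
        calls = {f"c{i}": [seg(f"c{i}", "1", 100, 200, "gain")]
                 for i in range(15)}
        calls.update({f"d{i}": [] for i in range(12)})  # 27 cases total
        pen = cytoband_penetrance(calls, band_map(self.BANDS))
        assert pen.n_cases == 27
        assert pen.table.loc["1p1", "gain_fraction"] == pytest.approx(15 / 27)
        assert pen.table.loc["1p1", "dominant"] == "gain"
        assert pen.table.loc["2q1", "dominant"] == "none"

    def test_case_contributes_once_per_band_direction(self):
        calls = {"c1": [seg("c1", "1", 0, 100, "gain"),
                        seg("c1", "1", 200, 300, "gain"),
                        seg("c1", "1", 400, 500, "gain")],
                 "c2": []}
        pen = cytoband_penetrance(calls, band_map(self.BANDS))
        assert pen.table.loc["1p1", "gain_fraction"] == pytest.approx(0.5)

    def test_invariant_under_reordering_and_duplication(self):
        bands = band_map(self.BANDS)
        calls = {"c1": [seg("c1", "1", 100, 1200, "gain")],
                 "c2": [seg("c2", "2", 0, 700, "loss")]}
        base = cytoband_penetrance(calls, bands).table
        shuffled = {"c2": calls["c2"] * 3, "c1": calls["c1"][::-1] * 2}
        pd.testing.assert_frame_equal(
            base, cytoband_penetrance(shuffled, bands).table)

    def test_tie_direction_flagged(self):
        calls = {"c1": [seg("c1", "1", 0, 10, "gain")],
                 "c2": [seg("c2", "1", 0, 10, "loss")]}
        pen = cytoband_penetrance(calls, band_map(self.BANDS))
        assert pen.table.loc["1p1", "dominant"] == "tie"

    def test_matches_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(SEED)
        bands = band_map([("1", i * 100, (i + 1) * 100, f"b{i}")
                          for i in range(10)] +
                         [("2", i * 100, (i + 1) * 100, f"b{i}")
                          for i in range(5)])
        calls = {}
        for ci in range(12):
            case = f"case{ci}"
            calls[case] = []
            for _ in range(int(rng.integers(0, 5))):
                chrom = str(rng.integers(1, 3))
                start = int(rng.integers(0, 900))
                stop = start + int(rng.integers(10, 400))
                direction = "gain" if rng.random() < 0.5 else "loss"
                calls[case].append(seg(case, chrom, start, stop, direction))
        pen = cytoband_penetrance(calls, bands)
        intervals = {k: bands.interval(k) for k in bands.keys()}
        expected = brute_penetrance(calls, intervals)
        for band, (g, l) in expected.items():
            assert pen.table.loc[band, "gain_fraction"] == pytest.approx(g)
            assert pen.table.loc[band, "loss_fraction"] == pytest.approx(l)


class TestRecurrentRegions:
    def pen_from(self, fractions):
        table = pd.DataFrame(fractions, columns=["band", "gain_fraction",
                                                 "loss_fraction"])
        table["dominant"] = "gain"
        from mircna.cna import CytobandPenetrance
        return CytobandPenetrance(table=table.set_index("band"), n_cases=27)

    def test_threshold_selection(self):
        pen = self.pen_from([("X", 0.55, 0.0), ("Y", 0.20, 0.0)])
        regions = recurrent_regions(pen, 0.33)
        assert regions.bands == {"X"}
        assert regions.directions["X"] == {"gain"}

    def test_tied_band_included_with_both_directions(self):
        pen = self.pen_from([("X", 0.40, 0.40)])
        regions = recurrent_regions(pen, 0.33)
        assert regions.tied("X")
        assert regions.directions["X"] == {"gain", "loss"}

    def test_thresholds_give_nested_sets(self, study_bundle):
        from mircna import call_segments as cs
        calls = {t.sample_id: cs(t) for t in study_bundle.tracks}
        pen = cytoband_penetrance(calls, study_bundle.cytobands)
        tight = recurrent_regions(pen, 0.40)
        loose = recurrent_regions(pen, 0.33)
        assert tight.members <= loose.members
        assert tight.bands <= loose.bands

    def test_boundary_inclusive(self):
        pen = self.pen_from([("X", 0.33, 0.0)])
        assert recurrent_regions(pen, 0.33).bands == {"X"}


class TestGenesInRegions:
    BANDS = [("1", 0, 1000, "p1"), ("1", 1000, 2000, "q1")]

    def regions(self, *bands):
        return RecurrentRegionSet(
            frequency_threshold=0.33,
            members={(b, "gain", 0.5) for b in bands},
            directions={b: {"gain"} for b in bands})

    def test_gene_inside_band_included(self):
        genes = [Locus(id="g1", chrom="1", start=10, stop=20)]
        out = genes_in_regions(genes, self.regions("1p1"), band_map(self.BANDS))
        assert out == {"g1"}

    def test_abutting_gene_excluded_by_half_open_rule(self):
        genes = [Locus(id="g1", chrom="1", start=1000, stop=1100)]
        out = genes_in_regions(genes, self.regions("1p1"), band_map(self.BANDS))
        assert out == set()

    def test_matches_quadratic_interval_scan(self):
        rng = np.random.default_rng(SEED)
        bands = band_map([(str(c), i * 500, (i + 1) * 500, f"b{i}")
                          for c in (1, 2) for i in range(6)])
        keys = bands.keys()
        chosen = [keys[i] for i in rng.choice(len(keys), 5, replace=False)]
        genes = []
        for gi in range(200):
            chrom = str(rng.integers(1, 3))
            start = int(rng.integers(0, 2900))
            genes.append(Locus(id=f"g{gi}", chrom=chrom, start=start,
                               stop=start + int(rng.integers(1, 300))))
        got = genes_in_regions(genes, self.regions(*chosen), bands)
        expected = set()
        for g in genes:
            for key in chosen:
                chrom, start, stop = bands.interval(key)
                if g.chrom == chrom and g.start < stop and start < g.stop:
                    expected.add(g.id)
        assert got == expected


def merge_adjacent(segments):
    """Union of planted segments per (sample, chrom, direction): adjacent
    whole-band plants with one direction present as a single aberration."""
    merged = []
    by_key = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom, s.direction), []).append(s)
    for (sample, chrom, direction), group in by_key.items():
        group = sorted(group, key=lambda s: s.start)
        cur_start, cur_stop = group[0].start, group[0].stop
        for s in group[1:]:
            if s.start <= cur_stop:
                cur_stop = max(cur_stop, s.stop)
            else:
                merged.append(seg(sample, chrom, cur_start, cur_stop, direction))
                cur_start, cur_stop = s.start, s.stop
        merged.append(seg(sample, chrom, cur_start, cur_stop, direction))
    return merged


def test_called_segments_recover_planted_probes(study_bundle):
    """Per planted segment, the best matching call covers >= 90% of its
    probes (Jaccard in probe space) at default noise."""
    calls = {t.sample_id: call_segments(t) for t in study_bundle.tracks}
    tracks = {t.sample_id: t for t in study_bundle.tracks}
    for planted in merge_adjacent(study_bundle.truth.segments):
        probes = tracks[planted.sample_id].probes
        on_chrom = probes[probes["chrom"] == planted.chrom]
        pos = on_chrom["position"].to_numpy()
        truth_idx = set(np.nonzero((pos >= planted.start) &
                                   (pos < planted.stop))[0])
        best = 0.0
        for call in calls[planted.sample_id]:
            if call.chrom != planted.chrom or call.direction != planted.direction:
                continue
            call_idx = set(np.nonzero((pos >= call.start) &
                                      (pos < call.stop))[0])
            union = truth_idx | call_idx
            if union:
                best = max(best, len(truth_idx & call_idx) / len(union))
        assert best >= 0.9, (planted.sample_id, planted.chrom, planted.start)
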