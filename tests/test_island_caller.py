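import math

import numpy as np
import pytest
from scipy import stats

from capmeth.island_caller import (
    CallerError,
    IslandCallerConfig,
    background_lambda,
    call_differential_regions,
    call_islands,
    island_score_threshold,
    link_islands,
    score_windows,
)
from capmeth.synthetic_data import (
    EnrichmentTruth,
    SimulationConfig,
    simulate_capture_library,
)
from capmeth.tag_processing import (
    TagSet,
    WindowCounts,
    count_window_tags,
    deduplicate_reads,
    reads_to_tags,
)
from capmeth.genome_model import GenomicInterval

CONFIG = IslandCallerConfig()


def make_window_counts(counts, window_size=200):
    counts = np.asarray(counts, dtype=np.int64)
    return WindowCounts(
        window_size=window_size,
        counts={"chr1": counts},
        library_size=int(counts.sum()),
        chrom_sizes={"chr1": len(counts) * window_size},
    )


def brute_force_islands(counts, lam, config, threshold=0.0):
    """Independent enumerator: test every maximal eligible run directly."""
    w = config.window_size
    p = [float(stats.poisson.sf(c - 1, lam)) for c in counts]
    eligible = [pi < config.window_pvalue_eligibility for pi in p]
    score = [-math.log(pi) if e else 0.0 for pi, e in zip(p, eligible)]
    islands = []
    i = 0
    n = len(counts)
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        last_eligible = i
        while j + 1 < n:
            # extend while the next eligible window is within gap_size
            k = j + 1
            while k < n and not eligible[k]:
                k += 1
            if k < n and (k - last_eligible - 1) * w <= config.gap_size:
                j = k
                last_eligible = k
            else:
                break
        s = sum(score[i:j + 1])
        if s >= threshold:
            islands.append((i * w, (j + 1) * w, s))
        i = j + 1
    return islands


class TestScoreWindows:
    def test_zero_count_ineligible(self):
        wc = make_window_counts([0, 0])
        sw = score_windows(wc, CONFIG, lam=1.0)["chr1"]
        assert sw.pvalues[0] == 1.0
        assert not sw.eligible.any()
        assert (sw.scores == 0).all()

    def test_closed_form_poisson_tail(self):
        wc = make_window_counts([4])
        sw = score_windows(wc, CONFIG, lam=1.0)["chr1"]
        expected = 1 - math.exp(-1) * (1 + 1 + 0.5 + 1 / 6)
        assert sw.pvalues[0] == pytest.approx(expected, rel=1e-12)
        assert sw.scores[0] == pytest.approx(-math.log(expected), rel=1e-12)
        assert sw.eligible[0]

    @pytest.mark.parametrize("lam", [1.0, 1.5, 2.0, 3.0, 5.0, 10.0])
    def test_round_lambda_counts_never_eligible(self, lam):
        wc = make_window_counts([round(lam)] * 3)
        sw = score_windows(wc, CONFIG, lam=lam)["chr1"]
        assert not sw.eligible.any()

    def test_empty_library_rejected(self):
        with pytest.raises(CallerError):
            background_lambda(0, CONFIG, {"chr1": 1000})


class TestLinkIslands:
    def _islands(self, counts, lam=1.0):
        wc = make_window_counts(counts)
        scored = score_windows(wc, CONFIG, lam=lam)
        return link_islands(scored, CONFIG, wc.chrom_sizes)

    def test_gap_equal_to_gap_size_merges(self):
        # eligible windows at window indices 0 and 4: 3 ineligible between
        # -> 600 bp gap == gap_size -> one island
        counts = [6, 0, 0, 0, 6]
        islands = self._islands(counts)
        assert len(islands) == 1
        assert (islands[0].start, islands[0].end) == (0, 1000)

    def test_gap_beyond_gap_size_splits(self):
        counts = [6, 0, 0, 0, 0, 6]  # 800 bp gap > 600
        islands = self._islands(counts)
        assert len(islands) == 2

    def test_single_window_island_score(self):
        counts = [6]
        islands = self._islands(counts)
        sw = score_windows(make_window_counts(counts), CONFIG, lam=1.0)["chr1"]
        assert islands[0].score == pytest.approx(float(sw.scores[0]))

    def test_island_score_at_least_max_member(self):
        counts = [6, 0, 7, 8, 0, 0, 0, 9]
        islands = self._islands(counts)
        sw = score_windows(make_window_counts(counts), CONFIG, lam=1.0)["chr1"]
        for isl in islands:
            members = sw.scores[isl.start // 200:isl.end // 200]
            assert isl.score >= members.max() - 1e-12

    def test_matches_brute_force_small(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            counts = rng.poisson(1.2, size=int(rng.integers(5, 80)))
            got = [(i.start, i.end, i.score)
                   for i in self._islands(counts, lam=1.2)]
            exp = brute_force_islands(counts, 1.2, CONFIG)
            assert [(s, e) for s, e, _ in exp] == [(s, e) for s, e, _ in got]
            for (_, _, a), (_, _, b) in zip(exp, got):
                assert a == pytest.approx(b, rel=1e-9)


class TestScoreThreshold:
    def test_infinite_evalue_threshold_zero(self):
        cfg = IslandCallerConfig(evalue=1e12)
        assert island_score_threshold(0.5, 1000, cfg) == 0.0

    def test_monotone_in_evalue(self):
        t = {}
        for ev in (100.0, 50.0, 25.0):
            cfg = IslandCallerConfig(evalue=ev, mc_replicates=10)
            t[ev] = island_score_threshold(1.0, 5000, cfg)
        assert t[100.0] <= t[50.0] <= t[25.0]

    def test_against_longer_simulation(self):
        cfg = IslandCallerConfig(evalue=20.0, mc_replicates=20)
        t_short = island_score_threshold(0.5, 10_000, cfg)
        cfg_long = IslandCallerConfig(evalue=20.0, mc_replicates=200)
        t_long = island_score_threshold(
            0.5, 10_000, cfg_long, rng=np.random.default_rng(999)
        )
        # agreement within the score of one strongly eligible window
        one_window = -math.log(stats.poisson.sf(0, 0.5))
        assert abs(t_short - t_long) <= one_window

    def test_bad_inputs(self):
        with pytest.raises(CallerError):
            island_score_threshold(0.0, 100, CONFIG)
        with pytest.raises(CallerError):
            island_score_threshold(1.0, 100,
                                   IslandCallerConfig(mc_replicates=0))


def _library_tags(truth, config):
    reads = simulate_capture_library(truth, config)
    return reads_to_tags(deduplicate_reads(reads, 1), 300, config.chrom_sizes)


SIM = SimulationConfig(
    chrom_sizes={"chr1": 2_000_000}, n_fragments=120_000, write_fasta=False
)


class TestCallIslands:
    def test_planted_region_recovered(self):
        from dataclasses import replace

        hits = 0
        for seed in range(3):
            cfg = replace(SIM, seed=seed)
            region = GenomicInterval("chr1", 1_000_000, 1_002_000)
            truth = EnrichmentTruth("5hmC", "c", [(region, 8.0)])
            tags = _library_tags(truth, cfg)
            islands = call_islands(tags, CONFIG, cfg.chrom_sizes)
            cover = sum(
                max(0, min(i.end, region.end) - max(i.start, region.start))
                for i in islands if i.chrom == "chr1"
            )
            if cover >= 0.8 * region.length():
                hits += 1
        assert hits == 3

    def test_control_identical_to_treatment_kills_all(self):
        truth = EnrichmentTruth("5hmC", "c", [])
        tags = _library_tags(truth, SIM)
        islands = call_islands(tags, CONFIG, SIM.chrom_sizes,
                               control_tags=tags)
        assert islands == []

    def test_per_chromosome_independence(self):
        cfg = SimulationConfig(
            chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000},
            n_fragments=100_000, seed=5, write_fasta=False,
        )
        truth = EnrichmentTruth(
            "5hmC", "c",
            [(GenomicInterval("chr1", 500_000, 502_000), 8.0),
             (GenomicInterval("chr2", 200_000, 202_000), 8.0)],
        )
        tags = _library_tags(truth, cfg)
        lam = background_lambda(tags.library_size, CONFIG, cfg.chrom_sizes)
        full = call_islands(tags, CONFIG, cfg.chrom_sizes)
        # chromosome order must not matter
        flipped = TagSet(
            dict(reversed(list(tags.midpoints.items()))), tags.fragment_length
        )
        again = call_islands(flipped, CONFIG, cfg.chrom_sizes)
        assert sorted((i.chrom, i.start, i.end) for i in full) == \
            sorted((i.chrom, i.start, i.end) for i in again)
        assert lam > 0


class TestDifferentialRegions:
    def test_identical_libraries_no_calls(self):
        truth = EnrichmentTruth(
            "5hmC", "c", [(GenomicInterval("chr1", 1_000_000, 1_002_000), 8.0)]
        )
        tags = _library_tags(truth, SIM)
        regions = call_differential_regions(
            tags, tags, CONFIG, SIM.chrom_sizes, significant_only=False
        )
        assert regions  # candidates exist
        assert all(r.norm_fc == pytest.approx(1.0) for r in regions)
        assert not [r for r in regions if r.q_value <= 0.5]

    def test_exact_binomial_example(self):
        mids_a = np.sort(np.arange(40) * 3 + 1_000_000)
        mids_b = np.sort(np.arange(10) * 3 + 1_000_000)
        n = 100_000
        filler_a = np.arange(n - 40) * 5  # stays below 500 kb
        filler_b = np.arange(n - 10) * 5
        tags_a = TagSet({"chr1": np.sort(np.concatenate([filler_a, mids_a]))}, 300)
        tags_b = TagSet({"chr1": np.sort(np.concatenate([filler_b, mids_b]))}, 300)
        regions = call_differential_regions(
            tags_a, tags_b, CONFIG, {"chr1": 2_000_000},
            significant_only=False,
            candidates=[("chr1", 1_000_000, 1_000_200)],
        )
        (r,) = regions
        assert (r.count_a, r.count_b) == (40, 10)
        assert r.norm_fc == pytest.approx(41 / 11)
        expected_p = stats.binomtest(40, 50, 0.5, alternative="two-sided").pvalue
        assert r.p_value == pytest.approx(expected_p, rel=1e-12)
        assert r.direction == "hyper"

    def test_doubling_tags_preserves_norm_fc(self):
        tags_a = TagSet({"chr1": np.sort(np.arange(100) * 50 + 10_000)}, 300)
        tags_b = TagSet({"chr1": np.sort(np.arange(400) * 11 + 10_000)}, 300)
        cand = [("chr1", 10_000, 15_000)]
        r1 = call_differential_regions(
            tags_a, tags_b, CONFIG, {"chr1": 100_000},
            significant_only=False, candidates=cand,
        )[0]
        double = lambda t: TagSet(
            {c: np.sort(np.concatenate([m, m])) for c, m in t.midpoints.items()},
            t.fragment_length,
        )
        r2 = call_differential_regions(
            double(tags_a), double(tags_b), CONFIG, {"chr1": 100_000},
            significant_only=False, candidates=cand,
        )[0]
        # pseudocount of 1 perturbs the ratio only marginally at these counts
        assert r2.norm_fc == pytest.approx(r1.norm_fc, rel=0.05)

    def test_empty_library_rejected(self):
        tags = TagSet({"chr1": np.array([100])}, 300)
        empty = TagSet({}, 300)
        with pytest.raises(CallerError):
            call_differential_regions(tags, empty, CONFIG, {"chr1": 1000})

    def test_qvalues_dominate_pvalues(self):
        truth = EnrichmentTruth(
            "5hmC", "c", [(GenomicInterval("chr1", 1_000_000, 1_002_000), 4.0)]
        )
        tags_a = _library_tags(truth, SIM)
        truth_b = EnrichmentTruth("5hmC", "b", [])
        tags_b = _library_tags(truth_b, SIM)
        for r in call_differential_regions(
            tags_a, tags_b, CONFIG, SIM.chrom_sizes, significant_only=False
        ):
            assert r.q_value >= r.p_value
            if r.q_value <= CONFIG.fdr:
                assert r.direction in ("hyper", "hypo")
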