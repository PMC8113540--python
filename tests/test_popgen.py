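"""Windowed diversity, ratio scan, fixed differences, gene reports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teparyscan import popgen, simulate
from teparyscan.io import GeneLocus, SiteRecord, VariantTable, assign_ranks

import oracles


def _table(genotype_rows, positions=None, chrom="Chr01"):
    """Build a VariantTable from int lists; first half wild, rest landrace."""
    n = len(genotype_rows[0])
    samples = [f"w{i}" for i in range(n // 2)] + [f"l{i}" for i in range(n - n // 2)]
    positions = positions or [100 * (i + 1) for i in range(len(genotype_rows))]
    sites = [
        SiteRecord(chrom, p, "A", "G", np.array(row, dtype=np.int8))
        for p, row in zip(positions, genotype_rows)
    ]
    return VariantTable(samples, sites)


def _popmap(table):
    return {s: ("wild" if s.startswith("w") else "landrace") for s in table.samples}


class TestSitePi:
    def test_two_of_four_haplotypes(self):
        # m=4, j=2 -> 2*2*2/(4*3) = 2/3, the mean over all C(4,2) pairs
        assert popgen.site_pi(np.array([1, 1], dtype=np.int8)) == pytest.approx(2 / 3)

    def test_monomorphic_zero(self):
        assert popgen.site_pi(np.array([0, 0, 0], dtype=np.int8)) == 0.0
        assert popgen.site_pi(np.array([2, 2], dtype=np.int8)) == 0.0

    def test_single_heterozygote(self):
        # m=2, j=1 -> the single haplotype pair differs
        assert popgen.site_pi(np.array([1, -1], dtype=np.int8)) == 1.0

    def test_insufficient_haplotypes_skipped(self):
        assert popgen.site_pi(np.array([-1, -1], dtype=np.int8)) is None

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=1, max_size=12))
    def test_matches_pairwise_oracle(self, genotypes):
        got = popgen.site_pi(np.array(genotypes, dtype=np.int8))
        expected = oracles.oracle_site_pi(genotypes)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)


class TestWindowDiversity:
    def test_watterson_closed_form(self):
        # one 100 kb window, 3 segregating sites, 8 haplotypes, no missing
        rows = [[1, 0, 1, 0], [0, 1, 0, 1], [1, 1, 0, 0]]
        table = _table(rows, positions=[10_000, 40_000, 90_000])
        cfg = popgen.ScanConfig(window_bp=100_000, step_bp=100_000, min_sites_per_window=1)
        windows = popgen.window_diversity(table, _popmap(table), cfg, {"Chr01": 100_000})
        (w,) = windows
        # 2 wild diploids = 4 haplotypes -> a_3 in the Watterson denominator
        a3 = sum(1 / i for i in range(1, 4))
        assert w.theta_wild == pytest.approx(3 / (a3 * 100_000))
        assert w.n_snps == 3

    def test_zero_snp_window(self):
        table = _table([[1, 0, 1, 0]], positions=[5_000])
        cfg = popgen.ScanConfig(window_bp=10_000, step_bp=10_000, min_sites_per_window=1)
        windows = popgen.window_diversity(table, _popmap(table), cfg, {"Chr01": 30_000})
        assert windows[1].pi_wild == 0.0 and windows[1].theta_wild == 0.0
        assert windows[1].ratio is None

    def test_sliding_windows_share_sites(self):
        """A SNP at 95,000 appears in every window starting 1..90,001."""
        table = _table([[1, 0, 1, 0]], positions=[95_000])
        cfg = popgen.ScanConfig(window_bp=100_000, step_bp=10_000, min_sites_per_window=1)
        windows = popgen.window_diversity(table, _popmap(table), cfg, {"Chr01": 200_000})
        containing = [w.start for w in windows if w.n_snps == 1]
        assert containing == [1 + 10_000 * i for i in range(10)]
        assert containing[-1] == 90_001

    def test_tiling_covers_all_sites(self, panel_sim):
        cfg = popgen.ScanConfig(seed=1)
        windows = popgen.window_diversity(
            panel_sim.table, panel_sim.popmap, cfg, panel_sim.chrom_lengths
        )
        per_chrom = {}
        for w in windows:
            per_chrom.setdefault(w.chrom, []).append(w)
        expected = cfg.window_bp // cfg.step_bp
        for site in panel_sim.table:
            hits = sum(
                1 for w in per_chrom[site.chrom] if w.start <= site.pos <= w.end
            )
            dist_from_edge = min(site.pos, panel_sim.chrom_lengths[site.chrom] - site.pos)
            if dist_from_edge >= cfg.window_bp:
                assert hits == expected
            else:
                assert 1 <= hits <= expected

    def test_infinite_ratio_on_landrace_monomorphy(self):
        rows = [[1, 1, 0, 0]]  # wild polymorphic, landrace monomorphic
        table = _table(rows, positions=[500])
        cfg = popgen.ScanConfig(window_bp=1000, step_bp=1000, min_sites_per_window=1)
        (w,) = popgen.window_diversity(table, _popmap(table), cfg, {"Chr01": 1000})
        assert math.isinf(w.ratio)


class TestRatioScan:
    def _windows(self, ratios):
        return [
            popgen.WindowDiversity("Chr01", 1 + i * 10_000, i * 10_000 + 100_000,
                                   10, r if r is not None else 0.0,
                                   1.0 if r is None else 1.0, 0, 0, r)
            for i, r in enumerate(ratios)
        ]

    def test_degenerate_equal_ratios_give_no_blocks(self):
        windows = self._windows([1.0] * 200)
        result = popgen.ratio_scan(windows, popgen.ScanConfig(seed=0))
        assert result.blocks == []
        assert not any(w.tail_strict for w in windows)

    def test_planted_outlier_lands_in_strict_tail(self):
        rng = np.random.default_rng(0)
        ratios = list(rng.uniform(0.9, 1.1, 999)) + [10.0]
        windows = self._windows(ratios)
        result = popgen.ratio_scan(windows, popgen.ScanConfig(seed=0))
        assert windows[-1].tail_strict
        assert windows[-1] in result.blocks[-1].member_windows

    def test_too_few_windows_rejected(self):
        with pytest.raises(popgen.ScanError, match="100"):
            popgen.ratio_scan(self._windows([1.0] * 50), popgen.ScanConfig())

    def test_consecutive_tail_windows_merge_into_one_block(self):
        # three consecutive windows with total landrace diversity loss
        inf = math.inf
        ratios = [1.0] * 150 + [inf, inf, inf] + [1.0] * 150
        windows = self._windows(ratios)
        result = popgen.ratio_scan(windows, popgen.ScanConfig(seed=3))
        assert len(result.blocks) == 1
        block = result.blocks[0]
        assert len(block.member_windows) == 3
        assert block.start == windows[150].start and block.end == windows[152].end

    def test_nonconsecutive_tail_windows_stay_separate_blocks(self):
        inf = math.inf
        ratios = [1.0] * 120 + [inf] + [1.0] * 120 + [inf, inf] + [1.0] * 120
        windows = self._windows(ratios)
        result = popgen.ratio_scan(windows, popgen.ScanConfig(seed=3))
        assert [len(b.member_windows) for b in result.blocks] == [1, 2]


class TestSweepRecovery:
    def test_planted_sweep_found_with_low_false_coverage(self, panel_sim):
        cfg = popgen.ScanConfig(seed=31)
        windows = popgen.window_diversity(
            panel_sim.table, panel_sim.popmap, cfg, panel_sim.chrom_lengths
        )
        result = popgen.ratio_scan(windows, cfg)
        truth = panel_sim.truth["sweep_blocks"]
        overlap = 0
        covered = 0
        for b in result.blocks:
            covered += b.end - b.start + 1
            for chrom, s, e, _ in truth:
                if b.chrom == chrom:
                    overlap += max(0, min(b.end, e) - max(b.start, s) + 1)
        planted = sum(e - s + 1 for _, s, e, _ in truth)
        genome = sum(panel_sim.chrom_lengths.values())
        assert overlap / planted >= 0.9
        assert (covered - overlap) / genome < 0.01

    def test_neutral_panel_pi_matches_theta(self):
        spec = simulate.PopSimSpec(
            n_wild=8, n_landrace=12,
            chrom_lengths={"Chr01": 3_000_000}, seed=77, missing_rate=0.0,
        )
        panel = simulate.simulate_two_population_vcf(spec)
        # non-overlapping windows so the standard error is honest
        cfg = popgen.ScanConfig(window_bp=100_000, step_bp=100_000, seed=77)
        windows = popgen.window_diversity(panel.table, panel.popmap, cfg, panel.chrom_lengths)
        for pop in ("wild", "landrace"):
            pis = np.array([getattr(w, f"pi_{pop}") for w in windows])
            thetas = np.array([getattr(w, f"theta_{pop}") for w in windows])
            diff = pis - thetas
            se = diff.std(ddof=1) / math.sqrt(len(diff))
            assert abs(diff.mean()) < 3 * se + 1e-9
        ratios = [w.ratio for w in windows if w.ratio is not None and math.isfinite(w.ratio)]
        assert 0.8 <= float(np.median(ratios)) <= 1.25


class TestFixedDifferences:
    def test_clean_fixed_difference(self):
        table = _table([[0, 0, 2, 2]])
        result = popgen.fixed_difference_scan(table, _popmap(table))
        (site,) = result.fixed_sites
        assert (site.wild_allele, site.landrace_allele) == ("A", "G")

    def test_heterozygote_disqualifies(self):
        table = _table([[0, 1, 2, 2]])
        assert popgen.fixed_difference_scan(table, _popmap(table)).fixed_sites == []

    def test_missing_calls_tolerated(self):
        table = _table([[0, 0, -1, 2]])
        assert len(popgen.fixed_difference_scan(table, _popmap(table)).fixed_sites) == 1

    def test_planted_fixed_sites_recovered_exactly(self, panel_sim):
        result = popgen.fixed_difference_scan(panel_sim.table, panel_sim.popmap)
        got = sorted((f.chrom, f.pos) for f in result.fixed_sites)
        assert got == sorted((c, p) for c, p in panel_sim.truth["fixed_sites"])

    def test_cross_consistency_with_classifier(self, panel_sim):
        """Every FixedSite is labeled fixed_difference and vice versa."""
        n_fixed = len(popgen.fixed_difference_scan(panel_sim.table, panel_sim.popmap).fixed_sites)
        tally = popgen.classify_snp_polymorphism(panel_sim.table, panel_sim.popmap)
        assert tally["fixed_difference"] == n_fixed


class TestPolymorphismClasses:
    def test_poly_wild_only(self):
        table = _table([[0, 1, 0, 0]])
        tally = popgen.classify_snp_polymorphism(table, _popmap(table))
        assert tally["poly_wild_only"] == 1

    def test_all_monomorphic(self):
        table = _table([[0, 0, 0, 0], [2, 2, 2, 2]])
        tally = popgen.classify_snp_polymorphism(table, _popmap(table))
        assert tally["mono_both"] == 2

    def test_percentages_to_one_decimal(self):
        # the published wild-only fraction: 2,247,877 of 3,377,439 -> 66.6%
        tally = {
            "poly_wild_only": 2_247_877,
            "poly_both": 3_377_439 - 2_247_877,
            "poly_landrace_only": 0,
            "mono_both": 0,
            "fixed_difference": 0,
        }
        summary = dict((label, pct) for label, _, pct in popgen.polymorphism_summary(tally))
        assert summary["poly_wild_only"] == 66.6

    def test_labels_partition_classifiable_sites(self, panel_sim):
        tally = popgen.classify_snp_polymorphism(panel_sim.table, panel_sim.popmap)
        assert sum(tally.values()) <= len(panel_sim.table)
        assert all(v >= 0 for v in tally.values())


class TestGeneBlockReport:
    def _setup(self):
        # block Chr01:1000-5000; gene gIn inside with monomorphic landrace,
        # gPoly inside with polymorphic landrace, gOut outside, gEmpty no SNPs
        block = popgen.DomesticationBlock("Chr01", 1000, 5000, [])
        loci = assign_ranks([
            GeneLocus("gIn", "Chr01", 1200, 1800),
            GeneLocus("gPoly", "Chr01", 2000, 2600),
            GeneLocus("gEmpty", "Chr01", 3000, 3400),
            GeneLocus("gOut", "Chr01", 9000, 9600),
        ])
        table = _table(
            [[1, 1, 0, 0], [0, 1, 0, 0], [1, 0, 1, 1], [1, 1, 1, 0]],
            positions=[1300, 1500, 2200, 9100],
        )
        return block, loci, table

    def test_statuses(self):
        block, loci, table = self._setup()
        report = popgen.gene_block_report([block], loci, table, _popmap(table))
        status = {g: s for g, _, s in report.gene_rows}
        assert status == {"gIn": "monomorphic", "gPoly": "polymorphic", "gEmpty": "no_data"}
        assert report.n_monomorphic == 1 and report.n_no_data == 1
        assert report.monomorphic_block_span_bp == 4001

    def test_planted_monomorphic_genes_recovered(self, panel_sim):
        cfg = popgen.ScanConfig(seed=31)
        windows = popgen.window_diversity(panel_sim.table, panel_sim.popmap, cfg, panel_sim.chrom_lengths)
        result = popgen.ratio_scan(windows, cfg)
        report = popgen.gene_block_report(result.blocks, panel_sim.loci, panel_sim.table, panel_sim.popmap)
        got_mono = {g for g, _, s in report.gene_rows if s == "monomorphic"}
        truth_mono = set(panel_sim.truth["monomorphic_genes"])
        # every called monomorphic gene is planted; block-resident planted
        # genes are recovered
        assert got_mono <= truth_mono
        in_blocks = {g for g, _, _ in report.gene_rows}
        assert truth_mono & in_blocks == got_mono
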