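"""Sliding-window Fisher DMR calling, merging, and gene association."""

import math

import numpy as np
import pandas as pd
import pytest

from bsmeth import dmr, simulate
from bsmeth._stats import fisher_exact_2x2
from bsmeth.errors import ConfigError, ValidationError
from bsmeth.io_formats import AnnotationSet, Gene
from conftest import make_sites


class TestSlidingWindows:
    def test_enumeration_oracle_len_1200(self):
        assert dmr.sliding_windows(1200, 1000, 100) == [
            (0, 1000), (100, 1100), (200, 1200)
        ]

    def test_window_equal_step_tiles(self):
        wins = dmr.sliding_windows(1000, 100, 100)
        assert wins == [(i * 100, (i + 1) * 100) for i in range(10)]

    def test_short_chromosome_single_clipped_window(self):
        assert dmr.sliding_windows(300, 1000, 100) == [(0, 300)]

    def test_every_base_covered(self):
        for n in (1, 99, 100, 101, 1999, 2000):
            wins = dmr.sliding_windows(n, 1000, 100)
            covered = np.zeros(n, dtype=bool)
            for s, e in wins:
                covered[s:e] = True
            assert covered.all()

    def test_bad_parameters_raise(self):
        with pytest.raises(ConfigError):
            dmr.sliding_windows(1000, 100, 200)


class TestFisher:
    def test_extreme_table_equals_hypergeometric_closed_form(self):
        # [[30,0],[0,30]]: the two extreme tables each have prob 1/C(60,30)
        assert fisher_exact_2x2(30, 0, 0, 30) == pytest.approx(
            2 / math.comb(60, 30), rel=1e-12
        )

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x2(10, 5, 10, 5) == 1.0

    def test_matches_scipy_on_random_tables_including_large(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 120, size=4)
            mine = fisher_exact_2x2(*t)
            ref = scipy_fisher([[t[0], t[1]], [t[2], t[3]]]).pvalue
            assert mine == pytest.approx(ref, rel=1e-8, abs=1e-12)


class TestWindowTest:
    def test_identical_pooled_counts_give_p_one(self):
        a = make_sites([("c", i, "+", 10, 10, "CG") for i in range(1, 8)])
        b = make_sites([("c", i, "+", 10, 10, "CG") for i in range(1, 8)])
        assert dmr.window_test(a, b, ("c", 0, 100)) == 1.0

    def test_too_few_qualifying_sites_is_undefined(self):
        a = make_sites([("c", 1, "+", 10, 10, "CG")])
        b = make_sites([("c", 1, "+", 10, 10, "CG")])
        assert dmr.window_test(a, b, ("c", 0, 100), min_sites=5) is None

    def test_low_coverage_sites_excluded_by_min_cov(self):
        a = make_sites([("c", i, "+", 1, 1, "CG") for i in range(1, 8)])
        b = make_sites([("c", i, "+", 1, 1, "CG") for i in range(1, 8)])
        assert dmr.window_test(a, b, ("c", 0, 100), min_cov=4) is None


def _planted_pair(seed, n_dmrs=10, chrom_len=150_000):
    cfg0 = simulate.SimulationConfig(
        seed=seed, n_chroms=1, chrom_len=chrom_len, n_genes=15, n_repeats=15
    )
    genome, ann = simulate.simulate_genome(cfg0)
    planted = tuple(
        simulate.PlantedDmr(
            "chr1", 10_000 + i * 13_000, 12_000 + i * 13_000, "CG",
            "petal", "stamen", 0.8, 0.2,
        )
        for i in range(n_dmrs)
    )
    cfg = simulate.SimulationConfig(
        seed=seed, n_chroms=1, chrom_len=chrom_len, n_genes=15, n_repeats=15,
        planted_dmrs=planted,
    )
    sa, _ = simulate.simulate_methylome(genome, ann, cfg, "petal")
    sb, _ = simulate.simulate_methylome(genome, ann, cfg, "stamen")
    return sa, sb, planted, {"chr1": chrom_len}


class TestCallDmrs:
    def test_planted_region_recovered_as_single_hypo_dmr(self):
        sa, sb, planted, sizes = _planted_pair(seed=2, n_dmrs=1)
        dmrs = dmr.call_dmrs(sa, sb, context="CG", chrom_sizes=sizes)
        hits = dmrs[(dmrs.end > planted[0].start) & (dmrs.start < planted[0].end)]
        assert len(hits) == 1
        d = hits.iloc[0]
        overlap = min(d.end, planted[0].end) - max(d.start, planted[0].start)
        assert overlap >= 0.8 * (planted[0].end - planted[0].start)
        assert d.direction == "hypo" and d.ml_b < d.ml_a

    def test_swapping_samples_flips_directions_only(self):
        sa, sb, _, sizes = _planted_pair(seed=3, n_dmrs=3)
        fwd = dmr.call_dmrs(sa, sb, context="CG", chrom_sizes=sizes)
        rev = dmr.call_dmrs(sb, sa, context="CG", chrom_sizes=sizes)
        assert list(fwd.start) == list(rev.start)
        assert list(fwd.end) == list(rev.end)
        assert np.allclose(fwd.p, rev.p)
        flip = {"hypo": "hyper", "hyper": "hypo"}
        assert [flip[d] for d in fwd.direction] == list(rev.direction)

    def test_merged_dmrs_are_idempotent_under_remerge(self):
        sa, sb, _, sizes = _planted_pair(seed=4, n_dmrs=5)
        dmrs = dmr.call_dmrs(sa, sb, context="CG", chrom_sizes=sizes, merge_gap=100)
        # consecutive same-direction DMRs must be separated by more than the
        # merge gap, otherwise merging was not exhaustive
        for (_, a), (_, b) in zip(dmrs.iterrows(), dmrs.iloc[1:].iterrows()):
            if a.chrom == b.chrom and a.direction == b.direction:
                assert b.start > a.end + 100

    def test_impossible_ml_diff_gives_empty_result(self):
        sa, sb, _, sizes = _planted_pair(seed=5, n_dmrs=2)
        dmrs = dmr.call_dmrs(sa, sb, context="CG", min_ml_diff=1.0, chrom_sizes=sizes)
        assert len(dmrs) == 0

    def test_same_collection_for_both_samples_raises(self):
        sa, _, _, _ = _planted_pair(seed=6, n_dmrs=1)
        with pytest.raises(ValidationError):
            dmr.call_dmrs(sa, sa, context="CG")

    def test_null_window_false_positive_rate_bounded(self):
        # identical per-site truth (no planted differences): window-level
        # rejections at alpha should not exceed alpha by sampling error
        cfg = simulate.SimulationConfig(seed=7, n_chroms=1, chrom_len=100_000, n_genes=10)
        genome, ann = simulate.simulate_genome(cfg)
        sa, _ = simulate.simulate_methylome(genome, ann, cfg, "petal")
        sb, _ = simulate.simulate_methylome(genome, ann, cfg, "stamen")
        scan = dmr.window_scan(sa, sb, context="CG", chrom_sizes={"chr1": 100_000})
        alpha = 0.01
        rate = (scan.p < alpha).mean()
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / len(scan))


class TestGeneAssociation:
    def _ann(self):
        genes = [
            Gene("gA", "c", "+", 10_000, 16_000, exons=[(10_000, 11_000), (15_000, 16_000)]),
            Gene("gB", "c", "-", 30_000, 33_000),
        ]
        return AnnotationSet(genes=genes, repeats=[("c", 12_000, 12_500)])

    def _dmr(self, start, end, direction="hypo"):
        return pd.DataFrame(
            [
                {
                    "chrom": "c", "start": start, "end": end, "context": "CG",
                    "direction": direction, "p": 1e-6, "p_min": 1e-6,
                    "ml_a": 0.8, "ml_b": 0.2, "n_windows": 1, "n_sites": 10,
                }
            ]
        )

    def test_dmr_inside_intron_links_as_intron(self):
        links, per_gene = dmr.associate_genes(self._dmr(12_600, 12_800), self._ann())
        assert len(links) == 1
        assert links.compartment[0] == "intron" and links.gene_id[0] == "gA"

    def test_promoter_takes_precedence_over_exon(self):
        # spans the promoter/first-exon boundary of gA
        links, _ = dmr.associate_genes(self._dmr(9_500, 10_500), self._ann())
        assert links[links.gene_id == "gA"].compartment.iloc[0] == "promoter"

    def test_gene_desert_dmr_has_no_links(self):
        links, _ = dmr.associate_genes(self._dmr(20_000, 21_000), self._ann())
        assert len(links) == 0

    def test_repeat_overlap_reported_independently(self):
        links, _ = dmr.associate_genes(self._dmr(12_100, 12_700), self._ann())
        assert bool(links.repeat_overlap[0]) and links.compartment[0] == "intron"

    def test_minus_strand_promoter_is_right_flank(self):
        links, _ = dmr.associate_genes(self._dmr(33_500, 34_000), self._ann())
        assert links[links.gene_id == "gB"].compartment.iloc[0] == "promoter"


class TestCompartmentDistribution:
    def test_intergenic_dmrs_are_all_other(self):
        ann = AnnotationSet(genes=[], repeats=[])
        d = TestGeneAssociation()._dmr(100, 500)
        out = dmr.dmr_compartment_distribution(d, ann).set_index("compartment")
        assert out.loc["other", "share_pct"] == 100.0

    def test_maximal_overlap_wins(self):
        ann = TestGeneAssociation()._ann()
        # 60% promoter (9400-10000), 40% first exon (10000-10400) for gA
        d = TestGeneAssociation()._dmr(9_400, 10_400)
        out = dmr.dmr_compartment_distribution(d, ann).set_index("compartment")
        assert out.loc["promoter", "n_dmrs"] == 1

    def test_empty_dmr_list_gives_empty_distribution(self):
        ann = TestGeneAssociation()._ann()
        out = dmr.dmr_compartment_distribution(pd.DataFrame(columns=["start"]), ann)
        assert len(out) == 0

    def test_planted_compartment_shares_recovered(self):
        # place DMRs with known primary compartments and check the shares
        ann = TestGeneAssociation()._ann()
        frames = [
            TestGeneAssociation()._dmr(9_000, 9_900),    # promoter gA
            TestGeneAssociation()._dmr(10_100, 10_900),  # exon gA
            TestGeneAssociation()._dmr(13_000, 13_800),  # intron gA
            TestGeneAssociation()._dmr(50_000, 50_500),  # other
        ]
        d = pd.concat(frames, ignore_index=True)
        out = dmr.dmr_compartment_distribution(d, ann).set_index("compartment")
        assert out.loc["promoter", "n_dmrs"] == 1
        assert out.loc["exon", "n_dmrs"] == 1
        assert out.loc["intron", "n_dmrs"] == 1
        assert out.loc["other", "n_dmrs"] == 1
        assert out.share_pct.sum() == pytest.approx(100.0)
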