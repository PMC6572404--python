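"""Feature-level ML, metagene profiles, and expression stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from bsmeth import core, profiles, simulate
from bsmeth.errors import ValidationError
from bsmeth.io_formats import AnnotationSet, Gene
from conftest import make_sites


def _fpkm(values):
    return pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(len(values))], "fpkm_s": values}
    )


class TestClassifyExpression:
    def test_below_one_is_none(self):
        # a single expressed gene sits on both quartile boundaries; ties go low
        out = profiles.classify_expression(_fpkm([0.5, 3.0]), "s")
        assert list(out.expr_class) == ["none", "low"]

    def test_quantile_oracle_on_1_to_100(self):
        values = list(range(1, 101))
        out = profiles.classify_expression(_fpkm(values), "s")
        q25, q75 = np.percentile(values, [25, 75])
        for fpkm, cls in zip(out.fpkm, out.expr_class):
            if fpkm <= q25:
                assert cls == "low"
            elif fpkm <= q75:
                assert cls == "medium"
            else:
                assert cls == "high"

    def test_all_unexpressed_does_not_crash(self):
        out = profiles.classify_expression(_fpkm([0.1, 0.9, 0.0]), "s")
        assert (out.expr_class == "none").all()

    def test_exactly_one_is_low_not_none(self):
        out = profiles.classify_expression(_fpkm([1.0, 2.0, 3.0, 4.0, 5.0]), "s")
        assert out.expr_class[0] == "low"

    def test_gene_order_invariance(self):
        values = [0.2, 5, 50, 7, 1, 90, 33]
        a = profiles.classify_expression(_fpkm(values), "s")
        shuffled = _fpkm(values).iloc[::-1].reset_index(drop=True)
        b = profiles.classify_expression(shuffled, "s")
        merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
        assert (merged.expr_class_a == merged.expr_class_b).all()

    def test_empty_table_raises(self):
        with pytest.raises(ValidationError):
            profiles.classify_expression(_fpkm([]), "s")


class TestFeatureMl:
    def test_exonic_sites_only(self):
        ann = AnnotationSet(
            genes=[Gene("g0", "c", "+", 3000, 4000)], repeats=[], promoter_span=2000
        )
        sites = make_sites([("c", 3500, "+", 5, 5, "CG"), ("c", 3600, "+", 5, 5, "CG")])
        out = profiles.feature_ml(sites, ann).set_index("feature")
        assert out.loc["exon", "weighted_ml"] == 0.5
        assert np.isnan(out.loc["repeat", "weighted_ml"])
        assert np.isnan(out.loc["intron", "weighted_ml"])

    def test_empty_annotation_all_undefined(self):
        ann = AnnotationSet(genes=[], repeats=[])
        sites = make_sites([("c", 10, "+", 5, 5, "CG")])
        out = profiles.feature_ml(sites, ann)
        assert out.weighted_ml.isna().all()

    def test_planted_intron_vs_exon_ordering_recovered(self):
        cfg = simulate.SimulationConfig(
            seed=4, n_chroms=1, chrom_len=60_000, n_genes=12,
            feature_rates={"intron": 0.5, "exon": 0.2},
        )
        genome, ann = simulate.simulate_genome(cfg)
        sites, _ = simulate.simulate_methylome(genome, ann, cfg, "petal")
        out = profiles.feature_ml(sites, ann, context="CG").set_index("feature")
        assert out.loc["intron", "weighted_ml"] > out.loc["exon", "weighted_ml"]
        assert out.loc["intron", "weighted_ml"] == pytest.approx(0.5, abs=0.05)
        assert out.loc["exon", "weighted_ml"] == pytest.approx(0.2, abs=0.05)


def _uniform_sites(chrom, n_pos, rate, cov, seed, spacing=10):
    rng = np.random.default_rng(seed)
    pos = np.arange(1, n_pos + 1) * spacing
    m = rng.binomial(cov, rate, size=n_pos)
    return pd.DataFrame(
        {
            "chrom": chrom, "pos": pos, "strand": "+",
            "count_meth": m, "count_unmeth": cov - m,
            "context": "CG", "trinucleotide": "CGA",
        }
    )


class TestMetagene:
    def test_flat_limit_on_uniform_rate(self):
        ann = AnnotationSet(
            genes=[Gene(f"g{i}", "c", "+", 5000 + i * 9000, 9000 + i * 9000) for i in range(10)],
            repeats=[],
        )
        sites = _uniform_sites("c", 10_000, 0.3, 30, seed=9)
        prof = profiles.metagene_profile(sites, ann, context="CG")
        mls = prof[prof.expression_class == "all"].ml.dropna()
        assert mls.max() - mls.min() < 0.05

    def test_minus_strand_profile_mirrors_plus(self):
        gene_plus = Gene("gp", "cA", "+", 5000, 8000)
        gene_minus = Gene("gm", "cB", "-", 5000, 8000)
        rng = np.random.default_rng(3)
        pos = np.arange(2500, 10_500, 7)
        m = rng.binomial(30, np.linspace(0.1, 0.9, len(pos)))
        plus_sites = pd.DataFrame(
            {
                "chrom": "cA", "pos": pos, "strand": "+",
                "count_meth": m, "count_unmeth": 30 - m,
                "context": "CG", "trinucleotide": "CGA",
            }
        )
        # mirror positions around the gene midpoint: x -> start + end - 1 - x0
        mirror_pos0 = 5000 + 8000 - 1 - (pos - 1)
        minus_sites = plus_sites.assign(chrom="cB", pos=mirror_pos0 + 1).sort_values("pos")
        prof_p = profiles.metagene_profile(
            plus_sites, AnnotationSet(genes=[gene_plus], repeats=[]), context="CG"
        )
        prof_m = profiles.metagene_profile(
            minus_sites, AnnotationSet(genes=[gene_minus], repeats=[]), context="CG"
        )
        a = prof_p[prof_p.expression_class == "all"]
        b = prof_m[prof_m.expression_class == "all"]
        assert list(a.pooled_meth) == list(b.pooled_meth)
        assert list(a.pooled_unmeth) == list(b.pooled_unmeth)

    def test_promoter_depleted_methylation_dips_near_tss(self):
        cfg = simulate.SimulationConfig(
            seed=6, n_chroms=1, chrom_len=60_000, n_genes=10,
            uniform_rate=0.6, feature_rates={"promoter": 0.05},
        )
        genome, ann = simulate.simulate_genome(cfg)
        sites, _ = simulate.simulate_methylome(genome, ann, cfg, "petal")
        prof = profiles.metagene_profile(sites, ann, context="CG")
        sub = prof[prof.expression_class == "all"]
        up = sub[sub.region == "up2k"].ml.to_numpy()
        body = sub[sub.region == "body"].ml.to_numpy()
        assert np.nanmean(up) < 0.2 and np.nanmean(body) > 0.4
        # dip is in the flank, nearest bins to the TSS included
        assert up[-1] < 0.2

    def test_counts_conserved_across_bins(self, small_dataset):
        sites, ann = small_dataset["sites"], small_dataset["ann"]
        prof = profiles.metagene_profile(sites, ann, context="CG", n_bins_body=20)
        total = prof[prof.expression_class == "all"][["pooled_meth", "pooled_unmeth"]].sum().sum()
        expected = 0
        sel = sites[sites.context == "CG"]
        for g in ann.genes:
            if g.length < 20:
                continue
            sub = sel[
                (sel.chrom == g.chrom)
                & (sel.pos - 1 >= g.start - 2000)
                & (sel.pos - 1 < g.end + 2000)
            ]
            expected += int(sub.count_meth.sum() + sub.count_unmeth.sum())
        assert total == expected

    def test_missing_genes_in_classing_raise(self, small_dataset):
        classing = pd.DataFrame({"gene_id": ["nope"], "expr_class": ["high"]})
        with pytest.raises(ValidationError):
            profiles.metagene_profile(
                small_dataset["sites"], small_dataset["ann"], classing=classing
            )


class TestMlByExpression:
    def _ann_and_classing(self, n=40, chrom_len=200_000):
        genes = [
            Gene(f"g{i}", "c", "+", 2500 + i * 5000, 4500 + i * 5000) for i in range(n)
        ]
        ann = AnnotationSet(genes=genes, repeats=[])
        return ann

    def test_separated_groups_give_tiny_p(self):
        ann = self._ann_and_classing()
        rows = []
        for i, g in enumerate(ann.genes):
            rate = 0.1 if i < 20 else 0.9
            for pos0 in range(g.start, g.end, 100):
                m = int(round(rate * 30))
                rows.append(("c", pos0 + 1, "+", m, 30 - m, "CG"))
        sites = make_sites(rows)
        classing = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in ann.genes],
                "expr_class": ["none"] * 20 + ["high"] * 20,
            }
        )
        _per_gene, summary = profiles.ml_by_expression(sites, ann, classing, context="CG")
        body = summary.set_index("region").loc["body"]
        # oracle: exact U-statistic on the same two lists
        oracle = mannwhitneyu([0.1] * 20, [0.9] * 20, alternative="two-sided").pvalue
        assert body.pvalue == pytest.approx(oracle)
        assert body.pvalue < 1e-6

    def test_identical_groups_give_p_one(self):
        ann = self._ann_and_classing(n=10)
        rows = []
        for g in ann.genes:
            for pos0 in range(g.start, g.end, 200):
                rows.append(("c", pos0 + 1, "+", 15, 15, "CG"))
        sites = make_sites(rows)
        classing = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in ann.genes],
                "expr_class": ["low"] * 5 + ["medium"] * 5,
            }
        )
        _pg, summary = profiles.ml_by_expression(sites, ann, classing, context="CG")
        body = summary.set_index("region").loc["body"]
        assert body.pvalue >= 0.99
        # flanks carry no sites here, so their tests are flagged undefined
        assert summary.set_index("region").loc["up2k", "undefined"]

    def test_single_gene_group_is_flagged_undefined(self):
        ann = self._ann_and_classing(n=3)
        rows = []
        for g in ann.genes:
            rows.append(("c", g.start + 1, "+", 10, 10, "CG"))
        sites = make_sites(rows)
        classing = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in ann.genes],
                "expr_class": ["none", "high", "high"],
            }
        )
        _pg, summary = profiles.ml_by_expression(sites, ann, classing, context="CG")
        assert summary.undefined.all()
        assert summary.pvalue.isna().all()
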