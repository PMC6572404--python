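# bsmeth

Whole-genome bisulfite sequencing (WGBS) methylome analysis for plant
genomes: cytosine-context methylation quantification, sliding-window
Fisher-exact detection of differentially methylated regions (DMRs),
integration of DMRs with gene expression, and validation of individual loci
by clone (Sanger) bisulfite sequencing. The package is aimed at analyses
that compare the methylomes of a few tissues or organs — for example floral
organs whose identity shifts (petal, stamen, and petaloid stamen) — and ask
which genes sit under differential methylation and whether their expression
responds.

## The model

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
while methylated cytosine stays C, so a site's methylation is read out as
per-site counts of methylated (mC) and unmethylated (umC) reads. bsmeth
works with three plant cytosine contexts — CG, CHG and CHH, where H is any
base but G — classified from the two bases 3' of the cytosine on its own
strand.

- **Methylation level.** ML(C) = reads(mC) / reads(mC + umC), per site or
  pooled over a window ("weighted" ML pools counts before dividing).
  Zero-coverage sites are undefined, never zero.
- **Site calling.** The methylated count at a covered site is modelled as
  s⁺ ~ Binomial(s⁺ + s⁻, r). A site is called methylated by a one-sided
  exact binomial test of H₀: r = ε against H₁: r > ε, where ε is the
  bisulfite non-conversion rate (default 0.005), with Benjamini–Hochberg
  correction across tested sites.
- **DMR calling.** For each 1000 bp window advanced in 100 bp steps, the
  pooled (mC, umC) counts of two samples form a 2×2 table tested with a
  two-sided Fisher exact test (default α = 0.01). Significant windows whose
  pooled MLs differ by at least 0.1 merge, same direction only, into DMRs
  that are re-scored from pooled counts. *Hypo* means the second sample is
  the less methylated one.
- **Integration.** Genes are DMR-associated when a DMR touches the gene
  body or its ±2 kb flanks (promoter = upstream 2 kb of the TSS). DEGs are
  genes with fold change ≥ 2 and FDR ≤ 0.05; enrichment of, say,
  up-regulated genes among hypo-DMR genes is a two-sided Fisher exact test
  on gene-set membership.
- **Clone bisulfite.** Clones are aligned to the untreated amplicon with a
  bisulfite-aware global alignment (reference C vs clone T is a match); at
  each cytosine, percent methylation = 100 · C / (C + T) across clones.

A fully seeded synthetic-data generator produces genomes, annotations,
per-cytosine count tables with planted DMRs, expression tables with planted
hypo-DMR/up-regulation coupling, and clone sets — the ground truth that the
test suite uses to verify every stage.

## Worked example

Plant one 2 kb CG DMR (methylation level 0.8 in petal vs 0.2 in stamen) in
a 60 kb simulated chromosome, then recover it:

```python
from bsmeth import simulate, dmr, core

base = dict(seed=1, n_chroms=1, chrom_len=60_000, n_genes=10)
genome, ann = simulate.simulate_genome(simulate.SimulationConfig(**base))
planted = simulate.PlantedDmr("chr1", 20_000, 22_000, "CG",
                              "petal", "stamen", rate_a=0.8, rate_b=0.2)
cfg = simulate.SimulationConfig(planted_dmrs=(planted,), **base)
petal, _ = simulate.simulate_methylome(genome, ann, cfg, "petal")
stamen, _ = simulate.simulate_methylome(genome, ann, cfg, "stamen")

frac = core.genome_context_fractions(core.call_methylated_sites(petal))
print(frac.round(3))

dmrs = dmr.call_dmrs(petal, stamen, context="CG", chrom_sizes={"chr1": 60_000})
print(dmrs[["chrom", "start", "end", "direction", "ml_a", "ml_b", "p"]].round(3))
```

Output:

```
         n_tested  n_methylated  share_of_methylated_pct  methylated_ratio
context
CG           4542          2768                   51.767             0.609
CHG          3772          1464                   27.380             0.388
CHH         15075          1115                   20.853             0.074
  chrom  start    end direction   ml_a   ml_b    p
0  chr1  19200  22900      hypo  0.705  0.333  0.0
```

The per-context methylated-site ratios recover the generator's rates
(0.6 / 0.4 / 0.08 for CG / CHG / CHH), and the single planted region comes
back as one merged hypomethylated DMR covering the planted span (the ~900 bp
overhang on each side is the sliding-window resolution limit).

The same analysis is available from the shell:

```bash
bsmeth simulate --seed 1 --outdir fixture
bsmeth methylome --cx fixture/cx_petal.txt --outdir out
bsmeth dmr --cx-a fixture/cx_petal.txt --cx-b fixture/cx_stamen.txt \
           --window 1000 --step 100 --alpha 0.01 \
           --annotation fixture/annotation.gff3 --outdir out
bsmeth run --config pipeline.yaml     # full pipeline + JSON manifest
```

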