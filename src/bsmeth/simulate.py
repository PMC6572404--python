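"""Synthetic genomes, methylomes, expression tables and clone sets.

The generator defines the study conditions the rest of the package is tested
against: a small multi-chromosome genome with genes and repeats, three organ
samples whose cytosines carry context-dependent methylation (high CG, middle
CHG, low CHH), binomially sampled read counts at Poisson coverage, planted
differentially methylated regions between sample pairs, and an expression
table in which genes with a hypomethylated promoter DMR can be forced
up-regulated.

Methylation architecture. ``base_rates`` give the probability that a site of
a context is methylated at all (a Bernoulli site state, matching how
per-context methylation ratios are reported as site fractions). A methylated
site draws its true methylation level from a per-context Beta distribution
(CG concentrated near 1, CHG broad, CHH low); an unmethylated site has level
0. Baseline states and levels are drawn once per seed and shared by all
samples, so samples differ only inside planted DMRs, whose (rate_A, rate_B)
override the per-site level directly. Read counts are then
``Binomial(Poisson(coverage), r + (1 - r) * conversion_error)`` — the
forward model whose inversion is the binomial site caller.

Context labels here come from a regular-expression scan of both strands,
deliberately independent of :func:`bsmeth.core.classify_context`, so the two
implementations can be checked against each other.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core
from ._intervals import covered_mask, merge_intervals
from .errors import ConfigError
from .io_formats import AnnotationSet, Gene

__all__ = [
    "PlantedDmr",
    "SimulationConfig",
    "simulate_genome",
    "simulate_methylome",
    "simulate_expression",
    "simulate_clones",
    "contexts_by_regex",
    "plant_promoter_dmrs",
]


@dataclass(frozen=True)
class PlantedDmr:
    """A region whose per-site methylation level differs between two samples."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    context: str
    sample_a: str
    sample_b: str
    rate_a: float
    rate_b: float

    def __post_init__(self):
        if not (0 <= self.rate_a <= 1 and 0 <= self.rate_b <= 1):
            raise ConfigError("planted DMR rates must be in [0, 1]")
        if self.rate_a == self.rate_b:
            raise ConfigError("planted DMR must have rate_a != rate_b")
        if self.end <= self.start:
            raise ConfigError("planted DMR span is empty")


@dataclass
class SimulationConfig:
    """Ground-truth generator parameters; fixed seed means byte-identical output."""

    seed: int = 0
    n_chroms: int = 3
    chrom_len: int = 100_000
    gc_content: float = 0.39
    n_genes: int = 60
    gene_len: tuple[int, int] = (1500, 4000)
    max_exons: int = 5
    n_repeats: int = 80
    repeat_len: tuple[int, int] = (150, 800)
    promoter_span: int = 2000
    samples: tuple[str, ...] = ("petal", "stamen_petaloid", "stamen")
    base_rates: dict = field(
        default_factory=lambda: {"CG": 0.6, "CHG": 0.4, "CHH": 0.08}
    )
    level_beta: dict = field(
        default_factory=lambda: {"CG": (8.0, 1.5), "CHG": (1.3, 1.3), "CHH": (2.0, 8.0)}
    )
    mean_coverage: float = 30.0
    conversion_error: float = 0.005
    uniform_rate: float | None = None
    feature_rates: dict | None = None  # {"exon": 0.2, ...}: per-site level override
    planted_dmrs: tuple = ()
    planted_assoc: float = 0.8
    background_deg_rate: float = 0.05
    fpkm_log_mean: float = 0.0
    fpkm_log_sd: float = 1.5

    def __post_init__(self):
        for name in ("gc_content", "conversion_error", "planted_assoc", "background_deg_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for ctx, r in self.base_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"base_rates[{ctx}] must be in [0, 1]")
        if self.uniform_rate is not None and not (0.0 <= self.uniform_rate <= 1.0):
            raise ConfigError("uniform_rate must be in [0, 1]")
        if self.mean_coverage < 0:
            raise ConfigError("mean_coverage must be >= 0")
        self.planted_dmrs = tuple(
            d if isinstance(d, PlantedDmr) else PlantedDmr(**d) for d in self.planted_dmrs
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Context scan (independent of core.classify_context)

_FWD_PATTERNS = (
    ("CG", re.compile(r"(?=(CG[ACGT]))")),
    ("CHG", re.compile(r"(?=(C[ACT]G))")),
    ("CHH", re.compile(r"(?=(C[ACT][ACT]))")),
)


def contexts_by_regex(seq: str) -> pd.DataFrame:
    """Contexts of every cytosine on both strands via regex scan.

    Returns columns pos (1-based), strand, context, trinucleotide. A cytosine
    whose two following strand bases are not both A/C/G/T (including within
    2 bp of the contig end) is Unknown.
    """
    seq = seq.upper()
    rc = core.revcomp(seq)
    n = len(seq)
    rows = []
    for strand, s in (("+", seq), ("-", rc)):
        ctx_at = {}
        tri_at = {}
        for label, pat in _FWD_PATTERNS:
            for m in pat.finditer(s):
                ctx_at[m.start()] = label
                tri_at[m.start()] = s[m.start() : m.start() + 3]
        for i, base in enumerate(s):
            if base != "C":
                continue
            ctx = ctx_at.get(i, "Unknown")
            tri = tri_at.get(i) or (s[i : i + 3] + "N" * (3 - len(s[i : i + 3])))
            pos = i + 1 if strand == "+" else n - i  # map back to forward coords
            rows.append((pos, strand, ctx, tri))
    df = pd.DataFrame(rows, columns=["pos", "strand", "context", "trinucleotide"])
    return df.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Genome and annotation

_MIN_GENE_GAP = 200
_MIN_EXON = 100
_MIN_INTRON = 60


def simulate_genome(config: SimulationConfig):
    """Random genome at the configured GC plus a non-overlapping gene annotation.

    Genes carry 1–5 exons; repeats are dropped into intergenic space (they may
    overlap one another). Deterministic under the config seed.
    """
    rng = np.random.default_rng([int(config.seed), 101])
    p_gc = config.gc_content / 2.0
    p_at = (1.0 - config.gc_content) / 2.0
    genome: dict[str, str] = {}
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    for chrom in chrom_names:
        bases = rng.choice(
            np.array(list("ACGT")), size=config.chrom_len, p=[p_at, p_gc, p_gc, p_at]
        )
        genome[chrom] = "".join(bases)

    # distribute genes over chromosomes round-robin
    per_chrom: dict[str, int] = {c: 0 for c in chrom_names}
    for k in range(config.n_genes):
        per_chrom[chrom_names[k % len(chrom_names)]] += 1

    genes = []
    counter = 0
    for chrom in chrom_names:
        n = per_chrom[chrom]
        if n == 0:
            continue
        lens = rng.integers(config.gene_len[0], config.gene_len[1] + 1, size=n)
        margin = _MIN_GENE_GAP
        leftover = config.chrom_len - int(lens.sum()) - 2 * margin - (n - 1) * _MIN_GENE_GAP
        if leftover < 0:
            raise ConfigError(
                f"genome too small: cannot place {n} genes of total length "
                f"{int(lens.sum())} on a {config.chrom_len} bp chromosome"
            )
        extra = rng.multinomial(leftover, np.full(n + 1, 1.0 / (n + 1)))
        pos = margin + int(extra[0])
        for j in range(n):
            counter += 1
            start, end = pos, pos + int(lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _random_exons(rng, start, end, config.max_exons)
            genes.append(Gene(f"g{counter:04d}", chrom, strand, start, end, exons))
            pos = end + _MIN_GENE_GAP + int(extra[j + 1])

    gene_ivs: dict[str, list] = {c: [] for c in chrom_names}
    for g in genes:
        gene_ivs[g.chrom].append((g.start, g.end))
    repeats = []
    for _ in range(config.n_repeats):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        rlen = int(rng.integers(config.repeat_len[0], config.repeat_len[1] + 1))
        starts, ends = merge_intervals(gene_ivs[chrom])
        for _attempt in range(50):
            s = int(rng.integers(0, max(1, config.chrom_len - rlen)))
            inside = covered_mask(starts, ends, np.array([s, s + rlen - 1]))
            if not inside.any():
                repeats.append((chrom, s, s + rlen))
                break
    ann = AnnotationSet(genes=genes, repeats=sorted(repeats), promoter_span=config.promoter_span)
    return genome, ann


def _random_exons(rng, start, end, max_exons):
    glen = end - start
    k_max = min(max_exons, (glen + _MIN_INTRON) // (_MIN_EXON + _MIN_INTRON))
    k = int(rng.integers(1, max(1, k_max) + 1))
    if k == 1:
        return [(start, end)]
    n_seg = 2 * k - 1  # exon, intron, exon, ...
    base = np.array([_MIN_EXON if i % 2 == 0 else _MIN_INTRON for i in range(n_seg)])
    extra = rng.multinomial(glen - int(base.sum()), np.full(n_seg, 1.0 / n_seg))
    seg = base + extra
    exons = []
    pos = start
    for i, L in enumerate(seg):
        if i % 2 == 0:
            exons.append((pos, pos + int(L)))
        pos += int(L)
    exons[-1] = (exons[-1][0], end)  # absorb rounding into the last exon
    return exons


# ---------------------------------------------------------------------------
# Methylome


def _baseline_rates(site_table: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Per-site true methylation level, shared by all samples (seed-determined)."""
    rng = np.random.default_rng([int(config.seed), 7])
    n = len(site_table)
    ctx = site_table["context"].to_numpy()
    # draw in fixed order so the stream is identical regardless of caller
    state_u = rng.random(n)
    level_u = rng.random(n)
    r = np.zeros(n)
    if config.uniform_rate is not None:
        return np.full(n, float(config.uniform_rate))
    from scipy.stats import beta as beta_dist

    for c in core.CONTEXTS:
        mask = ctx == c
        if not mask.any():
            continue
        a, b = config.level_beta[c]
        state = state_u[mask] < config.base_rates[c]
        levels = beta_dist.ppf(level_u[mask], a, b)
        r[mask] = np.where(state, levels, 0.0)
    return r


def _apply_feature_rates(r, site_table, ann: AnnotationSet, config: SimulationConfig):
    if not config.feature_rates:
        return r
    classes = _feature_class_intervals(ann)
    pos0 = site_table["pos"].to_numpy() - 1
    chroms = site_table["chrom"].to_numpy()
    for cls, rate in config.feature_rates.items():
        if cls not in classes:
            raise ConfigError(f"unknown feature class {cls!r} in feature_rates")
        for chrom, (starts, ends) in classes[cls].items():
            mask = (chroms == chrom) & covered_mask(starts, ends, pos0)
            r[mask] = float(rate)
    return r


def _feature_class_intervals(ann: AnnotationSet):
    by_class: dict[str, dict[str, list]] = {
        "promoter": {}, "exon": {}, "intron": {}, "repeat": {}, "downstream": {},
    }
    for g in ann.genes:
        by_class["promoter"].setdefault(g.chrom, []).append(ann.promoter(g))
        by_class["downstream"].setdefault(g.chrom, []).append(ann.downstream(g))
        by_class["exon"].setdefault(g.chrom, []).extend(g.exons)
        by_class["intron"].setdefault(g.chrom, []).extend(g.introns())
    for chrom, s, e in ann.repeats:
        by_class["repeat"].setdefault(chrom, []).append((s, e))
    return {
        cls: {chrom: merge_intervals(ivs) for chrom, ivs in per.items()}
        for cls, per in by_class.items()
    }


def simulate_methylome(
    genome: dict[str, str],
    ann: AnnotationSet,
    config: SimulationConfig,
    sample_id: str,
):
    """CX-style count table plus per-site truth rates for one sample.

    Returns ``(sites, truth)``: ``sites`` has the seven CX columns; ``truth``
    adds the true per-site rate actually used for sampling.
    """
    if sample_id not in config.samples:
        raise ConfigError(f"unknown sample {sample_id!r}; configured: {config.samples}")
    sample_idx = list(config.samples).index(sample_id)

    frames = []
    for chrom in genome:
        tbl = contexts_by_regex(genome[chrom])
        tbl.insert(0, "chrom", chrom)
        frames.append(tbl)
    site_table = pd.concat(frames, ignore_index=True)
    site_table = site_table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )

    r = _baseline_rates(site_table, config)
    r = _apply_feature_rates(r, site_table, ann, config)

    pos0 = site_table["pos"].to_numpy() - 1
    chroms = site_table["chrom"].to_numpy()
    ctx = site_table["context"].to_numpy()
    for dmr in config.planted_dmrs:
        if sample_id == dmr.sample_a:
            rate = dmr.rate_a
        elif sample_id == dmr.sample_b:
            rate = dmr.rate_b
        else:
            continue
        mask = (chroms == dmr.chrom) & (pos0 >= dmr.start) & (pos0 < dmr.end)
        if dmr.context not in (None, "all"):
            mask &= ctx == dmr.context
        r[mask] = rate

    rng = np.random.default_rng([int(config.seed), 1000 + sample_idx])
    n = len(site_table)
    coverage = rng.poisson(config.mean_coverage, size=n)
    p_eff = r + (1.0 - r) * config.conversion_error
    count_meth = rng.binomial(coverage, p_eff)
    sites = site_table.copy()
    sites["count_meth"] = count_meth
    sites["count_unmeth"] = coverage - count_meth
    sites = sites[
        ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "trinucleotide"]
    ]
    truth = site_table[["chrom", "pos", "strand", "context"]].copy()
    truth["rate"] = r
    return sites, truth


def plant_promoter_dmrs(
    ann: AnnotationSet,
    genes,
    sample_a: str,
    sample_b: str,
    rate_a: float = 0.8,
    rate_b: float = 0.2,
    context: str = "CG",
) -> list[PlantedDmr]:
    """Planted DMRs covering the promoters of the named genes.

    ``rate_b < rate_a`` plants hypomethylation in sample B, the configuration
    used to couple promoter hypo-DMRs to up-regulation.
    """
    wanted = set(genes)
    out = []
    for g in ann.genes:
        if g.gene_id in wanted:
            s, e = ann.promoter(g)
            out.append(PlantedDmr(g.chrom, s, e, context, sample_a, sample_b, rate_a, rate_b))
    missing = wanted - {g.gene_id for g in ann.genes}
    if missing:
        raise ConfigError(f"genes not in annotation: {sorted(missing)}")
    return out


# ---------------------------------------------------------------------------
# Expression


def _promoter_hypo_genes(ann: AnnotationSet, planted, sample_a, sample_b):
    """Genes whose promoter overlaps a planted DMR hypomethylated in sample_b."""
    spans = []
    for d in planted:
        pair = {d.sample_a: d.rate_a, d.sample_b: d.rate_b}
        if sample_a in pair and sample_b in pair and pair[sample_b] < pair[sample_a]:
            spans.append(d)
    hits = set()
    for g in ann.genes:
        ps, pe = ann.promoter(g)
        for d in spans:
            if d.chrom == g.chrom and d.start < pe and ps < d.end:
                hits.add(g.gene_id)
    return hits


def simulate_expression(ann: AnnotationSet, planted_dmrs, config: SimulationConfig):
    """FPKM table and a fold-change/FDR DEG table for every sample pair.

    Genes whose promoter overlaps a DMR planted hypomethylated in the second
    sample of a comparison are forced up-regulated (fold change >= 2, FDR
    drawn below 0.05) with probability ``planted_assoc``; all other genes get
    a small background DEG rate, independent of methylation.

    Returns ``(fpkm, degs)``. ``degs`` carries a ``planted_up`` truth column.
    """
    rng = np.random.default_rng([int(config.seed), 42])
    gene_ids = [g.gene_id for g in ann.genes]
    n = len(gene_ids)
    fpkm = pd.DataFrame({"gene_id": gene_ids})
    for s in config.samples:
        fpkm[f"fpkm_{s}"] = np.round(
            rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd, size=n), 4
        )

    comparisons = [
        (a, b) for i, a in enumerate(config.samples) for b in config.samples[i + 1 :]
    ]
    rows = []
    for a, b in comparisons:
        hypo_genes = _promoter_hypo_genes(ann, planted_dmrs, a, b)
        forced = rng.random(n) < config.planted_assoc
        bg = rng.random(n)
        up_lfc = rng.uniform(1.0, 3.0, size=n)
        dn_lfc = -rng.uniform(1.0, 3.0, size=n)
        ns_lfc = rng.normal(0.0, 0.3, size=n)
        sig_fdr = rng.uniform(0.0, 0.0499, size=n)
        ns_fdr = rng.uniform(0.05, 1.0, size=n)
        for i, gid in enumerate(gene_ids):
            planted_up = gid in hypo_genes and forced[i]
            if planted_up:
                lfc, fdr = up_lfc[i], sig_fdr[i]
            elif bg[i] < config.background_deg_rate:
                lfc, fdr = up_lfc[i], sig_fdr[i]
            elif bg[i] < 2 * config.background_deg_rate:
                lfc, fdr = dn_lfc[i], sig_fdr[i]
            else:
                lfc, fdr = ns_lfc[i], ns_fdr[i]
            rows.append(
                {
                    "gene_id": gid,
                    "comparison": f"{a}_vs_{b}",
                    "log2fc": round(float(lfc), 4),
                    "fdr": round(float(fdr), 5),
                    "planted_up": bool(planted_up),
                }
            )
    return fpkm, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clones


def simulate_clones(
    amplicon: str,
    per_site_rates,
    n_clones: int = 10,
    conversion_error: float = 0.0,
    seed: int = 0,
):
    """Bisulfite-converted clone sequences from an amplicon.

    ``per_site_rates`` is either a single rate for every cytosine or a
    {0-based amplicon position: rate} map (unlisted cytosines get rate 0).
    Each clone keeps a cytosine as C with its site's probability; otherwise
    the base reads T, except that conversion fails (C retained) with
    probability ``conversion_error``.

    Returns a list of ``(clone_id, sequence)`` pairs.
    """
    amplicon = amplicon.upper()
    c_pos = [i for i, b in enumerate(amplicon) if b == "C"]
    if not c_pos:
        raise ConfigError("amplicon contains no cytosines")
    if isinstance(per_site_rates, dict):
        rates = {int(k): float(v) for k, v in per_site_rates.items()}
        rate_at = {i: rates.get(i, 0.0) for i in c_pos}
    else:
        rate_at = {i: float(per_site_rates) for i in c_pos}
    for i, v in rate_at.items():
        if not (0.0 <= v <= 1.0):
            raise ConfigError(f"rate at position {i} outside [0, 1]")
    rng = np.random.default_rng([int(seed), 77])
    clones = []
    for k in range(n_clones):
        bases = list(amplicon)
        for i in c_pos:
            methylated = rng.random() < rate_at[i]
            if not methylated:
                converted = rng.random() >= conversion_error
                if converted:
                    bases[i] = "T"
        clones.append((f"clone{k + 1:02d}", "".join(bases)))
    return clones


# ---------------------------------------------------------------------------
# Fixture writer


def write_fixture(config: SimulationConfig, outdir) -> dict:
    """Materialise a full simulated dataset (genome, annotation, CX reports,
    truth tables, FPKM and DEG tables) under ``outdir``. Returns file paths."""
    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, ann = simulate_genome(config)
    paths = {}
    paths["genome"] = outdir / "genome.fa"
    io_formats.write_fasta(genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gff3"
    io_formats.write_annotation_gff3(ann, paths["annotation"])
    for s in config.samples:
        sites, truth = simulate_methylome(genome, ann, config, s)
        paths[f"cx_{s}"] = outdir / f"cx_{s}.txt"
        io_formats.write_cx_report(sites, paths[f"cx_{s}"])
        paths[f"truth_{s}"] = outdir / f"truth_sites_{s}.tsv"
        truth.to_csv(paths[f"truth_{s}"], sep="\t", index=False)
    fpkm, degs = simulate_expression(ann, config.planted_dmrs, config)
    paths["fpkm"] = outdir / "fpkm.tsv"
    fpkm.to_csv(paths["fpkm"], sep="\t", index=False)
    paths["degs"] = outdir / "degs.tsv"
    degs.to_csv(paths["degs"], sep="\t", index=False)
    if config.planted_dmrs:
        pd.DataFrame([d.__dict__ for d in config.planted_dmrs]).to_csv(
            outdir / "truth_dmrs.tsv", sep="\t", index=False
        )
        paths["truth_dmrs"] = outdir / "truth_dmrs.tsv"
    return paths
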