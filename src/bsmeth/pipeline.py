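"""End-to-end pipeline: simulate or load inputs, then run every stage in
dependency order (core -> motifs/profiles -> dmr -> integration), writing
tables, tracks and a JSON run manifest with checksums.

Reruns with an identical config and seed are byte-identical for every
deterministic stage, which is all of them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, core, dmr as dmr_mod, integration, io_formats, motifs, profiles
from .errors import ConfigError
from .simulate import SimulationConfig, write_fixture

log = logging.getLogger("bsmeth")

_DEFAULTS = {
    "methylome": {"conversion_error": 0.005, "alpha": 0.05, "bin_size": 10_000},
    "dmr": {
        "window": 1000,
        "step": 100,
        "alpha": 0.01,
        "min_sites": 5,
        "min_cov": 4,
        "min_ml_diff": 0.1,
        "merge_gap": None,
        "contexts": ["CG", "CHG", "CHH"],
    },
    "profiles": {"n_bins_flank": 20, "n_bins_body": 20},
    "integration": {"fc_threshold": 2.0, "fdr_threshold": 0.05},
}


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source)
    merged = {"seed": int(cfg.get("seed", 0))}
    for section, defaults in _DEFAULTS.items():
        merged[section] = {**defaults, **cfg.get(section, {})}
    for key in ("simulate", "inputs", "outdir"):
        if key in cfg:
            merged[key] = cfg[key]
    if "simulate" not in merged and "inputs" not in merged:
        raise ConfigError("config needs either a 'simulate' or an 'inputs' section")
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate_inputs(inputs: dict) -> None:
    missing = []
    for key in ("genome", "annotation"):
        if key not in inputs or not Path(inputs[key]).exists():
            missing.append(key)
    for sample, path in inputs.get("cx_reports", {}).items():
        if not Path(path).exists():
            missing.append(f"cx_reports[{sample}]")
    for key in ("fpkm", "degs"):
        if key in inputs and not Path(inputs[key]).exists():
            missing.append(key)
    if missing:
        raise ConfigError(f"missing input files: {', '.join(missing)}")


def run_pipeline(config, outdir=None) -> dict:
    """Run the full analysis; returns the manifest dict (also written as JSON)."""
    cfg = load_config(config)
    outdir = Path(outdir or cfg.get("outdir") or "bsmeth_out")
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]

    # --- stage: inputs -----------------------------------------------------
    if "simulate" in cfg:
        log.info("stage simulate: generating fixture")
        sim_cfg = SimulationConfig(**{"seed": seed, **(cfg["simulate"] or {})})
        fixture_dir = outdir / "fixture"
        paths = write_fixture(sim_cfg, fixture_dir)
        genome = io_formats.read_fasta(paths["genome"])
        ann = io_formats.read_annotation(
            paths["annotation"], promoter_span=sim_cfg.promoter_span
        )
        samples = list(sim_cfg.samples)
        cx_paths = {s: paths[f"cx_{s}"] for s in samples}
        fpkm = pd.read_csv(paths["fpkm"], sep="\t")
        degs = pd.read_csv(paths["degs"], sep="\t")
    else:
        inputs = cfg["inputs"]
        _validate_inputs(inputs)
        log.info("stage inputs: loading files")
        genome = io_formats.read_fasta(inputs["genome"])
        ann = io_formats.read_annotation(inputs["annotation"])
        cx_paths = dict(inputs.get("cx_reports", {}))
        samples = list(cx_paths)
        fpkm = pd.read_csv(inputs["fpkm"], sep="\t") if "fpkm" in inputs else None
        degs = pd.read_csv(inputs["degs"], sep="\t") if "degs" in inputs else None

    chrom_sizes = {c: len(s) for c, s in genome.items()}
    mcfg = cfg["methylome"]

    # --- stage: methylome core ---------------------------------------------
    called = {}
    for sample in samples:
        log.info("stage methylome: %s", sample)
        sites = io_formats.read_cx_report(cx_paths[sample])
        called[sample] = core.call_methylated_sites(
            sites, conversion_error=mcfg["conversion_error"], alpha=mcfg["alpha"]
        )
        core.genome_context_fractions(called[sample]).to_csv(
            outdir / f"context_fractions_{sample}.tsv", sep="\t"
        )
        for ctx in core.CONTEXTS:
            wml = core.windowed_ml(
                called[sample], bin_size=mcfg["bin_size"], context=ctx,
                chrom_sizes=chrom_sizes,
            )
            io_formats.write_bedgraph(
                wml, outdir / f"windowed_ml_{sample}_{ctx}.bedGraph"
            )
            core.ml_level_histogram(called[sample], context=ctx).to_csv(
                outdir / f"ml_histogram_{sample}_{ctx}.tsv", sep="\t", index=False
            )

    # --- stage: motifs ------------------------------------------------------
    for sample in samples:
        for ctx in core.CONTEXTS:
            table = motifs.build_motif_table(genome, called[sample], context=ctx)
            table.position_freqs.to_csv(
                outdir / f"motif_freqs_{sample}_{ctx}.tsv", sep="\t"
            )

    # --- stage: profiles ----------------------------------------------------
    pcfg = cfg["profiles"]
    for sample in samples:
        for ctx in core.CONTEXTS:
            profiles.feature_ml(called[sample], ann, context=ctx).to_csv(
                outdir / f"feature_ml_{sample}_{ctx}.tsv", sep="\t", index=False
            )
        classing = None
        if fpkm is not None:
            classing = profiles.classify_expression(fpkm, sample)
            classing.to_csv(outdir / f"expression_classes_{sample}.tsv", sep="\t", index=False)
        for ctx in core.CONTEXTS:
            prof = profiles.metagene_profile(
                called[sample], ann, context=ctx,
                n_bins_flank=pcfg["n_bins_flank"], n_bins_body=pcfg["n_bins_body"],
                classing=classing,
            )
            prof.to_csv(outdir / f"metagene_{sample}_{ctx}.tsv", sep="\t", index=False)
            if classing is not None:
                _per_gene, summary = profiles.ml_by_expression(
                    called[sample], ann, classing, context=ctx
                )
                summary.to_csv(
                    outdir / f"ml_by_expression_{sample}_{ctx}.tsv", sep="\t", index=False
                )

    # --- stage: dmr ---------------------------------------------------------
    dcfg = cfg["dmr"]
    pairs = [(a, b) for i, a in enumerate(samples) for b in samples[i + 1 :]]
    links_by_pair = {}
    for a, b in pairs:
        all_links = []
        for ctx in dcfg["contexts"]:
            log.info("stage dmr: %s vs %s (%s)", a, b, ctx)
            dmrs = dmr_mod.call_dmrs(
                called[a], called[b], context=ctx,
                window=dcfg["window"], step=dcfg["step"], alpha=dcfg["alpha"],
                min_sites=dcfg["min_sites"], min_cov=dcfg["min_cov"],
                min_ml_diff=dcfg["min_ml_diff"], merge_gap=dcfg["merge_gap"],
                chrom_sizes=chrom_sizes,
            )
            io_formats.write_dmr_bed(dmrs, outdir / f"dmrs_{a}_vs_{b}_{ctx}.bed")
            links, per_gene = dmr_mod.associate_genes(dmrs, ann)
            links.to_csv(outdir / f"dmr_genes_{a}_vs_{b}_{ctx}.tsv", sep="\t", index=False)
            dmr_mod.dmr_compartment_distribution(dmrs, ann).to_csv(
                outdir / f"dmr_compartments_{a}_vs_{b}_{ctx}.tsv", sep="\t", index=False
            )
            all_links.append(links)
        links_by_pair[(a, b)] = pd.concat(all_links, ignore_index=True)

    # --- stage: integration -------------------------------------------------
    if degs is not None:
        icfg = cfg["integration"]
        universe = {g.gene_id for g in ann.genes}
        enrich_rows = []
        for a, b in pairs:
            comp = f"{a}_vs_{b}"
            deg_sub = degs[degs["comparison"] == comp] if "comparison" in degs else degs
            statused = integration.filter_degs(
                deg_sub, fc_threshold=icfg["fc_threshold"], fdr_threshold=icfg["fdr_threshold"]
            )
            links = links_by_pair[(a, b)]
            dmr_sets = {
                direction: set(links.loc[links["direction"] == direction, "gene_id"])
                for direction in ("hypo", "hyper")
            }
            deg_sets = {
                status: set(statused.loc[statused["status"] == status, "gene_id"])
                for status in ("up", "down")
            }
            enrich_rows.append(
                integration.dmr_deg_enrichment(dmr_sets, deg_sets, universe, comparison=comp)
            )
            integration.venn_counts(
                {"dmr_genes": dmr_sets["hypo"] | dmr_sets["hyper"],
                 "up": deg_sets["up"], "down": deg_sets["down"]}
            ).to_csv(outdir / f"venn_{comp}.tsv", sep="\t", index=False)
        pd.concat(enrich_rows, ignore_index=True).to_csv(
            outdir / "dmr_deg_enrichment.tsv", sep="\t", index=False
        )

    # --- manifest -----------------------------------------------------------
    files = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "bsmeth_version": __version__,
        "seed": seed,
        "parameters": {k: cfg[k] for k in ("methylome", "dmr", "profiles", "integration")},
        "samples": samples,
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d files in %s", len(files), outdir)
    return manifest
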