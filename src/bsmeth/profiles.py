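"""Feature-level methylation, metagene profiles, and expression stratification.

Feature classes are promoter (upstream 2 kb of the TSS, strand-aware), exon,
intron and repeat. Metagene profiles average weighted methylation over a
common gene coordinate system: fixed-width bins across the upstream and
downstream 2 kb flanks and proportionally scaled bins across the gene body,
with the whole frame mirrored for minus-strand genes.

Expression classes follow the FPKM convention: *none* below 1, and *low* /
*medium* / *high* splitting the expressed genes (FPKM >= 1) at the lower and
upper quartiles. For the region-level comparison the classes are pooled into
L (none + low) and H (medium + high) and compared per region with a
two-sided Mann–Whitney U test on per-gene methylation levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._intervals import covered_mask
from .errors import ValidationError
from .io_formats import AnnotationSet
from .simulate import _feature_class_intervals

FEATURE_CLASSES = ("promoter", "exon", "intron", "repeat")
EXPRESSION_CLASSES = ("none", "low", "medium", "high")


def feature_ml(
    sites: pd.DataFrame, ann: AnnotationSet, context: str | None = None
) -> pd.DataFrame:
    """Pooled-count weighted ML per feature class.

    A site inside overlapping features counts once per class it touches.
    Classes with no covered sites get NaN.
    """
    sel = sites if context in (None, "all") else sites[sites["context"] == context]
    classes = _feature_class_intervals(ann)
    pos0 = sel["pos"].to_numpy() - 1
    chroms = sel["chrom"].to_numpy()
    m = sel["count_meth"].to_numpy()
    u = sel["count_unmeth"].to_numpy()
    rows = []
    for cls in FEATURE_CLASSES:
        mask = np.zeros(len(sel), dtype=bool)
        for chrom, (starts, ends) in classes[cls].items():
            cm = chroms == chrom
            if cm.any():
                mask[cm] |= covered_mask(starts, ends, pos0[cm])
        pm, pu = int(m[mask].sum()), int(u[mask].sum())
        rows.append(
            {
                "feature": cls,
                "context": context or "all",
                "n_sites": int(mask.sum()),
                "pooled_meth": pm,
                "pooled_unmeth": pu,
                "weighted_ml": pm / (pm + pu) if pm + pu else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression classes


def classify_expression(fpkm_table: pd.DataFrame, sample: str) -> pd.DataFrame:
    """Assign none/low/medium/high classes from one sample's FPKM column.

    *none*: FPKM < 1. Quartiles are computed over expressed genes only
    (FPKM >= 1); ties at a quartile boundary go to the lower class, so
    *low* is [1, q25], *medium* (q25, q75], *high* > q75. All genes below 1
    yields all-none with no error.
    """
    col = f"fpkm_{sample}" if f"fpkm_{sample}" in fpkm_table.columns else sample
    if col not in fpkm_table.columns:
        raise ValidationError(f"no FPKM column for sample {sample!r}")
    if len(fpkm_table) == 0:
        raise ValidationError("empty FPKM table")
    out = fpkm_table[["gene_id", col]].rename(columns={col: "fpkm"}).copy()
    fpkm = out["fpkm"].to_numpy(dtype=float)
    if (fpkm < 0).any():
        raise ValidationError("negative FPKM")
    cls = np.full(len(out), "none", dtype=object)
    expressed = fpkm >= 1.0
    if expressed.any():
        q25, q75 = np.percentile(fpkm[expressed], [25, 75])
        cls[expressed & (fpkm <= q25)] = "low"
        cls[expressed & (fpkm > q25) & (fpkm <= q75)] = "medium"
        cls[expressed & (fpkm > q75)] = "high"
    out["expr_class"] = cls
    return out


# ---------------------------------------------------------------------------
# Metagene profiles


def _chrom_site_arrays(sites: pd.DataFrame, context):
    sel = sites if context in (None, "all") else sites[sites["context"] == context]
    out = {}
    for chrom, sub in sel.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        out[chrom] = (
            sub["pos"].to_numpy() - 1,
            sub["count_meth"].to_numpy(),
            sub["count_unmeth"].to_numpy(),
        )
    return out


def _gene_bins(gene, flank, n_flank, n_body, pos0):
    """Bin index (0 .. 2*n_flank+n_body-1) for each position, -1 = outside."""
    w = flank / n_flank
    bins = np.full(pos0.shape, -1, dtype=np.int64)
    if gene.strand == "+":
        up_lo = gene.start - flank
        sel = (pos0 >= up_lo) & (pos0 < gene.start)
        bins[sel] = ((pos0[sel] - up_lo) // w).astype(np.int64)
        sel = (pos0 >= gene.start) & (pos0 < gene.end)
        bins[sel] = n_flank + (
            (pos0[sel] - gene.start) * n_body // gene.length
        ).astype(np.int64)
        sel = (pos0 >= gene.end) & (pos0 < gene.end + flank)
        bins[sel] = n_flank + n_body + ((pos0[sel] - gene.end) // w).astype(np.int64)
    else:
        sel = (pos0 >= gene.end) & (pos0 < gene.end + flank)
        bins[sel] = n_flank - 1 - ((pos0[sel] - gene.end) // w).astype(np.int64)
        sel = (pos0 >= gene.start) & (pos0 < gene.end)
        bins[sel] = n_flank + (
            (gene.end - 1 - pos0[sel]) * n_body // gene.length
        ).astype(np.int64)
        sel = (pos0 >= gene.start - flank) & (pos0 < gene.start)
        bins[sel] = (
            n_flank + n_body + ((gene.start - 1 - pos0[sel]) // w).astype(np.int64)
        )
    return bins


def metagene_profile(
    sites: pd.DataFrame,
    ann: AnnotationSet,
    context: str | None = None,
    n_bins_flank: int = 20,
    n_bins_body: int = 20,
    classing: pd.DataFrame | None = None,
    flank: int = 2000,
) -> pd.DataFrame:
    """Pooled weighted-ML metagene profile, optionally per expression class.

    Counts go to flank bins by absolute offset from the TSS/TES and to body
    bins by proportional position, strand-flipped for minus-strand genes.
    Genes shorter than ``n_bins_body`` bp are excluded (they cannot fill the
    body bins). Returns a tidy frame with one row per (class, bin); the
    ``all`` class always present.
    """
    class_of = {}
    if classing is not None:
        class_of = dict(zip(classing["gene_id"], classing["expr_class"]))
        missing = [g.gene_id for g in ann.genes if g.gene_id not in class_of]
        if missing:
            raise ValidationError(
                f"classing missing {len(missing)} genes (first: {missing[0]})"
            )
    by_chrom = _chrom_site_arrays(sites, context)
    n_tot = 2 * n_bins_flank + n_bins_body
    groups = ["all"] + (list(EXPRESSION_CLASSES) if classing is not None else [])
    acc = {g: np.zeros((n_tot, 2), dtype=np.int64) for g in groups}
    for gene in ann.genes:
        if gene.length < n_bins_body:
            continue
        if gene.chrom not in by_chrom:
            continue
        pos0, m, u = by_chrom[gene.chrom]
        lo = np.searchsorted(pos0, gene.start - flank)
        hi = np.searchsorted(pos0, gene.end + flank)
        if hi <= lo:
            continue
        bins = _gene_bins(gene, flank, n_bins_flank, n_bins_body, pos0[lo:hi])
        ok = bins >= 0
        if not ok.any():
            continue
        add_m = np.bincount(bins[ok], weights=m[lo:hi][ok], minlength=n_tot)
        add_u = np.bincount(bins[ok], weights=u[lo:hi][ok], minlength=n_tot)
        targets = ["all"]
        if classing is not None:
            targets.append(class_of[gene.gene_id])
        for t in targets:
            acc[t][:, 0] += add_m.astype(np.int64)
            acc[t][:, 1] += add_u.astype(np.int64)
    rows = []
    for g in groups:
        pm, pu = acc[g][:, 0], acc[g][:, 1]
        tot = pm + pu
        for b in range(n_tot):
            if b < n_bins_flank:
                region = "up2k"
            elif b < n_bins_flank + n_bins_body:
                region = "body"
            else:
                region = "down2k"
            rows.append(
                {
                    "expression_class": g,
                    "bin": b,
                    "region": region,
                    "context": context or "all",
                    "pooled_meth": int(pm[b]),
                    "pooled_unmeth": int(pu[b]),
                    "ml": pm[b] / tot[b] if tot[b] else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ML vs expression


def _gene_region_ml(sites_by_chrom, ann, gene, region, flank):
    if region == "up2k":
        s, e = ann.promoter(gene)
    elif region == "body":
        s, e = gene.start, gene.end
    elif region == "down2k":
        s, e = ann.downstream(gene)
    else:
        raise ValidationError(f"unknown region {region!r}")
    if gene.chrom not in sites_by_chrom:
        return np.nan
    pos0, m, u = sites_by_chrom[gene.chrom]
    lo, hi = np.searchsorted(pos0, (s, e))
    pm, pu = m[lo:hi].sum(), u[lo:hi].sum()
    return pm / (pm + pu) if pm + pu else np.nan


def ml_by_expression(
    sites: pd.DataFrame,
    ann: AnnotationSet,
    classing: pd.DataFrame,
    context: str | None = None,
    flank: int = 2000,
):
    """Per-gene region MLs grouped L (none+low) vs H (medium+high), with a
    two-sided Mann–Whitney U per region.

    Returns ``(per_gene, summary)``; a group with fewer than two genes gives
    an undefined (NaN) p flagged in the summary.
    """
    class_of = dict(zip(classing["gene_id"], classing["expr_class"]))
    by_chrom = _chrom_site_arrays(sites, context)
    regions = ("up2k", "body", "down2k")
    recs = []
    for gene in ann.genes:
        cls = class_of.get(gene.gene_id)
        if cls is None:
            raise ValidationError(f"gene {gene.gene_id} missing from classing")
        group = "L" if cls in ("none", "low") else "H"
        for region in regions:
            recs.append(
                {
                    "gene_id": gene.gene_id,
                    "region": region,
                    "expr_class": cls,
                    "group": group,
                    "ml": _gene_region_ml(by_chrom, ann, gene, region, flank),
                }
            )
    per_gene = pd.DataFrame(recs)
    rows = []
    for region in regions:
        sub = per_gene[(per_gene["region"] == region) & per_gene["ml"].notna()]
        mls_l = sub.loc[sub["group"] == "L", "ml"].to_numpy()
        mls_h = sub.loc[sub["group"] == "H", "ml"].to_numpy()
        if len(mls_l) < 2 or len(mls_h) < 2:
            stat, p, flagged = np.nan, np.nan, True
        elif np.ptp(np.concatenate([mls_l, mls_h])) == 0:
            # every value tied: no evidence either way (degenerate U test)
            stat, p, flagged = len(mls_l) * len(mls_h) / 2.0, 1.0, False
        else:
            res = mannwhitneyu(mls_l, mls_h, alternative="two-sided")
            stat, p, flagged = float(res.statistic), float(res.pvalue), False
        rows.append(
            {
                "region": region,
                "context": context or "all",
                "n_L": len(mls_l),
                "n_H": len(mls_h),
                "median_ml_L": float(np.median(mls_l)) if len(mls_l) else np.nan,
                "median_ml_H": float(np.median(mls_h)) if len(mls_h) else np.nan,
                "u_statistic": stat,
                "pvalue": p,
                "undefined": flagged,
            }
        )
    return per_gene, pd.DataFrame(rows)
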