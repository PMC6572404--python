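"""Sliding-window Fisher-exact differential methylation calling.

Two samples are compared over 1000 bp windows advanced in 100 bp steps.
In each window, pooled methylated and
unmethylated counts of the two samples form a 2x2 table tested with a
two-sided Fisher exact test; windows significant at ``alpha`` whose pooled
methylation levels also differ by at least ``min_ml_diff`` are kept, and
overlapping or near-adjacent kept windows of the same direction are merged
into DMRs. Merged regions are re-scored from their pooled counts — window
p-values are not combined, because overlapping windows are not independent.

Direction is reported for sample B relative to sample A: *hypo* means B is
less methylated over the merged region.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._intervals import merge_intervals, overlap_len
from ._stats import fisher_exact_2x2
from .errors import ConfigError, ValidationError
from .io_formats import AnnotationSet
from .simulate import _feature_class_intervals

DMR_COLUMNS = [
    "chrom", "start", "end", "context", "direction",
    "p", "p_min", "ml_a", "ml_b", "n_windows", "n_sites",
]


def sliding_windows(chrom_len: int, window: int = 1000, step: int = 100):
    """Window intervals [k*step, k*step + window) clipped at the chromosome end.

    Every base below ``chrom_len`` is covered by at least one window; windows
    that would start at or beyond the end of the previous clipped window are
    not emitted.
    """
    if not (window >= step >= 1):
        raise ConfigError("need window >= step >= 1")
    if chrom_len <= 0:
        return []
    n = max(0, math.ceil((chrom_len - window) / step))
    return [(k * step, min(k * step + window, chrom_len)) for k in range(n + 1)]


def _paired_sites(sites_a, sites_b, context, min_cov):
    cols = ["chrom", "pos", "strand", "count_meth", "count_unmeth"]
    a = sites_a if context in (None, "all") else sites_a[sites_a["context"] == context]
    b = sites_b if context in (None, "all") else sites_b[sites_b["context"] == context]
    merged = a[cols].merge(
        b[cols], on=["chrom", "pos", "strand"], suffixes=("_a", "_b")
    )
    cov_a = merged["count_meth_a"] + merged["count_unmeth_a"]
    cov_b = merged["count_meth_b"] + merged["count_unmeth_b"]
    merged = merged[(cov_a >= min_cov) & (cov_b >= min_cov)]
    return merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _chrom_cumsums(paired: pd.DataFrame):
    out = {}
    for chrom, sub in paired.groupby("chrom", sort=True):
        pos0 = sub["pos"].to_numpy() - 1
        cums = {
            key: np.concatenate([[0], np.cumsum(sub[key].to_numpy(dtype=np.int64))])
            for key in ("count_meth_a", "count_unmeth_a", "count_meth_b", "count_unmeth_b")
        }
        out[chrom] = (pos0, cums)
    return out


def _pool(cums, lo, hi):
    return tuple(
        int(cums[k][hi] - cums[k][lo])
        for k in ("count_meth_a", "count_unmeth_a", "count_meth_b", "count_unmeth_b")
    )


def window_test(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    interval: tuple[str, int, int],
    context: str | None = None,
    min_sites: int = 5,
    min_cov: int = 4,
):
    """Two-sided Fisher exact p for one interval (chrom, start, end), or None.

    Pools context sites inside the 0-based half-open interval that reach
    ``min_cov`` coverage in both samples; undefined (None) with fewer than
    ``min_sites`` qualifying sites.
    """
    if min_sites < 1:
        raise ConfigError("min_sites must be >= 1")
    chrom, start, end = interval
    paired = _paired_sites(sites_a, sites_b, context, min_cov)
    sub = paired[paired["chrom"] == chrom]
    pos0 = sub["pos"].to_numpy() - 1
    lo, hi = np.searchsorted(pos0, (start, end))
    if hi - lo < min_sites:
        return None
    ma = int(sub["count_meth_a"].to_numpy()[lo:hi].sum())
    ua = int(sub["count_unmeth_a"].to_numpy()[lo:hi].sum())
    mb = int(sub["count_meth_b"].to_numpy()[lo:hi].sum())
    ub = int(sub["count_unmeth_b"].to_numpy()[lo:hi].sum())
    return fisher_exact_2x2(ma, ua, mb, ub)


def window_scan(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    context: str | None = "CG",
    window: int = 1000,
    step: int = 100,
    min_sites: int = 5,
    min_cov: int = 4,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window pooled statistics and Fisher p for every testable window.

    Diagnostic companion to :func:`call_dmrs`; windows with fewer than
    ``min_sites`` qualifying sites are omitted (their p is undefined).
    """
    paired = _paired_sites(sites_a, sites_b, context, min_cov)
    rows = []
    for chrom, (pos0, cums) in _chrom_cumsums(paired).items():
        size = (
            int(chrom_sizes[chrom])
            if chrom_sizes is not None and chrom in chrom_sizes
            else int(pos0[-1]) + 1
        )
        for start, end in sliding_windows(size, window, step):
            lo, hi = np.searchsorted(pos0, (start, end))
            if hi - lo < min_sites:
                continue
            ma, ua, mb, ub = _pool(cums, lo, hi)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_sites": int(hi - lo),
                    "ml_a": ma / (ma + ua) if ma + ua else np.nan,
                    "ml_b": mb / (mb + ub) if mb + ub else np.nan,
                    "p": fisher_exact_2x2(ma, ua, mb, ub),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "ml_a", "ml_b", "p"]
    )


def call_dmrs(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    context: str | None = "CG",
    window: int = 1000,
    step: int = 100,
    alpha: float = 0.01,
    min_sites: int = 5,
    min_cov: int = 4,
    min_ml_diff: float = 0.1,
    merge_gap: int | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window Fisher DMR calling between two samples.

    Windows with p < ``alpha`` and |ml_a - ml_b| >= ``min_ml_diff`` are kept;
    same-direction kept windows separated by at most ``merge_gap`` bp
    (default: the step) merge into one DMR, re-scored over the union.
    """
    if sites_a is sites_b or (
        len(sites_a) == len(sites_b) and sites_a.reset_index(drop=True).equals(
            sites_b.reset_index(drop=True)
        )
    ):
        raise ValidationError("the same site collection was passed as both samples")
    if not (0 < alpha < 1):
        raise ConfigError("alpha must be in (0, 1)")
    if min_sites < 1:
        raise ConfigError("min_sites must be >= 1")
    if merge_gap is None:
        merge_gap = step

    paired = _paired_sites(sites_a, sites_b, context, min_cov)
    by_chrom = _chrom_cumsums(paired)
    dmrs = []
    for chrom in sorted(by_chrom):
        pos0, cums = by_chrom[chrom]
        size = (
            int(chrom_sizes[chrom])
            if chrom_sizes is not None and chrom in chrom_sizes
            else int(pos0[-1]) + 1
        )
        wins = sliding_windows(size, window, step)
        if not wins:
            continue
        starts = np.array([w[0] for w in wins])
        ends = np.array([w[1] for w in wins])
        lo = np.searchsorted(pos0, starts)
        hi = np.searchsorted(pos0, ends)
        kept = []  # (start, end, p, direction)
        for i in range(len(wins)):
            if hi[i] - lo[i] < min_sites:
                continue
            ma, ua, mb, ub = _pool(cums, lo[i], hi[i])
            if ma + ua == 0 or mb + ub == 0:
                continue
            ml_a = ma / (ma + ua)
            ml_b = mb / (mb + ub)
            if abs(ml_a - ml_b) < min_ml_diff:
                continue
            p = fisher_exact_2x2(ma, ua, mb, ub)
            if p >= alpha:
                continue
            kept.append((int(starts[i]), int(ends[i]), p, "hypo" if ml_b < ml_a else "hyper"))
        dmrs.extend(
            _merge_windows(kept, chrom, context, merge_gap, pos0, cums)
        )
    return pd.DataFrame(dmrs, columns=DMR_COLUMNS)


def _merge_windows(kept, chrom, context, merge_gap, pos0, cums):
    """Merge overlapping/near-adjacent same-direction windows and re-score."""
    out = []
    cluster: list | None = None
    for start, end, p, direction in kept:
        if cluster is not None and direction == cluster[3] and start <= cluster[1] + merge_gap:
            cluster[1] = max(cluster[1], end)
            cluster[2] = min(cluster[2], p)
            cluster[4] += 1
        else:
            if cluster is not None:
                out.append(_score_region(cluster, chrom, context, pos0, cums))
            cluster = [start, end, p, direction, 1]
    if cluster is not None:
        out.append(_score_region(cluster, chrom, context, pos0, cums))
    return out


def _score_region(cluster, chrom, context, pos0, cums):
    start, end, p_min, direction, n_windows = cluster
    lo, hi = np.searchsorted(pos0, (start, end))
    ma, ua, mb, ub = _pool(cums, lo, hi)
    ml_a = ma / (ma + ua) if ma + ua else np.nan
    ml_b = mb / (mb + ub) if mb + ub else np.nan
    p = fisher_exact_2x2(ma, ua, mb, ub)
    return {
        "chrom": chrom,
        "start": start,
        "end": end,
        "context": context or "all",
        "direction": "hypo" if ml_b < ml_a else "hyper",
        "p": p,
        "p_min": p_min,
        "ml_a": ml_a,
        "ml_b": ml_b,
        "n_windows": n_windows,
        "n_sites": int(hi - lo),
    }


# ---------------------------------------------------------------------------
# DMR-gene association


_COMPARTMENT_PRECEDENCE = ("promoter", "exon", "intron", "downstream")


def associate_genes(dmrs: pd.DataFrame, ann: AnnotationSet):
    """Link DMRs to genes they touch (gene body or +/- 2 kb flanks).

    Compartment per link follows the precedence promoter > exon > intron >
    downstream; repeat overlap is reported independently. Returns
    ``(links, per_gene)``.
    """
    span = ann.promoter_span
    trees: dict[str, IntervalTree] = {}
    for g in ann.genes:
        lo = max(0, g.start - span)
        hi = g.end + span
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)
    repeat_ivs: dict[str, tuple] = {}
    for chrom, grouped in _group_repeats(ann).items():
        repeat_ivs[chrom] = merge_intervals(grouped)

    links = []
    for idx, row in enumerate(dmrs.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        rep = False
        if row.chrom in repeat_ivs:
            rs, re_ = repeat_ivs[row.chrom]
            rep = overlap_len(rs, re_, int(row.start), int(row.end)) > 0
        for hit in sorted(tree.overlap(int(row.start), int(row.end)), key=lambda h: h.data.gene_id):
            gene = hit.data
            compartment = _compartment(row, gene, ann)
            links.append(
                {
                    "dmr_index": idx,
                    "chrom": row.chrom,
                    "start": int(row.start),
                    "end": int(row.end),
                    "context": row.context,
                    "direction": row.direction,
                    "gene_id": gene.gene_id,
                    "compartment": compartment,
                    "repeat_overlap": rep,
                }
            )
    links_df = pd.DataFrame(
        links,
        columns=[
            "dmr_index", "chrom", "start", "end", "context", "direction",
            "gene_id", "compartment", "repeat_overlap",
        ],
    )
    if len(links_df):
        per_gene = (
            links_df.groupby("gene_id")
            .agg(
                n_dmrs=("dmr_index", "nunique"),
                n_hypo=("direction", lambda d: int((d == "hypo").sum())),
                n_hyper=("direction", lambda d: int((d == "hyper").sum())),
                compartments=("compartment", lambda c: ",".join(sorted(set(c)))),
            )
            .reset_index()
        )
    else:
        per_gene = pd.DataFrame(
            columns=["gene_id", "n_dmrs", "n_hypo", "n_hyper", "compartments"]
        )
    return links_df, per_gene


def _intersects(s1, e1, s2, e2):
    return s1 < e2 and s2 < e1


def _compartment(dmr_row, gene, ann: AnnotationSet) -> str:
    s, e = int(dmr_row.start), int(dmr_row.end)
    ps, pe = ann.promoter(gene)
    if _intersects(s, e, ps, pe):
        return "promoter"
    if any(_intersects(s, e, xs, xe) for xs, xe in gene.exons):
        return "exon"
    if any(_intersects(s, e, is_, ie) for is_, ie in gene.introns()):
        return "intron"
    ds, de = ann.downstream(gene)
    if _intersects(s, e, ds, de):
        return "downstream"
    # only reachable for degenerate annotations; fall back to the flank side
    return "downstream"


def _group_repeats(ann: AnnotationSet):
    out: dict[str, list] = {}
    for chrom, s, e in ann.repeats:
        out.setdefault(chrom, []).append((s, e))
    return out


_DIST_PRECEDENCE = ("promoter", "exon", "intron", "repeat", "other")


def dmr_compartment_distribution(dmrs: pd.DataFrame, ann: AnnotationSet) -> pd.DataFrame:
    """Primary-compartment shares over DMRs (promoter/exon/intron/repeat/other).

    Each DMR is assigned the single class with maximal bp overlap, ties
    resolved by the precedence promoter > exon > intron > repeat > other;
    shares sum to 100. Empty input gives an empty distribution.
    """
    if len(dmrs) == 0:
        return pd.DataFrame(columns=["compartment", "n_dmrs", "share_pct"])
    classes = _feature_class_intervals(ann)
    assigned = []
    for row in dmrs.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        lengths = {}
        covered = []
        for cls in ("promoter", "exon", "intron", "repeat"):
            ivs = classes[cls].get(row.chrom)
            if ivs is None:
                lengths[cls] = 0
                continue
            starts, ends = ivs
            lengths[cls] = overlap_len(starts, ends, s, e)
            covered.extend(
                (max(int(a), s), min(int(b), e))
                for a, b in zip(starts, ends)
                if a < e and s < b
            )
        cs, ce = merge_intervals(covered)
        lengths["other"] = (e - s) - int(np.sum(ce - cs)) if len(cs) else e - s
        best = max(_DIST_PRECEDENCE, key=lambda c: (lengths[c], -_DIST_PRECEDENCE.index(c)))
        assigned.append(best)
    counts = pd.Series(assigned).value_counts()
    rows = [
        {
            "compartment": cls,
            "n_dmrs": int(counts.get(cls, 0)),
            "share_pct": 100.0 * counts.get(cls, 0) / len(assigned),
        }
        for cls in _DIST_PRECEDENCE
    ]
    return pd.DataFrame(rows)
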