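"""Cytosine-context classification and methylation-level statistics.

The sequencing readout is the per-site pair (methylated count, unmethylated
count). A site's methylation level is ML = mC / (mC + umC); it is *undefined*
(NaN) at zero coverage, never zero. "Weighted" methylation levels pool read
counts before dividing, so deeply covered sites carry proportionally more
weight than in a mean-of-fractions.

A site is *called* methylated by a one-sided exact binomial test against the
bisulfite non-conversion rate: under H0 the methylated count is
Binomial(coverage, conversion_error), and H1 is a methylation rate above it.
P-values are Benjamini–Hochberg corrected across tested sites by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._stats import benjamini_hochberg
from .errors import ConfigError, ValidationError

CONTEXTS = ("CG", "CHG", "CHH")

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_context(genome: dict[str, str], chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at 1-based ``pos`` on ``strand``.

    The context is read from the next two bases 5'→3' on the cytosine's own
    strand: CG when the next base is G, CHG when base+2 is G, CHH otherwise
    (H = A/C/T). Returns ``"Unknown"`` within 2 bp of a contig end or when
    either following base is not A/C/G/T.
    """
    seq = genome[chrom]
    i = pos - 1
    if strand == "+":
        if seq[i] != "C":
            raise ValidationError(f"{chrom}:{pos}(+) is {seq[i]!r}, not a cytosine")
        if i + 2 >= len(seq):
            return "Unknown"
        b1, b2 = seq[i + 1], seq[i + 2]
    elif strand == "-":
        if seq[i] != "G":
            raise ValidationError(f"{chrom}:{pos}(-) is {seq[i]!r}, not a cytosine")
        if i - 2 < 0:
            return "Unknown"
        b1 = _COMP.get(seq[i - 1], "N")
        b2 = _COMP.get(seq[i - 2], "N")
    else:
        raise ValidationError(f"bad strand {strand!r}")
    if b1 not in _COMP or b2 not in _COMP:
        return "Unknown"
    if b1 == "G":
        return "CG"
    if b2 == "G":
        return "CHG"
    return "CHH"


def _trinuc_fwd(seq: str, i: int) -> str:
    t = seq[i : i + 3]
    return t + "N" * (3 - len(t))


def _trinuc_rev(seq: str, i: int) -> str:
    lo = max(0, i - 2)
    t = revcomp(seq[lo : i + 1])
    return t + "N" * (3 - len(t))


def genome_cytosine_table(genome: dict[str, str]) -> pd.DataFrame:
    """All cytosines on both strands with context and trinucleotide.

    Vectorised equivalent of calling :func:`classify_context` at every
    cytosine; positions are 1-based (CX convention), sorted by (chrom, pos).
    """
    A, C, G, T = (ord(x) for x in "ACGT")
    valid = np.zeros(256, dtype=bool)
    valid[[A, C, G, T]] = True
    comp = np.zeros(256, dtype=np.uint8)
    comp[A], comp[C], comp[G], comp[T] = T, G, C, A

    frames = []
    for chrom in genome:
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = arr.size
        pad = np.concatenate([arr, np.zeros(2, dtype=np.uint8)])

        # forward-strand cytosines
        idx = np.flatnonzero(arr == C)
        if idx.size:
            b1, b2 = pad[idx + 1], pad[idx + 2]
            ok = (idx <= n - 3) & valid[b1] & valid[b2]
            code = np.where(~ok, 3, np.where(b1 == G, 0, np.where(b2 == G, 1, 2)))
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx + 1,
                        "strand": "+",
                        "context": _decode_context(code),
                        "trinucleotide": [_trinuc_fwd(seq, int(i)) for i in idx],
                    }
                )
            )
        # reverse-strand cytosines (G on the forward sequence)
        idx = np.flatnonzero(arr == G)
        if idx.size:
            prev1 = np.where(idx >= 1, pad[np.maximum(idx - 1, 0)], 0)
            prev2 = np.where(idx >= 2, pad[np.maximum(idx - 2, 0)], 0)
            b1, b2 = comp[prev1], comp[prev2]
            ok = (idx >= 2) & valid[prev1] & valid[prev2]
            code = np.where(~ok, 3, np.where(b1 == G, 0, np.where(b2 == G, 1, 2)))
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx + 1,
                        "strand": "-",
                        "context": _decode_context(code),
                        "trinucleotide": [_trinuc_rev(seq, int(i)) for i in idx],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "trinucleotide"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _decode_context(code: np.ndarray) -> np.ndarray:
    return np.array(["CG", "CHG", "CHH", "Unknown"], dtype=object)[code]


# ---------------------------------------------------------------------------
# Site-level statistics


def site_ml(count_meth, count_unmeth):
    """ML = mC/(mC+umC); NaN (undefined) at zero coverage. Array- or scalar-valued."""
    m = np.asarray(count_meth, dtype=float)
    u = np.asarray(count_unmeth, dtype=float)
    cov = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        ml = np.where(cov > 0, m / np.where(cov > 0, cov, 1.0), np.nan)
    if ml.ndim == 0:
        return float(ml)
    return ml


def call_methylated_sites(
    sites: pd.DataFrame,
    conversion_error: float = 0.005,
    alpha: float = 0.05,
    correction: str | None = "bh",
) -> pd.DataFrame:
    """One-sided exact binomial test per covered site, H0: rate = conversion_error.

    Adds columns ``ml``, ``pval``, ``qval``, ``tested`` and ``methylated``.
    Zero-coverage sites stay untested (NaN p, ``methylated`` False,
    ``tested`` False — the tri-state "untested").
    """
    if not (0 <= conversion_error < 1):
        raise ConfigError("conversion_error must be in [0, 1)")
    if not (0 < alpha < 1):
        raise ConfigError("alpha must be in (0, 1)")
    if correction not in ("bh", "none", None):
        raise ConfigError(f"unknown correction {correction!r}")
    out = sites.copy()
    m = out["count_meth"].to_numpy(dtype=np.int64)
    u = out["count_unmeth"].to_numpy(dtype=np.int64)
    cov = m + u
    tested = cov > 0
    out["ml"] = site_ml(m, u)
    pval = np.full(len(out), np.nan)
    # P(X >= k) under Binomial(n, conversion_error); sf(k-1) is that tail.
    pval[tested] = binom.sf(m[tested] - 1, cov[tested], conversion_error)
    qval = np.full(len(out), np.nan)
    if correction == "bh":
        qval[tested] = benjamini_hochberg(pval[tested])
    else:
        qval[tested] = pval[tested]
    out["pval"] = pval
    out["qval"] = qval
    out["tested"] = tested
    out["methylated"] = tested & (qval <= alpha)
    return out


# ---------------------------------------------------------------------------
# Windowed and genome-scale summaries


def windowed_ml(
    sites: pd.DataFrame,
    bin_size: int = 10_000,
    context: str | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Weighted ML in non-overlapping windows tiled from coordinate 0.

    Pooled counts are restricted to ``context`` when given (otherwise all
    contexts). Terminal partial windows are kept (flagged by ``end - start``
    shorter than ``bin_size``); windows with zero total reads get NaN.
    """
    if bin_size < 1:
        raise ConfigError("bin_size must be >= 1")
    sel = sites if context in (None, "all") else sites[sites["context"] == context]
    frames = []
    chroms = (
        sorted(chrom_sizes) if chrom_sizes is not None else sorted(sites["chrom"].unique())
    )
    for chrom in chroms:
        sub = sel[sel["chrom"] == chrom]
        size = (
            int(chrom_sizes[chrom])
            if chrom_sizes is not None
            else int(sites.loc[sites["chrom"] == chrom, "pos"].max())
        )
        n_bins = max(1, -(-size // bin_size))
        binned = (
            pd.DataFrame(
                {
                    "bin": (sub["pos"].to_numpy() - 1) // bin_size,
                    "count_meth": sub["count_meth"].to_numpy(),
                    "count_unmeth": sub["count_unmeth"].to_numpy(),
                }
            )
            .groupby("bin")
            .agg(
                n_sites=("count_meth", "size"),
                pooled_meth=("count_meth", "sum"),
                pooled_unmeth=("count_unmeth", "sum"),
            )
            .reindex(range(n_bins), fill_value=0)
        )
        binned["chrom"] = chrom
        binned["start"] = binned.index * bin_size
        binned["end"] = np.minimum((binned.index + 1) * bin_size, size)
        frames.append(binned.reset_index(drop=True))
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "context",
                "n_sites", "pooled_meth", "pooled_unmeth", "weighted_ml",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out["context"] = context if context not in (None, "all") else "all"
    total = out["pooled_meth"] + out["pooled_unmeth"]
    with np.errstate(invalid="ignore"):
        out["weighted_ml"] = np.where(
            total > 0, out["pooled_meth"] / total.where(total > 0, 1), np.nan
        )
    return out[
        [
            "chrom", "start", "end", "context",
            "n_sites", "pooled_meth", "pooled_unmeth", "weighted_ml",
        ]
    ]


def genome_context_fractions(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-context share of methylated cytosines and within-context call ratio.

    ``share_of_methylated_pct``: among all sites called methylated, the
    percentage in each of CG/CHG/CHH (sums to 100 when any site is called).
    ``methylated_ratio``: within each context, called / tested.
    Requires :func:`call_methylated_sites` output.
    """
    if "methylated" not in sites.columns or "tested" not in sites.columns:
        raise ValidationError("run call_methylated_sites first")
    rows = []
    in_ctx = sites[sites["context"].isin(CONTEXTS)]
    n_meth_total = int(in_ctx["methylated"].sum())
    for ctx in CONTEXTS:
        sub = in_ctx[in_ctx["context"] == ctx]
        n_tested = int(sub["tested"].sum())
        n_meth = int(sub["methylated"].sum())
        rows.append(
            {
                "context": ctx,
                "n_tested": n_tested,
                "n_methylated": n_meth,
                "share_of_methylated_pct": (
                    100.0 * n_meth / n_meth_total if n_meth_total else np.nan
                ),
                "methylated_ratio": n_meth / n_tested if n_tested else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("context")


def ml_level_histogram(
    sites: pd.DataFrame, context: str | None = None, n_bins: int = 4
) -> pd.DataFrame:
    """Distribution of site MLs over [0, 1] in ``n_bins`` equal bins.

    The default of four bins matches the quartile bands conventionally used
    to display per-context level distributions. Zero-coverage sites are
    excluded; ML exactly 1.0 falls in the last bin.
    """
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    sel = sites if context in (None, "all") else sites[sites["context"] == context]
    ml = site_ml(sel["count_meth"].to_numpy(), sel["count_unmeth"].to_numpy())
    ml = np.atleast_1d(ml)
    ml = ml[~np.isnan(ml)]
    counts, edges = np.histogram(ml, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "n_sites": counts}
    )
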