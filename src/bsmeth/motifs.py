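"""9-mer sequence preference around methylated cytosines.

For every methylated cytosine the 9 bp window (4 bases up, the cytosine,
4 bases down, read 5'→3' on the cytosine's strand) is extracted; the
position-frequency matrix over those windows is logo-renderer-ready, and the
per-9-mer table reports, for each observed 9-mer class, how many of its
tested sites are called methylated. "Percentage of methylation" per motif is
(methylated sites / tested sites) * 100 by default; a read-weighted variant
(pooled mC / pooled coverage) is available via ``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core
from .errors import ValidationError

K = 9
CENTER = 5  # 1-based index of the cytosine within the 9-mer


def extract_ninemer(genome: dict[str, str], chrom: str, pos: int, strand: str):
    """9-mer around the cytosine at 1-based ``pos``; None at contig edges or
    when the window contains a non-ACGT base."""
    seq = genome[chrom]
    i = pos - 1
    if i - 4 < 0 or i + 4 >= len(seq):
        return None
    window = seq[i - 4 : i + 5]
    if any(b not in "ACGT" for b in window):
        return None
    if strand == "-":
        window = core.revcomp(window)
    return window


@dataclass
class MotifTable:
    """Position-frequency matrix plus the per-9-mer methylation table."""

    k: int
    center: int
    position_freqs: pd.DataFrame  # index 1..k, columns A/C/G/T, rows sum to 1
    motif_ml: pd.DataFrame  # ninemer, n_methylated, n_tested, percent, low_confidence
    n_methylated_sites: int


def build_motif_table(
    genome: dict[str, str],
    sites: pd.DataFrame,
    context: str | None = None,
    weighted: bool = False,
    min_confident: int = 10,
) -> MotifTable:
    """Build the motif table from called sites.

    ``position_freqs`` is computed over methylated sites only; ``motif_ml``
    groups all tested sites by their 9-mer. Motifs with fewer than
    ``min_confident`` tested sites are flagged ``low_confidence``. Zero
    methylated sites yield an empty (all-NaN frequency) table, not an error.
    """
    if "methylated" not in sites.columns:
        raise ValidationError("run call_methylated_sites first")
    sel = sites if context in (None, "all") else sites[sites["context"] == context]
    sel = sel[sel["tested"]]

    nines = []
    for row in sel.itertuples(index=False):
        nines.append(extract_ninemer(genome, row.chrom, int(row.pos), row.strand))
    sel = sel.assign(ninemer=nines)
    sel = sel[sel["ninemer"].notna()]

    meth = sel[sel["methylated"]]
    freqs = pd.DataFrame(
        np.nan, index=range(1, K + 1), columns=list("ACGT"), dtype=float
    )
    if len(meth):
        mat = np.frombuffer("".join(meth["ninemer"]).encode("ascii"), dtype=np.uint8)
        mat = mat.reshape(len(meth), K)
        for j, base in enumerate("ACGT"):
            freqs[base] = (mat == ord(base)).mean(axis=0)

    if weighted:
        sel = sel.assign(cov=sel["count_meth"] + sel["count_unmeth"])
        grouped = sel.groupby("ninemer").agg(
            n_methylated=("methylated", "sum"),
            n_tested=("methylated", "size"),
            pooled_meth=("count_meth", "sum"),
            pooled_cov=("cov", "sum"),
        )
        grouped["percent"] = 100.0 * grouped["pooled_meth"] / grouped["pooled_cov"]
        grouped = grouped.drop(columns=["pooled_meth", "pooled_cov"])
    else:
        grouped = sel.groupby("ninemer").agg(
            n_methylated=("methylated", "sum"), n_tested=("methylated", "size")
        )
        grouped["percent"] = 100.0 * grouped["n_methylated"] / grouped["n_tested"]
    grouped["low_confidence"] = grouped["n_tested"] < min_confident
    motif_ml = grouped.reset_index().sort_values("ninemer").reset_index(drop=True)

    return MotifTable(
        k=K,
        center=CENTER,
        position_freqs=freqs,
        motif_ml=motif_ml,
        n_methylated_sites=int(len(meth)),
    )
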