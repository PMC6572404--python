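"""Clone (Sanger) bisulfite sequencing analysis.

After bisulfite treatment, cloning and sequencing, each clone reads C where
the original molecule was methylated and T where it was unmethylated. Clones
are aligned to the untreated amplicon reference with a bisulfite-aware
global alignment (reference C against clone T scores as a match); at every
amplicon cytosine the C/T calls are tallied across clones and the percent
methylation is 100 * C / (C + T), with any other base (mutation, uncalled)
excluded from the denominator.

Amplicon coordinates can be expressed promoter-relative: the base
immediately upstream of the TSS is -1, the first transcribed base +1, and
there is no position 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import core
from .errors import ConfigError, ValidationError


def _make_aligner(match=2.0, mismatch=-2.0, open_gap=-6.0, extend_gap=-1.0):
    m = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            m[x, y] = match if x == y else mismatch
    m["C", "T"] = match  # unmethylated reference C reads as T: not a mismatch
    for x in "ACGTN":
        m[x, "N"] = 0.0
        m["N", x] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = m
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.mode = "global"
    return aligner


def align_clone(amplicon: str, clone: str):
    """Global bisulfite-aware alignment of one clone to the amplicon.

    Returns ``(mapping, identity)`` where ``mapping`` maps amplicon positions
    to clone positions (gapped positions absent) and ``identity`` is the
    fraction of amplicon bases matched (C-to-T counted as a match).
    """
    if not amplicon or not clone:
        raise ValidationError("empty sequence")
    amplicon = amplicon.upper()
    clone = clone.upper()
    aln = _make_aligner().align(amplicon, clone)[0]
    mapping: dict[int, int] = {}
    matches = 0
    for (rs, re_), (qs, _qe) in zip(*aln.aligned):
        for k in range(re_ - rs):
            rp, qp = rs + k, qs + k
            mapping[rp] = qp
            rb, qb = amplicon[rp], clone[qp]
            if rb == qb or (rb == "C" and qb == "T"):
                matches += 1
    return mapping, matches / len(amplicon)


def promoter_coord(offset: int, i: int) -> int:
    """Promoter-relative coordinate of amplicon base ``i`` (no position 0)."""
    c = offset + i
    if offset < 0 <= c:
        c += 1
    return c


@dataclass
class CloneSet:
    """Amplicon reference plus aligned clone sequences."""

    amplicon: str
    offset: int  # promoter-relative coordinate of amplicon base 0
    clones: list = field(default_factory=list)  # (name, sequence)
    alignments: dict = field(default_factory=dict)  # name -> {ref_pos: clone_pos}
    rejected: list = field(default_factory=list)  # (name, identity)

    def coord_bounds(self) -> tuple[int, int]:
        return (
            promoter_coord(self.offset, 0),
            promoter_coord(self.offset, len(self.amplicon) - 1),
        )


def build_clone_set(
    amplicon: str,
    clones,
    offset: int = 1,
    min_identity: float = 0.7,
) -> CloneSet:
    """Align clones to the amplicon, rejecting those below ``min_identity``.

    ``clones`` is an iterable of (name, sequence) pairs (e.g. FASTA records).
    """
    amplicon = amplicon.upper()
    if "C" not in amplicon:
        raise ConfigError("amplicon contains no cytosines")
    if offset == 0:
        raise ConfigError("promoter-relative offsets have no position 0")
    cs = CloneSet(amplicon=amplicon, offset=offset)
    for name, seq in clones:
        mapping, identity = align_clone(amplicon, seq)
        if identity < min_identity:
            cs.rejected.append((name, identity))
            continue
        cs.clones.append((name, seq.upper()))
        cs.alignments[name] = mapping
    return cs


def call_sites(clone_set: CloneSet) -> pd.DataFrame:
    """Tally C/T calls across clones at every amplicon cytosine.

    Returns one row per cytosine with the per-clone call string (C, T,
    ``.`` = other base, ``-`` = not aligned), counts, and
    percent = 100 * C / (C + T); clone input order does not matter for the
    counts. Context is classified from the amplicon sequence.
    """
    genome = {"amplicon": clone_set.amplicon}
    rows = []
    for i, base in enumerate(clone_set.amplicon):
        if base != "C":
            continue
        calls = []
        for name, seq in clone_set.clones:
            qp = clone_set.alignments[name].get(i)
            if qp is None:
                calls.append("-")
            elif seq[qp] == "C":
                calls.append("C")
            elif seq[qp] == "T":
                calls.append("T")
            else:
                calls.append(".")
        n_c = calls.count("C")
        n_t = calls.count("T")
        denom = n_c + n_t
        rows.append(
            {
                "amplicon_pos": i,
                "coord": promoter_coord(clone_set.offset, i),
                "context": core.classify_context(genome, "amplicon", i + 1, "+"),
                "calls": "".join(calls),
                "n_meth": n_c,
                "n_unmeth": n_t,
                "n_other": calls.count("."),
                "n_uncalled": calls.count("-"),
                "percent": 100.0 * n_c / denom if denom else np.nan,
            }
        )
    return pd.DataFrame(rows)


def region_summary(
    site_calls: pd.DataFrame,
    regions,
    bounds: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Pooled percent methylation per context inside promoter-relative regions.

    ``regions`` is an iterable of inclusive (low, high) coordinate pairs.
    Contexts absent from a region are reported with zero counts and NaN
    percent. With ``bounds`` given (coordinate extent of the amplicon), a
    region outside the amplicon raises a validation error.
    """
    rows = []
    for lo, hi in regions:
        if lo > hi:
            lo, hi = hi, lo
        if bounds is not None and (hi < bounds[0] or lo > bounds[1]):
            raise ValidationError(
                f"region [{lo}, {hi}] lies outside the amplicon {bounds}"
            )
        sub = site_calls[(site_calls["coord"] >= lo) & (site_calls["coord"] <= hi)]
        for ctx in ("CG", "CHG", "CHH", "all"):
            part = sub if ctx == "all" else sub[sub["context"] == ctx]
            n_c = int(part["n_meth"].sum())
            n_t = int(part["n_unmeth"].sum())
            rows.append(
                {
                    "region_start": lo,
                    "region_end": hi,
                    "context": ctx,
                    "n_meth": n_c,
                    "n_unmeth": n_t,
                    "n_sites": len(part),
                    "percent": 100.0 * n_c / (n_c + n_t) if n_c + n_t else np.nan,
                }
            )
    return pd.DataFrame(rows)


def conversion_efficiency(
    site_calls: pd.DataFrame, control_contexts=("CHG", "CHH")
) -> float | None:
    """Bisulfite conversion QC: 100 * T / (C + T) over control-context sites.

    Non-CG sites are the default proxy for unmethylated controls. Returns
    None when no control site carries a C or T call.
    """
    sub = site_calls[site_calls["context"].isin(control_contexts)]
    n_c = int(sub["n_meth"].sum())
    n_t = int(sub["n_unmeth"].sum())
    if n_c + n_t == 0:
        return None
    return 100.0 * n_t / (n_c + n_t)
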