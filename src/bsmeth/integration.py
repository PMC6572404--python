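"""DEG filtering, DMR x DEG Fisher enrichment, Venn partitions, and 2^-ddCt.

The differential-expression model itself is not refit here: the module
consumes a fold-change/FDR table produced upstream (or by the simulator) and
applies the thresholds fold change >= 2 and FDR <= 0.05, both inclusive.
The headline association analysis asks whether genes carrying a
direction-specific DMR (hypo or hyper in the second sample) are enriched for
up- or down-regulated genes, via a two-sided Fisher exact test on gene-set
membership over a configurable gene universe.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._stats import fisher_exact_2x2
from .errors import ValidationError


def filter_degs(
    table: pd.DataFrame, fc_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Assign up/down/ns status per row from log2 fold change and FDR.

    ``up`` requires fold change >= ``fc_threshold`` (i.e. log2fc >=
    log2(threshold)) and FDR <= ``fdr_threshold``; ``down`` is symmetric.
    Both thresholds are inclusive. Missing columns raise a schema error.
    """
    for col in ("gene_id", "log2fc", "fdr"):
        if col not in table.columns:
            raise ValidationError(f"DEG table lacks required column {col!r}")
    lfc_thr = math.log2(fc_threshold)
    out = table.copy()
    sig = out["fdr"] <= fdr_threshold
    out["status"] = np.where(
        sig & (out["log2fc"] >= lfc_thr),
        "up",
        np.where(sig & (out["log2fc"] <= -lfc_thr), "down", "ns"),
    )
    return out


def dmr_deg_enrichment(
    dmr_genes_by_direction: dict[str, set],
    degs_by_status: dict[str, set],
    universe: set,
    comparison: str = "",
) -> pd.DataFrame:
    """Fisher enrichment of each (DMR direction) x (DEG status) pair.

    The 2x2 table partitions the universe by membership in the DMR gene set
    and the DEG set. The odds ratio is the cross-product, with a 0.5
    continuity correction (flagged) when any cell is zero.
    """
    universe = set(universe)
    for name, s in list(dmr_genes_by_direction.items()) + list(degs_by_status.items()):
        if not set(s) <= universe:
            raise ValidationError(
                f"gene set {name!r} contains genes outside the universe"
            )
    rows = []
    for direction in sorted(dmr_genes_by_direction):
        dset = set(dmr_genes_by_direction[direction])
        for status in sorted(degs_by_status):
            eset = set(degs_by_status[status])
            a = len(dset & eset)
            b = len(dset - eset)
            c = len(eset - dset)
            d = len(universe) - a - b - c
            p = fisher_exact_2x2(a, b, c, d)
            zero_cell = min(a, b, c, d) == 0
            if zero_cell:
                odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                odds = (a * d) / (b * c)
            rows.append(
                {
                    "comparison": comparison,
                    "direction": direction,
                    "status": status,
                    "n_both": a,
                    "n_dmr_only": b,
                    "n_deg_only": c,
                    "n_neither": d,
                    "odds_ratio": float(odds),
                    "pvalue": p,
                    "zero_cell_corrected": zero_cell,
                }
            )
    return pd.DataFrame(rows)


def venn_counts(set_map: dict[str, set]) -> pd.DataFrame:
    """Exact counts of every intersection region of the named sets.

    One row per non-empty membership signature plus all-empty regions with
    count 0, so each set's cardinality is reconstructable by summing the
    regions that contain it.
    """
    names = sorted(set_map)
    signature_of = {}
    for el in set().union(*set_map.values()) if set_map else set():
        signature_of[el] = tuple(el in set_map[n] for n in names)
    counts: dict[tuple, int] = {}
    for sig in signature_of.values():
        counts[sig] = counts.get(sig, 0) + 1
    rows = []
    import itertools

    for sig in itertools.product([False, True], repeat=len(names)):
        if not any(sig):
            continue
        rows.append(
            {**{n: inc for n, inc in zip(names, sig)}, "count": counts.get(sig, 0)}
        )
    return pd.DataFrame(rows)


def ddct(
    target_ct: float,
    reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
) -> float:
    """Relative quantity by the 2^-ddCt method.

    ddCt = (target - reference) - (calibrator_target - calibrator_reference);
    the result is 2 ** -ddCt.
    """
    for v in (target_ct, reference_ct, calibrator_target_ct, calibrator_reference_ct):
        if not math.isfinite(v):
            raise ValidationError("Ct values must be finite")
    delta_delta = (target_ct - reference_ct) - (
        calibrator_target_ct - calibrator_reference_ct
    )
    return 2.0 ** (-delta_delta)
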