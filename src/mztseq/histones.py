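"""Histone-centric transcriptome metrics.

Replication-dependent histone mRNAs lack poly(A) tails, so their expansion at
genome activation is only visible in tail-independent libraries. This module
computes the transcriptome proportion per histone class and the cross-species
"net activation" trajectory: per-gene reads-per-million increase over a
pre-activation baseline, gated at a minimum fold increase and summed per gene
class, optionally with a trimmed library-size normalization that keeps very
highly expressed genes from skewing RPM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["class_proportions", "net_activation"]


def class_proportions(tpm: pd.DataFrame, class_map: pd.Series) -> pd.DataFrame:
    """Per-sample share of the transcriptome per histone class.

    Genes absent from ``class_map`` count as ``non_histone``. Rows are the
    classes plus non_histone; columns follow ``tpm``; each column sums to 1.
    """
    classes = class_map.reindex(tpm.index).fillna("non_histone")
    totals = tpm.sum(axis=0)
    rows = {}
    for cls, genes in tpm.groupby(classes).groups.items():
        rows[cls] = tpm.loc[genes].sum(axis=0) / totals
    out = pd.DataFrame(rows).T
    order = sorted(k for k in rows if k != "non_histone") + (
        ["non_histone"] if "non_histone" in rows else []
    )
    return out.loc[order]


def net_activation(
    counts_by_timepoint: pd.DataFrame,
    class_map: pd.Series,
    baseline: str = "max_first_two",
    fold_min: float = 2.0,
    trimmed: bool = False,
    trim_pct: tuple = (10, 90),
) -> pd.DataFrame:
    """Summed RPM increase over baseline per gene class and timepoint.

    The baseline RPM per gene is the maximum of the first two timepoints
    (``max_first_two``) or the first alone (``first_only``). At every
    timepoint a gene contributes RPM_t - baseline only when
    RPM_t >= ``fold_min`` x baseline — the gate is re-evaluated per
    timepoint. With ``trimmed``, the RPM denominator is the summed counts of
    genes whose totals lie within the ``trim_pct`` percentiles (inclusive).

    ``counts_by_timepoint`` columns must be in temporal order (one library or
    replicate-mean per timepoint).
    """
    if fold_min < 1:
        raise ValueError("fold_min must be >= 1")
    if baseline not in ("max_first_two", "first_only"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if baseline == "max_first_two" and counts_by_timepoint.shape[1] < 2:
        raise ValueError("max_first_two baseline needs at least 2 timepoints")

    counts = counts_by_timepoint.astype(float)
    if trimmed:
        totals = counts.sum(axis=1)
        lo, hi = np.percentile(totals, trim_pct)
        in_trim = (totals >= lo) & (totals <= hi)
        denom = counts.loc[in_trim].sum(axis=0)
    else:
        denom = counts.sum(axis=0)
    rpm = counts.div(denom, axis=1) * 1e6

    if baseline == "max_first_two":
        base = rpm.iloc[:, :2].max(axis=1)
    else:
        base = rpm.iloc[:, 0]

    gated = rpm.ge(fold_min * base, axis=0)
    increase = rpm.sub(base, axis=0).where(gated, 0.0).clip(lower=0.0)

    classes = class_map.reindex(rpm.index).fillna("non_histone")
    return increase.groupby(classes).sum()
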