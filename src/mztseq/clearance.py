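"""Maternal mRNA clearance timing and transcription dependence.

The central readout is the per-gene first timepoint of significant (>= 2-fold,
adjusted P < 0.05) decrease relative to the egg, measured separately in the
poly(A)+ and rRNA-depleted protocols. A poly(A)+ decrease preceding the
rRNA-depleted decrease is the signature of deadenylation before degradation.
Genes are grouped by poly(A)+ timing (early: 2-4 h.p.f.; late: >= 5), screened
for oscillating trajectories, and compared between Triptolide- and
DMSO-treated embryos by paired Wilcoxon signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import CountMatrix, nb_test, wilcoxon_signed_rank

__all__ = [
    "first_decrease",
    "oscillation_filter",
    "clearance_profiles",
    "timing_matrix",
    "clearance_mode",
    "stable_reference_set",
    "condition_fold_change",
    "triptolide_effect",
]

PSEUDO_TPM = 0.1  # pseudocount for TPM-space fold ratios


def first_decrease(
    de_series: dict,
    fold_min: float = 2.0,
    padj_max: float = 0.05,
) -> pd.Series:
    """First timepoint with a significant >= ``fold_min`` decrease vs egg.

    ``de_series`` maps timepoint -> nb_test frame (egg vs t) for one
    protocol. The fold boundary is inclusive (a decrease of exactly 2-fold
    counts). Returns NaN for genes that never decrease.
    """
    log2_min = np.log2(fold_min)
    tps = sorted(de_series)
    genes = de_series[tps[0]].index
    out = pd.Series(np.nan, index=genes, name="first_decrease")
    for t in tps:
        de = de_series[t]
        hit = (de.padj < padj_max) & (de.log2FC <= -log2_min)
        hit = hit.fillna(False).reindex(genes, fill_value=False)
        newly = hit & out.isna()
        out[newly] = t
    return out


def oscillation_filter(
    tpm_traj: pd.DataFrame, rise_max: float = 1.5, pseudocount: float = PSEUDO_TPM
) -> pd.Series:
    """Pass/fail per gene: fail iff any stage-to-stage rise is > ``rise_max``.

    The boundary is strict: a consecutive-stage ratio of exactly 1.5 passes.
    ``tpm_traj`` columns must be in temporal order.
    """
    vals = tpm_traj.to_numpy(dtype=float) + pseudocount
    ratios = vals[:, 1:] / vals[:, :-1]
    fail = (ratios > rise_max).any(axis=1)
    return pd.Series(~fail, index=tpm_traj.index, name="passes_oscillation")


@dataclass
class ClearanceProfiles:
    """Per-gene clearance timing and grouping (the timing-matrix rows)."""

    table: pd.DataFrame  # first_decrease_polyA/_ribo, group, deadenylation_lead

    def genes_in_group(self, group: str):
        return self.table.index[self.table.group == group]


def clearance_profiles(
    de_polyA: dict,
    de_ribo: dict,
    polyA_tpm_traj: pd.DataFrame,
    fold_min: float = 2.0,
    padj_max: float = 0.05,
    early_range: tuple = (2.0, 4.0),
    rise_max: float = 1.5,
) -> ClearanceProfiles:
    """Assemble per-gene clearance profiles from both protocols.

    Groups: ``early`` / ``late`` by poly(A)+ first-decrease timing,
    ``stable`` when no qualifying decrease exists, ``excluded_oscillating``
    for trajectories failing the oscillation screen, and
    ``excluded_insignificant`` for genes with a significant but sub-2-fold
    decrease only.
    """
    if sorted(de_polyA) != sorted(de_ribo):
        raise ValueError("protocols must cover the same timepoint set")
    fd_pa = first_decrease(de_polyA, fold_min, padj_max)
    fd_rb = first_decrease(de_ribo, fold_min, padj_max)
    # significant decreases that never reach the fold boundary
    weak = first_decrease(de_polyA, fold_min=1.0, padj_max=padj_max)
    osc = oscillation_filter(polyA_tpm_traj, rise_max)

    genes = fd_pa.index
    group = pd.Series("stable", index=genes, name="group")
    group[fd_pa.notna() & (fd_pa >= early_range[0]) & (fd_pa <= early_range[1])] = (
        "early"
    )
    group[fd_pa.notna() & (fd_pa > early_range[1])] = "late"
    group[fd_pa.isna() & weak.notna()] = "excluded_insignificant"
    group[~osc.reindex(genes, fill_value=True)] = "excluded_oscillating"

    lead = fd_rb - fd_pa
    table = pd.DataFrame(
        {
            "first_decrease_polyA": fd_pa,
            "first_decrease_ribo": fd_rb,
            "group": group,
            "deadenylation_lead": lead,
        }
    )
    return ClearanceProfiles(table)


def timing_matrix(profiles: ClearanceProfiles, timepoints=(2, 3, 4, 5, 6, 7)) -> pd.DataFrame:
    """Gene counts per (poly(A)+ first decrease, ribo first decrease) cell.

    Genes without a decrease in a protocol land in the ``7+`` (never) bin,
    reproducing the 2-7+ axis layout of the clearance bubble chart.
    """
    bins = [f"{t:g}" for t in timepoints] + ["7+"]

    def to_bin(x):
        return "7+" if pd.isna(x) else f"{x:g}"

    t = profiles.table
    keep = ~t.group.isin(["excluded_oscillating", "excluded_insignificant"])
    pa = t.loc[keep, "first_decrease_polyA"].map(to_bin)
    rb = t.loc[keep, "first_decrease_ribo"].map(to_bin)
    mat = pd.crosstab(rb, pa).reindex(index=bins, columns=bins, fill_value=0)
    mat.index.name = "ribo_first"
    mat.columns.name = "polyA_first"
    return mat


def clearance_mode(profiles: ClearanceProfiles) -> pd.Series:
    """Observed clearance mode per gene.

    ``deadenylated_then_degraded`` when both protocols decrease,
    ``deadenylated_only`` when only poly(A)+ decreases, ``stable`` when
    neither does. Timing-based only: the oscillation and insignificance
    screens are group labels, not mode evidence.
    """
    t = profiles.table
    mode = pd.Series("stable", index=t.index, name="mode")
    mode[t.first_decrease_polyA.notna() & t.first_decrease_ribo.isna()] = (
        "deadenylated_only"
    )
    mode[t.first_decrease_polyA.notna() & t.first_decrease_ribo.notna()] = (
        "deadenylated_then_degraded"
    )
    return mode


def stable_reference_set(
    polyA_tpm_by_timepoint: pd.DataFrame,
    triptolide_de: pd.DataFrame,
    max_fold: float = 1.25,
    timepoints=(4.0, 5.0, 6.0, 7.0),
    egg_timepoint: float = 0.0,
    padj_max: float = 0.05,
    pseudocount: float = PSEUDO_TPM,
    renormalize: bool = True,
) -> pd.Index:
    """Stable maternal reference genes.

    Members show < ``max_fold`` difference (either direction) from egg in the
    poly(A)+ TPM at every one of ``timepoints``, and are not significantly
    changed in Triptolide vs DMSO. With ``renormalize`` (default), each
    timepoint's ratios are divided by their across-gene median first: TPM is
    compositional, so wholesale remodeling of the transcriptome (histone
    expansion, mass clearance) shifts every flat gene's raw ratio, and the
    median-ratio correction re-centers unchanged genes at 1 — the same
    compositional logic as median-of-ratios count normalization.
    """

    def col(t):
        for cand in (t, f"{t:g}", str(t)):
            if cand in polyA_tpm_by_timepoint.columns:
                return cand
        raise ValueError(f"missing timepoint {t} in poly(A)+ TPM table")

    egg = polyA_tpm_by_timepoint[col(egg_timepoint)] + pseudocount
    ok = pd.Series(True, index=polyA_tpm_by_timepoint.index)
    for t in timepoints:
        ratio = (polyA_tpm_by_timepoint[col(t)] + pseudocount) / egg
        if renormalize:
            ratio = ratio / ratio.median()
        ok &= (ratio < max_fold) & (ratio > 1.0 / max_fold)
    trip_sig = (triptolide_de.padj < padj_max).fillna(False)
    ok &= ~trip_sig.reindex(ok.index, fill_value=False)
    return ok.index[ok]


def condition_fold_change(
    cm: CountMatrix, protocol: str, condition: str, timepoint: float
) -> pd.Series:
    """log2 fold change of a treated timepoint vs the untreated egg."""
    meta = cm.metadata
    sub = meta[meta.protocol == protocol]
    egg_t = sorted(sub[sub.condition == "untreated"].timepoint_hpf.unique())[0]
    egg = list(sub.index[(sub.timepoint_hpf == egg_t) & (sub.condition == "untreated")])
    grp = list(sub.index[(sub.timepoint_hpf == timepoint) & (sub.condition == condition)])
    if not grp:
        raise ValueError(f"no {protocol}/{condition} samples at {timepoint}")
    de = nb_test(cm, egg, grp)
    return de.log2FC


def triptolide_effect(
    fc_triptolide: pd.Series,
    fc_dmso: pd.Series,
    genes,
    min_genes: int = 5,
) -> dict:
    """Transcription dependence of clearance for a gene group.

    Paired differences d_g = FC(triptolide) - FC(dmso) over the group are
    tested by a two-sided Wilcoxon signed-rank test; positive median
    difference means stabilization under transcription inhibition.
    """
    genes = list(genes)
    if len(genes) < min_genes:
        raise ValueError(f"group of {len(genes)} genes is below minimum {min_genes}")
    d = (fc_triptolide.reindex(genes) - fc_dmso.reindex(genes)).dropna()
    res = wilcoxon_signed_rank(d.to_numpy())
    med = float(np.median(d))
    return {
        "n": int(d.size),
        "median_shift": med,
        "W": res["W"],
        "p": res["p"],
        "direction": "stabilized" if med > 0 else "destabilized",
    }
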