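"""Zygotic genome-activation calling.

Exonic activation uses tail-independent (rRNA-depleted) differential
expression against the egg with the standard thresholds (adjusted P < 0.05,
fold strictly > 2, TPM > 1). Subtler re-activation of maternally provided
genes is detected from intronic (nascent pre-mRNA) signal: an intron count
table is built by subtracting exon counts from pre-mRNA counts, gated at
intronic RPKM >= 0.5, and tested jointly with the exon entries so each gene
can carry up to two entries in one BH family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genemodels import GeneModelSet
from .stats import CountMatrix, nb_test

logger = logging.getLogger(__name__)

__all__ = [
    "IntronCountTable",
    "build_intron_counts",
    "call_exonic_activation",
    "call_intron_activation",
    "categorize_genes",
    "window_scan",
    "bin_counts_by_window",
]

CATEGORIES = (
    "maternal_only",
    "maternal_reactivated",
    "de_novo_zygotic",
    "ambiguous",
    "not_expressed",
)


@dataclass
class IntronCountTable:
    """Intron counts (pre-mRNA minus exon, clamped at zero) after RPKM gating.

    ``rpkm`` uses the summed intronic length as the length factor and each
    library's summed pre-mRNA count as the depth factor. Genes whose intronic
    RPKM is below the threshold in every sample, and intronless genes, are
    excluded.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    rpkm_min: float
    n_clamped: int


def build_intron_counts(
    premrna: CountMatrix,
    exon: CountMatrix,
    models: GeneModelSet,
    rpkm_min: float = 0.5,
) -> IntronCountTable:
    """Construct the gated intron count table from pre-mRNA and exon counts."""
    if list(premrna.counts.columns) != list(exon.counts.columns):
        raise ValueError("pre-mRNA and exon matrices must share samples")
    if not premrna.counts.index.equals(exon.counts.index):
        raise ValueError("pre-mRNA and exon matrices must share genes")
    pre = premrna.counts
    diff = pre - exon.counts
    n_clamped = int((diff < 0).to_numpy().sum())
    if n_clamped:
        logger.info("clamped %d negative intron counts to 0", n_clamped)
    intron = diff.clip(lower=0)

    intron_len = models.intron_lengths().reindex(intron.index).fillna(0)
    has_intron = intron_len > 0
    intron = intron.loc[has_intron]
    kb = intron_len[has_intron] / 1e3
    lib_millions = pre.sum(axis=0) / 1e6
    rpkm = intron.div(kb, axis=0).div(lib_millions, axis=1)
    keep = (rpkm >= rpkm_min).any(axis=1)
    return IntronCountTable(
        counts=intron.loc[keep], rpkm=rpkm.loc[keep], rpkm_min=rpkm_min,
        n_clamped=n_clamped,
    )


def call_exonic_activation(
    de_series: dict,
    tpm_by_timepoint: pd.DataFrame,
    protocol: str = "ribo",
    fold_min: float = 2.0,
    padj_max: float = 0.05,
    tpm_min: float = 1.0,
) -> dict:
    """Activated gene sets per timepoint from exon-level DE against the egg.

    ``de_series`` maps timepoint -> nb_test frame (egg vs t) computed on
    rRNA-depleted samples; ``tpm_by_timepoint`` holds replicate-mean TPM with
    one column per timepoint. A gene is activated at t iff adjusted P <
    ``padj_max``, fold strictly greater than ``fold_min`` upward, and TPM at
    t strictly above ``tpm_min``.
    """
    if protocol != "ribo":
        raise ValueError(
            "activation calls require the rRNA-depleted (ribo) protocol; "
            "poly(A)+ changes confound tail dynamics with transcription"
        )
    log2_min = np.log2(fold_min)
    out = {}
    for t, de in de_series.items():
        col = _tp_col(tpm_by_timepoint, t)
        tpm_t = tpm_by_timepoint[col].reindex(de.index)
        hit = (de.padj < padj_max) & (de.log2FC > log2_min) & (tpm_t > tpm_min)
        out[t] = set(de.index[hit.fillna(False)])
    return out


def _tp_col(df: pd.DataFrame, t):
    for cand in (t, f"{t:g}", str(t)):
        if cand in df.columns:
            return cand
    raise KeyError(f"timepoint {t} not in TPM table")


def combined_exon_intron_de(
    exon: CountMatrix,
    introns: IntronCountTable,
    group_egg,
    group_t,
    min_total: int = 10,
) -> pd.DataFrame:
    """Joint DE over a two-entry table (gene@exon, gene@intron rows).

    BH adjustment spans both entry types, mirroring a single combined count
    table submitted to the differential test.
    """
    ex = exon.counts.copy()
    ex.index = [f"{g}@exon" for g in ex.index]
    inc = introns.counts[exon.counts.columns].copy()
    inc.index = [f"{g}@intron" for g in inc.index]
    combined = CountMatrix(pd.concat([ex, inc]), exon.metadata)
    return nb_test(combined, group_egg, group_t, min_total=min_total)


def call_intron_activation(
    exon: CountMatrix,
    introns: IntronCountTable,
    timepoints=None,
    condition: str = "untreated",
    padj_max: float = 0.05,
    min_total: int = 10,
) -> dict:
    """Re-activated gene sets per timepoint from intron-entry significance.

    A gene is intron-called at t iff its intron entry in the combined
    exon+intron test (egg vs t) has adjusted P < ``padj_max`` with positive
    fold. Genes absent from the intron table are silently exonic-only.
    """
    meta = exon.metadata
    sub = meta[meta.protocol == "ribo"]
    all_tps = sorted(sub[sub.condition == "untreated"].timepoint_hpf.unique())
    egg = all_tps[0]
    egg_samples = list(
        sub.index[(sub.timepoint_hpf == egg) & (sub.condition == "untreated")]
    )
    if timepoints is None:
        timepoints = [t for t in all_tps if t != egg]
    out = {}
    for t in timepoints:
        smp = list(
            sub.index[(sub.timepoint_hpf == t) & (sub.condition == condition)]
        )
        if not smp:
            raise ValueError(f"no ribo/{condition} samples at {t} h.p.f.")
        de = combined_exon_intron_de(exon, introns, egg_samples, smp, min_total)
        intron_rows = de.index.str.endswith("@intron")
        hit = de[intron_rows & (de.padj < padj_max) & (de.log2FC > 0)]
        out[t] = {g.rsplit("@", 1)[0] for g in hit.index}
    return out


def categorize_genes(
    egg_tpm: pd.Series,
    exonic_calls: dict,
    intron_calls: dict | None = None,
    denovo_egg_max: float = 0.5,
    maternal_egg_min: float = 1.0,
) -> pd.DataFrame:
    """Per-gene, per-timepoint categories (the stacked-bar classification).

    Activation evidence is cumulative (a gene activated at an earlier stage
    stays activated). Egg TPM must come from the tail-independent protocol.
    Categories: maternally provided only, maternal + re-activated, de novo
    zygotic (egg TPM < 0.5), ambiguous (egg TPM in [0.5, 1) with activation
    evidence), or not expressed.
    """
    intron_calls = intron_calls or {}
    tps = sorted(set(exonic_calls) | set(intron_calls))
    out = {}
    active: set = set()
    for t in tps:
        active = active | exonic_calls.get(t, set()) | intron_calls.get(t, set())
        egg = egg_tpm
        is_active = egg.index.isin(active)
        cat = np.where(
            is_active & (egg < denovo_egg_max).to_numpy(),
            "de_novo_zygotic",
            np.where(
                is_active & (egg >= maternal_egg_min).to_numpy(),
                "maternal_reactivated",
                np.where(
                    is_active,
                    "ambiguous",
                    np.where(
                        (egg >= maternal_egg_min).to_numpy(),
                        "maternal_only",
                        "not_expressed",
                    ),
                ),
            ),
        )
        out[t] = pd.Series(cat, index=egg.index)
    return pd.DataFrame(out)


def bin_counts_by_window(
    models: GeneModelSet, counts: pd.Series, window_size: int = 10_000
) -> pd.DataFrame:
    """Aggregate per-gene counts into tiling genomic windows.

    Each gene's counts are assigned to the window containing the midpoint of
    its span — a count-table surrogate for binned read coverage.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    rows: dict[tuple, float] = {}
    for gid, model in models.genes.items():
        if gid not in counts.index:
            continue
        s, e = model.span
        mid = (s + e) // 2
        w = mid // window_size
        key = (model.scaffold, w * window_size, (w + 1) * window_size)
        rows[key] = rows.get(key, 0.0) + float(counts.loc[gid])
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["scaffold", "start", "end"])
    return pd.DataFrame({"count": list(rows.values())}, index=idx).sort_index()


def window_scan(
    windows_t: pd.DataFrame,
    windows_egg: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-window log2 fold difference of RPM-scaled window counts vs egg.

    Returns windows ranked by descending log2 fold change.
    """
    joined = windows_t.join(windows_egg, how="outer", lsuffix="_t", rsuffix="_egg")
    joined = joined.fillna(0.0)
    rpm_t = joined["count_t"] / joined["count_t"].sum() * 1e6
    rpm_egg = joined["count_egg"] / joined["count_egg"].sum() * 1e6
    out = pd.DataFrame(
        {
            "rpm_t": rpm_t,
            "rpm_egg": rpm_egg,
            "log2fc": np.log2((rpm_t + pseudocount) / (rpm_egg + pseudocount)),
        },
        index=joined.index,
    )
    return out.sort_values("log2fc", ascending=False)
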