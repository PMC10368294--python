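"""Stage-specific expression and GO-term stage enrichment.

A gene is stage-specific when its replicate-mean TPM is below 1 in at least
one stage, above 5 in another, and it is significantly different from the
egg at some stage. Qualifying genes are clustered by peak stage; per GO term
a 2 x k chi-squared test of independence (annotated vs not, across the stage
clusters) with BH adjustment flags stage-enriched functions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import bh_adjust, chi2_independence

logger = logging.getLogger(__name__)

__all__ = ["call_stage_specific", "go_stage_enrichment"]


def call_stage_specific(
    tpm_by_stage: pd.DataFrame,
    de_significant: pd.Series,
    min_tpm: float = 1.0,
    max_tpm: float = 5.0,
) -> pd.DataFrame:
    """Stage-specificity calls and peak-stage assignment.

    ``tpm_by_stage``: replicate-mean TPM, one column per stage in temporal
    order. ``de_significant``: per gene, True when any stage-vs-egg contrast
    is significant. Peak ties break toward the earliest stage.
    Returns a frame with qualifies, peak_stage, and the three criteria.
    """
    low_somewhere = (tpm_by_stage < min_tpm).any(axis=1)
    high_somewhere = (tpm_by_stage > max_tpm).any(axis=1)
    sig = de_significant.reindex(tpm_by_stage.index).fillna(False).astype(bool)
    qualifies = low_somewhere & high_somewhere & sig
    # idxmax returns the first maximum: earliest stage on ties
    peak = tpm_by_stage.idxmax(axis=1)
    return pd.DataFrame(
        {
            "qualifies": qualifies,
            "peak_stage": peak.where(qualifies),
            "has_low_stage": low_somewhere,
            "has_high_stage": high_somewhere,
            "de_significant": sig,
        }
    )


def go_stage_enrichment(
    go_map: pd.DataFrame,
    clusters: pd.Series,
    padj_max: float = 0.05,
    required_groups: int = 5,
) -> pd.DataFrame:
    """Per-GO-term chi-squared test of stage-cluster independence.

    ``go_map`` has columns (gene_id, go_id); ``clusters`` maps qualifying
    genes to their (pooled) stage group — exactly ``required_groups`` groups
    are expected after pooling. Terms never annotated among clustered genes
    are skipped, as are terms with zero expected cells (logged). BH
    adjustment spans the tested terms.
    """
    clusters = clusters.dropna()
    groups = sorted(clusters.unique())
    if len(groups) < required_groups:
        raise ValueError(
            f"{len(groups)} stage groups after pooling; need {required_groups}"
        )
    genes_by_group = {g: set(clusters.index[clusters == g]) for g in groups}
    sizes = {g: len(s) for g, s in genes_by_group.items()}
    clustered = set(clusters.index)
    term_genes = {
        t: set(sub.gene_id) & clustered for t, sub in go_map.groupby("go_id")
    }

    rows = []
    for term, members in sorted(term_genes.items()):
        if not members:
            continue
        annotated = [len(members & genes_by_group[g]) for g in groups]
        not_annotated = [sizes[g] - a for g, a in zip(groups, annotated)]
        try:
            res = chi2_independence([annotated, not_annotated])
        except ValueError as err:
            logger.info("skipping %s: %s", term, err)
            continue
        rows.append(
            {
                "go_id": term,
                "n_annotated": int(sum(annotated)),
                "statistic": res["statistic"],
                "dof": res["dof"],
                "pvalue": res["p"],
            }
        )
    out = pd.DataFrame(
        rows, columns=["go_id", "n_annotated", "statistic", "dof", "pvalue"]
    )
    if len(out):
        out["padj"] = bh_adjust(out.pvalue.to_numpy())
        out["significant"] = out.padj < padj_max
    else:
        out["padj"] = np.nan
        out["significant"] = False
    return out.set_index("go_id")
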