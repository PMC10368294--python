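"""Codon adaptation index and 3'UTR extraction.

The CAI reference table is built empirically from the most highly expressed
stable maternal mRNA: relative adaptiveness w_c is each codon's frequency
divided by the frequency of the most-used synonymous codon of the same amino
acid. CAI of a CDS is the geometric mean of w over its codons, excluding the
initiator codon and single-codon amino-acid families (Met, Trp), following
the classical formulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CodonUsageTable", "build_codon_table", "cai", "extract_3utrs"]

_STOPS = {"TAA", "TAG", "TGA"}


def _families() -> dict[str, str]:
    """codon -> amino acid for the 61 sense codons."""
    from Bio.Data import CodonTable

    return dict(CodonTable.standard_dna_table.forward_table)


def _codons_of(seq: str):
    s = seq.upper().replace("U", "T")
    return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


def _usable_cds(seq: str, gene_id: str) -> list | None:
    s = seq.upper().replace("U", "T")
    if len(s) % 3 != 0:
        logger.warning("%s: CDS length not divisible by 3, skipped", gene_id)
        return None
    codons = _codons_of(s)
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    fams = _families()
    for c in codons:
        if c in _STOPS:
            logger.warning("%s: internal stop codon, skipped", gene_id)
            return None
        if c not in fams:
            logger.warning("%s: non-ACGT codon %s, skipped", gene_id, c)
            return None
    return codons


@dataclass
class CodonUsageTable:
    """Counts, frequencies and relative adaptiveness for 61 sense codons."""

    counts: dict
    frequency: dict
    w: dict
    reference_genes: list

    def as_frame(self) -> pd.DataFrame:
        fams = _families()
        return pd.DataFrame(
            {
                "amino_acid": {c: fams[c] for c in self.counts},
                "count": self.counts,
                "frequency": self.frequency,
                "w": self.w,
            }
        ).rename_axis("codon")


def build_codon_table(
    cds: dict,
    ranking: pd.Series,
    top_n: int = 100,
    zero_count_floor: float = 0.5,
) -> CodonUsageTable:
    """Empirical codon usage from the ``top_n`` genes of ``ranking``.

    ``ranking`` orders candidate reference genes (e.g. egg TPM of stable
    maternal mRNA, descending). CDS with internal stops, non-ACGT codons, or
    lengths not divisible by 3 are skipped with a warning; fewer than 10
    usable genes is an error. Codons never observed receive
    ``zero_count_floor`` pseudo-counts before w computation so every w is
    positive.
    """
    ordered = [g for g in ranking.sort_values(ascending=False).index if g in cds]
    fams = _families()
    counts = {c: 0.0 for c in fams}
    used = []
    for g in ordered:
        if len(used) >= top_n:
            break
        codons = _usable_cds(cds[g], g)
        if codons is None:
            continue
        for c in codons:
            counts[c] += 1
        used.append(g)
    if len(used) < 10:
        raise ValueError(f"only {len(used)} usable reference CDS (< 10)")
    floored = {c: (n if n > 0 else zero_count_floor) for c, n in counts.items()}
    total = sum(floored.values())
    freq = {c: n / total for c, n in floored.items()}
    by_aa: dict[str, list] = {}
    for c, aa in fams.items():
        by_aa.setdefault(aa, []).append(c)
    w = {}
    for aa, codons in by_aa.items():
        mx = max(freq[c] for c in codons)
        for c in codons:
            w[c] = freq[c] / mx
    return CodonUsageTable(counts=counts, frequency=freq, w=w, reference_genes=used)


def cai(cds: str, table: CodonUsageTable) -> float:
    """Codon adaptation index of one CDS against a usage table.

    Geometric mean of w over codons, excluding the initiator codon,
    single-codon families (Met, Trp) and stops. Empty included set is an
    error.
    """
    codons = _codons_of(cds)
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    codons = codons[1:]  # exclude the start codon
    fams = _families()
    single = {aa for aa in set(fams.values())
              if sum(1 for c in fams.values() if c == aa) == 1}
    logs = []
    for c in codons:
        if c in _STOPS or c not in fams:
            continue
        if fams[c] in single:
            continue
        logs.append(math.log(table.w[c]))
    if not logs:
        raise ValueError("no codons usable for CAI (empty included set)")
    return math.exp(sum(logs) / len(logs))


def extract_3utrs(
    transcripts: dict,
    cds_end: dict | pd.Series,
    strands: dict | None = None,
    min_len_exclusive: int = 20,
) -> dict:
    """3'UTRs from transcript sequences, discarding UTRs <= ``min_len_exclusive`` nt.

    ``cds_end`` gives, per gene, the sense-orientation transcript coordinate
    one past the stop codon. Sequences flagged '-' in ``strands`` are stored
    in genomic orientation and are reverse-complemented to sense before
    cutting. Genes without a CDS end are skipped with a warning.
    """
    from .mirna import revcomp

    out = {}
    for gene, seq in transcripts.items():
        end = cds_end.get(gene) if not isinstance(cds_end, pd.Series) else (
            cds_end.get(gene)
        )
        if end is None or (isinstance(end, float) and math.isnan(end)):
            logger.warning("%s: missing CDS end, skipped", gene)
            continue
        if strands and strands.get(gene) == "-":
            seq = revcomp(seq)
        utr = seq[int(end):]
        if len(utr) > min_len_exclusive:
            out[gene] = utr
    return out
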