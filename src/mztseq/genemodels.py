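"""Gene model intervals: exon/intron structure derived from GTF annotations.

Coordinates are stored 0-based half-open internally; GTF is read and written
1-based inclusive. Introns are the gaps between merged exons, so single-exon
genes have none and intron/exon intervals are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["GeneModel", "GeneModelSet"]


def _merge_intervals(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GeneModel:
    """One gene: scaffold, strand, and per-transcript exon intervals."""

    gene_id: str
    scaffold: str
    strand: str
    transcripts: dict = field(default_factory=dict)  # tx_id -> [(start, end)]

    @property
    def merged_exons(self):
        return _merge_intervals(
            [iv for exons in self.transcripts.values() for iv in exons]
        )

    @property
    def introns(self):
        ex = self.merged_exons
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]

    @property
    def span(self):
        ex = self.merged_exons
        return (ex[0][0], ex[-1][1])

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.merged_exons)

    @property
    def intron_length(self) -> int:
        return sum(e - s for s, e in self.introns)

    @property
    def longest_transcript_length(self) -> int:
        return max(
            sum(e - s for s, e in _merge_intervals(exons))
            for exons in self.transcripts.values()
        )


class GeneModelSet:
    """Collection of gene models with length lookups for TPM/RPKM."""

    def __init__(self, genes: dict[str, GeneModel]):
        self.genes = genes

    def __len__(self):
        return len(self.genes)

    def __contains__(self, gene_id):
        return gene_id in self.genes

    def __getitem__(self, gene_id) -> GeneModel:
        return self.genes[gene_id]

    @property
    def gene_ids(self):
        return list(self.genes)

    def gene_lengths(self, mode: str = "longest_transcript") -> pd.Series:
        """Per-gene length in bp for TPM.

        ``longest_transcript``: summed merged-exon length of the longest
        transcript (default). ``union``: summed merged-exon length over all
        transcripts.
        """
        if mode == "longest_transcript":
            vals = {g: m.longest_transcript_length for g, m in self.genes.items()}
        elif mode == "union":
            vals = {g: m.exon_length for g, m in self.genes.items()}
        else:
            raise ValueError(f"unknown length mode {mode!r}")
        return pd.Series(vals, name="length")

    def intron_lengths(self) -> pd.Series:
        return pd.Series(
            {g: m.intron_length for g, m in self.genes.items()}, name="intron_length"
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for g, m in self.genes.items():
            s, e = m.span
            rows.append(
                {
                    "gene_id": g,
                    "scaffold": m.scaffold,
                    "strand": m.strand,
                    "start": s,
                    "end": e,
                    "n_exons": len(m.merged_exons),
                    "exon_length": m.exon_length,
                    "intron_length": m.intron_length,
                }
            )
        return pd.DataFrame(rows).set_index("gene_id")

    @classmethod
    def from_gtf(cls, path) -> "GeneModelSet":
        """Parse a GTF (1-based inclusive) into gene models via gffutils."""
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        genes: dict[str, GeneModel] = {}
        for feat in db.features_of_type("exon"):
            gid = feat.attributes["gene_id"][0]
            tid = feat.attributes.get("transcript_id", [gid])[0]
            model = genes.setdefault(
                gid, GeneModel(gid, feat.seqid, feat.strand or "+")
            )
            # GTF start is 1-based inclusive; convert to 0-based half-open
            model.transcripts.setdefault(tid, []).append((feat.start - 1, feat.end))
        for model in genes.values():
            for tid in model.transcripts:
                model.transcripts[tid] = sorted(model.transcripts[tid])
        return cls(genes)

    def to_gtf(self, path) -> None:
        """Write exon features as GTF (1-based inclusive)."""
        with open(path, "w") as fh:
            for gid in sorted(self.genes):
                m = self.genes[gid]
                for tid in sorted(m.transcripts):
                    for s, e in m.transcripts[tid]:
                        attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                        fh.write(
                            f"{m.scaffold}\tmztseq\texon\t{s + 1}\t{e}\t.\t"
                            f"{m.strand}\t.\t{attrs}\n"
                        )
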