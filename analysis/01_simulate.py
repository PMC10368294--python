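"""Generate the default synthetic timecourse and summarize its ground truth.

Writes the four count tables, sample metadata, gene models, sequences and
per-gene truth under results/simulated/, and prints the class composition.
"""

from common import get_args, default_workspace

from mztseq import io as mio


def main():
    args = get_args(__doc__)
    ws = default_workspace(args, with_sequences=True)
    out = args.outdir / "simulated"
    out.mkdir(parents=True, exist_ok=True)
    ws.config.to_yaml(out / "config.yaml")
    for name, cm in (
        ("polyA", ws.counts.polyA),
        ("ribo", ws.counts.ribo),
        ("premrna", ws.counts.premrna),
        ("exon", ws.counts.exon),
    ):
        mio.write_counts(cm, out / f"counts_{name}.tsv")
    mio.write_metadata(ws.counts.metadata, out / "metadata.tsv")
    ws.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    ws.truth.models.to_gtf(out / "genes.gtf")
    ws.sequences.write_fastas(out)

    print(f"simulated {ws.config.n_genes} genes, seed {ws.config.seed}")
    print("class composition:")
    print(ws.truth.genes["class"].value_counts().to_string())
    egg = ws.truth.egg_tpm()
    maternal = (egg >= 1.0).mean()
    print(f"maternal contribution (egg TPM >= 1): {maternal:.1%} of genes")


if __name__ == "__main__":
    main()
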