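"""Genome-activation calling: intron table construction, thresholds,
categorization, and the windowed scan."""

import numpy as np
import pandas as pd
import pytest

from mztseq import activation as act
from mztseq.genemodels import GeneModel, GeneModelSet
from mztseq.stats import CountMatrix


def _models(intron_lengths: dict) -> GeneModelSet:
    genes = {}
    pos = 0
    for g, ilen in intron_lengths.items():
        if ilen > 0:
            exons = [(pos, pos + 500), (pos + 500 + ilen, pos + 1000 + ilen)]
        else:
            exons = [(pos, pos + 1000)]
        genes[g] = GeneModel(g, "s", "+", {f"{g}.t": exons})
        pos += 20000
    return GeneModelSet(genes)


def _cm(d: dict, samples) -> CountMatrix:
    return CountMatrix(pd.DataFrame(d, index=samples).T)


class TestBuildIntronCounts:
    def test_subtraction(self):
        models = _models({"g1": 1000})
        pre = _cm({"g1": [100, 100]}, ["a", "b"])
        ex = _cm({"g1": [60, 60]}, ["a", "b"])
        table = act.build_intron_counts(pre, ex, models)
        assert (table.counts.loc["g1"] == 40).all()

    def test_negative_differences_clamped_and_counted(self):
        models = _models({"g1": 1000})
        pre = _cm({"g1": [60, 60]}, ["a", "b"])
        ex = _cm({"g1": [70, 50]}, ["a", "b"])
        table = act.build_intron_counts(pre, ex, models)
        assert table.counts.loc["g1", "a"] == 0
        assert table.n_clamped == 1

    def test_rpkm_boundary_exactly_half_retained(self):
        # 2 kb introns, 1 intron read, 1e6 total pre-mRNA reads -> RPKM 0.5
        models = _models({"g1": 2000, "ballast": 0})
        pre = _cm({"g1": [3], "ballast": [999997]}, ["a"])
        ex = _cm({"g1": [2], "ballast": [999997]}, ["a"])
        table = act.build_intron_counts(pre, ex, models)
        assert table.rpkm.loc["g1", "a"] == pytest.approx(0.5)
        assert "g1" in table.counts.index

    def test_below_threshold_in_all_samples_excluded(self):
        models = _models({"g1": 2000, "ballast": 0})
        pre = _cm({"g1": [1, 1], "ballast": [10**6] * 2}, ["a", "b"])
        ex = _cm({"g1": [1, 1], "ballast": [10**6] * 2}, ["a", "b"])
        table = act.build_intron_counts(pre, ex, models)
        assert "g1" not in table.counts.index

    def test_intronless_genes_excluded(self):
        models = _models({"g1": 0})
        pre = _cm({"g1": [100]}, ["a"])
        ex = _cm({"g1": [40]}, ["a"])
        table = act.build_intron_counts(pre, ex, models)
        assert len(table.counts) == 0

    def test_mismatched_samples_rejected(self):
        models = _models({"g1": 1000})
        with pytest.raises(ValueError, match="samples"):
            act.build_intron_counts(
                _cm({"g1": [1, 2]}, ["a", "b"]), _cm({"g1": [1]}, ["a"]), models
            )


def _de_frame(genes, log2fc, padj):
    return pd.DataFrame(
        {
            "baseMean": 100.0,
            "log2FC": log2fc,
            "pvalue": padj,
            "padj": padj,
            "filtered": False,
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TestExonicActivation:
    def test_threshold_conjunction(self):
        de = {4.0: _de_frame(["up", "weak", "notsig", "lowtpm"],
                             [3.0, 0.8, 3.0, 3.0],
                             [1e-9, 1e-9, 0.2, 1e-9])}
        tpm = pd.DataFrame(
            {"4": [50.0, 50.0, 50.0, 0.5]},
            index=["up", "weak", "notsig", "lowtpm"],
        )
        calls = act.call_exonic_activation(de, tpm)
        assert calls[4.0] == {"up"}

    def test_exact_twofold_not_called(self):
        de = {4.0: _de_frame(["g"], [1.0], [1e-9])}
        tpm = pd.DataFrame({"4": [50.0]}, index=["g"])
        assert calls_empty(act.call_exonic_activation(de, tpm))

    def test_downregulation_never_called(self):
        de = {4.0: _de_frame(["g"], [-4.0], [1e-9])}
        tpm = pd.DataFrame({"4": [50.0]}, index=["g"])
        assert calls_empty(act.call_exonic_activation(de, tpm))

    def test_polyA_protocol_rejected(self):
        with pytest.raises(ValueError, match="ribo"):
            act.call_exonic_activation({}, pd.DataFrame(), protocol="polyA")


def calls_empty(calls):
    return all(len(v) == 0 for v in calls.values())


class TestIntronActivation:
    def test_intronless_gene_never_intron_called(self, small_ws):
        models = small_ws.truth.models
        intronless = {g for g in models.gene_ids if models[g].intron_length == 0}
        called = set().union(*small_ws.intron_calls.values())
        assert not (called & intronless)

    def test_triptolide_condition_has_no_intron_calls(self, small_ws):
        last = small_ws.config.timepoints[-1]
        calls = act.call_intron_activation(
            small_ws.counts.exon,
            small_ws.introns,
            timepoints=[last],
            condition="triptolide",
        )
        n_testable = len(small_ws.introns.counts)
        assert len(calls[last]) <= max(1, 0.05 * n_testable)

    def test_joint_bh_family_spans_both_entry_types(self, small_ws):
        meta = small_ws.counts.exon.metadata
        egg = list(meta.index[(meta.timepoint_hpf == 0)])
        smp = list(meta.index[(meta.timepoint_hpf == 4) & (meta.condition == "untreated")])
        de = act.combined_exon_intron_de(
            small_ws.counts.exon, small_ws.introns, egg, smp
        )
        assert de.index.str.endswith("@exon").any()
        assert de.index.str.endswith("@intron").any()


class TestCategorization:
    def test_rule_applications(self):
        egg = pd.Series({"denovo": 0.2, "react": 30.0, "amb": 0.7, "mat": 5.0,
                         "off": 0.1})
        exonic = {4.0: {"denovo", "amb"}}
        intron = {4.0: {"react"}}
        cats = act.categorize_genes(egg, exonic, intron)
        col = cats[4.0]
        assert col["denovo"] == "de_novo_zygotic"
        assert col["react"] == "maternal_reactivated"
        assert col["amb"] == "ambiguous"
        assert col["mat"] == "maternal_only"
        assert col["off"] == "not_expressed"

    def test_every_gene_gets_exactly_one_category(self, small_ws):
        cats = small_ws.categories
        assert cats.notna().all().all()
        assert cats.isin(act.CATEGORIES).all().all()

    def test_activation_is_cumulative(self):
        egg = pd.Series({"g": 0.2})
        cats = act.categorize_genes(egg, {4.0: {"g"}, 5.0: set()})
        assert cats.loc["g", 5.0] == "de_novo_zygotic"


class TestWindowScan:
    def test_identical_libraries_all_zero(self):
        idx = pd.MultiIndex.from_tuples(
            [("s", 0, 10000), ("s", 10000, 20000)], names=["scaffold", "start", "end"]
        )
        w = pd.DataFrame({"count": [100.0, 300.0]}, index=idx)
        scan = act.window_scan(w, w.copy())
        assert scan.log2fc.to_numpy() == pytest.approx([0.0, 0.0])

    def test_fourfold_rpm_increase_log2_two(self):
        idx = pd.MultiIndex.from_tuples(
            [("s", 0, 10000), ("s", 10000, 20000)], names=["scaffold", "start", "end"]
        )
        egg = pd.DataFrame({"count": [10000.0, 990000.0]}, index=idx)
        t = pd.DataFrame({"count": [40000.0, 960000.0]}, index=idx)
        scan = act.window_scan(t, egg, pseudocount=0.0)
        up = scan.loc[("s", 0, 10000), "log2fc"]
        # 4x the window count, slightly offset by the shared denominator
        assert up == pytest.approx(2.0, abs=0.1)

    def test_histone_cluster_tops_the_scan(self, small_ws):
        meta = small_ws.counts.ribo.metadata
        tps = sorted(meta[meta.condition == "untreated"].timepoint_hpf.unique())

        def mean_counts(t):
            smp = meta.index[
                (meta.timepoint_hpf == t) & (meta.condition == "untreated")
            ]
            return small_ws.counts.ribo.counts[list(smp)].mean(axis=1)

        scan = act.window_scan(
            act.bin_counts_by_window(small_ws.truth.models, mean_counts(tps[-1])),
            act.bin_counts_by_window(small_ws.truth.models, mean_counts(tps[0])),
        )
        top = scan[scan.log2fc > np.log2(3)]
        assert len(top) > 0
        hist_windows = top.index.get_level_values("scaffold") == "scaffold_hist"
        assert hist_windows.any()

    def test_nonpositive_window_size_rejected(self, small_ws):
        with pytest.raises(ValueError, match="window size"):
            act.bin_counts_by_window(
                small_ws.truth.models, pd.Series(dtype=float), window_size=0
            )
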