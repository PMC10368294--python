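"""Forward simulator: determinism, class allocation, capture model,
count-table structure, condition arms, and sequence implants."""

import numpy as np
import pandas as pd
import pytest

from mztseq.simulate import (
    SimulationConfig,
    capture_probability,
    simulate_counts,
    simulate_sequences,
    simulate_truth,
)


def cfg(**kw):
    base = dict(n_genes=120, seed=9)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(class_fractions={"stable_maternal": 0.5}).validate()

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown classes"):
            SimulationConfig(class_fractions={"mystery": 1.0}).validate()

    def test_nonmonotone_timepoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SimulationConfig(timepoints=(0, 2, 1)).validate()

    def test_mirna_length_bounds(self):
        with pytest.raises(ValueError, match="18, 25"):
            SimulationConfig(mirna_length=30).validate()

    def test_yaml_round_trip(self, tmp_path):
        c = cfg(nb_dispersion=0.07, seed=42)
        path = tmp_path / "c.yaml"
        c.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == c


class TestCaptureProbability:
    def test_no_tail_no_capture(self):
        assert capture_probability(0.0, cfg()) == 0.0

    def test_half_saturation_at_K(self):
        c = cfg()
        assert capture_probability(c.tail_capture_K, c) == pytest.approx(0.5)

    def test_hill_closed_form(self):
        c = SimulationConfig(tail_capture_K=30, tail_capture_h=2)
        assert capture_probability(90.0, c) == pytest.approx(0.9)

    def test_monotone_and_below_one(self):
        c = cfg()
        tails = np.linspace(0, 500, 100)
        p = capture_probability(tails, c)
        assert (np.diff(p) >= 0).all()
        assert (p < 1).all() and (p >= 0).all()

    def test_negative_tail_rejected(self):
        with pytest.raises(ValueError):
            capture_probability(-1.0, cfg())


class TestSimulateTruth:
    def test_determinism_same_seed(self):
        t1, t2 = simulate_truth(cfg()), simulate_truth(cfg())
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        pd.testing.assert_frame_equal(t1.abundance, t2.abundance)
        pd.testing.assert_frame_equal(t1.tail_nt, t2.tail_nt)

    def test_single_class_degenerate_all_constant(self):
        c = cfg(class_fractions={"stable_maternal": 1.0})
        truth = simulate_truth(c)
        assert (truth.genes["class"] == "stable_maternal").all()
        assert (truth.abundance.nunique(axis=1) == 1).all()
        assert (truth.tail_nt.nunique(axis=1) == 1).all()

    def test_class_counts_within_one_of_fractions(self):
        c = SimulationConfig(
            n_genes=1000,
            seed=3,
            class_fractions={"stable_maternal": 0.5, "de_novo_zygotic": 0.5},
        )
        counts = simulate_truth(c).genes["class"].value_counts()
        assert abs(counts["stable_maternal"] - 500) <= 1
        assert abs(counts["de_novo_zygotic"] - 500) <= 1

    def test_decay_strictly_after_deadenylation(self):
        g = simulate_truth(cfg(n_genes=600)).genes
        dd = g[g["class"] == "deadenylated_then_degraded"]
        assert (dd.t_decay > dd.t_deadenylation).all()

    def test_triptolide_zeroes_zygotic_components(self):
        truth = simulate_truth(cfg(n_genes=600))
        g = truth.genes
        zyg = g.index[g["class"] == "de_novo_zygotic"]
        last = truth.abundance.columns[-1]
        assert (
            truth.abundance_triptolide.loc[zyg, last]
            == g.loc[zyg, "maternal_abundance"]
        ).all()

    def test_abundance_nonnegative(self):
        assert (simulate_truth(cfg()).abundance.to_numpy() >= 0).all()


class TestSimulateCounts:
    def test_determinism_byte_identical(self):
        c = cfg()
        truth = simulate_truth(c)
        s1, s2 = simulate_counts(truth, c), simulate_counts(truth, c)
        for a, b in ((s1.polyA, s2.polyA), (s1.premrna, s2.premrna)):
            pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_exon_counts_bounded_by_premrna(self):
        c = cfg()
        s = simulate_counts(simulate_truth(c), c)
        assert (s.exon.counts.to_numpy() <= s.premrna.counts.to_numpy()).all()

    def test_zero_dispersion_gives_poisson_variance(self):
        c = SimulationConfig(
            n_genes=20,
            seed=2,
            nb_dispersion=0.0,
            replicates=60,
            class_fractions={"stable_maternal": 1.0},
        )
        s = simulate_counts(simulate_truth(c), c)
        meta = s.metadata
        egg = meta.index[
            (meta.protocol == "ribo")
            & (meta.timepoint_hpf == 0)
            & (meta.condition == "untreated")
        ]
        sub = s.ribo.counts[list(egg)]
        ratio = sub.var(axis=1) / sub.mean(axis=1)
        # index of dispersion ~ 1 for Poisson; chi2-based tolerance at n=60
        assert ratio.mean() == pytest.approx(1.0, abs=0.15)

    def test_depth_must_be_positive(self):
        c = cfg()
        truth = simulate_truth(c)
        c.library_depth = 0
        with pytest.raises(ValueError, match="depth"):
            simulate_counts(truth, c)

    def test_protocol_contrast_for_deadenylated_genes(self):
        # tail loss drops poly(A)+ capture while true abundance is unchanged
        c = SimulationConfig(
            n_genes=40,
            seed=6,
            replicates=200,
            class_fractions={"stable_maternal": 0.5, "deadenylated_only": 0.5},
        )
        truth = simulate_truth(c)
        s = simulate_counts(truth, c)
        meta = s.metadata
        genes = truth.genes.index[truth.genes["class"] == "deadenylated_only"]

        def mean_counts(cm, t):
            smp = meta.index[
                (meta.protocol == cm)
                & (meta.timepoint_hpf == t)
                & (meta.condition == "untreated")
            ]
            m = s.ribo if cm == "ribo" else s.polyA
            return m.counts.loc[genes, list(smp)].mean(axis=1)

        last = c.timepoints[-1]
        ribo_ratio = mean_counts("ribo", last) / mean_counts("ribo", 0)
        polyA_ratio = mean_counts("polyA", last) / mean_counts("polyA", 0)
        assert ribo_ratio.mean() == pytest.approx(1.0, abs=0.1)
        assert (polyA_ratio < 0.5).all()

    def test_triptolide_denovo_counts_stay_at_egg_level(self):
        c = SimulationConfig(
            n_genes=40,
            seed=8,
            replicates=100,
            class_fractions={"stable_maternal": 0.7, "de_novo_zygotic": 0.3},
        )
        truth = simulate_truth(c)
        s = simulate_counts(truth, c)
        meta = s.metadata
        genes = truth.genes.index[truth.genes["class"] == "de_novo_zygotic"]
        egg = meta.index[
            (meta.protocol == "ribo")
            & (meta.timepoint_hpf == 0)
            & (meta.condition == "untreated")
        ]
        trip = meta.index[(meta.protocol == "ribo") & (meta.condition == "triptolide")]
        m_egg = s.ribo.counts.loc[genes, list(egg)].mean(axis=1)
        m_trip = s.ribo.counts.loc[genes, list(trip)].mean(axis=1)
        assert np.abs(m_trip.mean() - m_egg.mean()) < 1.0

    def test_histone_like_invisible_in_polyA(self):
        c = cfg(n_genes=400)
        truth = simulate_truth(c)
        s = simulate_counts(truth, c)
        hist = truth.genes.index[truth.genes["class"] == "histone_like"]
        frac_polyA = s.polyA.counts.loc[hist].sum().sum() / s.polyA.counts.sum().sum()
        frac_ribo = s.ribo.counts.loc[hist].sum().sum() / s.ribo.counts.sum().sum()
        assert frac_polyA < 0.1 * frac_ribo

    def test_seed_streams_isolated_per_matrix(self):
        # the ribo draw must not depend on whether polyA was drawn first
        c = cfg()
        truth = simulate_truth(c)
        full = simulate_counts(truth, c)
        again = simulate_counts(truth, c)
        pd.testing.assert_frame_equal(full.ribo.counts, again.ribo.counts)


class TestSimulateSequences:
    def test_zero_mismatch_site_is_exact_reverse_complement(self):
        from mztseq.mirna import revcomp

        c = cfg(n_genes=400, target_site_edits=((0, 0),))
        truth = simulate_truth(c)
        seqs = simulate_sequences(truth, c)
        sites = seqs.target_sites[~seqs.target_sites.is_decoy]
        assert len(sites)
        for _, row in sites.iterrows():
            tx = seqs.transcripts[row.gene_id]
            site = tx[row.site_start : row.site_end]
            assert site == revcomp(seqs.matures[row.mirna_id])

    def test_gu_edits_preserve_pairing_but_not_wc(self):
        from mztseq.mirna import pair_type

        c = cfg(n_genes=400, target_site_edits=((0, 2),))
        truth = simulate_truth(c)
        seqs = simulate_sequences(truth, c)
        sites = seqs.target_sites[~seqs.target_sites.is_decoy]
        for _, row in sites.iterrows():
            tx = seqs.transcripts[row.gene_id]
            site = tx[row.site_start : row.site_end]
            mature = seqs.matures[row.mirna_id]
            kinds = [
                pair_type(mature[i], site[len(site) - 1 - i])
                for i in range(len(mature))
            ]
            assert kinds.count("GU") == 2
            assert kinds.count("MM") == 0

    def test_hairpin_contains_mature_and_its_arm_folds(self):
        from mztseq.mirna import fold_hairpin

        c = cfg(n_genes=400)
        truth = simulate_truth(c)
        seqs = simulate_sequences(truth, c)
        assert len(seqs.hairpins)
        for _, hp in seqs.hairpins.iterrows():
            tx = seqs.transcripts[hp.host_gene]
            mature = seqs.matures[hp.mirna_id]
            assert tx[hp.mature_start : hp.mature_end] == mature
            fold = fold_hairpin(tx)
            paired = sum(
                1
                for i in range(hp.mature_start, hp.mature_end)
                if fold["partner"][i] >= 0
            )
            assert paired >= 14

    def test_cds_lengths_match_gene_models(self):
        c = cfg(n_genes=100)
        truth = simulate_truth(c)
        seqs = simulate_sequences(truth, c)
        lens = truth.models.gene_lengths("union")
        for g, tx in seqs.transcripts.items():
            if g in seqs.annotations.index:
                assert len(tx) == lens[g]

    def test_determinism(self):
        c = cfg(n_genes=100)
        truth = simulate_truth(c)
        s1, s2 = simulate_sequences(truth, c), simulate_sequences(truth, c)
        assert s1.transcripts == s2.transcripts
        assert s1.mature_refs == s2.mature_refs
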