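"""miRNA discovery: homology scan, Nussinov folding, stem-loop detection,
candidate filtering, and full-complementarity target prediction."""

import numpy as np
import pandas as pd
import pytest

from mztseq import mirna
from oracles import nussinov_enumerate


class TestScan:
    refs = {"ref1": "ACGGATTCAGCTCAAGGTCTAC"}  # 22 nt, aperiodic

    def test_exact_match_zero_mismatches(self):
        tx = {"t1": "GG" + self.refs["ref1"] + "GGG"}
        hits = mirna.scan_reference_mirnas(self.refs, tx)
        row = hits.iloc[0]
        assert (row.start, row.end, row.strand, row.mismatches) == (2, 24, "+", 0)

    def test_three_mismatches_not_reported_at_max_two(self):
        q = list(self.refs["ref1"])
        q[0], q[10], q[21] = "T", "A", "G"
        tx = {"t1": "GG" + "".join(q) + "GGG"}
        hits = mirna.scan_reference_mirnas(self.refs, tx, max_mismatch=2)
        assert hits.empty

    def test_reverse_strand_hit_flagged_with_plus_coordinates(self):
        tx = {"t1": "AAAA" + mirna.revcomp(self.refs["ref1"]) + "CCCC"}
        hits = mirna.scan_reference_mirnas(self.refs, tx)
        row = hits.iloc[0]
        assert row.strand == "-"
        assert tx["t1"][row.start : row.end] == mirna.revcomp(self.refs["ref1"])

    def test_reference_shorter_than_word_rejected(self):
        with pytest.raises(ValueError, match="word size"):
            mirna.scan_reference_mirnas({"r": "ACGTA"}, {"t": "ACGTACGT" * 5})

    def test_seed_completeness_on_planted_occurrences(self):
        # any planted hit sharing one exact 7-mer with the reference is found
        rng = np.random.default_rng(1)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 22))
        for trial in range(10):
            q = list(ref)
            pos = rng.choice(22, size=2, replace=False)  # 2 mm leaves a 7-mer
            for p in pos:
                q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
            tx = {"t": "".join("ACGT"[i] for i in rng.integers(0, 4, 40)) + "".join(q)}
            hits = mirna.scan_reference_mirnas({"r": ref}, tx)
            plus = hits[hits.strand == "+"]
            assert (plus.start == 40).any()


class TestFold:
    def test_simple_hairpin(self):
        res = mirna.fold_hairpin("GGGAAACCC")
        assert res["structure"] == "(((...)))"
        assert res["pairs"] == 3

    def test_unpairable_sequence(self):
        assert mirna.fold_hairpin("AAAAAAA")["pairs"] == 0

    def test_gu_wobble_toggle(self):
        # with wobble the three G:U closures beat the single A:U pairing
        # available under the Watson-Crick-only alphabet
        assert mirna.fold_hairpin("GGGAAAUUU", allow_gu=True)["pairs"] == 3
        wc_only = mirna.fold_hairpin("GGGAAAUUU", allow_gu=False)["pairs"]
        assert wc_only == nussinov_enumerate("GGGAAAUUU", allow_gu=False) == 1

    def test_non_nucleotide_rejected_but_n_tolerated(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            mirna.fold_hairpin("ACGX")
        res = mirna.fold_hairpin("GGGNNNCCC")
        assert res["pairs"] == 3  # N never pairs but flanks can

    @pytest.mark.parametrize("allow_gu", [True, False])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_enumeration(self, seed, allow_gu):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, n))
        ours = mirna.fold_hairpin(seq, allow_gu=allow_gu)["pairs"]
        assert ours == nussinov_enumerate(seq, allow_gu=allow_gu)

    def test_structure_consistent_with_partner_list(self):
        res = mirna.fold_hairpin("GGCGAAAGCGAAACGC")
        partner = res["partner"]
        for i, p in enumerate(partner):
            if p >= 0:
                assert partner[p] == i
        assert res["structure"].count("(") == res["pairs"]


class TestStemLoop:
    mature = "GCGCGCAUAUGCGCAUAUGGCC".replace("U", "T")  # 22 nt

    def _transcript(self, arm="5p", loop="AACAATTC"):
        hp = (
            self.mature + loop + mirna.revcomp(self.mature)
            if arm == "5p"
            else mirna.revcomp(self.mature) + loop + self.mature
        )
        flank5 = "ATCTGATCGTAGCTAGCTAGCA"
        flank3 = "TGACTGATCGATCGTACGATCA"
        start = len(flank5) if arm == "5p" else len(flank5) + 22 + len(loop)
        return flank5 + hp + flank3, start

    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_implanted_hairpin_passes_with_correct_arm(self, arm):
        tx, start = self._transcript(arm)
        hit = {"start": start, "end": start + 22}
        det = mirna.detect_stem_loop(hit, tx)
        assert det["passes"]
        assert det["arm"] == arm
        assert det["stem_pairs"] >= 14

    def test_mature_inside_loop_fails(self):
        # an A/T-only mature flanked by a strong unrelated stem: the mature
        # region itself stays unpaired
        mature = "ATATAAATATTAAATATAAATA"
        stem5, stem3 = "GGGCCCGGGCCC", "GGGCCCGGGCCC"
        tx = stem5 + mature + mirna.revcomp(stem5) + "AAAA"
        hit = {"start": len(stem5), "end": len(stem5) + 22}
        det = mirna.detect_stem_loop(hit, tx, flank=20)
        assert not det["passes"]

    def test_duplicated_mature_on_both_arms_reports_each(self):
        # a perfect long stem whose two arms are the mature and its
        # reverse complement: scanning the reference finds both arms
        tx, _ = self._transcript("5p")
        hits = mirna.scan_reference_mirnas({"ref": self.mature}, {"t": tx})
        arms = set()
        for _, h in hits.iterrows():
            det = mirna.detect_stem_loop(h, tx)
            if det["passes"]:
                arms.add(det["arm"])
        assert arms == {"5p", "3p"}

    def test_edge_hit_truncation_flagged(self):
        tx, start = self._transcript("5p")
        hit = {"start": 0, "end": 22}
        det = mirna.detect_stem_loop(hit, tx)
        assert det["truncated"]


class TestFilterCandidates:
    def _hairpin_hit(self, tx_id, passes=True):
        return {
            "transcript_id": tx_id,
            "start": 10,
            "end": 32,
            "mismatches": 1,
            "ref_id": "ref",
            "mature_seq": "A" * 22,
            "detect": {
                "passes": passes,
                "arm": "5p",
                "structure": ".",
                "stem_pairs": 20,
                "loop_length": 5,
            },
        }

    def _de(self, rows):
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["log2FC", "padj"]
        ).assign(baseMean=1.0, filtered=False)

    def test_activated_transcripts_retained_others_dropped(self):
        de = self._de({"up": [3.0, 1e-6], "flat": [0.1, 0.9], "weak": [2.0, 0.2]})
        hits = [self._hairpin_hit(t) for t in ("up", "flat", "weak")]
        cands = mirna.filter_candidates(hits, de)
        assert [c.transcript_id for c in cands] == ["up"]

    def test_failed_hairpins_never_pass(self):
        de = self._de({"up": [3.0, 1e-6]})
        cands = mirna.filter_candidates([self._hairpin_hit("up", passes=False)], de)
        assert cands == []

    def test_triptolide_inhibition_annotated_not_required(self):
        de = self._de({"up": [3.0, 1e-6], "up2": [3.0, 1e-6]})
        trip = self._de({"up": [-2.0, 1e-4], "up2": [-0.1, 0.8]})
        cands = mirna.filter_candidates(
            [self._hairpin_hit("up"), self._hairpin_hit("up2")], de, trip
        )
        flags = {c.transcript_id: c.triptolide_inhibited for c in cands}
        assert flags == {"up": True, "up2": False}


class TestTargets:
    mature = "ACGGCAUAUGCGCAUAUGGCAC".replace("U", "T")

    def _cand(self):
        from mztseq.mirna import MiRNACandidate

        return MiRNACandidate(
            candidate_id="c0",
            mature_seq=self.mature,
            transcript_id="src",
            start=0,
            end=22,
            arm="5p",
            structure=".",
            stem_pairs=20,
            loop_length=5,
            mismatches_vs_ref=0,
            ref_id="r",
        )

    def test_exact_reverse_complement_full_pairing(self):
        site = mirna.revcomp(self.mature)
        targets = {"t1": "AAAA" + site + "CCCC"}
        dups = mirna.predict_targets([self._cand()], targets)
        assert len(dups) == 1
        d = dups[0]
        assert (d.wc, d.gu, d.mismatches) == (22, 0, 0)
        assert d.paired_fraction == 1.0
        assert d.pairing == "|" * 22

    def test_single_gu_site_counted(self):
        site = list(mirna.revcomp(self.mature))
        # mature[1] is C... choose a G position: mature G pairs site C -> T
        gpos = self.mature.index("G")
        site[21 - gpos] = "T"
        targets = {"t1": "AAAA" + "".join(site) + "CCCC"}
        d = mirna.predict_targets([self._cand()], targets)[0]
        assert (d.wc, d.gu, d.mismatches) == (21, 1, 0)
        assert d.paired_fraction == 1.0

    def test_four_mismatches_rejected_at_default_threshold(self):
        site = list(mirna.revcomp(self.mature))
        for i in (2, 8, 14, 20):
            site[i] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[i]]
        targets = {"t1": "AAAA" + "".join(site) + "CCCC"}
        assert mirna.predict_targets([self._cand()], targets) == []

    def test_control_set_hits_flagged_separately(self):
        site = mirna.revcomp(self.mature)
        dups = mirna.predict_targets(
            [self._cand()], {"cl": "AA" + site}, {"st": "TT" + site}
        )
        flags = {d.target_id: d.in_control_set for d in dups}
        assert flags == {"cl": False, "st": True}

    def test_empty_candidate_list_empty_output(self):
        assert mirna.predict_targets([], {"t": "ACGT" * 30}) == []


class TestEndToEnd:
    def test_implanted_hairpins_recovered_with_correct_arm(self, small_ws):
        cands = small_ws.mirna_candidates()
        truth = small_ws.sequences.hairpins
        refs_mm = dict(
            zip(small_ws.truth.mirnas.mirna_id, small_ws.truth.mirnas.reference_mismatches)
        )
        for _, hp in truth.iterrows():
            if refs_mm[hp.mirna_id] > 1:
                continue
            match = [
                c
                for c in cands
                if c.transcript_id == hp.host_gene
                and c.start == hp.mature_start
                and c.arm == hp.arm
            ]
            assert match, f"hairpin {hp.mirna_id} not recovered"

    def test_implanted_targets_recovered_decoys_absent(self, small_ws):
        cands = small_ws.mirna_candidates()
        dups = small_ws.mirna_targets(cands)
        sites = small_ws.sequences.target_sites
        hit_genes = {d.target_id for d in dups}
        cleared_modes = ("deadenylated_only", "deadenylated_then_degraded")
        for _, row in sites.iterrows():
            if row.is_decoy:
                assert row.gene_id not in hit_genes
            elif small_ws.modes.get(row.gene_id) in cleared_modes:
                assert row.gene_id in hit_genes
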