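"""End-to-end orchestration over a simulated (or loaded) dataset.

``Workspace`` wires the stage analyses together and caches the shared
intermediates: gene lengths, TPM tables, per-protocol differential series
against the egg, the gated intron table, clearance profiles, and the
Triptolide contrasts. Every method is a thin call into the stage modules, so
scripts and tests can ask for exactly the readout they need.
"""

from __future__ import annotations

from functools import cached_property

import numpy as np
import pandas as pd

from . import activation as act
from . import clearance as clr
from . import codon, histones, mirna, stages
from .simulate import (
    SimulatedCounts,
    SimulatedSequences,
    SimulationTruth,
    histone_class_map,
    simulate_counts,
    simulate_sequences,
    simulate_truth,
)
from .stats import compute_tpm, de_vs_egg_series, nb_test

__all__ = ["Workspace"]


class Workspace:
    """Cached analysis state for one dataset."""

    def __init__(
        self,
        truth: SimulationTruth,
        counts: SimulatedCounts,
        sequences: SimulatedSequences | None = None,
    ):
        self.truth = truth
        self.counts = counts
        self.sequences = sequences
        self.config = truth.config

    @classmethod
    def from_config(cls, config, with_sequences: bool = False) -> "Workspace":
        truth = simulate_truth(config)
        counts = simulate_counts(truth, config)
        seqs = simulate_sequences(truth, config) if with_sequences else None
        return cls(truth, counts, seqs)

    # -- shared intermediates ------------------------------------------------

    @cached_property
    def lengths(self) -> pd.Series:
        return self.truth.models.gene_lengths("union")

    def _tpm(self, cm) -> pd.DataFrame:
        return compute_tpm(cm, self.lengths.reindex(cm.counts.index))

    def _by_timepoint(self, cm, condition: str = "untreated") -> pd.DataFrame:
        """Replicate-mean TPM with one column per timepoint."""
        tpm = self._tpm(cm)
        meta = cm.metadata
        cols = {}
        for t in sorted(meta[meta.condition == condition].timepoint_hpf.unique()):
            smp = meta.index[
                (meta.timepoint_hpf == t) & (meta.condition == condition)
            ]
            cols[f"{t:g}"] = tpm[list(smp)].mean(axis=1)
        return pd.DataFrame(cols)

    @cached_property
    def tpm_ribo(self) -> pd.DataFrame:
        return self._by_timepoint(self.counts.ribo)

    @cached_property
    def tpm_polyA(self) -> pd.DataFrame:
        return self._by_timepoint(self.counts.polyA)

    @cached_property
    def egg_tpm(self) -> pd.Series:
        return self.tpm_ribo.iloc[:, 0]

    @cached_property
    def de_ribo(self) -> dict:
        return de_vs_egg_series(self.counts.ribo, "ribo")

    @cached_property
    def de_polyA(self) -> dict:
        return de_vs_egg_series(self.counts.polyA, "polyA")

    @cached_property
    def introns(self) -> act.IntronCountTable:
        return act.build_intron_counts(
            self.counts.premrna, self.counts.exon, self.truth.models
        )

    # -- activation ----------------------------------------------------------

    @cached_property
    def exonic_calls(self) -> dict:
        return act.call_exonic_activation(self.de_ribo, self.tpm_ribo)

    @cached_property
    def intron_calls(self) -> dict:
        return act.call_intron_activation(self.counts.exon, self.introns)

    @cached_property
    def categories(self) -> pd.DataFrame:
        return act.categorize_genes(self.egg_tpm, self.exonic_calls, self.intron_calls)

    # -- clearance -----------------------------------------------------------

    def _late_de(self, series: dict) -> dict:
        return {t: de for t, de in series.items() if t >= 2.0}

    @cached_property
    def profiles(self) -> clr.ClearanceProfiles:
        return clr.clearance_profiles(
            self._late_de(self.de_polyA), self._late_de(self.de_ribo), self.tpm_polyA
        )

    @cached_property
    def modes(self) -> pd.Series:
        return clr.clearance_mode(self.profiles)

    @cached_property
    def triptolide_de_polyA(self) -> pd.DataFrame:
        return self._trip_vs_dmso("polyA")

    @cached_property
    def triptolide_de_ribo(self) -> pd.DataFrame:
        return self._trip_vs_dmso("ribo")

    def _trip_vs_dmso(self, protocol: str) -> pd.DataFrame:
        cm = self.counts.polyA if protocol == "polyA" else self.counts.ribo
        meta = cm.metadata
        last = self.config.timepoints[-1]
        dmso = list(
            meta.index[(meta.condition == "dmso") & (meta.timepoint_hpf == last)]
        )
        trip = list(
            meta.index[(meta.condition == "triptolide") & (meta.timepoint_hpf == last)]
        )
        return nb_test(cm, dmso, trip)

    @cached_property
    def stable_set(self) -> pd.Index:
        return clr.stable_reference_set(self.tpm_polyA, self.triptolide_de_polyA)

    def triptolide_test(self, group: str, protocol: str) -> dict:
        cm = self.counts.polyA if protocol == "polyA" else self.counts.ribo
        last = self.config.timepoints[-1]
        fc_trip = clr.condition_fold_change(cm, protocol, "triptolide", last)
        fc_dmso = clr.condition_fold_change(cm, protocol, "dmso", last)
        genes = self.profiles.genes_in_group(group)
        return clr.triptolide_effect(fc_trip, fc_dmso, genes)

    # -- histones ------------------------------------------------------------

    @cached_property
    def histone_map(self) -> pd.Series:
        return histone_class_map(self.truth)

    def histone_proportions(self) -> pd.DataFrame:
        return histones.class_proportions(self.tpm_ribo, self.histone_map)

    def histone_net_activation(self, trimmed: bool = False) -> pd.DataFrame:
        meta = self.counts.ribo.metadata
        cols = {}
        for t in sorted(
            meta[meta.condition == "untreated"].timepoint_hpf.unique()
        ):
            smp = meta.index[
                (meta.timepoint_hpf == t) & (meta.condition == "untreated")
            ]
            cols[f"{t:g}"] = self.counts.ribo.counts[list(smp)].mean(axis=1)
        binary_map = pd.Series(
            np.where(self.truth.genes["class"] == "histone_like", "histone", "non_histone"),
            index=self.truth.genes.index,
        )
        return histones.net_activation(
            pd.DataFrame(cols), binary_map, trimmed=trimmed
        )

    # -- sequence features ---------------------------------------------------

    def codon_table(self, top_n: int = 100) -> codon.CodonUsageTable:
        if self.sequences is None:
            raise ValueError("workspace has no sequences")
        stable = self.truth.genes.index[
            (self.truth.genes["class"] == "stable_maternal")
        ]
        ranking = self.egg_tpm.reindex(stable).dropna()
        return codon.build_codon_table(self.sequences.cds, ranking, top_n=top_n)

    def cai_table(self, table=None) -> pd.Series:
        table = table or self.codon_table()
        vals = {
            g: codon.cai(s, table)
            for g, s in self.sequences.cds.items()
        }
        return pd.Series(vals, name="cai")

    # -- miRNA ---------------------------------------------------------------

    def mirna_candidates(self, stem_min: int = 14) -> list:
        if self.sequences is None:
            raise ValueError("workspace has no sequences")
        hits = mirna.scan_reference_mirnas(
            self.sequences.mature_refs, self.sequences.transcripts
        )
        last = self.config.timepoints[-1]
        activation_de = self.de_ribo[last]
        hairpin_hits = []
        for _, h in hits.iterrows():
            tx = self.sequences.transcripts[h.transcript_id]
            det = mirna.detect_stem_loop(h, tx, stem_min=stem_min)
            mature = tx[h.start : h.end]
            hairpin_hits.append(
                {**h.to_dict(), "detect": det, "mature_seq": mature}
            )
        return mirna.filter_candidates(
            hairpin_hits, activation_de, self.triptolide_de_ribo
        )

    def mirna_targets(self, candidates=None) -> list:
        candidates = candidates if candidates is not None else self.mirna_candidates()
        cleared = self.modes.index[
            self.modes.isin(["deadenylated_only", "deadenylated_then_degraded"])
        ]
        stable = self.stable_set
        cleared_seqs = {
            g: self.sequences.transcripts[g]
            for g in cleared
            if g in self.sequences.transcripts
        }
        stable_seqs = {
            g: self.sequences.transcripts[g]
            for g in stable
            if g in self.sequences.transcripts
        }
        return mirna.predict_targets(candidates, cleared_seqs, stable_seqs)

    # -- stages --------------------------------------------------------------

    def stage_calls(self) -> pd.DataFrame:
        sig = pd.Series(False, index=self.counts.polyA.counts.index)
        for de in self.de_polyA.values():
            sig |= (de.padj < 0.05).fillna(False)
        return stages.call_stage_specific(self.tpm_polyA, sig)

    def stage_clusters(self, n_groups: int = 5) -> pd.Series:
        """Peak-stage clusters pooled into up to ``n_groups`` ordered groups.

        Adjacent low-count peak stages are pooled by cumulative gene count
        (the sparse later clusters merge together), keeping every resulting
        group nonempty. Fewer than ``n_groups`` occupied peak stages yield
        that many groups.
        """
        calls = self.stage_calls()
        q = calls[calls.qualifies]
        order = list(self.tpm_polyA.columns)
        peaks = q.peak_stage.map(order.index)
        occupied = sorted(peaks.unique())
        k = min(n_groups, len(occupied))
        counts = peaks.value_counts().reindex(occupied, fill_value=0)
        total = counts.sum()
        pool, gi, cum = {}, 0, 0
        remaining = len(occupied)
        for stage_idx in occupied:
            pool[stage_idx] = f"stage_group_{gi}"
            cum += counts[stage_idx]
            remaining -= 1
            # advance when this group reached its share, keeping enough
            # stages for the groups still to fill
            if gi < k - 1 and (cum >= total * (gi + 1) / k or remaining <= k - gi - 1):
                gi += 1
        return peaks.map(pool)
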