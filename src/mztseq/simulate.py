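"""Forward simulator for a maternal-to-zygotic transition RNA-seq timecourse.

Generates paired poly(A)+ / rRNA-depleted count matrices, exon and pre-mRNA
count tables, sequences (CDS, 3'UTRs, transcripts, reference mature miRNAs),
and per-gene ground truth, with the statistical structure the downstream
analyses assume:

* a maternal contribution whose poly(A)-tail trajectories (readenylation,
  staged deadenylation) change poly(A)+ capture but not true abundance;
* delayed zygotic activation, including re-activation of maternal genes that
  is visible mainly as intronic (nascent pre-mRNA) signal;
* non-adenylated histone-like genes that activate first and expand to a
  configurable share of the transcriptome;
* nucleolytic decay delayed relative to deadenylation, suppressed in a
  transcription-inhibited (Triptolide-like) condition;
* coding sequences with controllable codon bias, and transcripts carrying
  implanted miRNA hairpins plus near-complementary 3'UTR target sites.

Counts are generated at the count-table level (no read simulation): the
expected read count of gene g in a library is proportional to abundance x
length, multiplied by the oligo-dT capture probability of its current tail
length for poly(A)+ libraries. Counts are NB(mean m, variance m + alpha m^2);
alpha = 0 degenerates to Poisson. Each output matrix draws from its own
documented seed stream so adding one matrix never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genemodels import GeneModel, GeneModelSet
from .stats import CountMatrix

__all__ = [
    "CLASSES",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedCounts",
    "SimulatedSequences",
    "capture_probability",
    "simulate_truth",
    "simulate_counts",
    "simulate_sequences",
    "simulate_go_map",
]

CLASSES = (
    "stable_maternal",
    "readenylated",
    "deadenylated_only",
    "deadenylated_then_degraded",
    "reactivated_maternal",
    "de_novo_zygotic",
    "histone_like",
    "mirna_target",
)

#: named sub-seed streams (spawn keys off the master seed)
_STREAMS = {"truth": 0, "polyA": 1, "ribo": 2, "exon_intron": 3, "sequences": 4}

_DEFAULT_FRACTIONS = {
    "stable_maternal": 0.28,
    "readenylated": 0.14,
    "deadenylated_only": 0.16,
    "deadenylated_then_degraded": 0.16,
    "reactivated_maternal": 0.14,
    "de_novo_zygotic": 0.06,
    "histone_like": 0.04,
    "mirna_target": 0.02,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the forward model.

    Defaults emulate the study design: unfertilized egg (0 h.p.f.) through
    7 h.p.f. hourly (plus 0.5), two replicates, ~1e6 reads per library, and a
    Triptolide/DMSO arm at 7 h.p.f. Tail capture is a Hill function with
    half-saturation ``tail_capture_K`` (nt) and exponent ``tail_capture_h``.
    """

    n_genes: int = 2000
    timepoints: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    replicates: int = 2
    library_depth: float = 1.0e6
    #: NB dispersion of library counts; parallel libraries built from the
    #: same pooled-embryo RNA behave close to technical replicates
    nb_dispersion: float = 0.01
    tail_capture_K: float = 30.0
    tail_capture_h: float = 2.0
    class_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    #: fraction of de novo zygotic transcriptional signal attributed to introns
    nascent_intron_fraction: float = 0.3
    #: zygotic exonic increment of reactivated genes, relative to maternal level
    reactivation_exon_frac: float = 0.2
    #: intron signal of reactivated genes, as a multiple of the exonic increment
    reactivation_intron_ratio: float = 10.0
    #: background intron signal (mis-spliced / nascent) for all multi-exon genes
    background_intron_frac: float = 0.01
    #: histone-like share of total abundance at full activation (4 h.p.f.)
    histone_share: float = 1.0 / 3.0
    #: maternal histone share of the egg transcriptome
    maternal_histone_share: float = 0.018
    decay_rate_per_h: float = 1.0  # log2-fold decay per hour after onset
    n_mirnas: int = 4
    mirna_length: int = 22
    #: mismatches of each reference mature vs the implanted mature (cycled)
    reference_mismatches: tuple = (0, 1)
    #: (mismatches, G:U conversions) per implanted target site (cycled)
    target_site_edits: tuple = ((0, 0), (0, 1), (1, 0), (0, 2))
    decoy_mismatches: int = 5
    n_decoys: int = 3
    high_bias_fraction: float = 0.2
    #: when False, the Triptolide-like arm has no effect (null configuration)
    triptolide_effective: bool = True
    seed: int = 0

    def validate(self) -> None:
        fr = self.class_fractions
        unknown = set(fr) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_fractions: {unknown}")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be nonnegative")
        tps = list(self.timepoints)
        if sorted(tps) != tps or len(set(tps)) != len(tps):
            raise ValueError("timepoints must be strictly increasing")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not (18 <= self.mirna_length <= 25):
            raise ValueError("mature miRNA length must be in [18, 25]")
        for frac in (
            self.nascent_intron_fraction,
            self.high_bias_fraction,
            self.maternal_histone_share,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-matrix generator from the shared master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["timepoints"] = list(d["timepoints"])
        d["reference_mismatches"] = list(d["reference_mismatches"])
        d["target_site_edits"] = [list(x) for x in d["target_site_edits"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["timepoints"] = tuple(d["timepoints"])
        d["reference_mismatches"] = tuple(d["reference_mismatches"])
        d["target_site_edits"] = tuple(tuple(x) for x in d["target_site_edits"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def capture_probability(tail_length, config: SimulationConfig):
    """Oligo-dT capture probability of a transcript with the given tail (nt).

    Hill saturation L^h / (L^h + K^h): 0 at L=0, 0.5 at L=K, monotone
    nondecreasing, strictly below 1.
    """
    L = np.asarray(tail_length, dtype=float)
    if np.any(L < 0):
        raise ValueError("tail length must be >= 0")
    K, h = config.tail_capture_K, config.tail_capture_h
    with np.errstate(divide="ignore"):
        p = 1.0 / (1.0 + (K / np.where(L > 0, L, np.inf)) ** h)
    out = np.where(L > 0, p, 0.0)
    return float(out) if np.isscalar(tail_length) else out


@dataclass
class SimulationTruth:
    """Per-gene generative parameters, labels, and trajectory tables.

    Trajectory frames are genes x timepoints. ``abundance`` is the true
    (tail-independent) abundance A_g(t) in the untreated condition;
    ``abundance_triptolide`` zeroes every zygotic component (production and
    transcription-dependent decay). ``tail_nt`` is the poly(A)-tail length
    L_g(t); ``intron_abundance`` is nascent intronic signal.
    """

    config: SimulationConfig
    genes: pd.DataFrame
    abundance: pd.DataFrame
    maternal: pd.DataFrame
    zygotic: pd.DataFrame
    tail_nt: pd.DataFrame
    tail_triptolide: pd.DataFrame
    intron_abundance: pd.DataFrame
    abundance_triptolide: pd.DataFrame
    intron_triptolide: pd.DataFrame
    models: GeneModelSet
    mirnas: pd.DataFrame

    @property
    def timepoints(self):
        return list(self.config.timepoints)

    def egg_tpm(self) -> pd.Series:
        a = self.abundance.iloc[:, 0]
        return 1e6 * a / a.sum()


def _allocate_classes(fractions: dict, n: int) -> list:
    """Deterministic allocation: floor then largest remainders."""
    keys = [k for k in CLASSES if fractions.get(k, 0) > 0]
    raw = {k: fractions[k] * n for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    labels = []
    for k in keys:
        labels.extend([k] * counts[k])
    return labels


def _ramp(t, t_start, t_end, lo, hi):
    """Piecewise-linear ramp from lo at t_start to hi at t_end."""
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - t_start) / max(t_end - t_start, 1e-9), 0.0, 1.0)
    return lo + (hi - lo) * frac


def simulate_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw per-gene classes, parameters, trajectories, and gene models."""
    config.validate()
    rng = config.rng("truth")
    n = config.n_genes
    tps = np.array(config.timepoints, dtype=float)
    nt = len(tps)

    labels = _allocate_classes(config.class_fractions, n)
    rng.shuffle(labels)
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    cls = pd.Series(labels, index=gene_ids, name="class")

    # baseline maternal abundance (arbitrary units; TPM emerges by closure)
    a0 = np.exp(rng.normal(np.log(50.0), 1.0, size=n))
    a0[cls == "de_novo_zygotic"] = rng.uniform(0.01, 0.06, (cls == "de_novo_zygotic").sum())

    is_hist = (cls == "histone_like").to_numpy()
    maternal_nonhist = a0[~is_hist].sum()
    # scale maternal histone abundance to the configured egg share
    ms = config.maternal_histone_share
    if is_hist.any():
        target_h = maternal_nonhist * ms / (1.0 - ms)
        a0[is_hist] *= target_h / a0[is_hist].sum()

    t_on = np.full(n, np.nan)
    t_deaden = np.full(n, np.nan)
    t_decay = np.full(n, np.nan)
    zmax = np.zeros(n)

    tail_egg = np.full(n, 60.0)
    tail_late = np.full(n, 60.0)

    for i, c in enumerate(labels):
        if c == "readenylated":
            tail_egg[i] = 15.0
            tail_late[i] = 80.0
            t_deaden[i] = rng.choice([1.0, 2.0])  # readenylation onset, reused axis
        elif c in ("deadenylated_only", "deadenylated_then_degraded", "mirna_target"):
            tail_egg[i] = 80.0
            tail_late[i] = 10.0
            if c == "deadenylated_only":
                t_deaden[i] = rng.choice([2.0, 3.0, 4.0])
            elif c == "mirna_target":
                t_deaden[i] = 5.0
                t_decay[i] = 6.0
            else:
                t_deaden[i] = rng.choice([2.0, 3.0, 4.0, 5.0])
                lo = max(5.0, t_deaden[i] + 1.0)
                t_decay[i] = rng.choice([lo, 6.0]) if lo < 6.0 else lo
        elif c == "de_novo_zygotic":
            t_on[i] = rng.choice([3.0, 4.0])
            zmax[i] = np.exp(rng.normal(np.log(30.0), 0.6))
        elif c == "reactivated_maternal":
            t_on[i] = rng.choice([4.0, 5.0])
            zmax[i] = config.reactivation_exon_frac * a0[i]
        elif c == "histone_like":
            t_on[i] = 2.0
            tail_egg[i] = 5.0  # non-adenylated: capture ~ 0 at all times
            tail_late[i] = 5.0

    # solve histone zygotic amplitude for the configured share at 4 h.p.f.
    if is_hist.any():
        t_ref = 4.0
        nonhist = ~is_hist
        z_nonhist = np.array(
            [
                _ramp(t_ref, t_on[i], t_on[i] + 1.0, 0.0, zmax[i])
                if np.isfinite(t_on[i]) and not is_hist[i]
                else 0.0
                for i in range(n)
            ]
        )
        s_nonhist = a0[nonhist].sum() + z_nonhist.sum()
        m_hist = a0[is_hist].sum()
        share = config.histone_share
        x_total = max(0.0, (share * s_nonhist - (1.0 - share) * m_hist) / (1.0 - share))
        w = rng.uniform(0.5, 1.5, is_hist.sum())
        zmax[is_hist] = x_total * w / w.sum()

    # trajectories
    maternal = np.tile(a0[:, None], (1, nt))
    zygotic = np.zeros((n, nt))
    tail = np.zeros((n, nt))
    for i, c in enumerate(labels):
        if np.isfinite(t_decay[i]):
            dt = np.maximum(tps - (t_decay[i] - 1.0), 0.0)
            maternal[i] = a0[i] * 2.0 ** (-config.decay_rate_per_h * dt)
        if np.isfinite(t_on[i]):
            if c == "histone_like":
                # doubling of the (small) maternal pool by one hour after
                # onset, then the full expansion by the next
                zygotic[i] = np.interp(
                    tps,
                    [t_on[i], t_on[i] + 1.0, t_on[i] + 2.0],
                    [0.0, a0[i], zmax[i]],
                )
            else:
                zygotic[i] = _ramp(tps, t_on[i], t_on[i] + 1.0, 0.0, zmax[i])
        if c == "readenylated":
            tail[i] = _ramp(tps, t_deaden[i] - 1.0, t_deaden[i], tail_egg[i], tail_late[i])
        elif c in ("deadenylated_only", "deadenylated_then_degraded", "mirna_target"):
            tail[i] = _ramp(tps, t_deaden[i] - 1.0, t_deaden[i], tail_egg[i], tail_late[i])
        else:
            tail[i] = tail_egg[i]

    abundance = maternal + zygotic

    # Triptolide: zygotic production off; transcription-dependent decay off
    # (all nucleolytic decay is zygotic-dependent — it follows activation);
    # late (>= 5 h.p.f.) deadenylation is also zygotic-dependent, while early
    # deadenylation and readenylation are maternal and persist.
    maternal_trip = np.tile(a0[:, None], (1, nt))
    abundance_trip = maternal_trip  # zygotic zeroed
    tail_trip = tail.copy()
    late_deaden = np.isfinite(t_deaden) & (t_deaden >= 5.0) & np.isin(
        labels, ["deadenylated_only", "deadenylated_then_degraded", "mirna_target"]
    )
    tail_trip[late_deaden] = tail_egg[late_deaden, None]

    # intron signal: nascent transcription only, plus a small background
    intron = np.zeros((n, nt))
    for i, c in enumerate(labels):
        if c == "reactivated_maternal":
            intron[i] = config.reactivation_intron_ratio * zygotic[i]
        elif np.isfinite(t_on[i]):
            intron[i] = config.nascent_intron_fraction * zygotic[i]
    intron_bg = config.background_intron_frac * abundance
    intron_trip = config.background_intron_frac * abundance_trip

    genes = pd.DataFrame(
        {
            "class": labels,
            "maternal_abundance": a0,
            "t_on": t_on,
            "t_deadenylation": t_deaden,
            "t_decay": t_decay,
            "zygotic_amplitude": zmax,
            "tail_egg_nt": tail_egg,
            "tail_late_nt": tail_late,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # codon-bias groups, orthogonal to class
    bias = np.where(
        rng.random(n) < config.high_bias_fraction, "high_bias", "uniform"
    )
    genes["codon_bias_group"] = bias

    # miRNA assignments: hairpins hosted in de novo zygotic genes, targets
    # are the mirna_target class; decoy sites go into stable genes
    denovo_ids = [g for g, c in zip(gene_ids, labels) if c == "de_novo_zygotic"]
    target_ids = [g for g, c in zip(gene_ids, labels) if c == "mirna_target"]
    stable_ids = [g for g, c in zip(gene_ids, labels) if c == "stable_maternal"]
    n_mir = min(config.n_mirnas, len(denovo_ids)) if target_ids else 0
    mir_rows = []
    hosts = list(rng.choice(denovo_ids, size=n_mir, replace=False)) if n_mir else []
    for k, host in enumerate(hosts):
        mir_rows.append(
            {
                "mirna_id": f"mir_{k:02d}",
                "host_gene": host,
                "arm": "5p" if k % 2 == 0 else "3p",
                "reference_mismatches": config.reference_mismatches[
                    k % len(config.reference_mismatches)
                ],
            }
        )
    mirnas = pd.DataFrame(
        mir_rows, columns=["mirna_id", "host_gene", "arm", "reference_mismatches"]
    )

    genes["is_mirna_target"] = False
    genes["partner_mirna"] = ""
    genes["target_mismatches"] = 0
    genes["target_gu"] = 0
    if n_mir:
        for j, g in enumerate(target_ids):
            mm, gu = config.target_site_edits[j % len(config.target_site_edits)]
            genes.loc[g, "is_mirna_target"] = True
            genes.loc[g, "partner_mirna"] = mirnas.mirna_id.iloc[j % n_mir]
            genes.loc[g, "target_mismatches"] = mm
            genes.loc[g, "target_gu"] = gu
    genes["is_decoy"] = False
    if n_mir and stable_ids:
        decoys = rng.choice(
            stable_ids, size=min(config.n_decoys, len(stable_ids)), replace=False
        )
        genes.loc[decoys, "is_decoy"] = True
        genes.loc[decoys, "partner_mirna"] = [
            mirnas.mirna_id.iloc[j % n_mir] for j in range(len(decoys))
        ]

    # sequence-scale parameters, drawn here so gene-model lengths and the
    # emitted sequences agree
    genes["n_codons"] = rng.integers(150, 500, size=n)
    utr_len = rng.integers(10, 300, size=n)
    needs_site = (genes["is_mirna_target"] | genes["is_decoy"]).to_numpy()
    utr_len = np.where(needs_site, np.maximum(utr_len, 80), utr_len)
    genes["utr3_len"] = utr_len
    genes["is_pri_mirna"] = genes.index.isin(mirnas.host_gene)

    models = _build_gene_models(genes, rng)

    tp_cols = [f"{t:g}" for t in tps]

    def frame(arr):
        return pd.DataFrame(arr, index=genes.index, columns=tp_cols)

    return SimulationTruth(
        config=config,
        genes=genes,
        abundance=frame(abundance),
        maternal=frame(maternal),
        zygotic=frame(zygotic),
        tail_nt=frame(tail),
        tail_triptolide=frame(tail_trip),
        intron_abundance=frame(intron + intron_bg),
        abundance_triptolide=frame(abundance_trip),
        intron_triptolide=frame(intron_trip),
        models=models,
        mirnas=mirnas,
    )


def _build_gene_models(genes: pd.DataFrame, rng: np.random.Generator) -> GeneModelSet:
    """Lay genes on scaffolds; histone-like genes form one intronless cluster."""
    models: dict[str, GeneModel] = {}
    cursor: dict[str, int] = {}
    per_scaffold = 100
    idx = 0
    for gene_id, row in genes.iterrows():
        cls = row["class"]
        tx_len = 3 * int(row["n_codons"]) + int(row["utr3_len"]) + 3
        if cls == "histone_like":
            scaffold, n_exons = "scaffold_hist", 1
        else:
            scaffold = f"scaffold_{idx // per_scaffold:03d}"
            n_exons = int(rng.integers(2, 7)) if cls == "reactivated_maternal" else int(
                rng.integers(1, 7)
            )
            idx += 1
        # split transcript length into exons
        if n_exons == 1:
            exon_lens = [tx_len]
        else:
            cuts = np.sort(rng.choice(np.arange(1, tx_len), n_exons - 1, replace=False))
            exon_lens = np.diff(np.concatenate([[0], cuts, [tx_len]])).tolist()
        intron_lens = rng.integers(100, 2000, size=max(n_exons - 1, 0)).tolist()
        start = cursor.get(scaffold, 1000) + int(rng.integers(200, 2000))
        pos = start
        exons = []
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if k < len(intron_lens):
                pos += int(intron_lens[k])
        cursor[scaffold] = pos
        strand = "+" if rng.random() < 0.5 else "-"
        models[gene_id] = GeneModel(
            gene_id, scaffold, strand, {f"{gene_id}.t1": exons}
        )
    return GeneModelSet(models)


@dataclass
class SimulatedCounts:
    polyA: CountMatrix
    ribo: CountMatrix
    premrna: CountMatrix
    exon: CountMatrix
    metadata: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(mean, 0.0)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / alpha, alpha * mean)
    return rng.poisson(lam)


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in config.timepoints:
        for rep in range(1, config.replicates + 1):
            rows.append((t, "untreated", rep))
    last = config.timepoints[-1]
    for cond in ("dmso", "triptolide"):
        for rep in range(1, config.replicates + 1):
            rows.append((last, cond, rep))
    return pd.DataFrame(rows, columns=["timepoint_hpf", "condition", "replicate"])


def sample_id(protocol: str, timepoint: float, condition: str, replicate: int) -> str:
    return f"{protocol}_t{timepoint:g}_{condition}_r{replicate}"


def simulate_counts(truth: SimulationTruth, config: SimulationConfig | None = None) -> SimulatedCounts:
    """Draw the four count tables plus sample metadata from the truth."""
    config = config or truth.config
    if config.library_depth <= 0:
        raise ValueError("library_depth must be positive")
    tps = list(config.timepoints)
    tp_cols = {t: f"{t:g}" for t in tps}
    genes = truth.genes
    n = len(genes)
    lengths = truth.models.gene_lengths("union").reindex(genes.index).to_numpy(float)
    intron_len = truth.models.intron_lengths().reindex(genes.index).to_numpy(float)

    samples = _sample_table(config)
    meta_rows = []
    polyA_cols, ribo_cols, exon_cols, pre_cols = {}, {}, {}, {}
    rng_pa = config.rng("polyA")
    rng_rb = config.rng("ribo")
    rng_ei = config.rng("exon_intron")
    alpha = config.nb_dispersion
    depth = config.library_depth

    cap = capture_probability(truth.tail_nt.to_numpy(float), config)
    cap_trip = capture_probability(truth.tail_triptolide.to_numpy(float), config)

    for _, s in samples.iterrows():
        t, cond, rep = s.timepoint_hpf, s.condition, int(s.replicate)
        j = tps.index(t)
        if cond == "triptolide" and config.triptolide_effective:
            abund = truth.abundance_triptolide[tp_cols[t]].to_numpy(float)
            intr = truth.intron_triptolide[tp_cols[t]].to_numpy(float)
            cap_j = cap_trip[:, j]
        else:
            abund = truth.abundance[tp_cols[t]].to_numpy(float)
            intr = truth.intron_abundance[tp_cols[t]].to_numpy(float)
            cap_j = cap[:, j]
        for protocol in ("polyA", "ribo"):
            sid = sample_id(protocol, t, cond, rep)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "timepoint_hpf": t,
                    "protocol": protocol,
                    "condition": cond,
                    "replicate": rep,
                }
            )
            if protocol == "polyA":
                w = abund * lengths * cap_j
                mean = depth * w / w.sum()
                polyA_cols[sid] = _nb_draw(rng_pa, mean, alpha)
            else:
                w = abund * lengths
                mean = depth * w / w.sum()
                ribo_cols[sid] = _nb_draw(rng_rb, mean, alpha)
                # exon / pre-mRNA tables follow the ribo libraries
                we = abund * lengths
                wi = intr * np.where(intron_len > 0, intron_len, 0.0)
                tot = we.sum() + wi.sum()
                exon_counts = _nb_draw(rng_ei, depth * we / tot, alpha)
                intron_counts = _nb_draw(rng_ei, depth * wi / tot, alpha)
                exon_cols[sid] = exon_counts
                pre_cols[sid] = exon_counts + intron_counts

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    def cm(cols):
        df = pd.DataFrame(cols, index=genes.index)
        return CountMatrix(df, metadata.loc[df.columns])

    return SimulatedCounts(
        polyA=cm(polyA_cols),
        ribo=cm(ribo_cols),
        premrna=cm(pre_cols),
        exon=cm(exon_cols),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# sequences


def _codon_families() -> dict[str, list[str]]:
    from Bio.Data import CodonTable

    fams: dict[str, list[str]] = {}
    for codon, aa in CodonTable.standard_dna_table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    for aa in fams:
        fams[aa] = sorted(fams[aa])
    return fams


def codon_usage_probs(bias_group: str) -> dict[str, dict[str, float]]:
    """Per-amino-acid codon sampling probabilities for a bias group.

    ``uniform``: equal weight on synonymous codons. ``high_bias``: weight 0.9
    on the alphabetically first codon of each family, the rest shared.
    """
    fams = _codon_families()
    probs: dict[str, dict[str, float]] = {}
    for aa, codons in fams.items():
        if bias_group == "uniform" or len(codons) == 1:
            probs[aa] = {c: 1.0 / len(codons) for c in codons}
        elif bias_group == "high_bias":
            rest = 0.1 / (len(codons) - 1)
            probs[aa] = {c: (0.9 if i == 0 else rest) for i, c in enumerate(codons)}
        else:
            raise ValueError(f"unknown codon bias group {bias_group!r}")
    return probs


@dataclass
class SimulatedSequences:
    """FASTA-ready sequence sets plus implant annotations."""

    cds: dict
    utr3: dict
    transcripts: dict
    mature_refs: dict
    matures: dict
    annotations: pd.DataFrame  # cds_start/cds_end/utr_start per coding gene
    hairpins: pd.DataFrame  # mirna_id, host_gene, mature_start/end, arm
    target_sites: pd.DataFrame  # gene_id, mirna_id, site_start/end, mm, gu

    def write_fastas(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, seqs in (
            ("cds", self.cds),
            ("utr3", self.utr3),
            ("transcripts", self.transcripts),
            ("mature_mirnas", self.mature_refs),
        ):
            write_fasta(out / f"{name}.fa", seqs)


def write_fasta(path, seqs: dict) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


_BASES = "ACGT"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(seq: str, positions, rng: np.random.Generator) -> str:
    from .mirna import pair_type  # noqa: F401 (alphabet helpers live there)

    s = list(seq)
    for i in positions:
        choices = [b for b in _BASES if b != s[i]]
        s[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(s)


def _make_target_site(mature: str, mm: int, gu: int, rng: np.random.Generator) -> str:
    """Sense-strand target site: reverse complement with G:U and mismatch edits."""
    from .mirna import revcomp

    L = len(mature)
    site = list(revcomp(mature))
    gu_eligible = [i for i in range(L) if mature[i] in "GT"]
    gu_pos = list(
        rng.choice(gu_eligible, size=min(gu, len(gu_eligible)), replace=False)
    )
    for i in gu_pos:
        site[L - 1 - i] = "T" if mature[i] == "G" else "G"
    mm_eligible = [i for i in range(L) if i not in gu_pos]
    mm_pos = rng.choice(mm_eligible, size=min(mm, len(mm_eligible)), replace=False)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in mm_pos:
        banned = {comp[mature[i]]}
        if mature[i] == "G":
            banned.add("T")
        elif mature[i] == "T":
            banned.add("G")
        choices = [b for b in _BASES if b not in banned]
        site[L - 1 - i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(site)


def simulate_sequences(
    truth: SimulationTruth, config: SimulationConfig | None = None
) -> SimulatedSequences:
    """Emit CDS, 3'UTRs, transcripts, and reference mature miRNAs.

    Coding genes get a CDS sampled from their codon-bias group's usage table
    (ATG + sense codons + TAA) followed by the 3'UTR. Each pri-miRNA host
    gets a noncoding transcript containing a perfect stem-loop whose one arm
    is the mature sequence; target genes carry a near-complementary site in
    their 3'UTR; decoy sites in stable genes carry >= the configured decoy
    mismatch count. Reference matures differ from the implanted matures by
    the configured number of mismatches.
    """
    from .mirna import revcomp

    config = config or truth.config
    if not (18 <= config.mirna_length <= 25):
        raise ValueError("mature miRNA length must be in [18, 25]")
    rng = config.rng("sequences")
    genes = truth.genes
    probs = {g: codon_usage_probs(g) for g in ("uniform", "high_bias")}
    # flatten per-group codon pools for fast sampling
    pools = {}
    for grp, by_aa in probs.items():
        codons, weights = [], []
        for aa, d in sorted(by_aa.items()):
            for c, p in sorted(d.items()):
                codons.append(c)
                weights.append(p)
        w = np.array(weights)
        pools[grp] = (codons, w / w.sum())

    matures = {}
    refs = {}
    hairpin_rows = []
    for _, m in truth.mirnas.iterrows():
        mature = _random_seq(rng, config.mirna_length)
        matures[m.mirna_id] = mature
        mmn = int(m.reference_mismatches)
        pos = rng.choice(
            np.arange(2, config.mirna_length - 2), size=mmn, replace=False
        )
        refs[f"ref_{m.mirna_id}"] = _mutate(mature, pos, rng)

    cds_seqs, utr_seqs, tx_seqs = {}, {}, {}
    ann_rows, site_rows = [], []
    host_to_mir = dict(zip(truth.mirnas.host_gene, truth.mirnas.mirna_id))
    arm_of = dict(zip(truth.mirnas.mirna_id, truth.mirnas.arm))

    for gene_id, row in genes.iterrows():
        if row.get("is_pri_mirna", False):
            mid = host_to_mir[gene_id]
            mature = matures[mid]
            loop = _random_seq(rng, 8)
            flank5 = _random_seq(rng, 30)
            flank3 = _random_seq(rng, 30)
            if arm_of[mid] == "5p":
                hairpin = mature + loop + revcomp(mature)
                m_start = len(flank5)
            else:
                hairpin = revcomp(mature) + loop + mature
                m_start = len(flank5) + config.mirna_length + len(loop)
            tx = flank5 + hairpin + flank3
            tx_seqs[gene_id] = tx
            hairpin_rows.append(
                {
                    "mirna_id": mid,
                    "host_gene": gene_id,
                    "mature_start": m_start,
                    "mature_end": m_start + config.mirna_length,
                    "arm": arm_of[mid],
                }
            )
            continue
        grp = row["codon_bias_group"]
        codons, w = pools[grp]
        n_codons = int(row["n_codons"])
        body = "".join(
            codons[i] for i in rng.choice(len(codons), size=n_codons - 1, p=w)
        )
        cds = "ATG" + body + "TAA"
        utr = _random_seq(rng, int(row["utr3_len"]))
        if row["is_mirna_target"] or row["is_decoy"]:
            mid = row["partner_mirna"]
            mature = matures[mid]
            if row["is_decoy"]:
                mm, gu = config.decoy_mismatches, 0
            else:
                mm, gu = int(row["target_mismatches"]), int(row["target_gu"])
            site = _make_target_site(mature, mm, gu, rng)
            pos = 20
            utr = utr[:pos] + site + utr[pos + len(site) :]
            site_rows.append(
                {
                    "gene_id": gene_id,
                    "mirna_id": mid,
                    "site_start": len(cds) + pos,
                    "site_end": len(cds) + pos + len(site),
                    "mismatches": mm,
                    "gu": gu,
                    "is_decoy": bool(row["is_decoy"]),
                }
            )
        cds_seqs[gene_id] = cds
        utr_seqs[gene_id] = utr
        tx_seqs[gene_id] = cds + utr
        ann_rows.append(
            {
                "gene_id": gene_id,
                "cds_start": 0,
                "cds_end": len(cds),
                "utr_start": len(cds),
                "transcript_length": len(cds) + len(utr),
            }
        )

    return SimulatedSequences(
        cds=cds_seqs,
        utr3=utr_seqs,
        transcripts=tx_seqs,
        mature_refs=refs,
        matures=matures,
        annotations=pd.DataFrame(ann_rows).set_index("gene_id")
        if ann_rows
        else pd.DataFrame(),
        hairpins=pd.DataFrame(
            hairpin_rows,
            columns=["mirna_id", "host_gene", "mature_start", "mature_end", "arm"],
        ),
        target_sites=pd.DataFrame(
            site_rows,
            columns=[
                "gene_id",
                "mirna_id",
                "site_start",
                "site_end",
                "mismatches",
                "gu",
                "is_decoy",
            ],
        ),
    )


# ---------------------------------------------------------------------------
# annotation maps


def histone_class_map(truth: SimulationTruth) -> pd.Series:
    """Assign histone-like genes to the five histone classes, round robin."""
    classes = ["H1", "H2A", "H2B", "H3", "H4"]
    hist = [g for g, c in truth.genes["class"].items() if c == "histone_like"]
    return pd.Series(
        {g: classes[i % 5] for i, g in enumerate(hist)}, name="histone_class"
    )


def simulate_go_map(
    truth: SimulationTruth,
    n_terms: int = 25,
    mean_term_size: int = 40,
    enriched_term: str | None = "GO:ENRICHED",
    enriched_class: str = "de_novo_zygotic",
    enrichment: float = 0.8,
) -> pd.DataFrame:
    """Random gene->GO map with one optional class-concentrated term.

    Background terms draw genes uniformly; the enriched term draws a fraction
    ``enrichment`` of its members from ``enriched_class`` genes.
    """
    rng = truth.config.rng("truth")  # independent jump: advance via fresh spawn
    rng = np.random.default_rng(
        np.random.SeedSequence(truth.config.seed, spawn_key=(_STREAMS["truth"], 1))
    )
    gene_ids = np.array(truth.genes.index)
    rows = []
    for k in range(n_terms):
        size = max(5, int(rng.poisson(mean_term_size)))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        for g in members:
            rows.append({"gene_id": g, "go_id": f"GO:{k:07d}"})
    if enriched_term:
        in_class = truth.genes.index[truth.genes["class"] == enriched_class]
        out_class = truth.genes.index[truth.genes["class"] != enriched_class]
        n_in = max(1, int(enrichment * min(len(in_class), mean_term_size)))
        n_out = max(1, int((1 - enrichment) * mean_term_size))
        members = list(rng.choice(in_class, size=min(n_in, len(in_class)), replace=False))
        members += list(
            rng.choice(out_class, size=min(n_out, len(out_class)), replace=False)
        )
        for g in members:
            rows.append({"gene_id": g, "go_id": enriched_term})
    return pd.DataFrame(rows).drop_duplicates()
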