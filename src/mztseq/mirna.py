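"""miRNA candidate discovery and full-complementarity target prediction.

Cnidarian miRNAs pair with near-full-length complementarity to their targets,
so target search here is an ungapped antisense scan scoring every position of
the mature sequence as Watson-Crick, G:U wobble, or mismatch. Candidate
discovery is a seeded ungapped homology scan against reference mature miRNAs
followed by a maximum-base-pairing (Nussinov) hairpin check and
activation/transcription-inhibition filters.

Sequences may use T or U interchangeably; pairing logic treats them as U.
Structure prediction is maximum pairing with a minimum hairpin loop, not a
thermodynamic model — a self-contained, brute-force-verifiable stand-in for
free-energy folding, which is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MiRNACandidate",
    "TargetDuplex",
    "revcomp",
    "pair_type",
    "scan_reference_mirnas",
    "fold_hairpin",
    "detect_stem_loop",
    "filter_candidates",
    "predict_targets",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(_norm(seq)))


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def pair_type(mirna_base: str, target_base: str) -> str:
    """Classify an antiparallel miRNA:mRNA base pair: 'WC', 'GU', or 'MM'."""
    pair = (_norm(mirna_base), _norm(target_base))
    if pair in _WC:
        return "WC"
    if pair in _GU:
        return "GU"
    return "MM"


def _pairs_allowed(allow_gu: bool) -> set:
    return _WC | _GU if allow_gu else set(_WC)


# ---------------------------------------------------------------------------
# homology scan


def scan_reference_mirnas(
    refs: dict[str, str],
    transcripts: dict[str, str],
    word_size: int = 7,
    max_mismatch: int = 2,
) -> pd.DataFrame:
    """Ungapped scan of reference mature miRNAs against transcripts.

    Exact ``word_size``-mer seeds anchor full-length ungapped extensions on
    both strands; hits with at most ``max_mismatch`` mismatches are reported.
    Overlapping hits of the same (ref, transcript, strand) keep the fewest
    mismatches. Coordinates are 0-based half-open on the transcript's plus
    strand.
    """
    rows = []
    for tx_id, tx_seq in transcripts.items():
        tx = _norm(tx_seq)
        index: dict[str, list[int]] = {}
        for i in range(len(tx) - word_size + 1):
            index.setdefault(tx[i : i + word_size], []).append(i)
        for ref_id, ref_seq in refs.items():
            ref = _norm(ref_seq)
            L = len(ref)
            if L < word_size:
                raise ValueError(
                    f"reference {ref_id} shorter than word size {word_size}"
                )
            for strand in ("+", "-"):
                query = ref if strand == "+" else revcomp(ref)
                seen = set()
                for k in range(L - word_size + 1):
                    for pos in index.get(query[k : k + word_size], ()):
                        start = pos - k
                        if start < 0 or start + L > len(tx) or start in seen:
                            continue
                        seen.add(start)
                        mm = sum(
                            1 for a, b in zip(query, tx[start : start + L]) if a != b
                        )
                        if mm <= max_mismatch:
                            rows.append(
                                {
                                    "ref_id": ref_id,
                                    "transcript_id": tx_id,
                                    "start": start,
                                    "end": start + L,
                                    "strand": strand,
                                    "mismatches": mm,
                                }
                            )
    hits = pd.DataFrame(
        rows,
        columns=["ref_id", "transcript_id", "start", "end", "strand", "mismatches"],
    )
    if hits.empty:
        return hits
    # deduplicate overlapping hits, keeping the fewest mismatches
    hits = hits.sort_values(["transcript_id", "ref_id", "strand", "mismatches", "start"])
    kept = []
    for _, group in hits.groupby(["transcript_id", "ref_id", "strand"], sort=False):
        chosen: list[tuple[int, int]] = []
        for _, h in group.iterrows():
            if all(h.end <= s or h.start >= e for s, e in chosen):
                chosen.append((h.start, h.end))
                kept.append(h)
    return (
        pd.DataFrame(kept)
        .sort_values(["transcript_id", "start"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# structure


def fold_hairpin(seq: str, allow_gu: bool = True, min_loop: int = 3) -> dict:
    """Maximum base-pairing structure by Nussinov dynamic programming.

    Pairs {AU, UA, GC, CG} plus {GU, UG} when ``allow_gu``; hairpin loops of
    at least ``min_loop`` unpaired bases; no pseudoknots. Ties in the
    traceback prefer pairing (i, j) with the smallest j, making the reported
    structure deterministic. N never pairs. Returns {"structure": dot-bracket,
    "pairs": count, "partner": list (partner index or -1)}.
    """
    s = _norm(seq)
    if any(b not in "ACGTN" for b in s):
        bad = sorted({b for b in s if b not in "ACGTN"})
        raise ValueError(f"non-nucleotide characters: {bad}")
    n = len(s)
    allowed = _pairs_allowed(allow_gu)

    def can_pair(i, j):
        return (s[i], s[j]) in allowed

    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    # dp[i][j] over interval [i, j); iterate by increasing length
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j):
                if can_pair(i, k):
                    cand = 1 + dp[i + 1, k] + dp[k + 1, j]
                    if cand > best:
                        best = cand
            dp[i, j] = best
    partner = [-1] * n
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 2:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j):
            if can_pair(i, k) and dp[i, j] == 1 + dp[i + 1, k] + dp[k + 1, j]:
                partner[i], partner[k] = k, i
                stack.append((i + 1, k))
                stack.append((k + 1, j))
                break
    structure = "".join(
        "(" if p > i else ")" if 0 <= p < i else "." for i, p in enumerate(partner)
    )
    return {"structure": structure, "pairs": int(dp[0, n]), "partner": partner}


def detect_stem_loop(
    hit: pd.Series | dict,
    transcript: str,
    flank: int = 60,
    stem_min: int = 14,
    allow_gu: bool = True,
    min_loop: int = 3,
) -> dict:
    """Assess whether a homology hit sits on one arm of a stem-loop.

    Folds the hit plus ``flank`` nt of context and requires at least
    ``stem_min`` of the mature positions to be paired, with the mature region
    on one arm (not spanning the loop). Records the deviation from the
    canonical 2-nt 3' overhang without rejecting non-canonical cases.
    """
    tx = _norm(transcript)
    start, end = int(hit["start"]), int(hit["end"])
    wstart = max(0, start - flank)
    wend = min(len(tx), end + flank)
    truncated = (wstart > start - flank) or (wend < end + flank)
    window = tx[wstart:wend]
    fold = fold_hairpin(window, allow_gu=allow_gu, min_loop=min_loop)
    partner = fold["partner"]
    m0, m1 = start - wstart, end - wstart  # mature within window
    mature_partners = [partner[i] for i in range(m0, m1) if partner[i] >= 0]
    stem_pairs = len(mature_partners)
    passes = stem_pairs >= stem_min
    arm = None
    loop_len = None
    overhang_offset = None
    if mature_partners:
        before = sum(1 for p in mature_partners if p < m0)
        after = sum(1 for p in mature_partners if p >= m1)
        if after >= before and after > 0:
            arm = "5p"
        elif before > 0:
            arm = "3p"
        inside = sum(1 for p in mature_partners if m0 <= p < m1)
        if inside > stem_pairs / 2:
            arm = None  # mature pairs with itself: sits across the loop
            passes = False
        if arm == "5p":
            star = sorted(p for p in mature_partners if p >= m1)
            if star:
                loop_len = star[0] - m1
                # canonical duplex: star 3' end 2 nt past mature start
                overhang_offset = (star[-1] + 1) - (m0 + (m1 - m0)) - 2
        elif arm == "3p":
            star = sorted(p for p in mature_partners if p < m0)
            if star:
                loop_len = m0 - (star[-1] + 1)
                overhang_offset = (m1 - 1 - star[0]) - (m1 - m0) - 2 + 1
    return {
        "passes": bool(passes),
        "arm": arm,
        "stem_pairs": stem_pairs,
        "loop_length": loop_len,
        "overhang_offset": overhang_offset,
        "structure": fold["structure"],
        "window_start": wstart,
        "truncated": truncated,
    }


# ---------------------------------------------------------------------------
# candidates


@dataclass
class MiRNACandidate:
    candidate_id: str
    mature_seq: str
    transcript_id: str
    start: int
    end: int
    arm: str
    structure: str
    stem_pairs: int
    loop_length: int | None
    mismatches_vs_ref: int
    ref_id: str
    activation_padj: float = np.nan
    activation_log2fc: float = np.nan
    triptolide_inhibited: bool = False


def filter_candidates(
    hairpin_hits: list[dict],
    activation_de: pd.DataFrame,
    triptolide_de: pd.DataFrame | None = None,
    padj_max: float = 0.05,
) -> list[MiRNACandidate]:
    """Keep hairpin-passing hits on significantly activated transcripts.

    ``hairpin_hits`` items carry the scan hit plus the detect_stem_loop
    result and the mature sequence. ``activation_de`` / ``triptolide_de`` are
    nb_test frames indexed by transcript id (activation: timepoint vs egg;
    triptolide: triptolide vs DMSO). The Triptolide flag is annotated, not
    required — some primary transcripts also have a maternal contribution.
    """
    out = []
    k = 0
    for h in hairpin_hits:
        if not h["detect"]["passes"]:
            continue
        tx = h["transcript_id"]
        if tx not in activation_de.index:
            continue
        row = activation_de.loc[tx]
        if not (row.padj < padj_max and row.log2FC > 0):
            continue
        inhibited = False
        if triptolide_de is not None and tx in triptolide_de.index:
            trow = triptolide_de.loc[tx]
            inhibited = bool(trow.padj < padj_max and trow.log2FC < 0)
        det = h["detect"]
        out.append(
            MiRNACandidate(
                candidate_id=f"cand_{k:02d}",
                mature_seq=h["mature_seq"],
                transcript_id=tx,
                start=int(h["start"]),
                end=int(h["end"]),
                arm=det["arm"],
                structure=det["structure"],
                stem_pairs=det["stem_pairs"],
                loop_length=det["loop_length"],
                mismatches_vs_ref=int(h.get("mismatches", 0)),
                ref_id=h.get("ref_id", ""),
                activation_padj=float(row.padj),
                activation_log2fc=float(row.log2FC),
                triptolide_inhibited=inhibited,
            )
        )
        k += 1
    return out


# ---------------------------------------------------------------------------
# targets


@dataclass
class TargetDuplex:
    mirna_id: str
    target_id: str
    start: int
    end: int
    pairing: str  # | for WC, : for G:U, . for mismatch (5'->3' on the miRNA)
    wc: int
    gu: int
    mismatches: int
    in_control_set: bool = False

    @property
    def paired_fraction(self) -> float:
        return (self.wc + self.gu) / (self.wc + self.gu + self.mismatches)


def _duplex_at(mirna: str, target: str, start: int) -> TargetDuplex | None:
    """Classify each miRNA position against the antiparallel target site."""
    L = len(mirna)
    site = target[start : start + L]
    if len(site) < L:
        return None
    marks, wc, gu, mm = [], 0, 0, 0
    for i in range(L):
        pt = pair_type(mirna[i], site[L - 1 - i])
        if pt == "WC":
            wc += 1
            marks.append("|")
        elif pt == "GU":
            gu += 1
            marks.append(":")
        else:
            mm += 1
            marks.append(".")
    return TargetDuplex("", "", start, start + L, "".join(marks), wc, gu, mm)


def predict_targets(
    candidates,
    cleared_mrnas: dict[str, str],
    stable_mrnas: dict[str, str] | None = None,
    word_size: int = 4,
    min_paired_fraction: float = 0.85,
) -> list[TargetDuplex]:
    """Ungapped antisense scan for near-fully-complementary target sites.

    Seeds are exact ``word_size``-mers of the reverse complement of each
    mature sequence; anchored full-length duplexes are scored per position as
    WC / G:U / mismatch and reported when the paired fraction (WC+GU over
    length) reaches ``min_paired_fraction``. Hits in the stable control set
    are reported with ``in_control_set=True`` as a specificity readout.
    """
    out = []
    sets = [(cleared_mrnas, False)]
    if stable_mrnas:
        sets.append((stable_mrnas, True))
    for cand in candidates:
        cid = cand.candidate_id if hasattr(cand, "candidate_id") else cand[0]
        mature = _norm(cand.mature_seq if hasattr(cand, "mature_seq") else cand[1])
        query = revcomp(mature)  # the sense-strand site we expect
        L = len(mature)
        for mrnas, is_control in sets:
            for tx_id, tx_seq in mrnas.items():
                tx = _norm(tx_seq)
                index: dict[str, list[int]] = {}
                for i in range(len(tx) - word_size + 1):
                    index.setdefault(tx[i : i + word_size], []).append(i)
                seen = set()
                for k in range(L - word_size + 1):
                    for pos in index.get(query[k : k + word_size], ()):
                        start = pos - k
                        if start < 0 or start + L > len(tx) or start in seen:
                            continue
                        seen.add(start)
                        dup = _duplex_at(mature, tx, start)
                        if dup and dup.paired_fraction >= min_paired_fraction:
                            dup.mirna_id = cid
                            dup.target_id = tx_id
                            dup.in_control_set = is_control
                            out.append(dup)
    # deduplicate overlapping duplexes per (mirna, target): keep most paired
    best: dict[tuple, TargetDuplex] = {}
    for d in out:
        key = (d.mirna_id, d.target_id)
        cur = best.get(key)
        if cur is None or (d.wc + d.gu) > (cur.wc + cur.gu):
            best[key] = d
    return sorted(best.values(), key=lambda d: (d.mirna_id, d.target_id, d.start))


def candidates_to_frame(candidates) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in candidates])


def duplexes_to_frame(duplexes) -> pd.DataFrame:
    rows = []
    for d in duplexes:
        r = dict(d.__dict__)
        r["paired_fraction"] = d.paired_fraction
        rows.append(r)
    return pd.DataFrame(rows)
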