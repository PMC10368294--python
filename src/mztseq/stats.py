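"""Core expression statistics.

Normalization (median-of-ratios size factors), TPM, a self-contained
negative-binomial Wald test with Benjamini-Hochberg FDR, an exact/approximate
Wilcoxon signed-rank test, and the Pearson chi-squared test of independence.

The NB test is a documented stand-in for DESeq2-style testing: size-factor
normalization, per-gene method-of-moments dispersion (floored, with a prior
when both groups are single libraries), and a Wald z on the log2 fold change.
No claim of equality with DESeq2 is made; dispersion shrinkage and outlier
filtering are deliberately absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CountMatrix",
    "compute_tpm",
    "size_factors",
    "nb_test",
    "bh_adjust",
    "wilcoxon_signed_rank",
    "chi2_independence",
]


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with sample metadata.

    ``counts`` is a genes x samples DataFrame; ``metadata`` is indexed by
    sample id with columns ``timepoint_hpf``, ``protocol`` ({"polyA","ribo"}),
    ``condition`` ({"untreated","dmso","triptolide"}), ``replicate``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self):
        c = self.counts
        vals = c.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        if not c.index.is_unique:
            raise ValueError("gene_ids must be unique")
        if self.metadata is not None:
            missing = set(c.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")

    @property
    def gene_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns

    def select_samples(self, mask) -> "CountMatrix":
        cols = self.metadata.index[mask] if self.metadata is not None else mask
        cols = [c for c in self.counts.columns if c in set(cols)]
        meta = self.metadata.loc[cols] if self.metadata is not None else None
        return CountMatrix(self.counts[cols], meta)


def compute_tpm(counts, lengths) -> pd.DataFrame:
    """Transcripts per million.

    TPM_g = 1e6 * (c_g/l_g) / sum_j(c_j/l_j). ``counts`` may be a CountMatrix
    or a DataFrame; ``lengths`` is a per-gene effective length in bp (Series
    or dict). Zero-depth samples yield an all-zero column with a warning.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    lens = pd.Series(lengths).reindex(df.index)
    if lens.isna().any():
        raise ValueError("length missing for some genes")
    if (lens <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = df.div(lens, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"zero-depth samples: {list(denom.index[zero])}")
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def size_factors(counts) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    Uses genes with nonzero counts in every sample; the reference is the
    per-gene geometric mean across samples.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] == 1:
        return pd.Series([1.0], index=df.columns)
    vals = df.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; consider a "
            "pseudo-reference fallback"
        )
    sub = vals[allpos]
    loggm = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - loggm
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=df.columns)


def _nb_group_stats(norm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1) if norm.shape[1] > 1 else np.zeros(norm.shape[0])
    return mean, var


def nb_test(
    counts,
    group_a,
    group_b,
    min_total: int = 10,
    prior_dispersion: float = 0.1,
    mean_floor: float = 0.5,
    moderation_weight: float = 20.0,
) -> pd.DataFrame:
    """NB Wald differential test of group B vs group A.

    Genes with fewer than ``min_total`` reads summed over the tested samples
    are flagged ``filtered`` and carry no p value. Dispersion is estimated per
    gene by the method of moments pooled over the two groups (with a
    small-sample bias correction of the squared-mean denominator), then
    moderated toward the across-gene mean dispersion with prior weight
    ``moderation_weight`` — sharing information across genes the way
    DESeq2-style shrinkage does, which keeps the Wald z calibrated at n=3
    per group. The result is floored at 1e-8; when both groups are single
    libraries the per-gene estimate is unavailable and ``prior_dispersion``
    is used. Group means of exactly zero are floored at ``mean_floor``
    normalized counts for the fold and variance terms.

    Returns a DataFrame (gene_id, baseMean, log2FC, pvalue, padj, filtered).
    """
    cm = counts if isinstance(counts, CountMatrix) else CountMatrix(counts)
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    sub = cm.counts[group_a + group_b]
    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()
    na, nb = len(group_a), len(group_b)
    a, b = norm[:, :na], norm[:, na:]

    total = sub.sum(axis=1).to_numpy()
    filtered = total < min_total

    mean_a, var_a = _nb_group_stats(a)
    mean_b, var_b = _nb_group_stats(b)
    base_mean = norm.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        dof = (na - 1) + (nb - 1)
        if dof > 0:
            # pooled method-of-moments dispersion: var = mu + alpha mu^2,
            # with E[mbar^2] corrected to estimate mu^2 (mbar^2 - s^2/n)
            num = np.zeros(len(base_mean))
            den = np.zeros(len(base_mean))
            if na > 1:
                mu2a = np.maximum(mean_a**2 - var_a / na, 1e-8)
                num += (var_a - mean_a) * (na - 1)
                den += mu2a * (na - 1)
            if nb > 1:
                mu2b = np.maximum(mean_b**2 - var_b / nb, 1e-8)
                num += (var_b - mean_b) * (nb - 1)
                den += mu2b * (nb - 1)
            per_gene = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
            # low-count genes can hit the floored mu^2 denominator and
            # explode; bound the estimates before any averaging
            per_gene = np.clip(per_gene, -1.0, 10.0)
            tested_pg = per_gene[~filtered] if (~filtered).any() else per_gene
            common = max(float(np.mean(tested_pg)), 0.0) if tested_pg.size else 0.0
            alpha = (dof * per_gene + moderation_weight * common) / (
                dof + moderation_weight
            )
            alpha = np.maximum(alpha, 1e-8)
        else:
            alpha = np.full(len(base_mean), max(prior_dispersion, 1e-8))

        ma = np.maximum(mean_a, mean_floor)
        mb = np.maximum(mean_b, mean_floor)
        log2fc = np.log2(mb / ma)
        # delta method on log2 means: Var(K) = mu + alpha mu^2 per library
        se2 = (ma + alpha * ma**2) / (na * ma**2) + (mb + alpha * mb**2) / (
            nb * mb**2
        )
        se = np.sqrt(se2) / np.log(2)
        z = log2fc / se
        pvals = 2.0 * sps.norm.sf(np.abs(z))

    pvals = np.where(filtered, np.nan, pvals)
    padj = np.full(len(pvals), np.nan)
    tested = ~filtered
    if tested.any():
        padj[tested] = bh_adjust(pvals[tested])
    return pd.DataFrame(
        {
            "gene_id": cm.counts.index,
            "baseMean": base_mean,
            "log2FC": np.where(filtered, np.nan, log2fc),
            "pvalue": pvals,
            "padj": padj,
            "filtered": filtered,
        }
    ).set_index("gene_id")


def de_vs_egg_series(
    cm: CountMatrix,
    protocol: str,
    condition: str = "untreated",
    timepoints=None,
    min_total: int = 10,
) -> dict:
    """Per-timepoint differential tests of each stage against the egg.

    Egg is the first timepoint of the matrix's metadata (untreated). Returns
    {timepoint: nb_test frame} for each later timepoint of the requested
    protocol/condition.
    """
    meta = cm.metadata
    if meta is None:
        raise ValueError("CountMatrix metadata required")
    sub = meta[meta.protocol == protocol]
    all_tps = sorted(sub[sub.condition == "untreated"].timepoint_hpf.unique())
    egg = all_tps[0]
    egg_samples = list(
        sub.index[(sub.timepoint_hpf == egg) & (sub.condition == "untreated")]
    )
    if timepoints is None:
        timepoints = [t for t in all_tps if t != egg]
    out = {}
    for t in timepoints:
        smp = list(
            sub.index[(sub.timepoint_hpf == t) & (sub.condition == condition)]
        )
        if not smp:
            raise ValueError(f"no {protocol}/{condition} samples at {t} h.p.f.")
        out[t] = nb_test(cm, egg_samples, smp, min_total=min_total)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def _wilcoxon_exact_sf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) for doubled ranks via the exact distribution.

    ``ranks2`` are midranks doubled to integers; each sign pattern is
    equiprobable. Polynomial (generating-function) convolution — equivalent
    to full 2^n enumeration.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    lo = dist[: w2 + 1].sum()
    hi = dist[w2:].sum()
    return lo, hi


def wilcoxon_signed_rank(paired_diffs) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. Exact p by enumeration (via the exact
    null distribution of W+) for n <= 25 nonzero differences; normal
    approximation with mid-rank tie correction and continuity correction
    otherwise. Returns {"W": W+, "p": two-sided p, "n": n nonzero}.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate paired sample: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.round(ranks * 2).astype(int)
        w2 = int(round(w_plus * 2))
        lo, hi = _wilcoxon_exact_sf(ranks2, w2)
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        mu = n * (n + 1) / 4.0
        # tie correction on the variance of W+
        _, counts = np.unique(ranks, return_counts=True)
        tie = (counts**3 - counts).sum() / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie
        diff = w_plus - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / np.sqrt(sigma2)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return {"W": w_plus, "p": float(p), "n": int(n)}


def chi2_independence(table) -> dict:
    """Pearson chi-squared test of independence for a 2 x k table.

    Returns {"statistic", "dof", "p"}. Zero expected cells raise; callers
    must pool categories first.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (cols == 0).any():
        raise ValueError("zero expected cell; pool categories before testing")
    if (rows == 0).any():
        raise ValueError("row sums must be positive")
    expected = rows @ cols / total
    if (expected == 0).any():
        raise ValueError("zero expected cell; pool categories before testing")
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = obs.shape[1] - 1
    return {"statistic": stat, "dof": dof, "p": float(sps.chi2.sf(stat, dof))}
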