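"""Per-sample richness and diversity estimation with subsample replication.

Implements the estimators used for amplicon OTU tables: observed richness,
bias-corrected Chao1 and ACE (nonparametric richness from the low-abundance
frequency counts), Shannon's H' (natural log) with evenness, Faith's rooted
phylogenetic diversity, and the analytic (hypergeometric) rarefaction curve.
Each estimator can be reported as the mean over several independent even-depth
down-samplings, with the 95% confidence interval presented as the mean of the
per-replicate analytic intervals.

Confidence intervals
--------------------
Chao1 uses Chao's log-normal interval on the estimated number of unseen
species. ACE uses a delta-method variance (numerical gradient of the estimator
with respect to the frequency counts, multinomial-type covariance) mapped
through the same log-normal transform. Shannon uses the standard first-order
variance ``(Σ p (ln p)² − H²)/N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import TreeNode

from .io import OtuTable
from .subsample import SubsampleSpec, replicate_tables

__all__ = [
    "FrequencyCounts",
    "Estimate",
    "AlphaSummary",
    "shannon",
    "shannon_evenness",
    "chao1",
    "ace",
    "faith_pd",
    "rarefaction_curve",
    "alpha_summary",
]

_Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class FrequencyCounts:
    """Abundance-frequency counts of one sample: F_k = #OTUs seen exactly k times."""

    freqs: dict[int, int]  # k -> F_k, k >= 1

    @classmethod
    def from_counts(cls, counts) -> "FrequencyCounts":
        c = np.asarray(counts)
        c = c[c > 0]
        if not np.all(np.mod(c, 1) == 0):
            raise ValueError("frequency counts require integer abundances")
        ks, fs = np.unique(c.astype(np.int64), return_counts=True)
        return cls({int(k): int(f) for k, f in zip(ks, fs)})

    def F(self, k: int) -> int:
        return self.freqs.get(k, 0)

    @property
    def s_obs(self) -> int:
        return sum(self.freqs.values())

    @property
    def n_reads(self) -> int:
        return sum(k * f for k, f in self.freqs.items())


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a 95% confidence interval and optional flag."""

    value: float
    lo: float = math.nan
    hi: float = math.nan
    flag: str | None = None

    def __iter__(self):
        return iter((self.value, self.lo, self.hi))


def shannon(counts) -> float:
    """Shannon's H' = −Σ pᵢ ln pᵢ (nats) over the nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or not np.any(c > 0):
        raise ValueError("Shannon's H requires at least one positive count")
    if np.any(c < 0):
        raise ValueError("negative counts")
    p = c[c > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def shannon_ci(counts) -> Estimate:
    """H' with the standard analytic 95% CI, ``Var ≈ (Σ p ln²p − H²)/N``."""
    c = np.asarray(counts, dtype=float)
    h = shannon(c)
    p = c[c > 0] / c[c > 0].sum()
    n = c.sum()
    var = max(((p * np.log(p) ** 2).sum() - h * h) / n, 0.0)
    half = _Z95 * math.sqrt(var)
    return Estimate(h, max(h - half, 0.0), h + half)


def shannon_evenness(counts, n_categories: int) -> float:
    """Pielou-style evenness E = H'/ln(k) over ``n_categories`` categories.

    Used both per sample (k = observed OTU richness) and — for core-microbiome
    delineation — across samples, treating the samples as categories and the
    reads of one OTU as individuals.
    """
    if n_categories < 2:
        raise ValueError("evenness needs at least 2 categories")
    c = np.asarray(counts, dtype=float)
    support = int((c > 0).sum())
    if support > n_categories:
        raise ValueError(
            f"{support} categories have support but n_categories={n_categories}")
    e = shannon(c) / math.log(n_categories)
    # E <= 1 holds mathematically; shave float-epsilon overshoot at the bound
    return min(e, 1.0)


def chao1(fc: FrequencyCounts) -> Estimate:
    """Bias-corrected Chao1: S_obs + F₁(F₁−1)/(2(F₂+1)), log-normal 95% CI.

    The +1 correction keeps the estimator defined when no doubletons exist;
    with no singletons the estimate reduces to S_obs.
    """
    s_obs = fc.s_obs
    f1, f2 = fc.F(1), fc.F(2)
    t = f1 * (f1 - 1) / (2.0 * (f2 + 1))
    est = s_obs + t
    if f1 == 0 or t <= 0:
        return Estimate(float(est), float(s_obs), float(est))
    # Chao 1987 variance of the bias-corrected estimator
    var = (f1 * (f1 - 1) / (2.0 * (f2 + 1))
           + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
           + f1 ** 2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4))
    lo, hi = _lognormal_ci(s_obs, est, var)
    return Estimate(float(est), lo, hi)


def _lognormal_ci(s_obs: float, est: float, var: float) -> tuple[float, float]:
    """Chao's log-normal CI on the unseen-species count T = est − S_obs."""
    t = est - s_obs
    if t <= 0 or var <= 0:
        return float(s_obs), float(est)
    k = math.exp(_Z95 * math.sqrt(math.log(1.0 + var / (t * t))))
    return s_obs + t / k, s_obs + t * k


def _ace_point(fc: FrequencyCounts, rare_cutoff: int) -> tuple[float, bool]:
    """ACE point estimate; returns (value, used_chao1_fallback)."""
    s_abund = sum(f for k, f in fc.freqs.items() if k > rare_cutoff)
    s_rare = sum(f for k, f in fc.freqs.items() if k <= rare_cutoff)
    n_rare = sum(k * f for k, f in fc.freqs.items() if k <= rare_cutoff)
    f1 = fc.F(1)
    if s_rare == 0:
        return float(s_abund), False
    c_ace = 1.0 - f1 / n_rare
    if c_ace <= 0:  # every rare read is a singleton: coverage zero
        return chao1(fc).value, True
    sum_k = sum(k * (k - 1) * f for k, f in fc.freqs.items() if k <= rare_cutoff)
    gamma_sq = (s_rare / c_ace) * sum_k / (n_rare * (n_rare - 1.0)) - 1.0 \
        if n_rare > 1 else 0.0
    gamma_sq = max(gamma_sq, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma_sq, False


def ace(fc: FrequencyCounts, rare_cutoff: int = 10) -> Estimate:
    """ACE richness with rare class ≤ ``rare_cutoff``; delta-method 95% CI.

    When sample coverage of the rare class is zero (all rare reads are
    singletons) the estimator is undefined; Chao1 is reported instead with the
    fallback flagged.
    """
    est, fallback = _ace_point(fc, rare_cutoff)
    if fallback:
        ch = chao1(fc)
        return Estimate(ch.value, ch.lo, ch.hi, flag="chao1_fallback")
    s_obs = fc.s_obs
    if est <= s_obs:
        return Estimate(float(est), float(s_obs), float(est))
    var = _ace_variance(fc, rare_cutoff, est)
    lo, hi = _lognormal_ci(s_obs, est, var)
    return Estimate(float(est), lo, hi)


def _ace_variance(fc: FrequencyCounts, rare_cutoff: int, est: float) -> float:
    """Delta-method variance: numerical gradient over F_k, multinomial covariance."""
    ks = sorted(fc.freqs)
    grad = np.empty(len(ks))
    h = 1e-4
    for i, k in enumerate(ks):
        up = dict(fc.freqs); up[k] = up[k] + h
        dn = dict(fc.freqs); dn[k] = dn[k] - h
        grad[i] = (_ace_point(FrequencyCounts(up), rare_cutoff)[0]
                   - _ace_point(FrequencyCounts(dn), rare_cutoff)[0]) / (2 * h)
    f = np.array([fc.freqs[k] for k in ks], dtype=float)
    # Cov(F_i, F_j) = F_i (δ_ij − F_j / Ŝ)
    cov = np.diag(f) - np.outer(f, f) / est
    return float(max(grad @ cov @ grad, 0.0))


def faith_pd(tree: TreeNode, present_leaves) -> float:
    """Faith's rooted PD: branch length of the minimal subtree that connects
    ``present_leaves`` to the root (stem edges included)."""
    present = set(present_leaves)
    if not present:
        raise ValueError("faith_pd requires at least one present leaf")
    by_name = {leaf.name: leaf for leaf in tree.tips()}
    missing = sorted(present - by_name.keys())
    if missing:
        raise KeyError(f"leaves not in tree: {missing}")
    seen: set[int] = set()
    pd_sum = 0.0
    for name in sorted(present):
        node = by_name[name]
        while node.parent is not None and id(node) not in seen:
            seen.add(id(node))
            pd_sum += node.length or 0.0
            node = node.parent
    return pd_sum


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Analytic expected richness E[S_n] at each down-sampling depth n.

    E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)] — the without-replacement
    expectation — evaluated with log-binomials for numerical stability.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    n_total = int(c.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if np.any(depths < 0) or np.any(depths > n_total):
        raise ValueError(f"depths must lie in [0, {n_total}]")
    out = np.empty(len(depths), dtype=float)
    for j, n in enumerate(depths):
        if n == 0:
            out[j] = 0.0
            continue
        # log C(N−N_i, n) − log C(N, n); absent term when n > N−N_i
        rem = n_total - c
        ok = rem >= n
        log_miss = np.full(len(c), -np.inf)
        if ok.any():
            log_miss[ok] = (_log_comb(rem[ok], n) - _log_comb(n_total, n))
        out[j] = float(np.sum(1.0 - np.exp(log_miss)))
    return out


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# replicate-averaged summary (the shape of a per-sample diversity table)
# ---------------------------------------------------------------------------

@dataclass
class AlphaSummary:
    """Per-sample alpha-diversity estimates averaged over subsample replicates."""

    data: pd.DataFrame
    depth: int
    replicates: int
    label: str
    notes: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# label={self.label} depth={self.depth} "
                     f"replicates={self.replicates}\n")
            self.data.to_csv(fh, sep="\t", index_label="sample",
                             float_format="%.6g")

    def summary(self) -> str:
        return self.data.round(3).to_string()


_MEASURES = ["sobs", "chao1", "chao1_lo", "chao1_hi", "ace", "ace_lo",
             "ace_hi", "shannon", "shannon_lo", "shannon_hi",
             "shannon_evenness", "faith_pd"]


def _single_sample_row(counts, tree: TreeNode | None,
                       otu_ids, rare_cutoff: int) -> dict[str, float]:
    fc = FrequencyCounts.from_counts(counts)
    ch = chao1(fc)
    ac = ace(fc, rare_cutoff)
    sh = shannon_ci(counts)
    row = {
        "sobs": float(fc.s_obs),
        "chao1": ch.value, "chao1_lo": ch.lo, "chao1_hi": ch.hi,
        "ace": ac.value, "ace_lo": ac.lo, "ace_hi": ac.hi,
        "shannon": sh.value, "shannon_lo": sh.lo, "shannon_hi": sh.hi,
        "shannon_evenness": (sh.value / math.log(fc.s_obs)
                             if fc.s_obs > 1 else 0.0),
        "ace_fallback": 1.0 if ac.flag else 0.0,
    }
    if tree is not None:
        present = {o for o, c in zip(otu_ids, np.asarray(counts)) if c > 0}
        row["faith_pd"] = faith_pd(tree, present)
    return row


def alpha_summary(table: OtuTable, spec: SubsampleSpec,
                  tree: TreeNode | None = None,
                  rare_cutoff: int = 10,
                  ci_of_means: bool = False) -> AlphaSummary:
    """Replicate-averaged per-sample diversity table.

    Each estimator is computed on each of ``spec.replicates`` independent
    down-samplings at ``spec.depth`` and reported as the mean across
    replicates. By default the CI columns are means of the per-replicate
    analytic CI bounds; ``ci_of_means=True`` instead reports the empirical
    t-interval of the replicate point estimates.
    """
    reps = replicate_tables(table, spec)
    per_rep: list[pd.DataFrame] = []
    for rep in reps:
        rows = {s: _single_sample_row(rep.counts.loc[s].to_numpy(), tree,
                                      rep.otu_ids, rare_cutoff)
                for s in rep.sample_ids}
        per_rep.append(pd.DataFrame.from_dict(rows, orient="index"))
    stack = pd.concat(per_rep, keys=range(len(per_rep)))
    mean = stack.groupby(level=1, sort=False).mean()
    mean = mean.loc[table.sample_ids]
    notes = []
    if mean["ace_fallback"].any():
        notes.append("ACE fell back to Chao1 for at least one replicate "
                     "(zero rare-class coverage)")
    if ci_of_means and spec.replicates > 1:
        from scipy import stats as _st
        for col in ("chao1", "ace", "shannon"):
            pts = stack[col].unstack(level=0)
            m = pts.mean(axis=1)
            se = pts.std(axis=1, ddof=1) / math.sqrt(spec.replicates)
            tq = _st.t.ppf(0.975, spec.replicates - 1)
            mean[f"{col}_lo"] = m - tq * se
            mean[f"{col}_hi"] = m + tq * se
    mean = mean.drop(columns=["ace_fallback"])
    if tree is None:
        notes.append("no tree supplied: faith_pd omitted")
    return AlphaSummary(mean, spec.depth, spec.replicates, table.label, notes)
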