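"""Differential miRNA abundance between two conditions.

Counts are normalized by library size (counts per million hairpin-mapped
reads).  Each miRNA is tested with a conditional exact test for
overdispersed counts: replicate counts are rescaled to a common
effective library size, summed per condition, and — conditional on the
grand total *s* — the probability of every split ``(a, s−a)`` is
evaluated under a null in which each condition sum is negative binomial
with mean proportional to its replicate number and variance
``μ + (φ/n)μ²`` (a sum of *n* replicate-level NB(μ/n, φ) draws).  The
two-sided p-value is the total probability of all splits no more likely
than the observed one; with φ = 0 this reduces to an exact binomial
split test.  The common dispersion φ is a pooled method-of-moments
estimate across miRNAs.

Fold changes are ratios of mean CPM with a pseudocount (default the CPM
equivalent of 0.5 reads at the smallest library), so zero counts give
finite ratios.  Classification is two-tier: at p < α, a ratio above 2
(below 1/2) marks a miRNA as different (``mark2``), above 10 (below
1/10) as strongly different (``mark10``).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .quantify import CountMatrix

__all__ = [
    "cpm",
    "estimate_common_dispersion",
    "exact_count_test",
    "fold_ratio",
    "classify",
    "run_differential",
]

logger = logging.getLogger(__name__)


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads, per sample."""
    if (cm.lib_sizes <= 0).any():
        bad = list(cm.lib_sizes.index[cm.lib_sizes <= 0])
        raise ValueError(f"zero/negative library size for samples: {bad}")
    return cm.counts / cm.lib_sizes.astype(float) * 1e6


def _split_conditions(
    cm: CountMatrix, labels: Mapping[str, str], condition_a: str, condition_b: str
) -> tuple[list[str], list[str]]:
    samples_a = [s for s in cm.samples if labels[s] == condition_a]
    samples_b = [s for s in cm.samples if labels[s] == condition_b]
    if not samples_a or not samples_b:
        raise ValueError(
            f"need samples in both conditions {condition_a!r} and {condition_b!r}"
        )
    return samples_a, samples_b


def _scaled_counts(cm: CountMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Counts rescaled to the geometric-mean library size; also the factors."""
    libs = cm.lib_sizes.astype(float)
    target = float(np.exp(np.log(libs).mean()))
    factors = target / libs
    return cm.counts * factors, factors


def estimate_common_dispersion(
    cm: CountMatrix,
    labels: Mapping[str, str],
    condition_a: str,
    condition_b: str,
) -> float:
    """Pooled method-of-moments NB dispersion on library-size-scaled counts.

    For scaled counts with within-condition sample mean m (over n
    replicates) and sample variance v, ``E[v] = f·μ + φ·μ²`` where f is
    the mean scaling factor, and ``E[m² − v/n] = μ²``, so φ is estimated
    as ``Σ(v − f·m) / Σ(m² − v/n)`` pooled over miRNAs and conditions
    (the denominator correction removes the upward bias of m² as an
    estimate of μ²), floored at 0.  With a single replicate per
    condition in both groups no variance is estimable: returns 0 with a
    warning.
    """
    samples_a, samples_b = _split_conditions(cm, labels, condition_a, condition_b)
    scaled, factors = _scaled_counts(cm)
    num = 0.0
    den = 0.0
    usable = False
    for group in (samples_a, samples_b):
        if len(group) < 2:
            continue
        usable = True
        sub = scaled[group].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        f = float(factors[group].mean())
        keep = m > 0
        num += float(np.sum(v[keep] - f * m[keep]))
        den += float(np.sum(m[keep] ** 2 - v[keep] / len(group)))
    if not usable:
        logger.warning(
            "no condition has >= 2 replicates; dispersion set to 0 (Poisson)"
        )
        return 0.0
    if den == 0.0:
        return 0.0
    return max(0.0, num / den)


def exact_count_test(
    sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided conditional exact test for a split of a count total.

    ``sum_a``/``sum_b`` are condition count sums (already scaled to a
    common effective library size and rounded), ``n_a``/``n_b`` the
    replicate numbers, ``phi`` the common replicate-level NB dispersion.
    Conditional on ``s = sum_a + sum_b``, the null probability of the
    split ``(s−k, k)`` is proportional to ``NB(s−k; μ_a, φ/n_a) ·
    NB(k; μ_b, φ/n_b)`` with μ's proportional to ``n_a : n_b`` (binomial
    when φ = 0); p is the summed probability of all splits with
    probability <= that of the observed split.  Always in (0, 1].
    """
    if min(sum_a, sum_b, ) < 0 or min(n_a, n_b) < 1 or phi < 0:
        raise ValueError("counts must be >= 0, replicates >= 1, phi >= 0")
    sum_a, sum_b = int(sum_a), int(sum_b)
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    frac_b = n_b / (n_a + n_b)
    k = np.arange(s + 1)
    if phi == 0:
        logp = stats.binom.logpmf(k, s, frac_b)
    else:
        mu_a = s * (1.0 - frac_b)
        mu_b = s * frac_b
        # group sum of n iid NB(mu/n, phi) is NB(mu, phi/n): size r = n/phi
        r_a, r_b = n_a / phi, n_b / phi
        logp = stats.nbinom.logpmf(s - k, r_a, r_a / (r_a + mu_a)) + stats.nbinom.logpmf(
            k, r_b, r_b / (r_b + mu_b)
        )
        logp = logp - logsumexp(logp)
    observed = logp[sum_b]
    in_tail = logp <= observed + 1e-10
    if in_tail.all():  # observed split is the mode
        return 1.0
    return float(min(1.0, np.exp(logsumexp(logp[in_tail]))))


def fold_ratio(
    mean_cpm_a: float, mean_cpm_b: float, pseudo: float
) -> tuple[float, float]:
    """Pseudocounted linear and log2 fold change, condition B over A."""
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    ratio = (mean_cpm_b + pseudo) / (mean_cpm_a + pseudo)
    return ratio, float(np.log2(ratio))


def classify(
    ratio: float,
    p_value: float,
    alpha: float = 0.05,
    fc2: float = 2.0,
    fc10: float = 10.0,
) -> tuple[str, str]:
    """Two-tier (mark2, mark10) classification of one miRNA.

    UP/DOWN require p < alpha and the ratio beyond the tier threshold in
    the corresponding direction; otherwise NS.
    """
    mark2 = mark10 = "NS"
    if p_value < alpha:
        if ratio > fc2:
            mark2 = "UP"
        elif ratio < 1.0 / fc2:
            mark2 = "DOWN"
        if ratio > fc10:
            mark10 = "UP"
        elif ratio < 1.0 / fc10:
            mark10 = "DOWN"
    return mark2, mark10


def run_differential(
    cm: CountMatrix,
    labels: Mapping[str, str],
    condition_a: str = "milk",
    condition_b: str = "exosome",
    alpha: float = 0.05,
    fc2: float = 2.0,
    fc10: float = 10.0,
    pseudo_reads: float = 0.5,
    dispersion: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full differential analysis; returns (results, volcano) tables.

    Results has one row per miRNA with nonzero counts somewhere:
    per-condition mean raw counts and mean CPM, exact-test p-value,
    pseudocounted ratio (B vs A) with log2, and the two-tier marks.
    The volcano table is (mirna, log2_ratio, neglog10_p).  miRNAs with
    all-zero counts are excluded and logged.
    """
    samples_a, samples_b = _split_conditions(cm, labels, condition_a, condition_b)
    n_a, n_b = len(samples_a), len(samples_b)

    total = cm.counts.sum(axis=1)
    zero = total.index[total == 0]
    if len(zero) > 0:
        logger.info("excluding %d miRNA(s) with all-zero counts", len(zero))
    kept = total.index[total > 0]

    cpm_mat = cpm(cm)
    phi = (
        dispersion
        if dispersion is not None
        else estimate_common_dispersion(cm, labels, condition_a, condition_b)
    )
    scaled, _ = _scaled_counts(cm)
    pseudo = pseudo_reads / float(cm.lib_sizes.min()) * 1e6

    rows = []
    for mirna in kept:
        sum_a = int(round(scaled.loc[mirna, samples_a].sum()))
        sum_b = int(round(scaled.loc[mirna, samples_b].sum()))
        p = exact_count_test(sum_a, sum_b, n_a, n_b, phi)
        mean_cpm_a = float(cpm_mat.loc[mirna, samples_a].mean())
        mean_cpm_b = float(cpm_mat.loc[mirna, samples_b].mean())
        ratio, l2 = fold_ratio(mean_cpm_a, mean_cpm_b, pseudo)
        mark2, mark10 = classify(ratio, p, alpha=alpha, fc2=fc2, fc10=fc10)
        rows.append(
            {
                "mirna": mirna,
                f"mean_count_{condition_a}": float(cm.counts.loc[mirna, samples_a].mean()),
                f"mean_count_{condition_b}": float(cm.counts.loc[mirna, samples_b].mean()),
                f"mean_cpm_{condition_a}": mean_cpm_a,
                f"mean_cpm_{condition_b}": mean_cpm_b,
                "p_value": p,
                "ratio": ratio,
                "log2_ratio": l2,
                "mark2": mark2,
                "mark10": mark10,
            }
        )
    results = pd.DataFrame(rows)
    if not results.empty:
        results = results.sort_values(
            ["p_value", "mirna"], kind="mergesort"
        ).reset_index(drop=True)
        with np.errstate(divide="ignore"):
            neglog = -np.log10(results["p_value"].to_numpy())
        volcano = pd.DataFrame(
            {
                "mirna": results["mirna"],
                "log2_ratio": results["log2_ratio"],
                "neglog10_p": neglog,
            }
        )
    else:
        volcano = pd.DataFrame(columns=["mirna", "log2_ratio", "neglog10_p"])
    results.attrs["dispersion"] = phi
    return results, volcano
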