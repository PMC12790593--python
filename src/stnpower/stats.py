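"""Across-patient statistics.

Effect sizes with bootstrap confidence intervals, rank correlations with
bootstrap CIs and Cohen-style required-sample-size estimates, cluster-based
permutation tests on whole spectra (Maris-Oostenveld style, mean-difference
statistic), per-frequency correlation profiles, Kruskal-Wallis/Dunn dataset
comparability checks, and bootstrap standard errors of mean spectra.

All Monte-Carlo routines take an explicit seed and use the (b+1)/(B+1)
p-value convention; paired permutation tests switch to exhaustive sign-flip
enumeration whenever 2^n does not exceed the requested permutation count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "EffectSizeResult",
    "CorrelationResult",
    "ClusterTestResult",
    "cohens_d_band",
    "bonferroni_confidence_level",
    "correlate_with_ci",
    "required_sample_size",
    "cluster_permutation_test",
    "frequency_correlation_profile",
    "dataset_comparability",
    "bootstrap_spectrum_se",
]


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    ci_low: float
    ci_high: float
    conf_level: float
    n: int
    paired: bool
    label: str = ""

    @property
    def significant(self) -> bool:
        """CI excludes zero at the (possibly Bonferroni-adjusted) level."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # 'spearman' | 'pearson'
    coefficient: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    label: str = ""

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class ClusterTestResult:
    frequencies: np.ndarray
    statistic: np.ndarray  # per-bin mean difference (a - b)
    bin_p: np.ndarray
    clusters: list[tuple[float, float]]  # [f_start, f_stop] inclusive, Hz
    cluster_p: list[float]
    n_permutations: int
    alpha: float
    exhaustive: bool

    @property
    def significant_clusters(self) -> list[tuple[float, float]]:
        return [c for c, p in zip(self.clusters, self.cluster_p) if p < self.alpha]


def bonferroni_confidence_level(n_comparisons: int, alpha: float = 0.05) -> float:
    """Confidence level 1 - alpha/n for n simultaneous comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return 1.0 - alpha / n_comparisons


def _cohens_d(x: np.ndarray, y: np.ndarray, paired: bool) -> float:
    if paired:
        diff = x - y
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance of paired differences")
        return float(diff.mean() / sd)
    nx, ny = len(x), len(y)
    pooled = math.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((x.mean() - y.mean()) / pooled)


def cohens_d_band(
    x,
    y,
    paired: bool = True,
    n_boot: int = 10_000,
    conf_level: float = 0.95,
    seed: int | None = 0,
    label: str = "",
) -> EffectSizeResult:
    """Cohen's d with a bootstrap percentile CI.

    Sign convention: x is the off-state, y the on-state, so positive d means
    a Levodopa-induced reduction. For six canonical bands at alpha = 0.05,
    pass conf_level = bonferroni_confidence_level(6) = 0.992.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and x.shape != y.shape:
        raise ValueError("paired samples must be aligned by patient")
    if min(len(x), len(y)) < 3:
        raise ValueError("need at least 3 observations per sample")
    d = _cohens_d(x, y, paired)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        if paired:
            idx = rng.integers(0, len(x), len(x))
            diff = x[idx] - y[idx]
            sd = diff.std(ddof=1)
            boots[b] = diff.mean() / sd if sd > 0 else 0.0
        else:
            xb = x[rng.integers(0, len(x), len(x))]
            yb = y[rng.integers(0, len(y), len(y))]
            try:
                boots[b] = _cohens_d(xb, yb, paired=False)
            except ValueError:
                boots[b] = 0.0
    tail = (1.0 - conf_level) / 2.0
    lo, hi = np.quantile(boots, [tail, 1.0 - tail])
    return EffectSizeResult(d, float(lo), float(hi), conf_level, len(x), paired, label)


def correlate_with_ci(
    x,
    y,
    method: str = "spearman",
    n_boot: int = 10_000,
    conf_level: float = 0.95,
    seed: int | None = 0,
    label: str = "",
) -> CorrelationResult:
    """Correlation coefficient, two-sided p, and a percentile bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "spearman":
        coef, p = scipy.stats.spearmanr(x, y)
    elif method == "pearson":
        coef, p = scipy.stats.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(x)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[b] = 0.0
        elif method == "spearman":
            boots[b] = scipy.stats.spearmanr(xb, yb).statistic
        else:
            boots[b] = scipy.stats.pearsonr(xb, yb).statistic
    tail = (1.0 - conf_level) / 2.0
    lo, hi = np.quantile(boots, [tail, 1.0 - tail])
    return CorrelationResult(method, float(coef), float(p), float(lo), float(hi), n, label)


def required_sample_size(rho: float, power: float = 0.80, alpha: float = 0.05) -> int:
    """Patients needed to detect a correlation rho (two-sided, Fisher z).

    n = ((z_{1-alpha/2} + z_{power}) / atanh(|rho|))^2 + 3, rounded up.
    """
    if not 0.0 < abs(rho) < 1.0:
        raise ValueError("rho must satisfy 0 < |rho| < 1")
    z_alpha = scipy.stats.norm.ppf(1.0 - alpha / 2.0)
    z_power = scipy.stats.norm.ppf(power)
    n = ((z_alpha + z_power) / math.atanh(abs(rho))) ** 2 + 3.0
    return int(math.ceil(n))


def _max_cluster_masses(stats: np.ndarray, pseudo_p: np.ndarray, alpha: float) -> np.ndarray:
    """Largest |cluster mass| per permutation row; 0 when no cluster forms."""
    below = pseudo_p < alpha
    best = np.zeros(stats.shape[0])
    run = np.zeros(stats.shape[0])
    for j in range(stats.shape[1]):
        run = (run + stats[:, j]) * below[:, j]
        np.maximum(best, np.abs(run), out=best)
    return best


def _clusters_from_mask(freqs: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True, as (start, stop) index pairs (inclusive)."""
    out = []
    j = 0
    while j < mask.size:
        if mask[j]:
            k = j
            while k + 1 < mask.size and mask[k + 1]:
                k += 1
            out.append((j, k))
            j = k + 1
        else:
            j += 1
    return out


def cluster_permutation_test(
    spectra_a,
    spectra_b,
    paired: bool = True,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = 0,
    frequencies: np.ndarray | None = None,
) -> ClusterTestResult:
    """Cluster-corrected permutation test on per-bin mean differences.

    Bin-level two-sided p-values come from the permutation distribution of
    the mean difference; clusters are maximal contiguous runs of bins with
    p < alpha; the cluster statistic is the summed bin statistic, compared
    against the permutation distribution of the maximum |cluster mass|.
    Paired designs permute by sign-flipping within-subject differences and
    enumerate all 2^n flips when that is no larger than n_perm.
    """
    a = np.atleast_2d(np.asarray(spectra_a, dtype=float))
    b = np.atleast_2d(np.asarray(spectra_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("frequency grids differ between conditions")
    if frequencies is None:
        frequencies = np.arange(a.shape[1], dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)

    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test needs aligned subjects")
        n = a.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        diff = a - b
        exhaustive = 2**n <= n_perm
        if exhaustive:
            signs = np.array(list(product((1.0, -1.0), repeat=n)))
        else:
            rng = np.random.default_rng(seed)
            signs = rng.choice([1.0, -1.0], size=(n_perm, n))
        perm_stats = signs @ diff / n  # (B, F) permuted mean differences
        obs = diff.mean(axis=0)
    else:
        n_a, n_b = a.shape[0], b.shape[0]
        if min(n_a, n_b) < 2:
            raise ValueError("need at least 2 subjects per group")
        pooled = np.vstack([a, b])
        total = n_a + n_b
        n_comb = math.comb(total, n_a)
        exhaustive = n_comb <= n_perm
        if exhaustive:
            from itertools import combinations

            labels = []
            for comb in combinations(range(total), n_a):
                mask = np.zeros(total, dtype=bool)
                mask[list(comb)] = True
                labels.append(mask)
            labels = np.array(labels)
        else:
            rng = np.random.default_rng(seed)
            labels = np.zeros((n_perm, total), dtype=bool)
            for i in range(n_perm):
                labels[i, rng.permutation(total)[:n_a]] = True
        perm_stats = np.array(
            [pooled[m].mean(axis=0) - pooled[~m].mean(axis=0) for m in labels]
        )
        obs = a.mean(axis=0) - b.mean(axis=0)

    B = perm_stats.shape[0]
    # Two-sided bin p of the observed stat against the permutation
    # distribution. Exhaustive enumerations include the identity relabelling,
    # so the plain count/B is already exact and never zero; random sampling
    # uses the (b+1)/(B+1) convention.
    add = 0.0 if exhaustive else 1.0
    abs_perm = np.abs(perm_stats)
    bin_p = ((abs_perm >= np.abs(obs)[None, :] - 1e-12).sum(axis=0) + add) / (B + add)
    # pseudo bin p-values for every permutation (rank within the distribution)
    order = np.argsort(abs_perm, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(B)[:, None]
    ranks[order, np.arange(abs_perm.shape[1])[None, :]] = rows
    # p of permutation row = fraction of permutations with |stat| >= its own
    pseudo_p = (B - ranks) / B

    obs_masses_idx = _clusters_from_mask(frequencies, bin_p < alpha)
    clusters = [(float(frequencies[i]), float(frequencies[j])) for i, j in obs_masses_idx]
    obs_mass = [float(np.abs(obs[i : j + 1].sum())) for i, j in obs_masses_idx]
    null_max = _max_cluster_masses(perm_stats, pseudo_p, alpha)
    cluster_p = [
        float(((null_max >= m - 1e-12).sum() + add) / (B + add)) for m in obs_mass
    ]
    return ClusterTestResult(
        frequencies=frequencies,
        statistic=obs,
        bin_p=bin_p,
        clusters=clusters,
        cluster_p=cluster_p,
        n_permutations=B,
        alpha=alpha,
        exhaustive=exhaustive,
    )


def frequency_correlation_profile(
    powers: np.ndarray,
    scores,
    frequencies: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin Spearman correlation with uncorrected p-values.

    Returns a tidy frame (frequency, rho, p, significant). Contiguous
    significant runs can be read off with `significant_runs`. Neighbouring
    bins are strongly dependent, which is why no Bonferroni correction is
    applied here.
    """
    powers = np.atleast_2d(np.asarray(powers, dtype=float))  # (n_subjects, n_bins)
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("correlation undefined for a constant score vector")
    if frequencies is None:
        frequencies = np.arange(powers.shape[1], dtype=float)
    rows = []
    for j, f in enumerate(frequencies):
        rho, p = scipy.stats.spearmanr(powers[:, j], scores)
        rows.append({"frequency": float(f), "rho": float(rho), "p": float(p)})
    df = pd.DataFrame(rows)
    df["significant"] = df["p"] < alpha
    return df


def significant_runs(profile: pd.DataFrame) -> list[tuple[float, float]]:
    """Contiguous frequency intervals with significant correlations."""
    mask = profile["significant"].to_numpy()
    freqs = profile["frequency"].to_numpy()
    return [(freqs[i], freqs[j]) for i, j in _clusters_from_mask(freqs, mask)]


def _dunn_posthoc(groups: dict, alpha: float) -> pd.DataFrame:
    """All pairwise Dunn z tests on pooled ranks with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in labels:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    rows = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            se = math.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term)
                * (1.0 / sizes[gi] + 1.0 / sizes[gj])
            )
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            p = 2.0 * scipy.stats.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": gi,
                    "group_b": gj,
                    "z": float(z),
                    "p": float(p),
                    "direction": f"{gi} > {gj}" if z > 0 else f"{gj} > {gi}",
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def _kruskal_h(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    h, start = 0.0, 0
    for g in groups:
        k = len(g)
        h += ranks[start : start + k].sum() ** 2 / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, ties = np.unique(pooled, return_counts=True)
    correction = 1.0 - (ties**3 - ties).sum() / (n**3 - n)
    return h / correction if correction > 0 else h


def _exact_kruskal_p(groups: list[np.ndarray]) -> float:
    """Exhaustive permutation p of the H statistic over group relabellings."""
    from itertools import combinations

    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h_obs = _kruskal_h(groups)

    def _assignments(indices: tuple, remaining_sizes: list[int]):
        if not remaining_sizes:
            yield []
            return
        k = remaining_sizes[0]
        for chosen in combinations(indices, k):
            rest = tuple(i for i in indices if i not in chosen)
            for tail in _assignments(rest, remaining_sizes[1:]):
                yield [list(chosen)] + tail

    count = total = 0
    for assign in _assignments(tuple(range(pooled.size)), sizes):
        perm_groups = [pooled[idx] for idx in assign]
        total += 1
        if _kruskal_h(perm_groups) >= h_obs - 1e-12:
            count += 1
    return count / total


def dataset_comparability(values_by_dataset: dict, alpha: float = 0.05,
                          exact: bool | None = None):
    """Kruskal-Wallis omnibus test with Dunn post-hoc pairs when significant.

    exact=None switches to an exhaustive rank-permutation p-value when the
    pooled sample is small (<= 10 observations), where the chi-square
    approximation is unreliable. Returns (H, p, posthoc_frame_or_None).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_dataset.items()}
    if len(groups) < 2:
        raise ValueError("need at least two datasets")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"dataset {k!r} has fewer than 2 observations")
    glist = list(groups.values())
    h = _kruskal_h(glist)
    total_n = sum(len(g) for g in glist)
    if exact is None:
        exact = total_n <= 10
    if exact:
        p = _exact_kruskal_p(glist)
    else:
        p = float(scipy.stats.kruskal(*glist).pvalue)
    posthoc = _dunn_posthoc(groups, alpha) if p < alpha else None
    return float(h), float(p), posthoc


def bootstrap_spectrum_se(
    spectra, n_boot: int = 1000, seed: int | None = 0
) -> np.ndarray:
    """Per-bin SD of bootstrap means across a spectrum collection."""
    arr = np.atleast_2d(np.asarray(spectra, dtype=float))
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least two spectra")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = arr[idx].mean(axis=1)  # (n_boot, n_bins)
    return boot_means.std(axis=0, ddof=1)
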