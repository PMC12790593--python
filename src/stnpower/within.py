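"""Within-patient analyses: hemispheres as repeated measures.

Patients qualify when both STNs were recorded and the lateralized
bradykinesia-rigidity subscores differ by at least one point with the same
asymmetry sign in both medication conditions. The more affected hemisphere
is the STN contralateral to the worse hemibody.

Repeated-measures correlation follows the ANCOVA formulation: subtract each
patient's mean from x and y, correlate the residuals, and test with
df = n_observations - n_patients - 1. The ranked variant rank-transforms x
and y across all observations first (the non-parametric extension). These
analyses are exploratory by design: no multiple-comparison correction is
applied, and every exported table carries an ``exploratory`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .stats import ClusterTestResult, cluster_permutation_test

__all__ = [
    "HemispherePair",
    "RmCorrResult",
    "inclusion_filter",
    "rm_corr",
    "hemisphere_spectral_contrast",
    "hemisphere_feature_contrast",
]


@dataclass(frozen=True)
class HemispherePair:
    """Feature and subscore values for one included patient in one condition."""

    patient_id: str
    condition: str
    feature_more: float  # more affected hemisphere
    feature_less: float
    subscore_more: int  # contralateral bradykinesia-rigidity (or variant)
    subscore_less: int


@dataclass(frozen=True)
class RmCorrResult:
    r_rm: float
    df: int
    p: float
    ranked: bool
    n_patients: int
    n_observations: int
    exploratory: bool = True


def inclusion_filter(
    assessments: pd.DataFrame,
    recorded_hemispheres: dict[str, set] | None = None,
    condition: str = "off",
    strict_both: bool = False,
) -> pd.DataFrame:
    """Eligibility for within-patient analysis, with per-patient reasons.

    assessments: tidy frame with columns patient_id, condition,
    brady_rigidity_left_body, brady_rigidity_right_body (one row per
    patient x condition). recorded_hemispheres maps patient_id to the set of
    recorded STNs; None means both were recorded for everyone.

    Included iff both STNs recorded, |left - right| >= 1 in the analysed
    condition (both conditions when strict_both), and the asymmetry sign is
    identical in off and on. Returns a frame (patient_id, included, reason,
    more_affected_hemisphere).
    """
    rows = []
    for pid, grp in assessments.groupby("patient_id", sort=False):
        by_cond = {r["condition"]: r for _, r in grp.iterrows()}
        if recorded_hemispheres is not None and set(
            recorded_hemispheres.get(pid, set())
        ) != {"left", "right"}:
            rows.append((pid, False, "missing hemisphere recording", None))
            continue
        if "off" not in by_cond or "on" not in by_cond:
            rows.append((pid, False, "missing condition scores", None))
            continue
        diffs = {}
        missing = False
        for cond in ("off", "on"):
            r = by_cond[cond]
            lb, rb = r["brady_rigidity_left_body"], r["brady_rigidity_right_body"]
            if pd.isna(lb) or pd.isna(rb):
                missing = True
                break
            diffs[cond] = int(lb) - int(rb)
        if missing:
            rows.append((pid, False, "missing subscores", None))
            continue
        need = ("off", "on") if strict_both else (condition,)
        if any(abs(diffs[c]) < 1 for c in need):
            rows.append((pid, False, "no asymmetry", None))
            continue
        if diffs["off"] * diffs["on"] < 0 or (
            diffs["off"] == 0 or diffs["on"] == 0
        ) and diffs["off"] != diffs["on"]:
            rows.append((pid, False, "inconsistent asymmetry", None))
            continue
        # worse left hemibody -> right STN more affected (contralateral)
        more = "right" if diffs[condition] > 0 else "left"
        rows.append((pid, True, "", more))
    return pd.DataFrame(
        rows, columns=["patient_id", "included", "reason", "more_affected_hemisphere"]
    )


def rm_corr(
    x,
    y,
    subjects,
    ranked: bool = False,
) -> RmCorrResult:
    """Repeated-measures correlation of x and y over subjects' observations.

    Subjects with fewer than two observations are dropped; at least three
    subjects must remain. Invariant to per-subject location shifts in both
    variables by construction.
    """
    df_in = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float), "s": subjects})
    counts = df_in["s"].value_counts()
    df_in = df_in[df_in["s"].isin(counts[counts >= 2].index)]
    n_subj = df_in["s"].nunique()
    if n_subj < 3:
        raise ValueError(f"need >= 3 subjects with >= 2 observations, have {n_subj}")
    if ranked:
        df_in["x"] = scipy.stats.rankdata(df_in["x"])
        df_in["y"] = scipy.stats.rankdata(df_in["y"])
    xc = df_in["x"] - df_in.groupby("s")["x"].transform("mean")
    yc = df_in["y"] - df_in.groupby("s")["y"].transform("mean")
    sxx = float((xc**2).sum())
    syy = float((yc**2).sum())
    if sxx == 0 or syy == 0:
        raise ValueError("no within-subject variance in x or y")
    r = float((xc * yc).sum() / np.sqrt(sxx * syy))
    n_obs = len(df_in)
    dof = n_obs - n_subj - 1
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), dof))
    return RmCorrResult(r, dof, p, ranked, n_subj, n_obs)


def pairs_to_rm_inputs(pairs: list[HemispherePair]):
    """Unpack hemisphere pairs into (x, y, subjects) arrays for rm_corr."""
    x, y, s = [], [], []
    for p in pairs:
        x += [p.feature_more, p.feature_less]
        y += [p.subscore_more, p.subscore_less]
        s += [p.patient_id, p.patient_id]
    return np.array(x), np.array(y), np.array(s)


def hemisphere_spectral_contrast(
    spectra_more,
    spectra_less,
    frequencies=None,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> ClusterTestResult:
    """Paired cluster permutation test: more vs less affected hemisphere."""
    return cluster_permutation_test(
        spectra_more,
        spectra_less,
        paired=True,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        frequencies=frequencies,
    )


def hemisphere_feature_contrast(pairs: list[HemispherePair]) -> dict:
    """Wilcoxon signed-rank test on more-minus-less-affected differences.

    Exact p for n <= 25 (no ties/zeros permitting), normal approximation
    otherwise. All-zero differences yield a degenerate result flag instead
    of a test statistic.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 included patients")
    diffs = np.array([p.feature_more - p.feature_less for p in pairs], dtype=float)
    if np.all(diffs == 0):
        return {
            "n": len(diffs),
            "statistic": None,
            "p": None,
            "degenerate": True,
            "exploratory": True,
        }
    method = "exact" if len(diffs) <= 25 and not np.any(diffs == 0) else "approx"
    res = scipy.stats.wilcoxon(diffs, method=method)
    return {
        "n": len(diffs),
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "degenerate": False,
        "median_difference": float(np.median(diffs)),
        "exploratory": True,
    }
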