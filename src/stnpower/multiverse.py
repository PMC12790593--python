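"""Multiverse (specification-grid) analysis of beta-symptom correlations.

The grid crosses three factors: medication state (off, on, off-minus-on),
sampling unit (patient with hemisphere-averaged power, or hemisphere as an
observation), and beta range (alpha-beta 8-35 Hz, beta 13-30 Hz, low beta
13-20 Hz) - 18 paths; with five datasets that is 90 dataset x path tests.
Relative power is the default framework. Spearman correlations with
bootstrap CIs are computed per dataset and pooled by concatenating patients;
no correction is applied across paths (the point of the exercise is to
compare paths, not to test them jointly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .stats import CorrelationResult, correlate_with_ci, required_sample_size

__all__ = [
    "MultiversePath",
    "MultiverseResult",
    "enumerate_paths",
    "run_multiverse",
    "summarize",
    "DEFAULT_STATES",
    "DEFAULT_UNITS",
    "DEFAULT_BANDS",
]

DEFAULT_STATES = ("off", "on", "off_minus_on")
DEFAULT_UNITS = ("patient", "hemisphere")
DEFAULT_BANDS = ("alpha_beta", "beta", "low_beta")


@dataclass(frozen=True)
class MultiversePath:
    state: str
    unit: str
    band: str

    @property
    def key(self) -> str:
        return f"{self.state}|{self.unit}|{self.band}"


@dataclass
class MultiverseResult:
    per_cell: pd.DataFrame  # dataset x path rows with rho, CI, p, n, classification
    pooled: pd.DataFrame  # one row per path, incl. required-n
    paths: list[MultiversePath]
    datasets: list[str]


def enumerate_paths(
    states=DEFAULT_STATES, units=DEFAULT_UNITS, bands=DEFAULT_BANDS
) -> list[MultiversePath]:
    """Full Cartesian product in stable (state, unit, band) order."""
    if not (states and units and bands):
        raise ValueError("every factor list must be non-empty")
    return [MultiversePath(s, u, b) for s, u, b in product(states, units, bands)]


def _path_xy(df: pd.DataFrame, path: MultiversePath):
    """Assemble (power, score) observations for one path from a tidy table.

    df columns: patient_id, hemisphere, condition, updrs_total and one
    power column per band. The off-minus-on state correlates the power
    decrease (off - on) with the UPDRS improvement (off - on).
    """
    col = path.band
    if path.state in ("off", "on"):
        sub = df[df["condition"] == path.state]
        if sub.empty:
            return None
        if path.unit == "patient":
            g = sub.groupby("patient_id").agg(
                power=(col, "mean"), score=("updrs_total", "first")
            )
            return g["power"].to_numpy(), g["score"].to_numpy()
        return sub[col].to_numpy(), sub["updrs_total"].to_numpy()
    # off-minus-on
    piv = df.pivot_table(
        index=["patient_id", "hemisphere"], columns="condition",
        values=[col, "updrs_total"], aggfunc="first",
    )
    try:
        dp = piv[(col, "off")] - piv[(col, "on")]
        ds = piv[("updrs_total", "off")] - piv[("updrs_total", "on")]
    except KeyError:
        return None
    keep = dp.notna() & ds.notna()
    dp, ds = dp[keep], ds[keep]
    if dp.empty:
        return None
    if path.unit == "patient":
        frame = pd.DataFrame({"dp": dp, "ds": ds}).reset_index()
        g = frame.groupby("patient_id").agg(power=("dp", "mean"), score=("ds", "first"))
        return g["power"].to_numpy(), g["score"].to_numpy()
    return dp.to_numpy(), ds.to_numpy()


def _classify(res: CorrelationResult | None) -> str:
    if res is None:
        return "unavailable"
    if res.p < 0.05:
        return "significant_positive" if res.coefficient > 0 else "significant_negative"
    return "nonsignificant"


def run_multiverse(
    datasets: dict[str, pd.DataFrame],
    paths: list[MultiversePath] | None = None,
    n_boot: int = 10_000,
    seed: int | None = 0,
) -> MultiverseResult:
    """Execute every dataset x path correlation plus pooled estimates.

    datasets: mapping dataset_id -> tidy frame with columns patient_id,
    hemisphere, condition, updrs_total, and one relative-power column per
    beta variant. A dataset missing a state yields an 'unavailable' cell,
    not an error.
    """
    paths = paths or enumerate_paths()
    cells, pooled_rows = [], []
    for p_idx, path in enumerate(paths):
        pooled_x, pooled_y = [], []
        for d_idx, (ds_name, df) in enumerate(datasets.items()):
            xy = _path_xy(df, path)
            res = None
            if xy is not None and len(xy[0]) >= 4 and np.ptp(xy[0]) > 0 and np.ptp(xy[1]) > 0:
                res = correlate_with_ci(
                    xy[0], xy[1], method="spearman", n_boot=n_boot,
                    seed=None if seed is None else seed + 97 * p_idx + d_idx,
                    label=path.key,
                )
                pooled_x.append(xy[0])
                pooled_y.append(xy[1])
            cells.append(
                {
                    "dataset": ds_name,
                    "state": path.state,
                    "unit": path.unit,
                    "band": path.band,
                    "rho": res.coefficient if res else np.nan,
                    "ci_low": res.ci_low if res else np.nan,
                    "ci_high": res.ci_high if res else np.nan,
                    "p": res.p if res else np.nan,
                    "n": res.n if res else 0,
                    "classification": _classify(res),
                }
            )
        if pooled_x:
            x = np.concatenate(pooled_x)
            y = np.concatenate(pooled_y)
            pres = correlate_with_ci(
                x, y, method="spearman", n_boot=n_boot,
                seed=None if seed is None else seed + 7919 * p_idx, label=path.key,
            )
            try:
                req_n = required_sample_size(pres.coefficient)
            except ValueError:
                req_n = None
            pooled_rows.append(
                {
                    "state": path.state,
                    "unit": path.unit,
                    "band": path.band,
                    "rho": pres.coefficient,
                    "ci_low": pres.ci_low,
                    "ci_high": pres.ci_high,
                    "p": pres.p,
                    "n": pres.n,
                    "classification": _classify(pres),
                    "required_n": req_n,
                }
            )
    return MultiverseResult(
        per_cell=pd.DataFrame(cells),
        pooled=pd.DataFrame(pooled_rows),
        paths=paths,
        datasets=list(datasets),
    )


def summarize(result: MultiverseResult) -> dict:
    """Robustness/replicability counts and a forest-plot-ready table."""
    cells = result.per_cell
    counts = cells["classification"].value_counts().to_dict()
    by_dataset = (
        cells.groupby("dataset")["classification"].value_counts().unstack(fill_value=0)
    )
    by_path = (
        cells.groupby(["state", "unit", "band"])["classification"]
        .value_counts()
        .unstack(fill_value=0)
    )
    total = len(cells)
    return {
        "n_paths": len(result.paths),
        "n_datasets": len(result.datasets),
        "n_tests": total,
        "counts": {
            "significant_positive": int(counts.get("significant_positive", 0)),
            "significant_negative": int(counts.get("significant_negative", 0)),
            "nonsignificant": int(counts.get("nonsignificant", 0)),
            "unavailable": int(counts.get("unavailable", 0)),
        },
        "by_dataset": by_dataset,
        "by_path": by_path,
        "forest_table": cells[
            ["dataset", "state", "unit", "band", "rho", "ci_low", "ci_high", "n"]
        ].copy(),
    }
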