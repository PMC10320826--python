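"""Predictive model comparison across weighting variants.

Each fitted variant is scored by its negative expected log pointwise
predictive density (-ELPD), estimated both by Pareto-smoothed leave-one-out
cross-validation (LOO) and by WAIC, per dependent measure and in total.
Lower -ELPD is better.  Differences are reported against the null
(no-weighting) variant with a standard error computed from the paired
pointwise ELPD contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .fit import FitResult
from .model import DV_NAMES

DV_LABELS = {"la": "Look-Away", "sl": "Saccadic Latency", "lt": "Looking Time"}


@dataclass(frozen=True)
class ComparisonTable:
    """Model-comparison scores in the layout of a variants x measures table."""

    frame: pd.DataFrame
    pointwise: dict[str, dict[str, np.ndarray]]  # variant -> criterion -> concatenated elpd_i

    def totals(self, criterion: str = "loo") -> pd.Series:
        sub = self.frame[self.frame["dv"] == "Total"]
        return sub.set_index("model")[f"neg_elpd_{criterion}"]

    def best(self, criterion: str = "loo") -> str:
        return str(self.totals(criterion).idxmin())


def _pointwise_elpd(result: FitResult) -> dict[str, dict[str, np.ndarray]]:
    out = {"loo": {}, "waic": {}}
    for dv in DV_NAMES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loo = az.loo(result.idata, var_name=dv, pointwise=True)
            waic = az.waic(result.idata, var_name=dv, pointwise=True)
        out["loo"][dv] = np.asarray(loo.loo_i).ravel()
        out["waic"][dv] = np.asarray(waic.waic_i).ravel()
    return out


def compare_models(fits: dict[str, FitResult]) -> ComparisonTable:
    """Score every fitted variant by -ELPD (LOO and WAIC).

    All fits must come from the same gaze table.  ``Delta`` columns are the
    improvement over the ``null`` variant (null minus model, so positive
    means better than null) with the paired-difference standard error.
    """
    hashes = {name: f.data_hash for name, f in fits.items()}
    if len(set(hashes.values())) > 1:
        raise ValueError(f"fits were run on different data: {hashes}")

    pw = {name: _pointwise_elpd(f) for name, f in fits.items()}
    concat = {
        name: {
            crit: np.concatenate([pw[name][crit][dv] for dv in DV_NAMES])
            for crit in ("loo", "waic")
        }
        for name in fits
    }

    rows = []
    for name in fits:
        for dv in DV_NAMES:
            rows.append(
                {
                    "model": name,
                    "dv": DV_LABELS[dv],
                    "neg_elpd_loo": -float(pw[name]["loo"][dv].sum()),
                    "neg_elpd_waic": -float(pw[name]["waic"][dv].sum()),
                    "delta_loo": np.nan,
                    "delta_loo_se": np.nan,
                    "delta_waic": np.nan,
                    "delta_waic_se": np.nan,
                }
            )
        row = {
            "model": name,
            "dv": "Total",
            "neg_elpd_loo": -float(concat[name]["loo"].sum()),
            "neg_elpd_waic": -float(concat[name]["waic"].sum()),
        }
        for crit in ("loo", "waic"):
            if "null" in fits:
                diff = concat[name][crit] - concat["null"][crit]
                row[f"delta_{crit}"] = float(diff.sum())
                row[f"delta_{crit}_se"] = float(
                    np.sqrt(len(diff) * diff.var(ddof=1))
                )
            else:
                row[f"delta_{crit}"] = np.nan
                row[f"delta_{crit}_se"] = np.nan
        rows.append(row)
    frame = pd.DataFrame(rows)
    return ComparisonTable(frame=frame, pointwise=concat)


def write_comparison(table: ComparisonTable, path) -> None:
    table.frame.to_csv(path, index=False)
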