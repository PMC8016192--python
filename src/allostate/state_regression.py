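"""State boundary construction and efficacy regression.

External predictions are summarized per trajectory group as the
percentage of frames classified I: TPR% for inhibitor-bound ligand
groups, FPR% for inhibitor-free groups.  Two vertical thresholds then
partition the axis:

* threshold 1 is the largest FPR% attained by at least a quorum fraction
  of the inhibitor-free groups — formally the ceil(quorum * n)-th order
  statistic of the group FPR% values, counted from below (quorum 5/8 for
  an 8-group panel, 8/11 for 11 groups);
* threshold 2 is the smallest ligand TPR% strictly above threshold 1,
  and a ligand is called I-like iff its TPR% >= threshold 2 (the
  defining point is itself I-like); if no ligand exceeds threshold 1,
  threshold 2 is undefined and nothing is I-like.

Finally, ligand TPR% is regressed by ordinary least squares against the
experimental percentage decrease of ATPase activity, and r^2 reports the
share of assay variance the predictions explain.  Inhibitor-free groups
appear in the plot table at y = 0 but never enter the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BoundarySpec", "RegressionResult", "load_inhibition_table",
    "build_boundary", "fit_linear", "run_boundary_analysis",
]


def load_inhibition_table(path: str | Path | None = None) -> pd.Series:
    """Experimental % decrease of ATPase activity per ligand id.

    Ships with the measured panel of the 11 allosteric inhibitors; a CSV
    with ``ligand_id`` and ``pct_inhibition`` columns overrides it.
    """
    if path is None:
        source = resources.files("allostate.data") / "inhibition.csv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if not {"ligand_id", "pct_inhibition"} <= set(df.columns):
        raise ValueError("inhibition table needs ligand_id and "
                         "pct_inhibition columns")
    values = df.set_index(df["ligand_id"].astype(str))["pct_inhibition"]
    if ((values < 0) | (values > 100)).any():
        raise ValueError("% inhibition values must lie in [0, 100]")
    return values


@dataclass(frozen=True)
class BoundarySpec:
    quorum: float
    threshold_1: float  # FPR% order statistic
    threshold_2: float | None  # first ligand TPR% beyond threshold_1
    i_like_ligands: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.threshold_2 is not None \
                and self.threshold_2 < self.threshold_1:
            raise ValueError("threshold_2 must be >= threshold_1")

    def as_dict(self) -> dict:
        return {"quorum": self.quorum, "threshold_1": self.threshold_1,
                "threshold_2": self.threshold_2,
                "i_like_ligands": list(self.i_like_ligands)}


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def as_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "n": self.n}


def build_boundary(fpr_groups: pd.Series | dict, tpr_ligands: pd.Series | dict,
                   quorum: float) -> BoundarySpec:
    """Two-threshold A/I boundary from group FPR% and ligand TPR% values."""
    fpr = pd.Series(fpr_groups, dtype=float)
    tpr = pd.Series(tpr_ligands, dtype=float)
    if fpr.empty or tpr.empty:
        raise ValueError("need at least one inhibitor-free group and one "
                         "ligand group")
    if not 0.0 < quorum <= 1.0:
        raise ValueError("quorum must lie in (0, 1]")
    m = math.ceil(quorum * len(fpr))
    threshold_1 = float(np.sort(fpr.to_numpy())[m - 1])
    above = tpr[tpr > threshold_1]
    if above.empty:
        return BoundarySpec(quorum, threshold_1, None, ())
    threshold_2 = float(above.min())
    i_like = tuple(sorted(str(k) for k, v in tpr.items()
                          if v >= threshold_2))
    return BoundarySpec(quorum, threshold_1, threshold_2, i_like)


def fit_linear(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the coefficient of
    determination."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in x: slope undefined")
    if np.ptp(y) == 0.0:
        raise ValueError("zero variance in y: r^2 undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2), n=len(x))


def run_boundary_analysis(group_rates: pd.DataFrame,
                         inhibition: pd.Series,
                         quorum: float) -> dict:
    """Assemble the plot table, boundary and TPR%-vs-inhibition regression.

    ``group_rates`` is the output of
    :func:`allostate.validation.aggregate_by_group` on external
    predictions.  Bound groups are placed at (TPR%, % inhibition), free
    groups at (FPR%, 0).  The regression uses ligand points only.
    """
    required = {"group_id", "state", "ligand_id", "pct_I"}
    if not required <= set(group_rates.columns):
        raise ValueError(f"group_rates needs columns {sorted(required)}")
    bound = group_rates[group_rates["state"] == "I"]
    free = group_rates[group_rates["state"] == "A"]
    inhibition = pd.Series(inhibition, dtype=float)
    inhibition.index = inhibition.index.astype(str)

    rows = []
    for _, r in bound.iterrows():
        lig = str(r["ligand_id"])
        if lig not in inhibition.index:
            raise ValueError(f"no experimental inhibition value for "
                             f"ligand {lig!r}")
        rows.append({"group_id": r["group_id"], "class": "inhibitor-bound",
                     "ligand_id": lig, "x": r["pct_I"],
                     "y": float(inhibition[lig])})
    for _, r in free.iterrows():
        rows.append({"group_id": r["group_id"], "class": "inhibitor-free",
                     "ligand_id": "none", "x": r["pct_I"], "y": 0.0})
    plot_table = pd.DataFrame(rows)

    boundary = build_boundary(
        fpr_groups=free.set_index("group_id")["pct_I"],
        tpr_ligands=bound.set_index(bound["ligand_id"].astype(str))["pct_I"],
        quorum=quorum)
    bound_points = plot_table[plot_table["class"] == "inhibitor-bound"]
    regression = fit_linear(bound_points["x"], bound_points["y"])
    return {"plot_table": plot_table, "boundary": boundary,
            "regression": regression}
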