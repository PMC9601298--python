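"""Long-format CSV reading/writing and fit-result serialization.

The on-disk panel format is one row per subject x time with columns
``subject, time, y1, y2`` followed by covariate columns. Which covariates
enter the shared predictor z and which enter the success-specific predictor
x is chosen by the caller (they may coincide, and by default they do). An
intercept column of ones is prepended to both unless disabled.

Floats are written with repr precision so that write/read round trips are
lossless and outputs are byte-identical for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult
from .model_core import (
    ModelParams,
    PanelData,
    PanelFormatError,
    SubjectData,
)

REQUIRED_COLUMNS = ("subject", "time", "y1", "y2")


def panel_from_dataframe(
    df: pd.DataFrame,
    z_cols: Sequence[str] | None = None,
    x_cols: Sequence[str] | None = None,
    intercept: bool = True,
) -> PanelData:
    """Build a validated PanelData from a long-format table.

    Defaults put every covariate column in both predictors. Duplicate
    (subject, time) rows, non-integer counts and time gaps are rejected.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise PanelFormatError(f"missing required column {col!r}")
    covariates = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    z_cols = list(z_cols) if z_cols is not None else covariates
    x_cols = list(x_cols) if x_cols is not None else covariates
    for c in z_cols + x_cols:
        if c not in df.columns:
            raise PanelFormatError(f"covariate column {c!r} not in table")

    dup = df.duplicated(subset=["subject", "time"])
    if dup.any():
        offenders = df.loc[dup, ["subject", "time"]].to_records(index=False).tolist()
        raise PanelFormatError(f"duplicate (subject, time) rows: {offenders}")
    for col in ("y1", "y2"):
        vals = df[col].to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
            raise PanelFormatError(f"column {col!r} must contain integers")

    df = df.sort_values(["subject", "time"], kind="mergesort")
    subjects = []
    for sid, block in df.groupby("subject", sort=False):
        Z = block[z_cols].to_numpy(dtype=float) if z_cols else np.empty((len(block), 0))
        X = block[x_cols].to_numpy(dtype=float) if x_cols else np.empty((len(block), 0))
        if intercept:
            ones = np.ones((len(block), 1))
            Z = np.hstack([ones, Z])
            X = np.hstack([ones, X])
        subjects.append(
            SubjectData(
                subject=sid,
                times=block["time"].to_numpy(dtype=int),
                y1=block["y1"].to_numpy(),
                y2=block["y2"].to_numpy(),
                Z=Z,
                X=X,
            )
        )
    z_names = (["intercept"] if intercept else []) + z_cols
    x_names = (["intercept"] if intercept else []) + x_cols
    return PanelData(subjects=subjects, z_names=z_names, x_names=x_names)


def read_panel(
    path: str | Path,
    z_cols: Sequence[str] | None = None,
    x_cols: Sequence[str] | None = None,
    intercept: bool = True,
) -> PanelData:
    """Read a long-format CSV panel; see :func:`panel_from_dataframe`."""
    df = pd.read_csv(path, float_precision="round_trip")
    return panel_from_dataframe(df, z_cols=z_cols, x_cols=x_cols, intercept=intercept)


def panel_to_dataframe(data: PanelData, intercept_in_covariates: bool = False) -> pd.DataFrame:
    """Flatten a PanelData back to the long-format table.

    Covariate columns are taken from the z/x design matrices; a leading
    intercept column (detected by name) is dropped unless requested, and
    columns shared by z and x are written once.
    """
    z_names = list(data.z_names or [f"z{k}" for k in range(data.q)])
    x_names = list(data.x_names or [f"x{k}" for k in range(data.p)])
    rows = []
    for s in data.subjects:
        for t_idx in range(s.T):
            row = {
                "subject": s.subject,
                "time": int(s.times[t_idx]),
                "y1": int(s.y1[t_idx]),
                "y2": int(s.y2[t_idx]),
            }
            for k, name in enumerate(z_names):
                if name == "intercept" and not intercept_in_covariates:
                    continue
                row[name] = s.Z[t_idx, k]
            for k, name in enumerate(x_names):
                if name == "intercept" and not intercept_in_covariates:
                    continue
                if name not in row:
                    row[name] = s.X[t_idx, k]
            rows.append(row)
    return pd.DataFrame(rows)


def write_panel(data: PanelData, path: str | Path) -> None:
    """Write a panel as the long-format CSV consumed by :func:`read_panel`."""
    df = panel_to_dataframe(data)
    # pandas writes float64 at full repr precision, so round trips are lossless
    df.to_csv(path, index=False)


def fit_to_dict(result: FitResult) -> dict:
    """JSON-serializable summary of a fit."""
    p = result.params
    out = {
        "gamma_names": list(result.gamma_names),
        "gamma": [float(v) for v in p.gamma],
        "alpha": [float(v) for v in p.alpha],
        "beta": [float(v) for v in p.beta],
        "se": [float(v) for v in result.se],
        "p_values": [float(v) for v in result.pvalues],
        "sigma2": float(p.sigma2),
        "tau2": [float(v) for v in p.tau2],
        "corr_structure": p.corr_structure,
        "n_iter": int(result.n_iter),
        "converged": bool(result.converged),
        "tolerance": float(result.tolerance),
    }
    if p.corr_structure == "ar1":
        out["rho"] = [float(v) for v in p.rho]
    else:
        out["R1"] = np.asarray(p.R1).tolist()
        out["R2"] = np.asarray(p.R2).tolist()
    return out


def write_fit(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(result), indent=2) + "\n")


def read_fit_params(path: str | Path) -> tuple[ModelParams, list[str]]:
    """Reload a saved fit as ModelParams (plus gamma coordinate names)."""
    d = json.loads(Path(path).read_text())
    params = ModelParams(
        alpha=np.asarray(d["alpha"], dtype=float),
        beta=np.asarray(d["beta"], dtype=float),
        sigma2=d["sigma2"],
        tau2=np.asarray(d["tau2"], dtype=float),
        rho=np.asarray(d.get("rho", [0.0, 0.0]), dtype=float),
        corr_structure=d["corr_structure"],
        R1=np.asarray(d["R1"]) if "R1" in d else None,
        R2=np.asarray(d["R2"]) if "R2" in d else None,
    )
    return params, list(d["gamma_names"])
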