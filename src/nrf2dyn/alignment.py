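"""Alignment of biological replicates onto common-scale average time courses.

Independent experiments differ by systematic multiplicative factors (cell
number, illumination).  The signal of condition i, experiment k at time t_n is
modelled as S_{i,k,n} = y_{i,n} / s_k with log-normally distributed noise of
constant standard deviation, so in log space the model is linear and the
maximum-likelihood estimates of log y and log s are an exact least-squares
solve (gauge: s of the first experiment fixed to 1).

Two experiment series measured on different overall scales (e.g. the
dose-response series and the knock-down series) are merged with a mixed
scaling-offset model S = y/s + b fitted on bridging conditions present in
both series; the offset breaks log-linearity, so that 2-parameter fit is done
by nonlinear least squares on the natural scale (gauge: b of the reference
series fixed to 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["AlignmentResult", "align_replicates", "merge_series"]


@dataclass
class AlignmentResult:
    """Aligned time courses y_{i,n}, per-experiment scalings s_k and fit stats."""

    aligned: pd.DataFrame          # columns: condition, time, value (plus observable)
    scalings: pd.Series            # experiment id -> s_k (first == 1)
    sigma: float                   # residual sd in log space
    objective: float               # sum of squared log residuals
    offsets: pd.Series | None = None  # series merge only

    def table(self) -> pd.DataFrame:
        return self.aligned.copy()


_REQUIRED = ("condition", "experiment", "time", "value")


def _check_replicates(records: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(records)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"replicate table missing columns {missing}")
    if len(df) == 0:
        raise ValueError("empty replicate table")
    vals = df["value"].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("signals must be finite and positive "
                         "(log-normal noise model)")
    return df.reset_index(drop=True)


def _align_one(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, float, float]:
    logs = np.log(df["value"].to_numpy(dtype=float))
    cond_time = pd.MultiIndex.from_frame(df[["condition", "time"]])
    y_levels = cond_time.unique()
    y_pos = {key: j for j, key in enumerate(y_levels)}
    experiments = list(pd.unique(df["experiment"]))
    s_pos = {k: j for j, k in enumerate(experiments[1:])}  # gauge: first s = 1

    n, ny, ns = len(df), len(y_levels), len(s_pos)
    A = np.zeros((n, ny + ns))
    for row, (key, exp) in enumerate(zip(cond_time, df["experiment"])):
        A[row, y_pos[key]] = 1.0
        if exp in s_pos:
            A[row, ny + s_pos[exp]] = -1.0  # log S = log y - log s
    beta, *_ = np.linalg.lstsq(A, logs, rcond=None)
    resid = logs - A @ beta
    ssr = float(resid @ resid)
    dof = max(n - (ny + ns), 1)
    sigma = float(np.sqrt(ssr / dof)) if n > ny + ns else 0.0

    aligned = pd.DataFrame({
        "condition": [k[0] for k in y_levels],
        "time": [k[1] for k in y_levels],
        "value": np.exp(beta[:ny]),
    })
    s_vals = np.concatenate([[1.0], np.exp(beta[ny:])])
    scalings = pd.Series(s_vals, index=pd.Index(experiments, name="experiment"),
                         name="s")
    return aligned, scalings, sigma, ssr


def align_replicates(records: pd.DataFrame) -> AlignmentResult:
    """ML alignment of replicate signals under the scaling model S = y/s.

    If an ``observable`` column is present, each target is aligned separately
    (its own scalings and noise level) and the results are concatenated.
    """
    df = _check_replicates(records)
    if "observable" in df.columns:
        parts, scal_parts, ssrs, sig_parts = [], [], [], []
        for obs, grp in df.groupby("observable", sort=False):
            a, s, sigma, ssr = _align_one(grp)
            a.insert(0, "observable", obs)
            s.index = pd.MultiIndex.from_product([[obs], s.index],
                                                 names=["observable", "experiment"])
            parts.append(a)
            scal_parts.append(s)
            ssrs.append(ssr)
            sig_parts.append(sigma)
        aligned = pd.concat(parts, ignore_index=True)
        scalings = pd.concat(scal_parts)
        return AlignmentResult(aligned=aligned, scalings=scalings,
                               sigma=float(np.mean(sig_parts)),
                               objective=float(np.sum(ssrs)))
    aligned, scalings, sigma, ssr = _align_one(df)
    return AlignmentResult(aligned=aligned, scalings=scalings, sigma=sigma,
                           objective=ssr)


def merge_series(series_a: AlignmentResult, series_b: AlignmentResult,
                 bridge_conditions: list | None = None,
                 require_positive: bool = True) -> AlignmentResult:
    """Put series B on series A's scale via the mixed model y_B = y_A/s + b.

    The scaling s and systematic offset b are estimated from conditions
    present in both series (at shared times); B's aligned values are then
    transformed as y_common = s * (y_B - b) and concatenated with A's.
    """
    a, b = series_a.aligned, series_b.aligned
    keys = [c for c in ("observable", "condition", "time") if c in a.columns
            and c in b.columns]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    if bridge_conditions is not None:
        merged = merged[merged["condition"].isin(bridge_conditions)]
    if len(merged) == 0:
        raise ValueError("no bridging condition shared between the two series")

    ya = merged["value_a"].to_numpy(dtype=float)
    yb = merged["value_b"].to_numpy(dtype=float)

    def resid(theta):
        s, off = theta
        return yb - (ya / s + off)

    s0 = float(np.mean(ya) / np.mean(yb)) if np.mean(yb) > 0 else 1.0
    fit = least_squares(resid, x0=[max(s0, 1e-6), 0.0], method="trf",
                        bounds=([1e-9, -np.inf], [np.inf, np.inf]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    s_hat, b_hat = fit.x

    b_common = b.copy()
    b_common["value"] = s_hat * (b_common["value"] - b_hat)
    if require_positive and (b_common["value"] <= 0).any():
        raise ValueError("merged series has non-positive values; offset model "
                         "inconsistent with the data")
    combined = pd.concat([a.assign(series="A"), b_common.assign(series="B")],
                         ignore_index=True)
    ssr = float(np.sum(fit.fun**2))
    return AlignmentResult(
        aligned=combined,
        scalings=pd.Series({"A": 1.0, "B": float(s_hat)}, name="s"),
        sigma=float(np.sqrt(ssr / max(len(merged) - 2, 1))),
        objective=ssr,
        offsets=pd.Series({"A": 0.0, "B": float(b_hat)}, name="b"),
    )
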