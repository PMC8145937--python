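"""Non-compartmental analysis of single-dose concentration profiles.

AUClast uses the linear-up/log-down rule: linear trapezoids for
ascending segments (and any segment touching a zero concentration), log
trapezoids ``(C1 - C2)/ln(C1/C2) * dt`` for strictly descending positive
segments.  The terminal slope is fitted by log-linear regression over
candidate tails chosen by best adjusted R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NCAResult", "NCAError", "compute_nca", "nca_table"]


class NCAError(ValueError):
    """Profile unsuitable for non-compartmental analysis."""


@dataclass(frozen=True)
class NCAResult:
    cmax: float                     # ug/L
    tmax: float                     # h
    auc_last: float                 # ug*h/L
    lambda_z: float | None = None   # 1/h
    t_half: float | None = None     # h
    lambda_z_npoints: int = 0
    lambda_z_r2adj: float = float("nan")


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    c1, c2 = c[:-1], c[1:]
    dt = np.diff(t)
    use_log = (c2 < c1) & (c1 > 0) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c1 - c2) / np.log(np.where(use_log, c1 / c2, np.e)) * dt
    lin_seg = 0.5 * (c1 + c2) * dt
    return float(np.sum(np.where(use_log, log_seg, lin_seg)))


def _fit_lambda_z(t: np.ndarray, c: np.ndarray, tmax: float):
    """Best-adjusted-R2 log-linear terminal fit on >= 3 points after tmax.

    Ties within 1e-4 in adjusted R2 prefer the longer tail (the common
    best-fit convention).  Returns (lambda_z, n_points, r2_adj) or
    (None, 0, nan) when no valid fit exists.
    """
    mask = (t > tmax) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    best = (None, 0, float("nan"))
    m = tt.size
    for k in range(m, 2, -1):  # longest tail first
        x, y = tt[-k:], cc[-k:]
        sx = x - x.mean()
        sxx = float(sx @ sx)
        if sxx == 0.0:
            continue
        slope = float(sx @ (y - y.mean())) / sxx
        if slope >= 0.0:
            continue
        resid = (y - y.mean()) - slope * sx
        sst = float((y - y.mean()) @ (y - y.mean()))
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
        r2adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best[0] is None or r2adj > best[2] + 1e-4:
            best = (-slope, k, r2adj)
    return best


def compute_nca(times, conc, blq=None, *,
                estimate_lambda_z: bool = True) -> NCAResult:
    """Non-compartmental summary of one concentration-time profile.

    Parameters
    ----------
    times, conc : sampling times (h, ascending) and concentrations (ug/L).
    blq : optional boolean flags; flagged records are excluded, except
        that a flagged pre-dose zero at the first time point is kept as
        the AUC origin.
    estimate_lambda_z : skip the terminal-slope fit when False (the
        optional fields are then absent).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape:
        raise NCAError("times and conc must have the same length")
    if np.any(np.diff(t) <= 0):
        raise NCAError("times must be strictly ascending")
    if blq is not None:
        keep = ~np.asarray(blq, dtype=bool)
        keep[0] = keep[0] or c[0] == 0.0  # pre-dose zero anchors the AUC
        t, c = t[keep], c[keep]
    if t.size < 3:
        raise NCAError("need at least 3 non-missing concentrations")
    if np.all(c == 0.0):
        raise NCAError("all concentrations are zero; NCA undefined")

    imax = int(np.argmax(c))  # argmax returns the first of tied maxima
    cmax, tmax = float(c[imax]), float(t[imax])
    auc = _auc_lin_up_log_down(t, c)

    lz, npts, r2 = (None, 0, float("nan"))
    if estimate_lambda_z:
        lz, npts, r2 = _fit_lambda_z(t, c, tmax)
    t_half = float(np.log(2.0) / lz) if lz else None
    return NCAResult(cmax=cmax, tmax=tmax, auc_last=auc, lambda_z=lz,
                     t_half=t_half, lambda_z_npoints=npts,
                     lambda_z_r2adj=r2)


def nca_table(df: pd.DataFrame, *,
              estimate_lambda_z: bool = True) -> pd.DataFrame:
    """Per subject x period NCA of a concentration dataset.

    ``df`` uses the dataset dialect (SUBJ, SEQ, PERIOD, TRT, DOSE, TIME,
    DV, BLQ).  Returns one row per profile with the NCAResult columns.
    """
    rows = []
    for (subj, period), g in df.groupby(["SUBJ", "PERIOD"], sort=True):
        g = g.sort_values("TIME")
        res = compute_nca(g["TIME"].to_numpy(), g["DV"].to_numpy(),
                          blq=g["BLQ"].to_numpy(),
                          estimate_lambda_z=estimate_lambda_z)
        rows.append({
            "SUBJ": subj, "SEQ": g["SEQ"].iloc[0], "PERIOD": period,
            "TRT": g["TRT"].iloc[0], "DOSE": g["DOSE"].iloc[0],
            "CMAX": res.cmax, "TMAX": res.tmax, "AUCLAST": res.auc_last,
            "LAMBDA_Z": res.lambda_z, "THALF": res.t_half,
            "LZ_NPOINTS": res.lambda_z_npoints,
            "LZ_R2ADJ": res.lambda_z_r2adj,
        })
    return pd.DataFrame(rows)
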