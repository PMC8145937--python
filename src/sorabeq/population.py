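"""Synthetic concentration-data generator.

Emulates the single-dose healthy-volunteer study: log-normal IIV on
ka/CL/V, IOV on CL redrawn each period, treatment-specific relative
bioavailability for the test formulation, and proportional (optionally
additive) residual error.  Supports the study's replicated two-period
parallel-arm design and simulated 2x2 crossover bioequivalence trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import simulate_profiles
from .params import LLOQ, PROTOCOL_TIMES, StructuralParams, VariabilityParams

__all__ = [
    "Treatment", "TrialDesign", "ConcDataset",
    "study_design", "crossover_design", "sequence_assignment",
    "draw_subjects", "simulate_dataset",
]


@dataclass(frozen=True)
class Treatment:
    label: str
    dose: float          # mg
    is_test: bool        # test arms get the f_rel bioavailability multiplier


@dataclass(frozen=True)
class TrialDesign:
    """Design grid for a simulated study.

    ``replicated_two_period``: each subject receives the same treatment in
    both periods; subjects are split evenly over the treatment arms.
    ``crossover_2x2``: two treatments (one test, one reference); the first
    half of subjects follows sequence RT, the second half TR.
    """

    design_kind: str                       # replicated_two_period | crossover_2x2
    treatments: tuple[Treatment, ...]
    n_subjects: int
    sampling_times: tuple[float, ...] = PROTOCOL_TIMES
    n_periods: int = 2

    def validate(self) -> None:
        problems = []
        if self.design_kind not in ("replicated_two_period", "crossover_2x2"):
            problems.append(f"unknown design_kind {self.design_kind!r}")
        if self.n_subjects < 2:
            problems.append("n_subjects must be >= 2")
        if self.design_kind == "crossover_2x2":
            if len(self.treatments) != 2:
                problems.append("crossover_2x2 needs exactly 2 treatments")
            elif sorted(t.is_test for t in self.treatments) != [False, True]:
                problems.append("crossover_2x2 needs one test and one "
                                "reference treatment")
            if self.n_subjects % 2:
                problems.append("n_subjects must be even for a balanced 2x2")
        if self.design_kind == "replicated_two_period" and \
                self.n_subjects % max(len(self.treatments), 1):
            problems.append("n_subjects must be a multiple of the number of "
                            "treatment arms")
        times = np.asarray(self.sampling_times)
        if times.size < 3 or np.any(np.diff(times) <= 0) or times[0] < 0:
            problems.append("sampling_times must be >= 3 ascending times")
        if self.n_periods != 2:
            problems.append("only two-period designs are supported")
        if problems:
            raise ValueError("invalid design: " + "; ".join(problems))


def study_design(n_subjects: int = 32,
                 sampling_times: Sequence[float] = PROTOCOL_TIMES,
                 ) -> TrialDesign:
    """The four-arm replicated two-period study design."""
    return TrialDesign(
        design_kind="replicated_two_period",
        treatments=(
            Treatment("SYO-1644 100", 100.0, True),
            Treatment("SYO-1644 150", 150.0, True),
            Treatment("SYO-1644 200", 200.0, True),
            Treatment("Nexavar 200", 200.0, False),
        ),
        n_subjects=n_subjects,
        sampling_times=tuple(sampling_times),
    )


def crossover_design(dose_test: float, n_subjects: int,
                     dose_ref: float = 200.0,
                     sampling_times: Sequence[float] = PROTOCOL_TIMES,
                     ) -> TrialDesign:
    """A balanced 2x2 crossover: test formulation vs reference 200 mg."""
    return TrialDesign(
        design_kind="crossover_2x2",
        treatments=(
            Treatment("SYO-1644", dose_test, True),
            Treatment("Nexavar", dose_ref, False),
        ),
        n_subjects=n_subjects,
        sampling_times=tuple(sampling_times),
    )


def sequence_assignment(design: TrialDesign):
    """Deterministic treatment allocation.

    Returns (sequence labels (n,), treatment index matrix (n, 2)) where
    the matrix entries index ``design.treatments``.
    """
    n = design.n_subjects
    trt_idx = np.empty((n, design.n_periods), dtype=int)
    seq = np.empty(n, dtype=object)
    if design.design_kind == "crossover_2x2":
        i_test = next(i for i, t in enumerate(design.treatments) if t.is_test)
        i_ref = 1 - i_test
        half = n // 2
        trt_idx[:half] = [i_ref, i_test]   # sequence RT
        trt_idx[half:] = [i_test, i_ref]   # sequence TR
        seq[:half] = "RT"
        seq[half:] = "TR"
    else:
        per_arm = n // len(design.treatments)
        for i in range(n):
            arm = min(i // per_arm, len(design.treatments) - 1)
            trt_idx[i] = arm
            seq[i] = design.treatments[arm].label
    return seq, trt_idx


@dataclass
class ConcDataset:
    """Concentration records plus provenance metadata.

    ``df`` columns: SUBJ, SEQ, PERIOD, TRT, DOSE, TIME, DV (ug/L), BLQ.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)


def draw_subjects(p: StructuralParams, v: VariabilityParams, n_subjects: int,
                  n_occasions: int, rng: np.random.Generator) -> dict:
    """Sample individual parameters for ``n_subjects`` subjects.

    ka_i = ka*exp(eta_ka); V_i = V*exp(eta_V);
    CL_i,occ = CL*exp(eta_CL + kappa_occ) with kappa drawn independently
    per occasion.  Draw order (ka, CL, V, kappa) is part of the
    reproducibility contract.
    """
    eta_ka = rng.normal(0.0, v.omega_ka, n_subjects)
    eta_cl = rng.normal(0.0, v.omega_cl, n_subjects)
    eta_v = rng.normal(0.0, v.omega_v, n_subjects)
    kappa = rng.normal(0.0, v.omega_iov_cl, (n_subjects, n_occasions))
    return {
        "ka": p.ka * np.exp(eta_ka),
        "cl": p.cl * np.exp(eta_cl[:, None] + kappa),
        "v": p.v * np.exp(eta_v),
    }


def _seed_streams(seed):
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    params_ss, resid_ss = ss.spawn(2)
    return np.random.default_rng(params_ss), np.random.default_rng(resid_ss)


def simulate_dataset(design: TrialDesign, p: StructuralParams,
                     v: VariabilityParams, seed,
                     censor_lloq: bool = False, lloq: float = LLOQ,
                     rtol: float = 1e-7, atol: float = 1e-9) -> ConcDataset:
    """Simulate one dataset under ``design``.

    Observed concentrations are ``pred*(1+eps_prop) + eps_add`` truncated
    at zero.  With ``censor_lloq`` the BLQ flag marks values below the
    assay limit (default off: simulated bioequivalence trials analyse the
    uncensored values).
    """
    design.validate()
    n, n_per = design.n_subjects, design.n_periods
    times = np.asarray(design.sampling_times)
    nt = times.size
    rng_params, rng_resid = _seed_streams(seed)

    seq, trt_idx = sequence_assignment(design)
    ind = draw_subjects(p, v, n, n_per, rng_params)

    doses = np.array([t.dose for t in design.treatments])
    fmult = np.array([p.f_rel if t.is_test else 1.0
                      for t in design.treatments])
    dose_f = (doses * fmult)[trt_idx]              # (n, n_per)
    ka_sp = np.repeat(ind["ka"][:, None], n_per, axis=1)
    v_sp = np.repeat(ind["v"][:, None], n_per, axis=1)

    pred = simulate_profiles(dose_f.ravel(), ka_sp.ravel(),
                             ind["cl"].ravel(), v_sp.ravel(), times, p,
                             rtol=rtol, atol=atol)
    pred = pred.reshape(n, n_per, nt)

    eps = rng_resid.normal(0.0, v.sigma_prop_sd, (n, n_per, nt))
    obs = pred * (1.0 + eps)
    if v.sigma_add > 0:
        obs = obs + rng_resid.normal(0.0, v.sigma_add, (n, n_per, nt))
    obs = np.maximum(obs, 0.0)

    blq = (obs < lloq) if censor_lloq else np.zeros_like(obs, dtype=bool)

    subj = np.arange(1, n + 1)
    df = pd.DataFrame({
        "SUBJ": np.repeat(subj, n_per * nt),
        "SEQ": np.repeat(seq, n_per * nt),
        "PERIOD": np.tile(np.repeat(np.arange(1, n_per + 1), nt), n),
        "TRT": np.array([design.treatments[k].label
                         for k in trt_idx.ravel()]).repeat(nt),
        "DOSE": doses[trt_idx].ravel().repeat(nt),
        "TIME": np.tile(times, n * n_per),
        "DV": obs.ravel(),
        "BLQ": blq.ravel(),
    })
    meta = {
        "design_kind": design.design_kind,
        "n_subjects": n,
        "treatments": [asdict(t) for t in design.treatments],
        "censor_lloq": bool(censor_lloq),
        "lloq": float(lloq),
        "structural": asdict(p),
        "variability": asdict(v),
        "seed": repr(seed),
    }
    return ConcDataset(df=df, meta=meta)
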