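"""Maximum-likelihood fitting of the uncertainty model and diagnostics.

Observed repeatability values R12_i are treated as independent zero-mean
Gaussians whose standard deviations eps_i = eps_R12(pair_i; theta) come
from the error model, giving (constants dropped)

    NLL(theta) = sum_i [ ln eps_i + R12_i^2 / (2 eps_i^2) ].

Fitting minimises the NLL over the variant's free parameters in
log-space (positivity by construction) from multiple seeded starts.
Motion-flagged records are excluded from fitting by default — motion is
not a fixed, modellable error — but retained for evaluation and
standardisation.

Goodness of fit uses chi^2 = sum z_i^2 with z_i = R12_i / eps_i and
dof equal to the number of records evaluated (the convention used when
quoting chi^2 against a subset of the cohort); the model is "accepted"
when the upper-tail probability exceeds 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .error_model import (FREE_PARAMS, ErrorModelParams, model_uncertainty)
from .io import InsufficientDataError, RepeatabilityRecord
from .metrics import GroupSummary, group_summary

#: seeded multi-start ranges (log-uniform) for each free parameter
_START_RANGES = {
    "beta": (0.3, 30.0),
    "sigma_fix": (1.0, 500.0),
    "epsilon_sys": (0.2, 30.0),
}

_NLL_TOL = 1e-8


@dataclass
class FitResult:
    """Outcome of an MLE fit."""

    params: ErrorModelParams
    neg_log_likelihood: float
    n_records_used: int
    n_excluded_motion: int
    converged: bool
    n_starts: int
    seed: int
    start_nlls: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(neg_log_likelihood=self.neg_log_likelihood,
                 n_records_used=self.n_records_used,
                 n_excluded_motion=self.n_excluded_motion,
                 converged=self.converged, n_starts=self.n_starts,
                 seed=self.seed, start_nlls=self.start_nlls)
        return d


@dataclass(frozen=True)
class GOFResult:
    """Chi-squared goodness-of-fit summary."""

    chi2: float
    dof: int
    p_value: float

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not (0 <= self.p_value <= 1):
            raise ValueError("invalid GOF values")

    @property
    def accepted(self) -> bool:
        """Model accepted at the 5% level (p > 0.05)."""
        return self.p_value > 0.05

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "dof": self.dof,
                "p_value": self.p_value, "accepted": self.accepted}


def _record_arrays(records: Sequence[RepeatabilityRecord]):
    """Column arrays (d1, d2, w1, w2, n1, n2, r12, motion) for vector math."""
    p = [r.pair for r in records]
    return (np.array([q.roi_1.mean_adc for q in p]),
            np.array([q.roi_2.mean_adc for q in p]),
            np.array([q.roi_1.adc_sd for q in p]),
            np.array([q.roi_2.adc_sd for q in p]),
            np.array([q.roi_1.n_voxels for q in p], dtype=float),
            np.array([q.roi_2.n_voxels for q in p], dtype=float),
            np.array([r.r12 for r in records]),
            np.array([r.motion for r in records], dtype=bool))


def _eps(arrays, params: ErrorModelParams) -> np.ndarray:
    d1, d2, w1, w2, n1, n2, _, _ = arrays
    return np.atleast_1d(model_uncertainty(d1, d2, w1, w2, n1, n2, params))


def negative_log_likelihood(records: Sequence[RepeatabilityRecord],
                            params: ErrorModelParams) -> float:
    """sum_i [ln eps_i + r_i^2 / (2 eps_i^2)], additive constants dropped."""
    arrays = _record_arrays(list(records))
    eps = _eps(arrays, params)
    if np.any(eps <= 0):
        raise ValueError("model uncertainty must be > 0 for every record")
    r12 = arrays[6]
    return float(np.sum(np.log(eps) + r12**2 / (2.0 * eps**2)))


def fit_mle(records: Iterable[RepeatabilityRecord], *,
            variant: str = "three_param", exclude_motion: bool = True,
            seed: int = 0, n_starts: int = 8) -> FitResult:
    """Fit the error model to repeatability records by maximum likelihood.

    Optimisation runs in log-parameter space (positivity enforced) with
    ``n_starts`` seeded log-uniform starts plus a moment-based start;
    each start is minimised with Nelder-Mead and the best optimum is
    polished.  Ties (NLL within tolerance) break toward the smallest
    parameter-vector norm.  Reproducible given (records, seed).
    """
    records = list(records)
    n_motion = sum(r.motion for r in records)
    if exclude_motion:
        records = [r for r in records if not r.motion]
    free = FREE_PARAMS[variant]
    if len(records) < len(free) + 1:
        raise InsufficientDataError(
            f"{len(records)} usable records for {len(free)} parameters")
    arrays = _record_arrays(records)
    r12 = arrays[6]

    def nll_log(x: np.ndarray) -> float:
        params = ErrorModelParams.from_free(variant, np.exp(x))
        eps = _eps(arrays, params)
        return float(np.sum(np.log(eps) + r12**2 / (2.0 * eps**2)))

    rng = np.random.default_rng(seed)
    starts = []
    # moment-based start: all spread attributed to eps_sys, beta ~ 1
    rms = float(np.sqrt(np.mean(r12**2)))
    moment = {"beta": 1.0, "sigma_fix": 10.0, "epsilon_sys": max(rms, 1e-3)}
    starts.append(np.log([moment[k] for k in free]))
    for _ in range(max(n_starts - 1, 1)):
        lo = np.log([_START_RANGES[k][0] for k in free])
        hi = np.log([_START_RANGES[k][1] for k in free])
        starts.append(rng.uniform(lo, hi))

    candidates = []
    start_nlls = []
    for x0 in starts:
        res = optimize.minimize(nll_log, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": _NLL_TOL,
                                         "maxiter": 4000, "maxfev": 4000})
        start_nlls.append(float(res.fun))
        candidates.append((float(res.fun), res.x, bool(res.success)))
    best_nll = min(c[0] for c in candidates)
    # tie-break: among near-optimal starts take the smallest parameter norm
    near = [c for c in candidates if c[0] <= best_nll + 10 * _NLL_TOL]
    near.sort(key=lambda c: float(np.linalg.norm(np.exp(c[1]))))
    fun, x, success = near[0]
    polish = optimize.minimize(nll_log, x, method="BFGS",
                               options={"gtol": 1e-10, "maxiter": 500})
    if polish.fun <= fun:
        fun, x, success = float(polish.fun), polish.x, True
    if not any(c[2] for c in candidates) and not success:
        raise RuntimeError(
            f"no optimizer start converged (best NLL {best_nll:.6g}; "
            f"trace {start_nlls})")
    params = ErrorModelParams.from_free(variant, np.exp(x))
    return FitResult(params=params, neg_log_likelihood=float(fun),
                     n_records_used=len(records),
                     n_excluded_motion=n_motion, converged=True,
                     n_starts=len(starts), seed=seed,
                     start_nlls=start_nlls)


def chi_squared_gof(records: Sequence[RepeatabilityRecord],
                    params: ErrorModelParams,
                    subset: str | Callable | None = None) -> GOFResult:
    """Chi-squared of standardised residuals over a record subset.

    ``subset`` may be an ROI-kind name, a predicate on records, or None
    (all records).  dof equals the subset size (not reduced by the
    fitted-parameter count).
    """
    records = list(records)
    if isinstance(subset, str):
        kind = subset
        records = [r for r in records if r.pair.roi_kind == kind]
    elif callable(subset):
        records = [r for r in records if subset(r)]
    if not records:
        raise InsufficientDataError("empty subset")
    arrays = _record_arrays(records)
    eps = _eps(arrays, params)
    if np.any(eps <= 0):
        raise ValueError("model uncertainty must be > 0 for every record")
    chi2 = float(np.sum((arrays[6] / eps) ** 2))
    dof = len(records)
    return GOFResult(chi2=chi2, dof=dof,
                     p_value=float(stats.chi2.sf(chi2, dof)))


def standardise(records: Sequence[RepeatabilityRecord],
                params: ErrorModelParams, *, ddof: int = 0
                ) -> tuple[list[RepeatabilityRecord], GroupSummary]:
    """Populate z = R12 / eps_R12 and summarise the z distribution.

    Motion-flagged records are standardised too (they stay flagged); the
    group width is 1.96 x SD(z), the same convention as for raw R12, so
    raw and standardised reproducibility are directly comparable.
    """
    records = list(records)
    arrays = _record_arrays(records)
    eps = _eps(arrays, params)
    if np.any(eps <= 0):
        raise ValueError("model uncertainty must be > 0 for every record")
    out = [rec.with_uncertainty(float(e)) for rec, e in zip(records, eps)]
    summary = group_summary([r.z for r in out], ddof=ddof)
    return out, summary
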