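"""The measurement-uncertainty model for ADC repeatability.

The uncertainty of a repeatability value R12 due to statistical errors
sigma_D1, sigma_D2 on the two session means follows from first-order
error propagation:

    eps(s1, s2) = 400 * sqrt(D1^2 s2^2 + D2^2 s1^2) / (D1 + D2)^2   [%]

Three error sources are combined in quadrature into the predicted
uncertainty of an observed pair:

    eps_R12^2 = beta^2 * eps(sem1, sem2)^2
              + eps(sigma_fix/sqrt(N1), sigma_fix/sqrt(N2))^2
              + eps_sys^2

where sem_j = w_j / sqrt(N_j) is the standard error of the ROI mean from
the ADC histogram width w_j; beta is a dimensionless inflation of that
histogram-derived term (spatially correlated noise, heterogeneity);
sigma_fix is a fixed per-voxel fitting dispersion, entering through its
contribution sigma_fix/sqrt(N_j) to each session's mean-ADC error; and
eps_sys is the irreducible systematic (scanner) error in percent.

Nested variants: ``sys_only`` (eps_sys alone), ``two_param`` (beta and
eps_sys) and the full ``three_param`` model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import TestRetestPair

VARIANTS = ("sys_only", "two_param", "three_param")

#: free parameter names per nested variant
FREE_PARAMS = {
    "sys_only": ("epsilon_sys",),
    "two_param": ("beta", "epsilon_sys"),
    "three_param": ("beta", "sigma_fix", "epsilon_sys"),
}


@dataclass(frozen=True)
class ErrorModelParams:
    """Parameters (beta, sigma_fix, eps_sys) of the uncertainty model.

    ``sigma_fix`` is in 10^-5 mm^2/s, ``epsilon_sys`` in percent, ``beta``
    dimensionless.  The ``variant`` tag pins parameters that the nested
    sub-models hold at zero.
    """

    beta: float
    sigma_fix: float
    epsilon_sys: float
    variant: str = "three_param"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if min(self.beta, self.sigma_fix, self.epsilon_sys) < 0:
            raise ValueError("parameters must be >= 0")
        if self.variant == "sys_only" and (self.beta or self.sigma_fix):
            raise ValueError("sys_only forces beta = sigma_fix = 0")
        if self.variant == "two_param" and self.sigma_fix:
            raise ValueError("two_param forces sigma_fix = 0")

    @property
    def free_names(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.variant]

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.free_names])

    @classmethod
    def from_free(cls, variant: str,
                  values: Sequence[float]) -> "ErrorModelParams":
        base = {"beta": 0.0, "sigma_fix": 0.0, "epsilon_sys": 0.0}
        for name, v in zip(FREE_PARAMS[variant], values, strict=True):
            base[name] = float(v)
        return cls(variant=variant, **base)

    def to_dict(self) -> dict:
        return {"beta": self.beta, "sigma_fix": self.sigma_fix,
                "epsilon_sys": self.epsilon_sys, "variant": self.variant}

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorModelParams":
        return cls(beta=float(d["beta"]), sigma_fix=float(d["sigma_fix"]),
                   epsilon_sys=float(d["epsilon_sys"]),
                   variant=d.get("variant", "three_param"))


def propagate(d1, d2, s1, s2):
    """Propagated uncertainty (percent) of R12 from session-mean errors.

    Literal evaluation of 400 sqrt(d1^2 s2^2 + d2^2 s1^2) / (d1 + d2)^2.
    Homogeneous of degree zero: scaling all four arguments by c leaves
    the result unchanged.  Accepts scalars or arrays.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    denom = d1 + d2
    if np.any(denom <= 0):
        raise ValueError("d1 + d2 must be > 0")
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("uncertainties must be >= 0")
    out = 400.0 * np.sqrt(d1**2 * s2**2 + d2**2 * s1**2) / denom**2
    return out if out.ndim else float(out)


def model_uncertainty(d1, d2, w1, w2, n1, n2,
                      params: ErrorModelParams):
    """Vectorised eps_R12 (percent) from raw pair quantities.

    ``w`` are ADC histogram SDs, ``n`` voxel counts; sem_j = w_j/sqrt(n_j)
    and the sigma_fix term contributes sigma_fix/sqrt(n_j) per session.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    sem1 = np.asarray(w1, dtype=float) / np.sqrt(n1)
    sem2 = np.asarray(w2, dtype=float) / np.sqrt(n2)
    term_w = params.beta * propagate(d1, d2, sem1, sem2)
    term_fix = propagate(d1, d2, params.sigma_fix / np.sqrt(n1),
                         params.sigma_fix / np.sqrt(n2))
    total = np.sqrt(np.asarray(term_w)**2 + np.asarray(term_fix)**2
                    + params.epsilon_sys**2)
    return total if total.ndim else float(total)


def total_uncertainty(pair: TestRetestPair,
                      params: ErrorModelParams) -> float:
    """Predicted uncertainty (percent) of a pair's R12 under the model.

    Raises if every term is zero (standardisation would divide by zero).
    """
    eps = model_uncertainty(pair.roi_1.mean_adc, pair.roi_2.mean_adc,
                            pair.roi_1.adc_sd, pair.roi_2.adc_sd,
                            pair.roi_1.n_voxels, pair.roi_2.n_voxels,
                            params)
    if not eps > 0:
        raise ValueError("all model terms are zero: uncertainty undefined")
    return float(eps)


@dataclass
class LookupGrid:
    """eps_R12 (percent) tabulated over ROI size and histogram width.

    Rows follow ``n_voxels`` (log-spaced ROI sizes), columns ``sd_values``
    (ADC histogram SDs in 10^-5 mm^2/s); each cell is the model
    uncertainty of a symmetric pair at the nominal ADC level
    ``d_nominal``.
    """

    n_voxels: np.ndarray
    sd_values: np.ndarray
    cells: np.ndarray
    d_nominal: float
    params: ErrorModelParams

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.cells, index=self.n_voxels,
                            columns=self.sd_values)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "n_voxels"
        df.columns.name = "adc_sd"
        df.to_csv(path)

    def plot(self, path=None):
        """Iso-SD uncertainty curves vs ROI size (log x-axis)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for j, sd in enumerate(self.sd_values):
            ax.plot(self.n_voxels, self.cells[:, j], label=f"SD={sd:g}")
        ax.set_xscale("log")
        ax.set_xlabel("ROI size (voxels)")
        ax.set_ylabel(r"$\epsilon_{R12}$ (%)")
        ax.set_title(f"Uncertainty look-up (D={self.d_nominal:g})")
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def build_lookup(params: ErrorModelParams, n_grid, sd_grid,
                 d_nominal: float = 109.0) -> LookupGrid:
    """Tabulate the model uncertainty for symmetric pairs on a grid.

    Each cell equals ``model_uncertainty`` for D1 = D2 = d_nominal,
    N1 = N2 = N and w1 = w2 = SD.  Cells strictly decrease with N at
    fixed SD (whenever beta or sigma_fix is non-zero) and are
    non-decreasing with SD at fixed N.
    """
    n_grid = np.asarray(n_grid, dtype=float)
    sd_grid = np.asarray(sd_grid, dtype=float)
    if n_grid.size == 0 or sd_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(n_grid <= 0) or np.any(sd_grid < 0) or not d_nominal > 0:
        raise ValueError("grid values must be positive")
    nn, ss = np.meshgrid(n_grid, sd_grid, indexing="ij")
    cells = model_uncertainty(d_nominal, d_nominal, ss, ss, nn, nn, params)
    return LookupGrid(n_voxels=n_grid, sd_values=sd_grid,
                      cells=np.asarray(cells), d_nominal=float(d_nominal),
                      params=params)


def default_lookup_grid(params: ErrorModelParams,
                        d_nominal: float = 109.0) -> LookupGrid:
    """Look-up chart over the study's plotted ranges (50..20000 voxels,
    SD 5..100)."""
    n_grid = np.geomspace(50, 20000, 25)
    sd_grid = np.array([5, 10, 20, 30, 40, 50, 75, 100], dtype=float)
    return build_lookup(params, n_grid, sd_grid, d_nominal)
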