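"""Dissociation constants from chemical-shift-perturbation titrations.

Peak movements in fast exchange report the bound fraction of the
protein directly: the observed combined shift change is the saturation
shift difference scaled by the exactly computed (quadratic, ligand
depletion included) single-site bound fraction.  One K_D is shared by
all residues in a global fit; per-residue saturation amplitudes are
nuisance parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy import optimize

from .constants import DEFAULT_R_SCALE
from .types import TitrationSeries

__all__ = [
    "BindingFit",
    "combined_shift",
    "binding_isotherm",
    "fit_kd_global",
]


@dataclass
class BindingFit:
    """Global single-site binding fit across residues."""

    K_D: float                            # mM
    K_D_se: float
    per_residue_dsat: Dict[str, float]    # combined ppm at saturation
    included_residues: Set[str]
    excluded_residues: Dict[str, str]     # residue -> reason
    chi2: float
    n_data: int
    kd_at_bound: bool = False

    def __post_init__(self) -> None:
        if self.K_D <= 0:
            raise ValueError("K_D must be positive")


def combined_shift(
    d_H: Union[float, np.ndarray],
    d_N: Union[float, np.ndarray],
    r_scale: float = DEFAULT_R_SCALE,
) -> Union[float, np.ndarray]:
    """Combined 1H/15N chemical-shift distance
    ``sqrt(dH^2 + (dN / r_scale)^2)`` in ppm."""
    if r_scale <= 0:
        raise ValueError("r_scale must be positive")
    return np.sqrt(np.square(d_H) + np.square(np.asarray(d_N) / r_scale))


def binding_isotherm(
    L_tot: Union[float, np.ndarray],
    P_tot: float,
    K_D: float,
) -> Union[float, np.ndarray]:
    """Bound fraction of the protein for total ligand/protein
    concentrations, from the exact single-site quadratic

    ``((L + P + K_D) - sqrt((L + P + K_D)^2 - 4 L P)) / (2 P)``.
    """
    if P_tot <= 0:
        raise ValueError("protein concentration must be positive")
    if K_D < 0:
        raise ValueError("K_D must be >= 0")
    L = np.asarray(L_tot, dtype=float)
    s = L + P_tot + K_D
    disc = np.maximum(s * s - 4.0 * L * P_tot, 0.0)
    out = (s - np.sqrt(disc)) / (2.0 * P_tot)
    return float(out) if np.ndim(L_tot) == 0 else out


def _series_dshift(series: TitrationSeries,
                   r_scale: float) -> np.ndarray:
    """Combined shift change relative to the apo point, per concentration."""
    d = series.positions - series.positions[0]
    return np.asarray(combined_shift(d[:, 0], d[:, 1], r_scale))


def fit_kd_global(
    series: Sequence[TitrationSeries],
    threshold: float = 0.035,
    r_scale: float = DEFAULT_R_SCALE,
    kd_max: float = 1000.0,
) -> BindingFit:
    """Global fit of one K_D and per-residue saturation shifts.

    Residues whose maximal combined shift change stays below
    ``threshold`` (ppm) are excluded.  Standard errors come from the
    covariance matrix of the global fit; a K_D pinned at ``kd_max`` is
    flagged as poorly constrained.
    """
    if not series:
        raise ValueError("no titration series provided")
    n_conc = {s.ligand_concentrations.size for s in series}
    if min(n_conc) < 3:
        raise ValueError("need at least 3 concentrations")
    included: List[TitrationSeries] = []
    excluded: Dict[str, str] = {}
    dshifts: Dict[str, np.ndarray] = {}
    for s in series:
        ds = _series_dshift(s, r_scale)
        if ds.max() < threshold:
            excluded[s.residue_id] = "max_dshift_below_threshold"
        else:
            included.append(s)
            dshifts[s.residue_id] = ds
    if not included:
        raise ValueError(
            f"no residue passes the {threshold} ppm inclusion threshold"
        )

    n_res = len(included)

    def residuals(x):
        kd = np.exp(x[0])
        out = []
        for i, s in enumerate(included):
            frac = binding_isotherm(s.ligand_concentrations,
                                    s.protein_concentration, kd)
            out.append(dshifts[s.residue_id] - x[1 + i] * frac)
        return np.concatenate(out)

    dsat0 = [1.2 * dshifts[s.residue_id].max() for s in included]
    x0 = np.concatenate([[np.log(2.0)], dsat0])
    lo = np.concatenate([[np.log(1e-3)], np.zeros(n_res)])
    hi = np.concatenate([[np.log(kd_max)], np.full(n_res, 10.0)])
    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                 x_scale="jac", ftol=1e-12, xtol=1e-12)
    kd = float(np.exp(sol.x[0]))
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J)
        # delta method: se(K_D) = K_D * se(log K_D); residual variance
        # scales the covariance (unweighted fit)
        n_data = residuals(sol.x).size
        dof = max(n_data - sol.x.size, 1)
        s2 = 2.0 * sol.cost / dof
        kd_se = kd * float(np.sqrt(max(cov[0, 0] * s2, 0.0)))
    except np.linalg.LinAlgError:
        kd_se = float("nan")
    return BindingFit(
        K_D=kd, K_D_se=kd_se,
        per_residue_dsat={s.residue_id: float(sol.x[1 + i])
                          for i, s in enumerate(included)},
        included_residues={s.residue_id for s in included},
        excluded_residues=excluded,
        chi2=float(2.0 * sol.cost),
        n_data=sum(dshifts[s.residue_id].size for s in included),
        kd_at_bound=kd > 0.98 * kd_max,
    )
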