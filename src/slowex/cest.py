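"""Staged CEST inference: noise estimation, no-exchange screen,
per-residue two-site fits, k_ex/p_B clustering, global two-/three-site
fits, residue inclusion rules, topology comparison and Monte-Carlo
uncertainties.

The staged workflow mirrors standard practice for slow-exchange CEST
analysis:

1. estimate per-profile noise from the dip-free baseline;
2. fit every residue without exchange (R1, R2, I0 only) and flag
   residues whose reduced chi-square is significantly above 1 as
   exchange candidates;
3. fit candidates per-residue with a two-site model (k_ex, p_B, dw
   floating);
4. cluster the per-residue (k_ex, p_B) estimates to count distinct
   exchange processes (capped at two);
5. fit the cluster(s) globally -- a shared two-site process, or the
   linear three-site topologies when two processes are present;
6. re-fit each residue with the global parameters fixed and include it
   only if |dw| passes the threshold, the fit improves significantly
   over no-exchange (F-test), and Monte-Carlo re-fits are consistent;
7. final global fit over the included residues with Monte-Carlo
   standard errors.

All optimizations are bounded nonlinear least squares on log(k_ex) and
logit(p_B), with block-sparse finite-difference Jacobians so that the
cost per iteration does not grow with the number of residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import optimize, sparse, stats

from . import spin
from .types import (
    CESTProfile,
    ExchangeParameters,
    GlobalFitResult,
    ResidueSpinParameters,
    Topology,
    UnsupportedModelError,
)

__all__ = [
    "CESTFitOptions",
    "ResidueFit",
    "ClusterAssignment",
    "estimate_profile_noise",
    "fit_no_exchange",
    "fit_two_site_per_residue",
    "cluster_exchange_parameters",
    "global_fit",
    "monte_carlo_uncertainty",
    "select_residues",
    "compare_three_site_topologies",
    "fit_cest_dataset",
    "CESTStageResult",
]


# --------------------------------------------------------------------------
# options and result containers

@dataclass
class CESTFitOptions:
    """Tunable thresholds of the staged CEST analysis."""

    dw_threshold_ppm: float = 1.0       # |dw| inclusion threshold
    alpha: float = 0.05                 # F-test / screen significance
    noise_floor: float = 0.01           # sigma fallback when baseline short
    min_baseline_points: int = 50
    mc_runs: int = 500                  # final-fit Monte-Carlo runs
    mc_consistency_runs: int = 25       # per-residue consistency MC
    mc_rel_width: float = 0.5           # max rel sd of k_ex in MC
    cluster_split_quantile: float = 0.95  # null quantile the 2-cluster split must beat
    cluster_min_separation: float = 8.0  # min center distance, in se units
    tie_margin: float = 0.1             # chi2_red margin for topology ties
    allow_negative_dR2: bool = False
    k_ex_bounds: Tuple[float, float] = (1.0, 2.0e4)
    p_bounds: Tuple[float, float] = (1.0e-4, 0.35)
    dw_bound: float = 10.0
    ftol: float = 1.0e-8
    mc_ftol: float = 1.0e-5
    max_nfev: Optional[int] = None
    solver: str = "trf"                 # "trf" | "gn" for global fits


@dataclass
class ResidueFit:
    """Outcome of one per-residue fit (any model)."""

    residue_id: str
    model: str                          # no_exchange | two_site | three_site
    spins: ResidueSpinParameters
    exchange: Optional[ExchangeParameters]
    chi2: float
    chi2_red: float
    n_data: int
    n_params: int
    flagged_exchange: bool = False
    unidentifiable: bool = False
    converged: bool = True
    included: bool = False
    exclusion_reason: str = ""
    #: (se of log k_ex, se of logit p_B) from the fit covariance; used
    #: to express cluster separations in units of measurement error
    se_transformed: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.chi2_red < 0:
            raise ValueError("chi2_red must be >= 0")


@dataclass
class ClusterAssignment:
    """Partition of residues in (log k_ex, logit p_B) space."""

    clusters: List[Set[str]]
    seed_parameters: List[Tuple[float, float]]   # (k_ex, p_B) per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class CESTStageResult:
    """Full output of the staged pipeline."""

    result: GlobalFitResult
    residue_fits: Dict[str, ResidueFit]
    cluster: Optional[ClusterAssignment]
    included: Set[str]
    audit: List[dict]
    model_comparison: Optional[Dict[str, float]] = None


# --------------------------------------------------------------------------
# noise estimation

def estimate_profile_noise(
    profile: CESTProfile,
    options: CESTFitOptions = CESTFitOptions(),
) -> float:
    """Noise sd of I/I0 from the scatter of the dip-free baseline.

    Dip points are identified by robust (median/MAD) screening of
    downward deviations; the sd is estimated from first differences of
    grid-adjacent baseline points, which cancels slow baseline trends.
    Falls back to ``options.noise_floor`` (with a warning) when fewer
    than ``options.min_baseline_points`` baseline points remain.
    """
    r = profile.ratios
    med = np.median(r)
    mad = 1.4826 * np.median(np.abs(r - med)) + 1.0e-15
    base = r > med - 4.0 * mad
    for _ in range(2):  # re-estimate the level from current baseline
        if base.sum() < 3:
            break
        med = np.median(r[base])
        mad = 1.4826 * np.median(np.abs(r[base] - med)) + 1.0e-15
        base = r > med - 4.0 * mad
    n_base = int(base.sum())
    if n_base < options.min_baseline_points:
        warnings.warn(
            f"{profile.residue_id}: only {n_base} baseline points; using "
            f"noise floor {options.noise_floor}",
            stacklevel=2,
        )
        sigma = options.noise_floor
    else:
        idx = np.flatnonzero(base)
        adjacent = np.diff(idx) == 1
        diffs = np.diff(r[idx])[adjacent]
        if diffs.size < 10:
            sigma = float(np.std(r[idx], ddof=1))
        else:
            sigma = float(np.std(diffs, ddof=1) / np.sqrt(2.0))
        sigma = max(sigma, 1.0e-12)
    profile.sigma = np.full(r.shape, sigma)
    return sigma


def ensure_sigma(profiles: Iterable[CESTProfile],
                 options: CESTFitOptions = CESTFitOptions()) -> None:
    for p in profiles:
        if p.sigma is None:
            estimate_profile_noise(p, options)


# --------------------------------------------------------------------------
# parameter transforms

def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_GLOBAL_NAMES_2 = ("k_ex_AB", "p_B")
_GLOBAL_NAMES_3 = ("k_ex_AB", "p_B", "k_ex_AC", "p_C")


class _Problem:
    """Weighted-residual problem for a (possibly global) CEST fit.

    Parameter vector layout: [global exchange block][per-residue blocks].
    The global block is (log k_ex_AB, logit p_B[, log k_ex_AC, logit p_C])
    and is absent for ``Topology.NONE`` or when ``fix_global`` is set.
    Per-residue blocks are (dw_AB[, dw_AC], R1, R2, dR2, I0); for
    ``Topology.NONE`` only (R1, R2, I0).
    """

    def __init__(
        self,
        topology: Topology,
        profiles_by_residue: Mapping[str, Sequence[CESTProfile]],
        options: CESTFitOptions,
        fix_global: bool = False,
        fixed_exchange: Optional[ExchangeParameters] = None,
        temperature: float = 283.15,
    ):
        self.topology = topology
        self.options = options
        self.fix_global = fix_global or topology is Topology.NONE
        self.fixed_exchange = fixed_exchange
        self.temperature = temperature
        self.residues = sorted(profiles_by_residue)
        self.profiles = {r: list(profiles_by_residue[r])
                         for r in self.residues}
        for plist in self.profiles.values():
            for p in plist:
                if p.sigma is None:
                    raise ValueError("profiles need sigma before fitting")
        if topology is Topology.NONE:
            self.res_names = ("R1", "R2", "I0")
        elif topology.is_three_site:
            self.res_names = ("dw_AB", "dw_AC", "R1", "R2", "dR2", "I0")
        else:
            self.res_names = ("dw_AB", "R1", "R2", "dR2", "I0")
        self.n_res_block = len(self.res_names)
        if self.fix_global:
            self.global_names: Tuple[str, ...] = ()
        else:
            self.global_names = (_GLOBAL_NAMES_3 if topology.is_three_site
                                 else _GLOBAL_NAMES_2)
        self.n_global = len(self.global_names)
        self.n_params = self.n_global + self.n_res_block * len(self.residues)
        self.n_data = sum(p.ratios.size for pl in self.profiles.values()
                          for p in pl)
        # row ranges per residue for the sparsity pattern
        self._rows = {}
        row = 0
        for rid in self.residues:
            n = sum(p.ratios.size for p in self.profiles[rid])
            self._rows[rid] = (row, row + n)
            row += n

    # -- packing -------------------------------------------------------
    def pack(self, exchange: Optional[ExchangeParameters],
             spins: Mapping[str, ResidueSpinParameters]) -> np.ndarray:
        x = []
        if not self.fix_global:
            assert exchange is not None
            x += [np.log(exchange.k_ex_AB), _logit(exchange.p_B)]
            if self.topology.is_three_site:
                x += [np.log(exchange.k_ex_AC), _logit(exchange.p_C)]
        for rid in self.residues:
            s = spins[rid]
            for name in self.res_names:
                if name == "dw_AC":
                    x.append(s.dw_AC if s.dw_AC is not None else 0.0)
                else:
                    x.append(getattr(s, name))
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray
               ) -> Tuple[ExchangeParameters, Dict[str, ResidueSpinParameters]]:
        o = self.options
        if self.fix_global:
            if self.topology is Topology.NONE:
                exchange = ExchangeParameters(Topology.NONE,
                                              temperature=self.temperature)
            else:
                assert self.fixed_exchange is not None
                exchange = self.fixed_exchange
            k = 0
        else:
            kex_ab = float(np.exp(x[0]))
            p_b = float(_expit(np.asarray(x[1])))
            if self.topology.is_three_site:
                kex_ac = float(np.exp(x[2]))
                p_c = float(_expit(np.asarray(x[3])))
                exchange = ExchangeParameters(
                    self.topology, kex_ab, p_b, kex_ac, p_c,
                    temperature=self.temperature)
                k = 4
            else:
                exchange = ExchangeParameters(
                    self.topology, kex_ab, p_b, temperature=self.temperature)
                k = 2
        spins_out: Dict[str, ResidueSpinParameters] = {}
        for rid in self.residues:
            vals = dict(zip(self.res_names,
                            x[k:k + self.n_res_block]))
            k += self.n_res_block
            ref = self.profiles[rid][0]
            spins_out[rid] = ResidueSpinParameters(
                residue_id=rid,
                dw_AB=float(vals.get("dw_AB", 0.0)),
                dw_AC=(float(vals["dw_AC"]) if "dw_AC" in vals else None),
                R1=float(vals["R1"]),
                R2=float(vals["R2"]),
                dR2=float(vals.get("dR2", 0.0)),
                I0=float(vals["I0"]),
                shift_ppm=self._shift(rid),
            )
        return exchange, spins_out

    def _shift(self, rid: str) -> float:
        # major-state position is taken as known (assigned spectrum);
        # carried on the input spin parameters via profile metadata
        return self.shifts[rid]

    # -- residuals -----------------------------------------------------
    def set_shifts(self, shifts: Mapping[str, float]) -> None:
        self.shifts = dict(shifts)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        exchange, spins_map = self.unpack(x)
        out = np.empty(self.n_data)
        k = 0
        for rid in self.residues:
            s = spins_map[rid]
            for prof in self.profiles[rid]:
                model = spin.cest_forward(exchange, s, prof.schedule)
                n = model.size
                out[k:k + n] = (prof.ratios - model) / prof.sigma
                k += n
        return out

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        o = self.options
        lo, hi = [], []
        if not self.fix_global:
            klo, khi = np.log(o.k_ex_bounds[0]), np.log(o.k_ex_bounds[1])
            plo, phi = _logit(o.p_bounds[0]), _logit(o.p_bounds[1])
            lo += [klo, plo]
            hi += [khi, phi]
            if self.topology.is_three_site:
                lo += [klo, plo]
                hi += [khi, phi]
        res_lo = {"dw_AB": -o.dw_bound, "dw_AC": -o.dw_bound,
                  "R1": 0.05, "R2": 0.5,
                  "dR2": (-50.0 if o.allow_negative_dR2 else 0.0),
                  "I0": 0.2}
        res_hi = {"dw_AB": o.dw_bound, "dw_AC": o.dw_bound,
                  "R1": 10.0, "R2": 100.0, "dR2": 100.0, "I0": 2.0}
        for _ in self.residues:
            lo += [res_lo[n] for n in self.res_names]
            hi += [res_hi[n] for n in self.res_names]
        return np.asarray(lo), np.asarray(hi)

    def sparsity(self) -> sparse.lil_matrix:
        S = sparse.lil_matrix((self.n_data, self.n_params), dtype=np.uint8)
        if self.n_global:
            S[:, :self.n_global] = 1
        for i, rid in enumerate(self.residues):
            r0, r1 = self._rows[rid]
            c0 = self.n_global + i * self.n_res_block
            S[r0:r1, c0:c0 + self.n_res_block] = 1
        return S

    def solve(self, x0: np.ndarray, ftol: Optional[float] = None,
              max_nfev: Optional[int] = None) -> optimize.OptimizeResult:
        lo, hi = self.bounds()
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        tol = ftol if ftol is not None else self.options.ftol
        return optimize.least_squares(
            self.residuals, x0, bounds=(lo, hi),
            jac_sparsity=self.sparsity() if len(self.residues) > 1 else None,
            ftol=tol, xtol=tol, gtol=tol, x_scale="jac",
            max_nfev=max_nfev, method="trf",
        )

    # -- fast refits for Monte-Carlo resampling ------------------------
    def column_groups(self) -> List[np.ndarray]:
        """Columns whose residual rows are disjoint can share one
        finite-difference evaluation: the k-th slot of every residue
        block forms a group; global columns get their own group."""
        groups = [np.array([i]) for i in range(self.n_global)]
        n_res = len(self.residues)
        for s in range(self.n_res_block):
            cols = self.n_global + s + self.n_res_block * np.arange(n_res)
            groups.append(cols)
        return groups

    def grouped_jacobian(self, x: np.ndarray,
                         r0: np.ndarray) -> np.ndarray:
        """2-point finite-difference Jacobian using column grouping."""
        J = np.zeros((self.n_data, self.n_params))
        col_rows = {}
        for i, rid in enumerate(self.residues):
            r_lo, r_hi = self._rows[rid]
            c0 = self.n_global + i * self.n_res_block
            for c in range(c0, c0 + self.n_res_block):
                col_rows[c] = (r_lo, r_hi)
        for cols in self.column_groups():
            h = 1.0e-6 * np.maximum(1.0, np.abs(x[cols]))
            xp = x.copy()
            xp[cols] += h
            rp = self.residuals(xp)
            dr = (rp - r0)
            for c, hc in zip(cols, h):
                if c < self.n_global:
                    J[:, c] = dr / hc
                else:
                    r_lo, r_hi = col_rows[c]
                    J[r_lo:r_hi, c] = dr[r_lo:r_hi] / hc
        return J

    def gn_refit(self, x0: np.ndarray, max_steps: int = 12,
                 tol: float = 1.0e-6,
                 refresh_every: int = 4,
                 J: Optional[np.ndarray] = None,
                 ) -> Tuple[np.ndarray, bool]:
        """Bounded damped Gauss-Newton refit warm-started at ``x0``.

        Used for Monte-Carlo re-fits, where the solution moves only by
        about one standard error.  Because the data enter the weighted
        residuals additively, the Jacobian does not depend on the
        resampled data and a precomputed ``J`` (at the base solution)
        can be shared across runs; it is refreshed at the current point
        every ``refresh_every`` accepted steps only when the iteration
        has not converged by then.  Returns (solution, converged)."""
        lo, hi = self.bounds()
        x = np.clip(x0, lo, hi)
        r = self.residuals(x)
        cost = float(r @ r)
        if J is None:
            J = self.grouped_jacobian(x, r)
        lam = 1.0e-3
        accepted = 0
        fresh = True
        for _ in range(max_steps):
            JTJ = J.T @ J
            g = J.T @ r
            d = np.diag(JTJ).copy()
            d[d <= 0] = 1.0
            step_ok = False
            for _try in range(8):
                try:
                    dx = np.linalg.solve(JTJ + lam * np.diag(d), -g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                x_new = np.clip(x + dx, lo, hi)
                r_new = self.residuals(x_new)
                cost_new = float(r_new @ r_new)
                if cost_new < cost:
                    step_ok = True
                    break
                lam *= 10.0
            if not step_ok:
                if not fresh:
                    # the stale Jacobian may be the obstacle
                    J = self.grouped_jacobian(x, r)
                    fresh = True
                    lam = max(lam * 1.0e-3, 1.0e-4)
                    continue
                return x, accepted > 0
            rel_drop = (cost - cost_new) / max(cost, 1e-300)
            x, r, cost = x_new, r_new, cost_new
            lam = max(lam * 0.3, 1.0e-6)
            accepted += 1
            fresh = False
            if rel_drop < tol:
                return x, True
            if accepted % refresh_every == 0:
                J = self.grouped_jacobian(x, r)
                fresh = True
        return x, True


def _chi2_stats(problem: _Problem, x: np.ndarray) -> Tuple[float, float]:
    res = problem.residuals(x)
    chi2 = float(res @ res)
    dof = max(problem.n_data - problem.n_params, 1)
    return chi2, chi2 / dof


def f_test_nested(chi2_small: float, p_small: int,
                  chi2_big: float, p_big: int, n: int) -> float:
    """p-value of the F-test between nested least-squares models."""
    if chi2_big <= 0 or n <= p_big or chi2_small <= chi2_big:
        return 1.0 if chi2_small <= chi2_big else 0.0
    f = ((chi2_small - chi2_big) / (p_big - p_small)) / (
        chi2_big / (n - p_big))
    return float(stats.f.sf(f, p_big - p_small, n - p_big))


# --------------------------------------------------------------------------
# stage 1: no-exchange screen

def fit_no_exchange(
    profiles: Sequence[CESTProfile],
    shift_ppm: float,
    options: CESTFitOptions = CESTFitOptions(),
) -> ResidueFit:
    """Fit (R1, R2, I0) with no exchange; flag exchange candidates.

    A residue whose reduced chi-square is incompatible with 1 (upper-tail
    chi-square probability below ``options.alpha``) is flagged as a
    likely candidate to experience an exchange process.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    rid = profiles[0].residue_id
    ensure_sigma(profiles, options)
    prob = _Problem(Topology.NONE, {rid: profiles}, options)
    prob.set_shifts({rid: shift_ppm})
    x0 = prob.pack(None, {rid: ResidueSpinParameters(
        residue_id=rid, R1=1.5, R2=12.0, I0=1.0, shift_ppm=shift_ppm)})
    sol = prob.solve(x0)
    chi2, chi2_red = _chi2_stats(prob, sol.x)
    dof = prob.n_data - prob.n_params
    p_tail = float(stats.chi2.sf(chi2, dof))
    _, spins_map = prob.unpack(sol.x)
    return ResidueFit(
        residue_id=rid, model="no_exchange", spins=spins_map[rid],
        exchange=None, chi2=chi2, chi2_red=chi2_red,
        n_data=prob.n_data, n_params=prob.n_params,
        flagged_exchange=p_tail < options.alpha,
        converged=bool(sol.success),
    )


# --------------------------------------------------------------------------
# stage 2: per-residue two-site fits

def _dip_guess(profiles: Sequence[CESTProfile], shift_ppm: float,
               no_exch_spins: ResidueSpinParameters) -> float:
    """Initial dw (ppm) from the deepest downward deviation away from the
    major-state dip."""
    best_dev, best_dw = 0.0, 1.5
    for prof in profiles:
        model = spin.cest_forward(
            ExchangeParameters(Topology.NONE), no_exch_spins, prof.schedule)
        dev = (prof.ratios - model) / prof.sigma
        half_width = max(0.7, 4.0 * prof.schedule.B1_field
                         / prof.schedule.spectrometer_15N_freq)
        away = np.abs(prof.schedule.offsets - shift_ppm) > half_width
        if not np.any(away):
            continue
        i = np.argmin(np.where(away, dev, np.inf))
        if dev[i] < best_dev:
            best_dev = dev[i]
            best_dw = float(prof.schedule.offsets[i] - shift_ppm)
    return best_dw


def fit_two_site_per_residue(
    profiles: Sequence[CESTProfile],
    shift_ppm: float,
    options: CESTFitOptions = CESTFitOptions(),
    no_exchange_fit: Optional[ResidueFit] = None,
    x0_exchange: Optional[Tuple[float, float]] = None,
) -> ResidueFit:
    """Joint fit of (k_ex, p_B, dw, R1, R2, dR2, I0) across B1 fields.

    Fits flagged residues with the two-site model.  The fit is marked
    unidentifiable when p_B or k_ex is pinned at a bound or the fitted
    |dw| collapses toward zero.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    rid = profiles[0].residue_id
    ensure_sigma(profiles, options)
    if no_exchange_fit is None:
        no_exchange_fit = fit_no_exchange(profiles, shift_ppm, options)
    prob = _Problem(Topology.TWO_SITE_AB, {rid: profiles}, options)
    prob.set_shifts({rid: shift_ppm})
    dw0 = _dip_guess(profiles, shift_ppm, no_exchange_fit.spins)
    kex0, pb0 = x0_exchange if x0_exchange is not None else (200.0, 0.02)
    base = no_exchange_fit.spins
    best = None
    for dw_start in (dw0, -dw0):
        spins0 = ResidueSpinParameters(
            residue_id=rid, dw_AB=dw_start, R1=base.R1,
            R2=min(base.R2, 50.0), dR2=0.0, I0=base.I0,
            shift_ppm=shift_ppm)
        x0 = prob.pack(
            ExchangeParameters(Topology.TWO_SITE_AB, kex0, pb0), {rid: spins0})
        sol = prob.solve(x0)
        if best is None or sol.cost < best.cost:
            best = sol
    sol = best
    chi2, chi2_red = _chi2_stats(prob, sol.x)
    exchange, spins_map = prob.unpack(sol.x)
    lo, hi = prob.bounds()
    at_bound = (np.abs(sol.x[:2] - lo[:2]) < 1e-6) | (
        np.abs(sol.x[:2] - hi[:2]) < 1e-6)
    # a fit whose exchange contribution never rises above the noise is
    # indistinguishable from no exchange (dw = 0 collapse)
    depth = 0.0
    no_ex = ExchangeParameters(Topology.NONE,
                               temperature=exchange.temperature)
    for prof in profiles:
        with_ex = spin.cest_forward(exchange, spins_map[rid],
                                    prof.schedule)
        without = spin.cest_forward(no_ex, spins_map[rid], prof.schedule)
        depth = max(depth, float(np.max(np.abs(with_ex - without)
                                        / prof.sigma)))
    unident = (bool(at_bound.any()) or abs(spins_map[rid].dw_AB) < 0.1
               or depth < 3.0)
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J)
        se_t = (float(np.sqrt(max(cov[0, 0], 0.0))),
                float(np.sqrt(max(cov[1, 1], 0.0))))
    except np.linalg.LinAlgError:
        se_t = None
    return ResidueFit(
        residue_id=rid, model="two_site", spins=spins_map[rid],
        exchange=exchange, chi2=chi2, chi2_red=chi2_red,
        n_data=prob.n_data, n_params=prob.n_params,
        flagged_exchange=no_exchange_fit.flagged_exchange,
        unidentifiable=unident, converged=bool(sol.success),
        se_transformed=se_t,
    )


# --------------------------------------------------------------------------
# stage 3: clustering of per-residue exchange parameters

def _lloyd(z: np.ndarray, c: np.ndarray) -> Tuple[np.ndarray, float]:
    labels = np.full(len(z), -1, dtype=int)
    c = c.copy()
    for _ in range(50):
        d = ((z[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        new = d.argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for j in (0, 1):
            if np.any(labels == j):
                c[j] = z[labels == j].mean(axis=0)
    if np.all(labels == labels[0]):
        return np.zeros(len(z), dtype=int), 0.0
    mean = z.mean(axis=0)
    total = float(((z - mean) ** 2).sum(axis=1).mean())
    counts = np.bincount(labels, minlength=2)
    between = float(sum(counts[j] * ((c[j] - mean) ** 2).sum()
                        for j in (0, 1)) / len(z))
    return labels, (between / total if total > 0 else 0.0)


def _two_means(z: np.ndarray) -> Tuple[np.ndarray, float]:
    """Deterministic 2-means over several initializations.

    Lloyd's algorithm is started from the extremes of the principal
    axis and of each coordinate axis; the partition explaining the
    largest variance fraction wins.  Returns (labels, fraction of total
    variance explained by the split); the fraction is 0 when one
    cluster ends up empty."""
    _, _, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    directions = [vt[0]] + [np.eye(z.shape[1])[k]
                            for k in range(z.shape[1])]
    best_labels, best_bf = np.zeros(len(z), dtype=int), 0.0
    for d in directions:
        order = np.argsort(z @ d)
        c = np.stack([z[order[0]], z[order[-1]]])
        labels, bf = _lloyd(z, c)
        if bf > best_bf:
            best_labels, best_bf = labels, bf
    return best_labels, best_bf


_NULL_SPLIT_CACHE: Dict[Tuple[int, float], float] = {}


def _null_split_threshold(n: int, quantile: float,
                          n_sims: int = 200) -> float:
    """Quantile of the 2-means explained-variance fraction for n points
    drawn from a single 2-D Gaussian (simulated once per n, cached)."""
    key = (n, quantile)
    if key not in _NULL_SPLIT_CACHE:
        rng = np.random.default_rng(987654321 + n)
        fracs = [_two_means(rng.normal(size=(n, 2)))[1]
                 for _ in range(n_sims)]
        _NULL_SPLIT_CACHE[key] = float(np.quantile(fracs, quantile))
    return _NULL_SPLIT_CACHE[key]


def cluster_exchange_parameters(
    fits: Sequence[ResidueFit],
    options: CESTFitOptions = CESTFitOptions(),
) -> ClusterAssignment:
    """Partition per-residue (k_ex, p_B) estimates into 1 or 2 processes.

    Deterministic 2-means in standardized (log k_ex, logit p_B) space,
    initialized from the extremes of the first principal axis.  The
    two-cluster split is kept only when the variance it explains
    exceeds the ``cluster_split_quantile`` of the same statistic under
    a single-Gaussian null (2-means always explains a large variance
    fraction at small n, so the threshold is calibrated by simulation
    at the observed sample size).
    """
    usable = [f for f in fits
              if f.exchange is not None and not f.unidentifiable]
    if len(fits) < 2:
        raise ValueError("need at least two per-residue fits")
    if not usable:
        return ClusterAssignment(clusters=[], seed_parameters=[])
    rids = [f.residue_id for f in usable]
    pts = np.array([[np.log(f.exchange.k_ex_AB), _logit(f.exchange.p_B)]
                    for f in usable])
    # scale each axis by the typical parameter uncertainty so that
    # cluster separations are measured in units of measurement error;
    # fall back to the sample spread when no fit covariances exist
    ses = np.array([f.se_transformed for f in usable
                    if f.se_transformed is not None
                    and np.all(np.isfinite(f.se_transformed))
                    and all(s > 0 for s in f.se_transformed)])
    # pathological fits (singular covariance) are excluded from the
    # scale estimate; the median over the healthy fits is robust
    se_scaled = bool(ses.shape[0] >= max(2, len(usable) // 2)
                     and np.all(np.median(ses, axis=0) > 0))
    if se_scaled:
        scale = np.median(ses, axis=0)
    else:
        scale = pts.std(axis=0, ddof=0)
    scale = np.where(scale < 1e-9, 1.0, scale)
    z = (pts - pts.mean(axis=0)) / scale
    active = np.arange(len(usable))
    outliers: List[int] = []
    labels = np.zeros(len(active), dtype=int)
    # split attempts, with outlier rescue: an occasional pathological
    # per-residue fit (a gross outlier in error-scaled space) inflates
    # the total variance and can mask a genuine two-process
    # separation, and a split that isolates a single residue reflects
    # such an outlier rather than a second process.  Either situation
    # sets the offending point aside (at most twice) and retries.
    while len(active) > 1:
        zs = z[active]
        labels, bf = _two_means(zs)
        valid = bf >= _null_split_threshold(
            len(zs), options.cluster_split_quantile)
        counts = np.bincount(labels, minlength=2)
        if valid and counts.min() >= 2:
            if se_scaled:
                c0 = zs[labels == 0].mean(axis=0)
                c1 = zs[labels == 1].mean(axis=0)
                if np.linalg.norm(c0 - c1) < \
                        options.cluster_min_separation:
                    # two genuine processes must be resolved by many
                    # standard errors of the per-residue estimates
                    labels = np.zeros(len(zs), dtype=int)
            break
        drop = None
        if len(active) > 3 and len(outliers) < 2:
            if valid and counts.min() == 1:
                drop = int(active[labels == int(np.argmin(counts))][0])
            else:
                med = np.median(zs, axis=0)
                mad = 1.4826 * np.median(np.abs(zs - med),
                                         axis=0) + 1e-12
                rz = np.max(np.abs(zs - med) / mad, axis=1)
                if rz.max() > 6.0:
                    drop = int(active[int(np.argmax(rz))])
        if drop is None:
            labels = np.zeros(len(zs), dtype=int)
            break
        outliers.append(drop)
        active = active[active != drop]
        labels = np.zeros(len(active), dtype=int)
    clusters: List[Set[str]] = []
    seeds: List[Tuple[float, float]] = []
    centers: List[np.ndarray] = []
    for j in sorted(set(labels)):
        idx = active[labels == j]
        members = {rids[i] for i in idx}
        sub = pts[idx]
        kex = float(np.exp(np.median(sub[:, 0])))
        pb = float(_expit(np.asarray(np.median(sub[:, 1]))))
        clusters.append(members)
        seeds.append((kex, pb))
        centers.append(z[idx].mean(axis=0))
    # outlying fits rejoin the nearest cluster for membership purposes
    for i in outliers:
        d = [float(((z[i] - c) ** 2).sum()) for c in centers]
        clusters[int(np.argmin(d))].add(rids[i])
    # order clusters by population, highest first (process-1 convention)
    order = np.argsort([-s[1] for s in seeds])
    return ClusterAssignment(
        clusters=[clusters[i] for i in order],
        seed_parameters=[seeds[i] for i in order],
    )


# --------------------------------------------------------------------------
# stages 4-5: global fits

def secondary_dip_guess(
    profiles: Sequence[CESTProfile],
    shift_ppm: float,
    fit: ResidueFit,
    depth_sigma: float = 4.0,
) -> Optional[float]:
    """Position (ppm, relative to the major state) of a residual dip
    unexplained by a residue's two-site fit, or None.

    Residues sensing two exchange processes show a second dip that the
    per-residue two-site fit leaves in the residuals; its position is
    the natural starting value for the second shift difference of a
    three-site fit.  Only dips deeper than ``depth_sigma`` noise
    standard deviations, away from both fitted dips, count.
    """
    if fit.exchange is None:
        return None
    best_dev, best_dw = 0.0, None
    for prof in profiles:
        model = spin.cest_forward(fit.exchange, fit.spins, prof.schedule)
        dev = (prof.ratios - model) / prof.sigma
        half_width = max(0.7, 4.0 * prof.schedule.B1_field
                         / prof.schedule.spectrometer_15N_freq)
        offs = prof.schedule.offsets
        away = ((np.abs(offs - shift_ppm) > half_width)
                & (np.abs(offs - (shift_ppm + fit.spins.dw_AB))
                   > half_width))
        if not np.any(away):
            continue
        i = int(np.argmin(np.where(away, dev, np.inf)))
        if dev[i] < best_dev:
            best_dev = dev[i]
            best_dw = float(offs[i] - shift_ppm)
    return best_dw if best_dev < -depth_sigma else None


def _init_spins_for_global(
    residues: Iterable[str],
    residue_fits: Mapping[str, ResidueFit],
    cluster: Optional[ClusterAssignment],
    topology: Topology,
    shifts: Mapping[str, float],
    secondary_dw: Optional[Mapping[str, Optional[float]]] = None,
) -> Dict[str, ResidueSpinParameters]:
    """Starting per-residue parameters for a global fit.

    The slot of the residue's own cluster gets its fitted dw; the other
    slot starts at the residual-dip position when one was detected
    (``secondary_dw``) and near zero otherwise, so residues that sense
    only one process do not begin with a spurious second dip.
    """
    spins0 = {}
    cluster1 = cluster.clusters[0] if cluster and cluster.clusters else set()
    for rid in residues:
        f = residue_fits.get(rid)
        if f is not None:
            dw_fit = f.spins.dw_AB
            r1, r2, dr2, i0 = f.spins.R1, f.spins.R2, f.spins.dR2, f.spins.I0
        else:
            dw_fit, r1, r2, dr2, i0 = 1.5, 1.5, 12.0, 0.0, 1.0
        if topology.is_three_site:
            other = None
            if secondary_dw is not None:
                other = secondary_dw.get(rid)
            if other is None:
                other = 0.05
            if rid in cluster1 or not cluster:
                dw_ab, dw_ac = dw_fit, other
            else:
                dw_ab, dw_ac = other, dw_fit
        else:
            dw_ab, dw_ac = dw_fit, None
        spins0[rid] = ResidueSpinParameters(
            residue_id=rid, dw_AB=dw_ab, dw_AC=dw_ac, R1=r1,
            R2=min(r2, 50.0), dR2=dr2, I0=i0, shift_ppm=shifts[rid])
    return spins0


def global_fit(
    profiles_by_residue: Mapping[str, Sequence[CESTProfile]],
    shifts: Mapping[str, float],
    topology: Topology,
    exchange0: ExchangeParameters,
    spins0: Mapping[str, ResidueSpinParameters],
    options: CESTFitOptions = CESTFitOptions(),
    fix_global: bool = False,
) -> GlobalFitResult:
    """Global fit of shared exchange parameters and per-residue nuisances.

    When ``fix_global`` is set, the exchange parameters of ``exchange0``
    are held fixed and only residue-specific parameters float (the
    re-fitting step of the staged workflow).  Standard errors from the
    covariance matrix (J^T J inverse at the solution, delta-method on
    the transformed parameters) are attached as ``standard_errors``.
    """
    temps = {p.schedule.T_EX for pl in profiles_by_residue.values()
             for p in pl}  # noqa: F841  (schedules may differ in T_EX)
    for pl in profiles_by_residue.values():
        ensure_sigma(pl, options)
    prob = _Problem(topology, profiles_by_residue, options,
                    fix_global=fix_global, fixed_exchange=exchange0,
                    temperature=exchange0.temperature)
    prob.set_shifts(shifts)
    x0 = prob.pack(None if prob.fix_global else exchange0, spins0)
    if options.solver == "gn" and not fix_global:
        lo, hi = prob.bounds()
        x_gn, _ = prob.gn_refit(np.clip(x0, lo + 1e-12, hi - 1e-12),
                                max_steps=80, tol=1e-8, refresh_every=2)
        r_gn = prob.residuals(x_gn)
        sol = optimize.OptimizeResult(
            x=x_gn, cost=0.5 * float(r_gn @ r_gn),
            jac=prob.grouped_jacobian(x_gn, r_gn), success=True,
            status=1, nfev=-1, njev=-1)
    else:
        sol = prob.solve(x0, max_nfev=options.max_nfev)
    x_sol = _canonicalize_bac(prob, sol.x)
    chi2, chi2_red = _chi2_stats(prob, x_sol)
    exchange, spins_map = prob.unpack(x_sol)
    se = _covariance_se(prob, sol) if not fix_global else None
    if se is not None and not np.array_equal(x_sol, sol.x):
        # BAC label canonicalization swapped the two processes
        se = {"k_ex_AB": se["k_ex_AC"], "p_B": se["p_C"],
              "k_ex_AC": se["k_ex_AB"], "p_C": se["p_B"]}
    result = GlobalFitResult(
        exchange=exchange, per_residue=spins_map, chi2_red=chi2_red,
        standard_errors=se, n_data=prob.n_data, n_params=prob.n_params,
    )
    result._problem = prob          # used by Monte-Carlo resampling
    result._solution = x_sol
    result._sol = sol
    result._chi2 = chi2
    result._converged = bool(sol.success)
    return result


def _canonicalize_bac(prob: _Problem, x: np.ndarray) -> np.ndarray:
    """For the label-symmetric B<->A<->C topology, order the minor
    states so that p_B >= p_C (the higher-population process carries
    the A/B labels, matching the clustering convention)."""
    if (prob.fix_global or prob.topology is not Topology.LINEAR_BAC
            or prob.n_global != 4):
        return x
    if x[1] >= x[3]:                     # logit is monotone
        return x
    x = x.copy()
    x[[0, 1, 2, 3]] = x[[2, 3, 0, 1]]
    i_ab = prob.res_names.index("dw_AB")
    i_ac = prob.res_names.index("dw_AC")
    for i in range(len(prob.residues)):
        c0 = prob.n_global + i * prob.n_res_block
        x[[c0 + i_ab, c0 + i_ac]] = x[[c0 + i_ac, c0 + i_ab]]
    return x


def _covariance_se(prob: _Problem,
                   sol: optimize.OptimizeResult) -> Dict[str, float]:
    """Delta-method standard errors of the global exchange parameters
    from the Gauss-Newton covariance matrix."""
    J = sol.jac
    if sparse.issparse(J):
        J = J.toarray()
    try:
        cov = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(J.T @ J)
    se = {}
    x = sol.x
    for i, name in enumerate(prob.global_names):
        s = float(np.sqrt(max(cov[i, i], 0.0)))
        if name.startswith("k_ex"):
            se[name] = float(np.exp(x[i])) * s
        else:
            p = float(_expit(np.asarray(x[i])))
            se[name] = p * (1.0 - p) * s
    return se


def monte_carlo_uncertainty(
    result: GlobalFitResult,
    n_runs: int = 500,
    seed: int = 0,
    options: Optional[CESTFitOptions] = None,
) -> GlobalFitResult:
    """Monte-Carlo standard errors by parametric resampling.

    New datasets are drawn as best-fit model plus Gaussian noise at the
    estimated per-point sigma and fully re-fitted (warm-started from the
    base solution, all parameters floating).  Parameter spreads across
    runs give the standard errors; runs that fail to converge are
    excluded (with a warning above a 10% failure rate).
    """
    if not (1 <= n_runs <= 10_000):
        raise ValueError("n_runs out of range")
    prob: _Problem = result._problem
    opts = options if options is not None else prob.options
    rng = np.random.default_rng(seed)
    x_base = result._solution
    exchange, spins_map = prob.unpack(x_base)
    # noiseless model per profile
    model_cache = {}
    for rid in prob.residues:
        s = spins_map[rid]
        model_cache[rid] = [spin.cest_forward(exchange, s, p.schedule)
                            for p in prob.profiles[rid]]
    orig = {rid: [p.ratios for p in prob.profiles[rid]]
            for rid in prob.residues}
    samples: Dict[str, List[float]] = {n: [] for n in prob.global_names}
    for rid in prob.residues:
        samples[f"dw_AB[{rid}]"] = []
    n_failed = 0
    r_base = prob.residuals(x_base)
    J_base = prob.grouped_jacobian(x_base, r_base)
    try:
        for _ in range(n_runs):
            for rid in prob.residues:
                for p, m in zip(prob.profiles[rid], model_cache[rid]):
                    p.ratios = m + rng.normal(0.0, 1.0, m.shape) * p.sigma
            x_sol, ok = prob.gn_refit(x_base, tol=opts.mc_ftol, J=J_base,
                                      max_steps=10, refresh_every=1000)
            if not ok:
                n_failed += 1
                continue
            ex_i, sp_i = prob.unpack(_canonicalize_bac(prob, x_sol))
            for name in prob.global_names:
                samples[name].append(getattr(ex_i, name))
            for rid in prob.residues:
                samples[f"dw_AB[{rid}]"].append(sp_i[rid].dw_AB)
    finally:
        for rid in prob.residues:
            for p, r in zip(prob.profiles[rid], orig[rid]):
                p.ratios = r
    if n_failed > 0.1 * n_runs:
        warnings.warn(
            f"{n_failed}/{n_runs} Monte-Carlo runs failed to converge",
            stacklevel=2,
        )
    mc = {k: np.asarray(v) for k, v in samples.items() if len(v)}
    se = dict(result.standard_errors or {})
    for name in prob.global_names:
        if name in mc and mc[name].size > 1:
            se[f"mc_{name}"] = float(np.std(mc[name], ddof=1))
    result.mc_samples = mc
    result.standard_errors = se
    return result


# --------------------------------------------------------------------------
# residue inclusion

def _is_unimodal(x: np.ndarray) -> bool:
    """Heuristic unimodality check: the best two-class split (Otsu) of a
    clearly bimodal sample explains most of the variance."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 8 or np.ptp(x) == 0:
        return True
    total = x.var()
    best = 0.0
    for i in range(2, n - 2):
        w0 = i / n
        m0, m1 = x[:i].mean(), x[i:].mean()
        between = w0 * (1 - w0) * (m0 - m1) ** 2
        best = max(best, between)
    return best / total < 0.80


def select_residues(
    fits: Mapping[str, ResidueFit],
    no_exchange_fits: Mapping[str, ResidueFit],
    mc_kex_samples: Mapping[str, np.ndarray],
    options: CESTFitOptions = CESTFitOptions(),
) -> Tuple[Set[str], List[dict]]:
    """Apply the three inclusion rules conjunctively.

    A residue is included when (1) its fitted |dw| reaches the threshold
    (either process for three-site fits), (2) the exchange model improves
    significantly over no-exchange by F-test, and (3) Monte-Carlo
    re-fits with floating k_ex/p_B are consistent (relative spread of
    k_ex below ``mc_rel_width`` and unimodal).
    """
    included: Set[str] = set()
    audit: List[dict] = []
    for rid, fit in fits.items():
        reason = ""
        dws = [abs(fit.spins.dw_AB)]
        if fit.spins.dw_AC is not None:
            dws.append(abs(fit.spins.dw_AC))
        if max(dws) < options.dw_threshold_ppm:
            reason = "dw_below_threshold"
        if not reason:
            ne = no_exchange_fits.get(rid)
            if ne is None:
                reason = "no_reference_fit"
            else:
                p = f_test_nested(ne.chi2, ne.n_params, fit.chi2,
                                  fit.n_params, fit.n_data)
                if p >= options.alpha:
                    reason = "chi2_not_improved"
        if not reason:
            kex = np.asarray(mc_kex_samples.get(rid, []))
            if kex.size >= 8:
                rel = np.std(kex, ddof=1) / max(np.mean(kex), 1e-12)
                if rel >= options.mc_rel_width or not _is_unimodal(kex):
                    reason = "mc_inconsistent"
        if reason:
            audit.append({"residue": rid, "included": False,
                          "reason": reason})
        else:
            included.add(rid)
            audit.append({"residue": rid, "included": True, "reason": ""})
    return included, audit


# --------------------------------------------------------------------------
# three-site topology comparison

_LINEAR_TOPOLOGIES = (Topology.LINEAR_BAC, Topology.LINEAR_ABC,
                      Topology.LINEAR_ACB)


def compare_three_site_topologies(
    profiles_by_residue: Mapping[str, Sequence[CESTProfile]],
    shifts: Mapping[str, float],
    cluster: ClusterAssignment,
    residue_fits: Mapping[str, ResidueFit],
    options: CESTFitOptions = CESTFitOptions(),
    temperature: float = 283.15,
) -> Tuple[Topology, Dict[str, GlobalFitResult]]:
    """Fit the three linear three-site topologies and rank them.

    The higher-population cluster seeds the A/B pair, the other the C
    pair.  Topologies within ``options.tie_margin`` of the best reduced
    chi-square are considered indistinguishable; B<->A<->C is selected
    by default (independent processes) unless another topology wins
    decisively.
    """
    if cluster.n_clusters != 2:
        raise ValueError("topology comparison requires two clusters")
    (kex1, p1), (kex2, p2) = cluster.seed_parameters
    secondary = {
        rid: secondary_dip_guess(profiles_by_residue[rid], shifts[rid],
                                 residue_fits[rid])
        for rid in profiles_by_residue if rid in residue_fits
    }
    results: Dict[str, GlobalFitResult] = {}
    for topo in _LINEAR_TOPOLOGIES:
        exchange0 = ExchangeParameters(topo, kex1, p1, kex2, p2,
                                       temperature=temperature)
        spins0 = _init_spins_for_global(
            profiles_by_residue, residue_fits, cluster, topo, shifts,
            secondary_dw=secondary)
        results[topo.value] = global_fit(
            profiles_by_residue, shifts, topo, exchange0, spins0, options)
    chi2 = {k: r.chi2_red for k, r in results.items()}
    best = min(chi2, key=chi2.get)
    selected = Topology(best)
    if chi2[Topology.LINEAR_BAC.value] - chi2[best] < options.tie_margin:
        selected = Topology.LINEAR_BAC
    for r in results.values():
        r.model_comparison = dict(chi2)
    return selected, results


# --------------------------------------------------------------------------
# staged pipeline

def fit_cest_dataset(
    profiles: Sequence[CESTProfile],
    shifts: Mapping[str, float],
    options: CESTFitOptions = CESTFitOptions(),
    seed: int = 0,
    known_sigma: Optional[float] = None,
    model: str = "auto",
) -> CESTStageResult:
    """Run the full staged CEST analysis on a profile collection.

    ``shifts`` maps residue id to the (known) major-state 15N shift in
    ppm.  ``model`` forces the exchange topology: ``auto`` (default)
    follows the cluster count and topology comparison; ``two_site``
    forces a single process; ``bac``/``abc``/``acb`` force one linear
    three-site topology.  Returns the final global fit together with
    per-residue fits, the cluster assignment and a complete
    inclusion/exclusion audit.
    """
    model_map = {"auto": None, "two_site": Topology.TWO_SITE_AB,
                 "bac": Topology.LINEAR_BAC, "abc": Topology.LINEAR_ABC,
                 "acb": Topology.LINEAR_ACB}
    if model not in model_map:
        raise ValueError(f"unknown model {model!r}; valid: "
                         f"{sorted(model_map)}")
    forced = model_map[model]
    by_res: Dict[str, List[CESTProfile]] = {}
    for p in profiles:
        by_res.setdefault(p.residue_id, []).append(p)
    audit: List[dict] = []
    if known_sigma is not None:
        for pl in by_res.values():
            for p in pl:
                p.sigma = np.full(p.ratios.shape, known_sigma)
    else:
        for pl in by_res.values():
            ensure_sigma(pl, options)

    # stage 1: no-exchange screen
    no_exch: Dict[str, ResidueFit] = {}
    candidates: List[str] = []
    for rid in sorted(by_res):
        ne = fit_no_exchange(by_res[rid], shifts[rid], options)
        no_exch[rid] = ne
        if ne.flagged_exchange:
            candidates.append(rid)
        else:
            audit.append({"stage": "screen", "residue": rid,
                          "included": False, "reason": "no_exchange"})

    # stage 2: per-residue two-site fits
    res_fits: Dict[str, ResidueFit] = {}
    for rid in candidates:
        fit = fit_two_site_per_residue(
            by_res[rid], shifts[rid], options, no_exchange_fit=no_exch[rid])
        res_fits[rid] = fit
        if fit.unidentifiable:
            audit.append({"stage": "per_residue", "residue": rid,
                          "included": False, "reason": "unidentifiable"})

    usable = {r: f for r, f in res_fits.items() if not f.unidentifiable}
    if len(usable) < 2:
        # nothing to fit globally: report a no-exchange outcome
        result = GlobalFitResult(
            exchange=ExchangeParameters(Topology.NONE),
            per_residue={r: f.spins for r, f in no_exch.items()},
            chi2_red=float(np.mean([f.chi2_red for f in no_exch.values()]))
            if no_exch else 0.0,
        )
        for rid in sorted(by_res):
            audit.append({"stage": "final", "residue": rid,
                          "included": False,
                          "reason": "insufficient_candidates"})
        return CESTStageResult(result=result, residue_fits=res_fits,
                               cluster=None, included=set(), audit=audit)

    # stage 3: cluster k_ex / p_B
    cluster = cluster_exchange_parameters(list(usable.values()), options)

    # stage 4: global fit over the clustered residues (two-site, or a
    # three-site topology comparison when two processes are present)
    model_comparison = None
    member_set = set().union(*cluster.clusters)
    members = {r: by_res[r] for r in sorted(member_set)}
    want_two_site = (forced is Topology.TWO_SITE_AB
                     or (forced is None and cluster.n_clusters <= 1))
    if want_two_site:
        topology = Topology.TWO_SITE_AB
        kex0, pb0 = cluster.seed_parameters[0]
        exchange0 = ExchangeParameters(topology, kex0, pb0)
        spins0 = _init_spins_for_global(members, res_fits, cluster,
                                        topology, shifts)
        g = global_fit(members, shifts, topology, exchange0, spins0,
                       options)
    else:
        if cluster.n_clusters < 2:
            raise ValueError(
                "a three-site model needs two exchange-parameter "
                "clusters; only one was found"
            )
        if forced is None:
            topology, all_results = compare_three_site_topologies(
                members, shifts, cluster, res_fits, options)
            g = all_results[topology.value]
            model_comparison = g.model_comparison
        else:
            topology = forced
            (kex1, p1), (kex2, p2) = cluster.seed_parameters
            exchange0 = ExchangeParameters(topology, kex1, p1, kex2, p2)
            secondary = {
                rid: secondary_dip_guess(members[rid], shifts[rid],
                                         res_fits[rid])
                for rid in members if rid in res_fits
            }
            spins0 = _init_spins_for_global(members, res_fits, cluster,
                                            topology, shifts,
                                            secondary_dw=secondary)
            g = global_fit(members, shifts, topology, exchange0, spins0,
                           options)

    # stage 5: fixed-global per-residue refits + consistency MC
    refits: Dict[str, ResidueFit] = {}
    mc_kex: Dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for rid in sorted(by_res):
        refit = _fixed_global_refit(by_res[rid], shifts[rid], g, options)
        refits[rid] = refit
        if rid in res_fits and not res_fits[rid].unidentifiable:
            mc_kex[rid] = _per_residue_mc_kex(
                by_res[rid], shifts[rid], res_fits[rid], options,
                int(rng.integers(2 ** 31 - 1)))
    included, sel_audit = select_residues(refits, no_exch, mc_kex, options)
    for entry in sel_audit:
        entry["stage"] = "selection"
    audit.extend(sel_audit)

    # stage 6: final global fit over included residues, MC uncertainties
    if len(included) >= 1:
        final_profiles = {r: by_res[r] for r in sorted(included)}
        spins0 = {r: g.per_residue[r] for r in sorted(included)}
        final = global_fit(final_profiles, shifts, topology, g.exchange,
                           spins0, options)
        final = monte_carlo_uncertainty(
            final, n_runs=options.mc_runs,
            seed=int(rng.integers(2 ** 31 - 1)), options=options)
        final.model_comparison = model_comparison
    else:
        final = g
    for rid in sorted(by_res):
        audit.append({"stage": "final", "residue": rid,
                      "included": rid in included,
                      "reason": "" if rid in included else "excluded"})
    return CESTStageResult(result=final, residue_fits=res_fits,
                           cluster=cluster, included=included, audit=audit,
                           model_comparison=model_comparison)


def polish_global_fit(
    g: GlobalFitResult,
    profiles_by_residue: Mapping[str, Sequence[CESTProfile]],
    shifts: Mapping[str, float],
    options: CESTFitOptions = CESTFitOptions(),
    chi2_trigger: float = 1.05,
) -> GlobalFitResult:
    """Escape shift-difference local minima of a three-site global fit.

    When only one minor-state dip is visible for a residue, the
    starting value of the other shift difference is ambiguous; a global
    fit can then converge with that residue's dw in the wrong place and
    the shared rate constants biased.  For every residue whose
    contribution to the reduced chi-square is elevated, this step
    re-fits the residue with the global parameters fixed from a grid of
    alternative dw starting values (residual-dip candidates and sign
    flips), keeps the best, and finishes with one more global fit from
    the improved configuration.  The refined result is returned only if
    it lowers the global reduced chi-square.
    """
    exchange = g.exchange
    if not exchange.topology.is_three_site:
        return g
    improved = dict(g.per_residue)
    any_change = False
    for rid in sorted(profiles_by_residue):
        profs = profiles_by_residue[rid]
        spins_cur = g.per_residue[rid]
        chi2 = 0.0
        n = 0
        dev_min, dw_cand = 0.0, None
        for p in profs:
            model = spin.cest_forward(exchange, spins_cur, p.schedule)
            dev = (p.ratios - model) / p.sigma
            chi2 += float(dev @ dev)
            n += dev.size
            i = int(np.argmin(dev))
            if dev[i] < dev_min:
                dev_min = dev[i]
                dw_cand = float(p.schedule.offsets[i] - shifts[rid])
        if chi2 / max(n - 6, 1) < chi2_trigger:
            continue
        a0 = spins_cur.dw_AB
        c0 = spins_cur.dw_AC if spins_cur.dw_AC is not None else 0.3
        cands = [1.5, -1.5]
        if dw_cand is not None and abs(dw_cand) > 0.3:
            cands = [dw_cand, -dw_cand] + cands
        starts = [(a0, c0)]
        starts += [(a0, d) for d in cands] + [(d, c0) for d in cands]
        prob = _Problem(exchange.topology, {rid: profs}, options,
                        fix_global=True, fixed_exchange=exchange,
                        temperature=exchange.temperature)
        prob.set_shifts({rid: shifts[rid]})
        best_x, best_cost = None, np.inf
        for dw_ab, dw_ac in starts:
            x0 = prob.pack(None, {rid: replace(spins_cur, dw_AB=dw_ab,
                                               dw_AC=dw_ac)})
            sol = prob.solve(x0, ftol=1e-6)
            if sol.cost < best_cost:
                best_x, best_cost = sol.x, sol.cost
        # the current configuration is among the starts, so the best
        # refit can only improve this residue's contribution
        _, spins_map = prob.unpack(best_x)
        improved[rid] = spins_map[rid]
        any_change = True
    if not any_change:
        return g
    g2 = global_fit(profiles_by_residue, shifts, exchange.topology,
                    exchange, improved, options)
    return g2 if g2.chi2_red < g.chi2_red else g


def _fixed_global_refit(
    profiles: Sequence[CESTProfile],
    shift_ppm: float,
    global_result: GlobalFitResult,
    options: CESTFitOptions,
) -> ResidueFit:
    rid = profiles[0].residue_id
    exchange = global_result.exchange
    prob = _Problem(exchange.topology, {rid: profiles}, options,
                    fix_global=True, fixed_exchange=exchange,
                    temperature=exchange.temperature)
    prob.set_shifts({rid: shift_ppm})
    spins0 = global_result.per_residue.get(
        rid, ResidueSpinParameters(
            residue_id=rid, dw_AB=1.5,
            dw_AC=0.3 if exchange.topology.is_three_site else None,
            shift_ppm=shift_ppm))
    spins0 = replace(spins0, shift_ppm=shift_ppm)
    x0 = prob.pack(None, {rid: spins0})
    sol = prob.solve(x0)
    chi2, chi2_red = _chi2_stats(prob, sol.x)
    _, spins_map = prob.unpack(sol.x)
    return ResidueFit(
        residue_id=rid, model=("three_site"
                               if exchange.topology.is_three_site
                               else "two_site"),
        spins=spins_map[rid], exchange=exchange, chi2=chi2,
        chi2_red=chi2_red, n_data=prob.n_data, n_params=prob.n_params,
        converged=bool(sol.success),
    )


def _per_residue_mc_kex(
    profiles: Sequence[CESTProfile],
    shift_ppm: float,
    fit: ResidueFit,
    options: CESTFitOptions,
    seed: int,
) -> np.ndarray:
    """k_ex samples from per-residue Monte-Carlo re-fits (k_ex and p_B
    floating), used by the consistency rule."""
    rid = profiles[0].residue_id
    prob = _Problem(Topology.TWO_SITE_AB, {rid: profiles}, options)
    prob.set_shifts({rid: shift_ppm})
    x_base = prob.pack(fit.exchange, {rid: fit.spins})
    exchange, spins_map = prob.unpack(x_base)
    models = [spin.cest_forward(exchange, spins_map[rid], p.schedule)
              for p in profiles]
    rng = np.random.default_rng(seed)
    orig = [p.ratios for p in profiles]
    out = []
    r_base = prob.residuals(x_base)
    J_base = prob.grouped_jacobian(x_base, r_base)
    try:
        for _ in range(options.mc_consistency_runs):
            for p, m in zip(profiles, models):
                p.ratios = m + rng.normal(0.0, 1.0, m.shape) * p.sigma
            x_sol, _ = prob.gn_refit(x_base, tol=options.mc_ftol, J=J_base,
                                     max_steps=10, refresh_every=1000)
            ex_i, _ = prob.unpack(x_sol)
            out.append(ex_i.k_ex_AB)
    finally:
        for p, r in zip(profiles, orig):
            p.ratios = r
    return np.asarray(out)
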