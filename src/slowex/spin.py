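"""Forward models for chemical exchange: Bloch-McConnell CEST propagation,
analytical Carver-Richards CPMG dispersion, and a numerical CPMG propagator.

The magnetization state space is three components (x, y, z) of in-phase
15N magnetization per exchange state, assuming composite-pulse 1H
decoupling during the relaxation delay.  Longitudinal relaxation is
modeled as decay toward zero; the I/I0 normalization of CEST data cancels
the equilibrium term at the saturation delays used here.

Conventions
-----------
* State order is always (A, B[, C]); component order within a state is
  (x, y, z), so the full vector is ``[Ax, Ay, Az, Bx, By, Bz, ...]``.
* The exchange rate matrix K acts on populations as ``dp/dt = K p`` with
  ``K[i, j]`` the rate j -> i.  Every edge of the (linear) topology obeys
  microscopic balance ``k_i->j * p_i = k_j->i * p_j`` at the configured
  equilibrium populations, which are therefore stationary.
* ``nu_cpmg = 1 / (4 tau)`` with ``2 tau`` the spacing between the
  centers of successive (instantaneous, perfect) 180-degree pulses; a
  constant-time period ``T_cp`` accommodates ``n = 2 T_cp nu_cpmg``
  refocusing pulses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._expm import expm_action_batch
from .constants import TWO_PI, NITROGEN_FREQ_600, hz_to_rad_per_s, ppm_to_rad_per_s
from .types import (
    CESTProfile,
    CESTSchedule,
    CPMGSchedule,
    ExchangeParameters,
    ResidueSpinParameters,
    Topology,
    UnsupportedModelError,
)

__all__ = [
    "EvolutionMatrix",
    "exchange_rate_matrix",
    "build_evolution_matrix",
    "simulate_cest_profile",
    "cest_forward",
    "carver_richards_r2eff",
    "numerical_cpmg_r2eff",
    "r2eff_from_intensities",
]


def _chain_edges(topology: Topology):
    """Edges of the linear exchange chain as (i, j, which_rate) with
    state indices A=0, B=1, C=2 and which_rate in {"AB", "AC"}.

    ``k_ex_AB``/``p_B`` always describe minor state B and the edge that
    attaches it to the chain; ``k_ex_AC``/``p_C`` likewise for state C.
    """
    if topology is Topology.TWO_SITE_AB:
        return [(0, 1, "AB")]
    if topology is Topology.LINEAR_BAC:
        return [(0, 1, "AB"), (0, 2, "AC")]
    if topology is Topology.LINEAR_ABC:
        return [(0, 1, "AB"), (1, 2, "AC")]
    if topology is Topology.LINEAR_ACB:
        return [(0, 2, "AC"), (2, 1, "AB")]
    raise UnsupportedModelError(
        f"unsupported exchange topology: {topology}; triangular models "
        "are deliberately not implemented"
    )


def exchange_rate_matrix(exchange: ExchangeParameters) -> np.ndarray:
    """N x N first-order rate matrix of the exchange network.

    Columns sum to zero (probability conservation) and the configured
    populations are the stationary distribution.
    """
    if exchange.topology is Topology.NONE:
        return np.zeros((1, 1))
    pops = exchange.populations
    n = pops.size
    K = np.zeros((n, n))
    for i, j, which in _chain_edges(exchange.topology):
        k_ex = exchange.k_ex_AB if which == "AB" else exchange.k_ex_AC
        denom = pops[i] + pops[j]
        k_ij = k_ex * pops[j] / denom      # rate i -> j
        k_ji = k_ex * pops[i] / denom      # rate j -> i
        K[j, i] += k_ij
        K[i, i] -= k_ij
        K[i, j] += k_ji
        K[j, j] -= k_ji
    return K


def _state_shifts(exchange: ExchangeParameters,
                  spins: ResidueSpinParameters) -> np.ndarray:
    """Absolute chemical shift (ppm) of each state."""
    n = exchange.topology.n_states
    shifts = np.full(n, spins.shift_ppm)
    if n >= 2:
        shifts[1] += spins.dw_AB
    if n == 3:
        shifts[2] += spins.dw_AC if spins.dw_AC is not None else 0.0
    return shifts


@dataclass
class EvolutionMatrix:
    """Bloch-McConnell evolution matrix for one irradiation offset.

    ``matrix`` has shape (3N, 3N) and units of s^-1 / rad s^-1; it
    combines relaxation, exchange, RF nutation and offset terms.
    """

    matrix: np.ndarray
    n_states: int
    populations: np.ndarray


def _base_matrix(exchange: ExchangeParameters,
                 spins: ResidueSpinParameters,
                 B1_hz: float) -> np.ndarray:
    """Offset-independent part: relaxation + exchange + RF nutation."""
    n = exchange.topology.n_states
    dim = 3 * n
    L = np.zeros((dim, dim))
    K = exchange_rate_matrix(exchange)
    # exchange acts identically on x, y, z
    for c in range(3):
        L[c::3, c::3] += K
    w1 = hz_to_rad_per_s(B1_hz)
    for i in range(n):
        r2 = spins.R2 if i == 0 else spins.R2 + spins.dR2
        b = 3 * i
        L[b, b] -= r2
        L[b + 1, b + 1] -= r2
        L[b + 2, b + 2] -= spins.R1
        # B1 along x: dMy/dt -= w1 Mz ; dMz/dt += w1 My
        L[b + 1, b + 2] -= w1
        L[b + 2, b + 1] += w1
    return L


def build_evolution_matrix(
    exchange: ExchangeParameters,
    spins: ResidueSpinParameters,
    B1: float,
    offset: float,
    carrier_freq: float,
) -> EvolutionMatrix:
    """Assemble the Bloch-McConnell matrix for one irradiation position.

    Parameters
    ----------
    B1 : saturation field strength nu1 in Hz.
    offset : irradiation position in ppm (absolute scale).
    carrier_freq : 15N Larmor frequency in MHz (1 ppm == carrier_freq Hz).
    """
    if B1 < 0:
        raise ValueError("B1 must be >= 0")
    L = _base_matrix(exchange, spins, B1)
    shifts = _state_shifts(exchange, spins)
    for i, shift in enumerate(shifts):
        omega = ppm_to_rad_per_s(shift - offset, carrier_freq)
        b = 3 * i
        # rotation about z: dMx/dt = -Omega My ; dMy/dt = +Omega Mx
        L[b, b + 1] = -omega
        L[b + 1, b] = omega
    return EvolutionMatrix(matrix=L, n_states=exchange.topology.n_states,
                           populations=exchange.populations)


def _stacked_matrices(exchange: ExchangeParameters,
                      spins: ResidueSpinParameters,
                      schedule: CESTSchedule) -> np.ndarray:
    """(n_offsets, 3N, 3N) evolution matrices, already scaled by T_EX."""
    base = _base_matrix(exchange, spins, schedule.B1_field)
    shifts = _state_shifts(exchange, spins)
    offs = schedule.offsets
    A = np.broadcast_to(base, (offs.size,) + base.shape).copy()
    for i, shift in enumerate(shifts):
        omega = TWO_PI * (shift - offs) * schedule.spectrometer_15N_freq
        b = 3 * i
        A[:, b, b + 1] = -omega
        A[:, b + 1, b] = omega
    A *= schedule.T_EX
    return A


def cest_forward(exchange: ExchangeParameters,
                 spins: ResidueSpinParameters,
                 schedule: CESTSchedule) -> np.ndarray:
    """Noiseless I/I0 ratios for one residue over the schedule's offsets.

    Initial magnetization is the equilibrium populations on z; the
    reference plane is the T_EX = 0 intensity, so the ratio is
    ``I0 * Mz_A(T_EX) / p_A``.
    """
    if schedule.T_EX <= 0:
        raise ValueError("T_EX must be positive")
    pops = exchange.populations
    n = pops.size
    v0 = np.zeros(3 * n)
    v0[2::3] = pops
    A = _stacked_matrices(exchange, spins, schedule)
    out = expm_action_batch(A, v0)
    return spins.I0 * out[:, 2] / pops[0]


def simulate_cest_profile(exchange: ExchangeParameters,
                          spins: ResidueSpinParameters,
                          schedule: CESTSchedule) -> CESTProfile:
    """Forward-model CEST profile (no noise) as a :class:`CESTProfile`."""
    ratios = cest_forward(exchange, spins, schedule)
    return CESTProfile(residue_id=spins.residue_id, schedule=schedule,
                       ratios=ratios)


def carver_richards_r2eff(
    exchange: ExchangeParameters,
    spins: ResidueSpinParameters,
    nu_cpmg: Union[float, np.ndarray],
    carrier_freq: float = NITROGEN_FREQ_600,
) -> Union[float, np.ndarray]:
    """Analytical two-site effective relaxation rate (Carver-Richards).

    Valid for two-site exchange only; reduces exactly to R2 when p_B = 0
    or dw = 0 (with dR2 = 0).  ``nu_cpmg`` may be scalar or array (Hz).
    """
    if exchange.topology.is_three_site:
        raise UnsupportedModelError(
            "the analytical Carver-Richards expression is two-site only"
        )
    nu = np.asarray(nu_cpmg, dtype=float)
    scalar = nu.ndim == 0
    nu = np.atleast_1d(nu)
    r2a = spins.R2
    if exchange.topology is Topology.NONE or exchange.p_B == 0.0:
        out = np.full_like(nu, r2a)
        return float(out[0]) if scalar else out
    r2b = spins.R2 + spins.dR2
    p_b = exchange.p_B
    p_a = 1.0 - p_b
    kex = exchange.k_ex_AB
    dw = ppm_to_rad_per_s(spins.dw_AB, carrier_freq)
    fact = r2a - r2b - kex + 2.0 * p_a * kex          # = dR2' + k_BA - k_AB
    psi = fact * fact - dw * dw + 4.0 * p_a * p_b * kex * kex
    zeta = 2.0 * dw * fact
    root = np.sqrt(psi * psi + zeta * zeta)
    eta_scale = 2.0 ** (-1.5) / nu
    etapos = eta_scale * np.sqrt(np.maximum(psi + root, 0.0))
    etaneg = eta_scale * np.sqrt(np.maximum(root - psi, 0.0))
    if root == 0.0:                                   # degenerate dw = 0, kex = 0
        out = np.full_like(nu, r2a)
        return float(out[0]) if scalar else out
    dpos = 0.5 * (1.0 + (psi + 2.0 * dw * dw) / root)
    dneg = 0.5 * (-1.0 + (psi + 2.0 * dw * dw) / root)
    arg = dpos * np.cosh(etapos) - dneg * np.cos(etaneg)
    arg = np.maximum(arg, 1.0)
    out = 0.5 * (r2a + r2b + kex) - nu * np.arccosh(arg)
    return float(out[0]) if scalar else out


def _transverse_generator(exchange: ExchangeParameters,
                          spins: ResidueSpinParameters,
                          carrier_freq: float) -> np.ndarray:
    """Complex N x N generator of transverse (M+) evolution, with the
    major state on resonance."""
    K = exchange_rate_matrix(exchange)
    shifts = _state_shifts(exchange, spins)
    n = shifts.size
    L = K.astype(complex)
    for i in range(n):
        r2 = spins.R2 if i == 0 else spins.R2 + spins.dR2
        omega = ppm_to_rad_per_s(shifts[i] - spins.shift_ppm, carrier_freq)
        L[i, i] += -r2 + 1j * omega
    return L


def numerical_cpmg_r2eff(
    exchange: ExchangeParameters,
    spins: ResidueSpinParameters,
    schedule: CPMGSchedule,
    nu: float,
    carrier_freq: float = NITROGEN_FREQ_600,
) -> float:
    """R2,eff from explicit propagation of the constant-time CPMG block.

    Brute-force reference for :func:`carver_richards_r2eff`: free
    precession is propagated with the matrix exponential of the complex
    transverse generator and each (instantaneous, perfect) 180x pulse
    conjugates the transverse magnetization.  Works for any supported
    topology.
    """
    from scipy.linalg import expm

    n_echo_f = 2.0 * schedule.T_cp * nu
    n_echo = int(round(n_echo_f))
    if n_echo < 1 or abs(n_echo_f - n_echo) > 1e-6:
        raise ValueError(
            f"nu_cpmg = {nu} Hz does not fit an integer number of echoes "
            f"into T_cp = {schedule.T_cp} s"
        )
    tau = schedule.T_cp / (2.0 * n_echo)
    L = _transverse_generator(exchange, spins, carrier_freq)
    P = expm(L * tau)
    m = exchange.populations.astype(complex)
    p_a = exchange.populations[0]
    for _ in range(n_echo):
        m = P @ np.conj(P @ m)
    intensity = float(np.real(m[0]))
    if intensity <= 0:
        return float("inf")
    return -np.log(intensity / p_a) / schedule.T_cp


def r2eff_from_intensities(
    I: Union[float, np.ndarray],
    I0: Union[float, np.ndarray],
    T_cp: float,
) -> Union[float, np.ndarray]:
    """Constant-time conversion ``R2,eff = -ln(I/I0) / T_cp``.

    Non-positive intensities cannot be converted; they are returned as
    NaN (flagged below-noise) with a warning.
    """
    if T_cp <= 0:
        raise ValueError("T_cp must be positive")
    I_arr = np.asarray(I, dtype=float)
    I0_arr = np.asarray(I0, dtype=float)
    if np.any(I0_arr <= 0):
        raise ValueError("reference intensity I0 must be positive")
    scalar = I_arr.ndim == 0
    I_arr = np.atleast_1d(I_arr)
    bad = I_arr <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} intensity point(s) <= 0 flagged below noise "
            "and excluded (NaN)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, -np.log(I_arr / I0_arr) / T_cp)
    return float(out[0]) if scalar else out
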