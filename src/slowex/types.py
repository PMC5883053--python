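"""Domain types shared by all analysis stages.

The containers are plain frozen-ish dataclasses with eager validation:
invalid physical parameters raise ``ValueError`` at construction time so
that fitting code never has to re-check them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


class Topology(str, enum.Enum):
    """Kinetic topology of the exchange model.

    ``TWO_SITE_AB``: major state A exchanging with one minor state B.
    ``LINEAR_BAC``: B <-> A <-> C, both minor states exchange with the
    major state and the two processes are independent.
    ``LINEAR_ABC``: A <-> B <-> C, minor state C connects through B.
    ``LINEAR_ACB``: A <-> C <-> B, minor state B connects through C
    (the least-populated minor state as intermediate).
    """

    TWO_SITE_AB = "two_site_AB"
    LINEAR_BAC = "linear_BAC"
    LINEAR_ABC = "linear_ABC"
    LINEAR_ACB = "linear_ACB"
    NONE = "none"

    @property
    def n_states(self) -> int:
        if self is Topology.NONE:
            return 1
        if self is Topology.TWO_SITE_AB:
            return 2
        return 3

    @property
    def is_three_site(self) -> bool:
        return self.n_states == 3


class UnsupportedModelError(ValueError):
    """Raised for exchange topologies the package deliberately excludes
    (e.g. the triangular three-site model)."""


@dataclass
class ExchangeParameters:
    """Kinetic/population parameters of an N-state exchange model.

    ``k_ex_AB`` is the sum of forward and reverse rate constants of the
    A/B pair (k_AB + k_BA); ``p_B`` the equilibrium population of minor
    state B.  For linear three-site topologies the second pair is
    described by ``k_ex_AC``/``p_C`` (the edge involving state C,
    whichever state it connects to in the chosen chain).
    """

    topology: Topology
    k_ex_AB: float = 0.0
    p_B: float = 0.0
    k_ex_AC: Optional[float] = None
    p_C: Optional[float] = None
    temperature: float = 283.15

    def __post_init__(self) -> None:
        self.topology = Topology(self.topology)
        if self.topology.is_three_site:
            if self.k_ex_AC is None or self.p_C is None:
                raise ValueError(
                    "three-site topology requires k_ex_AC and p_C"
                )
            if not (0.0 < self.p_C < 1.0):
                raise ValueError(f"p_C must lie in (0, 1), got {self.p_C}")
            if self.k_ex_AC < 0:
                raise ValueError("rate constants must be >= 0")
        elif self.topology is Topology.TWO_SITE_AB:
            if self.k_ex_AC is not None or self.p_C is not None:
                raise ValueError("k_ex_AC/p_C only valid for three-site models")
        if self.topology is not Topology.NONE:
            if not (0.0 < self.p_B < 1.0):
                raise ValueError(f"p_B must lie in (0, 1), got {self.p_B}")
            if self.p_B + (self.p_C or 0.0) >= 1.0:
                raise ValueError("p_B + p_C must be < 1")
            if self.k_ex_AB < 0:
                raise ValueError("rate constants must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def populations(self) -> np.ndarray:
        """Equilibrium populations in state order (A, B[, C])."""
        if self.topology is Topology.NONE:
            return np.array([1.0])
        if self.topology is Topology.TWO_SITE_AB:
            return np.array([1.0 - self.p_B, self.p_B])
        return np.array([1.0 - self.p_B - self.p_C, self.p_B, self.p_C])


@dataclass
class ResidueSpinParameters:
    """Per-residue spin parameters entering the forward models.

    ``dw_AB``/``dw_AC`` are minor-state chemical-shift differences
    relative to the major state (ppm, signed); ``shift_ppm`` is the
    major-state 15N chemical shift, taken as known from the assigned
    spectrum.  ``dR2`` is the excess transverse relaxation of the minor
    state(s), shared across minor states.
    """

    residue_id: str
    dw_AB: float = 0.0
    dw_AC: Optional[float] = None
    R1: float = 1.5
    R2: float = 12.0
    dR2: float = 0.0
    I0: float = 1.0
    shift_ppm: float = 118.0

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError("R1 and R2 must be positive")
        if self.R2 + self.dR2 <= 0:
            raise ValueError("minor-state R2 (R2 + dR2) must be positive")


@dataclass
class CESTSchedule:
    """Acquisition schedule of one CEST experiment (one B1 field)."""

    B1_field: float                      # saturation field nu1, Hz
    T_EX: float                          # saturation delay, s
    offsets: np.ndarray                  # irradiation positions, ppm
    spectrometer_15N_freq: float         # MHz, for ppm <-> Hz
    includes_reference: bool = True

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.B1_field < 0:
            raise ValueError("B1_field must be >= 0")
        if self.T_EX <= 0:
            raise ValueError("T_EX must be positive")
        if self.offsets.size == 0:
            raise ValueError("offset list must be non-empty")
        d = np.diff(self.offsets)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("offsets must be strictly monotone")


@dataclass
class CESTProfile:
    """I/I0 versus irradiation offset for one residue at one B1 field."""

    residue_id: str
    schedule: CESTSchedule
    ratios: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != self.schedule.offsets.shape:
            raise ValueError("ratios must align with schedule offsets")
        if self.sigma is not None:
            self.sigma = np.broadcast_to(
                np.asarray(self.sigma, dtype=float), self.ratios.shape
            ).copy()
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive once estimated")


@dataclass
class CPMGSchedule:
    """Constant-time CPMG schedule at one temperature."""

    nu_cpmg: np.ndarray                  # refocusing frequencies, Hz
    T_cp: float = 0.040                  # constant-time relaxation period, s
    temperature: float = 283.15          # K
    duplicated_points: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("nu_cpmg values must be positive")
        if self.T_cp <= 0:
            raise ValueError("T_cp must be positive")


@dataclass
class CPMGProfile:
    """R2,eff versus nu_CPMG for one residue at one temperature.

    ``nu_values`` carries one entry per measured point (duplicated
    frequencies appear twice), aligned with ``R2_eff``.
    """

    residue_id: str
    schedule: CPMGSchedule
    nu_values: np.ndarray
    R2_eff: np.ndarray
    sigma_R2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.nu_values = np.asarray(self.nu_values, dtype=float)
        self.R2_eff = np.asarray(self.R2_eff, dtype=float)
        if self.nu_values.shape != self.R2_eff.shape:
            raise ValueError("nu_values and R2_eff must align")
        if not np.all(np.isfinite(self.R2_eff)):
            raise ValueError("R2_eff must be finite")
        if self.sigma_R2 is not None:
            self.sigma_R2 = np.broadcast_to(
                np.asarray(self.sigma_R2, dtype=float), self.R2_eff.shape
            ).copy()

    def duplicate_mask(self) -> np.ndarray:
        """Boolean mask of points whose frequency occurs more than once."""
        _, inv, counts = np.unique(
            self.nu_values, return_inverse=True, return_counts=True
        )
        return counts[inv] > 1


@dataclass
class TitrationSeries:
    """Cross-peak positions of one residue across ligand concentrations."""

    residue_id: str
    ligand_concentrations: np.ndarray    # mM, first point apo (0)
    protein_concentration: float         # mM
    positions: np.ndarray                # (n, 2): (delta_H, delta_N) ppm

    def __post_init__(self) -> None:
        self.ligand_concentrations = np.asarray(
            self.ligand_concentrations, dtype=float
        )
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(self.ligand_concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.ligand_concentrations[0] != 0.0:
            raise ValueError("first titration point must be apo (0 mM)")
        if self.protein_concentration <= 0:
            raise ValueError("protein concentration must be positive")
        if self.positions.shape != (self.ligand_concentrations.size, 2):
            raise ValueError("need one (dH, dN) position per concentration")


@dataclass
class AssayCurve:
    """Absorbance progress curve of the isomerase-coupled assay."""

    times: np.ndarray                    # s
    absorbance: np.ndarray               # AU at 390 nm
    enzyme_concentration: float          # M; 0 for background

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.size < 8:
            raise ValueError("progress curve needs >= 8 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must align")
        if self.enzyme_concentration < 0:
            raise ValueError("enzyme concentration must be >= 0")


@dataclass
class GlobalFitResult:
    """Result of a global CEST fit: shared exchange parameters plus
    per-residue nuisance parameters and Monte-Carlo draws."""

    exchange: ExchangeParameters
    per_residue: Dict[str, ResidueSpinParameters]
    chi2_red: float
    mc_samples: Optional[Dict[str, np.ndarray]] = None
    standard_errors: Optional[Dict[str, float]] = None
    model_comparison: Optional[Dict[str, float]] = None
    n_data: int = 0
    n_params: int = 0

    def __post_init__(self) -> None:
        if self.chi2_red < 0:
            raise ValueError("chi2_red must be >= 0")
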