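"""Synthetic CEST, CPMG, titration, and assay data with known ground truth.

Every generator draws from the forward models in :mod:`slowex.spin` and
adds configurable Gaussian noise, so that each fitting stage can be
validated against a dataset whose exchange parameters, populations and
shift differences are known exactly.  The built-in scenarios mirror the
exchange regimes characterized for the cyclophilin A rescue-mutant
series: a single two-site slow process ("S99T-like") and two independent
slow processes requiring a linear three-site B<->A<->C model
("double-like", "triple-like").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import spin
from .constants import NITROGEN_FREQ_500, NITROGEN_FREQ_600
from .types import (
    AssayCurve,
    CESTProfile,
    CESTSchedule,
    CPMGProfile,
    CPMGSchedule,
    ExchangeParameters,
    ResidueSpinParameters,
    TitrationSeries,
    Topology,
)

__all__ = [
    "ScenarioTruth",
    "SCENARIO_EXCHANGE",
    "make_scenario",
    "default_cest_schedules",
    "default_cpmg_schedule",
    "generate_cest_dataset",
    "generate_cpmg_dataset",
    "generate_titration_dataset",
    "generate_assay_curves",
]

#: Exchange parameters of the built-in scenarios (at 283.15 K).
SCENARIO_EXCHANGE: Dict[str, ExchangeParameters] = {
    "S99T-like": ExchangeParameters(
        Topology.TWO_SITE_AB, k_ex_AB=188.3, p_B=0.0122
    ),
    "double-like": ExchangeParameters(
        Topology.LINEAR_BAC, k_ex_AB=422.9, p_B=0.0193,
        k_ex_AC=177.7, p_C=0.0031,
    ),
    "triple-like": ExchangeParameters(
        Topology.LINEAR_BAC, k_ex_AB=265.1, p_B=0.0432,
        k_ex_AC=186.5, p_C=0.0073,
    ),
}

# Residue-number pools used for labels: a catalysis-coupled core network
# ("process1") and an active-site-adjacent loop ("process2"), following
# cyclophilin A numbering so that audit logs read naturally.
_PROCESS1_POOL = [55, 57, 91, 97, 98, 99, 101, 102, 107, 109, 110, 113,
                  115, 117, 120, 121, 122, 126]
_PROCESS2_POOL = [65, 66, 67, 68, 69, 70, 71, 72, 73, 74, 75, 76, 78, 79, 80]
_OTHER_POOL = list(range(2, 50))


@dataclass
class ScenarioTruth:
    """Ground truth of a synthetic scenario.

    ``group_assignment`` maps each residue to the exchange process(es)
    its chemical shift senses: ``process1`` (dw_AB != 0), ``process2``
    (dw_AC != 0), ``both``, or ``none``.
    """

    name: str
    exchange: ExchangeParameters
    per_residue: Dict[str, ResidueSpinParameters]
    group_assignment: Dict[str, str]
    noise_sd: float = 0.005           # relative sd on I/I0
    noise_sd_r2: float = 0.3          # absolute sd on R2,eff (s^-1)
    temperature_factor: float = 1.8   # k_ex scaling per +5 K

    def __post_init__(self) -> None:
        missing = set(self.per_residue) - set(self.group_assignment)
        if missing:
            raise ValueError(f"residues without group assignment: {missing}")

    # -- truth sidecar -------------------------------------------------
    def to_dict(self) -> dict:
        ex = self.exchange
        return {
            "name": self.name,
            "exchange": {
                "topology": ex.topology.value,
                "k_ex_AB": ex.k_ex_AB,
                "p_B": ex.p_B,
                "k_ex_AC": ex.k_ex_AC,
                "p_C": ex.p_C,
                "temperature": ex.temperature,
            },
            "per_residue": {
                rid: {
                    "dw_AB": s.dw_AB,
                    "dw_AC": s.dw_AC,
                    "R1": s.R1,
                    "R2": s.R2,
                    "dR2": s.dR2,
                    "I0": s.I0,
                    "shift_ppm": s.shift_ppm,
                }
                for rid, s in self.per_residue.items()
            },
            "group_assignment": dict(self.group_assignment),
            "noise_sd": self.noise_sd,
            "noise_sd_r2": self.noise_sd_r2,
            "temperature_factor": self.temperature_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioTruth":
        exd = d["exchange"]
        exchange = ExchangeParameters(
            Topology(exd["topology"]), exd["k_ex_AB"], exd["p_B"],
            exd["k_ex_AC"], exd["p_C"], exd["temperature"],
        )
        per_residue = {
            rid: ResidueSpinParameters(residue_id=rid, **s)
            for rid, s in d["per_residue"].items()
        }
        return cls(
            name=d["name"], exchange=exchange, per_residue=per_residue,
            group_assignment=dict(d["group_assignment"]),
            noise_sd=d["noise_sd"], noise_sd_r2=d["noise_sd_r2"],
            temperature_factor=d["temperature_factor"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _draw_spins(rng: np.ndarray, rid: str, group: str,
                three_site: bool) -> ResidueSpinParameters:
    def draw_dw() -> float:
        return float(rng.uniform(1.0, 5.0) * rng.choice([-1.0, 1.0]))

    dw_ab = draw_dw() if group in ("process1", "both") else 0.0
    dw_ac: Optional[float] = None
    if three_site:
        dw_ac = draw_dw() if group in ("process2", "both") else 0.0
    return ResidueSpinParameters(
        residue_id=rid,
        dw_AB=dw_ab,
        dw_AC=dw_ac,
        R1=float(rng.uniform(1.0, 2.0)),
        R2=float(rng.uniform(8.0, 20.0)),
        dR2=0.0,
        I0=1.0,
        shift_ppm=float(rng.uniform(108.0, 128.0)),
    )


def make_scenario(
    name: str,
    n_residues_per_group: int = 5,
    seed: int = 0,
    noise_sd: float = 0.005,
    n_non_exchanging: int = 0,
) -> ScenarioTruth:
    """Build a ground-truth scenario with the given residue count per group.

    Two-site scenarios have a single ``process1`` group; three-site
    scenarios have ``process1``, ``process2`` and ``both`` groups.
    ``n_non_exchanging`` extra flat residues can be added for
    false-positive control experiments.
    """
    if name not in SCENARIO_EXCHANGE:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: "
            f"{sorted(SCENARIO_EXCHANGE)}"
        )
    exchange = SCENARIO_EXCHANGE[name]
    three = exchange.topology.is_three_site
    rng = np.random.default_rng(seed)
    groups = ["process1", "process2", "both"] if three else ["process1"]
    per_residue: Dict[str, ResidueSpinParameters] = {}
    assignment: Dict[str, str] = {}
    pools = {"process1": _PROCESS1_POOL, "process2": _PROCESS2_POOL,
             "both": _PROCESS1_POOL[::-1], "none": _OTHER_POOL}
    used = set()
    for group in groups:
        count = 0
        for num in pools[group]:
            if count >= n_residues_per_group:
                break
            if num in used:
                continue
            used.add(num)
            rid = f"R{num}"
            per_residue[rid] = _draw_spins(rng, rid, group, three)
            assignment[rid] = group
            count += 1
    for k in range(n_non_exchanging):
        num = _OTHER_POOL[k % len(_OTHER_POOL)]
        rid = f"N{num}_{k}"
        per_residue[rid] = _draw_spins(rng, rid, "none", three)
        assignment[rid] = "none"
    return ScenarioTruth(
        name=name, exchange=exchange, per_residue=per_residue,
        group_assignment=assignment, noise_sd=noise_sd,
    )


def default_cest_schedules(
    name: str = "S99T-like",
    spacing_hz: float = 20.0,
    spectrometer_15N_freq: float = NITROGEN_FREQ_500,
    window_ppm: Tuple[float, float] = (97.0, 139.5),
) -> List[CESTSchedule]:
    """CEST schedules patterned on the study acquisitions.

    The B1 fields and saturation delays follow the acquisition settings
    used for each variant (e.g. 16.3/29.7 Hz with T_EX = 0.5 s for the
    single mutant, 10.8/22.0 Hz with T_EX = 0.4 s for the triple
    mutant); ``spacing_hz`` sets the offset-grid increment (20-25 Hz in
    the original schedules; coarser grids speed up simulation studies).
    """
    setups = {
        "S99T-like": [(16.3, 0.5), (29.7, 0.5)],
        "double-like": [(12.2, 0.5), (23.6, 0.4), (34.7, 0.5)],
        "triple-like": [(10.8, 0.4), (22.0, 0.4)],
    }
    if name not in setups:
        raise ValueError(f"unknown scenario {name!r}")
    lo, hi = window_ppm
    step_ppm = spacing_hz / spectrometer_15N_freq
    n = int(np.floor((hi - lo) / step_ppm)) + 1
    offsets = lo + step_ppm * np.arange(n)
    return [
        CESTSchedule(B1_field=b1, T_EX=tex, offsets=offsets,
                     spectrometer_15N_freq=spectrometer_15N_freq)
        for b1, tex in setups[name]
    ]


def default_cpmg_schedule(temperature: float = 283.15) -> CPMGSchedule:
    """The 40-ms constant-time CPMG schedule with duplicates at
    200, 800 and 1000 Hz."""
    nu = np.array([100, 200, 300, 400, 500, 600, 700, 800, 900, 950, 1000],
                  dtype=float)
    return CPMGSchedule(nu_cpmg=nu, T_cp=0.040, temperature=temperature,
                        duplicated_points=(200.0, 800.0, 1000.0))


def generate_cest_dataset(
    truth: ScenarioTruth,
    schedules: Sequence[CESTSchedule],
    seed: int = 0,
) -> List[CESTProfile]:
    """Noisy CEST profiles for every residue at every schedule.

    i.i.d. Gaussian noise of sd ``truth.noise_sd`` is added to I/I0.
    Profiles whose minor-state dip would fall outside the offset grid
    trigger a warning (the dip is unobservable in that window).
    """
    if not schedules:
        raise ValueError("at least one CEST schedule is required")
    rng = np.random.default_rng(seed)
    profiles: List[CESTProfile] = []
    for rid in sorted(truth.per_residue):
        spins = truth.per_residue[rid]
        for sched in schedules:
            lo, hi = sched.offsets.min(), sched.offsets.max()
            for dw in (spins.dw_AB, spins.dw_AC or 0.0):
                if dw != 0.0 and not (lo <= spins.shift_ppm + dw <= hi):
                    warnings.warn(
                        f"minor-state dip of {rid} at "
                        f"{spins.shift_ppm + dw:.1f} ppm is outside the "
                        f"offset grid [{lo:.1f}, {hi:.1f}] and will not "
                        "be observable",
                        stacklevel=2,
                    )
            ratios = spin.cest_forward(truth.exchange, spins, sched)
            if truth.noise_sd > 0:
                ratios = ratios + rng.normal(0.0, truth.noise_sd,
                                             ratios.shape)
            profiles.append(
                CESTProfile(residue_id=rid, schedule=sched, ratios=ratios)
            )
    return profiles


def _scaled_exchange(truth: ScenarioTruth,
                     temperature: float) -> ExchangeParameters:
    """Exchange parameters with k_ex scaled by the configured factor per
    +5 K relative to the truth temperature (populations unchanged)."""
    base = truth.exchange
    scale = truth.temperature_factor ** (
        (temperature - base.temperature) / 5.0
    )
    return ExchangeParameters(
        base.topology,
        k_ex_AB=base.k_ex_AB * scale,
        p_B=base.p_B,
        k_ex_AC=None if base.k_ex_AC is None else base.k_ex_AC * scale,
        p_C=base.p_C,
        temperature=temperature,
    )


def generate_cpmg_dataset(
    truth: ScenarioTruth,
    schedules: Sequence[CPMGSchedule],
    seed: int = 0,
) -> List[CPMGProfile]:
    """Noisy CPMG dispersion profiles (one per residue per schedule).

    Duplicated frequencies are drawn independently so pooled-error
    estimation is exercised.  Two-site truths use the analytical forward
    model; three-site truths use numerical propagation.
    """
    rng = np.random.default_rng(seed)
    profiles: List[CPMGProfile] = []
    for rid in sorted(truth.per_residue):
        spins = truth.per_residue[rid]
        for sched in schedules:
            exchange = _scaled_exchange(truth, sched.temperature)
            nu_all = np.concatenate(
                [sched.nu_cpmg, np.asarray(sched.duplicated_points)]
            )
            nu_all.sort()
            if (exchange.topology is Topology.TWO_SITE_AB
                    and (spins.dw_AC in (None, 0.0))):
                r2 = np.asarray(
                    spin.carver_richards_r2eff(
                        exchange, spins, nu_all,
                        carrier_freq=NITROGEN_FREQ_600)
                )
            elif exchange.topology is Topology.NONE or (
                    spins.dw_AB == 0.0 and (spins.dw_AC in (None, 0.0))):
                r2 = np.full(nu_all.shape, spins.R2)
            else:
                r2 = np.array([
                    spin.numerical_cpmg_r2eff(
                        exchange, spins, sched, nu,
                        carrier_freq=NITROGEN_FREQ_600)
                    for nu in nu_all
                ])
            if truth.noise_sd_r2 > 0:
                r2 = r2 + rng.normal(0.0, truth.noise_sd_r2, r2.shape)
            profiles.append(
                CPMGProfile(residue_id=rid, schedule=sched,
                            nu_values=nu_all, R2_eff=r2)
            )
    return profiles


def bound_fraction(L_tot: np.ndarray, P_tot: float,
                   K_D: float) -> np.ndarray:
    """Exact single-site bound fraction of the protein (quadratic in the
    total concentrations; no free-ligand approximation)."""
    L = np.asarray(L_tot, dtype=float)
    s = L + P_tot + K_D
    return (s - np.sqrt(s * s - 4.0 * L * P_tot)) / (2.0 * P_tot)


def generate_titration_dataset(
    kd: float,
    dmax: Mapping[str, Tuple[float, float]],
    concentrations: Sequence[float] = (0.0, 1.0, 3.0, 5.0, 9.0),
    protein_conc: float = 0.25,
    seed: int = 0,
    noise_h: float = 0.002,
    noise_n: float = 0.01,
) -> List[TitrationSeries]:
    """Titration peak positions for residues with given saturation shifts.

    ``dmax`` maps residue id -> (ddelta_H_sat, ddelta_N_sat) in ppm; the
    observed position moves by the bound fraction times that endpoint
    (fast-exchange averaging), plus Gaussian positional noise.
    """
    if kd <= 0:
        raise ValueError("K_D must be positive")
    if protein_conc <= 0:
        raise ValueError("protein concentration must be positive")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    frac = bound_fraction(conc, protein_conc, kd)
    out: List[TitrationSeries] = []
    for rid in sorted(dmax):
        dh_sat, dn_sat = dmax[rid]
        base = np.array([rng.uniform(7.0, 9.5), rng.uniform(105.0, 130.0)])
        pos = base[None, :] + np.column_stack(
            [frac * dh_sat, frac * dn_sat]
        )
        if noise_h > 0 or noise_n > 0:
            pos = pos + np.column_stack([
                rng.normal(0.0, noise_h, conc.size),
                rng.normal(0.0, noise_n, conc.size),
            ])
            pos[0] = base  # the apo position defines the reference
        out.append(
            TitrationSeries(residue_id=rid, ligand_concentrations=conc,
                            protein_concentration=protein_conc,
                            positions=pos)
        )
    return out


def generate_assay_curves(
    kcat_over_km: float,
    k0: float,
    enzyme_concs: Sequence[float],
    seed: int = 0,
    n_replicates: int = 3,
    noise_sd: float = 0.002,
    n_points: int = 40,
) -> List[AssayCurve]:
    """Single-exponential absorbance progress curves of the coupled assay.

    Observed rate ``k_obs = k0 + (kcat/KM) * [E]``; background curves
    ([E] = 0) are generated in triplicate.  A warning is emitted when the
    catalyzed/background rate ratio falls outside the 3-15x design
    window.
    """
    rng = np.random.default_rng(seed)
    curves: List[AssayCurve] = []
    all_concs = [0.0] * n_replicates + [
        c for c in enzyme_concs for _ in range(n_replicates)
    ]
    for conc in all_concs:
        k_obs = k0 + kcat_over_km * conc
        if conc > 0:
            ratio = k_obs / k0
            if not (3.0 <= ratio <= 15.0):
                warnings.warn(
                    f"[E] = {conc:.2e} M gives k_obs/k0 = {ratio:.1f}, "
                    "outside the 3-15x design window",
                    stacklevel=2,
                )
        t_end = 4.0 / k_obs
        times = np.linspace(0.0, t_end, n_points)
        a0, da = 0.10, 0.50
        absorbance = a0 + da * (1.0 - np.exp(-k_obs * times))
        if noise_sd > 0:
            absorbance = absorbance + rng.normal(0.0, noise_sd, times.shape)
        curves.append(
            AssayCurve(times=times, absorbance=absorbance,
                       enzyme_concentration=conc)
        )
    return curves
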