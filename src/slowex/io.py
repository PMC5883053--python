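"""Tabular I/O: long-format TSV/CSV data tables and fit reports.

Schemas (one row per (residue, condition, point); tab-separated by
default, comma accepted):

``cest``
    residue_id, shift_ppm, B1_hz, T_EX_s, spectrometer_MHz, offset_ppm,
    ratio [, sigma]
``cpmg``
    residue_id, temperature_K, T_cp_s, nu_cpmg_hz, R2_eff [, sigma]
``titration``
    residue_id, protein_mM, ligand_mM, delta_H_ppm, delta_N_ppm
``assay``
    curve_id, enzyme_M, time_s, absorbance

Floating-point values are written with ``repr`` so that a
write -> read -> write cycle is byte-identical.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import (
    AssayCurve,
    CESTProfile,
    CESTSchedule,
    CPMGProfile,
    CPMGSchedule,
    ExchangeParameters,
    GlobalFitResult,
    TitrationSeries,
)

__all__ = [
    "SchemaError",
    "read_profile_table",
    "write_cest_table",
    "write_cpmg_table",
    "write_titration_table",
    "write_assay_table",
    "write_fit_report",
    "read_fit_report",
]

_REQUIRED = {
    "cest": ["residue_id", "shift_ppm", "B1_hz", "T_EX_s",
             "spectrometer_MHz", "offset_ppm", "ratio"],
    "cpmg": ["residue_id", "temperature_K", "T_cp_s", "nu_cpmg_hz",
             "R2_eff"],
    "titration": ["residue_id", "protein_mM", "ligand_mM", "delta_H_ppm",
                  "delta_N_ppm"],
    "assay": ["curve_id", "enzyme_M", "time_s", "absorbance"],
}


class SchemaError(ValueError):
    """A table does not match the documented schema."""


def _read_table(path: Union[str, os.PathLike], kind: str) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#",
                     float_precision="round_trip")
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for kind "
            f"{kind!r}"
        )
    numeric = [c for c in _REQUIRED[kind] if c not in
               ("residue_id", "curve_id")]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header+1-based
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in "
                f"column {col!r} at line {line}"
            )
        df[col] = converted
    return df


def read_profile_table(path: Union[str, os.PathLike], kind: str):
    """Read a typed profile collection from a long-format table.

    ``kind`` selects the schema: ``cest`` -> list of
    :class:`CESTProfile`, ``cpmg`` -> list of :class:`CPMGProfile`,
    ``titration`` -> list of :class:`TitrationSeries`, ``assay`` ->
    list of :class:`AssayCurve`.  Duplicate (residue, nu_CPMG) rows in
    CPMG tables are retained (they feed pooled-error estimation).
    """
    if kind not in _REQUIRED:
        raise ValueError(f"unknown table kind {kind!r}; expected one of "
                         f"{sorted(_REQUIRED)}")
    df = _read_table(path, kind)
    if kind == "cest":
        return _cest_from_frame(df)
    if kind == "cpmg":
        return _cpmg_from_frame(df)
    if kind == "titration":
        return _titration_from_frame(df)
    return _assay_from_frame(df)


def _cest_from_frame(df: pd.DataFrame) -> List[CESTProfile]:
    out = []
    keys = ["residue_id", "B1_hz", "T_EX_s", "spectrometer_MHz"]
    for (rid, b1, tex, freq), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("offset_ppm")
        sched = CESTSchedule(B1_field=float(b1), T_EX=float(tex),
                             offsets=grp["offset_ppm"].to_numpy(),
                             spectrometer_15N_freq=float(freq))
        sigma = (grp["sigma"].to_numpy()
                 if "sigma" in grp and grp["sigma"].notna().all() else None)
        prof = CESTProfile(residue_id=str(rid), schedule=sched,
                           ratios=grp["ratio"].to_numpy(), sigma=sigma)
        prof.shift_ppm = float(grp["shift_ppm"].iloc[0])
        out.append(prof)
    return out


def _cpmg_from_frame(df: pd.DataFrame) -> List[CPMGProfile]:
    out = []
    for (rid, temp, tcp), grp in df.groupby(
            ["residue_id", "temperature_K", "T_cp_s"], sort=True):
        grp = grp.sort_values("nu_cpmg_hz", kind="stable")
        nu = grp["nu_cpmg_hz"].to_numpy()
        dup = tuple(sorted({float(v) for v, c in
                            zip(*np.unique(nu, return_counts=True))
                            if c > 1}))
        sched = CPMGSchedule(nu_cpmg=np.unique(nu), T_cp=float(tcp),
                             temperature=float(temp),
                             duplicated_points=dup)
        sigma = (grp["sigma"].to_numpy()
                 if "sigma" in grp and grp["sigma"].notna().all() else None)
        out.append(CPMGProfile(residue_id=str(rid), schedule=sched,
                               nu_values=nu,
                               R2_eff=grp["R2_eff"].to_numpy(),
                               sigma_R2=sigma))
    return out


def _titration_from_frame(df: pd.DataFrame) -> List[TitrationSeries]:
    out = []
    for (rid, pconc), grp in df.groupby(["residue_id", "protein_mM"],
                                        sort=True):
        grp = grp.sort_values("ligand_mM")
        out.append(TitrationSeries(
            residue_id=str(rid),
            ligand_concentrations=grp["ligand_mM"].to_numpy(),
            protein_concentration=float(pconc),
            positions=grp[["delta_H_ppm", "delta_N_ppm"]].to_numpy(),
        ))
    return out


def _assay_from_frame(df: pd.DataFrame) -> List[AssayCurve]:
    out = []
    for (cid, conc), grp in df.groupby(["curve_id", "enzyme_M"],
                                       sort=True):
        grp = grp.sort_values("time_s")
        out.append(AssayCurve(times=grp["time_s"].to_numpy(),
                              absorbance=grp["absorbance"].to_numpy(),
                              enzyme_concentration=float(conc)))
    return out


# --------------------------------------------------------------------------
# writers

def _write_rows(path, header: Sequence[str],
                rows: Sequence[Sequence[object]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                repr(v) if isinstance(v, float) else str(v)
                for v in row) + "\n")


def write_cest_table(profiles: Sequence[CESTProfile], path,
                     shifts: Optional[Mapping[str, float]] = None) -> None:
    rows = []
    for p in profiles:
        shift = (shifts[p.residue_id] if shifts is not None
                 else getattr(p, "shift_ppm", 0.0))
        s = p.schedule
        for i, off in enumerate(s.offsets):
            row = [p.residue_id, float(shift), float(s.B1_field),
                   float(s.T_EX), float(s.spectrometer_15N_freq),
                   float(off), float(p.ratios[i])]
            if p.sigma is not None:
                row.append(float(p.sigma[i]))
            rows.append(row)
    header = list(_REQUIRED["cest"])
    if profiles and profiles[0].sigma is not None:
        header.append("sigma")
    _write_rows(path, header, rows)


def write_cpmg_table(profiles: Sequence[CPMGProfile], path) -> None:
    rows = []
    for p in profiles:
        s = p.schedule
        for i, nu in enumerate(p.nu_values):
            row = [p.residue_id, float(s.temperature), float(s.T_cp),
                   float(nu), float(p.R2_eff[i])]
            if p.sigma_R2 is not None:
                row.append(float(p.sigma_R2[i]))
            rows.append(row)
    header = list(_REQUIRED["cpmg"])
    if profiles and profiles[0].sigma_R2 is not None:
        header.append("sigma")
    _write_rows(path, header, rows)


def write_titration_table(series: Sequence[TitrationSeries], path) -> None:
    rows = []
    for s in series:
        for i, L in enumerate(s.ligand_concentrations):
            rows.append([s.residue_id, float(s.protein_concentration),
                         float(L), float(s.positions[i, 0]),
                         float(s.positions[i, 1])])
    _write_rows(path, _REQUIRED["titration"], rows)


def write_assay_table(curves: Sequence[AssayCurve], path) -> None:
    rows = []
    for j, c in enumerate(curves):
        cid = f"curve{j:03d}"
        for t, a in zip(c.times, c.absorbance):
            rows.append([cid, float(c.enzyme_concentration), float(t),
                         float(a)])
    _write_rows(path, _REQUIRED["assay"], rows)


# --------------------------------------------------------------------------
# fit reports

def write_fit_report(result: GlobalFitResult, path_prefix) -> Tuple[str, str]:
    """Write a machine-readable parameter CSV and a human-readable
    summary for a global fit.

    Returns (csv_path, summary_path).  Re-reading the CSV with
    :func:`read_fit_report` reproduces all parameter values
    bit-identically (floats are written with ``repr``).
    """
    csv_path = f"{path_prefix}_parameters.csv"
    txt_path = f"{path_prefix}_summary.txt"
    ex = result.exchange
    se = result.standard_errors or {}
    with open(csv_path, "w") as fh:
        fh.write("section,name,residue_id,value,standard_error\n")
        glob_rows = [
            ("topology", "", ex.topology.value, ""),
            ("k_ex_AB", "", repr(float(ex.k_ex_AB)),
             repr(float(se["k_ex_AB"])) if "k_ex_AB" in se else ""),
            ("p_B", "", repr(float(ex.p_B)),
             repr(float(se["p_B"])) if "p_B" in se else ""),
            ("temperature_K", "", repr(float(ex.temperature)), ""),
            ("chi2_red", "", repr(float(result.chi2_red)), ""),
        ]
        if ex.k_ex_AC is not None:
            glob_rows.insert(3, ("k_ex_AC", "", repr(float(ex.k_ex_AC)),
                                 repr(float(se["k_ex_AC"]))
                                 if "k_ex_AC" in se else ""))
            glob_rows.insert(4, ("p_C", "", repr(float(ex.p_C)),
                                 repr(float(se["p_C"]))
                                 if "p_C" in se else ""))
        for name, rid, val, err in glob_rows:
            fh.write(f"global,{name},{rid},{val},{err}\n")
        for rid in sorted(result.per_residue):
            s = result.per_residue[rid]
            for name in ("dw_AB", "dw_AC", "R1", "R2", "dR2", "I0",
                         "shift_ppm"):
                v = getattr(s, name)
                if v is None:
                    continue
                fh.write(f"residue,{name},{rid},{float(v)!r},\n")
    with open(txt_path, "w") as fh:
        fh.write("Global exchange fit\n")
        fh.write("===================\n")
        fh.write(f"topology      : {ex.topology.value}\n")
        fh.write(f"k_ex_AB (s^-1): {ex.k_ex_AB:.4g}")
        if "mc_k_ex_AB" in se:
            fh.write(f" +/- {se['mc_k_ex_AB']:.2g} (MC)")
        fh.write("\n")
        fh.write(f"p_B           : {100 * ex.p_B:.3g} %\n")
        if ex.k_ex_AC is not None:
            fh.write(f"k_ex_AC (s^-1): {ex.k_ex_AC:.4g}\n")
            fh.write(f"p_C           : {100 * ex.p_C:.3g} %\n")
        fh.write(f"chi2_red      : {result.chi2_red:.4g}\n")
        fh.write(f"residues      : {len(result.per_residue)}\n")
    return csv_path, txt_path


def read_fit_report(csv_path) -> Dict[str, object]:
    """Parse a parameter CSV written by :func:`write_fit_report` into
    nested dictionaries of exact float values."""
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    glob: Dict[str, object] = {}
    residues: Dict[str, Dict[str, float]] = {}
    for _, row in df.iterrows():
        if row["section"] == "global":
            val = row["value"] if row["name"] == "topology" \
                else float(row["value"])
            glob[row["name"]] = val
        else:
            residues.setdefault(row["residue_id"], {})[row["name"]] = \
                float(row["value"])
    return {"global": glob, "per_residue": residues}
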