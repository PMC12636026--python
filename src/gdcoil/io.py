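"""Readers and writers for every file schema the analyses use.

CSV schemas (comma separator, ``.`` decimal, UTF-8, mandatory header):

* NMRD profile:   ``freq_mhz,r1_mM_s[,r1_err]``
* titration:      ``metal_total_uM,signal[,competitor_total_uM,peptide_total_uM]``
* decay series:   ``time_min,signal[,control]``
* CD records:     ``mre222,n_residues``

Sequences travel as FASTA with annotation tags in the description line
(``XL=15;NTERM=Ac;CTERM=NH2``); trajectories as multi-frame XYZ whose
comment line carries ``t=<ns>``. Model/generator parameters are YAML or
JSON mappings with strictly validated keys. All error messages name the
offending row or frame.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, ConfigDict

from .binding import TitrationSeries
from .hydration import TrajectoryFrames
from .kinetics import CDRecord, DecaySeries, PeptideSequence
from .relaxation import (ElectronSpinParams, NMRDProfile, OuterSphereParams,
                         RelaxationModel, SecondSphereParams)

__all__ = [
    "read_profile", "write_profile", "read_titration", "write_titration",
    "read_decay", "write_decay", "read_cd_records", "read_sequences",
    "write_sequences", "read_xyz_trajectory", "write_xyz_trajectory",
    "read_model_config", "write_result_json", "RESULT_SCHEMA_VERSION",
]

RESULT_SCHEMA_VERSION = "1.0"


def _read_csv_strict(path, required: List[str], optional: List[str]):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in required + optional]
    if extra:
        raise ValueError(f"{path}: unknown column(s) {extra}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy()
                             | df[col].isna().to_numpy())
        if bad.size:
            raise ValueError(f"{path}: non-numeric or missing value in "
                             f"column '{col}', row {bad[0] + 1}")
        df[col] = vals
    return df


# -- NMRD profiles ----------------------------------------------------------

def read_profile(path) -> NMRDProfile:
    df = _read_csv_strict(path, ["freq_mhz", "r1_mM_s"], ["r1_err"])
    freqs = df["freq_mhz"].to_numpy()
    if np.any(np.diff(freqs) <= 0):
        row = int(np.flatnonzero(np.diff(freqs) <= 0)[0]) + 2
        raise ValueError(f"{path}: frequencies not strictly increasing at "
                         f"row {row}")
    err = df["r1_err"].to_numpy() if "r1_err" in df.columns else None
    return NMRDProfile(frequencies=freqs, r1=df["r1_mM_s"].to_numpy(),
                       r1_err=err, label=str(path))


def write_profile(path, profile: NMRDProfile) -> None:
    data = {"freq_mhz": profile.frequencies, "r1_mM_s": profile.r1}
    if profile.r1_err is not None:
        data["r1_err"] = profile.r1_err
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# -- titrations -------------------------------------------------------------

def read_titration(path, peptide_total: Optional[float] = None,
                   ph: float = 7.5) -> TitrationSeries:
    df = _read_csv_strict(path, ["metal_total_uM", "signal"],
                          ["competitor_total_uM", "peptide_total_uM"])
    if "peptide_total_uM" in df.columns:
        pt = df["peptide_total_uM"].to_numpy()
    elif peptide_total is not None:
        pt = peptide_total
    else:
        raise ValueError(f"{path}: peptide_total_uM column absent and no "
                         "peptide_total given")
    et = (df["competitor_total_uM"].to_numpy()
          if "competitor_total_uM" in df.columns else 0.0)
    return TitrationSeries(metal_total=df["metal_total_uM"].to_numpy(),
                           signal=df["signal"].to_numpy(),
                           peptide_total=pt, competitor_total=et, ph=ph)


def write_titration(path, series: TitrationSeries) -> None:
    pd.DataFrame({
        "metal_total_uM": series.metal_total,
        "signal": series.signal,
        "competitor_total_uM": series.competitor_total,
        "peptide_total_uM": series.peptide_total,
    }).to_csv(path, index=False, float_format="%.17g")


# -- decay series and CD ----------------------------------------------------

def read_decay(path) -> DecaySeries:
    df = _read_csv_strict(path, ["time_min", "signal"], ["control"])
    control = df["control"].to_numpy() if "control" in df.columns else None
    return DecaySeries(time=df["time_min"].to_numpy(),
                       signal=df["signal"].to_numpy(), control=control)


def write_decay(path, series: DecaySeries) -> None:
    data = {"time_min": series.time, "signal": series.signal}
    if series.control is not None:
        data["control"] = series.control
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_cd_records(path) -> List[CDRecord]:
    df = _read_csv_strict(path, ["mre222", "n_residues"], [])
    return [CDRecord(mre_222=float(r.mre222), n_residues=int(r.n_residues))
            for r in df.itertuples()]


# -- FASTA sequences --------------------------------------------------------

def _parse_tags(description: str) -> dict:
    tags = {}
    for token in description.split():
        if "=" not in token:
            continue
        for pair in token.split(";"):
            if "=" in pair:
                key, val = pair.split("=", 1)
                tags[key.upper()] = val
    return tags


def read_sequences(path) -> List[PeptideSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = _parse_tags(rec.description)
        xl = tuple(int(p) for p in tags.get("XL", "").split(",") if p)
        out.append(PeptideSequence(
            residues=str(rec.seq),
            n_term_cap="acetyl" if tags.get("NTERM") == "Ac" else "none",
            c_term_cap="amide" if tags.get("CTERM") == "NH2" else "none",
            crosslinked_positions=xl))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_sequences(path, seqs: List[PeptideSequence],
                    names: Optional[List[str]] = None) -> None:
    records = []
    for i, s in enumerate(seqs):
        tags = []
        if s.crosslinked_positions:
            tags.append("XL=" + ",".join(str(p)
                                         for p in s.crosslinked_positions))
        if s.n_term_cap == "acetyl":
            tags.append("NTERM=Ac")
        if s.c_term_cap == "amide":
            tags.append("CTERM=NH2")
        name = names[i] if names else f"seq{i + 1}"
        records.append(SeqRecord(Seq(s.residues), id=name,
                                 description=";".join(tags)))
    SeqIO.write(records, str(path), "fasta")


# -- multi-frame XYZ --------------------------------------------------------

def read_xyz_trajectory(path, center_label: str = "GD",
                        water_label: str = "HW") -> TrajectoryFrames:
    """Multi-frame XYZ with ``t=<ns>`` timestamps on the comment line.

    Frame spacing is inferred from consecutive timestamps and must be
    constant; inconsistent atom counts or missing timestamps are
    rejected with the frame index in the message.
    """
    lines = Path(path).read_text().splitlines()
    frames, labels, times = [], None, []
    i, frame_no = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}: frame {frame_no}: expected atom "
                             f"count, got {lines[i]!r}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = None
        for token in comment.replace(",", " ").split():
            if token.startswith("t="):
                t = float(token[2:])
        if t is None:
            raise ValueError(f"{path}: frame {frame_no}: comment line "
                             "lacks a 't=<ns>' timestamp")
        times.append(t)
        body = lines[i + 2:i + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ValueError(f"{path}: frame {frame_no}: truncated "
                             f"(expected {n_atoms} atoms)")
        labs, xyz = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: frame {frame_no}: malformed "
                                 f"atom line {ln!r}")
            labs.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        if labels is None:
            labels = labs
        elif len(labs) != len(labels):
            raise ValueError(f"{path}: frame {frame_no}: atom count "
                             f"{len(labs)} differs from frame 0 "
                             f"({len(labels)})")
        frames.append(xyz)
        i += 2 + n_atoms
        frame_no += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    if len(times) > 1:
        dts = np.diff(times)
        if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6):
            raise ValueError(f"{path}: timestamps are not uniformly spaced")
        dt = float(dts[0])
    else:
        dt = times[0] if times[0] > 0 else 1.0
    return TrajectoryFrames(coords=np.asarray(frames, dtype=float),
                            labels=labels, dt_ns=dt,
                            center_label=center_label,
                            water_label=water_label)


def write_xyz_trajectory(path, traj: TrajectoryFrames,
                         precision: int = 6) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{len(traj.labels)}\n")
            fh.write(f"t={(f + 1) * traj.dt_ns:.9g}\n")
            for lab, (x, y, z) in zip(traj.labels, traj.coords[f]):
                fh.write(f"{lab} {x:.{precision}f} {y:.{precision}f} "
                         f"{z:.{precision}f}\n")


# -- structured model config ------------------------------------------------

class _ModelConfig(BaseModel):
    """User-facing relaxation-model keys (ns/ps/Å units at the boundary)."""

    model_config = ConfigDict(extra="forbid")

    q_ss: float = 2.0
    r_ss_A: float = 3.6
    tau_M_ss_ns: float = 5.0
    tau_RG_ns: float = 7.0
    tau_RL_ps: float = 318.0
    S2: float = 0.5
    a_A: float = 4.0
    D_m2s: float = 2.3e-10
    delta2_s2: float = 1.0e19
    tau_v_ps: float = 20.0
    g: float = 2.0
    S: float = 3.5


def read_model_config(path) -> RelaxationModel:
    """YAML/JSON relaxation-model config; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg = _ModelConfig(**data)
    return RelaxationModel(
        second_sphere=SecondSphereParams(
            q_ss=cfg.q_ss, r_ss_A=cfg.r_ss_A,
            tau_m_ss=cfg.tau_M_ss_ns * 1e-9, tau_rg=cfg.tau_RG_ns * 1e-9,
            tau_rl=cfg.tau_RL_ps * 1e-12, s2=cfg.S2),
        outer_sphere=OuterSphereParams(a_A=cfg.a_A, d=cfg.D_m2s),
        electron=ElectronSpinParams(delta2=cfg.delta2_s2,
                                    tau_v=cfg.tau_v_ps * 1e-12,
                                    spin=cfg.S, g=cfg.g),
    )


def write_result_json(path, payload: dict) -> None:
    doc = {"schema_version": RESULT_SCHEMA_VERSION}
    doc.update(payload)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)}")
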