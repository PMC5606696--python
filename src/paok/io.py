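"""Readers and writers for the package's file formats.

Formats:

* parameters CSV — columns ``label,vmax,km,ki`` (header required);
* cycle-records CSV — one row per sampled cycle, columns matching
  :class:`~paok.balance.CycleRecord` field names (optional columns fall back
  to the record defaults);
* FASTA — clone libraries and the clade reference panel; a panel entry's
  clade is parsed from a ``clade=IIB`` token on its description line;
* YAML — reactor configuration mirroring :class:`~paok.competition.ReactorConfig`.

All readers validate and report offending rows by line/record; write-then-read
round-trips are identities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .balance import CycleBalance, CycleRecord
from .community import CladeReferencePanel, CloneLibrary, CompositionTable
from .competition import CompetitionTrajectory, ReactorConfig
from .kinetics import KineticParams, RateCurve

__all__ = [
    "RunManifest",
    "read_params_csv",
    "write_params_csv",
    "read_cycle_records_csv",
    "write_balances_csv",
    "read_fasta_library",
    "read_fasta_panel",
    "write_fasta",
    "read_reactor_config_yaml",
    "write_rate_curve_csv",
    "write_trajectory_csv",
    "write_composition_csv",
    "parse_grid",
]


@dataclass(frozen=True)
class RunManifest:
    """The enrichment campaign: run labels and held aerobic phosphate levels.

    Defaults are the five-run design spanning 0.05-500 mg P L^-1 with a
    200 mg COD L^-1 anaerobic feed.
    """

    run_ids: tuple[str, ...] = ("Run1", "Run2", "Run3", "Run4", "Run5")
    aerobic_p: tuple[float, ...] = (0.05, 0.5, 5.0, 50.0, 500.0)
    anaerobic_cod: float = 200.0

    def __post_init__(self) -> None:
        if len(self.run_ids) != len(self.aerobic_p):
            raise ValueError("run_ids and aerobic_p lengths differ")
        arr = np.asarray(self.aerobic_p, float)
        if np.any(arr <= 0):
            raise ValueError("aerobic phosphate concentrations must be > 0")
        if arr.size > 1 and np.any(np.diff(arr) <= 0):
            raise ValueError("aerobic phosphate concentrations must be strictly increasing")


def read_params_csv(path) -> list[KineticParams]:
    """Read kinetic parameter sets from a ``label,vmax,km,ki`` CSV."""
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"label", "vmax", "km", "ki"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        raise ValueError(f"{path}: no parameter rows")
    params = []
    for idx, row in frame.iterrows():
        try:
            params.append(
                KineticParams(
                    str(row["label"]),
                    vmax=float(row["vmax"]),
                    km=float(row["km"]),
                    ki=float(row["ki"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad row {idx + 2}: {exc}") from exc
    labels = [p.label for p in params]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate labels {labels}")
    return params


def write_params_csv(params: Sequence[KineticParams], path) -> None:
    pd.DataFrame(
        {
            "label": [p.label for p in params],
            "vmax": [p.vmax for p in params],
            "km": [p.km for p in params],
            "ki": [p.ki for p in params],
        }
    ).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


_RECORD_REQUIRED = (
    "run_id",
    "day",
    "aerobic_influent_p",
    "aerobic_effluent_p",
    "anaerobic_end_p",
    "anaerobic_end_cod",
)
_RECORD_OPTIONAL = (
    "aerobic_flow",
    "aerobic_hours",
    "anaerobic_hours",
    "anaerobic_fill_volume",
    "anaerobic_influent_cod",
    "sponge_volume",
    "retained_liquid_volume",
)


def read_cycle_records_csv(path) -> list[CycleRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(_RECORD_REQUIRED) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in frame.iterrows():
        kwargs = {name: row[name] for name in _RECORD_REQUIRED}
        kwargs["run_id"] = str(kwargs["run_id"])
        for name in _RECORD_OPTIONAL:
            if name in frame.columns and pd.notna(row[name]):
                kwargs[name] = float(row[name])
        try:
            kwargs = {
                k: (float(v) if k not in ("run_id",) else v)
                for k, v in kwargs.items()
            }
            records.append(CycleRecord(**kwargs))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad row {idx + 2}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no cycle records")
    return records


def write_cycle_records_csv(records: Sequence[CycleRecord], path) -> None:
    columns = _RECORD_REQUIRED + _RECORD_OPTIONAL
    rows = []
    for rec in records:
        row = {name: getattr(rec, name) for name in columns}
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )


def write_balances_csv(balances: Sequence[CycleBalance], path) -> None:
    pd.DataFrame(
        {
            "run_id": [b.run_id for b in balances],
            "day": [b.day for b in balances],
            "p_uptake_mg": [b.p_uptake_mg for b in balances],
            "p_release_mg": [b.p_release_mg for b in balances],
            "cod_consumed_mg": [b.cod_consumed_mg for b in balances],
            "cod_fraction_remaining": [b.cod_fraction_remaining for b in balances],
            "specific_uptake": [b.specific_uptake for b in balances],
            "specific_release": [b.specific_release for b in balances],
            "flags": [";".join(b.flags) for b in balances],
        }
    ).to_csv(path, index=False)


def read_fasta_library(path, run_id: str | None = None) -> CloneLibrary:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    if run_id is None:
        run_id = Path(str(path)).stem
    return CloneLibrary(
        run_id=run_id,
        sequences=tuple((rec.id, str(rec.seq).upper()) for rec in records),
    )


def read_fasta_panel(path) -> CladeReferencePanel:
    """Read a clade panel FASTA; each description carries ``clade=<label>``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        clade = None
        for token in rec.description.split():
            if token.startswith("clade="):
                clade = token.split("=", 1)[1]
        if clade is None:
            raise ValueError(f"{path}: record {rec.id!r} lacks a clade=<label> tag")
        entries.append((clade, str(rec.seq).upper()))
    if not entries:
        raise ValueError(f"{path}: empty FASTA")
    return CladeReferencePanel(entries=tuple(entries))


def write_fasta(sequences: Sequence[tuple[str, str]], path, descriptions=None) -> None:
    """Write (id, sequence) pairs; ``descriptions`` optionally adds per-id text."""
    records = []
    for sid, seq in sequences:
        desc = "" if not descriptions else descriptions.get(sid, "")
        records.append(SeqRecord(Seq(seq), id=sid, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_reactor_config_yaml(path) -> ReactorConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    try:
        return ReactorConfig(**data)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_rate_curve_csv(curve: RateCurve, path, dominant: Sequence[str] | None = None) -> None:
    frame = curve.to_frame()
    if dominant is not None:
        frame["dominant"] = list(dominant)
    frame.to_csv(path, index=False)


def write_trajectory_csv(trajectory: CompetitionTrajectory, path) -> None:
    trajectory.to_frame().to_csv(path, index=False)


def write_composition_csv(tables: Sequence[CompositionTable], path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, index=False
    )


def parse_grid(spec: str) -> np.ndarray:
    """Parse a ``lo:hi:log|lin:n`` grid specifier, e.g. ``0.01:1000:log:200``."""
    parts = spec.split(":")
    if len(parts) != 4:
        raise ValueError(f"grid spec {spec!r} is not lo:hi:log|lin:n")
    lo, hi, scale, n = float(parts[0]), float(parts[1]), parts[2], int(parts[3])
    if n < 2 or hi <= lo:
        raise ValueError(f"grid spec {spec!r}: need hi > lo and n >= 2")
    if scale == "log":
        if lo <= 0:
            raise ValueError("log grid requires lo > 0")
        return np.geomspace(lo, hi, n)
    if scale == "lin":
        return np.linspace(lo, hi, n)
    raise ValueError(f"grid scale must be 'log' or 'lin', got {scale!r}")
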