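"""Formats, configuration and packaged fixtures.

FASTA input goes through Biopython; traces and run summaries are plain
CSV; schedules and test results are JSON; the run configuration is a
flat YAML key-value file whose keys mirror the schedule symbols
(alpha_annealing, tau_initial, L1, L_max, C, lambda, phase
temperatures) in ASCII.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, fields
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from Bio import SeqIO

from .conformation import CHI_COUNTS, Conformation
from .phases import TraceRecord
from .tuning import Schedule

__all__ = [
    "read_fasta",
    "write_trace",
    "read_trace",
    "write_conformation_csv",
    "load_config",
    "fixture_path",
    "fixture_sequence",
    "fixture_table",
    "synthetic_energy_stream",
    "schedule_to_dict",
    "schedule_from_dict",
]

_TRACE_COLUMNS = [
    "iteration", "phase", "subphase", "temperature",
    "current_energy", "proposal_energy", "accepted", "law", "uniform",
]


def read_fasta(path: str | Path, record_id: str | None = None) -> list[tuple[str, str]]:
    """Parse FASTA records as (id, sequence) pairs, validating the alphabet.

    With ``record_id`` only the matching record is returned; otherwise
    all records, first one first.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in CHI_COUNTS:
                raise ValueError(
                    f"record {rec.id!r}: non-amino-acid character {ch!r} "
                    f"at position {i + 1}"
                )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is not None:
        for rid, seq in records:
            if rid == record_id:
                return [(rid, seq)]
        raise ValueError(f"record {record_id!r} not found in {path}")
    return records


def write_trace(trace: list[TraceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRACE_COLUMNS)
        for rec in trace:
            writer.writerow(rec)


def read_trace(path: str | Path) -> list[TraceRecord]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _TRACE_COLUMNS:
            raise ValueError(
                f"trace schema mismatch: expected {_TRACE_COLUMNS}, got {header}"
            )
        out = []
        for row in reader:
            out.append(
                TraceRecord(
                    int(row[0]), row[1], int(row[2]), float(row[3]),
                    float(row[4]), float(row[5]), row[6] == "True",
                    row[7], float(row[8]),
                )
            )
    return out


def write_conformation_csv(conf: Conformation, path: str | Path) -> None:
    """Serialize angles as residue_index, angle_name, degrees rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residue_index", "angle_name", "degrees"])
        for (i, name), value in zip(conf.angle_names, conf.angles):
            writer.writerow([i + 1, name, repr(float(value))])


def load_config(path: str | Path) -> dict[str, Any]:
    """Flat YAML key-value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a flat key-value mapping")
    return cfg


def schedule_to_dict(schedule: Schedule) -> dict[str, Any]:
    return asdict(schedule)


def schedule_from_dict(d: dict[str, Any]) -> Schedule:
    names = {f.name for f in fields(Schedule)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown schedule fields: {sorted(unknown)}")
    return Schedule(**d)


# ---------------------------------------------------------------------------
# packaged fixtures


def fixture_path(name: str) -> Path:
    """Path of a packaged data file (met_enkephalin.fasta, table CSVs)."""
    ref = resources.files("mpsabbe").joinpath("data", name)
    with resources.as_file(ref) as p:
        return Path(p)


def fixture_sequence(name: str = "met_enkephalin") -> str:
    """Packaged peptide sequence by fixture name."""
    if name != "met_enkephalin":
        raise ValueError(f"unknown sequence fixture {name!r}")
    return read_fasta(fixture_path("met_enkephalin.fasta"))[0][1]


def fixture_table(name: str) -> pd.DataFrame:
    """Packaged replicate-summary tables: 'mpsabbe' or 'cmqa' arm."""
    files = {
        "mpsabbe": "table7_mpsabbe.csv",
        "cmqa": "table8_cmqa.csv",
    }
    if name not in files:
        raise ValueError(f"unknown table fixture {name!r}; have {sorted(files)}")
    return pd.read_csv(fixture_path(files[name]), index_col="instance")


def synthetic_energy_stream(
    seed: int, n: int = 500, plateau_after: int = 250, noise: float = 0.05
) -> list[float]:
    """Deterministic synthetic energy trajectory for equilibrium-detector
    tests: linear descent that flattens after ``plateau_after`` samples,
    with seeded Gaussian noise."""
    import numpy as np

    rng = np.random.default_rng(seed)
    out = []
    e = 10.0
    for i in range(n):
        if i < plateau_after:
            e -= 10.0 / plateau_after
        out.append(e + noise * float(rng.standard_normal()))
    return out
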