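"""Per-subject trial data: container, validation, and CSV round-tripping.

The on-disk format is a plain CSV with columns

    subject, trial, cond_type, s_A, s_V, resp_A, resp_V

where ``cond_type`` is one of A, V, AV; locations and responses are in
degrees azimuth at one-decimal precision; and fields for absent modalities
are left empty.  Provenance metadata (seeds, generator settings) is stored
as ``# key: value`` comment lines before the header and survives a
read/write round trip byte-for-byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .simulate import StimulusCondition

__all__ = ["SubjectDataset", "read_datasets_csv", "write_datasets_csv"]

COLUMNS = ["subject", "trial", "cond_type", "s_A", "s_V", "resp_A", "resp_V"]
_FLOAT_COLS = ["s_A", "s_V", "resp_A", "resp_V"]


class DatasetFormatError(ValueError):
    """Raised when a trial table violates the dataset contract."""


@dataclass
class SubjectDataset:
    """All trials of one subject, across unisensory and bisensory conditions.

    ``trials`` holds one row per trial with the CSV columns above; ``meta``
    carries provenance (generating strategy, parameters, seeds) as flat
    key/value strings.
    """

    subject: str
    trials: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = self.trials.reset_index(drop=True)
        validate_trials(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_responses(self) -> int:
        """Total response count; bisensory trials contribute two reports."""
        return int(self.trials["resp_A"].notna().sum() + self.trials["resp_V"].notna().sum())

    def conditions(self) -> list[StimulusCondition]:
        """Unique stimulus conditions, ordered unisensory-auditory, unisensory-visual, bisensory."""
        seen = (
            self.trials[["cond_type", "s_A", "s_V"]]
            .drop_duplicates()
            .sort_values(["cond_type", "s_A", "s_V"], na_position="first")
        )
        out = []
        for _, row in seen.iterrows():
            out.append(
                StimulusCondition(
                    s_A=None if pd.isna(row.s_A) else float(row.s_A),
                    s_V=None if pd.isna(row.s_V) else float(row.s_V),
                )
            )
        return out


def validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in trials.columns]
    if missing:
        raise DatasetFormatError(f"missing columns: {missing}")
    if len(trials) == 0:
        raise DatasetFormatError("dataset contains no trials")
    for i, row in trials.iterrows():
        ct = row["cond_type"]
        if ct not in ("A", "V", "AV"):
            raise DatasetFormatError(f"row {i}: unknown cond_type {ct!r}")
        need_a, need_v = ct in ("A", "AV"), ct in ("V", "AV")
        for col, needed in (("s_A", need_a), ("s_V", need_v), ("resp_A", need_a), ("resp_V", need_v)):
            present = not pd.isna(row[col])
            if needed and not present:
                raise DatasetFormatError(f"row {i}, column {col}: required for cond_type {ct} but empty")
            if not needed and present:
                raise DatasetFormatError(f"row {i}, column {col}: must be empty for cond_type {ct}")


def _fmt(x: float) -> str:
    return "" if pd.isna(x) else f"{x:.1f}"


def write_datasets_csv(
    datasets: Union[SubjectDataset, Iterable[SubjectDataset]],
    path: Union[str, Path],
    meta: dict | None = None,
) -> None:
    """Write one or more subjects to a single CSV with a provenance header.

    ``meta`` defaults to the union of the subjects' own metadata; keys are
    emitted in insertion order as ``# key: value`` lines.
    """
    if isinstance(datasets, SubjectDataset):
        datasets = [datasets]
    datasets = list(datasets)
    if meta is None:
        meta = {}
        for ds in datasets:
            for k, v in ds.meta.items():
                meta.setdefault(k, v)
    frames = [ds.trials[COLUMNS] for ds in datasets]
    table = pd.concat(frames, ignore_index=True)
    buf = io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}: {v}\n")
    out = table.copy()
    for col in _FLOAT_COLS:
        out[col] = out[col].map(_fmt)
    out.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_datasets_csv(path: Union[str, Path]) -> list[SubjectDataset]:
    """Read a dataset CSV; returns one SubjectDataset per subject id, in file order."""
    text = Path(path).read_text()
    meta: dict = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    table = pd.read_csv(
        io.StringIO("\n".join(body_lines)),
        dtype={"subject": str, "cond_type": str},
    )
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")
    for col in _FLOAT_COLS:
        table[col] = pd.to_numeric(table[col], errors="raise")
    out = []
    for subject in table["subject"].unique():
        sub = table[table["subject"] == subject].reset_index(drop=True)
        out.append(SubjectDataset(subject=str(subject), trials=sub, meta=dict(meta)))
    return out
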