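"""Readers and writers for the pipeline's tabular formats, and run configuration.

All tables are TSV (or CSV by extension), gzip-transparent, never binary.
Expression matrices are genes x samples with a header row of sample ids
and gene ids in the first column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from reodeg.calling import SampleDEGCall

__all__ = [
    "read_expression",
    "write_expression",
    "read_drug_response",
    "read_proportions",
    "calls_to_table",
    "write_calls",
    "RunConfig",
]


def _sep_for(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_expression(path) -> pd.DataFrame:
    """Read a gene x sample expression matrix from TSV/CSV.

    Rejects duplicate gene/sample ids, missing values and negative values
    with an error naming the offender and its line number (1-based,
    counting the header line).
    """
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, compression="infer", float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    dup = df.index.duplicated()
    if dup.any():
        pos = int(np.nonzero(dup)[0][0])
        raise ValueError(f"{path}: duplicate gene id {df.index[pos]!r} (line {pos + 2})")
    dupc = df.columns.duplicated()
    if dupc.any():
        raise ValueError(f"{path}: duplicate sample id {df.columns[int(np.nonzero(dupc)[0][0])]!r} (line 1)")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    na = values.isna()
    if na.any().any():
        pos = int(np.nonzero(na.any(axis=1).to_numpy())[0][0])
        raise ValueError(
            f"{path}: missing value for gene {values.index[pos]!r} (line {pos + 2}); "
            "expression matrices may not contain missing values"
        )
    neg = values.lt(0)
    if neg.any().any():
        pos = int(np.nonzero(neg.any(axis=1).to_numpy())[0][0])
        raise ValueError(f"{path}: negative value for gene {values.index[pos]!r} (line {pos + 2})")
    return values


def write_expression(df: pd.DataFrame, path) -> None:
    """Write an expression matrix; floats keep full (round-trip) precision."""
    df.to_csv(path, sep=_sep_for(path), index_label="gene")


def read_drug_response(path) -> pd.DataFrame:
    """Read a cell-line x drug IC50 matrix; missing values are allowed."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, compression="infer")
    df.index = df.index.astype(str)
    return df.astype(float)


def read_proportions(path) -> pd.DataFrame:
    """Read a sample x cell-type proportion matrix (rows should sum to 1)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, compression="infer")
    df.index = df.index.astype(str)
    return df.astype(float)


def calls_to_table(calls: list[SampleDEGCall]) -> pd.DataFrame:
    """Flatten per-sample calls into a long table: sample, gene, status, p, q, n_partners."""
    frames = []
    for call in calls:
        t = call.table.reset_index(names="gene")
        t.insert(0, "sample", call.sample_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def write_calls(calls: list[SampleDEGCall], path) -> None:
    calls_to_table(calls).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    Thresholds default to the method's standard operating points: 90%
    ordering stability for the normal background, per-sample FDR 0.05,
    85% dysregulation frequency for UDEGs, and half-coverage for the drug
    screen. The ``*_inclusive`` flags choose >= (default) versus > at
    each threshold.
    """

    normal: str
    tumor: str
    paired_tumor: str
    paired_adjacent: str
    output_dir: str
    drug_response: str | None = None
    cell_line_expression: str | None = None
    immune_proportions: str | None = None
    stable_threshold: float = 0.90
    q_threshold: float = 0.05
    udeg_threshold: float = 0.85
    min_drug_coverage: float = 0.5
    p_threshold: float = 0.05
    q_inclusive: bool = True
    udeg_inclusive: bool = True
    coverage_inclusive: bool = True
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.5 < self.stable_threshold <= 1.0:
            raise ValueError(f"stable_threshold must be in (0.5, 1], got {self.stable_threshold}")
        if not 0.0 < self.q_threshold <= 1.0:
            raise ValueError(f"q_threshold must be in (0, 1], got {self.q_threshold}")
        if not 0.0 < self.udeg_threshold <= 1.0:
            raise ValueError(f"udeg_threshold must be in (0, 1], got {self.udeg_threshold}")
        if not 0.0 < self.min_drug_coverage <= 1.0:
            raise ValueError(f"min_drug_coverage must be in (0, 1], got {self.min_drug_coverage}")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")

    def required_paths(self) -> dict[str, str]:
        paths = {
            "normal": self.normal,
            "tumor": self.tumor,
            "paired_tumor": self.paired_tumor,
            "paired_adjacent": self.paired_adjacent,
        }
        for key in ("drug_response", "cell_line_expression", "immune_proportions"):
            value = getattr(self, key)
            if value is not None:
                paths[key] = value
        return paths

    def validate_paths(self) -> None:
        for key, value in self.required_paths().items():
            if not Path(value).exists():
                raise FileNotFoundError(f"config input {key!r}: path {value} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
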