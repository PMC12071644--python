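"""Conventions and validation for the gene-by-sample expression container.

An expression matrix is a :class:`pandas.DataFrame` with gene identifiers
as the (unique) index and sample identifiers as the (unique) columns.
Values are nonnegative floats on any scale — linear or log — because the
core pipeline consumes only within-sample orderings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def validate_expression_matrix(df: pd.DataFrame, name: str = "expression matrix") -> pd.DataFrame:
    """Validate an expression matrix and return it as a float frame.

    Raises ``ValueError`` naming the offending gene/sample for duplicate
    identifiers, missing values, or negative values.
    """
    if not isinstance(df, pd.DataFrame):
        raise TypeError(f"{name}: expected a pandas DataFrame, got {type(df).__name__}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{name}: matrix is empty ({df.shape[0]} genes x {df.shape[1]} samples)")
    dup_genes = df.index[df.index.duplicated()].unique()
    if len(dup_genes) > 0:
        raise ValueError(f"{name}: duplicate gene id {dup_genes[0]!r}")
    dup_samples = df.columns[df.columns.duplicated()].unique()
    if len(dup_samples) > 0:
        raise ValueError(f"{name}: duplicate sample id {dup_samples[0]!r}")
    try:
        out = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{name}: non-numeric values present ({exc})") from exc
    if out.isna().any().any():
        gene = out.index[out.isna().any(axis=1)][0]
        sample = out.columns[out.isna().any(axis=0)][0]
        raise ValueError(
            f"{name}: missing value (first at gene {gene!r}, sample {sample!r}); "
            "missing expression values are not allowed"
        )
    if (out.values < 0).any():
        r, c = np.argwhere(out.values < 0)[0]
        raise ValueError(
            f"{name}: negative value {out.iat[r, c]} at gene {out.index[r]!r}, sample {out.columns[c]!r}"
        )
    return out


def check_aligned(left: pd.DataFrame, right: pd.DataFrame, left_name: str, right_name: str) -> None:
    """Require identical gene index and sample columns, in order.

    Used for paired tumor/adjacent cohorts where column k of both matrices
    must belong to the same patient.
    """
    if not left.index.equals(right.index):
        for a, b in zip(left.index, right.index):
            if a != b:
                raise ValueError(
                    f"gene sets of {left_name} and {right_name} differ: first mismatch {a!r} vs {b!r}"
                )
        raise ValueError(
            f"gene sets of {left_name} and {right_name} differ in length: "
            f"{len(left.index)} vs {len(right.index)}"
        )
    if not left.columns.equals(right.columns):
        for a, b in zip(left.columns, right.columns):
            if a != b:
                raise ValueError(
                    f"sample columns of {left_name} and {right_name} differ: first mismatch {a!r} vs {b!r}"
                )
        raise ValueError(
            f"sample columns of {left_name} and {right_name} differ in length: "
            f"{len(left.columns)} vs {len(right.columns)}"
        )
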