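"""Stable relative-expression-ordering background from a normal cohort.

A gene pair is *stable* when one gene's expression exceeds the other's in
at least a threshold fraction (default 90%) of normal samples. The set of
stable pairs with their majority directions forms the normal background
against which single disease samples are screened for ordering reversals.

Only within-sample orderings are used, so the background is invariant to
any within-sample monotone transform of the expression values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from reodeg.matrix import validate_expression_matrix

__all__ = [
    "StableOrderBackground",
    "pair_support",
    "build_background",
    "read_background",
    "write_background",
]

PAIR_COLUMNS = ["gene_a", "gene_b", "direction", "support"]


@dataclass
class StableOrderBackground:
    """Stable ordered gene pairs over a normal cohort.

    ``pairs`` has columns ``gene_a, gene_b, direction, support`` where
    ``direction`` is ``"gt"`` (a > b) or ``"lt"`` (a < b), the majority
    direction over the cohort, and ``support`` is the fraction of
    strictly ordered samples exhibiting it. Each unordered pair appears
    at most once, with ``gene_a`` lexicographically smaller.
    """

    threshold: float
    pairs: pd.DataFrame
    n_normal_samples: int

    def __post_init__(self):
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError(
                f"stability threshold must be in (0.5, 1], got {self.threshold} "
                "(a majority direction is ill-defined at or below 0.5)"
            )
        self.pairs = self.pairs.reset_index(drop=True)[PAIR_COLUMNS]

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StableOrderBackground):
            return NotImplemented
        a = self.pairs.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
        b = other.pairs.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
        return (
            self.threshold == other.threshold
            and self.n_normal_samples == other.n_normal_samples
            and a.equals(b)
        )

    def gene_universe(self) -> set[str]:
        return set(self.pairs["gene_a"]) | set(self.pairs["gene_b"])


def pair_support(normal: pd.DataFrame, gene_a: str, gene_b: str) -> tuple[str, float]:
    """Majority ordering direction and its support fraction for one pair.

    Returns ``(direction, support)`` with direction ``"gt"`` if gene_a is
    above gene_b in the majority of strictly ordered normal samples,
    ``"lt"`` otherwise. Samples where the two values are exactly equal
    support neither ordering and are excluded from both numerator and
    denominator. If every sample is tied the support is NaN (the pair can
    never be stable) and the direction defaults to ``"gt"`` with the
    lexicographically smaller gene first.
    """
    for g in (gene_a, gene_b):
        if g not in normal.index:
            raise KeyError(f"gene {g!r} not in the normal matrix")
    if normal.shape[1] < 2:
        raise ValueError("pair support requires at least 2 normal samples")
    va = normal.loc[gene_a].to_numpy(float)
    vb = normal.loc[gene_b].to_numpy(float)
    gt = int(np.sum(va > vb))
    lt = int(np.sum(va < vb))
    denom = gt + lt
    if denom == 0:
        return ("gt" if gene_a <= gene_b else "lt"), float("nan")
    if gt > lt:
        return "gt", gt / denom
    if lt > gt:
        return "lt", lt / denom
    # exact 0.5 split: record the lexicographically smaller gene as the
    # greater one; such a pair is never stable at any valid threshold
    return ("gt" if gene_a <= gene_b else "lt"), 0.5


def build_background(normal: pd.DataFrame, threshold: float = 0.90) -> StableOrderBackground:
    """Build the stable-pair background over all gene pairs of a normal cohort.

    A pair is stored iff its majority-direction support is at least
    ``threshold`` and a strict ordering exists in more than half of the
    samples (a pair tied in most samples cannot be stable). Quadratic in
    the number of genes; intended for matrices up to a few thousand genes
    in memory — evaluate larger inputs in gene chunks against a fixed
    partner set.
    """
    normal = validate_expression_matrix(normal, "normal cohort")
    if normal.shape[1] < 2:
        raise ValueError("building a background requires at least 2 normal samples")
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"stability threshold must be in (0.5, 1], got {threshold}")
    genes = np.asarray(normal.index)
    order = np.argsort(genes, kind="stable")  # canonical: gene_a lexicographically smaller
    x = normal.to_numpy(float)[order]
    genes = genes[order]
    n_genes, n_samples = x.shape
    rec_a, rec_b, rec_dir, rec_sup = [], [], [], []
    for i in range(n_genes - 1):
        gt = (x[i] > x[i + 1 :]).sum(axis=1)
        lt = (x[i] < x[i + 1 :]).sum(axis=1)
        denom = gt + lt
        with np.errstate(invalid="ignore", divide="ignore"):
            support = np.maximum(gt, lt) / denom
        keep = (denom > n_samples / 2) & (denom > 0) & (support >= threshold)
        if not keep.any():
            continue
        j_idx = np.nonzero(keep)[0]
        rec_a.append(np.full(len(j_idx), genes[i]))
        rec_b.append(genes[i + 1 + j_idx])
        rec_dir.append(np.where(gt[j_idx] > lt[j_idx], "gt", "lt"))
        rec_sup.append(support[j_idx])
    if rec_a:
        pairs = pd.DataFrame(
            {
                "gene_a": np.concatenate(rec_a),
                "gene_b": np.concatenate(rec_b),
                "direction": np.concatenate(rec_dir),
                "support": np.concatenate(rec_sup),
            }
        )
    else:
        pairs = pd.DataFrame({c: [] for c in PAIR_COLUMNS}).astype(
            {"gene_a": str, "gene_b": str, "direction": str, "support": float}
        )
    return StableOrderBackground(threshold=threshold, pairs=pairs, n_normal_samples=n_samples)


def write_background(background: StableOrderBackground, path) -> None:
    """Write a background to TSV (gzip-transparent by extension).

    Two comment lines carry the threshold and cohort size; supports are
    serialized at full precision (shortest round-trip repr).
    """
    df = background.pairs.copy()
    df["support"] = [repr(float(s)) for s in df["support"]]
    header = (
        f"#threshold={background.threshold!r}\n"
        f"#n_normal_samples={background.n_normal_samples}\n"
    )
    compression = "gzip" if str(path).endswith(".gz") else None
    import gzip as _gzip

    opener = _gzip.open if compression else open
    with opener(path, "wt") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_background(path) -> StableOrderBackground:
    """Read a background written by :func:`write_background`."""
    import gzip as _gzip

    opener = _gzip.open if str(path).endswith(".gz") else open
    meta: dict[str, str] = {}
    with opener(path, "rt") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        pairs = pd.read_csv(
            fh,
            sep="\t",
            dtype={"gene_a": str, "gene_b": str, "direction": str},
            float_precision="round_trip",
        )
    if "support" not in pairs.columns:
        pairs["support"] = pd.Series(dtype=float)
    pairs["support"] = pairs["support"].astype(float)
    try:
        threshold = float(meta["threshold"])
        n_samples = int(meta["n_normal_samples"])
    except KeyError as exc:
        raise ValueError(f"background file {path} is missing metadata line {exc}") from exc
    return StableOrderBackground(threshold=threshold, pairs=pairs, n_normal_samples=n_samples)
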