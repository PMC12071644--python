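"""Downstream association screens.

* Drug screen: drop sparsely assayed drugs (observed IC50 in fewer than
  half the cell lines by default), then Spearman-correlate each query
  gene's expression with each drug's IC50 across cell lines. A positive
  rho means high expressors are resistant (higher IC50).
* Immune screen: the same correlation engine against deconvolved
  immune-cell proportions per sample.
* Consistence: a symmetric overlap score between two enriched-pathway
  sets, ``(con/n + con/t) / 2`` for ``n`` normal-enriched, ``t``
  tumor-enriched and ``con`` common pathways.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConsistenceInput",
    "consistence",
    "format_consistence_percent",
    "filter_drugs",
    "spearman_screen",
    "immune_correlation",
]

logger = logging.getLogger(__name__)

# exact Spearman permutation null is used at or below this sample size
EXACT_N_MAX = 9


@dataclass(frozen=True)
class ConsistenceInput:
    """Pathway counts: n normal-enriched, t tumor-enriched, con in common."""

    n: int
    t: int
    con: int

    def __post_init__(self):
        if self.n <= 0 or self.t <= 0:
            raise ValueError(f"pathway counts n and t must be positive, got n={self.n}, t={self.t}")
        if self.con < 0:
            raise ValueError(f"common pathway count must be nonnegative, got {self.con}")
        if self.con > min(self.n, self.t):
            raise ValueError(
                f"common pathways ({self.con}) cannot exceed the smaller set (min({self.n}, {self.t}))"
            )


def consistence(n: int, t: int, con: int) -> float:
    """Symmetric overlap of two pathway sets: (con/n + con/t) / 2.

    Returns a fraction in [0, 1]; equals 1 iff both sets coincide
    (con = n = t) and 0 iff they are disjoint.
    """
    inp = ConsistenceInput(n=n, t=t, con=con)
    return (inp.con / inp.n + inp.con / inp.t) / 2.0


def format_consistence_percent(value: float) -> str:
    """Render a consistence fraction as a percentage with two decimals."""
    return f"{value * 100:.2f}%"


def filter_drugs(
    resp: pd.DataFrame, min_coverage: float = 0.5, inclusive: bool = True
) -> pd.DataFrame:
    """Keep drugs assayed in at least ``min_coverage`` of the cell lines.

    ``resp`` is cell lines x drugs with NaN for unassayed pairs. With the
    default inclusive rule a drug is retained when its observed count is
    at least ``ceil(min_coverage * n_lines)``; the strict variant
    requires strictly more than ``min_coverage * n_lines``.
    """
    if resp.shape[0] == 0 or resp.shape[1] == 0:
        raise ValueError("drug response matrix is empty")
    if not 0.0 < min_coverage <= 1.0:
        raise ValueError(f"min_coverage must be in (0, 1], got {min_coverage}")
    n_lines = resp.shape[0]
    observed = resp.notna().sum(axis=0)
    if inclusive:
        keep = observed >= math.ceil(min_coverage * n_lines)
    else:
        keep = observed > min_coverage * n_lines
    kept = resp.loc[:, keep[keep].index]
    logger.info("drug coverage filter: %d of %d drugs retained", kept.shape[1], resp.shape[1])
    return kept


@lru_cache(maxsize=16)
def _exact_abs_rho_null(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free exact null)."""
    base = np.arange(n)
    perms = np.array(list(permutations(range(n))), dtype=np.int64)
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return np.sort(np.abs(rho))


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Spearman rho with average ranks, two-sided p, and the p regime used.

    For n <= 9 with no ties in either vector the p-value is exact (share
    of permutations with |rho| at least as large); otherwise the
    large-sample t approximation is used.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return 0.0, 1.0, "degenerate"
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= EXACT_N_MAX and not ties:
        null = _exact_abs_rho_null(n)
        count = int(np.sum(null >= abs(rho) - 1e-12))
        return rho, count / len(null), "exact-permutation"
    if abs(rho) >= 1.0:
        return rho, 0.0, "t-approx"
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0)), "t-approx"


def _pairwise_spearman(
    expr: pd.DataFrame,
    resp: pd.DataFrame,
    p_threshold: float,
    target_name: str,
    adjust: str | None,
) -> pd.DataFrame:
    shared = expr.columns.intersection(resp.index)
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared samples between expression and {target_name} matrices, "
            f"got {len(shared)}"
        )
    expr = expr.loc[:, shared]
    resp = resp.loc[shared]
    rows = []
    for target in resp.columns:
        y_full = resp[target].to_numpy(float)
        mask = ~np.isnan(y_full)
        n_used = int(mask.sum())
        if n_used < 3:
            logger.info("skipping %s %r: only %d observed values", target_name, target, n_used)
            continue
        y = y_full[mask]
        for gene in expr.index:
            x = expr.loc[gene].to_numpy(float)[mask]
            rho, p, method = _spearman(x, y)
            rows.append((gene, target, rho, p, n_used, method))
    result = pd.DataFrame(rows, columns=["gene", target_name, "rho", "p", "n_used", "p_method"])
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        result["q"] = multipletests(result["p"], method="fdr_bh")[1] if len(result) else []
        result["significant"] = result["q"] < p_threshold
    elif adjust is None:
        result["significant"] = result["p"] < p_threshold
    else:
        raise ValueError(f"unknown adjust mode {adjust!r} (use None or 'bh')")
    result["sign"] = np.where(result["rho"] > 0, "positive", np.where(result["rho"] < 0, "negative", "zero"))
    return result


def spearman_screen(
    expr: pd.DataFrame,
    resp: pd.DataFrame,
    p_threshold: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Correlate query-gene expression with drug IC50 across cell lines.

    ``expr`` is genes x cell lines; ``resp`` is cell lines x drugs with
    NaN allowed (pairwise-complete observations per gene-drug pair; pairs
    with fewer than 3 observations are skipped). All pairs are reported
    with rho, two-sided p and a significance flag at raw ``p <
    p_threshold`` by default; pass ``adjust='bh'`` for an FDR-adjusted
    flag instead.
    """
    return _pairwise_spearman(expr, resp, p_threshold, "drug", adjust)


def immune_correlation(
    expr: pd.DataFrame,
    proportions: pd.DataFrame,
    p_threshold: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Correlate gene expression with immune-cell proportions per sample.

    ``proportions`` is samples x cell types and every row must sum to 1
    (tolerance 1e-6), as produced by bulk immune deconvolution. The
    result's ``significant`` column is the mask to display (non-significant
    pairs are conventionally crossed out in heatmap views).
    """
    sums = proportions.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad) > 0:
        raise ValueError(
            f"cell-type proportions must sum to 1 per sample: sample {bad.index[0]!r} sums to {bad.iloc[0]}"
        )
    return _pairwise_spearman(expr, proportions, p_threshold, "cell_type", adjust)
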