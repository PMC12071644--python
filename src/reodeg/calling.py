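"""Per-sample up/down/stable gene calls.

Paired samples are called directly: a gene is up in a patient if its
tumor value exceeds its adjacent-normal value, down if smaller, stable
if exactly equal.

Unpaired samples are called against a stable-ordering background. For a
gene *i* with stable partners, a 2x2 contingency table is formed with
rows = context (normal background vs the disease sample) and columns =
ordering (i above partner vs i below partner) over the identical partner
set; a two-sided Fisher exact test asks whether the reversed pairs
supporting up- and down-regulation of *i* are balanced. The direction is
up when the fraction of partners below *i* is larger in the disease
sample than in the background, down when smaller. P-values are
Benjamini–Hochberg adjusted across genes within the sample, and a call
is retained only if it survives iterative exclusion of reversed pairs
whose partner is itself called in the opposite direction (a down partner
falling below *i* fabricates evidence that *i* rose, and vice versa).

Pairs tied within the disease sample (equal values) are dropped from
both table rows for that gene, so row margins always agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from reodeg.background import StableOrderBackground
from reodeg.matrix import check_aligned, validate_expression_matrix

__all__ = [
    "SampleDEGCall",
    "call_paired",
    "fisher_two_sided",
    "call_sample_reo",
    "refine_calls",
    "cohort_calls",
]

logger = logging.getLogger(__name__)

UP, DOWN, STABLE = 1, -1, 0
_STATUS_LABEL = {UP: "up", DOWN: "down", STABLE: "stable"}


@dataclass
class SampleDEGCall:
    """Per-sample call table: status, p, BH q and partner count per gene."""

    sample_id: str
    table: pd.DataFrame  # index gene; columns status, p, q, n_partners
    n_iterations: int = 0
    converged: bool = True
    _index: "_BackgroundIndex | None" = field(default=None, repr=False, compare=False)

    @property
    def status(self) -> pd.Series:
        return self.table["status"]

    @property
    def p_value(self) -> pd.Series:
        return self.table["p"]

    @property
    def q_value(self) -> pd.Series:
        return self.table["q"]

    @property
    def n_partners_used(self) -> pd.Series:
        return self.table["n_partners"]

    def genes_called(self, direction: str) -> list[str]:
        return list(self.table.index[self.table["status"] == direction])


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table of counts.

    Degenerate tables (a zero row or column margin) carry no information
    and return 1.0.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError(f"expected a 2x2 table of nonnegative counts, got {table!r}")
    return _fisher_cached(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def call_paired(tumor: pd.DataFrame, adjacent: pd.DataFrame) -> list[SampleDEGCall]:
    """Direct per-patient calls for a paired tumor/adjacent cohort.

    The two matrices must share genes and patient columns in order. Calls
    are deterministic (no test): called genes carry p = q = 0, stable
    genes p = q = 1, by convention.
    """
    tumor = validate_expression_matrix(tumor, "paired tumor")
    adjacent = validate_expression_matrix(adjacent, "paired adjacent")
    check_aligned(tumor, adjacent, "paired tumor", "paired adjacent")
    tv, av = tumor.to_numpy(float), adjacent.to_numpy(float)
    status = np.where(tv > av, UP, np.where(tv < av, DOWN, STABLE))
    calls = []
    for k, patient in enumerate(tumor.columns):
        s = status[:, k]
        called = s != STABLE
        table = pd.DataFrame(
            {
                "status": [_STATUS_LABEL[v] for v in s],
                "p": np.where(called, 0.0, 1.0),
                "q": np.where(called, 0.0, 1.0),
                "n_partners": 0,
            },
            index=tumor.index,
        )
        calls.append(SampleDEGCall(sample_id=patient, table=table))
    return calls


class _BackgroundIndex:
    """Background pairs flattened to per-gene entry arrays for one gene set.

    Each stable pair (a, b) yields two entries, one per endpoint, so that
    per-gene contingency counts aggregate with a single bincount. Pairs
    whose partner is absent from the sample gene set are dropped.
    """

    def __init__(self, background: StableOrderBackground, gene_ids: pd.Index):
        self.gene_ids = gene_ids
        self.n_genes = len(gene_ids)
        pos = {g: i for i, g in enumerate(gene_ids)}
        pairs = background.pairs
        ia = pairs["gene_a"].map(pos)
        ib = pairs["gene_b"].map(pos)
        present = ia.notna() & ib.notna()
        ia = ia[present].to_numpy(int)
        ib = ib[present].to_numpy(int)
        a_gt_b = (pairs.loc[present, "direction"] == "gt").to_numpy(bool)
        # entry arrays: each pair seen from both endpoints
        self.node = np.concatenate([ia, ib])
        self.partner = np.concatenate([ib, ia])
        self.bg_gt = np.concatenate([a_gt_b, ~a_gt_b])  # background says node > partner
        self.n_partners = np.bincount(self.node, minlength=self.n_genes)

    def sample_relations(self, values: np.ndarray):
        """Strictly ordered entries of one sample: (node, partner, bg_gt, smp_gt)."""
        va = values[self.node]
        vb = values[self.partner]
        strict = va != vb
        return (
            self.node[strict],
            self.partner[strict],
            self.bg_gt[strict],
            (va > vb)[strict],
        )


def _fisher_vector(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    p = np.ones(len(a))
    for g in range(len(a)):
        if a[g] + b[g] > 0:
            p[g] = _fisher_cached(int(a[g]), int(b[g]), int(c[g]), int(d[g]))
    return p


def _counts(n_genes, node, bg_gt, smp_gt, keep=None):
    if keep is not None:
        node, bg_gt, smp_gt = node[keep], bg_gt[keep], smp_gt[keep]
    a = np.bincount(node[bg_gt], minlength=n_genes)
    b = np.bincount(node[~bg_gt], minlength=n_genes)
    c = np.bincount(node[smp_gt], minlength=n_genes)
    d = np.bincount(node[~smp_gt], minlength=n_genes)
    return a, b, c, d


def _statuses(a, c, p, tested, q_threshold, inclusive):
    """BH across tested genes within the sample, then threshold to statuses.

    Because the two table rows share a margin, the sample-vs-background
    ratio comparison reduces to comparing c with a.
    """
    q = np.ones(len(p))
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    significant = (q <= q_threshold) if inclusive else (q < q_threshold)
    direction = np.sign(c - a)  # up where more partners fall below the gene than in normal
    status = np.where(tested & significant, direction, STABLE).astype(int)
    return status, q


def _call_column(
    index: _BackgroundIndex, values: np.ndarray, q_threshold: float, inclusive: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
    node, partner, bg_gt, smp_gt = index.sample_relations(values)
    a, b, c, d = _counts(index.n_genes, node, bg_gt, smp_gt)
    tested = (a + b) > 0
    p = _fisher_vector(a, b, c, d)
    status, q = _statuses(a, c, p, tested, q_threshold, inclusive)
    return status, p, q, (node, partner, bg_gt, smp_gt, tested)


def _refine_column(
    index: _BackgroundIndex,
    status: np.ndarray,
    relations: tuple,
    q_threshold: float,
    inclusive: bool,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """Iterate partner exclusion to a fixed point of the status map.

    Each pass starts from the full tables and removes, for every gene
    currently called up (down), the reversed pairs whose partner is
    currently called down (up) — the pair leaves both table rows, keeping
    the margins equal. A call survives the pass only if it is still
    significant with the same direction; refinement can revoke calls but
    never create them, so the called set shrinks monotonically and the
    loop reaches a fixed point in at most one pass per called gene.
    """
    node, partner, bg_gt, smp_gt, tested = relations
    p = np.ones(index.n_genes)
    q = np.ones(index.n_genes)
    for iteration in range(1, max_iter + 1):
        s_node = status[node]
        s_partner = status[partner]
        # reversed pairs supporting an up call whose partner is called down
        excl_up = (s_node == UP) & ~bg_gt & smp_gt & (s_partner == DOWN)
        # reversed pairs supporting a down call whose partner is called up
        excl_down = (s_node == DOWN) & bg_gt & ~smp_gt & (s_partner == UP)
        a, b, c, d = _counts(index.n_genes, node, bg_gt, smp_gt, keep=~(excl_up | excl_down))
        p = _fisher_vector(a, b, c, d)
        recalled, q = _statuses(a, c, p, tested, q_threshold, inclusive)
        new_status = np.where(recalled == status, status, STABLE)
        if np.array_equal(new_status, status):
            return status, p, q, iteration, True
        status = new_status
    logger.warning("refinement did not converge within %d iterations", max_iter)
    return status, p, q, max_iter, False


def _to_call(sample_id, gene_ids, status, p, q, n_partners, n_iter, converged, index):
    table = pd.DataFrame(
        {
            "status": [_STATUS_LABEL[v] for v in status],
            "p": p,
            "q": q,
            "n_partners": n_partners,
        },
        index=gene_ids,
    )
    return SampleDEGCall(
        sample_id=sample_id,
        table=table,
        n_iterations=n_iter,
        converged=converged,
        _index=index,
    )


def call_sample_reo(
    sample: pd.Series,
    background: StableOrderBackground,
    q_threshold: float = 0.05,
    inclusive: bool = True,
) -> SampleDEGCall:
    """Call one disease sample against the stable-ordering background.

    ``sample`` is one column of an expression matrix (a Series indexed by
    gene). Genes with no stable partner are stable with p = 1 by
    convention. This is the first-pass call; apply :func:`refine_calls`
    to enforce the partner-exclusion clause.
    """
    if len(background) == 0:
        logger.warning("empty background: every gene is called stable")
    index = _BackgroundIndex(background, sample.index)
    values = sample.to_numpy(float)
    status, p, q, _ = _call_column(index, values, q_threshold, inclusive)
    return _to_call(sample.name, sample.index, status, p, q, index.n_partners, 0, True, index)


def refine_calls(
    sample_call: SampleDEGCall,
    sample: pd.Series,
    background: StableOrderBackground,
    q_threshold: float = 0.05,
    max_iter: int = 100,
    inclusive: bool = True,
) -> SampleDEGCall:
    """Apply iterative opposite-direction partner exclusion to a first-pass call.

    A gene keeps its call only if it remains significant after the
    reversed pairs supporting it that involve an oppositely called
    partner are excluded. Refinement is a fixed point: refining an
    already refined call changes nothing.
    """
    index = sample_call._index or _BackgroundIndex(background, sample.index)
    values = sample.to_numpy(float)
    node, partner, bg_gt, smp_gt = index.sample_relations(values)
    tested = index.n_partners > 0
    # tested must reflect strictly ordered pairs actually available
    tested = tested & (np.bincount(node, minlength=index.n_genes) > 0)
    status0 = sample_call.table["status"].map({"up": UP, "down": DOWN, "stable": STABLE}).to_numpy(int)
    status, p, q, n_iter, converged = _refine_column(
        index, status0, (node, partner, bg_gt, smp_gt, tested), q_threshold, inclusive, max_iter
    )
    return _to_call(
        sample_call.sample_id, sample.index, status, p, q, index.n_partners, n_iter, converged, index
    )


def cohort_calls(
    cohort: pd.DataFrame,
    background: StableOrderBackground,
    q_threshold: float = 0.05,
    max_iter: int = 100,
    inclusive: bool = True,
) -> list[SampleDEGCall]:
    """First-pass plus refined calls for every column of a disease cohort.

    Samples are independent; the result preserves column order.
    """
    cohort = validate_expression_matrix(cohort, "disease cohort")
    if len(background) == 0:
        logger.warning("empty background: every gene is called stable")
    index = _BackgroundIndex(background, cohort.index)
    calls = []
    matrix = cohort.to_numpy(float)
    for k, sample_id in enumerate(cohort.columns):
        values = matrix[:, k]
        status, p, q, relations = _call_column(index, values, q_threshold, inclusive)
        status, p, q, n_iter, converged = _refine_column(
            index, status, relations, q_threshold, inclusive, max_iter
        )
        calls.append(
            _to_call(sample_id, cohort.index, status, p, q, index.n_partners, n_iter, converged, index)
        )
    return calls
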