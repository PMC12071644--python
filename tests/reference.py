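"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit Python loops and closed-form
enumeration, deliberately sharing no code path with the package: pair
supports by double loops over samples, Fisher p-values by exhaustive
hypergeometric enumeration, BH adjustment from the textbook step-up
definition, and the full per-sample calling/refinement procedure gene by
gene.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def brute_pair_support(normal: pd.DataFrame, gene_a: str, gene_b: str):
    """Majority direction and support fraction by explicit sample loop."""
    gt = lt = 0
    for sample in normal.columns:
        va, vb = normal.at[gene_a, sample], normal.at[gene_b, sample]
        if va > vb:
            gt += 1
        elif va < vb:
            lt += 1
    denom = gt + lt
    if denom == 0:
        return ("gt" if gene_a <= gene_b else "lt"), float("nan")
    if gt > lt:
        return "gt", gt / denom
    if lt > gt:
        return "lt", lt / denom
    return ("gt" if gene_a <= gene_b else "lt"), 0.5


def brute_background(normal: pd.DataFrame, threshold: float = 0.90):
    """Stable pairs as a dict {(gene_a, gene_b): (direction, support)}.

    gene_a lexicographically smaller; requires a strict ordering in more
    than half the samples and support >= threshold.
    """
    genes = sorted(normal.index)
    n_samples = normal.shape[1]
    pairs = {}
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            direction, support = brute_pair_support(normal, a, b)
            gt = lt = 0
            for sample in normal.columns:
                va, vb = normal.at[a, sample], normal.at[b, sample]
                if va > vb:
                    gt += 1
                elif va < vb:
                    lt += 1
            if gt + lt > n_samples / 2 and not math.isnan(support) and support >= threshold:
                pairs[(a, b)] = (direction, support)
    return pairs


def enum_fisher(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with the standard
    relative tolerance for floating-point ties). Degenerate margins give 1.
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    n = r1 + r2

    def pmf(k: int) -> float:
        return math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)

    p_obs = pmf(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(k) <= p_obs * (1 + 1e-7):
            total += pmf(k)
    return min(total, 1.0)


def brute_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def gene_tables(sample: pd.Series, background: dict):
    """Per-gene contingency (a, b, c, d) and per-pair detail rows.

    Detail rows are (gene, partner, bg_gene_gt, sample_gene_gt), one per
    stable pair per endpoint, excluding pairs tied in the sample.
    """
    detail: dict[str, list] = {}
    for (ga, gb), (direction, _support) in background.items():
        if ga not in sample.index or gb not in sample.index:
            continue
        va, vb = sample[ga], sample[gb]
        if va == vb:
            continue  # tie: pair leaves both table rows
        a_gt_b = direction == "gt"
        detail.setdefault(ga, []).append((gb, a_gt_b, va > vb))
        detail.setdefault(gb, []).append((ga, not a_gt_b, vb > va))
    tables = {}
    for gene, rows in detail.items():
        a = sum(1 for (_, bg_gt, _) in rows if bg_gt)
        b = sum(1 for (_, bg_gt, _) in rows if not bg_gt)
        c = sum(1 for (_, _, s_gt) in rows if s_gt)
        d = sum(1 for (_, _, s_gt) in rows if not s_gt)
        tables[gene] = (a, b, c, d)
    return tables, detail


def _statuses_from_tables(tables: dict, genes: list[str], q_threshold: float):
    tested = [g for g in genes if g in tables and sum(tables[g][:2]) > 0]
    p = {g: 1.0 for g in genes}
    for g in tested:
        a, b, c, d = tables[g]
        p[g] = enum_fisher(a, b, c, d)
    q = {g: 1.0 for g in genes}
    if tested:
        adj = brute_bh([p[g] for g in tested])
        for g, qv in zip(tested, adj):
            q[g] = qv
    status = {}
    for g in genes:
        if g in tables and sum(tables[g][:2]) > 0 and q[g] <= q_threshold:
            a, _b, c, _d = tables[g]
            status[g] = "up" if c > a else ("down" if c < a else "stable")
        else:
            status[g] = "stable"
    return status, p, q


def brute_call_sample(sample: pd.Series, background: dict, q_threshold: float = 0.05):
    """First-pass per-sample call: status, p and BH q maps."""
    tables, _ = gene_tables(sample, background)
    return _statuses_from_tables(tables, list(sample.index), q_threshold)


def brute_refine(sample: pd.Series, background: dict, q_threshold: float = 0.05, max_iter: int = 100):
    """Iterative opposite-partner exclusion to a status fixed point.

    Revocation-only: a gene keeps its first-pass call only while it stays
    significant with the same direction under the exclusions implied by
    the current status map; calls are never created during refinement.
    """
    genes = list(sample.index)
    tables, detail = gene_tables(sample, background)
    status, p, q = _statuses_from_tables(tables, genes, q_threshold)
    for _ in range(max_iter):
        reduced = {}
        for gene, rows in detail.items():
            kept = []
            for partner, bg_gt, s_gt in rows:
                drop = (
                    status[gene] == "up" and not bg_gt and s_gt and status[partner] == "down"
                ) or (status[gene] == "down" and bg_gt and not s_gt and status[partner] == "up")
                if not drop:
                    kept.append((partner, bg_gt, s_gt))
            a = sum(1 for (_, bg_gt, _) in kept if bg_gt)
            b = sum(1 for (_, bg_gt, _) in kept if not bg_gt)
            c = sum(1 for (_, _, s_gt) in kept if s_gt)
            d = sum(1 for (_, _, s_gt) in kept if not s_gt)
            reduced[gene] = (a, b, c, d)
        recalled, p, q = _statuses_from_tables(reduced, genes, q_threshold)
        new_status = {g: (status[g] if recalled[g] == status[g] else "stable") for g in genes}
        if new_status == status:
            break
        status = new_status
    return status, p, q


def brute_spearman(x, y):
    """Spearman rho by explicit average ranking and the Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den if den > 0 else 0.0
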