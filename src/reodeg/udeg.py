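"""Dysregulation frequencies and universal-DEG selection.

A gene's dysregulation frequency is the fraction of cohort samples in
which it is called up (or down). Genes meeting the frequency threshold
(default 85%) with the same direction in both a paired and an unpaired
cohort are universal DEGs (UDEGs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from reodeg.calling import SampleDEGCall

__all__ = [
    "UDEGSet",
    "dysregulation_frequency",
    "select_udegs",
    "udeg_report",
    "read_udeg_report",
]

FREQ_COLUMNS = ["up_freq", "down_freq", "n_samples"]


@dataclass
class UDEGSet:
    """Genes passing the frequency threshold in both cohorts, by direction."""

    up_genes: set[str]
    down_genes: set[str]
    threshold: float
    paired: pd.DataFrame
    unpaired: pd.DataFrame
    excluded_genes: set[str] = field(default_factory=set)  # absent from one cohort's universe

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def dysregulation_frequency(calls: list[SampleDEGCall]) -> pd.DataFrame:
    """Per-gene up/down call fractions over a cohort of per-sample calls.

    Returns a frame indexed by gene with ``up_freq``, ``down_freq`` and
    ``n_samples``. All calls must share one gene universe.
    """
    if not calls:
        raise ValueError("dysregulation frequency requires at least one sample call")
    genes = calls[0].table.index
    for call in calls[1:]:
        if not call.table.index.equals(genes):
            raise ValueError(
                f"sample {call.sample_id!r} has a different gene universe than {calls[0].sample_id!r}"
            )
    status = pd.DataFrame({c.sample_id: c.status for c in calls}, index=genes)
    n = len(calls)
    return pd.DataFrame(
        {
            "up_freq": (status == "up").sum(axis=1) / n,
            "down_freq": (status == "down").sum(axis=1) / n,
            "n_samples": n,
        },
        index=genes,
    )


def select_udegs(
    paired: pd.DataFrame,
    unpaired: pd.DataFrame,
    threshold: float = 0.85,
    inclusive: bool = True,
) -> UDEGSet:
    """Intersect paired and unpaired frequency tables at the threshold.

    A gene is an up-UDEG iff its up-frequency meets the threshold in both
    cohorts (and analogously down); a gene exceeding the threshold in
    opposite directions in the two cohorts is excluded. Genes absent from
    either cohort's universe are not candidates and are reported in
    ``excluded_genes``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"UDEG frequency threshold must be in (0, 1], got {threshold}")
    if len(paired) == 0 or len(unpaired) == 0:
        raise ValueError("both frequency tables must be nonempty")
    common = paired.index.intersection(unpaired.index)
    excluded = (set(paired.index) | set(unpaired.index)) - set(common)
    p = paired.loc[common]
    u = unpaired.loc[common]

    def meets(series: pd.Series) -> pd.Series:
        return series >= threshold if inclusive else series > threshold

    up = meets(p["up_freq"]) & meets(u["up_freq"])
    down = meets(p["down_freq"]) & meets(u["down_freq"])
    return UDEGSet(
        up_genes=set(common[up]),
        down_genes=set(common[down]),
        threshold=threshold,
        paired=paired,
        unpaired=unpaired,
        excluded_genes=excluded,
    )


def udeg_report(udegs: UDEGSet, path) -> pd.DataFrame:
    """Write the UDEG table to TSV, sorted by the weaker of the two frequencies.

    Columns: ``gene, direction, paired_freq, unpaired_freq``. Returns the
    frame that was written.
    """
    rows = []
    for gene in udegs.up_genes:
        rows.append((gene, "up", udegs.paired.at[gene, "up_freq"], udegs.unpaired.at[gene, "up_freq"]))
    for gene in udegs.down_genes:
        rows.append(
            (gene, "down", udegs.paired.at[gene, "down_freq"], udegs.unpaired.at[gene, "down_freq"])
        )
    df = pd.DataFrame(rows, columns=["gene", "direction", "paired_freq", "unpaired_freq"])
    df["_key"] = df[["paired_freq", "unpaired_freq"]].min(axis=1)
    df = df.sort_values(["_key", "gene"], ascending=[False, True]).drop(columns="_key")
    df.to_csv(path, sep="\t", index=False)
    return df.reset_index(drop=True)


def read_udeg_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "direction": str})
    if df.empty:
        df = df.astype({"paired_freq": float, "unpaired_freq": float}, errors="ignore")
    return df
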