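"""Synthetic expression, paired-cohort, drug-response and immune-proportion generators.

Every pipeline stage is testable offline against planted ground truth.
The expression model is log-normal: gene *i* carries a fixed location
``mu_i`` on an evenly spaced log-scale grid of step ``baseline_spread``,
and a sample's value is ``exp(mu_i + patient_effect + planted_shift +
Normal(0, noise_sd))``. Only within-sample orderings matter downstream,
so the grid controls ordering stability (pairs far apart on the grid are
stably ordered; adjacent pairs flip under noise) and planted shifts in
log units control how decisively a gene's rank moves.

All generators are deterministic given the spec seed: a single global
seed feeds a named child stream per generator call.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from reodeg.matrix import validate_expression_matrix

__all__ = [
    "SimulationSpec",
    "PlantedTruth",
    "generate_normal_cohort",
    "generate_tumor_cohort",
    "generate_paired_cohort",
    "generate_drug_response",
    "generate_immune_proportions",
]

# (gene id, fraction of cohort samples shifted, log-scale effect size)
PlantedGene = tuple[str, float, float]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults emulate a bulk-transcriptomics regime at desk scale: a few
    hundred genes whose baseline orderings are mostly but not perfectly
    stable across a normal cohort of ~100 samples, tumor cohorts of
    similar size, and a smaller paired cohort.
    """

    n_genes: int = 300
    n_normal: int = 100
    n_tumor: int = 100
    n_pairs: int = 50
    baseline_spread: float = 0.1
    noise_sd: float = 0.2
    planted_up: Sequence[PlantedGene] = field(default_factory=tuple)
    planted_down: Sequence[PlantedGene] = field(default_factory=tuple)
    patient_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for fname in ("n_genes", "n_normal", "n_tumor", "n_pairs"):
            v = getattr(self, fname)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"SimulationSpec.{fname} must be a positive integer, got {v!r}")
        for fname in ("baseline_spread", "noise_sd", "patient_effect_sd"):
            v = getattr(self, fname)
            if not v > 0:
                raise ValueError(f"SimulationSpec.{fname} must be > 0, got {v!r}")
        genes = set(self.gene_ids)
        seen_up, seen_down = set(), set()
        for listname, seen in (("planted_up", seen_up), ("planted_down", seen_down)):
            for entry in getattr(self, listname):
                gene, freq, effect = entry
                if gene not in genes:
                    raise ValueError(f"SimulationSpec.{listname}: gene {gene!r} not in the gene set")
                if not 0.0 <= freq <= 1.0:
                    raise ValueError(f"SimulationSpec.{listname}: frequency {freq!r} for {gene!r} not in [0, 1]")
                if not effect > 0:
                    raise ValueError(f"SimulationSpec.{listname}: effect size {effect!r} for {gene!r} must be > 0")
                if gene in seen:
                    raise ValueError(f"SimulationSpec.{listname}: gene {gene!r} listed twice")
                seen.add(gene)
        overlap = seen_up & seen_down
        if overlap:
            raise ValueError(
                f"SimulationSpec: gene {sorted(overlap)[0]!r} appears in both planted_up and planted_down"
            )

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def gene_locations(self) -> np.ndarray:
        """Fixed per-gene log-scale locations: an evenly spaced grid."""
        return np.arange(self.n_genes) * self.baseline_spread


@dataclass
class PlantedTruth:
    """Ground truth of a generated disease cohort.

    ``direction`` maps each planted gene to ``"up"``/``"down"``;
    ``frequency`` records the realized fraction (shifted samples divided
    by cohort size, exactly); ``shifted_samples`` lists which samples
    received the shift; ``effect`` the log-scale shift magnitude.
    """

    direction: dict[str, str]
    frequency: dict[str, float]
    shifted_samples: dict[str, list[str]]
    effect: dict[str, float]
    n_samples: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(seed: int, label: str) -> np.random.Generator:
    # named child stream: one global seed, one deterministic stream per call site
    return np.random.default_rng([zlib.crc32(label.encode()), seed & 0x7FFFFFFF])


def _n_shifted(freq: float, n: int) -> int:
    """frequency x cohort size rounded to the nearest count, ties up."""
    return int(np.floor(freq * n + 0.5))


def _sample_ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_normal_cohort(spec: SimulationSpec) -> pd.DataFrame:
    """Generate the normal cohort: a consistent ordering backbone plus noise."""
    rng = _rng(spec.seed, "normal")
    mu = spec.gene_locations()[:, None]
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_normal))
    values = np.exp(mu + noise)
    df = pd.DataFrame(values, index=spec.gene_ids, columns=_sample_ids("N", spec.n_normal))
    return validate_expression_matrix(df, "normal cohort")


def _plant(
    spec: SimulationSpec,
    log_values: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> PlantedTruth:
    """Apply planted shifts in place on the log-scale matrix; return the truth."""
    n = log_values.shape[1]
    gene_index = {g: i for i, g in enumerate(spec.gene_ids)}
    direction, frequency, shifted, effect_map = {}, {}, {}, {}
    for entries, sign, label in ((spec.planted_up, +1.0, "up"), (spec.planted_down, -1.0, "down")):
        for gene, freq, effect in entries:
            k = _n_shifted(freq, n)
            cols = np.sort(rng.choice(n, size=k, replace=False))
            log_values[gene_index[gene], cols] += sign * effect
            direction[gene] = label
            frequency[gene] = k / n
            shifted[gene] = [sample_ids[c] for c in cols]
            effect_map[gene] = effect
    return PlantedTruth(direction, frequency, shifted, effect_map, n)


def generate_tumor_cohort(
    spec: SimulationSpec, normal_reference: pd.DataFrame
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate an unpaired tumor cohort on the reference gene set.

    Each planted gene is shifted by its effect size, in its direction, in
    an independently chosen random subset of tumor samples whose size is
    the planted frequency times ``n_tumor`` rounded to the nearest count.
    """
    missing = [g for g in spec.gene_ids if g not in normal_reference.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} of the simulation spec is absent from the normal reference")
    rng = _rng(spec.seed, "tumor")
    sample_ids = _sample_ids("T", spec.n_tumor)
    mu = spec.gene_locations()[:, None]
    log_values = mu + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_tumor))
    truth = _plant(spec, log_values, sample_ids, _rng(spec.seed, "tumor-plant"))
    df = pd.DataFrame(np.exp(log_values), index=spec.gene_ids, columns=sample_ids)
    return validate_expression_matrix(df, "tumor cohort"), truth


def generate_paired_cohort(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate aligned tumor and adjacent-normal matrices for the same patients.

    A shared per-patient, per-gene effect (sd ``patient_effect_sd``) is
    added to both members; planted shifts are applied to the tumor member
    only, in a random subset of patients at the stated frequency.
    """
    if spec.n_pairs <= 0:
        raise ValueError(f"SimulationSpec.n_pairs must be positive, got {spec.n_pairs}")
    rng = _rng(spec.seed, "paired")
    sample_ids = _sample_ids("P", spec.n_pairs)
    mu = spec.gene_locations()[:, None]
    patient = rng.normal(0.0, spec.patient_effect_sd, size=(spec.n_genes, spec.n_pairs))
    log_tumor = mu + patient + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_pairs))
    log_adj = mu + patient + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_pairs))
    truth = _plant(spec, log_tumor, sample_ids, _rng(spec.seed, "paired-plant"))
    tumor = pd.DataFrame(np.exp(log_tumor), index=spec.gene_ids, columns=sample_ids)
    adjacent = pd.DataFrame(np.exp(log_adj), index=spec.gene_ids, columns=sample_ids)
    return (
        validate_expression_matrix(tumor, "paired tumor"),
        validate_expression_matrix(adjacent, "paired adjacent"),
        truth,
    )


def generate_drug_response(
    expr: pd.DataFrame,
    links: Sequence[tuple[str, str, str, float]] = (),
    n_drugs: int = 20,
    missing_rate: float = 0.0,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Generate a cell-line x drug log-IC50 matrix with gene-linked effects.

    ``links`` are ``(gene, drug, sign, strength)`` with sign ``"+"`` or
    ``"-"``: the drug's log-IC50 is ``sign * strength * z(log expr[gene])
    + Normal(0, noise_sd)`` across cell lines, so strong positive links
    make high expressors resistant. Drugs named in links must be among
    the ``n_drugs`` generated drug ids (``D001``...). Entries are masked
    missing at ``missing_rate``, independently.
    """
    if n_drugs <= 0:
        raise ValueError(f"n_drugs must be positive, got {n_drugs}")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = _rng(seed, "drug-response")
    lines = list(expr.columns)
    width = max(3, len(str(n_drugs)))
    drugs = [f"D{i:0{width}d}" for i in range(1, n_drugs + 1)]
    values = rng.normal(0.0, noise_sd, size=(len(lines), n_drugs))
    drug_index = {d: j for j, d in enumerate(drugs)}
    for gene, drug, sign, strength in links:
        if gene not in expr.index:
            raise ValueError(f"linked gene {gene!r} not in the expression matrix")
        if drug not in drug_index:
            raise ValueError(f"linked drug {drug!r} not among the generated drugs")
        if sign not in ("+", "-"):
            raise ValueError(f"link sign must be '+' or '-', got {sign!r}")
        if not strength > 0:
            raise ValueError(f"link strength must be > 0, got {strength!r}")
        x = np.log(expr.loc[gene].to_numpy(float))
        z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        values[:, drug_index[drug]] += (1.0 if sign == "+" else -1.0) * strength * z
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)
    return pd.DataFrame(values, index=pd.Index(lines, name="cell_line"), columns=drugs)


def generate_immune_proportions(
    sample_ids: Sequence[str],
    cell_types: Sequence[str] | int = 8,
    seed: int = 0,
    concentration: float = 2.0,
) -> pd.DataFrame:
    """Generate a samples x cell-type proportion matrix (rows sum to 1).

    Proportions are Dirichlet-distributed per sample, mimicking the output
    shape of bulk immune deconvolution.
    """
    if isinstance(cell_types, int):
        cell_types = [f"CellType{i:02d}" for i in range(1, cell_types + 1)]
    rng = _rng(seed, "immune-proportions")
    alpha = np.full(len(cell_types), concentration)
    values = rng.dirichlet(alpha, size=len(sample_ids))
    return pd.DataFrame(values, index=pd.Index(sample_ids, name="sample"), columns=list(cell_types))
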