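"""End-to-end pipeline: background -> per-sample calls -> frequencies -> UDEGs -> screens.

Every intermediate table is written to the output directory together
with a machine-readable manifest recording inputs, thresholds, seed,
package version and per-stage counts. Any stage failure aborts with the
stage name; artifacts of completed stages are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from reodeg import __version__ as _version
from reodeg import simulate as _sim
from reodeg.association import filter_drugs, immune_correlation, spearman_screen
from reodeg.background import build_background, write_background
from reodeg.calling import call_paired, cohort_calls
from reodeg.io import (
    RunConfig,
    read_drug_response,
    read_expression,
    read_proportions,
    write_calls,
    write_expression,
)
from reodeg.simulate import (
    SimulationSpec,
    generate_drug_response,
    generate_immune_proportions,
    generate_normal_cohort,
    generate_paired_cohort,
    generate_tumor_cohort,
)
from reodeg.udeg import dysregulation_frequency, select_udegs, udeg_report

__all__ = ["PipelineError", "run_pipeline", "simulate_bundle"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow described by ``config``; return the manifest."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version,
        "inputs": config.required_paths(),
        "thresholds": {
            "stable_threshold": config.stable_threshold,
            "q_threshold": config.q_threshold,
            "udeg_threshold": config.udeg_threshold,
            "min_drug_coverage": config.min_drug_coverage,
            "p_threshold": config.p_threshold,
            "q_inclusive": config.q_inclusive,
            "udeg_inclusive": config.udeg_inclusive,
            "coverage_inclusive": config.coverage_inclusive,
            "max_iter": config.max_iter,
        },
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                counts = fn()
            except Exception as exc:  # abort, but keep completed artifacts
                _write_manifest(manifest, out)
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = counts
            logger.info("stage %s: %s", name, counts)
            return counts

        return wrap

    state: dict = {}

    @stage("load_inputs")
    def _load():
        state["normal"] = read_expression(config.normal)
        state["tumor"] = read_expression(config.tumor)
        state["paired_tumor"] = read_expression(config.paired_tumor)
        state["paired_adjacent"] = read_expression(config.paired_adjacent)
        return {
            "n_genes": state["normal"].shape[0],
            "n_normal": state["normal"].shape[1],
            "n_tumor": state["tumor"].shape[1],
            "n_pairs": state["paired_tumor"].shape[1],
        }

    @stage("background")
    def _background():
        bg = build_background(state["normal"], threshold=config.stable_threshold)
        write_background(bg, out / "background.tsv")
        state["background"] = bg
        return {"n_stable_pairs": len(bg)}

    @stage("paired_calls")
    def _paired():
        calls = call_paired(state["paired_tumor"], state["paired_adjacent"])
        write_calls(calls, out / "paired_calls.tsv")
        freq = dysregulation_frequency(calls)
        freq.to_csv(out / "paired_frequency.tsv", sep="\t", index_label="gene")
        state["paired_freq"] = freq
        return _freq_counts(freq, config.udeg_threshold, config.udeg_inclusive)

    @stage("unpaired_calls")
    def _unpaired():
        calls = cohort_calls(
            state["tumor"],
            state["background"],
            q_threshold=config.q_threshold,
            max_iter=config.max_iter,
            inclusive=config.q_inclusive,
        )
        write_calls(calls, out / "unpaired_calls.tsv")
        freq = dysregulation_frequency(calls)
        freq.to_csv(out / "unpaired_frequency.tsv", sep="\t", index_label="gene")
        state["unpaired_freq"] = freq
        return _freq_counts(freq, config.udeg_threshold, config.udeg_inclusive)

    @stage("udeg_selection")
    def _udeg():
        udegs = select_udegs(
            state["paired_freq"],
            state["unpaired_freq"],
            threshold=config.udeg_threshold,
            inclusive=config.udeg_inclusive,
        )
        udeg_report(udegs, out / "udegs.tsv")
        state["udegs"] = udegs
        return {"n_up": len(udegs.up_genes), "n_down": len(udegs.down_genes)}

    if config.drug_response is not None and config.cell_line_expression is not None:

        @stage("drug_screen")
        def _drug():
            resp = read_drug_response(config.drug_response)
            expr = read_expression(config.cell_line_expression)
            kept = filter_drugs(
                resp, min_coverage=config.min_drug_coverage, inclusive=config.coverage_inclusive
            )
            genes = sorted(state["udegs"].up_genes | state["udegs"].down_genes)
            genes = [g for g in genes if g in expr.index]
            if not genes:
                (out / "drug_screen.tsv").write_text("gene\tdrug\trho\tp\tn_used\tp_method\tsignificant\tsign\n")
                return {"n_drugs_kept": kept.shape[1], "n_genes": 0, "n_significant": 0}
            result = spearman_screen(expr.loc[genes], kept, p_threshold=config.p_threshold)
            result.to_csv(out / "drug_screen.tsv", sep="\t", index=False)
            return {
                "n_drugs_kept": kept.shape[1],
                "n_genes": len(genes),
                "n_significant": int(result["significant"].sum()),
            }

    if config.immune_proportions is not None:

        @stage("immune_screen")
        def _immune():
            proportions = read_proportions(config.immune_proportions)
            genes = sorted(state["udegs"].up_genes | state["udegs"].down_genes)
            genes = [g for g in genes if g in state["tumor"].index]
            if not genes:
                (out / "immune_screen.tsv").write_text(
                    "gene\tcell_type\trho\tp\tn_used\tp_method\tsignificant\tsign\n"
                )
                return {"n_genes": 0, "n_significant": 0}
            result = immune_correlation(
                state["tumor"].loc[genes], proportions, p_threshold=config.p_threshold
            )
            result.to_csv(out / "immune_screen.tsv", sep="\t", index=False)
            return {"n_genes": len(genes), "n_significant": int(result["significant"].sum())}

    _write_manifest(manifest, out)
    return manifest


def _freq_counts(freq: pd.DataFrame, threshold: float, inclusive: bool) -> dict:
    up = freq["up_freq"] >= threshold if inclusive else freq["up_freq"] > threshold
    down = freq["down_freq"] >= threshold if inclusive else freq["down_freq"] > threshold
    return {
        "n_samples": int(freq["n_samples"].iloc[0]),
        "n_up_at_threshold": int(up.sum()),
        "n_down_at_threshold": int(down.sum()),
    }


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def simulate_bundle(
    spec: SimulationSpec,
    outdir,
    n_cell_lines: int = 32,
    n_drugs: int = 20,
    drug_links: tuple = (),
    drug_missing_rate: float = 0.1,
    n_cell_types: int = 8,
) -> RunConfig:
    """Materialize every input the pipeline needs, plus truth sidecars.

    Writes the normal, tumor and paired matrices, a cell-line expression
    matrix drawn from the same gene backbone, a linked IC50 matrix,
    Dirichlet immune proportions for the tumor samples, truth JSON files,
    and a ready-to-run ``config.yaml``. Returns the RunConfig.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    normal = generate_normal_cohort(spec)
    tumor, tumor_truth = generate_tumor_cohort(spec, normal)
    paired_tumor, paired_adjacent, paired_truth = generate_paired_cohort(spec)
    write_expression(normal, outdir / "normal.tsv")
    write_expression(tumor, outdir / "tumor.tsv")
    write_expression(paired_tumor, outdir / "paired_tumor.tsv")
    write_expression(paired_adjacent, outdir / "paired_adjacent.tsv")
    tumor_truth.to_json(outdir / "tumor_truth.json")
    paired_truth.to_json(outdir / "paired_truth.json")

    # cell-line cohort on the same gene backbone, its own noise stream
    rng = _sim._rng(spec.seed, "cell-lines")
    mu = spec.gene_locations()[:, None]
    log_values = mu + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_cell_lines))
    lines = [f"CL{i:03d}" for i in range(1, n_cell_lines + 1)]
    cell_expr = pd.DataFrame(np.exp(log_values), index=spec.gene_ids, columns=lines)
    write_expression(cell_expr, outdir / "cell_line_expression.tsv")

    resp = generate_drug_response(
        cell_expr, links=drug_links, n_drugs=n_drugs, missing_rate=drug_missing_rate, seed=spec.seed
    )
    resp.to_csv(outdir / "drug_response.tsv", sep="\t", index_label="cell_line")

    proportions = generate_immune_proportions(list(tumor.columns), n_cell_types, seed=spec.seed)
    proportions.to_csv(outdir / "immune_proportions.tsv", sep="\t", index_label="sample")

    config = RunConfig(
        normal=str(outdir / "normal.tsv"),
        tumor=str(outdir / "tumor.tsv"),
        paired_tumor=str(outdir / "paired_tumor.tsv"),
        paired_adjacent=str(outdir / "paired_adjacent.tsv"),
        drug_response=str(outdir / "drug_response.tsv"),
        cell_line_expression=str(outdir / "cell_line_expression.tsv"),
        immune_proportions=str(outdir / "immune_proportions.tsv"),
        output_dir=str(outdir / "results"),
        seed=spec.seed,
    )
    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "simulation_spec.json", "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=1, default=list)
    return config
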