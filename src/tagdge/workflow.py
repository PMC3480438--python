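"""End-to-end two-library DGE experiment on synthetic data.

Convenience driver wiring the stages together: generate a transcriptome and
truth table, simulate paired raw tag libraries, run QC, build the reference
tag library, map, quantify, and call differential expression.  Used by the
examples and by simulation studies; each stage remains individually callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import call_degs
from .library import ReferenceTagLibrary, build_tag_library
from .mapping import ExpressionVector, MappingResult, map_library, tpm_normalize
from .qc import TagCountSet, filter_raw_tags
from .reporting import LibraryReport, build_library_report
from .simulate import (
    SimulationConfig,
    SyntheticTranscript,
    TruthTable,
    generate_transcriptome,
    make_truth_table,
    simulate_tag_reads,
)

__all__ = ["PipelineResult", "run_two_library_experiment", "evaluate_de_calls"]


@dataclass
class PipelineResult:
    """Everything one simulated two-library comparison produces."""

    config: SimulationConfig
    transcripts: list[SyntheticTranscript]
    truth: TruthTable
    library: ReferenceTagLibrary
    qc: dict[str, TagCountSet]
    mapping: dict[str, MappingResult]
    expression: dict[str, ExpressionVector]
    degs: pd.DataFrame
    reports: dict[str, LibraryReport] = field(default_factory=dict)


def run_two_library_experiment(
    config: SimulationConfig,
    n_de: int = 50,
    log2fc: float = 3.0,
    min_de_abundance: float = 2e-4,
    max_fdr: float = 0.001,
    min_abs_log2: float = 1.0,
) -> PipelineResult:
    """Simulate conditions A and B and run the full pipeline on both."""
    transcripts = generate_transcriptome(config)
    truth = make_truth_table(
        transcripts,
        n_de=n_de,
        log2fc=log2fc,
        min_de_abundance=min_de_abundance,
        seed=config.seed,
    )
    library = build_tag_library(transcripts)
    universe = [t.gene_id for t in transcripts]

    qc, mapping, expression, reports = {}, {}, {}, {}
    for cond in ("A", "B"):
        reads = simulate_tag_reads(transcripts, truth, config, cond)
        qc[cond] = filter_raw_tags(reads, config.adapter)
        mapping[cond] = map_library(qc[cond], library)
        expression[cond] = tpm_normalize(
            mapping[cond], qc[cond].clean_total, gene_universe=universe
        )
        reports[cond] = build_library_report(qc[cond], mapping[cond], len(transcripts))

    degs = call_degs(
        expression["A"], expression["B"], max_fdr=max_fdr, min_abs_log2=min_abs_log2
    )
    return PipelineResult(
        config, transcripts, truth, library, qc, mapping, expression, degs, reports
    )


def evaluate_de_calls(degs: pd.DataFrame, truth: TruthTable) -> dict:
    """Confusion summary of DE calls against the planted truth."""
    called = set(degs.loc[degs["call"] != "not-DE", "gene_id"])
    planted = set(np.asarray(truth.genes)[truth.is_de])
    tp = len(called & planted)
    fp = len(called - planted)
    return {
        "n_called": len(called),
        "n_planted": len(planted),
        "tp": tp,
        "fp": fp,
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "empirical_fdr": fp / len(called) if called else 0.0,
    }
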