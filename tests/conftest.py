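import numpy as np
import pytest
from hypothesis import settings

import tagdge as t

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim():
    """A mid-sized two-condition simulation shared across test modules.

    200 genes, 10^5 tags per library, 20 planted DE genes at |log2FC|=3,
    default error/contaminant rates.
    """
    cfg = t.SimulationConfig(n_genes=200, depth=100_000, seed=11)
    tx = t.generate_transcriptome(cfg)
    truth = t.make_truth_table(tx, n_de=20, seed=11, min_de_abundance=1e-3)
    lib = t.build_tag_library(tx)
    reads = {c: t.simulate_tag_reads(tx, truth, cfg, c) for c in "AB"}
    qc = {c: t.filter_raw_tags(reads[c], cfg.adapter) for c in "AB"}
    mapping = {c: t.map_library(qc[c], lib) for c in "AB"}
    return {
        "cfg": cfg,
        "tx": tx,
        "truth": truth,
        "lib": lib,
        "reads": reads,
        "qc": qc,
        "mapping": mapping,
        "universe": [x.gene_id for x in tx],
    }


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, contaminant-free simulation with uniform abundances.

    Every gene carries a tag site and is deep enough that biological
    singletons are essentially impossible, so QC/mapping results can be
    compared against truth labels exactly.
    """
    cfg = t.SimulationConfig(
        n_genes=20,
        depth=20_000,
        catg_fraction=1.0,
        base_error_rate=0.0,
        adapter_only_rate=0.0,
        n_read_rate=0.0,
        singleton_noise_rate=0.0,
        seed=5,
    )
    tx = t.generate_transcriptome(cfg)
    n = len(tx)
    a = np.full(n, 1.0 / n)
    truth = t.TruthTable(
        genes=[x.gene_id for x in tx],
        abundance_a=a,
        abundance_b=a.copy(),
        log2fc=np.zeros(n),
        is_de=np.zeros(n, dtype=bool),
    )
    reads = t.simulate_tag_reads(tx, truth, cfg, "A")
    return {"cfg": cfg, "tx": tx, "truth": truth, "reads": reads}
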