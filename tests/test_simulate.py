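"""Synthetic-data generator: determinism, CATG-site control, read structure."""

import re
from collections import Counter

import numpy as np
import pytest

import tagdge as t


def _fasta_bytes(cfg, tmp_path, name):
    tx = t.generate_transcriptome(cfg)
    p = tmp_path / name
    t.write_fasta(tx, p)
    return p.read_bytes()


def test_transcriptome_deterministic_under_seed(tmp_path):
    cfg = t.SimulationConfig(n_genes=100, seed=1)
    assert _fasta_bytes(cfg, tmp_path, "a.fa") == _fasta_bytes(cfg, tmp_path, "b.fa")


def test_different_seeds_differ(tmp_path):
    a = _fasta_bytes(t.SimulationConfig(n_genes=100, seed=1), tmp_path, "a.fa")
    b = _fasta_bytes(t.SimulationConfig(n_genes=100, seed=2), tmp_path, "b.fa")
    assert a != b


def test_full_catg_fraction_forces_a_tag_site_everywhere():
    tx = t.generate_transcriptome(t.SimulationConfig(n_genes=500, catg_fraction=1.0, seed=2))
    assert all(x.tag_3prime() is not None for x in tx)


def test_catg_bearing_count_matches_regex_scan_of_emitted_fasta(tmp_path):
    """Independent oracle: regex scan of the written FASTA file."""
    cfg = t.SimulationConfig(n_genes=200, seed=7)
    tx = t.generate_transcriptome(cfg)
    p = tmp_path / "ref.fa"
    t.write_fasta(tx, p)

    n_bearing = 0
    for gene_id, seq in t.read_fasta(p):
        if any(m.start() + 21 <= len(seq) for m in re.finditer("(?=CATG)", seq)):
            n_bearing += 1
    assert n_bearing == sum(x.tag_3prime() is not None for x in tx)
    assert n_bearing == round(cfg.catg_fraction * cfg.n_genes)


def test_min_length_and_alphabet():
    tx = t.generate_transcriptome(t.SimulationConfig(n_genes=150, seed=3))
    assert all(x.length >= 100 for x in tx)
    assert all(set(x.sequence) <= set("ACGT") for x in tx)


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_genes", 0),
        ("depth", 0),
        ("base_error_rate", 1.5),
        ("catg_fraction", -0.1),
        ("adapter", "ACNGT"),
        ("min_length", 50),
    ],
)
def test_invalid_config_rejected_naming_field(field, value):
    cfg = t.SimulationConfig(**{field: value})
    with pytest.raises(ValueError, match=field.split("_")[0]):
        cfg.validate()


def test_error_free_reads_start_with_a_sense_tag_of_their_gene(clean_sim):
    tx = {x.gene_id: x for x in clean_sim["tx"]}
    reads = clean_sim["reads"]
    sense_tags = {
        g: {x.sequence[i : i + 21] for i in t.sense_tag_offsets(x.sequence)}
        for g, x in tx.items()
    }
    for read, cat, gene in zip(reads.reads, reads.category, reads.source_gene):
        assert cat == "biological"
        assert read[:21] in sense_tags[gene]
        # and specifically the 3'-most site's tag
        assert read[:21] == tx[gene].tag_3prime()


def test_read_counts_follow_the_abundance_vector_binomially(clean_sim):
    """A gene at abundance 0.05 should land within 4 binomial SDs."""
    reads = clean_sim["reads"]
    n = len(reads)
    p = 1.0 / len(clean_sim["tx"])
    counts = Counter(reads.source_gene)
    sd = np.sqrt(n * p * (1 - p))
    for g in clean_sim["truth"].genes:
        assert abs(counts[g] - n * p) < 4 * sd


def test_fastq_deterministic_and_depth_partition(tmp_path):
    cfg = t.SimulationConfig(n_genes=50, depth=5000, seed=9)
    tx = t.generate_transcriptome(cfg)
    truth = t.make_truth_table(tx, n_de=5, seed=9, min_de_abundance=2e-3)
    out = []
    for name in ("x.fq", "y.fq"):
        reads = t.simulate_tag_reads(tx, truth, cfg, "A")
        p = tmp_path / name
        t.write_fastq(reads, p)
        out.append(p.read_bytes())
    assert out[0] == out[1]

    reads = t.simulate_tag_reads(tx, truth, cfg, "A")
    assert len(reads) == cfg.depth
    assert sum(reads.category_counts().values()) == cfg.depth
    assert all(len(r) == cfg.read_length for r in reads.reads)


def test_conditions_a_and_b_are_independent_streams():
    cfg = t.SimulationConfig(n_genes=50, depth=2000, seed=9)
    tx = t.generate_transcriptome(cfg)
    truth = t.make_truth_table(tx, n_de=5, seed=9, min_de_abundance=2e-3)
    a = t.simulate_tag_reads(tx, truth, cfg, "A")
    b = t.simulate_tag_reads(tx, truth, cfg, "B")
    assert a.reads != b.reads
    with pytest.raises(ValueError, match="condition"):
        truth.abundance("C")


def test_mass_reassignment_warns_for_siteless_genes():
    cfg = t.SimulationConfig(n_genes=40, depth=1000, catg_fraction=0.5, seed=4)
    tx = t.generate_transcriptome(cfg)
    truth = t.make_truth_table(
        tx, n_de=0, seed=4, min_de_abundance=0.0, restrict_to_taggable=False
    )
    with pytest.warns(UserWarning, match="reassigning"):
        reads = t.simulate_tag_reads(tx, truth, cfg, "A")
    taggable = {x.gene_id for x in tx if x.tag_3prime() is not None}
    bio = {g for g, c in zip(reads.source_gene, reads.category) if c == "biological"}
    assert bio <= taggable


def test_truth_table_invariants():
    tx = t.generate_transcriptome(t.SimulationConfig(n_genes=100, seed=6))
    truth = t.make_truth_table(tx, n_de=10, log2fc=3.0, seed=6, min_de_abundance=1e-3)
    assert np.isclose(truth.abundance_a.sum(), 1.0)
    assert np.isclose(truth.abundance_b.sum(), 1.0)
    assert truth.is_de.sum() == 10
    assert np.array_equal(truth.is_de, np.abs(truth.log2fc) >= truth.de_threshold)
    # planted effects keep their sign in the realized abundance ratio
    de = truth.is_de
    ratio = np.log2(truth.abundance_b[de] / truth.abundance_a[de])
    assert np.all(np.sign(ratio) == np.sign(truth.log2fc[de]))


def test_annotation_fixed_term_size_and_determinism(tmp_path):
    genes = [f"g{i}" for i in range(100)]
    ann = t.generate_annotation(genes, n_terms=10, term_size=5, seed=2)
    sizes = ann.groupby("term_id").size()
    assert (sizes == 5).all() and len(sizes) == 10
    assert set(ann["gene_id"]) <= set(genes)

    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    t.write_annotation(t.generate_annotation(genes, n_terms=10, seed=3), p1)
    t.write_annotation(t.generate_annotation(genes, n_terms=10, seed=3), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_annotation_rejects_empty_gene_list():
    with pytest.raises(ValueError, match="non-empty"):
        t.generate_annotation([], n_terms=5)


def test_truth_tsv_roundtrip(tmp_path):
    import pandas as pd

    tx = t.generate_transcriptome(t.SimulationConfig(n_genes=30, seed=8))
    truth = t.make_truth_table(tx, n_de=3, seed=8, min_de_abundance=1e-3)
    p = tmp_path / "truth.tsv"
    t.write_truth_table(truth, p)
    back = pd.read_csv(p, sep="\t")
    assert list(back.columns) == ["gene_id", "abundance_A", "abundance_B", "log2fc", "is_DE"]
    assert back["is_DE"].sum() == 3
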