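"""Synthetic DGE data: transcriptomes, truth tables, raw 49-nt tag reads, annotations.

The generator emulates the statistical structure of a tag-based digital gene
expression (DGE) experiment: a reference transcript set with variable length
and CATG-site content, and paired raw tag libraries drawn multinomially from
per-gene abundance vectors with planted log2 fold changes.  Each biological
read is the 3'-most sense-strand CATG+17nt tag of its source transcript (the
library protocol captures the 3' cDNA fragment on oligo(dT) beads, so only the
3'-most NlaIII site survives MmeI digestion), carries per-base sequencing
error at a configurable rate, and is padded to 49 nt with a fixed 3' adapter.
Contaminant reads -- adapter-only, N-containing, and singleton noise tags --
are injected at configurable rates, and every read keeps a truth label so the
QC and mapping stages have an exact ground-truth surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ADAPTER",
    "SimulationConfig",
    "SyntheticTranscript",
    "TruthTable",
    "SimulatedReads",
    "generate_transcriptome",
    "make_truth_table",
    "simulate_tag_reads",
    "generate_annotation",
    "sense_tag_offsets",
    "write_fasta",
    "write_fastq",
    "write_truth_table",
    "write_annotation",
]

# Fixed 28-nt 3' adapter padding the 21-nt tag to the 49-nt read length.
# The exact sequence is arbitrary (it is a configurable constant); it must not
# contain N and should not begin with CATG.
DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTGAAAAAAA"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# read categories carried as truth labels
BIOLOGICAL = "biological"
ADAPTER_ONLY = "adapter_only"
N_READ = "n_containing"
SINGLETON_NOISE = "singleton_noise"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sense_tag_offsets(seq: str) -> list[int]:
    """0-based offsets of every CATG on the sense strand with >=17 nt downstream."""
    out = []
    start = 0
    while True:
        i = seq.find("CATG", start)
        if i == -1:
            break
        if i + 21 <= len(seq):
            out.append(i)
        start = i + 1
    return out


@dataclass(frozen=True)
class SyntheticTranscript:
    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def tag_3prime(self) -> str | None:
        """The 3'-most sense CATG+17 tag, or None if the gene has no usable site."""
        offs = sense_tag_offsets(self.sequence)
        if not offs:
            return None
        i = offs[-1]
        return self.sequence[i : i + 21]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic DGE experiment.

    Lengths are drawn from a lognormal with the given mean (676 bp, the mean
    assembled-transcript length this generator emulates) and floored at
    ``min_length``.  ``catg_fraction`` of transcripts are guaranteed at least
    one sense-strand CATG site with 17 bases downstream; the remainder are
    guaranteed none.  Contaminant-rate defaults target a clean/raw tag
    fraction around 98.4%.
    """

    n_genes: int = 1000
    mean_length: int = 676
    min_length: int = 100
    length_sigma: float = 0.5
    gc_content: float = 0.42
    catg_fraction: float = 0.95
    depth: int = 500_000
    base_error_rate: float = 5e-4
    adapter_only_rate: float = 0.004
    n_read_rate: float = 0.004
    singleton_noise_rate: float = 0.003
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 49
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.min_length < 100:
            raise ValueError("min_length must be >= 100")
        if self.mean_length < self.min_length:
            raise ValueError("mean_length must be >= min_length")
        if self.length_sigma <= 0:
            raise ValueError("length_sigma must be > 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        for name in ("catg_fraction", "base_error_rate", "adapter_only_rate",
                     "n_read_rate", "singleton_noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.adapter_only_rate + self.n_read_rate + self.singleton_noise_rate > 1.0:
            raise ValueError("contaminant rates must sum to <= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not self.adapter or "N" in self.adapter:
            raise ValueError("adapter must be non-empty and N-free")
        if self.read_length < 21:
            raise ValueError("read_length must be >= 21")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _remove_sense_catg(seq: str) -> str:
    # break every sense CATG by flipping its C -> A; repeat in case edits
    # create new sites (AC|ATG etc.)
    while "CATG" in seq:
        i = seq.find("CATG")
        seq = seq[:i] + "A" + seq[i + 1 :]
    return seq


def generate_transcriptome(config: SimulationConfig) -> list[SyntheticTranscript]:
    """Generate a synthetic reference transcript set.

    Deterministic under ``config.seed``.  Exactly
    ``round(catg_fraction * n_genes)`` transcripts carry >=1 sense CATG+17
    site; the rest carry none on the sense strand.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mu = np.log(config.mean_length) - config.length_sigma**2 / 2
    lengths = np.maximum(
        rng.lognormal(mu, config.length_sigma, size=config.n_genes).astype(int),
        config.min_length,
    )
    n_bearing = int(round(config.catg_fraction * config.n_genes))
    bearing = np.zeros(config.n_genes, dtype=bool)
    bearing[rng.permutation(config.n_genes)[:n_bearing]] = True

    width = len(str(config.n_genes))
    out = []
    for g in range(config.n_genes):
        seq = _random_seq(rng, int(lengths[g]), config.gc_content)
        if bearing[g]:
            if not sense_tag_offsets(seq):
                # plant one CATG at a position with 17 nt downstream
                pos = int(rng.integers(0, len(seq) - 20))
                seq = seq[:pos] + "CATG" + seq[pos + 4 :]
        else:
            seq = _remove_sense_catg(seq)
        out.append(SyntheticTranscript(f"gene{g + 1:0{width}d}", seq))
    return out


@dataclass
class TruthTable:
    """Ground truth for a two-condition DGE simulation.

    ``abundance_a``/``abundance_b`` each sum to 1 over genes; ``log2fc`` is
    the planted per-gene log2(B/A) effect and ``is_de`` flags genes whose
    planted |log2fc| meets ``de_threshold``.
    """

    genes: list[str]
    abundance_a: np.ndarray
    abundance_b: np.ndarray
    log2fc: np.ndarray
    is_de: np.ndarray
    de_threshold: float = 1.0
    terms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("abundance_a", "abundance_b"):
            a = getattr(self, name)
            if not np.isclose(a.sum(), 1.0):
                raise ValueError(f"{name} must sum to 1")
            if (a < 0).any():
                raise ValueError(f"{name} must be non-negative")
        expect = np.abs(self.log2fc) >= self.de_threshold
        if not np.array_equal(expect, self.is_de):
            raise ValueError("is_de must equal |log2fc| >= de_threshold")

    def abundance(self, condition: str) -> np.ndarray:
        if condition == "A":
            return self.abundance_a
        if condition == "B":
            return self.abundance_b
        raise ValueError(f"condition must be 'A' or 'B', got {condition!r}")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "abundance_A": self.abundance_a,
                "abundance_B": self.abundance_b,
                "log2fc": self.log2fc,
                "is_DE": self.is_de,
            }
        )


def make_truth_table(
    transcripts: list[SyntheticTranscript],
    n_de: int = 50,
    log2fc: float = 3.0,
    de_threshold: float = 1.0,
    abundance_sigma: float = 1.0,
    min_de_abundance: float = 2e-4,
    seed: int = 0,
    restrict_to_taggable: bool = True,
) -> TruthTable:
    """Draw per-gene abundances and plant ``n_de`` DE genes at |log2fc|.

    Baseline abundances are lognormal (dispersion ``abundance_sigma``) and
    normalised; DE genes are chosen among genes with baseline relative
    abundance >= ``min_de_abundance`` so every planted effect sits on a gene
    deep enough to be measurable, with signs split at random.  By default only
    transcripts carrying a usable sense tag site receive nonzero abundance.
    """
    rng = np.random.default_rng(seed)
    n = len(transcripts)
    base = rng.lognormal(0.0, abundance_sigma, size=n)
    if restrict_to_taggable:
        taggable = np.array([t.tag_3prime() is not None for t in transcripts])
        if not taggable.any():
            raise ValueError("no transcript has a usable sense CATG+17 site")
        base[~taggable] = 0.0
    a = base / base.sum()

    eligible = np.flatnonzero(a >= min_de_abundance)
    if len(eligible) < n_de:
        raise ValueError(
            f"only {len(eligible)} genes reach min_de_abundance; cannot plant {n_de}"
        )
    de_idx = rng.choice(eligible, size=n_de, replace=False)
    lfc = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[de_idx] = signs * abs(log2fc)

    b = a * np.exp2(lfc)
    b = b / b.sum()
    return TruthTable(
        genes=[t.gene_id for t in transcripts],
        abundance_a=a,
        abundance_b=b,
        log2fc=lfc,
        is_de=np.abs(lfc) >= de_threshold,
        de_threshold=de_threshold,
    )


@dataclass
class SimulatedReads:
    """A raw 49-nt read stream with per-read truth labels."""

    reads: list[str]
    category: np.ndarray  # one of BIOLOGICAL/ADAPTER_ONLY/N_READ/SINGLETON_NOISE
    source_gene: np.ndarray  # gene_id for biological/N reads, "" otherwise
    library: str = ""
    read_length: int = 49

    def __len__(self) -> int:
        return len(self.reads)

    def category_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.category, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _apply_errors(tag: str, rng: np.random.Generator, k: int) -> str:
    pos = rng.choice(len(tag), size=k, replace=False)
    chars = list(tag)
    for p in pos:
        alts = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_tag_reads(
    transcripts: list[SyntheticTranscript],
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
) -> SimulatedReads:
    """Simulate one raw DGE tag library (49-nt reads) for condition A or B.

    Read counts per category come from one multinomial draw at the configured
    rates, so the depth is partitioned exactly.  Biological reads are the
    3'-most sense tag of a gene drawn from the condition's abundance vector,
    with per-base substitution error on the 21-nt tag, padded with the
    adapter.  Genes with nonzero abundance but no usable tag site have their
    mass reassigned to the remaining genes with a warning.
    """
    config.validate()
    abund = truth.abundance(condition).copy()
    if truth.genes != [t.gene_id for t in transcripts]:
        raise ValueError("truth table and transcript set disagree on gene ids")

    tags = [t.tag_3prime() for t in transcripts]
    no_site = np.array([tg is None for tg in tags]) & (abund > 0)
    if no_site.any():
        lost = abund[no_site].sum()
        warnings.warn(
            f"{int(no_site.sum())} gene(s) with abundance {lost:.3g} have no "
            "sense CATG+17 site; reassigning their mass",
            stacklevel=2,
        )
        abund[no_site] = 0.0
        abund = abund / abund.sum()

    # condition folded into the seed so A and B are independent streams
    rng = np.random.default_rng([config.seed, 0 if condition == "A" else 1])
    rates = [config.adapter_only_rate, config.n_read_rate,
             config.singleton_noise_rate]
    n_adapter, n_nread, n_noise, n_bio = rng.multinomial(
        config.depth, rates + [1.0 - sum(rates)]
    )

    L = config.read_length
    adapter_read = (config.adapter * (L // len(config.adapter) + 1))[:L]

    def pad(tag: str) -> str:
        return (tag + config.adapter * ((L - len(tag)) // len(config.adapter) + 1))[:L]

    # biological reads (N-reads are biological reads with one base masked);
    # padded tags are precomputed per gene, only error/N reads are patched
    n_biolike = int(n_bio + n_nread)
    gidx = rng.choice(len(transcripts), size=n_biolike, p=abund)
    nerr = rng.binomial(21, config.base_error_rate, size=n_biolike)
    padded = [pad(tg) if tg is not None else None for tg in tags]
    gene_ids = [t.gene_id for t in transcripts]

    reads = [padded[g] for g in gidx]
    for j in np.flatnonzero(nerr):
        tag = _apply_errors(tags[gidx[j]], rng, int(nerr[j]))
        reads[j] = pad(tag)
    for j in range(int(n_bio), n_biolike):
        p = int(rng.integers(0, 21))
        r = reads[j]
        reads[j] = r[:p] + "N" + r[p + 1 :]
    cats = [BIOLOGICAL] * int(n_bio) + [N_READ] * int(n_nread)
    genes = [gene_ids[g] for g in gidx]

    for _ in range(int(n_adapter)):
        reads.append(adapter_read)
        cats.append(ADAPTER_ONLY)
        genes.append("")

    seen: set[str] = set()
    for _ in range(int(n_noise)):
        while True:
            t = "CATG" + rng.choice(_BASES, size=17).tobytes().decode()
            if t not in seen:
                seen.add(t)
                break
        reads.append(pad(t))
        cats.append(SINGLETON_NOISE)
        genes.append("")

    order = rng.permutation(len(reads))
    return SimulatedReads(
        reads=[reads[i] for i in order],
        category=np.array(cats, dtype=object)[order],
        source_gene=np.array(genes, dtype=object)[order],
        library=condition,
        read_length=L,
    )


def generate_annotation(
    genes: list[str],
    n_terms: int = 50,
    mean_term_size: int = 20,
    seed: int = 0,
    term_size: int | None = None,
    enriched_term_genes: list[str] | None = None,
    enriched_fraction: float = 0.8,
) -> pd.DataFrame:
    """Random gene->term annotation map (columns gene_id, term_id, term_name).

    Term sizes are Poisson around ``mean_term_size`` (floored at 1), or fixed
    at ``term_size`` when given.  If ``enriched_term_genes`` is supplied, one
    extra term ``TERM_ENRICHED`` is planted whose members are drawn
    ``enriched_fraction`` from that gene list and the rest at random -- the
    power-test target for downstream enrichment.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    width = len(str(n_terms))
    for t in range(n_terms):
        size = term_size if term_size is not None else max(1, int(rng.poisson(mean_term_size)))
        size = min(size, len(genes))
        members = rng.choice(len(genes), size=size, replace=False)
        tid = f"T{t + 1:0{width}d}"
        rows += [(genes[i], tid, f"term {t + 1}") for i in members]

    if enriched_term_genes:
        pool = [g for g in enriched_term_genes if g in set(genes)]
        size = term_size if term_size is not None else mean_term_size
        k = min(int(round(enriched_fraction * size)), len(pool))
        chosen = list(rng.choice(pool, size=k, replace=False))
        rest = [g for g in genes if g not in set(chosen)]
        fill = rng.choice(len(rest), size=size - k, replace=False)
        chosen += [rest[i] for i in fill]
        rows += [(g, "TERM_ENRICHED", "planted enriched term") for g in chosen]

    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


# ---------------------------------------------------------------------------
# plain-text writers

def write_fasta(transcripts: list[SyntheticTranscript], path) -> None:
    """60-column-wrapped FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(t.sequence), id=t.gene_id, description="") for t in transcripts]
    seqio_write(records, str(path), "fasta")


def write_fastq(sim: SimulatedReads, path) -> None:
    """Sanger-encoded FASTQ with constant quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for i, r in enumerate(sim.reads):
            fh.write(f"@{sim.library or 'read'}_{i + 1}\n{r}\n+\n{'I' * len(r)}\n")


def write_truth_table(truth: TruthTable, path) -> None:
    truth.frame().to_csv(path, sep="\t", index=False)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)
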