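"""Virtual reference tag library: every CATG+17nt tag on both strands.

Tag-based DGE quantifies transcripts by their NlaIII/MmeI tags — 21-nt
sequences beginning with the CATG recognition site followed by the 17
downstream bases.  Before mapping, a virtual library of all possible such
tags is enumerated from both strands of every reference transcript and
indexed for exact and one-mismatch lookup.  A tag whose reference
occurrences all fall in a single gene is *unambiguous*; only unambiguous
tags can identify a transcript.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .simulate import revcomp

__all__ = [
    "TagOccurrence",
    "ReferenceTagLibrary",
    "build_tag_library",
    "lookup",
    "read_fasta",
]

SENSE = "sense"
ANTISENSE = "antisense"
_ACGT = frozenset("ACGT")

# match classes (mutually exclusive; exact matches take priority)
PM_SENSE = "PM-sense"
PM_ANTISENSE = "PM-antisense"
MM1_SENSE = "1MM-sense"
MM1_ANTISENSE = "1MM-antisense"


@dataclass(frozen=True)
class TagOccurrence:
    """One reference site yielding a tag.

    ``offset`` is the 0-based position of the C of CATG in the coordinates of
    the scanned strand (sense coordinates for sense occurrences, reverse-
    complement coordinates for antisense), so ``offset + 21 <= len`` always.
    """

    tag: str
    gene_id: str
    strand: str
    offset: int


@dataclass
class ReferenceTagLibrary:
    """All CATG+17 tags of a transcript set, grouped by tag sequence."""

    occurrences: dict[str, list[TagOccurrence]]
    gene_ids: list[str]
    n_skipped_sites: int = 0
    _genes_by_tag: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._genes_by_tag = {
            t: frozenset(o.gene_id for o in occ) for t, occ in self.occurrences.items()
        }

    def genes_of(self, tag: str) -> frozenset[str]:
        return self._genes_by_tag.get(tag, frozenset())

    @property
    def tags(self) -> set[str]:
        return set(self.occurrences)

    @property
    def unambiguous_tags(self) -> set[str]:
        return {t for t, g in self._genes_by_tag.items() if len(g) == 1}

    @property
    def ambiguous_tags(self) -> set[str]:
        return {t for t, g in self._genes_by_tag.items() if len(g) >= 2}

    @property
    def tag_bearing_genes(self) -> set[str]:
        return {o.gene_id for occ in self.occurrences.values() for o in occ}

    def build_report(self) -> dict:
        return {
            "n_genes": len(self.gene_ids),
            "n_tag_bearing_genes": len(self.tag_bearing_genes),
            "n_reference_tags": len(self.occurrences),
            "n_unambiguous_tags": len(self.unambiguous_tags),
            "n_ambiguous_tags": len(self.ambiguous_tags),
            "n_skipped_sites": self.n_skipped_sites,
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tgene_id\tstrand\toffset\n")
            for tag in sorted(self.occurrences):
                for o in self.occurrences[tag]:
                    fh.write(f"{o.tag}\t{o.gene_id}\t{o.strand}\t{o.offset}\n")

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.build_report(), fh, indent=2)
            fh.write("\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """(gene_id, sequence) pairs from a FASTA file, sequences upper-cased."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _coerce(transcripts) -> list[tuple[str, str]]:
    if isinstance(transcripts, (str,)) or hasattr(transcripts, "__fspath__"):
        return read_fasta(transcripts)
    out = []
    for t in transcripts:
        if isinstance(t, tuple):
            out.append((t[0], t[1].upper()))
        else:  # SyntheticTranscript or any object with gene_id/sequence
            out.append((t.gene_id, t.sequence.upper()))
    return out


def build_tag_library(transcripts) -> ReferenceTagLibrary:
    """Enumerate every CATG+17 site on both strands of every transcript.

    ``transcripts`` may be a FASTA path, (id, sequence) pairs, or
    SyntheticTranscript objects.  Candidate sites whose 21-nt window contains
    a non-ACGT letter are skipped and counted in the build report.
    """
    records = _coerce(transcripts)
    if not records:
        raise ValueError("transcript set is empty")
    ids = [g for g, _ in records]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dup[:5]}")

    occurrences: dict[str, list[TagOccurrence]] = {}
    skipped = 0
    for gene_id, seq in records:
        for strand, s in ((SENSE, seq), (ANTISENSE, revcomp(seq))):
            start = 0
            while True:
                i = s.find("CATG", start)
                if i == -1:
                    break
                start = i + 1
                if i + 21 > len(s):
                    continue
                tag = s[i : i + 21]
                if not _ACGT.issuperset(tag):
                    skipped += 1
                    continue
                occurrences.setdefault(tag, []).append(
                    TagOccurrence(tag, gene_id, strand, i)
                )
    return ReferenceTagLibrary(occurrences, ids, skipped)


def _variants_1mm(tag: str):
    """All 51 single-substitution variants in the 17-nt variable region."""
    for p in range(4, 21):
        for b in "ACGT":
            if b != tag[p]:
                yield tag[:p] + b + tag[p + 1 :]


def lookup(
    tag: str, library: ReferenceTagLibrary, max_mismatch: int = 1
) -> list[tuple[str, str, str]]:
    """Match one 21-nt tag against the library.

    Returns deduplicated (gene_id, strand, match_class) triples.  Exact hits
    take priority: a tag with any perfect match never receives one-mismatch
    hits.  Mismatches are restricted to the 17-nt variable region — the CATG
    anchor is an enzymatic recognition site present by construction in both
    tag and reference, so it is held fixed.
    """
    if len(tag) != 21:
        raise ValueError(f"tag must be 21 nt, got {len(tag)}")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")

    hits: dict[tuple[str, str], str] = {}
    exact = library.occurrences.get(tag)
    if exact:
        for o in exact:
            cls = PM_SENSE if o.strand == SENSE else PM_ANTISENSE
            hits[(o.gene_id, o.strand)] = cls
        return [(g, s, c) for (g, s), c in sorted(hits.items())]

    if max_mismatch == 1 and tag.startswith("CATG"):
        for v in _variants_1mm(tag):
            occ = library.occurrences.get(v)
            if occ:
                for o in occ:
                    cls = MM1_SENSE if o.strand == SENSE else MM1_ANTISENSE
                    hits.setdefault((o.gene_id, o.strand), cls)
    return [(g, s, c) for (g, s), c in sorted(hits.items())]
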