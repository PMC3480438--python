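"""Map clean tags to the reference tag library and quantify genes.

Each distinct clean tag is looked up exactly first, then with one mismatch in
the variable region.  Tags hitting two or more genes (ambiguous) count toward
the all-mapped totals but are excluded from quantification; tags hitting no
gene are "unknown".  Per-gene expression accumulates the *copy numbers* of
that gene's unambiguous tags and is normalised to TPM — transcript copies per
million clean tags (denominator: the library's total clean tags, not mapped
tags).

Antisense unambiguous hits count toward a gene's expression (the mapped-tag
taxonomy includes antisense matches); a per-strand breakdown is kept so a
sense-only analysis can be run as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .library import ReferenceTagLibrary, SENSE, lookup
from .qc import TagCountSet

__all__ = [
    "MappingResult",
    "ExpressionVector",
    "map_library",
    "tpm_normalize",
    "UNKNOWN",
]

UNKNOWN = "unknown"


@dataclass
class MappingResult:
    """Per-tag match classification and per-gene unambiguous counts."""

    tag_class: dict[str, tuple[str, int]]  # tag -> (match_class, n_genes_hit)
    gene_counts: dict[str, int]  # unambiguous copy numbers per gene
    gene_distinct: dict[str, int]  # unambiguous distinct tags per gene
    gene_strand_counts: dict[str, dict[str, int]]  # per gene {sense, antisense}
    tag_mapped_genes: set[str]  # genes hit by >=1 mapped tag (incl. ambiguous)
    clean_total: int
    clean_distinct: int
    all_mapped_total: int = 0
    all_mapped_distinct: int = 0
    unambiguous_total: int = 0
    unambiguous_distinct: int = 0
    unknown_total: int = 0
    unknown_distinct: int = 0
    class_totals: dict[str, int] = field(default_factory=dict)
    class_distinct: dict[str, int] = field(default_factory=dict)
    label: str = ""

    @property
    def unambiguous_tag_mapped_genes(self) -> set[str]:
        return set(self.gene_counts)

    def check_accounting(self) -> None:
        if self.all_mapped_total + self.unknown_total != self.clean_total:
            raise AssertionError("mapped + unknown != clean (totals)")
        if self.all_mapped_distinct + self.unknown_distinct != self.clean_distinct:
            raise AssertionError("mapped + unknown != clean (distinct)")
        if sum(self.gene_counts.values()) != self.unambiguous_total:
            raise AssertionError("per-gene counts do not sum to unambiguous total")
        if self.unambiguous_total > self.all_mapped_total:
            raise AssertionError("unambiguous exceeds all-mapped")

    def report(self) -> dict:
        return {
            "library": self.label,
            "clean_total": self.clean_total,
            "clean_distinct": self.clean_distinct,
            "all_mapped_total": self.all_mapped_total,
            "all_mapped_distinct": self.all_mapped_distinct,
            "unambiguous_total": self.unambiguous_total,
            "unambiguous_distinct": self.unambiguous_distinct,
            "unknown_total": self.unknown_total,
            "unknown_distinct": self.unknown_distinct,
            "tag_mapped_genes": len(self.tag_mapped_genes),
            "unambiguous_tag_mapped_genes": len(self.gene_counts),
            "class_totals": dict(self.class_totals),
            "class_distinct": dict(self.class_distinct),
        }

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2)
            fh.write("\n")


def map_library(tags: TagCountSet, library: ReferenceTagLibrary) -> MappingResult:
    """Look up every distinct clean tag and accumulate gene counts.

    Match classes follow the mapped-tag taxonomy: PM/1MM x sense/antisense,
    with exact matches taking priority, plus "unknown" for tags at Hamming
    distance >= 2 from every reference tag.
    """
    res = MappingResult(
        tag_class={},
        gene_counts={},
        gene_distinct={},
        gene_strand_counts={},
        tag_mapped_genes=set(),
        clean_total=tags.clean_total,
        clean_distinct=tags.clean_distinct,
        label=tags.label,
    )
    for tag, copies in tags.counts.items():
        hits = lookup(tag, library, max_mismatch=1)
        if not hits:
            res.tag_class[tag] = (UNKNOWN, 0)
            res.unknown_total += copies
            res.unknown_distinct += 1
            res.class_totals[UNKNOWN] = res.class_totals.get(UNKNOWN, 0) + copies
            res.class_distinct[UNKNOWN] = res.class_distinct.get(UNKNOWN, 0) + 1
            continue

        genes = {g for g, _, _ in hits}
        # sense attribution wins when a tag hits one gene on both strands
        cls = next(
            (c for _, s, c in hits if s == SENSE), hits[0][2]
        )
        res.tag_class[tag] = (cls, len(genes))
        res.all_mapped_total += copies
        res.all_mapped_distinct += 1
        res.class_totals[cls] = res.class_totals.get(cls, 0) + copies
        res.class_distinct[cls] = res.class_distinct.get(cls, 0) + 1
        res.tag_mapped_genes |= genes

        if len(genes) == 1:
            (g,) = genes
            res.unambiguous_total += copies
            res.unambiguous_distinct += 1
            res.gene_counts[g] = res.gene_counts.get(g, 0) + copies
            res.gene_distinct[g] = res.gene_distinct.get(g, 0) + 1
            strand = SENSE if any(s == SENSE for _, s, _ in hits) else "antisense"
            sc = res.gene_strand_counts.setdefault(g, {"sense": 0, "antisense": 0})
            sc[strand] += copies

    res.check_accounting()
    return res


@dataclass
class ExpressionVector:
    """Per-gene unambiguous tag counts with TPM normalisation.

    TPM_g = count_g * 1e6 / clean_total, where clean_total is the library's
    total clean tags.
    """

    counts: pd.Series  # index: gene_id, values: int counts
    clean_total: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.clean_total <= 0:
            raise ValueError("clean_total must be > 0")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def tpm(self) -> pd.Series:
        return self.counts * 1e6 / self.clean_total

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.counts.index, "count": self.counts.values,
             "TPM": self.tpm.values}
        )

    def write_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)


def tpm_normalize(
    counts,
    clean_total: int,
    gene_universe=None,
    label: str = "",
) -> ExpressionVector:
    """Build an ExpressionVector from per-gene counts.

    ``counts`` may be a MappingResult, a dict, or a Series.  Genes in
    ``gene_universe`` absent from the counts get zero, so two libraries can
    be laid over the same reference gene set.
    """
    if isinstance(counts, MappingResult):
        label = label or counts.label
        counts = counts.gene_counts
    s = pd.Series(counts, dtype="int64")
    if gene_universe is not None:
        s = s.reindex(list(gene_universe), fill_value=0).astype("int64")
    return ExpressionVector(counts=s.sort_index(), clean_total=clean_total, label=label)
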