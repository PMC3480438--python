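"""Per-library sequencing/mapping reports with exact percentage arithmetic.

The report mirrors the standard DGE accounting table: raw and clean tag
totals (total and distinct), all-mapped and unambiguously mapped tags with
their percentages of clean tags, tag-mapped gene counts with their
percentages of reference genes, and unknown tags.  Every percentage is
recomputed from the integer fields — never cached — and rounded half-up to
two decimals, which reproduces printed values exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

from .mapping import MappingResult
from .qc import TagCountSet

__all__ = ["percentage", "LibraryReport", "build_library_report"]


def percentage(numerator: int, denominator: int) -> float:
    """numerator/denominator as a percent, rounded half-up to 2 decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    frac = Decimal(numerator) / Decimal(denominator) * 100
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LibraryReport:
    """One library's row block of the DGE statistics table."""

    label: str
    n_ref_genes: int
    raw_total: int
    raw_distinct: int
    clean_total: int
    clean_distinct: int
    all_mapped_total: int
    all_mapped_distinct: int
    unambiguous_total: int
    unambiguous_distinct: int
    tag_mapped_genes: int
    unambiguous_tag_mapped_genes: int
    unknown_total: int
    unknown_distinct: int

    # percentages are derived, never stored
    @property
    def clean_pct_of_raw(self) -> float:
        return percentage(self.clean_total, self.raw_total)

    @property
    def all_mapped_total_pct(self) -> float:
        return percentage(self.all_mapped_total, self.clean_total)

    @property
    def all_mapped_distinct_pct(self) -> float:
        return percentage(self.all_mapped_distinct, self.clean_distinct)

    @property
    def unambiguous_total_pct(self) -> float:
        return percentage(self.unambiguous_total, self.clean_total)

    @property
    def unambiguous_distinct_pct(self) -> float:
        return percentage(self.unambiguous_distinct, self.clean_distinct)

    @property
    def tag_mapped_genes_pct(self) -> float:
        return percentage(self.tag_mapped_genes, self.n_ref_genes)

    @property
    def unambiguous_tag_mapped_genes_pct(self) -> float:
        return percentage(self.unambiguous_tag_mapped_genes, self.n_ref_genes)

    @property
    def unknown_total_pct(self) -> float:
        return percentage(self.unknown_total, self.clean_total)

    @property
    def unknown_distinct_pct(self) -> float:
        return percentage(self.unknown_distinct, self.clean_distinct)

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in (
            "clean_pct_of_raw",
            "all_mapped_total_pct",
            "all_mapped_distinct_pct",
            "unambiguous_total_pct",
            "unambiguous_distinct_pct",
            "tag_mapped_genes_pct",
            "unambiguous_tag_mapped_genes_pct",
            "unknown_total_pct",
            "unknown_distinct_pct",
        ):
            d[name] = getattr(self, name)
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def build_library_report(
    qc: TagCountSet, mapping: MappingResult, n_ref_genes: int
) -> LibraryReport:
    """Assemble one library's report from its QC and mapping results.

    The two stages must describe the same library: their clean totals (and
    distinct counts) are cross-checked before any ratio is formed.
    """
    if qc.clean_total != mapping.clean_total:
        raise ValueError(
            f"QC clean total {qc.clean_total} != mapping clean total "
            f"{mapping.clean_total}"
        )
    if qc.clean_distinct != mapping.clean_distinct:
        raise ValueError("QC and mapping disagree on distinct clean tags")
    if n_ref_genes <= 0:
        raise ValueError("n_ref_genes must be positive")
    return LibraryReport(
        label=qc.label,
        n_ref_genes=n_ref_genes,
        raw_total=qc.raw_total,
        raw_distinct=qc.raw_distinct,
        clean_total=qc.clean_total,
        clean_distinct=qc.clean_distinct,
        all_mapped_total=mapping.all_mapped_total,
        all_mapped_distinct=mapping.all_mapped_distinct,
        unambiguous_total=mapping.unambiguous_total,
        unambiguous_distinct=mapping.unambiguous_distinct,
        tag_mapped_genes=len(mapping.tag_mapped_genes),
        unambiguous_tag_mapped_genes=len(mapping.gene_counts),
        unknown_total=mapping.unknown_total,
        unknown_distinct=mapping.unknown_distinct,
    )
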