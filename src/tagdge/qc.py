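"""Raw-tag filtering: 49-nt reads -> clean 21-nt tags with copy numbers.

The filter reproduces the five-step DGE cleaning pipeline, in this fixed
order:

1. trim the 3' adapter (a 21-nt tag sequenced as a 49-nt read always runs
   into adapter; trimming takes the leftmost position where the remainder of
   the read matches a prefix of the adapter, minimum overlap configurable);
2. drop reads that are empty after trimming (adapter-only reads);
3. drop reads containing an unknown nucleotide N;
4. drop tags whose copy number over the whole library, counted after steps
   1-3, is exactly one (likely sequencing errors);
5. keep only tags of exactly 21 nt with the CATG prefix.

The accounting ledger is exact: raw total = clean total + the sum of the
four discard categories (weighted by copies).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import ReferenceTagLibrary, lookup

__all__ = [
    "TagCountSet",
    "filter_raw_tags",
    "copy_number_distribution",
    "saturation_curve",
    "read_fastq",
    "DEFAULT_COPY_BINS",
]

# Fig-5-style copy-number bins: [2,5], [6,10], [11,20], [21,50], [51,100], >100
DEFAULT_COPY_BINS = ((2, 5), (6, 10), (11, 20), (21, 50), (51, 100), (101, None))


@dataclass
class TagCountSet:
    """Clean tags with copy numbers plus the QC discard ledger."""

    counts: dict[str, int]
    raw_total: int
    raw_distinct: int
    discards: dict[str, int] = field(
        default_factory=lambda: {
            "adapter_only": 0,
            "n_containing": 0,
            "singleton": 0,
            "bad_length": 0,
        }
    )
    label: str = ""

    @property
    def clean_total(self) -> int:
        return sum(self.counts.values())

    @property
    def clean_distinct(self) -> int:
        return len(self.counts)

    def check_conservation(self) -> None:
        total = self.clean_total + sum(self.discards.values())
        if total != self.raw_total:
            raise AssertionError(
                f"conservation violated: clean {self.clean_total} + discards "
                f"{sum(self.discards.values())} != raw {self.raw_total}"
            )

    def report(self) -> dict:
        return {
            "library": self.label,
            "raw_total": self.raw_total,
            "raw_distinct": self.raw_distinct,
            "clean_total": self.clean_total,
            "clean_distinct": self.clean_distinct,
            "discards": dict(self.discards),
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tcopy_number\n")
            for tag in sorted(self.counts):
                fh.write(f"{tag}\t{self.counts[tag]}\n")

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2)
            fh.write("\n")


def read_fastq(path) -> list[str]:
    """Read sequences from a FASTQ file (plain text, Sanger encoding)."""
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def trim_adapter(read: str, adapter: str, min_overlap: int = 5) -> str:
    """Trim the 3' adapter: cut at the leftmost i where read[i:] matches a
    prefix of the adapter (the adapter may itself be truncated by the read
    end), requiring at least ``min_overlap`` matching bases.  Exact matching,
    no mismatches."""
    L = len(read)
    # full adapter occurrence (fast path, C-level find)
    full = read.find(adapter) if len(adapter) <= L else -1
    limit = full if full != -1 else L - min_overlap + 1
    best = full
    # a shorter suffix-prefix overlap can only start after L - len(adapter)
    lo = max(L - len(adapter) + 1, 0)
    for i in range(lo, limit):
        if read[i:] == adapter[: L - i]:
            best = i
            break
    return read if best == -1 else read[:best]


def filter_raw_tags(
    reads,
    adapter: str,
    min_overlap: int = 5,
    label: str = "",
) -> TagCountSet:
    """Run filtering steps 1-5 over raw reads and return clean tag counts.

    ``reads`` is an iterable of read sequences (or a SimulatedReads object).
    """
    if hasattr(reads, "reads"):
        label = label or getattr(reads, "library", "")
        reads = reads.reads
    reads = list(reads)
    if not reads:
        raise ValueError("no reads supplied")
    if not adapter or "N" in adapter.upper():
        raise ValueError("adapter must be non-empty and N-free")
    adapter = adapter.upper()

    discards = {"adapter_only": 0, "n_containing": 0, "singleton": 0, "bad_length": 0}
    surviving: list[str] = []
    for r in reads:
        t = trim_adapter(r, adapter, min_overlap)  # step 1
        if not t:  # step 2
            discards["adapter_only"] += 1
        elif "N" in t:  # step 3
            discards["n_containing"] += 1
        else:
            surviving.append(t)

    counter = Counter(surviving)
    clean: dict[str, int] = {}
    for tag, k in counter.items():
        if k == 1:  # step 4
            discards["singleton"] += 1
        elif len(tag) != 21 or not tag.startswith("CATG"):  # step 5
            discards["bad_length"] += k
        else:
            clean[tag] = k

    out = TagCountSet(
        counts=clean,
        raw_total=len(reads),
        raw_distinct=len(set(reads)),
        discards=discards,
        label=label,
    )
    out.check_conservation()
    return out


def copy_number_distribution(
    tags: TagCountSet, bins=DEFAULT_COPY_BINS
) -> pd.DataFrame:
    """Tag-abundance histogram over copy-number bins.

    Returns one row per bin with both the distinct-tag share and the
    total-copy share (the two panels of the classic DGE abundance figure).
    """
    if not tags.counts:
        raise ValueError("empty tag set")
    copies = np.array(list(tags.counts.values()))
    rows = []
    for lo, hi in bins:
        mask = (copies >= lo) if hi is None else (copies >= lo) & (copies <= hi)
        name = f">{lo - 1}" if hi is None else f"[{lo},{hi}]"
        rows.append(
            {
                "bin": name,
                "distinct_tags": int(mask.sum()),
                "total_copies": int(copies[mask].sum()),
            }
        )
    df = pd.DataFrame(rows)
    df["distinct_share"] = df["distinct_tags"] / tags.clean_distinct
    df["total_share"] = df["total_copies"] / tags.clean_total
    return df


def saturation_curve(
    tags: TagCountSet,
    library: ReferenceTagLibrary,
    n_points: int = 20,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Detected genes as a function of subsampled sequencing depth.

    Clean tags are subsampled without replacement on an even depth grid up to
    the clean total; a gene counts as detected once at least one tag mapping
    unambiguously to it (exact or one mismatch) is drawn.  One random
    permutation drives all depths, so the curve is monotone non-decreasing
    and deterministic under ``seed``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    total = tags.clean_total
    depths = np.linspace(0, total, n_points).round().astype(int)

    # gene for each distinct tag that maps unambiguously, else None
    tag_list = list(tags.counts)
    gene_of: list[str | None] = []
    for t in tag_list:
        hits = lookup(t, library, max_mismatch=1)
        genes = {g for g, _, _ in hits}
        gene_of.append(next(iter(genes)) if len(genes) == 1 else None)

    expanded = np.repeat(
        np.arange(len(tag_list)), [tags.counts[t] for t in tag_list]
    )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(expanded)

    curve = []
    seen: set[str] = set()
    pos = 0
    for d in depths:
        for i in perm[pos:d]:
            g = gene_of[i]
            if g is not None:
                seen.add(g)
        pos = d
        curve.append((int(d), len(seen)))
    return curve
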