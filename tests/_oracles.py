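"""Independent brute-force oracles used by several test modules.

These deliberately avoid the library's own index structures: enumeration
slides a window over raw strings, lookup scans every reference tag computing
an anchored Hamming distance (CATG anchor must match exactly, substitutions
counted over the 17-nt variable region, exact hits shadowing 1-mismatch
hits).
"""

from tagdge.simulate import revcomp


def brute_force_occurrences(records):
    """Slide a 21-nt window over both strands, test prefix CATG."""
    occ = []
    for gene_id, seq in records:
        for strand, s in (("sense", seq), ("antisense", revcomp(seq))):
            for i in range(len(s) - 20):
                if s[i : i + 4] == "CATG" and set(s[i : i + 21]) <= set("ACGT"):
                    occ.append((s[i : i + 21], gene_id, strand, i))
    return occ


def brute_force_lookup(tag, library, max_mismatch=1):
    """Exhaustive anchored-Hamming scan over every reference tag."""
    exact, near = set(), set()
    for ref, occs in library.occurrences.items():
        if tag[:4] != ref[:4]:
            continue
        d = sum(a != b for a, b in zip(tag[4:], ref[4:]))
        for o in occs:
            if d == 0:
                exact.add((o.gene_id, o.strand, "PM"))
            elif d == 1 and max_mismatch >= 1:
                near.add((o.gene_id, o.strand, "1MM"))
    if exact:
        return {(g, s, f"{c}-{s}") for g, s, c in exact}
    return {(g, s, f"{c}-{s}") for g, s, c in near}
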