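"""Build the virtual reference tag library from a transcript FASTA.

Enumerates every CATG+17nt tag on both strands of every transcript and
classifies tags as unambiguous (all occurrences in one gene) or ambiguous.
Run 01_simulate_libraries.py first to create the reference.
"""

from pathlib import Path

import tagdge as t

ref = Path("scratch_example/reference.fasta")
if not ref.exists():
    raise SystemExit("run 01_simulate_libraries.py first")

lib = t.build_tag_library(ref)
rep = lib.build_report()
print(f"{rep['n_genes']} reference genes, {rep['n_tag_bearing_genes']} carry >=1 tag site")
print(f"{rep['n_reference_tags']} distinct reference tags, "
      f"{rep['n_unambiguous_tags']} unambiguous / {rep['n_ambiguous_tags']} ambiguous")

lib.write_tsv("scratch_example/tag_library.tsv")
lib.write_report("scratch_example/tag_library.json")

# look one tag up with and without a sequencing error
tag = next(iter(sorted(lib.unambiguous_tags)))
print("exact lookup:", t.lookup(tag, lib))
mutated = tag[:10] + ("A" if tag[10] != "A" else "C") + tag[11:]
print("1-mismatch lookup:", t.lookup(mutated, lib))
print("Only tags whose occurrences all fall in a single gene can identify a transcript.")
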