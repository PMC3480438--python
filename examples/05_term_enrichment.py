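"""Hypergeometric term enrichment of a DE gene set.

Builds a random annotation with one term deliberately enriched in the DE set
(80% of its members), then tests every term against the annotated background.
"""

import numpy as np

import tagdge as t

rng = np.random.default_rng(3)
genes = [f"g{i:03d}" for i in range(400)]
de_genes = list(rng.choice(genes, size=40, replace=False))

ann = t.generate_annotation(
    genes, n_terms=25, term_size=20, seed=3,
    enriched_term_genes=de_genes, enriched_fraction=0.8,
)

out = t.enrich(de_genes, ann, mode="go")
print("top terms (N annotated genes, n DE among them, M term members, m DE members):")
print(out.head(5).round(6).to_string(index=False))

planted = out.set_index("term_id").loc["TERM_ENRICHED"]
print(f"\nplanted term: m={planted['m']}/{planted['M']} members DE, "
      f"p={planted['p_value']:.3g}, q={planted['q_value']:.3g}, "
      f"significant={bool(planted['significant'])}")
print("A small upper-tail p means more DE genes carry the term than a random")
print("draw of n genes from the N annotated ones would explain.")

pw = t.enrich(de_genes, ann, mode="pathway")
print(f"\npathway-style convention (q<0.05): "
      f"{int(pw['significant'].sum())} significant term(s)")
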