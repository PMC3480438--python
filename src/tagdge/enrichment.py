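"""Hypergeometric term enrichment of a DE gene set against an annotation map.

For each term the test asks whether DE genes are over-represented among the
term's members relative to the annotated background:

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)

where N is the number of annotated genes (the background), n the number of
DE genes within N, M the number of genes carrying the term, and m the number
of DE genes carrying the term.  P is the upper tail P(X >= m) of a
hypergeometric(N, M, n) variable, computed with log-gamma binomials and
compensated summation.

Term hierarchies are not traversed: the annotation is taken as given, and a
gene with several terms counts once per term.  q-values are Benjamini-
Hochberg across the term family; the significance flag follows the domain
convention (GO-style: raw p < 0.05; pathway-style: q < 0.05).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .de import bh_fdr

__all__ = ["hypergeom_enrichment_p", "enrich"]


def _log_binom(n: float, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_enrichment_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    Validates m <= min(n, M), n <= N, M <= N.  Out-of-support terms of the
    complementary sum (i with n - i > N - M) contribute zero.
    """
    if not (0 <= m <= min(n, M)):
        raise ValueError(f"need 0 <= m <= min(n, M); got N={N} n={n} M={M} m={m}")
    if not (0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"need n <= N and M <= N; got N={N} n={n} M={M} m={m}")
    if m == 0:
        return 1.0
    i = np.arange(m)
    valid = (n - i) <= (N - M)
    i = i[valid]
    if i.size == 0:
        return 1.0
    log_terms = _log_binom(M, i) + _log_binom(N - M, n - i) - _log_binom(N, n)
    p = 1.0 - math.fsum(np.exp(log_terms))
    if p < 1e-2:
        # small complements are cancellation-limited (log-gamma carries
        # ~1e-13 absolute error); sum the upper tail i = m..min(n, M)
        # directly instead, which is accurate relative to itself
        j = np.arange(m, min(n, M) + 1)
        j = j[(n - j) <= (N - M)]
        if j.size == 0:
            return 0.0
        upper = _log_binom(M, j) + _log_binom(N - M, n - j) - _log_binom(N, n)
        p = math.fsum(np.exp(upper))
    return max(min(p, 1.0), 0.0)


def enrich(
    deg_genes,
    annotation: pd.DataFrame,
    mode: str = "go",
    p_threshold: float = 0.05,
    q_threshold: float = 0.05,
    background=None,
) -> pd.DataFrame:
    """Enrichment table over every annotated term with at least one member.

    ``annotation`` needs columns gene_id and term_id (term_name optional).
    The background N defaults to the genes carrying >=1 annotation in this
    map; pass ``background`` to override.  ``mode`` picks the significance
    convention: "go" flags raw p < ``p_threshold``, "pathway" flags
    BH q < ``q_threshold``.

    Returns one row per term: term_id, term_name, N, n, M, m, p_value,
    q_value, significant — sorted by p-value.
    """
    if annotation.empty:
        raise ValueError("annotation map is empty")
    if mode not in ("go", "pathway"):
        raise ValueError(f"mode must be 'go' or 'pathway', got {mode!r}")

    ann = annotation.drop_duplicates(subset=["gene_id", "term_id"])
    universe = set(background) if background is not None else set(ann["gene_id"])
    deg = set(deg_genes) & universe
    if not deg:
        warnings.warn("no DE gene overlaps the annotated universe", stacklevel=2)

    N, n = len(universe), len(deg)
    rows = []
    names = (
        ann.drop_duplicates("term_id").set_index("term_id")["term_name"]
        if "term_name" in ann.columns
        else pd.Series(dtype=object)
    )
    for term_id, grp in ann.groupby("term_id", sort=True):
        members = set(grp["gene_id"]) & universe
        M = len(members)
        if M == 0:
            continue
        m = len(members & deg)
        rows.append(
            {
                "term_id": term_id,
                "term_name": names.get(term_id, ""),
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "p_value": hypergeom_enrichment_p(N, n, M, m),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"])
    if mode == "go":
        out["significant"] = out["p_value"] < p_threshold
    else:
        out["significant"] = out["q_value"] < q_threshold
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
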