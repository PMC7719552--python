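"""Gene-set statistics: enrichment, overlaps, chi-squared tests, orthologs.

The downstream comparisons of a parent-of-origin screen: hypergeometric
term enrichment against an explicit background, hypergeometric overlap of
two gene lists within a universe, chi-squared tests on label counts
(goodness of fit against an equal split; 2x2 independence with Yates
continuity correction), and reciprocal-best-hit ortholog mapping from
tabular similarity-search output.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

from .poe import bh_adjust


def hypergeom_enrichment(
    study: Set[str],
    background: Set[str],
    annot: Mapping[str, Set[str]],
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of annotation terms.

    For each term: k = study genes annotated, K = background genes
    annotated, n = |study|, N = |background|; p = P(X >= k) for
    X ~ Hypergeom(N, K, n), BH-adjusted across terms.  ``study`` must be a
    subset of ``background``; annotations outside the background are
    ignored.
    """
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    if not study:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q", "significant"])
    N = len(background)
    n = len(study)
    term_background: Dict[str, int] = {}
    term_study: Dict[str, int] = {}
    for gene, terms in annot.items():
        if gene not in background:
            continue
        for t in terms:
            term_background[t] = term_background.get(t, 0) + 1
            if gene in study:
                term_study[t] = term_study.get(t, 0) + 1
    rows = []
    for term, K in sorted(term_background.items()):
        k = term_study.get(term, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_thresh
    return out


def overlap_test(
    list_a: Set[str], list_b: Set[str], universe: Set[str]
) -> Tuple[int, float]:
    """Hypergeometric test of the overlap between two gene lists.

    Returns ``(|A ∩ B|, p)`` where p is the upper-tail probability of an
    intersection at least this large when ``list_b`` is drawn at random
    from the universe.
    """
    if not (list_a <= universe and list_b <= universe):
        raise ValueError("both lists must be subsets of the universe")
    k = len(list_a & list_b)
    p = float(hypergeom.sf(k - 1, len(universe), len(list_a), len(list_b)))
    return k, min(p, 1.0)


def chisq_gof_equal(counts: Sequence[int]) -> Tuple[float, int, float]:
    """Pearson goodness-of-fit of two category counts against a 50:50 split.

    Returns ``(statistic, df=1, p)``.
    """
    if len(counts) != 2:
        raise ValueError("exactly two category counts expected")
    a, b = counts
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    total = a + b
    if total == 0:
        raise ValueError("total count must be positive")
    expected = total / 2.0
    stat = (a - expected) ** 2 / expected + (b - expected) ** 2 / expected
    return float(stat), 1, chisq_pvalue(stat, 1)


def chisq_independence_2x2(
    table: Sequence[Sequence[int]],
) -> Tuple[float, int, float]:
    """Pearson 2x2 independence test with Yates continuity correction.

    |ad - bc| is reduced by N/2 and floored at zero before squaring, the
    convention under which nearly-proportional tables give a statistic of
    exactly 0 and p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("a non-negative 2x2 table is required")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    (a, b), (c, d) = t
    n = t.sum()
    num = max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2 * n
    den = (a + b) * (c + d) * (a + c) * (b + d)
    stat = float(num / den)
    return stat, 1, chisq_pvalue(stat, 1)


def chisq_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-squared probability."""
    if statistic < 0:
        raise ValueError("statistic must be non-negative")
    if df <= 0:
        raise ValueError("df must be a positive integer")
    return float(chi2.sf(statistic, df))


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    max_evalue: float = 1e-3,
) -> pd.DataFrame:
    """Reciprocal-best-hit orthologs from two tabular hit lists.

    Each table needs columns ``query, subject, evalue, score`` (tabular
    similarity-search output).  Per query, the best hit is the lowest
    e-value (ties: highest score, then lexicographic subject id) subject to
    ``evalue <= max_evalue``; a pair is an ortholog when the best hits in
    the two directions designate each other.  Output is one-to-one with
    columns ``gene_a, gene_b``.
    """
    def best(hits: pd.DataFrame) -> Dict[str, str]:
        required = {"query", "subject", "evalue", "score"}
        if not required <= set(hits.columns):
            raise ValueError(f"hit table must have columns {sorted(required)}")
        if hits[["evalue", "score"]].isna().any().any():
            bad = int(hits[["evalue", "score"]].isna().any(axis=1).idxmax())
            raise ValueError(f"malformed hit row at index {bad}")
        h = hits[hits["evalue"] <= max_evalue]
        h = h.sort_values(
            ["query", "evalue", "score", "subject"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        return h.drop_duplicates("query").set_index("query")["subject"].to_dict()

    best_ab = best(hits_ab)
    best_ba = best(hits_ba)
    pairs = sorted(
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    )
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
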