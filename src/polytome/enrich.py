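"""Functional-category enrichment and isoleucine codon-content tests.

Category enrichment of a gene subset against its background uses the
one-sided hypergeometric upper tail (equivalently a one-sided Fisher exact
test): with N background genes of which K carry the category, the chance of
seeing at least k carriers in a subset of size n is P(X >= k). Raw p-values
are compared to 0.05 by default; Benjamini-Hochberg adjustment is optional.

The codon-content check asks whether a gene group's coding sequences are
enriched in isoleucine codons (ATT, ATC, ATA) relative to the remaining
genes: per-gene Ile codon frequencies are compared with a two-sided
Mann-Whitney rank-sum test (an exact permutation variant is available for
small groups).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ILE_CODONS",
    "category_enrichment",
    "ile_codon_frequency",
    "compare_codon_content",
]

ILE_CODONS = ("ATT", "ATC", "ATA")


def category_enrichment(
    subset: Iterable[str],
    background: Iterable[str],
    categories: Mapping[str, str],
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every category in ``subset``.

    ``categories`` maps gene_id -> category label; genes without a label are
    pooled as ``"unknown"``. Returns one row per category sorted by p-value:
    category, subset_hits (k), subset_size (n), background_hits (K),
    background_size (N), p_value, significant.
    """
    subset = set(subset)
    background = set(background)
    if not subset <= background:
        raise ValueError("subset must be contained in background")
    cat_of = {g: categories.get(g, "unknown") for g in background}
    N = len(background)
    n = len(subset)
    rows = []
    for cat in sorted(set(cat_of.values())):
        members = {g for g, c in cat_of.items() if c == cat}
        K = len(members)
        k = len(subset & members)
        # upper tail: P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "category": cat,
                "subset_hits": k,
                "subset_size": n,
                "background_hits": K,
                "background_size": N,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).sort_values("p_value", ignore_index=True)
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(
            out["p_value"], alpha=alpha, method="fdr_bh"
        )
        out["p_adjusted"] = p_adj
        out["significant"] = reject
    else:
        out["significant"] = out["p_value"] < alpha
    return out


def ile_codon_frequency(cds_sequence: str) -> float:
    """Fraction of a CDS's codons encoding isoleucine (ATT/ATC/ATA)."""
    seq = cds_sequence.upper()
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise ValueError("sequence length must be a non-zero multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return sum(c in ILE_CODONS for c in codons) / len(codons)


def compare_codon_content(
    group: Iterable[str],
    rest: Iterable[str],
    sequences: Mapping[str, str],
    permutation: bool = False,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of Ile codon frequencies.

    Returns (statistic, p). ``permutation=True`` swaps the asymptotic
    Mann-Whitney p for an exact/randomized permutation p (recommended for
    very small groups).
    """
    group = [g for g in group if g in sequences]
    rest = [g for g in rest if g in sequences]
    if not group or not rest:
        raise ValueError("both gene sets must be non-empty with sequences")
    fg = np.array([ile_codon_frequency(sequences[g]) for g in group])
    fr = np.array([ile_codon_frequency(sequences[g]) for g in rest])
    if permutation:
        res = stats.permutation_test(
            (fg, fr),
            lambda a, b: np.mean(a) - np.mean(b),
            alternative="two-sided",
            n_resamples=9999,
            rng=np.random.default_rng(seed),
        )
        return float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(fg, fr, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
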