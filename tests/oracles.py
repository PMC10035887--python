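"""Independent reference computations used to validate the implementation.

Everything here deliberately avoids the package's own code paths:
transition matrices come from scipy's matrix exponential, likelihoods
from explicit state enumeration, and rank statistics from direct formula
evaluation.
"""

import numpy as np
from scipy.linalg import expm
from scipy.special import comb
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from ligevo.substitution import AA_INDEX


def four_leaf_enumeration_loglik(residues, lengths, model, rate):
    """Brute-force likelihood of ((A:t1,B:t2):t5,(C:t3,D:t4):t6).

    ``residues`` = (a, b, c, d) one-letter residues, ``lengths`` =
    (t1, t2, t3, t4, t5, t6).  Sums over all 20^3 internal-state
    assignments using scipy expm transition matrices.
    """
    a, b, c, d = (AA_INDEX[r] for r in residues)
    t1, t2, t3, t4, t5, t6 = lengths
    p = {t: expm(model.Q * rate * t) for t in {t1, t2, t3, t4, t5, t6}}
    total = 0.0
    for root in range(20):
        for x in range(20):
            for y in range(20):
                total += (
                    model.pi[root]
                    * p[t5][root, x]
                    * p[t1][x, a]
                    * p[t2][x, b]
                    * p[t6][root, y]
                    * p[t3][y, c]
                    * p[t4][y, d]
                )
    return float(np.log(total))


def fisher_enumeration(table):
    """Two-sided Fisher p by direct enumeration of all tables with the margins."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (
            comb(r1, k, exact=True)
            * comb(n - r1, c1 - k, exact=True)
            / comb(n, c1, exact=True)
        )

    p_obs = pmf(a)
    total = 0.0
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def hypergeom_tail(k_study, n_bg, k_bg, n_study):
    """Upper-tail hypergeometric probability by direct summation."""
    total = 0.0
    for k in range(k_study, min(k_bg, n_study) + 1):
        total += (
            comb(k_bg, k, exact=True)
            * comb(n_bg - k_bg, n_study - k, exact=True)
            / comb(n_bg, n_study, exact=True)
        )
    return total


def conover_iman_reference(groups):
    """Conover-Iman all-pairs p-values computed from the published formula.

    Returns a dict (i, j) -> (raw_p, bonferroni_p) over group index
    pairs, using tie-corrected Kruskal-Wallis H evaluated from first
    principles (no scipy.stats.kruskal).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    sizes = [a.size for a in arrays]
    n = sum(sizes)
    k = len(arrays)
    pooled = np.concatenate(arrays)
    ranks = rankdata(pooled)
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    rank_sums = [r.sum() for r in split]

    h = (12.0 / (n * (n + 1))) * sum(
        rs**2 / ni for rs, ni in zip(rank_sums, sizes)
    ) - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    h /= correction

    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    df = n - k
    n_pairs = k * (k - 1) // 2
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = rank_sums[i] / sizes[i] - rank_sums[j] / sizes[j]
            denom = np.sqrt(
                s2 * ((n - 1 - h) / df) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            tstat = diff / denom
            raw = 2.0 * t_dist.sf(abs(tstat), df)
            out[(i, j)] = (raw, min(1.0, raw * n_pairs))
    return out
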