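"""Comparative statistics for site classes.

Builds conservation summaries (counts and percent fully conserved per
site class, with multi-ligand sites counted once per ligand class) and
runs the group-comparison battery: Fisher's exact test on
conserved/variable proportions, Mann-Whitney U on pooled rates or
entropies, Kruskal-Wallis across ligand types, and the Conover-Iman
all-against-all post-hoc with Bonferroni correction and mean-rank
directionality.

Fisher's two-sided p-value uses the point-probability convention (sum
over all tables with fixed margins whose hypergeometric probability does
not exceed the observed one) and is computed in log-space via the
log-gamma function, so tables with counts in the millions are handled
without overflow.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .annotation import (
    CLASS_BINDING,
    CLASS_OTHER_DOMAIN,
    CLASS_OTHER_OUTSIDE,
    LIGAND_TYPES,
)

SUMMARY_CLASSES = ("other", "other_within_domain", "ligand_binding") + LIGAND_TYPES


# ------------------------------------------------------ conservation table


def conservation_table(site_table: pd.DataFrame) -> pd.DataFrame:
    """Counts of sites and fully conserved sites per class.

    ``site_table`` has one row per scored MSA column with columns
    ``class``, ``ligand_types`` (comma-joined) and ``variable`` (bool).
    The ``other`` class pools non-binding sites inside and outside
    domains; a site binding several ligand types increments each of its
    ligand classes once and ``ligand_binding`` once.
    """
    t = site_table.dropna(subset=["variable"])
    masks = {
        "other": t["class"].isin([CLASS_OTHER_DOMAIN, CLASS_OTHER_OUTSIDE]),
        "other_within_domain": t["class"] == CLASS_OTHER_DOMAIN,
        "ligand_binding": t["class"] == CLASS_BINDING,
    }
    ligand_sets = t["ligand_types"].fillna("").str.split(",")
    for ligand in LIGAND_TYPES:
        masks[ligand] = ligand_sets.apply(lambda s, L=ligand: L in s)
    rows = []
    for name in SUMMARY_CLASSES:
        sub = t[masks[name]]
        n = len(sub)
        conserved = int((~sub["variable"].astype(bool)).sum())
        rows.append(
            {
                "class": name,
                "n_sites": n,
                "n_conserved": conserved,
                "percent_conserved": 100.0 * conserved / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("class")


# ------------------------------------------------------------------ tests


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table (log-space).

    Point-probability method: sums the hypergeometric probabilities of
    all tables with the observed margins that are no more probable than
    the observed table (with the usual 1 + 1e-7 relative slack for
    floating-point ties).  A zero margin means no association is
    testable: p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(np.int64)
        if np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        warnings.warn("zero margin in 2x2 table; p set to 1", stacklevel=2)
        return 1.0
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - (c1 - k) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    log_obs = logpmf[k == a][0]
    mask = logpmf <= log_obs + np.log1p(1e-7)
    # log-sum-exp over the selected tables
    m = logpmf[mask].max()
    p = float(np.exp(m) * np.exp(logpmf[mask] - m).sum())
    return min(p, 1.0)


def mann_whitney_u(sample_x, sample_y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both samples have at most 20 observations,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if max(x.size, y.size) <= 20 else "asymptotic"
    if method == "exact" and (np.unique(np.concatenate([x, y])).size < x.size + y.size):
        # ties invalidate the exact null distribution
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def conover_posthoc(
    groups: dict[str, np.ndarray] | list, p_adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Conover-Iman all-pairs comparison after Kruskal-Wallis.

    Pooled-rank t statistics with tie correction; two-sided p from the
    t distribution with N - k degrees of freedom; Bonferroni adjustment
    over the k(k-1)/2 pairs.  ``direction`` marks which group of the
    pair has the larger mean rank (i.e. evolves faster when applied to
    rates): ``"a_faster"`` or ``"b_faster"``.  Pairs involving a group
    with fewer than two observations are returned with NaN p-values.
    """
    if p_adjust not in ("bonferroni", "none"):
        raise ValueError("p_adjust must be 'bonferroni' or 'none'")
    if not isinstance(groups, dict):
        groups = {str(i): g for i, g in enumerate(groups)}
    names = list(groups)
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    sizes = np.array([a.size for a in arrays])
    k = len(names)
    n_total = int(sizes.sum())
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum(sizes)[:-1]
    group_ranks = np.split(ranks, bounds)
    mean_ranks = np.array([r.mean() if r.size else np.nan for r in group_ranks])

    degenerate = np.unique(pooled).size == 1
    h, _ = kruskal_wallis(arrays) if not degenerate else (0.0, 1.0)
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    df = n_total - k
    n_pairs = k * (k - 1) // 2
    rows = []
    for ia, ib in combinations(range(k), 2):
        testable = sizes[ia] >= 2 and sizes[ib] >= 2 and df > 0
        if not testable:
            raw = np.nan
        elif degenerate or s2 <= 0:
            raw = 1.0
        else:
            denom = np.sqrt(
                s2 * ((n_total - 1 - h) / df) * (1.0 / sizes[ia] + 1.0 / sizes[ib])
            )
            tstat = (mean_ranks[ia] - mean_ranks[ib]) / denom if denom > 0 else 0.0
            raw = float(2.0 * sps.t.sf(abs(tstat), df))
        adj = raw if p_adjust == "none" else min(1.0, raw * n_pairs)
        rows.append(
            {
                "ligand_a": names[ia],
                "ligand_b": names[ib],
                "raw_p": raw,
                "adj_p": adj,
                "neglog10_adj_p": -np.log10(adj) if adj == adj and adj > 0 else np.nan,
                "direction": "a_faster"
                if mean_ranks[ia] >= mean_ranks[ib]
                else "b_faster",
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------- pooled helpers


def conserved_variable_2x2(summary: pd.DataFrame, class_a: str, class_b: str):
    """Build the conserved/variable 2x2 table for two summary classes."""
    rows = []
    for cls in (class_a, class_b):
        n = int(summary.loc[cls, "n_sites"])
        cons = int(summary.loc[cls, "n_conserved"])
        rows.append([cons, n - cons])
    return np.array(rows, dtype=np.int64)


def ligand_rate_groups(
    site_table: pd.DataFrame, value: str = "normalized_rate"
) -> dict[str, np.ndarray]:
    """Pooled per-ligand value vectors; multi-ligand sites join each group."""
    t = site_table[site_table["class"] == CLASS_BINDING]
    groups: dict[str, np.ndarray] = {}
    ligand_sets = t["ligand_types"].fillna("").str.split(",")
    for ligand in LIGAND_TYPES:
        mask = ligand_sets.apply(lambda s, L=ligand: L in s)
        vals = t.loc[mask, value].dropna().to_numpy()
        if vals.size:
            groups[ligand] = vals
    return groups
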