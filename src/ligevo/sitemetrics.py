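"""Per-column conservation metrics: entropy and ML evolutionary rates.

Two complementary measures are computed for every alignment column:

* **Shannon entropy** ``H = -sum_a q_a ln q_a`` over the amino-acid
  frequencies ``q_a`` among non-gap residues (natural-log units, no
  sliding window, gaps excluded).  ``H = 0`` iff the column is invariant.

* **ML evolutionary rate** ``r``: the per-site rate multiplier that
  maximises the pruning-algorithm (Felsenstein) likelihood of the column
  on the fixed species tree, with branch lengths scaled by ``r`` and
  transition probabilities ``P(r t) = expm(Q r t)`` under an empirical
  amino-acid model (JTT by default).  This is the Rate4Site-style
  maximum-likelihood point estimate: the tree is fixed, only ``r`` is
  free, and higher ``r`` means faster evolution at that site.

Gaps are treated as missing data: a gapped leaf contributes an all-ones
partial likelihood, which is mathematically identical to pruning that
leaf out of the tree (transition-matrix rows sum to one).  Rates are
searched on ``[1e-6, 20]`` with a 17-point log-spaced grid followed by
bounded scalar refinement; invariant columns sit at the lower bound.

Raw ML rates are not comparable across orthogroups (each orthogroup has
its own information content), so :func:`normalize_rates` rescales each
orthogroup's rate vector to mean one before pooling.
"""

from __future__ import annotations

import logging
import math
from collections import Counter

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .ortho import GAP_CHARS, Orthogroup
from .phylo import PrimatePhylogeny, TreeArrays
from .substitution import AA_INDEX, AMINO_ACIDS, N_STATES, SubstitutionModel, jtt

logger = logging.getLogger(__name__)

RATE_LOWER = 1e-6
RATE_UPPER = 20.0
GRID_POINTS = 17
REFINE_XATOL = 1e-6


# ---------------------------------------------------------------- entropy


def column_entropy(residues) -> float:
    """Shannon entropy (nats) of a column's non-gap amino-acid frequencies.

    ``residues`` is an iterable of single characters (a dict of
    species -> residue also works; its values are used).  All-gap columns
    have no defined frequency distribution and return ``nan``.
    """
    if isinstance(residues, dict):
        residues = residues.values()
    counts = Counter(r for r in residues if r not in GAP_CHARS)
    n = sum(counts.values())
    if n == 0:
        return float("nan")
    h = 0.0
    for c in counts.values():
        q = c / n
        h -= q * math.log(q)
    return h


def classify_variability(residues) -> str | None:
    """``"conserved"`` iff exactly one distinct non-gap residue; all-gap -> None."""
    if isinstance(residues, dict):
        residues = residues.values()
    distinct = {r for r in residues if r not in GAP_CHARS}
    if not distinct:
        return None
    return "conserved" if len(distinct) == 1 else "variable"


# ------------------------------------------------------------- likelihood


def encode_columns(orthogroup: Orthogroup, arrays: TreeArrays) -> np.ndarray:
    """Integer-encode the MSA as (n_columns, n_leaves); gaps/missing = -1.

    Leaf order follows ``arrays.leaf_names``; species absent from the
    orthogroup are encoded as missing for every column.
    """
    ncol = orthogroup.n_columns
    codes = np.full((ncol, arrays.n_leaves), -1, dtype=np.int8)
    for li, name in enumerate(arrays.leaf_names):
        seq = orthogroup.sequences.get(name)
        if seq is None:
            continue
        codes[:, li] = [AA_INDEX.get(c, -1) for c in seq]
    return codes


def _batch_log_likelihood(
    codes: np.ndarray, arrays: TreeArrays, model: SubstitutionModel, rate: float
) -> np.ndarray:
    """Pruning log-likelihood of every encoded column at rate ``rate``."""
    ncol = codes.shape[0]
    pmats = model.transition_matrices(rate * arrays.blen)  # (n_nodes, 20, 20)
    eye = np.eye(N_STATES)
    partials: list[np.ndarray | None] = [None] * len(arrays.blen)
    logscale = np.zeros(ncol)
    for li in range(arrays.n_leaves):
        col = codes[:, li]
        leafp = np.ones((ncol, N_STATES))
        obs = col >= 0
        leafp[obs] = eye[col[obs]]
        partials[li] = leafp
    for node in arrays.postorder:
        acc = np.ones((ncol, N_STATES))
        for child in arrays.children[node]:
            acc *= partials[child] @ pmats[child].T
            partials[child] = None  # release
        scale = acc.max(axis=1)
        scale[scale == 0.0] = 1.0
        logscale += np.log(scale)
        partials[node] = acc / scale[:, None]
    root = partials[arrays.root]
    return np.log(root @ model.pi) + logscale


def site_log_likelihood(
    column: dict[str, str],
    tree: PrimatePhylogeny,
    model: SubstitutionModel,
    rate: float,
) -> float:
    """Log-likelihood of one column (species -> residue) at rate ``rate``.

    Gaps are missing data; species not named in ``column`` are likewise
    missing.  ``rate`` must be positive.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    arrays = tree.to_arrays()
    unknown = set(column) - set(arrays.leaf_names)
    if unknown:
        raise ValueError(f"column references taxa not in tree: {sorted(unknown)}")
    codes = np.full((1, arrays.n_leaves), -1, dtype=np.int8)
    n_obs = 0
    for li, name in enumerate(arrays.leaf_names):
        res = column.get(name)
        if res is not None and res not in GAP_CHARS:
            codes[0, li] = AA_INDEX[res]
            n_obs += 1
    if n_obs == 0:
        raise ValueError("column has no non-gap residues")
    return float(_batch_log_likelihood(codes, arrays, model, rate)[0])


# ---------------------------------------------------------- rate estimation


def _grid_local_maxima(ll: np.ndarray) -> list[int]:
    """Indices of grid points that are local maxima (boundaries included).

    The site likelihood in ``r`` can be multimodal; refining around every
    local grid maximum and keeping the best guards against locking onto
    the wrong mode.
    """
    idx = []
    n = ll.size
    for i in range(n):
        left_ok = i == 0 or ll[i] >= ll[i - 1]
        right_ok = i == n - 1 or ll[i] >= ll[i + 1]
        if left_ok and right_ok:
            idx.append(i)
    return idx


def _refine(codes_row, arrays, model, lo, hi, best_r, best_ll):
    def negll(r):
        return -_batch_log_likelihood(codes_row, arrays, model, r)[0]

    res = minimize_scalar(
        negll, bounds=(lo, hi), method="bounded", options={"xatol": REFINE_XATOL}
    )
    if not res.success:  # pragma: no cover - scipy bounded rarely fails
        logger.warning("rate refinement did not converge; keeping grid optimum")
        return best_r, best_ll
    if -res.fun >= best_ll:
        return float(res.x), float(-res.fun)
    return best_r, best_ll


def estimate_site_rates(
    orthogroup: Orthogroup,
    tree: PrimatePhylogeny,
    model: SubstitutionModel | None = None,
) -> np.ndarray:
    """ML rate for every column of an orthogroup (vectorised grid + refine).

    Invariant and all-gap columns are pinned to the lower rate bound; the
    grid stage is evaluated for all columns simultaneously, the bounded
    refinement per column within its bracketing grid interval.
    """
    model = model or jtt()
    arrays = tree.to_arrays()
    codes = encode_columns(orthogroup, arrays)
    ncol = codes.shape[0]
    rates = np.full(ncol, RATE_LOWER)

    n_distinct = np.array(
        [len({c for c in col if c >= 0}) for col in codes], dtype=int
    )
    active = np.flatnonzero(n_distinct >= 2)
    if active.size == 0:
        return rates

    grid = np.geomspace(RATE_LOWER, RATE_UPPER, GRID_POINTS)
    sub = codes[active]
    ll = np.empty((GRID_POINTS, active.size))
    for gi, r in enumerate(grid):
        ll[gi] = _batch_log_likelihood(sub, arrays, model, r)
    for k, col_idx in enumerate(active):
        rates[col_idx] = _refine_over_modes(
            codes[col_idx : col_idx + 1], arrays, model, grid, ll[:, k]
        )
    return rates


def _refine_over_modes(codes_row, arrays, model, grid, ll_grid) -> float:
    best_r, best_ll = None, -np.inf
    for gi in _grid_local_maxima(ll_grid):
        lo = grid[max(gi - 1, 0)]
        hi = grid[min(gi + 1, grid.size - 1)]
        r_hat, ll_hat = _refine(
            codes_row, arrays, model, lo, hi, grid[gi], ll_grid[gi]
        )
        if ll_hat > best_ll:
            best_r, best_ll = r_hat, ll_hat
    return float(best_r)


def estimate_site_rate(
    column: dict[str, str],
    tree: PrimatePhylogeny,
    model: SubstitutionModel | None = None,
) -> float:
    """ML rate multiplier for a single column (species -> residue)."""
    model = model or jtt()
    distinct = {r for r in column.values() if r not in GAP_CHARS}
    if len(distinct) <= 1:
        return RATE_LOWER
    arrays = tree.to_arrays()
    codes = np.full((1, arrays.n_leaves), -1, dtype=np.int8)
    for li, name in enumerate(arrays.leaf_names):
        res = column.get(name)
        if res is not None and res not in GAP_CHARS:
            codes[0, li] = AA_INDEX[res]
    grid = np.geomspace(RATE_LOWER, RATE_UPPER, GRID_POINTS)
    ll = np.array([_batch_log_likelihood(codes, arrays, model, r)[0] for r in grid])
    return _refine_over_modes(codes, arrays, model, grid, ll)


def normalize_rates(rates) -> np.ndarray:
    """Scale an orthogroup's rate vector to mean one for cross-group pooling.

    An all-invariant orthogroup carries no rate information; its vector is
    set to ones with a warning.
    """
    r = np.asarray(rates, dtype=float)
    if r.size == 0:
        return r.copy()
    mean = r.mean()
    if mean <= RATE_LOWER * 1.001:
        logger.warning("all-invariant orthogroup: normalized rates set to 1")
        return np.ones_like(r)
    return r / mean


# ----------------------------------------------------------- model façade


class SiteRateModel:
    """Per-site evolutionary-rate model for one aligned orthogroup.

    The data are an :class:`~ligevo.ortho.Orthogroup` MSA and a fixed
    :class:`~ligevo.phylo.PrimatePhylogeny`; the only free parameters are
    the per-column rate multipliers, estimated independently per column
    by maximum likelihood under ``subst_model``.  ``fit`` returns a
    :class:`SiteRateResults`.
    """

    def __init__(
        self,
        orthogroup: Orthogroup,
        tree: PrimatePhylogeny,
        subst_model: SubstitutionModel | str = "JTT",
    ):
        if isinstance(subst_model, str):
            subst_model = SubstitutionModel.from_name(subst_model)
        self.orthogroup = orthogroup
        self.tree = tree
        self.subst_model = subst_model

    @classmethod
    def from_fasta(cls, path, tree, subst_model="JTT") -> "SiteRateModel":
        from .ortho import read_orthogroup_fasta

        return cls(read_orthogroup_fasta(path), tree, subst_model)

    def fit(self) -> "SiteRateResults":
        og = self.orthogroup
        rates = estimate_site_rates(og, self.tree, self.subst_model)
        human_pos = og.human_position_of_column()
        rows = []
        for col in range(1, og.n_columns + 1):
            residues = og.column(col)
            var = classify_variability(residues)
            rows.append(
                {
                    "orthogroup": og.orthogroup_id,
                    "column": col,
                    "human_position": human_pos[col - 1],
                    "entropy": column_entropy(residues),
                    "ml_rate": rates[col - 1],
                    "variable": None if var is None else var == "variable",
                    "n_effective": sum(
                        1 for r in residues.values() if r not in GAP_CHARS
                    ),
                }
            )
        frame = pd.DataFrame(rows)
        frame["normalized_rate"] = normalize_rates(frame["ml_rate"].to_numpy())
        return SiteRateResults(self, frame)


class SiteRateResults:
    """Fitted per-site rates and entropies for one orthogroup."""

    def __init__(self, model: SiteRateModel, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def rates(self) -> np.ndarray:
        return self.frame["ml_rate"].to_numpy()

    @property
    def normalized_rates(self) -> np.ndarray:
        return self.frame["normalized_rate"].to_numpy()

    @property
    def entropies(self) -> np.ndarray:
        return self.frame["entropy"].to_numpy()

    def summary(self) -> str:
        f = self.frame
        scored = f[f["n_effective"] > 0]
        lines = [
            "Site rate estimation results",
            "=" * 60,
            f"Orthogroup:          {self.model.orthogroup.orthogroup_id}",
            f"Substitution model:  {self.model.subst_model.name}",
            f"Taxa in tree:        {len(self.model.tree)}",
            f"Columns scored:      {len(scored)} / {len(f)}",
            f"Variable columns:    {int(scored['variable'].sum())}"
            f" ({100 * scored['variable'].mean():.1f}%)",
            f"Mean ML rate:        {scored['ml_rate'].mean():.4f}",
            f"Mean entropy (nats): {scored['entropy'].mean():.4f}",
            "=" * 60,
        ]
        return "\n".join(lines)
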