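"""Continuous-time amino-acid substitution models.

A :class:`SubstitutionModel` holds a time-reversible 20x20 instantaneous
rate matrix ``Q`` together with its stationary distribution ``pi``.  ``Q``
is built from a symmetric exchangeability matrix ``S`` and ``pi`` as
``Q[i, j] = S[i, j] * pi[j]`` (i != j), with the diagonal set so rows sum
to zero, and is normalised so that the expected number of substitutions
per unit time at stationarity, ``-sum_i pi_i Q_ii``, equals one.  Branch
lengths on trees used with these models are therefore in expected
substitutions per site.

Transition probability matrices ``P(t) = expm(Q t)`` are computed through
the symmetric eigendecomposition available for reversible models, which
makes evaluating ``P`` at many rate-scaled branch lengths cheap.
"""

from __future__ import annotations

import numpy as np

from . import _model_data

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_STATES = 20


def _lower_triangle_to_symmetric(values) -> np.ndarray:
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            s[i, j] = s[j, i] = values[k]
            k += 1
    if k != len(values):
        raise ValueError(f"expected {k} exchangeabilities, got {len(values)}")
    return s


class SubstitutionModel:
    """Time-reversible amino-acid rate matrix with fast P(t) evaluation.

    Parameters
    ----------
    exchangeabilities : (20, 20) array
        Symmetric matrix of exchangeability parameters, zero diagonal.
    frequencies : (20,) array
        Stationary amino-acid frequencies; must sum to one (renormalised
        if off by rounding).
    name : str
        Model label used in summaries.
    """

    def __init__(self, exchangeabilities, frequencies, name="custom"):
        s = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if s.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values")
        pi = pi / pi.sum()

        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise to 1 expected substitution per unit time at stationarity
        scale = -np.dot(pi, np.diag(q))
        q /= scale

        self.name = name
        self.Q = q
        self.pi = pi
        # reversible Q is similar to the symmetric B = D^1/2 Q D^-1/2
        d_sqrt = np.sqrt(pi)
        b = d_sqrt[:, None] * q / d_sqrt[None, :]
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / d_sqrt[:, None]          # D^-1/2 V
        self._right = eigvec.T * d_sqrt[None, :]       # V' D^1/2

    @classmethod
    def from_name(cls, name: str) -> "SubstitutionModel":
        """Load a published empirical model: ``"JTT"``, ``"WAG"`` or ``"LG"``."""
        key = name.upper()
        try:
            exch = getattr(_model_data, f"_EXCH_{key}")
            freq = getattr(_model_data, f"_FREQ_{key}")
        except AttributeError:
            raise ValueError(f"unknown substitution model {name!r}") from None
        return cls(_lower_triangle_to_symmetric(exch), freq, name=key)

    def transition_matrices(self, lengths) -> np.ndarray:
        """P(t) for an array of branch lengths; returns shape (..., 20, 20).

        Small negative entries from round-off are clipped to zero.
        """
        t = np.asarray(lengths, dtype=float)
        ew = np.exp(t[..., np.newaxis] * self._eigval)  # (..., 20)
        p = np.einsum("ik,...k,kj->...ij", self._left, ew, self._right)
        np.clip(p, 0.0, None, out=p)
        return p

    def __repr__(self):  # pragma: no cover
        return f"SubstitutionModel(name={self.name!r})"


def jtt() -> SubstitutionModel:
    """The Jones-Taylor-Thornton model, the package default for rate inference."""
    return SubstitutionModel.from_name("JTT")
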