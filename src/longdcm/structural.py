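"""Structural (latent transition) side of the longitudinal model.

The latent state of an examinee is their attribute profile; over T occasions
it follows a first-order Markov chain on the permissible profile space with
initial prevalence ``delta`` (length C) and one C x C row-stochastic
transition matrix per adjacent pair of occasions.  The multinomial-logit
parameterization of the transition rows is provided as a conversion layer
(the saturated probability parameterization is what estimation updates, the
two are one-to-one for strictly positive rows).

An optional hierarchy-flavoured constraint forbids "backsliding": transitions
to a destination profile that is not componentwise >= the source are fixed at
zero and the rows renormalized.  Self-transitions are always allowed, so no
row can become empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hierarchy import ProfileSpace

_ATOL = 1e-10


def _check_stochastic(mat: np.ndarray) -> None:
    if (mat < -_ATOL).any():
        raise ValueError("transition probabilities must be nonnegative")
    if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition rows must sum to 1")


@dataclass
class TransitionSet:
    """T-1 row-stochastic C x C matrices; ``mask`` marks structurally
    forbidden (fixed-zero) cells, shared across occasions."""

    matrices: list[np.ndarray]
    stationary: bool = False
    mask: np.ndarray | None = None  # True where the cell is forced to zero

    def __post_init__(self):
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        for m in self.matrices:
            _check_stochastic(m)
            if self.mask is not None and (m[self.mask] != 0).any():
                raise ValueError("masked transition cells must be exactly zero")

    @property
    def n_profiles(self) -> int:
        return self.matrices[0].shape[0]


@dataclass
class InitialPrevalence:
    """Profile membership probabilities at the first occasion."""

    delta: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if (self.delta < -_ATOL).any() or not np.isclose(
            self.delta.sum(), 1.0, atol=1e-8
        ):
            raise ValueError("delta must be a probability vector")


@dataclass
class LogitTransition:
    """Multinomial-logit form of one transition matrix.

    ``logits[r, c]`` is the log-odds of destination c against the reference
    destination for source profile r; the reference column is identically 0.
    Equivalent to intercept-plus-source-dummy coding with the reference
    source's coefficients absorbed into the intercepts.
    """

    logits: np.ndarray
    reference: int = 0

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=float)
        if not np.allclose(self.logits[:, self.reference], 0.0, atol=_ATOL):
            raise ValueError("reference-destination logits must be zero")

    @property
    def intercepts(self) -> np.ndarray:
        """Destination intercepts a_c (the first source row's logits)."""
        return self.logits[0].copy()

    @property
    def source_coefs(self) -> np.ndarray:
        """Dummy-coded source effects b_{c|r} relative to source 0."""
        return self.logits - self.logits[0]


def transition_from_logits(lt: LogitTransition) -> np.ndarray:
    """Row-wise softmax of the logits; exactly row-stochastic."""
    z = lt.logits - lt.logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def logits_from_transition(
    mat: np.ndarray, reference: int = 0, mask: np.ndarray | None = None
) -> LogitTransition:
    """Inverse of :func:`transition_from_logits` for strictly positive rows.

    Cells flagged in ``mask`` are excluded (their logits set to -inf); any
    other zero entry is an error because its logit is undefined.
    """
    mat = np.asarray(mat, dtype=float)
    _check_stochastic(mat)
    if mask is None:
        mask = np.zeros_like(mat, dtype=bool)
    if mask[:, reference].any():
        raise ValueError("the reference destination may not be masked")
    free = ~mask
    if (mat[free] <= 0).any():
        raise ValueError("zero transition probability outside the mask has no logit")
    logits = np.full_like(mat, -np.inf)
    logits[free] = np.log(mat[free])
    logits = logits - logits[:, [reference]]
    return LogitTransition(logits, reference)


def regression_mask(space: ProfileSpace) -> np.ndarray:
    """Forbidden-cell mask for the no-backsliding constraint: True where the
    destination profile is not componentwise >= the source profile."""
    p = space.profiles
    return ~((p[None, :, :] >= p[:, None, :]).all(axis=2))


def apply_hierarchy_constraints(
    ts: TransitionSet, space: ProfileSpace, forbid_regression: bool = False
) -> TransitionSet:
    """Zero out backward (mastery-losing) transitions and renormalize rows.

    With ``forbid_regression`` false the input is returned unchanged.  The
    diagonal is never masked, so every row keeps positive mass.
    """
    if not forbid_regression:
        return ts
    mask = regression_mask(space)
    new = []
    for m in ts.matrices:
        m = np.where(mask, 0.0, m)
        m = m / m.sum(axis=1, keepdims=True)
        new.append(m)
    return TransitionSet(new, stationary=ts.stationary, mask=mask)


def uniform_initial(space: ProfileSpace) -> InitialPrevalence:
    c = space.n_profiles
    return InitialPrevalence(np.full(c, 1.0 / c))
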