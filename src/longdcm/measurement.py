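"""Log-linear cognitive diagnosis measurement model (LCDM) and its
hierarchy-constrained form (HDCM).

Each item i has a logistic response function

    P(X_i = 1 | alpha) = expit( lambda_{i,0} + sum_S lambda_{i,S} prod_{k in S} alpha_k )

where S ranges over nonempty subsets of the attributes the item measures
(main effects are the singletons, interactions the larger subsets).  Under an
attribute hierarchy the permissible profile space shrinks, making some effect
columns linearly dependent; the HDCM fixes the redundant effects at zero.
:func:`active_terms` derives that constraint mask constructively, by greedy
rank reduction over the permissible space, which reproduces the textbook
nested parameterization for a linear hierarchy (intercept, main effect of the
first attribute, and the chain of higher-order interactions) and keeps all
2^m - 1 effects free when attributes are independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .hierarchy import AttributeHierarchy, ProfileSpace, enumerate_profiles, reachability
from .qmatrix import QMatrix

Term = tuple[int, ...]  # sorted 0-based attribute indices


def _closed_subsets_first(measured: tuple[int, ...], r: np.ndarray) -> list[Term]:
    """Candidate effect subsets of the measured attributes.

    Ordered so that prerequisite-closed subsets (every measured prerequisite
    of a member is also a member) come first, each group sorted by size then
    lexicographically.  The closed subsets are the effects the hierarchical
    parameterization keeps; listing them first makes the greedy rank filter
    reproduce it exactly.
    """
    mset = set(measured)

    def closed(s: tuple[int, ...]) -> bool:
        ss = set(s)
        return all(
            j in ss
            for k in s
            for j in range(r.shape[0])
            if j != k and r[j, k] and j in mset
        )

    subsets = [
        s
        for size in range(1, len(measured) + 1)
        for s in itertools.combinations(sorted(measured), size)
    ]
    return sorted(subsets, key=lambda s: (not closed(s), len(s), s))


def active_terms(q_vector, hierarchy: AttributeHierarchy) -> list[Term]:
    """Free (non-masked) effect subsets for an item under a hierarchy.

    Greedy rank reduction: walk the candidate subsets (prerequisite-closed
    first, size ascending) and retain a subset iff its indicator column over
    the permissible profile space is linearly independent of the intercept and
    the already-retained columns.  The retained count equals the number of
    distinct linear-predictor values the item can take over the space.
    """
    q = np.asarray(q_vector, dtype=np.int8)
    if q.shape != (hierarchy.n_attributes,):
        raise ValueError("q-vector length does not match the hierarchy")
    if not q.any():
        raise ValueError("q-vector measures no attribute")
    measured = tuple(int(k) for k in np.flatnonzero(q))
    space = enumerate_profiles(hierarchy)
    r = reachability(hierarchy)

    cols = [np.ones(space.n_profiles)]  # intercept
    kept: list[Term] = []
    for s in _closed_subsets_first(measured, r):
        col = space.profiles[:, s].all(axis=1).astype(float)
        basis = np.column_stack(cols + [col])
        if np.linalg.matrix_rank(basis) > len(cols):
            cols.append(col)
            kept.append(s)
    return sorted(kept, key=lambda s: (len(s), s))


@dataclass
class ItemParams:
    """Intercept and free effect coefficients of one item.

    ``effects`` maps each free subset (sorted 0-based attribute indices) to
    its coefficient; masked subsets are simply absent and contribute zero.
    """

    intercept: float
    effects: dict[Term, float] = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        """Free parameter count including the intercept."""
        return 1 + len(self.effects)

    def to_json_dict(self) -> dict:
        """1-based serialization: ``{"intercept": x, "effects": {"1,2": x}}``."""
        return {
            "intercept": float(self.intercept),
            "effects": {
                ",".join(str(k + 1) for k in s): float(v)
                for s, v in self.effects.items()
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ItemParams":
        effects = {
            tuple(sorted(int(tok) - 1 for tok in key.split(","))): float(v)
            for key, v in d.get("effects", {}).items()
        }
        return cls(float(d["intercept"]), effects)


def linear_predictor(params: ItemParams, profile) -> float:
    """Logit-scale predictor: intercept + sum of triggered free effects."""
    alpha = np.asarray(profile, dtype=np.int8)
    z = params.intercept
    for s, lam in params.effects.items():
        if alpha[list(s)].all():
            z += lam
    return float(z)


def prob_correct(params: ItemParams, profile) -> float:
    """Correct-response probability: logistic transform of the predictor."""
    return float(expit(linear_predictor(params, profile)))


def default_study_params(
    q: QMatrix,
    hierarchy: AttributeHierarchy,
    intercept: float = -1.0,
    main_effect: float = 2.0,
    interaction: float = 1.0,
) -> list[ItemParams]:
    """Fixed item-quality scheme used across all study conditions: intercept
    -1, every free main effect 2, every free interaction (any order) 1.

    With these values P(correct | nothing mastered) = expit(-1) ~ 0.27 and
    P(correct | full mastery) >= expit(1) ~ 0.73 for every item type.
    """
    out = []
    for i in range(q.n_items):
        terms = active_terms(q.row(i), hierarchy)
        effects = {s: (main_effect if len(s) == 1 else interaction) for s in terms}
        out.append(ItemParams(intercept, effects))
    return out


def design_columns(terms: list[Term], space: ProfileSpace) -> np.ndarray:
    """C x (1 + len(terms)) design matrix over a profile space: intercept
    column followed by the indicator column of each effect subset."""
    cols = [np.ones(space.n_profiles)]
    cols += [space.profiles[:, s].all(axis=1).astype(float) for s in terms]
    return np.column_stack(cols)


def response_prob_matrix(
    item_params: list[ItemParams], space: ProfileSpace
) -> np.ndarray:
    """I x C matrix of P(correct | profile) for every item and profile."""
    out = np.empty((len(item_params), space.n_profiles))
    for i, p in enumerate(item_params):
        terms = list(p.effects)
        x = design_columns(terms, space)
        beta = np.concatenate([[p.intercept], [p.effects[s] for s in terms]])
        out[i] = expit(x @ beta)
    return out
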