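"""Q-matrix construction, auditing, and identifiability diagnostics.

The Q-matrix (items x attributes, binary) declares which attributes each item
measures.  Two ingredients recur in design guidance for diagnostic models with
an attribute hierarchy:

* **R-transpose blocks.**  The columns of the reachability matrix, read as
  q-vectors (the rows of R^T), are the "restricted" item types that measure an
  attribute together with all of its prerequisites.  Stacking copies of R^T in
  the Q-matrix is the classical recipe for identifiable designs; for
  independent attributes R^T is the identity, recovering the "each attribute
  in isolation" rule.
* **Gamma-matrix separability.**  Over a profile space, ``Gamma[i, c] = 1``
  iff profile c attains the item's maximal success probability (for monotone
  models: c masters every attribute the item measures).  Distinct Gamma
  columns for all profiles is a necessary condition for strict identification;
  one R^T block in the Q-matrix guarantees it.

:func:`build_design` constructs the three canonical 10-item study designs
Q1/Q2/Q3 (zero, one, or two R^T blocks) used in the classification-accuracy
experiment; the remaining rows follow a deterministic documented fill rule, so
the same inputs always give a bit-identical matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import AttributeHierarchy, ProfileSpace, enumerate_profiles, reachability


@dataclass(frozen=True)
class QMatrix:
    """I x K binary item-attribute incidence matrix."""

    entries: np.ndarray
    item_labels: tuple[str, ...] = ()

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=np.int8)
        if e.ndim != 2:
            raise ValueError("Q-matrix must be 2-dimensional")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("Q-matrix entries must be binary")
        if (e.sum(axis=1) == 0).any():
            bad = int(np.flatnonzero(e.sum(axis=1) == 0)[0]) + 1
            raise ValueError(f"item {bad} measures no attribute (all-zero row)")
        if (e.sum(axis=0) == 0).any():
            bad = int(np.flatnonzero(e.sum(axis=0) == 0)[0]) + 1
            raise ValueError(f"attribute {bad} is measured by no item (all-zero column)")
        object.__setattr__(self, "entries", e)
        labels = self.item_labels or tuple(f"item{i+1}" for i in range(e.shape[0]))
        if len(labels) != e.shape[0]:
            raise ValueError("item_labels length mismatch")
        object.__setattr__(self, "item_labels", tuple(labels))

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def row(self, i: int) -> np.ndarray:
        return self.entries[i]

    # -- CSV round trip: header ``item,A1,...,AK``, item labels first column --

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        df = pd.read_csv(path)
        labels = tuple(str(x) for x in df.iloc[:, 0])
        return cls(df.iloc[:, 1:].to_numpy(), labels)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.entries,
            columns=[f"A{k+1}" for k in range(self.n_attributes)],
        )
        df.insert(0, "item", list(self.item_labels))
        df.to_csv(path, index=False)


def rt_rows(hierarchy: AttributeHierarchy) -> np.ndarray:
    """Rows of R^T: the restricted q-vectors (attribute + all prerequisites)."""
    return reachability(hierarchy).T.copy()


def _unstructured_qvectors(k: int) -> np.ndarray:
    """All 2^K - 1 nonzero q-vectors in canonical order (mastery count
    ascending, ties by binary value with attribute 1 most significant)."""
    vecs = np.array(
        [v for v in itertools.product((0, 1), repeat=k) if any(v)], dtype=np.int8
    )
    weights = 2 ** np.arange(k - 1, -1, -1)
    order = np.lexsort((vecs @ weights, vecs.sum(axis=1)))
    return vecs[order]


def _count_blocks(rows: np.ndarray, rt: np.ndarray) -> int:
    counts = [(rows == row).all(axis=1).sum() for row in rt]
    return int(min(counts))


def count_rt_blocks(q: QMatrix, r: np.ndarray) -> int:
    """Maximum number of disjoint row-subsets of Q each equal, up to row
    permutation, to the rows of R^T.

    The rows of R^T are pairwise distinct (each contains its own attribute on
    the diagonal), so the maximum equals the minimum, over R^T rows, of that
    row's multiplicity in Q — an exact count, no search needed.
    """
    rt = np.asarray(r, dtype=np.int8).T
    if rt.shape[1] != q.n_attributes:
        raise ValueError("Q-matrix and R-matrix disagree on the number of attributes")
    return _count_blocks(q.entries, rt)


def gamma_matrix(q, space: ProfileSpace) -> np.ndarray:
    """I x C indicator: ``Gamma[i, c] = 1`` iff profile c masters every
    attribute item i measures (componentwise profile >= q-vector).

    Accepts a :class:`QMatrix` or a plain binary array (handy for auditing
    item subsets that would not pass the full Q-matrix invariants).
    """
    entries = q.entries if isinstance(q, QMatrix) else np.asarray(q, dtype=np.int8)
    if entries.shape[1] != space.n_attributes:
        raise ValueError("Q-matrix and profile space disagree on K")
    return (space.profiles[None, :, :] >= entries[:, None, :]).all(axis=2).astype(np.int8)


def is_separable(gamma: np.ndarray) -> bool:
    """True iff all profile columns of the Gamma-matrix are pairwise distinct."""
    g = np.asarray(gamma)
    return len({tuple(col) for col in g.T}) == g.shape[1]


@dataclass(frozen=True)
class CoverageReport:
    """Per-attribute item counts with warnings for thin coverage (< 3 items)."""

    counts: tuple[int, ...]
    warnings: tuple[str, ...] = field(default=())


def coverage_report(q: QMatrix, min_items: int = 3) -> CoverageReport:
    counts = tuple(int(c) for c in q.entries.sum(axis=0))
    warnings = tuple(
        f"attribute {k+1} is measured by only {c} item(s); at least {min_items} recommended"
        for k, c in enumerate(counts)
        if c < min_items
    )
    return CoverageReport(counts, warnings)


def build_design(
    hierarchy: AttributeHierarchy, design_id: str, n_items: int = 10
) -> QMatrix:
    """Canonical Q1/Q2/Q3 study design for a hierarchy.

    * ``Q1`` — contains no R^T block; under an independent hierarchy it also
      never measures attribute 1 in isolation.
    * ``Q2`` — exactly one R^T block plus one identity block (when R^T *is*
      the identity, i.e. independent attributes, a single block; the fill then
      measures attribute 1 in isolation only within that block).
    * ``Q3`` — exactly two R^T blocks.

    Remaining rows cycle through the 2^K - 1 unstructured q-vectors in
    canonical order, skipping any row that would violate the design's defining
    block count.  Deterministic: same inputs, bit-identical output.
    """
    design_id = design_id.upper()
    if design_id not in {"Q1", "Q2", "Q3"}:
        raise ValueError(f"unknown design id {design_id!r}")
    k = hierarchy.n_attributes
    r = reachability(hierarchy)
    rt = rt_rows(hierarchy)
    identity = np.eye(k, dtype=np.int8)
    rt_is_identity = bool((rt == identity).all())

    rows: list[np.ndarray] = []
    if design_id == "Q2":
        rows.extend(rt)
        if not rt_is_identity:
            rows.extend(identity)
        max_blocks = 1
    elif design_id == "Q3":
        rows.extend(rt)
        rows.extend(rt)
        max_blocks = 2
    else:
        max_blocks = 0
    if len(rows) > n_items:
        raise ValueError(
            f"{design_id} for K={k} needs at least {len(rows)} items, got {n_items}"
        )

    forbid_a1_isolation = design_id == "Q1" and rt_is_identity
    a1_iso = identity[0]
    pool = itertools.cycle(_unstructured_qvectors(k))
    guard = 0
    while len(rows) < n_items:
        cand = next(pool)
        guard += 1
        if guard > 10_000:  # pragma: no cover - defensive
            raise RuntimeError("canonical fill failed to complete the design")
        if forbid_a1_isolation and (cand == a1_iso).all():
            continue
        if _count_blocks(np.vstack(rows + [cand]), rt) > max_blocks:
            continue
        rows.append(cand)
    return QMatrix(np.vstack(rows))
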