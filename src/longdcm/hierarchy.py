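"""Attribute prerequisite hierarchies, reachability, and permissible profile spaces.

An *attribute hierarchy* is a DAG over K binary latent skills (attributes) in
which an edge ``j -> k`` means "mastery of attribute j is a prerequisite for
mastery of attribute k".  The hierarchy determines

* the **reachability matrix** (R-matrix): ``R[j, k] = 1`` iff attribute j is a
  direct or indirect prerequisite of k, or ``j == k``; and
* the **permissible profile space**: the binary K-vectors alpha in which every
  mastered attribute has all its prerequisites mastered.

Attributes are labelled 1..K in user-facing I/O (edge lists, config files,
printed tables) and indexed 0..K-1 everywhere inside the package; the
conversion happens exactly once, in :class:`AttributeHierarchy`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


class HierarchyError(ValueError):
    """Raised for malformed hierarchies (bad labels, self-edges, cycles)."""


@dataclass(frozen=True)
class AttributeHierarchy:
    """Prerequisite DAG among K attributes.

    Parameters
    ----------
    n_attributes
        Number of attributes K (>= 1).
    edges
        Direct prerequisite pairs ``(j, k)`` with **1-based** attribute labels,
        meaning j must be mastered before k.
    kind_label
        Free-form tag (``independent``, ``divergent``, ``linear``, ``custom``).
    """

    n_attributes: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    kind_label: str = "custom"

    def __init__(self, n_attributes, edges=(), kind_label="custom"):
        if n_attributes < 1:
            raise HierarchyError("need at least one attribute")
        edges = frozenset((int(j), int(k)) for j, k in edges)
        for j, k in edges:
            if not (1 <= j <= n_attributes and 1 <= k <= n_attributes):
                raise HierarchyError(
                    f"edge ({j}, {k}) outside attribute labels 1..{n_attributes}"
                )
            if j == k:
                raise HierarchyError(f"self-edge on attribute {j}")
        g = nx.DiGraph()
        g.add_nodes_from(range(1, n_attributes + 1))
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise HierarchyError(f"prerequisite relation has a cycle: {cycle}")
        object.__setattr__(self, "n_attributes", int(n_attributes))
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "kind_label", str(kind_label))

    # -- named shapes -------------------------------------------------------

    @classmethod
    def independent(cls, n_attributes: int) -> "AttributeHierarchy":
        """No prerequisite relations; all 2^K profiles permissible."""
        return cls(n_attributes, (), "independent")

    @classmethod
    def linear(cls, n_attributes: int) -> "AttributeHierarchy":
        """Single chain a1 -> a2 -> ... -> aK."""
        edges = [(k, k + 1) for k in range(1, n_attributes)]
        return cls(n_attributes, edges, "linear")

    @classmethod
    def divergent(cls, n_attributes: int) -> "AttributeHierarchy":
        """One root attribute prerequisite to each of the others."""
        edges = [(1, k) for k in range(2, n_attributes + 1)]
        return cls(n_attributes, edges, "divergent")

    @classmethod
    def from_config(cls, cfg: dict) -> "AttributeHierarchy":
        """Build from a config mapping: ``{attributes: K, shape: linear}`` or
        ``{attributes: K, edges: [[1, 2], [2, 3]]}``."""
        k = int(cfg["attributes"])
        shape = cfg.get("shape")
        if shape is not None:
            try:
                return getattr(cls, shape)(k)
            except AttributeError:
                raise HierarchyError(f"unknown hierarchy shape {shape!r}") from None
        return cls(k, [tuple(e) for e in cfg.get("edges", [])])

    @property
    def is_independent(self) -> bool:
        return not self.edges


def reachability(hierarchy: AttributeHierarchy) -> np.ndarray:
    """Reflexive transitive closure of the prerequisite relation.

    Returns the K x K binary R-matrix with ``R[j, k] = 1`` iff attribute j+1 is
    a (possibly indirect) prerequisite of attribute k+1 or ``j == k``
    (0-based indices).
    """
    k = hierarchy.n_attributes
    g = nx.DiGraph()
    g.add_nodes_from(range(k))
    g.add_edges_from((j - 1, l - 1) for j, l in hierarchy.edges)
    closure = nx.transitive_closure(g, reflexive=True)
    r = np.zeros((k, k), dtype=np.int8)
    for j, l in closure.edges:
        r[j, l] = 1
    return r


@dataclass(frozen=True)
class ProfileSpace:
    """Ordered permissible attribute profiles for a hierarchy.

    ``profiles`` is a (C, K) binary array; row order is canonical: ascending
    mastery count, ties broken by the profile read as a binary number with
    attribute 1 as the most significant bit.  For a linear hierarchy this is
    the textbook order 000, 100, 110, ..., 111.
    """

    profiles: np.ndarray
    hierarchy: AttributeHierarchy

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.profiles.shape[1]

    def index_of(self, profile) -> int:
        """Canonical index of a permissible profile; KeyError if impermissible."""
        p = np.asarray(profile, dtype=np.int8)
        hits = np.flatnonzero((self.profiles == p).all(axis=1))
        if hits.size == 0:
            raise KeyError(f"profile {tuple(int(x) for x in p)} is not permissible")
        return int(hits[0])

    def labels(self) -> list[str]:
        return ["".join(str(int(a)) for a in row) for row in self.profiles]


def _canonical_sort(mat: np.ndarray) -> np.ndarray:
    weights = 2 ** np.arange(mat.shape[1] - 1, -1, -1)
    key = mat @ weights
    order = np.lexsort((key, mat.sum(axis=1)))
    return mat[order]


def enumerate_profiles(hierarchy: AttributeHierarchy) -> ProfileSpace:
    """All hierarchy-consistent binary profiles, canonically ordered.

    A profile is permissible iff every mastered attribute has all its
    (reachability) prerequisites mastered.  |space| = 2^K for an independent
    hierarchy and K+1 for a single chain.
    """
    k = hierarchy.n_attributes
    r = reachability(hierarchy)
    all_profiles = np.array(list(itertools.product((0, 1), repeat=k)), dtype=np.int8)
    # alpha_k = 1 requires alpha_j = 1 for every prerequisite j:  alpha @ (R - I) counts
    # mastered attributes whose prerequisites include each j; cheaper to test directly.
    ok = np.array([_permissible(p, r) for p in all_profiles])
    return ProfileSpace(_canonical_sort(all_profiles[ok]), hierarchy)


def _permissible(profile: np.ndarray, r: np.ndarray) -> bool:
    mastered = profile.astype(bool)
    needed = r[:, mastered].any(axis=1)  # attributes prerequisite to any mastered one
    return bool(mastered[needed].all())


def is_permissible(profile, hierarchy: AttributeHierarchy) -> bool:
    """True iff ``profile`` satisfies every prerequisite of the hierarchy."""
    p = np.asarray(profile, dtype=np.int8)
    if p.shape != (hierarchy.n_attributes,):
        raise ValueError(
            f"profile has length {p.size}, hierarchy has {hierarchy.n_attributes} attributes"
        )
    return _permissible(p, reachability(hierarchy))
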