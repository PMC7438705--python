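"""Monte Carlo data generation for the classification-accuracy study.

One study condition crosses an attribute hierarchy (independent, divergent,
linear) with a Q-matrix design (Q1/Q2/Q3).  Data generation follows the study
conditions throughout: N = 1000 examinees, T = 3 occasions, 10-item tests on
K = 3 attributes, item parameters fixed at intercept -1 / main effect 2 /
interaction 1, and initial profiles uniform over the permissible space.

The study design pins down everything except the occasion-to-occasion
transition law, for which the generator uses a learning kernel: between adjacent occasions each unmastered
attribute whose prerequisites were all mastered at the previous occasion is
gained independently with probability ``p_gain`` (default 0.4); mastery is
never lost.  This moves mass up the hierarchy across occasions, producing the
rising time trend in classification rates, and always yields permissible
profiles and row-stochastic transition matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import AttributeHierarchy, ProfileSpace, enumerate_profiles, reachability
from .measurement import ItemParams, default_study_params, response_prob_matrix
from .qmatrix import QMatrix, build_design
from .structural import InitialPrevalence, TransitionSet, uniform_initial
from .estimation import ResponseData


@dataclass
class StudyDesign:
    """One simulation condition: hierarchy x Q-matrix design plus sizes."""

    hierarchy: AttributeHierarchy
    design_id: str | None = "Q2"
    qmatrix: QMatrix | None = None
    n_items: int = 10
    n_examinees: int = 1000
    n_times: int = 3
    p_gain: float = 0.4
    intercept: float = -1.0
    main_effect: float = 2.0
    interaction: float = 1.0
    n_reps: int = 100
    base_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_gain <= 1.0:
            raise ValueError("p_gain must be in [0, 1]")
        if min(self.n_examinees, self.n_times, self.n_items) < 1:
            raise ValueError("sizes must be positive")
        if self.qmatrix is None:
            if self.design_id is None:
                raise ValueError("give either design_id or an explicit qmatrix")
            self.qmatrix = build_design(self.hierarchy, self.design_id, self.n_items)
        if self.qmatrix.n_items != self.n_items:
            raise ValueError("explicit Q-matrix does not have n_items rows")

    def space(self) -> ProfileSpace:
        return enumerate_profiles(self.hierarchy)

    def item_params(self) -> list[ItemParams]:
        return default_study_params(
            self.qmatrix,
            self.hierarchy,
            intercept=self.intercept,
            main_effect=self.main_effect,
            interaction=self.interaction,
        )

    def rep_seed(self, rep: int) -> int:
        """Replication r uses base_seed + r (kept below 2^31)."""
        return int((self.base_seed + rep) % (2**31 - 1))


def kernel_to_transitions(design: StudyDesign) -> TransitionSet:
    """Explicit C x C transition matrix implied by the gain kernel.

    ``P(dest | src) = prod_k p_k`` where eligible unmastered attributes (all
    prerequisites mastered at the source) contribute ``p_gain`` if gained and
    ``1 - p_gain`` if not; destinations that drop mastery or gain a
    non-eligible attribute get probability zero.
    """
    space = design.space()
    r = reachability(design.hierarchy)
    profiles = space.profiles
    c = space.n_profiles
    mat = np.zeros((c, c))
    for s in range(c):
        src = profiles[s]
        eligible = np.array(
            [
                src[k] == 0 and all(src[j] for j in range(len(src)) if j != k and r[j, k])
                for k in range(len(src))
            ]
        )
        for d in range(c):
            dst = profiles[d]
            gained = (dst == 1) & (src == 0)
            if (dst < src).any() or (gained & ~eligible).any():
                continue
            kept = eligible & ~gained
            mat[s, d] = design.p_gain ** gained.sum() * (1 - design.p_gain) ** kept.sum()
    n_mats = max(design.n_times - 1, 1)
    return TransitionSet([mat.copy() for _ in range(n_mats)], stationary=True)


def sample_trajectories(design: StudyDesign, seed: int | None = None) -> np.ndarray:
    """(N, T) array of true profile indices: uniform over the permissible
    space at occasion 1, then the gain kernel."""
    rng = np.random.default_rng(design.rep_seed(0) if seed is None else seed)
    space = design.space()
    c = space.n_profiles
    tau = kernel_to_transitions(design).matrices[0]
    n, t_len = design.n_examinees, design.n_times
    out = np.empty((n, t_len), dtype=np.int64)
    out[:, 0] = rng.integers(0, c, size=n)
    cum = tau.cumsum(axis=1)
    for t in range(1, t_len):
        u = rng.random(n)
        out[:, t] = (u[:, None] > cum[out[:, t - 1]]).sum(axis=1)
    return out


def generate_responses(
    trajectories: np.ndarray,
    q: QMatrix,
    item_params: list[ItemParams],
    space: ProfileSpace,
    seed: int | None = None,
) -> ResponseData:
    """Bernoulli item responses given true profile trajectories.

    Item parameters are the same at every occasion (time invariance), so the
    response probability depends only on the item and the current profile.
    """
    rng = np.random.default_rng(seed)
    pmat = response_prob_matrix(item_params, space)  # (I, C)
    probs = pmat.T[trajectories]  # (N, T, I)
    y = (rng.random(probs.shape) < probs).astype(np.int8)
    return ResponseData(y)


def simulate_dataset(design: StudyDesign, rep: int = 0):
    """One replication: ``(responses, trajectories)`` with the replication's
    seed protocol (trajectories use seed, responses seed + a fixed offset)."""
    seed = design.rep_seed(rep)
    space = design.space()
    traj = sample_trajectories(design, seed=seed)
    resp = generate_responses(
        traj, design.qmatrix, design.item_params(), space, seed=seed + 500_000_000
    )
    return resp, traj


def truth_frame(design: StudyDesign, trajectories: np.ndarray) -> pd.DataFrame:
    """Long-format truth table: examinee, time, profile index, alpha columns."""
    space = design.space()
    n, t_len = trajectories.shape
    rows = []
    for nn in range(n):
        for t in range(t_len):
            idx = int(trajectories[nn, t])
            rows.append(
                [nn + 1, t + 1, idx]
                + [int(a) for a in space.profiles[idx]]
            )
    cols = ["examinee", "time", "profile_index"] + [
        f"alpha{k+1}" for k in range(space.n_attributes)
    ]
    return pd.DataFrame(rows, columns=cols)
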