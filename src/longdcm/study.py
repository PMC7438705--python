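"""Classification-accuracy metrics and the Monte Carlo study runner.

Two criteria summarize recovery of the true latent profiles:

* **profile CCR** — fraction of examinees whose MAP-estimated profile at an
  occasion equals the true profile exactly;
* **marginal CCR (MCCR)** — fraction agreeing on one attribute at an
  occasion (an exact profile match implies a match on every attribute, so
  the profile CCR never exceeds the smallest MCCR).

:func:`run_study` crosses hierarchies with Q-matrix designs, repeats
simulate -> fit -> classify -> score per condition, and aggregates replication
means with Monte Carlo standard errors into a report shaped like the familiar
classification-rate table (profile CCR by occasion plus mean, MCCR by
attribute x occasion plus means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hierarchy import AttributeHierarchy
from .estimation import ModelSpec, classify, fit_em
from .simulate import StudyDesign, simulate_dataset

log = logging.getLogger(__name__)


def profile_ccr(true_profiles: np.ndarray, est_profiles: np.ndarray, t: int) -> float:
    """Exact-match classification rate at occasion ``t`` (0-based)."""
    true_profiles = np.asarray(true_profiles)
    est_profiles = np.asarray(est_profiles)
    if true_profiles.shape != est_profiles.shape:
        raise ValueError("true and estimated profile arrays differ in shape")
    return float((true_profiles[:, t] == est_profiles[:, t]).mean())


def marginal_ccr(
    true_profiles: np.ndarray,
    est_profiles: np.ndarray,
    profiles: np.ndarray,
    attribute: int,
    t: int,
) -> float:
    """Per-attribute agreement rate at occasion ``t``.

    ``profiles`` is the canonical (C, K) profile table used to decode the
    index arrays into attribute masteries; ``attribute`` is 0-based.
    """
    true_profiles = np.asarray(true_profiles)
    est_profiles = np.asarray(est_profiles)
    if true_profiles.shape != est_profiles.shape:
        raise ValueError("true and estimated profile arrays differ in shape")
    a_true = profiles[true_profiles[:, t], attribute]
    a_est = profiles[est_profiles[:, t], attribute]
    return float((a_true == a_est).mean())


@dataclass
class StudyConfig:
    """Configuration of a (possibly multi-condition) study run."""

    hierarchies: list[AttributeHierarchy]
    design_ids: list[str] = field(default_factory=lambda: ["Q1", "Q2", "Q3"])
    n_items: int = 10
    n_examinees: int = 1000
    n_times: int = 3
    p_gain: float = 0.4
    n_reps: int = 100
    base_seed: int = 1
    variant: str | None = None  # None: H-TDCM for hierarchies, TDCM for independent
    n_starts: int = 2
    max_iter: int = 200
    tol: float = 1e-5

    @classmethod
    def from_dict(cls, cfg: dict) -> "StudyConfig":
        hier_cfgs = cfg.get("hierarchies") or [cfg["hierarchy"]]
        hierarchies = []
        for h in hier_cfgs:
            if isinstance(h, str):
                h = {"attributes": cfg.get("attributes", 3), "shape": h}
            hierarchies.append(AttributeHierarchy.from_config(h))
        kwargs = {
            k: cfg[k]
            for k in (
                "n_items n_examinees n_times p_gain n_reps base_seed "
                "variant n_starts max_iter tol"
            ).split()
            if k in cfg
        }
        designs = cfg.get("design_ids", cfg.get("designs"))
        if designs is not None:
            kwargs["design_ids"] = list(designs)
        return cls(hierarchies=hierarchies, **kwargs)


@dataclass
class ConditionResult:
    """Aggregated rates for one hierarchy x design condition."""

    hierarchy_label: str
    design_id: str
    profile_ccr_by_time: np.ndarray  # (T,) replication means
    profile_ccr_se: np.ndarray  # (T,) MC standard errors of the means
    marginal_ccr: np.ndarray  # (T, K) replication means
    marginal_ccr_se: np.ndarray  # (T, K)
    n_reps: int
    n_failed: int
    seeds: list[int]

    @property
    def mean_profile_ccr(self) -> float:
        return float(self.profile_ccr_by_time.mean())

    @property
    def mean_marginal_ccr_by_time(self) -> np.ndarray:
        return self.marginal_ccr.mean(axis=1)


@dataclass
class StudyResult:
    conditions: list[ConditionResult]
    config: StudyConfig

    def get(self, hierarchy_label: str, design_id: str) -> ConditionResult:
        for c in self.conditions:
            if c.hierarchy_label == hierarchy_label and c.design_id == design_id:
                return c
        raise KeyError((hierarchy_label, design_id))

    def to_frame(self) -> pd.DataFrame:
        """Wide report: one column per condition, rows in the classic layout
        (profile CCR by occasion + mean, then MCCR by occasion x attribute
        + per-occasion means)."""
        cols = {}
        t_len = self.conditions[0].profile_ccr_by_time.size
        k = self.conditions[0].marginal_ccr.shape[1]
        index = [f"profile_ccr_time{t+1}" for t in range(t_len)] + ["profile_ccr_mean"]
        for t in range(t_len):
            index += [f"mccr_time{t+1}_a{a+1}" for a in range(k)]
            index += [f"mccr_time{t+1}_mean"]
        for c in self.conditions:
            vals = list(c.profile_ccr_by_time) + [c.mean_profile_ccr]
            for t in range(t_len):
                vals += list(c.marginal_ccr[t]) + [float(c.marginal_ccr[t].mean())]
            cols[f"{c.hierarchy_label}_{c.design_id}"] = vals
        return pd.DataFrame(cols, index=index)

    def to_json_dict(self) -> dict:
        out = {}
        for c in self.conditions:
            out[f"{c.hierarchy_label}_{c.design_id}"] = {
                "profile_ccr_by_time": c.profile_ccr_by_time.tolist(),
                "profile_ccr_se": c.profile_ccr_se.tolist(),
                "profile_ccr_mean": c.mean_profile_ccr,
                "marginal_ccr": c.marginal_ccr.tolist(),
                "marginal_ccr_se": c.marginal_ccr_se.tolist(),
                "n_reps": c.n_reps,
                "n_failed": c.n_failed,
                "seeds": c.seeds,
            }
        return out


def _condition_variant(hierarchy: AttributeHierarchy, requested: str | None) -> str:
    if requested is not None:
        return requested
    return "tdcm" if hierarchy.is_independent else "htdcm"


def run_condition(
    config: StudyConfig, hierarchy: AttributeHierarchy, design_id: str
) -> ConditionResult:
    """Replicated simulate -> fit -> classify -> score for one condition."""
    design = StudyDesign(
        hierarchy=hierarchy,
        design_id=design_id,
        n_items=config.n_items,
        n_examinees=config.n_examinees,
        n_times=config.n_times,
        p_gain=config.p_gain,
        n_reps=config.n_reps,
        base_seed=config.base_seed,
    )
    variant = _condition_variant(hierarchy, config.variant)
    spec = ModelSpec(
        hierarchy=hierarchy,
        qmatrix=design.qmatrix,
        variant=variant,
        n_times=config.n_times,
    )
    space = spec.space()
    t_len, k = config.n_times, hierarchy.n_attributes

    pccr, mccr, seeds = [], [], []
    n_failed = 0
    for rep in range(config.n_reps):
        seed = design.rep_seed(rep)
        seeds.append(seed)
        resp, traj = simulate_dataset(design, rep)
        try:
            fit = fit_em(
                resp,
                spec,
                tol=config.tol,
                max_iter=config.max_iter,
                n_starts=config.n_starts,
                seed=seed,
            )
        except Exception:  # pragma: no cover - defensive bookkeeping
            log.exception("replication %d (seed %d) failed; excluded", rep, seed)
            n_failed += 1
            continue
        est, _ = classify(fit.model, resp)
        # truth is indexed in the hierarchy's permissible space; re-index into
        # the fitted model's space (identical for H-TDCM, embedded for TDCM)
        truth_space = design.space()
        remap = np.array(
            [space.index_of(p) for p in truth_space.profiles], dtype=np.int64
        )
        true_idx = remap[traj]
        pccr.append([profile_ccr(true_idx, est, t) for t in range(t_len)])
        mccr.append(
            [
                [marginal_ccr(true_idx, est, space.profiles, a, t) for a in range(k)]
                for t in range(t_len)
            ]
        )
        log.info(
            "condition %s/%s rep %d seed %d logL %.2f converged %s",
            hierarchy.kind_label, design_id, rep, seed, fit.loglik, fit.converged,
        )
    pccr_arr = np.asarray(pccr)
    mccr_arr = np.asarray(mccr)
    n_ok = pccr_arr.shape[0]
    se_div = np.sqrt(max(n_ok, 1))
    return ConditionResult(
        hierarchy_label=hierarchy.kind_label,
        design_id=design_id,
        profile_ccr_by_time=pccr_arr.mean(axis=0),
        profile_ccr_se=pccr_arr.std(axis=0, ddof=1) / se_div if n_ok > 1 else np.zeros(t_len),
        marginal_ccr=mccr_arr.mean(axis=0),
        marginal_ccr_se=mccr_arr.std(axis=0, ddof=1) / se_div if n_ok > 1 else np.zeros((t_len, k)),
        n_reps=n_ok,
        n_failed=n_failed,
        seeds=seeds,
    )


def run_study(config: StudyConfig) -> StudyResult:
    """All hierarchy x design conditions of a configuration, sequentially.

    Deterministic for a given base seed: each condition uses the same
    replication seed sequence base_seed + rep.
    """
    conditions = []
    for h in config.hierarchies:
        for d in config.design_ids:
            conditions.append(run_condition(config, h, d))
    return StudyResult(conditions, config)
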