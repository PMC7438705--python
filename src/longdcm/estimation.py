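"""Marginal maximum likelihood estimation of (hierarchical) transition
diagnostic classification models.

The model is a hidden Markov chain over attribute profiles: an examinee's
profile at occasion 1 is drawn from the prevalence ``delta``, evolves by the
transition matrices ``tau``, and at every occasion generates I dichotomous
item responses through the LCDM/HDCM measurement model (time-invariant item
parameters).  The observed-data likelihood of one examinee therefore sums the
product of structural and measurement probabilities over all C^T latent
trajectories; the forward recursion evaluates it in O(T C^2 + T C I) instead.

Estimation is EM:

* E-step — exact forward-backward posteriors: occasion marginals gamma and
  adjacent-pair marginals xi.
* M-step — closed-form updates for delta and tau (masked cells pinned at
  zero); item parameters by box-constrained quasi-Newton maximization of the
  weighted Bernoulli likelihood on the C profile covariate patterns, warm
  started and iteration-capped (a generalized EM step: the surrogate never
  decreases, so the observed-data log-likelihood is nondecreasing).

Monotone items (default): all non-intercept effects are bounded below by 0,
a sufficient condition for the success probability to be nondecreasing along
the mastery order.

The hierarchical variant (H-TDCM) differs from the plain TDCM only through
the restricted profile space and the measurement-effect masks, so the two are
nested and comparable with a likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from scipy.stats import chi2

from .hierarchy import AttributeHierarchy, ProfileSpace, enumerate_profiles
from .measurement import (
    ItemParams,
    active_terms,
    design_columns,
    response_prob_matrix,
)
from .qmatrix import QMatrix
from .structural import (
    InitialPrevalence,
    TransitionSet,
    regression_mask,
)

__all__ = [
    "ModelSpec",
    "LongitudinalModel",
    "ResponseData",
    "PosteriorSet",
    "FitResult",
    "loglik",
    "e_step",
    "m_step",
    "fit_em",
    "classify",
    "embed_htdcm",
    "lrt",
]


@dataclass(frozen=True)
class ResponseData:
    """Complete dichotomous responses, shape (N examinees, T occasions, I items)."""

    y: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y)
        if y.ndim != 3:
            raise ValueError("responses must have shape (N, T, I)")
        if np.isnan(y.astype(float)).any():
            raise ValueError("missing responses are not supported")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("responses must be 0/1")
        object.__setattr__(self, "y", y.astype(np.int8))

    @property
    def n_examinees(self) -> int:
        return self.y.shape[0]

    @property
    def n_times(self) -> int:
        return self.y.shape[1]

    @property
    def n_items(self) -> int:
        return self.y.shape[2]


def _as_y(data) -> np.ndarray:
    if isinstance(data, ResponseData):
        return data.y
    return ResponseData(np.asarray(data)).y


@dataclass(frozen=True)
class ModelSpec:
    """Everything that defines the model family before parameters.

    ``variant`` is ``"htdcm"`` (profile space and effect masks derived from
    the hierarchy) or ``"tdcm"`` (full 2^K space, no masks; the hierarchy is
    only used for K).
    """

    hierarchy: AttributeHierarchy
    qmatrix: QMatrix
    variant: str = "htdcm"
    n_times: int = 3
    forbid_regression: bool = False
    stationary: bool = False
    monotone: bool = True

    def __post_init__(self):
        if self.variant not in {"tdcm", "htdcm"}:
            raise ValueError("variant must be 'tdcm' or 'htdcm'")
        if self.qmatrix.n_attributes != self.hierarchy.n_attributes:
            raise ValueError("Q-matrix and hierarchy disagree on K")
        if self.n_times < 1:
            raise ValueError("need at least one occasion")

    @property
    def effective_hierarchy(self) -> AttributeHierarchy:
        if self.variant == "tdcm":
            return AttributeHierarchy.independent(self.hierarchy.n_attributes)
        return self.hierarchy

    def space(self) -> ProfileSpace:
        return enumerate_profiles(self.effective_hierarchy)

    def item_terms(self) -> list[list[tuple[int, ...]]]:
        h = self.effective_hierarchy
        return [active_terms(self.qmatrix.row(i), h) for i in range(self.qmatrix.n_items)]

    def tau_mask(self, space: ProfileSpace) -> np.ndarray | None:
        return regression_mask(space) if self.forbid_regression else None


@dataclass
class LongitudinalModel:
    """A fully parameterized (H-)TDCM."""

    spec: ModelSpec
    item_params: list[ItemParams]
    initial: InitialPrevalence
    transitions: TransitionSet
    _space: ProfileSpace | None = field(default=None, repr=False)

    @property
    def space(self) -> ProfileSpace:
        if self._space is None:
            self._space = self.spec.space()
        return self._space

    @property
    def variant(self) -> str:
        return self.spec.variant

    def prob_matrix(self) -> np.ndarray:
        """I x C correct-response probabilities."""
        return response_prob_matrix(self.item_params, self.space)

    @property
    def n_free_parameters(self) -> int:
        n_item = sum(p.n_free for p in self.item_params)
        c = self.space.n_profiles
        n_struct = c - 1
        mask = self.transitions.mask
        free_per_row = (
            np.full(c, c - 1) if mask is None else (~mask).sum(axis=1) - 1
        )
        n_mats = 1 if self.spec.stationary else self.spec.n_times - 1
        return int(n_item + n_struct + n_mats * free_per_row.sum())


def _log_emission(y: np.ndarray, pmat: np.ndarray) -> np.ndarray:
    """(N, T, C) log-probability of each occasion's response vector per profile."""
    logp = np.log(np.clip(pmat, 1e-300, 1.0))
    log1m = np.log(np.clip(1.0 - pmat, 1e-300, 1.0))
    return np.einsum("nti,ic->ntc", y, logp - log1m) + log1m.sum(axis=0)


def _forward_backward(model: LongitudinalModel, y: np.ndarray):
    """Scaled forward-backward; returns (gamma, xi, loglik)."""
    n, t_len, _ = y.shape
    delta = model.initial.delta
    taus = model.transitions.matrices
    logb = _log_emission(y, model.prob_matrix())
    # per-occasion stabilization before exponentiating
    shift = logb.max(axis=2, keepdims=True)
    b = np.exp(logb - shift)

    c = delta.size
    alpha = np.empty((n, t_len, c))
    scales = np.empty((n, t_len))
    a = delta[None, :] * b[:, 0, :]
    scales[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scales[:, [0]]
    for t in range(1, t_len):
        a = (alpha[:, t - 1] @ taus[t - 1]) * b[:, t, :]
        scales[:, t] = a.sum(axis=1)
        alpha[:, t] = a / scales[:, [t]]

    beta = np.empty((n, t_len, c))
    beta[:, -1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[:, t] = (b[:, t + 1, :] * beta[:, t + 1]) @ taus[t].T
        beta[:, t] /= scales[:, [t + 1]]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)

    xi = []
    for t in range(t_len - 1):
        x = (
            alpha[:, t, :, None]
            * taus[t][None, :, :]
            * (b[:, t + 1, :] * beta[:, t + 1])[:, None, :]
        )
        x /= x.sum(axis=(1, 2), keepdims=True)
        xi.append(x)

    loglik = float(np.log(scales).sum() + shift.sum())
    return gamma, xi, loglik


def loglik(model: LongitudinalModel, data) -> float:
    """Observed-data log-likelihood via the forward recursion.

    Mathematically equal to summing the structural-times-measurement product
    over all C^T latent trajectories; computed in log-stabilized form so valid
    input never yields NaN.
    """
    y = _as_y(data)
    _, _, ll = _forward_backward(model, y)
    return ll


@dataclass
class PosteriorSet:
    """E-step sufficient statistics: occasion marginals and pair marginals."""

    gamma: np.ndarray  # (N, T, C)
    xi: list[np.ndarray]  # T-1 arrays (N, C, C)
    loglik: float


def e_step(model: LongitudinalModel, data) -> PosteriorSet:
    """Exact posterior profile marginals by forward-backward smoothing."""
    y = _as_y(data)
    gamma, xi, ll = _forward_backward(model, y)
    return PosteriorSet(gamma, xi, ll)


# -- M-step ----------------------------------------------------------------


def _item_objective(beta, x, s, w, ridge):
    z = x @ beta
    f = -(s @ log_expit(z) + (w - s) @ log_expit(-z))
    g = -(x.T @ (s - w * expit(z)))
    if ridge:
        f += 0.5 * ridge * beta @ beta
        g += ridge * beta
    return f, g


def _update_item(
    params: ItemParams,
    terms,
    x: np.ndarray,
    s: np.ndarray,
    w: np.ndarray,
    monotone: bool,
    maxiter: int = 40,
) -> ItemParams:
    beta0 = np.concatenate([[params.intercept], [params.effects[t] for t in terms]])
    bounds = None
    if monotone:
        bounds = [(None, None)] + [(0.0, None)] * len(terms)
    res = minimize(
        _item_objective,
        beta0,
        args=(x, s, w, 0.0),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x
    if np.abs(beta).max() > 20.0:  # quasi-separation: retreat to a ridge fit
        warnings.warn(
            "separation detected in item update; applying ridge penalty 1e-4",
            RuntimeWarning,
            stacklevel=2,
        )
        res = minimize(
            _item_objective,
            beta0,
            args=(x, s, w, 1e-4),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
        beta = res.x
    return ItemParams(float(beta[0]), dict(zip(terms, beta[1:].astype(float))))


def m_step(posteriors: PosteriorSet, data, model: LongitudinalModel) -> LongitudinalModel:
    """One EM parameter update given posteriors.

    delta and tau have closed forms (posterior-weighted relative frequencies,
    masked tau cells forced to zero before renormalizing); item parameters are
    re-estimated by the box-constrained weighted logistic update.
    """
    y = _as_y(data)
    spec = model.spec
    space = model.space
    gamma, xi = posteriors.gamma, posteriors.xi

    delta = gamma[:, 0, :].mean(axis=0)
    delta = delta / delta.sum()

    mask = model.transitions.mask
    if spec.stationary and xi:
        pooled = sum(x.sum(axis=0) for x in xi)
        mats = [_normalize_tau(pooled, mask)] * len(xi)
    else:
        mats = [_normalize_tau(x.sum(axis=0), mask) for x in xi]

    w = gamma.sum(axis=(0, 1))  # posterior exposure per profile
    s = np.einsum("nti,ntc->ic", y, gamma)  # posterior-weighted successes
    new_items = []
    for i, params in enumerate(model.item_params):
        terms = sorted(params.effects, key=lambda t: (len(t), t))
        x = design_columns(terms, space)
        new_items.append(_update_item(params, terms, x, s[i], w, spec.monotone))

    return LongitudinalModel(
        spec,
        new_items,
        InitialPrevalence(delta),
        TransitionSet(mats, stationary=spec.stationary, mask=mask),
        _space=space,
    )


def _normalize_tau(counts: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    m = counts.copy()
    if mask is not None:
        m[mask] = 0.0
    rows = m.sum(axis=1, keepdims=True)
    # a row with no posterior mass stays where it is (self-transition)
    dead = rows[:, 0] <= 0
    if dead.any():
        m[dead] = np.eye(m.shape[0])[dead]
        rows = m.sum(axis=1, keepdims=True)
    return m / rows


# -- EM driver ---------------------------------------------------------------


@dataclass
class FitResult:
    model: LongitudinalModel
    loglik_trace: list[float]
    converged: bool
    n_free_parameters: int
    aic: float
    bic: float
    seed: int | None
    n_starts: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _random_start(spec: ModelSpec, space: ProfileSpace, rng) -> LongitudinalModel:
    c = space.n_profiles
    delta = rng.dirichlet(np.ones(c))
    mask = spec.tau_mask(space)
    n_mats = max(spec.n_times - 1, 0)
    mats = []
    for _ in range(n_mats):
        m = rng.dirichlet(np.ones(c), size=c)
        if mask is not None:
            m[mask] = 0.0
            m = m / m.sum(axis=1, keepdims=True)
        mats.append(m)
    if spec.stationary and mats:
        mats = [mats[0]] * n_mats
    items = []
    for terms in spec.item_terms():
        intercept = rng.normal(-1.0, 0.5)
        effects = {t: abs(rng.normal(1.0, 0.5)) for t in terms}
        items.append(ItemParams(float(intercept), effects))
    return LongitudinalModel(
        spec,
        items,
        InitialPrevalence(delta),
        TransitionSet(mats, stationary=spec.stationary, mask=mask),
        _space=space,
    )


def _em_run(model: LongitudinalModel, y: np.ndarray, tol: float, max_iter: int):
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        post = e_step(model, y)
        trace.append(post.loglik)
        if len(trace) > 1:
            rel = (trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
            if abs(rel) < tol:
                converged = True
                break
        model = m_step(post, y, model)
    if not converged:
        trace.append(loglik(model, y))  # value for the last accepted update
    return model, trace, converged


def fit_em(
    data,
    spec: ModelSpec,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 5,
    seed: int | None = None,
    start_iter: int = 30,
    init: LongitudinalModel | None = None,
) -> FitResult:
    """Best-of-starts EM fit.

    Each random start (plus the optional ``init`` model, e.g. a nested fit
    embedded in a larger space) runs ``start_iter`` burn-in iterations; the
    best is continued to convergence (relative log-likelihood change below
    ``tol``).  Deterministic given ``seed``.
    """
    y = _as_y(data)
    if y.shape[1] != spec.n_times:
        raise ValueError(
            f"data has {y.shape[1]} occasions, spec declares {spec.n_times}"
        )
    if y.shape[2] != spec.qmatrix.n_items:
        raise ValueError("data and Q-matrix disagree on the number of items")
    space = spec.space()
    rng = np.random.default_rng(seed)
    starts = [_random_start(spec, space, rng) for _ in range(n_starts)]
    if init is not None:
        starts.append(init)

    burned = []
    for m0 in starts:
        m1, tr, conv = _em_run(m0, y, tol, min(start_iter, max_iter))
        burned.append((tr[-1], m1, tr, conv))
    best_idx = int(np.argmax([b[0] for b in burned]))
    _, model, trace, conv = burned[best_idx]
    if not conv:
        model, tail, conv = _em_run(model, y, tol, max_iter - min(start_iter, max_iter))
        trace = trace + tail[1:]
    if not conv:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning, stacklevel=2)

    k_free = model.n_free_parameters
    ll = trace[-1]
    n = y.shape[0]
    return FitResult(
        model=model,
        loglik_trace=trace,
        converged=conv,
        n_free_parameters=k_free,
        aic=2 * k_free - 2 * ll,
        bic=k_free * np.log(n) - 2 * ll,
        seed=seed,
        n_starts=len(starts),
    )


def embed_htdcm(model: LongitudinalModel) -> LongitudinalModel:
    """Re-express an H-TDCM fit as a TDCM over the full 2^K profile space.

    Masked effects enter as zeros; impermissible profiles get zero prevalence
    and zero destination probability (their own outgoing rows are uniform and
    never receive mass).  The embedded model has the identical likelihood, so
    it is a valid warm start when fitting the unconstrained TDCM — which
    guarantees the fitted TDCM log-likelihood is at least the H-TDCM's.
    """
    spec = model.spec
    if spec.variant != "htdcm":
        raise ValueError("only an H-TDCM can be embedded in the TDCM space")
    full_spec = ModelSpec(
        hierarchy=spec.hierarchy,
        qmatrix=spec.qmatrix,
        variant="tdcm",
        n_times=spec.n_times,
        forbid_regression=False,
        stationary=spec.stationary,
        monotone=spec.monotone,
    )
    full_space = full_spec.space()
    small = model.space
    idx = np.array([full_space.index_of(p) for p in small.profiles])

    items = []
    for p, terms in zip(model.item_params, full_spec.item_terms()):
        effects = {t: float(p.effects.get(t, 0.0)) for t in terms}
        items.append(ItemParams(p.intercept, effects))

    c_full = full_space.n_profiles
    delta = np.zeros(c_full)
    delta[idx] = model.initial.delta
    mats = []
    for m in model.transitions.matrices:
        big = np.full((c_full, c_full), 1.0 / c_full)
        big[idx] = 0.0
        big[np.ix_(idx, idx)] = m
        mats.append(big)
    return LongitudinalModel(
        full_spec,
        items,
        InitialPrevalence(delta),
        TransitionSet(mats, stationary=spec.stationary),
        _space=full_space,
    )


def classify(model: LongitudinalModel, data):
    """MAP profile assignment per examinee and occasion.

    Returns ``(indices, gamma)`` where ``indices[n, t]`` is the canonical
    index of the profile with maximal smoothed marginal posterior (ties break
    toward the lower index) and ``gamma`` the full posterior array.
    """
    post = e_step(model, data)
    return post.gamma.argmax(axis=2), post.gamma


def lrt(fit_nested: FitResult, fit_full: FitResult):
    """Likelihood-ratio comparison of nested fits (e.g. H-TDCM vs TDCM).

    Returns ``(statistic, df, p_value)`` with the statistic clipped at zero.
    Boundary effects (parameters fixed at zero probabilities) are not
    corrected for; the chi-square reference is the conventional one.
    """
    df = fit_full.n_free_parameters - fit_nested.n_free_parameters
    if df < 0:
        raise ValueError("first argument must be the nested (smaller) model")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_nested.loglik))
    if df == 0:
        p = 1.0 if stat == 0.0 else 0.0
    else:
        p = float(chi2.sf(stat, df))
    return stat, df, p
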