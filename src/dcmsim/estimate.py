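"""Constrained marginal maximum likelihood for restricted latent class models.

The fitted model is a finite mixture over the 2^A attribute classes: the
marginal likelihood of response vector x_j is

    L_j = sum_c pi_c prod_i P_ic^{x_ji} (1 - P_ic)^{1 - x_ji},

with item probabilities P_ic given by the submodel item response functions
and a saturated structural model (free class proportions pi).  Estimation is
EM with multiple random starts: short runs from every start, the best few
survivors run to convergence, best final log-likelihood wins.

The M-step for each item maximizes the expected complete-data Bernoulli
log-likelihood over that item's log-linear parameters subject to the order
constraints that identify the submodels (main effects > 0, e > 0,
interaction > -each main).  The objective is concave in the parameters, so a
damped Newton solver on the item's class-level design matrix is used;
whenever the unconstrained optimum violates a constraint the item is
re-solved with SLSQP under explicit bounds/inequalities, with the strict
inequalities enforced at a small margin eps.  Because the constraints anchor
each class to its attribute profile, class labels cannot switch between
starts.

Respondent response patterns are deduplicated before the EM loop, so the
per-iteration cost scales with the number of distinct patterns rather than
the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .design import QMatrix, enumerate_profiles
from .models import ItemParams, item_design_matrix, item_term_structure

PROB_FLOOR = 1e-10
_PARAM_CAP = 15.0  # |log-odds| cap keeping probabilities away from exact 0/1


@dataclass(frozen=True)
class FitConfig:
    """Multi-start EM settings (emulating a starts/final-stage-starts scheme)."""

    n_starts: int = 20
    n_survivors: int = 5
    short_iters: int = 10
    max_iter: int = 1000
    loglik_tol: float = 1e-6
    param_bound_eps: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_survivors > self.n_starts:
            raise ValueError("n_survivors cannot exceed n_starts")
        if self.loglik_tol <= 0:
            raise ValueError("loglik_tol must be positive")
        if self.param_bound_eps < 0:
            raise ValueError("param_bound_eps must be nonnegative")


@dataclass
class FitResult:
    """Estimates, posteriors and diagnostics of one fitted model."""

    item_params: list[ItemParams]
    class_proportions: np.ndarray
    posterior: np.ndarray
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    best_start_id: int
    profiles: np.ndarray


def _log_bernoulli(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.clip(table, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return np.log(p), np.log1p(-p)


def _pattern_loglik(
    xu: np.ndarray, table: np.ndarray, class_props: np.ndarray
) -> np.ndarray:
    """U x C joint log density log pi_c + log P(pattern | class)."""
    logp, log1mp = _log_bernoulli(table)
    ll = xu @ logp + (1 - xu) @ log1mp  # U x C
    return ll + np.log(np.clip(class_props, PROB_FLOOR, None))


def marginal_loglik(
    data: np.ndarray,
    item_params: list[ItemParams],
    class_proportions: np.ndarray,
    qmatrix: QMatrix,
    model_spec: np.ndarray,
    profiles: np.ndarray | None = None,
) -> float:
    """Observed-data mixture log-likelihood."""
    from .models import probability_table

    if profiles is None:
        profiles = enumerate_profiles(qmatrix.n_attributes)
    table = probability_table(item_params, qmatrix, model_spec, profiles)
    joint = _pattern_loglik(np.asarray(data, dtype=float), table, class_proportions)
    return float(logsumexp(joint, axis=1).sum())


def e_step(
    data: np.ndarray,
    item_params: list[ItemParams],
    class_proportions: np.ndarray,
    qmatrix: QMatrix,
    model_spec: np.ndarray,
    profiles: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior class membership probabilities, one row per respondent."""
    from .models import probability_table

    if profiles is None:
        profiles = enumerate_profiles(qmatrix.n_attributes)
    table = probability_table(item_params, qmatrix, model_spec, profiles)
    joint = _pattern_loglik(np.asarray(data, dtype=float), table, class_proportions)
    return np.exp(joint - logsumexp(joint, axis=1, keepdims=True))


def m_step_structural(posterior: np.ndarray, weights: np.ndarray | None = None):
    """Saturated structural model: class proportions = weighted posterior means."""
    posterior = np.asarray(posterior, dtype=float)
    if weights is None:
        props = posterior.mean(axis=0)
    else:
        props = weights @ posterior / weights.sum()
    return props / props.sum()


def _neg_expected_loglik(values, design, successes, trials):
    kern = np.clip(design @ values, -35, 35)
    f = successes @ kern - trials @ np.logaddexp(0.0, kern)
    grad = design.T @ (successes - trials * expit(kern))
    return -f, -grad


def _item_constraints(families, eps):
    """Box bounds plus linear order constraints for one item's parameters."""
    bounds, constraints = [], []
    fam = list(families)
    for j, f in enumerate(fam):
        if f in ("main", "e_param"):
            bounds.append((eps, _PARAM_CAP))
        else:
            bounds.append((-_PARAM_CAP, _PARAM_CAP))
    if "interaction" in fam:
        j_int = fam.index("interaction")
        for j, f in enumerate(fam):
            if f == "main":
                a = np.zeros(len(fam))
                a[j_int] = 1.0
                a[j] = 1.0
                constraints.append(
                    {"type": "ineq", "fun": (lambda v, a=a: a @ v - eps),
                     "jac": (lambda v, a=a: a)}
                )
    return bounds, constraints


def _violates(values, families, eps):
    fam = list(families)
    for j, f in enumerate(fam):
        if f in ("main", "e_param") and values[j] < eps:
            return True
        if abs(values[j]) > _PARAM_CAP:
            return True
    if "interaction" in fam:
        j_int = fam.index("interaction")
        for j, f in enumerate(fam):
            if f == "main" and values[j_int] + values[j] < eps:
                return True
    return False


def _newton_item(design, successes, trials, x0):
    """Damped Newton on the concave expected complete-data log-likelihood."""
    vals = np.asarray(x0, dtype=float).copy()
    f, _ = _neg_expected_loglik(vals, design, successes, trials)
    for _ in range(60):
        kern = np.clip(design @ vals, -35, 35)
        p = expit(kern)
        grad = design.T @ (successes - trials * p)
        w = trials * p * (1 - p)
        hess = (design * w[:, None]).T @ design
        hess += 1e-10 * np.eye(len(vals))
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # step halving on the (negated) objective
        t = 1.0
        for _ in range(30):
            cand = vals + t * step
            f_new, _ = _neg_expected_loglik(cand, design, successes, trials)
            if f_new <= f:
                break
            t *= 0.5
        else:
            break
        moved = t * np.max(np.abs(step))
        vals, f = cand, f_new
        if moved < 1e-9:
            break
    return vals


def m_step_item(
    expected_counts: tuple[np.ndarray, np.ndarray],
    qrow: np.ndarray,
    model_type: str,
    profiles: np.ndarray,
    eps: float = 1e-4,
    x0: np.ndarray | None = None,
) -> ItemParams:
    """Constrained maximizer of one item's expected complete-data log-likelihood.

    ``expected_counts`` is (successes, trials) per latent class.  Degenerate
    counts (no class weight anywhere) return the warm-start parameters.
    """
    successes, trials = (np.asarray(a, dtype=float) for a in expected_counts)
    names, fams = item_term_structure(qrow, model_type)
    design = item_design_matrix(qrow, model_type, profiles)
    if x0 is None:
        x0 = np.zeros(len(names))
        x0[0] = -0.5
        x0[1:] = 1.0
    if trials.sum() <= 0:
        return ItemParams(model_type, np.asarray(x0, float), names, fams)
    vals = _newton_item(design, successes, trials, x0)
    if _violates(vals, fams, eps):
        bounds, constraints = _item_constraints(fams, eps)
        start = np.clip(vals, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            _neg_expected_loglik,
            start,
            args=(design, successes, trials),
            jac=True,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        vals = res.x if res.success or np.all(np.isfinite(res.x)) else start
        # final projection in case SLSQP leaves a microscopic violation
        for j, f in enumerate(fams):
            if f in ("main", "e_param"):
                vals[j] = max(vals[j], eps)
    return ItemParams(model_type, vals, names, fams)


def _random_start(qmatrix, model_spec, profiles, rng):
    params = []
    for i in range(qmatrix.n_items):
        names, fams = item_term_structure(qmatrix.entries[i], model_spec[i])
        vals = np.empty(len(names))
        vals[0] = rng.uniform(-2.0, 0.0)
        for j, f in enumerate(fams[1:], start=1):
            if f == "interaction":
                vals[j] = rng.uniform(-0.5, 0.5)
            else:
                vals[j] = rng.uniform(0.5, 3.0)
        params.append(ItemParams(model_spec[i], vals, names, fams))
    props = rng.dirichlet(np.ones(profiles.shape[0]))
    return params, props


def _prob_table_fast(item_params, designs):
    k = len(item_params)
    table = np.empty((k, designs[0].shape[0]))
    for i in range(k):
        table[i] = expit(np.clip(designs[i] @ item_params[i].values, -35, 35))
    return table


def _em_run(
    xu, counts, qmatrix, model_spec, profiles, designs, params, props, n_iter, tol, eps
):
    """EM iterations on deduplicated patterns; returns updated state and trace."""
    n = counts.sum()
    xu_w = xu * counts[:, None]
    trace = []
    converged = False
    post = None
    for _ in range(n_iter):
        table = _prob_table_fast(params, designs)
        joint = _pattern_loglik(xu, table, props)
        ll_u = logsumexp(joint, axis=1)
        ll = float(counts @ ll_u)
        post = np.exp(joint - ll_u[:, None])
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        trials = counts @ post  # per-class expected trials (same for every item)
        succ = xu_w.T @ post  # k x C expected successes
        props = np.clip(trials / n, PROB_FLOOR, None)
        props = props / props.sum()
        params = [
            m_step_item(
                (succ[i], trials),
                qmatrix.entries[i],
                model_spec[i],
                profiles,
                eps=eps,
                x0=params[i].values,
            )
            for i in range(qmatrix.n_items)
        ]
    return params, props, post, np.array(trace), converged


def em_fit(
    data,
    qmatrix: QMatrix,
    model_spec: np.ndarray,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Best-of-multi-start constrained EM fit.

    ``data`` may be a DatasetBundle or an N x k binary matrix.
    """
    responses = getattr(data, "responses", data)
    x = np.asarray(responses, dtype=float)
    if x.ndim != 2 or not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("data must be an N x k binary matrix")
    if x.shape[1] != qmatrix.n_items:
        raise ValueError("data width must match the Q-matrix item count")
    profiles = enumerate_profiles(qmatrix.n_attributes)
    designs = [
        item_design_matrix(qmatrix.entries[i], model_spec[i], profiles)
        for i in range(qmatrix.n_items)
    ]
    xu, inverse, counts = np.unique(
        x, axis=0, return_inverse=True, return_counts=True
    )
    counts = counts.astype(float)
    rng = np.random.default_rng(config.seed)
    eps = config.param_bound_eps

    # stage 1: short runs from every random start
    stage1 = []
    for start_id in range(config.n_starts):
        params, props = _random_start(qmatrix, model_spec, profiles, rng)
        params, props, _, trace, _ = _em_run(
            xu, counts, qmatrix, model_spec, profiles, designs,
            params, props, config.short_iters, config.loglik_tol, eps,
        )
        stage1.append((trace[-1], start_id, params, props, len(trace)))

    # stage 2: run the survivors to convergence
    stage1.sort(key=lambda t: -t[0])
    best = None
    for ll0, start_id, params, props, used in stage1[: config.n_survivors]:
        params, props, post, trace, conv = _em_run(
            xu, counts, qmatrix, model_spec, profiles, designs,
            params, props, config.max_iter, config.loglik_tol, eps,
        )
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], start_id, params, props, post, trace, conv)

    ll, start_id, params, props, post, trace, conv = best
    return FitResult(
        item_params=params,
        class_proportions=props,
        posterior=post[inverse],
        loglik=float(ll),
        loglik_trace=trace,
        converged=bool(conv),
        n_iter=len(trace),
        best_start_id=start_id,
        profiles=profiles,
    )


def classify(
    fit: FitResult, profiles: np.ndarray | None = None, method: str = "modal"
):
    """Attribute classification from the posterior.

    ``modal`` assigns each respondent the profile of the maximum-posterior
    class (ties broken toward the lowest class index and flagged); ``eap``
    thresholds the marginal posterior mastery probability at 0.5.
    Returns (profiles N x A, class_ids, tie_flags).
    """
    if profiles is None:
        profiles = fit.profiles
    post = fit.posterior
    if method == "modal":
        class_ids = post.argmax(axis=1)
        best = post[np.arange(post.shape[0]), class_ids]
        ties = (np.isclose(post, best[:, None])).sum(axis=1) > 1
        return profiles[class_ids], class_ids, ties
    if method == "eap":
        marg = post @ profiles
        est = (marg > 0.5).astype(np.int8)
        class_ids = post.argmax(axis=1)
        return est, class_ids, np.zeros(post.shape[0], dtype=bool)
    raise ValueError("method must be 'modal' or 'eap'")
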