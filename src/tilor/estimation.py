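"""Penalized maximum likelihood for the threshold index logistic model.

The objective is non-differentiable in the index vectors and thresholds
(the regime indicator switches discontinuously), so the final refinement
uses the downhill simplex (Nelder-Mead), which tolerates the kinks.  The
surface is also severely multi-modal in the index directions; purely
random simplex restarts land in spurious basins, so each restart is first
carried through a smoothing homotopy — the regime indicator is replaced
by a logistic ramp of bandwidth h, the smoothed likelihood is maximized
with L-BFGS-B, and h is shrunk stepwise toward zero with warm starts —
before the exact objective is polished by the simplex.  Smoothing the
transition is the standard estimation device for threshold-type
regressions; here it only supplies starting values, the reported optimum
always comes from the exact (unsmoothed) objective.

Estimation is carried out over a compact parameter box (regime
coefficients bounded, thresholds confined to the attainable index range):
the threshold link can otherwise manufacture quasi-separated subgroups
whose coefficients diverge.  Uncertainty comes from a parametric
bootstrap: responses are resimulated from the fitted model at the
observed genotypes and the model refitted, warm-started at the original
estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .model import (
    DegenerateDataError,
    FitConfig,
    GenotypeMatrix,
    ThresholdLinkParams,
    TILoRParams,
    align_to,
    canonicalize,
    case_probability,
    log_likelihood,
    n_parameters,
    pack_params,
    unpack_params,
    PROB_CLIP,
)

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "BootstrapConfig", "fit_mle", "bootstrap_sd"]

#: index-coordinate box; unit-norm vectors live well inside it
INDEX_BOUND = 1.5


@dataclass
class FitResult:
    """Outcome of a multi-start fit.

    ``theta_hat`` is canonicalized (unit-norm indices, positive leading
    components).  ``objective`` is the penalized objective at the best
    *pre-canonicalization* terminal point; ``loglik`` is the plain
    log-likelihood at ``theta_hat``.
    """

    theta_hat: TILoRParams
    objective: float
    loglik: float
    n_restarts_run: int
    best_restart_index: int
    converged: bool
    seed: int
    restart_objectives: np.ndarray | None = None
    sd: TILoRParams | None = None


@dataclass
class BootstrapConfig:
    n_replicates: int = 100
    perturbation_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if self.perturbation_scale <= 0:
            raise ValueError("perturbation_scale must be positive")


def _check_two_classes(data: GenotypeMatrix) -> None:
    data._require_phenotype()
    if data.phenotype.min() == data.phenotype.max():
        raise DegenerateDataError(
            "phenotype contains a single class; both cases and controls are required"
        )


def _parameter_bounds(p: int, config: FitConfig) -> list[tuple[float, float]]:
    c_bound = 1.0 + np.sqrt(p)
    return (
        [(-INDEX_BOUND, INDEX_BOUND)] * (2 * p)
        + [(-config.coef_bound, config.coef_bound)] * 8
        + [(-c_bound, c_bound)] * 2
    )


def _make_negative_objective(data: GenotypeMatrix, lam: float):
    """Vectorized -(loglik - penalty) on the packed parameter vector."""
    X = np.asarray(data.genotypes, dtype=float)
    y = np.asarray(data.phenotype, dtype=float)
    p = X.shape[1]

    def neg(vec: np.ndarray) -> float:
        a = vec[:p]
        b = vec[p : 2 * p]
        u1 = X @ a
        u2 = X @ b
        c1, c2 = vec[-2], vec[-1]
        l1 = vec[2 * p : 2 * p + 4]
        l2 = vec[2 * p + 4 : 2 * p + 8]
        eta = np.where(u1 <= c1, l1[0] + l1[1] * u1, l1[2] + l1[3] * u1)
        eta += np.where(u2 <= c2, l2[0] + l2[1] * u2, l2[2] + l2[3] * u2)
        prob = np.clip(expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)
        ll = y @ np.log(prob) + (1.0 - y) @ np.log(1.0 - prob)
        pen = (np.sqrt(a @ a) - 1.0) ** 2 + (np.sqrt(b @ b) - 1.0) ** 2
        return -(ll - lam * pen)

    return neg


def _make_smoothed_neg_grad(data: GenotypeMatrix, lam: float, h: float):
    """Smoothed objective (indicator -> logistic ramp of bandwidth h) with
    its analytic gradient, for the homotopy stage."""
    X = np.asarray(data.genotypes, dtype=float)
    y = np.asarray(data.phenotype, dtype=float)
    p = X.shape[1]

    def neg_grad(z: np.ndarray):
        a = z[:p]
        b = z[p : 2 * p]
        l1 = z[2 * p : 2 * p + 4]
        l2 = z[2 * p + 4 : 2 * p + 8]
        c1, c2 = z[-2], z[-1]
        u1 = X @ a
        u2 = X @ b
        s1 = expit((c1 - u1) / h)
        s2 = expit((c2 - u2) / h)
        g1lo = l1[0] + l1[1] * u1
        g1hi = l1[2] + l1[3] * u1
        g2lo = l2[0] + l2[1] * u2
        g2hi = l2[2] + l2[3] * u2
        eta = s1 * g1lo + (1 - s1) * g1hi + s2 * g2lo + (1 - s2) * g2hi
        mu = np.clip(expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)
        ll = y @ np.log(mu) + (1 - y) @ np.log(1 - mu)
        na = np.linalg.norm(a)
        nb = np.linalg.norm(b)
        f = -(ll - lam * ((na - 1.0) ** 2 + (nb - 1.0) ** 2))

        r = y - mu  # d loglik / d eta
        ds1 = s1 * (1 - s1) / h  # d s1 / d c1 (and -d s1 / d u1)
        ds2 = s2 * (1 - s2) / h
        deta_du1 = s1 * l1[1] + (1 - s1) * l1[3] - ds1 * (g1lo - g1hi)
        deta_du2 = s2 * l2[1] + (1 - s2) * l2[3] - ds2 * (g2lo - g2hi)
        ga = X.T @ (r * deta_du1) - 2 * lam * (na - 1.0) * a / max(na, 1e-12)
        gb = X.T @ (r * deta_du2) - 2 * lam * (nb - 1.0) * b / max(nb, 1e-12)
        gl1 = np.array([r @ s1, r @ (s1 * u1), r @ (1 - s1), r @ ((1 - s1) * u1)])
        gl2 = np.array([r @ s2, r @ (s2 * u2), r @ (1 - s2), r @ ((1 - s2) * u2)])
        gc1 = r @ (ds1 * (g1lo - g1hi))
        gc2 = r @ (ds2 * (g2lo - g2hi))
        return f, -np.r_[ga, gb, gl1, gl2, gc1, gc2]

    return neg_grad


def _simplex(neg, x0: np.ndarray, config: FitConfig, bounds=None):
    return minimize(
        neg,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={
            "maxiter": config.max_iterations,
            "maxfev": 2 * config.max_iterations,
            "fatol": config.simplex_tolerance,
            "xatol": 1e-8,
            "adaptive": True,
        },
    )


def _polished(neg, x0: np.ndarray, config: FitConfig, bounds):
    """Iterated simplex reruns from the incumbent until the objective stalls."""
    x = x0
    prev = np.inf
    res = None
    for _ in range(max(config.polish_rounds, 1)):
        res = _simplex(neg, x, config, bounds)
        x = res.x
        if prev - res.fun < max(config.simplex_tolerance, 1e-7):
            break
        prev = res.fun
    return res


def _random_start(
    rng: np.random.Generator, data: GenotypeMatrix, config: FitConfig
) -> np.ndarray:
    """Random initial vector: coordinates uniform on ±init_scale, index
    blocks normalized, thresholds placed at a random central quantile of
    the start's own index values (a far-off threshold empties a regime and
    strands the search)."""
    p = data.p
    X = np.asarray(data.genotypes, dtype=float)
    vec = rng.uniform(-config.init_scale, config.init_scale, size=n_parameters(p))
    for sl in (slice(0, p), slice(p, 2 * p)):
        nrm = np.linalg.norm(vec[sl])
        if nrm < 1e-12:  # essentially impossible, but keep the start valid
            vec[sl][0] = 1.0
            nrm = 1.0
        vec[sl] /= nrm
    vec[-2] = np.quantile(X @ vec[:p], rng.uniform(0.2, 0.8))
    vec[-1] = np.quantile(X @ vec[p : 2 * p], rng.uniform(0.2, 0.8))
    return vec


def fit_mle(
    data: GenotypeMatrix,
    config: FitConfig | None = None,
    extra_initials: Sequence[TILoRParams] | None = None,
) -> FitResult:
    """Maximize the penalized log-likelihood by homotopy-started multi-start
    downhill simplex.

    Each of ``n_restarts`` random starting vectors is first refined on the
    smoothed surrogate surface (L-BFGS-B over the shrinking bandwidths in
    ``smooth_bandwidths``); ``extra_initials`` join the candidate pool
    as-is (used e.g. to inject a previous estimate).  All candidates are
    ranked by the exact objective and the best is polished by iterated
    bounded Nelder-Mead runs, then canonicalized.  Deterministic given
    ``config.seed``.
    """
    if config is None:
        config = FitConfig()
    _check_two_classes(data)
    p = data.p
    if p < 2:
        raise DegenerateDataError("at least 2 SNP columns are required")

    lam = config.penalty_weight
    neg = _make_negative_objective(data, lam)
    bounds = _parameter_bounds(p, config)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(config.seed)

    smoothed = [
        _make_smoothed_neg_grad(data, lam, h) for h in config.smooth_bandwidths
    ]
    candidates: list[np.ndarray] = []
    for _ in range(config.n_restarts):
        z = _random_start(rng, data, config)
        for fg in smoothed:
            z = minimize(
                fg,
                z,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": config.gradient_iterations},
            ).x
        candidates.append(z)
    if extra_initials is not None:
        candidates += [np.clip(pack_params(t), lo, hi) for t in extra_initials]

    exact = np.array([neg(z) for z in candidates])
    best_idx = int(np.argmin(exact))
    res = _polished(neg, candidates[best_idx], config, bounds)
    moved = res.fun < exact[best_idx] + 1e-12

    theta_hat = canonicalize(unpack_params(res.x, p))
    if not moved:
        logger.warning("simplex polishing did not improve on its starting point")
    return FitResult(
        theta_hat=theta_hat,
        objective=float(-res.fun),
        loglik=log_likelihood(theta_hat, data),
        n_restarts_run=len(candidates),
        best_restart_index=best_idx,
        converged=bool(moved or res.success),
        seed=config.seed,
        restart_objectives=-exact,
    )


def _sd_over_replicates(estimates: np.ndarray) -> np.ndarray:
    """Componentwise sample sd (divisor B-1) around the replicate mean."""
    if estimates.shape[0] < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    return np.std(estimates, axis=0, ddof=1)


def bootstrap_sd(
    theta_hat: TILoRParams,
    data: GenotypeMatrix,
    config: BootstrapConfig | None = None,
    fit_config: FitConfig | None = None,
) -> TILoRParams:
    """Parametric-bootstrap standard deviations of the parameter estimates.

    For each of B replicates, responses y* are drawn Bernoulli with
    probabilities from the fitted model at the *original* genotypes, and
    the model is refitted by iterated simplex runs warm-started at
    ``theta_hat`` plus uniform jitter of size ``perturbation_scale``.  A
    replicate whose simulated phenotype is single-class is redrawn up to 10
    times, then skipped with a warning.  Returns per-parameter sds with
    divisor B-1, in a parameter container of the same shape as
    ``theta_hat``.
    """
    if config is None:
        config = BootstrapConfig()
    if fit_config is None:
        fit_config = FitConfig()
    _check_two_classes(data)

    X = data.genotypes
    p_hat = case_probability(theta_hat, X)
    rng = np.random.default_rng(config.seed)
    base = pack_params(theta_hat)
    bounds = _parameter_bounds(data.p, fit_config)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    estimates = []
    n_skipped = 0
    for b in range(config.n_replicates):
        y_star = None
        for _attempt in range(10):
            draw = (rng.random(data.n) < p_hat).astype(int)
            if 0 < draw.sum() < data.n:
                y_star = draw
                break
        if y_star is None:
            n_skipped += 1
            warnings.warn(
                f"bootstrap replicate {b}: simulated phenotype single-class "
                "after 10 redraws; replicate skipped"
            )
            continue
        boot = GenotypeMatrix(X, y_star, list(data.snp_ids), list(data.subject_ids))
        neg = _make_negative_objective(boot, fit_config.penalty_weight)
        x0 = np.clip(
            base
            + rng.uniform(
                -config.perturbation_scale, config.perturbation_scale, size=base.size
            ),
            lo,
            hi,
        )
        res = _polished(neg, x0, fit_config, bounds)
        theta_b = align_to(canonicalize(unpack_params(res.x, data.p)), theta_hat)
        estimates.append(pack_params(theta_b))

    if len(estimates) < 2:
        raise DegenerateDataError(
            "fewer than 2 usable bootstrap replicates; cannot estimate sds"
        )
    if n_skipped:
        logger.warning("bootstrap: skipped %d degenerate replicates", n_skipped)
    sd_vec = _sd_over_replicates(np.asarray(estimates))
    p = data.p
    return TILoRParams(
        sd_vec[:p],
        sd_vec[p : 2 * p],
        ThresholdLinkParams(*sd_vec[2 * p : 2 * p + 4], sd_vec[-2]),
        ThresholdLinkParams(*sd_vec[2 * p + 4 : 2 * p + 8], sd_vec[-1]),
    )
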