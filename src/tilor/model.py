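"""Core of the additive threshold index logistic regression (A-TILoR) model.

The model describes the case probability in a case-control study with
``p`` categorical SNP regressors ``x`` (coded 0/1/2 copies of the variant
allele) as

    P(Y = 1 | x) = logistic( g1(alpha' x) + g2(beta' x) ),

where ``alpha`` and ``beta`` are unit-norm index vectors whose first
nonzero components are positive (identifiability), and each link ``g_k``
is a two-regime ("threshold") affine function

    g_k(u) = b_k1 + b_k2 * u   if u <= c_k,
             b_k3 + b_k4 * u   if u >  c_k,

with an unknown threshold ``c_k``.  The index alpha' x aggregates many
small per-SNP effects into one regime variable; the link lets the joint
effect change qualitatively once the index crosses the threshold.

This module holds the parameter containers, probability / likelihood
evaluation, the norm-penalized objective used by the optimizer, and the
canonicalization that maps any parameter vector onto the identifiable
representative of its equivalence class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "GenotypeMatrix",
    "ThresholdLinkParams",
    "TILoRParams",
    "FitConfig",
    "DegenerateParameterError",
    "DegenerateDataError",
    "eval_threshold_link",
    "case_probability",
    "log_likelihood",
    "penalized_objective",
    "canonicalize",
    "align_to",
    "below_threshold_fractions",
    "pack_params",
    "unpack_params",
    "n_parameters",
    "parameter_names",
]

#: probabilities are kept this far from {0, 1} before taking logs
PROB_CLIP = 1e-12


class DegenerateParameterError(ValueError):
    """Raised for parameter vectors outside the model class (e.g. a zero index)."""


class DegenerateDataError(ValueError):
    """Raised when the data cannot support estimation (e.g. one phenotype class)."""


@dataclass
class GenotypeMatrix:
    """Case-control genotype data: subjects × SNPs plus a binary phenotype.

    Parameters
    ----------
    genotypes : (n, p) integer array with entries in {0, 1, 2}
        Copies of the variant allele per subject and SNP.
    phenotype : (n,) integer array with entries in {0, 1}, or None
        1 = case, 0 = control.  May be None for covariate-only data
        (e.g. freshly simulated genotypes awaiting a phenotype).
    snp_ids : list of str, optional
        Unique marker names; defaults to ``SNP1..SNPp``.
    subject_ids : list of str, optional
        Defaults to ``S1..Sn``.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray | None = None
    snp_ids: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2 or g.shape[0] < 1 or g.shape[1] < 1:
            raise ValueError("genotypes must be a non-empty 2-D matrix")
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("genotype entries must all be in {0, 1, 2}")
        self.genotypes = g.astype(np.int64, copy=False)
        n, p = g.shape
        if self.phenotype is not None:
            y = np.asarray(self.phenotype)
            if y.shape != (n,):
                raise ValueError(f"phenotype length {y.shape} does not match n={n}")
            if not np.isin(y, (0, 1)).all():
                raise ValueError("phenotype entries must all be in {0, 1}")
            self.phenotype = y.astype(np.int64, copy=False)
        if not self.snp_ids:
            self.snp_ids = [f"SNP{j + 1}" for j in range(p)]
        if len(self.snp_ids) != p:
            raise ValueError("snp_ids length does not match number of SNP columns")
        if len(set(self.snp_ids)) != p:
            raise ValueError("snp_ids must be unique")
        if not self.subject_ids:
            self.subject_ids = [f"S{i + 1}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match number of rows")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def p(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        self._require_phenotype()
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        self._require_phenotype()
        return int(self.n - self.phenotype.sum())

    def _require_phenotype(self) -> None:
        if self.phenotype is None:
            raise ValueError("phenotype has not been set")


@dataclass
class ThresholdLinkParams:
    """Coefficients of one two-regime affine link g(u).

    ``(b1, b2)`` are the intercept and slope below (and at) the threshold
    ``c``; ``(b3, b4)`` apply above it.  Continuity at ``c`` is not imposed.
    """

    b1: float
    b2: float
    b3: float
    b4: float
    c: float

    def __post_init__(self) -> None:
        vals = (self.b1, self.b2, self.b3, self.b4, self.c)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all link coefficients and the threshold must be finite")
        self.b1, self.b2, self.b3, self.b4, self.c = (float(v) for v in vals)

    def as_array(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3, self.b4], dtype=float)


@dataclass
class TILoRParams:
    """Full A-TILoR parameter vector: two index directions and two links."""

    alpha: np.ndarray
    beta: np.ndarray
    g1: ThresholdLinkParams
    g2: ThresholdLinkParams

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have the same length")
        if self.alpha.size < 1:
            raise ValueError("index vectors must be non-empty")
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.beta).all()):
            raise ValueError("index vectors must be finite")

    @property
    def p(self) -> int:
        return self.alpha.size

    def copy(self) -> "TILoRParams":
        return TILoRParams(
            self.alpha.copy(), self.beta.copy(), replace(self.g1), replace(self.g2)
        )


@dataclass
class FitConfig:
    """Controls for the multi-start downhill-simplex maximization.

    ``penalty_weight`` is the weight λ on the quadratic unit-norm penalty
    λ(‖alpha‖−1)² + λ(‖beta‖−1)² that replaces the exact constraint during
    optimization; the optimum is renormalized exactly afterwards.

    ``smooth_bandwidths`` is the shrinking sequence of transition
    bandwidths used by the gradient homotopy that turns each random restart
    into a well-placed simplex start (``gradient_iterations`` L-BFGS-B
    steps per bandwidth); ``coef_bound`` bounds each regime coefficient
    (compact parameter space — the threshold link can otherwise isolate
    quasi-separated subgroups with divergent coefficients); and
    ``polish_rounds`` caps the repeated simplex reruns from the incumbent.
    """

    n_restarts: int = 50
    penalty_weight: float = 1e3
    max_iterations: int = 20000
    simplex_tolerance: float = 1e-9
    seed: int = 0
    init_scale: float = 0.5
    smooth_bandwidths: tuple[float, ...] = (0.5, 0.2, 0.08)
    gradient_iterations: int = 250
    coef_bound: float = 4.0
    polish_rounds: int = 6

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be positive")
        if self.penalty_weight <= 0:
            raise ValueError("penalty_weight must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.simplex_tolerance <= 0:
            raise ValueError("simplex_tolerance must be positive")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be positive")
        if self.gradient_iterations < 0 or self.polish_rounds < 0:
            raise ValueError("gradient_iterations and polish_rounds must be nonnegative")
        if self.coef_bound <= 0 or any(h <= 0 for h in self.smooth_bandwidths):
            raise ValueError("coef_bound and smoothing bandwidths must be positive")


# ---------------------------------------------------------------------------
# parameter vector packing (layout: alpha, beta, b11..b14, b21..b24, c1, c2)
# ---------------------------------------------------------------------------

def n_parameters(p: int) -> int:
    """Dimension of the packed parameter vector for p SNPs."""
    return 2 * p + 10


def pack_params(theta: TILoRParams) -> np.ndarray:
    return np.concatenate(
        [
            theta.alpha,
            theta.beta,
            theta.g1.as_array(),
            theta.g2.as_array(),
            [theta.g1.c, theta.g2.c],
        ]
    )


def unpack_params(vec: np.ndarray, p: int) -> TILoRParams:
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size != n_parameters(p):
        raise ValueError(f"expected vector of length {n_parameters(p)}, got {vec.size}")
    a = vec[:p]
    b = vec[p : 2 * p]
    l1 = vec[2 * p : 2 * p + 4]
    l2 = vec[2 * p + 4 : 2 * p + 8]
    return TILoRParams(
        a.copy(),
        b.copy(),
        ThresholdLinkParams(*l1, vec[-2]),
        ThresholdLinkParams(*l2, vec[-1]),
    )


def parameter_names(p: int, snp_ids: list[str] | None = None) -> list[str]:
    """Names of the packed coordinates, e.g. alpha[rs123], b12, c2."""
    if snp_ids is None:
        snp_ids = [f"{j + 1}" for j in range(p)]
    names = [f"alpha[{s}]" for s in snp_ids] + [f"beta[{s}]" for s in snp_ids]
    names += [f"b1{i}" for i in range(1, 5)] + [f"b2{i}" for i in range(1, 5)]
    names += ["c1", "c2"]
    return names


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def eval_threshold_link(params: ThresholdLinkParams, u):
    """Evaluate the two-regime link g(u); u = c belongs to the lower regime."""
    u = np.asarray(u, dtype=float)
    if not np.isfinite(u).all():
        raise ValueError("link argument u must be finite")
    out = np.where(u <= params.c, params.b1 + params.b2 * u, params.b3 + params.b4 * u)
    return float(out) if out.ndim == 0 else out


def _linear_predictor(theta: TILoRParams, X: np.ndarray) -> np.ndarray:
    u1 = X @ theta.alpha
    u2 = X @ theta.beta
    return eval_threshold_link(theta.g1, u1) + eval_threshold_link(theta.g2, u2)


def case_probability(theta: TILoRParams, x):
    """P(Y=1 | x) under the model, for one genotype vector or a matrix of them."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != theta.p:
        raise ValueError(f"genotype vector length {X.shape[1]} != p={theta.p}")
    prob = expit(_linear_predictor(theta, X))
    return float(prob[0]) if single else prob


def log_likelihood(theta: TILoRParams, data: GenotypeMatrix) -> float:
    """Bernoulli log-likelihood Σ yᵢ ln pᵢ + (1−yᵢ) ln(1−pᵢ).

    Probabilities are clipped to [1e-12, 1 − 1e-12] before the logs so the
    value stays finite under complete separation.
    """
    data._require_phenotype()
    if data.n < 1:
        raise ValueError("data is empty")
    prob = case_probability(theta, data.genotypes)
    prob = np.clip(prob, PROB_CLIP, 1.0 - PROB_CLIP)
    y = data.phenotype
    return float(y @ np.log(prob) + (1 - y) @ np.log(1.0 - prob))


def penalized_objective(
    theta: TILoRParams, data: GenotypeMatrix, penalty_weight: float
) -> float:
    """Log-likelihood minus λ(‖alpha‖−1)² + λ(‖beta‖−1)².

    Equals the log-likelihood exactly on the constraint set (unit-norm
    indices); elsewhere it is strictly smaller.
    """
    if penalty_weight <= 0:
        raise ValueError("penalty_weight must be positive")
    pen = (np.linalg.norm(theta.alpha) - 1.0) ** 2
    pen += (np.linalg.norm(theta.beta) - 1.0) ** 2
    return log_likelihood(theta, data) - penalty_weight * pen


# ---------------------------------------------------------------------------
# identifiability
# ---------------------------------------------------------------------------

def _canonicalize_one(
    v: np.ndarray, link: ThresholdLinkParams
) -> tuple[np.ndarray, ThresholdLinkParams]:
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise DegenerateParameterError("index vector has zero norm")
    nz = np.nonzero(v)[0]
    lead = v[nz[0]]
    s = norm if lead > 0 else -norm
    v_new = v / s
    if s > 0:
        link_new = ThresholdLinkParams(
            link.b1, s * link.b2, link.b3, s * link.b4, link.c / s
        )
    else:
        # dividing the index by s < 0 reverses the order of u, so the two
        # regimes swap and the threshold flips sign (scaled)
        link_new = ThresholdLinkParams(
            link.b3, s * link.b4, link.b1, s * link.b2, link.c / s
        )
    return v_new, link_new


def canonicalize(theta: TILoRParams) -> TILoRParams:
    """Map theta to the identifiable representative of its equivalence class.

    The returned parameters satisfy ‖alpha‖ = ‖beta‖ = 1 with positive first
    nonzero components, and define the same case probability as the input at
    every genotype vector (up to the measure-zero threshold boundary when a
    sign flip swaps the regimes of a discontinuous link).
    """
    a, g1 = _canonicalize_one(theta.alpha, theta.g1)
    b, g2 = _canonicalize_one(theta.beta, theta.g2)
    return TILoRParams(a, b, g1, g2)


def _mirror_link(link: ThresholdLinkParams) -> ThresholdLinkParams:
    """Link of the sign-flipped index: regimes swap, slopes negate, c flips."""
    return ThresholdLinkParams(link.b3, -link.b4, link.b1, -link.b2, -link.c)


def align_to(theta: TILoRParams, reference: TILoRParams) -> TILoRParams:
    """Pick the representative of theta's equivalence class nearest a reference.

    The additive model is invariant to swapping the two index/link pairs,
    and to flipping the sign of either index while mirroring its link.  The
    leading-sign canonicalization rule resolves the flip through the first
    nonzero component, which in finite samples is driven by noise whenever
    the corresponding true loading is near zero — so for error summaries
    against a known truth (and for pooling bootstrap replicates) all eight
    swap/flip representatives are considered and the one with the smallest
    total index-vector distance to the reference is returned.
    """
    pairs = [
        (theta.alpha, theta.g1, theta.beta, theta.g2),
        (theta.beta, theta.g2, theta.alpha, theta.g1),  # label swap
    ]
    best = None
    best_d = np.inf
    for a, g1, b, g2 in pairs:
        for sa in (1.0, -1.0):
            for sb in (1.0, -1.0):
                cand = TILoRParams(
                    sa * a,
                    sb * b,
                    replace(g1) if sa > 0 else _mirror_link(g1),
                    replace(g2) if sb > 0 else _mirror_link(g2),
                )
                d = np.linalg.norm(cand.alpha - reference.alpha) + np.linalg.norm(
                    cand.beta - reference.beta
                )
                if d < best_d:
                    best_d = d
                    best = cand
    return best


def below_threshold_fractions(
    theta: TILoRParams, data: GenotypeMatrix
) -> tuple[float, float]:
    """Empirical P(alpha'x <= c1) and P(beta'x <= c2) over the subjects.

    These are the "how often does each regime index stay below its
    threshold" summaries reported alongside a fit.
    """
    X = np.asarray(data.genotypes, dtype=float)
    u1 = X @ theta.alpha
    u2 = X @ theta.beta
    return float(np.mean(u1 <= theta.g1.c)), float(np.mean(u2 <= theta.g2.c))
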