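"""Group-level inference over subject posteriors.

Two complementary analyses: a classical canonical variates analysis (CVA)
asking whether a receptor-specific parameter set separates diagnostic
groups, and a Bayesian hierarchy (parametric empirical Bayes, PEB) whose
second level places a linear model over subject parameters and whose
reduced models (Bayesian model reduction, BMR) let one *accept the null*
of no group effect parameter by parameter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .inversion import Posterior

__all__ = [
    "GROUP_LABELS",
    "build_design",
    "CVAResult",
    "cva",
    "PEBModel",
    "peb_fit",
    "PEBResult",
    "bmr_search",
    "classify",
]

GROUP_LABELS = ("control", "encephalopathy", "nmdar")


def build_design(groups) -> np.ndarray:
    """Second-level design matrix with nested disease coding.

    Column 1: mean (all ones).  Column 2: encephalopathy indicator — one
    for both encephalopathic and NMDAR-encephalitis subjects.  Column 3:
    NMDAR-encephalitis indicator.  Encephalitis subjects are a subset of
    the encephalopathic coding, so column 3 is nonzero only where column 2
    is.
    """
    X = np.zeros((len(groups), 3))
    X[:, 0] = 1.0
    for i, g in enumerate(groups):
        if g not in GROUP_LABELS:
            raise ValueError(f"unknown group label {g!r}")
        if g in ("encephalopathy", "nmdar"):
            X[i, 1] = 1.0
        if g == "nmdar":
            X[i, 2] = 1.0
    return X


# --------------------------------------------------------------------- #
# canonical variates analysis
# --------------------------------------------------------------------- #
@dataclass
class CVAResult:
    canonical_vectors: np.ndarray      # (p, k) weights over parameters
    canonical_variates: np.ndarray     # (n, k) subject scores
    canonical_correlations: np.ndarray  # (k,)
    chi2: float
    dof: int
    p_value: float


def cva(Y: np.ndarray, X: np.ndarray, subset=None) -> CVAResult:
    """Canonical variates analysis of parameters against group contrasts.

    Finds the unit mixtures of the (column-subset of) parameters ``Y``
    maximally correlated with the explanatory variables ``X``; Bartlett's
    chi-square approximation gives the significance of the canonical
    correlations.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != Y.shape[0]:
        X = X.T
    if subset is not None:
        Y = Y[:, np.asarray(subset, dtype=int)]
    n, p = Y.shape
    q = X.shape[1]
    if n <= p + q:
        raise ValueError(
            f"too few subjects (n={n}) for p={p} parameters and q={q} "
            "contrasts"
        )
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    # drop constant contrast columns (centering annihilates them)
    keep = Xc.std(axis=0) > 1e-12
    Xc = Xc[:, keep]
    q = Xc.shape[1]
    if q == 0:
        raise ValueError("explanatory variables are constant")
    # whiten both blocks via SVD; canonical correlations are the singular
    # values of the cross-covariance of the whitened variables
    Uy, sy, Vty = np.linalg.svd(Yc, full_matrices=False)
    ry = int((sy > 1e-10 * sy[0]).sum())
    Ux, sx, Vtx = np.linalg.svd(Xc, full_matrices=False)
    rx = int((sx > 1e-10 * sx[0]).sum())
    if ry == 0 or rx == 0:
        raise np.linalg.LinAlgError("rank-deficient data in CVA")
    M = Uy[:, :ry].T @ Ux[:, :rx]
    Uc, cc, Vc = np.linalg.svd(M)
    k = min(ry, rx)
    cc = np.clip(cc[:k], 0.0, 1.0)
    # weights over original parameters
    W = Vty[:ry].T @ np.diag(1.0 / sy[:ry]) @ Uc[:, :k]
    variates = Yc @ W
    # Bartlett's approximation on all k roots
    lam = np.prod(1.0 - cc**2)
    lam = max(lam, 1e-300)
    chi2 = -(n - 1 - (p + q + 1) / 2.0) * np.log(lam)
    dof = p * q
    p_value = float(sp_stats.chi2.sf(chi2, dof))
    return CVAResult(W, variates, cc, float(chi2), int(dof), p_value)


def cva_permutation_p(Y, X, subset=None, n_perm: int = 999,
                      seed: int = 0) -> float:
    """Permutation check of the first canonical correlation."""
    rng = np.random.default_rng(seed)
    obs = cva(Y, X, subset).canonical_correlations[0]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(Y).shape[0]:
        X = X.T
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        r = cva(Y, X[perm], subset).canonical_correlations[0]
        count += r >= obs
    return count / (n_perm + 1)


# --------------------------------------------------------------------- #
# parametric empirical Bayes
# --------------------------------------------------------------------- #
@dataclass
class PEBModel:
    """Fitted second-level model.

    The hierarchy is  theta_i ~ N(X_i beta, Sigma_i + Q)  with known
    first-level posterior covariances Sigma_i, diagonal between-subject
    covariance Q, and Gaussian prior beta ~ N(0, prior_var I).  Everything
    is jointly Gaussian, so the beta posterior and the model log evidence
    (free energy) are exact.
    """

    beta_mean: np.ndarray          # (q * p,) ordered covariate-major
    beta_cov: np.ndarray
    free_energy: float
    design: np.ndarray             # (n, q)
    labels: tuple
    prior_var: float
    q_diag: np.ndarray             # between-subject variances (p,)
    n_params: int

    def effect(self, covariate: int) -> np.ndarray:
        p = self.n_params
        return self.beta_mean[covariate * p:(covariate + 1) * p]


def _peb_evidence(theta, covs, X, prior_var, q_diag):
    """Exact log evidence and beta posterior of the Gaussian hierarchy."""
    n, p = theta.shape
    q = X.shape[1]
    W = [np.linalg.inv(covs[i] + np.diag(q_diag)) for i in range(n)]
    Pb = np.eye(q * p) / prior_var
    g = np.zeros(q * p)
    Lam = Pb.copy()
    for i in range(n):
        xxt = np.outer(X[i], X[i])
        Lam += np.kron(xxt, W[i])
        g += np.kron(X[i], W[i] @ theta[i])
    beta_cov = np.linalg.inv(Lam)
    beta_mean = beta_cov @ g
    # evidence: log N(theta; 0, blockdiag(Sigma_i+Q) + (X (x) I) Vb (X (x) I)^T)
    # computed via the matrix inversion lemma in information form
    quad = 0.0
    logdet = 0.0
    for i in range(n):
        sign, ld = np.linalg.slogdet(covs[i] + np.diag(q_diag))
        logdet += ld
        quad += theta[i] @ W[i] @ theta[i]
    sign, ld_lam = np.linalg.slogdet(Lam)
    logdet += ld_lam + (q * p) * np.log(prior_var)
    quad -= g @ beta_mean
    F = -0.5 * (n * p * np.log(2 * np.pi) + logdet + quad)
    return float(F), beta_mean, beta_cov


def peb_fit(posteriors, design: np.ndarray,
            between_subject_variance_prior: float = 1.0 / 16,
            beta_prior_var: float = 1.0 / 16,
            optimize_q: bool = True) -> PEBModel:
    """Fit the second-level Gaussian hierarchy over subject posteriors.

    ``between_subject_variance_prior`` initializes the diagonal random-
    effects variance; when ``optimize_q`` is set, a shared scale on that
    diagonal is optimized by maximizing the exact model evidence over a
    log-spaced grid (one hyperparameter, as the between-subject covariance
    is a single shared variance per parameter).
    """
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular second-level design")
    labels = tuple(posteriors[0].labels)
    if any(tuple(p.labels) != labels for p in posteriors):
        raise ValueError("posteriors carry different parameter labelings")
    theta = np.stack([p.mean for p in posteriors])
    covs = [p.cov for p in posteriors]
    n, p = theta.shape
    if X.shape[0] != n:
        raise ValueError("design rows != number of subjects")

    base = between_subject_variance_prior * np.ones(p)
    scales = [1.0]
    if optimize_q:
        scales = [0.25, 0.5, 1.0, 2.0, 4.0]
    best = None
    for s in scales:
        F, bm, bc = _peb_evidence(theta, covs, X, beta_prior_var, base * s)
        if best is None or F > best[0]:
            best = (F, bm, bc, base * s)
    F, bm, bc, qd = best
    return PEBModel(bm, bc, F, X, labels, beta_prior_var, qd, p)


# --------------------------------------------------------------------- #
# Bayesian model reduction over second-level effects
# --------------------------------------------------------------------- #
@dataclass
class PEBResult:
    """Pruned second-level effects and per-effect posterior probabilities."""

    effect_probability: dict       # (covariate, label) -> P(effect != 0)
    effect_mean: dict              # (covariate, label) -> BMA effect size
    free_energy_full: float
    free_energy_best: float
    surviving: set = field(default_factory=set)


def _reduced_log_evidence(mu_q, Sq, prior_var_full, prior_var_red):
    """Analytic evidence change when prior variances shrink (zero means).

    For Gaussians with diagonal priors P_full = diag(v), reduced
    P_red = diag(v'), posterior q = N(mu, S):
    dF = 0.5 [ ln|S^-1 + dP| ... ] computed in information form.
    """
    Pq = np.linalg.inv(Sq)
    dP = np.diag(1.0 / prior_var_red - 1.0 / prior_var_full)
    Pr = Pq + dP
    sign, ld_r = np.linalg.slogdet(Pr)
    if sign <= 0:
        return -np.inf
    _, ld_q = np.linalg.slogdet(Pq)
    h = Pq @ mu_q
    mu_r = np.linalg.solve(Pr, h)
    dF = 0.5 * (
        ld_q - ld_r
        + np.sum(np.log(prior_var_full) - np.log(prior_var_red))
        + mu_r @ Pr @ mu_r - mu_q @ Pq @ mu_q
    )
    # note: with zero prior means the quadratic terms reduce to the above
    return float(dF)


def bmr_search(full: PEBModel, covariates=(1, 2), p_threshold: float = 0.95,
               max_exhaustive: int = 8, shrink: float = 1e-8) -> PEBResult:
    """Greedy pruning of second-level effects with exhaustive finish.

    Effects are (covariate, parameter) entries of beta; switching one off
    shrinks its prior variance to ~0 and the reduced evidence follows
    analytically from the full posterior.  Greedy pruning removes the
    effect whose removal most increases the evidence until no removal
    helps; the final <= ``max_exhaustive`` survivors are searched
    exhaustively.  Per-effect probabilities come from Bayesian model
    averaging over every model visited.
    """
    p = full.n_params
    d = full.beta_mean.size
    effects = [
        (c, j) for c in covariates for j in range(p)
    ]
    idx = {e: e[0] * p + e[1] for e in effects}
    v_full = np.full(d, full.prior_var)

    visited: dict[frozenset, float] = {}

    def evidence(off: frozenset) -> float:
        if off in visited:
            return visited[off]
        v_red = v_full.copy()
        for e in off:
            v_red[idx[e]] = shrink * full.prior_var
        dF = _reduced_log_evidence(full.beta_mean, full.beta_cov,
                                   v_full, v_red)
        visited[off] = dF
        return dF

    current: frozenset = frozenset()
    evidence(current)
    remaining = list(effects)
    improved = True
    while improved and remaining:
        improved = False
        scores = []
        for e in remaining:
            scores.append((evidence(current | {e}), e))
        scores.sort(key=lambda t: -t[0])
        best_dF, best_e = scores[0]
        if best_dF > evidence(current):
            current = current | {best_e}
            remaining.remove(best_e)
            improved = True
    survivors = [e for e in effects if e not in current]
    if len(survivors) <= max_exhaustive:
        for r in range(len(survivors) + 1):
            for comb in itertools.combinations(survivors, r):
                evidence(current | set(comb))

    # Bayesian model averaging over visited models
    offs = list(visited.keys())
    logz = np.array([visited[o] for o in offs])
    w = np.exp(logz - logz.max())
    w /= w.sum()
    prob = {}
    eff_mean = {}
    for e in effects:
        on_w = sum(wi for o, wi in zip(offs, w) if e not in o)
        prob[(e[0], full.labels[e[1]])] = float(on_w)
        eff_mean[(e[0], full.labels[e[1]])] = float(
            full.beta_mean[idx[e]] * on_w
        )
    best_off = offs[int(np.argmax(logz))]
    surviving = {
        (e[0], full.labels[e[1]]) for e in effects if e not in best_off
    }
    return PEBResult(
        effect_probability=prob,
        effect_mean=eff_mean,
        free_energy_full=full.free_energy,
        free_energy_best=full.free_energy + float(logz.max()),
        surviving=surviving,
    )


# --------------------------------------------------------------------- #
# individual classification
# --------------------------------------------------------------------- #
def classify(Y: np.ndarray, canonical_vector: np.ndarray, labels,
             positive_label="nmdar", alpha_power=None) -> dict:
    """Project subjects on a canonical axis and threshold at the midpoint
    of the two group means; optionally regress out an alpha-power
    covariate from the scores first.

    Returns predicted labels, accuracy against ``labels``, the scores and
    the threshold used.
    """
    Y = np.asarray(Y, dtype=float)
    w = np.asarray(canonical_vector, dtype=float).ravel()
    if Y.ndim != 2 or Y.shape[1] != w.size:
        raise ValueError("canonical vector does not match parameter dim")
    if Y.shape[0] < 2:
        raise ValueError("need at least two subjects to set a threshold")
    scores = Y @ w
    labels = np.asarray(labels)
    if alpha_power is not None:
        a = np.asarray(alpha_power, dtype=float)
        if a.size != scores.size or np.any(~np.isfinite(a)):
            raise ValueError("alpha power covariate missing or non-finite")
        Z = np.column_stack([np.ones_like(a), a])
        coef, *_ = np.linalg.lstsq(Z, scores, rcond=None)
        scores = scores - Z @ coef
    pos = labels == positive_label
    if pos.all() or (~pos).all():
        raise ValueError("need both classes to define a separation")
    mu_pos, mu_neg = scores[pos].mean(), scores[~pos].mean()
    thresh = 0.5 * (mu_pos + mu_neg)
    sign = 1.0 if mu_pos >= mu_neg else -1.0
    predicted = np.where(sign * (scores - thresh) > 0, positive_label, "other")
    truth = np.where(pos, positive_label, "other")
    acc = float((predicted == truth).mean())
    return {
        "predicted": predicted,
        "accuracy": acc,
        "scores": scores,
        "threshold": float(thresh),
    }
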