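"""Growth mixture models: finite mixtures of polynomial growth curves with
Gaussian random effects, fitted by multistart EM.

Each player contributes a 12-point series y_i over time bins t = 0..11.
Trajectory class k has mean curve X beta_k (polynomial design of degree d)
and players deviate through Gaussian random effects b_i on the intercept and
optionally the slope, shared covariance Psi, plus i.i.d. residual noise:

    y_i | class k  ~  N(X beta_k,  Z Psi Z' + sigma^2 I)

Random effects are marginalized analytically, so the observed-data
log-likelihood is a finite mixture of 12-dimensional Gaussians with a
structured common covariance.  Estimation is EM with the random effects and
class labels as missing data; all M-step updates are closed-form, which
preserves the EM monotonicity guarantee.

Local maxima are handled with a short-run/finalist multistart schedule
(default 400 random starts x 10 EM iterations, full EM on the 50 best), and
a solution is called *stable* when the best final log-likelihood is
replicated by at least one other finalist (|dLL| <= 0.01).  Candidate models
over K are compared by BIC among converged, stable fits.

Internally time is standardized ((t - mean)/sd) to condition the cubic
design; fixed-effect coefficients are reported back on the raw 0..11 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "GrowthSpec",
    "MultistartProtocol",
    "GMMParams",
    "TrajectoryModel",
    "StabilityReport",
    "design_matrices",
    "marginal_loglik",
    "em_fit",
    "multistart_fit",
    "count_gmm_parameters",
    "bic",
    "select_trajectory_model",
    "simulate_growth_mixture",
]

_RE_DESIGNS = {"none": 0, "intercept": 1, "intercept_slope": 2}


@dataclass(frozen=True)
class GrowthSpec:
    """Structure of one growth mixture model."""

    n_trajectories: int
    degree: int = 3
    random_effects: str = "intercept_slope"  # none | intercept | intercept_slope
    shared_covariance: bool = True
    n_bins: int = 12

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if not 0 <= self.degree <= 3:
            raise ValueError("degree must be in 0..3")
        if self.random_effects not in _RE_DESIGNS:
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        if _RE_DESIGNS[self.random_effects] > self.degree + 1:
            raise ValueError("random-effects design must be a subset of the "
                             "fixed design")
        if not self.shared_covariance:
            raise NotImplementedError(
                "only trajectory-shared covariance is implemented")

    @property
    def n_fixed(self) -> int:
        return self.degree + 1

    @property
    def n_random(self) -> int:
        return _RE_DESIGNS[self.random_effects]


@dataclass(frozen=True)
class MultistartProtocol:
    """Short-run/finalist schedule for escaping local maxima."""

    n_random_starts: int = 400
    short_iterations: int = 10
    n_finalists: int = 50
    #: absolute log-likelihood change at which full EM stops; zero-inflated
    #: indicators produce slow near-degenerate ridges, so demanding much
    #: less than 1e-4 trades hours of iterations for BIC-irrelevant digits
    tol: float = 1e-4
    max_iterations: int = 2000
    replication_tol: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_finalists > self.n_random_starts:
            raise ValueError("n_finalists must be <= n_random_starts")
        if min(self.n_random_starts, self.short_iterations,
               self.n_finalists, self.max_iterations) < 1:
            raise ValueError("all protocol counts must be positive")


@dataclass
class GMMParams:
    """One parameter point: per-class curves + shared covariance components."""

    beta: np.ndarray      # (K, d+1) coefficients on the standardized design
    weights: np.ndarray   # (K,)
    psi: np.ndarray       # (q, q) random-effects covariance (possibly 0x0)
    sigma2: float

    def copy(self) -> "GMMParams":
        return GMMParams(self.beta.copy(), self.weights.copy(),
                         self.psi.copy(), float(self.sigma2))


@dataclass
class StabilityReport:
    finalist_loglik: np.ndarray
    n_replications: int
    stable: bool
    replication_tol: float


@dataclass
class TrajectoryModel:
    """Fitted growth mixture for one indicator."""

    spec: GrowthSpec
    params: GMMParams
    coefficients: np.ndarray      # (K, d+1) on the raw t = 0..11 scale
    loglik: float
    n_parameters: int
    bic: float
    converged: bool
    n_iterations: int
    posteriors: np.ndarray        # (N, K) trajectory-membership probabilities
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    stability: StabilityReport | None = None

    @property
    def weights(self) -> np.ndarray:
        return self.params.weights

    def membership_frame(self, player_ids) -> pd.DataFrame:
        cols = [f"traj{k + 1}" for k in range(self.spec.n_trajectories)]
        return pd.DataFrame(self.posteriors, columns=cols,
                            index=pd.Index(player_ids, name="player_id"))

    def to_dict(self) -> dict:
        return {
            "n_trajectories": self.spec.n_trajectories,
            "degree": self.spec.degree,
            "random_effects": self.spec.random_effects,
            "coefficients_raw_time": self.coefficients.tolist(),
            "weights": self.params.weights.tolist(),
            "psi": self.params.psi.tolist(),
            "sigma2": self.params.sigma2,
            "loglik": self.loglik,
            "n_parameters": self.n_parameters,
            "bic": self.bic,
            "converged": self.converged,
            "stable": None if self.stability is None else self.stability.stable,
        }


def design_matrices(spec: GrowthSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized polynomial design X (T x p), its random-effects columns Z,
    and the raw time grid."""
    t = np.arange(spec.n_bins, dtype=float)
    ts = (t - t.mean()) / t.std()
    X = np.vander(ts, spec.n_fixed, increasing=True)
    Z = X[:, : spec.n_random]
    return X, Z, t


def _raw_scale_coefficients(beta_std: np.ndarray, spec: GrowthSpec) -> np.ndarray:
    """Re-express standardized-time polynomial coefficients on t = 0..11."""
    t = np.arange(spec.n_bins, dtype=float)
    mu, sd = t.mean(), t.std()
    sub = Polynomial([-mu / sd, 1.0 / sd])  # ts as a polynomial in t
    out = np.zeros_like(beta_std)
    for k in range(beta_std.shape[0]):
        raw = Polynomial(beta_std[k])(sub).coef
        out[k, : len(raw)] = raw
    return out


def _marginal_cov(spec: GrowthSpec, params: GMMParams) -> np.ndarray:
    _, Z, _ = design_matrices(spec)
    V = params.sigma2 * np.eye(spec.n_bins)
    if spec.n_random:
        V += Z @ params.psi @ Z.T
    return V


def _log_densities(Y: np.ndarray, spec: GrowthSpec,
                   params: GMMParams) -> np.ndarray:
    """(N, K) log N(y_i; X beta_k, V) with the shared marginal covariance."""
    X, _, _ = design_matrices(spec)
    V = _marginal_cov(spec, params)
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    const = -0.5 * (spec.n_bins * np.log(2.0 * np.pi) + logdet)
    out = np.empty((Y.shape[0], spec.n_trajectories))
    for k in range(spec.n_trajectories):
        resid = Y - X @ params.beta[k]          # (N, T)
        w = np.linalg.solve(L, resid.T)         # whitened residuals
        out[:, k] = const - 0.5 * np.einsum("ij,ij->j", w, w)
    return out


def marginal_loglik(Y: np.ndarray, spec: GrowthSpec, params: GMMParams) -> float:
    """Observed-data log-likelihood with random effects integrated out."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != spec.n_bins:
        raise ValueError(f"Y must be (n_players, {spec.n_bins})")
    ld = _log_densities(Y, spec, params) + np.log(params.weights)
    return float(logsumexp(ld, axis=1).sum())


def count_gmm_parameters(spec: GrowthSpec) -> int:
    """Free parameters: K(d+1) fixed effects + q(q+1)/2 shared covariance
    terms + 1 residual variance + (K-1) mixing weights."""
    K, p, q = spec.n_trajectories, spec.n_fixed, spec.n_random
    return K * p + q * (q + 1) // 2 + 1 + (K - 1)


def bic(loglik: float, n_parameters: int, n: int) -> float:
    """Bayesian information criterion, -2 LL + k ln(n); lower is better."""
    if n < 1:
        raise ValueError("n must be positive")
    return -2.0 * loglik + n_parameters * np.log(n)


def _posterior_re_moments(Y, X, Z, params):
    """Conditional moments of the random effects given data and class.

    Returns m (K, N, q) = E[b_i | y_i, class k] and S (q, q) = Cov[b_i | y_i]
    (class-independent because the covariance is shared)."""
    V = params.sigma2 * np.eye(X.shape[0]) + Z @ params.psi @ Z.T
    G = params.psi @ Z.T @ np.linalg.inv(V)      # (q, T)
    S = params.psi - G @ Z @ params.psi
    m = np.empty((params.beta.shape[0], Y.shape[0], params.psi.shape[0]))
    for k in range(params.beta.shape[0]):
        m[k] = (Y - X @ params.beta[k]) @ G.T
    return m, S


def em_fit(Y: np.ndarray, spec: GrowthSpec, init: GMMParams,
           tol: float = 1e-6, max_iter: int = 500,
           weight_floor: float = 1e-6) -> TrajectoryModel:
    """EM for the growth mixture, monotone in the marginal log-likelihood.

    E-step: class posteriors p_ik and conditional random-effect moments.
    M-step (closed form): weighted OLS on partial residuals for beta_k,
    posterior means for the weights, expected outer products for Psi and
    sigma^2.  Variance floors (sigma^2 >= 1e-6 var(Y), Psi eigenvalues >= 0)
    guard against degenerate components; a trajectory whose total posterior
    mass falls below ``weight_floor`` is floored with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    N, T = Y.shape
    if T != spec.n_bins:
        raise ValueError(f"Y must have {spec.n_bins} columns")
    X, Z, _ = design_matrices(spec)
    K, q = spec.n_trajectories, spec.n_random
    XtX_inv = np.linalg.inv(X.T @ X)
    var_floor = max(1e-6 * float(Y.var()), 1e-12)

    params = init.copy()
    params.sigma2 = max(params.sigma2, var_floor)
    ll_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # ---- E-step
        ld = _log_densities(Y, spec, params) + np.log(params.weights)
        ll = float(logsumexp(ld, axis=1).sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood during EM")
        post = np.exp(ld - logsumexp(ld, axis=1, keepdims=True))
        if ll_path and ll < ll_path[-1] - 1e-8:
            warnings.warn(f"EM log-likelihood decreased by {ll_path[-1] - ll:.3g}"
                          " (variance floor active)", RuntimeWarning)
        done = bool(ll_path) and abs(ll - ll_path[-1]) < tol
        ll_path.append(ll)
        if done:
            converged = True
            break

        nk = post.sum(axis=0)
        if (nk < weight_floor * N).any():
            warnings.warn("near-empty trajectory floored", RuntimeWarning)
            nk = np.maximum(nk, weight_floor * N)

        if q:
            m, S = _posterior_re_moments(Y, X, Z, params)
            trZSZ = float(np.trace(Z @ S @ Z.T))
        else:
            m = np.zeros((K, N, 0))
            S = np.zeros((0, 0))
            trZSZ = 0.0

        # ---- M-step
        new_beta = np.empty_like(params.beta)
        for k in range(K):
            target = (post[:, k] @ (Y - m[k] @ Z.T)) / nk[k]
            new_beta[k] = XtX_inv @ (X.T @ target)
        new_w = nk / nk.sum()
        if q:
            psi_acc = np.zeros((q, q))
            for k in range(K):
                psi_acc += (m[k].T * post[:, k]) @ m[k]
            new_psi = psi_acc / N + S
            # PSD repair: clip negative eigenvalues from roundoff
            evals, evecs = np.linalg.eigh(new_psi)
            new_psi = (evecs * np.maximum(evals, 0.0)) @ evecs.T
        else:
            new_psi = params.psi
        sse = 0.0
        for k in range(K):
            resid = Y - X @ new_beta[k] - m[k] @ Z.T
            sse += float(post[:, k] @ np.einsum("ij,ij->i", resid, resid))
        new_sigma2 = max(sse / (N * T) + trZSZ / T, var_floor)

        params = GMMParams(new_beta, new_w, new_psi, new_sigma2)

    # final E-step quantities at the last parameter point
    ld = _log_densities(Y, spec, params) + np.log(params.weights)
    ll = float(logsumexp(ld, axis=1).sum())
    post = np.exp(ld - logsumexp(ld, axis=1, keepdims=True))
    ll_path.append(ll)

    k_params = count_gmm_parameters(spec)
    return TrajectoryModel(
        spec=spec, params=params,
        coefficients=_raw_scale_coefficients(params.beta, spec),
        loglik=ll, n_parameters=k_params, bic=bic(ll, k_params, N),
        converged=converged, n_iterations=it, posteriors=post,
        loglik_path=np.asarray(ll_path),
    )


def _random_inits(Y: np.ndarray, spec: GrowthSpec, n_starts: int,
                  rng: np.random.Generator) -> list[GMMParams]:
    """Half perturbed-KMeans-on-curves starts, half fully random draws."""
    N, T = Y.shape
    X, _, _ = design_matrices(spec)
    K, q = spec.n_trajectories, spec.n_random
    XtX_inv = np.linalg.inv(X.T @ X)
    pooled_beta = XtX_inv @ (X.T @ Y.mean(axis=0))
    y_var = max(float(Y.var()), 1e-8)
    beta_scale = np.sqrt(y_var)

    km_beta = None
    km_w = None
    if K > 1 and N > K:
        km = KMeans(n_clusters=K, n_init=3,
                    random_state=int(rng.integers(2**31 - 1))).fit(Y)
        km_beta = np.stack([XtX_inv @ (X.T @ c) for c in km.cluster_centers_])
        km_w = np.bincount(km.labels_, minlength=K) / N
        km_w = np.maximum(km_w, 0.02)
        km_w /= km_w.sum()

    inits = []
    for s in range(n_starts):
        if km_beta is not None and s % 2 == 0:
            beta = km_beta + rng.normal(0, 0.2 * beta_scale, (K, spec.n_fixed))
            w = km_w * np.exp(rng.normal(0, 0.3, K))
        else:
            beta = pooled_beta + rng.normal(0, beta_scale, (K, spec.n_fixed))
            w = rng.dirichlet(np.ones(K) * 2.0)
        w = np.maximum(w, 1e-3)
        w /= w.sum()
        frac = rng.uniform(0.1, 0.5)
        psi = np.eye(q) * frac * y_var
        sigma2 = y_var * rng.uniform(0.2, 0.8)
        inits.append(GMMParams(beta, w, psi, sigma2))
    return inits


def multistart_fit(Y: np.ndarray, spec: GrowthSpec,
                   protocol: MultistartProtocol = MultistartProtocol()
                   ) -> TrajectoryModel:
    """Short-run/finalist multistart EM with a log-likelihood stability flag.

    Runs ``n_random_starts`` inits for ``short_iterations`` EM iterations,
    carries the ``n_finalists`` best into full EM, and returns the best
    final model.  The attached :class:`StabilityReport` marks the solution
    stable when >=2 finalists reach the best final log-likelihood within
    ``replication_tol``.
    """
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(protocol.seed)
    inits = _random_inits(Y, spec, protocol.n_random_starts, rng)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        short = []
        for init in inits:
            try:
                short.append(em_fit(Y, spec, init, tol=0.0,
                                    max_iter=protocol.short_iterations))
            except (FloatingPointError, np.linalg.LinAlgError):
                continue
        if not short:
            raise RuntimeError("all short EM runs failed")
        short.sort(key=lambda mdl: -mdl.loglik)

        finals = []
        for mdl in short[: protocol.n_finalists]:
            try:
                finals.append(em_fit(Y, spec, mdl.params, tol=protocol.tol,
                                     max_iter=protocol.max_iterations))
            except (FloatingPointError, np.linalg.LinAlgError):
                continue
    if not finals:
        raise RuntimeError(
            "no finalist converged; short-run logliks: "
            + ", ".join(f"{m.loglik:.2f}" for m in short[:10]))

    lls = np.array([m.loglik for m in finals])
    best = finals[int(np.argmax(lls))]
    n_rep = int((lls >= lls.max() - protocol.replication_tol).sum())
    best.stability = StabilityReport(
        finalist_loglik=np.sort(lls)[::-1], n_replications=n_rep,
        stable=n_rep >= 2, replication_tol=protocol.replication_tol)
    return best


def select_trajectory_model(candidates: list[TrajectoryModel]
                            ) -> tuple[TrajectoryModel, pd.DataFrame]:
    """Rank candidate models and auto-select by BIC among stable fits.

    Returns the best-BIC converged+stable model and the full fit table
    (K, LL, BIC, parameters, converged, stable) so a human can override —
    interpretability of the trajectories is not automatable.
    """
    if not candidates:
        raise ValueError("no candidate models")
    table = pd.DataFrame({
        "n_trajectories": [m.spec.n_trajectories for m in candidates],
        "loglik": [m.loglik for m in candidates],
        "bic": [m.bic for m in candidates],
        "n_parameters": [m.n_parameters for m in candidates],
        "converged": [m.converged for m in candidates],
        "stable": [bool(m.stability and m.stability.stable) for m in candidates],
    }).sort_values("bic", ignore_index=True)
    eligible = [m for m in candidates
                if m.converged and m.stability and m.stability.stable]
    if not eligible:
        raise RuntimeError("no converged, stable candidate to select from")
    best = min(eligible, key=lambda m: m.bic)
    return best, table


def simulate_growth_mixture(n_players: int, spec: GrowthSpec,
                            params: GMMParams, seed: int = 0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (Y, true_class) directly from a growth mixture — the exact data-
    generating model of :func:`em_fit`, used for parameter-recovery checks."""
    rng = np.random.default_rng(seed)
    X, Z, _ = design_matrices(spec)
    labels = rng.choice(spec.n_trajectories, size=n_players, p=params.weights)
    Y = np.empty((n_players, spec.n_bins))
    for i, k in enumerate(labels):
        mean = X @ params.beta[k]
        if spec.n_random:
            mean = mean + Z @ rng.multivariate_normal(
                np.zeros(spec.n_random), params.psi)
        Y[i] = mean + rng.normal(0, np.sqrt(params.sigma2), spec.n_bins)
    return Y, labels
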