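"""Latent profile analysis over concatenated trajectory-membership
probabilities (step 2 of the two-step classification).

After a growth mixture model has been selected per indicator, each player is
summarized by the concatenation of their posterior membership vectors — with
the study's selected trajectory models, 7 + 3 + 3 + 4 = 17 columns.  Players
are then clustered with a mixture of diagonal Gaussians over those columns
(class-specific means and variances, free mixing proportions), so the free
parameter count is C*2J + (C - 1).

Membership probabilities enter untransformed; since they are often near 0/1,
near-degenerate columns are expected and variance floors are part of the
design, not an error path.  The same multistart/replication machinery as the
growth-mixture step provides the stability flag, and the classification
error E = 1 - mean_i max_c q_ic summarizes how crisp the partition is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from lottotraj.gmm import MultistartProtocol, StabilityReport, bic

__all__ = [
    "MembershipMatrix",
    "ProfileModel",
    "assemble_memberships",
    "fit_lpa",
    "count_lpa_parameters",
    "classification_error",
    "select_profile_model",
]


@dataclass
class MembershipMatrix:
    """Players x (indicator, trajectory) membership probabilities.

    ``data`` has one row per player; ``blocks`` maps each indicator to its
    column labels, each block summing to 1 per player.
    """

    data: pd.DataFrame
    blocks: dict[str, list[str]]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def player_ids(self) -> pd.Index:
        return self.data.index

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def assemble_memberships(blocks: dict[str, pd.DataFrame]) -> MembershipMatrix:
    """Column-blocked join of per-indicator membership tables.

    Every table must be indexed by player_id and cover the same player set;
    total width J is the sum of the per-indicator trajectory counts.
    """
    if not blocks:
        raise ValueError("no membership blocks supplied")
    ids = None
    for name, df in blocks.items():
        if ids is None:
            ids = set(df.index)
        elif set(df.index) != ids:
            missing = sorted(ids.symmetric_difference(df.index))[:10]
            raise ValueError(
                f"player sets differ across membership blocks; block {name!r} "
                f"mismatches on e.g. {missing}")
    parts, labels = [], {}
    for name, df in blocks.items():
        renamed = df.rename(columns=lambda c: f"{name}:{c}")
        parts.append(renamed.sort_index())
        labels[name] = list(renamed.columns)
    data = pd.concat(parts, axis=1)
    if ((data < -1e-9) | (data > 1 + 1e-9)).any().any():
        raise ValueError("membership probabilities must lie in [0, 1]")
    return MembershipMatrix(data=data, blocks=labels)


def count_lpa_parameters(n_classes: int, n_indicators: int) -> int:
    """Free parameters of a C-class diagonal-Gaussian profile model on J
    indicators: C means + C variances per indicator, plus C-1 weights."""
    if n_classes < 1 or n_indicators < 1:
        raise ValueError("n_classes and n_indicators must be >= 1")
    return n_classes * 2 * n_indicators + (n_classes - 1)


def classification_error(posteriors: np.ndarray) -> float:
    """Expected modal-assignment error, E = 1 - mean_i max_c q_ic."""
    q = np.asarray(posteriors, dtype=float)
    return float(1.0 - q.max(axis=1).mean())


@dataclass
class ProfileModel:
    """Fitted latent profile model over a membership matrix."""

    n_classes: int
    weights: np.ndarray      # (C,)
    means: np.ndarray        # (C, J)
    variances: np.ndarray    # (C, J)
    loglik: float
    n_parameters: int
    bic: float
    classification_error: float
    converged: bool
    n_iterations: int
    posteriors: np.ndarray   # (N, C)
    columns: list[str]
    loglik_path: np.ndarray | None = None
    stability: StabilityReport | None = None

    def modal_classes(self) -> np.ndarray:
        return self.posteriors.argmax(axis=1)

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "columns": self.columns,
            "loglik": self.loglik,
            "n_parameters": self.n_parameters,
            "bic": self.bic,
            "classification_error": self.classification_error,
            "converged": self.converged,
            "stable": None if self.stability is None else self.stability.stable,
        }


def _lpa_log_densities(Xv, means, variances):
    # (N, C) sums of independent Gaussian log-densities per column
    const = -0.5 * np.log(2.0 * np.pi * variances)  # (C, J)
    out = np.empty((Xv.shape[0], means.shape[0]))
    for c in range(means.shape[0]):
        z2 = (Xv - means[c]) ** 2 / variances[c]
        out[:, c] = const[c].sum() - 0.5 * z2.sum(axis=1)
    return out


def _em_lpa(Xv: np.ndarray, n_classes: int, w0, mu0, var0,
            tol: float, max_iter: int, var_floor: np.ndarray,
            columns: list[str]) -> ProfileModel:
    N, J = Xv.shape
    w, mu, var = w0.copy(), mu0.copy(), np.maximum(var0, var_floor)
    ll_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ld = _lpa_log_densities(Xv, mu, var) + np.log(w)
        ll = float(logsumexp(ld, axis=1).sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite LPA log-likelihood")
        post = np.exp(ld - logsumexp(ld, axis=1, keepdims=True))
        if ll_path and ll < ll_path[-1] - 1e-8:
            warnings.warn("LPA log-likelihood decreased (variance floor "
                          "active)", RuntimeWarning)
        done = bool(ll_path) and abs(ll - ll_path[-1]) < tol
        ll_path.append(ll)
        if done:
            converged = True
            break
        nk = np.maximum(post.sum(axis=0), 1e-10)
        w = nk / nk.sum()
        mu = (post.T @ Xv) / nk[:, None]
        var = (post.T @ Xv**2) / nk[:, None] - mu**2
        if (var < var_floor).any():
            var = np.maximum(var, var_floor)
    ld = _lpa_log_densities(Xv, mu, var) + np.log(w)
    ll = float(logsumexp(ld, axis=1).sum())
    post = np.exp(ld - logsumexp(ld, axis=1, keepdims=True))
    ll_path.append(ll)
    k = count_lpa_parameters(n_classes, J)
    return ProfileModel(
        n_classes=n_classes, weights=w, means=mu, variances=var,
        loglik=ll, n_parameters=k, bic=bic(ll, k, N),
        classification_error=classification_error(post),
        converged=converged, n_iterations=it, posteriors=post,
        columns=columns, loglik_path=np.asarray(ll_path))


def fit_lpa(M: MembershipMatrix, n_classes: int,
            protocol: MultistartProtocol = MultistartProtocol(),
            var_floor_abs: float = 1e-4) -> ProfileModel:
    """Multistart EM for the diagonal-Gaussian latent profile model.

    Same short-run/finalist schedule and stability (log-likelihood
    replication) contract as the growth-mixture step.

    Membership columns are frequently near 0/1, so near-degenerate variances
    are the rule, not the exception.  Without regularization the likelihood
    rewards classes that split players on hairline (<1e-3) differences in
    near-constant columns — partitions with no behavioral meaning.  Each
    column's variance is therefore floored at
    ``max(1e-6 var_j, var_floor_abs)``; the default absolute floor of 1e-4
    corresponds to a 0.01 standard deviation on the probability scale, the
    resolution below which membership differences carry no information about
    trajectories.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    Xv = M.values()
    N, J = Xv.shape
    col_var = Xv.var(axis=0)
    var_floor = np.maximum(1e-6 * col_var, var_floor_abs)
    cols = list(M.data.columns)
    rng = np.random.default_rng(protocol.seed)

    if N < n_classes:
        raise ValueError(f"need at least {n_classes} players for {n_classes} "
                         "classes")
    if n_classes == 1:
        # closed form: MLE means and variances; the global maximum, so the
        # solution is stable by construction
        model = _em_lpa(Xv, 1, np.ones(1), Xv.mean(axis=0, keepdims=True),
                        np.maximum(col_var, var_floor)[None, :],
                        protocol.tol, protocol.max_iterations, var_floor, cols)
        model.stability = StabilityReport(
            finalist_loglik=np.array([model.loglik]), n_replications=2,
            stable=True, replication_tol=protocol.replication_tol)
        return model

    glob_var = np.maximum(col_var, var_floor)
    km = KMeans(n_clusters=n_classes, n_init=3,
                random_state=int(rng.integers(2**31 - 1))).fit(Xv)
    km_mu = km.cluster_centers_
    km_w = np.maximum(np.bincount(km.labels_, minlength=n_classes) / N, 0.02)
    km_w /= km_w.sum()
    col_sd = np.sqrt(glob_var)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        short = []
        for s in range(protocol.n_random_starts):
            if s % 2 == 0:
                mu0 = km_mu + rng.normal(0, 0.3, (n_classes, J)) * col_sd
                w0 = km_w * np.exp(rng.normal(0, 0.3, n_classes))
            else:
                mu0 = Xv[rng.choice(N, n_classes, replace=False)] \
                    + rng.normal(0, 0.1, (n_classes, J)) * col_sd
                w0 = rng.dirichlet(np.ones(n_classes) * 2.0)
            w0 = np.maximum(w0, 1e-3)
            w0 /= w0.sum()
            var0 = glob_var[None, :] * rng.uniform(0.5, 1.5, (n_classes, 1))
            try:
                short.append(_em_lpa(Xv, n_classes, w0, mu0, var0, 0.0,
                                     protocol.short_iterations, var_floor, cols))
            except FloatingPointError:
                continue
        if not short:
            raise RuntimeError("all short LPA runs failed")
        short.sort(key=lambda m: -m.loglik)
        finals = []
        for mdl in short[: protocol.n_finalists]:
            try:
                finals.append(_em_lpa(Xv, n_classes, mdl.weights, mdl.means,
                                      mdl.variances, protocol.tol,
                                      protocol.max_iterations, var_floor, cols))
            except FloatingPointError:
                continue
    if not finals:
        raise RuntimeError("no LPA finalist converged")
    lls = np.array([m.loglik for m in finals])
    best = finals[int(np.argmax(lls))]
    n_rep = int((lls >= lls.max() - protocol.replication_tol).sum())
    best.stability = StabilityReport(
        finalist_loglik=np.sort(lls)[::-1], n_replications=n_rep,
        stable=n_rep >= 2, replication_tol=protocol.replication_tol)
    return best


def _profiles_similar(small: ProfileModel, large: ProfileModel,
                      threshold: float) -> bool:
    """True when every class profile of the larger model is within
    ``threshold`` (max abs mean difference) of some class of the smaller —
    i.e. the extra classes add nothing materially distinct."""
    for c in range(large.n_classes):
        dists = np.abs(small.means - large.means[c]).max(axis=1)
        if dists.min() > threshold:
            return False
    return True


def select_profile_model(models: list[ProfileModel],
                         similarity_threshold: float = 0.10
                         ) -> tuple[ProfileModel, pd.DataFrame]:
    """Emit the fit table and auto-select the class count.

    The table reports LL, BIC, parameter count, classification error and
    stability for every candidate.  Auto-choice is restricted to converged,
    stable models: the smallest C whose next stable neighbor adds no
    materially distinct class profile (mean profiles within
    ``similarity_threshold``); if every step adds a distinct profile, the
    best-BIC stable model, with ties within 1 BIC point broken toward the
    smallest C.  The table is always returned for human override.
    """
    if not models:
        raise ValueError("no candidate models")
    models = sorted(models, key=lambda m: m.n_classes)
    table = pd.DataFrame({
        "n_classes": [m.n_classes for m in models],
        "loglik": [m.loglik for m in models],
        "bic": [m.bic for m in models],
        "n_parameters": [m.n_parameters for m in models],
        "classification_error": [m.classification_error for m in models],
        "converged": [m.converged for m in models],
        "stable": [bool(m.stability and m.stability.stable) for m in models],
    })
    stable = [m for m in models
              if m.converged and m.stability and m.stability.stable]
    if not stable:
        raise RuntimeError("no converged, stable profile model to select from")
    for a, b in zip(stable, stable[1:]):
        if _profiles_similar(a, b, similarity_threshold):
            return a, table
    best_bic = min(m.bic for m in stable)
    within = [m for m in stable if m.bic <= best_bic + 1.0]
    return min(within, key=lambda m: m.n_classes), table
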