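"""Class description and end-to-end pipeline orchestration.

Once a latent profile model is selected, each class is described
*probabilistically*: every player contributes to every class in proportion
to their posterior q_ic, so class sizes are mean posteriors (in %), the
trajectory table holds posterior-weighted mean membership probabilities per
(indicator, trajectory), and covariate summaries are posterior-weighted
means / percentages.  Percentages therefore describe probability mass, not
head counts of modally assigned players.

``run_pipeline`` chains the stages — simulate (optional), reduce, fit a
growth mixture per indicator, assemble memberships, fit the profile model,
describe classes — writing every intermediate to disk with a config-hash
sidecar so that reruns with an unchanged config reuse cached stages and
identical seeds reproduce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lottotraj import indicators as ind
from lottotraj import synthetic
from lottotraj.gmm import (GrowthSpec, MultistartProtocol, TrajectoryModel,
                           multistart_fit, select_trajectory_model)
from lottotraj.lpa import (MembershipMatrix, ProfileModel, assemble_memberships,
                           fit_lpa, select_profile_model)

__all__ = ["ClassProfileTable", "PipelineConfig", "class_profiles",
           "run_pipeline", "plot_trajectories"]

log = logging.getLogger("lottotraj")

HIGHLIGHT_THRESHOLD = 0.10  # membership probabilities above this are "main"


@dataclass
class ClassProfileTable:
    """Probabilistic description of the selected classes."""

    sizes: pd.Series              # % of probability mass per class
    trajectories: pd.DataFrame    # rows (indicator, trajectory), cols classes
    covariates: pd.DataFrame      # rows covariate summaries, cols classes
    highlights: pd.DataFrame      # boolean, same shape as ``trajectories``

    def to_frame(self) -> pd.DataFrame:
        head = self.sizes.to_frame().T
        head.index = pd.MultiIndex.from_tuples([("class size", "%")])
        return pd.concat([head, self.trajectories, self.covariates])


def class_profiles(M: MembershipMatrix, covariates: pd.DataFrame,
                   model: ProfileModel) -> ClassProfileTable:
    """Posterior-weighted class description.

    size_c = 100 * mean_i q_ic; trajectory cell (j, c) =
    sum_i q_ic M_ij / sum_i q_ic; numeric covariates are posterior-weighted
    means and categorical ones posterior-weighted percentages.  Classes with
    essentially no mass are reported with a warning rather than dropped.
    """
    cov = covariates.set_index("player_id").loc[M.player_ids]
    q = model.posteriors
    n_classes = model.n_classes
    mass = q.sum(axis=0)
    sizes = pd.Series(100.0 * q.mean(axis=0),
                      index=[f"class{c + 1}" for c in range(n_classes)],
                      name="probabilistic_size_pct")
    for c, m in enumerate(mass):
        if m < 1e-3 * len(cov):
            log.warning("class %d holds <0.1%% of posterior mass", c + 1)

    wmean = (q.T @ M.values()) / np.maximum(mass[:, None], 1e-300)  # (C, J)
    rows = [tuple(col.split(":", 1)) for col in M.data.columns]
    traj = pd.DataFrame(wmean.T, columns=sizes.index,
                        index=pd.MultiIndex.from_tuples(
                            rows, names=["indicator", "trajectory"]))
    highlights = traj > HIGHLIGHT_THRESHOLD

    def weighted_mean(series: pd.Series) -> np.ndarray:
        v = series.to_numpy(dtype=float)
        return (q.T @ v) / np.maximum(mass, 1e-300)

    cov_rows: dict[tuple[str, str], np.ndarray] = {}
    cov_rows[("age", "mean")] = weighted_mean(cov["age"])
    for g in ("male", "female"):
        cov_rows[("gender", f"% {g}")] = 100.0 * weighted_mean(cov["gender"] == g)
    cov_rows[("self_exclusion", "% yes")] = (
        100.0 * weighted_mean(cov["self_exclusion"] == "yes"))
    cov_rows[("cumulative_losses", "mean EUR")] = weighted_mean(cov["net_loss"])
    cov_rows[("cumulative_deposits", "mean EUR")] = (
        weighted_mean(cov["cumulative_deposits"]))
    cov_rows[("largest_single_day_deposit", "mean EUR")] = (
        weighted_mean(cov["largest_single_day_deposit"]))
    cov_rows[("instant_lotteries", "% of bets")] = weighted_mean(cov["pct_instant"])
    for tag in ("green", "orange", "red"):
        cov_rows[("risk_tag", f"% {tag}")] = (
            100.0 * weighted_mean(cov["risk_tag"] == tag))
    cov_df = pd.DataFrame(cov_rows, index=sizes.index).T
    return ClassProfileTable(sizes=sizes, trajectories=traj,
                             covariates=cov_df, highlights=highlights)


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline end to end, reproducibly."""

    cohort: synthetic.CohortConfig
    gmm_protocol: MultistartProtocol = MultistartProtocol()
    lpa_protocol: MultistartProtocol = MultistartProtocol()
    #: trajectory counts to try per indicator; a single int pins K directly
    k_candidates: dict[str, list[int]] = field(default_factory=lambda: {
        "wagered": [1, 2, 3, 4, 5, 6, 7],
        "gambling_days": [1, 2, 3, 4],
        "chasing": [1, 2, 3],
        "involvement": [1, 2, 3, 4, 5],
    })
    degree: int = 3
    random_effects: str = "intercept_slope"
    c_candidates: list[int] = field(default_factory=lambda: list(range(1, 9)))
    count_all_burst: bool = False
    seed: int = 0

    def digest(self) -> str:
        import dataclasses

        doc = {
            "cohort": dataclasses.asdict(self.cohort),
            "gmm_protocol": dataclasses.asdict(self.gmm_protocol),
            "lpa_protocol": dataclasses.asdict(self.lpa_protocol),
            "k_candidates": self.k_candidates,
            "degree": self.degree,
            "random_effects": self.random_effects,
            "c_candidates": self.c_candidates,
            "count_all_burst": self.count_all_burst,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()


def indicator_series_matrix(panel: pd.DataFrame, indicator: str
                            ) -> tuple[np.ndarray, pd.Index]:
    """Pivot the tidy panel into an (n_players, 12) matrix for one indicator,
    ln(x+1)-transforming the wagered series."""
    wide = panel.pivot(index="player_id", columns="bin", values=indicator)
    wide = wide.sort_index(axis=1).astype(float)
    Y = wide.to_numpy()
    if indicator == "wagered":
        Y = ind.log_wager_transform(Y)
    return Y, wide.index


def fit_indicator(panel: pd.DataFrame, indicator: str,
                  k_values: list[int], protocol: MultistartProtocol,
                  degree: int = 3, random_effects: str = "intercept_slope",
                  ) -> tuple[TrajectoryModel, pd.DataFrame, pd.Index]:
    """Fit candidate growth mixtures for one indicator and select by BIC."""
    Y, ids = indicator_series_matrix(panel, indicator)
    candidates = []
    for i, k in enumerate(k_values):
        spec = GrowthSpec(n_trajectories=k, degree=degree,
                          random_effects=random_effects)
        proto = MultistartProtocol(**{
            **protocol.__dict__, "seed": protocol.seed + 1000 * i})
        log.info("fitting %s with K=%d", indicator, k)
        candidates.append(multistart_fit(Y, spec, proto))
    best, table = select_trajectory_model(candidates)
    return best, table, ids


def plot_trajectories(model: TrajectoryModel, indicator: str, path: Path,
                      back_transform: bool = False) -> None:
    """Plot the fitted mean trajectory of each class over the 12 bins."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from lottotraj.gmm import design_matrices

    X, _, t = design_matrices(model.spec)
    fig, ax = plt.subplots(figsize=(6, 4))
    for k in range(model.spec.n_trajectories):
        mean = X @ model.params.beta[k]
        ax.plot(t, mean, marker="o", ms=3,
                label=f"traj {k + 1} ({100 * model.weights[k]:.1f}%)")
    ax.set_xlabel("15-day bin")
    ylabel = indicator
    if indicator == "wagered":
        ylabel = "wagered, ln(EUR + 1)"
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage(out: Path, name: str, digest: str, compute, reader, writer):
    """Run ``compute`` unless a cached artifact with a matching config hash
    exists; deleting an intermediate forces recomputation downstream."""
    meta = out / f"{name}.meta.json"
    if meta.exists():
        info = json.loads(meta.read_text())
        if info.get("digest") == digest:
            try:
                value = reader()
                log.info("stage %s: cached", name)
                return value
            except Exception:  # corrupt cache -> recompute
                pass
    log.info("stage %s: computing", name)
    value = compute()
    writer(value)
    meta.write_text(json.dumps({"digest": digest, "stage": name}))
    return value


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate -> reduce -> per-indicator growth mixtures -> membership
    assembly -> latent profile model -> class profiles.

    Returns a report bundle (dict of the main objects) and writes all
    tables, model JSONs, plots and a markdown summary under ``out_dir``.
    Deterministic given the config (which includes every seed).
    """
    from lottotraj import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    log.info("pipeline start: config %s, lottotraj %s", digest[:12], __version__)

    stream = _stage(
        out, "events", digest,
        lambda: synthetic.generate_cohort(config.cohort),
        lambda: synthetic.read_events(out / "events.csv"),
        lambda s: synthetic.write_events(s, out / "events.csv"))

    panel = _stage(
        out, "panel", digest,
        lambda: ind.build_indicator_panel(stream, config.count_all_burst),
        lambda: pd.read_csv(out / "panel.csv", float_precision="round_trip"),
        lambda p: p.to_csv(out / "panel.csv", index=False))

    covariates = _stage(
        out, "covariates", digest,
        lambda: ind.compute_covariates(stream,
                                       count_all_burst=config.count_all_burst),
        lambda: pd.read_csv(out / "covariates.csv",
                            float_precision="round_trip"),
        lambda c: c.to_csv(out / "covariates.csv", index=False))

    blocks: dict[str, pd.DataFrame] = {}
    gmm_models: dict[str, TrajectoryModel] = {}
    for indicator, k_values in config.k_candidates.items():
        model, table, ids = fit_indicator(
            panel, indicator, k_values, config.gmm_protocol,
            config.degree, config.random_effects)
        gmm_models[indicator] = model
        table.to_csv(out / f"gmm_{indicator}_selection.csv", index=False)
        (out / f"gmm_{indicator}.json").write_text(
            json.dumps(model.to_dict(), indent=1))
        memb = model.membership_frame(ids)
        memb.to_csv(out / f"membership_{indicator}.csv")
        blocks[indicator] = memb
        plot_trajectories(model, indicator, out / f"trajectories_{indicator}.png")

    M = assemble_memberships(blocks)
    M.data.to_csv(out / "memberships.csv")

    lpa_models = []
    for i, c in enumerate(config.c_candidates):
        proto = MultistartProtocol(**{
            **config.lpa_protocol.__dict__,
            "seed": config.lpa_protocol.seed + 7000 * i})
        log.info("fitting LPA with C=%d", c)
        lpa_models.append(fit_lpa(M, c, proto))
    best_lpa, fit_table = select_profile_model(lpa_models)
    fit_table.to_csv(out / "lpa_fit_table.csv", index=False)
    (out / "lpa_model.json").write_text(json.dumps(best_lpa.to_dict(), indent=1))
    pd.DataFrame(best_lpa.posteriors,
                 index=M.player_ids,
                 columns=[f"class{c + 1}" for c in range(best_lpa.n_classes)]
                 ).to_csv(out / "class_posteriors.csv")

    profiles = class_profiles(M, covariates, best_lpa)
    profiles.to_frame().to_csv(out / "class_profiles.csv")

    _write_summary(out, config, digest, gmm_models, fit_table, best_lpa, profiles)
    return {"stream": stream, "panel": panel, "covariates": covariates,
            "gmm_models": gmm_models, "memberships": M,
            "lpa_models": lpa_models, "lpa_fit_table": fit_table,
            "profile_model": best_lpa, "profiles": profiles}


def _write_summary(out: Path, config: PipelineConfig, digest: str,
                   gmm_models, fit_table, best_lpa, profiles) -> None:
    from lottotraj import __version__

    lines = [
        "# Early gambling trajectory report",
        "",
        f"- lottotraj {__version__}, config hash `{digest[:12]}`, "
        f"seed {config.seed}",
        f"- cohort: {config.cohort.n_players} players, "
        f"{config.cohort.observation_days} days",
        "",
        "## Selected trajectory models",
        "",
    ]
    for name, model in gmm_models.items():
        stable = model.stability.stable if model.stability else None
        lines.append(
            f"- **{name}**: {model.spec.n_trajectories} trajectories, "
            f"LL {model.loglik:.1f}, BIC {model.bic:.1f}, stable {stable} "
            f"(plot: `trajectories_{name}.png`)")
    lines += ["", "## Latent profile model selection", "",
              fit_table.to_markdown(index=False), "",
              f"Selected: {best_lpa.n_classes} classes "
              f"(classification error {best_lpa.classification_error:.4f})",
              "", "## Probabilistic class profiles", "",
              profiles.to_frame().round(3).to_markdown()]
    (out / "report.md").write_text("\n".join(lines))
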