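import numpy as np
import pandas as pd
import pytest

from lottotraj.gmm import MultistartProtocol
from lottotraj.indicators import build_indicator_panel, compute_covariates
from lottotraj.synthetic import default_cohort_config, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Small five-class cohort shared across tests (deterministic)."""
    return generate_cohort(default_cohort_config(n_players=150, seed=11))


@pytest.fixture(scope="session")
def panel(cohort):
    return build_indicator_panel(cohort)


@pytest.fixture(scope="session")
def covariates(cohort):
    return compute_covariates(cohort)


@pytest.fixture(scope="session")
def small_protocol():
    return MultistartProtocol(n_random_starts=12, short_iterations=5,
                              n_finalists=4, seed=5)


@pytest.fixture(scope="session")
def mini_pipeline(tmp_path_factory):
    """One reduced end-to-end pipeline run shared by the profiling tests.

    Cohort seed fixed to one whose high-risk class contains self-exclusion
    events, so the covariate-propagation path is exercised.
    """
    from lottotraj.profiling import PipelineConfig, run_pipeline

    proto = MultistartProtocol(n_random_starts=12, short_iterations=5,
                               n_finalists=4, seed=3)
    cfg = PipelineConfig(
        cohort=default_cohort_config(n_players=250, seed=10),
        gmm_protocol=proto, lpa_protocol=proto,
        k_candidates={"wagered": [2, 3, 4], "gambling_days": [2, 3],
                      "chasing": [2], "involvement": [2, 3]},
        c_candidates=[1, 2, 3, 4, 5], seed=7)
    out = tmp_path_factory.mktemp("pipeline")
    result = run_pipeline(cfg, out)
    return cfg, out, result


def make_stream(events, players=None):
    """Build a minimal EventStream from (player_id, ts, type, amount, game,
    gtype) tuples; players default to one row per distinct id."""
    from lottotraj.synthetic import EventStream

    ev = pd.DataFrame(events, columns=["player_id", "timestamp", "event_type",
                                       "amount", "game_id", "game_type"])
    ev["timestamp"] = pd.to_datetime(ev["timestamp"], utc=True)
    if players is None:
        ids = ev["player_id"].unique()
        players = pd.DataFrame({
            "player_id": ids,
            "account_created": pd.Timestamp("2016-01-01"),
            "age": 40, "gender": "male", "true_class": "synthetic",
        })
    return EventStream(events=ev, players=players)
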