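#!/usr/bin/env python
"""Describe the selected classes probabilistically and check them against
the generator's ground truth.

Each class is summarized by its probabilistic size (mean posterior, %), the
posterior-weighted mean membership probability per trajectory (cells > .10
are the class's main trajectories), and posterior-weighted covariate
summaries.  Because the cohort is synthetic, the script also reports the
cross-tabulation of modal classes against the generator's latent classes.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lottotraj.lpa import MembershipMatrix, ProfileModel
from lottotraj.profiling import class_profiles
from lottotraj.synthetic import read_events

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    data = pd.read_csv(OUT / "memberships.csv", index_col="player_id",
                       float_precision="round_trip")
    blocks: dict[str, list[str]] = {}
    for col in data.columns:
        blocks.setdefault(col.split(":", 1)[0], []).append(col)
    M = MembershipMatrix(data=data, blocks=blocks)

    doc = json.loads((OUT / "lpa_model.json").read_text())
    post = pd.read_csv(OUT / "class_posteriors.csv", index_col="player_id",
                       float_precision="round_trip").loc[M.player_ids]
    model = ProfileModel(
        n_classes=doc["n_classes"], weights=np.asarray(doc["weights"]),
        means=np.asarray(doc["means"]), variances=np.asarray(doc["variances"]),
        loglik=doc["loglik"], n_parameters=doc["n_parameters"],
        bic=doc["bic"], classification_error=doc["classification_error"],
        converged=doc["converged"], n_iterations=0,
        posteriors=post.to_numpy(), columns=doc["columns"])

    covariates = pd.read_csv(OUT / "covariates.csv",
                             float_precision="round_trip")
    prof = class_profiles(M, covariates, model)
    prof.to_frame().to_csv(OUT / "class_profiles.csv")
    print("probabilistic class sizes (%):")
    print(prof.sizes.round(1).to_string())
    print("\nmean membership probabilities (main trajectories marked *):")
    marked = prof.trajectories.round(3).astype(str)
    marked = marked.where(~prof.highlights, marked + "*")
    print(marked.to_string())
    print("\nposterior-weighted covariates:")
    print(prof.covariates.round(2).to_string())

    truth = (read_events(OUT / "events.csv").players
             .set_index("player_id")["true_class"].loc[M.player_ids])
    modal = model.modal_classes()
    print("\nmodal class vs generator truth:")
    print(pd.crosstab(truth.to_numpy(), modal,
                      rownames=["true_class"], colnames=["modal"]))


if __name__ == "__main__":
    main()
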