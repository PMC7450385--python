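#!/usr/bin/env python
"""Cluster players on trajectory-membership probabilities (step 2).

Concatenates the per-indicator membership blocks and fits latent profile
models with C = 1..6 classes (diagonal Gaussians, full 400-start/50-finalist
multistart EM).
Prints the fit table — log-likelihood, BIC, parameter count, classification
error, stability — and the auto-selected class count (parsimony rule over
stable models; the table is the basis for any human override).
"""

import json
from pathlib import Path

import pandas as pd

from lottotraj.gmm import MultistartProtocol
from lottotraj.lpa import assemble_memberships, fit_lpa, select_profile_model

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
INDICATORS = ("wagered", "gambling_days", "chasing", "involvement")


def main() -> None:
    blocks = {ind: pd.read_csv(OUT / f"membership_{ind}.csv",
                               index_col="player_id",
                               float_precision="round_trip")
              for ind in INDICATORS}
    M = assemble_memberships(blocks)
    M.data.to_csv(OUT / "memberships.csv")
    print(f"membership matrix: {M.data.shape[0]} players x "
          f"{M.n_columns} columns "
          f"({' + '.join(str(len(c)) for c in M.blocks.values())})")

    models = []
    for i, c in enumerate(range(1, 7)):
        proto = MultistartProtocol(n_random_starts=400, short_iterations=10,
                                   n_finalists=50, seed=42 + 7000 * i)
        models.append(fit_lpa(M, c, proto))
    best, table = select_profile_model(models)
    table.to_csv(OUT / "lpa_fit_table.csv", index=False)
    (OUT / "lpa_model.json").write_text(json.dumps(best.to_dict(), indent=1))
    pd.DataFrame(best.posteriors, index=M.player_ids,
                 columns=[f"class{c+1}" for c in range(best.n_classes)]
                 ).to_csv(OUT / "class_posteriors.csv")
    print(table.round(4).to_string(index=False))
    print(f"selected C={best.n_classes} "
          f"(classification error {best.classification_error:.4f})")


if __name__ == "__main__":
    main()
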