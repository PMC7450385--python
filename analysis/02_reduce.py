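#!/usr/bin/env python
"""Reduce the event stream to the 12-bin indicator panel and covariates.

Computes, per player and 15-day bin: amount wagered, gambling days, chasing
episodes (recurrent/post-bet deposit proxy) and breadth of involvement; plus
six-month covariates (deposits, net loss, % instant lotteries, self-
exclusion, risk tag).  Prints the cohort descriptives with the
between/within-subject variance decomposition of monthly activity.
"""

from pathlib import Path

from lottotraj.indicators import (build_indicator_panel, compute_covariates,
                                  describe_sample)
from lottotraj.synthetic import read_events

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    stream = read_events(OUT / "events.csv")
    panel = build_indicator_panel(stream)
    covariates = compute_covariates(stream)
    panel.to_csv(OUT / "panel.csv", index=False)
    covariates.to_csv(OUT / "covariates.csv", index=False)

    desc = describe_sample(panel, covariates)
    desc.indicators.to_csv(OUT / "descriptives_indicators.csv")
    desc.covariates.to_csv(OUT / "descriptives_covariates.csv")
    print("monthly indicator descriptives (between/within decomposition):")
    print(desc.indicators.round(2).to_string())
    print("\ncovariate descriptives:")
    print(desc.covariates.round(2).to_string())
    chase = panel.groupby("player_id")["chasing"].sum()
    print(f"\nplayers with >=1 chasing episode: {(chase > 0).sum()} "
          f"of {len(chase)}")
    print(f"wrote {OUT / 'panel.csv'} and {OUT / 'covariates.csv'}")


if __name__ == "__main__":
    main()
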