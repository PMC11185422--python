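#!/usr/bin/env python
"""Participant exclusion screening: per participant and task, Bayes factors
for a positive slope of (a) orientation discrimination and (b) OP-interval
selection over visibility levels. BF10 <= 1/3 on either flags exclusion.

Reads results/data/trials_<task>.csv; writes results/exclusion_report.csv.
"""

from pathlib import Path

import pandas as pd

from vernier2ifc.data import load_trials, screen_participants
from vernier2ifc.design import Task

DATA = Path("results/data")


def main() -> None:
    rows = []
    for task in Task:
        trials = load_trials(DATA / f"trials_{task.value}.csv")
        for r in screen_participants(trials, task):
            rows.append(dict(
                participant_id=r.participant_id, task=task.value,
                bf_orientation_slope=r.bf_orientation_slope,
                bf_interval_slope=r.bf_interval_slope,
                excluded=r.excluded, triggered_by=";".join(r.triggered_by),
            ))
    df = pd.DataFrame(rows)
    out = Path("results/exclusion_report.csv")
    df.to_csv(out, index=False)
    n_excl = int(df["excluded"].sum())
    print(f"wrote {out}; {n_excl} of {len(df)} participant-task screenings "
          f"flagged for exclusion")
    if n_excl == 0:
        print("all synthetic participants show credible positive slopes, "
              "as expected from the generative strengths")


if __name__ == "__main__":
    main()
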