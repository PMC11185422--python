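#!/usr/bin/env python
"""Level-wise Bayes-factor analyses on the synthetic cohorts: above-chance
performance (orientation and interval), Type-2 HR vs FAR, conditional
discrimination, and the interval-order effect, each built on hierarchical
logistic posterior predictions with the level-dependent priors.

Writes results/bayes_factors.csv. MCMC runs at a reduced but adequate
length (64 walkers x 2000 steps); the seeds make the table reproducible.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from vernier2ifc import bayes
from vernier2ifc.data import collapse_to_level_summaries, load_trials
from vernier2ifc.design import Task, scaled_levels

DATA = Path("results/data")
SEED = 2024
MCMC = dict(n_walkers=64, n_steps=2000)


def predictions(summaries, task, value_fn, seed):
    x = np.array([s.level.scaled_value for s in summaries])
    k = np.array([value_fn(s)[0] for s in summaries])
    n = np.array([value_fn(s)[1] for s in summaries])
    pid = [s.participant_id for s in summaries]
    post = bayes.fit_hier_logistic(x, k, n, pid, seed=seed, **MCMC)
    if post.warnings:
        print(f"  [diagnostics] {post.warnings[0]}")
    return [bayes.posterior_predict(post, float(v)) for v in scaled_levels(task)]


def main() -> None:
    warnings.filterwarnings("ignore", category=UserWarning)
    rows = []
    for ti, task in enumerate(Task):
        trials = load_trials(DATA / f"trials_{task.value}.csv")
        summaries = collapse_to_level_summaries(trials)
        seed = SEED + 1000 * (ti + 1)

        def emit(family, results):
            for lev, r in enumerate(results, start=1):
                rows.append(dict(family=family, task=task.value,
                                 level_index=lev, obs_mean=r.obs_mean,
                                 obs_sd=r.obs_sd, h1_sd=r.h1.sd, bf10=r.bf10))

        print(f"{task.value}:")
        for name, fn in (("orientation", lambda s: (s.n11 + s.n10, s.n)),
                         ("interval", lambda s: (s.n11 + s.n01, s.n))):
            preds = predictions(summaries, task, fn, seed)
            res = bayes.bf_above_chance([p[0] for p in preds],
                                        [p[1] for p in preds])
            emit(f"above_chance_{name}", res)
            print(f"  above-chance {name}: hardest-level BF10 = {res[0].bf10:.2f}")
            seed += 1

        hr = predictions(summaries, task, lambda s: (s.n11, s.n11 + s.n10), seed)
        far = predictions(summaries, task, lambda s: (s.n01, s.n01 + s.n00), seed + 1)
        res = bayes.bf_difference(hr, far, "type2_HRFAR")
        emit("type2_HRFAR", res)
        print(f"  type-2 HR-FAR: hardest-level BF10 = {res[0].bf10:.2f}")

        op = predictions(summaries, task, lambda s: (s.n11, s.n11 + s.n01), seed + 2)
        oa = predictions(summaries, task, lambda s: (s.n10, s.n10 + s.n00), seed + 3)
        res = bayes.bf_difference(op, oa, "conditional")
        emit("conditional", res)
        print(f"  conditional accuracy: hardest-level BF10 = {res[0].bf10:.2f}")

        first = predictions([s.restricted("first") for s in summaries], task,
                            lambda s: (s.n11 + s.n01, s.n), seed + 4)
        second = predictions([s.restricted("second") for s in summaries], task,
                             lambda s: (s.n11 + s.n01, s.n), seed + 5)
        res = bayes.bf_difference(first, second, "interval_order")
        emit("interval_order", res)
        print(f"  interval-order effect: hardest-level BF10 = {res[0].bf10:.2f} "
              f"(generator is order-symmetric; expect < 1)")

    pd.DataFrame(rows).to_csv("results/bayes_factors.csv", index=False)
    print("wrote results/bayes_factors.csv")


if __name__ == "__main__":
    main()
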