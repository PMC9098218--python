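"""Count standard/deviant trials under the INIT and 2REP definitions.

INIT (deviants after >= 5 repetitions, standards as 6th repetitions) gives
roughly 110-120 deviants and 90-100 standards per 1800-tone sequence; 2REP
(every tone after >= 2 repetitions, with repetition-matched standard
subsampling) retains several times more trials per condition.
"""
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from volmmn import labeling, paradigm

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0, n_seeds: int = 100) -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    rng = np.random.default_rng(seed)
    for s in rng.integers(0, 2**31, size=n_seeds):
        sched = paradigm.build_schedule(seed=int(s))
        seq = paradigm.generate_sequence(sched, seed=int(s))
        init = labeling.label_trials_init(seq).counts()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            two = labeling.label_trials_2rep(seq, seed=int(s)).counts()
        rows.append(
            {
                "seed": int(s),
                "init_deviants": init["deviant"],
                "init_standards": init["standard"],
                "tworep_deviants": two["deviant"],
                "tworep_standards": two["standard"],
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "trial_counts.tsv", sep="\t", index=False)
    m = frame.mean(numeric_only=True)
    print(f"{n_seeds} sequences labeled")
    print(
        f"INIT: {m['init_deviants']:.1f} deviants / {m['init_standards']:.1f} "
        "standards on average (plausibility band 95-140 / 80-125)"
    )
    print(
        f"2REP: {m['tworep_deviants']:.1f} deviants / {m['tworep_standards']:.1f} standards"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
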