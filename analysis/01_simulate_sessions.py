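#!/usr/bin/env python
"""Generate the four synthetic dataset-style sessions used by the analyses.

Writes HDF5 sessions plus ground-truth JSON to scratch/sessions/ (bulky,
regenerable) and the per-session condition tables to results/.
"""

import pathlib
import sys

import pandas as pd

from v1gamma.session import save_session
from v1gamma.synth import example_session_configs, simulate_session

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"


def main(seed: int = 0):
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, cfg in example_session_configs(seed).items():
        sess, truth = simulate_session(cfg)
        save_session(sess, SCRATCH / f"{name}.h5")
        truth.to_json(SCRATCH / f"{name}.truth.json")
        for c in cfg.conditions:
            rows.append(
                {
                    "session": name,
                    "condition": c.label,
                    "gamma_amplitude": c.gamma_amplitude,
                    "gamma_peak_freq": c.gamma_peak_freq,
                    "rate_sustained": c.rate_sustained,
                    "locking_kappa": c.locking_kappa,
                    "n_trials": cfg.n_trials_per_condition,
                }
            )
        print(
            f"{name}: {sess.n_trials} trials x {sess.n_channels} channels, "
            f"{sess.trial_duration:.1f} s/trial -> scratch/sessions/{name}.h5"
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "session_conditions.csv", index=False)
    print(f"condition table ({len(table)} rows) -> results/session_conditions.csv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
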