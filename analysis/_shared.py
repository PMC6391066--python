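"""Shared loader for the analysis drivers: read a simulated session from
scratch/, regenerating it on the fly if 01_simulate_sessions.py has not
been run."""

import pathlib

from v1gamma.session import load_session, save_session
from v1gamma.synth import example_session_configs, simulate_session

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"


def get_session(name: str, seed: int = 0):
    path = SCRATCH / f"{name}.h5"
    if path.exists():
        return load_session(path)
    cfg = example_session_configs(seed)[name]
    sess, truth = simulate_session(cfg)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    save_session(sess, path)
    truth.to_json(SCRATCH / f"{name}.truth.json")
    return sess
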