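#!/usr/bin/env python
"""Eye-movement controls: microsaccade detection against the generator's
ground truth, gamma amplitude with and without post-saccade censoring
(100 ms epochs, Hann, zero-padded to 1 s), and pupil light responses."""

import json

import numpy as np
import pandas as pd
from _shared import RESULTS, SCRATCH, get_session

from v1gamma.evaluation import _short_epoch_gamma
from v1gamma.firing import censor_after_microsaccades, detect_microsaccades, pupil_response
from v1gamma.pipeline import clean_session_lfp


def main():
    sess = get_session("predictability")
    truth = json.load(open(SCRATCH / "predictability.truth.json"))
    fs_eye = sess.fs_eye
    hits = n_inj = n_det = 0
    events_per_trial = []
    for k in range(sess.n_trials):
        ev = detect_microsaccades(sess.eye[k], fs_eye)
        inj = np.asarray(truth[k]["saccade_times"])
        events_per_trial.append(ev)
        n_det += len(ev)
        n_inj += len(inj)
        for e in ev:
            if len(inj) and np.min(np.abs(inj - e.onset)) <= 0.02:
                hits += 1
    print(
        f"microsaccades: {n_inj} injected, {n_det} detected, "
        f"recall {hits / max(n_inj, 1):.3f}"
    )

    clean = clean_session_lfp(sess)
    onset, dur = sess.stim_onset, sess.trial_duration
    uni = sess.trials_for("uniform")
    full_w, cens_w, trials = [], [], []
    for k in uni:
        ev = events_per_trial[k]
        fw = censor_after_microsaccades(onset, [], start=0.0) + \
            censor_after_microsaccades(dur, [], start=onset + 0.3)
        cw = censor_after_microsaccades(onset, ev, start=0.0) + \
            censor_after_microsaccades(dur, ev, start=onset + 0.3)
        for ch in range(sess.n_channels):
            trials.append(clean[k, ch])
            full_w.append(fw)
            cens_w.append(cw)
    g_full = _short_epoch_gamma(trials, sess.fs_lfp, onset, full_w, 0)
    g_cens = _short_epoch_gamma(trials, sess.fs_lfp, onset, cens_w, 0)
    print(
        f"uniform gamma fold (100 ms epochs): {g_full.amplitude_fold:.2f} all data, "
        f"{g_cens.amplitude_fold:.2f} censored"
    )

    rows = []
    for label in sess.labels:
        pc = [
            pupil_response(sess.pupil[k], fs_eye, onset).percent_change[-500:].mean()
            for k in sess.trials_for(label)
        ]
        rows.append({"condition": label, "late_pupil_change": float(np.mean(pc))})
        print(f"pupil late change ({label}): {np.mean(pc):+.4f}")
    pd.DataFrame(
        {
            "metric": ["recall", "gamma_fold_all", "gamma_fold_censored"],
            "value": [hits / max(n_inj, 1), g_full.amplitude_fold, g_cens.amplitude_fold],
        }
    ).to_csv(RESULTS / "eye_controls.csv", index=False)
    pd.DataFrame(rows).to_csv(RESULTS / "pupil_responses.csv", index=False)


if __name__ == "__main__":
    main()
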