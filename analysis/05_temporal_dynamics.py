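#!/usr/bin/env python
"""Temporal evolution of the gamma response: sliding-window (0.3 s Hann,
50 ms steps) time-frequency analysis in dB relative to baseline, showing
the within-trial decay of the injected gamma band."""

import numpy as np
import pandas as pd
from _shared import RESULTS, get_session

from v1gamma.pipeline import clean_session_lfp
from v1gamma.spectral import tfr, to_db


def main():
    sess = get_session("predictability")
    clean = clean_session_lfp(sess)
    fs = sess.fs_lfp
    rows = []
    for label in sess.labels:
        trials = sess.trials_for(label)
        maps = [
            tfr(clean[k, ch], fs, t_start=-sess.stim_onset)
            for k in trials
            for ch in range(sess.n_channels)
        ]
        mean_map = np.mean([m.values for m in maps], axis=0)
        times, freqs = maps[0].times, maps[0].frequencies
        base = mean_map[times < -0.15].mean(axis=0)
        db = to_db(mean_map / base)
        band = (freqs >= 45) & (freqs <= 65)
        for t, v in zip(times, db[:, band].mean(axis=1)):
            rows.append({"condition": label, "time_s": t, "gamma_db": v})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "gamma_time_course_db.csv", index=False)
    for label in sess.labels:
        sub = df[df.condition == label]
        early = sub[(sub.time_s > 0.2) & (sub.time_s < 0.5)].gamma_db.mean()
        late = sub[sub.time_s > 1.0].gamma_db.mean()
        print(f"{label}: gamma {early:+.2f} dB early -> {late:+.2f} dB late")


if __name__ == "__main__":
    main()
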