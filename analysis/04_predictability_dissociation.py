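#!/usr/bin/env python
"""Center-surround predictability: uniform surfaces vs mismatch stimuli.

The headline dissociation: uniform surfaces drive stronger gamma but
sustained firing below baseline; mismatch stimuli weaken gamma while
elevating firing. A max-statistic-corrected permutation test localizes the
frequency bins where the relative power spectra differ.
"""

import numpy as np
import pandas as pd
from _shared import RESULTS, get_session

from v1gamma.pipeline import AnalysisConfig, clean_session_lfp, condition_spectra, run_experiment
from v1gamma.stats import permutation_test_corrected


def main():
    sess = get_session("predictability")
    cfg = AnalysisConfig(
        dataset_style="predictability_mismatch",
        required_conditions=("uniform", "mismatch"),
        seed=0,
    )
    bundle = run_experiment(cfg, sess)
    s = bundle.summary
    print(
        f"gamma fold: uniform {s['gamma_uniform']:.2f} vs mismatch "
        f"{s['gamma_mismatch']:.2f}; rate modulation: uniform "
        f"{s['rate_mod_uniform']:+.3f} vs mismatch {s['rate_mod_mismatch']:+.3f}"
    )
    print(
        f"dissociation recovered: gamma {s['gamma_dissociation']}, "
        f"rate {s['rate_dissociation']}; modulation index {s['modulation_index']:.3f}"
    )

    # frequency-resolved permutation test on per-trial fold-change spectra
    clean = clean_session_lfp(sess)
    stim, base = condition_spectra(sess, cfg, clean)
    base_mean = base.mean().power
    freqs = stim["uniform"].frequencies
    band = (freqs >= 20) & (freqs <= 140)
    a = stim["uniform"].power[:, band] / base_mean[band]
    b = stim["mismatch"].power[:, band] / base_mean[band]
    res = permutation_test_corrected(a, b, n_permutations=1000, rng=0)
    sig = pd.DataFrame(
        {
            "frequency_hz": freqs[band],
            "abs_difference": res.observed,
            "significant": res.significant,
        }
    )
    sig.to_csv(RESULTS / "predictability_permutation.csv", index=False)
    fsig = freqs[band][res.significant]
    if len(fsig):
        print(
            f"{res.significant.sum()} significant bins, "
            f"{fsig.min():.0f}-{fsig.max():.0f} Hz (max-statistic corrected)"
        )
    else:
        print("no significant frequency bins")
    pd.DataFrame([s]).to_csv(RESULTS / "predictability_summary.csv", index=False)


if __name__ == "__main__":
    main()
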