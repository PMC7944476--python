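"""Simulate the TBI-vs-control Raman probe cohort.

Generates the default study conditions — 20 samples per class, 15
accumulations each on the 600-1800 cm^-1 fingerprint grid, cardiolipin
depleted to 50% in the TBI class, fluorescence background, 1% channel noise
and cosmic-ray spikes — and writes the raw cohort (per-sample accumulation
CSVs, labels, ground-truth coefficients) under scratch/cohort/ (bulky per-sample
intermediates stay out of results/).

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

import numpy as np

from neuroraman import default_cohort_config, default_library, generate_cohort
from neuroraman.io import write_cohort

SEED = 20260929
OUT = "scratch/cohort"


def main():
    library = default_library()
    config = default_cohort_config(n_per_class=20, seed=SEED)
    cohort = generate_cohort(config, library)
    paths = write_cohort(cohort, OUT)

    n_spiked = int((cohort.accumulations
                    > cohort.clean[:, None, :] + 8 * config.noise_sd).sum())
    print(f"wrote {cohort.n_samples} samples "
          f"({cohort.accumulations.shape[1]} accumulations each) to {OUT}")
    print(f"classes: {dict(zip(*np.unique(cohort.labels, return_counts=True)))}")
    print(f"cosmic-ray spike channels across all accumulations: {n_spiked}")
    for cls in config.class_names:
        idx = [i for i, l in enumerate(cohort.labels) if l == cls]
        card = cohort.truth_coefficients[idx, 0]
        print(f"  true cardiolipin coefficient, {cls}: "
              f"{card.mean():.3f} +/- {card.std():.3f}")


if __name__ == "__main__":
    main()
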