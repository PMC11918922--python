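"""Capture-enrichment QC: specificity, stability threshold, correlation.

Capture specificity is the on-target / off-target sequenced-base ratio.
Sorting samples by library DNA concentration and sliding a five-sample
window across them exposes the low-input regime where capture becomes
erratic: the window with the highest spread marks the concentration
threshold below which specificity is unreliable.
"""

import numpy as np

from ylineage import qcstats, simdata

metas = qcstats.meta_from_frame(simdata.simulate_capture_meta(59, seed=1))

ratios = [qcstats.capture_specificity(m) for m in metas]
print(f"59-sample capture cohort: on/off-target ratio "
      f"mean {np.mean(ratios):.2f}, range {min(ratios):.2f}-{max(ratios):.2f}")

windows = qcstats.window_stats(metas, window=5, variation="sd")
threshold = qcstats.concentration_threshold(windows)
r, p = qcstats.concentration_correlation(metas)

print(f"{len(windows)} five-sample moving windows over increasing concentration")
worst = max(windows, key=lambda w: w.variation)
print(f"most variable window: sd {worst.variation:.2f} at "
      f"{worst.mean_concentration:.2f} ng/uL")
print(f"-> stability threshold {threshold:.2f} ng/uL: below this input "
      "concentration capture specificity is erratic")
print(f"concentration vs specificity: Pearson r = {r:.2f} (p = {p:.1e}) — "
      "more input DNA, more on-target capture")

# cohort-level variant bookkeeping on the same arithmetic the study uses
print(f"\nfold change in cohort size 59 -> 277: "
      f"{qcstats.fold_change(277, 59)}-fold")
print(f"singletons 2267 of 4128 variants: {qcstats.percent_of(2267, 4128)}%")
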