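"""Agreement analysis between truth-based and segmentation-based measurements.

Simulates paired per-case measurements (ground-truth value and a noisy,
slightly biased 'segmentation' value) for one morphology item and prints
the agreement summary: Pearson's r, the Bland-Altman mean difference with
1.96 SD limits of agreement, absolute error and error rate, the paired
t-test at the Bonferroni-corrected threshold 0.05/19, and the
proportional-error correlation r_p.
"""

import numpy as np

from valvemorph import PairedMeasurements, agreement_summary, paired_t

rng = np.random.default_rng(0)
n_cases = 120
truth_values = rng.normal(11.0, 2.4, n_cases)          # e.g. effective height
seg_values = truth_values - 0.4 + rng.normal(0, 1.2, n_cases)

pm = PairedMeasurements(truth_values, seg_values, item="effective_height_rcc")
summ = agreement_summary(pm)
test = paired_t(pm)

print(f"item: {pm.item}  (n = {pm.n})")
print(f"  r = {summ['r']:.3f}  (truth vs segmentation correlation)")
print(f"  mean difference = {summ['mean_diff']:+.2f} mm, "
      f"limits of agreement [{summ['loa_low']:+.2f}, {summ['loa_high']:+.2f}]")
print(f"  absolute error  = {summ['abs_err_mean']:.2f} "
      f"(SE {summ['abs_err_se']:.2f}) mm")
print(f"  error rate      = {summ['err_rate_mean']:.1f} "
      f"(SE {summ['err_rate_se']:.1f}) %")
print(f"  paired t: p = {test['p']:.2e} vs threshold {test['threshold']:.4f} "
      f"-> fixed error {'detected' if test['significant'] else 'absent'}")
print(f"  proportional error r_p = {summ['r_p']:.3f}")
print("\nA significant paired t with these limits of agreement mirrors how "
      "systematic segmentation bias is reported per measurement item.")
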