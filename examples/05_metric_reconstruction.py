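"""Reconstruct Cohen's kappa from printed sensitivity/false-positive rates.

Published evaluation tables often report only rates. Given TP rate 0.99 and
FP rate 0.0020 at class sizes 2045 abnormal / 2055 normal, the implied
(real-valued) confusion matrix determines kappa exactly — a consistency
check on any reported rate table.
"""

from wavemri import ConfusionCounts, cohen_kappa, kappa_from_rates

tp_rate, fp_rate = 0.99, 0.0020
n_pos, n_neg = 2045, 2055

kappa = kappa_from_rates(tp_rate, fp_rate, n_pos, n_neg)
print(f"TP rate {tp_rate}, FP rate {fp_rate}, classes {n_pos}/{n_neg}")
print(f"implied kappa: {kappa:.4f}")

tp = tp_rate * n_pos
fp = fp_rate * n_neg
counts = ConfusionCounts(tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
print(f"implied cells: tp={counts.tp:.2f} fp={counts.fp:.2f} "
      f"tn={counts.tn:.2f} fn={counts.fn:.2f}")
print(f"cohen_kappa on those cells: {cohen_kappa(counts):.4f}")
print("keeping the cells fractional is what preserves 4-decimal agreement")
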