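"""The 11-metric evaluation suite and its internal identities.

Builds a confusion table at the sensitivity/specificity operating point of
a strong detector (0.988 / 0.986) and prints the full suite; balanced
accuracy, FPR, FNR and NLR follow from Sen/Spec by identity.
"""

from mitodet import ConfusionCounts, metric_suite

counts = ConfusionCounts(tp=988, fn=12, tn=986, fp=14)
report = metric_suite(counts)
for name, value in report.to_dict().items():
    if name != "degenerate":
        print(f"{name:10s} {value:.4f}")
print(f"identity check: ba == (sen+spec)/2 -> "
      f"{report.ba == (report.sen + report.spec) / 2}")
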