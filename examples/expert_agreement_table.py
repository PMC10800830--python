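"""Expert-agreement arithmetic: from label counts to the summary table.

Given how many matched rings an expert judged better-manual / similar /
better-model, compute the percentages (truncated at two decimals) and the
pooled equal-or-better figure.
"""

from ringseg import summary_from_counts

s = summary_from_counts(n_manual=108, n_similar=619, n_model=601, total_rings=1329)

for name in ("manual", "similar", "model"):
    print(f"{name:>8}: {s.counts[name]:4d} rings  ({s.percentages[name]}%)")
print(f"equal or better than manual: {s.equal_or_better_pct}%")
# Percentages are count/total*100 truncated (not rounded) at two decimals;
# 'equal or better' pools the similar and model labels.
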