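"""Score a manually curated association sample and cluster scaling figures.

Precision rates a sample of derived associations that human curators
labelled true or false. Speedup and sizeup summarize how a distributed
deployment scales with nodes and with input volume; the baseline is the
smallest configuration that can hold the data.
"""

from kgchain import EvaluationCounts, TimingPair, precision, sizeup, speedup

# 150 sampled herb-gene pairs, 126 confirmed by all curators
counts = EvaluationCounts.from_sample(sample_size=150, tp=126)
print(f"precision: {precision(counts):.1%} (126 of 150 confirmed)")

# cluster of 6 nodes vs the 2-node baseline
t = TimingPair(baseline_minutes=8.45, measured_minutes=2.16)
print(f"speedup 2→6 nodes: {speedup(t):.2f}x")

# 8-fold input on a fixed 4-node cluster
t = TimingPair(baseline_minutes=3.07, measured_minutes=24.09)
print(f"sizeup at 8x data: {sizeup(t):.2f} (sublinear: below 8)")
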