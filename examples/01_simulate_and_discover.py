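"""Generate a synthetic salt-stress study and run the lncRNA discovery cascade.

The generator plants 30 true lncRNAs among 200 transcripts, plus decoys that
each fail exactly one filter (wrong class code, too short, coding, weakly
expressed, or overlapping a small RNA).  The cascade should recover the
planted set exactly.
"""

from lncregnet.discovery import run_discovery_cascade
from lncregnet.synthetic import SimulationConfig, simulate_dataset

dataset = simulate_dataset(SimulationConfig(seed=0))
annotations, counts = run_discovery_cascade(
    dataset.transcripts, dataset.matrix, dataset.small_rnas, dataset.evidence
)

print("transcripts surviving each filter stage:")
for stage, n in counts.items():
    print(f"  {stage:18s} {n}")

found = {a.transcript.transcript_id for a in annotations}
truth = dataset.manifest.lncrna_ids()
print(f"\nrecovered {len(found & truth)} / {len(truth)} planted lncRNAs "
      f"({len(found - truth)} false positives)")

by_category = {}
for a in annotations:
    by_category[a.category] = by_category.get(a.category, 0) + 1
print("category tallies (from class codes u/i/x/o):", by_category)
# The funnel narrows monotonically; at these settings recovery is exact.
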