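"""Screen lncRNAs as miRNA target mimics.

Candidate sites are scored by a banded antiparallel alignment: Watson-Crick
pair 0, G:U wobble 0.5, mismatch 1.0, gap 2.0, doubled inside the miRNA seed
(positions 2-13).  Sites pass at expectation <= 5 with fewer than four
mismatches; the unpairing-energy (UPE) term is not evaluated (it requires
RNA secondary-structure prediction).
"""

from lncregnet.mimicry import screen
from lncregnet.synthetic import SimulationConfig, simulate_dataset

dataset = simulate_dataset(SimulationConfig(seed=0))
by_id = {t.transcript_id: t for t in dataset.transcripts}
lncrnas = {
    tid: by_id[tid].spliced_sequence(dataset.genome)
    for _, tid, _ in dataset.manifest.mirna_sites
}

duplexes = screen(dataset.mirnas, lncrnas, max_expectation=5, max_mismatches=3)
print(f"{len(duplexes)} passing duplex sites:")
for d in duplexes:
    if d.expectation == 0:
        print(f"  {d.mirna_id} x {d.lncrna_id} at offset {d.offset}: "
              f"expectation {d.expectation}, {d.n_mismatches} mismatches")
        print(f"    {d.alignment}   (| = Watson-Crick pair)")

print("\nplanted decoy sites:", dataset.manifest.mirna_sites)
# Expectation 0 marks a perfect antiparallel complement — the planted
# decoy sites should all surface at the top of the screen.
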