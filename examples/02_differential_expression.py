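"""Call differentially expressed lncRNAs with the study thresholds.

Fold changes are log2 of salt/control mean FPKM (pseudocount 0.01); a
transcript is up-regulated at log2FC >= 1 and q <= 0.05, down-regulated at
log2FC <= -1.  The planted design mirrors the published tallies: 2 up + 2
down in the tolerant genotype, 6 up + 3 down in the sensitive one.
"""

from lncregnet.de import DEResult, call_de, compute_log2fc, count_directions, ddct
from lncregnet.synthetic import SimulationConfig, simulate_dataset

dataset = simulate_dataset(SimulationConfig(seed=0, noise_sigma=0.0))
qvalues = {
    (r.transcript_id, r.genotype): r.qvalue
    for r in dataset.de_stats.itertuples()
}

for genotype in ("tolerant", "sensitive"):
    results = []
    for tid in sorted(dataset.manifest.lncrna_ids()):
        lfc = compute_log2fc(dataset.matrix, tid, genotype)
        q = qvalues[(tid, genotype)]
        results.append(DEResult(tid, lfc, q, call_de(lfc, q)))
    n_up, n_down = count_directions(results)
    print(f"{genotype}: {n_up} up-regulated, {n_down} down-regulated")

# qPCR-style validation arithmetic: 2^-ddCt relative expression
rel = ddct(20, 18, 22, 18)
print(f"\n2^-ddCt for Ct (target,ref) = (20,18) treated vs (22,18) control: {rel}")
# 4.0 means the target is 4x more abundant under treatment after
# normalizing to the reference gene.
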