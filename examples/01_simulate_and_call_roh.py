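"""Generate a small synthetic cohort and call runs of homozygosity.

The cohort mimics a selection-signature study: 9 inbred case animals
with planted homozygous tracts, 3 F1 crossbreeds and 22 outbred
controls on one 5-Mb chromosome at WGS-like SNP density (~100 bp).
"""

import rohtrace as rt
from rohtrace.roh import roh_summary
from rohtrace.simulate import SimConfig, simulate

cfg = SimConfig(seed=1, n_chroms=1, chrom_length_bp=5_000_000,
                n_planted_tracts=2, n_consensus_tracts=3,
                n_cross_shared_tracts=1,
                tract_length_bounds=(300_000, 800_000))
sim = simulate(cfg)
print(f"cohort: {sim.matrix.n_samples} samples x {sim.matrix.n_sites} SNPs")

segments = rt.call_roh(sim.matrix, rt.WGS_PRESET)
summary = roh_summary(segments)
print(summary.head(12).to_string(index=False))

# Case animals carry the planted autozygosity (consensus + private
# tracts, here ~2-3 Mb each); crossbreeds only the one tract shared with
# the case breed; controls essentially nothing.  n_roh counts segments,
# total_kb their summed length per sample.
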