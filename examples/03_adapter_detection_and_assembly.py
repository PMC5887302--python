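"""Adapter contamination: turning-point diagnosis and contig recovery.

Simulates one clean sample and one with adapter read-through in 5% of
reads, detects the turning point the contamination adds to the zipfian
curve, and greedily assembles the most-enriched 6-mers back into the
complete adapter sequence — without knowing the adapter in advance.
"""

import prism
from prism import synth

for rate in (0.0, 0.05):
    spec = synth.spiked_sample(seed=3, adapter_rate=rate)
    reads = synth.simulate_reads(
        synth.LaneConfig([spec], seed=3))[spec.sample_id]
    z = prism.zipfian_from_profile(prism.count_kmers(reads, k=6),
                                   spec.sample_id)
    tps = prism.detect_turning_points(z)
    print(f"adapter rate {rate}: {len(tps)} turning point(s)"
          + (f", strongest at rank {tps[0][0]}" if tps else ""))
    if rate > 0:
        contigs = prism.assemble_enriched_kmers(z, rank_range=(1, 33))
        print("longest assembled contig:", contigs[0])
        print("planted adapter:         ", synth.DEFAULT_ADAPTER)
        print("exact reconstruction:", contigs[0] == synth.DEFAULT_ADAPTER)
# The clean lane's curve is smooth in ln-rank, so no turning point is
# reported; the spiked lane shows one near the adapter's rank range, and
# the 33 co-abundant 6-mers reassemble the full 38-base contaminant.
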