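"""Partition variants into subclones and detect clonal replacement.

Variants are grouped by their binary presence profile across samples
(present = VAF > 0.10). The profile that is positive in every sample is the
shared/truncal set; the remaining profiles become clones labeled A, B, ...
in order of first appearance. A replacement event is called when one
clone's presence collapses between consecutive samples while another's
rises to dominance.
"""

import serialclones as sc

cohort = sc.simulate_cohort(sc.CohortConfig(seed=7))
matrix = sc.harmonize_across_samples(cohort.variant_tables)
presence = sc.call_presence(matrix, presence_vaf=0.10)
partition = sc.partition_clones(presence, min_clone_size=2)

print(f"clone sizes: {partition.clone_sizes()}")
print(f"exclusivity index: {partition.exclusivity_index:.3f}")
# 1.0 means no variant assigned to one clone is ever seen in the samples
# that characterize a different clone.

print("\npresence fraction of each clone per sample:")
print(partition.presence_fraction.round(2))

events = sc.detect_replacement(partition)
for e in events:
    print(
        f"\nclonal replacement: clone {e.clone_out} -> clone {e.clone_in} "
        f"between {e.sample_from} and {e.sample_to}"
    )
# The dominant clone of the first sample is gone by the second sample and a
# different clone accounts for the later disease: one event, first interval.
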