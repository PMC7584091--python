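"""From aligned amplicon reads to a called microhaplotype genotype.

Simulates noisy reads for one heterozygous genomic sample at one locus,
builds the haplotype observation profile (filtering, base masking,
partial-haplotype resolution), and applies the sequential genotype rules.
"""

import numpy as np

from mhnipt import (
    MicrohapDef,
    ReadSimSpec,
    build_locus_profile,
    call_genotype,
    generate_sample_reads,
)

locus = MicrohapDef("MH01", "chr1", 1001, 1120, (1010, 1050, 1080, 1100))
genotype = ("ACGT", "TGCA")
spec = ReadSimSpec(coverage=300, error_rate=0.005, truncated_fraction=0.15,
                   low_qual_fraction=0.05, low_mapq_fraction=0.03,
                   indel_fraction=0.02, nonunique_fraction=0.02)
rng = np.random.default_rng(42)

reads = generate_sample_reads(genotype, locus, spec, rng)
profile = build_locus_profile(reads, locus, "father_gdna")

print(f"{len(reads)} simulated reads -> coverage {profile.coverage} "
      "(accepted complete haplotypes)")
print("rejected:", dict(profile.rejected_counts),
      "-- low_mapq/cigar/not_unique fail the alignment filter;")
print("   too_partial/ambiguous_partial are read haplotypes with masked "
      "bases that could not be rescued")
print("\nrelative frequencies of observed haplotypes:")
for hap, freq in profile.rel_freqs.items():
    print(f"  {hap}  {freq:.3f}")

call = call_genotype(profile)
print(f"\ngenotype call: {call.status}, {call.zygosity}, "
      f"haplotypes {call.haplotypes}")
print("(a heterozygote needs two haplotypes above 10% with both relative "
      "frequencies inside 20-80%)")
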