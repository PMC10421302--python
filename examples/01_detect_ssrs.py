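"""Detect perfect microsatellites in a genome and summarize them by motif length.

Builds a small synthetic genome with planted repeats, runs the detector and
prints each locus plus the motif-length breakdown.
"""

from mgbssr import GenomeSequence, detect_ssrs, summarize_ssrs

genome = GenomeSequence(
    "demo",
    {
        "chr1": "ATGGCTTACGAT" + "GCA" * 7 + "TTGACCTGAGCA"
        + "CTTG" * 5 + "ATCCGATTAGCC" + "GTT" * 12 + "TGACCAGT",
    },
)

loci = detect_ssrs(genome, motif_lengths=(3, 4, 5, 6), min_repeats=4)
for locus in loci:
    print(
        f"{locus.seq_id}:{locus.start + 1}-{locus.end}  "
        f"({locus.motif}){locus.repeat_count}"
    )
print()
print(summarize_ssrs(loci, genome).format_table())

# Each line is one perfect repeat tract: 1-based coordinates and the core
# written motif-x-count, e.g. (GCA)7 = 21 bp of GCAGCA... The summary gives
# the count and share of loci per motif length, the standard first look at
# a genome's SSR landscape.
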