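"""Derive a methylated-binding consensus from bound motif sequences.

Aligns bound motifs on their methylated CpG, clusters the centered 6-mers
on flank similarity, and prints the PWM/IUPAC consensus of each group.
"""

from mcpgbind import consensus as cns

motifs = [
    cns.MotifSeq("M197", "TCCCGCCCA", cpg_offset=3),   # -> CCCGCC
    cns.MotifSeq("M201", "ACCCGCCTT", cpg_offset=3),   # -> CCCGCC
    cns.MotifSeq("M209", "AGTCGCCAA", cpg_offset=3),   # -> GTCGCC
    cns.MotifSeq("M412", "TTACGCCGA", cpg_offset=3),   # -> TACGCC
    cns.MotifSeq("M917", "GAAACGCTG", cpg_offset=4),   # -> AACGCT
]

kmers = cns.extract_centered_kmers(motifs, k=6)
print("centered 6-mers:", [k.kmer for k in kmers])

for group in cns.consensus_report(kmers, min_similarity=0.5):
    members = ", ".join(k.kmer for k in group.members)
    print(f"group of {len(group.members)} ({members}): consensus {group.iupac}")
# Each IUPAC letter covers every base reaching 25% frequency at that
# position; the central CG is invariant by construction.
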