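"""Collapse an alignment into haplotypes and summarize its diversity.

Builds a small aligned sample in memory, collapses identical sequences,
and prints S (segregating sites), k-bar (mean pairwise differences) and
pi (per-site nucleotide diversity).
"""

from molexpand import Alignment, collapse_haplotypes, diversity

aln = Alignment(
    records=[
        ("ind1", "ACGTACGTAC"),
        ("ind2", "ACGTACGTAC"),
        ("ind3", "ACGTACGTAT"),
        ("ind4", "ACGAACGTAT"),
        ("ind5", "ACGAACGTAT"),
    ]
)

table = collapse_haplotypes(aln)
d = diversity(aln)

print(f"n = {d.n} sequences, {table.k_obs} distinct haplotypes")
for i, (seq, freq, members) in enumerate(table.haplotypes, 1):
    print(f"  H{i}: frequency {freq}  ({', '.join(members)})")
print(f"S = {d.S} segregating sites")
print(f"k-bar = {d.k_bar:.3f} mean pairwise differences")
print(f"pi = {d.pi:.4f} per site")
# Low pi with few haplotypes is typical of a small, recently bottlenecked
# or recently expanded mtDNA sample.
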