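"""One-off generator for the packaged synthetic reference FASTA.

Produces a 16,569 bp circular sequence with human-mtDNA-like base
composition (L-strand: A 31%, C 31%, G 13%, T 25%), with the reference
alleles of the packaged polymorphism snapshot planted at their positions
and the two microsatellite polyC motifs planted at 302-315 and 16184-16193.
"""
import numpy as np

L = 16569
rng = np.random.default_rng(20170911)
bases = np.array(list("ACGT"))
probs = [0.309, 0.313, 0.131, 0.247]
seq = list(rng.choice(bases, size=L, p=probs))

# polyC microsatellite motifs (1-based coords -> 0-based index)
for pos in range(302, 316):
    seq[pos - 1] = "C"
for pos in range(16184, 16194):
    seq[pos - 1] = "C"
seq[16189 - 1] = "T"  # the interrupted polyC stretch

db_refs = {
    73: "A", 146: "T", 263: "A", 489: "T", 750: "A", 1438: "A", 2706: "A",
    3010: "G", 4769: "A", 7028: "C", 8860: "A", 9540: "T", 10398: "A",
    10873: "T", 11719: "G", 12705: "C", 14766: "C", 15326: "A",
    16189: "T", 16519: "T",
}
for pos, b in db_refs.items():
    seq[pos - 1] = b

s = "".join(seq)
assert len(s) == L
header = (">NC_012920_synthetic synthetic stand-in for the 16,569 bp human "
          "mitochondrial reference (rCRS-scale, circular); not the real rCRS sequence")
with open("src/mtlineage/data/rcrs_synthetic.fa", "w") as out:
    out.write(header + "\n")
    for i in range(0, L, 70):
        out.write(s[i:i + 70] + "\n")
print("written", len(s))
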