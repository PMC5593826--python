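# Methods

## Coordinate and naming conventions

All genome coordinates are 1-based inclusive on the circular mitochondrial
map; an interval whose start exceeds its end wraps through the origin (the
control region / D-LOOP is fixed at 16024–576, the MITOMAP convention).
BED exports convert to 0-based half-open at the I/O boundary only, splitting
wrapping intervals into two records. Variant labels follow the compact
mitochondrial dialect: `G3036A` (substitution), `66 del-G` (deletion,
anchored on the first deleted base) and `12384^12385-ins C` (insertion,
anchored on the 5′ flanking base); parsing and formatting round-trip.
Substitutions collapse into strand-symmetric spectrum classes
`T>C/A>G`, `G>A/C>T` and `other` (all transversions and indels).

## Packaged reference data

Real NC_012920 sequence data is not redistributed. The packaged FASTA
(`data/rcrs_synthetic.fa`) is a **synthetic stand-in**: 16,569 bp, generated
once with a fixed seed at human mtDNA L-strand base composition
(A 31 %, C 31 %, G 13 %, T 25 %), with two constraints planted so the rest
of the packaged data is internally consistent — the reference alleles of
every packaged polymorphism record (e.g. A at 10398, T at 16189) and the two
polyC microsatellite motifs at 302–315 and 16184–16193 (with the
interrupting T at 16189). Every coordinate-level behaviour (region lookup,
panel geometry, wrap handling) is exactly as on the real reference; only the
base identities elsewhere are synthetic, so variant labels produced by the
simulator are reference-build-dependent. Users with the real rCRS can pass
it via `--reference`/`reference:`; nothing in the code assumes the synthetic
sequence.

The region table (`data/regions_rcrs.tsv`) carries the standard 37-gene
annotation (13 protein-coding, 2 rRNA, 22 tRNA) plus the control region and
the two microsatellites. The polymorphism snapshot
(`data/mito_polymorphisms.tsv`) is a 20-site excerpt of well-known
population polymorphisms with source (MITOMAP/dbSNP/HAPMAP) and a
disease-association flag; it is a frozen file — no live database access.

## Panel design

The circle is tiled with `n_amplicons` inserts whose starts sit at
`round(i·L/n)+1`, so steps differ by at most 1 bp and the tiling closes
exactly (a strictly uniform step cannot, since `L/n` is rarely integral);
each insert runs `min_overlap` bases past the next start. Defaults —
108 amplicons, mean insert 160 bp, 6 bp minimum overlap, 22 bp primers,
4 pools — give inserts of 159–160 bp, full circular coverage with overlap
zones covered exactly twice, and a wrapping final amplicon. Primer
thermodynamics is out of scope: primers are defined geometrically as the
flanking reference 22-mers, which is what every downstream stage consumes.

Pool assignment is round-robin by amplicon ordinal with greedy repair of
residual conflicts; for a circular chain whose length is a multiple of the
pool count this is conflict-free and perfectly balanced by construction
(4 pools × 27). An odd cycle with two pools is correctly rejected as
unsatisfiable.

## Synthetic cohorts

A patient is a rooted clonal tree whose leaves are lesions (`TN1`, `TN2`,
…). Germline polymorphisms (drawn from the packaged snapshot so annotation
recognises them) and trunk variants sit above the root; branch variants on
internal nodes (one, or two nested, depending on lesion count and the
requested branch count); private variants round-robin over leaves. With two
lesions no internal edge exists and branch variants are re-allocated
alternately to trunk and private. Planted positions avoid primer footprints
(a variant under a primer would be invisible in that amplicon's error-free
primer bases and half-visible overall) and never collide; single-base indels
are only planted where their placement is unambiguous (no homopolymer
shift), so the planted anchor equals the aligned anchor.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| `lesions_per_patient` | (2, 4) | multi-lesion cohorts have 2–4 nodules per patient |
| `n_germline` | 10 | homoplasmic polymorphism load per patient |
| `n_trunk`, `n_branch`, `n_private` | 3, 2, 2 | a few somatic marks per category |
| VAF distribution | Beta(0.8, 0.8) truncated to [0.05, 1], plus a 0.2 point-mass at 1.0 | tumour mt-variants are mostly homoplasmic or highly heteroplasmic |
| `depth_mean`, `depth_dispersion` | 2000, 20 | ultra-deep per-amplicon coverage, thousands of read pairs, overdispersed (negative binomial) |
| `deamination_rate` | 0.005 | probability per vulnerable C/G site of acquiring an FFPE artifact in a lesion (a modelling choice; the assay literature gives no single number) |
| `artifact_vaf_max` | 0.01 | FFPE deamination artifacts live at sub-percent allele fractions; the 5 % calling floor is the designed defence |
| `sequencing_error_rate` | 0.001 | flat per-base substitution error |
| `off_target_fraction` | 0.025 | matches ~97.5 % on-target specificity |
| `read_length` | 300 | 2×300 bp chemistry; every read spans its full insert |

Reads: each fragment is forward-primer + insert + reverse-primer site; read 1
is the fragment, read 2 its reverse complement. Variant carriage is decided
per *fragment* (both mates agree — they sequence one template), so the
independent-trial count behind an observed VAF is the fragment count, i.e.
half the read depth; tests use that in their binomial error bars. Sequencing
errors are applied per mate independently; primer bases stay error-free so
amplicon assignment by primer prefix is exact, which removes the need for a
production aligner. Off-target pairs come from a scrambled decoy and are
labelled in the FASTQ header (`target=off`), giving a truth label for
specificity accounting. Identical config + seed yields byte-identical FASTQ
and truth files.

What the generator does **not** model — and hence what green tests do not
show about real data: base-quality variation (flat Q40), indel sequencing
errors, PCR duplicates and polymerase stutter in homopolymers, NUMT
(nuclear-pseudogene) cross-mapping, primer-site variants dropping an
amplicon, and real FFPE fragment-length distributions. The artifact model is
deliberately the idealised version of the deamination mechanism the
threshold filter is designed against.

## Calling

Pileups are dense strand-split count arrays; reads of the expected insert
length are counted by vectorised column comparison, length-changed reads
(planted indels) are aligned to their insert with edlib and walked via the
CIGAR. Deletions count a `gap` at each deleted column (the read still spans
it, so it contributes to depth) and one deletion event anchored at the first
deleted base; insertions count one event at the 5′ anchor and do not add to
depth (the carrying read is already counted by its anchor base).

A call is emitted per (position, alternate allele) when depth ≥ 30 and
VAF ≥ 5 %; "balanced forward–backward performance > 0.2" is operationalised
as minor-strand alt fraction strictly greater than 0.2 (the commercial
workbench statistic behind that phrase is undocumented; this is the natural
reading). Sites failing only the strand test are emitted with a
`strand_imbalance` flag rather than dropped. Multi-allelic sites emit one
call per qualifying allele. Homoplasmy is VAF ≥ 0.95, boundary inclusive —
the threshold mirrors the 5 % calling floor symmetrically and is
configurable; no canonical value exists.

Run metrics: specificity = mapped/total reads (%), covered fraction = % of
positions at depth ≥ 30, and mean reads per 100 bp window (each read counts
toward every window its insert overlaps).

## Filtering

The four heuristics are pure functions of the cohort snapshot, so they
commute and never delete rows:

- **recurrent_similar_vaf** — same (position, alt) in ≥ 3 patients with VAF
  spread ≤ 0.05 (both configurable; no canonical quantification of "similar
  frequency" exists). Known homoplasmic polymorphisms are exempt: true
  shared germline alleles recur at VAF ≈ 1 by nature.
- **amplicon_end** — within 5 bp (configurable) of an insert boundary of
  *every* covering amplicon; interior to any overlapping neighbour exempts.
- **repetitive_region** — inside a microsatellite-category region. Deeper
  NUMT-homology masking would need a nuclear-genome alignment and is out of
  scope; an exclusion BED can be supplied instead.
- **noisy_region** — per position, background noise is the mean non-reference
  fraction over samples *not* carrying a call there (carrier exclusion stops
  true variants flagging themselves); positions above the cohort's 0.99
  noise quantile flag their calls. Needs ≥ 3 samples.

Flagged calls go to a review table with flag provenance and a
`needs_orthogonal_confirmation` marker — the in-silico analogue of deciding
between discarding an obvious artifact and re-checking by Sanger — so the
pass/review split is an auditable partition, never a silent deletion.

## Clonality

Somatic status without a matched normal is necessarily heuristic: a call
annotated as a known polymorphism *and* homoplasmic in every lesion of the
patient is treated as germline; everything else is a somatic candidate.
Presence of a variant in a lesion means a PASS call with VAF ≥ 0.05 there
(the calling floor; an optional rescue re-inspection of raw pileups at lower
VAF in non-carrier lesions was considered and left out — it belongs with an
orthogonal-confirmation workflow, not the default batch path).

Carrier sets classify variants: all lesions → trunk, proper subset ≥ 2 →
branch, singleton → private; the three categories partition the somatic set.
A laminar carrier-set family (any two nested or disjoint) is exactly the
clade family of a rooted tree, which is built directly with variants on
edges. Non-laminar families occur in real cohorts (two branch variants with
overlapping, non-nested carrier sets); the reconstruction keeps a maximal
laminar subfamily — greedily by descending variant support, then larger set,
then smaller minimum position — and reports every crossing pair as a
conflict instead of forcing a tree.

Verdicts: **untrackable** when no somatic variant remains (only shared
homoplasmic polymorphisms — nothing to track); **monoclonal** when any
somatic variant is shared by ≥ 2 lesions — a trunk variant proves a common
origin of all lesions, and a branch variant equally proves it for its
carriers, so shared-subset-only evidence is still scored monoclonal;
**independent** when somatic variants exist but no two lesions share any.
Evidence counts (trunk/branch/private/polymorphisms) accompany every verdict
so the strength of the call is visible. Subclonal VAF trends (branch
variants rising along an expansion) are reported descriptively in the
per-patient table, not tested statistically.

## Pipeline and numerical choices

`run-all` processes every lesion of every patient with one threshold set
(batch comparability; per-sample overrides are deliberately unsupported).
Randomness derives from one seed through `numpy.random.SeedSequence.spawn`,
one child per patient, so outputs are byte-identical across runs; the run
log (timestamps) is the only exception and carries the config hash and
package version for audit. Config files are YAML validated against a strict
schema (unknown keys rejected with their key path; defaults: depth 30,
VAF 5 %, strand balance 0.2, homoplasmy 0.95, 108 amplicons, 4 pools).

Desk-scale problem sizes used by the test suite and demo — depth 250–800,
1–3 patients, 20 seeds for caller recovery, 50 seeds for tree recovery —
are chosen so the full suite runs in about a minute while keeping every
binomial check well-powered; the generator's own defaults stay at the
study-scale depth of thousands.

Ties and degenerate inputs: multi-allelic candidates are ordered by allele
representation; empty pileups yield empty call lists; a deletion whose first
base is position 1 left-anchors at the origin boundary in VCF output;
single-lesion patients are rejected for clonality rather than silently
verdicted.

## Known limitations

- No real-alignment ingestion path: amplicon assignment relies on exact
  primer prefixes, which is valid for the simulator's reads but not for
  arbitrary BAMs; NUMT exclusion is delegated to whatever produced the input
  reads.
- The polymorphism snapshot is a small excerpt, not a full database; novel
  homoplasmic germline variants will be mis-treated as somatic candidates
  (they inflate trunk counts, never break the partition).
- The strand-balance statistic assumes roughly balanced strand sampling, as
  amplicon pairs provide; it is uninformative for single-strand protocols.
- Verdicts are rule-based evidence summaries, not probabilistic clonality
  inference; no confidence measure accompanies them.
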