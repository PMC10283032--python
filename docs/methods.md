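# Methods

## Genome model and coordinates

A mitogenome is modelled as the majority-strand (heavy, sequenced) string of
one circular molecule plus ordered features.  Interior coordinates are
0-based half-open; GenBank's 1-based inclusive convention is converted at
the I/O boundary only.  A feature spanning the arbitrary sequence origin
carries `wraps_origin=True` with `end <= start`; its length is
`L − start + end`.  Light-strand genes are stored reverse-complemented on
the majority strand and re-oriented on extraction.  Duplicate gene/CDS
annotations over one span (common in GenBank records) collapse to the most
specific feature type; unknown feature types are kept as `other` and
excluded from all partitions.  The duplicated Leu/Ser tRNAs are
disambiguated by anticodon when one is annotated, otherwise by order of
appearance against the canonical arrangement (Leu(UUR) and Ser(UCN) come
first).  `N` bases are preserved verbatim.

## Composition and skew

`AT-skew = (A − T)/(A + T)` and `GC-skew = (G − C)/(G + C)`; a zero
denominator yields an undefined value (`None`), not an error.  Ambiguous
bases are excluded from every percentage and skew denominator — the
convention is deterministic and alphabet-safe where published tables are
silent.  Partition rows (whole genome, concatenated PCGs / rRNAs / tRNAs,
control region) use majority-strand slices concatenated in genome order, the
convention under which whole-genome composition tables are computed; this is
what makes *ND6* flip to a positive majority-strand GC-skew while its
coding-strand profile stays negative.  Per-gene profiles use the coding
strand for stranded genes and the majority strand for the control region.
Overlapping genes contribute their full spans to their partitions (bases may
be counted twice across genes but once in the whole-genome row).  Codon-
position composition drops the 1–2 bases of incomplete terminal codons per
gene before pooling.  Rounding (A+T% to 1 decimal, skews to 2, distances to
5) lives only in the report renderers; all computation is full precision.

## Codon usage and RSCU

The genetic code is fixed to the vertebrate mitochondrial table (AGA/AGG
stop, ATA Met, TGA Trp), giving 20 amino-acid families plus one 4-member
stop family.  `RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij)`; families with zero
total get RSCU 0 and class `unused-family`.  Bias classes: > 1.6
overrepresented, (1.0, 1.6] positive, exactly 1.0 unbiased, [0.6, 1.0)
negative, < 0.6 underrepresented.  Codon counting reads frame 0, drops
trailing incomplete codons (tallied separately — they are the province of
the stop-codon report) and drops codons containing ambiguity.  Amino-acid
usage pools each amino acid's full synonymous family (both Leu and both Ser
sub-families jointly); the stop family is excluded from most/least ranking
and ties are broken alphabetically and flagged.

## Gene architecture

The embedded canonical constant is the typical vertebrate arrangement: 39
elements from tRNA-Phe through the control region, with OL inside the WANCY
tRNA cluster and the light-strand set {ND6 + 8 tRNAs}.  Order comparison is
rotation-invariant, anchored at tRNA-Phe (fallback: lexicographically
smallest rotation, flagged).  Cluster detection requires members strictly
adjacent in order, with the noncoding elements (OL, control region)
transparent to adjacency — otherwise the OL embedded in WANCY would defeat
the cluster it names.  Start codons are the first three coding-strand
bases; the stop codon is the final `length mod 3` bases (3 for codon-
multiple lengths) padded with `-`, classifying TA-/T-- terminations as
incomplete.  Because published values for light-strand genes are sometimes
read off the majority strand, light-strand CDS reports carry both the
coding-strand and the majority-strand codons; neither convention is
asserted as "correct".  Adjacent-pair gaps are signed (positive spacer,
negative overlap, zero abutting) and computed around the circle, so feature
lengths plus gaps tile the genome exactly; the published phrase "intronic
regions" is implemented as intergenic spacers, since mitochondrial genes
lack introns.

## Distances

K2P with pairwise deletion: columns with a gap or ambiguous base in either
sequence are excluded before `P` (transitions) and `Q` (transversions) are
computed; `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`.  Saturation (a non-positive
logarithm argument) raises a descriptive error in the scalar API and is
flagged per cell (NaN) in the matrix API.  Pairwise deletion is the common
default in distance software and the least destructive choice where the
alignment protocol behind published distances is unstated; whole-genome
reproduction of such values therefore carries an alignment-protocol caveat.
Alignment itself is out of scope: the module consumes aligned FASTA
(`--assume-aligned` allows direct pairing of equal-length sequences).

## Read trimming

While the mean Phred quality of the final `min(window, length)` bases is
below the threshold, the last `trim_step` bases are removed; a read below
`min_len` at any point (including on input) is removed outright — the
prefix/length invariant (output in {removed} ∪ [min_len, input length])
forces the input-length rule, which the original description leaves
undocumented.  A mean exactly at the threshold passes: the trigger clause
("lower than") is primary.  Defaults: window 30, threshold 16, step 15,
minimum length 25, Sanger offset 33.  Only the 3' end is trimmed; adapter
removal and paired-end logic are out of scope for single-end Ion
Torrent-style data.

## Synthetic data

The generator is the package's study-condition stand-in, not a fixture: it
emulates a ~16.4–16.6 kb circular genome with the canonical 39 elements.
Protein-coding genes are generated codon-wise — amino acids drawn from a
fish-mitochondrion-like proteome profile (Leu ≈ 17%, Cys ≈ 1.1%, reduced
Gly/Trp), synonymous codons weighted by third-position base
(A 0.36, C 0.33, T 0.16, G 0.15) — which reproduces the observed A/C-ending
RSCU bias, the second-position G depletion, Leu ≈ 650 and Cys ≈ 42 codons
per genome, and whole-genome A+T ≈ 54–55%.  Gene lengths: fixed typical
CDS sizes (168–1839 bp), tRNAs uniform 65–76 bp, rRNAs 950/1700 bp, control
region uniform 603–862 bp and more AT-rich (66%), random spacers 0–3 bp
with user-injectable spacer lengths.  Start/stop conventions follow the
common teleost pattern (GTG start for COI; T--/TA-/AGA stops on
COII/ND3/CYTB, ND2/COIII, ND4).  Noncoding partitions are sampled i.i.d.
from base probabilities realizing the target A+T% and skews exactly in
expectation; `codon_model=False` extends that sampling to CDS bodies for
clean parameter-recovery checks.  Mutation applies per-site independent
transitions (`p_ts`) and transversions (`p_tv`, uniform over the two
options), so the analytic expectation of the recovered K2P distance is the
closed form evaluated at (p_ts, p_tv).  Reads are sampled uniformly from
the circular genome on both strands, lengths normal (mean 374, sd 80,
floor 50), per-position quality `qv_start − qv_decay·i` plus Gaussian noise
clipped to [0, 40].  A single root seed spawns substreams for genome,
mutation and reads.

What the generator deliberately does not model: sequencing indels and
homopolymer errors, coverage structure, tRNA secondary structure,
between-gene compositional heterogeneity beyond the partition level, and
codon autocorrelation.  Passing tests therefore demonstrate correctness of
the statistics and pipelines under the stated generative model, not
robustness to every artefact of real records.

## Problem sizes

The default suite and the acceptance script use five-genome panels
(~82 kb of sequence), 16 kb mutated pairs with 20–50 replicates for
distance recovery, 10,000-read trimming runs, and 100 rotated genomes for
order-invariance checks — sizes at which binomial standard errors on the
recovered parameters are a few tenths of a percent.

## Known limitations

GenBank parsing targets well-formed flat files with the usual qualifier
conventions; exotic location strings beyond origin-spanning two-part joins
are not interpreted.  The gene-name normalizer covers the common
MitoAnnotator/MITOS/GenBank dialects and passes unknown names through with
a warning flag rather than guessing.  Distance computation offers the K2P
model only.
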