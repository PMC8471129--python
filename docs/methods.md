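# Methods

## Scope and data model

`mitochar` analyzes annotated circular mitochondrial genomes of the insect
type: 13 protein-coding genes (PCGs), 22 tRNAs, two rRNAs and one A+T-rich
control region (CR). Internally all coordinates are 0-based half-open on
the majority strand (J); GenBank I/O converts from/to 1-based inclusive,
and a CDS annotated as `join(a..L,1..b)` on a circular record becomes a
single origin-wrapping feature. Gene labels are normalized to one
canonical vocabulary (COX1…COX3, ATP6/8, ND1–6, ND4L, CYTB, trnX with
trnL1/L2 and trnS1/S2 disambiguated by anticodon or isotype tag, rrnL/rrnS,
CR); unrecognized features are preserved in record metadata rather than
dropped. De novo annotation and tRNA secondary-structure prediction are out
of scope.

## Composition and skews

A+T content and AT/GC skews are computed from exact integer counts.
Ambiguity codes are counted separately and excluded from every denominator,
so a skew with a zero denominator is reported as null (undefined), never
as 0 — "compositionally balanced" and "bases absent" are different facts.
Region pools follow the conventional reporting layout: whole molecule,
J-strand PCGs, N-strand PCGs (both in coding sense), all PCGs, pooled
tRNAs, pooled rRNAs, CR. Overlapping genes contribute their full spans to
each pool, so region lengths equal sums of gene lengths. Report rounding
is one decimal for A+T% and two for skews; full precision is kept
internally.

## Codon analyses

Translation and codon counting use NCBI table 5. Terminal classification
is driven by annotated length mod 3: remainder 0 requires a TAA/TAG stop
(flagged otherwise), remainder 1 is an incomplete `T` stop, remainder 2 an
incomplete `TA` stop; starts are classified ATN / GTG / nonstandard.
Pooled codon counting **includes the initiation codon and excludes the
terminal stop** by default — conventions differ between published RSCU
figures, so both toggles are exposed and the default is fixed here for
reproducibility, not asserted as anyone else's choice. RSCU for codons of
an amino acid absent from the data is null (0/0 is undefined). Codons
containing ambiguity letters are tallied separately.

## Gene architecture

The gene order is read in J-strand positional order, rotated to trnI, and
compared by breakpoint distance on circular signed orders (adjacencies are
canonicalized so that reading the circle backwards with flipped strands is
the same circle). Full rearrangement-event inference (inversions, DCJ,
tandem-duplication-random-loss) is deliberately not attempted.

Junctions between positionally consecutive features are classified as
spacer / abutting / overlap; the full junction list always covers the
circle, so Σ gene lengths + Σ spacers − Σ overlaps = genome length (checked
exactly on synthetic genomes). The *summary* counts follow the compact-
mitogenome reporting convention in which a spacer flanking the CR is not an
intergenic region (the CR itself is the spacer); published counts are
ambiguous on this point, so `include_cr_junctions=True` switches to the
all-junctions convention and the deposited-record checks accept either.
Overlap sequences are reported on the J strand regardless of gene strands,
and overlaps shared by all input genomes get a minimal-ambiguity IUPAC
consensus (e.g. the conserved 8 bp trnW/trnC overlap AAGYCTTA).

## Repeat detection

Tandem repeats are found by self-alignment at each candidate lag
u ∈ [min_unit, max_unit] (defaults 10–300 bp): the boolean profile
m[i] = (seq[i] == seq[i+u]) is seeded by runs of ≥ 8 consecutive matches
(processed longest-first so the clean core of an array fixes the block
phase), then extended one u-block at a time while each block's own identity
stays ≥ min_identity (default 0.85), plus fractional leading/trailing
partial copies. Block-wise extension is what keeps calls from leaking into
AT-rich flanking sequence, where per-position match probability is ~0.34.

Accepted calls must reach min_copies (default 2.0) and overall identity ≥
min_identity, and must survive a one-sided binomial significance filter:
the probability of the observed match count under an i.i.d. uniform null
(p = 1/4) must be ≤ 1e-6. The fixed uniform null is intentional — an
AT-rich null would reject genuine short exact duplications (e.g. a 10 bp
unit × 2), while the uniform null admits them and still rejects the
borderline ~85%-identity periodicities that arise by chance in random
sequence. `alpha=1` disables the filter for exhaustive small-scale
periodicity testing.

Consensus units are column-majority over full blocks; a consensus that is
itself periodic is reduced to its primitive unit, with the span re-derived
at the primitive lag (carrying the coarse-lag span over would inflate copy
numbers with chance matches). Overlapping calls across lags are merged by
most matched positions, then smaller unit — a fine-lag call always
out-matches a coarse multiple-lag description of the same array, so the
primitive description wins. Known limitation: arrays whose copies are
≲ 95% identical may be reported at a multiple of the primitive unit (when
adjacent copies share correlated differences) or with fewer copies;
near-identical arrays, the norm in insect control regions, are recovered
exactly. Wraparound repeats across the CR boundary and gapped alignment
are not attempted.

Dispersed (non-tandem) repeats use exact 12-mer seeding, the same
block-wise extension at ≥ 0.9 identity over ≥ 50 bp, exclusion of pairs
whose aligned length reaches their separation (those are tandem), and
masking of detected tandem arrays so array-internal harmonics are not
reported as dispersed pairs.

## Supermatrix assembly

Coding-sense PCG sequences are exported per gene; alignment, conserved-
block filtering, saturation testing, model selection and tree inference
are external tools by design — this module consumes aligned FASTA and
produces inference-ready files. Codon phase is taken from annotation
(row 1 = first codon position); rows are gap-padded to a multiple of 3
first, so incomplete terminal codons keep frame. Position stripping keeps
any subset of {1,2,3}; concatenation gap-fills taxa missing from a gene
and records 1-based inclusive partitions that tile the matrix exactly.
Output formats: relaxed PHYLIP, NEXUS with charsets, FASTA, and
RAxML-style partition files; taxon names are sanitized for PHYLIP/NEXUS
with collisions rejected.

## Synthetic data generator

The generator emulates the study conditions of recently described
phasmatodean mitogenomes: ancestral insect gene order; default gene sizes
summing to 11,178 bp of PCGs, 1,454 bp of tRNAs, 2,070 bp of rRNAs and a
2,200 bp CR (total ≈ 16.9 kb); genome A+T fraction 0.756 with J-strand
AT skew +0.19 and GC skew −0.22; CR A+T fraction 0.80; five planted
intergenic spacers totalling 41 bp (including the commonly reported long
trnI–trnQ and ND1–trnL1 insertions); the four conserved overlaps
trnW/trnC (8 bp, AAGTCTTA), COX1/trnL2 (5 bp, TCTAA), ATP8/ATP6 (4 bp),
ATP6/COX3 (1 bp, A); incomplete `T` stops on COX2 and ND5; and a 32 bp × 6
tandem array planted in the CR. All of these are configurable.

Base composition is controlled by solving p_A+p_T = AT-fraction plus the
two skew definitions under the unit-sum constraint (four probabilities,
fully determined). N-strand features sample their coding sense from the
mirrored distribution so the J-strand projection carries the genome-wide
skew. PCG interiors are drawn codon-wise with stop codons rejected, which
guarantees clean ORFs but slightly depresses realized A+T (TAA/TAG are
AT-rich); the whole-genome A+T lands within ~0.5 points of target, well
inside the ±2-point tolerance the tests assert at n ≥ 10 kb. Planted
tandem units are resampled until aperiodic so the (unit, copies) ground
truth is unique. Multi-taxon sets descend from one generated ancestor by
i.i.d. substitutions with PCG third positions mutated at an elevated
multiplier (default 3×, capped at 0.75/site) to mimic third-position
saturation; substitutions can create internal stops in descendants, which
is acceptable because descendant genes are not claimed intact.

What the generator does **not** emulate: phylogenetically structured
sequence evolution (no tree, no rate heterogeneity beyond the codon-
position split), tRNA structural realism, heteroplasmy, and sequencing
error. Passing tests on synthetic data therefore validate the arithmetic
and the detection machinery under realistic composition and architecture,
not robustness to annotation errors in real records — that is what the
deposited-record checks (which require downloading MW450873–MW450875 into
`data/deposited/`) are for.

## Problem sizes and numerics

The default test and acceptance workloads are desk-scale by choice:
exhaustive formula checks on all ≤ 8 bp strings, 500 planted control
regions for repeat recovery (units 10–150 bp × 2–8 copies), 50 × 1 kb
uniform sequences for the false-positive screen, and a 13-gene × 81-taxon
supermatrix. Ties in codon ranking break alphabetically; consensus-column
ties break toward the first block; rounding of copy numbers to one decimal
matches integer copy counts by `round()`. Degenerate inputs (empty
sequence, missing CR, empty regions, length < one codon, min_unit >
max_unit) raise or return explicit markers rather than silent zeros.
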