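# Methods

## The scan

A coding sequence is framed from its `codon_start` (GenBank semantics:
leading bases before the annotated frame are trimmed) and every codon
except the last is tested against the stop set of the genome's translation
table — {TAA, TAG, TGA} for the standard bacterial code (table 11),
{TAA, TAG} for table 4, where TGA decodes tryptophan. A gene is classified
**frameshift** iff at least one premature in-frame stop exists;
**no_frameshift** otherwise; **gene_absent** when no *prfB* (or *prfA*) can
be selected from the annotation; **unscannable** when the framed length is
shorter than two codons or not a multiple of three. Classification depends
only on premature-stop presence; the motif elements below are descriptive.
Codons containing N never count as stops (conservative), and when several
premature stops exist the 5'-most anchors the motif while all are retained.

For joined or frameshift-annotated CDS the scanned sequence is the
contiguous genomic span from the 5' end of the first segment to the 3' end
of the last, read in the frame of the first segment — not the spliced
concatenation — so a programmed premature stop stays visible in frame 0.
This is one defensible realization of an underspecified step and is the
package's own choice. Pseudogenes are retained, scanned, and flagged.

## Motif characterization

Around the 5'-most premature stop (stop start at 0-based offset `o`):

- **Slippery run** — `cds[o-3 : o+1]`, the codon before the stop plus the
  stop's first nucleotide; canonical iff exactly `CTTT` (poly-T variants
  such as `TTTT`, where tRNA-Phe rather than tRNA-Leu would occupy the P
  site, are reported but flagged non-canonical).
- **SD-like element** — best ungapped placement of the anti-SD reference
  against the upstream sequence, scoring Watson-Crick pairs plus G·T(U)
  wobble, one point per paired base. The reference is DNA `TCCTCC`,
  representing the 16S 3' tail 3'-UCCUCC-5'; this is the simplest rule
  that scores both `AGGAGG` and `AGGGGG` maximally (6). Placements are
  constrained so the element's 3' end sits `min_spacer`..`max_spacer`
  (defaults 2..8) nt upstream of the slippery start; score ties break
  toward the stop-proximal placement, since the mechanism requires defined
  spacing to the slippery site; matches scoring below `min_sd_score`
  (default 4) are reported as absent.
- **Following nucleotide** — the base after the stop (`o+3`), conserved as
  C because `TGAC` terminates poorly.
- **Window** — `cds[o-15 : o+5]` (parameters `upstream`/`downstream`,
  defaults 15 and 4 nt around the stop start), clipped at sequence bounds,
  with the stop-start anchor recorded so clipped windows still stack
  correctly in the logo.

## Expected-region projection

For frameshift-negative sequences the motif region is located through a
user-supplied alignment (the package consumes, never computes, alignments):
each motif-positive row's stop start is mapped to its alignment column, the
modal column (ties → smallest) anchors a `[anchor − 15, anchor + 4]` column
interval, and the target row's residues in that interval are returned with
gaps removed. The modal-anchor rule is a deterministic choice among several
defensible ones and is named in the output metadata.

## Logo math

Windows are stacked anchor-aligned (not left-aligned). Per position:
counts over {A,C,G,T} (N and out-of-window positions contribute nothing),
plug-in frequencies over the position's coverage, and information
`I_j = log2 4 + Σ_b f_b log2 f_b` bits against the uniform background
(0·log 0 := 0), so `I ∈ [0, 2]` with 2 bits at full conservation and 0 at
uniformity; a non-uniform background switches to relative entropy. The
small-sample correction `3/(2 ln 2 · n)` is available behind a flag and off
by default — the plain Schneider formula is the documented choice.
Consensus calling takes the modal base, writing `N` on exact ties and `.`
at zero coverage.

## Per-genome statistics

GC is `(G+C)/(A+C+G+T)` with ambiguity codes ignored; the pipeline uses the
genome-level value computed at parse time (standing in for database GC).
Terminal stop usage classifies the last three nucleotides of every CDS;
fractions are over canonical-stop-ending CDS only, with other endings
tallied separately so mis-annotations do not dilute the fractions. A
TGA-suppressor call is sequence-based — any tRNA with anticodon TCA/UCA,
regardless of the annotated amino acid — because annotation labels vary.

## Group comparison

All comparisons are Welch two-sample t-tests:
`t = (x̄ − ȳ)/√(s²x/n_x + s²y/n_y)` with Welch-Satterthwaite degrees of
freedom and two-sided p from the t distribution (scipy's t-CDF; the test
suite cross-checks p against direct numerical quadrature of the t density
to 1e-6). Degenerate inputs: two constant samples give t = 0, p = 1 when
means agree and p = 0 with a degeneracy note otherwise. No
multiple-testing correction is applied anywhere — comparisons are reported
singly. Random genome subsets order items by string form and draw without
replacement from `numpy.random.PCG64`, named in the run manifest so seeds
are portable. Per-taxon aggregation excludes `gene_absent`/`unscannable`
genomes from the percentage denominator and reports them separately.
Frameshifting efficiency of a two-band reporter is
`I_fs / (I_fs + I_term)`.

## The synthetic-data generator

Each genome is assembled from random-strand ORFs separated by 20–60 nt
intergenic spacers, one or two tRNAs, and a source feature carrying
phylum and CheckM-contamination metadata. ORFs are ATG + sense codons +
a terminal stop drawn from the genome's stop distribution; sense codons
are sampled from GC-weighted base probabilities with stop codons
rejection-resampled, and the base-level GC is numerically calibrated
(bisection over the 61-codon expectation) so the rejection does not bias
realized GC — uncorrected, it would run ≈ 0.02 high. Realized genome-level
GC tracks the target within 0.02; per-CDS GC fluctuates with binomial
noise (≈ 0.03 SD at 300 nt), which is why the audit is at genome scale.

*prfB* (120 codons) optionally carries the planted motif
`AGGGGG·TAT·CTT·TGA·C` with the stop at codon 26; the spacer is the fixed
low-purine `TAT` so no competing SD placement can tie the planted one.
Partially-planted codons that happen to spell a stop are re-resolved in
their free positions. Element sites may then be mutated per-site; the
truth manifest records post-mutation reality (elements re-read from the
final sequence, premature stops re-enumerated by direct translation), i.e.
truth is what is on disk, not what was intended. An intact *prfA* is
emitted in every genome as the negative comparator. Table-4 genomes can
lack *prfB* entirely and then always carry a TCA-anticodon suppressor
tRNA, with zero terminal TGA usage.

Cohorts draw per-genome specs independently from one root seed
(`numpy.random.SeedSequence.spawn`, one child per genome, so cohorts are
reproducible piecewise): default motif prevalence 0.64; premature-stop
identities {TGA 0.986, TAA 0.014, TAG 0}; genome GC from
Normal(0.45, 0.05) for motif-positive and Normal(0.62, 0.05) for
motif-negative genomes (clipped to [0.25, 0.75]); terminal TGA usage tied
to GC by the logistic link `p_TGA = 1/(1 + e^{−12(GC − 0.52)})` with the
non-TGA mass split 0.8/0.2 between TAA and TAG; 1 % reduced table-4
genomes; 20 CDS of 80 codons per genome. These defaults are the study
conditions; the CDS count and lengths are kept at desk scale because the
statistics of interest (census proportions, stop-usage fractions, group
means) depend on the number of genomes and CDS draws, not on CDS length.

A second, summary-level mode (`simulate_group_summaries`) draws exactly the
per-genome quantities the group comparison consumes — GC from the group
normal, terminal-TGA fraction as a binomial at the linked probability —
without emitting sequences; replicate-heavy power studies use it, while
full-sequence cohorts back the end-to-end recovery and census checks
(500 genomes through GenBank write → parse → scan).

What the generator does **not** emulate: phylogenetic correlation between
genomes (draws are i.i.d. given the group), sequence evolution along a
tree, codon-usage bias beyond GC, operon structure, overlapping genes,
annotation errors other than the planted kinds, and real intergenic or
regulatory sequence. Passing tests therefore demonstrate correctness of
the measurement pipeline under the assumed population structure, not
robustness to real-data annotation noise or phylogenetic confounding.

## Numerical and edge-case choices

- External coordinates stay 1-based inclusive; internal offsets are
  0-based half-open; codon indices are 1-based.
- Out-of-bounds features are skipped with a per-record warning and
  counted, preserving feature-count conservation.
- Gene selection precedence: exact gene-name match, then product-string
  match ("release factor 2"/"RF2", resp. "…1"/"RF1"); equally ranked
  candidates flag the result ambiguous and return the first by coordinate.
- The contamination gate is strict (`< threshold`); genomes without a
  score pass with a warning — the gate acts on metadata availability, not
  sequence quality.
- Stop-identity censuses count each genome once via its 5'-most premature
  stop.
- Reports are sorted by accession and floats printed at fixed precision,
  so reruns are byte-identical; the GenBank writer pins the record date
  for the same reason.

## Problem sizes and limitations

The test suite and the acceptance script run cohorts of 500 genomes
(~1.1 k codon-sampled ORFs per genome-set stage), 1,000-sequence scanner
oracles, 2,000-replicate null calibrations and 100-replicate power
studies; together they complete in well under a minute on one CPU. Known
limitations: the SD scorer is a pairing count, not a thermodynamic duplex
model; no frameshift-efficiency prediction from sequence is attempted; the
expected-region anchor is one defensible rule among several; and per-taxon
results are only as good as the supplied taxonomy metadata.
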