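# Methods

`isoswitch` implements a desk-scale analysis chain for comparing a
knockdown transcriptome against a control: quantification, differential
expression, isoform-switch detection, structural classification of the
splicing difference between isoform pairs, motif scanning of the affected
splice-junction flanks, protein-level consequence prediction, and two
auxiliary analyses (phosphosite cross-referencing against a
splicing-machinery catalogue, and spectral-count enrichment for pulldown
baits). This note records the models, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer would want written down.

## Coordinates and sequence conventions

All internal coordinates are 0-based half-open on the forward reference
strand; GTF I/O converts to/from the 1-based inclusive file convention.
Sequence-facing operations return transcript-sense sequence
(reverse-complemented on the minus strand). `N` bases are allowed in the
genome; any scan window containing one scores minus infinity.

## Quantification and differential expression

TPM is computed with the standard definition
`tpm[i,s] = 1e6 * (count[i,s]/len_i) / sum_j(count[j,s]/len_j)`; columns
of an all-zero sample stay zero rather than propagating NaN. Gene-level
values are plain sums of transcript TPM.

The expression filter keeps a feature when its mean TPM is at least 1 in
either condition group; the boundary reads "below 1 removed", so a mean of
exactly 1 is kept.

The differential test is intentionally a lightweight stand-in for
bootstrap-based RNA-seq engines, whose uncertainty models are out of scope
here: `b` is the difference of group means of `log2(TPM + 0.5)`
(knockdown minus control; pseudocount 0.5 avoids log 0 and is symmetric),
the p-value is a Welch two-sample t-test on the same transform, and
q-values are Benjamini–Hochberg adjusted across features passing the
expression filter, per analysis level. Features are labelled
up/down at `q <= 0.05` (threshold configurable; some analyses in this
setting use 0.01 for single-gene claims, so it is a parameter rather than
a constant). With triplicates the Welch test has little power — its role
downstream is the `(b, q)` contract and null calibration, both of which it
satisfies; it is not a quantitative reimplementation of any published
engine. Degenerate input (zero variance in both groups, equal means)
yields p = 1 by definition rather than NaN.

## Isoform fractions and switch detection

A transcript's isoform fraction is `IF = transcript TPM / gene TPM` per
sample; samples where the gene is silent give missing IF and are excluded
from condition means. `dIF` is mean IF in knockdown minus mean IF in
control.

The usage test transforms per-sample IFs with a smoothed logit,
`logit((IF*(n-1) + 0.5)/n)` with `n` the total sample count, then applies
a **moderated** two-sample t-test: per-isoform pooled variances are shrunk
toward an empirical-Bayes prior `(d0, s0^2)` fitted by moment matching on
the log sample variances (the scaled-F model familiar from moderated
t-statistics in microarray/RNA-seq practice), and the residual degrees of
freedom are augmented by `d0`. When the observed spread of variances is
no larger than chi-square sampling noise, `d0` is infinite and the test
degenerates gracefully to a z-like test at the common variance. The
moderation matters: at 3-vs-3 replicates a plain Welch t-test cannot
produce p-values small enough to survive BH correction across ~1,000
isoforms (its minimum attainable p is about 7e-4), and the recovery
experiment below would sit near zero recall. With moderation, the
documented cohort yields recall 0.74 and precision 0.95 at Q < 0.1.

A switch call is a pair of isoforms of one gene with `dIF` above +0.05 and
below −0.05 respectively (the floor suppresses numerically trivial
opposite pairs and stands in for the manual inspection a human analyst
would apply) where at least one side has `q < 0.1`. All valid opposite
pairs are emitted for genes with more than two isoforms; the pair
maximising `|dIF_up| + |dIF_down|` is flagged `best_pair`.

## Splice-event classification

Two isoforms are compared on their internal splice-site chains (exon
boundaries excluding the transcript termini), each site typed as exon-end
or exon-start. Shared sites — plus shared transcript termini, which
anchor the frame — bound the comparison; differences outside the
outermost shared anchor are alternative transcription start/termination
and are not reported. Termini anchoring is needed because a retained
first intron between identical transcript starts is a genuine splicing
difference even though the two chains share no splice site.

Within the frame, each maximal run of disagreement between consecutive
shared sites (a bubble) is classified by its sub-chain pattern:

| pattern (shorter / longer sub-chain)       | class |
|--------------------------------------------|-------|
| empty / end+start pair (an extra intron)   | IR    |
| empty / start+end pair (an extra exon)     | ES    |
| one site each, same type, positions differ | A5 (donor side) or A3 (acceptor side), by strand |
| two exons, one private to each, disjoint   | ME    |
| anything else                              | complex |

Bubbles with more than one elementary difference are labelled `complex`
rather than decomposed — forcing a decomposition would invent structure
the comparison does not support. ME requires exactly two exclusive,
disjoint exons. The classifier is symmetric in its arguments, invariant
under coordinate mirroring combined with strand flip (the same molecule),
and swaps A5/A3 under strand relabeling; the test suite verifies it
against an independent exonic-coverage oracle on an exhaustive enumeration
of same-span exon chains (≤4 exons on a 12-position grid; >100,000
pairs).

`affected_junction_regions` maps an event to the introns whose flanks are
scanned: the retained intron itself for IR, the two introns flanking the
skipped exon for ES, and every junction private to one isoform otherwise.

## Flank regions and motif scanning

Around each affected intron, four 100-base regions are read in transcript
sense and converted to RNA: IR1 (exonic, 5' of the donor), IR2 (intronic,
3' of the donor), IR3 (intronic, 5' of the acceptor), IR4 (exonic, 3' of
the acceptor). In introns shorter than 200 bases, IR2 and IR3 are
truncated at the intron midpoint so they never overlap; truncated regions
are flagged. Exonic flanks are fixed-width genomic windows (they may
extend past a short exon into the neighbouring intron, as a fixed-window
analysis does).

PWMs are position probability matrices over A/C/G/U. Scores are
`log2((p + pc*0.25) / (0.25 + pc*0.25))` summed over the window, with
uniform 0.25 background and pseudocount `pc = 1e-3`; a window is a hit at
score ≥ 6 (inclusive — conventional for score cutoffs). Base,
background and pseudocount are configurable since scanning services do
not publish their exact constants. Scanning is sense-strand only: these
are RNA-binding proteins and the antisense strand is not part of the
transcript. The per-RBP × region count matrix pools hits over all events
(matching a single pooled heatmap across genes) and drops RBPs whose hits
fall in a single region, the analogue of removing singleton sites.

## Protein consequences

Translation starts from an explicitly supplied CDS offset — reference
proteins are known in practice, and silent ORF inference would add
unvalidated behaviour; a `longest_orf_start` helper exists but is never
called implicitly. Standard genetic code; stops TAA/TAG/TGA; translation
that runs off the mRNA is flagged `nonstop`.

Classification compares the reference and variant coding sequences via
longest common prefix/suffix: a difference entirely 5' of the CDS is
UTR-only (class `identical`), a difference overlapping the start codon is
`start_lost`, a length delta not divisible by three is
`frameshift_truncation` at the first divergent codon, an in-frame delta
whose protein is a pure contiguous block deletion/insertion is
`inframe_deletion`/`inframe_insertion` (the insertion class covers
in-frame intron retention without a stop codon, which the deletion-only
vocabulary cannot express), and an in-frame delta interrupted by a novel
stop is `stop_gain_truncation`. The invariants — in-frame ⇔ delta ≡ 0
(mod 3) with no introduced stop — are verified exhaustively on an
engineered stop-free coding cohort.

## Phosphosites and pulldowns

Phosphosite records carry LT_LIT / MS_LIT / MS_CST evidence counts. A
site passes when LT_LIT ≥ 1 or the high-throughput count reaches 3; "three
or more high-throughput experiments (MS_LIT and MS_CST)" is read as the
*sum* of the two columns (the parenthetical groups both under one count),
with an `either`-column mode available. Residue splitting partitions into
S/T/Y and counts unknown codes. The catalogue cross-reference keeps
tyrosine sites on catalogue proteins and flags exact (protein, position)
matches against Src-family rows of a kinase-substrate table; isoform
position offsets are not reconciled. Subclass proportion columns are
percentages and sum to 100 per non-empty dataset.

Pulldown enrichment uses a likelihood-ratio (G) test on spectral counts
summed over replicates, bait vs GST control, with library-size offsets and
BH correction; a protein is an interactor at `q <= 0.05` in the enriched
direction. The test consumes only summed counts, so a single replicate
degrades to the pooled comparison by construction. emPAI is
`10^(observed/observable) − 1` with observable peptides from an in silico
tryptic digest (cleave after K/R, never before P, zero missed cleavages,
via pyteomics) filtered to monoisotopic mass 500–5000 Da — typical LC-MS/MS
observability bounds, configurable.

## Synthetic data: what it emulates and what it does not

The generator builds one gene per chromosome with 4–8 exons of 90–300
bases and introns of 250–500 bases (long enough that the four flank
regions of a junction never collide), i.i.d. uniform A/C/G/T sequence,
and exactly two isoforms per gene differing by one planted event drawn
from the mix ES 0.30 / IR 0.30 / A5 0.15 / A3 0.15 / ME 0.10 — exon
skipping and intron retention dominate, as they do in the knockdown
setting this emulates. Events are planted strictly internal to the shared
splice-site frame so each is recoverable by the classifier.

Counts are negative binomial (variance μ + φμ², dispersion φ = 0.1 —
mid-range for bulk RNA-seq replicates) with expected totals of 1e6 per
sample across 3 control and 3 knockdown replicates, gene abundances
uniform on 5–200 in TPM-like units, and expected counts proportional to
abundance × isoform fraction × length, so TPM recovers the planted
fractions. A configurable fraction of genes (0.1 by default) receives an
isoform-usage shift of ±0.3 between conditions, applied with opposite
signs to the two isoforms. No published effect-size distribution exists
for real switches; these are free parameters and are documented as such.
Motif plantings overwrite genome sequence with a PWM's consensus word at
recorded offsets inside flank regions, with chromosome-wide collision
avoidance. Phosphosite and spectral-count tables are generated with
recorded pass counts and enriched sets; the neuronal-bait interactor set
is a subset of the other bait's by construction.

The generator does not emulate: read-level data (alignment and
quantification noise beyond NB counting), positional coverage biases,
multi-isoform genes beyond pairs, correlated replicates, sequence
composition (real splice sites, branch points), motif co-occurrence
structure, or real database content for phosphosites. Passing tests
therefore demonstrate that the algorithms recover what was planted under
the stated noise model, not performance on real libraries.

A second, separate cohort (`simulate_cds_cohort`) engineers stop-free
reading frames with controlled length deltas (159/160-nt cassette exons,
261/262-nt retained introns, 33/34-nt boundary shifts, optional in-frame
planted stops) to exercise the consequence classes non-trivially; on
uniform random sequence a premature stop almost always precedes the event
and every call would be `identical`.

## Determinism and problem sizes

Every stochastic stage draws from `default_rng([seed, crc32(stage_name)])`
so stages re-run independently and full runs are byte-reproducible; the
pipeline summary JSON is sorted and timestamp-free, and two runs with the
same seed hash identically. Default scales — 500 genes for the recovery
experiment, 1,000-row phosphosite tables, 300-protein pulldowns, a
60-gene pipeline demo — were chosen so that every property of interest
(power, calibration, recovery) is measurable with stable statistics on a
single CPU.

## Known limitations

- The DE and usage tests are stand-ins; absolute p-values will not match
  bootstrap- or count-model engines, only the selection semantics.
- Complex bubbles are not decomposed into elementary events.
- Exonic flank windows ignore exon boundaries (fixed-width genomic).
- Consequence calls assume the variant shares the reference 5' end up to
  the splicing difference; trans effects and NMD are out of scope.
- Domain-level annotation (which protein domain a truncation removes) is
  limited to coordinates; interval lists must be supplied by the user.
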