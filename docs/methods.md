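# Methods

## Scope and data model

The package analyses annotated Ig heavy-chain rearrangements from four
sorted B-cell populations — germinal-centre (GC) B cells and three memory
subsets (MBC1, MBC2, MBC3) — in two isotypes (IgM, IgG). Records travel as
pandas DataFrames in an AIRR Rearrangement TSV dialect: one row per
sequence with `sequence_id`, `population`, `isotype`, `v_call`, `j_call`,
an IMGT-gapped `sequence_alignment` (gap character `.`), the IMGT
`junction` (conserved Cys ... conserved Trp) and its translation
`junction_aa`, `duplicate_count`, and alignment coordinates
(`v_germline_end`, `j_germline_start`, `cdr3_start`, `cdr3_end`) that make
germline reconstruction deterministic. Junction conventions are fixed
once: the junction includes the conserved flanking residues; the H-CDR3
proper is `junction_aa` minus its first and last residue; all clonotyping
operates on `junction_aa` as printed.

## Synthetic repertoire generator

The generator emulates the statistical structure of the target experiment,
not its raw reads; there is no sequencing-error or indel model, so
sequences stay length-aligned to their germline (mutation counting and
parsimony then reduce to Hamming comparisons).

**Germline references.** Synthetic V segments (291 nt) for the three
dominant families VH1, VH5, VH14 with a fixed IMGT-style layout — FR1
[0,78), CDR1 [78,102), FR2 [102,153), CDR2 [153,177), FR3 [177,291) — are
drawn from the 61 non-stop codons, ending in the conserved Cys codon; D
segments are 12–18 random nt; J segments carry the conserved Trp codon at
a fixed offset (6 nt). Segment names follow the IMGT grammar
(`IGHV1-2*01`), from which family labels are parsed.

**Recombination.** founder = V[0:end−trimV] + N1 + D[trimD5:end−trimD3] +
N2 + J[trimJ:]; trims uniform on [0, trim_max=4] (J trimming capped so the
Trp survives), insert lengths uniform on [0, n_insert_max=6] with bases
uniform on ACGT. Draws are rejected until the junction is in frame and
stop-free (D and J are re-drawn per attempt since rare pairings make a
stop-free junction unreachable). When the V is 3'-trimmed the junction
starts at the last complete V codon, which need not be the Cys — a
simplification of IMGT numbering that has no effect downstream.

**Lineages.** Each clone grows by sequential uniform attachment (member i
attaches to a uniformly chosen earlier member or the founder), a Yule-type
law under which the expected depth of a random member of an n-member clone
is the harmonic number H(n). Every edge carries a Poisson number of
substitutions placed on *distinct* V-encoded positions — so the per-edge V
Hamming distance equals the recorded truth count exactly — with the mean
set by the child's population; the non-V junction part mutates at a
separate low rate (0.1/branch by default). Isotype is drawn per cell from
the population's switch probability.

**Defaults as study conditions.** Population weights (GC .25, MBC1 .20,
MBC2 .10, MBC3 .45) follow the relative sample sizes of the sorted
populations; switch probabilities (GC .20, MBC1 .25, MBC2 .10, MBC3 .10)
make IgM dominant with MBC1 the most switched subset (75% IgM); branch
rates in mutations per branch per 100 V nt default to GC 2.4, MBC1 2.2,
MBC3 2.0, MBC2 1.0, preserving the observed ordering MBC1 ≥ MBC3 > MBC2;
7% of clones are seeded across ≥ 2 populations; clone sizes follow a
truncated power law P(k) ∝ k^-2 on [1, 100] (the size law is a free
parameter of the generator, not an inference target; `{"fixed": k}` gives
constant sizes for calibration runs). Rates are configuration, not claims
about biology.

**What the generator does not emulate** — sequencing error, indels,
allelic variation, hotspot-biased mutation targeting, clonal selection,
light chains. Parameter-recovery results on synthetic data therefore show
that the analysis code measures what the generative model produces; they
do not validate the annotation upstream of real data.

## Germline reconstruction and mutation counting

The germline alignment is rebuilt per record as: V reference over the
V-encoded prefix, `N` over the junction N/D segment (unknowable from the
germline), J reference over the J-encoded suffix. Mutations are
enumerated over FR1–FR3 only; a position counts as informative when both
sequence and germline carry a plain base (gaps, masks and the junction are
excluded). Frequency = 100 × mutations / informative length — the
denominator is stated because published figures rarely print theirs.
J-region mutations are not counted; the choice is recorded in the output
metadata. Replacement/silent classification substitutes one mutated base
at a time into the germline codon (IMGT convention; co-occurring mutations
in one codon are not jointly evaluated); codons touching a gap or mask are
"indeterminate" — counted in the total, excluded from R/S tallies.
Mutation-count histogram bins default to 0, 1–5, 6–10, 11–15, >15 and are
configurable. Group comparisons use the unpaired two-sample t-test on
per-sequence frequencies, a χ² test on mutated-vs-unmutated counts, and
Tukey's HSD across more than two groups; identical zero-variance groups
report p = 1 with a warning.

## Clone definitions

Two definitions coexist, as in standard repertoire practice. Exact
clonotypes group records with identical `junction_aa`, either per isotype
(for the summary table) or pooled (for the overlap heatmap) — the scope is
explicit because published analyses use both. Clonal groups partition
records by gene-level (allele-stripped) V and J call plus junction length,
then form single-linkage components at normalized Hamming distance
≤ 0.16; the threshold is interpreted as a normalized distance (the only
reading under which 0.16 is meaningful) and single linkage matches the
clone-assignment methodology the threshold comes from. An "≥ 85% amino
acid identity" phrasing of the same rule is treated as a gloss of
1 − 0.16 ≈ 84%; grouping uses the nucleotide rule. Component labels are
canonical (ordered by each component's smallest member id), making the
partition invariant to input order. `distance_to_nearest` provides the
standard bimodality diagnostic for the threshold; singleton partitions are
flagged rather than given a distance.

## Sharing bookkeeping

A clonotype is *shared* when its members come from ≥ 2 populations within
the isotype scope; expansion alone never makes a clone shared. The
summary table counts a shared clone once per population it touches (so
per-population shared-clone counts exceed the number of unique shared
clones), and percentages are computed from the counts and rounded half-up
to integers, matching how such tables are printed. Sequence conservation
(single + shared = total, per isotype) holds exactly by construction in
every table the package computes; the published IgG row it mirrors has a
7-sequence discrepancy (3233 + 1265 = 4498 vs a printed total of 4505),
which the package surfaces through `SharingTable.validate()` rather than
reproducing. Relative overlap is |A∩B|/|A∪B| over unique `junction_aa`
sets per population×isotype sample. k-way sharing reports combinations of
*exactly* k populations, with an at-least-k column alongside, since
published 3-way counts can be read either way.

## Lineage trees

Members of a clonal group are collapsed to one node per distinct
nucleotide sequence; labels are the union of (population, isotype) pairs
of the collapsed members. A node is an *overlap* node when its labels
span ≥ 2 populations, and isotype-mixed when they span both isotypes. The
tree search implements a dnapars-style vertical lineage in-package rather
than wrapping the external binary: vertices are the germline root plus the
observed collapsed sequences (observed sequences may be internal
ancestors; no unobserved intermediate sequences are inferred), edge
weights are Hamming distances over germline-informative positions
(junction-masked and gap columns excluded, the germline being unknowable
there), and the score is the edge-weight sum. Search is sequential
addition in decreasing-abundance order followed by local re-grafting until
no move lowers the score; every tie-break resolves to the smallest node
id, so results are deterministic. The exhaustive oracle enumerates all
labelled rooted topologies on the same vertex set via Prüfer sequences
(≤ 6 observed nodes, 16 807 topologies at the limit); because both search
the same space the heuristic can never score below the oracle. An
observed sequence identical to the germline remains a distinct node
attached by a zero-weight edge (the root keeps no labels), so the score of
that degenerate case is 0.

Ancestor→progeny transitions are counted in two modes, reported side by
side since either reading of tree hierarchy is defensible: *edge* links
each labelled node to its nearest labelled ancestor (unlabelled inferred
nodes and the germline are transparently skipped); *path* counts every
labelled ancestor/descendant pair on root-to-tip paths. Multi-label nodes
contribute all label combinations, and isotype-switch transitions (e.g.
IgM ancestor → IgG descendant) are tabulated separately. Top clones are
ranked by total sequence count with both isotypes pooled, ties broken by
clone id.

## Calibration and problem sizes

The acceptance computations run on sizes chosen to give stable statistics
at interactive runtimes: 100 replicate clones for the parsimony-oracle
comparison (clones capped at 6 unique sequences and 8 mutations, the
oracle's enumeration limit); 500 clones (~1 500 sequences) for clonal
recovery; 800 clones (~2 500 sequences) for SHM rate recovery; 500 clones
per arm for the shared-vs-single comparison.

Two calibration details matter. First, the clonal-recovery check is
defined under explicit separation conditions — within-clone junction
distance ≤ 0.10, between-clone > 0.30. Realistic V(D)J generation
produces convergent junctions (same V/J and length, shared D core), so
the check's repertoire is configured for junction diversity (4 segments
per family, inserts up to 10 nt, junction rate 0.02/branch) and the few
clone pairs still violating the separation premise are excluded before
scoring, implementing the stated conditions as fixture constraints.
Second, the shared-vs-single null is simulated with equal branch rates
across *all* populations and a fixed clone size: sharing is necessarily
confined to clones with ≥ 2 members, so under heavy-tailed sizes shared
clones are systematically deeper (more accumulated mutations), and with
population-specific rates a low-rate population's shared members inherit
mutations from higher-rate ancestors — both are genuine properties of the
generative model, not analysis artefacts, and both would break a naive
null. With size and rates held flat, single and shared sequences differ
only in the sharing label, and the per-population t-tests reject at the
nominal type-I rate.

SHM recovery is scored against the truth-derived expectation (accumulated
per-edge counts along each lineage path over the informative length); the
residual gap between recovered and expected frequency is the back-mutation
collision loss, about 3–5% at default rates, well inside the 10% band.

## Known limitations

Clonal groups merged across rearrangements of unequal alignment length
cannot share a single germline; the tree stage keeps the dominant length
and logs the drop. Junction mutations in descendants can create stop
codons (the founder is guaranteed productive; descendants are not
filtered). The parsimony heuristic is a local search: on adversarial
instances it can exceed the optimum, which the oracle-agreement statistic
quantifies rather than hides. Trees with more than 150 unique sequences
are truncated to the most abundant nodes (configurable), with a warning in
the run log.
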