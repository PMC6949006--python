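# Methods

## Data model

Each locus is one aligned FASTA over the characters `ACGT`, IUPAC
ambiguity codes, `-` (gap) and `N` (missing; `?` and `.` are normalised to
`N` on input).  Records are *direct* reads (one per individual) or *clone*
reads (one per sequenced colony).  Roles are `parent_a`, `parent_b`,
`hybrid`, resolved from a sample-map TSV or overridden in the FASTA header
(`>sample_id[|clone_id][|role]`).  Alignment columns are 1-based and
inclusive everywhere; intervals such as indel runs are closed.

## Diagnostic fixed differences

A column is a fixed substitution when, after dropping `N`, each parental
panel carries exactly one state, the states differ and neither is a gap.
Maximal runs of columns that are entirely gap in one panel and entirely
base in the other are fixed indel *events*; a run is broken where the
orientation (which panel is gapped) flips.  Design choices:

* `N` is ignored for fixation, but a column where a panel has only `N` is
  disqualified — panels in the intended use are complete, yet behaviour on
  partial data must be predictable.
* A polymorphic column is never diagnostic even when the two panels'
  state sets are disjoint: "differentially fixed" is taken strictly, which
  is conservative and testable.  Columns failing fixation by exactly one
  deviant sequence are logged as near-fixed so they can be audited.
* Columns containing ambiguity codes in a parental panel are disqualified
  with a warning: panels must be phased or homozygous.

Intraspecific polymorphism is counted as columns with ≥ 2 distinct
non-missing, non-gap states, plus one per maximal run of gap/base-mixed
columns (a segregating indel is one event).

## Additivity of hybrid direct reads

At a diagnostic substitution site the expected heterozygote signal is the
IUPAC code of the unordered parental base pair (A/G → R, C/T → Y, ...).
A direct read is fully additive when it shows that code at every
evaluable site.  Indel sites are non-evaluable from a direct read — a
heterozygous indel desynchronises the trace — so such loci are resolved by
cloning; a read with zero evaluable sites is flagged `no_evidence` rather
than additive.

## Haplotypes

Phased sequences (parental reads, chloroplast reads, clone-phased hybrid
sequences) are collapsed under an explicit comparison policy: all columns
compared, gap as a fifth state, `N` a pairwise wildcard whose positions
are resolved by the sequences that join a haplotype.  Gap-as-fifth-state
departs from DnaSP's default site exclusion deliberately: the loci this
pipeline targets segregate fixed indels, which must separate haplotypes.
Haplotypes are ordered by (descending count, first appearance) with
stable ids `<locus>_H<rank>`.

Phasing by cloning uses a majority rule per individual: clone reads are
grouped by identity; singleton groups within one mutational step of a
larger group are folded in as PCR/cloning artifacts; the top two surviving
groups are the individual's haplotypes (one group ⇒ homozygote).  The
artifact threshold of one step is a stated choice — with a per-base clone
error rate near 10⁻³ over ≤ 1 kb amplicons, double-error clones are rare,
and true alleles are protected because either they are seen in multiple
clones or they differ from the other allele by at least the number of
diagnostic differences (≥ 2 in all intended designs).

Mutational distance between aligned haplotypes is the number of differing
substitution columns plus the number of differing maximal gap-run events
(orientation flips open a new event); `N` positions are skipped.  This is
the field's "mutational step".  **Limitation:** it is a metric only on
gap-free sequences; with gaps, a k-column indel costs one step and can
undercut the k substitutions it shadows, so the triangle inequality can
fail.  This is inherent to counting indels as single events and is the
behaviour the networks require.

## Hybrid classification

Each hybrid contributes an unordered origin pair per nuclear locus over
{A, B, U}.  A haplotype found verbatim in exactly one parental panel is
that parent's origin; a haplotype in neither panel is attributed to a
parent when its minimum distance to that parent's haplotypes is ≤ t
(default t = 1) *and* strictly smaller than to the other parent,
otherwise it stays U and its locus is dropped from the call.  The class
rules over the usable loci: all {A,B} ⇒ F1; all {A,A} ⇒ parental_A (resp.
B); {A,A}+{A,B} mixes ⇒ later_gen_or_backcross_A (resp. B); anything else,
including zero usable loci, ⇒ ambiguous.  F2 and BC1 are a single merged
class by design: with a handful of unlinked loci their composition
patterns overlap, and the scientific claim of interest is only the
presence or absence of non-F1 signatures.

Maternal assignment compares the hybrid's chloroplast sequence to the
parental chlorotypes: exact match wins; otherwise nearest-within-t with
strict inequality, default t = 0 because F1 chlorotypes should be
identical to a parental one.  Maternal inheritance of the chloroplast is
an assumption, recorded in the summary output.  Direction verdict:
bidirectional iff both parents appear as mothers; the majority parent is
reported as the major maternal parent.

Diploidy and free recombination between (none within) loci are assumed
throughout; under them a BC1 is {A,B} per locus with probability 1/2
exactly, giving the (1/2)^L F1-mimicry rate the tests verify.

## Median-joining networks

Per locus, the observed haplotypes enter an epsilon-relaxed minimum
spanning network: a link (u, v) is kept iff its cost exceeds the pair's
connection threshold — the minimax path cost, i.e. the Kruskal level at
which u and v first join — by at most epsilon.  With the default
epsilon = 0 this is exactly the union of all minimum spanning trees (the
sparsest choice, and the default of the software this mirrors).  Then,
iteratively: median vectors of mutually connected triplets (per-column
majority; columns where all three states differ expand to the full
quasi-median set, capped at 64 combinations per triplet) are scored by the
MST weight of the node set with the candidate added; the single best
cost-reducing median is adopted per round; median nodes of degree ≤ 2 on
no shortest observed-observed path are pruned; repeat to a fixed point,
with a global cap of 100 medians (a `truncated` flag reports a cap hit).
All ties break by (weight, lexicographic node id), so output is identical
across runs and platforms.  Exports: GraphML with role counts per node
and step weights per edge, a TSV edge list, and an optional static plot
with node size proportional to haplotype frequency.

## Synthetic data generator

The generator emulates a two-species hybrid-zone Sanger study and is the
package's test bed.  Per nuclear locus it draws a random ancestral
sequence, plants the requested fixed substitutions at distinct columns
and fixed indels as non-adjacent gap runs of 1–5 columns (infinite-sites:
no column is used twice), and creates the requested number of
within-panel haplotypes by giving each extra haplotype one private
substitution at a fresh non-diagnostic column; the first k individuals of
a panel carry the k haplotypes so every planted haplotype is realised.
Parents are homozygous; hybrids are built by Mendelian segregation (F1:
one haplotype from each species per locus; BC1: an F1 gamete — fair coin
per locus — plus a parental gamete; F2: two F1 gametes), the chloroplast
copied from the designated mother.  Per hybrid and nuclear locus the
generator emits eight clone reads and one IUPAC-consensus direct read
(gap-heterozygous columns become `N`, mirroring an unreadable trace).

Clone templates are drawn uniformly from the two alleles *conditioned on
both alleles appearing* when the individual is heterozygous: phasing by
cloning in practice sequences colonies until both alleles are recovered,
and unconditioned sampling would silently drop an allele with probability
2⁻⁷ per individual-locus, which is not a property of the laboratory
procedure being emulated.  Clone errors (default rate 0) are independent
per base and never placed at diagnostic columns, isolating the artifact-
folding rule from fixed-difference detection.

Default design (the study conditions): 20 + 20 parental individuals and
14 hybrids; five nuclear loci of 657, 505, 529, 263 and 271 bp with
(substitutions + indels, panel-haplotype counts) of (7+0, 1/1), (2+2,
5/2), (4+1, 7/5), (2+0, 5/4) and (4+1, 1/1); an 815 bp chloroplast spacer
with 6 fixed substitutions; all hybrids F1; maternal mix 11 from parent B
and 3 from parent A; 8 clones per individual.  A single seeded
`numpy.random.default_rng` stream drives every draw, so identical configs
give byte-identical files.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: recurrent mutation and homoplasy, recombination
within loci, shared ancestral polymorphism between the parental species,
alignment error, base-calling noise in direct reads, and chloroplast
heteroplasmy.  On real data these would surface as near-fixed columns,
unresolvable unique haplotypes, or ambiguous class calls, all of which
the pipeline reports rather than hides.

## Numerical and degenerate-input choices

Problem sizes in the test suite and acceptance script are the study-scale
design (54 individuals, six loci) plus a 1000-individual BC1 cohort at
five 60 bp loci for the Mendelian-rate check; both run in seconds.
Degenerate inputs are errors with named offenders: ragged alignments,
empty panels, ambiguity codes where phased sequence is required, sites
beyond read length, empty chlorotype lists.  An empty cohort yields a
defined `undefined` direction verdict rather than an error.
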