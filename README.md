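# hybdiag

Multilocus diagnosis of natural plant hybrids from Sanger sequence
alignments: diagnostic fixed-difference detection between two parental
species panels, F1-versus-backcross classification from phased haplotypes,
chloroplast-based inference of hybridization direction, and median-joining
haplotype networks.

## The problem

When a morphologically intermediate plant grows sympatrically with two
candidate parental species, a handful of sequenced loci can settle whether
it is a hybrid, what generation it is, and which species mothered it.  The
approach implemented here rests on three observations:

* **Differentially fixed differences.**  An alignment column where each
  parental panel is monomorphic for a different nucleotide (or a maximal
  gap run present in all of one panel and absent from all of the other) is
  diagnostic for ancestry.  A true hybrid's direct Sanger read shows *peak
  additivity* at every such substitution site — superimposed chromatogram
  peaks of both parental bases, coded as the IUPAC ambiguity character
  (e.g. A/G → R).

* **F1 versus later generations.**  With phased haplotypes (obtained by
  cloning PCR products, eight colonies per individual), each diploid
  individual has an origin composition per locus: {A,B} (one haplotype from
  each parent), {A,A} or {B,B}.  An F1 is {A,B} at *every* nuclear locus; a
  first-generation backcross (BC1) is {A,B} at each unlinked locus
  independently with probability 1/2, so it mimics an F1 at L loci with
  probability (1/2)^L ≈ 0.031 for L = 5.  Hybrid haplotypes absent from the
  sampled parents are attributed to the nearer parent when within one
  mutational step (unsampled parental polymorphism).

* **Direction from the chloroplast.**  The chloroplast is maternally
  inherited, so an F1's chlorotype names its seed parent; exact identity
  with a parental chlorotype is required by default.

Mutational distance is counted in *steps*: one per differing substitution
column plus one per differing maximal gap run (an indel of any length is a
single event).  Median-joining networks are built per locus: the
epsilon-relaxed minimum spanning network (epsilon = 0 gives exactly the
union of all minimum spanning trees) extended with cost-reducing median
(consensus) vectors of connected triplets.

A seeded synthetic-data generator emulates the full study design — two
divergent parental panels with planted fixed differences and low
intraspecific polymorphism, Mendelian F1/F2/BC1 hybrids, clone-phased and
IUPAC-coded direct reads, maternal chloroplast — with a truth table, so the
whole pipeline is testable end to end without any sequence downloads.

## Worked example

```bash
hybdiag simulate --outdir ds --seed 2020
hybdiag classify --loci ds/its.fasta --loci ds/dbr1.fasta \
    --loci ds/sos4a.fasta --loci ds/sos4b.fasta --loci ds/pcrf1.fasta \
    --loci ds/trnv_trnm.fasta --samples ds/samples.tsv \
    --cp-locus trnv_trnm --outdir out
```

prints

```
classes: {'F1': 14}
direction: maternal parent_a=3, parent_b=11, unassigned=0 (bidirectional, major=parent_b)
```

meaning: all 14 putative hybrids are heterozygous for one parent-A and one
parent-B haplotype at all five nuclear loci (first-generation hybrids, no
backcross signature), and their chlorotypes split 11:3 between the two
parents — hybridization ran in both directions with parent B as the major
maternal parent.  `out/` contains the diagnostic-sites table, the haplotype
table with sharing classes, per-individual calls and a JSON cohort summary.

The same analysis as a narrated sequence of steps lives under `analysis/`
(`01_simulate.py` … `05_networks.py`); each driver prints its findings and
writes its tables under `results/`.

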