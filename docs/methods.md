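# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Protein physicochemistry

Molecular weight is the sum of **average** (not monoisotopic) residue
masses plus one water (18.0153 Da); unknown residues (`X`) contribute the
mean residue mass 111.1 Da. The isoelectric point solves
`net_charge(pH) = 0` for the Henderson–Hasselbalch charge of the two
termini and the D/E/C/Y/H/K/R side chains with an EMBOSS-style pKa set
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1), by bisection on [0, 14] to 1e-4 pH. The charge function is
strictly decreasing in pH, so the root is unique whenever the endpoint
charges bracket zero; a peptide with no effective crossing is reported at
the convention value 7.0 with a warning instead of failing. Absolute pI
values depend on the pKa table; only classification against the pI > 7
threshold is intended to be table-robust. Composition fractions exclude
`X` from the denominator and sum to 1 over the 20 standard residues.

## Core-box classification

"Similarity" to the S-core box is ungapped percent identity: the motif is
slid over every placement against the sequence (overhangs allowed) and
scored as identities divided by the **motif length**, so overhang positions
and deletions in the subject count as mismatches. This is deterministic and
reproducible; a gapped local-alignment mode exists behind a flag but is not
the default, since at the 70% scale on a 20-mer gaps add nothing but
aligner-dependence. All five thresholds are strict inequalities as printed
(>= only for the motif's 70%); a protein at exactly 10% cysteine does not
receive the cysteine-rich flag.

## Trees, placement and dating

Distances over aligned sequences are p-distances with pairwise deletion of
gap sites, optionally Poisson-corrected (−ln(1−p); p >= 1 is reported as a
saturated pair). Trees are built by neighbor joining (via scikit-bio) and
midpoint-rooted unless an outgroup is named; negative NJ branch lengths are
clamped to zero with a warning. On an additive matrix the reconstruction is
exact (path-length error below 1e-9 in the tests).

Subgroup placement assigns a query the label of its nearest reference
under the chosen distance; support is the margin between the best and
second-best subgroup mean distances, and an exact nearest-distance tie
across subgroups yields `ambiguous` rather than an arbitrary pick. Queries
must be supplied aligned to the reference alignment; alignment itself is
out of scope (use e.g. mafft upstream).

Dating is the minimal strict-clock procedure: a node's depth is the mean
path length from the node to its subtree leaves; a single rate
(subst/site/Myr) is the least-squares slope through the origin of depth
against calibration age over the calibration MRCAs, interval calibrations
(66–51 Myr) resolving to their midpoint by default; every internal node of
the focal clade is dated as depth/rate. Bursts are maximal descending runs
of node ages with consecutive gaps <= `max_gap` (default 5 Myr, which
separates two reported expansion windows 9 Myr apart edge-to-edge) and at
least two members; singleton ages are reported separately, so the ages
partition exactly. Dating is scale-equivariant: scaling all branch lengths
and the rate by the same constant leaves ages unchanged.

## Pseudogene scanning

Coordinates are 0-based half-open throughout; GFF3 input is converted on
read, and exon lists are kept in transcript orientation. The spliced
candidate CDS is scanned for a lost ATG, internal stops (standard nuclear
code) and a missing terminal stop; a length not divisible by 3 is flagged
as a terminal frameshift and the in-frame prefix is scanned. Against a
functional ortholog, candidate and reference exons are paired by an
order-preserving (collinear) best-identity assignment computed by dynamic
programming over global pairwise alignments; a reference exon is *missing*
when no candidate exon reaches the identity floor (default 50%),
*incomplete* when aligned coverage falls below 80%, and *shifted* when its
cumulative CDS offset differs from the reference's by a non-multiple of 3.
Indel runs inside aligned exons whose length is not a multiple of 3 are
frameshifts. The verdict is `pseudogene` iff any disruption field is
populated, `unresolvable` when no exon pairs at all, and `functional`
otherwise; comparing a gene with itself is always clean. The identity and
coverage floors are conventions (configurable), not published values.

## Ka/Ks and the selection screen

The estimator is classic NG86: per-codon fractional synonymous sites from
the nine single-nucleotide neighbours (changes to stops counted as
nonsynonymous), differences resolved by averaging over all minimal
mutational pathways with equal weights, pathways through stop codons
excluded. In the degenerate case where every pathway is blocked by a stop,
all pathways are averaged with stop-traversing steps counted as
nonsynonymous rather than dropping the codon — this affects at most a
handful of codons per alignment and keeps the counts conservative.
Proportions are Jukes–Cantor corrected (`K = −(3/4)ln(1 − 4p/3)`); p >=
3/4 yields a `saturated` flag and Ks = 0 a `Ks_zero` flag instead of an
infinite ratio. Sites are averaged over the two sequences and gapped or
non-sense codons are skipped pairwise, so S + N = 3 × compared codons
exactly.

Pairwise NG86 deliberately replaces branch-model maximum likelihood
(codeml free-ratio): the screen's contract — ratio > 1 marks a candidate —
is preserved, but branch-specific rates are not estimated. Upstream, the
block filter drops codon columns whose gap fraction exceeds 20% or whose
modal-codon share of ungapped entries is below 50%, then drops surviving
runs shorter than 3 codons — a transparent stand-in for the Gblocks role
that never breaks the reading frame. The screen reports, per gene, the
focal-vs-comparator pair with the largest defined ratio, requires at least
30 compared codons, and logs every exclusion. The expression overlap
counts a PSG as upregulated when any of days 1/3/7 reaches
`fold_threshold` (default 2.0) times the day-0 baseline; a zero baseline
counts as upregulated iff any later value is positive.

## Synthetic data

The family simulator is a forward birth–death process (rates per lineage
per Myr); surviving lineages become leaves and the reconstructed tree's
duplication ages are returned as planted truth. Protein evolution is
site-wise Poisson under a single-parameter equal-rates model — adequate
for classifier and dating tests, **not** a biological exchangeability
matrix — with motif columns slowed by the conservation factor c (c = 0
freezes the motif, so planted family members always carry it verbatim).
There is no indel evolution.

The codon simulator is a per-codon Gillespie mutation–selection walk:
nucleotide proposals with transition/transversion ratio kappa, stop codons
rejected, nonsynonymous changes accepted at relative rate omega. Rates are
normalised so each codon's total neutral rate is 1; `t` is therefore the
pair's expected neutral substitutions per codon site (each lineage runs
t/2). Realised synonymous/nonsynonymous counts are returned, which makes
the walk a valid oracle for NG86 regardless of its simplicity. Estimator
recovery is tested at kappa = 1, the unbiased-mutation regime NG86's site
counting assumes; at kappa > 1 NG86 exhibits its known downward bias
(transitions are disproportionately synonymous), which the simulator can
demonstrate but the recovery tests do not require.

Disruption injection edits a gene model and contig in place (substitutions
for start/stop loss, insertions for frameshifts with downstream exon
coordinates re-mapped, exon deletion/truncation for structural defects)
and mirrors each edit in a truth record. The expression generator draws
log-normal day-0 baselines and multiplies planted genes by >= `fold` at
one random post-autotomy timepoint; with `noise_cv = 0` the overlap
statistic recovers the planted fraction exactly. All generators take
mandatory integer seeds through `numpy.random.default_rng`; identical
seeds give identical outputs, and no global random state is used.

What passing these tests does **not** show: recovery on real proteomes
(real beta-keratins diverge under selection, not equal-rates drift), real
alignment error (inputs are simulated already aligned), or the published
genome-scale gene counts, which require the full gecko assembly and
comparator proteomes.

## Problem sizes and runtime choices

The test-suite and acceptance-script simulations use desk-scale sizes
chosen to make Monte-Carlo error small relative to the asserted
tolerances: 100 random peptides for the pI oracle, 200 random pairs for
the motif-scan oracle, 200 replicates of 300 codons per omega for
estimator recovery, 20 independent 50-gene screens for PSG recovery, and
10 random additive matrices for NJ inversion. The full suite runs in well
under a minute of compute for the numeric checks and a few seconds for
each simulation batch.

## Known limitations

* NG86 is a counting estimator: no codon frequencies, no transition bias,
  no branch or site models; ratios are pairwise, not lineage-specific.
* The strict-clock dating ultrametricises by mean root-to-tip depth; rate
  variation across lineages biases node ages, and no uncertainty is
  attached to burst edges.
* Placement is nearest-neighbour over a fixed alignment — no tree-based
  placement or bootstrap support.
* The pseudogene caller assumes collinear exon structure (no
  rearrangements) and a functional reference that translates cleanly.
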