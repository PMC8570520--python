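# Methods

## The question and the approach

Codon adaptation — bias toward the "major" codons favoured by translational
selection — can persist in a gene either because selection maintains it or
because it is an ancestral state still decaying under mutation pressure.
The two hypotheses are distinguishable by simulation: reconstruct an
ancestral sequence, let it evolve forward under the genome's *mutational*
dynamics with no selection on synonymous codon choice, and ask whether
extant genes retain more adaptation than the simulated neutral trajectories
allow at their estimated divergence.  Chloroplast DNA makes the mutation
model the hard part: mutation probabilities depend strongly on the two
immediately flanking bases, so a context-independent model (e.g. K2P)
predicts the wrong equilibrium codon usage.  The package therefore estimates
a 10-matrix context-dependent model directly from substitutions observed in
noncoding DNA of very closely related genomes, where multiple hits are
negligible and observed substitution spectra approximate relative
instantaneous mutation probabilities.

## Substitution counting

Triplet alignments (ingroup pair + outgroup) are scored column-wise.  A
column contributes only when (a) both flanking columns are gap-free,
ambiguity-free and identical across all three sequences — otherwise a
"conserved context" cannot be asserted — and (b) the focal column is
gap-free A/C/G/T in all three.  Context is read from the adjacent alignment
columns, matching the column-wise scoring of an alignment; the first and
last columns are never scoreable.  Conserved ingroup pairs count on the
diagonal for the ingroup base irrespective of the outgroup; ingroup
differences are polarised ancestral → derived by the outgroup and ignored
when all three bases differ.  Only regions whose ungapped length (shortest
member) strictly exceeds 70 nt are scored; the threshold is applied to
ungapped length because the filter exists to exclude short, poorly
alignable regions of the source genome, not short alignments.

Merging adds the complement-transformed matrix of each context's reverse
complement (index relabelling i → comp(i)); the four self-complementary
contexts (A_T, T_A, C_G, G_C) pass through unchanged.  They are deliberately
*not* symmetrized: the counts are strand-specific, and forcing symmetry
would erase the strand skews the model is meant to capture.  A consequence
is that the complement-lookup identity (context and complement return
relabelled-identical rows) holds for the 12 paired contexts but not, and
should not, for the self-complementary four.

## Probability matrices and normalisation

Counts become probabilities by row division; zero row totals are an error
(the data cannot inform that row).  The global rescaling multiplies every
off-diagonal entry by a single scalar c = target_max_rate / r_max, where
r_max is the largest off-diagonal row sum over all matrices, and resets the
diagonals.  Algebraically the rescaled matrix is Q = (1−c′)I + c′P for a
row-wise-consistent c′, a uniformisation that provably leaves every
stationary vector unchanged — so the rescaling affects only simulation
efficiency (the rate of self-mutation rejections), never the process.  The
default target of 1.0 gives the fastest row a zero diagonal, minimising
rejected self-mutations.  Stationary vectors are computed by repeated
squaring of P until all rows agree within 1e−10, with failure (reducible or
periodic matrices) raised as an error by the core routine and reported as
undefined by the summary table.  The K2P comparison model places the same
row everywhere: off-diagonal mass `rate`, 3/5 to the transition and 1/5 to
each transversion (3:1 Ts:Tv); its stationary vector is exactly uniform.

Model summaries report, per context: Ts:Tv among substitutions with
ancestral base G/C and A/T (classification is by *inferred ancestral* base;
at conserved sites this equals the shared base, and at substituted sites it
is the outgroup-matching base — the alternative of classifying by outgroup
base everywhere differs only through rare polarisation errors),
substitutions/site × 100, the ratio of per-site substitution rates from
ancestral G/C vs A/T, and the equilibrium G+C and skews of π.  Skews are
defined as 100·(C−G)/(C+G) and 100·(T−A)/(T+A); the sign and denominator
conventions are this package's choice and are stated here because several
conventions circulate.

## Fitness tables, CAI, ambiguity resolution

Within each synonymous family (families defined by amino acid, so the
sixfold Leu/Ser/Arg families are single families), w(c) = (n_c + 0.5) /
(n_max + 0.5) from pooled reference-gene counts: observed majority codons
get w = 1 and unobserved codons a small positive value; families entirely
absent from the references are omitted rather than assigned uninformative
w = 1.  Met, Trp and stop codons are excluded from estimation and from CAI,
per standard practice for single-codon families.  CAI is the geometric mean
of w over a gene's scorable codons.

MP-High/MP-Low resolution visits ambiguous sites left to right; each
candidate base is scored by the w of the codon it completes, taking the
mode-extreme w over any ambiguities remaining later in the same codon
(a greedy completion; for the common single-ambiguity codon this is exactly
"pick the synonymous codon with the highest/lowest fitness").  Candidates
whose every completion is a stop are disallowed; ties go to the
alphabetically earlier base.  Codons without table entries (ATG, TGG) score
w = 1 during resolution only, being the sole codon of their family.  The
wording of the resolution rule presumes synonymous ambiguities; when an
ambiguity is amino-acid-changing the same w comparison is applied to the
full codons.

## The decay simulator

Each round proposes then selects.  Propose: a site uniform over positions
2..L−1 (terminal bases have no two-sided context and are immutable — one of
several places where the ends of the gene are treated conservatively), the
context row of the current base sampled; a draw landing on the diagonal is
discarded, which converts the non-zero diagonals into per-base and
per-context rate variation without explicit rate bookkeeping.  Select:
synonymous → accept; stop-creating → discard (a stop is never an acceptable
replacement); nonsynonymous → discard in synonymous-only mode, and in the
nonsynonymous mode accept with probability dN/dS provided the new residue is
in the site's acceptable set (residues observed at that alignment column
across extant taxa).  The acceptability check precedes the dN/dS coin, so a
run whose acceptable sets contain only the ancestral residues consumes the
identical random stream as a synonymous-only run.  The start codon gets no
special protection; any change to it is nonsynonymous and follows the
normal rules.  The accepted-mutation counter drives the checkpoints: CAI
(maintained incrementally as a running sum of log w) is recorded at 0 and
at every `record_every` accepted mutations.  Replicates use counter-based
child streams of the master seed (`SeedSequence(seed, spawn_key=(rep,))`),
so runs are bit-reproducible and replicates individually re-runnable.
Trajectories report the mean and sample SD (ddof = 1) over replicates;
checkpoint 0 is the ancestral CAI with SD 0 by construction.  A proposal
cap (default 10 000 × n_mutations + 100 000) guards against degenerate
ancestors admitting no acceptable change.

Defaults mirror the study conditions: 500 mutations, CAI every 5, 1000
replicates, per-gene dN/dS supplied as configuration (e.g. 0.029 for psbA,
0.101 psbD, 0.074 rbcL, 0.039 psaB).

## Divergence and the overlay

K2P: k = ½ln(1/(1−2P−Q)) + ¼ln(1/(1−2Q)), variance
(a²P + b²Q − (aP+bQ)²)/n with a = 1/(1−2P−Q), b = (a + 1/(1−2Q))/2.
Columns containing gaps or ambiguity codes are excluded from n; the
mutation count is k × n, i.e. the multiplier is the number of *compared*
(ungapped) columns — the aligned or ancestor lengths are the alternatives,
and they differ only through gap columns that carry no distance
information.  Pairs of unequal length require a user-supplied aligner hook
(any callable or external pairwise aligner); alignment itself is not
claimed by this package.  The overlay classifies each extant gene's CAI
against [min(mean−SD), max(mean+SD)] over the supplied trajectories at each
trajectory's checkpoint nearest the gene's mutation count, separately for
the minimum and maximum counts over the ancestors; mutation counts beyond
the simulated range are flagged, not refused.  The envelope definition
(±1 SD at the nearest checkpoint) makes a visual comparison operational;
no hypothesis test is attached because the extant points share ancestry and
are not independent.

## Synthetic data: what it does and does not emulate

Triplet regions evolve on a star (root → in1, in2, outgroup) using the same
proposal kernel as the simulator without coding constraints; the accepted
count per branch is Poisson with mean expectation × mutable sites, and the
root is drawn i.i.d. from the model's stationary composition averaged over
contexts (exact root composition is immaterial to recovery tests).  Branch
expectations are capped at 0.01 subs/site, the regime where multiple hits
are rare — matching the sub-percent divergence real triplets are selected
for.  No indels are generated; gap handling in the counting stage is
exercised by separately constructed gapped fixtures, keeping evolution and
alignment concerns orthogonal.  Synthetic coding sequences draw a uniform
random protein and then codons within each family with probability ∝ w^β.
What passing recovery tests therefore show is that counting + model
building invert the generative process they assume (star topology, no
indels, stationary roots, context-conserved scoring); they cannot show
robustness to alignment error, indel misplacement, selection in "noncoding"
DNA, or non-stationary base composition in real genomes.

## Numerical and design choices

- Bases are ordered A,C,G,T; complementation is index reversal, so the
  complement transform of a matrix is `M[::-1, ::-1]`.
- Stationary iteration: convergence when the largest column spread is
  < 1e−10 (components then agree with a left-eigenvector computation to
  1e−8); rows renormalised each squaring to curb floating-point drift;
  at most 64 doublings (P^(2^64)) before declaring non-convergence.
- The simulator's inner loop uses precomputed cumulative probability rows
  and batched random draws; CAI updates are O(1) per accepted mutation.
- The noncoding scorer is vectorised over alignment columns, so
  multi-megabase recovery runs take seconds.
- Sites with IUPAC codes other than A/C/G/T anywhere in the focal or
  flanking columns are skipped (treated like gaps).
- Serialization is plain JSON/TSV with `repr`-precision floats; count
  round-trips are bit-exact.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` size their runs for thorough
statistics: parameter recovery scores 4–12 million synthetic noncoding
sites (≥ 10^5 scoreable sites per context, several hundred thousand in the
tests), the simulator equilibrium check runs 1000 replicates of 2000
accepted mutations on a 120-codon gene against a closed-form oracle
(uniform occupancy of each codon's single-step synonymous component under
the symmetric K2P kernel), and the decay runs in the acceptance script use
the full 500 × 1000 study conditions on a 353-codon gene.

## Known limitations

- K2P mutation counts are downward-biased once synonymous changes saturate
  third positions (rate concentration violates K2P's site-homogeneity);
  placements are therefore most trustworthy at low divergence, and the
  acceptance script keeps its synthetic extants in that regime.
- The model treats the 70-nt filter, context conservation and outgroup
  polarisation as exact rules; real data add alignment uncertainty that the
  synthetic generator does not model.
- The greedy ambiguity resolution optimises per site, not jointly per
  codon; for codons with two or more interacting ambiguities a joint
  optimum could differ, though high/low bracketing is preserved in
  practice (property-tested).
- Equilibrium CAI predictions inherit any mismatch between noncoding and
  coding mutation dynamics; the package assumes they are identical.
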