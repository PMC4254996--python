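# Methods

This note documents the models, estimators and numerical conventions
implemented in `hairpin-evol`, the choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## The analysis

The package quantifies selective constraint on a pre-miRNA hairpin by
partitioning its alignment into the 5′ fold-back arm, the terminal loop
region and the 3′ fold-back arm, and contrasting variability across the
three regions and against a linked, putatively neutral reference locus
(e.g. ITS1 of nuclear rDNA). Under purifying selection on the stem the
arms should show fewer segregating sites, lower per-site diversity, lower
pairwise divergence, and fewer rate-constancy rejections than the loop or
the neutral locus; co-evolution of the arms shows up as stem substitutions
that create or preserve base pairing.

### Region partition

The default partition mode uses fixed coordinates supplied by the user
(e.g. the 73/66/75 split of a 214-column alignment): curated hairpin
alignments normally come with declared region boundaries, and a different
folding engine could shift a structure-derived boundary by a few columns.
When no coordinates are given, the partition is derived from a secondary
structure: with (i, j) the stem pair closest to the loop (maximal 5′
index), the 5′ arm is 1..i, the loop i+1..j−1, the 3′ arm j..length.

### Folding

`fold_maxpair` is a Nussinov-style base-pair maximisation dynamic
programme over Watson–Crick pairs plus the G-U wobble, with a minimum
hairpin loop of `min_loop` unpaired bases (default 3, the steric minimum).
It is *not* a free-energy minimiser; it exists so that the pipeline is
self-contained and deterministic. Every downstream consumer accepts an
externally supplied dot-bracket string, which is the recommended route
when a thermodynamic structure (ViennaRNA, mfold) is available. The
traceback is deterministic: within any interval the 5′-most base is
paired whenever pairing it is optimal, taking the 3′-most optimal
partner, so ties never introduce run-to-run variation. Sequences too
short to admit any pair fold to the open chain.

### Diversity statistics

Per column, only A/C/G/T residues are counted; gaps and N are missing
data, never alleles. A segregating site has ≥ 2 countable states; a
singleton is a biallelic site whose minor state occurs in exactly one
sequence. Watterson's per-site estimator is

    theta_W = S / (a_{n-1} · L),   a_m = sum_{i=1..m} 1/i,

with L the *full* region width in columns (gapped columns included),
matching the convention of the standard polymorphism reports this table
mirrors. Site entropy is H_i = −Σ_j P_ij log P_ij over the four bases,
with proportions among countable residues and 0·log 0 = 0; natural log is
the default and base 2 is available by flag (sources for this statistic
rarely state a base; the choice only rescales the profile). Columns with
no countable residue report H_i as missing rather than zero. Indel
polymorphism is reported separately as maximal gap runs per row.
Diversity is computed over ingroup rows; outgroups never enter
polymorphism counts.

### Pairwise distances

Three models, all under pairwise deletion (a column is dropped for a pair
when either row carries a gap or N — regional distances must remain
defined on indel-bearing loops):

* `p` — raw mismatch proportion;
* `jc69` — d = −(3/4) ln(1 − 4p/3);
* `six_parameter` — a six-parameter correction separating the A↔G and
  C↔T transition classes from transversions with unequal base
  frequencies estimated per pair (the Tamura–Nei composite closed form;
  the full expression is in the `evo_distance` docstring). It collapses
  to JC69 when composition is uniform and transitions unbiased, which is
  verified by simulation in the test suite.

A pair whose correction is undefined (logarithm of a non-positive
argument) is flagged saturated (NaN) rather than raising; summaries
exclude saturated entries and report how many were excluded.

The neutral-locus contrast is a matched-pairs t-test on per-pair
distances (test locus minus reference locus), pairs matched by sorted id
pair. Negative mean difference means the test locus is the less
divergent. The C(n, 2) species pairs are treated as independent
observations, exactly as this analysis is conventionally run; because
pairs share taxa the test is anti-conservative, and every report carries
that pseudo-replication caveat. If all differences are equal and nonzero
the p-value is reported as the zero-variance limit 0 with a
degenerate-variance flag; all-zero differences give t = 0, p = 1.

### Relative-rate test

For ingroup sequences a, b and outgroup o, the unrooted three-taxon tree
under JC69 depends on the data only through five site-pattern classes
(all equal; a=b≠o; a=o≠b; b=o≠a; all distinct). Branch lengths are
estimated by maximum likelihood with L-BFGS-B on [0, 10]
substitutions/site (log-likelihood tolerance 1e-8), initialised
deterministically from the three pairwise JC69 distances via the
midpoint formulas — no stochastic restarts, so results are exactly
reproducible. Rate constancy (a = b) is tested by the likelihood-ratio
statistic against chi-square with 1 df. The free fit is floored at the
constrained optimum so the LRT is never negative. Columns with a gap or N
in any of the three rows are deleted per triplet; fewer than 10
comparable sites is an error. Batch mode runs one test per unordered
ingroup pair against one designated outgroup (with two outgroups, run
each separately); raw p-values are retained and rejections counted at
alpha = 0.05 by default, with Benjamini–Hochberg available by flag.

Calibration: on independent simulated triplets (214 sites, a = b = 0.1,
o = 0.2) the empirical type-I error is ~0.056 at the nominal 0.05. Note
that within one dataset the per-pair tests are strongly correlated
(pairs share tree branches), so a single batch's rejection *count* is
over-dispersed relative to Binomial(990, alpha).

### Substitution classification

Each polymorphic site inside the arms yields one record per derived
allele. The ancestral state is the majority base (ties broken by a
designated reference record; outgroup-based polarisation is available
when outgroups are present). Context is the partner base at the paired
stem position — projected from the structure through the gap map of the
reference row, or supplied explicitly in a context table — or an
internal-loop marker. With z the ancestral partner and z′ the partner
state among the carrier taxa (z′ = z unless the carriers are unanimous
on a different state):

| before = pc(anc, z) | after = pc(der, z′) | class |
|---|---|---|
| mismatch | WC or wobble | `new_pairing` |
| WC or wobble | WC or wobble | `synonymous_pair` |
| mismatch | mismatch | `no_change` |
| WC or wobble | mismatch | `destabilizing` |

Unpaired/internal-loop records are `no_change`. Evaluating the derived
pair against the carriers' partner state is what lets a true compensatory
double substitution (A-U → G-C) classify as pairing-preserving — such
records carry an explicit "compensatory" note naming the partner column's
state change. The structure-preserved fraction is (new_pairing +
synonymous_pair + no_change) / total.

## The simulator

`synthetic_data.simulate` generates, from one seed, an ultrametric Yule
tree (or accepts any Newick), a hairpin locus evolving under stem
constraint, and a fully neutral reference locus on the same tree.

Substitutions are proposed under JC69 — each site proposes at rate `mu`
per unit branch length, target base uniform among the three alternatives,
Poisson event counts per branch — and accepted with the weight of the
*resulting* pair class at paired sites: Watson–Crick 1 (fixed), wobble
`w_wobble`, mismatch `w_mismatch`. Unpaired sites accept everything.
This is a rejection-sampling caricature of purifying selection on
pairing: mutation is random; inheritance is structure-filtered. With
probability `compensatory_rate` an accepted stem change that is not
itself Watson–Crick is immediately accompanied by the partner
substitution restoring a Watson–Crick pair. At most one deletion per
branch may hit the terminal loop (length uniform 1–10 nt, echoing the
single-digit loop deletions seen in real hairpin alignments); arms never
receive indels. Deletions become gap characters, so rows stay aligned.
Every proposal — accepted or rejected — is logged.

Defaults define the study-like condition: 45 taxa, a 214-nt hairpin
template partitioned 73/66/75 (fully paired 5′ arm, two 3′-arm bulges
absorbing the arm-length difference), a 266-nt neutral locus, tree height
1.0, `mu` = 0.042 (calibrated so the neutral locus shows theta_W near
0.09, the diversity scale of a fast-evolving nuclear spacer),
`w_wobble` = `w_mismatch` = 0.05, `compensatory_rate` = 0.5,
`loop_indel_rate` = 0.02 per branch. The root sequence is drawn uniform
at unpaired positions with Watson–Crick partners imposed at paired ones.

What the simulator does *not* emulate: thermodynamic fitness (pair-class
weights are not energies), context-dependent mutation, rate variation
among loop sites, insertions, recombination, sequence-motif selection
(conserved motifs in real hairpins arise from protein binding, which is
outside this mechanism), and alignment error — the "alignment" is exact
by construction. Passing tests on simulated data therefore demonstrate
correctness of the estimators and the qualitative stem/loop contrast,
not the realism of any particular parameter value for a given genus.

## Numerical conventions

* Coordinates are 1-based inclusive everywhere on the public surface.
* U ↔ T: sequences are normalised to DNA internally; each record's input
  alphabet is restored on output. IUPAC ambiguity codes other than N are
  rejected; N is missing data; the only gap character is `-`.
* Pattern-class probabilities are floored at 1e-300 before taking logs
  (zero-length branches zero some classes; classes with zero counts then
  contribute nothing).
* Human-readable tables round theta to 3 decimals, distances to 4 and
  p-values to 3 significant figures; JSON reports keep full precision.
* All randomness flows through one `numpy` generator seeded from the
  configuration; identical configurations give byte-identical outputs.

## Problem sizes in the test suite

The suite verifies the folder against exhaustive enumeration on 1,000
random sequences of length ≤ 12; rate-test calibration on 1,000
independent null triplets of 214 sites; six-parameter/JC69 agreement on
10 replicates of 10 kb; and the simulator's stem/loop ordering and
neutral-limit equality on 100 replicates each of the 45-taxon default
condition. These sizes were chosen to bound Monte-Carlo error well below
the assertion tolerances while keeping the default run quick.

## Known limitations

* The matched-pairs contrast inherits the field's pseudo-replication;
  treat its p-values as descriptive.
* The chi-square reference for the LRT is asymptotic; at < 100 sites the
  test runs slightly liberal.
* The base-pair-maximisation structure can differ substantially from a
  minimum-free-energy structure; supply an external dot-bracket for
  structure-sensitive conclusions.
* Majority-consensus ancestral states can mis-polarise substitutions at
  sites where the derived allele has spread to more than half the taxa;
  outgroup polarisation is available where outgroups exist.
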