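# Methods

## Model

Sequences of an aligned family are modeled by a Potts distribution over
q = 21 states (the 20 amino acids in alphabetical one-letter order,
codes 0–19, plus the gap, code 20):

P(X) ∝ exp[ Σ_i h_i(X_i) + Σ_{i<j} J_ij(X_i, X_j) ].

The parameterization is redundant (gauge freedom): adding per-state
offsets to a coupling block and compensating in the fields leaves P
unchanged. All scoring is done in the zero-sum gauge, the unique
representative whose coupling blocks have zero row and column means;
`zero_sum_gauge` double-centers every block and folds the removed row
means into the fields, so sequence probabilities are preserved up to a
single global constant (verified by exact enumeration on a 3-site,
3-state toy to 1e-10).

## Alignment preprocessing

Ambiguous and nonstandard residues (B, Z, J, X, U, O) are encoded as
gap — they carry no usable coupling information and appear routinely in
database-derived alignments. Sequences with more than 10% gapped
positions are removed (a sequence at exactly the threshold is kept).
Sequence weights are w_s = 1/|{t : identity(s,t) ≥ 0.9}| with the
neighbor set including s itself; identity is counted over all L columns
with the gap as an ordinary 21st symbol (the simplest deterministic
convention; alternatives such as ignoring gap–gap columns change N_eff
only marginally on realistic alignments). N_eff = Σ w_s.

## Pseudo-likelihood inference

The full likelihood is intractable (Z sums over 21^L states), so each
position's conditional distribution is maximized independently:

f_i(h_i, J_i·) = −(1/N_eff) Σ_s w_s log P(x_si | x_s,−i)
                 + λ_h ‖h_i‖² + λ_J Σ_{j≠i} ‖J_ij‖²,

a convex multinomial logistic regression on the one-hot encoding of the
other columns. λ_h = λ_J = 0.01 on this weighted-mean scale (the
standard value; no depth-dependent rescaling is applied). Minimization
uses L-BFGS-B from a zero start with analytic gradients (checked
against central finite differences; the relative error is measured
against max(|fd|, ‖g‖∞) because finite-difference roundoff ~1e-10
dominates components of magnitude ≲1e-5) and is declared converged at
projected-gradient norm ≤ 1e-5; a fit that stops above the tolerance
raises with the final gradient norm rather than returning silently.
The two directed estimates of each J_ij are averaged, restoring exact
coupling symmetry.

## Mean-field solver

The paralog-matching loop refits the model dozens of times on small
matched alignments, where pseudo-likelihood would be both slow and
noisy; there the classical mean-field inversion is used: pseudocount-
regularized weighted frequencies f_i, f_ij (default pseudocount 0.5 of
uniform), the connected-correlation matrix C over q−1 states per
position (the gap state is the gauge reference), and J = −C⁻¹ with
fields from the independent-site relation. A singular C raises with
advice to increase the pseudocount.

## Contact scoring

Raw score S_ij = Frobenius norm of the gauged coupling block restricted
to the 20×20 amino-acid sub-block, with the gauge computed on that
sub-block — couplings carried entirely by gap states score exactly
zero, suppressing artifacts of long gap stretches. The average product
correction S'_ij = S_ij − S̄_i S̄_j / S̄ (row means excluding the
diagonal) removes conservation/entropy background; a constant matrix
maps exactly to zero. For two concatenated families the correction is
asymmetric: the two averages are taken over the two families
separately, which absorbs differences in evolutionary rate between the
families; intra-family blocks keep the symmetric rule.

Ranked predictions keep the top N pairs (N = L by default; an optional
multiplier doubles retention for use cases such as homodimer
interfaces) among pairs with j − i ≥ 5; inter-family pairs have no
separation rule. Ties break lexicographically so rankings are
reproducible. For a 109-column family the eligible set has
(109−5)(109−5+1)/2 = 5460 pairs and default retention keeps 109 (~2%).

The inter-family score is additionally normalized,

S̃_ij = S_ij / ( |min over inter pairs S| · (1 + N/N_eff) ),

which makes the 0.8 acceptance threshold comparable across family
pairs. The grouping with (1 + N/N_eff) in the denominator is adopted
(the alternative reading multiplies the score); the choice is isolated
in `normalized_inter_score` and is a positive rescaling either way, so
rankings are unaffected. N and N_eff refer to the concatenated matched
alignment.

## Structural validation

Two residues are in contact when at least one pair of heavy atoms lies
strictly below 8.5 Å (the topology is robust to moderate cutoff
changes; lowering the cutoff only removes contacts). Structures are
read from PDB/mmCIF; hydrogens are dropped, altlocs resolved to highest
occupancy, heteroatoms excluded except selenomethionine (kept as
methionine). Alignment columns are mapped to structure residues by
global alignment of the family consensus (most frequent non-gap residue
per column, ties to the lower code) against the structure sequence,
match +1 / mismatch 0 / affine gaps with free ends; the mapping is
flagged unreliable when either the aligned fraction of the consensus or
the identity over aligned columns falls below 30% — the identity guard
is needed because a mismatch-0 global alignment of unrelated sequences
still attains full coverage.

The true-positive rate at rank k is the fraction of the first k
mappable predictions that are native contacts; unmappable predictions
are excluded from the denominator and counted separately (the
conservative convention — they are neither right nor wrong about the
reference). The shortest-path class of a prediction is its graph
distance in the contact graph containing *all* structural contacts,
including sequence neighbors: mediation through the chain is part of
what the measure captures, so no separation filter is applied there.
Native contacts have SP = 1; disconnected pairs get the sentinel −1.

## Iterative paralog matching

Organisms present in both families contribute min(N_A, N_B) matchable
pairs; N_max is the sum over organisms. One run proceeds:

1. uniformly random one-to-one matching within each organism (the seed);
2. mean-field fit on the concatenated matched MSA;
3. every candidate (a, b) pair in every organism scored by the sum of
   gauged inter-family couplings J_ij(a_i, b_j);
4. all candidates ranked globally and greedily accepted under the
   one-to-one-per-organism constraint until n_select pairs are matched
   (an exact per-organism Hungarian assignment is available behind
   `match_method="exact"`; the greedy rule is the default because
   confidence-ranked greedy growth is what lets early high-confidence
   pairs bootstrap the signal);
5. n_select grows by 6 per iteration (the first iteration keeps 6 —
   the random seed is discarded), until n_select ≥ N_max.

Because a single run depends on its seed, the procedure is repeated
with child seeds spawned from the master seed by counter; each run's
*final* matched MSA is scored with the pseudo-likelihood model,
asymmetric APC and the normalized score, and an inter-family column
pair is accepted when S̃ > 0.8 (strict). The acceptance frequency over
runs is the robustness measure reported; with zero planted
inter-couplings no pair approaches frequency 1, the negative control.

## Synthetic data

The generators provide what real inputs cannot: exact ground truth.

- **Topology**: a self-avoiding biased random walk with 3.8 Å steps
  (Cα virtual bond) and 3.9 Å clearance; chains are redrawn until the
  realized number of |i−j| ≥ 5 contacts under the 8.5 Å cutoff lies in
  [target, 1.2·target]. The returned contact list is the *realized*
  one, so structure-derived maps reproduce it exactly.
- **Planted couplings**: zero fields; each long-range contact gets a
  coupling block that is either sparse (±strength on 60 random
  amino-acid state pairs — a generic interaction pattern) or a
  permutation (+strength on a random one-to-one amino-acid
  correspondence — the strongly specific regime). Blocks are planted
  already in zero-sum gauge and never touch gap states.
- **Sampling**: single-chain, single-site heat-bath Gibbs with burn-in
  and thinning (numba kernel). Correctness is bounded by the exact
  2-site enumeration check; the null model reproduces uniform column
  frequencies.
- **Paired families**: true interaction partners are co-sampled jointly
  from a model with permutation couplings on 20 planted inter-pairs;
  decoy paralogs are halves of independent joint samples. Thinning is
  30 sweeps here: with strong couplings the chain decorrelates slowly,
  and insufficient thinning makes consecutive samples (hence decoys and
  true pairs) spuriously similar, which destroys the matching signal —
  the study condition is independent draws, and 30 sweeps achieves that
  to within the tests' tolerance.

What the generators do *not* emulate: phylogenetic correlation between
sequences, indel processes (gaps appear only as a 21st Potts state at
~1/21 per site), position-specific conservation profiles, and database
artifacts (fragments, misalignments). Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's
own assumptions, not expected accuracy on real families, where
phylogenetic bias and shallow alignments degrade both DCA and IPA.

## Problem sizes and calibrated floors

The standard synthetic monomer is L = 40, ~60 planted long-range
contacts, sparse couplings of strength 1.2, M = 6000 samples: pilot
runs recover the planted contacts with top-L TPR = 1.0, and the
acceptance floor is kept at the conservative 0.7. The paired preset is
20 organisms with 2–3 paralogs per side (N_max ≈ 45), permutation
couplings of strength 5.0: pilot mean matching accuracy across seeds is
0.91–1.0 (floor 0.8, measured as the mean over 5 runs), collapsing to
~0.3–0.4 with the couplings removed (chance for 2–3 paralogs). Module
tests use further scaled-down instances (L = 12–16, hundreds of
sequences) chosen to keep the full suite under a minute apart from the
two preset-scale recovery tests.

## Known limitations

- Pseudo-likelihood fits hold the dense one-hot design matrix per site
  (M × (L−1)·q doubles); for alignments much deeper or longer than the
  preset scale a batched or sparse implementation would be needed.
- The mean-field solver inverts an L(q−1) matrix; memory grows
  quadratically in L.
- The IPA bootstrap needs a detectable inter-family signal at the
  random-seed stage; on weak couplings or very few shared organisms it
  converges to seed-dependent matchings (visible as low acceptance
  frequencies, which is the intended diagnostic).
- Organism extraction from FASTA headers covers the common database
  conventions (OS= tag, db|acc|name ids) only.
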