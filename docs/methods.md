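# Methods

## Model

All variables are binary ("on/off"). A network is a DAG whose nodes carry
conditional probability tables (CPTs): node *X* with parents pa(X) is on
with probability P(X=1 | pa(X)) read from its CPT row; roots carry a single
prior row. The joint factorizes as ∏ᵢ P(Xᵢ | pa(Xᵢ)). Exact inference is
full enumeration of the 2^K state space, refused above K = 20 nodes (the
reference network needs 512 states); sampling is ancestral.

Stochasticity is represented explicitly: each node's draw compares one
uniform exogenous noise *u* ∈ [0,1) against its CPT probability
(*state = 1 iff u < p*). Sampled realizations record these noises, which
makes individual-level counterfactuals well defined: clamping nodes and
replaying the stored noises through the reconstruction rule yields *the*
counterfactual for that individual, deterministically and idempotently,
even for stochastic CPTs. This generalizes the common practice of reasoning
counterfactually only through deterministic gates.

## Information measures

All quantities are in **bits** (the convention of the higher-order
information literature; a downstream threshold like "MI < 0.05" is
therefore a bits threshold). For variables X₁…Xₙ with joint entropy H(X):

- total correlation TC = Σᵢ H(Xᵢ) − H(X);
- dual total correlation DTC = (1−n) H(X) + Σᵢ H(X \ Xᵢ);
- O-information Ω = TC − DTC, computed independently as
  (n−2) H(X) + Σᵢ [H(Xᵢ) − H(X \ Xᵢ)] so the identity serves as a
  cross-check. Ω < 0 flags synergy-dominated interdependence (XOR triplet:
  exactly −1 bit), Ω > 0 redundancy (three copies of a bit: +1);
- Whole-Minus-Sum synergy WMS = MI({P₁,P₂};T) − MI(P₁;T) − MI(P₂;T).

From data, measures use the plug-in (maximum-likelihood) estimator on
empirical cell frequencies. Plug-in MI/Ω are biased at small n, but the
scan's permutation null is computed with the same estimator, so the bias
cancels where it matters; an optional Miller–Madow entropy correction
exists and is off by default. Missing values are rejected unless listwise
deletion is requested explicitly (`missing="drop"`), so denominators never
drift silently.

## The reference network

Nine nodes: signs S1…S6, diseases D1…D3. S1, S2, S5 are roots; S2→S3 and
S3→D3 are strong noisy-channel links; S4 is a synergistic child of
{S1,S2} and S6 of {S2,S3}; D1 = OR(S1,S4), D2 = OR(S5,S6) are
deterministic gates (diseases are inferences from signs, with no back-edges
to signs).

**Synergistic CPT design.** `optimize_synergistic_cpt` maximizes an
information objective over the 4 free probabilities by multi-start
Nelder–Mead in [0,1]⁴ (default 50 restarts, seeded, reproducible), with
single-parent MIs above a cap (default 0.01 bits) penalized. The default
objective is WMS; with fair independent parents the optimum is a parity
gate (XOR/XNOR) at WMS = 1 bit. Every information objective is exactly
invariant under complementing the output (q → 1−q), so optima come in
pairs; ties are broken first by smaller maximum pairwise MI, then by
preferring the table in which both parents on activates the child — the
convention under which a patient may present with all signs co-active.

**Why the builder is not a plain WMS maximizer.** The gate D1 = OR(S1,S4)
shares the parent S1 with the triplet S1,S2 → S4. An OR gate masks its
other input whenever S1 = 1, which breaks the cancellation that makes
MI(S2;S4) ≈ 0 and *leaks* a pairwise association MI(S2;D1) — for a pure
XOR table the leak is ≈ 0.31 bits, enough to fuse the pairwise network into
one component and destroy the phenomenon the model exists to display.
The builder therefore maximizes the *joint* parent information
MI({S1,S2};S4) subject to penalty caps of 0.008 bits on each parent–child
MI and 0.04 bits on the OR-gate leak (both safely below the 0.05-bit graph
threshold). Numerical exploration of this constrained problem shows the
feasible optimum needs a moderate-low P(S1): root priors are therefore
drawn once, at build time, from designed windows — P(S1) ~ U(0.25,0.35),
P(S2) ~ U(0.45,0.55), P(S5) ~ U(0.40,0.60) — rather than from an
unconstrained flat prior, whose extreme draws would silently void the
designed structure (e.g. a skewed P(S2) collapses MI(S2;S3) below 0.3
bits; a low P(S5) lets the high prevalence of the XNOR-type S6 swamp the
S5–D2 association). The S5 window's lower edge also keeps a +0.2 nudge
in range.

**Why the S2→S3 channel is asymmetric** (P(S3=1|S2)=0.85/0.10 rather than
a symmetric 0.9/0.1): with a symmetric channel the optimal synergistic S6
is an exact parity gate, whose output marginal is *invariant* to any shift
in P(S2) — a population nudge on S2 would then have literally zero effect
on S6 and D2. The asymmetry (kept small) restores causal sensitivity while
leaving MI(S2;S3) ≈ 0.46 bits. The S3→D3 channel is 0.95/0.05.

The default network is built from seed 1851 and shipped frozen as JSON
(`src/synergynet/data/`); `build_reference_network` regenerates it
bit-identically. A second variant, `figure1b`, replaces the optimized S4
table with the literal worked-example CPT
(P(S4=1|0,0)=0.028, (0,1)→1, (1,0)→0, (1,1)→1). The two variants are
deliberately both available: the literal table makes S4 a near-copy of S2
(strong pairwise association) and supports the all-signs-active patient
narrative; the optimized table realizes the pairwise-blind synergy claims.

## Interventions

*Nudges* (soft interventions) add signed probability mass to a **root**
prior and leave every CPT untouched. Non-roots are rejected: their
marginals are not free parameters once the conditionals are fixed. Effects
are reported per node as Δlog-odds = logit(post) − logit(pre) in natural
log units, computed from exact marginals; a marginal at exactly 0 or 1
reports a signed infinity with an explicit flag rather than an epsilon
fudge. Non-descendants of the nudged node change by exactly zero.

*do* interventions clamp nodes of a single realization and recompute
descendants in topological order with the original noises (see Model).

## Synergy scan

1. **Triangle filter**: all unordered triples whose three pairwise plug-in
   MIs are each strictly below 0.05 bits — the triples a pairwise analysis
   dismisses; deterministic lexicographic ordering.
2. **Permutation test**: the observed plug-in Ω is compared with B = 1000
   null datasets in which *each of the three columns* is independently
   row-shuffled (marginals preserved, all dependence destroyed). This
   targets the global null of mutual independence, which matches the
   filter's premise that dyadic dependence is already negligible. The
   one-sided p = (1 + #{Ω_null ≤ Ω_obs}) / (B+1) points at the synergistic
   (negative) tail; the +1 smoothing keeps the test valid at finite B, and
   a two-sided variant is reported alongside. RNG streams attach to columns
   in sorted label order, so p-values are reproducible and independent of
   triple orientation. Constant columns yield a degenerate warning and
   p = 1.
3. **FDR control**: Benjamini–Hochberg (via statsmodels) at q ≤ 0.15 over
   exactly the filtered candidate set. This is post-selection — filter and
   test use the same data — and is documented as approximate, mirroring
   standard practice. An ordinary α-threshold on p is available for users
   who prefer it.

The permutation engine bit-packs shuffled columns and reads the eight
contingency cells of each triple off three AND-popcount reductions; all
candidate triples share each column's B shuffles (valid under the
mutual-independence null), which makes 455 candidates × 1000 permutations
run in seconds.

`conditional_profile` provides the clinical-style view of a triple:
P(target=1) under each configuration of one or two conditioning signs, with
empty cells reported as undefined rather than 0. For a synergistic triple,
single-sign conditionals hug the marginal while two-sign conditionals swing
far from it.

## Synthetic surveys

`generate_survey` emulates the *shape and mechanism structure* of a
geriatric screening table: defaults of 587 subjects, 37 signs and 14
binarized disease indicators; background signs independent with skewed
prevalences U(0.05, 0.40); planted noisy-copy pairs (fidelity 0.9); planted
synergistic triplets C = XOR(A,B) with 5% flip noise; diseases as OR gates
over 1–3 signs with the same flip noise. Planted-triplet *inputs* draw
prevalences from U(0.4, 0.6): the XOR of two strongly skewed inputs has
≈ 0.16 bits of *pairwise* MI with each input, so the low-MI triangle filter
would eject every planted triple and recovery would be impossible by
construction — near-balanced inputs are the regime in which purely
synergistic triples exist at all. Five triplets and three pairs are planted
by default, enough structure to exercise recovery without crowding the
37-sign pool. Every generator emits a manifest of all planted mechanisms
(and drawn prevalences) and is deterministic given its seed;
`generate_null_survey` produces a same-shape, all-independent table for
type-I-error calibration.

What the generator does **not** emulate: real item wording, missingness,
ordinal-scale binarization, or dependence among background signs. Passing
recovery tests therefore demonstrates the pipeline's statistical behaviour
under its own assumptions, not performance on real cohort data.

## Numerical choices and problem sizes

- Exact joint tables must sum to 1 within 1e-9; topological order breaks
  ties lexicographically for bit-reproducibility; every stochastic
  operation takes an explicit seed.
- Optimizer: Nelder–Mead with bounds, xatol 1e-8, penalty weight 200 on
  cap violations; candidate set includes each restart's complement; 50
  restarts make the 4-d search robust in practice.
- Validation sweeps use 100 000-realization samples for network-level MI
  claims; scan calibration uses 20 independent-null replicates and power
  uses 50 planted replicates of 15-column, 5 000-subject tables at 1 000
  permutations — sizes chosen to give stable Monte-Carlo estimates while
  keeping a full run in the minutes range on one core.

## Known limitations

- The scan enumerates triples only; quadruplet and higher synergies are
  out of scope, and C(m,3) growth makes very wide tables expensive.
- O-information is conservative: a non-negative Ω does not rule out partly
  synergistic structure, and no decomposition into unique/redundant/
  synergistic atoms is attempted.
- BH over a data-dependent candidate set is approximate (see above).
- Soft interventions are defined for root nodes only; there is no
  intervention search or cost model.
- Binary variables only; continuous or ordinal data must be dichotomized
  upstream.
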