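# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, so that a maintainer can see not only what
the code does but why.

## Inputs and preprocessing

The pipeline consumes a background PPI edge list, a genes × samples
expression table with a sample manifest (one tumor and one tumor-adjacent
sample per patient), a minimal mutation table (sample, gene), a driver
gene list, a clinical table (stage 1–4, subtype CMS1–4, either may be
unknown), GMT gene-set collections and directed SIF pathways. Gene
symbols are trimmed and uppercased everywhere; symbol case drift between
resources otherwise splits one gene into two nodes. Network
preprocessing removes self-interactions, collapses duplicate unordered
pairs and leaves no isolated nodes; a load report accounts for every
input line (kept + dropped-by-reason sums to the line count). Parsing is
strict by default; a tolerant mode logs and skips malformed lines
instead.

Expression values are treated as arbitrary nonnegative abundances. The
pipeline never assumes counts, RSEM or log scale; the only operations
applied are an exact zero test (patient-network filter) and a
pseudo-count log ratio (DNB stage). This is deliberate: the methods are
rank/correlation-based downstream, and the zero test is about detected
vs. undetected expression, not magnitude.

## Patient-specific networks

An edge survives for a patient iff **both** endpoints are expressed in at
least one of the two tissues. The test is exact equality to zero — the
rule is about zeros, not near-zeros, and abundances are nonnegative.
Genes missing from the expression table count as zero in both tissues
(the conservative reading: absence of evidence of expression). Isolated
nodes are re-pruned per patient, consistent with the global
preprocessing. The filter is per-gene and independent, so expressing an
additional gene can only add edges (monotonicity, property-tested).

## Random walk with restart

With adjacency A and column-normalized M (M[i,j] = A[i,j]/degree(j)),
the walk from a single seed iterates
P(t+1) = (1−r) M P(t) + r P(0), P(0) = e_seed, until the **max-norm**
difference between iterates falls below the tolerance. Max-norm is the
strictest of the common choices; the iteration is a convex combination of
stochastic vectors, so mass is conserved exactly and p[seed] ≥ r always.
Defaults r = 0.7, tol = 1e-10, max 10 000 iterations (the contraction
factor is 1−r, so convergence takes ~70–130 iterations in practice; the
cap only guards pathological inputs). Walks are single-seed by design;
multi-seed restart vectors are out of scope. Disconnected patient
networks need no teleport correction: the walk provably stays in the
seed's component and scores elsewhere are exactly zero.

The iterative solution is tested against the closed form
p = r (I − (1−r) M)⁻¹ e_seed on random connected graphs (n ≤ 200) to
1e-8 max-norm.

## Modules and giant clusters

A seed's propagation module keeps genes with score strictly greater than
the threshold (default 0.001; exposed as a parameter since the useful
value depends on network size). Any threshold below r keeps at least the
seed; an empty module is permitted but logged. The giant cluster is the
largest connected component of the subgraph induced by the union of all
module gene sets; ties are broken by number of contributing seeds, then
by lexicographically smallest gene set, making the result deterministic.
Seed coverage is the fraction of the patient's seeds whose module
intersects the GC.

## Greedy mutation ordering

One sequence is generated per non-driver initial seed (drivers may still
appear later in a sequence). At each step the candidate set is the
unmutated seeds whose module shares at least one gene with the union of
the modules of already-chosen seeds ("overlap" = nonempty intersection);
the chosen candidate minimizes the size of the connected component
containing its seed in the subgraph induced by the current union plus
its module. Ties go to the lexicographically smallest gene. When no
candidate overlaps (a dead end the rule itself does not cover), the
remaining seed with the smallest module is appended and the position is
flagged as a fallback, keeping sequences total so the precedence matrix
stays well defined.

Precedence counts C[i][j] (sequences where i occurs before j) satisfy
C[i][j] + C[j][i] = number of sequences containing both — an identity
the tests verify exhaustively. A total order is derived by Copeland
scoring over the restricted gene set (wins − losses on pairwise
majorities), ties broken by net margin then lexicographically; Copeland
is the simplest deterministic completion of a pairwise-majority
relation. Subtype consensus sums the per-patient matrices before
scoring, which weights patients by how many sequences they contribute.

## Log-ratio matrix and the criticality index

Each patient contributes one tumor/adjacent pair, so fluctuation and
correlation statistics cannot be computed within a patient. They are
computed **across patients** on per-patient log2((tumor+1)/(adjacent+1))
ratios — each patient's pair reduced to a "how far from normal" profile.
This is the main inference the method requires and at least three
patients are needed for it to be defined.

For a dominant group against a background (all other measured genes):

    CI = size × SD_i × PCC_i / max(PCC_o, 1e-8)

with SD_i the mean sample standard deviation (ddof = 1) of member
log-ratios, PCC_i the mean absolute Pearson correlation over
within-group pairs, PCC_o the mean absolute correlation over
group×background pairs. Pairs involving a zero-variance gene contribute
|r| = 0. SD_i sits in the numerator because criterion (1) demands that
members fluctuate strongly — high SD must raise, not lower, the index.
The 1e-8 floor on PCC_o keeps CI finite when the background is
uncorrelated; engaging it is flagged. CI is linear in the overall scale
of the matrix (through SD_i) and invariant to patient order — both are
property-tested.

## Dominant-group selection

At driver step k the candidate pool is the union of the first k drivers'
modules, restricted to the GC and to measured genes. A differential
filter keeps genes whose mean |log-ratio| reaches the pool's
`de_quantile` quantile (default 0.5); "differential expression analysis"
is otherwise unspecified in this setting, and a within-pool quantile
keeps the filter scale-free. The filtered pool is partitioned by
k-medoids (PAM-style, hand-written since no installed library provides
it) on the distance 1 − |r|, with k ∈ [2, min(8, n−1)] chosen by maximum
average silhouette; medoid seeding uses a seeded generator (default 17, a
required config field). Pools smaller than 4 after filtering fall back
to a single flagged group.

Among the resulting clusters, the one with the highest CI is selected
and then **trimmed to its coherent core**: members are removed one at a
time (lowest mean within-group |r| first) and the subgroup along this
prune path maximizing size × SD_i × max(PCC_i − PCC_o, 0) is kept. The
trim operationalizes criteria (2) and (3) jointly — a member must
correlate with the group clearly above the background level. It is
needed because with cohort-scale sample sizes (a few dozen patients) the
null |r| level is ≈ 0.8/√n ≈ 0.16, and CI's linear size factor then
rewards loose supersets: genes correlating at the background level add
to size while diluting PCC_i toward PCC_o, and we measured mixed
clusters out-scoring the true coherent group on raw CI. The excess-
correlation score is size-stable because such genes contribute nothing
to PCC_i − PCC_o. The reported CI is still the canonical formula,
computed on the trimmed group.

The transition point is the earliest step attaining the maximum CI of
the series; an all-zero series is flagged as no-signal. In the full
pipeline the series is indexed by the patient's greedy-derived driver
order; the recovery experiments (below) may instead condition on a known
order.

## Clinical-stage validation

Within each subtype, for every ordered patient pair (e earlier stage,
l later stage), the pair is consistent when every transition gene of e
appears in l's driver order at a position no later than every transition
gene of l; strictly later is inconsistent; absent genes make the pair
not evaluable. Position equality is deliberately allowed: two patients
sharing a transition gene should not count against the ordering. The
report gives per-subtype counts and the overall consistent fraction
(consistent / (consistent + inconsistent)).

## Enrichment and subtype comparison

Giant clusters are tested against each gene set with the upper-tail
hypergeometric test P(X ≥ overlap) on the universe of global-network
nodes (GCs are drawn from it), sets intersected with the universe first,
Benjamini–Hochberg adjusted per collection. Per-patient profiles are
reduced to the median of −log10(adjusted p) across sets — a documented
reduction, since the comparison of full profiles between subtypes is
otherwise not a scalar test — and subtype pairs are compared with the
exact two-sided Wilcoxon rank-sum test (subtypes with fewer than two
patients are skipped).

## Target mining

Per subtype: the DNB set is the union of transition-point dominant
groups; the driver set is the union of transition-point drivers and the
driver immediately preceding the transition in each patient's order
(patients transitioning at step 1 contribute only their transition
driver). A candidate target is a DNB, non-driver gene strictly interior
to a simple directed pathway path d1 → … → d2 (≤ `max_path_len` edges,
default 6, bounding the enumeration) between two driver-set genes with
d1 before d2 in the consensus order. An independent checker re-verifies
all three conditions for every emitted candidate; raising the path
budget can only add candidates (monotonicity, tested).

## Synthetic cohorts

The generator emulates the real input battery at desk scale with planted
ground truth. Defaults (the reference study conditions): 300 genes,
preferential-attachment m = 2 (edge count C(m,2) + m(n−m); for n = 100,
m = 2 that is 197), 24 patients, 8 drivers placed on the highest-degree
nodes (large, overlapping modules), planted transition step k\* = 5, DNB
group of 6, within-group correlation ρ_in = 0.8, group-to-background
ρ_out = 0.1, SD inflation 3×, order noise p_swap = 0.1, 6–14 passengers
per patient sampled from mutated drivers' neighborhoods (guaranteeing
module overlap for the greedy rule), 2% per-patient silent genes
(exercising the expression filter; drivers and DNB genes are protected).

Each patient mutates a prefix of the planted driver order; prefix length
cycles over 1..8 so all stage bands (quartiles of prefix length) are
populated, and subtypes cycle CMS1–4. Order noise is a Thurstonian
rank-jitter: each driver's rank is perturbed with Gaussian noise of
σ = 1/(√2 Φ⁻¹(1−p_swap)), calibrated so adjacent pairs invert with
probability p_swap; p_swap ≥ 0.5 degenerates to a uniform random
permutation. (A single-pass adjacent-transposition channel cannot
destroy long-range order even at p = 0.5, so it has no usable negative
control.)

Expression is generated in log-ratio space with a one-factor model:
DNB genes load √ρ_in on a latent per-patient factor, background genes
load ρ_out/√ρ_in, giving pairwise correlations ρ_in within the group and
ρ_out across; DNB amplitudes are multiplied by the SD ratio in patients
whose prefix reaches k\*. Baseline log2-ratio SD is 0.5 — a typical
tumor/normal fold-change dispersion. Tumor and adjacent abundances are
reconstructed from uniform(4, 8) log2 baselines so that the +1
pseudo-count ratio reproduces the planted values exactly and all
abundances are nonnegative. The DNB genes are non-driver neighbors of
the k\*-th driver chosen to be maximally distant from earlier drivers,
so the full group enters the candidate pool only once driver k\* has
mutated.

What the generator does **not** emulate: count-model realism (library
size, overdispersion), mutational signatures, co-expression structure
beyond the single planted factor, subtype-specific biology (all subtypes
share one planted order), and network rewiring between patients. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of a planted signal under the stated conditions — not
performance on real tumor cohorts.

## Recovery experiments and problem sizes

Three seeded experiments (`tippingnet.evaluate`) quantify recovery; the
acceptance script reruns them from scratch.

- **Transition recovery**: 50 one-cohort replicates at the default
  configuration; per replicate up to 3 eligible patients (driver prefix
  reaching k\*) are analyzed and the median detected step is compared to
  k\* (hit = within ±1); DNB overlap is Jaccard vs the planted group
  among hits. The CI series here is conditioned on the generator's true
  per-patient driver order: the greedy rule is a structural heuristic
  with no temporal signal in synthetic mutation *sets*, so conditioning
  isolates the detection stage; order inference is measured separately.
  Measured: hit rate 1.0, mean Jaccard ≈ 0.98.
- **Consensus-order recovery**: 12 full-length noisy patient orders per
  replicate; Kendall τ (direct pair counting) between the Copeland
  consensus and the planted order. τ = 1.0 at p_swap = 0.1; at
  p_swap = 0.5 the mean τ over 20 replicates is ≈ 0.01–0.04, inside the
  null band.
- **Clinical consistency**: every patient carries the full planted order
  with transition depth equal to their prefix length (the quantity the
  stage label is derived from), so the true-label fraction is 1.0 by
  construction and shuffling stage labels breaks it in 20/20 replicates.
  Full orders are essential: with nested prefix orders an early-stage
  gene is either before the late gene or absent, and inconsistency would
  be structurally impossible.

## Numerical choices and degenerate inputs

- Strict ">" at the module threshold; exact zero test in the patient
  filter; ddof = 1 standard deviations; |r| clipped to [0, 1].
- Zero-variance genes contribute |r| = 0 to all correlation averages.
- All tie-breaks (GC components, greedy candidates, Copeland, cluster
  choice) are total and lexicographic at the last resort, so identical
  inputs give byte-identical outputs.
- Degenerate cases are explicit: empty networks and empty module unions
  raise; patients with no usable seeds are skipped with a warning; pools
  under 4 genes fall back to a flagged single group; series of all-zero
  CI are flagged rather than silently argmax'd.
- The pipeline manifest hashes parameters and counts records per stage;
  reruns of an unchanged config produce identical manifests.

## Known limitations

- CI's linear size factor makes raw cluster selection scale-sensitive;
  the coherent-core trim addresses it, but very small groups (2–3 genes)
  remain hard to distinguish from chance correlation at n ≈ 24 patients.
- The cross-patient log-ratio design estimates one global correlation
  structure; truly patient-private DNBs (present in one patient only)
  are invisible to it.
- The greedy mutation order is a heuristic; its sequences are
  deterministic given modules but carry no calibrated uncertainty.
- Enrichment assumes the global network as universe; if GCs are built on
  a much smaller expressed subnetwork the test is conservative.
- Pathway target mining depends entirely on the curation and gene
  aliasing of the input SIF files.
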