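# Methods

## Model

The cohort is a single undirected, simple interaction network
G = (V, E) over gene symbols together with one coloring per sample:
C[i, j] ⊆ A is the set of alteration types ("colors", alphabet A)
observed for gene j in sample i; an absent entry means no alteration. A
*conserved colored subnetwork* T is a connected node set with exactly one
assigned color c_j per node. Sample i *shares* T when c_j ∈ C[i, j] for
every node, up to at most ⌊δ·|T|⌋ exception nodes when the error rate δ
is nonzero. Sharing tests set membership, never equality: a node carrying
several colors in a sample may support any one of them. The number of
sharing samples is T's *depth*.

Two exception semantics are provided. In the default **strict** mode an
exception node must carry *no* color in that sample (a miscolored node
disqualifies the sample outright); the **lenient** switch also admits
miscolored exceptions. Strict is the default because the δ relaxation is
meant to absorb sensitivity losses of upstream callers — a missing call —
not genuine disagreement in alteration type; both semantics are
implemented and tested because either reading is defensible.

The omission budget is ⌊δ·|T|⌋, i.e. integral and equal to 0 for small
subnetworks at small δ.

## Candidate enumeration

Candidates of size ≤ k and depth ≥ t are generated breadth-first, one
node at a time, in the spirit of the a-priori algorithm for frequent-set
mining with a connectivity requirement. The anti-monotone property of
sharing (a sample sharing T shares every connected colored sub-network of
T with no more omissions) justifies pruning: a candidate whose attainable
support falls below t cannot be completed into a valid subnetwork.

Two design points matter for exactness:

* **δ-lookahead.** With δ > 0 the budget ⌊δ·s⌋ grows with size, so a
  subnetwork can reach depth t while none of its one-node-smaller
  subnetworks does at their own budget. Growth therefore retains any
  candidate whose support under the *maximal* budget — ⌊δ·K⌋, with K the
  size bound k, or, when k is unlimited, an upper bound on the largest
  reachable size derived from the t-th largest per-sample colored-gene
  count (a sharing sample must properly color at least (1−δ) of the
  nodes) — is at least t. Emission into the candidate set applies the
  per-size budget. Every connected colored subset of a valid candidate
  passes the retention test, so the search is complete; this is verified
  against a brute-force enumerator on hundreds of randomized instances.
* **Each node set once.** Node sets are generated uniquely by growing
  only from an ordered extension frontier excluding nodes already
  adjacent to the candidate (the exclusion-set scheme of connected-
  subgraph census algorithms), with colors branched when a node enters.
  This removes the need for canonical-key deduplication during growth;
  canonical keys (sorted (gene, color) sequences) remain the identity
  used for reporting, regression tests and determinism of output order.

Candidate node sets are restricted to genes carrying at least one
observed color, and a node's assignable colors are exactly those observed
for it somewhere in the cohort — an assignment no sample exhibits cannot
contribute support under strict semantics and would make the δ > 0
candidate set ill-defined over an arbitrary alphabet.

Support is tracked as bit masks over the cohort indexed by omission
level, so extending a candidate costs a handful of bitwise operations
independent of cohort size. A per-iteration candidate cap (default
2·10⁶) aborts infeasibly deep runs explicitly rather than truncating.

Colorful mode (≥ 2 distinct node colors) is an emission filter; growth
itself is unchanged, which keeps the unique-generation argument intact.
Redundancy pruning for the cover step removes any candidate with a
single-node colored extension (within the size bound) shared by at least
as many samples.

## Single- and multi-subnetwork modes

The single mode returns all maximum-size candidates at depth ≥ t (the
full tie set; callers may filter). The depth scan iterates t from
⌈fraction·m⌉ upward and stops when the maximal size drops below the
minimum (maximal size is non-increasing in t) or the candidate cap
trips; for each achieved size the largest depth attaining it is flagged
as a "valley end". Reported supports are maximal sharing sets (≥ t).

The multi mode maximizes Σ C[i,j] over binary choice variables X_p (one
per candidate) and coverage variables C[i,j] (one per colored
(sample, gene) pair in the universe), subject to
C[i,j] ≤ Σ_{p: pair covered by T_p} X_p and Σ X_p ≤ l. A pair is covered
by a chosen T when T contains the gene *properly colored* for that
sample and the sample shares T; δ-exception nodes are never counted as
covered. The ILP is solved with HiGHS via `scipy.optimize.milp`
(variables in canonical-key order for determinism, integrality tolerance
the solver's default 1e-6); the reported objective is re-verified by
recomputing coverage from the chosen set, and a subset-enumeration
brute-force oracle provides an independent check on small instances.
The parameter-free minimum-cover variant (cover *all* colored nodes with
as few subnetworks as possible) is described in the literature but not
solved here.

## Permutation significance

For a discovered subnetwork of size s at depth t, two nulls bracket the
true p-value; each replicate permutes every sample's coloring, re-runs
the single-subnetwork search at the same t and options, and counts a
success when the largest shared subnetwork reaches size s. p = successes
/ replicates (default 1,000 replicates; an optional (r+1)/(n+1)
pseudocount is off by default). A replicate that trips the candidate cap
is counted as a success, which can only make the estimate conservative.

* **p₁ (independent null, lower bound):** each color is shuffled
  independently across the network's nodes within each sample; per-
  sample per-color counts are preserved exactly.
* **p₂ (arm-level null, upper bound):** for each chromosome arm and each
  copy-number color E, *all* of the arm's originally-colored nodes
  receive E together with probability N_E / Σ_j |C[i,j]| (clamped to 1
  with a warning on tiny inputs), independently per (arm, color);
  remaining colors are then shuffled over the nodes still uncolored.
  The expected per-color count is preserved exactly when every colored
  node carries one color and has an arm assignment, and approximately
  otherwise. Arm reassignment targets only originally-colored nodes
  (taken literally from the null's definition); N_E is read as the
  per-sample count of color E.

The bracket holds to the extent that chromosome arms are the largest
units of co-alteration.

## Survival scoring

S_j = Σ_i β_i·x_ij over the subnetwork's genes for the covered patients;
the mean of S splits patients into high (S ≥ mean, ties high) and low
risk. β_i estimation is delegated to lifelines' Cox proportional-hazards
fitter, one gene at a time (Efron tie handling — lifelines offers no
exact-ties method); precomputed coefficients are accepted as-is, since
the bespoke content of this module is the score and the split.
Expression is taken as given (no further normalization). Kaplan–Meier
curves, log-rank tests and hazard ratios are out of scope.

## Synthetic data

The generator emulates, at desk scale, the alteration structure the
miner targets: a sparse random network (largest component of G(n, p)
with p set for a target mean degree; default 6, PPI-like), independent
per-(sample, gene, color) background alterations, optional arm-coherent
copy-number events (all-or-none per arm per sample), and a planted
connected colored pattern carried by a chosen number of samples, each
planted node dropped independently with the omission rate. Independent
background matches the independence assumption of the p₁ null, so p₁
calibration checks are exact by construction. The generator does not
imitate real PPI topology (degree correlations, modularity), mutation
spectra, or inter-gene alteration correlations beyond arm blocks —
passing tests demonstrate algorithmic correctness and calibration, not
biological fidelity on consortium-scale tumor data.

Standard study conditions used by the tests and the acceptance script:

* Oracle equivalence: 200 randomized instances with 5–10 network nodes,
  2–4 samples, 3 colors, background rate 0.2, t ∈ {1,2,3},
  δ ∈ {0, 0.34}, colorful and lenient variants interleaved.
* Planted recovery: 200-node network (mean degree 6), 50 samples,
  planted size 6 at depth 20. Noise-free recovery is exact at t = 20.
  The noisy condition adds background rate 0.01 per (gene, color)
  (≈ 5% of genes altered per sample with the 5-color alphabet) and
  omission rate 0.1, analyzed at δ = 0.2 with size cap k = 10 and
  t = 14: with 10% omissions the expected fraction of carriers within
  the budget ⌊δ·6⌋ = 1 is ≈ 0.885, so demanding the full planted depth
  would fail by construction; 70% of the planted depth is the
  noise-consistent threshold. The cap k = 10 (well above the planted
  size) fixes the maximal omission budget at 2, which keeps the search
  frontier proportionate to the signal actually present.
* Bracketing: 60-node network, 20 samples, arm-coherent AMP rate 0.3
  over 10-gene arms plus independent MUT rate 0.05; discovery at
  t = 5 (25% of the cohort), 10 bracketing runs of 20 replicates per
  null.
* Cox sign recovery: 100 cohorts of n = 200, one gene with β = 0.8,
  baseline hazard 0.1, exponential censoring at rate 0.05.

## Numerical and degenerate-input choices

Omission budgets use ⌊δ·s + 1e−9⌋ to guard against floating-point
underflow of exact products. Duplicate network edges keep the maximum
score (confidence scores; maximum is conservative toward inclusion).
Genes altered but absent from the network are kept in the data model,
logged, and ignored by enumeration and coverage. An empty cohort or an
empty filtered network raises immediately. Solutions, chosen cover sets
and profile rows are emitted in canonical-key order, so identical inputs
and seeds give byte-identical outputs.

## Known limitations

Exhaustive enumeration is exponential in the worst case; the candidate
cap turns pathological instances into explicit errors rather than long
silent runs. The δ-lookahead bound is loose when k is unlimited and
cohorts are dense, which can make error-tolerant unlimited-size runs
slow; bounding k is the practical remedy. The arm-level null is an upper
bound only under the arms-as-largest-units assumption (a duplication
spanning both arms of a chromosome would violate it). Networks are
unweighted beyond the read-time score filter; directed interactions and
edge colors are not modelled.
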