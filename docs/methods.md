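# Methods

This note documents the models, numerical choices and synthetic-data design
behind `mtqsar`, in the order the pipeline runs.

## Molecular graphs and atomic properties

Descriptors operate on the hydrogen-suppressed heavy-atom graph.  Adjacency
ignores bond multiplicity: aromatic, double and single bonds are one edge,
so the topological distance between atoms is a pure bond count.  Hydrogen
counts are retained per atom for molecular weight, H-bond donor counting and
the charge scheme, but hydrogens never appear as graph vertices.

Eight atomic properties weight the quadratic indices.  Four are computed per
atom in its chemical environment via RDKit: Ghose–Crippen logP contributions
(HYD, logP units), Ghose–Crippen molar refractivity contributions (R,
cm³/mol), Ertl polar-surface-area contributions (PSA, Å²; zero on apolar
carbons), and Gasteiger partial charges (CHR, e).  Charges are run for a
fixed 8 iterations, seeded from formal charges, with each atom's attached-H
charges folded into it, so the per-molecule sum equals the net formal charge
to ~1e-15 and results are deterministic.  The other four are element-level
lookups shipped as versioned CSV tables with JSON manifests: Pauling
electronegativity (E), standard atomic mass (M, Da), static dipole
polarizability (POL, Å³) and van der Waals volume from Bondi radii (VDW,
Å³).  Tables cover C, N, O, S, P, F, Cl, Br, I (plus H, B, Si); an
uncovered element is a hard error naming the atom and property, never a
silent default.  Users may override any table through `PropertyTable`.

Salt/counterion handling: multi-fragment SMILES are an error unless
keep-largest-fragment curation is requested (the default in dataset
readers).

## Quadratic indices

Local index of order k at atom i:  Lq_k(x, i) = x_i · (M^k x)_i.  Two
readings of k are implemented:

* `walk_power` (default): M^k is the k-th matrix power, counting length-k
  walks.  This is the standard formalism; k = 0 gives the identity, so
  order-0 indices are per-atom squares x_i².
* `shortest_path_distance`: the 0/1 indicator of topological distance
  exactly k.  Offered because descriptor interpretation conventionally
  speaks of "atoms separated by k bonds"; the two readings agree at k ≤ 1
  and diverge beyond, which the documentation flags rather than hides.

Stochastic (`ss`) variants row-normalise the adjacency before powering
(rows of any power then sum to 1); in distance semantics the indicator
itself is row-normalised and all-zero rows stay zero.  Aggregation
operators: N1 = ΣL; N2 = ΣL² by default — the sum-of-squares form is kept
as primary with a Euclidean-norm (√ΣL²) option; GM is the sign-preserving
n-th root of the product (0 if any local is 0), computed in log space to
avoid overflow; RA = max − min; MX; MN.  NaN is never returned.

Column names are canonical and parseable: `T{ns|s}sq{k}({PROP}){AGG}`, with
CHR abbreviated CH.  The default order range is 0–15, giving headroom over
the 1–13 range typically selected by feature search.

## Condition ontology and Box–Jenkins deviations

A record is one (compound, condition) assay with condition
c_j → (bt, me); the default ontology is the four ERK combinations
(ERK-1/ERK-2 × IC50/Ki).  Labels: active (+1) iff activity ≤ 500 nM,
boundary inclusive.

Deviation descriptors subtract, per condition element, the descriptor mean
of the *active training* records sharing that element value.  Means are
frozen at training time and serialised with the model; prediction under an
element value never seen among training actives is a hard error.  Plain
subtraction is the primary definition; a probability-weighted variant
(deviation × training-active prevalence of the element value) is available
behind a flag for sensitivity analysis.  Duplicated compounds assayed under
several conditions enter the averages as independent records.

Consequences used as test invariants: each Δ column has mean 0 over the
training actives of its element value; adding a constant to a raw
descriptor leaves Δ unchanged; recomputing means with held-out records
included changes Δ (the leakage the pipeline must never commit).

## Dataset division and pre-treatment

Curation keeps one record per (canonical structure, bt, me), resolving
duplicates to the most potent (lowest nM) measurement.

The modelling/external-validation division is k-means cluster analysis on
the z-standardised raw descriptors with the class label appended as one
extra standardised coordinate (k = 10 clusters, ≤ 500 iterations,
Euclidean); a fixed fraction (default 0.30, mirroring a 1919/6400 hold-out)
of every cluster is sampled without replacement into the validation set, so
both sets span the same chemobiological space.  The modelling set is then
randomly sub-split 80/20 into sub-training and test.

Pre-treatment drops columns with variance < 0.001, then scans surviving
pairs in canonical column order and drops the later member of any pair with
r² > 0.85.  Keep-earlier is the deterministic tie-break; the filter is
idempotent.

## Models and statistics

The linear model is a two-group Fisher discriminant expressed as intercept
plus coefficients, oriented so actives score positive and the boundary is
score = 0 (equivalently: nearest class centroid under pooled-covariance
Mahalanobis distance, equal priors).  Statistics: Wilks λ = |W|/|T| via
log-determinants; canonical R = √(1−λ); Bartlett χ² = −(n−1−(p+g)/2)·ln λ
with g = 2; D² = Δμᵀ S_p⁻¹ Δμ; F = ((n−p−1)/p)·(1−λ)/λ on (p, n−p−1)
degrees of freedom.  Singular scatter falls back to a 1e-8 ridge; if still
singular, the fit errors rather than returning garbage.

The GA evolves fixed-length descriptor subsets (defaults: 100 generations,
length 10, mutation 0.3 per gene, population 100, elitist top-30
selection), fitness = Wilks λ of the candidate LDA, memoised per subset.
Elitism makes the best fitness non-increasing, a tested invariant.  Because
a fixed search length can exceed the length of the best parsimonious
equation, a post-search backward-elimination pass drops terms whose removal
worsens λ by at most 1% relative — this is how a 10-slot search can yield a
7-term model, and it is logged when it fires.

The random forest uses 100 trees, bootstrap bags of size n, unlimited
depth, int(log₂ p)+1 candidate features per split, Gini criterion; scores
are active-vote fractions.  Y-randomisation refits the *same* descriptor
subset on scrambled labels (default 100 scrambles) and reports the mean
randomised λ; informative models show λ_rand near 1 far above the original
λ.

## Validation battery

Rates are percentages; F-measure is active-class F1; MCC uses the four-term
formula with the zero-marginal convention MCC = 0 (never NaN).  AUC is the
rank-based Mann–Whitney statistic with ties counting ½ (equal to the
brute-force pairwise probability, a tested equivalence).  Cross-validation
is stratified, pools the out-of-fold predictions, and computes one report;
when the minority class is smaller than the fold count the fold count is
reduced to keep stratification feasible.

Applicability domain (standardisation approach): s_ki = |x_ki − μ_k|/σ_k
from training moments; inside if max ≤ 3; outside if min > 3; otherwise
s* = mean + 1.28·SD (sample SD, ddof = 1), outside iff s* > 3.
Zero-variance descriptors are excluded with a warning.  The domain is
computed on the model's own deviation descriptors.  Out-of-domain
predictions are flagged, not removed.

## Fragment contribution scores

Bemis–Murcko scaffolds (acyclic molecules → empty), SSSR rings split out of
fused systems as standalone single-ring molecules, counted once per
compound and kept when present in strictly more than 15 compounds (the
threshold scales down for small synthetic runs via configuration).  Each
fragment is scored by the linear model under each condition using the
frozen condition averages; all fragment × condition cells are standardised
jointly with the sample SD (per-condition standardisation is a flag), and
ACS is the per-fragment mean of the standardised scores.  Fragments are
scored as standalone molecules with implicit hydrogens; attachment-point
context is out of scope, so scores are relative rankings, not additive
energies — the ACS ordering is invariant under positive affine transforms
of the raw scores, and that invariance is tested.

## Virtual screening and drug-likeness

Every library compound is predicted under every condition; consensus hits
are positive under all of them, so the hit count is monotone non-increasing
in the number of screened conditions.  Rule-of-five profile: MW (implicit H
included) < 500 Da, N/O-with-H donors ≤ 5, N+O acceptors ≤ 10, Crippen
logP < 5.  These use the classical N/O counting convention; tools with
finer-grained donor/acceptor typing will produce different counts, which is
why no external table of such values is asserted against.

## Synthetic data: what it emulates and what it does not

The generator assembles 10–40 heavy-atom molecules from a ring/linker/
substituent grammar (12 ring templates, 12 linkers, 14 substituents),
validated by the parser and deterministic under seed.  Each compound is
assayed under 1–4 of the four conditions (probabilities 0.45/0.30/0.15/
0.10).  The planted rule is a linear combination of three real computed
descriptors — Tnsq1(PSA)N1 (+3), Tnsq2(HYD)N1 (−3), Tnsq0(CH)N1 (−3),
z-standardised over the generated set — plus a condition intercept, passed
through a logistic with noise scale 0.4.  P(active) = σ((s + a_c + b)/0.4);
the global offset b is calibrated by bisection so the expected active
fraction hits the target (default 1/3), and activity values are drawn
log-uniformly on the class-consistent side of 500 nM so the labelling rule
reproduces the planted classes exactly.

Parameter rationale, chosen once:

* **Planted descriptors** are the canonical-first members of their r² > 0.85
  correlation groups, so pre-treatment provably retains them and "recovery"
  is well-defined.  Adjacent-order indices of the same property alias each
  other; planting an aliased column would make exact recovery impossible by
  construction.
* **Noise scale 0.4** puts the attainable (Bayes) accuracy near 96%, the
  separability level a curated kinase SAR dataset supports — weaker noise
  would make every classifier look perfect, stronger noise would cap all
  accuracies near 85% regardless of method.
* **Condition intercepts** {c1: +2.0, c2: −2.0, c3: +0.75, c4: −3.0} give
  per-condition active fractions of roughly 0.5/0.25/0.4/0.12, emulating
  IC50 assays being richer in actives than Ki assays.  They are large
  enough that a condition-blind model on raw descriptors measurably
  underperforms the Box–Jenkins deviation model — the property the
  transform exists to deliver.

What passing tests on this generator do **not** show: real medicinal-
chemistry property distributions, activity cliffs, assay noise structure,
inter-laboratory variability, or scaffold-series correlation between
training and external sets.  Recovery results certify the machinery, not
chemical validity on public-database-scale data.

## Problem sizes

The test suite and the acceptance script run the pipeline at 500 synthetic
compounds (~1000 records, 1536 raw descriptor columns before
pre-treatment), the recovery simulations at ~2000 records, and the
screening simulation with a 2000-compound library — sizes chosen so the
full battery certifies every stage while a complete run stays in the
minutes range on a single CPU.  A full pipeline pass at these sizes takes
about 20 s.

## Known limitations

* Descriptor values depend on the shipped property tables and RDKit's atom
  typing; other implementations of the same index family will differ
  numerically, so cross-tool comparisons should be made on ranks or model
  outputs, not raw descriptor values.
* The GA is a stochastic search; at small sample sizes different seeds can
  land on correlated near-equivalent subsets.  The backward-elimination
  tolerance (1% relative λ) is a pragmatic parsimony choice, not an
  information criterion.
* LDA assumes shared within-class covariance; strongly non-linear planted
  rules are the random forest's territory, and the pipeline reports both.
* Stochastic-matrix indices use plain row normalisation; no additional
  probability weighting is applied.
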