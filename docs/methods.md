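# Methods

## Data model

Genotypes are minor-allele counts (0/1/2, missing = -1) over samples x
markers, chromosomes labelled 1-22 and X.  The minor allele of each
marker is fixed when data are read (the less frequent allele over
non-missing calls, ties broken lexicographically) and stored, so all
downstream counts are reproducible regardless of processing order.
Hemizygous X genotypes of males are carried in diploid coding as 0/2;
every X-aware computation (allele frequencies, sex inference, error
injection) treats a male's X genotype as a single allele.

Marker filtering removes duplicate marker ids (first occurrence kept —
duplicates on arrays are repeated assays of the same id, so identity of
id, not position, is the criterion) and monomorphic markers (at most one
allele observed, including fully missing columns).  Filtering is
idempotent.

## Pairwise estimators

**Robust kinship.**  phi_hat = (N_AaAa - 2 N_AAaa) / (N_Aa(i) +
N_Aa(j)) over jointly non-missing autosomal markers.  Conditioning on
the pair's own heterozygote counts removes the allele-frequency model
entirely, which is what makes the estimate robust to unknown population
substructure; the cost is negative estimates for unrelated pairs when
one member is more heterozygous, which is harmless for banding.  The
estimator is exactly unbiased for any IBD mixture (its expectation is
(k1 + 2 k2)/4 = phi marker-by-marker), which the simulation suite
verifies for every relationship class.  It is undefined (raises) when
neither member has a heterozygous call.

**Method-of-moments IBD.**  Under HWE with minor-allele frequency p
(q = 1 - p), the per-marker IBS probabilities conditional on IBD state
are P(IBS0|IBD0) = 2 p^2 q^2, P(IBS1|IBD0) = 4 p^3 q + 4 p q^3,
P(IBS1|IBD1) = 2 p^2 q + 2 p q^2, P(IBS0|IBD1) = P(IBS0|IBD2) = 0,
P(IBS2|IBD2) = 1.  Z0_hat is the observed IBS0 count over the summed
IBD0 expectation; Z1_hat is the IBS1 residual over its IBD1 expectation;
Z2_hat the complement.  Components are clamped to [0, 1] in that
sequential order and renormalised to sum to one (deterministic, and the
clamped Z0 feeds the Z1 residual).  The closed forms are tested to
1e-12 against exhaustive enumeration of the nine joint genotype
outcomes.  Frequencies are cohort-level without small-sample bias
correction (second-order at the cohort sizes this tool targets); all
frequencies at 0/1 raise an error.

**X-inbreeding sex inference.**  F = (O_hom - E_hom) / (N - E_hom) with
E_hom = sum(1 - 2 p q) over the sample's non-missing X markers.  Calls:
female below 0.2, male above 0.8, otherwise uncertain (both thresholds
configurable).  Hemizygotes coded as homozygotes give F = 1
identically, so male/female separation at ~1,000 X markers is many
standard deviations wide (female F has sd ~0.04 at 1,153 markers).
Expected homozygosity uses diploid weighting for all samples — sexes
are unknown at this stage by construction — which is exactly what makes
males surface at F ~ 1.

**IBS distance and MDS.**  D_ij = 1 - mean(IBS)/2 over jointly
non-missing autosomal markers; classical (Torgerson) MDS
double-centers D^2 and eigendecomposes.  Negative eigenvalues among
the requested axes zero the coordinate with a warning; axis signs are
fixed by making the largest-magnitude loading positive so plots are
reproducible.  Default 2 dimensions.

## Classification and reconciliation

Kinship bands use the midpoints between relationship expectations on
the log2 scale: 0.354 (= 2^-1.5), 0.177, 0.0884.  Lower bounds are
inclusive — a pair sitting exactly on a cutoff is kept at the closer
degree, the conservative choice when the goal is excluding relatives.
Within the first-degree band, PO is separated from FS by the
opposite-homozygote fraction: PO pairs show IBS0 only through genotype
error (rate ~eps (p^2 + q^2) per marker, averaging ~0.64 eps), FS pairs
show ~0.25 E[2 p^2 q^2] ~ 0.018 regardless of error.  The default cutoff
0.012 is the geometric midpoint of the two class means at a 1% error
rate on 50k markers; at error rates above ~2% it should be raised
(it is a config field).

Reconciliation applies ordered rules, first match wins, and the winning
rule is recorded per pair: (1) band-MZ confirmed at PI_HAT > 0.99;
band-MZ with PI_HAT < 0.5 is contradictory and degrades to first-degree
with an inconsistency flag rather than raising; band-MZ in between is
retained on the kinship evidence (realistic error rates push a true
duplicate's PI_HAT well below 0.99 — see Limitations — so failing the
MZ confirmation is expected, not contradictory).  (2) first-degree
confirmed PO at PI_HAT > 0.5 and Z0 < 0.013; (3) confirmed FS at
PI_HAT > 0.44 and Z0 > 0.13; (4) band-second promoted to FS at
PI_HAT > 0.49; (5) band-FS demoted to second at PI_HAT < 0.41;
(6) an FS-like IBD signature below the second-degree band is recorded
as second-degree (conservative); otherwise the band call stands.
Cross-subset pairs weaker than first-cousin kinship (0.0442) are
dropped; since every band already implies kinship >= 0.0884, the rule
can only affect sub-band pairs rescued by rule 6, and is logged for
auditability.

**Pedigree assembly.**  A trio requires PO calls from a child to two
candidate parents that have *no* relationship call between them, sexes
admitting a father and a mother (unknown sex fills either role), and PO
edges not already consumed by an accepted trio; children are processed
in sorted order for determinism.  Requiring candidate parents to be
fully uncalled (rather than merely not first-degree) is what keeps a
child's own parent and grandparent — a second-degree pair — from being
misread as a spousal pair.  Candidates rejected only by shared declared
sex, ambiguous parent pairs, and full sibs assigned different parent
sets are recorded as inconsistencies; nothing is silently dropped.
Remaining PO calls become unoriented duos (with no ages, the direction
of a lone PO edge is unknowable).  Second-degree calls explained by a
grandparental path through a trio are annotated as such.  Per-population
summaries tally MZ pairs, trios, duos, FS and second-degree calls, with
cross-population relationships in a separate row.

**Panels.**  Tier 1 removes one member per duplicate/MZ pair; tier 2
greedily deletes the vertex of maximal current degree in the
first-degree call graph among tier-1 survivors until no edge remains;
tier 3 repeats on second-degree calls among tier-2 survivors.  Degrees
are recomputed after every removal (iterative max-degree deletion keeps
more samples than one-shot ranking); ties go to higher missingness,
then to the lexicographically larger id.  The removed set is a vertex
cover of the tier's graph, so the greedy solution is within the usual
factor-2 of the optimum (checked against brute force on small graphs);
exact maximum-independent-set solving is out of scope.

## Simulator

The gene-drop simulator is the package's test instrument and defines
the conditions every verification runs under: founder genotypes drawn
per marker under HWE with MAF ~ U(0.05, 0.5) (truncating at 0.05 keeps
the moments estimator well-conditioned at 50k markers), Mendelian
transmission of one allele per parent at independent markers, X
hemizygosity in males, duplicate individuals copied before corruption.
Genotype error re-draws a call uniformly from the other two states
(X-male calls flip 0 <-> 2, the only alternative state); missingness is
then applied independently.  A mutation process separate from genotype
error is not modelled: at the genotype level the two are
indistinguishable, so a combined error rate stands in for both.
Defaults are 50,000 autosomal and 1,153 X markers with clean genotypes;
0.01 and 0.05 are the error rates exercised in tests.

What the simulator deliberately omits — linkage disequilibrium,
population-structured founder frequencies within a cohort (a separate
two-population Balding-Nichols generator covers the MDS checks),
inbred founders, X inactivation — bounds what passing tests show: the
estimators are validated under independent markers and panmictic
founders.  The robust kinship estimator is insensitive to LD and
substructure by construction, but the MoM IBD expectations are not
substructure-robust, which is exactly why the pipeline treats kinship
bands as primary and IBD as corroborating evidence.  Exact pedigree
kinship coefficients (tabular recursion, founders unrelated and
non-inbred) provide the truth labels; PO/FS/MZ labels are structural,
second-degree labels cover half-sib, avuncular and grandparental
(phi = 0.125) without distinguishing subtypes, matching the resolution
limit of 50k markers (third-degree inference needs ~150k).

## Numerical and design choices

- Missing sentinel is a single reserved integer (-1); text dialects use
  "0 0" (ped) and "NA" (tabular) so round-trips are bit-exact.  The
  simulator orients every marker to its realized minor allele, making
  the ped-map read rule (minor = less frequent, ties lexicographic) an
  exact inverse of writing.
- Per-subset re-analysis uses subset-specific allele frequencies
  (mirroring per-source tool runs); whole-cohort analysis uses cohort
  frequencies.  Both are written and discrepancies surfaced, not hidden.
- Marker-subsampling robustness (`subsample-check`) recomputes calls on
  random marker fractions and reports degree agreement against the
  full-data calls over the union of called pairs.
- Verification scales: estimator-expectation and banding suites use 50
  MZ/PO/FS and 60 second-degree focal pairs at 50k error-free markers;
  the end-to-end recovery suite uses 40 focal pairs per class at 50k
  markers with 1% error and 2% missingness, requiring >= 95% per-class
  degree accuracy and exact recovery for MZ and PO.  These sizes give
  binomial 95%-confidence margins of a few percent per class while
  keeping the whole suite under half a minute.

## Known limitations

- Genotype error inflates Z0_hat sharply for duplicates and PO pairs
  (opposite homozygotes are impossible under IBD >= 1 without error):
  at 1% error a duplicate pair's PI_HAT drops to ~0.91, so the
  PI_HAT > 0.99 MZ confirmation only fires at array-quality (<0.1%)
  error rates; the kinship band, which degrades far more slowly
  (phi_hat ~ 0.47 at 1% error), carries the call in noisy data.
- Relationships are resolved to second degree; third degree and beyond
  are reported as unrelated-or-distant.
- No LD pruning; the kinship estimator does not need it, and the IBD
  moments assume independent markers.
- Duo orientation (which member is the parent) is not guessed.
- Panels are greedy, not optimal; on adversarial graphs they may remove
  up to twice the minimum number of individuals.
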