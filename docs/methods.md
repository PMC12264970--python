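# Methods

`rbfebench` re-implements, as a tested library, the analysis layer of a
nonequilibrium relative binding free energy (RBFE) benchmark: from raw
switching-work values to per-pair ΔΔG with bootstrapped uncertainties, and
from benchmark tables of experimental vs. calculated ΔΔG to the accuracy
statistics that relate prediction error to the quality of the starting
structure. No molecular dynamics is run anywhere; seeded synthetic
generators stand in for simulation output and deposited structures, with
ground truth known by construction.

## Free-energy estimation

A fast alchemical switching trajectory produces a work value
W = ∫ dH/dλ dλ, evaluated here with the trapezoid rule on the stored λ
grid (forward trajectories integrate 0→1, reverse ones 1→0; the
integration rule is a package choice, and at the grid densities of
fast-switching protocols its error is negligible next to sampling noise).

Given n_F forward works W_F and n_R reverse works W_R (reverse works are
reported for the 1→0 process), the Crooks fluctuation theorem
P_F(W)/P_R(−W) = exp((W−ΔG)/kT) leads to the maximum-likelihood (Bennett
acceptance ratio) estimate: ΔG solves

    Σ_i 1/(1 + exp(β(M + W_F,i − ΔG))) − Σ_j 1/(1 + exp(−β(M − W_R,j − ΔG))) = 0,

with β = 1/kT and M = kT ln(n_F/n_R). The left side minus the right is
strictly increasing in ΔG, so the root is unique and a bracketed solver
([min, max] of all forward and negated-reverse works, padded by
10 kT + |M|) converges unconditionally; we use Brent's method at absolute
tolerance 1e-8 kJ/mol, max 500 iterations, raising an explicit
convergence error (carrying the last iterate) when the distributions do
not overlap. The bootstrap path solves thousands of resampled instances
simultaneously with a vectorised bisection of the same equation; tests
pin scalar/vectorised agreement. A plug-in asymptotic SE (Fermi-function
variance estimate) accompanies every estimate for quick consistency
checks; the headline uncertainties come from the bootstrap below.

Numerical note: near its minimum the Fermi log-likelihood is flat to
double precision over ~5e-8 kJ/mol at typical sample sizes, so a
grid-search minimiser of the likelihood (the independent oracle in the
tests) can only localise the optimum to ~1e-7 kJ/mol; oracle-comparison
tests therefore run the solver at tolerance 1e-6 and compare at twice
that, while the 1e-8 default applies everywhere else.

The default thermal energy is kT = 2.479 kJ/mol (298.15 K), configurable.
Work values are kJ/mol internally (the GROMACS convention); benchmark
ΔΔG/UE/AUE are kcal/mol (1 kcal = 4.184 kJ).

ΔΔG assembles as ΔG(protein leg) − ΔG(water leg), with state A the more
potent ligand so the experimental ΔΔG is positive by convention. For
double-system-single-box (DSSB) setups — used for charge-changing
transformations so the box stays neutral — both legs switch
simultaneously and each work value already carries the leg difference;
the ML estimate on the combined works is returned directly as ΔΔG.
(Whether combined or separated works are the better treatment for DSSB
is an open modelling question; the combined-work treatment is what is
implemented, and a construction-equivalence test shows it agrees with
separate-leg assembly on synthetic works.) The reported per-pair ΔΔG is
the arithmetic mean over replicas (three by default).

## Uncertainty propagation

The SE on ΔΔG follows a two-step bootstrap per leg and replica:
(i) the 80 forward and 80 reverse works are resampled with replacement
n_boot = 1000 times and ΔG re-estimated for each; (ii) n_boot draws are
taken from Normal(ΔG_point, SD(ΔG_b)), where ΔG_point uses the original
works. The step-(ii) draws from all n_replica = 3 replicas are pooled per
leg, SE(leg) = sqrt(variance(pool)/n_replica), and
SE(ΔΔG) = sqrt(SE(protein)² + SE(water)²). All variances and SDs use the
unbiased (n−1) convention — a package decision where the convention was
unspecified — and the tests pin it (e.g. pooled {0, 2} with one replica
gives SE = √2). Resamples that fail to converge are skipped and redrawn
with a warning. Every random stream derives from one integer seed; the
per-work-set stream is keyed on the seed and the work values themselves,
which makes the reported SE exactly invariant under exchanging the two
legs' labels.

Calibration: on synthetic triplicates the pooled variance contains the
within-replica bootstrap variance plus the between-replica spread of
point estimates, so the formula is mildly conservative by design —
analytically ~1.3× the true SD of the replica-mean ΔΔG, measured at
~1.15× (mean SE over 25 triplets vs. the SD over 300 independently
regenerated triplets). A single triplet's SE is itself noisy (the
between-replica term has two degrees of freedom), which is why the
calibration test averages the reported SE over 25 triplets.

SEs on derived statistics (AUE, percentages) use a nonparametric
bootstrap over entries — pairs for paired statistics, structures for
placement percentages — with 10,000 seeded resamples by default.

## Water-placement scoring

The ligand binding site is the region within 5 Å (inclusive) of any
ligand heavy atom; waters are points at their oxygen. A predicted water
is correctly placed if it lies within 1 Å of a crystal water of the
binding site. Because several predicted waters can crowd one crystal
position, counting uses maximum-cardinality one-to-one matching on the
bipartite graph of within-cutoff pairs (solved as an optimal assignment;
among maximum-cardinality matchings the minimum-total-distance one is
returned). A greedy nearest-first variant exists for sensitivity checks
and is provably suboptimal on crowded instances. Predicted waters
outside the reference structure's binding site are ignored rather than
penalised. A structure with no reference waters yields an explicit
"no reference" outcome, not 0%. The summary statistic is the unweighted
mean of per-structure percentages (a pooled-denominator variant would
weight structures by their water count; the per-structure mean is the
implemented reading) with a bootstrap SE over structures.

## Structure features

From a PDB entry the package computes: resolution (REMARK 2; absent is
represented as missing, never zero), ligand mean B-factor, the number of
waters within 5 Å of the ligand, and the mean B-factor over *all* atoms
of protein residues having at least one atom within 5 Å of ligand heavy
atoms (residue-level inclusion). Contacts are atom-based (not residue
centres) with an inclusive boundary — a choice; crystal structures carry
no hydrogens, so "heavy atoms only" is effectively the whole ligand.
Alternate locations keep the highest-occupancy conformer; insertion
codes are preserved in residue identifiers. The ligand is the designated
heteroresidue, or by default the largest non-water heteroresidue.

Feature-based splits assign, per ligand pair, the record from the
higher-feature-value structure to one class and the other to the second
class, restricted to pairs differing by at least a minimum gap — 0.4 Å
for resolution (clearing typical resolution noise), any nonzero
difference otherwise. The UE-vs-resolution relation uses unweighted OLS
of per-structure UE on resolution plus a binned series: the AUE over all
points within ±0.1 Å of each distinct observed resolution (centred
sliding windows, a choice over fixed-grid bins). Inverting the fitted
line at an observed AUE yields the *nominal resolution* of a non-crystal
(e.g. predicted) structure; values beyond the largest fitted resolution
are clamped there and flagged censored ("> x Å") instead of
extrapolating.

## Synthetic generators — what they emulate and what they do not

**Work sets.** Forward works ~ N(ΔG + σ²/2kT, σ) and reverse (1→0) works
~ N(−ΔG + σ²/2kT, σ) satisfy the Crooks relation exactly, so ΔG is
recoverable and all moment identities are closed-form. Defaults follow
the fast-switching protocol the analysis layer targets: 80 works per
direction, 3 replicas, kT at 298.15 K, and dissipation σ = 2 kT (a
typical well-behaved transformation). Real work distributions can be
skewed or multi-modal (slow degrees of freedom); the Gaussian family is
the canonical analytically tractable case, and nothing in the estimator
assumes it.

**Structure fixtures.** A ligand of 8 heavy atoms at the origin, pocket
residues (4 atoms each) at 3–6 Å, and n binding-site waters placed
2.4–4.4 Å from the ligand with ≥ 2.8 Å mutual separation (hydrogen-bond
spacing). The separation guarantees make displacement tests exact:
waters displaced 0.5 Å always have their parent within 1 Å (and stay
inside the site), while waters displaced 1.5 Å are ≥ 1.3 Å from every
crystal position, so they never match. Spurious predicted waters are
placed > 2 Å from all reference waters. The geometry is deliberately
schematic — no covalent structure, packing or energetics — which is
irrelevant to the distance- and B-factor-based statistics under test but
means the fixtures say nothing about parsing pathological real-world
PDB deposits.

**Benchmark tables.** Experimental ΔΔG is uniform on 2.7–6.6 kcal/mol
(the activity-cliff regime, where positive-by-convention ΔΔG is large);
resolutions are uniform on 1.0–3.4 Å; B-factors and water counts co-vary
with resolution the way crystallography makes them (worse resolution →
higher B, fewer resolved waters). The planted error model sets each
record's UE magnitude to slope·res + intercept (+ offset on the
lower-affinity structure) + noise. The error *sign* is drawn once per
pair and shared by its two records: the two structure-based estimates
share the ligand pair and the experimental reference, so their errors
are modelled as same-signed. That correlated-error regime is also what
makes the best-set ≤ consensus ≤ all-values AUE ordering exact (per
pair, min ≤ mean ≤ max of same-signed magnitudes); with opposite-sign
errors the first inequality can fail (errors +e and −e cancel in the
consensus while the best-set UE stays e), so the ordering is a property
of this regime, not a theorem about arbitrary tables. Sign flips
(probability `flip_prob`) negate the calculated ΔΔG to model
direction-of-effect failures; a flip necessarily changes the record's
unsigned error, so the table carries a ground-truth `sign_flipped`
column and recovery analyses of the planted line and affinity offset
read the unflipped records (the regression additionally conditions on
the higher-affinity class, since the offset shifts the lower class by
construction). Sign accuracy is evaluated on all records and equals
1 − flip_prob in expectation because unflipped calculated values are
kept positive (the pair sign is forced positive in the rare case a
magnitude would exceed ΔΔG_exp).

## Degenerate inputs and tie-breaks

Zero-dissipation work sets (all forward = c, all reverse = −c) give
ΔG = c and SE = 0 exactly. Best-set ties go to the higher-affinity
structure. Sign accuracy counts ΔΔG_calc = 0 as incorrect. Empty split
classes are reported as absent/None, never as zero. Zero-variance
columns in the correlation matrix give NaN with a warning. The Pearson
matrix requires ≥ 3 complete records; the OLS fit ≥ 3 points with
non-constant resolution.

## Problem sizes used in the test suite

The estimator oracle comparison runs 200 random instances (≤ 100 works
per direction) plus 200 recovery datasets at the 80+80 protocol size;
bootstrap calibration uses 25 full SE pipelines against 300 regenerated
triplets; water matching checks 200 random ≤ 8-water instances against
exhaustive assignment; feature extraction checks 100 random fixtures
against O(N²) scans; benchmark recovery uses one 400-pair table. These
sizes give comfortable statistical resolution for every planted effect
while keeping the whole suite under a minute.

## Known limitations

- Only the Gaussian work family is generated; estimator behaviour on
  heavy-tailed or barely-overlapping work distributions is exercised
  only incidentally (the convergence-error path).
- The per-structure-mean convention for placement percentages and the
  mean-of-estimates reading of "consensus" are choices among defensible
  alternatives; the pooled-AUE variant is computed alongside so either
  reading of consensus is available.
- PDB handling targets well-formed single-model files; mmCIF and
  multi-model NMR entries are out of scope.
- The DSSB treatment assumes combined works; separated per-leg works in
  one box are not modelled.
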