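# Methods

## Scientific setting

TRAP1, the mitochondrial Hsp90-family chaperone, is an asymmetric
homodimer whose ATPase cycle can be dampened by ligands binding an
allosteric pocket more than 40 Å from the nucleotide site.  The
question this package addresses is operational: given molecular-
dynamics ensembles of the inhibitor-free (state **A**) and
inhibitor-bound (state **I**) dimer started from one common reference
conformation, can a small set of *local* structural descriptors,
computed frame by frame, support a statistical classification of
unknown frames into A or I — and does the fraction of frames a system
spends in state I track the experimentally measured loss of ATPase
activity?

## The eight descriptors

Every frame of a two-protomer system is reduced to an 8-vector, four
descriptors per monomer:

1. **Cross-monomer strap contacts** — the number of heavy-atom pairs
   closer than 4.5 Å (strict inequality) between the N-terminal strap
   and β-strand of one monomer (residues 85–108, author numbering of
   the zebrafish crystal structure) and the N-terminal-domain core of
   the partner (residues 109–308).  The strap is a kinetic barrier to
   dimer opening/closing; its engagement is a closure fingerprint.
2. **ATP-lid side-chain SASA** — Shrake–Rupley solvent-accessible
   surface area of the side chains of residues 191–217, probe radius
   1.4 Å.  The lid gates nucleotide hydrolysis; its burial state
   reports on the catalytically loaded conformation.
3. **R417–γ-phosphate distance** — the distance between the centers of
   mass of the R417 guanidinium group (NE, CZ, NH1, NH2) and the
   γ-phosphate of the bound ATP (PG, O1G, O2G, O3G).  The formed salt
   bridge marks the catalytically competent state.
4. **S582 side-chain SASA** — the exposure of the phosphorylatable
   hydroxymethyl group (CB, OG) at the end of the middle–C-terminal
   domain linker.

Numerical choices: "heavy atom" means element ≠ H; SASA occlusion
context is *all* atoms of the frame (protein, nucleotide, ligand) while
the reported area is summed over the named group only — a side chain
in vacuum would be meaningless; van der Waals radii come from a fixed
Bondi-style table recorded in the output metadata; the sphere lattice
is a deterministic golden-spiral set, 960 points per atom by default
(the isolated-sphere error is below 1 %, halving the point count
roughly doubles it); contacts use a k-d tree with an explicit re-check
of the strict inequality, so a pair at exactly the cutoff never
counts.  All descriptors are rigid-motion invariant, so trajectories
are not superposed; inputs are assumed whole (a coordinate span above
500 Å aborts with a periodic-image diagnostic).

## Dataset design

The comparative design balances every bound ensemble against free
replicates simulated identically.  Frames saved every 20 ps over 80 ns
of production give 4000 records per system.  The *original training
set* merges 9 bound systems (3 training ligands × 3 replicates) with 9
free replicates: 72 000 labeled rows.  Extending every training system
by 200 ns sampled every 100 ps adds 2000 records each: the *extended
training set*, 108 000 rows.  The *small test set* holds 8 further
ligands × 3 replicates plus 24 free replicates (192 000 unlabeled
rows); the *large test set* adds the 200 ns extensions of one replicate
per training ligand and of three free replicates (2000 records each,
204 000 rows total), giving 11 bound and 11 free observation groups.
The package reproduces this bookkeeping exactly at full scale and
preserves all ratios under a single `frame_scale` knob used for
desk-scale runs (analysis drivers use 1/20 scale, 200 records per
system; the end-to-end recovery checks use 1/8, i.e. 500).

## Classifiers

Let x be an 8-vector and c ∈ {A, I}.  The generative models use the
naive factorization p(x|c) = Π_j p(x_j|c) with empirical class priors:

* **GNB** fits one Gaussian per class-feature by sample mean and
  unbiased variance.  Exactly zero within-class variance is an error
  (the data are degenerate); variances below 1e-12 times the squared
  feature scale are floored and logged.
* **KNB** replaces each Gaussian by a kernel density estimate with
  Gaussian kernel and the normal-reference bandwidth
  h = 1.06 · sd · n^(−1/5) per class-feature (fixed bandwidths can be
  supplied).  Evaluation is exact (log-sum-exp over training points),
  so prediction cost grows with the training-set size.

Posteriors are computed in log space; a tie at exactly P(I|x) = 0.5 is
resolved to A, favoring specificity.  The discriminative route is a
soft-margin SVM with kernel exp(−‖u−v‖²/(2σ²)) applied after
per-feature standardization by the training statistics; named presets
fix σ at 11 (coarse), 2.8 (medium) and 0.71 (fine) with box constraint
C = 1, and a randomized log-uniform search over [10⁻³, 10³]² selects
(σ, C) by 5-fold cross-validated error.  The search replaces the
original Bayesian optimizer deliberately: it preserves the contract
(bounded budget, CV objective, deterministic under a seed) without
reimplementing a proprietary optimizer, and the medium preset is what
the rest of the analysis uses anyway.  The quadratic program itself is
solved by libsvm via scikit-learn; the fitted machine is re-expressed
as explicit support vectors, dual coefficients and bias, so models
serialize to JSON and predict without pickled estimators.  Tests check
the decision values against an independently solved dense dual QP.

## Evaluation protocol

Frames predicted I are positives.  Q = (TP+TN)/N,
TPR = TP/(TP+FN), TNR = TN/(TN+FP), FPR = FP/(FP+TN) = 1 − TNR.
Cross-validation splits at the record level into 5 random folds of
near-equal size (20 % validation each; 14 400 rows at full training
scale) and reports the mean of per-fold accuracies next to TPR/TNR
pooled over the validation folds.  Record-level splitting ignores the
temporal autocorrelation of MD frames and therefore *inflates* internal
accuracy on real trajectories; a blocked-by-replicate split is provided
for sanity analyses, and external (per-system) validation is the
measure that matters.  A rate whose reference class is absent is
reported missing, never zero.

External predictions are pooled per observation group: each ligand's
replicates give one TPR% (percent of frames predicted I), each free
block one FPR%.  In the large-test layout the single-replicate
extension matrices each form their own group — the only reading that
yields 11 bound plus 11 free observations.

## Boundary and regression

On the group-rate axis, threshold 1 is the ceil(q·n)-th order statistic
of the free-group FPR% values (the largest FPR% attained by at least
the quorum fraction q of groups, counted from below); q is 5/8 for an
8-group panel and 8/11 for 11 groups (no single rounding rule produces
both, so the two panel sizes are mapped explicitly and other sizes fall
back to 62.5 %).  Threshold 2 is the smallest ligand TPR% strictly
above threshold 1; a ligand is called I-like iff its TPR% ≥ threshold 2
(the defining point is itself I-like), and if no ligand exceeds
threshold 1 nothing is.  Ordinary least squares of ligand TPR% against
the experimental percentage decrease of ATPase activity (the packaged
11-ligand assay panel, or the simulated assay of a synthetic run)
yields slope, intercept and r²; free groups appear in the plot table at
y = 0 but never enter the fit.

## Synthetic data: what it emulates and what it does not

The underlying MD trajectories are not publicly deposited, so two generators provide
ground-truth-bearing stand-ins.

**Feature-level ensembles.**  Each class anchor is a per-feature
univariate Gaussian mixture (the default anchors are overlapping and
partly bimodal; their shapes are plausible knobs, not calibrated to any
measured density — no quantitative target for them exists).  Features
are independent given the latent state, deliberately matching the
naive-Bayes assumption so that parameter recovery is a clean test.  A
ligand of effect e ∈ [0, 1] emits each frame wholly from the I anchor
with probability e, else from the A anchor: one latent draw is shared
by all 8 features of a frame.  The marginal of every feature is then
the e-weighted blend of the anchors, and the true bound-state occupancy
is exactly e — an independent per-feature blend would instead produce
feature-mosaic frames and break the occupancy/TPR% correspondence.
The simulated assay is % inhibition = slope·e + intercept + Gaussian
noise, clipped to [0, 100]; defaults (76, 0, 3) span the measured
panel's range.  Every system draws from its own RNG stream keyed by
(base seed, CRC32 of the system id); extension segments continue the
stream of their original segment, so extended sets contain the original
spans unchanged.  Frames are i.i.d. — the generator does *not* emulate
the temporal autocorrelation, slow conformational drift or cross-feature
correlation of real MD, so internal CV figures on synthetic data say
nothing about CV optimism on real trajectories.

**Toy bead dimers.**  Two protomers of annotated beads (explicit
masses and radii, no chemistry) whose geometry knobs — protomer
separation, lid and S582 burial fractions, ion-pair distance — are
state-dependent, with isotropic Gaussian jitter as the only dynamics.
Residue numbering and atom naming follow the real selection rules, so
the featurization path is exercised end to end; descriptor responses to
the knobs are monotone by construction (zero jitter freezes the
geometry exactly).  These trajectories validate featurization, not
thermodynamics.

## What the tests establish — and what they cannot

The acceptance suite verifies: (1) the dataset bookkeeping reproduces
every record count and aggregate-duration figure of the design at full
scale; (2) featurization agrees with exhaustive-pair, analytic-sphere,
spherical-cap and Monte-Carlo-surface oracles and is rigid-motion
invariant; (3) NB posteriors match hand-coded Bayes rules to 1e-10,
SVM decisions match a dense QP to 1e-6, and GNB recovers generating
parameters and the analytic Bayes accuracy Φ(Δ/2) within 3 standard
errors; (4) the CV/metric identities hold on random labelings; (5) on
noise-free synthetic ensembles with strong effects, the full pipeline
places every ligand beyond threshold 2 and recovers the injected
inhibition link within 3 seed-level standard errors with r² > 0.9.
Headline accuracies and external r² values obtained on the original
multi-microsecond ensembles are not reproducible from synthetic data; the package makes the *procedure* reproducible and
falsifiable, not those numbers.

## Known limitations

* No periodic-boundary handling; inputs must be whole and imaged.
* KNB prediction is O(n_train · n_test) per feature; at the full
  108 000-row training scale it is impractical without subsampling.
* The SASA implementation is exact only in the sphere-point limit;
  areas carry lattice noise of order 4πR²/n_points per atom.
* Binary trajectory formats (DCD/XTC) are out of scope; the reader
  contract (multi-model PDB, flat CSV dialect) is pluggable.
* The boundary quorum is defined for the two panel sizes the analysis
  uses; other sizes use the 62.5 % fallback.
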