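# Methods

## Scope and model

`korbias` implements two linked analyses for κ-opioid receptor (KOR)
pharmacology, both reusable for other class A GPCRs:

1. **Conformational-state analysis** of molecular-dynamics trajectories: each
   frame is reduced to five geometric observables and classified into one of
   three intracellular-interface states — *canonical* active, *alternative*
   (clockwise-rotated TM7), or *occluded* (the bottom of TM7 contacting TM2).
2. **Signaling-bias quantification** from dose–response data via the
   Black–Leff operational model, yielding transduction coefficients
   log(τ/K_A), reference-normalized Δlog and between-pathway ΔΔlog values,
   and bias factors 10^ΔΔlog with confidence intervals; supporting
   radioligand competition (one-site Ki) and dissociation-kinetics fits.

## Trajectory model and superposition

Trajectories are ordered frames of named atoms addressed by
Ballesteros–Weinstein (BW) code through a `ResidueMap` (e.g. `"7.47"` →
chain A residue 324, author numbering). I/O uses the multi-model PDB dialect
(one `MODEL`/`ENDMDL` block per frame; only coordinate records are honored),
read and written through biotite. The coordinate convention is the OPM
membrane frame: +z points extracellular, so negative z-displacement means
motion toward the intracellular side.

Before metric evaluation every frame is superposed onto a reference
structure by least-squares rigid fit (proper rotation + translation,
determinant +1, no reflection — `scipy`'s `Rotation.align_vectors`) on the
Cα atoms of the TM2/TM3/TM5 helix ranges. The same TM2/3/5 anchor set is
used for all metrics; selections with fewer than three atoms or collinear
geometry are rejected.

## Per-frame observables

| metric | definition | units |
|---|---|---|
| `t94_d334_distance` | min distance, T94(2.39) OG1 to D334(8.47) {OD1, OD2} | Å |
| `tm7_rotation` | signed XY angle between frame and reference helix tangents, the tangent being the Cα(7.48) − Cα(7.47) XY difference | degrees |
| `q115_dihedral` | torsion over Q115(2.60) C–CA–CG–CD | degrees |
| `k227_e297_distance` | min distance, K227(5.39) NZ to E297(6.58) {OE1, OE2} | Å |
| `w287_z_displacement` | mean z of the W287(6.48) indole-ring atoms minus the reference | Å |

Chemically equivalent atoms (the two carboxylate oxygens) enter distances
through the minimum over pairs. Torsions use the standard signed atan2
construction and return values in (−180°, +180°]. The TM7 rotation is
counter-clockwise-positive viewed from the extracellular side; a
`clockwise_positive` flag flips the convention, since a signed threshold of
−20° presumes a handedness that could be defined either way.

## Classification and occupancy

The three-state rule is fixed, with strict `<` at both thresholds and the
contact rule taking precedence:

- occluded if `t94_d334_distance` < 3.5 Å (regardless of rotation),
- else alternative if `tm7_rotation` < −20°,
- else canonical.

Occupancies are computed per replicate (one independent simulation each) and
pooled two ways: frame-weighted (default) and as the unweighted mean of
replicate fractions; both are reported because the two conventions differ
when replicate lengths differ. Frames are equally weighted with no burn-in
discard by default.

Side-chain summaries use `fraction_satisfying` with configurable predicates:
W287 counts as "downward" when its ring z-displacement is ≤ −0.5 Å, and
Q115 as "rotated toward TM1" when its dihedral is more than 60° (shortest
arc on the circle) from the crystallographic value. Both cutoffs are
package choices — the downstream percentages depend on them and no
published cutoff exists — so they live in `MetricConfig`, not in code.

Condition comparisons act on replicate-level fractions. The default is an
exact two-sided rank (Mann–Whitney) test computed by complete enumeration of
group assignments (via `scipy.stats.permutation_test` with exhaustive
resampling, which also handles ties correctly); a seeded Monte-Carlo
permutation test on the difference of means is the alternative. A
nonparametric replicate-level test is the defensible default for ~10
replicates per condition; no attempt is made to reproduce any particular
published p-value, which would require the original trajectories.

## Operational model and bias

The response model is

    B = 10^(X·n) · 10^(logτ·n),   Y = Emax · B / [B + (10^X + 10^logK_A)^n]

fit globally per pathway with `lmfit`: Emax fixed at 100 (responses are
normalized to the reference full agonist), Hill slope n shared across
ligands within a pathway but not across pathways, per-ligand logτ and
logK_A. For n = 1 the model implies EC50 = K_A/(τ+1) and plateau
Emax·τ/(τ+1); fitted noise-free curves satisfy both to < 1e-6 relative
error (tested).

Identifiability: for a full agonist τ and K_A trade off and only their ratio
is determined. Fits bound logτ at 3 (flagging fits that approach it) and
always report log(τ/K_A), whose standard error is computed from the joint
(logτ, logK_A) covariance — bias quantities depend only on this ratio.

Bias proceeds as Δlog(τ/K_A) = log(τ/K_A)_ligand − log(τ/K_A)_reference per
pathway, ΔΔlog = Δlog_pathway1 − Δlog_pathway2 (antisymmetric in pathway
order; positive means bias toward pathway 1), bias factor = 10^ΔΔlog. The
reference ligand's Δlog and ΔΔlog are identically zero by construction, so
its bias factor is exactly 1 regardless of noise.

Two error models are available. The default (`per_experiment`) fits each
independent experiment (replicate) separately, forms ΔΔlog per experiment,
and averages, with SE and df = n_exp − 1 from the between-experiment
scatter; `global` propagates the joint-fit covariance. Confidence intervals
are t-based and symmetric in log10: 10^(ΔΔ ± t_df·SE). Published intervals
of this kind are near-symmetric in log10, which motivates the choice; the
exact construction behind any given published interval is generally
unstated, so the method is recorded in the output.

Mutant potency changes are EC50(variant)/EC50(wild type), reported both as
the conventionally rounded integer fold and as log10 fold for heatmaps.

## Binding fits

Competition curves use a fixed-slope (Hill −1) logistic — the one-site
model — with top, bottom and logIC50 free, followed by the Cheng–Prusoff
correction Ki = IC50/(1 + L/Kd); a variable slope is available behind a
flag. Dissociation time courses fit Y(t) = (Y0 − NS)·exp(−koff·t) + NS with
t½ = ln2/koff; the nonspecific plateau NS is free by default or can be fixed
from a blocker-defined value. Expression normalization is the plain
CPM/μg-protein quotient.

## Synthetic data

The generators define the test conditions; they are pure functions of
(prescription, seed).

**Trajectories.** Rather than simulating physics, atoms are placed
analytically so each observable equals its per-state target plus Gaussian
noise: D334's oxygens sit on the x-axis at the target distance from T94 OG1,
the S324/L325 Cα tangent pair is rotated in the XY plane by the target
angle, Q115's CD is placed to realize the target torsion, and the W287 ring
is shifted along z. Alignment-anchor Cα atoms are held fixed across frames,
so analysis-time superposition is the identity and planted values are
recovered exactly at zero noise. State sequences are either fixed or sampled
from a 3×3 Markov chain started at its stationary distribution. Default
targets: occluded (3.0 Å, −30°), alternative (6.5 Å, −35°), canonical
(6.5 Å, 0°); default noise SDs 0.3 Å on distances, 5° on the rotation, 10°
on the torsion, 0.2 Å on z. Noise is independent per metric per frame; an
AR(1) option exists for stress-testing occupancy standard errors. What this
does *not* emulate: real MD kinetics, correlated multi-metric fluctuations,
a full receptor topology, or alignment noise — so passing tests demonstrate
the correctness of the measurement/classification machinery, not robustness
to every pathology of real trajectories.

**Assays.** Dose–response data are drawn from the operational model itself
with per-(ligand, pathway) (logτ, logK_A), shared n = 1, Emax 100, 8
concentrations spanning 10⁻¹²–10⁻⁵ M, 3 independent experiments and Gaussian
noise SD 2% of Emax — mirroring a typical normalized assay design. The
bundled example prescription encodes a balanced reference, a G-biased ligand
with true bias factor 6 and an arrestin-biased ligand with true factor 10,
matching the magnitudes the machinery is meant to resolve. Binding data come
from the closed-form competition and decay models (competition IC50 placed
by inverse Cheng–Prusoff; dissociation sampled on a 2 min–2 h grid).

## Numerical choices

- All nonlinear fits use deterministic Levenberg–Marquardt from fixed,
  data-derived starts (logEC50/logK_A at the median tested concentration,
  logτ = 0, n = 1) with tight tolerances (1e-13); no random restarts.
- Flat curves, non-convergence and boundary-pinned parameters return flagged
  results rather than raising mid-pipeline.
- Exact rank tests enumerate completely for group sizes where the
  combination count is feasible (≤ 12 per group); the Monte-Carlo
  permutation test is seeded and reproducible.
- Degenerate geometry (coincident torsion axis, zero-length XY projection,
  collinear alignment selection) raises typed errors naming the offense.
- Classifier boundary values go to the *later* branch (strict `<`), e.g. a
  distance of exactly 3.5 Å is not occluded.

## Problem sizes in the test suite

The suite exercises 5 000-frame trajectories for occupancy-fidelity checks,
2 000-frame Markov chains for generator statistics, and 200-seed repetition
studies for operational-model recovery; these sizes give binomial/Monte-Carlo
margins comfortably tighter than the tested tolerances while keeping the
default run under a minute.

## Known limitations

- The per-frame metric loop is pure Python over frames; it handles the
  tens of thousands of frames typical of downsampled trajectories but is
  not vectorized for millions of frames.
- Binary trajectory formats (DCD/XTC) are out of scope; convert externally
  to multi-model PDB.
- The occupancy comparison assumes exchangeable replicates; temporal
  autocorrelation within a replicate shortens the effective sample size of
  *frame-level* fractions, which is why all inference runs on replicate-level
  summaries.
- The operational fit assumes responses are already normalized to a
  reference full agonist (Emax = 100); raw luminescence processing is out of
  scope.
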