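# Methods

This note records the models implemented in `gagtk`, the conventions and
defaults chosen where more than one reasonable definition exists, and what
the synthetic-data generators do and do not emulate.

## Oligosaccharide sequences and libraries

Sequences are alternating IdoA/GlcN chains.  Validity rules: IdoA may carry
2-O-sulfation and a ring conformer of ¹C₄ or ²S₀; GlcN must carry an
N-substituent (acetyl or sulfate), may carry 3-O-/6-O-sulfation, and sits
in ⁴C₁.  The notation grammar is
`Unit := Base Subst? OSulf* ("(" Conformer ")")?`, units joined by `-`.
The leftmost token is taken as the non-reducing end; an orientation flag
records the opposite reading where a data source uses it.  Parsing and
formatting are exact inverses on canonical notation (property-tested over
the full toy library).

Combinatorial enumeration takes per-position variant alphabets (IdoA
variants at IdoA positions, GlcN variants at GlcN positions) and emits the
Cartesian product, deduplicated and sorted lexicographically by notation so
output order is deterministic.  The default toy spec — 2 IdoA × 4 GlcN
variants at dp4 — yields 64 sequences; alphabets are fully configurable and
the library size always equals the product of variant counts when no
exclusion predicates are set.  Ring conformers are metadata: they do not
multiply the library unless listed as separate variants, since conformer
annotations describe named sequences rather than enumeration axes.

Net charge counts one negative charge per sulfate plus one per uronic-acid
carboxylate, all fully ionised — adequate near neutral pH where sulfates
(pKa ≪ 2) and carboxylates (pKa ≈ 3–4) are deprotonated.

Basic-cluster scanning slides a window (default 5 residues) over the
one-letter sequence, flags windows with at least `min_basic` (default 3)
basic residues, merges overlapping flagged windows, and trims each merged
region to its first and last basic residue.  Histidine is excluded from
"basic" by default (its side chain is mostly neutral at physiological pH,
and chemokine GAG epitopes are K/R-driven); a flag includes it.

## Dual-filter screening

The screen selects ligands by *affinity* (docking score) and *specificity*
(pose consistency):

1. every library member is docked once and ranked by best score; the top
   fraction (default 0.10, i.e. 25 of a 254-member library under half-up
   rounding of n·fraction) advances.  Ties at the cut are broken
   lexicographically by ligand label so the selection is reproducible;
2. shortlisted ligands are re-docked in `n_runs` runs (default 3); the
   poses are pooled and the `top_k_poses` (default 6) highest-scoring are
   compared pairwise.  The consistency statistic is the **mean** RMSD over
   all 15 pairs (a maximum-pairwise option exists); ligands below 2.5 Å are
   "specific".  Pooling the top six across runs was chosen over two-per-run
   selection (also available) because it uses the score information
   directly; the mean was chosen over the maximum because it matches the
   consistency-of-ensemble semantics and is stable against one stray pose;
3. RMSD is computed in the fixed receptor frame with **no
   re-superposition**: all poses are docked into the same site, so rigid
   displacement between poses is exactly the signal the filter exists to
   measure;
4. the hydrogen-bond filter counts ligand sulfate-/carboxylate-oxygen
   contacts with protein polar atoms within a distance cutoff (default
   3.5 Å) grouped by residue, and requires contacts with at least
   `min_hbond_residues` key residues (default 1; the required level of
   hydrogen bonding is a tunable because no single threshold is canonical).

The docking engine is deliberately out of scope: the pipeline accepts any
pose supplier.  The built-in surrogate backend derives a pseudo-structure
from the sequence (one anionic oxygen per sulfate, one carboxylate oxygen
per uronic acid, ring centroids), places poses near the site centre with a
configurable Gaussian spatial spread, and scores them as
Σ 1/(1 + d) over anion–basic-atom pairs.  It exists to exercise the
pipeline with controllable ground truth (spread σ maps monotonically to
consistency RMSD); its scores have no physical calibration.

## MD occupancy and energy summaries

Occupancy is the fraction of frames in which an interaction is present.  A
frame with three H-bonds to a residue counts once — presence, not
multiplicity.  Runs are averaged with equal weight regardless of length
(frame-weighted averaging is available), so a short run cannot be silenced
by a long one.  Classes: persistent > 0.5, transient [0.2, 0.5],
negligible < 0.2.  Water bridges require the conjunction, within one frame,
of a water–residue bond and a water–ligand bond for the same water
molecule; the bridge occupancy is therefore bounded by both marginal
contact occupancies.  Geometric H-bond criteria (3.5 Å donor–acceptor,
30° linearity deviation) apply only when raw geometry rather than
pre-computed events is supplied; they are stated defaults, not assertions
about how upstream event tables were produced.

Per-residue energy summaries average frames within runs, then runs with
equal weight; the SD is the sample SD over pooled frames.  Anchors are the
most-negative-mean residues.  Total binding energies over runs are reported
as arithmetic mean ± sample SD; a single run yields a mean with the SD
flagged undefined.  Because the aggregation rule behind statements like
"site A's overall occupancy exceeds site B's" is ambiguous, the per-site
aggregate reports both the sum and the mean of residue occupancies.

## SPR kinetics

The 1:1 Langmuir model is closed-form (association
`Req(1 − e^−(kon·C+koff)t)` with `Req = Rmax·C/(C + K_D)`; exponential
dissociation), with no mass-transport term — curves are assumed kinetically
limited.  The global fit shares (kon, koff, Rmax) across all
concentrations, stacking all residuals into one least-squares problem
solved with lmfit/Levenberg–Marquardt.  Rates are fitted in log₁₀ space
with bounds (kon ∈ [10, 10⁹] M⁻¹s⁻¹, koff ∈ [10⁻⁶, 10] s⁻¹), which
prevents negative excursions and conditions the search across the decades
the parameters span; standard errors are mapped back to linear scale by the
delta method.  Initial guesses come from the data (koff from a log-linear
fit of the dissociation tail, kon from koff and the median concentration).
A per-curve fitting mode reports mean ± SD of the rates across
concentrations, mirroring instrument-software practice.  Flat data
(response span indistinguishable from zero) is flagged degenerate rather
than fitted.  K_D = koff/kon is an identity of the result object, not a
fitted quantity.

Steady-state affinity fits `Req = Rmax·C/(K_D + C)` to equilibrium
responses (taken as the mean over a late-association window, default the
last 10 s); at least 4 concentrations spanning > 4-fold are required, and a
fitted K_D above the highest tested concentration is flagged
ill-conditioned because the plateau was never approached.  Reference-surface
correction is plain point-wise curve subtraction.

## NMR analysis

Combined CSPs use weight w = 0.159 on the ¹⁵N term (the conventional
scaling of the nitrogen shift range to the proton's); w is configurable.
Perturbed residues are called above mean + 1 SD of the (non-proline) CSP
distribution — a convention, not a law; the threshold rule is a pluggable
callable.

The dimerization estimator assumes dimer peak intensity proportional to
protomer concentration 2[D] (each protomer contributes its amide) and
monomer intensity proportional to [M], stated explicitly because intensity
proportionality conventions differ.  With r = I_dim/I_mono and
C_tot = [M] + 2[D], mass action K_D = [M]²/[D] inverts in closed form to
K_D = 2·C_tot/(r(1 + r)); r = 0 (pure monomer) is signalled as undefined.
Table-level estimation pools the intensity ratio over a user-selected
residue set by mean at each concentration and averages the
per-concentration K_D estimates.

Correlation times use τc = sqrt(6·T1/T2 − 7)/(4π·ν_N), valid for isotropic
tumbling and T1/T2 ≥ 7/6; residues below the bound (fast internal motion)
are flagged, not silently clamped.  The apparent-MW conversion is linear
with default slope 1/0.55 kDa·ns⁻¹ (≈ 0.55 ns of τc per kDa at room
temperature for compact globular proteins) and is labelled *apparent*: it
breaks down for elongated or partially disordered molecules.

## Synthetic-data generators

Every generator is the exact forward model of its estimator, so noise-free
output round-trips to the generating parameters (tested to numerical
tolerance for sensorgrams ↔ kinetic fit, intensities ↔ dimer K_D,
relaxation ↔ τc, isotherm ↔ steady-state fit).  Noise models are the
simplest consistent with each estimator: additive Gaussian RU noise for
SPR, multiplicative Gaussian for peak intensities and relaxation times,
Bernoulli per-frame events for H-bonds, Gaussian per-frame energies.
Defaults are the published CXCL13 study conditions (`gagtk.presets`): the
per-variant SPR concentration series (12–140 nM wild type up to 86–977 nM
double mutant), rate constants (3.08×10⁵ M⁻¹s⁻¹ / 5.8×10⁻³ s⁻¹ wild type),
steady-state affinities (50 nM to 1.62 µM), the 0.3 mM dimerization
constant with a 50–950 µM concentration series, and a titration at 100 µM
protein (the methods-section value; a figure legend cites 37 µM for the
same experiment — the generator takes the former, and both are ordinary
parameters).

What the generators do **not** emulate: instrument drift, injection spikes
and bulk-refractive-index steps in SPR; peak overlap, differential line
broadening and incomplete assignment in NMR; correlated frames,
equilibration transients and force-field error in MD tables; and any real
docking energetics.  Passing tests therefore demonstrate the correctness of
the estimators under their own assumptions, not robustness to instrument
artefacts.

## Problem sizes and numerics

The test suite and the acceptance script run desk-scale problems: the
64-member toy library (20-member subsets for full screen runs), 6–18 poses
per ligand, 10⁴ frames for occupancy convergence checks, 7-concentration
SPR series at 1 s (simulation) to 5 s (long-plateau checks) sampling, and
5-concentration dimer series — sizes at which every check completes in
seconds while leaving the statistics informative.  Tie-breaks are
lexicographic everywhere a cut or sort could be ambiguous; all randomness
flows through seeded numpy Generators, and the pipeline fans a master seed
out to stages by a stable FNV-1a string hash so stages are individually
reproducible.

## Known limitations

No 3D saccharide coordinate generation or glycosidic-torsion modelling; no
GlcA epimers (the base enum is the extension point); no mass-transport or
bivalent SPR models; no lineshape/exchange-rate fitting and no model-free
relaxation analysis beyond the single τc estimator; docking scores from the
surrogate backend are ordinal, not calibrated energies.
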