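# Methods

## The model

Each bond length and bond angle of the nucleoside sugar moiety is restrained
by a target + standard deviation that depends on the fragment's conformation.
The conditioning variables are of two kinds.

**Discrete labels.** Sugar type (ribose / 2′-deoxyribose, decided by the
presence of O2′), base type (purine / pyrimidine, decided by the glycosidic
nitrogen N9 vs N1), ring-pucker class from the pseudorotation phase
(C3′-endo for 0° ≤ P ≤ 36°, C2′-endo for 144° ≤ P ≤ 190°, Other elsewhere —
the 190° bound is kept verbatim although it exceeds the conventional 180°
half-range), the χ rotamer (syn iff |χ| ≤ 90°, boundary inclusive) and the γ
rotamer (±30° windows about +60°, −60° and 180°; the trans window spans the
±180° wrap). γ values outside all three windows are real in deposited models,
so the lookup never refuses them: it falls back to the N-weighted pool of the
γ-split groups with the pooled (mixture) standard deviation and logs a
warning. Pooling rather than nearest-window assignment was an open choice;
pooling was picked because it is unbiased under ignorance of the true
rotamer.

**Continuous variables.** The pseudorotation pair (P, τ_m) is solved by
linear least squares over all five endocyclic torsions under
ν_j = τ_m·cos(P + 144°·(j−2)) with ν0 = C4′–O4′–C1′–C2′ …
ν4 = C3′–C4′–O4′–C1′; using all five torsions instead of the two-torsion
closed form makes the solution robust to ring-closure noise. A flat ring
yields τ_m = 0 with P = 0 by convention, flagged. χ is measured along
O4′–C1′–N9–C4 (purines) / O4′–C1′–N1–C2 (pyrimidines); γ along
O5′–C5′–C4′–C3′. All internal math is in Å and degrees; torsions are wrapped
to (−180°, 180°].

Three functional target forms exist beside plain group means:

* `linear_tau`: value = a·τ_m + b for the five endocyclic angles; slopes are
  all negative (a larger pucker amplitude closes the ring angles). Evaluation
  outside the fitted amplitude range 20°–50° proceeds but logs an
  extrapolation warning.
* `periodic_chi`: value = a·cos(2χ + b) + c for the glycosidic C1′–N and the
  anomeric O4′–C1′ bonds — 180°-periodic with extremes at χ ≈ ±90°, where
  the base is optimally staggered with respect to the ring.
* `grid_chi`: dense tabulated χ-curves (5° spacing, linear interpolation,
  curve-local sigma) for the four glycosidic-link angles, which are
  360°-periodic but not sinusoidal: a second harmonic encodes the syn/anti
  asymmetry. Converting a Gaussian-process posterior into a single sigma per
  group is underdetermined; the curve-local predictive sigma was chosen (and
  is flagged in the derivation report) so that well-sampled χ regions are
  restrained more tightly than sparse ones.

Terminal sugars (no phosphorus within 1.8 Å of O3′/O5′) swap in dedicated
targets for the five parameters that touch the hydroxyl: C3′–O3′, C5′–O5′,
C2′–C3′–O3′, C4′–C3′–O3′, C4′–C5′–O5′. Non-terminal C3′–O3′/C5′–O5′ bond
targets belong to the phosphodiester dictionary and are deliberately absent
here; the SHELXL writer therefore cannot convert angles that need them and
either raises (library default, naming the missing bond) or skips with a log
entry (CLI default).

## The shipped dictionaries

`data/sugar_targets_synthetic.csv` is a synthetic-labelled reference set.
Entries fixed by accompanying running text are exact: the terminal C5′–O5′
bond (1.421 Å), the terminal vs non-terminal C4′–C5′–O5′ pair for anti /
gauche+ (111.5° / 110.6°), the terminal C3′–O3′ endpoints (1.414 / 1.422 Å),
cosine amplitudes spanning 0.007–0.018 Å (family peak-to-peak envelope
2·0.018 = 0.036 Å), τ_m slopes spanning −0.241…−0.088 °/° (maximum swing
over a 20° amplitude change: 4.8°), and the group sizes (130 R-Pu, 51 D-Pu,
84 R-Py, 167 D-Py; terminal counts 351/291). All other group values are
standard nucleoside geometry, not transcriptions.
`data/parkinson_reference_synthetic.csv` plays the role of the classical
fixed-target compilation (keys: sugar type, plus base type at the glycosidic
link) and is likewise a synthetic stand-in. The tabulated χ-grids are
regenerated by `scripts/build_dictionary_data.py`: seeded populations drawn
from the analytic truth curves in `sugarcdl.synthetic` are fitted with the
package's own periodic GPR and tabulated with their predictive sigma.

## The derivation pipeline

Order of operations per parameter, mirroring how such libraries are compiled:

1. **Quality filter**: keep rows with R ≤ 8.5% (inclusive) and
   σ(C–C) < 0.01 Å (strict). Disordered structures are kept — discarding
   them shrinks the sample and inflates the SEM more than it cleans the
   spread. `sampling_diagnostics` reports the SEM/STD trade-off over an
   R-cutoff grid; it drives no decision.
2. **Outlier rejection**: modified Z-score M_i = 0.6745(x_i − x̃)/MAD with
   |M_i| > 3.5, computed per parameter within each sugar-base class; one
   flagged parameter removes the whole structure. A zero MAD with deviating
   points flags the deviators (the formula's limit) and logs. On clean data
   the structure-level false-positive rate is a few percent — the price of
   testing ~24 parameters per structure.
3. **Subgroup discovery**: pairwise two-sided Welch t-tests (α = 0.05, no
   equal-variance assumption, deliberately uncorrected for multiplicity —
   the report counts the tests performed). A factor is accepted when a
   strict majority of its level pairs differ; with several accepted factors,
   the two with the smallest p-values are combined only if the majority of
   sibling-cell comparisons stay significant, otherwise the smallest-p
   factor wins alone. Cells below 5 members merge into their largest sibling,
   flagged. Occasional α-level false positives are expected and observed
   (≈1 spurious grouping per full run); they are visible in the report and
   wash out of the closed-loop statistics (below).
4. **Functional screen**: Spearman correlation with |ρ| > 0.5 and p < 0.05.
   τ_m relations are screened directly (they are monotone). χ relations are
   screened within χ-sign × rotamer quadrants: each quadrant is a monotone
   stretch of a curve whose extremes sit near 0/±90/180°, which is the
   regime rank correlation can detect; a plain |χ| fold would cancel the
   odd (syn/anti-asymmetric) harmonic. Quadrant votes are weighted by
   sample size, as is the family-level majority across groups.
5. **Fitting**: Bayesian ridge regression for linear relations (the
   conjugate, shrinkage-stable equivalent of a linear-kernel GP; restraint
   sigma = the learned noise sigma). For periodic relations, GPR with
   constant × exp-sine-squared (period fixed at 180° or 360°, length scale
   free) + white noise (level free over 1e-7…1e7), candidates ranked by log
   marginal likelihood; inputs are mean-normalised before fitting and
   de-normalised on output. sklearn's predictive standard deviation at new
   points already includes the white-noise level, so it is used directly as
   the curve sigma. A non-convergent search degrades to a flat curve at the
   sample mean/SD, flagged.

`DictionaryBuilder` wraps the pipeline fit-style (`fit(table)` →
`targets_`, `curves_`, `report_`) and `build_dictionary` returns a ready
`RestraintDictionary`.

## The synthetic generator

`generate_synthetic_table` emulates a curated small-molecule fragment table
under the study conditions: class sizes 130/51/84/167; pucker mixture 55%
C3′-endo / 35% C2′-endo / 10% Other for ribose (reversed endo weights for
deoxyribose), with P uniform inside each window; τ_m uniform on 28°–48°
(22°–48° for intermediate puckers, which show the broadest amplitudes); χ
85% anti with uniform magnitude and a 65% bias to negative values; γ drawn
from the gauche+/trans/gauche− mixture (65/21/14) with a clipped 10° spread
and a 3% unassigned tail; R-factor uniform on 4.5–8.4% and σ(C–C) on
0.003–0.0095 Å, with a 5% poor-quality fraction beyond the cutoffs; 10%
disorder flags; 2% planted gross outliers at 8–12 population SD. Parameter
values are the dictionary's evaluated target plus Gaussian noise at the
dictionary sigma; the four glycosidic-link angles are drawn from the
analytic truth curves with their observation noise (the tabulated grid
sigma also carries curve-estimation uncertainty and would double-count).
What the generator does **not** emulate: correlations between parameters
within a sugar (ring closure couples them in reality), heteroscedasticity
across laboratories and eras, non-Gaussian error tails, and any dependence
between conformational variables beyond their marginal mixtures. Passing
closed-loop tests therefore demonstrates the statistical machinery, not the
chemical truth of the shipped numbers.

## Closed-loop self-consistency

`recovery.closed_loop_recovery` draws tables from the shipped dictionary,
re-derives a dictionary from each, and compares every recovered target with
the noise-free generating values of its own member fragments (so legitimate
regroupings are compared against the effective truth of the pooled members).
Because single draws at the study sample sizes have sampling errors
comparable to the tolerances of interest (the shallowest slope, −0.088, has
a ≈10% standard error even at n = 120), the harness runs 7 independently
seeded replicates and takes, per group recovered in at least 4 of them, the
median error. Under these conditions fixed targets recover within 2 SEM,
slopes within 15% and curve amplitudes within 20%, and the glycosidic-bond
χ-dependence is detected in every replicate. The O4′–C1′ relation is a
documented detection-limit case: its 0.007 Å amplitude against 0.009 Å noise
gives ρ ≈ 0.49 versus the |ρ| > 0.5 rule, so its periodic form is found only
in a minority of replicates — faithfully reproducing what the screening
procedure can and cannot see.

## Numerical and interface choices

* Writers print 3 decimals for Å and 2 for degrees, matching tabulated
  precision; records are sorted (chain, residue, altloc, kind, parameter) so
  output is byte-stable; every invocation regenerates restraints from
  scratch because group assignments move with the model.
* SHELXL angles become DANG 1–3 distances,
  d13 = √(b1² + b2² − 2·b1·b2·cosθ), with first-order sigma propagation
  over both bond sigmas and the angle sigma; DANG was chosen as SHELXL's
  native mechanism for angle restraints.
* Altloc conformers are expanded into independent fragments with independent
  restraints; the well-ordered filter used for validation keeps only
  full-occupancy, single-conformer sugars (switchable).
* Validation evaluates every functional target at the fragment's own
  (P, τ_m, χ, γ) — the point of conformation-dependent restraints — and
  reports RMSD over bonds and angles separately, with per-record |Δ| tables
  for histogram comparisons and a paired Wilcoxon signed-rank test between
  two dictionaries (all-zero differences are reported as the degenerate
  no-difference case, p = 1). All measured parameters of the dictionary
  enter the score, including the glycosidic-link angles into the base.
* Problem sizes: the closed loop uses the study sample sizes (432 fragments
  per replicate, 7 replicates); the acceptance script scores one 432-row
  population and runs one closed-loop ensemble.

## Known limitations

The shipped numeric dictionary is a synthetic reference (see above), so
absolute target values should not be quoted as the published library.
Restraints for the phosphodiester and nucleobase moieties are out of scope
(the schema accommodates them). Refinement itself (REFMAC/PHENIX/SHELXL
runs, R-factor sweeps) is not performed; the validation layer stops at
restraint-vs-model scoring. Hydrogens, anisotropic displacement and symmetry
expansion are ignored; only the first model of multi-model files is read.
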