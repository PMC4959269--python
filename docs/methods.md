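# Methods

## The model

`adiposwitch` implements a six-variable ODE model of the preadipocyte-to-
adipocyte commitment decision.  State variables are relative concentrations
(arbitrary units) of C/EBPβ (`cebpb`), PPARγ (`pparg`), C/EBPα (`cebpa`),
phospho-AKT (`pakt`), the insulin receptor (`ir`) and accumulated lipid
(`fat`).  Each species obeys synthesis-minus-first-order-degradation
kinetics; the synthesis terms carry the circuit structure:

* glucocorticoid (GR) × cAMP drives C/EBPβ additively;
* C/EBPβ + C/EBPα drive PPARγ through a third-order Hill term in their sum
  (half-saturation α₂), gated multiplicatively by pAKT (α₃);
* PPARγ activity drives C/EBPα (Hill 3, α₄) — feedback loop 1 — and C/EBPβ
  (Hill 2, α₁) — feedback loop 2, with a higher activation threshold
  (α₁ > α₄);
* C/EBPα drives insulin-receptor expression (α₆) — feedback loop 3 — which
  raises pAKT and hence PPARγ;
* cAMP × GR suppresses pAKT synthesis (α₅), so insulin signalling is partly
  muted while the induction cocktail is present;
* pAKT and PPARγ activity jointly drive fat accumulation (α₇, α₈), with no
  feedback back into the switch.

Thiazolidinediones (the `rosi` input) are ligands of PPARγ: they multiply
the *activity* of existing protein by `1 + rosi_gain·r/(rosi_k + r)` without
adding protein.  This activity replaces PPARγ wherever it acts as a
regulator (the C/EBPβ, C/EBPα and fat equations).  Doses are expressed in
units of the half-saturation `rosi_k`; no pharmacokinetic mapping to molar
concentrations is attempted.

Insulin is modelled as an external channel `u_ins ∈ [0, 1]` multiplying pAKT
synthesis, while the insulin receptor remains a dynamic state variable.
This keeps the receptor loop (loop 3) intact and lets the no-insulin
control be expressed as a protocol rather than a parameter change.  The
C/EBPα activation denominator uses the Hill exponent 3, matching its
numerator; `alpha4_exp = 2` switches to the alternative form with mismatched
exponents, which changes no qualitative behaviour (it only rescales the
effective threshold).  The basal IR term `base_ir` appears in both the pAKT
and IR equations.

siRNA knockdowns are multiplicative reductions of the target's synthesis
scale (basal term included), constant over the whole simulation;
glucocorticoid-receptor knockdown instead scales the GR input channel.

## Units convention and the reference parameter set

Concentrations are normalised so that every transcription factor and the
insulin receptor sit at exactly 1.0 in the unstimulated steady state
(all inputs zero, hence pAKT = 0 and fat = 0).  `normalized_params()`
enforces this by solving the basal fixed-point equations for the synthesis
scales; pAKT synthesis is scaled so pAKT ≈ 1 under insulin alone with basal
receptor levels, and fat synthesis so the resting insulin-on fat level is 1.

The remaining shape constants were calibrated against the behaviours the
model is meant to exhibit, with four qualitative gates treated as mandatory:
bistability of the intact circuit under insulin alone, monostability of the
one-loop variant (loop 2 removed), commitment after 48 h of induction, and
reversion without loop 2.  Numeric targets (population Hill coefficient
≈ 2.5, bimodality window edges, commitment timing, lipid contrast) were
scored at the tolerances given with each statistic.  `calibrate_reference_
params` exposes the same machinery as a bounded log-space search (random
multistart plus Nelder–Mead refinement).  Because many parameter sets
satisfy the targets, the shipped set is a convention, not an estimate; the
JSON in `adiposwitch/data/reference_params.json` is the single source of
truth and `reference_params()` loads it.

Reference values: degradation 0.2 h⁻¹ for the three transcription factors
(half-life ≈ 3.5 h), 1.0 h⁻¹ for pAKT (fast signalling), 0.05 h⁻¹ for the
insulin receptor (the slow accumulation that delays loop 3 by ~1 day) and
0.06 h⁻¹ for fat; basal expression 0.012–0.1; α₁ = 9, α₂ = 17.5, α₃ = 2.5,
α₄ = 3.5, α₅ = 0.65, α₆ = 10, α₇ = 1, α₈ = 4.8; `rosi_gain` = 24.  With
these values the insulin-on circuit has a low state at PPARγ ≈ 1.01, a high
state at ≈ 10.0 and a saddle at ≈ 4.2.

## Integration

Trajectories use LSODA (stiff-capable, adaptive) at rtol 10⁻⁸ / atol 10⁻¹⁰,
restarted at every protocol breakpoint so the piecewise-constant inputs are
handled exactly.  Negative overshoots below 10⁻⁸ are clipped to zero;
anything larger raises.  Population runs default to rtol 10⁻⁶ / atol 10⁻⁹
(population statistics are insensitive at this level and runs are several-
fold faster).  A fixed-step RK4 integrator in the test suite provides an
independent oracle: adaptive and fixed-step solutions agree to better than
10⁻⁴ relative error across random parameter sets.

## Cell-to-cell variability

Heterogeneity is purely extrinsic: each simulated cell draws its parameters
once, before time zero, and keeps them.  The synthesis, degradation and
basal parameters of the C/EBPβ, PPARγ and C/EBPα groups are multiplied by
independent lognormal factors with median 1 (σ = √ln(1+cv²)), so the
deterministic model is exactly the population-median cell.  Default CVs are
15% for the PPARγ group and 30% for the C/EBPβ and C/EBPα groups; pAKT,
receptor and fat parameters are noise-free unless enabled.  Each cell
starts from the basal fixed point of its own parameter set (cells are
assumed equilibrated before stimulation).  Reproducibility comes from
spawning one child seed per cell from the root `SeedSequence`, so tables
are bit-identical across runs and machine counts.

What the generator does *not* emulate: intrinsic (temporal) noise, cell
division and crowding, parameter correlations between genes, and slow
drifts — so passing tests show that extrinsic lognormal variability is
*sufficient* to produce the observed population behaviour, not that real
cells have independent parameter noise.

## Bimodality classification

`classify_bimodality` fits one- and two-component Gaussian mixtures to
log₁₀ intensities and calls a distribution bimodal when (i) BIC prefers two
components, (ii) the kernel-density estimate of the data itself has at
least two modes (Scott bandwidth, 2% prominence floor), and (iii) both
posterior-assigned subpopulations hold ≥ 5% of the cells.  The low/high
threshold is the equal-posterior crossing between the component means.
Two choices deserve comment.  The subpopulation floor is applied to
assigned fractions rather than raw mixture weights because a component that
merely absorbs the tail of the other can carry > 5% weight with almost no
cells of its own.  Mode-counting replaces a component-separation rule
because late-committing cells form a thin bridge between the modes at
intermediate sample times; the bridge inflates the fitted component widths
but does not create a second density mode, and conversely a genuine minor
mode stays visible regardless of how the mixture allocates variance.

## The noise window ("sweet spot") scan

For each CV on the grid the per-group defaults are scaled uniformly (the
grid value is the C/EBPβ/α-group CV; the PPARγ group is half of it), a
population is run through induction + washout, and two verdicts recorded:
bimodality of end-state PPARγ, and "bistability intact", implemented as a
majority of sampled cells whose individual parameter sets still admit two
attractors under insulin alone (checked by relaxing each cell from its
basal state and from a high push state).  At large CV the lognormal draws
push most cells outside the bistable region of parameter space — they
become monostable-low or monostable-high — which is what "breaking the
bistability" means here.  The window is the contiguous CV range where both
verdicts hold.

## Dose-response conventions

Two sweeps exist.  `steady_state_dose_response` is the deterministic
forward branch: each dose held ≥ 240 h from the basal state.  Because the
single-cell response is a bistable jump, this curve is nearly a step
function; it is the right object for locating saddle-node thresholds, not
for cooperativity estimates.  `ensemble_dose_response_48h` mirrors the
plate experiment: population means over a noisy ensemble measured 48 h
after applying sustained doses (insulin present — PPARγ induction requires
basal pAKT signalling — plus a dose-0 vehicle control with the same
sampled cells).  The smooth Hill ≈ 2.5 sigmoids arise from averaging
all-or-none switches across cells with variable thresholds.  Converted
fractions are reported as the excess over the vehicle control, matching a
paired control-well design; the 5%→95% conversion span is evaluated on that
excess.  Hill fits are 4-parameter least squares (floor free), multi-started
over initial exponents {0.5, 1, 2, 4}.

## Synthetic imaging

Fields default to 512×512 px at 1.6 µm/px (a plausible calibration for a
low-magnification objective; configurable).  Nuclei are uniform disks
(radius ~6 µm) placed with a minimum separation; nuclear stains scale the
disk amplitude by the cell's state value, cytosolic stains cover the
7 µm perinuclear annulus; the field is Gaussian-blurred, offset by a
(possibly tilted) background and corrupted with Poisson plus Gaussian read
noise.  Quantification: local maxima of the smoothed Hoechst channel above
median + 6·MAD give sub-pixel centroids; the nucleus mask grows from each
centroid to 30% of the *background-subtracted* local peak (the relative
cutoff must exclude the background level or the level set is unbounded on
noisy images); the cell mask is the nucleus dilated by round(7 µm/pixel
size); backgrounds are per-channel medians over a 2–5 µm annulus beyond the
cell mask excluding neighbours, with a field-wide fallback when occluded.
Touching nuclei may merge into one detection; this is accepted behaviour at
the default separation.

## Problem sizes

Unit and acceptance tests use 150–400-cell ensembles; the reproduction
script uses 1,000 cells per condition (2,000 for the dose sweep, whose 5%
and 95% conversion edges benefit most from counting statistics) and a
9-point CV grid.  These sizes put binomial standard errors near or below
one percentage point, which is small compared with every tolerance used.

## Known limitations

* The deterministic EC50 separation between the C/EBPβ and C/EBPα responses
  is ~1.3-fold, not the ~4-fold seen experimentally.  In this architecture
  the population curves of all readouts are dominated by the same
  commitment event, so their EC50s cannot separate much; reproducing the
  separation kinetically requires C/EBPβ turnover slow enough (half-life
  ~1 day) that the washout race — the mechanism that creates the
  non-committing subpopulation at moderate noise — disappears.  The shipped
  calibration resolves this tension in favour of the bimodality window.
* For the same reason commitment under a saturating ligand pulse completes
  within ~12 h, so a 24 h saturating pulse commits ~90% of cells rather
  than ~half.
* Mean fold-inductions (e.g. C/EBPβ ~40-fold at saturating doses) are
  larger than typical immunofluorescence fold-changes; concentrations are
  relative units normalised to the basal state, not calibrated intensities.
* The one-parameter sweeps use warm-started relaxation, not arclength
  continuation; adequate for the S-shaped diagrams here, but folds closer
  than one grid step apart would be missed.
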