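# Methods

This note records the models implemented in `crispri_circuits`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where more than one
reasonable option existed.

## Equilibrium binding model

**Model.** dCas9 (*C*), sgRNA (*g*) and free target-promoter DNA (*D*)
interact through two reversible binding steps, C + g ⇌ C:g and
C:g + D ⇌ C:g:D.  Binding is assumed much faster than transcription,
translation, degradation and dilution, so the bound fractions are at
quasi-equilibrium given the total concentrations *C_tot*, *g_tot*, *D_tot*
(all in nM; ≈ molecules per cell in *E. coli*, which is how plasmid copy
number enters as *D_tot*).  Reporter output is R = θ·D with the lumped gain
θ absorbing transcription, translation, maturation, degradation and
dilution; the repressed promoter is taken as fully silent.  θ defaults to
1.0 — it is a pure scale factor, and results are usually reported as the
free fraction D/D_tot.

**Fixed-point solver.** The implicit system is iterated sequentially in
the order C, g, D, each update using the latest values, from the all-free
start (C, g, D) = (C_tot, g_tot, D_tot).  The all-free state dominates the
root componentwise and the map is a contraction toward it over the tested
box ([0.01, 10⁴] nM per axis).  Convergence is declared when the maximum
relative change across (C, g, D) falls below 1e-9 (max 10⁵ iterations).
If the undamped iteration starts oscillating — detected as a growing step
after the first ten iterations, which occurs when C_tot ≈ g_tot ≫ K₁ —
a damping factor of 0.5 is blended in automatically.  Should the iteration
ever fail to converge, the bisection solver's result is returned with
`converged=False` and a logged warning; in practice the whole acceptance
box converges in ≤ a few hundred iterations.

**Independent oracle.** Substituting the conservation laws reduces the
system to two unknowns x = [C:g], y = [C:g:D] with
K₁x = (C_tot−x−y)(g_tot−x−y) and K₂y = x(D_tot−y).  For fixed y the first
equation is a quadratic solved in closed form (smaller root, evaluated in
the product form 2ab/(s+√(s²−4ab)) to avoid cancellation); the outer
residual K₂y − x(y)(D_tot−y) is strictly increasing in y on
[0, min(C_tot, g_tot, D_tot)] and is bisected to machine precision.  The
oracle shares no code path with the fixed-point iteration and is the ground
truth in the test suite; the two agree in D to better than 1e-6 relative
over a 1000-point Latin-hypercube of the concentration box.

**Boundary cases.** g_tot = 0, C_tot = 0 and D_tot = 0 are solved
analytically (no complex can form, or the problem reduces to a single
binding quadratic); this also keeps the explicit-limit formula finite,
which is evaluated as θ·D_tot / (1 + C_tot·g_tot/(K₂(K₁+g_tot))) — an
algebraic rearrangement with no 0/0 at g_tot = 0.  The explicit form is
documented as valid only for g ≫ C ≫ D; at 100× separations it tracks the
implicit solution to within 2%, and the package treats it as an
approximation to compare against, never as the solver.

**Switch points.** A transfer curve's switch point is located by scanning
for the bracketing grid pair and interpolating linearly in log₁₀(input)
(transfer curves live on log axes).  A curve that never crosses the
requested level yields an explicit no-crossing result rather than an
exception or a sentinel number.  Note that half repression (D/D_tot = 0.5)
does not exist when the repressor complex is capped below D_tot/2 by a
scarce species — e.g. C_tot = 1 nM against D_tot ≥ 10 nM — which is itself
a prediction of the model (incomplete repression).

**Default parameters.** K₁ = 0.3 nM, K₂ = 2 nM (plausible affinities for
dCas9–sgRNA and complex–operator binding); exploration ranges 1–100 nM for
DNA and 1 nM–10 µM for dCas9 and sgRNA, with sweep grids extended downward
to 0.01 nM for plotting the full sigmoid.

## Plate-reader kinetics

**Pipeline.** Tidy CSV input (time_min, well, channel, value) plus a well
map.  Steps: (i) subtract the time-pointwise mean of blank-medium wells
from OD600 and fluorescence; (ii) optionally subtract strain
autofluorescence, interpolated from the control wells as a function of
corrected OD rather than time so that growth-timing differences between
control and sample do not bias the correction (sample OD beyond the
control's range is clamped to the nearest covered value with a warning);
(iii) negative corrected values are clipped to zero and counted; (iv) the
exponential window is selected from corrected OD; (v) µ is the OLS slope
of ln(OD) against time in hours within the window; (vi)
S(t) = (dF/dt)/OD600 with central differences (one-sided at the series
ends, `numpy.gradient`), masking points with OD below 0.001;
(vii) S_ave = mean of S(t) over the window of the same well;
(viii) S_cell = S_ave/S_ave,ref with channel-matched reference strains
(distinct strains calibrate RFP and GFP); reference wells are averaged per
strain.  Time is minutes in, µ per hour out; S_ave is AU·OD⁻¹·min⁻¹ and
units cancel in S_cell.

**Exponential-window definition.**  The window is the longest contiguous
run of points with corrected OD inside [0.003, 0.015]·max(OD) whose
log-linear fit reaches R² ≥ 0.99 with at least 5 points, ties broken
toward earlier windows.  The band placement matters more than any other
default in this module: on a logistic growth curve the apparent log-linear
rate at OD equal to a fraction f of the carrying capacity is depressed by
≈f, so a window reaching half-saturation underestimates µ by about 20%,
and even a band at 5–50% of the maximum biases µ by 10–20%.  The chosen
band keeps the curvature bias below ~1% while staying above typical
inoculum/lag levels; with it, round-trip recovery on synthetic plates is
within 1% of truth at zero noise and within 5% at 2% noise CV.  The band
edges, R² threshold and minimum point count are all keyword arguments.

**Background procedure.** The two-stage blank + OD-matched
autofluorescence correction is this package's own choice of a standard
procedure; both stages are optional per channel.

**Smoothing.** None by default; an odd-width Savitzky–Golay filter on the
fluorescence channel is available behind `--smooth N` for noisy
instruments.

## Hill circuit models

**Forms.** Activation y = basal + range·xⁿ/(Kmⁿ+xⁿ); repression
y = basal + range/(1+(x/Km)ⁿ).  Four free parameters per stage; basal,
range ≥ 0, Km, n > 0.

**Composition.** Cascades feed each stage's output into the next.  A
CRISPRi NOT gate is composed mechanistically: an activation stage maps the
inducer to g_tot, and the equilibrium model computes the repression — so
the gate inherits the DNA-dependent switch point and incomplete-repression
behaviour rather than assuming a phenomenological repression Hill.  The
NOR gate multiplies the two normalized repression terms on a shared output
scale, y(a,b) = basal + range·f₁(a)·f₂(b), the natural form when the two
repressors have overlapping, mutually exclusive binding sites.  A min-based
composition would instead describe independent full blocking; the
multiplicative choice is flagged as a modelling decision and both give the
same truth table at saturating inputs.

**Fitting.** Component-wise: each stage is fitted to its own transfer
curve and the stages are composed without joint refinement, mirroring how
individual devices are characterized in isolation before assembly.  Least
squares is run on log(output + ε), ε = 1e-6·max(output), because outputs
span decades and a linear-scale fit would ignore the repressed tail.
Optimization is `scipy.optimize.least_squares` (trust-region reflective,
bounded) restarted from 8 deterministic initial guesses — Km at four
log-spaced positions across the positive input range × n ∈ {1, 3} — with
the best residual winning and ties broken toward smaller n.  Randomness
never enters the fit; seeds only control synthetic noise.  Replicates
enter the residual jointly, unweighted.  At least 4 distinct input values
are required (4 parameters).

## Synthetic-data generator

**Plates.** Per well: three-parameter logistic OD with lag,
OD(t) = K·x₀·e^{µ(t−lag)}/(K−x₀+x₀e^{µ(t−lag)}); fluorescence accumulates
as the trapezoidal integral of s_true·OD(t); the measured series are
signal·lognormal-noise + additive instrument background.  The background
is a stable offset (it is what the blank wells measure); the
multiplicative lognormal (mean-one, stated CV) models pipetting and
biological proportional variability.  Optionally an OD-proportional
autofluorescence can be added to every well and to the
autofluorescence-control wells.  Defaults: 5-min sampling over 18 h,
µ ∈ [0.5, 0.9] h⁻¹, capacity 1.0 OD, lag 60 min, inoculum 0.002 OD
(a deep dilution into fresh medium), OD background 0.04, reference strains
in biological triplicate.  Blank-medium and autofluorescence-control wells
are always appended so the reduction pipeline runs end to end.  Identical
seed + configuration produce byte-identical CSV/JSON artifacts, and the
truth file records every generating parameter.

**Curves.** Either a Hill stage or an equilibrium-model sweep evaluated on
a grid (default inducer grids: HSL 0.1–500 nM, IPTG 0.1–100 µM, each with
a zero point), with independent mean-one lognormal noise per replicate and
grid point.

**What passing the round trip does and does not show.** The generator
shares the logistic/accumulation model family with none of the reduction
code (the reduction never fits a logistic), so recovery is a genuine
cross-check of windowing, differentiation and normalization.  It does not
emulate: burden feedback of reporter expression on growth, maturation and
dilution of fluorophores, lag-phase metabolic adaptation beyond a time
shift, instrument drift, or cell-to-cell variability — so the stated
recovery tolerances characterize the pipeline's numerics, not its accuracy
on real reads where those effects dominate.

## Interface

All subcommands consume/emit tidy CSV and validated YAML configs (pydantic
models, unknown keys rejected with a field-level message and exit status
2); each run writes a manifest (config hash, package version, input/output
paths).  Figures are rendered from the written CSVs, never from in-memory
state, so any figure is regenerable from its data artifact.

## Known limitations

- Steady-state only: no kinetics of binding or expression dynamics.
- Single sgRNA: no dCas9 resource competition across guides.
- The NOR composition is multiplicative by choice (see above).
- The growth-rate estimator is a windowed log-linear OLS; cultures whose
  exponential phase is shorter than ~5 samples in the selected OD band
  fail explicitly rather than returning a biased estimate.
- Hill fitting reports the best bounded local optimum from a fixed
  multi-start grid; pathological curves (non-monotone data, all-zero
  outputs) are rejected rather than fitted.
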