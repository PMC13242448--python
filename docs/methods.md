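# Methods

## Osmotic volume dynamics

The simulator and the fitting stages share one physical model of a cell
of initial volume `V0` and constant membrane area `A` (fixed at its
initial value — volume excursions in these assays are modest, and the
permeability formulas use a single `V0/A`). Water flux is proportional
to the osmotic gradient:

    dV/dt = −Pf · A · Vw · (osm_out − Ns/V)

with `Ns` the conserved amount of impermeant internal solute
(`Ns/V0 = osm_in,0`) and `Vw = 18 cm³/mol`. In relative volume
`v = V/V0` this is a one-state ODE whose equilibrium is the
Boyle–van 't Hoff ratio `v(∞) = osm_in,0 / osm_out,∞`. A glycerol shock
adds the permeant amount `Ng`:

    dNg/dt = Pgly · A · (gly_out − Ng/V),   osm_in = (Ns + Ng)/V

giving the familiar biphasic shrink/re-swell trace with a single
minimum. Osmolarities are user-facing osmol/L and convert to mol/cm³
(×10⁻³) wherever they multiply `Vw`. Integration uses LSODA with
relative tolerance 10⁻⁸ (the re-swell phase is mildly stiff at high
Pf). The fluorescence of the volume-sensitive dye is taken linear in
relative volume, `signal = 1 + α(v − 1)` with α = 1 by default; any
monotone calibration gives the same fitted rate after normalization.

Default geometry: a sphere of radius 2.5 µm, `V0/A = r/3 ≈ 8.33×10⁻⁵
cm` — a typical budding-yeast cell; configurable, since the true value
for a given strain preparation is rarely known. Default shocks:
sorbitol 0.35 → 0.42 osmol/L (water assays) and a doubling of external
osmolarity entirely by glycerol, 0.35 → 0.70 osmol/L (glycerol
assays), with Gaussian signal noise of SD 0.005 in the demo
configuration. These stand in for instrument conditions that real data
would supply; all are configurable.

## Shrinkage fit window — why 90% of the decay

The field's convention fits the shrinkage signal to a single
exponential and converts with `Pf = k (V0/A)/(Vw (osm_out)∞)`. That
formula assumes the *initial-gradient* (linearized) rate constant
`k_lin = Pf · Vw · osm_out,∞ · (A/V0)`. The true relaxation is not
exponential: near equilibrium it decays at `k_lin · osm_out/osm_in`,
i.e. faster than `k_lin` by the shock ratio. A least-squares
exponential fitted over the *entire* relaxation is therefore biased
upward (about +6% at shock ratio 1.2, +15% at ratio 2), while a fit
confined to the early transient is biased downward (curvature matching
at t = 0 gives `k_lin · osm_in/osm_out`).

The default window runs from t = 0 until the smoothed signal has
completed 90% of its decay amplitude. Empirically this keeps the fitted
rate within ±3% of `k_lin` for shock ratios up to 2 (+1.8% at the
default ratio 1.2), which is what makes the round trip through
`compute_pf` accurate. The plateau is estimated as the mean of the last
decile of the smoothed signal (a minimum would sit systematically low
under noise and stretch the window); the window end is configurable via
the `band` parameter. Smoothing for window and minimum detection is a
centered 5-sample moving average; fits always run on unsmoothed data.
Fit initialization is data-derived (offset ← last-decile mean,
amplitude ← first sample minus offset, k ← 1/t₆₃), with k bounded in
(10⁻⁴, 10³) s⁻¹; an estimate at a bound is flagged rather than silently
returned. Traces should span ~8–10 relaxation times so the plateau
estimate is meaningful.

## Re-swell slope — window placement and gradient correction

`Pgly = m (V0/A)` with `m` the slope of an OLS line over the
glycerol-influx phase, normalized by the glycerol fraction of the shock
`g = gly_out/osm_out,∞` (so `m` reduces to the bare slope for a
pure-glycerol shock). Two systematic effects matter:

1. **Water transient.** At the volume minimum the *net* slope is zero
   by definition; the quasi-steady influx slope is only reached a few
   water relaxation times later. The window therefore starts 4/k_w
   after the smoothed minimum, where k_w is fitted from the trace's own
   shrinkage phase (falling back to one sampling interval when no
   shrinkage fit is possible). Ties in the minimum break toward the
   earliest time.
2. **Gradient depletion.** Glycerol taken up before and during the
   window lowers the driving gradient below `gly_out`, so the raw
   normalized slope underestimates Pgly — by ~10–30% under the default
   conditions, worst for fast transporters. Under fast-water
   quasi-equilibrium the internal glycerol content is readable from the
   trace itself (`Ng/V0 = osm_out·v − osm_in,0`), so the remaining
   gradient fraction is `(gly_out − osm_out + osm_in,0/v̄)/osm_out`
   with `v̄` the mean relative volume over the window. Normalizing the
   slope by this measured fraction instead of `g` removes the bias
   (residual < 2% across the simulated permeability range, including at
   the default 40%-recovery window end) and reduces exactly to the
   plain `g` normalization when no glycerol has entered. The correction
   is off in the low-level `fit_reswell_slope` (whose contract is the
   plain normalized slope) and on in the pipeline path. It requires the
   shock composition in the trace metadata, and it assumes the
   fluorescence–volume scale is anchored correctly — hence the
   simulator samples glycerol shocks densely enough that the
   normalization anchor (mean of the first three samples) sits at
   relative volume ≈ 1.

The window ends where the signal has recovered 40% of the shrinkage
amplitude (or at the trace end if never reached, with a minimum of 20
points); a monotone trace raises a window error, which the pipeline
treats as glycerol-impermeable behaviour.

## Arrhenius, effects, intracellular pH

Activation energies use OLS of `ln P` on `1/T` (kelvin = °C + 273.15);
`Ea = −R·slope` with R in kcal units because activation energies in
this field are reported in kcal/mol. At least three distinct
temperatures are required; the estimator is invariant to scaling all
permeabilities (the prefactor absorbs it). The pipeline's Arrhenius
stage fits per-temperature mean permeabilities.

Replicate aggregation reports mean and sample SD (n−1), with a quality
filter r² ≥ 0.9 (configurable); exclusions are counted and logged, and
single-survivor aggregates are flagged. Treatment effects report the
signed percent change and fold change of the means — percent also
rounded half-away-from-zero to the nearest integer, the convention used
in published effect statements — plus Welch's t-test on the replicate
values (scipy's unequal-variance test; the suite cross-checks it
against the textbook formulas). Significance stars: * p<0.05,
** p<0.01, *** p<0.001. No multiple-testing correction is applied;
reports carry the comparison count implicitly (one row per comparison).
Dose–response tables are sorted by dose and classified
strictly-increasing / strictly-decreasing / non-monotone on the means;
ties count as non-monotone.

The weak-acid probe assumes only the neutral species equilibrates, so
the in/out accumulation ratio is
`R = (1 + 10^(pH_in−pKa)) / (1 + 10^(pH_out−pKa))`; inversion gives
pH_in, and a ratio making the inversion argument non-positive is
rejected as inconsistent with any pH. pKa defaults to 4.87 (propionic
acid at 25 °C) and is configurable. Generator and inverter are exact
mutual inverses to 10⁻⁹ across pH_in ∈ (3, 8).

## qPCR stage

Amplification curves are modeled as a constant baseline plus a logistic
plateau; the sigmoid midpoint is placed so the baseline-corrected
signal crosses the threshold at the intended Cq. Quantification assumes
100% efficiency (doubling per cycle), matching 2^(−ΔΔCq)
quantification; per-gene efficiency correction is out of scope. Cq
calling subtracts the mean over baseline cycles 5–17 (endpoints
inclusive) and interpolates the threshold crossing linearly in
log₁₀(ΔRn) — amplification is exponential there, and the interpolation
keeps round-trip error below 0.02 cycles. Non-positive ΔRn values are
floored at 10⁻⁶ inside the logarithms only. The default threshold 68 is
an instrument-scale-specific value; it is a parameter everywhere. A
curve that never crosses returns an *undetermined* Cq — a result, not
an error, since a non-amplifying gene is a legitimate observation — and
undetermined wells are excluded from ΔΔCq with a logged count.
Technical replicates are averaged before biological replicates; the
ΔΔCq standard error and a two-sample t-test run across biological
replicates (Welch by default, pooled-variance variant available, since
both conventions appear in practice).

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the analysis
assumes: near-exponential shrinkage with additive Gaussian noise,
biphasic glycerol traces, exactly ln-linear Arrhenius series,
equilibrium weak-acid ratios, and sigmoid qPCR curves with
perfect-efficiency Cq placement. It does not emulate instrument
artifacts (mixing dead time, photobleaching, drift), CF loading or
esterase kinetics, cell-size heterogeneity, mercury-binding chemistry
or channel conformational states (treatments enter only as labels with
different effective permeabilities), or qPCR efficiency differences
between genes. Passing tests therefore validate the estimators under
the model's assumptions; real data can violate them (notably the
fluorescence–volume linearity and the constant-area approximation), and
the configurable windows/thresholds exist for exactly that reason.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds through numpy
Generators; identical configuration + seed is bit-identical, and the
orchestrated run stamps every output table with the configuration hash
and master seed. Default problem sizes — 1200 samples per water trace
(10 linearized relaxation times), ~2000–30000 samples per glycerol
trace (8 water relaxation times plus 60% of glycerol equilibration,
sampled finely enough to anchor the normalization), 10 replicate shocks
per condition, 6 Arrhenius temperatures, 3 biological × 2 technical
qPCR replicates — mirror the replication structure of the assays the
pipeline is designed for and keep a full demo run under two seconds.
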