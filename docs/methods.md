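# Methods

## Scope

`grasshydro` implements the computational chain linking grass leaf anatomy to
whole-leaf hydraulic function, drought response and comparative statistics:

1. theoretical vein xylem conductance from conduit geometry;
2. partitioning of measured leaf hydraulic conductance (K_leaf) into xylem
   (K_xc) and outside-xylem (K_oxc) components;
3. a quasi-static soil dry-down simulator coupling leaf water supply,
   stomatal closure and C3/C4 photosynthesis;
4. phylogenetic comparative statistics (Pagel's λ, PGLS, simulation-based
   phylogenetic ANOVA, phylogenetic RMA);
5. a synthetic-data generator producing trees, trait tables, anatomy tables
   and vulnerability curves with the statistical structure the analyses
   assume, so the whole chain is testable offline.

## Anatomy-based xylem conductance

Each xylem conduit (or protoxylem lacuna) is an elliptical capillary with
full major/minor axes a, b (µm).  Its conductivity is Poiseuille's law
modified for ellipses,

    k_t = (π / 64 µ) · a³b³ / (a² + b²),

with µ = 8.9 × 10⁻¹⁰ MPa s (water at 25 °C) and the volumetric result
converted to molar units via 5.556 × 10⁷ mmol per m³ of liquid water.  Axes
are interpreted as *full* diameters because the circular case a = b = 2r
then reduces exactly to Hagen–Poiseuille π r⁴ / 8µ; this identity is tested
to < 10⁻¹² relative error.

Per vein order, k_t sums over all conduits: type I (wide) and type II
(narrow) xylem plus the single protoxylem lacuna in the 1° and 2° (major)
veins; type II only in the 3° and 4° (minor) veins.  The whole-leaf xylem
conduit conductance is

    K_xc = ( Σ_order k_t(order) · D_v(order) ÷ (0.5 · LL²) ) ÷ 0.71,

with vein density D_v in mm mm⁻² (converted to m⁻¹), leaf length LL in m and
0.71 the area correction for linear leaves.  The normalization `0.5·LL²` is
the default; the typographically plausible alternative `(0.5·LL)²` is exposed
as `ll_convention="half-then-square"` (it scales K_xc by exactly 2, so no
qualitative conclusion depends on the choice).

Construction cost is the cell-wall volume index CC = π · CD^e · CN · D_v with
exponent e = 1 by default (constant wall thickness) and e < 1 available for
the walls-scale-sublinearly-with-diameter variant.  Wall thickness itself is
not an input; e is purely a sensitivity knob.

Sheath metrics treat each bundle/mestome sheath cell as a circle of mean
diameter D: outer perimeter per order is (D/2)·π·N for N cells, averaged
over the orders that actually possess the sheath (this generalizes the
fixed ÷3 / ÷4 of the three- and four-order layouts to leaves lacking a
sheath on some orders).  Surface area, projected area and volume per leaf
area are D·π·D_v·N, D·D_v·N and (D/2)²·π·D_v·N, reported in SI-consistent
m²·m⁻² / m³·m⁻² after unit conversion.

## Hydraulic partitioning

K_leaf is two conductances in series, so

    K_oxc = (1/K_leaf − 1/K_xc)⁻¹,   valid only when K_xc > K_leaf;

an infeasible pair raises rather than returning a negative resistance.
Vulnerability curves (Ψ_leaf, K_leaf) are fitted by ordinary least squares
as K = K_max + a·Ψ, and P50 = −K_max / 2a is the potential at which the
fitted line reaches half its intercept.  OLS is the default because the P50
definition operates on the fitted intercept and slope; a standardized major
axis option (`method="sma"`) is provided for sensitivity since the slope of
an errors-in-both-variables line differs.  A non-positive fitted slope is a
"no decline" signal with P50 undefined, not silently clamped.

Species means in meta-analysis aggregation weight each study once; the
K_leaf:g_s ratio is computed from aggregated species means but only for
species where at least one study reported both traits (pairing values
measured under different conditions is avoided).  Pathway fold contrasts
are arithmetic means of species means with C3 fixed at 100% (geometric
means optional).  Dixon's Q10 test (Q = extreme gap / range, two-sided
critical values for n = 3–30 at α = 0.05) screens single outliers in the
small per-trait samples.

## Photosynthesis

C3: Farquhar-type, A = min(Wc, Wj)·(1 − Γ*/Ci) − Rd, with Rubisco-limited
Wc = Vcmax·Ci/(Ci + Kc(1 + O/Ko)) and electron-transport-limited
Wj = J·Ci/(4Ci + 8Γ*).  Below the compensation point (Ci ≤ Γ*) the gross
term is clamped at zero so A = −Rd, which keeps A continuous and
non-decreasing in Ci down to Ci = 0; the unclamped expression would tend to
−Vcmax·Γ*/Km there, an unphysical CO₂ efflux for this application.

C4: the enzyme-limited skeleton A = min(Vpmax·Ci/(Ci + Kp), Vcmax) − Rd.
The PEP-carboxylase initial slope Vpmax/Kp is much steeper than the C3
response, which is the operative property; bundle-sheath leakiness and
mesophyll conductance are treated as non-limiting (the carbon-concentrating
mechanism suppresses mesophyll draw-down), with an inert leakiness hook for
future use.  Default kinetic constants are representative textbook values
at 25 °C (Vcmax 60 / J 120 for C3; Vpmax 120 / Kp 80 / Vcmax 90 for C4) and
are not fits to any particular dataset; every scenario can override them.
The default C4 Vcmax ceiling is set above the PEP-limited rate over the
operating Ci range so the A–Ci response stays PEP-limited there; operating
A is stomatal-supply-limited far below that ceiling.

Coupling: A = (gs/1.6)(Ca − Ci), 1.6 the water:CO₂ stomatal diffusivity
ratio.  The intersection with the demand curve is found by bracketed Brent
root finding (residual < 10⁻⁸ µmol m⁻² s⁻¹); the bracket is expanded above
Ca when respiration dominates, and gs = 0 returns A = 0 at the internal
compensation Ci.

## Dry-down simulator

A quasi-static (steady-state-per-step) reduction of a full dynamic
soil–plant model: plant capacitance is ignored, so each soil state maps to
one operating leaf state.  The reported outputs are curves against soil
water potential, which the quasi-static model reproduces while remaining
analytically testable.  At each step Ψ_leaf solves

    K_leaf(Ψ_leaf)·(Ψ_soil − Ψ_leaf) = gs(Ψ_leaf)·VPD/Patm ·10³,

with gs = g_max / (1 + exp((Ψ_gs50 − Ψ_leaf)/c)) (sign fixed so drying
closes stomata; c > 0) and K_leaf = max(K_max − a·|Ψ_leaf|, K_floor·K_max).
Roots are located by a downward grid scan (first sign change from the soil
potential) plus Brent refinement and Newton polishing; when multiple roots
exist the wettest (highest Ψ_leaf) stable state is returned, and its
disappearance — the supply-curve maximum dropping below demand — produces
the abrupt decline characteristic of hydraulic runaway.  Transpiration
depletes a finite soil bucket (default 2000 mol m⁻² leaf) whose potential
follows the Campbell retention law Ψ_soil = Ψ_e·θ^(−b) (Ψ_e = −0.002 MPa,
b = 5); a run spans a few hundred hourly steps from field capacity to
stomatal closure (gs < 1% g_max), with a guard stop for zero-VPD runs.

Default plant types: C3 (g_max 0.32 mol m⁻² s⁻¹, K_max 8 mmol m⁻² s⁻¹
MPa⁻¹, so K_leaf:g_s = 25 mmol mol⁻¹ MPa⁻¹) and C4 (g_max 0.16, K_max 8:
twice the supply per demand, the observed C4 hydraulic hyper-efficiency).
Stomatal (Ψ_gs50 = −1.5 MPa, c = 0.15) and vulnerability (slope placing
P50 at −1.2 MPa; floor 5%) parameters are shared between pathways, which
are observed to have statistically similar P50 and turgor loss points;
pathway differences enter only through g_max and the photosynthesis
parameters.  The two VPD environments are 0.5 kPa (20 °C, RH 78.6%) and
3 kPa (30 °C, RH 29.5%) via the Tetens saturation formula.

Ratio-swap scenarios rescale K_max only: the C4-with-C3-ratio plant gets
K_max = g_max(C4)·[K:g of C3] and vice versa, so the swapped ratio is exact.
The vulnerability slope stays at the pathway's mean value (it is a measured
per-pathway constant, not a quantity the swap redefines), which makes the
low-ratio C4 swap more vulnerable in absolute terms — the mechanism behind
its steep decline and early loss of the C4 assimilation advantage at mild
drought.  An optional calibration op instead rescales K_max and slope
together (preserving P50) to hit a target operating Ψ_leaf at field
capacity.

## Phylogenetic statistics

Brownian motion on the tree gives tip covariance V[i,j] = shared
root-to-MRCA path length; Pagel's λ multiplies the off-diagonals
(diagonal untransformed).  λ is estimated by maximizing the full Gaussian
log-likelihood (σ² profiled out) on a 201-point grid over [0, 1] with
golden-section refinement; boundary maxima are reported as such unless an
interior value is within 10⁻⁶ log-likelihood, in which case the interior
value is preferred.  PGLS solves the GLS normal equations through the
Cholesky factor of V(λ̂); coefficient p-values use t statistics on n − k
degrees of freedom, and R² is measured against the phylogenetic
intercept-only model.  On a star tree (or at λ = 0 on an ultrametric tree)
PGLS reduces to OLS to numerical precision, which is tested.

Phylogenetic ANOVA is simulation-based: the observed one-way F is referred
to the F distribution of BM datasets simulated on the tree (rate estimated
from the data by the GLS quadratic form; F is scale-invariant so the rate
only matters for reporting), group labels held fixed;
p = (1 + #{F_sim ≥ F_obs}) / (n_sim + 1).  The "parametric" variant is PGLS
with a group indicator.  PRMA whitens both variables by the inverse
Cholesky factor, centers on GLS means, and takes slope = sign(r)·SD(y*)/
SD(x*).  Plain Pearson tests back the non-phylogenetic analyses.

Regressions of strictly positive traits spanning more than one order of
magnitude are log-transformed by default (`maybe_log_transform`), mirroring
the power-law character of hydraulic scaling; the rule is a package
convention and can be disabled.

## Synthetic data: what it emulates and what it does not

The generator emulates: an ultrametric Yule tree (the simplest
ultrametric branching model); C4 labels forming a requested number of
independent origins (maximal monophyletic clades, sampled by rejection over
non-nested edges); multiplicative trait structure (positive, ratio-scaled:
C3 mean × C4 fold × exp(BM) × lognormal noise); grass vein anatomy with
realistic exemplar conduit geometry in which major veins carry ≥ 98% of
K_xc; and linear vulnerability declines with Gaussian noise truncated at
zero conductance.

The default fold map is the internally consistent common-garden pattern —
g_s × 0.5 and K_leaf × 1.0, so the derived K_leaf:g_s contrast is exactly
twofold — with A_area × 1.6 and D_v × 1.8.  The meta-analysis preset
encodes the literature-compilation pattern (K_leaf × 1.4, g_s × 0.29,
K_leaf:g_s × 2.0): because each trait in a compilation is covered by a
different species subset, the published per-trait contrasts are not
row-wise consistent, so there the ratio is simulated as a primary trait
with its own fold rather than derived from the marginal K_leaf and g_s
folds.

Not emulated: within-species measurement variance structure (the lognormal
cv is a stand-in, not an estimate), trait–trait correlation beyond the
shared tree, extinction, among-lineage rate variation, or any attempt to
match the 27 real common-garden species.  Passing tests therefore show the
*code* recovers what was injected, not that real grasses satisfy the
injected magnitudes.

## Numerical choices and problem sizes

* Root finding: Brent with xtol 10⁻¹³–10⁻¹⁵ plus Newton polish in the water
  balance; supply–demand residuals are < 10⁻⁸ (typically < 10⁻¹²) at every
  reported step.
* Dry-downs use hourly steps; halving the step changes the Ψ_leaf(Ψ_soil)
  curves by < 0.02% (tested bound: 1%).
* Simulation studies run at sizes that make their Monte-Carlo error small
  relative to the asserted tolerances: 200 vulnerability replicates, 100
  PGLS slope-recovery replicates on 100-tip trees, 500 null ANOVA runs at
  n_sim = 199 on a 50-tip tree, 50 λ-recovery replicates.
* Degenerate inputs are signalled, not absorbed: constant traits (ANOVA,
  Dixon, correlation), non-declining vulnerability curves, infeasible
  series partitions, absent sheath tissue and unattainable calibration
  targets all raise typed errors.
* Determinism: every stochastic component takes a seed or Generator; the
  pipeline writes a manifest of SHA-256 checksums and identical
  config + seed reproduces identical bytes.

## Known limitations

* The dry-down model omits plant capacitance, cuticular water loss,
  stem/root embolism and leaf energy balance; simulated trajectories are
  qualitative analogues, not reproductions of any published trajectory.
* Photosynthesis kinetics are fixed at 25 °C; the two climates differ only
  through VPD.
* Pagel's λ applies to the off-diagonal covariance with untransformed
  diagonal, the standard construction for ultrametric trees; for strongly
  non-ultrametric trees λ = 0 is then weighted (not ordinary) least squares.
* Dixon critical values are embedded for α = 0.05 only.
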