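# Methods

## Scope and model assumptions

The package analyses exchange of an NMR-visible species (a JDP construct)
between a free state A and a ligand-bound state B under a single
bimolecular equilibrium. Everything downstream assumes two-state
exchange: no intermediate complexes, no cooperative or multi-site
binding, one global (k_on, k_off) shared by all residues. Where a real
system hints at more states (e.g. two binding interfaces), the two-state
parameters are effective quantities — the simplest model consistent with
dispersion plus induced-shift data.

Concentrations are molar inside the library; file and CLI boundaries use
µM, matching how such samples are reported. Residue numbering is author/
PDB numbering, 1-based, never re-indexed.

## Material balance

The bound fraction depends only on the two totals and K_d (quadratic
root). It is evaluated as `2·[JDP]t·[Hsc]t / (b + sqrt(b² − 4·[JDP]t·[Hsc]t))`
with `b = [JDP]t + [Hsc]t + K_d` — algebraically identical to the
subtracting root but free of cancellation when the bound fraction is
small, and with the correct analytic limit p → [Hsc]t/([Hsc]t + K_d) as
[JDP]t → 0 (the literal quadratic divides by [JDP]t). The discriminant is
mathematically ≥ K_d² > 0; tiny negative values from rounding are clamped
to zero. Because p_B is exact given K_d, no inner iteration is needed
inside the optimizer.

Two closed-form inverses are provided because they are how fitted numbers
are cross-checked: k_off = k_ex·K_d/(K_d + [Hsc]free) given (K_d, k_ex),
and Brent root-finding for K_d given (k_off, k_ex).

## Exchange forward models

Transverse magnetization of each ¹⁵N spin evolves under the 2×2 complex
matrix L given in the README, with the apo resonance at frequency zero
and the bound state offset by Δω. Conversions use Δω_rad = 2π · field_MHz
· 0.101329118 · Δω_ppm (the ¹⁵N/¹H gyromagnetic-ratio magnitude); the
sign of the nitrogen gyromagnetic ratio is folded into one global
convention (positive Δω = downfield bound state) since only relative
signs are identifiable from these data.

**CPMG propagation.** One echo unit is τ–180°–τ with τ = 1/(4ν_CPMG);
the refocusing pulse acts on in-phase coherence as complex conjugation.
The number of units N = 2·t_relax·ν_CPMG must be an even integer; the
generator and schedule validator snap requested ν_CPMG to the nearest
compatible value, as acquisition software does. The 2×2 matrix
exponential uses the closed form e^s(cosh q·I + sinh(q)/q·(M − sI)),
where the sinh(q)/q factor passes smoothly through eigenvalue degeneracy
(series for |q| < 1e−6), so the hot path has no degeneracy branches. The
train is applied as iterated batched matrix–vector products, vectorized
over all dispersion points of a fit. R₂,eff is extracted from the
magnitude |M_A(T)| relative to M_A(0) = 1 − p_B, consistent with
intensity-based measurement; a magnitude exceeding the start value raises
an internal consistency error.

**Closed-form oracle.** `carver_richards_r2eff(exact=True)` solves the
same train analytically: a pair of echo units is a linear map
Q = P·conj(P)·conj(P)·P on the magnetization vector, and Q^(N/2) follows
from the two eigen-projectors of Q (integer powers of complex scalars are
exact). This includes the initial-condition amplitude term that the
classic large-N asymptotic expression drops; that asymptote (available
via `exact=False`) deviates from the exact result by up to ~ln(a)/T at
the lowest ν_CPMG (N = 2), where a is the slow-mode projection of the
start vector — a property of the formula, not a numerical artifact. Tests
additionally check the propagator against an independent
scipy.linalg.expm loop and, in the fast limit, the Luz–Meiboom
expression.

**Exchange-induced shifts.** δ_ex is the imaginary part of the eigenvalue
of the free-precession L whose real part is largest (the slowly decaying,
observed line), relative to the apo frequency, converted to ppm. At exact
coalescence the eigenvalues degenerate and the mean shift is returned with
a warning. The definition is validated against a dense FID simulation:
the total transverse signal is sampled on a fine grid, its discrete-time
Fourier transform evaluated, and the spectral maximum refined by bounded
scalar optimization. The two agree to ≲0.2% in the minor-population
regime (p_B up to ~0.1, k_ex/Δω ≥ 1) where δ_ex analysis is meaningful;
for slow exchange with a large minor state the broad component genuinely
pulls the lineshape maximum away from the slow eigenvalue, and no
agreement should be expected.

## Global fit

The objective is χ² over all dispersion points, plus induced-shift terms
when enabled. Parameters: log₁₀ k_on and log₁₀ k_off (rates span decades;
bounds 1 ≤ k_on ≤ 1e10 M⁻¹s⁻¹ — the diffusion limit — and 1e−2 ≤ k_off ≤
1e6 s⁻¹), per-residue Δω in ppm shared across fields (|Δω| ≤ 30 ppm), and
log₁₀ R₂ᴬ per residue per field (no field model is imposed on R₂ᴬ).
R₂ᴮ = scale·R₂ᴬ with scale defaulting to 5. Optimization is scipy's
trust-region-reflective least squares with a structural Jacobian sparsity
pattern (each residue's parameters touch only its own residuals), which
cuts finite-difference cost by roughly the number of residues.

Initialization screens a coarse 5×5 log-spaced (k_on, k_off) grid;
per-residue guesses at each node come from the data (R₂ᴬ from the high-ν
plateau corrected for the bound-state contribution, |Δω| from the
fast-limit relation R_ex ≈ p_A p_B Δω²/k_ex, sign from δ_ex when
present), and local optimization runs from the three best nodes. The
procedure is deterministic given the data; the `seed` argument exists for
interface stability. δ_ex uncertainties default to a 0.002 ppm floor when
not provided — the relative weighting of shift and dispersion terms is
exposed rather than hard-coded, since there is no single convention.

Non-convergence returns a flagged result, not an exception. An
identifiability probe perturbs each global rate by ±0.1 decades at the
optimum; a χ² response below 0.1% of its value flags the fit
non-identifiable (the Δω = 0 pathology). Uncertainties come from the
inverse Gauss–Newton Hessian at the optimum; a singular covariance
reports absent errors. Reported K_d, k_ex, p_B and [Hsc]free all derive
from the optimum through the same material-balance code, so the identities
K_d = k_off/k_on and k_ex = k_on_app + k_off hold exactly.

The convergence grid re-optimizes all per-residue parameters at each
(k_on, k_off) node — a profile-likelihood surface. `span` is in decades;
span = 0 degenerates to re-optimizing at the optimum itself.

**R₂,eff extraction.** R₂,eff = −ln(I/I₀)/T against the reference
experiment with the relaxation period omitted. Duplicate ν_CPMG points
give the pooled duplicate-difference estimate σ = sqrt(Σd²/2m) applied to
every point of that curve; with the customary two duplicates this is a
2-degree-of-freedom estimate and individual curve weights scatter
accordingly. Non-positive intensities are dropped with a log entry.

## Ancillary calculators

**Relaxometry.** Single-exponential fits I(t) = A·e^(−Rt) with errors from
the fit covariance; replicates at equal delays are averaged first, and
negative tail points are retained. The tilt angle comes from the
spin-lock field and per-residue offset, θ = arctan(ν₁/|offset|) ∈ (0, π/2].
hetNOE = I_sat/I_ref with first-order error propagation.

**CSP significance.** Δδ_comb = sqrt(Δδ_H² + (0.2·Δδ_N)²). The trimming
loop removes values more than 3 SD above the mean and repeats until
stable; the final corrected SD is computed about zero because CSPs are
magnitudes, and the cutoff is twice it. Both centers are configurable:
the trim-about-mean / SD-about-zero combination is the default because the
two conventions in circulation differ on exactly this point, and mean-
centred trimming is the more conservative outlier test.

**Open-state populations.** In fast exchange the observed position is the
population-weighted average of the closed and open reference positions,
so p = (δ_obs − δ_closed)/(δ_open − δ_closed), clipped to [0, 1].
Residues whose reference separation is below a noise floor (default
0.05 ppm) are excluded; the aggregate is the inverse-variance-weighted
mean with per-residue variance 2σ²/(δ_open − δ_closed)². The function is
agnostic to nucleus; in practice ¹⁵N positions are used because their
open/closed separations dominate. The fast-limit inversion
k_ex = p(1−p)Δω²/R_ex is provided for placing order-of-magnitude exchange
rates from small R_ex terms; it is only meaningful when the caller has
established the fast regime.

**Hydrogen exchange.** The WEX buildup is modelled as two-pool transfer,
I(T) = A·k_obs·(e^(−R1w·T) − e^(−(R1a+k_obs)·T))/(R1a + k_obs − R1w),
with the analytic limit A·k_obs·T·e^(−R1w·T) at rate degeneracy. The
buildup determines only the overall amplitude and the rate R1a + k_obs,
so a floating amplitude makes k_obs structurally unidentifiable from one
curve; the amplitude is therefore anchored to the series' reference
(equilibrium) intensity, with a `fit_amplitude` flag for data where an
independent check exists. The water rate R1w is shared globally across
residues (one water pool): supplied, or fitted once across all series and
then fixed. Intrinsic rates k_int are supplied per residue as an input
table — computing sequence-context intrinsic rates is a separate problem
with its own reference data, deliberately out of scope — and
log P = log₁₀(1.5·k_int/k_obs); the 1.5 factor keeps fully exposed amides
at log P ≈ 0 rather than slightly negative.

**RDC.** Couplings are linear in the five Saupe components,
D = Dmax·Σ S_ij c_i c_j, solved by least squares; the design-matrix
condition number is checked (error above 1e8) because near-collinear
vector sets make the tensor meaningless. Dmax = −μ₀γ_iγ_jh/(16π³r³) from
physical constants, with r from the coordinate model per pair; the N–H
distance defaults to the conventional libration-corrected effective
1.041 Å (override available). Two-bond C′–H couplings use the
C′(i−1)–H_N(i) vector. Plain (unweighted) least squares is the default;
σ-weighting is optional. The Clore–Garrett R-factor is
100·sqrt(⟨(D_obs − D_calc)²⟩/(2⟨D_obs²⟩)); a "powder" denominator variant
(2⟨D_calc²⟩) is exposed because both conventions circulate. PDB reading:
first model, altloc '' or 'A', author numbering; mmCIF is rejected with
an explicit message.

**Fluorescence polarisation.** The isotherm is fitted with the Hill
exponent fixed at 1 (a rectangular hyperbola, as the binding model
implies); a free slope is available behind a flag. K_d is parameterized
logarithmically to stay positive. Curves with no resolvable curvature are
flagged non-identifiable rather than reported. Competition-mode data
report the raw inflection without conversion to K_i.

## Synthetic data

Generators emulate the acquisition this package targets: three fields
(600/800/950 MHz ¹H), a 40 ms constant-time CPMG delay, 12 ν_CPMG values
from 25 Hz to 1 kHz snapped to even echo counts, the first two ν values
duplicated, and 2% fractional Gaussian noise applied to intensities —
before R₂,eff conversion, so the duplicate-difference error estimator is
exercised exactly as for measured data. Binding truth defaults to
k_off = 580 s⁻¹, K_d = 380 µM at 200 µM protein + 20 µM ligand (k_ex ≈
600 s⁻¹, p_B ≈ 0.034); shift differences are drawn uniformly from
1–4 ppm with random sign, apo rates 8–20 s⁻¹ at 600 MHz with a √field
trend. HX truths span the 10–40 s⁻¹ disordered-linker regime; CSP sets
plant configurable outliers on a half-normal background; RDC couplings
come from a known tensor on seeded random unit vectors; FP curves invert
the polarisation definition at constant total intensity. Every generator
is a pure function of its seed (identical seeds give byte-identical
files) and writes a manifest sufficient to regenerate its fixture.

What the generators do *not* emulate: peak overlap and missing
assignments, field-dependent δ_ex baselines, off-resonance and pulse
imperfections in the CPMG train, correlated (non-Gaussian) plate-reader
noise, and real coordinate geometry for RDCs unless a PDB is supplied.
Passing tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to every artifact of measured
spectra.

## Numerical choices and limitations

- Quadratic root via the non-cancelling form; discriminant clamped at
  −1e−12·scale; bound fraction clipped to [0, 1].
- Eigen-degeneracy tolerances: 1e−6 (series switch in the 2×2
  exponential), 1e−9 (δ_ex coalescence warning), 1e−12 (closed-form train
  fallback).
- The classic large-N dispersion formula is kept only as an asymptotic
  reference; all fitting uses the exact propagator.
- Problem sizes in the test-suite recovery study (15 residues × 3 fields
  × 12 points × 20 seeds) were chosen as the smallest set that exercises
  the multi-field, duplicate-error pipeline while keeping the full study
  in the minutes range on one core.
- The fit assumes within-curve homoscedastic errors from the duplicate
  estimator; intensity noise actually makes R₂,eff errors grow with
  R₂,eff·T, which is visible as mildly inflated reduced χ² (~2–4) at 2%
  noise and is inherited from the standard duplicate-based protocol, not
  a defect of the optimizer.
- Out of scope by design: three-site and anti-phase/multi-quantum
  exchange models, off-resonance R₁ρ, Bayesian posterior sampling, model
  selection beyond the two-state scheme, ensemble RDC fitting, alignment
  prediction from shape, intrinsic HX rate computation, and D₂O-based
  HDX.
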