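# nmrbind

Analysis of transient protein–ligand binding by solution NMR, built around
a two-state chemical-exchange model fitted globally to ¹⁵N CPMG
relaxation-dispersion and exchange-induced-shift data under explicit
ligand material balance. The package was written for studies of J-domain
co-chaperone (JDP) constructs binding Hsc70, where reactant concentrations
are comparable and ligand depletion cannot be ignored, but the model is
generic for any bimolecular exchange observed on the NMR-visible partner.

It also bundles the calculators such a study needs around the core fit:

- **relaxometry** — R₁/R₁ρ exponential fitting with covariance errors,
  R₂ = (R₁ρ − R₁cos²θ)/sin²θ conversion, heteronuclear NOE;
- **shift analysis** — combined ¹H/¹⁵N CSPs with the iteratively corrected
  standard-deviation significance cutoff, open-state populations from
  fast-exchange peak positions, fast-limit k_ex from R_ex;
- **hydrogen exchange** — water-magnetization (WEX-type) buildup fitting
  and protection factors log P = log₁₀(1.5·k_int/k_obs);
- **RDC** — SVD fitting of the five-component alignment (Saupe) tensor
  against PDB coordinates, with the Clore–Garrett R-factor;
- **fluorescence polarisation** — P = (I∥−I⊥)/(I∥+I⊥) and the hyperbolic
  binding isotherm y = b + (t−b)/(1 + K_d/x);
- **synthetic data** — seeded generators for every observable, so the full
  pipeline is testable without measured spectra.

## The model

Binding follows the bimolecular scheme

```
JDP + Hsc  ⇌  JDP:Hsc        k_on, k_off,   K_d = k_off / k_on
```

With comparable totals, the bound fraction of the visible species is the
physical root of the material-balance quadratic

```
p_B = { [JDP]t + [Hsc]t + K_d − sqrt(([JDP]t + [Hsc]t + K_d)² − 4 [JDP]t [Hsc]t) } / 2 [JDP]t
```

which sets the free-ligand concentration [Hsc]free = [Hsc]t − p_B·[JDP]t,
the pseudo-first-order on-rate k_on_app = k_on·[Hsc]free, and the exchange
rate k_ex = k_on_app + k_off. Per-residue transverse magnetization evolves
under the 2×2 complex matrix

```
L = [ −R₂ᴬ − k_on_app      k_off            ]
    [  k_on_app           −R₂ᴮ − k_off + iΔω ]
```

CPMG profiles R₂,eff(ν_CPMG) are computed by exact propagation through
τ–180°–τ echo units (refocusing = complex conjugation); exchange-induced
shifts δ_ex are the imaginary part of the slowly decaying eigenvalue of L.
The global fit shares (k_on, k_off) across all residues, fields and
titration conditions, with per-residue Δω (ppm, field independent) and
R₂ᴬ per field; R₂ᴮ is tied to 5·R₂ᴬ by the molecular-weight ratio of
complex to free protein. Convergence is assessed by a χ² grid search
around the optimum with per-residue parameters re-optimized at each node.

## Worked example

Generate a synthetic three-field titration (15 residues, 2% intensity
noise, truth k_off = 580 s⁻¹, K_d = 380 µM at 200 µM protein + 20 µM
ligand) and refit it:

```
nmrbind synth cpmg --seed 7 --out demo
cat > demo/run.yaml <<EOF
seed: 7
grid_steps: 3
grid_span: 0.15
datasets:
  - cpmg_csv: demo/cpmg.csv
    delta_ex_csv: demo/delta_ex.csv
    jdp_total_uM: 200
    hsc_total_uM: 20
EOF
nmrbind fit-binding --config demo/run.yaml --out demo/fit.json
```

The result JSON contains the global parameters, per-residue values, the
χ² grid and a provenance block. For this seed:

```
k_on  = 1.51e+06 /M/s ± 5.8e+03
k_off = 574.1 /s ± 8.2
K_d   = 379.0 uM
k_ex  = 594.2 /s   p_bound = 0.0338   hsc_free = 13.25 uM
chi2 = 2113.0 over n = 555
```

i.e. the dissociation rate and affinity are recovered within ~1% of the
generating truth, and the derived exchange rate at this sample composition
is ~600 s⁻¹ — the regime where dispersion amplitudes are large but
exchange-induced shifts stay small. The same library calls are available
directly in Python (`nmrbind.fit_global`, `nmrbind.binding_state`, …);
other subcommands (`fit-relax`, `csp`, `open-pop`, `hx`, `rdc`, `fp`)
wrap the remaining modules.

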