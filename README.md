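# exflex

Binding kinetics from exchange NMR line shapes, and conformational
flexibility from trajectory clustering — for macrocycle–receptor complexes.

## The problem

Macrocyclization is a standard way to pre-organize a peptide into its
bioactive conformation, and its effect on affinity is usually discussed in
equilibrium terms. But the *kinetics* matter too: the residence time of a
bound ligand (1/k_off) tracks pharmacological efficacy, and for closely
related macrocycles binding the adaptor protein 14-3-3ζ the dissociation
rates differ several-fold while the thermodynamic profiles look similar.
Linking those rate differences to the conformational flexibility of the
bound complex requires three computations that this package implements as
one tested pipeline:

1. **Line-shape kinetics** — a ligand in slow exchange between free and
   bound states shows two ¹⁹F resonances; the free line is exchange-broadened
   by the pseudo-first-order rate k_off·p_b/(1−p_b). Fitting the free
   resonance across a titration with the steady-state two-site
   Bloch–McConnell shape, I(ω) = Re[1ᵀA(ω)⁻¹p] with A(ω) = diag(R2 + i(ω−ω_s))
   + K, yields k_off and its standard error.
2. **Thermodynamic/kinetic closure** — the single-site binding quadratic
   gives p_b from total concentrations and K_d; k_on = k_off/K_d; ΔG = RT ln
   K_d; −TΔS = ΔG − ΔH.
3. **Ensemble flexibility** — trajectory frames are Kabsch-superposed,
   clustered at a 2 Å RMSD cutoff (leader algorithm), and the cluster
   populations give the conformational entropy S_conf = −RT Σ p_i ln p_i
   (kcal/mol, 300 K), decomposed into complex / ligand / receptor terms;
   per-atom RMSF is computed for ligand main-chain and crosslink atoms in
   the receptor frame.

A synthetic-data module generates titrations and Markov-state conformer
ensembles with known ground truth, so every stage is verified by parameter
recovery; a three-complex benchmark ties the stages together and reproduces
the measured orderings (slower dissociation ↔ more flexible complex).

## Worked example

```python
import numpy as np
from exflex import fit_koff, initial_guess, generate_titration, k_on_from
from exflex.benchmark import spectra_scenario

scn = spectra_scenario("L", seed=1, noise_sd=0.0)   # K_d = 0.65 uM, k_off* = 0.89 1/s
series = generate_titration(scn)                    # 5 spectra, p_b from 0 to 0.87
fit = fit_koff(series, initial_guess(series))
print(f"k_off = {fit.k_off_hat:.4f} s^-1")
print(f"k_on  = {k_on_from(fit.k_off_hat, scn.K_d_true):.3e} /M/s")
print("free-line widths (Hz):", np.round(fit.widths_hz, 2))
```

prints

```
k_off = 0.8901 s^-1
k_on  = 1.369e+06 /M/s
free-line widths (Hz): [5.   5.07 5.18 5.58 6.83]
```

The fitted k_off recovers the generating value (0.89 s⁻¹) to 0.01%, the
implied association rate matches k_off/K_d, and the fitted free-line width
grows from the intrinsic 5 Hz to ~6.8 Hz as the fraction bound rises to
0.87 — the exchange broadening the fit inverts.

The same workflow is available from the shell:

```bash
exflex demo --out demo/ --seed 0        # full three-complex benchmark
exflex fit-koff --manifest series.yaml --out fit.json
exflex flex --traj traj.pdb --cutoff 2.0 --temp 300 --out report.json
exflex report --thermo thermo.csv --kinetics fit.json --flex report.json --out summary.json
```

`exflex demo` prints the benchmark summary table — fitted k_off per complex
(truth 0.89/1.58/0.45 s⁻¹ for L/MC18/MC22), the recomputed k_on, the
entropy decomposition (receptor term ≈ 0 by construction) — and the Pearson
correlation between S_conf and k_off, which is strongly negative: the most
flexible complex dissociates slowest.

## Layout

| module | contents |
|---|---|
| `exflex.binding` | binding quadratic, ΔG/−TΔS bookkeeping, k_on closure, thermo CSV I/O |
| `exflex.lineshape` | Bloch–McConnell simulator, FWHM, titration k_off fit |
| `exflex.synthetic` | titration and Markov-ensemble generators with ground truth |
| `exflex.trajflex` | superposition, RMSD clustering, S_conf, RMSF |
| `exflex.report` | summary join, mismatch flags, S_conf–k_off association |
| `exflex.benchmark` | three-complex synthetic benchmark, end-to-end runner |
| `exflex.io` | TSV spectra, multi-model PDB / XYZ trajectories, YAML sidecars |
| `exflex.cli` | `exflex` command group |

See `docs/methods.md` for the models, defaults, numerical choices, and known
limitations (including one documented information-limited recovery case).
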