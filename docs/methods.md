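# Methods

`exflex` links three measurements that together characterize how a
macrocyclic peptide binds its receptor: equilibrium affinity (ITC-derived
K_d), dissociation kinetics (ligand-observed ¹⁹F NMR line shapes), and
bound-state conformational flexibility (clustering entropy and RMSF of a
conformer ensemble). This note records the models, the defaults and why they
were chosen, and what the synthetic benchmark does and does not demonstrate.

## Binding model

Binding is treated as a single-site equilibrium. The receptor (a 14-3-3ζ
homodimer) is modelled as two independent, equivalent sites, so all receptor
concentrations in the package are *site* concentrations (twice the dimer
concentration); this matches the convention of reporting a single K_d per
ligand. With total ligand L, total sites P and dissociation constant K_d, the
fraction of ligand bound is the exact root of the mass-balance quadratic,
evaluated in the rationalized form p_b = 2P / (b + √(b² − 4LP)), b = L + P +
K_d, which is numerically stable when K_d is many orders of magnitude below
the totals (sub-µM K_d against tens-of-µM concentrations).

Free energies use ΔG° = RT ln(K_d / 1 M) with R = 1.98720425×10⁻³
kcal mol⁻¹ K⁻¹, natural logarithm, 1 M standard state, and a default
temperature of 298.15 K (a config field; the measurement temperature is not
part of the inputs). The kinetic closure is k_on = k_off / K_d and the
residence time is 1/k_off.

The reference thermodynamic table for the ligand L carries ΔH and −TΔS values
whose sum (−10.22 kcal/mol) disagrees with RT ln K_d at 298.15 K
(−8.44 kcal/mol). The package does not attempt to reconcile this (the
temperature or rounding convention behind the reported values is not
recoverable); `build_summary` computes both and emits a flag whenever
ΔH + (−TΔS) and RT ln K_d differ by more than 2%.

## Two-site exchange line shape

A ligand exchanging between free and bound environments gives the
steady-state Bloch–McConnell absorption spectrum

    I(ω) = Re[ 1ᵀ A(ω)⁻¹ p ],  A(ω) = diag(R2f + i(ω−ω_f), R2b + i(ω−ω_b)) + K

with populations p = (1−p_b, p_b) and exchange matrix K = [[k_fb, −k_off],
[−k_fb, k_off]], k_fb = k_off·p_b/(1−p_b) (detailed balance, K p = 0). The
2×2 inverse is evaluated in closed form, vectorized over the axis, so a
2048-point spectrum costs microseconds. Frequencies are offset Hz relative to
the carrier; the absolute field never enters. The integral of I over ω
(rad/s) equals π independently of k_off — conservation of total
magnetization — which is used as a correctness invariant.

In slow exchange (2π·Δδ ≫ k_ex) the free line is exchange-broadened by k_fb:
FWHM_free = (R2f + k_off·p_b/(1−p_b))/π. This is the physical content that a
titration-wide fit extracts.

### Dissociation-rate fitting

`fit_koff` fits the free-resonance window of every titration point jointly:

* shared parameters (log k_off, δ_free, log R2_free) — the log
  parameterizations enforce positivity;
* per-point amplitude and constant baseline, solved linearly at every
  iteration (variable projection), so the nonlinear problem stays
  3-dimensional (plus optional per-point logit-p_b when co-fitting is
  requested);
* p_b fixed per point from concentrations and K_d by default (co-fitting is a
  flag, off by default, because the concentrations are known in a designed
  titration);
* δ_bound and R2_bound held at their initial-guess values: in slow exchange
  they influence the free window only through the exchange terms, and across
  a titration the bound linewidth carries no k_off information (R2b + k_off
  is constant), so co-fitting them would only add variance;
* residuals whitened per spectrum with a noise estimate from the robust MAD
  of first differences — the noise floor varies across titration points
  because it scales with each spectrum's maximum, and unwhitened residuals
  down-weight exactly the most informative high-p_b points;
* standard error of k_off from the Jacobian-based covariance at the solution.

The default fit window is ±45% of |Δδ| around the free shift (clipped to the
common axis), which excludes the bound peak; when the bound peak lies outside
the window it is represented only through the exchange terms. An analytic
fast path — weighted linear regression of π·FWHM_i on p_b_i/(1−p_b_i), slope
= k_off, intercept = R2_free — provides the initializer and a cross-check.
Trust-region least squares (`scipy.optimize.least_squares`) does the
minimization.

Degenerate inputs are rejected explicitly: a series whose p_b are all ≈0
leaves k_off unidentifiable; p_b = 1 with k_off > 0 has no free-state
lifetime; non-overlapping axes cannot be fit jointly.

## Conformational flexibility

Frames are superposed by iterated Kabsch alignment onto the running mean
structure of a selection (convergence: mean-structure shift < 10⁻⁶ Å). The
clustering distance is pair-optimal RMSD. Clustering is leader-style by
default: the first frame seeds cluster 0 and every subsequent frame joins the
lowest-id cluster whose *seed* lies within the cutoff (2 Å default), else
seeds a new cluster. The implementation sweeps vectorized passes (assign all
frames within the cutoff of the current seed, then let the first unassigned
frame seed the next cluster), which provably reproduces the sequential
first-seed-within-cutoff assignment at O(n_frames × n_clusters) cost.
Single- and average-linkage clustering on the full pairwise RMSD matrix are
available for sensitivity analysis on small ensembles. Leader clustering is
order-dependent by construction; this is documented, deterministic behaviour.

Conformational entropy is the temperature-weighted Shannon entropy of the
cluster populations, S_conf = −RT Σ p_i ln p_i in kcal/mol at T = 300 K
(default, configurable), with 0·ln 0 ≡ 0. It is bounded by RT ln(number of
clusters) and invariant under label permutation; merging clusters can only
decrease it. Three independent computations are reported: the full complex,
the ligand alone, and the receptor alone — the total is *not* the sum of the
parts, so all three are exposed.

Default distance atoms: ligand main-chain (N, CA, C, O) plus crosslink
carbons; receptor Cα; complex = union. When an ensemble carries no
recognizable atom names the selection falls back to all atoms of the group.
RMSF is computed per atom as √⟨‖r_a(t) − ⟨r_a⟩‖²⟩ for ligand main-chain and
crosslink atoms *after superposition on the receptor selection*, so ligand
RMSF measures motion relative to the receptor frame.

## Synthetic data: what it emulates, and what it does not

**Titrations.** One spectrum per receptor concentration, computed by the
exchange simulator at the exact p_b implied by the binding quadratic, plus
i.i.d. Gaussian noise with sd = noise_sd × (that spectrum's noiseless
maximum). Default conditions describe a realistic ligand-observed ¹⁹F
titration: 50 µM ligand; receptor sites at 0, 10, 20, 35 and 47.5 µM (p_b
from ~0 to ~0.87–0.92 depending on K_d, with a ligand-only reference point
anchoring the free linewidth); free linewidth 5 Hz (R2f = 15.7 s⁻¹), typical
of a small CF₃-labelled peptide; 2048 points spanning both resonances with
100 Hz margins. The generator does not emulate time-domain artefacts (FID
truncation, apodization, phase error), field drift, or scalar coupling.

**Ensembles.** A discrete-state first-order Markov chain over rigid conformer
templates with i.i.d. Gaussian jitter per coordinate (scalar, per-atom, or
per-coordinate sd). The chain stays put with probability s (default 0.95)
and otherwise redraws from the stationary populations, so the stationary
distribution equals the specified populations exactly for any s while the
trajectory has state autocorrelation, as real MD snapshot series do. The
realized state sequence and all scenario parameters are emitted as ground
truth alongside the data, so recovery tests never re-derive the truth. The
generator does not emulate force-field physics: no solvent, no sterics, no
continuous transition paths, no within-state anharmonicity. Passing recovery
tests therefore demonstrates the correctness of the *analysis chain*
(clustering, entropy, RMSF, fitting), not the realism of any dynamics.

## Three-complex benchmark

The benchmark builds one scenario per ligand (L, MC18, MC22) in which the
ground-truth kinetics and the bound-ligand state multiplicity co-vary the way
the measurements do: k_off = 0.89/1.58/0.45 s⁻¹ and K_d = 0.65/0.36/0.11 µM;
free/bound shift separations 350/175/598 Hz spanning the observed 175–598 Hz
range; bound-state R2 from the measured bound linewidths (π·ν₀.₅ =
105.2/105.9/39.0 s⁻¹); ligand state populations (0.5, 0.3, 0.2) for L,
(0.65, 0.35) for MC18, (0.4, 0.3, 0.2, 0.1) for MC22 on a rigid shared
receptor.

Geometry: the receptor is a compact 40-Cα four-helix-bundle trace — globular,
so rigid-body superposition on it is well-conditioned about every axis (a
thin elongated receptor would leave one rotational degree of freedom poorly
constrained and leak alignment noise into ligand RMSF). The ligand is an
8-residue main-chain trace across the bundle groove bridged by 6 crosslink
carbons. Conformer states displace the mobile region (terminal four residues
plus crosslink) by fixed random per-atom patterns of 10 Å RMS amplitude;
random patterns are used because rigid-body superposition cannot absorb
them, keeping every inter-state RMSD (≥ 5 Å on every selection) far above
both the 2 Å cutoff and the jitter spread (0.1 Å per coordinate).

Benchmark ensembles use stickiness 0.5 (state lifetime ≈ 2 frames = 40 ps at
the 20 ps frame interval — fast conformational hopping), chosen so that
20 000 frames give an effective sample size of ≈ 6700 independent state
draws and population estimates sit several standard errors inside a 2%
entropy-recovery band; the general-purpose generator default remains 0.95.
Problem sizes used throughout the tests and the acceptance script — 20 000
frames for entropy recovery, 50 000 for RMSF, 50 noise seeds per titration
scenario — are the package's chosen study scale.

Absolute entropies from the benchmark (tenths of kcal/mol for 2–4 states)
are intentionally *not* comparable to the measured values for the real
complexes (several kcal/mol, from microsecond force-field trajectories with
hundreds of accessible clusters); only orderings, decompositions and
recovery errors are meaningful, and only those are asserted.

## Known limitations

* The noise-robustness recovery target (median k_off error ≤ 5% at SNR 50
  with 5 titration points) is met for the L- and MC18-like scenarios but not
  for the MC22-like one (k_off = 0.45 s⁻¹, K_d = 0.11 µM, 12.4 Hz bound
  line): a Cramér–Rao analysis at those conditions shows the bound on the
  k_off error exceeds the target even for an estimator with every nuisance
  parameter known, because the near-stoichiometric titration leaves the free
  peak at ~8% of the spectrum maximum at the top point while k_off produces
  at most ~1.7 Hz of exchange broadening on a 5 Hz line. The implemented
  estimator tracks the bound (it is efficient); the corresponding check is
  left failing as a documented information limit of those study conditions.
* Leader clustering is order-dependent; linkage methods are provided for
  sensitivity analysis but are O(n²) in frames.
* The entropy convention (Shannon entropy of cluster populations × RT) is a
  declared choice; other conventions (quasi-harmonic, Schlitter) are out of
  scope.
* With three complexes the S_conf–k_off association is descriptive;
  coefficients are computed but no p-value is reported for n < 5.
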