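"""Synthetic spectra and conformer ensembles with known ground truth.

Every downstream stage of the pipeline (line-shape fitting, clustering,
entropy, RMSF) is validated by parameter recovery against data produced here,
so the ground truth is always emitted alongside the data (in ``meta`` /
sidecar YAML) rather than re-derived.

Spectra: slow-exchange two-site titrations.  The fraction bound at each
receptor concentration follows the single-site binding quadratic, the
noiseless line shape comes from the exchange simulator at exactly that p_b,
and i.i.d. Gaussian noise with sd = ``noise_sd`` x (noiseless maximum of that
spectrum) is added per point.

Ensembles: a discrete-state first-order Markov chain over rigid conformer
templates with i.i.d. Gaussian jitter per coordinate.  The chain is sticky —
it remains in its current state with probability ``markov_stickiness`` and
otherwise redraws from the stationary populations — so trajectories have
state autocorrelation as real MD snapshots do, while the stationary
distribution equals ``state_populations`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import fraction_bound
from .lineshape import ExchangeSystem, Spectrum, TitrationSeries, simulate_spectrum
from .trajflex import ConformerTrajectory, DEFAULT_FRAME_INTERVAL_PS, GROUPS

MIN_POINTS = 64


@dataclass
class SpectraScenario:
    """Ground-truth description of one synthetic 19F titration.

    Concentrations are mol/L (receptor concentrations are *site*
    concentrations), shifts Hz, rates s^-1.  ``noise_sd`` is a fraction of
    each spectrum's noiseless maximum.  The defaults describe a typical
    ligand-observed titration: 50 uM ligand, receptor sites titrated from 0
    to near-saturating, sub-uM K_d.
    """

    delta_free: float = 0.0
    delta_bound: float = 350.0
    r2_free: float = 15.7
    r2_bound: float = 105.9
    k_off_true: float = 0.89
    K_d_true: float = 0.65e-6
    ligand_total: float = 50e-6
    receptor_site_totals: tuple = (0.0, 10e-6, 20e-6, 35e-6, 47.5e-6)
    noise_sd: float = 0.02
    axis_min: float | None = None
    axis_max: float | None = None
    n_points: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        lo = min(self.delta_free, self.delta_bound)
        hi = max(self.delta_free, self.delta_bound)
        if self.axis_min is None:
            self.axis_min = lo - 100.0
        if self.axis_max is None:
            self.axis_max = hi + 100.0
        if self.n_points < MIN_POINTS:
            raise ValueError(f"n_points must be >= {MIN_POINTS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for attr in ("r2_free", "r2_bound", "K_d_true", "ligand_total"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if self.k_off_true < 0:
            raise ValueError("k_off_true must be >= 0")
        if any(c < 0 for c in self.receptor_site_totals):
            raise ValueError("receptor site concentrations must be >= 0")
        if not (self.axis_min <= lo and self.axis_max >= hi):
            raise ValueError(
                "axis does not cover both resonances: the line shape would be truncated"
            )

    def fractions_bound(self) -> np.ndarray:
        """Ground-truth p_b at every titration point."""
        return np.array(
            [
                fraction_bound(self.ligand_total, p, self.K_d_true)
                for p in self.receptor_site_totals
            ]
        )


def generate_titration(scenario: SpectraScenario) -> TitrationSeries:
    """Simulate one titration series with ground truth in ``meta``.

    Each spectrum is the exchange simulator's line shape at the exact p_b
    implied by (ligand_total, receptor_site_total, K_d_true), plus Gaussian
    noise scaled to that spectrum's noiseless maximum.  Deterministic given
    ``scenario.seed``; with ``noise_sd=0`` the output is bit-identical to the
    simulator's.
    """
    rng = np.random.default_rng(scenario.seed)
    axis = np.linspace(scenario.axis_min, scenario.axis_max, scenario.n_points)
    p_b = scenario.fractions_bound()
    spectra = []
    for pb in p_b:
        sys = ExchangeSystem(
            delta_free=scenario.delta_free,
            delta_bound=scenario.delta_bound,
            r2_free=scenario.r2_free,
            r2_bound=scenario.r2_bound,
            k_off=scenario.k_off_true,
            p_b=float(pb),
        )
        clean = simulate_spectrum(sys, axis)
        if scenario.noise_sd > 0:
            noise = rng.normal(0.0, scenario.noise_sd * clean.intensity.max(), axis.size)
            spectra.append(Spectrum(axis=axis, intensity=clean.intensity + noise))
        else:
            spectra.append(clean)
    return TitrationSeries(
        spectra=spectra,
        p_b=p_b,
        ligand_total=scenario.ligand_total,
        receptor_site_totals=np.asarray(scenario.receptor_site_totals, dtype=float),
        meta={"scenario": scenario, "k_off_true": scenario.k_off_true},
    )


@dataclass
class EnsembleScenario:
    """Ground-truth description of one synthetic conformer ensemble.

    ``state_templates``: (n_states, n_atoms, 3) rigid coordinate sets in A,
    identical atom count and ordering.  ``jitter_sd`` is the Gaussian sd per
    coordinate in A — a scalar, per-atom (n_atoms,), or per-coordinate
    (n_atoms, 3) array.  ``markov_stickiness`` is the probability of staying
    in the current state at each step.
    """

    state_templates: np.ndarray
    state_populations: np.ndarray
    atom_groups: np.ndarray
    atom_names: np.ndarray | None = None
    jitter_sd: float | np.ndarray = 0.1
    n_frames: int = 20_000
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS
    markov_stickiness: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_templates = np.asarray(self.state_templates, dtype=float)
        self.state_populations = np.asarray(self.state_populations, dtype=float)
        if self.state_templates.ndim != 3 or self.state_templates.shape[2] != 3:
            raise ValueError(
                "state_templates must be (n_states, n_atoms, 3); templates with "
                "mismatched atom counts cannot form a scenario"
            )
        n_states, n_atoms, _ = self.state_templates.shape
        if self.state_populations.shape != (n_states,):
            raise ValueError("one population per template state required")
        if np.any(self.state_populations < 0) or abs(self.state_populations.sum() - 1.0) > 1e-9:
            raise ValueError("state_populations must be >= 0 and sum to 1 (tol 1e-9)")
        if not 0.0 <= self.markov_stickiness < 1.0:
            raise ValueError("markov_stickiness must be in [0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        self.atom_groups = np.asarray(self.atom_groups, dtype=object)
        if self.atom_groups.shape != (n_atoms,):
            raise ValueError("one group label per atom required")
        if set(self.atom_groups) - set(GROUPS):
            raise ValueError(f"atom groups must be among {GROUPS}")
        if self.atom_names is None:
            self.atom_names = np.array([f"X{i}" for i in range(n_atoms)], dtype=object)
        else:
            self.atom_names = np.asarray(self.atom_names, dtype=object)
        jit = np.asarray(self.jitter_sd, dtype=float)
        if np.any(jit < 0):
            raise ValueError("jitter_sd must be >= 0")
        # broadcast to per-coordinate (n_atoms, 3)
        if jit.ndim == 0:
            jit = np.full((n_atoms, 3), float(jit))
        elif jit.shape == (n_atoms,):
            jit = np.repeat(jit[:, None], 3, axis=1)
        elif jit.shape != (n_atoms, 3):
            raise ValueError("jitter_sd must be scalar, (n_atoms,), or (n_atoms, 3)")
        self.jitter_sd = jit

    @property
    def n_states(self) -> int:
        return self.state_templates.shape[0]


def _markov_states(rng, populations, stickiness, n_frames) -> np.ndarray:
    """Sticky chain: stay w.p. s, else redraw from ``populations``.

    Transition matrix T = s*I + (1-s)*1 pi^T has stationary distribution pi
    for any s in [0, 1); the chain starts in pi so it is stationary from t=0.
    """
    draws = rng.choice(populations.size, size=n_frames, p=populations)
    stay = rng.random(n_frames) < stickiness
    states = np.empty(n_frames, dtype=int)
    states[0] = draws[0]
    for t in range(1, n_frames):
        states[t] = states[t - 1] if stay[t] else draws[t]
    return states


def generate_ensemble(scenario: EnsembleScenario) -> ConformerTrajectory:
    """Draw a trajectory from the scenario's Markov chain + Gaussian jitter.

    Deterministic given ``scenario.seed``.  The realized state sequence and
    the full scenario ride along in ``meta`` as ground truth.
    """
    rng = np.random.default_rng(scenario.seed)
    states = _markov_states(
        rng, scenario.state_populations, scenario.markov_stickiness, scenario.n_frames
    )
    coords = scenario.state_templates[states]
    jitter = rng.standard_normal(coords.shape) * scenario.jitter_sd[None, :, :]
    return ConformerTrajectory(
        coords=coords + jitter,
        atom_names=scenario.atom_names,
        atom_groups=scenario.atom_groups,
        frame_interval_ps=scenario.frame_interval_ps,
        meta={
            "scenario": scenario,
            "states": states,
            "state_populations": scenario.state_populations.copy(),
        },
    )
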