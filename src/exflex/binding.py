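"""Single-site binding thermodynamics and the kinetic closure k_on = k_off / K_d.

The receptor (the 14-3-3 zeta homodimer) is modelled as independent, equivalent
sites, so every "receptor concentration" in this package is a *site*
concentration (twice the dimer concentration).  With total ligand ``L``, total
sites ``P`` and dissociation constant ``K_d``, the equilibrium fraction of
ligand bound follows the single-site mass-balance quadratic

    p_b = (L + P + K_d - sqrt((L + P + K_d)^2 - 4 L P)) / (2 L)

evaluated here in the numerically stable rationalized form
``p_b = 2 P / (b + sqrt(b^2 - 4 L P))`` with ``b = L + P + K_d``, which avoids
catastrophic cancellation when K_d is orders of magnitude below the totals.

Free energies use the 1 M standard state and the natural logarithm:
``dG = R T ln(K_d / 1 M)`` with R in kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K = 1.98720425e-3

#: Default temperature (K) for free-energy conversions when none is given.
DEFAULT_TEMPERATURE_K = 298.15

THERMO_CSV_COLUMNS = ["name", "Kd_M", "dH_kcal_mol", "minus_TdS_kcal_mol", "T_K"]


@dataclass(frozen=True)
class BindingThermo:
    """Thermodynamic record for one ligand-receptor pair.

    All energies in kcal/mol; K_d in mol/L.  ``dG`` is checked against
    ``dH + minus_TdS`` when all three are present.
    """

    name: str
    K_d: float
    dH: float | None = None
    minus_TdS: float | None = None
    dG: float | None = None
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.K_d > 0:
            raise ValueError(f"K_d must be > 0, got {self.K_d}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.dG is not None and self.dH is not None and self.minus_TdS is not None:
            if abs(self.dG - (self.dH + self.minus_TdS)) > 1e-9:
                raise ValueError(
                    "inconsistent thermodynamics: dG != dH + (-TdS) "
                    f"({self.dG} vs {self.dH + self.minus_TdS})"
                )

    @property
    def dG_from_Kd(self) -> float:
        """Free energy implied by K_d at this record's temperature."""
        return delta_G(self.K_d, self.temperature)


@dataclass(frozen=True)
class RateSet:
    """Kinetic rates for one ligand-receptor pair.

    k_off in s^-1, k_on in s^-1 M^-1, residence time (1/k_off) in s.
    """

    k_off: float
    k_on: float
    residence_time: float
    k_off_err: float = 0.0

    @classmethod
    def from_koff(cls, k_off: float, K_d: float, k_off_err: float = 0.0) -> "RateSet":
        k_on = k_on_from(k_off, K_d)
        residence = math.inf if k_off == 0 else 1.0 / k_off
        return cls(k_off=k_off, k_on=k_on, residence_time=residence, k_off_err=k_off_err)


def fraction_bound(ligand_total, receptor_sites_total, K_d):
    """Equilibrium fraction of ligand bound, p_b, for 1:1 site binding.

    Exact root of the mass-balance quadratic; accepts scalars or arrays
    (broadcast).  ``ligand_total`` must be > 0 (the fraction is undefined for
    zero ligand); ``receptor_sites_total`` >= 0; ``K_d`` > 0.
    """
    L = np.asarray(ligand_total, dtype=float)
    P = np.asarray(receptor_sites_total, dtype=float)
    Kd = np.asarray(K_d, dtype=float)
    if np.any(L <= 0):
        raise ValueError("ligand_total must be > 0 (fraction bound undefined)")
    if np.any(P < 0):
        raise ValueError("receptor_sites_total must be >= 0")
    if np.any(Kd <= 0):
        raise ValueError("K_d must be > 0")
    b = L + P + Kd
    disc = np.sqrt(b * b - 4.0 * L * P)
    # Rationalized root: 2P/(b + disc) == (b - disc)/(2L), stable for small Kd.
    p_b = 2.0 * P / (b + disc)
    p_b = np.clip(p_b, 0.0, 1.0)
    if p_b.ndim == 0:
        return float(p_b)
    return p_b


def k_on_from(k_off, K_d):
    """Association rate from the kinetic closure k_on = k_off / K_d."""
    k_off = np.asarray(k_off, dtype=float)
    Kd = np.asarray(K_d, dtype=float)
    if np.any(Kd <= 0):
        raise ValueError("K_d must be > 0")
    if np.any(k_off < 0):
        raise ValueError("k_off must be >= 0")
    out = k_off / Kd
    return float(out) if out.ndim == 0 else out


def delta_G(K_d, temperature: float = DEFAULT_TEMPERATURE_K):
    """Standard binding free energy dG = R T ln(K_d / 1 M), kcal/mol."""
    Kd = np.asarray(K_d, dtype=float)
    if np.any(Kd <= 0):
        raise ValueError("K_d must be > 0")
    if not temperature > 0:
        raise ValueError("temperature must be > 0 K")
    out = R_KCAL_PER_MOL_K * temperature * np.log(Kd)
    return float(out) if out.ndim == 0 else out


def entropy_term(dG, dH):
    """Entropic contribution -T dS = dG - dH (kcal/mol)."""
    out = np.asarray(dG, dtype=float) - np.asarray(dH, dtype=float)
    return float(out) if out.ndim == 0 else out


def read_thermo_csv(path) -> pd.DataFrame:
    """Read a thermodynamics table (name, Kd_M, dH_kcal_mol, minus_TdS_kcal_mol, T_K)."""
    df = pd.read_csv(path)
    missing = [c for c in ("name", "Kd_M") if c not in df.columns]
    if missing:
        raise ValueError(f"thermo CSV missing required columns: {missing}")
    for col in THERMO_CSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["T_K"] = df["T_K"].fillna(DEFAULT_TEMPERATURE_K)
    return df[THERMO_CSV_COLUMNS]


def write_thermo_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def reference_ligand_table() -> pd.DataFrame:
    """Published measurements for the 14-3-3 zeta / ExoS-derived ligand system.

    One row per ligand: the linear 11-mer epitope (L) and its two macrocycles
    with 18- and 22-atom crosslinks (MC18, MC22).  Columns: ITC dissociation
    constant; calorimetric enthalpy and entropy terms where individually
    reported (for the macrocycles only the entropy term and the fold-reduction
    of dH relative to L were reported); NMR dissociation rate; bound-state
    19F linewidth; and MD-derived conformational entropy of the complex.
    These are measured inputs to downstream calculations, not quantities this
    package can recompute from scratch.
    """
    return pd.DataFrame(
        {
            "name": ["L", "MC18", "MC22"],
            "Kd_M": [0.65e-6, 0.36e-6, 0.11e-6],
            "dH_kcal_mol": [-9.81, np.nan, np.nan],
            "minus_TdS_kcal_mol": [-0.41, -3.75, -4.34],
            "dH_fold_reduction_vs_L": [np.nan, 1.9, 1.8],
            "k_off_s": [0.89, 1.58, 0.45],
            "nu_half_Hz": [33.5, 33.7, 12.4],
            "S_conf_kcal_mol": [6.6, 6.4, 7.5],
            "T_K": [DEFAULT_TEMPERATURE_K] * 3,
        }
    )
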