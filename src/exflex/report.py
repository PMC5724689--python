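"""Join kinetics, thermodynamics and flexibility into per-complex summaries
and compute the S_conf vs k_off association."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binding import DEFAULT_TEMPERATURE_K, delta_G, k_on_from

#: relative disagreement above which a supplied derived value is flagged
MISMATCH_TOL = 0.02


@dataclass
class ComplexSummary:
    """One ligand-receptor complex: affinity, kinetics, flexibility."""

    name: str
    K_d: float | None = None  # mol/L
    dH: float | None = None  # kcal/mol
    minus_TdS: float | None = None
    dG: float | None = None
    k_off: float | None = None  # s^-1
    k_off_err: float | None = None
    k_on: float | None = None  # s^-1 M^-1
    residence_time: float | None = None  # s
    nu_half: float | None = None  # Hz
    S_conf_total: float | None = None  # kcal/mol
    S_conf_ligand: float | None = None
    S_conf_receptor: float | None = None
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.k_on is not None and self.k_off is not None and self.K_d is not None:
            if abs(self.k_on * self.K_d - self.k_off) > 1e-9 * max(abs(self.k_off), 1e-300):
                raise ValueError(
                    f"{self.name}: k_on * K_d != k_off "
                    f"({self.k_on * self.K_d} vs {self.k_off})"
                )


@dataclass
class CorrelationResult:
    """Descriptive association between S_conf and k_off across complexes.

    ``slope``/``intercept`` are the least-squares line of k_off on S_conf;
    ``slope_log``/``intercept_log`` the same for ln k_off (both are emitted
    because either axis convention is defensible for a rate).  No p-value is
    reported for n < 5: with so few complexes significance is not meaningful.
    """

    pearson_r: float
    spearman_rho: float
    n: int
    slope: float
    intercept: float
    slope_log: float
    intercept_log: float
    note: str | None = None

    def __post_init__(self) -> None:
        for r in (self.pearson_r, self.spearman_rho):
            if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValueError("correlation coefficients must lie in [-1, 1]")


def correlate(summaries: list[ComplexSummary]) -> CorrelationResult:
    """Pearson/Spearman association of k_off with S_conf_total (n >= 3)."""
    pairs = [
        (s.S_conf_total, s.k_off)
        for s in summaries
        if s.S_conf_total is not None and s.k_off is not None
    ]
    if len(pairs) < 3:
        raise ValueError("correlate needs >= 3 complexes with both S_conf and k_off")
    s_conf = np.array([p[0] for p in pairs])
    k_off = np.array([p[1] for p in pairs])
    pear = float(stats.pearsonr(s_conf, k_off).statistic)
    spear = float(stats.spearmanr(s_conf, k_off).statistic)
    slope, intercept = np.polyfit(s_conf, k_off, 1)
    slope_l, intercept_l = np.polyfit(s_conf, np.log(k_off), 1)
    note = None
    if len(pairs) == 3:
        note = "n = 3: coefficients are descriptive only; significance is not meaningful"
        warnings.warn(note, stacklevel=2)
    return CorrelationResult(
        pearson_r=pear,
        spearman_rho=spear,
        n=len(pairs),
        slope=float(slope),
        intercept=float(intercept),
        slope_log=float(slope_l),
        intercept_log=float(intercept_l),
        note=note,
    )


def _rel_diff(a: float, b: float) -> float:
    denom = max(abs(a), abs(b), 1e-300)
    return abs(a - b) / denom


def build_summary(
    thermo: pd.DataFrame,
    kinetics: dict[str, dict] | None = None,
    flex: dict[str, dict] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Join thermodynamics, fitted kinetics and flexibility into one table.

    Parameters
    ----------
    thermo
        Frame with at least (name, Kd_M); optional dH_kcal_mol,
        minus_TdS_kcal_mol, T_K, nu_half_Hz.
    kinetics
        name -> dict with ``k_off_hat`` (s^-1) and optionally ``k_off_se``,
        ``k_on`` (any supplied k_on/dG is cross-checked, not trusted).
    flex
        name -> dict with S_conf_total/S_conf_ligand/S_conf_receptor
        (kcal/mol), e.g. ``FlexReport.to_dict()``.

    Returns the joined table plus a list of human-readable mismatch flags for
    supplied derived values that disagree with recomputation by more than 2%
    (including the dG-vs-dH+(-TdS) consistency of the thermo inputs).
    """
    kinetics = kinetics or {}
    flex = flex or {}
    known = set(thermo["name"])
    unmatched = sorted((set(kinetics) | set(flex)) - known)
    if unmatched:
        raise ValueError(f"names not present in thermo table: {unmatched}")

    flags: list[str] = []
    rows = []
    for _, t in thermo.iterrows():
        name = t["name"]
        T = float(t.get("T_K", DEFAULT_TEMPERATURE_K) or DEFAULT_TEMPERATURE_K)
        K_d = float(t["Kd_M"])
        dG = delta_G(K_d, T)
        dH = t.get("dH_kcal_mol")
        mTdS = t.get("minus_TdS_kcal_mol")
        dH = None if pd.isna(dH) else float(dH)
        mTdS = None if pd.isna(mTdS) else float(mTdS)
        if dH is not None and mTdS is not None:
            implied = dH + mTdS
            if _rel_diff(implied, dG) > MISMATCH_TOL:
                flags.append(
                    f"{name}: dH + (-TdS) = {implied:.2f} kcal/mol vs "
                    f"RT ln K_d = {dG:.2f} kcal/mol at {T:.2f} K"
                )
        kin = kinetics.get(name, {})
        k_off = kin.get("k_off_hat", kin.get("k_off"))
        k_on = None
        residence = None
        if k_off is not None:
            k_off = float(k_off)
            k_on = k_on_from(k_off, K_d)
            residence = np.inf if k_off == 0 else 1.0 / k_off
            for key, ours, label in (
                ("k_on", k_on, "k_on"),
                ("residence_time", residence, "residence time"),
            ):
                supplied = kin.get(key)
                if supplied is not None and _rel_diff(float(supplied), ours) > MISMATCH_TOL:
                    flags.append(
                        f"{name}: supplied {label} {supplied:.4g} differs from "
                        f"recomputed {ours:.4g} by > {MISMATCH_TOL:.0%}"
                    )
        fx = flex.get(name, {})
        rows.append(
            {
                "name": name,
                "Kd_M": K_d,
                "dH_kcal_mol": dH,
                "minus_TdS_kcal_mol": mTdS,
                "dG_kcal_mol": dG,
                "T_K": T,
                "k_off_s": k_off,
                "k_off_se_s": kin.get("k_off_se"),
                "k_on_per_M_s": k_on,
                "residence_time_s": residence,
                "nu_half_Hz": None if pd.isna(t.get("nu_half_Hz")) else float(t.get("nu_half_Hz")),
                "S_conf_total": fx.get("S_conf_total"),
                "S_conf_ligand": fx.get("S_conf_ligand"),
                "S_conf_receptor": fx.get("S_conf_receptor"),
            }
        )
    return pd.DataFrame(rows), flags


def summaries_from_table(df: pd.DataFrame) -> list[ComplexSummary]:
    """Convert a build_summary table into ComplexSummary records."""
    out = []
    for _, r in df.iterrows():
        def _get(col):
            v = r.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        out.append(
            ComplexSummary(
                name=r["name"],
                K_d=_get("Kd_M"),
                dH=_get("dH_kcal_mol"),
                minus_TdS=_get("minus_TdS_kcal_mol"),
                dG=_get("dG_kcal_mol"),
                k_off=_get("k_off_s"),
                k_off_err=_get("k_off_se_s"),
                k_on=_get("k_on_per_M_s"),
                residence_time=_get("residence_time_s"),
                nu_half=_get("nu_half_Hz"),
                S_conf_total=_get("S_conf_total"),
                S_conf_ligand=_get("S_conf_ligand"),
                S_conf_receptor=_get("S_conf_receptor"),
                temperature=float(r.get("T_K", DEFAULT_TEMPERATURE_K)),
            )
        )
    return out
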