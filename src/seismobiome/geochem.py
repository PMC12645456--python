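"""Groundwater geochemistry tables: filtering, 0–1 scaling, derived quantities.

The analyte table is sample-date-by-analyte with below-detection (BD) flags.
Before multivariate analysis the table is filtered by the study's stated
rules — drop analytes that do not vary among dates, analytes detected on at
most one date, the 0.22-µm-filtered member of each filtered/unfiltered pair
(redundant with the unfiltered total), and a configurable exclusion list
(DOC and its δ13C, water isotopes) — and then each retained column is
scaled to [0, 1] by its maximum measured value.

Also here: the soluble (filtered) fraction of a total analyte, and the
Henry's-law conversion of bubble-strip headspace mixing ratios to dissolved
aqueous concentrations via a closed-vessel two-compartment mass balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteTable",
    "ExclusionConfig",
    "apply_exclusion_rules",
    "scale_01",
    "soluble_fraction",
    "headspace_to_dissolved",
    "HENRY_CONSTANTS",
]


@dataclass
class AnalyteTable:
    """Sample-day × analyte concentration matrix with BD flags.

    ``values``: DataFrame indexed by Julian sampling day, one column per
    analyte. BD cells hold NaN in ``values`` and True in ``bd_mask``.
    ``filtered_variant_map`` maps each 0.22-µm-filtered column name to its
    unfiltered counterpart.
    """

    values: pd.DataFrame
    bd_mask: pd.DataFrame | None = None
    filtered_variant_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bd_mask is None:
            self.bd_mask = self.values.isna()
        if self.bd_mask.shape != self.values.shape:
            raise ValueError("bd_mask shape must match values")
        detected = self.values.to_numpy()[~self.bd_mask.to_numpy()]
        if np.any(detected[np.isfinite(detected)] < 0):
            raise ValueError("detected concentrations must be >= 0")

    @property
    def sample_days(self):
        return list(self.values.index)

    @property
    def analytes(self):
        return list(self.values.columns)


@dataclass(frozen=True)
class ExclusionConfig:
    """Knobs for the analyte exclusion rules.

    ``explicit_exclusions`` default to the study's: DOC concentration and
    δ13C-DOC (measured on only three of five dates) and the water isotopes
    (no plausible influence on the microbiota).
    """

    explicit_exclusions: tuple = (
        "DOC",
        "d13C_DOC",
        "d18O_H2O",
        "d2H_H2O",
    )
    # "did not vary": exact equality after rounding to this many decimals
    constant_decimals: int = 6
    bd_fill: float = 0.0  # imputed value for BD cells before variance/scaling


def apply_exclusion_rules(
    table: AnalyteTable, config: ExclusionConfig | None = None
) -> tuple[AnalyteTable, list[tuple[str, str]]]:
    """Drop analytes per the stated rules; returns (filtered table, exclusion log).

    Rules, applied in order and logged as ``(column, rule)``:
    ``constant`` — identical value on every date (BD imputed first);
    ``single-date`` — detected (non-BD) on at most one date;
    ``filtered-variant`` — the filtered member of a filtered/unfiltered pair;
    ``explicit`` — configured exclusions. Idempotent.
    """
    cfg = config or ExclusionConfig()
    vals = table.values
    bd = table.bd_mask
    log: list[tuple[str, str]] = []
    drop: list[str] = []

    for col in vals.columns:
        detected_n = int((~bd[col]).sum())
        filled = vals[col].where(~bd[col], cfg.bd_fill).round(cfg.constant_decimals)
        if detected_n <= 1:
            drop.append(col)
            log.append((col, "single-date"))
        elif filled.nunique(dropna=False) <= 1:
            drop.append(col)
            log.append((col, "constant"))
    for filt_col, unfilt_col in table.filtered_variant_map.items():
        if filt_col in vals.columns and filt_col not in drop and unfilt_col in vals.columns:
            drop.append(filt_col)
            log.append((filt_col, "filtered-variant"))
    for col in cfg.explicit_exclusions:
        if col in vals.columns and col not in drop:
            drop.append(col)
            log.append((col, "explicit"))

    kept = [c for c in vals.columns if c not in drop]
    if not kept:
        raise ValueError("all analytes excluded; nothing left to analyse")
    out = AnalyteTable(
        values=vals[kept].copy(),
        bd_mask=bd[kept].copy(),
        filtered_variant_map={
            k: v for k, v in table.filtered_variant_map.items() if k in kept
        },
    )
    return out, log


def scale_01(table: AnalyteTable, bd_fill: float = 0.0) -> pd.DataFrame:
    """Scale each analyte to [0, 1] by dividing by its column maximum.

    BD cells are imputed with ``bd_fill`` (default 0: below detection reads
    as absent) before scaling. Every retained column must have a positive
    maximum — a zero-max column should have been excluded upstream.
    """
    filled = table.values.where(~table.bd_mask, bd_fill)
    col_max = filled.max(axis=0)
    zero = col_max[col_max <= 0]
    if len(zero):
        raise ZeroDivisionError(
            f"column(s) with non-positive maximum cannot be scaled: {list(zero.index)}"
        )
    return filled / col_max


def soluble_fraction(filtered_conc, unfiltered_conc):
    """Soluble (0.22-µm-filtered) fraction of the unfiltered total, percent.

    Scale-invariant; values above 100% (measurement error) are allowed and
    flagged via the returned mask when arrays are passed. Scalars return a
    plain float rounded as reported (1 decimal).
    """
    f = np.asarray(filtered_conc, dtype=float)
    u = np.asarray(unfiltered_conc, dtype=float)
    if np.any(u <= 0):
        raise ZeroDivisionError("unfiltered concentration must be > 0")
    pct = 100.0 * f / u
    if np.ndim(filtered_conc) == 0 and np.ndim(unfiltered_conc) == 0:
        return round(float(pct), 1)
    return pct


# Henry solubility H_cp at 298.15 K (mol m^-3 Pa^-1) and van-'t-Hoff
# temperature coefficient d(ln H)/d(1/T) (K), Sander's compilation.
HENRY_CONSTANTS: dict[str, tuple[float, float]] = {
    "H2": (7.7e-6, 530.0),
    "CH4": (1.4e-5, 1750.0),
    "CO2": (3.3e-4, 2400.0),
    "N2": (6.4e-6, 1300.0),
    "O2": (1.3e-5, 1500.0),
}

_R = 8.314462618  # J mol^-1 K^-1
_P_ATM = 101325.0  # Pa
_T0 = 298.15  # K


def henry_cp(gas_id: str, temp_C: float) -> float:
    """Temperature-corrected Henry solubility H_cp, mol m^-3 Pa^-1."""
    try:
        h0, vant_hoff = HENRY_CONSTANTS[gas_id]
    except KeyError:
        raise KeyError(
            f"no Henry constant for {gas_id!r}; supported: {sorted(HENRY_CONSTANTS)}"
        ) from None
    T = temp_C + 273.15
    return h0 * np.exp(vant_hoff * (1.0 / T - 1.0 / _T0))


def headspace_to_dissolved(
    headspace_ppmv: float,
    bubble_vol_mL: float,
    water_vol_mL: float,
    temp_C: float,
    gas_id: str,
    pressure_Pa: float = _P_ATM,
    return_parts: bool = False,
):
    """Bubble-strip headspace mixing ratio → dissolved concentration, µM.

    Closed-vessel mass balance at equilibrium: the gas partitions between
    the injected bubble (ideal gas at ``pressure_Pa``) and the water
    (Henry's law, van-'t-Hoff corrected to ``temp_C``). The original
    dissolved concentration is total moles (bubble + equilibrium aqueous)
    per litre of water.

    With ``return_parts=True`` returns ``(µM, n_gas_mol, n_aq_mol)``.
    """
    if bubble_vol_mL <= 0 or water_vol_mL <= 0:
        raise ValueError("bubble and water volumes must be > 0")
    if headspace_ppmv < 0:
        raise ValueError("mixing ratio must be >= 0")
    hcp = henry_cp(gas_id, temp_C)  # raises for unknown gas
    T = temp_C + 273.15
    p_partial = headspace_ppmv * 1e-6 * pressure_Pa  # Pa
    n_gas = p_partial * (bubble_vol_mL * 1e-6) / (_R * T)  # mol in bubble
    c_aq = hcp * p_partial  # mol m^-3 at equilibrium
    n_aq = c_aq * (water_vol_mL * 1e-6)  # mol in water
    water_L = water_vol_mL / 1000.0
    umol_per_L = (n_gas + n_aq) * 1e6 / water_L
    if return_parts:
        return umol_per_L, n_gas, n_aq
    return umol_per_L
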