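"""van't Hoff decomposition of the binding free energy.

ln Ka is regressed on 1/T:

    ln Ka = -dH/(R T) + dS/R,

so dH = -R*slope and dS = R*intercept (R = 8.314 J mol^-1 K^-1), with a
temperature-independent enthalpy over the fitted range. The Gibbs energy at
each input temperature is reported from the fitted pair via
dG = dH - T*dS (constant-enthalpy rows); the pointwise diagnostic
-RT ln Ka is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datatypes import ValidationError

__all__ = ["GAS_CONSTANT", "ThermoResult", "VantHoffModel", "vant_hoff_fit",
           "gibbs", "interpret_forces"]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class ThermoResult:
    """van't Hoff estimates with per-temperature free-energy decomposition."""

    delta_h: float  # kJ/mol
    delta_h_se: float  # kJ/mol
    delta_s: float  # J/(mol K)
    delta_s_se: float  # J/(mol K)
    per_temperature: tuple  # (T, dG, dG_se, T*dS) rows, kJ/mol
    r_squared: float
    delta_g_pointwise: tuple = ()  # diagnostic -RT ln Ka per input pair, kJ/mol

    def summary(self) -> str:
        lines = [
            "van't Hoff thermodynamic analysis",
            "-" * 55,
            f"dH  {self.delta_h:8.2f} +/- {self.delta_h_se:.2f} kJ/mol",
            f"dS  {self.delta_s:8.2f} +/- {self.delta_s_se:.2f} J/(mol K)",
            f"R^2 {self.r_squared:8.4f}",
            "",
            "T (K)    dG (kJ/mol)         T*dS (kJ/mol)",
        ]
        for T, dg, dg_se, tds in self.per_temperature:
            lines.append(f"{T:6.1f}  {dg:8.2f} +/- {dg_se:.2f}   {tds:8.2f}")
        return "\n".join(lines)


class VantHoffModel:
    """Linear van't Hoff model over (temperature, Ka) pairs.

    Parameters
    ----------
    pairs : list of (T, ka)
        Temperatures in K and association constants in M^-1; at least two
        distinct temperatures, all ka > 0.
    """

    def __init__(self, pairs):
        pairs = [(float(T), float(ka)) for T, ka in pairs]
        if len(pairs) < 2:
            raise ValidationError("van't Hoff fit needs >= 2 temperatures")
        temps = [T for T, _ in pairs]
        if len(set(temps)) < 2:
            raise ValidationError("temperatures must include >= 2 distinct values")
        if any(ka <= 0 for _, ka in pairs):
            raise ValidationError("all ka must be positive")
        if any(T <= 0 for T in temps):
            raise ValidationError("temperatures must be positive (K)")
        self.pairs = pairs

    def fit(self) -> ThermoResult:
        T = np.array([p[0] for p in self.pairs])
        ka = np.array([p[1] for p in self.pairs])
        x = 1.0 / T
        y = np.log(ka)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = ols.params
        if ols.df_resid > 0:
            cov = np.asarray(ols.cov_params())
            bse = np.asarray(ols.bse)
        else:
            # exact interpolation: uncertainties undefined
            cov = np.full((2, 2), np.nan)
            bse = np.array([np.nan, np.nan])

        dh = -GAS_CONSTANT * slope / 1000.0  # kJ/mol
        ds = GAS_CONSTANT * intercept  # J/(mol K)
        dh_se = GAS_CONSTANT * float(bse[1]) / 1000.0
        ds_se = GAS_CONSTANT * float(bse[0])

        rows = []
        for t in T:
            dg = gibbs(dh, ds, t)
            # dG = -R*(slope + intercept*T)/1000; propagate jointly.
            g = np.array([-GAS_CONSTANT * t / 1000.0, -GAS_CONSTANT / 1000.0])
            if np.all(np.isfinite(cov)):
                dg_se = float(np.sqrt(max(float(g @ cov @ g), 0.0)))
            else:
                dg_se = float("nan")
            rows.append((float(t), dg, dg_se, t * ds / 1000.0))

        pointwise = tuple(
            (float(t), float(-GAS_CONSTANT * t * np.log(k) / 1000.0))
            for t, k in self.pairs
        )
        r2 = 1.0 if len(self.pairs) == 2 else float(ols.rsquared)
        return ThermoResult(
            delta_h=dh,
            delta_h_se=dh_se,
            delta_s=ds,
            delta_s_se=ds_se,
            per_temperature=tuple(rows),
            r_squared=min(max(r2, 0.0), 1.0),
            delta_g_pointwise=pointwise,
        )


def vant_hoff_fit(pairs) -> ThermoResult:
    """Fit ln Ka vs 1/T; see :class:`VantHoffModel`."""
    return VantHoffModel(pairs).fit()


def gibbs(delta_h: float, delta_s: float, temperature: float) -> float:
    """dG = dH - T*dS, with dH in kJ/mol and dS in J/(mol K)."""
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    return delta_h - temperature * delta_s / 1000.0


def interpret_forces(result: ThermoResult) -> dict:
    """Qualitative reading of the thermodynamic signature.

    Spontaneous if dG < 0 at every temperature; entropy-driven if T*dS > 0
    and T*dS > dH throughout; enthalpy-driven if dH < 0 and |dH| > |T*dS|;
    otherwise mixed.
    """
    dgs = [row[1] for row in result.per_temperature]
    tdss = [row[3] for row in result.per_temperature]
    spontaneous = all(dg < 0 for dg in dgs)
    entropy_driven = all(tds > 0 and tds > result.delta_h for tds in tdss)
    enthalpy_driven = result.delta_h < 0 and all(
        abs(result.delta_h) > abs(tds) for tds in tdss
    )
    if entropy_driven:
        driving = "entropic"
    elif enthalpy_driven:
        driving = "enthalpic"
    else:
        driving = "mixed"
    return {"spontaneous": spontaneous, "driving_force": driving}
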