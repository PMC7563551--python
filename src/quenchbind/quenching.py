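"""Stern-Volmer analysis and quenching-mechanism classification.

The Stern-Volmer model F0/F = 1 + K_SV*[Q] is fitted with the intercept
fixed at 1 (F0 comes from the same series, so the ratio at zero quencher is
1 by construction). The bimolecular quenching constant k_q = K_SV/tau0
against the diffusion-limited ceiling (~1e10 M^-1 s^-1), together with the
comparison of intensity ratios F0/F and lifetime ratios tau0/tau, decides
whether quenching is static (ground-state complex: intensities drop,
lifetime flat) or dynamic (collisional: F0/F = tau0/tau pointwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ValidationError
from .preprocess import IntensityPoint

__all__ = [
    "ClassificationThresholds",
    "QuenchingResult",
    "SternVolmerModel",
    "stern_volmer_fit",
    "bimolecular_constant",
    "classify_mechanism",
]

#: Diffusion-limited ceiling for collisional quenching, M^-1 s^-1.
KQ_DIFFUSION_LIMIT = 1e10


@dataclass(frozen=True)
class ClassificationThresholds:
    """Tunable decision thresholds for mechanism classification."""

    kq_limit: float = KQ_DIFFUSION_LIMIT  # M^-1 s^-1
    tau_flat_tol: float = 0.05  # mean |tau0/tau - 1| below this = flat lifetime
    equiv_tol: float = 0.05  # max relative |F0/F - tau0/tau| below this = equivalent


@dataclass(frozen=True)
class QuenchingResult:
    """Stern-Volmer fit plus derived bimolecular constant and verdict."""

    k_sv: float  # M^-1
    k_sv_se: float  # M^-1
    k_q: float  # M^-1 s^-1
    tau0: float  # s
    r_squared: float
    mechanism: str  # 'static' | 'dynamic' | 'inconclusive'
    temperature: float  # K

    def summary(self) -> str:
        lines = [
            "Stern-Volmer quenching analysis",
            "-" * 47,
            f"temperature        {self.temperature:10.1f} K",
            f"K_SV               {self.k_sv:10.4g} +/- {self.k_sv_se:.2g} M^-1",
            f"tau0               {self.tau0 * 1e9:10.3f} ns",
            f"k_q = K_SV/tau0    {self.k_q:10.4g} M^-1 s^-1",
            f"R^2                {self.r_squared:10.4f}",
            f"mechanism          {self.mechanism:>10s}",
        ]
        return "\n".join(lines)


class SternVolmerModel:
    """Linear Stern-Volmer model with the intercept constrained to 1.

    Parameters
    ----------
    points : list of IntensityPoint
        Corrected intensities, including the zero-ligand point.
    temperature : float
        Temperature in K (carried through to results).
    """

    def __init__(self, points: list[IntensityPoint], temperature: float = 298.0):
        if len(points) < 3:
            raise ValidationError("Stern-Volmer fit needs >= 3 points")
        self.points = list(points)
        self.temperature = float(temperature)
        self.q = np.array([p.ligand_conc for p in self.points])
        self.ratio = np.array([p.f0_over_f for p in self.points])

    def fit(self, tau0: float = 4.8e-9) -> QuenchingResult:
        """Least-squares slope of (F0/F - 1) on [Q] through the origin.

        ``tau0`` is the unquenched lifetime in seconds used for k_q.
        """
        if tau0 <= 0:
            raise ValidationError("tau0 must be positive")
        q, y = self.q, self.ratio - 1.0
        sxx = float(q @ q)
        if sxx == 0.0:
            raise ValidationError("all ligand concentrations are zero")
        slope = float(q @ y) / sxx
        resid = y - slope * q
        dof = max(q.size - 1, 1)
        slope_se = float(np.sqrt((resid @ resid) / dof / sxx))
        ss_tot = float(((self.ratio - self.ratio.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        r2 = min(max(r2, 0.0), 1.0)
        return QuenchingResult(
            k_sv=slope,
            k_sv_se=slope_se,
            k_q=slope / tau0,
            tau0=tau0,
            r_squared=r2,
            mechanism="unclassified",
            temperature=self.temperature,
        )


def stern_volmer_fit(
    points: list[IntensityPoint], temperature: float = 298.0
) -> tuple[float, float, float]:
    """Convenience wrapper: returns (k_sv, k_sv_se, r_squared)."""
    res = SternVolmerModel(points, temperature).fit()
    return res.k_sv, res.k_sv_se, res.r_squared


def bimolecular_constant(k_sv: float, tau0: float) -> float:
    """k_q = K_SV / tau0 (tau0 in seconds)."""
    if tau0 <= 0:
        raise ValidationError("tau0 must be positive")
    return k_sv / tau0


def classify_mechanism(
    sv: QuenchingResult,
    lifetime_ratios: list[tuple[float, float]],
    intensity_ratios: list[tuple[float, float]],
    thresholds: ClassificationThresholds | None = None,
) -> str:
    """Classify quenching as 'static', 'dynamic' or 'inconclusive'.

    * static — k_q exceeds the diffusion limit while the lifetime stays flat
      (mean |tau0/tau - 1| small) despite appreciable intensity quenching;
    * dynamic — k_q is at or below the limit and F0/F tracks tau0/tau
      pointwise within the equivalence tolerance;
    * inconclusive — anything else.

    Both ratio lists are (ligand_conc, ratio) pairs aligned on ligand_conc.
    """
    th = thresholds or ClassificationThresholds()
    if not lifetime_ratios or not intensity_ratios:
        raise ValidationError("ratio lists must be non-empty")

    tau_map = dict(lifetime_ratios)
    int_map = dict(intensity_ratios)
    common = sorted(set(tau_map) & set(int_map))
    if not common:
        raise ValidationError("no common ligand concentrations between ratio lists")

    tau_r = np.array([tau_map[c] for c in common])
    int_r = np.array([int_map[c] for c in common])

    tau_flat = float(np.mean(np.abs(tau_r - 1.0))) < th.tau_flat_tol
    quenched = float(np.max(int_r)) - 1.0 > th.tau_flat_tol
    equivalent = float(np.max(np.abs(int_r - tau_r) / int_r)) < th.equiv_tol

    if sv.k_q > th.kq_limit and tau_flat and quenched:
        return "static"
    if sv.k_q <= th.kq_limit and equivalent:
        return "dynamic"
    return "inconclusive"
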