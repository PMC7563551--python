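"""Binding constant and site number from the double-logarithm regression.

For a quencher forming a non-fluorescent (dark) complex with the protein,

    log10((F0-F)/F) = n*log10(Ka) + n*log10([L]_free),

where the free-ligand concentration is estimated per point from the
quenched fraction: [L]_free = [L]_tot - ((F0-F)/F0)*[P]_tot. For the 1:1
dark-complex model this bracket is exactly the true free-ligand
concentration, so the regression is exactly linear on noiseless data.

Decadic logarithms throughout: the base cancels in the slope (n) but not in
the intercept, so it must be fixed for Ka recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datatypes import ValidationError
from .preprocess import IntensityPoint

__all__ = ["BindingFit", "DoubleLogModel", "double_log_fit"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingFit:
    """Result of the double-log regression."""

    ka: float  # M^-1
    ka_se: float  # M^-1
    n_sites: float
    n_se: float
    r_squared: float
    temperature: float  # K
    n_points_used: int = 0
    n_points_dropped: int = 0

    def summary(self) -> str:
        return "\n".join(
            [
                "Double-log binding fit",
                "-" * 47,
                f"temperature  {self.temperature:10.1f} K",
                f"Ka           {self.ka:10.4g} +/- {self.ka_se:.2g} M^-1",
                f"n_sites      {self.n_sites:10.4f} +/- {self.n_se:.2g}",
                f"R^2          {self.r_squared:10.5f}",
                f"points       {self.n_points_used} used, "
                f"{self.n_points_dropped} dropped",
            ]
        )


class DoubleLogModel:
    """Double-logarithm binding model for one titration's intensity points.

    Parameters
    ----------
    points : list of IntensityPoint
        Corrected intensities including the zero-ligand point (which is
        excluded from the regression itself).
    protein_conc : float
        Total protein concentration, M.
    temperature : float
        Temperature, K.
    """

    def __init__(
        self,
        points: list[IntensityPoint],
        protein_conc: float,
        temperature: float = 298.0,
    ):
        if protein_conc <= 0:
            raise ValidationError("protein_conc must be positive")
        self.points = list(points)
        self.protein_conc = float(protein_conc)
        self.temperature = float(temperature)

    def fit(self) -> BindingFit:
        xs, ys = [], []
        dropped = 0
        for p in self.points:
            if p.ligand_conc <= 0 or p.f >= p.f0:
                continue
            quenched_frac = (p.f0 - p.f) / p.f0
            l_free = p.ligand_conc - quenched_frac * self.protein_conc
            if l_free <= 0:
                dropped += 1
                logger.warning(
                    "dropping titration point [L]=%.3g M: "
                    "non-positive free-ligand estimate %.3g M",
                    p.ligand_conc,
                    l_free,
                )
                continue
            ys.append(np.log10((p.f0 - p.f) / p.f))
            xs.append(np.log10(l_free))
        if len(xs) < 3:
            raise ValidationError(
                f"double-log fit needs >= 3 usable points, got {len(xs)}"
            )

        x = np.asarray(xs)
        y = np.asarray(ys)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        a, b = ols.params  # intercept, slope
        cov = ols.cov_params()
        if b <= 0:
            raise ValidationError("non-positive slope: no binding signal")

        ka = 10.0 ** (a / b)
        # Delta method on (a, b) jointly: d(ka)/da = ka ln10 / b,
        # d(ka)/db = -ka ln10 a / b^2. a and b are strongly correlated here.
        g = np.array([ka * np.log(10.0) / b, -ka * np.log(10.0) * a / b**2])
        ka_var = float(g @ np.asarray(cov) @ g)
        return BindingFit(
            ka=float(ka),
            ka_se=float(np.sqrt(max(ka_var, 0.0))),
            n_sites=float(b),
            n_se=float(ols.bse[1]),
            r_squared=float(min(max(ols.rsquared, 0.0), 1.0)),
            temperature=self.temperature,
            n_points_used=len(xs),
            n_points_dropped=dropped,
        )


def double_log_fit(
    points: list[IntensityPoint], protein_conc: float, temperature: float = 298.0
) -> BindingFit:
    """Fit the double-log binding model; see :class:`DoubleLogModel`."""
    return DoubleLogModel(points, protein_conc, temperature).fit()
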