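"""Model-free Interaction Density Function (IDF) and Scatchard analysis.

The IDF method extracts binding parameters without assuming a binding model
a priori, using only mass conservation: if two titrations at different
total protein concentrations show the same fractional quenching, the free
ligand concentration and the average binding density (sum nu_i) must be the
same at those points. For each quenching level dF the total-ligand
concentrations read off the fitted quench curves obey

    [L]_tot = [L]_free + (sum nu_i) * [P]_tot,

a straight line in [P]_tot whose slope is the binding density and whose
intercept is the free-ligand concentration. The (nu, [L]_free) pairs across
levels then feed the Scatchard regression

    nu / [L]_free = n*Kb - Kb*nu,

whose slope gives -Kb and x-intercept the site count n; linearity across
the whole range indicates equivalent, independent (non-cooperative) sites.

Quench curves dF(log10 [L]_tot) are smoothed with an asymmetric logistic
(Richards) curve, bottom fixed at 0:

    dF(x) = top / (1 + 10^(slope*(center - x)))^asym,

which has a closed-form inverse. The asymmetry exponent is needed because
ligand depletion at micromolar protein skews the curve; a symmetric
logistic leaves a systematic misfit that biases Kb by several percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import lmfit
import numpy as np
import statsmodels.api as sm

from .datatypes import TitrationSeries, ValidationError
from .preprocess import IntensityPoint, extract_intensities

__all__ = [
    "QuenchCurve",
    "IDFLevel",
    "ScatchardFit",
    "QuenchCurveModel",
    "ScatchardModel",
    "quench_percentage",
    "fit_quench_curve",
    "idf_levels",
    "scatchard_fit",
    "default_levels",
]

logger = logging.getLogger(__name__)


def quench_percentage(f: float, f0: float) -> float:
    """Percentage of fluorescence quenching, 100*(F0 - F)/F0.

    Reported as a magnitude so that quenching gives positive, increasing
    values.
    """
    if f0 <= 0:
        raise ValidationError("f0 must be positive")
    return 100.0 * (f0 - f) / f0


@dataclass(frozen=True)
class QuenchCurve:
    """Sigmoid-smoothed quenching curve at one protein concentration.

    ``sigmoid_params`` is (bottom %, top %, center log10 M, slope, asym);
    bottom is fixed at 0 by the fit.
    """

    protein_conc: float  # M
    points: tuple  # (ligand_conc M, delta_f %) ordered by ligand_conc
    sigmoid_params: tuple

    def predict(self, log10_ligand) -> np.ndarray:
        bottom, top, center, slope, asym = self.sigmoid_params
        x = np.asarray(log10_ligand, dtype=float)
        return bottom + (top - bottom) / (
            1.0 + 10.0 ** (slope * (center - x))
        ) ** asym

    def invert(self, delta_f_level: float) -> float:
        """Total ligand concentration (M) at a quenching level (%), closed form."""
        bottom, top, center, slope, asym = self.sigmoid_params
        if not (bottom < delta_f_level < top):
            raise ValidationError(
                f"level {delta_f_level}% outside fitted range ({bottom}, {top})"
            )
        ratio = (top - bottom) / (delta_f_level - bottom)
        x = center - np.log10(ratio ** (1.0 / asym) - 1.0) / slope
        return float(10.0**x)

    @property
    def fitted_range(self) -> tuple[float, float]:
        """(min, max) fitted dF over the observed ligand concentrations."""
        lc = np.array([p[0] for p in self.points if p[0] > 0])
        vals = self.predict(np.log10(lc))
        return float(vals.min()), float(vals.max())


@dataclass(frozen=True)
class IDFLevel:
    """Mass-conservation line for one quenching level."""

    delta_f_level: float  # %
    ligand_totals: tuple  # (protein_conc, ligand_total) pairs, M
    sum_nu: float  # binding density (slope)
    l_free: float  # free ligand, M (intercept)
    fit_se: tuple  # (slope SE, intercept SE); NaN with only two curves


@dataclass(frozen=True)
class ScatchardFit:
    """Scatchard regression over IDF levels."""

    kb: float  # M^-1
    kb_se: float
    n_sites: float
    n_se: float
    r_squared: float

    def summary(self) -> str:
        return "\n".join(
            [
                "IDF / Scatchard analysis",
                "-" * 47,
                f"Kb       {self.kb:10.4g} +/- {self.kb_se:.2g} M^-1",
                f"n_sites  {self.n_sites:10.4f} +/- {self.n_se:.2g}",
                f"R^2      {self.r_squared:10.5f}",
            ]
        )


class QuenchCurveModel:
    """Richards-curve model of dF vs log10 total ligand.

    Parameters
    ----------
    points : list of IntensityPoint
        Corrected intensities including the zero-ligand point; at least 6
        nonzero-ligand points.
    protein_conc : float
        Total protein concentration, M.
    """

    def __init__(self, points: list[IntensityPoint], protein_conc: float):
        nonzero = [p for p in points if p.ligand_conc > 0]
        if len(nonzero) < 6:
            raise ValidationError("quench-curve fit needs >= 6 nonzero-ligand points")
        if protein_conc <= 0:
            raise ValidationError("protein_conc must be positive")
        self.protein_conc = float(protein_conc)
        self.df_points = sorted(
            ((p.ligand_conc, quench_percentage(p.f, p.f0)) for p in nonzero),
            key=lambda t: t[0],
        )

    def fit(self) -> QuenchCurve:
        lc = np.array([p[0] for p in self.df_points])
        df = np.array([p[1] for p in self.df_points])
        x = np.log10(lc)

        if float(np.ptp(df)) < 1e-9:
            raise ValidationError("flat quenching curve: nothing to fit")

        params = lmfit.Parameters()
        params.add("top", value=min(max(df.max(), 10.0), 100.0), min=1.0, max=110.0)
        # center: log-ligand at half the observed maximum
        half_idx = int(np.argmin(np.abs(df - df.max() / 2.0)))
        params.add("center", value=float(x[half_idx]), min=x[0] - 2.0, max=x[-1] + 2.0)
        params.add("slope", value=1.0, min=0.05, max=10.0)
        params.add("asym", value=1.0, min=0.1, max=10.0)

        def residual(p):
            model = p["top"].value / (
                1.0 + 10.0 ** (p["slope"].value * (p["center"].value - x))
            ) ** p["asym"].value
            return model - df

        res = lmfit.minimize(residual, params, method="leastsq")
        if not res.success:
            raise ValidationError("quench-curve fit did not converge")
        pr = res.params
        return QuenchCurve(
            protein_conc=self.protein_conc,
            points=tuple(self.df_points),
            sigmoid_params=(
                0.0,
                float(pr["top"].value),
                float(pr["center"].value),
                float(pr["slope"].value),
                float(pr["asym"].value),
            ),
        )


def fit_quench_curve(
    series_or_points,
    band_center: float = 340.0,
    protein_conc: float | None = None,
    mode: str = "integral",
    **extract_kwargs,
) -> QuenchCurve:
    """Fit a quench curve from a TitrationSeries or pre-extracted points.

    For spectra input the band intensity is extracted in integral mode by
    default: integrating the band averages down pointwise spectral noise,
    which matters for the level-inversion stage.
    """
    if isinstance(series_or_points, TitrationSeries):
        points = extract_intensities(
            series_or_points, band_center=band_center, mode=mode, **extract_kwargs
        )
        protein_conc = series_or_points.protein_conc
    else:
        points = list(series_or_points)
        if protein_conc is None:
            raise ValidationError("protein_conc required with pre-extracted points")
    return QuenchCurveModel(points, protein_conc).fit()


def default_levels(
    curves: list[QuenchCurve], n_levels: int = 10, edge_frac: float = 0.05
) -> list[float]:
    """Equally spaced dF levels spanning the overlap of all curves' ranges,
    excluding the outer ``edge_frac`` of the overlap at each end (sigmoid
    inversion degenerates at the asymptotes)."""
    lo = max(c.fitted_range[0] for c in curves)
    hi = min(c.fitted_range[1] for c in curves)
    if hi <= lo:
        raise ValidationError("quench curves have no overlapping dF range")
    span = hi - lo
    return list(np.linspace(lo + edge_frac * span, hi - edge_frac * span, n_levels))


def idf_levels(
    curves: list[QuenchCurve], levels: list[float] | None = None
) -> list[IDFLevel]:
    """Build the mass-conservation line for each quenching level.

    Inverts every curve at each level to get the total-ligand concentration
    per protein concentration, then regresses ligand_total on protein_conc:
    slope = binding density (sum nu_i), intercept = free-ligand
    concentration. Levels outside any curve's fitted range are skipped with
    a warning.
    """
    if len(curves) < 2:
        raise ValidationError("IDF needs >= 2 protein concentrations")
    p = np.array([c.protein_conc for c in curves])
    if np.unique(p).size < 2:
        raise ValidationError("protein concentrations must be distinct")
    if levels is None:
        levels = default_levels(curves)

    out = []
    for lev in levels:
        try:
            l_tots = np.array([c.invert(lev) for c in curves])
        except ValidationError:
            logger.warning("skipping level %.2f%%: outside a curve's range", lev)
            continue
        X = sm.add_constant(p)
        ols = sm.OLS(l_tots, X).fit()
        intercept, slope = ols.params
        if len(curves) > 2:
            se = (float(ols.bse[1]), float(ols.bse[0]))
        else:
            se = (float("nan"), float("nan"))  # exact interpolation, SE undefined
        out.append(
            IDFLevel(
                delta_f_level=float(lev),
                ligand_totals=tuple(zip(p.tolist(), l_tots.tolist())),
                sum_nu=float(slope),
                l_free=float(intercept),
                fit_se=se,
            )
        )
    if len(out) < 2:
        raise ValidationError("fewer than 2 usable quenching levels")
    return out


class ScatchardModel:
    """Scatchard regression nu/[L]_free = n*Kb - Kb*nu over IDF levels."""

    def __init__(self, levels: list[IDFLevel]):
        usable = [lv for lv in levels if lv.l_free > 0 and lv.sum_nu > 0]
        if len(usable) < 3:
            raise ValidationError("Scatchard fit needs >= 3 levels with l_free > 0")
        self.levels = usable

    def fit(self) -> ScatchardFit:
        nu = np.array([lv.sum_nu for lv in self.levels])
        y = nu / np.array([lv.l_free for lv in self.levels])
        ols = sm.OLS(y, sm.add_constant(nu)).fit()
        intercept, slope = ols.params
        if slope >= 0:
            raise ValidationError(
                "non-negative Scatchard slope (anti-cooperativity artifact or "
                f"noise); slope={slope:.3g}, intercept={intercept:.3g}"
            )
        cov = np.asarray(ols.cov_params())
        kb = -slope
        kb_se = float(ols.bse[1])
        n_sites = intercept / kb
        # Delta method: n = -intercept/slope.
        g = np.array([-1.0 / slope, intercept / slope**2])
        n_var = float(g @ cov @ g)
        return ScatchardFit(
            kb=float(kb),
            kb_se=kb_se,
            n_sites=float(n_sites),
            n_se=float(np.sqrt(max(n_var, 0.0))),
            r_squared=float(min(max(ols.rsquared, 0.0), 1.0)),
        )


def scatchard_fit(levels: list[IDFLevel]) -> ScatchardFit:
    """Scatchard regression over IDF levels; see :class:`ScatchardModel`."""
    return ScatchardModel(levels).fit()
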