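"""End-to-end workflows: simulate -> extract -> fit -> classify -> report.

These functions wire the stage modules together the way a bench campaign
runs: a multi-temperature titration feeds Stern-Volmer and double-log fits,
the lifetime series fixes tau0 and the mechanism, the per-temperature Ka
values feed the van't Hoff decomposition, and a two-protein-concentration
titration pair feeds the IDF/Scatchard analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import io as qio
from .binding import BindingFit, DoubleLogModel
from .datatypes import CuvetteGeometry, ValidationError
from .idf import ScatchardFit, fit_quench_curve, idf_levels, scatchard_fit
from .lifetime import fit_decay, lifetime_ratio_series
from .preprocess import extract_intensities
from .quenching import (
    ClassificationThresholds,
    QuenchingResult,
    SternVolmerModel,
    classify_mechanism,
)
from .synthetic import GroundTruth, simulate_decay, simulate_titration
from .thermo import ThermoResult, interpret_forces, vant_hoff_fit

__all__ = [
    "classify_campaign",
    "binding_recovery_campaign",
    "idf_campaign",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def _decay_window(gt: GroundTruth) -> float:
    # ~10 unquenched lifetimes keeps the tail informative for any tau0
    return max(50.0, 10.0 * gt.tau0)


def classify_campaign(
    gt: GroundTruth,
    p_tot: float = 4e-6,
    ligand_concs=None,
    n_channels: int = 1024,
    total_counts: float = 1e5,
    mode: str = "integral",
    thresholds: ClassificationThresholds | None = None,
    decay_p_tot: float = 1e-5,
) -> QuenchingResult:
    """Simulate one campaign and classify its quenching mechanism.

    Runs the titration simulation, extracts band intensities (integral mode
    by default: integrating the emission band averages down pointwise
    spectral noise), fits the Stern-Volmer slope, fits a decay per titration
    point to get tau0 and the lifetime-ratio series, and applies the
    mechanism rules.
    """
    if ligand_concs is None:
        ligand_concs = np.arange(12) * 4e-6
    series = simulate_titration(gt, p_tot, ligand_concs)
    points = extract_intensities(series, mode=mode)

    n_comp = len(gt.decay_alphas) if gt.decay_alphas is not None else 1
    window = _decay_window(gt)
    fits = [
        fit_decay(
            simulate_decay(
                gt,
                float(lc),
                n_channels=n_channels,
                window_ns=window,
                total_counts=total_counts,
                p_tot=decay_p_tot,
                seed_offset=i,
            ),
            n_components=n_comp,
        )
        for i, lc in enumerate(ligand_concs)
    ]
    tau_ratios = lifetime_ratio_series(fits)
    tau0_s = fits[0].tau_avg * 1e-9

    sv = SternVolmerModel(points, temperature=series.temperature).fit(tau0=tau0_s)
    intensity_ratios = [(p.ligand_conc, p.f0_over_f) for p in points]
    verdict = classify_mechanism(sv, tau_ratios, intensity_ratios, thresholds)
    return replace(sv, mechanism=verdict)


def binding_recovery_campaign(
    gt: GroundTruth,
    p_tot: float = 4e-6,
    ligand_concs=None,
    mode: str = "peak",
) -> BindingFit:
    """Simulate a titration and fit the double-log binding model."""
    if ligand_concs is None:
        ligand_concs = np.arange(12) * 4e-6
    series = simulate_titration(gt, p_tot, ligand_concs)
    points = extract_intensities(series, mode=mode)
    return DoubleLogModel(points, p_tot, series.temperature).fit()


def idf_campaign(
    gt: GroundTruth,
    protein_concs=(4e-6, 8e-6),
    ligand_concs=None,
    n_levels: int = 10,
    mode: str = "integral",
) -> tuple[ScatchardFit, list]:
    """Two-(or more-)protein-concentration IDF + Scatchard campaign.

    Titrations use 1 uM ligand increments by default. Returns the Scatchard
    fit and the per-level IDF lines.
    """
    if ligand_concs is None:
        ligand_concs = np.concatenate([[0.0], np.arange(1, 61) * 1e-6])
    curves = []
    for i, p_tot in enumerate(protein_concs):
        gt_i = replace(gt, seed=gt.seed + 1000 * i)
        series = simulate_titration(gt_i, p_tot, ligand_concs)
        curves.append(fit_quench_curve(series, mode=mode))
    levels = idf_levels(curves)
    if n_levels != 10:
        from .idf import default_levels

        levels = idf_levels(curves, default_levels(curves, n_levels=n_levels))
    return scatchard_fit(levels), levels


@dataclass(frozen=True)
class PipelineReport:
    """Bundle of everything a full synthetic campaign produces."""

    quenching: list
    binding: list
    thermo: ThermoResult | None
    idf: ScatchardFit | None
    forces: dict | None
    manifest: dict


def run_pipeline(config: dict, out_dir=None) -> PipelineReport:
    """Run the full workflow from a config mapping.

    Config keys (all optional except ``seed``):

    * ``seed`` — int, required.
    * ``temperatures_K`` — list, default [288, 298, 308].
    * ``ka_per_temperature`` — true Ka per temperature for the simulation,
      default scaled from 2.41e4 at 298 K with dH = 41.26 kJ/mol.
    * ``protein_conc_uM`` (4), ``increment_uM`` (4), ``n_points`` (12),
      ``noise_rel`` (0.01), ``idf_protein_concs_uM`` ([4, 8]).

    Writes per-stage CSVs and a manifest under ``out_dir`` when given.
    """
    if "seed" not in config:
        raise ValidationError("config must provide a seed")
    seed = int(config["seed"])
    temps = [float(t) for t in config.get("temperatures_K", (288.0, 298.0, 308.0))]
    if len(temps) < 2 and config.get("run_thermo", True):
        raise ValidationError("thermo stage needs >= 2 temperatures")

    kas = config.get("ka_per_temperature")
    if kas is None:
        # van't Hoff-consistent defaults around Ka(298) = 2.41e4, dH = 41.26 kJ/mol
        dh = 41.26e3
        kas = [2.41e4 * float(np.exp(-dh / 8.314 * (1 / t - 1 / 298.0))) for t in temps]
    p_tot = float(config.get("protein_conc_uM", 4.0)) * 1e-6
    inc = float(config.get("increment_uM", 4.0)) * 1e-6
    n_points = int(config.get("n_points", 12))
    noise = float(config.get("noise_rel", 0.01))
    ligand_concs = np.arange(n_points) * inc

    quenching_rows, binding_rows = [], []
    for i, (T, ka) in enumerate(zip(temps, kas)):
        gt = GroundTruth(
            ka=float(ka),
            tau0=4.8,
            mechanism="static",
            noise_rel=noise,
            seed=seed + 17 * i,
            decay_alphas=(0.3, 0.7),
            decay_taus=(1.565, 5.216),
        )
        sv = classify_campaign(gt, p_tot, ligand_concs)
        sv = replace(sv, temperature=T)
        quenching_rows.append(sv)
        series = simulate_titration(gt, p_tot, ligand_concs, temperature=T)
        points = extract_intensities(series, mode="integral")
        binding_rows.append(DoubleLogModel(points, p_tot, T).fit())

    thermo_res = None
    forces = None
    if config.get("run_thermo", True):
        thermo_res = vant_hoff_fit([(b.temperature, b.ka) for b in binding_rows])
        forces = interpret_forces(thermo_res)

    idf_res = None
    if config.get("run_idf", True):
        gt_idf = GroundTruth(
            ka=float(config.get("idf_kb", 1.43e5)),
            mechanism="static",
            noise_rel=noise,
            seed=seed + 4242,
        )
        p_concs = [
            float(p) * 1e-6 for p in config.get("idf_protein_concs_uM", (4.0, 8.0))
        ]
        idf_res, _ = idf_campaign(gt_idf, protein_concs=p_concs)

    manifest = {
        "package": "quenchbind",
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {},
    }

    report = PipelineReport(
        quenching=quenching_rows,
        binding=binding_rows,
        thermo=thermo_res,
        idf=idf_res,
        forces=forces,
        manifest=manifest,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        bundle = {"quenching": quenching_rows, "binding": binding_rows}
        if thermo_res is not None:
            bundle["thermo"] = thermo_res
        if idf_res is not None:
            bundle["idf"] = idf_res
        written = qio.write_results(bundle, out_dir)
        for path in written:
            manifest["outputs"][path.name] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
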