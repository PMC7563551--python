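"""Delimited-text I/O for titration spectra, decay histograms and results.

All files are comma-separated with one header line and decimal points.
Concentrations are micromolar in file headers/configs (the natural bench
unit) and converted to molar on read; everything in memory is molar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import BindingFit
from .datatypes import (
    AbsorbancePair,
    CuvetteGeometry,
    DecayHistogram,
    EmissionSpectrum,
    TitrationSeries,
    ValidationError,
)
from .idf import ScatchardFit
from .quenching import QuenchingResult
from .thermo import ThermoResult

__all__ = [
    "TitrationConfig",
    "read_config",
    "read_titration",
    "write_titration",
    "read_decay",
    "write_decay",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

UM = 1e-6  # micromolar -> molar


@dataclass(frozen=True)
class TitrationConfig:
    """Run configuration for one titration (concentrations in uM as on the bench)."""

    protein_conc_uM: float
    ligand_concs_uM: tuple
    temperature_K: float = 298.0
    lambda_ex_nm: float = 295.0
    band_center_nm: float = 340.0
    path_ex_cm: float = 1.0
    path_em_cm: float = 0.2

    @property
    def geometry(self) -> CuvetteGeometry:
        return CuvetteGeometry(path_ex=self.path_ex_cm, path_em=self.path_em_cm)


def read_config(path) -> TitrationConfig:
    """Load a YAML run config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return TitrationConfig(
            protein_conc_uM=float(raw["protein_conc_uM"]),
            ligand_concs_uM=tuple(float(v) for v in raw["ligand_concs_uM"]),
            temperature_K=float(raw.get("temperature_K", 298.0)),
            lambda_ex_nm=float(raw.get("lambda_ex_nm", 295.0)),
            band_center_nm=float(raw.get("band_center_nm", 340.0)),
            path_ex_cm=float(raw.get("path_ex_cm", 1.0)),
            path_em_cm=float(raw.get("path_em_cm", 0.2)),
        )
    except KeyError as exc:
        raise ValidationError(f"config missing required key: {exc}") from exc


def read_titration(
    spectra_table_path, absorbance_table_path, config: TitrationConfig
) -> TitrationSeries:
    """Read a titration from a spectra table and an absorbance table.

    The spectra table has ``wavelength_nm`` first, then one intensity column
    per titration point in config order. The absorbance table has columns
    ``point, A_ex, A_em``.
    """
    spectra_df = pd.read_csv(spectra_table_path)
    abs_df = pd.read_csv(absorbance_table_path)

    n_points = len(config.ligand_concs_uM)
    if spectra_df.shape[1] - 1 != n_points:
        raise ValidationError(
            f"spectra table has {spectra_df.shape[1] - 1} intensity columns "
            f"but config lists {n_points} ligand concentrations"
        )
    if len(abs_df) != n_points:
        raise ValidationError(
            f"absorbance table has {len(abs_df)} rows but config lists "
            f"{n_points} titration points"
        )

    wl = spectra_df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise ValidationError("wavelength grid must be strictly increasing")

    spectra = tuple(
        EmissionSpectrum(
            wavelengths=wl,
            intensities=spectra_df.iloc[:, i + 1].to_numpy(dtype=float),
            excitation_wavelength=config.lambda_ex_nm,
            temperature=config.temperature_K,
        )
        for i in range(n_points)
    )
    pairs = tuple(
        AbsorbancePair(a_ex=float(r["A_ex"]), a_em=float(r["A_em"]))
        for _, r in abs_df.iterrows()
    )
    return TitrationSeries(
        protein_conc=config.protein_conc_uM * UM,
        ligand_concs=np.asarray(config.ligand_concs_uM, dtype=float) * UM,
        spectra=spectra,
        absorbances=pairs,
        temperature=config.temperature_K,
    )


def write_titration(series: TitrationSeries, spectra_path, absorbance_path) -> None:
    """Write a titration back to the CSV formats of :func:`read_titration`."""
    cols = {"wavelength_nm": series.spectra[0].wavelengths}
    for i, spec in enumerate(series.spectra):
        cols[f"intensity_point_{i:02d}"] = spec.intensities
    pd.DataFrame(cols).to_csv(spectra_path, index=False, float_format="%.10g")
    pd.DataFrame(
        {
            "point": np.arange(len(series)),
            "A_ex": [a.a_ex for a in series.absorbances],
            "A_em": [a.a_em for a in series.absorbances],
        }
    ).to_csv(absorbance_path, index=False, float_format="%.10g")


def read_decay(path, ligand_conc: float = 0.0) -> DecayHistogram:
    """Read a ``time_ns, counts`` CSV into a DecayHistogram."""
    df = pd.read_csv(path)
    return DecayHistogram(
        times=df.iloc[:, 0].to_numpy(dtype=float),
        counts=df.iloc[:, 1].to_numpy(dtype=float),
        ligand_conc=ligand_conc,
    )


def write_decay(hist: DecayHistogram, path) -> None:
    pd.DataFrame({"time_ns": hist.times, "counts": hist.counts}).to_csv(
        path, index=False, float_format="%.10g"
    )


def _quenching_frame(results: list[QuenchingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "temperature_K": [r.temperature for r in results],
            "K_SV_per_M": [r.k_sv for r in results],
            "K_SV_se_per_M": [r.k_sv_se for r in results],
            "k_q_per_M_s": [r.k_q for r in results],
            "tau0_s": [r.tau0 for r in results],
            "r_squared": [r.r_squared for r in results],
            "mechanism": [r.mechanism for r in results],
        }
    )


def _binding_frame(results: list[BindingFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "temperature_K": [r.temperature for r in results],
            "Ka_per_M": [r.ka for r in results],
            "Ka_se_per_M": [r.ka_se for r in results],
            "n_sites": [r.n_sites for r in results],
            "n_se": [r.n_se for r in results],
            "r_squared": [r.r_squared for r in results],
        }
    )


def _thermo_frame(result: ThermoResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "temperature_K": [row[0] for row in result.per_temperature],
            "delta_g_kJ_mol": [row[1] for row in result.per_temperature],
            "delta_g_se_kJ_mol": [row[2] for row in result.per_temperature],
            "delta_h_kJ_mol": result.delta_h,
            "delta_h_se_kJ_mol": result.delta_h_se,
            "t_delta_s_kJ_mol": [row[3] for row in result.per_temperature],
            "delta_s_J_mol_K": result.delta_s,
            "delta_s_se_J_mol_K": result.delta_s_se,
            "r_squared": result.r_squared,
        }
    )


def _scatchard_frame(result: ScatchardFit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Kb_per_M": [result.kb],
            "Kb_se_per_M": [result.kb_se],
            "n_sites": [result.n_sites],
            "n_se": [result.n_se],
            "r_squared": [result.r_squared],
        }
    )


def write_results(results_bundle: dict, out_dir) -> list[Path]:
    """Write one CSV summary per analysis plus a combined text report.

    ``results_bundle`` may contain any of the keys 'quenching' (list of
    QuenchingResult), 'binding' (list of BindingFit), 'thermo'
    (ThermoResult), 'idf' (ScatchardFit). Numeric fields round-trip through
    :func:`read_results` to 1e-9 relative.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report_lines: list[str] = []

    if not results_bundle:
        warnings.warn("empty results bundle: nothing written", stacklevel=2)
        return written

    if "quenching" in results_bundle:
        path = out_dir / "quenching_summary.csv"
        _quenching_frame(results_bundle["quenching"]).to_csv(
            path, index=False, float_format="%.12g"
        )
        written.append(path)
        report_lines += [r.summary() + "\n" for r in results_bundle["quenching"]]
    if "binding" in results_bundle:
        path = out_dir / "binding_summary.csv"
        _binding_frame(results_bundle["binding"]).to_csv(
            path, index=False, float_format="%.12g"
        )
        written.append(path)
        report_lines += [r.summary() + "\n" for r in results_bundle["binding"]]
    if "thermo" in results_bundle:
        path = out_dir / "thermo_summary.csv"
        _thermo_frame(results_bundle["thermo"]).to_csv(
            path, index=False, float_format="%.12g"
        )
        written.append(path)
        report_lines.append(results_bundle["thermo"].summary() + "\n")
    if "idf" in results_bundle:
        path = out_dir / "idf_summary.csv"
        _scatchard_frame(results_bundle["idf"]).to_csv(
            path, index=False, float_format="%.12g"
        )
        written.append(path)
        report_lines.append(results_bundle["idf"].summary() + "\n")

    report = out_dir / "report.txt"
    report.write_text("\n".join(report_lines))
    written.append(report)
    return written


def read_results(out_dir) -> dict:
    """Read back the CSV summaries written by :func:`write_results`."""
    out_dir = Path(out_dir)
    bundle: dict = {}
    q = out_dir / "quenching_summary.csv"
    if q.exists():
        df = pd.read_csv(q)
        bundle["quenching"] = [
            QuenchingResult(
                k_sv=r.K_SV_per_M,
                k_sv_se=r.K_SV_se_per_M,
                k_q=r.k_q_per_M_s,
                tau0=r.tau0_s,
                r_squared=r.r_squared,
                mechanism=r.mechanism,
                temperature=r.temperature_K,
            )
            for r in df.itertuples()
        ]
    b = out_dir / "binding_summary.csv"
    if b.exists():
        df = pd.read_csv(b)
        bundle["binding"] = [
            BindingFit(
                ka=r.Ka_per_M,
                ka_se=r.Ka_se_per_M,
                n_sites=r.n_sites,
                n_se=r.n_se,
                r_squared=r.r_squared,
                temperature=r.temperature_K,
            )
            for r in df.itertuples()
        ]
    t = out_dir / "thermo_summary.csv"
    if t.exists():
        df = pd.read_csv(t)
        bundle["thermo"] = ThermoResult(
            delta_h=float(df.delta_h_kJ_mol.iloc[0]),
            delta_h_se=float(df.delta_h_se_kJ_mol.iloc[0]),
            delta_s=float(df.delta_s_J_mol_K.iloc[0]),
            delta_s_se=float(df.delta_s_se_J_mol_K.iloc[0]),
            per_temperature=tuple(
                (
                    float(r.temperature_K),
                    float(r.delta_g_kJ_mol),
                    float(r.delta_g_se_kJ_mol),
                    float(r.t_delta_s_kJ_mol),
                )
                for r in df.itertuples()
            ),
            r_squared=float(df.r_squared.iloc[0]),
        )
    s = out_dir / "idf_summary.csv"
    if s.exists():
        df = pd.read_csv(s)
        bundle["idf"] = ScatchardFit(
            kb=float(df.Kb_per_M.iloc[0]),
            kb_se=float(df.Kb_se_per_M.iloc[0]),
            n_sites=float(df.n_sites.iloc[0]),
            n_se=float(df.n_se.iloc[0]),
            r_squared=float(df.r_squared.iloc[0]),
        )
    return bundle
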