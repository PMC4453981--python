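"""End-to-end constrained-modelling workflows.

``analyse_directory`` drives the full pipeline over a directory of
atomistic PDB models: each model is grid-transformed into a sphere model
and pushed through an X-ray branch (hydration shell -> Debye curve) and a
neutron branch (dry model -> Debye curve -> optional Gaussian smearing),
then scored against every experimental curve of the matching branch with
the R factor.  Sphere models and curves land under
``<output>/<branch>/models`` and ``<output>/<branch>/curves``; two
tab-separated tables summarize the experimental Guinier analyses and the
per-model comparisons.

``optimize_params_workflow`` determines the grid box side and hydration
cutoff that reproduce the sequence-derived dry and hydrated volumes, the
values a user then copies into the parameter file.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, scattering_curve, sequence_props, sphere_models
from .datatypes import AtomModel, ScatterCurve, SmearingSpec, SphereModel
from .io_formats import AnalysisParams

__all__ = [
    "analyse_directory",
    "optimize_params_workflow",
    "r_vs_rg_table",
    "OptimizationReport",
]

logger = logging.getLogger(__name__)

EXPERIMENT_SUMMARY_NAME = "expt_summary.tsv"
MODEL_COMPARISON_NAME = "model_comparison.tsv"
MANIFEST_NAME = "run_manifest.json"

_FLOAT_FORMAT = "%.6f"


def _guinier_values(curve: ScatterCurve, params: AnalysisParams):
    """Rg / Rxs1 / Rxs2 of a curve under the configured fit windows.

    A failed fit (e.g. positive slope in a noisy window) yields NaN for
    that quantity rather than aborting a many-model run.
    """
    out = {"rg": np.nan, "rxs1": np.nan, "rxs2": np.nan}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            out["rg"] = scattering_curve.guinier_rg(
                curve, params.rg.fitmin, params.rg.fitmax).value
        except ValueError as exc:
            logger.warning("Rg fit failed: %s", exc)
        for name in ("rxs1", "rxs2"):
            window = getattr(params, name)
            if window is None:
                continue
            try:
                out[name] = scattering_curve.guinier_rxs(
                    curve, window.fitmin, window.fitmax,
                    rg_window=(params.rg.fitmin, params.rg.fitmax)).value
            except ValueError as exc:
                logger.warning("%s fit failed: %s", name, exc)
    return out


def _theoretical_curve(model: SphereModel, params: AnalysisParams,
                       smear: bool) -> ScatterCurve:
    hist = scattering_curve.distance_histogram(
        model, mode="modern", nbins=params.curve.radbins)
    q = scattering_curve.theoretical_q_grid(params.curve.qmax,
                                            params.curve.npoints)
    curve = scattering_curve.debye_curve(hist, model.radius, q)
    if smear:
        spec = SmearingSpec(wavelength=params.curve.wavelength,
                            spread=params.curve.spread,
                            divergence=params.curve.divergence)
        curve = scattering_curve.smear_curve(curve, spec)
    return curve


def _write_manifest(path: Path, params: AnalysisParams,
                    branches: dict) -> None:
    # no timestamps or machine state: repeated runs must be byte-identical
    manifest = {
        "boxside_nm": params.sphere.boxside,
        "grid_cutoff": params.sphere.cutoff,
        "grid_threshold_semantics": "count >= cutoff",
        "hydration_cutoff": params.hydrate.cutoff,
        "hydration_positions": params.hydrate.positions,
        "histogram": {"mode": "modern", "nbins": params.curve.radbins},
        "q_grid": {"qmax": params.curve.qmax,
                   "npoints": params.curve.npoints},
        "smearing": {
            "enabled": params.curve.smear,
            "wavelength": params.curve.wavelength,
            "spread": params.curve.spread,
            "divergence": params.curve.divergence,
        },
        "rfactor_window": [params.rfac.qmin, params.rfac.qmax],
        "branches": branches,
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def analyse_directory(params: AnalysisParams, pdb_dir, xray_curves=(),
                      neutron_curves=(), output_dir="sas_output",
                      neutron_baseline: float = 0.0):
    """Run the constrained-modelling analysis over a directory of models.

    Parameters
    ----------
    params
        Validated analysis parameters.
    pdb_dir
        Directory holding the atomistic models (``*.pdb``), processed in
        sorted name order.
    xray_curves, neutron_curves
        Paths to experimental curve files for each branch; a branch with
        no curves is skipped with a log notice.
    output_dir
        Output tree root; receives ``<branch>/models``, ``<branch>/curves``,
        the two summary tables and a run manifest.
    neutron_baseline
        Optional flat incoherent baseline (fraction of I(0)) added to the
        *written* neutron curves only, after all R factors are computed.

    Returns
    -------
    (expt_summary, model_comparison) : tuple of pandas.DataFrame
        The two tables, also written as tab-separated files.
    """
    pdb_dir = Path(pdb_dir)
    out = Path(output_dir)
    pdb_paths = sorted(pdb_dir.glob("*.pdb"))
    if not pdb_paths:
        raise ValueError(f"no PDB models found in {pdb_dir}")

    branches: dict[str, list] = {}
    if xray_curves:
        branches["xray"] = [io_formats.read_experimental_curve(p)
                            for p in xray_curves]
    else:
        logger.info("no X-ray curves supplied; X-ray branch skipped")
    if neutron_curves:
        branches["neutron"] = [io_formats.read_experimental_curve(p)
                               for p in neutron_curves]
    else:
        logger.info("no neutron curves supplied; neutron branch skipped")
    if not branches:
        raise ValueError("need experimental curves in at least one branch")

    for branch in branches:
        (out / branch / "models").mkdir(parents=True, exist_ok=True)
        (out / branch / "curves").mkdir(parents=True, exist_ok=True)

    # first output: Guinier analyses of the experimental curves
    expt_rows = []
    for branch, curves in branches.items():
        for curve in curves:
            fits = _guinier_values(curve, params)
            expt_rows.append({"file": Path(curve.source_path).name,
                              "branch": branch, "rg": fits["rg"],
                              "rxs1": fits["rxs1"], "rxs2": fits["rxs2"]})
    expt_summary = pd.DataFrame(expt_rows)

    # second output: per-model, per-branch comparison records
    records = []
    for pdb_path in pdb_paths:
        name = pdb_path.stem
        atoms = io_formats.read_pdb_atoms(pdb_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dry = sphere_models.grid_transform(
                atoms, params.sphere.boxside, params.sphere.cutoff)
        for branch, curves in branches.items():
            record: dict = {"model": name, "branch": branch}
            if len(dry) < 2:
                record["status"] = "failed: sphere count < 2 at cutoff"
                records.append(record)
                logger.warning("model %s produced %d spheres; recorded as "
                               "failed", name, len(dry))
                continue
            if branch == "xray":
                model = sphere_models.hydrate_sphere_model(
                    dry, params.hydrate.cutoff)
                curve = _theoretical_curve(model, params, smear=False)
            else:
                # SANS in heavy water does not see the hydration shell:
                # the neutron branch always uses the dry model
                model = dry
                curve = _theoretical_curve(model, params,
                                           smear=params.curve.smear)
            fits = _guinier_values(curve, params)
            record.update({
                "rg_model": sphere_models.sphere_rg(model),
                "rg_curve": fits["rg"],
                "rxs1_curve": fits["rxs1"],
                "rxs2_curve": fits["rxs2"],
                "volume_nm3": sphere_models.sphere_model_volume(model, "box"),
                "status": "ok",
            })
            for expt in curves:
                label = Path(expt.source_path).name
                result = scattering_curve.r_factor(
                    curve, expt, params.rfac.qmin, params.rfac.qmax)
                record[f"rfactor_pct:{label}"] = result.r_factor
                record[f"eta:{label}"] = result.eta

            io_formats.write_sphere_model_pdb(
                model, out / branch / "models" / f"{name}.pdb")
            written = curve
            if branch == "neutron" and neutron_baseline > 0:
                # flat incoherent correction only after all fitting is done
                written = scattering_curve.apply_incoherent_baseline(
                    curve, neutron_baseline)
            io_formats.write_curve(written,
                                   out / branch / "curves" / f"{name}.dat")
            records.append(record)

    comparison = pd.DataFrame(records)
    expt_summary.to_csv(out / EXPERIMENT_SUMMARY_NAME, sep="\t", index=False,
                        float_format=_FLOAT_FORMAT)
    comparison.to_csv(out / MODEL_COMPARISON_NAME, sep="\t", index=False,
                      float_format=_FLOAT_FORMAT)
    _write_manifest(out / MANIFEST_NAME, params,
                    {b: [Path(c.source_path).name for c in cs]
                     for b, cs in branches.items()})
    return expt_summary, comparison


@dataclass(frozen=True)
class OptimizationReport:
    """Grid parameters that reproduce the sequence-derived volumes."""

    boxside: float  # nm
    dry_volume: float  # nm^3 achieved at that side
    target_dry_volume: float  # nm^3 from the sequence
    best_hydration_cutoff: int
    target_hydrated_volume: float  # nm^3 from the sequence
    cutoff_table: tuple[tuple[int, float], ...]

    def to_text(self) -> str:
        lines = [
            f"# target dry volume      {self.target_dry_volume:.3f} nm^3",
            f"# optimized box side     {self.boxside:.3f} nm "
            f"(model volume {self.dry_volume:.3f} nm^3)",
            f"# target hydrated volume {self.target_hydrated_volume:.3f} nm^3",
            f"# best hydration cutoff  {self.best_hydration_cutoff}",
            "cutoff\thydrated_volume_nm3",
        ]
        lines += [f"{c}\t{v:.3f}" for c, v in self.cutoff_table]
        return "\n".join(lines) + "\n"


def optimize_params_workflow(params: AnalysisParams, pdb_path,
                             sequence_path=None, output_path=None,
                             sequence_format: str | None = None,
                             mismatch_fraction: float = 0.05
                             ) -> OptimizationReport:
    """Optimize the grid box side and hydration cutoff for one structure.

    Target dry and hydrated volumes come from the sequence (a FASTA/YAML
    file covering residues missing from the structure, or the structure
    itself when ``sequence_path`` is omitted).  If the sequence length
    disagrees with the structure's residue count by more than
    ``mismatch_fraction`` a warning advises completing the model.  The
    resulting values are intended to be copied into the parameter file.
    """
    atoms = io_formats.read_pdb_atoms(pdb_path)
    structure_counts = io_formats.read_sequence(pdb_path, "pdb",
                                                on_unknown="skip")
    if sequence_path is not None:
        if sequence_format is None:
            suffix = Path(sequence_path).suffix.lower()
            sequence_format = {".fas": "fasta", ".fasta": "fasta",
                               ".yml": "yaml", ".yaml": "yaml",
                               ".pdb": "pdb"}.get(suffix, "fasta")
        counts = io_formats.read_sequence(sequence_path, sequence_format)
        mismatch = abs(counts.total() - structure_counts.total()) / max(
            counts.total(), 1)
        if mismatch > mismatch_fraction:
            warnings.warn(
                f"sequence has {counts.total()} residues but the structure "
                f"provides {structure_counts.total()} "
                f"({100 * mismatch:.1f}% apart); missing volume will not be "
                "distributed correctly - prefer completing the model",
                stacklevel=2)
    else:
        counts = structure_counts

    props = sequence_props.compute_properties(counts)
    box = sphere_models.optimize_box_side(
        atoms, props.dry_volume, cutoff=params.sphere.cutoff)
    dry = sphere_models.grid_transform(atoms, box.boxside,
                                       params.sphere.cutoff)
    hydration = sphere_models.optimize_hydration_cutoff(
        dry, props.hydrated_volume)

    report = OptimizationReport(
        boxside=box.boxside, dry_volume=box.volume,
        target_dry_volume=props.dry_volume,
        best_hydration_cutoff=hydration.best_cutoff,
        target_hydrated_volume=props.hydrated_volume,
        cutoff_table=hydration.table)
    if output_path is not None:
        Path(output_path).write_text(report.to_text())
    return report


def r_vs_rg_table(comparison: pd.DataFrame) -> pd.DataFrame:
    """Long-format (Rg, R factor) table for fit-progression plots.

    One row per (experimental curve, model, branch), sorted by the model
    curve Rg, with the best (lowest-R) model per curve flagged.
    """
    if len(comparison) == 0:
        raise ValueError("no analysis records")
    r_columns = [c for c in comparison.columns
                 if c.startswith("rfactor_pct:")]
    if not r_columns:
        raise ValueError("records carry no R-factor columns")
    ok = comparison[comparison["status"] == "ok"]
    rows = []
    for col in r_columns:
        label = col.split(":", 1)[1]
        for _, rec in ok.iterrows():
            rows.append({"curve": label, "model": rec["model"],
                         "branch": rec["branch"], "rg": rec["rg_curve"],
                         "rfactor_pct": rec[col]})
    table = pd.DataFrame(rows).sort_values(
        ["curve", "rg"], kind="stable").reset_index(drop=True)
    table["best"] = False
    for label, group in table.groupby("curve"):
        table.loc[group["rfactor_pct"].idxmin(), "best"] = True
    return table
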