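"""End-to-end orchestration: ingest -> CSM -> global fit -> SASA -> stats.

``run_pipeline`` executes the full analysis from a JSON run
configuration and writes per-stage CSV outputs plus one machine-readable
JSON report.  Each stage fails atomically with the stage name and
offending input in the error message; reruns with identical inputs give
identical reports (modulo the timestamp field).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .csm import build_profile
from .model import FitOptions, REESConstants, fit_group_global, summarize_table
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, parse_structure, shrake_rupley, trp_report
from .spectra_io import ingest_dataset
from .stats import GroupedValues, one_way_anova, pearson, tukey_hsd

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger("reesfit")

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the input."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration.

    ``structures`` maps sample_id to a PDB file path; when at least
    three samples have structures, REES-vs-SASA correlations are
    computed on per-sample averages.
    """

    manifest: str
    out_dir: str
    structures: dict[str, str] = field(default_factory=dict)
    emission_window: tuple[float, float] = (325.0, 500.0)
    csm_r_bounds: tuple[float, float] = (387.0, 440.0)
    temperature: float = 283.15
    m_display_scale: float = 1.0
    skip_sasa: bool = False
    probe_radius: float = DEFAULT_PROBE_RADIUS
    sasa_points: int = DEFAULT_N_POINTS
    alpha: float = 0.05
    clip_negative: bool = False

    def validate(self, base_dir: Path) -> None:
        if not (base_dir / self.manifest).exists():
            raise PipelineError(f"config: manifest not found: {self.manifest}")
        if not self.skip_sasa:
            for sample, pdb in self.structures.items():
                if not (base_dir / pdb).exists():
                    raise PipelineError(
                        f"config: structure for sample {sample!r} not found: {pdb}"
                    )
        lo, hi = self.emission_window
        if not lo < hi:
            raise PipelineError("config: emission_window must satisfy lo < hi")
        if self.temperature <= 0:
            raise PipelineError("config: temperature must be positive")


def load_config(path) -> tuple[RunConfig, Path]:
    """Read a JSON run configuration; relative paths resolve against the
    config file's directory."""
    path = Path(path)
    raw = json.loads(path.read_text())
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"config: unknown keys {sorted(unknown)}")
    for key in ("emission_window", "csm_r_bounds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    config = RunConfig(**raw)
    return config, path.parent


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
            dt = time.perf_counter() - t0
            logger.info("stage %s: done in %.2f s", name, dt)
            return result, dt
        return inner
    return wrap


@_stage("ingest")
def _ingest(config: RunConfig, base_dir: Path):
    return ingest_dataset(
        base_dir / config.manifest, clip_negative=config.clip_negative
    )


@_stage("csm")
def _csm(scans, config: RunConfig, out_dir: Path):
    profiles = [build_profile(s, config.emission_window) for s in scans]
    rows = []
    for p in profiles:
        for lx, csm in zip(p.excitation_wavelengths, p.csm):
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "group": p.group_label,
                    "replicate": p.replicate_index,
                    "lambda_ex": lx,
                    "csm": csm,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "csm_profiles.csv", index=False)
    return profiles


@_stage("fit")
def _fit(profiles, config: RunConfig, out_dir: Path):
    constants = REESConstants(T=config.temperature)
    options = FitOptions(
        csm_r_bounds=config.csm_r_bounds, m_display_scale=config.m_display_scale
    )
    by_group: dict[str, list] = {}
    for p in profiles:
        by_group.setdefault(p.group_label, []).append(p)
    results = [
        fit_group_global(group_profiles, constants, options)
        for group_profiles in by_group.values()
    ]
    table = summarize_table(results, options)
    table.to_csv(out_dir / "fit_results.csv", index=False)
    return results, table


@_stage("sasa")
def _sasa(config: RunConfig, base_dir: Path, out_dir: Path, n_trp_by_sample: dict):
    rows = []
    for sample_id, pdb in sorted(config.structures.items()):
        structure = parse_structure(base_dir / pdb)
        per_atom = shrake_rupley(structure, config.probe_radius, config.sasa_points)
        report = trp_report(
            structure, per_atom, expected_n_trp=n_trp_by_sample.get(sample_id)
        )
        rows.append(
            {
                "sample_id": sample_id,
                "file": str(pdb),
                "n_trp": report.n_trp,
                "total_trp_sasa": report.total_trp_sasa,
                "average_sasa_per_trp": report.average_sasa_per_trp,
                "warnings": "; ".join(report.warnings),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df.to_csv(out_dir / "trp_sasa.csv", index=False)
    return df


@_stage("stats")
def _stats(results, table: pd.DataFrame, sasa_df: pd.DataFrame, config: RunConfig):
    block: dict = {"group_comparison": {}, "correlations": {}}
    replicate_rows = [
        {
            "group": res.group_label,
            "csm_fc": rep.params.csm_fc,
            "m": rep.params.m * config.m_display_scale,
        }
        for res in results
        for rep in res.per_replicate
    ]
    reps = pd.DataFrame(replicate_rows)
    if reps["group"].nunique() >= 2 and reps.groupby("group").size().min() >= 2:
        for quantity in ("csm_fc", "m"):
            data = GroupedValues.from_frame(reps, "group", quantity)
            anova = one_way_anova(data)
            block["group_comparison"][quantity] = {
                "anova": {
                    "F": anova.F,
                    "p": anova.p,
                    "df_between": anova.df_between,
                    "df_within": anova.df_within,
                },
                "tukey": tukey_hsd(data, config.alpha).to_dict(orient="records"),
            }
    samples = table[table["row_type"] == "sample"]
    if len(sasa_df) >= 3:
        merged = samples.merge(sasa_df, on="sample_id", how="inner")
        if len(merged) >= 3:
            for quantity in ("csm_fc_avg", "m_avg"):
                corr = pearson(merged["average_sasa_per_trp"], merged[quantity])
                block["correlations"][f"{quantity}_vs_sasa_per_trp"] = {
                    "r": corr.r,
                    "p": corr.p,
                    "n": corr.n,
                }
    return block


def run_pipeline(config: RunConfig, base_dir=".") -> dict:
    """Execute all stages and return the report dictionary.

    The report is also written to ``<out_dir>/report.json`` and a run
    log to ``<out_dir>/run.log``.
    """
    base_dir = Path(base_dir)
    config.validate(base_dir)
    out_dir = base_dir / config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    try:
        scans, timings["ingest"] = _ingest(config, base_dir)
        profiles, timings["csm"] = _csm(scans, config, out_dir)
        (results, table), timings["fit"] = _fit(profiles, config, out_dir)
        n_trp_by_sample = {s.sample_id: s.n_trp for s in scans}
        if config.skip_sasa or not config.structures:
            sasa_df = pd.DataFrame()
        else:
            sasa_df, timings["sasa"] = _sasa(config, base_dir, out_dir, n_trp_by_sample)
        stats_block, timings["stats"] = _stats(results, table, sasa_df, config)
    finally:
        logger.removeHandler(handler)
        handler.close()
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "reesfit_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {
            "manifest": config.manifest,
            "emission_window": list(config.emission_window),
            "csm_r_bounds": list(config.csm_r_bounds),
            "temperature": config.temperature,
            "m_display_scale": config.m_display_scale,
            "skip_sasa": config.skip_sasa,
        },
        "n_scans": len(scans),
        "groups": {
            res.group_label: {
                "shared_csm_r": res.shared_csm_r,
                "shared_csm_r_se": res.shared_csm_r_se,
                "converged": res.diagnostics.converged,
                "identifiable": res.diagnostics.identifiable,
                "objective": res.diagnostics.objective,
            }
            for res in results
        },
        "parameter_table": table.to_dict(orient="records"),
        "sasa": sasa_df.to_dict(orient="records") if len(sasa_df) else [],
        "stats": stats_block,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
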