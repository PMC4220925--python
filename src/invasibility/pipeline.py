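"""End-to-end orchestration: ingest/simulate -> score -> metrics -> tests
-> deviance partition, with CSV reports and a machine-readable run summary.

The stage order mirrors the analysis design: sites are scored and split
into reference vs disturbed, community invasibility metrics are tabulated
per river type, the nonparametric battery contrasts strata and river types,
and finally each focal non-native species gets an occurrence (binomial) and
a density-class (Poisson) deviance partition over the environmental,
pressure and spatial variable sets.

All interchange files are UTF-8 comma-separated CSV with a header row and
"." decimal separator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import glm, metrics, pressure, simulate, stats
from .partition import DeviancePartition, build_spatial_terms

#: Default predictor sets over the simulated site-table schema.
DEFAULT_ENV_TERMS = list(simulate.ENV_VARS)
DEFAULT_PRESSURE_TERMS = (
    [f"pressure_{c}" for c in pressure.CRITERIA] + list(pressure.CHEMISTRY_VARS)
)
#: Linear measurements that get the log(x+1) transform before modelling.
DEFAULT_LOG_VARS = ["precipitation", "altitude", "drainage_area",
                    *pressure.CHEMISTRY_VARS]


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    Exactly one of ``sites_csv`` (with ``densities_csv``) or ``simulation``
    must be set. ``species_origins`` maps species name -> origin and is
    required when reading a density table.
    """

    outdir: str = "invasibility_run"
    seed: int = 0
    sites_csv: str | None = None
    densities_csv: str | None = None
    species_origins: dict[str, str] = field(default_factory=dict)
    simulation: dict | None = None
    focal_species: list[str] | None = None
    env_terms: list[str] = field(default_factory=lambda: list(DEFAULT_ENV_TERMS))
    pressure_terms: list[str] = field(
        default_factory=lambda: list(DEFAULT_PRESSURE_TERMS))
    log_vars: list[str] = field(default_factory=lambda: list(DEFAULT_LOG_VARS))
    proportion_vars: list[str] = field(default_factory=list)
    class_bounds: tuple[int, int, int, int] = pressure.DEFAULT_CLASS_BOUNDS
    spearman_threshold: float = 0.75
    vif_cap: float = 3.0
    min_focal_foc: float = 0.05
    select: bool = True

    def __post_init__(self) -> None:
        has_files = self.sites_csv is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError("set exactly one of sites_csv or simulation")
        if has_files and self.densities_csv is None:
            raise ValueError("densities_csv required alongside sites_csv")
        if self.spearman_threshold <= 0 or self.vif_cap <= 0:
            raise ValueError("thresholds must be positive")


def load_config(path) -> PipelineConfig:
    """Read a YAML config file into a :class:`PipelineConfig`."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "class_bounds" in raw:
        raw["class_bounds"] = tuple(raw["class_bounds"])
    return PipelineConfig(**raw)


@dataclass
class RunReport:
    """Run provenance plus the file produced by each stage."""

    outdir: str
    seed: int
    config_hash: str
    outputs: dict[str, str] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)
    failed_stage: str | None = None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_site_table(path) -> list[simulate.SiteRecord]:
    """Read and validate a site CSV into site records.

    Requires columns ``site_id``, ``river_type``, ``x``, ``y`` and the ten
    ``pressure_<criterion>`` columns; environmental and chemistry columns
    are carried through. Validation failures name the row (1-based, after
    the header) and column.
    """
    frame = pd.read_csv(path)
    required = ["site_id", "river_type", "x", "y"] + [
        f"pressure_{c}" for c in pressure.CRITERIA]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    errors = []
    for c in pressure.CRITERIA:
        col = f"pressure_{c}"
        bad = frame.index[~frame[col].isin([1, 2, 3, 4, 5])]
        errors += [f"row {i + 1}, column {col}: score {frame.at[i, col]!r} "
                   f"outside 1..5" for i in bad]
    for col in ("x", "y"):
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        errors += [f"row {i + 1}, column {col}: not a number" for i in bad]
    if frame["site_id"].duplicated().any():
        errors.append("duplicate site_id values")
    if errors:
        raise ValueError("invalid site table:\n" + "\n".join(errors[:20]))
    env_cols = [c for c in simulate.ENV_VARS if c in frame.columns]
    chem_cols = [c for c in pressure.CHEMISTRY_VARS if c in frame.columns]
    records = []
    for _, row in frame.iterrows():
        records.append(simulate.SiteRecord(
            site_id=str(row["site_id"]),
            river_type=str(row["river_type"]),
            x=float(row["x"]), y=float(row["y"]),
            environment={c: float(row[c]) for c in env_cols},
            pressure_scores={c: int(row[f"pressure_{c}"])
                             for c in pressure.CRITERIA},
            chemistry={c: float(row[c]) for c in chem_cols},
            disturbance=float(row.get("disturbance", np.nan)),
        ))
    return records


def read_density_table(path, origins: Mapping[str, str]
                       ) -> metrics.SpeciesDensityTable:
    """Read and validate a wide density CSV (site_id + one column/species)."""
    frame = pd.read_csv(path)
    if "site_id" not in frame.columns:
        raise ValueError("density table needs a site_id column")
    species_cols = [c for c in frame.columns if c != "site_id"]
    missing = [c for c in species_cols if c not in origins]
    if missing:
        raise ValueError(f"no origin recorded for species: {missing}")
    errors = []
    for col in species_cols:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.isna() | (vals < 0)]
        errors += [f"row {i + 1}, column {col}: density {frame.at[i, col]!r} "
                   f"invalid (must be >= 0)" for i in bad]
    if errors:
        raise ValueError("invalid density table:\n" + "\n".join(errors[:20]))
    return metrics.SpeciesDensityTable.from_frame(frame, dict(origins))


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in sorted(vars(config).items())},
        sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _simulate_inputs(config: PipelineConfig):
    sim = dict(config.simulation or {})
    species_spec = sim.pop("species", None)
    if species_spec is None:
        species = [metrics.SpeciesInfo(n, "non_native")
                   for n in ("nns_a", "nns_b", "nns_c")]
        species += [metrics.SpeciesInfo(n, "native")
                    for n in ("native_a", "native_b")]
    else:
        species = [metrics.SpeciesInfo(n, o) for n, o in species_spec.items()]
    effect_keys = {"env_coefficients", "pressure_coefficients",
                   "spatial_coefficients", "intercept", "zero_inflation_prob"}
    effect = {k: sim.pop(k) for k in list(sim) if k in effect_keys}
    n_per_type = sim.pop("n_per_type", None)
    specs = simulate.default_river_types()
    if n_per_type is not None:
        specs = [simulate.RiverTypeSpec(s.name, s.temperature,
                                        s.precipitation, s.altitude,
                                        s.drainage_area, int(n_per_type))
                 for s in specs]
    sites = simulate.simulate_sites(specs=specs, seed=config.seed, **sim)
    table = simulate.simulate_densities(
        sites, species,
        simulate.EffectConfig(seed=config.seed + 1, **effect))
    return sites, table


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage, writing one CSV per stage plus a JSON summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=str(outdir), seed=config.seed,
                       config_hash=_config_hash(config))
    stage = "ingest"
    try:
        if config.simulation is not None:
            sites, table = _simulate_inputs(config)
        else:
            sites = read_site_table(config.sites_csv)
            table = read_density_table(config.densities_csv,
                                       config.species_origins)
        frame = simulate.sites_to_frame(sites)
        frame.to_csv(outdir / "sites.csv", index=False)
        table.to_csv(outdir / "densities.csv")
        report.outputs["sites"] = str(outdir / "sites.csv")
        report.outputs["densities"] = str(outdir / "densities.csv")
        report.notices.append(
            f"ingest: {len(frame)} sites, {len(table.species)} species")

        stage = "pressure"
        classif = pressure.classification_report(frame,
                                                 bounds=config.class_bounds)
        classif.to_csv(outdir / "classification.csv", index=False)
        report.outputs["classification"] = str(outdir / "classification.csv")
        n_ref = int(classif["reference"].sum())
        report.notices.append(
            f"pressure: {n_ref} reference / {len(classif) - n_ref} disturbed")

        stage = "metrics"
        reference = pd.Series(classif["reference"].to_numpy(),
                              index=table.sites)
        summary = metrics.type_summary(table, frame, reference=reference)
        summary.to_csv(outdir / "metrics_by_type.csv", index=False)
        report.outputs["metrics"] = str(outdir / "metrics_by_type.csv")

        stage = "tests"
        tests = _stage_tests(frame, table, classif, config, report)
        stats.tidy_results(tests).to_csv(outdir / "tests.csv", index=False)
        report.outputs["tests"] = str(outdir / "tests.csv")

        stage = "partition"
        part_frame, traces = _stage_partition(frame, table, config, report)
        if part_frame is not None:
            part_frame.to_csv(outdir / "partition.csv", index=False)
            traces.to_csv(outdir / "selection_traces.csv", index=False)
            report.outputs["partition"] = str(outdir / "partition.csv")
            report.outputs["selection_traces"] = str(
                outdir / "selection_traces.csv")
    except Exception as err:  # partial outputs stay; failure is flagged
        report.failed_stage = stage
        report.notices.append(f"FAILED at stage {stage}: {err}")
        _write_summary(report, outdir)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    _write_summary(report, outdir)
    return report


def _write_summary(report: RunReport, outdir: Path) -> None:
    payload = {
        "seed": report.seed, "config_hash": report.config_hash,
        "outputs": report.outputs, "notices": report.notices,
        "failed_stage": report.failed_stage,
    }
    with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    report.outputs["summary"] = str(outdir / "run_summary.json")


def _stage_tests(frame, table, classif, config, report):
    nns = table.nonnative_names()
    results: dict[str, stats.TestResult] = {}
    if not nns:
        report.notices.append("tests: no non-native species, stage skipped")
        return results
    ref_mask = classif["reference"].to_numpy()
    nns_density = table.density[nns].sum(axis=1).to_numpy()
    present = (table.density[nns].to_numpy() > 0).any(axis=1)
    k_ref, n_ref = int(present[ref_mask].sum()), int(ref_mask.sum())
    k_dis, n_dis = int(present[~ref_mask].sum()), int((~ref_mask).sum())
    try:
        results["nns_occurrence_ref_vs_disturbed"] = stats.two_proportion_z(
            k_ref, n_ref, k_dis, n_dis)
    except ValueError as err:
        report.notices.append(f"tests: Z test skipped ({err})")
    try:
        results["nns_density_ref_vs_disturbed"] = stats.mann_whitney(
            nns_density[ref_mask], nns_density[~ref_mask])
    except ValueError as err:
        report.notices.append(f"tests: Mann-Whitney skipped ({err})")
    total = classif["total_pressure"].to_numpy()
    try:
        results["nns_density_by_river_type"] = stats.rank_ancova(
            nns_density, frame["river_type"].to_numpy(), total)
    except ValueError as err:
        report.notices.append(f"tests: river-type ANCOVA skipped ({err})")
    env_cols = [c for c in config.env_terms if c in frame.columns]
    try:
        pca1 = stats.pca_first_axis(frame[env_cols]).scores.to_numpy()
        results["nns_density_by_quality_class"] = stats.rank_ancova(
            nns_density, classif["quality_class"].to_numpy(), pca1)
    except ValueError as err:
        report.notices.append(f"tests: quality-class ANCOVA skipped ({err})")
    return results


def _stage_partition(frame, table, config, report):
    nns = table.nonnative_names()
    if not nns:
        report.notices.append("partition: no non-native species, "
                              "stage skipped")
        return None, None
    focal = config.focal_species
    if focal is None:
        focal = [s for s in nns
                 if metrics.frequency_of_occurrence(table, [s])
                 >= config.min_focal_foc]
    if not focal:
        report.notices.append("partition: no species above the occurrence "
                              "floor, stage skipped")
        return None, None

    data = frame.set_index("site_id")
    data = glm.transform_predictors(
        data,
        log_vars=[v for v in config.log_vars if v in data.columns],
        proportion_vars=[v for v in config.proportion_vars
                         if v in data.columns])
    spatial = build_spatial_terms(data[["x", "y"]])
    data = pd.concat([data, spatial], axis=1)

    env_terms = [c for c in config.env_terms if c in data.columns]
    pres_terms = [c for c in config.pressure_terms if c in data.columns]
    env_terms = stats.spearman_screen(data[env_terms],
                                      threshold=config.spearman_threshold,
                                      priorities=env_terms)
    pres_terms = stats.spearman_screen(data[pres_terms],
                                       threshold=config.spearman_threshold,
                                       priorities=pres_terms)
    sets = {"E": env_terms, "P": pres_terms, "S": list(spatial.columns)}

    classes = metrics.density_class_frame(table, focal)
    rows, trace_rows = [], []
    for sp in focal:
        dens = table.density[sp]
        responses = {
            "occurrence": ((dens > 0).astype(int), "binomial_logit"),
            "density_class": (classes[sp], "poisson_log"),
        }
        for kind, (resp, family) in responses.items():
            col = f"_resp_{kind}"
            model_data = data.copy()
            model_data[col] = resp.reindex(model_data.index)
            if model_data[col].nunique() < 2:
                report.notices.append(
                    f"partition: {sp} {kind} constant, skipped")
                continue
            model = DeviancePartition(model_data, col, family, sets,
                                      select=config.select,
                                      vif_cap=config.vif_cap)
            res = model.fit()
            row = res.to_frame()
            row.insert(0, "species", sp)
            row["response"] = kind
            rows.append(row)
            for key, trace in res.traces.items():
                tf = trace.to_frame()
                if len(tf):
                    tf.insert(0, "species", sp)
                    tf.insert(1, "response", kind)
                    tf.insert(2, "set", key)
                    trace_rows.append(tf)
            if res.negative_shared:
                report.notices.append(
                    f"partition: {sp} {kind} negative shared "
                    f"component(s) {res.negative_shared}")
    if not rows:
        report.notices.append("partition: nothing to fit, stage skipped")
        return None, None
    part = pd.concat(rows, ignore_index=True)
    traces = (pd.concat(trace_rows, ignore_index=True)
              if trace_rows else pd.DataFrame(
                  columns=["species", "response", "set", "step", "term"]))
    return part, traces
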