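"""End-to-end orchestration: ingest or simulate, analyse, report.

Stages run in order — ingest -> repertoire filters -> Dice similarity and
matrix permutations (per species) -> binomial GLMMs -> repeatability ->
random-regression model comparison — and every stage logs event counts in
and out, so exclusions (undersampled mothers, non-signallers) stay
auditable.  Direction filtering is centralized here: the redoings analysis
consumes mother-signalled events only, the responsiveness analysis consumes
infant requests; repertoires are built from mother-signalled acts.
Partial failures are recorded as report warnings, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glmm as glmm_mod
from . import reaction_norms as rn
from . import repertoire as rep_mod
from . import synthetic
from .errors import ConfigurationError, ValidationError

__version__ = "0.1.0"

log = logging.getLogger("commvar")

_CATEGORICAL = {
    "species": set(synthetic.SPECIES),
    "setting": set(synthetic.SETTINGS),
    "direction": set(synthetic.DIRECTIONS),
    "context": set(synthetic.CONTEXT_LABELS),
}
_BINARY = ("context_binary", "redo", "satisfactory")
_RANGES = {"infant_age": (1, 7), "parity": (1, 6)}


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    input: str = "simulate"  # path to an event table, or "simulate"
    population: synthetic.PopulationConfig = field(
        default_factory=synthetic.PopulationConfig
    )
    truth: synthetic.TruthParameters = field(default_factory=synthetic.TruthParameters)
    repertoire: synthetic.RepertoireConfig = field(
        default_factory=synthetic.RepertoireConfig
    )
    min_instances: int = 30
    min_type_uses: int = 2
    n_perm: int = 1000
    contrasts: tuple[str, ...] = rep_mod.CONTRASTS
    responses: tuple[str, ...] = ("redo", "satisfactory")
    fit_random_slopes: bool = True
    run_repertoire: bool = True
    run_glmm: bool = True
    n_boot: int = 0
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.input == "simulate":
            self.population.validate()
            self.truth.validate()
            self.repertoire.validate()
        for c in self.contrasts:
            if c not in rep_mod.CONTRASTS:
                raise ConfigurationError(f"contrasts: unknown contrast {c!r}")
        for r in self.responses:
            if r not in glmm_mod.RESPONSES:
                raise ConfigurationError(f"responses: unknown response {r!r}")
        if self.min_instances < 0 or self.min_type_uses < 0:
            raise ConfigurationError("filters: counts must be >= 0")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm: must be >= 1")
        if self.seed is None:
            raise ConfigurationError("seed: mandatory when stochastic stages run")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_as_plain(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_plain(obj):
    """Recursively convert dataclasses/arrays to YAML-safe builtins."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_as_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    return obj


@dataclass
class AnalysisReport:
    """Consolidated machine-readable results of one pipeline run."""

    provenance: dict
    repertoire: dict | None
    models: dict | None
    warnings: list[str]
    # non-serialized attachments (tables) for write_report
    tables: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "provenance": _as_plain(self.provenance),
            "repertoire": _as_plain(self.repertoire),
            "models": _as_plain(self.models),
            "warnings": list(self.warnings),
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def read_events(path) -> pd.DataFrame:
    """Read and validate an event table (CSV, or TSV by extension).

    Validation is row-level: unknown category labels, non-binary flags and
    out-of-range infant_age (1-7) / parity (1-6) are reported with their
    file line numbers (header = line 1).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    events = pd.read_csv(path, sep=sep)
    missing = sorted(set(synthetic.EVENT_COLUMNS) - set(events.columns))
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    problems = []

    def _line(i: int) -> int:
        return int(i) + 2  # header occupies line 1

    for col, allowed in _CATEGORICAL.items():
        bad = ~events[col].isin(allowed)
        for i in events.index[bad][:20]:
            problems.append(
                f"line {_line(i)}: {col}={events.at[i, col]!r} not in {sorted(allowed)}"
            )
    for col in _BINARY:
        bad = ~events[col].isin((0, 1))
        for i in events.index[bad][:20]:
            problems.append(f"line {_line(i)}: {col}={events.at[i, col]!r} not binary")
    for col, (lo, hi) in _RANGES.items():
        vals = pd.to_numeric(events[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        for i in events.index[bad][:20]:
            problems.append(
                f"line {_line(i)}: {col}={events.at[i, col]!r} outside range {lo}-{hi}"
            )
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return events[list(synthetic.EVENT_COLUMNS)]


def _permutation_to_dict(res: rep_mod.PermutationResult) -> dict:
    return {
        "contrast": res.contrast,
        "statistic_observed": float(res.statistic_observed),
        "p_value": float(res.p_value),
        "n_perm": int(res.n_perm),
        "seed": res.seed,
        "significant": bool(res.significant),
    }


def _fit_to_dict(fit: glmm_mod.GlmmFit) -> dict:
    return {
        "beta": {k: float(v) for k, v in fit.beta.items()},
        "se": {k: (None if np.isnan(v) else float(v)) for k, v in fit.se.items()},
        "varcomps": {k: float(v) for k, v in fit.varcomps.items()},
        "loglik": float(fit.loglik),
        "k": int(fit.k),
        "aic": float(fit.aic),
        "converged": bool(fit.converged),
        "n_obs": int(fit.n_obs),
        "boundary": dict(fit.boundary),
        "warnings": list(fit.warnings),
    }


def _repeat_to_dict(res: rn.RepeatabilityResult) -> dict:
    return {
        "R": float(res.R),
        "level": res.level,
        "se": None if res.se is None else float(res.se),
        "ci": None if res.ci is None else [float(res.ci[0]), float(res.ci[1])],
        "p_value": None if res.p_value is None else float(res.p_value),
        "p_reported": None
        if res.p_value is None
        else ("<0.001" if res.p_value < 0.001 else f"{res.p_value:.3f}"),
        "lrt_statistic": None
        if res.lrt_statistic is None
        else float(res.lrt_statistic),
        "n_boot": int(res.n_boot),
        "seed": res.seed,
        "n_boot_failed": int(res.n_boot_failed),
        "high_failure_rate": bool(res.high_failure_rate),
        "note": res.note,
    }


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run all enabled stages and return the consolidated report."""
    config.validate()
    warnings: list[str] = []
    tables: dict = {}

    # --- ingest -----------------------------------------------------------
    if config.input == "simulate":
        pop = dataclasses.replace(config.population, seed=config.seed)
        rcfg = dataclasses.replace(config.repertoire, seed=config.seed)
        roster = synthetic.generate_population(pop)
        events, effects = synthetic.generate_events(roster, config.truth, pop, rcfg)
        tables["truth_mother_effects"] = effects.mother
        tables["truth_group_effects"] = effects.group
    else:
        events = read_events(config.input)
    log.info("ingest: %d events, %d mothers", len(events), events["mother_id"].nunique())

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "input": config.input,
        "n_events": int(len(events)),
        "n_mothers": int(events["mother_id"].nunique()),
        "n_groups": int(events["group_id"].nunique()),
    }

    mother_signalled = events[events["direction"] == "mother_to_infant"]
    infant_requests = events[events["direction"] == "infant_to_mother"]
    log.info(
        "direction split: %d mother-signalled / %d infant requests",
        len(mother_signalled), len(infant_requests),
    )

    # --- repertoire similarity -------------------------------------------
    repertoire_section = None
    if config.run_repertoire:
        repertoire_section = {}
        try:
            reps, excluded = rep_mod.build_repertoires(
                mother_signalled,
                min_instances=config.min_instances,
                min_type_uses=config.min_type_uses,
            )
            log.info(
                "repertoire filters: %d retained, %d excluded", len(reps), len(excluded)
            )
            repertoire_section["n_retained"] = len(reps)
            repertoire_section["n_excluded"] = len(excluded)
            repertoire_section["excluded"] = excluded["mother_id"].tolist()
            tables["repertoire_counts"] = rep_mod.repertoire_table(reps)
            labels = events.drop_duplicates("mother_id")[
                ["mother_id", "setting", "species"]
            ]
            matrix = rep_mod.similarity_matrix(reps, labels)
            tables["similarity_matrix"] = matrix.to_frame()
            per_species = {}
            for sp_i, sp in enumerate(sorted(set(matrix.species))):
                sub = matrix.subset(sp)
                entry = {"n_individuals": len(sub.ids), "dice_means": rep_mod.dyad_means(sub)}
                for c_i, contrast in enumerate(config.contrasts):
                    try:
                        res = rep_mod.matrix_permutation_test(
                            sub,
                            contrast=contrast,
                            n_perm=config.n_perm,
                            seed=int(
                                np.random.SeedSequence(
                                    [config.seed, 101, sp_i, c_i]
                                ).generate_state(1)[0] % (2**31)
                            ),
                        )
                        entry[contrast] = _permutation_to_dict(res)
                    except Exception as exc:  # degenerate contrast on tiny data
                        warnings.append(f"repertoire[{sp}][{contrast}]: {exc}")
                per_species[sp] = entry
            repertoire_section["per_species"] = per_species
        except Exception as exc:
            warnings.append(f"repertoire stage failed: {exc}")

    # --- GLMMs, repeatability, random regression --------------------------
    models_section = None
    if config.run_glmm:
        models_section = {}
        for resp in config.responses:
            sub = mother_signalled if resp == "redo" else infant_requests
            entry: dict = {"n_obs": int(len(sub))}
            try:
                spec = glmm_mod.GlmmSpec(response=resp)
                design = glmm_mod.build_design(sub, spec)
                vres = glmm_mod.vif(design)
                entry["vif"] = {"values": vres.values, "max": vres.max_vif}
                fit_int = glmm_mod.fit_glmm(design)
                entry["fit_intercept"] = _fit_to_dict(fit_int)
                tables[f"blups_{resp}"] = pd.DataFrame(
                    {k: v for k, v in fit_int.blups.items() if k.startswith("mother")}
                )

                reduced = glmm_mod.fit_glmm(
                    design.with_spec(
                        dataclasses.replace(spec, mother_intercept=False)
                    )
                )
                test = glmm_mod.lrt(fit_int, reduced)
                entry["lrt_individual"] = {
                    "statistic": float(test.statistic),
                    "df": int(test.df),
                    "p_value": float(test.p_value),
                    "p_reported": "<0.001"
                    if test.p_value < 0.001
                    else f"{test.p_value:.3f}",
                    "note": test.note,
                }

                boot_seed = int(
                    np.random.SeedSequence([config.seed, 202, hash(resp) % 1000]
                                           ).generate_state(1)[0] % (2**31)
                )
                entry["repeatability"] = {}
                for level in rn.LEVELS:
                    if config.n_boot > 0:
                        res = rn.repeatability_uncertainty(
                            fit_int, level, n_boot=config.n_boot, seed=boot_seed
                        )
                    else:
                        res = rn.repeatability_uncertainty(
                            fit_int, level, n_boot=0
                        )
                    entry["repeatability"][level] = _repeat_to_dict(res)

                if config.fit_random_slopes:
                    fit_slope = glmm_mod.fit_glmm(
                        design.with_spec(dataclasses.replace(spec, mother_slope=True)),
                        start=fit_int.varcomps,
                    )
                    entry["fit_slope"] = _fit_to_dict(fit_slope)
                    comp = rn.compare_models(fit_int, fit_slope)
                    entry["model_comparison"] = {
                        "aic_intercept": float(comp.aic_intercept),
                        "aic_slope": float(comp.aic_slope),
                        "delta_aic": float(comp.delta_aic),
                        "preferred": comp.preferred,
                        "threshold": float(comp.threshold),
                        "lrt_statistic": comp.lrt_statistic,
                        "lrt_df": comp.lrt_df,
                        "lrt_p": comp.lrt_p,
                    }
                    tables[f"reaction_norms_{resp}"] = glmm_mod.predict_reaction_norms(
                        fit_slope
                    )
            except Exception as exc:
                warnings.append(f"glmm[{resp}] stage failed: {exc}")
            models_section[resp] = entry

    report = AnalysisReport(
        provenance=provenance,
        repertoire=repertoire_section,
        models=models_section,
        warnings=warnings,
        tables=tables,
    )
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def write_report(report: AnalysisReport, out_dir) -> list[Path]:
    """Write report.yaml plus delimited tables into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / "report.yaml"]
    (out / "report.yaml").write_text(report.to_yaml(), encoding="utf-8")
    for name, table in report.tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=table.index.name is not None)
        paths.append(p)
    return paths


def read_report(out_dir) -> dict:
    """Read back the YAML report written by :func:`write_report`."""
    with open(Path(out_dir) / "report.yaml", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
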