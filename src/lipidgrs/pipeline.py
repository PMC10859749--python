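"""End-to-end pipeline driver: simulate/load -> QC -> transform -> associate
-> risk scores -> interactions -> report bundle.

``run_pipeline`` chains every stage under one configuration object, writing a
cohort-summary TSV, QC report, association table (with appended GRS/wGRS
rows), score definitions and per-person scores, an interaction table and a
run log carrying the seed, package versions and every threshold used.  Any
stage failure aborts with the stage name; outputs already written stay on
disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, cohort, interactions, io, qc, reference, scores
from ._validation import PipelineError, ValidationError
from .transforms import TraitSummary

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, serializable to/from YAML."""

    out_dir: str = "lipidgrs_out"
    seed: int = 0
    # input paths; None means simulate
    genotypes: str | None = None
    phenotypes: str | None = None
    panel: str | None = None
    genotype_format: str = "csv"
    # simulation
    n: int = cohort.DEFAULT_N
    # simulated per-call completeness; kept above the 0.95 filter so a
    # compliant cohort is not rejected by chance at the threshold boundary
    call_rate: float = 0.98
    # QC
    min_call_rate: float = 0.95
    hwe_threshold: float = qc.STUDY_HWE_THRESHOLD
    hwe_method: str = "auto"
    # transforms
    skew_threshold: float = 1.0
    forced_log: tuple = reference.LOG_TRAITS
    # association
    traits: tuple = reference.TRAITS
    models: tuple = (1, 2)
    activity_coding: str = "ordinal"
    # risk scores
    selection_alpha: float = 0.05
    weight_model: int = 2
    score_rescale: str = "none"
    standardize_score: bool = False
    # interactions
    modifiers: tuple = interactions.MODIFIERS
    obesity_threshold: float = interactions.DEFAULT_OBESITY_THRESHOLD
    run_interactions: bool = True
    # output
    precision: str = "machine"

    def validate(self):
        if not 0.0 < self.min_call_rate <= 1.0:
            raise ValidationError("min_call_rate must be in (0, 1]")
        if not 0.0 < self.hwe_threshold <= 1.0:
            raise ValidationError("hwe_threshold must be in (0, 1]")
        if not 0.0 < self.selection_alpha < 1.0:
            raise ValidationError("selection_alpha must be in (0, 1)")
        if self.precision not in ("machine", "report"):
            raise ValidationError("precision must be 'machine' or 'report'")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("forced_log", "traits", "models", "modifiers"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for key in ("forced_log", "traits", "models", "modifiers"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs).validate()


@dataclass
class PipelineResult:
    """In-memory handles plus paths of everything the run wrote."""

    config: PipelineConfig
    panel: pd.DataFrame
    genotypes: pd.DataFrame
    cohort_table: pd.DataFrame
    qc_report: pd.DataFrame
    associations: pd.DataFrame
    score_definitions: dict
    score_table: pd.DataFrame
    grs_associations: pd.DataFrame
    interactions: pd.DataFrame | None
    paths: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


@_stage("simulate")
def _obtain_inputs(cfg: PipelineConfig):
    if cfg.genotypes is None:
        G, ct, panel = cohort.simulate_cohort(n=cfg.n, seed=cfg.seed, call_rate=cfg.call_rate)
        return G, ct, panel, True
    panel = io.read_panel(cfg.panel) if cfg.panel else reference.variant_panel()
    loaded = io.read_genotypes(cfg.genotypes, cfg.genotype_format)
    G = loaded[0] if isinstance(loaded, tuple) else loaded
    return G, None, panel, False


@_stage("transform")
def _load_and_summarize(cfg: PipelineConfig, ct):
    if ct is None:
        if cfg.phenotypes is None:
            raise ValidationError("no phenotype table: provide 'phenotypes' or simulate")
        ct = io.read_phenotypes(cfg.phenotypes)
    summaries = []
    for trait in cfg.traits:
        scale = "log" if trait in cfg.forced_log else "normal"
        s = TraitSummary.from_sample(trait, ct[trait].to_numpy(dtype=float), scale)
        summaries.append({"trait": trait, "scale": s.scale, "mean": s.mean, "sd": s.sd})
    z, flags = association.prepare_traits(ct, cfg.traits, cfg.skew_threshold, cfg.forced_log)
    summary_df = pd.DataFrame(summaries)
    summary_df["log_transformed"] = [flags[t] for t in cfg.traits]
    return ct, z, summary_df


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and write the report bundle."""
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    G, ct, panel, simulated = _obtain_inputs(cfg)
    if simulated:
        paths["genotypes"] = out / "genotypes.csv"
        io.write_genotypes(G, paths["genotypes"])
        paths["panel"] = out / "panel.csv"
        io.write_panel(panel, paths["panel"])
        paths["phenotypes"] = out / "phenotypes.csv"
        io.write_phenotypes(ct, paths["phenotypes"])

    ct, z, summary_df = _load_and_summarize(cfg, ct)
    paths["trait_summary"] = out / "trait_summary.tsv"
    io.write_table(summary_df, paths["trait_summary"], cfg.precision)

    try:
        retained, qc_report = qc.qc_filter(
            G, ct["site"].to_numpy(), cfg.min_call_rate, cfg.hwe_threshold, cfg.hwe_method
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", str(exc)) from exc
    paths["qc_report"] = out / "qc_report.tsv"
    io.write_table(qc_report, paths["qc_report"], cfg.precision)

    try:
        kept_panel = panel[panel["rsid"].isin(retained)].reset_index(drop=True)
        assoc = association.run_panel(
            G[retained], ct, kept_panel, cfg.traits, cfg.models,
            cfg.skew_threshold, cfg.forced_log, cfg.activity_coding,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("associate", str(exc)) from exc

    try:
        definitions, score_rows, grs_rows = {}, [], []
        for trait in cfg.traits:
            try:
                definition = scores.build_score_definition(
                    assoc, trait, cfg.selection_alpha, cfg.weight_model,
                    rescale=cfg.score_rescale, panel_order=list(kept_panel["rsid"]),
                )
            except ValidationError:
                continue  # no dual-significant variant for this trait
            definitions[trait] = definition
            u = scores.compute_ugrs(G, definition)
            w = scores.compute_wgrs(G, definition)
            score_rows.append(pd.DataFrame({"trait": trait, "uGRS": u, "wGRS": w}))
            for label, s in (("GRS", u), ("wGRS", w)):
                res = scores.grs_association(
                    s, ct, z[trait], trait, standardize_score=cfg.standardize_score
                )
                grs_rows.append(
                    {"score": label, "trait": trait, "model": 1, "beta": res.beta,
                     "se": res.se, "p": res.p, "n_used": res.n_used,
                     "n_variants": len(definition.rsids)}
                )
        score_table = (
            pd.concat(score_rows).rename_axis("sample_id").reset_index()
            if score_rows else pd.DataFrame()
        )
        grs_assoc = pd.DataFrame(grs_rows)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("grs", str(exc)) from exc

    paths["associations"] = out / "associations.tsv"
    io.write_table(assoc, paths["associations"], cfg.precision)
    paths["grs_associations"] = out / "grs_associations.tsv"
    io.write_table(grs_assoc, paths["grs_associations"], cfg.precision)
    if len(score_table):
        paths["scores"] = out / "scores.tsv"
        io.write_table(score_table, paths["scores"], cfg.precision)
    if definitions:
        paths["score_definitions"] = out / "score_definitions.json"
        with open(paths["score_definitions"], "w") as fh:
            json.dump(
                {t: dataclasses.asdict(d) for t, d in definitions.items()}, fh, indent=2
            )

    inter = None
    if cfg.run_interactions:
        try:
            inter = interactions.interaction_screen(
                G[retained], ct, kept_panel, cfg.traits, cfg.modifiers,
                obesity_threshold=cfg.obesity_threshold,
                skew_threshold=cfg.skew_threshold, forced_log=cfg.forced_log,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("interact", str(exc)) from exc
        paths["interactions"] = out / "interactions.tsv"
        io.write_table(inter, paths["interactions"], cfg.precision)

    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg.to_dict(),
        "n_samples": int(len(ct)),
        "variants_retained": retained,
    }
    paths["run_log"] = out / "run_log.yaml"
    with open(paths["run_log"], "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)

    return PipelineResult(
        cfg, panel, G, ct, qc_report, assoc, definitions, score_table, grs_assoc, inter,
        {k: str(v) for k, v in paths.items()},
    )
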