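"""End-to-end orchestration: simulate/read -> chemistry -> ordination ->
temporal enrichment -> resource use, with a serializable run report.

All randomness flows from one root seed; each stochastic stage draws a
derived seed that is recorded in the report, so a report suffices to
re-execute an identical run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemistry, ecology, io, resource_use, simulate, temporal
from .containers import AbundanceMatrix, IntensityMatrix
from .temporal import ThresholdSpec

__all__ = ["PipelineConfig", "RunReport", "run_all", "stage_seed"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one full pipeline run.

    Either ``simulation`` is set (synthetic mode) or the three input paths
    are, never neither.
    """

    output_dir: str = "domlink_out"
    simulation: simulate.SimulationConfig | None = None
    intensity_path: str | None = None
    abundance_path: str | None = None
    metadata_path: str | None = None
    formulas_path: str | None = None
    min_reps: int = 2
    time_top_fraction: float = 0.05
    species_top_fraction: float = 0.025
    time_negative_top_fraction: float = 0.025
    alpha: float = 0.05
    n_perm: int = 999
    n_perm_species: int = 999
    dbrda_inertia_target: float = 0.9
    days_allowed: tuple[int, ...] | None = (1, 4, 7, 14)
    seed: int = 0

    def __post_init__(self) -> None:
        synthetic = self.simulation is not None
        paths = all(
            p is not None
            for p in (self.intensity_path, self.abundance_path, self.metadata_path)
        )
        if not synthetic and not paths:
            raise ValueError(
                "either a SimulationConfig or the three input CSV paths are required"
            )


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    h = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    config: dict
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def add(self, name: str, **record) -> None:
        self.stages.append({"stage": name, **record})

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "config": self.config,
                "stages": self.stages,
                "warnings": self.warnings,
                "outputs": self.outputs,
            },
            indent=2,
            default=_jsonable,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, pd.Series)):
        return np.asarray(obj).tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def run_all(cfg: PipelineConfig) -> RunReport:
    """Execute every stage and write all artifacts under ``cfg.output_dir``."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(cfg))
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # -- stage 1: data ------------------------------------------------
        truth = None
        if cfg.simulation is not None:
            sim = simulate.simulate(cfg.simulation)
            m, ab, truth = sim.intensity, sim.abundance, sim.truth
            annotations = sim.library.annotations
            io.write_formulas(annotations, out / "formulas.csv")
            io.write_intensity(m, out / "intensity.csv")
            io.write_abundance(ab, out / "abundance.csv")
            io.write_metadata(m.samples, out / "metadata.csv")
            io.write_truth(truth.links, out / "truth.csv")
            (out / "simulation_config.yaml").write_text(
                yaml.safe_dump(dataclasses.asdict(cfg.simulation))
            )
            report.add("simulate", seed=cfg.simulation.seed,
                       n_links=len(truth.links))
        else:
            m, ab, meta = io.read_tables(
                cfg.intensity_path,
                cfg.abundance_path,
                cfg.metadata_path,
                days_allowed=cfg.days_allowed,
            )
            if cfg.formulas_path is None:
                raise ValueError("formulas_path is required when reading tables")
            formulas = pd.read_csv(cfg.formulas_path).set_index("formula_id")
            annotations = chemistry.annotate_formulas(formulas)
            report.add("read_tables", n_samples=m.values.shape[1])

        # -- stage 2: chemistry -------------------------------------------
        if not m.normalized:
            m = chemistry.normalize_tic(m)
        filtered = chemistry.replicate_presence_filter(m, min_reps=cfg.min_reps)
        bulk = chemistry.bulk_metrics(filtered, annotations)
        io.write_table(
            bulk.reset_index(names="sample"), out / "bulk_metrics.csv"
        )
        io.write_table(
            annotations.reset_index(), out / "annotations.csv"
        )
        report.add("chemistry", n_formulae=int((filtered.values.sum(axis=1) > 0).sum()),
                   min_reps=cfg.min_reps)

        # -- stage 3: multivariate ecology --------------------------------
        dom = filtered.without_controls()
        com = ab.without_controls()
        shared = [c for c in dom.samples.index if c in set(com.samples.index)]
        dom_s = dom.subset_samples(dom.samples.index.isin(shared))
        com_s = com.subset_samples(com.samples.index.isin(shared))
        d_dom = ecology.bray_curtis(dom_s)
        d_com = ecology.bray_curtis(com_s)
        ord_dom = ecology.pcoa(d_dom)
        ord_com = ecology.pcoa(d_com)
        io.write_table(ord_dom.coords.reset_index(names="sample"),
                       out / "pcoa_dom.csv")
        io.write_table(ord_com.coords.reset_index(names="sample"),
                       out / "pcoa_community.csv")
        s_perm = stage_seed(cfg.seed, "permanova")
        perm = ecology.permanova(
            d_com, com_s.samples["source"], n_perm=cfg.n_perm, seed=s_perm
        )
        bulk_vars = bulk.loc[shared, ["weighted_hc", "weighted_oc",
                                      "weighted_aimod", "weighted_mass",
                                      "bioavailable_fraction"]]
        s_env = stage_seed(cfg.seed, "envfit")
        envfit = ecology.envfit_vectors(
            ord_dom, bulk_vars, n_perm=cfg.n_perm, seed=s_env
        )
        io.write_table(envfit.reset_index(), out / "envfit.csv")
        s_proc = stage_seed(cfg.seed, "procrustes")
        proc = ecology.procrustes_protest(
            ord_dom, ord_com, n_perm=cfg.n_perm, seed=s_proc
        )
        cum = np.cumsum(ord_dom.prop_explained)
        n_axes = int(np.searchsorted(cum, cfg.dbrda_inertia_target) + 1)
        n_axes = min(n_axes, ord_dom.coords.shape[1])
        s_db = stage_seed(cfg.seed, "dbrda")
        db = ecology.dbrda(
            d_com, ord_dom.coords.iloc[:, :n_axes],
            n_perm=cfg.n_perm, seed=s_db,
        )
        ecology_stats = {
            "permanova": dataclasses.asdict(perm),
            "procrustes": dataclasses.asdict(proc),
            "dbrda": {**dataclasses.asdict(db), "n_predictor_axes": n_axes},
        }
        (out / "ecology_stats.json").write_text(
            json.dumps(ecology_stats, indent=2, default=_jsonable)
        )
        report.add("ecology", permanova_f=perm.pseudo_f, permanova_p=perm.p_value,
                   procrustes_m2=proc.m2, procrustes_p=proc.p_value,
                   dbrda_r2=db.r2, dbrda_p=db.p_value,
                   seeds={"permanova": s_perm, "envfit": s_env,
                          "procrustes": s_proc, "dbrda": s_db})

        # -- stage 4: temporal enrichment ---------------------------------
        time_corrs = temporal.correlate_time(filtered, min_reps=cfg.min_reps)
        spec_time = ThresholdSpec(top_fraction=cfg.time_top_fraction, sided="two")
        time_flagged, time_cut = temporal.percentile_threshold(time_corrs, spec_time)
        s_enrich = stage_seed(cfg.seed, "enrichment")
        enrichment = temporal.class_enrichment(
            time_flagged, annotations,
            top_fraction=cfg.time_top_fraction, alpha=cfg.alpha, seed=s_enrich,
        )
        io.write_table(time_flagged, out / "time_correlations.csv")
        io.write_table(enrichment, out / "enrichment.csv")
        report.add("enrich", realized_cutoff=time_cut, seed=s_enrich,
                   n_correlations=len(time_flagged))

        # -- stage 5: resource use ----------------------------------------
        sp_corrs = resource_use.correlate_species(com, filtered,
                                                  min_reps=cfg.min_reps)
        profile = resource_use.putative_use(
            sp_corrs, annotations,
            ThresholdSpec(top_fraction=cfg.species_top_fraction, sided="negative"),
        )
        s_diff = stage_seed(cfg.seed, "species_difference")
        diff = resource_use.species_difference_test(
            profile, n_perm=cfg.n_perm_species, seed=s_diff
        )
        joint = resource_use.joint_depletion(
            sp_corrs, time_corrs,
            species_spec=ThresholdSpec(top_fraction=cfg.species_top_fraction,
                                       sided="negative"),
            time_spec=ThresholdSpec(top_fraction=cfg.time_negative_top_fraction,
                                    sided="negative"),
        )
        io.write_table(profile.cells, out / "profile.csv")
        io.write_table(joint.counts, out / "joint.csv")
        contrasts = {
            "global_statistic": diff.statistic,
            "global_p": diff.p_value,
            "n_permutations": diff.n_permutations,
            "seed": s_diff,
            "pairwise": diff.contrasts.to_dict(orient="records"),
        }
        (out / "contrasts.json").write_text(
            json.dumps(contrasts, indent=2, default=_jsonable)
        )
        rec = None
        if truth is not None and len(truth.links):
            rec = simulate.recovery_metrics(joint.predicted_links, truth)
        report.add(
            "resource_use",
            species_cutoff=joint.species_cutoff,
            time_cutoff=joint.time_cutoff,
            species_means=profile.species_means.to_dict(),
            global_p=diff.p_value,
            seed=s_diff,
            recovery=dataclasses.asdict(rec) if rec else None,
        )
        caught = [str(w.message) for w in wlist]

    report.warnings = caught
    report.outputs = {
        p.name: str(p) for p in sorted(out.iterdir()) if p.is_file()
    }
    report.to_json(out / "run_report.json")
    return report
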