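"""End-to-end orchestration: simulate/load -> filter -> DE -> enrichment ->
concordance -> clock -> physiological overlap, with a run manifest.

Stages communicate only through the documented interchange files (ADAT-lite
tables, GMT, TSV/JSON outputs), so every stage can be re-run standalone from
the files the previous stage wrote. All randomness flows from one base seed;
two runs with the same resolved config produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import clock as clock_mod
from . import concordance as conc_mod
from . import diffexpr
from . import enrichment as enr_mod
from . import panel_io
from . import simkit

log = logging.getLogger("secretoclock")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run (YAML/JSON round-trippable)."""

    seed: int = 0
    simulate: bool = True
    sim: simkit.SimulationConfig = field(default_factory=simkit.SimulationConfig)
    # input paths, used when simulate is false
    study_table: str | None = None
    study_panel: str | None = None
    reference_table: str | None = None
    reference_panel: str | None = None
    gene_sets: str | None = None
    input_scale: str = "raw"            # raw RFU (log2-transformed on read) or log2
    # analysis switches
    moderation: bool = True
    weights: bool = True
    penalize_batch: bool = True
    # thresholds
    de_fdr: float = 0.05
    enrich_fdr: float = 0.1
    top_k: int = 500
    min_set: int = 5
    clock_iters: int = 200
    min_controls: int = 3
    freq_threshold: float = 0.30
    clock_folds: int = 10
    clock_n_lambda: int = 100
    young_window: tuple[float, float] = (3.0, 6.0)
    old_window: tuple[float, float] = (18.0, 21.0)
    phys_fdr: float = 0.1

    def __post_init__(self) -> None:
        for name, v, lo, hi in (
            ("de_fdr", self.de_fdr, 0, 1),
            ("enrich_fdr", self.enrich_fdr, 0, 1),
            ("freq_threshold", self.freq_threshold, 0, 1),
            ("phys_fdr", self.phys_fdr, 0, 1),
        ):
            if not lo < v <= hi:
                raise ValueError(f"{name} must be in ({lo}, {hi}], got {v}")
        if self.top_k <= 0 or self.clock_iters <= 0 or self.min_controls < 1:
            raise ValueError("top_k, clock_iters and min_controls must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["young_window"] = list(self.young_window)
        d["old_window"] = list(self.old_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = simkit.SimulationConfig.from_dict(d["sim"])
        for key in ("young_window", "old_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def simulated_gene_sets(
    panel: panel_io.AptamerPanel,
    truth: simkit.SimulationTruth,
    seed: int,
    n_random_sets: int = 20,
) -> panel_io.GeneSetCollection:
    """Gene sets for the enrichment stage of a simulated run: random sets
    drawn from the panel plus one set concentrated in the injected
    downregulated proteins (which enrichment should flag)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    genes = sorted(panel.gene_symbols())
    sets: dict[str, set[str]] = {}
    for i in range(n_random_sets):
        size = int(rng.integers(10, 51))
        sets[f"RANDOM_{i + 1:02d}"] = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
    t = truth.per_aptamer
    sym_of = panel.table.set_index("aptamer_id")["gene_symbol"]
    down = t.loc[t["effect_lmna"] < 0].sort_values("effect_lmna")
    down_genes = [sym_of[a] for a in down["aptamer_id"].head(40) if sym_of[a]]
    if len(down_genes) >= 5:
        sets["INJECTED_DOWN"] = set(down_genes)
    return panel_io.GeneSetCollection(sets)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; write the report bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "thresholds": {
            "de_fdr": config.de_fdr,
            "enrich_fdr": config.enrich_fdr,
            "top_k": config.top_k,
            "clock_iters": config.clock_iters,
            "min_controls": config.min_controls,
            "freq_threshold": config.freq_threshold,
        },
        "versions": _versions(),
        "inputs": {},
        "tables": {},
    }
    config.to_yaml(outdir / "config.yaml")
    results: dict = {}
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        stage = "inputs"
        truth = None
        if config.simulate:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            panel = simkit.simulate_panel(sim_cfg)
            fpanel, _, _ = panel_io.filter_panel(panel)
            ref_matrix, ref_meta, truth = simkit.simulate_aging_cohort(fpanel, sim_cfg)
            study_matrix, study_meta, _ = simkit.simulate_progeria_cohorts(fpanel, sim_cfg)
            gene_sets = simulated_gene_sets(fpanel, truth, config.seed)
            manifest["inputs"]["simulation"] = hashlib.sha256(
                json.dumps(sim_cfg.to_dict(), sort_keys=True).encode()
            ).hexdigest()
            truth.to_json(outdir / "simulation_truth.json")
        else:
            for key in ("study_table", "study_panel", "reference_table", "reference_panel", "gene_sets"):
                path = getattr(config, key)
                if path is None:
                    raise ValueError(f"simulate=false requires {key}")
                manifest["inputs"][key] = _sha256(path)
            study_matrix, panel, study_meta = panel_io.read_proteome_table(
                config.study_table, scale=config.input_scale, panel_path=config.study_panel
            )
            ref_matrix, ref_panel_raw, ref_meta = panel_io.read_proteome_table(
                config.reference_table, scale=config.input_scale, panel_path=config.reference_panel
            )
            gene_sets = panel_io.read_gmt(config.gene_sets)

        # ------------------------------------------------------------ filter
        stage = "filter"
        if config.simulate:
            # cohorts were simulated on the already-filtered panel; report the
            # filtering of the raw simulated panel
            _, _, report = panel_io.filter_panel(panel)
            study_panel_f = ref_panel_f = fpanel
        else:
            study_panel_f, study_matrix, report = panel_io.filter_panel(panel, study_matrix)
            ref_panel_f, ref_matrix, _ = panel_io.filter_panel(ref_panel_raw, ref_matrix)
        report.to_json(outdir / "filter_report.json")
        log.info("stage=filter seed=%d kept=%d of %d", config.seed, report.n_kept, report.n_input)

        # ------------------------------------------------------------ DE
        stage = "differential_expression"
        de_kwargs = dict(moderation=config.moderation, weights=config.weights, fdr_threshold=config.de_fdr)
        global_de, global_summary = diffexpr.run_de(
            study_matrix, study_meta, panel=study_panel_f, **de_kwargs
        )
        diffexpr.write_de_table(outdir / "de_global.tsv", global_de)
        results["de_global_summary"] = global_summary
        model_de = {}
        for model in sorted(study_meta.table["model"].unique()):
            sub_meta = study_meta.subset(
                study_meta.table.loc[study_meta.table["model"] == model, "sample_id"]
            )
            sub_matrix = study_matrix.subset_samples(sub_meta.sample_ids)
            tbl, summ = diffexpr.run_de(sub_matrix, sub_meta, panel=study_panel_f, **de_kwargs)
            model_de[model] = tbl
            diffexpr.write_de_table(outdir / f"de_{model}.tsv", tbl)
            results[f"de_{model}_summary"] = summ
            log.info("stage=de model=%s seed=%d rows=%d n_de=%d", model, config.seed, len(tbl), summ["n_de"])

        stage = "interaction"
        inter = diffexpr.test_interaction(study_matrix, study_meta, panel=study_panel_f,
                                          fdr_threshold=config.de_fdr,
                                          moderation=config.moderation, weights=config.weights)
        diffexpr.write_de_table(outdir / "interaction_global.tsv", inter)
        results["n_interaction_significant"] = int(inter["is_de"].sum())

        # ------------------------------------------------------------ enrichment
        stage = "enrichment"
        enr = enr_mod.run_enrichment(
            global_de, gene_sets, study_panel_f,
            k=config.top_k, fdr_keep=config.enrich_fdr, min_set=config.min_set,
        )
        enr_mod.write_enrichment_table(outdir / "enrichment.tsv", enr)
        results["n_enriched_sets"] = int(enr["reported"].sum()) if len(enr) else 0
        log.info("stage=enrichment seed=%d sets_tested=%d", config.seed, len(enr))

        # ------------------------------------------------------------ concordance
        stage = "concordance"
        models = sorted(model_de)
        if len(models) == 2:
            de_A, de_B = model_de[models[0]], model_de[models[1]]
            overlap = conc_mod.overlap_de(de_A, de_B)
            concord = conc_mod.fold_change_concordance(de_A, de_B)
            conc_mod.concordance_points(de_A, de_B).to_csv(
                outdir / "concordance_points.tsv", sep="\t", index=False
            )
            results["overlap"] = overlap.to_dict()
            results["concordance"] = concord.to_dict()

        # ------------------------------------------------------------ clock
        stage = "clock"
        feature_space = clock_mod.intersect_by_gene(ref_panel_f, study_panel_f)
        ensemble = clock_mod.build_clock_ensemble(
            ref_matrix, ref_meta, study_matrix, study_meta, feature_space,
            n_iter=config.clock_iters,
            min_train_controls=config.min_controls,
            min_infer_controls=config.min_controls,
            seed=config.seed,
            penalize_batch=config.penalize_batch,
            n_folds=config.clock_folds,
            n_lambda=config.clock_n_lambda,
        )
        ensemble.to_json(outdir / "clock_ensemble.json")
        ensemble.predictions.to_csv(outdir / "clock_predictions.tsv", sep="\t", index=False)
        freq = clock_mod.selection_frequency(ensemble, threshold=config.freq_threshold)
        freq.to_csv(outdir / "clock_selection_frequency.tsv", sep="\t", index=False)
        results["median_age_gap"] = {k: float(v) for k, v in ensemble.median_age_gap().items()}
        log.info("stage=clock seed=%d n_iter=%d n_features=%d", config.seed, ensemble.n_iter, len(feature_space))

        # ------------------------------------------------------------ physiological overlap
        stage = "physiological_overlap"
        results["physiological_overlap"] = conc_mod.physiological_overlap(
            ref_matrix, ref_meta, study_matrix, study_meta, feature_space,
            young_window=config.young_window, old_window=config.old_window,
            fdr=config.phys_fdr, moderation=config.moderation, weights=config.weights,
        )

        stage = "report"
        manifest["tables"] = {p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))}
        (outdir / "summary.json").write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:  # partial outputs retained, stage recorded
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(stage, exc) from exc
    return results


def _versions() -> dict:
    import numpy, pandas, scipy, sklearn, statsmodels

    from . import __version__

    return {
        "secretoclock": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
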