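"""End-to-end orchestration: simulate/ingest -> QC -> GRM -> mixed models ->
GEBVs -> selection index -> donor lists, with a checksummed run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gblup as gb
from .exceptions import ConfigurationError
from .lmm import MixedModel
from .markers import MarkerPanel, compute_grm, impute_missing, qc_markers
from .phenotypes import TRAITS, bonferroni_outlier_filter, plots_to_traits, stress_impact
from .simulate import SimConfig, TrialSimulator

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or file-based inputs)."""

    synthetic: SimConfig | None = None
    phenotype_csv: str | None = None
    marker_csv: str | None = None
    marker_vcf: str | None = None
    out_dir: str = "agscreen_run"
    seed: int = 0
    # marker QC
    sample_call_min: float = 0.66
    marker_call_min: float = 0.90
    maf_min: float = 0.01
    het_max: float = 0.10
    grm_ridge: float = 1e-6
    # phenotype QC / model
    outlier_alpha: float = 0.05
    blocks: str = "fixed"
    reml_tol: float = 1e-8
    reml_max_iter: int = 500
    # selection
    index_weights: dict[str, float] = field(
        default_factory=lambda: dict(gb.DEFAULT_INDEX_WEIGHTS))
    selection_rules: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(gb.DEFAULT_SELECTION_RULES))
    standardize_index: bool = True

    def validate(self) -> None:
        real = any([self.phenotype_csv, self.marker_csv, self.marker_vcf])
        if self.synthetic is not None and real:
            raise ConfigurationError(
                "configure either synthetic mode or real input paths, not both"
            )
        if self.synthetic is None:
            if not self.phenotype_csv or not (self.marker_csv or self.marker_vcf):
                raise ConfigurationError(
                    "file mode needs phenotype_csv and one of marker_csv/marker_vcf"
                )
        if self.marker_csv and self.marker_vcf:
            raise ConfigurationError("give markers as CSV or VCF, not both")

    # ------------------------------ YAML ------------------------------ #
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            sd = d["synthetic"]
            sd["trait_genetic_correlation"] = np.asarray(
                self.synthetic.trait_genetic_correlation, float
            ).tolist()
            sd["maf_range"] = list(self.synthetic.maf_range)
        d["selection_rules"] = {k: list(v) for k, v in self.selection_rules.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            sd = dict(d["synthetic"])
            if "trait_genetic_correlation" in sd:
                sd["trait_genetic_correlation"] = np.asarray(
                    sd["trait_genetic_correlation"], float
                )
            if "maf_range" in sd:
                sd["maf_range"] = tuple(sd["maf_range"])
            d["synthetic"] = SimConfig(**sd)
        if "selection_rules" in d:
            d["selection_rules"] = {k: tuple(v) for k, v in d["selection_rules"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _is_check(genotype: str) -> bool:
    return str(genotype).startswith("CHK")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Stages: simulate/ingest, phenotype preparation and outlier screen,
    marker QC + imputation + GRM, per-experiment SEA fits, per-condition
    across fits, MEA fit, GEBVs per environment, selection index, donor
    lists.  All outputs are TSV/CSV under ``cfg.out_dir`` and listed in the
    manifest with SHA-256 checksums.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 3),
                    "ok": exc_type is None,
                }
                if exc_type is not None:
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _Timer()

    # 1. inputs ---------------------------------------------------------- #
    with stage("ingest"):
        if cfg.synthetic is not None:
            sim_cfg = dataclasses.replace(cfg.synthetic, rng_seed=cfg.seed)
            result = TrialSimulator(sim_cfg).run()
            plots, panel = result.plots, result.panel
            fixture_paths = result.write_fixtures(out_dir / "fixtures")
            outputs.update({f"fixture_{k}": v for k, v in fixture_paths.items()})
            truth = result.genetics.true_breeding_values
        else:
            plots = pd.read_csv(cfg.phenotype_csv)
            panel = (
                MarkerPanel.from_csv(cfg.marker_csv)
                if cfg.marker_csv
                else MarkerPanel.from_vcf(cfg.marker_vcf)
            )
            truth = None

    # 2. phenotype preparation ------------------------------------------ #
    with stage("phenotype_prep"):
        table = plots_to_traits(plots)
        table, outlier_report = bonferroni_outlier_filter(table, alpha=cfg.outlier_alpha)
        p = out_dir / "trait_table.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs["trait_table"] = p
        p = out_dir / "outlier_report.tsv"
        outlier_report.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs["outlier_report"] = p
        impact = stress_impact(table)
        p = out_dir / "stress_impact.tsv"
        impact.to_csv(p, sep="\t", index=False, float_format="%.6g")
        outputs["stress_impact"] = p

    # 3. marker QC + GRM ------------------------------------------------- #
    with stage("marker_qc_grm"):
        cleaned, qc_report = qc_markers(
            panel, cfg.sample_call_min, cfg.marker_call_min, cfg.maf_min, cfg.het_max
        )
        qc_report.write(out_dir / "marker_qc.tsv")
        outputs["marker_qc"] = out_dir / "marker_qc.tsv"
        completed = impute_missing(cleaned)
        grm = compute_grm(completed, ridge=cfg.grm_ridge)
        grm.to_tsv(out_dir / "grm.tsv")
        outputs["grm"] = out_dir / "grm.tsv"

    # 4-6. phenotypic mixed models --------------------------------------- #
    fit_rows = []
    blup_frames: dict[str, pd.DataFrame] = {}

    def fit_block(label: str, scope: str, subset: pd.DataFrame):
        preds = {}
        for trait in TRAITS:
            model = MixedModel(scope=scope, blocks=cfg.blocks,
                               tol=cfg.reml_tol, max_iter=cfg.reml_max_iter)
            model.fit(subset[subset["trait"] == trait])
            preds[trait] = model.predict()
            fit_rows.append(
                {
                    "analysis": label,
                    "trait": trait,
                    "sigma2_g": model.varcomp_.sigma2_g,
                    "sigma2_e": model.varcomp_.sigma2_e,
                    "heritability": model.heritability_,
                    "mean_reliability": model.reliability_,
                    "n_obs": model.n_obs_,
                    "converged": model.converged_,
                }
            )
        blup_frames[label] = pd.DataFrame(preds).rename_axis("genotype")

    with stage("sea_fits"):
        cells = sorted(map(tuple, table[["experiment", "condition"]].drop_duplicates().to_numpy()))
        for exp, cond in cells:
            cleaned_sub = table[
                (table["experiment"] == exp) & (table["condition"] == cond)
            ]
            fit_block(f"sea_{exp}_{cond}", "sea", cleaned_sub)

    with stage("across_fits"):
        for cond in sorted(table["condition"].unique()):
            fit_block(f"across_{cond}", "across", table[table["condition"] == cond])

    with stage("mea_fit"):
        fit_block("mea", "mea", table)

    with stage("fit_reports"):
        fits = pd.DataFrame(fit_rows)
        p = out_dir / "fit_summary.tsv"
        fits.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs["fit_summary"] = p
        for label, frame in blup_frames.items():
            p = out_dir / f"blups_{label}.tsv"
            frame.to_csv(p, sep="\t", float_format="%.10g")
            outputs[f"blups_{label}"] = p

    # 7-9. genomic evaluation and donor selection ------------------------ #
    donor_lists: dict[str, pd.DataFrame] = {}
    with stage("gebv_index_select"):
        checks = {g for g in grm.genotype_ids if _is_check(g)}
        germ21_source = {
            "anaerobic": "across_anaerobic",
            "aerobic": "across_aerobic",
            "across": "mea",
        }
        index_frames = []
        for env in gb.ENVIRONMENTS:
            gebvs = gb.gblup_gebvs(
                table, grm, environment=env, blocks=cfg.blocks,
                tol=cfg.reml_tol, max_iter=cfg.reml_max_iter,
            )
            p = out_dir / f"gebvs_{env}.tsv"
            gebvs.to_csv(p, sep="\t", float_format="%.10g")
            outputs[f"gebvs_{env}"] = p
            scorer = gb.SelectionIndexScorer(
                weights=cfg.index_weights, standardize=cfg.standardize_index
            ).fit(gebvs)
            index = scorer.predict(gebvs)
            index_frames.append(index.rename(env))
            germ21 = blup_frames[germ21_source[env]]["germ21_pct"]
            idx_min, germ_min = cfg.selection_rules[env]
            donor_lists[env] = gb.select_donors(
                index, germ21, rule=env, index_min=idx_min, germ_min=germ_min,
                checks=checks,
            )
        p = out_dir / "selection_index.tsv"
        pd.concat(index_frames, axis=1).rename_axis("genotype").to_csv(
            p, sep="\t", float_format="%.10g"
        )
        outputs["selection_index"] = p
        for path in gb.donor_report(donor_lists, out_dir):
            outputs[path.stem] = path

    # optional ground-truth recovery summary (synthetic mode only)
    if cfg.synthetic is not None and truth is not None:
        with stage("truth_recovery"):
            rows = []
            for env in ("anaerobic",):
                gebvs = pd.read_csv(outputs[f"gebvs_{env}"], sep="\t", index_col=0)
                for trait in TRAITS:
                    aligned = truth[trait].reindex(gebvs.index)
                    if aligned.std() > 0 and gebvs[trait].std() > 0:
                        r = float(np.corrcoef(gebvs[trait], aligned)[0, 1])
                    else:
                        r = np.nan
                    rows.append({"environment": env, "trait": trait, "gebv_tbv_corr": r})
            p = out_dir / "truth_recovery.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
            outputs["truth_recovery"] = p

    with stage("manifest"):
        manifest["outputs"] = {
            name: {"path": str(path), "sha256": _sha256(Path(path))}
            for name, path in sorted(outputs.items())
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return manifest
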