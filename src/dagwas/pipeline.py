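"""End-to-end orchestration: QC -> imputation -> PCA -> DoubleML screen ->
PC graph -> role classification -> predictive validation.

Every stage writes its table under the output directory and records its
row/edge counts in a JSON manifest together with the package version, the
global seed and every stage parameter, so a rerun with the same
configuration reproduces all outputs bit for bit.  Per-stage randomness is
derived from the global seed by fixed offsets.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .dml_screen import ScreenConfig, genomic_inflation, run_screen, screening_report
from .pc_graph import learn_graph
from .preprocess import compute_pcs, impute_mean, run_qc
from .roles import classify_roles, concentric_layout, edge_weights
from .validate import compare_feature_sets

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]

# fixed per-stage seed offsets (documented contract)
_STAGE_SEED = {"screen": 11, "graph": 23, "validate": 37}


@dataclass
class PipelineConfig:
    """All pipeline parameters with the study's standard defaults
    (call-rate 0.10, MAF 0.05, 10 PCs, 100 x 5-fold screen at p<1e-4,
    Fisher-Z alpha 0.05)."""

    geno: str = ""
    pheno: str = ""
    out_dir: str = "dagwas_out"
    trait: str = "trait"
    max_missing: float = 0.10
    min_maf: float = 0.05
    n_pcs: int = 10
    n_rep: int = 100
    n_folds: int = 5
    p_thresh: float = 1e-4
    stability_pi: float = 0.8
    alpha: float = 0.05
    max_cond: int = 3
    uhs_min_out_degree: int = 2
    ancestral_include_undirected: bool = False
    residualize: bool = False
    n_random_draws: int = 20
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known, extra=unknown)
        for k, v in overrides.items():
            if v is not None:
                setattr(cfg, k, v)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def run_all(
    config: PipelineConfig,
    dosages: pd.DataFrame | None = None,
    phenotype: pd.Series | None = None,
) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    Input tables may be passed in memory (tests, notebooks) or read from
    ``config.geno`` / ``config.pheno``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": {k: v for k, v in asdict(config).items()
                                     if k != "extra"},
                      "stages": {}}

    def stage(name: str):
        logger.info("=== stage %s ===", name)
        return manifest["stages"].setdefault(name, {})

    try:
        if dosages is None:
            dosages = io.read_dosage(config.geno)
        if phenotype is None:
            pheno_table = io.read_phenotype(config.pheno)
            if config.trait not in pheno_table.columns:
                raise StageError("input", "missing-trait",
                                 f"trait {config.trait!r} not in phenotype table")
            phenotype = pheno_table[config.trait]
    except StageError:
        raise
    except Exception as err:
        raise StageError("input", "read-failed", str(err)) from err

    shared = dosages.index.intersection(phenotype.index)
    if len(shared) < len(dosages):
        logger.warning("dropping %d individuals without phenotype",
                       len(dosages) - len(shared))
    dosages = dosages.loc[shared]
    phenotype = phenotype.loc[shared]

    # --- qc + imputation
    s = stage("qc")
    qc_dos, report = run_qc(dosages, config.max_missing, config.min_maf)
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t")
    s.update(markers_in=report.n_markers_in,
             removed_call_rate=report.n_removed_call_rate,
             removed_maf=report.n_removed_maf, markers_out=report.n_markers_out)
    imputed = impute_mean(qc_dos)
    io.write_dosage(imputed, out / "dosages_qc_imputed.tsv")

    # --- pca
    s = stage("pca")
    pcs = compute_pcs(imputed, k=min(config.n_pcs, len(imputed) - 1,
                                     imputed.shape[1]))
    pcs.scores.to_csv(out / "pc_scores.tsv", sep="\t", index_label="individual_id")
    s.update(k=pcs.k, explained_variance_ratio=[round(float(v), 6) for v in
                                                pcs.explained_variance_ratio])

    # --- screen
    s = stage("screen")
    screen_cfg = ScreenConfig(n_rep=config.n_rep, n_folds=config.n_folds,
                              p_thresh=config.p_thresh,
                              stability_pi=config.stability_pi,
                              n_pcs=pcs.k,
                              seed=(config.seed + _STAGE_SEED["screen"]) % 2**31)
    table = run_screen(imputed, phenotype, pcs.scores, screen_cfg)
    table.to_csv(out / "screening.tsv", sep="\t", index=False)
    for name, tab in screening_report(table).items():
        tab.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    selected = list(table.loc[table["selected"], "marker_id"])
    s.update(markers_screened=len(table), selected=len(selected),
             lambda_gc=round(genomic_inflation(table["p"].to_numpy()), 4))
    if not selected:
        raise StageError("screen", "no-selection",
                         "no marker passed stability selection")

    # --- graph
    s = stage("graph")
    data = imputed[selected].copy()
    data[config.trait] = phenotype
    graph = learn_graph(
        data, config.trait, alpha=config.alpha, max_cond=config.max_cond,
        include_undirected=config.ancestral_include_undirected,
        residualize=pcs.scores if config.residualize else None)
    graph = edge_weights(graph, data)
    s.update(nodes=len(graph.nodes), directed_edges=len(graph.directed_edges),
             undirected_edges=len(graph.undirected_edges))

    # --- roles
    s = stage("roles")
    roles = classify_roles(graph, config.trait,
                           uhs_min_out_degree=config.uhs_min_out_degree)
    roles.to_csv(out / "roles.tsv", sep="\t", index=False)
    io.write_graph(graph, out / "causal_graph", roles=roles)
    concentric_layout(roles, config.trait).to_csv(out / "layout.tsv", sep="\t",
                                                  index=False)
    s.update(dps=int((roles["role"] == "DPS").sum()),
             uhs=int((roles["role"] == "UHS").sum()))

    # --- validate
    s = stage("validate")
    if (roles["role"] == "DPS").any():
        report_df = compare_feature_sets(
            imputed, phenotype, roles, n_random_draws=config.n_random_draws,
            n_folds=config.n_folds,
            seed=(config.seed + _STAGE_SEED["validate"]) % 2**31,
            full_selected=selected)
        report_df.to_csv(out / "validation.tsv", sep="\t", index=False)
        s.update({row["feature_set"]: round(float(row["r2"]), 6)
                  for _, row in report_df.iterrows()})
    else:
        logger.warning("no DPS found; skipping predictive validation")
        s.update(skipped="no DPS")

    io.write_manifest(manifest, out / "manifest.json")
    return manifest
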