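"""End-to-end orchestration: simulate/ingest -> QC -> association screens
-> top-feature selection -> bootstrap CGBN + consensus sweep -> pathway
enrichment -> cohort table, with per-stage seeds, logging and a manifest
of content digests so that re-runs with the same config and seed are
reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cohort, ingest, pathways, simulate
from . import network as net
from .datatypes import MISSING_DOSAGE, OmicsDataset, SyntheticConfig
from .simulate import PHENOTYPE_NODE

log = logging.getLogger("bnomics")

_STAGE_STREAMS = ("simulate", "screens", "network", "cv", "enrich")


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    snp_fdr: float = 0.20
    expr_top_k: int = 20
    cpg_per_metabolite: int = 2
    bootstraps: int = 250
    folds: int = 5
    score: net.ScoreConfig = field(default_factory=net.ScoreConfig)
    gene_gmt: str | None = None
    metabolite_gmt: str | None = None
    pathway_graphs: str | None = None
    seed: int = 0
    outdir: str = "bnomics_out"

    def validate(self) -> None:
        if self.synthetic is None and self.input_dir is None:
            raise ValueError("need either synthetic config or input_dir")
        if self.bootstraps < 1 or self.folds < 2:
            raise ValueError("bootstraps must be >= 1 and folds >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        score = raw.pop("score", None)
        cfg = cls(**raw)
        if syn is not None:
            syn = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in syn.items()}
            cfg.synthetic = SyntheticConfig(**syn)
        if score is not None:
            cfg.score = net.ScoreConfig(**score)
        return cfg


def stage_seeds(master: int) -> dict[str, int]:
    """Independent per-stage seeds derived from the master seed."""
    children = np.random.SeedSequence(master).spawn(len(_STAGE_STREAMS))
    return {
        name: int(child.generate_state(1)[0] % (2 ** 31))
        for name, child in zip(_STAGE_STREAMS, children)
    }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_dataset(input_dir: str | Path) -> OmicsDataset:
    """Assemble an OmicsDataset from the standard file layout."""
    d = Path(input_dir)
    cov = ingest.read_covariates(d / "covariates.tsv")
    pheno = ingest.read_phenotype(d / "phenotype.tsv")
    subjects = list(pheno.index)

    def _opt(name: str, kind: str) -> pd.DataFrame | None:
        for suffix in (".tsv", ".vcf"):
            p = d / f"{name}{suffix}"
            if p.exists():
                mat = ingest.read_matrix(p, kind)
                extra = set(mat.columns) - set(subjects)
                if extra:
                    raise ValueError(f"unknown subject ids in {p.name}: "
                                     f"{sorted(extra)[:5]}")
                fill = MISSING_DOSAGE if kind == "genotypes" else np.nan
                return mat.reindex(columns=subjects, fill_value=fill)
        return None

    cpg_type = {}
    if (d / "cpg_types.tsv").exists():
        cpg_type = ingest.read_cpg_types(d / "cpg_types.tsv")
    frames = {
        "metabolites": _opt("metabolites", "metabolites"),
        "expression": _opt("expression", "expression"),
        "methylation": _opt("methylation", "methylation"),
        "genotypes": _opt("genotypes", "genotypes"),
    }
    masks = {}
    for mod, frame in frames.items():
        if frame is None:
            continue
        if mod == "genotypes":
            masks[mod] = (frame != MISSING_DOSAGE).any(axis=0)
        else:
            masks[mod] = frame.notna().any(axis=0)
    return OmicsDataset(
        subjects=subjects, covariates=cov.loc[subjects],
        phenotype=pheno, cpg_type=cpg_type, modality_mask=masks, **frames,
    )


def prepare_network_data(
    dataset: OmicsDataset,
    metabolites: pd.DataFrame,
    top: association.TopFeatures,
) -> tuple[pd.DataFrame, list[net.NodeSpec]]:
    """Assemble the subjects x nodes table fed to the CGBN stage.

    ``metabolites`` is the post-QC matrix on the log2 scale. Continuous
    nodes (metabolites, expression, CpGs, age) are z-scored and
    mean-imputed; SNP dosages and sex are discrete; missing genotypes are
    mode-imputed.
    """
    subjects = dataset.subjects
    cols: dict[str, np.ndarray] = {}
    specs: list[net.NodeSpec] = []

    met_z = ingest.zscore(ingest.mean_impute(metabolites))
    for mid in met_z.index:
        cols[mid] = met_z.loc[mid].reindex(subjects).fillna(0.0).to_numpy()
        specs.append(net.NodeSpec(mid, "continuous"))

    if top.snps and dataset.genotypes is not None:
        for sid in top.snps:
            g = dataset.genotypes.loc[sid].astype(float).replace(
                MISSING_DOSAGE, np.nan)
            mode = g.mode()
            g = g.fillna(mode.iloc[0] if len(mode) else 0).astype(int)
            cols[sid] = g.reindex(subjects).to_numpy()
            specs.append(net.NodeSpec(sid, "discrete", (0, 1, 2)))

    for fid, source, prep in (
        ("expression", dataset.expression,
         lambda m: ingest.zscore(np.log2(ingest.mean_impute(m)))),
        ("methylation", dataset.methylation,
         lambda m: ingest.zscore(ingest.mean_impute(m))),
    ):
        wanted = top.expression if fid == "expression" else top.cpgs
        if wanted and source is not None:
            sub = source.loc[wanted].dropna(axis=1, how="all")
            z = prep(sub)
            for feat in z.index:
                cols[feat] = (z.loc[feat].reindex(subjects)
                              .fillna(0.0).to_numpy())
                specs.append(net.NodeSpec(feat, "continuous"))

    if dataset.covariates is not None:
        age = dataset.covariates["age"].reindex(subjects).astype(float)
        cols["age"] = ((age - age.mean()) / (age.std(ddof=0) or 1.0)).to_numpy()
        specs.append(net.NodeSpec("age", "continuous"))
        cols["sex"] = (dataset.covariates["sex"].reindex(subjects)
                       == "female").astype(int).to_numpy()
        specs.append(net.NodeSpec("sex", "discrete", ("male", "female")))

    cols[PHENOTYPE_NODE] = dataset.phenotype.reindex(subjects).astype(
        int).to_numpy()
    specs.append(net.NodeSpec(PHENOTYPE_NODE, "discrete", (0, 1)))
    return pd.DataFrame(cols, index=subjects), specs


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": []}

    def record(stage: str, t0: float, outputs: dict[str, Path]) -> None:
        manifest["stages"].append({
            "stage": stage,
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {k: {"path": str(p), "sha256": _digest(p)}
                        for k, p in outputs.items()},
        })
        log.info("stage=%s done outputs=%d", stage, len(outputs))

    # --- stage: data
    t0 = time.time()
    truth = None
    if config.synthetic is not None:
        syn = SyntheticConfig(**{**config.synthetic.__dict__,
                                 "seed": seeds["simulate"]})
        dataset, truth = simulate.generate_cohort(syn)
        paths = simulate.write_cohort(dataset, truth, outdir / "cohort")
        record("simulate", t0, paths)
    else:
        dataset = load_dataset(config.input_dir)
        record("ingest", t0, {})

    # --- stage: metabolite QC
    t0 = time.time()
    mets, qc = ingest.filter_metabolites(dataset.metabolites)
    log_mets = np.log2(mets)
    qc_path = outdir / "metabolite_qc.json"
    qc_path.write_text(json.dumps(qc.to_dict(), indent=1))
    corr = ingest.correlation_report(log_mets, threshold_r2=0.9)
    corr_path = outdir / "metabolite_correlations.tsv"
    pd.DataFrame(corr, columns=["feature_a", "feature_b", "r2"]).to_csv(
        corr_path, sep="\t", index=False)
    record("qc", t0, {"metabolite_qc": qc_path, "correlations": corr_path})

    # --- stage: association screens
    t0 = time.time()
    results: dict[str, pd.DataFrame] = {}
    screen_paths: dict[str, Path] = {}
    screens = [
        ("genotypes", ("age", "sex")),
        ("expression", ("age", "sex")),
        ("methylation", ("age", "PC1", "PC2")),
    ]
    for modality, adjustment in screens:
        if getattr(dataset, modality) is None:
            continue
        tab = association.run_screen(dataset, modality, adjustment,
                                     metabolites=log_mets)
        results[modality] = tab
        p = outdir / f"screen_{modality}.tsv"
        tab.to_csv(p, sep="\t", index=False, float_format="%.6g")
        screen_paths[modality] = p
    record("screens", t0, screen_paths)

    # --- stage: top-feature selection (leverage re-check first)
    t0 = time.time()
    for modality, adjustment in screens:
        if modality in results and len(results[modality]):
            results[modality] = association.flag_leverage_for_selection(
                results[modality], dataset, modality, log_mets, adjustment)
    top = association.select_top_features(
        results,
        genotypes=dataset.genotypes,
        snp_fdr=config.snp_fdr,
        expr_top_k=config.expr_top_k,
        cpg_per_metabolite=config.cpg_per_metabolite,
    )
    top_path = outdir / "top_features.json"
    top_path.write_text(json.dumps(top.to_dict(), indent=1))
    record("selection", t0, {"top_features": top_path})

    # --- stage: CGBN
    t0 = time.time()
    data, specs = prepare_network_data(dataset, log_mets, top)
    tally = net.bootstrap_learn(data, specs, config.score,
                                B=config.bootstraps,
                                seed=seeds["network"])
    sweep = net.consensus_sweep(tally, data, specs, config.score,
                                k_folds=config.folds, seed=seeds["cv"],
                                phenotype=PHENOTYPE_NODE)
    tally_path = outdir / "edge_tally.tsv"
    pd.DataFrame(
        [(p, c, f) for (p, c), f in sorted(tally.frequencies.items(),
                                           key=lambda kv: -kv[1])],
        columns=["parent", "child", "frequency"],
    ).to_csv(tally_path, sep="\t", index=False)
    trace_path = outdir / "sweep_trace.tsv"
    sweep.trace_frame().to_csv(trace_path, sep="\t", index=False)
    net_path = outdir / "consensus_network.json"
    sweep.chosen_network.to_json(net_path)
    dot_path = outdir / "consensus_network.dot"
    dot_path.write_text(sweep.chosen_network.to_dot(PHENOTYPE_NODE))
    neighborhood = net.markov_neighborhood(sweep.chosen_network,
                                           PHENOTYPE_NODE)
    summary = {
        "chosen_threshold": sweep.chosen_threshold,
        "cv_auc": sweep.chosen_auc,
        "n_edges": len(sweep.chosen_network.edges),
        "markov_neighborhood": neighborhood,
    }
    summary_path = outdir / "network_summary.json"
    summary_path.write_text(json.dumps(summary, indent=1))
    if truth is not None:
        planted = set(truth.true_markov_neighborhood)
        summary["planted_recovered"] = sorted(planted & set(neighborhood))
        summary_path.write_text(json.dumps(summary, indent=1))
    record("network", t0, {"edge_tally": tally_path, "trace": trace_path,
                           "network": net_path, "dot": dot_path,
                           "summary": summary_path})

    # --- stage: pathway enrichment (only when pathway files supplied)
    if config.gene_gmt or config.metabolite_gmt:
        t0 = time.time()
        ps = pathways.PathwaySet.from_gmt(config.gene_gmt,
                                          config.metabolite_gmt)
        graphs = (pathways.read_pathway_graphs(config.pathway_graphs)
                  if config.pathway_graphs else None)
        query_mets = set(log_mets.index)
        query_genes = set(top.expression)
        enr = pathways.run_integrative_ora(query_genes, query_mets, ps,
                                           graphs)
        enr_path = outdir / "enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
        record("enrich", t0, {"enrichment": enr_path})

    # --- stage: cohort table
    t0 = time.time()
    continuous = None
    if dataset.covariates is not None:
        continuous = dataset.covariates[["age"]]
    table = cohort.build_cohort_table(dataset.phenotype,
                                      continuous_vars=continuous)
    table_path = outdir / "cohort_table.tsv"
    table.to_csv(table_path, sep="\t", index=False, float_format="%.4g")
    record("cohort_table", t0, {"cohort_table": table_path})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


# ------------------------------------------------------- validation runs


def planted_recovery_run(
    seed: int,
    n_subjects: int = 200,
    n_snps: int = 12,
    n_metabolites: int = 12,
    bootstraps: int = 100,
    k_folds: int = 5,
) -> dict:
    """Learn a consensus network on one planted cohort and measure how much
    of the phenotype's true Markov neighborhood (4 SNPs + 2 metabolites)
    the chosen network recovers, together with its CV AUC.

    Recovery is counted on the full Markov blanket of the chosen network:
    the learner may orient a planted SNP as a phenotype parent, which the
    prediction uses identically.
    """
    syn = SyntheticConfig(
        n_subjects=n_subjects, n_snps=n_snps, n_expr_probes=0,
        n_cpg_sites=0, n_metabolites=n_metabolites,
        n_zero_variance_metabolites=0, n_high_missing_metabolites=0,
        metabolite_block_spec=(), missing_rate=0.0, modality_overlap={},
        seed=seed)
    dataset, truth = simulate.generate_cohort(syn)
    log_mets = np.log2(dataset.metabolites)
    top = association.TopFeatures(snps=list(dataset.genotypes.index))
    data, specs = prepare_network_data(dataset, log_mets, top)
    data = data.drop(columns=["age", "sex"])
    specs = [s for s in specs if s.name not in ("age", "sex")]
    tally = net.bootstrap_learn(data, specs, B=bootstraps, seed=seed)
    sweep = net.consensus_sweep(tally, data, specs, k_folds=k_folds,
                                seed=seed, phenotype=PHENOTYPE_NODE)
    blanket = net.markov_neighborhood(sweep.chosen_network, PHENOTYPE_NODE,
                                      include_parents=True)
    planted = set(truth.true_markov_neighborhood)
    return {
        "seed": seed,
        "n_recovered": len(planted & set(blanket)),
        "n_planted": len(planted),
        "cv_auc": sweep.chosen_auc,
        "threshold": sweep.chosen_threshold,
        "n_edges": len(sweep.chosen_network.edges),
    }


def null_screen_fraction(seed: int, n_features: int = 2000,
                         n_subjects: int = 100, fdr: float = 0.05) -> dict:
    """Fraction of BH-significant genotype-metabolite tests when no effect
    is planted (should not exceed the FDR level)."""
    syn = SyntheticConfig(
        n_subjects=n_subjects, n_snps=n_features, n_expr_probes=0,
        n_cpg_sites=0, n_metabolites=1, n_zero_variance_metabolites=0,
        n_high_missing_metabolites=0, metabolite_block_spec=(),
        blanket_metabolites=(0,), blanket_metabolite_effects=(0.0,),
        blanket_snp_effects=(0.0,) * 4, snp_metabolite_coupling=0.0,
        missing_rate=0.0, modality_overlap={}, seed=seed)
    dataset, _ = simulate.generate_cohort(syn)
    tab = association.run_screen(dataset, "genotypes", ("age", "sex"))
    return {
        "seed": seed,
        "n_tests": int(len(tab)),
        "bh_fraction": float((tab["q"] < fdr).mean()),
        "raw_fraction": float((tab["p"] < fdr).mean()),
    }
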