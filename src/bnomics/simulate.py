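"""Synthetic multi-omic cohort generator with planted ground truth.

The generator emulates the statistical structure of a small childhood-asthma
cohort profiled on four omic platforms: Hardy–Weinberg genotypes, log-normal
metabolite abundances with correlated blocks, expression and methylation
matrices with a configurable fraction of features linearly coupled to
metabolites, partial modality overlap, missing values, and a binary
asthma-control phenotype (rescue-inhaler use) with a known Markov
neighborhood of 4 SNPs and 2 metabolites.

The planted structure is generated in the orientation a conditional Gaussian
network can represent (discrete nodes upstream of continuous ones):

* planted SNPs -> phenotype (logistic model on standardized dosages),
* phenotype -> planted metabolites (mean shift on the log scale),
* planted SNPs -> those metabolites (the co-parents of the phenotype's
  children, completing the Markov neighborhood).

Because the metabolite children are Gaussian given (phenotype, SNPs), the
implied full conditional P(phenotype | SNPs, metabolites) is itself exactly
logistic; the direct SNP coefficients are adjusted analytically so that the
*configured* effect sizes are the coefficients of that full conditional,
i.e. what a logistic refit on the true blanket estimates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING_DOSAGE, OmicsDataset, PlantedTruth, SyntheticConfig

PHENOTYPE_NODE = "asthma_control"

# fixed substream indices: adding a modality never perturbs another
_STREAMS = {
    "snps": 0,
    "metabolites": 1,
    "expression": 2,
    "methylation": 3,
    "phenotype": 4,
    "covariates": 5,
    "missing": 6,
    "overlap": 7,
}


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


def _block_loading(target_r2: float) -> float:
    """Common-factor loading hitting a target pairwise r^2.

    With z_k = lam*f + sqrt(1-lam^2)*eps_k (unit variances), the pairwise
    correlation is lam^2, so r^2 = lam^4 and lam = r2**0.25.
    """
    return float(target_r2) ** 0.25


def _coparent_map(config: SyntheticConfig) -> dict[int, list[int]]:
    """Assign each planted metabolite its SNP co-parents, round-robin."""
    n_m = len(config.blanket_metabolites)
    out: dict[int, list[int]] = {j: [] for j in range(n_m)}
    for k, _snp in enumerate(config.blanket_snps):
        out[k % n_m].append(k)
    return out


def generate_cohort(config: SyntheticConfig) -> tuple[OmicsDataset, PlantedTruth]:
    """Draw one synthetic cohort plus the ground truth planted in it.

    Identical ``config`` (including ``seed``) yields bit-identical output.
    """
    config.validate()
    n = config.n_subjects
    subjects = [f"subj{i:03d}" for i in range(n)]

    # --- genotypes: per-SNP MAF ~ U(maf_range), HWE via Binomial(2, maf)
    rng = _rng(config, "snps")
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    geno = rng.binomial(2, mafs[:, None], size=(config.n_snps, n)).astype(np.int16)
    snp_ids = [f"rs{100000 + j}" for j in range(config.n_snps)]
    genotypes = pd.DataFrame(geno, index=snp_ids, columns=subjects)

    # --- metabolite latents on the natural-log scale
    rng = _rng(config, "metabolites")
    met_ids = [f"met{j:03d}" for j in range(config.n_metabolites)]
    z = rng.standard_normal((config.n_metabolites, n))
    for members, r2 in config.metabolite_block_spec:
        lam = _block_loading(r2)
        f = rng.standard_normal(n)
        for m in members:
            z[m] = lam * f + np.sqrt(1.0 - lam * lam) * rng.standard_normal(n)

    # --- phenotype: logistic on standardized planted-SNP dosages
    rng_p = _rng(config, "phenotype")
    snp_idx = list(config.blanket_snps)
    snp_eff = np.asarray(config.blanket_snp_effects, dtype=float)
    met_idx = list(config.blanket_metabolites)
    met_eff = np.asarray(config.blanket_metabolite_effects, dtype=float)
    centers = 2.0 * mafs[snp_idx]
    scales = np.sqrt(2.0 * mafs[snp_idx] * (1.0 - mafs[snp_idx]))
    c = (geno[snp_idx, :] - centers[:, None]) / scales[:, None]

    coparents = _coparent_map(config)
    b = config.snp_metabolite_coupling
    # direct coefficient = target + sum_j gamma_j * b_ij so the induced
    # full-conditional coefficient equals the configured target
    direct = snp_eff.copy()
    for j, snps in coparents.items():
        for k in snps:
            direct[k] += met_eff[j] * b
    intercept = float(np.log(0.4 / 0.6))  # ~40% uncontrolled, as observed
    logits = intercept + direct @ c
    y = (rng_p.uniform(size=n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)

    # planted metabolites: unit residual variance makes the induced
    # log-odds coefficient equal the mean-shift coefficient gamma_j
    for j, m in enumerate(met_idx):
        shift = met_eff[j] * y
        for k in coparents[j]:
            shift = shift + b * c[k]
        z[m] = shift + rng_p.standard_normal(n)

    baseline = rng.normal(8.0, 1.0, size=config.n_metabolites)
    if config.plate_effect:
        plate = (np.arange(n) >= n // 2).astype(float) * config.plate_effect
        z = z + plate[None, :]
    abundances = np.exp(z + baseline[:, None])

    # --- degenerate metabolites occupy the trailing indices
    n_zero = config.n_zero_variance_metabolites
    n_miss = config.n_high_missing_metabolites
    zero_idx = list(range(config.n_metabolites - n_zero - n_miss,
                          config.n_metabolites - n_miss))
    high_missing_idx = list(range(config.n_metabolites - n_miss,
                                  config.n_metabolites))
    for m in zero_idx:
        abundances[m, :] = np.exp(baseline[m])
    metabolites = pd.DataFrame(abundances, index=met_ids, columns=subjects)
    rng_m = _rng(config, "missing")
    for m in high_missing_idx:
        k = n // 2 + 1  # strictly more than half the subjects
        cols = rng_m.choice(n, size=k, replace=False)
        metabolites.iloc[m, cols] = np.nan

    # --- expression: log2 intensities, a fraction coupled to metabolites
    rng = _rng(config, "expression")
    expr_ids = [f"probe{j:05d}" for j in range(config.n_expr_probes)]
    base = rng.normal(8.0, 2.0, size=config.n_expr_probes)
    loge = base[:, None] + rng.standard_normal((config.n_expr_probes, n))
    true_assoc: list[tuple[str, str, float]] = []
    eligible = [j for j in range(config.n_metabolites)
                if j not in zero_idx and j not in high_missing_idx]
    n_coupled = int(round(config.assoc_fraction * config.n_expr_probes))
    coupled = rng.choice(config.n_expr_probes, size=n_coupled, replace=False)
    for f in coupled:
        m = int(rng.choice(eligible))
        loge[f] += config.assoc_effect * z[m]
        true_assoc.append((expr_ids[f], met_ids[m], config.assoc_effect))
    expression = pd.DataFrame(np.exp2(loge), index=expr_ids, columns=subjects)

    # --- methylation: beta values via a logistic squash of a normal latent
    rng = _rng(config, "methylation")
    cpg_ids = [f"cg{j:07d}" for j in range(config.n_cpg_sites)]
    mu = rng.normal(0.0, 2.0, size=config.n_cpg_sites)
    latent = mu[:, None] + rng.standard_normal((config.n_cpg_sites, n))
    n_coupled = int(round(config.assoc_fraction * config.n_cpg_sites))
    coupled = rng.choice(config.n_cpg_sites, size=n_coupled, replace=False)
    for f in coupled:
        m = int(rng.choice(eligible))
        latent[f] += config.assoc_effect * z[m]
        true_assoc.append((cpg_ids[f], met_ids[m], config.assoc_effect))
    methylation = pd.DataFrame(
        1.0 / (1.0 + np.exp(-latent)), index=cpg_ids, columns=subjects
    )
    # ~28% type I probes, matching the HM450 chemistry split
    cpg_type = {
        cid: ("I" if t else "II")
        for cid, t in zip(cpg_ids, rng.uniform(size=config.n_cpg_sites) < 0.28)
    }

    # --- covariates
    rng = _rng(config, "covariates")
    age = np.round(rng.uniform(6.0, 18.0, size=n), 1)
    sex = np.where(rng.uniform(size=n) < 0.35, "female", "male")
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=subjects)

    # --- scattered missingness (metabolites + methylation + genotypes)
    if config.missing_rate > 0:
        for frame in (metabolites, methylation):
            mask = rng_m.uniform(size=frame.shape) < config.missing_rate
            frame.values[mask] = np.nan
        gmask = rng_m.uniform(size=genotypes.shape) < config.missing_rate
        genotypes.values[gmask] = MISSING_DOSAGE

    # --- partial modality overlap
    overlap = config.modality_overlap
    if overlap is None:
        overlap = {
            "expression": max(2, int(round(0.8 * n))),
            "methylation": max(2, int(round(0.65 * n))),
        }
    rng_o = _rng(config, "overlap")
    modality_mask: dict[str, pd.Series] = {}
    frames = {
        "metabolites": metabolites,
        "expression": expression,
        "methylation": methylation,
        "genotypes": genotypes,
    }
    for mod, frame in frames.items():
        n_avail = overlap.get(mod, n)
        avail = np.zeros(n, dtype=bool)
        avail[rng_o.choice(n, size=n_avail, replace=False)] = True
        modality_mask[mod] = pd.Series(avail, index=subjects)
        if not avail.all():
            fill = MISSING_DOSAGE if mod == "genotypes" else np.nan
            frame.iloc[:, np.flatnonzero(~avail)] = fill

    dataset = OmicsDataset(
        subjects=subjects,
        metabolites=metabolites,
        expression=expression,
        methylation=methylation,
        genotypes=genotypes,
        cpg_type=cpg_type,
        covariates=covariates,
        phenotype=pd.Series(y, index=subjects, name=PHENOTYPE_NODE),
        modality_mask=modality_mask,
    )

    # --- ground truth
    edges: list[tuple[str, str]] = []
    for k, si in enumerate(snp_idx):
        edges.append((snp_ids[si], PHENOTYPE_NODE))
    for j, mi in enumerate(met_idx):
        edges.append((PHENOTYPE_NODE, met_ids[mi]))
        for k in coparents[j]:
            edges.append((snp_ids[snp_idx[k]], met_ids[mi]))
    truth = PlantedTruth(
        true_edges=edges,
        true_markov_neighborhood=sorted(
            [snp_ids[i] for i in snp_idx] + [met_ids[i] for i in met_idx]
        ),
        true_assoc_pairs=true_assoc,
        node_params={
            "phenotype_intercept": intercept,
            "snp_effects": {
                snp_ids[si]: {
                    "target": float(snp_eff[k]),
                    "direct": float(direct[k]),
                    "center": float(centers[k]),
                    "scale": float(scales[k]),
                }
                for k, si in enumerate(snp_idx)
            },
            "metabolite_effects": {
                met_ids[mi]: {
                    "target": float(met_eff[j]),
                    "log_baseline": float(baseline[mi]),
                }
                for j, mi in enumerate(met_idx)
            },
            "snp_metabolite_coupling": b,
            "zero_variance_metabolites": [met_ids[m] for m in zero_idx],
            "high_missing_metabolites": [met_ids[m] for m in high_missing_idx],
        },
    )
    return dataset, truth


def truth_markov_neighborhood(truth: PlantedTruth,
                              node: str = PHENOTYPE_NODE) -> list[str]:
    """Markov neighborhood of ``node`` implied by the planted edges.

    Children of the node plus the other parents of those children,
    deduplicated and sorted.
    """
    parents: dict[str, set[str]] = {}
    children: dict[str, set[str]] = {}
    for p, ch in truth.true_edges:
        parents.setdefault(ch, set()).add(p)
        children.setdefault(p, set()).add(ch)
    _check_acyclic(truth.true_edges)
    out: set[str] = set()
    for ch in children.get(node, set()):
        out.add(ch)
        out |= parents.get(ch, set())
    out.discard(node)
    return sorted(out)


def _check_acyclic(edges: list[tuple[str, str]]) -> None:
    import networkx as nx

    g = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("true_edges contain a cycle")


# ---------------------------------------------------------------- writers


def write_cohort(dataset: OmicsDataset, truth: PlantedTruth | None,
                 outdir: str | Path, vcf: bool = True) -> dict[str, Path]:
    """Write a cohort in the same formats the ingest module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write_tsv(frame: pd.DataFrame, name: str) -> None:
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", na_rep="NA", index_label="feature_id")
        paths[name] = p

    if dataset.metabolites is not None:
        _write_tsv(dataset.metabolites, "metabolites")
    if dataset.expression is not None:
        _write_tsv(dataset.expression, "expression")
    if dataset.methylation is not None:
        _write_tsv(dataset.methylation, "methylation")
        p = outdir / "cpg_types.tsv"
        pd.Series(dataset.cpg_type, name="type").rename_axis("cpg_id").to_csv(
            p, sep="\t"
        )
        paths["cpg_types"] = p
    if dataset.genotypes is not None:
        if vcf:
            p = outdir / "genotypes.vcf"
            write_vcf(dataset.genotypes, p)
            paths["genotypes"] = p
        else:
            _write_tsv(
                dataset.genotypes.replace(MISSING_DOSAGE, np.nan), "genotypes"
            )
    if dataset.covariates is not None:
        p = outdir / "covariates.tsv"
        dataset.covariates.rename_axis("subject").to_csv(p, sep="\t")
        paths["covariates"] = p
    if dataset.phenotype is not None:
        p = outdir / "phenotype.tsv"
        pd.DataFrame(
            {"albuterol_use_last7d": dataset.phenotype}
        ).rename_axis("subject").to_csv(p, sep="\t")
        paths["phenotype"] = p
    if truth is not None:
        p = outdir / "truth.json"
        p.write_text(json.dumps(truth.to_dict(), indent=1))
        paths["truth"] = p
    return paths


def write_vcf(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Write integer dosages as an uncompressed GT-only VCF."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_DOSAGE: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.columns) + "\n")
        for pos, (snp_id, row) in enumerate(genotypes.iterrows(), start=1):
            gts = "\t".join(gt_map[int(v)] for v in row.values)
            fh.write(f"1\t{pos}\t{snp_id}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
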