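"""Metabolome-wide association screens with covariate adjustment.

Each modality (SNP dosages under an additive model, log2 quantile-normalized
expression, methylation beta values split by probe chemistry) is screened
feature-by-feature against every metabolite with ordinary least squares,
two-sided t tests on the feature slope, and Benjamini–Hochberg FDR within
the screen. Selection rules reduce each screen to the handful of features
fed to the Bayesian network: FDR-thresholded SNPs pruned for complete
linkage disequilibrium (D' = 1), top-k expression probes, and the top two
CpG sites per top-associated metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import ingest
from .datatypes import MISSING_DOSAGE, OmicsDataset

RESULT_COLUMNS = [
    "feature", "metabolite", "effect", "se", "t_stat", "p", "q",
    "n_used", "df", "sigma2", "flag_exact_fit", "flag_high_leverage",
]

_TINY_P = np.nextafter(0, 1)


@dataclass
class AssociationResult:
    """One feature-metabolite linear-model fit."""

    feature: str
    metabolite: str
    effect: float
    se: float
    t_stat: float
    p: float
    n_used: int
    q: float = np.nan
    flag_exact_fit: bool = False
    flag_high_leverage: bool = False


@dataclass
class LDStats:
    """Two-locus linkage disequilibrium summary."""

    snp_a: str
    snp_b: str
    d_prime: float
    r2: float


@dataclass
class TopFeatures:
    """Per-modality feature selections with provenance."""

    snps: list[str] = field(default_factory=list)
    expression: list[str] = field(default_factory=list)
    cpgs: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "snps": self.snps,
            "expression": self.expression,
            "cpgs": self.cpgs,
            "provenance": self.provenance,
        }


# ------------------------------------------------------------- primitives


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _design(x: np.ndarray, covars: pd.DataFrame | None,
            subjects: np.ndarray | None = None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(x, dtype=float), np.asarray(x, dtype=float)]
    names = ["intercept", "x"]
    if covars is not None:
        cov = covars
        if subjects is not None:
            cov = cov.loc[subjects]
        for name in cov.columns:
            col = cov[name]
            if col.dtype == object:
                col = (col == "female").astype(float)  # male = 0, female = 1
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def linear_assoc(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    covars: pd.DataFrame | None = None,
    feature: str = "x",
    metabolite: str = "y",
) -> AssociationResult:
    """OLS of metabolite ``y`` on feature ``x`` plus covariates; two-sided
    t test on the ``x`` slope. Rows with any missing value are dropped.
    Genotype ``x`` enters as a numeric dosage (additive model)."""
    y = pd.Series(np.asarray(y, dtype=float)) if not isinstance(y, pd.Series) else y
    x = pd.Series(np.asarray(x, dtype=float), index=y.index) \
        if not isinstance(x, pd.Series) else x
    mask = y.notna() & x.notna()
    if covars is not None:
        mask &= covars.loc[y.index].notna().all(axis=1)
    yv = y[mask].to_numpy(dtype=float)
    X, names = _design(x[mask].to_numpy(dtype=float), covars,
                       subjects=y.index[mask])
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} complete observations, have {n}")
    if np.ptp(X[:, 1]) == 0:
        raise ValueError(f"feature {feature!r} is constant among used subjects")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        for j in range(2, k):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"design is collinear at column {names[j]!r}")
        raise ValueError("design matrix is rank-deficient")
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    df = n - k
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    if rss <= max(1e-12 * float(yv @ yv), 1e-300):
        return AssociationResult(feature, metabolite, float(beta[1]), 0.0,
                                 np.inf, _TINY_P, n, flag_exact_fit=True)
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta[1] / se)
    p = float(2 * stats.t.sf(abs(t), df))
    return AssociationResult(feature, metabolite, float(beta[1]), se, t,
                             max(p, _TINY_P), n)


def _screen_block(
    Y: np.ndarray, X: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of every metabolite (rows of Y) on every feature
    (rows of X) given shared covariates C (n x p, including intercept).

    Uses Frisch–Waugh residualization: slopes/t identical to the full fit.
    Returns (effect, se, t, p) arrays of shape (features, metabolites).
    """
    n = C.shape[0]
    Q, _ = np.linalg.qr(C)
    Yr = Y.T - Q @ (Q.T @ Y.T)  # n x m
    Xr = X.T - Q @ (Q.T @ X.T)  # n x f
    xss = np.einsum("nf,nf->f", Xr, Xr)
    xss_safe = np.where(xss > 0, xss, np.nan)
    xy = Xr.T @ Yr  # f x m
    beta = xy / xss_safe[:, None]
    yss = np.einsum("nm,nm->m", Yr, Yr)
    rss = yss[None, :] - beta * xy
    df = n - C.shape[1] - 1
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / xss_safe[:, None])
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(p), np.nan, np.maximum(p, _TINY_P))
    return beta, se, t, p, df, sigma2


def _modality_tables(
    dataset: OmicsDataset,
    modality: str,
    metabolites: pd.DataFrame,
    features: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, bool]:
    """Standard per-modality preparation shared by the screen and the
    leverage re-check: returns ({probe_type: feature table}, metabolite
    table, drop_incomplete_pairs)."""
    if modality == "genotypes":
        feats = (features if features is not None
                 else dataset.genotypes.astype(float).replace(MISSING_DOSAGE, np.nan))
        subjects = dataset.available_subjects("genotypes")
        mets = ingest.mean_impute(metabolites[metabolites.columns.intersection(
            subjects)])
        tables = {"": feats[mets.columns]}
        drop_incomplete_y = False
    elif modality == "expression":
        if features is None:
            expr, _ = ingest.filter_expression_samples(
                dataset.expression[dataset.available_subjects("expression")].dropna(
                    axis=1, how="all")
            )
            feats = ingest.quantile_normalize(np.log2(expr))
        else:
            feats = features
        common = metabolites.columns.intersection(feats.columns)
        tables = {"": feats[common]}
        mets = metabolites[common]
        drop_incomplete_y = True
    elif modality == "methylation":
        feats = (features if features is not None
                 else dataset.methylation[
                     dataset.available_subjects("methylation")])
        feats = feats.dropna(axis=1, how="all")
        common = metabolites.columns.intersection(feats.columns)
        feats = feats[common]
        mets = metabolites[common]
        type_of = dataset.cpg_type
        tables = {
            "I": feats.loc[[f for f in feats.index if type_of.get(f) == "I"]],
            "II": feats.loc[[f for f in feats.index if type_of.get(f) == "II"]],
        }
        drop_incomplete_y = True
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return tables, mets, drop_incomplete_y


def run_screen(
    dataset: OmicsDataset,
    modality: str,
    adjustment: tuple[str, ...] = ("age", "sex"),
    features: pd.DataFrame | None = None,
    metabolites: pd.DataFrame | None = None,
    n_pcs_from_features: int = 2,
) -> pd.DataFrame:
    """One OLS per feature x metabolite for the given modality.

    ``adjustment`` names covariates: ``age``/``sex`` from the covariate
    table, ``PC1``/``PC2`` computed from the modality matrix itself
    (methylation convention). Genotype screens mean-impute metabolites and
    drop subjects missing the genotype; expression and methylation screens
    drop incomplete pairs. Methylation probes are screened per probe type
    with separate BH adjustment within each type.
    """
    if metabolites is None:
        mets, _ = ingest.filter_metabolites(dataset.metabolites)
        metabolites = np.log2(mets)
    if metabolites.shape[0] == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    tables, mets, drop_incomplete_y = _modality_tables(
        dataset, modality, metabolites, features)

    frames = []
    for probe_type, table in tables.items():
        if table.shape[0] == 0:
            continue
        frame = _screen_table(table, mets, dataset, adjustment,
                              drop_incomplete_y, n_pcs_from_features)
        frame["probe_type"] = probe_type
        valid = frame["p"].notna()
        frame.loc[valid, "q"] = bh_fdr(frame.loc[valid, "p"].to_numpy())
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS + ["probe_type"])
    return pd.concat(frames, ignore_index=True)


def _covariate_table(
    dataset: OmicsDataset,
    adjustment: tuple[str, ...],
    feature_matrix: pd.DataFrame,
    n_pcs: int,
) -> pd.DataFrame | None:
    if not adjustment:
        return None
    cols = {}
    pcs = None
    for name in adjustment:
        if name in ("age", "sex"):
            if dataset.covariates is None or name not in dataset.covariates:
                raise ValueError(f"unknown covariate {name!r}")
            cols[name] = dataset.covariates[name]
        elif name.startswith("PC"):
            if pcs is None:
                complete = ingest.mean_impute(feature_matrix)
                pcs = ingest.compute_pcs(complete, k=max(
                    n_pcs, int(name[2:]) if name[2:].isdigit() else n_pcs))
            if name not in pcs.columns:
                raise ValueError(f"unknown covariate {name!r}")
            cols[name] = pcs[name]
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return pd.DataFrame(cols)


def _screen_table(
    table: pd.DataFrame,
    mets: pd.DataFrame,
    dataset: OmicsDataset,
    adjustment: tuple[str, ...],
    drop_incomplete_y: bool,
    n_pcs: int,
) -> pd.DataFrame:
    covars = _covariate_table(dataset, adjustment, table, n_pcs)
    subjects = table.columns
    C_full = None
    if covars is not None:
        cov = covars.loc[subjects].copy()
        if "sex" in cov.columns:
            cov["sex"] = (cov["sex"] == "female").astype(float)
        C_full = np.column_stack(
            [np.ones(len(subjects))] + [cov[c].to_numpy(dtype=float)
                                        for c in cov.columns])
    else:
        C_full = np.ones((len(subjects), 1))

    X = table.to_numpy(dtype=float)
    Y = mets[subjects].to_numpy(dtype=float)
    rows = []
    # group features by missing pattern so each block is one vectorized fit
    pattern_ids: dict[bytes, list[int]] = {}
    feat_mask = ~np.isnan(X)
    for i in range(X.shape[0]):
        pattern_ids.setdefault(feat_mask[i].tobytes(), []).append(i)
    met_ok = ~np.isnan(Y)
    feature_names = table.index.to_numpy()
    met_names = mets.index.to_numpy()
    for pat, feat_rows in pattern_ids.items():
        base = np.frombuffer(pat, dtype=bool)
        if drop_incomplete_y:
            met_groups: dict[bytes, list[int]] = {}
            for j in range(Y.shape[0]):
                met_groups.setdefault((base & met_ok[j]).tobytes(), []).append(j)
        else:
            met_groups = {base.tobytes(): list(range(Y.shape[0]))}
        for mpat, met_rows in met_groups.items():
            use = np.frombuffer(mpat, dtype=bool)
            n = int(use.sum())
            k = C_full.shape[1] + 1
            if n < k + 1:
                continue
            beta, se, t, p, df, sigma2 = _screen_block(
                Y[np.ix_(met_rows, np.flatnonzero(use))],
                X[np.ix_(feat_rows, np.flatnonzero(use))],
                C_full[use],
            )
            for a, fi in enumerate(feat_rows):
                for bj, mj in enumerate(met_rows):
                    if np.isnan(p[a, bj]):
                        continue
                    rows.append((feature_names[fi], met_names[mj],
                                 beta[a, bj], se[a, bj], t[a, bj],
                                 p[a, bj], np.nan, n, df,
                                 sigma2[a, bj], False, False))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def apply_variance_shrinkage(table: pd.DataFrame, d0: float,
                             s0_sq: float) -> pd.DataFrame:
    """Moderated t statistics via variance shrinkage toward a prior:
    s~^2 = (d0*s0^2 + d*s^2) / (d0 + d), t tested on d0 + d df.

    An opt-in parity switch with empirical-Bayes moderated screens; the
    prior df d0 and prior variance s0^2 must be supplied.
    """
    if d0 <= 0 or s0_sq <= 0:
        raise ValueError("d0 and s0_sq must be > 0")
    out = table.copy()
    d = out["df"].to_numpy(dtype=float)
    s2 = out["sigma2"].to_numpy(dtype=float)
    s_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
    # se^2 = s^2 / xss, so the moderated se rescales by s~/s
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.sqrt(s_tilde / np.where(s2 > 0, s2, np.nan))
    se_mod = out["se"].to_numpy(dtype=float) * scale
    t_mod = out["effect"].to_numpy(dtype=float) / se_mod
    out["se"] = se_mod
    out["t_stat"] = t_mod
    out["df"] = d + d0
    out["p"] = np.maximum(2 * stats.t.sf(np.abs(t_mod), d + d0), _TINY_P)
    valid = out["p"].notna()
    out.loc[valid, "q"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    return out


# ---------------------------------------------------------- leverage


def hat_values(x: np.ndarray, covars: pd.DataFrame | None = None,
               subjects: np.ndarray | None = None) -> np.ndarray:
    X, _ = _design(np.asarray(x, dtype=float), covars, subjects)
    Q, _ = np.linalg.qr(X)
    return np.einsum("ij,ij->i", Q, Q)


def remove_high_leverage(
    results: pd.DataFrame,
    feature_matrix: pd.DataFrame,
    metabolite_matrix: pd.DataFrame,
    covars: pd.DataFrame | None = None,
    hat_threshold: float | None = None,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Flag associations that vanish once high-leverage subjects are
    excluded (hat value > threshold, default 2*params/n); flagged rows are
    dropped from top-feature eligibility downstream."""
    if hat_threshold is not None and not 0 < hat_threshold <= 1:
        raise ValueError("hat_threshold must lie in (0, 1]")
    out = results.copy()
    flags = []
    for _, row in out.iterrows():
        x = feature_matrix.loc[row["feature"]]
        y = metabolite_matrix.loc[row["metabolite"]]
        mask = x.notna() & y.notna()
        if covars is not None:
            mask &= covars.loc[x.index].notna().all(axis=1)
        xs, ys = x[mask], y[mask]
        n = len(xs)
        k = 2 + (0 if covars is None else covars.shape[1])
        thr = hat_threshold if hat_threshold is not None else 2.0 * k / n
        h = hat_values(xs.to_numpy(dtype=float), covars, xs.index)
        keep = h <= thr
        if keep.all():
            flags.append(False)
            continue
        if keep.sum() < k + 1 or np.ptp(xs[keep]) == 0:
            # the fit cannot even be formed without the high-leverage
            # subjects: the association is entirely carried by them
            flags.append(True)
            continue
        refit = linear_assoc(ys[keep], xs[keep],
                             None if covars is None else covars)
        flags.append(bool(refit.p > p_cutoff))
    out["flag_high_leverage"] = flags
    return out


def flag_leverage_for_selection(
    results: pd.DataFrame,
    dataset: OmicsDataset,
    modality: str,
    metabolites: pd.DataFrame,
    adjustment: tuple[str, ...] = ("age", "sex"),
    top_n: int = 200,
    hat_threshold: float | None = None,
) -> pd.DataFrame:
    """Leverage re-check of the strongest screen rows before selection.

    Only the ``top_n`` smallest-p rows are refit (the only ones that can
    enter the top-feature lists); their ``flag_high_leverage`` column is
    updated in place on a copy of ``results``.
    """
    if not len(results):
        return results
    tables, mets, _ = _modality_tables(dataset, modality, metabolites)
    feats = pd.concat([t for t in tables.values() if len(t)])
    covars = _covariate_table(dataset, adjustment, feats, 2)
    if covars is not None:
        covars = covars.loc[feats.columns]
    candidates = results.nsmallest(top_n, "p")
    candidates = candidates[candidates["feature"].isin(feats.index)
                            & candidates["metabolite"].isin(mets.index)]
    flagged = remove_high_leverage(candidates, feats, mets, covars,
                                   hat_threshold=hat_threshold)
    out = results.copy()
    out.loc[flagged.index, "flag_high_leverage"] = flagged[
        "flag_high_leverage"]
    return out


# ---------------------------------------------------------- LD pruning


def dprime(snp_a: pd.Series | np.ndarray, snp_b: pd.Series | np.ndarray,
           name_a: str = "a", name_b: str = "b",
           tol: float = 1e-10, max_iter: int = 1000) -> LDStats:
    """D' and r^2 between two biallelic SNPs from unphased dosages.

    Haplotype frequencies are estimated by the two-locus EM algorithm
    (double heterozygotes are the only ambiguous class).
    """
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b)) & (a != MISSING_DOSAGE) & (b != MISSING_DOSAGE)
    a, b = a[ok].astype(int), b[ok].astype(int)
    if a.size == 0:
        raise ValueError("no complete genotype pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic SNP supplied to dprime")
    counts = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        counts[ga, gb] += 1
    n_hap = 2.0 * a.size
    # haplotype alleles: 1 = alternate; freq[i, j] = freq of haplotype (i, j)
    freq = np.full((2, 2), 0.25)
    for _ in range(max_iter):
        hap = np.zeros((2, 2))
        for ga in range(3):
            for gb in range(3):
                c = counts[ga, gb]
                if c == 0:
                    continue
                if ga == 1 and gb == 1:
                    denom = freq[1, 1] * freq[0, 0] + freq[1, 0] * freq[0, 1]
                    w = 0.5 if denom == 0 else freq[1, 1] * freq[0, 0] / denom
                    hap[1, 1] += c * w
                    hap[0, 0] += c * w
                    hap[1, 0] += c * (1 - w)
                    hap[0, 1] += c * (1 - w)
                else:
                    # unambiguous: phase is determined unless both loci are het
                    a1 = [0] * (2 - ga) + [1] * ga
                    b1 = [0] * (2 - gb) + [1] * gb
                    hap[a1[0], b1[0]] += c
                    hap[a1[1], b1[1]] += c
        new = hap / n_hap
        if np.abs(new - freq).max() < tol:
            freq = new
            break
        freq = new
    p_a = freq[1, 0] + freq[1, 1]
    p_b = freq[0, 1] + freq[1, 1]
    d = freq[1, 1] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = 0.0 if denom == 0 else d * d / denom
    return LDStats(name_a, name_b, float(min(d_prime, 1.0)), float(min(r2, 1.0)))


# ---------------------------------------------------------- selection


def select_top_features(
    results: dict[str, pd.DataFrame],
    genotypes: pd.DataFrame | None = None,
    snp_fdr: float = 0.20,
    expr_top_k: int = 20,
    cpg_top_per_type: int = 50,
    cpg_per_metabolite: int = 2,
    dprime_threshold: float = 1.0,
) -> TopFeatures:
    """Apply the per-modality selection rules that feed the network stage.

    SNPs: all features attaining FDR < ``snp_fdr`` for any metabolite,
    ranked by min p, then pairs in complete LD (D' >= threshold) pruned
    keeping the stronger association (ties keep the lower-index SNP).
    Expression: top-k probes by min p. CpGs: union of the top-50 type I and
    type II association rows -> their unique metabolites -> top two CpGs
    per metabolite, deduplicated.
    """
    top = TopFeatures()
    unflagged = {
        mod: (tab[~tab["flag_high_leverage"]] if "flag_high_leverage" in tab
              else tab)
        for mod, tab in results.items()
    }

    snp_tab = unflagged.get("genotypes")
    if snp_tab is not None and len(snp_tab):
        hits = snp_tab[snp_tab["q"] < snp_fdr]
        min_p = hits.groupby("feature")["p"].min().sort_values(kind="stable")
        ranked = list(min_p.index)
        kept: list[str] = []
        pruned: list[tuple[str, str, float]] = []
        for snp in ranked:
            in_ld = False
            for prev in kept:
                if genotypes is None:
                    break
                try:
                    ld = dprime(genotypes.loc[prev], genotypes.loc[snp],
                                prev, snp)
                except ValueError:
                    continue
                if ld.d_prime >= dprime_threshold:
                    in_ld = True
                    pruned.append((snp, prev, ld.d_prime))
                    break
            if not in_ld:
                kept.append(snp)
        top.snps = kept
        top.provenance["snps"] = {
            "fdr_cutoff": snp_fdr,
            "n_fdr_hits": int(len(hits)),
            "n_candidates": len(ranked),
            "ld_pruned": [list(t) for t in pruned],
        }

    expr_tab = unflagged.get("expression")
    if expr_tab is not None and len(expr_tab):
        min_p = expr_tab.groupby("feature")["p"].min().sort_values(kind="stable")
        top.expression = list(min_p.index[:expr_top_k])
        top.provenance["expression"] = {
            "top_k": expr_top_k,
            "n_candidates": int(min_p.size),
            "min_p_selected": float(min_p.iloc[0]) if len(min_p) else None,
        }

    cpg_tab = unflagged.get("methylation")
    if cpg_tab is not None and len(cpg_tab):
        selected_mets: set[str] = set()
        for probe_type in ("I", "II"):
            sub = cpg_tab[cpg_tab.get("probe_type", "") == probe_type]
            top_rows = sub.nsmallest(cpg_top_per_type, "p")
            selected_mets |= set(top_rows["metabolite"])
        chosen: list[str] = []
        for met in sorted(selected_mets):
            sub = cpg_tab[cpg_tab["metabolite"] == met].nsmallest(
                cpg_per_metabolite, "p")
            chosen.extend(sub["feature"].tolist())
        top.cpgs = sorted(set(chosen))
        top.provenance["cpgs"] = {
            "top_per_type": cpg_top_per_type,
            "per_metabolite": cpg_per_metabolite,
            "n_metabolites": len(selected_mets),
        }
    return top
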