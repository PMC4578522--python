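"""Readers and quality-control filters for the four omic modalities.

File conventions: feature-by-subject TSV matrices (header row = subject
ids, first column = feature ids, missing token ``NA``); genotypes as either
such a TSV of additive dosages or an uncompressed GT-only VCF; covariates
and phenotype as small subject tables. The phenotype column
``albuterol_use_last7d`` is a count of rescue-inhaler uses and is binarized
at >= 1 (uncontrolled asthma).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING_DOSAGE, QCReport

_KINDS = ("metabolites", "expression", "methylation", "genotypes")


# ---------------------------------------------------------------- readers


def read_matrix(path: str | Path, kind: str = "metabolites") -> pd.DataFrame:
    """Read a feature-by-subject TSV matrix.

    Duplicate feature ids, ragged rows and non-numeric cells (other than
    the ``NA`` missing token) are hard errors. Genotype matrices are
    returned as integer dosages with ``-1`` for missing.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    path = Path(path)
    if kind == "genotypes" and path.suffix.lower() == ".vcf":
        return read_vcf(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                        keep_default_na=False)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path.name}: {dups[:5]}")
    if frame.columns.has_duplicates:
        raise ValueError(f"duplicate subject ids in {path.name}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path.name}: {exc}") from exc
    frame.index.name = None
    if kind == "genotypes":
        vals = frame.values
        observed = vals[~np.isnan(vals)]
        if not np.all(np.isin(observed, [0, 1, 2])):
            raise ValueError("genotype dosages must be 0, 1 or 2")
        frame = frame.fillna(MISSING_DOSAGE).astype(np.int16)
    return frame


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Parse a VCF into an additive-dosage matrix (GT field only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subjects = list(vcf.samples)
    ids, rows = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gts012: 0/1/2 = alt count, 3 = unknown
        gt = np.asarray(var.gt_types, dtype=np.int16)
        gt[gt == 3] = MISSING_DOSAGE
        rows.append(gt)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate variant ids in {Path(path).name}")
    out = pd.DataFrame(rows, index=ids, columns=subjects)
    out.index.name = None
    return out


def read_covariates(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"age", "sex"} - set(cov.columns)
    if missing:
        raise ValueError(f"covariates file lacks columns: {sorted(missing)}")
    bad = set(cov["sex"].dropna().unique()) - {"male", "female"}
    if bad:
        raise ValueError(f"unrecognized sex values: {sorted(bad)}")
    cov.index.name = None
    return cov


def read_phenotype(path: str | Path,
                   column: str = "albuterol_use_last7d") -> pd.Series:
    """Read the phenotype table and binarize the use count at >= 1."""
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if column not in tab.columns:
        raise ValueError(f"phenotype file lacks column {column!r}")
    counts = tab[column].astype(float)
    if (counts < 0).any():
        raise ValueError("negative use counts in phenotype file")
    return (counts >= 1).astype(int)


def read_cpg_types(path: str | Path) -> dict[str, str]:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    types = tab.iloc[:, 0].astype(str)
    bad = set(types.unique()) - {"I", "II"}
    if bad:
        raise ValueError(f"CpG probe types must be I or II, got {sorted(bad)}")
    return types.to_dict()


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.replace(MISSING_DOSAGE, np.nan) if frame.dtypes.iloc[0].kind == "i" \
        else frame
    out.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


# ---------------------------------------------------------------- filters


def filter_metabolites(matrix: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Drop zero-variance features and features missing in > half the
    subjects (strictly), mirroring the metabolite panel QC that reduced 68
    assayed metabolites to 64."""
    # "no variation" judged on distinct observed values (exact, immune to
    # floating-point roundoff in a variance computation)
    zero_var = matrix.index[matrix.nunique(axis=1) <= 1]
    missing_frac = matrix.isna().mean(axis=1)
    high_missing = matrix.index[(missing_frac > 0.5) & ~matrix.index.isin(zero_var)]
    keep = matrix.index.difference(zero_var.union(high_missing), sort=False)
    if len(keep) == 0:
        raise ValueError("metabolite QC removed every feature")
    report = QCReport(
        n_input=matrix.shape[0],
        n_retained=len(keep),
        removed={
            "zero_variance": zero_var.tolist(),
            "high_missing": high_missing.tolist(),
        },
    )
    return matrix.loc[keep], report


def filter_methylation(
    matrix: pd.DataFrame,
    cpg_type: dict[str, str],
    exclusion_lists: dict[str, list[str]] | None = None,
    duplicates: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Methylation probe QC and type I/II split.

    Drops probes missing in more than half the subjects and probes on the
    supplied exclusion lists (cross-hybridizing, SNP probes); for subjects
    with replicate arrays keeps the replicate with the largest
    inter-quartile range; returns separate type I and type II matrices.
    """
    exclusion_lists = exclusion_lists or {}
    removed: dict[str, list[str]] = {}
    work = matrix

    if duplicates:
        keep_cols, dropped_cols = [], []
        replicate_cols = {c for cols in duplicates.values() for c in cols}
        for col in work.columns:
            if col not in replicate_cols:
                keep_cols.append(col)
        for subject, cols in duplicates.items():
            present = [c for c in cols if c in work.columns]
            if not present:
                raise ValueError(f"subject {subject!r} has no usable replicate")
            iqrs = {
                c: float(work[c].quantile(0.75) - work[c].quantile(0.25))
                for c in present
            }
            best = max(present, key=lambda c: (iqrs[c], c))
            keep_cols.append(best)
            dropped_cols.extend(c for c in present if c != best)
            work = work.rename(columns={best: subject})
            keep_cols[-1] = subject
        work = work[keep_cols]

    untyped = [p for p in work.index if cpg_type.get(p) not in ("I", "II")]
    if untyped:
        raise ValueError(f"probes with unknown type (not I/II): {untyped[:5]}")

    high_missing = work.index[work.isna().mean(axis=1) > 0.5]
    removed["high_missing"] = high_missing.tolist()
    work = work.drop(index=high_missing)
    for name, probes in exclusion_lists.items():
        hit = work.index.intersection(probes)
        removed[name] = hit.tolist()
        work = work.drop(index=hit)

    type_i = work.loc[[p for p in work.index if cpg_type[p] == "I"]]
    type_ii = work.loc[[p for p in work.index if cpg_type[p] == "II"]]
    report = QCReport(
        n_input=matrix.shape[0],
        n_retained=work.shape[0],
        removed=removed,
        details={"n_type_I": type_i.shape[0], "n_type_II": type_ii.shape[0]},
    )
    return type_i, type_ii, report


def filter_expression_samples(
    matrix: pd.DataFrame, min_ratio: float = 6.0
) -> tuple[pd.DataFrame, QCReport]:
    """Drop subjects with poor signal-to-noise: p95/p05 intensity ratio
    strictly greater than ``min_ratio`` is required to pass."""
    p95 = matrix.quantile(0.95, axis=0)
    p05 = matrix.quantile(0.05, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p95 / p05
    passing = matrix.columns[(ratio > min_ratio).values]
    dropped = [c for c in matrix.columns if c not in set(passing)]
    report = QCReport(
        n_input=matrix.shape[1],
        n_retained=len(passing),
        removed={"low_signal_to_noise": dropped},
        details={"ratio": {c: float(r) for c, r in ratio.items()}},
    )
    return matrix[passing], report


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every subject (column) onto the common distribution given by
    the row-wise mean of sorted columns; within-column ranks preserved."""
    if matrix.isna().any().any():
        raise ValueError("quantile_normalize requires complete data; impute first")
    vals = matrix.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[order[:, j], j] = reference
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def compute_pcs(matrix: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Top-k principal-component scores of the subjects.

    SVD on feature-centered data; components ordered by explained
    variance; sign fixed so each component's largest-magnitude feature
    loading is positive.
    """
    if k > min(matrix.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(matrix.shape)}")
    if matrix.isna().any().any():
        raise ValueError("compute_pcs requires complete data; impute first")
    centered = matrix.sub(matrix.mean(axis=1), axis=0).to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for i in range(k):
        j = np.argmax(np.abs(u[:, i]))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            vt[i, :] = -vt[i, :]
    scores = (vt[:k, :].T * s[:k])
    return pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )


def flag_pc_outliers(scores: pd.DataFrame, n_sd: float = 3.0) -> list[str]:
    """Flag subjects with |robust z| > n_sd on any listed component.

    Flag-only: outliers stay in the dataset unless explicitly removed.
    """
    flagged: set[str] = set()
    for col in scores.columns:
        x = scores[col]
        med = x.median()
        mad = (x - med).abs().median()
        sd = 1.4826 * mad if mad > 0 else x.std()
        if sd == 0 or np.isnan(sd):
            continue
        flagged |= set(scores.index[((x - med).abs() / sd) > n_sd])
    return sorted(flagged)


def mean_impute(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells by the feature's observed mean ("bias toward
    the null"); errors on fully-missing features."""
    n_obs = matrix.notna().sum(axis=1)
    empty = matrix.index[n_obs == 0].tolist()
    if empty:
        raise ValueError(f"fully-missing features (filter first): {empty[:5]}")
    means = matrix.mean(axis=1)
    return matrix.apply(lambda row: row.fillna(means[row.name]), axis=1)


def impute_dosages(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute missing genotype dosages (returns a float matrix)."""
    g = genotypes.astype(float).replace(MISSING_DOSAGE, np.nan)
    return mean_impute(g)


def correlation_report(
    matrix: pd.DataFrame, threshold_r2: float = 0.9, min_periods: int = 3
) -> list[tuple[str, str, float]]:
    """All unordered feature pairs with pairwise-complete squared Pearson
    correlation above the threshold, sorted by r^2 descending."""
    corr = matrix.T.corr(min_periods=min_periods)
    r2 = corr.to_numpy() ** 2
    ids = corr.index.to_list()
    out = []
    iu, ju = np.triu_indices(len(ids), k=1)
    for i, j in zip(iu, ju):
        if not np.isnan(r2[i, j]) and r2[i, j] > threshold_r2:
            out.append((ids[i], ids[j], float(r2[i, j])))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def log2_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform positive abundances then z-score each feature.

    The scale used for network and pathway stages; the raw scale is kept
    for reports.
    """
    if (matrix <= 0).any().any():
        raise ValueError("log2_zscore requires strictly positive values")
    logged = np.log2(matrix)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    sd = logged.std(axis=1, ddof=0).replace(0, 1.0)
    return centered.div(sd, axis=0)


def beta_to_mvalues(matrix: pd.DataFrame, eps: float = 1e-6) -> pd.DataFrame:
    """Logit (M-value) transform of methylation beta values.

    Betas are clipped away from 0/1 by ``eps`` before the logit. Opt-in:
    the default analysis scale is beta.
    """
    clipped = matrix.clip(lower=eps, upper=1 - eps)
    return np.log2(clipped / (1 - clipped))


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature (row) over its observed values."""
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    sd = matrix.std(axis=1, ddof=0).replace(0, 1.0)
    return centered.div(sd, axis=0)
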