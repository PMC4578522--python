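"""Shared in-memory containers for the multi-omic analysis.

Conventions used throughout the package:

* Feature matrices (metabolites, expression, methylation) are pandas
  DataFrames of shape ``features x subjects`` with ``NaN`` marking missing
  values — the orientation the profiling platforms emit.
* Genotypes are integer additive dosages (count of alternate alleles,
  0/1/2) with ``-1`` as the missing sentinel, so that a missing call can
  never be confused with a homozygous-reference call.
* The phenotype is binary: 1 = uncontrolled asthma (rescue-inhaler use in
  the preceding week), 0 = controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_DOSAGE = -1

__all__ = [
    "MISSING_DOSAGE",
    "OmicsDataset",
    "QCReport",
    "SyntheticConfig",
    "PlantedTruth",
]


@dataclass
class OmicsDataset:
    """Aligned subject-by-feature matrices for up to four omic modalities.

    All matrices are column-aligned to ``subjects``; a modality a subject
    was never assayed on is recorded in ``modality_mask`` (columns for
    unavailable subjects are all-missing).
    """

    subjects: list[str]
    metabolites: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None
    genotypes: pd.DataFrame | None = None
    cpg_type: dict[str, str] = field(default_factory=dict)
    covariates: pd.DataFrame | None = None  # subjects x {age, sex}
    phenotype: pd.Series | None = None  # subject -> {0, 1}
    modality_mask: dict[str, pd.Series] = field(default_factory=dict)

    MODALITIES = ("metabolites", "expression", "methylation", "genotypes")

    def __post_init__(self) -> None:
        for name in self.MODALITIES:
            mat = getattr(self, name)
            if mat is not None and list(mat.columns) != list(self.subjects):
                raise ValueError(
                    f"{name} matrix columns are not aligned to the subject list"
                )
        if self.phenotype is not None:
            vals = set(self.phenotype.dropna().unique())
            if not vals <= {0, 1}:
                raise ValueError(f"phenotype must be binary 0/1, got {sorted(vals)}")

    def available_subjects(self, modality: str) -> list[str]:
        """Subjects with data for ``modality`` per the availability mask."""
        mask = self.modality_mask.get(modality)
        if mask is None:
            return list(self.subjects)
        return [s for s in self.subjects if bool(mask.get(s, True))]


@dataclass
class QCReport:
    """Per-rule bookkeeping of what a QC step removed.

    ``n_input = n_retained + sum(len(v) for removed sets)`` must hold for
    feature filters (each feature is removed by exactly one rule).
    """

    n_input: int
    n_retained: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    flagged: dict[str, list[str]] = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + sum(
            len(v) for v in self.removed.values()
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed": self.removed,
            "flagged": self.flagged,
            "details": self.details,
        }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multi-omic cohort generator.

    Defaults mirror the structure of the motivating 20-subject childhood
    asthma cohort: 68 assayed metabolites of which 2 are constant and 2
    mostly missing, genome-scale SNP/expression/CpG panels at reduced
    width, and a binary phenotype whose true Markov neighborhood is 4 SNPs
    plus 2 metabolites.
    """

    n_subjects: int = 20
    n_snps: int = 2000
    n_expr_probes: int = 2000
    n_cpg_sites: int = 2000
    n_metabolites: int = 68
    n_zero_variance_metabolites: int = 2
    n_high_missing_metabolites: int = 2
    maf_range: tuple[float, float] = (0.1, 0.5)
    # planted Markov neighborhood of the phenotype: SNP/metabolite indices
    # with signed effects on the phenotype log-odds
    blanket_snps: tuple[int, ...] = (0, 1, 2, 3)
    blanket_snp_effects: tuple[float, ...] = (0.8, -0.8, 0.8, -0.8)
    blanket_metabolites: tuple[int, ...] = (0, 1)
    blanket_metabolite_effects: tuple[float, ...] = (0.8, -0.8)
    snp_metabolite_coupling: float = 0.6
    # correlated metabolite blocks: (member indices, target pairwise r^2);
    # defaults emulate the observed bile-acid pair (r^2 = 0.95) and the
    # 4-member saturated/eicosanoid fatty-acid block (r^2 > 0.9)
    metabolite_block_spec: tuple[tuple[tuple[int, ...], float], ...] = (
        ((2, 3), 0.95),
        ((4, 5, 6, 7), 0.92),
    )
    assoc_fraction: float = 0.01
    assoc_effect: float = 0.8
    modality_overlap: dict[str, int] | None = None  # modality -> n available
    missing_rate: float = 0.02
    plate_effect: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5 or (0 < lo <= hi <= 0.5)):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if len(self.blanket_snps) != len(self.blanket_snp_effects):
            raise ValueError("blanket_snps and blanket_snp_effects length mismatch")
        if len(self.blanket_metabolites) != len(self.blanket_metabolite_effects):
            raise ValueError(
                "blanket_metabolites and blanket_metabolite_effects length mismatch"
            )
        if any(i >= self.n_snps or i < 0 for i in self.blanket_snps):
            raise ValueError("blanket SNP index out of range")
        if any(i >= self.n_metabolites or i < 0 for i in self.blanket_metabolites):
            raise ValueError("blanket metabolite index out of range")
        if not all(np.isfinite(self.blanket_snp_effects)) or not all(
            np.isfinite(self.blanket_metabolite_effects)
        ):
            raise ValueError("effect sizes must be finite")
        n_degen = self.n_zero_variance_metabolites + self.n_high_missing_metabolites
        degenerate = set(
            range(self.n_metabolites - n_degen, self.n_metabolites)
        )
        for members, r2 in self.metabolite_block_spec:
            if not 0 <= r2 <= 1:
                raise ValueError(f"block target r^2 must be in [0, 1], got {r2}")
            if any(m >= self.n_metabolites or m < 0 for m in members):
                raise ValueError("block member index out of range")
            if set(members) & degenerate:
                raise ValueError(
                    "correlation-block members overlap degenerate "
                    "(zero-variance / high-missing) metabolites"
                )
            if set(members) & set(self.blanket_metabolites):
                raise ValueError("block members overlap planted blanket metabolites")
        if set(self.blanket_metabolites) & degenerate:
            raise ValueError("planted blanket metabolites overlap degenerate ones")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if self.modality_overlap:
            for mod, n in self.modality_overlap.items():
                if mod not in OmicsDataset.MODALITIES:
                    raise ValueError(f"unknown modality {mod!r}")
                if not 1 <= n <= self.n_subjects:
                    raise ValueError(f"overlap for {mod} outside [1, n_subjects]")


@dataclass
class PlantedTruth:
    """Ground truth the generator plants, for downstream recovery tests."""

    true_edges: list[tuple[str, str]]
    true_markov_neighborhood: list[str]
    true_assoc_pairs: list[tuple[str, str, float]]
    node_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "true_edges": [list(e) for e in self.true_edges],
            "true_markov_neighborhood": list(self.true_markov_neighborhood),
            "true_assoc_pairs": [list(p) for p in self.true_assoc_pairs],
            "node_params": self.node_params,
        }
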