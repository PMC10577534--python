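"""Cross-model comparison of DE results and the physiological-aging overlap.

Two progeroid models are compared by (i) the overlap of their DE aptamer
sets, (ii) Pearson/Spearman correlation and OLS slope of their log2
fold-changes over the union of aptamers significant in either model-specific
comparison, and (iii) the overlap between proteins changing in healthy aging
(young vs old reference mice) and proteins changing in progeria, restricted
to the gene-level intersection of the two assay panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import diffexpr
from .panel_io import ProteomeMatrix, SampleMetadata


@dataclass
class OverlapSummary:
    n_A: int
    n_B: int
    n_shared: int
    shared_frac_of_A: float
    shared_frac_of_B: float

    @property
    def shared_pct_of_A(self) -> float:
        return round(100.0 * self.shared_frac_of_A, 1)

    @property
    def shared_pct_of_B(self) -> float:
        return round(100.0 * self.shared_frac_of_B, 1)

    def to_dict(self) -> dict:
        return {
            "n_A": self.n_A,
            "n_B": self.n_B,
            "n_shared": self.n_shared,
            "shared_pct_of_A": self.shared_pct_of_A,
            "shared_pct_of_B": self.shared_pct_of_B,
        }


@dataclass
class ConcordanceSummary:
    pearson_r: float
    spearman_rho: float
    ols_slope: float
    ols_intercept: float
    n_points: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def shared_percentage(n_shared: int, n_total: int) -> float:
    """Shared percentage to one decimal (e.g. 32 of 67 -> 47.8)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_shared / n_total, 1)


def _de_set(table: pd.DataFrame) -> set[str]:
    return set(table.loc[table["is_de"], "aptamer_id"])


def overlap_de(de_A: pd.DataFrame, de_B: pd.DataFrame) -> OverlapSummary:
    """Venn-style overlap of the DE aptamer sets of two comparisons."""
    a, b = _de_set(de_A), _de_set(de_B)
    shared = a & b
    return OverlapSummary(
        n_A=len(a),
        n_B=len(b),
        n_shared=len(shared),
        shared_frac_of_A=len(shared) / len(a) if a else 0.0,
        shared_frac_of_B=len(shared) / len(b) if b else 0.0,
    )


def fold_change_concordance(de_A: pd.DataFrame, de_B: pd.DataFrame) -> ConcordanceSummary:
    """Fold-change agreement on the union of DE aptamers of the two models.

    OLS regresses B's log2FC on A's (with intercept), so the slope reads as
    the attenuation of model B's response relative to model A's.
    """
    union = _de_set(de_A) | _de_set(de_B)
    a = de_A.set_index("aptamer_id")["log2FC"]
    b = de_B.set_index("aptamer_id")["log2FC"]
    common = sorted(union & set(a.index) & set(b.index))
    if len(common) < 3:
        raise ValueError(f"need >= 3 aptamers in the union-of-significant set, got {len(common)}")
    x = a.loc[common].to_numpy(dtype=float)
    y = b.loc[common].to_numpy(dtype=float)
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    slope, intercept = np.polyfit(x, y, 1)
    return ConcordanceSummary(
        pearson_r=pearson,
        spearman_rho=spearman,
        ols_slope=float(slope),
        ols_intercept=float(intercept),
        n_points=len(common),
    )


def concordance_points(de_A: pd.DataFrame, de_B: pd.DataFrame) -> pd.DataFrame:
    """Scatter data (aptamer, log2FC_A, log2FC_B) behind the concordance fit."""
    union = _de_set(de_A) | _de_set(de_B)
    a = de_A.set_index("aptamer_id")["log2FC"]
    b = de_B.set_index("aptamer_id")["log2FC"]
    common = sorted(union & set(a.index) & set(b.index))
    return pd.DataFrame(
        {"aptamer_id": common, "log2FC_A": a.loc[common].to_numpy(), "log2FC_B": b.loc[common].to_numpy()}
    )


def physiological_overlap(
    reference_matrix: ProteomeMatrix,
    reference_meta: SampleMetadata,
    study_matrix: ProteomeMatrix,
    study_meta: SampleMetadata,
    feature_space,
    young_window: tuple[float, float] = (3.0, 6.0),
    old_window: tuple[float, float] = (18.0, 21.0),
    fdr: float = 0.1,
    moderation: bool = True,
    weights: bool = True,
) -> dict:
    """Overlap between healthy-aging DE and progeroid DE at the gene level.

    Young-vs-old DE is computed on reference mice inside the two age windows;
    progeroid-vs-wildtype DE is recomputed on the study cohorts; both are
    restricted to the shared gene-level feature space (one aptamer per gene
    per dataset) and compared at the same FDR threshold.
    """
    ref_tbl = reference_meta.table
    young = ref_tbl["age_months"].between(*young_window)
    old = ref_tbl["age_months"].between(*old_window)
    if young.sum() == 0 or old.sum() == 0:
        raise ValueError("empty young or old age-window selection")
    sel = ref_tbl[young | old].copy()
    sel["age_group"] = np.where(sel["age_months"] <= young_window[1], "young", "old")

    ref_apts = [feature_space.ref_aptamer_of[g] for g in feature_space.genes]
    study_apts = [feature_space.study_aptamer_of[g] for g in feature_space.genes]
    ref_sub = reference_matrix.subset_samples(sel["sample_id"]).subset_aptamers(ref_apts)
    spec = diffexpr.DesignSpec(
        terms=["age_group", "sex"], contrast="age_group", reference_levels={"age_group": "young"}
    )
    aging_de, _ = diffexpr.run_de(
        ref_sub, sel, spec=spec, fdr_threshold=fdr, moderation=moderation, weights=weights
    )

    study_sub = study_matrix.subset_aptamers(study_apts)
    study_sel = study_meta.subset(study_sub.sample_ids).aligned_to(study_sub)
    prog_de, _ = diffexpr.run_de(
        study_sub, study_sel, fdr_threshold=fdr, moderation=moderation, weights=weights
    )

    gene_of_ref = {v: k for k, v in feature_space.ref_aptamer_of.items()}
    gene_of_study = {v: k for k, v in feature_space.study_aptamer_of.items()}
    aging_genes = {gene_of_ref[a] for a in _de_set(aging_de)}
    prog_genes = {gene_of_study[a] for a in _de_set(prog_de)}
    shared = aging_genes & prog_genes
    return {
        "n_aging_de": len(aging_genes),
        "n_prog_de": len(prog_genes),
        "n_shared": len(shared),
        "shared_pct": shared_percentage(len(shared), len(aging_genes)) if aging_genes else 0.0,
    }
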