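"""Per-aptamer differential expression of log2 RFU.

The model is an ordinary (optionally precision-weighted) linear model fitted
independently to every aptamer, with treatment-coded covariates from the
sample metadata (genotype, sex, cohort, model, and a sex:genotype
interaction when requested). Residual variances are optionally shrunk toward
a common prior by empirical Bayes: the prior degrees of freedom d0 and prior
variance s0^2 of a scaled inverse-chi-square distribution are estimated by
matching the mean and variance of log s^2 to their digamma/trigamma
expressions, the posterior variance is

    s~^2_g = (d0 * s0^2 + df_g * s^2_g) / (d0 + df_g),

and the moderated t statistic coef / (s~_g * unscaled_se) is referred to a t
distribution on d0 + df_g degrees of freedom. FDR is controlled with the
Benjamini-Hochberg step-up procedure; aptamers with FDR below the threshold
(default 0.05) are called differentially expressed.

Precision weights mirror the mean-variance modelling step of the original
pipeline: a lowess curve of the quarter-root residual variance against mean
log2 abundance is interpolated at each observation's fitted value and
inverted to an inverse-variance weight; a flat trend yields unit weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .panel_io import AptamerPanel, ProteomeMatrix, SampleMetadata

DEFAULT_FDR = 0.05

# reference levels so that coefficients read as progeroid-vs-wildtype etc.
DEFAULT_REFERENCES = {"genotype": "wildtype", "sex": "female"}


class DesignError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Which covariates enter the model and which coefficient is the log2FC.

    ``terms`` name metadata columns (categorical or numeric) or a product
    term "a:b". ``contrast`` names a term (resolved to its indicator column
    when unambiguous) or a full design column. Categorical terms with fewer
    than two observed levels are dropped, so the same spec serves global and
    model-specific subsets.
    """

    terms: list[str] = field(default_factory=lambda: ["genotype", "model", "sex", "cohort"])
    contrast: str = "genotype"
    reference_levels: dict[str, str] = field(default_factory=dict)

    def reference_for(self, term: str) -> str | None:
        return {**DEFAULT_REFERENCES, **self.reference_levels}.get(term)


@dataclass
class DesignMatrix:
    X: np.ndarray
    columns: list[str]
    contrast_index: int
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def _meta_table(metadata: SampleMetadata | pd.DataFrame) -> pd.DataFrame:
    return metadata.table if isinstance(metadata, SampleMetadata) else metadata


def _term_columns(tbl: pd.DataFrame, term: str, spec: DesignSpec) -> list[tuple[str, np.ndarray]]:
    if term not in tbl.columns:
        raise DesignError(f"term {term!r} not found in metadata")
    col = tbl[term]
    if pd.api.types.is_numeric_dtype(col):
        return [(term, col.to_numpy(dtype=float))]
    levels = sorted(col.unique())
    ref = spec.reference_for(term)
    if ref in levels:
        levels = [ref] + [l for l in levels if l != ref]
    if len(levels) < 2:
        return []  # constant within this subset: absorbed by the intercept
    return [
        (f"{term}[{lev}]", (col == lev).to_numpy(dtype=float)) for lev in levels[1:]
    ]


def build_design(metadata: SampleMetadata | pd.DataFrame, spec: DesignSpec) -> DesignMatrix:
    """Treatment-coded full-rank design matrix with intercept.

    Interaction terms "a:b" are element-wise products of the main-effect
    codings. Rank deficiency raises an error naming the collinear columns.
    """
    tbl = _meta_table(metadata)
    names: list[str] = ["Intercept"]
    cols: list[np.ndarray] = [np.ones(len(tbl))]
    for term in spec.terms:
        if ":" in term:
            a, b = term.split(":", 1)
            for na, va in _term_columns(tbl, a, spec):
                for nb, vb in _term_columns(tbl, b, spec):
                    names.append(f"{na}:{nb}")
                    cols.append(va * vb)
        else:
            for name, vec in _term_columns(tbl, term, spec):
                names.append(name)
                cols.append(vec)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of columns that do not add rank
        bad = []
        kept = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(names[j])
            else:
                kept.append(j)
        raise DesignError(f"design matrix rank-deficient; collinear columns: {bad}")

    contrast = spec.contrast
    if contrast in names:
        idx = names.index(contrast)
    else:
        matches = [
            j
            for j, n in enumerate(names)
            if n == contrast
            or n.startswith(f"{contrast}[")
            or _strip_levels(n) == contrast
        ]
        if len(matches) != 1:
            raise DesignError(
                f"contrast {contrast!r} resolves to {len(matches)} design columns"
            )
        idx = matches[0]
    sample_ids = (
        list(tbl["sample_id"]) if "sample_id" in tbl.columns else [str(i) for i in range(len(tbl))]
    )
    return DesignMatrix(X=X, columns=names, contrast_index=idx, sample_ids=sample_ids)


def _strip_levels(name: str) -> str:
    # "sex[male]:genotype[progeroid]" -> "sex:genotype"
    out, depth = [], 0
    for ch in name:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        elif depth == 0:
            out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# Per-aptamer least squares
# ---------------------------------------------------------------------------

@dataclass
class LMFits:
    """Weighted least-squares fits for all aptamers against one design."""

    aptamer_ids: list[str]
    coefficients: np.ndarray      # p x q
    unscaled_se: np.ndarray       # p x q, sqrt(diag (X'WX)^-1)
    sigma2: np.ndarray            # p, residual variance s^2
    df: float                     # residual degrees of freedom (common)
    design: DesignMatrix
    fitted: np.ndarray            # n x p


def fit_per_aptamer_lm(
    matrix: ProteomeMatrix,
    design: DesignMatrix,
    weights: np.ndarray | pd.DataFrame | None = None,
) -> LMFits:
    """Fit y_g = X beta_g + e independently per aptamer (vectorized WLS)."""
    Y = matrix.values.to_numpy(dtype=float)
    if list(matrix.sample_ids) != list(design.sample_ids):
        matched = matrix.values.reindex(design.sample_ids)
        if matched.isna().any().any():
            raise DesignError("matrix and design sample ids differ")
        Y = matched.to_numpy(dtype=float)
    X = design.X
    n, q = X.shape
    p = Y.shape[1]
    df = n - q
    if df <= 0:
        raise DesignError(f"zero residual degrees of freedom (n={n}, q={q})")
    if weights is None:
        W = np.ones((n, p))
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != (n, p):
            raise DesignError(f"weights shape {W.shape} != {(n, p)}")
        if (W <= 0).any() or not np.all(np.isfinite(W)):
            raise DesignError("weights must be finite and positive")

    XtWX = np.einsum("np,nq,nr->pqr", W, X, X)
    XtWy = np.einsum("nq,np->pq", X, W * Y)
    XtWX_inv = np.linalg.inv(XtWX)
    beta = np.einsum("pqr,pr->pq", XtWX_inv, XtWy)
    fitted = X @ beta.T
    resid = Y - fitted
    sigma2 = np.einsum("np,np->p", W, resid**2) / df
    sigma2 = np.where(sigma2 < 0, 0.0, sigma2)  # guard tiny negative round-off
    unscaled_se = np.sqrt(np.einsum("pqq->pq", XtWX_inv))
    return LMFits(
        aptamer_ids=list(matrix.aptamer_ids),
        coefficients=beta,
        unscaled_se=unscaled_se,
        sigma2=sigma2,
        df=float(df),
        design=design,
        fitted=fitted,
    )


def estimate_precision_weights(
    matrix: ProteomeMatrix,
    design: DesignMatrix,
    lowess_frac: float = 0.5,
    flat_tol: float = 0.05,
) -> np.ndarray:
    """Mean-variance precision weights (n_samples x n_aptamers).

    Fits lowess of sqrt(residual sd) against mean log2 abundance across
    aptamers, interpolates the curve at each observation's fitted value and
    returns normalized inverse-variance weights. Returns all-ones when the
    trend is flat (the fitted linear slope moves the quarter-root sd by less
    than ``flat_tol`` of its median over the abundance range) or when fewer
    than 50 aptamers are available.
    """
    n, p = matrix.shape
    if p < 50:
        warnings.warn("fewer than 50 aptamers: precision weights set to 1", stacklevel=2)
        return np.ones((n, p))
    fits = fit_per_aptamer_lm(matrix, design)
    mean_abund = matrix.values.to_numpy().mean(axis=0)
    quarter_sd = fits.sigma2 ** 0.25

    span = mean_abund.max() - mean_abund.min()
    med = np.median(quarter_sd)
    if med <= 0 or span <= 0:
        return np.ones((n, p))
    slope, _ = np.polyfit(mean_abund, quarter_sd, 1)
    if abs(slope) * span < flat_tol * med:
        return np.ones((n, p))

    smoothed = lowess(quarter_sd, mean_abund, frac=lowess_frac, return_sorted=True)
    xs, ys = smoothed[:, 0], np.maximum(smoothed[:, 1], 1e-8)
    interp = np.interp(np.clip(fits.fitted, xs[0], xs[-1]), xs, ys)
    w = interp ** -4.0
    return w / w.mean()


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass
class ModerationParams:
    d0: float        # prior degrees of freedom (may be inf)
    s0_sq: float     # prior variance, (log2 RFU)^2


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y <= 0:
        raise FloatingPointError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < tol:
            return float(x)
    raise FloatingPointError("trigamma inversion did not converge")


def estimate_moderation_params(sigma2: np.ndarray, df: float) -> ModerationParams:
    """Method-of-moments fit of the scaled-F model to the observed s^2.

    Matches mean and variance of log s^2 to their digamma/trigamma
    expressions; a non-positive excess variance or a failed trigamma
    inversion falls back to d0 = inf (complete shrinkage to the pooled
    variance), with a warning in the latter case.
    """
    s2 = sigma2[sigma2 > 0]
    if len(s2) < 10:
        raise DesignError("moderation requires >= 10 aptamers with positive variance")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        try:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
            return ModerationParams(d0=d0, s0_sq=s0)
        except FloatingPointError:
            warnings.warn("trigamma inversion failed; using d0 = inf", stacklevel=2)
    return ModerationParams(d0=np.inf, s0_sq=float(np.exp(emean)))


def moderate_variances(
    fits: LMFits, params: ModerationParams | None = None
) -> tuple[ModerationParams, np.ndarray, np.ndarray]:
    """Posterior variances and moderated t / p for the contrast coefficient."""
    if params is None:
        params = estimate_moderation_params(fits.sigma2, fits.df)
    d0, s0 = params.d0, params.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(fits.sigma2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + fits.df * fits.sigma2) / (d0 + fits.df)
        df_total = d0 + fits.df
    j = fits.design.contrast_index
    coef = fits.coefficients[:, j]
    denom = np.sqrt(s2_post) * fits.unscaled_se[:, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, coef / denom, np.sign(coef) * np.inf)
    t = np.where((denom == 0) & (coef == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return params, t, p


def ordinary_t(fits: LMFits) -> tuple[np.ndarray, np.ndarray]:
    """Unmoderated t and p for the contrast coefficient."""
    j = fits.design.contrast_index
    coef = fits.coefficients[:, j]
    denom = np.sqrt(fits.sigma2) * fits.unscaled_se[:, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, coef / denom, np.sign(coef) * np.inf)
    t = np.where((denom == 0) & (coef == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), fits.df)
    return t, p


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------

DE_COLUMNS = ["aptamer_id", "gene_symbol", "log2FC", "t", "p", "fdr", "is_de", "direction"]


def summarize_counts(n_down: int, n_up: int) -> dict:
    """DE summary arithmetic from down/up counts (percentages to one decimal)."""
    n_de = n_down + n_up
    pct_down = round(100.0 * n_down / n_de, 1) if n_de else 0.0
    pct_up = round(100.0 * n_up / n_de, 1) if n_de else 0.0
    return {"n_de": n_de, "n_up": n_up, "n_down": n_down, "pct_down": pct_down, "pct_up": pct_up}


def _assemble_table(
    fits: LMFits,
    t: np.ndarray,
    p: np.ndarray,
    fdr_threshold: float,
    panel: AptamerPanel | None,
) -> pd.DataFrame:
    fdr = bh_adjust(p)
    j = fits.design.contrast_index
    coef = fits.coefficients[:, j]
    if panel is not None:
        sym = panel.table.set_index("aptamer_id")["gene_symbol"]
        gene = [sym.get(a, "") for a in fits.aptamer_ids]
    else:
        gene = [""] * len(fits.aptamer_ids)
    table = pd.DataFrame(
        {
            "aptamer_id": fits.aptamer_ids,
            "gene_symbol": gene,
            "log2FC": coef,
            "t": t,
            "p": p,
            "fdr": fdr,
            "is_de": fdr < fdr_threshold,
            "direction": np.where(coef >= 0, "up", "down"),
            "zero_variance": fits.sigma2 == 0,
        }
    )
    return table


def run_de(
    matrix: ProteomeMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    spec: DesignSpec | None = None,
    fdr_threshold: float = DEFAULT_FDR,
    moderation: bool = True,
    weights: bool = True,
    panel: AptamerPanel | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full DE analysis: design, (weights), per-aptamer WLS, (moderation), BH.

    Returns the per-aptamer result table and a summary dict with n_de, n_up,
    n_down and pct_down/pct_up rounded to one decimal.
    """
    spec = spec or DesignSpec()
    design = build_design(metadata, spec)
    w = estimate_precision_weights(matrix, design) if weights else None
    fits = fit_per_aptamer_lm(matrix, design, weights=w)
    if moderation:
        _, t, p = moderate_variances(fits)
    else:
        t, p = ordinary_t(fits)
    table = _assemble_table(fits, t, p, fdr_threshold, panel)
    de = table[table["is_de"]]
    summary = summarize_counts(
        n_down=int((de["direction"] == "down").sum()),
        n_up=int((de["direction"] == "up").sum()),
    )
    return table, summary


def test_interaction(
    matrix: ProteomeMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    spec: DesignSpec | None = None,
    fdr_threshold: float = DEFAULT_FDR,
    moderation: bool = True,
    weights: bool = True,
    panel: AptamerPanel | None = None,
) -> pd.DataFrame:
    """Sex-specific genotype effects: test the sex:genotype coefficient.

    The interaction table gets its own BH adjustment across aptamers.
    """
    tbl = _meta_table(metadata)
    cross = pd.crosstab(tbl["sex"], tbl["genotype"])
    if cross.shape != (2, 2) or (cross.to_numpy() == 0).any():
        raise DesignError("interaction test requires both sexes in both genotypes")
    if spec is None:
        terms = ["genotype", "sex", "sex:genotype"]
        if tbl["cohort"].nunique() > 1:
            terms.insert(2, "cohort")
        if "model" in tbl.columns and tbl["model"].nunique() > 1:
            terms.insert(1, "model")
        spec = DesignSpec(terms=terms, contrast="sex:genotype")
    table, _ = run_de(
        matrix,
        metadata,
        spec=spec,
        fdr_threshold=fdr_threshold,
        moderation=moderation,
        weights=weights,
        panel=panel,
    )
    return table


def write_de_table(path, table: pd.DataFrame) -> None:
    cols = [c for c in DE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)
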