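"""Ensemble proteomic aging clock.

A sparse linear model predicting chronological age (months) from standardized
log2 RFU protein levels is trained on a cross-sectional reference cohort plus
a resampled subset of the study's wild-type controls, with a binary batch
feature (reference = 0, study = 1) so the cross-dataset shift can be
inferred. Because the study contributes few controls, the sampling is
repeated (default 200 iterations), each iteration keeping at least
``min_train_controls`` controls in training and at least
``min_infer_controls`` out for inference. Each iteration fits an L1-penalized
(LASSO) regression by cyclic coordinate descent with soft-threshold updates;
the penalty is chosen by k-fold cross-validation over a geometric path from
lambda_max down to eps * lambda_max. The ensemble then yields per-sample
predicted-age distributions, per-group age gaps (predicted - chronological;
positive = age acceleration) and per-gene selection frequencies.

Features are the gene-level intersection of the two assay panels: genes
measured by exactly one aptamer in each dataset (multi-aptamer genes and
compound symbols are dropped as ambiguous).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel_io import AptamerPanel, ProteomeMatrix, SampleMetadata

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

BATCH_FEATURE = "__batch__"


class ClockError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Feature space: gene-level panel intersection
# ---------------------------------------------------------------------------

@dataclass
class ClockFeatureSpace:
    genes: list[str]
    ref_aptamer_of: dict[str, str]
    study_aptamer_of: dict[str, str]

    def __len__(self) -> int:
        return len(self.genes)


def _unambiguous_gene_map(panel: AptamerPanel) -> dict[str, str]:
    """gene -> aptamer for genes measured by exactly one aptamer.

    Compound symbols ("A|B") are excluded: they are ambiguous at gene level.
    """
    counts: dict[str, list[str]] = {}
    for apt, sym in zip(panel.table["aptamer_id"], panel.table["gene_symbol"]):
        if not sym or "|" in sym:
            continue
        counts.setdefault(sym, []).append(apt)
    return {g: apts[0] for g, apts in counts.items() if len(apts) == 1}


def intersect_by_gene(panel_ref: AptamerPanel, panel_study: AptamerPanel) -> ClockFeatureSpace:
    """Genes common to both panels, one aptamer per gene per dataset."""
    ref_map = _unambiguous_gene_map(panel_ref)
    study_map = _unambiguous_gene_map(panel_study)
    genes = sorted(set(ref_map) & set(study_map))
    if not genes:
        raise ClockError("empty gene-level intersection between panels")
    return ClockFeatureSpace(
        genes=genes,
        ref_aptamer_of={g: ref_map[g] for g in genes},
        study_aptamer_of={g: study_map[g] for g in genes},
    )


# ---------------------------------------------------------------------------
# LASSO by cyclic coordinate descent
# ---------------------------------------------------------------------------

MAX_SWEEPS = 100_000
CD_TOL = 1e-7


@njit(cache=False)
def _cd_solve(G, c, lam, pf, beta, tol, max_sweeps):  # pragma: no cover - jitted
    """Cyclic coordinate descent on the Gram system; beta updated in place.

    Minimizes 0.5 * beta'G beta - c'beta + lam * sum(pf_j * |beta_j|).
    Returns sweeps used, or -1 when max_sweeps is exhausted. Alternates one
    full cyclic sweep with inner sweeps over the active (nonzero) set.
    """
    p = G.shape[0]
    r = c - G @ beta
    sweeps = 0
    while True:
        # full sweep over all coordinates
        maxd = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            z = r[j] + gjj * beta[j]
            t = lam * pf[j]
            if z > t:
                bnew = (z - t) / gjj
            elif z < -t:
                bnew = (z + t) / gjj
            else:
                bnew = 0.0
            d = bnew - beta[j]
            if d != 0.0:
                beta[j] = bnew
                for k in range(p):
                    r[k] -= G[k, j] * d
                ad = abs(d)
                if ad > maxd:
                    maxd = ad
        sweeps += 1
        if maxd < tol:
            return sweeps
        if sweeps >= max_sweeps:
            return -1
        # inner sweeps over the active set only
        while True:
            maxd = 0.0
            for j in range(p):
                if beta[j] == 0.0:
                    continue
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                z = r[j] + gjj * beta[j]
                t = lam * pf[j]
                if z > t:
                    bnew = (z - t) / gjj
                elif z < -t:
                    bnew = (z + t) / gjj
                else:
                    bnew = 0.0
                d = bnew - beta[j]
                if d != 0.0:
                    beta[j] = bnew
                    for k in range(p):
                        r[k] -= G[k, j] * d
                    ad = abs(d)
                    if ad > maxd:
                        maxd = ad
            sweeps += 1
            if maxd < tol:
                break
            if sweeps >= max_sweeps:
                return -1


def _gram(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    xm = X.mean(axis=0)
    Xc = X - xm
    ym = float(y.mean())
    G = Xc.T @ Xc / n
    c = Xc.T @ (y - ym) / n
    return G, c, xm, ym


def lasso_objective(X: np.ndarray, y: np.ndarray, intercept: float, beta: np.ndarray, lam: float) -> float:
    """(1/2n)||y - b0 - X beta||^2 + lam * ||beta||_1."""
    n = X.shape[0]
    resid = y - intercept - X @ beta
    return float(0.5 * resid @ resid / n + lam * np.abs(beta).sum())


@dataclass
class ClockModel:
    """One fitted sparse clock: age (months) ~ standardized protein levels."""

    intercept: float
    coefficients: dict[str, float]      # nonzero only, months per standardized unit
    lam: float
    feature_names: list[str]
    training_sample_ids: list[str] = field(default_factory=list)

    @property
    def batch_coefficient(self) -> float:
        return self.coefficients.get(BATCH_FEATURE, 0.0)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients.get(f, 0.0) for f in self.feature_names])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coef_vector()


def fit_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    feature_names: list[str] | None = None,
    penalty_factors: np.ndarray | None = None,
    beta_init: np.ndarray | None = None,
    tol: float = CD_TOL,
) -> ClockModel:
    """Solve the LASSO at one penalty; the intercept is unpenalized.

    ``X`` is expected standardized (training-set mean 0, sd 1); ``y`` is
    centered internally and the intercept recovered afterwards.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ClockError("non-finite values in X or y")
    if lam < 0:
        raise ClockError("lambda must be >= 0")
    if X.shape[0] != y.shape[0] or X.shape[0] < 2:
        raise ClockError(f"bad shapes: X {X.shape}, y {y.shape}")
    p = X.shape[1]
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, dtype=float)
    G, c, xm, ym = _gram(X, y)
    beta = np.zeros(p) if beta_init is None else np.array(beta_init, dtype=float)
    sweeps = _cd_solve(G, c, lam, pf, beta, tol, MAX_SWEEPS)
    if sweeps < 0:
        raise ClockError(f"coordinate descent did not converge in {MAX_SWEEPS} sweeps")
    intercept = ym - float(xm @ beta)
    names = feature_names or [f"f{j}" for j in range(p)]
    coefs = {names[j]: float(beta[j]) for j in range(p) if beta[j] != 0.0}
    return ClockModel(intercept=intercept, coefficients=coefs, lam=float(lam), feature_names=list(names))


def lambda_path(X: np.ndarray, y: np.ndarray, n_lambda: int = 100, eps: float = 1e-3,
                penalty_factors: np.ndarray | None = None) -> np.ndarray:
    """Geometric penalty path from lambda_max (all-zero solution) downwards."""
    G, c, _, _ = _gram(X, y)
    pf = np.ones(len(c)) if penalty_factors is None else np.asarray(penalty_factors, dtype=float)
    with np.errstate(divide="ignore"):
        lam_max = float(np.max(np.where(pf > 0, np.abs(c) / np.maximum(pf, 1e-300), 0.0)))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, eps * lam_max, n_lambda)


PATH_SWEEP_CAP = 1000


def _fit_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
              pf: np.ndarray, tol: float = CD_TOL,
              sweep_cap: int = PATH_SWEEP_CAP) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started coefficient path; returns (betas n_lambda x p, intercepts).

    Path fits are for CV scoring only, so each lambda gets at most
    ``sweep_cap`` sweeps; a capped solution is kept as-is (the selected
    lambda's final model is re-solved tightly by ``fit_lasso``).
    """
    G, c, xm, ym = _gram(X, y)
    p = X.shape[1]
    betas = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        _cd_solve(G, c, float(lam), pf, beta, tol, sweep_cap)
        betas[i] = beta
        intercepts[i] = ym - float(xm @ beta)
    return betas, intercepts


def select_lambda_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    n_lambda: int = 100,
    eps: float = 1e-3,
    seed: int = 0,
    rule: str = "min",
    penalty_factors: np.ndarray | None = None,
) -> float:
    """Penalty selection by k-fold cross-validated mean squared error.

    ``rule="min"`` returns the CV-MSE-minimizing lambda; ``rule="1se"`` the
    largest lambda within one standard error of the minimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * n_folds:
        n_folds = max(2, n // 2)
        warnings.warn(f"too few samples; folds reduced to {n_folds}", stacklevel=2)
    pf = np.ones(X.shape[1]) if penalty_factors is None else np.asarray(penalty_factors, dtype=float)
    lambdas = lambda_path(X, y, n_lambda=n_lambda, eps=eps, penalty_factors=pf)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    # CV scoring tolerates a looser, y-scaled stopping rule than the final fit
    path_tol = max(CD_TOL, 1e-4 * float(np.std(y)))
    sq_err = np.zeros((n_folds, len(lambdas)))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx, assume_unique=False)
        betas, intercepts = _fit_path(X[train_idx], y[train_idx], lambdas, pf, tol=path_tol)
        preds = X[test_idx] @ betas.T + intercepts[None, :]
        sq_err[f] = ((preds - y[test_idx, None]) ** 2).mean(axis=0)
    cv_mean = sq_err.mean(axis=0)
    i_min = int(np.argmin(cv_mean))
    if rule == "min":
        return float(lambdas[i_min])
    if rule == "1se":
        cv_se = sq_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
        ok = cv_mean <= cv_mean[i_min] + cv_se[i_min]
        return float(lambdas[np.argmax(ok)])  # largest lambda on the path meeting it
    raise ClockError(f"unknown rule {rule!r}")


# ---------------------------------------------------------------------------
# Ensemble over constrained control resamplings
# ---------------------------------------------------------------------------

@dataclass
class ClockEnsemble:
    models: list[ClockModel]
    predictions: pd.DataFrame
    # columns: iteration, sample_id, role {control_inference, progeroid},
    #          model, chronological_age, predicted_age, age_gap
    feature_space: ClockFeatureSpace
    base_seed: int

    @property
    def n_iter(self) -> int:
        return len(self.models)

    def selection_counts(self) -> pd.Series:
        counts = pd.Series(0, index=self.feature_space.genes, dtype=int)
        for m in self.models:
            for gene in m.coefficients:
                if gene != BATCH_FEATURE:
                    counts[gene] += 1
        return counts

    def median_age_gap(self, by: str = "group") -> pd.Series:
        """Median predicted-minus-chronological age per group, pooled over
        all iterations' predictions."""
        return self.predictions.groupby(by)["age_gap"].median()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "base_seed": self.base_seed,
            "n_iter": self.n_iter,
            "genes": self.feature_space.genes,
            "models": [
                {
                    "intercept": m.intercept,
                    "lambda": m.lam,
                    "coefficients": m.coefficients,
                    "training_sample_ids": m.training_sample_ids,
                }
                for m in self.models
            ],
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def _standardize(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _feature_matrix(matrix: ProteomeMatrix, apt_of: dict[str, str], genes: list[str]) -> np.ndarray:
    return matrix.values[[apt_of[g] for g in genes]].to_numpy(dtype=float)


def build_clock_ensemble(
    ref_matrix: ProteomeMatrix,
    ref_meta: SampleMetadata,
    study_matrix: ProteomeMatrix,
    study_meta: SampleMetadata,
    feature_space: ClockFeatureSpace,
    n_iter: int = 200,
    min_train_controls: int = 3,
    min_infer_controls: int = 3,
    seed: int = 0,
    penalize_batch: bool = True,
    n_folds: int = 10,
    n_lambda: int = 100,
    eps: float = 1e-3,
    rule: str = "min",
) -> ClockEnsemble:
    """Fit the resampling ensemble of LASSO clocks.

    Per iteration i (seeded ``seed + i``): draw a without-replacement subset
    of the study's wild-type controls with at least ``min_train_controls``
    members and at least ``min_infer_controls`` left out; train on the full
    reference cohort plus those controls with the binary batch feature; pick
    the penalty by CV; predict the held-out controls and every progeroid
    sample (batch = 1).
    """
    genes = feature_space.genes
    ref_meta = ref_meta.aligned_to(ref_matrix)
    study_meta = study_meta.aligned_to(study_matrix)
    X_ref = _feature_matrix(ref_matrix, feature_space.ref_aptamer_of, genes)
    X_study = _feature_matrix(study_matrix, feature_space.study_aptamer_of, genes)
    y_ref = ref_meta.table["age_months"].to_numpy(dtype=float)
    y_study = study_meta.table["age_months"].to_numpy(dtype=float)

    is_control = (study_meta.table["genotype"] == "wildtype").to_numpy()
    control_idx = np.flatnonzero(is_control)
    prog_idx = np.flatnonzero(~is_control)
    n_controls = len(control_idx)
    if n_controls < min_train_controls + min_infer_controls:
        raise ClockError(
            f"{n_controls} controls cannot satisfy >= {min_train_controls} training "
            f"and >= {min_infer_controls} inference controls"
        )

    feature_names = genes + [BATCH_FEATURE]
    pf = np.ones(len(feature_names))
    if not penalize_batch:
        pf[-1] = 0.0

    study_ids = study_meta.table["sample_id"].to_numpy()
    study_models = study_meta.table["model"].to_numpy()

    models: list[ClockModel] = []
    rows: list[dict] = []
    for i in range(n_iter):
        rng = np.random.default_rng(seed + i)
        n_train = int(rng.integers(min_train_controls, n_controls - min_infer_controls + 1))
        train_controls = rng.choice(control_idx, size=n_train, replace=False)
        infer_controls = np.setdiff1d(control_idx, train_controls)

        X_train = np.vstack([X_ref, X_study[train_controls]])
        batch = np.concatenate([np.zeros(len(X_ref)), np.ones(n_train)])
        X_train = np.column_stack([X_train, batch])
        y_train = np.concatenate([y_ref, y_study[train_controls]])

        mu, sd = _standardize(X_train)
        Xs = (X_train - mu) / sd
        cv_seed = int(rng.integers(2**31))
        lam = select_lambda_cv(
            Xs, y_train, n_folds=n_folds, n_lambda=n_lambda, eps=eps,
            seed=cv_seed, rule=rule, penalty_factors=pf,
        )
        model = fit_lasso(Xs, y_train, lam, feature_names=feature_names, penalty_factors=pf)
        model.training_sample_ids = list(study_ids[train_controls])
        models.append(model)

        infer = np.concatenate([infer_controls, prog_idx])
        X_inf = np.column_stack([X_study[infer], np.ones(len(infer))])
        preds = model.predict((X_inf - mu) / sd)
        for j, idx in enumerate(infer):
            role = "control_inference" if idx in set(infer_controls) else "progeroid"
            rows.append(
                {
                    "iteration": i,
                    "sample_id": study_ids[idx],
                    "role": role,
                    "model": study_models[idx],
                    "group": f"{study_models[idx]}:{'wildtype' if role == 'control_inference' else 'progeroid'}",
                    "chronological_age": y_study[idx],
                    "predicted_age": float(preds[j]),
                }
            )
    predictions = pd.DataFrame(rows)
    predictions["age_gap"] = compute_age_gap(
        predictions["predicted_age"].to_numpy(), predictions["chronological_age"].to_numpy()
    )
    return ClockEnsemble(models=models, predictions=predictions, feature_space=feature_space, base_seed=seed)


def compute_age_gap(predicted: np.ndarray, chronological: np.ndarray) -> np.ndarray:
    """Age gap = predicted - chronological (months); positive = acceleration."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape:
        raise ClockError("predicted and chronological age vectors differ in length")
    if (chronological <= 0).any():
        raise ClockError("chronological ages must be positive")
    return predicted - chronological


def selection_frequency(ensemble: ClockEnsemble, threshold: float = 0.30) -> pd.DataFrame:
    """Genes with nonzero coefficients in at least ``threshold`` of the clocks."""
    counts = ensemble.selection_counts()
    freq = counts / ensemble.n_iter
    table = pd.DataFrame({"gene": freq.index, "frequency": freq.to_numpy()})
    table = table[table["frequency"] >= threshold]
    return table.sort_values(["frequency", "gene"], ascending=[False, True], kind="stable").reset_index(drop=True)
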