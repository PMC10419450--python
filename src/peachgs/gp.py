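"""rrBLUP genomic prediction with GWAS-selected marker panels.

The prediction model is ridge-regression BLUP: ``y = 1 mu + Z u + e`` with
marker effects ``u ~ N(0, sg2 I)`` over the panel of significant markers
selected by GWAS.  The shrinkage parameter ``lambda = se2/sg2`` comes from
EMMA REML on the training samples with the panel-derived relationship matrix
``Z Z' / m``.

Cross-validation follows the breeding-program protocol: the panel is split
into five subpopulations; in each loop, GWAS runs on four of them to select
markers, rrBLUP is fitted on the same four, and genomic estimated breeding
values (GEBVs) are predicted for the held-out fifth.  Replicate accuracy is
the Pearson correlation between observed phenotypes and pooled held-out
GEBVs; the final accuracy averages 30 such replicates.  In multi-trait mode
the panel is the union of markers selected for the focal trait and a set of
genetically correlated traits, which lifts accuracy when traits truly share
QTNs.  Held-out samples never touch marker selection or model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix, PhenotypeTable, normalize_traits
from .gwas import (
    AssociationResult,
    MLMWorkspace,
    VarianceComponents,
    blink_scan,
    call_significant,
    emma_reml,
    farmcpu_scan,
    mlm_scan,
    mlmm_scan,
)
from .kinship import genomic_kinship, pca_covariates

logger = logging.getLogger("peachgs")


class EmptyPanelError(ValueError):
    """No markers in the prediction panel; caller should fall back to top-k."""


@dataclass(frozen=True)
class CVScheme:
    """Replicated k-fold cross-validation plan, reproducible from a seed."""

    n_folds: int = 5
    n_replicates: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")

    def fold_assignment(self, replicate: int, n_samples: int) -> np.ndarray:
        """Fold label per sample for one replicate (a fresh seeded shuffle)."""
        if n_samples < self.n_folds:
            raise ValueError("fewer samples than folds")
        rng = np.random.default_rng([self.seed, replicate])
        perm = rng.permutation(n_samples)
        labels = np.empty(n_samples, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, self.n_folds)):
            labels[chunk] = f
        return labels


@dataclass
class RRBLUPModel:
    """Fitted rrBLUP model: intercept, per-marker effects and the panel order."""

    intercept: float
    effects: np.ndarray
    marker_ids: list[str]
    vc: VarianceComponents


@dataclass
class GPResult:
    """Cross-validated genomic prediction outcome for one trait."""

    trait: str
    mode: str
    replicate_accuracies: np.ndarray
    final_accuracy: float
    gebv: pd.Series  # pooled held-out GEBV per sample, averaged over replicates
    h2: float
    panels: dict = field(default_factory=dict)  # (replicate, fold) -> marker ids
    fallback_events: int = 0

    def __post_init__(self) -> None:
        acc = np.asarray(self.replicate_accuracies, dtype=float)
        if np.any(np.abs(acc[~np.isnan(acc)]) > 1 + 1e-9):
            raise ValueError("accuracy outside [-1, 1]")


# ---------------------------------------------------------------------------
# rrBLUP core
# ---------------------------------------------------------------------------

def rrblup_fit(y: np.ndarray, Z: np.ndarray,
               marker_ids: list[str] | None = None,
               lam: float | None = None) -> RRBLUPModel:
    """Fit ``y = 1 mu + Z u + e`` with ridge shrinkage from EMMA REML.

    ``lambda = se2/sg2`` is estimated on the training set using the panel
    relationship matrix ``K = Z Z' / m`` (so the per-marker ridge parameter is
    ``m * delta_K``); effects solve ``(Z'Z + lambda I) u = Z'(y - mu)`` with
    ``mu`` the phenotype mean.  ``lam`` overrides the REML estimate (e.g. to
    force the infinite-shrinkage limit).
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] == 0:
        raise EmptyPanelError("empty marker panel; use a top-k fallback panel")
    if Z.shape[0] != y.size:
        raise ValueError("Z rows must match phenotype length")
    if y.size <= 2:
        raise ValueError("need more than 2 training samples")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance phenotype")
    m = Z.shape[1]
    K = Z @ Z.T / m
    X0 = np.ones((y.size, 1))
    vc = emma_reml(y, X0, K)
    if lam is None:
        lam = m * vc.delta
    mu = float(y.mean())
    yc = y - mu
    if np.isfinite(lam):
        u = np.linalg.solve(Z.T @ Z + lam * np.eye(m), Z.T @ yc)
    else:  # infinite shrinkage: all effects vanish
        u = np.zeros(m)
    ids = list(marker_ids) if marker_ids is not None else [f"m{j}" for j in range(m)]
    return RRBLUPModel(intercept=mu, effects=u, marker_ids=ids, vc=vc)


def predict_gebv(model: RRBLUPModel, Z_new: np.ndarray,
                 marker_ids: list[str] | None = None) -> np.ndarray:
    """GEBVs ``mu + Z_new u`` for new samples.

    ``Z_new`` columns must follow the training panel order; passing
    ``marker_ids`` remaps columns by id instead (error if the sets differ).
    """
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    if marker_ids is not None:
        if set(marker_ids) != set(model.marker_ids):
            raise ValueError("marker id sets differ between panel and input")
        order = [list(marker_ids).index(mid) for mid in model.marker_ids]
        Z_new = Z_new[:, order]
    if Z_new.shape[1] != model.effects.size:
        raise ValueError(
            f"{Z_new.shape[1]} columns but the panel has {model.effects.size} markers"
        )
    return model.intercept + Z_new @ model.effects


def estimate_heritability(y: np.ndarray, K) -> float:
    """Narrow-sense heritability: genotype-explained fraction of phenotype
    variance, from EMMA REML with an intercept-only fixed model."""
    y = np.asarray(y, dtype=float).ravel()
    return emma_reml(y, np.ones((y.size, 1)), K).h2


# ---------------------------------------------------------------------------
# Cross-validated GWAS + GP
# ---------------------------------------------------------------------------

DEFAULT_GWAS_CONFIG = {
    "models": ("mlm", "mlmm", "farmcpu", "blink"),
    "n_pcs": 3,
    "alpha": 0.01,
    "fallback_k": 10,
}


def _run_models(y, X, K, g, models, alpha, workspace=None) -> list[AssociationResult]:
    out = []
    for model in models:
        if model == "mlm":
            out.append(mlm_scan(y, X, K, g, alpha=alpha, workspace=workspace))
        elif model == "mlmm":
            out.append(mlmm_scan(y, X, K, g, alpha=alpha, workspace=workspace))
        elif model == "farmcpu":
            out.append(farmcpu_scan(y, X, g, alpha=alpha))
        elif model == "blink":
            out.append(blink_scan(y, X, g, alpha=alpha))
        else:
            raise ValueError(f"unknown GWAS model {model!r}")
    return out


def _fold_panel(results: list[AssociationResult], alpha: float,
                n_markers: int, fallback_k: int) -> tuple[list[str], bool]:
    """Bonferroni-significant marker union; top-k fallback when empty."""
    cutoff = -np.log10(alpha / n_markers)
    panel = call_significant(results, cutoff).marker_ids
    if panel:
        return panel, False
    best_p: dict[str, float] = {}
    for res in results:
        tab = res.table.dropna(subset=["p"])
        for mid, p in zip(tab["id"], tab["p"]):
            if p < best_p.get(mid, np.inf):
                best_p[mid] = p
    top = sorted(best_p, key=lambda mid: best_p[mid])[:fallback_k]
    return top, True


def cv_gwas_gp(g: GenotypeMatrix, pheno: PhenotypeTable, trait: str,
               scheme: CVScheme, mode: str = "single",
               related_traits: list[str] | None = None,
               gwas_config: dict | None = None) -> GPResult:
    """Cross-validated rrBLUP with in-fold GWAS marker selection.

    Per replicate and fold, the configured GWAS models run on the training
    folds only; the prediction panel is the union of Bonferroni-significant
    markers for the focal trait (``single`` mode) or for the focal trait plus
    ``related_traits`` (``multi`` mode).  rrBLUP is fitted on the training
    folds and GEBVs predicted for the held-out fold; replicate accuracy is
    the Pearson r between observed and predicted values pooled over all
    held-out folds.  A fold whose GWAS yields no significant marker falls
    back to the top-k markers by p-value (logged).  Held-out samples never
    enter marker selection or fitting.
    """
    if mode not in ("single", "multi"):
        raise ValueError("mode must be 'single' or 'multi'")
    related = list(related_traits or [])
    if mode == "multi" and not related:
        raise ValueError("multi mode requires non-empty related_traits")
    cfg = {**DEFAULT_GWAS_CONFIG, **(gwas_config or {})}
    models, n_pcs, alpha = cfg["models"], cfg["n_pcs"], cfg["alpha"]

    pheno = normalize_traits(pheno)
    wanted = [trait] + related
    for t in wanted:
        if t not in pheno.trait_names:
            raise ValueError(f"trait {t!r} not in phenotype table")

    # align samples; require complete observations on the traits involved
    common = [s for s in g.sample_ids if s in set(pheno.sample_ids)]
    ytab = pheno.values.loc[common, wanted]
    keep = ~ytab.isna().any(axis=1)
    samples = [s for s, k in zip(common, keep) if k]
    sidx = [g.sample_ids.index(s) for s in samples]
    g = g.subset_samples(np.array(sidx))
    ytab = ytab.loc[samples]
    n = len(samples)
    if n < scheme.n_folds:
        raise ValueError("fewer samples than folds")

    y_obs = ytab[trait].to_numpy(dtype=float)
    h2 = estimate_heritability(y_obs, genomic_kinship(g, "zhang"))

    acc = np.empty(scheme.n_replicates)
    gebv_sum = np.zeros(n)
    panels: dict = {}
    fallbacks = 0
    for rep in range(scheme.n_replicates):
        folds = scheme.fold_assignment(rep, n)
        predicted = np.empty(n)
        for f in range(scheme.n_folds):
            test_idx = np.where(folds == f)[0]
            train_idx = np.where(folds != f)[0]
            # leakage audit: held-out samples are invisible to selection/fit
            assert not (set(test_idx) & set(train_idx))
            g_tr = g.subset_samples(train_idx)
            K_tr = genomic_kinship(g_tr, "zhang")
            X_tr = np.column_stack([np.ones(train_idx.size),
                                    pca_covariates(g_tr, n_pcs)])
            ws = MLMWorkspace(X_tr, K_tr, g_tr) if (
                "mlm" in models or "mlmm" in models) else None

            panel_ids: set[str] = set()
            fell_back = False
            for t in wanted if mode == "multi" else [trait]:
                y_tr = ytab[t].to_numpy(dtype=float)[train_idx]
                results = _run_models(y_tr, X_tr, K_tr, g_tr, models, alpha,
                                      workspace=ws)
                ids, fb = _fold_panel(results, alpha, g.n_markers,
                                      cfg["fallback_k"])
                fell_back |= fb and t == trait
                panel_ids.update(ids)
            panel = sorted(panel_ids)
            if fell_back:
                fallbacks += 1
                logger.info("cv_gwas_gp: rep %d fold %d used top-%d fallback",
                            rep, f, cfg["fallback_k"])
            cols = g.marker_index(panel)
            model = rrblup_fit(y_obs[train_idx], g.dosage[np.ix_(train_idx, cols)],
                               marker_ids=panel)
            predicted[test_idx] = predict_gebv(model,
                                               g.dosage[np.ix_(test_idx, cols)])
            panels[(rep, f)] = panel
        acc[rep] = stats.pearsonr(y_obs, predicted)[0]
        gebv_sum += predicted

    gebv = pd.Series(gebv_sum / scheme.n_replicates, index=samples, name="gebv")
    return GPResult(trait=trait, mode=mode, replicate_accuracies=acc,
                    final_accuracy=float(np.nanmean(acc)), gebv=gebv, h2=h2,
                    panels=panels, fallback_events=fallbacks)


def select_related_traits(corr: pd.DataFrame, trait: str,
                          min_abs_r: float = 0.5) -> list[str]:
    """Traits whose |Pearson r| with ``trait`` meets the threshold (helper for
    choosing the related-trait family in multi-trait prediction)."""
    if trait not in corr.columns:
        raise ValueError(f"trait {trait!r} not in correlation matrix")
    col = corr[trait].drop(index=trait)
    return list(col.index[col.abs() >= min_abs_r])
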