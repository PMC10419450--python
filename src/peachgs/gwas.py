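"""Mixed-model and multi-locus association scans.

Four scans over a dosage matrix, all controlling confounding with principal
components (fixed) and, where the model uses one, a genomic kinship (random):

* ``mlm_scan`` — single-locus mixed linear model, P3D/EMMAX style: variance
  components are estimated once under the null by EMMA REML, then every
  marker is tested by generalized least squares in the eigenspace of the
  kinship matrix.
* ``mlmm_scan`` — forward-stepwise multi-locus MLM: the most significant
  marker is moved into the fixed effects (a pseudo-QTN) and the scan repeats.
* ``farmcpu_scan`` — alternates a fixed-effect per-marker test conditioned on
  pseudo-QTNs with a random-effect step that re-selects pseudo-QTNs by
  genome binning and REML model comparison.
* ``blink_scan`` — FarmCPU-like iteration without kinship; pseudo-QTNs are
  chosen by LD-pruned greedy selection and BIC.

Per-marker p-values are two-sided Wald/t tests.  Significance calling uses a
Bonferroni cutoff ``alpha / n_markers`` or a fixed -log10(p) threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenotypeMatrix
from .kinship import KinshipMatrix, genomic_kinship

logger = logging.getLogger("peachgs")

MODELS = ("mlm", "mlmm", "farmcpu", "blink")

#: genome-bin sizes (bp) tried by the FarmCPU random-effect step
DEFAULT_BIN_SIZES = (500_000, 5_000_000, 50_000_000)
#: candidate counts (top bins) tried by the FarmCPU random-effect step
DEFAULT_TOP_BIN_COUNTS = tuple(range(5, 55, 5))
#: squared-correlation cutoff above which candidate pseudo-QTNs are pruned
LD_PRUNE_R = 0.7


@dataclass
class VarianceComponents:
    """REML variance components of a single-kinship mixed model."""

    sigma_g2: float
    sigma_e2: float
    reml_loglik: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def delta(self) -> float:
        return np.inf if self.sigma_g2 == 0 else self.sigma_e2 / self.sigma_g2

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return 0.0 if tot == 0 else self.sigma_g2 / tot


@dataclass
class AssociationResult:
    """Per-marker association statistics from one model on one trait."""

    model: str
    table: pd.DataFrame  # columns: id, chrom, pos, maf, effect, se, p
    threshold_p: float
    n_tested: int
    pseudo_qtns: list[str] = field(default_factory=list)
    trait: str = ""
    converged: bool = True

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        p = self.table["p"].to_numpy()
        ok = np.isnan(p) | ((p >= 0) & (p <= 1))
        if not ok.all():
            raise ValueError("p-values outside [0, 1]")

    @property
    def pvalues(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    def significant_ids(self, neglog10_cutoff: float) -> list[str]:
        p = self.pvalues
        with np.errstate(divide="ignore"):
            hit = ~np.isnan(p) & (p > 0) & (-np.log10(p) > neglog10_cutoff)
        return list(self.table.loc[hit, "id"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        with np.errstate(divide="ignore"):
            out["neglog10p"] = -np.log10(out["p"])
        out.to_csv(path, sep="\t", index=False)


@dataclass
class MarkerPanel:
    """Significant markers for one trait, with per-model provenance."""

    trait: str
    members: pd.DataFrame  # columns: id, models (tuple), n_models

    @property
    def marker_ids(self) -> list[str]:
        return list(self.members["id"])

    def supported_by(self, min_models: int) -> list[str]:
        return list(self.members.loc[self.members["n_models"] >= min_models, "id"])


# ---------------------------------------------------------------------------
# EMMA REML
# ---------------------------------------------------------------------------

def _as_kinship_values(K) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def _projected_kinship_eigen(X: np.ndarray, Kv: np.ndarray):
    """Eigenpairs of S K S with S the projection off the column space of X.

    Returns the ``n - rank(X)`` leading eigenvalues/eigenvectors, the basis of
    the restricted likelihood.
    """
    n = X.shape[0]
    q = np.linalg.matrix_rank(X)
    S = np.eye(n) - X @ np.linalg.pinv(X)
    w, v = np.linalg.eigh(S @ Kv @ S)
    order = np.argsort(w)[::-1][: n - q]
    return np.maximum(w[order], 0.0), v[:, order], q


def _restricted_loglik(log_delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    delta = np.exp(log_delta)
    nq = lam.size
    denom = lam + delta
    ss = np.sum(eta2 / denom)
    return 0.5 * (nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(ss))
                  - np.sum(np.log(denom)))


def emma_reml(y: np.ndarray, X: np.ndarray, K, *, _proj=None) -> VarianceComponents:
    """EMMA REML variance components for ``y = Xb + u + e``, ``u ~ N(0, sg2 K)``.

    The restricted likelihood is profiled to one dimension in
    ``log delta = log(se2/sg2)``, maximized on a 100-point grid over
    [-10, 10] and refined locally by bounded scalar optimization.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Kv = _as_kinship_values(K)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype: variance components undefined")
    if _proj is None:
        lam, U, q = _projected_kinship_eigen(X, Kv)
    else:
        lam, U, q = _proj
    if y.size < q + 2:
        raise ValueError("need n >= rank(X) + 2 observations")
    eta2 = (U.T @ y) ** 2

    grid = np.linspace(-10.0, 10.0, 100)
    ll = np.array([_restricted_loglik(g, lam, eta2) for g in grid])
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(lambda g: -_restricted_loglik(g, lam, eta2),
                                   bounds=(lo, hi), method="bounded")
    log_delta, loglik = (res.x, -res.fun)
    if ll[best] > loglik:  # keep the grid optimum if refinement regressed
        log_delta, loglik = grid[best], ll[best]
    delta = float(np.exp(log_delta))
    sigma_g2 = float(np.sum(eta2 / (lam + delta)) / lam.size)
    return VarianceComponents(sigma_g2=sigma_g2, sigma_e2=delta * sigma_g2,
                              reml_loglik=float(loglik))


# ---------------------------------------------------------------------------
# Whitened per-marker regression (shared by all scans)
# ---------------------------------------------------------------------------

def _batch_marker_tests(Xw: np.ndarray, yw: np.ndarray, Gw: np.ndarray):
    """Effect/SE/p of each column of ``Gw`` added to the regression ``yw ~ Xw``.

    All inputs are already whitened (GLS reduces to OLS).  Markers collinear
    with the covariates get nan statistics.
    """
    n, q = Xw.shape
    XtX = Xw.T @ Xw
    M = np.linalg.pinv(XtX)
    Xty = Xw.T @ yw
    A = Xw.T @ Gw                       # q x m
    MA = M @ A
    gtg = np.einsum("ij,ij->j", Gw, Gw)
    q_m = gtg - np.einsum("ij,ij->j", A, MA)
    r_m = Gw.T @ yw - A.T @ (M @ Xty)
    rss0 = float(yw @ yw - Xty @ (M @ Xty))

    df = n - q - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    ok = q_m > 1e-10 * np.maximum(gtg, 1.0)
    beta = np.full(Gw.shape[1], np.nan)
    se = np.full(Gw.shape[1], np.nan)
    p = np.full(Gw.shape[1], np.nan)
    beta[ok] = r_m[ok] / q_m[ok]
    rss = np.maximum(rss0 - beta[ok] * r_m[ok], 0.0)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / q_m[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(tval), df)
    if (~ok).any():
        logger.debug("marker tests: %d collinear markers flagged", int((~ok).sum()))
    return beta, se, p


class MLMWorkspace:
    """Precomputed eigenspace pieces shared by every trait scanned on one panel.

    Holds the kinship eigendecomposition, the rotated covariates/genotypes and
    the projected-kinship eigenpairs used by the REML step, so that repeated
    scans (different phenotypes, same samples/covariates) avoid re-rotating
    the genotype matrix.
    """

    def __init__(self, X: np.ndarray, K, g: GenotypeMatrix):
        if np.isnan(g.dosage).any():
            raise ValueError("scan requires imputed dosages")
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.Kv = _as_kinship_values(K)
        self.g = g
        d, U = np.linalg.eigh(self.Kv)
        self.d = np.maximum(d, 0.0)
        self.U = U
        self.Xs = U.T @ self.X
        self.Gs = U.T @ g.dosage
        self.proj = _projected_kinship_eigen(self.X, self.Kv)

    def reml(self, y: np.ndarray) -> VarianceComponents:
        return emma_reml(y, self.X, self.Kv, _proj=self.proj)

    def whiten(self, y: np.ndarray, vc: VarianceComponents):
        wgt = 1.0 / np.sqrt(vc.sigma_g2 * self.d + vc.sigma_e2)
        ys = (self.U.T @ y) * wgt
        return self.Xs * wgt[:, None], ys, self.Gs * wgt[:, None]


def _result_table(g: GenotypeMatrix, beta, se, p) -> pd.DataFrame:
    tab = g.markers[["id", "chrom", "pos"]].copy()
    tab["maf"] = g.maf()
    tab["effect"] = beta
    tab["se"] = se
    tab["p"] = p
    return tab


def mlm_scan(y, X, K, g: GenotypeMatrix, *, vc: VarianceComponents | None = None,
             alpha: float = 0.01, trait: str = "",
             workspace: MLMWorkspace | None = None) -> AssociationResult:
    """P3D mixed-linear-model scan.

    Variance components are estimated once on the marker-free null model and
    held fixed; each marker is then tested by GLS in the rotated space with a
    two-sided Wald/t test.  ``vc`` overrides the null estimate (used e.g. to
    force the fixed-effects limit).
    """
    y = np.asarray(y, dtype=float).ravel()
    ws = workspace if workspace is not None else MLMWorkspace(X, K, g)
    if vc is None:
        vc = ws.reml(y)
    Xw, yw, Gw = ws.whiten(y, vc)
    beta, se, p = _batch_marker_tests(Xw, yw, Gw)
    return AssociationResult(
        model="mlm", table=_result_table(ws.g, beta, se, p),
        threshold_p=bonferroni_threshold(ws.g.n_markers, alpha),
        n_tested=ws.g.n_markers, trait=trait,
    )


def _mlm_single_marker(ws: MLMWorkspace, y: np.ndarray, vc: VarianceComponents,
                       covar_cols: list[int], test_col: int):
    """Test one marker with extra pseudo-QTN covariates, in rotated space."""
    wgt = 1.0 / np.sqrt(vc.sigma_g2 * ws.d + vc.sigma_e2)
    Xs = np.column_stack([ws.Xs] + [ws.Gs[:, c] for c in covar_cols])
    Xw = Xs * wgt[:, None]
    yw = (ws.U.T @ y) * wgt
    Gw = (ws.Gs[:, [test_col]]) * wgt[:, None]
    beta, se, p = _batch_marker_tests(Xw, yw, Gw)
    return beta[0], se[0], p[0]


def mlmm_scan(y, X, K, g: GenotypeMatrix, *, alpha: float = 0.01,
              max_steps: int = 10, trait: str = "",
              workspace: MLMWorkspace | None = None) -> AssociationResult:
    """Forward-stepwise multi-locus MLM.

    Repeatedly runs the MLM scan with the current pseudo-QTNs as fixed
    covariates and promotes the most significant marker while its p-value
    beats the Bonferroni threshold, up to ``max_steps``.  The reported per-
    marker p-values come from the final conditional scan; each pseudo-QTN is
    re-tested leave-one-out against the final covariate set.  Variance
    components are re-estimated at every step.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    ws = workspace if workspace is not None else MLMWorkspace(X, K, g)
    threshold = bonferroni_threshold(g.n_markers, alpha)

    pseudo: list[int] = []
    beta = se = p = None
    for _step in range(max_steps + 1):
        Xs_aug = np.column_stack([ws.Xs] + [ws.Gs[:, c] for c in pseudo])
        X_aug = np.column_stack([ws.X] + [g.dosage[:, c] for c in pseudo])
        vc = emma_reml(y, X_aug, ws.Kv)
        wgt = 1.0 / np.sqrt(vc.sigma_g2 * ws.d + vc.sigma_e2)
        Xw = Xs_aug * wgt[:, None]
        yw = (ws.U.T @ y) * wgt
        Gw = ws.Gs * wgt[:, None]
        beta, se, p = _batch_marker_tests(Xw, yw, Gw)
        if _step == max_steps:
            break
        cand = np.where(~np.isnan(p))[0]
        if cand.size == 0:
            break
        best = cand[np.argmin(_tie_broken_order(ws.g, p, cand))]
        if p[best] >= threshold or best in pseudo:
            break
        pseudo.append(int(best))

    # leave-one-out re-test of the included pseudo-QTNs
    vc_final = emma_reml(y, np.column_stack([ws.X] + [g.dosage[:, c] for c in pseudo]),
                         ws.Kv) if pseudo else None
    for c in pseudo:
        others = [o for o in pseudo if o != c]
        b, s, pv = _mlm_single_marker(ws, y, vc_final, others, c)
        beta[c], se[c], p[c] = b, s, pv

    ids = ws.g.markers["id"]
    return AssociationResult(
        model="mlmm", table=_result_table(ws.g, beta, se, p),
        threshold_p=threshold, n_tested=g.n_markers,
        pseudo_qtns=[str(ids.iloc[c]) for c in pseudo], trait=trait,
    )


def _tie_broken_order(g: GenotypeMatrix, p: np.ndarray, cand: np.ndarray):
    """Sort key: p-value, ties broken by (chrom, pos)."""
    sub = g.markers.iloc[cand]
    order = pd.DataFrame({
        "p": p[cand],
        "chrom": sub["chrom"].to_numpy(),
        "pos": sub["pos"].to_numpy(),
    })
    rank = order.sort_values(["p", "chrom", "pos"]).index
    key = np.empty(cand.size)
    key[rank] = np.arange(cand.size)
    return key


# ---------------------------------------------------------------------------
# FarmCPU / BLINK fixed-effect machinery
# ---------------------------------------------------------------------------

def ols_scan(y, X, g: GenotypeMatrix, *, alpha: float = 0.01,
             pseudo_cols: list[int] | None = None):
    """Per-marker OLS t-test with optional pseudo-QTN covariates.

    Pseudo-QTN markers themselves are tested by substitution: each is removed
    from the covariates and tested against the remaining ones.  Returns
    (beta, se, p) arrays over all markers.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    pseudo_cols = list(pseudo_cols or [])
    G = g.dosage
    if np.isnan(G).any():
        raise ValueError("scan requires imputed dosages")
    Xa = np.column_stack([X] + [G[:, c] for c in pseudo_cols])
    beta, se, p = _batch_marker_tests(Xa, y, G)
    for c in pseudo_cols:  # leave-self-out substitution test
        others = [o for o in pseudo_cols if o != c]
        Xo = np.column_stack([X] + [G[:, o] for o in others])
        b, s, pv = _batch_marker_tests(Xo, y, G[:, [c]])
        beta[c], se[c], p[c] = b[0], s[0], pv[0]
    return beta, se, p


def _require_positions(g: GenotypeMatrix) -> None:
    if g.markers["pos"].isna().any():
        raise ValueError("marker map lacks positions; genome binning impossible")


def _bin_best_markers(g: GenotypeMatrix, p: np.ndarray, bin_size: int) -> np.ndarray:
    """Index of the smallest-p marker in each (chrom, pos // bin_size) bin,
    ordered by ascending p."""
    tab = pd.DataFrame({
        "chrom": g.markers["chrom"].to_numpy(),
        "bin": g.markers["pos"].to_numpy() // bin_size,
        "p": p,
    })
    tab = tab.dropna(subset=["p"])
    best = tab.groupby(["chrom", "bin"], sort=False)["p"].idxmin()
    idx = best.to_numpy()
    return idx[np.argsort(p[idx], kind="stable")]


def _prune_by_ld(G: np.ndarray, cand: np.ndarray, p: np.ndarray,
                 r_cut: float = LD_PRUNE_R) -> list[int]:
    """Greedy pruning: walk candidates by ascending p, keep a marker only if
    |r| <= r_cut with every already-kept marker."""
    order = cand[np.argsort(p[cand], kind="stable")]
    kept: list[int] = []
    for c in order:
        x = G[:, c]
        if x.std() == 0:
            continue
        ok = True
        for kcol in kept:
            r = np.corrcoef(x, G[:, kcol])[0, 1]
            if abs(r) > r_cut:
                ok = False
                break
        if ok:
            kept.append(int(c))
    return kept


def farmcpu_scan(y, X, g: GenotypeMatrix, *, bin_sizes=DEFAULT_BIN_SIZES,
                 max_loops: int = 10, top_bin_counts=DEFAULT_TOP_BIN_COUNTS,
                 alpha: float = 0.01, trait: str = "") -> AssociationResult:
    """FarmCPU: iterate fixed-effect marker tests and random-effect
    pseudo-QTN selection.

    The fixed-effect step is a per-marker OLS t-test conditioned on the
    current pseudo-QTNs (tested themselves by leave-self-out substitution).
    The random-effect step bins the genome at each candidate bin size, takes
    the best marker per bin, picks the (bin size, number of top bins)
    combination maximizing the REML likelihood of the phenotype under a
    kinship built from the selected candidates, and prunes candidates with
    pairwise |r| > 0.7 keeping the smaller-p member.  Iteration stops when
    the pseudo-QTN set repeats or ``max_loops`` is reached.  If no marker
    passes the Bonferroni threshold on the first scan, no pseudo-QTNs are
    selected at all (the false-positive control of the original method).
    """
    _require_positions(g)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = g.dosage
    threshold = bonferroni_threshold(g.n_markers, alpha)

    pseudo: list[int] = []
    history = {frozenset()}
    converged = False
    beta = se = p = None
    for _loop in range(max_loops):
        beta, se, p = ols_scan(y, X, g, pseudo_cols=pseudo)
        if _loop == 0 and not (np.nanmin(p) < threshold):
            # nothing genome-wide significant on the first scan: stop before
            # conditioning on spurious pseudo-QTNs (false-positive control)
            converged = True
            break
        new = _farmcpu_rem_select(y, X, g, p, bin_sizes, top_bin_counts)
        if frozenset(new) == frozenset(pseudo):
            converged = True
            break
        if frozenset(new) in history:  # oscillation: accept the repeat state
            converged = True
            pseudo = new
            beta, se, p = ols_scan(y, X, g, pseudo_cols=pseudo)
            break
        history.add(frozenset(new))
        pseudo = new
    if not converged:
        logger.warning("farmcpu_scan: max_loops=%d reached without stabilization",
                       max_loops)

    ids = g.markers["id"]
    return AssociationResult(
        model="farmcpu", table=_result_table(g, beta, se, p),
        threshold_p=threshold, n_tested=g.n_markers,
        pseudo_qtns=[str(ids.iloc[c]) for c in pseudo], trait=trait,
        converged=converged,
    )


def _farmcpu_rem_select(y, X, g: GenotypeMatrix, p: np.ndarray, bin_sizes,
                        top_bin_counts) -> list[int]:
    """Random-effect pseudo-QTN selection by bin-size/candidate-count REML."""
    if np.all(np.isnan(p)):
        return []
    best_ll, best_cand = -np.inf, []
    for bin_size in bin_sizes:
        by_bin = _bin_best_markers(g, p, int(bin_size))
        for t in top_bin_counts:
            cand = by_bin[: min(t, by_bin.size)]
            if cand.size == 0:
                continue
            sub = g.subset_markers(cand)
            try:
                K = genomic_kinship(sub, "vanraden")
            except ValueError:  # all-monomorphic candidate set
                continue
            ll = emma_reml(y, X, K).reml_loglik
            if ll > best_ll:
                best_ll, best_cand = ll, cand
    if len(best_cand) == 0:
        return []
    return _prune_by_ld(g.dosage, np.asarray(best_cand), p)


def blink_scan(y, X, g: GenotypeMatrix, *, max_loops: int = 10,
               alpha: float = 0.01, candidate_p: float = 0.01,
               max_kept: int = 40, trait: str = "") -> AssociationResult:
    """BLINK: FarmCPU-style iteration with LD pruning + BIC instead of bins.

    The selection step sorts markers by fixed-effect p ascending, greedily
    keeps a marker if its LD r-squared with every already-kept marker is
    below 0.7, and chooses how many of the kept markers become pseudo-QTNs by
    minimizing the BIC of the fixed model ``y ~ X + kept markers``.  No
    kinship is used anywhere.  Only markers with p below ``candidate_p``
    enter the greedy pass (markers this weak are always rejected by BIC), and
    at most ``max_kept`` are retained before BIC selection.  As in
    ``farmcpu_scan``, a first scan with nothing past the Bonferroni threshold
    ends the iteration with no pseudo-QTNs.
    """
    _require_positions(g)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = g.dosage
    n = y.size
    threshold = bonferroni_threshold(g.n_markers, alpha)

    pseudo: list[int] = []
    history = {frozenset()}
    converged = False
    beta = se = p = None
    for _loop in range(max_loops):
        beta, se, p = ols_scan(y, X, g, pseudo_cols=pseudo)
        if _loop == 0 and not (np.nanmin(p) < threshold):
            converged = True  # nothing significant: no pseudo-QTN conditioning
            break
        cand = np.where(~np.isnan(p) & (p < candidate_p))[0]
        kept = _prune_by_ld(G, cand, p, r_cut=np.sqrt(LD_PRUNE_R))[:max_kept]
        new = _bic_select(y, X, G, kept, n)
        if frozenset(new) == frozenset(pseudo):
            converged = True
            break
        if frozenset(new) in history:
            converged = True
            pseudo = new
            beta, se, p = ols_scan(y, X, g, pseudo_cols=pseudo)
            break
        history.add(frozenset(new))
        pseudo = new
    if not converged:
        logger.warning("blink_scan: max_loops=%d reached without stabilization",
                       max_loops)

    ids = g.markers["id"]
    return AssociationResult(
        model="blink", table=_result_table(g, beta, se, p),
        threshold_p=threshold, n_tested=g.n_markers,
        pseudo_qtns=[str(ids.iloc[c]) for c in pseudo], trait=trait,
        converged=converged,
    )


def _bic_select(y, X, G, kept: list[int], n: int) -> list[int]:
    """Prefix of the LD-pruned candidate list minimizing BIC of y ~ X + prefix."""
    best_bic, best_k = np.inf, 0
    for k in range(len(kept) + 1):
        Xk = np.column_stack([X] + [G[:, c] for c in kept[:k]])
        resid = y - Xk @ np.linalg.lstsq(Xk, y, rcond=None)[0]
        rss = float(resid @ resid)
        if rss <= 0:
            rss = np.finfo(float).tiny
        bic = n * np.log(rss / n) + Xk.shape[1] * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_k = bic, k
    return kept[:best_k]


# ---------------------------------------------------------------------------
# Thresholds and significance calling
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_markers: int, alpha: float = 0.01) -> float:
    """Bonferroni p-value cutoff: ``alpha / n_markers``."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_markers


def call_significant(results: list[AssociationResult],
                     neglog10_cutoff: float = 7.0,
                     trait: str | None = None) -> MarkerPanel:
    """Union of markers with -log10(p) strictly above the cutoff in any model.

    Records per-marker supporting-model provenance so panels can later be
    filtered to markers detected by at least two models.
    """
    if not results:
        raise ValueError("empty results list")
    provenance: dict[str, list[str]] = {}
    for res in results:
        for mid in res.significant_ids(neglog10_cutoff):
            provenance.setdefault(mid, []).append(res.model)
    rows = [{"id": mid, "models": tuple(models), "n_models": len(models)}
            for mid, models in provenance.items()]
    members = pd.DataFrame(rows, columns=["id", "models", "n_models"])
    return MarkerPanel(trait=trait if trait is not None else results[0].trait,
                       members=members)


def genomic_control_lambda(pvalues: np.ndarray) -> float:
    """Genomic-control inflation factor: median chi2(1) / 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
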