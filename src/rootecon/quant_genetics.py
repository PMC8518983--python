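"""Quantitative genetics: heritability, SNP QC, kinship and LMM association.

Heritability
    Plant-level trait values from a randomized complete block design are fit
    with the mixed model ``y_ij = mu + block_j + g_i + e_ij`` (genotype
    random, block fixed).  Variance components come from a one-dimensional
    REML profile over the variance ratio lambda = sigma_g^2 / sigma_e^2;
    broad-sense heritability is ``H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2/r)``
    with ``r`` the number of blocks.

Association scans
    Genotype-mean phenotypes are tested marker by marker under the linear
    mixed model ``y = mu + x beta + u + e`` with ``u ~ N(0, sigma_g^2 K)``
    and ``K`` the centered relatedness matrix.  ``K`` is eigendecomposed
    once; the variance ratio is estimated by REML under the no-marker null
    and reused across markers (an exact per-marker re-estimation mode is
    available).  Effects are tested with a Wald chi-square.  The
    multivariate scan generalises this to d traits with genetic covariance
    ``V_g (x) K`` and residual ``V_e (x) I``, estimated by EM-REML in the
    eigenbasis of K, and a d-df Wald test per marker.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.45494


# ---------------------------------------------------------------------------
# containers

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    n_reps: int
    reml_loglik: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class GenotypeData:
    """Biallelic dosage matrix (genotypes x markers) with a marker map.

    Dosages are minor-allele counts in {0, 1, 2}; missing calls are NaN in
    memory and ``NA`` on disk.  ``marker_map`` has columns
    ``marker_id, chrom, pos`` aligned with the dosage columns.
    """

    dosages: np.ndarray
    genotype_ids: list[str]
    marker_map: pd.DataFrame
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.genotype_ids), len(self.marker_map)):
            raise ValueError("dosage shape does not match ids/map")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("marker positions not sorted within chromosome")
        if (self.marker_map["pos"] < 0).any():
            raise ValueError("negative marker positions")

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker on non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        freq = np.nan_to_num(freq, nan=0.0)
        return np.minimum(freq, 1.0 - freq)

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-marker mean."""
        X = self.dosages.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(X, axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
        return X

    def subset_markers(self, mask: np.ndarray) -> "GenotypeData":
        return GenotypeData(
            dosages=self.dosages[:, mask],
            genotype_ids=list(self.genotype_ids),
            marker_map=self.marker_map.loc[mask].reset_index(drop=True),
            populations=self.populations,
        )

    def subset_genotypes(self, idx: np.ndarray) -> "GenotypeData":
        pops = self.populations[idx] if self.populations is not None else None
        return GenotypeData(
            dosages=self.dosages[idx, :],
            genotype_ids=[self.genotype_ids[i] for i in idx],
            marker_map=self.marker_map,
            populations=pops,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write markers-as-rows TSV: marker_id, chrom, pos, one column per genotype."""
        mat = self.dosages.T
        txt = np.where(
            np.isnan(mat), "NA",
            np.char.mod("%d", np.nan_to_num(mat).round().astype(int)),
        )
        df = pd.concat(
            [self.marker_map[["marker_id", "chrom", "pos"]],
             pd.DataFrame(txt, columns=self.genotype_ids)],
            axis=1,
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeData":
        df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
        meta = ["marker_id", "chrom", "pos"]
        gids = [c for c in df.columns if c not in meta]
        mat = df[gids].apply(pd.to_numeric, errors="coerce").to_numpy(float).T
        return cls(dosages=mat, genotype_ids=gids,
                   marker_map=df[meta].reset_index(drop=True))


# ---------------------------------------------------------------------------
# RCBD REML and heritability

def _rcbd_neg2reml(
    log10_lam: float,
    counts: np.ndarray,
    XtX: np.ndarray,
    ZtX: np.ndarray,
    Xty: np.ndarray,
    Zty: np.ndarray,
    yty: float,
    n: int,
) -> float:
    lam = 10.0 ** log10_lam
    w = lam / (1.0 + lam * counts)
    XtViX = XtX - ZtX.T @ (w[:, None] * ZtX)
    XtViy = Xty - ZtX.T @ (w * Zty)
    ytViy = yty - (w * Zty) @ Zty
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf
    yPy = max(ytViy - XtViy @ beta, 1e-300)
    p = XtX.shape[0]
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    logdet_v = float(np.sum(np.log1p(lam * counts)))
    return (n - p) * np.log(yPy) + logdet_v + logdet_x


def fit_rcbd_reml(
    data: pd.DataFrame,
    value_col: str = "value",
    genotype_col: str = "genotype_id",
    block_col: str = "block_id",
) -> VarianceComponents:
    """REML variance components for a randomized complete block design.

    Genotype is random, block fixed.  The REML profile in the variance ratio
    ``lambda = sigma_g2/sigma_e2`` is minimised by Brent search over
    ``log10 lambda in [-5, 5]``; the ``lambda -> 0`` boundary (no genetic
    variance) is checked explicitly.  On balanced data this equals the
    ANOVA estimator ``sigma_g2 = (MS_genotype - MS_error)/r`` truncated at 0.
    """
    if value_col not in data.columns:
        candidates = [c for c in data.columns
                      if c not in ("sample_id", genotype_col, block_col)]
        if len(candidates) == 1:
            value_col = candidates[0]
        else:
            raise ValueError(f"column {value_col!r} not found in the trait table")
    d = data.dropna(subset=[value_col])
    if d.empty:
        raise ValueError(f"trait {value_col!r} has no observed values")
    y = d[value_col].to_numpy(float)
    geno = pd.Categorical(d[genotype_col])
    block = pd.Categorical(d[block_col])
    g, b, n = len(geno.categories), len(block.categories), len(y)
    if g < 2 or b < 2:
        raise ValueError("need at least 2 genotypes and 2 blocks")

    # fixed effects: intercept + block dummies (first block as reference)
    X = np.ones((n, b))
    for j in range(1, b):
        X[:, j] = (block.codes == j).astype(float)
    zcodes = np.asarray(geno.codes)
    counts = np.bincount(zcodes, minlength=g).astype(float)

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ZtX = np.zeros((g, b))
    for j in range(b):
        ZtX[:, j] = np.bincount(zcodes, weights=X[:, j], minlength=g)
    Zty = np.bincount(zcodes, weights=y, minlength=g)

    args = (counts, XtX, ZtX, Xty, Zty, yty, n)
    res = optimize.minimize_scalar(
        _rcbd_neg2reml, bounds=(-5.0, 5.0), args=args, method="bounded",
        options={"xatol": 1e-10},
    )
    cand = [(res.fun, 10.0 ** res.x)]
    for edge in (-5.0, 5.0):
        cand.append((_rcbd_neg2reml(edge, *args), 10.0 ** edge))
    # boundary sigma_g2 = 0
    cand.append((_rcbd_neg2reml(-300.0, *args), 0.0))
    crit, lam = min(cand, key=lambda c: c[0])

    w = lam / (1.0 + lam * counts) if lam > 0 else np.zeros(g)
    XtViX = XtX - ZtX.T @ (w[:, None] * ZtX)
    XtViy = Xty - ZtX.T @ (w * Zty)
    ytViy = yty - (w * Zty) @ Zty
    beta = np.linalg.solve(XtViX, XtViy)
    yPy = max(ytViy - XtViy @ beta, 0.0)
    sigma_e2 = yPy / (n - b)
    sigma_g2 = lam * sigma_e2
    loglik = -0.5 * (crit + (n - b) * (1.0 + np.log(2.0 * np.pi / (n - b))))
    return VarianceComponents(
        sigma_g2=float(sigma_g2), sigma_e2=float(sigma_e2),
        n_reps=b, reml_loglik=float(loglik),
    )


def broad_sense_h2(vc: VarianceComponents) -> float:
    """H2 = sigma_g2 / (sigma_g2 + sigma_e2 / r)."""
    denom = vc.sigma_g2 + vc.sigma_e2 / vc.n_reps
    return 0.0 if denom == 0 else vc.sigma_g2 / denom


# ---------------------------------------------------------------------------
# SNP QC and kinship

def filter_markers(
    G: GenotypeData, max_missing: float = 0.5, min_maf: float = 0.05
) -> tuple[GenotypeData, dict]:
    """Drop markers with missing fraction > ``max_missing`` or MAF < ``min_maf``.

    Both comparisons are strict, so a marker at exactly the MAF threshold is
    kept.  Returns the filtered data and a report of counts dropped per rule.
    """
    miss = G.missing_fraction()
    maf = G.maf()
    drop_missing = miss > max_missing
    drop_maf = maf < min_maf
    keep = ~(drop_missing | drop_maf)
    if not keep.any():
        raise ValueError("all markers removed by QC filters")
    report = dict(
        n_input=G.n_markers,
        n_dropped_missing=int(drop_missing.sum()),
        n_dropped_maf=int((drop_maf & ~drop_missing).sum()),
        n_kept=int(keep.sum()),
    )
    return G.subset_markers(keep), report


def relatedness_matrix(G: GenotypeData) -> np.ndarray:
    """Centered relatedness matrix ``K = W W' / p``.

    ``W`` is the mean-imputed dosage matrix with each marker column centred
    on its mean; ``p`` is the marker count.
    """
    if G.n_markers == 0:
        raise ValueError("no markers available for kinship")
    W = G.imputed()
    W = W - W.mean(axis=0, keepdims=True)
    return (W @ W.T) / G.n_markers


# ---------------------------------------------------------------------------
# univariate LMM scan

def _eigen_k(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = np.asarray(K, float)
    K = 0.5 * (K + K.T)
    S, U = np.linalg.eigh(K)
    scale = max(abs(S[-1]), 1.0)
    if S[0] < -1e-6 * scale:
        raise ValueError("kinship matrix is not positive semi-definite")
    return np.clip(S, 0.0, None), U


def _null_reml_lambda(
    ystar: np.ndarray, X0: np.ndarray, S: np.ndarray
) -> float:
    """Brent REML estimate of lambda = sigma_g2/sigma_e2 in the eigenbasis."""
    m, p = X0.shape

    def neg2(log10_lam: float) -> float:
        lam = 10.0 ** log10_lam
        w = 1.0 / (lam * S + 1.0)
        Xw = X0 * w[:, None]
        A = X0.T @ Xw
        b = Xw.T @ ystar
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf
        rss = max(float(w @ (ystar - X0 @ beta) ** 2), 1e-300)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return (m - p) * np.log(rss) + float(np.sum(np.log(lam * S + 1.0))) + logdet_a

    res = optimize.minimize_scalar(
        neg2, bounds=(-5.0, 5.0), method="bounded", options={"xatol": 1e-10}
    )
    cand = [(res.fun, 10.0 ** res.x), (neg2(-300.0), 0.0)]
    for edge in (-5.0, 5.0):
        cand.append((neg2(edge), 10.0 ** edge))
    return min(cand, key=lambda c: c[0])[1]


def _align_phenotype(
    y: pd.Series, G: GenotypeData, K: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Match a genotype-mean phenotype to the dosage rows, dropping missing."""
    y = y.reindex(G.genotype_ids)
    obs = y.notna().to_numpy()
    idx = np.nonzero(obs)[0]
    if idx.size < 3:
        raise ValueError("fewer than 3 genotypes with observed phenotype")
    return (y.to_numpy(float)[idx], G.imputed()[idx, :],
            K[np.ix_(idx, idx)], idx)


def lmm_scan(
    y: pd.Series,
    G: GenotypeData,
    K: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    trait: str = "trait",
    reuse_null_lambda: bool = True,
) -> pd.DataFrame:
    """Single-trait mixed-model association scan (Wald chi2, 1 df).

    ``y`` is a genotype-mean phenotype indexed by genotype id.  The default
    reuses the null-model variance ratio across markers and re-estimates the
    residual scale per marker; ``reuse_null_lambda=False`` re-optimises the
    ratio for every marker (slower, negligibly different at panel scale).
    """
    if K is None:
        K = relatedness_matrix(G)
    yv, Xg, Ks, _ = _align_phenotype(y, G, K)
    m = yv.size
    S, U = _eigen_k(Ks)
    ystar = U.T @ yv
    cols = [np.ones(m)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != m:
            cov = cov.T
        cols.extend(cov.T)
    X0 = U.T @ np.column_stack(cols)
    p0 = X0.shape[1]
    Xm = U.T @ Xg

    lam = _null_reml_lambda(ystar, X0, S)

    if reuse_null_lambda:
        beta, se, wald, pvals = _scan_given_lambda(ystar, X0, Xm, S, lam)
    else:
        beta = np.empty(G.n_markers)
        se = np.empty(G.n_markers)
        wald = np.empty(G.n_markers)
        pvals = np.empty(G.n_markers)
        for j in range(G.n_markers):
            Xj = np.column_stack([X0, Xm[:, j]])
            lam_j = _null_reml_lambda(ystar, Xj, S)
            b, s_, w_, p_ = _scan_given_lambda(ystar, X0, Xm[:, [j]], S, lam_j)
            beta[j], se[j], wald[j], pvals[j] = b[0], s_[0], w_[0], p_[0]

    out = G.marker_map[["marker_id", "chrom", "pos"]].copy()
    out["maf"] = G.maf()
    out["beta"] = beta
    out["se"] = se
    out["wald"] = wald
    out["p_wald"] = pvals
    out["minus_log10_p"] = -np.log10(np.clip(pvals, 1e-300, None))
    out["trait"] = trait
    out["model"] = "univariate"
    out["lambda_null"] = lam
    return out


def _scan_given_lambda(
    ystar: np.ndarray, X0: np.ndarray, Xm: np.ndarray, S: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-marker GLS given a fixed variance ratio."""
    m, p0 = X0.shape
    w = 1.0 / (lam * S + 1.0)
    X0w = X0 * w[:, None]
    A00 = X0.T @ X0w
    A00inv = np.linalg.inv(A00)
    yw = ystar * w
    b0 = X0.T @ yw
    yMy = float(ystar @ yw - b0 @ (A00inv @ b0))

    t0 = X0w.T @ Xm                      # (p0, M)
    xMx = np.einsum("im,im,i->m", Xm, Xm, w) - np.einsum("pm,pm->m", t0, A00inv @ t0)
    xMy = Xm.T @ yw - t0.T @ (A00inv @ b0)

    dof = m - p0 - 1
    eps = 1e-12 * max(float(np.max(np.abs(xMx))), 1.0)
    good = xMx > eps
    beta = np.where(good, xMy / np.where(good, xMx, 1.0), 0.0)
    sigma2 = np.maximum(yMy - beta * xMy, 0.0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(good, sigma2 / np.where(good, xMx, 1.0), np.inf))
        wald = np.where(good & (sigma2 > 0), beta**2 / se**2, 0.0)
    pvals = stats.chi2.sf(wald, df=1)
    return beta, se, wald, pvals


# ---------------------------------------------------------------------------
# multivariate LMM scan

def _mv_neg2_reml(
    Vg: np.ndarray, Ve: np.ndarray, Ystar: np.ndarray, x0: np.ndarray, S: np.ndarray
) -> float:
    """Exact -2 REML log-likelihood (up to a constant) of the null mv model."""
    Sig = S[:, None, None] * Vg[None] + Ve[None]
    try:
        L = np.linalg.cholesky(Sig)
        W = np.linalg.inv(Sig)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
    A = np.einsum("i,ijk->jk", x0**2, W)
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    b = np.einsum("i,ijk,ik->j", x0, W, Ystar)
    mu = np.linalg.solve(A, b)
    R = Ystar - np.outer(x0, mu)
    quad = float(np.einsum("ij,ijk,ik->", R, W, R))
    return logdet + logdet_a + quad


def _chol_to_cov(theta: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Unpack two lower-triangular Cholesky factors (log-diagonals)."""
    k = d * (d + 1) // 2
    tril_idx = np.tril_indices(d)
    covs = []
    for half in (theta[:k], theta[k:]):
        L = np.zeros((d, d))
        L[tril_idx] = half
        diag = np.clip(np.diag(L), -30.0, 30.0)
        L[np.diag_indices(d)] = np.exp(diag)
        covs.append(L @ L.T)
    return covs[0], covs[1]


def _cov_to_chol(V: np.ndarray) -> np.ndarray:
    d = V.shape[0]
    evals, evecs = np.linalg.eigh(0.5 * (V + V.T))
    floor = max(evals.max(), 1.0) * 1e-12
    V = (evecs * np.maximum(evals, floor)) @ evecs.T
    L = np.linalg.cholesky(V)
    theta = L[np.tril_indices(d)].copy()
    # replace diagonal entries by their logs
    pos = np.cumsum(np.arange(1, d + 1)) - 1  # positions of diagonals in tril order
    theta[pos] = np.log(np.maximum(L[np.diag_indices(d)], 1e-15))
    return theta


def _em_reml_mv(
    Ystar: np.ndarray,
    x0: np.ndarray,
    S: np.ndarray,
    max_iter: int = 400,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """EM-REML for (V_g, V_e) in the null multivariate model.

    Rows of ``Ystar`` are independent with covariance ``S_i V_g + V_e``;
    the only fixed effect is the rotated intercept ``x0``.  EM steps are
    followed by a quasi-Newton polish of the exact REML likelihood in
    Cholesky coordinates (EM alone converges sublinearly when a variance
    component sits near its boundary).
    """
    m, d = Ystar.shape
    C = np.cov(Ystar, rowvar=False).reshape(d, d)
    C = C + 1e-8 * np.eye(d) * max(np.trace(C) / d, 1.0)
    Vg = C / 2.0
    Ve = C / 2.0
    active = S > 1e-10 * max(S.max(), 1.0)
    q = int(active.sum())
    x0sq = x0**2
    scale = max(float(np.trace(C)) / d, 1e-12)
    for _ in range(max_iter):
        Sig = S[:, None, None] * Vg[None, :, :] + Ve[None, :, :]
        try:
            W = np.linalg.inv(Sig)
        except np.linalg.LinAlgError:
            # degenerate component (e.g. duplicated traits): ridge and go on
            Sig = Sig + 1e-8 * scale * np.eye(d)[None]
            W = np.linalg.inv(Sig)
        A = np.einsum("i,ijk->jk", x0sq, W)
        Ainv = np.linalg.inv(A)
        b = np.einsum("i,ijk,ik->j", x0, W, Ystar)
        mu = Ainv @ b
        R = Ystar - np.outer(x0, mu)
        WR = np.einsum("ijk,ik->ij", W, R)
        ghat = S[:, None] * (WR @ Vg.T)
        # conditional covariances incl. fixed-effect (REML) correction
        VgW = np.einsum("jk,ikl->ijl", Vg, W)      # (m, d, d)
        VgWAinvWVg = np.einsum("ijl,lm,inm->ijn", VgW, Ainv, VgW)
        gcond = (
            S[:, None, None] * Vg[None]
            - (S**2)[:, None, None] * np.einsum("ijl,ln->ijn", VgW, Vg)
            + (S**2 * x0sq)[:, None, None] * VgWAinvWVg
        )
        Egg = np.einsum("ij,ik->ijk", ghat, ghat) + gcond
        Vg_new = np.einsum("i,ijk->jk", active / np.where(active, S, 1.0), Egg) / q
        ehat = R - ghat
        VeW = np.einsum("jk,ikl->ijl", Ve, W)
        VeWAinvWVe = np.einsum("ijl,lm,inm->ijn", VeW, Ainv, VeW)
        econd = (
            Ve[None]
            - np.einsum("ijl,ln->ijn", VeW, Ve)
            + x0sq[:, None, None] * VeWAinvWVe
        )
        Eee = np.einsum("ij,ik->ijk", ehat, ehat) + econd
        Ve_new = Eee.mean(axis=0)
        Vg_new = 0.5 * (Vg_new + Vg_new.T)
        Ve_new = 0.5 * (Ve_new + Ve_new.T)
        delta = max(np.max(np.abs(Vg_new - Vg)), np.max(np.abs(Ve_new - Ve)))
        Vg, Ve = Vg_new, Ve_new
        if delta < tol * scale:
            break

    # polish: quasi-Newton on the exact REML criterion in Cholesky coordinates
    def objective(theta: np.ndarray) -> float:
        Vg_t, Ve_t = _chol_to_cov(theta, d)
        return _mv_neg2_reml(Vg_t, Ve_t, Ystar, x0, S)

    theta0 = np.concatenate([_cov_to_chol(Vg), _cov_to_chol(Ve)])
    res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12})
    if np.isfinite(res.fun) and res.fun <= objective(theta0):
        Vg, Ve = _chol_to_cov(res.x, d)

    # keep V_e usable: project to the PSD cone with a small floor
    evals, evecs = np.linalg.eigh(Ve)
    floor = 1e-10 * max(evals.max(), scale)
    if evals.min() < floor:
        log.warning(
            "near-singular residual covariance (min eig %.3g); projecting to "
            "PSD — are two traits (nearly) identical?", evals.min(),
        )
        Ve = (evecs * np.maximum(evals, floor)) @ evecs.T
    evals_g, evecs_g = np.linalg.eigh(Vg)
    if evals_g.min() < 0:
        Vg = (evecs_g * np.maximum(evals_g, 0.0)) @ evecs_g.T
    return Vg, Ve


def mv_lmm_scan(
    Y: pd.DataFrame,
    G: GenotypeData,
    K: np.ndarray | None = None,
    label: str | None = None,
) -> pd.DataFrame:
    """Multi-trait mixed-model association scan (Wald chi2, d df).

    ``Y`` holds genotype-mean values for 1-6 traits, indexed by genotype id.
    Variance matrices are estimated once under the null by EM-REML and
    reused across markers; each marker's d-vector of effects is estimated by
    GLS and tested jointly.  At d = 1 this reduces exactly to
    :func:`lmm_scan`.
    """
    d = Y.shape[1]
    if not 1 <= d <= 6:
        raise ValueError("multivariate scan supports 1-6 traits")
    if K is None:
        K = relatedness_matrix(G)
    label = label or "+".join(map(str, Y.columns))
    # canonical trait order: makes the fit (hence the Wald statistic)
    # exactly invariant to the caller's column order
    Y = Y[sorted(Y.columns, key=str)]
    Y = Y.reindex(G.genotype_ids)
    obs = Y.notna().all(axis=1).to_numpy()
    idx = np.nonzero(obs)[0]
    if idx.size <= d + 2:
        raise ValueError("not enough complete cases for the multivariate scan")
    Yv = Y.to_numpy(float)[idx]
    Ks = K[np.ix_(idx, idx)]
    Xg = G.imputed()[idx, :]
    m = idx.size

    # standardize traits internally (conditioning); Wald is scale-invariant
    # and effects are transformed back at the end
    trait_sd = Yv.std(axis=0, ddof=1)
    trait_sd[trait_sd <= 0] = 1.0
    Yv = Yv / trait_sd

    S, U = _eigen_k(Ks)
    Ystar = U.T @ Yv
    x0 = U.T @ np.ones(m)
    Xm = U.T @ Xg

    Vg, Ve = _em_reml_mv(Ystar, x0, S)
    Sig = S[:, None, None] * Vg[None] + Ve[None]
    W = np.linalg.inv(Sig)

    x0sq = x0**2
    A00 = np.einsum("i,ijk->jk", x0sq, W)
    A00inv = np.linalg.inv(A00)
    WY = np.einsum("ijk,ik->ij", W, Ystar)
    b0 = x0 @ WY
    ytWy = float(np.einsum("ij,ij->", Ystar, WY))

    A0m = np.einsum("i,ia,ijk->ajk", x0, Xm, W)          # (M, d, d)
    Amm = np.einsum("ia,ijk->ajk", Xm**2, W)
    bm = Xm.T @ WY                                        # (M, d)

    Sm = Amm - A0m @ A00inv @ A0m
    rhs = bm - np.einsum("ajk,k->aj", A0m, A00inv @ b0)
    M = Xm.shape[1]
    beta = np.zeros((M, d))
    wald = np.zeros(M)
    pvals = np.ones(M)
    dof = m * d - 2 * d
    # batched solve with singular-marker guard
    try:
        beta = np.linalg.solve(Sm, rhs[..., None])[..., 0]
        solvable = np.all(np.isfinite(beta), axis=1)
    except np.linalg.LinAlgError:
        solvable = np.zeros(M, dtype=bool)
        for a in range(M):
            try:
                beta[a] = np.linalg.solve(Sm[a], rhs[a])
                solvable[a] = True
            except np.linalg.LinAlgError:
                pass
    mu_m = (A00inv @ (b0[:, None] - np.einsum("ajk,ak->ja", A0m, beta))).T  # (M, d)
    rss = ytWy - np.einsum("aj,j->a", mu_m, b0) - np.einsum("aj,aj->a", bm, beta)
    c = np.maximum(rss, 1e-300) / dof
    quad = np.einsum("aj,ajk,ak->a", beta, Sm, beta)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(solvable & (c > 0), quad / c, 0.0)
    wald = np.clip(wald, 0.0, None)
    pvals = stats.chi2.sf(wald, df=d)

    out = G.marker_map[["marker_id", "chrom", "pos"]].copy()
    out["maf"] = G.maf()
    for j, t in enumerate(Y.columns):
        out[f"beta_{t}"] = beta[:, j] * trait_sd[j]
    out["wald"] = wald
    out["p_wald"] = pvals
    out["minus_log10_p"] = -np.log10(np.clip(pvals, 1e-300, None))
    out["trait"] = label
    out["model"] = "multivariate"
    return out


def pc_gwas(
    scores: pd.DataFrame,
    G: GenotypeData,
    K: np.ndarray | None = None,
    n_pcs: int = 10,
) -> pd.DataFrame:
    """Univariate scans on the first ``n_pcs`` principal-component scores."""
    if K is None:
        K = relatedness_matrix(G)
    cols = list(scores.columns[:n_pcs])
    frames = []
    for c in cols:
        res = lmm_scan(scores[c], G, K=K, trait=str(c))
        res["model"] = "pc"
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# thresholds, FDR, candidate windows, diagnostics

def declare_significant(
    results: pd.DataFrame,
    logp_threshold: float = 3.5,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Flag markers by raw -log10(p) threshold (inclusive) and BH FDR.

    The Benjamini-Hochberg step-up procedure runs within each
    (model, trait) scan.  Both flags are reported; neither filters rows.
    """
    if results.empty:
        raise ValueError("empty association results")
    out = results.copy()
    out["raw_pass"] = out["minus_log10_p"] >= logp_threshold
    out["fdr_pass"] = False
    for _, idx in out.groupby(["model", "trait"]).groups.items():
        p = out.loc[idx, "p_wald"].to_numpy()
        out.loc[idx, "fdr_pass"] = multipletests(p, alpha=fdr_q, method="fdr_bh")[0]
    return out


def candidate_windows(
    significant: pd.DataFrame,
    annotation: pd.DataFrame,
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Genes within +/- ``window_bp`` of each marker (inclusive overlap).

    ``annotation`` needs columns ``gene_id, chrom, start, end`` with 1-based
    inclusive coordinates.  The window is clipped at position 0.  The
    reported distance is 0 when the gene spans the marker position,
    otherwise the gap between the marker and the nearest gene edge.
    """
    needed = {"gene_id", "chrom", "start", "end"}
    if not needed <= set(annotation.columns):
        raise ValueError(f"annotation table needs columns {sorted(needed)}")
    hits = []
    ann_by_chrom = {str(c): grp for c, grp in annotation.groupby("chrom")}
    for _, mk in significant.iterrows():
        chrom = str(mk["chrom"])
        pos = int(mk["pos"])
        lo = max(pos - window_bp, 0)
        hi = pos + window_bp
        grp = ann_by_chrom.get(chrom)
        if grp is None:
            continue
        sel = grp[(grp["start"] <= hi) & (grp["end"] >= lo)]
        for _, gene in sel.iterrows():
            if gene["start"] <= pos <= gene["end"]:
                dist = 0
            else:
                dist = int(min(abs(gene["start"] - pos), abs(gene["end"] - pos)))
            hits.append(
                dict(
                    marker_id=mk["marker_id"], chrom=chrom, pos=pos,
                    gene_id=gene["gene_id"], gene_start=int(gene["start"]),
                    gene_end=int(gene["end"]), distance_bp=dist,
                )
            )
    return pd.DataFrame(
        hits,
        columns=["marker_id", "chrom", "pos", "gene_id",
                 "gene_start", "gene_end", "distance_bp"],
    )


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic-control lambda: median observed chi2 over its null median."""
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    if p.size == 0:
        raise ValueError("no valid p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)
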