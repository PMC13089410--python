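"""Association models for burden scans.

Four models are supported for regressing a quantitative phenotype y on a
binary gene-burden marker x:

* ``glm``       y = x b + e                       (naive linear model)
* ``glm_pc``    y = x b + C g + e                 (top principal components)
* ``emmax``     y = x b + u + e,  u ~ N(0, s2g K) (kinship mixed model)
* ``emmax_pc``  y = x b + C g + u + e

The mixed models use the EMMAX approximation: the variance components
(s2g, s2e) are estimated once per phenotype by REML under the null model
(no marker), after which every marker is tested by generalized least
squares with the covariance structure K + delta*I held fixed.  The
residual scale is re-estimated per marker, so with K = I the test reduces
exactly to the ordinary t-test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phenotype preprocessing

def prep_expression(raw: pd.DataFrame, floor: float = 0.0) -> pd.DataFrame:
    """log2-transform an accession x gene expression matrix with min-fill.

    Non-finite values after log2 (zeros in the raw matrix) are replaced,
    per gene, by the lowest finite transformed value among all accessions
    for that gene.  Genes with no positive value anywhere are set to
    ``floor`` with a warning.
    """
    if (raw.to_numpy() < 0).any():
        raise ValueError("raw expression values must be nonnegative")
    with np.errstate(divide="ignore"):
        logged = np.log2(raw.to_numpy(dtype=float))
    logged[~np.isfinite(logged)] = np.nan
    out = pd.DataFrame(logged, index=raw.index, columns=raw.columns)
    col_min = out.min(axis=0, skipna=True)
    all_nan = col_min.isna()
    if all_nan.any():
        warnings.warn(
            f"{int(all_nan.sum())} genes with all-zero expression set to floor {floor}"
        )
        col_min[all_nan] = floor
    return out.fillna(col_min)


def int_transform(y: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transformation.

    Values are ranked with average ranks for ties and mapped through the
    standard normal quantile function at r/(n+1).  The result preserves the
    input's rank order and is invariant to monotone transforms of y.
    """
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 1:
        raise ValueError("int_transform expects a 1-D vector")
    if np.sum(np.isfinite(arr)) < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.nanmax(arr) == np.nanmin(arr):
        raise ValueError("constant vector: rank transform undefined")
    ranks = stats.rankdata(arr, method="average", nan_policy="omit")
    n = np.sum(np.isfinite(arr))
    out = np.full_like(arr, np.nan)
    ok = np.isfinite(arr)
    out[ok] = stats.norm.ppf(ranks[ok] / (n + 1))
    return out


# ---------------------------------------------------------------------------
# relatedness

def compute_kinship(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Centered genomic relationship matrix K = Z Z' / m.

    ``genotypes``: accession x SNP dosage matrix (0/2 coding for inbred
    lines).  Columns are mean-centered; monomorphic columns carry no
    information and an all-monomorphic matrix raises.  Rows of K sum to
    (numerically) zero by construction.
    """
    G = genotypes.to_numpy(dtype=float)
    if G.shape[0] < 2:
        raise ValueError("need at least two accessions")
    poly = G.std(axis=0) > 0
    if not poly.any():
        raise ValueError("no polymorphic SNPs in genotype matrix")
    Z = G[:, poly] - G[:, poly].mean(axis=0)
    K = Z @ Z.T / Z.shape[1]
    return pd.DataFrame(K, index=genotypes.index, columns=genotypes.index)


def compute_pcs(genotypes: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k genetic principal components (orthonormal eigenvectors of K)."""
    n = genotypes.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_accessions={n}")
    K = compute_kinship(genotypes).to_numpy()
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1][:k]
    pcs = vecs[:, order]
    return pd.DataFrame(
        pcs, index=genotypes.index, columns=[f"PC{i + 1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# REML variance components

@dataclass
class VarianceComponents:
    """REML estimates under y = C g + u + e with u ~ N(0, s2g K)."""

    sigma_g2: float
    sigma_e2: float
    delta: float  # s2e / s2g
    reml_loglik: float
    h2: float  # trace-normalized s2g*(trK/n) / (s2g*(trK/n) + s2e)
    boundary: bool  # optimizer pinned at the delta search boundary

    def as_dict(self) -> Dict[str, float]:
        return {
            "sigma_g2": self.sigma_g2,
            "sigma_e2": self.sigma_e2,
            "delta": self.delta,
            "reml_loglik": self.reml_loglik,
            "h2": self.h2,
        }


def _check_psd(K: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
    if vals.min() < -tol * max(1.0, vals.max()):
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {vals.min():.3g})")
    return np.clip(vals, 0.0, None), vecs


class _RotatedNull:
    """Eigen-rotated data for one phenotype/covariate pair."""

    __slots__ = ("yr", "Cr", "lam", "n", "q", "logdet_CtC")

    def __init__(self, y: np.ndarray, C: np.ndarray, lam: np.ndarray, U: np.ndarray):
        self.yr = U.T @ y
        self.Cr = U.T @ C
        self.lam = lam
        self.n, self.q = C.shape
        sign, logdet = np.linalg.slogdet(C.T @ C)
        if sign <= 0:
            raise ValueError("covariate block is rank deficient")
        self.logdet_CtC = logdet

    def reml_loglik(self, log10_delta: float) -> Tuple[float, float]:
        """Profiled REML log-likelihood and the implied sigma_g2."""
        delta = 10.0 ** log10_delta
        w = self.lam + delta
        Wi = 1.0 / w
        CtWC = self.Cr.T @ (self.Cr * Wi[:, None])
        CtWy = self.Cr.T @ (self.yr * Wi)
        beta = np.linalg.solve(CtWC, CtWy)
        r = self.yr - self.Cr @ beta
        rss = float(r @ (r * Wi))
        nq = self.n - self.q
        sigma_g2 = rss / nq
        sign, logdet_CtWC = np.linalg.slogdet(CtWC)
        ll = -0.5 * (
            nq * np.log(2 * np.pi * sigma_g2)
            + nq
            + np.sum(np.log(w))
            + logdet_CtWC
            - self.logdet_CtC
        )
        return ll, sigma_g2


def reml_fit(
    y: np.ndarray,
    C: np.ndarray,
    K: np.ndarray,
    grid_points: int = 100,
    log10_bounds: Tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-8,
) -> VarianceComponents:
    """REML fit of (s2g, s2e) by 1-D optimization of log10(delta).

    A coarse grid over ``log10_bounds`` seeds a bounded Brent refinement in
    the best grid cell; the reported optimum is reproducible given inputs.
    """
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    lam, U = _check_psd(np.asarray(K, dtype=float))
    rot = _RotatedNull(y, C, lam, U)
    grid = np.linspace(log10_bounds[0], log10_bounds[1], grid_points)
    lls = np.array([rot.reml_loglik(g)[0] for g in grid])
    i = int(np.argmax(lls))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(
        lambda g: -rot.reml_loglik(g)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    best = float(res.x)
    ll, sigma_g2 = rot.reml_loglik(best)
    # keep whichever of grid-argmax / refined point is better
    if lls[i] > ll:
        best, ll = float(grid[i]), float(lls[i])
        _, sigma_g2 = rot.reml_loglik(best)
    delta = 10.0 ** best
    sigma_e2 = delta * sigma_g2
    boundary = best <= log10_bounds[0] + 1e-6 or best >= log10_bounds[1] - 1e-6
    if boundary:
        logger.info("REML optimum at delta boundary (log10 delta = %.2f)", best)
    kbar = float(np.trace(np.asarray(K, dtype=float))) / len(y)
    h2 = sigma_g2 * kbar / (sigma_g2 * kbar + sigma_e2)
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        reml_loglik=float(ll),
        h2=float(h2),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# scans

class EmmaxEngine:
    """Shared machinery for scanning many phenotypes against one marker set.

    The kinship eigendecomposition is computed once; each phenotype gets a
    REML null fit, after which per-marker tests are vectorized weighted
    regressions in the rotated basis.  ``K=None`` gives the ordinary linear
    model (identity rotation, unit weights).
    """

    def __init__(self, K: Optional[np.ndarray], C: np.ndarray):
        self.C = np.asarray(C, dtype=float)
        self.n = self.C.shape[0]
        if K is None:
            self.lam, self.U = None, None
        else:
            self.lam, self.U = _check_psd(np.asarray(K, dtype=float))

    def rotate(self, X: np.ndarray) -> np.ndarray:
        return X if self.U is None else self.U.T @ X


class PhenotypeContext:
    """Rotated, weighted phenotype/covariate data ready for marker tests."""

    __slots__ = ("ys", "Cs", "CtC_inv", "yperp", "df", "vc", "sqrt_wi")

    def __init__(self, yr: np.ndarray, Cr: np.ndarray, w: np.ndarray,
                 vc: Optional[VarianceComponents]):
        self.sqrt_wi = 1.0 / np.sqrt(w)
        self.ys = yr * self.sqrt_wi
        self.Cs = Cr * self.sqrt_wi[:, None]
        self.CtC_inv = np.linalg.inv(self.Cs.T @ self.Cs)
        # residualize y against covariates once
        self.yperp = self.ys - self.Cs @ (self.CtC_inv @ (self.Cs.T @ self.ys))
        n, q = Cr.shape
        self.df = n - q - 1
        self.vc = vc


def _make_context(
    y: np.ndarray, C: np.ndarray, engine: EmmaxEngine, K: Optional[np.ndarray]
) -> PhenotypeContext:
    if engine.U is None:
        return PhenotypeContext(np.asarray(y, float), C, np.ones(len(y)), None)
    vc = reml_fit(np.asarray(y, float), C, K)
    yr = engine.U.T @ np.asarray(y, float)
    Cr = engine.U.T @ C
    w = engine.lam + vc.delta
    return PhenotypeContext(yr, Cr, w, vc)


def _scan_rotated(ctx: PhenotypeContext, Xr: np.ndarray,
                  min_var: float = 1e-12) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker GLS given rotated markers (n x m).

    Uses Frisch-Waugh residualization: each marker column is projected off
    the covariates in the weighted basis, then tested by simple regression
    of the residualized phenotype on the residualized marker.  The residual
    scale is re-estimated per marker with df = n - q - 1.
    """
    Xs = Xr * ctx.sqrt_wi[:, None]
    Xperp = Xs - ctx.Cs @ (ctx.CtC_inv @ (ctx.Cs.T @ Xs))
    xtx = np.einsum("ij,ij->j", Xperp, Xperp)
    xty = Xperp.T @ ctx.yperp
    yty = float(ctx.yperp @ ctx.yperp)
    ok = xtx > min_var
    beta = np.full(Xr.shape[1], np.nan)
    se = np.full(Xr.shape[1], np.nan)
    pval = np.full(Xr.shape[1], np.nan)
    beta[ok] = xty[ok] / xtx[ok]
    rss = np.maximum(yty - beta[ok] ** 2 * xtx[ok], 0.0)
    s2 = rss / ctx.df
    se[ok] = np.sqrt(s2 / xtx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    pv = 2.0 * stats.t.sf(np.abs(tstat), ctx.df)
    pval[ok] = np.clip(pv, np.finfo(float).tiny, 1.0)
    return beta, se, pval


def _as_2d(markers) -> Tuple[np.ndarray, List[str]]:
    if isinstance(markers, pd.DataFrame):
        return markers.to_numpy(dtype=float), list(markers.columns)
    X = np.asarray(markers, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"m{i}" for i in range(X.shape[1])]


def _covariates(n: int, C: Optional[np.ndarray]) -> np.ndarray:
    ones = np.ones((n, 1))
    if C is None:
        return ones
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    full = np.hstack([ones, C])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("collinear covariate columns (including intercept)")
    return full


def emmax_scan(
    y: np.ndarray,
    markers,
    K: np.ndarray,
    C: Optional[np.ndarray] = None,
    phenotype_id: str = "y",
    model_tag: str = "emmax",
) -> pd.DataFrame:
    """EMMAX scan of one phenotype across binary burden markers.

    Variance components are REML-fitted once under the null; each marker is
    then tested by GLS with fixed covariance structure.  Constant markers
    yield p = NaN with a warning.
    """
    X, names = _as_2d(markers)
    Cfull = _covariates(len(y), C)
    engine = EmmaxEngine(K, Cfull)
    ctx = _make_context(y, Cfull, engine, K)
    beta, se, p = _scan_rotated(ctx, engine.rotate(X))
    if np.isnan(p).any():
        warnings.warn(f"{int(np.isnan(p).sum())} constant markers yielded p=NaN")
    return _result_frame(names, phenotype_id, beta, se, p, model_tag, len(y), ctx.vc)


def glm_scan(
    y: np.ndarray,
    markers,
    C: Optional[np.ndarray] = None,
    phenotype_id: str = "y",
    model_tag: str = "glm",
) -> pd.DataFrame:
    """Per-marker ordinary least squares with optional PC covariates."""
    X, names = _as_2d(markers)
    Cfull = _covariates(len(y), C)
    engine = EmmaxEngine(None, Cfull)
    ctx = _make_context(y, Cfull, engine, None)
    beta, se, p = _scan_rotated(ctx, X)
    return _result_frame(names, phenotype_id, beta, se, p, model_tag, len(y), None)


def _result_frame(names, phenotype_id, beta, se, p, model_tag, n,
                  vc: Optional[VarianceComponents]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "marker": names,
            "phenotype": phenotype_id,
            "beta": beta,
            "se": se,
            "p_value": p,
            "model": model_tag,
            "n_used": n,
        }
    )
    if vc is not None:
        df.attrs["variance_components"] = vc.as_dict()
    return df


# ---------------------------------------------------------------------------
# model / results objects

class BurdenScan:
    """Burden-association model over many phenotypes.

    Parameters
    ----------
    phenotypes : DataFrame (accessions x phenotypes)
    markers : DataFrame (accessions x burden columns, binary)
    kinship : DataFrame or None — required for the emmax models
    pcs : DataFrame or None — required for the *_pc models
    model : {"glm", "glm_pc", "emmax", "emmax_pc"}

    All inputs are intersected on shared accession ids; the intersection
    size is recorded on the results.
    """

    MODELS = ("glm", "glm_pc", "emmax", "emmax_pc")

    def __init__(self, phenotypes: pd.DataFrame, markers: pd.DataFrame,
                 kinship: Optional[pd.DataFrame] = None,
                 pcs: Optional[pd.DataFrame] = None,
                 model: str = "emmax"):
        if model not in self.MODELS:
            raise ValueError(f"model must be one of {self.MODELS}")
        if model.startswith("emmax") and kinship is None:
            raise ValueError("emmax models require a kinship matrix")
        if model.endswith("_pc") and pcs is None:
            raise ValueError("*_pc models require principal components")
        panels = [set(phenotypes.index), set(markers.index)]
        if kinship is not None:
            panels.append(set(kinship.index))
        if pcs is not None:
            panels.append(set(pcs.index))
        shared = sorted(set.intersection(*panels))
        if not shared:
            raise ValueError("no shared accessions across inputs")
        self.accessions = shared
        self.phenotypes = phenotypes.loc[shared]
        self.markers = markers.loc[shared]
        self.kinship = kinship.loc[shared, shared] if kinship is not None else None
        self.pcs = pcs.loc[shared] if pcs is not None else None
        self.model = model

    def fit(self, progress: bool = False) -> "ScanResults":
        K = self.kinship.to_numpy() if self.kinship is not None else None
        Cextra = self.pcs.to_numpy() if self.model.endswith("_pc") else None
        Cfull = _covariates(len(self.accessions), Cextra)
        engine = EmmaxEngine(K, Cfull)
        X = self.markers.to_numpy(dtype=float)
        Xr = engine.rotate(X) if K is not None else X
        frames = []
        vcs = {}
        contexts = {}
        for pid in self.phenotypes.columns:
            y = self.phenotypes[pid].to_numpy(dtype=float)
            ctx = _make_context(y, Cfull, engine, K)
            if K is not None:
                beta, se, p = _scan_rotated(ctx, Xr)
            else:
                beta, se, p = _scan_rotated(ctx, X)
            frames.append(_result_frame(list(self.markers.columns), pid,
                                        beta, se, p, self.model,
                                        len(self.accessions), ctx.vc))
            if ctx.vc is not None:
                vcs[pid] = ctx.vc
            contexts[pid] = ctx
        table = pd.concat(frames, ignore_index=True)
        return ScanResults(self, table, vcs, engine, contexts)


class ScanResults:
    """Fitted burden-scan results: one row per (marker, phenotype)."""

    def __init__(self, model: BurdenScan, frame: pd.DataFrame,
                 variance_components: Dict[str, VarianceComponents],
                 engine: EmmaxEngine, contexts: Dict[str, PhenotypeContext]):
        self.model = model
        self.frame = frame
        self.variance_components = variance_components
        self._engine = engine
        self._contexts = contexts

    @property
    def p_values(self) -> pd.DataFrame:
        return self.frame.pivot(index="marker", columns="phenotype", values="p_value")

    def summary(self, top: int = 10) -> str:
        lines = [
            "Burden association scan",
            "=" * 56,
            f"model:       {self.model.model}",
            f"accessions:  {len(self.model.accessions)}",
            f"markers:     {self.model.markers.shape[1]}",
            f"phenotypes:  {self.model.phenotypes.shape[1]}",
        ]
        if self.variance_components:
            h2s = [vc.h2 for vc in self.variance_components.values()]
            lines.append(f"median h2:   {np.median(h2s):.3f}")
        lines.append("-" * 56)
        best = self.frame.nsmallest(top, "p_value")
        lines.append(best.to_string(index=False,
                                    float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def scan_permuted(self, permuted_markers: pd.DataFrame) -> pd.DataFrame:
        """Re-test every phenotype against a permuted marker matrix.

        Reuses the null variance components (the EMMAX null model does not
        involve the markers), so permutation scans are cheap.
        """
        X = permuted_markers.loc[self.model.accessions].to_numpy(dtype=float)
        Xr = self._engine.rotate(X)
        frames = []
        for pid, ctx in self._contexts.items():
            beta, se, p = _scan_rotated(ctx, Xr)
            frames.append(_result_frame(list(permuted_markers.columns), pid,
                                        beta, se, p, self.model.model,
                                        len(self.model.accessions), None))
        return pd.concat(frames, ignore_index=True)

    def manhattan_table(self, gene_coords: pd.DataFrame,
                        phenotype: str) -> pd.DataFrame:
        """Per-marker table (chromosome, midpoint, -log10 p) for one phenotype."""
        sub = self.frame[self.frame["phenotype"] == phenotype].set_index("marker")
        out = gene_coords.reindex(sub.index)[["chromosome", "midpoint"]].copy()
        out["neglog10_p"] = -np.log10(sub["p_value"])
        return out.reset_index(names="marker")

    def plot_manhattan(self, gene_coords: pd.DataFrame, phenotype: str, ax=None,
                       threshold: Optional[float] = None):
        import matplotlib.pyplot as plt

        tab = self.manhattan_table(gene_coords, phenotype)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        offset = 0.0
        for chrom, sub in tab.groupby("chromosome", sort=True):
            ax.scatter(sub["midpoint"] + offset, sub["neglog10_p"], s=8, label=str(chrom))
            offset += float(sub["midpoint"].max()) + 1e5
        if threshold is not None:
            ax.axhline(-np.log10(threshold), ls="--", c="grey")
        ax.set_xlabel("gene midpoint (cumulative bp)")
        ax.set_ylabel("-log10 p")
        ax.set_title(f"{self.model.model} scan: {phenotype}")
        return ax
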