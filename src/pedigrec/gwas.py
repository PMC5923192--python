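"""Linear mixed model association scan: y = Xg + Za + e.

The phenotype is modelled with a random polygenic animal effect
``a ~ N(0, sigma_a^2 K)`` (K a genomic or pedigree relationship
matrix) and residual ``e ~ N(0, sigma_e^2 I)``.  Variance components
are estimated once by restricted maximum likelihood under the null
(no-SNP) model using the eigendecomposition of K, then reused for a
generalized-least-squares Wald test of every SNP (the usual one-step
approximation; with K rotated away each SNP test is a weighted
regression, so the genome scan costs one eigendecomposition plus
O(n * m) arithmetic).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

_LOG10_DELTA_BOUNDS = (-5.0, 5.0)   # search range for sigma_e^2 / sigma_a^2


# ---------------------------------------------------------------------------
# relationship matrices

def compute_grm(genotypes: np.ndarray, freqs: np.ndarray | None = None) -> np.ndarray:
    """Genomic relationship matrix from allele counts (VanRaden form).

    Missing genotypes are mean-imputed per SNP; columns are centered by
    twice the allele frequency and the cross-product normalized by
    ``2 * sum p_j (1 - p_j)``.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need a 2-D genotype matrix with >= 2 animals")
    G = G.copy()
    miss = G < 0
    if miss.any():
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(miss, np.nan, G), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        G[miss] = np.broadcast_to(col_mean, G.shape)[miss]
    p = G.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs are monomorphic; GRM undefined")
    C = G - 2.0 * p
    return C @ C.T / denom


def pedigree_a_matrix(ped: pd.DataFrame, ids) -> np.ndarray:
    """Numerator relationship matrix by the tabular recursion.

    ``ped`` is indexed by animal id with ``sire``/``dam`` columns
    ("0" = unknown).  Returns A restricted to ``ids`` (which must be in
    the pedigree); ancestors are included in the recursion.
    """
    ids = list(ids)
    order: list = []
    seen = set()

    def visit(a):
        if a in seen or a == "0" or a not in ped.index:
            return
        seen.add(a)
        row = ped.loc[a]
        visit(row["sire"])
        visit(row["dam"])
        order.append(a)

    for a in ids:
        visit(a)
    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, a in enumerate(order):
        row = ped.loc[a]
        s = pos.get(row["sire"], -1)
        d = pos.get(row["dam"], -1)
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = A[j, i] = v
    sel = [pos[a] for a in ids]
    return A[np.ix_(sel, sel)]


# ---------------------------------------------------------------------------
# REML

def reml_loglik_dense(y, X, K, sigma_a2, sigma_e2) -> float:
    """Restricted log-likelihood by direct dense linear algebra.

    Reference implementation used to validate the eigen-rotated path:
    l = -1/2 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + r'V^-1 r ].
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    V = sigma_a2 * K + sigma_e2 * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdet_x = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_x
                   + r @ Vi @ r)


def _rotated_reml_loglik(y_r, X_r, s, sigma_a2, sigma_e2) -> float:
    """Same restricted log-likelihood in the eigenbasis of K."""
    n, p = X_r.shape
    w = sigma_a2 * s + sigma_e2
    iw = 1.0 / w
    XtWX = (X_r * iw[:, None]).T @ X_r
    beta = np.linalg.solve(XtWX, (X_r * iw[:, None]).T @ y_r)
    r = y_r - X_r @ beta
    _, logdet_x = np.linalg.slogdet(XtWX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + np.sum(np.log(w)) + logdet_x
                   + np.sum(r * r * iw))


@dataclass
class NullFit:
    """Variance components of the no-SNP mixed model."""

    sigma_a2: float
    sigma_e2: float
    loglik: float
    beta: np.ndarray
    flag: str                 # 'ok' | 'boundary' | 'indeterminate'
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @property
    def heritability(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else float("nan")


def fit_null_reml(y, K, X: np.ndarray | None = None) -> NullFit:
    """REML fit of the one-ratio model via eigen-rotation of K.

    The variance ratio delta = sigma_e^2 / sigma_a^2 is profiled out of
    sigma_a^2 and optimized by bounded scalar search on log10 delta in
    [-5, 5].  A flat profile (e.g. K = I, where only the total variance
    is identified) is flagged ``indeterminate`` and resolved to the
    ordinary-regression limit sigma_a^2 = 0.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n or n <= X.shape[1]:
        raise ValueError("need more observations than fixed effects")
    s, U = np.linalg.eigh(np.asarray(K, dtype=float))
    s = np.clip(s, 0.0, None)
    y_r = U.T @ y
    X_r = U.T @ X
    p = X.shape[1]

    def profiled(log10_delta: float):
        delta = 10.0 ** log10_delta
        w = s + delta
        iw = 1.0 / w
        XtWX = (X_r * iw[:, None]).T @ X_r
        XtWy = (X_r * iw[:, None]).T @ y_r
        beta = np.linalg.solve(XtWX, XtWy)
        r = y_r - X_r @ beta
        rss = float(np.sum(r * r * iw))
        sigma_a2 = rss / (n - p)
        _, logdet_x = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma_a2) + 1.0)
                     + np.sum(np.log(w)) + logdet_x)
        return ll, sigma_a2, beta

    lo, hi = _LOG10_DELTA_BOUNDS
    grid = np.linspace(lo, hi, 41)
    lls = np.array([profiled(g)[0] for g in grid])
    if not np.all(np.isfinite(lls)):
        raise ValueError("non-finite restricted likelihood; check K and y")

    if lls.max() - lls.min() < 1e-8:
        # ratio not identified: fall back to ordinary regression
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma_e2 = float(resid @ resid) / (n - p)
        return NullFit(sigma_a2=0.0, sigma_e2=sigma_e2, loglik=float(lls[0]),
                       beta=beta, flag="indeterminate", eigvals=s, eigvecs=U)

    g0 = grid[int(np.argmax(lls))]
    span = grid[1] - grid[0]
    res = minimize_scalar(lambda g: -profiled(g)[0],
                          bounds=(max(lo, g0 - span), min(hi, g0 + span)),
                          method="bounded",
                          options={"xatol": 1e-8})
    ll, sigma_a2, beta = profiled(res.x)
    delta = 10.0 ** res.x
    flag = "boundary" if (res.x <= lo + 1e-3 or res.x >= hi - 1e-3) else "ok"
    return NullFit(sigma_a2=sigma_a2, sigma_e2=delta * sigma_a2,
                   loglik=float(ll), beta=beta, flag=flag,
                   eigvals=s, eigvecs=U)


# ---------------------------------------------------------------------------
# scan

def snp_scan(y, genotypes, K=None, null: NullFit | None = None,
             snp_info: pd.DataFrame | None = None,
             alpha: float = 0.05) -> pd.DataFrame:
    """GLS Wald scan of each SNP with variance components held fixed.

    Monomorphic SNPs are skipped (NaN p, ``tested=False``) and excluded
    from the Bonferroni denominator.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if K is None and null is None:
        raise ValueError("provide a kinship matrix or a fitted null model")
    if null is None:
        null = fit_null_reml(y, K)

    U, s = null.eigvecs, null.eigvals
    w = null.sigma_a2 * s + null.sigma_e2
    iw = 1.0 / w
    y_r = U.T @ y
    one_r = U.T @ np.ones(n)
    G_r = U.T @ G

    a11 = float(np.sum(one_r * one_r * iw))
    a12 = (one_r * iw) @ G_r
    a22 = iw @ (G_r * G_r)
    b1 = float(np.sum(one_r * y_r * iw))
    b2 = (y_r * iw) @ G_r

    det = a11 * a22 - a12 ** 2
    tested = G.std(axis=0) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        var_beta = a11 / det
        se = np.sqrt(var_beta)
        zsq = (beta / se) ** 2
    p = np.where(tested, chi2.sf(zsq, df=1), np.nan)
    beta = np.where(tested, beta, np.nan)
    se = np.where(tested, se, np.nan)

    n_tests = int(tested.sum())
    threshold = alpha / n_tests if n_tests else np.nan
    out = pd.DataFrame({
        "beta": beta, "se": se, "p": p,
        "tested": tested,
        "significant": tested & (p < threshold),
    })
    if snp_info is not None:
        out = pd.concat([snp_info.reset_index(drop=True), out], axis=1)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tests"] = n_tests
    return out


# ---------------------------------------------------------------------------
# model / results interface

class RecombinationGwas:
    """Mixed-model GWAS of a recombination phenotype.

    Parameters
    ----------
    phenotypes : DataFrame with ``animal`` and ``phenotype`` columns
        (one record per animal), or a Series indexed by animal id.
    cohort : the genotyped :class:`~pedigrec.io.Cohort`.
    kinship : ``"grm"`` (genomic relationship matrix from the cohort
        genotypes), ``"pedigree"`` (numerator relationship matrix), or
        an explicit matrix aligned with the phenotype animals.
    """

    def __init__(self, phenotypes, cohort, kinship="grm"):
        if isinstance(phenotypes, pd.Series):
            phenotypes = phenotypes.rename("phenotype").rename_axis("animal").reset_index()
        keep = [a for a in phenotypes["animal"] if cohort.is_genotyped(a)]
        ph = phenotypes.set_index("animal").loc[keep]
        self.animals = list(ph.index)
        self.y = ph["phenotype"].to_numpy(dtype=float)
        self.cohort = cohort
        self.G = np.vstack([cohort.genotypes_of(a) for a in self.animals]).astype(float)
        self.snp_info = cohort.markers.table[["name", "chrom", "bp"]]
        if isinstance(kinship, str):
            if kinship == "grm":
                self.K = compute_grm(self.G)
            elif kinship == "pedigree":
                self.K = pedigree_a_matrix(cohort.ped, self.animals)
            else:
                raise ValueError(f"unknown kinship {kinship!r}")
        else:
            self.K = np.asarray(kinship, dtype=float)
        if self.K.shape != (len(self.animals),) * 2:
            raise ValueError("kinship matrix does not match phenotype animals")

    def fit(self, alpha: float = 0.05) -> "GwasResults":
        null = fit_null_reml(self.y, self.K)
        Gs = np.where(self.G < 0, np.nan, self.G)
        col_mean = np.nanmean(Gs, axis=0)
        Gs = np.where(np.isnan(Gs), col_mean, Gs)
        table = snp_scan(self.y, Gs, null=null, snp_info=self.snp_info,
                         alpha=alpha)
        return GwasResults(model=self, null=null, table=table, alpha=alpha)


@dataclass
class GwasResults:
    model: RecombinationGwas
    null: NullFit
    table: pd.DataFrame
    alpha: float

    @property
    def heritability(self) -> float:
        return self.null.heritability

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "p")

    def manhattan_data(self) -> pd.DataFrame:
        d = self.table[["name", "chrom", "bp", "p"]].copy()
        d["neglog10p"] = -np.log10(d["p"])
        return d

    def summary(self) -> str:
        t = self.table
        lines = [
            "Mixed-model GWAS (y = Xg + Za + e)",
            f"  animals: {len(self.model.animals)}   SNPs tested: "
            f"{t.attrs['n_tests']} of {len(t)}",
            f"  sigma_a^2 = {self.null.sigma_a2:.4g}   sigma_e^2 = "
            f"{self.null.sigma_e2:.4g}   h^2 = {self.heritability:.3f} "
            f"[{self.null.flag}]",
            f"  Bonferroni threshold (alpha={self.alpha}): "
            f"{t.attrs['bonferroni_threshold']:.3g}",
            f"  genome-wide significant SNPs: {int(t['significant'].sum())}",
            "  top associations:",
        ]
        top = self.top(5)
        for _, r in top.iterrows():
            lines.append(
                f"    {r['name']:<16} chr{int(r['chrom'])}:{int(r['bp'])}"
                f"  beta={r['beta']:+.4f}  se={r['se']:.4f}  p={r['p']:.3g}"
            )
        return "\n".join(lines)
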