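"""Differentiation and variance-partition statistics.

Per-SNP Weir & Cockerham (1984) theta for two populations of diploid calls,
its distribution/global summaries, one-level AMOVA with permutation testing,
and PCA with mean imputation of missing genotype calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GenotypeMatrix

__all__ = [
    "wc_fst_site", "fst_profile", "FstResult",
    "amova", "amova_snp", "AmovaResult", "snp_distance_matrix",
    "MeanImputePCA", "pca_mean_impute", "PcaResult",
]


def _wc_components(n, p, h):
    """Weir & Cockerham (1984) variance components a, b, c.

    n, p, h: per-population arrays of sample sizes (diploid individuals with
    calls), alt-allele frequencies and observed heterozygote frequencies.
    Arrays may carry a leading site axis for vectorized evaluation.
    """
    r = n.shape[-1]
    nbar = n.mean(axis=-1)
    nc = (r * nbar - (n * n).sum(axis=-1) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=-1) / (r * nbar)
    s2 = (n * (p - pbar[..., None]) ** 2).sum(axis=-1) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=-1) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def wc_fst_site(genotypes_by_pop):
    """Weir-Cockerham theta at one site from per-population diploid calls.

    Parameters
    ----------
    genotypes_by_pop : sequence of 1-D arrays of dosages {0,1,2}, -1 missing.

    Returns the estimate (negative values retained) or NaN when undefined:
    a population entirely missing, fewer than 2 populations with calls, a
    mean sample size of 1, or a zero denominator a+b+c.
    """
    ns, ps, hs = [], [], []
    for g in genotypes_by_pop:
        g = np.asarray(g)
        g = g[g >= 0]
        if g.size == 0:
            return np.nan
        ns.append(g.size)
        ps.append(g.mean() / 2.0)
        hs.append(np.mean(g == 1))
    if len(ns) < 2:
        return np.nan
    n = np.array(ns, dtype=float)
    if n.mean() <= 1:
        return np.nan
    a, b, c = _wc_components(n, np.array(ps), np.array(hs))
    denom = a + b + c
    if denom == 0:
        return np.nan
    return a / denom


@dataclass
class FstResult:
    """Per-site Weir-Cockerham estimates and their summaries.

    ``global_mean`` is the unweighted mean of defined per-site estimates (the
    headline statistic); ``global_ratio`` the ratio-of-sums alternative.
    """

    per_site: np.ndarray
    global_mean: float
    global_ratio: float
    histogram: pd.DataFrame

    @property
    def n_defined(self) -> int:
        return int(np.sum(~np.isnan(self.per_site)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site": np.arange(self.per_site.size),
                             "fst": self.per_site})


def fst_profile(G: GenotypeMatrix, pops=None) -> FstResult:
    """Per-SNP and global Weir-Cockerham F_ST between two populations."""
    labels = pops if pops is not None else G.pop_labels
    if len(labels) != 2:
        raise ValueError("fst_profile requires exactly two populations")
    idx = [G.pop_index(l) for l in labels]

    n = np.empty((G.n_sites, 2))
    p = np.empty((G.n_sites, 2))
    h = np.empty((G.n_sites, 2))
    for k, ix in enumerate(idx):
        g = G.genotypes[ix]
        called = g >= 0
        cnt = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n[:, k] = cnt
            p[:, k] = np.where(called, g, 0).sum(axis=0) / (2 * cnt)
            h[:, k] = np.where(called, g == 1, False).sum(axis=0) / cnt
    ok = (n > 0).all(axis=1) & (n.mean(axis=1) > 1)
    per_site = np.full(G.n_sites, np.nan)
    a = np.zeros(G.n_sites)
    b = np.zeros(G.n_sites)
    c = np.zeros(G.n_sites)
    if ok.any():
        a_, b_, c_ = _wc_components(n[ok], p[ok], h[ok])
        denom = a_ + b_ + c_
        vals = np.where(denom != 0, a_ / np.where(denom != 0, denom, 1.0), np.nan)
        per_site[ok] = vals
        a[ok], b[ok], c[ok] = a_, b_, c_
    defined = per_site[~np.isnan(per_site)]
    if defined.size == 0:
        raise ValueError("no site has a defined F_ST estimate")
    global_mean = float(defined.mean())
    tot = a.sum() + b.sum() + c.sum()
    global_ratio = float(a.sum() / tot) if tot != 0 else np.nan
    lo = min(0.0, np.floor(defined.min() / 0.05) * 0.05)
    edges = np.arange(lo, 1.0 + 0.05 / 2, 0.05)
    counts, edges = np.histogram(defined, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
    return FstResult(per_site, global_mean, global_ratio, hist)


@dataclass
class AmovaResult:
    """One-level AMOVA: variance among vs within groups."""

    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi: float
    p_value: float
    n_permutations: int
    distance: str = "unspecified"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": ["among_groups", "within_groups"],
            "sigma2": [self.sigma2_among, self.sigma2_within],
            "pct": [self.pct_among, self.pct_within],
            "phi": [self.phi, np.nan],
            "p_value": [self.p_value, np.nan],
        })


def _amova_ss(d2, group_indices, N):
    """(SSD_total, SSD_within) from a squared-distance matrix."""
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / 2.0 / idx.size
    return ss_total, ss_within


def _amova_phi(d2, group_indices, N, n_sizes):
    ss_total, ss_within = _amova_ss(d2, group_indices, N)
    ss_among = ss_total - ss_within
    g = len(group_indices)
    ms_among = ss_among / (g - 1)
    ms_within = ss_within / (N - g)
    n0 = (N - (n_sizes ** 2).sum() / N) / (g - 1)
    sig_w = ms_within
    sig_a = (ms_among - ms_within) / n0
    tot = sig_a + sig_w
    phi = sig_a / tot if tot != 0 else np.nan
    return sig_a, sig_w, phi


def amova(D, groups, n_perm: int = 9999, seed: int = 0,
          squared: bool = False, distance: str = "unspecified") -> AmovaResult:
    """One-level AMOVA on a pairwise distance matrix with a permutation test.

    Excoffier-style sums of squares on squared distances give the among- and
    within-group variance components and Phi = sigma2_a / (sigma2_a +
    sigma2_w); significance is assessed by permuting group labels, with
    p = (1 + #{Phi_perm >= Phi_obs}) / (n_perm + 1).
    """
    D = np.asarray(D, dtype=float)
    N = D.shape[0]
    if D.shape != (N, N):
        raise ValueError("distance matrix must be square")
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("AMOVA needs at least two groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        raise ValueError("every group needs at least two members")
    d2 = D if squared else D ** 2
    group_indices = [np.flatnonzero(inv == k) for k in range(labels.size)]
    sig_a, sig_w, phi = _amova_phi(d2, group_indices, N, sizes.astype(float))
    tot = sig_a + sig_w
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = np.arange(N)
    for _ in range(n_perm):
        rng.shuffle(perm)
        pinv = inv[perm]
        gidx = [np.flatnonzero(pinv == k) for k in range(labels.size)]
        _, _, phi_p = _amova_phi(d2, gidx, N, sizes.astype(float))
        if phi_p >= phi:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return AmovaResult(
        sigma2_among=float(sig_a), sigma2_within=float(sig_w),
        pct_among=float(100 * sig_a / tot), pct_within=float(100 * sig_w / tot),
        phi=float(phi), p_value=float(p), n_permutations=n_perm,
        distance=distance,
    )


def snp_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Euclidean distances on mean-imputed allele-count vectors."""
    X = G.genotypes.astype(float)
    X[X < 0] = np.nan
    means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), means, X)
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def amova_snp(G: GenotypeMatrix, n_perm: int = 9999, seed: int = 0) -> AmovaResult:
    """AMOVA between population labels on SNP allele-count distances."""
    return amova(snp_distance_matrix(G), G.populations, n_perm=n_perm,
                 seed=seed, distance="euclidean_allele_counts")


@dataclass
class PcaResult:
    coordinates: np.ndarray       # individuals x axes scores
    explained_pct: np.ndarray     # percentage of variance per axis

    def to_frame(self, samples=None) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates,
                          columns=[f"PC{i + 1}" for i in
                                   range(self.coordinates.shape[1])])
        if samples is not None:
            df.insert(0, "sample", samples)
        return df


class MeanImputePCA(TransformerMixin, BaseEstimator):
    """PCA of a genotype matrix with per-site mean imputation of missing calls.

    Missing dosages are replaced by the per-site mean of non-missing calls;
    columns are centered (and optionally scaled to unit variance); scores and
    per-axis explained-variance percentages come from the SVD of the
    centered matrix.

    Parameters
    ----------
    scale : bool, default False
        Also divide columns by their standard deviation.
    n_components : int or None
        Number of axes to keep (all by default).
    """

    def __init__(self, scale: bool = False, n_components: int | None = None):
        self.scale = scale
        self.n_components = n_components

    def fit(self, X, y=None):
        if isinstance(X, GenotypeMatrix):
            X = X.genotypes
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
            raise ValueError("need at least 2 individuals and 1 site")
        X = X.copy()
        X[X < 0] = np.nan
        if np.isnan(X).all(axis=0).any():
            raise ValueError("a site is missing in every individual")
        self.mean_ = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), self.mean_, X)
        center = X.mean(axis=0)
        Xc = X - center
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xc = Xc / sd
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        ncomp = self.n_components or S.size
        tot = (S ** 2).sum()
        self.components_ = Vt[:ncomp]
        self.singular_values_ = S[:ncomp]
        self.coordinates_ = U[:, :ncomp] * S[:ncomp]
        self.explained_pct_ = 100.0 * S[:ncomp] ** 2 / tot if tot > 0 \
            else np.zeros(ncomp)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).coordinates_


def pca_mean_impute(G, scale: bool = False) -> PcaResult:
    est = MeanImputePCA(scale=scale).fit(G)
    return PcaResult(est.coordinates_, est.explained_pct_)
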