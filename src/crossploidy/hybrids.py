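"""Detecting admixed individuals.

Two complementary analyses, both sklearn-style estimators:

``AdmixtureEM``
    K = 2 maximum-likelihood admixture proportions (the classic binomial
    admixture model: dosage g_il ~ Binomial(2, q_i p_1l + (1-q_i) p_2l)),
    fitted by expectation-maximization, with 90% parametric-bootstrap
    intervals and the interval-overlap nonhybrid rule (an individual whose
    interval overlaps 0 or 1 is called a nonhybrid).

``HybridClassifier``
    posterior assignment to six categories {PureD, PureT, F1, F2, BC_D,
    BC_T}.  Each category fixes the Mendelian proportions of per-locus
    ancestry pairs (D,D)/(D,T)/(T,T); parental allele frequencies are
    refined jointly by EM with the category posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix

CATEGORIES = ("PureD", "PureT", "F1", "F2", "BC_D", "BC_T")

#: per-category proportions of locus ancestry pairs, ordered (DD, DT, TT)
PHI = np.array([
    [1.00, 0.00, 0.00],   # PureD
    [0.00, 0.00, 1.00],   # PureT
    [0.00, 1.00, 0.00],   # F1
    [0.25, 0.50, 0.25],   # F2
    [0.50, 0.50, 0.00],   # BC_D
    [0.00, 0.50, 0.50],   # BC_T
])

_PCLIP = 1e-6


def _as_geno(X):
    if isinstance(X, GenotypeMatrix):
        return X
    raise TypeError("expected a GenotypeMatrix")


@dataclass
class AdmixtureResult:
    """Per-individual admixture proportion Q with a 90% interval."""

    samples: np.ndarray
    q: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    nonhybrid: np.ndarray
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.samples, "Q": self.q,
            "Q_lo90": self.lo, "Q_hi90": self.hi,
            "nonhybrid": self.nonhybrid,
        })


class AdmixtureEM(BaseEstimator):
    """K = 2 admixture-proportion estimation by EM with bootstrap intervals.

    Parameters
    ----------
    max_iter, tol : EM stopping rule (absolute log-likelihood change).
    n_boot : parametric-bootstrap replicates for the 90% interval
        (genotypes resampled from the fitted model, percentile interval).
    eps : numerical guard for the "interval overlapping 0 or 1" rule.
    anchor_population : population label whose samples define cluster 1
        (resolves label switching); defaults to the first label.
    random_state : seed for the bootstrap.

    Attributes (after fit)
    ----------------------
    q_ : admixture proportion assigned to cluster 1 per individual.
    p_ : (2, n_sites) cluster allele frequencies.
    q_lo_, q_hi_ : 90% interval bounds.
    nonhybrid_ : interval-overlap rule per individual.
    converged_ : EM convergence flag (non-convergence is flagged, not silent).
    """

    def __init__(self, max_iter: int = 2000, tol: float = 1e-6,
                 n_boot: int = 200, eps: float = 1e-6,
                 anchor_population=None, random_state: int = 0):
        self.max_iter = max_iter
        self.tol = tol
        self.n_boot = n_boot
        self.eps = eps
        self.anchor_population = anchor_population
        self.random_state = random_state

    @staticmethod
    def _em(g, called, q, p, max_iter, tol):
        """Run EM from (q, p); returns (q, p, loglik, converged)."""
        gz = np.where(called, g, 0).astype(float)
        two_minus = np.where(called, 2.0 - gz, 0.0)
        ll_old = -np.inf
        converged = False
        for _ in range(max_iter):
            p1, p2 = p
            f = q[:, None] * p1 + (1 - q[:, None]) * p2
            f = np.clip(f, _PCLIP, 1 - _PCLIP)
            # copy-level posteriors of cluster-1 origin
            a1 = q[:, None] * p1 / f
            b1 = q[:, None] * (1 - p1) / (1 - f)
            e1 = gz * a1 + two_minus * b1          # expected cluster-1 copies
            ncall = 2.0 * called.sum(axis=1)
            q = np.divide(e1.sum(axis=1), ncall,
                          out=np.full(q.shape, 0.5), where=ncall > 0)
            num1 = (gz * a1).sum(axis=0)
            den1 = e1.sum(axis=0)
            num2 = (gz * (1 - a1)).sum(axis=0)
            den2 = (gz * (1 - a1) + two_minus * (1 - b1)).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p1 = np.where(den1 > 0, num1 / den1, p1)
                p2 = np.where(den2 > 0, num2 / den2, p2)
            p = np.clip(np.vstack([p1, p2]), _PCLIP, 1 - _PCLIP)
            f = q[:, None] * p[0] + (1 - q[:, None]) * p[1]
            f = np.clip(f, _PCLIP, 1 - _PCLIP)
            ll = float((gz * np.log(f) + two_minus * np.log(1 - f))[called].sum())
            if abs(ll - ll_old) < tol:
                converged = True
                ll_old = ll
                break
            ll_old = ll
        return q, p, ll_old, converged

    def fit(self, X, y=None):
        G = _as_geno(X)
        g = G.genotypes
        called = g >= 0
        if not called.any(axis=1).all():
            # individuals with no data get Q = 0.5 and a full-width interval
            pass
        anchor = self.anchor_population or G.pop_labels[0]
        anchor_idx = G.pop_index(anchor)
        # initialize from the labeled populations
        others = np.setdiff1d(np.arange(G.n_individuals), anchor_idx)
        q0 = np.full(G.n_individuals, 0.5)
        q0[anchor_idx] = 0.9
        q0[others] = 0.1

        def pop_freq(idx):
            sub = g[idx]
            c = sub >= 0
            tot = 2 * c.sum(axis=0)
            alt = np.where(c, sub, 0).sum(axis=0)
            return np.divide(alt, tot, out=np.full(g.shape[1], 0.5),
                             where=tot > 0)

        p0 = np.clip(np.vstack([pop_freq(anchor_idx), pop_freq(others)]),
                     _PCLIP, 1 - _PCLIP)
        q, p, ll, conv = self._em(g, called, q0, p0, self.max_iter, self.tol)
        # anchor: cluster 1 is the majority ancestry of the anchor population
        if q[anchor_idx].mean() < 0.5:
            q = 1 - q
            p = p[::-1]
        self.q_, self.p_, self.loglik_, self.converged_ = q, p, ll, conv

        rng = np.random.default_rng(self.random_state)
        f = np.clip(q[:, None] * p[0] + (1 - q[:, None]) * p[1],
                    _PCLIP, 1 - _PCLIP)
        boot = np.empty((self.n_boot, G.n_individuals))
        for r in range(self.n_boot):
            gb = rng.binomial(2, f).astype(np.int8)
            gb[~called] = -1
            qb, pb, _, _ = self._em(gb, called, q.copy(), p.copy(),
                                    200, self.tol)
            if qb[anchor_idx].mean() < 0.5:
                qb = 1 - qb
            boot[r] = qb
        self.q_lo_ = np.minimum(np.quantile(boot, 0.05, axis=0), q)
        self.q_hi_ = np.maximum(np.quantile(boot, 0.95, axis=0), q)
        self.nonhybrid_ = (self.q_lo_ <= self.eps) | (self.q_hi_ >= 1 - self.eps)
        self.samples_ = G.samples
        return self

    def result(self) -> AdmixtureResult:
        return AdmixtureResult(self.samples_, self.q_, self.q_lo_, self.q_hi_,
                               self.nonhybrid_, self.converged_)


def estimate_admixture(G: GenotypeMatrix, K: int = 2, seed: int = 0,
                       **kwargs) -> AdmixtureResult:
    """Thin wrapper: K = 2 admixture proportions with 90% intervals."""
    if K != 2:
        raise ValueError("only K = 2 is supported")
    est = AdmixtureEM(random_state=seed, **kwargs).fit(G)
    return est.result()


@dataclass
class HybridPosterior:
    """Per-individual posterior over the six hybrid categories."""

    samples: np.ndarray
    probs: np.ndarray          # (n, 6), rows sum to 1
    map_category: np.ndarray
    flagged: np.ndarray        # True where no data -> uniform posterior

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(CATEGORIES))
        df.insert(0, "sample", self.samples)
        df["map_category"] = self.map_category
        df["flagged_no_data"] = self.flagged
        return df


def _pair_geno_probs(pD, pT):
    """(3 pairs, 3 genotypes, n_sites) genotype probabilities.

    Pair order (DD, DT, TT); genotype order (0, 1, 2 alt copies).
    """
    L = pD.size
    out = np.empty((3, 3, L))
    out[0] = [(1 - pD) ** 2, 2 * pD * (1 - pD), pD ** 2]
    out[1] = [(1 - pD) * (1 - pT),
              pD * (1 - pT) + (1 - pD) * pT,
              pD * pT]
    out[2] = [(1 - pT) ** 2, 2 * pT * (1 - pT), pT ** 2]
    return out


class HybridClassifier(BaseEstimator):
    """Six-category hybrid-class posterior from genotype-frequency classes.

    Each category c fixes proportions phi_c over per-locus ancestry pairs
    (D,D)/(D,T)/(T,T); the per-locus genotype likelihood is the phi-mixture
    of pair-conditional Hardy-Weinberg-cross probabilities at the parental
    allele frequencies.  Frequencies are initialized from the labeled
    populations and refined by EM (individuals contribute to each gene pool
    in proportion to their posterior expected ancestry).  Category prior is
    uniform.

    Attributes (after fit): ``posterior_`` (n, 6), ``map_category_``,
    ``p_D_``/``p_T_`` parental frequencies, ``flagged_`` (all-missing
    individuals, given a uniform posterior).
    """

    def __init__(self, n_iter: int = 25, tol: float = 1e-8,
                 parental_labels=None, random_state: int = 0):
        self.n_iter = n_iter
        self.tol = tol
        self.parental_labels = parental_labels
        self.random_state = random_state

    def fit(self, X, y=None):
        G = _as_geno(X)
        labels = self.parental_labels or G.pop_labels[:2]
        if len(labels) < 2:
            raise ValueError("both parental gene pools must be represented")
        idx_D, idx_T = G.pop_index(labels[0]), G.pop_index(labels[1])
        g = G.genotypes
        called = g >= 0
        n, L = g.shape

        def pop_freq(idx):
            sub = g[idx]
            c = sub >= 0
            tot = 2 * c.sum(axis=0)
            alt = np.where(c, sub, 0).sum(axis=0)
            return np.divide(alt, tot, out=np.full(L, 0.5), where=tot > 0)

        pD = np.clip(pop_freq(idx_D), _PCLIP, 1 - _PCLIP)
        pT = np.clip(pop_freq(idx_T), _PCLIP, 1 - _PCLIP)

        gz = np.where(called, g, 0)
        ll_old = -np.inf
        for _ in range(self.n_iter):
            pg = _pair_geno_probs(pD, pT)          # (3, 3, L)
            # per (individual, locus, pair): P(g_il | pair)
            like_z = pg[:, gz, np.arange(L)]       # (3, n, L)
            like_z = np.where(called, like_z, 1.0)
            # per-category per-locus likelihood and per-individual loglik
            mix = np.einsum("cz,znl->cnl", PHI, like_z)
            mix = np.clip(mix, 1e-300, None)
            logmix = np.where(called, np.log(mix), 0.0)
            ll_ic = logmix.sum(axis=2).T           # (n, 6)
            m = ll_ic.max(axis=1, keepdims=True)
            post = np.exp(ll_ic - m)
            post /= post.sum(axis=1, keepdims=True)
            ll = float((m[:, 0] + np.log(np.exp(ll_ic - m).sum(axis=1))).sum())

            # E-step over pair origin, weighted by category posteriors:
            # w[z, i, l] = sum_c post[i, c] * phi_cz * P(g|z) / P(g|c)
            w = np.einsum("nc,cz,znl,cnl->znl", post, PHI, like_z, 1.0 / mix)
            # expected alt copies attributed to each pool
            with np.errstate(invalid="ignore", divide="ignore"):
                altD_het = pD * (1 - pT) / (pD * (1 - pT) + (1 - pD) * pT)
            altD_g = np.stack([np.zeros(L), np.broadcast_to(altD_het, (L,)),
                               np.ones(L)])       # (3 genotypes, L)
            aD = altD_g[gz, np.arange(L)]          # (n, L)
            numD = (w[0] * gz + w[1] * aD) * called
            denD = (2 * w[0] + w[1]) * called
            numT = (w[2] * gz + w[1] * (gz - aD)) * called
            denT = (2 * w[2] + w[1]) * called
            with np.errstate(invalid="ignore", divide="ignore"):
                pD_new = numD.sum(axis=0) / denD.sum(axis=0)
                pT_new = numT.sum(axis=0) / denT.sum(axis=0)
            pD = np.clip(np.where(np.isfinite(pD_new), pD_new, pD),
                         _PCLIP, 1 - _PCLIP)
            pT = np.clip(np.where(np.isfinite(pT_new), pT_new, pT),
                         _PCLIP, 1 - _PCLIP)
            if abs(ll - ll_old) < self.tol:
                break
            ll_old = ll

        flagged = ~called.any(axis=1)
        post[flagged] = 1.0 / len(CATEGORIES)
        self.posterior_ = post
        self.map_category_ = np.array([CATEGORIES[k] for k in
                                       post.argmax(axis=1)], dtype=object)
        self.map_category_[flagged] = "unassigned"
        self.flagged_ = flagged
        self.p_D_, self.p_T_ = pD, pT
        self.loglik_ = ll
        self.samples_ = G.samples
        return self

    def predict_proba(self, X=None):
        return self.posterior_

    def predict(self, X=None):
        return self.map_category_

    def result(self) -> HybridPosterior:
        return HybridPosterior(self.samples_, self.posterior_,
                               self.map_category_, self.flagged_)


def classify_hybrids(G: GenotypeMatrix, seed: int = 0, **kwargs) -> HybridPosterior:
    """Thin wrapper over HybridClassifier."""
    est = HybridClassifier(random_state=seed, **kwargs).fit(G)
    return est.result()


def nonhybrid_report(adm: AdmixtureResult, hyb: HybridPosterior) -> pd.DataFrame:
    """Combine both analyses into a per-individual verdict table.

    Disagreements between the two methods are reported (verdict
    "discordant"), not resolved.  The returned frame carries category counts
    in ``.attrs["counts"]``.
    """
    if not np.array_equal(adm.samples, hyb.samples):
        raise ValueError("results cover different sample sets")
    adm_pure = adm.nonhybrid
    hyb_pure = np.isin(hyb.map_category, ("PureD", "PureT"))
    verdict = np.where(adm_pure & hyb_pure, "nonhybrid",
                       np.where(~adm_pure & ~hyb_pure, "hybrid", "discordant"))
    df = pd.DataFrame({
        "sample": adm.samples,
        "Q": adm.q, "Q_lo90": adm.lo, "Q_hi90": adm.hi,
        "admixture_nonhybrid": adm_pure,
        "map_category": hyb.map_category,
        "verdict": verdict,
    })
    df.attrs["counts"] = df["map_category"].value_counts().to_dict()
    df.attrs["n_nonhybrid"] = int((verdict == "nonhybrid").sum())
    df.attrs["n_hybrid"] = int((verdict == "hybrid").sum())
    df.attrs["n_discordant"] = int((verdict == "discordant").sum())
    return df
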