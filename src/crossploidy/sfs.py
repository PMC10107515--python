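"""Joint site-frequency-spectrum demographic inference.

Builds the two-population joint SFS from a genotype matrix (absorbing
missing data by expected-value hypergeometric projection, as in standard
SFS practice), computes expected spectra under four isolation-with-migration
model families with genotype-level inbreeding, fits them by Poisson
composite likelihood with randomly perturbed restarts, quantifies
uncertainty over individual subsamplings, and compares families by AIC.

The expected spectrum reuses the same structured-coalescent engine and the
same inbreeding-distorted genotype sampling as the synthetic-data generator,
so simulation and inference form an internally consistent pair: the branch
weights of pool-frequency configurations are mapped through (i) the
inbreeding genotype-sum distribution of the sampled individuals and (ii) the
hypergeometric projection to the target haploid sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._coalescent import branch_weight_spectrum, epoch_args
from .containers import FAMILY_K, DemographicModel, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "JointSFS", "joint_sfs", "project_sfs", "expected_sfs",
    "composite_loglik", "fit_model", "FitResult",
    "subsample_replicates", "compare_models", "ModelComparison",
]


def _fold_array(S, nD, nT):
    """Fold an (nD+1, nT+1) spectrum onto minor-allele orientation."""
    rev = S[::-1, ::-1]
    i = np.arange(nD + 1)[:, None]
    j = np.arange(nT + 1)[None, :]
    tot = i + j
    half = (nD + nT) / 2.0
    out = np.where(tot < half, S + rev,
                   np.where(tot == half, (S + rev) / 2.0, 0.0))
    return out


@dataclass
class JointSFS:
    """2-D spectrum of segregating-site counts for populations D and T.

    ``data[i, j]`` is the (possibly fractional, after projection) number of
    sites with allele count i in D and j in T; ``n_D``/``n_T`` are haploid
    sample sizes.  The fixed corners (0,0) and (n_D,n_T) are always masked;
    folded spectra additionally mask the non-canonical half.
    """

    data: np.ndarray
    n_D: int
    n_T: int
    folded: bool = False
    stderr: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.n_D + 1, self.n_T + 1):
            raise ValueError("SFS shape does not match sample sizes")

    @property
    def mask(self) -> np.ndarray:
        i = np.arange(self.n_D + 1)[:, None]
        j = np.arange(self.n_T + 1)[None, :]
        m = np.zeros(self.data.shape, dtype=bool)
        m[0, 0] = True
        m[self.n_D, self.n_T] = True
        if self.folded:
            m |= (i + j) > (self.n_D + self.n_T) / 2.0
        return m

    @property
    def total(self) -> float:
        """Total unmasked mass (= number of segregating sites counted)."""
        return float(self.data[~self.mask].sum())

    def fold(self) -> "JointSFS":
        if self.folded:
            return self
        out = _fold_array(self.data, self.n_D, self.n_T)
        err = None
        if self.stderr is not None:
            var = _fold_array(self.stderr ** 2, self.n_D, self.n_T)
            err = np.sqrt(var)
        return JointSFS(out, self.n_D, self.n_T, folded=True, stderr=err)

    def project(self, target) -> "JointSFS":
        return project_sfs(self, target)


@lru_cache(maxsize=None)
def _hyp_kernel(m: int, t: int) -> np.ndarray:
    """(m+1, t+1) matrix K[c, j] = P(j successes in t draws | c of m)."""
    c = np.arange(m + 1)[:, None]
    j = np.arange(t + 1)[None, :]
    return stats.hypergeom.pmf(j, m, c, t)


def project_sfs(S: JointSFS, target) -> JointSFS:
    """Expected-value hypergeometric projection to smaller sample sizes."""
    tD, tT = target
    if tD > S.n_D or tT > S.n_T:
        raise ValueError("projection target exceeds current sample sizes")
    KD = _hyp_kernel(S.n_D, tD)
    KT = _hyp_kernel(S.n_T, tT)
    out = KD.T @ S.data @ KT
    if S.folded:
        out = _fold_array(out, tD, tT)
    err = None
    if S.stderr is not None:
        var = (KD ** 2).T @ S.stderr ** 2 @ (KT ** 2)
        if S.folded:
            var = _fold_array(var, tD, tT)
        err = np.sqrt(var)
    return JointSFS(out, tD, tT, folded=S.folded, stderr=err)


def joint_sfs(G: GenotypeMatrix, pops=None, fold: bool = True,
              project_to=None) -> JointSFS:
    """Joint SFS of a biallelic genotype matrix.

    Without ``project_to``, only sites fully called in both populations are
    tallied at the full haploid sizes.  With ``project_to=(tD, tT)``, each
    site's allele count is redistributed by the product of two hypergeometric
    kernels over its non-missing calls (sites with fewer called haploids
    than the target are dropped), which is the standard way to absorb
    missing data into a fixed-size spectrum.
    """
    labels = pops if pops is not None else G.pop_labels
    if len(labels) != 2:
        raise ValueError("joint_sfs requires exactly two populations")
    idx_D, idx_T = (G.pop_index(l) for l in labels)
    cD, mD = G.allele_counts(idx_D)
    cT, mT = G.allele_counts(idx_T)
    if project_to is None:
        nD, nT = 2 * idx_D.size, 2 * idx_T.size
        S = np.zeros((nD + 1, nT + 1))
        complete = (mD == nD) & (mT == nT)
        np.add.at(S, (cD[complete], cT[complete]), 1.0)
        out = JointSFS(S, nD, nT, folded=False)
    else:
        tD, tT = project_to
        S = np.zeros((tD + 1, tT + 1))
        usable = (mD >= tD) & (mT >= tT)
        cD, mD, cT, mT = cD[usable], mD[usable], cT[usable], mT[usable]
        # group sites by their (called_D, called_T) pattern: within a group
        # the projection is a histogram followed by two kernel products
        for m1, m2 in {(int(x), int(y)) for x, y in zip(mD, mT)}:
            sel = (mD == m1) & (mT == m2)
            H = np.zeros((m1 + 1, m2 + 1))
            np.add.at(H, (cD[sel], cT[sel]), 1.0)
            S += _hyp_kernel(m1, tD).T @ H @ _hyp_kernel(m2, tT)
        out = JointSFS(S, tD, tT, folded=False)
    return out.fold() if fold else out


@lru_cache(maxsize=None)
def _geno_sum_projection(pool: int, n_ind: int, target: int,
                         F: float) -> np.ndarray:
    """(pool+1, target+1) map from pool allele count to projected SFS mass.

    Row a: distribution of the projected allele count after (i) drawing
    n_ind diploid genotypes at frequency a/pool with inbreeding F and (ii)
    hypergeometric projection of their 2*n_ind allele copies to ``target``.
    """
    out = np.empty((pool + 1, target + 1))
    proj = _hyp_kernel(2 * n_ind, target) if 2 * n_ind != target else None
    for a in range(pool + 1):
        p = a / pool
        het = 2 * p * (1 - p) * (1 - F)
        hom_alt = p * p + F * p * (1 - p)
        probs = np.array([1.0 - het - hom_alt, het, hom_alt])
        pmf = np.array([1.0])
        for _ in range(n_ind):
            pmf = np.convolve(pmf, probs)
        out[a] = pmf if proj is None else pmf @ proj
    return out


def expected_sfs(model: DemographicModel, n=(24, 24), n_ind=None,
                 n_trees: int = 4000, pool: int = 100, seed: int = 0,
                 fold: bool = True) -> JointSFS:
    """Expected joint SFS under a demographic model at unit mutation scale.

    Monte-Carlo over ``n_trees`` structured-coalescent genealogies of a
    ``pool``-lineage sample per population; the branch-length weight of each
    pool-frequency configuration is mapped through the inbreeding genotype
    distortion of ``n_ind = (n_ind_D, n_ind_T)`` diploid individuals (default
    n/2 each) and projected to the ``n`` haploid target.  The returned
    spectrum carries a per-cell Monte-Carlo standard error in ``stderr``.
    """
    nD, nT = n
    if n_ind is None:
        if nD % 2 or nT % 2:
            raise ValueError("odd haploid target requires explicit n_ind")
        n_ind = (nD // 2, nT // 2)
    t_rec, t_old, mdr, mtr, mdo, mto = epoch_args(model)
    S1, var_W = branch_weight_spectrum(pool, pool, model.nu_D, model.nu_T,
                                       t_rec, t_old, mdr, mtr, mdo, mto,
                                       n_trees, seed % (2**31 - 1))
    CD = _geno_sum_projection(pool, n_ind[0], nD, round(float(model.F_D), 10))
    CT = _geno_sum_projection(pool, n_ind[1], nT, round(float(model.F_T), 10))
    exp = CD.T @ S1 @ CT
    var = (CD ** 2).T @ var_W @ (CT ** 2)
    out = JointSFS(exp, nD, nT, folded=False, stderr=np.sqrt(var))
    return out.fold() if fold else out


def composite_loglik(data: JointSFS, model_sfs: JointSFS,
                     min_model: float = 1e-12):
    """Poisson composite log-likelihood and its analytic theta scale.

    theta-hat = sum(data)/sum(model) over unmasked cells maximizes the
    Poisson likelihood analytically; model cells that are zero where data is
    positive are floored at ``min_model`` (logged).  Returns (lnL, theta).
    """
    if data.data.shape != model_sfs.data.shape or data.folded != model_sfs.folded:
        raise ValueError("data and model spectra are not comparable")
    keep = ~(data.mask | model_sfs.mask)
    d = data.data[keep]
    m = model_sfs.data[keep].copy()
    bad = (m <= 0) & (d > 0)
    if bad.any():
        logger.info("composite_loglik: flooring %d zero model cells at %g",
                    int(bad.sum()), min_model)
        m[bad] = min_model
    msum = m[m > 0].sum()
    dsum = d.sum()
    if dsum == 0:
        logger.warning("composite_loglik: empty data spectrum (degenerate)")
        return 0.0, 0.0
    theta = dsum / msum
    pos = m > 0
    lam = theta * m[pos]
    lnL = float((d[pos] * np.log(lam) - lam - gammaln(d[pos] + 1)).sum()
                - theta * m[~pos].sum())
    return lnL, float(theta)


_PARAM_NAMES = {
    "constant_gene_flow": ("nu_D", "nu_T", "T0", "M_DT", "M_TD"),
    "historical_gene_flow": ("nu_D", "nu_T", "T0", "T1", "M_DT", "M_TD"),
    "secondary_contact": ("nu_D", "nu_T", "T0", "T1", "M_DT", "M_TD"),
    "no_gene_flow": ("nu_D", "nu_T", "T0"),
}

_DEFAULT_START = {"nu_D": 1.0, "nu_T": 1.0, "T0": 1.0, "T1": 0.5,
                  "M_DT": 1.0, "M_TD": 1.0}

#: optimization bounds (natural scale); search runs in log10 space
_BOUNDS = {"nu_D": (1e-3, 100.0), "nu_T": (1e-3, 100.0),
           "T0": (1e-3, 100.0), "T1": (1e-3, 100.0),
           "M_DT": (1e-4, 50.0), "M_TD": (1e-4, 50.0)}


def _make_model(family, values, F_D, F_T) -> DemographicModel:
    kw = dict(zip(_PARAM_NAMES[family], values))
    return DemographicModel(family=family, F_D=F_D, F_T=F_T, **kw)


def _pattern_search(objective, x0, lo, hi, step0, step_min, max_evals):
    """Greedy coordinate pattern search with halving steps (log10 space).

    Robust to the Monte-Carlo roughness of the composite-likelihood surface:
    moves are only taken between points separated by at least ``step_min``,
    which is kept large relative to the evaluation noise.  Returns
    (x_best, f_best, n_evals).
    """
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    f = objective(x)
    evals = 1
    step = step0
    k = x.size
    while step >= step_min and evals < max_evals:
        improved = False
        for d in range(k):
            for sgn in (1.0, -1.0):
                if evals >= max_evals:
                    break
                xt = x.copy()
                xt[d] = min(max(xt[d] + sgn * step, lo[d]), hi[d])
                if xt[d] == x[d]:
                    continue
                ft = objective(xt)
                evals += 1
                if ft < f:
                    x, f = xt, ft
                    improved = True
                    # accelerate along a successful direction
                    while evals < max_evals:
                        xt = x.copy()
                        xt[d] = min(max(xt[d] + sgn * step, lo[d]), hi[d])
                        if xt[d] == x[d]:
                            break
                        ft = objective(xt)
                        evals += 1
                        if ft < f:
                            x, f = xt, ft
                        else:
                            break
                    break
        if not improved:
            step /= 2.0
    return x, f, evals


@dataclass
class FitResult:
    """Best-restart fit of one model family to one observed spectrum."""

    family: str
    params: dict
    model: DemographicModel
    loglik: float
    theta: float
    k: int
    restarts: pd.DataFrame = field(repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    def to_frame(self) -> pd.DataFrame:
        row = {"family": self.family, **self.params,
               "loglik": self.loglik, "theta": self.theta,
               "k": self.k, "aic": self.aic}
        return pd.DataFrame([row])


def fit_model(data: JointSFS, family: str, F_D: float = 0.81,
              F_T: float = 0.75, n_restarts: int = 99, seed: int = 0,
              n_trees: int = 1000, pool: int = 100, n_ind=None,
              maxfev: int | None = None, refine_trees: int | None = None,
              refine_maxfev: int | None = None) -> FitResult:
    """Fit a model family to an observed joint SFS by composite likelihood.

    Derivative-free bounded coordinate pattern search in log10-parameter
    space from ``n_restarts`` start points, each the default start with
    every parameter multiplied by 2**Uniform(-1, 1).  Inbreeding
    coefficients are fixed, not optimized.  Within a stage every evaluation reuses
    one Monte-Carlo seed (common random numbers), so the objective is a
    deterministic function of the parameters.  The search runs in two
    stages: a coarse pass over all restarts at ``n_trees`` genealogies per
    evaluation, then a short polish from the best restart at
    ``refine_trees`` (default 8x) genealogies, which suppresses the
    Monte-Carlo-noise bias of optimizing a coarse surface.  The reported
    log-likelihood comes from a final evaluation at the refine precision
    with an independent seed.
    """
    names = _PARAM_NAMES[family]
    k = FAMILY_K[family]
    assert k == len(names)
    rng = np.random.default_rng(seed)
    mc_seed = int(rng.integers(0, 2**31 - 1))
    final_seed = int(rng.integers(0, 2**31 - 1))
    lo = np.log10([_BOUNDS[p][0] for p in names])
    hi = np.log10([_BOUNDS[p][1] for p in names])
    x0_default = np.log10([_DEFAULT_START[p] for p in names])

    def objective(x, trees, s):
        values = 10.0 ** np.clip(x, lo, hi)
        model = _make_model(family, values, F_D, F_T)
        exp = expected_sfs(model, n=(data.n_D, data.n_T), n_ind=n_ind,
                           n_trees=trees, pool=pool, seed=s,
                           fold=data.folded)
        return -composite_loglik(data, exp)[0]

    rows = []
    best = None
    nfev_cap = maxfev if maxfev is not None else 50 * k
    for r in range(n_restarts):
        x0 = np.clip(x0_default + rng.uniform(-1, 1, size=k) * np.log10(2.0),
                     lo, hi)
        try:
            x, fval, nfev = _pattern_search(
                lambda x: objective(x, n_trees, mc_seed), x0, lo, hi,
                step0=np.log10(2.0), step_min=0.05, max_evals=nfev_cap)
        except Exception as exc:  # pragma: no cover - defensive
            rows.append({"restart": r, "loglik": np.nan, "nfev": 0,
                         "success": False, "error": str(exc)})
            continue
        rows.append({"restart": r, "loglik": -fval, "nfev": nfev,
                     "success": True, "error": ""})
        if best is None or -fval > best[1]:
            best = (x, -fval)
    restarts = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(
            f"all {n_restarts} restarts failed for {family}:\n{restarts}")
    rtrees = refine_trees if refine_trees is not None else 8 * n_trees
    rfev = refine_maxfev if refine_maxfev is not None else 25 * k
    xr, _, _ = _pattern_search(
        lambda x: objective(x, rtrees, mc_seed + 1), best[0], lo, hi,
        step0=0.1, step_min=0.015, max_evals=rfev)
    values = 10.0 ** np.clip(xr, lo, hi)
    model = _make_model(family, values, F_D, F_T)
    exp = expected_sfs(model, n=(data.n_D, data.n_T), n_ind=n_ind,
                       n_trees=rtrees, pool=pool, seed=final_seed,
                       fold=data.folded)
    lnL, theta = composite_loglik(data, exp)
    return FitResult(family=family, params=dict(zip(names, values)),
                     model=model, loglik=lnL, theta=theta, k=k,
                     restarts=restarts)


def subsample_replicates(G: GenotypeMatrix, n_rep: int = 99, seed: int = 0,
                         n_per_pop=None, target=(24, 24), fold: bool = True,
                         pops=None):
    """Rebuild the projected joint SFS from resampled individual subsets.

    Each replicate draws, per population, a without-replacement subset large
    enough for the target projection (default: target/2 + 3 individuals, a
    margin against per-site missingness), rebuilds the SFS and projects it.
    """
    labels = pops if pops is not None else G.pop_labels
    if len(labels) != 2:
        raise ValueError("subsample_replicates requires two populations")
    rng = np.random.default_rng(seed)
    idx = [G.pop_index(l) for l in labels]
    need = [target[0] // 2 + (target[0] % 2), target[1] // 2 + (target[1] % 2)]
    if n_per_pop is None:
        n_per_pop = [min(idx[i].size, need[i] + 3) for i in range(2)]
    for i in range(2):
        if idx[i].size < need[i]:
            raise ValueError(
                f"population {labels[i]!r} has {idx[i].size} individuals; "
                f"at least {need[i]} are required for projection to {target}")
        if n_per_pop[i] < need[i]:
            raise ValueError("n_per_pop too small for the projection target")
    out = []
    for _ in range(n_rep):
        chosen = np.concatenate([
            rng.choice(idx[0], size=n_per_pop[0], replace=False),
            rng.choice(idx[1], size=n_per_pop[1], replace=False),
        ])
        sub = G.take_individuals(np.sort(chosen))
        rep = joint_sfs(sub, pops=labels, fold=fold, project_to=target)
        rep.subsample_sizes = tuple(n_per_pop)  # diploid counts behind rep
        out.append(rep)
    return out


@dataclass
class ModelComparison:
    """Median AICs per family and Welch t-tests against the best family."""

    aics: dict
    medians: dict
    best_family: str
    tests: pd.DataFrame | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam, med in self.medians.items():
            row = {"family": fam, "median_aic": med, "n_replicates":
                   len(self.aics[fam]), "best": fam == self.best_family}
            if self.tests is not None and fam != self.best_family:
                t = self.tests[self.tests.family == fam]
                row["t"] = float(t["t"].iloc[0])
                row["p"] = float(t["p"].iloc[0])
            rows.append(row)
        return pd.DataFrame(rows)


def compare_models(fits_by_family: dict) -> ModelComparison:
    """Compare families by median AIC over the same replicate set.

    ``fits_by_family`` maps family name to a list of FitResult, one per
    replicate.  The best family has the lowest median AIC; every other
    family's AIC distribution is compared with it by a Welch two-sample
    t-test (t is signed best-minus-other, so negative when the best family
    has lower AIC).  With fewer than 2 replicates only medians are reported.
    """
    aics = {fam: np.array([f.aic for f in fits])
            for fam, fits in fits_by_family.items()}
    n_rep = {len(v) for v in aics.values()}
    if len(n_rep) != 1:
        raise ValueError("families have different replicate counts")
    medians = {fam: float(np.median(v)) for fam, v in aics.items()}
    best = min(medians, key=medians.get)
    if n_rep.pop() < 2:
        return ModelComparison(aics, medians, best, None)
    rows = []
    for fam, v in aics.items():
        if fam == best:
            continue
        a, b = aics[best], v
        if np.array_equal(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            if np.isnan(t):  # zero variance in both, equal means handled above
                t, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else \
                    (-np.inf if np.mean(a) < np.mean(b) else np.inf, 0.0)
        rows.append({"family": fam, "t": float(t), "p": float(p)})
    return ModelComparison(aics, medians, best, pd.DataFrame(rows))
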