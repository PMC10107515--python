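"""Two-deme structured-coalescent engine.

Simulates per-site genealogies of a finite pool of lineages sampled from two
populations (demes) that descend from a single ancestral population of
relative size 1.  Time runs backward in units of 2*N_e generations; the
pair-coalescence rate in a deme of relative size nu is 1/nu and a lineage in
the deme receiving M migrant lineages per generation traces back to the other
deme at rate M.

``branch_weight_spectrum`` accumulates, over many independent genealogies,
the total branch length subtending each (i descendants in deme D, j
descendants in deme T) configuration.  Under the infinite-sites model the
expected number of segregating sites with pool-frequency configuration
(i, j) is proportional to this weight -- a Rao-Blackwellized (every branch
counted, not just one sampled mutation) Monte-Carlo estimate.  Drawing site
configurations i.i.d. from the normalized weights is the matching generative
model (the length-biased mixture over genealogies), used by the synthetic
data generator so that simulation and inference share one engine.

The implementation is O(#events) per genealogy: a lineage's subtended
configuration never changes during its lifetime (only coalescence creates a
new configuration), so each lineage deposits a single birth-to-death
interval into the weight matrix, and deme membership is kept in
swap-remove index lists for O(1) event sampling.

Epoch layout (backward from the present): a recent epoch of length
``t_recent`` with migration rates (``mig_D_rec``, ``mig_T_rec``), an older
epoch of length ``t_old`` with rates (``mig_D_old``, ``mig_T_old``), then the
merged ancestral population until the MRCA.  ``mig_D_*`` is the backward rate
at which a lineage currently in deme D jumps to deme T, i.e. the forward
number of migrants per generation into D.
"""

import numpy as np
from numba import njit

__all__ = ["branch_weight_spectrum", "epoch_args"]


def epoch_args(model):
    """Map a DemographicModel onto the kernel's epoch/rate arguments.

    Returns (t_recent, t_old, mig_D_rec, mig_T_rec, mig_D_old, mig_T_old)
    where mig_D_* is the backward jump rate of a D lineage (= M_TD, migrants
    into D) and mig_T_* that of a T lineage (= M_DT).
    """
    fam = model.family
    if fam == "constant_gene_flow":
        return (0.0, model.T0, 0.0, 0.0, model.M_TD, model.M_DT)
    if fam == "no_gene_flow":
        return (0.0, model.T0, 0.0, 0.0, 0.0, 0.0)
    if fam == "historical_gene_flow":
        # migration only in the older epoch
        return (model.T1, model.T0, 0.0, 0.0, model.M_TD, model.M_DT)
    if fam == "secondary_contact":
        # migration only since renewed contact (recent epoch)
        return (model.T1, model.T0, model.M_TD, model.M_DT, 0.0, 0.0)
    raise ValueError(f"unknown family {fam!r}")


@njit(cache=True)
def _one_tree(kD, kT, nuD, nuT, t_recent, t_old,
              mig_D_rec, mig_T_rec, mig_D_old, mig_T_old,
              a, b, birth, deme, pos, lst0, lst1, W):
    """Simulate one genealogy, adding branch lengths per configuration to W."""
    K = kD + kT
    for i in range(kD):
        a[i] = 1
        b[i] = 0
        birth[i] = 0.0
        deme[i] = 0
        lst0[i] = i
        pos[i] = i
    for i in range(kD, K):
        a[i] = 0
        b[i] = 1
        birth[i] = 0.0
        deme[i] = 1
        lst1[i - kD] = i
        pos[i] = i - kD
    n0 = kD
    n1 = kT
    nxt = K          # next free lineage slot
    t = 0.0          # global (cumulative) time
    # phase 0: recent epoch, 1: older epoch, 2: merged ancestral population
    for phase in range(3):
        if n0 + n1 == 1:
            break
        if phase == 0:
            end = t_recent
            mD = mig_D_rec
            mT = mig_T_rec
        elif phase == 1:
            end = t_recent + t_old
            mD = mig_D_old
            mT = mig_T_old
        else:
            end = np.inf
            # merge demes: append deme-1 lineages onto list 0
            for q in range(n1):
                s = lst1[q]
                lst0[n0 + q] = s
                deme[s] = 0
                pos[s] = n0 + q
            n0 += n1
            n1 = 0
            mD = 0.0
            mT = 0.0
        if end <= t:
            continue
        while n0 + n1 > 1:
            if phase < 2:
                c0 = 0.5 * n0 * (n0 - 1) / nuD
                c1 = 0.5 * n1 * (n1 - 1) / nuT
                rm0 = n0 * mD
                rm1 = n1 * mT
                R = c0 + c1 + rm0 + rm1
            else:
                c0 = 0.5 * n0 * (n0 - 1)
                c1 = 0.0
                rm0 = 0.0
                rm1 = 0.0
                R = c0
            if R <= 0.0:
                t = end
                break
            dt = np.random.exponential(1.0 / R)
            if t + dt >= end:
                t = end
                break
            t += dt
            u = np.random.random() * R
            if u < c0 + c1:
                # coalescence in deme 0 or 1
                if u < c0:
                    m = n0
                else:
                    m = n1
                r1 = np.random.randint(0, m)
                r2 = np.random.randint(0, m - 1)
                if r2 >= r1:
                    r2 += 1
                if u < c0:
                    si = lst0[r1]
                    sj = lst0[r2]
                else:
                    si = lst1[r1]
                    sj = lst1[r2]
                W[a[si], b[si]] += t - birth[si]
                W[a[sj], b[sj]] += t - birth[sj]
                sm = nxt
                nxt += 1
                a[sm] = a[si] + a[sj]
                b[sm] = b[si] + b[sj]
                birth[sm] = t
                if u < c0:
                    # replace slot at r1 with the merged lineage, swap-remove r2
                    lst0[r1] = sm
                    pos[sm] = r1
                    deme[sm] = 0
                    n0 -= 1
                    lst0[r2] = lst0[n0]
                    pos[lst0[r2]] = r2
                else:
                    lst1[r1] = sm
                    pos[sm] = r1
                    deme[sm] = 1
                    n1 -= 1
                    lst1[r2] = lst1[n1]
                    pos[lst1[r2]] = r2
            elif u < c0 + c1 + rm0:
                # a deme-0 lineage jumps to deme 1
                r = np.random.randint(0, n0)
                s = lst0[r]
                n0 -= 1
                lst0[r] = lst0[n0]
                pos[lst0[r]] = r
                lst1[n1] = s
                pos[s] = n1
                deme[s] = 1
                n1 += 1
            else:
                r = np.random.randint(0, n1)
                s = lst1[r]
                n1 -= 1
                lst1[r] = lst1[n1]
                pos[lst1[r]] = r
                lst0[n0] = s
                pos[s] = n0
                deme[s] = 0
                n0 += 1


@njit(cache=True)
def branch_weight_spectrum(kD, kT, nuD, nuT, t_recent, t_old,
                           mig_D_rec, mig_T_rec, mig_D_old, mig_T_old,
                           n_trees, seed, n_batches=16):
    """Per-configuration branch-length weights and their Monte-Carlo error.

    Returns (mean, var_of_mean): mean[i, j] is the across-genealogies mean
    total branch length subtending i-of-kD / j-of-kT configurations;
    var_of_mean its batch-means variance estimate (``n_batches`` batches).
    """
    np.random.seed(seed)
    K = kD + kT
    nslots = 2 * K
    a = np.empty(nslots, np.int64)
    b = np.empty(nslots, np.int64)
    birth = np.empty(nslots, np.float64)
    deme = np.empty(nslots, np.int64)
    pos = np.empty(nslots, np.int64)
    lst0 = np.empty(nslots, np.int64)
    lst1 = np.empty(nslots, np.int64)
    shape = (kD + 1, kT + 1)
    total = np.zeros(shape)
    sum_b = np.zeros(shape)     # running sum of batch means
    sum_b2 = np.zeros(shape)    # running sum of squared batch means
    Wb = np.zeros(shape)
    if n_batches < 2:
        n_batches = 2
    per_batch = max(1, n_trees // n_batches)
    done = 0
    batches = 0
    while done < n_trees:
        m = min(per_batch, n_trees - done)
        Wb[:, :] = 0.0
        for _ in range(m):
            _one_tree(kD, kT, nuD, nuT, t_recent, t_old,
                      mig_D_rec, mig_T_rec, mig_D_old, mig_T_old,
                      a, b, birth, deme, pos, lst0, lst1, Wb)
        done += m
        batches += 1
        bm = Wb / m
        total += Wb
        sum_b += bm
        sum_b2 += bm * bm
    mean = total / done
    mb = sum_b / batches
    var_batch = np.maximum(sum_b2 / batches - mb * mb, 0.0)
    var_mean = var_batch / max(batches - 1, 1)
    return mean, var_mean
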