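"""Synthetic genotype matrices and marker alignments with known truth.

The generator simulates many two-population structured-coalescent
genealogies for a finite pool of lineages per population, accumulates the
branch-length weight of every pool-frequency configuration, and draws each
site's configuration i.i.d. from those normalized weights (the infinite-sites
length-biased mixture over genealogies -- the same spectrum the inference
side uses as its expectation).  The pool frequencies (p_D, p_T) act as the
population allele frequencies, from which individual genotypes are drawn
with inbreeding-distorted Hardy-Weinberg probabilities:

    P(het) = 2 p (1 - p) (1 - F),
    P(hom alt) = p^2 + F p (1 - p),
    P(hom ref) = (1 - p)^2 + F p (1 - p).

Only matrix-segregating sites are retained (resampling until the requested
count is reached), each on its own scaffold, mimicking an unlinked GBS SNP
panel.  Hybrid individuals (F1/F2/backcross) can be injected as positive
controls by per-locus Mendelian gamete sampling from the pure populations.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._coalescent import branch_weight_spectrum, epoch_args
from .containers import DemographicModel, GenotypeMatrix, SimulationConfig, TruthRecord

HYBRID_CATEGORIES = ("F1", "F2", "BC_D", "BC_T")

#: hard cap on resampling rounds when conditioning on segregating sites
RESAMPLE_BUDGET = 60


def genotype_probs(p, F):
    """(P(0), P(1), P(2)) at allele frequency p with inbreeding F (vectorized)."""
    p = np.asarray(p, dtype=float)
    het = 2.0 * p * (1.0 - p) * (1.0 - F)
    hom_alt = p * p + F * p * (1.0 - p)
    hom_ref = 1.0 - het - hom_alt
    return hom_ref, het, hom_alt


def _draw_genotypes(p, F, n_ind, rng):
    """Draw an (n_ind, len(p)) int8 genotype block at frequencies p."""
    p0, p1, _ = genotype_probs(p, F)
    u = rng.random((n_ind, p.size))
    return ((u >= p0).astype(np.int8) + (u >= p0 + p1)).astype(np.int8)


def simulate_genotypes(model: DemographicModel, config: SimulationConfig):
    """Simulate a two-population genotype matrix under `model`.

    Returns (GenotypeMatrix, TruthRecord).  Deterministic given config.seed.
    Raises RuntimeError if the segregating-site budget is exhausted (e.g. a
    parameter corner where almost no site segregates in the sampled
    individuals).
    """
    rng = np.random.default_rng(config.seed)
    k = config.pool_size
    t_rec, t_old, mdr, mtr, mdo, mto = epoch_args(model)
    kseed = int(rng.integers(0, 2**31 - 1))
    W, _ = branch_weight_spectrum(k, k, model.nu_D, model.nu_T, t_rec, t_old,
                                  mdr, mtr, mdo, mto, config.n_trees, kseed)
    flat = W.ravel()
    probs = flat / flat.sum()
    grid_D = (np.arange(flat.size) // (k + 1)) / k
    grid_T = (np.arange(flat.size) % (k + 1)) / k

    kept_gD, kept_gT, kept_pD, kept_pT = [], [], [], []
    n_kept = 0
    for round_ in range(RESAMPLE_BUDGET):
        batch = max(32, int(1.3 * (config.n_sites - n_kept)) + 8)
        cells = rng.choice(flat.size, size=batch, p=probs)
        pD = grid_D[cells]
        pT = grid_T[cells]
        gD = _draw_genotypes(pD, model.F_D, config.n_D, rng)
        gT = _draw_genotypes(pT, model.F_T, config.n_T, rng)
        alt_total = gD.sum(axis=0) + gT.sum(axis=0)
        seg = (alt_total > 0) & (alt_total < 2 * (config.n_D + config.n_T))
        if seg.any():
            kept_gD.append(gD[:, seg])
            kept_gT.append(gT[:, seg])
            kept_pD.append(pD[seg])
            kept_pT.append(pT[seg])
            n_kept += int(seg.sum())
        if n_kept >= config.n_sites:
            break
    else:
        raise RuntimeError(
            f"could not obtain {config.n_sites} segregating sites within "
            f"{RESAMPLE_BUDGET} resampling rounds ({n_kept} found); the model "
            "may be a non-segregating corner"
        )

    gD = np.concatenate(kept_gD, axis=1)[:, :config.n_sites]
    gT = np.concatenate(kept_gT, axis=1)[:, :config.n_sites]
    pD = np.concatenate(kept_pD)[:config.n_sites]
    pT = np.concatenate(kept_pT)[:config.n_sites]

    genotypes = np.vstack([gD, gT])
    samples = [f"D_{i:03d}" for i in range(config.n_D)] + \
              [f"T_{i:03d}" for i in range(config.n_T)]
    populations = ["D"] * config.n_D + ["T"] * config.n_T
    scaffolds = [f"scaffold_{i + 1:05d}" for i in range(config.n_sites)]
    positions = rng.integers(1, 100_000, size=config.n_sites)
    G = GenotypeMatrix(genotypes, samples, populations, scaffolds, positions)
    truth = TruthRecord(
        model=model, freq_D=pD, freq_T=pT,
        categories=np.array(["PureD"] * config.n_D + ["PureT"] * config.n_T,
                            dtype=object),
    )
    return G, truth


def _gamete_from_pop(pop_genos, freqs, rng):
    """One haploid gamete per locus, each from a randomly chosen individual.

    Loci where the chosen parent has a missing call fall back to a draw from
    the population allele frequency.
    """
    n_pop, n_loci = pop_genos.shape
    parent = rng.integers(0, n_pop, size=n_loci)
    g = pop_genos[parent, np.arange(n_loci)].astype(float)
    miss = g < 0
    prob = np.where(miss, freqs, g / 2.0)
    return (rng.random(n_loci) < prob).astype(np.int8)


def inject_hybrids(G: GenotypeMatrix, truth: TruthRecord, counts: dict, seed: int):
    """Append hybrid individuals drawn by Mendelian gamete sampling.

    counts maps category in {"F1", "F2", "BC_D", "BC_T"} to the number of
    individuals to add.  An F1 receives one gamete from each pure population;
    an F2 gamete has D/T origin with probability 1/2 each; a backcross pairs
    an F1 gamete with a pure-parent gamete.  Returns a new
    (GenotypeMatrix, TruthRecord); the inputs are not modified.
    """
    bad = set(counts) - set(HYBRID_CATEGORIES)
    if bad:
        raise ValueError(f"unknown hybrid categories: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    pops = list(G.pop_labels)
    if len(pops) < 2:
        raise ValueError("hybrid injection needs two parental populations")
    lab_D, lab_T = pops[0], pops[1]
    idx_D, idx_T = G.pop_index(lab_D), G.pop_index(lab_T)
    gen_D = G.genotypes[idx_D]
    gen_T = G.genotypes[idx_T]
    n_loci = G.n_sites

    def pop_freq(gen):
        called = gen >= 0
        tot = 2 * called.sum(axis=0)
        alt = np.where(called, gen, 0).sum(axis=0)
        return np.divide(alt, tot, out=np.full(n_loci, 0.5), where=tot > 0)

    f_D, f_T = pop_freq(gen_D), pop_freq(gen_T)

    def gamete(origin):
        if origin == "D":
            return _gamete_from_pop(gen_D, f_D, rng)
        return _gamete_from_pop(gen_T, f_T, rng)

    def f1_gamete():
        # one allele per locus from an F1: D- or T-origin with prob 1/2
        pick_D = rng.random(n_loci) < 0.5
        return np.where(pick_D, gamete("D"), gamete("T")).astype(np.int8)

    new_rows, new_names, new_pops, new_cats = [], [], [], []
    for cat in HYBRID_CATEGORIES:
        for r in range(counts.get(cat, 0)):
            if cat == "F1":
                geno = gamete("D") + gamete("T")
            elif cat == "F2":
                geno = f1_gamete() + f1_gamete()
            elif cat == "BC_D":
                geno = f1_gamete() + gamete("D")
            else:  # BC_T
                geno = f1_gamete() + gamete("T")
            new_rows.append(geno)
            new_names.append(f"{cat}_{r:03d}")
            new_pops.append(cat)
            new_cats.append(cat)

    if not new_rows:
        return G, truth
    genotypes = np.vstack([G.genotypes, np.array(new_rows, dtype=np.int8)])
    G2 = GenotypeMatrix(
        genotypes,
        np.concatenate([G.samples, new_names]),
        np.concatenate([G.populations, new_pops]),
        G.scaffolds, G.positions, G.ref, G.alt,
    )
    truth2 = TruthRecord(
        model=truth.model, freq_D=truth.freq_D, freq_T=truth.freq_T,
        categories=np.concatenate([truth.categories, new_cats]),
    )
    return G2, truth2


def apply_missingness(G: GenotypeMatrix, config: SimulationConfig, seed: int):
    """Mask calls independently; combined rate = 1 - (1-site)(1-indiv)."""
    rate = 1.0 - (1.0 - config.site_missing_rate) * (1.0 - config.indiv_missing_rate)
    if rate == 0.0:
        return G
    rng = np.random.default_rng(seed)
    mask = rng.random(G.genotypes.shape) < rate
    genotypes = np.where(mask, np.int8(-1), G.genotypes)
    return GenotypeMatrix(genotypes, G.samples, G.populations, G.scaffolds,
                          G.positions, G.ref, G.alt)


_BASES = np.array(list("ACGT"))


def simulate_marker_alignment(n_D, n_T, length, n_fixed_diffs, singleton_rate,
                              seed) -> MultipleSeqAlignment:
    """Synthetic marker alignment (e.g. ITS-like) for two groups.

    Exactly ``n_fixed_diffs`` columns are fixed-different between groups,
    Poisson(singleton_rate * length) columns carry a single-sequence variant,
    and all remaining columns are invariant.  Group membership is encoded in
    the record ids (``D_*`` / ``T_*``).
    """
    if n_fixed_diffs > length:
        raise ValueError("n_fixed_diffs cannot exceed the alignment length")
    rng = np.random.default_rng(seed)
    base_idx = rng.integers(0, 4, size=length)
    mat = np.tile(_BASES[base_idx], (n_D + n_T, 1))
    cols = rng.permutation(length)
    fixed_cols = cols[:n_fixed_diffs]
    free_cols = cols[n_fixed_diffs:]
    for c in fixed_cols:
        alt = _BASES[(base_idx[c] + rng.integers(1, 4)) % 4]
        mat[n_D:, c] = alt  # T group carries the alternative state

    n_single = rng.poisson(singleton_rate * length)
    if n_single > 0:
        if n_single > free_cols.size:
            raise ValueError(
                f"impossible column budget: {n_single} singleton columns "
                f"requested but only {free_cols.size} invariant columns remain"
            )
        # place singletons in groups of size >= 2 so they never create an
        # extra fixed difference
        eligible = []
        if n_D >= 2:
            eligible.extend(range(n_D))
        if n_T >= 2:
            eligible.extend(range(n_D, n_D + n_T))
        if not eligible:
            raise ValueError("singletons need at least one group of size >= 2")
        eligible = np.array(eligible)
        for c in free_cols[:n_single]:
            row = eligible[rng.integers(0, eligible.size)]
            mat[row, c] = _BASES[(base_idx[c] + rng.integers(1, 4)) % 4]

    records = []
    for i in range(n_D + n_T):
        name = f"D_{i:03d}" if i < n_D else f"T_{i - n_D:03d}"
        records.append(SeqRecord(Seq("".join(mat[i])), id=name, description=""))
    return MultipleSeqAlignment(records)
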