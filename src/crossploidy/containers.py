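"""Core data containers shared across the pipeline.

Genotypes are diploid alt-allele dosages in {0, 1, 2}, with -1 for missing
calls.  The tetraploid population is represented by diploid calls throughout:
only the subgenome conserved between ploidy levels is analysed, and variants
there are assumed disomically inherited, so GBS-style genotype calls are
diploid-coded for both species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

MODEL_FAMILIES = (
    "constant_gene_flow",
    "historical_gene_flow",
    "secondary_contact",
    "no_gene_flow",
)

#: number of free parameters per model family (inbreeding is fixed, not fitted)
FAMILY_K = {
    "constant_gene_flow": 5,
    "historical_gene_flow": 6,
    "secondary_contact": 6,
    "no_gene_flow": 3,
}

#: families with a two-epoch history (older epoch T0, then recent epoch T1)
TWO_EPOCH_FAMILIES = ("historical_gene_flow", "secondary_contact")


@dataclass(frozen=True)
class DemographicModel:
    """An isolation-with-migration history for a diploid/tetraploid pair.

    One ancestral population of effective size N_e = 1 splits into a diploid
    population (D) and a tetraploid population (T).  Sizes ``nu_D``/``nu_T``
    are present-day sizes relative to the ancestral N_e; times are in
    coalescent units of 2*N_e generations; ``M_DT`` is the number of migrant
    lineages per generation into T from D (M = 2*N_e*m) and ``M_TD`` the
    reverse.  ``F_D``/``F_T`` are inbreeding coefficients applied at the
    genotype-sampling stage (excess homozygosity).

    Families
    --------
    constant_gene_flow
        single epoch of length T0 with migration throughout.
    historical_gene_flow
        migration during the older epoch T0, none in the recent epoch T1.
    secondary_contact
        no migration during T0, migration resumes in the recent epoch T1.
    no_gene_flow
        single epoch of length T0, no migration.
    """

    family: str
    nu_D: float = 1.0
    nu_T: float = 1.0
    T0: float = 1.0
    T1: float | None = None
    M_DT: float = 0.0
    M_TD: float = 0.0
    F_D: float = 0.0
    F_T: float = 0.0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; expected one of {MODEL_FAMILIES}"
            )
        if self.nu_D <= 0 or self.nu_T <= 0 or self.T0 <= 0:
            raise ValueError("population sizes and times must be > 0")
        if self.M_DT < 0 or self.M_TD < 0:
            raise ValueError("migration rates must be >= 0")
        for f, name in ((self.F_D, "F_D"), (self.F_T, "F_T")):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.family in TWO_EPOCH_FAMILIES:
            if self.T1 is None or self.T1 <= 0:
                raise ValueError(f"{self.family} requires T1 > 0")
        else:
            if self.T1 is not None:
                raise ValueError(f"{self.family} has no T1 epoch")
        if self.family == "no_gene_flow" and (self.M_DT != 0 or self.M_TD != 0):
            raise ValueError("no_gene_flow requires M_DT = M_TD = 0")

    @property
    def k(self) -> int:
        return FAMILY_K[self.family]

    def with_params(self, **kwargs) -> "DemographicModel":
        return replace(self, **kwargs)


@dataclass
class SimulationConfig:
    """Size/missingness settings for a synthetic genotype matrix."""

    n_D: int = 45
    n_T: int = 50
    n_sites: int = 356
    site_missing_rate: float = 0.0
    indiv_missing_rate: float = 0.0
    seed: int = 0
    pool_size: int = 100  # haploid lineages per population realizing frequencies
    n_trees: int = 4000   # genealogies behind the site-configuration spectrum

    def __post_init__(self):
        if self.n_D < 2 or self.n_T < 2:
            raise ValueError("each population needs at least 2 individuals")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for r in (self.site_missing_rate, self.indiv_missing_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("missingness rates must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth carried alongside a simulated genotype matrix."""

    model: DemographicModel
    freq_D: np.ndarray  # realized per-site allele frequency in the D gene pool
    freq_T: np.ndarray
    categories: np.ndarray  # per-individual label: PureD/PureT/F1/F2/BC_D/BC_T

    def __post_init__(self):
        self.categories = np.asarray(self.categories, dtype=object)


class GenotypeMatrix:
    """Individuals x biallelic-sites genotype table with site/sample metadata.

    Parameters
    ----------
    genotypes : array (n_individuals, n_sites) of int
        Alt-allele dosages 0/1/2; -1 marks a missing call.
    samples : sequence of sample identifiers.
    populations : sequence of population labels, one per individual.
    scaffolds : sequence of scaffold ids, one per site.
    positions : 1-based positions, one per site.
    ref, alt : optional per-site alleles (defaults A/T).
    """

    def __init__(self, genotypes, samples, populations, scaffolds, positions,
                 ref=None, alt=None):
        g = np.asarray(genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x sites)")
        n, s = g.shape
        if not np.isin(g, [-1, 0, 1, 2]).all():
            raise ValueError("genotype calls must be in {-1, 0, 1, 2}")
        self.genotypes = g
        self.samples = np.asarray(samples, dtype=object)
        self.populations = np.asarray(populations, dtype=object)
        self.scaffolds = np.asarray(scaffolds, dtype=object)
        self.positions = np.asarray(positions, dtype=np.int64)
        if len(self.samples) != n or len(self.populations) != n:
            raise ValueError("sample metadata length mismatch")
        if len(self.scaffolds) != s or len(self.positions) != s:
            raise ValueError("site metadata length mismatch")
        self.ref = np.asarray(ref if ref is not None else ["A"] * s, dtype=object)
        self.alt = np.asarray(alt if alt is not None else ["T"] * s, dtype=object)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def pop_labels(self):
        """Distinct population labels in order of first appearance."""
        seen = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def pop_index(self, label) -> np.ndarray:
        idx = np.flatnonzero(self.populations == label)
        if idx.size == 0:
            raise KeyError(f"no individuals in population {label!r}")
        return idx

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx], self.samples, self.populations,
            self.scaffolds[idx], self.positions[idx],
            self.ref[idx], self.alt[idx],
        )

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[idx], self.samples[idx], self.populations[idx],
            self.scaffolds, self.positions, self.ref, self.alt,
        )

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def allele_counts(self, idx=None):
        """(alt-allele count, called-haploid count) per site over individuals idx."""
        g = self.genotypes if idx is None else self.genotypes[idx]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0)

    def __eq__(self, other):
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.samples, other.samples)
            and np.array_equal(self.populations, other.populations)
            and np.array_equal(self.scaffolds, other.scaffolds)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
        )

    def __repr__(self):
        return (f"GenotypeMatrix({self.n_individuals} individuals x "
                f"{self.n_sites} sites, pops={self.pop_labels})")
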