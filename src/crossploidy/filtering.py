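"""Variant-matrix reduction to an analysis set of unlinked, variable sites.

The full chain mirrors a GBS workflow: drop sites with excessive missing
data, drop near-empty individuals, keep only sites on a conserved-scaffold
whitelist, remove invariant sites, and thin to one variant per scaffold.
Threshold comparisons are strict (a site missing in exactly the threshold
fraction is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


@dataclass
class FilterReport:
    """Per-stage site/individual counts, in application order."""

    stages: list = field(default_factory=list)  # (name, n_individuals, n_sites)
    warnings: list = field(default_factory=list)

    def record(self, name: str, G: GenotypeMatrix):
        self.stages.append((name, G.n_individuals, G.n_sites))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages,
                            columns=["stage", "n_individuals", "n_sites"])

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_sites_by_missingness(G: GenotypeMatrix, max_missing: float = 0.5):
    """Remove sites whose missing fraction is strictly greater than max_missing."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    frac = G.missing_mask().mean(axis=0)
    return G.take_sites(np.flatnonzero(frac <= max_missing))


def filter_individuals_by_missingness(G: GenotypeMatrix, max_missing: float = 0.75):
    """Remove individuals whose missing fraction is strictly greater than max_missing."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    frac = G.missing_mask().mean(axis=1)
    return G.take_individuals(np.flatnonzero(frac <= max_missing))


def subset_scaffolds(G: GenotypeMatrix, conserved, report: FilterReport | None = None):
    """Keep only sites on the conserved-scaffold whitelist (order preserved)."""
    conserved = set(conserved)
    if not conserved:
        raise ValueError("conserved scaffold set must be nonempty")
    keep = np.flatnonzero([sc in conserved for sc in G.scaffolds])
    if keep.size == 0 and report is not None:
        report.warnings.append(
            "subset_scaffolds: no sites on the conserved scaffold set")
    return G.take_sites(keep)


def remove_invariant(G: GenotypeMatrix):
    """Drop sites whose minor-allele count over non-missing calls is zero."""
    alt, called = G.allele_counts()
    variable = (alt > 0) & (alt < called)
    return G.take_sites(np.flatnonzero(variable))


def prune_one_per_scaffold(G: GenotypeMatrix):
    """Keep one site per scaffold: the lowest position, ties by input order."""
    order = np.lexsort((np.arange(G.n_sites), G.positions))
    seen = set()
    keep = []
    for j in order:
        sc = G.scaffolds[j]
        if sc not in seen:
            seen.add(sc)
            keep.append(j)
    return G.take_sites(np.sort(keep))


def filter_chain(G: GenotypeMatrix, conserved=None, max_site_missing: float = 0.5,
                 max_indiv_missing: float = 0.75):
    """Full reduction in the fixed order: site missingness -> individual
    missingness -> scaffold subset -> invariant removal -> per-scaffold
    pruning.  Returns (GenotypeMatrix, FilterReport)."""
    report = FilterReport()
    report.record("input", G)
    G = filter_sites_by_missingness(G, max_site_missing)
    report.record("site_missingness", G)
    G = filter_individuals_by_missingness(G, max_indiv_missing)
    report.record("individual_missingness", G)
    if conserved is not None:
        G = subset_scaffolds(G, conserved, report)
        report.record("conserved_scaffolds", G)
    G = remove_invariant(G)
    report.record("invariant_removal", G)
    G = prune_one_per_scaffold(G)
    report.record("one_per_scaffold", G)
    return G, report


def read_scaffold_list(path):
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
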