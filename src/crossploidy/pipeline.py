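"""End-to-end orchestration: one config, one output bundle.

A run either simulates a dataset (with known truth) or loads user VCF/FASTA
inputs, then executes filtering -> differentiation statistics -> hybrid
assignment -> SFS demographic inference (-> alignment summaries when an
alignment is present), writing tab-separated result tables, a
machine-readable summary.json (including the master seed and a config hash)
and a per-stage status log.  All randomness is funnelled through a single
master seed.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment as aln_mod
from . import filtering, hybrids, io, popgen, sfs, simulate
from .containers import DemographicModel, SimulationConfig


@dataclass
class RunConfig:
    """Validated run configuration (see `from_dict`)."""

    outdir: str
    seed: int = 0
    input_vcf: str | None = None
    input_popmap: str | None = None
    input_alignment: str | None = None
    simulation: dict | None = None
    filters: dict = field(default_factory=dict)
    analyses: dict = field(default_factory=dict)

    def __post_init__(self):
        has_input = self.input_vcf is not None
        has_sim = self.simulation is not None
        if has_input == has_sim:
            raise ValueError(
                "config must provide exactly one of an input VCF or a "
                "simulation block")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        inp = d.get("input", {}) or {}
        return cls(
            outdir=d["outdir"], seed=int(d.get("seed", 0)),
            input_vcf=inp.get("vcf"), input_popmap=inp.get("popmap"),
            input_alignment=inp.get("alignment"),
            simulation=d.get("simulate"),
            filters=d.get("filters", {}) or {},
            analyses=d.get("analyses", {}) or {},
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _simulate_dataset(cfg: RunConfig, outdir: Path):
    block = dict(cfg.simulation)
    model_kw = dict(block.pop("model", {}) or {})
    model_kw.setdefault("family", "constant_gene_flow")
    hybrids_kw = block.pop("hybrids", {}) or {}
    model = DemographicModel(**model_kw)
    sim_cfg = SimulationConfig(seed=cfg.seed, **block)
    G, truth = simulate.simulate_genotypes(model, sim_cfg)
    if hybrids_kw:
        G, truth = simulate.inject_hybrids(G, truth, hybrids_kw,
                                           seed=cfg.seed + 1)
    G = simulate.apply_missingness(G, sim_cfg, seed=cfg.seed + 2)
    io.write_vcf(G, outdir / "simulated.vcf")
    io.write_popmap(G, outdir / "simulated.popmap.tsv")
    io.write_truth(truth, outdir / "truth.tsv")
    return G, truth


def run(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns a machine-readable summary dict.

    Stage failures are recorded (with tracebacks in stages.log) and abort
    only the stages that depend on them; the summary's ``ok`` flag is False
    if any stage failed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    status = {}
    summary = {"seed": seed, "config_hash": _config_hash(cfg), "results": {}}
    log_lines = []

    def stage(name, fn, *deps):
        if any(status.get(d) != "ok" for d in deps):
            status[name] = "skipped"
            log_lines.append(f"{name}: skipped (failed dependency)")
            return None
        try:
            out = fn()
            status[name] = "ok"
            log_lines.append(f"{name}: ok")
            return out
        except Exception as exc:
            status[name] = "failed"
            log_lines.append(f"{name}: FAILED: {exc}\n{traceback.format_exc()}")
            return None

    truth = None

    def load():
        nonlocal truth
        if cfg.simulation is not None:
            G, truth = _simulate_dataset(cfg, outdir)
            return G
        return io.read_vcf(cfg.input_vcf, popmap=cfg.input_popmap)

    G = stage("load", load)

    def do_filter():
        Gf, report = filtering.filter_chain(
            G,
            conserved=cfg.filters.get("conserved_scaffolds"),
            max_site_missing=cfg.filters.get("max_site_missing", 0.5),
            max_indiv_missing=cfg.filters.get("max_indiv_missing", 0.75),
        )
        report.to_tsv(outdir / "filter_report.tsv")
        summary["results"]["n_sites"] = Gf.n_sites
        summary["results"]["n_individuals"] = Gf.n_individuals
        return Gf

    Gf = stage("filter", do_filter, "load")

    def do_fst():
        # differentiation is always between the two parental populations,
        # even when injected hybrid individuals carry their own label
        res = popgen.fst_profile(Gf, pops=Gf.pop_labels[:2])
        res.to_frame().to_csv(outdir / "fst_per_site.tsv", sep="\t",
                              index=False)
        res.histogram.to_csv(outdir / "fst_histogram.tsv", sep="\t",
                             index=False)
        summary["results"]["global_fst_mean"] = res.global_mean
        summary["results"]["global_fst_ratio"] = res.global_ratio
        return res

    stage("fst", do_fst, "filter")

    def do_amova():
        n_perm = int(cfg.analyses.get("n_permutations", 9999))
        res = popgen.amova_snp(Gf, n_perm=n_perm, seed=seed + 10)
        res.to_frame().to_csv(outdir / "amova_snp.tsv", sep="\t", index=False)
        summary["results"]["amova_pct_among"] = res.pct_among
        summary["results"]["amova_p"] = res.p_value
        return res

    stage("amova", do_amova, "filter")

    def do_pca():
        res = popgen.pca_mean_impute(Gf, scale=cfg.analyses.get("pca_scale",
                                                                False))
        res.to_frame(Gf.samples).to_csv(outdir / "pca_coordinates.tsv",
                                        sep="\t", index=False)
        summary["results"]["pc1_pct"] = float(res.explained_pct[0])
        return res

    stage("pca", do_pca, "filter")

    def do_admixture():
        res = hybrids.estimate_admixture(
            Gf, seed=seed + 20,
            n_boot=int(cfg.analyses.get("n_boot", 200)))
        res.to_frame().to_csv(outdir / "admixture_q.tsv", sep="\t",
                              index=False)
        summary["results"]["n_admixture_nonhybrid"] = int(res.nonhybrid.sum())
        return res

    adm = stage("admixture", do_admixture, "filter")

    def do_classify():
        res = hybrids.classify_hybrids(Gf, seed=seed + 21)
        res.to_frame().to_csv(outdir / "hybrid_posterior.tsv", sep="\t",
                              index=False)
        return res

    hyb = stage("classify", do_classify, "filter")

    def do_report():
        df = hybrids.nonhybrid_report(adm, hyb)
        df.to_csv(outdir / "nonhybrid_report.tsv", sep="\t", index=False)
        summary["results"]["category_counts"] = df.attrs["counts"]
        summary["results"]["n_nonhybrid"] = df.attrs["n_nonhybrid"]
        if truth is not None:
            truth_cats = np.asarray(truth.categories)
            if truth_cats.size == len(df):
                pred = df["map_category"].to_numpy()
                summary["results"]["map_accuracy"] = float(
                    np.mean(pred == truth_cats))
        return df

    stage("nonhybrid_report", do_report, "admixture", "classify")

    def do_demography():
        a = cfg.analyses
        target = tuple(a.get("sfs_target", (24, 24)))
        families = a.get("families", list(sfs._PARAM_NAMES))
        n_rep = int(a.get("n_replicates", 3))
        n_restarts = int(a.get("n_restarts", 3))
        n_trees = int(a.get("n_trees", 1000))
        F_D = float(a.get("F_D", 0.81))
        F_T = float(a.get("F_T", 0.75))
        reps = sfs.subsample_replicates(Gf, n_rep=n_rep, seed=seed + 30,
                                        target=target,
                                        pops=Gf.pop_labels[:2])
        io.write_sfs(reps[0], outdir / "joint_sfs_rep0.txt")
        fits = {fam: [] for fam in families}
        for i, rep in enumerate(reps):
            for fam in families:
                fits[fam].append(sfs.fit_model(
                    rep, fam, F_D=F_D, F_T=F_T, n_restarts=n_restarts,
                    seed=seed + 1000 + i, n_trees=n_trees,
                    n_ind=getattr(rep, "subsample_sizes", None)))
        comp = sfs.compare_models(fits)
        comp.to_frame().to_csv(outdir / "model_comparison.tsv", sep="\t",
                               index=False)
        rows = [f.to_frame().assign(replicate=i)
                for fam, fl in fits.items() for i, f in enumerate(fl)]
        pd.concat(rows).to_csv(outdir / "fit_results.tsv", sep="\t",
                               index=False)
        summary["results"]["best_family"] = comp.best_family
        summary["results"]["median_aic"] = comp.medians
        return comp

    if cfg.analyses.get("demography", True):
        stage("demography", do_demography, "filter")

    if cfg.input_alignment or cfg.analyses.get("simulate_alignment"):
        def do_alignment():
            if cfg.input_alignment:
                a = io.read_fasta(cfg.input_alignment)
            else:
                kw = dict(cfg.analyses.get("simulate_alignment"))
                a = simulate.simulate_marker_alignment(seed=seed + 40, **kw)
                io.write_fasta(a, outdir / "alignment.fasta")
            summ = aln_mod.alignment_summary(a)
            summ.to_frame().to_csv(outdir / "alignment_summary.tsv",
                                   sep="\t", index=False)
            D = aln_mod.pairwise_distance(a)
            groups = aln_mod.alignment_groups_vector(a)
            res = popgen.amova(D, groups, n_perm=int(
                cfg.analyses.get("n_permutations", 9999)),
                seed=seed + 41, distance="hamming")
            res.to_frame().to_csv(outdir / "amova_alignment.tsv", sep="\t",
                                  index=False)
            summary["results"]["alignment_fixed_diffs"] = summ.n_fixed_diff
            summary["results"]["alignment_amova_pct_among"] = res.pct_among
            return summ

        stage("alignment", do_alignment)

    summary["stages"] = status
    summary["ok"] = all(v == "ok" for v in status.values())
    (outdir / "stages.log").write_text("\n".join(log_lines) + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
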