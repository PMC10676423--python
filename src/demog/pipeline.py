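"""End-to-end orchestration: simulate -> het -> prune -> sfs -> fit /
stairway -> haplonet from a single JSON config, with per-stage sub-seeds
derived from the global seed by a fixed counter scheme so stages can be
re-run in isolation and whole runs are byte-reproducible."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import coalescent_sim as cs
from . import demographic_inference as di
from . import diversity_structure as ds
from . import genotype_io as gio
from . import sfs_builder as sb
from . import stairway_estimator as se
from . import haplotype_network as hn

logger = logging.getLogger("demog")

__all__ = ["stage_seed", "run_pipeline", "DEFAULT_MODEL1_TRUTH", "DEFAULT_MODEL2_TRUTH"]

# Stage order fixes the sub-seed counter: sub-seed = (global_seed * 1000 +
# index) mod 2^31-1.
_STAGES = ("simulate", "het", "prune", "sfs", "fit", "bootstrap", "stairway", "haplonet")

# Generating parameter values used by the built-in synthetic study.  TDIV of
# the ancient-divergence truth equals the study's point estimate (32,792
# years at two years per generation); the remaining magnitudes are plausible
# for a glacial-relict herb: large glacial sizes, a recent ~10x crash in the
# Mt. Ibuki-like lineage (~350 years ago) and a mid-Holocene decline in the
# Hokkaido-like lineage (~5,000 years ago).
DEFAULT_MODEL1_TRUTH = {
    "N1CUR": 2_000.0,
    "N1ANC": 40_000.0,
    "T1": 175.0,
    "N2CUR": 1_000.0,
    "N2ANC": 20_000.0,
    "T2": 2_500.0,
    "NANC": 40_000.0,
    "TDIV": 16_396.0,
}
# Recent introduction: founded ~150 years ago from the (already crashed)
# Mt. Ibuki lineage through a small founder population.
DEFAULT_MODEL2_TRUTH = {
    "N1CUR": 2_000.0,
    "N2CUR": 300.0,
    "TDIV": 75.0,
    "NANCMID": 2_000.0,
    "TANC": 175.0,
    "NANCOLD": 40_000.0,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1000 + _STAGES.index(stage)) % (2**31 - 1)


def _model_from_config(block: dict) -> tuple[di.ModelSpec, dict]:
    name = block.get("model", "model1")
    if name == "model1":
        spec = di.model1_spec(block.get("ranges"))
        truth = dict(DEFAULT_MODEL1_TRUTH)
    elif name == "model2":
        spec = di.model2_spec(block.get("ranges"))
        truth = dict(DEFAULT_MODEL2_TRUTH)
    else:
        raise ValueError(f"unknown model {name!r}")
    truth.update(block.get("params", {}))
    return spec, truth


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Run the configured stages; write stage outputs and summary.json
    under outdir; return the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", {})
    summary: dict = {"seed": seed, "stages": [s for s, on in stages.items() if on]}

    G = pm = None
    if stages.get("simulate"):
        blk = cfg.get("simulate", {})
        spec, truth = _model_from_config(blk)
        model = spec.build(truth)
        sample = cs.SampleConfig(
            n1=int(blk.get("n1", 67)),
            n2=int(blk.get("n2", 10)),
            n_snps=int(blk.get("snps", 766)),
            missingness=float(blk.get("missing", 0.163)),
            seed=stage_seed(seed, "simulate"),
        )
        G, pm = cs.simulate_dataset(model, sample)
        gio.write_vcf(G, outdir / "simulated.vcf")
        gio.write_popmap(pm, outdir / "popmap.tsv")
        # the surveyed-site count a real assay would report alongside the
        # SNP panel; gives downstream fits their absolute time/size scale
        mu = gio.ScalingConfig().mu
        mut_opp = cs.implied_mutation_opportunity(
            model, sample, G.n_sites, mu, seed=stage_seed(seed, "simulate")
        )
        (outdir / "truth.json").write_text(
            json.dumps({**truth, "mutation_opportunity": mut_opp}, indent=1)
        )
        summary["simulate"] = {
            "n_snps": G.n_sites,
            "model": spec.name,
            "truth": truth,
            "mutation_opportunity": mut_opp,
        }
    elif "vcf" in cfg:
        G = gio.read_vcf(cfg["vcf"])
        pm = gio.read_popmap(cfg["popmap"])

    if stages.get("het"):
        het = ds.heterozygosity_proportion(G)
        rows = [f"{ind}\t{pm.labels.get(ind, 'NA')}\t{h:.6f}" for ind, h in het.items()]
        (outdir / "heterozygosity.tsv").write_text("\n".join(rows) + "\n")
        by_pop: dict[str, list[float]] = {}
        for ind, h in het.items():
            by_pop.setdefault(pm.labels.get(ind, "NA"), []).append(h)
        summary["het"] = {p: float(np.nanmean(v)) for p, v in by_pop.items()}

    whitelist = None
    if stages.get("prune"):
        cfg_p = ds.LDPruneConfig(r2_threshold=cfg.get("prune", {}).get("r2", 0.6))
        whitelist = ds.ld_prune(G, cfg_p)
        (outdir / "whitelist.txt").write_text(
            "\n".join(G.sites[i] for i in whitelist) + "\n"
        )
        summary["prune"] = {"n_input": G.n_sites, "n_retained": len(whitelist)}

    sfs2 = None
    if stages.get("sfs"):
        Gs = G.subset_sites(whitelist) if whitelist is not None else G
        pops = tuple(cfg.get("sfs", {}).get("pops", ("pop1", "pop2")))
        s = stage_seed(seed, "sfs")
        sfs2 = sb.sfs_2d(Gs, pm, pops, seed=s)
        if "simulate" in summary:
            sfs2.mutation_opportunity = summary["simulate"]["mutation_opportunity"]
        elif "mutation_opportunity" in cfg.get("sfs", {}):
            sfs2.mutation_opportunity = float(cfg["sfs"]["mutation_opportunity"])
        gio.write_sfs(sfs2, outdir / "sfs2d.obs", dialect="obs")
        pop1_members = [i for i in Gs.individuals if i in set(pm.members(pops[0]))]
        sfs1 = sb.sfs_1d(Gs, pop1_members, seed=s + 1)
        gio.write_sfs(sfs1, outdir / "sfs1d_pop1.obs", dialect="obs")
        summary["sfs"] = {"n_sites_2d": sfs2.n_sites, "n_dropped": sfs2.n_dropped}

    if stages.get("fit"):
        blk = cfg.get("fit", {})
        icfg = di.InferenceConfig(
            n_starts=int(blk.get("starts", 10)),
            ecm_cycles=int(blk.get("cycles", 15)),
            sims_per_eval=int(blk.get("sims", 10_000)),
            n_bootstrap=int(blk.get("bootstrap", 20)),
            bootstrap_cycles=int(blk.get("bootstrap_cycles", 5)),
            seed=stage_seed(seed, "fit"),
        )
        fits = []
        for mname in blk.get("models", ["model1", "model2"]):
            spec, _ = _model_from_config({"model": mname})
            fits.append(di.fit_model(sfs2, spec, icfg))
        best, delta = di.select_model(fits)
        tdiv_years = di.convert_time(best.params.get("TDIV", 0.0), icfg.scaling)
        summary["fit"] = {
            "best_model": best.model_name,
            "delta_aic": delta,
            "loglik": {f.model_name: f.loglik for f in fits},
            "aic": {f.model_name: f.aic for f in fits},
            "params": best.params,
            "tdiv_years": tdiv_years,
        }
        if stages.get("bootstrap"):
            bres = di.parametric_bootstrap(sfs2, best, spec_for(best), icfg)
            summary["bootstrap"] = {
                "ci": bres.ci,
                "n_replicates": bres.n_replicates,
            }

    if stages.get("stairway"):
        blk = cfg.get("stairway", {})
        Gs = G.subset_sites(whitelist) if whitelist is not None else G
        pop = blk.get("pop", "pop1")
        members = [i for i in Gs.individuals if i in set(pm.members(pop))]
        sfs1 = sb.sfs_1d(Gs, members, seed=stage_seed(seed, "stairway"))
        scfg = se.StairwayConfig(
            n_bootstrap=int(blk.get("boot", 20)),
            breakpoints=tuple(blk.get("breakpoints", (0, 1, 2, 3))),
            mutation_opportunity=blk.get("L"),
            seed=stage_seed(seed, "stairway"),
        )
        traj = se.fit_stairway(sfs1, scfg)
        traj.to_table().to_csv(outdir / f"stairway_{pop}.tsv", sep="\t", index=False)
        summary["stairway"] = {
            "pop": pop,
            "ne_recent": float(traj.ne_median[0]),
            "ne_ancient": float(traj.ne_median[-1]),
        }

    if stages.get("haplonet"):
        blk = cfg.get("haplonet", {})
        if "fasta" in blk:
            aln = gio.read_fasta_alignment(blk["fasta"])
        else:
            aln = cs.simulate_cpdna(
                {"J": [], "UG": [(100, "G"), (400, "C")], "CG": [(100, "G")]},
                {"J": 32, "UG": 4, "CG": 6},
                length=1064,
                seed=stage_seed(seed, "haplonet"),
            )
        haps = hn.collapse_haplotypes(aln)
        net = hn.build_network(haps)
        nodes = [
            f"{n}\t{int(d.get('frequency', 0))}\t{int(bool(d.get('inferred')))}"
            for n, d in net.graph.nodes(data=True)
        ]
        (outdir / "haplonet_nodes.tsv").write_text("\n".join(nodes) + "\n")
        edges = [f"{a}\t{b}" for a, b in net.graph.edges()]
        (outdir / "haplonet_edges.tsv").write_text("\n".join(edges) + "\n")
        summary["haplonet"] = {
            "n_haplotypes": haps.n_haplotypes,
            "n_inferred": len(net.inferred_nodes),
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def spec_for(fit: "di.FitResult") -> di.ModelSpec:
    return di.model1_spec() if fit.model_name == "model1" else di.model2_spec()
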