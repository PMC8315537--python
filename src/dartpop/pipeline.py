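"""End-to-end orchestration: QC -> distances -> duplicates -> tree/PCoA ->
admixture structure -> platform concordance -> purge-and-recompute.

A single YAML config drives the run; every default is echoed into the
machine-readable report for provenance, all artifacts are flat
TSV/CSV/Newick/JSON, and a fixed seed makes the whole run
byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import duplicates as dup
from . import gower, markers, mantel as mantel_mod, ordination, simulate, structure, tree

log = logging.getLogger("dartpop")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Run configuration; any input source may be left unset.

    Exactly one of (``simulate``), (``snp_csv`` and/or ``silico_csv``),
    or (``snp_dist_csv`` and/or ``silico_dist_csv``) provides the
    inputs. With precomputed distance matrices the QC and Gower stages
    are skipped and the structure stage (which needs genotypes) is
    gated off.
    """

    outdir: str = "dartpop_out"
    seed: int = 0
    simulate: dict | None = None
    snp_csv: str | None = None
    silico_csv: str | None = None
    snp_dist_csv: str | None = None
    silico_dist_csv: str | None = None
    snp_coding: str = "dosage"
    min_call_rate: float = 0.95
    min_reproducibility: float = 1.0
    snp_gower_mode: str = "interval"
    tau_snp: float | None = None
    tau_silico: float | None = None
    # structure stage (desk-scale defaults; the full-length chains of
    # burn_in=20000 / mcmc=30000 are a config choice away)
    structure_burn_in: int = 2000
    structure_mcmc: int = 3000
    structure_K_range: tuple[int, int] = (1, 5)
    structure_runs_per_K: int = 3
    structure_max_loci: int | None = 500
    admix_threshold: float = 0.01
    mantel_permutations: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.structure_K_range, list):
            cfg.structure_K_range = tuple(cfg.structure_K_range)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written as JSON)."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
        "stages": {},
    }

    snp = sil = None
    truth = None
    if config.simulate is not None:
        sim_cfg = simulate.SimConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
        log.info("stage simulate: generating synthetic collection")
        snp, sil, truth = simulate.generate_collection(sim_cfg)
        markers.write_marker_csv(snp, out / "snp_markers.csv")
        markers.write_marker_csv(sil, out / "silico_markers.csv")
        simulate.write_truth(truth, out / "truth")
        report["stages"]["simulate"] = {"config": _jsonable(asdict(sim_cfg))}
    if config.snp_csv:
        snp = markers.read_marker_csv(config.snp_csv, "snp", snp_coding=config.snp_coding)
    if config.silico_csv:
        sil = markers.read_marker_csv(config.silico_csv, "silico")

    D = {}
    mats = {}
    if snp is not None or sil is not None:
        qc_report = {}
        for name, m in (("snp", snp), ("silico", sil)):
            if m is None:
                continue
            qc = markers.compute_qc(m)
            filt, filt_report = markers.filter_markers(
                m, qc, config.min_call_rate, config.min_reproducibility
            )
            bins = markers.summarize_pic_bins(qc.pic[np.isin(m.marker_ids, filt.marker_ids)])
            bins.to_csv(out / f"pic_bins_{name}.tsv", sep="\t", index=False)
            entry = {
                "filter": filt_report,
                "pic_bins_percent": bins["percent"].round(4).tolist(),
            }
            if name == "snp" and m.allele_pair is not None:
                tstv = markers.tstv_table(filt)
                tstv.to_csv(out / "tstv.tsv", sep="\t", index=False)
                tot = tstv[tstv["class"] == "total_transition"].iloc[0]
                entry["transition_fraction"] = float(tot["frequency"])
            qc_report[name] = entry
            mats[name] = filt
        report["stages"]["qc"] = qc_report

        for name, m in mats.items():
            log.info("stage gower: %s", name)
            D[name] = gower.gower_matrix(m, snp_mode=config.snp_gower_mode)
            gower.write_distance_csv(D[name], out / f"gower_{name}.csv")
    if config.snp_dist_csv:
        D["snp"] = gower.read_distance_csv(config.snp_dist_csv, "snp")
    if config.silico_dist_csv:
        D["silico"] = gower.read_distance_csv(config.silico_dist_csv, "silico")
    if not D:
        raise ValueError("no inputs: supply simulate, marker CSVs or distance CSVs")

    # distance summaries
    summaries = {}
    for name, dm in D.items():
        groups = None
        if name in mats:
            groups = {s: mats[name].sample_class.get(s, "unknown") for s in dm.labels}
        summ = gower.distance_summary(dm, groups)
        summ.to_csv(out / f"distance_summary_{name}.tsv", sep="\t", index=False)
        overall = summ[summ["group"] == "overall"].iloc[0]
        summaries[name] = {k: float(overall[k]) for k in ("min", "max", "mean")}
    report["stages"]["distances"] = summaries

    # duplicates (needs both platforms)
    cgs = None
    if "snp" in D and "silico" in D:
        rep_pairs = _replicate_pairs(mats.get("snp"), D["snp"])
        miss = _missing_rates(mats, D["snp"].labels)
        try:
            cgs = dup.detect_duplicates(
                D["snp"], D["silico"], rep_pairs, miss,
                tau_snp=config.tau_snp, tau_silico=config.tau_silico,
            )
        except ValueError as e:
            log.warning("stage duplicates skipped: %s", e)
        if cgs is not None:
            dup.groups_table(cgs).to_csv(out / "clone_groups.tsv", sep="\t", index=False)
            pd.DataFrame({"purge": cgs.purge_list}).to_csv(out / "purge_list.tsv", sep="\t", index=False)
            report["stages"]["duplicates"] = {
                "tau_snp": cgs.tau_snp,
                "tau_silico": cgs.tau_silico,
                "n_flagged": len(cgs.flagged),
                "n_groups": len(cgs.groups),
                "n_purged": len(cgs.purge_list),
                "flagged": cgs.flagged,
            }

    # tree and ordination
    trees = {}
    for name, dm in D.items():
        dend = tree.upgma(dm)
        (out / f"upgma_{name}.nwk").write_text(dend.newick() + "\n")
        cut = tree.cut_tree(dend, 2)
        pd.DataFrame(sorted(cut.items()), columns=["sample", "cluster"]).to_csv(
            out / f"clusters_{name}.tsv", sep="\t", index=False
        )
        ordn = ordination.pcoa(dm)
        ordn.to_frame().to_csv(out / f"pcoa_{name}.tsv", sep="\t")
        trees[name] = {
            "two_cluster_sizes": sorted(
                pd.Series(cut).value_counts().tolist(), reverse=True
            ),
            "pcoa_percent_first_two_axes": float(ordn.percent_variance[:2].sum()),
            "pcoa_negative_eigenvalues": ordn.n_negative,
        }
    report["stages"]["tree_ordination"] = trees

    # platform concordance
    if "snp" in D and "silico" in D:
        common = [s for s in D["snp"].labels if s in set(D["silico"].labels)]
        mres = mantel_mod.mantel_test(
            D["snp"].subset(common), D["silico"].subset(common),
            n_perm=config.mantel_permutations, seed=config.seed,
        )
        report["stages"]["mantel"] = {"r": mres.r, "p": mres.p, "n_perm": mres.n_perm}

    # admixture structure on SNP genotypes (accessions only)
    if "snp" in mats:
        report["stages"]["structure"] = _structure_stage(mats["snp"], config, out, cgs)

    report["runtime_seconds"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _structure_stage(snp: markers.MarkerMatrix, config: PipelineConfig, out: Path, cgs) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1001]))
    accessions = [s for s in snp.sample_ids if not s.endswith(markers.REPLICATE_SUFFIX)]
    m = snp.select_samples(accessions)
    if config.structure_max_loci is not None and m.n_markers > config.structure_max_loci:
        keep = np.zeros(m.n_markers, dtype=bool)
        keep[rng.choice(m.n_markers, size=config.structure_max_loci, replace=False)] = True
        m = m.select_markers(keep)
    cfg = structure.McmcConfig(
        burn_in=config.structure_burn_in,
        mcmc=config.structure_mcmc,
        K_range=tuple(config.structure_K_range),
        runs_per_K=config.structure_runs_per_K,
        seed=config.seed,
    )
    log.info("stage structure: K in %s, %d runs per K", cfg.K_range, cfg.runs_per_K)
    L_table, best = structure.run_K_selection(m, cfg)
    L_table.to_csv(out / "structure_L_table.tsv", sep="\t", index=False)
    dk_table, best_K = structure.evanno_deltaK(L_table)
    dk_table.to_csv(out / "structure_deltaK.tsv", sep="\t", index=False)
    res = best[best_K]
    stats = structure.diversity_stats(res, config.admix_threshold)
    qdf = pd.DataFrame(res.Q, columns=[f"q{k + 1}" for k in range(res.K)])
    qdf.insert(0, "sample", res.sample_ids)
    qdf["label"] = stats.labels
    qdf.to_csv(out / "structure_Q.tsv", sep="\t", index=False)
    entry = {
        "best_K": best_K,
        "He": stats.He.tolist(),
        "D_net": {f"{a}-{b}": v for (a, b), v in stats.D_net.items()},
        "membership": stats.membership.tolist(),
        "n_admixed": sum(1 for x in stats.labels if x == "admixed"),
    }

    # purge-and-recompute: rerun at the chosen K on representatives only
    if cgs is not None and cgs.purge_list:
        kept = [s for s in m.sample_ids if s not in set(cgs.purge_list)]
        m2 = m.select_samples(kept)
        res2 = structure.run_admixture(m2, best_K, cfg, seed=cfg.seed)
        stats2 = structure.diversity_stats(res2, config.admix_threshold)
        perm = structure.align_clusters(res2.Q, res.Q[[res.sample_ids.index(s) for s in kept]])
        entry["purged"] = {
            "n_samples": len(kept),
            "He": stats2.He[perm].tolist(),
            "n_admixed": sum(1 for x in stats2.labels if x == "admixed"),
        }
    return entry


def _replicate_pairs(m, dm) -> list[tuple[str, str]]:
    if m is not None and m.replicate_pairs:
        return list(m.replicate_pairs)
    labels = set(dm.labels)
    return [
        (s[: -len(markers.REPLICATE_SUFFIX)], s)
        for s in dm.labels
        if s.endswith(markers.REPLICATE_SUFFIX) and s[: -len(markers.REPLICATE_SUFFIX)] in labels
    ]


def _missing_rates(mats: dict, labels: list[str]) -> dict[str, float]:
    if "snp" in mats:
        m = mats["snp"]
        rates = m.missing_rate_per_sample()
        base = {s: float(r) for s, r in zip(m.sample_ids, rates)}
        return {s: base.get(s, 0.0) for s in labels}
    return dict.fromkeys(labels, 0.0)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
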