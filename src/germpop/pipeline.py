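"""End-to-end characterization pipeline: QC -> diversity -> scan ->
outliers -> LD -> blocks -> panel -> structure/tree/spatial.

Each stage writes a CSV artifact plus a JSON provenance stanza (package
version, seed, input hashes).  Optional stages (spatial grid, tree,
Bayesian outliers) log-and-continue on failure; mandatory stages abort
with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import germpop
from germpop import diversity, genome_scan, genotype_io, hapblocks, linkage
from germpop import outlier_scan, structure_lite

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str = ""
    dialect: str = "wide-dosage"
    samples: str = ""
    genome_map: str = ""
    out_dir: str = "germpop_out"
    min_call_rate: float = 0.75
    min_maf: float = 0.05
    window_bp: int = 100_000
    prune_r2: float = 0.5
    q_threshold: float = 0.7
    alpha: float = 0.05
    radius_km: float = 150.0
    grid_step_km: float = 50.0
    panel_size: int = 560
    max_ld_dist: int = 1_000_000
    bootstrap_n: int = 0
    run_bayes: bool = False
    seed: int = 0
    stages: tuple = ("qc", "structure", "diversity", "scan", "outliers",
                     "ld", "blocks", "panel", "tree", "spatial")

    def validate(self):
        for name, lo, hi in (("min_call_rate", 0, 1), ("min_maf", 0, 0.5),
                             ("prune_r2", 0, 1), ("q_threshold", 0, 1),
                             ("alpha", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.window_bp <= 0 or self.radius_km <= 0:
            raise ValueError("window_bp and radius_km must be positive")


def load_config(path) -> PipelineConfig:
    """Flat key: value config file (YAML subset); unknown keys rejected."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def save_config(config: PipelineConfig, path) -> None:
    import yaml

    d = asdict(config)
    d["stages"] = list(d["stages"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.provenance: dict = {
            "version": germpop.__version__,
            "seed": config.seed,
            "inputs": {},
            "stages": {},
        }

    def _record(self, stage: str, artifacts: list, t0: float) -> None:
        self.provenance["stages"][stage] = {
            "artifacts": [str(a) for a in artifacts],
            "seconds": round(time.time() - t0, 3),
        }
        with open(self.out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the provenance dict; artifacts land in ``config.out_dir``.
    """
    run = PipelineRun(config)
    cfg = config
    out = run.out

    # ---- inputs ------------------------------------------------------
    for key in ("genotypes", "samples", "genome_map"):
        path = getattr(cfg, key)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"stage=load missing mandatory input "
                                    f"{key}={path!r}")
        run.provenance["inputs"][key] = _sha256(path)
    gm, markers = genotype_io.read_genotype_table(cfg.genotypes, cfg.dialect)
    samples = genotype_io.read_sample_table(cfg.samples)
    gmap = genotype_io.read_genome_map(cfg.genome_map)

    # ---- qc ----------------------------------------------------------
    t0 = time.time()
    qc = genotype_io.marker_qc(gm)
    markers = markers.merge(qc, on="marker_id", how="left",
                            suffixes=("", "_qc"))
    gm, markers, report = genotype_io.filter_markers(
        gm, markers, min_call_rate=cfg.min_call_rate, qc=qc)
    qc_path = out / "marker_qc.csv"
    markers.to_csv(qc_path, index=False)
    with open(out / "qc_report.json", "w") as fh:
        json.dump(report, fh)
    run._record("qc", [qc_path], t0)
    log.info("qc: retained %d markers", gm.n_markers)

    # ---- structure (labels + covariates for LD) ----------------------
    q_cov = None
    if "structure" in cfg.stages:
        t0 = time.time()
        adm = structure_lite.admixture_em(gm, k=2, seed=cfg.seed)
        labels = structure_lite.assign_groups(adm.q, cfg.q_threshold)
        qdf = pd.DataFrame(adm.q, columns=["q1", "q2"])
        qdf.insert(0, "accession_id", gm.accession_ids)
        qdf["assigned"] = labels
        qpath = out / "admixture_q.csv"
        qdf.to_csv(qpath, index=False)
        q_cov = adm.q[:, :-1]
        if (samples["gene_pool"] == "unknown").all():
            samples = samples.copy()
            samples["gene_pool"] = labels
        run._record("structure", [qpath], t0)

    pools = [p for p in samples["gene_pool"].unique()
             if p not in ("admixed", "unknown")]
    acc_pool = samples.set_index("accession_id").reindex(
        gm.accession_ids)["gene_pool"].to_numpy()
    pool_masks = {p: acc_pool == p for p in pools}

    # ---- diversity ---------------------------------------------------
    if "diversity" in cfg.stages:
        t0 = time.time()
        groups, hier = diversity.group_summary(gm, samples, "gene_pool")
        table = diversity.group_summary_table(groups, hier)
        dpath = out / "diversity_gene_pool.csv"
        table.to_csv(dpath, index=False)
        run._record("diversity", [dpath], t0)

    # ---- genome scan -------------------------------------------------
    if "scan" in cfg.stages:
        t0 = time.time()
        fst_groups = (tuple(pool_masks.values())[:2]
                      if len(pool_masks) >= 2 else None)
        scan = genome_scan.scan_table(gm, markers, gmap,
                                      fst_groups=fst_groups,
                                      length=cfg.window_bp)
        spath = out / "window_scan.csv"
        scan.to_csv(spath, index=False)
        run._record("scan", [spath], t0)

    # ---- outliers ----------------------------------------------------
    if "outliers" in cfg.stages and len(pool_masks) >= 2:
        t0 = time.time()
        strat = samples.set_index("accession_id").reindex(
            gm.accession_ids)["stratum"].to_numpy()
        deme_masks = {}
        for p, mask in list(pool_masks.items())[:2]:
            demes = []
            for s in ("landrace", "cultivar_line"):
                demes.append(mask & (strat == s))
            if all(d.sum() >= 2 for d in demes):
                deme_masks[p] = demes
            else:
                deme_masks[p] = [mask, mask]  # degenerate demes
        obs = outlier_scan.observed_locus_stats(gm, deme_masks)
        target = float(np.nanmean(obs["fst"]))
        rng = np.random.default_rng(cfg.seed)
        sizes = [2 * int(d.sum()) for demes in deme_masks.values()
                 for d in demes]
        island = outlier_scan.calibrate_island_model(
            max(target, 0.01), sizes, rng=rng)
        cloud = outlier_scan.fdist_null_simulation(island, rng)
        fdist = outlier_scan.fdist_classify(obs, cloud, alpha=cfg.alpha)
        opath = out / "outliers_fdist.csv"
        fdist.to_csv(opath, index=False)
        artifacts = [opath]
        if cfg.run_bayes:
            try:
                rep = outlier_scan.bayes_fst_mcmc(
                    gm, pool_masks,
                    outlier_scan.BayesRunParams(seed=cfg.seed))
                bpath = out / "outliers_bayes.csv"
                rep.table.to_csv(bpath, index=False)
                joint = outlier_scan.intersect_outliers(fdist, rep.table)
                jpath = out / "outliers_joint.csv"
                joint.to_csv(jpath, index=False)
                artifacts += [bpath, jpath]
            except Exception:
                log.exception("optional Bayesian outlier stage failed")
        run._record("outliers", artifacts, t0)

    # ---- LD ----------------------------------------------------------
    records = None
    if "ld" in cfg.stages:
        t0 = time.time()
        records = linkage.pairwise_r2(gm, markers, max_dist=cfg.max_ld_dist,
                                      maf_min=cfg.min_maf)
        grm, _ = linkage.genetic_relationship_matrix(gm)
        if q_cov is not None:
            records = linkage.corrected_r2_sv(gm, q_cov, grm, records)
        lpath = out / "ld_records.csv"
        records.to_csv(lpath, index=False)
        artifacts = [lpath]
        try:
            fit = linkage.fit_decay_model(records, n=gm.n_accessions,
                                          use_r2_sv="r2_sv" in records)
            with open(out / "ld_decay.json", "w") as fh:
                json.dump({"rho": fit.rho, "n": fit.n,
                           "half_decay_bp": fit.half_decay_bp,
                           "r2_at_zero": fit.r2_at_zero}, fh)
            artifacts.append(out / "ld_decay.json")
        except (ValueError, RuntimeError):
            log.exception("optional LD decay fit failed")
        run._record("ld", artifacts, t0)

    # ---- haplotype blocks --------------------------------------------
    if "blocks" in cfg.stages:
        t0 = time.time()
        gmb, mb, _ = genotype_io.filter_markers(
            gm, markers, min_call_rate=cfg.min_call_rate,
            min_maf=cfg.min_maf)
        ci = hapblocks.pair_ci_records(gmb, mb)
        blocks = hapblocks.gabriel_blocks(ci, mb)
        bpath = out / "hapblocks.csv"
        hapblocks.blocks_table(blocks).to_csv(bpath, index=False)
        summ = hapblocks.per_chromosome_summary(blocks, gmap)
        summ.to_csv(out / "hapblocks_summary.csv", index=False)
        run._record("blocks", [bpath, out / "hapblocks_summary.csv"], t0)

    # ---- SNP panel ---------------------------------------------------
    if "panel" in cfg.stages and len(pool_masks) >= 2:
        t0 = time.time()
        panel = linkage.select_panel(gm, markers, samples, cfg.panel_size,
                                     min_call_rate=cfg.min_call_rate,
                                     min_maf=cfg.min_maf,
                                     r2_threshold=cfg.prune_r2)
        ppath = out / "panel.csv"
        pd.DataFrame({"marker_id": panel.marker_ids}).to_csv(ppath,
                                                             index=False)
        with open(out / "panel_report.json", "w") as fh:
            json.dump({"per_chromosome": panel.per_chromosome,
                       "mean_he": panel.mean_he,
                       "feasible": panel.feasible,
                       "notes": panel.notes}, fh)
        run._record("panel", [ppath], t0)

    # ---- tree (optional) ---------------------------------------------
    if "tree" in cfg.stages:
        t0 = time.time()
        try:
            dist = structure_lite.simple_matching_distance(gm)
            tree = structure_lite.nj_tree(dist, bootstrap_n=cfg.bootstrap_n,
                                          gm=gm, seed=cfg.seed)
            tpath = out / "nj_tree.nwk"
            with open(tpath, "w") as fh:
                fh.write(structure_lite.tree_to_newick(tree) + "\n")
            run._record("tree", [tpath], t0)
        except Exception:
            log.exception("optional tree stage failed")

    # ---- spatial He (optional) ---------------------------------------
    if "spatial" in cfg.stages:
        t0 = time.time()
        if samples[["lat", "lon"]].notna().all(axis=1).any():
            grid = structure_lite.spatial_he(gm, samples,
                                             radius_km=cfg.radius_km,
                                             grid_step_km=cfg.grid_step_km)
            gpath = out / "spatial_he.csv"
            grid.to_csv(gpath, index=False)
            run._record("spatial", [gpath], t0)
        else:
            log.info("spatial stage skipped: no coordinates")
            run.provenance["stages"]["spatial"] = {"skipped": "no coordinates"}

    with open(out / "provenance.json", "w") as fh:
        json.dump(run.provenance, fh, indent=2)
    return run.provenance
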