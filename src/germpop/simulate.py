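"""Synthetic germplasm collections with controlled population structure.

The generator emulates a two-gene-pool, highly selfing germplasm panel:

* pool allele frequencies diverge from a common ancestral frequency under
  a Balding-Nichols Beta model, with the Beta parameter calibrated by
  bisection so the realized Nei FST estimator hits the configured target;
* strata (landrace vs cultivar/line) add a second, weak Balding-Nichols
  tier within each pool;
* haplotype pools are built from a limited set of founder lineages and
  recombined for a configurable number of generations, which yields
  block-structured LD whose decay rate is set by the per-bp crossover
  rate (slower decay = lower rate);
* selfing is modeled as a per-accession identity-by-descent coin flip
  (probability ``selfing_F`` that the two gametes are the same haplotype);
* a configurable fraction of "admixed" accessions draw each gamete from a
  pool chosen by a true admixture proportion q ~ Beta(5,5) truncated to
  [0.3, 0.7];
* a minority of loci get a boosted divergence parameter (divergent
  selection stand-in) and are flagged in the returned ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from germpop.genotype_io import MISSING, GenotypeMatrix, marker_qc


@dataclass
class SimConfig:
    n_pool1: int = 64
    n_pool2: int = 111
    n_admixed: int = 6
    strata_split: float = 0.5          # fraction landrace per pool
    n_chrom: int = 11
    chrom_length_bp: int = 5_000_000
    n_markers: int = 5000
    target_fst_pools: float = 0.75
    target_fst_strata: float = 0.02
    selfing_F: float = 0.6
    outlier_fraction: float = 0.0
    outlier_fst_boost: float = 0.2
    recomb_rate_per_bp: tuple = (5e-9, 2e-8)   # pool 1 slower decay
    missing_rate: float = 0.08
    seed: int = 0
    # generative machinery knobs
    n_founder_lineages: int = 48
    n_generations: int = 8
    haplotype_pool_size: int = 300     # haplotypes per (pool, stratum)
    p_anc_range: tuple = (0.05, 0.95)
    admix_segment_bp: int = 500_000    # mosaic grain of admixed gametes
    calib_markers: int = 2000          # marker count used during calibration
    # geography
    bbox: tuple = (-35.0, 5.0, -75.0, -35.0)  # lat_min, lat_max, lon_min, lon_max
    spatial_clustering: float = 0.8

    def validate(self) -> None:
        for name in ("strata_split", "selfing_F", "outlier_fraction",
                     "missing_rate", "spatial_clustering"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.target_fst_pools < 1.0:
            raise ValueError("target_fst_pools must be in [0, 1)")
        if not 0.0 <= self.target_fst_strata < 1.0:
            raise ValueError("target_fst_strata must be in [0, 1)")
        if min(self.n_pool1, self.n_pool2, self.n_admixed) < 0:
            raise ValueError("accession counts must be >= 0")


@dataclass
class SimTruth:
    p_anc: np.ndarray
    pool_freqs: np.ndarray             # (2, n_markers)
    outlier_flags: np.ndarray
    q: np.ndarray                      # (n_accessions,) true pool-1 fraction
    pool: list
    stratum: list
    fst_param_pools: float = np.nan

    def to_json(self, path) -> None:
        d = {
            "p_anc": self.p_anc.tolist(),
            "pool_freqs": self.pool_freqs.tolist(),
            "outlier_flags": self.outlier_flags.astype(int).tolist(),
            "q": self.q.tolist(),
            "pool": list(self.pool),
            "stratum": list(self.stratum),
            "fst_param_pools": float(self.fst_param_pools),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


# ----------------------------------------------------------------------
# frequency models
# ----------------------------------------------------------------------

def simulate_pool_freqs(p_anc, fst, rng) -> np.ndarray:
    """Balding-Nichols divergence draw.

    ``p_pool ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F = fst``; expectation
    is ``p_anc``. ``fst = 0`` returns ``p_anc`` exactly.
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if np.any((p_anc <= 0) | (p_anc >= 1)):
        raise ValueError("ancestral frequencies must lie in (0, 1)")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if fst == 0.0:
        return p_anc.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def _nei_fst_from_freqs(p1, p2):
    """Per-locus mean Nei (Ht-Hs)/Ht between two frequency vectors."""
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    return float(np.nanmean(fst))


_CALIB_CACHE: dict = {}


def _realized_pool_fst(gm, truth) -> float:
    """Mean per-locus Nei FST between the truth-labelled pools."""
    from germpop.diversity import fixation_indices

    pool = np.asarray(truth.pool)
    masks = {p: pool == p for p in ("Andean", "Mesoamerican")}
    return fixation_indices(gm, masks).fst


def calibrate_fst_param(target, config: SimConfig,
                        n_calib_markers=2000, tol=0.006, max_iter=18):
    """Bisect the Balding-Nichols parameter so the realized mean per-locus
    Nei FST between the simulated pools matches ``target``.

    Each bisection step runs the full generative chain (frequency tiers,
    lineage founders, recombination-generation drift, selfing, accession
    sampling, missingness) on a reduced marker set with a fixed sub-seed,
    so every source of extra differentiation is accounted for.  Results
    are memoized on the generative knobs.
    """
    if target <= 0.0:
        return 0.0
    key = (round(target, 4), config.n_pool1, config.n_pool2,
           config.strata_split, round(config.selfing_F, 4),
           round(config.target_fst_strata, 4), round(config.missing_rate, 4),
           config.n_founder_lineages, config.n_generations,
           config.haplotype_pool_size, config.p_anc_range, n_calib_markers)
    if key in _CALIB_CACHE:
        return _CALIB_CACHE[key]
    from dataclasses import replace

    # LD makes loci strongly correlated, so a single replicate has a large
    # effective MC error; average a few fixed-seed replicates instead.
    calib_cfgs = [
        replace(config, n_markers=n_calib_markers, n_admixed=0,
                outlier_fraction=0.0, seed=0xC0FFEE + r)
        for r in range(3)
    ]

    def realized(theta):
        vals = []
        for c in calib_cfgs:
            gm, _, _, truth = _simulate_given_theta(c, theta)
            vals.append(_realized_pool_fst(gm, truth))
        return float(np.mean(vals))

    lo, hi = 1e-4, 1.0 - 1e-4
    result = None
    if realized(hi) < target:
        result = hi
    else:
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            val = realized(mid)
            if abs(val - target) < tol:
                result = mid
                break
            if val < target:
                lo = mid
            else:
                hi = mid
        if result is None:
            result = 0.5 * (lo + hi)
    _CALIB_CACHE[key] = result
    return result


# ----------------------------------------------------------------------
# haplotype machinery
# ----------------------------------------------------------------------

def _recombine(parents_a, parents_b, positions, rate, rng):
    """Single-crossover-process recombination of paired parent haplotypes.

    Crossovers fall independently in each inter-marker interval with
    probability ``rate * gap`` (thinned Poisson); the child copies from
    parent A or B according to the parity of crossovers so far.
    """
    n, m = parents_a.shape
    if m == 1:
        pick = rng.integers(2, size=n).astype(bool)
        return np.where(pick[:, None], parents_a, parents_b)
    gaps = np.diff(positions).astype(float)
    xo = rng.random((n, m - 1)) < np.clip(rate * gaps, 0, 0.5)[None, :]
    parity = np.zeros((n, m), dtype=np.int8)
    parity[:, 1:] = np.cumsum(xo, axis=1) % 2
    start = rng.integers(2, size=n)[:, None]
    use_b = (parity + start) % 2 == 1
    return np.where(use_b, parents_b, parents_a)


def _lineage_haplotype_pool(freqs, positions, rate, n_lineages,
                            n_generations, pool_size, rng):
    """Haplotype pool for one chromosome of one (sub)population.

    Founder lineages carry independent Bernoulli(p) alleles; the pool is
    seeded by copying lineages and then recombined for ``n_generations``.
    With ``rate = 0`` every pool haplotype is a verbatim lineage copy, so
    co-segregating marker pairs stay in complete LD.
    """
    m = len(freqs)
    if m == 0:
        return np.empty((pool_size, 0), dtype=np.int8)
    lineages = (rng.random((n_lineages, m)) < freqs[None, :]).astype(np.int8)
    pool = lineages[rng.integers(n_lineages, size=pool_size)]
    for _ in range(n_generations):
        pa = pool[rng.integers(pool_size, size=pool_size)]
        pb = pool[rng.integers(pool_size, size=pool_size)]
        pool = _recombine(pa, pb, positions, rate, rng)
    return pool


def simulate_haplotypes_ld(config: SimConfig, pool: int, rng,
                           freqs=None, positions=None, chrom_index=None):
    """Per-chromosome haplotype pools for one gene pool.

    Returns a list (one entry per chromosome) of arrays with shape
    ``(haplotype_pool_size, markers_on_chromosome)``.
    """
    config.validate()
    rate = config.recomb_rate_per_bp[pool]
    if freqs is None or positions is None:
        p_anc = rng.uniform(*config.p_anc_range, size=config.n_markers)
        freqs = simulate_pool_freqs(p_anc, max(config.target_fst_pools, 1e-6), rng) \
            if config.target_fst_pools > 0 else p_anc
        positions, chrom_index = _place_markers(config, rng)
    pools = []
    for c in range(config.n_chrom):
        on_c = np.flatnonzero(chrom_index == c)
        if on_c.size == 0:
            pools.append(np.empty((config.haplotype_pool_size, 0), dtype=np.int8))
            continue
        pools.append(_lineage_haplotype_pool(
            freqs[on_c], positions[on_c], rate,
            config.n_founder_lineages, config.n_generations,
            config.haplotype_pool_size, rng))
    return pools


def _place_markers(config: SimConfig, rng):
    """Sorted uniform positions, markers split across chromosomes."""
    per = np.full(config.n_chrom, config.n_markers // config.n_chrom)
    per[: config.n_markers % config.n_chrom] += 1
    chrom_index = np.repeat(np.arange(config.n_chrom), per)
    positions = np.empty(config.n_markers, dtype=int)
    for c in range(config.n_chrom):
        on_c = chrom_index == c
        pos = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp + 1), size=on_c.sum(),
            replace=False))
        positions[on_c] = pos
    return positions, chrom_index


# ----------------------------------------------------------------------
# the full collection
# ----------------------------------------------------------------------

def simulate_collection(config: SimConfig):
    """Generate a full synthetic collection.

    Returns ``(GenotypeMatrix, markers, samples, SimTruth)``.
    """
    config.validate()
    theta = calibrate_fst_param(config.target_fst_pools, config,
                                n_calib_markers=config.calib_markers)
    return _simulate_given_theta(config, theta)


def _simulate_given_theta(config: SimConfig, theta: float):
    """The generative chain for a fixed Balding-Nichols parameter."""
    rng = np.random.default_rng(config.seed)
    m = config.n_markers

    # -- marker map and ancestral/pool frequencies ---------------------
    positions, chrom_index = _place_markers(config, rng)
    p_anc = rng.uniform(*config.p_anc_range, size=m)

    n_out = int(round(config.outlier_fraction * m))
    outlier_flags = np.zeros(m, dtype=bool)
    if n_out:
        outlier_flags[rng.choice(m, size=n_out, replace=False)] = True

    theta_out = min(0.98, theta + config.outlier_fst_boost)

    pool_freqs = np.empty((2, m))
    for k in range(2):
        pool_freqs[k] = simulate_pool_freqs(p_anc, theta, rng) if theta > 0 \
            else p_anc.copy()
        if n_out:
            pool_freqs[k, outlier_flags] = simulate_pool_freqs(
                p_anc[outlier_flags], theta_out, rng)

    # -- per (pool, stratum) haplotype pools ---------------------------
    strata = ("landrace", "cultivar_line")
    hap_pools = {}
    for k in range(2):
        for s in strata:
            sf = simulate_pool_freqs(
                np.clip(pool_freqs[k], 1e-4, 1 - 1e-4),
                config.target_fst_strata, rng) \
                if config.target_fst_strata > 0 else pool_freqs[k]
            hap_pools[(k, s)] = _concat_chroms(
                sf, positions, chrom_index, config,
                config.recomb_rate_per_bp[k], rng)

    # -- accessions ----------------------------------------------------
    pools, strat, qs = [], [], []
    for k, count in ((0, config.n_pool1), (1, config.n_pool2)):
        n_land = int(round(config.strata_split * count))
        for i in range(count):
            pools.append(k)
            strat.append(strata[0] if i < n_land else strata[1])
            qs.append(1.0 if k == 0 else 0.0)
    for _ in range(config.n_admixed):
        pools.append(-1)
        strat.append(strata[int(rng.integers(2))])
        q = rng.beta(5, 5)
        qs.append(float(np.clip(q, 0.3, 0.7)))
    n_acc = len(pools)
    qs = np.asarray(qs)

    segments = _admix_segments(positions, chrom_index, config)
    calls = np.empty((n_acc, m), dtype=np.int8)
    for i in range(n_acc):
        g1 = _draw_gamete(pools[i], strat[i], qs[i], hap_pools,
                          segments, rng)
        if rng.random() < config.selfing_F:
            g2 = g1
        else:
            g2 = _draw_gamete(pools[i], strat[i], qs[i], hap_pools,
                              segments, rng)
        calls[i] = g1 + g2

    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    acc_ids = [f"ACC{i:04d}" for i in range(n_acc)]
    marker_ids = [f"M{j:05d}" for j in range(m)]
    gm = GenotypeMatrix(calls, acc_ids, marker_ids)

    markers = pd.DataFrame({
        "marker_id": marker_ids,
        "chrom": [f"chr{c + 1:02d}" for c in chrom_index],
        "pos": positions,
        "ref": "A",
        "alt": "C",
    })
    qc = marker_qc(gm)
    markers = markers.join(qc.drop(columns="marker_id"))
    markers["reproducibility"] = 1.0

    pool_name = {0: "Andean", 1: "Mesoamerican", -1: "admixed"}
    samples = pd.DataFrame({
        "accession_id": acc_ids,
        "gene_pool": [pool_name[k] for k in pools],
        "stratum": strat,
        "country": "synthetic",
        "lat": np.nan,
        "lon": np.nan,
    })
    truth = SimTruth(p_anc, pool_freqs, outlier_flags, qs,
                     [pool_name[k] for k in pools], strat, theta)
    samples = assign_geography(samples, config, rng, truth)
    return gm, markers, samples, truth


def _concat_chroms(freqs, positions, chrom_index, config, rate, rng):
    out = np.empty((config.haplotype_pool_size, len(freqs)), dtype=np.int8)
    for c in range(config.n_chrom):
        on_c = np.flatnonzero(chrom_index == c)
        if on_c.size == 0:
            continue
        out[:, on_c] = _lineage_haplotype_pool(
            freqs[on_c], positions[on_c], rate,
            config.n_founder_lineages, config.n_generations,
            config.haplotype_pool_size, rng)
    return out


def _admix_segments(positions, chrom_index, config):
    """Marker index groups per (chromosome, segment) mosaic block."""
    seg = positions // max(config.admix_segment_bp, 1)
    key = chrom_index.astype(np.int64) * 10 ** 9 + seg
    segments = []
    for k in np.unique(key):
        segments.append(np.flatnonzero(key == k))
    return segments


def _draw_gamete(pool, stratum, q, hap_pools, segments, rng):
    """One gamete; admixed gametes are segment-level mosaics of the pools."""
    if pool != -1:
        haps = hap_pools[(pool, stratum)]
        return haps[rng.integers(haps.shape[0])]
    m = sum(len(s) for s in segments)
    gamete = np.empty(m, dtype=np.int8)
    for sl in segments:
        k = 0 if rng.random() < q else 1
        haps = hap_pools[(k, stratum)]
        gamete[sl] = haps[rng.integers(haps.shape[0])][sl]
    return gamete


def assign_geography(samples: pd.DataFrame, config: SimConfig, rng,
                     truth: SimTruth | None = None) -> pd.DataFrame:
    """Assign coordinates clustered by (pool, stratum).

    ``spatial_clustering = 0`` makes coordinates uniform over the bounding
    box irrespective of ancestry; ``1`` concentrates each group tightly
    around its own center.
    """
    lat0, lat1, lon0, lon1 = config.bbox
    samples = samples.copy()
    c = config.spatial_clustering
    groups = samples["gene_pool"].astype(str) + ":" + samples["stratum"].astype(str)
    centers = {}
    for g in pd.unique(groups):
        centers[g] = (rng.uniform(lat0, lat1), rng.uniform(lon0, lon1))
    lat = np.empty(len(samples))
    lon = np.empty(len(samples))
    sd_lat = 0.03 * (lat1 - lat0) if lat1 > lat0 else 0.0
    sd_lon = 0.03 * (lon1 - lon0) if lon1 > lon0 else 0.0
    for i, g in enumerate(groups):
        u_lat = rng.uniform(lat0, lat1)
        u_lon = rng.uniform(lon0, lon1)
        lat[i] = c * (centers[g][0] + rng.normal(0, sd_lat)) + (1 - c) * u_lat
        lon[i] = c * (centers[g][1] + rng.normal(0, sd_lon)) + (1 - c) * u_lon
    samples["lat"] = np.clip(lat, -90, 90)
    samples["lon"] = np.clip(lon, -180, 180)
    return samples


def genome_map_for(config: SimConfig) -> pd.Series:
    return pd.Series(
        {f"chr{c + 1:02d}": config.chrom_length_bp
         for c in range(config.n_chrom)}, name="length_bp")


def config_to_json(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
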