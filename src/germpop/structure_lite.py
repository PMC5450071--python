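"""Lightweight structure tools: EM admixture estimation, q-threshold group
assignment, simple-matching distances, neighbor-joining trees with
bootstrap support, and spatial expected-heterozygosity grids.

The admixture estimator maximizes the binomial admixture likelihood

    sum_il [ x_il log sum_k q_ik f_kl + (2 - x_il) log sum_k q_ik (1 - f_kl) ]

by EM.  It is a deliberate stand-in for full Bayesian clustering: it
serves exactly two downstream needs — structure covariates for corrected
LD, and q >= 0.7 gene-pool labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from germpop.diversity import heterozygosity
from germpop.genotype_io import MISSING, GenotypeMatrix

EARTH_RADIUS_KM = 6371.0


# ----------------------------------------------------------------------
# admixture EM
# ----------------------------------------------------------------------

@dataclass
class AdmixtureResult:
    q: np.ndarray                       # (n_accessions, K)
    f: np.ndarray                       # (K, n_markers)
    log_likelihood: float
    k: int
    seed: int
    trajectory: list = field(default_factory=list, repr=False)


def _admixture_loglik(x, typed, q, f):
    pa = np.clip(q @ f, 1e-12, 1 - 1e-12)
    term = np.where(typed, x * np.log(pa) + (2 - x) * np.log1p(-pa), 0.0)
    return float(term.sum())


def admixture_em(gm: GenotypeMatrix, k: int, n_restarts: int = 3,
                 seed: int = 0, max_iter: int = 500,
                 tol: float = 1e-6) -> AdmixtureResult:
    """EM admixture estimation; best of ``n_restarts`` random starts."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > gm.n_accessions:
        raise ValueError("K exceeds number of accessions")
    x = np.where(gm.calls == MISSING, 0, gm.calls).astype(float)
    typed = gm.calls != MISSING
    n, m = x.shape
    overall = heterozygosity(gm)["p"].to_numpy()
    overall = np.nan_to_num(overall, nan=0.5)

    if k == 1:
        q = np.ones((n, 1))
        f = np.clip(overall, 1e-6, 1 - 1e-6)[None, :]
        ll = _admixture_loglik(x, typed, q, f)
        return AdmixtureResult(q, f, ll, 1, seed, [ll])

    best: AdmixtureResult | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        q = rng.dirichlet(np.ones(k), size=n)
        f = np.clip(overall[None, :]
                    + rng.normal(0, 0.05, size=(k, m)), 1e-4, 1 - 1e-4)
        traj = []
        prev = -np.inf
        for _ in range(max_iter):
            pa = np.clip(q @ f, 1e-12, 1 - 1e-12)        # (n, m)
            # responsibilities for alternate and reference allele copies
            w_alt = q[:, :, None] * f[None, :, :] / pa[:, None, :]
            w_ref = q[:, :, None] * (1 - f)[None, :, :] / (1 - pa)[:, None, :]
            xa = np.where(typed, x, 0.0)[:, None, :]
            xr = np.where(typed, 2 - x, 0.0)[:, None, :]
            alt_k = w_alt * xa                            # (n, k, m)
            ref_k = w_ref * xr
            q = (alt_k + ref_k).sum(axis=2)
            q /= q.sum(axis=1, keepdims=True)
            denom = (alt_k + ref_k).sum(axis=0)           # (k, m)
            f = np.clip(alt_k.sum(axis=0) / np.maximum(denom, 1e-12),
                        1e-6, 1 - 1e-6)
            ll = _admixture_loglik(x, typed, q, f)
            traj.append(ll)
            if ll - prev < tol and np.isfinite(prev):
                break
            prev = ll
        cand = AdmixtureResult(q, f, traj[-1], k, seed + r, traj)
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def assign_groups(q: np.ndarray, threshold: float = 0.7,
                  labels=None) -> list:
    """Assign each accession to its argmax cluster if max q >= threshold,
    else label it ``admixed``."""
    q = np.asarray(q)
    if labels is None:
        labels = [f"cluster{j + 1}" for j in range(q.shape[1])]
    out = []
    for row in q:
        j = int(np.argmax(row))
        out.append(labels[j] if row[j] >= threshold else "admixed")
    return out


# ----------------------------------------------------------------------
# simple matching distance and NJ trees
# ----------------------------------------------------------------------

def simple_matching_distance(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise mismatch fraction over jointly typed loci (states 0/1/2).

    Pairs with zero jointly typed loci get NaN.
    """
    if gm.n_accessions < 2:
        raise ValueError("need at least two accessions")
    calls = gm.calls
    typed = calls != MISSING
    n = gm.n_accessions
    d = np.zeros((n, n))
    t = typed.astype(float)
    joint = t @ t.T
    # mismatches = joint - matches; matches counted per genotype state
    matches = np.zeros((n, n))
    for state in (0, 1, 2):
        s = ((calls == state) & typed).astype(float)
        matches += s @ s.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(joint > 0, (joint - matches) / joint, np.nan)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=gm.accession_ids, columns=gm.accession_ids)


def nj_tree(distance: pd.DataFrame, bootstrap_n: int = 0,
            gm: GenotypeMatrix | None = None, seed: int = 0):
    """Neighbor-joining tree with optional locus-bootstrap support.

    Negative branch lengths are clamped to zero.  Support values (percent
    of bootstrap replicates containing each internal bipartition) are
    written into internal node names.  Returns an ``skbio.TreeNode``.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    dm = DistanceMatrix(np.ascontiguousarray(distance.to_numpy(dtype=float)),
                        ids=[str(i) for i in distance.index])
    tree = _nj(dm)
    n_clamped = _clamp_negative_lengths(tree)
    if n_clamped:
        import logging
        logging.getLogger(__name__).info(
            "clamped %d negative branch lengths", n_clamped)
    if bootstrap_n and gm is not None:
        rng = np.random.default_rng(seed)
        ref_parts = _bipartitions(tree)
        counts = dict.fromkeys(ref_parts, 0)
        for _ in range(bootstrap_n):
            idx = rng.integers(gm.n_markers, size=gm.n_markers)
            boot = GenotypeMatrix(gm.calls[:, idx], gm.accession_ids,
                                  [f"b{i}" for i in range(gm.n_markers)])
            bd = simple_matching_distance(boot)
            bt = _nj(DistanceMatrix(
                np.ascontiguousarray(bd.to_numpy(dtype=float)),
                ids=[str(i) for i in bd.index]))
            for part in _bipartitions(bt):
                if part in counts:
                    counts[part] += 1
        _annotate_support(tree, counts, bootstrap_n)
    return tree


def _clamp_negative_lengths(tree) -> int:
    n = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n += 1
    return n


def _bipartitions(tree) -> set:
    all_tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            parts.add(min(side, all_tips - side, key=sorted))
    return parts


def _annotate_support(tree, counts, n_boot):
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            key = min(side, all_tips - side, key=sorted)
            node.name = str(int(round(100.0 * counts.get(key, 0) / n_boot)))


def tree_to_newick(tree) -> str:
    import io
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ----------------------------------------------------------------------
# spatial He grid
# ----------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (mean Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def spatial_he(gm: GenotypeMatrix, samples: pd.DataFrame,
               radius_km: float = 150.0, grid_step_km: float = 50.0,
               single_accession: str = "own_freq") -> pd.DataFrame:
    """Expected heterozygosity on a regular grid of neighborhoods.

    Each grid node averages He over the accessions within ``radius_km``
    (haversine).  Nodes with no accessions emit no value.  For nodes with
    a single accession, ``own_freq`` uses that accession's own-genotype
    allele frequencies (He = 0.5 per heterozygous locus); the
    ``het_fraction`` alternative reports its proportion of heterozygous
    calls directly.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    s = samples.set_index("accession_id").loc[gm.accession_ids]
    has_geo = s["lat"].notna() & s["lon"].notna()
    n_dropped = int((~has_geo).sum())
    if n_dropped:
        import logging
        logging.getLogger(__name__).info(
            "excluded %d accessions without coordinates", n_dropped)
    if not has_geo.any():
        raise ValueError("no accessions with coordinates")
    lat = s["lat"].to_numpy(dtype=float)
    lon = s["lon"].to_numpy(dtype=float)
    geo_idx = np.flatnonzero(has_geo.to_numpy())

    lat_step = np.degrees(grid_step_km / EARTH_RADIUS_KM)
    lat_lo, lat_hi = lat[geo_idx].min(), lat[geo_idx].max()
    lon_lo, lon_hi = lon[geo_idx].min(), lon[geo_idx].max()
    grid_lat = np.arange(lat_lo, lat_hi + lat_step / 2, lat_step) \
        if lat_hi > lat_lo else np.array([lat_lo])
    mid_lat = np.radians((lat_lo + lat_hi) / 2)
    lon_step = lat_step / max(np.cos(mid_lat), 1e-6)
    grid_lon = np.arange(lon_lo, lon_hi + lon_step / 2, lon_step) \
        if lon_hi > lon_lo else np.array([lon_lo])

    rows = []
    for glat in grid_lat:
        dist_all = haversine_km(glat, grid_lon[:, None],
                                lat[geo_idx][None, :], lon[geo_idx][None, :])
        for gi, glon in enumerate(grid_lon):
            near = geo_idx[dist_all[gi] <= radius_km]
            if near.size == 0:
                continue
            rows.append(dict(lat=float(glat), lon=float(glon),
                             he=_neighborhood_he(gm, near, single_accession),
                             n_accessions=int(near.size)))
    return pd.DataFrame(rows)


def _neighborhood_he(gm, accession_index, single_accession):
    if len(accession_index) == 1 and single_accession == "het_fraction":
        calls = gm.calls[accession_index[0]]
        typed = calls != MISSING
        return float((calls[typed] == 1).mean()) if typed.any() else np.nan
    het = heterozygosity(gm, np.asarray(accession_index)) \
        if len(accession_index) > 1 else _single_he(gm, accession_index[0])
    if isinstance(het, float):
        return het
    return float(np.nanmean(het["he"].to_numpy()))


def _single_he(gm, i) -> float:
    calls = gm.calls[i]
    typed = calls != MISSING
    if not typed.any():
        return np.nan
    p = calls[typed] / 2.0
    return float(np.mean(2 * p * (1 - p)))
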