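"""Linkage disequilibrium: plain and structure/kinship-corrected r2,
decay-model fitting, LD pruning and SNP-panel selection.

Pairwise r2 is the squared Pearson correlation of genotype dosage vectors
(composite LD; phase is unknown and heterozygosity is very low in selfing
germplasm, so haplotype-EM r2 is unnecessary).  The corrected statistic
r2_SV whitens the dosage vectors by the inverse square root of the
kinship matrix and projects out the (whitened) intercept and structure
covariates before correlating the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from germpop.genotype_io import MISSING, GenotypeMatrix, marker_qc


# ----------------------------------------------------------------------
# genetic relationship matrix (Yang et al. / GCTA algorithm)
# ----------------------------------------------------------------------

def genetic_relationship_matrix(gm: GenotypeMatrix):
    """GRM with Yang's inbreeding-adjusted diagonal.

    Off-diagonal ``A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) /
    (2 p_i (1 - p_i))``; the diagonal uses
    ``1 + (1/m) sum_i (x_ij^2 - (1 + 2p_i) x_ij + 2 p_i^2) /
    (2 p_i (1 - p_i))``.  Missing calls are handled by per-pair
    available-marker averaging; monomorphic markers are excluded.

    Returns ``(A, n_markers_used)``.
    """
    calls = gm.calls.astype(float)
    typed = gm.calls != MISSING
    n_typed = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(typed, calls, 0).sum(axis=0) / (2 * n_typed)
    poly = (n_typed > 0) & (p > 0) & (p < 1)
    n_used = int(poly.sum())
    if n_used == 0:
        raise ValueError("no polymorphic markers for GRM")
    x = calls[:, poly]
    t = typed[:, poly]
    p = p[poly]
    denom = 2 * p * (1 - p)

    z = np.where(t, (x - 2 * p[None, :]) / np.sqrt(denom)[None, :], 0.0)
    counts = t.astype(float) @ t.T.astype(float)
    a = (z @ z.T) / np.maximum(counts, 1)

    diag_terms = np.where(
        t, (x * x - (1 + 2 * p[None, :]) * x + 2 * p[None, :] ** 2)
        / denom[None, :], 0.0)
    own = t.sum(axis=1)
    np.fill_diagonal(a, 1.0 + diag_terms.sum(axis=1) / np.maximum(own, 1))
    return a, n_used


# ----------------------------------------------------------------------
# pairwise r2
# ----------------------------------------------------------------------

def _candidate_pairs(markers: pd.DataFrame, max_dist):
    """Same-chromosome index pairs within max_dist, positions sorted."""
    pairs = []
    for _chrom, grp in markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = pos[b] - pos[a]
                if max_dist is not None and d > max_dist:
                    break
                if d > 0:
                    pairs.append((idx[a], idx[b], d))
    return pairs


def pairwise_r2(gm: GenotypeMatrix, markers: pd.DataFrame,
                max_dist=None, maf_min: float = 0.05,
                min_joint: int = 5) -> pd.DataFrame:
    """Pairwise dosage-correlation r2 for same-chromosome marker pairs.

    Markers below ``maf_min`` are excluded up front; pairs with fewer than
    ``min_joint`` jointly typed accessions are skipped (counted in the
    ``skipped`` attribute of the returned frame).
    """
    qc = marker_qc(gm)
    keep = (qc["maf"].to_numpy() >= maf_min) & np.isfinite(qc["maf"].to_numpy())
    sub = gm.subset_markers(keep)
    msub = markers.loc[keep].reset_index(drop=True)
    calls = sub.calls.astype(float)
    typed = sub.calls != MISSING
    pairs = _candidate_pairs(msub, max_dist)
    rows, skipped = [], 0
    for a, b, d in pairs:
        joint = typed[:, a] & typed[:, b]
        nj = int(joint.sum())
        if nj < min_joint:
            skipped += 1
            continue
        xa, xb = calls[joint, a], calls[joint, b]
        va, vb = xa.var(), xb.var()
        if va == 0 or vb == 0:
            continue
        r = np.corrcoef(xa, xb)[0, 1]
        rows.append((msub["marker_id"].iloc[a], msub["marker_id"].iloc[b],
                     msub["chrom"].iloc[a], int(d), float(r * r), nj))
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "chrom",
                                      "dist_bp", "r2", "n_joint"])
    out.attrs["skipped"] = skipped
    return out


# ----------------------------------------------------------------------
# structure/kinship-corrected r2
# ----------------------------------------------------------------------

def _inverse_sqrt_psd(k: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh((k + k.T) / 2.0)
    # mildly negative eigenvalues (pairwise-missing artifacts) are floored;
    # a substantially indefinite matrix is a caller error
    if vals.min() < -0.05 * max(abs(vals.max()), 1.0):
        raise ValueError(
            f"kinship not PSD after flooring; spectrum min={vals.min():.3e} "
            f"max={vals.max():.3e}")
    vals = np.maximum(vals, floor)
    return (vecs / np.sqrt(vals)) @ vecs.T


def corrected_r2_sv(gm: GenotypeMatrix, structure_covariates,
                    kinship: np.ndarray, pairs: pd.DataFrame) -> pd.DataFrame:
    """Add an ``r2_sv`` column to an LD-record frame.

    Dosage columns are mean-imputed at missing calls, whitened by
    ``K^{-1/2}`` and residualized against the whitened intercept and
    structure covariates; ``r2_sv`` is the squared correlation of the
    residual vectors.  With identity kinship and no covariates this
    reduces exactly to the plain dosage r2.
    """
    calls = gm.calls.astype(float)
    typed = gm.calls != MISSING
    col_mean = np.where(typed, calls, 0).sum(axis=0) / np.maximum(
        typed.sum(axis=0), 1)
    filled = np.where(typed, calls, col_mean[None, :])

    w = _inverse_sqrt_psd(np.asarray(kinship, dtype=float))
    design = [np.ones((gm.n_accessions, 1))]
    if structure_covariates is not None:
        cov = np.asarray(structure_covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.size:
            design.append(cov)
    s = w @ np.hstack(design)
    q, _ = np.linalg.qr(s)
    y = w @ filled
    resid = y - q @ (q.T @ y)

    idx = {mid: j for j, mid in enumerate(gm.marker_ids)}
    sd = resid.std(axis=0)
    centered = resid - resid.mean(axis=0)
    r2_sv = np.empty(len(pairs))
    for k, (ida, idb) in enumerate(zip(pairs["id_a"], pairs["id_b"])):
        a, b = idx[ida], idx[idb]
        if sd[a] == 0 or sd[b] == 0:
            r2_sv[k] = np.nan
            continue
        r = (centered[:, a] @ centered[:, b]) / (
            len(centered) * sd[a] * sd[b])
        r2_sv[k] = min(r * r, 1.0)
    out = pairs.copy()
    out["r2_sv"] = r2_sv
    return out


# ----------------------------------------------------------------------
# decay model (drift/recombination expectation with finite-sample term)
# ----------------------------------------------------------------------

def expected_r2(d, rho: float, n: int):
    """Expected r2 at distance d for recombination scale rho and sample n.

    ``C = rho * d``;
    ``E[r2] = (10 + C)/((2 + C)(11 + C)) *
    (1 + (3 + C)(12 + 12 C + C^2)/(n (2 + C)(11 + C)))``.
    The d -> infinity asymptote is 1/n.
    """
    c = rho * np.asarray(d, dtype=float)
    lead = (10 + c) / ((2 + c) * (11 + c))
    corr = 1 + (3 + c) * (12 + 12 * c + c * c) / (n * (2 + c) * (11 + c))
    return lead * corr


@dataclass
class DecayFit:
    rho: float
    n: int
    half_decay_bp: float
    rss: float
    n_records: int
    r2_at_zero: float

    def predict(self, d):
        return expected_r2(d, self.rho, self.n)


def fit_decay_model(records: pd.DataFrame, n: int, use_r2_sv: bool = False,
                    binned: bool = False, n_bins: int = 50,
                    min_records: int = 50) -> DecayFit:
    """Nonlinear least-squares fit of the decay expectation over rho.

    ``binned=True`` fits distance-bin means instead of raw pairs.  The
    half-decay distance solves ``E[r2](d) = E[r2](0+)/2`` by bracketed
    root finding.
    """
    col = "r2_sv" if use_r2_sv else "r2"
    rec = records[["dist_bp", col]].dropna()
    if len(rec) < min_records:
        raise ValueError(f"need >= {min_records} records, got {len(rec)}")
    d = rec["dist_bp"].to_numpy(dtype=float)
    y = rec[col].to_numpy(dtype=float)
    if binned:
        edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
        which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
        d = np.array([d[which == b].mean() for b in range(n_bins)
                      if (which == b).any()])
        y = np.array([y[which == b].mean() for b in range(n_bins)
                      if (which == b).any()])

    def resid(log_rho):
        return expected_r2(d, np.exp(log_rho[0]), n) - y

    best = None
    for start in np.log(10.0 ** np.arange(-9, 0)):
        try:
            sol = least_squares(resid, x0=[start], bounds=(-30.0, 5.0),
                                max_nfev=200)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("decay fit failed from every start")
    rho = float(np.exp(best.x[0]))
    r0 = float(expected_r2(0.0, rho, n))
    target = r0 / 2.0
    if target <= 1.0 / n:
        half = np.inf
    else:
        hi = 1.0
        while expected_r2(hi, rho, n) > target and hi < 1e15:
            hi *= 10
        half = brentq(lambda dd: expected_r2(dd, rho, n) - target, 1e-9, hi)
    return DecayFit(rho, n, float(half), float(2 * best.cost), len(d), r0)


# ----------------------------------------------------------------------
# LD pruning and panel selection
# ----------------------------------------------------------------------

def _r2_pair(calls, typed, a, b):
    joint = typed[:, a] & typed[:, b]
    if joint.sum() < 2:
        return 0.0
    xa, xb = calls[joint, a], calls[joint, b]
    if xa.var() == 0 or xb.var() == 0:
        return 0.0
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, markers: pd.DataFrame,
             r2_threshold: float = 0.5, window_markers: int = 50,
             step: int = 5, qc: pd.DataFrame | None = None) -> list:
    """Deterministic sliding-window greedy LD pruning.

    Within each window of ``window_markers`` consecutive markers (advanced
    by ``step``), for every remaining pair with r2 >= threshold the member
    with the lower call rate is dropped (ties: lower MAF, then later
    position).  Returns the retained marker ids in input order.
    """
    if qc is None:
        qc = marker_qc(gm)
    call_rate = qc["call_rate"].to_numpy()
    maf = np.nan_to_num(qc["maf"].to_numpy())
    calls = gm.calls.astype(float)
    typed = gm.calls != MISSING
    removed = np.zeros(gm.n_markers, dtype=bool)
    for _chrom, grp in markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()[np.argsort(grp["pos"].to_numpy(),
                                              kind="stable")]
        m = len(idx)
        start = 0
        while True:
            window = idx[start: start + window_markers]
            live = [i for i in window if not removed[i]]
            for ai in range(len(live)):
                for bi in range(ai + 1, len(live)):
                    a, b = live[ai], live[bi]
                    if removed[a] or removed[b]:
                        continue
                    if _r2_pair(calls, typed, a, b) >= r2_threshold:
                        removed[_prune_victim(a, b, call_rate, maf,
                                              markers)] = True
            if start + window_markers >= m:
                break
            start += step
    return [mid for j, mid in enumerate(gm.marker_ids) if not removed[j]]


def _prune_victim(a, b, call_rate, maf, markers):
    if call_rate[a] != call_rate[b]:
        return a if call_rate[a] < call_rate[b] else b
    if maf[a] != maf[b]:
        return a if maf[a] < maf[b] else b
    return a if markers["pos"].iloc[a] > markers["pos"].iloc[b] else b


def ld_prune_exhaustive(gm: GenotypeMatrix, markers: pd.DataFrame,
                        r2_threshold: float = 0.5,
                        qc: pd.DataFrame | None = None) -> list:
    """O(m^2) pruning over whole chromosomes (oracle for small fixtures)."""
    return ld_prune(gm, markers, r2_threshold,
                    window_markers=gm.n_markers, step=gm.n_markers, qc=qc)


@dataclass
class PanelResult:
    marker_ids: list
    per_chromosome: dict
    mean_he: float
    feasible: bool
    notes: list = field(default_factory=list)


def select_panel(gm: GenotypeMatrix, markers: pd.DataFrame,
                 samples: pd.DataFrame, size_target: int,
                 min_call_rate: float = 0.75, min_maf: float = 0.05,
                 r2_threshold: float = 0.5) -> PanelResult:
    """Select an evenly spaced, both-pool-polymorphic, LE SNP panel.

    Filters: call rate >= ``min_call_rate``, overall MAF > ``min_maf``,
    polymorphic within each gene pool; then LD pruning at ``r2_threshold``
    and greedy max-min spacing per chromosome down to ``size_target``.
    """
    from germpop.diversity import allele_frequencies

    qc = marker_qc(gm)
    keep = ((qc["call_rate"].to_numpy() >= min_call_rate)
            & (qc["maf"].to_numpy() > min_maf))
    pools = [p for p in samples["gene_pool"].unique()
             if p not in ("admixed", "unknown")]
    acc_pool = samples.set_index("accession_id").loc[
        gm.accession_ids, "gene_pool"].to_numpy()
    for pool in pools:
        p = allele_frequencies(gm, acc_pool == pool)
        keep &= np.nan_to_num(p) > 0
        keep &= np.nan_to_num(p, nan=1.0) < 1
    sub = gm.subset_markers(keep)
    msub = markers.loc[keep].reset_index(drop=True)
    retained = ld_prune(sub, msub, r2_threshold)
    notes = []
    rset = set(retained)
    msub = msub[msub["marker_id"].isin(rset)].reset_index(drop=True)
    sub = sub.subset_markers([i for i, mid in enumerate(sub.marker_ids)
                              if mid in rset])
    if len(retained) <= size_target:
        chosen = list(retained)
        feasible = len(retained) == size_target
        if not feasible:
            notes.append(f"only {len(retained)} markers survive filters; "
                         f"target was {size_target}")
    else:
        chosen = _maxmin_spacing(msub, size_target)
        feasible = True
    chosen_set = set(chosen)
    per_chrom = msub[msub["marker_id"].isin(chosen_set)].groupby(
        "chrom", sort=False).size().to_dict()
    het = marker_qc(sub.subset_markers(
        [i for i, mid in enumerate(sub.marker_ids) if mid in chosen_set]))
    maf = het["maf"].to_numpy()
    mean_he = float(np.nanmean(2 * maf * (1 - maf)))
    return PanelResult(chosen, per_chrom, mean_he, feasible, notes)


def _maxmin_spacing(markers: pd.DataFrame, size_target: int) -> list:
    """Greedy max-min spacing, proportional allocation per chromosome."""
    groups = {c: g.sort_values("pos") for c, g in
              markers.groupby("chrom", sort=False)}
    total = len(markers)
    alloc = {c: max(1, int(round(size_target * len(g) / total)))
             for c, g in groups.items()}
    while sum(alloc.values()) > size_target:
        c = max(alloc, key=lambda k: alloc[k])
        alloc[c] -= 1
    while sum(alloc.values()) < size_target:
        c = max(groups, key=lambda k: len(groups[k]) - alloc[k])
        alloc[c] += 1
    chosen = []
    for c, g in groups.items():
        ids = g["marker_id"].to_list()
        pos = g["pos"].to_numpy(dtype=float)
        k = min(alloc[c], len(ids))
        picked = [0, len(ids) - 1] if k >= 2 else [0]
        while len(picked) < k:
            best_i, best_d = None, -1.0
            for i in range(len(ids)):
                if i in picked:
                    continue
                d = min(abs(pos[i] - pos[j]) for j in picked)
                if d > best_d:
                    best_i, best_d = i, d
            picked.append(best_i)
        chosen.extend(ids[i] for i in sorted(picked))
    return chosen
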