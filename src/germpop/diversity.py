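"""Per-group and hierarchical diversity statistics.

Estimators follow the Nei / GenAlEx-style decomposition: per locus

* ``Hs`` = unweighted mean of subpopulation expected heterozygosities,
* ``Ht`` = expected heterozygosity of the unweighted mean allele frequency,
* ``FST = (Ht - Hs)/Ht``, ``FIS = (Hs - Ho)/Hs``, ``FIT = (Ht - Ho)/Ht``,

so that ``(1 - FIT) = (1 - FIS)(1 - FST)`` holds identically per locus.
Means are reported with SE = sd/sqrt(L) over defined loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from germpop.genotype_io import MISSING, GenotypeMatrix


# ----------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------

def allele_frequencies(gm: GenotypeMatrix, group_mask=None) -> np.ndarray:
    """Alternate-allele frequency per marker within a group.

    ``p = (2 n2 + n1) / (2 n_typed)``; markers with zero typed calls in
    the group are flagged as NaN.
    """
    calls = _group_calls(gm, group_mask)
    typed = calls != MISSING
    n_typed = typed.sum(axis=0)
    alt = np.where(typed, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_typed > 0, alt / (2.0 * n_typed), np.nan)


def _group_calls(gm: GenotypeMatrix, group_mask):
    if group_mask is None:
        return gm.calls
    group_mask = np.asarray(group_mask)
    if group_mask.dtype == bool:
        if not group_mask.any():
            raise ValueError("empty group")
        return gm.calls[group_mask]
    if len(group_mask) == 0:
        raise ValueError("empty group")
    return gm.calls[group_mask]


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return np.nan, np.nan
    return float(v.mean()), float(v.std(ddof=0) / np.sqrt(v.size))


def heterozygosity(gm: GenotypeMatrix, group_mask=None) -> pd.DataFrame:
    """Per-marker Ho, He, unbiased He and F within a group.

    ``He = 1 - p^2 - q^2``; ``uHe = He * 2n/(2n - 1)``; ``Ho`` = fraction
    of heterozygous calls among typed; ``F = 1 - Ho/He`` (NaN when He=0).
    """
    calls = _group_calls(gm, group_mask)
    typed = calls != MISSING
    n_typed = typed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_typed > 0,
                     np.where(typed, calls, 0).sum(axis=0) / (2 * n_typed),
                     np.nan)
        he = 2.0 * p * (1.0 - p)
        uhe = np.where(n_typed > 0.5, he * 2 * n_typed / (2 * n_typed - 1), np.nan)
        ho = np.where(n_typed > 0, (calls == 1).sum(axis=0) / n_typed, np.nan)
        f = np.where(he > 0, 1.0 - ho / he, np.nan)
    return pd.DataFrame({"p": p, "n_typed": n_typed.astype(int),
                         "ho": ho, "he": he, "uhe": uhe, "f": f})


# ----------------------------------------------------------------------
# hierarchical F-statistics
# ----------------------------------------------------------------------

@dataclass
class HierarchicalF:
    """Mean +/- SE F-statistics with the per-locus vectors behind them."""

    fst: float
    fst_se: float
    fis: float
    fis_se: float
    fit: float
    fit_se: float
    per_locus: pd.DataFrame = field(repr=False)
    pairwise_fst: pd.DataFrame | None = field(default=None, repr=False)


def fixation_indices(gm: GenotypeMatrix, subpop_masks: dict) -> HierarchicalF:
    """Nei-style FST/FIS/FIT across >=2 subpopulations.

    Loci with ``Ht = 0`` (monomorphic overall) are skipped.
    """
    if len(subpop_masks) < 2:
        raise ValueError("need at least two subpopulations")
    names = list(subpop_masks)
    per = {g: heterozygosity(gm, m) for g, m in subpop_masks.items()}
    p_mat = np.vstack([per[g]["p"].to_numpy() for g in names])
    he_mat = np.vstack([per[g]["he"].to_numpy() for g in names])
    ho_mat = np.vstack([per[g]["ho"].to_numpy() for g in names])

    hs = np.nanmean(he_mat, axis=0)
    pbar = np.nanmean(p_mat, axis=0)
    ht = 2.0 * pbar * (1.0 - pbar)
    ho = np.nanmean(ho_mat, axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
        fis = np.where(hs > 0, (hs - ho) / hs, np.nan)
        fit = np.where(ht > 0, (ht - ho) / ht, np.nan)
    if not np.isfinite(fst).any():
        raise ValueError("all loci monomorphic overall")

    per_locus = pd.DataFrame({"hs": hs, "ht": ht, "ho": ho,
                              "fst": fst, "fis": fis, "fit": fit})
    pw = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        pw.loc[a, a] = 0.0
        for b in names[i + 1:]:
            sub = {a: subpop_masks[a], b: subpop_masks[b]}
            hs2 = np.nanmean(he_mat[[names.index(a), names.index(b)]], axis=0)
            pb2 = np.nanmean(p_mat[[names.index(a), names.index(b)]], axis=0)
            ht2 = 2 * pb2 * (1 - pb2)
            with np.errstate(invalid="ignore", divide="ignore"):
                f2 = np.where(ht2 > 0, (ht2 - hs2) / ht2, np.nan)
            pw.loc[a, b] = pw.loc[b, a] = np.nanmean(f2)
    m_fst, se_fst = _mean_se(fst)
    m_fis, se_fis = _mean_se(fis)
    m_fit, se_fit = _mean_se(fit)
    return HierarchicalF(m_fst, se_fst, m_fis, se_fis, m_fit, se_fit,
                         per_locus, pw)


def weir_cockerham_fst(gm: GenotypeMatrix, subpop_masks: dict) -> float:
    """Weir-Cockerham theta (ratio of summed variance components).

    Provided as an alternative estimator; biallelic, missing-aware.
    """
    names = list(subpop_masks)
    r = len(names)
    if r < 2:
        raise ValueError("need at least two subpopulations")
    n_i, p_i, h_i = [], [], []
    for g in names:
        het = heterozygosity(gm, subpop_masks[g])
        n_i.append(het["n_typed"].to_numpy(dtype=float))
        p_i.append(het["p"].to_numpy())
        h_i.append(het["ho"].to_numpy())
    n_i = np.vstack(n_i)
    p_i = np.nan_to_num(np.vstack(p_i))
    h_i = np.nan_to_num(np.vstack(h_i))
    n_sum = n_i.sum(axis=0)
    nbar = n_sum / r
    valid = (n_i > 0).all(axis=0) & (nbar > 1)
    pbar = (n_i * p_i).sum(axis=0) / n_sum
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / n_sum
    nc = (n_sum - (n_i ** 2).sum(axis=0) / n_sum) / (r - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    a, b, c = (np.where(valid, x, np.nan) for x in (a, b, c))
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return float(num / den)


# ----------------------------------------------------------------------
# private alleles / identity / exclusion
# ----------------------------------------------------------------------

def private_alleles(gm: GenotypeMatrix, group_masks: dict) -> dict:
    """Count alleles private to each group (present there, absent elsewhere).

    Counts alleles, not loci: both the reference and the alternate allele
    of a locus can be private (to different groups).
    """
    names = list(group_masks)
    freqs = {g: allele_frequencies(gm, m) for g, m in group_masks.items()}
    counts = dict.fromkeys(names, 0)
    for allele in ("alt", "ref"):
        present = {}
        for g in names:
            p = freqs[g]
            pa = p if allele == "alt" else 1.0 - p
            present[g] = np.nan_to_num(pa) > 0
        for g in names:
            others = np.zeros(gm.n_markers, dtype=bool)
            for h in names:
                if h != g:
                    others |= present[h]
            counts[g] += int((present[g] & ~others).sum())
    return counts


@dataclass
class IdentityExclusion:
    pi: float
    pe: float
    pi_per_locus: np.ndarray = field(repr=False)
    pe_per_locus: np.ndarray = field(repr=False)


def _pe_one_parent(p: float) -> float:
    """One-parent exclusion probability by exhaustive HWE enumeration.

    Enumerates (mother, child) genotype pairs under HWE random mating and,
    for each, the probability that a random non-father carries none of the
    alleles compatible with paternity.
    """
    q = 1.0 - p
    af = {0: q, 1: p}  # allele 0 = ref, 1 = alt
    geno_p = {(0, 0): q * q, (0, 1): 2 * p * q, (1, 1): p * p}
    pe = 0.0
    for mg, mprob in geno_p.items():
        for ma in set(mg):
            p_ma = 0.5 if mg[0] != mg[1] else 1.0
            for pa in (0, 1):  # true paternal allele ~ population freq
                child = tuple(sorted((ma, pa)))
                prob = mprob * p_ma * af[pa]
                # paternal alleles consistent with (mother, child)
                allowed = {x for x in (0, 1)
                           for m in set(mg)
                           if tuple(sorted((m, x))) == child}
                p_excluded = sum(gp for gg, gp in geno_p.items()
                                 if not (set(gg) & allowed))
                pe += prob * p_excluded
    return pe


def identity_exclusion(gm: GenotypeMatrix, group_mask=None) -> IdentityExclusion:
    """Multilocus probability of identity and combined exclusion power.

    ``PI_l = p^4 + q^4 + (2pq)^2`` accumulated in log space;
    ``PE`` combines one-parent per-locus exclusions as ``1 - prod(1-PE_l)``.
    Monomorphic loci contribute ``PI_l = 1`` and ``PE_l = 0``.
    """
    p = allele_frequencies(gm, group_mask)
    p = p[np.isfinite(p)]
    q = 1.0 - p
    pi_l = p ** 4 + q ** 4 + (2 * p * q) ** 2
    pe_l = np.array([_pe_one_parent(x) for x in p])
    pi = float(np.exp(np.log(pi_l).sum()))
    pe = float(1.0 - np.exp(np.log1p(-pe_l).sum()))
    return IdentityExclusion(pi, pe, pi_l, pe_l)


# ----------------------------------------------------------------------
# group summaries
# ----------------------------------------------------------------------

@dataclass
class GroupDiversity:
    group: str
    sample_size: int
    percent_polymorphic: float
    private_alleles: int
    ho: float
    ho_se: float
    he: float
    he_se: float
    f: float
    f_se: float
    per_locus: pd.DataFrame = field(repr=False)


def group_masks_from_samples(gm: GenotypeMatrix, samples: pd.DataFrame,
                             grouping="gene_pool", exclude=("admixed", "unknown")):
    """Boolean masks per group label; admixed/unknown accessions excluded."""
    s = samples.set_index("accession_id")
    if grouping == "stratum_within_pool":
        labels = (s.loc[gm.accession_ids, "gene_pool"].astype(str) + ":" +
                  s.loc[gm.accession_ids, "stratum"].astype(str))
        drop = s.loc[gm.accession_ids, "gene_pool"].isin(exclude).to_numpy()
    else:
        labels = s.loc[gm.accession_ids, grouping].astype(str)
        drop = labels.isin(exclude).to_numpy()
    masks = {}
    lab = labels.to_numpy()
    for g in pd.unique(lab[~drop]):
        masks[str(g)] = (lab == g) & ~drop
    return masks


def group_summary(gm: GenotypeMatrix, samples: pd.DataFrame,
                  grouping="gene_pool"):
    """Per-group diversity table plus between-group F-statistics."""
    masks = group_masks_from_samples(gm, samples, grouping)
    if len(masks) < 2:
        raise ValueError("grouping yields fewer than two groups")
    nap = private_alleles(gm, masks)
    groups = []
    for g, mask in masks.items():
        het = heterozygosity(gm, mask)
        maf = np.minimum(het["p"], 1 - het["p"])
        defined = np.isfinite(maf.to_numpy())
        poly = 100.0 * float((maf.to_numpy()[defined] > 0).mean()) if defined.any() else np.nan
        ho, ho_se = _mean_se(het["ho"].to_numpy())
        he, he_se = _mean_se(het["he"].to_numpy())
        f, f_se = _mean_se(het["f"].to_numpy())
        groups.append(GroupDiversity(g, int(mask.sum()), poly, nap[g],
                                     ho, ho_se, he, he_se, f, f_se, het))
    hier = fixation_indices(gm, masks)
    return groups, hier


def group_summary_table(groups: list[GroupDiversity],
                        hier: HierarchicalF) -> pd.DataFrame:
    rows = []
    for g in groups:
        rows.append({
            "group": g.group, "S": g.sample_size,
            "P_percent": g.percent_polymorphic, "NAP": g.private_alleles,
            "Ho": g.ho, "Ho_se": g.ho_se, "He": g.he, "He_se": g.he_se,
            "F": g.f, "F_se": g.f_se,
        })
    df = pd.DataFrame(rows)
    df["FST"] = hier.fst
    df["FIS"] = hier.fis
    df["FIT"] = hier.fit
    return df
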