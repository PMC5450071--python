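import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germpop import diversity as dv
from germpop.genotype_io import MISSING, GenotypeMatrix

from conftest import random_matrix


def gm_from_rows(rows):
    rows = np.asarray(rows, dtype=np.int8)
    return GenotypeMatrix(rows, [f"a{i}" for i in range(rows.shape[0])],
                          [f"m{j}" for j in range(rows.shape[1])])


# ----------------------------------------------------------------------
# allele frequencies / heterozygosity
# ----------------------------------------------------------------------

def test_allele_freq_hand_count():
    gm = gm_from_rows([[2], [2], [1], [0]])
    assert dv.allele_frequencies(gm)[0] == pytest.approx(5 / 8)


def test_allele_freq_all_missing_flagged():
    gm = gm_from_rows([[MISSING], [MISSING]])
    assert np.isnan(dv.allele_frequencies(gm)[0])


def test_allele_freq_complement_symmetry(rng):
    gm = random_matrix(rng, 15, 20)
    p = dv.allele_frequencies(gm)
    flipped = GenotypeMatrix(
        np.where(gm.calls == MISSING, MISSING, 2 - gm.calls),
        gm.accession_ids, gm.marker_ids)
    q = dv.allele_frequencies(flipped)
    ok = np.isfinite(p)
    np.testing.assert_allclose(q[ok], 1 - p[ok], atol=1e-12)


def test_allele_freq_empty_group_errors(rng):
    gm = random_matrix(rng, 4, 3)
    with pytest.raises(ValueError):
        dv.allele_frequencies(gm, np.zeros(4, dtype=bool))


def test_he_at_half():
    gm = gm_from_rows([[0], [2]])
    het = dv.heterozygosity(gm)
    assert het["he"].iloc[0] == pytest.approx(0.5)


def test_all_heterozygotes_negative_f():
    gm = gm_from_rows([[1], [1], [1], [1]])
    het = dv.heterozygosity(gm)
    assert het["ho"].iloc[0] == pytest.approx(1.0)
    assert het["f"].iloc[0] == pytest.approx(1 - 1 / het["he"].iloc[0])
    assert het["f"].iloc[0] < 0


def test_he_invariant_to_allele_relabeling(rng):
    gm = random_matrix(rng, 12, 18)
    flipped = GenotypeMatrix(
        np.where(gm.calls == MISSING, MISSING, 2 - gm.calls),
        gm.accession_ids, gm.marker_ids)
    a = dv.heterozygosity(gm)
    b = dv.heterozygosity(flipped)
    np.testing.assert_allclose(a["he"], b["he"], atol=1e-12)
    np.testing.assert_allclose(a["ho"], b["ho"], atol=1e-12)


# ----------------------------------------------------------------------
# fixation indices
# ----------------------------------------------------------------------

def _two_pool_fixture():
    # pool A sample freq exactly 0.2, pool B exactly 0.8
    a = [[2], [0], [0], [0], [0]]
    b = [[2], [2], [2], [2], [0]]
    gm = gm_from_rows(a + b)
    masks = {"A": np.r_[np.ones(5, bool), np.zeros(5, bool)],
             "B": np.r_[np.zeros(5, bool), np.ones(5, bool)]}
    return gm, masks


def test_fst_closed_arithmetic():
    gm, masks = _two_pool_fixture()
    hier = dv.fixation_indices(gm, masks)
    assert hier.per_locus["hs"].iloc[0] == pytest.approx(0.32)
    assert hier.per_locus["ht"].iloc[0] == pytest.approx(0.5)
    assert hier.fst == pytest.approx(0.36)


def test_fst_identical_subpops_zero(rng):
    gm = random_matrix(rng, 10, 20, missing_rate=0)
    doubled = GenotypeMatrix(np.vstack([gm.calls, gm.calls]),
                             [f"x{i}" for i in range(20)], gm.marker_ids)
    masks = {"A": np.r_[np.ones(10, bool), np.zeros(10, bool)],
             "B": np.r_[np.zeros(10, bool), np.ones(10, bool)]}
    hier = dv.fixation_indices(doubled, masks)
    assert hier.fst == pytest.approx(0.0, abs=1e-12)


def test_fst_fixed_alternative_one():
    gm = gm_from_rows([[0]] * 4 + [[2]] * 4)
    masks = {"A": np.r_[np.ones(4, bool), np.zeros(4, bool)],
             "B": np.r_[np.zeros(4, bool), np.ones(4, bool)]}
    assert dv.fixation_indices(gm, masks).fst == pytest.approx(1.0)


def test_fst_invariant_to_group_order(rng):
    gm = random_matrix(rng, 16, 25)
    masks = {"A": np.arange(16) < 8, "B": np.arange(16) >= 8}
    fwd = dv.fixation_indices(gm, masks).fst
    rev = dv.fixation_indices(gm, dict(reversed(masks.items()))).fst
    assert fwd == pytest.approx(rev, abs=1e-12)


def test_all_monomorphic_errors():
    gm = gm_from_rows([[2, 2], [2, 2], [2, 2], [2, 2]])
    masks = {"A": np.arange(4) < 2, "B": np.arange(4) >= 2}
    with pytest.raises(ValueError):
        dv.fixation_indices(gm, masks)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_nei_decomposition_identity(seed):
    gm = random_matrix(np.random.default_rng(seed), 14, 12)
    masks = {"A": np.arange(14) < 7, "B": np.arange(14) >= 7}
    try:
        hier = dv.fixation_indices(gm, masks)
    except ValueError:
        return
    per = hier.per_locus
    ok = per[["fst", "fis", "fit"]].notna().all(axis=1)
    lhs = 1 - per.loc[ok, "fit"]
    rhs = (1 - per.loc[ok, "fis"]) * (1 - per.loc[ok, "fst"])
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_weir_cockerham_agrees_on_balanced_fixture(rng):
    # WC theta and Nei differ but should broadly agree on a strongly
    # differentiated balanced fixture
    a = np.zeros((25, 40), dtype=np.int8)
    b = np.full((25, 40), 2, dtype=np.int8)
    noise = rng.random((50, 40)) < 0.1
    calls = np.vstack([a, b])
    calls[noise] = 1
    gm = GenotypeMatrix(calls, [f"s{i}" for i in range(50)],
                        [f"m{j}" for j in range(40)])
    masks = {"A": np.arange(50) < 25, "B": np.arange(50) >= 25}
    wc = dv.weir_cockerham_fst(gm, masks)
    nei = dv.fixation_indices(gm, masks).fst
    assert abs(wc - nei) < 0.1


# ----------------------------------------------------------------------
# private alleles
# ----------------------------------------------------------------------

def test_private_allele_simple():
    # locus fixed ref in A, segregating in B: alt is private to B
    gm = gm_from_rows([[0], [0], [1], [0]])
    masks = {"A": np.arange(4) < 2, "B": np.arange(4) >= 2}
    counts = dv.private_alleles(gm, masks)
    assert counts == {"A": 0, "B": 1}


def test_private_alleles_identical_groups(rng):
    gm = random_matrix(rng, 6, 10, missing_rate=0)
    doubled = GenotypeMatrix(np.vstack([gm.calls, gm.calls]),
                             [f"x{i}" for i in range(12)], gm.marker_ids)
    masks = {"A": np.arange(12) < 6, "B": np.arange(12) >= 6}
    counts = dv.private_alleles(doubled, masks)
    assert counts == {"A": 0, "B": 0}


def test_private_alleles_brute_force(rng):
    gm = random_matrix(rng, 20, 30)
    masks = {"A": np.arange(20) < 9, "B": np.arange(20) >= 9}
    counts = dv.private_alleles(gm, masks)
    expected = {"A": 0, "B": 0}
    for j in range(gm.n_markers):
        for g, mask in masks.items():
            other = ~mask
            col = gm.calls[:, j]
            mine = col[mask & (col != MISSING)]
            theirs = col[other & (col != MISSING)]
            for allele, has in (("alt", lambda v: (v > 0).any()),
                                ("ref", lambda v: (v < 2).any())):
                if mine.size and has(mine) and not (theirs.size and has(theirs)):
                    expected[g] += 1
    assert counts == expected


# ----------------------------------------------------------------------
# identity / exclusion
# ----------------------------------------------------------------------

def test_pi_single_locus_half():
    gm = gm_from_rows([[0], [2]])
    ie = dv.identity_exclusion(gm)
    assert ie.pi == pytest.approx(0.375)


def test_monomorphic_panel_pi_pe():
    gm = gm_from_rows([[2, 2], [2, 2]])
    ie = dv.identity_exclusion(gm)
    assert ie.pi == pytest.approx(1.0)
    assert ie.pe == pytest.approx(0.0)


def test_pi_equals_enumeration(rng):
    gm = random_matrix(rng, 12, 3, missing_rate=0)
    ie = dv.identity_exclusion(gm)
    p = dv.allele_frequencies(gm)
    expected = 1.0
    for pj in p:
        q = 1 - pj
        # probability two random HWE genotypes match, by enumeration
        geno = {0: q * q, 1: 2 * pj * q, 2: pj * pj}
        expected *= sum(v * v for v in geno.values())
    assert ie.pi == pytest.approx(expected, rel=1e-10)


def test_pe_matches_independent_enumeration():
    # independent check over ordered parental allele draws
    for p in (0.5, 0.2, 0.85):
        q = 1 - p
        af = [q, p]
        pe = 0.0
        for m1 in (0, 1):
            for m2 in (0, 1):
                for pa in (0, 1):
                    for transmitted in (m1, m2):
                        prob = af[m1] * af[m2] * af[pa] * 0.5
                        child = tuple(sorted((transmitted, pa)))
                        mother = tuple(sorted((m1, m2)))
                        allowed = {x for x in (0, 1) for mm in mother
                                   if tuple(sorted((mm, x))) == child}
                        excl = sum(
                            af[g1] * af[g2]
                            for g1 in (0, 1) for g2 in (0, 1)
                            if not ({g1, g2} & allowed))
                        pe += prob * excl
        assert dv._pe_one_parent(p) == pytest.approx(pe, rel=1e-10)


def test_pi_non_increasing_with_loci(rng):
    gm = random_matrix(rng, 15, 8, missing_rate=0)
    pis = [dv.identity_exclusion(gm.subset_markers(np.arange(k))).pi
           for k in range(1, 9)]
    assert all(b <= a + 1e-15 for a, b in zip(pis, pis[1:]))


# ----------------------------------------------------------------------
# group summaries and the brute-force oracle
# ----------------------------------------------------------------------

def _brute_force_group_stats(gm, mask):
    """Independent loop-based Ho/He/F means for one group."""
    hos, hes, fs = [], [], []
    for j in range(gm.n_markers):
        col = gm.calls[np.asarray(mask), j]
        typed = col[col != MISSING]
        if typed.size == 0:
            continue
        p = sum(int(c) for c in typed) / (2 * typed.size)
        he = 1 - p * p - (1 - p) * (1 - p)
        ho = sum(1 for c in typed if c == 1) / typed.size
        hos.append(ho)
        hes.append(he)
        if he > 0:
            fs.append(1 - ho / he)
    return np.mean(hos), np.mean(hes), np.mean(fs)


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_group_stats_match_brute_force(seed):
    gm = random_matrix(np.random.default_rng(seed), 12, 10)
    mask = np.arange(12) < 6
    het = dv.heterozygosity(gm, mask)
    ho, he, f = _brute_force_group_stats(gm, mask)
    assert np.nanmean(het["ho"]) == pytest.approx(ho, abs=1e-12)
    assert np.nanmean(het["he"]) == pytest.approx(he, abs=1e-12)
    assert np.nanmean(het["f"]) == pytest.approx(f, abs=1e-12)


def test_group_summary_excludes_admixed(small_collection):
    gm = small_collection["gm"]
    samples = small_collection["samples"]
    groups, hier = dv.group_summary(gm, samples, "gene_pool")
    names = {g.group for g in groups}
    assert names == {"Andean", "Mesoamerican"}
    total = sum(g.sample_size for g in groups)
    n_admixed = (samples["gene_pool"] == "admixed").sum()
    assert total == gm.n_accessions - n_admixed
    assert 0 <= hier.fst <= 1


def test_group_summary_table_shape(small_collection):
    groups, hier = dv.group_summary(small_collection["gm"],
                                    small_collection["samples"])
    table = dv.group_summary_table(groups, hier)
    assert set(table.columns) >= {"group", "S", "P_percent", "NAP", "Ho",
                                  "He", "F", "FST", "FIS", "FIT"}
    assert (table["P_percent"].dropna() <= 100).all()


def test_stratum_within_pool_grouping(small_collection):
    masks = dv.group_masks_from_samples(
        small_collection["gm"], small_collection["samples"],
        "stratum_within_pool")
    assert len(masks) == 4
    assert all(":" in k for k in masks)
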