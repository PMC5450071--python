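import numpy as np
import pandas as pd
import pytest

from germpop import linkage as lk
from germpop.genotype_io import MISSING, GenotypeMatrix

from conftest import random_matrix, trivial_markers


# ----------------------------------------------------------------------
# GRM
# ----------------------------------------------------------------------

def test_grm_single_locus_closed_form():
    gm = GenotypeMatrix(np.array([[2], [0]], dtype=np.int8), ["a", "b"], ["m"])
    a, used = lk.genetic_relationship_matrix(gm)
    assert used == 1
    # p = 0.5: (2-1)(0-1)/0.5 = -2
    assert a[0, 1] == pytest.approx(-2.0)
    assert a[1, 0] == pytest.approx(-2.0)


def test_grm_duplicate_accessions(rng):
    gm = random_matrix(rng, 6, 30, missing_rate=0)
    calls = np.vstack([gm.calls, gm.calls[:1]])  # row 6 duplicates row 0
    twin = GenotypeMatrix(calls, [f"x{i}" for i in range(7)], gm.marker_ids)
    a, _ = lk.genetic_relationship_matrix(twin)
    # identical standardized scores: off-diagonal equals the plain
    # cross-product of the twin with itself
    assert a[0, 6] == pytest.approx(a[6, 0])
    z_self = a[0, 6]
    others = [a[0, j] for j in range(1, 6)]
    assert z_self > max(others)


def test_grm_matches_loop_oracle(rng):
    gm = random_matrix(rng, 8, 20, missing_rate=0.1)
    a, _ = lk.genetic_relationship_matrix(gm)
    calls = gm.calls.astype(float)
    typed = gm.calls != MISSING
    p = np.array([
        calls[typed[:, j], j].sum() / (2 * typed[:, j].sum())
        for j in range(20)])
    poly = (p > 0) & (p < 1)
    for j in range(8):
        for k in range(8):
            terms = []
            for i in np.flatnonzero(poly):
                if not (typed[j, i] and typed[k, i]):
                    continue
                d = 2 * p[i] * (1 - p[i])
                if j == k:
                    x = calls[j, i]
                    terms.append((x * x - (1 + 2 * p[i]) * x
                                  + 2 * p[i] ** 2) / d)
                else:
                    terms.append((calls[j, i] - 2 * p[i])
                                 * (calls[k, i] - 2 * p[i]) / d)
            expected = np.mean(terms) + (1.0 if j == k else 0.0)
            assert a[j, k] == pytest.approx(expected, rel=1e-10)


def test_grm_monomorphic_excluded(rng):
    gm = random_matrix(rng, 6, 10, missing_rate=0)
    gm.calls[:, 0] = 2
    _, used = lk.genetic_relationship_matrix(gm)
    assert used <= 9


# ----------------------------------------------------------------------
# pairwise r2
# ----------------------------------------------------------------------

def _gm_pair(col_a, col_b):
    calls = np.column_stack([col_a, col_b]).astype(np.int8)
    return GenotypeMatrix(calls, [f"s{i}" for i in range(len(col_a))],
                          ["mA", "mB"])


def test_r2_identical_vectors():
    gm = _gm_pair([0, 1, 2, 0, 2, 1], [0, 1, 2, 0, 2, 1])
    rec = lk.pairwise_r2(gm, trivial_markers(gm), maf_min=0.0)
    assert rec["r2"].iloc[0] == pytest.approx(1.0)


def test_r2_orthogonal_vectors():
    gm = _gm_pair([0, 0, 2, 2] * 2, [0, 2, 0, 2] * 2)
    rec = lk.pairwise_r2(gm, trivial_markers(gm), maf_min=0.0)
    assert rec["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_r2_contingency_oracle(rng):
    gm = random_matrix(rng, 40, 2, missing_rate=0)
    rec = lk.pairwise_r2(gm, trivial_markers(gm), maf_min=0.0)
    # brute force from the 3x3 genotype contingency table
    table = np.zeros((3, 3))
    for a, b in zip(gm.calls[:, 0], gm.calls[:, 1]):
        table[a, b] += 1
    n = table.sum()
    xs = np.arange(3)
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    ea, eb = (xs * pa).sum(), (xs * pb).sum()
    cov = sum(table[i, j] / n * (i - ea) * (j - eb)
              for i in range(3) for j in range(3))
    va = ((xs - ea) ** 2 * pa).sum()
    vb = ((xs - eb) ** 2 * pb).sum()
    assert rec["r2"].iloc[0] == pytest.approx(cov ** 2 / (va * vb), rel=1e-10)


def test_r2_max_dist_and_min_joint(rng):
    gm = random_matrix(rng, 30, 4, missing_rate=0)
    markers = trivial_markers(gm, spacing=100_000)
    rec = lk.pairwise_r2(gm, markers, max_dist=150_000, maf_min=0.0)
    assert (rec["dist_bp"] <= 150_000).all()
    # pair with too few joint calls is skipped
    gm.calls[5:, 0] = MISSING
    rec2 = lk.pairwise_r2(gm, markers, maf_min=0.0, min_joint=10)
    assert rec2.attrs["skipped"] >= 1


# ----------------------------------------------------------------------
# corrected r2
# ----------------------------------------------------------------------

def test_r2_sv_identity_reduction(rng):
    gm = random_matrix(rng, 25, 6, missing_rate=0)
    markers = trivial_markers(gm)
    rec = lk.pairwise_r2(gm, markers, maf_min=0.0)
    out = lk.corrected_r2_sv(gm, None, np.eye(25), rec)
    np.testing.assert_allclose(out["r2_sv"], out["r2"], atol=1e-10)


def test_r2_sv_confounding_deflation():
    # LD purely from inter-pool frequency divergence: near-fixed opposite
    # alleles in two pools, independent assortment within pools
    rng = np.random.default_rng(8)
    n_per, m = 40, 12
    calls = np.empty((2 * n_per, m), dtype=np.int8)
    for j in range(m):
        pa, pb = 0.05, 0.95
        calls[:n_per, j] = rng.binomial(2, pa, n_per)
        calls[n_per:, j] = rng.binomial(2, pb, n_per)
    gm = GenotypeMatrix(calls, [f"s{i}" for i in range(2 * n_per)],
                        [f"m{j}" for j in range(m)])
    markers = trivial_markers(gm)
    rec = lk.pairwise_r2(gm, markers)
    struct = np.r_[np.ones(n_per), np.zeros(n_per)][:, None]
    grm, _ = lk.genetic_relationship_matrix(gm)
    out = lk.corrected_r2_sv(gm, struct, grm, rec)
    assert rec["r2"].median() > 0.4
    assert out["r2_sv"].median() < 0.05


def test_r2_sv_projection_idempotent(rng):
    gm = random_matrix(rng, 20, 5, missing_rate=0)
    markers = trivial_markers(gm)
    rec = lk.pairwise_r2(gm, markers, maf_min=0.0)
    cov = rng.normal(size=(20, 1))
    k = np.eye(20)
    once = lk.corrected_r2_sv(gm, cov, k, rec)
    # residualizing residuals changes nothing: build a matrix of residuals
    from germpop.linkage import _inverse_sqrt_psd
    w = _inverse_sqrt_psd(k)
    filled = gm.calls.astype(float)
    s = w @ np.hstack([np.ones((20, 1)), cov])
    q, _ = np.linalg.qr(s)
    y = w @ filled
    resid = y - q @ (q.T @ y)
    resid2 = resid - q @ (q.T @ resid)
    np.testing.assert_allclose(resid, resid2, atol=1e-10)
    assert np.isfinite(once["r2_sv"]).all()


def test_r2_sv_bounds(small_collection):
    gm = small_collection["gm"]
    markers = small_collection["markers"]
    rec = lk.pairwise_r2(gm, markers, max_dist=300_000).head(200)
    grm, _ = lk.genetic_relationship_matrix(gm)
    out = lk.corrected_r2_sv(gm, None, grm, rec)
    vals = out["r2_sv"].dropna()
    assert ((vals >= 0) & (vals <= 1)).all()


def test_r2_sv_indefinite_kinship_errors(rng):
    gm = random_matrix(rng, 5, 3, missing_rate=0)
    rec = lk.pairwise_r2(gm, trivial_markers(gm), maf_min=0.0)
    bad = np.diag([1.0, 1.0, 1.0, 1.0, -5.0])
    with pytest.raises(ValueError):
        lk.corrected_r2_sv(gm, None, bad, rec)


# ----------------------------------------------------------------------
# decay model
# ----------------------------------------------------------------------

def test_decay_asymptote_one_over_n():
    assert lk.expected_r2(1e12, 1e-3, 50) == pytest.approx(1 / 50, rel=1e-3)


def test_decay_at_zero_closed_form():
    n = 100
    expected = (10 / 22) * (1 + 36 / (22 * n))
    assert lk.expected_r2(0.0, 1e-6, n) == pytest.approx(expected)


def test_decay_monotone_decreasing():
    d = np.linspace(0, 1e7, 200)
    y = lk.expected_r2(d, 1e-5, 80)
    assert np.all(np.diff(y) < 0)


def test_decay_rho_recovery(rng):
    true_rho, n = 1e-5, 100
    d = rng.uniform(1e3, 2e6, size=500)
    y = lk.expected_r2(d, true_rho, n) + rng.normal(0, 0.02, size=500)
    fit = lk.fit_decay_model(pd.DataFrame({"dist_bp": d, "r2": y}), n=n)
    assert abs(fit.rho - true_rho) / true_rho < 0.10
    # half-decay solves E[r2](d) = E[r2](0+)/2
    assert fit.predict(fit.half_decay_bp) == pytest.approx(
        fit.r2_at_zero / 2, rel=1e-6)


def test_decay_binned_mode(rng):
    true_rho, n = 5e-6, 80
    d = rng.uniform(1e3, 3e6, size=2000)
    y = lk.expected_r2(d, true_rho, n) + rng.normal(0, 0.05, size=2000)
    fit = lk.fit_decay_model(pd.DataFrame({"dist_bp": d, "r2": y}), n=n,
                             binned=True)
    assert abs(fit.rho - true_rho) / true_rho < 0.15


def test_decay_too_few_records():
    with pytest.raises(ValueError):
        lk.fit_decay_model(pd.DataFrame({"dist_bp": [1.0], "r2": [0.5]}),
                           n=10)


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------

def test_prune_perfect_pair_keeps_one():
    gm = _gm_pair([0, 1, 2, 0, 2, 1], [0, 1, 2, 0, 2, 1])
    retained = lk.ld_prune(gm, trivial_markers(gm))
    assert len(retained) == 1


def test_prune_uncorrelated_keeps_all(rng):
    gm = random_matrix(rng, 60, 8, missing_rate=0)
    markers = trivial_markers(gm)
    retained = lk.ld_prune(gm, markers, r2_threshold=1.01)
    assert len(retained) == 8


def test_prune_matches_exhaustive_on_small_fixture(rng):
    gm = random_matrix(rng, 30, 12, missing_rate=0.05)
    markers = trivial_markers(gm)
    fast = lk.ld_prune(gm, markers, r2_threshold=0.5,
                       window_markers=12, step=12)
    slow = lk.ld_prune_exhaustive(gm, markers, r2_threshold=0.5)
    assert fast == slow


def test_prune_deterministic(small_collection):
    gm = small_collection["gm"].subset_markers(np.arange(100))
    markers = small_collection["markers"].iloc[:100].reset_index(drop=True)
    a = lk.ld_prune(gm, markers)
    b = lk.ld_prune(gm, markers)
    assert a == b


def test_prune_threshold_monotone(rng):
    gm = random_matrix(rng, 25, 15, missing_rate=0)
    markers = trivial_markers(gm)
    lo = set(lk.ld_prune(gm, markers, r2_threshold=0.3))
    hi = set(lk.ld_prune(gm, markers, r2_threshold=0.8))
    assert lo <= hi


# ----------------------------------------------------------------------
# panel selection
# ----------------------------------------------------------------------

def test_panel_infeasible_target_warns(small_collection):
    gm = small_collection["gm"]
    res = lk.select_panel(gm, small_collection["markers"],
                          small_collection["samples"], size_target=10_000)
    assert not res.feasible
    assert res.notes


def test_panel_rules_audited(small_collection):
    from germpop.diversity import allele_frequencies

    gm = small_collection["gm"]
    markers = small_collection["markers"]
    samples = small_collection["samples"]
    res = lk.select_panel(gm, markers, samples, size_target=60)
    assert len(res.marker_ids) <= 60
    idx = [gm.marker_ids.index(m) for m in res.marker_ids]
    sub = gm.subset_markers(idx)
    pools = samples.set_index("accession_id").loc[
        gm.accession_ids, "gene_pool"].to_numpy()
    for pool in ("Andean", "Mesoamerican"):
        p = allele_frequencies(sub, pools == pool)
        assert np.all((np.nan_to_num(p) > 0)
                      & (np.nan_to_num(p, nan=1.0) < 1))
    # exhaustive pairwise r2 audit within chromosomes
    msub = markers.set_index("marker_id").loc[res.marker_ids].reset_index()
    rec = lk.pairwise_r2(sub, msub, maf_min=0.0)
    assert (rec["r2"] < 0.5).all()
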