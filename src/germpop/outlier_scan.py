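"""Detection of loci under divergent selection.

Two routes are implemented and can be intersected:

* an FDIST-style simulation envelope under a hierarchical island model
  (two groups, two demes per group): Balding-Nichols tiers with
  between-group ``F_CT`` and within-group ``F_SC`` parameters, binomial
  sampling at the observed sample sizes, and classification of observed
  loci against heterozygosity-conditioned quantiles of the simulated
  (het, FST) cloud;
* a Bayesian logistic FST decomposition ``logit(FST_ij) = alpha_i +
  beta_j`` with a spike-and-slab prior on the locus effects ``alpha_i``
  (point mass at zero; the posterior inclusion probability plays the
  role of the reversible-jump indicator) sampled by Metropolis-Hastings
  on the beta-binomial marginal likelihood, reported as posterior
  inclusion probabilities and q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from germpop.diversity import allele_frequencies
from germpop.genotype_io import GenotypeMatrix
from germpop.simulate import simulate_pool_freqs


# ----------------------------------------------------------------------
# hierarchical island null envelope
# ----------------------------------------------------------------------

@dataclass
class HierIslandConfig:
    f_ct: float                       # between-group divergence tier
    f_sc: float                       # among-deme within-group tier
    sample_sizes: tuple               # chromosomes per deme, groups nested
    n_groups: int = 2
    demes_per_group: int = 2
    n_sims: int = 20_000

    def validate(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.f_ct < 0 or self.f_sc < 0:
            raise ValueError("divergence parameters must be >= 0")
        if len(self.sample_sizes) != self.n_groups * self.demes_per_group:
            raise ValueError("sample_sizes must list every deme")


def _group_stats_from_deme_freqs(deme_freqs, n_groups, demes_per_group):
    """Per-locus (het, fst) from deme sample frequencies.

    Group frequency is the unweighted mean of its demes; ``Hs`` averages
    the group heterozygosities, ``Ht`` uses the grand mean frequency, and
    the recorded heterozygosity is ``Ht``.
    """
    g = deme_freqs.reshape(-1, n_groups, demes_per_group).mean(axis=2)
    hs = (2 * g * (1 - g)).mean(axis=1)
    pbar = g.mean(axis=1)
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    return ht, fst


def fdist_null_simulation(config: HierIslandConfig, rng) -> pd.DataFrame:
    """Simulate the (heterozygosity, FST) null cloud.

    Per simulated locus: ancestral frequency ~ U(0.01, 0.99); group
    frequencies via Balding-Nichols at ``F_CT``; deme frequencies via a
    second tier at ``F_SC``; binomial samples at the observed sizes.
    Loci monomorphic in the sample are dropped.
    """
    config.validate()
    return _island_draw(config, rng)


def _island_draw(config: HierIslandConfig, rng) -> pd.DataFrame:
    n = config.n_sims
    p_anc = rng.uniform(0.01, 0.99, size=n)
    sizes = np.asarray(config.sample_sizes, dtype=int)
    deme_freqs = np.empty((n, sizes.size))
    col = 0
    for _g in range(config.n_groups):
        gf = simulate_pool_freqs(p_anc, config.f_ct, rng) \
            if config.f_ct > 0 else p_anc
        gf = np.clip(gf, 1e-9, 1 - 1e-9)
        for _d in range(config.demes_per_group):
            df_ = simulate_pool_freqs(gf, config.f_sc, rng) \
                if config.f_sc > 0 else gf
            deme_freqs[:, col] = rng.binomial(sizes[col], df_) / sizes[col]
            col += 1
    het, fst = _group_stats_from_deme_freqs(
        deme_freqs, config.n_groups, config.demes_per_group)
    out = pd.DataFrame({"het": het, "fst": fst})
    return out[(out["het"] > 0) & np.isfinite(out["fst"])].reset_index(drop=True)


def calibrate_island_model(target_fst, sample_sizes, f_sc=0.02, rng=None,
                           n_sims=4000, tol=0.005, max_iter=25) -> HierIslandConfig:
    """Choose ``F_CT`` by bisection so the mean simulated between-group FST
    matches ``target_fst`` (method-of-moments on the generative model).
    """
    if target_fst <= 0:
        raise ValueError("calibration FST must be > 0")
    rng = np.random.default_rng(0 if rng is None else rng)
    seed = int(rng.integers(2 ** 31))
    lo, hi = 1e-4, 1 - 1e-4

    def mean_fst(f_ct):
        cfg = HierIslandConfig(f_ct, f_sc, tuple(sample_sizes), n_sims=n_sims)
        cloud = _island_draw(cfg, np.random.default_rng(seed))
        return float(cloud["fst"].mean())

    if mean_fst(hi) < target_fst:
        return HierIslandConfig(hi, f_sc, tuple(sample_sizes))
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = mean_fst(mid)
        if abs(val - target_fst) < tol:
            break
        if val < target_fst:
            lo = mid
        else:
            hi = mid
    else:
        mid = 0.5 * (lo + hi)
    return HierIslandConfig(mid, f_sc, tuple(sample_sizes))


def observed_locus_stats(gm: GenotypeMatrix, deme_masks: dict) -> pd.DataFrame:
    """Observed per-locus (het, fst) under the same group/deme convention.

    ``deme_masks`` maps group name -> list of deme accession masks.
    """
    freqs = []
    for _group, masks in deme_masks.items():
        for m in masks:
            freqs.append(allele_frequencies(gm, m))
    deme_freqs = np.vstack(freqs).T
    n_groups = len(deme_masks)
    demes_per_group = len(next(iter(deme_masks.values())))
    het, fst = _group_stats_from_deme_freqs(
        np.nan_to_num(deme_freqs), n_groups, demes_per_group)
    ok = ~np.isnan(deme_freqs).any(axis=1)
    het = np.where(ok, het, np.nan)
    fst = np.where(ok, fst, np.nan)
    return pd.DataFrame({"marker_id": gm.marker_ids, "het": het, "fst": fst})


def fdist_classify(observed: pd.DataFrame, cloud: pd.DataFrame,
                   alpha: float = 0.05, n_bins: int = 15,
                   min_bin_sims: int = 200) -> pd.DataFrame:
    """Classify observed loci against heterozygosity-conditioned envelopes.

    Simulated loci are split into ``n_bins`` equal-count heterozygosity
    bins (reduced if the cloud cannot give every bin >= ``min_bin_sims``
    members); per observed locus the upper/lower empirical p-values
    (``count / n``, duplication-invariant) are computed within its bin and
    the locus is an outlier when it falls outside the central
    ``1 - alpha`` envelope.  Monomorphic loci (het = 0 or undefined) get
    no call.
    """
    if len(cloud) == 0:
        raise ValueError("empty simulated cloud")
    if len(cloud) < n_bins:
        raise ValueError("cloud smaller than the number of bins")
    if len(cloud) < n_bins * min_bin_sims:
        warnings.warn(f"fewer than {min_bin_sims} simulations per bin",
                      stacklevel=2)
    het_sim = cloud["het"].to_numpy()
    fst_sim = cloud["fst"].to_numpy()
    # quantile edges: equal-count for continuous het and invariant to
    # duplication of the cloud
    inner_edges = np.quantile(het_sim, np.linspace(0, 1, n_bins + 1)[1:-1])
    which = np.searchsorted(inner_edges, het_sim, side="right")
    sorted_fst = [np.sort(fst_sim[which == b]) for b in range(n_bins)]
    bin_lo = inner_edges

    out = observed.copy()
    p_up = np.full(len(out), np.nan)
    p_lo = np.full(len(out), np.nan)
    oob = np.zeros(len(out), dtype=bool)
    callable_ = (out["het"].to_numpy() > 0) & np.isfinite(out["fst"].to_numpy())
    nonempty = [b for b in range(n_bins) if sorted_fst[b].size]
    for i in np.flatnonzero(callable_):
        h, f = out["het"].iloc[i], out["fst"].iloc[i]
        b = int(np.searchsorted(bin_lo, h, side="right"))
        if h < het_sim.min() or h > het_sim.max():
            oob[i] = True
        if not sorted_fst[b].size:  # tie-induced empty bin: nearest rule
            b = min(nonempty, key=lambda c: abs(c - b))
        s = sorted_fst[b]
        n = s.size
        lo_idx = np.searchsorted(s, f, side="left")
        hi_idx = np.searchsorted(s, f, side="right")
        n_gt = n - hi_idx
        n_lt = lo_idx
        n_eq = hi_idx - lo_idx
        # mid-p: ties (discrete sample FST values) split half-and-half
        p_up[i] = (n_gt + 0.5 * n_eq) / n
        p_lo[i] = (n_lt + 0.5 * n_eq) / n
    out["p_upper"] = p_up
    out["p_lower"] = p_lo
    out["het_out_of_range"] = oob
    out["fdist_outlier_high"] = p_up < alpha / 2
    out["fdist_outlier_low"] = p_lo < alpha / 2
    out["fdist_outlier"] = out["fdist_outlier_high"] | out["fdist_outlier_low"]
    out["no_call"] = ~callable_
    return out


# ----------------------------------------------------------------------
# Bayesian logistic FST decomposition (spike-and-slab)
# ----------------------------------------------------------------------

@dataclass
class BayesRunParams:
    n_pilot: int = 8
    pilot_len: int = 150
    burn_in: int = 500
    n_iter: int = 1500
    thin: int = 5
    slab_sd: float = 1.8
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.8
    prior_inclusion: float = 0.1
    seed: int = 0


@dataclass
class BayesReport:
    table: pd.DataFrame
    beta: np.ndarray
    fst_deme: np.ndarray               # posterior mean expit(beta_j)
    acceptance: dict
    warnings: list = field(default_factory=list)


def _counts_from_matrix(gm: GenotypeMatrix, subpop_masks: dict):
    alt, tot = [], []
    for m in subpop_masks.values():
        mask = np.asarray(m)
        calls = gm.calls[mask] if mask.dtype == bool else gm.calls[mask]
        typed = calls != -1
        alt.append(np.where(typed, calls, 0).sum(axis=0))
        tot.append(2 * typed.sum(axis=0))
    return np.vstack(alt).T.astype(float), np.vstack(tot).T.astype(float)


def _loglik(x, n, p, alpha, beta):
    """Beta-binomial marginal log-likelihood, constants dropped.

    ``theta_ij = 1/fst_ij - 1`` with ``logit(fst_ij) = alpha_i + beta_j``.
    """
    f = expit(alpha[:, None] + beta[None, :])
    theta = 1.0 / np.clip(f, 1e-12, 1 - 1e-12) - 1.0
    a = theta * p[:, None]
    b = theta * (1.0 - p[:, None])
    return betaln(x + a, n - x + b) - betaln(a, b)


def bayes_fst_mcmc(gm_or_counts, subpop_masks=None,
                   params: BayesRunParams | None = None) -> BayesReport:
    """Spike-and-slab sampler for per-locus selection effects.

    Accepts either a :class:`GenotypeMatrix` plus subpopulation masks or a
    pre-built ``(alt_counts, total_counts)`` pair of (loci x demes) arrays.
    Returns posterior inclusion probabilities and q-values (default
    decision rule q < 0.05).
    """
    params = params or BayesRunParams()
    if isinstance(gm_or_counts, GenotypeMatrix):
        x, n = _counts_from_matrix(gm_or_counts, subpop_masks)
        ids = list(gm_or_counts.marker_ids)
    else:
        x, n = (np.asarray(a, dtype=float) for a in gm_or_counts)
        ids = [f"locus{i}" for i in range(x.shape[0])]
    if x.shape[1] < 2:
        raise ValueError("need at least two subpopulations")
    L, J = x.shape
    rng = np.random.default_rng(params.seed)

    usable = n.min(axis=1) > 0
    p = np.clip((x.sum(axis=1) + 1) / (n.sum(axis=1) + 2), 1e-4, 1 - 1e-4)
    alpha = np.zeros(L)
    delta = np.zeros(L, dtype=bool)
    beta = np.full(J, params.beta_prior_mean)
    ll = _loglik(x, n, p, alpha, beta)

    s_p, s_a, s_b = 0.3, 0.8, 0.1
    acc = {"p": [], "alpha": [], "beta": []}
    log_odds_incl = np.log(params.prior_inclusion / (1 - params.prior_inclusion))

    # data-informed independence proposal for the spike<->slab jump:
    # center on the moment estimate of the locus effect so that strongly
    # divergent loci are proposed where their likelihood lives
    p_hat = np.divide(x, n, out=np.full_like(x, 0.5), where=n > 0)
    pbar = p_hat.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst_mom = np.clip(p_hat.var(axis=1, ddof=0)
                          / np.maximum(pbar * (1 - pbar), 1e-6), 1e-3, 0.999)
    global_mom = float(np.median(fst_mom))
    jump_mu = np.clip(logit(fst_mom) - logit(global_mom), -8, 8)
    jump_sd = 1.0

    def _log_norm(v, mu, sd):
        return -0.5 * ((v - mu) / sd) ** 2 - np.log(sd)

    def sweep(record_acc=False):
        nonlocal p, alpha, delta, beta, ll
        # ancestral frequencies (uniform prior, logit-space walk + Jacobian)
        lp = logit(p) + rng.normal(0, s_p, size=L)
        p_new = np.clip(expit(lp), 1e-6, 1 - 1e-6)
        ll_new = _loglik(x, n, p_new, alpha, beta)
        ratio = (ll_new.sum(axis=1) - ll.sum(axis=1)
                 + np.log(p_new * (1 - p_new)) - np.log(p * (1 - p)))
        take = (np.log(rng.random(L)) < ratio) & usable
        p = np.where(take, p_new, p)
        ll[take] = ll_new[take]
        acc_p = float(take.mean())

        # slab effects for included loci
        a_new = np.where(delta, alpha + rng.normal(0, s_a, size=L), alpha)
        ll_new = _loglik(x, n, p, a_new, beta)
        prior = (a_new ** 2 - alpha ** 2) / (-2 * params.slab_sd ** 2)
        ratio = ll_new.sum(axis=1) - ll.sum(axis=1) + prior
        take = (np.log(rng.random(L)) < ratio) & delta & usable
        alpha = np.where(take, a_new, alpha)
        ll[take] = ll_new[take]
        n_incl = max(int(delta.sum()), 1)
        acc_a = float(take.sum() / n_incl)

        # spike <-> slab jump (independence proposal around the moment
        # estimate; proposal and slab-prior densities enter the ratio)
        draw = rng.normal(jump_mu, jump_sd, size=L)
        a_prop = np.where(delta, 0.0, draw)
        ll_new = _loglik(x, n, p, a_prop, beta)
        dll = ll_new.sum(axis=1) - ll.sum(axis=1)
        lp_slab_new = _log_norm(draw, 0.0, params.slab_sd)
        lp_slab_old = _log_norm(alpha, 0.0, params.slab_sd)
        lg_new = _log_norm(draw, jump_mu, jump_sd)
        lg_old = _log_norm(alpha, jump_mu, jump_sd)
        ratio = np.where(
            delta,
            dll - log_odds_incl - lp_slab_old + lg_old,   # slab -> spike
            dll + log_odds_incl + lp_slab_new - lg_new)   # spike -> slab
        take = (np.log(rng.random(L)) < ratio) & usable
        alpha = np.where(take, a_prop, alpha)
        delta = np.where(take, ~delta, delta)
        ll[take] = ll_new[take]

        # deme effects
        acc_b = 0.0
        for j in range(J):
            b_new = beta.copy()
            b_new[j] += rng.normal(0, s_b)
            ll_new = _loglik(x, n, p, alpha, b_new)
            prior = ((b_new[j] - params.beta_prior_mean) ** 2
                     - (beta[j] - params.beta_prior_mean) ** 2) \
                / (-2 * params.beta_prior_sd ** 2)
            if np.log(rng.random()) < ll_new.sum() - ll.sum() + prior:
                beta = b_new
                ll = ll_new
                acc_b += 1.0 / J
        if record_acc:
            acc["p"].append(acc_p)
            acc["alpha"].append(acc_a)
            acc["beta"].append(acc_b)
        return acc_p, acc_a, acc_b

    # pilot adaptation of proposal scales
    for _ in range(params.n_pilot):
        rates = np.zeros(3)
        for _ in range(params.pilot_len):
            rates += sweep()
        rates /= params.pilot_len
        s_p *= np.exp(rates[0] - 0.3)
        s_a *= np.exp(rates[1] - 0.3)
        s_b *= np.exp(rates[2] - 0.3)

    for _ in range(params.burn_in):
        sweep()

    incl_sum = np.zeros(L)
    fst_deme_sum = np.zeros(J)
    n_samples = 0
    for it in range(params.n_iter):
        sweep(record_acc=True)
        if it % params.thin == 0:
            incl_sum += delta
            fst_deme_sum += expit(beta)
            n_samples += 1
    pip = incl_sum / n_samples
    fst_deme = fst_deme_sum / n_samples

    warnings_ = []
    mean_acc = {k: float(np.mean(v)) for k, v in acc.items()}
    for k, v in mean_acc.items():
        if k != "alpha" and not 0.1 <= v <= 0.7:
            warnings_.append(f"{k} acceptance {v:.2f} outside [0.1, 0.7]")

    q = q_values_from_pip(pip)
    table = pd.DataFrame({
        "marker_id": ids, "pip": pip, "qvalue": q,
        "bayes_outlier": q < 0.05, "usable": usable,
    })
    return BayesReport(table, beta, fst_deme, mean_acc, warnings_)


def q_values_from_pip(pip: np.ndarray) -> np.ndarray:
    """BayeScan-style q-values: running mean of (1 - PIP) down the ranking."""
    order = np.argsort(-pip, kind="stable")
    fdr = np.cumsum(1.0 - pip[order]) / np.arange(1, len(pip) + 1)
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(fdr)
    q[order] = fdr
    return np.clip(q, 0, 1)


# ----------------------------------------------------------------------
# intersection
# ----------------------------------------------------------------------

def intersect_outliers(*reports, flag_columns=None) -> pd.DataFrame:
    """Intersect outlier calls from several reports on the same loci.

    Each report needs a ``marker_id`` column and one boolean flag column
    (auto-detected among ``fdist_outlier`` / ``bayes_outlier`` / ``joint``
    unless given).  Raises if the locus universes differ.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports")
    universe = set(reports[0]["marker_id"])
    for r in reports[1:]:
        if set(r["marker_id"]) != universe:
            raise ValueError("reports cover different locus sets")
    flags = None
    provenance = {}
    for k, r in enumerate(reports):
        if flag_columns is not None:
            col = flag_columns[k]
        else:
            col = next(c for c in ("fdist_outlier", "bayes_outlier", "joint")
                       if c in r.columns)
        s = r.set_index("marker_id")[col].astype(bool)
        provenance[f"flag_{k}_{col}"] = s
        flags = s if flags is None else (flags & s)
    out = pd.DataFrame(provenance)
    out["joint"] = flags
    return out.reset_index().rename(columns={"index": "marker_id"})
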