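"""Non-overlapping window statistics along chromosomes.

Windows are half-open ``[start, start + L)``: a marker whose 1-based
position equals a window's end coordinate belongs to the next window.
Window statistics are computed from SNP data only; invariant sites are
unobserved, so per-site values depend on the ``normalization`` choice
(``window_length`` by default, ``genotyped_marker_count`` or ``none``
as alternatives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from germpop.diversity import heterozygosity
from germpop.genotype_io import GenotypeMatrix

WINDOW_LENGTH = 100_000


@dataclass
class Window:
    chrom: str
    start: int            # half-open [start, end); position p belongs iff start <= p < end
    end: int
    marker_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def make_windows(genome_map: pd.Series, markers: pd.DataFrame | None = None,
                 length: int = WINDOW_LENGTH) -> list[Window]:
    """Tile each chromosome with ``ceil(L_chrom / length)`` windows.

    Markers (optional) are assigned by position with the half-open rule;
    positions beyond the chromosome length go to the terminal window with
    a warning.
    """
    windows: list[Window] = []
    index_of: dict[tuple, int] = {}
    for chrom, clen in genome_map.items():
        n_win = int(np.ceil(clen / length))
        for k in range(n_win):
            index_of[(chrom, k)] = len(windows)
            windows.append(Window(str(chrom), k * length,
                                  min((k + 1) * length, int(clen))))
    if markers is not None:
        assign: list[list[int]] = [[] for _ in windows]
        n_beyond = 0
        for i, (chrom, pos) in enumerate(zip(markers["chrom"], markers["pos"])):
            if chrom not in genome_map.index:
                continue
            clen = genome_map[chrom]
            n_win = int(np.ceil(clen / length))
            k = int(pos) // length
            if pos > clen:
                n_beyond += 1
            k = min(k, n_win - 1)
            assign[index_of[(chrom, k)]].append(i)
        if n_beyond:
            warnings.warn(f"{n_beyond} markers beyond chromosome length "
                          "assigned to terminal windows", stacklevel=2)
        for w, idx in zip(windows, assign):
            w.marker_index = np.asarray(idx, dtype=int)
    return windows


# ----------------------------------------------------------------------
# per-window statistics
# ----------------------------------------------------------------------

def _denominator(window: Window, n_typed_markers: int, normalization: str) -> float:
    if normalization == "window_length":
        return float(window.end - window.start)
    if normalization == "genotyped_marker_count":
        return float(max(n_typed_markers, 1))
    if normalization == "none":
        return 1.0
    raise ValueError(f"unknown normalization {normalization!r}")


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def window_theta_pi(gm: GenotypeMatrix, group_mask, window: Window,
                    normalization: str = "window_length"):
    """Segregating sites, Watterson's theta, pi and within-diversity.

    ``pi`` sums per-marker unbiased expected heterozygosity (equal to the
    mean pairwise difference among sampled chromosomes); ``nd_within``
    uses the uncorrected ``2pq`` form.  Both are divided by the same
    normalization denominator as ``theta_w``.
    """
    idx = window.marker_index
    if idx.size == 0:
        return dict(S=0, theta_w=0.0, pi=0.0, nd_within=0.0, n_markers=0)
    het = heterozygosity(gm.subset_markers(idx), group_mask)
    p = het["p"].to_numpy()
    defined = np.isfinite(p)
    seg = defined & (p > 0) & (p < 1)
    S = int(seg.sum())
    n_chrom = 2 * int(np.asarray(group_mask).sum()) if group_mask is not None \
        else 2 * gm.n_accessions
    denom = _denominator(window, int(defined.sum()), normalization)
    a_n = harmonic_number(n_chrom)
    theta_w = S / a_n / denom
    pi = float(np.nansum(het["uhe"].to_numpy()[seg])) / denom
    nd_within = float(np.nansum(het["he"].to_numpy()[seg])) / denom
    return dict(S=S, theta_w=theta_w, pi=pi, nd_within=nd_within,
                n_markers=int(defined.sum()))


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalization constants for n sampled chromosomes."""
    if n < 4:
        raise ValueError("need at least 4 sampled chromosomes")
    a1 = harmonic_number(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def window_tajima_d(gm: GenotypeMatrix, group_mask, window: Window):
    """Tajima's D for one window; NaN when S = 0 (undefined, never 0)."""
    idx = window.marker_index
    if idx.size == 0:
        return np.nan
    het = heterozygosity(gm.subset_markers(idx), group_mask)
    p = het["p"].to_numpy()
    seg = np.isfinite(p) & (p > 0) & (p < 1)
    S = int(seg.sum())
    if S == 0:
        return np.nan
    n_chrom = 2 * int(np.asarray(group_mask).sum()) if group_mask is not None \
        else 2 * gm.n_accessions
    const = tajima_constants(n_chrom)
    pi_sum = float(np.nansum(het["uhe"].to_numpy()[seg]))
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    if var <= 0:
        return np.nan
    return float((pi_sum - S / const["a1"]) / np.sqrt(var))


def window_fst(gm: GenotypeMatrix, mask_a, mask_b, window: Window,
               estimator: str = "hudson"):
    """Between-group FST over the markers of one window.

    Default is the Hudson ratio-of-sums estimator
    ``1 - sum(Hw) / sum(Hb)`` with ``Hw`` the mean within-group unbiased
    heterozygosity and ``Hb = pa(1-pb) + pb(1-pa)``; ``'nei'`` averages
    the per-locus Nei ``(Ht - Hs)/Ht``.
    """
    idx = window.marker_index
    if idx.size == 0:
        return np.nan
    sub = gm.subset_markers(idx)
    het_a = heterozygosity(sub, mask_a)
    het_b = heterozygosity(sub, mask_b)
    pa, pb = het_a["p"].to_numpy(), het_b["p"].to_numpy()
    ok = np.isfinite(pa) & np.isfinite(pb)
    poly = ok & ~(((pa == pb) & ((pa == 0) | (pa == 1))))
    if not poly.any():
        return np.nan
    if estimator == "hudson":
        hw = (het_a["uhe"].to_numpy() + het_b["uhe"].to_numpy()) / 2.0
        hb = pa * (1 - pb) + pb * (1 - pa)
        num = np.nansum(hw[poly])
        den = np.nansum(hb[poly])
        return float(1.0 - num / den) if den > 0 else np.nan
    if estimator == "nei":
        hs = (het_a["he"].to_numpy() + het_b["he"].to_numpy()) / 2.0
        pbar = (pa + pb) / 2.0
        ht = 2 * pbar * (1 - pbar)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(ht > 0, (ht - hs) / ht, np.nan)
        return float(np.nanmean(f[poly]))
    raise ValueError(f"unknown estimator {estimator!r}")


def scan_table(gm: GenotypeMatrix, markers: pd.DataFrame,
               genome_map: pd.Series, group_mask=None,
               fst_groups: tuple | None = None,
               length: int = WINDOW_LENGTH,
               normalization: str = "window_length",
               estimator: str = "hudson") -> pd.DataFrame:
    """Per-window statistics table (the CSV artifact of the scan stage)."""
    windows = make_windows(genome_map, markers, length)
    rows = []
    for w in windows:
        stats = window_theta_pi(gm, group_mask, w, normalization)
        d = window_tajima_d(gm, group_mask, w) if stats["S"] > 0 else np.nan
        fst = np.nan
        if fst_groups is not None:
            fst = window_fst(gm, fst_groups[0], fst_groups[1], w, estimator)
        rows.append(dict(chrom=w.chrom, start=w.start, end=w.end,
                         S=stats["S"], theta_w=stats["theta_w"],
                         pi=stats["pi"], nd_within=stats["nd_within"],
                         tajima_d=d, fst=fst))
    return pd.DataFrame(rows)


def windows_to_bed(windows: list[Window], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")
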