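"""Genotype matrix I/O (wide DArT-style tables and VCF) and per-marker QC.

Conventions
-----------
* Calls are alternate-allele dosages in ``{0, 1, 2}``; missing calls are
  stored as :data:`MISSING` (``-1``) in an ``int8`` array of shape
  ``(n_accessions, n_markers)``.
* Positions are 1-based (VCF style).  Which allele is "alternate" is taken
  from file order and never re-polarized.
* Marker metadata travels as a :class:`pandas.DataFrame` with one row per
  marker (columns ``marker_id, chrom, pos, ref, alt`` plus QC columns);
  sample metadata as a DataFrame with one row per accession.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING: int = -1

#: call symbols mapped to missing when reading wide tables
DEFAULT_MISSING_CODES = ("-", "NA", "", "9")

UNPLACED = "unplaced"

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt"]


class DuplicateIdError(ValueError):
    """Raised when marker or accession identifiers are not unique."""


@dataclass
class GenotypeMatrix:
    """Accessions x markers alternate-allele dosage matrix.

    Parameters
    ----------
    calls
        ``int8`` array, shape ``(n_accessions, n_markers)``, values in
        ``{0, 1, 2, MISSING}``.
    accession_ids, marker_ids
        Ordered unique identifiers for rows / columns.
    """

    calls: np.ndarray
    accession_ids: list = field(default_factory=list)
    marker_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.accession_ids = list(self.accession_ids)
        self.marker_ids = list(self.marker_ids)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        n, m = self.calls.shape
        if len(self.accession_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lists inconsistent with matrix shape")
        if len(set(self.accession_ids)) != n:
            raise DuplicateIdError("duplicate accession ids")
        if len(set(self.marker_ids)) != m:
            raise DuplicateIdError("duplicate marker ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"{bad.sum()} calls outside {{0,1,2,{MISSING}}}"
            )

    # -- basic views ---------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def typed_mask(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def subset_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.accession_ids,
            [self.marker_ids[i] for i in index],
        )

    def subset_accessions(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[index, :],
            [self.accession_ids[i] for i in index],
            self.marker_ids,
        )

    def accession_indexer(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        return np.array([lookup[a] for a in ids], dtype=int)


# ----------------------------------------------------------------------
# wide (DArT-style) tables
# ----------------------------------------------------------------------

def read_wide_table(path, missing_codes=DEFAULT_MISSING_CODES, sep=None):
    """Read a markers x accessions dosage table.

    Expected layout: columns ``marker_id, chrom, pos`` followed by one
    column per accession; one row per marker.  Unknown call symbols map
    to missing.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    meta_cols = [c for c in ("marker_id", "chrom", "pos", "ref", "alt")
                 if c in df.columns]
    if "marker_id" not in meta_cols:
        raise ValueError("wide table must have a marker_id column")
    acc_ids = [c for c in df.columns if c not in meta_cols]
    if len(set(acc_ids)) != len(acc_ids):
        raise DuplicateIdError("duplicate accession ids in header")
    if df["marker_id"].duplicated().any():
        raise DuplicateIdError("duplicate marker ids")

    raw = df[acc_ids].to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    for code, dosage in (("0", 0), ("1", 1), ("2", 2)):
        calls[raw == code] = dosage
    known = set(missing_codes) | {"0", "1", "2"}
    unknown = np.isin(raw, list(known), invert=True)
    if unknown.any():
        log.warning("%d unknown call symbols mapped to missing", unknown.sum())
    # missing codes (and unknowns) stay MISSING
    gm = GenotypeMatrix(calls.T, acc_ids, df["marker_id"].tolist())

    markers = pd.DataFrame({"marker_id": df["marker_id"]})
    markers["chrom"] = df["chrom"] if "chrom" in df else UNPLACED
    if "pos" in df:
        markers["pos"] = pd.to_numeric(df["pos"], errors="coerce").fillna(0).astype(int)
    else:
        markers["pos"] = 0
    markers["ref"] = df["ref"] if "ref" in df else "A"
    markers["alt"] = df["alt"] if "alt" in df else "C"
    markers = markers.reset_index(drop=True)
    return gm, markers


def write_wide_table(gm: GenotypeMatrix, markers: pd.DataFrame, path,
                     missing_code="-", sep=","):
    """Inverse of :func:`read_wide_table` (round-trips calls and ids)."""
    out = markers[["marker_id", "chrom", "pos", "ref", "alt"]].copy()
    body = gm.calls.T.astype(object)
    body[body == MISSING] = missing_code
    for j, acc in enumerate(gm.accession_ids):
        out[acc] = body[:, j]
    out.to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def read_vcf(path):
    """Read biallelic SNPs from a VCF; multi-allelic records are skipped.

    Returns ``(GenotypeMatrix, markers, n_skipped)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    acc_ids = list(vcf.samples)
    rows, meta, n_skipped = [], [], 0
    # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
    dosage_of = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        rows.append(dosage_of[np.asarray(v.gt_types)])
        meta.append((v.ID or f"{v.CHROM}_{v.POS}", v.CHROM, v.POS,
                     v.REF, v.ALT[0]))
    vcf.close()
    if n_skipped:
        log.info("skipped %d non-biallelic VCF records", n_skipped)
    calls = (np.vstack(rows).T if rows
             else np.empty((len(acc_ids), 0), dtype=np.int8))
    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    gm = GenotypeMatrix(calls, acc_ids, markers["marker_id"].tolist())
    return gm, markers, n_skipped


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, markers: pd.DataFrame, path,
              drop_unplaced=False):
    """Write a VCF 4.2 file (dosage 0/1/2 -> 0/0, 0/1, 1/1; missing -> ./.)."""
    unplaced = (markers["chrom"].astype(str) == UNPLACED) | (markers["pos"] <= 0)
    if unplaced.any():
        if not drop_unplaced:
            raise ValueError(
                f"{unplaced.sum()} unplaced markers; pass drop_unplaced=True"
            )
        keep = np.flatnonzero(~unplaced.to_numpy())
        gm = gm.subset_markers(keep)
        markers = markers.iloc[keep].reset_index(drop=True)
    chroms = pd.unique(markers["chrom"].astype(str))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=germpop\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.accession_ids)) + "\n")
        calls = gm.calls
        for i, row in markers.iterrows():
            gts = "\t".join(_GT_STR[int(g)] for g in calls[:, i])
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{row.marker_id}\t"
                     f"{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_two_row_table(path, missing_codes=DEFAULT_MISSING_CODES, sep=None):
    """Read a two-row presence/absence table (one row per allele).

    Consecutive rows sharing a ``marker_id`` carry reference- and
    alternate-allele presence (1/0); dosage is derived as
    ``(1,0) -> 0``, ``(1,1) -> 1``, ``(0,1) -> 2`` and ``(0,0)`` or any
    missing code -> missing.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    meta_cols = [c for c in ("marker_id", "chrom", "pos", "ref", "alt")
                 if c in df.columns]
    acc_ids = [c for c in df.columns if c not in meta_cols]
    if len(df) % 2:
        raise ValueError("two-row table must have an even number of rows")
    ids = df["marker_id"].to_numpy()
    if not (ids[0::2] == ids[1::2]).all():
        raise ValueError("row pairs must share a marker_id")
    if pd.Series(ids[0::2]).duplicated().any():
        raise DuplicateIdError("duplicate marker ids")

    raw = df[acc_ids].to_numpy(dtype=object)
    present = np.full(raw.shape, -1, dtype=np.int8)
    present[raw == "1"] = 1
    present[raw == "0"] = 0
    ref_rows = present[0::2]
    alt_rows = present[1::2]
    calls = np.full(ref_rows.shape, MISSING, dtype=np.int8)
    ok = (ref_rows >= 0) & (alt_rows >= 0)
    calls[ok & (ref_rows == 1) & (alt_rows == 0)] = 0
    calls[ok & (ref_rows == 1) & (alt_rows == 1)] = 1
    calls[ok & (ref_rows == 0) & (alt_rows == 1)] = 2
    gm = GenotypeMatrix(calls.T, acc_ids, ids[0::2].tolist())
    meta = df.iloc[0::2].reset_index(drop=True)
    markers = pd.DataFrame({"marker_id": ids[0::2]})
    markers["chrom"] = meta["chrom"] if "chrom" in meta else UNPLACED
    markers["pos"] = (pd.to_numeric(meta["pos"], errors="coerce")
                      .fillna(0).astype(int) if "pos" in meta else 0)
    markers["ref"] = meta["ref"] if "ref" in meta else "A"
    markers["alt"] = meta["alt"] if "alt" in meta else "C"
    return gm, markers


def read_genotype_table(path, dialect="wide-dosage", **kw):
    """Dispatching reader; ``dialect`` in
    ``{'wide-dosage', 'wide-two-row', 'vcf'}``."""
    if dialect == "wide-dosage":
        gm, markers = read_wide_table(path, **kw)
        return gm, markers
    if dialect == "wide-two-row":
        return read_two_row_table(path, **kw)
    if dialect == "vcf":
        gm, markers, _ = read_vcf(path)
        return gm, markers
    raise ValueError(f"unknown dialect {dialect!r}")


# ----------------------------------------------------------------------
# sample metadata / genome map
# ----------------------------------------------------------------------

def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df["accession_id"].duplicated().any():
        raise DuplicateIdError("duplicate accession ids in sample table")
    for col, default in (("gene_pool", "unknown"), ("stratum", "unknown"),
                         ("country", ""), ("lat", np.nan), ("lon", np.nan)):
        if col not in df:
            df[col] = default
    lat, lon = df["lat"], df["lon"]
    if ((lat.dropna().abs() > 90).any() or (lon.dropna().abs() > 180).any()):
        raise ValueError("coordinates outside valid ranges")
    return df


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_genome_map(path) -> pd.Series:
    """Genome map CSV (``chrom, length_bp``) -> Series indexed by chrom."""
    df = pd.read_csv(path)
    if df["chrom"].duplicated().any():
        raise DuplicateIdError("duplicate chromosome labels")
    if (df["length_bp"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    return df.set_index("chrom")["length_bp"]


def write_genome_map(genome_map: pd.Series, path) -> None:
    genome_map.rename("length_bp").rename_axis("chrom").reset_index().to_csv(
        path, index=False)


# ----------------------------------------------------------------------
# marker QC
# ----------------------------------------------------------------------

def allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    """Per-marker alternate-allele frequency; NaN when no typed calls."""
    typed = gm.typed_mask()
    n_typed = typed.sum(axis=0)
    alt = np.where(typed, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_typed > 0, alt / (2.0 * n_typed), np.nan)


def marker_qc(gm: GenotypeMatrix, pic_convention="dart") -> pd.DataFrame:
    """Per-marker call rate, MAF, PIC and heterozygote rate.

    ``pic_convention='dart'`` uses ``1 - p^2 - q^2`` (biallelic maximum 0.5);
    ``'botstein'`` subtracts the additional ``2 p^2 q^2`` term.
    All-missing markers get NaN QC fields (flagged, never dropped silently).
    """
    typed = gm.typed_mask()
    n_typed = typed.sum(axis=0)
    p = allele_freq(gm)
    q = 1.0 - p
    maf = np.minimum(p, q)
    pic = 2.0 * p * q
    if pic_convention == "botstein":
        pic = pic - 2.0 * (p * q) ** 2
    elif pic_convention != "dart":
        raise ValueError(f"unknown PIC convention {pic_convention!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(n_typed > 0,
                            (gm.calls == 1).sum(axis=0) / n_typed, np.nan)
    return pd.DataFrame({
        "marker_id": gm.marker_ids,
        "call_rate": n_typed / gm.n_accessions,
        "maf": maf,
        "pic": pic,
        "het_rate": het_rate,
    })


def filter_markers(gm: GenotypeMatrix, markers: pd.DataFrame,
                   min_call_rate=None, min_maf=None, placed_only=False,
                   qc: pd.DataFrame | None = None):
    """Drop markers failing any active threshold; order preserved.

    Returns ``(gm, markers, report)`` where report counts removals per rule
    (counts are non-exclusive: a marker can fail several rules).
    """
    if qc is None:
        qc = marker_qc(gm)
    keep = np.ones(gm.n_markers, dtype=bool)
    report: dict[str, int] = {}
    if min_call_rate is not None:
        fail = ~(qc["call_rate"].to_numpy() >= min_call_rate)
        report["call_rate"] = int(fail.sum())
        keep &= ~fail
    if min_maf is not None:
        fail = ~(qc["maf"].to_numpy() >= min_maf)
        report["maf"] = int(fail.sum())
        keep &= ~fail
    if placed_only:
        fail = ((markers["chrom"].astype(str) == UNPLACED)
                | (markers["pos"] <= 0)).to_numpy()
        report["unplaced"] = int(fail.sum())
        keep &= ~fail
    report["retained"] = int(keep.sum())
    if report["retained"] == 0:
        warnings.warn("all markers removed by filters", stacklevel=2)
    idx = np.flatnonzero(keep)
    return (gm.subset_markers(idx),
            markers.iloc[idx].reset_index(drop=True),
            report)


# ----------------------------------------------------------------------
# optional XLSX import (supplementary-style tables)
# ----------------------------------------------------------------------

def read_wide_xlsx(path, sheet=0, missing_codes=DEFAULT_MISSING_CODES,
                   marker_col="marker_id", chrom_col=None, pos_col=None):
    """Best-effort import of an XLSX wide genotype table.

    The sheet must have one row per marker with an identifier column and
    one column per accession carrying 0/1/2/missing call codes; extra
    non-genotype columns are detected by failing to parse as calls.
    """
    df = pd.read_excel(path, sheet_name=sheet, dtype=str)
    df = df.rename(columns={marker_col: "marker_id"})
    if chrom_col:
        df = df.rename(columns={chrom_col: "chrom"})
    if pos_col:
        df = df.rename(columns={pos_col: "pos"})
    codes = set(missing_codes) | {"0", "1", "2", "nan"}
    acc_cols = [c for c in df.columns
                if c not in ("marker_id", "chrom", "pos")
                and set(df[c].astype(str).str.strip()) <= codes]
    keep = ["marker_id"] + [c for c in ("chrom", "pos") if c in df] + acc_cols
    import io as _io
    buf = _io.StringIO()
    df[keep].to_csv(buf, index=False)
    buf.seek(0)
    return read_wide_table(buf, missing_codes=missing_codes, sep=",")
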