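"""Reading, validating and writing the tabular formats the MR pipeline touches.

All on-disk formats are plain TSV: GWAS summary statistics (one row per SNP),
square LD matrices of r-squared values, proxy-SNP lookup tables, and the
per-cohort MR result tables.  Column headers for summary statistics are
configurable because public GWAS exports (Pan-UK Biobank, IEU OpenGWAS,
FinnGen) do not agree on naming.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("coagmr")

VALID_ALLELES = frozenset("ACGT")

#: Default summary-statistics header.  Pan-UKBB and IEU exports differ, so the
#: mapping is configurable; this is the documented package default.
DEFAULT_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "NEA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "PVAL",
    "n": "N",
    "n_case": "N_CASE",
    "n_control": "N_CONTROL",
}

#: Columns every summary-statistics file must provide (others are optional).
MANDATORY_FIELDS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
                    "beta", "se", "pval")

RESULT_COLUMNS = [
    "exposure", "method", "nsnp", "beta", "se", "or", "ci_low", "ci_high",
    "pval", "pval_adjusted", "q", "q_pval", "egger_intercept",
    "intercept_pval", "steiger_direction", "steiger_pval",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele estimate (log odds for binary traits),
    ``eaf`` the effect-allele frequency (``None`` when the source omits it),
    and ``n_case``/``n_control`` are populated for binary traits only.
    Positions are 1-based, following GWAS convention.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None
    n_case: int | None = None
    n_control: int | None = None

    @property
    def z(self) -> float:
        return self.beta / self.se

    def copy(self, **changes) -> "SummaryStatRecord":
        return replace(self, **changes)


@dataclass
class RejectedRow:
    """A summary-statistics row that failed validation, with the reason code."""

    row_index: int
    snp_id: str
    reason: str


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered set of SNPs.

    Stands in for LD estimated from an external reference panel (e.g. the
    1000 Genomes European panel).  Symmetric, unit diagonal, values in [0, 1].
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self.validate()
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def validate(self, atol: float = 1e-8) -> None:
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError(
                f"LD matrix shape {self.r2.shape} does not match {n} SNP ids")
        asym = np.abs(self.r2 - self.r2.T)
        if asym.max(initial=0.0) > atol:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"LD matrix asymmetric at ({self.snp_ids[i]}, {self.snp_ids[j]}): "
                f"{self.r2[i, j]} vs {self.r2[j, i]}")
        diag = np.diag(self.r2)
        if np.any(np.abs(diag - 1.0) > atol):
            i = int(np.argmax(np.abs(diag - 1.0)))
            raise ValueError(
                f"LD matrix diagonal not 1 at {self.snp_ids[i]}: {diag[i]}")
        if self.r2.min(initial=1.0) < -atol or self.r2.max(initial=0.0) > 1 + atol:
            bad = np.unravel_index(
                np.argmax(np.clip(-self.r2, 0, None) + np.clip(self.r2 - 1, 0, None)),
                self.r2.shape)
            raise ValueError(
                f"LD r² outside [0,1] at ({self.snp_ids[bad[0]]}, "
                f"{self.snp_ids[bad[1]]}): {self.r2[bad]}")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


@dataclass
class ProxyRecord:
    """A proxy SNP standing in for an instrument absent from the outcome data.

    ``allele_map`` maps each proxy allele to the corresponding target allele;
    it must be a bijection over the two allele pairs.
    """

    target_snp: str
    proxy_snp: str
    r2: float
    distance: int
    allele_map: dict[str, str]

    def __post_init__(self) -> None:
        if not self.r2 > 0:
            raise ValueError(f"proxy r² must be positive, got {self.r2}")
        if len(self.allele_map) != 2 or len(set(self.allele_map.values())) != 2:
            raise ValueError(
                f"allele_map must be a bijection over two alleles: {self.allele_map}")


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _chrom_sort_key(chrom: str):
    c = str(chrom).removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan", "."):
        return None
    return float(s)


def _parse_optional_int(value) -> int | None:
    v = _parse_optional_float(value)
    return None if v is None else int(round(v))


def validate_record(rec: SummaryStatRecord,
                    pval_abs_tol: float = 0.05,
                    pval_ratio_tol: float = 3.0) -> str | None:
    """Return a rejection reason code, or None when the record is valid.

    The reported p-value is cross-checked against the two-sided normal tail
    of beta/se; published p-values are rounded to few significant digits, so
    agreement is required only within ``pval_ratio_tol``-fold or
    ``pval_abs_tol`` absolutely.
    """
    if rec.effect_allele not in VALID_ALLELES or rec.other_allele not in VALID_ALLELES:
        return "non_acgt_allele"
    if rec.effect_allele == rec.other_allele:
        return "identical_alleles"
    if not rec.se > 0:
        return "nonpositive_se"
    if rec.eaf is not None and not (0.0 <= rec.eaf <= 1.0):
        return "eaf_out_of_range"
    if not (0.0 < rec.pval <= 1.0):
        return "pval_out_of_range"
    p_exact = 2.0 * stats.norm.sf(abs(rec.beta) / rec.se)
    if abs(rec.pval - p_exact) > pval_abs_tol:
        if p_exact == 0.0 or not (1.0 / pval_ratio_tol
                                  <= rec.pval / p_exact
                                  <= pval_ratio_tol):
            return "pval_inconsistent"
    return None


def read_sumstats(
    path: str | Path,
    trait: str = "",
    columns: Mapping[str, str] | None = None,
) -> tuple[list[SummaryStatRecord], list[RejectedRow]]:
    """Read a TSV of GWAS summary statistics.

    Returns accepted records sorted by (chromosome, position) and the list
    of rejected rows with reason codes; accepted + rejected always equals
    the number of input rows.  Missing mandatory columns are fatal.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [colmap[f] for f in MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    records: list[SummaryStatRecord] = []
    rejects: list[RejectedRow] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        snp_id = str(row_d[colmap["snp_id"]])
        try:
            rec = SummaryStatRecord(
                snp_id=snp_id,
                chrom=str(row_d[colmap["chrom"]]),
                pos=int(float(row_d[colmap["pos"]])),
                effect_allele=str(row_d[colmap["effect_allele"]]).upper(),
                other_allele=str(row_d[colmap["other_allele"]]).upper(),
                beta=float(row_d[colmap["beta"]]),
                se=float(row_d[colmap["se"]]),
                pval=float(row_d[colmap["pval"]]),
                eaf=_parse_optional_float(row_d.get(colmap["eaf"])),
                n=_parse_optional_int(row_d.get(colmap["n"])),
                n_case=_parse_optional_int(row_d.get(colmap["n_case"])),
                n_control=_parse_optional_int(row_d.get(colmap["n_control"])),
            )
        except (TypeError, ValueError):
            rejects.append(RejectedRow(idx, snp_id, "unparseable"))
            logger.warning("%s row %d (%s): rejected (unparseable)", path, idx, snp_id)
            continue
        reason = validate_record(rec)
        if reason is not None:
            rejects.append(RejectedRow(idx, snp_id, reason))
            logger.warning("%s row %d (%s): rejected (%s)", path, idx, snp_id, reason)
        else:
            records.append(rec)
    records.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.snp_id))
    if trait:
        logger.info("%s [%s]: %d records read, %d rejected",
                    path, trait, len(records), len(rejects))
    return records, rejects


def write_sumstats(records: Iterable[SummaryStatRecord], path: str | Path) -> Path:
    """Write records in the default TSV header, full float precision."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append({
            "SNP": r.snp_id, "CHR": r.chrom, "POS": r.pos,
            "EA": r.effect_allele, "NEA": r.other_allele,
            "EAF": "NA" if r.eaf is None else repr(float(r.eaf)),
            "BETA": repr(float(r.beta)), "SE": repr(float(r.se)),
            "PVAL": repr(float(r.pval)),
            "N": "NA" if r.n is None else r.n,
            "N_CASE": "NA" if r.n_case is None else r.n_case,
            "N_CONTROL": "NA" if r.n_control is None else r.n_control,
        })
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values())).to_csv(
        path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# LD matrices and proxy tables
# ---------------------------------------------------------------------------

def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square TSV r² matrix whose first column holds the SNP ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(s) for s in df.index]
    if list(df.columns) != ids:
        raise ValueError(
            f"{path}: LD matrix is not square-labelled "
            f"(rows {ids[:3]}..., columns {list(df.columns)[:3]}...)")
    return LDMatrix(snp_ids=ids, r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("SNP\t" + "\t".join(ld.snp_ids) + "\n")
        for i, snp in enumerate(ld.snp_ids):
            fh.write(snp + "\t" + "\t".join(repr(float(v)) for v in ld.r2[i]) + "\n")
    return path


def read_proxy_table(path: str | Path) -> list[ProxyRecord]:
    """Read a proxy table: target, proxy, r2, distance, ea_map, oa_map.

    ``ea_map``/``oa_map`` entries are ``proxyAllele:targetAllele`` pairs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["target", "proxy", "r2", "distance", "ea_map", "oa_map"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: proxy table missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        amap = {}
        for token in (row.ea_map, row.oa_map):
            src, dst = str(token).split(":")
            amap[src.upper()] = dst.upper()
        out.append(ProxyRecord(
            target_snp=str(row.target), proxy_snp=str(row.proxy),
            r2=float(row.r2), distance=int(float(row.distance)),
            allele_map=amap))
    return out


def write_proxy_table(proxies: Iterable[ProxyRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for p in proxies:
        (ea_p, ea_t), (oa_p, oa_t) = list(p.allele_map.items())
        rows.append({"target": p.target_snp, "proxy": p.proxy_snp,
                     "r2": repr(float(p.r2)), "distance": p.distance,
                     "ea_map": f"{ea_p}:{ea_t}", "oa_map": f"{oa_p}:{oa_t}"})
    pd.DataFrame(rows, columns=["target", "proxy", "r2", "distance",
                                "ea_map", "oa_map"]).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_result_tables(
    tables: Mapping[str, Sequence[Mapping]],
    outdir: str | Path,
) -> list[Path]:
    """Write one TSV of MR results per cohort; numbers at 6 significant digits.

    ``tables`` maps a cohort label to rows keyed by :data:`RESULT_COLUMNS`.
    Returns the manifest of files written.
    """
    if not tables or all(len(v) == 0 for v in tables.values()):
        raise ValueError("no results to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for cohort, rows in tables.items():
        path = outdir / f"mr_results_{cohort}.tsv"
        with open(path, "w") as fh:
            fh.write("\t".join(RESULT_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(_fmt(row.get(c)) for c in RESULT_COLUMNS) + "\n")
        manifest.append(path)
        logger.info("wrote %d result rows to %s", len(rows), path)
    return manifest


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
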