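"""Ingest, merge, filter and weight missense-variant heterozygote count tables.

The basic observational unit is a missense variant of a single protein
(1-based residue numbering on one fixed transcript) together with the number
of affected and unaffected heterozygous carriers observed for it.  Affected
counts come from clinical literature curation; unaffected counts come from a
population database (gnomAD-style), whose rare-variant carriers are assumed
unaffected.  Each variant receives an evidence weight that grows with the
number of carriers observed, so that singleton reports carry almost no weight
in downstream fits.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "HeterozygoteCounts",
    "CovariateSet",
    "VariantRecord",
    "VariantTable",
    "AMINO_ACIDS",
    "CLINVAR_CODES",
    "parse_variant_id",
    "normalize_clinvar",
    "encode_clinvar",
    "observed_penetrance",
    "evidence_weight",
    "read_count_table",
    "read_population_table",
    "merge_counts",
    "write_table",
    "read_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

#: canonical ClinVar classification codes used internally
CLINVAR_CODES = ("P/LP", "VUS", "B/LB", "absent")

_CLINVAR_ALIASES = {
    "p/lp": "P/LP",
    "pathogenic": "P/LP",
    "likely pathogenic": "P/LP",
    "pathogenic/likely pathogenic": "P/LP",
    "vus": "VUS",
    "uncertain significance": "VUS",
    "uncertain_significance": "VUS",
    "variant of uncertain significance": "VUS",
    "b/lb": "B/LB",
    "benign": "B/LB",
    "likely benign": "B/LB",
    "benign/likely benign": "B/LB",
    "absent": "absent",
    "": "absent",
}


class FormatError(ValueError):
    """Raised when an input table lacks required structure."""


class UndefinedPenetranceError(ValueError):
    """Raised when observed penetrance is requested for a variant with no carriers."""


@dataclass(frozen=True)
class HeterozygoteCounts:
    """Affected / unaffected heterozygous carrier counts for one variant."""

    affected: int
    unaffected: int

    def __post_init__(self) -> None:
        if self.affected < 0 or self.unaffected < 0:
            raise ValueError("heterozygote counts must be non-negative")

    @property
    def total(self) -> int:
        return self.affected + self.unaffected

    def __add__(self, other: "HeterozygoteCounts") -> "HeterozygoteCounts":
        return HeterozygoteCounts(self.affected + other.affected,
                                  self.unaffected + other.unaffected)


@dataclass
class CovariateSet:
    """Per-variant covariate scores.

    ``revel`` and ``alphamissense`` are in-silico deleteriousness scores in
    [0, 1]; ``clinvar_code`` is a canonical clinical classification;
    ``cpvt_density`` is the structural disease-density covariate (>= 0).
    Missing values are ``None``.
    """

    revel: Optional[float] = None
    alphamissense: Optional[float] = None
    clinvar_code: str = "absent"
    cpvt_density: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("revel", "alphamissense"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score {v} outside [0, 1]")
        if self.clinvar_code not in CLINVAR_CODES:
            raise ValueError(
                f"clinvar_code {self.clinvar_code!r} not in {CLINVAR_CODES}")
        if self.cpvt_density is not None and self.cpvt_density < 0:
            raise ValueError("cpvt_density must be >= 0")


@dataclass
class VariantRecord:
    """One missense variant with its carrier counts and covariates."""

    position: int
    ref_aa: str
    alt_aa: str
    counts: HeterozygoteCounts
    weight: Optional[float] = None
    allele_frequency: Optional[float] = None
    covariates: CovariateSet = field(default_factory=CovariateSet)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("residue position must be >= 1")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt amino acids must differ")
        if self.weight is not None and not (0.0 <= self.weight <= 1.0):
            raise ValueError("weight must lie in [0, 1]")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_aa, self.alt_aa)

    @property
    def label(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


def parse_variant_id(text: str) -> tuple[int, str, str]:
    """Parse a protein-level variant identifier.

    Accepts ``p.R420W``, ``R420W`` and three-letter HGVS such as
    ``p.Arg420Trp``.
    """
    s = text.strip()
    if s.lower().startswith("p."):
        s = s[2:]
    m = re.fullmatch(r"([A-Za-z]{3})(\d+)([A-Za-z]{3})", s)
    if m and m.group(1).capitalize() in _THREE_TO_ONE and \
            m.group(3).capitalize() in _THREE_TO_ONE:
        return (int(m.group(2)),
                _THREE_TO_ONE[m.group(1).capitalize()],
                _THREE_TO_ONE[m.group(3).capitalize()])
    m = re.fullmatch(r"([A-Za-z])(\d+)([A-Za-z])", s)
    if m:
        ref, alt = m.group(1).upper(), m.group(3).upper()
        if ref in AMINO_ACIDS and alt in AMINO_ACIDS:
            return (int(m.group(2)), ref, alt)
    raise ValueError(f"unrecognized variant identifier: {text!r}")


def normalize_clinvar(label: object) -> str:
    """Map a free-form ClinVar classification string to a canonical code."""
    if label is None or (isinstance(label, float) and math.isnan(label)):
        return "absent"
    key = str(label).strip().lower()
    if key in _CLINVAR_ALIASES:
        return _CLINVAR_ALIASES[key]
    raise ValueError(
        f"unrecognized ClinVar classification {label!r}; accepted labels: "
        f"{sorted(set(_CLINVAR_ALIASES))}")


def encode_clinvar(code: str) -> Optional[float]:
    """Binary encoding of a ClinVar code for use as a model covariate.

    Pathogenic / likely pathogenic -> 1; VUS and benign / likely benign -> 0
    (clinical practice treats VUS carriers as unaffected); absent -> missing.
    Free-form strings are normalized first.
    """
    canon = code if code in CLINVAR_CODES else normalize_clinvar(code)
    if canon == "absent":
        return None
    return 1.0 if canon == "P/LP" else 0.0


def observed_penetrance(counts: HeterozygoteCounts) -> float:
    """Fraction of carriers affected: affected / (affected + unaffected)."""
    if counts.total == 0:
        raise UndefinedPenetranceError(
            "observed penetrance undefined for a variant with no heterozygotes")
    return counts.affected / counts.total


def evidence_weight(total_heterozygotes: int, form: str = "printed") -> float:
    """Evidence weight for a variant with the given carrier total.

    ``printed`` form: ``1 - 1/(0.01 + n)``, clamped to [0, 1] — near zero for
    singletons, approaching 1 for well-observed variants.  ``soft`` form:
    ``1 - 1/(1 + 0.01 n)``, a much gentler ramp.
    """
    n = total_heterozygotes
    if n < 1:
        raise ValueError("evidence weight defined only for total >= 1")
    if form == "printed":
        w = 1.0 - 1.0 / (0.01 + n)
    elif form == "soft":
        w = 1.0 - 1.0 / (1.0 + 0.01 * n)
    else:
        raise ValueError(f"unknown weight form {form!r}")
    return min(1.0, max(0.0, w))


class VariantTable:
    """Ordered collection of :class:`VariantRecord`, keyed by (position, ref, alt).

    Adding a record whose key already exists sums the counts and fills any
    missing covariates, mirroring how independent reports of the same variant
    are aggregated.
    """

    def __init__(self, records: Iterable[VariantRecord] = ()) -> None:
        self._records: dict[tuple[int, str, str], VariantRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: VariantRecord) -> None:
        key = rec.key
        if key in self._records:
            old = self._records[key]
            cov = CovariateSet(
                revel=old.covariates.revel if old.covariates.revel is not None
                else rec.covariates.revel,
                alphamissense=old.covariates.alphamissense
                if old.covariates.alphamissense is not None
                else rec.covariates.alphamissense,
                clinvar_code=old.covariates.clinvar_code
                if old.covariates.clinvar_code != "absent"
                else rec.covariates.clinvar_code,
                cpvt_density=old.covariates.cpvt_density
                if old.covariates.cpvt_density is not None
                else rec.covariates.cpvt_density,
            )
            af = old.allele_frequency if old.allele_frequency is not None \
                else rec.allele_frequency
            self._records[key] = replace(
                old, counts=old.counts + rec.counts, covariates=cov,
                allele_frequency=af, weight=None)
        else:
            self._records[key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self._records.values())

    def __contains__(self, key: tuple[int, str, str]) -> bool:
        return key in self._records

    def __getitem__(self, key: tuple[int, str, str]) -> VariantRecord:
        return self._records[key]

    def keys(self) -> list[tuple[int, str, str]]:
        return list(self._records)

    def drop(self, key: tuple[int, str, str]) -> "VariantTable":
        """Return a copy of the table without the given variant."""
        return VariantTable(r for r in self if r.key != key)

    def finalize(self, weight_form: str = "printed") -> "VariantTable":
        """Drop zero-carrier records and (re)compute evidence weights."""
        out = VariantTable()
        for rec in self:
            if rec.counts.total == 0:
                continue
            out.add(replace(
                rec, weight=evidence_weight(rec.counts.total, weight_form)))
        return out

    def sorted(self) -> "VariantTable":
        return VariantTable(sorted(self, key=lambda r: r.key))

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular view (one row per variant, sorted by key)."""
        rows = []
        for rec in sorted(self, key=lambda r: r.key):
            rows.append({
                "variant": rec.label,
                "position": rec.position,
                "ref": rec.ref_aa,
                "alt": rec.alt_aa,
                "affected": rec.counts.affected,
                "unaffected": rec.counts.unaffected,
                "total": rec.counts.total,
                "weight": rec.weight,
                "af": rec.allele_frequency,
                "revel": rec.covariates.revel,
                "alphamissense": rec.covariates.alphamissense,
                "clinvar": rec.covariates.clinvar_code,
                "density": rec.covariates.cpvt_density,
            })
        cols = ["variant", "position", "ref", "alt", "affected", "unaffected",
                "total", "weight", "af", "revel", "alphamissense", "clinvar",
                "density"]
        return pd.DataFrame(rows, columns=cols)


_DEFAULT_COLUMN_MAP = {
    "variant": "variant",
    "position": "position",
    "ref": "ref",
    "alt": "alt",
    "affected": "affected",
    "unaffected": "unaffected",
    "af": "af",
    "allele_count": "allele_count",
    "revel": "revel",
    "alphamissense": "alphamissense",
    "clinvar": "clinvar",
}


def _read_frame(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _opt_float(row, col, lo=None, hi=None, name=None):
    if col is None or col not in row or row[col] == "":
        return None
    v = float(row[col])
    if lo is not None and not (lo <= v <= (hi if hi is not None else math.inf)):
        raise ValueError(f"{name or col} value {v} out of range")
    return v


def _parse_row_key(row, cmap, rownum: int) -> tuple[int, str, str]:
    vcol = cmap.get("variant")
    if vcol and vcol in row and row[vcol] != "":
        return parse_variant_id(row[vcol])
    pcol, rcol, acol = cmap.get("position"), cmap.get("ref"), cmap.get("alt")
    if pcol in row and rcol in row and acol in row:
        return (int(row[pcol]), row[rcol].strip().upper(),
                row[acol].strip().upper())
    raise FormatError(
        f"row {rownum}: no variant identifier (need a '{vcol}' column or "
        f"'{pcol}'/'{rcol}'/'{acol}' columns)")


def read_count_table(path, source_label: str = "curated",
                     column_map: Optional[dict] = None) -> VariantTable:
    """Read a curated affected/unaffected heterozygote count table (CSV/TSV).

    Rows for the same variant are summed.  Malformed rows raise a
    :class:`ValueError` naming the 1-based data row.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_frame(path)
    have_id = cmap["variant"] in df.columns or (
        cmap["position"] in df.columns and cmap["ref"] in df.columns
        and cmap["alt"] in df.columns)
    if not have_id or cmap["affected"] not in df.columns \
            or cmap["unaffected"] not in df.columns:
        raise FormatError(
            f"{path}: missing required columns (variant identifier, "
            f"'{cmap['affected']}', '{cmap['unaffected']}'); "
            f"found {list(df.columns)}")
    table = VariantTable()
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            pos, ref, alt = _parse_row_key(row, cmap, i)
            aff = int(row[cmap["affected"]])
            unaff = int(row[cmap["unaffected"]])
            cov = CovariateSet(
                revel=_opt_float(row, cmap.get("revel"), 0.0, 1.0),
                alphamissense=_opt_float(row, cmap.get("alphamissense"),
                                         0.0, 1.0),
                clinvar_code=normalize_clinvar(row.get(cmap.get("clinvar"))),
            )
            rec = VariantRecord(
                pos, ref, alt, HeterozygoteCounts(aff, unaff),
                allele_frequency=_opt_float(row, cmap.get("af"), 0.0, 1.0),
                covariates=cov)
        except FormatError:
            raise
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        table.add(rec)
    return table


def read_population_table(path, af_threshold: float = 1e-4,
                          column_map: Optional[dict] = None) -> VariantTable:
    """Read a population (gnomAD-style) variant table.

    Keeps variants with allele frequency strictly below ``af_threshold``
    and maps the carrier allele count to unaffected heterozygotes
    (affected = 0): rare population carriers are presumed unaffected.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_frame(path)
    for req in (cmap["af"], cmap["allele_count"]):
        if req not in df.columns:
            raise FormatError(
                f"{path}: missing required column '{req}'; "
                f"found {list(df.columns)}")
    table = VariantTable()
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            af = float(row[cmap["af"]])
            if af < 0:
                raise ValueError(f"negative allele frequency {af}")
            if af >= af_threshold:
                continue
            pos, ref, alt = _parse_row_key(row, cmap, i)
            ac = int(row[cmap["allele_count"]])
            rec = VariantRecord(
                pos, ref, alt, HeterozygoteCounts(0, ac),
                allele_frequency=af,
                covariates=CovariateSet(
                    revel=_opt_float(row, cmap.get("revel"), 0.0, 1.0),
                    alphamissense=_opt_float(row, cmap.get("alphamissense"),
                                             0.0, 1.0),
                    clinvar_code=normalize_clinvar(
                        row.get(cmap.get("clinvar")))))
        except FormatError:
            raise
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        table.add(rec)
    return table


def merge_counts(curated: VariantTable, population: VariantTable) -> VariantTable:
    """Sum affected/unaffected counts per variant key across sources.

    Covariates are joined, existing values taking precedence.  A position
    carrying inconsistent reference residues across sources raises.
    """
    by_pos: dict[int, str] = {}
    for table in (curated, population):
        for rec in table:
            prev = by_pos.setdefault(rec.position, rec.ref_aa)
            if prev != rec.ref_aa:
                raise ValueError(
                    f"conflicting reference residues at position "
                    f"{rec.position}: {prev} vs {rec.ref_aa}")
    out = VariantTable()
    for table in (curated, population):
        for rec in table:
            out.add(replace(rec))
    return out


def write_table(table: VariantTable, path) -> None:
    """Write the canonical variant CSV (deterministic, sorted)."""
    df = table.to_frame()
    df.to_csv(path, index=False, float_format="%.6g")


def read_table(path) -> VariantTable:
    """Read a canonical variant CSV written by :func:`write_table`."""
    df = pd.read_csv(path, dtype={"ref": str, "alt": str})
    table = VariantTable()
    for row in df.to_dict("records"):
        def _na(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v
        cov = CovariateSet(
            revel=_na(row.get("revel")),
            alphamissense=_na(row.get("alphamissense")),
            clinvar_code=normalize_clinvar(row.get("clinvar")),
            cpvt_density=_na(row.get("density")))
        table.add(VariantRecord(
            int(row["position"]), row["ref"], row["alt"],
            HeterozygoteCounts(int(row["affected"]), int(row["unaffected"])),
            weight=_na(row.get("weight")),
            allele_frequency=_na(row.get("af")),
            covariates=cov))
    return table
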