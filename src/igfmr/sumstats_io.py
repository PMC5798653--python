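"""Reading, validating and writing GWAS summary-association tables.

Every downstream stage consumes :class:`AssociationRecord` objects produced
here. Tables are tab-separated with a header row; column names are mapped
through a configurable :class:`Dialect` so that differently formatted
sources (e.g. the IGAP release, which uses ``MarkerName``/``Effect_allele``
headers) can be read without editing the files.

Coordinates are 1-based (dbSNP convention) and optional: the MR arithmetic
never uses positions. Effect-allele frequency (EAF) is tolerated missing —
IGAP-style tables omit it — but is required downstream if the palindromic
frequency rule is enabled during harmonization. Alleles are restricted to
single-nucleotide variants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

VALID_ALLELES = frozenset("ACGT")


class Scale(str, enum.Enum):
    """Scale of the per-allele effect size."""

    LOG_ODDS = "log_odds"
    SD_UNITS = "sd_units"
    RAW_UNITS = "raw_units"


class SumstatsError(Exception):
    """Base class for summary-statistics I/O errors."""


class DialectError(SumstatsError):
    """A required column is missing from the input table."""


class AmbiguousRecordError(SumstatsError):
    """The same rsid appears more than once for one trait."""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait association from a GWAS summary table.

    ``beta`` is the per-effect-allele-copy effect: log-odds for a binary
    outcome, trait units or SD units for a quantitative exposure.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    trait: str
    scale: Scale
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            problems.append(f"effect allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            problems.append(f"other allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele == other_allele")
        if not math.isfinite(self.beta):
            problems.append("beta not finite")
        if not (self.se > 0):
            problems.append("se > 0 violated")
        if not (0 < self.pvalue <= 1):
            problems.append("pvalue in (0,1] violated")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            problems.append("eaf in [0,1] violated")
        return problems

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))


class Affects(str, enum.Enum):
    """Which exposure(s) an instrument determines at genome-wide significance."""

    IGF1_ONLY = "igf1_only"
    IGFBP3_ONLY = "igfbp3_only"
    BOTH = "both"
    BIVARIATE_OPPOSITE = "bivariate_opposite"


@dataclass(frozen=True)
class InstrumentSpec:
    """Identity, raising allele and exposure class of one instrument SNP.

    ``bivariate_opposite`` marks the rs646776-like variant with inverse
    effects on IGF1 and IGFBP3; it is excluded from the main instrument set
    and enters only the molar-ratio analysis.
    """

    rsid: str
    exposure_trait: str
    raising_allele: str
    affects: Affects


@dataclass(frozen=True)
class Dialect:
    """Maps canonical field names to the column headers of a table."""

    rsid: str = "rsid"
    effect_allele: str = "effect_allele"
    other_allele: str = "other_allele"
    beta: str = "beta"
    se: str = "se"
    pvalue: str = "pvalue"
    chrom: str | None = "chrom"
    pos: str | None = "pos"
    eaf: str | None = "eaf"

    def required(self) -> dict[str, str]:
        return {
            "rsid": self.rsid,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
        }


CANONICAL_DIALECT = Dialect()

#: Column names of the published IGAP stage-1 release.
IGAP_DIALECT = Dialect(
    rsid="MarkerName",
    effect_allele="Effect_allele",
    other_allele="Non_Effect_allele",
    beta="Beta",
    se="SE",
    pvalue="Pvalue",
    chrom="Chromosome",
    pos="Position",
    eaf=None,
)

CANONICAL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "trait",
    "scale",
]


@dataclass
class ReadResult:
    """Records accepted from a table plus row-level rejection diagnostics.

    Rejection is total: every input data row becomes either a record or an
    entry in ``rejections`` (1-based row number, message).
    """

    records: list[AssociationRecord]
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.records) + len(self.rejections)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_association_table(
    path: str | Path,
    dialect: Dialect = CANONICAL_DIALECT,
    *,
    trait: str | None = None,
    scale: Scale | str | None = None,
    trait_column: str = "trait",
    scale_column: str = "scale",
) -> ReadResult:
    """Read a tab-separated summary table into validated records.

    ``trait``/``scale`` override (or supply, for tables lacking them) the
    per-row trait label and effect scale. Rows violating record invariants
    are rejected with row-number diagnostics rather than silently skipped;
    a missing required column raises :class:`DialectError` immediately.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for field_name, column in dialect.required().items():
        if column not in df.columns:
            raise DialectError(
                f"{path}: required column {column!r} (field {field_name}) not found; "
                f"available: {list(df.columns)}"
            )

    records: list[AssociationRecord] = []
    rejections: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            rec = AssociationRecord(
                rsid=str(rowd[dialect.rsid]).strip(),
                effect_allele=str(rowd[dialect.effect_allele]).strip().upper(),
                other_allele=str(rowd[dialect.other_allele]).strip().upper(),
                beta=float(rowd[dialect.beta]),
                se=float(rowd[dialect.se]),
                pvalue=float(rowd[dialect.pvalue]),
                trait=trait if trait is not None else str(rowd.get(trait_column, "")),
                scale=Scale(scale) if scale is not None else Scale(rowd.get(scale_column, "raw_units")),
                chrom=(
                    str(rowd[dialect.chrom])
                    if dialect.chrom and rowd.get(dialect.chrom) is not None
                    and not (isinstance(rowd.get(dialect.chrom), float) and math.isnan(rowd[dialect.chrom]))
                    else None
                ),
                pos=(
                    int(float(rowd[dialect.pos]))
                    if dialect.pos and rowd.get(dialect.pos) not in (None,)
                    and not (isinstance(rowd.get(dialect.pos), float) and math.isnan(rowd[dialect.pos]))
                    and str(rowd.get(dialect.pos)) != "nan"
                    else None
                ),
                eaf=(
                    _opt_float(rowd[dialect.eaf])
                    if dialect.eaf and dialect.eaf in df.columns
                    and str(rowd.get(dialect.eaf)) != "nan"
                    else None
                ),
            )
        except (TypeError, ValueError) as exc:
            rejections.append((idx, f"unparseable value: {exc}"))
            continue
        problems = rec.violations()
        if problems:
            rejections.append((idx, "; ".join(problems)))
        else:
            records.append(rec)
    return ReadResult(records=records, rejections=rejections)


def write_association_table(records: Sequence[AssociationRecord], path: str | Path) -> None:
    """Write records as canonical TSV with fixed column order.

    Betas and SEs are serialized at full double precision so that a write
    followed by a read reproduces them exactly.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "rsid": rec.rsid,
                "chrom": rec.chrom if rec.chrom is not None else "",
                "pos": rec.pos if rec.pos is not None else "",
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "eaf": repr(rec.eaf) if rec.eaf is not None else "",
                "beta": repr(rec.beta),
                "se": repr(rec.se),
                "pvalue": repr(rec.pvalue),
                "trait": rec.trait,
                "scale": rec.scale.value,
            }
        )
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_instrument_specs(path: str | Path) -> list[InstrumentSpec]:
    """Read an instrument-specification TSV (rsid, exposure_trait, raising_allele, affects)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"rsid", "exposure_trait", "raising_allele", "affects"}
    missing = needed - set(df.columns)
    if missing:
        raise DialectError(f"{path}: instrument spec missing columns {sorted(missing)}")
    return [
        InstrumentSpec(
            rsid=row.rsid.strip(),
            exposure_trait=row.exposure_trait.strip(),
            raising_allele=row.raising_allele.strip().upper(),
            affects=Affects(row.affects.strip()),
        )
        for row in df.itertuples(index=False)
    ]


def write_instrument_specs(specs: Sequence[InstrumentSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "rsid": s.rsid,
                "exposure_trait": s.exposure_trait,
                "raising_allele": s.raising_allele,
                "affects": s.affects.value,
            }
            for s in specs
        ]
    ).to_csv(path, sep="\t", index=False)


def select_instruments(
    records: Iterable[AssociationRecord],
    specs: Sequence[InstrumentSpec],
) -> tuple[list[AssociationRecord], list[str]]:
    """Pick the instrument SNPs out of a (possibly large) association table.

    Returns records matching the spec rsids, in spec order, plus the list of
    spec rsids absent from the table. A duplicated rsid for the same trait is
    an ambiguity error — the caller cannot know which row is the instrument.
    """
    rsids = [s.rsid for s in specs]
    if len(set(rsids)) != len(rsids):
        raise AmbiguousRecordError("duplicate rsid in instrument specs")
    by_rsid: dict[str, AssociationRecord] = {}
    for rec in records:
        key = rec.rsid
        if key in by_rsid and by_rsid[key].trait == rec.trait:
            raise AmbiguousRecordError(
                f"rsid {key} appears more than once for trait {rec.trait!r}"
            )
        by_rsid.setdefault(key, rec)
    selected = [by_rsid[r] for r in rsids if r in by_rsid]
    missing = [r for r in rsids if r not in by_rsid]
    return selected, missing


def flip_record(rec: AssociationRecord) -> AssociationRecord:
    """Re-express a record on its other allele (sign-flip beta, complement EAF)."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=(1.0 - rec.eaf) if rec.eaf is not None else None,
    )
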