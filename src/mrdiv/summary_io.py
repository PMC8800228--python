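"""Reading, validating and writing GWAS summary-statistic tables.

Summary statistics arrive as flat delimited tables with one row per variant
(rsID, effect allele, other allele, beta, SE, p-value, optionally
effect-allele frequency and sample size).  Because source files use
heterogeneous headers, column names are mapped onto a canonical schema at
read time.  Rows violating basic invariants (non-positive SE, p outside
(0, 1], identical alleles, ...) are rejected individually and reported;
duplicate rsIDs abort the read, since a duplicated instrument is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical column names; a user column_map maps canonical -> actual header
DEFAULT_COLUMNS: dict[str, str] = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "eaf": "eaf",
    "n": "n",
}

REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")


class SummaryFormatError(ValueError):
    """A table-level problem: missing mapped column, duplicate rsid."""


@dataclass
class VariantAssociation:
    """One variant's association summary in one dataset.

    beta is the per-effect-allele effect: log-odds for a binary outcome,
    phenotype SD units for a quantitative exposure.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_BASES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele identical")
        if not self.se > 0:
            raise ValueError("nonpositive SE")
        if not (0 < self.pvalue <= 1):
            raise ValueError("p-value outside (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError("EAF outside [0, 1]")
        if self.n is not None and self.n <= 0:
            raise ValueError("nonpositive sample size")


@dataclass
class RowRejection:
    row: int
    rsid: str
    reason: str


@dataclass
class SummaryDataset:
    """A labelled collection of variant associations, keyed by rsid."""

    label: str
    trait_type: str = "outcome"  # "exposure" or "outcome"
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    rejected: list[RowRejection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> VariantAssociation:
        return self.records[rsid]

    def add(self, rec: VariantAssociation) -> None:
        if rec.rsid in self.records:
            raise SummaryFormatError(f"duplicate rsid {rec.rsid} in {self.label}")
        self.records[rec.rsid] = rec

    @property
    def rsids(self) -> list[str]:
        return list(self.records)

    def validation_report(self) -> dict:
        return {
            "label": self.label,
            "n_valid": len(self.records),
            "n_rejected": len(self.rejected),
            "rejections": [
                {"row": r.row, "rsid": r.rsid, "reason": r.reason}
                for r in self.rejected
            ],
        }


def _coerce_float(value) -> float:
    out = float(value)
    if out != out:  # NaN
        raise ValueError("missing value")
    return out


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    label: str = "",
    trait_type: str = "outcome",
) -> SummaryDataset:
    """Parse a tab- or comma-delimited summary-statistics table.

    `column_map` maps canonical field names (see DEFAULT_COLUMNS) to the
    actual headers in the file; unmapped optional fields (eaf, n) are
    silently absent.  Invalid rows are collected in ``dataset.rejected``
    with a per-row reason; a duplicated rsid raises SummaryFormatError.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for f in REQUIRED_FIELDS:
        if cols[f] not in df.columns:
            raise SummaryFormatError(
                f"{path.name}: mapped column {cols[f]!r} for field {f!r} not found"
            )
    has_eaf = cols["eaf"] in df.columns
    has_n = cols["n"] in df.columns

    ds = SummaryDataset(label=label or path.stem, trait_type=trait_type)
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        rsid = str(row[cols["rsid"]]).strip()
        try:
            eaf = row[cols["eaf"]] if has_eaf else None
            if eaf is not None and pd.isna(eaf):
                eaf = None
            n = row[cols["n"]] if has_n else None
            if n is not None and pd.isna(n):
                n = None
            rec = VariantAssociation(
                rsid=rsid,
                effect_allele=str(row[cols["effect_allele"]]).strip().upper(),
                other_allele=str(row[cols["other_allele"]]).strip().upper(),
                beta=_coerce_float(row[cols["beta"]]),
                se=_coerce_float(row[cols["se"]]),
                pvalue=_coerce_float(row[cols["pvalue"]]),
                eaf=None if eaf is None else float(eaf),
                n=None if n is None else int(n),
            )
            rec.validate()
        except SummaryFormatError:
            raise
        except (ValueError, TypeError) as exc:
            ds.rejected.append(RowRejection(row=i, rsid=rsid, reason=str(exc)))
            continue
        ds.add(rec)
    if ds.rejected:
        logger.warning(
            "%s: rejected %d of %d rows", ds.label, len(ds.rejected), len(df)
        )
    return ds


def write_summary_table(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as TSV with canonical column names."""
    rows = []
    for rec in dataset.records.values():
        rows.append(
            {
                "rsid": rec.rsid,
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "beta": rec.beta,
                "se": rec.se,
                "pval": rec.pvalue,
                "eaf": rec.eaf,
                "n": rec.n,
            }
        )
    df = pd.DataFrame(rows)
    if df["eaf"].isna().all():
        df = df.drop(columns=["eaf"])
    if df["n"].isna().all():
        df = df.drop(columns=["n"])
    df.to_csv(path, sep="\t", index=False)


def select_instruments(
    exposure: SummaryDataset, p_threshold: float = 5e-8
) -> SummaryDataset:
    """Keep exposure variants below the genome-wide significance threshold.

    Instruments for the exposure are chosen at P < p_threshold (the usual
    genome-wide cut-off 5e-8); order is preserved.
    """
    if exposure.trait_type != "exposure":
        raise ValueError("instrument selection expects an exposure dataset")
    out = SummaryDataset(label=exposure.label, trait_type="exposure")
    for rec in exposure.records.values():
        if rec.pvalue < p_threshold:
            out.records[rec.rsid] = rec
    if not out.records:
        logger.warning(
            "%s: no variants pass P < %g — empty instrument set", exposure.label, p_threshold
        )
    return out


def intersect_datasets(
    datasets: Sequence[SummaryDataset], exclude: Iterable[str] = ()
) -> list[str]:
    """Sorted rsids present in every dataset and not excluded."""
    if not datasets:
        raise ValueError("at least one dataset required")
    shared = set(datasets[0].records)
    for ds in datasets[1:]:
        shared &= set(ds.records)
    shared -= set(exclude)
    return sorted(shared)
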