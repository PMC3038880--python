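"""Assay catalog and methylation-table data model.

The catalog holds one record per pyrosequencing assay (an imprinted DMR
with its genomic and epigenetic annotations); methylation data is a long
table of per-CpG percentages keyed by (assay, sample, cpg_index) with
sample metadata. Interval sets carry CTCF / CpG-island annotations from
BED files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "ParentalMark",
    "Timing",
    "LocationCategory",
    "CtcfClass",
    "AssayDefinition",
    "MethylationDataset",
    "GenomicInterval",
    "IntervalSet",
    "CatalogSummary",
    "load_assay_catalog",
    "packaged_catalog_path",
    "read_methylation_table",
    "write_methylation_table",
    "read_intervals",
    "summarize_catalog",
]


class ParentalMark(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    NONE = "none"
    UNKNOWN = "unknown"


class Timing(str, Enum):
    GERMLINE = "germline"
    GERMLINE_QUALIFIED = "germline_qualified"  # '#'-flagged in the catalog
    SOMATIC = "somatic"
    NONE = "none"
    UNKNOWN = "unknown"


class LocationCategory(str, Enum):
    PROMOTER = "promoter"
    ISOFORM_PROMOTER = "isoform_promoter"
    EMBEDDED_GENE_PROMOTER = "embedded_gene_promoter"
    ANTISENSE_PROMOTER = "antisense_promoter"
    FIVE_PRIME_UPSTREAM = "five_prime_upstream"
    INTERGENIC = "intergenic"
    GENE_BODY_EXONIC = "gene_body_exonic"
    GENE_BODY_INTRONIC = "gene_body_intronic"


class CtcfClass(str, Enum):
    NONE = "none"
    CONSTITUTIVE = "constitutive"
    VARIABLE = "variable"


_PARENTAL_ALIASES = {
    "maternal": ParentalMark.MATERNAL,
    "paternal": ParentalMark.PATERNAL,
    "none": ParentalMark.NONE,
    "unknown": ParentalMark.UNKNOWN,
}

_TIMING_ALIASES = {
    "germ-line": Timing.GERMLINE,
    "germline": Timing.GERMLINE,
    "germ-line#": Timing.GERMLINE_QUALIFIED,
    "germline#": Timing.GERMLINE_QUALIFIED,
    "germline_qualified": Timing.GERMLINE_QUALIFIED,
    "somatic": Timing.SOMATIC,
    "none": Timing.NONE,
    "unknown": Timing.UNKNOWN,
}

_CTCF_ALIASES = {
    "n": CtcfClass.NONE,
    "none": CtcfClass.NONE,
    "y": CtcfClass.CONSTITUTIVE,
    "constitutive": CtcfClass.CONSTITUTIVE,
    "yv": CtcfClass.VARIABLE,
    "variable": CtcfClass.VARIABLE,
}

_BOOL_ALIASES = {"yes": True, "y": True, "true": True, "1": True,
                 "no": False, "n": False, "false": False, "0": False}


@dataclass(frozen=True)
class AssayDefinition:
    """One pyrosequencing assay: an imprinted DMR and its annotations."""

    name: str
    chromosome: str
    position: int  # 1-based, on the catalog's original assembly
    parental_mark: ParentalMark
    timing: Timing
    avg_somatic_methylation: float
    location_category: LocationCategory
    cpg_island: bool
    ctcf_class: CtcfClass
    cpg_density: float  # CpGs per 100 bp over a 500 bp window
    cluster_id: str | None = None
    n_cpgs: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.name}: position must be >= 1, got {self.position}")
        if not 0.0 <= self.avg_somatic_methylation <= 100.0:
            raise ValueError(
                f"{self.name}: avg_somatic_methylation {self.avg_somatic_methylation} "
                "outside [0, 100]"
            )
        if self.cpg_density < 0:
            raise ValueError(f"{self.name}: cpg_density must be >= 0")
        if self.n_cpgs is not None and not 3 <= self.n_cpgs <= 9:
            raise ValueError(f"{self.name}: n_cpgs must be in [3, 9]")


CATALOG_COLUMNS = [
    "name", "chromosome", "position", "parental_mark", "timing",
    "avg_somatic_methylation", "location_category", "cpg_island",
    "ctcf_class", "cpg_density", "cluster_id",
]


def packaged_catalog_path() -> Path:
    """Path to the catalog CSV shipped with the package (49 assays)."""
    return Path(str(importlib.resources.files("imprintqc") / "data" / "assay_catalog.csv"))


def _parse_enum(aliases: Mapping[str, object], raw: str, row: int, column: str):
    key = str(raw).strip().lower()
    if key not in aliases:
        raise ValueError(f"row {row}, column '{column}': unrecognized value {raw!r}")
    return aliases[key]


def load_assay_catalog(path: str | Path | None = None) -> list[AssayDefinition]:
    """Load an assay catalog CSV into a list of :class:`AssayDefinition`.

    With no path the packaged catalog is loaded. Raw catalog spellings
    (``Germ-line#``, CTCF ``Y``/``YV``/``N``, island ``Yes``/``No``) and the
    normalized enum tokens are both accepted. Errors name the offending row
    and column; duplicate assay names are rejected.
    """
    if path is None:
        path = packaged_catalog_path()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path}: missing columns {missing}")

    records: list[AssayDefinition] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        name = row.name.strip()
        if not name:
            raise ValueError(f"row {idx}, column 'name': empty")
        if name in seen:
            raise ValueError(f"row {idx}: duplicate assay name {name!r}")
        seen.add(name)
        try:
            position = int(row.position)
            avg = float(row.avg_somatic_methylation)
            density = float(row.cpg_density)
        except ValueError as exc:
            raise ValueError(f"row {idx} ({name}): malformed numeric field: {exc}") from None
        loc_key = row.location_category.strip().lower()
        try:
            location = LocationCategory(loc_key)
        except ValueError:
            raise ValueError(
                f"row {idx}, column 'location_category': unrecognized value "
                f"{row.location_category!r}"
            ) from None
        records.append(
            AssayDefinition(
                name=name,
                chromosome=row.chromosome.strip(),
                position=position,
                parental_mark=_parse_enum(_PARENTAL_ALIASES, row.parental_mark, idx, "parental_mark"),
                timing=_parse_enum(_TIMING_ALIASES, row.timing, idx, "timing"),
                avg_somatic_methylation=avg,
                location_category=location,
                cpg_island=_parse_enum(_BOOL_ALIASES, row.cpg_island, idx, "cpg_island"),
                ctcf_class=_parse_enum(_CTCF_ALIASES, row.ctcf_class, idx, "ctcf_class"),
                cpg_density=density,
                cluster_id=row.cluster_id.strip() or None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Methylation tables

REQUIRED_METH_COLUMNS = ["assay", "sample", "cpg_index", "percent"]
OPTIONAL_METH_COLUMNS = ["tissue", "individual", "group", "replicate",
                         "template_mass_ng", "dose_label"]


class MethylationDataset:
    """Per-CpG methylation percentages for assays x samples.

    Wraps a long-format :class:`pandas.DataFrame` with required columns
    ``assay, sample, cpg_index, percent`` and optional sample metadata
    (``tissue, individual, group, replicate, template_mass_ng, dose_label``).
    Values are percentages in [0, 100]; missing readings are simply absent
    rows and are excluded pairwise from statistics.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        missing = [c for c in REQUIRED_METH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"methylation table missing columns {missing}")
        df["cpg_index"] = df["cpg_index"].astype(int)
        df["percent"] = df["percent"].astype(float)
        bad = df[(df["percent"] < 0) | (df["percent"] > 100)]
        if not bad.empty:
            first = bad.iloc[0]
            raise ValueError(
                f"percent {first['percent']} outside [0, 100] "
                f"(assay={first['assay']}, sample={first['sample']})"
            )
        if df.duplicated(subset=["assay", "sample", "cpg_index"]).any():
            dup = df[df.duplicated(subset=["assay", "sample", "cpg_index"])].iloc[0]
            raise ValueError(
                f"duplicate key (assay={dup['assay']}, sample={dup['sample']}, "
                f"cpg_index={dup['cpg_index']})"
            )
        if (df["cpg_index"] < 1).any():
            raise ValueError("cpg_index must start at 1")
        self._df = df.reset_index(drop=True)

    @property
    def data(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def assays(self) -> list[str]:
        return sorted(self._df["assay"].unique())

    @property
    def samples(self) -> pd.DataFrame:
        """One row of metadata per sample."""
        cols = ["sample"] + [c for c in OPTIONAL_METH_COLUMNS if c in self._df.columns]
        return self._df[cols].drop_duplicates(subset="sample").reset_index(drop=True)

    def subset(self, **conditions) -> "MethylationDataset":
        """Rows matching all column==value conditions (value may be a list)."""
        mask = pd.Series(True, index=self._df.index)
        for col, val in conditions.items():
            if col not in self._df.columns:
                raise KeyError(f"no column {col!r} in dataset")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self._df[col].isin(list(val))
            else:
                mask &= self._df[col] == val
        return MethylationDataset(self._df[mask])

    def sample_means(self) -> pd.DataFrame:
        """Mean percent over CpGs per (assay, sample), metadata preserved."""
        meta = [c for c in OPTIONAL_METH_COLUMNS if c in self._df.columns]
        grouped = (
            self._df.groupby(["assay", "sample"] + meta, dropna=False)["percent"]
            .mean()
            .reset_index()
            .rename(columns={"percent": "mean_percent"})
        )
        return grouped

    def tissue_means(self) -> pd.DataFrame:
        """Mean per (assay, tissue): individuals averaged over CpGs first,
        then averaged within tissue (unweighted by CpG count)."""
        if "tissue" not in self._df.columns:
            raise ValueError("dataset carries no tissue metadata")
        per_sample = self.sample_means()
        return (
            per_sample.groupby(["assay", "tissue"])["mean_percent"]
            .mean()
            .reset_index()
        )


def read_methylation_table(path: str | Path) -> MethylationDataset:
    """Read a long-format CSV/TSV methylation table (delimiter sniffed)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return MethylationDataset(df)


def write_methylation_table(dataset: MethylationDataset, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    dataset.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Intervals

@dataclass(frozen=True)
class GenomicInterval:
    chromosome: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Ordered collection of 0-based half-open intervals with overlap query.

    File order is preserved; queries are served from per-chromosome interval
    trees so they are independent of input sorting.
    """

    def __init__(self, records: Iterable[GenomicInterval] = ()):
        self._records: list[GenomicInterval] = list(records)
        self._trees: dict[str, IntervalTree] = {}
        for rec in self._records:
            self._trees.setdefault(rec.chromosome, IntervalTree()).addi(
                rec.start, rec.end, rec
            )

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._records)

    @property
    def records(self) -> list[GenomicInterval]:
        return list(self._records)

    def overlapping(self, chromosome: str, start: int, end: int) -> list[GenomicInterval]:
        """Intervals overlapping [start, end), in file order."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(start, end)}
        return [rec for rec in self._records if rec in hits]

    def contains_point(self, chromosome: str, position0: int) -> bool:
        """Whether any interval covers the 0-based position."""
        return bool(self.overlapping(chromosome, position0, position0 + 1))


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED3/BED4 file; coordinates kept 0-based half-open verbatim."""
    records: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 BED fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 else ""
            records.append(GenomicInterval(chrom, start, end, label))
    return IntervalSet(records)


def position_to_bed(position: int) -> int:
    """1-based catalog position -> 0-based BED coordinate."""
    if position < 1:
        raise ValueError("1-based position must be >= 1")
    return position - 1


def bed_to_position(start: int) -> int:
    """0-based BED coordinate -> 1-based catalog position."""
    if start < 0:
        raise ValueError("BED coordinate must be >= 0")
    return start + 1


# ---------------------------------------------------------------------------
# Catalog summaries

SUMMARY_FIELDS = ["timing", "parental_mark", "ctcf_class", "cpg_island"]


@dataclass
class CatalogSummary:
    """Counts keyed by (field, value); values are enum tokens or booleans."""

    counts: dict[tuple[str, object], int] = field(default_factory=dict)
    n_assays: int = 0

    def count(self, field_name: str, value: object) -> int:
        key = value.value if isinstance(value, Enum) else value
        return self.counts.get((field_name, key), 0)


def summarize_catalog(
    catalog: Sequence[AssayDefinition],
    exclusions: Iterable[str] = (),
) -> CatalogSummary:
    """Count assays by timing, parental mark, CTCF class and island status.

    ``exclusions`` removes assays by name before counting (e.g. the five
    regions never observed in the differential range); an unknown name is
    an error. Counts over any one field sum to the retained catalog size.
    """
    exclusions = set(exclusions)
    names = {a.name for a in catalog}
    unknown = exclusions - names
    if unknown:
        raise ValueError(f"exclusion names not in catalog: {sorted(unknown)}")
    kept = [a for a in catalog if a.name not in exclusions]
    summary = CatalogSummary(n_assays=len(kept))
    for assay in kept:
        for field_name in SUMMARY_FIELDS:
            value = getattr(assay, field_name)
            key = value.value if isinstance(value, Enum) else value
            summary.counts[(field_name, key)] = summary.counts.get((field_name, key), 0) + 1
    return summary
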