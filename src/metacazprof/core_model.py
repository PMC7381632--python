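"""Shared domain types, tabular I/O and run configuration.

Every tabular artifact in this package is a tab-separated UTF-8 text file
with a header row and "." as the decimal separator.  Floats are written
with 17 significant digits so that a write/read round trip reproduces
values exactly.

The types here mirror the inputs of a gut metaproteomics study:

* :class:`ProteinCatalog` — a pre-annotated reference gene catalog (genus,
  KEGG ortholog codes, CAZy family, enzyme product name per gene);
* :class:`PeptideTable` — the peptide × sample intensity matrix produced
  by a DIA search, together with the peptide → gene multi-mapping;
* :class:`AbundanceTable` — genus-level relative abundances from 16S
  rRNA gene sequencing of the same donors;
* :class:`DietRecord` — per-donor diet-quality scores and weekly food
  component frequencies.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("metacazprof")

FLOAT_FORMAT = "%.17g"

#: Recognised CAZy class prefixes (glycoside hydrolases, polysaccharide
#: lyases, carbohydrate esterases, glycosyl transferases,
#: carbohydrate-binding modules, auxiliary activities).
CAZY_CLASSES = ("GH", "PL", "CE", "GT", "CBM", "AA")

_CAZY_RE = re.compile(r"^(GH|PL|CE|GT|CBM|AA)\d+$")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def is_valid_cazy_family(family: str) -> bool:
    """True for strings like ``GH43`` / ``PL9`` / ``CBM48``."""
    return bool(_CAZY_RE.match(family))


# ---------------------------------------------------------------------------
# Protein catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One gene of the annotated reference catalog.

    ``genus``, ``cazy_family`` and ``enzyme_name`` are ``None`` when the
    catalog carries no annotation for the gene.  ``ko_codes`` may be empty.
    """

    gene_id: str
    genus: str | None = None
    ko_codes: frozenset[str] = frozenset()
    cazy_family: str | None = None
    enzyme_name: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.cazy_family is not None and not is_valid_cazy_family(self.cazy_family):
            raise ValidationError(
                f"gene {self.gene_id!r}: malformed CAZy family {self.cazy_family!r} "
                f"(expected one of {CAZY_CLASSES} followed by an integer)"
            )


class ProteinCatalog:
    """Immutable collection of :class:`GeneRecord` keyed by ``gene_id``."""

    def __init__(self, records: Iterable[GeneRecord]):
        genes: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in genes:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r} in catalog")
            genes[rec.gene_id] = rec
        self._genes = genes

    @property
    def genes(self) -> Mapping[str, GeneRecord]:
        return self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneRecord:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not present in catalog") from None

    def genera(self) -> set[str]:
        """Distinct genus annotations present in the catalog."""
        return {r.genus for r in self if r.genus is not None}


_CATALOG_COLUMNS = ["gene_id", "genus", "ko", "cazy_family", "enzyme_name"]


def read_catalog(path) -> ProteinCatalog:
    """Read a gene catalog TSV (columns: gene_id, genus, ko, cazy_family,
    enzyme_name; empty cells mean "no annotation"; multiple KO codes are
    separated by commas)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"catalog {path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        ko = frozenset(k for k in str(row.ko).split(",") if k)
        try:
            records.append(
                GeneRecord(
                    gene_id=row.gene_id,
                    genus=row.genus or None,
                    ko_codes=ko,
                    cazy_family=row.cazy_family or None,
                    enzyme_name=row.enzyme_name or None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"catalog {path}, row {i + 2}: {exc}") from None
    return ProteinCatalog(records)


def write_catalog(catalog: ProteinCatalog, path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "genus": r.genus or "",
            "ko": ",".join(sorted(r.ko_codes)),
            "cazy_family": r.cazy_family or "",
            "enzyme_name": r.enzyme_name or "",
        }
        for r in catalog
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Peptide table
# ---------------------------------------------------------------------------


class PeptideTable:
    """Peptide × sample intensity matrix with the peptide → gene multi-map.

    Zero and missing intensities are both stored as 0.0 and mean "not
    detected".  Peptides detected in no sample are dropped at construction
    (they cannot contribute to any per-sample statistic); the dropped count
    is logged.
    """

    def __init__(self, intensity: pd.DataFrame, gene_map: Mapping[str, frozenset[str]]):
        intensity = intensity.astype(float).fillna(0.0)
        if (intensity.values < 0).any():
            bad = intensity.index[(intensity.values < 0).any(axis=1)][0]
            raise ValidationError(f"negative intensity for peptide {bad!r}")
        unmapped = [p for p in intensity.index if p not in gene_map or not gene_map[p]]
        if unmapped:
            raise ValidationError(
                f"{len(unmapped)} peptide(s) lack a gene mapping, e.g. {unmapped[0]!r}"
            )
        never_detected = intensity.index[(intensity.values == 0).all(axis=1)]
        if len(never_detected):
            logger.info("dropping %d peptide(s) detected in no sample", len(never_detected))
            intensity = intensity.drop(index=never_detected)
        if intensity.shape[0] == 0:
            raise ValidationError("peptide table is empty after dropping undetected peptides")
        empty_samples = intensity.columns[(intensity.values == 0).all(axis=0)]
        if len(empty_samples):
            raise ValidationError(
                f"sample(s) with zero detected peptides: {list(empty_samples)}"
            )
        self.intensity = intensity
        self.gene_map: dict[str, frozenset[str]] = {
            p: frozenset(gene_map[p]) for p in intensity.index
        }

    @property
    def peptides(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    def detected(self) -> pd.DataFrame:
        """Boolean peptide × sample detection mask."""
        return self.intensity > 0


def read_peptides(intensity_path, map_path) -> PeptideTable:
    """Read the intensity TSV (first column = peptide, remaining columns =
    samples) and the mapping TSV (columns: peptide, gene_id; one row per
    peptide–gene pair)."""
    intensity = pd.read_csv(intensity_path, sep="\t", index_col=0)
    mapping = pd.read_csv(map_path, sep="\t", dtype=str)
    if not {"peptide", "gene_id"} <= set(mapping.columns):
        raise ValidationError(f"mapping {map_path}: needs columns peptide, gene_id")
    gene_map: dict[str, set[str]] = {}
    for pep, gid in zip(mapping["peptide"], mapping["gene_id"]):
        gene_map.setdefault(pep, set()).add(gid)
    return PeptideTable(intensity, {p: frozenset(g) for p, g in gene_map.items()})


def write_peptides(table: PeptideTable, intensity_path, map_path) -> None:
    out = table.intensity.copy()
    out.index.name = "peptide"
    out.to_csv(intensity_path, sep="\t", float_format=FLOAT_FORMAT)
    rows = [
        {"peptide": p, "gene_id": g}
        for p in table.peptides
        for g in sorted(table.gene_map[p])
    ]
    pd.DataFrame(rows, columns=["peptide", "gene_id"]).to_csv(map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# 16S relative abundance
# ---------------------------------------------------------------------------


class AbundanceTable:
    """Genus × sample relative abundances; each sample column sums to one."""

    def __init__(self, values: pd.DataFrame):
        values = values.astype(float)
        if (values.values < 0).any():
            raise ValidationError("relative abundances must be non-negative")
        sums = values.sum(axis=0)
        off = (sums - 1.0).abs()
        if (off > 1e-6).any():
            bad = off.idxmax()
            raise ValidationError(
                f"abundance column {bad!r} sums to {sums[bad]:.6g}, not 1"
            )
        # renormalize away round-off so downstream code can rely on exact sums
        self.values = values / sums

    @property
    def genera(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_abundance(path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceTable(df)


def write_abundance(table: AbundanceTable, path) -> None:
    out = table.values.copy()
    out.index.name = "genus"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Diet records
# ---------------------------------------------------------------------------

#: Weekly food-frequency components (days per week, range 0–7).
DIET_FREQUENCY_COMPONENTS = ("whole_grains", "vegetables", "fruits_and_berries")


@dataclass(frozen=True)
class DietRecord:
    """Diet questionnaire summary for one donor.

    ``idq`` is the index-of-diet-quality score; the frequency components
    count days per week on which the food group was consumed.
    """

    sample_id: str
    idq: float
    whole_grains: float
    vegetables: float
    fruits_and_berries: float
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for comp in DIET_FREQUENCY_COMPONENTS:
            v = getattr(self, comp)
            if not (0.0 <= v <= 7.0):
                raise ValidationError(
                    f"{self.sample_id}: {comp}={v} outside the 0–7 days/week range"
                )


def read_diet(path) -> list[DietRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "idq", *DIET_FREQUENCY_COMPONENTS}
    if not needed <= set(df.columns):
        raise ValidationError(f"diet table {path}: missing columns {sorted(needed - set(df.columns))}")
    extra_cols = [c for c in df.columns if c not in needed]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            DietRecord(
                sample_id=str(d["sample_id"]),
                idq=float(d["idq"]),
                whole_grains=float(d["whole_grains"]),
                vegetables=float(d["vegetables"]),
                fruits_and_berries=float(d["fruits_and_berries"]),
                extras={c: float(d[c]) for c in extra_cols},
            )
        )
    return records


def write_diet(records: Sequence[DietRecord], path) -> None:
    extra_cols = sorted({k for r in records for k in r.extras})
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "idq": r.idq,
            "whole_grains": r.whole_grains,
            "vegetables": r.vegetables,
            "fruits_and_berries": r.fruits_and_berries,
        }
        row.update({c: r.extras.get(c, math.nan) for c in extra_cols})
        rows.append(row)
    cols = ["sample_id", "idq", *DIET_FREQUENCY_COMPONENTS, *extra_cols]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Run configuration with the analysis defaults.

    ``pseudocount_policy`` is either the string ``"half_min"`` (half the
    smallest positive value of the matrix) or a non-negative number used
    verbatim.  ``top_k`` is the number of co-occurrence edges retained.
    """

    pseudocount_policy: str | float = "half_min"
    prior_df: float = 3.0
    fdr_cutoffs: tuple[float, ...] = (0.01, 0.05)
    top_k: int = 500
    n_permutations: int = 999
    linkage: str = "complete"
    seed: int = 0
    normalize_total: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not all(0.0 < c < 1.0 for c in self.fdr_cutoffs):
            raise ValidationError("fdr cutoffs must lie in (0, 1)")
        if self.linkage not in {"complete", "average", "ward"}:
            raise ValidationError(f"unsupported linkage {self.linkage!r}")
        if isinstance(self.pseudocount_policy, str):
            if self.pseudocount_policy != "half_min":
                raise ValidationError(
                    f"unknown pseudocount policy {self.pseudocount_policy!r}"
                )
        elif self.pseudocount_policy < 0:
            raise ValidationError("numeric pseudocount must be >= 0")


def load_config(path) -> Config:
    """Load a flat key–value YAML config; missing keys fall back to the
    documented defaults (logged)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path}: expected a flat key-value mapping")
    fields = {f.name: f for f in dataclasses.fields(Config)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValidationError(f"config {path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name in fields:
        if name in raw:
            value = raw[name]
            if name == "fdr_cutoffs":
                value = tuple(float(v) for v in value)
            kwargs[name] = value
        else:
            logger.info("config: key %r absent, using default", name)
    cfg = Config(**kwargs)
    logger.info("configuration: %s", cfg)
    return cfg


def check_sample_ids(*sample_lists: Sequence[str]) -> list[str]:
    """Require all inputs to share the same sample set; return it sorted."""
    sets = [set(s) for s in sample_lists]
    base = sets[0]
    for other in sets[1:]:
        if other != base:
            raise ValidationError(
                "sample ID mismatch between inputs: "
                f"only-first={sorted(base - other)[:5]}, only-other={sorted(other - base)[:5]}"
            )
    return sorted(base)
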