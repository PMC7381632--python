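"""Peptide annotation resolution.

A peptide identified by DIA search can map to several catalog genes.  Its
taxonomic annotation is the set of distinct genera among those genes:
exactly one genus makes the peptide *unique*, two or more make it
*ambiguous*, and none makes it *unannotated*.  Functional (KEGG ortholog)
and CAZy annotations are resolved as unions over the mapped genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .core_model import GeneRecord, PeptideTable, ProteinCatalog, ValidationError, logger

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNANNOTATED = "unannotated"
TAXON_CLASSES = (UNIQUE, AMBIGUOUS, UNANNOTATED)

KO_SINGLE = "single"
KO_MULTIPLE = "multiple"
KO_NONE = "none"
FUNCTION_CLASSES = (KO_SINGLE, KO_MULTIPLE, KO_NONE)


@dataclass(frozen=True)
class TaxonAssignment:
    category: str
    genera: frozenset[str]

    def __post_init__(self) -> None:
        n = len(self.genera)
        expected = UNANNOTATED if n == 0 else UNIQUE if n == 1 else AMBIGUOUS
        if self.category != expected:
            raise ValidationError(
                f"taxon class {self.category!r} inconsistent with {n} genera"
            )


@dataclass(frozen=True)
class FunctionAssignment:
    ko_class: str
    ko_codes: frozenset[str]

    def __post_init__(self) -> None:
        n = len(self.ko_codes)
        expected = KO_NONE if n == 0 else KO_SINGLE if n == 1 else KO_MULTIPLE
        if self.ko_class != expected:
            raise ValidationError(
                f"KO class {self.ko_class!r} inconsistent with {n} codes"
            )


@dataclass(frozen=True)
class CazyAssignment:
    """CAZy annotation of one peptide.

    ``members`` keeps the (family, enzyme name) pairing of each mapped
    gene; ``families`` and ``enzyme_names`` are the projected sets.
    """

    members: frozenset[tuple[str, str | None]]

    @property
    def families(self) -> frozenset[str]:
        return frozenset(f for f, _ in self.members)

    @property
    def enzyme_names(self) -> frozenset[str]:
        return frozenset(n for _, n in self.members if n is not None)

    def __bool__(self) -> bool:
        return bool(self.members)


@dataclass(frozen=True)
class PeptideAnnotation:
    peptide: str
    taxonomy: TaxonAssignment
    function: FunctionAssignment
    cazy: CazyAssignment


def _mapped_genes(gene_ids: Iterable[str], catalog: ProteinCatalog) -> list[GeneRecord]:
    genes = []
    for gid in gene_ids:
        if gid not in catalog:
            raise ValidationError(f"mapped gene {gid!r} absent from catalog")
        genes.append(catalog[gid])
    if not genes:
        raise ValidationError("peptide maps to no gene")
    return genes


def resolve_taxonomy(gene_ids: Iterable[str], catalog: ProteinCatalog) -> TaxonAssignment:
    genera = frozenset(g.genus for g in _mapped_genes(gene_ids, catalog) if g.genus)
    n = len(genera)
    category = UNANNOTATED if n == 0 else UNIQUE if n == 1 else AMBIGUOUS
    return TaxonAssignment(category, genera)


def resolve_function(gene_ids: Iterable[str], catalog: ProteinCatalog) -> FunctionAssignment:
    codes: set[str] = set()
    for g in _mapped_genes(gene_ids, catalog):
        codes |= g.ko_codes
    n = len(codes)
    ko_class = KO_NONE if n == 0 else KO_SINGLE if n == 1 else KO_MULTIPLE
    return FunctionAssignment(ko_class, frozenset(codes))


def resolve_cazy(gene_ids: Iterable[str], catalog: ProteinCatalog) -> CazyAssignment:
    members = frozenset(
        (g.cazy_family, g.enzyme_name)
        for g in _mapped_genes(gene_ids, catalog)
        if g.cazy_family is not None
    )
    return CazyAssignment(members)


def annotate_peptides(
    table: PeptideTable, catalog: ProteinCatalog
) -> dict[str, PeptideAnnotation]:
    """Resolve all three annotation layers for every peptide of the table."""
    out = {}
    for pep in table.peptides:
        gids = table.gene_map[pep]
        out[pep] = PeptideAnnotation(
            peptide=pep,
            taxonomy=resolve_taxonomy(gids, catalog),
            function=resolve_function(gids, catalog),
            cazy=resolve_cazy(gids, catalog),
        )
    return out


def taxon_state_label(assignment: TaxonAssignment) -> str:
    """Canonical string form of a taxon state: the genus name for unique
    peptides, ``ambiguous:A|B`` for ambiguous ones, ``unannotated`` else."""
    if assignment.category == UNIQUE:
        return next(iter(assignment.genera))
    if assignment.category == AMBIGUOUS:
        return "ambiguous:" + "|".join(sorted(assignment.genera))
    return UNANNOTATED


def summarize_annotations(
    table: PeptideTable,
    catalog: ProteinCatalog,
    annotations: Mapping[str, PeptideAnnotation] | None = None,
) -> pd.DataFrame:
    """Per-sample annotation-class counts and fractions over detected
    peptides.

    Returns a DataFrame indexed by sample with columns ``n_detected``,
    ``n_<class>`` and ``frac_<class>`` for the three taxon classes and the
    three KO classes.  Within each classification the fractions sum to one
    per sample.
    """
    if annotations is None:
        annotations = annotate_peptides(table, catalog)
    detected = table.detected()
    taxon = pd.Series(
        {p: annotations[p].taxonomy.category for p in table.peptides}, name="taxon"
    )
    func = pd.Series(
        {p: annotations[p].function.ko_class for p in table.peptides}, name="ko"
    )
    rows = []
    for sample in table.samples:
        mask = detected[sample]
        n = int(mask.sum())
        if n == 0:
            raise ValidationError(f"sample {sample!r} has zero detected peptides")
        row: dict[str, float] = {"n_detected": n}
        tcounts = taxon[mask.values].value_counts()
        for cls in TAXON_CLASSES:
            c = int(tcounts.get(cls, 0))
            row[f"n_{cls}"] = c
            row[f"frac_{cls}"] = c / n
        fcounts = func[mask.values].value_counts()
        for cls in FUNCTION_CLASSES:
            c = int(fcounts.get(cls, 0))
            row[f"n_ko_{cls}"] = c
            row[f"frac_ko_{cls}"] = c / n
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(table.samples, name="sample"))
    logger.info("annotation summary computed for %d samples", len(df))
    return df


def write_annotations(annotations: Mapping[str, PeptideAnnotation], path) -> None:
    rows = []
    for pep in annotations:
        a = annotations[pep]
        rows.append(
            {
                "peptide": pep,
                "taxon_class": a.taxonomy.category,
                "genera": "|".join(sorted(a.taxonomy.genera)),
                "ko_class": a.function.ko_class,
                "ko_codes": "|".join(sorted(a.function.ko_codes)),
                "cazy_families": "|".join(sorted(a.cazy.families)),
                "enzyme_names": "|".join(sorted(a.cazy.enzyme_names)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
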