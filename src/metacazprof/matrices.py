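"""Aggregation of peptide intensities to enzyme-level matrices and the
centered log-ratio (CLR) transform.

Intensities are aggregated by summation ("intensity-weighted"): the value
of an enzyme entity in a sample is the sum of the intensities of its
detected peptides.  Two matrix layouts are produced:

* the **enzyme matrix**, rows keyed by (taxon state, CAZy family, enzyme
  name) where the taxon state is a genus name, an ``ambiguous:A|B`` set
  label, or ``unannotated``;
* the **genus–family matrix**, rows keyed by (genus, family) pairs built
  from uniquely annotated peptides only — the node set of the
  co-occurrence network.

The CLR transform maps each sample column, viewed as a composition across
features, to log-ratios against its geometric mean; zeros are offset by a
pseudocount before taking logs.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import UNIQUE, PeptideAnnotation, taxon_state_label
from .core_model import PeptideTable, ProteinCatalog, ValidationError, logger

RAW = "raw"
CLR = "clr"


def aggregate_enzymes(
    table: PeptideTable,
    catalog: ProteinCatalog,
    annotations: Mapping[str, PeptideAnnotation],
) -> pd.DataFrame:
    """Sum peptide intensities into (taxon_state, family, enzyme_name) rows.

    Peptides without any CAZy annotation are excluded.  A peptide whose
    genes span several (family, name) combinations contributes its full
    intensity to each implied entity; the number of such duplicated
    peptides is logged.
    """
    acc: dict[tuple[str, str, str], np.ndarray] = {}
    n_samples = len(table.samples)
    duplicated = 0
    for pep in table.peptides:
        ann = annotations[pep]
        if not ann.cazy:
            continue
        state = taxon_state_label(ann.taxonomy)
        entities = {
            (state, fam, name if name is not None else f"{fam} family protein")
            for fam, name in ann.cazy.members
        }
        if len(entities) > 1:
            duplicated += 1
        row = table.intensity.loc[pep].values
        for ent in entities:
            acc.setdefault(ent, np.zeros(n_samples))
            acc[ent] += row
    if duplicated:
        logger.info(
            "aggregate_enzymes: %d peptide(s) span multiple entities; "
            "intensity duplicated across them",
            duplicated,
        )
    index = pd.MultiIndex.from_tuples(
        sorted(acc), names=["taxon_state", "family", "enzyme_name"]
    )
    data = np.array([acc[k] for k in index]) if len(acc) else np.empty((0, n_samples))
    df = pd.DataFrame(data, index=index, columns=table.samples)
    df.attrs["kind"] = RAW
    return df


def aggregate_genus_family(
    table: PeptideTable,
    catalog: ProteinCatalog,
    annotations: Mapping[str, PeptideAnnotation],
) -> pd.DataFrame:
    """Sum intensities of uniquely annotated CAZy peptides into
    (genus, family) rows; ambiguous and unannotated peptides are excluded."""
    acc: dict[tuple[str, str], np.ndarray] = {}
    n_samples = len(table.samples)
    for pep in table.peptides:
        ann = annotations[pep]
        if ann.taxonomy.category != UNIQUE or not ann.cazy:
            continue
        genus = next(iter(ann.taxonomy.genera))
        row = table.intensity.loc[pep].values
        for fam in ann.cazy.families:
            acc.setdefault((genus, fam), np.zeros(n_samples))
            acc[(genus, fam)] += row
    index = pd.MultiIndex.from_tuples(sorted(acc), names=["genus", "family"])
    data = np.array([acc[k] for k in index]) if len(acc) else np.empty((0, n_samples))
    df = pd.DataFrame(data, index=index, columns=table.samples)
    df.attrs["kind"] = RAW
    return df


def enzyme_entity_map(
    table: PeptideTable, annotations: Mapping[str, PeptideAnnotation]
) -> dict[str, set[tuple[str, str, str]]]:
    """Peptide -> enzyme-entity keys, consistent with the rows produced by
    :func:`aggregate_enzymes` (used for the differential roll-up)."""
    out: dict[str, set[tuple[str, str, str]]] = {}
    for pep in table.peptides:
        ann = annotations[pep]
        if not ann.cazy:
            continue
        state = taxon_state_label(ann.taxonomy)
        out[pep] = {
            (state, fam, name if name is not None else f"{fam} family protein")
            for fam, name in ann.cazy.members
        }
    return out


def resolve_pseudocount(matrix: pd.DataFrame, policy: str | float) -> float:
    """Turn a pseudocount policy into a number for the given matrix.

    ``"half_min"`` uses half the smallest positive value of the whole
    matrix (a single global offset keeps samples comparable); a numeric
    policy is used verbatim.
    """
    if isinstance(policy, str):
        if policy != "half_min":
            raise ValidationError(f"unknown pseudocount policy {policy!r}")
        positive = matrix.values[matrix.values > 0]
        if positive.size == 0:
            raise ValidationError("matrix has no positive entries")
        return 0.5 * float(positive.min())
    if policy < 0:
        raise ValidationError("pseudocount must be >= 0")
    return float(policy)


def clr_transform(matrix: pd.DataFrame, pseudocount_policy: str | float = "half_min") -> pd.DataFrame:
    """Centered log-ratio transform of each sample column.

    For a column x over D features: clr(x)_d = ln(x_d + eps) − mean_k
    ln(x_k + eps).  Every output column sums to zero (up to 1e-9).  A
    column that is entirely zero is an error, as is a zero entry when the
    resolved pseudocount is zero.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("CLR needs at least 2 features")
    if (matrix.values == 0).all(axis=0).any():
        bad = matrix.columns[(matrix.values == 0).all(axis=0)][0]
        raise ValidationError(f"column {bad!r} is entirely zero; CLR undefined")
    eps = resolve_pseudocount(matrix, pseudocount_policy)
    shifted = matrix.values + eps
    if (shifted <= 0).any():
        raise ValidationError(
            "zero intensities with a zero pseudocount; CLR undefined"
        )
    logx = np.log(shifted)
    out = pd.DataFrame(
        logx - logx.mean(axis=0, keepdims=True),
        index=matrix.index,
        columns=matrix.columns,
    )
    out.attrs["kind"] = CLR
    return out


_INDEX_COLS = {"enzyme": ["taxon_state", "family", "enzyme_name"], "genus-family": ["genus", "family"]}


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write an intensity matrix TSV; MultiIndex levels become leading
    columns."""
    matrix.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path, level: str) -> pd.DataFrame:
    """Read a matrix TSV written by :func:`write_matrix`; ``level`` is
    ``"enzyme"`` (3 index columns) or ``"genus-family"`` (2)."""
    if level not in _INDEX_COLS:
        raise ValidationError(f"unknown matrix level {level!r}")
    df = pd.read_csv(path, sep="\t", index_col=list(range(len(_INDEX_COLS[level]))))
    df.index.names = _INDEX_COLS[level]
    return df


def total_intensity_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to unit total intensity.

    CLR itself is invariant to per-sample scaling, so this only changes
    the relative size of the pseudocount; exposed as an option because the
    appropriate regime depends on the acquisition pipeline.
    """
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("cannot normalize a column with zero total intensity")
    out = matrix / totals
    out.attrs["kind"] = matrix.attrs.get("kind", RAW)
    return out
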