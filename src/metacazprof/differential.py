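"""Differential CAZy profiling between donor groups.

Donors are split at the cohort median relative abundance of a focal genus
(16S data).  Peptide-level CLR intensities are compared between the two
groups with a variance-moderated t statistic, peptide p-values are rolled
up to enzyme entities through the median-of-uniforms Beta law (the
reproducibility-optimized peptide change averaging construction), and
entity p-values are adjusted by Benjamini–Hochberg.  Significant enzymes
then drive hierarchical profile discovery and the shared-family set
comparison between two focal genera.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .annotation import UNIQUE, PeptideAnnotation
from .core_model import AbundanceTable, ValidationError, logger

HIGH = "high"
LOW = "low"


def split_by_median(abundance: AbundanceTable, genus: str) -> dict[str, str]:
    """Label each sample ``high`` (strictly above the cohort median of the
    focal genus) or ``low`` (at or below).  Even-n medians use the
    midpoint convention."""
    if genus not in abundance.values.index:
        raise ValidationError(f"genus {genus!r} absent from abundance table")
    row = abundance.values.loc[genus]
    med = float(np.median(row.values))
    labels = {s: (HIGH if v > med else LOW) for s, v in row.items()}
    if len(set(labels.values())) < 2:
        raise ValidationError(
            f"degenerate split: all samples tied at {med:.6g} for {genus!r}"
        )
    return labels


def peptide_stats(
    clr_peptides: pd.DataFrame,
    labels: Mapping[str, str],
    prior_df: float = 3.0,
    detected: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t statistics per peptide (high vs low).

    Pooled variances are shrunk toward the median peptide variance s0^2
    with ``prior_df`` pseudo-observations:

        s_mod^2 = (d0 * s0^2 + d * s^2) / (d0 + d),   d = n1 + n2 - 2

    and t = (mean_high - mean_low) / sqrt(s_mod^2 (1/n1 + 1/n2)) is
    referred to a t distribution with d0 + d degrees of freedom.
    ``prior_df = 0`` recovers the ordinary pooled t test.

    Peptides detected in fewer than 2 samples of either group (per the
    ``detected`` mask, if given) are skipped with a logged count.
    Returns a DataFrame indexed by peptide with columns ``logfc``
    (CLR units), ``t``, ``p``, ``df``.
    """
    if prior_df < 0:
        raise ValidationError("prior_df must be >= 0")
    high = [s for s in clr_peptides.columns if labels.get(s) == HIGH]
    low = [s for s in clr_peptides.columns if labels.get(s) == LOW]
    n1, n2 = len(high), len(low)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 samples")
    keep = np.ones(clr_peptides.shape[0], dtype=bool)
    if detected is not None:
        det = detected.reindex(index=clr_peptides.index, columns=clr_peptides.columns)
        keep = (det[high].sum(axis=1).values >= 2) & (det[low].sum(axis=1).values >= 2)
        skipped = int((~keep).sum())
        if skipped:
            logger.info(
                "peptide_stats: skipping %d peptide(s) below the detection "
                "threshold in a group",
                skipped,
            )
    X = clr_peptides.loc[keep]
    if X.shape[0] == 0:
        raise ValidationError("no peptide passes the detection threshold")
    xh = X[high].values
    xl = X[low].values
    m1, m2 = xh.mean(axis=1), xl.mean(axis=1)
    v1 = xh.var(axis=1, ddof=1)
    v2 = xl.var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    s0_sq = float(np.median(s2))
    d0 = float(prior_df)
    s2_mod = s2 if d0 == 0 else (d0 * s0_sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    df_t = d0 + d
    p = 2.0 * st.t.sf(np.abs(t), df_t)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"logfc": diff, "t": t, "p": p, "df": df_t}, index=X.index
    )


def rollup_median_p(pvalues: Sequence[float]) -> float:
    """Entity-level p from peptide p-values via the Beta order-statistic
    law of the median of n uniforms: p_roll = BetaCDF(median; a, a) with
    a = (n + 1) / 2 (exact for odd n, symmetric-Beta approximation for
    even n; the n = 1 case reduces to the identity)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("no peptide p-values to roll up")
    m = float(np.median(p))
    a = (p.size + 1) / 2.0
    return float(st.beta.cdf(m, a, a))


def rollup_ropeca(
    stats: pd.DataFrame,
    entity_map: Mapping[str, Iterable],
) -> pd.DataFrame:
    """Roll peptide statistics up to enzyme entities.

    ``entity_map`` maps each peptide to the entity key(s) it belongs to.
    Each entity's effect size is the median peptide log-fold-change and
    its p-value the Beta-law roll-up of its peptides' p-values.  Entities
    with no scored peptide are omitted (logged).
    """
    rows = []
    for pep in stats.index:
        for ent in entity_map.get(pep, ()):  # peptides without entity contribute nothing
            rows.append((ent, stats.at[pep, "p"], stats.at[pep, "logfc"]))
    if not rows:
        raise ValidationError("no peptide maps to any entity")
    df = pd.DataFrame(rows, columns=["entity", "p", "logfc"])
    n_entities_total = len({e for v in entity_map.values() for e in v})
    grouped = df.groupby("entity", sort=True)
    out = grouped.agg(
        n_peptides=("p", "size"),
        median_logfc=("logfc", "median"),
        median_p=("p", "median"),
    )
    a = (out["n_peptides"].values + 1) / 2.0
    out["p"] = st.beta.cdf(out["median_p"].values, a, a)
    out["p"] = np.clip(out["p"].values, np.finfo(float).tiny, 1.0)
    omitted = n_entities_total - len(out)
    if omitted > 0:
        logger.info("rollup: %d entit(ies) had no scored peptide; omitted", omitted)
    return out.drop(columns=["median_p"])


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), in the
    input order, capped at 1 with monotonicity enforced."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class ProfileAssignment:
    """Sample partition from hierarchical clustering of significant
    enzymes; ``positive`` is the cluster with the higher mean CLR."""

    clusters: dict[str, int]
    positive: frozenset[str]
    enzymes: list
    fdr_gate: float | None = None


def hierarchical_profiles(
    clr_enzymes: pd.DataFrame,
    k_clusters: int = 2,
    linkage: str = "complete",
    fdr_gate: float | None = None,
) -> ProfileAssignment:
    """Cluster samples on Euclidean distance over the CLR values of the
    (already gate-filtered) significant enzymes and cut the dendrogram
    into ``k_clusters``.

    The profile-positive cluster is the one whose samples have the higher
    mean CLR over the significant enzymes.
    """
    if clr_enzymes.shape[0] < 2:
        raise ValidationError(
            "fewer than 2 significant enzymes; relax the FDR gate"
        )
    if linkage not in {"complete", "average", "ward"}:
        raise ValidationError(f"unsupported linkage {linkage!r}")
    X = clr_enzymes.T.values  # samples as observations
    Z = sch.linkage(X, method=linkage, metric="euclidean")
    assignment = sch.fcluster(Z, t=k_clusters, criterion="maxclust")
    samples = list(clr_enzymes.columns)
    clusters = {s: int(c) for s, c in zip(samples, assignment)}
    means = {
        c: clr_enzymes.loc[:, [s for s in samples if clusters[s] == c]].values.mean()
        for c in set(assignment)
    }
    positive_id = max(means, key=lambda c: means[c])
    positive = frozenset(s for s in samples if clusters[s] == positive_id)
    return ProfileAssignment(
        clusters=clusters, positive=positive, enzymes=list(clr_enzymes.index), fdr_gate=fdr_gate
    )


def differential_profile_pipeline(
    table,
    catalog,
    annotations: Mapping[str, PeptideAnnotation],
    abundance: AbundanceTable,
    genus: str,
    prior_df: float = 3.0,
    fdr_gate: float = 0.01,
    k_clusters: int = 2,
    linkage: str = "complete",
    pseudocount_policy: str | float = "half_min",
) -> tuple[pd.DataFrame, ProfileAssignment]:
    """Median-split differential test with roll-up, BH adjustment and
    profile clustering, end to end.

    Returns the per-entity differential table (n_peptides, median_logfc,
    p, q) and the :class:`ProfileAssignment` from clustering the CLR
    enzyme matrix restricted to entities with q below the gate.
    """
    from .matrices import aggregate_enzymes, clr_transform, enzyme_entity_map

    labels = split_by_median(abundance, genus)
    pep_clr = clr_transform(table.intensity, pseudocount_policy)
    stats = peptide_stats(pep_clr, labels, prior_df=prior_df, detected=table.detected())
    records = rollup_ropeca(stats, enzyme_entity_map(table, annotations))
    records["q"] = adjust_bh(records["p"])
    significant = records.index[records["q"] < fdr_gate]
    enzymes = aggregate_enzymes(table, catalog, annotations)
    enzymes_clr = clr_transform(enzymes, pseudocount_policy)
    profile = hierarchical_profiles(
        enzymes_clr.loc[list(significant)],
        k_clusters=k_clusters,
        linkage=linkage,
        fdr_gate=fdr_gate,
    )
    return records, profile


@dataclass(frozen=True)
class SharedFamilyReport:
    """Set comparison of the CAZy repertoires of two genera, based purely
    on uniquely annotated peptides."""

    genus_a: str
    genus_b: str
    families_a: frozenset[str]
    families_b: frozenset[str]
    shared_families: frozenset[str]
    enzymes_same: frozenset[str]
    enzymes_different: frozenset[str]

    @property
    def n_families_a(self) -> int:
        return len(self.families_a)

    @property
    def n_families_b(self) -> int:
        return len(self.families_b)

    @property
    def n_shared(self) -> int:
        return len(self.shared_families)


def shared_family_analysis(
    annotations: Mapping[str, PeptideAnnotation],
    genus_a: str,
    genus_b: str,
) -> SharedFamilyReport:
    """Families observed for each genus (unique-genus peptides only),
    their intersection, and — within shared families — the enzyme names
    seen for both genera (*same*) versus only one (*different*)."""
    members: dict[str, set[tuple[str, str | None]]] = {genus_a: set(), genus_b: set()}
    for ann in annotations.values():
        if ann.taxonomy.category != UNIQUE or not ann.cazy:
            continue
        genus = next(iter(ann.taxonomy.genera))
        if genus in members:
            members[genus] |= set(ann.cazy.members)
    fams_a = frozenset(f for f, _ in members[genus_a])
    fams_b = frozenset(f for f, _ in members[genus_b])
    shared = fams_a & fams_b
    names_a = {n for f, n in members[genus_a] if f in shared and n is not None}
    names_b = {n for f, n in members[genus_b] if f in shared and n is not None}
    same = frozenset(names_a & names_b)
    different = frozenset((names_a | names_b) - same)
    return SharedFamilyReport(
        genus_a=genus_a,
        genus_b=genus_b,
        families_a=fams_a,
        families_b=fams_b,
        shared_families=shared,
        enzymes_same=same,
        enzymes_different=different,
    )
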