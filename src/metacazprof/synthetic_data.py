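"""Synthetic gut metaproteome generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at the scale of a real cohort:

* a donor community model — Dirichlet draws per donor from archetype-
  specific concentration vectors (a *Bacteroides*-dominant archetype, a
  *Prevotella*-high archetype, and a mixed archetype);
* an annotated gene catalog — per-genus CAZy family repertoires with a
  declared overlap between the two focal genera, plus background
  (non-CAZy) genes; a configurable fraction of genes lacks genus
  annotation and a configurable fraction of peptides is shared between
  two genera (those peptides resolve as taxonomically ambiguous);
* log-normal peptide intensities coupled to the true source genus
  abundance, with an extra "profile boost" planted on focal-genus CAZy
  peptides in donors of the matching archetype, and logistic
  intensity-dependent detection dropout.

Every simulation is a pure function of its spec and seed.  The planted
structure (archetype labels, boosted enzyme sets, co-occurring
genus–family clusters) is returned as :class:`GroundTruth` for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_model import (
    AbundanceTable,
    DietRecord,
    GeneRecord,
    PeptideTable,
    ProteinCatalog,
    ValidationError,
    logger,
)

#: Genera regularly observed in adult gut metaproteomes.
DEFAULT_GENERA = [
    "Bacteroides",
    "Prevotella",
    "Faecalibacterium",
    "Ruminococcus",
    "Alistipes",
    "Bifidobacterium",
    "Clostridium",
    "Collinsella",
    "Parabacteroides",
    "Eubacterium",
]


# ---------------------------------------------------------------------------
# Community model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Archetype:
    """One community archetype: Dirichlet concentrations per genus, the
    fraction of donors it covers, and (optionally) the focal genus whose
    CAZy enzymes receive the planted profile boost in its donors."""

    name: str
    concentrations: Mapping[str, float]
    fraction: float
    boosted_genus: str | None = None


@dataclass(frozen=True)
class CommunitySpec:
    archetypes: tuple[Archetype, ...]
    n_donors: int = 63

    def __post_init__(self) -> None:
        total = sum(a.fraction for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"archetype fractions sum to {total}, not 1")
        for a in self.archetypes:
            if not a.concentrations:
                raise ValidationError(f"archetype {a.name!r}: empty concentrations")
            if any(c <= 0 for c in a.concentrations.values()):
                raise ValidationError(f"archetype {a.name!r}: concentrations must be > 0")

    def boost_map(self) -> dict[str, str]:
        return {a.name: a.boosted_genus for a in self.archetypes if a.boosted_genus}


def default_community_spec(n_donors: int = 63) -> CommunitySpec:
    """Three archetypes: 40% Bacteroides-dominant, 13% Prevotella-high and
    47% mixed (63 donors yield a 25 / 8 / 30 split)."""

    def conc(**kw: float) -> dict[str, float]:
        base = {g: 1.5 for g in DEFAULT_GENERA}
        base.update(kw)
        return base

    return CommunitySpec(
        archetypes=(
            Archetype(
                "bacteroides_dominant",
                conc(Bacteroides=16.0, Faecalibacterium=5.0, Ruminococcus=2.0, Prevotella=0.4),
                fraction=0.40,
                boosted_genus="Bacteroides",
            ),
            Archetype(
                "prevotella_high",
                conc(Prevotella=12.0, Bacteroides=2.5, Faecalibacterium=4.0, Clostridium=1.0),
                fraction=0.13,
                boosted_genus="Prevotella",
            ),
            Archetype(
                "mixed",
                conc(Bacteroides=7.0, Faecalibacterium=6.0, Ruminococcus=3.0, Prevotella=0.8),
                fraction=0.47,
            ),
        ),
        n_donors=n_donors,
    )


def _largest_remainder_counts(fractions: Sequence[float], n: int) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def simulate_community(
    spec: CommunitySpec, seed: int = 0
) -> tuple[AbundanceTable, dict[str, str]]:
    """Draw per-donor genus compositions; donors are allocated to
    archetypes deterministically by largest-remainder rounding.

    Returns the relative-abundance table (columns sum to 1) and the
    donor -> archetype-name labels.
    """
    if spec.n_donors < 2:
        raise ValidationError("need at least 2 donors")
    rng = np.random.default_rng(seed)
    genera = sorted({g for a in spec.archetypes for g in a.concentrations})
    counts = _largest_remainder_counts([a.fraction for a in spec.archetypes], spec.n_donors)
    columns: list[np.ndarray] = []
    labels: dict[str, str] = {}
    donor = 0
    for arche, count in zip(spec.archetypes, counts):
        alpha = np.array([arche.concentrations.get(g, 1e-3) for g in genera])
        for _ in range(count):
            donor += 1
            sid = f"D{donor:02d}"
            columns.append(rng.dirichlet(alpha))
            labels[sid] = arche.name
    df = pd.DataFrame(
        np.column_stack(columns), index=genera, columns=list(labels.keys())
    )
    return AbundanceTable(df), labels


# ---------------------------------------------------------------------------
# Catalog model
# ---------------------------------------------------------------------------


def _default_family_pool() -> list[str]:
    return (
        [f"GH{i}" for i in range(1, 141)]
        + [f"PL{i}" for i in range(1, 30)]
        + [f"CE{i}" for i in range(1, 17)]
        + [f"GT{i}" for i in range(1, 31)]
    )


@dataclass(frozen=True)
class CatalogSpec:
    """Catalog shape: family repertoires, gene/peptide multiplicities and
    the annotation-class mix.

    ``shared_peptide_fraction`` is the fraction of peptides *of annotated
    genes* that also map to a homologous gene of another genus (those
    peptides resolve as ambiguous); ``unannotated_gene_fraction`` is the
    fraction of genes whose genus annotation is blanked.  With defaults
    0.70 and 0.30 the peptide class mix is 21% unique / 49% ambiguous /
    30% unannotated.
    """

    genera: tuple[str, ...] = tuple(DEFAULT_GENERA)
    focal_a: str = "Bacteroides"
    focal_b: str = "Prevotella"
    n_families_focal_a: int = 24
    n_families_focal_b: int = 16
    focal_overlap: float = 21 / 34
    n_families_other: int = 12
    enzymes_per_family: int = 2
    peptides_per_enzyme: int = 10
    background_genes_per_genus: int = 143
    peptides_per_background_gene: int = 10
    shared_peptide_fraction: float = 0.70
    unannotated_gene_fraction: float = 0.30
    enzyme_name_overlap: float = 0.23
    ko_single_prob: float = 0.78
    ko_multi_prob: float = 0.035

    def __post_init__(self) -> None:
        for name in (
            "focal_overlap",
            "shared_peptide_fraction",
            "unannotated_gene_fraction",
            "enzyme_name_overlap",
            "ko_single_prob",
            "ko_multi_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} must lie in [0, 1]")
        if min(self.n_families_focal_a, self.n_families_focal_b, self.n_families_other) < 1:
            raise ValidationError("family repertoires must be non-empty")
        if self.focal_a not in self.genera or self.focal_b not in self.genera:
            raise ValidationError("focal genera must be listed in genera")


@dataclass
class GroundTruth:
    """Planted structure of one simulated cohort."""

    archetype_labels: dict[str, str] = field(default_factory=dict)
    #: focal genus -> entity keys (genus, family, enzyme_name) of the
    #: boosted, uniquely attributable enzymes
    profile_enzymes: dict[str, frozenset] = field(default_factory=dict)
    #: focal genus -> (genus, family) co-occurrence network nodes planted
    #: as one cluster
    planted_clusters: dict[str, frozenset] = field(default_factory=dict)
    #: focal repertoires and their intersection, as realized in the catalog
    families: dict[str, frozenset] = field(default_factory=dict)
    shared_families: frozenset = frozenset()


@dataclass
class SimulatedCatalog:
    """Catalog plus the generator-internal truth needed to simulate
    intensities (true source genus of every peptide, which the annotation
    layer may not reveal)."""

    catalog: ProteinCatalog
    gene_map: dict[str, frozenset[str]]
    peptide_truth: pd.DataFrame  # peptide, gene_id, true_genus, family, enzyme_name, taxon_class
    truth: GroundTruth
    spec: CatalogSpec


def _draw_ko(rng: np.random.Generator, spec: CatalogSpec) -> frozenset[str]:
    u = rng.random()
    if u < spec.ko_single_prob:
        n = 1
    elif u < spec.ko_single_prob + spec.ko_multi_prob:
        n = 2
    else:
        return frozenset()
    return frozenset(f"K{rng.integers(1, 99999):05d}" for _ in range(n))


def simulate_catalog(spec: CatalogSpec, seed: int = 0) -> SimulatedCatalog:
    """Build the annotated catalog, the peptide -> gene multi-map and the
    catalog-level ground truth.

    The declared focal-repertoire overlap is realized exactly:
    |shared| = round(overlap * min repertoire size).  Peptide sharing is
    realized deterministically per gene (round(fraction * peptides per
    gene) shared peptides each).
    """
    rng = np.random.default_rng(seed)
    pool = _default_family_pool()
    n_shared = int(round(spec.focal_overlap * min(spec.n_families_focal_a, spec.n_families_focal_b)))
    chosen = rng.choice(
        len(pool),
        size=n_shared
        + (spec.n_families_focal_a - n_shared)
        + (spec.n_families_focal_b - n_shared),
        replace=False,
    )
    fam_names = [pool[i] for i in chosen]
    shared = fam_names[:n_shared]
    extra_a = fam_names[n_shared : spec.n_families_focal_a]
    extra_b = fam_names[spec.n_families_focal_a :]
    repertoires: dict[str, list[str]] = {
        spec.focal_a: sorted(shared + extra_a),
        spec.focal_b: sorted(shared + extra_b),
    }
    for genus in spec.genera:
        if genus in repertoires:
            continue
        picks = rng.choice(len(pool), size=spec.n_families_other, replace=False)
        repertoires[genus] = sorted(pool[i] for i in picks)

    # enzyme name slots shared between the focal genera within shared families
    slot_pool = [(fam, j) for fam in sorted(shared) for j in range(spec.enzymes_per_family)]
    n_same = int(round(spec.enzyme_name_overlap * len(slot_pool)))
    same_idx = rng.choice(len(slot_pool), size=n_same, replace=False) if slot_pool else []
    same_slots = {slot_pool[i] for i in np.sort(same_idx)} if len(slot_pool) else set()

    records: list[GeneRecord] = []
    gene_truth: list[tuple[str, str, str | None, str | None]] = []  # id, genus, family, name
    for genus in spec.genera:
        for fam in repertoires[genus]:
            for j in range(spec.enzymes_per_family):
                gid = f"{genus}_{fam}_g{j}"
                if genus in (spec.focal_a, spec.focal_b) and (fam, j) in same_slots:
                    name = f"{fam}_enz{j}"
                else:
                    name = f"{fam}_enz{j}_{genus[:4]}"
                gene_truth.append((gid, genus, fam, name))
        for b in range(spec.background_genes_per_genus):
            gene_truth.append((f"{genus}_bg{b:04d}", genus, None, None))

    # blank the genus of a fixed fraction of genes, per genus
    unannotated: set[str] = set()
    for genus in spec.genera:
        ids = [gid for gid, g, _, _ in gene_truth if g == genus]
        n_un = int(round(spec.unannotated_gene_fraction * len(ids)))
        picked = rng.choice(len(ids), size=n_un, replace=False)
        unannotated |= {ids[i] for i in np.sort(picked)}

    gene_ko: dict[str, frozenset[str]] = {}
    for gid, genus, fam, name in gene_truth:
        gene_ko[gid] = _draw_ko(rng, spec)
        records.append(
            GeneRecord(
                gene_id=gid,
                genus=None if gid in unannotated else genus,
                ko_codes=gene_ko[gid],
                cazy_family=fam,
                enzyme_name=name,
            )
        )

    # peptides; ambiguous ones get a homolog gene in a partner genus
    homologs: dict[tuple[str, str], str] = {}
    gene_map: dict[str, frozenset[str]] = {}
    truth_rows = []
    other = {g: [h for h in spec.genera if h != g] for g in spec.genera}
    pep_idx = 0
    for gid, genus, fam, name in gene_truth:
        k = spec.peptides_per_enzyme if fam is not None else spec.peptides_per_background_gene
        annotated = gid not in unannotated
        n_amb = int(round(spec.shared_peptide_fraction * k)) if annotated else 0
        amb_flags = np.zeros(k, dtype=bool)
        if n_amb:
            amb_flags[rng.choice(k, size=n_amb, replace=False)] = True
        for flag in amb_flags:
            pep_idx += 1
            pep = f"pep{pep_idx:06d}"
            if flag:
                partner = other[genus][rng.integers(len(other[genus]))]
                key = (gid, partner)
                if key not in homologs:
                    hom_id = f"hom_{gid}_{partner[:4]}"
                    homologs[key] = hom_id
                    records.append(
                        GeneRecord(
                            gene_id=hom_id,
                            genus=partner,
                            ko_codes=gene_ko[gid],
                            cazy_family=fam,
                            enzyme_name=name,
                        )
                    )
                gene_map[pep] = frozenset({gid, homologs[key]})
                cls = "ambiguous"
            else:
                gene_map[pep] = frozenset({gid})
                cls = "unique" if annotated else "unannotated"
            truth_rows.append(
                {
                    "peptide": pep,
                    "gene_id": gid,
                    "true_genus": genus,
                    "family": fam or "",
                    "enzyme_name": name or "",
                    "taxon_class": cls,
                }
            )
    peptide_truth = pd.DataFrame(truth_rows).set_index("peptide")

    catalog = ProteinCatalog(records)
    truth = GroundTruth()
    for focal in (spec.focal_a, spec.focal_b):
        fams = frozenset(repertoires[focal])
        truth.families[focal] = fams
        annotated_enzymes = {
            (genus, fam, name)
            for gid, genus, fam, name in gene_truth
            if genus == focal and fam is not None and gid not in unannotated
        }
        truth.profile_enzymes[focal] = frozenset(annotated_enzymes)
        truth.planted_clusters[focal] = frozenset(
            {(genus, fam) for genus, fam, _ in annotated_enzymes}
        )
    truth.shared_families = frozenset(shared)
    logger.info(
        "simulated catalog: %d genes, %d peptides, focal repertoires %d/%d (%d shared)",
        len(catalog),
        len(peptide_truth),
        spec.n_families_focal_a,
        spec.n_families_focal_b,
        n_shared,
    )
    return SimulatedCatalog(
        catalog=catalog,
        gene_map=gene_map,
        peptide_truth=peptide_truth,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Intensity model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    """Intensity and detection model parameters (natural-log scale).

    A detected peptide's log-intensity is

        base + coupling * ln(genus abundance) + gene effect
             + boost (focal CAZy peptide in matching archetype) + N(0, sigma)

    and detection is Bernoulli with probability
    ``expit((log_intensity - detect_mid) / detect_scale)``.
    """

    sigma: float = 1.0
    base_log_intensity: float = 20.0
    coupling: float = 1.0
    profile_boost: float = 2.0
    detect_mid: float = 15.58
    detect_scale: float = 1.5
    enzyme_effect_sd: float = 0.8
    sample_scale_sd: float = 0.0
    abundance_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.enzyme_effect_sd < 0 or self.sample_scale_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.detect_scale < 0:
            raise ValidationError("detect_scale must be >= 0")


def simulate_intensities(
    simcat: SimulatedCatalog,
    abundance: AbundanceTable,
    labels: Mapping[str, str],
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    boost_map: Mapping[str, str] | None = None,
) -> tuple[PeptideTable, GroundTruth]:
    """Draw the peptide × sample intensity matrix.

    ``boost_map`` maps archetype name -> boosted focal genus (default:
    the mapping of :func:`default_community_spec`).  Returns the peptide
    table (undetected-everywhere peptides dropped) and the completed
    ground truth (archetype labels attached).
    """
    if boost_map is None:
        boost_map = default_community_spec().boost_map()
    truth_df = simcat.peptide_truth
    genera_needed = set(truth_df["true_genus"])
    missing = genera_needed - set(abundance.genera)
    if missing:
        raise ValidationError(f"catalog genera absent from abundance table: {sorted(missing)}")
    samples = abundance.samples
    if set(labels) != set(samples):
        raise ValidationError("archetype labels must cover exactly the abundance samples")

    rng = np.random.default_rng(seed)
    genus_order = abundance.genera
    genus_idx = {g: i for i, g in enumerate(genus_order)}
    pep_genus = truth_df["true_genus"].map(genus_idx).values
    is_cazy = (truth_df["family"].values != "").astype(bool)

    lnA = np.log(np.clip(abundance.values.values, noise.abundance_floor, None))
    n_pep, n_samp = len(truth_df), len(samples)

    # per-gene expression effect, shared by all peptides of a gene
    gene_ids = truth_df["gene_id"].values
    unique_genes = pd.unique(gene_ids)
    effects = dict(zip(unique_genes, rng.normal(0.0, noise.enzyme_effect_sd, len(unique_genes))))
    pep_effect = np.array([effects[g] for g in gene_ids])

    boosted = np.zeros((n_pep, n_samp))
    if noise.profile_boost != 0:
        for j, s in enumerate(samples):
            focal = boost_map.get(labels[s])
            if focal is None:
                continue
            mask = is_cazy & (truth_df["true_genus"].values == focal)
            boosted[mask, j] = noise.profile_boost

    mu = (
        noise.base_log_intensity
        + noise.coupling * lnA[pep_genus, :]
        + pep_effect[:, None]
        + boosted
    )
    if noise.sample_scale_sd > 0:
        mu = mu + rng.normal(0.0, noise.sample_scale_sd, n_samp)[None, :]
    x = mu + (rng.normal(0.0, noise.sigma, (n_pep, n_samp)) if noise.sigma > 0 else 0.0)
    if noise.detect_scale > 0:
        p_detect = expit((x - noise.detect_mid) / noise.detect_scale)
    else:
        p_detect = (x >= noise.detect_mid).astype(float)
    detected = rng.random((n_pep, n_samp)) < p_detect
    intensity = np.where(detected, np.exp(x), 0.0)

    df = pd.DataFrame(intensity, index=truth_df.index, columns=samples)
    table = PeptideTable(df, simcat.gene_map)
    truth = GroundTruth(
        archetype_labels=dict(labels),
        profile_enzymes=dict(simcat.truth.profile_enzymes),
        planted_clusters=dict(simcat.truth.planted_clusters),
        families=dict(simcat.truth.families),
        shared_families=simcat.truth.shared_families,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Diet model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DietSpec:
    """Diet questionnaire generator: per-component location parameters
    (days/week for the food frequencies; score units for IDQ), a common
    noise scale, and optional per-archetype location shifts (default no
    shift, i.e. a null diet difference between archetypes)."""

    locations: Mapping[str, float] = field(
        default_factory=lambda: {
            "idq": 10.0,
            "whole_grains": 7.0,
            "vegetables": 7.0,
            "fruits_and_berries": 7.0,
        }
    )
    sigma: float = 1.5
    shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


def simulate_diet(
    labels: Mapping[str, str], spec: DietSpec = DietSpec(), seed: int = 0
) -> list[DietRecord]:
    """Draw diet records per donor; food frequencies are clipped to the
    0–7 days/week range (IDQ to 0–15)."""
    if not labels:
        raise ValidationError("no donor labels given")
    rng = np.random.default_rng(seed)
    records = []
    for sid in labels:
        arche = labels[sid]
        shift = spec.shifts.get(arche, {})
        vals = {}
        for comp, loc in spec.locations.items():
            v = loc + shift.get(comp, 0.0) + rng.normal(0.0, spec.sigma)
            hi = 15.0 if comp == "idq" else 7.0
            vals[comp] = float(np.clip(v, 0.0, hi))
        records.append(
            DietRecord(
                sample_id=sid,
                idq=vals.get("idq", 10.0),
                whole_grains=vals.get("whole_grains", 7.0),
                vegetables=vals.get("vegetables", 7.0),
                fruits_and_berries=vals.get("fruits_and_berries", 7.0),
            )
        )
    return records


# ---------------------------------------------------------------------------
# One-call cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    abundance: AbundanceTable
    table: PeptideTable
    catalog: ProteinCatalog
    gene_map: dict[str, frozenset[str]]
    diet: list[DietRecord]
    truth: GroundTruth


def simulate_cohort(
    seed: int = 0,
    community: CommunitySpec | None = None,
    catalog_spec: CatalogSpec | None = None,
    noise: NoiseSpec = NoiseSpec(),
    diet_spec: DietSpec = DietSpec(),
) -> SyntheticCohort:
    """Simulate a full cohort (community, catalog, intensities, diet)
    from a single seed; sub-stage seeds are derived by fixed offsets."""
    community = community or default_community_spec()
    catalog_spec = catalog_spec or CatalogSpec()
    abundance, labels = simulate_community(community, seed)
    simcat = simulate_catalog(catalog_spec, seed + 1_000_003)
    table, truth = simulate_intensities(
        simcat, abundance, labels, noise, seed + 2_000_003, community.boost_map()
    )
    diet = simulate_diet(labels, diet_spec, seed + 3_000_003)
    return SyntheticCohort(
        abundance=abundance,
        table=table,
        catalog=simcat.catalog,
        gene_map=simcat.gene_map,
        diet=diet,
        truth=truth,
    )
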