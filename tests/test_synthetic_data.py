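"""Determinism, declared-structure realization and limit cases of the
synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from metacazprof.core_model import ValidationError
from metacazprof.synthetic_data import (
    Archetype,
    CatalogSpec,
    CommunitySpec,
    DietSpec,
    NoiseSpec,
    default_community_spec,
    simulate_catalog,
    simulate_community,
    simulate_diet,
    simulate_intensities,
)


class TestCommunity:
    def test_columns_sum_to_one_and_reproducible(self):
        spec = CommunitySpec(
            archetypes=(Archetype("a", {"X": 1.0, "Y": 1.0}, 1.0),), n_donors=2
        )
        t1, l1 = simulate_community(spec, seed=7)
        t2, l2 = simulate_community(spec, seed=7)
        np.testing.assert_allclose(t1.values.sum(axis=0), 1.0, atol=1e-12)
        pd.testing.assert_frame_equal(t1.values, t2.values)
        assert l1 == l2

    def test_deterministic_donor_allocation(self):
        spec = CommunitySpec(
            archetypes=(
                Archetype("a", {"X": 1.0}, 0.6),
                Archetype("b", {"X": 1.0}, 0.4),
            ),
            n_donors=10,
        )
        _, labels = simulate_community(spec, seed=0)
        counts = pd.Series(labels).value_counts()
        assert counts["a"] == 6 and counts["b"] == 4

    def test_default_split_mirrors_cohort(self):
        _, labels = simulate_community(default_community_spec(), seed=0)
        counts = pd.Series(labels).value_counts()
        assert counts["bacteroides_dominant"] == 25
        assert counts["prevotella_high"] == 8
        assert counts["mixed"] == 30

    def test_concentration_weighting_drives_median_dominance(self):
        """A genus with dominant concentration has the highest median
        relative abundance across donors (checked over many draws)."""
        spec = CommunitySpec(
            archetypes=(
                Archetype("a", {"Heavy": 10.0, "L1": 1.0, "L2": 1.0}, 1.0),
            ),
            n_donors=1000,
        )
        table, _ = simulate_community(spec, seed=1)
        medians = table.values.median(axis=1)
        assert medians["Heavy"] > medians[["L1", "L2"]].max()

    def test_too_few_donors_rejected(self):
        spec = CommunitySpec(archetypes=(Archetype("a", {"X": 1.0}, 1.0),), n_donors=1)
        with pytest.raises(ValidationError):
            simulate_community(spec, seed=0)


class TestCatalog:
    def test_declared_overlap_realized_exactly(self):
        spec = CatalogSpec(n_families_focal_a=20, n_families_focal_b=10, focal_overlap=0.5)
        sim = simulate_catalog(spec, seed=3)
        fams_a = sim.truth.families["Bacteroides"]
        fams_b = sim.truth.families["Prevotella"]
        assert len(fams_a) == 20 and len(fams_b) == 10
        assert len(fams_a & fams_b) == round(0.5 * 10)
        assert sim.truth.shared_families == fams_a & fams_b

    def test_shared_peptide_count_per_gene(self):
        spec = CatalogSpec(shared_peptide_fraction=0.7, unannotated_gene_fraction=0.0)
        sim = simulate_catalog(spec, seed=0)
        per_gene = sim.peptide_truth.groupby("gene_id")["taxon_class"].apply(
            lambda s: (s == "ambiguous").sum()
        )
        k = spec.peptides_per_enzyme
        assert (abs(per_gene - round(0.7 * k)) <= 1).all()

    def test_zero_sharing_gives_single_genus_peptides(self):
        spec = CatalogSpec(shared_peptide_fraction=0.0, unannotated_gene_fraction=0.0)
        sim = simulate_catalog(spec, seed=0)
        assert (sim.peptide_truth["taxon_class"] == "unique").all()
        assert all(len(g) == 1 for g in sim.gene_map.values())

    def test_fully_unannotated_catalog(self):
        spec = CatalogSpec(unannotated_gene_fraction=1.0)
        sim = simulate_catalog(spec, seed=0)
        assert (sim.peptide_truth["taxon_class"] == "unannotated").all()
        assert sim.catalog.genera() == set()  # all genus annotations blanked

    def test_planted_enzymes_exist_in_catalog(self):
        sim = simulate_catalog(CatalogSpec(), seed=5)
        catalog_entities = {
            (g.genus, g.cazy_family, g.enzyme_name)
            for g in sim.catalog
            if g.cazy_family is not None and g.genus is not None
        }
        for ents in sim.truth.profile_enzymes.values():
            assert ents <= catalog_entities

    def test_determinism(self):
        s1 = simulate_catalog(CatalogSpec(), seed=9)
        s2 = simulate_catalog(CatalogSpec(), seed=9)
        pd.testing.assert_frame_equal(s1.peptide_truth, s2.peptide_truth)
        assert s1.gene_map == s2.gene_map


class TestIntensities:
    def _small_setup(self, seed=0):
        community = CommunitySpec(
            archetypes=(
                Archetype("a", {g: 2.0 for g in CatalogSpec().genera}, 0.5, "Bacteroides"),
                Archetype("b", {g: 2.0 for g in CatalogSpec().genera}, 0.5, "Prevotella"),
            ),
            n_donors=6,
        )
        spec = CatalogSpec(
            n_families_focal_a=3,
            n_families_focal_b=2,
            focal_overlap=0.5,
            n_families_other=2,
            background_genes_per_genus=5,
        )
        abundance, labels = simulate_community(community, seed)
        simcat = simulate_catalog(spec, seed)
        return community, simcat, abundance, labels

    def test_noise_free_intensity_is_monotone_in_abundance(self):
        community, simcat, abundance, labels = self._small_setup()
        noise = NoiseSpec(
            sigma=0.0,
            enzyme_effect_sd=0.0,
            profile_boost=0.0,
            detect_mid=-1e9,  # detection probability 1
        )
        table, _ = simulate_intensities(
            simcat, abundance, labels, noise, seed=1, boost_map={}
        )
        # per peptide, intensity ordering across samples follows the true
        # genus abundance ordering exactly
        lnA = np.log(abundance.values)
        for pep in table.peptides[:20]:
            genus = simcat.peptide_truth.loc[pep, "true_genus"]
            x = table.intensity.loc[pep].values
            order = np.argsort(lnA.loc[genus].values)
            assert (np.diff(x[order]) >= 0).all()

    def test_same_seed_identical_output(self):
        _, simcat, abundance, labels = self._small_setup()
        t1, _ = simulate_intensities(simcat, abundance, labels, NoiseSpec(), seed=4)
        t2, _ = simulate_intensities(simcat, abundance, labels, NoiseSpec(), seed=4)
        pd.testing.assert_frame_equal(t1.intensity, t2.intensity)

    def test_unknown_genus_rejected(self):
        _, simcat, abundance, labels = self._small_setup()
        trimmed = abundance.values.drop(index="Prevotella")
        from metacazprof.core_model import AbundanceTable

        bad = AbundanceTable(trimmed / trimmed.sum(axis=0))
        with pytest.raises(ValidationError, match="Prevotella"):
            simulate_intensities(simcat, bad, labels, NoiseSpec(), seed=0)

    def test_null_boost_balances_archetypes(self):
        """With profile_boost = 0, planted-profile enzymes show no mean
        log-intensity difference between archetypes (Monte-Carlo check)."""
        community, simcat, abundance, labels = self._small_setup()
        noise = NoiseSpec(profile_boost=0.0, detect_mid=-1e9, coupling=0.0)
        diffs = []
        for rep in range(200):
            table, truth = simulate_intensities(
                simcat, abundance, labels, noise, seed=100 + rep, boost_map=community.boost_map()
            )
            prof_peps = simcat.peptide_truth.index[
                (simcat.peptide_truth["true_genus"] == "Prevotella")
                & (simcat.peptide_truth["family"] != "")
            ]
            prof_peps = [p for p in prof_peps if p in table.intensity.index]
            X = np.log(table.intensity.loc[prof_peps])
            in_b = [s for s in table.samples if labels[s] == "b"]
            out_b = [s for s in table.samples if labels[s] == "a"]
            diffs.append(X[in_b].values.mean() - X[out_b].values.mean())
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-12


class TestEmulationTargets:
    def test_peptide_counts_in_calibration_range(self, default_cohort):
        det = (default_cohort.table.intensity.values > 0).sum(axis=0)
        assert ((det >= 5415) & (det <= 17904)).all()

    def test_class_fractions_in_calibration_ranges(self, default_cohort):
        from metacazprof.annotation import summarize_annotations

        summ = summarize_annotations(default_cohort.table, default_cohort.catalog)
        assert summ["frac_unique"].between(0.146, 0.275).mean() >= 0.9
        assert summ["frac_ambiguous"].between(0.385, 0.590).mean() >= 0.9
        assert summ["frac_unannotated"].between(0.138, 0.432).mean() >= 0.9


class TestDiet:
    def test_frequencies_clipped_and_deterministic(self):
        labels = {f"D{i}": "a" for i in range(40)}
        r1 = simulate_diet(labels, DietSpec(sigma=3.0), seed=2)
        r2 = simulate_diet(labels, DietSpec(sigma=3.0), seed=2)
        assert r1 == r2
        assert all(0 <= r.whole_grains <= 7 for r in r1)

    def test_location_parameters_set_generated_medians(self):
        """Location 5 vs 7 (days/week) reproduce medians 5 and 7 at
        large n, clipping included."""
        labels_a = {f"A{i}": "a" for i in range(2000)}
        labels_b = {f"B{i}": "b" for i in range(2000)}
        spec_a = DietSpec(locations={"whole_grains": 5.0})
        spec_b = DietSpec(locations={"whole_grains": 7.0})
        med_a = np.median([r.whole_grains for r in simulate_diet(labels_a, spec_a, 3)])
        med_b = np.median([r.whole_grains for r in simulate_diet(labels_b, spec_b, 3)])
        assert med_a == pytest.approx(5.0, abs=0.15)
        assert med_b == pytest.approx(7.0, abs=1e-12)

    def test_forced_separation_gives_exact_third(self):
        """A shift forcing all of group a below group b with n = 2 + 2
        yields the enumerated two-sided p = 1/3."""
        from metacazprof.ordination_stats import mann_whitney

        labels = {"D1": "a", "D2": "a", "D3": "b", "D4": "b"}
        spec = DietSpec(
            locations={"whole_grains": 3.5},
            sigma=0.1,
            shifts={"b": {"whole_grains": 3.0}},
        )
        recs = {r.sample_id: r.whole_grains for r in simulate_diet(labels, spec, seed=1)}
        res = mann_whitney([recs["D1"], recs["D2"]], [recs["D3"], recs["D4"]])
        assert res.p_value == pytest.approx(1 / 3)

    def test_null_shift_type_i_error_near_nominal(self):
        """With no archetype shift, Mann-Whitney on a diet component
        rejects at roughly the nominal rate."""
        from metacazprof.ordination_stats import mann_whitney

        labels = {f"D{i}": ("a" if i < 10 else "b") for i in range(20)}
        rejections = 0
        n_rep = 1000
        for rep in range(n_rep):
            recs = simulate_diet(labels, DietSpec(locations={"vegetables": 3.5}, sigma=1.0), seed=rep)
            vals = {r.sample_id: r.vegetables for r in recs}
            a = [vals[f"D{i}"] for i in range(10)]
            b = [vals[f"D{i}"] for i in range(10, 20)]
            rejections += mann_whitney(a, b).p_value < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)
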