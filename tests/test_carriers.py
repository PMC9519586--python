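"""Hardy-Weinberg carrier statistics, category aggregation, genotype census."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dsdscreen.carriers import (
    aggregate_by_category,
    biallelic_risk,
    cohort_carrier_fraction,
    cumulative_q,
    fold_changes,
    genotype_census,
    het_carrier_freq,
    one_in_n,
    per_gene_estimates,
)
from dsdscreen.ingest import AnnotatedVariant
from dsdscreen.panel import Category, GenePanelEntry, Inheritance, TierLabel
from dsdscreen.tiers import TierAssignment


def _var(gene, pos, aaf, an=100000):
    return AnnotatedVariant("chr1", pos, "A", "G", gene=gene, an=an, ac=int(round(aaf * an)))


def _assign(gene, pos, tier, ambiguous=False):
    return TierAssignment(("chr1", pos, "A", "G"), gene, TierLabel(tier), ambiguous=ambiguous)


class TestCumulativeQ:
    def test_empty_set_is_zero(self):
        assert cumulative_q("G1", TierLabel.SET4, [], []) == 0.0

    def test_sum_of_two(self):
        variants = [_var("G1", 1, 0.001), _var("G1", 2, 0.002)]
        assignments = [_assign("G1", 1, "SET1"), _assign("G1", 2, "SET2")]
        assert cumulative_q("G1", TierLabel.SET2, assignments, variants) == pytest.approx(0.003)
        assert cumulative_q("G1", TierLabel.SET1, assignments, variants) == pytest.approx(0.001)

    def test_single_reported_intronic_allele(self):
        # CYP21A2 c.293-13C>G: the gene's only Set 3 allele, frequency 0.00256
        variants = [_var("CYP21A2", 1, 0.00256)]
        assignments = [_assign("CYP21A2", 1, "SET3")]
        q = cumulative_q("CYP21A2", TierLabel.SET3, assignments, variants)
        assert q == pytest.approx(0.00256)

    def test_ambiguous_excluded(self):
        variants = [_var("G1", 1, 0.1), _var("G1", 2, 0.2)]
        assignments = [_assign("G1", 1, "SET1"), _assign("G1", 2, "SET1", ambiguous=True)]
        assert cumulative_q("G1", TierLabel.SET4, assignments, variants) == pytest.approx(0.1)


class TestHetCarrierFreq:
    @pytest.mark.parametrize("q,want", [(0.0, 0.0), (0.5, 0.5), (1.0, 0.0)])
    def test_formula_endpoints(self, q, want):
        assert het_carrier_freq(q) == pytest.approx(want)

    def test_reported_total_gives_one_in_40(self):
        # printed cumulative Q for the third tier: 0.01248
        f = het_carrier_freq(0.01248)
        assert f == pytest.approx(2 * (1 - 0.01248) * 0.01248)
        assert one_in_n(f) == 40

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            het_carrier_freq(1.5)

    def test_symmetric_and_bounded(self):
        qs = np.linspace(0, 1, 101)
        vals = np.array([het_carrier_freq(q) for q in qs])
        assert np.allclose(vals, vals[::-1])
        assert vals.max() == pytest.approx(0.5) and vals.argmax() == 50


class TestBiallelicRisk:
    def test_zero(self):
        assert biallelic_risk(0.0, "autosomal_recessive") == 0.0
        assert biallelic_risk(0.0, "x_linked_recessive") == 0.0

    def test_autosomal_square_one_in_29_thousand(self):
        # HGMD-DM CYP21A2 allele at frequency 0.00584 → homozygote rate Q²
        risk = biallelic_risk(0.00584, Inheritance.AUTOSOMAL_RECESSIVE)
        assert risk == pytest.approx(3.411e-5, rel=1e-3)
        assert one_in_n(risk) // 1000 == 29

    def test_x_linked_q_over_three(self):
        assert biallelic_risk(0.001308, "x_linked_recessive") == pytest.approx(0.000436)

    def test_x_linked_alternative_mode(self):
        assert biallelic_risk(0.001308, "x_linked_recessive", x_linked_mode="Q") == 0.001308

    def test_unknown_inheritance_rejected(self):
        with pytest.raises(ValueError):
            biallelic_risk(0.1, "dominant")

    def test_monotone_in_q(self):
        qs = np.linspace(0, 1, 50)
        for mode in (Inheritance.AUTOSOMAL_RECESSIVE, Inheritance.X_LINKED_RECESSIVE):
            vals = [biallelic_risk(q, mode) for q in qs]
            assert all(b >= a for a, b in zip(vals, vals[1:]))


def _mini_panel():
    mk = lambda g, cat, inh: GenePanelEntry(g, cat, inh, "chr1", 1, 10)  # noqa: E731
    return [
        mk("GD1", Category.GD, Inheritance.AUTOSOMAL_RECESSIVE),
        mk("HSA1", Category.HSA, Inheritance.AUTOSOMAL_RECESSIVE),
        mk("AR", Category.HSA, Inheritance.X_LINKED_RECESSIVE),
        mk("CHG1", Category.CHG, Inheritance.AUTOSOMAL_RECESSIVE),
    ]


class TestAggregateByCategory:
    def _per_gene(self, q_map):
        rows = []
        panel = _mini_panel()
        for e in panel:
            for tier in ("SET1", "SET2", "SET3", "SET4"):
                q = q_map.get((e.gene_symbol, tier), 0.0)
                rows.append(
                    {
                        "gene": e.gene_symbol,
                        "category": e.category.value,
                        "tier": tier,
                        "q": q,
                        "bi_risk": biallelic_risk(q, e.inheritance),
                    }
                )
        return pd.DataFrame(rows), panel

    def test_all_zero(self):
        per_gene, panel = self._per_gene({})
        summary = aggregate_by_category(per_gene, panel)
        assert (summary.values == 0).all()

    def test_total_excludes_x_linked_row(self):
        per_gene, panel = self._per_gene(
            {("HSA1", "SET4"): 0.01, ("AR", "SET4"): 0.3, ("GD1", "SET4"): 0.001}
        )
        summary = aggregate_by_category(per_gene, panel)
        assert summary.loc["AR", "SET4"] == pytest.approx(0.1)  # Q/3
        assert summary.loc["Total", "SET4"] == pytest.approx(0.01**2 + 0.001**2)
        # machine-precision identity of Total with the category sum
        assert summary.loc["Total"].equals(summary.loc[["GD", "HSA", "CHG"]].sum())

    def test_reported_set2_total_at_3sf(self):
        # category components 1.86e-7 + 8.13e-6 + 1.72e-7 print as 8.49E-06
        total = 1.86e-7 + 8.13e-6 + 1.72e-7
        assert f"{total:.2E}" == "8.49E-06"

    def test_reported_hsa_fold_change(self):
        df = pd.DataFrame({"SET2": [8.13e-6], "SET3": [1.93e-5]}, index=["HSA"])
        folds = fold_changes(df)
        assert round(float(folds.loc["HSA", "SET3/SET2"]), 2) == 2.37


class TestCohortCarrierFraction:
    def test_single_gene_forms_agree(self):
        out = cohort_carrier_fraction({"G1": 0.01})
        assert out["pooled"] == pytest.approx(out["product"])

    def test_product_form_matches_two_locus_enumeration(self):
        """Exhaustive 2-locus HWE genotype enumeration (independent loci)."""
        q = 0.01
        p_carrier = 0.0
        geno_p = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        for (d1, p1), (d2, p2) in itertools.product(enumerate(geno_p), repeat=2):
            if d1 == 1 or d2 == 1:  # heterozygous at either locus
                p_carrier += p1 * p2
        out = cohort_carrier_fraction({"G1": q, "G2": q})
        assert out["product"] == pytest.approx(p_carrier, rel=1e-12)
        assert out["pooled"] == pytest.approx(2 * 0.98 * 0.02)

    def test_reported_q_total_pooled_value(self):
        out = cohort_carrier_fraction({"all": 0.02997})
        assert out["pooled"] == pytest.approx(0.0581404, rel=1e-4)
        assert out["pooled_one_in_n"] == 17


class TestGenotypeCensus:
    def test_all_zero_matrix_empty(self):
        d = np.zeros((3, 5), dtype=int)
        meta = [(("chr1", i, "A", "G"), "G1") for i in range(3)]
        census = genotype_census(d, meta, [m[0] for m in meta])
        assert census.homozygotes == [] and census.compound_hets == []
        assert census.het_carriers == {} and census.multi_gene_carriers == []

    def test_compound_het_definition(self):
        d = np.array([[1, 0], [1, 0]])
        meta = [(("chr1", 1, "A", "G"), "G1"), (("chr1", 2, "A", "G"), "G1")]
        census = genotype_census(d, meta, [m[0] for m in meta])
        assert len(census.compound_hets) == 1 and census.homozygotes == []
        assert census.compound_hets[0][0] == 0  # individual index

    def test_untier_variants_ignored(self):
        d = np.array([[2, 2]])
        meta = [(("chr1", 1, "A", "G"), "G1")]
        census = genotype_census(d, meta, tiered_keys=[])
        assert census.homozygotes == []

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError, match="dosages outside"):
            genotype_census(np.array([[3]]), [(("chr1", 1, "A", "G"), "G1")], [])

    def test_random_matrix_matches_brute_force_rescan(self):
        rng = np.random.default_rng(42)
        n_var, n_ind = 20, 50
        genes = [f"G{i % 4}" for i in range(n_var)]
        meta = [(("chr1", i, "A", "G"), genes[i]) for i in range(n_var)]
        d = rng.choice([0, 0, 0, 1, 2, -1], size=(n_var, n_ind), p=[0.5, 0.2, 0.1, 0.12, 0.05, 0.03])
        tiered = {meta[i][0] for i in range(0, n_var, 2)}
        census = genotype_census(d, meta, tiered)

        # independent O(n·m) rescan
        homs, chet_pairs, carriers = [], [], {}
        for ind in range(n_ind):
            per_gene = {}
            for row, (key, gene) in enumerate(meta):
                if key not in tiered:
                    continue
                dose = d[row, ind]
                if dose >= 1:
                    per_gene.setdefault(gene, []).append(key)
                    carriers.setdefault(gene, set()).add(ind)
                if dose == 2:
                    homs.append((ind, gene, key))
            for gene, keys in per_gene.items():
                if len(keys) >= 2:
                    chet_pairs.extend(
                        (ind, gene, a, b) for a, b in itertools.combinations(sorted(keys), 2)
                    )
        assert sorted(census.homozygotes) == sorted(homs)
        assert sorted(census.compound_hets) == sorted(chet_pairs)
        assert census.het_carriers == {g: len(s) for g, s in carriers.items()}


class TestHWERecoveryOnCohort:
    def test_genotype_fractions_match_expectation(self):
        """On a synthetic HWE cohort (n=2000), observed heterozygote and
        homozygote fractions sit within 3 binomial SE of 2(1-Q)Q and Q²."""
        from dsdscreen.simulate import generate_cohort

        panel = [e for e in _mini_panel() if e.inheritance is Inheritance.AUTOSOMAL_RECESSIVE]
        panel = [
            GenePanelEntry(e.gene_symbol, e.category, e.inheritance, "chr1", i * 1000 + 1, i * 1000 + 500)
            for i, e in enumerate(panel)
        ]
        n = 2000
        q = 0.1
        cohort = generate_cohort(
            panel=panel,
            n_individuals=n,
            variants_per_gene=1,
            aaf_sampler=lambda rng, size: np.full(size, q),
            seed=123,
            n_isoform_traps=0,
            multiallelic_fraction=0.0,
            nonpass_fraction=0.0,
        )
        for row in range(cohort.dosages.shape[0]):
            d = cohort.dosages[row]
            het, hom = (d == 1).mean(), (d == 2).mean()
            p_het, p_hom = 2 * q * (1 - q), q * q
            assert abs(het - p_het) <= 3 * np.sqrt(p_het * (1 - p_het) / n)
            assert abs(hom - p_hom) <= 3 * np.sqrt(p_hom * (1 - p_hom) / n)
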