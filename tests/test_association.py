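"""Locus partitioning, SMA t-tests, heterosis, scan summaries."""

import numpy as np
import pandas as pd
import pytest

import hybridca as hc
from hybridca import association as asc
from hybridca.io import HOM_ALT, HOM_REF, MISSING
from hybridca.snp_summary import (
    EFFECT_MISSENSE,
    EFFECT_NA,
    REGION_EXON,
    REGION_INTERGENIC,
    REGION_SPLICE,
    SnpAnnotation,
    TRANSITION,
)

from conftest import make_matrix, make_pheno


def permutation_p(het, hom, n_perm=100_000, seed=0):
    """Monte-Carlo permutation oracle for the two-sided difference in
    group means (vectorised label shuffles)."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([het, hom])
    n1 = len(het)
    obs = abs(np.mean(het) - np.mean(hom))
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[idx]
    diffs = np.abs(perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1))
    return float((diffs >= obs - 1e-12).mean())


def het_partition(matrix, design, site_id):
    return asc.partition_crosses(matrix, design, site_id)


class TestPartitionCrosses:
    def _matrix_9x9(self, female_codes, male_codes):
        codes = list(female_codes) + list(male_codes)
        return make_matrix(
            [[c] for c in codes],
            parents=[f"F{i}" for i in range(9)] + [f"M{i}" for i in range(9)],
            roles=["female"] * 9 + ["male"] * 9,
            sites=[hc.SnpSite("chr1", 100, "A", "G")],
        )

    def test_fully_heterozygous_design_is_non_testable(self):
        mat = self._matrix_9x9([HOM_REF] * 9, [HOM_ALT] * 9)
        design = [(f, m) for f in mat.females for m in mat.males]
        part = asc.partition_crosses(mat, design, "chr1:100")
        assert part.n_het == 81 and part.n_hom == 0
        assert not part.testable()

    def test_missing_female_excludes_her_nine_crosses(self):
        mat = self._matrix_9x9([MISSING] + [HOM_REF] * 8, [HOM_REF] * 5 + [HOM_ALT] * 4)
        design = [(f, m) for f in mat.females for m in mat.males]
        part = asc.partition_crosses(mat, design, "chr1:100")
        assert len(part.excluded_crosses) == 9
        assert part.n_het + part.n_hom == 72

    def test_41_40_partition_on_9x9(self):
        """The canonical worked split of a 9x9 factorial: with 4 of 9
        females and 5 of 9 males carrying the alternate allele, the F1s
        divide into 41 heterozygous and 40 homozygous crosses
        (4*4 + 5*5 = 41 het)."""
        females = [HOM_ALT] * 4 + [HOM_REF] * 5
        males = [HOM_ALT] * 5 + [HOM_REF] * 4
        mat = self._matrix_9x9(females, males)
        design = [(f, m) for f in mat.females for m in mat.males]
        part = asc.partition_crosses(mat, design, "chr1:100")
        assert (part.n_het, part.n_hom) == (41, 40)
        assert part.excluded_crosses == []

    def test_unknown_parent_is_hard_error(self):
        mat = self._matrix_9x9([HOM_REF] * 9, [HOM_ALT] * 9)
        with pytest.raises(ValueError, match="unknown parent"):
            asc.SingleMarkerScan(
                mat,
                make_pheno({(f, m): 1.0 for f in mat.females for m in mat.males}),
                design=[("nope", "M0")],
            )

    def test_partition_conservation_property(self):
        rng = np.random.default_rng(4)
        cfg = hc.SimulationConfig(seed=4, n_sites=50, missing_rate=0.2)
        mat = hc.simulate_parent_genotypes(cfg)
        design = [(f, m) for f in mat.females for m in mat.males]
        for site_id in rng.choice(mat.site_ids, size=20, replace=False):
            part = asc.partition_crosses(mat, design, str(site_id))
            groups = (
                set(part.het_crosses) | set(part.hom_crosses) | set(part.excluded_crosses)
            )
            assert len(groups) == 81 == part.n_het + part.n_hom + len(part.excluded_crosses)


class TestSmaTest:
    def _partition_from_values(self, n_het, n_hom):
        het = [(f"F{i}", "M0") for i in range(n_het)]
        hom = [(f"G{i}", "M1") for i in range(n_hom)]
        return asc.LocusPartition("s", het, hom, [])

    def test_textbook_arithmetic(self):
        """het {12,14,16} vs hom {8,10,12}: Welch t = 4/sqrt(8/3) = 2.4495,
        df = 4, p ~ 0.0705, point-biserial R^2 = t^2/(t^2+4) = 0.6."""
        part = self._partition_from_values(3, 3)
        means = dict(zip(part.het_crosses, [12, 14, 16])) | dict(
            zip(part.hom_crosses, [8, 10, 12])
        )
        rec = asc.sma_test(part, means, min_group=3)
        assert rec.delta == pytest.approx(4.0)
        assert rec.t_stat == pytest.approx(2.449489, abs=1e-5)
        assert rec.df == pytest.approx(4.0)
        assert rec.p_value == pytest.approx(0.0705, abs=2e-4)
        assert not rec.significant  # not significant at 0.01
        assert rec.r_squared == pytest.approx(0.6)
        assert rec.heterosis_pct == pytest.approx(40.0)

    def test_identical_groups_degenerate(self):
        part = self._partition_from_values(5, 5)
        means = {c: 3.0 for c in part.het_crosses + part.hom_crosses}
        rec = asc.sma_test(part, means)
        assert rec.t_stat == 0.0 and rec.p_value == 1.0
        assert rec.sign_class == asc.NONE

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        part = self._partition_from_values(8, 6)
        vals_h = rng.normal(10, 2, 8)
        vals_o = rng.normal(9, 2, 6)
        means = dict(zip(part.het_crosses, vals_h)) | dict(zip(part.hom_crosses, vals_o))
        rec = asc.sma_test(part, means)
        flipped = asc.LocusPartition("s", part.hom_crosses, part.het_crosses, [])
        rec2 = asc.sma_test(flipped, means)
        assert rec2.delta == pytest.approx(-rec.delta)
        assert rec2.t_stat == pytest.approx(-rec.t_stat)
        assert rec2.p_value == pytest.approx(rec.p_value)
        assert rec2.r_squared == pytest.approx(rec.r_squared)

    def test_small_group_not_testable(self):
        part = self._partition_from_values(3, 40)
        means = {c: 1.0 for c in part.het_crosses + part.hom_crosses}
        rec = asc.sma_test(part, means, min_group=5)
        assert not rec.testable and np.isnan(rec.p_value)

    def test_pooled_matches_permutation_oracle(self):
        """Pooled-variance t p-value tracks a 1e5-shuffle permutation
        oracle on a moderate fixture."""
        rng = np.random.default_rng(8)
        het = rng.normal(10.5, 1.0, 14)
        hom = rng.normal(10.0, 1.0, 12)
        part = self._partition_from_values(14, 12)
        means = dict(zip(part.het_crosses, het)) | dict(zip(part.hom_crosses, hom))
        rec = asc.sma_test(part, means, variant="pooled")
        p_perm = permutation_p(het, hom, seed=1)
        assert rec.p_value == pytest.approx(p_perm, abs=0.02)


class TestHeterosis:
    @pytest.mark.parametrize(
        "mh, mo, expected", [(110, 100, 10.0), (7, 7, 0.0), (14, 10, 40.0)]
    )
    def test_formula(self, mh, mo, expected):
        assert asc.heterosis_percent(mh, mo) == pytest.approx(expected)

    def test_zero_homozygous_mean_error(self):
        with pytest.raises(ValueError, match="undefined heterosis"):
            asc.heterosis_percent(1.0, 0.0)


class TestGenomeScan:
    def test_monomorphic_only_matrix_gives_empty_results(self):
        mat = make_matrix(
            [[HOM_REF], [HOM_REF], [HOM_REF], [HOM_ALT]],
            sites=[hc.SnpSite("chr1", 10, "A", "G")],
        )
        pheno = make_pheno({(f, m): 1.0 for f in mat.females for m in mat.males})
        res = hc.SingleMarkerScan(mat, pheno).fit()
        assert res.records == []

    def test_planted_locus_detected_with_correct_sign(self):
        cfg = hc.SimulationConfig(
            seed=14,
            n_sites=30,
            missing_rate=0.0,
            traits={"yield": hc.TraitParams(30, 0.4, 0.4, 0.2, 0.3, 0.5)},
        )
        mat = hc.simulate_parent_genotypes(cfg)
        # pick a well-balanced site for the planted effect
        design_site = None
        design = [(f, m) for f in mat.females for m in mat.males]
        for s in mat.site_ids:
            part = asc.partition_crosses(mat, design, s)
            if 30 <= part.n_het <= 50:
                design_site = s
                break
        cfg.planted_loci = [hc.PlantedLocus(design_site, "yield", beta=4.0)]
        pheno, truth = hc.simulate_phenotypes(mat, cfg)
        res = hc.SingleMarkerScan(mat, pheno).fit(alpha=0.01)
        rec = {r.site_id: r for r in res.records}[design_site]
        assert rec.significant and rec.sign_class == asc.FAVORABLE
        assert rec.delta > 0

    def test_type_i_error_calibrated_under_exchangeable_null(self):
        """With i.i.d. cross means (no parental structure) and genotypes
        independent of phenotype, the Welch test rejects ~1% at alpha=0.01."""
        rng = np.random.default_rng(77)
        rej = tests = 0
        for _ in range(40):
            cfg = hc.SimulationConfig(seed=int(rng.integers(2**31)), n_sites=60, missing_rate=0.0)
            mat = hc.simulate_parent_genotypes(cfg)
            design = [(f, m) for f in mat.females for m in mat.males]
            y = dict(zip(design, rng.normal(0, 1, 81)))
            for s in mat.site_ids:
                part = asc.partition_crosses(mat, design, s)
                if not part.testable():
                    continue
                rec = asc.sma_test(part, y, alpha=0.01)
                tests += 1
                rej += rec.significant
        rate = rej / tests
        assert tests > 1500
        assert 0.003 < rate < 0.02

    def test_bh_correction_is_more_conservative(self):
        cfg = hc.SimulationConfig(
            seed=3,
            n_sites=200,
            missing_rate=0.0,
            traits={"yield": hc.TraitParams(30, 1.0, 1.0, 0.3, 0.5, 1.0)},
        )
        mat, pheno, _ = hc.simulate_trial(cfg)
        raw = hc.SingleMarkerScan(mat, pheno).fit(alpha=0.01, correction="none")
        bh = hc.SingleMarkerScan(mat, pheno).fit(alpha=0.01, correction="bh")
        assert len(bh.significant_records()) <= len(raw.significant_records())
        assert all(np.isfinite(r.p_adjusted) for r in bh.records)


class TestSummaries:
    def _scan(self, seed=6, n_sites=120):
        cfg = hc.SimulationConfig(
            seed=seed,
            n_sites=n_sites,
            missing_rate=0.0,
            traits={"yield": hc.TraitParams(30, 1.0, 1.0, 0.3, 0.5, 1.0)},
        )
        mat, pheno, _ = hc.simulate_trial(cfg)
        return mat, hc.SingleMarkerScan(mat, pheno).fit(alpha=0.05)

    def test_count_identity_without_missing_data(self):
        mat, res = self._scan()
        summ = res.per_trait_summary()
        row = summ.iloc[0]
        assert row["n_het_crosses"] + row["n_hom_crosses"] == row["n_loci"] * 81

    def test_single_locus_summary_heterosis_both_ways(self):
        part = asc.LocusPartition(
            "s1", [("F", f"M{i}") for i in range(5)], [("G", f"M{i}") for i in range(5)], []
        )
        means = dict(zip(part.het_crosses, [110] * 5)) | dict(zip(part.hom_crosses, [100] * 5))
        rec = asc.sma_test(part, means, alpha=0.5)
        summ = asc.per_trait_summary([rec])
        assert summ.iloc[0]["heterosis_pct_per_locus"] == pytest.approx(10.0)
        assert summ.iloc[0]["heterosis_pct_pooled"] == pytest.approx(10.0)

    def test_empty_results_give_zero_table(self):
        assert asc.per_trait_summary([]).empty

    def test_per_parent_counts_attribute_alt_carriers(self):
        mat = make_matrix(
            [
                [HOM_REF, HOM_REF],
                [HOM_REF, HOM_REF],
                [HOM_ALT, HOM_REF],
                [HOM_REF, HOM_REF],
            ],
            sites=[hc.SnpSite("chr1", 10, "A", "G"), hc.SnpSite("chr1", 20, "C", "T")],
        )
        rec = asc.AssociationRecord(
            "chr1:10", "yield", 5, 5, significant=True, sign_class=asc.FAVORABLE, delta=1.0
        )
        counts = asc.per_parent_counts([rec], mat)
        by_parent = counts.set_index("parent")
        assert by_parent.loc["M1", "positive"] == 1
        assert by_parent.drop("M1")["total"].sum() == 0

    def test_per_parent_counts_bounded_by_n_significant(self):
        mat, res = self._scan(seed=9)
        counts = res.per_parent_counts()
        n_sig = len(res.significant_records())
        assert (counts["total"] <= n_sig).all()

    def test_truth_ledger_attribution_of_planted_favorable_loci(self):
        """Two favorable loci carried (as alt) by a single male parent
        show up as that parent's positive counts."""
        cfg = hc.SimulationConfig(
            seed=33,
            n_sites=40,
            missing_rate=0.0,
            traits={"yield": hc.TraitParams(30, 0.2, 0.2, 0.1, 0.2, 0.4)},
        )
        mat = hc.simulate_parent_genotypes(cfg)
        carrier = mat.males[0]
        ci = mat.parent_index(carrier)
        # force two sites to be carried only by one male parent
        chosen = []
        for j, s in enumerate(mat.sites):
            if len(chosen) == 2:
                break
            mat.calls[:, j] = HOM_REF
            mat.calls[ci, j] = HOM_ALT
            chosen.append(s.site_id)
        mat.meta["true_calls"] = mat.calls.copy()
        cfg.planted_loci = [hc.PlantedLocus(s, "yield", beta=4.0) for s in chosen]
        pheno, truth = hc.simulate_phenotypes(mat, cfg)
        res = hc.SingleMarkerScan(mat, pheno).fit(alpha=0.01)
        planted_recs = [r for r in res.records if r.site_id in chosen]
        assert all(r.significant and r.sign_class == asc.FAVORABLE for r in planted_recs)
        counts = asc.per_parent_counts(planted_recs, mat).set_index("parent")
        assert counts.loc[carrier, "positive"] == 2
        assert counts.drop(carrier)["total"].sum() == 0

    def test_filter_functional_keeps_coding_and_splice(self):
        recs = [
            asc.AssociationRecord(f"s{i}", "yield", 5, 5, significant=True)
            for i in range(3)
        ]
        anns = {
            "s0": SnpAnnotation("s0", TRANSITION, REGION_INTERGENIC, EFFECT_NA),
            "s1": SnpAnnotation("s1", TRANSITION, REGION_EXON, EFFECT_MISSENSE),
            "s2": SnpAnnotation("s2", TRANSITION, REGION_SPLICE, EFFECT_NA),
        }
        kept = asc.filter_functional(recs, anns)
        assert [r.site_id for r in kept] == ["s1", "s2"]

    def test_filter_functional_unannotated_is_error(self):
        rec = asc.AssociationRecord("sX", "yield", 5, 5)
        with pytest.raises(ValueError, match="unannotated"):
            asc.filter_functional([rec], {})
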