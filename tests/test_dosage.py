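"""SV-gene linking, genotype orientation, expression filters and dosage calls."""

import numpy as np
import pandas as pd
import pytest

from svdosage.config import AnalysisConfig
from svdosage.dosage import (
    asymmetry_binomial,
    call_direction_panel,
    call_direction_population,
    dosage_pipeline,
    expressed_filter,
    fold_change_profile,
    link_sv_to_gene,
    mann_whitney_p,
    orient_genotypes,
    unique_links,
    zscore_profile,
)
from svdosage.models import (
    ABSENCE,
    MISSING,
    PRESENCE,
    DosageCall,
    EligibilityError,
    GeneModel,
    SVGeneLink,
    SVRecord,
)

from _oracles import nearest_gene_allpairs


def sv_at(lo, hi, i=0):
    t = "presence-PAV" if hi == lo else "absence-PAV"
    return SVRecord(id=f"s{i}", chrom="chr1", start=lo, end=hi, sv_type=t,
                    alt_length=max(hi - lo, 100))


GENE = GeneModel("g1", "chr1", 50_000, 53_000, "+",
                 exons=((50_000, 51_000), (52_000, 53_000)),
                 cds=((50_000, 51_000), (52_000, 53_000)))


class TestLinking:
    def test_beyond_radius_unlinked(self):
        sv = sv_at(53_000 + 10_001, 53_000 + 10_051)
        assert link_sv_to_gene(sv, [GENE]) is None

    def test_at_radius_linked(self):
        sv = sv_at(53_000 + 10_000, 53_000 + 10_050)
        link = link_sv_to_gene(sv, [GENE])
        assert link is not None and link.bin == "5-10kb"

    def test_cds_overlap(self):
        link = link_sv_to_gene(sv_at(50_100, 50_200), [GENE])
        assert link.distance == 0 and link.bin == "CDS"

    def test_intron_overlap(self):
        link = link_sv_to_gene(sv_at(51_200, 51_300), [GENE])
        assert link.bin == "intron"

    def test_signed_distance_strand_aware(self):
        up = link_sv_to_gene(sv_at(49_000, 49_100), [GENE])
        dn = link_sv_to_gene(sv_at(54_000, 54_100), [GENE])
        assert up.distance < 0 < dn.distance
        minus = GeneModel("g2", "chr1", 50_000, 53_000, "-", exons=((50_000, 53_000),),
                          cds=((50_000, 53_000),))
        up_minus = link_sv_to_gene(sv_at(54_000, 54_100), [minus])
        assert up_minus.distance < 0

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(13)
        genes = []
        for i in range(12):
            s = 10_000 + 18_000 * i
            genes.append(GeneModel(f"g{i:02d}", "chr1", s, s + 3_000, "+",
                                   exons=((s, s + 3_000),), cds=((s, s + 3_000),)))
        tuples = [(g.id, g.chrom, g.start, g.end) for g in genes]
        for k in range(300):
            lo = int(rng.integers(0, 230_000))
            hi = lo + int(rng.integers(0, 300))
            sv = sv_at(lo, hi, i=k)
            link = link_sv_to_gene(sv, genes)
            want = nearest_gene_allpairs((lo, hi), "chr1", tuples, 10_000)
            if want is None:
                assert link is None
            else:
                assert (abs(link.distance) if link.distance else 0, link.gene_id) == want

    def test_unique_links_drops_shared_genes(self):
        links = [SVGeneLink("a", "g1", 100, "0-1.5kb"),
                 SVGeneLink("b", "g1", -200, "0-1.5kb"),
                 SVGeneLink("c", "g2", 0, "CDS")]
        assert [l.sv_id for l in unique_links(links)] == ["c"]


class TestOrientation:
    def test_insertion_carriers_presence(self):
        calls = pd.Series([1, 0, -1], index=list("abc"))
        out = orient_genotypes(1, 501, calls)
        assert list(out) == [PRESENCE, ABSENCE, MISSING]

    def test_deletion_carriers_absence(self):
        calls = pd.Series([1, 0, -1], index=list("abc"))
        out = orient_genotypes(501, 1, calls)
        assert list(out) == [ABSENCE, PRESENCE, MISSING]

    def test_reference_flip_leaves_labels_unchanged(self):
        # same biological variant called against either haplotype
        carriers = pd.Series([1, 1, 0, 0], index=list("abcd"))
        as_insertion = orient_genotypes(1, 501, carriers)
        flipped = orient_genotypes(501, 1, 1 - carriers)  # other genome as reference
        assert list(as_insertion) == list(flipped)

    def test_equal_lengths_rejected(self):
        with pytest.raises(ValueError):
            orient_genotypes(100, 100, pd.Series([1, 0]))


class TestExpressedFilter:
    def test_panel_boundary_not_strictly_above(self):
        assert not expressed_filter([2, 2, 2, 0, 0], "panel")

    def test_panel_above_boundary(self):
        assert expressed_filter([2, 2, 2, 2, 0], "panel")

    def test_population_threshold(self):
        vals = [5] * 31 + [0] * 69
        assert expressed_filter(vals, "population")
        assert not expressed_filter([5] * 30 + [0] * 70, "population")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            expressed_filter([], "panel")


def _panel_inputs(mean_p, mean_a, n=6):
    link = SVGeneLink("sv", "g", 500, "0-1.5kb")
    gts = pd.Series([PRESENCE] * n + [ABSENCE] * n,
                    index=[f"G{i}" for i in range(2 * n)])
    expr = pd.Series([mean_p] * n + [mean_a] * n, index=gts.index)
    return link, gts, expr


class TestPanelCalls:
    def test_ratio_exactly_threshold_is_promoting(self):
        call = call_direction_panel(*_panel_inputs(3.0, 2.0))
        assert call.direction == "promoting"
        assert call.fold_ratio == pytest.approx(1.5)

    def test_mirror_is_suppressing(self):
        assert call_direction_panel(*_panel_inputs(2.0, 3.0)).direction == "suppressing"

    def test_below_threshold_is_none(self):
        assert call_direction_panel(*_panel_inputs(2.0, 1.5)).direction == "none"

    def test_zero_absence_mean_promoting(self):
        call = call_direction_panel(*_panel_inputs(4.0, 0.0))
        assert call.direction == "promoting" and np.isinf(call.fold_ratio)

    def test_both_zero_none_but_needs_expression(self):
        with pytest.raises(EligibilityError):
            call_direction_panel(*_panel_inputs(0.0, 0.0))

    def test_minority_group_eligibility(self):
        link = SVGeneLink("sv", "g", 500, "0-1.5kb")
        gts = pd.Series([PRESENCE] * 3 + [ABSENCE] * 9, index=[f"G{i}" for i in range(12)])
        expr = pd.Series(5.0, index=gts.index)
        with pytest.raises(EligibilityError):
            call_direction_panel(link, gts, expr)

    def test_direction_antisymmetric_under_label_swap(self):
        link, gts, expr = _panel_inputs(6.0, 2.0)
        fwd = call_direction_panel(link, gts, expr)
        swapped = gts.map({PRESENCE: ABSENCE, ABSENCE: PRESENCE})
        rev = call_direction_panel(link, swapped, expr)
        assert (fwd.direction, rev.direction) == ("promoting", "suppressing")


class TestPopulationCalls:
    def make(self, n_p=50, n_a=50, fold=3.0, seed=0, missing=0):
        rng = np.random.default_rng(seed)
        link = SVGeneLink("sv", "g", 500, "0-1.5kb")
        idx = [f"a{i}" for i in range(n_p + n_a + missing)]
        gts = pd.Series([PRESENCE] * n_p + [ABSENCE] * n_a + [MISSING] * missing, index=idx)
        base = 20.0
        vals = np.concatenate([
            base * fold * np.exp(rng.normal(0, 0.3, n_p)),
            base * np.exp(rng.normal(0, 0.3, n_a)),
            base * np.exp(rng.normal(0, 0.3, missing)),
        ])
        return link, gts, pd.Series(vals, index=idx)

    def test_too_few_genotyped_skipped(self):
        link, gts, expr = self.make(n_p=30, n_a=29)
        with pytest.raises(EligibilityError, match="genotyped"):
            call_direction_population(link, gts, expr)

    def test_small_group_skipped(self):
        link, gts, expr = self.make(n_p=9, n_a=60)
        with pytest.raises(EligibilityError, match="group"):
            call_direction_population(link, gts, expr)

    def test_planted_promoter_recovered(self):
        call = call_direction_population(*self.make(fold=3.0, seed=1))
        assert call.direction == "promoting" and call.p_value < 0.05

    def test_null_gives_none(self):
        call = call_direction_population(*self.make(fold=1.0, seed=2))
        assert call.direction == "none"

    def test_missing_excluded_from_groups(self):
        call = call_direction_population(*self.make(n_p=40, n_a=40, missing=20))
        assert call.n_presence == 40 and call.n_absence == 40


class TestAsymmetryBinomial:
    def test_reported_suppression_excess(self):
        # 3,536 suppressed vs 2,990 promoted SV genes
        assert asymmetry_binomial(3536, 2990) == pytest.approx(1.48e-11, rel=0.05)

    def test_symmetric_counts(self):
        assert asymmetry_binomial(5, 5) == 1.0

    def test_onesided_extreme(self):
        assert asymmetry_binomial(10, 0) == pytest.approx(2 * 0.5**10)

    def test_argument_symmetry(self):
        assert asymmetry_binomial(30, 12) == pytest.approx(asymmetry_binomial(12, 30))


class TestProfiles:
    def test_zscore_values(self):
        z = zscore_profile(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"]))
        assert np.allclose(z.loc["g"], [-1, 0, 1])

    def test_zscore_constant_row(self):
        z = zscore_profile(pd.DataFrame([[4.0, 4.0, 4.0]], index=["g"]))
        assert (z.loc["g"] == 0).all()

    def test_zscore_random_matrix_normalized(self):
        rng = np.random.default_rng(0)
        z = zscore_profile(pd.DataFrame(rng.normal(5, 2, (20, 30))))
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_fold_profile_conserves_calls(self):
        calls = [
            DosageCall("s1", "g1", 5, 5, 4.0, 2.0, 2.0, "promoting", "panel", bin="CDS"),
            DosageCall("s2", "g2", 5, 5, 1.0, 2.0, 0.5, "suppressing", "panel", bin="CDS"),
            DosageCall("s3", "g3", 5, 5, 2.0, 2.0, 1.0, "none", "panel", bin="5-10kb"),
        ]
        prof = fold_change_profile(calls)
        assert prof["n_calls"].sum() == 3

    def test_unit_folds_give_zero_log(self):
        calls = [DosageCall("s", "g", 5, 5, 2.0, 2.0, 1.0, "none", "panel", bin="CDS")]
        prof = fold_change_profile(calls).set_index("bin")
        assert prof.loc["CDS", "q0.5"] == 0.0


class TestPipelineRecovery:
    def test_panel_and_population_agree_on_planted_truth(self, small_bundle):
        b = small_bundle
        panel_calls, _ = dosage_pipeline(
            b.catalog, b.genes, b.panel_genotypes, b.expression_panel, "panel"
        )
        pop_calls, _ = dosage_pipeline(
            b.catalog, b.genes, b.population_genotypes, b.expression_population,
            "population",
        )
        panel = {c.sv_id: c.direction for c in panel_calls}
        pop = {c.sv_id: c.direction for c in pop_calls}
        truth = b.truth["direction"]
        strong = b.truth[(b.truth["fold"] >= 2) | (b.truth["direction"] == "none")]
        both = [s for s in strong.index if s in panel and s in pop]
        agree = [s for s in both if panel[s] == pop[s] == truth[s]]
        assert len(agree) / len(both) >= 0.9

    def test_skip_log_reasons_recorded(self, small_bundle):
        b = small_bundle
        strict = AnalysisConfig(min_genomes_per_group=14)
        calls, skipped = dosage_pipeline(
            b.catalog, b.genes, b.panel_genotypes, b.expression_panel, "panel", strict
        )
        assert len(calls) + len(skipped) > 0
        if len(skipped):
            assert skipped["reason"].str.len().gt(0).all()
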