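"""Window merging, tissue-specific enhancer calling and gene assignment."""

import numpy as np
import pandas as pd
import pytest

from dvchrom.genome import GeneModel, GenomicInterval
from dvchrom.insulation import Boundary
from dvchrom.linking import (
    SignedRegion,
    assign_enhancers,
    domain_size_comparison,
    filter_expressed_genes,
    merge_windows,
    tissue_specific_regions,
    validate_assignment_expression,
)


def _window_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "contrast", "logFC", "FDR"])


class TestMergeWindows:
    def test_gap_within_tolerance_merged(self):
        table = _window_table(
            [
                ("c", 1000, 1150, "A_vs_B", 2.0, 1e-4),
                ("c", 1200, 1350, "A_vs_B", 2.5, 1e-4),
            ]
        )
        (region,) = merge_windows(table, "A_vs_B", tol_bp=100)
        assert (region.start, region.end, region.sign) == (1000, 1350, 1)

    def test_long_run_split_below_max_width(self):
        rows = [
            ("c", s, s + 150, "A_vs_B", 1.5, 1e-4)
            for s in range(0, 6200, 155)
        ]
        regions = merge_windows(_window_table(rows), "A_vs_B", max_width_bp=5000)
        assert len(regions) >= 2
        for r in regions:
            assert r.end - r.start <= 5000

    def test_mixed_direction_discarded(self):
        table = _window_table(
            [
                ("c", 0, 150, "A_vs_B", 2.0, 1e-4),
                ("c", 200, 350, "A_vs_B", -2.0, 1e-4),
            ]
        )
        assert merge_windows(table, "A_vs_B") == []

    def test_region_fdr_is_simes_combination(self):
        table = _window_table(
            [
                ("c", 0, 150, "A_vs_B", 2.0, 0.01),
                ("c", 200, 350, "A_vs_B", 2.0, 0.04),
            ]
        )
        (region,) = merge_windows(table, "A_vs_B", window_fdr_max=0.05)
        assert region.fdr == pytest.approx(min(2 * 0.01 / 1, 2 * 0.04 / 2))

    def test_gap_above_tolerance_separate_regions(self):
        table = _window_table(
            [
                ("c", 0, 150, "A_vs_B", 2.0, 1e-4),
                ("c", 400, 550, "A_vs_B", 2.0, 1e-4),
            ]
        )
        regions = merge_windows(table, "A_vs_B", tol_bp=100)
        assert len(regions) == 2

    def test_empty_table(self):
        assert merge_windows(_window_table([]), "A_vs_B") == []


class TestTissueSpecific:
    def _region(self, start, end, sign=1):
        return SignedRegion("c", start, end, sign, 1e-3)

    def test_intersection_of_both_contrasts(self):
        regions = {
            "A_vs_B": [self._region(100, 400)],
            "A_vs_C": [self._region(200, 500)],
            "B_vs_A": [], "B_vs_C": [], "C_vs_A": [], "C_vs_B": [],
        }
        out = tissue_specific_regions(regions, ["A", "B", "C"])
        assert [(iv.start, iv.end) for iv in out["A"]] == [(200, 400)]
        assert out["B"] == [] and out["C"] == []

    def test_single_contrast_not_enough(self):
        regions = {
            "A_vs_B": [self._region(100, 400)],
            "A_vs_C": [], "B_vs_A": [], "B_vs_C": [], "C_vs_A": [], "C_vs_B": [],
        }
        out = tissue_specific_regions(regions, ["A", "B", "C"])
        assert out["A"] == []

    def test_promoter_overlap_excluded(self):
        regions = {
            "A_vs_B": [self._region(100, 400)],
            "A_vs_C": [self._region(100, 400)],
            "B_vs_A": [], "B_vs_C": [], "C_vs_A": [], "C_vs_B": [],
        }
        prom = [GenomicInterval("c", 300, 350)]
        out = tissue_specific_regions(regions, ["A", "B", "C"], prom)
        assert out["A"] == []

    def test_missing_contrast_errors(self):
        with pytest.raises(KeyError):
            tissue_specific_regions({"A_vs_B": []}, ["A", "B", "C"])

    def test_sets_mutually_exclusive(self):
        # a region up in A vs B cannot also be up in B vs A
        regions = {
            "A_vs_B": [self._region(100, 400)],
            "A_vs_C": [self._region(100, 400)],
            "B_vs_A": [self._region(100, 400, sign=-1)],
            "B_vs_C": [self._region(100, 400, sign=-1)],
            "C_vs_A": [], "C_vs_B": [],
        }
        out = tissue_specific_regions(regions, ["A", "B", "C"])
        for iv_a in out["A"]:
            assert not any(iv_a.overlaps(iv_b) for iv_b in out["B"])


def _toy_model():
    genes = pd.DataFrame(
        {
            "gene_id": ["hk", "low", "g1", "g2", "g3"],
            "symbol": ["hk", "low", "g1", "g2", "g3"],
            "chrom": ["c"] * 5,
            "housekeeping": [True, False, False, False, False],
        }
    )
    tx = pd.DataFrame(
        {
            "transcript_id": ["t_hk", "t_low", "t1", "t2", "t3"],
            "gene_id": ["hk", "low", "g1", "g2", "g3"],
            "chrom": ["c"] * 5,
            "start": [500_000, 600_000, 10_000, 100_000, 200_000],
            "end": [505_000, 605_000, 30_000, 120_000, 220_000],
            "strand": ["+", "+", "+", "+", "-"],
        }
    )
    return GeneModel(genes, tx)


class TestFilterExpressedGenes:
    def _tpm(self):
        return pd.DataFrame(
            {
                "A": [50.0, 0.5, 10.0, 0.0, 5.0],
                "B": [50.0, 0.9, 10.0, 0.0, 5.0],
                "C": [50.0, 1.0, 10.0, 4.0, 5.0],
            },
            index=["hk", "low", "g1", "g2", "g3"],
        )

    def test_rules(self):
        out = filter_expressed_genes(_toy_model(), self._tpm())
        assert "hk" not in out  # housekeeping dropped despite high TPM
        assert "low" not in out  # mean (0.5+0.9+1.0)/3 = 0.8 < 1
        assert "g2" in out  # mean (0+0+4)/3 = 1.33 >= 1
        assert "g1" in out and "g3" in out

    def test_missing_gene_counts_as_zero_with_warning(self):
        tpm = self._tpm().drop(index="g3")
        with pytest.warns(UserWarning):
            out = filter_expressed_genes(_toy_model(), tpm)
        assert "g3" not in out


class TestAssignEnhancers:
    model = _toy_model()
    candidates = ["g1", "g2", "g3"]

    def test_rule1_single_transcript_overlap(self):
        enh = GenomicInterval("c", 15_000, 16_000)  # inside t1 only
        (a,) = assign_enhancers([enh], self.candidates, self.model)
        assert (a.gene_id, a.rule) == ("g1", "overlap_single_transcript")

    def test_rule2_boundary_redirects_to_farther_promoter(self):
        # enhancer at 80k: g2 TSS (100k) is 20 kb away but blocked;
        # g1 TSS (10k) is 69 kb away, unblocked
        enh = GenomicInterval("c", 79_000, 80_000)
        boundary = [Boundary("c", 90_000, 91_000, 1.0)]
        (a,) = assign_enhancers([enh], self.candidates, self.model, boundary)
        assert (a.gene_id, a.rule) == ("g1", "closest_no_boundary")

    def test_rule2_without_blockers_takes_nearest(self):
        enh = GenomicInterval("c", 79_000, 80_000)
        (a,) = assign_enhancers([enh], self.candidates, self.model)
        assert (a.gene_id, a.rule) == ("g2", "closest_no_boundary")
        assert a.distance == 20_000

    def test_rule3_domain_restriction(self):
        # all promoters blocked -> fall through to the domain rule
        enh = GenomicInterval("c", 150_000, 151_000)
        boundaries = [
            Boundary("c", 140_000, 141_000, 1.0),
            Boundary("c", 180_000, 181_000, 1.0),
        ]
        domains = [GenomicInterval("c", 140_000, 260_000)]
        (a,) = assign_enhancers(
            [enh], self.candidates, self.model, boundaries, domains
        )
        # g3 TSS at 219_999 (minus strand) is inside the domain
        assert (a.gene_id, a.rule) == ("g3", "closest_in_domain")

    def test_rule4_unconstrained_fallback(self):
        enh = GenomicInterval("c", 150_000, 151_000)
        boundaries = [
            Boundary("c", 140_000, 141_000, 1.0),
            Boundary("c", 180_000, 181_000, 1.0),
        ]
        (a,) = assign_enhancers([enh], self.candidates, self.model, boundaries)
        assert a.rule == "closest_any"

    def test_two_gene_overlap_falls_through_rule1(self):
        model = _toy_model()
        tx2 = model.transcripts.copy()
        tx2.loc[len(tx2)] = ["t2b", "g2", "c", 25_000, 40_000, "+"]
        model = GeneModel(model.genes, tx2)
        enh = GenomicInterval("c", 26_000, 27_000)  # overlaps t1 and t2b
        (a,) = assign_enhancers([enh], self.candidates, model)
        assert a.rule != "overlap_single_transcript"

    def test_no_promoter_on_chromosome_warns(self):
        enh = GenomicInterval("chrX", 100, 200)
        with pytest.warns(UserWarning):
            out = assign_enhancers([enh], self.candidates, self.model)
        assert out == []

    def test_at_most_one_assignment_per_enhancer(self):
        enhs = [
            GenomicInterval("c", s, s + 500)
            for s in (15_000, 50_000, 79_000, 150_000)
        ]
        out = assign_enhancers(enhs, self.candidates, self.model)
        assert len(out) == len(enhs)


class TestExpressionValidation:
    def test_planted_effect_detected(self, rng):
        genes = [f"g{k}" for k in range(20)]
        tpm = pd.DataFrame(
            {
                "A": rng.lognormal(np.log(40), 0.3, 20),
                "B": rng.lognormal(np.log(10), 0.3, 20),
                "C": rng.lognormal(np.log(10), 0.3, 20),
            },
            index=genes,
        )
        from dvchrom.linking import EnhancerAssignment

        asgn = {
            "A": [
                EnhancerAssignment(
                    GenomicInterval("c", k * 1000, k * 1000 + 100), g, "closest_any", 5000
                )
                for k, g in enumerate(genes)
            ]
        }
        out = validate_assignment_expression(asgn, tpm)
        assert (out["p_value"] < 0.01).all()
        assert (out["median_matching"] > out["median_other"]).all()

    def test_empty_set_missing_with_warning(self):
        tpm = pd.DataFrame({"A": [1.0], "B": [1.0]}, index=["g0"])
        with pytest.warns(UserWarning):
            out = validate_assignment_expression({"A": []}, tpm)
        assert out["p_value"].isna().all()


class TestDomainSizeComparison:
    def test_planted_size_difference_recovered(self, rng):
        big = [
            GenomicInterval("c", int(s), int(s) + int(w))
            for s, w in zip(
                np.arange(50) * 300_000, rng.integers(80_000, 120_000, 50)
            )
        ]
        small = [
            GenomicInterval("c", int(s), int(s) + int(w))
            for s, w in zip(
                20_000_000 + np.arange(50) * 300_000,
                rng.integers(40_000, 60_000, 50),
            )
        ]
        features = [
            GenomicInterval("c", d.start + 100, d.start + 200) for d in big
        ]
        out = domain_size_comparison(big + small, features)
        assert out["mean_with"] > out["mean_without"]
        assert out["p_value"] < 1e-6

    def test_single_group_no_test(self):
        doms = [GenomicInterval("c", 0, 50_000)]
        feats = [GenomicInterval("c", 10, 20)]
        out = domain_size_comparison(doms, feats)
        assert np.isnan(out["p_value"])
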