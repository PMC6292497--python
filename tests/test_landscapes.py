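import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from _oracles import perbase_great_domain, quadratic_peak_counts
from chordcomp.landscapes import (
    GenomeAnnotation,
    PeakSet,
    _basal_interval,
    bidirectional_pairs,
    classify_apres,
    conservation_group_summary,
    count_apres_per_gene,
    family_min_max_counts,
    great_domains,
    mean_conservation,
    stratified_match,
    tss_distance,
)
from chordcomp.orthology import FamilySet, GeneFamily


def _peaks(rows):
    return PeakSet(
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])
    )


class TestClassify:
    def test_promoter_window(self, toy_annotation):
        # midpoint 300 bp upstream of gA TSS (100000)
        res = classify_apres(_peaks([("chr1", 99_500, 99_900, "p")]), toy_annotation)
        assert res.intervals["category"].iloc[0] == "promoter"

    def test_gene_body(self, toy_annotation):
        res = classify_apres(_peaks([("chr1", 104_000, 104_400, "p")]), toy_annotation)
        assert res.intervals["category"].iloc[0] == "gene_body"

    def test_proximal_and_distal(self, toy_annotation):
        res = classify_apres(
            _peaks([("chr1", 96_800, 97_200, "prox"), ("chr1", 500_000, 500_400, "dist")]),
            toy_annotation,
        )
        assert res.intervals["category"].tolist() == ["proximal", "distal"]

    def test_minus_strand_promoter(self, toy_annotation):
        # gB is minus strand: TSS at 214999, upstream extends right
        res = classify_apres(_peaks([("chr1", 215_400, 215_800, "p")]), toy_annotation)
        assert res.intervals["category"].iloc[0] == "promoter"

    def test_unknown_chromosome_rejected(self, toy_annotation):
        with pytest.raises(ValueError, match="chrZ"):
            classify_apres(_peaks([("chrZ", 0, 100, "p")]), toy_annotation)

    def test_categories_partition(self, toy_annotation):
        rng = np.random.default_rng(0)
        rows = [
            ("chr1", int(s), int(s) + 200, f"pk{i}")
            for i, s in enumerate(rng.integers(0, 900_000, size=200))
        ]
        res = classify_apres(_peaks(rows), toy_annotation)
        assert res.intervals["category"].notna().all()
        assert len(res.intervals) == 200

    def test_zero_peaks_ok(self, toy_annotation):
        res = classify_apres(_peaks([]), toy_annotation)
        assert len(res) == 0


class TestTssDistance:
    def test_peak_on_tss_zero(self, toy_annotation):
        res = tss_distance(_peaks([("chr1", 99_900, 100_100, "p")]), toy_annotation)
        assert res["distance"].iloc[0] == 0

    def test_cdf_steps(self, toy_annotation):
        res = tss_distance(
            _peaks([("chr2", 50_000, 50_200, "p1"), ("chr2", 50_200, 50_400, "p2")]),
            toy_annotation,
        )
        assert sorted(res["distance"]) == [100, 300]

    def test_matches_all_pairs_minimum(self, toy_annotation):
        rng = np.random.default_rng(1)
        rows = [
            ("chr1", int(s), int(s) + 100, f"pk{i}")
            for i, s in enumerate(rng.integers(0, 999_000, size=50))
        ]
        res = tss_distance(_peaks(rows), toy_annotation)
        tss = toy_annotation.genes.query("chrom == 'chr1'")["tss"].to_numpy()
        for (_, row), (c, s, e, _) in zip(res.iterrows(), rows):
            mid = (s + e) // 2
            assert row["distance"] == min(abs(mid - t) for t in tss)

    def test_geneless_chromosome_warns(self):
        ann = GenomeAnnotation(
            chromosomes={"chr1": 1000, "chrEmpty": 1000},
            genes=pd.DataFrame(
                [{"gene_id": "g", "chrom": "chr1", "strand": "+", "start": 10, "end": 20}]
            ),
        )
        with pytest.warns(UserWarning, match="gene-less"):
            res = tss_distance(_peaks([("chrEmpty", 0, 100, "p")]), ann)
        assert np.isnan(res["distance"].iloc[0])


def _annotation(genes, lengths):
    return GenomeAnnotation(chromosomes=lengths, genes=pd.DataFrame(genes))


class TestGreatDomains:
    def test_lone_gene_capped_at_max_ext(self):
        ann = _annotation(
            [{"gene_id": "g", "chrom": "c", "strand": "+", "start": 2_000_000, "end": 2_010_000}],
            {"c": 10_000_000},
        )
        (d,) = great_domains(ann)
        assert d.basal == (1_995_000, 2_001_000)
        # extension reaches max_ext from the TSS on both sides
        assert d.extended == (1_000_000, 3_000_000)

    def test_extension_stops_at_foreign_basal(self):
        ann = _annotation(
            [
                {"gene_id": "g1", "chrom": "c", "strand": "+", "start": 100_000, "end": 101_000},
                {"gene_id": "g2", "chrom": "c", "strand": "+", "start": 200_000, "end": 201_000},
            ],
            {"c": 1_000_000},
        )
        d1, d2 = great_domains(ann)
        assert d1.extended[1] == 195_000  # g2 basal start
        assert d2.extended[0] == 101_000  # g1 basal end

    def test_chromosome_start_clipping(self):
        ann = _annotation(
            [{"gene_id": "g", "chrom": "c", "strand": "+", "start": 1_000, "end": 2_000}],
            {"c": 5_000_000},
        )
        (d,) = great_domains(ann)
        assert d.basal[0] == 0
        assert d.extended[0] == 0

    def test_matches_perbase_oracle_on_random_genomes(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            clen = int(rng.integers(5_000, 20_000))
            n_genes = int(rng.integers(1, 6))
            starts = np.sort(rng.choice(clen - 300, size=n_genes, replace=False))
            genes = []
            for i, s in enumerate(starts):
                end = min(int(s) + int(rng.integers(50, 250)), clen)
                genes.append(
                    {
                        "gene_id": f"g{i}",
                        "chrom": "c",
                        "strand": rng.choice(["+", "-"]),
                        "start": int(s),
                        "end": end,
                    }
                )
            ann = _annotation(genes, {"c": clen})
            basal_up, basal_down, max_ext = 500, 100, 2_000
            domains = great_domains(ann, basal_up, basal_down, max_ext)
            basals = {d.gene_id: d.basal for d in domains}
            for d in domains:
                row = ann.genes.set_index("gene_id").loc[d.gene_id]
                expected = perbase_great_domain(
                    tss=int(row["tss"]),
                    strand=row["strand"],
                    chrom_len=clen,
                    own_basal=basals[d.gene_id],
                    foreign_basals=[b for g, b in basals.items() if g != d.gene_id],
                    max_ext=max_ext,
                )
                assert d.extended == expected, f"{d.gene_id}: {d.extended} != {expected}"


class TestCounting:
    def test_overlapping_domains_count_for_both(self, toy_annotation):
        domains = great_domains(toy_annotation)
        peaks = _peaks([("chr1", 150_000, 150_200, "shared")])
        counts = count_apres_per_gene(domains, peaks)
        assert counts["gA"] == 1 and counts["gB"] == 1

    def test_no_peaks_all_zero(self, toy_annotation):
        counts = count_apres_per_gene(great_domains(toy_annotation), _peaks([]))
        assert (counts == 0).all()

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            clen = int(rng.integers(10_000, 30_000))
            n_genes = int(rng.integers(1, 5))
            starts = np.sort(rng.choice(clen - 500, size=n_genes, replace=False))
            genes = [
                {
                    "gene_id": f"g{i}",
                    "chrom": "c",
                    "strand": rng.choice(["+", "-"]),
                    "start": int(s),
                    "end": int(s) + 100,
                }
                for i, s in enumerate(starts)
            ]
            ann = _annotation(genes, {"c": clen})
            domains = great_domains(ann, 500, 100, 2000)
            peak_rows = [
                ("c", int(p), int(p) + 50, f"pk{i}")
                for i, p in enumerate(rng.integers(0, clen - 50, size=30))
            ]
            counts = count_apres_per_gene(domains, _peaks(peak_rows))
            oracle = quadratic_peak_counts(
                [(d.gene_id, d.chrom, *d.extended) for d in domains],
                [(c, s, e) for c, s, e, _ in peak_rows],
            )
            assert counts.to_dict() == oracle


class TestStratify:
    def test_identical_multisets_fully_retained(self):
        sizes = pd.Series([100, 600, 1100], index=["a", "b", "c"])
        ka, kb, log = stratified_match(sizes, sizes.copy(), bin_bp=500, seed=0)
        assert sorted(ka) == ["a", "b", "c"] and sorted(kb) == ["a", "b", "c"]
        assert (log["kept"] == 1).all()

    def test_min_rule(self):
        sa = pd.Series([100, 110, 120], index=["a1", "a2", "a3"])
        sb = pd.Series([105], index=["b1"])
        ka, kb, log = stratified_match(sa, sb, bin_bp=500, seed=0)
        assert len(ka) == 1 and len(kb) == 1

    def test_per_bin_counts_exactly_equal(self):
        rng = np.random.default_rng(4)
        sa = pd.Series(rng.integers(0, 5000, 100), index=[f"a{i}" for i in range(100)])
        sb = pd.Series(rng.integers(0, 5000, 80), index=[f"b{i}" for i in range(80)])
        ka, kb, _ = stratified_match(sa, sb, seed=1)
        ca = (sa[ka] // 500).value_counts().sort_index()
        cb = (sb[kb] // 500).value_counts().sort_index()
        assert ca.to_dict() == cb.to_dict()

    def test_ks_calibration(self):
        ns = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sa = pd.Series(rng.uniform(0, 3000, 150), index=[f"a{i}" for i in range(150)])
            sb = pd.Series(rng.uniform(0, 3000, 120), index=[f"b{i}" for i in range(120)])
            ka, kb, _ = stratified_match(sa, sb, seed=seed)
            if ks_2samp(sa[ka], sb[kb]).pvalue > 0.05:
                ns += 1
        assert ns >= 95

    def test_no_shared_bin_rejected(self):
        sa = pd.Series([100], index=["a"])
        sb = pd.Series([9000], index=["b"])
        with pytest.raises(ValueError, match="shared size bin"):
            stratified_match(sa, sb)


class TestFamilyMinMax:
    def test_min_max(self):
        fams = FamilySet(
            families=[GeneFamily("f", {"v": ["x", "y", "z"]})], species=["v"]
        )
        counts = pd.Series({"x": 2, "y": 7, "z": 11})
        res = family_min_max_counts(counts, fams)
        assert res.loc["f", "min"] == 2 and res.loc["f", "max"] == 11

    def test_single_member_min_equals_max(self):
        fams = FamilySet(families=[GeneFamily("f", {"v": ["x"]})], species=["v"])
        res = family_min_max_counts(pd.Series({"x": 4}), fams)
        assert res.loc["f", "min"] == res.loc["f", "max"] == 4

    def test_missing_member_skipped_with_warning(self):
        fams = FamilySet(families=[GeneFamily("f", {"v": ["x", "missing"]})], species=["v"])
        with pytest.warns(UserWarning, match="skipped"):
            res = family_min_max_counts(pd.Series({"x": 4}), fams)
        assert len(res) == 0


class TestBidirectional:
    def _ann(self, gene_tuples, clen=100_000):
        genes = [
            {"gene_id": f"g{i}", "chrom": "c", "strand": strand, "start": s, "end": e}
            for i, (s, e, strand) in enumerate(gene_tuples)
        ]
        return _annotation(genes, {"c": clen})

    def test_divergent_pair_reported(self):
        # minus gene TSS at 9999, plus gene TSS at 10299 -> separation 300
        ann = self._ann([(5_000, 10_000, "-"), (10_299, 15_000, "+")])
        pairs, seps = bidirectional_pairs(ann, max_sep_bp=1000)
        assert len(pairs) == 1
        assert pairs["tss_separation"].iloc[0] == 300
        assert seps.tolist() == [300]

    def test_convergent_pair_not_reported(self):
        ann = self._ann([(5_000, 10_000, "+"), (10_299, 15_000, "-")])
        pairs, _ = bidirectional_pairs(ann, max_sep_bp=10_000)
        assert len(pairs) == 0

    def test_tandem_pair_not_reported(self):
        ann = self._ann([(5_000, 10_000, "+"), (10_299, 15_000, "+")])
        pairs, _ = bidirectional_pairs(ann, max_sep_bp=10_000)
        assert len(pairs) == 0

    def test_separation_threshold(self):
        ann = self._ann([(5_000, 10_000, "-"), (12_000, 15_000, "+")])
        pairs, seps = bidirectional_pairs(ann, max_sep_bp=1000)
        assert len(pairs) == 0
        assert len(seps) == 1  # histogram still records the divergent pair


class TestConservation:
    def _track(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])

    def test_constant_track(self):
        res = mean_conservation(
            _peaks([("c", 100, 200, "p")]), self._track([("c", 0, 1000, 0.5)])
        )
        assert res["mean_conservation"].iloc[0] == pytest.approx(0.5)

    def test_half_and_half(self):
        track = self._track([("c", 100, 150, 0.0), ("c", 150, 200, 1.0)])
        res = mean_conservation(_peaks([("c", 100, 200, "p")]), track)
        assert res["mean_conservation"].iloc[0] == pytest.approx(0.5)

    def test_matches_perbase_average(self):
        rng = np.random.default_rng(6)
        # random step track over [0, 1000)
        edges = np.sort(rng.choice(np.arange(1, 1000), size=9, replace=False))
        bounds = [0, *edges.tolist(), 1000]
        scores = rng.uniform(0, 1, size=len(bounds) - 1)
        track = self._track(
            [("c", bounds[i], bounds[i + 1], scores[i]) for i in range(len(scores))]
        )
        perbase = np.concatenate(
            [np.full(bounds[i + 1] - bounds[i], scores[i]) for i in range(len(scores))]
        )
        peaks = _peaks([("c", 137, 684, "p1"), ("c", 20, 990, "p2")])
        res = mean_conservation(peaks, track)
        assert res["mean_conservation"].iloc[0] == pytest.approx(perbase[137:684].mean())
        assert res["mean_conservation"].iloc[1] == pytest.approx(perbase[20:990].mean())

    def test_uncovered_peak_null_with_warning(self):
        with pytest.warns(UserWarning, match="uncovered"):
            res = mean_conservation(
                _peaks([("c", 5000, 5100, "p")]), self._track([("c", 0, 1000, 0.5)])
            )
        assert np.isnan(res["mean_conservation"].iloc[0])

    def test_group_summary_iqr(self):
        scored = pd.DataFrame(
            {
                "category": ["x"] * 4,
                "mean_conservation": [0.1, 0.2, 0.3, 0.4],
            }
        )
        summary = conservation_group_summary(scored)
        assert summary.loc["x", "mean"] == pytest.approx(0.25)
        assert summary.loc["x", "q25"] == pytest.approx(0.175)
        assert summary.loc["x", "q75"] == pytest.approx(0.325)
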