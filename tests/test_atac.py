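"""Occupancy and affinity analysis: masking, consensus, partition, score
comparison, promoter definition, coverage sums, differential accessibility,
peak-gene links and expression integration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridshock import atac, syndata
from hybridshock.intervals import PeakSet


def peakset(rows, label=""):
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                               "name", "score"]), label=label)


class TestMaskRegions:
    def test_empty_bed_is_identity(self):
        seqs = {"chr1": "ACGT" * 25}
        out = atac.mask_regions(seqs, pd.DataFrame(columns=["chrom", "start",
                                                            "end"]))
        assert out == seqs

    def test_half_open_masking(self):
        seqs = {"chr1": "A" * 100}
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]})
        out = atac.mask_regions(seqs, regions)
        assert out["chr1"].count("N") == 10
        assert out["chr1"][9] == "A" and out["chr1"][10] == "N"
        assert out["chr1"][19] == "N" and out["chr1"][20] == "A"

    def test_rdna_style_regions_on_synthetic_chromosome(self):
        # two repeat regions of a 500 kb chromosome: 18264 + 1262 = 19526 N
        rng = np.random.default_rng(0)
        seqs = {"XII": "".join(rng.choice(list("ACGT"), 500_000))}
        regions = pd.DataFrame({
            "chrom": ["XII", "XII"],
            "start": [450_915, 489_349],
            "end": [469_179, 490_611]})
        out = atac.mask_regions(seqs, regions)
        assert out["XII"].count("N") == 19_526

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            atac.mask_regions({"chr1": "A" * 50},
                              pd.DataFrame({"chrom": ["chr1"], "start": [40],
                                            "end": [60]}))


class TestReplicateConsensus:
    def test_identical_replicates_pass_through(self):
        rep = peakset([("chr1", 100, 200, "p1", 10.0),
                       ("chr1", 500, 600, "p2", 20.0)])
        cons = atac.replicate_consensus([rep, rep, rep], min_reps=2)
        assert len(cons) == 2
        assert cons.df["start"].tolist() == [100, 500]

    def test_singleton_peak_dropped(self):
        shared = [("chr1", 100, 200, "p1", 10.0)]
        only_r1 = shared + [("chr1", 900, 950, "p2", 5.0)]
        cons = atac.replicate_consensus(
            [peakset(only_r1), peakset(shared), peakset(shared)], min_reps=2)
        assert len(cons) == 1
        assert cons.df["start"].iloc[0] == 100

    def test_union_interval_semantics(self):
        r1 = peakset([("chr1", 100, 200, "a", 10.0)])
        r2 = peakset([("chr1", 150, 250, "b", 30.0)])
        cons = atac.replicate_consensus([r1, r2], min_reps=2)
        assert len(cons) == 1
        assert (cons.df["start"].iloc[0], cons.df["end"].iloc[0]) == (100, 250)
        assert cons.df["score"].iloc[0] == pytest.approx(20.0)

    def test_min_reps_exceeding_replicates_rejected(self):
        with pytest.raises(ValueError, match="min_reps"):
            atac.replicate_consensus([peakset([("chr1", 0, 10, "a", 1.0)])],
                                     min_reps=2)


class TestPartition:
    def test_disjoint_sets_are_fully_specific(self):
        parent = peakset([("chr1", 0, 100, "a", 1.0)])
        hybrid = peakset([("chr1", 500, 600, "b", 1.0)])
        part = atac.partition_peaksets(parent, hybrid)
        assert part["counts"]["parent_specific"] == 1
        assert part["counts"]["hybrid_specific"] == 1
        assert part["counts"]["consensus_from_parent"] == 0

    def test_identical_sets_are_fully_consensus(self):
        rows = [("chr1", 0, 100, "a", 1.0), ("chr2", 5, 50, "b", 2.0)]
        part = atac.partition_peaksets(peakset(rows), peakset(rows))
        assert part["counts"]["parent_specific"] == 0
        assert part["counts"]["consensus_from_parent"] == 2

    def test_partition_conserves_input_sizes(self):
        rng = np.random.default_rng(1)
        def random_set(seed):
            r = np.random.default_rng(seed)
            starts = np.sort(r.choice(10_000, 50, replace=False)) * 10
            return peakset([("chr1", int(s), int(s + r.integers(50, 300)),
                             f"p{i}", 1.0) for i, s in enumerate(starts)])
        for seed in range(5):
            parent, hybrid = random_set(seed), random_set(seed + 100)
            c = atac.partition_peaksets(parent, hybrid)["counts"]
            assert c["consensus_from_parent"] + c["parent_specific"] == len(parent)
            assert c["consensus_from_hybrid"] + c["hybrid_specific"] == len(hybrid)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_overlap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        def rand_set(r):
            rows = []
            for i in range(r.integers(1, 8)):
                s = int(r.integers(0, 500))
                rows.append(("chr1", s, s + int(r.integers(1, 100)),
                             f"p{i}", 1.0))
            return peakset(rows)
        a, b = rand_set(rng), rand_set(rng)
        mask_ab = a.overlaps_mask(b)
        mask_ba = b.overlaps_mask(a)
        # brute-force per-base oracle
        def bases(ps):
            out = set()
            for row in ps.df.itertuples(index=False):
                out |= set(range(row.start, row.end))
            return out
        assert mask_ab.any() == mask_ba.any() == bool(bases(a) & bases(b))

    def test_recovers_designed_shared_fraction(self):
        tmpl = syndata.random_promoter_grid(3400, seed=5)
        peaks, _ = syndata.simulate_atac(tmpl, shared_fraction=0.88,
                                         n_peaks=3000, seed=6)
        cons = {bg: atac.replicate_consensus(reps, 2)
                for bg, reps in peaks.items()}
        part = atac.partition_peaksets(cons["parent"], cons["hybrid"])
        est = part["counts"]["consensus_from_parent"] / part["counts"]["parent"]
        assert est == pytest.approx(0.88, abs=0.02)


class TestScoreComparison:
    def test_identical_distributions_are_null(self):
        rng = np.random.default_rng(2)
        pool = rng.normal(100, 10, 200)
        out = atac.score_comparison({"a": pool[:100], "b": pool[100:]})
        assert out["p"].iloc[0] > 0.5

    def test_exact_small_sample_p_matches_enumeration(self):
        out = atac.score_comparison({"low": np.array([1, 2, 3]),
                                     "high": np.array([10, 20, 30])})
        # exhaustive rank enumeration oracle
        values = [1, 2, 3, 10, 20, 30]
        n1 = 3
        observed_u = 0.0  # low group wins no pairs
        extremes = 0
        total = 0
        for combo in itertools.combinations(range(6), n1):
            group1 = [values[i] for i in combo]
            group2 = [values[i] for i in range(6) if i not in combo]
            u = sum(a > b for a in group1 for b in group2)
            total += 1
            if min(u, 9 - u) <= min(observed_u, 9 - observed_u):
                extremes += 1
        assert extremes / total == pytest.approx(0.1)
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_lower_scoring_specific_peaks_detected(self):
        rng = np.random.default_rng(3)
        groups = {"specific": rng.normal(300, 90, 150),
                  "consensus": rng.normal(600, 120, 1000)}
        out = atac.score_comparison(groups)
        assert out["p"].iloc[0] < 0.01
        assert out["median_a"].iloc[0] < out["median_b"].iloc[0]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            atac.score_comparison({"a": np.array([]), "b": np.array([1.0])})


class TestDefinePromoters:
    CHROMS = {"chr1": 10_000}

    def ann(self, rows):
        # rows as (gene_id, start0, end0, strand) half-open -> GTF 1-based
        return pd.DataFrame(
            [(g, "chr1", s + 1, e, st) for g, s, e, st in rows],
            columns=["gene_id", "chrom", "start", "end", "strand"])

    def test_truncation_by_upstream_neighbor(self):
        ann = self.ann([("up", 4000, 4500, "+"), ("g", 5000, 6000, "+")])
        prom = atac.define_promoters(ann, self.CHROMS).set_index("gene_id")
        assert (prom.loc["g", "start"], prom.loc["g", "end"]) == (4500, 5000)
        assert prom.loc["g", "reason"] == "neighbor_gene"

    def test_truncation_by_chromosome_start(self):
        ann = self.ann([("g", 300, 900, "+")])
        prom = atac.define_promoters(ann, self.CHROMS).set_index("gene_id")
        assert (prom.loc["g", "start"], prom.loc["g", "end"]) == (0, 300)
        assert prom.loc["g", "reason"] == "chromosome_border"

    def test_full_1kb_for_isolated_minus_strand_gene(self):
        ann = self.ann([("g", 2000, 3000, "-")])
        prom = atac.define_promoters(ann, self.CHROMS).set_index("gene_id")
        assert (prom.loc["g", "start"], prom.loc["g", "end"]) == (3000, 4000)
        assert prom.loc["g", "reason"] == "full_1kb"

    def test_minus_strand_truncated_by_chromosome_end(self):
        ann = self.ann([("g", 9500, 9800, "-")])
        prom = atac.define_promoters(ann, self.CHROMS).set_index("gene_id")
        assert (prom.loc["g", "start"], prom.loc["g", "end"]) == (9800, 10_000)
        assert prom.loc["g", "reason"] == "chromosome_border"

    def test_abutting_genes_give_zero_length_promoter(self):
        ann = self.ann([("a", 1000, 2000, "+"), ("g", 2000, 3000, "+")])
        prom = atac.define_promoters(ann, self.CHROMS).set_index("gene_id")
        assert prom.loc["g", "length"] == 0

    def test_promoters_never_overlap_gene_bodies(self):
        _, _, ann = syndata.generate_genome_pair(
            n_chrom=2, chrom_len=30_000, n_genes=40, divergence=0.1, seed=4)
        genomes, _, _ = syndata.generate_genome_pair(
            n_chrom=2, chrom_len=30_000, n_genes=40, divergence=0.1, seed=4)
        prom = atac.define_promoters(ann, genomes.chrom_lengths)
        assert (prom["length"] <= 1000).all()
        bodies = [(r.chrom, r.start - 1, r.end) for r in ann.itertuples()]
        for p in prom.itertuples():
            for chrom, s, e in bodies:
                if chrom == p.chrom:
                    assert min(e, p.end) - max(s, p.start) <= 0 or p.length == 0


class TestPromoterCounts:
    PROM = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                         "start": [100], "end": [600], "length": [500]})

    def test_uniform_coverage_sums_to_length(self):
        cov = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000],
                            "value": [1.0]})
        assert atac.promoter_counts(cov, self.PROM)["g1"] == 500.0

    def test_zero_coverage(self):
        cov = pd.DataFrame({"chrom": ["chr1"], "start": [700], "end": [900],
                            "value": [5.0]})
        assert atac.promoter_counts(cov, self.PROM)["g1"] == 0.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(5)
        blocks = []
        pos = 0
        for _ in range(30):
            width = int(rng.integers(10, 120))
            blocks.append(("chr1", pos, pos + width, float(rng.integers(0, 8))))
            pos += width
        cov = pd.DataFrame(blocks, columns=["chrom", "start", "end", "value"])
        # per-base oracle
        arr = np.zeros(pos)
        for _, s, e, v in blocks:
            arr[s:e] = v
        proms = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(10)],
            "chrom": "chr1",
            "start": rng.integers(0, pos - 400, 10),
        })
        proms["end"] = proms["start"] + rng.integers(50, 400, 10)
        proms["length"] = proms["end"] - proms["start"]
        counts = atac.promoter_counts(cov, proms)
        for p in proms.itertuples(index=False):
            assert counts[p.gene_id] == pytest.approx(arr[p.start:p.end].sum())

    def test_missing_chromosome_rejected(self):
        cov = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [10],
                            "value": [1.0]})
        with pytest.raises(KeyError, match="coverage"):
            atac.promoter_counts(cov, self.PROM)


class TestDifferentialAccessibility:
    def _samples(self):
        return (["A_r1", "A_r2", "A_r3", "B_r1", "B_r2", "B_r3"],
                pd.Series(["A"] * 3 + ["B"] * 3,
                          index=["A_r1", "A_r2", "A_r3",
                                 "B_r1", "B_r2", "B_r3"]))

    def test_equal_counts_equal_lengths_no_calls(self):
        cols, groups = self._samples()
        rng = np.random.default_rng(6)
        base = rng.poisson(800, (100, 1))
        counts = pd.DataFrame(np.tile(base, (1, 6))
                              + rng.poisson(20, (100, 6)), columns=cols)
        lengths = pd.DataFrame(500, index=counts.index, columns=cols)
        out = atac.differential_accessibility(counts, lengths, groups)
        assert len(out["de"]) == 0

    def test_designed_accessibility_recovered(self):
        cols, groups = self._samples()
        recovered = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu = np.full((200, 6), 800.0)
            mu[:20, 3:] *= 4.0  # 20 promoters 4x more open in B
            counts = pd.DataFrame(rng.poisson(mu), columns=cols)
            lengths = pd.DataFrame(500, index=counts.index, columns=cols)
            out = atac.differential_accessibility(counts, lengths, groups,
                                                  numerator="B",
                                                  denominator="A")
            recovered.append(np.isin(np.arange(20), out["de"].index).sum())
        assert np.mean(recovered) >= 16

    def test_length_control_removes_length_bias(self):
        cols, groups = self._samples()
        rng = np.random.default_rng(7)
        # 2x longer B promoters collect 2x coverage at equal accessibility
        counts = pd.DataFrame(
            np.column_stack([rng.poisson(500, (150, 3)),
                             rng.poisson(1000, (150, 3))]), columns=cols)
        lengths = pd.DataFrame(
            np.column_stack([np.full((150, 3), 400), np.full((150, 3), 800)]),
            index=counts.index, columns=cols)
        out = atac.differential_accessibility(counts, lengths, groups,
                                              numerator="B", denominator="A")
        assert len(out["de"]) == 0
        assert abs(out["result"]["l2fc"].median()) < 0.15
        # without length control the same data shows ~1 l2fc of pure bias
        unit = pd.DataFrame(500, index=counts.index, columns=cols)
        biased = atac.differential_accessibility(counts, unit, groups,
                                                 numerator="B",
                                                 denominator="A")
        assert biased["result"]["l2fc"].median() == pytest.approx(1.0, abs=0.15)


class TestPeakGeneLinks:
    ANN = pd.DataFrame({
        "gene_id": ["left", "right"],
        "chrom": ["chr1", "chr1"],
        "start": [1001, 3001],   # GTF 1-based: bodies [1000,2000) and [3000,4000)
        "end": [2000, 4000],
        "strand": ["-", "+"],
    })

    @pytest.fixture()
    def promoters(self):
        return atac.define_promoters(self.ANN, {"chr1": 10_000})

    def test_peak_in_promoter_is_linked(self, promoters):
        peaks = peakset([("chr1", 2500, 2600, "pk", 5.0)])
        links = atac.assign_peaks_to_genes(peaks, self.ANN, promoters)
        assert set(links["gene_id"].dropna()) == {"left", "right"}

    def test_divergent_promoters_link_both_genes(self, promoters):
        # the region between a - gene and a + gene is promoter to both
        peaks = peakset([("chr1", 2000, 3000, "pk", 5.0)])
        links = atac.assign_peaks_to_genes(peaks, self.ANN, promoters)
        assert len(links) == 2
        assert set(links["gene_strand"]) == {"+", "-"}

    def test_distant_peak_unlinked(self, promoters):
        peaks = peakset([("chr1", 5600, 5700, "pk", 5.0)])
        links = atac.assign_peaks_to_genes(peaks, self.ANN, promoters)
        assert links["gene_id"].isna().all()


class TestIntegration:
    def test_empty_links_give_zero_concordance(self):
        links = pd.DataFrame(columns=["peak", "chrom", "start", "end",
                                      "gene_id", "gene_strand"])
        de = pd.DataFrame({"direction": []})
        out = atac.integrate_expression(links, de)
        assert out["concordance"] == {"same_direction": 0, "opposite": 0,
                                      "no_de": 0}

    def test_constructed_full_concordance(self):
        links = pd.DataFrame({
            "peak": [f"pk{i}" for i in range(10)],
            "chrom": "chr1", "start": 0, "end": 10,
            "gene_id": [f"g{i}" for i in range(10)],
            "gene_strand": "+"})
        de = pd.DataFrame({"direction": ["up"] * 10},
                          index=[f"g{i}" for i in range(10)])
        out = atac.integrate_expression(links, de)
        assert out["concordance"]["same_direction"] == 10

    def test_independent_placement_matches_hypergeometric(self):
        # when DE genes and linked genes are placed independently, the overlap
        # follows the hypergeometric law
        n_genes, n_links, n_de = 200, 40, 30
        overlaps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(n_genes)]
            linked = rng.choice(genes, n_links, replace=False)
            de_genes = rng.choice(genes, n_de, replace=False)
            links = pd.DataFrame({
                "peak": [f"pk{i}" for i in range(n_links)],
                "chrom": "chr1", "start": 0, "end": 10,
                "gene_id": linked, "gene_strand": "+"})
            de = pd.DataFrame({"direction": ["up"] * n_de}, index=de_genes)
            out = atac.integrate_expression(links, de)
            overlaps.append(out["concordance"]["same_direction"])
        expected = n_links * n_de / n_genes
        var = (n_links * n_de / n_genes
               * (n_genes - n_de) / n_genes
               * (n_genes - n_links) / (n_genes - 1))
        se = np.sqrt(var / 20)
        assert abs(np.mean(overlaps) - expected) < 3 * se
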