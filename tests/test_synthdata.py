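import numpy as np
import pytest
from scipy import stats

from estrores.homology import map_to_human
from estrores.regulome import scan_motif
from estrores.synthdata import (
    SynthTruth,
    gen_expression,
    gen_genome_and_loci,
    gen_regulome_and_sets,
    gen_spot_tables,
)

ERE = "GGTCANNNTGACC"


class TestExpression:
    def test_same_seed_bitwise_identical(self):
        m1, t1 = gen_expression(n_genes=200, n_planted=20, seed=5)
        m2, t2 = gen_expression(n_genes=200, n_planted=20, seed=5)
        assert np.array_equal(m1.values, m2.values)
        assert t1.planted_up == t2.planted_up
        assert t1.rescue == t2.rescue

    def test_different_seed_differs(self):
        m1, _ = gen_expression(n_genes=200, seed=5)
        m2, _ = gen_expression(n_genes=200, seed=6)
        assert not np.array_equal(m1.values, m2.values)

    def test_truth_consistent_with_matrix(self):
        # planted genes realize their recorded fold in the class means up to
        # normal-theory noise: the sample mean difference has SD
        # sigma*sqrt(1/n_e + 1/n_c); a 5-sigma band over 60 genes should
        # essentially never fail
        sigma = 0.5
        m, truth = gen_expression(n_genes=500, n_planted=60, sigma=sigma, seed=7)
        ctrl = m.values[:, m.class_columns("control")]
        e2 = m.values[:, m.class_columns("E2")]
        band = 5 * sigma * np.sqrt(1 / e2.shape[1] + 1 / ctrl.shape[1])
        idx = {g: i for i, g in enumerate(m.gene_ids)}
        for gene, fold in truth.planted_up.items():
            delta = e2[idx[gene]].mean() - ctrl[idx[gene]].mean()
            assert abs(delta - np.log2(fold)) < band
        for gene, fold in truth.planted_down.items():
            delta = e2[idx[gene]].mean() - ctrl[idx[gene]].mean()
            assert abs(delta + np.log2(fold)) < band

    def test_fold_range_respected(self):
        _, truth = gen_expression(n_genes=500, n_planted=80, seed=8,
                                  fold_range=(2.0, 128.0))
        folds = list(truth.planted_up.values()) + list(truth.planted_down.values())
        assert all(2.0 <= f <= 128.0 for f in folds)

    def test_rescue_labels_partition_planted(self):
        _, truth = gen_expression(n_genes=300, n_planted=40, seed=9)
        assert set(truth.rescue) == truth.planted_ids()
        assert set(truth.rescue.values()) <= {"normalized", "partial"}

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            gen_expression(n_genes=10, n_planted=10)
        with pytest.raises(ValueError):
            gen_expression(n_per_class=(4, 1, 3))


class TestSpotTables:
    def test_deterministic_and_complete(self):
        m, _ = gen_expression(n_genes=150, n_planted=10, seed=3)
        t1 = gen_spot_tables(m, seed=4)
        t2 = gen_spot_tables(m, seed=4)
        assert set(t1) == set(m.sample_ids)
        for s in t1:
            assert t1[s].equals(t2[s])
            assert len(t1[s]) == m.n_genes

    def test_log_ratio_recovers_matrix_plus_bias(self):
        # with the dye bias removed analytically, good spots reproduce the
        # matrix entries exactly
        m, _ = gen_expression(n_genes=100, n_planted=0, seed=1)
        tables = gen_spot_tables(m, seed=2, bias=0.15, missing_rate=0.0,
                                 background=64.0)
        for j, sample in enumerate(m.sample_ids):
            t = tables[sample]
            net5 = t["F635 Median"] - t["B635 Median"]
            net3 = t["F532 Median"] - t["B532 Median"]
            mlog = np.log2(net5 / net3)
            alog = 0.5 * np.log2(net5 * net3)
            recovered = mlog - 0.15 * (alog - 10.5)
            assert np.allclose(recovered, m.values[:, j], atol=1e-9)

    def test_missing_rate_flags(self):
        m, _ = gen_expression(n_genes=2000, n_planted=0, seed=1)
        tables = gen_spot_tables(m, seed=5, missing_rate=0.1)
        frac = np.mean([(t["Flags"] < 0).mean() for t in tables.values()])
        assert 0.07 < frac < 0.13


class TestGenome:
    def test_base_composition_binomial_ci(self):
        gc = 0.4
        genome, _, _ = gen_genome_and_loci(n_chrom=1, chrom_len=200_000,
                                           n_genes=10, gc=gc, seed=11)
        seq = genome["chr1"]
        n_gc = seq.count("G") + seq.count("C")
        lo, hi = stats.binom.interval(0.999, len(seq), gc)
        assert lo <= n_gc <= hi

    def test_loci_non_overlapping_and_inside(self):
        genome, loci, _ = gen_genome_and_loci(n_chrom=2, chrom_len=300_000,
                                              n_genes=60, seed=12)
        by_chrom = {}
        for locus in loci:
            assert 0 <= locus.start < locus.end <= len(genome[locus.chrom])
            by_chrom.setdefault(locus.chrom, []).append((locus.start, locus.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_planted_motifs_found_by_scanner(self):
        genome, _, truth = gen_genome_and_loci(
            n_chrom=1, chrom_len=100_000, n_genes=5, gc=0.4,
            n_background_motifs=30, seed=13,
        )
        hits = {(h.chrom, h.pos) for h in scan_motif(genome, ERE)}
        planted = {(c, p) for c, p in truth.planted_motif_positions["genome"]}
        assert planted <= hits

    def test_flank_planting_lands_in_flanks(self):
        genome, loci, truth = gen_genome_and_loci(
            n_chrom=1, chrom_len=200_000, n_genes=10, gene_length=600,
            motif_genes=["hs00002", "hs00005"], planted_motifs_per_flank=2.0,
            flank=2000, seed=14,
        )
        by_id = {l.gene_id: l for l in loci}
        for gene in ("hs00002", "hs00005"):
            for _, pos in truth.planted_motif_positions.get(gene, []):
                locus = by_id[gene]
                in5 = locus.start - 2000 <= pos < locus.start
                in3 = locus.end <= pos < locus.end + 2000
                assert in5 or in3

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            gen_genome_and_loci(n_chrom=1, chrom_len=10_000, n_genes=50,
                                gene_length=600)


class TestRegulomeAndSets:
    @staticmethod
    def _study(seed=20, **kwargs):
        genome, loci, truth = gen_genome_and_loci(
            n_chrom=2, chrom_len=500_000, n_genes=100, seed=seed,
        )
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        zf = [f"zf{i:05d}" for i in range(200)]
        responsive = zf[:60]
        params = dict(
            n_sites=300, n_target_genes=20, window=10_000,
            homolog_rate=0.435, n_cell_lines=4, cell_line_size=60,
            overlap_fraction=0.29, seed=seed + 1, truth=truth,
        )
        params.update(kwargs)
        sites, homology, cells, truth = gen_regulome_and_sets(
            loci, chrom_lengths, zf, responsive, **params
        )
        return loci, sites, homology, cells, truth, zf, responsive

    def test_homolog_rate_one_maps_everything(self):
        _, _, homology, _, _, zf, _ = self._study(homolog_rate=1.0,
                                                  many_to_one_rate=0.0)
        human, rate, unmapped = map_to_human(zf[:100], homology)
        assert rate == 1.0 and unmapped == []
        assert len(human) == 100  # one-to-one when many_to_one_rate = 0

    def test_mapping_rate_near_requested(self):
        realized = []
        for s in range(5):
            _, _, homology, _, _, zf, _ = self._study(seed=30 + s)
            _, rate, _ = map_to_human(zf, homology)
            realized.append(rate)
        assert abs(np.mean(realized) - 0.435) < 0.1

    def test_overlap_fraction_realized(self):
        # conserved_truth / mapped responsive should be near overlap_fraction
        fracs = []
        for s in range(6):
            _, _, homology, _, truth, _, responsive = self._study(
                seed=40 + s, overlap_fraction=0.5
            )
            mapped = {homology.pairs[g] for g in responsive
                      if g in homology.pairs}
            if mapped:
                fracs.append(len(set(truth.conserved_truth)) / len(mapped))
        assert abs(np.mean(fracs) - 0.5) < 0.15

    def test_sites_sorted_and_in_bounds(self):
        loci, sites, *_ = self._study()
        keys = [(s.chrom, s.start) for s in sites]
        assert keys == sorted(keys)
        assert all(0 <= s.start < s.end for s in sites)

    def test_truth_round_trip(self, tmp_path):
        *_, truth, _, _ = self._study()
        truth.to_json(tmp_path / "truth.json")
        back = SynthTruth.from_json(tmp_path / "truth.json")
        assert back.homology_pairs == truth.homology_pairs
        assert back.conserved_truth == truth.conserved_truth
        assert back.seed == truth.seed
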