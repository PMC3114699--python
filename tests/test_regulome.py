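import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from estrores.regulome import (
    BindingSite,
    GeneLocus,
    assign_sites,
    extract_flanks,
    is_palindromic,
    iupac_to_regex,
    merged_region_width,
    motif_enrichment,
    reverse_complement,
    scan_motif,
    site_enrichment,
    truncate2,
)

ERE = "GGTCANNNTGACC"
COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def regex_scan_oracle(seq, pattern):
    """Independent both-strand scan with palindrome dedup, via plain regex."""
    fwd = re.compile(f"(?=({iupac_to_regex(pattern)}))")
    hits = {(m.start(), "+") for m in fwd.finditer(seq)}
    rc_pattern = pattern.upper().translate(COMP)[::-1]
    if pattern.upper() != rc_pattern:
        rev = re.compile(f"(?=({iupac_to_regex(rc_pattern)}))")
        for m in rev.finditer(seq):
            hits.add((m.start(), "-"))
    return sorted(hits)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScanMotif:
    def test_literal_consensus_hit(self):
        hits = scan_motif({"chr1": "GGTCAAAATGACC"}, ERE)
        assert len(hits) == 1
        assert hits[0].pos == 0 and hits[0].strand == "+"
        assert hits[0].matched == "GGTCAAATGACC"[:0] + "GGTCAAAATGACC"

    def test_no_hits_in_homopolymer(self):
        assert scan_motif({"chr1": "T" * 100}, ERE) == []

    def test_palindromic_pattern_detected(self):
        assert is_palindromic(ERE)
        assert not is_palindromic("GGTCA")
        assert reverse_complement("GGTCA") == "TGACC"

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif({"chr1": "ACGT" * 10}, "GGTCAXTGACC")

    def test_non_palindromic_both_strands(self):
        # GGTCA on the minus strand appears as TGACC in forward coordinates
        hits = scan_motif({"chr1": "AATGACCAA"}, "GGTCA")
        assert [(h.pos, h.strand) for h in hits] == [(2, "-")]

    def test_matches_regex_oracle_on_random_sequence(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 100_000)
        # short degenerate pattern so hits are plentiful
        for pattern in (ERE, "GGTCA", "RRYNN"):
            hits = scan_motif({"chr1": seq}, pattern)
            assert [(h.pos, h.strand) for h in hits] == regex_scan_oracle(
                seq, pattern
            )

    def test_palindrome_mirror_property(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 5000)
        rc = seq.translate(COMP)[::-1]
        fwd_hits = {h.pos for h in scan_motif({"c": seq}, ERE)}
        rc_hits = {h.pos for h in scan_motif({"c": rc}, ERE)}
        assert rc_hits == {len(seq) - len(ERE) - p for p in fwd_hits}


class TestFlanks:
    def test_basic_arithmetic(self):
        loci = [GeneLocus("g", "chr1", 50_000, 60_000)]
        regions = extract_flanks(loci, flank=20_000,
                                 chrom_lengths={"chr1": 1_000_000})["g"]
        span = [(s, e) for _, s, e, _ in regions]
        assert span == [(30_000, 50_000), (50_000, 60_000), (60_000, 80_000)]
        assert merged_region_width([(c, s, e) for c, s, e, _ in regions]) == 50_000

    def test_upstream_clipping(self):
        loci = [GeneLocus("g", "chr1", 5000, 6000)]
        regions = extract_flanks(loci, flank=20_000,
                                 chrom_lengths={"chr1": 1_000_000})["g"]
        assert regions[0][1:3] == (0, 5000)

    def test_total_width_unclipped(self):
        loci = [GeneLocus("g", "chr1", 400_000, 410_000)]
        regions = extract_flanks(loci, flank=20_000)["g"]
        total = sum(e - s for _, s, e, _ in regions)
        assert total == 10_000 + 2 * 20_000

    def test_strand_labels(self):
        plus = extract_flanks([GeneLocus("g", "c", 100_000, 101_000, "+")],
                              flank=10)["g"]
        minus = extract_flanks([GeneLocus("g", "c", 100_000, 101_000, "-")],
                               flank=10)["g"]
        assert plus[0][3] == "5p" and plus[2][3] == "3p"
        assert minus[0][3] == "3p" and minus[2][3] == "5p"


class TestMotifEnrichment:
    def test_whole_genome_regions_ratio_one(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 20_000)
        hits = scan_motif({"chr1": seq}, "GGTCA")
        res = motif_enrichment(hits, [("chr1", 0, 20_000)], 20_000)
        assert res.observed == len(hits)
        assert res.expected == pytest.approx(len(hits))

    def test_zero_hits_is_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            motif_enrichment([], [("chr1", 0, 10)], 100)

    def test_planted_density_detected(self):
        # 10x motif density inside a region covering 1% of the genome
        rng = np.random.default_rng(3)
        n = 1_000_000
        seq = list(random_seq(rng, n))
        inside = [int(p) for p in rng.integers(0, 10_000 - 13, 60)]
        outside = [int(p) for p in rng.integers(10_000, n - 13, 60)]
        for p in inside + outside:
            seq[p:p + 13] = "GGTCAAAATGACC"
        hits = scan_motif({"chr1": "".join(seq)}, ERE)
        res = motif_enrichment(hits, [("chr1", 0, 10_000)], n)
        assert res.p_binomial < 0.01
        assert res.observed >= 50


class TestAssignSites:
    GENE = GeneLocus("g", "chr1", 200_000, 210_000)

    @pytest.mark.parametrize(
        "start, end, counted",
        [
            (150_000, 150_100, True),    # 50 kb upstream, inside window
            (320_000, 320_100, False),   # 110 kb past the end
            (205_000, 205_050, True),    # overlapping the gene body
            (99_000, 100_000, False),    # ends exactly at window edge
            (99_999, 100_001, True),     # crosses the window edge
        ],
    )
    def test_window_rule(self, start, end, counted):
        counts = assign_sites([self.GENE],
                              [BindingSite("chr1", start, end)],
                              window=100_000)
        assert counts["g"] == (1 if counted else 0)

    def test_site_counts_for_multiple_genes(self):
        loci = [GeneLocus("a", "c", 1000, 2000), GeneLocus("b", "c", 2500, 3500)]
        counts = assign_sites(loci, [BindingSite("c", 2200, 2300)], window=1000)
        assert counts == {"a": 1, "b": 1}

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(-10**6, 10**6))
    def test_translation_equivariance(self, shift):
        rng = np.random.default_rng(7)
        base = 2_000_000
        loci = [
            GeneLocus(f"g{i}", "c", int(s) + base, int(s) + base + 500)
            for i, s in enumerate(rng.integers(0, 500_000, 20))
        ]
        sites = [
            BindingSite("c", int(s) + base, int(s) + base + 100)
            for s in rng.integers(0, 500_000, 50)
        ]
        moved_loci = [
            GeneLocus(l.gene_id, l.chrom, l.start + shift, l.end + shift)
            for l in loci
        ]
        moved_sites = [
            BindingSite(s.chrom, s.start + shift, s.end + shift) for s in sites
        ]
        assert assign_sites(loci, sites, 10_000) == assign_sites(
            moved_loci, moved_sites, 10_000
        )


def uniform_study(rng, n_genes=200, n_sites=300, chrom_len=2_000_000,
                  gene_len=500, site_len=100):
    slot = chrom_len // n_genes
    starts = [i * slot + int(rng.integers(0, slot - gene_len))
              for i in range(n_genes)]
    loci = [GeneLocus(f"g{i}", "chr1", s, s + gene_len)
            for i, s in enumerate(starts)]
    sites = [
        BindingSite("chr1", int(s), int(s) + site_len)
        for s in rng.integers(0, chrom_len - site_len, n_sites)
    ]
    return loci, sites, chrom_len


class TestSiteEnrichment:
    def test_printed_per_gene_rate_truncation(self):
        assert truncate2(210 / 336) == 0.62
        assert truncate2(158 / 139) == 1.13
        assert truncate2(0.999) == 0.99

    def test_per_gene_rate_and_observed(self):
        rng = np.random.default_rng(8)
        loci, sites, _ = uniform_study(rng)
        targets = [f"g{i}" for i in range(30)]
        res = site_enrichment(targets, loci, sites, window=5000, n_rand=50,
                              seed=0)
        counts = assign_sites([l for l in loci if l.gene_id in set(targets)],
                              sites, window=5000)
        assert res.observed == sum(counts.values())
        assert res.per_gene_rate == truncate2(res.observed / 30)

    def test_background_smaller_than_targets_rejected(self):
        rng = np.random.default_rng(9)
        loci, sites, _ = uniform_study(rng, n_genes=5)
        with pytest.raises(ValueError, match="background"):
            site_enrichment([l.gene_id for l in loci], loci[:3], sites)

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(10)
        loci, sites, chrom_len = uniform_study(rng, n_sites=200)
        targets = [f"g{i}" for i in range(0, 60, 3)]
        target_set = {l.gene_id: l for l in loci if l.gene_id in set(targets)}
        extra = []
        for locus in target_set.values():
            for _ in range(3):
                pos = int(rng.integers(max(0, locus.start - 4000),
                                       locus.end + 4000))
                extra.append(BindingSite("chr1", pos, pos + 100))
        res = site_enrichment(targets, loci, sites + extra, window=5000,
                              n_rand=500, seed=1)
        assert res.p_empirical <= 0.01

    def test_empirical_p_resolution(self):
        rng = np.random.default_rng(11)
        loci, sites, _ = uniform_study(rng, n_genes=50, n_sites=50)
        res = site_enrichment([f"g{i}" for i in range(10)], loci, sites,
                              window=5000, n_rand=99, seed=2)
        assert res.p_empirical >= 1 / 100
        assert (res.p_empirical * 100) == pytest.approx(
            round(res.p_empirical * 100))
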