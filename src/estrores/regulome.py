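"""ERE motif scanning and estrogen-receptor binding-site enrichment.

The estrogen-response element consensus GGTCAnnnTGACC is a degenerate,
self-reverse-complementary 13-mer.  This module scans FASTA genomes for
arbitrary IUPAC consensus patterns on both strands (reporting palindromic
matches once), extracts gene flanking regions, tests motif enrichment in
regions against the genome-wide distribution with a binomial tail, assigns
binding sites to genes within a distance window, and tests binding-site
enrichment in a target gene set with both a binomial model and a
randomization null that redraws equally sized gene sets from a background.

All coordinates are 0-based half-open (BED convention); the BED readers can
shift 1-based inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "GeneLocus",
    "BindingSite",
    "MotifHit",
    "EnrichmentResult",
    "iupac_to_regex",
    "reverse_complement",
    "is_palindromic",
    "scan_motif",
    "extract_flanks",
    "motif_enrichment",
    "assign_sites",
    "site_enrichment",
    "merged_region_width",
    "read_loci_bed",
    "read_sites_bed",
    "write_hits_bed",
    "truncate2",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid locus {self.gene_id}: [{self.start}, {self.end})")


@dataclass(frozen=True)
class BindingSite:
    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"invalid site [{self.start}, {self.end})")


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    pos: int
    strand: str
    matched: str


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    per_gene_rate: float | None
    p_binomial: float
    p_empirical: float | None
    n_randomizations: int
    null: str
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "per_gene_rate": self.per_gene_rate,
            "p_binomial": self.p_binomial,
            "p_empirical": self.p_empirical,
            "n_randomizations": self.n_randomizations,
            "null": self.null,
            **self.extra,
        }


def truncate2(x: float) -> float:
    """Truncate (not round) to 2 decimals, e.g. 210/336 = 0.625 -> 0.62."""
    return np.trunc(x * 100) / 100


# ---------------------------------------------------------------------------
# motif scanning

def iupac_to_regex(pattern: str) -> str:
    try:
        return "".join(IUPAC[c] for c in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r} in pattern") from None


def reverse_complement(pattern: str) -> str:
    return str(Seq(pattern.upper()).reverse_complement())


def is_palindromic(pattern: str) -> bool:
    """True when the pattern equals its own reverse complement (as IUPAC)."""
    return pattern.upper() == reverse_complement(pattern)


def _as_sequences(genome) -> dict[str, str]:
    """Accept a {chrom: sequence} dict or a FASTA path."""
    if isinstance(genome, dict):
        return {c: str(s).upper() for c, s in genome.items()}
    from pyfaidx import Fasta

    fasta = Fasta(str(genome))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def scan_motif(genome, pattern: str) -> list[MotifHit]:
    """All exact matches of a degenerate IUPAC consensus, both strands.

    Overlapping matches are reported.  For a self-reverse-complementary
    pattern each genomic position is reported once with strand "+";
    otherwise reverse-strand matches carry the forward-strand start of the
    site and strand "-".
    """
    if len(pattern) < 4:
        raise ValueError("pattern must be at least 4 bases")
    fwd = re.compile(f"(?=({iupac_to_regex(pattern)}))")
    palindromic = is_palindromic(pattern)
    rev = None if palindromic else re.compile(
        f"(?=({iupac_to_regex(reverse_complement(pattern))}))"
    )
    hits: list[MotifHit] = []
    for chrom, seq in _as_sequences(genome).items():
        fwd_pos = {m.start(): m.group(1) for m in fwd.finditer(seq)}
        for pos in sorted(fwd_pos):
            hits.append(MotifHit(chrom=chrom, pos=pos, strand="+",
                                 matched=fwd_pos[pos]))
        if rev is not None:
            for m in rev.finditer(seq):
                hits.append(MotifHit(chrom=chrom, pos=m.start(), strand="-",
                                     matched=m.group(1)))
    hits.sort(key=lambda h: (h.chrom, h.pos, h.strand))
    return hits


# ---------------------------------------------------------------------------
# regions

def extract_flanks(
    loci: list[GeneLocus],
    flank: int = 20_000,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, list[tuple[str, int, int, str]]]:
    """Upstream flank + gene body + downstream flank per gene.

    Returns ``{gene_id: [(chrom, start, end, label), ...]}`` with labels
    ``5p``/``body``/``3p`` relative to the gene strand, clipped to
    chromosome bounds when lengths are given.
    """
    out: dict[str, list[tuple[str, int, int, str]]] = {}
    for locus in loci:
        limit = (chrom_lengths or {}).get(locus.chrom)
        left = max(0, locus.start - flank)
        right = locus.end + flank
        if limit is not None:
            right = min(right, limit)
        up_label, down_label = ("5p", "3p") if locus.strand != "-" else ("3p", "5p")
        parts = []
        if left < locus.start:
            parts.append((locus.chrom, left, locus.start, up_label))
        parts.append((locus.chrom, locus.start, locus.end, "body"))
        if locus.end < right:
            parts.append((locus.chrom, locus.end, right, down_label))
        out[locus.gene_id] = parts
    return out


def _merge_intervals(intervals) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        acc = [list(ivals[0])]
        for start, end in ivals[1:]:
            if start <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], end)
            else:
                acc.append([start, end])
        merged[chrom] = [(s, e) for s, e in acc]
    return merged


def merged_region_width(intervals) -> int:
    """Total width of the union of (chrom, start, end) intervals."""
    return sum(
        e - s
        for ivals in _merge_intervals(intervals).values()
        for s, e in ivals
    )


def motif_enrichment(
    hits: list[MotifHit],
    regions,
    genome_size: int,
) -> EnrichmentResult:
    """Binomial test of motif density in regions vs the whole genome.

    ``regions`` is an iterable of (chrom, start, end); overlapping regions
    are merged before measuring coverage.  A hit lies in a region when its
    start position does.
    """
    if not hits:
        raise ValueError("undefined test: zero motif hits genome-wide")
    merged = _merge_intervals(regions)
    width = sum(e - s for ivals in merged.values() for s, e in ivals)
    if not 0 < width <= genome_size:
        raise ValueError(
            f"region width {width} must be in (0, genome size {genome_size}]"
        )
    observed = 0
    starts = {c: np.array([s for s, _ in iv]) for c, iv in merged.items()}
    ends = {c: np.array([e for _, e in iv]) for c, iv in merged.items()}
    for hit in hits:
        if hit.chrom not in starts:
            continue
        i = np.searchsorted(starts[hit.chrom], hit.pos, side="right") - 1
        if i >= 0 and hit.pos < ends[hit.chrom][i]:
            observed += 1
    total = len(hits)
    p_cov = width / genome_size
    expected = total * p_cov
    p = float(stats.binom.sf(observed - 1, total, p_cov))
    return EnrichmentResult(
        observed=observed,
        expected=expected,
        per_gene_rate=None,
        p_binomial=min(1.0, p),
        p_empirical=None,
        n_randomizations=0,
        null="binomial: hits land in regions w.p. region-width/genome-size",
        extra={"total_hits": total, "region_width": width,
               "genome_size": genome_size},
    )


# ---------------------------------------------------------------------------
# binding sites

def assign_sites(
    loci: list[GeneLocus],
    sites: list[BindingSite],
    window: int = 100_000,
) -> dict[str, int]:
    """Count sites overlapping each gene's [start - window, end + window).

    A site may count for several genes.  Returns per-gene counts; genes with
    no nearby site get 0.
    """
    counts = {locus.gene_id: 0 for locus in loci}
    by_chrom: dict[str, list[BindingSite]] = {}
    for site in sites:
        by_chrom.setdefault(site.chrom, []).append(site)
    for locus in loci:
        lo = locus.start - window
        hi = locus.end + window
        for site in by_chrom.get(locus.chrom, ()):
            if site.start < hi and site.end > lo:
                counts[locus.gene_id] += 1
    return counts


def _site_gene_incidence(loci, sites, window):
    """Boolean (n_sites, n_genes) incidence of site-within-window-of-gene."""
    inc = np.zeros((len(sites), len(loci)), dtype=bool)
    gene_idx = {locus.gene_id: j for j, locus in enumerate(loci)}
    by_chrom: dict[str, list[tuple[int, BindingSite]]] = {}
    for i, site in enumerate(sites):
        by_chrom.setdefault(site.chrom, []).append((i, site))
    for locus in loci:
        j = gene_idx[locus.gene_id]
        lo, hi = locus.start - window, locus.end + window
        for i, site in by_chrom.get(locus.chrom, ()):
            if site.start < hi and site.end > lo:
                inc[i, j] = True
    return inc


def site_enrichment(
    target_ids,
    background_loci: list[GeneLocus],
    sites: list[BindingSite],
    window: int = 100_000,
    n_rand: int = 1000,
    seed: int = 0,
    merge_windows: bool = False,
) -> EnrichmentResult:
    """Randomization test of binding-site abundance near a target gene set.

    The null redraws ``len(target_ids)`` genes uniformly without replacement
    from ``background_loci`` ``n_rand`` times and recomputes the statistic:
    the per-gene-sum of nearby sites (default; a site near two sampled genes
    counts twice) or, with ``merge_windows``, the number of distinct sites
    within the union of the sampled windows.  ``expected`` is the null mean
    and ``p_empirical = (1 + #{null >= observed}) / (n_rand + 1)``.  The
    binomial tail models each of the ``len(sites)`` sites as landing near a
    target w.p. expected/len(sites).
    """
    target_ids = sorted(set(target_ids))
    ids = [locus.gene_id for locus in background_loci]
    index = {g: j for j, g in enumerate(ids)}
    missing = [g for g in target_ids if g not in index]
    if missing:
        raise ValueError(f"target genes absent from background: {missing[:10]}")
    n_targets = len(target_ids)
    if len(background_loci) < n_targets:
        raise ValueError("background smaller than target set")
    inc = _site_gene_incidence(background_loci, sites, window)
    per_gene = inc.sum(axis=0)  # per-gene site count over background

    target_cols = np.array([index[g] for g in target_ids])
    if merge_windows:
        observed = int(inc[:, target_cols].any(axis=1).sum())
    else:
        observed = int(per_gene[target_cols].sum())

    rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    n_genes = len(ids)
    for b in range(n_rand):
        sample = rng.choice(n_genes, size=n_targets, replace=False)
        if merge_windows:
            null[b] = inc[:, sample].any(axis=1).sum()
        else:
            null[b] = per_gene[sample].sum()
    expected = float(null.mean())
    p_emp = float((1 + np.count_nonzero(null >= observed)) / (n_rand + 1))
    n_sites = len(sites)
    p_rate = min(1.0, expected / n_sites) if n_sites else 0.0
    p_bin = float(stats.binom.sf(observed - 1, n_sites, p_rate)) if n_sites else 1.0
    return EnrichmentResult(
        observed=observed,
        expected=expected,
        per_gene_rate=float(truncate2(observed / n_targets)) if n_targets else None,
        p_binomial=min(1.0, p_bin),
        p_empirical=p_emp,
        n_randomizations=n_rand,
        null=(
            f"{n_rand} draws of {n_targets} genes from a background of "
            f"{n_genes}; statistic = "
            + ("distinct sites in merged windows" if merge_windows
               else "per-gene site-count sum")
        ),
        extra={
            "null_sd": float(null.std(ddof=1)),
            "n_sites": n_sites,
            "window": window,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# BED input/output

def read_loci_bed(path, one_based: bool = False) -> list[GeneLocus]:
    """Read gene loci from BED (3+ columns; name in col 4, strand in col 6)."""
    loci = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
        start = int(parts[1]) - (1 if one_based else 0)
        loci.append(
            GeneLocus(
                gene_id=parts[3] if len(parts) > 3 else f"locus{ln}",
                chrom=parts[0],
                start=start,
                end=int(parts[2]),
                strand=parts[5] if len(parts) > 5 else "+",
            )
        )
    return loci


def read_sites_bed(path, one_based: bool = False, source: str = "") -> list[BindingSite]:
    sites = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
        start = int(parts[1]) - (1 if one_based else 0)
        sites.append(BindingSite(chrom=parts[0], start=start, end=int(parts[2]),
                                 source=source or (parts[3] if len(parts) > 3 else "")))
    return sites


def write_hits_bed(hits: list[MotifHit], path, pattern_length: int) -> None:
    """Write motif hits as 6-column BED with the matched 13-mer in the name."""
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(
                f"{hit.chrom}\t{hit.pos}\t{hit.pos + pattern_length}\t"
                f"{hit.matched}\t0\t{hit.strand}\n"
            )
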