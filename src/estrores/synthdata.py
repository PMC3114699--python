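"""Seeded synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* a three-class (control / E2 / E2+ICI) expression matrix whose planted
  responsive genes shift 2- to 128-fold under E2 and are pulled back toward
  control under E2+ICI (strongly for "normalized" genes, weakly for
  "partial" ones);
* spot-level two-channel tables with an intensity-dependent dye bias, so the
  normalization stage has something to remove;
* a random genome with non-overlapping gene loci, optional uniform
  background motif instances and extra instances planted in the flanks of
  designated genes;
* binding sites placed uniformly except for a density multiplier inside the
  windows of designated target genes;
* a many-to-one zebrafish-to-human homology map and overlapping cell-line
  gene lists with a controlled expected overlap fraction.

Every generator is a pure function of its arguments including ``seed``; the
returned :class:`SynthTruth` suffices to score recall/precision of any
stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .arrayio import ExpressionMatrix
from .regulome import BindingSite, GeneLocus, iupac_to_regex
from .homology import HomologyMap

__all__ = [
    "SynthTruth",
    "gen_expression",
    "gen_spot_tables",
    "gen_genome_and_loci",
    "gen_regulome_and_sets",
    "write_fasta",
    "write_bed_loci",
    "write_bed_sites",
]

IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class SynthTruth:
    """Ground-truth record accumulated across the generators."""

    seed: int
    planted_up: dict[str, float] = field(default_factory=dict)     # id -> fold
    planted_down: dict[str, float] = field(default_factory=dict)
    rescue: dict[str, str] = field(default_factory=dict)           # id -> label
    planted_motif_positions: dict[str, list] = field(default_factory=dict)
    planted_enriched_site_genes: list[str] = field(default_factory=list)
    homology_pairs: dict[str, str] = field(default_factory=dict)
    cell_lines: dict[str, list[str]] = field(default_factory=dict)
    human_universe: list[str] = field(default_factory=list)
    conserved_truth: list[str] = field(default_factory=list)

    def planted_ids(self) -> set[str]:
        return set(self.planted_up) | set(self.planted_down)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# expression

def gen_expression(
    n_genes: int = 2000,
    n_per_class: tuple[int, int, int] = (4, 3, 3),
    n_planted: int = 100,
    sigma: float = 0.5,
    seed: int = 0,
    rescue_fraction: float = 0.5,
    fold_range: tuple[float, float] = (2.0, 128.0),
    truth: SynthTruth | None = None,
) -> tuple[ExpressionMatrix, SynthTruth]:
    """Three-class expression matrix with planted estrogen responses.

    Null genes are Normal(0, sigma) in every class.  Planted genes shift
    their E2 mean by +/- log2(f) with f log-uniform on ``fold_range`` and
    set the E2+ICI mean to control + r * (E2 - control) with r = 0.1 for
    "normalized" and r = 0.6 for "partial" rescue.
    """
    if n_planted >= n_genes:
        raise ValueError("n_planted must be < n_genes")
    if len(n_per_class) != 3 or any(n < 2 for n in n_per_class):
        raise ValueError("need three classes with >= 2 samples each")
    rng = np.random.default_rng(seed)
    n_c, n_e, n_i = n_per_class
    classes = ["control"] * n_c + ["E2"] * n_e + ["E2_ICI"] * n_i
    sample_ids = (
        [f"ctrl_{i+1}" for i in range(n_c)]
        + [f"e2_{i+1}" for i in range(n_e)]
        + [f"e2ici_{i+1}" for i in range(n_i)]
    )
    gene_ids = [f"zf{g:05d}" for g in range(n_genes)]
    values = rng.normal(0.0, sigma, size=(n_genes, len(classes)))

    truth = truth or SynthTruth(seed=seed)
    if n_planted:
        planted = rng.choice(n_genes, size=n_planted, replace=False)
        signs = rng.choice([1.0, -1.0], size=n_planted)
        lo, hi = np.log2(fold_range[0]), np.log2(fold_range[1])
        lfc = rng.uniform(lo, hi, size=n_planted)  # log-uniform fold
        normalized = rng.random(n_planted) < rescue_fraction
        e2_cols = np.arange(n_c, n_c + n_e)
        ici_cols = np.arange(n_c + n_e, n_c + n_e + n_i)
        for g, sign, shift, norm in zip(planted, signs, lfc, normalized):
            r = 0.1 if norm else 0.6
            values[g, e2_cols] += sign * shift
            values[g, ici_cols] += r * sign * shift
            gene = gene_ids[g]
            fold = float(2.0**shift)
            if sign > 0:
                truth.planted_up[gene] = fold
            else:
                truth.planted_down[gene] = fold
            truth.rescue[gene] = "normalized" if norm else "partial"
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        classes=classes,
        values=values,
        meta={"synthetic": True, "seed": seed, "sigma": sigma},
    )
    return matrix, truth


def gen_spot_tables(
    matrix: ExpressionMatrix,
    seed: int = 0,
    bias: float = 0.15,
    missing_rate: float = 0.02,
    background: float = 64.0,
) -> dict[str, pd.DataFrame]:
    """Spot-level GenePix-style tables realizing an expression matrix.

    For each spot the mean log2 intensity A is drawn Uniform(7, 14); the two
    channel nets are 2**(A -/+ M/2) with M the matrix entry plus the planted
    intensity-dependent dye bias ``bias * (A - 10.5)`` that the LOWESS stage
    is expected to remove.  A ``missing_rate`` fraction of spots is flagged
    bad.
    """
    rng = np.random.default_rng(seed)
    tables = {}
    n_genes = matrix.n_genes
    for j, sample in enumerate(matrix.sample_ids):
        a = rng.uniform(7.0, 14.0, size=n_genes)
        m_true = np.nan_to_num(matrix.values[:, j], nan=0.0)
        m_obs = m_true + bias * (a - 10.5)
        net5 = np.power(2.0, a + m_obs / 2)
        net3 = np.power(2.0, a - m_obs / 2)
        flags = np.where(rng.random(n_genes) < missing_rate, -50, 0).astype(int)
        flags = np.where(flags == 0, 100, flags)
        tables[sample] = pd.DataFrame(
            {
                "ID": [f"spot{g:05d}" for g in range(n_genes)],
                "Name": matrix.gene_ids,
                "F635 Median": net5 + background,
                "B635 Median": np.full(n_genes, background),
                "F532 Median": net3 + background,
                "B532 Median": np.full(n_genes, background),
                "Flags": flags,
            }
        )
    return tables


# ---------------------------------------------------------------------------
# genome

def _concrete_motif(pattern: str, rng) -> str:
    return "".join(
        c if c in "ACGT" else rng.choice(list(IUPAC_CHOICES[c.upper()]))
        for c in pattern.upper()
    )


def gen_genome_and_loci(
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    n_genes: int = 400,
    gc: float = 0.5,
    gene_length: int = 600,
    motif: str = "GGTCANNNTGACC",
    motif_genes: list[str] | None = None,
    planted_motifs_per_flank: float = 0.0,
    n_background_motifs: int = 0,
    flank: int = 2000,
    gene_prefix: str = "hs",
    seed: int = 0,
    truth: SynthTruth | None = None,
) -> tuple[dict[str, str], list[GeneLocus], SynthTruth]:
    """Random genome with non-overlapping gene loci and planted motifs.

    Bases are i.i.d. with the given GC fraction.  Genes are laid out on an
    even grid of slots with random jitter; generation fails when the slots
    cannot hold a gene plus its flanks.  ``n_background_motifs`` concrete
    motif instances are planted uniformly genome-wide; designated
    ``motif_genes`` additionally receive Poisson(``planted_motifs_per_flank``)
    instances in each flank.  All planted positions are recorded in the
    truth (uniform plants under key ``"genome"``).
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    truth = truth or SynthTruth(seed=seed)
    bases = np.array(list("ATGC"))  # A/T share 1-gc, G/C share gc
    base_p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])

    per_chrom = [n_genes // n_chrom + (1 if c < n_genes % n_chrom else 0)
                 for c in range(n_chrom)]
    genome: dict[str, str] = {}
    loci: list[GeneLocus] = []
    gene_counter = 0
    motif_len = len(motif)
    for c, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{c+1}"
        seq = rng.choice(bases, size=chrom_len, p=base_p)
        if n_on_chrom:
            slot = chrom_len // n_on_chrom
            if slot < gene_length + 2 * motif_len + 2:
                raise ValueError(
                    f"infeasible packing: slot {slot} bp cannot hold a "
                    f"{gene_length} bp gene"
                )
            for s in range(n_on_chrom):
                jitter_max = slot - gene_length
                start = s * slot + int(rng.integers(0, jitter_max))
                strand = "+" if rng.random() < 0.5 else "-"
                loci.append(
                    GeneLocus(
                        gene_id=f"{gene_prefix}{gene_counter:05d}",
                        chrom=chrom,
                        start=start,
                        end=start + gene_length,
                        strand=strand,
                    )
                )
                gene_counter += 1
        genome[chrom] = seq

    planted: dict[str, list] = {}

    def plant(chrom: str, pos: int, key: str) -> None:
        instance = _concrete_motif(motif, rng)
        genome[chrom][pos:pos + motif_len] = list(instance)
        planted.setdefault(key, []).append([chrom, int(pos)])

    for _ in range(n_background_motifs):
        chrom = f"chr{int(rng.integers(0, n_chrom)) + 1}"
        pos = int(rng.integers(0, chrom_len - motif_len))
        plant(chrom, pos, "genome")

    designated = set(motif_genes or [])
    if planted_motifs_per_flank > 0 and designated:
        by_id = {locus.gene_id: locus for locus in loci}
        for gene in sorted(designated):
            locus = by_id[gene]
            limit = chrom_len
            flanks = [
                (max(0, locus.start - flank), locus.start),
                (locus.end, min(limit, locus.end + flank)),
            ]
            for lo, hi in flanks:
                n_inst = rng.poisson(planted_motifs_per_flank)
                for _ in range(n_inst):
                    if hi - lo <= motif_len:
                        continue
                    pos = int(rng.integers(lo, hi - motif_len))
                    plant(locus.chrom, pos, gene)

    genome = {c: "".join(s) for c, s in genome.items()}
    truth.planted_motif_positions.update(planted)
    return genome, loci, truth


# ---------------------------------------------------------------------------
# regulome + sets

def gen_regulome_and_sets(
    loci: list[GeneLocus],
    chrom_lengths: dict[str, int],
    zebrafish_genes: list[str],
    responsive_genes: list[str],
    n_sites: int = 500,
    site_length: int = 200,
    enrich_factor: float = 1.0,
    n_target_genes: int = 50,
    window: int = 10_000,
    homolog_rate: float = 0.435,
    many_to_one_rate: float = 0.1,
    n_cell_lines: int = 4,
    cell_line_size: int = 300,
    overlap_fraction: float = 0.29,
    seed: int = 0,
    truth: SynthTruth | None = None,
) -> tuple[list[BindingSite], HomologyMap, dict[str, list[str]], SynthTruth]:
    """Binding sites, homology map and cell-line lists with planted structure.

    * The homology map sends each zebrafish gene to a human gene id with
      probability ``homolog_rate``; a ``many_to_one_rate`` fraction of the
      mapped genes reuses an already-assigned human id.  Human ids are the
      ``loci`` gene ids, so mapped genes have genomic coordinates.
    * Binding sites are uniform over the genome except for an
      ``enrich_factor`` x density inside the windows of ``n_target_genes``
      designated target loci (drawn from the human homologs of the
      responsive genes when possible).
    * Each of ``n_cell_lines`` gene lists contains every human homolog of a
      responsive zebrafish gene independently with probability such that the
      union hits ``overlap_fraction`` of them in expectation, padded with
      uniform non-responsive universe genes up to ``cell_line_size``.
    """
    if enrich_factor < 1:
        raise ValueError("enrich_factor must be >= 1")
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = truth or SynthTruth(seed=seed)

    human_ids = [locus.gene_id for locus in loci]
    # homology: mapped zebrafish genes consume human ids in a shuffled order
    pairs: dict[str, str] = {}
    shuffled = list(human_ids)
    rng.shuffle(shuffled)
    next_free = 0
    for gene in zebrafish_genes:
        if rng.random() >= homolog_rate:
            continue
        if pairs and rng.random() < many_to_one_rate:
            pairs[gene] = pairs[sorted(pairs)[int(rng.integers(0, len(pairs)))]]
        elif next_free < len(shuffled):
            pairs[gene] = shuffled[next_free]
            next_free += 1
    homology = HomologyMap(pairs=pairs, provenance=f"synthetic(seed={seed})")

    mapped_responsive = sorted({pairs[g] for g in responsive_genes if g in pairs})

    # designated site-enriched target genes
    pool = mapped_responsive if len(mapped_responsive) >= n_target_genes else human_ids
    targets = sorted(
        rng.choice(pool, size=min(n_target_genes, len(pool)), replace=False)
    )
    by_id = {locus.gene_id: locus for locus in loci}
    target_windows = []
    for gene in targets:
        locus = by_id[gene]
        lo = max(0, locus.start - window)
        hi = min(chrom_lengths[locus.chrom], locus.end + window)
        target_windows.append((locus.chrom, lo, hi))
    from .regulome import _merge_intervals

    merged = _merge_intervals(target_windows) if target_windows else {}
    w_target = sum(e - s for iv in merged.values() for s, e in iv)
    genome_size = sum(chrom_lengths.values())
    w_rest = genome_size - w_target
    p_target = (enrich_factor * w_target) / (enrich_factor * w_target + w_rest)

    chroms = sorted(chrom_lengths)
    chrom_w = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    sites: list[BindingSite] = []
    flat_target = [(c, s, e) for c, iv in merged.items() for s, e in iv]
    t_widths = np.array([e - s for _, s, e in flat_target], dtype=float)
    for _ in range(n_sites):
        if flat_target and rng.random() < p_target:
            i = rng.choice(len(flat_target), p=t_widths / t_widths.sum())
            chrom, lo, hi = flat_target[i]
            start = int(rng.integers(lo, max(lo + 1, hi - site_length)))
        else:
            ci = rng.choice(len(chroms), p=chrom_w / chrom_w.sum())
            chrom = chroms[ci]
            start = int(rng.integers(0, chrom_lengths[chrom] - site_length))
        sites.append(BindingSite(chrom=chrom, start=start, end=start + site_length,
                                 source="synthetic"))
    sites.sort(key=lambda s: (s.chrom, s.start))

    # cell-line lists: P(in at least one of L lists) = overlap_fraction
    if n_cell_lines and overlap_fraction > 0:
        p_each = 1.0 - (1.0 - overlap_fraction) ** (1.0 / n_cell_lines)
    else:
        p_each = 0.0
    non_responsive = sorted(set(human_ids) - set(mapped_responsive))
    cell_lines: dict[str, list[str]] = {}
    for li in range(n_cell_lines):
        members = [g for g in mapped_responsive if rng.random() < p_each]
        n_pad = max(0, cell_line_size - len(members))
        if n_pad and non_responsive:
            pad = rng.choice(non_responsive, size=min(n_pad, len(non_responsive)),
                             replace=False)
            members.extend(pad.tolist())
        cell_lines[f"cellline_{li+1}"] = sorted(members)

    in_any = set().union(*map(set, cell_lines.values())) if cell_lines else set()
    truth.homology_pairs = dict(pairs)
    truth.cell_lines = {k: list(v) for k, v in cell_lines.items()}
    truth.human_universe = sorted(set(human_ids))
    truth.planted_enriched_site_genes = list(targets)
    truth.conserved_truth = sorted(set(mapped_responsive) & in_any)
    return sites, homology, cell_lines, truth


# ---------------------------------------------------------------------------
# writers for the pipeline's external formats

def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed_loci(loci: list[GeneLocus], path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(f"{locus.chrom}\t{locus.start}\t{locus.end}\t"
                     f"{locus.gene_id}\t0\t{locus.strand}\n")


def write_bed_sites(sites: list[BindingSite], path) -> None:
    with open(path, "w") as fh:
        for site in sites:
            fh.write(f"{site.chrom}\t{site.start}\t{site.end}\t{site.source}\n")
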