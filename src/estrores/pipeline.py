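"""End-to-end orchestration: spots -> SAM -> rescue -> homology -> regulome.

A single :class:`RunConfig` names every threshold of the analysis (SAM
q-value cutoffs, minimum fold change, rescue tolerance, flank and window
sizes, permutation and randomization counts) and either points at input
files or carries parameters for the synthetic generator.  ``run_pipeline``
executes the stages in order, writes per-stage TSV/JSON artifacts to the
output directory, and returns a structured report whose numbers are all
recomputable from those artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .arrayio import build_matrix, lowess_normalize, read_spot_table
from .enrich import AnnotationTable, fisher_enrichment
from .homology import map_to_human, overlap_test, venn_counts
from .regulome import (
    assign_sites,
    extract_flanks,
    motif_enrichment,
    scan_motif,
    site_enrichment,
)
from .response import classify_response, responsive_frame
from .sam import SamModel
from . import synthdata

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("estrores")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs remain."""


def _default_synth() -> dict:
    # Default synthetic study: the array design (4 control / 3 E2 / 3 E2+ICI),
    # 2000 probes with 100 planted 2-128x responses at sigma = 0.5, a
    # 2 x 1 Mb genome, 500 binding sites at 3x density near 20 designated
    # targets, a 43.5% homolog rate and 4 cell-line lists hitting half of the
    # responsive homologs.  Flank/window are scaled to the 1 Mb chromosomes.
    return {
        "n_genes": 2000,
        "n_per_class": [4, 3, 3],
        "n_planted": 100,
        "sigma": 0.5,
        "rescue_fraction": 0.5,
        "n_chrom": 2,
        "chrom_len": 1_000_000,
        "n_human_genes": 800,
        "gene_length": 600,
        "gc": 0.4,
        "n_background_motifs": 300,
        "planted_motifs_per_flank": 0.0,
        "n_sites": 500,
        "site_length": 200,
        "enrich_factor": 3.0,
        "n_target_genes": 20,
        "homolog_rate": 0.435,
        "n_cell_lines": 4,
        "cell_line_size": 300,
        "overlap_fraction": 0.5,
        "flank": 2000,
        "window": 10_000,
    }


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds; YAML round-trippable.

    The analysis defaults mirror the study: 3-class then 2-class SAM at
    q < 0.08, 2-fold minimum response, 6-missing-value cap, 20 kb flanks,
    100 kb binding-site window, 1000 randomizations.
    """

    outdir: str = "estrores_run"
    seed: int = 0
    # inputs (file mode); when spot_tables is empty the synthetic generator
    # defined by `synth` supplies everything
    spot_tables: dict[str, str] = field(default_factory=dict)  # sample -> path
    sample_classes: dict[str, str] = field(default_factory=dict)
    genome_fasta: str | None = None
    loci_bed: str | None = None
    sites_bed: str | None = None
    homology_tsv: str | None = None
    cell_line_lists: dict[str, str] = field(default_factory=dict)
    annotations_gmt: str | None = None
    # thresholds
    q_sam_3class: float = 0.08
    q_sam_2class: float = 0.08
    min_fold: float = 2.0
    tau: float = 0.25
    max_missing: int = 6
    span: float = 0.3
    flank: int = 20_000
    window: int = 100_000
    n_perm: int = 100
    n_rand: int = 1000
    motif: str = "GGTCANNNTGACC"
    synth: dict = field(default_factory=_default_synth)

    def __post_init__(self):
        if not 0 <= self.q_sam_3class <= 1 or not 0 <= self.q_sam_2class <= 1:
            raise ValueError("q thresholds must lie in [0, 1]")
        if self.min_fold < 1 or not 0 <= self.tau <= 1:
            raise ValueError("min_fold must be >= 1 and tau in [0, 1]")
        if min(self.flank, self.window, self.n_perm, self.n_rand) <= 0:
            raise ValueError("flank/window/n_perm/n_rand must be positive")
        synth = _default_synth()
        synth.update(self.synth or {})
        self.synth = synth

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def synthetic(self) -> bool:
        return not self.spot_tables


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    if not log.handlers:
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    config.to_yaml(outdir / "config.yaml")
    seed = int(config.seed) % (2**31)

    report: dict = {"seed": seed, "version": __version__,
                    "synthetic": config.synthetic}

    # ------------------------------------------------------------- inputs
    if config.synthetic:
        synth = config.synth
        matrix_true, truth = synthdata.gen_expression(
            n_genes=synth["n_genes"],
            n_per_class=tuple(synth["n_per_class"]),
            n_planted=synth["n_planted"],
            sigma=synth["sigma"],
            rescue_fraction=synth["rescue_fraction"],
            seed=seed,
        )
        tables = synthdata.gen_spot_tables(matrix_true, seed=seed + 1)
        spot_dir = outdir / "spots"
        spot_dir.mkdir(exist_ok=True)
        spot_paths = {}
        for sample, frame in tables.items():
            path = spot_dir / f"{sample}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            spot_paths[sample] = str(path)
        sample_classes = dict(zip(matrix_true.sample_ids, matrix_true.classes))
        genome, loci, truth = synthdata.gen_genome_and_loci(
            n_chrom=synth["n_chrom"],
            chrom_len=synth["chrom_len"],
            n_genes=synth["n_human_genes"],
            gc=synth["gc"],
            gene_length=synth["gene_length"],
            motif=config.motif,
            planted_motifs_per_flank=synth["planted_motifs_per_flank"],
            n_background_motifs=synth["n_background_motifs"],
            flank=synth["flank"],
            seed=seed + 2,
            truth=truth,
        )
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        sites, homology, cell_lines, truth = synthdata.gen_regulome_and_sets(
            loci=loci,
            chrom_lengths=chrom_lengths,
            zebrafish_genes=matrix_true.gene_ids,
            responsive_genes=sorted(truth.planted_ids()),
            n_sites=synth["n_sites"],
            site_length=synth["site_length"],
            enrich_factor=synth["enrich_factor"],
            n_target_genes=synth["n_target_genes"],
            window=synth["window"],
            homolog_rate=synth["homolog_rate"],
            n_cell_lines=synth["n_cell_lines"],
            cell_line_size=synth["cell_line_size"],
            overlap_fraction=synth["overlap_fraction"],
            seed=seed + 3,
            truth=truth,
        )
        synthdata.write_fasta(genome, outdir / "genome.fa")
        synthdata.write_bed_loci(loci, outdir / "loci.bed")
        synthdata.write_bed_sites(sites, outdir / "sites.bed")
        homology.to_tsv(outdir / "homology.tsv")
        for name, members in cell_lines.items():
            (outdir / f"{name}.txt").write_text("\n".join(members) + "\n")
        truth.to_json(outdir / "truth.json")
        flank, window = synth["flank"], synth["window"]
        annotations = _synthetic_annotations(truth, seed + 4)
    else:
        from .regulome import read_loci_bed, read_sites_bed
        from .homology import HomologyMap

        spot_paths = dict(config.spot_tables)
        sample_classes = dict(config.sample_classes)
        genome = config.genome_fasta
        loci = read_loci_bed(config.loci_bed) if config.loci_bed else []
        sites = read_sites_bed(config.sites_bed) if config.sites_bed else []
        homology = (HomologyMap.from_tsv(config.homology_tsv)
                    if config.homology_tsv else None)
        cell_lines = {
            name: [ln.strip() for ln in Path(p).read_text().splitlines()
                   if ln.strip()]
            for name, p in config.cell_line_lists.items()
        }
        truth = None
        flank, window = config.flank, config.window
        annotations = (AnnotationTable.from_gmt(config.annotations_gmt)
                       if config.annotations_gmt else None)
        chrom_lengths = None

    # ------------------------------------------------------------ arrayio
    @_stage("arrayio")
    def stage_arrayio():
        arrays, samples = [], []
        probe_ids = gene_ids = None
        for sample in sorted(spot_paths):
            spots = read_spot_table(spot_paths[sample])
            if probe_ids is None:
                probe_ids = spots.data["spot_id"].tolist()
                gene_ids = spots.data["gene_id"].tolist()
            arrays.append(lowess_normalize(spots, span=config.span))
            samples.append(sample)
        # probes are identified by gene annotation when unique, else spot id
        names = [g or p for g, p in zip(gene_ids, probe_ids)]
        matrix = build_matrix(
            arrays, samples, [sample_classes[s] for s in samples],
            probe_ids=names, max_missing=config.max_missing,
        )
        matrix.write_tsv(outdir / "matrix.tsv")
        return matrix

    matrix = stage_arrayio()
    report["n_total"] = matrix.n_genes

    # ------------------------------------------------------- SAM 3-class
    @_stage("sam_3class")
    def stage_sam3():
        res = SamModel(matrix, design="multiclass").fit(
            n_perm=config.n_perm, seed=seed + 10
        )
        res.write_tsv(outdir / "sam_3class.tsv")
        res.delta_table.to_csv(outdir / "sam_3class_delta.tsv", sep="\t",
                               index=False)
        return res

    sam3 = stage_sam3()
    up3, down3 = sam3.select_significant(config.q_sam_3class)
    prefilter = sorted(up3 | down3)
    report["n_prefilter"] = len(prefilter)
    report["sam_3class"] = {"s0": sam3.s0, "pi0": sam3.pi0,
                            "n_permutations": sam3.n_permutations}

    # ------------------------------------------------------- SAM 2-class
    @_stage("sam_2class")
    def stage_sam2():
        sub = matrix.subset_genes(prefilter)
        res = SamModel(sub, design="twoclass", class_pair=("E2", "control")).fit(
            n_perm=config.n_perm, seed=seed + 11
        )
        res.write_tsv(outdir / "sam_2class.tsv")
        return res

    if not prefilter:
        raise PipelineError("stage 'sam_2class' failed: empty prefilter set")
    sam2 = stage_sam2()
    up2, down2 = sam2.select_significant(config.q_sam_2class)

    # --------------------------------------------------------- response
    @_stage("response")
    def stage_response():
        kept, skipped = classify_response(
            matrix, up2, down2, min_fold=config.min_fold, tau=config.tau
        )
        responsive_frame(kept).to_csv(outdir / "responsive.tsv", sep="\t",
                                      index=False)
        return kept, skipped

    responsive, skipped = stage_response()
    up_ids = sorted(g.gene_id for g in responsive if g.direction == "up")
    down_ids = sorted(g.gene_id for g in responsive if g.direction == "down")
    report["n_responsive"] = len(responsive)
    report["n_up"] = len(up_ids)
    report["n_down"] = len(down_ids)
    report["n_rescue_normalized"] = sum(
        1 for g in responsive if g.rescue == "normalized")
    report["n_rescue_partial"] = sum(
        1 for g in responsive if g.rescue == "partial")
    report["n_candidates_skipped"] = len(skipped)

    # --------------------------------------------------------- homology
    conserved: list[str] = []
    mapped: set[str] = set()
    if homology is not None:
        @_stage("homology")
        def stage_homology():
            human, rate, unmapped = map_to_human(up_ids + down_ids, homology)
            universe = set(locus.gene_id for locus in loci) or homology.targets()
            overlaps = {}
            for name in sorted(cell_lines):
                members = set(cell_lines[name]) & universe
                overlaps[name] = overlap_test(
                    human, members, universe, labels=("zebrafish_homologs", name)
                ).as_dict()
            union = set()
            for members in cell_lines.values():
                union |= set(members)
            union &= universe
            pooled = overlap_test(human, union, universe,
                                  labels=("zebrafish_homologs", "any_cell_line"))
            cons = sorted(human & union)
            venn = None
            if 2 <= len(cell_lines) <= 4:
                venn = {
                    "+".join(k): v
                    for k, v in venn_counts(
                        {n: set(m) for n, m in cell_lines.items()}
                    ).items()
                }
            (outdir / "conserved.txt").write_text("\n".join(cons) + "\n")
            with open(outdir / "overlaps.json", "w") as fh:
                json.dump({"per_cell_line": overlaps,
                           "pooled": pooled.as_dict(), "venn": venn}, fh,
                          indent=1, sort_keys=True)
            return human, rate, overlaps, pooled, cons, venn

        human, rate, overlaps, pooled, conserved, venn = stage_homology()
        mapped = human
        report["n_mapped"] = len(human)
        report["mapping_rate"] = rate
        report["overlaps"] = overlaps
        report["pooled_overlap"] = pooled.as_dict()
        report["n_conserved"] = len(conserved)
        report["venn"] = venn

    # --------------------------------------------------------- regulome
    if genome is not None and loci and conserved:
        @_stage("regulome")
        def stage_regulome():
            hits = scan_motif(genome, config.motif)
            by_id = {locus.gene_id: locus for locus in loci}
            cons_loci = [by_id[g] for g in conserved if g in by_id]
            noncons = [locus for locus in loci
                       if locus.gene_id not in set(conserved)]
            lengths = chrom_lengths
            if lengths is None:
                if isinstance(genome, dict):
                    lengths = {c: len(s) for c, s in genome.items()}
                else:
                    from pyfaidx import Fasta

                    fasta = Fasta(str(genome))
                    lengths = {name: len(fasta[name]) for name in fasta.keys()}
            flanks = extract_flanks(cons_loci, flank=flank,
                                    chrom_lengths=lengths)
            regions = [iv[:3] for parts in flanks.values() for iv in parts]
            genome_size = sum(lengths.values())
            motif_res = motif_enrichment(hits, regions, genome_size)
            counts_cons = assign_sites(cons_loci, sites, window=window)
            counts_non = assign_sites(noncons, sites, window=window)
            site_res = site_enrichment(
                [locus.gene_id for locus in cons_loci],
                background_loci=loci, sites=sites, window=window,
                n_rand=config.n_rand, seed=seed + 20,
            )
            from .regulome import write_hits_bed, truncate2

            write_hits_bed(hits, outdir / "motif_hits.bed", len(config.motif))
            with open(outdir / "regulome.json", "w") as fh:
                json.dump({"motif": motif_res.as_dict(),
                           "sites": site_res.as_dict()}, fh, indent=1,
                          sort_keys=True)
            return hits, motif_res, counts_cons, counts_non, site_res

        hits, motif_res, counts_cons, counts_non, site_res = stage_regulome()
        from .regulome import truncate2

        n_with_sites = sum(1 for v in counts_cons.values() if v > 0)
        total_cons = sum(counts_cons.values())
        total_non = sum(counts_non.values())
        report["n_motif_hits"] = len(hits)
        report["motif_enrichment"] = motif_res.as_dict()
        report["n_conserved_with_sites"] = n_with_sites
        report["sites_conserved_total"] = total_cons
        report["sites_nonconserved_total"] = total_non
        report["sites_per_gene_conserved"] = (
            float(truncate2(total_cons / len(counts_cons))) if counts_cons else None
        )
        report["sites_per_gene_nonconserved"] = (
            float(truncate2(total_non / len(counts_non))) if counts_non else None
        )
        report["site_enrichment"] = site_res.as_dict()

    # ----------------------------------------------------------- enrich
    if annotations is not None and conserved:
        @_stage("enrich")
        def stage_enrich():
            universe = set(locus.gene_id for locus in loci)
            frame = fisher_enrichment(set(conserved) & universe, annotations,
                                      universe)
            frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            return frame

        enr = stage_enrich()
        report["n_enriched_categories_p05"] = int((enr["p"] < 0.05).sum())
        report["top_category"] = (enr.iloc[0]["category_id"]
                                  if len(enr) else None)

    # ----------------------------------------------- truth-based scoring
    if truth is not None:
        planted = truth.planted_ids()
        detected = set(up_ids) | set(down_ids)
        report["truth"] = {
            "n_planted": len(planted),
            "responsive_recall": (len(detected & planted) / len(planted)
                                  if planted else None),
            "responsive_false": len(detected - planted),
            "n_conserved_truth": len(truth.conserved_truth),
            "conserved_recall": (
                len(set(conserved) & set(truth.conserved_truth))
                / len(truth.conserved_truth)
                if truth.conserved_truth else None
            ),
        }

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("report written to %s", report_path)
    return report


def _synthetic_annotations(truth, seed: int) -> AnnotationTable:
    """Annotation table for the synthetic study: a handful of random
    categories plus one holding the homologs of planted responsive genes."""
    rng = np.random.default_rng(seed)
    universe = list(truth.human_universe)
    cats = {}
    for i in range(5):
        size = int(rng.integers(30, 80))
        cats[f"random_{i+1}"] = set(
            rng.choice(universe, size=min(size, len(universe)), replace=False)
        )
    planted_h = {
        truth.homology_pairs[g]
        for g in truth.planted_ids()
        if g in truth.homology_pairs
    }
    cats["planted_response_homologs"] = planted_h
    return AnnotationTable(categories=cats)
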