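"""Cross-species homolog mapping and gene-set intersection statistics.

Zebrafish gene identifiers are translated to human identifiers through a
two-column homology table (HomoloGene-style).  Intersections between the
mapped set and human cell-line estrogen-responsive gene lists are scored
with one-sided binomial and hypergeometric enrichment tails against a
declared background universe (e.g. all human homologs represented on the
array).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HomologyMap", "OverlapResult", "map_to_human", "overlap_test", "venn_counts"]


@dataclass
class HomologyMap:
    """Source -> target identifier map collapsed to one target per source."""

    pairs: dict[str, str]
    provenance: str = ""

    @classmethod
    def from_tsv(cls, path, provenance: str | None = None) -> "HomologyMap":
        """Load a two-column TSV (source, target); later rows win on duplicates."""
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", header=None, names=["source", "target"],
                            dtype=str, comment="#")
        pairs = dict(zip(frame["source"], frame["target"]))
        return cls(pairs=pairs, provenance=provenance or str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.pairs.items())).to_csv(
            path, sep="\t", header=False, index=False
        )

    def targets(self) -> set[str]:
        return set(self.pairs.values())

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class OverlapResult:
    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap_k: int
    percent_overlap: float       # k / |a|
    p_binomial: float
    p_hypergeometric: float
    saturated: bool = False
    labels: tuple[str, str] = ("A", "B")

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "set_a_size": self.set_a_size,
            "set_b_size": self.set_b_size,
            "universe_size": self.universe_size,
            "overlap_k": self.overlap_k,
            "percent_overlap": self.percent_overlap,
            "p_binomial": self.p_binomial,
            "p_hypergeometric": self.p_hypergeometric,
            "saturated": self.saturated,
        }


def map_to_human(gene_ids, homology: HomologyMap):
    """Translate a gene-id set through the homology map.

    Returns (human_ids, mapping_rate, unmapped).  The human set collapses
    many-to-one mappings to unique target ids; the mapping rate is the
    fraction of distinct inputs with a homolog (0, flagged via the empty
    unmapped/human sets, when the input is empty).
    """
    inputs = sorted(set(gene_ids))
    mapped = [g for g in inputs if g in homology.pairs]
    unmapped = [g for g in inputs if g not in homology.pairs]
    human = {homology.pairs[g] for g in mapped}
    rate = len(mapped) / len(inputs) if inputs else 0.0
    return human, rate, unmapped


def overlap_test(a, b, universe, labels: tuple[str, str] = ("A", "B")) -> OverlapResult:
    """One-sided enrichment of the intersection of two sets in a universe.

    ``p_binomial`` treats each member of ``a`` as hitting ``b`` independently
    with probability |b|/N; ``p_hypergeometric`` is the exact tail of the
    2x2 table.  ``percent_overlap`` uses |a| (the first-listed set) as the
    denominator.
    """
    a, b, universe = set(a), set(b), set(universe)
    if not universe:
        raise ValueError("empty universe")
    offenders = sorted((a | b) - universe)
    if offenders:
        raise ValueError(f"sets not contained in universe: {offenders[:10]}")
    n = len(universe)
    k = len(a & b)
    p_bin = float(stats.binom.sf(k - 1, len(a), len(b) / n)) if a else 1.0
    p_hyp = float(stats.hypergeom.sf(k - 1, n, len(b), len(a))) if a else 1.0
    return OverlapResult(
        set_a_size=len(a),
        set_b_size=len(b),
        universe_size=n,
        overlap_k=k,
        percent_overlap=k / len(a) if a else 0.0,
        p_binomial=min(1.0, p_bin),
        p_hypergeometric=min(1.0, p_hyp),
        saturated=(a == b == universe),
        labels=labels,
    )


def venn_counts(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for every nonempty-membership region of 2-4 labelled sets.

    Keys are the sorted tuples of labels whose exclusive intersection the
    count describes; region counts sum to the size of the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    labels = list(sets)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels")
    if len(labels) > 4:
        raise ValueError("at most 4 sets supported")
    regions: dict[tuple[str, ...], int] = {}
    union = set().union(*sets.values())
    membership: dict[str, tuple[str, ...]] = {}
    for item in union:
        key = tuple(sorted(lab for lab in labels if item in sets[lab]))
        membership[item] = key
    from itertools import combinations

    for r in range(1, len(labels) + 1):
        for combo in combinations(sorted(labels), r):
            regions[combo] = 0
    for key in membership.values():
        regions[tuple(sorted(key))] += 1
    return regions
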