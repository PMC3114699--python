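"""Right-tailed Fisher's exact gene-set enrichment over user annotations.

Generic replacement for knowledge-base category enrichment: given a query
gene set, an annotation table (category -> member ids) and a background
universe, each category is scored with the upper hypergeometric tail of its
2x2 table (identical to a right-tailed Fisher's exact test), optionally
Benjamini-Hochberg adjusted across categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AnnotationTable", "fisher_enrichment"]


@dataclass
class AnnotationTable:
    """category_id -> member gene-id set, with optional display labels."""

    categories: dict[str, set]
    labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_gmt(cls, path) -> "AnnotationTable":
        """Read GMT: one category per line, tab-separated: id, label, members..."""
        categories: dict[str, set] = {}
        labels: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            categories[parts[0]] = set(parts[2:])
            labels[parts[0]] = parts[1]
        return cls(categories=categories, labels=labels)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        """Read two-column TSV of (category_id, member_id) pairs."""
        frame = pd.read_csv(path, sep="\t", header=None,
                            names=["category", "member"], dtype=str, comment="#")
        categories: dict[str, set] = {}
        for cat, member in zip(frame["category"], frame["member"]):
            categories.setdefault(cat, set()).add(member)
        return cls(categories=categories)


def fisher_enrichment(
    geneset,
    annotations: AnnotationTable,
    universe,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Score every annotation category against the query set.

    Parameters
    ----------
    geneset : iterable of gene ids, must lie within ``universe``.
    annotations : AnnotationTable
        Category members are intersected with the universe before testing;
        categories with no member in the universe are skipped with a warning.
    universe : background gene-id set.
    adjust : {"BH", "none"}
        Multiple-testing adjustment across the tested categories.

    Returns
    -------
    DataFrame sorted by p with columns category_id, label, k_in_set,
    set_size, k_in_universe, universe_size, p, p_adjusted.
    """
    geneset, universe = set(geneset), set(universe)
    stray = geneset - universe
    if stray:
        raise ValueError(f"geneset not contained in universe: {sorted(stray)[:10]}")
    if adjust not in ("BH", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    rows = []
    for cat, members in annotations.categories.items():
        in_universe = members & universe
        if not in_universe:
            warnings.warn(f"category {cat!r} has no members in universe; skipped",
                          stacklevel=2)
            continue
        k = len(geneset & in_universe)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_universe),
                                     len(geneset)))
        rows.append(
            {
                "category_id": cat,
                "label": annotations.labels.get(cat, cat),
                "k_in_set": k,
                "set_size": len(geneset),
                "k_in_universe": len(in_universe),
                "universe_size": len(universe),
                "p": min(1.0, p),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["category_id", "label", "k_in_set", "set_size",
                 "k_in_universe", "universe_size", "p"],
    )
    if frame.empty:
        frame["p_adjusted"] = []
        return frame
    if adjust == "BH":
        frame["p_adjusted"] = multipletests(frame["p"], method="fdr_bh")[1]
    else:
        frame["p_adjusted"] = frame["p"]
    return frame.sort_values(["p", "category_id"], kind="stable").reset_index(drop=True)
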