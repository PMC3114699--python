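"""Anti-estrogen rescue classification of estrogen-responsive candidates.

A gene counts as estrogen-responsive when it is deregulated under E2 and the
deregulation is direction-consistently suppressed when the pure anti-estrogen
ICI 182,780 is co-administered (E2+ICI): an up-regulated gene must sit higher
in E2 than in both control and E2+ICI, a down-regulated gene lower.  The
suppression is further labelled ``normalized`` when the E2+ICI mean returns
close to the control mean (within a fraction ``tau`` of the E2 displacement)
and ``partial`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrayio import ExpressionMatrix

__all__ = ["ResponsiveGene", "classify_response", "responsive_frame"]


@dataclass(frozen=True)
class ResponsiveGene:
    gene_id: str
    direction: str            # "up" | "down"
    fold_change_e2: float     # linear magnitude, >= 1
    rescue: str               # "normalized" | "partial"
    mean_control: float
    mean_e2: float
    mean_e2_ici: float


def _class_means(matrix: ExpressionMatrix) -> dict[str, np.ndarray]:
    means = {}
    for label in ExpressionMatrix.VALID_CLASSES:
        cols = matrix.class_columns(label)
        if len(cols) == 0:
            raise ValueError(f"matrix lacks class {label!r}")
        with np.errstate(invalid="ignore"):
            means[label] = np.nanmean(matrix.values[:, cols], axis=1)
    return means


def classify_response(
    matrix: ExpressionMatrix,
    up_candidates,
    down_candidates,
    min_fold: float = 2.0,
    tau: float = 0.25,
):
    """Filter SAM candidates by the rescue criterion.

    Parameters
    ----------
    matrix : ExpressionMatrix with all three classes.
    up_candidates, down_candidates : iterables of gene ids
        Signed candidate sets from the two-class SAM stage.
    min_fold : float
        Minimum linear E2-vs-control fold-change magnitude (default 2).
    tau : float
        "Normalized" when |mean(E2+ICI) - mean(control)| is at most
        tau * |mean(E2) - mean(control)| (default 0.25).

    Returns
    -------
    (kept, skipped) : list of ResponsiveGene, list of gene ids absent from
    the matrix.
    """
    means = _class_means(matrix)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    min_lfc = np.log2(min_fold)
    kept: list[ResponsiveGene] = []
    skipped: list[str] = []
    for direction, candidates in (("up", up_candidates), ("down", down_candidates)):
        for gene in sorted(candidates):
            i = index.get(gene)
            if i is None:
                skipped.append(gene)
                continue
            mc = means["control"][i]
            me = means["E2"][i]
            mi = means["E2_ICI"][i]
            if not np.isfinite([mc, me, mi]).all():
                skipped.append(gene)
                continue
            displacement = me - mc
            if direction == "up":
                suppressed = me > mc and me > mi
            else:
                suppressed = me < mc and me < mi
            if not suppressed or abs(displacement) < min_lfc:
                continue
            rescue = (
                "normalized"
                if abs(mi - mc) <= tau * abs(displacement)
                else "partial"
            )
            kept.append(
                ResponsiveGene(
                    gene_id=gene,
                    direction=direction,
                    fold_change_e2=float(2.0 ** abs(displacement)),
                    rescue=rescue,
                    mean_control=float(mc),
                    mean_e2=float(me),
                    mean_e2_ici=float(mi),
                )
            )
    return kept, skipped


def responsive_frame(genes: list[ResponsiveGene]) -> pd.DataFrame:
    """Tabular view (one row per responsive gene) for TSV output."""
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "direction": g.direction,
                "mean_control": g.mean_control,
                "mean_E2": g.mean_e2,
                "mean_E2_ICI": g.mean_e2_ici,
                "fold_change_E2": g.fold_change_e2,
                "rescue": g.rescue,
            }
            for g in genes
        ],
        columns=[
            "gene_id", "direction", "mean_control", "mean_E2",
            "mean_E2_ICI", "fold_change_E2", "rescue",
        ],
    )
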