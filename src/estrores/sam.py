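"""Significance Analysis of Microarrays (SAM).

SAM tests each gene with a variance-shrunken statistic

    d_i = r_i / (s_i + s0)

where ``r_i`` is the class-mean contrast (two-class) or a between-class
spread (multiclass), ``s_i`` the gene-specific pooled standard error and
``s0`` a small "fudge" constant tuned so that the spread of ``d`` is roughly
independent of gene variance. Significance is calibrated by permuting class
labels: the sorted observed statistics are compared against the mean sorted
permuted statistics, a family of thresholds (deltas) defines called gene
sets, and the false discovery rate at each delta is the median number of
null genes exceeding the cuts, scaled by an estimate of the null proportion
pi0.  A gene's q-value is the smallest FDR at which it is called.

The module follows the statsmodels idiom: build a :class:`SamModel` from an
expression matrix, call :meth:`SamModel.fit`, and read estimates off the
returned :class:`SamResults`.  Thin functional wrappers (``compute_scores``,
``estimate_fdr``, ``select_significant``) expose the same steps.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrayio import ExpressionMatrix

__all__ = [
    "SamModel",
    "SamResults",
    "tune_s0",
    "compute_scores",
    "estimate_fdr",
    "select_significant",
]


def _class_moments(values: np.ndarray, cols: np.ndarray):
    """Per-gene count, mean and within-class sum of squares for one class.

    NaN entries are ignored; genes with fewer than 2 usable values in the
    class get NaN moments.
    """
    block = values[:, cols]
    ok = ~np.isnan(block)
    n = ok.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = np.where(ok, block, 0.0).sum(axis=1)
        mean = np.where(n >= 1, total / np.maximum(n, 1), np.nan)
        centered = np.where(ok, block - mean[:, None], 0.0)
        ss = (centered**2).sum(axis=1)
    bad = n < 2
    mean = np.where(n >= 1, mean, np.nan)
    ss = np.where(bad, np.nan, ss)
    return n, mean, ss


def _raw_stats(values: np.ndarray, labels: np.ndarray, class_names: list[str],
               signed: bool | None = None):
    """Numerator r_i and scatter s_i for a label assignment.

    With ``signed`` (the two-class design) the numerator is the contrast of
    the first-listed class minus the second; otherwise it is the
    nonnegative multiclass between-class spread, whose two-class
    specialization equals |r| with the same s_i.
    """
    if signed is None:
        signed = len(class_names) == 2
    moments = []
    for name in class_names:
        cols = np.flatnonzero(labels == name)
        moments.append(_class_moments(values, cols))
    ns = np.stack([m[0] for m in moments])        # (K, G)
    means = np.stack([m[1] for m in moments])
    sss = np.stack([m[2] for m in moments])
    with np.errstate(invalid="ignore", divide="ignore"):
        dof = (ns - 1).clip(min=0).sum(axis=0)
        pooled = sss.sum(axis=0) / dof
        inv_n = (1.0 / ns).sum(axis=0)
        s = np.sqrt(inv_n * pooled)
        if signed:
            if len(class_names) != 2:
                raise ValueError("signed contrast requires exactly two classes")
            r = means[0] - means[1]
        else:
            n_tot = ns.sum(axis=0)
            grand = (ns * means).sum(axis=0) / n_tot
            between = (ns * (means - grand) ** 2).sum(axis=0)
            fac = n_tot / ns.prod(axis=0)
            r = np.sqrt(fac * between)
    invalid = np.isnan(sss).any(axis=0) | (dof <= 0)
    r = np.where(invalid, np.nan, r)
    s = np.where(invalid, np.nan, s)
    return r, s


def tune_s0(scatters: np.ndarray, raw_stats: np.ndarray, n_windows: int = 100) -> float:
    """Tune the fudge factor s0.

    Candidates are the percentiles of the gene scatters ``s_i`` on the grid
    0, 5, ..., 100.  For each candidate the genes are split into up to
    ``n_windows`` quantile windows of ``s_i`` and the candidate minimizing
    the coefficient of variation of the within-window median absolute
    deviations of d = r/(s + s0) is chosen.
    """
    ok = np.isfinite(scatters) & np.isfinite(raw_stats)
    s = np.asarray(scatters, float)[ok]
    r = np.asarray(raw_stats, float)[ok]
    if len(s) == 0:
        return 0.0
    if np.ptp(s) == 0:
        warnings.warn("constant gene scatter; s0 set to 0", stacklevel=2)
        return 0.0
    order = np.argsort(s, kind="stable")
    s_sorted, r_sorted = s[order], r[order]
    n_win = max(2, min(n_windows, len(s) // 10))
    bounds = np.linspace(0, len(s), n_win + 1).astype(int)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = r_sorted / (s_sorted + s0)
        mads = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi - lo < 2:
                continue
            w = d[lo:hi]
            mads.append(np.median(np.abs(w - np.median(w))) / 0.64)
        mads = np.asarray(mads)
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std(ddof=1) / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _count_label_arrangements(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(counts.sum())
    for c in counts:
        total //= math.factorial(c)
    return total


def _all_arrangements(labels: np.ndarray) -> np.ndarray:
    """Every distinct arrangement of the label multiset, as an array."""
    seen = sorted(set(itertools.permutations(labels.tolist())))
    return np.array(seen, dtype=labels.dtype)


class SamModel:
    """SAM model bound to an expression matrix and a class design.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Normalized log2-ratio matrix with class labels.
    design : {"twoclass", "multiclass"}
    class_pair : tuple of str, optional
        For the two-class design, (treatment, reference); defaults to
        ("E2", "control").  The multiclass design uses every class present.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: str = "multiclass",
        class_pair: tuple[str, str] | None = None,
    ) -> None:
        if design not in ("twoclass", "multiclass"):
            raise ValueError(f"unknown design {design!r}")
        self.matrix = matrix
        self.design = design
        labels = np.asarray(matrix.classes)
        if design == "twoclass":
            self.class_names = list(class_pair or ("E2", "control"))
        else:
            # stable order: control first, then treatment classes as declared
            self.class_names = [c for c in ExpressionMatrix.VALID_CLASSES
                                if c in set(labels)]
        cols = np.flatnonzero(np.isin(labels, self.class_names))
        if any((labels == c).sum() < 2 for c in self.class_names):
            raise ValueError(
                "degenerate design: every involved class needs >= 2 samples"
            )
        self.columns = cols
        self.values = matrix.values[:, cols]
        self.labels = labels[cols]
        self.gene_ids = list(matrix.gene_ids)

    # ------------------------------------------------------------------
    def raw_statistics(self):
        return _raw_stats(self.values, self.labels, self.class_names,
                          signed=(self.design == "twoclass"))

    def log2_fold_change(self) -> np.ndarray:
        """Per-gene mean log2 contrast of treatment vs control.

        Uses the two-class pair when fitted as two-class; otherwise E2 minus
        control when both are present, else the last vs first class.
        """
        if self.design == "twoclass":
            treat, ref = self.class_names
        else:
            names = set(self.class_names)
            treat = "E2" if "E2" in names else self.class_names[-1]
            ref = "control" if "control" in names else self.class_names[0]
        _, m_t, _ = _class_moments(self.values, np.flatnonzero(self.labels == treat))
        _, m_r, _ = _class_moments(self.values, np.flatnonzero(self.labels == ref))
        return m_t - m_r

    def permutation_labels(self, n_perm: int, seed: int):
        """Label arrangements for the null: exhaustive when feasible.

        Returns (labels_matrix, exhaustive_flag); ``labels_matrix`` has one
        arrangement per row.
        """
        n_distinct = _count_label_arrangements(self.labels)
        if n_perm >= n_distinct:
            return _all_arrangements(self.labels), True
        rng = np.random.default_rng(seed)
        rows = [rng.permutation(self.labels) for _ in range(n_perm)]
        return np.array(rows), False

    # ------------------------------------------------------------------
    def fit(
        self,
        n_perm: int = 100,
        seed: int = 0,
        s0: float | None = None,
        n_delta: int = 60,
    ) -> "SamResults":
        """Estimate statistics, tune s0, and calibrate FDR by permutation.

        Parameters
        ----------
        n_perm : int
            Requested permutations (>= 25; capped at the number of distinct
            label arrangements, in which case they are enumerated).
        seed : int
            Seed for the permutation sampler and the tie-break shuffle.
        s0 : float, optional
            Fudge factor override; tuned from the data when None.
        n_delta : int
            Size of the delta grid for the FDR table.
        """
        if n_perm < 25:
            raise ValueError("n_perm must be >= 25")
        r, s = self.raw_statistics()
        if s0 is None:
            s0 = tune_s0(s, r)
        with np.errstate(invalid="ignore"):
            d = r / (s + s0)
        lfc = self.log2_fold_change()

        perm_labels, exhaustive = self.permutation_labels(n_perm, seed)
        d_perm = np.empty((len(perm_labels), len(d)))
        for p, lab in enumerate(perm_labels):
            rp, sp = _raw_stats(self.values, lab, self.class_names,
                                signed=(self.design == "twoclass"))
            with np.errstate(invalid="ignore"):
                d_perm[p] = rp / (sp + s0)

        res = _fdr_from_permutations(
            d=d, d_perm=d_perm, signed=(self.design == "twoclass"),
            n_delta=n_delta,
        )
        return SamResults(
            model=self,
            gene_ids=self.gene_ids,
            statistic=d,
            gene_scatter=s,
            s0=float(s0),
            log2_fold_change=lfc,
            fold_change=np.power(2.0, lfc),
            q_value=res["q_value"],
            delta_table=res["delta_table"],
            pi0=res["pi0"],
            n_permutations=len(perm_labels),
            exhaustive=exhaustive,
            seed=seed,
            design=self.design,
        )


def _fdr_from_permutations(d, d_perm, signed: bool, n_delta: int = 60) -> dict:
    """SAM delta-threshold FDR machinery shared by both designs.

    Returns the delta table (delta, cutlow, cutup, called, median_false,
    fdr), pi0 and per-gene q-values.  Genes with NaN statistics are ignored
    throughout and get q = NaN.
    """
    finite = np.isfinite(d)
    d_f = d[finite]
    n_genes = len(d_f)
    if n_genes == 0:
        raise ValueError("no gene has a finite statistic")
    perm_f = d_perm[:, finite]
    # expected order statistics of the null
    order = np.argsort(d_f, kind="stable")
    d_sorted = d_f[order]
    perm_sorted = np.sort(perm_f, axis=1)
    with warnings.catch_warnings():
        # ranks where every permutation is NaN yield NaN dbar, handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        dbar = np.nanmean(perm_sorted, axis=0)

    # pi0 from the central mass of the permuted statistics
    all_perm = perm_f[np.isfinite(perm_f)]
    q25, q75 = np.percentile(all_perm, [25, 75])
    in_iqr = np.count_nonzero((d_f > q25) & (d_f < q75))
    pi0 = min(1.0, in_iqr / (0.5 * n_genes))

    diff = d_sorted - dbar
    max_delta = float(np.nanmax(np.abs(diff))) if np.isfinite(diff).any() else 1.0
    deltas = np.linspace(0.0, max_delta, n_delta)

    rows = []
    q = np.full(n_genes, 1.0)
    for delta in deltas:
        up_idx = np.flatnonzero(diff >= delta)
        cutup = d_sorted[up_idx].min() if len(up_idx) else np.inf
        if signed:
            low_idx = np.flatnonzero(-diff >= delta)
            cutlow = d_sorted[low_idx].max() if len(low_idx) else -np.inf
        else:
            cutlow = -np.inf
        called_mask = (d_f >= cutup) | (signed & (d_f <= cutlow))
        called = int(called_mask.sum())
        # null counts per permutation (NaN comparisons are False, so genes
        # lacking a statistic under a permuted labelling never count)
        with np.errstate(invalid="ignore"):
            n_up = (perm_f >= cutup).sum(axis=1)
            n_low = (perm_f <= cutlow).sum(axis=1) if signed else 0
        median_false = pi0 * float(np.median(n_up + n_low))
        fdr = min(1.0, median_false / called) if called else 0.0
        rows.append((delta, cutlow, cutup, called, median_false, fdr))
        if called:
            q[called_mask] = np.minimum(q[called_mask], fdr)

    # enforce q monotone nonincreasing in statistic extremity
    extremity = np.abs(d_f) if signed else d_f
    rank = np.argsort(-extremity, kind="stable")
    q_desc = q[rank]
    q_desc = np.minimum.accumulate(q_desc[::-1])[::-1]
    q[rank] = q_desc

    q_full = np.full(len(d), np.nan)
    q_full[finite] = q
    table = pd.DataFrame(
        rows, columns=["delta", "cutlow", "cutup", "called", "median_false", "fdr"]
    )
    return {"q_value": q_full, "delta_table": table, "pi0": pi0}


@dataclass
class SamResults:
    """Fitted SAM estimates: statistics, fold changes, q-values, delta table."""

    model: SamModel
    gene_ids: list[str]
    statistic: np.ndarray
    gene_scatter: np.ndarray
    s0: float
    log2_fold_change: np.ndarray
    fold_change: np.ndarray
    q_value: np.ndarray
    delta_table: pd.DataFrame
    pi0: float
    n_permutations: int
    exhaustive: bool
    seed: int
    design: str
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "d": self.statistic,
                "s": self.gene_scatter,
                "fold_change": self.fold_change,
                "log2_fold_change": self.log2_fold_change,
                "q": self.q_value,
            }
        )

    def select_significant(self, q_threshold: float = 0.08):
        """Genes called at q below the threshold, split by direction.

        Returns (up_ids, down_ids) partitioned by the sign of the log2 fold
        change (equivalently, of d in the two-class design).  A threshold of
        1 keeps every gene with a finite statistic; a threshold of 0 keeps
        none.
        """
        finite = np.isfinite(self.statistic)
        if q_threshold >= 1.0:
            mask = finite
        else:
            with np.errstate(invalid="ignore"):
                mask = finite & (self.q_value < q_threshold)
        sign = self.log2_fold_change
        ids = np.asarray(self.gene_ids, dtype=object)
        up = set(ids[mask & (sign > 0)])
        down = set(ids[mask & (sign < 0)])
        return up, down

    def summary(self) -> str:
        up, down = self.select_significant()
        lines = [
            "SAM results",
            "=" * 46,
            f"design:          {self.design}",
            f"genes:           {len(self.gene_ids)}",
            f"permutations:    {self.n_permutations}"
            + (" (exhaustive)" if self.exhaustive else ""),
            f"s0:              {self.s0:.5g}",
            f"pi0:             {self.pi0:.3f}",
            f"called q<0.08:   {len(up)} up, {len(down)} down",
            "=" * 46,
        ]
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# functional wrappers

def compute_scores(
    matrix: ExpressionMatrix,
    design: str = "multiclass",
    class_pair: tuple[str, str] | None = None,
    s0: float | None = None,
):
    """Per-gene d, s, s0 and fold change without permutation calibration."""
    model = SamModel(matrix, design=design, class_pair=class_pair)
    r, s = model.raw_statistics()
    if s0 is None:
        s0 = tune_s0(s, r)
    with np.errstate(invalid="ignore"):
        d = r / (s + s0)
    lfc = model.log2_fold_change()
    return pd.DataFrame(
        {
            "gene_id": model.gene_ids,
            "d": d,
            "s": s,
            "fold_change": np.power(2.0, lfc),
            "log2_fold_change": lfc,
        }
    ).assign(s0=s0)


def estimate_fdr(
    matrix: ExpressionMatrix,
    design: str = "multiclass",
    class_pair: tuple[str, str] | None = None,
    n_perm: int = 100,
    seed: int = 0,
    s0: float | None = None,
) -> SamResults:
    """Fit the full SAM permutation machinery; see :meth:`SamModel.fit`."""
    return SamModel(matrix, design=design, class_pair=class_pair).fit(
        n_perm=n_perm, seed=seed, s0=s0
    )


def select_significant(results: SamResults, q_threshold: float = 0.08):
    return results.select_significant(q_threshold)
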