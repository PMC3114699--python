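"""Two-channel spot-level array ingestion, LOWESS normalization and matrix assembly.

A two-channel spotted array measures, per spot, foreground and local-background
intensities in the sample channel (Cy5) and the common-reference channel (Cy3).
This module turns GenePix-style spot tables into a per-array vector of
intensity-dependent-bias-corrected log2(sample/reference) ratios, and stacks
per-array vectors into a gene x sample expression matrix with a missingness
filter.

Coordinates of record: net intensity = foreground - background; a spot whose
net intensity is nonpositive in either channel, or whose quality flag is
nonpositive, carries no usable ratio and is missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "GENEPIX_DIALECT",
    "SpotTable",
    "ExpressionMatrix",
    "FormatError",
    "read_spot_table",
    "lowess_normalize",
    "build_matrix",
]

#: Default column-name map for GenePix .gpr-style tables.
GENEPIX_DIALECT: dict[str, str] = {
    "spot_id": "ID",
    "gene_id": "Name",
    "f_cy5": "F635 Median",
    "b_cy5": "B635 Median",
    "f_cy3": "F532 Median",
    "b_cy3": "B532 Median",
    "flag": "Flags",
}


class FormatError(ValueError):
    """Raised when a spot table does not match the declared column dialect."""


@dataclass
class SpotTable:
    """Spot-level two-channel measurements for one array.

    ``data`` has one row per spot with canonical columns
    ``spot_id, gene_id, f_cy5, b_cy5, f_cy3, b_cy3, flag``; ``missing`` marks
    spots with a nonpositive flag or nonpositive net intensity in either
    channel.
    """

    data: pd.DataFrame
    missing: np.ndarray  # bool per spot

    def __post_init__(self) -> None:
        self.missing = np.asarray(self.missing, dtype=bool)
        if len(self.missing) != len(self.data):
            raise ValueError("missing mask length does not match spot count")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def net_cy5(self) -> np.ndarray:
        return (self.data["f_cy5"] - self.data["b_cy5"]).to_numpy(dtype=float)

    @property
    def net_cy3(self) -> np.ndarray:
        return (self.data["f_cy3"] - self.data["b_cy3"]).to_numpy(dtype=float)


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of normalized log2(sample/reference) ratios.

    ``values`` may contain NaN for missing entries. ``classes`` assigns each
    sample to one of ``control``, ``E2``, ``E2_ICI``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    classes: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    VALID_CLASSES = ("control", "E2", "E2_ICI")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(self.classes) != len(self.sample_ids):
            raise ValueError("one class label required per sample")
        bad = set(self.classes) - set(self.VALID_CLASSES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_columns(self, label: str) -> np.ndarray:
        """Column indices of samples in class ``label``."""
        return np.flatnonzero(np.asarray(self.classes) == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(list(gene_ids))
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            classes=list(self.classes),
            values=self.values[idx],
            meta=dict(self.meta),
        )

    def write_tsv(self, path, sidecar: str | Path | None = None) -> None:
        """Write the matrix as TSV (NA for missing) plus a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
        payload = {"sample_ids": self.sample_ids, "classes": self.classes,
                   "meta": self.meta}
        sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def read_tsv(cls, path, sidecar: str | Path | None = None) -> "ExpressionMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
        payload = json.loads(sidecar.read_text())
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            classes=list(payload["classes"]),
            values=frame.to_numpy(dtype=float),
            meta=payload.get("meta", {}),
        )


def read_spot_table(path, dialect: dict[str, str] | None = None) -> SpotTable:
    """Read a GPR-like tab-separated spot table.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header row.
    dialect : dict, optional
        Map from canonical field names (``spot_id``, ``gene_id``, ``f_cy5``,
        ``b_cy5``, ``f_cy3``, ``b_cy3``, ``flag``) to the file's column names.
        Defaults to GenePix naming.
    """
    dialect = dict(GENEPIX_DIALECT if dialect is None else dialect)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype={dialect.get("spot_id", "ID"): str})
    if raw.empty:
        raise ValueError(f"empty spot table: {path}")
    missing_cols = [col for col in dialect.values() if col not in raw.columns]
    if missing_cols:
        raise FormatError(
            f"spot table {path.name} lacks mapped column(s): {missing_cols}"
        )
    data = pd.DataFrame(
        {
            "spot_id": raw[dialect["spot_id"]].astype(str),
            "gene_id": raw[dialect["gene_id"]].fillna("").astype(str),
            "f_cy5": raw[dialect["f_cy5"]].astype(float),
            "b_cy5": raw[dialect["b_cy5"]].astype(float),
            "f_cy3": raw[dialect["f_cy3"]].astype(float),
            "b_cy3": raw[dialect["b_cy3"]].astype(float),
            "flag": raw[dialect["flag"]].astype(int),
        }
    )
    net5 = data["f_cy5"] - data["b_cy5"]
    net3 = data["f_cy3"] - data["b_cy3"]
    missing = (data["flag"] <= 0) | (net5 <= 0) | (net3 <= 0)
    return SpotTable(data=data, missing=missing.to_numpy())


def lowess_normalize(spots: SpotTable, span: float = 0.3) -> np.ndarray:
    """Intensity-dependent normalization of per-spot log ratios.

    Computes, for every non-missing spot, M = log2(net_cy5/net_cy3) and
    A = 0.5*log2(net_cy5*net_cy3), fits a locally weighted degree-1
    regression of M on A (tricube weights, 3 robustness iterations) and
    returns the residual M - f(A). Missing spots come back as NaN.

    Parameters
    ----------
    spots : SpotTable
    span : float in (0, 1]
        Fraction of spots contributing to each local fit.

    Returns
    -------
    numpy.ndarray of length ``len(spots)``.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    ok = ~spots.missing
    if ok.sum() < 10:
        raise ValueError(
            f"insufficient data: {int(ok.sum())} non-missing spots (need >= 10)"
        )
    net5 = spots.net_cy5[ok]
    net3 = spots.net_cy3[ok]
    m = np.log2(net5 / net3)
    a = 0.5 * np.log2(net5 * net3)
    # statsmodels returns the smooth evaluated at the input A values.
    fitted = _sm_lowess(m, a, frac=span, it=3, return_sorted=False)
    out = np.full(len(spots), np.nan)
    out[ok] = m - fitted
    return out


def build_matrix(
    arrays: list[np.ndarray],
    sample_ids: list[str],
    classes: list[str],
    probe_ids: list[str],
    gene_ids: list[str] | None = None,
    max_missing: int = 6,
) -> ExpressionMatrix:
    """Stack per-array normalized ratios into an ExpressionMatrix.

    Probes missing in more than ``max_missing`` samples are dropped.  Probes
    are kept separate even when several share a gene annotation; collapse to
    one probe per gene happens at reporting time (most significant probe),
    not here, to avoid averaging artifacts.

    Parameters
    ----------
    arrays : list of 1-D arrays
        One normalized ratio vector per sample; NaN marks missing. All must
        share ``probe_ids`` order.
    sample_ids, classes : per-sample labels.
    probe_ids : probe identifiers defining row order.
    gene_ids : optional gene annotation per probe (empty string = none);
        recorded in ``meta['probe_gene']`` for downstream collapsing.
    max_missing : int
        Maximum tolerated missing entries per probe (default 6).
    """
    n_probes = len(probe_ids)
    for i, arr in enumerate(arrays):
        if len(arr) != n_probes:
            raise ValueError(
                f"array {i} has {len(arr)} probes, expected {n_probes}: "
                "probe lists must align"
            )
    values = np.column_stack([np.asarray(a, dtype=float) for a in arrays])
    n_missing = np.isnan(values).sum(axis=1)
    keep = n_missing <= max_missing
    meta = {
        "n_probes_input": int(n_probes),
        "n_probes_retained": int(keep.sum()),
        "max_missing": int(max_missing),
    }
    if gene_ids is not None:
        meta["probe_gene"] = {
            p: g for p, g, k in zip(probe_ids, gene_ids, keep) if k and g
        }
    return ExpressionMatrix(
        gene_ids=[p for p, k in zip(probe_ids, keep) if k],
        sample_ids=list(sample_ids),
        classes=list(classes),
        values=values[keep],
        meta=meta,
    )
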