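"""Prefiltering and normalisation applied before recursive gene selection.

The prefilter drops genes whose two-sample Welch t-test p-value exceeds a
threshold — a load-reduction device, not an inference, so no multiplicity
correction is applied.  Normalisation rescales each sample column so that its
mean (or median) equals 1, the reading of array-wise "MA" normalisation used
throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionDataset


@dataclass
class FilterReport:
    """Outcome of the significance prefilter."""

    kept_gene_ids: list
    removed_gene_ids: list
    p_values: np.ndarray  # per input gene, in input order
    threshold: float


def welch_p_values(ds: ExpressionDataset) -> np.ndarray:
    """Per-gene Welch (unequal-variance) two-sample t-test p-values.

    Genes with zero variance in both classes carry no signal; their undefined
    statistic is reported as p = 1 so any usual threshold removes them.
    """
    a = ds.values[:, ds.labels == 0]
    b = ds.values[:, ds.labels == 1]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError(
            "each class needs at least 2 samples for a two-sample test "
            f"(got {a.shape[1]} and {b.shape[1]})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def filter_insignificant(
    ds: ExpressionDataset,
    threshold: float = 0.05,
    max_genes: int | None = None,
):
    """Keep genes with Welch p ≤ ``threshold``, preserving input order.

    ``max_genes`` optionally caps the kept set at the N smallest p-values
    (still reported in input order).  Returns ``(filtered_dataset, report)``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    p = welch_p_values(ds)
    keep = p <= threshold
    if max_genes is not None and max_genes > 0 and keep.sum() > max_genes:
        order = np.argsort(p, kind="stable")
        allowed = set(order[:max_genes].tolist())
        keep = keep & np.isin(np.arange(ds.n_genes), list(allowed))
    kept_idx = np.flatnonzero(keep)
    report = FilterReport(
        kept_gene_ids=[ds.gene_ids[i] for i in kept_idx],
        removed_gene_ids=[ds.gene_ids[i] for i in np.flatnonzero(~keep)],
        p_values=p,
        threshold=float(threshold),
    )
    return ds.subset_genes(kept_idx), report


def normalize_manorm(ds: ExpressionDataset, center: str = "mean") -> ExpressionDataset:
    """Rescale each sample column so its mean (or median) equals 1.

    Idempotent and invariant to per-sample scalar rescaling.  A sample whose
    centring statistic is zero cannot be rescaled and raises an error naming
    the sample.
    """
    if center not in ("mean", "median"):
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    stat = ds.values.mean(axis=0) if center == "mean" else np.median(ds.values, axis=0)
    zero = np.isclose(stat, 0.0)
    if zero.any():
        bad = ds.sample_ids[int(np.flatnonzero(zero)[0])]
        raise ValueError(f"sample {bad!r} has {center} 0 and cannot be rescaled")
    out = ds.subset_genes(np.arange(ds.n_genes))  # cheap copy via replace
    out.values = ds.values / stat[None, :]
    return out
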