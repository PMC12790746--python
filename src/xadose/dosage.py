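"""Filtering, normalization, the X:A dosage statistic, and sample structure.

The X-to-autosome (X:A) ratio is the per-sample median of transformed
X-linked expression divided by the median of transformed autosomal
expression; a value near 1.0 indicates full X-dosage compensation
(X-upregulation plus X inactivation). Y-linked genes contribute to neither
median. Normalization is median-of-ratios; the variance-stabilizing step is
approximated by log2(normalized + 1), which leaves median-based statistics
essentially unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import InputError, NumericalError

__all__ = [
    "filter_low_expression",
    "size_factors_median_of_ratios",
    "transform",
    "xa_ratio",
    "xa_ratio_by_genotype",
    "top_variable_genes",
    "pca_embed",
    "correlation_matrix",
]


def filter_low_expression(counts: pd.DataFrame, min_row_sum: int = 10
                          ) -> pd.DataFrame:
    """Keep genes whose total count across all samples is >= min_row_sum.

    The boundary is inclusive (a row summing exactly to the threshold is
    retained). The sample set is unchanged.
    """
    if min_row_sum < 0:
        raise InputError("min_row_sum must be >= 0")
    kept = counts.loc[counts.sum(axis=1) >= min_row_sum]
    if kept.empty:
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return kept


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, s_j is the median over reference genes (genes with a
    positive geometric mean across samples) of count_gj / geomean_g.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    ref = np.isfinite(log_geo)
    if not ref.any():
        raise NumericalError(
            "no gene has positive counts in every sample; median-of-ratios "
            "normalization is undefined (consider a pseudo-reference fallback "
            "or less sparse data)")
    ratios = mat[ref] / np.exp(log_geo[ref])[:, None]
    s = np.median(ratios, axis=0)
    if np.any(s <= 0):
        raise NumericalError("non-positive size factor; data too sparse")
    return pd.Series(s, index=counts.columns, name="size_factor")


def transform(counts: pd.DataFrame, size_factors: pd.Series,
              pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), a VST-like monotone transform."""
    s = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise InputError("size factors must be finite and positive for all samples")
    t = np.log2(counts.to_numpy(dtype=float) / s[None, :] + pseudocount)
    out = pd.DataFrame(t, index=counts.index, columns=counts.columns)
    out.attrs["transform"] = f"log2(norm+{pseudocount:g})"
    return out


def xa_ratio(transformed: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-sample X:A ratio: median X-linked / median autosomal expression.

    Operates on all retained (post-filter) X-linked and autosomal genes;
    Y-linked genes are excluded from both medians. The median of an even
    number of values is the midpoint of the central pair.
    """
    ann = annotation.set_index("gene_id")["chrom_class"].reindex(transformed.index)
    x_genes = transformed.index[ann == "X"]
    a_genes = transformed.index[ann == "autosome"]
    if len(x_genes) == 0 or len(a_genes) == 0:
        raise InputError("need at least one X-linked and one autosomal gene "
                         "for the X:A ratio")
    x_med = transformed.loc[x_genes].median(axis=0)
    a_med = transformed.loc[a_genes].median(axis=0)
    if (a_med == 0).any():
        bad = list(a_med.index[a_med == 0])
        raise NumericalError(f"autosomal median is zero for sample(s) {bad}; "
                             f"X:A ratio undefined")
    return pd.DataFrame({
        "n_x_genes": len(x_genes),
        "n_autosomal_genes": len(a_genes),
        "x_median": x_med,
        "autosomal_median": a_med,
        "xa_ratio": x_med / a_med,
    })


def xa_ratio_by_genotype(ratios: pd.DataFrame, sample_sheet: pd.DataFrame
                         ) -> pd.DataFrame:
    """Aggregate per-sample X:A ratios to per-genotype mean and sd."""
    geno = sample_sheet.set_index("sample_id")["genotype"].reindex(ratios.index)
    grouped = ratios["xa_ratio"].groupby(geno)
    return pd.DataFrame({"mean": grouped.mean(), "sd": grouped.std(ddof=1),
                         "n": grouped.size()})


def top_variable_genes(transformed: pd.DataFrame, n: int = 500,
                       annotation: pd.DataFrame | None = None,
                       subset: str = "all") -> list[str]:
    """Genes ranked by unbiased sample variance, descending; ties by gene_id.

    ``subset`` restricts the candidate set: 'all', 'sex' (X and Y linked) or
    'autosome' (requires an annotation). Asking for more genes than available
    returns all of them with a warning.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    mat = transformed
    if subset != "all":
        if annotation is None:
            raise InputError("subset selection requires an annotation")
        ann = annotation.set_index("gene_id")["chrom_class"].reindex(mat.index)
        if subset == "sex":
            mat = mat.loc[ann.isin(["X", "Y"])]
        elif subset == "autosome":
            mat = mat.loc[ann == "autosome"]
        else:
            raise InputError(f"unknown subset {subset!r}; "
                             f"use 'all', 'sex' or 'autosome'")
    if n > len(mat):
        warnings.warn(f"requested {n} genes but only {len(mat)} available; "
                      f"returning all", stacklevel=2)
        n = len(mat)
    var = mat.var(axis=1, ddof=1)
    order = var.to_frame("var").reset_index().rename(
        columns={var.index.name or "index": "gene_id"})
    order = order.sort_values(["var", "gene_id"], ascending=[False, True],
                              kind="mergesort")
    return order["gene_id"].head(n).tolist()


def pca_embed(transformed: pd.DataFrame, genes: list[str] | None = None,
              k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the samples over the chosen genes.

    Genes are centered; components are oriented so that each component's
    largest-magnitude gene loading is positive. Returns (coordinates
    [samples x k], explained-variance fractions).
    """
    mat = transformed if genes is None else transformed.loc[genes]
    n_samples = mat.shape[1]
    if n_samples < 2:
        raise InputError("PCA requires at least 2 samples")
    # per-gene centering caps the rank at n_samples - 1
    max_k = min(n_samples - 1, mat.shape[0])
    if k > max_k:
        warnings.warn(f"k={k} reduced to {max_k} (limited by matrix rank)",
                      stacklevel=2)
        k = max_k
    X = mat.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    # sign convention: largest-|loading| positive per component
    for i in range(k):
        j = np.argmax(np.abs(pca.components_[i]))
        if pca.components_[i, j] < 0:
            pca.components_[i] *= -1
            coords[:, i] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(coords, index=mat.columns, columns=cols),
            pca.explained_variance_ratio_.copy())


def correlation_matrix(transformed: pd.DataFrame,
                       genes: list[str] | None = None) -> pd.DataFrame:
    """Sample x sample Pearson correlation over the chosen genes."""
    mat = transformed if genes is None else transformed.loc[genes]
    vals = mat.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        bad = list(mat.columns[sd == 0])
        warnings.warn(f"zero-variance sample(s) {bad}: correlation undefined "
                      f"(NaN)", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals.T)
    return pd.DataFrame(corr, index=mat.columns, columns=mat.columns)
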