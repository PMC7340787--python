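"""Expression-matrix loading and cleaning.

Covers the standard pre-network steps: removing genes/samples with too many
missing values, keeping the top-variance fraction of genes, and flagging
outlier samples by hierarchical clustering of sample profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from coexppi.utils import CoexppiError

__all__ = [
    "read_expression",
    "read_geo_series_matrix",
    "read_traits",
    "filter_missing",
    "top_variance",
    "detect_sample_outliers",
    "align",
    "collapse_probes_max_variance",
]


def read_expression(path) -> pd.DataFrame:
    """Read a tab-separated expression matrix (first column gene id,
    header row sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    _check_unique(df)
    return df


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Read the expression table embedded in a GEO series-matrix text file.

    Lines beginning with ``!`` are metadata; the table sits between the
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` markers.
    """
    lines = []
    inside = False
    with open(path) as fh:
        for line in fh:
            low = line.strip().lower()
            if low.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if low.startswith("!series_matrix_table_end"):
                break
            if inside and not line.startswith("!"):
                lines.append(line)
    if not lines:
        raise CoexppiError(f"no series-matrix table found in {path}")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    _check_unique(df)
    return df


def read_traits(path) -> pd.DataFrame:
    """Read the clinical trait table (CSV, first column sample id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise CoexppiError("duplicate sample ids in trait table")
    return df


def _check_unique(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise CoexppiError(f"duplicate gene id {dup!r} in expression matrix")
    if pd.Index(df.columns).duplicated().any():
        raise CoexppiError("duplicate sample ids in expression matrix")


def filter_missing(
    matrix: pd.DataFrame,
    max_missing_fraction: float = 0.5,
    min_variance: float = 0.0,
) -> pd.DataFrame:
    """Drop genes with too many missing values or no variance, drop samples
    with too many missing values, impute the rest by gene median.

    A gene is removed when its missing fraction exceeds
    ``max_missing_fraction`` or its variance over non-missing entries is
    <= ``min_variance`` (so the default 0 removes exactly the constant
    genes).  Surviving gene order is preserved.
    """
    if not 0 <= max_missing_fraction < 1:
        raise CoexppiError("max_missing_fraction must lie in [0, 1)")
    gene_missing = matrix.isna().mean(axis=1)
    gene_var = matrix.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    keep_genes = (gene_missing <= max_missing_fraction) & (gene_var > min_variance)
    if not keep_genes.any():
        raise CoexppiError(
            f"all genes removed at max_missing_fraction={max_missing_fraction}, "
            f"min_variance={min_variance}"
        )
    out = matrix.loc[keep_genes]

    sample_missing = out.isna().mean(axis=0)
    out = out.loc[:, sample_missing <= max_missing_fraction]
    if out.shape[1] == 0:
        raise CoexppiError("all samples removed by missing-value filter")

    if out.isna().any().any():
        medians = out.median(axis=1, skipna=True)
        out = out.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    return out


def top_variance(matrix: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Keep the floor(fraction * n_genes) genes of largest sample variance.

    Ties are broken by gene id (lexicographic) so the result is
    deterministic; surviving genes keep their input order.
    """
    if not 0 < fraction <= 1:
        raise CoexppiError("fraction must lie in (0, 1]")
    n_keep = int(np.floor(fraction * matrix.shape[0]))
    if n_keep < 2:
        raise CoexppiError(f"top_variance would keep {n_keep} gene(s); need at least 2")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-var[g], g))
    chosen = set(order[:n_keep])
    return matrix.loc[[g for g in matrix.index if g in chosen]]


def detect_sample_outliers(
    matrix: pd.DataFrame,
    method: str = "k_sd",
    param: float = 3.0,
    max_removed_fraction: float = 0.2,
) -> list[str]:
    """Flag outlier samples from average-linkage clustering of samples.

    Samples are clustered on Euclidean distance between expression
    profiles.  ``static_height`` flags every sample outside the largest
    cluster obtained by cutting the dendrogram at height ``param``;
    ``k_sd`` flags samples whose first merge height reaches
    mean + param * sd of all first-merge heights (population sd,
    inclusive threshold).  Never flags all samples, and refuses to flag
    more than ``max_removed_fraction`` of them.
    """
    if param <= 0:
        raise CoexppiError("param must be positive")
    if matrix.shape[1] < 4:
        raise CoexppiError("outlier detection needs at least 4 samples")
    samples = list(matrix.columns)
    profiles = matrix.T.to_numpy()
    dist = pdist(profiles, metric="euclidean")
    if np.allclose(dist, 0):
        return []
    Z = linkage(dist, method="average")

    if method == "static_height":
        labels = fcluster(Z, t=param, criterion="distance")
        counts = pd.Series(labels).value_counts()
        main = counts.idxmax()
        flagged = [s for s, lab in zip(samples, labels) if lab != main]
    elif method == "k_sd":
        n = len(samples)
        # height at which each leaf (sample) first merges into the tree
        merge_height = np.zeros(n)
        for a, b, h, _ in Z:
            for node in (int(a), int(b)):
                if node < n:
                    merge_height[node] = h
        thresh = merge_height.mean() + param * merge_height.std(ddof=0)
        flagged = [s for s, h in zip(samples, merge_height) if h >= thresh and h > 0]
    else:
        raise CoexppiError(f"unknown outlier method {method!r}")

    if len(flagged) == len(samples):
        raise CoexppiError("outlier rule would flag every sample")
    if len(flagged) > max_removed_fraction * len(samples):
        raise CoexppiError(
            f"outlier rule would flag {len(flagged)}/{len(samples)} samples "
            f"(> {max_removed_fraction:.0%}); inspect the dendrogram instead"
        )
    return flagged


def align(matrix: pd.DataFrame, traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict matrix and traits to their common samples, same order."""
    common = [s for s in matrix.columns if s in set(traits.index)]
    if not common:
        raise CoexppiError("expression matrix and trait table share no samples")
    return matrix.loc[:, common], traits.loc[common]


def collapse_probes_max_variance(matrix: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probe-level rows to genes, keeping each gene's
    maximal-variance probe (for GEO-style inputs)."""
    mapped = matrix.loc[matrix.index.isin(probe_to_gene.index)].copy()
    if mapped.empty:
        raise CoexppiError("no probes map to genes")
    var = mapped.var(axis=1, ddof=1)
    genes = probe_to_gene.loc[mapped.index]
    best = var.groupby(genes).idxmax()
    out = mapped.loc[best.values]
    out.index = best.index.astype(str)
    return out.sort_index()
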