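"""Local enrichment statistics: hypergeometric over-representation and
GSEA-style running-sum enrichment with a phenotype-permutation null.

ORA uses the plain hypergeometric upper tail (not the EASE k-1 variant),
so p-values differ slightly from DAVID's by construction.  GSEA follows
the classic weighted Kolmogorov-Smirnov scheme: genes ranked by
signal-to-noise between two phenotype groups, hits increment the running
sum by |score|^p (normalized), misses decrement by 1/(N - N_hits); the
enrichment score is the signed maximum deviation.  Significance comes
from phenotype-label permutations with the add-one rule, normalization by
the mean same-sign permutation |ES|, and the same-sign pooled-NES FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from coexppi.utils import CoexppiError, stream_rng

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora",
    "gsea_rank",
    "gsea_es",
    "gsea_significance",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with one-line descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise CoexppiError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members)."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CoexppiError(f"malformed GMT line {lineno} in {path}")
            name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise CoexppiError(f"duplicate gene set name {name!r} in {path}")
            sets[name] = tuple(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora(
    query,
    background,
    sets: GeneSetCollection,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within each set.

    Per set: upper-tail probability of observing at least the seen overlap
    given N = |background|, K = |set & background|, n = |query|; BH
    adjustment across the tested sets.  Sets overlapping the query by
    fewer than ``min_overlap`` genes are skipped.
    """
    background = set(background)
    query = set(query) & background
    if not query:
        raise CoexppiError("empty query after intersecting with the background")
    N, n = len(background), len(query)
    rows = []
    for name, members in sets.items():
        in_bg = set(members) & background
        K = len(in_bg)
        overlap = sorted(query & in_bg)
        k = len(overlap)
        if K == 0 or k < min_overlap:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        # odds ratio of the 2x2 overlap table (Haldane 0.5 when degenerate)
        a, b_, c, d = k, n - k, K - k, N - K - (n - k)
        if min(a, b_, c, d) == 0:
            a, b_, c, d = a + 0.5, b_ + 0.5, c + 0.5, d + 0.5
        rows.append((name, K, k, (a * d) / (b_ * c), min(p, 1.0), ";".join(overlap)))
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "odds_ratio", "p", "overlap_genes"]
    ).set_index("set")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out.sort_values("p")


def _signal_to_noise(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Classic GSEA signal-to-noise with the variance floor
    sigma >= max(0.2 * |mu|, 0.2) per group."""
    g1, g0 = values[:, labels == 1], values[:, labels == 0]
    m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
    s1, s0 = g1.std(axis=1, ddof=1), g0.std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 0.2))
    s0 = np.maximum(s0, np.maximum(0.2 * np.abs(m0), 0.2))
    return (m1 - m0) / (s1 + s0)


def _t_statistic(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    g1, g0 = values[:, labels == 1], values[:, labels == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    v1, v0 = g1.var(axis=1, ddof=1), g0.var(axis=1, ddof=1)
    denom = np.sqrt(v1 / n1 + v0 / n0)
    denom = np.where(denom == 0, np.finfo(float).eps, denom)
    return (g1.mean(axis=1) - g0.mean(axis=1)) / denom


_METRICS = {"signal2noise": _signal_to_noise, "t_stat": _t_statistic}


def gsea_rank(
    matrix: pd.DataFrame, group_labels, metric: str = "signal2noise"
) -> pd.Series:
    """Rank genes by a two-group differential metric, descending.

    ``group_labels`` is binary per sample (1 = the "high"/treatment
    group); both groups need at least 3 samples.
    """
    labels = np.asarray(group_labels).astype(int)
    if labels.shape[0] != matrix.shape[1]:
        raise CoexppiError("group_labels length must match the number of samples")
    if (labels == 1).sum() < 3 or (labels == 0).sum() < 3:
        raise CoexppiError("each group needs at least 3 samples")
    if metric not in _METRICS:
        raise CoexppiError(f"unknown metric {metric!r}")
    scores = _METRICS[metric](matrix.to_numpy(dtype=float), labels)
    out = pd.Series(scores, index=matrix.index, name=metric)
    return out.sort_values(ascending=False, kind="stable")


def gsea_es(
    ranked: pd.Series, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running sum over a ranked list for one gene set.

    Returns (ES, running sum, leading-edge genes).  Hits increment by
    |score|^p normalized over hits; misses decrement by 1/(N - N_hits);
    ES is the signed maximum deviation from zero, the leading edge the
    genes from the top of the list up to the extremum (for positive ES)
    or from the extremum to the bottom (negative ES).
    """
    genes = ranked.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    if not in_set.any():
        raise CoexppiError("gene set does not intersect the ranked list")
    scores = ranked.to_numpy(dtype=float)
    running = _running_sum(scores, in_set, weight_p)
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_max + 1], in_set[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_max:], in_set[i_max:]) if h]
    return es, running, leading


def _running_sum(scores: np.ndarray, in_set: np.ndarray, weight_p: float) -> np.ndarray:
    n = len(scores)
    n_hits = int(in_set.sum())
    w = np.abs(scores) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores are zero: fall back to equal weights
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    inc = hit_w / total
    if n == n_hits:
        return np.cumsum(inc)
    dec = np.where(in_set, 0.0, 1.0 / (n - n_hits))
    return np.cumsum(inc - dec)


def _es_all_sets(scores: np.ndarray, order: np.ndarray, membership: np.ndarray,
                 weight_p: float) -> np.ndarray:
    """Vectorized ES for every set (rows of ``membership``) at once."""
    s = np.abs(scores[order]) ** weight_p
    m = membership[:, order]
    hit_w = m * s
    totals = hit_w.sum(axis=1, keepdims=True)
    totals = np.where(totals == 0, 1.0, totals)
    n = m.shape[1]
    n_hits = m.sum(axis=1, keepdims=True)
    dec = (1.0 - m) / np.maximum(n - n_hits, 1)
    running = np.cumsum(hit_w / totals - dec, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def _permutation_labels(labels: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Permuted label matrix; exact enumeration when the label arrangement
    count does not exceed ``n_perm`` (logged)."""
    n = len(labels)
    n1 = int(labels.sum())
    if comb(n, n1) <= n_perm:
        logger.info("exact enumeration of %d label arrangements", comb(n, n1))
        perms = []
        for pos in combinations(range(n), n1):
            lab = np.zeros(n, dtype=int)
            lab[list(pos)] = 1
            perms.append(lab)
        return np.array(perms)
    out = np.empty((n_perm, n), dtype=int)
    for i in range(n_perm):
        out[i] = rng.permutation(labels)
    return out


def gsea_significance(
    matrix: pd.DataFrame,
    group_labels,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "signal2noise",
    weight_p: float = 1.0,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """GSEA with a phenotype-permutation null for every set.

    Nominal p uses the add-one rule over same-sign permutation scores (so
    p >= 1/(n_perm + 1)); NES divides ES by the mean same-sign
    permutation |ES|; FDR pools same-sign NES across sets in the standard
    GSEA fashion.  Deterministic under a fixed seed.
    """
    if n_perm < 100:
        raise CoexppiError("n_perm must be >= 100")
    labels = np.asarray(group_labels).astype(int)
    ranked = gsea_rank(matrix, labels, metric=metric)  # validates group sizes

    genes = matrix.index.to_numpy()
    names, rows_m = [], []
    for name, members in sets.items():
        mask = np.isin(genes, list(members))
        if mask.sum() >= min_set_size:
            names.append(name)
            rows_m.append(mask)
    if not names:
        raise CoexppiError("no gene set intersects the expression matrix")
    membership = np.array(rows_m, dtype=float)

    values = matrix.to_numpy(dtype=float)
    metric_fn = _METRICS[metric]

    def es_for(lab):
        sc = metric_fn(values, lab)
        order = np.argsort(-sc, kind="stable")
        return _es_all_sets(sc, order, membership, weight_p)

    es_obs = es_for(labels)
    rng = stream_rng(seed, 0)
    perms = _permutation_labels(labels, n_perm, rng)
    es_perm = np.array([es_for(lab) for lab in perms])  # perms x sets

    n_sets = len(names)
    p = np.empty(n_sets)
    nes = np.empty(n_sets)
    nes_perm = np.full_like(es_perm, np.nan)
    for j in range(n_sets):
        col = es_perm[:, j]
        same_pos, same_neg = col[col >= 0], col[col < 0]
        mean_pos = np.abs(same_pos).mean() if len(same_pos) else np.nan
        mean_neg = np.abs(same_neg).mean() if len(same_neg) else np.nan
        if es_obs[j] >= 0:
            same = same_pos
            nes[j] = es_obs[j] / mean_pos if mean_pos and mean_pos > 0 else np.nan
        else:
            same = same_neg
            nes[j] = es_obs[j] / mean_neg if mean_neg and mean_neg > 0 else np.nan
        p[j] = (1 + int((np.abs(same) >= abs(es_obs[j])).sum())) / (1 + len(same))
        pos_mask = col >= 0
        nes_perm[pos_mask, j] = col[pos_mask] / mean_pos if mean_pos else np.nan
        nes_perm[~pos_mask, j] = col[~pos_mask] / mean_neg if mean_neg else np.nan

    fdr = _gsea_fdr(nes, nes_perm)

    leading = []
    for j, name in enumerate(names):
        _, _, le = gsea_es(ranked, sets[name], weight_p=weight_p)
        leading.append(";".join(le))

    out = pd.DataFrame(
        {
            "size": membership.sum(axis=1).astype(int),
            "es": es_obs,
            "nes": nes,
            "p": p,
            "fdr": fdr,
            "leading_edge": leading,
        },
        index=pd.Index(names, name="set"),
    )
    return out.sort_values("p")


def _gsea_fdr(nes_obs: np.ndarray, nes_perm: np.ndarray) -> np.ndarray:
    """Same-sign pooled-NES FDR: for a positive observed NES*, the ratio of
    the pooled-permutation tail fraction to the observed tail fraction."""
    pool = nes_perm[np.isfinite(nes_perm)]
    pool_pos, pool_neg = pool[pool >= 0], pool[pool < 0]
    obs = nes_obs[np.isfinite(nes_obs)]
    obs_pos, obs_neg = obs[obs >= 0], obs[obs < 0]
    fdr = np.full_like(nes_obs, np.nan)
    for j, v in enumerate(nes_obs):
        if not np.isfinite(v):
            continue
        if v >= 0:
            num = (pool_pos >= v).mean() if len(pool_pos) else 1.0
            den = (obs_pos >= v).mean() if len(obs_pos) else 1.0
        else:
            num = (pool_neg <= v).mean() if len(pool_neg) else 1.0
            den = (obs_neg <= v).mean() if len(obs_neg) else 1.0
        fdr[j] = min(1.0, num / den) if den > 0 else 1.0
    return fdr
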