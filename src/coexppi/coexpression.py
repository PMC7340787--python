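"""Weighted gene co-expression network core.

Soft-threshold adjacency, scale-free topology fit, topological overlap,
adaptive dendrogram cutting into modules, module eigengenes, and
module-trait statistics (gene significance / module membership).

The network model: pairwise Pearson correlations are raised to a soft
power beta, a_ij = |cor|^beta (unsigned) or ((1+cor)/2)^beta (signed);
beta is the smallest power whose connectivity distribution is approximately
scale-free (signed fit index R^2 above a threshold, conventionally 0.9).
The topological overlap

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj,  k_i = sum_u a_iu

measures shared neighborhood; 1 - w is the clustering distance.  Branches
of the average-linkage dendrogram that are well separated from their
surroundings and hold at least ``min_module_size`` genes become modules;
everything else is "grey".  Each module is summarized by its eigengene,
the first principal component of its standardized expression, whose
correlation with clinical traits identifies the critical module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from scipy.stats import t as t_dist

from coexppi.utils import CoexppiError

__all__ = [
    "soft_adjacency",
    "scale_free_fit",
    "ScaleFreeFit",
    "choose_power",
    "tom_similarity",
    "cluster_and_cut",
    "ModuleAssignment",
    "module_eigengenes",
    "ModuleEigengenes",
    "module_trait_correlation",
    "ModuleTraitStats",
    "select_critical_module",
    "CoexpressionNetwork",
    "CoexpressionResults",
]

GREY = "grey"

# size-ordered module color vocabulary (largest module first)
_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]


def _module_color(i: int) -> str:
    return _COLORS[i] if i < len(_COLORS) else f"module{i + 1}"


def _correlation(matrix: pd.DataFrame) -> np.ndarray:
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if np.any(sd == 0):
        gene = matrix.index[int(np.argmax(sd == 0))]
        raise CoexppiError(f"gene {gene!r} is constant across samples; correlation undefined")
    cor = np.corrcoef(values)
    return np.clip(cor, -1.0, 1.0)


def soft_adjacency(matrix: pd.DataFrame, power: int, mode: str = "unsigned") -> np.ndarray:
    """Soft-threshold adjacency from gene-gene Pearson correlation.

    unsigned: a_ij = |cor|^beta; signed: a_ij = ((1 + cor)/2)^beta.
    """
    if power < 1 or int(power) != power:
        raise CoexppiError("power must be an integer >= 1")
    if matrix.shape[1] < 3:
        raise CoexppiError("need at least 3 samples")
    cor = _correlation(matrix)
    if mode == "unsigned":
        adj = np.abs(cor) ** power
    elif mode == "signed":
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        raise CoexppiError(f"unknown mode {mode!r}")
    np.fill_diagonal(adj, 1.0)
    return adj


@dataclass
class ScaleFreeFit:
    """Signed scale-free fit of one adjacency's connectivity distribution."""

    r_squared: float          # signed: positive means p(k) decreases with k
    slope: float
    mean_connectivity: float
    degenerate: bool = False  # all connectivities identical


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> ScaleFreeFit:
    """Fit log10(frequency) ~ log10(mean connectivity) over equal-width
    connectivity bins; report R^2 signed by -sign(slope) so decreasing
    degree distributions score positively."""
    n = adjacency.shape[0]
    if n < 10:
        raise CoexppiError("scale_free_fit needs at least 10 genes")
    k = adjacency.sum(axis=0) - np.diag(adjacency)
    mean_k = float(k.mean())
    if np.allclose(k, k[0]):
        return ScaleFreeFit(0.0, 0.0, mean_k, degenerate=True)

    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        log_k.append(np.log10(mk))
        log_f.append(np.log10(mask.sum() / n))
    if len(log_k) < 2 or np.allclose(log_k, log_k[0]) or np.allclose(log_f, log_f[0]):
        return ScaleFreeFit(0.0, 0.0, mean_k, degenerate=True)
    fit = linregress(log_k, log_f)
    signed_r2 = -np.sign(fit.slope) * fit.rvalue**2
    return ScaleFreeFit(float(signed_r2), float(fit.slope), mean_k)


def choose_power(
    matrix: pd.DataFrame,
    candidates=tuple(range(1, 13)),
    threshold: float = 0.9,
    mode: str = "unsigned",
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power whose signed R^2 exceeds ``threshold``;
    falls back to the argmax with a warning when none qualifies.

    Returns (power, fit table with one row per candidate).
    """
    candidates = list(candidates)
    if not candidates:
        raise CoexppiError("no candidate powers")
    cor = _correlation(matrix)
    base = np.abs(cor) if mode == "unsigned" else (1.0 + cor) / 2.0
    rows = []
    for beta in candidates:
        adj = base ** beta
        np.fill_diagonal(adj, 1.0)
        fit = scale_free_fit(adj, n_bins=n_bins)
        rows.append((beta, fit.r_squared, fit.slope, fit.mean_connectivity))
    table = pd.DataFrame(rows, columns=["power", "r_squared", "slope", "mean_connectivity"])
    ok = table[table.r_squared > threshold]
    if len(ok):
        power = int(ok.power.iloc[0])
    else:
        power = int(table.loc[table.r_squared.idxmax(), "power"])
        warnings.warn(
            f"no candidate power reaches R^2 > {threshold}; "
            f"using argmax power {power} (R^2 = {table.r_squared.max():.3f})",
            stacklevel=2,
        )
    return power, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency (unit diagonal)."""
    a = adjacency.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    l = a @ a                      # l_ij = sum_{u != i,j} a_iu a_uj (diag(a)=0)
    num = l + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class ModuleAssignment:
    """Partition of genes into labeled modules; "grey" collects the
    unassignable genes."""

    labels: pd.Series  # gene -> module label

    @property
    def modules(self) -> list[str]:
        """Non-grey labels, largest module first."""
        counts = self.labels[self.labels != GREY].value_counts()
        return sorted(counts.index, key=lambda m: (-counts[m], m))

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def __len__(self) -> int:
        return len(self.modules)


def _tree_nodes(Z: np.ndarray, n: int):
    """Per internal node: member leaves, height, parent height."""
    members = {i: [i] for i in range(n)}
    height = {}
    parent_height = {}
    for step, (a, b, h, _) in enumerate(Z):
        node = n + step
        members[node] = members[int(a)] + members[int(b)]
        height[node] = h
        parent_height[int(a)] = h
        parent_height[int(b)] = h
    root = n + len(Z) - 1
    parent_height[root] = np.inf
    return members, height, parent_height, root


def cluster_and_cut(
    tom: np.ndarray,
    matrix: pd.DataFrame,
    min_module_size: int = 10,
    deep_split: int = 2,
    merge_height: float = 0.25,
    reassign_threshold: float = 0.3,
) -> ModuleAssignment:
    """Detect modules by adaptive branch cutting of the 1-TOM dendrogram.

    A dendrogram branch qualifies as a module candidate when it holds at
    least ``min_module_size`` genes and is cohesive: its cohesion score

        q = (mean external - mean within dissimilarity)
            / (spread of external + spread of within dissimilarities)

    reaches 1.4 - 0.2 * deep_split.  Both spreads matter: sub-cores of a
    module lose external separation (their external pairs include the
    rest of the module), supersets gain within heterogeneity.  A weak
    separation floor (height difference to the parent merge divided by
    height difference to the root, at least 0.3 - 0.05 * deep_split)
    screens out transient branches.  Candidates are nested or disjoint;
    they are scanned largest-first, and a branch is accepted when it is
    disjoint from everything accepted and its cohesion is within 10% of
    the best candidate nested inside it — so a barely-diluted superset
    defers to its pure core, while the full module beats its own
    sub-cores.
    Both criteria are scale-invariant, which matters because the soft
    power compresses topological-overlap dissimilarities into a narrow
    band near 1.  This is an adaptive variable-height cut in the spirit of
    the dynamic hybrid tree cut, validated by planted-partition recovery
    rather than label-for-label agreement with the reference
    implementation.  Unassigned genes are then rescued to the module whose
    eigengene they correlate with best when that correlation exceeds
    ``reassign_threshold``, and modules whose eigengenes correlate above
    1 - ``merge_height`` are merged.  Labels are size-ordered color names
    ("turquoise" largest); leftover genes are "grey".
    """
    if min_module_size < 2:
        raise CoexppiError("min_module_size must be >= 2")
    if not 0 <= deep_split <= 4:
        raise CoexppiError("deep_split must be in 0..4")
    genes = list(matrix.index)
    n = len(genes)
    if n != tom.shape[0]:
        raise CoexppiError("TOM size does not match the expression matrix")
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; everything is grey", stacklevel=2)
        return ModuleAssignment(pd.Series(GREY, index=pd.Index(genes, name="gene")))

    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    members, height, parent_height, root = _tree_nodes(Z, n)

    ratio_min = 0.3 - 0.05 * deep_split
    q_min = 1.4 - 0.2 * deep_split
    cohesion_tolerance = 0.9  # superset must reach 90% of its best core's q
    root_height = height[root]
    all_idx = np.arange(n)
    quality = {}
    for node in height:
        if node == root or len(members[node]) < min_module_size:
            continue
        span = root_height - height[node]
        if span <= 0:
            continue
        ratio = (parent_height[node] - height[node]) / span
        if ratio < ratio_min:
            continue
        idx = np.array(members[node])
        rest = np.setdiff1d(all_idx, idx)
        if not len(rest):
            continue
        within = diss[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)]
        external = diss[np.ix_(idx, rest)]
        denom = external.std() + within.std()
        separation = external.mean() - within.mean()
        if denom == 0:
            q = np.inf if separation > 0 else 0.0
        else:
            q = separation / denom
        if q >= q_min:
            quality[node] = q
    # candidates are laminar (nested or disjoint); scan largest-first
    cand_sets = {node: set(members[node]) for node in quality}
    selected = []
    order = sorted(quality, key=lambda nd: (-len(cand_sets[nd]), -quality[nd], nd))
    for node in order:
        if not all(cand_sets[node].isdisjoint(cand_sets[s]) for s in selected):
            continue
        nested_best = max(
            (quality[o] for o in quality if o != node and cand_sets[o] < cand_sets[node]),
            default=quality[node],
        )
        if quality[node] >= cohesion_tolerance * nested_best:
            selected.append(node)

    labels = pd.Series(GREY, index=pd.Index(genes, name="gene"), dtype=object)
    for i, node in enumerate(sorted(selected, key=lambda x: -len(members[x]))):
        for leaf in members[node]:
            labels.iloc[leaf] = f"_tmp{i}"

    assignment = ModuleAssignment(labels)
    if assignment.modules:
        assignment = _reassign_to_eigengenes(matrix, assignment, reassign_threshold)
        assignment = _merge_close_modules(matrix, assignment, merge_height, min_module_size)
    return _relabel_by_size(assignment)


def _reassign_to_eigengenes(matrix, assignment, threshold):
    """PAM-like rescue: a grey gene joins the module whose eigengene it
    correlates with best, when that correlation exceeds ``threshold``."""
    me = module_eigengenes(matrix, assignment)
    grey_genes = assignment.members(GREY)
    if not grey_genes:
        return assignment
    x = matrix.loc[grey_genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    labels = assignment.labels.copy()
    eig = me.eigengenes.to_numpy()  # samples x modules
    eig_std = (eig - eig.mean(axis=0)) / eig.std(axis=0)
    usable = sd > 0
    xs = (x[usable] - x[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    cors = xs @ eig_std / matrix.shape[1]
    best = cors.argmax(axis=1)
    best_cor = cors[np.arange(len(best)), best]
    cols = list(me.eigengenes.columns)
    for gene, b, c in zip(np.array(grey_genes)[usable], best, best_cor):
        if c > threshold:
            labels[gene] = cols[b]
    return ModuleAssignment(labels)


def _merge_close_modules(matrix, assignment, merge_height, min_module_size):
    """Merge modules whose eigengene correlation exceeds 1 - merge_height."""
    while True:
        mods = assignment.modules
        if len(mods) < 2:
            break
        me = module_eigengenes(matrix, assignment)
        eig = me.eigengenes[mods]
        cor = np.corrcoef(eig.to_numpy().T)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= 1.0 - merge_height:
            break
        labels = assignment.labels.copy()
        labels[labels == mods[j]] = mods[i]
        assignment = ModuleAssignment(labels)
    return assignment


def _relabel_by_size(assignment: ModuleAssignment) -> ModuleAssignment:
    counts = assignment.labels[assignment.labels != GREY].value_counts()
    # deterministic order: size descending, then smallest member gene id
    firsts = {
        m: min(assignment.members(m)) for m in counts.index
    }
    ordered = sorted(counts.index, key=lambda m: (-counts[m], firsts[m]))
    mapping = {old: _module_color(i) for i, old in enumerate(ordered)}
    mapping[GREY] = GREY
    return ModuleAssignment(assignment.labels.map(mapping))


@dataclass
class ModuleEigengenes:
    """First-principal-component summaries of each module."""

    eigengenes: pd.DataFrame          # samples x modules, unit sample variance
    variance_explained: pd.Series     # per module


def module_eigengenes(matrix: pd.DataFrame, assignment: ModuleAssignment) -> ModuleEigengenes:
    """Eigengene (first PC sample scores) per non-grey module.

    Genes are standardized across samples; the first right singular
    direction of the module's gene x sample block gives the scores, which
    are standardized to unit sample variance and sign-oriented to
    correlate positively with the module's mean standardized expression.
    Constant genes are dropped from the PCA with a warning.
    """
    cols = {}
    ve = {}
    samples = matrix.columns
    for label in assignment.modules:
        genes = assignment.members(label)
        x = matrix.loc[genes].to_numpy(dtype=float)
        sd = x.std(axis=1)
        if np.any(sd == 0):
            bad = [g for g, s in zip(genes, sd) if s == 0]
            warnings.warn(
                f"module {label}: dropping constant gene(s) {bad} from PCA", stacklevel=2
            )
            x = x[sd > 0]
            if x.shape[0] < 2:
                raise CoexppiError(f"module {label} has < 2 non-constant genes")
            sd = sd[sd > 0]
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        scores = vt[0]
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        mean_profile = xs.mean(axis=0)
        if np.corrcoef(scores, mean_profile)[0, 1] < 0:
            scores = -scores
        cols[label] = scores
        ve[label] = float(s[0] ** 2 / (s**2).sum())
    eig = pd.DataFrame(cols, index=samples)
    return ModuleEigengenes(eigengenes=eig, variance_explained=pd.Series(ve))


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    if x.std() == 0 or y.std() == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, np.finfo(float).tiny
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * t_dist.sf(abs(t), df=n - 2)
    return r, float(max(p, np.finfo(float).tiny))


@dataclass
class ModuleTraitStats:
    """Module-trait correlations with Student p-values, plus per-gene
    gene significance (GS) and module membership (MM)."""

    correlation: pd.DataFrame          # modules x traits
    p_value: pd.DataFrame              # modules x traits
    gene_significance: pd.DataFrame | None = None   # genes x traits (signed)
    module_membership: pd.Series | None = None      # gene -> cor with own eigengene
    module_sizes: pd.Series | None = None
    flagged_traits: list = field(default_factory=list)


def module_trait_correlation(
    eigengenes: ModuleEigengenes,
    traits: pd.DataFrame,
    matrix: pd.DataFrame | None = None,
    assignment: ModuleAssignment | None = None,
) -> ModuleTraitStats:
    """Pearson correlation of each eigengene with each (numeric) trait,
    with two-sided Student-t p-values on n-2 df.

    When the expression matrix and assignment are supplied, also returns
    GS (per-gene trait correlation) and MM (per-gene correlation with its
    own module's eigengene; grey genes get NaN).
    """
    eig = eigengenes.eigengenes
    common = [s for s in eig.index if s in set(traits.index)]
    if len(common) < 4:
        raise CoexppiError("module-trait correlation needs >= 4 shared samples")
    eig = eig.loc[common]
    tr = traits.loc[common].select_dtypes(include=[np.number])

    flagged = [c for c in tr.columns if tr[c].std() == 0]
    cor = pd.DataFrame(index=eig.columns, columns=tr.columns, dtype=float)
    pv = pd.DataFrame(index=eig.columns, columns=tr.columns, dtype=float)
    for m in eig.columns:
        for c in tr.columns:
            r, p = _pearson_with_p(eig[m].to_numpy(dtype=float), tr[c].to_numpy(dtype=float))
            cor.loc[m, c], pv.loc[m, c] = r, p

    gs = mm = sizes = None
    if matrix is not None and assignment is not None:
        sub = matrix.loc[:, common]
        gs = pd.DataFrame(index=sub.index, columns=tr.columns, dtype=float)
        for c in tr.columns:
            y = tr[c].to_numpy(dtype=float)
            for g in sub.index:
                gs.loc[g, c] = _pearson_with_p(sub.loc[g].to_numpy(dtype=float), y)[0]
        mm = pd.Series(np.nan, index=sub.index, dtype=float)
        for label in assignment.modules:
            e = eig[label].to_numpy(dtype=float)
            for g in assignment.members(label):
                if g in mm.index:
                    mm[g] = _pearson_with_p(sub.loc[g].to_numpy(dtype=float), e)[0]
        sizes = assignment.sizes()
    return ModuleTraitStats(
        correlation=cor,
        p_value=pv,
        gene_significance=gs,
        module_membership=mm,
        module_sizes=sizes,
        flagged_traits=flagged,
    )


def select_critical_module(stats: ModuleTraitStats, trait: str, alpha: float = 0.05) -> str:
    """Module with the largest |correlation| to ``trait`` among those with
    p < alpha.  Ties: smaller p wins, then the larger module."""
    if trait not in stats.correlation.columns:
        raise CoexppiError(f"trait {trait!r} not in module-trait statistics")
    r = stats.correlation[trait].drop(index=GREY, errors="ignore")
    p = stats.p_value[trait].drop(index=GREY, errors="ignore")
    significant = p[p < alpha]
    if significant.empty:
        best = r.abs().idxmax()
        raise CoexppiError(
            f"no module significant for {trait!r} at alpha={alpha}; best candidate "
            f"{best} (r={r[best]:.3f}, p={p[best]:.3g})"
        )
    sizes = stats.module_sizes if stats.module_sizes is not None else pd.Series(0, index=r.index)
    ranked = sorted(
        significant.index,
        key=lambda m: (-abs(r[m]), p[m], -sizes.get(m, 0), m),
    )
    return ranked[0]


class CoexpressionNetwork:
    """Co-expression network model for a preprocessed expression matrix.

    Parameters
    ----------
    matrix : DataFrame, genes x samples
        Preprocessed (filtered, variance-selected) expression values.
    traits : DataFrame, optional
        Per-sample clinical variables; enables module-trait statistics.

    ``fit()`` chooses the soft power (unless fixed), builds adjacency and
    TOM, cuts modules, computes eigengenes and trait statistics, and
    returns a :class:`CoexpressionResults`.
    """

    def __init__(self, matrix: pd.DataFrame, traits: pd.DataFrame | None = None):
        if matrix.index.duplicated().any() or pd.Index(matrix.columns).duplicated().any():
            raise CoexppiError("duplicate gene or sample ids")
        self.matrix = matrix
        self.traits = traits

    @classmethod
    def from_files(cls, expression_path, traits_path=None) -> "CoexpressionNetwork":
        from coexppi.preprocessing import align, read_expression, read_traits

        matrix = read_expression(expression_path)
        traits = read_traits(traits_path) if traits_path else None
        if traits is not None:
            matrix, traits = align(matrix, traits)
        return cls(matrix, traits)

    def fit(
        self,
        powers=tuple(range(1, 13)),
        r2_threshold: float = 0.9,
        mode: str = "unsigned",
        power: int | None = None,
        min_module_size: int = 10,
        deep_split: int = 2,
        merge_height: float = 0.25,
        n_bins: int = 10,
    ) -> "CoexpressionResults":
        if power is None:
            power, fit_table = choose_power(
                self.matrix, candidates=powers, threshold=r2_threshold, mode=mode, n_bins=n_bins
            )
        else:
            _, fit_table = choose_power(
                self.matrix, candidates=[power], threshold=r2_threshold, mode=mode, n_bins=n_bins
            )
        adjacency = soft_adjacency(self.matrix, power, mode=mode)
        tom = tom_similarity(adjacency)
        assignment = cluster_and_cut(
            tom,
            self.matrix,
            min_module_size=min_module_size,
            deep_split=deep_split,
            merge_height=merge_height,
        )
        eigengenes = (
            module_eigengenes(self.matrix, assignment) if assignment.modules else None
        )
        trait_stats = None
        if eigengenes is not None and self.traits is not None:
            trait_stats = module_trait_correlation(
                eigengenes, self.traits, matrix=self.matrix, assignment=assignment
            )
        return CoexpressionResults(
            model=self,
            power=power,
            mode=mode,
            fit_table=fit_table,
            adjacency=adjacency,
            tom=tom,
            modules=assignment,
            eigengenes=eigengenes,
            trait_stats=trait_stats,
        )


@dataclass
class CoexpressionResults:
    """Fitted co-expression network: chosen power, matrices, modules,
    eigengenes and module-trait statistics."""

    model: CoexpressionNetwork
    power: int
    mode: str
    fit_table: pd.DataFrame
    adjacency: np.ndarray
    tom: np.ndarray
    modules: ModuleAssignment
    eigengenes: ModuleEigengenes | None
    trait_stats: ModuleTraitStats | None

    def critical_module(self, trait: str, alpha: float = 0.05) -> str:
        if self.trait_stats is None:
            raise CoexppiError("no traits were supplied to the model")
        return select_critical_module(self.trait_stats, trait, alpha=alpha)

    def summary(self) -> str:
        n_genes, n_samples = self.model.matrix.shape
        lines = [
            "Co-expression network results",
            "=" * 48,
            f"genes: {n_genes}   samples: {n_samples}",
            f"soft power: {self.power} ({self.mode}); "
            f"signed R^2 at power: "
            f"{float(self.fit_table.set_index('power').r_squared.get(self.power, np.nan)):.3f}",
            f"modules ({len(self.modules)} non-grey):",
        ]
        sizes = self.modules.sizes()
        for label in self.modules.modules:
            ve = (
                f", var.explained={self.eigengenes.variance_explained[label]:.2f}"
                if self.eigengenes is not None
                else ""
            )
            lines.append(f"  {label:<12} {sizes[label]:>5} genes{ve}")
        if GREY in sizes.index:
            lines.append(f"  {GREY:<12} {sizes[GREY]:>5} genes (unassigned)")
        if self.trait_stats is not None:
            lines.append("module-trait correlations (r, p):")
            cor, pv = self.trait_stats.correlation, self.trait_stats.p_value
            for m in cor.index:
                cells = "  ".join(
                    f"{c}: {cor.loc[m, c]:+.2f} ({pv.loc[m, c]:.2g})" for c in cor.columns
                )
                lines.append(f"  {m:<12} {cells}")
        return "\n".join(lines)
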