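"""Synthetic data with planted structure for every pipeline stage.

The generator emulates the statistical world the downstream analysis
assumes: a genes x samples expression matrix whose co-expression blocks are
driven by latent module factors, a binary recurrence-like trait correlated
with one module's factor, survival times whose hazard depends on designated
target genes, a PPI edge list denser within modules than between, and GMT
gene sets overlapping the planted modules.

The model for a gene g in module m at sample s is

    x_gs = lambda_g * f_ms + sqrt(1 - lambda_g^2) * eps_gs

with f and eps standard normal and the loading lambda_g drawn uniformly
from ``factor_loading_range``; every gene row therefore has expectation 0
and variance 1.  Background genes are pure noise.  The module eigengene of
a planted module estimates its factor, which makes parameter-recovery
tests sharp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import pointbiserialr

from coexppi.utils import CoexppiError, stream_rng

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "default_design",
    "generate_expression",
    "generate_traits",
    "generate_ppi",
    "generate_gene_sets",
    "generate_normal_cohort",
]

# stream ids for the single master seed
_EXPR, _TRAITS, _PPI, _SETS, _NORMAL = range(5)

# baseline hazard: median survival ~50 months at the average exposure
_BASELINE_HAZARD = np.log(2.0) / 50.0


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the planted world.

    ``module_sizes`` lists one size per planted module; the remaining
    ``background_genes`` genes carry no module signal.  ``ppi_coverage``
    is the fraction of genes present in the PPI universe at all — a
    drug-target interaction network covers only a minority of the genome,
    and the mapped network is driven by that intersection.  Designated
    ``target_genes`` are always part of the PPI universe (they are the
    drug's targets by construction).
    """

    n_genes: int
    n_samples: int
    module_sizes: tuple[int, ...]
    background_genes: int
    factor_loading_range: tuple[float, float] = (0.6, 0.9)
    trait_module_index: int = 0
    trait_point_biserial: float = 0.32
    target_genes: tuple[str, ...] = ()
    log_hazard_ratio: float = 1.0
    censoring_rate: float = 0.3
    ppi_within_prob: float = 0.35
    ppi_between_prob: float = 0.02
    ppi_coverage: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if sum(self.module_sizes) + self.background_genes != self.n_genes:
            raise CoexppiError(
                "module_sizes plus background_genes must sum to n_genes "
                f"({sum(self.module_sizes)} + {self.background_genes} != {self.n_genes})"
            )
        if any(m < 2 for m in self.module_sizes):
            raise CoexppiError("every planted module needs >= 2 genes (eigengene undefined below)")
        if not self.ppi_within_prob > self.ppi_between_prob:
            raise CoexppiError("ppi_within_prob must exceed ppi_between_prob")
        lo, hi = self.factor_loading_range
        if not (0 < lo <= hi <= 1):
            raise CoexppiError("factor_loading_range must lie in (0, 1]")
        if not 0 <= self.censoring_rate < 1:
            raise CoexppiError("censoring_rate must lie in [0, 1)")
        if self.module_sizes and not 0 <= self.trait_module_index < len(self.module_sizes):
            raise CoexppiError("trait_module_index out of range")
        for g in self.target_genes:
            if _gene_index(g, self.n_genes) is None:
                raise CoexppiError(f"target gene {g!r} is not among the {self.n_genes} genes")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"S{i:0{width}d}" for i in range(1, self.n_samples + 1)]

    @property
    def module_labels(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.module_sizes))]


def _gene_index(gene: str, n_genes: int):
    try:
        i = int(gene.lstrip("G"))
    except ValueError:
        return None
    return i - 1 if 1 <= i <= n_genes else None


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    module_of_gene: pd.Series           # planted label per non-background gene
    loading_of_gene: pd.Series          # lambda_g per gene (0 for background)
    factor_matrix: pd.DataFrame         # modules x samples
    gene_ids: list[str]
    trait_vector: pd.Series | None = None
    survival_times: pd.Series | None = None
    event_flags: pd.Series | None = None


def default_design(seed: int = 0) -> SyntheticDesign:
    """The package's reference world, sized for a desk-scale demo.

    Three co-expressed modules (45/35/25 genes) among 400 genes and 150
    samples; the largest module carries the recurrence trait and hosts the
    three survival-relevant target genes.  The PPI covers 5% of the genes:
    a drug-target network intersects only a small part of the
    transcriptome (in published module-projection analyses the mapped
    network holds on the order of 2% of the co-expression genes), so the
    mapped module network is an order of magnitude smaller than the
    co-expression modules.
    """
    return SyntheticDesign(
        n_genes=400,
        n_samples=150,
        module_sizes=(45, 35, 25),
        background_genes=295,
        factor_loading_range=(0.6, 0.9),
        trait_module_index=0,
        trait_point_biserial=0.32,
        target_genes=("G001", "G002", "G003"),
        log_hazard_ratio=1.0,
        censoring_rate=0.3,
        ppi_within_prob=0.35,
        ppi_between_prob=0.02,
        ppi_coverage=0.05,
        seed=seed,
    )


def generate_expression(design: SyntheticDesign) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the genes x samples matrix from the latent-factor model."""
    rng = stream_rng(design.seed, _EXPR)
    genes, samples = design.gene_ids, design.sample_ids
    n_mod = len(design.module_sizes)

    factors = rng.standard_normal((n_mod, design.n_samples))
    if n_mod:
        # factors are identified only up to location/scale; standardize
        # empirically so cohort means carry no spurious batch signal
        factors = (factors - factors.mean(axis=1, keepdims=True)) / factors.std(
            axis=1, keepdims=True
        )
    lo, hi = design.factor_loading_range

    values = np.empty((design.n_genes, design.n_samples))
    module_of_gene = {}
    loadings = np.zeros(design.n_genes)
    row = 0
    for m, size in enumerate(design.module_sizes):
        lam = rng.uniform(lo, hi, size=size)
        eps = rng.standard_normal((size, design.n_samples))
        values[row:row + size] = lam[:, None] * factors[m] + np.sqrt(1 - lam**2)[:, None] * eps
        loadings[row:row + size] = lam
        for g in genes[row:row + size]:
            module_of_gene[g] = design.module_labels[m]
        row += size
    values[row:] = rng.standard_normal((design.background_genes, design.n_samples))

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    truth = SyntheticTruth(
        module_of_gene=pd.Series(module_of_gene, name="module"),
        loading_of_gene=pd.Series(loadings, index=genes, name="loading"),
        factor_matrix=pd.DataFrame(factors, index=design.module_labels, columns=samples),
        gene_ids=list(genes),
    )
    return expr, truth


def _calibrate_binary_trait(factor: np.ndarray, noise: np.ndarray, target_r: float) -> np.ndarray:
    """Binary trait whose sample point-biserial correlation with the factor
    is as close as possible to ``target_r``.

    The trait is a median threshold of ``factor + sigma * noise``; the noise
    scale sigma is picked on a fixed grid by the realized sample correlation,
    so the calibration holds for the actual draw, not just in expectation.
    """
    sigmas = np.concatenate([[0.0], np.geomspace(0.02, 60.0, 400)])
    best, best_err = None, np.inf
    for sigma in sigmas:
        latent = factor + sigma * noise
        y = (latent > np.median(latent)).astype(int)
        if y.std() == 0:
            continue
        r = pointbiserialr(y, factor).correlation
        err = abs(r - target_r)
        if err < best_err:
            best, best_err = y, err
    if best is None:
        raise CoexppiError("could not calibrate binary trait (degenerate factor)")
    return best


def generate_traits(design: SyntheticDesign, truth: SyntheticTruth) -> pd.DataFrame:
    """Clinical table: survival time/event, recurrence, age, grade.

    Recurrence thresholds the trait module's factor plus calibrated noise.
    Survival is exponential with hazard h0 * exp(log_hazard_ratio * zbar)
    where zbar is the mean standardized expression of the target genes;
    censoring is independent exponential tuned to the requested rate.
    """
    rng = stream_rng(design.seed, _TRAITS)
    n = design.n_samples
    if not design.module_sizes:
        raise CoexppiError("trait generation needs at least one planted module")
    factor = truth.factor_matrix.iloc[design.trait_module_index].to_numpy()

    recurrence = _calibrate_binary_trait(
        factor, rng.standard_normal(n), design.trait_point_biserial
    )

    if design.target_genes:
        # standardized target expression; regenerating is not possible here,
        # so recompute from the truth loadings and factors plus implied noise
        expr, _ = generate_expression(design)
        sub = expr.loc[list(design.target_genes)].to_numpy()
        sub = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        zbar = sub.mean(axis=0)
    else:
        zbar = np.zeros(n)

    hazard = _BASELINE_HAZARD * np.exp(design.log_hazard_ratio * zbar)
    event_time = rng.exponential(1.0 / hazard)
    if design.censoring_rate > 0:
        def mean_censored(hc):
            return float(np.mean(hc / (hc + hazard))) - design.censoring_rate
        hc = brentq(mean_censored, 1e-8, 1e4)
        censor_time = rng.exponential(1.0 / hc, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)

    traits = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "recurrence": recurrence,
            "age": np.round(rng.normal(62, 10, size=n), 1),
            "grade": rng.integers(1, 5, size=n),
        },
        index=pd.Index(design.sample_ids, name="sample"),
    )
    truth.trait_vector = traits["recurrence"]
    truth.survival_times = traits["time"]
    truth.event_flags = traits["event"]
    return traits


def generate_ppi(
    design: SyntheticDesign,
    truth: SyntheticTruth,
    include_subthreshold: bool = False,
) -> pd.DataFrame:
    """Undirected PPI edge list: Bernoulli(ppi_within_prob) within planted
    modules, Bernoulli(ppi_between_prob) otherwise, over the covered genes.

    Confidence scores are uniform on [0.4, 1.0] so the fixture passes the
    standard medium-confidence filter unchanged; ``include_subthreshold``
    appends an extra Bernoulli(ppi_between_prob) layer of edges scored
    below 0.4 to exercise the filter.  The designated target genes always
    interact pairwise: the PPI emulates a drug-target network seeded on
    those proteins, which are its best-documented interactions.
    """
    rng = stream_rng(design.seed, _PPI)
    genes = np.array(truth.gene_ids)
    n = len(genes)

    if design.ppi_coverage >= 1.0:
        covered = np.arange(n)
    else:
        n_cov = max(2, int(round(design.ppi_coverage * n)))
        covered = rng.choice(n, size=n_cov, replace=False)
        forced = [i for g in design.target_genes if (i := _gene_index(g, n)) is not None]
        covered = np.unique(np.concatenate([covered, np.array(forced, dtype=int)]))

    module_idx = np.full(n, -1)
    offset = 0
    for m, size in enumerate(design.module_sizes):
        module_idx[offset:offset + size] = m
        offset += size

    cov = np.sort(covered)
    ii, jj = np.triu_indices(len(cov), k=1)
    gi, gj = cov[ii], cov[jj]
    same = (module_idx[gi] >= 0) & (module_idx[gi] == module_idx[gj])
    p = np.where(same, design.ppi_within_prob, design.ppi_between_prob)
    keep = rng.uniform(size=p.size) < p
    if design.target_genes:
        targets = {_gene_index(g, n) for g in design.target_genes}
        both_targets = np.isin(gi, list(targets)) & np.isin(gj, list(targets))
        keep |= both_targets
    scores = rng.uniform(0.4, 1.0, size=int(keep.sum()))

    frames = [pd.DataFrame({
        "protein1": genes[gi[keep]],
        "protein2": genes[gj[keep]],
        "combined_score": scores,
    })]
    if include_subthreshold:
        keep2 = (rng.uniform(size=p.size) < design.ppi_between_prob) & ~keep
        frames.append(pd.DataFrame({
            "protein1": genes[gi[keep2]],
            "protein2": genes[gj[keep2]],
            "combined_score": rng.uniform(0.0, 0.4, size=int(keep2.sum())),
        }))
    edges = pd.concat(frames, ignore_index=True)
    return edges.reset_index(drop=True)


def generate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int,
    overlap_fraction: float,
    seed: int = 0,
) -> "GeneSetCollection":
    """Gene-set collection with one planted "positive" set per module.

    Each positive set has its module's size and draws ``overlap_fraction``
    of its members from that module (the rest from outside); the remaining
    sets are uniform random draws.
    """
    from coexppi.enrichment import GeneSetCollection

    if not 0 <= overlap_fraction <= 1:
        raise CoexppiError("overlap_fraction must lie in [0, 1]")
    rng = stream_rng(seed, _SETS)
    universe = np.array(truth.gene_ids)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}

    modules = truth.module_of_gene.groupby(truth.module_of_gene).groups
    for label in sorted(modules):
        members = np.array(sorted(modules[label]))
        size = len(members)
        k = int(round(overlap_fraction * size))
        inside = rng.choice(members, size=k, replace=False)
        outside_pool = np.setdiff1d(universe, members)
        outside = rng.choice(outside_pool, size=size - k, replace=False)
        name = f"POS_{label}"
        sets[name] = tuple(sorted(np.concatenate([inside, outside])))
        descriptions[name] = f"planted positive set for module {label}"

    i = 0
    while len(sets) < n_sets:
        i += 1
        size = int(rng.integers(10, 41))
        name = f"RAND_{i:04d}"
        sets[name] = tuple(sorted(rng.choice(universe, size=size, replace=False)))
        descriptions[name] = "random set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def generate_normal_cohort(
    design: SyntheticDesign,
    truth: SyntheticTruth,
    n_samples: int = 60,
    target_shift: float = 1.5,
) -> pd.DataFrame:
    """External "normal tissue" cohort for differential expression.

    Fresh samples from the same latent-factor model (same loadings, new
    factors and noise) with the designated target genes shifted *down* by
    ``target_shift`` standard deviations — i.e. the tumor cohort
    over-expresses the targets relative to normal tissue, and only the
    targets carry a planted tumor/normal difference.
    """
    rng = stream_rng(design.seed, _NORMAL)
    n_mod = len(design.module_sizes)
    factors = rng.standard_normal((n_mod, n_samples))
    if n_mod:
        factors = (factors - factors.mean(axis=1, keepdims=True)) / factors.std(
            axis=1, keepdims=True
        )
    lam = truth.loading_of_gene.to_numpy()

    module_idx = np.full(design.n_genes, -1)
    offset = 0
    for m, size in enumerate(design.module_sizes):
        module_idx[offset:offset + size] = m
        offset += size

    eps = rng.standard_normal((design.n_genes, n_samples))
    values = np.sqrt(1 - lam**2)[:, None] * eps
    in_mod = module_idx >= 0
    values[in_mod] += lam[in_mod, None] * factors[module_idx[in_mod]]

    for g in design.target_genes:
        i = _gene_index(g, design.n_genes)
        values[i] -= target_shift

    width = len(str(n_samples))
    samples = [f"N{i:0{width}d}" for i in range(1, n_samples + 1)]
    return pd.DataFrame(values, index=pd.Index(truth.gene_ids, name="gene"), columns=samples)


def write_fixture_files(outdir, design: SyntheticDesign) -> dict:
    """Generate one full fixture and persist it as plain-text files."""
    from pathlib import Path

    from coexppi.enrichment import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth = generate_expression(design)
    traits = generate_traits(design, truth)
    ppi = generate_ppi(design, truth)
    sets = generate_gene_sets(truth, n_sets=20, overlap_fraction=0.8, seed=design.seed)
    normal = generate_normal_cohort(design, truth)

    expr.to_csv(outdir / "expression.tsv", sep="\t")
    normal.to_csv(outdir / "normal.tsv", sep="\t")
    traits.to_csv(outdir / "traits.csv")
    ppi.to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    write_gmt(sets, outdir / "gene_sets.gmt")
    truth.module_of_gene.rename_axis("gene").to_csv(outdir / "true_modules.tsv", sep="\t")
    return {
        "expression": outdir / "expression.tsv",
        "normal": outdir / "normal.tsv",
        "traits": outdir / "traits.csv",
        "ppi": outdir / "ppi.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "true_modules": outdir / "true_modules.tsv",
    }
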