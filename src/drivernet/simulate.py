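"""Multi-cohort synthetic data with a planted master regulator.

The generator emulates the statistical structure the downstream network
analysis assumes: several cohorts share one ground-truth regulatory DAG
in which a designated regulator directly controls many genes; expression
follows a linear-Gaussian structural equation model (SEM) evaluated in
topological order; a subset of genes carries a cis-acting genetic effect
(one locus per mapped gene); disease samples lose gene-gene coordination
through a multiplicative attenuation of every path coefficient,
calibrated so that the mean absolute pairwise correlation among module
genes drops by a configured fraction (default 71%) relative to
controls; clinical traits load on a latent severity correlated with the
regulator's expression; and a regulator-knockout experiment provides a
ground-truth differential-expression signature.

The model for gene ``j`` in sample ``s`` is::

    x_js = sum_{i in pa(j)} beta_ij * x_is + gamma_j * L_js + eps_js

with ``eps_js ~ N(0, sigma_j^2)`` and ``L_js`` the allele dosage at the
gene's mapped locus (``gamma_j = 0`` for unmapped genes).  In disease
samples every ``beta_ij`` is replaced by ``a * beta_ij`` with
``a in [0, 1]``.  The implied covariance in matrix form is
``(I - B)^-T D (I - B)^-1`` where ``B[i, j] = beta_ij`` and ``D`` is the
diagonal of exogenous variances — this closed form drives both the
attenuation calibration and the generator's convergence tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    APOE_GENOTYPES,
    Cohort,
    CohortCollection,
    ExpressionMatrix,
    GenotypeMatrix,
    TraitTable,
)

# independent RNG stream labels derived from the base seed
_STREAM_DAG = 1
_STREAM_COHORT = 2
_STREAM_KNOCKOUT = 3
_STREAM_TRAITS = 4


def _default_trait_loadings() -> dict[str, float]:
    return {
        "CDR": 0.6,
        "Braak": 0.6,
        "CERAD": 0.6,
        "MMSE": 0.5,
        "PLQ_Mn": 0.5,
        "NTrSum": 0.5,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions.

    ``n_cohorts`` defaults to the eight cohort datasets the consensus
    correlation analysis expects.  ``attenuation_target`` is the
    fractional loss of mean absolute module correlation in disease
    samples (0.71 = 71% loss); the edge multiplier ``a`` realising it is
    calibrated at generation time, not set directly.
    """

    n_genes: int = 50
    n_cohorts: int = 8
    n_control: int = 500
    n_disease: int = 500
    edge_density: float = 0.05
    regulator_out_degree: int = 10
    beta_range: tuple[float, float] = (0.5, 0.9)
    neg_edge_prob: float = 0.0
    sigma_range: tuple[float, float] = (0.5, 1.0)
    eqtl_fraction: float = 0.3
    eqtl_effect: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    attenuation_target: float = 0.71
    knockout_n: int = 100
    # clamp depth (log2 units) chosen so that a total path effect at the
    # relevance threshold produces exactly the DEG fold-change gate:
    # shift * deg_effect_threshold = log2(1.2)
    knockout_shift: float = float(np.log2(1.2)) / 0.3
    deg_effect_threshold: float = 0.3
    baseline_expression: float = 8.0
    severity_coupling: float = 0.7
    trait_loadings: dict[str, float] = field(default_factory=_default_trait_loadings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.n_cohorts < 1:
            raise ValueError("need at least 1 cohort")
        if not 0.0 <= self.attenuation_target <= 1.0:
            raise ValueError("attenuation target must be in [0, 1]")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge density must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie within (0, 0.5]")
        if min(self.beta_range) <= 0.0:
            raise ValueError("beta magnitude range must be positive")
        if min(self.sigma_range) <= 0.0:
            raise ValueError("noise scales must be strictly positive")
        if self.regulator_out_degree >= self.n_genes:
            raise ValueError(
                f"regulator out-degree {self.regulator_out_degree} must be "
                f"< gene count {self.n_genes}"
            )
        if self.n_control < 0 or self.n_disease < 0:
            raise ValueError("group sizes must be nonnegative")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TrueNetwork:
    """Ground-truth weighted DAG plus the companion simulation maps.

    ``edges`` maps ``(source, target) -> beta`` (all nonzero);
    ``sigma`` the per-gene exogenous noise SD; ``eqtl`` maps a gene to
    its (locus id, genetic effect, minor allele frequency); ``module``
    is the planted regulator together with its descendants — the
    generative analog of a disease-dysregulated co-expression module.
    ``genes`` is in topological order of the DAG.
    """

    genes: list[str]
    edges: dict[tuple[str, str], float]
    regulator: str
    sigma: dict[str, float]
    eqtl: dict[str, tuple[str, float, float]]
    module: set[str]

    def __post_init__(self) -> None:
        order = {g: i for i, g in enumerate(self.genes)}
        for (u, v), beta in self.edges.items():
            if beta == 0.0:
                raise ValueError(f"zero path coefficient on edge {u}->{v}")
            if order[u] >= order[v]:
                raise ValueError("gene list is not a topological order")
        for g, s in self.sigma.items():
            if not s > 0:
                raise ValueError(f"noise SD for {g} must be positive")

    # -- structure helpers -------------------------------------------------
    @property
    def loci(self) -> list[str]:
        return [locus for locus, _, _ in self.eqtl.values()]

    def adjacency(self) -> pd.DataFrame:
        """Weighted adjacency B with B.loc[i, j] = beta for edge i -> j."""
        p = len(self.genes)
        B = pd.DataFrame(
            np.zeros((p, p)), index=self.genes, columns=self.genes
        )
        for (u, v), beta in self.edges.items():
            B.loc[u, v] = beta
        return B

    def children(self, gene: str) -> set[str]:
        return {v for (u, v) in self.edges if u == gene}

    def descendants(self, gene: str) -> set[str]:
        """All genes reachable from ``gene`` via directed edges."""
        out: dict[str, set[str]] = {g: set() for g in self.genes}
        for u, v in self.edges:
            out[u].add(v)
        seen: set[str] = set()
        stack = [gene]
        while stack:
            node = stack.pop()
            for child in out[node]:
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen

    # -- closed-form moments ----------------------------------------------
    def exogenous_variances(self, with_genetics: bool = True) -> pd.Series:
        var = pd.Series({g: self.sigma[g] ** 2 for g in self.genes})
        if with_genetics:
            for g, (_, gamma, maf) in self.eqtl.items():
                var[g] += gamma**2 * 2.0 * maf * (1.0 - maf)
        return var.loc[self.genes]

    def implied_covariance(
        self, attenuation: float = 1.0, with_genetics: bool = True
    ) -> pd.DataFrame:
        """SEM-implied gene covariance (I - aB)^-T D (I - aB)^-1."""
        B = self.adjacency().to_numpy() * attenuation
        p = len(self.genes)
        inv = np.linalg.inv(np.eye(p) - B)  # rows: source, cols: target
        D = np.diag(self.exogenous_variances(with_genetics).to_numpy())
        cov = inv.T @ D @ inv
        return pd.DataFrame(cov, index=self.genes, columns=self.genes)

    def total_effects(self, source: str) -> pd.Series:
        """Sum over directed paths of path-coefficient products, per target."""
        B = self.adjacency().to_numpy()
        p = len(self.genes)
        T = np.linalg.inv(np.eye(p) - B) - np.eye(p)
        i = self.genes.index(source)
        return pd.Series(T[i], index=self.genes).drop(source)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "beta": b}
            for (u, v), b in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "beta"])


@dataclass
class TrueDEGSet:
    """Ground-truth knockout signature: signed descendants of the target."""

    target: str
    up: set[str]
    down: set[str]
    effects: pd.Series  # total path effect of target on every other gene

    @property
    def genes(self) -> set[str]:
        return self.up | self.down


@dataclass
class KnockoutExperiment:
    wildtype: ExpressionMatrix
    knockout: ExpressionMatrix
    true_degs: TrueDEGSet


# ---------------------------------------------------------------------------
# ground-truth DAG
# ---------------------------------------------------------------------------

def generate_true_dag(config: SimulationConfig) -> TrueNetwork:
    """Plant a high-out-degree regulator in a random sparse DAG.

    The regulator is first in a random topological order and receives
    exactly ``regulator_out_degree`` direct targets; remaining ordered
    non-regulator pairs receive an edge independently at
    ``edge_density``.  Acyclicity holds by construction because every
    edge points forward in the order.
    """
    rng = np.random.default_rng([_STREAM_DAG, config.seed])
    p = config.n_genes
    width = len(str(p))
    names = [f"G{i:0{width}d}" for i in range(1, p + 1)]
    # random topological order with the regulator first
    order = list(rng.permutation(names))
    regulator = order[0]
    rest = order[1:]

    lo, hi = config.beta_range

    def draw_beta() -> float:
        mag = rng.uniform(lo, hi)
        sign = -1.0 if rng.random() < config.neg_edge_prob else 1.0
        return sign * mag

    edges: dict[tuple[str, str], float] = {}
    child_idx = rng.choice(len(rest), size=config.regulator_out_degree, replace=False)
    for i in sorted(child_idx):
        edges[(regulator, rest[i])] = draw_beta()
    for i in range(len(rest)):
        for j in range(i + 1, len(rest)):
            if rng.random() < config.edge_density:
                edges[(rest[i], rest[j])] = draw_beta()

    sigma = {
        g: float(rng.uniform(*config.sigma_range)) for g in order
    }

    # the regulator is always genetically anchored: the causal-test stage
    # needs an instrument at the hub to orient its edges
    n_mapped = max(1, int(round(config.eqtl_fraction * p)))
    others = rng.choice(rest, size=n_mapped - 1, replace=False) if n_mapped > 1 else []
    mapped = [regulator] + list(others)
    eqtl: dict[str, tuple[str, float, float]] = {}
    for k, g in enumerate(mapped):
        maf = float(rng.uniform(*config.maf_range))
        eqtl[g] = (f"L{k + 1:0{width}d}", config.eqtl_effect, maf)

    truth = TrueNetwork(
        genes=order,
        edges=edges,
        regulator=regulator,
        sigma=sigma,
        eqtl=eqtl,
        module=set(),
    )
    truth.module = {regulator} | truth.descendants(regulator)
    return truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    truth: TrueNetwork,
    n_samples: int,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg dosages, one independent locus per mapped gene."""
    if n_samples < 1:
        raise ValueError("empty sample set")
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    loci, mafs = [], []
    for _, (locus, _, maf) in sorted(truth.eqtl.items(), key=lambda kv: kv[1][0]):
        loci.append(locus)
        mafs.append(maf)
    dosages = rng.binomial(2, np.asarray(mafs)[:, None], size=(len(loci), n_samples))
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=loci, columns=sample_ids)
    )


# ---------------------------------------------------------------------------
# attenuation calibration and cohort simulation
# ---------------------------------------------------------------------------

def _module_mean_abs_corr(truth: TrueNetwork, attenuation: float) -> float:
    module = sorted(truth.module, key=truth.genes.index)
    if len(module) < 2:
        raise ValueError("module has fewer than 2 genes; no pairwise correlation")
    cov = truth.implied_covariance(attenuation).loc[module, module].to_numpy()
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    iu = np.triu_indices_from(corr, k=1)
    return float(np.mean(np.abs(corr[iu])))


def calibrate_attenuation(
    truth: TrueNetwork, config: SimulationConfig, tol: float = 1e-6
) -> float:
    """Bisection for the edge multiplier hitting the target correlation loss.

    Solves for ``a`` such that the population mean absolute pairwise
    correlation among module genes under ``a * B`` is reduced by
    ``attenuation_target`` relative to ``B`` itself, using the
    SEM-implied covariance (exact, no sampling noise).
    """
    target = config.attenuation_target
    if target == 0.0:
        return 1.0
    base = _module_mean_abs_corr(truth, 1.0)

    def reduction(a: float) -> float:
        return 1.0 - _module_mean_abs_corr(truth, a) / base

    lo_val, hi_val = reduction(0.0), reduction(1.0)  # hi_val == 0
    if not (hi_val <= target <= lo_val):
        raise ValueError(
            f"attenuation target {target:.3f} not bracketed: reduction ranges "
            f"over [{hi_val:.3f}, {lo_val:.3f}] for a in [1, 0]"
        )
    lo, hi = 0.0, 1.0  # reduction(lo) >= target >= reduction(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if reduction(mid) >= target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sem_sample(
    truth: TrueNetwork,
    n: int,
    rng: np.random.Generator,
    attenuation: float = 1.0,
    genotypes: GenotypeMatrix | None = None,
    clamp: dict[str, float] | None = None,
) -> np.ndarray:
    """Draw n samples (genes x n) in topological order.

    ``clamp`` fixes listed genes to a constant (their incoming edges and
    noise are overridden; outgoing edges still propagate).
    """
    p = len(truth.genes)
    idx = {g: i for i, g in enumerate(truth.genes)}
    X = np.zeros((p, n))
    parents: dict[str, list[tuple[int, float]]] = {g: [] for g in truth.genes}
    for (u, v), beta in truth.edges.items():
        parents[v].append((idx[u], beta))
    for g in truth.genes:
        i = idx[g]
        if clamp and g in clamp:
            X[i] = clamp[g]
            continue
        x = rng.normal(0.0, truth.sigma[g], size=n)
        for j, beta in parents[g]:
            x += attenuation * beta * X[j]
        if genotypes is not None and g in truth.eqtl:
            locus, gamma, _ = truth.eqtl[g]
            x += gamma * genotypes.dosages.loc[locus].to_numpy(dtype=float)
        X[i] = x
    return X


def simulate_cohorts(
    truth: TrueNetwork,
    config: SimulationConfig,
    attenuation: float | None = None,
) -> CohortCollection:
    """Generate expression + genotype + diagnosis data for every cohort.

    Cohorts share the truth but draw independent noise, genotypes and
    samples.  Disease samples use edge coefficients ``a * beta`` with
    ``a`` calibrated (unless supplied) so module coordination drops by
    the configured fraction.
    """
    if config.n_disease > 0 and attenuation is None:
        attenuation = calibrate_attenuation(truth, config)
    if attenuation is None:
        attenuation = 1.0
    if not np.isfinite(attenuation):
        raise ValueError("non-finite attenuation coefficient")

    cohorts = []
    for d in range(1, config.n_cohorts + 1):
        rng = np.random.default_rng([_STREAM_COHORT, config.seed, d])
        name = f"cohort{d}"
        n = config.n_control + config.n_disease
        sample_ids = [f"{name}_S{i:04d}" for i in range(1, n + 1)]
        geno = simulate_genotypes(truth, n, rng, sample_ids) if truth.eqtl else None
        ctrl_geno = dis_geno = None
        if geno is not None:
            ctrl_geno = GenotypeMatrix(geno.dosages.iloc[:, : config.n_control])
            dis_geno = GenotypeMatrix(geno.dosages.iloc[:, config.n_control :])
        blocks = []
        if config.n_control:
            blocks.append(
                _sem_sample(truth, config.n_control, rng, 1.0, ctrl_geno)
            )
        if config.n_disease:
            blocks.append(
                _sem_sample(truth, config.n_disease, rng, attenuation, dis_geno)
            )
        X = np.concatenate(blocks, axis=1)
        expr = ExpressionMatrix(
            pd.DataFrame(X, index=truth.genes, columns=sample_ids),
            value_kind="residual",
            dataset=name,
        )
        diagnosis = ["control"] * config.n_control + ["AD"] * config.n_disease
        traits = TraitTable(
            pd.DataFrame({"diagnosis": diagnosis}, index=sample_ids)
        )
        cohorts.append(Cohort(name, expr, geno, traits))
    return CohortCollection(cohorts, attenuation=attenuation)


# ---------------------------------------------------------------------------
# knockout experiment
# ---------------------------------------------------------------------------

def true_deg_set(
    truth: TrueNetwork, target: str, effect_threshold: float
) -> TrueDEGSet:
    """Descendants whose total path effect magnitude exceeds the threshold.

    Signs record the direction of change in the knockout, where the
    target is clamped *below* its wildtype mean: a positive path effect
    means the gene goes down when the target is removed.
    """
    if target not in truth.genes:
        raise ValueError(f"knockout target {target!r} not in network")
    effects = truth.total_effects(target)
    reachable = truth.descendants(target)
    up, down = set(), set()
    for g, eff in effects.items():
        if g in reachable and abs(eff) > effect_threshold:
            (down if eff > 0 else up).add(g)
    return TrueDEGSet(target=target, up=up, down=down, effects=effects)


def simulate_knockout(
    truth: TrueNetwork,
    config: SimulationConfig,
    target: str | None = None,
    contrast: str = "KO",
    seed_offset: int = 0,
) -> KnockoutExperiment:
    """Paired wildtype/knockout expression with ground-truth DEGs.

    Wildtype samples follow the SEM around a constant baseline (log2
    scale); knockout samples clamp the target ``knockout_shift`` log2
    units below its wildtype mean with zero variance, with outgoing
    edges intact so the perturbation propagates.  Genetic effects are
    omitted: the experiment emulates cultured cells from one genetic
    background.
    """
    if target is None:
        target = truth.regulator
    if target not in truth.genes:
        raise ValueError(f"knockout target {target!r} not in network")
    rng = np.random.default_rng([_STREAM_KNOCKOUT, config.seed, seed_offset])
    n = config.knockout_n
    base = config.baseline_expression
    wt = _sem_sample(truth, n, rng)
    ko = _sem_sample(truth, n, rng, clamp={target: -config.knockout_shift})
    genes = truth.genes
    wt_ids = [f"{contrast}_WT{i:03d}" for i in range(1, n + 1)]
    ko_ids = [f"{contrast}_KO{i:03d}" for i in range(1, n + 1)]
    wildtype = ExpressionMatrix(
        pd.DataFrame(wt + base, index=genes, columns=wt_ids),
        value_kind="log",
        dataset=f"{contrast}_wildtype",
    )
    knockout = ExpressionMatrix(
        pd.DataFrame(ko + base, index=genes, columns=ko_ids),
        value_kind="log",
        dataset=f"{contrast}_knockout",
    )
    degs = true_deg_set(truth, target, config.deg_effect_threshold)
    return KnockoutExperiment(wildtype=wildtype, knockout=knockout, true_degs=degs)


# ---------------------------------------------------------------------------
# clinical traits
# ---------------------------------------------------------------------------

def _quantile_bins(score: np.ndarray, n_bins: int) -> np.ndarray:
    """Monotone map of a continuous score onto 0..n_bins-1 by rank."""
    order = np.argsort(score, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(score))
    return (ranks * n_bins) // len(score)


_TRAIT_BINS = {"CDR": 6, "Braak": 7, "CERAD": 4, "MMSE": 31}
_REVERSED_TRAITS = {"CERAD", "MMSE"}  # low value = severe disease


def simulate_traits(
    cohorts: CohortCollection,
    truth: TrueNetwork,
    config: SimulationConfig,
) -> CohortCollection:
    """Attach clinical trait tables driven by a latent severity.

    Severity mixes the standardized regulator expression with
    independent noise (``severity_coupling`` sets the weight); each
    trait score is ``lambda_t * severity + N(0, 1)`` mapped monotonically
    onto its clinical scale (CERAD and MMSE are reversed scales).
    Demographics (sex, age of death, APOE genotype) are drawn
    independently.  Returns the collection with traits replaced.
    """
    unknown = set(config.trait_loadings) - set(_TRAIT_BINS) - {"PLQ_Mn", "NTrSum"}
    if unknown:
        raise ValueError(f"unknown trait name(s): {sorted(unknown)}")
    c = config.severity_coupling
    for d, cohort in enumerate(cohorts, start=1):
        rng = np.random.default_rng([_STREAM_TRAITS, config.seed, d])
        expr = cohort.expression
        seed_expr = expr.values.loc[truth.regulator].to_numpy(dtype=float)
        z = (seed_expr - seed_expr.mean()) / seed_expr.std()
        n = len(z)
        severity = c * z + np.sqrt(max(0.0, 1.0 - c**2)) * rng.normal(size=n)
        raw_scores: dict[str, np.ndarray] = {"severity": severity}
        cols: dict[str, np.ndarray | list] = {}
        for trait, lam in config.trait_loadings.items():
            score = lam * severity + rng.normal(size=n)
            raw_scores[trait] = score
            if trait in _REVERSED_TRAITS:
                score = -score
            if trait in _TRAIT_BINS:
                binned = _quantile_bins(score, _TRAIT_BINS[trait])
                if trait == "CERAD":
                    binned = binned + 1  # CERAD runs 1 (definite AD) .. 4 (control)
                cols[trait] = binned.astype(float)
            else:  # nonnegative density scales (PLQ_Mn, NTrSum)
                cols[trait] = np.log1p(np.exp(1.5 * score)) * 4.0
        cols["sex"] = rng.choice(["F", "M"], size=n)
        cols["AOD"] = np.clip(np.round(rng.normal(85.0, 6.0, size=n), 1), 60, 105)
        cols["APOE"] = rng.choice(APOE_GENOTYPES, size=n, p=[0.10, 0.62, 0.28])
        table = pd.DataFrame(cols, index=expr.samples)
        if cohort.traits is not None:
            table = pd.concat([cohort.traits.table, table], axis=1)
        cohort.traits = TraitTable(table)
        cohort.trait_scores = pd.DataFrame(raw_scores, index=expr.samples)
    return cohorts
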