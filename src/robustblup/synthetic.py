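"""Synthetic genotypes, pedigrees, genetic values and phenotypes.

The generator reproduces the statistical structure the predictors assume:
g ~ N(0, K sigma_g2) with K built from binomially sampled marker dosages,
and residuals from a normal, scaled-t(nu) or Laplace family, each scaled so
Var(e_i) = sigma_e2 / n_i.  Matching the residual variance across families
keeps heritability comparable when methods are compared.  Optional
contamination adds a sign-balanced mean shift (in residual-SD units) to a
random fraction of records — the "undeclared preferential treatment"
scenario — and optional major-gene effects add sparse large effects to the
genetic values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mixedmodels import DispersionParams
from .relmat import GenotypeMatrix, KinshipMatrix, PedigreeTable, compute_vanraden_g


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults: n=200 individuals, p=500 markers, h2 = 0.3
    (sigma_g2=0.3, sigma_e2=0.7), Gaussian residuals, no replication
    structure, no contamination.
    """

    n_individuals: int = 200
    n_markers: int = 500
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    sigma_g2: float = 0.3
    sigma_e2: float = 0.7
    residual_family: str = "normal"  # normal | student_t | laplace
    nu: float | None = None
    n_counts: np.ndarray | None = None
    contamination_fraction: float = 0.0
    contamination_shift: float = 0.0  # in residual SDs
    major_gene_effects: np.ndarray | None = None  # added to g, length n
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination_fraction < 1.0):
            raise ValueError("contamination fraction must be in [0, 1)")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be non-negative")
        if self.residual_family not in ("normal", "student_t", "laplace"):
            raise ValueError(f"unknown family {self.residual_family!r}")
        if self.residual_family == "student_t":
            if self.nu is None or self.nu <= 2:
                raise ValueError("student_t family requires nu > 2")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix | None
    K: KinshipMatrix
    g_true: np.ndarray
    e_true: np.ndarray
    y: np.ndarray
    outlier_flags: np.ndarray
    params_true: DispersionParams
    n_counts: np.ndarray = field(default_factory=lambda: np.ones(0))
    contamination: np.ndarray | None = None


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Binomial(2, p_j) dosages at frequencies drawn uniformly in range.

    Monomorphic columns are redrawn so G is always defined.
    """
    if config.n_markers < 1:
        raise ValueError("need at least one marker")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.allele_freq_range
    n, p = config.n_individuals, config.n_markers
    freqs = rng.uniform(lo, hi, size=p)
    X = rng.binomial(2, freqs, size=(n, p)).astype(float)
    for _ in range(100):
        mono = X.std(axis=0) == 0
        if not mono.any():
            break
        X[:, mono] = rng.binomial(2, freqs[mono], size=(n, int(mono.sum())))
    return GenotypeMatrix(
        sample_ids=[f"id{i:04d}" for i in range(n)],
        marker_ids=[f"m{j:05d}" for j in range(p)],
        dosages=X,
    )


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    family_size: int,
    seed: int | None = None,
) -> PedigreeTable:
    """Forward random-mating pedigree with discrete generations."""
    if n_founders < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str | None, str | None]] = []
    current = [f"F{i}" for i in range(n_founders)]
    records.extend((ind, None, None) for ind in current)
    counter = 0
    for gen in range(1, n_generations + 1):
        nxt = []
        n_pairs = max(1, len(current) // 2)
        for _ in range(n_pairs):
            sire, dam = rng.choice(len(current), size=2, replace=False)
            for _ in range(family_size):
                child = f"G{gen}_{counter}"
                counter += 1
                records.append((child, current[sire], current[dam]))
                nxt.append(child)
        current = nxt
    return PedigreeTable(records=records)


def simulate_genetic_values(
    K: KinshipMatrix,
    sigma_g2: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw g ~ N(0, K sigma_g2) via the eigen square root.

    Negative eigenvalues (numerical, or from a singular genomic K) are
    clipped at zero.
    """
    if sigma_g2 < 0:
        raise ValueError("sigma_g2 must be non-negative")
    if sigma_g2 == 0:
        return np.zeros(K.n)
    if rng is None:
        rng = np.random.default_rng(seed)
    vals, vecs = np.linalg.eigh(K.values)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return np.sqrt(sigma_g2) * (root @ rng.standard_normal(K.n))


def _draw_residuals(config: SimulationConfig, n_counts: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Residuals with Var(e_i) = sigma_e2 / n_i for every family."""
    n = n_counts.size
    se = np.sqrt(config.sigma_e2 / n_counts)
    if config.sigma_e2 == 0:
        return np.zeros(n)
    fam = config.residual_family
    if fam == "normal":
        return se * rng.standard_normal(n)
    if fam == "student_t":
        nu = config.nu
        tau = np.sqrt((nu - 2.0) / nu * config.sigma_e2 / n_counts)
        return tau * rng.standard_t(nu, size=n)
    # laplace: Var = 2 b^2, so b = sigma_e / sqrt(2 n_i)
    b = np.sqrt(config.sigma_e2 / (2.0 * n_counts))
    return rng.laplace(0.0, b, size=n)


def simulate_phenotypes(
    g_true: np.ndarray,
    config: SimulationConfig,
    K: KinshipMatrix,
    genotypes: GenotypeMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Phenotypes y = g + e (+ contamination), with flags for outliers.

    Contamination shifts a random pi-fraction of records by
    contamination_shift * sigma_e with random sign.  Major-gene effects, if
    configured, are added to g before phenotypes are formed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = np.asarray(g_true, dtype=float).copy()
    n = g.size
    if config.major_gene_effects is not None:
        mg = np.asarray(config.major_gene_effects, dtype=float)
        if mg.shape != g.shape:
            raise ValueError("major_gene_effects length must match g")
        g = g + mg
    n_counts = (np.ones(n) if config.n_counts is None
                else np.asarray(config.n_counts, dtype=float))
    e = _draw_residuals(config, n_counts, rng)
    flags = np.zeros(n, dtype=bool)
    contamination = np.zeros(n)
    if config.contamination_fraction > 0 and config.contamination_shift != 0:
        n_out = int(round(config.contamination_fraction * n))
        idx = rng.choice(n, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        contamination[idx] = (signs * config.contamination_shift
                              * np.sqrt(config.sigma_e2))
        flags[idx] = True
    y = g + e + contamination
    nu = config.nu if config.residual_family == "student_t" else None
    params = DispersionParams(
        sigma_g2=max(config.sigma_g2, 1e-12),
        sigma_e2=max(config.sigma_e2, 1e-12),
        nu=nu,
    )
    return SimulatedDataset(
        genotypes=genotypes, K=K, g_true=g, e_true=e,
        y=y, outlier_flags=flags, params_true=params, n_counts=n_counts,
        contamination=contamination,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genotypes -> G -> genetic values -> phenotypes in one call."""
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config, rng=rng)
    K = compute_vanraden_g(geno)
    # genomic G is singular by construction when p < n or from centering;
    # a tiny ridge keeps K^-1 well defined for the solvers
    K = KinshipMatrix(labels=K.labels,
                      values=K.values + 1e-6 * np.eye(K.n),
                      kind=K.kind, meta=K.meta)
    g = simulate_genetic_values(K, config.sigma_g2, rng=rng)
    return simulate_phenotypes(g, config, K, genotypes=geno, rng=rng)
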