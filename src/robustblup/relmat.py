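"""Relationship (kinship) matrices: genomic G from marker dosages and
pedigree A via the tabular method.

The genomic matrix follows VanRaden's first method,

    G = (X - P)(X - P)' / (ploidy * sum_k p_k (1 - p_k)),

with ``P`` the matrix of per-marker expected dosages (``ploidy * p_k``) and
``p_k`` the allele frequency of marker ``k``.  For biallelic SNP dosages in
{0, 1, 2} the ploidy is 2 and the denominator is the familiar
``2 * sum p(1-p)``; for presence/absence markers coded {0, 1} (e.g. DArT)
the dosage ceiling is 1 and the denominator drops the factor of 2.

The pedigree (numerator) matrix A uses the standard tabular recursion:
``a_ii = 1 + a_sd / 2`` and ``a_ij = (a_js + a_jd) / 2`` for ``j`` preceding
``i``, with unknown parents contributing zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

UNKNOWN_PARENTS = ("0", "NA", "", None)


@dataclass
class GenotypeMatrix:
    """Marker dosages for a set of samples.

    Parameters
    ----------
    sample_ids : ordered unique sample labels (length n).
    marker_ids : ordered unique marker labels (length p).
    dosages : (n, p) float array of allele counts; NaN marks missing calls.
    ploidy : maximum dosage code, 2 for SNPs coded 0/1/2, 1 for
        dominant/presence-absence markers coded 0/1.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if len(self.sample_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lengths do not match dosage shape")
        if len(set(self.sample_ids)) != n or len(set(self.marker_ids)) != p:
            raise ValueError("sample/marker ids must be unique")
        observed = self.dosages[~np.isnan(self.dosages)]
        valid = set(range(self.ploidy + 1))
        if not np.all(np.isin(observed, sorted(valid))):
            bad = sorted(set(observed.tolist()) - valid)
            raise ValueError(f"dosage codes outside {{0..{self.ploidy}}}: {bad}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PedigreeTable:
    """Ordered (individual, sire, dam) triples; unknown parent = sentinel.

    Records must be topologically sortable (parents before offspring); the
    constructor sorts them and rejects cycles.
    """

    records: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        norm = []
        for ind, sire, dam in self.records:
            sire = None if sire in UNKNOWN_PARENTS else str(sire)
            dam = None if dam in UNKNOWN_PARENTS else str(dam)
            norm.append((str(ind), sire, dam))
        ids = [r[0] for r in norm]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        known = set(ids)
        for ind, sire, dam in norm:
            for par in (sire, dam):
                if par is not None and par not in known:
                    raise ValueError(
                        f"parent {par!r} of {ind!r} is not a recorded "
                        "individual nor the unknown sentinel"
                    )
        self.records = self._toposort(norm)

    @staticmethod
    def _toposort(records):
        parents = {ind: (s, d) for ind, s, d in records}
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if state.get(node) == 2:
                return
            if state.get(node) == 1:
                raise ValueError(f"cyclic pedigree involving {node!r}")
            state[node] = 1
            for par in parents[node]:
                if par is not None:
                    visit(par, stack + (node,))
            state[node] = 2
            order.append(node)

        for ind in parents:
            visit(ind, ())
        pos = {ind: i for i, ind in enumerate(order)}
        return sorted(records, key=lambda r: pos[r[0]])

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]


@dataclass
class KinshipMatrix:
    """Symmetric similarity matrix K with sample labels.

    ``kind`` tags the provenance: ``pedigree_A``, ``genomic_G`` or
    ``custom``.  ``meta`` records regularization events.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric to 1e-10")
        diag = np.diag(self.values)
        if np.any(diag < -1e-10) or not np.any(diag > 0):
            raise ValueError("kinship diagonal must be non-negative and "
                             "not identically zero")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.labels)

    def cholesky(self):
        """Cholesky factor of K (raises LinAlgError if not PD)."""
        return cho_factor(self.values, lower=True)

    def inverse(self) -> np.ndarray:
        """Dense K^-1 via Cholesky solves (cached)."""
        if "_inv" not in self.meta:
            c = self.cholesky()
            self.meta["_inv"] = cho_solve(c, np.eye(self.n))
        return self.meta["_inv"]

    def subset(self, idx: Sequence[int]) -> "KinshipMatrix":
        idx = np.asarray(idx)
        return KinshipMatrix(
            labels=[self.labels[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
        )


def compute_vanraden_g(
    genotypes: GenotypeMatrix,
    allele_freqs: np.ndarray | None = None,
) -> KinshipMatrix:
    """Genomic relationship matrix from marker dosages.

    Missing dosages are imputed to the marker mean.  Monomorphic markers
    (zero frequency variance) are dropped from numerator and denominator,
    with a logged count.  When ``allele_freqs`` is absent, frequencies are
    the observed column means divided by ploidy; the resulting G is
    column-centered, so its grand sum is zero.
    """
    X = genotypes.dosages.copy()
    ploidy = genotypes.ploidy
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    if allele_freqs is None:
        p = X.mean(axis=0) / ploidy
    else:
        p = np.asarray(allele_freqs, dtype=float)
        if p.shape != (genotypes.n_markers,):
            raise ValueError(
                f"allele_freqs length {p.size} does not match "
                f"{genotypes.n_markers} markers"
            )

    poly = (p > 0) & (p < 1)
    n_mono = int(np.sum(~poly))
    if n_mono:
        logger.info("dropping %d monomorphic markers", n_mono)
    if not poly.any():
        raise ValueError("all markers monomorphic: G denominator is zero")

    Xp = X[:, poly] - ploidy * p[poly]
    denom = ploidy * np.sum(p[poly] * (1.0 - p[poly]))
    G = (Xp @ Xp.T) / denom
    G = 0.5 * (G + G.T)
    return KinshipMatrix(
        labels=list(genotypes.sample_ids),
        values=G,
        kind="genomic_G",
        meta={"n_markers_used": int(poly.sum()), "n_monomorphic": n_mono},
    )


def compute_pedigree_a(pedigree: PedigreeTable) -> KinshipMatrix:
    """Numerator relationship matrix A by the tabular method."""
    ids = pedigree.ids
    pos = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, (ind, sire, dam) in enumerate(pedigree.records):
        s = pos.get(sire) if sire is not None else None
        d = pos.get(dam) if dam is not None else None
        a_sd = A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            a_js = A[j, s] if s is not None else 0.0
            a_jd = A[j, d] if d is not None else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jd)
    return KinshipMatrix(labels=ids, values=A, kind="pedigree_A")


def regularize_kinship(K: KinshipMatrix, jitter: float | None = None) -> KinshipMatrix:
    """Ensure K admits a Cholesky factorization (K^-1 exists).

    If K is already positive definite it is returned unchanged.  Otherwise
    ``jitter * mean(diag(K))`` is added to the diagonal and the event is
    recorded in ``meta['jitter_added']``.  Default jitter is 1e-8.
    """
    if jitter is None:
        jitter = 1e-8
    if jitter <= 0:
        raise ValueError("jitter must be positive")
    try:
        K.cholesky()
        return K
    except np.linalg.LinAlgError:
        pass
    mean_diag = float(np.mean(np.diag(K.values)))
    if mean_diag <= 0:
        raise ValueError("kinship diagonal must be positive to regularize")
    bump = jitter * mean_diag
    out = KinshipMatrix(
        labels=list(K.labels),
        values=K.values + bump * np.eye(K.n),
        kind=K.kind,
        meta={**{k: v for k, v in K.meta.items() if not k.startswith("_")},
              "jitter_added": bump},
    )
    out.cholesky()  # must succeed now for sensible jitter
    return out
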