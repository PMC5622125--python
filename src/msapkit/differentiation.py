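"""Differentiation of methylation profiles: distances, AMOVA/Phi_ST, PCoA.

The analysis of molecular variance (AMOVA) partitions the sum of squared
pairwise distances between binary methylation profiles into among- and
within-group components.  With G groups of sizes n_g (N total) and squared
distances d2:

    SSD_total  = (1/N) * sum_{i<j} d2_ij
    SSD_within = sum_g (1/n_g) * sum_{i<j in g} d2_ij
    SSD_among  = SSD_total - SSD_within
    MSD        = SSD / df,   df_among = G-1, df_within = N-G
    n0         = (N - sum_g n_g^2 / N) / (G - 1)
    sigma2_within = MSD_within
    sigma2_among  = (MSD_among - MSD_within) / n0
    Phi_ST        = sigma2_among / (sigma2_among + sigma2_within)

Phi_ST is the fixation-index analogue for molecular data: the fraction of
total variance attributable to group membership.  Its significance is
assessed by permuting sample-to-group assignment (group sizes preserved).
Negative variance components are retained, not truncated at zero, so a
Phi_ST slightly below zero is a legitimate "no differentiation" outcome.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedValueError
from .methylation import MslBinaryMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of squared pairwise distances between samples."""

    sample_ids: list[str]
    d2: np.ndarray

    def __post_init__(self) -> None:
        d2 = np.asarray(self.d2, dtype=float)
        n = len(self.sample_ids)
        if d2.shape != (n, n):
            raise ConfigurationError("d2 must be square with one row per sample")
        if not np.allclose(d2, d2.T):
            raise ConfigurationError("d2 must be symmetric")
        if np.any(np.diag(d2) != 0):
            raise ConfigurationError("d2 must have a zero diagonal")
        if np.any(d2 < 0):
            raise ConfigurationError("d2 must be non-negative")
        self.d2 = d2

    def subset(self, samples: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return DistanceMatrix(list(samples), self.d2[np.ix_(idx, idx)])


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    df_total: int
    ssd_among: float
    ssd_within: float
    ssd_total: float
    msd_among: float
    msd_within: float
    n0: float
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    n_permutations: int = 0
    p_perm: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Three-row source table in the conventional AMOVA layout."""
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within, self.df_total],
                "SSD": [self.ssd_among, self.ssd_within, self.ssd_total],
                "MSD": [self.msd_among, self.msd_within,
                        self.ssd_total / self.df_total if self.df_total else float("nan")],
                "variance": [self.sigma2_among, self.sigma2_within, float("nan")],
                "phi_st": [self.phi_st, float("nan"), float("nan")],
                "p": [self.p_perm, float("nan"), float("nan")],
            },
            index=pd.Index(["among_groups", "within_groups", "total"], name="source"),
        )


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray   # samples x retained axes
    eigenvalues: np.ndarray   # positive eigenvalues, descending
    pct_variance: np.ndarray  # percent per retained axis, sums to 100

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pairwise_distances(matrix: MslBinaryMatrix) -> DistanceMatrix:
    """Squared distances between samples' binary methylation profiles.

    d2_ij = (L / L_ij) * #{loci with opposite states among the L_ij loci
    non-missing in both samples}, L the total locus count.  Without missing
    data this is the squared Euclidean distance on 0/1 vectors; the L/L_ij
    factor rescales pairs with missing calls to the full-matrix scale.
    """
    x = matrix.states.to_numpy(dtype=float)
    n, L = x.shape
    if n < 2:
        raise ConfigurationError("pairwise_distances requires >= 2 samples")
    obs = ~np.isnan(x)
    x0 = np.nan_to_num(x)
    # mismatches_ij = sum over jointly observed loci of |x_i - x_j|
    both = obs.astype(float) @ obs.astype(float).T            # L_ij
    same1 = x0 @ x0.T                                         # both methylated
    same0 = (obs & (x0 == 0)).astype(float) @ (obs & (x0 == 0)).astype(float).T
    mism = both - same1 - same0
    zero_overlap = (both == 0) & ~np.eye(n, dtype=bool)
    if zero_overlap.any():
        i, j = np.argwhere(zero_overlap)[0]
        raise UndefinedValueError(
            f"samples {matrix.sample_ids[i]} and {matrix.sample_ids[j]} share "
            "no jointly non-missing locus"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(both > 0, L * mism / both, 0.0)
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(list(matrix.sample_ids), (d2 + d2.T) / 2)


def variance_components(
    ssd_among: float, ssd_within: float, group_sizes: list[int]
) -> AmovaResult:
    """AMOVA variance components and Phi_ST from sums of squares.

    Accepts the printed-table route into the decomposition: given SSDs and
    group sizes it fills degrees of freedom, mean squares, the weighted
    average group size n0, the variance components (negative values
    retained) and Phi_ST.  Permutation fields are left empty.
    """
    sizes = np.asarray(group_sizes, dtype=float)
    G = len(sizes)
    N = int(sizes.sum())
    if G < 2:
        raise ConfigurationError("need >= 2 groups")
    if np.any(sizes < 1):
        raise ConfigurationError("all group sizes must be >= 1")
    if N < G + 1:
        raise ConfigurationError("need N >= G + 1 for a within-group df")
    df_among, df_within, df_total = G - 1, N - G, N - 1
    msd_among = ssd_among / df_among
    msd_within = ssd_within / df_within
    n0 = (N - (sizes**2).sum() / N) / (G - 1)
    sigma2_within = msd_within
    sigma2_among = (msd_among - msd_within) / n0
    denom = sigma2_among + sigma2_within
    if denom == 0:
        raise UndefinedValueError("Phi_ST undefined: total variance is zero")
    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        df_total=df_total,
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        ssd_total=ssd_among + ssd_within,
        msd_among=msd_among,
        msd_within=msd_within,
        n0=n0,
        sigma2_among=sigma2_among,
        sigma2_within=sigma2_within,
        phi_st=sigma2_among / denom,
    )


def _ssds(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    N = len(labels)
    total = d2.sum() / 2.0 / N
    within = 0.0
    for g in uniq:
        idx = labels == g
        n_g = idx.sum()
        within += d2[np.ix_(idx, idx)].sum() / 2.0 / n_g
    return total - within, within


def amova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA with a seeded permutation test for Phi_ST.

    ``groups`` is one label per sample in ``dist`` order.  The permutation
    p-value uses the (1 + b) / (1 + B) estimator, b the number of permuted
    Phi_ST values >= the observed one; for B = 0 the p-value is NaN.
    """
    labels = np.asarray(list(groups))
    if len(labels) != len(dist.sample_ids):
        raise ConfigurationError("groups must have one label per sample")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ConfigurationError("need >= 2 groups")
    if np.any(counts == 0):
        raise ConfigurationError("groups must be non-empty")
    if n_permutations < 0:
        raise ConfigurationError("n_permutations must be >= 0")
    d2 = dist.d2
    ssd_among, ssd_within = _ssds(d2, labels, uniq)
    res = variance_components(ssd_among, ssd_within, counts.tolist())
    res.n_permutations = n_permutations
    if n_permutations == 0:
        return res
    rng = np.random.default_rng(seed)
    N = len(labels)
    G = len(uniq)
    df_a, df_w = G - 1, N - G
    ssd_tot = res.ssd_total
    n0 = res.n0
    lab_idx = np.searchsorted(uniq, labels)
    base_onehot = np.eye(G)[lab_idx]  # N x G
    exceed = 0
    chunk = max(1, min(n_permutations, int(2e7 // (N * G))))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        perms = np.argsort(rng.random((b, N)), axis=1)       # b random permutations
        onehots = base_onehot[perms]                         # b x N x G
        within = np.einsum("bng,nm,bmg->bg", onehots, d2, onehots) / 2.0
        ssd_w = (within / counts).sum(axis=1)
        msd_a = (ssd_tot - ssd_w) / df_a
        msd_w = ssd_w / df_w
        s2a = (msd_a - msd_w) / n0
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = s2a / (s2a + msd_w)
        exceed += int(np.sum(phi >= res.phi_st - 1e-12))
        done += b
    res.p_perm = (1 + exceed) / (1 + n_permutations)
    return res


def pairwise_group_amova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """One AMOVA per unordered group pair, restricted to that pair's samples.

    P-values are reported raw (no multiplicity adjustment).  Each pair's
    permutation stream is derived from ``seed`` and the pair's position so
    results do not depend on evaluation order.
    """
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ConfigurationError("need >= 2 groups")
    rows = []
    for k, (a, b) in enumerate(itertools.combinations(uniq.tolist(), 2)):
        sel = (labels == a) | (labels == b)
        sub_ids = [s for s, keep in zip(dist.sample_ids, sel) if keep]
        sub = dist.subset(sub_ids)
        sub_seed = None if seed is None else (seed + 7919 * k) % (2**31)
        r = amova(sub, labels[sel], n_permutations=n_permutations, seed=sub_seed)
        rows.append(
            {"group_a": a, "group_b": b, "phi_st": r.phi_st, "p": r.p_perm,
             "sigma2_among": r.sigma2_among, "sigma2_within": r.sigma2_within,
             "df_among": r.df_among, "df_within": r.df_within}
        )
    return pd.DataFrame(rows)


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis (classical metric scaling).

    Double-centers -d2/2, eigendecomposes, and keeps axes with positive
    eigenvalues; coordinates are eigenvectors scaled by sqrt(eigenvalue).
    Negative eigenvalues (non-Euclidean input) are dropped and logged;
    percent variance is computed over the positive eigenvalues only.
    """
    n = len(dist.sample_ids)
    if n < 2:
        raise ConfigurationError("pcoa requires >= 2 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ dist.d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-10
    pos = evals > tol
    if np.any(evals < -tol):
        logger.info("pcoa: dropping %d negative eigenvalue(s); input is not "
                    "Euclidean-embeddable", int((evals < -tol).sum()))
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum()
    return PcoaResult(list(dist.sample_ids), coords, lam, pct)
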