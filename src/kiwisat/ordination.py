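"""Codominant genetic distance and principal coordinates analysis.

The pairwise distance is the Smouse-Peakall squared metric for codominant
data. Coding each single-locus genotype as its allele count vector
:math:`x` (entries summing to 2), the per-locus squared distance is
:math:`d^2 = \\tfrac12 \\sum_a (x_a - y_a)^2`, which reproduces the
canonical case table::

    (ii, ii) = 0   (ij, ij) = 0   (ii, ij) = 1   (ij, ik) = 1
    (ij, kl) = 2   (ii, jk) = 3   (ii, jj) = 4

Multilocus distance sums (or rescales to a mean over) the loci both
samples have typed. PCoA Gower-centers :math:`-\\tfrac12 d^2` and
eigendecomposes; coordinates are eigenvectors scaled by the square root
of their (positive) eigenvalues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator


@dataclass
class DistanceMatrix:
    """Symmetric matrix of summed per-locus squared genetic distances."""

    ids: list[str]
    values: np.ndarray  # squared distances
    shared_loci: np.ndarray  # per-pair count of loci used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def locus_distance2(g1: tuple[int, int], g2: tuple[int, int]) -> float:
    """Squared codominant distance between two single-locus genotypes."""
    c1, c2 = Counter(g1), Counter(g2)
    return 0.5 * sum((c1[a] - c2[a]) ** 2 for a in set(c1) | set(c2))


def genetic_distance(
    genotypes: pd.DataFrame, scaling: str = "sum"
) -> DistanceMatrix:
    """All-pairs squared genetic distance from a genotype table.

    Loci missing in either sample of a pair are skipped. With
    ``scaling='mean'`` the sum over shared loci is rescaled to the full
    panel length (sum x total loci / shared loci), so samples typed at
    different locus subsets stay comparable; with ``'sum'`` the raw sum is
    kept. A pair sharing no typed locus is an error.
    """
    if scaling not in ("sum", "mean"):
        raise ValueError("scaling must be 'sum' or 'mean'")
    loci_all = list(pd.unique(genotypes["locus"]))
    typed = genotypes.dropna(subset=["allele_a", "allele_b"])
    profiles: dict[str, dict[str, tuple[int, int]]] = {}
    for sample, grp in typed.groupby("sample", sort=True):
        profiles[sample] = {
            r.locus: (int(r.allele_a), int(r.allele_b)) for r in grp.itertuples()
        }
    ids = sorted(profiles)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples with typed loci")
    n = len(ids)
    d2 = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        shared[i, i] = len(profiles[ids[i]])
        for j in range(i + 1, n):
            common = profiles[ids[i]].keys() & profiles[ids[j]].keys()
            if not common:
                raise ValueError(f"samples {ids[i]} and {ids[j]} share no typed locus")
            total = sum(
                locus_distance2(profiles[ids[i]][l], profiles[ids[j]][l])
                for l in common
            )
            if scaling == "mean":
                total *= len(loci_all) / len(common)
            d2[i, j] = d2[j, i] = total
            shared[i, j] = shared[j, i] = len(common)
    return DistanceMatrix(ids=ids, values=d2, shared_loci=shared)


class PCoA(BaseEstimator):
    """Principal coordinates analysis of a squared-distance matrix.

    Parameters
    ----------
    n_axes : int or None
        Number of axes to keep (None keeps every positive-eigenvalue axis).

    Attributes
    ----------
    coordinates_ : np.ndarray of shape (n_samples, k)
    eigenvalues_ : np.ndarray, positive eigenvalues, descending
    negative_eigenvalues_ : np.ndarray, eigenvalues below -1e-8 (reported,
        their axes dropped)
    proportion_explained_ : np.ndarray, eigenvalue share of the positive sum
    ids_ : list of sample ids when fitted from a DistanceMatrix
    """

    def __init__(self, n_axes: int | None = None):
        self.n_axes = n_axes

    def fit(self, d2: DistanceMatrix | np.ndarray) -> "PCoA":
        if isinstance(d2, DistanceMatrix):
            ids, m = d2.ids, d2.values
        else:
            ids, m = None, np.asarray(d2, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        n = m.shape[0]
        centerer = np.eye(n) - np.full((n, n), 1.0 / n)
        b = -0.5 * centerer @ m @ centerer
        vals, vecs = eigh((b + b.T) / 2)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        pos = vals > 1e-8
        k = int(pos.sum())
        if self.n_axes is not None:
            k = min(k, self.n_axes)
        self.eigenvalues_ = vals[:k] if k else np.array([])
        self.negative_eigenvalues_ = vals[vals < -1e-8]
        self.coordinates_ = vecs[:, :k] * np.sqrt(vals[:k]) if k else np.zeros((n, 0))
        pos_sum = vals[pos].sum()
        self.proportion_explained_ = (
            self.eigenvalues_ / pos_sum if pos_sum > 0 else np.array([])
        )
        self.ids_ = ids
        return self

    def fit_transform(self, d2: DistanceMatrix | np.ndarray) -> np.ndarray:
        return self.fit(d2).coordinates_

    def to_frame(self) -> pd.DataFrame:
        ids = self.ids_ if self.ids_ is not None else range(len(self.coordinates_))
        return pd.DataFrame(
            self.coordinates_,
            index=ids,
            columns=[f"axis_{i + 1}" for i in range(self.coordinates_.shape[1])],
        )


def pcoa(d2: DistanceMatrix | np.ndarray, n_axes: int | None = None) -> PCoA:
    """Functional wrapper: fit a :class:`PCoA` and return it."""
    return PCoA(n_axes=n_axes).fit(d2)
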