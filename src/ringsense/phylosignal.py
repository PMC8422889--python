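"""Blomberg's K phylogenetic signal with permutation significance.

K compares the phylogenetic signal observed in a species-level trait to
the expectation under Brownian-motion evolution along the tree.  With
``C`` the Brownian variance-covariance matrix of the tips (shared
root-to-MRCA branch length per pair) and ``x`` the trait vector:

    a_hat = (1' C^-1 x) / (1' C^-1 1)          (phylogenetic mean)
    MSE0  = (x - a_hat)' (x - a_hat) / (n - 1)
    MSE   = (x - a_hat)' C^-1 (x - a_hat) / (n - 1)
    K     = (MSE0 / MSE) / ( [tr(C) - n / (1' C^-1 1)] / (n - 1) )

K is about 1 for traits evolving by Brownian motion, below 1 for traits
less structured by phylogeny than Brownian expectation, and above 1 for
strongly conserved traits.  Significance is assessed by permuting trait
values across tips and asking how often the permuted MSE is as small as
(or smaller than) the observed one — lower MSE means stronger signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .ring_io import PhyloTree

__all__ = [
    "PhyloCov",
    "phylo_vcv",
    "blomberg_k",
    "k_significance",
]


@dataclass
class PhyloCov:
    """Brownian-motion tip variance-covariance matrix with its species order."""

    species: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        n = len(self.species)
        if C.shape != (n, n):
            raise ValueError("C must be square and match the species list")
        if not np.allclose(C, C.T):
            raise ValueError("C must be symmetric")
        if np.any(np.diag(C) + 1e-12 < C.max(axis=1)):
            raise ValueError("diagonal of C must dominate each row")
        # positive definiteness verified via Cholesky on first use
        self.C = C

    def reorder(self, species: list[str]) -> "PhyloCov":
        missing = [s for s in species if s not in self.species]
        if missing:
            raise ValueError(f"species not in tree: {', '.join(missing)}")
        idx = [self.species.index(s) for s in species]
        return PhyloCov(list(species), self.C[np.ix_(idx, idx)])


def phylo_vcv(ptree: PhyloTree) -> PhyloCov:
    """Variance-covariance matrix of the tips under Brownian motion.

    ``C[i, j]`` is the root-to-MRCA depth of tips i and j; the diagonal is
    the root-to-tip path length.  Computed from root distances and
    patristic distances: ``depth(MRCA) = (d_i + d_j - dist_ij) / 2``.
    """
    tree = ptree.tree
    tree.calc_node_root_distances()
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    depths = np.array([lf.root_distance for lf in leaves], dtype=float)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = depths[i]
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            C[i, j] = C[j, i] = 0.5 * (depths[i] + depths[j] - dist)
    return PhyloCov(labels, C)


def _k_pieces(cov: PhyloCov) -> tuple:
    C = cov.C
    n = C.shape[0]
    try:
        chol = cho_factor(C)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("singular phylogenetic covariance matrix") from exc
    ones = np.ones(n)
    Ci1 = cho_solve(chol, ones)
    s = float(ones @ Ci1)  # 1' C^-1 1
    expected = (float(np.trace(C)) - n / s) / (n - 1)
    return chol, Ci1, s, expected, n


def blomberg_k(trait: np.ndarray, cov: PhyloCov) -> float:
    """Blomberg's K for one trait vector (order must match ``cov.species``)."""
    x = np.asarray(trait, dtype=float)
    chol, Ci1, s, expected, n = _k_pieces(cov)
    if len(x) != n:
        raise ValueError("trait length does not match covariance dimension")
    if n < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(x) == 0:
        raise ValueError("constant trait has no phylogenetic signal")
    a_hat = float(Ci1 @ x) / s
    dev = x - a_hat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ cho_solve(chol, dev)) / (n - 1)
    return (mse0 / mse) / expected


def k_significance(
    trait: np.ndarray,
    cov: PhyloCov,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Permutation test for K: (K, p).

    Trait values are shuffled across tips ``n_perm`` times; the statistic
    is the phylogenetically weighted MSE (smaller = more signal), and
    ``p = (1 + #{MSE_perm <= MSE_obs}) / (n_perm + 1)``.
    """
    x = np.asarray(trait, dtype=float)
    k_obs = blomberg_k(x, cov)
    chol, Ci1, s, _, n = _k_pieces(cov)
    Ci = cho_solve(chol, np.eye(n))

    def mse_of(mat: np.ndarray) -> np.ndarray:
        # rows of mat are trait vectors
        a = (mat @ Ci1) / s
        dev = mat - a[:, None]
        return np.einsum("ij,jk,ik->i", dev, Ci, dev) / (n - 1)

    mse_obs = float(mse_of(x[None, :])[0])
    rng = np.random.default_rng(rng)
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = rng.permutation(x)
    mse_perm = mse_of(perms)
    p = (1.0 + int(np.sum(mse_perm <= mse_obs + 1e-15))) / (n_perm + 1.0)
    return k_obs, float(p)
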