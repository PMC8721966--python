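"""Coexpression network construction and topology-based re-weighting.

A coexpression network is the dense symmetric matrix of pairwise
correlations between gene expression vectors (no self-edges).  Two
optional transformations re-score edges using network topology:

* **CLR** (context likelihood of relatedness) compares each edge weight to
  the edge-weight distributions of both endpoint genes: per gene *i* with
  mean/SD mu_i, sigma_i over its n-1 edges, z_i(j) = max(0, (w_ij -
  mu_i)/sigma_i), and the new weight is sqrt(z_i(j)^2 + z_j(i)^2).  Edges
  that are strong relative to *both* genes' neighborhoods are upweighted.

* **WTO** (weighted topological overlap) upweights gene pairs that share
  strong neighbors: with adjacency a (signed for the ``sign`` variant,
  absolute for ``abs``) and connectivity k_i = sum_u |a_iu|,
  omega_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - |a_ij|).
  With signed input the result lies in [-1, 1] (it can be negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .normalization import ExpressionMatrix, _as_frame

__all__ = ["CoexpressionNetwork", "correlation_network", "clr_transform", "wto_transform"]


@dataclass
class CoexpressionNetwork:
    """Symmetric weighted gene-pair map with no self-pairs.

    ``weights`` is a dense (n, n) symmetric float array with zero diagonal;
    ``kind`` tags the weight semantics (pearson/spearman/clr/wto).
    """

    genes: list[str]
    weights: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match gene list")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def get(self, gene_a: str, gene_b: str) -> float:
        i, j = self.genes.index(gene_a), self.genes.index(gene_b)
        if i == j:
            raise KeyError("self-pairs carry no weight")
        return float(self.weights[i, j])

    def to_edge_frame(self) -> pd.DataFrame:
        """Edge list with lexicographically ordered pairs, sorted by pair."""
        order = np.argsort(np.asarray(self.genes, dtype=object))
        genes = [self.genes[i] for i in order]
        w = self.weights[np.ix_(order, order)]
        iu, ju = np.triu_indices(len(genes), k=1)
        return pd.DataFrame(
            {
                "gene_a": np.asarray(genes, dtype=object)[iu],
                "gene_b": np.asarray(genes, dtype=object)[ju],
                "weight": w[iu, ju],
            }
        )

    def write_edge_list(self, path) -> None:
        """Write a (optionally gzipped, by extension) 3-column TSV edge list."""
        self.to_edge_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_edge_frame(cls, edges: pd.DataFrame, kind: str = "pearson") -> "CoexpressionNetwork":
        """Rebuild a dense network from a (gene_a, gene_b, weight) edge list;
        missing pairs default to weight 0."""
        genes = sorted(set(edges["gene_a"].astype(str)) | set(edges["gene_b"].astype(str)))
        index = {g: i for i, g in enumerate(genes)}
        w = np.zeros((len(genes), len(genes)))
        for a, b, weight in zip(edges["gene_a"], edges["gene_b"], edges["weight"]):
            i, j = index[str(a)], index[str(b)]
            if i == j:
                raise ValueError(f"self-pair in edge list for gene {a!r}")
            w[i, j] = w[j, i] = float(weight)
        return cls(genes, w, kind)

    @classmethod
    def read_edge_list(cls, path, kind: str = "pearson") -> "CoexpressionNetwork":
        return cls.from_edge_frame(pd.read_csv(path, sep="\t"), kind=kind)


def correlation_network(
    matrix: pd.DataFrame | ExpressionMatrix, method: str = "pearson"
) -> CoexpressionNetwork:
    """All-pairs gene correlation across samples.

    Gene pairs where either gene has zero variance get weight 0 (the
    correlation is undefined; zero keeps the network total and evaluable).
    """
    frame = _as_frame(matrix)
    n_genes, n_samples = frame.shape
    if n_samples < 3:
        raise ValueError("correlation needs >= 3 samples")
    if n_genes < 2:
        raise ValueError("correlation needs >= 2 genes")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    x = frame.to_numpy(float)
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)  # average ranks for ties
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance genes; their correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.where(np.isfinite(c), c, 0.0)
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 0.0)
    c = (c + c.T) / 2.0
    return CoexpressionNetwork(list(frame.index), c, method)


def clr_transform(net: CoexpressionNetwork) -> CoexpressionNetwork:
    """Context-likelihood-of-relatedness re-weighting (z-score form,
    negative z clipped to zero); output weights are >= 0.

    Per-gene mean and standard deviation are taken over the gene's n-1
    off-diagonal weights, with the population (n) denominator.
    """
    n = net.n_genes
    if n < 3:
        raise ValueError("CLR needs >= 3 genes")
    w = net.weights
    mu = w.sum(axis=1) / (n - 1)
    ex2 = (w ** 2).sum(axis=1) / (n - 1)
    var = np.maximum(ex2 - mu ** 2, 0.0)
    sigma = np.sqrt(var)
    degenerate = sigma == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes with constant edge weights; their z-scores are 0",
            stacklevel=2,
        )
    safe_sigma = np.where(degenerate, 1.0, sigma)
    z = (w - mu[:, None]) / safe_sigma[:, None]
    z[degenerate, :] = 0.0
    z = np.clip(z, 0.0, None)
    np.fill_diagonal(z, 0.0)
    out = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(out, 0.0)
    return CoexpressionNetwork(net.genes, out, "clr")


def wto_transform(net: CoexpressionNetwork, variant: str = "sign") -> CoexpressionNetwork:
    """Weighted topological overlap of the correlation network.

    ``variant="sign"`` uses signed weights (output in [-1, 1]);
    ``variant="abs"`` uses absolute weights (output in [0, 1]).
    """
    if variant not in ("sign", "abs"):
        raise ValueError(f"unknown WTO variant {variant!r}")
    if net.n_genes < 3:
        raise ValueError("WTO needs >= 3 genes")
    w = net.weights
    if np.max(np.abs(w)) > 1 + 1e-9:
        raise ValueError("WTO input weights must lie in [-1, 1]")
    a = w if variant == "sign" else np.abs(w)
    k = np.abs(a).sum(axis=1)
    # diagonal of `a` is zero, so a @ a already sums over u != i, j
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - np.abs(a)
    if np.any(den <= 0):
        raise AssertionError("WTO denominator must be positive for weights in [-1, 1]")
    omega = num / den
    np.fill_diagonal(omega, 0.0)
    omega = (omega + omega.T) / 2.0
    return CoexpressionNetwork(net.genes, omega, "wto")
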