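"""Trait correlation structure: Pearson matrix, PCA and the GGM network.

The Gaussian graphical model expresses each pairwise association
conditional on all remaining traits: with ``P`` the inverse of the trait
correlation matrix, the partial correlation is
``pcor_ij = -P_ij / sqrt(P_ii * P_jj)``.  Edges with |partial correlation|
at or above a cutoff form an unweighted graph on which outdegree (edge
count per node) and Brandes betweenness (bridge count along shortest paths,
fractional over ties) measure trait centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: traits excluded from the network by default (high collinearity with the
#: remaining set): volumes, surface areas and the two lateral:axial ratios.
GGM_EXCLUDED_TRAITS = ["TRV", "ARV", "LRV", "L_A_V", "TSA", "ASA", "LSA", "L_A_L"]


def pearson_matrix(traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with two-sided t-test p-values.

    Uses pairwise-complete observations; the diagonal is r = 1 with p = 0.
    """
    cols = list(traits.columns)
    if len(traits) < 3:
        raise ValueError("need at least 3 observations")
    k = len(cols)
    r = traits.corr(method="pearson")
    pmat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    notna = traits.notna().to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            n = int((notna[:, i] & notna[:, j]).sum())
            rij = r.iloc[i, j]
            if n < 3 or not np.isfinite(rij):
                p = np.nan
            elif abs(rij) >= 1.0:
                p = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1.0 - rij**2))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return r, pmat


@dataclass
class PcaResult:
    scores: pd.DataFrame              # observations x PCs
    loadings: pd.DataFrame            # traits x PCs (unit eigenvectors)
    explained_variance_pct: pd.Series
    contributions_pct: pd.DataFrame   # traits x PCs, columns sum to 100


def pca(traits: pd.DataFrame, scale: bool = True, n_pcs: int | None = None) -> PcaResult:
    """Principal component analysis of a trait table via SVD.

    Columns are centred and, by default, scaled to unit variance (the traits
    carry incommensurate units).  Explained variance percentages are
    eigenvalue shares; the contribution of trait j to PC k is
    ``100 * loading_jk^2`` (loadings are unit eigenvectors, so each PC's
    contributions sum to 100).
    """
    d = traits.dropna()
    if d.shape[1] < 2:
        raise ValueError("PCA needs at least 2 traits")
    X = d.to_numpy(float)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = sd <= 0
        if zero.any():
            names = [c for c, z in zip(d.columns, zero) if z]
            raise ValueError(f"constant trait(s) cannot be scaled: {names}")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    n_total = s.size
    n_keep = n_total if n_pcs is None else min(n_pcs, n_total)
    pcs = [f"PC{k + 1}" for k in range(n_total)]
    eig = s**2
    explained = pd.Series(100.0 * eig / eig.sum(), index=pcs)
    scores = pd.DataFrame(U * s, index=d.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=d.columns, columns=pcs)
    contributions = 100.0 * loadings**2
    keep = pcs[:n_keep]
    return PcaResult(
        scores=scores[keep],
        loadings=loadings[keep],
        explained_variance_pct=explained[keep],
        contributions_pct=contributions[keep],
    )


@dataclass
class PartialCorrelationNetwork:
    pcor: pd.DataFrame  # traits x traits, unit diagonal
    jitter_used: float = 0.0

    def edges(self, cutoff: float = 0.15) -> pd.DataFrame:
        """Edge list with |partial correlation| >= cutoff (diagonal excluded)."""
        cols = list(self.pcor.columns)
        rows = []
        for i, a in enumerate(cols):
            for j in range(i + 1, len(cols)):
                v = self.pcor.iloc[i, j]
                if abs(v) >= cutoff:
                    rows.append(dict(trait_a=a, trait_b=cols[j], pcor=v))
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "pcor"])

    def graph(self, cutoff: float = 0.15) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.pcor.columns)
        for _, e in self.edges(cutoff).iterrows():
            g.add_edge(e["trait_a"], e["trait_b"], pcor=e["pcor"])
        return g


def ggm_partial_correlations(
    traits: pd.DataFrame,
    subset: list[str] | None = None,
    max_jitter: float = 1e-4,
) -> PartialCorrelationNetwork:
    """Partial-correlation matrix by inverting the trait correlation matrix.

    ``subset=None`` keeps every column except :data:`GGM_EXCLUDED_TRAITS`.
    Near-singular correlation matrices get an escalating ridge on the
    diagonal (logged); failure at ``max_jitter`` raises, naming the most
    collinear trait pair.
    """
    if subset is None:
        subset = [c for c in traits.columns if c not in GGM_EXCLUDED_TRAITS]
    d = traits[subset].dropna()
    if len(d) <= len(subset):
        raise ValueError("need more observations than traits for the GGM")
    R = d.corr(method="pearson").to_numpy()
    k = R.shape[0]
    jitter = 0.0
    P = None
    for attempt_jitter in (0.0, 1e-10, 1e-8, 1e-6, max_jitter):
        Rj = R + attempt_jitter * np.eye(k)
        evals = np.linalg.eigvalsh(Rj)
        # inv() of a numerically singular matrix "succeeds" with garbage, so
        # gate on the spectrum instead of on LinAlgError
        if evals[0] <= 1e-10 * evals[-1]:
            continue
        P = np.linalg.inv(Rj)
        jitter = attempt_jitter
        break
    if P is None:
        off = np.abs(R - np.eye(k))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            "correlation matrix singular even with ridge jitter; most "
            f"collinear traits: {subset[i]} ~ {subset[j]}"
        )
    if jitter > 0:
        log.warning("GGM: ridge jitter %.1e applied to invert correlation matrix", jitter)
    dsqrt = np.sqrt(np.outer(np.diag(P), np.diag(P)))
    pcor = -P / dsqrt
    np.fill_diagonal(pcor, 1.0)
    pcor = 0.5 * (pcor + pcor.T)
    return PartialCorrelationNetwork(
        pcor=pd.DataFrame(pcor, index=subset, columns=subset),
        jitter_used=jitter,
    )


def network_centrality(
    network: PartialCorrelationNetwork, cutoff: float = 0.15
) -> pd.DataFrame:
    """Outdegree and betweenness per trait on the thresholded graph.

    The graph is unweighted: outdegree is the number of retained edges at a
    node and betweenness is the (pair-count) Brandes betweenness, i.e. the
    number of shortest paths between other node pairs passing through the
    node, fractional over tied paths.
    """
    g = network.graph(cutoff)
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    return pd.DataFrame(
        {
            "trait": list(network.pcor.columns),
            "outdegree": [deg[t] for t in network.pcor.columns],
            "betweenness": [btw[t] for t in network.pcor.columns],
        }
    )
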