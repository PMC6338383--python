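"""Phi-coefficient symptom association networks.

Symptoms are binary, so the zero-order Pearson correlation between two items
is the phi coefficient, computable from the pair's 2x2 cross-table as
phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).  The network has one node per
symptom and the phi matrix as its weighted adjacency.  Edge significance uses
the chi-square test of independence (chi2 = n * phi^2, 1 df, no continuity
correction), and family-wise error across all node pairs is controlled with
Hochberg's step-up procedure: an edge survives when its adjusted p-value is
below alpha.  Thresholding zeroes non-surviving edges and never rescales the
survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .symptoms import DOMAINS, SYMPTOMS


@dataclass
class AssociationMatrix:
    """Pairwise phi coefficients with bookkeeping for degenerate items."""

    phi: np.ndarray                 # k x k symmetric, diagonal 0
    n_effective: np.ndarray         # k x k pairwise-complete sample sizes
    degenerate: np.ndarray          # k boolean: zero variance in this group


@dataclass
class SymptomNetwork:
    """Weighted symptom graph with optional significance and threshold state."""

    nodes: tuple[str, ...]
    weights: np.ndarray
    raw_p: np.ndarray | None = None
    adjusted_p: np.ndarray | None = None
    n_effective: np.ndarray | None = None
    degenerate: np.ndarray | None = None
    alpha: float | None = None
    method: str = "none"            # {"none", "hochberg"}
    layout: np.ndarray | None = None
    group: str = "combined"

    @property
    def k(self) -> int:
        return len(self.nodes)

    def edge_table(self) -> pd.DataFrame:
        """One row per unordered pair with nonzero weight."""
        rows = []
        for i in range(self.k):
            for j in range(i + 1, self.k):
                w = self.weights[i, j]
                if w == 0:
                    continue
                rows.append(
                    {
                        "node_a": self.nodes[i],
                        "node_b": self.nodes[j],
                        "weight": w,
                        "raw_p": self.raw_p[i, j] if self.raw_p is not None else np.nan,
                        "adjusted_p": (
                            self.adjusted_p[i, j] if self.adjusted_p is not None else np.nan
                        ),
                        "survives_threshold": (
                            bool(self.adjusted_p[i, j] < self.alpha)
                            if self.method == "hochberg" and self.adjusted_p is not None
                            else True
                        ),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["node_a", "node_b", "weight", "raw_p", "adjusted_p", "survives_threshold"],
        )

    def to_graph(self, absolute: bool = True) -> nx.Graph:
        """networkx view; edge ``weight`` = |phi| (or signed), ``length`` = 1/|phi|."""
        g = nx.Graph()
        for name in self.nodes:
            g.add_node(name, domain=DOMAINS.get(name, ""))
        for i in range(self.k):
            for j in range(i + 1, self.k):
                w = self.weights[i, j]
                if w != 0:
                    mag = abs(w)
                    g.add_edge(
                        self.nodes[i],
                        self.nodes[j],
                        weight=mag if absolute else w,
                        length=1.0 / mag,
                    )
        return g


def phi_matrix(profiles) -> AssociationMatrix:
    """Phi coefficients between all pairs of binary columns.

    Pairwise-complete over missing values; numerically identical to the
    Pearson correlation of the 0/1 columns.  Zero-variance columns are
    flagged degenerate and their coefficients set to 0 (the node is kept).
    """
    df = pd.DataFrame(np.asarray(profiles, dtype=float))
    if len(df) < 2:
        raise ValueError(f"need >= 2 participants, got {len(df)}")
    k = df.shape[1]
    notna = df.notna().to_numpy(dtype=float)
    n_eff = (notna.T @ notna).astype(np.int64)
    std = df.std(ddof=0)
    degenerate = (std == 0).to_numpy() | df.isna().all().to_numpy()
    phi = df.corr(method="pearson").to_numpy()  # pairwise complete
    phi[np.isnan(phi)] = 0.0
    phi[degenerate, :] = 0.0
    phi[:, degenerate] = 0.0
    np.fill_diagonal(phi, 0.0)
    phi = np.clip((phi + phi.T) / 2.0, -1.0, 1.0)
    return AssociationMatrix(phi=phi, n_effective=n_eff, degenerate=degenerate)


def edge_significance(assoc: AssociationMatrix) -> np.ndarray:
    """Raw two-sided p-value per edge from chi2 = n * phi^2 with 1 df.

    Equivalent to the Pearson chi-square test of independence on the pair's
    2x2 table without continuity correction.  Edges touching a degenerate
    item get p = 1; the diagonal is set to 0 (self-association, never tested).
    """
    chi2 = assoc.n_effective * assoc.phi**2
    p = stats.chi2.sf(chi2, df=1)
    deg = assoc.degenerate
    p[deg, :] = 1.0
    p[:, deg] = 1.0
    np.fill_diagonal(p, 0.0)
    return p


def hochberg_adjust(p) -> np.ndarray:
    """Hochberg step-up adjusted p-values for a family of m tests.

    Sorted descending, adjusted p(i) is the running minimum of
    (m - rank + 1) * p over the larger p-values, capped at 1; dominates
    (is never larger than) the Bonferroni adjustment.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="simes-hochberg")[1]


def build_network(
    profiles,
    nodes: tuple[str, ...] | None = None,
    group: str = "combined",
) -> SymptomNetwork:
    """Unthresholded phi network with raw edge p-values attached."""
    assoc = phi_matrix(profiles)
    k = assoc.phi.shape[0]
    if nodes is None:
        nodes = tuple(SYMPTOMS) if k == len(SYMPTOMS) else tuple(f"v{i}" for i in range(k))
    return SymptomNetwork(
        nodes=tuple(nodes),
        weights=assoc.phi,
        raw_p=edge_significance(assoc),
        n_effective=assoc.n_effective,
        degenerate=assoc.degenerate,
        group=group,
    )


def threshold_network(net: SymptomNetwork, alpha: float = 0.05) -> SymptomNetwork:
    """Family-wise-error thresholding at ``alpha`` over all node pairs.

    The family is the full set of k*(k-1)/2 upper-triangle pairs (153 for the
    18-symptom network), including degenerate ones.  Edges whose Hochberg-
    adjusted p-value is >= alpha are zeroed; surviving weights are the
    unthresholded phi values.  Idempotent: raw p-values are preserved, so
    re-thresholding reproduces the same network.
    """
    if net.raw_p is None:
        raise ValueError("network has no raw p-values; build it with build_network")
    k = net.k
    iu = np.triu_indices(k, 1)
    adj_flat = hochberg_adjust(net.raw_p[iu])
    adjusted = np.zeros((k, k))
    adjusted[iu] = adj_flat
    adjusted = adjusted + adjusted.T
    survives = adjusted < alpha
    np.fill_diagonal(survives, False)
    weights = np.where(survives, net.weights, 0.0)
    return replace(
        net,
        weights=weights,
        adjusted_p=adjusted,
        alpha=alpha,
        method="hochberg",
    )


def fr_layout(net: SymptomNetwork, seed: int = 0) -> np.ndarray:
    """Deterministic Fruchterman–Reingold coordinates on |phi| weights.

    Visualization plumbing only: nodes with stronger associations land
    closer together; no statistic depends on the coordinates.
    """
    g = net.to_graph(absolute=True)
    pos = nx.spring_layout(g, weight="weight", seed=int(seed))
    return np.array([pos[name] for name in net.nodes])
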