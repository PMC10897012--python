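"""Comorbidity edge inference: hypergeometric co-occurrence tests, FDR, MI weights.

Two diseases are comorbid in a stratum when they co-occur in the same person
more often than expected by chance. With N cases in the stratum, n_a and n_b
cases carrying diseases A and B, and k cases carrying both, the chance model
is the hypergeometric distribution: the upper-tail probability

    p = P(X >= k),   X ~ Hypergeometric(N, n_a, n_b)

is the one-sided test of excess co-occurrence. The test universe is every
unordered pair of observed diseases that co-occurs at least once (k >= 1);
Benjamini-Hochberg step-up over that universe controls the false-discovery
rate, and pairs significant at the chosen level become edges weighted by the
plug-in mutual information (in nats) of the two binary indicators:

    MI = sum_{x,y} p(x,y) ln[ p(x,y) / (p(x) p(y)) ],   0 ln 0 = 0.

The estimator :class:`ComorbidityNetworkInference` exposes this as a
scikit-learn-style ``fit`` on a binary patient x disease matrix, with the
full test table in ``tests_`` and the significance-filtered, MI-weighted
undirected graph in ``graph_``. The module-level functions are thin wrappers
used by the per-stratum pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.stats.multitest import multipletests

from .records import IncidenceMatrix, StratumSpec

__all__ = [
    "PairTest",
    "ComorbidityNetwork",
    "ComorbidityNetworkInference",
    "hypergeom_pvalue",
    "bh_adjust",
    "mutual_information",
    "pairwise_tests",
    "build_network",
]

TEST_TABLE_COLUMNS = [
    "code_a",
    "code_b",
    "N",
    "n_a",
    "n_b",
    "k",
    "p_value",
    "q_value",
    "mi",
    "significant",
]


@dataclass(frozen=True)
class PairTest:
    """One disease pair's co-occurrence test (pair stored with code_a < code_b)."""

    code_a: str
    code_b: str
    N: int
    n_a: int
    n_b: int
    k: int
    p_value: float
    q_value: float
    mi: float
    significant: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.code_a, self.code_b)


@dataclass
class ComorbidityNetwork:
    """Undirected MI-weighted graph of FDR-significant disease pairs for one stratum.

    Edge attributes: ``mi`` (= ``weight``), ``p_value``, ``q_value``, ``k``,
    ``n_a``, ``n_b``. Nodes are exactly the union of edge endpoints.
    """

    graph: nx.Graph
    stratum: str | None = None
    alpha: float = 0.05

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, code_a: str, code_b: str) -> bool:
        return self.graph.has_edge(code_a, code_b)

    def edge_mi(self, code_a: str, code_b: str) -> float:
        return self.graph.edges[code_a, code_b]["mi"]


def hypergeom_pvalue(N: int, n_a: int, n_b: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap of two fixed subsets of sizes ``n_a`` and ``n_b``
    drawn from a population of ``N``; the function is symmetric in
    ``n_a``/``n_b`` and uses the scipy survival function (log-space stable).
    """
    N, n_a, n_b, k = int(N), int(n_a), int(n_b), int(k)
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError(f"marginals out of range: N={N}, n_a={n_a}, n_b={n_b}")
    if not (max(0, n_a + n_b - N) <= k <= min(n_a, n_b)):
        raise ValueError(f"infeasible overlap k={k} for N={N}, n_a={n_a}, n_b={n_b}")
    p = float(hypergeom.sf(k - 1, N, n_a, n_b))
    # the upper tail at a feasible k is mathematically > 0; guard underflow
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and rejection flags.

    q-values are monotone (cumulative minimum from the largest p); rejection
    follows the canonical step-up, i.e. q <= alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def mutual_information(n11: int, n10: int, n01: int, n00: int) -> float:
    """Plug-in mutual information of two binary indicators, in nats.

    Arguments are the 2x2 joint counts (both, A only, B only, neither);
    zero cells contribute nothing (0 ln 0 = 0). Exactly 0 when the empirical
    joint factorizes (n11 * n00 == n10 * n01), which covers degenerate
    margins.
    """
    counts = np.array([n11, n10, n01, n00], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("total count must be >= 1")
    if n11 * n00 == n10 * n01:  # exact empirical independence
        return 0.0
    pa = (counts[0] + counts[1]) / n
    pb = (counts[0] + counts[2]) / n
    margins = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    pj = counts / n
    nz = pj > 0
    return float(max(np.sum(pj[nz] * np.log(pj[nz] / margins[nz])), 0.0))


def _mi_vectorized(n11, n10, n01, n00) -> np.ndarray:
    """Vectorized plug-in MI over arrays of 2x2 counts (nats)."""
    stacked = np.stack([n11, n10, n01, n00]).astype(float)
    n = stacked.sum(axis=0)
    pa = (stacked[0] + stacked[1]) / n
    pb = (stacked[0] + stacked[2]) / n
    margins = np.stack([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    pj = stacked / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pj > 0, pj * np.log(pj / margins), 0.0)
    mi = np.maximum(terms.sum(axis=0), 0.0)
    return np.where(n11 * n00 == n10 * n01, 0.0, mi)


def _test_table(matrix: np.ndarray, names: list[str], alpha: float) -> pd.DataFrame:
    """Pairwise test table over every unordered pair with k >= 1."""
    N = matrix.shape[0]
    X = matrix.astype(np.int64)
    co = X.T @ X
    marg = np.diag(co).copy()
    ia, ib = np.triu_indices(len(names), k=1)
    k = co[ia, ib]
    keep = k >= 1
    ia, ib, k = ia[keep], ib[keep], k[keep]
    na, nb = marg[ia], marg[ib]
    if len(k):
        p = hypergeom.sf(k - 1, N, na, nb)
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
        q, reject = bh_adjust(p, alpha)
        mi = _mi_vectorized(k, na - k, nb - k, N - na - nb + k)
    else:
        p = q = mi = np.empty(0)
        reject = np.empty(0, dtype=bool)
    code_a = np.array([names[i] for i in ia], dtype=object)
    code_b = np.array([names[j] for j in ib], dtype=object)
    # store each pair with code_a < code_b regardless of column order
    swap = code_a > code_b
    code_a[swap], code_b[swap] = code_b[swap], code_a[swap].copy()
    na = np.where(swap, nb, na)
    nb_ = np.where(swap, marg[ia], nb)
    df = pd.DataFrame(
        {
            "code_a": code_a,
            "code_b": code_b,
            "N": N,
            "n_a": na,
            "n_b": nb_,
            "k": k,
            "p_value": p,
            "q_value": q,
            "mi": mi,
            "significant": reject,
        }
    )
    return df.sort_values(
        ["q_value", "p_value", "code_a", "code_b"], kind="mergesort"
    ).reset_index(drop=True)


class ComorbidityNetworkInference(BaseEstimator):
    """Significance-filtered, MI-weighted comorbidity network estimator.

    Fits on a binary patient x disease matrix: tests every co-occurring
    disease pair with the one-sided hypergeometric test, applies
    Benjamini-Hochberg FDR across the stratum's test universe, and keeps
    significant pairs as undirected edges weighted by mutual information.

    Parameters
    ----------
    alpha : float, default 0.05
        FDR level; an edge requires q <= alpha.

    Attributes
    ----------
    tests_ : pandas.DataFrame
        Full test table (code_a, code_b, N, n_a, n_b, k, p_value, q_value,
        mi, significant), sorted by (q, p, pair).
    graph_ : networkx.Graph
        Significant pairs as edges; nodes are edge endpoints only.
    n_features_in_ : int
    feature_names_in_ : ndarray of str
        Disease codes (column names when X is a DataFrame).

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"I10": [1, 1, 0, 1], "E11": [1, 1, 0, 0]})
    >>> est = ComorbidityNetworkInference(alpha=0.5).fit(X)
    >>> est.tests_.shape[0]
    1
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y=None):
        """Run the pairwise tests on binary occurrence data X."""
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if hasattr(X, "columns"):
            names = [str(c) for c in X.columns]
        else:
            names = None
        X = check_array(X, dtype=None, ensure_2d=True)
        values = np.unique(X)
        if not np.isin(values, [0, 1, True, False]).all():
            raise ValueError("X must be a binary occurrence matrix")
        X = X.astype(bool)
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.tests_ = _test_table(X, names, self.alpha)
        G = nx.Graph()
        for row in self.tests_.itertuples(index=False):
            if row.significant:
                G.add_edge(
                    row.code_a,
                    row.code_b,
                    mi=float(row.mi),
                    weight=float(row.mi),
                    p_value=float(row.p_value),
                    q_value=float(row.q_value),
                    k=int(row.k),
                    n_a=int(row.n_a),
                    n_b=int(row.n_b),
                )
        self.graph_ = G
        return self

    def to_network(self, stratum: str | None = None) -> ComorbidityNetwork:
        """Wrap the fitted graph as a :class:`ComorbidityNetwork`."""
        check_is_fitted(self, "graph_")
        return ComorbidityNetwork(
            graph=self.graph_.copy(), stratum=stratum, alpha=self.alpha
        )


def pairwise_tests(incidence: IncidenceMatrix, alpha: float = 0.05) -> list[PairTest]:
    """Test every co-occurring disease pair of one stratum's incidence matrix.

    Returns the full table as :class:`PairTest` objects sorted by
    (q, p, pair); q-values come from BH over exactly this test universe.
    """
    if incidence.is_empty or not incidence.diseases:
        return []
    df = _test_table(incidence.matrix, incidence.diseases, alpha)
    return [
        PairTest(
            code_a=r.code_a,
            code_b=r.code_b,
            N=int(r.N),
            n_a=int(r.n_a),
            n_b=int(r.n_b),
            k=int(r.k),
            p_value=float(r.p_value),
            q_value=float(r.q_value),
            mi=float(r.mi),
            significant=bool(r.significant),
        )
        for r in df.itertuples(index=False)
    ]


def build_network(incidence: IncidenceMatrix, alpha: float = 0.05) -> ComorbidityNetwork:
    """Assemble the significance-filtered, MI-weighted network for one stratum.

    Nodes are the union of significant-edge endpoints (no isolated nodes);
    an empty incidence matrix yields a valid empty network.
    """
    label = incidence.stratum.label if isinstance(incidence.stratum, StratumSpec) else (
        incidence.stratum if isinstance(incidence.stratum, str) else None
    )
    if incidence.is_empty or not incidence.diseases:
        return ComorbidityNetwork(graph=nx.Graph(), stratum=label, alpha=alpha)
    est = ComorbidityNetworkInference(alpha=alpha).fit(
        pd.DataFrame(incidence.matrix, columns=incidence.diseases)
    )
    return est.to_network(stratum=label)
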