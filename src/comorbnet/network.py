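"""Spearman association testing and disease-network construction.

Each unordered pair of diagnosis codes is tested for association across
patient-year binary presence vectors using Spearman's rank-order correlation
(on binary data this coincides with the phi coefficient).  Pairs whose
p-value clears the significance threshold become edges of an undirected
weighted network whose nodes are ICD-10 codes; edge weight is the
correlation.  Hubs — codes connecting to many others — are read off the
degree/strength table.

Significance defaults to the raw two-sided p < 0.05; Benjamini-Hochberg
false-discovery-rate adjustment is available but off by default, since claims
analyses of this kind commonly report uncorrected associations and flag the
multiplicity caveat instead.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cooccurrence import DiagnosisSetTable, Window

__all__ = [
    "CODE_LABELS",
    "FOCAL_CODES",
    "SpearmanResult",
    "EdgeTest",
    "spearman_association",
    "pairwise_associations",
    "adjust_bh",
    "build_network",
    "node_centrality",
    "compute_layout",
    "export_network",
    "import_network",
]

#: Human-readable labels for the focal comorbidity vocabulary.
CODE_LABELS: dict[str, str] = {
    "J45909": "Asthma",
    "J449": "COPD",
    "J9601": "Acute respiratory failure",
    "J189": "Pneumonia",
    "J441": "COPD with acute exacerbation",
    "I10": "Hypertension",
    "E785": "Hyperlipidemia",
    "E119": "Type 2 diabetes",
    "K219": "GERD",
    "F419": "Anxiety disorder",
    "F329": "Depressive disorder",
    "E6601": "Morbid obesity",
    "E669": "Obesity",
    "E876": "Hypokalemia",
    "E1122": "Type 2 diabetes with CKD",
    "E1151": "Type 2 diabetes with angiopathy",
}

#: Default ten-code focal vocabulary: five respiratory codes and five common
#: systemic comorbidities.
FOCAL_CODES: tuple[str, ...] = (
    "J45909", "J449", "J9601", "J189", "J441",
    "I10", "E785", "E119", "K219", "F419",
)

_T_APPROX_MIN_N = 30
_MAX_EXACT_PERMUTATIONS = 10_000
_MC_PERMUTATIONS = 10_000


@dataclasses.dataclass(frozen=True)
class SpearmanResult:
    """One Spearman test: rho, two-sided p, sample size, degeneracy flag."""

    rho: float | None
    p_value: float | None
    n: int
    degenerate: bool = False


def _distinct_permutation_count(values: np.ndarray) -> float:
    """Number of distinct orderings of a multiset: n! / prod(tie-count!)."""
    n = len(values)
    total = math.lgamma(n + 1)
    for count in pd.Series(values).value_counts().to_numpy():
        total -= math.lgamma(count + 1)
    return math.exp(total)


def _multiset_permutations(values: np.ndarray):
    """Yield each distinct ordering of ``values`` exactly once."""
    items = sorted(pd.Series(values).value_counts().items())
    n = len(values)
    out = np.empty(n, dtype=float)

    def rec(pos: int, counts: list[list[float]]):
        if pos == n:
            yield out.copy()
            return
        for entry in counts:
            if entry[1] > 0:
                out[pos] = entry[0]
                entry[1] -= 1
                yield from rec(pos + 1, counts)
                entry[1] += 1

    yield from rec(0, [[v, c] for v, c in items])


def _rank_correlation(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two mid-rank vectors (tie-corrected Spearman)."""
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    return float((rxc @ ryc) / denom)


def spearman_association(
    x: Sequence[float],
    y: Sequence[float],
    seed: int | None = 0,
) -> SpearmanResult:
    """Spearman rank correlation with a sample-size-adaptive p-value.

    rho is the Pearson correlation of mid-ranks (tie-corrected).  The
    two-sided p-value uses the t-distribution approximation for n >= 30; for
    smaller samples it is a permutation p-value — full enumeration of the
    distinct orderings of y when there are at most 10,000 of them, otherwise
    a seeded 10,000-draw Monte-Carlo permutation test.

    A constant input vector has no ranking to correlate: the result is
    flagged ``degenerate`` with ``rho`` and ``p_value`` absent (callers
    exclude such pairs from edges rather than erroring).

    Raises
    ------
    ValueError
        On mismatched lengths or fewer than 3 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=None, p_value=None, n=n, degenerate=True)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_correlation(rx, ry)

    if n >= _T_APPROX_MIN_N:
        p = _t_approx_p(rho, n)
    else:
        abs_obs = abs(rho) - 1e-12
        if _distinct_permutation_count(ry) <= _MAX_EXACT_PERMUTATIONS:
            hits = total = 0
            for perm in _multiset_permutations(ry):
                total += 1
                if abs(_rank_correlation(rx, perm)) >= abs_obs:
                    hits += 1
            p = hits / total
        else:
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(_MC_PERMUTATIONS):
                if abs(_rank_correlation(rx, rng.permutation(ry))) >= abs_obs:
                    hits += 1
            p = (hits + 1) / (_MC_PERMUTATIONS + 1)
    return SpearmanResult(rho=rho, p_value=float(p), n=n)


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


@dataclasses.dataclass(frozen=True)
class EdgeTest:
    """Association test for one unordered code pair."""

    code_a: str
    code_b: str
    rho: float | None
    p_value: float | None
    n: int
    p_adjusted: float | None = None
    significant: bool = False
    degenerate: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.code_a, self.code_b)))


def pairwise_associations(
    sets: DiagnosisSetTable,
    vocabulary: Sequence[str],
    window: Window = "pooled",
    alpha: float = 0.05,
    use_adjusted: bool = False,
    seed: int = 0,
    n_universe: int | None = None,
) -> list[EdgeTest]:
    """Test every unordered pair of vocabulary codes for association.

    Binary presence vectors are indexed by the patient-year entries in the
    window; all k(k-1)/2 pairs are returned, significant or not.  Pairs
    involving a constant (all-present or all-absent) code column are flagged
    degenerate and never significant.  When ``use_adjusted`` is set,
    Benjamini-Hochberg adjusted p-values (computed across the non-degenerate
    pairs) drive the significance flag; otherwise raw p-values do.

    ``n_universe`` is the total number of enrolled patient-years in the
    window when known (e.g. from a membership roster or a synthetic cohort's
    design).  Patient-years that generated no claim then enter as all-zero
    presence rows, so correlations refer to the enrolled population.  Left
    unset, the observation unit is utilizing patient-years only — the only
    denominator visible in bare claims — which conditions on care-seeking
    and can induce mild negative (Berkson-type) association between
    otherwise independent codes.

    Raises
    ------
    ValueError
        With fewer than 2 codes or fewer than 3 patient-year observations.
    """
    vocab = list(dict.fromkeys(vocabulary))
    if len(vocab) < 2:
        raise ValueError("need at least 2 vocabulary codes")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1): {alpha}")
    presence = sets.presence_frame(vocabulary=vocab, window=window)
    n = len(presence)
    if n_universe is not None:
        if n_universe < n:
            raise ValueError(
                f"universe ({n_universe}) smaller than observed entries ({n})"
            )
        n = n_universe
    if n < 3:
        raise ValueError("need at least 3 patient-year observations")

    data = presence.to_numpy(dtype=float)
    if n > len(presence):
        data = np.vstack([data, np.zeros((n - len(presence), len(vocab)))])
    constant = np.ptp(data, axis=0) == 0
    # Ranking is column-wise, so rank once and correlate every pair at once.
    ranks = np.apply_along_axis(stats.rankdata, 0, data)

    tests: list[EdgeTest] = []
    for i, j in itertools.combinations(range(len(vocab)), 2):
        a, b = vocab[i], vocab[j]
        if constant[i] or constant[j]:
            tests.append(EdgeTest(a, b, None, None, n, degenerate=True))
            continue
        if n >= _T_APPROX_MIN_N:
            rho = _rank_correlation(ranks[:, i], ranks[:, j])
            res = SpearmanResult(rho=rho, p_value=_t_approx_p(rho, n), n=n)
        else:
            res = spearman_association(data[:, i], data[:, j], seed=seed)
        tests.append(EdgeTest(a, b, res.rho, res.p_value, n))

    live = [t for t in tests if not t.degenerate]
    adjusted = adjust_bh([t.p_value for t in live]) if live else []
    adj_map = {t.pair: q for t, q in zip(live, adjusted)}

    out: list[EdgeTest] = []
    for t in tests:
        if t.degenerate:
            out.append(t)
            continue
        q = adj_map[t.pair]
        chosen = q if use_adjusted else t.p_value
        out.append(
            dataclasses.replace(t, p_adjusted=q, significant=bool(chosen < alpha))
        )
    return out


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Sort ascending, scale p_(i) by m/i, enforce monotone non-decreasing from
    the largest rank down, cap at 1.

    Raises
    ------
    ValueError
        If any value falls outside [0, 1].
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def build_network(
    tests: Sequence[EdgeTest],
    alpha: float = 0.05,
    use_adjusted: bool = False,
    include_isolates: Sequence[str] | None = None,
    labels: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Assemble the undirected weighted disease network from edge tests.

    Nodes are ICD-10 codes appearing in at least one retained edge (plus, if
    ``include_isolates`` is given, every code of that vocabulary); edges are
    the tests whose chosen p-value (raw, or BH-adjusted with
    ``use_adjusted``) is strictly below ``alpha``, weighted by rho.
    Degenerate tests never become edges.  An empty network is a valid result,
    not an error.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1): {alpha}")
    labels = CODE_LABELS if labels is None else dict(labels)
    G = nx.Graph(alpha=alpha, use_adjusted=use_adjusted)
    if include_isolates is not None:
        for code in include_isolates:
            G.add_node(code)
    for t in tests:
        if t.degenerate:
            continue
        chosen = t.p_adjusted if use_adjusted else t.p_value
        if chosen is None:
            raise ValueError(f"adjusted p requested but absent for pair {t.pair}")
        if chosen < alpha:
            G.add_edge(t.code_a, t.code_b, weight=float(t.rho),
                       p=float(t.p_value), n=int(t.n))
    for code in G.nodes:
        if code in labels:
            G.nodes[code]["label"] = labels[code]
    return G


def node_centrality(network: nx.Graph) -> pd.DataFrame:
    """Degree and strength (sum of |rho| over incident edges) per node.

    Sorted by degree, then strength, descending, with lexicographic code
    order as the deterministic tie-break.  Empty network → empty table.
    """
    rows = [
        (
            code,
            network.degree(code),
            float(sum(abs(d["weight"]) for d in network[code].values())),
        )
        for code in network.nodes
    ]
    table = pd.DataFrame(rows, columns=["code", "degree", "strength"])
    return table.sort_values(
        ["degree", "strength", "code"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)


def compute_layout(
    network: nx.Graph, seed: int = 0, iterations: int = 100
) -> dict[str, tuple[float, float]]:
    """Seeded Fruchterman-Reingold force-directed layout.

    Runs a fixed number of spring iterations from seeded initial positions,
    so the same network and seed always reproduce the same coordinates.
    Coordinates are stored on the nodes (attributes ``x``, ``y``) and
    returned as a mapping.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty network")
    pos = nx.spring_layout(network, seed=seed, iterations=iterations)
    out = {}
    for code, (x, y) in pos.items():
        network.nodes[code]["x"] = float(x)
        network.nodes[code]["y"] = float(y)
        out[code] = (float(x), float(y))
    return out


def export_network(network: nx.Graph, target: str, fmt: str = "graphml") -> None:
    """Write the network as GraphML or a long-format edge list.

    GraphML keeps node labels and layout coordinates as attributes; the edge
    list is a delimited table (code_a, code_b, rho, p, n).

    Raises
    ------
    ValueError
        On an unknown format name.
    """
    if fmt == "graphml":
        nx.write_graphml(network, target)
    elif fmt == "edge-list":
        rows = [
            (a, b, d["weight"], d["p"], d["n"])
            for a, b, d in sorted(network.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["code_a", "code_b", "rho", "p", "n"]).to_csv(
            target, index=False
        )
    else:
        raise ValueError(f"unknown network export format: {fmt!r}")


def import_network(source: str, fmt: str = "graphml") -> nx.Graph:
    """Re-read a network written by :func:`export_network`."""
    if fmt == "graphml":
        return nx.read_graphml(source)
    if fmt == "edge-list":
        df = pd.read_csv(source)
        G = nx.Graph()
        for row in df.itertuples(index=False):
            G.add_edge(row.code_a, row.code_b, weight=float(row.rho),
                       p=float(row.p), n=int(row.n))
        return G
    raise ValueError(f"unknown network import format: {fmt!r}")
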