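"""Metabolite association networks from abundance profiles.

Edges are partial correlations between feature abundances across cultivars,
estimated by a shrinkage covariance scheme (sample correlation shrunk toward
the identity with an analytic, variance-minimizing intensity), so the
estimate is well conditioned even with many more features than samples.
Edge significance follows an empirical-Bayes mixture: observed partial
correlations r are modelled as eta0 * f0(r; kappa) + (1 - eta0) * fA(r)
with the null density f0(r; kappa) proportional to (1 - r^2)^((kappa-3)/2);
an edge's posterior probability is 1 minus its local false discovery rate,
and edges with probability above a threshold (default 0.99) enter the
network. Dense regions are extracted with the MCODE heuristic (k-core
vertex weighting, greedy seed expansion) and compound-class annotations are
transferred from annotated nodes to their unannotated cluster neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .spectra import FeatureRecord, MS2TEntry


@dataclass(frozen=True)
class AlignParams:
    """Tolerances for aligning sample features against an MS2T library."""

    rt_tol: float = 0.35
    mz_tol_ppm: float = 5.0

    def __post_init__(self):
        if self.rt_tol <= 0 or self.mz_tol_ppm <= 0:
            raise ValueError("alignment tolerances must be positive")


@dataclass(frozen=True)
class ShrinkageResult:
    """Shrinkage intensity and the resulting partial-correlation matrix."""

    lam: float
    pcor: pd.DataFrame
    n_samples: int


@dataclass(frozen=True)
class GGMNullModel:
    """Null component of the partial-correlation mixture."""

    kappa: float
    eta0: float

    def density(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        k = self.kappa
        logc = special.betaln(0.5, (k - 1) / 2)
        return np.exp(((k - 3) / 2) * np.log1p(-np.clip(r, -1, 1) ** 2) - logc)


@dataclass(frozen=True)
class NetworkEdge:
    """A feature pair with its partial correlation and posterior probability."""

    a: str
    b: str
    pcor: float
    probability: float


@dataclass(frozen=True)
class MCODEParams:
    """MCODE clustering parameters (published defaults)."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False


@dataclass(frozen=True)
class Cluster:
    """A ranked MCODE cluster."""

    members: tuple[str, ...]
    score: float
    density: float
    seed: str


@dataclass(frozen=True)
class AssociationNetwork:
    """Selected edges as a graph, plus features left without any edge."""

    graph: nx.Graph
    isolated: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Profile construction


def align_profiles(sample_features: Mapping[str, Sequence[FeatureRecord]],
                   library: Sequence[MS2TEntry],
                   p: AlignParams = AlignParams()) -> pd.DataFrame:
    """Align per-sample features to the MS2T library (samples x library ids).

    Each sample feature is assigned to at most one library entry within the
    RT and ppm windows, nearest RT first then smallest ppm; unmatched sample
    features are dropped and unmatched library entries get zero. Cell values
    are the feature's maximal area (pre-normalization).
    """
    lib_ids = [e.feature.id for e in library]
    out = pd.DataFrame(0.0, index=list(sample_features), columns=lib_ids)
    for sample, feats in sample_features.items():
        for f in feats:
            best: Optional[tuple[float, float, str]] = None
            for e in library:
                lf = e.feature
                if lf.ion_mode != f.ion_mode:
                    continue
                drt = abs(lf.rt - f.rt)
                if drt > p.rt_tol:
                    continue
                ppm = abs(lf.mz - f.mz) / lf.mz * 1e6
                if ppm > p.mz_tol_ppm:
                    continue
                key = (drt, ppm, lf.id)
                if best is None or key < best:
                    best = key
            if best is not None:
                out.loc[sample, best[2]] += f.max_area()
    return out


def normalize_profiles(areas: pd.DataFrame,
                       internal_standard: pd.Series,
                       reference_runs: Sequence[str],
                       replicates: Optional[Mapping[str, str]] = None,
                       ) -> pd.DataFrame:
    """Normalize injection areas and return averaged, log2 profiles.

    ``areas`` is injections x features in analytical-sequence order
    (row order = injection order). Each injection's areas are divided by
    its internal-standard area; per feature, a drift factor interpolated
    linearly between the flanking reference-mixture runs (named in
    ``reference_runs``) divides the result. Biological replicates (grouped
    by ``replicates``: injection -> sample label) are averaged, and the
    matrix is log2(x + eps) transformed with eps = half the smallest nonzero
    normalized value. Injections with a non-positive internal standard are
    rejected.
    """
    bad = [inj for inj in areas.index if internal_standard.get(inj, 0) <= 0]
    if bad:
        raise ValueError(f"injections with non-positive internal standard: {bad}")
    norm = areas.div(internal_standard.reindex(areas.index), axis=0)

    positions = {inj: i for i, inj in enumerate(areas.index)}
    ref_pos = np.array([positions[r] for r in reference_runs if r in positions])
    if ref_pos.size >= 2:
        all_pos = np.arange(len(areas.index))
        for col in norm.columns:
            ref_vals = norm[col].iloc[ref_pos].to_numpy(dtype=float)
            mean_ref = ref_vals.mean()
            if mean_ref <= 0:
                continue
            drift = np.interp(all_pos, ref_pos, ref_vals) / mean_ref
            drift[drift <= 0] = 1.0
            norm[col] = norm[col].to_numpy() / drift

    biological = norm.drop(index=[r for r in reference_runs if r in norm.index])
    if replicates:
        groups = pd.Series({inj: replicates[inj] for inj in biological.index
                            if inj in replicates})
        biological = biological.loc[groups.index].groupby(groups).mean()
    vals = biological.to_numpy()
    nonzero = vals[vals > 0]
    eps = nonzero.min() / 2 if nonzero.size else 1.0
    return np.log2(biological + eps)


# ---------------------------------------------------------------------------
# Shrinkage partial correlation


def estimate_pcor(matrix: pd.DataFrame) -> ShrinkageResult:
    """Shrinkage partial correlations (identity target, analytic intensity).

    Columns are standardized; the sample correlation R is shrunk as
    R* = (1 - lambda) R + lambda I with the analytic variance-minimizing
    lambda clipped to [0, 1]; partial correlations come from the negative
    scaled inverse of R*.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("estimate_pcor requires at least 3 samples")
    sd = X.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        names = [matrix.columns[i] for i in zero_var]
        raise ValueError(f"constant feature columns: {names}")
    Z = (X - X.mean(axis=0)) / sd

    W = np.einsum("ki,kj->kij", Z, Z)          # n x p x p products
    wbar = W.mean(axis=0)
    R = wbar * n / (n - 1)
    var_r = (n / (n - 1) ** 3) * ((W - wbar) ** 2).sum(axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = (R[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))

    R_star = (1 - lam) * R
    np.fill_diagonal(R_star, 1.0)
    omega = np.linalg.inv(R_star)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = (pcor + pcor.T) / 2
    return ShrinkageResult(lam=lam,
                           pcor=pd.DataFrame(pcor, index=matrix.columns,
                                             columns=matrix.columns),
                           n_samples=n)


# ---------------------------------------------------------------------------
# Empirical-Bayes edge probabilities


def _fit_kappa(r_null: np.ndarray, r0: float) -> float:
    """ML fit of kappa from |r| <= r0, under the truncated null density."""
    r2 = np.clip(r_null, -1 + 1e-12, 1 - 1e-12) ** 2
    log1m = np.log1p(-r2)
    n0 = r_null.size

    def nll(phi: float) -> float:
        k = 3.0 + math.exp(phi)
        logc = special.betaln(0.5, (k - 1) / 2)
        mass = special.betainc(0.5, (k - 1) / 2, r0 ** 2)
        mass = max(mass, 1e-300)
        ll = ((k - 3) / 2) * log1m.sum() - n0 * (logc + math.log(mass))
        return -ll

    res = optimize.minimize_scalar(nll, bounds=(-5, 20), method="bounded")
    return 3.0 + math.exp(res.x)


def fit_null_and_probabilities(result: ShrinkageResult,
                               ) -> tuple[GGMNullModel, list[NetworkEdge]]:
    """Fit the null mixture and assign each edge a posterior probability.

    kappa is fitted by maximum likelihood of the truncated null on the
    central 75% of |r|; eta0 is the central count divided by the null mass
    in that region (capped at 1). The total density f is a Gaussian kernel
    estimate over all r; local fdr = eta0 f0 / f (clipped to [0, 1]) and
    probability = 1 - fdr, made monotone non-decreasing in |r| by a running
    maximum.
    """
    cols = list(result.pcor.columns)
    P = result.pcor.to_numpy()
    iu = np.triu_indices(len(cols), k=1)
    r = P[iu]
    if r.size < 10:
        raise ValueError("need at least 10 feature pairs to fit the null")
    if np.all(r == 0):
        # full shrinkage (lambda = 1): no evidence for any association
        null = GGMNullModel(kappa=result.n_samples + 10.0, eta0=1.0)
        return null, [NetworkEdge(a=cols[i], b=cols[j], pcor=0.0, probability=0.0)
                      for i, j in zip(*iu)]
    if np.allclose(r, r[0]):
        raise ValueError("degenerate partial correlations: all values equal")

    r0 = float(np.quantile(np.abs(r), 0.75))
    r0 = min(max(r0, 1e-4), 0.999)
    central = r[np.abs(r) <= r0]
    kappa = _fit_kappa(central, r0)
    null = GGMNullModel(kappa=kappa, eta0=1.0)
    mass0 = float(special.betainc(0.5, (kappa - 1) / 2, r0 ** 2))
    eta0 = min(1.0, (central.size / r.size) / max(mass0, 1e-12))
    null = GGMNullModel(kappa=kappa, eta0=eta0)

    try:
        kde = stats.gaussian_kde(r)
        f_total = kde(r)
    except np.linalg.LinAlgError:
        f_total = np.full(r.size, np.nan)
    f0 = null.density(r)
    f_total = np.fmax(f_total, eta0 * f0)     # fdr <= 1 by construction
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(f_total > 0, eta0 * f0 / f_total, 1.0)
    prob = 1.0 - np.clip(fdr, 0.0, 1.0)

    order = np.argsort(np.abs(r), kind="stable")
    prob_sorted = np.maximum.accumulate(prob[order])
    prob_final = np.empty_like(prob)
    prob_final[order] = prob_sorted

    edges = [NetworkEdge(a=cols[i], b=cols[j], pcor=float(P[i, j]),
                         probability=float(pr))
             for i, j, pr in zip(iu[0], iu[1], prob_final)]
    return null, edges


def permutation_null_probabilities(matrix: pd.DataFrame,
                                   result: ShrinkageResult,
                                   rounds: int = 100,
                                   seed: int = 0) -> list[NetworkEdge]:
    """Permutation-null alternative to the parametric mixture fit.

    Columns are permuted independently ``rounds`` times; the pooled null
    partial correlations give a kernel null density f0 and each edge's
    probability is 1 - f0(r)/f(r) (capped to [0, 1], eta0 = 1, monotone in
    |r| by running maximum). Heavier than the parametric route but free of
    the null-family assumption.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy().copy()
    n, p = X.shape
    null_vals = []
    for _ in range(rounds):
        perm = np.empty_like(X)
        for j in range(p):
            perm[:, j] = X[rng.permutation(n), j]
        res = estimate_pcor(pd.DataFrame(perm, columns=matrix.columns))
        iu = np.triu_indices(p, k=1)
        null_vals.append(res.pcor.to_numpy()[iu])
    null_vals = np.concatenate(null_vals)

    cols = list(result.pcor.columns)
    P = result.pcor.to_numpy()
    iu = np.triu_indices(len(cols), k=1)
    r = P[iu]
    f0 = stats.gaussian_kde(null_vals)(r)
    f = np.fmax(stats.gaussian_kde(r)(r), f0)
    prob = 1.0 - np.clip(f0 / f, 0.0, 1.0)
    order = np.argsort(np.abs(r), kind="stable")
    prob_sorted = np.maximum.accumulate(prob[order])
    prob_final = np.empty_like(prob)
    prob_final[order] = prob_sorted
    return [NetworkEdge(a=cols[i], b=cols[j], pcor=float(P[i, j]),
                        probability=float(pr))
            for i, j, pr in zip(iu[0], iu[1], prob_final)]


def select_edges(edges: Sequence[NetworkEdge], threshold: float = 0.99,
                 all_features: Optional[Sequence[str]] = None,
                 ) -> AssociationNetwork:
    """Keep edges with posterior probability above ``threshold``.

    Nodes are the features incident to a kept edge; features named in
    ``all_features`` (or appearing in any candidate edge) that end up with
    no edge are flagged as isolated.
    """
    G = nx.Graph()
    mentioned: set[str] = set()
    for e in edges:
        mentioned.update((e.a, e.b))
        if e.probability > threshold:
            G.add_edge(e.a, e.b, pcor=e.pcor, probability=e.probability)
    universe = set(all_features) if all_features is not None else mentioned
    isolated = tuple(sorted(universe - set(G.nodes)))
    return AssociationNetwork(graph=G, isolated=isolated)


# ---------------------------------------------------------------------------
# MCODE clustering


def _core_weight(G: nx.Graph, v) -> float:
    """Core-clustering weight: (highest core number of the closed
    neighborhood) times the density of that highest k-core."""
    nbhd = set(G[v]) | {v}
    H = G.subgraph(nbhd)
    if H.number_of_edges() == 0:
        return 0.0
    core = nx.core_number(H)
    kmax = max(core.values())
    knodes = [u for u, c in core.items() if c >= kmax]
    K = H.subgraph(knodes)
    n = K.number_of_nodes()
    if n < 2:
        return 0.0
    density = 2 * K.number_of_edges() / (n * (n - 1))
    return kmax * density


def mcode_cluster(network: AssociationNetwork | nx.Graph,
                  p: MCODEParams = MCODEParams()) -> list[Cluster]:
    """Find dense clusters with the MCODE heuristic.

    Vertices are weighted by their core-clustering coefficient; seeds are
    taken in descending weight and expanded breadth-first, admitting
    unvisited neighbours whose weight is at least (1 - node_score_cutoff)
    times the seed weight, up to ``max_depth``. Haircut removes degree-1
    members; clusters must contain a k-core of ``k_core``. Clusters are
    ranked by score = density x size, ties broken by smallest member id.
    """
    G = network.graph if isinstance(network, AssociationNetwork) else network
    if G.number_of_nodes() == 0:
        return []
    weights = {v: _core_weight(G, v) for v in G.nodes}
    visited: set = set()
    clusters: list[Cluster] = []
    for seed in sorted(G.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1 - p.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < p.max_depth:
            nxt = []
            for v in frontier:
                for u in G[v]:
                    if u in visited or u in members:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        sub = G.subgraph(members).copy()
        if p.haircut:
            drop = [v for v in sub.nodes if sub.degree(v) < 2]
            sub.remove_nodes_from(drop)
        if sub.number_of_nodes() < 2:
            continue
        core = nx.core_number(sub)
        if max(core.values(), default=0) < p.k_core:
            continue
        visited.update(members)
        n = sub.number_of_nodes()
        density = 2 * sub.number_of_edges() / (n * (n - 1))
        clusters.append(Cluster(members=tuple(sorted(sub.nodes, key=str)),
                                score=density * n, density=density, seed=seed))
    clusters.sort(key=lambda c: (-c.score, c.members))
    return clusters


def transfer_annotations(network: AssociationNetwork | nx.Graph,
                         cluster: Cluster | Sequence[str],
                         classes: Mapping[str, str],
                         ) -> dict[str, tuple[str, ...]]:
    """Transfer compound classes to unannotated cluster members.

    Each member absent from ``classes`` receives the majority class among
    its annotated direct neighbours within the cluster (all tied classes on
    a tie); members with no annotated neighbour receive an empty tuple.
    """
    G = network.graph if isinstance(network, AssociationNetwork) else network
    members = set(cluster.members if isinstance(cluster, Cluster) else cluster)
    out: dict[str, tuple[str, ...]] = {}
    for v in sorted(members, key=str):
        if v in classes:
            continue
        counts: dict[str, int] = {}
        for u in G[v]:
            if u in members and u in classes:
                counts[classes[u]] = counts.get(classes[u], 0) + 1
        if not counts:
            out[v] = ()
            continue
        best = max(counts.values())
        out[v] = tuple(sorted(c for c, k in counts.items() if k == best))
    return out


def classes_from_entries(entries: Sequence[MS2TEntry],
                         class_of: Mapping[str, str]) -> dict[str, str]:
    """Compound class per annotated feature id (helper for transfer)."""
    out = {}
    for e in entries:
        if e.annotation_source != "none" and e.annotation_name in class_of:
            out[e.feature.id] = class_of[e.annotation_name]
    return out
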