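"""Spectral similarity scoring and library search.

Two weighted-cosine scores are provided. NDP (normalized dot product)
weights every peak by intensity^a * mz^b (defaults a = 0.5, b = 2) and
computes the squared cosine between the full weighted vectors, so peaks of
one spectrum absent from the other dilute the score through the norms.
INCOS computes the squared cosine over matched peak pairs only (a = 0.5,
b = 1) and multiplies it by the geometric mean of the two matched-intensity
fractions, penalizing unmatched signal explicitly. Peak pairs are matched
greedily, closest m/z first, each peak used once, within a fragment
tolerance that is the larger of an absolute (Th) and a ppm window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .spectra import Spectrum


class EmptySpectrumError(ValueError):
    """Similarity is undefined for an empty spectrum."""


@dataclass(frozen=True)
class SimilarityParams:
    """Weighting and matching parameters for spectral similarity."""

    algorithm: str = "incos"
    intensity_power: float = 0.5
    mz_power: Optional[float] = None      # default 2 for ndp, 1 for incos
    fragment_tol: float = 0.01            # Th
    fragment_tol_ppm: float = 20.0        # ppm; effective tol = max of the two

    def __post_init__(self):
        if self.algorithm not in ("ndp", "incos"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.intensity_power < 0 or (self.mz_power is not None and self.mz_power < 0):
            raise ValueError("weighting exponents must be non-negative")
        if self.fragment_tol <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("fragment tolerances must be positive")

    @property
    def effective_mz_power(self) -> float:
        if self.mz_power is not None:
            return self.mz_power
        return 2.0 if self.algorithm == "ndp" else 1.0


@dataclass(frozen=True)
class SearchParams:
    """Precursor gating, score cutoff and result depth for library search."""

    precursor_tol_ppm: float = 10.0
    score_cutoff: float = 0.75
    top_k: int = 5

    def __post_init__(self):
        if not 0 <= self.score_cutoff <= 1:
            raise ValueError("score_cutoff must lie in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be a positive integer")


@dataclass(frozen=True)
class AnnotationResult:
    """One scored library candidate for a query spectrum."""

    query_id: str
    candidate_name: str
    candidate_library: str
    score: float
    rank: int


def match_peaks(q: Spectrum, r: Spectrum, params: SimilarityParams,
                ) -> list[tuple[int, int]]:
    """Greedy closest-pair peak matching; each peak used at most once.

    A pair (i, j) is admissible when |mz_q[i] - mz_r[j]| <= max(fragment_tol,
    fragment_tol_ppm at the mean m/z). Returns index pairs into q.peaks and
    r.peaks.
    """
    pairs = []
    for i, pq in enumerate(q.peaks):
        for j, pr in enumerate(r.peaks):
            delta = abs(pq.mz - pr.mz)
            tol = max(params.fragment_tol,
                      params.fragment_tol_ppm * 1e-6 * (pq.mz + pr.mz) / 2)
            if delta <= tol:
                pairs.append((delta, i, j))
    pairs.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_q or j in used_r:
            continue
        used_q.add(i)
        used_r.add(j)
        matched.append((i, j))
    return matched


def _weights(s: Spectrum, a: float, b: float) -> list[float]:
    return [p.intensity ** a * p.mz ** b for p in s.peaks]


def ndp_similarity(q: Spectrum, r: Spectrum,
                   params: SimilarityParams = SimilarityParams(algorithm="ndp"),
                   ) -> float:
    """Normalized dot product: squared weighted cosine over full spectra."""
    if not q.peaks or not r.peaks:
        raise EmptySpectrumError("NDP similarity requires non-empty spectra")
    a, b = params.intensity_power, (params.mz_power if params.mz_power is not None else 2.0)
    wq = _weights(q, a, b)
    wr = _weights(r, a, b)
    matched = match_peaks(q, r, params)
    dot = sum(wq[i] * wr[j] for i, j in matched)
    nq = sum(w * w for w in wq)
    nr = sum(w * w for w in wr)
    if nq == 0 or nr == 0:
        return 0.0
    return min(1.0, dot * dot / (nq * nr))


def incos_similarity(q: Spectrum, r: Spectrum,
                     params: SimilarityParams = SimilarityParams(algorithm="incos"),
                     ) -> float:
    """Matched-peak squared cosine times geometric-mean matched fraction."""
    if not q.peaks or not r.peaks:
        raise EmptySpectrumError("INCOS similarity requires non-empty spectra")
    a, b = params.intensity_power, (params.mz_power if params.mz_power is not None else 1.0)
    matched = match_peaks(q, r, params)
    if not matched:
        return 0.0
    wq = _weights(q, a, b)
    wr = _weights(r, a, b)
    dot = sum(wq[i] * wr[j] for i, j in matched)
    nq = sum(wq[i] ** 2 for i, _ in matched)
    nr = sum(wr[j] ** 2 for _, j in matched)
    if nq == 0 or nr == 0:
        return 0.0
    cos2 = dot * dot / (nq * nr)
    tq = q.total_intensity()
    tr = r.total_intensity()
    fq = sum(q.peaks[i].intensity for i, _ in matched) / tq if tq else 0.0
    fr = sum(r.peaks[j].intensity for _, j in matched) / tr if tr else 0.0
    return min(1.0, cos2 * math.sqrt(fq * fr))


def similarity(q: Spectrum, r: Spectrum, params: SimilarityParams) -> float:
    """Dispatch to the score named by ``params.algorithm``."""
    fn = ndp_similarity if params.algorithm == "ndp" else incos_similarity
    return fn(q, r, params)


def library_search(q: Spectrum, library: Sequence[Spectrum],
                   sp: SimilarityParams = SimilarityParams(),
                   kp: SearchParams = SearchParams(),
                   exclude_self: bool = False,
                   library_name: str = "library") -> list[AnnotationResult]:
    """Score a query against precursor-gated library candidates.

    Candidates within the precursor ppm window are scored, filtered at the
    score cutoff, sorted by descending score (ties: smaller precursor ppm
    error, then candidate name) and truncated to top_k. With
    ``exclude_self`` the reference whose id equals the query id is dropped.
    """
    if q.precursor_mz is None:
        raise ValueError(f"query {q.id!r} has no precursor m/z")
    scored = []
    for ref in library:
        if exclude_self and ref.id == q.id:
            continue
        if ref.precursor_mz is None:
            continue
        ppm = abs(ref.precursor_mz - q.precursor_mz) / q.precursor_mz * 1e6
        if ppm > kp.precursor_tol_ppm:
            continue
        score = similarity(q, ref, sp)
        if score > kp.score_cutoff:
            name = ref.metadata.get("NAME", ref.id) if ref.metadata else ref.id
            scored.append((-score, ppm, name, ref))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    results = []
    for rank, (negscore, ppm, name, ref) in enumerate(scored[:kp.top_k], start=1):
        results.append(AnnotationResult(query_id=q.id, candidate_name=name,
                                        candidate_library=library_name,
                                        score=-negscore, rank=rank))
    return results


def merge_annotations(per_library: Sequence[Sequence[AnnotationResult]],
                      ) -> dict[str, AnnotationResult]:
    """Keep the globally best-scoring candidate per query across libraries."""
    best: dict[str, AnnotationResult] = {}
    for results in per_library:
        for res in results:
            cur = best.get(res.query_id)
            if cur is None or res.score > cur.score:
                best[res.query_id] = replace(res, rank=1)
    return best


def evaluate_identification(queries: Sequence[tuple[Spectrum, str]],
                            library: Sequence[Spectrum],
                            sp: SimilarityParams = SimilarityParams(),
                            kp: SearchParams = SearchParams(),
                            k_values: Sequence[int] = (1, 5),
                            ) -> dict[int, float]:
    """Top-k identification rates over labelled query spectra.

    Each query is a (spectrum, true compound name) pair; the query spectrum
    itself (same id) is excluded from the library during its own search.
    rate(k) = fraction of queries whose true compound appears within the
    top k retained candidates; monotone non-decreasing in k.
    """
    if not queries:
        raise ValueError("evaluate_identification needs at least one query")
    max_k = max(k_values)
    deep = SearchParams(precursor_tol_ppm=kp.precursor_tol_ppm,
                        score_cutoff=kp.score_cutoff, top_k=max_k)
    hits_at = {k: 0 for k in k_values}
    for spec, truth in queries:
        results = library_search(spec, library, sp, deep, exclude_self=True)
        ranks = [res.rank for res in results if res.candidate_name == truth]
        first = min(ranks) if ranks else None
        for k in k_values:
            if first is not None and first <= k:
                hits_at[k] += 1
    n = len(queries)
    return {k: hits_at[k] / n for k in k_values}
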