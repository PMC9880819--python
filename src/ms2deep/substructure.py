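"""Substructure annotation by structural-motif search and neutral-loss scanning.

Glycosylated and acylated flavonoids fragment predictably: the aglycone
skeleton yields a characteristic "featured ion" and each decoration departs
as a characteristic neutral loss. A spectrum is annotated by (1) detecting
featured ions among its most intense peaks, (2) decomposing the mass gap
between the precursor and each detected skeleton ion into a multiset of
known losses, and (3) ranking proposals by how many of their losses are
independently witnessed as ion-pair differences in the spectrum, then by
mass-balance error. Motif and loss tables can also be mined from a
class-labelled corpus by pooling fragment masses and pairwise losses,
single-linkage clustering at a mass tolerance, and thresholding on the
fraction of spectra that contribute to a cluster.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chem import MotifEntry, NeutralLossEntry
from .spectra import Spectrum


@dataclass(frozen=True)
class ScanParams:
    """Tolerances and search depth for motif / neutral-loss scanning."""

    ion_tol: float = 0.01          # Th, absolute
    ion_tol_ppm: float = 20.0      # effective ion tol = max(abs, ppm at m/z)
    nl_tol: float = 0.01           # Da, for loss matching and decomposition
    max_mods: int = 4
    top_n_fragments: int = 20

    def __post_init__(self):
        if min(self.ion_tol, self.ion_tol_ppm, self.nl_tol) <= 0:
            raise ValueError("scan tolerances must be positive")
        if self.max_mods < 0 or self.top_n_fragments < 1:
            raise ValueError("max_mods must be >= 0 and top_n_fragments >= 1")


@dataclass(frozen=True)
class LossDetection:
    """A matched neutral loss between two ions of one spectrum."""

    entry: NeutralLossEntry
    from_mz: float      # heavier ion (precursor or fragment)
    to_mz: float        # lighter ion
    delta: float


@dataclass(frozen=True)
class SubstructureAnnotation:
    """Skeleton + modification multiset inferred for one spectrum."""

    skeleton: MotifEntry
    modifications: tuple[NeutralLossEntry, ...]   # sorted by name
    witnessed: int                 # modifications seen as ion-pair losses
    mass_balance_error: float      # ppm
    matched_ion_mz: float
    name: str


def detect_motifs(s: Spectrum, motifs: Sequence[MotifEntry],
                  p: ScanParams = ScanParams()) -> list[tuple[MotifEntry, tuple]]:
    """Featured ions present among the spectrum's most intense peaks.

    Only the ``top_n_fragments`` most intense peaks are searched; a motif
    matches when its ion m/z is within tolerance of a peak and its ion mode
    matches the spectrum's. Results are sorted by matched-peak intensity,
    descending.
    """
    if not s.peaks:
        raise ValueError("cannot scan an empty spectrum")
    top = sorted(s.peaks, key=lambda pk: -pk.intensity)[:p.top_n_fragments]
    hits = []
    for motif in motifs:
        if motif.ion_mode != s.ion_mode:
            continue
        tol = max(p.ion_tol, p.ion_tol_ppm * 1e-6 * motif.ion_mz)
        best = None
        for pk in top:
            if abs(pk.mz - motif.ion_mz) <= tol:
                if best is None or pk.intensity > best.intensity:
                    best = pk
        if best is not None:
            hits.append((motif, best))
    hits.sort(key=lambda t: -t[1].intensity)
    return hits


def detect_neutral_losses(s: Spectrum, nls: Sequence[NeutralLossEntry],
                          p: ScanParams = ScanParams()) -> list[LossDetection]:
    """All precursor-fragment and fragment-fragment differences matching a loss."""
    if not s.peaks:
        raise ValueError("cannot scan an empty spectrum")
    mzs = [pk.mz for pk in s.peaks]
    pairs: list[tuple[float, float]] = []
    if s.precursor_mz is not None:
        pairs.extend((s.precursor_mz, m) for m in mzs if m < s.precursor_mz)
    pairs.extend((hi, lo) for lo, hi in itertools.combinations(mzs, 2))
    out = []
    for hi, lo in pairs:
        delta = hi - lo
        for entry in nls:
            if abs(delta - entry.mass) <= p.nl_tol:
                out.append(LossDetection(entry, from_mz=hi, to_mz=lo, delta=delta))
    return out


def decompose_mass(target: float, nls: Sequence[NeutralLossEntry],
                   tol: float = 0.01, max_mods: int = 4,
                   ) -> list[tuple[NeutralLossEntry, ...]]:
    """All loss multisets (<= max_mods entries) summing to ``target`` within tol.

    Bounded depth-first search over entries sorted descending by mass, each
    entry limited to its ``max_multiplicity``. Results sorted by |error|,
    ties by fewer modifications then name.
    """
    if target < -tol:
        raise ValueError("target mass must be non-negative (beyond tolerance)")
    entries = sorted(nls, key=lambda e: -e.mass)
    results: list[tuple[float, tuple[NeutralLossEntry, ...]]] = []

    def dfs(start: int, remaining: float, count: int, chosen: list[NeutralLossEntry]):
        if abs(remaining) <= tol:
            results.append((abs(remaining), tuple(sorted(chosen, key=lambda e: e.name))))
        if count >= max_mods:
            return
        for idx in range(start, len(entries)):
            e = entries[idx]
            used = sum(1 for c in chosen if c is e)
            if used >= e.max_multiplicity:
                continue
            if e.mass > remaining + tol:
                continue
            chosen.append(e)
            dfs(idx, remaining - e.mass, count + 1, chosen)
            chosen.pop()

    dfs(0, target, 0, [])
    seen = set()
    unique = []
    for err, combo in sorted(results, key=lambda t: (t[0], len(t[1]),
                                                     tuple(e.name for e in t[1]))):
        key = tuple(e.name for e in combo)
        if key not in seen:
            seen.add(key)
            unique.append(combo)
    return unique


def _compose_name(skeleton: MotifEntry, mods: Sequence[NeutralLossEntry]) -> str:
    if not mods:
        return skeleton.name
    return skeleton.name + " + " + " + ".join(e.name for e in mods)


def scan_spectrum(s: Spectrum, motifs: Sequence[MotifEntry],
                  nls: Sequence[NeutralLossEntry],
                  p: ScanParams = ScanParams()) -> list[SubstructureAnnotation]:
    """Annotate a spectrum as skeleton + modification multiset.

    For each detected featured ion, the precursor-skeleton mass gap is
    decomposed into candidate loss multisets; proposals are ranked by the
    number of their modifications independently witnessed as ion-pair losses
    in the spectrum (descending), then by absolute mass-balance error.
    """
    if s.precursor_mz is None:
        raise ValueError("scan_spectrum requires a precursor m/z")
    witnessed_losses = detect_neutral_losses(s, nls, p)
    witnessed_counts: dict[str, int] = {}
    for det in witnessed_losses:
        witnessed_counts[det.entry.name] = witnessed_counts.get(det.entry.name, 0) + 1

    annotations = []
    for motif, peak in detect_motifs(s, motifs, p):
        gap = s.precursor_mz - motif.ion_mz
        if gap < -p.nl_tol:
            continue
        for combo in decompose_mass(max(gap, 0.0), nls, tol=p.nl_tol,
                                    max_mods=p.max_mods):
            total = motif.ion_mz + sum(e.mass for e in combo)
            err_ppm = (s.precursor_mz - total) / s.precursor_mz * 1e6
            support = 0
            for name in {e.name for e in combo}:
                need = sum(1 for e in combo if e.name == name)
                support += min(need, witnessed_counts.get(name, 0))
            annotations.append(SubstructureAnnotation(
                skeleton=motif, modifications=combo, witnessed=support,
                mass_balance_error=err_ppm, matched_ion_mz=peak.mz,
                name=_compose_name(motif, combo)))
    annotations.sort(key=lambda a: (-a.witnessed, abs(a.mass_balance_error),
                                    len(a.modifications), a.name))
    return annotations


def _cluster_1d(values: list[tuple[float, float, int]], bin_tol: float,
                ) -> list[list[tuple[float, float, int]]]:
    """Single-linkage clustering of (mass, weight, spectrum index) at bin_tol."""
    if not values:
        return []
    values = sorted(values)
    clusters = [[values[0]]]
    for v in values[1:]:
        if v[0] - clusters[-1][-1][0] <= bin_tol:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return clusters


def mine_motifs(corpus: Sequence[Spectrum], freq_threshold: float = 0.5,
                bin_tol: float = 0.01,
                ) -> tuple[list[MotifEntry], list[NeutralLossEntry]]:
    """Mine candidate motif and neutral-loss tables from a labelled corpus.

    Fragment m/z values, and all precursor-fragment / fragment-fragment
    differences, are pooled across spectra and single-linkage clustered at
    ``bin_tol``. A cluster's frequency is the fraction of spectra that
    contribute at least one member; clusters at or above ``freq_threshold``
    are reported with the cluster's intensity-weighted mean mass (losses are
    weighted by the geometric mean of their two ion intensities).
    """
    if not corpus:
        raise ValueError("mine_motifs requires a non-empty corpus")
    n = len(corpus)
    frag_pool: list[tuple[float, float, int]] = []
    loss_pool: list[tuple[float, float, int]] = []
    for idx, s in enumerate(corpus):
        for pk in s.peaks:
            frag_pool.append((pk.mz, pk.intensity, idx))
        peaks = list(s.peaks)
        if s.precursor_mz is not None:
            for pk in peaks:
                if pk.mz < s.precursor_mz:
                    loss_pool.append((s.precursor_mz - pk.mz, pk.intensity, idx))
        for a, b in itertools.combinations(peaks, 2):
            loss_pool.append((abs(b.mz - a.mz),
                              math.sqrt(a.intensity * b.intensity), idx))

    mode = corpus[0].ion_mode
    cls = corpus[0].metadata.get("COMPOUND_CLASS", "") if corpus[0].metadata else ""

    def summarize(pool, make):
        out = []
        for cluster in _cluster_1d(pool, bin_tol):
            contributing = {idx for _, _, idx in cluster}
            freq = len(contributing) / n
            if freq >= freq_threshold:
                wsum = sum(w for _, w, _ in cluster)
                mass = (sum(m * w for m, w, _ in cluster) / wsum if wsum
                        else sum(m for m, _, _ in cluster) / len(cluster))
                out.append(make(mass, freq))
        return out

    motifs = summarize(frag_pool, lambda m, f: MotifEntry(
        name=f"motif_{m:.4f}", ion_mz=m, ion_mode=mode, compound_class=cls))
    losses = summarize(loss_pool, lambda m, f: NeutralLossEntry(
        name=f"loss_{m:.4f}", mass=m))
    return motifs, losses
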