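"""Structure-database construction and annotation against predicted spectra.

The structural database of biologically relevant compounds (SDBRC) merges
structure tables from several sources (KEGG, a curated biochemical subset
of PubChem, KNApSAcK) into one mass-sorted record list. Queries are
annotated by retrieving candidates within a ppm window of the query's
neutral mass and scoring the query MS2 spectrum against each candidate's
predicted fragmentation spectra (produced by an external fragmenter and
consumed here as files, one peak list per collision-energy level).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .matching import AnnotationResult, SearchParams, SimilarityParams, incos_similarity
from .spectra import SchemaError, Spectrum

logger = logging.getLogger(__name__)

SOURCE_PRIORITY = ("kegg", "biochem", "knapsack")


@dataclass(frozen=True)
class StructureRecord:
    """One compound structure: identifier, line notation, formula, mass."""

    identifier: str
    line_notation: str = ""
    formula: str = ""
    exact_mass: float = 0.0
    sources: frozenset = frozenset()

    def __post_init__(self):
        if not self.identifier and not self.line_notation:
            raise ValueError("structure record needs an identifier or line notation")
        if not self.exact_mass > 0:
            raise ValueError("exact_mass must be positive")


@dataclass(frozen=True)
class PredictedSpectrumSet:
    """Predicted spectra per structure (>=1 collision-energy level each)."""

    spectra: Mapping[str, tuple[Spectrum, ...]]
    predictor: str = "external"

    def __post_init__(self):
        for ident, specs in self.spectra.items():
            if not specs:
                raise ValueError(f"structure {ident!r} has no predicted spectra")

    def get(self, identifier: str) -> Optional[tuple[Spectrum, ...]]:
        return self.spectra.get(identifier)


def read_structure_table(path, source: str) -> list[StructureRecord]:
    """Read a TSV structure table (identifier, line_notation, formula, exact_mass)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"identifier", "exact_mass"}
    if not required <= set(df.columns):
        raise SchemaError(f"structure table missing columns: {sorted(required - set(df.columns))}")
    records = []
    for _, row in df.iterrows():
        records.append(StructureRecord(
            identifier=str(row["identifier"]),
            line_notation=str(row.get("line_notation", "") or ""),
            formula=str(row.get("formula", "") or ""),
            exact_mass=float(row["exact_mass"]),
            sources=frozenset([source]),
        ))
    return records


def write_structure_table(records: Sequence[StructureRecord], path) -> None:
    rows = [{"identifier": r.identifier, "line_notation": r.line_notation,
             "formula": r.formula, "exact_mass": repr(r.exact_mass),
             "sources": ",".join(sorted(r.sources))} for r in records]
    pd.DataFrame(rows, columns=["identifier", "line_notation", "formula",
                                "exact_mass", "sources"]).to_csv(path, sep="\t", index=False)


def build_sdbrc(sources: Sequence[Sequence[StructureRecord]],
                ) -> tuple[list[StructureRecord], list[str]]:
    """Merge structure tables into one non-redundant, mass-sorted database.

    Duplicate identifiers collapse to one record whose sources set is the
    union; conflicting field values are resolved by source priority
    (kegg > biochem > knapsack). Returns (records, conflict log).
    """
    def priority(rec: StructureRecord) -> int:
        best = len(SOURCE_PRIORITY)
        for s in rec.sources:
            if s in SOURCE_PRIORITY:
                best = min(best, SOURCE_PRIORITY.index(s))
        return best

    merged: dict[str, StructureRecord] = {}
    conflicts: list[str] = []
    for table in sources:
        for rec in table:
            cur = merged.get(rec.identifier)
            if cur is None:
                merged[rec.identifier] = rec
                continue
            keep, other = (cur, rec) if priority(cur) <= priority(rec) else (rec, cur)
            if abs(keep.exact_mass - other.exact_mass) > 1e-9:
                conflicts.append(
                    f"{rec.identifier}: exact_mass {other.exact_mass} from "
                    f"{sorted(other.sources)} superseded by {keep.exact_mass} "
                    f"from {sorted(keep.sources)}")
            merged[rec.identifier] = StructureRecord(
                identifier=keep.identifier,
                line_notation=keep.line_notation or other.line_notation,
                formula=keep.formula or other.formula,
                exact_mass=keep.exact_mass,
                sources=cur.sources | rec.sources,
            )
    records = sorted(merged.values(), key=lambda r: (r.exact_mass, r.identifier))
    return records, conflicts


def retrieve_candidates(query_neutral_mass: float,
                        db: Sequence[StructureRecord],
                        tol_ppm: float = 5.0) -> list[StructureRecord]:
    """All records within a ppm window of the query mass, by binary search.

    ``db`` must be sorted ascending by exact_mass (as build_sdbrc emits).
    Results are sorted by ppm error.
    """
    if not db:
        return []
    masses = np.array([r.exact_mass for r in db])
    tol = query_neutral_mass * tol_ppm * 1e-6
    lo = int(np.searchsorted(masses, query_neutral_mass - tol, side="left"))
    hi = int(np.searchsorted(masses, query_neutral_mass + tol, side="right"))
    hits = [(abs(db[i].exact_mass - query_neutral_mass) / query_neutral_mass * 1e6, i)
            for i in range(lo, hi)]
    hits.sort()
    return [db[i] for _, i in hits]


def merge_energy_levels(spectra: Sequence[Spectrum]) -> Spectrum:
    """Concatenate energy-level predictions; duplicate m/z keep max intensity.

    m/z values are considered duplicates at 5-decimal precision (the stored
    precision of predicted peak lists).
    """
    pool: dict[float, float] = {}
    for s in spectra:
        for p in s.peaks:
            key = round(p.mz, 5)
            pool[key] = max(pool.get(key, 0.0), p.intensity)
    ref = spectra[0]
    return Spectrum(id=ref.id, ion_mode=ref.ion_mode,
                    peaks=tuple(pool.items()),
                    precursor_mz=ref.precursor_mz, metadata=ref.metadata)


def insilico_search(q: Spectrum,
                    candidates: Sequence[StructureRecord],
                    predicted: PredictedSpectrumSet,
                    sp: SimilarityParams = SimilarityParams(algorithm="incos"),
                    cutoff: float = 0.3) -> list[AnnotationResult]:
    """Score a query against candidates' merged predicted spectra.

    Candidates whose score exceeds ``cutoff`` are retained, ranked by
    descending score (ties by smaller ppm error against the query precursor,
    then identifier). Candidates without predicted spectra are skipped with
    a warning.
    """
    scored = []
    for rec in candidates:
        specs = predicted.get(rec.identifier)
        if specs is None:
            warnings.warn(f"no predicted spectra for {rec.identifier!r}; skipped",
                          stacklevel=2)
            continue
        merged = merge_energy_levels(specs)
        score = incos_similarity(q, merged, sp)
        if score > cutoff:
            if q.precursor_mz:
                ppm = abs(rec.exact_mass - q.precursor_mz) / q.precursor_mz * 1e6
            else:
                ppm = 0.0
            scored.append((-score, ppm, rec.identifier))
    scored.sort()
    return [AnnotationResult(query_id=q.id, candidate_name=ident,
                             candidate_library=predicted.predictor,
                             score=-negscore, rank=rank)
            for rank, (negscore, ppm, ident) in enumerate(scored, start=1)]
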