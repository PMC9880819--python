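"""Quality control, redundancy removal and ion-mode merging of LC-MS features.

Turns raw aligned features into the non-redundant, quality-controlled,
mode-merged feature set that seeds an MS2T library. QC relies on repeated
injections of a pooled reference mixture (detection reproducibility, RSD),
blank injections (background subtraction) and absolute area floors.
Redundant ion species of one molecule — isotopologues, alkali/ammonium/
chloride adducts, in-source fragments and dimers — are collapsed onto the
protonated/deprotonated monoisotopic representative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mean
from typing import Optional, Sequence

import numpy as np

from .chem import PROTON_MASS
from .spectra import (NEGATIVE, POSITIVE, FeatureRecord, MS2TEntry,
                      neutral_mass)


class ConfigurationError(ValueError):
    """The input lacks the injections a QC criterion requires."""


@dataclass(frozen=True)
class QCThresholds:
    """Feature-level quality-control thresholds.

    A feature is kept only if its detection reproducibility across the
    reference-mixture injections, sample:blank ratio, reference RSD and
    maximal area all pass. ``min_peak_intensity`` and ``sn_min`` are
    upstream peak-detection settings, applied only when the table carries
    the corresponding columns.
    """

    reproducibility_min: float = 0.90
    sample_blank_ratio_min: float = 10.0
    rsd_max: float = 0.50
    min_area: float = 1e5
    min_peak_intensity: float = 2e6
    sn_min: float = 5.0

    def __post_init__(self):
        vals = (self.reproducibility_min, self.sample_blank_ratio_min,
                self.rsd_max, self.min_area, self.min_peak_intensity, self.sn_min)
        if any(v <= 0 for v in vals):
            raise ValueError("all QC thresholds must be strictly positive")
        if self.reproducibility_min > 1:
            raise ValueError("reproducibility_min is a fraction <= 1")


@dataclass(frozen=True)
class RedundancyRules:
    """Rules for collapsing redundant ion species of one molecule."""

    rt_coelution_tol: float = 0.05          # min; same-mode co-elution window
    isotope_spacing: float = 1.003355       # Da (13C - 12C)
    adduct_offsets_pos: dict = field(default_factory=lambda: {
        "Na": 21.981944, "K": 37.955882, "NH4": 17.026549})
    adduct_offsets_neg: dict = field(default_factory=lambda: {"Cl": 35.976678})
    dimer_enabled: bool = True
    mz_tol_ppm: float = 5.0
    proton_mass: float = PROTON_MASS

    def __post_init__(self):
        if self.rt_coelution_tol <= 0:
            raise ValueError("rt_coelution_tol must be positive")
        for d in (self.adduct_offsets_pos, self.adduct_offsets_neg):
            if any(v <= 0 for v in d.values()):
                raise ValueError("adduct offsets must be positive")


@dataclass(frozen=True)
class MergeParams:
    """Tolerances for merging [M+H]+ and [M-H]- features of one metabolite."""

    mz_tol_ppm: float = 5.0
    rt_tol: float = 0.5
    proton_mass: float = PROTON_MASS

    def __post_init__(self):
        if self.mz_tol_ppm <= 0 or self.rt_tol <= 0:
            raise ValueError("merge tolerances must be positive")


def _rsd(values: Sequence[float]) -> float:
    if len(values) < 2:
        return 0.0
    m = mean(values)
    if m == 0:
        return 0.0
    sd = math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))
    return sd / m


def qc_filter(features: Sequence[FeatureRecord],
              thresholds: QCThresholds = QCThresholds(),
              ) -> tuple[list[FeatureRecord], dict[str, list[str]]]:
    """Apply QC criteria; return kept features and per-feature failure reasons.

    A feature is kept iff ALL of: detection fraction across reference
    injections >= reproducibility_min; mean sample / mean blank area >=
    sample_blank_ratio_min (a blank mean of zero passes); RSD of nonzero
    reference areas <= rsd_max; maximal area >= min_area. The report maps
    each removed feature id to every criterion it failed.
    """
    kept: list[FeatureRecord] = []
    report: dict[str, list[str]] = {}
    for f in features:
        ref = f.class_areas("reference")
        if not ref:
            raise ConfigurationError(
                f"feature {f.id!r} has no reference-class injections")
        reasons = []
        detected = sum(1 for a in ref if a > 0)
        if detected / len(ref) < thresholds.reproducibility_min:
            reasons.append("reproducibility")
        sample = f.class_areas("sample")
        blank = f.class_areas("blank")
        blank_mean = mean(blank) if blank else 0.0
        if blank_mean > 0:
            sample_mean = mean(sample) if sample else 0.0
            if sample_mean / blank_mean < thresholds.sample_blank_ratio_min:
                reasons.append("sample_blank_ratio")
        nonzero_ref = [a for a in ref if a > 0]
        if nonzero_ref and _rsd(nonzero_ref) > thresholds.rsd_max:
            reasons.append("rsd")
        if f.max_area() < thresholds.min_area:
            reasons.append("min_area")
        if reasons:
            report[f.id] = reasons
        else:
            kept.append(f)
    return kept, report


def _ppm(a: float, b: float) -> float:
    return abs(a - b) / b * 1e6


@dataclass(frozen=True)
class RemovedFeature:
    """A redundant feature, the kind of species it is, and its parent id."""

    feature: FeatureRecord
    kind: str      # isotope | adduct | in_source_fragment | dimer
    parent_id: str
    ppm_error: float


def remove_redundancy(features: Sequence[FeatureRecord],
                      rules: RedundancyRules = RedundancyRules(),
                      ) -> tuple[list[FeatureRecord], list[RemovedFeature]]:
    """Collapse isotopes, adducts, in-source fragments and dimers.

    Within each co-eluting group (|dRT| <= rt_coelution_tol of a candidate
    parent) a feature is removed when its m/z is arithmetically explained by
    a larger-area parent. Multi-parent ambiguity is resolved by smallest
    ppm error; the retained representative is the protonated/deprotonated
    monoisotopic member with the largest area.
    """
    if len({f.ion_mode for f in features}) > 1:
        raise ValueError("remove_redundancy expects features of a single ion mode")
    order = sorted(range(len(features)), key=lambda i: -features[i].max_area())
    removed: dict[int, RemovedFeature] = {}

    offsets = (rules.adduct_offsets_pos if features and features[0].ion_mode == POSITIVE
               else rules.adduct_offsets_neg)
    sign = 1.0 if (features and features[0].ion_mode == POSITIVE) else -1.0

    def explain(child: FeatureRecord, parent: FeatureRecord) -> Optional[tuple[str, float]]:
        """Best (kind, ppm error) by which parent explains child, or None."""
        best: Optional[tuple[str, float]] = None

        def consider(kind: str, expected_mz: float, need_smaller_area: bool = False):
            nonlocal best
            if need_smaller_area and child.max_area() > parent.max_area():
                return
            err = _ppm(child.mz, expected_mz)
            if err <= rules.mz_tol_ppm and (best is None or err < best[1]):
                best = (kind, err)

        for k in (1, 2):
            consider("isotope", parent.mz + k * rules.isotope_spacing,
                     need_smaller_area=True)
        for off in offsets.values():
            consider("adduct", parent.mz + off)
        if rules.dimer_enabled:
            neutral = parent.mz - sign * rules.proton_mass
            consider("dimer", 2 * neutral + sign * rules.proton_mass)
        if parent.ms2 is not None and child.max_area() <= parent.max_area():
            for p in parent.ms2.peaks:
                err = _ppm(child.mz, p.mz)
                if err <= rules.mz_tol_ppm and (best is None or err < best[1]):
                    best = ("in_source_fragment", err)
        return best

    for i in order:              # parents in descending area
        if i in removed:
            continue
        parent = features[i]
        for j in range(len(features)):
            if j == i:
                continue
            child = features[j]
            if abs(child.rt - parent.rt) > rules.rt_coelution_tol:
                continue
            hit = explain(child, parent)
            if hit is None:
                continue
            kind, err = hit
            prev = removed.get(j)
            if prev is None or err < prev.ppm_error:
                removed[j] = RemovedFeature(child, kind, parent.id, err)

    kept = [f for idx, f in enumerate(features) if idx not in removed]
    return kept, [removed[j] for j in sorted(removed)]


def merge_modes(pos: Sequence[FeatureRecord], neg: Sequence[FeatureRecord],
                params: MergeParams = MergeParams()) -> list[MS2TEntry]:
    """Merge [M+H]+ / [M-H]- features of the same metabolite into MS2T entries.

    A pair merges when its neutral masses agree within ppm tolerance and
    retention times within rt_tol; each feature merges at most once (greedy
    by ascending ppm error, ties by ascending |dRT|). The merged entry is
    quantified in the mode with the larger maximal area; its partner id is
    recorded.
    """
    for f in pos:
        if f.ion_mode != POSITIVE:
            raise ValueError(f"{f.id!r} in positive list is not positive mode")
    for f in neg:
        if f.ion_mode != NEGATIVE:
            raise ValueError(f"{f.id!r} in negative list is not negative mode")

    pos_nm = [neutral_mass(f.mz, POSITIVE, params.proton_mass) for f in pos]
    neg_nm = [neutral_mass(f.mz, NEGATIVE, params.proton_mass) for f in neg]
    candidates = []
    for i, (fp, mp) in enumerate(zip(pos, pos_nm)):
        for j, (fn, mn) in enumerate(zip(neg, neg_nm)):
            drt = abs(fp.rt - fn.rt)
            if drt > params.rt_tol:
                continue
            ppm = abs(mp - mn) / ((mp + mn) / 2) * 1e6
            if ppm <= params.mz_tol_ppm:
                candidates.append((ppm, drt, i, j))
    candidates.sort()
    used_pos: set[int] = set()
    used_neg: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for ppm, drt, i, j in candidates:
        if i in used_pos or j in used_neg:
            continue
        used_pos.add(i)
        used_neg.add(j)
        pairs.append((i, j))

    entries: list[MS2TEntry] = []
    for i, j in sorted(pairs):
        fp, fn = pos[i], neg[j]
        primary, partner = (fp, fn) if fp.max_area() >= fn.max_area() else (fn, fp)
        nm = (pos_nm[i] + neg_nm[j]) / 2
        entries.append(MS2TEntry(feature=primary, neutral_mass=nm,
                                 partner_id=partner.id))
    for i, f in enumerate(pos):
        if i not in used_pos:
            entries.append(MS2TEntry(feature=f, neutral_mass=pos_nm[i]))
    for j, f in enumerate(neg):
        if j not in used_neg:
            entries.append(MS2TEntry(feature=f, neutral_mass=neg_nm[j]))
    return entries
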