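"""Synthetic data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: MS2 spectra from a
forward fragmentation model (the inverse of substructure scanning), aligned
feature tables with planted QC failures and redundant ion species, abundance
profiles drawn from a known sparse Gaussian graphical model, and labelled
spectral corpora with planted motif/loss frequencies. Each generator is
driven by a single seeded random generator and returns the planted truth
alongside the data, so tests can assert exact recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, MotifEntry, NeutralLossEntry
from .spectra import (NEGATIVE, POSITIVE, FeatureRecord, Peak, Spectrum)

#: Geometric decay of ladder-ion intensities per lost modification.
LADDER_DECAY = 0.6
BASE_INTENSITY = 1e6


@dataclass(frozen=True)
class FixturePlan:
    """Counts and noise levels shared by the generators."""

    seed: int = 0
    n_features: int = 50
    n_spectra: int = 50
    n_samples: int = 59
    mz_jitter_ppm: float = 0.0
    intensity_jitter: float = 0.0
    drift_slope: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _jitter_mz(mz: float, ppm: float, rng: np.random.Generator) -> float:
    if ppm <= 0:
        return mz
    return mz * (1 + rng.uniform(-ppm, ppm) * 1e-6)


def _subsets(items: Sequence) -> list[tuple]:
    """All sub-multisets of a small multiset (by index masks)."""
    out = []
    n = len(items)
    for mask in range(1 << n):
        out.append(tuple(items[i] for i in range(n) if mask >> i & 1))
    # dedupe equal-name multisets
    seen = set()
    unique = []
    for combo in out:
        key = tuple(sorted(e.name for e in combo))
        if key not in seen:
            seen.add(key)
            unique.append(combo)
    return unique


def simulate_spectrum(skeleton: MotifEntry,
                      mods: Sequence[NeutralLossEntry],
                      plan: FixturePlan = FixturePlan(),
                      rng: Optional[np.random.Generator] = None,
                      spectrum_id: str = "synthetic") -> Spectrum:
    """Forward fragmentation model: skeleton + modifications -> spectrum.

    The precursor is the skeleton ion plus the summed modification masses;
    one ladder ion appears for every sub-multiset of modifications lost
    (including the bare skeleton ion), with intensities decaying
    geometrically in the number of losses. m/z values are perturbed by up to
    the planned ppm jitter.
    """
    rng = rng if rng is not None else plan.rng()
    precursor = skeleton.ion_mz + sum(e.mass for e in mods)
    peaks = []
    for lost in _subsets(list(mods)):
        mz = precursor - sum(e.mass for e in lost)
        inten = BASE_INTENSITY * LADDER_DECAY ** len(lost)
        if plan.intensity_jitter > 0:
            inten *= 1 + rng.uniform(-plan.intensity_jitter, plan.intensity_jitter)
        peaks.append(Peak(_jitter_mz(mz, plan.mz_jitter_ppm, rng), inten))
    return Spectrum(id=spectrum_id, ion_mode=skeleton.ion_mode, peaks=tuple(peaks),
                    precursor_mz=precursor,
                    metadata={"COMPOSITION": " + ".join(
                        [skeleton.name] + sorted(e.name for e in mods))})


# ---------------------------------------------------------------------------
# Feature tables with planted QC failures and redundancy


def _areas(rng, n_ref=8, n_sample=4, n_blank=2, level=1e6, rsd=0.08,
           blank_level=0.0, ref_dropout=0):
    labels, classes, areas = [], {}, {}
    for i in range(n_ref):
        lab = f"ref{i+1}"
        labels.append(lab)
        classes[lab] = "reference"
        if i < ref_dropout:
            areas[lab] = 0.0
        else:
            areas[lab] = max(0.0, level * (1 + rng.normal(0, rsd)))
    for i in range(n_sample):
        lab = f"s{i+1}"
        classes[lab] = "sample"
        areas[lab] = max(0.0, level * (1 + rng.normal(0, rsd)))
    for i in range(n_blank):
        lab = f"b{i+1}"
        classes[lab] = "blank"
        areas[lab] = blank_level
    return areas, classes


def simulate_feature_table(plan: FixturePlan = FixturePlan(),
                           n_qc_failures: int = 8,
                           n_children_per_kind: int = 1,
                           n_mode_twins: int = 3,
                           ) -> tuple[list[FeatureRecord], list[FeatureRecord], dict]:
    """Positive- and negative-mode features with planted defects.

    Returns (positive features, negative features, truth) where truth maps
    planted QC failures to their expected reasons, redundant children to
    (kind, parent id), and lists the cross-mode twin pairs.
    """
    rng = plan.rng()
    truth = {"qc_fail": {}, "redundant": {}, "merge_pairs": []}
    pos: list[FeatureRecord] = []
    neg: list[FeatureRecord] = []
    counter = [0]

    def fid(mode):
        counter[0] += 1
        return f"RSM{counter[0]:05d}{'p' if mode == POSITIVE else 'n'}"

    # pre-allocate well-separated retention times (>=0.25 min apart) so each
    # planted redundancy group co-elutes only with itself
    n_slots = plan.n_features * 2 + 16
    rt_grid = 1.0 + 0.25 * rng.permutation(n_slots) + rng.uniform(0, 0.04, n_slots)
    rt_iter = iter(rt_grid.tolist())

    def fresh_rt():
        return float(next(rt_iter))

    n_clean = max(plan.n_features - n_qc_failures, 4)
    for _ in range(n_clean):
        mz = float(rng.uniform(200, 800))
        rt = fresh_rt()
        areas, classes = _areas(rng, level=10 ** rng.uniform(5.5, 7.5))
        ms2 = Spectrum(id="frag", ion_mode=POSITIVE, precursor_mz=mz,
                       peaks=((Peak(mz - 120.0, 5e5), Peak(mz - 162.052823, 8e5))))
        pos.append(FeatureRecord(id=fid(POSITIVE), ion_mode=POSITIVE, mz=mz, rt=rt,
                                 areas=areas, classes=classes, ms2=ms2))

    fail_kinds = ["reproducibility", "sample_blank_ratio", "rsd", "min_area"]
    for i in range(n_qc_failures):
        kind = fail_kinds[i % len(fail_kinds)]
        mz = float(rng.uniform(200, 800))
        rt = fresh_rt()
        if kind == "reproducibility":
            areas, classes = _areas(rng, ref_dropout=2)          # 6/8 detected
        elif kind == "sample_blank_ratio":
            areas, classes = _areas(rng, level=1e6, blank_level=5e5)
        elif kind == "rsd":
            areas, classes = _areas(rng, rsd=0.9)
            # force a large spread deterministically
            areas = dict(areas)
            areas["ref1"], areas["ref2"] = 3e6, 1e5
        else:
            areas, classes = _areas(rng, level=4e4)
        f = FeatureRecord(id=fid(POSITIVE), ion_mode=POSITIVE, mz=mz, rt=rt,
                          areas=areas, classes=classes)
        pos.append(f)
        truth["qc_fail"][f.id] = kind

    # redundant children around the first clean parents
    parents = pos[:4]
    child_defs = [
        ("isotope", lambda p: p.mz + 1.003355, 0.2),
        ("adduct", lambda p: p.mz + 21.981944, 0.5),        # Na
        ("adduct", lambda p: p.mz + 37.955882, 0.3),        # K
        ("dimer", lambda p: 2 * (p.mz - PROTON_MASS) + PROTON_MASS, 0.4),
        ("in_source_fragment", lambda p: p.ms2.peaks[1].mz, 0.3),
    ]
    for k in range(n_children_per_kind):
        parent = parents[k % len(parents)]
        for kind, mz_of, scale in child_defs:
            # keep children above the QC area floor but below the parent
            level = min(max(parent.max_area() * scale * 0.5, 2e5),
                        parent.max_area() * 0.6)
            areas, classes = _areas(rng, level=level)
            child = FeatureRecord(id=fid(POSITIVE), ion_mode=POSITIVE,
                                  mz=float(mz_of(parent)),
                                  rt=parent.rt + float(rng.uniform(-0.02, 0.02)),
                                  areas=areas, classes=classes)
            pos.append(child)
            truth["redundant"][child.id] = (kind, parent.id)

    # negative-mode twins of clean parents (same neutral mass and RT)
    for parent in pos[4:4 + n_mode_twins]:
        neutral = parent.mz - PROTON_MASS
        areas, classes = _areas(rng, level=parent.max_area() * 0.6)
        twin = FeatureRecord(id=fid(NEGATIVE), ion_mode=NEGATIVE,
                             mz=neutral - PROTON_MASS,
                             rt=parent.rt + float(rng.uniform(-0.1, 0.1)),
                             areas=areas, classes=classes)
        neg.append(twin)
        truth["merge_pairs"].append((parent.id, twin.id))

    # stand-alone negative features far from any positive neutral mass
    for _ in range(max(plan.n_features // 5, 2)):
        areas, classes = _areas(rng, level=10 ** rng.uniform(5.5, 7))
        neg.append(FeatureRecord(id=fid(NEGATIVE), ion_mode=NEGATIVE,
                                 mz=float(rng.uniform(820, 1000)), rt=fresh_rt(),
                                 areas=areas, classes=classes))
    return pos, neg, truth


# ---------------------------------------------------------------------------
# Gaussian graphical model profiles


def random_sparse_precision(p: int, n_edges: int, rng: np.random.Generator,
                            pcor_range: tuple[float, float] = (0.30, 0.45),
                            ) -> tuple[np.ndarray, np.ndarray]:
    """A sparse precision matrix with planted partial correlations.

    Off-diagonal entries are set on ``n_edges`` random pairs with partial
    correlation magnitudes drawn from ``pcor_range`` (random sign). Node
    degree is capped at 2 so the matrix stays strictly diagonally dominant
    (hence positive definite) without rescaling, and the planted partial
    correlations keep their drawn magnitudes exactly. Returns
    (precision, true partial-correlation matrix).
    """
    if pcor_range[1] * 2 >= 1.0:
        raise ValueError("pcor magnitudes must satisfy 2*max < 1 for the degree cap")
    if n_edges > p:  # degree-2 cap admits at most p edges
        raise ValueError("too many edges for the degree cap")
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    order = rng.permutation(len(pairs))
    omega = np.eye(p)
    degree = np.zeros(p, dtype=int)
    planted = 0
    for k in order:
        if planted == n_edges:
            break
        i, j = pairs[k]
        if degree[i] >= 2 or degree[j] >= 2:
            continue
        rho = rng.uniform(*pcor_range) * rng.choice([-1.0, 1.0])
        omega[i, j] = omega[j, i] = -rho
        degree[i] += 1
        degree[j] += 1
        planted += 1
    if planted < n_edges:
        raise ValueError("could not place all edges under the degree cap")
    d = np.sqrt(np.diag(omega))
    true_pcor = -omega / np.outer(d, d)
    np.fill_diagonal(true_pcor, 1.0)
    return omega, true_pcor


def simulate_profiles(precision: np.ndarray, n: int,
                      seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw n samples from the zero-mean MVN with the given precision.

    Returns (samples x features DataFrame, true partial-correlation matrix).
    Raises if the precision matrix is not positive definite.
    """
    precision = np.asarray(precision, dtype=float)
    try:
        np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix must be positive definite") from exc
    cov = np.linalg.inv(precision)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(len(precision)), cov, size=n,
                                method="cholesky")
    d = np.sqrt(np.diag(precision))
    true_pcor = -precision / np.outer(d, d)
    np.fill_diagonal(true_pcor, 1.0)
    cols = [f"F{i:03d}" for i in range(len(precision))]
    return pd.DataFrame(X, columns=cols), true_pcor


# ---------------------------------------------------------------------------
# Labelled corpora


def simulate_corpus(motif_freqs: dict[float, float],
                    loss_freqs: dict[float, float],
                    n_spectra: int, seed: int = 0,
                    compound_class: str = "flavone",
                    n_noise_peaks: int = 5) -> list[Spectrum]:
    """Class-labelled spectra with planted motif/loss frequencies.

    Each planted motif m/z appears in a spectrum with its planned
    probability; each planted loss appears as a fragment pair (x, x + loss).
    Noise peaks are drawn far from planted masses.
    """
    if n_spectra <= 0:
        raise ValueError("n_spectra must be positive")
    rng = np.random.default_rng(seed)
    corpus = []
    for i in range(n_spectra):
        peaks = []
        for mz, freq in motif_freqs.items():
            if rng.random() < freq:
                peaks.append(Peak(mz, float(rng.uniform(5e5, 1e6))))
        for loss, freq in loss_freqs.items():
            if rng.random() < freq:
                base = float(rng.uniform(150, 400))
                inten = float(rng.uniform(2e5, 8e5))
                peaks.append(Peak(base, inten))
                peaks.append(Peak(base + loss, inten * 0.8))
        for _ in range(n_noise_peaks):
            peaks.append(Peak(float(rng.uniform(1000, 1500)),
                              float(rng.uniform(1e4, 1e5))))
        if not peaks:
            peaks.append(Peak(float(rng.uniform(1000, 1500)), 1e4))
        corpus.append(Spectrum(id=f"corpus_{i}", ion_mode=POSITIVE,
                               peaks=tuple(peaks),
                               metadata={"COMPOUND_CLASS": compound_class}))
    return corpus


def simulate_replicate_library(n_compounds: int = 40,
                               recoverable_fraction: float = 0.8,
                               seed: int = 0,
                               ) -> tuple[list[tuple[Spectrum, str]], list[Spectrum], float]:
    """A reference library plus noisy replicate queries with known answer rate.

    Every compound has one library spectrum and one query replicate with
    mild intensity jitter. A planted fraction of queries is recoverable;
    the rest have their precursor shifted far outside any search window, so
    the top-k identification rate equals the planted fraction at every k.
    Returns (queries, library, planted recoverable fraction).
    """
    rng = np.random.default_rng(seed)
    library: list[Spectrum] = []
    queries: list[tuple[Spectrum, str]] = []
    n_recover = int(round(n_compounds * recoverable_fraction))
    precursors = np.linspace(200, 900, n_compounds) + rng.uniform(0, 0.3, n_compounds)
    for i in range(n_compounds):
        name = f"compound_{i:03d}"
        prec = float(precursors[i])
        frag_mz = np.sort(rng.uniform(50, prec - 10, size=6))
        frag_int = rng.uniform(1e4, 1e6, size=6)
        lib = Spectrum(id=f"LIB{i:03d}", ion_mode=POSITIVE,
                       peaks=tuple(zip(frag_mz, frag_int)), precursor_mz=prec,
                       metadata={"NAME": name})
        library.append(lib)
        jitter = 1 + rng.uniform(-0.1, 0.1, size=6)
        q_prec = prec if i < n_recover else prec * (1 + 200e-6)
        q = Spectrum(id=f"Q{i:03d}", ion_mode=POSITIVE,
                     peaks=tuple(zip(frag_mz, frag_int * jitter)),
                     precursor_mz=q_prec, metadata={"NAME": name})
        queries.append((q, name))
    return queries, library, n_recover / n_compounds


def write_truth(truth: dict, path) -> None:
    """Write a generator's ground truth as JSON."""
    Path(path).write_text(json.dumps(truth, indent=2, default=str))
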