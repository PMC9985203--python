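"""Spectral-library dereplication scoring.

Two spectra are compared by pairing fragment peaks one-to-one inside a ppm
window and scoring the pairing four ways:

* **cosine** — normalized dot product of matched intensities over the full
  peak vectors; with the precursor-shift clause enabled this is the
  modified-cosine score used for GNPS-style libraries.
* **mz_score** — a matched-peak-count score. The default ``dice`` mode is
  the Sørensen–Dice coefficient ``2·n_matched / (n_q + n_d)`` over the two
  peak counts; the alternative ``printed`` mode,
  ``n_matched / (n_q + n_matched)``, keeps the literal legend of the
  original formulation (whose denominator mixes total query peaks with
  matched database peaks and therefore tops out at 0.5).
* **int_score** — mean intensity agreement of matched pairs,
  ``1 − mean(|ΔI|)/100`` on the base-peak-100 scale.
* **matching_ratio** — matched pairs over total query peaks.

A candidate survives per-source similarity gating (0.85 for GNPS, 0.70 for
HMDB/MassBank by default) and is additionally flagged by the conjunctive
post-filter requiring mz_score, int_score and matching_ratio all ≥ 0.50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ms2derep.preprocess import is_normalized, normalize_and_filter, select_by_precursor
from ms2derep.spectra_io import LibraryEntry, MassSpectrum

logger = logging.getLogger(__name__)

DEFAULT_FRAGMENT_PPM = 15.0
DEFAULT_POSTFILTER = 0.50

#: Per-source cosine gates: GNPS scores with the precursor-shift clause and a
#: stricter threshold; HMDB and MassBank use the plain cosine.
DEFAULT_SIMILARITY_THRESHOLDS = {"GNPS": 0.85, "HMDB": 0.70, "MassBank": 0.70}
SHIFT_AWARE_SOURCES = frozenset({"GNPS"})


@dataclass(frozen=True)
class MatchedPair:
    query_index: int
    library_index: int
    query_mz: float
    library_mz: float
    query_intensity: float
    library_intensity: float
    shifted: bool


@dataclass
class PeakMatching:
    """A 1:1 pairing between the peaks of a query and a library spectrum.

    Carries the full intensity vectors of both spectra so every downstream
    score can be computed from the matching alone.
    """

    pairs: list[MatchedPair]
    query_intensities: np.ndarray
    library_intensities: np.ndarray
    ppm_tol: float

    def __post_init__(self) -> None:
        q_idx = [p.query_index for p in self.pairs]
        d_idx = [p.library_index for p in self.pairs]
        if len(set(q_idx)) != len(q_idx) or len(set(d_idx)) != len(d_idx):
            raise ValueError("matching is not 1:1 — an index appears twice")

    @property
    def n_q(self) -> int:
        return int(self.query_intensities.size)

    @property
    def n_d_total(self) -> int:
        return int(self.library_intensities.size)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class SpectralMatch:
    """One query-vs-library comparison with all scores and gate flags."""

    query_feature_id: str
    library_accession: str
    library_source: str
    similarity: float
    mz_score: float
    int_score: float
    matching_ratio: float
    n_matched: int
    passed_similarity_threshold: bool
    passed_postfilter: bool
    candidate_name: str = ""
    candidate_smiles: str | None = None
    query_scan_id: str = ""


def _candidate_pairs(
    query: MassSpectrum,
    library: MassSpectrum,
    ppm_tol: float,
    allow_precursor_shift: bool,
) -> list[tuple[float, float, int, int, bool]]:
    """All admissible (i, j) pairs as (-product, residual, i, j, shifted)."""
    out = []
    shift = query.precursor_mz - library.precursor_mz
    for i, (qmz, qint) in enumerate(zip(query.mz, query.intensities)):
        tol = ppm_tol * qmz * 1e-6  # window relative to the query fragment
        for j, (dmz, dint) in enumerate(zip(library.mz, library.intensities)):
            direct = abs(qmz - dmz)
            if direct <= tol:
                out.append((-(qint * dint), direct, i, j, False))
                continue
            if allow_precursor_shift:
                shifted = abs((qmz - dmz) - shift)
                if shifted <= tol:
                    out.append((-(qint * dint), shifted, i, j, True))
    return out


def match_peaks(
    query: MassSpectrum,
    library: MassSpectrum,
    ppm_tol: float = DEFAULT_FRAGMENT_PPM,
    allow_precursor_shift: bool = False,
) -> PeakMatching:
    """Pair query and library peaks 1:1 within a ppm tolerance.

    A pair (i, j) is admissible when ``|mz_q − mz_d|`` is within tolerance,
    or — with ``allow_precursor_shift`` — when the difference adjusted by
    the precursor mass offset ``prec_q − prec_d`` is. The tolerance is ppm
    relative to the query fragment m/z. Admissible pairs are consumed
    greedily in descending order of intensity product (ties: smaller m/z
    residual, then lower query index, then lower library index); each peak
    is used at most once.

    Both spectra must be normalized to base peak 100 beforehand.
    """
    for name, spec in (("query", query), ("library", library)):
        if not is_normalized(spec):
            raise ValueError(
                f"{name} spectrum {spec.spectrum_id!r} is not normalized to base peak 100"
            )
    candidates = _candidate_pairs(query, library, ppm_tol, allow_precursor_shift)
    candidates.sort()
    used_q: set[int] = set()
    used_d: set[int] = set()
    pairs: list[MatchedPair] = []
    for neg_product, _residual, i, j, shifted in candidates:
        if i in used_q or j in used_d:
            continue
        used_q.add(i)
        used_d.add(j)
        pairs.append(
            MatchedPair(
                query_index=i,
                library_index=j,
                query_mz=float(query.mz[i]),
                library_mz=float(library.mz[j]),
                query_intensity=float(query.intensities[i]),
                library_intensity=float(library.intensities[j]),
                shifted=shifted,
            )
        )
    return PeakMatching(
        pairs=pairs,
        query_intensities=query.intensities.copy(),
        library_intensities=library.intensities.copy(),
        ppm_tol=ppm_tol,
    )


def cosine_score(matching: PeakMatching) -> float:
    """Cosine similarity over the matched pairs, normalized by full vectors.

    ``Σ I_q·I_d`` over pairs divided by the product of the Euclidean norms
    of *all* query and *all* library intensities, so unmatched peaks dilute
    the score. Bounded in [0, 1]; 0 when no pair matched.
    """
    q_norm = float(np.linalg.norm(matching.query_intensities))
    d_norm = float(np.linalg.norm(matching.library_intensities))
    if q_norm == 0.0 or d_norm == 0.0:
        raise ValueError("cannot compute cosine against a zero-norm spectrum")
    num = sum(p.query_intensity * p.library_intensity for p in matching.pairs)
    return float(num / (q_norm * d_norm))


def mz_score(matching: PeakMatching, mode: str = "dice") -> float:
    """Matched-peak-count score (see module docstring for the two modes)."""
    if matching.n_q == 0:
        raise ValueError("mz_score undefined for an empty query spectrum")
    m = matching.n_matched
    if mode == "dice":
        return 2.0 * m / (matching.n_q + matching.n_d_total)
    if mode == "printed":
        return m / (matching.n_q + m) if m else 0.0
    raise ValueError(f"unknown mz_score mode {mode!r} (dice or printed)")


def int_score(matching: PeakMatching) -> float:
    """Mean intensity agreement over matched pairs on the 0–100 scale.

    ``(1/n) Σ (1 − |I_q − I_d|/100)``. With zero matched pairs the score is
    undefined; 0.0 is returned so a batch run records the failure instead
    of aborting (such a match always fails the post-filter anyway).
    """
    if matching.n_matched == 0:
        return 0.0
    diffs = [abs(p.query_intensity - p.library_intensity) for p in matching.pairs]
    return float(np.mean([1.0 - d / 100.0 for d in diffs]))


def matching_ratio(matching: PeakMatching) -> float:
    """Matched pairs over total query peaks."""
    if matching.n_q == 0:
        raise ValueError("matching_ratio undefined for an empty query spectrum")
    return matching.n_matched / matching.n_q


@dataclass
class MatchConfig:
    """Thresholds and tolerances for :func:`dereplicate_feature`."""

    fragment_ppm: float = DEFAULT_FRAGMENT_PPM
    precursor_ppm: float = DEFAULT_FRAGMENT_PPM
    similarity_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_SIMILARITY_THRESHOLDS)
    )
    postfilter: float = DEFAULT_POSTFILTER
    mz_score_mode: str = "dice"
    min_rel_intensity: float = 0.05


def score_pair(
    query: MassSpectrum,
    entry: LibraryEntry,
    config: MatchConfig,
    feature_id: str = "",
) -> SpectralMatch:
    """Score one normalized query spectrum against one library entry."""
    shift_aware = entry.library_source in SHIFT_AWARE_SOURCES
    lib_spec = normalize_and_filter(entry.spectrum, config.min_rel_intensity)
    matching = match_peaks(
        query, lib_spec, ppm_tol=config.fragment_ppm, allow_precursor_shift=shift_aware
    )
    similarity = cosine_score(matching)
    mz_s = mz_score(matching, config.mz_score_mode)
    int_s = int_score(matching)
    ratio = matching_ratio(matching)
    threshold = config.similarity_thresholds[entry.library_source]
    return SpectralMatch(
        query_feature_id=feature_id,
        library_accession=entry.accession,
        library_source=entry.library_source,
        similarity=similarity,
        mz_score=mz_s,
        int_score=int_s,
        matching_ratio=ratio,
        n_matched=matching.n_matched,
        passed_similarity_threshold=similarity >= threshold,
        passed_postfilter=(
            mz_s >= config.postfilter
            and int_s >= config.postfilter
            and ratio >= config.postfilter
        ),
        candidate_name=entry.compound_name,
        candidate_smiles=entry.smiles,
        query_scan_id=query.spectrum_id,
    )


def dereplicate_feature(
    feature,
    libraries: dict[str, list[LibraryEntry]],
    config: MatchConfig | None = None,
) -> list[SpectralMatch]:
    """Search a feature against all libraries and return gated matches.

    For each library entry inside the feature's precursor window the cosine
    is computed (shift-aware for GNPS-tagged libraries, direct otherwise);
    entries at or above the per-source similarity threshold are returned
    with their mz/int/ratio scores and the post-filter flag. When a feature
    owns several MS2 scans each scan is scored and the best-scoring scan
    per library entry is reported. Results are sorted by similarity
    descending, ties broken by matched-peak count then accession.
    """
    config = config or MatchConfig()
    unknown = set(libraries) - set(config.similarity_thresholds)
    if unknown:
        raise ValueError(
            f"unknown library source tags {sorted(unknown)}; "
            f"valid tags: {sorted(config.similarity_thresholds)}"
        )
    queries = [
        normalize_and_filter(s, config.min_rel_intensity) for s in feature.spectra
    ]
    matches: list[SpectralMatch] = []
    for source, entries in libraries.items():
        in_window = select_by_precursor(entries, feature.precursor_mz, config.precursor_ppm)
        for entry in in_window:
            best: SpectralMatch | None = None
            for query in queries:
                m = score_pair(query, entry, config, feature_id=feature.feature_id)
                if best is None or (m.similarity, m.n_matched) > (
                    best.similarity,
                    best.n_matched,
                ):
                    best = m
            if best is not None and best.passed_similarity_threshold:
                matches.append(best)
    matches.sort(key=lambda m: (-m.similarity, -m.n_matched, m.library_accession))
    return matches
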