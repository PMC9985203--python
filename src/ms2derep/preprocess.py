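"""Feature enumeration and MS2 spectrum conditioning.

A *feature* is the set of MS2 scans sharing a precursor m/z (within a ppm
window) in one file. Each feature gets a human-readable id of the form
``<file>M<int mz>R<int rt>ID<index>``, e.g. a precursor at 287.065 with a
median retention time of 318.265 s becomes ``file_1M287R318ID319``.

Before any library comparison each spectrum is rescaled so its base peak is
100 and peaks below a relative-intensity floor (default 5% of base) are
dropped — applied identically to query and library spectra so the two sides
stay comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ms2derep.spectra_io import LibraryEntry, MassSpectrum

logger = logging.getLogger(__name__)

DEFAULT_PRECURSOR_PPM = 15.0
DEFAULT_MIN_REL_INTENSITY = 0.05


def ppm_diff(mz_a: float, mz_b: float, reference: float | None = None) -> float:
    """Relative difference of two m/z values in parts-per-million.

    The reference defaults to ``mz_a`` (by convention the query value).
    """
    ref = mz_a if reference is None else reference
    return abs(mz_a - mz_b) / ref * 1e6


def _median_low(values: list[float]) -> float:
    """Median with the lower middle value on even counts (deterministic)."""
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


@dataclass
class Feature:
    """All MS2 scans of one precursor in one file."""

    feature_id: str
    file_id: str
    precursor_mz: float
    median_rt: float
    spectra: list[MassSpectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("a feature must own at least one spectrum")


def make_feature_id(file_id: str, precursor_mz: float, median_rt: float, index: int) -> str:
    """Compose the feature id; m/z and RT integers are truncated, not rounded."""
    return f"{file_id}M{int(precursor_mz)}R{int(median_rt)}ID{index}"


def enumerate_features(
    spectra: list[MassSpectrum],
    file_id: str,
    ppm_tol: float = DEFAULT_PRECURSOR_PPM,
    start_index: int = 1,
) -> list[Feature]:
    """Group MS2 spectra into features by precursor m/z proximity.

    Spectra are sorted by precursor m/z and clustered greedily: a spectrum
    joins the open group while it lies within ``ppm_tol`` of the group's
    running mean precursor. Every input spectrum lands in exactly one
    feature. ``start_index`` sets the first ID number (ids are sequential in
    ascending precursor order).
    """
    if not spectra:
        return []
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.retention_time, s.spectrum_id))
    groups: list[list[MassSpectrum]] = [[ordered[0]]]
    for spec in ordered[1:]:
        group = groups[-1]
        mean_mz = float(np.mean([g.precursor_mz for g in group]))
        if ppm_diff(mean_mz, spec.precursor_mz) <= ppm_tol:
            group.append(spec)
        else:
            groups.append([spec])

    features = []
    for offset, group in enumerate(groups):
        pmz = _median_low([g.precursor_mz for g in group])
        rt = _median_low([g.retention_time for g in group])
        features.append(
            Feature(
                feature_id=make_feature_id(file_id, pmz, rt, start_index + offset),
                file_id=file_id,
                precursor_mz=pmz,
                median_rt=rt,
                spectra=group,
            )
        )
    return features


def normalize_and_filter(
    spectrum: MassSpectrum, min_rel_intensity: float = DEFAULT_MIN_REL_INTENSITY
) -> MassSpectrum:
    """Rescale intensities to base peak 100 and drop low-intensity peaks.

    Peaks strictly below ``100 * min_rel_intensity`` after rescaling are
    removed (the base peak itself always survives). The input spectrum is
    left unmodified; the operation is idempotent.
    """
    base = float(np.max(spectrum.intensities)) if spectrum.n_peaks else 0.0
    if base <= 0:
        raise ValueError(
            f"spectrum {spectrum.spectrum_id!r} has no positive intensity; cannot normalize"
        )
    scaled = spectrum.intensities * (100.0 / base)
    keep = scaled >= 100.0 * min_rel_intensity
    out = spectrum.copy()
    out.mz = spectrum.mz[keep]
    out.intensities = scaled[keep]
    return out


def is_normalized(spectrum: MassSpectrum, atol: float = 1e-9) -> bool:
    """True when the base peak sits at intensity 100 (the matching contract)."""
    return spectrum.n_peaks > 0 and abs(float(np.max(spectrum.intensities)) - 100.0) <= atol


def select_by_precursor(
    library: list[LibraryEntry], precursor_mz: float, ppm_tol: float
) -> list[LibraryEntry]:
    """Library entries whose precursor lies within ±ppm_tol of the query's.

    The ppm window is taken relative to the query precursor; library order
    is preserved.
    """
    return [
        e
        for e in library
        if ppm_diff(precursor_mz, e.spectrum.precursor_mz) <= ppm_tol
    ]
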