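"""Readers and writers for every external format the pipeline touches.

Query spectra arrive as mzML (centroided DDA) or MGF; spectral libraries as
MSP or MGF dialects; structure maps as SDF; annotator candidates as TSV.
The only format written from scratch here is the SIRIUS ``.ms`` parameter
file, for which no general-purpose writer exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276466812

#: Fixed vocabulary of spectral-library provenance tags.
LIBRARY_SOURCES = ("GNPS", "HMDB", "MassBank", "other")


class SpectraIOError(Exception):
    """Unreadable or structurally invalid input file."""


class EmptyInputError(SpectraIOError):
    """A file parsed cleanly but contained no usable MS2 scans."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MassSpectrum:
    """A centroided peak list with precursor metadata; the unit of matching.

    Parameters
    ----------
    spectrum_id:
        Identifier of the scan or library record.
    precursor_mz:
        m/z of the ion selected for fragmentation (Da); must be positive.
    mz, intensities:
        Parallel arrays of fragment m/z (Da) and intensity (arbitrary
        counts). Stored sorted ascending by m/z.
    precursor_charge:
        Signed charge; negative in negative ionization mode.
    retention_time:
        Seconds.
    polarity:
        ``positive`` | ``negative`` | ``unknown``.
    """

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensities: np.ndarray
    precursor_charge: int = 1
    retention_time: float = 0.0
    polarity: str = "unknown"
    source_file: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz.shape != self.intensities.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensities must be parallel 1-D arrays")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensities = self.intensities[order]
        if self.mz.size and self.mz[0] <= 0:
            raise ValueError("all fragment m/z must be positive")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if not self.precursor_mz > 0:
            raise ValueError("precursor_mz must be positive")
        if self.polarity not in ("positive", "negative", "unknown"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def peaks(self) -> list[tuple[float, float]]:
        """Peak list as ``(mz, intensity)`` tuples, ascending in m/z."""
        return list(zip(self.mz.tolist(), self.intensities.tolist()))

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def copy(self) -> "MassSpectrum":
        return replace(self, mz=self.mz.copy(), intensities=self.intensities.copy())


@dataclass
class LibraryEntry:
    """One reference spectrum of a known compound in a spectral library."""

    spectrum: MassSpectrum
    compound_name: str
    accession: str
    library_source: str
    smiles: str | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
        if self.library_source not in LIBRARY_SOURCES:
            raise ValueError(
                f"library_source {self.library_source!r} not in {LIBRARY_SOURCES}"
            )


@dataclass(frozen=True)
class StructureMapEntry:
    """Row of a structure map (an SDF like HMDB's structures.sdf)."""

    database_id: str
    name: str
    formula: str
    smiles: str


# ---------------------------------------------------------------------------
# Query spectra (mzML / MGF)
# ---------------------------------------------------------------------------

def read_ms2_spectra(path: str | Path, format: str | None = None) -> list[MassSpectrum]:
    """Read all MS2 scans from an mzML or MGF file.

    MS1 scans in mzML are skipped; if a file yields no MS2 scans an
    :class:`EmptyInputError` reporting the scan counts is raised. When
    ``format`` is omitted it is inferred from the file extension.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "mzml":
        return _read_mzml(path)
    if format == "mgf":
        return _read_query_mgf(path)
    raise ValueError(f"unsupported query format {format!r} (expected mzml or mgf)")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(array_el) -> tuple[str | None, np.ndarray]:
    """Decode one mzML binaryDataArray element (float32/64, zlib or none)."""
    import base64
    import zlib

    kind = None
    dtype = "<f8"
    compressed = False
    payload = b""
    for child in array_el.iter():
        name = _local(child.tag)
        if name == "cvParam":
            cv = child.get("name", "")
            if cv == "m/z array":
                kind = "mz"
            elif cv == "intensity array":
                kind = "intensity"
            elif cv == "32-bit float":
                dtype = "<f4"
            elif cv == "zlib compression":
                compressed = True
        elif name == "binary" and child.text:
            payload = base64.b64decode(child.text)
    if compressed:
        payload = zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[MassSpectrum]:
    # pyteomics' mzML backend needs psims at runtime, which this toolchain
    # does not ship; a direct reader over lxml covers the schema subset a
    # centroided DDA file uses (scan list, precursor block, peak arrays).
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise SpectraIOError(f"cannot read mzML file {path}: {exc}") from exc

    spectra: list[MassSpectrum] = []
    n_total = 0
    for spec_el in tree.iter():
        if _local(spec_el.tag) != "spectrum":
            continue
        n_total += 1
        ms_level = None
        polarity = "unknown"
        centroided = True
        rt = 0.0
        pmz = None
        charge = None
        mz = intensities = None
        for el in spec_el.iter():
            name = _local(el.tag)
            if name == "cvParam":
                cv = el.get("name", "")
                parent = _local(el.getparent().tag)
                if cv == "ms level":
                    ms_level = int(el.get("value"))
                elif cv == "positive scan":
                    polarity = "positive"
                elif cv == "negative scan":
                    polarity = "negative"
                elif cv == "profile spectrum":
                    centroided = False
                elif cv == "scan start time":
                    rt = float(el.get("value"))
                    if el.get("unitName") in ("minute", "minutes", "min"):
                        rt *= 60.0
                elif cv == "selected ion m/z":
                    pmz = float(el.get("value"))
                elif cv == "charge state" and parent == "selectedIon":
                    charge = int(float(el.get("value")))
            elif name == "binaryDataArray":
                kind, values = _decode_binary_array(el)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    intensities = values
        if ms_level != 2:
            continue
        if not centroided:
            logger.warning("profile-mode MS2 scan in %s rejected", path)
            continue
        if pmz is None or mz is None or intensities is None:
            logger.warning("MS2 scan without precursor or peaks in %s; skipped", path)
            continue
        if charge is None:
            # DDA small-molecule default: singly charged, sign from polarity
            charge = -1 if polarity == "negative" else 1
        elif polarity == "negative" and charge > 0:
            charge = -charge
        spectra.append(
            MassSpectrum(
                spectrum_id=str(spec_el.get("id", f"scan={n_total}")),
                precursor_mz=pmz,
                mz=mz,
                intensities=intensities,
                precursor_charge=charge,
                retention_time=rt,
                polarity=polarity,
                source_file=str(path),
            )
        )
    if not spectra:
        raise EmptyInputError(
            f"{path}: no MS2 scans found ({n_total} scans total, 0 usable at MS level 2)"
        )
    return spectra


def _charge_and_polarity(params: dict) -> tuple[int, str]:
    charge_list = params.get("charge")
    if charge_list:
        charge = int(charge_list[0])
        return charge, ("negative" if charge < 0 else "positive")
    return 1, "unknown"


def _read_query_mgf(path: Path) -> list[MassSpectrum]:
    spectra: list[MassSpectrum] = []
    n_total = 0
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            n_total += 1
            params = entry["params"]
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                logger.warning("MGF entry without PEPMASS in %s; skipped", path)
                continue
            charge, polarity = _charge_and_polarity(params)
            spectra.append(
                MassSpectrum(
                    spectrum_id=str(params.get("title", f"index={n_total}")),
                    precursor_mz=float(pepmass[0]),
                    mz=entry["m/z array"],
                    intensities=entry["intensity array"],
                    precursor_charge=charge,
                    retention_time=float(params.get("rtinseconds", 0.0)),
                    polarity=polarity,
                    source_file=str(path),
                )
            )
    if not spectra:
        raise EmptyInputError(f"{path}: no MS2 spectra found ({n_total} entries)")
    return spectra


def write_mgf(spectra: Iterable[MassSpectrum], path: str | Path) -> Path:
    """Write spectra as MGF (one BEGIN IONS block per spectrum)."""
    path = Path(path)
    records = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "rtinseconds": s.retention_time,
            "charge": s.precursor_charge,
        }
        records.append(
            {"m/z array": s.mz, "intensity array": s.intensities, "params": params}
        )
    _mgf.write(records, str(path), file_mode="w")
    return path


# ---------------------------------------------------------------------------
# Spectral libraries (MSP / MGF dialects)
# ---------------------------------------------------------------------------

def read_library(
    path: str | Path, format: str, library_source: str
) -> list[LibraryEntry]:
    """Parse a spectral library into :class:`LibraryEntry` records.

    Entries lacking a precursor m/z or containing no peaks are skipped with
    a logged warning; parsing never aborts on a bad record.
    """
    if library_source not in LIBRARY_SOURCES:
        raise ValueError(
            f"library_source {library_source!r} not in {LIBRARY_SOURCES}"
        )
    path = Path(path)
    if format == "msp":
        raw = _iter_msp(path)
    elif format == "mgf":
        raw = _iter_library_mgf(path)
    else:
        raise ValueError(f"unsupported library format {format!r} (msp or mgf)")

    entries: list[LibraryEntry] = []
    n_skipped = 0
    for idx, rec in enumerate(raw, start=1):
        pmz = rec.get("precursor_mz")
        if pmz is None or not rec["mz"].size:
            n_skipped += 1
            logger.warning(
                "library entry %d in %s skipped (missing precursor m/z or peaks)",
                idx,
                path,
            )
            continue
        spectrum = MassSpectrum(
            spectrum_id=rec["accession"],
            precursor_mz=float(pmz),
            mz=rec["mz"],
            intensities=rec["intensities"],
            precursor_charge=rec.get("charge", 1),
            polarity=rec.get("polarity", "unknown"),
            source_file=str(path),
        )
        entries.append(
            LibraryEntry(
                spectrum=spectrum,
                compound_name=rec.get("name", ""),
                accession=rec["accession"],
                library_source=library_source,
                smiles=rec.get("smiles") or None,
                formula=rec.get("formula") or None,
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d of %d entries", path, n_skipped, n_skipped + len(entries))
    return entries


def _iter_msp(path: Path) -> Iterable[dict]:
    # matchms owns the MSP dialect zoo; we only remap its harmonized metadata.
    from matchms.importing import load_from_msp

    for idx, spec in enumerate(load_from_msp(str(path), metadata_harmonization=True), 1):
        meta = spec.metadata
        yield {
            "accession": str(
                meta.get("spectrum_id") or meta.get("accession") or f"MSP{idx:06d}"
            ),
            "name": meta.get("compound_name", ""),
            "precursor_mz": meta.get("precursor_mz"),
            "smiles": meta.get("smiles"),
            "formula": meta.get("formula"),
            "charge": int(meta.get("charge") or 1),
            "mz": np.asarray(spec.peaks.mz, dtype=float),
            "intensities": np.asarray(spec.peaks.intensities, dtype=float),
        }


def _iter_library_mgf(path: Path) -> Iterable[dict]:
    with _mgf.MGF(str(path)) as reader:
        for idx, entry in enumerate(reader, 1):
            params = entry["params"]
            pepmass = params.get("pepmass")
            charge, polarity = _charge_and_polarity(params)
            yield {
                "accession": str(
                    params.get("accession") or params.get("title") or f"MGF{idx:06d}"
                ),
                "name": str(params.get("name", params.get("title", ""))),
                "precursor_mz": None if not pepmass or pepmass[0] is None else pepmass[0],
                "smiles": params.get("smiles"),
                "formula": params.get("formula"),
                "charge": charge,
                "polarity": polarity,
                "mz": np.asarray(entry["m/z array"], dtype=float),
                "intensities": np.asarray(entry["intensity array"], dtype=float),
            }


def write_msp(entries: Iterable[LibraryEntry], path: str | Path) -> Path:
    """Write library entries in NIST-style MSP. Deterministic byte output."""
    path = Path(path)
    with open(path, "w") as fh:
        for e in entries:
            s = e.spectrum
            fh.write(f"NAME: {e.compound_name}\n")
            fh.write(f"PRECURSORMZ: {s.precursor_mz}\n")
            if e.formula:
                fh.write(f"FORMULA: {e.formula}\n")
            if e.smiles:
                fh.write(f"SMILES: {e.smiles}\n")
            fh.write(f"DB#: {e.accession}\n")
            fh.write(f"Num Peaks: {s.n_peaks}\n")
            for mz, inten in zip(s.mz, s.intensities):
                fh.write(f"{mz} {inten}\n")
            fh.write("\n")
    return path


def write_library_mgf(entries: Iterable[LibraryEntry], path: str | Path) -> Path:
    """Write library entries as an MGF dialect carrying NAME/SMILES/ACCESSION."""
    path = Path(path)
    with open(path, "w") as fh:
        for e in entries:
            s = e.spectrum
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={e.accession}\n")
            fh.write(f"ACCESSION={e.accession}\n")
            fh.write(f"NAME={e.compound_name}\n")
            fh.write(f"PEPMASS={s.precursor_mz}\n")
            charge = s.precursor_charge
            fh.write(f"CHARGE={abs(charge)}{'-' if charge < 0 else '+'}\n")
            if e.smiles:
                fh.write(f"SMILES={e.smiles}\n")
            if e.formula:
                fh.write(f"FORMULA={e.formula}\n")
            for mz, inten in zip(s.mz, s.intensities):
                fh.write(f"{mz} {inten}\n")
            fh.write("END IONS\n")
    return path


# ---------------------------------------------------------------------------
# Structure maps (SDF)
# ---------------------------------------------------------------------------

#: Property-name fallbacks tried in order; HMDB's structures.sdf spellings first.
SDF_ID_PROPS = ("DATABASE_ID", "HMDB_ID", "ID")
SDF_NAME_PROPS = ("GENERIC_NAME", "NAME", "COMMON_NAME")
SDF_FORMULA_PROPS = ("CHEMICAL_FORMULA", "FORMULA", "MOLECULAR_FORMULA")
SDF_SMILES_PROPS = ("SMILES", "CANONICAL_SMILES")


def _first_prop(mol, names: Sequence[str]) -> str | None:
    for name in names:
        if mol.HasProp(name):
            return mol.GetProp(name)
    return None


def read_structure_map(
    path: str | Path,
    id_props: Sequence[str] = SDF_ID_PROPS,
    name_props: Sequence[str] = SDF_NAME_PROPS,
    formula_props: Sequence[str] = SDF_FORMULA_PROPS,
    smiles_props: Sequence[str] = SDF_SMILES_PROPS,
) -> list[StructureMapEntry]:
    """Read an SDF structure map (id, name, formula, SMILES per record).

    When a record has no SMILES property the SMILES is derived from the
    molblock itself; records whose molblock fails to parse are skipped.
    """
    from rdkit import Chem

    path = Path(path)
    entries: list[StructureMapEntry] = []
    if path.stat().st_size == 0:
        return entries
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for idx, mol in enumerate(supplier):
        if mol is None:
            logger.warning("unparsable molblock at record %d in %s; skipped", idx, path)
            continue
        smiles = _first_prop(mol, smiles_props)
        if smiles is None:
            smiles = Chem.MolToSmiles(mol)
        database_id = _first_prop(mol, id_props) or f"SDF{idx:06d}"
        entries.append(
            StructureMapEntry(
                database_id=database_id,
                name=_first_prop(mol, name_props) or "",
                formula=_first_prop(mol, formula_props) or "",
                smiles=smiles,
            )
        )
    return entries


def structure_map_index(entries: Iterable[StructureMapEntry]) -> dict[str, StructureMapEntry]:
    """Index a structure map by database_id (last record wins on duplicates)."""
    return {e.database_id: e for e in entries}


# ---------------------------------------------------------------------------
# SIRIUS .ms parameter files
# ---------------------------------------------------------------------------

def write_sirius_ms(
    feature: MassSpectrum,
    out: str | Path,
    ms1_peaks: Sequence[tuple[float, float]] | None = None,
    isotope_peaks: Sequence[tuple[float, float]] | None = None,
    compound_id: str | None = None,
) -> Path:
    """Write one SIRIUS ``.ms`` parameter file for a fragmented feature.

    The file carries the feature id, the precursor (parent) mass, the signed
    charge, the median retention time in seconds, then optional ``>ms1`` and
    isotope blocks and the mandatory ``>ms2`` peak block. Output is
    byte-deterministic for fixed input.
    """
    if not feature.precursor_mz > 0:
        raise ValueError("feature has no precursor m/z; refusing to write .ms")
    if feature.n_peaks < 1:
        raise ValueError("feature has no MS2 peaks; refusing to write .ms")
    out = Path(out)
    lines = [
        f">compound {compound_id or feature.spectrum_id}",
        f">parentmass {feature.precursor_mz!r}",
        f">charge {feature.precursor_charge}",
        f">rt {feature.retention_time!r}",
        "",
    ]
    if ms1_peaks:
        lines.append(">ms1")
        lines.extend(f"{float(mz)!r} {float(inten)!r}" for mz, inten in ms1_peaks)
        lines.append("")
    if isotope_peaks:
        lines.append(">ms1merged")
        lines.extend(f"{float(mz)!r} {float(inten)!r}" for mz, inten in isotope_peaks)
        lines.append("")
    lines.append(">ms2")
    lines.extend(
        f"{float(mz)!r} {float(inten)!r}" for mz, inten in zip(feature.mz, feature.intensities)
    )
    out.write_text("\n".join(lines) + "\n")
    return out


def parse_sirius_ms(path: str | Path) -> dict:
    """Line-level reader for ``.ms`` files (round-trip checks, not SIRIUS)."""
    header: dict[str, str] = {}
    blocks: dict[str, list[tuple[float, float]]] = {}
    current: str | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            key, _, value = line[1:].partition(" ")
            if value:
                header[key] = value
                current = None
            else:
                current = key
                blocks[current] = []
        elif current is not None:
            mz, inten = line.split()
            blocks[current].append((float(mz), float(inten)))
    return {"header": header, "blocks": blocks}


# ---------------------------------------------------------------------------
# Candidate tables (TSV)
# ---------------------------------------------------------------------------

def read_candidate_table(path: str | Path, source: str):
    """Read a per-source candidate TSV into :class:`CandidateRecord` rows.

    Expected columns: ``rank`` plus ``smiles`` and/or ``formula``; optional
    ``score``, ``name``, ``feature_id``, ``compound_class``, ``accession``.
    Rows with neither SMILES nor formula are rejected with a warning; ranks
    are re-densified to 1..n when sparse.
    """
    from ms2derep.compound_results import CANDIDATE_SOURCES, CandidateRecord

    if source not in CANDIDATE_SOURCES:
        raise ValueError(f"source {source!r} not in {CANDIDATE_SOURCES}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "rank" not in df.columns:
        raise SpectraIOError(f"{path}: candidate table lacks a 'rank' column")
    if "smiles" not in df.columns and "formula" not in df.columns:
        raise SpectraIOError(f"{path}: candidate table has neither smiles nor formula")

    records = []
    for _, row in df.iterrows():
        smiles = row.get("smiles", "") or None
        formula = row.get("formula", "") or None
        if smiles is None and formula is None:
            logger.warning("%s: row with neither SMILES nor formula rejected", path)
            continue
        score = row.get("score", "")
        records.append(
            CandidateRecord(
                feature_id=row.get("feature_id", ""),
                source=source,
                source_rank=int(float(row["rank"])),
                source_score=float(score) if score != "" else None,
                smiles=smiles,
                formula=formula,
                name=row.get("name", "") or None,
                compound_class=row.get("compound_class", "") or None,
                accession=row.get("accession", "") or None,
                is_formula_only=smiles is None and formula is not None,
                source_file=str(path),
            )
        )
    records.sort(key=lambda r: r.source_rank)
    expected = list(range(1, len(records) + 1))
    if [r.source_rank for r in records] != expected:
        logger.warning("%s: sparse ranks re-densified to 1..%d", path, len(records))
        for r, dense in zip(records, expected):
            r.source_rank = dense
    return records


def write_candidate_table(records, path: str | Path) -> Path:
    """Write candidate records to TSV (inverse of :func:`read_candidate_table`)."""
    path = Path(path)
    rows = [
        {
            "feature_id": r.feature_id,
            "rank": r.source_rank,
            "score": "" if r.source_score is None else r.source_score,
            "smiles": r.smiles or "",
            "formula": r.formula or "",
            "name": r.name or "",
            "compound_class": r.compound_class or "",
            "accession": r.accession or "",
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "feature_id", "rank", "score", "smiles", "formula",
            "name", "compound_class", "accession",
        ],
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Suspect / standards lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standard:
    """User-supplied reference compound; a hit promotes a feature to MSI 1."""

    name: str
    smiles: str | None = None


def read_suspect_list(path: str | Path) -> list[Standard]:
    """Read a CSV of user standards with columns ``name`` and ``smiles``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "name" not in df.columns:
        raise SpectraIOError(f"{path}: suspect list needs a 'name' column")
    return [
        Standard(name=row["name"], smiles=row.get("smiles", "") or None)
        for _, row in df.iterrows()
    ]
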