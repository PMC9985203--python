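"""Synthetic spectral libraries, query spectra and candidate scenarios.

Everything the pipeline consumes can be generated here from a seed, so the
full toolchain is testable offline. Spectra are *random-fragment*: fragment
m/z values are drawn uniformly below the precursor rather than derived from
bond chemistry — they exercise the matching mathematics, not fragmentation
realism. Structures come from a packaged catalog of ~110 real small-molecule
SMILES.

Noise applied to queries emulates instrument effects at the levels typical
of a well-calibrated orbitrap DDA run: sub-tolerance m/z jitter (uniform,
ppm), multiplicative intensity error (lognormal-ish via a clipped normal
CV), random peak dropout, and spurious decoy peaks.
"""

from __future__ import annotations

import base64
import json
import struct
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from ms2derep.spectra_io import (
    PROTON_MASS,
    LibraryEntry,
    MassSpectrum,
    write_mgf,
    write_msp,
)

SCENARIOS = ("three_agree", "two_agree_plus_rival", "singletons", "formula_only", "standards_hit")


def load_catalog() -> list[tuple[str, str]]:
    """The packaged (name, SMILES) catalog of real small molecules."""
    text = resources.files("ms2derep.data").joinpath("smiles_catalog.tsv").read_text()
    rows = [line.split("\t") for line in text.strip().splitlines()[1:]]
    return [(name, smiles) for name, smiles in rows]


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def generate_library(
    n_compounds: int,
    seed: int,
    out_dir: str | Path,
    peaks_per_spectrum: tuple[int, int] = (5, 12),
    polarity: str = "positive",
) -> tuple[Path, Path]:
    """Write a seeded MSP spectral library and its cross-referenced SDF map.

    Compounds are drawn from the packaged catalog; each gets a spectrum of
    ``peaks_per_spectrum`` random fragments between 50 Da and the precursor,
    with the precursor m/z derived from the monoisotopic mass ± a proton.
    Identical seed ⇒ byte-identical files.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    catalog = load_catalog()
    if n_compounds > len(catalog):
        raise ValueError(f"catalog holds only {len(catalog)} compounds")
    picks = sorted(rng.choice(len(catalog), size=n_compounds, replace=False).tolist())

    entries: list[LibraryEntry] = []
    mols = []
    lo, hi = peaks_per_spectrum
    sign = -1.0 if polarity == "negative" else 1.0
    charge = -1 if polarity == "negative" else 1
    for i, pick in enumerate(picks, start=1):
        name, smiles = catalog[pick]
        mol = Chem.MolFromSmiles(smiles)
        precursor = Descriptors.ExactMolWt(mol) + sign * PROTON_MASS
        n_peaks = int(rng.integers(lo, hi + 1))
        mz = np.sort(rng.uniform(50.0, max(60.0, precursor - 10.0), size=n_peaks))
        intensities = rng.uniform(10.0, 100.0, size=n_peaks)
        accession = f"SYN{i:06d}"
        entries.append(
            LibraryEntry(
                spectrum=MassSpectrum(
                    spectrum_id=accession,
                    precursor_mz=round(precursor, 5),
                    mz=np.round(mz, 5),
                    intensities=np.round(intensities, 2),
                    precursor_charge=charge,
                    polarity=polarity,
                ),
                compound_name=name,
                accession=accession,
                library_source="other",
                smiles=smiles,
                formula=rdMolDescriptors.CalcMolFormula(mol),
            )
        )
        mol.SetProp("DATABASE_ID", accession)
        mol.SetProp("GENERIC_NAME", name)
        mol.SetProp("CHEMICAL_FORMULA", rdMolDescriptors.CalcMolFormula(mol))
        mol.SetProp("SMILES", smiles)
        mols.append(mol)

    msp_path = write_msp(entries, out_dir / "library.msp")
    sdf_path = out_dir / "structures.sdf"
    writer = Chem.SDWriter(str(sdf_path))
    writer.SetKekulize(True)
    for mol in mols:
        writer.write(mol)
    writer.close()
    return msp_path, sdf_path


# ---------------------------------------------------------------------------
# Query generation with planted ground truth
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    """Perturbations applied to a library spectrum to fake a measurement."""

    ppm_jitter: float = 5.0
    intensity_cv: float = 0.1
    dropout_fraction: float = 0.1
    n_decoy_peaks: int = 2

    def __post_init__(self) -> None:
        if min(self.ppm_jitter, self.intensity_cv, self.dropout_fraction) < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_decoy_peaks < 0:
            raise ValueError("n_decoy_peaks must be >= 0")
        if self.dropout_fraction >= 1:
            raise ValueError("dropout_fraction must be < 1")


@dataclass
class ManifestEntry:
    query_id: str
    true_accession: str
    true_smiles: str
    true_name: str
    precursor_mz: float
    planted_sources: list[str] = field(default_factory=list)


@dataclass
class GroundTruthManifest:
    """What was planted where; the oracle for recovery tests."""

    seed: int
    noise: NoiseParams
    entries: list[ManifestEntry]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "noise": asdict(self.noise),
            "entries": [asdict(e) for e in self.entries],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            noise=NoiseParams(**payload["noise"]),
            entries=[ManifestEntry(**e) for e in payload["entries"]],
        )


def perturb_spectrum(
    spectrum: MassSpectrum, noise: NoiseParams, rng: np.random.Generator
) -> MassSpectrum:
    """Apply jitter, intensity error, dropout and decoys to one spectrum.

    The base peak is never dropped, so the perturbed spectrum always keeps
    its anchor; decoy intensities sit between 10% and 50% of the base peak.
    """
    mz = spectrum.mz.copy()
    intensities = spectrum.intensities.copy()
    mz *= 1.0 + rng.uniform(-noise.ppm_jitter, noise.ppm_jitter, size=mz.size) * 1e-6
    intensities *= np.clip(1.0 + rng.normal(0.0, noise.intensity_cv, size=mz.size), 0.05, None)
    n_drop = int(np.floor(noise.dropout_fraction * mz.size))
    if n_drop:
        base_idx = int(np.argmax(intensities))
        droppable = np.delete(np.arange(mz.size), base_idx)
        drop = rng.choice(droppable, size=min(n_drop, droppable.size), replace=False)
        keep = np.setdiff1d(np.arange(mz.size), drop)
        mz, intensities = mz[keep], intensities[keep]
    if noise.n_decoy_peaks:
        decoy_mz = rng.uniform(50.0, spectrum.precursor_mz, size=noise.n_decoy_peaks)
        decoy_int = rng.uniform(0.1, 0.5, size=noise.n_decoy_peaks) * float(np.max(intensities))
        mz = np.concatenate([mz, decoy_mz])
        intensities = np.concatenate([intensities, decoy_int])
    out = spectrum.copy()
    out.mz = np.round(mz, 6)
    out.intensities = np.round(intensities, 4)
    return out


def generate_queries(
    library: list[LibraryEntry],
    noise: NoiseParams,
    seed: int,
    out_dir: str | Path,
) -> tuple[Path, GroundTruthManifest]:
    """One noised query per library entry, written as MGF plus a manifest."""
    if not library:
        raise ValueError("library is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    queries: list[MassSpectrum] = []
    entries: list[ManifestEntry] = []
    for entry in library:
        q = perturb_spectrum(entry.spectrum, noise, rng)
        q.spectrum_id = f"Q_{entry.accession}"
        q.retention_time = round(float(rng.uniform(60.0, 900.0)), 3)
        queries.append(q)
        entries.append(
            ManifestEntry(
                query_id=q.spectrum_id,
                true_accession=entry.accession,
                true_smiles=entry.smiles or "",
                true_name=entry.compound_name,
                precursor_mz=entry.spectrum.precursor_mz,
            )
        )
    mgf_path = write_mgf(queries, out_dir / "queries.mgf")
    manifest = GroundTruthManifest(seed=seed, noise=noise, entries=entries)
    manifest.to_json(out_dir / "ground_truth.json")
    return mgf_path, manifest


# ---------------------------------------------------------------------------
# Candidate-table scenarios (consolidation test cases with known answers)
# ---------------------------------------------------------------------------

def _catalog_smiles(name: str) -> str:
    for cname, smiles in load_catalog():
        if cname == name:
            return smiles
    raise KeyError(name)


def generate_candidate_scenario(
    scenario: str, seed: int, out_dir: str | Path
) -> dict:
    """Write per-source candidate TSVs plus the hand-computed expected result.

    Scenarios encode the agreement patterns that drive prioritization and
    MSI grading: three sources sharing one structure, two agreeing against
    a rival third source, four mutually dissimilar singletons, a
    formula-only annotator group, and a standards-list hit. Returns a dict
    with the written paths and the expected annotation.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    from ms2derep.compound_results import CandidateRecord, canonical_smiles
    from ms2derep.spectra_io import write_candidate_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    nicotiflorin = _catalog_smiles("Nicotiflorin")
    chlorobenzotriazole = _catalog_smiles("1-Chlorobenzotriazole")
    cysteinolic = _catalog_smiles("Cysteinolic acid")

    def rec(source, rank, smiles=None, formula=None, name=None, cls=None, score=None):
        return CandidateRecord(
            feature_id=feature_id,
            source=source,
            source_rank=rank,
            source_score=score,
            smiles=smiles,
            formula=formula,
            name=name,
            compound_class=cls,
            is_formula_only=smiles is None and formula is not None,
        )

    per_source: dict[str, list] = {}
    standards_csv: Path | None = None

    if scenario in ("three_agree", "standards_hit"):
        feature_id = "file_1M287R318ID319"
        per_source = {
            "GNPS": [rec("GNPS", 1, smiles=nicotiflorin, name="Nicotiflorin", score=0.95)],
            "HMDB": [rec("HMDB", 1, smiles=nicotiflorin, name="Nicotiflorin", score=0.81)],
            "MassBank": [rec("MassBank", 1, smiles=nicotiflorin, name="Nicotiflorin", score=0.77)],
        }
        expected = {
            "feature_id": feature_id,
            "final_smiles": canonical_smiles(nicotiflorin),
            "msi_level": 1 if scenario == "standards_hit" else 2,
            "overall_ranks": {"G_1": 1, "H_1": 2, "M_1": 3},
        }
        if scenario == "standards_hit":
            standards_csv = out_dir / "standards.csv"
            standards_csv.write_text(f"name,smiles\nNicotiflorin,{nicotiflorin}\n")
    elif scenario == "two_agree_plus_rival":
        feature_id = "file_1M154R155ID7"
        per_source = {
            "GNPS": [rec("GNPS", 1, smiles=chlorobenzotriazole, name="1-Chlorobenzotriazole", score=0.92)],
            "MassBank": [rec("MassBank", 1, smiles=chlorobenzotriazole, name="1-Chlorobenzotriazole", score=0.74)],
            "SIRIUS": [rec("SIRIUS", 1, smiles=cysteinolic, name="Cysteinolic acid")],
        }
        expected = {
            "feature_id": feature_id,
            "final_smiles": canonical_smiles(chlorobenzotriazole),
            "msi_level": 2,
            "overall_ranks": {"G_1": 1, "M_1": 2, "S_1": 3},
        }
    elif scenario == "singletons":
        feature_id = "file_1M100R100ID1"
        per_source = {
            "GNPS": [rec("GNPS", 1, smiles=_catalog_smiles("Caffeine"), name="Caffeine", score=0.9)],
            "SIRIUS": [rec("SIRIUS", 1, smiles=_catalog_smiles("Palmitic acid"), name="Palmitic acid")],
            "HMDB": [rec("HMDB", 1, smiles=_catalog_smiles("Glucose"), name="Glucose", score=0.72)],
            "MassBank": [rec("MassBank", 1, smiles=_catalog_smiles("Taurine"), name="Taurine", score=0.71)],
        }
        expected = {
            "feature_id": feature_id,
            "final_smiles": canonical_smiles(_catalog_smiles("Caffeine")),
            "msi_level": 2,
            "overall_ranks": {"G_1": 1, "S_1": 2, "M_1": 3, "H_1": 4},
        }
    else:  # formula_only
        feature_id = "file_1M447R531ID42"
        per_source = {
            "SIRIUS": [
                rec("SIRIUS", 1, formula="C27H30O15"),
                rec("SIRIUS", 2, formula="C26H26O16"),
            ],
        }
        expected = {
            "feature_id": feature_id,
            "final_smiles": None,
            "msi_level": 4,
            "overall_ranks": {"S_1": 1, "S_2": 2},
        }

    paths = {}
    for source, records in per_source.items():
        path = out_dir / f"candidates_{source.lower()}.tsv"
        write_candidate_table(records, path)
        paths[source] = path
    expected_path = out_dir / "expected.json"
    expected_path.write_text(json.dumps(expected, indent=1, sort_keys=True) + "\n")
    result = {
        "scenario": scenario,
        "feature_id": feature_id,
        "tables": paths,
        "expected": expected,
        "expected_path": expected_path,
    }
    if standards_csv is not None:
        result["standards"] = standards_csv
    return result


# ---------------------------------------------------------------------------
# Minimal mzML writing (fixtures only)
# ---------------------------------------------------------------------------

_MZML_HEAD = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{count}">
"""

_MZML_TAIL = """    </spectrumList>
  </run>
</mzML>
"""


def _b64_floats(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def write_synthetic_mzml(
    spectra: list[MassSpectrum], path: str | Path, ms1_spectra: list[MassSpectrum] | None = None
) -> Path:
    """Write a minimal centroided mzML for fixture use.

    Synthetic stand-in for instrument output: just enough of the PSI schema
    (scan list, precursor block, base64 little-endian doubles) for standard
    mzML readers. Optional ``ms1_spectra`` are interleaved first as MS1
    scans so MS-level filtering is exercisable.
    """
    path = Path(path)
    parts = []
    index = 0

    def spectrum_xml(s: MassSpectrum, ms_level: int) -> str:
        nonlocal index
        mz_b64 = _b64_floats(s.mz)
        int_b64 = _b64_floats(s.intensities)
        polarity_cv = {
            "positive": '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>',
            "negative": '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>',
        }.get(s.polarity, "")
        precursor = ""
        if ms_level == 2:
            precursor = f"""
        <precursorList count="1"><precursor>
          <selectedIonList count="1"><selectedIon>
            <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
          </selectedIon></selectedIonList>
        </precursor></precursorList>"""
        xml = f"""      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{s.n_peaks}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        {polarity_cv}
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.retention_time}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>{precursor}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""
        index += 1
        return xml

    for s in ms1_spectra or []:
        parts.append(spectrum_xml(s, ms_level=1))
    for s in spectra:
        parts.append(spectrum_xml(s, ms_level=2))
    total = len(parts)
    path.write_text(_MZML_HEAD.format(count=total) + "".join(parts) + _MZML_TAIL)
    return path
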