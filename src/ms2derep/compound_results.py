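"""Post-processing of annotation candidates from spectral and compound sources.

Covers structure resolution (SDF structure map first, then an optional
pluggable name→SMILES resolver, off by default so runs never touch the
network), cleanup of decorated spectral-library compound names, SMILES
canonicalization, conversion of passing spectral matches into candidate
records, and the formula fallback for compound-annotator output that
predicted no structures.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable

from rdkit import Chem
from rdkit import RDLogger

from ms2derep.spectra_io import StructureMapEntry, structure_map_index
from ms2derep.spectral_match import SpectralMatch

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")

#: Candidate provenance vocabulary: three spectral libraries plus the
#: compound-database annotator (SIRIUS-style structure/formula tables).
CANDIDATE_SOURCES = ("GNPS", "HMDB", "MassBank", "SIRIUS")

#: Default cleanup patterns for decorated spectral-library names, e.g.
#: "Spectral Match to Kaempferol from NIST14" or trailing adduct tags.
DEFAULT_NAME_PATTERNS: list[tuple[str, str]] = [
    (r"^Spectral Match to (.+?) from .+$", r"\1"),
    (r"^MoNA:\d+\s*", ""),
    (r"^Massbank:\s*\S+\s+", ""),
    (r"\s*\[M[+-][^\]]*\][+-]?\d*$", ""),
    (r"\s*\[\d+\.?\d*\]$", ""),
    (r"[\x00-\x1f]", ""),
]


@dataclass
class CandidateRecord:
    """One (source, rank) annotation candidate for a feature."""

    feature_id: str
    source: str
    source_rank: int
    source_score: float | None = None
    smiles: str | None = None
    canonical_smiles: str | None = None
    formula: str | None = None
    name: str | None = None
    compound_class: str | None = None
    accession: str | None = None
    is_formula_only: bool = False
    resolution: str = ""
    overall_rank: int | None = None
    source_file: str = ""

    def __post_init__(self) -> None:
        if self.source not in CANDIDATE_SOURCES:
            raise ValueError(f"source {self.source!r} not in {CANDIDATE_SOURCES}")
        if self.source_rank < 1:
            raise ValueError("source_rank must be a positive integer")


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES via RDKit, or None when the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def clean_name(name: str, patterns: list[tuple[str, str]] | None = None) -> str:
    """Strip library decoration from a compound name.

    Patterns are applied in order until the name is stable, so nested
    decoration (prefix + adduct suffix) also comes off.
    """
    patterns = DEFAULT_NAME_PATTERNS if patterns is None else patterns
    prev = None
    while prev != name:
        prev = name
        for pattern, repl in patterns:
            name = re.sub(pattern, repl, name)
        name = name.strip()
    return name


def resolve_structures(
    records: list[CandidateRecord],
    structure_map: list[StructureMapEntry] | None = None,
    resolver: Callable[[str], str | None] | None = None,
    name_patterns: list[tuple[str, str]] | None = None,
) -> list[CandidateRecord]:
    """Fill in and canonicalize candidate structures; never drops a record.

    Records already carrying SMILES are canonicalized in place. Records
    without SMILES are resolved from the structure map by accession (the
    HMDB structures.sdf path), else — when a resolver is supplied — by
    cleaned compound name. A resolver exception is logged and leaves the
    record unresolved; remote lookups must never abort a run.
    """
    index = structure_map_index(structure_map or [])
    for rec in records:
        if rec.name:
            rec.name = clean_name(rec.name, name_patterns)
        if rec.smiles is None and rec.accession and rec.accession in index:
            entry = index[rec.accession]
            rec.smiles = entry.smiles
            rec.name = rec.name or entry.name
            rec.formula = rec.formula or entry.formula
            rec.resolution = "structure_map"
        if rec.smiles is None and resolver is not None and rec.name:
            try:
                rec.smiles = resolver(rec.name)
            except Exception as exc:
                logger.warning("resolver failed for %r: %s", rec.name, exc)
            else:
                if rec.smiles is not None:
                    rec.resolution = "resolver"
        if rec.smiles is not None:
            canon = canonical_smiles(rec.smiles)
            rec.canonical_smiles = canon
            if canon is None:
                rec.resolution = "invalid_smiles"
                logger.warning(
                    "invalid SMILES %r on %s rank %d", rec.smiles, rec.source, rec.source_rank
                )
            rec.is_formula_only = False
        elif rec.formula is not None:
            rec.is_formula_only = True
            rec.resolution = rec.resolution or "unresolved"
        else:
            rec.resolution = rec.resolution or "unresolved"
    return records


def apply_formula_fallback(records: list[CandidateRecord]) -> list[CandidateRecord]:
    """Keep formula-only rows of a compound-annotator group only as fallback.

    Within each (feature, SIRIUS) group: when at least one structure
    candidate exists, formula-only rows are dropped; when none does, the
    formula-only rows are admitted as the candidates. Spectral-source
    groups pass through untouched.
    """
    out: list[CandidateRecord] = []
    sirius_groups: dict[str, list[CandidateRecord]] = {}
    for rec in records:
        if rec.source == "SIRIUS":
            sirius_groups.setdefault(rec.feature_id, []).append(rec)
        else:
            out.append(rec)
    for group in sirius_groups.values():
        has_structure = any(not r.is_formula_only for r in group)
        if has_structure:
            out.extend(r for r in group if not r.is_formula_only)
        else:
            out.extend(group)
    return out


def filter_spectral_candidates(matches: Iterable[SpectralMatch]) -> list[CandidateRecord]:
    """Turn spectral matches that passed both gates into candidate records.

    Only matches passing the per-source similarity threshold *and* the
    conjunctive 0.50 post-filter survive. Ranks are dense per source in
    similarity order.
    """
    per_source: dict[tuple[str, str], list[SpectralMatch]] = {}
    for m in matches:
        if m.passed_similarity_threshold and m.passed_postfilter:
            per_source.setdefault((m.query_feature_id, m.library_source), []).append(m)
    records: list[CandidateRecord] = []
    for (feature_id, source), group in sorted(per_source.items()):
        group.sort(key=lambda m: (-m.similarity, -m.n_matched, m.library_accession))
        for rank, m in enumerate(group, start=1):
            records.append(
                CandidateRecord(
                    feature_id=feature_id,
                    source=source,
                    source_rank=rank,
                    source_score=m.similarity,
                    smiles=m.candidate_smiles,
                    name=m.candidate_name,
                    accession=m.library_accession,
                    is_formula_only=False,
                )
            )
    return records
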