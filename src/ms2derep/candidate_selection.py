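"""Multi-source candidate consolidation, final pick and MSI-level assignment.

Top candidates from up to four sources (GNPS, SIRIUS, HMDB, MassBank) are
merged and compared pairwise by Tanimoto similarity on circular (Morgan
radius-2, 2048-bit) fingerprints:

* at ≥ 0.85 a chemical similarity network is built — candidates similar to
  nothing else are discarded, the rest become nodes labelled
  ``{G,S,H,M}_<rank>``, with the maximum common substructure (MCSS)
  attached to every edge — exported as a Cytoscape-importable TSV;
* at ≥ 0.99 single-linkage *identity clusters* are formed; a cluster backed
  by more sources outranks one backed by fewer, and among single-source
  clusters GNPS > SIRIUS > MassBank = HMDB. The representative of the top
  cluster is the feature's final candidate.

Each feature then receives a Metabolomics Standards Initiative (MSI)
confidence level: 1 when the pick matches a user-supplied standard, 2 when
it is backed by a spectral database or by more than one source, 3 for a
compound-annotator-only structure and/or a chemical class prediction, 4
for formula-only annotations, 5 for bare MS2 features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFMCS, rdFingerprintGenerator

from ms2derep.compound_results import CandidateRecord, canonical_smiles
from ms2derep.spectra_io import Standard

logger = logging.getLogger(__name__)

DEFAULT_SIMILARITY_THRESHOLD = 0.85
DEFAULT_IDENTITY_THRESHOLD = 0.99
DEFAULT_TOP_N = 25
DEFAULT_MCSS_TIMEOUT_S = 5

SOURCE_PREFIX = {"GNPS": "G", "SIRIUS": "S", "HMDB": "H", "MassBank": "M"}
#: Lower number = higher priority; MassBank and HMDB are tied at the bottom.
SOURCE_PRIORITY = {"GNPS": 0, "SIRIUS": 1, "MassBank": 2, "HMDB": 2}
SPECTRAL_SOURCES = frozenset({"GNPS", "HMDB", "MassBank"})


@dataclass(frozen=True)
class FingerprintConfig:
    radius: int = 2
    n_bits: int = 2048


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected edge of the chemical similarity network (node_a < node_b)."""

    node_a: str
    node_b: str
    tanimoto: float
    mcss: str | None = None
    mcss_atom_count: int = 0
    source_a: str = ""
    source_b: str = ""
    smiles_a: str = ""
    smiles_b: str = ""


@dataclass
class IdentityCluster:
    """Candidates agreeing on (essentially) one structure across sources."""

    member_records: list[CandidateRecord]
    sources: set[str]
    representative_smiles: str
    priority_key: tuple

    @property
    def source_count(self) -> int:
        return len(self.sources)


@dataclass
class AnnotationEvidence:
    has_standard_match: bool = False
    in_spectral_db: bool = False
    n_agreeing_sources: int = 0
    sirius_structure_only: bool = False
    class_predicted: bool = False
    formula_only: bool = False
    ms2_only: bool = False


@dataclass
class FeatureAnnotation:
    """Consolidated annotation of one feature."""

    feature_id: str
    ranked_candidates: list[CandidateRecord]
    final_candidate: CandidateRecord | None
    msi_level: int
    evidence: AnnotationEvidence


# ---------------------------------------------------------------------------
# Fingerprints and Tanimoto
# ---------------------------------------------------------------------------

def _mol(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def fingerprint(smiles: str, fp: FingerprintConfig = FingerprintConfig()):
    """Morgan bit-vector fingerprint of a SMILES string."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=fp.radius, fpSize=fp.n_bits)
    return gen.GetFingerprint(_mol(smiles))


def tanimoto(
    smiles_a: str, smiles_b: str, fp: FingerprintConfig = FingerprintConfig()
) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B| over Morgan fingerprint bit sets."""
    return float(
        DataStructs.TanimotoSimilarity(fingerprint(smiles_a, fp), fingerprint(smiles_b, fp))
    )


def node_label(record: CandidateRecord) -> str:
    """Network node label ``{G,S,H,M}_<source rank>``."""
    return f"{SOURCE_PREFIX[record.source]}_{record.source_rank}"


def _structure_records(candidates: list[CandidateRecord]) -> list[CandidateRecord]:
    return [c for c in candidates if c.canonical_smiles is not None]


# ---------------------------------------------------------------------------
# Similarity network (threshold 0.85, MCSS edges)
# ---------------------------------------------------------------------------

def mcss(smiles_a: str, smiles_b: str, timeout_s: int = DEFAULT_MCSS_TIMEOUT_S):
    """Maximum common substructure of two molecules.

    Returns ``(smarts, n_atoms)``; smarts is None when the search timed out
    or found nothing (MCSS is NP-hard, so every pair gets a time budget).
    """
    result = rdFMCS.FindMCS([_mol(smiles_a), _mol(smiles_b)], timeout=timeout_s)
    if result.canceled and not result.numAtoms:
        return None, 0
    if result.numAtoms == 0:
        return None, 0
    return result.smartsString, int(result.numAtoms)


def build_similarity_network(
    candidates: list[CandidateRecord],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    compute_mcss: bool = True,
    fp: FingerprintConfig = FingerprintConfig(),
    mcss_timeout_s: int = DEFAULT_MCSS_TIMEOUT_S,
) -> list[SimilarityEdge]:
    """Pairwise similarity network over structure candidates.

    Candidates whose Tanimoto to every other candidate falls below the
    threshold are discarded; an edge is emitted for every remaining pair at
    or above it, optionally labelled with the pair's MCSS. Fewer than two
    structure candidates yield an empty edge list.
    """
    records = _structure_records(candidates)
    if len(records) < 2:
        return []
    fps = [fingerprint(r.canonical_smiles, fp) for r in records]
    edges: list[SimilarityEdge] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            sim = float(DataStructs.TanimotoSimilarity(fps[i], fps[j]))
            if sim < threshold:
                continue
            a, b = records[i], records[j]
            if node_label(a) > node_label(b):
                a, b = b, a
            smarts, n_atoms = (None, 0)
            if compute_mcss:
                smarts, n_atoms = mcss(
                    a.canonical_smiles, b.canonical_smiles, timeout_s=mcss_timeout_s
                )
            edges.append(
                SimilarityEdge(
                    node_a=node_label(a),
                    node_b=node_label(b),
                    tanimoto=sim,
                    mcss=smarts,
                    mcss_atom_count=n_atoms,
                    source_a=a.source,
                    source_b=b.source,
                    smiles_a=a.canonical_smiles,
                    smiles_b=b.canonical_smiles,
                )
            )
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    return edges


def export_cytoscape_tsv(edges: list[SimilarityEdge], path) -> "Path":
    """Write the similarity network as a Cytoscape-importable edge table."""
    from pathlib import Path

    path = Path(path)
    header = (
        "source_node\ttarget_node\ttanimoto\tmcss_smarts\tmcss_atoms"
        "\tsource_a\tsource_b\tsmiles_a\tsmiles_b\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for e in sorted(edges, key=lambda e: (e.node_a, e.node_b)):
            fh.write(
                f"{e.node_a}\t{e.node_b}\t{e.tanimoto!r}\t{e.mcss or ''}\t"
                f"{e.mcss_atom_count}\t{e.source_a}\t{e.source_b}\t"
                f"{e.smiles_a}\t{e.smiles_b}\n"
            )
    return path


def read_cytoscape_tsv(path) -> list[SimilarityEdge]:
    """Re-read an exported edge table (round-trip checks)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SimilarityEdge(
            node_a=row["source_node"],
            node_b=row["target_node"],
            tanimoto=float(row["tanimoto"]),
            mcss=row["mcss_smarts"] or None,
            mcss_atom_count=int(row["mcss_atoms"]),
            source_a=row["source_a"],
            source_b=row["source_b"],
            smiles_a=row["smiles_a"],
            smiles_b=row["smiles_b"],
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Identity clustering (threshold 0.99) and prioritization
# ---------------------------------------------------------------------------

def _member_key(r: CandidateRecord) -> tuple:
    # MassBank and HMDB share a priority; source name breaks that tie
    return (SOURCE_PRIORITY[r.source], r.source_rank, r.source, r.accession or "")


def _best_member(records: list[CandidateRecord]) -> CandidateRecord:
    """Member with the best (source priority, source rank) key."""
    return min(records, key=_member_key)


def cluster_identity(
    candidates: list[CandidateRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    fp: FingerprintConfig = FingerprintConfig(),
) -> list[IdentityCluster]:
    """Single-linkage clusters over the ≥ threshold Tanimoto graph.

    The threshold relation is not transitive, so clusters are the connected
    components of the pairwise graph — order-independent and deterministic.
    The representative is the member from the highest-priority source with
    the best source rank.
    """
    records = _structure_records(candidates)
    if not records:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(range(len(records)))
    fps = [fingerprint(r.canonical_smiles, fp) for r in records]
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if DataStructs.TanimotoSimilarity(fps[i], fps[j]) >= threshold:
                graph.add_edge(i, j)
    clusters = []
    for component in nx.connected_components(graph):
        members = [records[i] for i in sorted(component)]
        best = _best_member(members)
        sources = {m.source for m in members}
        priority_key = (
            len(sources),
            SOURCE_PRIORITY[best.source],
            best.source_rank,
        )
        clusters.append(
            IdentityCluster(
                member_records=members,
                sources=sources,
                representative_smiles=best.canonical_smiles,
                priority_key=priority_key,
            )
        )
    return clusters


def prioritize(clusters: list[IdentityCluster]) -> list[IdentityCluster]:
    """Order clusters by agreement then source priority; assign overall ranks.

    More agreeing sources beat fewer; among equals, GNPS > SIRIUS >
    MassBank = HMDB by the best member's source, then best source rank,
    then representative SMILES (a total, deterministic order). Members get
    dense overall ranks in cluster order; within a cluster members are
    ordered by source priority then source rank.
    """
    ordered = sorted(
        clusters,
        key=lambda c: (
            -c.priority_key[0],
            c.priority_key[1],
            c.priority_key[2],
            c.representative_smiles,
        ),
    )
    rank = 1
    for cluster in ordered:
        cluster.member_records.sort(key=_member_key)
        for member in cluster.member_records:
            member.overall_rank = rank
            rank += 1
    return ordered


# ---------------------------------------------------------------------------
# Final pick and MSI level
# ---------------------------------------------------------------------------

def _matches_standard(candidate: CandidateRecord, standards: list[Standard]) -> bool:
    for std in standards:
        if std.smiles:
            canon = canonical_smiles(std.smiles)
            if canon is not None and canon == candidate.canonical_smiles:
                return True
        elif candidate.name and std.name.strip().lower() == candidate.name.strip().lower():
            return True
    return False


def assign_msi_level(evidence: AnnotationEvidence) -> int:
    """Map evidence flags to an MSI confidence level (1 best … 5 worst)."""
    if evidence.has_standard_match:
        return 1
    if evidence.in_spectral_db or evidence.n_agreeing_sources > 1:
        return 2
    if evidence.sirius_structure_only or evidence.class_predicted:
        return 3
    if evidence.formula_only:
        return 4
    return 5


def select_final(
    feature_id: str,
    ordered_clusters: list[IdentityCluster],
    all_records: list[CandidateRecord],
    standards: list[Standard] | None = None,
) -> FeatureAnnotation:
    """Pick the final candidate from prioritized clusters and grade it.

    The representative of the highest-priority cluster becomes the final
    candidate; with no structure candidates at all, a formula-only record
    (if any) is surfaced and the annotation is graded formula-only.
    """
    standards = standards or []
    ranked = [m for c in ordered_clusters for m in c.member_records]
    evidence = AnnotationEvidence()
    final: CandidateRecord | None = None

    if ordered_clusters:
        top = ordered_clusters[0]
        final = _best_member(top.member_records)
        evidence.n_agreeing_sources = top.source_count
        evidence.in_spectral_db = bool(top.sources & SPECTRAL_SOURCES)
        evidence.sirius_structure_only = top.sources == {"SIRIUS"}
        evidence.class_predicted = any(
            m.compound_class for m in top.member_records
        )
        evidence.has_standard_match = any(
            _matches_standard(m, standards) for m in top.member_records
        )
    else:
        formula_records = [r for r in all_records if r.is_formula_only]
        if formula_records:
            evidence.formula_only = True
            evidence.class_predicted = any(r.compound_class for r in formula_records)
            ranked = sorted(
                formula_records,
                key=lambda r: (SOURCE_PRIORITY[r.source], r.source_rank),
            )
            for i, r in enumerate(ranked, 1):
                r.overall_rank = i
        else:
            evidence.ms2_only = True

    return FeatureAnnotation(
        feature_id=feature_id,
        ranked_candidates=ranked,
        final_candidate=final,
        msi_level=assign_msi_level(evidence),
        evidence=evidence,
    )


def annotate_feature(
    feature_id: str,
    records: list[CandidateRecord],
    standards: list[Standard] | None = None,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    top_n: int = DEFAULT_TOP_N,
    fp: FingerprintConfig = FingerprintConfig(),
) -> FeatureAnnotation:
    """Run the full selection for one feature: cluster, prioritize, pick.

    Only the top ``top_n`` candidates per source (by source rank) enter the
    similarity mathematics; formula-only records participate only in the
    formula fallback grading.
    """
    trimmed = [r for r in records if r.source_rank <= top_n]
    clusters = cluster_identity(trimmed, threshold=identity_threshold, fp=fp)
    ordered = prioritize(clusters)
    return select_final(feature_id, ordered, trimmed, standards=standards)
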