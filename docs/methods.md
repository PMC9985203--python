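# Methods

## Scope and model

`ms2derep` annotates LC-MS² features in three stages: (1) spectral-library
dereplication, (2) candidate post-processing, (3) multi-source candidate
selection with MSI confidence grading. The package assumes centroided DDA
data with singly charged small-molecule precursors; when an mzML scan
carries no charge state, charge ±1 is inferred from scan polarity.

### Feature enumeration

MS² scans are grouped into features by precursor m/z: scans are sorted and
clustered greedily, a scan joining the open group while it lies within the
precursor tolerance (default 15 ppm) of the group's running mean. The
median retention time uses the lower middle value on even counts so that
repeated runs cannot disagree by floating tie-breaks. Feature IDs embed the
*truncated* integer precursor m/z and retention time
(`file_1M287R318ID319` for 287.065 m/z at 318.265 s); truncation rather
than rounding keeps the ID stable under sub-0.5 jitter of the mass. A
feature may own several MS² scans; each scan is scored separately against
a library entry and the best-scoring scan is reported (no consensus
spectrum is built — merging scans averages away peak-intensity structure
that int_score is designed to test).

### Spectrum conditioning

Intensities are rescaled so the base peak is 100 and peaks below
`min_rel_intensity` (default 0.05, i.e. 5% of base) are removed. The floor
is relative to the base peak: that choice makes the operation idempotent
and puts intensities on the 0–100 scale that the intensity-agreement score
divides by. The same transform is applied to query and library spectra so
both sides of a comparison are conditioned identically.

### Peak matching

A query peak i and library peak j are an admissible pair when
|mz_q − mz_d| ≤ tol, or — for shift-aware (GNPS-style) matching — when
|(mz_q − mz_d) − (prec_q − prec_d)| ≤ tol. The tolerance is ppm relative
to the **query** fragment m/z; anchoring to one side keeps the relation
asymmetric but deterministic. Admissible pairs are consumed greedily in
descending order of intensity product, ties broken by smaller m/z residual,
then lower query index, then lower library index; each peak is used at most
once. Greedy selection is the field's standard (it is what cosine-greedy
implementations do); the test suite verifies it against an exhaustive
optimal-assignment search on spectra up to 8 peaks, where tolerance windows
are narrow enough that the two coincide.

### Scores

* cosine = Σ_pairs I_q·I_d / (‖I_q‖·‖I_d‖) over the *full* intensity
  vectors, so unmatched peaks dilute the score; with the shift clause this
  is the modified-cosine score.
* mz_score, default **dice** mode: 2·n_matched/(n_q + n_d). The literal
  published formula (kept as mode `printed`, n_matched/(n_q + n_matched))
  mixes total query peaks with matched database peaks in its denominator
  and cannot exceed 0.5 — which would make a 0.50 pass threshold
  unsatisfiable. The Dice form preserves the intent (matched fraction of
  both peak sets) while making the threshold meaningful; both modes are
  implemented and tested, and the mode is a config key.
* int_score = mean over pairs of (1 − |I_q − I_d|/100). Undefined at zero
  matched pairs; it then returns 0 (and the post-filter fails) rather than
  raising, so one empty comparison cannot abort a batch.
* matching ratio = n_matched / n_q.

Similarity gates are per source: 0.85 for GNPS (shift-aware cosine), 0.70
for HMDB and MassBank (direct cosine). Matches at or above the gate are
reported; the conjunctive post-filter flag additionally requires mz_score,
int_score and matching ratio all ≥ 0.50, and only flagged matches become
selection candidates. Ties in the reported order break by matched-peak
count, then accession.

### Candidate post-processing

Spectral-library names are stripped of decoration ("Spectral Match to X
from NIST14", trailing adduct tags, control characters) by an ordered,
configurable regex list applied to a fixed point. Missing SMILES are filled
from an SDF structure map by accession (the HMDB path), then optionally
from a pluggable name→SMILES resolver; the resolver is **off by default**
and its exceptions are logged, never raised, so offline runs and network
failures cannot abort processing. All SMILES are canonicalized with RDKit;
unparsable ones are flagged, not dropped. For compound-annotator output,
formula-only rows are kept only when a (feature, source) group has no
structure candidate at all — the formula fallback. Annotator scores are
treated as opaque ordering (no threshold is applied to them).

### Candidate selection

Structure candidates (top 25 per source by default) are compared pairwise
by Tanimoto similarity over Morgan radius-2, 2048-bit fingerprints — the
de-facto community default; radius and width are config keys. Two
thresholds drive two artifacts:

* **Similarity network (≥ 0.85).** Candidates similar to nothing else are
  discarded; each remaining pair at or above threshold becomes an edge
  labelled with its Tanimoto value and the pair's maximum common
  substructure (SMARTS and heavy-atom count). MCSS search is NP-hard, so
  each pair gets a timeout (default 5 s); on timeout the edge keeps its
  Tanimoto but no substructure. Node labels are `{G,S,H,M}_<rank>` by
  source and source rank. The network is exported as a deterministic,
  Cytoscape-importable TSV.
* **Identity clusters (≥ 0.99).** Clusters are the connected components of
  the pairwise graph (single linkage): near-identity is not transitive, so
  components are the only order-independent choice. Clusters are ranked by
  number of agreeing sources, then source priority GNPS > SIRIUS >
  MassBank = HMDB, then best source rank, then representative SMILES; the
  MassBank/HMDB tie, when everything else is equal, breaks alphabetically.
  Members receive dense overall ranks in cluster order. The representative
  of the top cluster is the final candidate; no minimum source count is
  imposed.

### MSI levels

Evidence flags map to levels in strict precedence: 1 when the final
candidate matches a user standard (canonical-SMILES equality, falling back
to case-insensitive name equality when the standard has no structure); 2
when it is backed by a spectral database or by more than one source; 3 for
an annotator-only structure and/or a chemical class prediction; 4 for
formula-only annotations; 5 for a bare MS² feature. The precedence makes
the level monotone: additional agreeing evidence can only improve it.

## Synthetic data

The generator emulates the study conditions the pipeline is meant for:
libraries of real structures (a packaged catalog of ~110 public-domain
SMILES) with random-fragment spectra (uniform m/z in [50, precursor−10],
intensities uniform in [10, 100], 5–12 peaks), and queries derived from
library spectra by uniform m/z jitter (default 5 ppm), multiplicative
intensity noise (clipped normal, CV 0.1), 10% peak dropout (the base peak
is never dropped, anchoring normalization), and 2 decoy peaks at 10–50% of
base intensity. Fragment m/z values are *not* chemistry-derived: the
fixtures exercise the matching and selection mathematics, so passing tests
demonstrate correctness of the algorithms, not annotation accuracy on real
fragmentation patterns, collision-energy effects, adducts or co-isolation.
Candidate-table scenarios (three sources agreeing, two against a rival,
four singletons, formula-only, standards hit) are fixed compound patterns
whose correct consolidated output is computed by hand and emitted beside
the tables.

All randomness flows from one integer seed through `numpy`'s Generator;
outputs are byte-deterministic for a fixed seed.

## Numerical choices and degenerate inputs

* ppm windows are always evaluated against the query-side value.
* Normalization errors on all-zero spectra; matching errors on
  unnormalized input (base peak ≠ 100) instead of silently rescaling.
* Zero matched pairs: cosine and both mz_score modes return 0; int_score
  returns 0 with the post-filter failing.
* `.ms` files are written with Python float `repr` (shortest round-trip
  representation), giving byte-identical output across runs and platforms.
* Sparse candidate ranks (1,2,4) are re-densified with a logged warning;
  rows lacking both SMILES and formula are rejected, also logged.
* Problem sizes in the shipped tests — 8-peak oracles, 50-compound
  recovery benchmark, 10–20-compound I/O fixtures — were chosen as the
  smallest sizes at which every code path (shift clause, dropout, decoys,
  merged isobaric features) is actually exercised.

## Known limitations

* mzML support covers centroided spectra with the usual cvParam layout
  (float32/64, zlib or uncompressed); exotic encodings (numpress) are not
  read. Profile-mode MS² scans are rejected with a warning.
* One query spectrum per feature per comparison; no consensus merging.
* Isobaric compounds within the precursor tolerance merge into one
  feature, so at most one of them can rank first (visible in the recovery
  benchmark, where two catalog isomers share a feature).
* The remote name resolver interface is deliberately unimplemented beyond
  the plug point; shipped behavior is fully offline.
* MCSS timeouts leave edges without substructure labels rather than
  blocking the run.
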