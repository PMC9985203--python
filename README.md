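# ms2derep

Spectral dereplication and multi-source candidate selection for LC-MS²
metabolomics.

Untargeted tandem-MS experiments yield thousands of fragmentation spectra
whose compounds are mostly unknown. The fastest route to an annotation is
*dereplication*: matching each measured MS² spectrum against libraries of
reference spectra (GNPS, HMDB, MassBank), complemented by compound-database
annotators such as SIRIUS whose structure/formula candidates arrive as
ranked tables. `ms2derep` implements that pipeline end to end for
computational metabolomics researchers: spectrum conditioning, library
search with peak-level quality scores, post-processing of all candidate
sources, and a deterministic algorithm that consolidates the sources into a
single annotation per feature with a Metabolomics Standards Initiative
(MSI) confidence level.

## Scoring model

Query and library spectra are rescaled to base peak 100 and peaks below 5%
of base are dropped. Fragment peaks are paired 1:1 within a 15 ppm window;
for GNPS-style libraries a pair may also match after shifting by the
precursor mass difference Δ = prec_q − prec_d (modified cosine). Each
comparison yields:

- **cosine** = Σ I_q·I_d over matched pairs / (‖I_q‖·‖I_d‖), gated per
  source (GNPS ≥ 0.85, HMDB/MassBank ≥ 0.70);
- **mz_score** = 2·n_matched / (n_q + n_d) (Sørensen–Dice over peak
  counts; an alternative `printed` mode n_matched/(n_q + n_matched) is
  also available);
- **int_score** = (1/n_matched) Σ (1 − |I_q − I_d|/100);
- **matching ratio** = n_matched / n_q.

A match additionally passes a conjunctive post-filter only when mz_score,
int_score and the matching ratio are all ≥ 0.50.

Candidates surviving both gates, plus annotator candidates read from TSV,
are compared pairwise by Tanimoto similarity on Morgan (radius 2, 2048-bit)
fingerprints: at ≥ 0.85 a chemical similarity network with maximum-common-
substructure edge labels is exported for Cytoscape; at ≥ 0.99 single-linkage
identity clusters are ranked — more agreeing sources beat fewer, and among
single-source clusters GNPS > SIRIUS > MassBank = HMDB. The top cluster's
representative becomes the final candidate, graded MSI 1 (user standard
matched) through 5 (bare MS² feature).

## Worked example

Everything below runs offline from a seeded synthetic fixture: a
20-compound spectral library with known structures, plus one noised query
per compound.

```bash
ms2derep simulate library --n-compounds 20 --seed 42 --out-dir lib
ms2derep simulate queries --library lib/library.msp --seed 42 --out-dir q
ms2derep run --queries q/queries.mgf --library GNPS=lib/library.msp --out-dir results
```

which prints

```
wrote lib/library.msp and lib/structures.sdf
wrote q/queries.mgf (20 queries)
annotated 20 features -> results/annotations.tsv
```

and the first lines of `results/annotations.tsv` are

```
feature_id         msi_level  final_name    final_smiles      final_formula  final_source
file_1M105R175ID1  2          Choline       C[N+](C)(C)CCO                   GNPS
file_1M123R184ID2  2          Benzoic acid  O=C(O)c1ccccc1                   GNPS
```

Feature IDs encode the truncated precursor m/z (`M105`), the truncated
median retention time in seconds (`R175`) and a running index. Every
feature here reaches MSI level 2 because its spectrum matched a spectral
library; `results/<feature_id>/` holds the per-source match tables and the
similarity-network TSV for each feature, and `run_config.json` records the
effective thresholds.

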