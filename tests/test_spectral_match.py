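"""Scoring engine: peak pairing, cosine, mz/int scores, threshold gates."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ms2derep.preprocess import normalize_and_filter
from ms2derep.spectra_io import LibraryEntry
from ms2derep.spectral_match import (
    MatchConfig,
    cosine_score,
    dereplicate_feature,
    int_score,
    match_peaks,
    matching_ratio,
    mz_score,
    score_pair,
)
from ms2derep.preprocess import Feature

from conftest import make_entry, make_spectrum


def brute_force_best_pairing(query, library, ppm_tol, allow_shift=False):
    """Exhaustive search for the 1:1 pairing maximizing Σ I_q·I_d.

    Independent of the greedy matcher: enumerates every admissible pair
    subset that forms a matching. Returns (best product sum, pair count).
    """
    shift = query.precursor_mz - library.precursor_mz
    admissible = []
    for i, qmz in enumerate(query.mz):
        tol = ppm_tol * qmz * 1e-6
        for j, dmz in enumerate(library.mz):
            if abs(qmz - dmz) <= tol or (allow_shift and abs((qmz - dmz) - shift) <= tol):
                admissible.append((i, j))
    best = (0.0, 0)
    for r in range(len(admissible), 0, -1):
        for combo in itertools.combinations(admissible, r):
            qs = [i for i, _ in combo]
            ds = [j for _, j in combo]
            if len(set(qs)) < len(qs) or len(set(ds)) < len(ds):
                continue
            total = math.fsum(
                sorted(query.intensities[i] * library.intensities[j] for i, j in combo)
            )
            best = max(best, (total, len(combo)))
    return best


def _noised_pair(rng, n_peaks):
    """A library spectrum and a jittered copy, both normalized."""
    mz = np.sort(rng.uniform(60, 280, size=n_peaks))
    intens = rng.uniform(10, 100, size=n_peaks)
    lib = normalize_and_filter(make_spectrum(list(zip(mz, intens)), precursor_mz=300.0))
    jmz = lib.mz * (1 + rng.uniform(-5, 5, size=lib.mz.size) * 1e-6)
    jint = np.clip(lib.intensities * (1 + rng.normal(0, 0.1, size=lib.mz.size)), 1, None)
    query = normalize_and_filter(
        make_spectrum(list(zip(jmz, jint)), precursor_mz=300.0)
    )
    return query, lib


class TestPeakMatching:
    def test_identity_matches_all_peaks_unshifted(self):
        spec = normalize_and_filter(
            make_spectrum([(100, 50), (120, 100), (150, 30), (180, 80), (200, 60)])
        )
        matching = match_peaks(spec, spec, ppm_tol=15)
        assert matching.n_matched == 5
        assert not any(p.shifted for p in matching.pairs)
        assert all(p.query_index == p.library_index for p in matching.pairs)

    def test_disjoint_spectra_give_no_pairs(self):
        a = normalize_and_filter(make_spectrum([(100, 100), (150, 50)]))
        b = normalize_and_filter(
            make_spectrum([(110, 100), (160, 50)], precursor_mz=300.0)
        )
        matching = match_peaks(a, b, ppm_tol=15, allow_precursor_shift=True)
        assert matching.n_matched == 0

    def test_precursor_shift_clause_admits_offset_fragment(self):
        # neutral-loss shift: query precursor 304.123 vs library 288.107,
        # fragment offset by the same Δ=16.016 matches only via the shift
        query = normalize_and_filter(
            make_spectrum([(136.096, 100)], precursor_mz=304.123)
        )
        lib = normalize_and_filter(
            make_spectrum([(120.080, 100)], precursor_mz=288.107)
        )
        direct = match_peaks(query, lib, ppm_tol=15, allow_precursor_shift=False)
        assert direct.n_matched == 0
        shifted = match_peaks(query, lib, ppm_tol=15, allow_precursor_shift=True)
        assert shifted.n_matched == 1
        assert shifted.pairs[0].shifted

    def test_unnormalized_input_rejected(self):
        raw = make_spectrum([(100, 55), (150, 70)])
        with pytest.raises(ValueError, match="not normalized"):
            match_peaks(raw, raw)

    def test_matching_is_one_to_one(self):
        # two query peaks near one library peak: only one may claim it
        query = normalize_and_filter(
            make_spectrum([(100.0000, 100), (100.0005, 90)], precursor_mz=300.0)
        )
        lib = normalize_and_filter(make_spectrum([(100.0001, 100)], precursor_mz=300.0))
        matching = match_peaks(query, lib, ppm_tol=15)
        assert matching.n_matched == 1
        assert matching.pairs[0].query_index == 0  # higher intensity product wins

    @pytest.mark.parametrize("n_peaks", [3, 5, 8])
    @pytest.mark.parametrize("allow_shift", [False, True])
    def test_greedy_equals_brute_force_on_noised_pairs(self, n_peaks, allow_shift):
        rng = np.random.default_rng(2024 + n_peaks)
        for _ in range(8):
            query, lib = _noised_pair(rng, n_peaks)
            matching = match_peaks(
                query, lib, ppm_tol=15, allow_precursor_shift=allow_shift
            )
            greedy_total = math.fsum(
                sorted(p.query_intensity * p.library_intensity for p in matching.pairs)
            )
            best_total, best_count = brute_force_best_pairing(
                query, lib, 15, allow_shift
            )
            assert greedy_total == pytest.approx(best_total, abs=1e-12)
            assert matching.n_matched == best_count


class TestScores:
    def test_identical_spectra_forced_values(self):
        spec = normalize_and_filter(
            make_spectrum([(100, 20), (120, 100), (150, 40), (170, 60), (200, 80), (250, 30)])
        )
        matching = match_peaks(spec, spec)
        assert cosine_score(matching) == pytest.approx(1.0, abs=1e-12)
        assert int_score(matching) == pytest.approx(1.0, abs=1e-12)
        assert mz_score(matching, "dice") == pytest.approx(1.0, abs=1e-12)
        assert mz_score(matching, "printed") == pytest.approx(0.5, abs=1e-12)
        assert matching_ratio(matching) == pytest.approx(1.0)

    def test_disjoint_spectra_all_zero(self):
        a = normalize_and_filter(make_spectrum([(100, 100), (150, 50)]))
        b = normalize_and_filter(make_spectrum([(110, 100), (160, 50)]))
        matching = match_peaks(a, b)
        assert cosine_score(matching) == 0.0
        assert int_score(matching) == 0.0
        assert mz_score(matching, "dice") == 0.0
        assert mz_score(matching, "printed") == 0.0
        assert matching_ratio(matching) == 0.0

    def test_cosine_hand_computed_partial_overlap(self):
        # query [(100,100),(200,50)], library [(100,100),(300,50)]:
        # one pair (100↔100) → 10000 / (√12500·√12500) = 0.8
        q = normalize_and_filter(make_spectrum([(100, 100), (200, 50)]))
        d = normalize_and_filter(make_spectrum([(100, 100), (300, 50)]))
        matching = match_peaks(q, d)
        assert matching.n_matched == 1
        assert cosine_score(matching) == pytest.approx(0.8, abs=1e-12)

    def test_mz_score_arithmetic_both_modes(self):
        # n_q=4, n_d=6, matched=3 → dice 0.6, printed 3/7
        rng = np.random.default_rng(5)
        shared = [100.0, 150.0, 200.0]
        q = normalize_and_filter(
            make_spectrum([(m, 80) for m in shared] + [(250.0, 100)])
        )
        d = normalize_and_filter(
            make_spectrum([(m, 70) for m in shared] + [(300.0, 100), (350.0, 40), (400.0, 30)])
        )
        matching = match_peaks(q, d)
        assert matching.n_q == 4 and matching.n_d_total == 6 and matching.n_matched == 3
        assert mz_score(matching, "dice") == pytest.approx(0.6, abs=1e-12)
        assert mz_score(matching, "printed") == pytest.approx(3 / 7, abs=1e-12)

    def test_int_score_mean_of_intensity_differences(self):
        # pairs with |ΔI| 10 and 20 → ((1−0.1)+(1−0.2))/2 = 0.85
        q = normalize_and_filter(make_spectrum([(100, 100), (150, 80)]))
        d = normalize_and_filter(make_spectrum([(100, 90), (150, 100)]))
        matching = match_peaks(q, d)
        # after normalization: q=(100,80), d=(90,100) → diffs 10 and 20
        assert int_score(matching) == pytest.approx(0.85, abs=1e-12)

    def test_single_pair_with_maximal_difference_scores_zero(self):
        q = normalize_and_filter(make_spectrum([(100, 100), (150.0, 1e-9 + 5)]))
        # force a pair with intensities 100 vs ~0 via constructed matching
        from ms2derep.spectral_match import MatchedPair, PeakMatching

        matching = PeakMatching(
            pairs=[
                MatchedPair(0, 0, 100.0, 100.0, 100.0, 0.0, False),
            ],
            query_intensities=np.array([100.0]),
            library_intensities=np.array([100.0]),
            ppm_tol=15,
        )
        assert int_score(matching) == pytest.approx(0.0, abs=1e-12)

    def test_matching_ratio_three_of_four(self):
        q = normalize_and_filter(
            make_spectrum([(100, 50), (150, 60), (200, 70), (250, 100)])
        )
        d = normalize_and_filter(make_spectrum([(100, 50), (150, 60), (200, 70)]))
        matching = match_peaks(q, d)
        assert matching_ratio(matching) == pytest.approx(0.75)

    def test_cross_check_against_matchms_cosine(self):
        """Dual-route check: our cosine vs matchms CosineGreedy on random pairs."""
        import matchms
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(99)
        for _ in range(5):
            query, lib = _noised_pair(rng, 6)
            matching = match_peaks(query, lib, ppm_tol=15)
            ours = cosine_score(matching)
            ms_q = matchms.Spectrum(
                mz=query.mz, intensities=query.intensities,
                metadata={"precursor_mz": query.precursor_mz},
                metadata_harmonization=False,
            )
            ms_d = matchms.Spectrum(
                mz=lib.mz, intensities=lib.intensities,
                metadata={"precursor_mz": lib.precursor_mz},
                metadata_harmonization=False,
            )
            theirs = float(CosineGreedy(tolerance=0.01).pair(ms_q, ms_d)["score"])
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestScoreProperties:
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=50, max_value=500),
                st.floats(min_value=1, max_value=100),
            ),
            min_size=1,
            max_size=10,
            unique_by=lambda p: round(p[0], 1),
        ),
        st.lists(
            st.tuples(
                st.floats(min_value=50, max_value=500),
                st.floats(min_value=1, max_value=100),
            ),
            min_size=1,
            max_size=10,
            unique_by=lambda p: round(p[0], 1),
        ),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_score_ranges(self, peaks_a, peaks_b):
        a = normalize_and_filter(make_spectrum(peaks_a, precursor_mz=510.0))
        b = normalize_and_filter(make_spectrum(peaks_b, precursor_mz=510.0))
        matching = match_peaks(a, b, ppm_tol=20, allow_precursor_shift=True)
        assert 0.0 <= cosine_score(matching) <= 1.0 + 1e-12
        assert 0.0 <= mz_score(matching, "dice") <= 1.0
        assert 0.0 <= mz_score(matching, "printed") <= 0.5
        assert 0.0 <= int_score(matching) <= 1.0
        assert matching_ratio(matching) >= 0.0

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=50, max_value=500),
                st.floats(min_value=1, max_value=100),
            ),
            min_size=1,
            max_size=8,
            unique_by=lambda p: round(p[0], 1),
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_cosine_symmetric_for_equal_precursors(self, peaks):
        a = normalize_and_filter(make_spectrum(peaks, precursor_mz=510.0))
        shuffled = list(reversed(peaks))
        b = normalize_and_filter(make_spectrum(shuffled, precursor_mz=510.0))
        ab = cosine_score(match_peaks(a, b, ppm_tol=15))
        ba = cosine_score(match_peaks(b, a, ppm_tol=15))
        assert ab == pytest.approx(ba, abs=1e-12)


class TestDereplicateFeature:
    def _feature(self, spec, feature_id="file_1M300R100ID1"):
        return Feature(
            feature_id=feature_id,
            file_id="file_1",
            precursor_mz=spec.precursor_mz,
            median_rt=spec.retention_time,
            spectra=[spec],
        )

    def test_self_match_ranks_first_and_passes(self):
        peaks = [(100, 40), (140, 100), (180, 60), (220, 85)]
        entry = make_entry(peaks, 300.0, "GNPS0001", "GNPS", name="compound A")
        decoy = make_entry(
            [(105, 100), (145, 50)], 300.0, "GNPS0002", "GNPS", name="decoy"
        )
        feature = self._feature(make_spectrum(peaks, precursor_mz=300.0))
        matches = dereplicate_feature(feature, {"GNPS": [entry, decoy]})
        assert matches[0].library_accession == "GNPS0001"
        assert matches[0].similarity == pytest.approx(1.0, abs=1e-12)
        assert matches[0].passed_postfilter

    def test_below_threshold_match_excluded(self):
        # library entry sharing only the base peak scores ≈0.63 < 0.70
        entry = make_entry(
            [(140, 100), (400.0, 90), (410.0, 80)], 300.0, "MB0001", "MassBank"
        )
        feature = self._feature(
            make_spectrum([(100, 40), (140, 100), (180, 60)], precursor_mz=300.0)
        )
        match = score_pair(
            normalize_and_filter(feature.spectra[0]), entry, MatchConfig()
        )
        assert match.similarity < 0.70
        matches = dereplicate_feature(feature, {"MassBank": [entry]})
        assert matches == []

    def test_high_cosine_low_ratio_fails_postfilter_only(self):
        # library has many extra peaks: cosine stays high, mz_score dives
        shared = [(100, 100), (150, 90), (200, 80)]
        extras = [(210 + 10 * i, 4.9) for i in range(9)]
        entry = make_entry(shared + extras, 300.0, "GNPS0003", "GNPS")
        feature = self._feature(make_spectrum(shared, precursor_mz=300.0))
        cfg = MatchConfig(min_rel_intensity=0.0)
        matches = dereplicate_feature(feature, {"GNPS": [entry]}, cfg)
        assert len(matches) == 1
        m = matches[0]
        assert m.passed_similarity_threshold
        assert m.mz_score < 0.50 and not m.passed_postfilter

    def test_unknown_source_tag_raises(self):
        feature = self._feature(make_spectrum([(100, 100)], precursor_mz=300.0))
        with pytest.raises(ValueError, match="unknown library source"):
            dereplicate_feature(feature, {"NIST": []})

    def test_gnps_gate_is_085_and_hmdb_is_070(self):
        # construct a pair scoring between the two gates (≈0.78)
        q_peaks = [(100, 100), (150, 80), (200, 60), (250, 40)]
        d_peaks = [(100, 100), (150, 80), (300, 60), (350, 40)]
        feature = self._feature(make_spectrum(q_peaks, precursor_mz=300.0))
        gnps_entry = make_entry(d_peaks, 300.0, "G1", "GNPS")
        hmdb_entry = make_entry(d_peaks, 300.0, "H1", "HMDB")
        sim = score_pair(
            normalize_and_filter(feature.spectra[0]), hmdb_entry, MatchConfig()
        ).similarity
        assert 0.70 <= sim < 0.85
        assert dereplicate_feature(feature, {"GNPS": [gnps_entry]}) == []
        kept = dereplicate_feature(feature, {"HMDB": [hmdb_entry]})
        assert len(kept) == 1 and kept[0].passed_similarity_threshold
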