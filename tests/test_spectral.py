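"""Fragment-ion generation, peak matching, QC criteria, similarity and FDR."""

import itertools
import math

import numpy as np
import pytest
from pyteomics import mass as pyt_mass

from lncpep.digestion import Peptide, ProteomeIndex
from lncpep.errors import InputError, ParameterError
from lncpep.simulate import make_spectrum
from lncpep.spectral import (
    CARBAMIDOMETHYL_DELTA,
    OXIDATION_DELTA,
    PROTON_MASS,
    Ms2Spectrum,
    Psm,
    QcCriterion,
    QcParams,
    filter_by_qvalue,
    high_intensity_purity,
    ion_coverage,
    longest_consecutive_run,
    match_peaks,
    match_report,
    modified_forms,
    peptide_neutral_mass,
    qc_filter,
    spectral_similarity,
    target_decoy_qvalues,
    theoretical_ions,
)

from conftest import random_peptide


def _spectrum(mz, intensity, sid="s1", pmz=500.0, z=2):
    return Ms2Spectrum(spectrum_id=sid, precursor_mz=pmz, precursor_charge=z,
                       mz=np.asarray(mz, float),
                       intensity=np.asarray(intensity, float))


def _psm(peptide, sid="s1", score=10.0, decoy=False):
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    return Psm(spectrum_id=sid, peptide=peptide, charge=2,
               engine_score=score, is_decoy=decoy)


# --- theoretical ions ----------------------------------------------------

def test_ion_count_is_2_l_minus_1():
    ions = theoretical_ions(Peptide("PEPTIDE"), max_frag_charge=1)
    assert len(ions) == 2 * (7 - 1)
    ions2 = theoretical_ions(Peptide("PEPTIDE"), max_frag_charge=2)
    assert len(ions2) == 4 * (7 - 1)


def test_fragment_masses_match_pyteomics(rng):
    for _ in range(30):
        seq = random_peptide(rng, int(rng.integers(6, 20)))
        by_key = {
            (i.series, i.ordinal, i.charge): i.theoretical_mz
            for i in theoretical_ions(Peptide(seq), max_frag_charge=2)
        }
        L = len(seq)
        for z in (1, 2):
            for i in range(1, L):
                expected_b = pyt_mass.fast_mass(seq[:i], ion_type="b", charge=z)
                expected_y = pyt_mass.fast_mass(seq[L - i:], ion_type="y", charge=z)
                assert abs(by_key[("b", i, z)] - expected_b) < 1e-4
                assert abs(by_key[("y", i, z)] - expected_y) < 1e-4


def test_y1_of_tryptic_peptide_is_lysine_plus_water_plus_proton():
    y1 = next(i for i in theoretical_ions(Peptide("GAVLK"))
              if i.series == "y" and i.ordinal == 1)
    assert abs(y1.theoretical_mz - (128.09496 + 18.010565 + PROTON_MASS)) < 1e-5


def test_b_ladder_increases_and_complementarity(rng):
    for _ in range(100):
        seq = random_peptide(rng, int(rng.integers(6, 26)))
        pep = Peptide(seq)
        ions = {(i.series, i.ordinal): i.theoretical_mz
                for i in theoretical_ions(pep)}
        L = len(seq)
        b_ladder = [ions[("b", i)] for i in range(1, L)]
        assert all(a < b for a, b in zip(b_ladder, b_ladder[1:]))
        M = peptide_neutral_mass(pep)
        for i in range(1, L):
            assert abs(ions[("b", i)] + ions[("y", L - i)]
                       - 2 * PROTON_MASS - M) < 1e-6


def test_modification_deltas_shift_ions():
    plain = theoretical_ions(Peptide("ACDK"))
    cam = theoretical_ions(
        Peptide("ACDK", modifications=((2, "Carbamidomethyl",
                                        CARBAMIDOMETHYL_DELTA),))
    )
    plain_b2 = next(i.theoretical_mz for i in plain
                    if i.series == "b" and i.ordinal == 2)
    cam_b2 = next(i.theoretical_mz for i in cam
                  if i.series == "b" and i.ordinal == 2)
    assert abs(cam_b2 - plain_b2 - CARBAMIDOMETHYL_DELTA) < 1e-9
    plain_y1 = next(i.theoretical_mz for i in plain
                    if i.series == "y" and i.ordinal == 1)
    cam_y1 = next(i.theoretical_mz for i in cam
                  if i.series == "y" and i.ordinal == 1)
    assert abs(cam_y1 - plain_y1) < 1e-9  # site 2 is not in y1


def test_unknown_residue_named_in_error():
    with pytest.raises(InputError, match="'B'"):
        theoretical_ions(Peptide("ABK"))


def test_modified_forms_enumeration():
    forms = modified_forms("MCMK", max_oxidations=3)
    # fixed carbamidomethyl always present; 0..2 oxidations over 2 Met sites
    assert len(forms) == 4
    assert all(any(name == "Carbamidomethyl" for _, name, _d in f.modifications)
               for f in forms)


# --- peak matching -------------------------------------------------------

def test_exact_peaks_all_match():
    pep = Peptide("PEPTIDEK")
    ions = theoretical_ions(pep)
    spec = _spectrum([i.theoretical_mz for i in ions], [100.0] * len(ions))
    matches = match_peaks(spec, ions)
    assert len(matches) == len(ions)
    assert all(m.delta_mz == 0.0 for m in matches)


def test_offset_peaks_beyond_tolerance_do_not_match():
    pep = Peptide("PEPTIDEK")
    ions = theoretical_ions(pep)
    spec = _spectrum([i.theoretical_mz + 0.03 for i in ions],
                     [100.0] * len(ions))
    assert match_peaks(spec, ions, tol=0.02) == []


def test_tolerance_must_be_positive():
    spec = _spectrum([100.0], [1.0])
    with pytest.raises(ParameterError):
        match_peaks(spec, theoretical_ions(Peptide("PEK")), tol=0.0)


def oracle_optimal_assignment(spec, ions, tol):
    """Exhaustive one-to-one assignment maximizing matches then minimizing
    total |delta|; tractable for <= 12 ions."""
    candidates = []
    for idx, ion in enumerate(ions):
        opts = [j for j, m in enumerate(spec.mz)
                if abs(m - ion.theoretical_mz) <= tol]
        candidates.append(opts)
    best = (-1, float("inf"), frozenset())
    ion_indices = [i for i, opts in enumerate(candidates) if opts]

    def search(k, used, pairs, total):
        nonlocal best
        if k == len(ion_indices):
            score = (len(pairs), total)
            if (len(pairs) > best[0]
                    or (len(pairs) == best[0] and total < best[1])):
                best = (len(pairs), total,
                        frozenset((i, j) for i, j in pairs))
            return
        i = ion_indices[k]
        search(k + 1, used, pairs, total)
        for j in candidates[i]:
            if j not in used:
                d = abs(spec.mz[j] - ions[i].theoretical_mz)
                search(k + 1, used | {j}, pairs + [(i, j)], total + d)

    search(0, set(), [], 0.0)
    return best[2]


def test_greedy_assignment_equals_exhaustive_on_planted(rng):
    for trial in range(20):
        seq = random_peptide(rng, 6)
        ions = theoretical_ions(Peptide(seq))[:12]
        keep = rng.uniform(size=len(ions)) < 0.7
        mzs = [i.theoretical_mz + rng.normal(0, 0.004)
               for i, k in zip(ions, keep) if k]
        spec = _spectrum(sorted(mzs), [100.0] * len(mzs))
        got = {(m.ion.series, m.ion.ordinal, m.ion.charge)
               for m in match_peaks(spec, ions, tol=0.02)}
        optimal = oracle_optimal_assignment(spec, ions, 0.02)
        expected = {(ions[i].series, ions[i].ordinal, ions[i].charge)
                    for i, _j in optimal}
        assert got == expected


# --- run / coverage / purity --------------------------------------------

@pytest.mark.parametrize(
    "ordinals, expected",
    [({2, 3, 4, 5, 6}, 5), ({1, 3, 5, 7}, 1), (set(), 0), ({4}, 1)],
)
def test_longest_consecutive_run(ordinals, expected):
    assert longest_consecutive_run(ordinals) == expected


def test_longest_run_matches_window_scan(rng):
    for _ in range(100):
        ordinals = set((rng.choice(20, size=int(rng.integers(0, 15)),
                                   replace=False) + 1).tolist())
        best = 0
        for start in range(1, 21):
            length = 0
            while start + length in ordinals:
                length += 1
            best = max(best, length)
        assert longest_consecutive_run(ordinals) == best


def test_ion_coverage_counts_distinct_ordinals():
    full = {("b", i) for i in range(1, 6)} | {("y", i) for i in range(1, 6)}
    assert ion_coverage(full, 6) == 1.0
    assert ion_coverage(set(itertools.islice(sorted(full), 4)), 6) == 0.4


def test_purity_fractions():
    spec = _spectrum(range(100, 112), [float(i) for i in range(12)])
    all_matched = set(range(12))
    assert high_intensity_purity(spec, all_matched, top_n=10) == 0.0
    assert high_intensity_purity(spec, set(), top_n=10) == 1.0


def test_purity_counts_planted_noise_in_top10(rng):
    pep = Peptide("LGEYGFQNALIVR")
    for k in (2, 5):
        spec, truth = make_spectrum(pep, ion_fraction=1.0, n_noise_peaks=k,
                                    seed=7, noise_intensity=1e7)
        report = match_report(spec, pep)
        # noise intensities dwarf the signal, so all k noise peaks sit in
        # the top 10 and none can be matched
        assert report.high_intensity_unmatched_fraction == k / 10


# --- qc_filter -----------------------------------------------------------

def test_complete_ladder_passes_all_criteria():
    pep = Peptide("WAVEFTRMK")
    spec, _ = make_spectrum(pep, ion_fraction=1.0, seed=3,
                            spectrum_id="s1")
    decision, report = qc_filter(_psm(pep), spec, None)
    assert decision.passed
    assert report.by_coverage == 1.0


def test_sparse_ladder_fails_continuity_and_coverage():
    pep = Peptide("WAVEFTRM")  # L=8 -> 14 possible ordinals
    subset = [("b", 1), ("b", 3), ("b", 5), ("y", 2)]
    spec, _ = make_spectrum(pep, ion_subset=subset, seed=4, spectrum_id="s1")
    decision, report = qc_filter(_psm(pep), spec, None)
    assert not decision.passed
    assert QcCriterion.CONTINUITY in decision.failed_criteria
    assert QcCriterion.COVERAGE in decision.failed_criteria
    assert max(report.longest_run_b, report.longest_run_y) == 1
    assert report.by_coverage == pytest.approx(4 / 14)


def test_known_peptide_fails_novelty():
    pep = Peptide("AAAAAAK")
    idx = ProteomeIndex(["CCCAAAAAAKCCC"])
    spec, _ = make_spectrum(pep, ion_fraction=1.0, seed=5, spectrum_id="s1")
    decision, _report = qc_filter(_psm(pep), spec, idx)
    assert decision.failed_criteria == (QcCriterion.KNOWN_PEPTIDE,)


def test_short_peptide_fails_length():
    pep = Peptide("AWGKR")
    spec, _ = make_spectrum(pep, ion_fraction=1.0, seed=6, spectrum_id="s1")
    decision, _ = qc_filter(_psm(pep), spec, None)
    assert QcCriterion.LENGTH in decision.failed_criteria


def test_spectrum_id_mismatch_is_an_error():
    pep = Peptide("WAVEFTRMK")
    spec, _ = make_spectrum(pep, seed=3, spectrum_id="other")
    with pytest.raises(InputError, match="other"):
        qc_filter(_psm(pep, sid="s1"), spec, None)


def test_coverage_monotone_in_tolerance(rng):
    pep = Peptide("LGEYGFQNALIVR")
    spec, _ = make_spectrum(pep, ion_fraction=0.7, n_noise_peaks=10,
                            seed=8, spectrum_id="s1")
    coverages = [
        match_report(spec, pep, QcParams(tol=tol)).by_coverage
        for tol in (0.005, 0.01, 0.02, 0.05)
    ]
    assert coverages == sorted(coverages)


# --- spectral similarity -------------------------------------------------

def test_identical_spectra_score_one():
    spec, _ = make_spectrum(Peptide("WAVEFTRMK"), seed=9)
    assert spectral_similarity(spec, spec) == pytest.approx(1.0)


def test_disjoint_spectra_score_zero():
    a = _spectrum([100.0, 200.0], [5.0, 5.0])
    b = _spectrum([300.0, 400.0], [5.0, 5.0])
    assert spectral_similarity(a, b) == 0.0


def test_similarity_matches_binned_vector_oracle(rng):
    pep = Peptide("LGEYGFQNALIVR")
    a, _ = make_spectrum(pep, seed=10, mz_jitter_sd=0.0)
    jitter = rng.uniform(-0.009, 0.009, size=len(a.mz))
    noise = 1.0 + rng.normal(0, 0.05, size=len(a.mz))
    b = _spectrum(a.mz + jitter, a.intensity * np.abs(noise))
    bin_width = 0.02

    def vec(s):
        d = {}
        for m, i in zip(s.mz, s.intensity):
            d[int(m // bin_width)] = d.get(int(m // bin_width), 0.0) + math.sqrt(i)
        return d

    va, vb = vec(a), vec(b)
    keys = set(va) | set(vb)
    dot = sum(va.get(k, 0.0) * vb.get(k, 0.0) for k in keys)
    expected = dot / math.sqrt(
        sum(v * v for v in va.values()) * sum(v * v for v in vb.values())
    )
    assert spectral_similarity(a, b, bin_width) == pytest.approx(expected)


def test_high_similarity_for_jittered_copy():
    pep = Peptide("LGEYGFQNALIVR")
    a, _ = make_spectrum(pep, seed=11, mz_jitter_sd=0.0)
    b, _ = make_spectrum(pep, seed=12, mz_jitter_sd=0.005)
    assert spectral_similarity(a, b, bin_width=0.02) > 0.7


# --- target-decoy FDR ----------------------------------------------------

def test_targets_above_all_decoys_have_q_zero():
    psms = [_psm("AAAAAK", sid=f"t{i}", score=100 - i) for i in range(5)]
    psms += [_psm("CCCCCK", sid=f"d{i}", score=10 - i, decoy=True)
             for i in range(3)]
    scored = target_decoy_qvalues(psms)
    assert all(p.q_value == 0.0 for p in scored if not p.is_decoy)


def test_qvalues_match_hand_enumeration():
    # ranked: T T D T T D D T T D with scores 10..1
    flags = [False, False, True, False, False, True, True, False, False, True]
    psms = [_psm("AAAAAK", sid=f"p{i}", score=10 - i, decoy=d)
            for i, d in enumerate(flags)]
    scored = target_decoy_qvalues(psms)
    # FDR after each rank: 0/1,0/2,1/2,1/3,1/4,2/4,3/4,3/5,3/6,4/6
    # q = running min from bottom
    expected_fdr = [0, 0, 1 / 2, 1 / 3, 1 / 4, 2 / 4, 3 / 4, 3 / 5, 3 / 6, 4 / 6]
    expected_q = []
    running = float("inf")
    for f in reversed(expected_fdr):
        running = min(running, f)
        expected_q.append(running)
    expected_q.reverse()
    assert [p.q_value for p in scored] == pytest.approx(expected_q)


def test_qvalues_non_increasing_with_score():
    rng = np.random.default_rng(13)
    psms = [_psm("AAAAAK", sid=f"p{i}", score=float(rng.normal()),
                 decoy=bool(rng.integers(0, 2)))
            for i in range(50)]
    psms[0] = _psm("AAAAAK", sid="force-target", score=99.0)
    scored = target_decoy_qvalues(psms)
    qs = [p.q_value for p in scored]
    assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))


def test_retained_set_is_score_prefix():
    rng = np.random.default_rng(14)
    psms = [_psm("AAAAAK", sid=f"t{i}", score=float(100 - i)) for i in range(30)]
    psms += [_psm("CCCCCK", sid=f"d{i}", score=float(rng.uniform(0, 50)),
                  decoy=True) for i in range(10)]
    kept = filter_by_qvalue(psms, threshold=0.01)
    kept_scores = [p.engine_score for p in kept]
    all_target_scores = sorted((p.engine_score for p in psms
                                if not p.is_decoy), reverse=True)
    assert kept_scores == all_target_scores[: len(kept_scores)]


def test_all_decoys_is_an_error():
    with pytest.raises(InputError):
        target_decoy_qvalues([_psm("AAAAAK", decoy=True)])
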