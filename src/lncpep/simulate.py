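"""Deterministic synthetic data with planted ground truth for every stage.

Three generators emulate the statistical structure the pipeline assumes,
so that database construction, spectrum QC and cohort comparison are all
testable without any external download:

* :func:`make_transcripts` — random lncRNA-like transcripts with smORFs of
  each start class planted at known strand/frame/coordinates;
* :func:`make_spectrum` — an MS2 spectrum rendering a chosen subset of a
  peptide's b/y ladder with small m/z jitter plus well-separated noise peaks;
* :func:`make_cohort` — a two-group label-free cohort with a shared
  microprotein core, group-specific microproteins (emulating group-level
  presence/absence divergence) and per-sample Bernoulli detection.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .orfdb import (
    NEAR_COGNATE_CODONS,
    STOP_CODONS,
    SmOrf,
    StartClass,
    Transcript,
    find_stop_to_stop_orfs,
    reverse_complement,
    translate_frame,
)
from .quantify import DetectionMatrix
from .spectral import PROTON_MASS, Peptide, peptide_neutral_mass, theoretical_ions
from .spectral import Ms2Spectrum

__all__ = [
    "PlantedOrf",
    "TranscriptGroundTruth",
    "SpectrumGroundTruth",
    "CohortGroundTruth",
    "make_transcripts",
    "make_spectrum",
    "make_cohort",
]

_SENSE_CODONS = sorted(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)
_STOPS = sorted(STOP_CODONS)
_NEAR = sorted(NEAR_COGNATE_CODONS)
_UNKNOWN_STARTS = sorted(
    set(_SENSE_CODONS) - NEAR_COGNATE_CODONS - {"ATG"}
)


@dataclass(frozen=True)
class PlantedOrf:
    """Ground truth for one planted smORF (strand-oriented coordinates)."""

    transcript_accession: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    start_class: StartClass
    aa_seq: str


@dataclass(frozen=True)
class TranscriptGroundTruth:
    planted: tuple[PlantedOrf, ...]
    seed: int

    def by_id(self) -> dict[tuple[str, str, int, int, int], PlantedOrf]:
        return {
            (p.transcript_accession, p.strand, p.frame, p.nt_start, p.nt_end): p
            for p in self.planted
        }


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n)]


def _orf_construct(
    rng: np.random.Generator, start_class: StartClass, n_aa: int
) -> tuple[str, str]:
    """Return (nucleotides, aa_seq) for stop + ORF + stop."""
    if start_class is StartClass.AUG:
        first = "ATG"
    elif start_class is StartClass.NEAR_COGNATE:
        first = _NEAR[rng.integers(0, len(_NEAR))]
    else:
        first = _UNKNOWN_STARTS[rng.integers(0, len(_UNKNOWN_STARTS))]
    body = _random_codons(rng, n_aa - 1)
    # internal ATG codons would only add nested AUG ORFs; avoid them so the
    # planted interval is the unique record at these coordinates
    body = [c if c != "ATG" else "ACG" for c in body]
    codons = (
        [_STOPS[rng.integers(0, 3)], first]
        + body
        + [_STOPS[rng.integers(0, 3)]]
    )
    nt = "".join(codons)
    aa = translate_frame(nt, 0)
    # layout: stop, ORF codons, stop -> product is between the two stops
    aa_seq = aa[1:-1]
    assert "*" not in aa_seq
    return nt, aa_seq


def make_transcripts(
    n: int,
    length_range: tuple[int, int] = (300, 600),
    n_aug: int = 1,
    n_near_cognate: int = 1,
    n_unknown: int = 1,
    orf_aa_range: tuple[int, int] = (12, 30),
    seed: int = 0,
    both_strands: bool = True,
) -> tuple[list[Transcript], TranscriptGroundTruth]:
    """Random transcripts with smORFs of each start class planted at known
    positions.

    Planted ORFs are flanked by in-frame stop codons on both sides, contain
    no internal stop and no internal ATG, and are placed at non-overlapping
    positions (on the reverse strand the construct is inserted as its
    reverse complement). The generator retries if background sequence happens
    to reproduce a planted amino-acid product elsewhere, so planted products
    are unique in the transcript set.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    min_len, max_len = length_range
    per_transcript = (
        [(StartClass.AUG, n_aug), (StartClass.NEAR_COGNATE, n_near_cognate),
         (StartClass.UNKNOWN, n_unknown)]
    )
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    planted: list[PlantedOrf] = []
    for t_idx in range(n):
        accession = f"SYNT{t_idx:06d}"
        for _attempt in range(20):
            length = int(rng.integers(min_len, max_len + 1))
            seq = np.array(list("ACGT"))[
                rng.integers(0, 4, length)
            ].tolist()
            occupied: list[tuple[int, int]] = []
            orfs_here: list[PlantedOrf] = []
            feasible = True
            for start_class, count in per_transcript:
                for _ in range(count):
                    n_aa = int(rng.integers(orf_aa_range[0], orf_aa_range[1] + 1))
                    nt, aa_seq = _orf_construct(rng, start_class, n_aa)
                    strand = "+" if not both_strands else (
                        "+" if rng.integers(0, 2) == 0 else "-"
                    )
                    placed = False
                    for _try in range(50):
                        if length < len(nt):
                            break
                        offset = int(rng.integers(0, length - len(nt) + 1))
                        span = (offset, offset + len(nt))
                        if any(a < span[1] and span[0] < b for a, b in occupied):
                            continue
                        insert = nt if strand == "+" else reverse_complement(nt)
                        seq[span[0] : span[1]] = list(insert)
                        occupied.append(span)
                        if strand == "+":
                            orf_start = offset + 3
                            orf_end = offset + len(nt)
                        else:
                            # oriented coordinates on the reverse complement
                            c_start = length - span[1]
                            orf_start = c_start + 3
                            orf_end = c_start + len(nt)
                        orfs_here.append(
                            PlantedOrf(
                                transcript_accession=accession,
                                strand=strand,
                                frame=orf_start % 3,
                                nt_start=orf_start,
                                nt_end=orf_end,
                                start_class=start_class,
                                aa_seq=aa_seq,
                            )
                        )
                        placed = True
                        break
                    if not placed:
                        feasible = False
                        break
                if not feasible:
                    break
            if not feasible:
                continue
            transcript = Transcript(accession=accession, sequence="".join(seq))
            if _background_clash(transcript, orfs_here):
                continue
            transcripts.append(transcript)
            planted.extend(sorted(
                orfs_here,
                key=lambda p: (p.strand, p.frame, p.nt_start),
            ))
            break
        else:
            raise InputError(
                f"could not place {sum(c for _, c in per_transcript)} ORFs "
                f"into a transcript of length <= {max_len}"
            )
    return transcripts, TranscriptGroundTruth(planted=tuple(planted), seed=seed)


def _background_clash(
    transcript: Transcript, planted: Sequence[PlantedOrf]
) -> bool:
    """True if any planted product also arises from a non-planted interval."""
    planted_keys = {
        (p.strand, p.frame, p.nt_start, p.nt_end) for p in planted
    }
    planted_seqs = {p.aa_seq for p in planted}
    if len(planted_seqs) != len(planted):
        return True
    for orf in find_stop_to_stop_orfs(transcript, min_aa=1,
                                      require_bounding_stops=False):
        key = (orf.strand, orf.frame, orf.nt_start, orf.nt_end)
        if orf.aa_seq in planted_seqs and key not in planted_keys:
            return True
    return False


@dataclass(frozen=True)
class SpectrumGroundTruth:
    peptide: Peptide
    planted_ions: frozenset[tuple[str, int]]   # (series, ordinal)
    n_noise_peaks: int
    seed: int


def make_spectrum(
    peptide: Peptide | str,
    charge: int = 2,
    ion_fraction: float = 1.0,
    n_noise_peaks: int = 0,
    mz_jitter_sd: float = 0.002,
    seed: int = 0,
    ion_subset: Sequence[tuple[str, int]] | None = None,
    spectrum_id: str | None = None,
    signal_intensity: float = 1e5,
    noise_intensity: float = 2e3,
) -> tuple[Ms2Spectrum, SpectrumGroundTruth]:
    """Render a peptide's (partial) singly-charged b/y ladder as a spectrum.

    ``ion_fraction`` of the 2(L-1) (series, ordinal) ions are planted
    (rounded; or pass ``ion_subset`` explicitly), each jittered by a normal
    m/z error of ``mz_jitter_sd`` (kept well below the 0.02 Da matching
    tolerance). Noise peaks are uniform in m/z but rejected within 0.05 Da
    of any theoretical ion (charge 1-2), so they can never be matched at the
    default tolerance. Matched-ion intensities are log-normal and high;
    noise intensities log-normal and low.
    """
    if isinstance(peptide, str):
        peptide = Peptide(sequence=peptide)
    if not 0.0 <= ion_fraction <= 1.0:
        raise ParameterError("ion_fraction must be in [0, 1]")
    if mz_jitter_sd < 0 or mz_jitter_sd > 0.005:
        raise ParameterError("mz_jitter_sd must be in [0, 0.005] Da")
    rng = np.random.default_rng(seed)
    ladder = {
        (ion.series, ion.ordinal): ion.theoretical_mz
        for ion in theoretical_ions(peptide, max_frag_charge=1)
    }
    all_keys = sorted(ladder)
    if ion_subset is not None:
        chosen = [tuple(k) for k in ion_subset]
        unknown = [k for k in chosen if k not in ladder]
        if unknown:
            raise ParameterError(f"ion_subset contains unknown ions {unknown}")
    else:
        n_chosen = int(round(ion_fraction * len(all_keys)))
        idx = rng.choice(len(all_keys), size=n_chosen, replace=False)
        chosen = [all_keys[i] for i in sorted(idx)]
    mzs, intens = [], []
    for key in chosen:
        mzs.append(ladder[key] + rng.normal(0.0, mz_jitter_sd))
        intens.append(rng.lognormal(np.log(signal_intensity), 0.5))
    guard = [
        ion.theoretical_mz
        for ion in theoretical_ions(peptide, max_frag_charge=2)
    ]
    guard_arr = np.array(guard)
    lo, hi = 150.0, max(guard) + 200.0
    placed = 0
    while placed < n_noise_peaks:
        m = float(rng.uniform(lo, hi))
        if np.min(np.abs(guard_arr - m)) < 0.05:
            continue
        mzs.append(m)
        intens.append(rng.lognormal(np.log(noise_intensity), 0.5))
        placed += 1
    neutral = peptide_neutral_mass(peptide)
    spectrum = Ms2Spectrum(
        spectrum_id=spectrum_id or f"synthetic|{peptide.sequence}|seed{seed}",
        precursor_mz=(neutral + charge * PROTON_MASS) / charge,
        precursor_charge=charge,
        mz=np.array(mzs, dtype=float),
        intensity=np.array(intens, dtype=float),
    )
    truth = SpectrumGroundTruth(
        peptide=peptide,
        planted_ions=frozenset(chosen),
        n_noise_peaks=n_noise_peaks,
        seed=seed,
    )
    return spectrum, truth


@dataclass(frozen=True)
class CohortGroundTruth:
    shared_ids: tuple[str, ...]
    specific_a: tuple[str, ...]
    specific_b: tuple[str, ...]
    effect_ids: tuple[str, ...]
    group_names: tuple[str, str]
    seed: int


def make_cohort(
    n_per_group: int = 3,
    n_shared: int = 30,
    n_specific_a: int = 17,
    n_specific_b: int = 19,
    group_effect: float = 3.0,
    effect_fraction: float = 0.5,
    detection_prob_a: float = 0.9,
    detection_prob_b: float = 0.9,
    base_sigma: float = 0.5,
    sigma: float = 0.25,
    seed: int = 0,
    group_names: tuple[str, str] = ("healthy", "glioma"),
) -> tuple[DetectionMatrix, CohortGroundTruth]:
    """Two-group label-free cohort with planted structure.

    A shared microprotein core is present in both groups; ``n_specific_a`` /
    ``n_specific_b`` microproteins are present only in their own group
    (defaults emulate the 17-missing / 19-new divergence between healthy and
    glioma plasma EV cohorts, with three donors per group). Base abundances
    are log-normal with spread ``base_sigma`` (natural-log units) around
    1e6 area units; a random ``effect_fraction`` of the shared core is
    multiplied by ``2**group_effect`` in group B; each truly present value is
    observed per sample with the group's Bernoulli detection probability and
    log-normal replicate-level spread ``sigma``.
    """
    for p in (detection_prob_a, detection_prob_b):
        if not 0.0 <= p <= 1.0:
            raise ParameterError("detection probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shared = [f"MP{i:04d}" for i in range(n_shared)]
    spec_a = [f"MPA{i:04d}" for i in range(n_specific_a)]
    spec_b = [f"MPB{i:04d}" for i in range(n_specific_b)]
    ids = shared + spec_a + spec_b
    base = rng.lognormal(np.log(1e6), base_sigma, size=len(ids))
    n_effect = int(round(effect_fraction * n_shared))
    effect_idx = rng.choice(n_shared, size=n_effect, replace=False)
    effect_ids = [shared[i] for i in sorted(effect_idx)]
    effect_set = set(effect_ids)
    samples_a = [f"{group_names[0]}_{i + 1}" for i in range(n_per_group)]
    samples_b = [f"{group_names[1]}_{i + 1}" for i in range(n_per_group)]
    spec_a_set, spec_b_set = set(spec_a), set(spec_b)
    data: dict[str, list[float]] = {}
    for samples, group_idx in ((samples_a, 0), (samples_b, 1)):
        p_detect = detection_prob_a if group_idx == 0 else detection_prob_b
        for sample in samples:
            col = []
            for mp_idx, mp in enumerate(ids):
                present = not (
                    (mp in spec_a_set and group_idx == 1)
                    or (mp in spec_b_set and group_idx == 0)
                )
                if not present or rng.uniform() >= p_detect:
                    col.append(np.nan)
                    continue
                value = base[mp_idx] * rng.lognormal(0.0, sigma)
                if group_idx == 1 and mp in effect_set:
                    value *= 2.0 ** group_effect
                col.append(value)
            data[sample] = col
    values = pd.DataFrame(data, index=ids)
    groups = {s: group_names[0] for s in samples_a}
    groups.update({s: group_names[1] for s in samples_b})
    matrix = DetectionMatrix(values, groups)
    truth = CohortGroundTruth(
        shared_ids=tuple(shared),
        specific_a=tuple(spec_a),
        specific_b=tuple(spec_b),
        effect_ids=tuple(effect_ids),
        group_names=group_names,
        seed=seed,
    )
    return matrix, truth
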