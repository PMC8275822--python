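"""Spectrum-level validation of claimed microprotein peptide identifications.

Search engines report peptide-spectrum matches (PSMs), but for novel
microproteins the prior probability of a correct match against a multi-million
entry putative database is low, so every PSM is re-examined against its MS2
spectrum with strict, auditable criteria:

* LENGTH        — peptide at least 6 residues;
* CONTINUITY    — more than four *consecutive* b- or y-ions matched within a
                  single series (run length >= 5 by default);
* COVERAGE      — more than 40% of the 2(L-1) possible b/y ordinals matched;
* PURITY        — at most half of the 10 most intense peaks left unexplained;
* KNOWN_PEPTIDE — the peptide must not occur in the annotated proteome.

Fragment masses are monoisotopic throughout: a b-ion of ordinal i is the sum
of the first i residue masses plus z protons (divided by z), a y-ion the sum
of the last i residue masses plus water plus z protons. Peaks are matched at
+/- 0.02 Da with a greedy one-to-one assignment in ascending |delta m/z|.

The module also provides binned spectral similarity for synthetic-peptide
validation and target-decoy q-value estimation for FDR control.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .digestion import Peptide, ProteomeIndex, is_novel_peptide
from .errors import InputError, ParameterError

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASSES",
    "CARBAMIDOMETHYL_DELTA",
    "OXIDATION_DELTA",
    "Ms2Spectrum",
    "Psm",
    "FragmentIon",
    "PeakMatch",
    "IonMatchReport",
    "QcCriterion",
    "QcParams",
    "QcDecision",
    "peptide_neutral_mass",
    "theoretical_ions",
    "match_peaks",
    "longest_consecutive_run",
    "ion_coverage",
    "high_intensity_purity",
    "match_report",
    "qc_filter",
    "spectral_similarity",
    "modified_forms",
    "target_decoy_qvalues",
    "filter_by_qvalue",
]

PROTON_MASS = 1.007276466
WATER_MASS = 18.010565

#: Monoisotopic residue masses (Da) of the 20 canonical amino acids.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

CARBAMIDOMETHYL_DELTA = 57.02146  # fixed on C (iodoacetamide alkylation)
OXIDATION_DELTA = 15.99491        # variable on M


@dataclass(frozen=True)
class Ms2Spectrum:
    """A centroided MS2 spectrum; peaks sorted ascending by m/z."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise InputError(
                f"spectrum {self.spectrum_id}: mismatched peak arrays"
            )
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size and mz[0] <= 0:
            raise InputError(f"spectrum {self.spectrum_id}: non-positive m/z")
        if np.any(inten < 0):
            raise InputError(
                f"spectrum {self.spectrum_id}: negative intensity"
            )
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class Psm:
    """One peptide-spectrum match as reported by an upstream search engine."""

    spectrum_id: str
    peptide: Peptide
    charge: int
    engine_score: float
    q_value: float | None = None
    source_ids: tuple[str, ...] = ()
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise InputError(f"PSM {self.spectrum_id}: charge < 1")
        if self.q_value is not None and not 0.0 <= self.q_value <= 1.0:
            raise InputError(f"PSM {self.spectrum_id}: q-value outside [0,1]")


@dataclass(frozen=True)
class FragmentIon:
    series: str           # 'b' or 'y'
    ordinal: int          # 1 .. L-1
    charge: int
    theoretical_mz: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise InputError(f"unknown ion series {self.series!r}")
        if self.ordinal < 1 or self.charge < 1 or self.theoretical_mz <= 0:
            raise InputError("invalid fragment ion")


@dataclass(frozen=True)
class PeakMatch:
    ion: FragmentIon
    peak_index: int
    peak_mz: float
    peak_intensity: float
    delta_mz: float


@dataclass(frozen=True)
class IonMatchReport:
    """Computed fragment-matching evidence for one PSM."""

    peptide_length: int
    matches: tuple[PeakMatch, ...]
    longest_run_b: int
    longest_run_y: int
    by_coverage: float
    high_intensity_unmatched_fraction: float

    @property
    def matched_ordinals(self) -> set[tuple[str, int]]:
        return {(m.ion.series, m.ion.ordinal) for m in self.matches}


class QcCriterion(str, Enum):
    LENGTH = "LENGTH"
    CONTINUITY = "CONTINUITY"
    COVERAGE = "COVERAGE"
    PURITY = "PURITY"
    KNOWN_PEPTIDE = "KNOWN_PEPTIDE"


@dataclass(frozen=True)
class QcParams:
    """Thresholds of the PSM acceptance criteria (strict inequalities noted)."""

    tol: float = 0.02                 # fragment tolerance, Da
    min_peptide_length: int = 6       # length >= 6
    min_run: int = 5                  # "> 4 continuous ions" == run >= 5
    min_coverage: float = 0.40        # coverage strictly > 0.40
    max_unmatched_top_fraction: float = 0.5
    top_n: int = 10
    max_frag_charge: int = 2


@dataclass(frozen=True)
class QcDecision:
    passed: bool
    failed_criteria: tuple[QcCriterion, ...]

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_criteria):
            raise InputError("QcDecision: passed inconsistent with criteria")


def _residue_mass(residue: str, peptide: Peptide) -> float:
    try:
        return RESIDUE_MASSES[residue]
    except KeyError:
        raise InputError(
            f"unknown residue {residue!r} in peptide {peptide.sequence!r}"
        ) from None


def peptide_neutral_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass including modification deltas."""
    total = WATER_MASS + sum(
        _residue_mass(r, peptide) for r in peptide.sequence
    )
    return total + sum(delta for _site, _name, delta in peptide.modifications)


def theoretical_ions(
    peptide: Peptide, max_frag_charge: int = 1
) -> list[FragmentIon]:
    """Singly- to ``max_frag_charge``-charged b/y ladders of a peptide.

    For a peptide of length L there are L-1 ordinals per series per charge;
    site-localized modification deltas are carried by the prefix (b) or
    suffix (y) containing the site.
    """
    if len(peptide.sequence) < 2:
        raise InputError("fragment ions require a peptide of length >= 2")
    if max_frag_charge < 1:
        raise ParameterError("max_frag_charge must be >= 1")
    L = len(peptide.sequence)
    masses = [_residue_mass(r, peptide) for r in peptide.sequence]
    for site, _name, delta in peptide.modifications:
        masses[site - 1] += delta
    prefix = list(itertools.accumulate(masses))
    total = prefix[-1]
    ions = []
    for z in range(1, max_frag_charge + 1):
        for i in range(1, L):
            ions.append(FragmentIon("b", i, z, (prefix[i - 1] + z * PROTON_MASS) / z))
        for i in range(1, L):
            suffix = total - prefix[L - i - 1]
            ions.append(
                FragmentIon("y", i, z, (suffix + WATER_MASS + z * PROTON_MASS) / z)
            )
    return ions


def match_peaks(
    spectrum: Ms2Spectrum,
    ions: Sequence[FragmentIon],
    tol: float = 0.02,
) -> list[PeakMatch]:
    """Greedy one-to-one assignment of theoretical ions to observed peaks.

    Candidate (ion, peak) pairs within ``tol`` are taken in ascending
    |delta m/z|, ties broken in favour of the more intense peak; each ion and
    each peak is used at most once.
    """
    if tol <= 0:
        raise ParameterError(f"tolerance must be positive, got {tol}")
    mz = spectrum.mz
    candidates = []
    for ion_idx, ion in enumerate(ions):
        lo = int(np.searchsorted(mz, ion.theoretical_mz - tol, side="left"))
        hi = int(np.searchsorted(mz, ion.theoretical_mz + tol, side="right"))
        for peak_idx in range(lo, hi):
            delta = float(mz[peak_idx] - ion.theoretical_mz)
            candidates.append(
                (abs(delta), -float(spectrum.intensity[peak_idx]),
                 ion_idx, peak_idx, delta)
            )
    candidates.sort()
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    matches = []
    for _absd, _negint, ion_idx, peak_idx, delta in candidates:
        if ion_idx in used_ions or peak_idx in used_peaks:
            continue
        used_ions.add(ion_idx)
        used_peaks.add(peak_idx)
        matches.append(
            PeakMatch(
                ion=ions[ion_idx],
                peak_index=peak_idx,
                peak_mz=float(mz[peak_idx]),
                peak_intensity=float(spectrum.intensity[peak_idx]),
                delta_mz=delta,
            )
        )
    matches.sort(key=lambda m: (m.ion.series, m.ion.ordinal, m.ion.charge))
    return matches


def longest_consecutive_run(ordinals: Iterable[int]) -> int:
    """Length of the longest run of consecutive integers in ``ordinals``."""
    s = set(ordinals)
    best = 0
    for o in s:
        if o - 1 not in s:
            length = 1
            while o + length in s:
                length += 1
            best = max(best, length)
    return best


def ion_coverage(matched_ordinals: set[tuple[str, int]], length: int) -> float:
    """Distinct matched (series, ordinal) pairs over the 2(L-1) possible."""
    if length < 2:
        raise ParameterError("coverage requires peptide length >= 2")
    return len(matched_ordinals) / (2 * (length - 1))


def high_intensity_purity(
    spectrum: Ms2Spectrum,
    matched_peak_indices: set[int],
    top_n: int = 10,
) -> float:
    """Fraction of the ``top_n`` most intense peaks not explained by any ion."""
    if len(spectrum) == 0:
        raise InputError("purity undefined for an empty spectrum")
    n = min(top_n, len(spectrum))
    top = np.argsort(-spectrum.intensity, kind="stable")[:n]
    unmatched = sum(1 for idx in top if int(idx) not in matched_peak_indices)
    return unmatched / n


def match_report(
    spectrum: Ms2Spectrum,
    peptide: Peptide,
    params: QcParams = QcParams(),
) -> IonMatchReport:
    """Match the peptide's theoretical b/y ladder against the spectrum."""
    ions = theoretical_ions(peptide, max_frag_charge=params.max_frag_charge)
    matches = tuple(match_peaks(spectrum, ions, tol=params.tol))
    b_ords = {m.ion.ordinal for m in matches if m.ion.series == "b"}
    y_ords = {m.ion.ordinal for m in matches if m.ion.series == "y"}
    matched = {(m.ion.series, m.ion.ordinal) for m in matches}
    return IonMatchReport(
        peptide_length=len(peptide.sequence),
        matches=matches,
        longest_run_b=longest_consecutive_run(b_ords),
        longest_run_y=longest_consecutive_run(y_ords),
        by_coverage=ion_coverage(matched, len(peptide.sequence)),
        high_intensity_unmatched_fraction=high_intensity_purity(
            spectrum, {m.peak_index for m in matches}, top_n=params.top_n
        ),
    )


def qc_filter(
    psm: Psm,
    spectrum: Ms2Spectrum,
    proteome_index: ProteomeIndex | None,
    params: QcParams = QcParams(),
) -> tuple[QcDecision, IonMatchReport]:
    """Apply all acceptance criteria to one PSM.

    ``proteome_index`` may be ``None`` to skip the novelty criterion (e.g.
    when peptides were pre-screened). The spectrum must belong to the PSM.
    """
    if spectrum.spectrum_id != psm.spectrum_id:
        raise InputError(
            f"spectrum {spectrum.spectrum_id!r} does not match PSM "
            f"{psm.spectrum_id!r}"
        )
    report = match_report(spectrum, psm.peptide, params)
    failed = []
    if len(psm.peptide.sequence) < params.min_peptide_length:
        failed.append(QcCriterion.LENGTH)
    if max(report.longest_run_b, report.longest_run_y) < params.min_run:
        failed.append(QcCriterion.CONTINUITY)
    if not report.by_coverage > params.min_coverage:
        failed.append(QcCriterion.COVERAGE)
    if report.high_intensity_unmatched_fraction > params.max_unmatched_top_fraction:
        failed.append(QcCriterion.PURITY)
    if proteome_index is not None and not is_novel_peptide(
        psm.peptide, proteome_index
    ):
        failed.append(QcCriterion.KNOWN_PEPTIDE)
    return (
        QcDecision(passed=not failed, failed_criteria=tuple(failed)),
        report,
    )


def spectral_similarity(
    a: Ms2Spectrum, b: Ms2Spectrum, bin_width: float = 0.02
) -> float:
    """Normalized dot product of square-root intensities on fixed m/z bins.

    Used to compare an experimental spectrum with the spectrum of a synthetic
    peptide standard; 1.0 for identical spectra, 0.0 for disjoint ones.
    """
    if len(a) == 0 or len(b) == 0:
        raise InputError("spectral similarity requires nonempty spectra")
    if bin_width <= 0:
        raise ParameterError("bin width must be positive")

    def binned(s: Ms2Spectrum) -> dict[int, float]:
        vec: dict[int, float] = {}
        for m, i in zip(s.mz, s.intensity):
            key = int(m // bin_width)
            vec[key] = vec.get(key, 0.0) + math.sqrt(i)
        return vec

    va, vb = binned(a), binned(b)
    dot = sum(v * vb.get(k, 0.0) for k, v in va.items())
    na = math.sqrt(sum(v * v for v in va.values()))
    nb = math.sqrt(sum(v * v for v in vb.values()))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return dot / (na * nb)


def modified_forms(
    sequence: str,
    fixed_carbamidomethyl: bool = True,
    max_oxidations: int = 3,
) -> list[Peptide]:
    """Enumerate the modified forms considered during validation.

    Carbamidomethylation of every cysteine is fixed; methionine oxidation is
    variable, enumerated combinatorially up to ``max_oxidations`` sites.
    """
    fixed = []
    if fixed_carbamidomethyl:
        fixed = [
            (i + 1, "Carbamidomethyl", CARBAMIDOMETHYL_DELTA)
            for i, r in enumerate(sequence)
            if r == "C"
        ]
    met_sites = [i + 1 for i, r in enumerate(sequence) if r == "M"]
    forms = []
    for k in range(0, min(max_oxidations, len(met_sites)) + 1):
        for combo in itertools.combinations(met_sites, k):
            mods = fixed + [(s, "Oxidation", OXIDATION_DELTA) for s in combo]
            mods.sort()
            forms.append(Peptide(sequence=sequence, modifications=tuple(mods)))
    return forms


def target_decoy_qvalues(psms: Sequence[Psm]) -> list[Psm]:
    """Assign target-decoy q-values.

    PSMs are ranked by descending engine score; at each threshold the FDR is
    estimated as (decoys at or above) / (targets at or above), ties sharing
    one estimate. The q-value is the running minimum of the FDR taken from
    the bottom of the list upward. Returned in the ranked order.
    """
    psms = list(psms)
    if not any(not p.is_decoy for p in psms):
        raise InputError("target-decoy estimation requires at least one target")
    order = sorted(range(len(psms)), key=lambda i: -psms[i].engine_score)
    ranked = [psms[i] for i in order]
    n = len(ranked)
    fdr = [0.0] * n
    targets = decoys = 0
    i = 0
    while i < n:
        j = i
        while j < n and ranked[j].engine_score == ranked[i].engine_score:
            if ranked[j].is_decoy:
                decoys += 1
            else:
                targets += 1
            j += 1
        estimate = decoys / targets if targets else float("inf")
        for k in range(i, j):
            fdr[k] = estimate
        i = j
    q = [0.0] * n
    running = float("inf")
    for k in range(n - 1, -1, -1):
        running = min(running, fdr[k])
        q[k] = min(running, 1.0)  # FDR estimates above 1 carry no information
    return [replace(p, q_value=qv) for p, qv in zip(ranked, q)]


def filter_by_qvalue(psms: Sequence[Psm], threshold: float = 0.01) -> list[Psm]:
    """Targets with q-value strictly below ``threshold`` (FDR < 1% default)."""
    scored = target_decoy_qvalues(psms)
    return [p for p in scored if not p.is_decoy and p.q_value < threshold]
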