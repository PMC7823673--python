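"""Detection of nonmaternal (assumed paternal) alleles in plasma counts.

Against the maternal genotype, every plasma allele whose fraction of the
total locus depth D_i reaches the detection threshold (default 1.0%) and is
not carried by the mother is an *assumed paternal allele* (PA). Loci are
classified by the number of such alleles:

* Type I   — no nonmaternal allele (fetal alleles hidden in the maternal
  genotype);
* Type II  — one nonmaternal allele (shared by the fetuses, or a single
  fetal genome);
* Type III — two distinct nonmaternal alleles, only possible when two
  genetically distinct fetuses contribute: the *informative* pattern for a
  dizygotic pregnancy.

More than two nonmaternal alleles cannot arise from two fetuses and is
treated as suspected drop-in: the locus is left unclassified and excluded
from downstream zygosity and fetal-fraction estimation.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .datamodel import Genotype, GenotypeProfile, PlasmaLocusCounts, PlasmaProfile
from .errors import DegenerateLocusError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.01
DEFAULT_MIN_DEPTH = 50


class PatternType(enum.Enum):
    TYPE_I = "I"
    TYPE_II = "II"
    TYPE_III = "III"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class LocusCall:
    """Per-locus derived record: nonmaternal alleles and pattern type.

    ``nonmaternal_alleles`` holds ``(allele, depth, ratio)`` triples sorted
    by depth descending, ties broken by allele string ascending.
    """

    locus_id: str
    maternal_alleles: frozenset
    nonmaternal_alleles: Tuple[Tuple[str, int, float], ...]
    pattern_type: PatternType
    total_depth: int
    qc_pass: bool


@dataclass
class CaseCallSet:
    """All locus calls for one plasma case, with the thresholds used."""

    case_id: str
    calls: List[LocusCall] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD
    min_depth: int = DEFAULT_MIN_DEPTH

    @property
    def usable(self) -> List[LocusCall]:
        return [c for c in self.calls if c.qc_pass]

    def of_type(self, pattern: PatternType) -> List[LocusCall]:
        return [c for c in self.usable if c.pattern_type is pattern]

    @property
    def n_loci_with_pa(self) -> int:
        """Loci with at least one assumed paternal allele."""
        return sum(1 for c in self.usable if c.nonmaternal_alleles)

    @property
    def n_informative(self) -> int:
        """Type III (informative) locus count."""
        return len(self.of_type(PatternType.TYPE_III))

    @property
    def n_assumed_pa(self) -> int:
        """Total assumed paternal alleles across usable loci."""
        return sum(len(c.nonmaternal_alleles) for c in self.usable)

    @property
    def assumed_pa(self) -> Dict[str, frozenset]:
        """Assumed paternal allele set per locus (usable loci only)."""
        return {
            c.locus_id: frozenset(a for a, _, _ in c.nonmaternal_alleles)
            for c in self.usable
        }

    def summary(self) -> Tuple[int, int, int]:
        return (self.n_loci_with_pa, self.n_informative, self.n_assumed_pa)


def allele_ratios(counts: PlasmaLocusCounts) -> Dict[str, float]:
    """Fraction of the total locus depth D_i carried by each allele."""
    if counts.total_depth <= 0:
        raise DegenerateLocusError(f"locus {counts.locus_id!r}: zero total depth")
    d = counts.total_depth
    return {allele: depth / d for allele, depth in counts.depth.items()}


def detect_nonmaternal(
    counts: PlasmaLocusCounts,
    maternal: Genotype,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> LocusCall:
    """Call one locus: nonmaternal alleles at fraction ≥ ``threshold``.

    The threshold comparison is inclusive (an allele at exactly 1.0%
    counts). Loci with total depth below ``min_depth`` fail QC and are left
    unclassified, as are loci with more than two nonmaternal alleles
    (suspected drop-in).
    """
    if counts.locus_id != maternal.locus_id:
        raise ValidationError(
            f"locus mismatch: counts {counts.locus_id!r} vs maternal genotype "
            f"{maternal.locus_id!r}"
        )
    maternal_set = maternal.allele_set
    if counts.total_depth < min_depth or counts.total_depth == 0:
        return LocusCall(
            locus_id=counts.locus_id,
            maternal_alleles=maternal_set,
            nonmaternal_alleles=(),
            pattern_type=PatternType.UNCLASSIFIED,
            total_depth=counts.total_depth,
            qc_pass=False,
        )
    ratios = allele_ratios(counts)
    nonmat = [
        (allele, counts.depth[allele], ratio)
        for allele, ratio in ratios.items()
        if allele not in maternal_set and ratio >= threshold
    ]
    nonmat.sort(key=lambda t: (-t[1], t[0]))
    n = len(nonmat)
    if n == 0:
        pattern = PatternType.TYPE_I
    elif n == 1:
        pattern = PatternType.TYPE_II
    elif n == 2:
        pattern = PatternType.TYPE_III
    else:
        logger.warning(
            "locus %s: %d nonmaternal alleles (suspected drop-in); unclassified",
            counts.locus_id,
            n,
        )
        pattern = PatternType.UNCLASSIFIED
    return LocusCall(
        locus_id=counts.locus_id,
        maternal_alleles=maternal_set,
        nonmaternal_alleles=tuple(nonmat),
        pattern_type=pattern,
        total_depth=counts.total_depth,
        qc_pass=pattern is not PatternType.UNCLASSIFIED,
    )


def call_case(
    plasma: PlasmaProfile,
    maternal_profile: GenotypeProfile,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> CaseCallSet:
    """Call every plasma locus covered by the maternal genotype profile.

    Plasma loci without a maternal genotype are skipped with a warning; an
    empty overlap is an error.
    """
    callset = CaseCallSet(
        case_id=plasma.case_id, threshold=threshold, min_depth=min_depth
    )
    skipped = []
    for counts in plasma:
        if counts.locus_id not in maternal_profile:
            skipped.append(counts.locus_id)
            continue
        callset.calls.append(
            detect_nonmaternal(
                counts, maternal_profile[counts.locus_id], threshold, min_depth
            )
        )
    if skipped:
        logger.warning(
            "case %s: skipped %d plasma loci without maternal genotype: %s",
            plasma.case_id,
            len(skipped),
            ", ".join(sorted(skipped)[:5]),
        )
    if not callset.calls:
        raise ValidationError(
            f"case {plasma.case_id!r}: no overlap between plasma loci and "
            "maternal genotype profile"
        )
    callset.calls.sort(key=lambda c: c.locus_id)
    return callset
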