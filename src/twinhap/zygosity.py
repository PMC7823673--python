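"""Zygosity calling and fetal-fraction (FF) estimation from locus calls.

Zygosity rule
-------------
A dizygotic (DZ) pregnancy is called when the number of informative
(Type III) loci reaches ``min_informative`` (default 1); otherwise the
twins are considered monozygotic (MZ).

Fetal fraction
--------------
For a DZ case, each informative locus i carries two fetus-specific alleles
with depths d(l)_i ≤ d(h)_i out of total depth D_i. Under the assumption
that the lower-depth allele is consistently derived from the fetus with the
lower FF, the per-fetus fractions are estimated as unweighted means over the
N informative loci::

    FF_lower  = (1/N) Σ 2 d(l)_i / D_i
    FF_higher = (1/N) Σ 2 d(h)_i / D_i

and the combined FF is their sum. The factor 2 reflects that a fetus
heterozygous for a fetus-specific allele contributes only one of its two
genome copies to that allele. For an MZ case the two fetal genomes are
identical and the combined FF is estimated as for a singleton: the mean of
2 d_f_i / D_i over Type II loci.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from scipy import stats

from .calls import CaseCallSet, PatternType
from .datamodel import GenotypeProfile, PlasmaProfile
from .errors import ValidationError

logger = logging.getLogger(__name__)


class Zygosity(enum.Enum):
    MZ = "MZ"
    DZ = "DZ"


@dataclass(frozen=True)
class ZygosityResult:
    case_id: str
    n_informative: int
    call: Zygosity
    informative_loci: Tuple[str, ...]
    min_informative_threshold: int


@dataclass(frozen=True)
class FFLocus:
    """Per-locus FF contribution. ``d_higher``/``ff_higher_i`` are ``None``
    for MZ (singleton-style) loci, which carry a single fetal allele."""

    locus_id: str
    d_lower: int
    d_higher: Optional[int]
    total_depth: int
    ff_lower_i: float
    ff_higher_i: Optional[float]


@dataclass
class FFEstimate:
    """Fetal-fraction estimate for one case.

    For DZ estimates ``ff_combined == ff_lower + ff_higher`` by
    construction; for MZ estimates the per-fetus fractions are not
    attributable and are ``None``.
    """

    case_id: str
    ff_lower: Optional[float]
    ff_higher: Optional[float]
    ff_combined: float
    n_loci_used: int
    per_locus: List[FFLocus] = field(default_factory=list)

    @property
    def is_dz(self) -> bool:
        return self.ff_lower is not None and self.ff_higher is not None


@dataclass(frozen=True)
class ValidationSummary:
    """Accounting of assumed vs. real paternal alleles for one case."""

    case_id: str
    n_real_pa: int
    n_dropout: int
    n_dropin: int
    detection_rate: float
    n_real_informative: int
    ratio_h_over_l: Optional[float]
    n_loci_real_pa: int = 0


def zygosity_from_informative_count(
    case_id: str,
    n_informative: int,
    min_informative: int = 1,
    informative_loci: Sequence[str] = (),
) -> ZygosityResult:
    """Apply the informative-locus rule to a Type III locus count."""
    call = Zygosity.DZ if n_informative >= min_informative else Zygosity.MZ
    return ZygosityResult(
        case_id=case_id,
        n_informative=n_informative,
        call=call,
        informative_loci=tuple(informative_loci),
        min_informative_threshold=min_informative,
    )


def call_zygosity(calls: CaseCallSet, min_informative: int = 1) -> ZygosityResult:
    """Call MZ/DZ for a case from its usable locus calls."""
    if not calls.usable:
        raise ValidationError(f"case {calls.case_id!r}: no usable loci, no call")
    informative = sorted(c.locus_id for c in calls.of_type(PatternType.TYPE_III))
    return zygosity_from_informative_count(
        calls.case_id, len(informative), min_informative, informative
    )


def estimate_ff_dz(calls: CaseCallSet) -> FFEstimate:
    """Estimate lower/higher/combined FF for a DZ case from Type III loci.

    Type II loci are excluded: their single shared allele cannot be
    attributed to one fetus. At a locus where the two fetus-specific alleles
    have equal depth, both fetuses receive that depth.
    """
    informative = calls.of_type(PatternType.TYPE_III)
    if not informative:
        raise ValidationError(
            f"case {calls.case_id!r}: no informative (Type III) locus; "
            "use estimate_ff_mz for an MZ/singleton-style estimate"
        )
    per_locus: List[FFLocus] = []
    for call in informative:
        (a1, d1, _), (a2, d2, _) = call.nonmaternal_alleles[:2]
        d_low, d_high = min(d1, d2), max(d1, d2)
        per_locus.append(
            FFLocus(
                locus_id=call.locus_id,
                d_lower=d_low,
                d_higher=d_high,
                total_depth=call.total_depth,
                ff_lower_i=2 * d_low / call.total_depth,
                ff_higher_i=2 * d_high / call.total_depth,
            )
        )
    n = len(per_locus)
    ff_lower = sum(p.ff_lower_i for p in per_locus) / n
    ff_higher = sum(p.ff_higher_i for p in per_locus) / n
    return FFEstimate(
        case_id=calls.case_id,
        ff_lower=ff_lower,
        ff_higher=ff_higher,
        ff_combined=ff_lower + ff_higher,
        n_loci_used=n,
        per_locus=per_locus,
    )


def estimate_ff_mz(calls: CaseCallSet) -> FFEstimate:
    """Estimate the combined FF for an MZ case as for a singleton."""
    type2 = calls.of_type(PatternType.TYPE_II)
    if not type2:
        raise ValidationError(
            f"case {calls.case_id!r}: no Type II locus for singleton-style FF"
        )
    per_locus = [
        FFLocus(
            locus_id=c.locus_id,
            d_lower=c.nonmaternal_alleles[0][1],
            d_higher=None,
            total_depth=c.total_depth,
            ff_lower_i=2 * c.nonmaternal_alleles[0][1] / c.total_depth,
            ff_higher_i=None,
        )
        for c in type2
    ]
    combined = sum(p.ff_lower_i for p in per_locus) / len(per_locus)
    return FFEstimate(
        case_id=calls.case_id,
        ff_lower=None,
        ff_higher=None,
        ff_combined=combined,
        n_loci_used=len(per_locus),
        per_locus=per_locus,
    )


def estimate_ff(calls: CaseCallSet, zygosity: ZygosityResult) -> FFEstimate:
    """Dispatch to the DZ or MZ estimator according to the zygosity call."""
    if zygosity.call is Zygosity.DZ:
        return estimate_ff_dz(calls)
    return estimate_ff_mz(calls)


def pa_detection_rate(n_real_pa: int, n_dropout: int) -> float:
    """Fraction of real paternal alleles recovered: (real − dropout)/real."""
    if n_real_pa <= 0:
        raise ValidationError("detection rate undefined without real PAs")
    return (n_real_pa - n_dropout) / n_real_pa


def real_pa_sets(
    maternal: GenotypeProfile,
    fetal1: GenotypeProfile,
    fetal2: GenotypeProfile,
    loci: Sequence[str],
) -> Dict[str, frozenset]:
    """Real paternal-allele set per locus: fetal alleles absent from the
    maternal genotype, over both fetal reference genomes."""
    out: Dict[str, frozenset] = {}
    for locus_id in loci:
        if locus_id not in maternal:
            continue
        maternal_set = maternal[locus_id].allele_set
        fetal = set()
        for profile in (fetal1, fetal2):
            if locus_id in profile:
                fetal.update(profile[locus_id].allele_set)
        out[locus_id] = frozenset(fetal - maternal_set)
    return out


def validate_against_fetal_genotypes(
    calls: CaseCallSet,
    fetal1: GenotypeProfile,
    fetal2: GenotypeProfile,
    maternal: GenotypeProfile,
    plasma: Optional[PlasmaProfile] = None,
) -> ValidationSummary:
    """Compare assumed paternal alleles against fetal reference genotypes.

    Dropouts are real paternal alleles missed in plasma; drop-ins are
    assumed paternal alleles carried by neither fetus. When ``plasma`` is
    given, validated per-fetus FFs are computed from the real informative
    loci and their ratio (higher/lower) is reported.
    """
    if not len(fetal1) or not len(fetal2):
        raise ValidationError("both fetal reference profiles are required")
    loci = [c.locus_id for c in calls.usable]
    real = real_pa_sets(maternal, fetal1, fetal2, loci)
    assumed = calls.assumed_pa
    n_real = n_dropout = n_dropin = n_real_informative = n_loci_real = 0
    for locus_id in loci:
        real_set = real.get(locus_id, frozenset())
        assumed_set = assumed.get(locus_id, frozenset())
        n_real += len(real_set)
        n_dropout += len(real_set - assumed_set)
        n_dropin += len(assumed_set - real_set)
        if len(real_set) == 2:
            n_real_informative += 1
        if real_set:
            n_loci_real += 1
    ratio = None
    if plasma is not None and n_real_informative > 0:
        vff = validated_ff(plasma, maternal, fetal1, fetal2)
        if vff.is_dz and vff.ff_lower > 0:
            ratio = vff.ff_higher / vff.ff_lower
    return ValidationSummary(
        case_id=calls.case_id,
        n_real_pa=n_real,
        n_dropout=n_dropout,
        n_dropin=n_dropin,
        detection_rate=pa_detection_rate(n_real, n_dropout),
        n_real_informative=n_real_informative,
        ratio_h_over_l=ratio,
        n_loci_real_pa=n_loci_real,
    )


def validated_ff(
    plasma: PlasmaProfile,
    maternal: GenotypeProfile,
    fetal1: GenotypeProfile,
    fetal2: GenotypeProfile,
) -> FFEstimate:
    """FF estimate using real fetus-specific alleles as the reference.

    Real informative loci (exactly two real paternal alleles) drive the
    DZ-style estimate; with none, loci carrying one real paternal allele
    give a singleton-style combined FF. Observed plasma depths are used
    regardless of the detection threshold (a dropped-out allele contributes
    depth 0).
    """
    loci = sorted(plasma.loci)
    real = real_pa_sets(maternal, fetal1, fetal2, loci)
    dz_loci: List[FFLocus] = []
    mz_loci: List[FFLocus] = []
    for locus_id in loci:
        real_set = real.get(locus_id, frozenset())
        counts = plasma.loci[locus_id]
        if counts.total_depth == 0:
            continue
        depths = sorted(counts.depth.get(a, 0) for a in real_set)
        if len(real_set) == 2:
            d_low, d_high = depths
            dz_loci.append(
                FFLocus(
                    locus_id,
                    d_low,
                    d_high,
                    counts.total_depth,
                    2 * d_low / counts.total_depth,
                    2 * d_high / counts.total_depth,
                )
            )
        elif len(real_set) == 1:
            (d_f,) = depths
            mz_loci.append(
                FFLocus(
                    locus_id,
                    d_f,
                    None,
                    counts.total_depth,
                    2 * d_f / counts.total_depth,
                    None,
                )
            )
    if dz_loci:
        n = len(dz_loci)
        ff_lower = sum(p.ff_lower_i for p in dz_loci) / n
        ff_higher = sum(p.ff_higher_i for p in dz_loci) / n
        return FFEstimate(
            plasma.case_id, ff_lower, ff_higher, ff_lower + ff_higher, n, dz_loci
        )
    if not mz_loci:
        raise ValidationError(
            f"case {plasma.case_id!r}: no locus with a real paternal allele"
        )
    combined = sum(p.ff_lower_i for p in mz_loci) / len(mz_loci)
    return FFEstimate(plasma.case_id, None, None, combined, len(mz_loci), mz_loci)


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation (the R² of the least-squares line)."""
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("R² needs at least 3 paired observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValidationError("R² undefined for a zero-variance vector")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def ff_concordance(
    estimates: Sequence[FFEstimate], validated: Sequence[FFEstimate]
) -> Tuple[float, float, float]:
    """R² of estimated vs. validated lower, higher and combined FF across
    DZ cases, paired by case id."""
    val_by_case = {v.case_id: v for v in validated}
    pairs = [
        (e, val_by_case[e.case_id])
        for e in estimates
        if e.case_id in val_by_case and e.is_dz and val_by_case[e.case_id].is_dz
    ]
    if len(pairs) < 3:
        raise ValidationError(
            f"need ≥3 paired DZ cases for concordance, got {len(pairs)}"
        )
    r2_lower = r_squared([e.ff_lower for e, _ in pairs], [v.ff_lower for _, v in pairs])
    r2_higher = r_squared(
        [e.ff_higher for e, _ in pairs], [v.ff_higher for _, v in pairs]
    )
    r2_combined = r_squared(
        [e.ff_combined for e, _ in pairs], [v.ff_combined for _, v in pairs]
    )
    return (r2_lower, r2_higher, r2_combined)


def ff_ratio(estimate: FFEstimate) -> float:
    """Higher/lower FF ratio for a DZ estimate (cfDNA contribution skew)."""
    if not estimate.is_dz:
        raise ValidationError("FF ratio defined only for DZ estimates")
    if estimate.ff_lower == 0:
        raise ValidationError("FF ratio undefined: lower FF is zero")
    return estimate.ff_higher / estimate.ff_lower
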