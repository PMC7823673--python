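"""Core domain types for microhaplotype NIPT interpretation.

A microhaplotype is a short (<200 bp) genomic segment containing two or more
linked SNPs; its alleles are SNP haplotypes treated as opaque strings (e.g.
``"ACT"``). Haplotype phasing from reads happens upstream; this package starts
from per-locus allele read counts in maternal plasma plus genotype profiles
for the mother, the alleged father and (optionally) fetal reference samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

from .errors import ValidationError

#: Population frequency assigned to alleles absent from the frequency table.
#: Probability math must never see a zero frequency.
DEFAULT_UNSEEN_FREQ = 0.002

_FREQ_SUM_TOL = 1e-6


class FrequencyTable:
    """Per-locus allele → population frequency map with an unseen-allele floor.

    Lookups of alleles absent from a locus return ``unseen_freq`` (default
    0.002), never zero, so likelihoods stay finite for rare haplotypes.
    Frequencies are deliberately *not* renormalised after applying the floor.
    """

    def __init__(
        self,
        entries: Mapping[str, Mapping[str, float]],
        unseen_freq: float = DEFAULT_UNSEEN_FREQ,
    ) -> None:
        if not 0 < unseen_freq < 1:
            raise ValidationError(f"unseen_freq must be in (0,1), got {unseen_freq}")
        self.unseen_freq = float(unseen_freq)
        self.entries: Dict[str, Dict[str, float]] = {}
        for locus, alleles in entries.items():
            if not alleles:
                raise ValidationError(f"locus {locus!r} has no alleles")
            total = 0.0
            locus_map: Dict[str, float] = {}
            for allele, freq in alleles.items():
                if not allele:
                    raise ValidationError(f"locus {locus!r}: empty allele label")
                freq = float(freq)
                if not 0 < freq <= 1 or math.isnan(freq):
                    raise ValidationError(
                        f"locus {locus!r} allele {allele!r}: frequency {freq} "
                        "outside (0, 1]"
                    )
                locus_map[allele] = freq
                total += freq
            if total > 1 + _FREQ_SUM_TOL:
                raise ValidationError(
                    f"locus {locus!r}: frequencies sum to {total:.6g} > 1"
                )
            self.entries[locus] = locus_map

    @property
    def loci(self) -> Tuple[str, ...]:
        return tuple(self.entries)

    def alleles(self, locus_id: str) -> Tuple[str, ...]:
        return tuple(self.entries.get(locus_id, ()))

    def lookup(self, locus_id: str, allele: str) -> float:
        """Frequency of ``allele`` at ``locus_id``; the floor if unseen."""
        return self.entries.get(locus_id, {}).get(allele, self.unseen_freq)

    def effective_n_alleles(self, locus_id: str) -> float:
        """Effective number of alleles Ae = 1/Σp² for a locus."""
        freqs = self.entries[locus_id].values()
        return 1.0 / sum(p * p for p in freqs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        return (
            self.unseen_freq == other.unseen_freq and self.entries == other.entries
        )

    def __repr__(self) -> str:
        return (
            f"FrequencyTable({len(self.entries)} loci, "
            f"unseen_freq={self.unseen_freq})"
        )


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid allele pair at one locus; ``{A,B} == {B,A}``."""

    locus_id: str
    alleles: Tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if not a or not b:
            raise ValidationError(f"locus {self.locus_id!r}: empty allele in genotype")
        # canonical ordering makes equality and hashing order-independent
        if b < a:
            object.__setattr__(self, "alleles", (b, a))

    @property
    def allele_set(self) -> frozenset:
        return frozenset(self.alleles)

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    def __contains__(self, allele: str) -> bool:
        return allele in self.alleles


@dataclass
class GenotypeProfile:
    """Genotypes across the panel for one named individual."""

    sample_id: str
    genotypes: Dict[str, Genotype] = field(default_factory=dict)

    def add(self, genotype: Genotype) -> None:
        if genotype.locus_id in self.genotypes:
            raise ValidationError(
                f"sample {self.sample_id!r}: duplicate genotype for locus "
                f"{genotype.locus_id!r}"
            )
        self.genotypes[genotype.locus_id] = genotype

    def __getitem__(self, locus_id: str) -> Genotype:
        return self.genotypes[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.genotypes

    def __len__(self) -> int:
        return len(self.genotypes)


class PlasmaLocusCounts:
    """Read depth per allele at one locus of a maternal plasma sample.

    ``total_depth`` (D_i) is always the sum of the per-allele depths;
    zero-depth alleles are dropped on construction.
    """

    __slots__ = ("locus_id", "depth", "total_depth")

    def __init__(self, locus_id: str, depth: Mapping[str, int]) -> None:
        self.locus_id = locus_id
        clean: Dict[str, int] = {}
        for allele, d in depth.items():
            if isinstance(d, bool) or not isinstance(d, (int,)):
                raise ValidationError(
                    f"locus {locus_id!r} allele {allele!r}: depth {d!r} not an integer"
                )
            if d < 0:
                raise ValidationError(
                    f"locus {locus_id!r} allele {allele!r}: negative depth {d}"
                )
            if d > 0:
                clean[allele] = d
        self.depth = clean
        self.total_depth = sum(clean.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlasmaLocusCounts):
            return NotImplemented
        return self.locus_id == other.locus_id and self.depth == other.depth

    def __repr__(self) -> str:
        return f"PlasmaLocusCounts({self.locus_id!r}, D={self.total_depth})"


@dataclass
class PlasmaProfile:
    """Per-locus plasma read counts for one case (one maternal draw)."""

    case_id: str
    loci: Dict[str, PlasmaLocusCounts] = field(default_factory=dict)

    def add(self, counts: PlasmaLocusCounts) -> None:
        self.loci[counts.locus_id] = counts

    def __iter__(self) -> Iterator[PlasmaLocusCounts]:
        return iter(self.loci.values())

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.loci

    def __len__(self) -> int:
        return len(self.loci)
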