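"""Synthetic twin-pregnancy cohorts with known ground truth.

The generator emulates the structure of a microhaplotype NIPT study: a
multiallelic panel (default 60 loci with 4–8 SNP-haplotype alleles each),
Hardy–Weinberg parents, Mendelian twins (monozygotic, dizygotic, or
dizygotic with heteropaternal superfecundation), and maternal plasma
read-count mixtures in which each fetus contributes its own fetal fraction.
Default fractions follow the ranges observed in twin cfDNA cohorts: the
lower-FF fetus of a DZ pair at 3–8%, the higher at 5–20%, and MZ combined
FF at 9–18%.

Expected allele proportions at a locus: the mother contributes
``1 − ff1 − ff2`` split equally between her two allele copies and each
fetus contributes ``ff_k/2`` per allele copy; read counts are multinomial
at the locus depth. Consequently a fetus-specific allele carried
heterozygously sits at an expected fraction of ``ff_k/2`` — the origin of
the factor 2 in the fetal-fraction estimator. Optional noise: per-allele
fetal dropout, and per-locus drop-in of a spurious population allele at
0.5–1.5% (straddling the 1% detection threshold on purpose).

All randomness flows from a single seed; identical seeds give
byte-identical TSV bundles.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .datamodel import (
    FrequencyTable,
    Genotype,
    GenotypeProfile,
    PlasmaLocusCounts,
    PlasmaProfile,
)
from .errors import ValidationError
from .io import (
    write_frequency_table,
    write_genotype_profiles,
    write_plasma_profiles,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one simulated case."""

    n_loci: int = 60
    alleles_per_locus: Tuple[int, int] = (4, 8)
    zygosity: str = "DZ"  # "MZ" | "DZ"
    paternity: str = "AF_BOTH"  # "AF_BOTH" | "HS" | "NEITHER"
    ff_twin1: float = 0.05
    ff_twin2: float = 0.08
    mean_depth: int = 2000
    depth_dispersion: float = 0.3
    dropin_rate: float = 0.0
    dropout_sim: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise ValidationError(f"unknown zygosity {self.zygosity!r}")
        if self.paternity not in ("AF_BOTH", "HS", "NEITHER"):
            raise ValidationError(f"unknown paternity {self.paternity!r}")
        if self.zygosity == "MZ" and self.paternity == "HS":
            raise ValidationError("MZ twins have a single father; HS impossible")
        if self.zygosity == "DZ" and not self.ff_twin1 + self.ff_twin2 < 1:
            raise ValidationError("combined fetal fraction must be < 1")

    @property
    def combined_ff(self) -> float:
        return (
            self.ff_twin1
            if self.zygosity == "MZ"
            else self.ff_twin1 + self.ff_twin2
        )


@dataclass
class SimTruth:
    """Ground-truth ledger for one simulated case."""

    case_id: str
    scenario: SimScenario
    mother: GenotypeProfile
    af: GenotypeProfile
    random_men: List[GenotypeProfile]
    twin1: GenotypeProfile
    twin2: GenotypeProfile
    real_pa: Dict[str, frozenset] = field(default_factory=dict)
    true_informative: List[str] = field(default_factory=list)

    @property
    def is_dz(self) -> bool:
        return self.scenario.zygosity == "DZ"


def simulate_frequencies(
    n_loci: int = 60,
    alleles_per_locus: Tuple[int, int] = (4, 8),
    seed: int | np.random.Generator = 0,
) -> FrequencyTable:
    """Panel allele frequencies: per locus, a flat-Dirichlet draw over
    4–8 SNP-haplotype alleles. Reproducible under the seed."""
    if n_loci < 1:
        raise ValidationError("n_loci must be ≥ 1")
    lo, hi = alleles_per_locus
    if lo < 2:
        raise ValidationError("need at least 2 alleles per locus")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    width = len(str(n_loci))
    entries: Dict[str, Dict[str, float]] = {}
    hap_len = 3 if hi <= len(_BASES) ** 3 else 4
    all_haps = ["".join(t) for t in itertools.product(_BASES, repeat=hap_len)]
    for i in range(n_loci):
        k = int(rng.integers(lo, hi + 1))
        alleles = [all_haps[j] for j in rng.choice(len(all_haps), size=k, replace=False)]
        freqs = rng.dirichlet(np.ones(k))
        entries[f"MH-{i + 1:0{width}d}"] = dict(zip(sorted(alleles), freqs.tolist()))
    return FrequencyTable(entries)


def _draw_hw_genotype(
    locus_id: str, freqs: FrequencyTable, rng: np.random.Generator
) -> Genotype:
    alleles = list(freqs.entries[locus_id])
    p = np.array([freqs.entries[locus_id][a] for a in alleles])
    p = p / p.sum()
    pair = rng.choice(len(alleles), size=2, replace=True, p=p)
    return Genotype(locus_id, (alleles[pair[0]], alleles[pair[1]]))


def _draw_profile(
    sample_id: str, freqs: FrequencyTable, rng: np.random.Generator
) -> GenotypeProfile:
    profile = GenotypeProfile(sample_id)
    for locus_id in freqs.loci:
        profile.add(_draw_hw_genotype(locus_id, freqs, rng))
    return profile


def _mendelian_child(
    sample_id: str,
    mother: GenotypeProfile,
    father: GenotypeProfile,
    rng: np.random.Generator,
) -> GenotypeProfile:
    child = GenotypeProfile(sample_id)
    for locus_id, m_gt in mother.genotypes.items():
        f_gt = father[locus_id]
        child.add(
            Genotype(
                locus_id,
                (
                    m_gt.alleles[int(rng.integers(2))],
                    f_gt.alleles[int(rng.integers(2))],
                ),
            )
        )
    return child


def simulate_family(
    freqs: FrequencyTable,
    scenario: SimScenario,
    rng: Optional[np.random.Generator] = None,
    case_id: str = "case1",
) -> SimTruth:
    """Draw parents under Hardy–Weinberg and twins per zygosity/paternity.

    ``AF_BOTH``: the alleged father fathers both twins (or the single MZ
    embryo). ``HS``: the AF fathers twin 1, a random man twin 2.
    ``NEITHER``: one random man for an MZ pair, two independent random men
    for a DZ pair.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    mother = _draw_profile(f"{case_id}_mother", freqs, rng)
    af = _draw_profile(f"{case_id}_af", freqs, rng)
    random_men = [
        _draw_profile(f"{case_id}_rm1", freqs, rng),
        _draw_profile(f"{case_id}_rm2", freqs, rng),
    ]
    if scenario.paternity == "AF_BOTH":
        father1, father2 = af, af
    elif scenario.paternity == "HS":
        father1, father2 = af, random_men[0]
    else:
        father1, father2 = random_men[0], random_men[1]
    twin1 = _mendelian_child(f"{case_id}_twin1", mother, father1, rng)
    if scenario.zygosity == "MZ":
        twin2 = GenotypeProfile(f"{case_id}_twin2", dict(twin1.genotypes))
    else:
        twin2 = _mendelian_child(f"{case_id}_twin2", mother, father2, rng)
    truth = SimTruth(
        case_id=case_id,
        scenario=scenario,
        mother=mother,
        af=af,
        random_men=random_men,
        twin1=twin1,
        twin2=twin2,
    )
    for locus_id, m_gt in mother.genotypes.items():
        fetal = twin1[locus_id].allele_set | twin2[locus_id].allele_set
        pa = frozenset(fetal - m_gt.allele_set)
        truth.real_pa[locus_id] = pa
        if len(pa) == 2:
            truth.true_informative.append(locus_id)
    truth.true_informative.sort()
    return truth


def _locus_depth(scenario: SimScenario, rng: np.random.Generator) -> int:
    """Total locus depth: constant at dispersion 0, otherwise negative
    binomial with variance μ(1 + φ)."""
    mu, phi = scenario.mean_depth, scenario.depth_dispersion
    if phi <= 0:
        return mu
    size = mu / phi
    return int(rng.negative_binomial(size, 1 / (1 + phi)))


def simulate_plasma(
    truth: SimTruth,
    freqs: FrequencyTable,
    rng: Optional[np.random.Generator] = None,
) -> PlasmaProfile:
    """Maternal plasma read counts for a simulated case.

    See the module docstring for the mixture model. Dropout zeroes a fetal
    allele-copy contribution with probability ``dropout_sim``; drop-in adds
    one spurious population allele per locus with probability
    ``dropin_rate`` at a 0.5–1.5% fraction.
    """
    scenario = truth.scenario
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    profile = PlasmaProfile(truth.case_id)
    if scenario.zygosity == "MZ":
        fetal_sources = [(truth.twin1, scenario.ff_twin1)]
    else:
        fetal_sources = [
            (truth.twin1, scenario.ff_twin1),
            (truth.twin2, scenario.ff_twin2),
        ]
    ff_total = sum(ff for _, ff in fetal_sources)
    for locus_id, m_gt in truth.mother.genotypes.items():
        weights: Dict[str, float] = {}
        for allele in m_gt.alleles:
            weights[allele] = weights.get(allele, 0.0) + (1 - ff_total) / 2
        for fetus, ff in fetal_sources:
            for allele in fetus[locus_id].alleles:
                if scenario.dropout_sim > 0 and rng.random() < scenario.dropout_sim:
                    continue
                weights[allele] = weights.get(allele, 0.0) + ff / 2
        if scenario.dropin_rate > 0 and rng.random() < scenario.dropin_rate:
            absent = [a for a in freqs.entries[locus_id] if a not in weights]
            if absent:
                p = np.array([freqs.entries[locus_id][a] for a in absent])
                spurious = absent[int(rng.choice(len(absent), p=p / p.sum()))]
                target = rng.uniform(0.005, 0.015)
                total = sum(weights.values())
                weights[spurious] = target * total / (1 - target)
        alleles = sorted(weights)
        probs = np.array([weights[a] for a in alleles])
        probs = probs / probs.sum()
        depth = _locus_depth(scenario, rng)
        counts = rng.multinomial(depth, probs)
        profile.add(
            PlasmaLocusCounts(locus_id, dict(zip(alleles, counts.tolist())))
        )
    return profile


def simulate_case(
    freqs: FrequencyTable,
    scenario: SimScenario,
    rng: Optional[np.random.Generator] = None,
    case_id: str = "case1",
) -> Tuple[SimTruth, PlasmaProfile]:
    """Family draw plus plasma counts with one stream of randomness."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    truth = simulate_family(freqs, scenario, rng, case_id)
    plasma = simulate_plasma(truth, freqs, rng)
    return truth, plasma


# ---------------------------------------------------------------------------
# cohort generation


def study_cohort_sampler(
    n_dz: int = 13, n_mz: int = 6, **overrides
) -> Callable[[int, np.random.Generator], SimScenario]:
    """Scenario sampler mirroring a 19-case twin cohort: ``n_dz`` dizygotic
    cases (lower FF 3–8%, higher FF 5–20%) then ``n_mz`` monozygotic cases
    (combined FF 9–18%), all fathered by the alleged father."""

    def sample(index: int, rng: np.random.Generator) -> SimScenario:
        if index < n_dz:
            ff_lo = rng.uniform(0.03, 0.08)
            ff_hi = rng.uniform(0.05, 0.20)
            ff1, ff2 = min(ff_lo, ff_hi), max(ff_lo, ff_hi)
            kw = dict(zygosity="DZ", ff_twin1=ff1, ff_twin2=ff2)
        else:
            kw = dict(zygosity="MZ", ff_twin1=rng.uniform(0.09, 0.18))
        kw.update(overrides)
        return SimScenario(**kw)

    return sample


def generate_cohort(
    n_cases: int,
    scenario_sampler: Optional[
        Callable[[int, np.random.Generator], SimScenario]
    ] = None,
    seed: int = 0,
    outdir: Optional[str | Path] = None,
) -> Tuple[List[PlasmaProfile], List[SimTruth], Optional[FrequencyTable]]:
    """Simulate ``n_cases`` over one shared panel; optionally write the TSV
    bundle (freqs.tsv, genotypes.tsv, plasma.tsv, truth.json)."""
    if n_cases < 1:
        raise ValidationError("n_cases must be ≥ 1")
    if scenario_sampler is None:
        scenario_sampler = study_cohort_sampler(
            n_dz=max(1, round(n_cases * 13 / 19)),
            n_mz=n_cases - max(1, round(n_cases * 13 / 19)),
        )
    rng = np.random.default_rng(seed)
    first = scenario_sampler(0, np.random.default_rng(seed))
    freqs = simulate_frequencies(first.n_loci, first.alleles_per_locus, rng)
    truths: List[SimTruth] = []
    profiles: List[PlasmaProfile] = []
    width = len(str(n_cases))
    for i in range(n_cases):
        scenario = scenario_sampler(i, rng)
        truth, plasma = simulate_case(freqs, scenario, rng, f"case{i + 1:0{width}d}")
        truths.append(truth)
        profiles.append(plasma)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_frequency_table(freqs, outdir / "freqs.tsv")
        genotype_profiles: List[GenotypeProfile] = []
        for t in truths:
            genotype_profiles.extend([t.mother, t.af, t.twin1, t.twin2])
        write_genotype_profiles(genotype_profiles, outdir / "genotypes.tsv")
        write_plasma_profiles(profiles, outdir / "plasma.tsv")
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump([_truth_record(t) for t in truths], fh, indent=1)
            fh.write("\n")
    return profiles, truths, freqs


def _truth_record(truth: SimTruth) -> Dict:
    return {
        "case_id": truth.case_id,
        "scenario": asdict(truth.scenario),
        "real_pa": {k: sorted(v) for k, v in truth.real_pa.items()},
        "true_informative": truth.true_informative,
        "zygosity": truth.scenario.zygosity,
        "combined_ff": truth.scenario.combined_ff,
    }
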