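"""Qualitative DNA-mixture likelihood ratios for twin-pregnancy paternity.

The maternal plasma at each locus is treated as a qualitative three-person
mixture: the mother plus two fetal contributors. The weight of evidence for
paternity is the likelihood ratio between competing hypotheses

* H1 — the alleged father (AF) fathered both twins,
* H2 — the AF fathered one twin and a random man the other
  (heteropaternal superfecundation),
* H3 — random men fathered both twins,

evaluated per locus and multiplied across loci (the panel loci are treated
as independent).

Evidence model
--------------
The evidence at a locus is the *set* of alleles observed above the
detection threshold. Given contributor genotypes, each allele copy of twin
k drops out independently with probability ``d_k`` (a fetal homozygote
therefore drops with probability d²); maternal copies never drop. At most
one drop-in per locus occurs: with probability ``1 − c`` none, otherwise a
single allele drawn by population frequency (a drop-in of an allele already
present is invisible). Observed alleles carried by no contributor and not
dropped in have probability zero. Fetal genotypes are marginalised over
Mendelian priors given the mother and the hypothesised father; each
transmission mutates with probability ``r`` to a population allele
(excluding the transmitted one, renormalised). With the coancestry
correction θ > 0, random-man alleles follow the Balding–Nichols sampling
formula conditioned on the typed parental genotypes (default θ = 0 gives
Hardy–Weinberg).
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .calls import DEFAULT_MIN_DEPTH, DEFAULT_THRESHOLD, allele_ratios
from .datamodel import FrequencyTable, Genotype, GenotypeProfile, PlasmaProfile
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Sentinel father for a random man drawn from the population.
POPULATION = "POPULATION"

#: Recommended floor for fetal dropout probabilities; a minor cfDNA
#: contributor never has dropout exactly zero.
MIN_DROPOUT = 0.001

#: Default equal-dropout grid d1 = d2.
DEFAULT_GRID_VALUES = (0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


class Hypothesis(enum.Enum):
    H1 = "H1"  # AF fathers both twins
    H2 = "H2"  # AF fathers one twin, a random man the other
    H3 = "H3"  # random men father both twins


@dataclass(frozen=True)
class HypothesisSpec:
    id: Hypothesis
    father_of_twin1: str  # "AF" or POPULATION
    father_of_twin2: str

    @staticmethod
    def standard(hyp: Hypothesis) -> "HypothesisSpec":
        mapping = {
            Hypothesis.H1: ("AF", "AF"),
            Hypothesis.H2: ("AF", POPULATION),
            Hypothesis.H3: (POPULATION, POPULATION),
        }
        f1, f2 = mapping[hyp]
        return HypothesisSpec(hyp, f1, f2)


@dataclass(frozen=True)
class MixtureParams:
    """Stochastic-model parameters for the mixture likelihood.

    Maternal dropout is fixed at zero: the mother is the major contributor
    of the cfDNA mixture. Silent alleles are accepted for interface parity
    but only ``silent = 0`` is supported.
    """

    d1: float = MIN_DROPOUT
    d2: float = MIN_DROPOUT
    drop_in: float = 0.01
    mutation_rate: float = 1e-8
    theta: float = 0.0
    silent: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "drop_in", "mutation_rate", "theta", "silent"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if self.silent > 0:
            raise ValidationError("silent alleles (s > 0) are not supported")


@dataclass(frozen=True)
class EvidenceLocus:
    """Observed allele set at one locus (maternal alleles included)."""

    locus_id: str
    observed_alleles: frozenset

    def __post_init__(self) -> None:
        if not self.observed_alleles:
            raise ValidationError(f"locus {self.locus_id!r}: empty evidence set")


@dataclass
class LRResult:
    """Per-locus and cumulative log10 LRs over a dropout grid.

    ``per_locus_log10[locus][g]`` and ``cumulative_log10[g]`` are
    ``(log10 LR_H1H3, log10 LR_H2H3, log10 LR_H1H2)`` triples for grid
    point ``g``.
    """

    case_id: str
    grid: List[Tuple[float, float]]
    per_locus_log10: Dict[str, List[Tuple[float, float, float]]] = field(
        default_factory=dict
    )
    cumulative_log10: List[Tuple[float, float, float]] = field(default_factory=list)
    skipped_loci: List[str] = field(default_factory=list)

    def min_cumulative(self, index: int = 0) -> float:
        return min(t[index] for t in self.cumulative_log10)

    def max_cumulative(self, index: int = 0) -> float:
        return max(t[index] for t in self.cumulative_log10)


def default_grid(
    values: Sequence[float] = DEFAULT_GRID_VALUES,
) -> List[Tuple[float, float]]:
    """Equal-dropout grid d1 = d2 over ``values``."""
    return [(float(d), float(d)) for d in values]


def cross_grid(
    values: Sequence[float] = DEFAULT_GRID_VALUES,
) -> List[Tuple[float, float]]:
    """Full (d1, d2) cross grid for unequal per-twin dropout."""
    return [(float(a), float(b)) for a in values for b in values]


# ---------------------------------------------------------------------------
# transmission and genotype priors


def _mutation_target_dist(
    parental: str, support: Mapping[str, float]
) -> Dict[str, float]:
    """Population distribution excluding the parental allele, renormalised."""
    rest = {a: p for a, p in support.items() if a != parental and p > 0}
    total = sum(rest.values())
    if total <= 0:
        return {}
    return {a: p / total for a, p in rest.items()}


def _transmission_dist(
    parent: Union[Genotype, str],
    support: Mapping[str, float],
    r: float,
    theta: float = 0.0,
    conditioning: Sequence[str] = (),
) -> Dict[str, float]:
    """Distribution of the allele transmitted by one parent.

    ``parent`` is a concrete :class:`Genotype` (each allele transmitted with
    probability 1/2, mutating with probability ``r``) or :data:`POPULATION`
    (a random man's transmitted allele drawn from the population, with the
    Balding–Nichols adjustment when θ > 0).
    """
    if parent == POPULATION:
        if theta > 0:
            n = len(conditioning)
            weights = {}
            for a, p in support.items():
                n_a = sum(1 for x in conditioning if x == a)
                weights[a] = (n_a * theta + (1 - theta) * p) / (1 + (n - 1) * theta)
        else:
            weights = dict(support)
        total = sum(weights.values())
        if total <= 0:
            raise ValidationError("empty population allele distribution")
        return {a: w / total for a, w in weights.items() if w > 0}
    dist: Dict[str, float] = {}
    for allele in parent.alleles:
        dist[allele] = dist.get(allele, 0.0) + 0.5 * (1 - r)
        if r > 0:
            for target, q in _mutation_target_dist(allele, support).items():
                dist[target] = dist.get(target, 0.0) + 0.5 * r * q
    return dist


def _locus_support(
    freqs: FrequencyTable, locus_id: str, extra_alleles: Sequence[str] = ()
) -> Dict[str, float]:
    """Allele → frequency over the locus's table alleles plus any extra
    alleles (evidence or parental alleles absent from the table, at the
    unseen-allele floor)."""
    support = dict(freqs.entries.get(locus_id, {}))
    for a in extra_alleles:
        support.setdefault(a, freqs.unseen_freq)
    if not support:
        raise ValidationError(f"locus {locus_id!r}: no allele frequencies")
    return support


def child_genotype_prior(
    mother: Genotype,
    father: Union[Genotype, str],
    freqs: FrequencyTable,
    r: float = 1e-8,
    theta: float = 0.0,
    extra_alleles: Sequence[str] = (),
    conditioning: Sequence[str] = (),
) -> Dict[Genotype, float]:
    """Prior over unordered child genotypes given the parents.

    The child receives one maternal and one paternal allele; each
    transmission passes the parental allele with probability ``1 − r`` and
    otherwise a population allele (excluding the parental one,
    renormalised). ``father`` may be :data:`POPULATION` for a random man.
    The returned probabilities sum to 1.
    """
    support = _locus_support(freqs, mother.locus_id, extra_alleles)
    mat = _transmission_dist(mother, support, r)
    pat = _transmission_dist(father, support, r, theta, conditioning)
    prior: Dict[Genotype, float] = {}
    for (a, pa), (b, pb) in itertools.product(mat.items(), pat.items()):
        g = Genotype(mother.locus_id, (a, b))
        prior[g] = prior.get(g, 0.0) + pa * pb
    return prior


# ---------------------------------------------------------------------------
# mixture likelihood (closed form over per-allele dropout)


def mixture_likelihood(
    evidence: EvidenceLocus,
    mother: Genotype,
    g1: Genotype,
    g2: Genotype,
    params: MixtureParams,
    freqs: FrequencyTable,
) -> float:
    """Probability of the observed allele set given contributor genotypes.

    Maternal copies never drop out, so evidence missing a maternal allele
    has probability zero. Twin copies drop independently with probabilities
    ``d1``/``d2``; the drop-in term follows the at-most-one-per-locus model
    described in the module docstring.
    """
    E = evidence.observed_alleles
    m_set = mother.allele_set
    if not m_set <= E:
        return 0.0
    d1, d2, c = params.d1, params.d2, params.drop_in

    def unobs(a: str) -> float:
        k1 = sum(1 for x in g1.alleles if x == a)
        k2 = sum(1 for x in g2.alleles if x == a)
        return (d1**k1) * (d2**k2)

    # fetal alleles outside the evidence must all drop out
    u = 1.0
    for a in set(g1.alleles) | set(g2.alleles):
        if a not in E:
            if a in m_set:  # unreachable: m_set <= E
                return 0.0
            u *= unobs(a)
    e_nm = sorted(E - m_set)
    surv = {a: 1.0 - unobs(a) for a in e_nm}
    a_full = u * math.prod(surv.values())
    if c == 0:
        return a_full
    support = _locus_support(freqs, evidence.locus_id, sorted(E))
    q0 = (1 - c) + c * sum(support[a] for a in E)
    dropin = 0.0
    for x in e_nm:
        partial = u * unobs(x)
        for a in e_nm:
            if a != x:
                partial *= surv[a]
        dropin += c * support[x] * partial
    return a_full * q0 + dropin


# ---------------------------------------------------------------------------
# fast per-locus evaluation over a dropout grid
#
# Alleles outside the named set (evidence ∪ parental alleles) behave
# identically in the likelihood — they only ever have to drop out — so they
# are lumped into a single pseudo-allele carrying their total frequency
# mass. The lumping is exact.

_OTHER = "\x00OTHER"


class _LocusEngine:
    """Precomputed genotype priors and copy counts for one locus."""

    def __init__(
        self,
        evidence: EvidenceLocus,
        mother: Genotype,
        af: Genotype,
        freqs: FrequencyTable,
        params: MixtureParams,
    ) -> None:
        E = evidence.observed_alleles
        named = sorted(E | mother.allele_set | af.allele_set)
        support_full = _locus_support(freqs, evidence.locus_id, named)
        other_mass = sum(p for a, p in support_full.items() if a not in named)
        support = {a: support_full[a] for a in named}
        if other_mass > 0:
            support[_OTHER] = other_mass
        alleles = list(support)
        index = {a: i for i, a in enumerate(alleles)}
        conditioning = tuple(mother.alleles) + tuple(af.alleles)
        r = params.mutation_rate
        mat = _transmission_dist(mother, support, r)
        pat_af = _transmission_dist(af, support, r)
        pat_pop = _transmission_dist(
            POPULATION, support, r, params.theta, conditioning
        )
        genos: Dict[Tuple[int, int], int] = {}
        prior_af: List[float] = []
        prior_pop: List[float] = []
        for (a, pa) in mat.items():
            ia = index[a]
            for b in set(pat_af) | set(pat_pop):
                ib = index[b]
                key = (min(ia, ib), max(ia, ib))
                if key not in genos:
                    genos[key] = len(prior_af)
                    prior_af.append(0.0)
                    prior_pop.append(0.0)
                gi = genos[key]
                prior_af[gi] += pa * pat_af.get(b, 0.0)
                prior_pop[gi] += pa * pat_pop.get(b, 0.0)
        n_g = len(genos)
        k = np.zeros((n_g, len(alleles)), dtype=np.int8)
        for (ia, ib), gi in genos.items():
            k[gi, ia] += 1
            k[gi, ib] += 1
        self.k = k
        self.prior_af = np.asarray(prior_af)
        self.prior_pop = np.asarray(prior_pop)
        m_idx = {index[a] for a in mother.allele_set}
        self.e_nm_idx = [index[a] for a in sorted(E) if index[a] not in m_idx]
        self.u_nm_idx = [i for a, i in index.items() if a not in E]
        self.c = params.drop_in
        self.q0 = (1 - self.c) + self.c * sum(support[a] for a in E)
        self.p = np.array([support[a] for a in alleles])

    def likelihoods(self, d1: float, d2: float) -> Tuple[float, float, float, float]:
        """(L_H1, L_H2 twin1-by-AF, L_H2 twin2-by-AF, L_H3) at one grid point."""
        w1 = np.power(d1, self.k)  # P(all copies of allele a in g drop | twin 1)
        w2 = np.power(d2, self.k)
        unobs_mats = {
            a: np.outer(w1[:, a], w2[:, a]) for a in self.e_nm_idx + self.u_nm_idx
        }
        n_g = self.k.shape[0]
        if not unobs_mats:
            # evidence covers the whole allele universe and is all-maternal:
            # the contributor set is the evidence for every genotype pair
            prob = np.full((n_g, n_g), self.q0)
        else:
            u_prod = np.ones((n_g, n_g))
            for a in self.u_nm_idx:
                u_prod = u_prod * unobs_mats[a]
            surv = {a: 1.0 - unobs_mats[a] for a in self.e_nm_idx}
            a_full = u_prod.copy()
            for a in self.e_nm_idx:
                a_full = a_full * surv[a]
            prob = a_full * self.q0
            for x in self.e_nm_idx:
                partial = u_prod * unobs_mats[x]
                for a in self.e_nm_idx:
                    if a != x:
                        partial = partial * surv[a]
                prob = prob + self.c * self.p[x] * partial
        l_h1 = float(self.prior_af @ prob @ self.prior_af)
        l_h2a = float(self.prior_af @ prob @ self.prior_pop)
        l_h2b = float(self.prior_pop @ prob @ self.prior_af)
        l_h3 = float(self.prior_pop @ prob @ self.prior_pop)
        return l_h1, l_h2a, l_h2b, l_h3


def locus_likelihood(
    evidence: EvidenceLocus,
    mother: Genotype,
    af: Genotype,
    hyp: Union[Hypothesis, HypothesisSpec],
    params: MixtureParams,
    freqs: FrequencyTable,
) -> float:
    """Evidence likelihood at one locus under a hypothesis, marginalised
    over the two fetal genotypes.

    Under H2 the two labelings (AF fathers twin 1 vs. twin 2) are averaged
    with equal prior; with ``d1 == d2`` both labelings coincide.
    """
    if isinstance(hyp, HypothesisSpec):
        hyp = hyp.id
    engine = _LocusEngine(evidence, mother, af, freqs, params)
    l_h1, l_h2a, l_h2b, l_h3 = engine.likelihoods(params.d1, params.d2)
    if hyp is Hypothesis.H1:
        return l_h1
    if hyp is Hypothesis.H2:
        return 0.5 * (l_h2a + l_h2b)
    return l_h3


def evidence_from_plasma(
    plasma: PlasmaProfile,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> List[EvidenceLocus]:
    """Qualitative evidence: per locus, all alleles at fraction ≥ threshold
    (maternal alleles included). Loci below ``min_depth`` are skipped."""
    out = []
    for counts in plasma:
        if counts.total_depth < min_depth or counts.total_depth == 0:
            continue
        observed = frozenset(
            a for a, ratio in allele_ratios(counts).items() if ratio >= threshold
        )
        if observed:
            out.append(EvidenceLocus(counts.locus_id, observed))
    return sorted(out, key=lambda e: e.locus_id)


def _log10(x: float) -> float:
    return math.log10(x) if x > 0 else -math.inf


def compute_lr(
    evidence_case: Sequence[EvidenceLocus],
    mother: GenotypeProfile,
    af: GenotypeProfile,
    freqs: FrequencyTable,
    grid: Optional[Sequence[Tuple[float, float]]] = None,
    params: MixtureParams = MixtureParams(),
    case_id: str = "",
) -> LRResult:
    """Per-locus and cumulative log10 LRs over a dropout-probability grid.

    Loci lacking a maternal or AF genotype, or whose evidence does not
    contain both maternal alleles, are skipped with a warning. By shared
    denominators, ``log10 LR_H1H3 = log10 LR_H1H2 + log10 LR_H2H3`` at
    every grid point.
    """
    if grid is None:
        grid = default_grid()
    grid = [(float(a), float(b)) for a, b in grid]
    result = LRResult(case_id=case_id, grid=grid)
    n_grid = len(grid)
    cum = np.zeros((n_grid, 3))
    n_used = 0
    for evidence in evidence_case:
        locus_id = evidence.locus_id
        if locus_id not in mother or locus_id not in af:
            result.skipped_loci.append(locus_id)
            continue
        m_gt = mother[locus_id]
        if not m_gt.allele_set <= evidence.observed_alleles:
            logger.warning(
                "locus %s: maternal allele below detection threshold; skipped",
                locus_id,
            )
            result.skipped_loci.append(locus_id)
            continue
        engine = _LocusEngine(evidence, m_gt, af[locus_id], freqs, params)
        triples = []
        for gi, (d1, d2) in enumerate(grid):
            l_h1, l_h2a, l_h2b, l_h3 = engine.likelihoods(d1, d2)
            l_h2 = 0.5 * (l_h2a + l_h2b)
            t = (
                _log10(l_h1) - _log10(l_h3),
                _log10(l_h2) - _log10(l_h3),
                _log10(l_h1) - _log10(l_h2),
            )
            triples.append(t)
            cum[gi] += t
        result.per_locus_log10[locus_id] = triples
        n_used += 1
    if n_used == 0:
        raise ValidationError(f"case {case_id!r}: no usable locus for LR")
    if result.skipped_loci:
        logger.info(
            "case %s: skipped %d loci in LR computation", case_id,
            len(result.skipped_loci),
        )
    result.cumulative_log10 = [tuple(row) for row in cum]
    return result


@dataclass(frozen=True)
class CandidateScreenRow:
    candidate_id: str
    min_log10_lr_h1h3: float
    max_log10_lr_h1h3: float
    min_log10_lr_h2h3: float
    max_log10_lr_h2h3: float
    lr_h2h3_crosses_one: bool


def specificity_screen(
    evidence_case: Sequence[EvidenceLocus],
    mother: GenotypeProfile,
    candidate_fathers: Sequence[GenotypeProfile],
    freqs: FrequencyTable,
    grid: Optional[Sequence[Tuple[float, float]]] = None,
    params: MixtureParams = MixtureParams(),
) -> List[CandidateScreenRow]:
    """Cumulative LR summaries treating each candidate as the alleged
    father; flags candidates whose LR_H2,H3 exceeds 1 anywhere on the grid."""
    if not candidate_fathers:
        raise ValidationError("specificity screen needs at least one candidate")
    rows = []
    for candidate in candidate_fathers:
        res = compute_lr(
            evidence_case, mother, candidate, freqs, grid, params,
            case_id=candidate.sample_id,
        )
        lr13 = [t[0] for t in res.cumulative_log10]
        lr23 = [t[1] for t in res.cumulative_log10]
        rows.append(
            CandidateScreenRow(
                candidate_id=candidate.sample_id,
                min_log10_lr_h1h3=min(lr13),
                max_log10_lr_h1h3=max(lr13),
                min_log10_lr_h2h3=min(lr23),
                max_log10_lr_h2h3=max(lr23),
                lr_h2h3_crosses_one=max(lr23) > 0,
            )
        )
    return rows
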