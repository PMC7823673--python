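"""Independent brute-force oracles for the mixture-likelihood model.

These enumerate every dropout/drop-in outcome explicitly and never share
code with the closed-form implementation they check.
"""

from __future__ import annotations

import itertools
from typing import Dict, Set

from twinhap.datamodel import FrequencyTable, Genotype
from twinhap.kinship import (
    POPULATION,
    EvidenceLocus,
    Hypothesis,
    MixtureParams,
    child_genotype_prior,
)


def _universe(freqs: FrequencyTable, locus_id: str, *allele_sets: Set[str]) -> Dict[str, float]:
    support = dict(freqs.entries.get(locus_id, {}))
    for allele_set in allele_sets:
        for a in allele_set:
            support.setdefault(a, freqs.unseen_freq)
    return support


def oracle_mixture_likelihood(
    evidence: EvidenceLocus,
    mother: Genotype,
    g1: Genotype,
    g2: Genotype,
    params: MixtureParams,
    freqs: FrequencyTable,
) -> float:
    """Sum over all 16 fetal dropout patterns and every drop-in outcome."""
    E = set(evidence.observed_alleles)
    d1, d2, c = params.d1, params.d2, params.drop_in
    support = _universe(freqs, evidence.locus_id, E)
    fetal_copies = [(a, d1) for a in g1.alleles] + [(a, d2) for a in g2.alleles]
    total = 0.0
    for pattern in itertools.product((False, True), repeat=4):
        p_pattern = 1.0
        observed = set(mother.alleles)
        for (allele, d), dropped in zip(fetal_copies, pattern):
            if dropped:
                p_pattern *= d
            else:
                p_pattern *= 1 - d
                observed.add(allele)
        if c == 0:
            if observed == E:
                total += p_pattern
            continue
        # no visible drop-in: either none occurred, or it hit an allele
        # already observed
        if observed == E:
            total += p_pattern * ((1 - c) + c * sum(support[a] for a in observed))
        for a, p_a in support.items():
            if a not in observed and observed | {a} == E:
                total += p_pattern * c * p_a
    return total


def oracle_locus_likelihood(
    evidence: EvidenceLocus,
    mother: Genotype,
    af: Genotype,
    hyp: Hypothesis,
    params: MixtureParams,
    freqs: FrequencyTable,
) -> float:
    """Double loop over fetal genotype priors times the enumeration oracle."""
    extras = sorted(
        set(evidence.observed_alleles) | set(mother.alleles) | set(af.alleles)
    )
    conditioning = tuple(mother.alleles) + tuple(af.alleles)

    def prior(father):
        return child_genotype_prior(
            mother,
            father,
            freqs,
            r=params.mutation_rate,
            theta=params.theta,
            extra_alleles=extras,
            conditioning=conditioning,
        )

    def joint(p1, p2):
        return sum(
            pa * pb * oracle_mixture_likelihood(evidence, mother, g1, g2, params, freqs)
            for g1, pa in p1.items()
            for g2, pb in p2.items()
        )

    p_af, p_pop = prior(af), prior(POPULATION)
    if hyp is Hypothesis.H1:
        return joint(p_af, p_af)
    if hyp is Hypothesis.H2:
        return 0.5 * (joint(p_af, p_pop) + joint(p_pop, p_af))
    return joint(p_pop, p_pop)


def all_evidence_sets(universe):
    """Every non-empty subset of the locus allele universe."""
    universe = sorted(universe)
    for r in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, r):
            yield frozenset(combo)
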