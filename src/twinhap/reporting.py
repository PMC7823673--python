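"""Case orchestration, cohort summaries, and the packaged reference table.

``run_case`` ties the stages together — plasma calls → zygosity → fetal
fraction → paternity LRs → validation against fetal reference genotypes —
and produces a flat report record suitable for
:func:`twinhap.io.write_report`.

The packaged file ``data/twin_cohort_summary.tsv`` is a transcription of
the published per-case summary statistics of a 19-pregnancy twin validation
cohort (13 dizygotic, 6 monozygotic): assumed and real paternal-allele
counts, dropout/drop-in tallies, detection rates, and estimated vs.
validated fetal fractions. It is the worked-example dataset for the
documentation and test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from typing import Any, Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .calls import DEFAULT_MIN_DEPTH, DEFAULT_THRESHOLD, CaseCallSet, call_case
from .datamodel import FrequencyTable, GenotypeProfile, PlasmaProfile
from .errors import TwinhapError, ValidationError
from .kinship import (
    DEFAULT_GRID_VALUES,
    LRResult,
    MixtureParams,
    compute_lr,
    default_grid,
    evidence_from_plasma,
)
from .zygosity import (
    FFEstimate,
    ValidationSummary,
    Zygosity,
    ZygosityResult,
    call_zygosity,
    estimate_ff,
    ff_concordance,
    ff_ratio,
    validate_against_fetal_genotypes,
    validated_ff,
    zygosity_from_informative_count,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters for a pipeline run; serialisable to JSON."""

    threshold: float = DEFAULT_THRESHOLD
    min_depth: int = DEFAULT_MIN_DEPTH
    min_informative: int = 1
    grid_values: Tuple[float, ...] = DEFAULT_GRID_VALUES
    drop_in: float = 0.01
    mutation_rate: float = 1e-8
    theta: float = 0.0
    unseen_freq: float = 0.002
    seed: int = 0

    def params(self) -> MixtureParams:
        return MixtureParams(
            drop_in=self.drop_in,
            mutation_rate=self.mutation_rate,
            theta=self.theta,
        )

    def grid(self) -> List[Tuple[float, float]]:
        return default_grid(self.grid_values)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "grid_values" in data:
            data["grid_values"] = tuple(data["grid_values"])
        return cls(**data)


@dataclass
class CaseReport:
    """Full per-case result bundle plus the flat report record."""

    case_id: str
    config: RunConfig
    calls: CaseCallSet
    zygosity: ZygosityResult
    ff: FFEstimate
    lr: Optional[LRResult] = None
    validation: Optional[ValidationSummary] = None
    ff_validated: Optional[FFEstimate] = None

    def record(self) -> Dict[str, Any]:
        """Flat record mirroring the cohort summary table layout."""
        pct = lambda x: None if x is None else 100 * x
        rec: Dict[str, Any] = {
            "case_id": self.case_id,
            "zygosity": self.zygosity.call.value,
            "n_locus_pa": self.calls.n_loci_with_pa,
            "n_informative": self.calls.n_informative,
            "n_assumed_pa": self.calls.n_assumed_pa,
            "est_ff_lower_pct": pct(self.ff.ff_lower),
            "est_ff_higher_pct": pct(self.ff.ff_higher),
            "est_ff_combined_pct": pct(self.ff.ff_combined),
            "ff_ratio": ff_ratio(self.ff) if self.ff.is_dz else None,
        }
        if self.lr is not None:
            rec["min_cum_log10_lr_h1h3"] = self.lr.min_cumulative(0)
            rec["max_cum_log10_lr_h1h3"] = self.lr.max_cumulative(0)
            rec["min_cum_log10_lr_h2h3"] = self.lr.min_cumulative(1)
        if self.validation is not None:
            rec.update(
                n_real_pa=self.validation.n_real_pa,
                n_real_informative=self.validation.n_real_informative,
                n_dropout=self.validation.n_dropout,
                n_dropin=self.validation.n_dropin,
                detection_rate_pct=100 * self.validation.detection_rate,
            )
        if self.ff_validated is not None:
            rec.update(
                val_ff_lower_pct=pct(self.ff_validated.ff_lower),
                val_ff_higher_pct=pct(self.ff_validated.ff_higher),
                val_ff_combined_pct=pct(self.ff_validated.ff_combined),
            )
        rec["config"] = asdict(self.config)
        return rec


def run_case(
    config: RunConfig,
    plasma: PlasmaProfile,
    maternal: GenotypeProfile,
    af: Optional[GenotypeProfile] = None,
    freqs: Optional[FrequencyTable] = None,
    fetal1: Optional[GenotypeProfile] = None,
    fetal2: Optional[GenotypeProfile] = None,
) -> CaseReport:
    """Run call → zygosity → FF (→ LR → validation) for one case.

    Without an AF profile (or frequency table) the LR stage is skipped with
    a warning — zygosity and FF need no paternal sample. Validation runs
    only when both fetal reference profiles are given.
    """

    def _stage(name, fn):
        try:
            return fn()
        except TwinhapError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    calls = _stage(
        "call",
        lambda: call_case(plasma, maternal, config.threshold, config.min_depth),
    )
    zygosity = _stage("zygosity", lambda: call_zygosity(calls, config.min_informative))
    ff = _stage("ff", lambda: estimate_ff(calls, zygosity))
    lr = None
    if af is not None and freqs is not None:
        evidence = evidence_from_plasma(plasma, config.threshold, config.min_depth)
        lr = _stage(
            "lr",
            lambda: compute_lr(
                evidence,
                maternal,
                af,
                freqs,
                config.grid(),
                config.params(),
                case_id=plasma.case_id,
            ),
        )
    else:
        logger.warning(
            "case %s: no alleged-father profile or frequency table; LR skipped",
            plasma.case_id,
        )
    validation = ff_val = None
    if fetal1 is not None and fetal2 is not None:
        validation = _stage(
            "validate",
            lambda: validate_against_fetal_genotypes(
                calls, fetal1, fetal2, maternal, plasma
            ),
        )
        ff_val = _stage(
            "validate", lambda: validated_ff(plasma, maternal, fetal1, fetal2)
        )
    return CaseReport(
        case_id=plasma.case_id,
        config=config,
        calls=calls,
        zygosity=zygosity,
        ff=ff,
        lr=lr,
        validation=validation,
        ff_validated=ff_val,
    )


def cohort_summary(
    reports: Sequence[CaseReport],
    truths: Optional[Sequence] = None,
) -> Dict[str, Any]:
    """Aggregate a cohort: MZ/DZ counts, FF ranges, detection-rate range,
    the R² concordance triple when validation is present, and a zygosity
    confusion matrix when simulation truths are supplied."""
    if not reports:
        raise ValidationError("cohort summary needs at least one report")
    summary: Dict[str, Any] = {
        "n_cases": len(reports),
        "n_dz": sum(1 for r in reports if r.zygosity.call is Zygosity.DZ),
        "n_mz": sum(1 for r in reports if r.zygosity.call is Zygosity.MZ),
    }
    combined = [r.ff.ff_combined for r in reports]
    summary["ff_combined_range"] = (min(combined), max(combined))
    dz_ff = [r.ff for r in reports if r.ff.is_dz]
    if dz_ff:
        summary["ff_lower_range"] = (
            min(f.ff_lower for f in dz_ff),
            max(f.ff_lower for f in dz_ff),
        )
        summary["ff_higher_range"] = (
            min(f.ff_higher for f in dz_ff),
            max(f.ff_higher for f in dz_ff),
        )
    rates = [r.validation.detection_rate for r in reports if r.validation]
    if rates:
        summary["detection_rate_range"] = (min(rates), max(rates))
    validated = [r.ff_validated for r in reports if r.ff_validated is not None]
    estimates = [r.ff for r in reports if r.ff_validated is not None]
    if sum(1 for v in validated if v.is_dz) >= 3:
        summary["r2_lower"], summary["r2_higher"], summary["r2_combined"] = (
            ff_concordance(estimates, validated)
        )
    if truths is not None:
        truth_by_case = {t.case_id: t for t in truths}
        confusion = {("MZ", "MZ"): 0, ("MZ", "DZ"): 0, ("DZ", "MZ"): 0, ("DZ", "DZ"): 0}
        for r in reports:
            t = truth_by_case.get(r.case_id)
            if t is not None:
                confusion[(t.scenario.zygosity, r.zygosity.call.value)] += 1
        summary["zygosity_confusion"] = confusion
    return summary


# ---------------------------------------------------------------------------
# packaged reference cohort table


def load_cohort_table() -> pd.DataFrame:
    """Load the transcribed 19-case cohort summary table.

    Numeric columns come back as floats with NaN where the published table
    prints NA (per-fetus FFs of monozygotic cases).
    """
    with resources.files("twinhap.data").joinpath(
        "twin_cohort_summary.tsv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(
            fh, sep="\t", dtype={"case_id": str}, na_values=["NA"]
        )


def cohort_table_zygosity(min_informative: int = 1) -> List[ZygosityResult]:
    """Apply the informative-locus rule to the reference table's per-case
    Type III locus counts."""
    table = load_cohort_table()
    return [
        zygosity_from_informative_count(
            row.case_id, int(row.n_informative), min_informative
        )
        for row in table.itertuples(index=False)
    ]


def cohort_table_ff_estimates() -> Tuple[List[FFEstimate], List[FFEstimate]]:
    """Estimated and validated FF columns of the reference table as
    :class:`FFEstimate` pairs (fractions, not percent)."""
    table = load_cohort_table()
    est, val = [], []
    for row in table.itertuples(index=False):
        dz = pd.notna(row.est_ff_lower_pct)
        est.append(
            FFEstimate(
                case_id=row.case_id,
                ff_lower=row.est_ff_lower_pct / 100 if dz else None,
                ff_higher=row.est_ff_higher_pct / 100 if dz else None,
                ff_combined=row.est_ff_combined_pct / 100,
                n_loci_used=int(row.n_informative),
            )
        )
        val.append(
            FFEstimate(
                case_id=row.case_id,
                ff_lower=row.val_ff_lower_pct / 100 if dz else None,
                ff_higher=row.val_ff_higher_pct / 100 if dz else None,
                ff_combined=row.val_ff_combined_pct / 100,
                n_loci_used=int(row.n_real_informative),
            )
        )
    return est, val
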