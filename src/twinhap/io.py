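"""Readers and writers for the package's tab-separated input tables.

Three TSV dialects are accepted (tab-delimited, UTF-8, header row required —
no delimiter sniffing, for determinism):

* frequency table:   columns ``locus, allele, frequency``
* genotype profiles: columns ``sample, locus, allele1, allele2``
* plasma counts:     columns ``case, locus, allele, depth``

Reports are written as TSV or JSON with a deterministic column order;
percentage fields are rendered with 2 decimals and log10 likelihood ratios
with 3 decimals.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Dict, List, Mapping, Sequence, Union

import pandas as pd

from .datamodel import (
    DEFAULT_UNSEEN_FREQ,
    FrequencyTable,
    Genotype,
    GenotypeProfile,
    PlasmaLocusCounts,
    PlasmaProfile,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_frequency_table(
    path: PathLike, unseen_freq: float = DEFAULT_UNSEEN_FREQ
) -> FrequencyTable:
    """Read a per-locus allele frequency TSV into a :class:`FrequencyTable`.

    Raises :class:`FormatError` for missing columns or non-numeric
    frequencies and :class:`ValidationError` for out-of-range frequencies or
    per-locus sums exceeding 1.
    """
    df = _read_tsv(path, ("locus", "allele", "frequency"))
    entries: Dict[str, Dict[str, float]] = {}
    for row in df.itertuples(index=False):
        try:
            freq = float(row.frequency)
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric frequency {row.frequency!r} at locus "
                f"{row.locus!r}"
            ) from exc
        locus_map = entries.setdefault(str(row.locus), {})
        if row.allele in locus_map:
            raise ValidationError(
                f"{path}: duplicate allele {row.allele!r} at locus {row.locus!r}"
            )
        locus_map[str(row.allele)] = freq
    return FrequencyTable(entries, unseen_freq=unseen_freq)


def read_genotype_profiles(path: PathLike) -> Dict[str, GenotypeProfile]:
    """Read every sample in a genotype TSV, keyed by sample id."""
    df = _read_tsv(path, ("sample", "locus", "allele1", "allele2"))
    profiles: Dict[str, GenotypeProfile] = {}
    for row in df.itertuples(index=False):
        if not row.allele1 or not row.allele2:
            raise ValidationError(
                f"{path}: empty allele field for sample {row.sample!r} locus "
                f"{row.locus!r}"
            )
        profile = profiles.setdefault(
            str(row.sample), GenotypeProfile(str(row.sample))
        )
        profile.add(Genotype(str(row.locus), (str(row.allele1), str(row.allele2))))
    return profiles


def read_genotype_profile(path: PathLike, sample_id: str | None = None) -> GenotypeProfile:
    """Read one genotype profile; the file must hold a single sample unless
    ``sample_id`` selects one."""
    profiles = read_genotype_profiles(path)
    if sample_id is not None:
        try:
            return profiles[sample_id]
        except KeyError as exc:
            raise ValidationError(f"{path}: no sample {sample_id!r}") from exc
    if len(profiles) != 1:
        raise ValidationError(
            f"{path}: expected one sample, found {sorted(profiles)}; "
            "pass sample_id to select"
        )
    return next(iter(profiles.values()))


def read_plasma_profiles(path: PathLike) -> Dict[str, PlasmaProfile]:
    """Read every case in a plasma count TSV, keyed by case id.

    Depths must be non-negative integers; zero-depth rows are dropped. An
    empty file yields an empty mapping with a logged warning.
    """
    df = _read_tsv(path, ("case", "locus", "allele", "depth"))
    if df.empty:
        logger.warning("%s: empty plasma table", path)
        return {}
    raw: Dict[str, Dict[str, Dict[str, int]]] = {}
    for row in df.itertuples(index=False):
        try:
            depth = int(row.depth)
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-integer depth {row.depth!r} at locus {row.locus!r}"
            ) from exc
        if depth < 0:
            raise ValidationError(
                f"{path}: negative depth {depth} at case {row.case!r} locus "
                f"{row.locus!r}"
            )
        locus_map = raw.setdefault(str(row.case), {}).setdefault(str(row.locus), {})
        locus_map[str(row.allele)] = locus_map.get(str(row.allele), 0) + depth
    profiles: Dict[str, PlasmaProfile] = {}
    for case_id, loci in raw.items():
        profile = PlasmaProfile(case_id)
        for locus_id, depth_map in loci.items():
            profile.add(PlasmaLocusCounts(locus_id, depth_map))
        profiles[case_id] = profile
    return profiles


def read_plasma_profile(path: PathLike, case_id: str | None = None) -> PlasmaProfile:
    """Read one plasma profile (single-case file, or select by ``case_id``)."""
    profiles = read_plasma_profiles(path)
    if case_id is not None:
        try:
            return profiles[case_id]
        except KeyError as exc:
            raise ValidationError(f"{path}: no case {case_id!r}") from exc
    if len(profiles) == 0:
        return PlasmaProfile("")
    if len(profiles) != 1:
        raise ValidationError(
            f"{path}: expected one case, found {sorted(profiles)}; "
            "pass case_id to select"
        )
    return next(iter(profiles.values()))


# ---------------------------------------------------------------------------
# report writing

#: field-name suffixes that pick the rendering rule
_PCT_DECIMALS = 2
_LOG10_DECIMALS = 3


def format_value(key: str, value: Any) -> str:
    """Render one report cell.

    Fields named ``*_pct`` (percentages) get 2 decimals; fields containing
    ``log10`` get 3 decimals; ``None`` renders as ``NA``. Rounding is the
    IEEE default (round half to even).
    """
    if value is None:
        return "NA"
    if isinstance(value, float):
        if key.endswith("_pct") or key.endswith("_rate_pct"):
            return f"{value:.{_PCT_DECIMALS}f}"
        if "log10" in key:
            return f"{value:.{_LOG10_DECIMALS}f}"
        return repr(value)
    return str(value)


def write_report(
    records: Sequence[Mapping[str, Any]],
    path: PathLike,
    format: str = "tsv",
) -> None:
    """Write result records to ``path`` as TSV or JSON.

    Column order follows the key order of the first record; records missing a
    key render ``NA``. An empty record list yields a header-only TSV (or an
    empty JSON list).
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    path = Path(path)
    try:
        if format == "json":
            with open(path, "w", encoding="utf-8") as fh:
                json.dump([dict(r) for r in records], fh, indent=1, sort_keys=False)
                fh.write("\n")
            return
        columns: List[str] = list(records[0].keys()) if records else []
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(columns) + "\n")
            for rec in records:
                fh.write(
                    "\t".join(format_value(c, rec.get(c)) for c in columns) + "\n"
                )
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report_json(path: PathLike) -> List[Dict[str, Any]]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# table writers (inverse of the readers; floats use repr for exact
# round-trips)


def write_frequency_table(table: FrequencyTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("locus\tallele\tfrequency\n")
        for locus_id in table.loci:
            for allele, freq in table.entries[locus_id].items():
                fh.write(f"{locus_id}\t{allele}\t{freq!r}\n")


def write_genotype_profiles(
    profiles: Sequence[GenotypeProfile], path: PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tlocus\tallele1\tallele2\n")
        for profile in profiles:
            for locus_id in sorted(profile.genotypes):
                a1, a2 = profile.genotypes[locus_id].alleles
                fh.write(f"{profile.sample_id}\t{locus_id}\t{a1}\t{a2}\n")


def write_plasma_profiles(profiles: Sequence[PlasmaProfile], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("case\tlocus\tallele\tdepth\n")
        for profile in profiles:
            for locus_id in sorted(profile.loci):
                counts = profile.loci[locus_id]
                for allele in sorted(counts.depth):
                    fh.write(
                        f"{profile.case_id}\t{locus_id}\t{allele}\t"
                        f"{counts.depth[allele]}\n"
                    )
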