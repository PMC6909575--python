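"""Cross-species table assembly and correlation analyses.

A species panel is a TSV with one row per species carrying cytological
genome size measurements (C-values, pg), assembly size (Mb), genomic GC%
(GC_G), TE fraction of the genome, consensus-level TE GC (GC_TE) and the
GC of the repeat-masked / non-repetitive assembly fractions (GC_REP,
GC_NONREP).  The analyses test the compositional relationships seen across
fish genomes: bigger genomes carry more TEs, bigger genomes are GC-poorer
(once salmonids — rediploidized after their lineage-specific whole-genome
duplication, with hugely amplified GC-rich rRNA arrays — are excluded),
and TE GC tracks host genome GC both at the consensus level and between the
repetitive and non-repetitive fractions.

Both Pearson and Spearman statistics are computed for every analysis;
Spearman is reported first because genome size is heavy-tailed.  Missing
data are handled by pairwise-complete deletion, never imputation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .composition import MB_PER_PG

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesRecord",
    "CorrelationResult",
    "InsufficientDataError",
    "load_species_table",
    "write_species_table",
    "mean_c_value",
    "apply_filters",
    "FILTER_REGISTRY",
    "correlate",
    "analysis_suite",
    "AnalysisReport",
    "SPECIES_TABLE_COLUMNS",
]

SPECIES_TABLE_COLUMNS = [
    "species_id",
    "short_code",
    "lineage_flags",
    "c_values_pg",
    "assembly_size_mb",
    "gc_genome",
    "te_percent",
    "gc_te",
    "gc_rep",
    "gc_nonrep",
]

_PERCENT_FIELDS = ("gc_genome", "te_percent", "gc_te", "gc_rep", "gc_nonrep")


class InsufficientDataError(ValueError):
    """Fewer than three complete pairs remain after filtering."""


@dataclass
class SpeciesRecord:
    """One row of the cross-species panel; missing values are None."""

    species_id: str
    short_code: str = ""
    lineage_flags: frozenset = frozenset()
    c_values_pg: Tuple[float, ...] = ()
    assembly_size_mb: Optional[float] = None
    gc_genome: Optional[float] = None
    te_percent: Optional[float] = None
    gc_te: Optional[float] = None
    gc_rep: Optional[float] = None
    gc_nonrep: Optional[float] = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.c_values_pg):
            raise ValueError(
                f"{self.species_id}: C-values must be positive, got {self.c_values_pg}"
            )
        for name in _PERCENT_FIELDS:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.species_id}: {name}={v} outside [0, 100]")


def mean_c_value(record: SpeciesRecord) -> Optional[float]:
    """Arithmetic mean of a species' C-value measurements (pg); None if none.

    Multiple cytological records for one species are averaged rather than
    picked from.
    """
    if not record.c_values_pg:
        return None
    return sum(record.c_values_pg) / len(record.c_values_pg)


def _get_variable(record: SpeciesRecord, var: str) -> Optional[float]:
    if var == "size_pg":
        return mean_c_value(record)
    if var == "size_mb":
        return record.assembly_size_mb
    if var in _PERCENT_FIELDS:
        return getattr(record, var)
    raise KeyError(f"unknown analysis variable {var!r}")


def _parse_cell(value: str, column: str, line_no: int) -> Optional[float]:
    value = value.strip()
    if value in ("", ".", "NA", "nan"):
        return None
    try:
        return float(value)
    except ValueError:
        raise ValueError(
            f"line {line_no}: cannot parse {column}={value!r} as a number"
        ) from None


def load_species_table(path: Union[str, Path]) -> List[SpeciesRecord]:
    """Read a species metadata TSV into typed records.

    Expected columns are :data:`SPECIES_TABLE_COLUMNS`; unknown columns are
    warned about and ignored; missing cells ("", "." or NA) become missing
    values, never zeros.  Multiple C-values live in one cell separated by
    ";"; lineage flags are "|"-separated.  Numeric parse failures and
    invariant violations raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in SPECIES_TABLE_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns in %s: %s", path, unknown)
    if "species_id" not in df.columns:
        raise ValueError(f"{path}: species table must have a species_id column")

    records: List[SpeciesRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        cvals: Tuple[float, ...] = ()
        raw_c = row.get("c_values_pg", "") or ""
        if raw_c.strip() not in ("", "."):
            cvals = tuple(
                _parse_cell(tok, "c_values_pg", line_no)
                for tok in raw_c.split(";")
                if tok.strip() not in ("", ".")
            )
        flags = frozenset(
            tok.strip()
            for tok in (row.get("lineage_flags", "") or "").split("|")
            if tok.strip()
        )
        kwargs = {
            col: _parse_cell(row.get(col, "") or "", col, line_no)
            for col in ("assembly_size_mb", *_PERCENT_FIELDS)
        }
        try:
            records.append(
                SpeciesRecord(
                    species_id=row["species_id"].strip(),
                    short_code=(row.get("short_code", "") or "").strip(),
                    lineage_flags=flags,
                    c_values_pg=cvals,
                    **kwargs,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from None
    return records


def _fmt_opt(x: Optional[float], nd: int = 4) -> str:
    return "." if x is None else f"{x:.{nd}f}"


def write_species_table(records: Sequence[SpeciesRecord], path: Union[str, Path]) -> None:
    """Write records back to the TSV dialect read by :func:`load_species_table`."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SPECIES_TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.species_id,
                        r.short_code or ".",
                        "|".join(sorted(r.lineage_flags)) or ".",
                        ";".join(f"{c:.4f}" for c in r.c_values_pg) or ".",
                        _fmt_opt(r.assembly_size_mb),
                        _fmt_opt(r.gc_genome),
                        _fmt_opt(r.te_percent),
                        _fmt_opt(r.gc_te),
                        _fmt_opt(r.gc_rep),
                        _fmt_opt(r.gc_nonrep),
                    ]
                )
                + "\n"
            )


# --- filters -----------------------------------------------------------------

def _exclude_salmonids(record: SpeciesRecord) -> bool:
    return "salmonid" not in record.lineage_flags


def _teleosts_only(record: SpeciesRecord) -> bool:
    return "teleost" in record.lineage_flags


def _require_variables(variables: Sequence[str]) -> Callable[[SpeciesRecord], bool]:
    def predicate(record: SpeciesRecord) -> bool:
        return all(_get_variable(record, v) is not None for v in variables)

    return predicate


FILTER_REGISTRY: Dict[str, Callable] = {
    "exclude_salmonids": _exclude_salmonids,
    "teleosts_only": _teleosts_only,
    "require_variables": _require_variables,
}


def _resolve_filter(spec) -> Tuple[str, Callable[[SpeciesRecord], bool]]:
    """Resolve a filter given as a name, "require_variables(a,b)" string, or
    (name, args) tuple, against the registry."""
    if callable(spec):
        return getattr(spec, "__name__", "custom"), spec
    if isinstance(spec, tuple):
        name, args = spec
    else:
        name, args = str(spec), None
        if "(" in name and name.endswith(")"):
            name, inner = name[:-1].split("(", 1)
            args = [a.strip() for a in inner.split(",") if a.strip()]
    if name not in FILTER_REGISTRY:
        raise ValueError(f"unknown filter {name!r}; known: {sorted(FILTER_REGISTRY)}")
    entry = FILTER_REGISTRY[name]
    if args is not None:
        return f"{name}({','.join(args)})", entry(args)
    return name, entry


def apply_filters(
    records: Sequence[SpeciesRecord], filters: Iterable = ()
) -> Tuple[List[SpeciesRecord], List[Tuple[str, str]]]:
    """Apply named filters; returns (kept, exclusion log).

    The exclusion log is a list of ``(species_id, filter_name)`` pairs; a
    species appears once, attributed to the first filter that dropped it.
    ``len(kept) + len(log) == len(records)`` always holds.
    """
    resolved = [_resolve_filter(f) for f in filters]
    kept: List[SpeciesRecord] = []
    excluded: List[Tuple[str, str]] = []
    for rec in records:
        for name, pred in resolved:
            if not pred(rec):
                excluded.append((rec.species_id, name))
                break
        else:
            kept.append(rec)
    return kept, excluded


# --- correlation -------------------------------------------------------------

@dataclass
class CorrelationResult:
    x_var: str
    y_var: str
    method: str  # "pearson" | "spearman"
    n: int
    coefficient: Optional[float]
    p_value: Optional[float]
    filter_description: str = ""
    excluded: List[str] = field(default_factory=list)


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    return float(rxc @ ryc) / denom


def exact_spearman_p(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p-value.

    Enumerates all n! assignments of the y ranks (average ranks for ties)
    and counts those with |rho| at least the observed, so the p-value is the
    exact permutation-null tail probability.  Only sensible for small n.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = _rank_pearson(rx, ry)
    n = len(rx)
    threshold = abs(rho_obs) - 1e-12
    hits = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        if abs(_rank_pearson(rx, np.asarray(perm))) >= threshold:
            hits += 1
    return rho_obs, hits / total


#: Largest n for which the Spearman p-value is computed by exhaustive
#: permutation enumeration (8! = 40320 evaluations) rather than the
#: large-sample t approximation.
EXACT_SPEARMAN_MAX_N = 8


def correlate(
    records: Sequence[SpeciesRecord],
    x_var: str,
    y_var: str,
    method: str = "spearman",
    filters: Iterable = (),
    exact_max_n: int = EXACT_SPEARMAN_MAX_N,
) -> CorrelationResult:
    """Correlate two panel variables over pairwise-complete species.

    Variables: ``size_pg`` (mean C-value), ``size_mb``, ``gc_genome``,
    ``te_percent``, ``gc_te``, ``gc_rep``, ``gc_nonrep``.  Spearman uses
    average ranks for ties and an exact permutation p-value when
    n <= ``exact_max_n``.  Fewer than 3 complete pairs raises
    :class:`InsufficientDataError`; zero variance yields an undefined
    coefficient (None) rather than an error.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    kept, excluded = apply_filters(records, filters)
    pairs = [
        (xv, yv, rec.species_id)
        for rec in kept
        for xv, yv in [(_get_variable(rec, x_var), _get_variable(rec, y_var))]
        if xv is not None and yv is not None
    ]
    filter_desc = ",".join(_resolve_filter(f)[0] for f in filters) or "none"
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError(
            f"{x_var} vs {y_var}: only {n} complete pairs after filters ({filter_desc})"
        )
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    excluded_ids = [sp for sp, _ in excluded]

    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.warning("%s vs %s: zero variance, coefficient undefined", x_var, y_var)
        coef, p = None, None
    elif method == "pearson":
        r = stats.pearsonr(x, y)
        coef, p = float(r.statistic), float(r.pvalue)
    else:
        if n <= exact_max_n:
            coef, p = exact_spearman_p(x, y)
        else:
            r = stats.spearmanr(x, y)
            coef, p = float(r.statistic), float(r.pvalue)
    return CorrelationResult(
        x_var=x_var,
        y_var=y_var,
        method=method,
        n=n,
        coefficient=coef,
        p_value=p,
        filter_description=filter_desc,
        excluded=excluded_ids,
    )


# --- the full analysis suite -------------------------------------------------

#: (analysis name, x, y, filters) — the panel-level relationships examined:
#: TE load vs genome size, GC vs genome size on both size scales with and
#: without salmonids, TE GC vs host GC, and repeat vs non-repeat GC.
SUITE_ANALYSES: Sequence[Tuple[str, str, str, Tuple[str, ...]]] = (
    ("size_vs_te", "size_pg", "te_percent", ()),
    ("size_vs_gc_excl_salmonids", "size_pg", "gc_genome", ("exclude_salmonids",)),
    ("size_vs_gc_incl_salmonids", "size_pg", "gc_genome", ()),
    ("assembly_size_vs_gc", "size_mb", "gc_genome", ()),
    ("gc_te_vs_gc_genome", "gc_te", "gc_genome", ()),
    ("gc_rep_vs_gc_nonrep", "gc_nonrep", "gc_rep", ()),
)


@dataclass
class AnalysisReport:
    """Bundle of correlation results plus the per-species GC_TE sign table."""

    results: List[CorrelationResult]
    sign_table: pd.DataFrame
    skipped: List[Tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "analysis": f"{r.x_var}~{r.y_var}",
                    "x": r.x_var,
                    "y": r.y_var,
                    "method": r.method,
                    "n": r.n,
                    "coefficient": r.coefficient,
                    "p_value": r.p_value,
                    "filter": r.filter_description,
                    "excluded_n": len(r.excluded),
                }
            )
        return pd.DataFrame(rows)


def analysis_suite(
    records: Sequence[SpeciesRecord],
    methods: Sequence[str] = ("spearman", "pearson"),
) -> AnalysisReport:
    """Run every panel analysis with both correlation methods.

    Analyses lacking enough data are skipped with a logged reason, never
    silently.  The sign table lists, per species, GC_TE minus GC_G and
    whether the TE consensus pool is GC-richer than its host genome —
    across real fish panels the difference is positive in nearly all
    species.
    """
    results: List[CorrelationResult] = []
    skipped: List[Tuple[str, str]] = []
    for name, x, y, filters in SUITE_ANALYSES:
        for method in methods:
            try:
                results.append(correlate(records, x, y, method, filters))
            except InsufficientDataError as exc:
                logger.warning("skipping %s (%s): %s", name, method, exc)
                skipped.append((f"{name}:{method}", str(exc)))

    rows = []
    for rec in records:
        if rec.gc_te is None or rec.gc_genome is None:
            continue
        diff = rec.gc_te - rec.gc_genome
        rows.append(
            {
                "species_id": rec.species_id,
                "gc_genome": rec.gc_genome,
                "gc_te": rec.gc_te,
                "gc_te_minus_gc_genome": diff,
                "te_gc_richer": diff > 0,
            }
        )
    sign_table = pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "gc_genome",
            "gc_te",
            "gc_te_minus_gc_genome",
            "te_gc_richer",
        ],
    )
    return AnalysisReport(results=results, sign_table=sign_table, skipped=skipped)
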