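"""TE consensus library parsing, classification, and pooled GC (GC_TE).

Libraries such as those distributed by FishTEDB or Repbase name each
consensus ``name#Class/Superfamily`` (the RepeatMasker two-level scheme).
Classification here normalizes that string into the Class I / Class II
dichotomy of TE biology: Class I retrotransposons (LTR, LINE, SINE, DIRS,
Penelope, Retroposon) move via RNA intermediates; Class II DNA transposons
(TcMar, hAT, CMC, PIF-Harbinger, Helitron, Maverick, ...) move via DNA
intermediates.  Helitrons (``RC/``) count as Class II by the standard
Wicker/RepeatMasker convention; Penelope counts as Class I (retroelement by
mechanism).  Both assignments are configurable.

GC_TE is consensus-level: each family's consensus counts once, unweighted
by its genomic copy number, so the statistic approximates TEs at their time
of insertion rather than their present genomic distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

from .composition import (
    BaseCounts,
    SequenceRecord,
    count_bases,
    gc_percent,
    read_fasta,
)

__all__ = [
    "CLASS_I",
    "CLASS_II",
    "UNKNOWN",
    "NON_TE",
    "ClassificationTable",
    "DEFAULT_TABLE",
    "TEConsensus",
    "TEGroupGC",
    "SpeciesTEProfile",
    "parse_te_header",
    "load_te_library",
    "species_gc_te",
    "pool_groups_across_species",
    "group_table",
    "class_contrast",
]

CLASS_I = "I"
CLASS_II = "II"
UNKNOWN = "unknown"
NON_TE = "non-TE"


@dataclass(frozen=True)
class ClassificationTable:
    """Mapping from RepeatMasker-style top-level tokens to TE classes.

    ``composite_preserve`` lists superfamily tokens that contain a hyphen
    but are themselves the superfamily name (PIF-Harbinger), so they are
    not collapsed to their leading token the way CMC-EnSpm -> CMC is.
    """

    class1_orders: frozenset = frozenset(
        {"LINE", "SINE", "LTR", "DIRS", "Retroposon", "Penelope"}
    )
    class2_orders: frozenset = frozenset({"DNA", "RC"})
    non_te_categories: frozenset = frozenset(
        {
            "Simple_repeat",
            "Low_complexity",
            "Satellite",
            "rRNA",
            "tRNA",
            "snRNA",
            "scRNA",
            "ARTEFACT",
        }
    )
    composite_preserve: frozenset = frozenset({"PIF-Harbinger"})


DEFAULT_TABLE = ClassificationTable()


@dataclass
class TEConsensus:
    """One consensus sequence with its parsed TE taxonomy."""

    name: str
    te_class: str  # CLASS_I | CLASS_II | UNKNOWN | NON_TE
    group: str  # order for Class I (LTR, LINE, ...); superfamily for Class II
    superfamily_raw: str
    record: SequenceRecord


def _collapse_superfamily(token: str, table: ClassificationTable) -> str:
    for preserved in table.composite_preserve:
        if token == preserved or token.startswith(preserved + "-"):
            return preserved
    return token.split("-", 1)[0]


def parse_te_header(
    description: str, table: ClassificationTable = DEFAULT_TABLE
) -> tuple[str, str, str, str]:
    """Parse a ``name#Class/Superfamily`` header into taxonomy fields.

    Returns ``(name, te_class, group, superfamily_raw)``.  Anything
    unparseable degrades to ``(description, "unknown", "Unknown", "")``
    rather than raising; the raw classification string is always retained
    for audit.
    """
    head = description.split(None, 1)[0] if description else ""
    if "#" not in head:
        return (head or description, UNKNOWN, "Unknown", "")
    name, raw = head.split("#", 1)
    if not raw:
        return (name or description, UNKNOWN, "Unknown", raw)
    top, _, rest = raw.partition("/")
    if top in table.non_te_categories:
        return (name, NON_TE, top, raw)
    if top in table.class1_orders:
        return (name, CLASS_I, top, raw)
    if top in table.class2_orders:
        if rest:
            group = _collapse_superfamily(rest.partition("/")[0], table)
        else:
            # "RC" alone can only mean a rolling-circle Helitron.
            group = "Helitron" if top == "RC" else "Unknown"
        return (name, CLASS_II, group, raw)
    return (name, UNKNOWN, "Unknown", raw)


def load_te_library(
    path: Union[str, Path], table: ClassificationTable = DEFAULT_TABLE
) -> List[TEConsensus]:
    """Load a consensus library FASTA into classified :class:`TEConsensus`.

    Record order is preserved.  Zero-length records are retained (so the
    library round-trips) but excluded from GC pooling downstream.
    """
    out = []
    for rec in read_fasta(path):
        name, te_class, group, raw = parse_te_header(rec.description, table)
        out.append(
            TEConsensus(
                name=name,
                te_class=te_class,
                group=group,
                superfamily_raw=raw,
                record=rec,
            )
        )
    return out


@dataclass
class TEGroupGC:
    """Pooled GC over every consensus of one TE group (order/superfamily)."""

    group: str
    te_class: str
    n_families: int
    pooled_counts: BaseCounts
    gc: Optional[float]

    @classmethod
    def from_counts(
        cls, group: str, te_class: str, n_families: int, counts: BaseCounts
    ) -> "TEGroupGC":
        return cls(
            group=group,
            te_class=te_class,
            n_families=n_families,
            pooled_counts=counts,
            gc=gc_percent(counts).gc_percent,
        )


@dataclass
class SpeciesTEProfile:
    """Consensus-level GC_TE of one species' TE library.

    All values pool base counts over consensus sequences, each family
    counted once (copy-number-unweighted).  Families of unknown class enter
    ``gc_te_overall`` but not the class-level values; non-TE categories
    (simple repeats, satellites, structural RNAs) never enter any value.
    """

    species_id: str
    n_te_families: int
    gc_te_overall: Optional[float]
    gc_class1: Optional[float]
    gc_class2: Optional[float]
    per_group: Dict[str, TEGroupGC]
    pooled_counts: BaseCounts


def species_gc_te(
    library: Iterable[TEConsensus],
    species_id: str = "",
    include_classes: Optional[Sequence[str]] = None,
) -> SpeciesTEProfile:
    """Pool a species' consensus library into a :class:`SpeciesTEProfile`.

    ``include_classes`` restricts pooling to the given TE classes (default:
    Class I + Class II + unknown).  Non-TE entries and empty records are
    always excluded.
    """
    allowed = (
        set(include_classes)
        if include_classes is not None
        else {CLASS_I, CLASS_II, UNKNOWN}
    )
    allowed.discard(NON_TE)

    overall = BaseCounts()
    by_class: Dict[str, BaseCounts] = {CLASS_I: BaseCounts(), CLASS_II: BaseCounts()}
    group_counts: Dict[str, BaseCounts] = {}
    group_class: Dict[str, str] = {}
    group_n: Dict[str, int] = {}
    n_families = 0

    for te in library:
        if te.te_class not in allowed or not te.record.residues:
            continue
        counts = count_bases(te.record.residues)
        n_families += 1
        overall += counts
        if te.te_class in by_class:
            by_class[te.te_class] += counts
        key = te.group
        if key not in group_counts:
            group_counts[key] = BaseCounts()
            group_class[key] = te.te_class
            group_n[key] = 0
        group_counts[key] += counts
        group_n[key] += 1

    per_group = {
        g: TEGroupGC.from_counts(g, group_class[g], group_n[g], group_counts[g])
        for g in group_counts
    }
    return SpeciesTEProfile(
        species_id=species_id,
        n_te_families=n_families,
        gc_te_overall=gc_percent(overall).gc_percent,
        gc_class1=gc_percent(by_class[CLASS_I]).gc_percent,
        gc_class2=gc_percent(by_class[CLASS_II]).gc_percent,
        per_group=per_group,
        pooled_counts=overall,
    )


def pool_groups_across_species(
    profiles: Sequence[SpeciesTEProfile], mode: str = "pooled_bases"
) -> List[TEGroupGC]:
    """Aggregate per-group GC across a species panel.

    ``pooled_bases`` sums base counts per group over all species and takes
    GC of the pool; ``mean_of_species`` averages the per-species group GC
    values unweighted.  The two agree exactly when every species contributes
    the same number of counted bases to a group.  Groups absent from every
    species are simply not present in the output.
    """
    if not profiles:
        raise ValueError("need at least one species profile")
    if mode not in {"pooled_bases", "mean_of_species"}:
        raise ValueError(f"unknown aggregation mode {mode!r}")

    groups: Dict[str, List[TEGroupGC]] = {}
    for prof in profiles:
        for g, ggc in prof.per_group.items():
            groups.setdefault(g, []).append(ggc)

    out: List[TEGroupGC] = []
    for g in sorted(groups):
        members = groups[g]
        te_class = members[0].te_class
        n_fam = sum(m.n_families for m in members)
        if mode == "pooled_bases":
            pooled = BaseCounts()
            for m in members:
                pooled += m.pooled_counts
            out.append(TEGroupGC.from_counts(g, te_class, n_fam, pooled))
        else:
            vals = [m.gc for m in members if m.gc is not None]
            mean = sum(vals) / len(vals) if vals else None
            pooled = BaseCounts()
            for m in members:
                pooled += m.pooled_counts
            out.append(
                TEGroupGC(
                    group=g,
                    te_class=te_class,
                    n_families=n_fam,
                    pooled_counts=pooled,
                    gc=mean,
                )
            )
    return out


def group_table(profiles: Sequence[SpeciesTEProfile]):
    """Cross-species per-group GC table with both aggregation modes.

    Returns a pandas DataFrame with columns ``group, class, n_families,
    n_species, gc_pooled, gc_mean_of_species``.
    """
    import pandas as pd

    pooled = {g.group: g for g in pool_groups_across_species(profiles, "pooled_bases")}
    mean = {g.group: g for g in pool_groups_across_species(profiles, "mean_of_species")}
    n_species = {
        g: sum(1 for p in profiles if g in p.per_group) for g in pooled
    }
    rows = [
        {
            "group": g,
            "class": pooled[g].te_class,
            "n_families": pooled[g].n_families,
            "n_species": n_species[g],
            "gc_pooled": pooled[g].gc,
            "gc_mean_of_species": mean[g].gc,
        }
        for g in sorted(pooled)
    ]
    return pd.DataFrame(rows)


def class_contrast(profile: SpeciesTEProfile) -> Optional[float]:
    """Class I minus Class II pooled GC, in percentage points.

    Positive when retrotransposons are GC-richer than DNA transposons.
    Undefined (None) when either class has no counted bases.
    """
    if profile.gc_class1 is None or profile.gc_class2 is None:
        return None
    return profile.gc_class1 - profile.gc_class2
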