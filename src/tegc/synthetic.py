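"""Synthetic species panels with planted compositional structure.

The generator emulates the three inputs of the comparative analysis — a
soft-masked genome assembly per species, a TE consensus library per species,
and a species metadata table — with known ("planted") parameters, so every
pipeline stage can be tested for parameter recovery without downloading any
public dataset.

Planted structure, per panel:

* genome size uniform over a range; TE fraction rises linearly with size
  (larger genomes are TE-richer) and background GC falls linearly with size
  (larger genomes are GC-poorer), both with Gaussian scatter;
* a per-species coupling pulls every TE group's GC toward the species'
  background GC, so TE GC tracks host GC across the panel and the repeat
  fraction's GC tracks the non-repetitive fraction's GC;
* Class I retrotransposon consensi are GC-richer than Class II DNA
  transposon consensi by a fixed offset, with group-level spread around the
  class means (DIRS richest, CMC poorest);
* a fraction of species is flagged "salmonid" and gets an inflated genome
  size together with a GC boost, off the panel's size-GC trend — these
  species weaken the negative size-GC correlation unless excluded, the
  situation whole-genome-duplicated, rRNA-amplified salmonids create in
  real panels.

Sequences are i.i.d. per base (no isochore-scale autocorrelation, no indels,
no family phylogenies): sufficient for composition statistics, unrealistic
for windowed or alignment analyses.  TE copies inserted into genomes are
point-mutated at a configurable rate; because a substitution picks one of
the other three bases uniformly, mutation drifts copy GC toward 50%, which
the recorded realized truth reflects.

Determinism: one scalar seed drives a splittable per-species substream
(numpy ``SeedSequence.spawn``), so identical seeds give byte-identical
output trees and panels can be extended without disturbing earlier species.
"""

from __future__ import annotations

import gzip
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .composition import (
    BaseCounts,
    GenomePartition,
    SequenceRecord,
    count_bases,
    gc_percent,
    partition_genome,
)
from .cross_species import SpeciesRecord, write_species_table
from .te_library import CLASS_I, CLASS_II, TEConsensus, parse_te_header, species_gc_te

__all__ = [
    "GroupSpec",
    "PanelSpec",
    "DEFAULT_GROUPS",
    "LibraryTruth",
    "GenomeTruth",
    "SpeciesTruth",
    "PanelResult",
    "generate_te_library",
    "generate_genome",
    "generate_panel",
    "write_library_fasta",
    "write_genome_fasta",
]

#: RepeatMasker-style classification string written into synthetic headers,
#: chosen so the parser assigns the intended class and group.
_CLASS_STRINGS: Dict[str, str] = {
    "LTR": "LTR/Gypsy",
    "LINE": "LINE/L2",
    "SINE": "SINE/tRNA",
    "DIRS": "DIRS/DIRS",
    "Penelope": "Penelope/Penelope",
    "CMC": "DNA/CMC-EnSpm",
    "TcMar": "DNA/TcMar-Tc1",
    "hAT": "DNA/hAT-Ac",
    "PIF-Harbinger": "DNA/PIF-Harbinger",
    "Helitron": "RC/Helitron",
    "Maverick": "DNA/Maverick",
}


@dataclass(frozen=True)
class GroupSpec:
    """One TE group in the panel profile.

    ``gc_offset`` is the group's GC deviation (percentage points) from its
    class mean; offsets within a class should sum to ~0 so the class-level
    contrast stays at the planted value.
    """

    name: str
    te_class: str  # CLASS_I or CLASS_II
    gc_offset: float
    n_families: int = 6
    length_range: Tuple[int, int] = (500, 5000)


#: Six groups, three per class.  DIRS is the GC-richest group and CMC the
#: poorest, mirroring the ordering seen in fish consensus libraries.
DEFAULT_GROUPS: Tuple[GroupSpec, ...] = (
    GroupSpec("LTR", CLASS_I, 0.0),
    GroupSpec("LINE", CLASS_I, -5.0),
    GroupSpec("DIRS", CLASS_I, +5.0),
    GroupSpec("CMC", CLASS_II, -5.0),
    GroupSpec("TcMar", CLASS_II, 0.0),
    GroupSpec("hAT", CLASS_II, +5.0),
)


@dataclass
class PanelSpec:
    """Planted parameters of a synthetic species panel.

    Defaults give a 30-species panel of ~2 Mb genomes: TE fraction climbing
    from ~10% to ~40% and background GC falling from ~45% to ~37% over the
    size range, TE-library GC centred at 44% and coupled to background GC,
    Class I consensi 6 points GC-richer than Class II, and one fifth of the
    species salmonid-flagged with inflated size and boosted GC.
    """

    n_species: int = 30
    seed: int = 0
    size_range_mb: Tuple[float, float] = (1.0, 3.0)
    te_slope: float = 15.0  # TE % of genome per Mb
    te_intercept: float = -5.0
    gc_slope: float = -4.0  # background GC % per Mb
    gc_intercept: float = 49.0
    noise_sd: float = 1.5  # Gaussian scatter on TE% and GC%, percentage points
    te_gc_center: float = 44.0  # panel-level centre of TE consensus GC
    class1_gc_offset: float = 6.0  # Class I minus Class II consensus GC
    gc_te_coupling: float = 0.8  # TE GC shift per point of background GC deviation
    group_profile: Tuple[GroupSpec, ...] = DEFAULT_GROUPS
    copy_mutation_rate: float = 0.02  # per-base substitutions on inserted copies
    salmonid_fraction: float = 0.2
    salmonid_size_factor: float = 1.9
    salmonid_gc_boost: float = 3.5
    n_gap_runs: int = 2
    gap_run_length: int = 500

    def group_gc_targets(self, shift: float = 0.0) -> Dict[str, float]:
        """Panel-level target GC per group, optionally shifted per species."""
        out = {}
        for g in self.group_profile:
            class_half = (
                +self.class1_gc_offset / 2.0
                if g.te_class == CLASS_I
                else -self.class1_gc_offset / 2.0
            )
            out[g.name] = self.te_gc_center + class_half + g.gc_offset + shift
        return out


@dataclass
class LibraryTruth:
    """Planted vs realized composition of one synthetic consensus library."""

    group_target_gc: Dict[str, float]
    group_realized_gc: Dict[str, float]
    group_bases: Dict[str, int]
    class_target_gc: Dict[str, float]
    class_realized_gc: Dict[str, Optional[float]]
    overall_realized_gc: Optional[float]


@dataclass
class GenomeTruth:
    """Planted vs realized composition of one synthetic assembly."""

    size_bp: int
    planted_gc_background: float
    planted_te_percent: float
    expected_copy_gc: float  # library GC after mutation drift toward 50%
    te_bases: int
    gap_bases: int
    realized_repeat_fraction: float
    realized_gc_rep: Optional[float]
    realized_gc_nonrep: Optional[float]
    realized_gc_genome: Optional[float]


@dataclass
class SpeciesTruth:
    species_id: str
    short_code: str
    lineage_flags: frozenset
    planted_size_mb: float
    planted_gc_background: float
    planted_te_percent: float
    gc_te_shift: float
    library: LibraryTruth
    genome: GenomeTruth


@dataclass
class PanelResult:
    spec: PanelSpec
    species: List[SpeciesTruth]
    records: List[SpeciesRecord]  # metadata rows with realized (measured) values
    libraries: List[List[TEConsensus]]
    genomes: Optional[List[SequenceRecord]] = None
    outdir: Optional[Path] = None


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """n i.i.d. uppercase bases (uint8 array) at the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = np.searchsorted(np.cumsum(p), rng.random(n), side="right")
    return _BASES[np.minimum(idx, 3)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Symmetric point substitutions: each hit base becomes one of the other
    three uniformly (drifts GC toward 50%)."""
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size == 0:
        return seq
    out = seq.copy()
    # index of current base in _BASES, shifted by 1..3 mod 4 -> a different base
    cur = np.searchsorted(_BASES, out[hits])  # _BASES is sorted (A<C<G<T)
    out[hits] = _BASES[(cur + rng.integers(1, 4, hits.size)) % 4]
    return out


def generate_te_library(
    seed_or_rng,
    group_targets: Dict[str, float],
    group_profile: Sequence[GroupSpec] = DEFAULT_GROUPS,
) -> Tuple[List[TEConsensus], LibraryTruth]:
    """Generate one species' consensus library at the given group GC targets.

    For each group, ``n_families`` consensi with lengths uniform over the
    group's length range and bases i.i.d. at the group target GC; headers
    follow the ``name#Class/Superfamily`` dialect so they round-trip through
    the library parser.
    """
    rng = _as_rng(seed_or_rng)
    profile = [g for g in group_profile if g.name in group_targets]
    if not profile or all(g.n_families == 0 for g in profile):
        raise ValueError("group profile plants zero TE families")

    consensi: List[TEConsensus] = []
    group_counts: Dict[str, BaseCounts] = {}
    class_counts: Dict[str, BaseCounts] = {CLASS_I: BaseCounts(), CLASS_II: BaseCounts()}
    overall = BaseCounts()
    for g in profile:
        target = group_targets[g.name] / 100.0
        tally = BaseCounts()
        for i in range(g.n_families):
            length = int(rng.integers(g.length_range[0], g.length_range[1] + 1))
            seq = _random_bases(rng, length, target).tobytes().decode("ascii")
            header = f"{g.name}-{i + 1}_SYN#{_CLASS_STRINGS[g.name]}"
            rec = SequenceRecord(
                identifier=header, description=header, residues=seq
            )
            name, te_class, group, raw = parse_te_header(header)
            assert te_class == g.te_class and group == g.name, header
            consensi.append(
                TEConsensus(
                    name=name,
                    te_class=te_class,
                    group=group,
                    superfamily_raw=raw,
                    record=rec,
                )
            )
            tally += count_bases(seq)
        group_counts[g.name] = tally
        class_counts[g.te_class] += tally
        overall += tally

    class_targets: Dict[str, List[float]] = {}
    for g in profile:
        class_targets.setdefault(g.te_class, []).append(group_targets[g.name])
    truth = LibraryTruth(
        group_target_gc={g.name: group_targets[g.name] for g in profile},
        group_realized_gc={
            name: gc_percent(c).gc_percent for name, c in group_counts.items()
        },
        group_bases={name: c.counted() for name, c in group_counts.items()},
        class_target_gc={
            cls: sum(v) / len(v) for cls, v in class_targets.items()
        },
        class_realized_gc={
            cls: gc_percent(c).gc_percent for cls, c in class_counts.items()
        },
        overall_realized_gc=gc_percent(overall).gc_percent,
    )
    return consensi, truth


def generate_genome(
    seed_or_rng,
    size_bp: int,
    gc_background: float,
    te_percent: float,
    library: Sequence[TEConsensus],
    copy_mutation_rate: float = 0.02,
    n_gap_runs: int = 2,
    gap_run_length: int = 500,
    identifier: str = "chr1",
) -> Tuple[SequenceRecord, GenomeTruth]:
    """Assemble one soft-masked synthetic chromosome.

    Non-repetitive background is drawn i.i.d. at ``gc_background``
    (uppercase); TE copies are sampled uniformly from the library consensi,
    point-mutated, truncated as needed to hit the TE base budget exactly,
    lowercased, and spliced in at uniform positions.  Uppercase N runs model
    assembly gaps.  Realized composition is measured back from the finished
    sequence and recorded in the truth.
    """
    if not 0 <= te_percent < 100:
        raise ValueError(f"te_percent must be in [0, 100), got {te_percent}")
    if not library:
        raise ValueError("TE library is empty")
    rng = _as_rng(seed_or_rng)

    te_budget = int(round(size_bp * te_percent / 100.0))
    gap_bases = n_gap_runs * gap_run_length
    if te_budget + gap_bases >= size_bp:
        raise ValueError(
            f"TE bases ({te_budget}) + gaps ({gap_bases}) exceed genome size {size_bp}"
        )

    consensi = [
        np.frombuffer(te.record.residues.upper().encode("ascii"), dtype=np.uint8)
        for te in library
        if te.record.residues
    ]
    copies: List[np.ndarray] = []
    total = 0
    while total < te_budget:
        src = consensi[int(rng.integers(len(consensi)))]
        copy = _mutate(rng, src, copy_mutation_rate)
        if total + copy.size > te_budget:
            copy = copy[: te_budget - total]
        # lowercase = soft mask (ASCII upper + 32)
        copies.append(copy + 32)
        total += copy.size

    background = _random_bases(rng, size_bp - te_budget - gap_bases, gc_background / 100.0)
    inserts = copies + [
        np.full(gap_run_length, ord("N"), dtype=np.uint8) for _ in range(n_gap_runs)
    ]
    order = rng.permutation(len(inserts))
    positions = np.sort(rng.integers(0, background.size + 1, size=len(inserts)))
    segments: List[np.ndarray] = []
    prev = 0
    for pos, k in zip(positions, order):
        segments.append(background[prev:pos])
        segments.append(inserts[k])
        prev = pos
    segments.append(background[prev:])
    seq = np.concatenate(segments).tobytes().decode("ascii")

    part = partition_genome(seq)
    lib_gc = gc_percent(count_bases(te.record.residues for te in library)).gc_percent
    r = copy_mutation_rate
    expected_copy_gc = (
        None
        if lib_gc is None
        else lib_gc * (1 - 4 * r / 3) + 100.0 * 2 * r / 3
    )
    truth = GenomeTruth(
        size_bp=size_bp,
        planted_gc_background=gc_background,
        planted_te_percent=te_percent,
        expected_copy_gc=expected_copy_gc,
        te_bases=total,
        gap_bases=gap_bases,
        realized_repeat_fraction=part.repeat_fraction,
        realized_gc_rep=part.gc_rep,
        realized_gc_nonrep=part.gc_nonrep,
        realized_gc_genome=part.gc_genome,
    )
    return SequenceRecord(identifier=identifier, description=identifier, residues=seq), truth


def _wrap_fasta(header: str, seq: str, width: int = 80) -> str:
    lines = [f">{header}"]
    lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    if not seq:
        pass
    return "\n".join(lines) + "\n"


def write_library_fasta(library: Sequence[TEConsensus], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for te in library:
            fh.write(_wrap_fasta(te.record.description, te.record.residues))


def write_genome_fasta(record: SequenceRecord, path: Union[str, Path]) -> None:
    """Write a genome FASTA; gzip (with zeroed mtime, for reproducible bytes)
    when the path ends in .gz."""
    text = _wrap_fasta(record.description, record.residues)
    path = Path(path)
    if path.suffix == ".gz":
        with open(path, "wb") as raw:
            with gzip.GzipFile(
                fileobj=raw, mode="wb", filename="", mtime=0, compresslevel=2
            ) as gz:
                gz.write(text.encode("ascii"))
    else:
        path.write_text(text, encoding="ascii", newline="\n")


def generate_panel(
    spec: PanelSpec,
    outdir: Optional[Union[str, Path]] = None,
    write_genomes: bool = True,
    keep_genomes: bool = False,
) -> PanelResult:
    """Generate a full species panel and, optionally, write it to disk.

    When ``outdir`` is given the layout is ``genomes/<id>.fa.gz``,
    ``te_libs/<id>.fa``, ``species_table.tsv`` (metadata with *measured*
    values, directly loadable by the cross-species module) and ``truth.tsv``
    / ``truth_groups.tsv`` (planted and realized parameters).  Genome
    sequences are held in memory only if ``keep_genomes`` is set.
    """
    rng_panel = np.random.default_rng(np.random.SeedSequence(spec.seed))
    substreams = np.random.SeedSequence(spec.seed).spawn(spec.n_species)

    lo, hi = spec.size_range_mb
    sizes = rng_panel.uniform(lo, hi, spec.n_species)
    n_salmonid = int(round(spec.salmonid_fraction * spec.n_species))
    salmonid_idx = set(
        rng_panel.choice(spec.n_species, size=n_salmonid, replace=False).tolist()
    )
    gc_center = spec.gc_intercept + spec.gc_slope * (lo + hi) / 2.0

    species: List[SpeciesTruth] = []
    records: List[SpeciesRecord] = []
    libraries: List[List[TEConsensus]] = []
    genomes: List[SequenceRecord] = []

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        (out / "genomes").mkdir(parents=True, exist_ok=True)
        (out / "te_libs").mkdir(parents=True, exist_ok=True)

    for i in range(spec.n_species):
        rng = np.random.default_rng(substreams[i])
        is_salmonid = i in salmonid_idx
        base_size = sizes[i]
        gc_bg = spec.gc_intercept + spec.gc_slope * base_size + rng.normal(0, spec.noise_sd)
        size_mb = base_size
        if is_salmonid:
            size_mb = base_size * spec.salmonid_size_factor
            gc_bg += spec.salmonid_gc_boost
        te_pct = spec.te_intercept + spec.te_slope * size_mb + rng.normal(0, spec.noise_sd)
        te_pct = float(np.clip(te_pct, 2.0, 70.0))
        gc_bg = float(np.clip(gc_bg, 25.0, 60.0))

        shift = spec.gc_te_coupling * (gc_bg - gc_center)
        targets = spec.group_gc_targets(shift)

        species_id = f"Synthopterus sp{i + 1:02d}"
        short = f"S{i + 1:02d}"
        library, lib_truth = generate_te_library(rng, targets, spec.group_profile)
        genome_rec, gen_truth = generate_genome(
            rng,
            size_bp=int(round(size_mb * 1e6)),
            gc_background=gc_bg,
            te_percent=te_pct,
            library=library,
            copy_mutation_rate=spec.copy_mutation_rate,
            n_gap_runs=spec.n_gap_runs,
            gap_run_length=spec.gap_run_length,
            identifier=f"{short}_chr1",
        )

        profile = species_gc_te(library, species_id=species_id)
        k = int(rng.integers(1, 4))
        c_true = size_mb * 1e6 / (978.0 * 1e6)
        cvals = tuple(
            float(c_true * (1 + rng.normal(0, 0.01))) for _ in range(k)
        )
        flags = frozenset({"teleost", "salmonid"}) if is_salmonid else frozenset({"teleost"})
        rec = SpeciesRecord(
            species_id=species_id,
            short_code=short,
            lineage_flags=flags,
            c_values_pg=cvals,
            assembly_size_mb=round(size_mb, 4),
            gc_genome=gen_truth.realized_gc_genome,
            te_percent=100.0 * gen_truth.realized_repeat_fraction,
            gc_te=profile.gc_te_overall,
            gc_rep=gen_truth.realized_gc_rep,
            gc_nonrep=gen_truth.realized_gc_nonrep,
        )
        truth = SpeciesTruth(
            species_id=species_id,
            short_code=short,
            lineage_flags=flags,
            planted_size_mb=float(size_mb),
            planted_gc_background=gc_bg,
            planted_te_percent=te_pct,
            gc_te_shift=float(shift),
            library=lib_truth,
            genome=gen_truth,
        )
        species.append(truth)
        records.append(rec)
        libraries.append(library)
        if keep_genomes:
            genomes.append(genome_rec)
        if out is not None:
            write_library_fasta(library, out / "te_libs" / f"{short}.fa")
            if write_genomes:
                write_genome_fasta(genome_rec, out / "genomes" / f"{short}.fa.gz")

    if out is not None:
        write_species_table(records, out / "species_table.tsv")
        _write_truth(spec, species, out)

    return PanelResult(
        spec=spec,
        species=species,
        records=records,
        libraries=libraries,
        genomes=genomes if keep_genomes else None,
        outdir=out,
    )


def _write_truth(spec: PanelSpec, species: List[SpeciesTruth], out: Path) -> None:
    with open(out / "truth.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "species_id\tlineage_flags\tplanted_size_mb\tplanted_gc_background\t"
            "planted_te_percent\tgc_te_shift\trealized_repeat_fraction\t"
            "realized_gc_rep\trealized_gc_nonrep\trealized_gc_genome\n"
        )
        for s in species:
            g = s.genome
            fh.write(
                f"{s.species_id}\t{'|'.join(sorted(s.lineage_flags))}\t"
                f"{s.planted_size_mb:.6f}\t{s.planted_gc_background:.6f}\t"
                f"{s.planted_te_percent:.6f}\t{s.gc_te_shift:.6f}\t"
                f"{g.realized_repeat_fraction:.6f}\t{g.realized_gc_rep:.6f}\t"
                f"{g.realized_gc_nonrep:.6f}\t{g.realized_gc_genome:.6f}\n"
            )
    with open(out / "truth_groups.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("species_id\tgroup\ttarget_gc\trealized_gc\tcounted_bases\n")
        for s in species:
            for grp, target in s.library.group_target_gc.items():
                fh.write(
                    f"{s.species_id}\t{grp}\t{target:.6f}\t"
                    f"{s.library.group_realized_gc[grp]:.6f}\t"
                    f"{s.library.group_bases[grp]}\n"
                )
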