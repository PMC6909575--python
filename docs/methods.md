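# Methods

## Problem and quantities

Fish genomes are AT/GC-homogeneous and their size, transposable-element (TE)
load, and GC content covary: larger genomes carry proportionally more TEs and
tend to be GC-poorer, while the GC of a species' TEs tracks the GC of its
host genome. `tegc` computes the composition statistics this kind of
comparative analysis rests on and tests their relationships across a species
panel:

* **GC_G** — GC% of a whole assembly;
* **GC_REP / GC_NONREP** — GC% of the repeat-masked (lowercase) versus
  non-repetitive (uppercase) fraction of a soft-masked assembly;
* **GC_TE** — GC% of a species' TE consensus library, every family pooled
  once, *unweighted* by genomic copy number, so the statistic approximates
  TEs at their time of insertion rather than their present genomic
  distribution. A copy-number-weighted mobilome GC is deliberately out of
  scope;
* **isochore band** — the classical L/H classification of a GC percentage.

## Composition conventions

GC% is `100·(G+C)/(A+C+G+T)` over unambiguous bases only. N, IUPAC ambiguity
codes (including S, which *is* G/C) and gap symbols are excluded from both
numerator and denominator. This is the common assembly-GC convention and it
makes the partition identity exact: with `c_rep`, `c_nonrep` counted bases,

```
c_rep·GC_REP + c_nonrep·GC_NONREP = (c_rep + c_nonrep)·GC_G
```

which the test suite checks to 1e-9 relative tolerance on arbitrary input.
Databases differ in whether Ns enter the denominator, so GC values quoted
from external resources may differ slightly from recomputed ones; no
convention choice can reproduce all of them.

Lowercase means repeat-masked (soft-masking, as in Ensembl `_sm` dumps);
uppercase N means assembly gap. Hard-masked (N-for-repeat) input is not
supported: it is indistinguishable from gaps, so a genome with zero lowercase
bases triggers a warning and an undefined GC_REP rather than a silent zero.
U is counted as T because some consensus libraries contain RNA-alphabet
entries. GC over an empty base set is undefined (`None`, written `.` in
TSV), never zero.

Isochore bands must tile [0, 100] to give a total classifier, but the
classical definitions leave gaps (36→37, 40→41, 45→46, 52→53). The default
closes them downward with half-open intervals — sub-L1 [0,34), L1 [34,37),
L2 [37,41), H1 [41,46), H2 [46,53), H3 [53,100] — and the boundaries are an
argument, not a constant. The pg→Mb constant (978 Mb/pg) is likewise a
configurable default used only for cross-checks; analyses accept either size
scale natively.

## TE classification

Headers follow the RepeatMasker two-level scheme `name#Class/Superfamily`.
The mapping is table-driven: `DNA/*` and `RC/*` (Helitrons, by the standard
Wicker/RepeatMasker convention) are Class II; `LINE/*`, `SINE/*`, `LTR/*`,
`DIRS/*`, `Retroposon/*`, `Penelope/*` (retroelement by mechanism) are
Class I; `Simple_repeat`, `Low_complexity`, `Satellite`, structural RNAs and
`ARTEFACT` are non-TE and never enter TE statistics. The group label is the
order token for Class I and the superfamily token for Class II, with
composite names collapsed to their leading superfamily (`CMC-EnSpm` → `CMC`,
`TcMar-Tc1` → `TcMar`; `PIF-Harbinger` is itself a superfamily and is
preserved). Anything unmatched is `unknown`/`Unknown` — included in the
overall GC_TE, excluded from class-level values — and the raw classification
string is always retained for audit.

Cross-species per-group aggregation is reported in two modes because they
answer different questions and sources differ in which they use:
`pooled_bases` (sum the base counts over species, then take GC; the default)
and `mean_of_species` (unweighted mean of per-species group GC). They agree
exactly when species contribute equal counted-base totals.

## Correlation analysis

Each analysis correlates two panel variables over pairwise-complete species
(no imputation): genome size — as mean C-value in pg, averaging multiple
cytological records, or as assembly Mb — against TE%, GC_G, and GC_TE, and
GC_REP against GC_NONREP. Both Pearson and Spearman are computed; Spearman
is reported first because genome size is heavy-tailed. Spearman uses average
ranks for ties; its p-value is an exact two-sided permutation probability
(enumeration of all n! rank assignments) for n ≤ 8 and the large-sample t
approximation above that. Fewer than three complete pairs is an error; zero
variance yields an undefined coefficient, flagged rather than raised.

The salmonid filter exists because rediploidized, rRNA-amplified salmonid
genomes are simultaneously very large and GC-enriched, sitting off the
size–GC trend of other fish; the suite runs the size–GC analysis both with
and without them so the contrast is visible, and every exclusion is logged
by species and filter. No phylogenetic correction (PIC/PGLS) is applied and
p-values are reported raw, without multiple-testing correction; both are
documented limitations, not oversights.

## Synthetic panels

The generator plants known structure so every stage can be checked for
recovery:

| parameter | default | meaning |
|---|---|---|
| `n_species` | 30 | panel size |
| `size_range_mb` | 1–3 | genome size, uniform (≈2 Mb: large enough for tight binomial tolerances, small enough to run in seconds) |
| `te_slope`, `te_intercept` | 15 %/Mb, −5 | TE% of genome vs size → ~10–40% |
| `gc_slope`, `gc_intercept` | −4 %/Mb, 49 | background GC vs size → ~45–37% |
| `noise_sd` | 1.5 | Gaussian scatter on both relations (points) |
| `te_gc_center` | 44 | panel centre of consensus GC |
| `class1_gc_offset` | 6 | Class I minus Class II consensus GC (points) |
| `gc_te_coupling` | 0.8 | TE-GC shift per point of background-GC deviation |
| `copy_mutation_rate` | 0.02 | per-base substitutions on inserted copies |
| `salmonid_fraction` | 0.2 | species flagged salmonid, ×1.9 size, +3.5 GC |

Six TE groups (LTR, LINE, DIRS / CMC, TcMar, hAT; six families each,
0.5–5 kb) sit ±5 points around their class means, DIRS richest and CMC
poorest. Per species, every group target is shifted by
`coupling · (background GC − panel centre)`, which is what makes GC_TE track
GC_G and GC_REP track GC_NONREP across the panel. Genomes are background
bases drawn i.i.d. at the background GC, TE copies sampled uniformly from
the library, point-mutated, lowercased and spliced in at uniform positions,
plus two 500 bp uppercase-N gap runs. A substitution picks one of the other
three bases uniformly, so expected copy GC drifts toward 50% as
`gc·(1 − 4r/3) + 200r/3`; the recorded truth carries both the planted
targets and the realized (post-sampling) values, and tolerances for recovery
tests come from binomial sampling theory at the generated lengths.

What the generator does **not** emulate: isochore-scale autocorrelation
(bases are i.i.d.), TE nesting/fragmentation, indels, family phylogenies,
copy-number variation between families, and any mechanistic GC process
(gene conversion, methylation spillover). Passing recovery tests therefore
demonstrates the correctness of the composition and correlation machinery
under known truth — not that real genomes satisfy the planted model.

The metadata table written by `simulate` carries *measured* values (the
realized GC and repeat fractions of the generated sequences), so the
downstream analysis closes the loop end to end; planted parameters live in
`truth.tsv`/`truth_groups.tsv`.

## Determinism and numerics

One scalar seed drives a `numpy.random.SeedSequence` with per-species spawned
substreams. Gzip output zeroes the archive mtime and run logs record input
paths relative to the output directory, so two runs with the same seed are
byte-identical wherever they are rooted (hash-checked in tests). GC values
are carried at full double precision internally; report TSVs round GC to one
decimal and coefficients to three. The default test suite and the acceptance
script use the 30-species/~2 Mb panel plus miniature (0.2–0.9 Mb) panels with
proportionally steeper planted slopes, keeping the whole validation run to
well under a minute of sequence simulation.
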