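# Methods

## The document model

An HXMS document is three ordered sections. The metadata section is a set of
tab-delimited lines, `METADATA<TAB>TITLE<TAB>VALUE` (or `REMARK` for
free-form notes), carrying four required conditions — the protein sequence,
temperature in Kelvin, the uncorrected pH-meter reading pH(read), and the
D2O saturation fraction in (0, 1] — plus the optional protein name and
state. The experimental section is one fixed-width `TP` line per peptide
timepoint with columns `INDEX, MOD, START, END, REP, PTM_ID, TIME(SEC),
UPTAKE, ENVELOPE` (character widths 12, 8, 7, 7, 7, 5, 8, 16, 9; the
envelope is unbounded and comma-separated). The PTM section is a lookup
table from 4-digit identifiers to modification descriptions; `0000` is
reserved for "no modification" and never appears as a dictionary entry.

Invariants enforced by `validate()`: spans are 1-based, inclusive, and lie
inside the sequence; `INDEX` runs 0, 1, 2, … file-wide, one per physical
line (including each mode of a bimodal peptide); `MOD` is a single letter
A–Z; every non-zero `PTM_ID` resolves in the dictionary; a file is either
entirely full-spectrum or entirely centroid-level. Validation reports
rather than throws: each finding has a severity (ERROR for a broken
invariant, WARNING for legal-but-suspicious data such as an envelope sum
off by more than 1e-3 but at most 1e-2, or a duplicated measurement) and a
record locator, in deterministic order.

Two points the format's description leaves open were decided here and are
conventions of this implementation: `INDEX` is a file-wide serial (not
restarted per peptide), and each mode of a multimodal peptide occupies its
own line with its own index.

## Serialization

Write strictly, read liberally. The writer left-justifies and space-pads
every bounded field to its published width, so the first nine fields of a
record sit at character offsets 0, 12, 20, 27, 34, 41, 46, 54, 70; a value
that cannot fit its field aborts with an overflow error rather than
shifting its neighbours. Times are printed in 6-fractional-digit scientific
notation (`0.000000e+00`), with fully deuterated samples as `inf`. Uptake
is printed with two decimals, envelope peaks with three (matching the
format's printed examples; the stated "4 per peak" is ambiguous between
characters and digits, and three decimals reproduces every example).
Metadata numbers use the shortest decimal representation that round-trips
the double exactly, so `293.15` is written back as `293.15` byte-for-byte.
Rounding happens only at serialization; all computation is done in full
precision.

The reader accepts fixed-width or tab-delimited data lines (record fields
never contain spaces, so a whitespace split recovers fixed-width fields;
PTM content can contain spaces and is sliced by column offsets instead),
skips blank lines and `#` comments, tolerates out-of-order sections with a
warning, and treats unknown line tags or malformed time tokens as parse
errors carrying the line number. Reading a written file reproduces the
document exactly, and re-writing it reproduces the bytes.

## Centroids and uptake

With normalized peak intensities p₀ … p_{k−1} at an assumed exact 1 Da
spacing, the centroid is Σᵢ i·pᵢ, in Daltons relative to the first reported
peak (charge-state deconvolution is assumed done upstream). Uptake is
centroid(t) − centroid(0) per peptide and replicate, so the 0 s record is
exactly zero. When a replicate lacks a 0 s sample its reference is the
arithmetic mean of the zero-centroids of the replicates that have one; when
a sub-population ("B" mode and beyond) has no 0 s sample in any replicate it
borrows the "A" population's reference, since zero-time samples are
typically unimodal — that fallback is a documented convention of this
package, not a requirement of the format.

## Converters

Each supported export dialect is described declaratively in
`hxms.converters.DIALECTS`: its column names, time unit, fully-deuterated
labels, and capability flags (whether it reports uptake directly, carries
PTMs, carries spectra). The dialect schemas themselves are conventions of
this package — the upstream programs are named but their export layouts
vary by version — so the maps are configuration, versioned with the code,
not hard-wired parsing. DynamX-style exposures are minutes (that vendor's
convention) and are converted to seconds; the other dialects use seconds.
Replicates come from a replicate or run-identifier column when the dialect
has one; otherwise rows of the same (peptide, state, mode, time) group are
numbered in input order and a warning is logged. Distinct modification
strings receive PTM ids `0001`, `0002`, … in order of first appearance over
the records sorted by (start, end, time, replicate, mode), which makes the
assignment a pure function of the input bytes. Multi-state exports produce
one HXMS document per state; `convert()` refuses an ambiguous multi-state
input rather than guessing, and `convert_all_states()` (used by the CLI)
emits one file per state. The custom CSV embeds the metadata block above
its data table, so it needs no separate conditions.

## The synthetic generator

`hxms.synthetic` emulates the data shapes the format must carry, not the
physics of exchange. A peptide of length L is given n = max(L − 2, 1)
exchangeable sites (the N-terminal residues' fast back-exchange is the
usual reason to discount two); deuteration follows a single-exponential
p(t) = sat·(1 − e^(−kt)) with one rate constant k per peptide (defaults
0.005, 0.02, 0.08 s⁻¹ across the three default peptides, spanning
slow-to-fast exchange over the default 0/15/60/600 s time course), and the
fully deuterated control sits at p = sat. The envelope is
Binomial(n, p) convolved with a fixed natural-abundance-like base envelope
(0.60, 0.27, 0.10, 0.03), so the true centroid is the base centroid plus
n·p exactly — an analytic oracle — and zero-timepoint centroids are
non-zero, which actually exercises the zero-reference arithmetic.
Truncated Gaussian intensity noise (default sd 0.01 per peak, a typical
relative-intensity scatter for well-behaved spectra) is added before
renormalization. Default conditions: the 18-residue example sequence,
293.15 K, pH(read) 6.0, D2O saturation 0.91, two replicates.

What the generator does not emulate — per-residue intrinsic rate
heterogeneity (Bai–Englander rates), back-exchange during quench and
separation, charge-state and m/z-accuracy effects, peak-picking errors —
bounds what passing tests show: they demonstrate that the format, math and
converters are correct on data of realistic shape, not that any upstream
peak assignment is.

Ground truth for the emitted fixtures (uptakes, record ordering, PTM ids)
is computed by a plain-loop implementation inside the generator that shares
no code with `hxms.envelopes` or the converters, so converter tests compare
two independent routes to the same numbers. Fixture envelopes are rounded
to six decimals before both the CSV is written and the truth is computed,
keeping oracle and file consistent. All randomness flows through one seeded
NumPy generator; a fixed seed yields byte-identical fixture files.

## Numerical choices and degenerate inputs

Envelope normalization rejects empty, all-zero or negative input rather
than guessing. Centroid comparisons in tests use absolute tolerances of
1e-9 (closed-form and cross-route checks) or 1e-12 (hand-computed
examples); the binomial mass function is computed with exact integer
combinatorics (`math.comb`) to keep the oracle sharp. Ties and orderings
are all lexicographic and stable: records sort by (start, end, time,
replicate, mode) with `inf` last, states keep first-appearance order, and
validation findings follow file position.

## Problem sizes

The default synthetic experiment is 3 peptides × 5 timepoints × 2
replicates (30–36 records depending on bimodality), the round-trip property
suite uses 200 generated documents of up to 8 records, and the acceptance
script converts one default experiment end to end — sizes chosen to keep
the whole suite near a second while still covering every hard case
(missing-zero replicate, bimodal peptide, PTM peptide, fully deuterated
row, centroid-only dialect).

## Known limitations

No raw instrument-file parsing, no back-exchange correction (the format
stores the fully deuterated records for downstream tools to use), no
protection-factor or exchange-rate fitting, and no bit-faithful emulation
of any particular vendor software version's export. Streaming parsing of
very large files is out of scope; documents are held in memory.
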