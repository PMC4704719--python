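# Methods

## Identifier model

dbSNP's merge history is a functional graph on rs numbers: each retired ID
has at most one successor (`rsHigh → rsLow`, the RsMergeArch relation), so
resolution is a walk along unique out-edges until an ID with no mapping is
reached. Two facts shape the implementation:

* **`rsCurrent` is advisory.** The dump's third identifier column records
  what dbSNP believed the current ID was when the row was written; rows
  are not rewritten when the target is merged again, so the column goes
  stale. Resolution therefore always walks the chain; `rsCurrent`
  disagreements are counted in a log line and otherwise ignored.
* **Merges point downward.** dbSNP folds the higher number into the lower
  one, so in clean data the walk strictly decreases and must terminate.
  The resolver still guards against cycles (corrupt or adversarial input)
  with a visited set; on a cycle it returns the smallest member — the
  canonical pick under the same downward convention — flags the result,
  and never fails. Duplicate `rsHigh` rows are resolved last-wins, since
  dump order is chronological.

`compile_resource` materializes the transitive closure once (one chain
walk per mapped ID; chains are short, so path compression would buy
nothing measurable at dump scale) and the compiled map is checked for the
defining invariant: no value is itself a key. Batch tracking is then one
dictionary probe per variant.

## Status cascade

Each input receives exactly one status, decided in this order: resolve the
merge chain; a position record with a real chromosome and exact position
⇒ `UNCHANGED`/`MERGED`; chromosome `NotOn` ⇒ `CHR_NOTON`; `Multi` or a
blank position ⇒ `NO_COORD`; otherwise, presence in the deletion history
⇒ `DELETED` when the input was never merged and `INVALID` when a merge
led to the withdrawn ID (the split mirrors the practice of withdrawing a
cluster after merging it); anything else ⇒ `UNKNOWN`. Reactivated IDs are
removed from the deleted set at compile time, so they classify as live —
by construction no reactivated ID can surface as `DELETED`/`INVALID`.
Within a batch, later rows resolving to an already-claimed current ID are
reassigned `DUPLICATED` (first occurrence wins, making the rule order-
dependent but deterministic). `PAR` and `Un` are treated as real
chromosomes: they carry genuine coordinates in dbSNP.

## Coordinate handling

SNPChrPosOnRef stores 0-based positions; that convention is confined to
`resource_io`, and every user-facing position is 1-based. For coordinate
queries, the base convention of the *input* is detected globally per file:
the first ≤10,000 rows are counted as index hits both as-given and shifted
by +1, and the shift is adopted only if it strictly wins. A single global
offset (rather than per-line correction) means systematically 0-based
files are fixed while scattered bad rows still surface as `UNKNOWN`
instead of being silently patched. Ties and all-miss samples default to
1-based. Loci carrying several rs IDs return all of them, one output row
per hit, ascending.

hg17/hg18 inputs are converted to hg19 before lookup by point liftover
through UCSC chain files: chains are expanded into ungapped blocks held in
per-chromosome interval trees; a covered source base maps by offset within
its block, with negative-strand targets flipped through the destination
chromosome length. Overlapping chains are resolved by score, then file
order, as UCSC does. Only points are lifted (variants are points here);
no match-fraction thresholds are applied. Two `--chain` flags perform a
two-hop conversion when no direct chain exists. hg38 output uses the hg38
SNPChrPosOnRef dump natively — no back-lifting.

## PLINK marker files

`.map`/`.bim` rows index genotype matrices positionally, so updates never
add, drop or reorder rows, and fields other than the ID and coordinate
pass through byte-identical (including the genetic-distance token).
Markers whose ID is not an rs accession fall back to coordinate lookup;
markers that cannot be tracked — including later duplicates of an
already-claimed current ID — are kept verbatim and written to an exclusion
list for the genotype tool. A wrong field count aborts with the line
number rather than guessing.

## Synthetic resource generator

`fixtures.generate` emulates the three dbSNP dumps at test scale.  Every
simulated variant is assigned a fate up front — live, withdrawn,
reactivated, multi-contig, off-chromosome, blank-position, or absent from
all files — plus a merge chain of uniform depth 0..`max_chain_depth`
realized as fresh rs numbers drawn without replacement (so chains cannot
collide); the files are then written to realize that fate, and the
expected status/ID/coordinate of each input is recorded *during
construction*. The truth table is therefore an oracle independent of the
tracker, and a recovery test closes the loop without circularity.
Defaults (1,000 variants, depth ≤ 3, 5% deleted, 3% reactivated, 2% each
multi/NotOn/blank/unknown) keep every status class populated at the rates
such problem classes appear in aged genotyping-array content, while the
acceptance run scales to 10,000 variants with depth ≤ 5 and injected
cycles. The generator also writes a toy chain file (two shifted
plus-strand chains and one negative-strand chain) for end-to-end liftover
runs.

What the fixtures do **not** emulate: real dump scale (tens of gigabytes),
the long-tailed real distribution of merge depths, secondary SNPHistory
columns, multi-assembly position dumps, or loci shared by several rs IDs.
Passing tests demonstrate the resolution/classification logic, not
robustness to every formatting quirk of historical dbSNP releases.

## Numerical and degenerate-input choices

* Gzip is detected by magic bytes, so misnamed files parse correctly.
* Malformed resource lines are skipped and counted, never fatal; marker
  files and chain files, whose misparse would corrupt downstream data,
  fail fast instead.
* Empty inputs produce empty outputs and an all-zero summary.
* Identical inputs and resources give byte-identical outputs; timestamps
  appear only in logs.
* The reactivation marker is the case-insensitive substring `reactiv` in
  the SNPHistory comment after hyphen stripping, covering both
  "Reactivated" and "Re-activation" spellings.

## Known limitations

* No allele/strand reconciliation and no variant-type awareness: identity
  and position only.
* No per-build historical snapshots ("what was this ID in build 130?");
  only latest-build resolution.
* The `DELETED`/`INVALID` boundary and the first-wins `DUPLICATED` rule
  are pinned design choices; other tools may partition these edge cases
  differently.
* Coordinate queries are point lookups; indels spanning intervals are
  matched by their start position only.
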