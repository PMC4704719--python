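# rstrack

Batch-update dbSNP rs IDs of sequence variants to the current build and
unify their genomic coordinates, with PLINK-compatible output.

## The problem

dbSNP continuously merges redundant Reference SNP clusters and withdraws
falsely discovered ones, so the same variant carries different rs IDs
across array manifests, legacy GWAS datasets and annotation databases.
A merge always folds the later-assigned number (rsHigh) into the earlier
one (rsLow), and a variant can be merged several times, leaving old
datasets several merge events behind the current name — or pointing at IDs
that were later withdrawn, reactivated, remapped to multiple contigs, or
dropped from every chromosome. Harmonizing identifiers is a precondition
for merging genotype datasets, meta-analysis, and annotation lookups.

`rstrack` resolves any historical rs ID to its current one by computing the
transitive closure of the merge relation recorded in dbSNP's **RsMergeArch**
dump: the forward map `rsHigh → rsLow` is walked until an ID with no further
mapping is reached, so an input `rs_a` with chain
`rs_a → rs_b → ... → rs_z` reports `rs_z`. The recorded `rsCurrent` column
is deliberately *not* trusted (it is frequently stale); it is only logged
when it disagrees with the chain walk. Deletion and reactivation history
(**SNPHistory**) and per-build coordinates (**SNPChrPosOnRef**) then place
each variant in exactly one status class:

| status | meaning |
|---|---|
| `UNCHANGED` / `MERGED` | live; reported with current ID and 1-based hg19/hg38 position |
| `DELETED` | withdrawn, never merged |
| `INVALID` | reached a withdrawn ID through one or more merges |
| `CHR_NOTON` | no longer mapped to any current chromosome |
| `NO_COORD` | mapped to multiple contigs, or no exact position |
| `UNKNOWN` | absent from every resource dataset |
| `DUPLICATED` | a later query row resolving to an already-claimed current ID |
| `UNLIFTED` | coordinate input not covered by any liftover chain |

Variants can also be queried *by coordinate* (the input convention,
0-based vs 1-based, is auto-detected by majority vote against the
position index; hg17/hg18 inputs are first lifted to hg19 through UCSC
chain files), and PLINK `.map`/`.bim` marker files are rewritten in place
with row order preserved and untrackable markers listed for `--exclude`.

## Worked example

The repository ships a miniature dbSNP snapshot under `tests/data/toyA/`
(merge chain `rs1002 → rs1001 → rs1000`, chain `rs2001 → rs2000`, a
withdrawn `rs4000`, and more). Tracking four IDs:

```sh
$ printf 'rs1002\nrs2001\nrs4000\nrs9999\n' > ids.txt
$ rstrack track ids.txt out --resource-dir tests/data/toyA
INFO no compiled resource found; compiling raw files on the fly
INFO run summary:
INFO   MERGED       2
INFO   DELETED      1
INFO   UNKNOWN      1
INFO   Total        4
```

`out.result.txt` holds the live variants with their current IDs and
1-based positions:

```
#input	rs_id	chrom	pos
rs1002	rs1000	1	1000
rs2001	rs2000	2	5000
```

and `out.error.txt` the problematic ones with their status and detail
(the withdrawn terminal ID, or the merge chain):

```
#input	status	detail
rs4000	DELETED	rs4000
rs9999	UNKNOWN
```

The summary counts always sum to the input row count — every query row
lands in exactly one of the two files.

Other entry points: `rstrack compile` precompiles the three dbSNP dumps
into a fast lookup file; `--kind coord` tracks chromosome/position input
(`--chain` for hg17/hg18); `--kind map|bim` rewrites PLINK marker files;
`rstrack make-fixture` generates a synthetic resource snapshot with a
known ground truth; `rstrack fetch` lists the dbSNP files to download.

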