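# octal

RF-optimal completion of incomplete gene trees.

Multi-locus phylogenomic datasets routinely contain *incomplete* gene trees:
trees estimated for individual loci that are missing some of the species of
interest, because of patchy sequencing, gene loss, or sampling design.
Many downstream species-tree methods assume complete gene trees, so adding
the missing taxa back — *completing* the gene tree — is a practical
preprocessing step.

This package solves the **RF Optimal Tree Completion problem** exactly.
Given an unrooted binary reference tree *T* on the full taxon set *S*
(typically an estimated species tree) and an unrooted binary gene tree *t*
on *R* ⊆ *S*, it returns a binary tree *T′* on *S* such that

* *T′* is a completion of *t* — restricting *T′* to *R* gives back *t*
  exactly (`T′|_R = t`), and
* *T′* minimizes the Robinson–Foulds distance RF(*T*, *T′*) over **all**
  completions of *t*.

The algorithm (OCTAL) is greedy and runs in polynomial time: missing taxa
are inserted one at a time, each onto the gene-tree edge paired with the
first *shared* edge found on a depth-first walk of *T* restricted to the
current taxa and rooted at the new leaf.  Optimality is certified by a
closed form: writing *r* = RF(*T*|_R, *t*) and *m* for the number of
**Type II superleaves** — pendant groups of missing taxa hanging off a
backbone edge of *T* whose split is absent from *t* — every completion
satisfies RF(*T*, *T′*) ≥ *r* + 2*m*, and the tree returned here achieves
equality.  The library also ships the two other standard evaluation
distances (quartet and matching), a brute-force enumeration oracle, and a
synthetic-data generator (random trees, NNI-tuned gene-tree discordance,
clade-multiset taxon deletion, greedy consensus).

## Worked example

```python
import octal as oc

reference = oc.parse_newick("((a,b),(((c,d),q),(e,f)));")   # tree on S
gene      = oc.parse_newick("((a,b),(c,(d,(e,f))));")       # tree on S \ {q}

report = oc.octal(reference, gene)
print("completed tree :", oc.write_newick(report.tree))
print("r, m           :", report.r, report.m)
print("achieved RF    :", report.achieved_rf)
print("lower bound    :", report.lower_bound)
```

prints

```
completed tree : (a,b,((c,(d,(e,f))),q));
r, m           : 2 1
achieved RF    : 4
lower bound    : 4
```

The restricted reference *T*|_R and the gene tree disagree on one split, so
*r* = 2.  The missing taxon `q` hangs off a reference edge whose split
(`cd | abef`) is not in the gene tree, making it a Type II superleaf
(*m* = 1): wherever `q` goes, the RF distance rises by at least 2.  The
achieved RF of 4 = *r* + 2*m* therefore certifies the completion as
optimal — and `oc.brute_force_complete(reference, gene)` confirms it by
trying all 9 possible placements.

## Command line

```sh
octal simulate --n-taxa 26 --n-genes 200 --target-ad 0.10 --seed 1 \
      --outdir data --consensus-reference
octal complete --reference data/reference_consensus.nwk \
      --genes data/genes_incomplete.nwk --out completed.nwk \
      --manifest manifest.tsv --truth data/genes_true.nwk
octal compare completed.nwk data/genes_true.nwk --metrics rf,qd,md
```

`complete` writes one completed tree per input line plus a TSV manifest
with the per-gene certificate quantities (*r*, *m*, achieved RF);
`compare` reports RF, normalized RF, quartet, normalized quartet, and
matching distances per tree pair.

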