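# pancdbg

Searchable compressed de Bruijn graphs for pan-genomes, built directly
from an FM-index.

A pan-genome (several genomes of the same or closely related species) is
concatenated into one text `S = S1#S2#...#Sd$`. The package builds the
FM-index of `S` (suffix array, BWT in a rank-capable wavelet tree,
C-array), derives two marking bit vectors from a level-`k` LCP
computation done purely on the BWT, and from these constructs the
*implicit* compressed de Bruijn graph of order `k`: an array of node
records `(len, lb, size, suffix_lb)` addressing the suffix array rather
than storing strings. Separator occurrences are treated as pairwise
distinct characters, so no graph node ever spans a sequence boundary.

On top of the implicit graph the package provides:

- conversion to the *explicit* (splitMEM-style) representation with
  position lists, visit-ordered adjacency lists and start nodes;
- pattern search: locate the chain of graph nodes spelling any pattern
  of length >= k, plus its occurrence positions;
- membership queries via a document array: which sequences contain a
  pattern or node, and how often;
- a brute-force reference oracle (naive suffix sort, definitional
  maximality scans, window-graph compaction) used as ground truth in
  the tests;
- a synthetic pan-genome simulator and a CLI.

## CLI

```sh
pancdbg simulate --length 5000 -d 4 --seed 7 -o pan.fa
pancdbg build pan.fa -k 31 -o pan.cdbg.json --tsv nodes.tsv
pancdbg stats pan.cdbg.json
pancdbg explicit pan.cdbg.json --fmt gfa -o pan.gfa   # also: tsv, dot
pancdbg search pan.cdbg.json -p ACGTACGTACGT --json
pancdbg index pan.fa -o pan.idx.json                  # index only
```

`build` stores a versioned JSON container holding the text, suffix
array, BWT, marking vectors and node table; reloading it reproduces all
query results bit-identically.

## Library sketch

```python
from pancdbg import (
    encode_and_concatenate, build_fm_index, build_kmer_marks,
    build_implicit, to_explicit, search_pattern,
    build_document_array, interval_sequences,
)

text = encode_and_concatenate([("a", "ACGTT"), ("b", "ACGCC")])
fm = build_fm_index(text)
marks = build_kmer_marks(fm, k=3)
G = build_implicit(fm, marks)
res = search_pattern(fm, marks, G, "ACG")
doc = build_document_array(fm, text)
print(res.resList, interval_sequences(doc, res.iv))
```

All coordinates are 1-based with closed intervals, matching the usual
suffix-array presentation, so intermediate values can be checked against
hand-written tables.

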