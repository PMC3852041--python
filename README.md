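# diploidalign

Recombination-aware haploid-to-diploid alignment for assessing variant-calling
predictions.

## The problem

When variant callers are benchmarked against a simulated diploid truth, naive
per-variant matching breaks down on indels: a predicted deletion can be placed
a few bases away from the true one yet change the genome identically, and
split/merged calls make the mismatch worse. The robust question is not *"is
this exact call in the truth list?"* but *"does the genome implied by the
calls match the truth genome?"* — and for a diploid truth observed through
short reads, phase is unknown, so the implied genome should be compared
against **any recombination of the two truth alleles** that is consistent with
their alignment to the reference.

`diploidalign` implements that comparison end to end:

1. apply the predicted variants to the reference greedily left to right,
   producing one haploid genome `A` (or several, if heterozygous predictions
   conflict);
2. compute the minimum unit-cost (Levenshtein) edit distance between `A` and
   any *valid reference-guided recombination* of the truth alleles `B¹`, `B²` —
   a mosaic that may switch alleles only at positions both share with the
   reference `P`, as recorded in their mapping tables `m¹`, `m²` (for each
   allele character, the reference position it aligns to).

The distance is computed by filling two edit-distance matrices simultaneously
(one per allele ending) in a single sweep over reference positions, exchanging
column minima wherever a switch is legal. A banded variant restricts work to
cells that can lie on a path within a cutoff `k` and doubles `k` until the
result certifies, giving `O(dn)` time for true distance `d` — practical for
megabase references. A brute-force oracle (explicit enumeration of every valid
recombination, scored with edlib) independently verifies both engines on small
instances, and a diploid simulator reproduces the benchmark conditions used to
validate the method (per-position mutation probability 0.003 per type,
homozygous with probability 0.5).

## Worked example

The reference `AGCTGATAC` is mutated into a diploid by five variants (one
homozygous substitution, one homozygous insertion, two heterozygous changes on
allele 1 and one on allele 2):

```python
>>> from diploidalign import derive_mappings, diploid_align, levenshtein
>>> b1, b2 = derive_mappings("AGCTGAT-A-C",   # reference row
...                          "ACCTGATCACG",   # allele 1
...                          "ACCTGCT-ACC")   # allele 2
>>> b1.mapping.tolist()
[0, 1, 2, 3, 4, 5, 6, 6, 7, 7, 8]
>>> a = "ACCTGCTCACC"        # haploid built from all five predicted variants
>>> levenshtein(a, b1.sequence), levenshtein(a, b2.sequence)
(2, 1)
>>> diploid_align(a, b1, b2, reference_length=9).distance
0
```

The haploid matches *neither* allele (single-allele distances 2 and 1) but
aligns with **zero** errors to a recombination that follows allele 2, borrows
two characters from allele 1, and returns — exactly the behaviour a fair,
phase-agnostic evaluation needs. Equivalent but differently written indel
call sets score identically for the same reason: two encodings that both
produce donor `GTCCCATAAG` from `GATCAATGAG` evaluate to distance 0, where
naive variant matching finds only two of five calls in common.

The same workflow from the shell:

```sh
diploidalign simulate -n 10000 --seed 1 --outdir sim      # diploid truth
diploidalign apply-variants sim/reference.fasta calls.tsv --out pred.fasta
diploidalign align pred.fasta --alleles alleles.fasta --mappings sim/mappings.tsv
diploidalign evaluate sim/reference.fasta sim/variants.tsv calls.tsv
diploidalign verify --instances 500 --seed 0              # oracle cross-check
```

`align`/`evaluate` print a JSON report with per-haploid distances, the engine
and cutoff used, and the number of DP cells computed. Exit codes: 0 success,
2 input error, 3 distance above a fixed `--cutoff`.

## Layout

- `genome.py` — reference/allele/diploid types, mapping tables, gapped-alignment projection
- `variants.py` — variant records, normalisation, greedy application, truth construction
- `align.py` — full-matrix distance, Levenshtein, non-overlap shortcut
- `banded.py` — banded engine with diagonal doubling (`O(dn)`)
- `oracle.py` — brute-force recombination enumeration (verification only)
- `simulate.py` — diploid simulator
- `io.py`, `evaluation.py`, `cli.py` — formats, reports, command line

See `docs/methods.md` for the model, the band construction, and the boundary
conventions.
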