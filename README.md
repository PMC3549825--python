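# subphylo

Alignment-free whole-genome comparison and phylogeny reconstruction from
shared subwords.

For each ordered pair of genomes the pipeline:

1. builds an **extended target** — the second genome concatenated with its
   reversal and its base complement, separator-joined — so direct, inversion,
   and complement matches are all visible;
2. discovers the **irredundant common subwords**: the shared words with at
   least one occurrence not covered by an occurrence of another shared word.
   These are exactly the words needed to reconstruct the per-position
   matching statistics, and there are at most `|s1| + |s2|` of them;
3. filters them to the **underlying set** by a priority rule (longer word
   wins, ties broken by earliest occurrence), keeping for each word only the
   occurrences that do not overlap higher-priority selections ("untied") and
   requiring at least one untied occurrence per sequence. Untied occurrences
   are pairwise disjoint, so no genome region is counted twice;
4. scores each member as `h_w · |w| · (|w|+1) / 2` (suffix-length sum per
   untied occurrence in the scored sequence), normalizes with base-4
   logarithms and a self-match correction, and symmetrizes into a distance;
5. assembles the all-pairs matrix and runs neighbor joining; tree topologies
   can be compared with Robinson–Foulds and triplet distances.

A deterministic synthetic-genome generator (substitutions plus planted
segmental inversions/complements along a known tree) makes every stage
testable without external data.

## CLI

```sh
subphylo simulate --seed 1 --leaves 8 --length 5000 --rate 0.02 \
    --out-fasta family.fa --out-tree true.nwk
subphylo ms family.fa                  # matching statistics (first vs second record)
subphylo irredundant family.fa         # irredundant common subwords, TSV
subphylo underlying family.fa          # underlying subwords + untied occurrences
subphylo dist family.fa --out d.phy    # PHYLIP distance matrix (or --format tsv)
subphylo tree d.phy --out nj.nwk       # neighbor-joining tree, Newick
subphylo treedist nj.nwk true.nwk      # Robinson-Foulds + triplet distance
subphylo pipeline family.fa --outdir run/   # matrix + tree + subword report
```

All subcommands accept `--mode direct|extended` (default `extended`, i.e.
inversion and complement matches are included). Reports use 1-based
coordinates; occurrences in the extended target are mapped back to source
coordinates and tagged with their match class.

## Layout

| module | role |
| --- | --- |
| `subphylo.seqio` | FASTA IO, alphabet normalization (unique sentinels for ambiguity codes), extended-sequence construction |
| `subphylo.index` | suffix array + LCP + generalized suffix tree over a pair; colored nodes, ancestor queries |
| `subphylo.matchstats` | matching statistics (direct and reconstructed from subwords), ACS similarity |
| `subphylo.irredundant` | two-phase discovery of irredundant common subwords |
| `subphylo.underlying` | priority ranking and Γ/χ-based selection of the underlying set |
| `subphylo.distance` | similarity/distance formulas, all-pairs matrices, match-class statistics |
| `subphylo.phylo` | neighbor joining, Robinson–Foulds, triplet distance, Newick IO |
| `subphylo.synth` | synthetic genome families with known phylogeny and planted events |
| `subphylo.cli` | `subphylo` command-line entry point |

Tests live under `tests/`; brute-force definition-level oracles used to
validate the algorithms are in `tests/oracles.py`, and
`tests/test_acceptance.py` holds the acceptance criteria (the scaled
phylogeny-recovery experiment in it takes a few minutes on one CPU).
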