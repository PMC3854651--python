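# gapminer

Mining gapped sequential patterns (motifs) in biological sequence databases.

A *gapped pattern* is an ordered list of residues (written `C*A`, `T*A*C`, …)
that occurs in a sequence as a position chain `q_1 < q_2 < … < q_m` in which
every adjacent pair satisfies the strict gap window `q_{i+1} < q_i + G`
(so `G=1` admits nothing and `G=2` means adjacency). A pattern's *support* is
the number of database sequences containing at least one occurrence; patterns
meeting a minimum support (absolute count, or a fraction of N rounded up) are
reported.

The core miner spells candidates depth-first over the alphabet. Its only
per-pattern state is a **counting matrix** — for each sequence, the set of
positions where an occurrence of the pattern can end. Extending a pattern by
one item maps every end position through a windowed binary-search query on an
inverted **position index** (item × sequence → sorted occurrence positions,
built in one pass over the data). All in-window successor positions are
retained, never just the first: keeping only a minimal successor provably
loses patterns (see `tests/test_acceptance.py`, min-only regression).
Support is anti-monotone under extension, so any candidate below the
threshold prunes its entire subtree.

Two reference miners with identical gap semantics serve as oracles and
comparators:

- `bruteforce` — exhaustive pattern enumeration with direct containment
  checks (guarded to ≤ 10⁶ candidates);
- `genprefixspan` — a projected-database pattern-growth miner that
  recursively scans pseudo-projections (sequence, offset pairs) for items
  frequent within the gap window of each entry.

All three return identical (pattern, support) sets; the test suite asserts
this on hundreds of randomized instances.

## Layout

| module | contents |
| --- | --- |
| `gapminer.seqdb` | alphabets, sequence database, FASTA / line-oriented I/O |
| `gapminer.index` | one-pass inverted position index, windowed successor queries |
| `gapminer.miner` | counting matrices, depth-first miner, TSV output |
| `gapminer.baseline` | containment oracle, brute-force and projected-database miners |
| `gapminer.synth` | seeded uniform i.i.d. sequence generator (DNA `A=4`, protein `A=20`) |
| `gapminer.cli` | `gapminer mine | synth | bench` |

## CLI

```sh
# mine motifs from FASTA (or --format lines: one sequence per line, optional id<TAB>)
gapminer mine --input db.fa --gap 3 --min-support 3 --out motifs.tsv
gapminer mine --input db.fa --gap 5 --min-support-frac 0.9 --sort --out motifs.tsv
gapminer mine --input db.fa --gap 3 --min-support 3 --algorithm genprefixspan --out motifs.tsv
gapminer mine --input db.fa --gap 3 --min-support 3 --report-positions --out motifs.tsv

# seeded synthetic data (uniform i.i.d. letters)
gapminer synth --A 4 --L 30 --N 3000 --seed 7 --out synth.fa

# benchmark miners over a parameter grid (timings informational)
printf 'A=4\nL=25\nN=3000\nG=5\nS=0.5,0.6,0.7,0.8,0.9\n' > grid.txt
gapminer bench --grid grid.txt --algorithms dfsg,genprefixspan --seed 7 --out bench.tsv
```

Output TSV columns: `pattern`, `length`, `support`, `support_fraction`
(6 decimals). `--report-positions` writes a second file mapping each pattern
to its per-sequence end positions. Exit codes: 0 success, 1 data error,
2 invalid flags. Logging goes to stderr (`--quiet`, `--debug`).

Real nucleotide data of the kind used for benchmarking can be obtained from
the NCBI nucleotide database with a length-restricted query such as
`sequence AND 35:35[Sequence Length]`, exporting the first N records as
FASTA; no test depends on remote data.

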