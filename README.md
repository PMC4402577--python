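# guidealign

Progressive multiple sequence alignment with pluggable guide-tree
construction, SP/TC evaluation, and a protein-family simulator.

The central feature is the **adaptive guide tree**: the family's average
percent identity (PID — identities in the optimal pairwise alignment
divided by the alignment length) selects a similarity regime, and the
regime selects the distance estimate used for UPGMA tree building:

| average PID | regime   | tree distances                         |
|-------------|----------|----------------------------------------|
| > 40%       | HIGH     | 1 − PID (global alignment)             |
| 25–40%      | MODERATE | 1 − PID (local alignment)              |
| < 25%       | LOW      | 1 − mean of global and local PID       |

Alternative guide-tree sources: uniform random topologies (seeded),
reference trees supplied as Newick (midpoint-rooted / binarized as
needed), and a neighbor-joining fallback built from a trusted reference
alignment. Alignments are built by profile–profile merges along the
tree (BLOSUM62, affine gaps: open 10, extend 1, a length-k gap costs
open + (k−1)·extend) and evaluated with sum-of-pairs (SP) and
total-column (TC) percentages, with similarity-binned reporting.

The `synthetic` module simulates families down a Yule tree with
substitutions and indels, tracking every event so the true alignment
and true tree are exact; `calibrate_divergence` bisects a branch-length
scale to hit a target average PID. The `bench` module compares tree
strategies on such families (or on your own) and summarizes paired
scores against the diagonal.

## CLI

```sh
# similarity matrix, average PID and regime
guidealign similarity family.fasta --as-json

# guide trees (adaptive | random | reference | nj-reference)
guidealign tree family.fasta --strategy adaptive --newick-out tree.nwk
guidealign tree family.fasta --strategy random --seed 7

# progressive alignment
guidealign align family.fasta --tree-strategy adaptive -o aligned.fasta
guidealign align family.fasta --tree-strategy reference \
    --reference-tree tree.nwk -o aligned.fasta

# SP / TC against a reference alignment
guidealign score aligned.fasta reference.fasta --as-json

# simulate a family with known truth (optionally calibrated)
guidealign simulate --n-taxa 8 --seed 5 --target-avg-pid 0.3 --out-prefix fam

# strategy comparison over a manifest (family_id, fasta, ref_msa[, true_tree])
guidealign bench manifest.tsv --strategies adaptive,random --seed 0 \
    --out-prefix results/run

# similarity-binned aggregation of a results TSV (avg_pid, sp, tc columns)
guidealign report results.tsv --edges 0,20,40,70,100
```

## Layout

- `src/guidealign/seqio.py` — FASTA / aligned FASTA / Newick I/O
- `src/guidealign/pairwise.py` — Gotoh global/local alignment, PID
- `src/guidealign/similarity.py` — PID matrix, average PID, regimes
- `src/guidealign/guidetree.py` — adaptive / random / reference trees,
  UPGMA, NJ, Robinson–Foulds
- `src/guidealign/progressive.py` — profile merges along the tree
- `src/guidealign/scoring.py` — SP / TC, binned reports
- `src/guidealign/synthetic.py` — family simulator + calibration
- `src/guidealign/bench.py` — strategy-comparison harness
- `tests/` — unit + property tests and the acceptance suite, with
  independent brute-force oracles in `tests/oracles.py`
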