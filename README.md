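# consnet

Conserved colored-subnetwork mining in tumor cohorts.

Large tumor-sequencing cohorts show that particular *combinations* of
alterations — a somatic mutation here, an arm-level amplification there, an
expression outlier next door — recur across many patients, and that the
affected genes often sit next to each other in the protein–protein
interaction (PPI) network. `consnet` finds such patterns. It models the
cohort as one interaction network G = (V, E) plus a per-sample *coloring*:
gene *j* in sample *i* carries a (possibly empty) set of alteration types
C‚ᵢⱼ drawn from an alphabet (default `MUT`, `AMP`, `DEL`, `UP`, `DOWN`). A
**conserved colored subnetwork** is a connected subgraph with one color cⱼ
per node such that every supporting sample has cⱼ ∈ Cᵢⱼ at every node; the
number of supporting samples is its **depth**.

The package is aimed at computational cancer biologists who already have
discretized alteration calls (the upstream variant/CNA/outlier calling is
out of scope) and want exact, reproducible pattern mining with honest
significance estimates.

## What it computes

* **Single-subnetwork mode** — the largest conserved subnetwork of depth
  ≥ t (all ties returned), found by an a-priori breadth-first enumeration
  of candidate subnetworks with anti-monotone support pruning; plus a
  depth scan reporting, for every feasible t, the maximum size and the
  number of distinct maximal solutions.
* **Multi-subnetwork mode** — up to *l* candidate subnetworks of size ≤ k
  and depth ≥ t maximizing the number of covered colored (sample, gene)
  pairs, solved exactly as a 0/1 ILP (HiGHS branch-and-bound), with a
  brute-force oracle for small instances.
* **Variants** — *colorful* subnetworks (≥ 2 distinct node colors) and an
  error rate δ allowing each supporting sample up to ⌊δ·|T|⌋ uncolored
  nodes.
* **Significance** — two permutation nulls that bracket the true p-value
  of a discovered subnetwork: independent per-color shuffling (lower
  bound p₁) and arm-coherent copy-number reassignment that treats an
  arm-level gain/loss as a single event (upper bound p₂).
* **Survival** — per-patient risk score S = Σᵢ βᵢ·xᵢⱼ over the subnetwork
  genes (βᵢ from univariate Cox fits, xᵢⱼ normalized expression) with a
  mean split into high-risk (S ≥ mean) and low-risk groups.
* **Synthetic data** — random PPI-like networks, background alterations,
  arm-coherent copy-number structure, and planted conserved patterns with
  known ground truth, so everything is testable without downloads.

## Worked example

The bundled demo instance is a 5-gene path g1–g2–g3–g4–g5 with three
samples (P1: g1:A g2:A g3:{A,B} g4:B; P2: g1:A g2:A g3:B; P3: g2:A g3:A
g4:B g5:B):

```python
from consnet import solve_mcsi, solve_mcsc, build_universe, \
    enumerate_candidates, prune_non_maximal, EnumOptions
from consnet.synthetic import demo_instance

net, cohort = demo_instance()
for sub in solve_mcsi(net, cohort, t=2):
    print(dict(sub.assignment), "depth", sub.depth)

opts = EnumOptions(t=2, k=3)
cands = prune_non_maximal(enumerate_candidates(net, cohort, opts), net, cohort, opts)
sol = solve_mcsc(list(cands), build_universe(net, cohort), cohort, l=2)
print("covered", sol.objective, "of", len(build_universe(net, cohort)))
```

prints

```
{'g1': 'A', 'g2': 'A', 'g3': 'B'} depth 2
{'g2': 'A', 'g3': 'A', 'g4': 'B'} depth 2
covered 10 of 11
```

At depth 2 the largest conserved subnetworks have 3 genes and there are
two of them (g3 supports color A via P1/P3 or color B via P1/P2).
Choosing two subnetworks of size ≤ 3 covers 10 of the 11 colored
(sample, gene) pairs — only g5 in P3 stays uncovered, because no
subnetwork containing it reaches depth 2.

The same pipeline is available from the shell:

```sh
consnet simulate --nodes 200 --samples 50 --plant-size 6 --plant-depth 20 \
    --seed 1 --outdir sim
consnet single --network sim/network.tsv --alterations sim/alterations.tsv \
    --min-depth 20 --outdir out
consnet permute --network sim/network.tsv --alterations sim/alterations.tsv \
    --min-depth 20 --observed out/subnetworks.json --arms sim/arms.tsv \
    --mode both --reps 1000 --seed 1 --outdir pvals
```

Network files are STRING-style tab-separated edge lists (scores on the
0–1000 scale are divided by 1,000 and filtered at ≥ 0.9 by default);
alteration tables are `sample  gene  alteration` TSVs.

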