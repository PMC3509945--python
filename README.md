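# pathdiv

Quantifying the predictability of evolution on fitness landscapes.

Under strong-selection/weak-mutation (SSWM) dynamics, adaptation is a
monotone walk on the genotype hypercube: at each step one of the strictly
fitter single-mutation neighbors is fixed, chosen uniformly, until a local
peak is reached. `pathdiv` provides:

- **Landscape model & I/O** — partial genotype→fitness maps over binary
  loci, plain TSV/CSV tables (holds published empirical combinatorial
  landscapes directly), viability filtering of non-positive fitness.
- **Monotone paths** — exhaustive enumeration of maximal monotone paths,
  SSWM occurrence probabilities, exact dynamic-programming path counts,
  per-peak reach probabilities, peak-accessibility summaries, and a seeded
  walk sampler.
- **Path divergence** — inter-path distance (symmetrized, length-normalized
  minimum Hamming distance), probability-weighted ensemble divergence
  (raw sum or normalized weighted mean), and the landscape-level mean path
  divergence: low divergence = predictable evolution.
- **Roughness measures** — additive deviation (roughness-to-slope ratio of
  the least-squares additive fit), RMS neighbor fitness difference, peak
  fraction, and mean distance to the tree component, with a
  fitness-permutation null comparison.
- **Generators** — seeded noisy-additive landscapes (exponential per-locus
  effects, multiplicative `uniform^k` noise, viability filter), exactly
  additive and uncorrelated (house-of-cards) limits, and fitness-permutation
  nulls.

## CLI

```sh
# generate a noisy-additive landscape (k = noise power; k=0 is exactly additive)
pathdiv generate --model noisy-additive --L 6 --noise-power 0.5 --seed 1 --out ls.tsv

# roughness measures with a 200-replicate permutation null
pathdiv stats --in ls.tsv --permutations 200 --seed 2

# enumerate monotone paths with SSWM probabilities
pathdiv paths --in ls.tsv --start 000000 --global-peak

# accessibility of the global peak, and mean path divergence
pathdiv accessibility --in ls.tsv
pathdiv divergence --in ls.tsv --mode normalized --target global-peak

# fitness-permutation null landscape
pathdiv permute --in ls.tsv --seed 3 --out null.tsv
```

All outputs are TSV with `#`-prefixed provenance headers; identical command
lines reproduce identical outputs.

Landscape table format: header `genotype<TAB>fitness`, one `{0,1}`-string
genotype and one positive decimal fitness per row; `#` comments allowed;
rows with non-positive fitness are dropped as nonviable.

## Library example

```python
from pathdiv import (FitnessLandscape, enumerate_monotone_paths,
                     ensemble_divergence, mean_path_divergence)

ls = FitnessLandscape({"00": 0.6, "01": 0.7, "10": 0.9, "11": 1.0})
(ens,) = enumerate_monotone_paths(ls, "00")   # two paths, P = 1/2 each
ensemble_divergence(ens, "raw")               # 1/12
mean_path_divergence(ls).mean_divergence      # 1/12 (normalized mode)
```
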