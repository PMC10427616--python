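# Methods

## The problem

Homo-oligomeric membrane protein complexes assemble with Cn rotational
symmetry; knowing which residue pairs touch across the chain interface
(nearest heavy atoms within 8 Å) constrains docking enough to recover
the assembly. Direct supervised training is data-starved — only a few
hundred non-redundant transmembrane complexes exist — while soluble
homodimers are abundant and share much of the interfacial physics
(hydrophobic packing, hydrogen-bond networks). `tmcontact` therefore
implements a two-stage protocol: train an initial model on
soluble-like complexes, then fine-tune **all** parameters (no frozen
layers) on the membrane-like set.

## Features

All features derive from the monomer, because the chains of a
homo-oligomer are identical and the monomer MSA substitutes for a
paired alignment:

* **PSSM** (L×20): sequence-weighted column frequencies with a unit
  pseudocount; weights are inverse 80%-identity neighbourhood counts.
* **DCA** (L×L×2): mean-field direct coupling analysis — the one-hot
  column covariance (20 states, gap as reference) is shrunk toward a
  scaled identity (default shrinkage 0.5), inverted, and couplings are
  scored by the Frobenius norm of the q×q blocks; the average product
  correction `S_ij − S_i·S_·j / S_··` removes background coupling.
  Pseudo-likelihood solvers score better at scale; externally computed
  matrices can be ingested through the HDF5 feature container.
* **Language-model tensors**: per-residue embedding (L×768) and pair
  attentions (L×L×144) are ingested, shape-validated, never
  transformed. The embedding enters the pair tensor through a fixed
  seeded random projection to 16 channels per side (an explicit,
  swappable choice recorded in the channel manifest).
* **Distance encoding** (L×L×64): the monomer Cβ–Cβ (Cα for Gly)
  distance map under Gaussian radial basis functions with 64 centers at
  2 + 0.3125·k Å and σ = 0.3125 Å. Receptor and ligand tensors carry
  this block; the complex tensor omits it — inter-chain geometry is the
  prediction target, not an input.

Sequence depth is reported as M_eff at 70% identity; conservation as
the mean per-column entropy (natural log) over the 20 amino acids with
gaps excluded from denominators.

## Network

Receptor, ligand, and complex pair tensors are projected to width `d`
and pass four ResNet-Inception blocks each (parallel 1×1 / 3×3 / 5×5-as-
stacked-3×3 branches with channel split d/4 + d/2 + d/4, instance
normalisation, ELU, 1×1 fusion, residual add). The complex tensor is
then refined by `k` triangle-aware blocks; each applies

1. a **triangle multiplicative update**
   `z̃_ij = z_ij + φ(Σ_m r′_im z′_mj + Σ_n z″_in l′_nj) ⊙ ϕ(z_ij)`,
   with `x′ = Linear(ϕ(x))`, gate `ϕ(x) = sigmoid(Linear(x))`, and
   output map `φ = Linear(LayerNorm(·))` (the bounded gate is used; a
   literal "sigmoid then linear" order would leave the gate unbounded);
2. **row and column triangle self-attention**: multi-head attention
   with logits scaled by 1/√d_head, whose post-softmax weights are
   multiplied by the geometric gate `g(d) = exp(−d²/2λ²)`, λ = 8 Å,
   where `d` is the intra-monomer distance between the attended residue
   m and the query's residue on the attended side (row mode: ligand
   d(j,m); column mode: receptor d(i,m)). Buried residues (relative
   SASA < 5% of the Gly-X-Gly reference) are excluded as keys and from
   the update sums: interfaces form between surface residues;
3. a **transition layer** (LayerNorm → linear ×2 expansion → ELU →
   linear, residual).

A linear head plus logistic squashing yields the probability map,
symmetrized as (P + Pᵀ)/2. Training minimises the focal loss
`−α(1−p_t)^γ log p_t` (γ = 2, α = 0.25, probabilities clamped at 1e−7),
with Adam (lr 10⁻³), batch 1, dropout 0.1, and max-contact window
cropping at 256 residues (all maximal windows collected, one drawn with
the run seed).

The network runs on an in-repo reverse-mode autodiff engine over numpy
(`tmcontact.nn`): tape-based, float32 by default, with every primitive
checked against central finite differences in the test suite. Evaluation
passes run in a no-tape inference mode.

## SASA

Shrake–Rupley with a deterministic Fibonacci-spiral sphere lattice
(default 400 points/atom, probe 1.4 Å, vdW radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å, unknown elements defaulting to 1.70 with the carbon
radius). At 400 points the per-residue error against a 10× finer
lattice is below 2% on the helical fixtures. Interface area is
(SASA_A + SASA_B − SASA_AB)/2, clamped at zero.

## Evaluation

Chains are indistinguishable, so the truth for scoring is the union of
all ordered chain-pair contact maps (a switchable policy; the
max-interface-only alternative is stricter for n > 2). Predictions are
deduplicated over (i,j)/(j,i), ranked with lexicographic tie-breaks,
and precision is reported at top 1/10/25/50/⌊L/10⌋/⌊L/5⌋/L (floored,
min 1). A target with zero true contacts reports missing, not zero.
Contact density is the contact count of the maximum interface divided
by 2L. Oligomeric state is called from the maximum predicted contact
probability: ≤ 0.77 monomer, ≤ 0.97 dimer, above that higher-order.

## Restraints

The top 10 predicted pairs with probability > 0.65 become docking
restraints with a piecewise energy: E₀ = −100 kcal/mol inside 8 Å, a
linear ramp to zero over 8–12 Å, zero beyond; continuous at both
joints. Distances follow the Cβ (Cα for Gly) convention of the distance
map. The restraint file is neutral TSV since docking engines are out of
scope.

## The synthetic benchmark

The generator makes the full pipeline testable without downloads. What
it emulates, and what it does not:

* **Structures**: ideal α-helices (rise 1.5 Å/residue, 100°/residue,
  Cα radius 2.3 Å, Cα+Cβ pseudo-atoms) on a Cn ring about z; the
  helix-axis separation (9.0 Å soluble, 9.5 Å tmp) sets the interface
  size. The tmp regime tilts helices by 10° and biases sequences
  hydrophobic. Real side-chain packing, loops, and β-barrels are not
  modelled, so passing tests show the pipeline is correct, not that it
  predicts real interfaces.
* **MSAs**: rows mutate i.i.d. per column (rate 0.35) except a greedy
  matching of true interface pairs, which jointly adopt one of three
  compatible residue-pair states with probability equal to the coupling
  strength (0.85 soluble, 0.6 tmp). Disjointness of the coupled pairs
  matters: overlapping pairs overwrite each other's covariation.
  Membrane families genuinely have fewer homologs, so tmp MSAs are
  shallower (depth 80 vs 200).
* **Surrogate language-model features**: a fixed subset of attention
  channels carries truth + Gaussian noise; the rest are noise. The two
  regimes use half-overlapping channel sets (soluble 0–7, tmp 4–11)
  with per-channel noise above the signal (σ 1.0 / 1.5), so a useful
  readout must pool channels and corroborate with DCA — this is the
  domain shift that makes transfer learning, rather than either
  training regime alone, the winning strategy, mirroring the difference
  between soluble and membrane co-evolution statistics.
* **Benchmark**: 60/12 soluble-like train/valid, 12/4/8 tmp-like
  train/valid/test, L ∈ [48, 64], regenerated bit-identically from
  (seed, config).

## Scale choices and defaults

The library default width is d = 64 with 4 triangle blocks (the full
architecture). The end-to-end protocol runs at a reduced width chosen
for a single CPU: d = 8, 2 heads, 1 triangle block, 4 ResNet-Inception
blocks, 20 initial epochs and 20 fine-tune epochs with patience-5 early
stopping on validation focal loss. At this scale the protocol
(initial training, direct training, fine-tuning, evaluation) completes
in a few minutes per seed and the fine-tuned model's mean top-10 test
precision exceeds both the direct-training and initial-only baselines,
reproducibly across seeds.

## Numerical notes and limitations

* Distance-map rows with a missing representative atom carry an +inf
  sentinel; they RBF-encode to zeros and gate to zero in attention.
* All-gap columns yield uniform PSSM rows with a warning; a fully
  conserved MSA makes the DCA covariance singular and raises.
* Softmax over a fully masked key set returns zeros (residual
  preserved); this is logged behaviour, not an error.
* Ties in ranking and restraint selection break lexicographically for
  determinism; greedy clustering is deterministic by input order, with
  representative choice delegated to the caller's pre-sort.
* The focal loss applies a single constant α to both classes, so
  γ = 0, α = 1 reduces exactly to mean binary cross-entropy; the
  class-balanced α_t variant is not used.
* Checkpoints store parameters plus the JSON model config in HDF5 and
  reload bit-identically.
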