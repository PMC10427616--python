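# tmcontact

Inter-chain residue–residue contact prediction for homo-oligomeric
(transmembrane) protein complexes, built around a geometric
triangle-aware pair-representation network and a soluble→membrane
transfer-learning protocol.

Membrane proteins frequently assemble into Cn-symmetric homo-oligomers,
but too few non-redundant transmembrane complexes exist to train a deep
contact predictor directly. `tmcontact` implements the two-stage answer:
pre-train on abundant soluble-like homodimers, then fine-tune **every**
parameter (no frozen layers) on the scarce membrane-like set. The
network couples each pair representation z_ij with (i,m) and (m,j)
entries through a triangle multiplicative update and distance-gated
triangle self-attention (gate g(d) = exp(−d²/2λ²), λ = 8 Å, d the
intra-monomer Cβ distance), so predictions respect the monomer's
geometry; buried residues are masked out of attention. Two residues of
different chains are "in contact" when any two heavy atoms lie within
8 Å; precision is scored symmetry-aware at top 1/10/25/50/L/10/L/5/L.

The package also provides the surrounding toolchain: PDB/mmCIF parsing,
Shrake–Rupley SASA and interface areas, A3M/FASTA MSA handling with
diversity filtering, PSSM/M_eff/entropy, mean-field DCA with APC,
language-model feature ingestion (L×768 embeddings, L×L×144
attentions), dataset curation filters and greedy identity clustering,
contact-to-docking-restraint conversion (−100 kcal/mol piecewise well),
oligomeric-state calling from the maximum contact probability
(thresholds 0.77 and 0.97), and a synthetic Cn-symmetric benchmark
generator that makes everything runnable without downloads. The network
runs on an in-repo numpy autodiff engine; no GPU or deep-learning
framework is required.

## Worked example

```python
from tmcontact import synthdata, structures, evaluation, restraints

cplx = synthdata.make_toy_complex(n_chains=3, L=48, seed=5, regime="tmp")
cm = structures.interchain_contact_map(cplx, cutoff=8.0)
print("chains:", cplx.n_chains, "| L:", len(cplx.chains[0]))
print("contact density:", round(evaluation.contact_density(cplx), 4))
print("interface area A-B: %.1f A^2" % structures.interface_area(cplx, "A", "B"))
for r in (6.0, 10.0, 13.0):
    print(f"restraint energy at r={r:4.1f} A: {restraints.restraint_energy(r):7.1f} kcal/mol")
```

prints

```
chains: 3 | L: 48
contact density: 0.2917
interface area A-B: 110.2 A^2
restraint energy at r= 6.0 A:  -100.0 kcal/mol
restraint energy at r=10.0 A:   -50.0 kcal/mol
restraint energy at r=13.0 A:     0.0 kcal/mol
```

The toy trimer buries a ~110 Å² interface per chain pair; 26 of its
residue pairs touch across chains, a contact density of 0.29 (contacts
at the maximal interface over 2L). The three restraint energies show the
piecewise docking well: flat at −100 kcal/mol inside 8 Å, ramping
linearly to zero by 12 Å.

The full transfer protocol on the synthetic benchmark (60 soluble-like
training targets, 12 membrane-like, 8 held-out tests):

```python
from tmcontact.synthdata import build_transfer_benchmark
from tmcontact.train import run_protocol, TrainConfig

bench = build_transfer_benchmark(seed=101)
result = run_protocol(bench, TrainConfig(seed=101))
print(result.report.groupby("model")["top10"].mean())
```

trains the initial (IT), direct (DT), and fine-tuned (transfer) models
and reports their mean top-10 precision on the membrane-like test split;
the fine-tuned model outscores both baselines — the transfer-learning
effect the package exists to demonstrate.

A CLI mirrors the library: `tmcontact contacts|features|predict|train|
eval|restraints|synth|curate` (see `tmcontact --help`).

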