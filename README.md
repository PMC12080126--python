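# ensdock

Ensemble-docking toolkit for partially disordered proteins (PDPs).

Proteins with large intrinsically disordered regions have no single stable
fold: they live as a weighted conformational ensemble, and their functional
small-molecule binding sites are transient pockets that open and close along
the dynamics. Screening a large compound library against every pocket of
every conformation is multiplicatively expensive — the number of docking
runs is (compounds × sites). `ensdock` implements the deep ensemble docking
strategy for this problem:

1. **Ensemble analytics** — per-frame statistical weights from enhanced-
   sampling bias traces (Torrie–Valleau reweighting, w_i ∝ exp(V_i/k_BT)),
   weighted per-residue RMSF, radius of gyration, Shrake–Rupley SASA and
   holo/apo region exposure ratios, protein–ligand minimum distances.
2. **Restraint selection** — from a structure-prediction bundle (pLDDT,
   PAE, predicted distance matrix), select trustworthy inter-residue
   distance restraints (PAE below cutoff, not both residues inside a
   high-pLDDT structured region) and evaluate the metainference restraint
   energy of an ensemble: the Gaussian negative log-likelihood
   E = k_BT Σ_{r,i} (d_i(X_r) − d_i^pred)²/(2σ²_{r,i}) plus the error term
   k_BT Σ (log σ + ½ log 2π), with σ² = (σ^SEM)² + (σ^B)².
3. **Pocket selection** — filter grid-detector cavities with conjunctive
   physicochemical and dynamics criteria (>5 residues, Eisenberg–Weiss mean
   hydropathy ≤ 0, area in [80, 2480] Å², volume ≥ 120 Å³, mean lining
   RMSF < 4.1 nm), cluster the surviving sites by residue sharing
   (overlap coefficient > 0.6, single linkage), and emit docking boxes.
4. **Docking adapter** — per (compound, site) docking with best-of-five-
   poses bookkeeping into a compounds × sites energy matrix; a
   deterministic mock engine makes every downstream stage runnable and
   bit-reproducible without the external physics engine.
5. **QSAR surrogate screening** — per-site top-5% energy labeling, 1412-bit
   hashed topological path fingerprints, a feed-forward multilabel
   classifier (4 × 1256 ReLU reference architecture, dropout on first/last
   hidden layers, sigmoid outputs, BCE loss, best-mean-MCC epoch
   checkpointing), and library screening with the strict
   "active at > 70% of sites" multibinder rule, evaluated with per-site
   MCC, subset zero-one loss, Hamming loss and BCE.

The intended users are computational chemists and structural
bioinformaticians prototyping ensemble-docking campaigns against
disordered targets, and anyone who needs the individual operators
(reweighting, pocket filters, multilabel metrics) as tested building
blocks.

## Worked example

Train the surrogate on synthetic docking energies with planted multi-site
binders (chlorinated compounds boosted by 3 kcal/mol at 90% of 20 sites),
then screen the library for multibinders:

```python
from ensdock.fixtures import FixtureSpec, gen_energy_matrix, gen_smiles_library
from ensdock.qsar import (ModelConfig, SiteActivityClassifier, build_labels,
                          featurize, multibinding_hit_histogram, screen)

library = gen_smiles_library(2000, seed=7, motif_fraction=0.04)
ids = [f"cmpd-{k:04d}" for k in range(len(library))]
planted = [cid for cid, smi in zip(ids, library) if "Cl" in smi]
spec = FixtureSpec(n_compounds=2000, n_sites=20, n_planted=len(planted), seed=7)
energies, planted, _ = gen_energy_matrix(spec, ids, planted_ids=planted)

labels = build_labels(energies, percentile=5.0)
print("per-site active fraction:", labels.values().mean())

fingerprints, _ = featurize(library)
config = ModelConfig(hidden_sizes=(128, 128), epochs=25, seed=7)
results = SiteActivityClassifier(fingerprints, labels, config).fit()
print(results.summary())

selection = screen(results, library, ids, site_fraction_threshold=0.70)
print(f"selected {len(selection.selected)} compounds")
count, _ = multibinding_hit_histogram(labels, min_sites=14)
print(f"naive multibinding hits: {count}/{len(ids)}")
```

Output (abridged):

```
per-site active fraction: 0.05
Multilabel site-activity classifier
===================================================
sites: 20   best epoch: 1
test mean MCC:      0.6104
test Hamming loss:  0.0352
test zero-one loss: 0.4000
test BCE:           0.1400
...
selected 72 compounds
naive multibinding hits: 56/2000
```

The labeling rule marks exactly the lowest 5% of energies per site active.
The surrogate reaches a held-out mean per-site MCC of 0.61 (strong for a
95/5 imbalanced multilabel problem with irreducible label noise from the
random background tail), and the strict >70%-of-sites rule recovers 72 of
the 80 planted multibinders while the naive library contains only ~2.8%
multibinding hits — screening enriches the redocked set roughly 25-fold on
this fixture.

The same stages are scriptable from the shell via the `ensdock` CLI
(`ensdock ensemble-analyze | restraints | pockets | dock | label | train |
screen | hits | report`); `ensdock report` runs the whole fixture-scale
pipeline and prints the stage manifest.

## Layout

```
src/ensdock/
  ensemble.py     ensemble model, reweighting, RMSF/Rg/SASA/distances
  restraints.py   pLDDT/PAE restraint selection, metainference energy
  pockets.py      cavity filters, site clustering, docking boxes
  docking.py      engine adapters, mock scorer, energy matrix
  qsar.py         labels, fingerprints, metrics, classifier, screening
  _mlp.py         seeded NumPy feed-forward network
  fixtures.py     synthetic generators (ensembles, bundles, SMILES, energies)
  experiments.py  planted-binder enrichment experiment
  pipeline.py     stage orchestration with JSON manifest
  benchmarks.py   deposited-data benchmark harness
  cli.py          `ensdock` command line
docs/methods.md   model, parameters, numerics, limitations
```
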