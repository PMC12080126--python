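# Methods

This note documents the models and procedures `ensdock` implements, the
parameters that matter, the numerical choices, what the synthetic fixtures
do and do not emulate, and known limitations.

## Ensemble model and reweighting

A partially disordered protein is represented as a `StructuralEnsemble`:
an ordered list of conformations with non-negative per-frame weights
summing to 1 (tolerance 1e-9). Conformations store per-atom coordinates in
angstrom; all reported distances, radii of gyration and RMSF are converted
to nm (×0.1), SASA stays in Å².

Frames sampled under an enhanced-sampling bias V_i (kJ/mol, temperature T)
are unbiased with Torrie–Valleau weights w_i ∝ exp(V_i / k_B T),
k_B = 0.008314462618 kJ/(mol·K). The exponent is stabilized with
log-sum-exp, which also makes the weights exactly invariant under adding a
constant to the bias.

**RMSF.** Weighted root-mean-square fluctuation of each Cα about the
weighted mean position. Superposition is exposed as a flag and defaults to
*off*: for highly disordered chains the laboratory-frame fluctuation is the
quantity on the nm scale that the pocket filter threshold refers to; with
`superpose=True` each frame is first aligned to the weighted mean structure
by weighted least squares (Kabsch, two refinement passes). Permuting frame
order or rescaling all weights leaves the result unchanged.

**Radius of gyration** is mass-weighted by default (standard atomic
masses; unknown elements fall back to carbon), so equal-mass toy systems
reduce to the geometric formula.

**SASA** uses Shrake–Rupley sphere sampling: each atom inflated by the
probe radius (default 1.4 Å water probe) is sampled with a deterministic
golden-spiral quadrature (default 960 points per sphere; minimum 32), and a
point is accessible when outside every other inflated atom. Van der Waals
radii come from a fixed Bondi-style table; an unknown element is an error
naming the atom. At 960 points the two-sphere result agrees with the
analytic cap formula to well under 1%. Residue SASA sums its atoms; the
ensemble value is the weight-averaged residue SASA. The holo/apo region
ratio divides weighted-mean region SASA of the ligand-bound ensemble by the
free one; a region with zero apo SASA is flagged and excluded from the mean
of per-region ratios (which is unweighted across regions).

## Restraint selection and the metainference score

From a prediction bundle (per-residue pLDDT in [0,1], pairwise PAE and
predicted distances in Å):

- **Structured regions** are maximal contiguous runs with pLDDT strictly
  above the threshold (default 0.75).
- **Restraints** are unordered residue pairs (i < j) with symmetrized PAE
  strictly below the cutoff (default 4 Å), sequence separation at least
  `min_separation` (default 3), excluding pairs whose two residues both
  lie in structured regions (those are restrained by other means, and the
  disordered-chain prior is not parameterized for them). PAE matrices are
  asymmetric; the pair value is min(pae[i,j], pae[j,i]) — the lenient
  choice consistent with applying the cutoff per distance — with `mean` as
  a config alternative. Restraint count is monotone in the cutoff.

The **metainference restraint energy** of replicas X_r against targets
d_i^pred is the Gaussian negative log-likelihood scaled by k_B T:

    data_term  = k_B T Σ_{r,i} (d_i(X_r) − d_i^pred)² / (2 σ²_{r,i})
    error_term = k_B T Σ_{r,i} (log σ_{r,i} + ½ log 2π)

with σ²_{r,i} = (σ_i^SEM)² + (σ_{r,i}^B)², the forward model d_i(X) being
the Cα–Cα distance (the prior model is one-bead-per-residue), and every σ
required to lie in the sampling range [0.0001, 10] Å. The √(2π)
normalization is included so the total is a true negative log-likelihood;
doubling every σ divides the data term by exactly 4. The
molecular-dynamics prior energy and the Gibbs sampling of σ belong to a
simulation engine and are deliberately not implemented here — the
evaluator takes σ values as inputs. Reference enhanced-sampling settings
(parallel-bias metadynamics: hill height 0.5 kJ/mol, deposition pace 200
steps, bias factor 35, six replicas) are recorded here for provenance
only.

## Pocket selection

Cavity records carry frame id, lining-residue set, volume, area, depths
and mean Eisenberg–Weiss hydropathy (embedded consensus scale). A cavity
becomes a binding site iff **all** of: strictly more than 5 residues; mean
hydropathy ≤ 0; area within [80, 2480] Å²; volume ≥ 120 Å³; and mean
lining-residue RMSF strictly below 4.1. The RMSF statistic is the mean
over lining residues (max is a config alternative). The threshold's unit
is treated as nm; the alternative published value 4.5 nm appears in
sticky-residue analyses and both are plain config values. Filtering is
conjunctive, order-independent, idempotent, and site ids are deterministic
in (frame, detection order).

**Clustering.** Sites sharing more than the threshold fraction of residues
(default 0.6) are linked; clusters are connected components (single
linkage). Sharing is the overlap coefficient |A∩B| / min(|A|, |B|) —
tolerant of nested pockets of unequal size — with Jaccard as the config
alternative. Cluster count is monotone non-increasing as the threshold
decreases.

**Docking boxes** are axis-aligned bounding boxes of the lining-residue Cα
coordinates padded by 5 Å per side; a degenerate zero-edge box is returned
with a warning.

Cavity *detection* itself is an adapter contract to an external grid-based
detector run at its default parameters; the fixture backend injects
pre-specified cavities so the rest of the pipeline is testable without it.

## Docking adapter

Ligands are prepared from SMILES with RDKit (parse, protonate, seeded ETKDG
3D embedding); unparseable SMILES are rejected naming the compound. An
engine is asked for 5 poses per (compound, site) and the minimum pose
energy (kcal/mol) is bookkept; engine failures become missing matrix cells,
never crashes, and missing cells are excluded from labeling denominators.
The mock engine derives energies from a SHA-256 hash of
(compound, site, seed) mapped through the normal quantile function —
bit-reproducible across platforms — with baseline N(−5, 1) kcal/mol and an
exact planted boost Δ for designated (compound, site) pairs. The external
docking binary is wrapped behind the same pose-scoring interface with
num_modes=5 and engine defaults otherwise.

## Labels, fingerprints, classifier, screening

**Labeling.** Per site, sort the n non-missing energies ascending and take
the order statistic at index k = ceil(n·p/100) (0-based) as the threshold;
a compound is active iff its energy is strictly below it. On tie-free data
with n divisible by 100/p this gives exactly n·p/100 actives; ties at the
threshold are inactive. Default percentile p = 5.

**Oversampling.** Compounds with at least one active label are resampled
with replacement and appended until the pool's mean per-site active
fraction reaches a target (default 0.25), capped at 10× the active count
when the target is unreachable by duplication (a warning is emitted);
originals are always retained and the resampling is seeded.

**Fingerprints.** Hashed linear-path topological fingerprints (path
lengths 1–7) folded to 1412 bits via RDKit; canonical-equal SMILES give
identical rows; invalid SMILES are reported per row.

**Classifier.** A feed-forward multilabel network: ReLU hidden layers with
inverted dropout (rate 0.2) on the first and last hidden layers, per-site
sigmoid outputs, mean binary cross-entropy loss, Adam (step 1e-3), He
initialization, all randomness through one seeded PCG64 generator. The
network is implemented in NumPy inside the package (`_mlp.py`). The
reference architecture is 4 × 1256 units; fixture-scale runs use smaller
configurations (e.g. 2 × 128, 25 epochs) so training completes in seconds
on one CPU. Compounds are split 80/10/10 into train/validation/test (a
90/10/10 split would sum to 110%; the fractions are configurable).
Validation mean per-site MCC is tracked every epoch and the best epoch's
weights are the checkpoint; the reported metrics are computed on the
held-out test split. A site whose validation/test truth is single-class
has undefined MCC and is excluded from the mean rather than imputed.

**Metrics.** MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
defined as 0 when a denominator factor vanishes; subset zero-one loss
(a sample counts 1 unless every label matches); Hamming loss (fraction of
wrong cells); BCE with 1e-7 probability clipping. All cross-checked
against scikit-learn in the tests.

**Screening.** Predicted probabilities are binarized at 0.5 (the
conventional choice); a compound is selected when its active-site fraction
is strictly greater than the threshold (default 0.70 — with 41 sites that
requires ≥ 29 active sites; with 20 sites, ≥ 15). The multibinding hit
histogram counts compounds active at strictly more than `min_sites` sites.

## Synthetic fixtures: what they emulate and what they do not

The generators produce every input the pipeline consumes, deterministically
under a seed:

- **Toy ensembles**: self-avoiding random-walk Cα chains (3.8 Å virtual
  bonds), each frame a perturbation of a base chain with small amplitude
  (0.3 Å) inside a designated rigid block and large amplitude (5 Å)
  elsewhere, so the block has lower RMSF by construction. Bias traces are
  N(5, 2) kJ/mol at 298 K.
- **Prediction bundles**: predicted distances are the reference Cα
  distances (plus optional noise), PAE is low exactly on designated
  confident pairs, pLDDT is high inside the rigid block — so the selected
  restraints are known in advance and the metainference data term is zero
  at the reference conformation.
- **Cavity sets**: residue-window cavities where a stated fraction is
  constructed to pass all filters and the rest each violate at least one.
- **SMILES libraries**: enumerated from a small scaffold grammar
  (aliphatics, alcohols, amines, substituted benzenes/pyridines; ~5400
  canonically unique structures), guaranteeing parseability and
  uniqueness. A requested fraction carries a chlorine motif.
- **Energy matrices**: baseline i.i.d. N(−5, 1) kcal/mol; planted
  multibinders (by default the motif-bearing compounds, so the signal is
  structurally learnable) get an extra −Δ (default 3 kcal/mol = 3σ) at a
  per-compound random subset of ceil(0.9 × n_sites) sites. The planted
  site fraction was calibrated once by simulation so that planted-binder
  recovery through the screen has power above 0.95 at Δ = 3σ, and pinned.

Default fixture scale: 60 residues × 50 frames; 2000 compounds × 20 sites
with 80 planted binders. These sizes keep the full test suite and the
acceptance script within a couple of minutes on one CPU.

What passing fixture tests shows: the operators implement their stated
contracts, the surrogate learns a genuinely present structure–activity
signal, and screening enriches multibinders end-to-end. What it does not
show: performance on real docking energies (whose noise is neither
Gaussian nor independent across sites), chemically realistic conformers,
real pocket geometry, or force-field validity — the fixtures are
deliberately minimal statistical stand-ins.

## Numerical choices and degenerate inputs

- Weights must sum to 1 within 1e-9; zero-weight frames are allowed.
- SASA quadrature is deterministic (golden spiral), so results are exactly
  reproducible; accuracy grows with `n_sphere_points` (default 960 for
  single conformations, 240 inside ensemble averages).
- MCC zero-denominator → 0; single-class sites → excluded from means.
- The enrichment experiment trains once and evaluates 100 replicate
  libraries (250 compounds each) drawn from grammar structures disjoint
  from the training compounds; a replicate with an empty selection scores
  a screened hit rate of 0.
- Strictness conventions: labeling `<` threshold, selection `>` site
  fraction, histogram `>` min_sites, structured regions `>` pLDDT
  threshold, clustering `>` overlap threshold.

## Limitations

- The external cavity detector and docking engine are adapter contracts;
  their scientific behaviour is not reproduced, only consumed.
- The metainference evaluator scores ensembles against restraints; it does
  not sample (no MD prior, no σ sampling).
- Entropy estimation and secondary-structure/phase-separation predictors
  are out of scope.
- Full-scale benchmark counts (thousands of cavities, tens of sites,
  thousands of restraints and compounds) require externally deposited
  reference archives and external engines; `ensdock.benchmarks` runs them when the
  data are staged locally.
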