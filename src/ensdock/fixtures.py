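"""Synthetic inputs for every pipeline stage.

Generators here produce toy conformational ensembles, structure-prediction
bundles, cavity sets, energy matrices with planted multi-site binders, and
syntactically valid SMILES libraries, so the whole pipeline runs and is
testable with no external data or engines.  Planted binders can be tied to
a structural motif (a chlorine substituent by default) so the QSAR
surrogate has a genuinely learnable signal; the ground truth is always
returned alongside the generated data.

All randomness flows through ``numpy.random.default_rng(seed)``; every
generator is bit-deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement, product
from typing import Sequence

import numpy as np
import pandas as pd

from ensdock.docking import EnergyMatrix
from ensdock.ensemble import BiasTrace, Conformation, StructuralEnsemble
from ensdock.pockets import Cavity
from ensdock.restraints import PredictionBundle

CA_BOND = 3.8  # angstrom, virtual C-alpha bond length


@dataclass
class FixtureSpec:
    """Condition knobs for the synthetic generators.

    Defaults mirror the fixture scale the package is exercised at: a
    50-frame, 60-residue toy chain; 2000 compounds over 20 sites with 80
    planted multibinders boosted by 3 kcal/mol (three baseline standard
    deviations) at 90% of the sites.  The planted-site fraction was
    calibrated once by simulation so that planted-binder recovery through
    the screen has power above 0.95 at a 3-sigma boost, then pinned.
    """

    n_residues: int = 60
    n_frames: int = 50
    n_compounds: int = 2000
    n_sites: int = 20
    n_planted: int = 80
    boost: float = 3.0  # kcal/mol, planted stabilization (Delta)
    planted_site_fraction: float = 0.9
    base_mean: float = -5.0  # kcal/mol
    noise_scale: float = 1.0  # kcal/mol, baseline energy s.d.
    rigid_block: tuple[int, int] | None = (10, 20)  # 1-based inclusive
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.planted_site_fraction <= 1.0):
            raise ValueError("planted_site_fraction must be in (0, 1]")
        if self.boost < 0:
            raise ValueError("boost must be non-negative")


# ---------------------------------------------------------------------------
# Toy ensembles


def _self_avoiding_walk(n: int, rng: np.random.Generator, min_sep: float = 3.0) -> np.ndarray:
    """C-alpha chain with fixed virtual bonds and soft self-avoidance."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(60):
            step = rng.normal(size=3)
            step *= CA_BOND / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)) > min_sep:
                coords[i] = cand
                break
        else:  # fall back to whatever the last candidate was
            coords[i] = cand
    return coords


def gen_toy_ensemble(spec: FixtureSpec) -> tuple[StructuralEnsemble, BiasTrace]:
    """Self-avoiding random-walk C-alpha ensemble with an optional rigid block.

    Every frame is a fresh perturbation of a base chain: residues inside
    ``spec.rigid_block`` fluctuate with a small amplitude (0.3 A) emulating
    a structured domain, all others with a large one (5 A), so the rigid
    block has lower RMSF by construction.  The bias trace is drawn from a
    normal distribution (mean 5, s.d. 2 kJ/mol) at 298 K.
    """
    if spec.n_residues < 5:
        raise ValueError("need at least 5 residues")
    rng = np.random.default_rng(spec.seed)
    base = _self_avoiding_walk(spec.n_residues, rng)
    amp = np.full(spec.n_residues, 5.0)
    if spec.rigid_block is not None:
        a, b = spec.rigid_block
        amp[a - 1 : b] = 0.3
    res_ids = np.arange(1, spec.n_residues + 1)
    names = np.array(["CA"] * spec.n_residues, dtype=object)
    elements = np.array(["C"] * spec.n_residues, dtype=object)
    res_names = np.array(["GLY"] * spec.n_residues, dtype=object)
    frames = []
    for _ in range(spec.n_frames):
        disp = rng.normal(size=(spec.n_residues, 3)) * amp[:, None]
        frames.append(
            Conformation(
                residue_ids=res_ids,
                coords=base + disp,
                elements=elements,
                atom_names=names,
                res_names=res_names,
            )
        )
    ens = StructuralEnsemble(frames)
    bias = BiasTrace(bias=rng.normal(5.0, 2.0, size=spec.n_frames), temperature=298.0)
    return ens, bias


# ---------------------------------------------------------------------------
# Prediction bundles


def gen_prediction_bundle(
    spec: FixtureSpec,
    reference: Conformation,
    confident_pairs: Sequence[tuple[int, int]] | None = None,
    noise: float = 0.0,
    low_pae: float = 1.0,
    high_pae: float = 10.0,
) -> PredictionBundle:
    """Prediction bundle whose restraint selection is known by construction.

    Predicted distances are the reference C-alpha distances plus optional
    Gaussian noise; PAE is ``low_pae`` on the designated confident pairs
    (all pairs when None) and ``high_pae`` elsewhere; pLDDT is 0.95 inside
    the rigid block and 0.3 elsewhere.
    """
    rng = np.random.default_rng(spec.seed + 1)
    res_ids, ca = reference.ca_coords()
    n = len(res_ids)
    diff = ca[:, None, :] - ca[None, :, :]
    d_af = np.sqrt((diff**2).sum(axis=2))
    if noise > 0:
        pert = rng.normal(0.0, noise, size=(n, n))
        d_af = np.abs(d_af + 0.5 * (pert + pert.T))
    pae = np.full((n, n), high_pae)
    if confident_pairs is None:
        pae[:] = low_pae
    else:
        for i, j in confident_pairs:
            pae[i - 1, j - 1] = low_pae
            pae[j - 1, i - 1] = low_pae
    plddt = np.full(n, 0.3)
    if spec.rigid_block is not None:
        a, b = spec.rigid_block
        plddt[a - 1 : b] = 0.95
    return PredictionBundle(plddt=plddt, pae=pae, d_af=d_af)


# ---------------------------------------------------------------------------
# Cavities


def gen_cavity_set(
    spec: FixtureSpec,
    ensemble: StructuralEnsemble,
    n_cavities_per_frame: int = 4,
    pass_fraction: float = 0.5,
) -> list[Cavity]:
    """Random residue-window cavities, a stated fraction built to pass filters.

    Passing cavities get >5 residues, hydrophobic mean hydropathy, area and
    volume inside the default filter window, and are windows drawn inside
    the rigid (low-RMSF) block neighbourhood; failing cavities violate at
    least one of those conditions.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n_res = spec.n_residues
    cavities = []
    for frame_id in range(ensemble.n_frames):
        for k in range(n_cavities_per_frame):
            should_pass = rng.random() < pass_fraction
            if should_pass and spec.rigid_block is not None:
                a, b = spec.rigid_block
                width = int(rng.integers(6, max(7, b - a + 1)))
                start = int(rng.integers(a, max(a + 1, b - width + 2)))
                residues = range(start, min(start + width, n_res) + 1)
                cav = Cavity(
                    frame_id=frame_id,
                    residues=frozenset(residues),
                    volume=float(rng.uniform(150, 800)),
                    area=float(rng.uniform(120, 2000)),
                    avg_hydropathy=float(rng.uniform(-1.0, -0.1)),
                )
            else:
                mode = rng.integers(0, 4)
                start = int(rng.integers(1, n_res - 4))
                residues = frozenset(range(start, start + 4))  # too few residues
                volume, area, hyd = 200.0, 500.0, -0.5
                if mode == 1:
                    residues = frozenset(range(start, min(start + 8, n_res + 1)))
                    hyd = 0.8  # hydropathy above the upper cutoff
                elif mode == 2:
                    residues = frozenset(range(start, min(start + 8, n_res + 1)))
                    area = 3000.0
                elif mode == 3:
                    residues = frozenset(range(start, min(start + 8, n_res + 1)))
                    volume = 50.0
                cav = Cavity(
                    frame_id=frame_id,
                    residues=residues,
                    volume=volume,
                    area=area,
                    avg_hydropathy=hyd,
                )
            cavities.append(cav)
    return cavities


# ---------------------------------------------------------------------------
# SMILES libraries


_ALKYL = ["C", "CC", "CCC", "CC(C)C", "CCCC", "CCO", "CC(C)O", "CCN", "C(C)C"]
_SUBSTITUENTS = [
    "C", "CC", "CCC", "O", "OC", "OCC", "N", "N(C)C", "Cl", "CCl",
    "CCO", "C(C)C", "CC(C)C", "F", "C(F)(F)F", "C=C",
]


def _grammar_pool() -> list[str]:
    """Enumerate the scaffold grammar (alkanes/alcohols/substituted arenes)."""
    pool: list[str] = []
    # linear / branched aliphatics with optional heteroatom cap
    for chain in range(2, 9):
        backbone = "C" * chain
        for cap in ("", "O", "N", "Cl"):
            pool.append(backbone + cap)
        if chain >= 4:
            for cap in ("C", "O", "Cl"):
                pool.append("C" * (chain - 2) + "C(C)" + cap)
    for a in _ALKYL:
        pool.append(f"{a}OC")
        pool.append(f"{a}OCC")
    # mono-substituted benzenes and pyridines
    for r in _SUBSTITUENTS:
        pool.append(f"c1ccccc1{r}")
        pool.append(f"{r}c1ccncc1")
    # di-substituted (ortho/meta/para) benzenes, ordered pairs
    patterns = ["c1ccc({r1})c({r2})c1", "c1cc({r1})cc({r2})c1", "c1cc({r1})ccc1{r2}"]
    for r1, r2 in product(_SUBSTITUENTS, repeat=2):
        for pat in patterns:
            pool.append(pat.format(r1=r1, r2=r2))
    # tri-substituted (1,3,5 and 1,2,4) benzenes
    for r1, r2, r3 in combinations_with_replacement(_SUBSTITUENTS, 3):
        pool.append(f"c1c({r1})cc({r2})cc1{r3}")
    for r1, r2, r3 in product(_SUBSTITUENTS, repeat=3):
        pool.append(f"c1cc({r1})c({r2})cc1{r3}")
    return pool


def gen_smiles_library(
    n: int,
    seed: int = 0,
    motif: str = "Cl",
    motif_fraction: float | None = None,
) -> list[str]:
    """Seeded library of valid, canonically unique SMILES.

    Strings are enumerated from a small scaffold grammar (aliphatics,
    alcohols, amines, substituted benzenes), canonicalized and de-duplicated
    with RDKit, then sampled.  With ``motif_fraction`` set, that fraction of
    the returned library contains the motif substring (chlorine by default),
    giving downstream planted-binder fixtures a learnable structural signal.
    """
    from rdkit import Chem

    canon: dict[str, str] = {}
    for smi in _grammar_pool():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon.setdefault(Chem.MolToSmiles(mol), smi)
    unique = sorted(canon.keys())
    rng = np.random.default_rng(seed)
    if motif_fraction is None:
        if n > len(unique):
            raise ValueError(f"requested {n} > grammar capacity {len(unique)}")
        picks = rng.choice(len(unique), size=n, replace=False)
        return [unique[i] for i in picks]
    with_motif = [s for s in unique if motif in s]
    without = [s for s in unique if motif not in s]
    n_motif = int(round(motif_fraction * n))
    if n_motif > len(with_motif) or (n - n_motif) > len(without):
        raise ValueError(
            f"capacity exceeded: {len(with_motif)} motif / {len(without)} plain "
            f"structures available, {n_motif}/{n - n_motif} requested"
        )
    chosen = [with_motif[i] for i in rng.choice(len(with_motif), n_motif, replace=False)]
    chosen += [without[i] for i in rng.choice(len(without), n - n_motif, replace=False)]
    rng.shuffle(chosen)
    return chosen


# ---------------------------------------------------------------------------
# Energy matrices


def gen_energy_matrix(
    spec: FixtureSpec,
    compound_ids: Sequence[str] | None = None,
    planted_ids: Sequence[str] | None = None,
) -> tuple[EnergyMatrix, list[str], dict[str, list[str]]]:
    """Energy matrix with planted multi-site binders and its ground truth.

    Baseline energies are i.i.d. normal(base_mean, noise_scale) kcal/mol.
    Planted compounds (chosen at random unless ``planted_ids`` is given)
    receive an extra ``-boost`` at a per-compound random subset of
    ceil(planted_site_fraction * n_sites) sites.  Returns the matrix, the
    planted compound ids, and the per-compound boosted-site map.
    """
    if planted_ids is None and spec.n_compounds <= 20 * spec.n_planted:
        raise ValueError("need n_compounds > 20 * n_planted")
    rng = np.random.default_rng(spec.seed + 3)
    if compound_ids is None:
        compound_ids = [f"cmpd-{k:05d}" for k in range(spec.n_compounds)]
    compound_ids = list(compound_ids)
    site_ids = [f"site-{k:02d}" for k in range(spec.n_sites)]
    energies = rng.normal(spec.base_mean, spec.noise_scale, size=(len(compound_ids), spec.n_sites))
    if planted_ids is None:
        picks = rng.choice(len(compound_ids), size=spec.n_planted, replace=False)
        planted = [compound_ids[i] for i in sorted(picks)]
    else:
        planted = [c for c in compound_ids if c in set(planted_ids)]
    n_boost = int(np.ceil(spec.planted_site_fraction * spec.n_sites))
    site_map: dict[str, list[str]] = {}
    index = {c: i for i, c in enumerate(compound_ids)}
    for cid in planted:
        cols = rng.choice(spec.n_sites, size=n_boost, replace=False)
        energies[index[cid], cols] -= spec.boost
        site_map[cid] = [site_ids[c] for c in sorted(cols)]
    table = pd.DataFrame(energies, index=compound_ids, columns=site_ids)
    return EnergyMatrix(table), planted, site_map
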