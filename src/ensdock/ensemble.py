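"""Ensemble data model, reweighting, and per-residue structural analytics.

A partially disordered protein is represented by a :class:`StructuralEnsemble`:
an ordered set of conformations with normalized statistical weights that
approximate a Boltzmann population.  Analytics in this module (RMSF, radius
of gyration, solvent-accessible surface area, ligand distances) are
weight-aware so that biased-sampling ensembles can be analysed after
Torrie–Valleau reweighting.

Units: coordinates are stored in angstrom; distances, radii of gyration and
RMSF are reported in nm; SASA in angstrom squared; bias energies in kJ/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

#: Boltzmann constant in kJ/(mol K).
KB_KJ_PER_MOL_K = 0.008314462618

ANGSTROM_PER_NM = 10.0

#: Van der Waals radii (angstrom), Bondi-style published values.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Standard atomic masses (unified amu) for mass-weighted statistics.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}


@dataclass
class Conformation:
    """One frame of the ensemble: per-atom coordinates plus identity.

    ``residue_ids`` are 1-based and non-decreasing atom-by-atom (strictly
    increasing residue-by-residue).  An optional ligand block is flagged by
    the boolean ``is_ligand`` mask.
    """

    residue_ids: np.ndarray  # (n_atoms,) int
    coords: np.ndarray  # (n_atoms, 3) float, angstrom
    elements: np.ndarray  # (n_atoms,) str
    atom_names: np.ndarray  # (n_atoms,) str
    res_names: np.ndarray  # (n_atoms,) str
    is_ligand: np.ndarray | None = None  # (n_atoms,) bool

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.elements = np.asarray(self.elements, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.res_names = np.asarray(self.res_names, dtype=object)
        if self.is_ligand is None:
            self.is_ligand = np.zeros(len(self.residue_ids), dtype=bool)
        self.is_ligand = np.asarray(self.is_ligand, dtype=bool)
        if self.coords.shape != (len(self.residue_ids), 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        prot_res = self.residue_ids[~self.is_ligand]
        if len(prot_res) and np.any(np.diff(prot_res) < 0):
            raise ValueError("protein residue ids must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.residue_ids)

    @property
    def protein_residue_ids(self) -> np.ndarray:
        """Sorted unique residue ids of the protein block."""
        return np.unique(self.residue_ids[~self.is_ligand])

    def ca_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(residue_ids, coords) of C-alpha atoms of the protein block."""
        mask = (~self.is_ligand) & (self.atom_names == "CA")
        return self.residue_ids[mask], self.coords[mask]


@dataclass
class BiasTrace:
    """Per-frame enhanced-sampling bias energies (kJ/mol) at temperature T (K)."""

    bias: np.ndarray
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float)
        if self.bias.ndim != 1 or len(self.bias) == 0:
            raise ValueError("bias must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.bias)):
            raise ValueError("bias energies must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class StructuralEnsemble:
    """Ordered conformations with normalized per-frame statistical weights."""

    frames: list[Conformation]
    weights: np.ndarray | None = None
    replica_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ensemble must contain at least one frame")
        n = len(self.frames)
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != n:
            raise ValueError("one weight per frame required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total!r})")
        ref = self.frames[0]
        for i, fr in enumerate(self.frames[1:], start=1):
            if not np.array_equal(
                fr.residue_ids[~fr.is_ligand], ref.residue_ids[~ref.is_ligand]
            ) or not np.array_equal(
                fr.atom_names[~fr.is_ligand], ref.atom_names[~ref.is_ligand]
            ):
                raise ValueError(f"frame {i} atom naming differs from frame 0")
        if self.replica_ids is not None:
            self.replica_ids = np.asarray(self.replica_ids, dtype=int)
            if len(self.replica_ids) != n:
                raise ValueError("one replica id per frame required")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_replicas(self) -> int | None:
        if self.replica_ids is None:
            return None
        return len(np.unique(self.replica_ids))

    def reweighted(self, weights: np.ndarray) -> "StructuralEnsemble":
        return StructuralEnsemble(self.frames, weights, self.replica_ids)


@dataclass
class RegionSet:
    """Named residue intervals, 1-based inclusive; one name may own several."""

    regions: Mapping[str, Sequence[tuple[int, int]]]

    def __post_init__(self) -> None:
        for name, intervals in self.regions.items():
            for start, end in intervals:
                if not (1 <= start <= end):
                    raise ValueError(f"bad interval {start}-{end} in region {name!r}")

    def residue_ids(self, name: str) -> np.ndarray:
        ids: list[int] = []
        for start, end in self.regions[name]:
            ids.extend(range(start, end + 1))
        return np.unique(ids)


# ---------------------------------------------------------------------------
# Reweighting


def torrie_valleau_weights(bias: BiasTrace) -> np.ndarray:
    """Unbiasing weights from a metadynamics bias trace.

    Frames sampled under a bias potential V are reweighted with
    w_i ∝ exp(V_i / kB T); the exponent is shifted by its maximum before
    exponentiation, so the result is invariant under adding a constant to
    the bias and numerically safe for large biases.
    """
    x = bias.bias / (KB_KJ_PER_MOL_K * bias.temperature)
    logw = x - logsumexp(x)
    return np.exp(logw)


# ---------------------------------------------------------------------------
# RMSF


def _kabsch(mobile: np.ndarray, target: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least-squares superposition of ``mobile`` onto ``target``."""
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    tc = (w[:, None] * target).sum(axis=0)
    a = mobile - mc
    b = target - tc
    h = (w[:, None] * a).T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    del b
    return (a @ rot.T) + tc


def residue_rmsf(
    ensemble: StructuralEnsemble,
    selection: Iterable[int] | None = None,
    superpose: bool = False,
) -> pd.Series:
    """Weighted per-residue root-mean-square fluctuation (nm) over C-alpha.

    Fluctuations are taken about the weighted mean position.  With
    ``superpose=True`` every frame is first superposed onto the weighted mean
    structure by weighted least squares over the selected C-alpha atoms
    (two refinement passes); the default leaves frames in their original
    laboratory frame, which is the convention that yields nm-scale values
    for highly disordered chains.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    res_ids, _ = ensemble.frames[0].ca_coords()
    if selection is not None:
        sel = np.asarray(sorted(set(int(r) for r in selection)))
        if len(sel) == 0:
            raise ValueError("selection is empty")
        missing = set(sel) - set(res_ids.tolist())
        if missing:
            raise ValueError(f"selection residues not in ensemble: {sorted(missing)}")
        keep = np.isin(res_ids, sel)
    else:
        keep = np.ones(len(res_ids), dtype=bool)
    coords = np.stack([fr.ca_coords()[1][keep] for fr in ensemble.frames])
    ids = res_ids[keep]
    w = ensemble.weights / ensemble.weights.sum()
    if superpose:
        atom_w = np.ones(coords.shape[1])
        for _ in range(2):
            mean = np.einsum("f,fij->ij", w, coords)
            coords = np.stack([_kabsch(c, mean, atom_w) for c in coords])
    mean = np.einsum("f,fij->ij", w, coords)
    sq = ((coords - mean[None]) ** 2).sum(axis=2)  # (frames, residues)
    rmsf_ang = np.sqrt(np.einsum("f,fi->i", w, sq))
    return pd.Series(rmsf_ang / ANGSTROM_PER_NM, index=ids, name="rmsf_nm")


# ---------------------------------------------------------------------------
# Radius of gyration


def radius_of_gyration(
    conformation: Conformation,
    selection: Iterable[int] | None = None,
    mass_weighted: bool = True,
) -> float:
    """Mass-weighted radius of gyration (nm) of the selected residues."""
    mask = ~conformation.is_ligand
    if selection is not None:
        sel = np.asarray(sorted(set(int(r) for r in selection)))
        if len(sel) == 0:
            raise ValueError("selection is empty")
        mask &= np.isin(conformation.residue_ids, sel)
    if not mask.any():
        raise ValueError("selection matches no atoms")
    xyz = conformation.coords[mask]
    if mass_weighted:
        masses = np.array(
            [ATOMIC_MASSES.get(str(e).upper(), 12.011) for e in conformation.elements[mask]]
        )
    else:
        masses = np.ones(mask.sum())
    com = (masses[:, None] * xyz).sum(axis=0) / masses.sum()
    rg2 = (masses * ((xyz - com) ** 2).sum(axis=1)).sum() / masses.sum()
    return float(np.sqrt(rg2)) / ANGSTROM_PER_NM


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley sphere sampling)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    conformation: Conformation,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: Mapping[str, float] | None = None,
    per_atom: bool = False,
) -> pd.Series:
    """Per-residue solvent-accessible surface area (A^2), Shrake–Rupley style.

    Each atom is inflated by the probe radius and sampled with a fixed
    golden-spiral quadrature of ``n_sphere_points`` points; a point is
    accessible when it lies outside every other inflated atom.  Atom SASA is
    the accessible fraction of the sphere area 4*pi*(r+probe)^2 and residue
    SASA sums its atoms.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32")
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    elems = [str(e).upper() for e in conformation.elements]
    unknown = [
        f"{name} ({el})"
        for name, el in zip(conformation.atom_names, elems)
        if el not in table
    ]
    if unknown:
        raise ValueError(f"no van der Waals radius for atoms: {unknown[:5]}")
    r = np.array([table[e] for e in elems]) + probe_radius
    xyz = conformation.coords
    n_atoms = len(r)
    unit = _sphere_points(n_sphere_points)
    atom_sasa = np.empty(n_atoms)
    # neighbour lists keep the test point loop O(n_points * n_neighbours)
    d = cdist(xyz, xyz)
    for i in range(n_atoms):
        nbr = np.where((d[i] < r[i] + r) & (np.arange(n_atoms) != i))[0]
        pts = xyz[i] + r[i] * unit
        if len(nbr):
            buried = (
                cdist(pts, xyz[nbr]) < r[nbr][None, :]
            ).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        atom_sasa[i] = frac * 4.0 * np.pi * r[i] ** 2
    if per_atom:
        return pd.Series(atom_sasa, name="sasa_A2")
    return pd.Series(atom_sasa, index=conformation.residue_ids).groupby(level=0).sum().rename("sasa_A2")


def ensemble_residue_sasa(
    ensemble: StructuralEnsemble, probe_radius: float = 1.4, n_sphere_points: int = 240
) -> pd.Series:
    """Weight-averaged per-residue SASA (A^2) over the ensemble."""
    acc = None
    for w, fr in zip(ensemble.weights, ensemble.frames):
        s = shrake_rupley_sasa(fr, probe_radius, n_sphere_points)
        acc = w * s if acc is None else acc.add(w * s, fill_value=0.0)
    return acc.rename("sasa_A2")


def region_sasa_ratio(
    holo: StructuralEnsemble,
    apo: StructuralEnsemble,
    regions: RegionSet,
    probe_radius: float = 1.4,
    n_sphere_points: int = 240,
) -> pd.DataFrame:
    """Holo/apo ratio of weighted-mean region SASA, per region plus the mean.

    Quantifies ligand-induced changes in solvent exposure, e.g. shielding of
    phase-separation-prone regions by a bound modulator.  Regions whose apo
    SASA is zero are flagged and excluded from the mean row.
    """
    holo_sasa = ensemble_residue_sasa(holo, probe_radius, n_sphere_points)
    apo_sasa = ensemble_residue_sasa(apo, probe_radius, n_sphere_points)
    rows = []
    for name in regions.regions:
        ids = regions.residue_ids(name)
        h = holo_sasa.reindex(ids).fillna(0.0).sum()
        a = apo_sasa.reindex(ids).fillna(0.0).sum()
        if a == 0.0:
            warnings.warn(f"region {name!r} has zero apo SASA; excluded from mean")
            rows.append((name, np.nan, True))
        else:
            rows.append((name, h / a, False))
    df = pd.DataFrame(rows, columns=["region", "ratio", "flagged"]).set_index("region")
    valid = df.loc[~df["flagged"], "ratio"]
    df.loc["mean"] = [valid.mean() if len(valid) else np.nan, False]
    return df


# ---------------------------------------------------------------------------
# Ligand distances


def min_ligand_distance(conformation: Conformation) -> float:
    """Minimum heavy-atom protein–ligand distance (nm)."""
    lig = conformation.is_ligand
    heavy = np.array([str(e).upper() != "H" for e in conformation.elements])
    lig_xyz = conformation.coords[lig & heavy]
    prot_xyz = conformation.coords[~lig & heavy]
    if len(lig_xyz) == 0:
        raise ValueError("conformation has no ligand heavy atoms")
    if len(prot_xyz) == 0:
        raise ValueError("conformation has no protein heavy atoms")
    return float(cdist(prot_xyz, lig_xyz).min()) / ANGSTROM_PER_NM


# ---------------------------------------------------------------------------
# I/O


def read_pdb_ensemble(path: str | Path, ligand_resnames: Sequence[str] = ()) -> StructuralEnsemble:
    """Read a multi-model PDB file into an ensemble with uniform weights."""
    import biotite.structure.io.pdb as pdb

    pf = pdb.PDBFile.read(str(path))
    stack = pf.get_structure(model=None)
    frames = []
    for model in stack:
        is_lig = np.isin(model.res_name, list(ligand_resnames)) | model.hetero
        frames.append(
            Conformation(
                residue_ids=model.res_id,
                coords=model.coord,
                elements=model.element,
                atom_names=model.atom_name,
                res_names=model.res_name,
                is_ligand=is_lig,
            )
        )
    return StructuralEnsemble(frames)


def write_pdb_ensemble(ensemble: StructuralEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB file (CA-level or full-atom)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = ensemble.frames[0].n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n_atoms)
    ref = ensemble.frames[0]
    stack.res_id = ref.residue_ids
    stack.atom_name = ref.atom_names.astype("U6")
    stack.res_name = ref.res_names.astype("U5")
    stack.element = ref.elements.astype("U2")
    stack.chain_id = np.full(n_atoms, "A", dtype="U4")
    stack.hetero = ref.is_ligand
    for i, fr in enumerate(ensemble.frames):
        stack.coord[i] = fr.coords
    pf = pdb.PDBFile()
    pf.set_structure(stack)
    pf.write(str(path))


def read_bias_trace(path: str | Path, temperature: float = 298.0) -> BiasTrace:
    """Read a two-column (frame, kJ/mol) plain-text bias file."""
    arr = np.loadtxt(str(path))
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return BiasTrace(bias=arr[:, 1], temperature=temperature)


def write_residue_series(series: pd.Series, path: str | Path, value_name: str = "value") -> None:
    df = pd.DataFrame({"residue_id": series.index, value_name: series.values})
    df.to_csv(path, index=False)
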