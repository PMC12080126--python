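"""Docking-engine adapter with best-of-five-poses bookkeeping.

Compounds are prepared from SMILES (3D embedding, protonation, engine
format conversion) and docked per (compound, site); the lowest binding
energy among the requested poses is kept and assembled into a compounds x
sites energy matrix.  A deterministic mock engine replaces the external
physics engine everywhere a real docking run is not available, so every
downstream stage is testable and reproducible.
"""

from __future__ import annotations

import hashlib
import shutil
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ensdock.pockets import DockingBox


@dataclass
class Compound:
    compound_id: str
    smiles: str
    provenance: str | None = None


@dataclass
class PreparedLigand:
    """Engine-ready ligand record (3D-embedded, protonated)."""

    compound_id: str
    smiles: str
    n_heavy_atoms: int
    mol: object | None = None  # RDKit Mol with conformer; omitted in stub mode


@dataclass
class DockingResult:
    compound_id: str
    site_id: str
    best_energy: float  # kcal/mol
    n_poses: int

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")


class EnergyMatrix:
    """Compounds x sites best docking energies (kcal/mol); NaN marks missing."""

    def __init__(self, table: pd.DataFrame):
        if table.index.duplicated().any() or table.columns.duplicated().any():
            raise ValueError("row/column labels must be unique")
        self.table = table.astype(float)

    @property
    def compounds(self) -> list[str]:
        return list(self.table.index)

    @property
    def sites(self) -> list[str]:
        return list(self.table.columns)

    @property
    def n_missing(self) -> int:
        return int(self.table.isna().sum().sum())

    @property
    def n_stored(self) -> int:
        return self.table.size - self.n_missing

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="compound_id")

    def to_long_csv(self, path) -> None:
        long = self.table.stack().rename("energy").reset_index()
        long.columns = ["compound_id", "site_id", "energy"]
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EnergyMatrix":
        return cls(pd.read_csv(path, index_col="compound_id"))


# ---------------------------------------------------------------------------
# Ligand preparation


def prepare_ligand(compound: Compound, embed_3d: bool = True, seed: int = 2024) -> PreparedLigand:
    """Parse, protonate and 3D-embed a compound for the docking engine.

    Raises ``ValueError`` naming the compound when the SMILES does not
    parse.  With ``embed_3d=False`` a stub record (no conformer) is emitted,
    which is sufficient for the mock engine.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        raise ValueError(f"compound {compound.compound_id!r}: unparseable SMILES {compound.smiles!r}")
    n_heavy = mol.GetNumHeavyAtoms()
    if embed_3d:
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            warnings.warn(f"3D embedding failed for {compound.compound_id}; keeping 2D stub")
            mol = None
    else:
        mol = None
    return PreparedLigand(compound.compound_id, compound.smiles, n_heavy, mol)


# ---------------------------------------------------------------------------
# Engines


def _hash_unit(key: str) -> float:
    """Deterministic uniform(0,1) from a string key, platform independent."""
    digest = hashlib.sha256(key.encode()).digest()
    return (int.from_bytes(digest[:8], "big") + 0.5) / 2**64


def mock_scorer(
    compound_id: str,
    site_id: str,
    planted_binders: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
    base_mean: float = -5.0,
    base_sd: float = 1.0,
    boost: float = 3.0,
) -> float:
    """Deterministic surrogate docking energy (kcal/mol).

    The baseline energy is Gaussian noise derived from a seeded hash of
    (compound_id, site_id), so it is bit-reproducible across runs and
    platforms.  A compound listed in ``planted_binders`` (mapping
    compound_id -> iterable of boosted site ids) receives a fixed extra
    stabilization ``boost`` at those sites.
    """
    u = _hash_unit(f"{compound_id}|{site_id}|{seed}")
    energy = base_mean + base_sd * float(norm.ppf(u))
    if planted_binders and compound_id in planted_binders:
        if site_id in set(planted_binders[compound_id]):
            energy -= boost
    return energy


class MockDockingEngine:
    """Pose-level mock engine: n_poses hashed energies, best is their min."""

    def __init__(
        self,
        seed: int = 0,
        planted_binders: Mapping[str, Sequence[str]] | None = None,
        base_mean: float = -5.0,
        base_sd: float = 1.0,
        boost: float = 3.0,
    ):
        self.seed = seed
        self.planted_binders = planted_binders
        self.base_mean = base_mean
        self.base_sd = base_sd
        self.boost = boost

    def score_poses(
        self, ligand: PreparedLigand, site_id: str, box: DockingBox | None, n_poses: int
    ) -> list[float]:
        base = mock_scorer(
            ligand.compound_id,
            site_id,
            self.planted_binders,
            self.seed,
            self.base_mean,
            self.base_sd,
            self.boost,
        )
        # subsequent poses jitter upward from the best pose, deterministically
        poses = [base]
        for k in range(1, n_poses):
            poses.append(base + 2.0 * _hash_unit(f"{ligand.compound_id}|{site_id}|{self.seed}|pose{k}"))
        return poses


class VinaEngine:
    """Adapter for the external AutoDock Vina binary.

    Only the invocation contract lives here; the binary itself must be on
    PATH.  ``num_modes`` poses are requested and the pose energies parsed
    from the engine's table output.
    """

    def __init__(self, executable: str = "vina", exhaustiveness: int | None = None, seed: int | None = None):
        self.executable = executable
        self.exhaustiveness = exhaustiveness
        self.seed = seed

    def score_poses(self, ligand, site_id, box, n_poses) -> list[float]:
        if shutil.which(self.executable) is None:
            raise RuntimeError(
                f"docking engine {self.executable!r} not found on PATH; "
                "use the mock engine for engine-free runs"
            )
        raise NotImplementedError(
            "receptor/ligand PDBQT staging requires a filesystem workflow; "
            "drive Vina through the CLI `ensdock dock --engine vina`"
        )


def dock(
    ligand: PreparedLigand,
    site_id: str,
    box: DockingBox | None,
    engine,
    n_poses: int = 5,
) -> DockingResult | None:
    """Dock one prepared ligand against one site; keep the lowest energy.

    The engine is asked for ``n_poses`` poses and the minimum pose energy is
    bookkept.  Engine failures are recorded as a missing entry (``None``)
    rather than raised.
    """
    try:
        poses = engine.score_poses(ligand, site_id, box, n_poses)
    except Exception as exc:  # engine failure -> missing datum
        warnings.warn(f"docking failed for ({ligand.compound_id}, {site_id}): {exc}")
        return None
    if len(poses) == 0:
        warnings.warn(f"engine returned no poses for ({ligand.compound_id}, {site_id})")
        return None
    if len(poses) < n_poses:
        warnings.warn(
            f"engine returned {len(poses)} pose(s) for ({ligand.compound_id}, {site_id}); "
            f"{n_poses} requested"
        )
    best = float(min(poses))
    if not np.isfinite(best):
        warnings.warn(f"non-finite energy for ({ligand.compound_id}, {site_id})")
        return None
    return DockingResult(ligand.compound_id, site_id, best, len(poses))


def dock_library(
    compounds: Sequence[Compound],
    site_ids: Sequence[str],
    engine,
    boxes: Mapping[str, DockingBox] | None = None,
    n_poses: int = 5,
    embed_3d: bool = False,
) -> "EnergyMatrix":
    """Dock every compound against every site and assemble the matrix."""
    results: list[DockingResult] = []
    for comp in compounds:
        ligand = prepare_ligand(comp, embed_3d=embed_3d)
        for sid in site_ids:
            res = dock(ligand, sid, (boxes or {}).get(sid), engine, n_poses)
            if res is not None:
                results.append(res)
    return assemble_energy_matrix(results, compounds=[c.compound_id for c in compounds], sites=list(site_ids))


def assemble_energy_matrix(
    results: Iterable[DockingResult],
    compounds: Sequence[str] | None = None,
    sites: Sequence[str] | None = None,
) -> EnergyMatrix:
    """Assemble docking results into a compounds x sites matrix.

    Order-invariant; duplicate (compound, site) entries with conflicting
    energies are rejected with the offending ids.  ``compounds``/``sites``
    fix the full label universe so failed dockings appear as missing cells.
    """
    seen: dict[tuple[str, str], float] = {}
    conflicts = []
    for res in results:
        key = (res.compound_id, res.site_id)
        if key in seen and seen[key] != res.best_energy:
            conflicts.append(key)
        seen[key] = res.best_energy
    if conflicts:
        raise ValueError(f"conflicting duplicate results for {sorted(set(conflicts))}")
    comp_labels = list(compounds) if compounds is not None else sorted({k[0] for k in seen})
    site_labels = list(sites) if sites is not None else sorted({k[1] for k in seen})
    table = pd.DataFrame(np.nan, index=comp_labels, columns=site_labels)
    for (cid, sid), e in seen.items():
        table.loc[cid, sid] = e
    return EnergyMatrix(table)
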