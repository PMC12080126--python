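"""AlphaFold-derived distance restraints and the metainference score.

A structure-prediction bundle (per-residue pLDDT confidence, pairwise
predicted aligned error, pairwise predicted distances) is filtered into a
set of trustworthy inter-residue distance restraints: pairs with low PAE
that do not both sit inside high-confidence structured regions.  The
metainference restraint energy — the Gaussian negative log-likelihood of
the replica-averaged forward model against the predicted distances, with a
per-datapoint error budget — can then be evaluated on any ensemble.  The
molecular-dynamics prior energy of a full metainference simulation is out
of scope here; this module scores ensembles against the data term only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ensdock.ensemble import KB_KJ_PER_MOL_K, Conformation

SIGMA_RANGE = (0.0001, 10.0)


@dataclass
class PredictionBundle:
    """Per-residue pLDDT in [0,1]; pairwise PAE and predicted distances (A)."""

    plddt: np.ndarray
    pae: np.ndarray
    d_af: np.ndarray

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        self.d_af = np.asarray(self.d_af, dtype=float)
        n = len(self.plddt)
        if n == 0:
            raise ValueError("empty pLDDT vector")
        if self.pae.shape != (n, n) or self.d_af.shape != (n, n):
            raise ValueError("PAE and distance matrices must be n x n")
        if np.any(self.pae < 0) or np.any(self.d_af < 0):
            raise ValueError("PAE and predicted distances must be non-negative")

    @property
    def n_residues(self) -> int:
        return len(self.plddt)

    @classmethod
    def from_files(cls, plddt_path, pae_path, d_af_path) -> "PredictionBundle":
        """Load from whitespace/comma-delimited numeric text files."""
        def load(p):
            return np.loadtxt(str(p), delimiter="," if str(p).endswith(".csv") else None)

        return cls(load(plddt_path), load(pae_path), load(d_af_path))

    @classmethod
    def from_json(cls, path) -> "PredictionBundle":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.array(obj["plddt"]), np.array(obj["pae"]), np.array(obj["d_af"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "plddt": self.plddt.tolist(),
                    "pae": self.pae.tolist(),
                    "d_af": self.d_af.tolist(),
                },
                fh,
            )


@dataclass
class StructuredRegionSet:
    """Maximal contiguous residue runs whose pLDDT exceeds the threshold."""

    intervals: list[tuple[int, int]]
    threshold: float

    def contains(self, residue: int) -> bool:
        return any(a <= residue <= b for a, b in self.intervals)

    def membership(self, n_residues: int) -> np.ndarray:
        mask = np.zeros(n_residues + 1, dtype=bool)  # index by 1-based residue id
        for a, b in self.intervals:
            mask[a : b + 1] = True
        return mask


@dataclass
class RestraintSet:
    """Selected residue pairs (i < j) with target distances and PAE metadata."""

    pairs: np.ndarray  # (n, 2) int, 1-based residue ids
    targets: np.ndarray  # (n,) float, angstrom
    pae: np.ndarray  # (n,) float, angstrom

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.targets = np.asarray(self.targets, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must satisfy i < j")
        if len({tuple(p) for p in self.pairs.tolist()}) != len(self.pairs):
            raise ValueError("pairs must be unique")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "i": self.pairs[:, 0],
                "j": self.pairs[:, 1],
                "d_af": self.targets,
                "pae": self.pae,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RestraintSet":
        df = pd.read_csv(path)
        return cls(df[["i", "j"]].to_numpy(), df["d_af"].to_numpy(), df["pae"].to_numpy())

    def to_plumed(self, path, kappa: float = 1.0) -> None:
        """Write a PLUMED-style harmonic distance-restraint block (nm units)."""
        lines = []
        for k, ((i, j), d) in enumerate(zip(self.pairs, self.targets)):
            lines.append(f"d{k}: DISTANCE ATOMS={i},{j}")
            lines.append(f"r{k}: RESTRAINT ARG=d{k} AT={d / 10.0:.4f} KAPPA={kappa}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ErrorModel:
    """Per-datapoint SEM errors and per-replica random/systematic errors (A).

    ``sigma_sem`` has shape (n_restraints,); ``sigma_b`` has shape
    (n_replicas, n_restraints).  All values must lie inside the sampling
    range used by the reference simulations, [0.0001, 10] A.
    """

    sigma_sem: np.ndarray
    sigma_b: np.ndarray

    def __post_init__(self) -> None:
        self.sigma_sem = np.atleast_1d(np.asarray(self.sigma_sem, dtype=float))
        self.sigma_b = np.atleast_2d(np.asarray(self.sigma_b, dtype=float))
        lo, hi = SIGMA_RANGE
        for name, arr in (("sigma_sem", self.sigma_sem), ("sigma_b", self.sigma_b)):
            if np.any(arr < lo) or np.any(arr > hi):
                raise ValueError(f"{name} outside the sampling range {SIGMA_RANGE}")
        if self.sigma_b.shape[1] != len(self.sigma_sem):
            raise ValueError("sigma_b must have one column per datapoint")


@dataclass
class MetainferenceScore:
    """Restraint energy decomposition (kJ/mol) at temperature T (K)."""

    data_term: float
    error_term: float
    temperature: float

    @property
    def total(self) -> float:
        return self.data_term + self.error_term


# ---------------------------------------------------------------------------


def structured_regions(plddt: np.ndarray, threshold: float = 0.75) -> StructuredRegionSet:
    """Maximal contiguous runs of residues with pLDDT strictly above threshold."""
    plddt = np.asarray(plddt, dtype=float)
    if plddt.size == 0:
        raise ValueError("empty pLDDT vector")
    above = plddt > threshold
    intervals: list[tuple[int, int]] = []
    start = None
    for idx, flag in enumerate(above, start=1):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            intervals.append((start, idx - 1))
            start = None
    if start is not None:
        intervals.append((start, len(plddt)))
    return StructuredRegionSet(intervals, threshold)


def symmetrize_pae(pae: np.ndarray, mode: str = "min") -> np.ndarray:
    """PAE matrices are asymmetric; reduce to one value per unordered pair."""
    if mode == "min":
        return np.minimum(pae, pae.T)
    if mode == "mean":
        return 0.5 * (pae + pae.T)
    raise ValueError(f"unknown symmetrization mode {mode!r}")


def select_restraints(
    bundle: PredictionBundle,
    structured: StructuredRegionSet,
    pae_cutoff: float = 4.0,
    min_separation: int = 3,
    pae_mode: str = "min",
) -> RestraintSet:
    """Select trustworthy distance restraints from a prediction bundle.

    A pair (i < j) is kept when its symmetrized PAE is strictly below the
    cutoff, the residues are at least ``min_separation`` apart in sequence,
    and the two residues are not both inside a structured region (structured
    blocks are restrained by other means, and the coarse-grained prior is
    not parameterized for them).
    """
    if pae_cutoff <= 0:
        raise ValueError("pae_cutoff must be positive")
    n = bundle.n_residues
    pae = symmetrize_pae(bundle.pae, pae_mode)
    member = structured.membership(n)
    iu, ju = np.triu_indices(n, k=max(1, int(min_separation)))
    ri, rj = iu + 1, ju + 1  # 1-based residue ids
    keep = pae[iu, ju] < pae_cutoff
    keep &= ~(member[ri] & member[rj])
    return RestraintSet(
        pairs=np.column_stack([ri[keep], rj[keep]]),
        targets=bundle.d_af[iu[keep], ju[keep]],
        pae=pae[iu[keep], ju[keep]],
    )


def forward_model_distances(
    conformation: Conformation, restraints: RestraintSet
) -> np.ndarray:
    """Per-restraint C-alpha–C-alpha distances (A) in one conformation."""
    res_ids, ca = conformation.ca_coords()
    index = {int(r): k for k, r in enumerate(res_ids)}
    out = np.empty(len(restraints))
    for k, (i, j) in enumerate(restraints.pairs):
        if int(i) not in index or int(j) not in index:
            raise ValueError(f"restraint pair ({i}, {j}): residue missing from conformation")
        out[k] = np.linalg.norm(ca[index[int(i)]] - ca[index[int(j)]])
    return out


def metainference_energy(
    replica_frames: Sequence[Conformation],
    restraints: RestraintSet,
    errors: ErrorModel,
    temperature: float = 298.0,
) -> MetainferenceScore:
    """Metainference restraint energy of a set of replicas (kJ/mol).

    The likelihood of each datapoint in each replica is Gaussian about the
    predicted distance with combined variance
    sigma^2 = sigma_sem_i^2 + sigma_b_{r,i}^2, so

        data_term  = kB T * sum_{r,i} (d_i(X_r) - d_af_i)^2 / (2 sigma_{r,i}^2)
        error_term = kB T * sum_{r,i} (log sigma_{r,i} + 0.5 log 2 pi)

    The error term is the negative log of the Gaussian normalization, making
    data_term + error_term a true negative log-likelihood times kB T.  The
    molecular-dynamics prior energy is not included.
    """
    if len(replica_frames) == 0:
        raise ValueError("at least one replica required")
    if errors.sigma_b.shape[0] != len(replica_frames):
        raise ValueError("sigma_b must have one row per replica")
    kbt = KB_KJ_PER_MOL_K * temperature
    var = errors.sigma_sem[None, :] ** 2 + errors.sigma_b**2
    dev = np.stack(
        [forward_model_distances(fr, restraints) - restraints.targets for fr in replica_frames]
    )
    data_term = kbt * float((dev**2 / (2.0 * var)).sum())
    error_term = kbt * float((0.5 * np.log(2.0 * np.pi * var)).sum())
    return MetainferenceScore(data_term=data_term, error_term=error_term, temperature=temperature)
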