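"""Transient binding-site selection from detected cavities.

Cavity records from a grid-based geometric detector are filtered down to
candidate binding sites with conjunctive physicochemical and dynamics
criteria (residue count, hydropathy, surface area, volume, and mean RMSF of
the lining residues — low RMSF marks the sticky, interaction-prone pockets
this pipeline targets), then clustered across the ensemble by residue
sharing, and finally turned into axis-aligned docking boxes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ensdock.ensemble import Conformation

#: Eisenberg–Weiss normalized consensus hydrophobicity scale.
EISENBERG_WEISS = {
    "ALA": 0.62, "ARG": -2.53, "ASN": -0.78, "ASP": -0.90, "CYS": 0.29,
    "GLN": -0.85, "GLU": -0.74, "GLY": 0.48, "HIS": -0.40, "ILE": 1.38,
    "LEU": 1.06, "LYS": -1.50, "MET": 0.64, "PHE": 1.19, "PRO": 0.12,
    "SER": -0.18, "THR": -0.05, "TRP": 0.81, "TYR": 0.26, "VAL": 1.08,
}


@dataclass
class Cavity:
    """One detected cavity on one ensemble frame."""

    frame_id: int
    residues: frozenset[int]
    volume: float  # A^3
    area: float  # A^2
    max_depth: float = 0.0  # A
    avg_depth: float = 0.0  # A
    avg_hydropathy: float = 0.0  # Eisenberg-Weiss units
    cavity_id: str | None = None

    def __post_init__(self) -> None:
        self.residues = frozenset(int(r) for r in self.residues)
        if not self.residues:
            raise ValueError("cavity residue set is empty")
        for name in ("volume", "area", "max_depth", "avg_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FilterConfig:
    """Conjunctive binding-site selection thresholds.

    Defaults: a site must have strictly more
    than ``min_residues`` lining residues, mean hydropathy at most
    ``max_hydropathy`` (hydrophobic), area within ``area_bounds``, volume at
    least ``min_volume``, and mean lining-residue RMSF strictly below
    ``max_mean_rmsf`` (in nm; see the methods note on the threshold's unit).
    """

    min_residues: int = 5  # strict >
    max_hydropathy: float = 0.0
    area_bounds: tuple[float, float] = (80.0, 2480.0)  # A^2
    min_volume: float = 120.0  # A^3
    max_mean_rmsf: float = 4.1  # nm, strict <
    rmsf_reduction: str = "mean"  # or "max"

    def __post_init__(self) -> None:
        lo, hi = self.area_bounds
        if lo > hi:
            raise ValueError("area bounds must be ordered")
        for v in (self.max_hydropathy, lo, hi, self.min_volume, self.max_mean_rmsf):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")
        if self.rmsf_reduction not in ("mean", "max"):
            raise ValueError("rmsf_reduction must be 'mean' or 'max'")


@dataclass
class DockingBox:
    center: tuple[float, float, float]  # A
    size: tuple[float, float, float]  # A edge lengths


@dataclass
class BindingSite:
    """Filtered cavity promoted to a docking target."""

    site_id: str
    cavity: Cavity
    box: DockingBox | None = None

    @property
    def residues(self) -> frozenset[int]:
        return self.cavity.residues


@dataclass
class SiteClusterSet:
    """Partition of site ids into residue-sharing clusters."""

    clusters: list[list[str]]
    overlap_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def multi_member(self) -> list[list[str]]:
        return [c for c in self.clusters if len(c) > 1]

    def singletons(self) -> list[list[str]]:
        return [c for c in self.clusters if len(c) == 1]


# ---------------------------------------------------------------------------


def eisenberg_weiss_hydropathy(residue_names: Sequence[str]) -> float:
    """Arithmetic-mean Eisenberg–Weiss hydropathy of a residue list."""
    if len(residue_names) == 0:
        raise ValueError("empty residue list")
    vals = []
    for name in residue_names:
        key = str(name).upper()
        if key not in EISENBERG_WEISS:
            raise ValueError(f"unknown residue name {name!r}")
        vals.append(EISENBERG_WEISS[key])
    return float(np.mean(vals))


def detect_cavities(
    conformation: Conformation | None,
    backend: str = "fixture",
    fixture_cavities: Sequence[Cavity] | None = None,
    detector_config: Mapping | None = None,
) -> list[Cavity]:
    """Cavity-detector adapter.

    ``backend="fixture"`` returns the injected cavity records unchanged
    (empty list when none are given), which is how tests and the synthetic
    pipeline run.  ``backend="pykvfinder"`` shells into the grid-based
    detector at its default parameters when that package is importable.
    """
    if backend == "fixture":
        return list(fixture_cavities or [])
    if backend == "pykvfinder":
        try:
            import pyKVFinder  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "the pyKVFinder backend is not installed; rerun with "
                "backend='fixture' and supply fixture_cavities"
            ) from exc
        raise NotImplementedError(
            "pyKVFinder adapter requires a PDB path workflow; use "
            "ensdock.pipeline with detector settings"
        )
    raise ValueError(f"unknown cavity backend {backend!r}")


def filter_cavities(
    cavities: Iterable[Cavity],
    rmsf: pd.Series | Mapping[int, float],
    config: FilterConfig | None = None,
) -> list[BindingSite]:
    """Apply the conjunctive binding-site filters to detected cavities.

    ``rmsf`` maps residue id to RMSF (nm) and must cover every cavity
    residue.  Site ids are assigned deterministically as
    ``site-<frame>-<index>`` in (frame_id, detection order).
    """
    config = config or FilterConfig()
    rmsf = pd.Series(dict(rmsf)) if not isinstance(rmsf, pd.Series) else rmsf
    sites: list[BindingSite] = []
    ordered = sorted(
        enumerate(cavities), key=lambda kv: (kv[1].frame_id, kv[0])
    )
    counters: dict[int, int] = {}
    for _, cav in ordered:
        missing = sorted(set(cav.residues) - set(int(i) for i in rmsf.index))
        if missing:
            raise ValueError(f"RMSF missing for cavity residues {missing}")
        idx = counters.get(cav.frame_id, 0)
        counters[cav.frame_id] = idx + 1
        res_rmsf = rmsf.loc[sorted(cav.residues)]
        rmsf_stat = res_rmsf.max() if config.rmsf_reduction == "max" else res_rmsf.mean()
        lo, hi = config.area_bounds
        passes = (
            len(cav.residues) > config.min_residues
            and cav.avg_hydropathy <= config.max_hydropathy
            and lo <= cav.area <= hi
            and cav.volume >= config.min_volume
            and rmsf_stat < config.max_mean_rmsf
        )
        if passes:
            site_id = cav.cavity_id or f"site-{cav.frame_id}-{idx}"
            sites.append(BindingSite(site_id=site_id, cavity=cav))
    return sites


def overlap_coefficient(a: frozenset[int], b: frozenset[int]) -> float:
    return len(a & b) / min(len(a), len(b))


def jaccard(a: frozenset[int], b: frozenset[int]) -> float:
    return len(a & b) / len(a | b)


def cluster_sites(
    sites: Sequence[BindingSite],
    overlap_threshold: float = 0.6,
    metric: str = "overlap",
) -> SiteClusterSet:
    """Group sites that share more than a threshold fraction of residues.

    Two sites are linked when their residue-sharing score is strictly above
    the threshold; clusters are the connected components of that graph
    (single linkage).  ``metric`` is ``"overlap"`` (|A∩B| / min(|A|,|B|),
    the default — tolerant of nested pockets of unequal size) or
    ``"jaccard"``.
    """
    if not sites:
        raise ValueError("at least one site required")
    if not (0.0 < overlap_threshold <= 1.0):
        raise ValueError("overlap_threshold must be in (0, 1]")
    score = overlap_coefficient if metric == "overlap" else jaccard
    if metric not in ("overlap", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    n = len(sites)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if score(sites[i].residues, sites[j].residues) > overlap_threshold:
                rows.append(i)
                cols.append(j)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for idx, lab in enumerate(labels):
        clusters[lab].append(sites[idx].site_id)
    # deterministic ordering: by first member's input position
    first_pos = {tuple(c): min(i for i, s in enumerate(sites) if s.site_id in c) for c in clusters}
    clusters.sort(key=lambda c: first_pos[tuple(c)])
    return SiteClusterSet(clusters=clusters, overlap_threshold=overlap_threshold)


def site_to_box(
    site: BindingSite, conformation: Conformation, padding: float = 5.0
) -> DockingBox:
    """Axis-aligned docking box over the cavity residues' C-alpha atoms.

    The bounding box of the lining residues is expanded by ``padding``
    angstrom on each side.  A box with any zero edge (padding 0 and
    degenerate geometry) is returned with a warning.
    """
    res_ids, ca = conformation.ca_coords()
    mask = np.isin(res_ids, sorted(site.residues))
    if not mask.any():
        raise ValueError(f"no cavity residues of {site.site_id} in conformation")
    xyz = ca[mask]
    lo = xyz.min(axis=0) - padding
    hi = xyz.max(axis=0) + padding
    size = hi - lo
    if np.any(size <= 0):
        warnings.warn(f"degenerate docking box for {site.site_id} (zero edge)")
    center = 0.5 * (hi + lo)
    return DockingBox(center=tuple(float(x) for x in center), size=tuple(float(x) for x in size))


# ---------------------------------------------------------------------------
# I/O


def cavities_from_csv(path) -> list[Cavity]:
    """Read cavity records from CSV (residues as ;-joined ids)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            Cavity(
                frame_id=int(row["frame_id"]),
                residues=frozenset(int(x) for x in str(row["residues"]).split(";")),
                volume=float(row["volume"]),
                area=float(row["area"]),
                max_depth=float(row.get("max_depth", 0.0)),
                avg_depth=float(row.get("avg_depth", 0.0)),
                avg_hydropathy=float(row["avg_hydropathy"]),
                cavity_id=str(row["cavity_id"]) if "cavity_id" in row else None,
            )
        )
    return out


def cavities_to_csv(cavities: Sequence[Cavity], path) -> None:
    rows = []
    for cav in cavities:
        rows.append(
            {
                "frame_id": cav.frame_id,
                "residues": ";".join(str(r) for r in sorted(cav.residues)),
                "volume": cav.volume,
                "area": cav.area,
                "max_depth": cav.max_depth,
                "avg_depth": cav.avg_depth,
                "avg_hydropathy": cav.avg_hydropathy,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def sites_to_csv(sites: Sequence[BindingSite], path) -> None:
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id,
            "frame_id": s.cavity.frame_id,
            "residues": ";".join(str(r) for r in sorted(s.residues)),
        }
        if s.box is not None:
            row.update(
                center_x=s.box.center[0], center_y=s.box.center[1], center_z=s.box.center[2],
                size_x=s.box.size[0], size_y=s.box.size[1], size_z=s.box.size[2],
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def box_to_engine_config(site: BindingSite) -> str:
    """Per-site docking-engine config text block (center_x .. size_z)."""
    if site.box is None:
        raise ValueError(f"site {site.site_id} has no docking box")
    c, s = site.box.center, site.box.size
    return (
        f"center_x = {c[0]:.3f}\ncenter_y = {c[1]:.3f}\ncenter_z = {c[2]:.3f}\n"
        f"size_x = {s[0]:.3f}\nsize_y = {s[1]:.3f}\nsize_z = {s[2]:.3f}\n"
    )
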