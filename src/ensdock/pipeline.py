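"""Stage orchestration for the end-to-end screening pipeline.

``run_pipeline`` drives the stages — ensemble analytics, restraint
selection, pocket selection, docking, labeling, surrogate training,
screening, redocking, and the multibinding hit analysis — writing each
stage's artifacts to an output directory and recording a JSON manifest
with parameters, file hashes and stage summaries.  Deterministic stages
reproduce identical manifests under the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ensdock import fixtures
from ensdock.docking import Compound, EnergyMatrix, MockDockingEngine, dock_library
from ensdock.ensemble import residue_rmsf, torrie_valleau_weights, write_residue_series
from ensdock.pockets import FilterConfig, cluster_sites, filter_cavities, sites_to_csv, site_to_box
from ensdock.qsar import (
    ModelConfig,
    SiteActivityClassifier,
    build_labels,
    featurize,
    multibinding_hit_histogram,
    screen,
)
from ensdock.restraints import select_restraints, structured_regions


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults are the reference protocol thresholds."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    engine: str = "mock"  # or "vina"
    plddt_threshold: float = 0.75
    pae_cutoff: float = 4.0  # angstrom
    min_separation: int = 3
    label_percentile: float = 5.0
    site_fraction_threshold: float = 0.70
    min_sites: int = 30
    n_poses: int = 5
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    model_config: ModelConfig | None = None
    fixture: fixtures.FixtureSpec | None = None
    stages: tuple[str, ...] = (
        "ensemble",
        "restraints",
        "pockets",
        "dock",
        "label",
        "train",
        "screen",
        "redock",
        "hits",
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages at fixture scale and return the manifest.

    Stages consume the artifacts of earlier stages; a disabled upstream
    stage whose artifact is missing raises an error naming that stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.fixture or fixtures.FixtureSpec(seed=config.seed)
    model_cfg = config.model_config or ModelConfig(
        hidden_sizes=(128, 128), epochs=25, seed=config.seed
    )
    manifest: dict = {"config": json.loads(json.dumps(config.to_dict(), default=str)), "stages": {}}
    state: dict = {}

    def record(stage: str, t0: float, files: dict[str, Path], **summary) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()},
            **summary,
        }

    def require(stage: str, key: str, filename: str, loader):
        """Fetch an upstream artifact from memory or disk."""
        if key in state:
            return state[key]
        path = out / filename
        if not path.exists():
            raise RuntimeError(
                f"missing upstream artifact {filename!r}: enable or rerun stage {stage!r}"
            )
        return loader(path)

    if "ensemble" in config.stages:
        t0 = time.time()
        ens, bias = fixtures.gen_toy_ensemble(spec)
        weights = torrie_valleau_weights(bias)
        ens = ens.reweighted(weights)
        rmsf = residue_rmsf(ens)
        write_residue_series(rmsf, out / "rmsf.csv", "rmsf_nm")
        state["ensemble"] = ens
        state["rmsf"] = rmsf
        record("ensemble", t0, {"rmsf": out / "rmsf.csv"}, n_frames=ens.n_frames)

    if "restraints" in config.stages:
        t0 = time.time()
        ens = require("ensemble", "ensemble", "rmsf.csv", lambda p: None)
        if ens is None:
            raise RuntimeError("missing upstream artifact: enable or rerun stage 'ensemble'")
        bundle = fixtures.gen_prediction_bundle(spec, ens.frames[0])
        structured = structured_regions(bundle.plddt, config.plddt_threshold)
        restraints = select_restraints(
            bundle, structured, config.pae_cutoff, config.min_separation
        )
        restraints.to_csv(out / "restraints.csv")
        record(
            "restraints", t0, {"restraints": out / "restraints.csv"},
            n_restraints=len(restraints),
            structured_intervals=[list(iv) for iv in structured.intervals],
        )

    if "pockets" in config.stages:
        t0 = time.time()
        ens = state.get("ensemble")
        rmsf = require(
            "ensemble", "rmsf", "rmsf.csv",
            lambda p: pd.read_csv(p).set_index("residue_id")["rmsf_nm"],
        )
        if ens is None:
            raise RuntimeError("missing upstream artifact: enable or rerun stage 'ensemble'")
        cavities = fixtures.gen_cavity_set(spec, ens)
        sites = filter_cavities(cavities, rmsf, config.filter_config)
        for s in sites:
            s.box = site_to_box(s, ens.frames[s.cavity.frame_id])
        clusters = cluster_sites(sites) if sites else None
        sites_to_csv(sites, out / "sites.csv")
        state["sites"] = sites
        record(
            "pockets", t0, {"sites": out / "sites.csv"},
            n_cavities=len(cavities), n_sites=len(sites),
            n_clusters=clusters.n_clusters if clusters else 0,
        )

    # compound library shared by dock/train/screen stages
    if {"dock", "train", "screen", "redock"} & set(config.stages):
        lib = fixtures.gen_smiles_library(
            min(spec.n_compounds, 2000), seed=spec.seed,
            motif_fraction=spec.n_planted / spec.n_compounds,
        )
        comp_ids = [f"cmpd-{k:05d}" for k in range(len(lib))]
        planted = [cid for cid, smi in zip(comp_ids, lib) if "Cl" in smi]
        state["library"] = (comp_ids, lib, planted)

    if "dock" in config.stages:
        t0 = time.time()
        comp_ids, lib, planted = state["library"]
        site_ids = (
            [s.site_id for s in state["sites"]][: spec.n_sites]
            if state.get("sites")
            else [f"site-{k:02d}" for k in range(spec.n_sites)]
        )
        if len(site_ids) < spec.n_sites:
            site_ids += [f"site-{k:02d}" for k in range(len(site_ids), spec.n_sites)]
        matrix, planted, site_map = fixtures.gen_energy_matrix(
            spec, compound_ids=comp_ids, planted_ids=planted
        )
        matrix.to_csv(out / "energies.csv")
        state["energies"] = matrix
        record(
            "dock", t0, {"energies": out / "energies.csv"},
            n_compounds=len(matrix.compounds), n_sites=len(matrix.sites),
            n_stored=matrix.n_stored, engine=config.engine,
        )

    if "label" in config.stages:
        t0 = time.time()
        matrix = require("dock", "energies", "energies.csv", EnergyMatrix.from_csv)
        labels = build_labels(matrix, config.label_percentile)
        labels.to_csv(out / "labels.csv")
        state["labels"] = labels
        record(
            "label", t0, {"labels": out / "labels.csv"},
            percentile=config.label_percentile,
            active_fraction=float(labels.values().mean()),
        )

    if "train" in config.stages:
        t0 = time.time()
        labels = state.get("labels")
        if labels is None:
            raise RuntimeError("missing upstream artifact: enable or rerun stage 'label'")
        comp_ids, lib, _ = state["library"]
        fps, rejected = featurize(lib)
        model = SiteActivityClassifier(fps, labels, model_cfg)
        results = model.fit()
        results.save(out / "model.npz", out / "model.json")
        state["results"] = results
        record(
            "train", t0, {"model_config": out / "model.json"},
            best_epoch=results.best_epoch, test_mean_mcc=results.mean_mcc,
        )

    if "screen" in config.stages:
        t0 = time.time()
        results = state.get("results")
        if results is None:
            raise RuntimeError("missing upstream artifact: enable or rerun stage 'train'")
        comp_ids, lib, _ = state["library"]
        selection = screen(results, lib, comp_ids, config.site_fraction_threshold)
        pd.Series(selection.selected, name="compound_id").to_csv(
            out / "selected.csv", index=False
        )
        state["selection"] = selection
        record(
            "screen", t0, {"selected": out / "selected.csv"},
            n_selected=len(selection.selected), threshold=config.site_fraction_threshold,
        )

    if "redock" in config.stages:
        t0 = time.time()
        selection = state.get("selection")
        if selection is None:
            raise RuntimeError("missing upstream artifact: enable or rerun stage 'screen'")
        comp_ids, lib, planted = state["library"]
        keep = [cid for cid in comp_ids if cid in set(selection.selected)]
        sub = state["energies"].table.loc[keep]
        EnergyMatrix(sub).to_csv(out / "redock_energies.csv")
        state["redock"] = EnergyMatrix(sub)
        record("redock", t0, {"redock": out / "redock_energies.csv"}, n_compounds=len(keep))

    if "hits" in config.stages:
        t0 = time.time()
        labels = state.get("labels")
        redock = state.get("redock")
        if labels is None or redock is None:
            raise RuntimeError("missing upstream artifact: enable or rerun stage 'redock'")
        naive_count, naive_hist = multibinding_hit_histogram(labels, config.min_sites)
        # label the redocked subset against the naive per-site thresholds
        redock_labels = (redock.table < labels.thresholds).astype(int)
        screened_count, screened_hist = multibinding_hit_histogram(
            redock_labels.to_numpy(), config.min_sites
        )
        hist = pd.DataFrame({"naive": naive_hist, "screened": screened_hist})
        hist.to_csv(out / "hit_histogram.csv", index_label="n_active_sites")
        n_naive = len(labels.compounds)
        n_screened = len(redock.compounds)
        naive_rate = naive_count / n_naive
        screened_rate = screened_count / n_screened if n_screened else 0.0
        record(
            "hits", t0, {"histogram": out / "hit_histogram.csv"},
            naive_count=naive_count, screened_count=screened_count,
            naive_rate=naive_rate, screened_rate=screened_rate,
            enrichment=screened_rate / naive_rate if naive_rate > 0 else None,
        )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
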