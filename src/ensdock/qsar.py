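"""Multilabel QSAR surrogate: labels, fingerprints, training, screening.

Docking energies are binarized per site with a top-percentile rule (the
lowest-energy tail defines the active class), compounds are embedded as
hashed topological path fingerprints, and a feed-forward multilabel
classifier is trained to predict per-site activity.  The trained surrogate
screens large SMILES libraries orders of magnitude faster than docking; a
compound is selected when it is predicted active at more than a stated
fraction of the binding sites, which enriches for multi-site binders.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ensdock._mlp import MLP
from ensdock.docking import EnergyMatrix

N_FINGERPRINT_BITS = 1412


# ---------------------------------------------------------------------------
# Labels


@dataclass
class LabelMatrix:
    """Binary compounds x sites activity matrix with per-site thresholds."""

    table: pd.DataFrame  # entries in {0, 1}, NaN where energy was missing
    thresholds: pd.Series  # kcal/mol, per site
    percentile: float

    @property
    def sites(self) -> list[str]:
        return list(self.table.columns)

    @property
    def compounds(self) -> list[str]:
        return list(self.table.index)

    def values(self) -> np.ndarray:
        """Dense {0,1} matrix with missing entries counted inactive."""
        return self.table.fillna(0).to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="compound_id")


def build_labels(
    energies: EnergyMatrix,
    percentile: float = 5.0,
    min_site_count: int = 20,
) -> LabelMatrix:
    """Binarize docking energies per site with a top-percentile rule.

    For each site the threshold is the order statistic at index
    ceil(n * percentile / 100) (0-based) of the site's non-missing energies
    sorted ascending, and a compound is active iff its energy is strictly
    below that threshold.  On tie-free energies with n divisible by
    100/percentile this labels exactly n * percentile / 100 compounds
    active per site; ties at the threshold are inactive.  Missing energies
    are excluded from the threshold and stay missing in the label table.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must be in (0, 100)")
    table = energies.table
    labels = pd.DataFrame(np.nan, index=table.index, columns=table.columns)
    thresholds = {}
    for site in table.columns:
        col = table[site].dropna()
        if len(col) == 0:
            raise ValueError(f"site {site!r} has no non-missing energies")
        if len(col) < min_site_count:
            raise ValueError(
                f"site {site!r} has only {len(col)} energies (< {min_site_count})"
            )
        k = int(np.ceil(len(col) * percentile / 100.0))
        srt = np.sort(col.to_numpy())
        thr = srt[k] if k < len(srt) else np.inf
        thresholds[site] = thr
        labels.loc[col.index, site] = (col < thr).astype(float)
    return LabelMatrix(
        table=labels, thresholds=pd.Series(thresholds), percentile=percentile
    )


def oversample_actives(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    target_active_fraction: float = 0.25,
    max_factor: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate active compounds until labels are less imbalanced.

    Rows with at least one active label are resampled with replacement and
    appended until the mean per-site active fraction of the pool reaches
    ``target_active_fraction`` (or the pool has grown by ``max_factor``
    times the active count).  Originals are always retained; deterministic
    under the seed.
    """
    features = np.asarray(features)
    labels = np.asarray(labels, dtype=float)
    active_rows = np.where(labels.sum(axis=1) > 0)[0]
    if len(active_rows) == 0:
        warnings.warn("no active compounds; oversampling is a no-op")
        return features, labels
    n0, n_sites = labels.shape
    total_active = labels.sum()
    mean_active_per_dup = labels[active_rows].sum(axis=1).mean()
    frac = total_active / (n0 * n_sites)
    if frac >= target_active_fraction:
        return features, labels
    # solve (A0 + d*a) / ((n0 + d) * S) >= t for the duplicate count d
    t, s, a = target_active_fraction, n_sites, mean_active_per_dup
    denom = a - t * s
    if denom <= 0:
        n_dup = max_factor * len(active_rows)
        warnings.warn("target active fraction unreachable by duplication; capped")
    else:
        n_dup = int(np.ceil((t * n0 * s - total_active) / denom))
        n_dup = min(n_dup, max_factor * len(active_rows))
    rng = np.random.default_rng(seed)
    picks = rng.choice(active_rows, size=n_dup, replace=True)
    return np.vstack([features, features[picks]]), np.vstack([labels, labels[picks]])


# ---------------------------------------------------------------------------
# Fingerprints


def featurize(
    smiles_list: Sequence[str], n_bits: int = N_FINGERPRINT_BITS
) -> tuple[np.ndarray, list[int]]:
    """Hashed topological path fingerprints folded to ``n_bits``.

    Linear paths of 1–7 bonds are enumerated and hashed (the classic
    Daylight-style topological fingerprint).  Returns the bit matrix for
    the valid molecules plus the indices of rejected SMILES; identical
    molecules (canonical-equal SMILES) map to identical rows.
    """
    from rdkit import Chem
    from rdkit.Chem import rdmolops

    rows = []
    rejected: list[int] = []
    for idx, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            rejected.append(idx)
            continue
        fp = rdmolops.RDKFingerprint(mol, minPath=1, maxPath=7, fpSize=n_bits)
        arr = np.zeros(n_bits, dtype=np.uint8)
        for bit in fp.GetOnBits():
            arr[bit] = 1
        rows.append(arr)
    matrix = np.vstack(rows) if rows else np.zeros((0, n_bits), dtype=np.uint8)
    return matrix, rejected


# ---------------------------------------------------------------------------
# Metrics


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Defined as 0 when any factor of the denominator vanishes (the
    conventional continuity choice).
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise ValueError("all counts are zero")
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


def zero_one_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Subset zero-one loss: a sample counts 1 unless every label matches."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    return float((y_true != y_pred).any(axis=-1).mean())


def hamming_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Fraction of individual labels predicted incorrectly."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    return float((y_true != y_pred).mean())


def bce_loss(y_true: np.ndarray, p_pred: np.ndarray, clip: float = 1e-7) -> float:
    """Mean binary cross-entropy with probability clipping."""
    y = np.asarray(y_true, dtype=float)
    p = np.clip(np.asarray(p_pred, dtype=float), clip, 1.0 - clip)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    """Per-site TP/TN/FP/FN for binary matrices of shape (n, n_sites)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = ((y_true == 1) & (y_pred == 1)).sum(axis=0)
    tn = ((y_true == 0) & (y_pred == 0)).sum(axis=0)
    fp = ((y_true == 0) & (y_pred == 1)).sum(axis=0)
    fn = ((y_true == 1) & (y_pred == 0)).sum(axis=0)
    return pd.DataFrame({"tp": tp, "tn": tn, "fp": fp, "fn": fn})


def mean_site_mcc(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-site MCC; one-class sites are undefined and excluded."""
    counts = confusion_counts(y_true, y_pred)
    vals = []
    for _, row in counts.iterrows():
        if row.tp + row.fn == 0 or row.tn + row.fp == 0:
            vals.append(np.nan)  # site has one class only in the truth
        else:
            vals.append(mcc(row.tp, row.tn, row.fp, row.fn))
    vals = np.array(vals)
    valid = vals[~np.isnan(vals)]
    mean = float(valid.mean()) if len(valid) else float("nan")
    return mean, vals


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class ModelConfig:
    """Feed-forward multilabel classifier settings.

    The reference architecture is four ReLU hidden layers of 1256 units
    with dropout on the first and last hidden layers, a per-site logistic
    output, BCE loss, and Adam.  Training tracks validation mean MCC every
    epoch and checkpoints the best epoch.
    """

    hidden_sizes: tuple[int, ...] = (1256, 1256, 1256, 1256)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 128
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1)  # train/val/test
    oversample_target: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


class SiteActivityResults:
    """Fitted-surrogate results: checkpoint, history, held-out metrics."""

    def __init__(
        self,
        model: "SiteActivityClassifier",
        history: pd.DataFrame,
        best_epoch: int,
        test_metrics: dict,
        per_site: pd.DataFrame,
    ):
        self.model = model
        self.history = history
        self.best_epoch = best_epoch
        self.test_metrics = test_metrics
        self.per_site = per_site

    @property
    def mean_mcc(self) -> float:
        return self.test_metrics["mean_mcc"]

    def predict_proba(self, fingerprints: np.ndarray) -> np.ndarray:
        return self.model._net.predict_proba(np.asarray(fingerprints, dtype=float))

    def predict(self, fingerprints: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
        return (self.predict_proba(fingerprints) >= cutoff).astype(int)

    def summary(self) -> str:
        m = self.test_metrics
        lines = [
            "Multilabel site-activity classifier",
            "=" * 51,
            f"sites: {len(self.per_site)}   best epoch: {self.best_epoch}",
            f"test mean MCC:      {m['mean_mcc']:.4f}",
            f"test Hamming loss:  {m['hamming_loss']:.4f}",
            f"test zero-one loss: {m['zero_one_loss']:.4f}",
            f"test BCE:           {m['bce']:.4f}",
            "-" * 51,
            f"{'site':<16}{'tp':>6}{'tn':>8}{'fp':>6}{'fn':>6}{'mcc':>8}",
        ]
        for site, row in self.per_site.iterrows():
            mcc_txt = "  undef" if np.isnan(row["mcc"]) else f"{row['mcc']:8.3f}"
            lines.append(
                f"{str(site):<16}{int(row.tp):>6}{int(row.tn):>8}{int(row.fp):>6}"
                f"{int(row.fn):>6}{mcc_txt}"
            )
        return "\n".join(lines)

    def save(self, weights_path, config_path) -> None:
        params = self.model._net.get_params()
        np.savez(
            weights_path,
            **{f"W{i}": w for i, w in enumerate(params["W"])},
            **{f"b{i}": b for i, b in enumerate(params["b"])},
        )
        with open(config_path, "w") as fh:
            json.dump(
                {
                    "config": asdict(self.model.config),
                    "sites": self.model.site_ids,
                    "n_bits": self.model.fingerprints.shape[1],
                    "best_epoch": self.best_epoch,
                    "test_metrics": self.test_metrics,
                },
                fh,
                indent=2,
            )


class SiteActivityClassifier:
    """Multilabel surrogate for per-site docking activity.

    Built from a fingerprint matrix and a :class:`LabelMatrix` (or a raw
    binary array); ``fit()`` splits the compounds, oversamples actives in
    the training pool, trains the network, and returns a
    :class:`SiteActivityResults` carrying the best-validation-MCC
    checkpoint and held-out test metrics.
    """

    def __init__(
        self,
        fingerprints: np.ndarray,
        labels: LabelMatrix | np.ndarray,
        config: ModelConfig | None = None,
        site_ids: Sequence[str] | None = None,
    ):
        self.fingerprints = np.asarray(fingerprints, dtype=float)
        if isinstance(labels, LabelMatrix):
            self.labels = labels.values()
            self.site_ids = list(labels.sites)
        else:
            self.labels = np.asarray(labels, dtype=int)
            self.site_ids = list(site_ids) if site_ids is not None else [
                f"site-{k}" for k in range(self.labels.shape[1])
            ]
        if len(self.fingerprints) != len(self.labels):
            raise ValueError("fingerprints and labels must have equal row counts")
        self.config = config or ModelConfig()
        if len(self.site_ids) != self.labels.shape[1]:
            raise ValueError("site id count must equal label width")
        self._net: MLP | None = None

    @classmethod
    def from_smiles(
        cls,
        smiles: Sequence[str],
        labels: LabelMatrix | np.ndarray,
        config: ModelConfig | None = None,
        n_bits: int = N_FINGERPRINT_BITS,
    ) -> "SiteActivityClassifier":
        fps, rejected = featurize(smiles, n_bits)
        if rejected:
            raise ValueError(f"invalid SMILES at indices {rejected[:10]}")
        return cls(fps, labels, config)

    def fit(self) -> SiteActivityResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n = len(self.fingerprints)
        order = rng.permutation(n)
        n_train = int(round(cfg.splits[0] * n))
        n_val = int(round(cfg.splits[1] * n))
        idx_train = order[:n_train]
        idx_val = order[n_train : n_train + n_val]
        idx_test = order[n_train + n_val :]
        x_train, y_train = self.fingerprints[idx_train], self.labels[idx_train].astype(float)
        x_train, y_train = oversample_actives(
            x_train, y_train, seed=cfg.seed, target_active_fraction=cfg.oversample_target
        )
        x_val, y_val = self.fingerprints[idx_val], self.labels[idx_val]
        x_test, y_test = self.fingerprints[idx_test], self.labels[idx_test]

        net = MLP(
            n_in=self.fingerprints.shape[1],
            hidden=cfg.hidden_sizes,
            n_out=self.labels.shape[1],
            dropout=cfg.dropout,
            seed=cfg.seed,
        )
        best = {"epoch": -1, "mcc": -np.inf, "params": net.get_params()}
        rows = []
        for epoch in range(cfg.epochs):
            perm = rng.permutation(len(x_train))
            losses = []
            for i in range(0, len(perm), cfg.batch_size):
                sel = perm[i : i + cfg.batch_size]
                losses.append(net.train_batch(x_train[sel], y_train[sel], cfg.learning_rate))
            p_val = net.predict_proba(x_val)
            val_mcc, _ = mean_site_mcc(y_val, (p_val >= 0.5).astype(int))
            rows.append({"epoch": epoch, "train_bce": float(np.mean(losses)), "val_mean_mcc": val_mcc})
            if np.isfinite(val_mcc) and val_mcc > best["mcc"]:
                best = {"epoch": epoch, "mcc": val_mcc, "params": net.get_params()}
        net.set_params(best["params"])
        self._net = net

        p_test = net.predict_proba(x_test)
        y_hat = (p_test >= 0.5).astype(int)
        test_mean_mcc, site_mcc = mean_site_mcc(y_test, y_hat)
        per_site = confusion_counts(y_test, y_hat)
        per_site.index = self.site_ids
        per_site["mcc"] = site_mcc
        metrics = {
            "mean_mcc": test_mean_mcc,
            "hamming_loss": hamming_loss(y_test, y_hat),
            "zero_one_loss": zero_one_loss(y_test, y_hat),
            "bce": bce_loss(y_test, p_test),
        }
        return SiteActivityResults(
            model=self,
            history=pd.DataFrame(rows),
            best_epoch=best["epoch"],
            test_metrics=metrics,
            per_site=per_site,
        )


# ---------------------------------------------------------------------------
# Screening


@dataclass
class ScreeningSelection:
    """Compounds predicted active at more than a fraction of all sites."""

    selected: list[str]
    fractions: pd.Series  # per-compound active-site fraction
    threshold: float
    rejected_smiles: list[int] = field(default_factory=list)


def screen(
    results: SiteActivityResults,
    smiles_library: Sequence[str],
    compound_ids: Sequence[str] | None = None,
    site_fraction_threshold: float = 0.70,
    batch_size: int = 4096,
    cutoff: float = 0.5,
) -> ScreeningSelection:
    """Screen a SMILES library with the trained surrogate.

    Each compound's predicted labels are binarized at ``cutoff`` and the
    compound is selected when its active-site fraction is strictly greater
    than ``site_fraction_threshold`` (for 41 sites at 0.70 that requires at
    least 29 active sites).  Invalid SMILES are reported, not fatal.
    """
    n_bits = results.model.fingerprints.shape[1]
    fps, rejected = featurize(smiles_library, n_bits)
    if len(fps) == 0:
        raise ValueError("no valid SMILES in the library")
    ids = list(compound_ids) if compound_ids is not None else [
        f"lib-{k}" for k in range(len(smiles_library))
    ]
    kept_ids = [i for k, i in enumerate(ids) if k not in set(rejected)]
    n_sites = len(results.model.site_ids)
    fracs = np.empty(len(fps))
    for i in range(0, len(fps), batch_size):
        p = results.predict_proba(fps[i : i + batch_size])
        fracs[i : i + batch_size] = (p >= cutoff).sum(axis=1) / n_sites
    series = pd.Series(fracs, index=kept_ids, name="active_site_fraction")
    selected = [cid for cid, f in series.items() if f > site_fraction_threshold]
    return ScreeningSelection(
        selected=selected,
        fractions=series,
        threshold=site_fraction_threshold,
        rejected_smiles=rejected,
    )


def multibinding_hit_histogram(
    labels: LabelMatrix | np.ndarray, min_sites: int = 30
) -> tuple[int, pd.Series]:
    """Count compounds active at strictly more than ``min_sites`` sites.

    Returns (count, histogram) where the histogram indexes the number of
    active sites from 1 to n_sites and sums to the number of compounds with
    at least one active site.
    """
    mat = labels.values() if isinstance(labels, LabelMatrix) else np.asarray(labels, dtype=int)
    row_sums = mat.sum(axis=1)
    n_sites = mat.shape[1]
    hist = pd.Series(
        {k: int((row_sums == k).sum()) for k in range(1, n_sites + 1)},
        name="n_compounds",
    )
    count = int((row_sums > min_sites).sum())
    return count, hist
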