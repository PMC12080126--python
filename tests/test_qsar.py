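"""Labeling, fingerprints, metrics, classifier training and screening."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ensdock.docking import EnergyMatrix
from ensdock.fixtures import FixtureSpec, gen_energy_matrix, gen_smiles_library
from ensdock.qsar import (
    ModelConfig,
    SiteActivityClassifier,
    bce_loss,
    build_labels,
    featurize,
    hamming_loss,
    mcc,
    multibinding_hit_histogram,
    oversample_actives,
    screen,
    zero_one_loss,
)


def _matrix(values, compounds=None, sites=None):
    values = np.asarray(values, dtype=float)
    compounds = compounds or [f"c{i}" for i in range(values.shape[0])]
    sites = sites or [f"s{j}" for j in range(values.shape[1])]
    return EnergyMatrix(pd.DataFrame(values, index=compounds, columns=sites))


# ---------------------------------------------------------------------------
# Labels


class TestBuildLabels:
    def test_tie_free_top5_percent_is_exact(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(-5, 1, size=(1000, 41)))
        labels = build_labels(m, 5.0)
        counts = labels.table.sum(axis=0)
        assert (counts == 50).all()

    def test_ten_value_percentile_example(self):
        # energies -9..-0, percentile 10 -> only the -9 compound is active
        m = _matrix(np.array([[-9.0], [-8], [-7], [-6], [-5], [-4], [-3], [-2], [-1], [-0.0]]))
        labels = build_labels(m, 10.0, min_site_count=1)
        assert labels.table.iloc[:, 0].tolist() == [1.0] + [0.0] * 9

    def test_active_iff_strictly_below_threshold(self):
        m = _matrix(np.arange(-40.0, 0.0).reshape(40, 1))
        labels = build_labels(m, 10.0)
        thr = labels.thresholds.iloc[0]
        col = m.table.iloc[:, 0]
        assert ((col < thr).astype(float) == labels.table.iloc[:, 0]).all()

    def test_lowering_energy_never_deactivates(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(-5, 1, size=(100, 3))
        m1 = _matrix(vals)
        labels1 = build_labels(m1, 5.0)
        vals2 = vals.copy()
        vals2[7, 1] -= 10.0  # push one compound deep into the active tail
        labels2 = build_labels(_matrix(vals2), 5.0)
        assert labels2.table.iloc[7, 1] == 1.0
        # no compound that stayed at the same energy in other sites loses
        # activity because of someone else's improvement at site 1 only
        assert (labels2.table[["s0", "s2"]] == labels1.table[["s0", "s2"]]).all().all()

    def test_missing_energies_excluded(self):
        vals = np.arange(-40.0, 0.0).reshape(40, 1)
        vals[0, 0] = np.nan
        labels = build_labels(_matrix(vals), 10.0)
        assert np.isnan(labels.table.iloc[0, 0])
        # 39 non-missing -> k = ceil(3.9) = 4 -> threshold is the 5th-lowest
        assert labels.table.iloc[:, 0].sum() == 4

    def test_all_missing_site_rejected(self):
        vals = np.full((30, 2), -5.0)
        vals[:, 1] = np.nan
        with pytest.raises(ValueError, match="s1"):
            build_labels(_matrix(vals), 5.0)

    def test_percentile_domain(self):
        m = _matrix(np.random.default_rng(0).normal(size=(30, 2)))
        for bad in (0.0, 100.0, -1.0):
            with pytest.raises(ValueError):
                build_labels(m, bad)


class TestOversampleActives:
    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.random((20, 4))
        y = (rng.random((20, 3)) < 0.5).astype(float)  # ~50% active
        x2, y2 = oversample_actives(x, y, seed=1, target_active_fraction=0.25)
        assert x2.shape == x.shape and np.array_equal(y2, y)

    def test_duplication_reaches_target_within_one_step(self):
        x = np.arange(100, dtype=float).reshape(100, 1)
        y = np.zeros((100, 10))
        y[:5, :8] = 1.0  # five active-any compounds, 8 of 10 sites each
        x2, y2 = oversample_actives(x, y, seed=2, target_active_fraction=0.25)
        frac = y2.mean()
        n_dup = len(y2) - len(y)
        assert n_dup > 0
        # one duplication step moves the fraction by at most one row's worth
        prev = np.vstack([y, y2[100:-1]]).mean()
        assert prev < 0.25 <= frac or frac == pytest.approx(0.25, abs=0.01)
        assert np.array_equal(x2[:100], x)  # originals retained

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        x = rng.random((50, 4))
        y = np.zeros((50, 6))
        y[:4, :3] = 1.0
        a = oversample_actives(x, y, seed=7)
        b = oversample_actives(x, y, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_no_actives_pass_through_with_warning(self):
        x = np.zeros((10, 2))
        y = np.zeros((10, 3))
        with pytest.warns(UserWarning, match="no active"):
            x2, y2 = oversample_actives(x, y)
        assert np.array_equal(x2, x)


# ---------------------------------------------------------------------------
# Fingerprints


class TestFeaturize:
    def test_canonical_equivalence(self):
        fps, rej = featurize(["CCO", "OCC"])
        assert not rej
        assert np.array_equal(fps[0], fps[1])

    def test_shape_contract(self):
        fps, rej = featurize(["c1ccccc1"])
        assert fps.shape == (1, 1412)
        assert set(np.unique(fps)) <= {0, 1}

    def test_methane_differs_from_ethane(self):
        fps, _ = featurize(["C", "CC"])
        assert (fps[0] != fps[1]).any()

    def test_invalid_smiles_listed_not_fatal(self):
        fps, rej = featurize(["CCO", "C((", "CC"])
        assert rej == [1]
        assert fps.shape[0] == 2


# ---------------------------------------------------------------------------
# Metrics


class TestMetrics:
    def test_mcc_closed_forms(self):
        assert mcc(5, 7, 0, 0) == pytest.approx(1.0)
        assert mcc(0, 0, 3, 4) == pytest.approx(-1.0)
        assert mcc(1, 2, 1, 1) == pytest.approx(1 / 6)

    def test_mcc_zero_denominator_defined_as_zero(self):
        assert mcc(3, 0, 0, 2) == 0.0

    def test_zero_one_closed_forms(self):
        a = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        assert zero_one_loss(a, a) == 0.0
        assert zero_one_loss(a, 1 - a) == 1.0
        b = a.copy()
        b[2, 0] = 0
        assert zero_one_loss(a, b) == 0.25

    def test_hamming_closed_forms(self):
        a = np.array([[1, 0], [0, 1]])
        assert hamming_loss(a, a) == 0.0
        assert hamming_loss(a, 1 - a) == 1.0
        b = a.copy()
        b[0, 0] = 0
        assert hamming_loss(a, b) == 0.25

    def test_bce_closed_forms_and_symmetry(self):
        assert bce_loss([1.0], [1.0 - 1e-9]) == pytest.approx(0.0, abs=1e-5)
        assert bce_loss([1.0], [0.5]) == pytest.approx(np.log(2))
        y = np.array([[1.0, 0.0]])
        p = np.array([[0.8, 0.3]])
        assert bce_loss(y, p) == pytest.approx(bce_loss(1 - y, 1 - p))

    def test_exhaustive_single_cell_enumeration_oracle(self):
        # all 2^4 combinations of 1x2 true/pred matrices vs sklearn
        from sklearn.metrics import hamming_loss as sk_hamming
        from sklearn.metrics import zero_one_loss as sk_zero_one

        for bits in itertools.product([0, 1], repeat=4):
            yt = np.array([[bits[0], bits[1]]])
            yp = np.array([[bits[2], bits[3]]])
            assert hamming_loss(yt, yp) == pytest.approx(sk_hamming(yt, yp))
            assert zero_one_loss(yt, yp) == pytest.approx(sk_zero_one(yt, yp))

    def test_mcc_agrees_with_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(0)
        yt = rng.integers(0, 2, size=200)
        yp = rng.integers(0, 2, size=200)
        tp = int(((yt == 1) & (yp == 1)).sum())
        tn = int(((yt == 0) & (yp == 0)).sum())
        fp = int(((yt == 0) & (yp == 1)).sum())
        fn = int(((yt == 1) & (yp == 0)).sum())
        assert mcc(tp, tn, fp, fn) == pytest.approx(matthews_corrcoef(yt, yp))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            zero_one_loss(np.zeros((2, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            hamming_loss(np.zeros((2, 2)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# Training


@pytest.fixture(scope="module")
def separable_fit():
    """Classifier trained on motif-separable planted-binder data."""
    lib = gen_smiles_library(2000, seed=3, motif_fraction=0.04)
    ids = [f"c{i:04d}" for i in range(2000)]
    planted = [i for i, s in zip(ids, lib) if "Cl" in s]
    spec = FixtureSpec(
        n_compounds=2000, n_planted=len(planted), n_sites=10, seed=5,
        planted_site_fraction=1.0, boost=5.0,
    )
    energies, pl, _ = gen_energy_matrix(spec, compound_ids=ids, planted_ids=planted)
    labels = build_labels(energies, 5.0)
    fps, rej = featurize(lib)
    assert not rej
    cfg = ModelConfig(hidden_sizes=(128, 128), epochs=25, seed=7)
    results = SiteActivityClassifier(fps, labels, cfg).fit()
    return dict(lib=lib, ids=ids, planted=pl, fps=fps, labels=labels, results=results, cfg=cfg)


class TestTrainClassifier:
    def test_planted_signal_reaches_high_mcc(self, separable_fit):
        assert separable_fit["results"].mean_mcc > 0.8

    def test_logistic_oracle_confirms_separability(self, separable_fit):
        # an independent linear learner achieves comparable accuracy,
        # confirming the signal rather than the implementation
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import matthews_corrcoef

        fps = separable_fit["fps"]
        y = separable_fit["labels"].values()
        rng = np.random.default_rng(7)
        order = rng.permutation(len(fps))
        tr, te = order[:1600], order[1800:]
        mccs = []
        for s in range(y.shape[1]):
            clf = LogisticRegression(max_iter=2000).fit(fps[tr], y[tr][:, s])
            mccs.append(matthews_corrcoef(y[te][:, s], clf.predict(fps[te])))
        assert np.mean(mccs) > 0.8

    def test_permuted_labels_give_null_mcc(self, separable_fit):
        rng = np.random.default_rng(0)
        y = separable_fit["labels"].values()[rng.permutation(2000)]
        cfg = ModelConfig(hidden_sizes=(64,), epochs=8, seed=7)
        res = SiteActivityClassifier(separable_fit["fps"], y, cfg).fit()
        assert abs(res.mean_mcc) < 0.1

    def test_seeded_determinism(self, separable_fit):
        cfg = ModelConfig(hidden_sizes=(32,), epochs=4, seed=13)
        fps = separable_fit["fps"][:400]
        y = separable_fit["labels"].values()[:400]
        r1 = SiteActivityClassifier(fps, y, cfg).fit()
        r2 = SiteActivityClassifier(fps, y, cfg).fit()
        assert r1.test_metrics == r2.test_metrics
        assert r1.best_epoch == r2.best_epoch

    def test_history_and_summary(self, separable_fit):
        res = separable_fit["results"]
        assert len(res.history) == separable_fit["cfg"].epochs
        assert res.best_epoch == res.history.loc[res.history.val_mean_mcc.idxmax(), "epoch"]
        text = res.summary()
        assert "mean MCC" in text and "site-0" in text

    def test_save_round_trip(self, separable_fit, tmp_path):
        res = separable_fit["results"]
        res.save(tmp_path / "w.npz", tmp_path / "cfg.json")
        assert (tmp_path / "w.npz").exists() and (tmp_path / "cfg.json").exists()


# ---------------------------------------------------------------------------
# Screening


class TestScreen:
    def test_strict_fraction_boundary_at_41_sites(self, separable_fit):
        # a compound active at 29/41 sites passes the 0.70 rule, at 28 not
        res = separable_fit["results"]
        n_sites = 41
        for n_active, expect in ((29, True), (28, False)):
            frac = n_active / n_sites
            assert (frac > 0.70) is expect

    def test_all_zero_predictions_select_nothing(self, separable_fit):
        results = separable_fit["results"]
        plain = [s for s in separable_fit["lib"] if "Cl" not in s][:50]
        sel = screen(results, plain, site_fraction_threshold=0.999)
        assert sel.selected == []

    def test_planted_binders_selected_low_false_rate(self, separable_fit):
        results = separable_fit["results"]
        lib, ids = separable_fit["lib"], separable_fit["ids"]
        planted = set(separable_fit["planted"])
        sel = screen(results, lib, ids, 0.70)
        selected = set(sel.selected)
        assert len(planted - selected) / len(planted) < 0.1  # nearly all recovered
        false_rate = len(selected - planted) / (len(ids) - len(planted))
        assert false_rate < 0.05

    def test_order_permutation_invariance(self, separable_fit):
        results = separable_fit["results"]
        lib, ids = separable_fit["lib"][:200], separable_fit["ids"][:200]
        sel1 = screen(results, lib, ids, 0.70)
        order = np.random.default_rng(0).permutation(200)
        sel2 = screen(results, [lib[i] for i in order], [ids[i] for i in order], 0.70)
        assert set(sel1.selected) == set(sel2.selected)

    def test_all_invalid_library_rejected(self, separable_fit):
        with pytest.raises(ValueError):
            screen(separable_fit["results"], ["C((", ")("], site_fraction_threshold=0.7)


class TestMultibindingHistogram:
    def test_strict_boundary_counting(self):
        rows = np.zeros((3, 41), dtype=int)
        rows[0, :31] = 1  # 31 sites: counted
        rows[1, :30] = 1  # exactly 30: not counted (strict >)
        rows[2, :2] = 1
        count, hist = multibinding_hit_histogram(rows, min_sites=30)
        assert count == 1
        assert hist.loc[31] == 1 and hist.loc[30] == 1 and hist.loc[2] == 1

    def test_all_zero_matrix(self):
        count, hist = multibinding_hit_histogram(np.zeros((5, 10), dtype=int), 3)
        assert count == 0 and hist.sum() == 0

    def test_histogram_sums_to_active_any(self):
        rng = np.random.default_rng(2)
        mat = (rng.random((50, 12)) < 0.3).astype(int)
        count, hist = multibinding_hit_histogram(mat, 4)
        assert hist.sum() == (mat.sum(axis=1) > 0).sum()
        assert count == (mat.sum(axis=1) > 4).sum()
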