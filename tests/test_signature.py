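"""Subject signatures, z-scaling, LOO classification, PCA and the
score/size-range ratio."""

import numpy as np
import pandas as pd
import pytest

from podoseg.signature import (FEATURE_SUBSETS, ZScaler, adapted_score_ratio,
                               feature_names, loo_classify, pca_glomeruli,
                               signature_frame, subject_signature)
from podoseg.stereology import GlomRecord


def make_record(sid="s1", gid="g1", number=100.0, density=200.0,
                distance=12.0, nuclear_area=40.0, glom_area=8000.0):
    vol = 1e6 * number / density if density else 1.0
    return GlomRecord(sid, gid, glom_area, vol, int(number // 10),
                      nuclear_area, 7.0, number, density,
                      [distance, distance], "normal")


class TestSubjectSignature:
    def test_identical_glomeruli_statistics(self):
        recs = [make_record(gid=f"g{i}") for i in range(4)]
        sig = subject_signature(recs, group="control")
        assert sig.features["number_min"] == sig.features["number_max"]
        assert sig.features["number_mean"] == sig.features["number_median"]
        assert sig.features["number_variance"] == 0.0
        assert sig.n_glomeruli == 4

    def test_hand_computed_statistics(self):
        recs = [make_record(gid=f"g{i}", number=v)
                for i, v in enumerate((100.0, 200.0, 300.0))]
        sig = subject_signature(recs)
        f = sig.features
        assert f["number_min"] == 100.0
        assert f["number_max"] == 300.0
        assert f["number_mean"] == 200.0
        assert f["number_median"] == 200.0
        assert f["number_variance"] == pytest.approx(10000.0)  # n-1

    def test_single_glomerulus_variance_missing(self):
        sig = subject_signature([make_record()])
        assert np.isnan(sig.features["number_variance"])
        assert np.isfinite(sig.features["number_mean"])

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            subject_signature([])

    def test_feature_count_is_25(self):
        assert len(feature_names()) == 25
        sig = subject_signature([make_record()])
        assert set(feature_names()) <= set(sig.features)


class TestZScaler:
    def test_train_columns_standardized(self, rng):
        X = rng.random((20, 5)) * 10
        z = ZScaler().fit(X).transform(X)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_column_centered_only(self):
        X = np.ones((5, 2))
        X[:, 1] = np.arange(5)
        z = ZScaler().fit(X).transform(X)
        assert np.allclose(z[:, 0], 0)

    def test_closed_form_on_new_value(self):
        scaler = ZScaler().fit(np.array([[1.0], [3.0]]))
        z = scaler.transform(np.array([[5.0]]))
        assert z[0, 0] == pytest.approx((5 - 2) / np.sqrt(2))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            ZScaler().fit(np.ones((1, 3)))


def _signature_table(n_per_group, sep, seed=0, n_glom=5):
    """Synthetic signature table via GlomRecords with a group offset."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, label in ((0, "control"), (1, "disease")):
        for i in range(n_per_group):
            sid = f"{label[0]}{i}"
            recs = []
            for k in range(n_glom):
                base = 100 + rng.normal(0, 10) - g * sep
                recs.append(make_record(sid, f"{sid}_g{k}",
                                        number=base + rng.normal(0, 5),
                                        density=200 - g * sep
                                        + rng.normal(0, 10)))
            sig = subject_signature(recs, group=label)
            row = dict(sig.features)
            row.update(subject_id=sid, group=label, n_glomeruli=n_glom)
            rows.append(row)
    return pd.DataFrame(rows)


class TestLooClassify:
    def test_perfectly_separated_groups(self):
        sigs = _signature_table(6, sep=80.0)
        res = loo_classify(sigs)
        assert res.auc_roc == 1.0
        assert res.accuracy == 1.0

    def test_one_model_per_subject(self):
        sigs = _signature_table(5, sep=50.0)
        res = loo_classify(sigs)
        assert len(res.oof_prob) == len(sigs)
        assert len(res.subject_ids) == len(sigs)
        conf = res.confusion
        assert conf["tn"] + conf["fp"] + conf["fn"] + conf["tp"] == len(sigs)

    def test_loo_is_leak_free(self):
        """Perturbing the held-out subject's features must not change the
        model of the fold that holds it out (it legitimately changes the
        other folds, where the subject is a training point)."""
        sigs = _signature_table(6, sep=30.0, seed=3)
        res1 = loo_classify(sigs, seed=0)
        bumped = sigs.copy()
        cols = feature_names()
        bumped.loc[0, cols] = bumped.loc[0, cols] * 3.0 + 17.0
        res2 = loo_classify(bumped, seed=0)
        assert np.allclose(res1.fold_coefs[0], res2.fold_coefs[0])
        assert not np.allclose(res1.fold_coefs[1], res2.fold_coefs[1])

    def test_missing_variance_imputed(self):
        sigs = _signature_table(5, sep=60.0)
        sigs.loc[0, [c for c in sigs.columns if c.endswith("variance")]] = \
            np.nan
        res = loo_classify(sigs)
        assert np.isfinite(res.oof_prob).all()

    def test_single_class_group_rejected(self):
        sigs = _signature_table(5, sep=10.0)
        sigs["group"] = "control"
        with pytest.raises(ValueError):
            loo_classify(sigs)

    def test_feature_subsets(self):
        sigs = _signature_table(5, sep=60.0)
        res3 = loo_classify(sigs, feature_subset="combined_score_3")
        assert len(res3.oof_prob) == len(sigs)
        with pytest.raises(ValueError):
            loo_classify(sigs, feature_subset="nope")


class TestPcaGlomeruli:
    def _glom_frame(self, X):
        df = pd.DataFrame(X, columns=["podocyte_number_est",
                                      "podocyte_density_per_1e6um3",
                                      "median_neighbor_distance_um",
                                      "mean_nuclear_area_um2",
                                      "glom_area_um2"])
        df["subject_id"] = "s"
        df["glomerulus_id"] = [f"g{i}" for i in range(len(df))]
        return df

    def test_rank_one_data_first_component_dominates(self, rng):
        u = rng.random(5)
        t = rng.standard_normal(50)
        X = np.outer(t, u) + rng.standard_normal((50, 5)) * 1e-4 + 10
        _, ev = pca_glomeruli(self._glom_frame(X))
        assert ev[0] > 0.99

    def test_explained_variance_sums_below_one(self, rng):
        X = rng.random((30, 5)) * [10, 100, 5, 50, 1000]
        scores, ev = pca_glomeruli(self._glom_frame(X), n_components=3)
        assert ev.sum() <= 1.0 + 1e-9
        assert {"pc1", "pc2", "pc3"} <= set(scores.columns)

    def test_pareto_differs_from_unit_variance(self, rng):
        # scaling by sqrt(sd) equals unit-variance scaling only when sd=1
        X = rng.random((30, 5)) * [1, 10, 100, 1, 5] + [0, 5, 50, 0, 2]
        sd = X.std(axis=0, ddof=1)
        pareto = (X - X.mean(0)) / np.sqrt(sd)
        unitvar = (X - X.mean(0)) / sd
        assert not np.allclose(pareto.std(0, ddof=1), 1.0)
        assert not np.allclose(pareto, unitvar)

    def test_constant_matrix_rejected(self):
        X = np.ones((10, 5))
        with pytest.raises(ValueError):
            pca_glomeruli(self._glom_frame(X))


class TestAdaptedScoreRatio:
    def test_equal_sizes_give_score(self):
        recs = [make_record(gid=f"g{i}", nuclear_area=40.0)
                for i in range(3)]
        assert adapted_score_ratio(8.0, recs) == pytest.approx(8.0)

    def test_reference_value(self):
        assert adapted_score_ratio(8.0, [50.0, 100.0]) == pytest.approx(4.0)

    def test_monotone_in_max_size(self):
        r1 = adapted_score_ratio(8.0, [50.0, 100.0])
        r2 = adapted_score_ratio(8.0, [50.0, 150.0])
        assert r2 < r1

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            adapted_score_ratio(8.0, [50.0])
        with pytest.raises(ValueError):
            adapted_score_ratio(8.0, [0.0, 50.0])


def test_signature_frame_matches_subject_signature():
    recs = [make_record("s1", f"g{i}", number=v)
            for i, v in enumerate((100.0, 200.0, 300.0))]
    from podoseg.stereology import records_to_frame
    frame = signature_frame(records_to_frame(recs))
    sig = subject_signature(recs)
    for name in ("number_min", "number_max", "number_mean",
                 "number_variance"):
        assert frame.loc[0, name] == pytest.approx(sig.features[name])
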