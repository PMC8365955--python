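"""Meta-feature assembly, combination enumeration/selection, stacking net."""

import numpy as np
import pytest

from hergstack.metaensemble import (
    CombinationResult,
    MetaFeatureMatrix,
    assemble_meta_features,
    best_single_baseline,
    classify_threshold,
    enumerate_feature_combinations,
    select_best_combination,
    train_meta_model,
)
from hergstack.metrics import MetricReport, auc_roc
from hergstack.nn import TrainConfig, predict_proba


class TestAssemble:
    def test_columns_follow_canonical_order(self, rng):
        probs = {m: np.asarray(rng.random(100)) for m in ("DESC", "MGF", "MFP", "SeV", "FPeV")}
        meta = assemble_meta_features(probs, ["FPeV", "DESC", "MFP"])
        assert meta.members == ("DESC", "MFP", "FPeV")
        assert meta.values.shape == (100, 3)
        assert np.array_equal(meta.values[:, 0], probs["DESC"])

    def test_single_member(self, rng):
        meta = assemble_meta_features({"SeV": np.asarray(rng.random(40))}, ["SeV"])
        assert meta.values.shape == (40, 1)

    def test_rejects_empty_mismatch_and_out_of_range(self, rng):
        with pytest.raises(ValueError):
            assemble_meta_features({}, [])
        with pytest.raises(ValueError):
            assemble_meta_features(
                {"DESC": np.zeros(5), "MGF": np.zeros(6)}, ["DESC", "MGF"]
            )
        with pytest.raises(ValueError):
            MetaFeatureMatrix(np.array([[1.2]]), ("DESC",))


class TestEnumeration:
    def test_group_sizes_and_total(self):
        combos = enumerate_feature_combinations()
        assert len(combos) == 31  # 2^5 - 1 nonempty subsets
        by_size = {}
        for cid, members in combos:
            by_size.setdefault(len(members), []).append(members)
        assert [len(by_size[s]) for s in (1, 2, 3, 4, 5)] == [5, 10, 10, 5, 1]
        assert len({frozenset(m) for _, m in combos}) == 31

    def test_deterministic_ids(self):
        a = enumerate_feature_combinations()
        b = enumerate_feature_combinations()
        assert a == b
        assert a[0] == ("M1-1", ("DESC",))
        assert a[-1][0] == "M5-1"

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            enumerate_feature_combinations(("A", "A", "B", "C", "D"))


def _result(cid, members, **metrics):
    return CombinationResult(cid, tuple(members), MetricReport(**metrics))


class TestSelection:
    def test_most_improvements_wins(self):
        base = dict(mcc=0.5, npv=0.5, acc=0.5, ppv=0.5, spe=0.5, sen=0.5, auc=0.5)
        m1 = [_result("M1-1", ("DESC",), **base)]
        good = _result("M2-1", ("DESC", "MGF"),
                       mcc=0.6, npv=0.6, acc=0.6, ppv=0.6, spe=0.6, sen=0.4, auc=0.4)
        meh = _result("M2-2", ("DESC", "MFP"),
                      mcc=0.6, npv=0.6, acc=0.6, ppv=0.4, spe=0.4, sen=0.4, auc=0.4)
        assert select_best_combination(m1 + [good, meh]) is good

    def test_tie_breaks_by_mcc_then_size(self):
        base = dict(mcc=0.5, npv=0.5, acc=0.5, ppv=0.5, spe=0.5, sen=0.5, auc=0.5)
        m1 = [_result("M1-1", ("DESC",), **base)]
        a = _result("A", ("DESC", "MGF"), **{**base, "mcc": 0.72, "acc": 0.6})
        b = _result("B", ("DESC", "MFP"), **{**base, "mcc": 0.70, "acc": 0.6})
        assert select_best_combination(m1 + [a, b]) is a
        c = _result("C", ("DESC", "MGF", "MFP"), **{**base, "mcc": 0.72, "acc": 0.6})
        assert select_best_combination(m1 + [a, c]) is a  # smaller subset wins

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            select_best_combination([])

    def test_published_grid_selects_mfp_desc_sev_fpev(self):
        """On the published 10-fold meta-validation grid the winning subset
        is {MFP, DESC, SeV, FPeV} (the four-feature combination)."""
        rows = {
            "M1-1": (("DESC",), (.676, .829, .838, .862, .868, .819, .909)),
            "M1-2": (("MGF",), (.599, .784, .799, .815, .792, .806, .878)),
            "M1-3": (("MFP",), (.682, .829, .840, .853, .838, .843, .909)),
            "M1-4": (("FPeV",), (.636, .820, .817, .819, .795, .839, .897)),
            "M1-5": (("SeV",), (.621, .806, .809, .816, .791, .828, .880)),
            "M2-1": (("MGF", "MFP"), (.691, .826, .846, .864, .850, .842, .919)),
            "M2-2": (("MGF", "DESC"), (.683, .818, .842, .865, .848, .835, .914)),
            "M2-3": (("MGF", "SeV"), (.685, .837, .842, .848, .830, .854, .916)),
            "M2-4": (("MGF", "FPeV"), (.682, .828, .841, .854, .833, .848, .916)),
            "M2-5": (("MFP", "DESC"), (.710, .843, .855, .866, .855, .855, .928)),
            "M2-6": (("MFP", "SeV"), (.698, .838, .849, .861, .844, .853, .921)),
            "M2-7": (("MFP", "FPeV"), (.690, .831, .845, .859, .840, .850, .920)),
            "M2-8": (("DESC", "SeV"), (.707, .847, .853, .860, .846, .861, .926)),
            "M2-9": (("DESC", "FPeV"), (.715, .848, .857, .867, .859, .856, .929)),
            "M2-10": (("SeV", "FPeV"), (.680, .828, .840, .853, .835, .845, .918)),
            "M3-1": (("MGF", "MFP", "DESC"), (.707, .851, .853, .857, .841, .866, .924)),
            "M3-2": (("MGF", "MFP", "SeV"), (.711, .855, .855, .857, .835, .874, .927)),
            "M3-3": (("MGF", "MFP", "FPeV"), (.701, .849, .850, .853, .833, .867, .921)),
            "M3-4": (("MGF", "DESC", "SeV"), (.710, .847, .855, .864, .849, .861, .926)),
            "M3-5": (("MGF", "DESC", "FPeV"), (.706, .853, .852, .855, .831, .874, .928)),
            "M3-6": (("MGF", "SeV", "FPeV"), (.697, .844, .849, .854, .838, .859, .925)),
            "M3-7": (("MFP", "DESC", "SeV"), (.718, .854, .859, .865, .850, .868, .930)),
            "M3-8": (("MFP", "DESC", "FPeV"), (.710, .850, .855, .861, .846, .864, .926)),
            "M3-9": (("MFP", "SeV", "FPeV"), (.699, .837, .849, .862, .848, .851, .925)),
            "M3-10": (("DESC", "SeV", "FPeV"), (.712, .846, .856, .866, .854, .858, .928)),
            "M4-1": (("MGF", "MFP", "DESC", "SeV"), (.711, .850, .855, .861, .841, .869, .927)),
            "M4-2": (("MGF", "MFP", "DESC", "FPeV"), (.719, .851, .860, .869, .853, .867, .929)),
            "M4-3": (("MGF", "MFP", "SeV", "FPeV"), (.705, .846, .852, .859, .846, .859, .921)),
            "M4-4": (("MGF", "DESC", "SeV", "FPeV"), (.707, .849, .853, .859, .841, .865, .926)),
            "M4-5": (("MFP", "DESC", "SeV", "FPeV"), (.720, .849, .860, .871, .856, .864, .930)),
            "M5-1": (("MGF", "DESC", "SeV", "FPeV", "MFP"), (.717, .853, .858, .864, .850, .867, .925)),
        }
        results = [
            _result(cid, members,
                    mcc=v[0], npv=v[1], acc=v[2], ppv=v[3], spe=v[4], sen=v[5], auc=v[6])
            for cid, (members, v) in rows.items()
        ]
        baseline = best_single_baseline(results)
        assert baseline == pytest.approx(
            dict(mcc=.682, npv=.829, acc=.840, ppv=.862, spe=.868, sen=.843, auc=.909)
        )
        winner = select_best_combination(results)
        assert winner.combination_id == "M4-5"
        assert set(winner.members) == {"MFP", "DESC", "SeV", "FPeV"}


class TestMetaModel:
    def test_perfect_feature_gives_perfect_auc(self, rng):
        y = np.asarray(rng.integers(0, 2, 200))
        meta = MetaFeatureMatrix(
            np.column_stack([y.astype(float), rng.random(200)]), ("DESC", "MFP")
        )
        model = train_meta_model(meta, y, TrainConfig(learning_rate=1e-2, epochs=80, seed=3))
        probs = predict_proba(model, meta.values)
        assert auc_roc(y, probs) >= 0.99

    def test_noise_features_stay_at_chance(self, rng):
        y = np.asarray(rng.integers(0, 2, 300))
        meta = MetaFeatureMatrix(np.asarray(rng.random((300, 3))), ("DESC", "MFP", "SeV"))
        model = train_meta_model(meta, y, TrainConfig(learning_rate=1e-3, epochs=30, seed=3))
        hold = MetaFeatureMatrix(np.asarray(rng.random((300, 3))), meta.members)
        y_hold = np.asarray(rng.integers(0, 2, 300))
        assert abs(auc_roc(y_hold, predict_proba(model, hold.values)) - 0.5) < 0.1

    def test_seeded_rerun_identical(self, rng):
        y = np.asarray(rng.integers(0, 2, 100))
        meta = MetaFeatureMatrix(np.asarray(rng.random((100, 2))), ("DESC", "MFP"))
        cfg = TrainConfig(learning_rate=1e-3, epochs=10, seed=12)
        p1 = predict_proba(train_meta_model(meta, y, cfg), meta.values)
        p2 = predict_proba(train_meta_model(meta, y, cfg), meta.values)
        assert np.array_equal(p1, p2)


class TestThreshold:
    @pytest.mark.parametrize("p,expected", [(0.50, 1), (0.49, 0), (1.0, 1), (0.0, 0)])
    def test_boundary(self, p, expected):
        assert classify_threshold([p])[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_threshold([1.2])
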