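"""Fold-space searches and order/disorder classification."""

import numpy as np
import pytest

from cdsk.errors import DataError, InputFormatError
from cdsk.neighbors import (
    DisorderReference,
    ErrorRadii,
    FoldDB,
    classify_disorder,
    closest_k,
    cosine_distance,
    radius_search,
    wknn_predict,
)
from cdsk.synthetic import (
    DisorderConfig,
    FoldSpaceConfig,
    gen_disorder_ref,
    gen_fold_db,
)


@pytest.fixture(scope="module")
def big_db():
    return gen_fold_db(FoldSpaceConfig(seed=8, n_per_fold=143))  # 1001 records


@pytest.fixture(scope="module")
def disorder_ref():
    return gen_disorder_ref(DisorderConfig(seed=9))


class TestClosestK:
    def test_self_query_is_first_with_zero_distance(self, big_db):
        hits = closest_k(big_db.ss[37], big_db, 5)
        assert hits.id[0] == big_db.ids[37]
        assert hits.distance[0] == 0.0

    def test_matches_exhaustive_sort_oracle(self, big_db, rng):
        q = rng.dirichlet(np.ones(8))
        hits = closest_k(q, big_db, 20)
        d = np.linalg.norm(big_db.ss - q, axis=1)
        oracle = sorted(range(len(big_db)), key=lambda i: (d[i], big_db.ids[i]))[:20]
        assert list(hits.id) == [big_db.ids[i] for i in oracle]
        assert np.allclose(hits.distance, d[oracle])

    def test_k_equal_db_size_returns_all_sorted(self, big_db):
        hits = closest_k(big_db.ss[0], big_db, len(big_db))
        assert len(hits) == len(big_db)
        assert np.all(np.diff(hits.distance) >= 0)

    def test_empty_db_and_bad_k(self, big_db):
        with pytest.raises(InputFormatError):
            closest_k(big_db.ss[0], big_db, len(big_db) + 1)


class TestRadiusSearch:
    def test_tiny_radii_hit_only_exact_matches(self, big_db):
        r = ErrorRadii(np.full(8, 1e-12))
        tables = radius_search(big_db.ss[11], big_db, r)
        assert tables["homology"]["count"].sum() == 1

    def test_planted_records_inside_box(self, rng):
        q = rng.dirichlet(np.ones(8))
        radii = np.full(8, 0.02)
        inside = []
        for _ in range(7):
            delta = rng.uniform(-0.015, 0.015, size=8)
            delta -= delta.mean()  # stay on the simplex plane
            inside.append(np.clip(q + delta, 0, None))
        outside = [np.clip(q + 0.5, 0, None) for _ in range(5)]
        ss = np.array(inside + outside)
        ss /= ss.sum(axis=1, keepdims=True)
        m = int(np.sum(np.all(np.abs(ss - q) <= radii, axis=1)))
        db = FoldDB(
            tuple(f"r{i}" for i in range(len(ss))),
            ss,
            np.full(len(ss), 100),
            tuple(["1.10.10.10"] * len(ss)),
        )
        tables = radius_search(q, db, ErrorRadii(radii))
        assert tables["class"]["count"].sum() == m >= 5

    def test_counts_partition_at_every_level(self, big_db, rng):
        q = rng.dirichlet(np.ones(8) * 3)
        tables = radius_search(q, big_db, ErrorRadii(np.full(8, 0.1)))
        totals = {lev: df["count"].sum() for lev, df in tables.items()}
        assert len(set(totals.values())) == 1

    def test_hit_set_monotone_in_radius(self, big_db):
        q = big_db.ss[500]
        prev = -1
        for r in (0.01, 0.05, 0.1, 0.3):
            tables = radius_search(q, big_db, ErrorRadii(np.full(8, r)))
            n = tables["class"]["count"].sum()
            assert n >= prev
            prev = n

    def test_zero_hits_is_empty_not_error(self, big_db):
        q = np.zeros(8)
        q[0] = 1.0
        tables = radius_search(q, big_db, ErrorRadii(np.full(8, 1e-6)))
        assert tables["class"].empty


class TestWknn:
    def test_coincident_query_k1_wins_all_levels(self, big_db):
        tables = wknn_predict(big_db.ss[77], big_db, k=1)
        lab = big_db.labels[77]
        parts = lab.split(".")
        for lev, name in enumerate(("class", "architecture", "topology", "homology"), 1):
            assert tables[name].label[0] == ".".join(parts[:lev])

    def test_cluster_centers_recover_labels(self):
        cfg = FoldSpaceConfig(seed=10, n_per_fold=30, concentration=400.0)
        db = gen_fold_db(cfg)
        for label, centroid in cfg.folds.items():
            c = np.asarray(centroid) / np.sum(centroid)
            tables = wknn_predict(c, db, k=15)
            assert tables["homology"].label[0] == label

    def test_scores_match_brute_force_oracle(self, big_db, rng):
        q = rng.dirichlet(np.ones(8))
        k = 25
        tables = wknn_predict(q, big_db, k=k)
        d = np.linalg.norm(big_db.ss - q, axis=1)
        order = sorted(range(len(big_db)), key=lambda i: (d[i], big_db.ids[i]))[:k]
        for lev, name in enumerate(("class", "architecture", "topology", "homology"), 1):
            scores = {}
            for i in order:
                pref = ".".join(big_db.labels[i].split(".")[:lev])
                scores[pref] = scores.get(pref, 0.0) + 1.0 / (d[i] + 1e-9)
            df = tables[name]
            for lab, sc in scores.items():
                got = float(df[df.label == lab].score.iloc[0])
                assert got == pytest.approx(sc, rel=1e-12)

    def test_parent_score_at_least_child_score(self, big_db, rng):
        q = rng.dirichlet(np.ones(8) * 2)
        tables = wknn_predict(q, big_db, k=30)
        for child_level, parent_level in (
            ("architecture", "class"),
            ("topology", "architecture"),
            ("homology", "topology"),
        ):
            parents = dict(zip(tables[parent_level].label, tables[parent_level].score))
            for lab, sc in zip(tables[child_level].label, tables[child_level].score):
                parent = ".".join(lab.split(".")[:-1])
                assert parents[parent] >= sc - 1e-12


class TestDisorder:
    def test_identical_query_has_zero_distance(self, disorder_ref):
        call = classify_disorder(disorder_ref.triplets[0], disorder_ref)
        assert call.neighbors.distance[0] == pytest.approx(0.0, abs=1e-12)

    def test_cosine_scale_invariance(self, disorder_ref, rng):
        q = disorder_ref.triplets[5]
        c1 = classify_disorder(q, disorder_ref)
        c2 = classify_disorder(123.4 * q, disorder_ref)
        assert c1.label == c2.label
        assert np.allclose(c1.neighbors.distance, c2.neighbors.distance, atol=1e-12)

    def test_doubled_reference_triplet_still_zero_distance(self, disorder_ref):
        assert cosine_distance(2.0 * disorder_ref.triplets[3], disorder_ref.triplets[3]) == pytest.approx(0.0, abs=1e-15)

    def test_matches_exhaustive_knn_oracle(self, disorder_ref, rng):
        for _ in range(100):
            q = rng.normal(size=3)
            if np.linalg.norm(q) < 1e-6:
                continue
            call = classify_disorder(q, disorder_ref)
            d = 1.0 - (disorder_ref.triplets @ q) / (
                np.linalg.norm(disorder_ref.triplets, axis=1) * np.linalg.norm(q)
            )
            order = sorted(range(len(d)), key=lambda i: (d[i], disorder_ref.ids[i]))[:10]
            votes = [disorder_ref.labels[i] for i in order]
            n_dis = votes.count("disordered")
            expected = "disordered" if n_dis >= 5 else "ordered"
            assert call.label == expected

    def test_well_separated_cones_fully_correct(self, disorder_ref, rng):
        cfg = DisorderConfig(seed=9)
        for label, direction in (
            ("ordered", cfg.ordered_direction),
            ("disordered", cfg.disordered_direction),
        ):
            u = np.asarray(direction) / np.linalg.norm(direction)
            for _ in range(100):
                v = u + cfg.spread * rng.normal(size=3)
                call = classify_disorder(v * rng.uniform(0.5, 20.0), disorder_ref)
                assert call.label == label

    def test_tie_resolves_to_disordered_and_flags(self):
        # 5 ordered and 5 disordered records equidistant from the query
        tri = np.array([[1.0, e, 0.0] for e in np.linspace(-0.1, 0.1, 5)] +
                       [[1.0, 0.0, e] for e in np.linspace(-0.1, 0.1, 5)])
        ref = DisorderReference(
            tuple(f"x{i}" for i in range(10)),
            tri,
            tuple(["ordered"] * 5 + ["disordered"] * 5),
        )
        call = classify_disorder(np.array([1.0, 0.0, 0.0]), ref)
        assert call.tie
        assert call.label == "disordered"

    def test_zero_norm_query_rejected(self, disorder_ref):
        with pytest.raises(DataError):
            classify_disorder(np.zeros(3), disorder_ref)


class TestFoldDbIO:
    def test_csv_round_trip(self, tmp_path):
        db = gen_fold_db(FoldSpaceConfig(seed=12, n_per_fold=5))
        p = tmp_path / "folds.csv"
        db.to_csv(p)
        back = FoldDB.from_csv(p)
        assert back.ids == db.ids
        assert np.allclose(back.ss, db.ss)
        assert back.labels == db.labels

    def test_bad_label_rejected(self):
        with pytest.raises(InputFormatError):
            FoldDB(("a",), np.full((1, 8), 0.125), np.array([100]), ("1.10.10",))
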