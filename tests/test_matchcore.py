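"""Feature extraction, pairwise scoring, LNBNN (vs brute force), ranking."""

import numpy as np
import pytest

from patternpipe import coatsim as cs
from patternpipe import matchcore as mc
from patternpipe.preprocess import Crop, remove_background


def synthetic_descriptor_set(crop_id, n, rng, d=128, coords_span=200.0):
    desc = rng.standard_normal((n, d)).astype(np.float32)
    desc /= np.linalg.norm(desc, axis=1, keepdims=True)
    kps = np.column_stack([
        rng.uniform(0, coords_span, n), rng.uniform(0, coords_span, n),
        np.ones(n), np.zeros(n),
    ])
    return mc.DescriptorSet(crop_id=crop_id, keypoints=kps, descriptors=desc)


def brute_force_lnbnn(query, database, k):
    """Independent oracle: exhaustive distance matrix, no spatial index."""
    pool, owners = [], []
    for i, ds in enumerate(database):
        for row in ds.descriptors:
            pool.append(row)
            owners.append(i)
    pool = np.asarray(pool, dtype=np.float64)
    owners = np.asarray(owners)
    scores = np.zeros(len(database))
    for q in query.descriptors.astype(np.float64):
        dists = np.linalg.norm(pool - q, axis=1)
        order = np.argsort(dists, kind="stable")
        kq = min(k + 1, len(pool))
        idx = order[:kq]
        d_bg = dists[idx[-1]] if kq == k + 1 else dists[idx].max()
        first_k = idx[: kq - 1] if kq == k + 1 else idx
        seen = {}
        for j in first_k:
            o = owners[j]
            if o not in seen:
                seen[o] = dists[j]
        for o, d_i in seen.items():
            scores[o] += max(0.0, d_bg - d_i)
    return scores


class TestExtractFeatures:
    def test_uniform_image_no_keypoints(self):
        c = Crop(crop_id="u", pixels=np.full((64, 64, 3), 100, dtype=np.uint8))
        ds = mc.extract_features(c)
        assert len(ds) == 0 and ds.empty_flagged

    def test_deterministic(self, small_crops):
        a = mc.extract_features(small_crops[0])
        b = mc.extract_features(small_crops[0])
        assert np.array_equal(a.descriptors, b.descriptors)
        assert np.array_equal(a.keypoints, b.keypoints)

    def test_descriptors_unit_normalized(self, small_crops):
        ds = mc.extract_features(small_crops[0])
        assert len(ds) > 0
        norms = np.linalg.norm(ds.descriptors, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_tiny_crop_rejected(self):
        c = Crop(crop_id="t", pixels=np.zeros((16, 16, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            mc.extract_features(c)

    def test_scale_change_keeps_half_of_matches(self, small_crops):
        from skimage.transform import rescale
        c = small_crops[0]
        big = (rescale(c.pixels.astype(float) / 255.0, (1.5, 1.5, 1.0),
                       anti_aliasing=True) * 255).astype(np.uint8)
        a = mc.extract_features(c)
        b = mc.extract_features(Crop(crop_id="big", pixels=big))
        matches = mc._ratio_mutual_matches(a, b, ratio=0.9)
        assert len(matches) >= 0.5 * min(len(a), len(b)) * 0.5

    def test_black_fill_masked_crop_keypoints_on_animal(self, small_crops):
        c = remove_background(small_crops[0], small_crops[0].mask, fill="black")
        ds = mc.extract_features(c)
        rows = ds.keypoints[:, 1].astype(int)
        cols = ds.keypoints[:, 0].astype(int)
        assert len(ds) > 0
        assert c.mask[rows, cols].all()


class TestPairwiseScore:
    def test_self_match_scores_full_set(self, rng):
        a = synthetic_descriptor_set("a", 40, rng)
        s = mc.pairwise_score(a, a)
        assert s.score == len(a)

    def test_translated_copy_all_inliers(self, rng):
        a = synthetic_descriptor_set("a", 30, rng)
        b = mc.DescriptorSet(
            crop_id="b",
            keypoints=a.keypoints + np.array([10.0, 5.0, 0, 0]),
            descriptors=a.descriptors.copy(),
        )
        s = mc.pairwise_score(a, b, seed=0)
        assert s.score == len(a)

    def test_random_descriptors_score_low(self, rng):
        a = synthetic_descriptor_set("a", 100, rng)
        b = synthetic_descriptor_set("b", 100, rng)
        s = mc.pairwise_score(a, b, seed=0)
        assert s.score <= 5

    def test_empty_set_scores_zero(self, rng):
        a = synthetic_descriptor_set("a", 10, rng)
        empty = mc.DescriptorSet("e", np.zeros((0, 4)),
                                 np.zeros((0, 128), dtype=np.float32))
        assert mc.pairwise_score(a, empty).score == 0.0


class TestLNBNN:
    def test_one_dimensional_toy_example(self):
        # query at origin; I1's nearest at distance 1, I2's at 2; k=1:
        # score(I1) = d2 - d1 = 1, score(I2) = 0
        q = mc.DescriptorSet("q", np.zeros((1, 4)),
                             np.zeros((1, 1), dtype=np.float32))
        i1 = mc.DescriptorSet("i1", np.zeros((1, 4)),
                              np.array([[1.0]], dtype=np.float32))
        i2 = mc.DescriptorSet("i2", np.zeros((1, 4)),
                              np.array([[2.0]], dtype=np.float32))
        scores = {m.database_id: m.score for m in mc.lnbnn_scores(q, [i1, i2], k=1)}
        assert scores["i1"] == pytest.approx(1.0)
        assert scores["i2"] == 0.0

    def test_exact_duplicate_gets_maximal_score(self, rng):
        q = synthetic_descriptor_set("q", 50, rng)
        dup = mc.DescriptorSet("dup", q.keypoints.copy(), q.descriptors.copy())
        others = [synthetic_descriptor_set(f"o{i}", 50, rng) for i in range(4)]
        scores = {m.database_id: m.score
                  for m in mc.lnbnn_scores(q, [dup] + others)}
        assert scores["dup"] == max(scores.values())

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            n_crops = int(rng.integers(2, 6))
            db = [synthetic_descriptor_set(f"c{i}", int(rng.integers(5, 60)), rng)
                  for i in range(n_crops)]
            q = synthetic_descriptor_set("q", int(rng.integers(5, 40)), rng)
            k = int(rng.integers(1, 6))
            fast = {m.database_id: m.score for m in mc.lnbnn_scores(q, db, k=k)}
            slow = brute_force_lnbnn(q, db, k)
            for i, ds in enumerate(db):
                assert fast[ds.crop_id] == pytest.approx(slow[i], abs=1e-9)

    def test_fewer_than_k_plus_one_descriptors(self, rng):
        q = synthetic_descriptor_set("q", 5, rng)
        db = [synthetic_descriptor_set("only", 3, rng)]
        scores = mc.lnbnn_scores(q, db, k=5)
        assert scores[0].score >= 0.0

    def test_score_monotone_in_database_descriptors(self, rng):
        # appending descriptors to a crop never decreases its score
        q = synthetic_descriptor_set("q", 20, rng)
        base = synthetic_descriptor_set("t", 10, rng)
        others = [synthetic_descriptor_set(f"o{i}", 30, rng) for i in range(3)]
        s_before = {m.database_id: m.score
                    for m in mc.lnbnn_scores(q, [base] + others)}["t"]
        extra = np.concatenate([base.descriptors,
                                q.descriptors[:5]])  # near-duplicates of query
        bigger = mc.DescriptorSet("t", np.zeros((len(extra), 4)), extra)
        s_after = {m.database_id: m.score
                   for m in mc.lnbnn_scores(q, [bigger] + others)}["t"]
        assert s_after >= s_before

    def test_exclusions_respected(self, rng):
        q = synthetic_descriptor_set("q", 10, rng)
        db = [synthetic_descriptor_set(f"c{i}", 10, rng) for i in range(3)]
        scores = mc.lnbnn_scores(q, db, exclusions={"c1"})
        assert {m.database_id for m in scores} == {"c0", "c2"}


class TestMirror:
    def test_pixel_exact_flip_and_involution(self, small_crops):
        c = small_crops[0]
        m = mc.mirror(c)
        assert np.array_equal(m.pixels, c.pixels[:, ::-1])
        mm = mc.mirror(m)
        assert mm.crop_id == c.crop_id
        assert np.array_equal(mm.pixels, c.pixels)
        assert np.array_equal(mm.mask, c.mask)

    def test_mirrored_left_not_inflated_against_own_right(self):
        # left/right patterns are independent: a mirrored left crop should
        # not preferentially match the same individual's right flank
        params = cs.PopulationParams(name="mir", n_individuals=8, seed=51,
                                     photos_per_individual=4)
        from patternpipe.pipeline import PipelineConfig, catalog_to_crops
        crops, _ = catalog_to_crops(cs.generate_catalog(params), PipelineConfig())
        rights = {c.attributes["individual_id"]: c for c in crops
                  if c.attributes["side"] == "right"}
        lefts = {c.attributes["individual_id"]: c for c in crops
                 if c.attributes["side"] == "left"}
        own, cross = [], []
        inds = sorted(set(rights) & set(lefts))
        for ind in inds:
            q = mc.extract_features(mc.mirror(lefts[ind]))
            own.append(mc.pairwise_score(q, mc.extract_features(rights[ind]),
                                         seed=0).score)
            other = inds[(inds.index(ind) + 1) % len(inds)]
            cross.append(mc.pairwise_score(q, mc.extract_features(rights[other]),
                                           seed=0).score)
        assert np.mean(own) <= np.mean(cross) + 5.0


class TestRank:
    def test_duplicate_ranks_first(self, rng):
        q = synthetic_descriptor_set("q", 30, rng)
        dup = mc.DescriptorSet("dup", q.keypoints.copy(), q.descriptors.copy())
        db = [dup] + [synthetic_descriptor_set(f"o{i}", 30, rng)
                      for i in range(9)]
        r = mc.rank(q, db, true_id="dup")
        assert r.ordering[0] == "dup" and r.true_match_rank == 1

    def test_all_zero_scores_orders_by_id(self):
        q = mc.DescriptorSet("q", np.zeros((0, 4)),
                             np.zeros((0, 128), dtype=np.float32))
        db = [mc.DescriptorSet(cid, np.zeros((0, 4)),
                               np.zeros((0, 128), dtype=np.float32))
              for cid in ["c", "a", "b"]]
        r = mc.rank(q, db)
        assert r.ordering == ["a", "b", "c"]

    def test_consistent_with_lnbnn_toy(self):
        q = mc.DescriptorSet("q", np.zeros((1, 4)),
                             np.zeros((1, 1), dtype=np.float32))
        i1 = mc.DescriptorSet("i1", np.zeros((1, 4)),
                              np.array([[1.0]], dtype=np.float32))
        i2 = mc.DescriptorSet("i2", np.zeros((1, 4)),
                              np.array([[2.0]], dtype=np.float32))
        r = mc.rank(q, [i2, i1], k=1, true_id="i1")
        assert r.ordering == ["i1", "i2"] and r.true_match_rank == 1

    def test_query_and_exclusions_never_appear(self, rng):
        q = synthetic_descriptor_set("q", 10, rng)
        db = [q] + [synthetic_descriptor_set(f"c{i}", 10, rng) for i in range(3)]
        r = mc.rank(q, db, exclusions={"c0"})
        assert "q" not in r.ordering and "c0" not in r.ordering
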