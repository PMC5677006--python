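"""Tractometer metrics: recognition, invalid clustering, overlap, strict VC."""

import numpy as np
import pytest

from tractobench.evaluation import (
    EvaluationConfig,
    classify_invalid,
    count_potential_pairs,
    evaluate,
    overlap_overreach,
    recognize_valid,
    strict_vc,
    streamline_bundle_distances,
)
from tractobench.streamlines import mdf_distance

VS = 2.0
CFG = EvaluationConfig(voxel_size=VS)


def all_refs(bundles):
    return [s for b in bundles for s in b.reference_streamlines]


class TestPairCounting:
    def test_paper_scale_counts(self):
        # 25 bundles -> 50 endpoint regions -> 1275 pairs, 1250 potential IBs
        assert count_potential_pairs(25) == (1275, 1250)

    def test_single_bundle_enumeration(self):
        # 2 regions {H, T}: pairs {HH, HT, TT}; HT is the valid one
        assert count_potential_pairs(1) == (3, 2)

    def test_zero_bundles(self):
        assert count_potential_pairs(0) == (0, 0)

    def test_matches_exhaustive_enumeration(self):
        for n in range(1, 8):
            regions = list(range(2 * n))
            pairs = {(a, b) for i, a in enumerate(regions)
                     for b in regions[i:]}
            valid = {(2 * i, 2 * i + 1) for i in range(n)}
            assert count_potential_pairs(n) == (len(pairs),
                                                len(pairs - valid))


class TestRecognizeValid:
    def test_references_recognized_by_their_own_bundle(self, canonical):
        _, _, bundles = canonical
        refs = all_refs(bundles)
        assignment, dist = recognize_valid(refs, bundles, CFG)
        expected = np.repeat(np.arange(len(bundles)),
                             [len(b.reference_streamlines) for b in bundles])
        assert np.array_equal(assignment, expected)
        assert dist.max() < 1e-9

    def test_translated_reference_beyond_threshold_unassigned(self, canonical):
        _, _, bundles = canonical
        b = bundles[0]
        # clear the threshold even from the farthest-out reference: shift by
        # 1.5 x threshold plus the bundle cross-section radius
        shift = 1.5 * b.recognition_threshold + 4.0
        off = b.reference_streamlines[0] + np.array([0.0, 0.0, shift])
        d = streamline_bundle_distances([off], bundles)[0]
        assert d[0] > b.recognition_threshold  # construction check
        assignment, _ = recognize_valid([off], bundles, CFG)
        # moved vertically off the crossing plane: far from every bundle
        assert assignment[0] == -1

    def test_reversal_invariance(self, canonical, rng):
        _, _, bundles = canonical
        sls = [b.reference_streamlines[i] + rng.normal(0, 1.0, (1, 3))
               for b in bundles for i in (0, 3)]
        fwd, _ = recognize_valid(sls, bundles, CFG)
        rev, _ = recognize_valid([s[::-1] for s in sls], bundles, CFG)
        assert np.array_equal(fwd, rev)

    def test_equidistant_tie_broken_by_lower_bundle_index(self):
        from tractobench.phantom import BundleGeometry, PhantomSpec, assemble_phantom
        # two parallel straight bundles, equal thresholds; a probe exactly
        # midway is equidistant by construction
        ga = BundleGeometry("a", [(10, 30, 40), (70, 30, 40)], radius=0.0,
                            n_streamlines=1, recognition_threshold=12.0)
        gb = BundleGeometry("b", [(10, 50, 40), (70, 50, 40)], radius=0.0,
                            n_streamlines=1, recognition_threshold=12.0)
        _, bundles = assemble_phantom(
            PhantomSpec((40, 40, 40), VS, [ga, gb], rng_seed=0))
        probe = np.array([[10.0, 40, 40], [70.0, 40, 40]])
        d = streamline_bundle_distances([probe], bundles)[0]
        assert d[0] == pytest.approx(d[1], abs=1e-9)
        assignment, _ = recognize_valid([probe], bundles, CFG)
        assert assignment[0] == 0

    def test_agrees_with_brute_force_nearest_bundle(self, canonical, rng):
        _, _, bundles = canonical
        # 50 perturbed streamlines, some recognizable, some not
        sls = []
        for _ in range(50):
            b = bundles[rng.integers(len(bundles))]
            s = b.reference_streamlines[rng.integers(len(b.reference_streamlines))]
            sls.append(s + rng.normal(0, rng.uniform(0.5, 6.0), (1, 3)))
        assignment, _ = recognize_valid(sls, bundles, CFG)
        for i, s in enumerate(sls):
            dists = np.array([
                min(mdf_distance(s, r) for r in b.reference_streamlines)
                for b in bundles])
            ok = dists <= [b.recognition_threshold for b in bundles]
            expected = int(np.argmin(np.where(ok, dists, np.inf))) if ok.any() else -1
            assert assignment[i] == expected


class TestClassifyInvalid:
    def test_cross_bundle_streamline_forms_invalid_cluster(self, canonical):
        spec, _, bundles = canonical
        # bridge funnel_a's head region to funnel_b's tail region: a pair
        # absent from ground truth
        a, b = bundles[3], bundles[4]
        start = a.reference_streamlines[0][0]
        end = b.reference_streamlines[0][-1]
        t = np.linspace(0, 1, 20)[:, None]
        bridge = start + t * (end - start)
        assignment, _ = recognize_valid([bridge], bundles, CFG)
        assert assignment[0] == -1
        cls = classify_invalid([bridge], assignment, bundles, CFG)
        assert cls.kind[0] == "invalid"
        assert cls.invalid_pairs == [(6, 9)]  # head of bundle 3, tail of 4

    def test_same_pair_clusters_merge_into_one_ib(self, canonical):
        spec, _, bundles = canonical
        a, b = bundles[3], bundles[4]
        start = a.reference_streamlines[0][0]
        end = b.reference_streamlines[0][-1]
        t = np.linspace(0, 1, 20)[:, None]
        straight = start + t * (end - start)
        # a strongly detoured variant: same endpoints, different shape, so
        # QuickBundles puts it in a different cluster
        detour = straight.copy()
        detour[:, 2] += 40.0 * np.sin(np.pi * t[:, 0])
        sls = [straight, detour]
        assert mdf_distance(straight, detour) > CFG.qb_threshold
        assignment, _ = recognize_valid(sls, bundles, CFG)
        cls = classify_invalid(sls, assignment, bundles, CFG)
        assert list(cls.kind) == ["invalid", "invalid"]
        assert len(cls.invalid_pairs) == 1  # merged: one IB, one pair

    def test_short_streamline_is_non_connecting(self, canonical):
        _, _, bundles = canonical
        stub = np.array([[40.0, 40, 40], [41.0, 40, 40], [42.0, 40, 40]])
        assignment, _ = recognize_valid([stub], bundles, CFG)
        cls = classify_invalid([stub], assignment, bundles, CFG)
        assert cls.kind[0] == "non_connecting"

    def test_uncaptured_endpoint_is_non_connecting(self, canonical):
        _, _, bundles = canonical
        # long streamline ending mid-volume, far from any endpoint region
        s = np.column_stack([np.linspace(20, 60, 30),
                             np.full(30, 40.0), np.full(30, 47.0)])
        assignment, _ = recognize_valid([s], bundles, CFG)
        if assignment[0] == -1:
            cls = classify_invalid([s], assignment, bundles, CFG)
            assert cls.kind[0] == "non_connecting"

    def test_partition_property(self, canonical):
        from tractobench.phantom import white_matter_mask
        from tractobench.tracking import TrackingConfig, track
        spec, field, bundles = canonical
        tg = track(field, white_matter_mask(field),
                   TrackingConfig(seeds_per_voxel=1, rng_seed=6))
        assignment, _ = recognize_valid(tg, bundles, CFG)
        cls = classify_invalid(tg, assignment, bundles, CFG)
        kinds = set(cls.kind)
        assert kinds <= {"valid", "invalid", "non_connecting"}
        n_labeled = sum((cls.kind == k).sum() for k in kinds)
        assert n_labeled == len(tg)
        # invalid clusters never carry a ground-truth pair
        gt = {(2 * i, 2 * i + 1) for i in range(len(bundles))}
        assert not (set(cls.invalid_pairs) & gt)


class TestOverlapOverreach:
    def test_reference_streamlines_give_full_overlap_zero_overreach(self, canonical):
        _, _, bundles = canonical
        for b in bundles:
            ol, orr = overlap_overreach(b.reference_streamlines, b, VS)
            assert ol == 100.0 and orr == 0.0

    def test_matches_brute_force_voxel_counting(self, canonical):
        from tractobench.phantom import point_to_voxel, subdivide_polyline
        _, _, bundles = canonical
        b = bundles[2]
        subset = b.reference_streamlines[:5]
        shifted = [s + np.array([0.0, 6.0, 0.0]) for s in subset]
        ol, orr = overlap_overreach(subset + shifted, b, VS)
        visited = set()
        for s in subset + shifted:
            for v in point_to_voxel(subdivide_polyline(s, VS / 4), VS):
                visited.add(tuple(v))
        mask_vox = set(map(tuple, np.argwhere(b.mask)))
        assert ol == pytest.approx(100 * len(visited & mask_vox) / len(mask_vox))
        assert orr == pytest.approx(100 * len(visited - mask_vox) / len(mask_vox))

    def test_no_valid_streamlines_gives_zero_zero(self, canonical):
        _, _, bundles = canonical
        assert overlap_overreach([], bundles[0], VS) == (0.0, 0.0)


class TestStrictVC:
    def test_reference_streamlines_pass(self, canonical):
        _, _, bundles = canonical
        refs = all_refs(bundles)
        assert strict_vc(refs, bundles, VS).all()

    def test_excursion_outside_mask_fails(self, canonical):
        _, _, bundles = canonical
        s = bundles[0].reference_streamlines[0].copy()
        mid = len(s) // 2
        s[mid] = s[mid] + np.array([0.0, 0.0, 10.0])  # leaves the mask briefly
        assert not strict_vc([s], bundles, VS)[0]

    def test_truncated_streamline_fails(self, canonical):
        # fully inside the mask but stopping short of the tail region
        _, _, bundles = canonical
        s = bundles[0].reference_streamlines[0]
        truncated = s[: int(0.7 * len(s))]
        assert not strict_vc([truncated], bundles, VS)[0]


class TestEvaluate:
    def test_identity_evaluation_is_perfect(self, canonical):
        _, _, bundles = canonical
        rep = evaluate(all_refs(bundles), bundles, CFG)
        assert rep.vc_ratio == 100.0
        assert rep.vb_count == len(bundles)
        assert rep.ib_count == 0
        assert rep.recall == 100.0
        assert np.allclose(rep.per_bundle["overlap"], 100.0)
        assert np.allclose(rep.per_bundle["overreach"], 0.0)
        # connectivity matrix holds each bundle's streamlines at its pair
        for i, b in enumerate(bundles):
            assert rep.connectivity_matrix.iloc[2 * i, 2 * i + 1] == \
                len(b.reference_streamlines)

    def test_empty_tractogram_all_zero(self, canonical):
        _, _, bundles = canonical
        rep = evaluate([], bundles, CFG)
        assert rep.vc_ratio == 0.0 and rep.vb_count == 0 and rep.ib_count == 0

    def test_ratio_partition_sums_to_100(self, canonical, rng):
        _, _, bundles = canonical
        sls = all_refs(bundles)[:40]
        sls += [s + rng.normal(0, 8.0, (1, 3)) for s in sls[:10]]
        rep = evaluate(sls, bundles, CFG)
        assert rep.vc_ratio + rep.ic_ratio + rep.nc_ratio == pytest.approx(100.0)

    def test_hand_counted_vc_ratio(self, canonical):
        _, _, bundles = canonical
        a, b = bundles[3], bundles[4]
        valid = (a.reference_streamlines[:4] + b.reference_streamlines[:4])
        start = a.reference_streamlines[0][0]
        end = b.reference_streamlines[0][-1]
        t = np.linspace(0, 1, 20)[:, None]
        bridge = start + t * (end - start)
        invalid = [bridge, bridge + np.array([0.0, 1.0, 0.0])]
        rep = evaluate(valid + invalid, bundles, CFG)
        assert rep.vc_ratio == pytest.approx(80.0)
        assert rep.ib_count == 1

    def test_threshold_monotonicity(self, canonical, rng):
        import copy
        _, _, bundles = canonical
        sls = [b.reference_streamlines[i] + rng.normal(0, 3.0, (1, 3))
               for b in bundles for i in range(0, 20, 4)]
        rep1 = evaluate(sls, bundles, CFG)
        grown = copy.deepcopy(bundles)
        for b in grown:
            b.recognition_threshold *= 2.0
        rep2 = evaluate(sls, grown, CFG)
        assert rep2.vc_ratio >= rep1.vc_ratio
        assert rep2.vb_count >= rep1.vb_count

    def test_precision_recall_specificity_consistency(self, canonical):
        from tractobench.phantom import white_matter_mask
        from tractobench.tracking import TrackingConfig, track
        spec, field, bundles = canonical
        tg = track(field, white_matter_mask(field),
                   TrackingConfig(seeds_per_voxel=1, rng_seed=8))
        rep = evaluate(tg, bundles, CFG)
        vb, ib, n = rep.vb_count, rep.ib_count, rep.n_bundles
        _, pot = count_potential_pairs(n)
        assert rep.precision == pytest.approx(100 * vb / (vb + ib))
        assert rep.recall == pytest.approx(100 * vb / n)
        assert rep.specificity == pytest.approx(100 * (pot - ib) / pot)
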