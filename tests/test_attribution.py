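from collections import Counter
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakmil.attribution import (
    attribute,
    dinuc_shuffle,
    integrated_gradients,
    localization_distances,
    normalize_per_instance,
    top_instance,
)
from peakmil.bagging import AlphabetError, Bag, InstanceConfig, encode_onehot, instance_spans
from peakmil.genomic_datasets import CenteredSiteSequence, MarginSequence


def dimer_counts(seq):
    return Counter(seq[i : i + 2] for i in range(len(seq) - 1))


class TestDinucShuffle:
    def test_homopolymer_unchanged(self, rng):
        assert dinuc_shuffle("AAAA", rng) == "AAAA"

    @given(seq=st.text(alphabet="ACGU", min_size=2, max_size=60))
    @settings(derandomize=True, max_examples=80)
    def test_dimer_table_preserved(self, seq):
        out = dinuc_shuffle(seq, np.random.default_rng(1))
        assert dimer_counts(out) == dimer_counts(seq)

    def test_endpoints_and_monomer_counts_preserved(self, rng):
        seq = "ACGUACGGUUCA"
        out = dinuc_shuffle(seq, rng)
        assert out[0] == seq[0] and out[-1] == seq[-1]
        assert Counter(out) == Counter(seq)

    def test_toy_string_lands_in_enumerated_euler_paths(self):
        seq = "ACGCGT"  # T -> U on ingest
        ref = dimer_counts("ACGCGU")
        valid = {
            "A" + "".join(mid) + "U"
            for mid in permutations("CGCG")
            if dimer_counts("A" + "".join(mid) + "U") == ref
        }
        for s in range(10):
            assert dinuc_shuffle(seq, np.random.default_rng(s)) in valid

    def test_deterministic_given_seed(self):
        seq = "ACGUACGGUUCAACGU"
        a = dinuc_shuffle(seq, np.random.default_rng(3))
        b = dinuc_shuffle(seq, np.random.default_rng(3))
        assert a == b

    def test_rejections(self, rng):
        with pytest.raises(ValueError):
            dinuc_shuffle("A", rng)
        with pytest.raises(AlphabetError):
            dinuc_shuffle("ACGN", rng)


class _LinearStub:
    """F(x) = sum of w (x) over every instance; linear in the input."""

    pooling = "linear"

    def __init__(self, W):
        self.W = W  # (c, 4)

    def forward(self, x, mask, train=False):
        prob = np.array([(x[0] * self.W).sum()])
        return prob, None, {"shape": x.shape}

    def backward(self, cache, dprob):
        dx = np.broadcast_to(self.W, cache["shape"]) * dprob[0]
        return None, dx.copy()


class TestIntegratedGradients:
    def test_linear_model_exact_any_steps(self, rng):
        cfg = InstanceConfig(window_length=10, stride=4, crop_threshold=400, crop_fraction=1.0)
        W = rng.normal(size=(10, 4))
        model = _LinearStub(W)
        L = 26
        x = encode_onehot("".join(rng.choice(list("ACGU"), L)))
        x_ref = encode_onehot("".join(rng.choice(list("ACGU"), L)))
        spans = instance_spans(L, cfg)
        grad = np.zeros((L, 4))
        for a, b in spans:
            grad[a:b] += W
        expected = (x - x_ref) * grad
        for steps in (2, 7, 64):
            amap = integrated_gradients(model, x, x_ref, steps, cfg)
            np.testing.assert_allclose(amap.scores, expected, atol=1e-12)
            # completeness holds exactly for linear F
            assert abs(amap.scores.sum() - (amap.f_x - amap.f_ref_mean)) < 1e-9

    def test_zero_map_when_input_equals_reference(self, toy_model):
        model, cfg = toy_model["model"], toy_model["inst_cfg"]
        bag = toy_model["test_bags"][0]
        x = encode_onehot(bag.sequence)
        amap = integrated_gradients(model, x, x.copy(), 16, cfg)
        assert np.all(amap.scores == 0)

    def test_too_few_steps_rejected(self, toy_model):
        x = encode_onehot("ACGU" * 20)
        with pytest.raises(ValueError, match="steps"):
            integrated_gradients(toy_model["model"], x, x, 1, toy_model["inst_cfg"])

    def test_completeness_error_shrinks_with_steps(self, confident_attribution_case):
        case = confident_attribution_case
        errs = {}
        for m in (4, 16, 64, 256):
            amap = integrated_gradients(
                case["model"], case["x"], case["x_ref"], m, case["inst_cfg"]
            )
            diff = amap.f_x - amap.f_ref_mean
            errs[m] = abs(amap.scores.sum() - diff) / max(abs(diff), 1e-12)
        # piecewise-linear activations make the error oscillate at O(1/m);
        # compare widely separated step counts
        assert errs[64] < errs[4]
        assert errs[256] < errs[16]


class TestAttribute:
    def test_single_reference_reduces_to_integrated_gradients(self, toy_model):
        model, cfg = toy_model["model"], toy_model["inst_cfg"]
        bag = toy_model["test_bags"][0]
        x = encode_onehot(bag.sequence)
        ref_seq = dinuc_shuffle(bag.sequence, np.random.default_rng(0))
        single = integrated_gradients(model, x, encode_onehot(ref_seq), 8, cfg)
        avg = attribute(model, bag, cfg, n_refs=1, steps=8, rng=np.random.default_rng(0))
        np.testing.assert_allclose(avg.scores, single.scores, atol=1e-12)

    @pytest.mark.parametrize("reference", ["zero", "frequency"])
    def test_alternative_references_give_finite_maps(self, toy_model, reference):
        model, cfg = toy_model["model"], toy_model["inst_cfg"]
        bag = toy_model["test_bags"][0]
        amap = attribute(model, bag, cfg, steps=8, reference=reference)
        assert np.isfinite(amap.scores).all()
        assert amap.n_refs == 1

    def test_reference_averaging_stabilizes(self, toy_model):
        model, cfg = toy_model["model"], toy_model["inst_cfg"]
        bag = min(toy_model["test_bags"], key=len)
        x = encode_onehot(bag.sequence)
        rng = np.random.default_rng(5)
        maps = [
            integrated_gradients(
                model, x, encode_onehot(dinuc_shuffle(bag.sequence, rng)), 8, cfg
            ).scores
            for _ in range(20)
        ]
        mean10 = np.mean(maps[:10], axis=0)
        mean20 = np.mean(maps, axis=0)
        sd = np.std(maps, axis=0)
        assert np.linalg.norm(mean20 - mean10) <= 2 * np.linalg.norm(sd) / np.sqrt(10)


class TestNormalizePerInstance:
    def test_max_abs_scaling(self):
        out = normalize_per_instance(np.array([2.0, -1.0]), [(0, 2)])
        assert out.tolist() == [[1.0, -0.5]]

    def test_all_zero_span_left_zero(self):
        out = normalize_per_instance(np.zeros(4), [(0, 2), (2, 4)])
        assert np.all(out == 0)

    def test_idempotent(self, rng):
        collapsed = rng.normal(size=30)
        spans = [(0, 10), (5, 15), (20, 30)]
        once = normalize_per_instance(collapsed, spans)
        twice = np.stack(
            [normalize_per_instance(once[k], [(0, 10)])[0] for k in range(len(spans))]
        )
        np.testing.assert_allclose(once, twice, atol=1e-12)


class TestTopInstance:
    def test_argmax(self):
        res = top_instance(np.array([0.1, 0.7, 0.2]), [(0, 50), (10, 60), (20, 70)])
        assert res.top_instance_index == 1 and res.top_span == (10, 60)

    def test_tie_broken_to_smallest_start(self):
        res = top_instance(np.array([0.5, 0.5]), [(0, 50), (10, 60)])
        assert res.top_instance_index == 0 and res.tie_broken

    def test_masked_instance_never_selected(self):
        res = top_instance(
            np.array([0.2, 0.9, 0.3]), [(0, 50), (10, 60), (20, 70)], mask=np.array([1, 0, 1])
        )
        assert res.top_instance_index == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_instance(np.array([]), [])


class _FixedAttentionModel:
    """Predicts a fixed probability and peaks attention at a fixed instance."""

    def __init__(self, prob, top_idx):
        self.prob, self.top_idx = prob, top_idx

    def predict(self, x, mask):
        K = x.shape[1]
        w = np.full((1, K), 0.1 / max(K - 1, 1))
        w[0, self.top_idx] = 0.9
        return np.array([self.prob]), w


class TestLocalizationDistances:
    cfg = InstanceConfig(window_length=50, stride=10)

    def test_centered_distance_arithmetic(self, rng):
        # top span (280, 330) on a 601-nt sequence: center 305, site 300 -> +5
        item = CenteredSiteSequence("".join(rng.choice(list("ACGU"), 601)), 300, "s1")
        summary = localization_distances(_FixedAttentionModel(0.9, 28), [item], self.cfg)
        (res,) = summary.results
        assert res.top_span == (280, 330)
        assert res.distance_to_reference_point == 5.0
        assert res.contains_reference

    def test_predicted_negative_excluded(self, rng):
        item = CenteredSiteSequence("".join(rng.choice(list("ACGU"), 601)), 300, "s1")
        summary = localization_distances(_FixedAttentionModel(0.3, 28), [item], self.cfg)
        assert summary.n_predicted_positive == 0 and summary.results == []

    def test_margin_correct_side(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 600))
        item = MarginSequence(seq, "five_prime", "second", "p1", None)
        # top span (300, 350) lies wholly in the second half -> correct side
        summary = localization_distances(_FixedAttentionModel(0.9, 30), [item], self.cfg)
        assert summary.results[0].correct_side is True
        assert summary.frac_correct_side == 1.0

    def test_margin_wrong_side(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 600))
        item = MarginSequence(seq, "three_prime", "first", "p1", None)
        summary = localization_distances(_FixedAttentionModel(0.9, 30), [item], self.cfg)
        assert summary.results[0].correct_side is False

    def test_mode_of_distance_histogram(self, rng):
        items = [
            CenteredSiteSequence("".join(rng.choice(list("ACGU"), 601)), 300, f"s{i}")
            for i in range(5)
        ]
        summary = localization_distances(_FixedAttentionModel(0.9, 28), items, self.cfg)
        assert summary.mode_distance == pytest.approx(5.0, abs=5.0)

    def test_attribution_larger_in_top_than_bottom_instance(self, e2e_run):
        """Predicted positives attribute more signal to the top-attention
        instance than to the lowest-weight one (majority over bags)."""
        from peakmil.bagging import make_instances
        from peakmil.synthetic_data import SyntheticSpec, make_centered_eval

        model = e2e_run["model"]
        cfg = InstanceConfig()
        centered = make_centered_eval(e2e_run["truth"], SyntheticSpec(seed=42))
        rng = np.random.default_rng(0)
        wins = total = 0
        for item in centered[:12]:
            bag = Bag(id=item.site_id, sequence=item.sequence, label=1)
            iset = make_instances(bag, cfg)
            prob, w = model.predict(iset.instances[None], iset.mask[None])
            if prob[0] < 0.5:
                continue
            amap = attribute(model, bag, cfg, n_refs=5, steps=10, rng=rng)
            hi, lo = int(np.argmax(w[0])), int(np.argmin(w[0]))
            a, b = iset.spans[hi]
            c, d = iset.spans[lo]
            wins += np.abs(amap.collapsed[a:b]).mean() > np.abs(amap.collapsed[c:d]).mean()
            total += 1
        assert total >= 8
        assert wins / total >= 0.7
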