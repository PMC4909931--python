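import numpy as np
import pytest
from hypothesis import given, strategies as st

from spinex import aggregate_replicates, control_check, differential, normalize
from spinex.shape import ARTIFACT_FLAG, CONTROL_FLAG, REFERENCE_FLAG, ShapeProfile
from spinex.synth import default_structure_states, generate_shape_dataset


def profile(reactivities, sem=None, flags=None, label="a", normalized=False):
    n = len(reactivities)
    annotations = flags if flags is not None else [frozenset()] * n
    return ShapeProfile(
        positions=np.arange(1, n + 1),
        reactivities=np.asarray(reactivities, dtype=float),
        sem=None if sem is None else np.asarray(sem, dtype=float),
        annotations=annotations,
        condition_label=label,
        normalized=normalized,
    )


class TestAggregation:
    def test_identical_replicates_have_zero_sem(self):
        agg = aggregate_replicates([profile([1.0, 0.5, 2.0])] * 3)
        assert np.allclose(agg.sem, 0.0)
        assert np.allclose(agg.reactivities, [1.0, 0.5, 2.0])

    def test_two_replicates_hand_arithmetic(self):
        agg = aggregate_replicates([profile([0.8]), profile([1.2])])
        assert agg.reactivities[0] == pytest.approx(1.0)
        assert agg.sem[0] == pytest.approx(0.2)

    def test_three_replicates_hand_arithmetic(self):
        agg = aggregate_replicates([profile([1.0]), profile([2.0]), profile([3.0])])
        assert agg.reactivities[0] == pytest.approx(2.0)
        assert agg.sem[0] == pytest.approx(0.5774, abs=1e-4)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            aggregate_replicates([profile([1.0])])


class TestNormalization:
    def test_divides_by_reference_mean(self):
        flags = [frozenset(), frozenset([REFERENCE_FLAG]), frozenset([REFERENCE_FLAG])]
        p = profile([1.0, 1.5, 2.5], sem=[0.2, 0.1, 0.1], flags=flags)
        norm = normalize(p)
        assert norm.reactivities[0] == pytest.approx(0.5)
        assert norm.sem[0] == pytest.approx(0.1)
        assert norm.normalized

    def test_idempotent(self):
        flags = [frozenset([REFERENCE_FLAG])] * 3
        p = profile([0.5, 1.0, 1.5], sem=[0.1, 0.1, 0.1], flags=flags)
        once = normalize(p)
        twice = normalize(once)
        assert np.allclose(once.reactivities, twice.reactivities)

    @given(st.floats(0.01, 100.0))
    def test_scale_invariant(self, scale):
        flags = [frozenset(), frozenset([REFERENCE_FLAG]), frozenset([REFERENCE_FLAG])]
        base = np.array([1.0, 1.5, 2.5])
        a = normalize(profile(base, flags=flags))
        b = normalize(profile(scale * base, flags=flags))
        assert np.allclose(a.reactivities, b.reactivities, rtol=1e-12)

    def test_negative_reactivities_floored_and_counted(self):
        flags = [frozenset(), frozenset([REFERENCE_FLAG]), frozenset([REFERENCE_FLAG])]
        with pytest.warns(UserWarning, match="floored 1"):
            norm = normalize(profile([-0.3, 1.0, 1.0], flags=flags))
        assert norm.reactivities[0] == 0.0
        assert norm.n_floored == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            normalize(profile([1.0, 2.0]))

    def test_explicit_reference_positions(self):
        norm = normalize(profile([1.0, 2.0, 3.0]), reference_positions=[2, 3])
        assert norm.reactivities[0] == pytest.approx(0.4)


class TestControlCheck:
    def make_annotated(self, control_value):
        flags = (
            [frozenset([CONTROL_FLAG])] * 2
            + [frozenset()]
            + [frozenset([REFERENCE_FLAG])] * 2
        )
        return profile([control_value, control_value, 0.3, 1.0, 1.0], flags=flags, normalized=True)

    def test_matched_control_gives_unity(self):
        chk = control_check(self.make_annotated(1.0))
        assert chk.ratio == pytest.approx(1.0)
        assert chk.passed

    def test_depressed_control_warns_outside_band(self):
        with pytest.warns(UserWarning, match="outside"):
            chk = control_check(self.make_annotated(0.5))
        assert not chk.passed

    def test_ratio_equals_control_mean_after_normalization(self):
        flags = (
            [frozenset([CONTROL_FLAG])] * 2
            + [frozenset()]
            + [frozenset([REFERENCE_FLAG])] * 3
        )
        raw = profile([1.9, 1.94, 0.6, 2.1, 1.9, 2.0], flags=flags)
        norm = normalize(raw)
        chk = control_check(norm)
        assert chk.ratio == pytest.approx(float(np.mean(norm.reactivities[:2])), rel=1e-12)

    def test_missing_annotations_rejected(self):
        with pytest.raises(ValueError, match="annotations"):
            control_check(profile([1.0, 1.0], normalized=True))


class TestDifferential:
    def paired(self, a_vals, b_vals, sem=0.1, flags=None):
        n = len(a_vals)
        f = flags if flags is not None else [frozenset()] * n
        a = profile(a_vals, sem=[sem] * n, flags=f, label="A", normalized=True)
        b = profile(b_vals, sem=[sem] * n, flags=f, label="B", normalized=True)
        return a, b

    def test_identical_profiles_give_zero(self):
        a, b = self.paired([0.5, 1.0], [0.5, 1.0])
        d = differential(a, b)
        assert np.allclose(d.delta, 0.0)

    def test_quadrature_error_propagation(self):
        a, b = self.paired([0.8], [0.3])
        d = differential(a, b)
        assert d.delta[0] == pytest.approx(0.5)
        assert d.sigma[0] == pytest.approx(np.sqrt(0.02), abs=1e-6)  # 0.1414

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        vals_a, vals_b = rng.uniform(0, 2, 10), rng.uniform(0, 2, 10)
        a, b = self.paired(vals_a, vals_b)
        ab = differential(a, b)
        ba = differential(b, a)
        assert np.allclose(ab.delta, -ba.delta)
        assert np.allclose(ab.sigma, ba.sigma)

    def test_artifact_positions_flagged_not_dropped(self):
        flags = [frozenset(), frozenset([ARTIFACT_FLAG])]
        a, b = self.paired([0.5, 1.5], [0.4, 0.2], flags=flags)
        d = differential(a, b)
        assert list(d.caveat) == [False, True]
        assert len(d.delta) == 2

    def test_unnormalized_profiles_rejected(self):
        a = profile([1.0], sem=[0.1], normalized=False)
        b = profile([1.0], sem=[0.1], normalized=True)
        with pytest.raises(ValueError, match="normalized"):
            differential(a, b)


class TestGeneratorGroundTruth:
    def test_register_shift_positions_dominate_differential(self):
        states = default_structure_states()
        data = generate_shape_dataset(states, replicates=3, seed=42)
        norm = {
            lbl: normalize(aggregate_replicates(reps)) for lbl, reps in data.items()
        }
        d = differential(norm["condition_b"], norm["condition_a"])
        core_start = len(d.positions) - len(states["condition_a"]) - 10
        flips_up = [
            core_start + j
            for j, (sa, sb) in enumerate(zip(states["condition_a"], states["condition_b"]))
            if sa == "p" and sb == "u"
        ]
        expected_up = np.zeros(len(d.positions), dtype=bool)
        expected_up[flips_up] = True
        # the positions that become unpaired must top the positive ranking
        top = np.argsort(d.delta)[-len(flips_up):]
        assert set(top) == set(np.flatnonzero(expected_up))

    def test_identical_states_give_null_differential(self):
        states = {"x": "ppppuuuu", "y": "ppppuuuu"}
        data = generate_shape_dataset(states, replicates=3, seed=7)
        norm = {lbl: normalize(aggregate_replicates(reps)) for lbl, reps in data.items()}
        d = differential(norm["x"], norm["y"])
        assert np.abs(np.mean(d.delta)) < 0.05
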