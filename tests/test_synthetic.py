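import numpy as np
import pytest

from cytobool import binarize as B
from cytobool import fitting as F
from cytobool.network import BooleanNetwork, BoolRule
from cytobool.synthetic import (
    DESIGN_TIMES,
    ShapeKernel,
    SyntheticDesign,
    default_kernels,
    generate_ground_truth_bn,
    render_panel,
    shape_value,
)


class TestShapeKernels:
    @pytest.mark.parametrize(
        "kernel,t,expected",
        [
            (ShapeKernel("promotion", c=10), 0.0, 0.0),
            (ShapeKernel("promotion", c=10), 1.0, 5.0),
            (ShapeKernel("inhibition", c=10, bias=2), 1e9, pytest.approx(2.0)),
        ],
    )
    def test_values(self, kernel, t, expected):
        assert shape_value(kernel, t) == expected

    def test_promotion_nondecreasing_inhibition_nonincreasing(self):
        t = np.linspace(0, 24, 200)
        promo = shape_value(ShapeKernel("promotion", c=7), t)
        inhib = shape_value(ShapeKernel("inhibition", c=7, bias=1), t)
        assert np.all(np.diff(promo) >= 0)
        assert np.all(np.diff(inhib) <= 0)
        assert np.all(promo >= 0) and np.all(inhib >= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ShapeKernel("promotion", c=-1)
        with pytest.raises(ValueError):
            ShapeKernel("bell", c=1, width=0)
        with pytest.raises(ValueError):
            shape_value(ShapeKernel("promotion", c=1), -0.5)


class TestGroundTruthGenerator:
    def test_single_node_is_self_copy(self):
        bn = generate_ground_truth_bn(1)
        assert bn.step((0,)) == (0,) and bn.step((1,)) == (1,)

    def test_seed_determinism(self):
        a = generate_ground_truth_bn(6, 3, seed=42)
        b = generate_ground_truth_bn(6, 3, seed=42)
        assert a == b
        c = generate_ground_truth_bn(6, 3, seed=43)
        assert a != c

    def test_rules_match_bruteforce_over_all_states(self):
        bn = generate_ground_truth_bn(3, 2, seed=5)
        pos = {n: i for i, n in enumerate(bn.nodes)}
        for r in range(8):
            state = tuple((r >> (2 - i)) & 1 for i in range(3))
            nxt = bn.step(state)
            for i, nd in enumerate(bn.nodes):
                rule = bn.rules[nd]
                expect = rule([state[pos[p]] for p in rule.parents])
                assert nxt[i] == expect

    def test_rules_nonconstant_and_within_parent_budget(self):
        for seed in range(5):
            bn = generate_ground_truth_bn(7, 3, seed=seed)
            for nd in bn.nodes:
                rule = bn.rules[nd]
                assert not rule.is_constant()
                assert 1 <= len(rule.parents) <= 3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_ground_truth_bn(12)
        with pytest.raises(ValueError):
            generate_ground_truth_bn(0)


class TestRenderPanel:
    def test_default_design_shape(self, ring5):
        design = SyntheticDesign(proteins=ring5.nodes, seed=1)
        panel = render_panel(ring5, default_kernels(ring5.nodes), design)
        assert tuple(sorted(panel.data["time_h"].unique())) == DESIGN_TIMES
        assert panel.data["replicate"].nunique() == 4
        counts = panel.data.groupby(["protein", "group"]).size()
        assert (counts == 7 * 4).all()
        assert panel.check_complete() == []
        assert (panel.data["value"] >= 0).all()

    def test_seed_determinism(self, ring5):
        k = default_kernels(ring5.nodes)
        d = SyntheticDesign(proteins=ring5.nodes, seed=9)
        p1 = render_panel(ring5, k, d)
        p2 = render_panel(ring5, k, d)
        assert p1.data.equals(p2.data)

    def test_control_group_is_constant_low(self, ring5):
        d = SyntheticDesign(proteins=ring5.nodes, seed=2, noise_sigma=0.0)
        panel = render_panel(ring5, default_kernels(ring5.nodes), d)
        for nd in ring5.nodes:
            assert set(panel.truth["control"][nd]) == {0}

    def test_overlapping_kernels_flagged(self, ring5):
        kernels = {
            nd: (
                ShapeKernel("inhibition", c=20, bias=5),
                ShapeKernel("inhibition", c=20, bias=10),  # overlaps low
            )
            for nd in ring5.nodes
        }
        d = SyntheticDesign(proteins=ring5.nodes, seed=3)
        panel = render_panel(ring5, kernels, d)
        assert len(panel.warnings) == len(ring5.nodes)

    def test_constant_low_node_never_crosses_high_threshold(self, grid):
        # a node clamped low renders as a decaying (inhibition-like) profile
        bn = BooleanNetwork(
            {"lo": BoolRule.constant(0), "other": BoolRule.identity("other")}
        )
        d = SyntheticDesign(
            proteins=bn.nodes,
            times=tuple(grid.times),
            groups=("LPS",),
            noise_sigma=0.0,
            seed=4,
        )
        kernels = default_kernels(bn.nodes)
        panel = render_panel(bn, kernels, d, initial_states={"LPS": (0, 1)})
        vals = panel.values("lo", "LPS")["value"].to_numpy()
        hi_min = kernels["lo"][1].range_over(24.0)[0]
        assert np.all(vals < hi_min)
        fit = F.fit_smoothing_spline(
            np.asarray(sorted(set(panel.values("lo", "LPS")["time_h"]))),
            panel.values("lo", "LPS").groupby("time_h")["value"].mean().to_numpy(),
            p=1.0,
        )
        label = F.classify_shape(F.resample(fit, grid), 24.0, grid).label
        assert label in ("inhibition", "bell")


class TestRoundTrip:
    def test_zero_noise_binarization_recovers_boolean_course(
        self, ring5, ring5_panel, grid
    ):
        """fit -> resample -> binarize reproduces the ground truth at every
        one of the 50 grid points when noise is zero and kernels are
        separated."""
        for nd in ring5.nodes:
            sub = ring5_panel.values(nd, "LPS")
            times = np.asarray(sorted(sub["time_h"].unique()))
            avg = sub.groupby("time_h")["value"].mean().reindex(times).to_numpy()
            fit = F.fit_smoothing_spline(times, avg, p=1.0)
            series = F.resample(fit, grid)
            thr = B.iterative_kmeans_threshold(series)
            bits = B.binarize(series, thr).bits
            assert bits == ring5_panel.truth["LPS"][nd]

    def test_noise_monotonicity_of_mismatches(self, grid):
        """More replicate noise never reduces the expected number of
        binarization mismatches (checked over 20 seeds, non-strict)."""
        rules = {
            "N1": BoolRule.from_sop(["N3"], [(("N3", True),)]),
            "N2": BoolRule.from_sop(["N1"], [(("N1", False),)]),
            "N3": BoolRule.from_sop(["N2"], [(("N2", False),)]),
        }
        bn = BooleanNetwork(rules)

        def mean_mismatches(sigma):
            total = 0
            for seed in range(20):
                d = SyntheticDesign(
                    proteins=bn.nodes,
                    times=tuple(grid.times),
                    replicates=2,
                    groups=("LPS",),
                    noise_sigma=sigma,
                    seed=seed,
                )
                panel = render_panel(bn, default_kernels(bn.nodes), d)
                for nd in bn.nodes:
                    sub = panel.values(nd, "LPS")
                    times = np.asarray(sorted(sub["time_h"].unique()))
                    avg = (
                        sub.groupby("time_h")["value"].mean().reindex(times).to_numpy()
                    )
                    fit = F.fit_smoothing_spline(times, avg, p=1.0)
                    series = F.resample(fit, grid)
                    bits = B.binarize(
                        series, B.iterative_kmeans_threshold(series)
                    ).bits
                    total += sum(
                        b != t for b, t in zip(bits, panel.truth["LPS"][nd])
                    )
            return total / 20.0

        rates = [mean_mismatches(s) for s in (0.0, 0.1, 0.3, 0.6)]
        assert all(a <= b + 1e-9 for a, b in zip(rates, rates[1:]))
        assert rates[0] == 0.0
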