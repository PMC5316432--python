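"""Fuzzy variables, grid partition, and Sugeno inference.

The inference oracle here is deliberately independent of the package's
vectorized path: it loops over rules in plain Python, evaluating each
membership degree from the closed forms with ``math`` functions.
"""

import json
import math

import numpy as np
import pytest

from fuzzybase import (
    ConfigurationError,
    SugenoFIS,
    ValidationError,
    grid_partition,
    make_variable,
)
from conftest import random_fis


def _degree(family, params, x):
    if family == "triangular":
        a, b, c = params
        if x <= a or x >= c:
            return 1.0 if (a == b == x or b == c == x) else 0.0
        left = (x - a) / (b - a) if b > a else 1.0
        right = (c - x) / (c - b) if c > b else 1.0
        return max(0.0, min(left, right, 1.0))
    if family == "trapezoidal":
        a, b, c, d = params
        if x <= a and a < b:
            return 0.0
        if x >= d and c < d:
            return 0.0
        left = (x - a) / (b - a) if b > a else 1.0
        right = (d - x) / (d - c) if d > c else 1.0
        return max(0.0, min(left, 1.0, right))
    s1, c1, s2, c2 = params
    if x < c1:
        return math.exp(-((x - c1) ** 2) / (2 * s1 * s1))
    if x > c2:
        return math.exp(-((x - c2) ** 2) / (2 * s2 * s2))
    return 1.0


def oracle_infer(fis, x):
    """Brute-force rule enumeration with scalar math."""
    num = 0.0
    den = 0.0
    for rule in fis.rules:
        degrees = [
            _degree(var.mfs[idx].family, var.mfs[idx].params, x[j])
            for j, (var, idx) in enumerate(zip(fis.inputs, rule.antecedent))
        ]
        w = math.prod(degrees) if fis.tnorm == "product" else min(degrees)
        num += w * rule.consequent
        den += w
    return num / den


class TestMakeVariable:
    def test_five_triangular_apexes(self):
        var = make_variable("NP_called", (0.0, 1.0), 5, "triangular")
        apexes = [mf.params[1] for mf in var.mfs]
        np.testing.assert_allclose(apexes, [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_two_point_partition(self):
        var = make_variable("x", (0.0, 1.0), 2, "triangular")
        assert [mf.params[1] for mf in var.mfs] == [0.0, 1.0]

    def test_too_few_mfs(self):
        with pytest.raises(ConfigurationError):
            make_variable("x", (0.0, 1.0), 1, "triangular")

    @pytest.mark.parametrize("family", ["triangular", "trapezoidal", "gauss2"])
    @pytest.mark.parametrize("n_mfs", [2, 3, 5, 7])
    def test_full_coverage(self, family, n_mfs):
        var = make_variable("x", (0.0, 1.0), n_mfs, family)
        grid = np.linspace(0.0, 1.0, 1001)
        max_degree = var.memberships(grid).max(axis=1)
        assert max_degree.min() > 0.0

    @pytest.mark.parametrize("family", ["triangular", "trapezoidal", "gauss2"])
    def test_centers_strictly_increasing(self, family):
        var = make_variable("x", (0.0, 1.0), 5, family)
        centers = [mf.center for mf in var.mfs]
        assert all(a < b for a, b in zip(centers, centers[1:]))


class TestGridPartition:
    @pytest.mark.parametrize(
        "n_inputs,n_mfs,expected", [(2, 5, 25), (3, 5, 125), (1, 2, 2), (2, 3, 9)]
    )
    def test_rule_count_is_full_factorial(self, n_inputs, n_mfs, expected):
        variables = [make_variable(f"x{j}", n_mfs=n_mfs) for j in range(n_inputs)]
        fis = grid_partition(variables)
        assert fis.n_rules == expected

    def test_antecedents_unique(self):
        fis = grid_partition([make_variable(f"x{j}", n_mfs=3) for j in range(3)])
        combos = {tuple(a) for a in fis.antecedents}
        assert len(combos) == fis.n_rules

    def test_no_variables(self):
        with pytest.raises(ConfigurationError):
            grid_partition([])


class TestInference:
    def test_constant_consequents(self, rng):
        fis = grid_partition([make_variable(f"x{j}", n_mfs=5) for j in range(2)], consequent=0.7)
        for x in rng.uniform(0, 1, (20, 2)):
            assert fis.infer(x) == pytest.approx(0.7)

    def test_single_active_rule_at_apex(self):
        fis = grid_partition([make_variable("x", n_mfs=5, family="triangular")])
        fis.consequents = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        # at an apex only that MF fires, so the output is that rule's consequent
        for k, apex in enumerate([0.0, 0.25, 0.5, 0.75, 1.0]):
            assert fis.infer([apex]) == pytest.approx(fis.consequents[k])

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(20):
            n_inputs = int(rng.integers(1, 4))
            n_mfs = int(rng.integers(2, 6))
            fis = random_fis(rng, n_inputs, n_mfs)
            X = rng.uniform(0, 1, (100, n_inputs))
            got = fis.infer_batch(X)
            want = [oracle_infer(fis, x) for x in X]
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_min_tnorm_agrees_with_oracle(self, rng):
        fis = random_fis(rng, 2, 3)
        fis.tnorm = "min"
        X = rng.uniform(0, 1, (50, 2))
        np.testing.assert_allclose(
            fis.infer_batch(X), [oracle_infer(fis, x) for x in X], atol=1e-12
        )

    def test_output_bounded_by_consequents(self, rng):
        for _ in range(10):
            fis = random_fis(rng, 2, 4)
            out = fis.infer_batch(rng.uniform(0, 1, (200, 2)))
            assert np.all(out >= fis.consequents.min() - 1e-12)
            assert np.all(out <= fis.consequents.max() + 1e-12)

    def test_continuity_on_grid(self, rng):
        fis = random_fis(rng, 1, 5)
        x = np.linspace(0, 1, 5001).reshape(-1, 1)
        out = fis.infer_batch(x)
        assert np.abs(np.diff(out)).max() < 0.01

    def test_out_of_domain_inputs_clipped_with_warning(self, rng, caplog):
        fis = random_fis(rng, 2, 3)
        with caplog.at_level("WARNING", logger="fuzzybase.fis"):
            out = fis.infer([1.5, -0.2])
        assert any("clipped" in r.message for r in caplog.records)
        assert out == pytest.approx(fis.infer([1.0, 0.0]))

    def test_dimension_mismatch(self, rng):
        fis = random_fis(rng, 2, 3)
        with pytest.raises(ValidationError):
            fis.infer([0.5])

    def test_degenerate_firing_guarded(self, caplog):
        # a variable with a coverage hole: single narrow triangular MF pair
        from fuzzybase import FuzzyVariable, MembershipFunction

        var = FuzzyVariable(
            "x",
            (0.0, 1.0),
            [
                MembershipFunction("triangular", (0.0, 0.05, 0.1)),
                MembershipFunction("triangular", (0.9, 0.95, 1.0)),
            ],
        )
        fis = grid_partition([var], consequent=0.5)
        with caplog.at_level("WARNING", logger="fuzzybase.fis"):
            out = fis.infer([0.5])
        assert any("fired no rule" in r.message for r in caplog.records)
        assert np.isfinite(out)


class TestSerialization:
    def test_round_trip_is_bit_faithful(self, rng):
        fis = random_fis(rng, 2, 5, jitter=0.013)
        doc = fis.to_json()
        back = SugenoFIS.from_json(doc)
        assert back.to_json() == doc
        for v1, v2 in zip(fis.inputs, back.inputs):
            for m1, m2 in zip(v1.mfs, v2.mfs):
                assert m1.params == m2.params  # exact float equality
        np.testing.assert_array_equal(fis.consequents, back.consequents)

    def test_round_trip_preserves_inference(self, rng):
        fis = random_fis(rng, 3, 3, jitter=0.01)
        back = SugenoFIS.from_json(fis.to_json())
        X = rng.uniform(0, 1, (50, 3))
        np.testing.assert_allclose(fis.infer_batch(X), back.infer_batch(X), atol=0, rtol=0)

    def test_document_structure(self, rng):
        doc = json.loads(random_fis(rng, 2, 3).to_json())
        assert set(doc) == {"inputs", "rules", "tnorm"}
        assert set(doc["inputs"][0]) == {"name", "domain", "mfs"}
        assert set(doc["rules"][0]) == {"antecedent", "consequent"}
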