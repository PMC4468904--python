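"""MetChange LPs, standardization and aggregation rules."""

import io

import numpy as np
import pandas as pd
import pytest

from metchange.expression import GeneProfile, ReactionPenalty, map_gene_pvals
from metchange.io import read_reaction_table
from metchange.network import MediaSpec, apply_media, make_irreversible
from metchange.scoring import (
    MetChangeModel,
    collapse_compartments,
    consensus_across_cell_lines,
    drug_response,
    longitudinal_log2_scores,
    standardize_columns,
    standardized_scores,
)


def _penalty(net, mapping):
    base = {r: 0.0 for r in net.reaction_ids}
    base.update(mapping)
    return ReactionPenalty("s", base)


class TestMaxProduction:
    def test_unit_chain(self, toy3_irrev):
        model = MetChangeModel(toy3_irrev)
        assert model.max_production("C_c") == pytest.approx(1.0, abs=1e-9)

    def test_stoichiometric_halving(self):
        table = (
            "EX_A\tA_e <=> \t-1000\t1000\t\n"
            "T_A\tA_e -> A_c\t0\t1000\tg1\n"
            "R1\t2 A_c -> B_c\t0\t1000\tg2\n"
        )
        net = read_reaction_table(io.StringIO(table))
        constrained, _ = apply_media(net, MediaSpec.of(["A_e"], 1.0))
        model = MetChangeModel(make_irreversible(constrained))
        assert model.max_production("B_c") == pytest.approx(0.5, abs=1e-9)

    def test_unproducible_under_media_flagged(self, toy3):
        # closed medium: no uptake, nothing producible, vmax pinned at 0
        closed, _ = apply_media(toy3, MediaSpec.of([]))
        cap = MetChangeModel(make_irreversible(closed)).production_capability()
        assert cap.non_producible == set(toy3.metabolite_ids)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in cap.vmax.values())


class TestConsistencyScore:
    def test_zero_penalties_give_zero(self, toy3_irrev):
        model = MetChangeModel(toy3_irrev)
        x = model.consistency_score("C_c", _penalty(toy3_irrev, {}))
        assert x == pytest.approx(0.0, abs=1e-9)

    def test_forced_route_sums_penalties(self, toy3_irrev):
        """The only route to C_c carries all three penalized reactions at
        unit flux, so x = 0.2 + 0.5 + 0.1."""
        model = MetChangeModel(toy3_irrev)
        pen = _penalty(toy3_irrev, {"T_A": 0.2, "R1": 0.5, "R2": 0.1})
        x = model.consistency_score("C_c", pen)
        assert x == pytest.approx(0.8, rel=1e-5)

    def test_parallel_routes_pick_cheaper(self, parallel_net):
        model = MetChangeModel(parallel_net)
        pen = _penalty(parallel_net, {"R2a": 0.9, "R2b": 0.1})
        x = model.consistency_score("C_c", pen)
        assert x == pytest.approx(0.1, rel=1e-5)

    def test_zero_penalty_route_gives_zero(self, parallel_net):
        """A zero-penalty optimal route exists (through R2b), so the
        minimal inconsistency is 0 despite the other route's penalty."""
        model = MetChangeModel(parallel_net)
        pen = _penalty(parallel_net, {"R2a": 0.9})
        assert model.consistency_score("C_c", pen) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_each_penalty(self, parallel_net, rng):
        model = MetChangeModel(parallel_net)
        internal = [r for r in parallel_net.reaction_ids if not r.startswith("EX")]
        base = {r: float(p) for r, p in zip(internal, rng.uniform(0, 0.5, len(internal)))}
        x0 = model.consistency_score("C_c", _penalty(parallel_net, base))
        for r in internal:
            bumped = dict(base)
            bumped[r] = min(1.0, bumped[r] + 0.3)
            x1 = model.consistency_score("C_c", _penalty(parallel_net, bumped))
            assert x1 >= x0 - 1e-9

    def test_objective_reproducible_across_restarts(self, parallel_net):
        pen = _penalty(parallel_net, {"T_A": 0.3, "R1": 0.2, "R2a": 0.5, "R2b": 0.5})
        vals = [
            MetChangeModel(parallel_net).consistency_score("C_c", pen)
            for _ in range(3)
        ]
        assert max(vals) - min(vals) < 1e-6

    def test_nonproducible_raises(self, toy3_irrev):
        closed, _ = apply_media(toy3_irrev, MediaSpec.of([]))
        model = MetChangeModel(closed)
        with pytest.raises(Exception, match="non-producible"):
            model.consistency_score("C_c", _penalty(closed, {}))


class TestStandardizedScores:
    def _scores(self, rows):
        return pd.DataFrame(rows).T.rename_axis(None)

    def test_arithmetic(self):
        scores = pd.DataFrame(
            {"m": [2.0, 0.5, 1.5]}, index=["t1", "c1", "c2"]
        )
        meta = pd.DataFrame(
            {"batch": ["b1"] * 3, "is_control": [False, True, True]},
            index=["t1", "c1", "c2"],
        )
        z = standardized_scores(scores, meta)
        # control mean 1.0, sd (n-1) of {0.5, 1.5} = 0.7071...
        assert z.loc["t1", "m"] == pytest.approx((2.0 - 1.0) / np.std([0.5, 1.5], ddof=1))

    def test_treated_equal_to_control_mean_is_zero(self):
        scores = pd.DataFrame({"m": [1.0, 0.5, 1.5]}, index=["t1", "c1", "c2"])
        meta = pd.DataFrame(
            {"batch": ["b1"] * 3, "is_control": [False, True, True]},
            index=["t1", "c1", "c2"],
        )
        assert standardized_scores(scores, meta).loc["t1", "m"] == pytest.approx(0.0)

    def test_single_control_batch_uses_global_pool(self):
        scores = pd.DataFrame(
            {"m": [3.0, 1.0, 1.0, 2.0, 4.0]},
            index=["t1", "c1", "c2", "c3", "c4"],
        )
        meta = pd.DataFrame(
            {
                "batch": ["b1", "b1", "b2", "b2", "b2"],
                "is_control": [False, True, True, True, True],
            },
            index=scores.index,
        )
        z = standardized_scores(scores, meta)
        pool = scores.loc[["c1", "c2", "c3", "c4"], "m"]
        expected = (3.0 - pool.mean()) / pool.std(ddof=1)
        assert z.loc["t1", "m"] == pytest.approx(expected)

    def test_zero_control_sd_gives_missing(self):
        scores = pd.DataFrame({"m": [2.0, 1.0, 1.0]}, index=["t1", "c1", "c2"])
        meta = pd.DataFrame(
            {"batch": ["b1"] * 3, "is_control": [False, True, True]},
            index=scores.index,
        )
        assert np.isnan(standardized_scores(scores, meta).loc["t1", "m"])


def test_standardize_columns_contract(rng):
    df = pd.DataFrame(rng.normal(3, 2, size=(30, 5)))
    z = standardize_columns(df)
    assert np.allclose(z.mean(axis=0), 0.0, atol=1e-8)
    assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-8)


class TestCollapseCompartments:
    def test_cytosol_wins(self):
        df = pd.DataFrame({"atp[c]": [1.2], "atp[m]": [-0.4]})
        out = collapse_compartments(df)
        assert out.loc[0, "atp"] == pytest.approx(1.2)

    def test_median_without_cytosol(self):
        df = pd.DataFrame({"x[m]": [1.0], "x[r]": [3.0]})
        assert collapse_compartments(df).loc[0, "x"] == pytest.approx(2.0)

    def test_singleton(self):
        df = pd.DataFrame({"y[n]": [-1.1]})
        assert collapse_compartments(df).loc[0, "y"] == pytest.approx(-1.1)

    def test_underscore_tags(self):
        df = pd.DataFrame({"glc_c": [0.7], "glc_m": [5.0]})
        assert collapse_compartments(df).loc[0, "glc"] == pytest.approx(0.7)


class TestDrugResponse:
    def test_median_then_standardize(self):
        z = pd.DataFrame(
            {"m": [1.0, 3.0, 5.0, 0.0, 2.0]},
            index=["s1", "s2", "s3", "s4", "s5"],
        )
        drugs = pd.Series(
            {"s1": "d1", "s2": "d1", "s3": "d1", "s4": "d2", "s5": "d2"}
        )
        out = drug_response(z, drugs)
        # medians: d1 -> 3, d2 -> 1; standardized over two drugs: +-1/sqrt(2)
        assert out.loc["d1", "m"] == pytest.approx(1 / np.sqrt(2))
        assert out.loc["d2", "m"] == pytest.approx(-1 / np.sqrt(2))

    def test_single_drug_flagged_missing(self):
        z = pd.DataFrame({"m": [1.0, 2.0]}, index=["s1", "s2"])
        out = drug_response(z, pd.Series({"s1": "d1", "s2": "d1"}))
        assert np.isnan(out.loc["d1", "m"])


class TestConsensus:
    def test_mean_then_standardize(self):
        a = pd.DataFrame({"m": [1.0, 5.0]}, index=["d1", "d2"])
        b = pd.DataFrame({"m": [3.0, 7.0]}, index=["d1", "d2"])
        out = consensus_across_cell_lines([a, b])
        # means {2, 6} -> standardized +-1/sqrt(2)
        assert out.loc["d1", "m"] == pytest.approx(-1 / np.sqrt(2))

    def test_inner_join_drops_unshared(self):
        a = pd.DataFrame({"m": [1.0, 2.0], "n": [0.0, 1.0]}, index=["d1", "d2"])
        b = pd.DataFrame({"m": [3.0, 4.0]}, index=["d1", "d2"])
        out = consensus_across_cell_lines([a, b])
        assert list(out.columns) == ["m"]

    def test_empty_intersection_errors(self):
        a = pd.DataFrame({"m": [1.0]}, index=["d1"])
        b = pd.DataFrame({"m": [1.0]}, index=["d2"])
        with pytest.raises(ValueError):
            consensus_across_cell_lines([a, b])


class TestLongitudinal:
    def test_identity_and_doubling(self):
        x = pd.DataFrame({"m": [2.0, 2.0, 4.0]}, index=["t0", "t1", "t2"])
        out = longitudinal_log2_scores(x)
        assert out.loc["t1", "m"] == pytest.approx(0.0)
        assert out.loc["t2", "m"] == pytest.approx(1.0)

    def test_zero_reference_uses_pseudocount(self):
        x = pd.DataFrame({"m": [0.0, 2.0]}, index=["t0", "t1"])
        with pytest.warns(UserWarning, match="pseudocount"):
            out = longitudinal_log2_scores(x)
        assert out.loc["t1", "m"] == pytest.approx(np.log2(2.0 / 1.0))  # pc = 1.0
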