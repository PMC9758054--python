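import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unzipmap.estimator import (
    ChamberCounts,
    NuisanceParams,
    aggregate,
    collision_competence,
    estimate_chamber,
    read_through,
    removal,
)
from unzipmap.simulate import (
    GeneratorConfig,
    chamber_counts_from_outcomes,
    expected_fractions,
    sample_outcomes,
)


def counts(pre, post, cid="c0"):
    return ChamberCounts(pre=pre, post=post, chamber_id=cid)


def _uniform_counts(**post_overrides):
    pre = {"A20_dCas": 0.90, "A20_only": 0.05, "dCas_only": 0.03, "Nak": 0.02}
    post = {
        "TEC_up_dCas": 0.0,
        "TEC_up_only": 0.0,
        "Coll": 0.0,
        "dCas_rem": 0.0,
        "TEC_dn": 0.0,
        "Nak": 0.0,
        "dCas_only": 0.0,
    }
    post.update(post_overrides)
    rest = 1.0 - sum(post.values())
    post["Coll"] += rest
    return counts(pre, post)


class TestCollisionCompetence:
    def test_no_upstream_motors_gives_one(self):
        c = _uniform_counts()
        assert collision_competence(c, NuisanceParams()) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        """Oracle: hand evaluation of
        1 - 0.15 / (0.95 * 0.90) = 0.824561..."""
        pre = {"A20_dCas": 0.90, "A20_only": 0.05, "dCas_only": 0.03, "Nak": 0.02}
        post = {
            "TEC_up_dCas": 0.10,
            "TEC_up_only": 0.05,
            "Coll": 0.85,
            "dCas_rem": 0.0,
            "TEC_dn": 0.0,
            "Nak": 0.0,
            "dCas_only": 0.0,
        }
        c = counts(pre, post)
        nu = NuisanceParams(p_motor_diss=0.10)
        assert collision_competence(c, nu) == pytest.approx(
            1 - 0.15 / (0.95 * 0.90), abs=1e-12
        )

    def test_zero_denominator_diagnosed(self):
        pre = {"A20_dCas": 0.0, "A20_only": 0.0, "dCas_only": 0.5, "Nak": 0.5}
        post = {k: 0.0 for k in ("TEC_up_dCas", "TEC_up_only", "Coll", "dCas_rem", "TEC_dn")}
        post.update({"Nak": 0.5, "dCas_only": 0.5})
        with pytest.raises(ZeroDivisionError, match="denominator"):
            collision_competence(counts(pre, post), NuisanceParams())


class TestReadThrough:
    def test_degenerate_limit_returns_naked_pool(self):
        """With perfect initial co-occupancy, no nuisance dissociation and
        full collision competence, the estimate equals the post-chase
        naked + downstream pool: 0.43 exactly."""
        pre = {"A20_dCas": 1.0, "A20_only": 0.0, "dCas_only": 0.0, "Nak": 0.0}
        post = {
            "TEC_up_dCas": 0.0,
            "TEC_up_only": 0.0,
            "Coll": 0.57,
            "dCas_rem": 0.0,
            "TEC_dn": 0.20,
            "Nak": 0.23,
            "dCas_only": 0.0,
        }
        c = counts(pre, post)
        assert read_through(c, NuisanceParams(), 1.0) == pytest.approx(0.43, abs=1e-15)

    def test_no_change_gives_zero(self):
        pre = {"A20_dCas": 0.95, "A20_only": 0.0, "dCas_only": 0.0, "Nak": 0.05}
        post = {
            "TEC_up_dCas": 0.0,
            "TEC_up_only": 0.0,
            "Coll": 0.95,
            "dCas_rem": 0.0,
            "TEC_dn": 0.0,
            "Nak": 0.05,
            "dCas_only": 0.0,
        }
        assert read_through(counts(pre, post), NuisanceParams(), 1.0) == pytest.approx(0.0)

    def test_zero_nuisance_reduction(self):
        """With zero nuisance probabilities the equation reduces to
        (F_Nak_f + F_TEC_dn_f - F_Nak_i - F_A20_only_i p_cc) / (F_A20_dCas_i p_cc)."""
        pre = {"A20_dCas": 0.85, "A20_only": 0.05, "dCas_only": 0.05, "Nak": 0.05}
        post = {
            "TEC_up_dCas": 0.1,
            "TEC_up_only": 0.02,
            "Coll": 0.43,
            "dCas_rem": 0.05,
            "TEC_dn": 0.18,
            "Nak": 0.17,
            "dCas_only": 0.05,
        }
        c = counts(pre, post)
        p_cc = 0.8
        expected = (0.18 + 0.17 - 0.05 - 0.05 * p_cc) / (0.85 * p_cc)
        assert read_through(c, NuisanceParams(), p_cc) == pytest.approx(expected)

    def test_out_of_range_flagged_not_clipped(self):
        pre = {"A20_dCas": 0.9, "A20_only": 0.0, "dCas_only": 0.0, "Nak": 0.1}
        post = {
            "TEC_up_dCas": 0.0,
            "TEC_up_only": 0.0,
            "Coll": 0.95,
            "dCas_rem": 0.0,
            "TEC_dn": 0.0,
            "Nak": 0.05,
            "dCas_only": 0.0,
        }
        est = estimate_chamber(counts(pre, post), NuisanceParams())
        assert est.p_read_through < 0.0
        assert any("outside" in f for f in est.flags)

    def test_nuisance_sensitivity_direction(self):
        """Holding fractions fixed, raising p_dcas_diss lowers the estimate
        over a parameter grid (numerical assertion)."""
        pre = {"A20_dCas": 0.90, "A20_only": 0.04, "dCas_only": 0.04, "Nak": 0.02}
        post = {
            "TEC_up_dCas": 0.08,
            "TEC_up_only": 0.02,
            "Coll": 0.35,
            "dCas_rem": 0.05,
            "TEC_dn": 0.20,
            "Nak": 0.25,
            "dCas_only": 0.05,
        }
        c = counts(pre, post)
        for p_cc in (0.7, 0.85, 1.0):
            vals = [
                read_through(c, NuisanceParams(0.05, pd), p_cc)
                for pd in (0.0, 0.05, 0.10, 0.20)
            ]
            assert np.all(np.diff(vals) < 0)


class TestRemoval:
    def test_equals_readthrough_without_stalled_removals(self):
        c = _uniform_counts(Nak=0.3, TEC_dn=0.1)
        nu = NuisanceParams(0.05, 0.05)
        assert removal(c, nu, 0.9) == pytest.approx(read_through(c, nu, 0.9))

    def test_removal_at_least_readthrough(self, rng):
        for _ in range(20):
            post = rng.dirichlet(np.ones(7))
            pre = rng.dirichlet([20, 1, 1, 1])
            c = counts(
                dict(zip(("A20_dCas", "A20_only", "dCas_only", "Nak"), pre)),
                dict(
                    zip(
                        ("TEC_up_dCas", "TEC_up_only", "Coll", "dCas_rem", "TEC_dn", "Nak", "dCas_only"),
                        post,
                    )
                ),
            )
            nu = NuisanceParams(0.05, 0.05)
            assert removal(c, nu, 0.9) >= read_through(c, nu, 0.9)


class TestGenerativeIdentity:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.floats(0.5, 0.98),
        rest=st.tuples(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)),
        pm=st.floats(0, 0.4),
        ps=st.floats(0, 0.4),
        pcc=st.floats(0.3, 1.0),
        rt=st.floats(0.01, 0.98),
        rem_frac=st.floats(0, 1),
        prun=st.floats(0, 1),
    )
    def test_estimator_inverts_generative_tree(
        self, a, rest, pm, ps, pcc, rt, rem_frac, prun
    ):
        """Centerpiece identity: the estimator applied to the exact expected
        fractions returns the generator's parameters to machine precision."""
        r = np.array(rest)
        r = (1 - a) * r / r.sum()
        prem = (1 - rt) * rem_frac
        cfg = GeneratorConfig(
            f_A20_dCas=a,
            f_A20_only=r[0],
            f_dCas_only=r[1],
            f_nak=1 - a - r[0] - r[1],
            p_motor_diss=pm,
            p_dcas_diss=ps,
            p_coll_comp=pcc,
            p_read_through=rt,
            p_removal_stall=prem,
            p_block=1 - rt - prem,
            p_runoff_given_readthrough=prun,
        )
        c = expected_fractions(cfg)
        nu = NuisanceParams(pm, ps)
        p_cc = collision_competence(c, nu)
        assert p_cc == pytest.approx(pcc, abs=1e-10)
        assert read_through(c, nu, p_cc) == pytest.approx(rt, abs=1e-10)
        assert removal(c, nu, p_cc) == pytest.approx(rt + prem, abs=1e-10)

    @pytest.mark.parametrize("n_chase", [50, 500, 5000])
    def test_consistency_bias_shrinks_with_traces(self, n_chase):
        """Sampled-chamber estimates converge to the truth as the per-chamber
        trace count grows."""
        cfg = GeneratorConfig(
            seed=100 + n_chase,
            chambers=8,
            traces_control=max(n_chase // 2, 10),
            traces_chase=n_chase,
        )
        out = sample_outcomes(cfg)
        nu = NuisanceParams(cfg.p_motor_diss, cfg.p_dcas_diss)
        res = aggregate(
            [estimate_chamber(c, nu) for c in chamber_counts_from_outcomes(out)]
        )
        tol = 6.0 / np.sqrt(n_chase)  # ~3 binomial s.e. through the estimator
        assert abs(res.mean_read_through - cfg.p_read_through) < tol


class TestAggregate:
    def test_identical_chambers(self):
        ests = [
            estimate_chamber(_uniform_counts(Nak=0.4), NuisanceParams())
            for _ in range(3)
        ]
        res = aggregate(ests)
        assert res.sem_read_through == pytest.approx(0.0)
        assert res.n_valid == 3

    def test_hand_computed_sem(self):
        """Oracle: chambers {0.4, 0.5, 0.6} give mean 0.5 and
        s.e.m. 0.1/sqrt(3)."""
        from unzipmap.estimator import ChamberEstimate

        ests = [
            ChamberEstimate(f"c{i}", 0.9, v, v) for i, v in enumerate((0.4, 0.5, 0.6))
        ]
        res = aggregate(ests)
        assert res.mean_read_through == pytest.approx(0.5)
        assert res.sem_read_through == pytest.approx(0.1 / np.sqrt(3))

    def test_single_chamber_sem_unavailable(self):
        from unzipmap.estimator import ChamberEstimate

        res = aggregate([ChamberEstimate("c0", 0.9, 0.4, 0.5)])
        assert res.mean_read_through == pytest.approx(0.4)
        assert np.isnan(res.sem_read_through)

    def test_invalid_chambers_excluded_and_counted(self):
        from unzipmap.estimator import ChamberEstimate

        ests = [
            ChamberEstimate("c0", 0.9, 0.4, 0.5),
            ChamberEstimate("c1", np.nan, np.nan, np.nan, valid=False),
            ChamberEstimate("c2", 0.9, 0.6, 0.7),
        ]
        res = aggregate(ests)
        assert res.n_valid == 2
        assert res.n_excluded == 1
        assert res.mean_read_through == pytest.approx(0.5)

    def test_no_valid_chambers_rejected(self):
        from unzipmap.estimator import ChamberEstimate

        with pytest.raises(ValueError, match="no valid"):
            aggregate([ChamberEstimate("c0", np.nan, np.nan, np.nan, valid=False)])


class TestChamberCounts:
    def test_fractions_must_sum_to_one(self):
        pre = {"A20_dCas": 0.5, "A20_only": 0.1, "dCas_only": 0.1, "Nak": 0.1}
        post = {k: 1 / 7 for k in ("TEC_up_dCas", "TEC_up_only", "Coll", "dCas_rem", "TEC_dn", "Nak", "dCas_only")}
        with pytest.raises(ValueError, match="sum to 1"):
            ChamberCounts(pre=pre, post=post)

    def test_from_counts(self):
        c = ChamberCounts.from_counts(
            {"A20_dCas": 36, "A20_only": 2, "dCas_only": 1, "Nak": 1},
            {"Coll": 30, "Nak": 20, "TEC_dn": 10},
            chamber_id="ch",
        )
        assert c.pre["A20_dCas"] == pytest.approx(0.9)
        assert c.post["Coll"] == pytest.approx(0.5)
        assert c.pre_total == 40 and c.post_total == 60
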