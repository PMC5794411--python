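import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import etamu
from etamu import DeficitClass, SubjectSession

ALL_TESTS = etamu.default_battery().names


def session(z_map, subject="s", label="t"):
    return SubjectSession(subject_id=subject, session=label, z_scores=z_map)


@st.composite
def random_sessions(draw, z_min=-4.0, z_max=4.0):
    names = draw(st.sets(st.sampled_from(ALL_TESTS), min_size=1))
    z = {
        n: draw(st.floats(z_min, z_max, allow_nan=False, allow_infinity=False))
        for n in sorted(names)
    }
    return session(z)


# --- worked example and pilot profiles against their published derived values

# printed 2-decimal reference values: (avg_z, eta, mu, eta_exp, mu_exp, delta_eta)
PUBLISHED = {
    ("pre", "subject1"): (-1.75, 140.29, 34.61, 132.92, 41.98, 7.37),
    ("pre", "subject2"): (-0.91, 69.60, 21.70, 69.39, 21.91, 0.21),
    ("pre", "subject3"): (-1.16, 82.70, 33.44, 76.32, 39.82, 6.38),
    ("pre", "subject4"): (-0.86, 55.56, 30.74, 65.59, 20.71, -10.03),
}


def test_worked_example_full_scoring(worked_example, battery):
    r = etamu.score_session(worked_example, battery)
    assert r.avg_z == pytest.approx(-1.65, abs=1e-9)
    assert r.eta == pytest.approx(140.5, abs=1e-9)
    assert r.mu == pytest.approx(24.5, abs=1e-9)
    assert r.eta_exp == pytest.approx(125.4, abs=1e-9)
    assert r.mu_exp == pytest.approx(39.6, abs=1e-9)
    assert r.delta_eta == pytest.approx(15.1, abs=1e-9)
    assert r.classification is DeficitClass.VP_PREVALENT


@pytest.mark.parametrize("key", sorted(PUBLISHED))
def test_pilot_pre_sessions_match_published_values(key, pilot_pre, battery):
    _, subject = key
    avg, eta, mu, eta_exp, mu_exp, d_eta = PUBLISHED[key]
    r = etamu.score_session(pilot_pre[subject], battery)
    assert r.avg_z == pytest.approx(avg, abs=0.01)
    assert r.eta == pytest.approx(eta, abs=0.01)
    assert r.mu == pytest.approx(mu, abs=0.01)
    assert r.eta_exp == pytest.approx(eta_exp, abs=0.01)
    assert r.mu_exp == pytest.approx(mu_exp, abs=0.01)
    assert r.delta_eta == pytest.approx(d_eta, abs=0.01)
    assert r.delta_mu == pytest.approx(-d_eta, abs=0.01)


def test_incomplete_battery_is_reweighted(pilot_pre, battery):
    """A subject with 7 of 10 tests gets expected values from the 7-test means."""
    r = etamu.score_session(pilot_pre["subject3"], battery)
    assert r.n_tests == 7
    assert r.mean_vp == pytest.approx(460 / 7)
    assert r.avg_z == pytest.approx(-1.1614, abs=1e-4)
    assert any("incomplete battery" in w for w in r.warnings)


def test_pilot_pre_classifications(pilot_pre, battery):
    cls = {
        s: etamu.score_session(sess, battery).classification
        for s, sess in pilot_pre.items()
    }
    assert cls["subject1"] is DeficitClass.VP_PREVALENT
    assert cls["subject2"] is DeficitClass.BALANCED
    assert cls["subject3"] is DeficitClass.VP_PREVALENT
    assert cls["subject4"] is DeficitClass.VMC_PREVALENT


def test_expected_indices_examples():
    assert etamu.expected_indices(-1.65, 76, 24) == pytest.approx((125.4, 39.6))
    assert etamu.expected_indices(-2, 76, 24) == pytest.approx((152.0, 48.0))
    eta_exp, mu_exp = etamu.expected_indices(-1.1614, 460 / 7, 240 / 7)
    assert eta_exp == pytest.approx(76.32, abs=0.01)
    assert mu_exp == pytest.approx(39.82, abs=0.01)
    with pytest.raises(ValueError):
        etamu.expected_indices(-1, 60, 30)


def test_all_zero_profile_scores_zero(battery):
    r = etamu.score_session(session({n: 0.0 for n in ALL_TESTS}), battery)
    assert r.eta == r.mu == r.eta_exp == r.mu_exp == 0
    assert r.classification is DeficitClass.BALANCED


def test_uniform_impairment_gives_mean_weights(battery):
    """All z = -1 reduces eta/mu to the battery's mean recruitment weights."""
    r = etamu.score_session(session({n: -1.0 for n in ALL_TESTS}), battery)
    assert r.eta == pytest.approx(76.0)
    assert r.mu == pytest.approx(24.0)
    assert r.delta_eta == pytest.approx(0.0, abs=1e-9)


def test_unknown_test_name_is_reported(battery):
    with pytest.raises(KeyError, match="mystery_test"):
        etamu.compute_eta(session({"mystery_test": -1.0}), battery)


def test_empty_session_rejected():
    with pytest.raises(ValueError):
        SubjectSession("s", "t", {})


def test_positive_average_z_flagged_not_classified(battery):
    """Above-norm mean performance yields a no-net-impairment warning, no deficit."""
    r = etamu.score_session(session({n: 1.0 for n in ALL_TESTS}), battery)
    assert r.avg_z == pytest.approx(1.0)
    assert r.classification is DeficitClass.BALANCED
    assert any("no net impairment" in w for w in r.warnings)


def test_outlying_z_warned_but_scored(pilot_post, battery):
    """The as-published post profile with z = 10.72 scores, with an outlier flag."""
    r = etamu.score_session(pilot_post["subject1"], battery)
    assert any("exceeds 5" in w for w in r.warnings)
    assert r.mu == pytest.approx(7.05, abs=0.01)


def test_boundary_delta_is_balanced(battery):
    """delta exactly at the tolerance stays BALANCED (inclusive band)."""
    z = {n: -1.0 for n in ALL_TESTS}
    r0 = etamu.score_session(session(z), battery)
    assert r0.delta_eta == pytest.approx(0.0, abs=1e-12)
    assert etamu.score_session(session(z), battery, tolerance=0.0).classification \
        is DeficitClass.BALANCED


def test_model_lines_slopes():
    df = etamu.model_lines(76, 24, [-1, -2, 0])
    assert df.loc[0, "eta_exp"] == pytest.approx(76.0)
    assert df.loc[0, "mu_exp"] == pytest.approx(24.0)
    assert df.loc[1, "eta_exp"] == pytest.approx(2 * df.loc[0, "eta_exp"])
    assert (df.loc[2, ["eta_exp", "mu_exp"]] == 0).all()
    with pytest.raises(ValueError):
        etamu.model_lines(76, 24, [])


# --- algebraic properties ----------------------------------------------------

@settings(derandomize=True, max_examples=200)
@given(sess=random_sessions())
def test_indices_agree_with_loop_oracle_and_split_total(sess):
    """eta/mu match an explicit per-term loop, and split -100*avg_z exactly."""
    battery = etamu.default_battery()
    n = len(sess.z_scores)
    eta_oracle = 0.0
    mu_oracle = 0.0
    for name, z in sess.z_scores.items():
        t = battery[name]
        eta_oracle -= t.vp_weight * z / n
        mu_oracle -= t.vmc_weight * z / n
    eta, mu = etamu.compute_eta(sess, battery), etamu.compute_mu(sess, battery)
    assert eta == pytest.approx(eta_oracle, abs=1e-9)
    assert mu == pytest.approx(mu_oracle, abs=1e-9)
    assert eta + mu == pytest.approx(-100 * etamu.average_z(sess), abs=1e-9)


@settings(derandomize=True, max_examples=200)
@given(sess=random_sessions(z_max=0.0))
def test_delta_complementarity_below_norm(sess):
    """With avg_z <= 0 the deltas are exact opposites."""
    r = etamu.score_session(sess, etamu.default_battery())
    assert r.delta_eta + r.delta_mu == pytest.approx(0.0, abs=1e-9)


@settings(derandomize=True, max_examples=100)
@given(sess=random_sessions(z_max=0.0), c=st.floats(0.1, 5.0))
def test_linear_scaling(sess, c):
    """Scaling all z by c > 0 scales every index (and delta, below norm) by c."""
    battery = etamu.default_battery()
    r1 = etamu.score_session(sess, battery)
    scaled = SubjectSession(
        sess.subject_id, sess.session, {k: c * v for k, v in sess.z_scores.items()}
    )
    r2 = etamu.score_session(scaled, battery)
    for attr in ("avg_z", "eta", "mu", "eta_exp", "mu_exp", "delta_eta", "delta_mu"):
        assert getattr(r2, attr) == pytest.approx(
            c * getattr(r1, attr), abs=1e-7 * max(1, abs(getattr(r1, attr)))
        )


@settings(derandomize=True, max_examples=100)
@given(sess=random_sessions())
def test_subset_consistency(sess):
    """Scoring against the full battery equals scoring against the restricted one."""
    full = etamu.default_battery()
    restricted = full.subset(sess.z_scores.keys())
    r1 = etamu.score_session(sess, full)
    r2 = etamu.score_session(sess, restricted)
    for attr in ("avg_z", "eta", "mu", "eta_exp", "mu_exp", "delta_eta", "delta_mu"):
        assert getattr(r1, attr) == pytest.approx(getattr(r2, attr), abs=1e-9)


@settings(derandomize=True, max_examples=50)
@given(z0=st.floats(-4.0, 0.0, allow_nan=False))
def test_ideal_subject_has_zero_deltas(z0):
    """Identical z on every test (the balanced subject) makes both deltas vanish."""
    battery = etamu.default_battery()
    r = etamu.score_session(session({n: z0 for n in ALL_TESTS}), battery)
    assert r.delta_eta == pytest.approx(0.0, abs=1e-9)
    assert r.delta_mu == pytest.approx(0.0, abs=1e-9)
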