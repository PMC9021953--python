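"""Model update rules, sequential likelihoods, and generative agents."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import random_session_trials
from igtpain import (
    ORLParams,
    PVLParams,
    VPPParams,
    SessionRecord,
    session_loglik,
    simulate_agent,
)
from igtpain.models import (
    LatentState,
    ParameterError,
    consistency_to_sensitivity,
    decay_update,
    delta_update,
    orl_update,
    orl_value,
    prospect_utility,
    softmax_probs,
    vpp_perseverance_update,
    vpp_value,
)
from igtpain.task import Trial
from igtpain._batch import PARAM_ORDER, batch_loglik, pack_sessions


def make_session(trials_list):
    trials = [
        Trial(t=i + 1, deck="ABCD"[ch], reward=max(net, 0.0), loss=min(net, 0.0))
        for i, (ch, net) in enumerate(trials_list)
    ]
    return SessionRecord(subject_id="x", group="healthy", trials=trials)


class TestElementaryUpdates:
    @pytest.mark.parametrize("x,alpha,lam,expected", [
        (0.0, 0.5, 3.0, 0.0),
        (1.0, 0.37, 1.0, 1.0),
        (-1.0, 0.8, 2.5, -2.5),
        (4.0, 0.5, 1.0, 2.0),
        (-4.0, 0.5, 2.0, -4.0),
    ])
    def test_prospect_utility(self, x, alpha, lam, expected):
        assert prospect_utility(x, alpha, lam) == pytest.approx(expected)

    def test_delta_update_limits(self):
        E = np.array([0.3, -0.2, 0.0, 1.0])
        assert np.array_equal(delta_update(E, 1, 5.0, 0.0), E)
        assert delta_update(E, 1, 5.0, 1.0)[1] == 5.0
        assert delta_update(np.zeros(4), 2, 1.0, 0.5)[2] == 0.5

    def test_decay_update_hand_value(self):
        E = np.ones(4)
        out = decay_update(E, 0, 2.0, 0.5)
        assert np.allclose(out, [2.5, 0.5, 0.5, 0.5])

    def test_decay_update_limits(self):
        E = np.array([1.0, 2.0, 3.0, 4.0])
        full = decay_update(E.copy(), 1, 7.0, 1.0)
        assert np.allclose(full, [1.0, 9.0, 3.0, 4.0])
        zero = decay_update(E.copy(), 1, 7.0, 0.0)
        assert np.allclose(zero, [0.0, 7.0, 0.0, 0.0])

    def test_vpp_perseverance_hand_value(self):
        P = np.array([1.0, 0.0, 0.0, 0.0])
        out = vpp_perseverance_update(P, 0, -1.0, 0.5, 1.0, -2.0)
        assert np.allclose(out, [-1.5, 0.0, 0.0, 0.0])

    def test_vpp_perseverance_limits(self):
        out = vpp_perseverance_update(np.ones(4), 2, +1.0, 0.0, 3.0, -2.0)
        assert np.allclose(out, [0.0, 0.0, 3.0, 0.0])
        decay_only = vpp_perseverance_update(np.ones(4), 2, +1.0, 0.5, 0.0, 0.0)
        assert np.allclose(decay_only, 0.5)

    def test_vpp_value_mixing(self):
        E = np.array([2.0, 0.0, 0.0, 0.0])
        P = np.array([0.0, 2.0, 0.0, 0.0])
        assert np.array_equal(vpp_value(E, P, 1.0), E)
        assert np.array_equal(vpp_value(E, P, 0.0), P)
        assert np.allclose(vpp_value(E, P, 0.5), [1, 1, 0, 0])

    def test_orl_update_hand_values(self):
        p = ORLParams(a_rew=0.5, a_pun=0.25, k_prime=0.0, beta_f=0.0, beta_p=0.0)
        out = orl_update(LatentState(), chosen=0, x=1.0, params=p)
        assert out.EV[0] == pytest.approx(0.5)
        assert out.EF[0] == pytest.approx(0.5)
        # unchosen decks move toward -sgn(x)/3 at the opposite-valence rate
        assert np.allclose(out.EF[1:], 0.25 * (-1 / 3))
        assert out.PS[0] == 1.0 and np.allclose(out.PS[1:], 0.0)

    def test_orl_zero_outcome_targets(self):
        p = ORLParams(a_rew=0.9, a_pun=0.9, k_prime=1.0, beta_f=0.0, beta_p=0.0)
        state = orl_update(LatentState(), chosen=2, x=0.5, params=p)
        out = orl_update(state, chosen=2, x=0.0, params=p)
        # sgn(0)=0: frequency targets are 0 everywhere
        assert abs(out.EF[2]) < abs(state.EF[2])

    def test_orl_full_update_rate_one(self):
        p = ORLParams(a_rew=0.999999, a_pun=0.5, k_prime=0.0, beta_f=0.0, beta_p=0.0)
        out = orl_update(LatentState(), chosen=3, x=1.0, params=p)
        assert out.EV[3] == pytest.approx(1.0, abs=1e-5)
        assert out.EF[3] == pytest.approx(1.0, abs=1e-5)

    def test_orl_value_combinations(self):
        EV = np.array([1.0, 0, 0, 0])
        EF = np.array([0, 1.0, 0, 0])
        PS = np.array([1.0, 0, 0, 0])
        assert np.array_equal(orl_value(EV, EF, PS, 0.0, 0.0), EV)
        assert np.allclose(orl_value(np.zeros(4), EF, PS, -1.0, 2.0), [2, -1, 0, 0])


class TestSoftmax:
    def test_symmetry_and_zero_sensitivity(self):
        assert np.allclose(softmax_probs(np.array([3.0, 3, 3, 3]), 2.0), 0.25)
        assert np.allclose(softmax_probs(np.array([9.0, -4, 0, 2]), 0.0), 0.25)

    def test_consistency_zero_gives_uniform(self):
        assert consistency_to_sensitivity(0.0) == 0.0

    def test_argmax_limit(self):
        p = softmax_probs(np.array([1.0, 0, 0, 0]), 1000.0)
        assert p[0] > 0.999

    def test_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            softmax_probs(np.array([np.inf, 0, 0, 0]), 1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        v=st.lists(st.floats(-700, 700), min_size=4, max_size=4),
        sens=st.floats(0, 100),
    )
    def test_probability_conservation(self, v, sens):
        p = softmax_probs(np.array(v), sens)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()


class TestParameterBounds:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"alpha": 1.0}, {"lam": 0.0}, {"lam": 10.0},
        {"a": -0.1}, {"a": 1.1}, {"c": 5.5},
    ])
    def test_pvl_bounds_enforced(self, kwargs):
        base = dict(alpha=0.5, lam=1.0, a=0.5, c=1.0)
        with pytest.raises(ParameterError):
            PVLParams(**{**base, **kwargs})

    def test_derived_sensitivity_range(self):
        assert PVLParams(alpha=0.5, lam=1.0, a=0.5, c=5.0 - 1e-12).theta == pytest.approx(242.0)
        assert ORLParams(a_rew=0.5, a_pun=0.5, k_prime=5.0, beta_f=0.0, beta_p=0.0).k == pytest.approx(242.0)

    def test_orl_bounds_enforced(self):
        with pytest.raises(ParameterError):
            ORLParams(a_rew=1.0, a_pun=0.5, k_prime=1.0, beta_f=0.0, beta_p=0.0)


ORL_P = ORLParams(a_rew=0.4, a_pun=0.15, k_prime=0.9, beta_f=1.2, beta_p=-0.8)
VPP_P = VPPParams(alpha=0.45, lam=2.2, a=0.35, c=1.2, k=0.6, ep_p=0.8, ep_n=-1.1, w=0.65)
PVL_DELTA_P = PVLParams(alpha=0.45, lam=2.2, a=0.35, c=1.2, rule="delta")
PVL_DECAY_P = PVLParams(alpha=0.45, lam=2.2, a=0.6, c=1.2, rule="decay")


def _oracle_loglik(model, params, trials):
    if model == "pvl_delta":
        return oracles.pvl_loglik(trials, params.alpha, params.lam, params.a, params.c, "delta")
    if model == "pvl_decay":
        return oracles.pvl_loglik(trials, params.alpha, params.lam, params.a, params.c, "decay")
    if model == "vpp":
        return oracles.vpp_loglik(
            trials, params.alpha, params.lam, params.a, params.c,
            params.k, params.ep_p, params.ep_n, params.w,
        )
    return oracles.orl_loglik(
        trials, params.a_rew, params.a_pun, params.k_prime, params.beta_f, params.beta_p
    )


MODEL_CASES = [
    ("pvl_delta", PVL_DELTA_P),
    ("pvl_decay", PVL_DECAY_P),
    ("vpp", VPP_P),
    ("orl", ORL_P),
]


class TestSessionLoglik:
    @pytest.mark.parametrize("model,params", MODEL_CASES)
    def test_first_trial_is_uniform(self, model, params):
        s = make_session([(2, 50.0)])
        assert session_loglik(model, params, s)[0] == pytest.approx(np.log(0.25))

    @pytest.mark.parametrize("model,params", MODEL_CASES)
    def test_matches_scalar_oracle(self, model, params, rng):
        for _ in range(10):
            trials = random_session_trials(rng, n=20)
            ours = session_loglik(model, params, make_session(trials))
            ref = _oracle_loglik(model, params, trials)
            assert np.max(np.abs(ours - np.array(ref))) < 1e-10

    @pytest.mark.parametrize("model,params", MODEL_CASES)
    def test_batch_matches_sequential(self, model, params, rng):
        sessions = [make_session(random_session_trials(rng, n=n)) for n in (20, 15, 20)]
        choices, xs = pack_sessions(sessions, 100.0)
        order = PARAM_ORDER[model]
        mat = np.tile([getattr(params, k) for k in order], (3, 1))
        got = batch_loglik(model, mat, choices, xs)
        for i, s in enumerate(sessions):
            ref = session_loglik(model, params, s)
            assert np.max(np.abs(got[i, : len(s)] - ref)) < 1e-12
            assert np.all(got[i, len(s):] == 0.0)

    def test_vpp_reduces_to_pvl_delta(self, rng):
        trials = random_session_trials(rng, n=30)
        s = make_session(trials)
        vpp = VPPParams(alpha=0.45, lam=2.2, a=0.35, c=1.2, k=0.3, ep_p=0.0, ep_n=0.0, w=1.0)
        pvl = PVLParams(alpha=0.45, lam=2.2, a=0.35, c=1.2, rule="delta")
        assert np.max(np.abs(session_loglik("vpp", vpp, s) - session_loglik("pvl_delta", pvl, s))) < 1e-10

    def test_orl_reduces_to_raw_outcome_delta_rule(self, rng):
        # with beta_F = beta_P = 0 and equal rates, ORL is a delta rule on
        # raw scaled outcomes with unit-sensitivity softmax
        trials = random_session_trials(rng, n=30)
        s = make_session(trials)
        a = 0.3
        orl = ORLParams(a_rew=a, a_pun=a, k_prime=1.0, beta_f=0.0, beta_p=0.0)
        got = session_loglik("orl", orl, s)
        E = [0.0] * 4
        ref = []
        for ch, net in trials:
            p = oracles.softmax4(E, 1.0)
            ref.append(np.log(p[ch]))
            E[ch] += a * (net / 100.0 - E[ch])
        assert np.max(np.abs(got - np.array(ref))) < 1e-10

    def test_same_rate_fictive_toggle_changes_likelihood(self, rng):
        trials = random_session_trials(rng, n=30)
        s = make_session(trials)
        base = session_loglik("orl", ORL_P, s)
        toggled_params = ORLParams(
            a_rew=ORL_P.a_rew, a_pun=ORL_P.a_pun, k_prime=ORL_P.k_prime,
            beta_f=ORL_P.beta_f, beta_p=ORL_P.beta_p, same_rate_fictive=True,
        )
        toggled = session_loglik("orl", toggled_params, s)
        assert not np.allclose(base, toggled)
        ref = oracles.orl_loglik(
            trials, ORL_P.a_rew, ORL_P.a_pun, ORL_P.k_prime, ORL_P.beta_f, ORL_P.beta_p,
            same_rate=True,
        )
        assert np.max(np.abs(toggled - np.array(ref))) < 1e-10

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            session_loglik("orl", ORL_P, make_session([]))


class TestParameterFiles:
    def test_yaml_and_json_roundtrip(self, tmp_path):
        import json
        import yaml
        from igtpain.models import params_from_file

        values = {"a_rew": 0.4, "a_pun": 0.15, "k_prime": 0.9, "beta_f": 1.2, "beta_p": -0.8}
        yml = tmp_path / "p.yaml"
        yml.write_text(yaml.safe_dump(values))
        jsn = tmp_path / "p.json"
        jsn.write_text(json.dumps(values))
        assert params_from_file("orl", yml) == params_from_file("orl", jsn) == ORL_P


class TestSimulateAgent:
    def test_determinism(self, scheme):
        a = simulate_agent("orl", ORL_P, scheme, n_trials=50, seed=11)
        b = simulate_agent("orl", ORL_P, scheme, n_trials=50, seed=11)
        assert a.trials == b.trials

    def test_zero_sensitivity_agent_is_uniform(self, scheme):
        p = PVLParams(alpha=0.5, lam=1.0, a=0.3, c=0.0, rule="delta")
        s = simulate_agent("pvl_delta", p, scheme, n_trials=10_000, seed=4)
        freqs = np.bincount(s.choices, minlength=4) / len(s)
        assert np.all(np.abs(freqs - 0.25) < 0.02)

    def test_perseverance_dominated_agent_repeats(self, scheme):
        p = ORLParams(a_rew=0.01, a_pun=0.01, k_prime=0.0, beta_f=0.0, beta_p=50.0)
        s = simulate_agent("orl", p, scheme, n_trials=500, seed=8)
        repeats = np.mean(s.choices[1:] == s.choices[:-1])
        assert repeats > 0.9

    @pytest.mark.parametrize("model,params", MODEL_CASES)
    def test_self_consistency_of_likelihood(self, model, params, scheme):
        # the generating parameters beat strongly perturbed ones on average
        sessions = [simulate_agent(model, params, scheme, 400, seed=s) for s in range(3)]
        if model == "orl":
            worse = ORLParams(a_rew=0.9, a_pun=0.9, k_prime=3.0, beta_f=-2.0, beta_p=3.0)
        elif model == "vpp":
            worse = VPPParams(alpha=0.9, lam=8.0, a=0.95, c=3.0, k=0.05, ep_p=-3.0, ep_n=3.0, w=0.1)
        else:
            worse = PVLParams(alpha=0.9, lam=8.0, a=0.95, c=3.0, rule=params.rule)
        for s in sessions:
            assert session_loglik(model, params, s).mean() > session_loglik(model, worse, s).mean()
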