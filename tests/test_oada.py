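"""Diffusion-likelihood oracles, acquisition-order plumbing, model set."""

import numpy as np
import pandas as pd
import pytest

import flocklearn as fl
from flocklearn import oada as od
from flocklearn.association_network import AssociationMatrix
from flocklearn.exceptions import (InvalidArgumentError, SpecificationError,
                                   TieError)

from conftest import toy_roster


@pytest.fixture
def three_birds():
    roster = toy_roster(3)
    net = np.zeros((3, 3))
    net[0, 1] = net[1, 0] = 1.0
    data = od.AcquisitionData(order=["b2", "b3"], times=[1.0, 2.0],
                              roster=roster, seeds=["b1"])
    return roster, net, data


class TestLikelihood:
    def test_hand_computed_three_bird_oracle(self, three_birds):
        """Bird 1 seeded, a_12 = 1, all other edges 0, s = 1, order (2, 3):
        event 1 contributes log(2/3), event 2 log(1)."""
        _, net, data = three_birds
        ll = od.oada_loglik(data, {"all": net}, [1.0])
        assert ll == pytest.approx(np.log(2.0 / 3.0), abs=1e-12)

    def test_asocial_closed_form(self, three_birds):
        _, net, data = three_birds
        ll = od.oada_loglik(data, {"all": net}, [0.0])
        assert ll == pytest.approx(np.log(1 / 2) + np.log(1 / 1), abs=1e-12)

    def test_negative_s_rejected(self, three_birds):
        _, net, data = three_birds
        with pytest.raises(InvalidArgumentError):
            od.oada_loglik(data, {"all": net}, [-0.5])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_risk_sets(self, seed):
        """Arbitrary parameters equal an explicit risk-set enumeration to
        1e-12 on random fixtures of <= 12 birds."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        roster = toy_roster(
            n, species=[rng.choice(["A", "B"]) for _ in range(n)],
            age=[rng.choice(["adult", "juvenile"]) for _ in range(n)])
        ids = list(roster["bird_id"])
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        n_seed = int(rng.integers(0, 2))
        perm = list(rng.permutation(ids))
        seeds, rest = perm[:n_seed], perm[n_seed:]
        k_acq = int(rng.integers(1, len(rest) + 1))
        order = rest[:k_acq]
        data = od.AcquisitionData(order=order,
                                  times=list(np.arange(1.0, k_acq + 1)),
                                  roster=roster, seeds=seeds,
                                  censored=rest[k_acq:])
        nets = {"adult": w * (roster["age"] == "adult").to_numpy()[None, :],
                "juvenile": w * (roster["age"] == "juvenile").to_numpy()[None, :]}
        s = {"adult": float(rng.uniform(0, 8)),
             "juvenile": float(rng.uniform(0, 8))}
        ba, bs = float(rng.normal()), float(rng.normal())
        got = od.oada_loglik(data, nets, s, beta_asocial=ba, beta_social=bs)

        # brute force: materialise every risk set explicitly
        x = (roster["species"] == "B").astype(float).to_numpy()
        informed = set(seeds)
        ll = 0.0
        for acq in order:
            rates = {}
            for b in ids:
                if b in informed:
                    continue
                i = ids.index(b)
                soc = sum(s[m] * sum(nets[m][i, ids.index(j)]
                                     for j in informed) for m in nets)
                rates[b] = np.exp(ba * x[i]) + np.exp(bs * x[i]) * soc
            ll += np.log(rates[acq] / sum(rates.values()))
            informed.add(acq)
        assert got == pytest.approx(ll, abs=1e-12)

    def test_pooling_two_networks_with_equal_s(self, three_birds):
        roster, _, data = three_birds
        rng = np.random.default_rng(7)
        w = rng.uniform(0, 1, (3, 3))
        np.fill_diagonal(w, 0.0)
        w1, w2 = w * 0.3, w * 0.7
        ll_two = od.oada_loglik(data, {"m1": w1, "m2": w2},
                                {"m1": 2.5, "m2": 2.5})
        ll_one = od.oada_loglik(data, {"m": w1 + w2}, {"m": 2.5})
        assert ll_two == pytest.approx(ll_one, abs=1e-12)

    def test_asocial_equals_exchangeable_on_any_dataset(
            self, population, small_cfg):
        roster, net = population
        diff = fl.simulate_reversal_diffusion(roster, net, small_cfg)
        data = od.AcquisitionData(order=diff.order, times=diff.times,
                                  roster=roster, censored=diff.censored)
        ll = od.oada_loglik(data, {}, [])
        n = len(roster)
        expect = sum(np.log(1.0 / (n - k)) for k in range(len(diff.order)))
        assert ll == pytest.approx(expect, abs=1e-12)


class TestAcquisitionOrder:
    def _visits(self, rows):
        df = pd.DataFrame(rows, columns=["bird_id", "time", "colour"])
        df["phase"] = "reversal"
        df["species"] = "A"
        df["age"] = "adult"
        return df

    def test_single_bird(self):
        data = od.build_acquisition_order(
            self._visits([("b1", 5.0, "blue")]), "blue")
        assert data.order == ["b1"] and data.n_events == 1

    def test_interleaved_revisits_hand_oracle(self):
        rows = [("b2", 1.0, "purple"), ("b1", 2.0, "blue"),
                ("b2", 3.0, "blue"), ("b1", 4.0, "blue"),
                ("b3", 5.0, "blue"), ("b2", 6.0, "blue")]
        data = od.build_acquisition_order(self._visits(rows), "blue")
        assert data.order == ["b1", "b2", "b3"]
        assert data.times == [2.0, 3.0, 5.0]

    def test_exact_ties_are_an_error_naming_birds(self):
        rows = [("b1", 2.0, "blue"), ("b2", 2.0, "blue")]
        with pytest.raises(TieError, match="b1.*b2"):
            od.build_acquisition_order(self._visits(rows), "blue")
        data = od.build_acquisition_order(self._visits(rows), "blue",
                                          tie_break=True)
        assert data.order == ["b1", "b2"]

    def test_censored_nonvisitors_enter_risk_sets(self):
        roster = toy_roster(4)
        data = od.build_acquisition_order(
            self._visits([("b1", 1.0, "blue")]), "blue", roster=roster)
        assert set(data.censored) == {"b2", "b3", "b4"}
        ll = od.oada_loglik(data, {}, [])
        assert ll == pytest.approx(np.log(1 / 4))


class TestFitAndProfile:
    def test_asocial_diffusion_prefers_asocial_model(self):
        """s = 0 generation: the asocial model sits within dAICc 2 of the
        best model in most replicates and s-hat is near 0."""
        wins = 0
        s_hats = []
        for seed in range(12):
            cfg = fl.SimConfig(n_birds=25, seed=seed, s_true={"all": 0.0})
            roster, net = fl.simulate_population(cfg)
            diff = fl.simulate_reversal_diffusion(roster, net, cfg)
            am = AssociationMatrix(birds=list(roster["bird_id"]), weights=net)
            data = od.AcquisitionData(order=diff.order, times=diff.times,
                                      roster=roster, censored=diff.censored)
            m_a = od.fit_oada(data, od.OadaSpec(network_class="asocial"))
            m_s = od.fit_oada(data, od.OadaSpec(network_class="observed"),
                              network=am, seed=seed)
            s_hats.append(m_s.s["all"])
            wins += m_a.aicc <= m_s.aicc + 2.0
        assert wins >= 8
        assert np.median(s_hats) < 1.0

    def test_profile_ci_boundary_and_bracketing(self):
        cfg = fl.SimConfig(n_birds=20, seed=13)
        roster, net = fl.simulate_population(cfg)
        diff = fl.simulate_reversal_diffusion(roster, net, cfg)
        am = AssociationMatrix(birds=list(roster["bird_id"]), weights=net)
        data = od.AcquisitionData(order=diff.order, times=diff.times,
                                  roster=roster, censored=diff.censored)
        m = od.fit_oada(data, od.OadaSpec(network_class="observed", by_age=True),
                        network=am, seed=0)
        for lab in ("adult", "juvenile"):
            lo, hi = od.profile_ci(m, lab)
            assert lo <= m.s[lab] <= hi
            if m.boundary[lab]:
                assert lo == 0.0

    def test_unknown_labels_rejected(self, three_birds):
        roster, net, data = three_birds
        with pytest.raises(SpecificationError):
            od.OadaSpec(network_class="bogus")
        with pytest.raises(SpecificationError):
            od.OadaSpec(network_class="asocial", ilv="social")
        m = od.fit_oada(data, od.OadaSpec(network_class="observed"),
                        network=AssociationMatrix(
                            birds=list(roster["bird_id"]), weights=net))
        with pytest.raises(SpecificationError):
            od.profile_ci(m, "nonexistent")


class TestPercentSocial:
    def test_zero_s_gives_zero_percent(self, three_birds):
        roster, net, data = three_birds
        am = AssociationMatrix(birds=list(roster["bird_id"]), weights=net)
        m = od.OadaModel(spec=od.OadaSpec(network_class="observed"),
                         s={"all": 0.0}, beta_asocial=0.0, beta_social=0.0,
                         loglik=0.0, n_events=2, data=data,
                         networks={"all": net})
        assert od.percent_social(m)["all"]["percent"] == 0.0

    def test_hand_computed_attribution(self, three_birds):
        """s = 1 in the 3-bird toy: event 1 acquirer b2 has rate 1 + 1 with
        social share 1/2; event 2 acquirer b3 has share 0."""
        roster, net, data = three_birds
        m = od.OadaModel(spec=od.OadaSpec(network_class="observed"),
                         s={"all": 1.0}, beta_asocial=0.0, beta_social=0.0,
                         loglik=0.0, n_events=2, data=data,
                         networks={"all": net})
        assert od.percent_social(m)["all"]["percent"] == \
            pytest.approx(100 * 0.5 * (0.5 + 0.0))

    def test_saturating_s_approaches_hundred(self, three_birds):
        """With s enormous and nonzero connections at every event the social
        share of each acquisition tends to 100%."""
        roster, net, data = three_birds
        w = np.full((3, 3), 1.0)
        np.fill_diagonal(w, 0.0)
        m = od.OadaModel(spec=od.OadaSpec(network_class="observed"),
                         s={"all": 1e9}, beta_asocial=0.0, beta_social=0.0,
                         loglik=0.0, n_events=2, data=data,
                         networks={"all": w})
        assert od.percent_social(m)["all"]["percent"] == \
            pytest.approx(100.0, abs=1e-5)


class TestModelSetReport:
    def test_twin_models_share_weight(self):
        cfg = fl.SimConfig(n_birds=20, seed=19)
        roster, net = fl.simulate_population(cfg)
        diff = fl.simulate_reversal_diffusion(roster, net, cfg)
        am = AssociationMatrix(birds=list(roster["bird_id"]), weights=net)
        data = od.AcquisitionData(order=diff.order, times=diff.times,
                                  roster=roster, censored=diff.censored)
        m1 = od.fit_oada(data, od.OadaSpec(network_class="observed"),
                         network=am, seed=0)
        m2 = od.fit_oada(data, od.OadaSpec(network_class="observed"),
                         network=am, seed=1)
        tab = od.model_set_report([m1, m2])
        np.testing.assert_allclose(tab["weight"], [0.5, 0.5], atol=1e-6)

    def test_report_weights_and_class_sums(self, three_birds):
        """Report weights follow exp(-dAICc/2) normalisation and summed
        class weights add to 1."""
        roster, net, data = three_birds
        spec_o = od.OadaSpec(network_class="observed")
        spec_a = od.OadaSpec(network_class="asocial")
        m1 = od.OadaModel(spec=spec_o, s={"all": 1.0}, beta_asocial=0.0,
                          beta_social=0.0, loglik=-10.0, n_events=20,
                          data=data, networks={"all": net})
        m2 = od.OadaModel(spec=spec_a, s={}, beta_asocial=0.0,
                          beta_social=0.0, loglik=-10.0, n_events=20,
                          data=data, networks={})
        tab = od.model_set_report([m1, m2])
        d = tab["dAICc"].to_numpy()
        w = np.exp(-0.5 * d)
        np.testing.assert_allclose(tab["weight"], w / w.sum(), atol=1e-12)
        assert sum(tab.attrs["class_weights"].values()) == pytest.approx(1.0)
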