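import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

from oscmem.cli import main as cli_main
from oscmem.experiments import (EXPERIMENTS, ExperimentSpec, make_fixture,
                                run_experiment)
from oscmem.simulator import SimConfig, SimResult, simulate


class TestFixtures:
    def test_locked_train_is_periodic_two_per_cycle(self):
        fx = make_fixture("locked_train")
        T = 2 * math.pi / fx["omega"]
        sp = fx["spikes"]
        assert np.all(np.diff(sp) > 0)
        # exactly two spikes in every full period
        per_cycle = np.histogram(sp, bins=np.arange(sp[0] - 0.3 * T,
                                                    sp[-1] + T, T))[0]
        assert np.all(per_cycle[per_cycle > 0] == 2)

    def test_mini_ring_matches_builder_constants(self):
        fx = make_fixture("mini_ring")
        W, N, A, B = fx["W"], fx["N"], fx["A"], fx["B"]
        assert W.shape == (N, N)
        assert W[0, 0] == pytest.approx(A + B)
        assert W[0, N // 2] == pytest.approx(A - B)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("nope")

    def test_mini_network_population_equals_autapse(self):
        """Homogeneous all-to-all network reproduces the autapse exactly.

        With identical phases and initial conditions every neuron follows
        the same trajectory and the summed recurrent input equals the
        autapse feedback, so even individual spike times coincide.
        """
        fx = make_fixture("mini_network")
        ds = fx["params"]["alpha_syn"] * fx["params"]["tau_syn"] * \
            fx["drive"].omega / (2 * math.pi)
        cfg = SimConfig(duration=1500.0, record_V=5.0)
        net = simulate(fx["model"], W=fx["W"], drives=fx["drive"],
                       config=cfg, init={"s": 1.25 * ds})
        aut = simulate(fx["autapse"], W=[[fx["w"]]], drives=fx["drive"],
                       config=cfg, init={"s": 1.25 * ds})
        assert len(aut.spikes[0]) > 0
        for i in range(fx["model"].N):
            assert np.allclose(net.spikes[i], aut.spikes[0], atol=1e-6)
        pop_rate = np.mean([len(sp) for sp in net.spikes])
        assert pop_rate == len(aut.spikes[0])


class TestRegistry:
    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError):
            ExperimentSpec(name="fig9_unknown")
        with pytest.raises(ValueError):
            ExperimentSpec(name="fig6_network/bogus")

    def test_known_names_accepted(self):
        for name in EXPERIMENTS:
            ExperimentSpec(name=name)

    def test_seeded_rerun_is_identical(self):
        """The same spec and seed reproduce the result bit for bit."""
        spec = dict(name="fig6_network/weight_noise", seed=11, n_neurons=40,
                    overrides={"noise_to_mean": 2.0})
        a = run_experiment(ExperimentSpec(**spec))
        b = run_experiment(ExperimentSpec(**spec))
        assert a["summary"]["window_rates_hz"] == b["summary"]["window_rates_hz"]
        assert np.array_equal(a["result"].all_spikes(),
                              b["result"].all_spikes())


class TestPersistence:
    def test_bundle_written_to_outdir(self, tmp_path):
        spec = ExperimentSpec(name="fig4_if_phaselock", seed=2,
                              outdir=str(tmp_path))
        bundle = run_experiment(spec)
        summary = json.loads(
            (tmp_path / "fig4_if_phaselock_summary.json").read_text())
        assert summary["summary"]["leaky_has_plateaus"] is True
        csvs = list(tmp_path.glob("*.csv"))
        assert len(csvs) >= 2  # both staircases exported as text tables


class TestCLI:
    def test_defaults_and_fixtures_commands(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["defaults"])
        assert res.exit_code == 0
        assert json.loads(res.output)["wb_autapse"]["tau_syn"] == 150.0
        res = runner.invoke(cli_main, ["fixtures", "--kind", "mini_ring"])
        assert res.exit_code == 0

    def test_run_command_writes_summary(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "run", "--name", "fig6_network/sparsity", "--seed", "4",
            "--n-neurons", "40", "--outdir", str(tmp_path), "--quiet"])
        assert res.exit_code == 0, res.output
        out = json.loads(res.output)
        assert "held_levels" in out["summary"]
        assert (tmp_path / "fig6_network_sparsity_summary.json").exists()

    def test_config_file_validation(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("not_a_parameter: 3\n")
        runner = CliRunner()
        res = runner.invoke(cli_main, ["run", "--name", "fig2_staircase",
                                       "--config", str(bad)])
        assert res.exit_code != 0

    def test_analyze_round_trip(self, tmp_path, autapse):
        params, model, w, drive = autapse
        res = simulate(model, W=[[w]], drives=drive,
                       config=SimConfig(duration=800.0), init={"s": 0.18})
        path = tmp_path / "res.h5"
        res.save(path)
        runner = CliRunner()
        out = runner.invoke(cli_main, ["analyze", str(path)])
        assert out.exit_code == 0, out.output
        report = json.loads(out.output)
        assert report["neurons"] == 1
        assert report["total_spikes"] == len(res.spikes[0])
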