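"""Model assembly, genome codec, session runs and readout inverses."""

import numpy as np
import pytest

import timesense as ts
from timesense.architecture import (
    decode_genome,
    encode_genome,
    lift_genomes,
    load_genomes,
    save_genomes,
)
from timesense.ctrnn import ModuleState, step_module
from timesense.targets import distance_target_trace, duration_target_trace


class TestSpecLayout:
    def test_model1_module_census(self, model1_spec):
        assert len(model1_spec.modules) == 8
        assert model1_spec.module("tSen1").n_neurons == 16
        assert model1_spec.module("tSen2").n_neurons == 16
        for i in range(6):
            assert model1_spec.module(f"tDuration{i+1}").n_neurons == 2
        assert model1_spec.n_neurons == 44

    def test_model2_module_census(self, model2_spec):
        assert len(model2_spec.modules) == 16
        for hub in ("tDuration", "tDistance"):
            assert model2_spec.module(hub).n_neurons == 16
        assert model2_spec.n_neurons == 88

    def test_parameter_counts_hand_computed(self, model1_spec, model2_spec):
        # tSen1: 16x4 sensory + 16x(16+16) presynaptic + 16 biases = 592
        assert model1_spec.genome_length("tSen1") == 16 * 4 + 16 * 32 + 16
        # tSen2: no sensory inputs, same recurrent pool = 528
        assert model1_spec.genome_length("tSen2") == 16 * 32 + 16
        # event module: 2x7 sensory (tone + 6 ids) + 2x(2+16) + 2 = 52
        assert model1_spec.genome_length("tDuration1") == 2 * 7 + 2 * 18 + 2
        assert model1_spec.total_parameters == 592 + 528 + 6 * 52
        # combined model: hubs add 528 each; event modules gain a hub block
        assert model2_spec.genome_length("tDuration") == 16 * 32 + 16
        assert model2_spec.genome_length("tDuration1") == 2 * 7 + 2 * 34 + 2
        assert model2_spec.total_parameters == 592 + 528 + 2 * 528 + 12 * 84

    def test_oscillators_feed_only_time_sense(self, model1_spec, model2_spec):
        for spec in (model1_spec, model2_spec):
            for m in spec.modules:
                osc = set(range(4))
                if m.name == "tSen1":
                    assert set(m.ext_channels) == osc
                else:
                    assert not osc & set(m.ext_channels)

    def test_tone_and_ids_feed_event_modules(self, model2_spec):
        for m in model2_spec.modules:
            if m.name.startswith(("tDuration", "tDistance")) and m.name[-1].isdigit():
                assert set(m.ext_channels) == set(range(4, 11))

    def test_downstream_closure(self, model1_spec):
        # a time-sense candidate affects everything; a leaf only itself
        assert model1_spec.downstream_rows("tSen1").size == 44
        np.testing.assert_array_equal(
            model1_spec.downstream_rows("tDuration3"),
            model1_spec.rows("tDuration3"),
        )


class TestGenomeCodec:
    def test_round_trip_identity_every_module(self, model2_spec, rng):
        for m in model2_spec.modules:
            vec = rng.normal(size=model2_spec.genome_length(m.name))
            ws, wp, theta = decode_genome(model2_spec, m.name, vec)
            back = encode_genome(model2_spec, m.name, ws, wp, theta)
            np.testing.assert_array_equal(back, vec)

    def test_wrong_length_names_module(self, model1_spec):
        with pytest.raises(ValueError, match="tSen2"):
            decode_genome(model1_spec, "tSen2", np.zeros(10))

    def test_missing_genome_rejected(self, model1_spec, rng):
        genomes = {
            m.name: np.zeros(model1_spec.genome_length(m.name))
            for m in model1_spec.modules
        }
        del genomes["tDuration4"]
        with pytest.raises(ValueError, match="tDuration4"):
            ts.AssembledModel(model1_spec, genomes)

    def test_genome_file_round_trip(self, model1_spec, rng, tmp_path):
        genomes = {
            m.name: rng.normal(size=model1_spec.genome_length(m.name))
            for m in model1_spec.modules
        }
        path = tmp_path / "genomes.json"
        save_genomes(path, model1_spec, genomes, metadata={"seed": 3})
        spec2, genomes2, meta = load_genomes(path)
        assert spec2 == model1_spec
        assert meta["seed"] == 3
        for name in genomes:
            np.testing.assert_allclose(genomes2[name], genomes[name])


class TestRunSession:
    def test_zero_genome_stays_at_half(self, model1_spec, random_session):
        genomes = {
            m.name: np.zeros(model1_spec.genome_length(m.name))
            for m in model1_spec.modules
        }
        model = ts.AssembledModel(model1_spec, genomes)
        trace = model.run_session(random_session)
        np.testing.assert_allclose(trace.acts, 0.5)

    def test_deterministic(self, random_model, random_session):
        a = random_model.run_session(random_session)
        b = random_model.run_session(random_session)
        np.testing.assert_array_equal(a.acts, b.acts)

    def test_matches_per_module_stepping(self, random_model, random_session):
        """The dense kernel equals composing step_module over all modules."""
        spec = random_model.spec
        inputs = random_session.inputs
        states = {}
        for m in spec.modules:
            _, params = random_model.module_wiring(m.name)
            states[m.name] = ModuleState.zeros(params)
        A = np.concatenate([states[m.name].activation for m in spec.modules])
        ref = [A]
        for t in range(200):
            new = {}
            for m in spec.modules:
                wiring, params = random_model.module_wiring(m.name)
                aff = A[spec.afferent_columns(m.name)]
                ext = (
                    inputs[t, np.array(m.ext_channels)]
                    if m.ext_channels
                    else np.zeros(0)
                )
                new[m.name] = step_module(states[m.name], wiring, params, ext, aff)
            states = new
            A = np.concatenate([states[m.name].activation for m in spec.modules])
            ref.append(A)
        trace = random_model.run_session(random_session)
        np.testing.assert_allclose(trace.acts[:201], np.stack(ref), atol=1e-12)

    def test_update_order_independence(self, random_session, rng):
        """Permuting the module list leaves every module's trace unchanged."""
        spec = ts.interval_timing_model()
        genomes = {
            m.name: rng.normal(0, 0.5, spec.genome_length(m.name))
            for m in spec.modules
        }
        base = ts.AssembledModel(spec, genomes).run_session(random_session)

        perm = list(spec.modules)
        order = np.random.default_rng(0).permutation(len(perm))
        spec_p = ts.ModelSpec(
            name=spec.name,
            modules=tuple(perm[i] for i in order),
            n_events=spec.n_events,
            n_channels=spec.n_channels,
        )
        shuffled = ts.AssembledModel(spec_p, genomes).run_session(random_session)
        for m in spec.modules:
            np.testing.assert_allclose(
                base.module_activations(m.name),
                shuffled.module_activations(m.name),
                atol=1e-12,
            )

    def test_channel_count_mismatch_raises(self, random_model):
        with pytest.raises(ValueError, match="channels"):
            random_model.run_session(np.zeros((100, 5)))


class TestReadouts:
    def _oracle_trace(self, spec, sched):
        """A trace whose readout rows carry the exact target signals."""
        T = sched.horizon
        acts = np.full((T + 1, spec.n_neurons), 0.5)
        D = duration_target_trace(sched)
        for i in range(sched.n_events):
            line = int(sched.event_ids[i])
            acts[1:, spec.readout_row("dur", line)] = D[i]
        if any(m.name == "tDistance1" for m in spec.modules):
            TD = distance_target_trace(sched)
            for i in range(sched.n_events):
                line = int(sched.event_ids[i])
                acts[1:, spec.readout_row("dist", line)] = TD[i]
        return ts.SessionTrace(spec=spec, acts=acts, schedule=sched)

    def test_duration_readout_inverts_target(self, model1_spec, rng):
        sched = ts.generate_schedule(rng)
        trace = self._oracle_trace(model1_spec, sched)
        for i in range(6):
            est = ts.read_duration(trace, i, sched)
            assert est == pytest.approx(float(sched.durations[i]), abs=1e-9)

    def test_plateau_084_reads_42_moments(self, model1_spec):
        sched = ts.EventSchedule(starts=np.array([443]), ends=np.array([485]))
        trace = self._oracle_trace(model1_spec, sched)
        assert ts.read_duration(trace, 0, sched) == pytest.approx(42.0)

    def test_duration_readout_requires_ended_event(self, model1_spec):
        sched = ts.EventSchedule(
            starts=np.array([980]), ends=np.array([999]), horizon=1000
        )
        trace = self._oracle_trace(model1_spec, sched)
        short = ts.SessionTrace(
            spec=model1_spec, acts=trace.acts[:999], schedule=sched
        )
        with pytest.raises(ValueError, match="not ended"):
            ts.read_duration(short, 0, sched)

    def test_distance_readout_inverts_target(self, model2_spec, rng):
        sched = ts.generate_schedule(rng)
        trace = self._oracle_trace(model2_spec, sched)
        for i in range(6):
            st_i = int(sched.starts[i])
            for t in (st_i + 50, 800, 999):
                if t <= st_i or t >= trace.horizon:
                    continue
                est = ts.read_distance(trace, i, t, sched)
                assert est == pytest.approx(t - st_i, abs=1e-6)

    def test_distance_worked_example(self, model2_spec):
        """An output of 0.353 at moment 1000 decodes to ~557 moments back."""
        sched = ts.EventSchedule(
            starts=np.array([443]), ends=np.array([485]), horizon=1001
        )
        acts = np.full((1002, model2_spec.n_neurons), 0.5)
        acts[:, model2_spec.readout_row("dist", 0)] = 0.353
        trace = ts.SessionTrace(spec=model2_spec, acts=acts, schedule=sched)
        est = ts.read_distance(trace, 0, 1000, sched)
        assert est == pytest.approx(557, abs=1.0)

    def test_distance_before_onset_rejected(self, model2_spec):
        sched = ts.EventSchedule(starts=np.array([443]), ends=np.array([485]))
        trace = self._oracle_trace(model2_spec, sched)
        with pytest.raises(ValueError, match="onset"):
            ts.read_distance(trace, 0, 443, sched)


class TestLifting:
    def test_lifted_model_reproduces_interval_model(self, rng, random_session):
        """Adding the distance branch with zeroed new links changes nothing
        on the duration pathway."""
        spec1 = ts.interval_timing_model()
        spec2 = ts.when_and_how_long_model()
        genomes1 = {
            m.name: rng.normal(0, 0.5, spec1.genome_length(m.name))
            for m in spec1.modules
        }
        lifted = lift_genomes(spec1, spec2, genomes1)
        for m in spec2.modules:
            if m.name not in lifted:
                lifted[m.name] = np.zeros(spec2.genome_length(m.name))
        t1 = ts.AssembledModel(spec1, genomes1).run_session(random_session)
        t2 = ts.AssembledModel(spec2, lifted).run_session(random_session)
        for name in ("tSen1", "tSen2", *(f"tDuration{i+1}" for i in range(6))):
            np.testing.assert_allclose(
                t1.module_activations(name),
                t2.module_activations(name),
                atol=1e-12,
            )
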