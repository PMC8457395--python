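"""Model initialization, forward-pass symmetries, training contracts."""

import numpy as np
import pytest

from shiftgnn import (
    Conformer,
    ModelConfig,
    Molecule,
    build_graph,
    evaluate,
    forward,
    load_checkpoint,
    make_labelled,
    save_checkpoint,
    train,
)
from shiftgnn import synthetic as syn
from shiftgnn.gnn import ChemicalShiftModel, LabelledGraph, init_model

from conftest import random_rotation


class TestInit:
    def test_seeded_determinism(self, tiny_config):
        assert init_model(tiny_config).checksum() == init_model(tiny_config).checksum()

    def test_different_seeds_differ(self, tiny_config):
        import dataclasses

        other = dataclasses.replace(tiny_config, seed=99)
        assert init_model(tiny_config).checksum() != init_model(other).checksum()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(feature_dim=0)
        with pytest.raises(ValueError):
            ModelConfig(readout_layer_widths=(256, 2))

    def test_every_tensor_carries_one_group_label(self, tiny_params):
        from shiftgnn.gnn import PARAM_GROUPS

        assert set(tiny_params.groups) == set(tiny_params.tensors)
        assert set(tiny_params.groups.values()) <= set(PARAM_GROUPS)
        assert tiny_params.n_params == sum(
            t.size for t in tiny_params.tensors.values()
        )


class TestForward:
    def test_empty_target_mask_gives_empty_output(self, tiny_params, rbf16):
        mol = Molecule(id="oo", elements=["O", "O"])
        conf = Conformer("oo", np.array([[0.0, 0, 0], [1.2, 0, 0]]))
        graph = build_graph(conf, mol, rbf16, "C13")
        assert forward(tiny_params, graph).size == 0

    def test_rigid_motion_invariance(self, tiny_params, rbf16):
        mol, (conf, _) = syn.make_fixture("cyclohexane_chair_boat")
        ref = forward(tiny_params, build_graph(conf, mol, rbf16, "C13"))
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(25):
            moved = conf.coords @ random_rotation(rng).T + rng.normal(0, 10, 3)
            got = forward(
                tiny_params, build_graph(Conformer(mol.id, moved), mol, rbf16, "C13")
            )
            worst = max(worst, np.max(np.abs(got - ref)))
        assert worst < 1e-5

    def test_permutation_equivariance(self, tiny_params, rbf16):
        mol, (conf, _) = syn.make_fixture("butane_anti_gauche")
        ref = forward(tiny_params, build_graph(conf, mol, rbf16, "C13"))
        rng = np.random.default_rng(6)
        for _ in range(5):
            perm = rng.permutation(mol.n_atoms)
            pmol = Molecule(id=mol.id, elements=[None] * mol.n_atoms)
            pcoords = np.empty_like(conf.coords)
            for old, new in enumerate(perm):
                pmol.elements[new] = mol.elements[old]
                pcoords[new] = conf.coords[old]
            got = forward(
                tiny_params, build_graph(Conformer(mol.id, pcoords), pmol, rbf16, "C13")
            )
            # align predictions through the permutation of target atoms
            old_targets = [i for i in range(mol.n_atoms) if mol.elements[i] == "C"]
            new_targets = sorted(perm[i] for i in old_targets)
            mapping = {perm[i]: ref[k] for k, i in enumerate(old_targets)}
            expected = np.array([mapping[j] for j in new_targets])
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_locality_beyond_message_range(self, tiny_params, rbf16):
        mol, (conf,) = syn.make_fixture("methane")
        ref = forward(tiny_params, build_graph(conf, mol, rbf16, "C13"))
        far = Molecule(id="m2", elements=mol.elements + ["O"])
        coords = np.vstack([conf.coords, [60.0, 0.0, 0.0]])
        got = forward(tiny_params, build_graph(Conformer("m2", coords), far, rbf16, "C13"))
        assert np.max(np.abs(got - ref)) < 1e-5

    def test_nucleus_mismatch_rejected(self, tiny_params, rbf16):
        mol, (conf,) = syn.make_fixture("methane")
        graph = build_graph(conf, mol, rbf16, "H1")
        with pytest.raises(ValueError, match="nucleus"):
            forward(tiny_params, graph)

    def test_predictions_cover_only_target_element(self, tiny_params, rbf16):
        mol, (conf,) = syn.make_fixture("valine_like")
        graph = build_graph(conf, mol, rbf16, "C13")
        assert all(mol.elements[i] == "C" for i in graph.target_indices)
        assert forward(tiny_params, graph).shape == (5,)


class TestEvaluate:
    @pytest.fixture()
    def pair_graph(self, tiny_params, rbf16):
        mol = Molecule(id="cc", elements=["C", "C"])
        conf = Conformer("cc", np.array([[0.0, 0, 0], [1.5, 0, 0]]))
        graph = build_graph(conf, mol, rbf16, "C13")
        pred = forward(tiny_params, graph)
        return graph, pred

    def test_perfect_predictions_score_zero(self, tiny_params, pair_graph):
        graph, pred = pair_graph
        mae, rmse = evaluate(tiny_params, [LabelledGraph(graph, [0, 1], pred)])
        assert mae == pytest.approx(0.0, abs=1e-9)
        assert rmse == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_unit_errors(self, tiny_params, pair_graph):
        graph, pred = pair_graph
        mae, rmse = evaluate(
            tiny_params, [LabelledGraph(graph, [0, 1], pred + np.array([1.0, -1.0]))]
        )
        assert mae == pytest.approx(1.0, abs=1e-9)
        assert rmse == pytest.approx(1.0, abs=1e-9)

    def test_rmse_dominates_mae(self, tiny_params, pair_graph):
        graph, pred = pair_graph
        mae, rmse = evaluate(
            tiny_params, [LabelledGraph(graph, [0, 1], pred + np.array([0.0, 2.0]))]
        )
        assert mae == pytest.approx(1.0, abs=1e-9)
        assert rmse == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_empty_data_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            evaluate(tiny_params, [])


class TestTrain:
    def test_loss_decreases_on_learnable_target(self, tiny_params, tiny_oracle_data):
        fitted, report = train(
            tiny_params, tiny_oracle_data[:32], tiny_oracle_data[32:],
            n_epochs=25, batch_size=8, lr=3e-3, seed=1,
        )
        assert report.train_loss[-1] < report.train_loss[0]
        assert report.best_epoch <= report.n_epochs

    def test_full_freeze_returns_bitwise_identical_model(self, tiny_params, tiny_oracle_data):
        fitted, _ = train(
            tiny_params, tiny_oracle_data[:8],
            n_epochs=3, batch_size=4, freeze=set(tiny_params.tensors), seed=2,
        )
        for name, t in tiny_params.tensors.items():
            assert np.array_equal(fitted.tensors[name], t)

    def test_training_is_reproducible(self, tiny_params, tiny_oracle_data):
        runs = [
            train(tiny_params, tiny_oracle_data[:8], n_epochs=3, batch_size=4, seed=5)
            for _ in range(2)
        ]
        assert runs[0][0].checksum() == runs[1][0].checksum()
        assert runs[0][1].train_loss == runs[1][1].train_loss

    def test_input_params_not_mutated(self, tiny_params, tiny_oracle_data):
        before = tiny_params.checksum()
        train(tiny_params, tiny_oracle_data[:8], n_epochs=2, batch_size=4, seed=1)
        assert tiny_params.checksum() == before

    def test_empty_training_set_rejected(self, tiny_params):
        with pytest.raises(ValueError, match="empty"):
            train(tiny_params, [])

    def test_nan_loss_aborts_with_diagnostics(self, tiny_params, tiny_oracle_data):
        broken = tiny_params.copy()
        broken.tensors["readout.W0"][0, 0] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            train(broken, tiny_oracle_data[:8], n_epochs=1, batch_size=4, seed=1)


class TestCheckpoint:
    def test_roundtrip_is_bitwise(self, tmp_path, tiny_params):
        p = tmp_path / "model.npz"
        tiny_params.lineage["note"] = "base"
        save_checkpoint(tiny_params, p)
        back = load_checkpoint(p)
        assert back.checksum() == tiny_params.checksum()
        assert back.config == tiny_params.config
        assert back.groups == tiny_params.groups
        assert back.lineage == tiny_params.lineage

    def test_rejects_foreign_archive(self, tmp_path):
        p = tmp_path / "x.npz"
        np.savez(p, __meta__=np.frombuffer(b'{"format": "other"}', dtype=np.uint8))
        with pytest.raises(ValueError, match="checkpoint"):
            load_checkpoint(p)


class TestModelResultsSurface:
    def test_fit_returns_results_with_summary(self, tiny_config, tiny_oracle_data):
        model = ChemicalShiftModel(tiny_oracle_data[:16], tiny_oracle_data[16:24],
                                   tiny_config)
        res = model.fit(n_epochs=5, batch_size=8, seed=3)
        text = res.summary()
        assert "val MAE" in text and "parameters" in text
        mae, rmse = res.evaluate(tiny_oracle_data[24:])
        assert rmse >= mae > 0

    def test_predict_conformer_emits_records(self, tiny_config, tiny_oracle_data, rbf16):
        res = ChemicalShiftModel(tiny_oracle_data[:8], config=tiny_config).fit(
            n_epochs=2, batch_size=4, seed=1
        )
        mol, (conf,) = syn.make_fixture("methane")
        recs = res.predict_conformer(mol, conf, rbf16)
        assert len(recs) == 1
        assert recs[0].provenance == "predicted"
        assert recs[0].nucleus == "C13"
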