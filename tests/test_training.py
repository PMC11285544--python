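"""Loss identities, gradient-penalty oracles, and the staged training loop."""

import dataclasses
import hashlib

import numpy as np
import pytest

import liggen.autodiff as ad
from liggen.autodiff import Tensor
from liggen import (
    LigandGraph,
    ModelDims,
    TrainingConfig,
    discriminator_loss,
    energy_loss,
    generator_loss,
    gradient_penalty,
    interpolate,
    train,
)
from liggen.networks import NetConfig
from liggen.training import gradient_penalty_t, stack_graphs

from conftest import random_valid_graph


@pytest.fixture(scope="module")
def graph_pair(toy_dims):
    rng = np.random.default_rng(0)
    return (random_valid_graph(toy_dims, rng),
            random_valid_graph(toy_dims, rng))


# -- simple critics with known gradient fields ----------------------------

def constant_critic(atoms, bonds):
    return ad.mul(ad.sum_(atoms, axis=(1, 2)), 0.0)


def make_unit_gradient_critic(dims: ModelDims):
    n_entries = (dims.n_atoms * dims.n_atom_types
                 + dims.n_atoms ** 2 * dims.n_bond_types)
    c = 1.0 / np.sqrt(n_entries)

    def critic(atoms, bonds):
        return ad.mul(ad.add(ad.sum_(atoms, axis=(1, 2)),
                             ad.sum_(bonds, axis=(1, 2, 3))), c)

    return critic


def make_linear_critic(dims: ModelDims, seed: int):
    rng = np.random.default_rng(seed)
    wa = rng.normal(size=(dims.n_atoms, dims.n_atom_types))
    wb = rng.normal(size=(dims.n_atoms, dims.n_atoms, dims.n_bond_types))

    def critic(atoms, bonds):
        return ad.add(ad.sum_(ad.mul(atoms, Tensor(wa)), axis=(1, 2)),
                      ad.sum_(ad.mul(bonds, Tensor(wb)), axis=(1, 2, 3)))

    return critic, wa, wb


class TestInterpolate:
    def test_boundaries_reproduce_endpoints(self, graph_pair):
        y, y_fake = graph_pair
        at_one = interpolate(y, y_fake, 1.0)
        at_zero = interpolate(y, y_fake, 0.0)
        assert np.array_equal(at_one.atom_probs, y.atoms)
        assert np.array_equal(at_zero.bond_probs, y_fake.bonds)

    def test_midpoint_splits_mass(self, toy_dims, graph_pair):
        y, y_fake = graph_pair
        mid = interpolate(y, y_fake, 0.5)
        i = 0
        k, l = np.argmax(y.atoms[i]), np.argmax(y_fake.atoms[i])
        if k != l:
            assert mid.atom_probs[i, k] == 0.5 and mid.atom_probs[i, l] == 0.5
        assert np.allclose(mid.atom_probs.sum(axis=1), 1.0)

    def test_epsilon_out_of_range(self, graph_pair):
        with pytest.raises(ValueError):
            interpolate(*graph_pair, epsilon=1.5)


class TestGradientPenalty:
    def test_constant_critic_pays_full_penalty(self, toy_dims, graph_pair):
        """Zero critic gradient leaves (||g|| - 1)^2 = 1, so the penalty is
        exactly lambda = 10 at the default weight."""
        pen = gradient_penalty(constant_critic, [graph_pair[0]],
                               [graph_pair[1]], 10.0,
                               np.random.default_rng(0))
        assert pen == pytest.approx(10.0, abs=1e-4)

    def test_unit_gradient_critic_pays_nothing(self, toy_dims, graph_pair):
        critic = make_unit_gradient_critic(toy_dims)
        pen = gradient_penalty(critic, [graph_pair[0]], [graph_pair[1]],
                               10.0, np.random.default_rng(1))
        assert pen == pytest.approx(0.0, abs=1e-9)

    def test_matches_central_difference_norm(self, toy_dims, graph_pair):
        """Autodiff gradient norm inside the penalty agrees with a
        central-difference estimate on a small random critic."""
        rng = np.random.default_rng(2)
        w = rng.normal(size=(toy_dims.n_atom_types, 4))
        v = rng.normal(size=4)

        def critic(atoms, bonds):
            h = ad.tanh(ad.matmul(atoms, Tensor(w)))
            per_atom = ad.matmul(h, Tensor(v.reshape(-1, 1)))
            bond_term = ad.sum_(ad.mul(bonds, bonds), axis=(1, 2, 3))
            return ad.add(ad.sum_(per_atom, axis=(1, 2)), bond_term)

        atoms_r, bonds_r = graph_pair[0].atoms, graph_pair[0].bonds
        atoms_f, bonds_f = graph_pair[1].atoms, graph_pair[1].bonds
        eps_draw = np.random.default_rng(33).uniform(size=1)[0]
        hat = interpolate(graph_pair[0], graph_pair[1], eps_draw)

        def f(a, b):
            return float(critic(Tensor(a[None]), Tensor(b[None])).data[0])

        # numeric gradient over every coordinate
        num = []
        h = 1e-5
        for arr, other, is_atom in ((hat.atom_probs, hat.bond_probs, True),
                                    (hat.bond_probs, hat.atom_probs, False)):
            flat = arr.flatten()
            for idx in range(flat.size):
                up, dn = flat.copy(), flat.copy()
                up[idx] += h
                dn[idx] -= h
                if is_atom:
                    num.append((f(up.reshape(arr.shape), hat.bond_probs)
                                - f(dn.reshape(arr.shape), hat.bond_probs))
                               / (2 * h))
                else:
                    num.append((f(hat.atom_probs, up.reshape(arr.shape))
                                - f(hat.atom_probs, dn.reshape(arr.shape)))
                               / (2 * h))
        num_norm = np.linalg.norm(num)

        class FixedEps:
            def uniform(self, lo, hi, size):
                return np.full(size, eps_draw)

        pen = gradient_penalty_t(critic, atoms_r[None], bonds_r[None],
                                 atoms_f[None], bonds_f[None], 10.0,
                                 FixedEps())
        implied_norm = 1.0 + np.sqrt(float(pen.data) / 10.0) * np.sign(
            num_norm - 1.0)
        assert implied_norm == pytest.approx(num_norm, abs=1e-4)


class TestDiscriminatorLoss:
    def test_zero_critic_reduces_to_penalty(self, toy_dims, graph_pair):
        cfg = TrainingConfig(batch_size=1)
        loss = discriminator_loss(constant_critic, [graph_pair[0]],
                                  [graph_pair[1]], cfg,
                                  np.random.default_rng(3))
        assert loss == pytest.approx(cfg.lambda_gp, abs=1e-4)

    def test_unit_gradient_equal_scores_is_zero(self, toy_dims):
        critic = make_unit_gradient_critic(toy_dims)
        g = random_valid_graph(toy_dims, np.random.default_rng(4))
        cfg = TrainingConfig(batch_size=1)
        loss = discriminator_loss(critic, [g], [g], cfg,
                                  np.random.default_rng(5))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_linear_critic(self, toy_dims):
        critic, wa, wb = make_linear_critic(toy_dims, seed=6)
        rng = np.random.default_rng(7)
        reals = [random_valid_graph(toy_dims, rng) for _ in range(2)]
        fakes = [random_valid_graph(toy_dims, rng) for _ in range(2)]
        cfg = TrainingConfig(batch_size=2, lambda_gp=0.0)
        loss = discriminator_loss(critic, reals, fakes, cfg,
                                  np.random.default_rng(8))
        by_hand = np.mean([(wa * f.atoms).sum() + (wb * f.bonds).sum()
                           for f in fakes]) - np.mean(
            [(wa * r.atoms).sum() + (wb * r.bonds).sum() for r in reals])
        assert loss == pytest.approx(by_hand, abs=1e-9)

    def test_empty_batch_rejected(self, toy_dims):
        cfg = TrainingConfig(batch_size=1)
        with pytest.raises(ValueError):
            discriminator_loss(constant_critic, [], [], cfg,
                               np.random.default_rng(0))


def make_fixed_energy(value_real: float, value_fake: float):
    """Energy stub returning a fixed value per call order (real first)."""
    calls = []

    def energy_fn(x, atoms, bonds):
        v = value_real if not calls else value_fake
        calls.append(v)
        return ad.mul(ad.sum_(atoms, axis=(1, 2)), 0.0) + v

    return energy_fn


class TestEnergyLoss:
    def test_equal_energies_leave_only_regulariser(self, toy_dims, graph_pair):
        fn = make_fixed_energy(2.0, 2.0)
        le, lenergy, mse = energy_loss(fn, None, [graph_pair[0]],
                                       [graph_pair[1]], alpha_l2=0.001)
        assert lenergy == pytest.approx(0.0, abs=1e-9)
        assert mse == pytest.approx(2 * 0.001 * 4.0, abs=1e-9)
        assert le == pytest.approx(mse, abs=1e-9)

    def test_unit_separation_at_default_alpha(self, toy_dims, graph_pair):
        fn = make_fixed_energy(0.0, 1.0)
        le, lenergy, mse = energy_loss(fn, None, [graph_pair[0]],
                                       [graph_pair[1]], alpha_l2=0.001)
        assert lenergy == pytest.approx(-1.0, abs=1e-9)
        assert mse == pytest.approx(0.001, abs=1e-9)
        assert le == pytest.approx(-0.999, abs=1e-9)

    def test_alpha_zero_reduces_to_contrastive_term(self, toy_dims,
                                                    graph_pair):
        fn = make_fixed_energy(0.3, -0.4)
        le, lenergy, _ = energy_loss(fn, None, [graph_pair[0]],
                                     [graph_pair[1]], alpha_l2=0.0)
        assert le == lenergy

    def test_misaligned_batches_rejected(self, toy_dims, graph_pair):
        fn = make_fixed_energy(0.0, 0.0)
        with pytest.raises(ValueError):
            energy_loss(fn, None, [graph_pair[0]],
                        [graph_pair[1], graph_pair[0]], alpha_l2=0.001)


class TestGeneratorLoss:
    def test_beta_zero_is_pure_wgan_term(self, toy_dims, graph_pair):
        critic, wa, wb = make_linear_critic(toy_dims, seed=9)
        f = graph_pair[1]
        loss = generator_loss(critic, energy_loss_value=123.0,
                              fake_batch=[f], beta=0.0)
        assert loss == pytest.approx(-((wa * f.atoms).sum()
                                       + (wb * f.bonds).sum()), abs=1e-9)

    def test_zero_critic_beta_one_returns_energy_loss(self, graph_pair):
        loss = generator_loss(constant_critic, energy_loss_value=-0.75,
                              fake_batch=[graph_pair[0]], beta=1.0)
        assert loss == pytest.approx(-0.75, abs=1e-12)

    def test_hand_computed_two_sample_batch(self, toy_dims):
        critic, wa, wb = make_linear_critic(toy_dims, seed=10)
        rng = np.random.default_rng(11)
        fakes = [random_valid_graph(toy_dims, rng) for _ in range(2)]
        le = 0.42
        loss = generator_loss(critic, le, fakes, beta=2.0)
        d_mean = np.mean([(wa * f.atoms).sum() + (wb * f.bonds).sum()
                          for f in fakes])
        assert loss == pytest.approx(-d_mean + 2.0 * le, abs=1e-9)


# -- the training loop -----------------------------------------------------

def _hash_params(model, owner):
    h = hashlib.sha256()
    for p in model.parameters(owner):
        h.update(p.data.tobytes())
    return h.hexdigest()


@pytest.fixture(scope="module")
def smoke_config():
    return TrainingConfig(k_iterations=2, m_critic_steps=2, batch_size=16,
                          lr_initial=1e-3, seed=0)


class TestTrainLoop:
    def test_smoke_run_completes_with_finite_records(self, toy_dataset,
                                                     toy_dims, tiny_net,
                                                     smoke_config):
        result = train(toy_dataset, toy_dims, smoke_config, tiny_net)
        assert len(result.records) == 2
        assert all(r.is_finite() for r in result.records)
        assert not result.stopped_early

    def test_identical_seeds_identical_traces(self, toy_dataset, toy_dims,
                                              tiny_net, smoke_config):
        r1 = train(toy_dataset, toy_dims, smoke_config, tiny_net)
        r2 = train(toy_dataset, toy_dims, smoke_config, tiny_net)
        for a, b in zip(r1.records, r2.records):
            assert a == b

    def test_stage_updates_freeze_other_owners(self, toy_dataset, toy_dims,
                                               tiny_net, smoke_config):
        """After the critic stage the generator/encoder/energy parameters
        are bit-identical; after the generator stage the critic/energy
        parameters are bit-identical (and so on)."""
        before = {}
        touched = {"critic": set(), "energy": set(), "generator": set()}

        def callback(stage, step, model):
            now = {o: _hash_params(model, o) for o in model.OWNERS}
            if before:
                for owner, digest in now.items():
                    if digest != before[owner]:
                        touched[stage].add(owner)
            before.update(now)

        train(toy_dataset, toy_dims, smoke_config, tiny_net,
              stage_callback=callback)
        assert touched["critic"] <= {"critic"}
        assert touched["energy"] <= {"energy"}
        assert touched["generator"] <= {"generator", "encoder"}
        assert "critic" in touched["critic"]
        assert "generator" in touched["generator"]

    def test_dataset_smaller_than_batch_rejected(self, toy_dataset, toy_dims,
                                                 tiny_net):
        cfg = TrainingConfig(k_iterations=1, batch_size=1000)
        with pytest.raises(ValueError):
            train(toy_dataset, toy_dims, cfg, tiny_net)

    def test_divergence_triggers_early_stop(self, toy_dataset, toy_dims,
                                            tiny_net, monkeypatch,
                                            smoke_config):
        import liggen.training as tr

        def bad_loss(*args, **kwargs):
            nan = Tensor(np.nan)
            return nan, nan

        monkeypatch.setattr(tr, "discriminator_loss_t", bad_loss)
        cfg = dataclasses.replace(smoke_config, k_iterations=5)
        result = tr.train(toy_dataset, toy_dims, cfg, tiny_net)
        assert result.stopped_early
        assert len(result.records) == 1

    def test_learning_rate_milestone_drop(self, toy_dataset, toy_dims,
                                          tiny_net):
        """With the milestone at epoch 0 every stage must use the decayed
        learning rate."""
        cfg = TrainingConfig(k_iterations=1, m_critic_steps=1, batch_size=16,
                             lr_initial=1e-3, lr_after_milestone=1e-5,
                             lr_milestone_epoch=0, seed=1)
        seen = []

        import liggen.training as tr
        orig = tr._adam_step

        def spy(opt, loss, params, lr):
            seen.append(lr)
            return orig(opt, loss, params, lr)

        tr._adam_step = spy
        try:
            tr.train(toy_dataset, toy_dims, cfg, tiny_net)
        finally:
            tr._adam_step = orig
        assert seen and all(lr == 1e-5 for lr in seen)

    def test_checkpoint_and_trace_written(self, toy_dataset, toy_dims,
                                          tiny_net, smoke_config, tmp_path):
        train(toy_dataset, toy_dims, smoke_config, tiny_net,
              out_dir=tmp_path)
        assert (tmp_path / "checkpoint.npz").exists()
        trace = (tmp_path / "loss_trace.csv").read_text()
        assert "loss_d" in trace and "mse_term" in trace
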