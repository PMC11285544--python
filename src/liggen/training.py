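"""Loss functions and the staged adversarial training loop.

One training iteration performs three stages in order:

1. ``m`` critic steps minimising the Wasserstein critic loss with gradient
   penalty, ``L_D = D(fake) - D(real) + lambda (||grad D(x_hat)|| - 1)^2``,
   updating only the critic;
2. one energy step minimising ``L_E = L_energy + alpha (E(x,y)^2 +
   E(x,y_hat)^2)`` with the contrastive term ``L_energy = E(x, y) -
   E(x, y_hat)`` (one generator fake per real pair), updating only the
   energy network;
3. one generator step minimising ``L_G = -D(fake) + beta E_guid``,
   updating the generator and the protein encoder jointly, where
   ``E_guid = mean E(x, y_hat)`` is the energy guidance: the generator is
   pulled toward ligands the energy network scores as compatible
   (low-energy) with their targets.

On the energy guidance: substituting the contrastive ``L_E`` itself into
the generator objective would flip the sign of the fake term (the
generator would then *raise* fake energies, cooperating with the energy
network's contrastive push until both saturate at the L2 equilibrium
``1/(2 alpha)`` and swamp the critic signal — measurably destabilising
training).  Guidance toward low fake energy is the energy-based reading of
"generated ligands should be compatible with their targets" and keeps the
energies bounded; see the methods note.

Each stage owns its optimiser, so the other parameter sets are untouched
bit-for-bit.  All stochasticity flows from a single seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor, grad
from .molgraph import (
    DenseMolDistribution,
    LigandGraph,
    ModelDims,
    PairedSample,
)
from .networks import Model, NetConfig, stack_clouds

#: signature of a critic callable used by the loss helpers
CriticFn = Callable[[Tensor, Tensor], Tensor]


@dataclass
class TrainingConfig:
    """All training hyperparameters.

    ``lambda_gp`` weights the gradient penalty, ``alpha_l2`` the energy
    L2 regulariser, ``beta_energy`` the energy term inside the generator
    loss (0 drops the energy network entirely).  ``m_critic_steps`` inner
    critic updates per iteration.  The learning rate starts at
    ``lr_initial`` and drops to ``lr_after_milestone`` once the epoch
    counter passes ``lr_milestone_epoch``.
    """

    lambda_gp: float = 10.0
    alpha_l2: float = 0.001
    beta_energy: float = 1.0
    k_iterations: int | None = None
    m_critic_steps: int = 5
    batch_size: int = 64
    lr_initial: float = 1e-4
    lr_after_milestone: float = 1e-5
    lr_milestone_epoch: int = 200
    max_epochs: int = 1000
    adam_betas: tuple[float, float] = (0.5, 0.999)
    #: consecutive epoch-end FD increases tolerated before stopping; the
    #: monitor only runs when the schedule is long enough to ever trigger it
    early_stop_patience: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.lambda_gp < 0 or self.alpha_l2 < 0 or self.beta_energy < 0:
            raise ValueError("loss weights must be non-negative")
        if self.m_critic_steps < 1 or self.batch_size < 1:
            raise ValueError("m_critic_steps and batch_size must be >= 1")


@dataclass
class LossRecord:
    """Per-iteration trace of every loss component and energy statistic."""

    step: int
    epoch: int
    loss_d: float
    loss_g: float
    loss_energy: float
    mse_term: float
    loss_e: float
    mean_energy_real: float
    mean_energy_fake: float
    gradient_penalty: float

    def is_finite(self) -> bool:
        return all(math.isfinite(v) for v in
                   (self.loss_d, self.loss_g, self.loss_e))


# ---------------------------------------------------------------------------
# batch helpers
# ---------------------------------------------------------------------------

def stack_graphs(graphs: Sequence[LigandGraph]) -> tuple[np.ndarray, np.ndarray]:
    """Stack ligand graphs into (B, N, A) and (B, N, N, B) arrays."""
    if not graphs:
        raise ValueError("empty batch")
    return (np.stack([g.atoms for g in graphs]),
            np.stack([g.bonds for g in graphs]))


def _dense_parts(y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, LigandGraph):
        return y.atoms, y.bonds
    if isinstance(y, DenseMolDistribution):
        return y.atom_probs, y.bond_probs
    atoms, bonds = y
    return np.asarray(atoms, float), np.asarray(bonds, float)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def interpolate(y, y_fake, epsilon: float) -> DenseMolDistribution:
    """Convex combination ``eps * y + (1 - eps) * y_fake`` of two graphs."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    ra, rb = _dense_parts(y)
    fa, fb = _dense_parts(y_fake)
    return DenseMolDistribution(
        atom_probs=epsilon * ra + (1 - epsilon) * fa,
        bond_probs=epsilon * rb + (1 - epsilon) * fb,
    )


def gradient_penalty_t(critic: CriticFn, atoms_real: np.ndarray,
                       bonds_real: np.ndarray, atoms_fake: np.ndarray,
                       bonds_fake: np.ndarray, lambda_gp: float,
                       rng: np.random.Generator) -> Tensor:
    """Differentiable batch-mean gradient penalty.

    Interpolates real and fake samples with one uniform epsilon per pair,
    differentiates the critic with respect to the full interpolated input
    (atom and bond entries jointly), and returns
    ``lambda * mean((||grad||_2 - 1)^2)`` as a graph node so critic
    parameters receive second-order gradients.
    """
    B = atoms_real.shape[0]
    eps = rng.uniform(0.0, 1.0, size=B)
    ea = eps[:, None, None]
    eb = eps[:, None, None, None]
    hat_atoms = Tensor(ea * atoms_real + (1 - ea) * atoms_fake,
                       requires_grad=True)
    hat_bonds = Tensor(eb * bonds_real + (1 - eb) * bonds_fake,
                       requires_grad=True)
    scores = critic(hat_atoms, hat_bonds)
    ga, gb = grad(ad.sum_(scores), [hat_atoms, hat_bonds])
    sq = ad.add(ad.sum_(ad.mul(ga, ga), axis=(1, 2)),
                ad.sum_(ad.mul(gb, gb), axis=(1, 2, 3)))
    norm = ad.sqrt(ad.add(sq, 1e-12))
    pen = ad.mean(ad.power(ad.sub(norm, 1.0), 2.0))
    return ad.mul(pen, float(lambda_gp))


def gradient_penalty(critic: CriticFn, y_batch, fake_batch,
                     lambda_gp: float, rng: np.random.Generator) -> float:
    """Numpy-facing gradient penalty over aligned real/fake batches."""
    ra, rb = _batch_arrays(y_batch)
    fa, fb = _batch_arrays(fake_batch)
    return float(gradient_penalty_t(critic, ra, rb, fa, fb,
                                    lambda_gp, rng).data)


def _batch_arrays(batch) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(batch, (list, tuple)) and batch and isinstance(
            batch[0], (LigandGraph, DenseMolDistribution)):
        parts = [_dense_parts(g) for g in batch]
        return np.stack([p[0] for p in parts]), np.stack([p[1] for p in parts])
    atoms, bonds = batch
    return np.asarray(atoms, float), np.asarray(bonds, float)


def discriminator_loss_t(critic: CriticFn, atoms_real, bonds_real,
                         atoms_fake, bonds_fake, config: TrainingConfig,
                         rng: np.random.Generator) -> tuple[Tensor, Tensor]:
    """(L_D, penalty): mean D(fake) - mean D(real) + gradient penalty."""
    d_real = ad.mean(critic(Tensor(atoms_real), Tensor(bonds_real)))
    d_fake = ad.mean(critic(Tensor(atoms_fake), Tensor(bonds_fake)))
    pen = gradient_penalty_t(critic, atoms_real, bonds_real,
                             atoms_fake, bonds_fake, config.lambda_gp, rng)
    return ad.add(ad.sub(d_fake, d_real), pen), pen


def discriminator_loss(critic: CriticFn, y_batch, fake_batch,
                       config: TrainingConfig,
                       rng: np.random.Generator) -> float:
    ra, rb = _batch_arrays(y_batch)
    fa, fb = _batch_arrays(fake_batch)
    if ra.shape[0] == 0:
        raise ValueError("empty batch")
    loss, _ = discriminator_loss_t(critic, ra, rb, fa, fb, config, rng)
    return float(loss.data)


def energy_loss_t(e_real: Tensor, e_fake: Tensor,
                  alpha_l2: float) -> tuple[Tensor, Tensor, Tensor]:
    """(L_E, L_energy, mse_term) from per-pair energy scores."""
    l_energy = ad.sub(ad.mean(e_real), ad.mean(e_fake))
    mse = ad.mul(ad.add(ad.mean(ad.mul(e_real, e_real)),
                        ad.mean(ad.mul(e_fake, e_fake))), float(alpha_l2))
    return ad.add(l_energy, mse), l_energy, mse


def energy_loss(energy_fn, x_batch, y_batch, fake_batch,
                alpha_l2: float) -> tuple[float, float, float]:
    """Contrastive energy loss over aligned batches.

    ``energy_fn(x, atoms, bonds) -> Tensor`` scores each (protein, ligand)
    pair; real and fake batches must align pairwise with ``x_batch``.
    """
    ra, rb = _batch_arrays(y_batch)
    fa, fb = _batch_arrays(fake_batch)
    if ra.shape[0] != fa.shape[0]:
        raise ValueError("real and fake batches must align pairwise")
    xt = None if x_batch is None else Tensor(np.asarray(x_batch, float))
    if xt is not None and xt.shape[0] != ra.shape[0]:
        raise ValueError("x_batch misaligned with ligand batches")
    e_real = energy_fn(xt, Tensor(ra), Tensor(rb))
    e_fake = energy_fn(xt, Tensor(fa), Tensor(fb))
    le, lenergy, mse = energy_loss_t(e_real, e_fake, alpha_l2)
    return float(le.data), float(lenergy.data), float(mse.data)


def generator_loss_t(d_fake_mean: Tensor, loss_e: Tensor | float,
                     beta: float) -> Tensor:
    return ad.add(ad.neg(d_fake_mean), ad.mul(loss_e, float(beta)))


def generator_loss(critic: CriticFn, energy_loss_value: float,
                   fake_batch, beta: float) -> float:
    """-mean D(fake) + beta * L_E for an already-computed energy loss."""
    fa, fb = _batch_arrays(fake_batch)
    d_fake = ad.mean(critic(Tensor(fa), Tensor(fb)))
    return float(generator_loss_t(d_fake, float(energy_loss_value), beta).data)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: Model
    records: list[LossRecord]
    stopped_early: bool = False
    fd_trace: list[tuple[int, float]] = field(default_factory=list)


def _fd_features(atoms: np.ndarray, bonds: np.ndarray) -> np.ndarray:
    """Vectorised per-molecule count features for the training monitor."""
    mask = atoms[..., -1] < 0.5
    atom_counts = (atoms * mask[..., None]).sum(axis=1)
    atom_counts[:, -1] = 0.0
    iu = np.triu_indices(atoms.shape[1], k=1)
    bond_counts = bonds[:, iu[0], iu[1], :].sum(axis=1)
    return np.concatenate([atom_counts, bond_counts], axis=1)


def _adam_step(opt: Adam, loss: Tensor, params: list[Tensor], lr: float) -> None:
    opt.lr = lr
    opt.step(grad(loss, params))


def train(dataset: Sequence[PairedSample], dims: ModelDims,
          config: TrainingConfig, net_config: NetConfig | None = None,
          model: Model | None = None,
          out_dir: str | Path | None = None,
          stage_callback: Callable[[str, int, Model], None] | None = None
          ) -> TrainResult:
    """Run the staged adversarial loop on a paired dataset.

    Returns the trained model and one :class:`LossRecord` per iteration.
    Training stops early when any loss becomes non-finite.  When
    ``out_dir`` is given, the final checkpoint and the loss trace (CSV)
    are written there.  ``stage_callback(stage, step, model)`` fires after
    each update stage (``"critic"``, ``"energy"``, ``"generator"``), e.g.
    to audit which parameter sets each stage touched.
    """
    if len(dataset) < config.batch_size:
        raise ValueError("dataset smaller than one batch")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = Model(dims, net_config, seed=config.seed,
                      build_energy=config.beta_energy > 0)

    iters_per_epoch = max(1, len(dataset) // config.batch_size)
    k = config.k_iterations
    if k is None:
        k = config.max_epochs * iters_per_epoch

    opt_d = Adam(model.parameters("critic"), config.lr_initial,
                 config.adam_betas)
    opt_e = Adam(model.parameters("energy"), config.lr_initial,
                 config.adam_betas) if model.energy is not None else None
    gen_params = model.parameters("generator") + model.parameters("encoder")
    opt_g = Adam(gen_params, config.lr_initial, config.adam_betas)

    # protein tensors are static; stack once
    clouds = [s.protein for s in dataset]
    all_atoms, all_bonds = stack_graphs([s.ligand for s in dataset])
    coords, types_oh, mask = stack_clouds(clouds)
    if model.encoder is not None and (mask.sum(axis=1) == 0).any():
        raise ValueError("dataset contains an all-pad protein cloud")

    def encode(idx) -> Tensor | None:
        if model.encoder is None:
            return None
        return model.encoder.forward_t(Tensor(coords[idx]),
                                       Tensor(types_oh[idx]),
                                       Tensor(mask[idx]))

    def make_fakes(idx):
        x = encode(idx)
        z = Tensor(rng.standard_normal((len(idx), dims.z_dim)))
        fa, fb = model.generate_st_t(x, z, rng)
        return x, fa, fb

    critic_fn = model.critic.score_t
    records: list[LossRecord] = []
    fd_trace: list[tuple[int, float]] = []
    stopped = False

    # FD divergence monitor: one fixed subset, its own deterministic stream;
    # skipped when the run is too short for the patience rule to ever fire
    total_epochs = k // iters_per_epoch
    monitor_on = bool(config.early_stop_patience) and (
        total_epochs > config.early_stop_patience)
    mon_idx = np.arange(min(128, len(dataset)))
    mon_rng = np.random.default_rng([config.seed, 1])
    real_mon_feats = _fd_features(all_atoms[mon_idx], all_bonds[mon_idx])
    fd_streak = 0
    fd_last = None
    for step in range(k):
        epoch = step // iters_per_epoch
        lr = (config.lr_initial if epoch < config.lr_milestone_epoch
              else config.lr_after_milestone)

        # -- stage (a): m critic updates -----------------------------
        loss_d_val = pen_val = math.nan
        for _ in range(config.m_critic_steps):
            idx = rng.choice(len(dataset), size=config.batch_size,
                             replace=False)
            _, fa, fb = make_fakes(idx)
            loss_d, pen = discriminator_loss_t(
                critic_fn, all_atoms[idx], all_bonds[idx],
                fa.data, fb.data, config, rng)  # fakes detached for D step
            _adam_step(opt_d, loss_d, opt_d.params, lr)
            loss_d_val, pen_val = float(loss_d.data), float(pen.data)
        if stage_callback is not None:
            stage_callback("critic", step, model)

        # -- stage (b): energy update --------------------------------
        idx = rng.choice(len(dataset), size=config.batch_size, replace=False)
        le_val = lenergy_val = mse_val = 0.0
        er_val = ef_val = math.nan
        if model.energy is not None:
            x, fa, fb = make_fakes(idx)
            xd = None if x is None else Tensor(x.data)
            e_real = model.energy.energy_t(xd, Tensor(all_atoms[idx]),
                                           Tensor(all_bonds[idx]))
            e_fake = model.energy.energy_t(xd, Tensor(fa.data), Tensor(fb.data))
            le, lenergy, mse = energy_loss_t(e_real, e_fake, config.alpha_l2)
            _adam_step(opt_e, le, opt_e.params, lr)
            le_val, lenergy_val, mse_val = (float(le.data),
                                            float(lenergy.data),
                                            float(mse.data))
            er_val = float(e_real.data.mean())
            ef_val = float(e_fake.data.mean())
        if stage_callback is not None:
            stage_callback("energy", step, model)

        # -- stage (c): generator + encoder update -------------------
        x, fa, fb = make_fakes(idx)
        d_fake = ad.mean(critic_fn(fa, fb))
        if model.energy is not None and config.beta_energy > 0:
            e_fake = model.energy.energy_t(x, fa, fb)
            guidance = ad.mean(e_fake)  # pull fakes to low (compatible) energy
        else:
            guidance = Tensor(0.0)
        loss_g = generator_loss_t(d_fake, guidance, config.beta_energy)
        _adam_step(opt_g, loss_g, opt_g.params, lr)
        if stage_callback is not None:
            stage_callback("generator", step, model)

        rec = LossRecord(step=step, epoch=epoch, loss_d=loss_d_val,
                         loss_g=float(loss_g.data), loss_energy=lenergy_val,
                         mse_term=mse_val, loss_e=le_val,
                         mean_energy_real=er_val, mean_energy_fake=ef_val,
                         gradient_penalty=pen_val)
        records.append(rec)
        if not rec.is_finite():
            stopped = True  # learning diverged
            break
        if monitor_on and (step + 1) % iters_per_epoch == 0:
            from .evaluation import frechet_distance

            x = encode(mon_idx)
            z = Tensor(mon_rng.standard_normal((len(mon_idx), dims.z_dim)))
            fa, fb = model.generate_st_t(
                None if x is None else Tensor(x.data), z, mon_rng)
            fd = frechet_distance(real_mon_feats,
                                  _fd_features(fa.data, fb.data))
            fd_trace.append((epoch, fd))
            fd_streak = fd_streak + 1 if (fd_last is not None
                                          and fd > fd_last) else 0
            fd_last = fd
            if fd_streak >= config.early_stop_patience:
                stopped = True  # FD kept rising for `patience` epochs
                break

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "checkpoint.npz",
                   extra={"training_config": asdict(config),
                          "rng_state": rng.bit_generator.state})
        write_trace(records, out / "loss_trace.csv")
    return TrainResult(model=model, records=records, stopped_early=stopped,
                       fd_trace=fd_trace)


def write_trace(records: list[LossRecord], path: str | Path) -> None:
    """Write per-iteration loss records as CSV."""
    import pandas as pd

    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)
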