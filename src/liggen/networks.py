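"""The four model networks and their composition.

* ``Encoder``     — deterministic, permutation-invariant map from a protein
                    point cloud to a low-dimensional embedding ``x``;
* ``Generator``   — latent-variable ligand generator: ``[x ‖ z]`` through a
                    stack of linear layers into dense atom/bond
                    probabilities (early fusion, two output heads);
* ``Critic``      — unbounded Wasserstein critic over ligand graphs (real
                    one-hot or relaxed dense), no protein conditioning;
* ``EnergyNet``   — scalar binding-energy surrogate E(x, y); low energy
                    means the ligand is compatible with the target.

All forward passes run on autodiff tensors so the training loop can reach
every parameter, including the encoder's (end-to-end conditioning).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .gnn import GNNStack, graph_readout_t
from .io_prep import OTHER_ELEMENT_CODE
from .molgraph import (
    DenseMolDistribution,
    LigandGraph,
    ModelDims,
    NO_BOND,
    ProteinCloud,
    straight_through_sample,
)

#: protein element codes 0..OTHER are one-hot encoded for the encoder
N_PROTEIN_CODES = OTHER_ELEMENT_CODE + 1
_COORD_SCALE = 0.05  # angstrom -> O(1) features


@dataclass
class NetConfig:
    """Architecture hyperparameters shared by all four networks."""

    gen_hidden: tuple[int, ...] = (128, 256, 512)
    enc_hidden: tuple[int, ...] = (64,)
    enc_atom_feat: int = 32
    head_hidden: tuple[int, ...] = (32,)
    gnn_layers: int = 3
    backbone: str = "gat"
    self_loops: bool = True
    leaky_slope: float = 0.2
    temperature: float = 1.0


def _glorot(rng: np.random.Generator, fi: int, fo: int) -> Tensor:
    return Tensor(rng.normal(0, np.sqrt(2.0 / (fi + fo)), (fi, fo)),
                  requires_grad=True)


class _MLP:
    """Linear stack with LeakyReLU between layers (not after the last)."""

    def __init__(self, rng, sizes: tuple[int, ...], slope: float):
        self.slope = slope
        self.layers = [(_glorot(rng, fi, fo),
                        Tensor(np.zeros(fo), requires_grad=True))
                       for fi, fo in zip(sizes[:-1], sizes[1:])]

    def __call__(self, h: Tensor) -> Tensor:
        for i, (W, b) in enumerate(self.layers):
            h = ad.add(ad.matmul(h, W), b)
            if i < len(self.layers) - 1:
                h = ad.leaky_relu(h, self.slope)
        return h

    def parameters(self) -> list[Tensor]:
        return [t for pair in self.layers for t in pair]


# ---------------------------------------------------------------------------
# protein encoder
# ---------------------------------------------------------------------------

class Encoder:
    """Shared per-atom MLP + masked mean/max pooling + linear projection.

    Per-atom inputs are the scaled coordinates concatenated with the
    element-code one-hot; pooling makes the embedding invariant to the
    order of protein atoms and independent of pad rows.
    """

    def __init__(self, dims: ModelDims, cfg: NetConfig, rng):
        self.dims = dims
        in_dim = 3 + N_PROTEIN_CODES
        self.atom_mlp = _MLP(rng, (in_dim, *cfg.enc_hidden, cfg.enc_atom_feat),
                             cfg.leaky_slope)
        self.proj = _MLP(rng, (2 * cfg.enc_atom_feat, dims.x_dim),
                         cfg.leaky_slope)
        self.slope = cfg.leaky_slope

    def parameters(self) -> list[Tensor]:
        return self.atom_mlp.parameters() + self.proj.parameters()

    def forward_t(self, coords: Tensor, types_oh: Tensor, mask: Tensor) -> Tensor:
        feats = ad.concat([ad.mul(coords, _COORD_SCALE), types_oh], axis=-1)
        h = ad.leaky_relu(self.atom_mlp(feats), self.slope)
        pooled = graph_readout_t(h, mask)
        return self.proj(pooled)


def stack_clouds(clouds: list[ProteinCloud]):
    """Stack protein clouds into (coords, one-hot types, mask) arrays."""
    coords = np.stack([c.coords for c in clouds])
    types = np.stack([c.atom_types for c in clouds])
    mask = np.stack([c.mask for c in clouds])
    types_oh = np.eye(N_PROTEIN_CODES)[np.clip(types, 0, N_PROTEIN_CODES - 1)]
    return coords, types_oh, mask


def encoder_forward(x_p: ProteinCloud, encoder: Encoder) -> np.ndarray:
    """Embed one protein cloud; deterministic and permutation-invariant."""
    if x_p.n_real() == 0:
        raise ValueError("cannot encode an all-pad protein cloud")
    coords, types_oh, mask = stack_clouds([x_p])
    return encoder.forward_t(Tensor(coords), Tensor(types_oh),
                             Tensor(mask)).data[0]


# ---------------------------------------------------------------------------
# ligand generator
# ---------------------------------------------------------------------------

class Generator:
    """Early-fused ``[x ‖ z]`` trunk with separate atom and bond heads.

    Bond logits are symmetrized by averaging with their transpose before
    the per-pair softmax, so the output distribution is symmetric by
    construction.
    """

    def __init__(self, dims: ModelDims, cfg: NetConfig, rng):
        self.dims = dims
        in_dim = dims.x_dim + dims.z_dim
        self.trunk = _MLP(rng, (in_dim, *cfg.gen_hidden), cfg.leaky_slope)
        last = cfg.gen_hidden[-1]
        N, A, B = dims.n_atoms, dims.n_atom_types, dims.n_bond_types
        self.atom_head = _MLP(rng, (last, N * A), cfg.leaky_slope)
        self.bond_head = _MLP(rng, (last, N * N * B), cfg.leaky_slope)
        self.slope = cfg.leaky_slope

    def parameters(self) -> list[Tensor]:
        return (self.trunk.parameters() + self.atom_head.parameters()
                + self.bond_head.parameters())

    def forward_t(self, x: Tensor | None, z: Tensor) -> tuple[Tensor, Tensor]:
        fused = z if x is None else ad.concat([x, z], axis=-1)
        h = ad.leaky_relu(self.trunk(fused), self.slope)
        N, A, B = self.dims.n_atoms, self.dims.n_atom_types, self.dims.n_bond_types
        batch = z.shape[0]
        atom_logits = ad.reshape(self.atom_head(h), (batch, N, A))
        bond_logits = ad.reshape(self.bond_head(h), (batch, N, N, B))
        bond_logits = ad.mul(ad.add(bond_logits,
                                    ad.swapaxes(bond_logits, 1, 2)), 0.5)
        return ad.softmax(atom_logits, axis=-1), ad.softmax(bond_logits, axis=-1)


def generator_forward(x: np.ndarray | None, z: np.ndarray,
                      generator: Generator) -> DenseMolDistribution:
    """Dense atom/bond probabilities for one (embedding, latent) pair."""
    if x is not None and not np.isfinite(np.asarray(x)).all():
        raise ValueError("non-finite protein embedding")
    if not np.isfinite(np.asarray(z)).all():
        raise ValueError("non-finite latent vector")
    xt = None if x is None else Tensor(np.asarray(x, float)[None])
    ap, bp = generator.forward_t(xt, Tensor(np.asarray(z, float)[None]))
    return DenseMolDistribution(atom_probs=ap.data[0], bond_probs=bp.data[0])


# ---------------------------------------------------------------------------
# critic and energy network
# ---------------------------------------------------------------------------

class Critic:
    def __init__(self, dims: ModelDims, cfg: NetConfig, rng):
        self.gnn = GNNStack(dims, feat_dim=dims.feat_dim,
                            n_layers=cfg.gnn_layers, backbone=cfg.backbone,
                            self_loops=cfg.self_loops,
                            leaky_slope=cfg.leaky_slope,
                            head_hidden=cfg.head_hidden, rng=rng)

    def parameters(self) -> list[Tensor]:
        return self.gnn.parameters()

    def score_t(self, atoms: Tensor, bonds: Tensor) -> Tensor:
        return self.gnn.score_t(atoms, bonds)


def critic_forward(g: LigandGraph | DenseMolDistribution,
                   critic: Critic) -> float:
    """Unbounded critic score; accepts hard graphs or relaxed inputs."""
    if isinstance(g, DenseMolDistribution):
        atoms, bonds = g.atom_probs, g.bond_probs
    else:
        atoms, bonds = g.atoms, g.bonds
    return float(critic.score_t(Tensor(atoms[None]),
                                Tensor(bonds[None])).data[0])


class EnergyNet:
    """GNN readout of the ligand concatenated with the protein embedding,
    through an MLP head to a scalar energy."""

    def __init__(self, dims: ModelDims, cfg: NetConfig, rng):
        self.dims = dims
        self.gnn = GNNStack(dims, feat_dim=dims.feat_dim,
                            n_layers=cfg.gnn_layers, backbone=cfg.backbone,
                            self_loops=cfg.self_loops,
                            leaky_slope=cfg.leaky_slope,
                            head_hidden=None, rng=rng)
        in_dim = 2 * self.gnn.feat_dim + dims.x_dim
        self.head = _MLP(rng, (in_dim, *cfg.head_hidden, 1), cfg.leaky_slope)

    def parameters(self) -> list[Tensor]:
        return self.gnn.parameters() + self.head.parameters()

    def energy_t(self, x: Tensor | None, atoms: Tensor, bonds: Tensor) -> Tensor:
        g = self.gnn.readout_t(atoms, bonds)
        if x is not None:
            g = ad.concat([g, x], axis=-1)
        return ad.reshape(self.head(g), (g.shape[0],))


def energy_forward(x: np.ndarray | None, g: LigandGraph,
                   energy: EnergyNet) -> float:
    xt = None if x is None else Tensor(np.asarray(x, float)[None])
    return float(energy.energy_t(xt, Tensor(g.atoms[None]),
                                 Tensor(g.bonds[None])).data[0])


# ---------------------------------------------------------------------------
# straight-through sampling inside the graph
# ---------------------------------------------------------------------------

def straight_through_t(atom_probs: Tensor, bond_probs: Tensor,
                       temperature: float, rng: np.random.Generator,
                       pad_index: int) -> tuple[Tensor, Tensor]:
    """Hard one-hot forward value with relaxed (Gumbel-softmax) gradients.

    Bond noise is drawn on the upper triangle and mirrored so the relaxed
    sample stays symmetric; the hard sample forces the diagonal and every
    pad-involving pair to no-bond.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    B_, N, A = atom_probs.shape
    nb = bond_probs.shape[-1]

    def gumbel(shape):
        return -np.log(-np.log(rng.uniform(1e-12, 1.0, size=shape)))

    log_a = ad.log(ad.add(atom_probs, 1e-12))
    soft_a = ad.softmax(ad.mul(ad.add(log_a, Tensor(gumbel((B_, N, A)))),
                               1.0 / temperature), axis=-1)

    gb = gumbel((B_, N, N, nb))
    iu = np.triu_indices(N, k=1)
    gb_sym = np.zeros_like(gb)
    gb_sym[:, iu[0], iu[1], :] = gb[:, iu[0], iu[1], :]
    gb_sym += np.swapaxes(gb_sym, 1, 2)
    log_b = ad.log(ad.add(bond_probs, 1e-12))
    soft_b = ad.softmax(ad.mul(ad.add(log_b, Tensor(gb_sym)),
                               1.0 / temperature), axis=-1)

    hard_a = np.eye(A)[np.argmax(soft_a.data, axis=-1)]
    hard_b = np.zeros_like(soft_b.data)
    bidx = np.argmax(soft_b.data, axis=-1)
    for b in range(B_):
        hard_b[b, iu[0], iu[1], bidx[b][iu]] = 1.0
    hard_b += np.swapaxes(hard_b, 1, 2)
    diag = np.arange(N)
    hard_b[:, diag, diag, :] = 0.0
    hard_b[:, diag, diag, NO_BOND] = 1.0
    pad = hard_a[:, :, pad_index] > 0.5
    pair_pad = pad[:, :, None] | pad[:, None, :]
    np.copyto(hard_b, 0.0, where=pair_pad[:, :, :, None])
    hard_b[:, :, :, NO_BOND] = np.where(pair_pad, 1.0,
                                        hard_b[:, :, :, NO_BOND])
    hard_b[:, diag, diag, :] = 0.0
    hard_b[:, diag, diag, NO_BOND] = 1.0

    st_atoms = ad.add(soft_a, Tensor(hard_a - soft_a.data))
    st_bonds = ad.add(soft_b, Tensor(hard_b - soft_b.data))
    return st_atoms, st_bonds


# ---------------------------------------------------------------------------
# model bundle
# ---------------------------------------------------------------------------

class Model:
    """Bundle of encoder (optional), generator, critic and energy network.

    With ``dims.x_dim == 0`` no encoder is built and generation is
    unconditional (latent-only), the baseline for the conditioning
    ablation.
    """

    OWNERS = ("encoder", "generator", "critic", "energy")

    def __init__(self, dims: ModelDims, cfg: NetConfig | None = None,
                 seed: int = 0, build_energy: bool = True):
        self.dims = dims
        self.cfg = cfg or NetConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.encoder = Encoder(dims, self.cfg, rng) if dims.x_dim > 0 else None
        self.generator = Generator(dims, self.cfg, rng)
        self.critic = Critic(dims, self.cfg, rng)
        self.energy = EnergyNet(dims, self.cfg, rng) if build_energy else None

    def parameters(self, owner: str) -> list[Tensor]:
        net = getattr(self, {"encoder": "encoder", "generator": "generator",
                             "critic": "critic", "energy": "energy"}[owner])
        return [] if net is None else net.parameters()

    # -- forward helpers ---------------------------------------------
    def encode_clouds_t(self, clouds: list[ProteinCloud]) -> Tensor | None:
        if self.encoder is None:
            return None
        if any(c.n_real() == 0 for c in clouds):
            raise ValueError("cannot encode an all-pad protein cloud")
        coords, types_oh, mask = stack_clouds(clouds)
        return self.encoder.forward_t(Tensor(coords), Tensor(types_oh),
                                      Tensor(mask))

    def generate_st_t(self, x: Tensor | None, z: Tensor,
                      rng: np.random.Generator) -> tuple[Tensor, Tensor]:
        ap, bp = self.generator.forward_t(x, z)
        return straight_through_t(ap, bp, self.cfg.temperature, rng,
                                  self.dims.pad_index)

    def sample_ligands(self, x_p: ProteinCloud, n: int,
                       rng: np.random.Generator,
                       temperature: float | None = None) -> list[LigandGraph]:
        """Draw ``n`` ligand candidates for one protein target."""
        if n < 1:
            raise ValueError("n must be >= 1")
        temperature = temperature or self.cfg.temperature
        x = None
        if self.encoder is not None:
            x = encoder_forward(x_p, self.encoder)
        out = []
        for _ in range(n):
            z = rng.standard_normal(self.dims.z_dim)
            dense = generator_forward(x, z, self.generator)
            out.append(straight_through_sample(dense, temperature, rng))
        return out

    # -- checkpointing -----------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for owner in self.OWNERS:
            for i, p in enumerate(self.parameters(owner)):
                out[f"{owner}.{i}"] = p.data
        return out

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        """Write all four parameter sets plus a versioned JSON manifest.

        ``extra`` lands in the manifest verbatim (e.g. the training
        configuration and RNG state at checkpoint time).
        """
        manifest = {
            "format": "liggen-checkpoint-v1",
            "dims": asdict(self.dims),
            "cfg": asdict(self.cfg),
            "seed": self.seed,
            "has_energy": self.energy is not None,
        }
        if extra:
            manifest["extra"] = extra
        np.savez_compressed(path, manifest=np.array(json.dumps(manifest)),
                            **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            dims = ModelDims(**manifest["dims"])
            cfg_d = manifest["cfg"]
            for key in ("gen_hidden", "enc_hidden", "head_hidden"):
                cfg_d[key] = tuple(cfg_d[key])
            model = cls(dims, NetConfig(**cfg_d), seed=manifest["seed"],
                        build_energy=manifest["has_energy"])
            for owner in cls.OWNERS:
                for i, p in enumerate(model.parameters(owner)):
                    p.data = z[f"{owner}.{i}"].copy()
        return model


def sample_ligands(x_p: ProteinCloud, n: int, rng: np.random.Generator,
                   model: Model) -> list[LigandGraph]:
    """Module-level convenience mirroring :meth:`Model.sample_ligands`."""
    return model.sample_ligands(x_p, n, rng)
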