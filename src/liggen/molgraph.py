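"""Molecular-graph data model for fixed-size one-hot ligand graphs.

A ligand with at most ``N`` heavy atoms is encoded as an atom matrix
``(N, A)`` — one-hot over the element vocabulary plus an explicit pad/empty
category — and a symmetric bond tensor ``(N, N, B)`` — one-hot over bond
types including an explicit no-bond category.  The generator emits dense
probabilities over the same spaces; :func:`straight_through_sample` bridges
the two with a hard Gumbel-softmax draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: heavy-atom element vocabulary; the pad/empty category is appended last
ATOM_TYPES: tuple[str, ...] = ("C", "N", "O", "F", "S", "Cl")
#: bond vocabulary; index 0 is the explicit "no bond" category
BOND_TYPES: tuple[str, ...] = ("none", "single", "double", "triple", "aromatic")
NO_BOND = 0


class GraphShapeError(ValueError):
    """Array shapes disagree with the declared model dimensions."""


@dataclass
class ModelDims:
    """Fixed sizes of the molecular and protein representations.

    ``n_atoms`` is the maximum number of heavy atoms N per ligand;
    ``n_atom_types`` counts the element vocabulary plus the pad category;
    ``n_bond_types`` counts bond categories including no-bond, so the number
    of message-passing relations is ``n_bond_types - 1``.  ``x_dim`` is the
    protein-embedding width (0 disables conditioning) and ``z_dim`` the
    latent width.
    """

    n_atoms: int = 32
    n_atom_types: int = len(ATOM_TYPES) + 1
    n_bond_types: int = len(BOND_TYPES)
    n_protein_atoms: int = 4096
    x_dim: int = 16
    z_dim: int = 32
    feat_dim: int = 64

    def __post_init__(self):
        for name in ("n_atoms", "n_atom_types", "n_bond_types",
                     "n_protein_atoms", "z_dim", "feat_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_atom_types < 2:
            raise ValueError("n_atom_types must be >= 2 (element + pad)")
        if self.n_bond_types < 2:
            raise ValueError("n_bond_types must be >= 2 (no-bond + one bond)")
        if self.x_dim < 0:
            raise ValueError("x_dim must be >= 0")

    @property
    def n_relations(self) -> int:
        """Message-passing relations: bond types without the no-bond slot."""
        return self.n_bond_types - 1

    @property
    def pad_index(self) -> int:
        """Column of the pad/empty atom category (always the last)."""
        return self.n_atom_types - 1


@dataclass
class LigandGraph:
    """One-hot atom matrix ``(N, A)`` and symmetric bond tensor ``(N, N, B)``."""

    atoms: np.ndarray
    bonds: np.ndarray

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        self.bonds = np.asarray(self.bonds, dtype=np.float64)

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    def pad_mask(self) -> np.ndarray:
        """Boolean vector, True for real (non-pad) atoms."""
        return self.atoms[:, -1] < 0.5

    def n_heavy(self) -> int:
        return int(self.pad_mask().sum())


@dataclass
class DenseMolDistribution:
    """Generator output: per-row atom probabilities and per-pair bond
    probabilities, bond fibers symmetric in the first two indices."""

    atom_probs: np.ndarray
    bond_probs: np.ndarray

    def __post_init__(self):
        self.atom_probs = np.asarray(self.atom_probs, dtype=np.float64)
        self.bond_probs = np.asarray(self.bond_probs, dtype=np.float64)


@dataclass
class ProteinCloud:
    """Fixed-size heavy-atom point cloud of a protein target.

    ``coords`` are in angstroms; ``atom_types`` are small integer element
    codes with 0 reserved for padding; ``mask`` flags real atoms.
    """

    coords: np.ndarray
    atom_types: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.atom_types = np.asarray(self.atom_types, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=np.float64)

    def n_real(self) -> int:
        return int(self.mask.sum())


@dataclass
class PairedSample:
    """One training example: a protein cloud and its bound ligand graph."""

    protein: ProteinCloud
    ligand: LigandGraph
    pair_id: str


def validate_ligand_graph(g: LigandGraph, dims: ModelDims) -> list[str]:
    """Check every LigandGraph invariant; return a list of violations.

    An empty list means the graph is valid.  A shape mismatch against
    ``dims`` is a structural error and raises :class:`GraphShapeError`
    instead of being reported as an invariant violation.
    """
    N, A, B = dims.n_atoms, dims.n_atom_types, dims.n_bond_types
    if g.atoms.shape != (N, A):
        raise GraphShapeError(f"atoms shape {g.atoms.shape} != {(N, A)}")
    if g.bonds.shape != (N, N, B):
        raise GraphShapeError(f"bonds shape {g.bonds.shape} != {(N, N, B)}")

    out: list[str] = []
    binary = np.isin(g.atoms, (0.0, 1.0)).all() and np.isin(g.bonds, (0.0, 1.0)).all()
    if not binary:
        out.append("entries must be exactly 0 or 1")

    row_sums = g.atoms.sum(axis=1)
    for i in np.nonzero(row_sums != 1)[0]:
        out.append(f"atom row {i} is not one-hot (sum={row_sums[i]:g})")

    fiber = g.bonds.sum(axis=2)
    for i, j in zip(*np.nonzero(fiber != 1)):
        out.append(f"bond fiber ({i},{j}) is not one-hot (sum={fiber[i, j]:g})")

    asym = np.nonzero(np.any(g.bonds != np.swapaxes(g.bonds, 0, 1), axis=2))
    for i, j in zip(*asym):
        if i < j:
            out.append(f"bond symmetry violated at ({i},{j})")

    diag = np.arange(N)
    bad_diag = np.nonzero(g.bonds[diag, diag, NO_BOND] != 1)[0]
    for i in bad_diag:
        out.append(f"diagonal entry ({i},{i}) is not no-bond")

    pad = ~g.pad_mask()
    if pad.any():
        pair_pad = pad[:, None] | pad[None, :]
        bad = np.nonzero(pair_pad & (g.bonds[:, :, NO_BOND] != 1))
        for i, j in zip(*bad):
            if i <= j:
                out.append(f"pad atom involved in bond at ({i},{j})")
    return out


def validate_dense_distribution(d: DenseMolDistribution, dims: ModelDims,
                                atol: float = 1e-5) -> list[str]:
    """Invariant diagnostics for a dense generator output."""
    N, A, B = dims.n_atoms, dims.n_atom_types, dims.n_bond_types
    if d.atom_probs.shape != (N, A):
        raise GraphShapeError(f"atom_probs shape {d.atom_probs.shape} != {(N, A)}")
    if d.bond_probs.shape != (N, N, B):
        raise GraphShapeError(f"bond_probs shape {d.bond_probs.shape} != {(N, N, B)}")
    out: list[str] = []
    if d.atom_probs.min() < -atol or d.atom_probs.max() > 1 + atol:
        out.append("atom probabilities outside [0, 1]")
    if d.bond_probs.min() < -atol or d.bond_probs.max() > 1 + atol:
        out.append("bond probabilities outside [0, 1]")
    if not np.allclose(d.atom_probs.sum(axis=1), 1.0, atol=atol):
        out.append("atom rows do not sum to 1")
    if not np.allclose(d.bond_probs.sum(axis=2), 1.0, atol=atol):
        out.append("bond fibers do not sum to 1")
    if not np.allclose(d.bond_probs, np.swapaxes(d.bond_probs, 0, 1), atol=atol):
        out.append("bond probabilities not symmetric")
    return out


def _gumbel_argmax(log_probs: np.ndarray, temperature: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Index of the hard Gumbel-softmax sample along the last axis."""
    gumbel = -np.log(-np.log(rng.uniform(1e-12, 1.0, size=log_probs.shape)))
    return np.argmax((log_probs + gumbel) / temperature, axis=-1)


def straight_through_sample(d: DenseMolDistribution, temperature: float,
                            rng: np.random.Generator) -> LigandGraph:
    """Draw a hard one-hot ligand graph from dense probabilities.

    Forward value is a hard categorical (Gumbel-argmax) sample at the given
    temperature.  During training the same draw is re-expressed inside the
    autodiff graph so the backward pass sees the relaxed soft sample
    (straight-through); this function returns only the discrete forward
    value.  Bonds are sampled on the upper triangle and mirrored, the
    diagonal is forced to no-bond, and any pair touching a pad atom is
    forced to no-bond, so the result always satisfies the ligand-graph
    invariants.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if not (np.isfinite(d.atom_probs).all() and np.isfinite(d.bond_probs).all()):
        raise ValueError("non-finite probabilities")

    N, A = d.atom_probs.shape
    B = d.bond_probs.shape[-1]
    log_atom = np.log(np.clip(d.atom_probs, 1e-12, None))
    atom_idx = _gumbel_argmax(log_atom, temperature, rng)
    atoms = np.eye(A)[atom_idx]

    log_bond = np.log(np.clip(d.bond_probs, 1e-12, None))
    bond_idx = _gumbel_argmax(log_bond, temperature, rng)
    iu, ju = np.triu_indices(N, k=1)
    bonds = np.zeros((N, N, B))
    bonds[iu, ju, bond_idx[iu, ju]] = 1.0
    bonds[ju, iu, bond_idx[iu, ju]] = 1.0
    diag = np.arange(N)
    bonds[diag, diag, :] = 0.0
    bonds[diag, diag, NO_BOND] = 1.0

    pad = atoms[:, -1] > 0.5
    if pad.any():
        pair_pad = pad[:, None] | pad[None, :]
        np.copyto(bonds, 0.0, where=pair_pad[:, :, None])
        bonds[:, :, NO_BOND][pair_pad] = 1.0
        bonds[diag, diag, :] = 0.0
        bonds[diag, diag, NO_BOND] = 1.0
    return LigandGraph(atoms=atoms, bonds=bonds)


def relational_adjacency(g: LigandGraph) -> np.ndarray:
    """Per-relation adjacency matrices, shape ``(B-1, N, N)``.

    Relation ``r`` (0-based over bond types excluding no-bond) has a 1 at
    ``(i, j)`` iff the bond fiber is one-hot on that bond type.  Pairs that
    involve pad atoms never carry bonds in a valid graph, so pads are
    automatically excluded.
    """
    adj = np.moveaxis(g.bonds[:, :, 1:], 2, 0)
    return (adj > 0.5).astype(np.float64)
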