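"""Input readers, preprocessing, and the synthetic paired-data generator.

Real data enters as a directory of protein ``.pdb`` files with ligand
``.sdf``/``.mol2`` files (one sub-directory per complex, PDBbind layout).
Preprocessing standardizes each pair to fixed-size tensors: ligands above
the atom budget lose their lowest-degree atoms one at a time; proteins are
cut to the atoms nearest the ligand centroid or zero-padded.

The synthetic generator emulates the same data model with a planted
dependence between a hidden class, the protein point cloud, and the ligand
composition, so that conditional learning is verifiable without any
external download.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .molgraph import (
    ATOM_TYPES,
    BOND_TYPES,
    NO_BOND,
    LigandGraph,
    ModelDims,
    PairedSample,
    ProteinCloud,
)

logger = logging.getLogger(__name__)

#: integer codes for protein heavy-atom elements; 0 is reserved for padding
PROTEIN_ELEMENT_CODES = {"C": 1, "N": 2, "O": 3, "S": 4, "P": 5}
OTHER_ELEMENT_CODE = 6

_RDKIT_BOND_ORDER = {"SINGLE": 1, "DOUBLE": 2, "TRIPLE": 3, "AROMATIC": 4}


class UnsupportedElementError(ValueError):
    """Ligand contains a heavy element outside the model vocabulary."""


@dataclass
class RawMolecule:
    """Heavy-atom ligand before trimming/encoding.

    ``bond_list`` stores each bond once as ``(i, j, bond_type)`` with
    ``i < j`` and ``bond_type`` indexing the bond vocabulary (1 = single ...).
    ``coords`` (optional) keeps the heavy-atom 3-D coordinates so the
    ligand centroid can be computed before trimming.
    """

    elements: list[str]
    bond_list: list[tuple[int, int, int]]
    source_id: str
    coords: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.elements)
        for i, j, b in self.bond_list:
            if i == j:
                raise ValueError(f"self-bond at atom {i} in {self.source_id}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index out of range in {self.source_id}")

    def n_atoms(self) -> int:
        return len(self.elements)

    def centroid(self) -> np.ndarray:
        if self.coords is None:
            raise ValueError("molecule carries no coordinates")
        return np.asarray(self.coords, dtype=float).mean(axis=0)


# ---------------------------------------------------------------------------
# file loaders
# ---------------------------------------------------------------------------

def load_ligand(path: str | Path, fmt: str | None = None,
                on_unsupported: str = "error") -> RawMolecule:
    """Read a ligand from SDF or MOL2, dropping hydrogens.

    ``on_unsupported`` controls what happens when a heavy element outside
    the vocabulary remains after hydrogen removal: ``"error"`` raises
    :class:`UnsupportedElementError`, ``"keep"`` returns the molecule as-is
    (encoding will fail later unless the caller handles it).
    """
    from rdkit import Chem

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "sdf":
        mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    else:
        raise ValueError(f"unsupported ligand format: {fmt!r}")
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"could not parse ligand file {path}")

    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if not heavy:
        raise ValueError(f"no heavy atoms in {path}")
    index_map = {old: new for new, old in enumerate(heavy)}

    elements = [mol.GetAtomWithIdx(i).GetSymbol() for i in heavy]
    unsupported = sorted({e for e in elements if e not in ATOM_TYPES})
    if unsupported:
        msg = f"{path}: elements outside vocabulary: {', '.join(unsupported)}"
        if on_unsupported == "error":
            raise UnsupportedElementError(msg)
        logger.warning(msg)

    bonds: list[tuple[int, int, int]] = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in index_map and j in index_map:
            order = _RDKIT_BOND_ORDER.get(str(b.GetBondType()), 1)
            i2, j2 = sorted((index_map[i], index_map[j]))
            bonds.append((i2, j2, order))

    coords = None
    if mol.GetNumConformers():
        coords = np.asarray(mol.GetConformer().GetPositions())[heavy]
    return RawMolecule(elements=elements, bond_list=bonds,
                       source_id=path.stem, coords=coords)


def load_protein_pdb(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read heavy-atom coordinates (angstrom) and element symbols from PDB."""
    from Bio.PDB import PDBParser

    path = Path(path)
    try:
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython raises with line context
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc

    coords, elements = [], []
    for atom in structure.get_atoms():
        elem = (atom.element or "").strip().capitalize()
        if elem in ("H", "D", ""):
            continue
        coords.append(atom.get_coord())
        elements.append(elem)
    if not coords:
        raise ValueError(f"no heavy ATOM/HETATM records in {path}")
    return np.asarray(coords, dtype=np.float64), elements


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def encode_molecule(m: RawMolecule, dims: ModelDims) -> LigandGraph:
    """One-hot encode a molecule with at most ``dims.n_atoms`` heavy atoms."""
    n = m.n_atoms()
    N, A, B = dims.n_atoms, dims.n_atom_types, dims.n_bond_types
    if n == 0:
        raise ValueError("empty molecule")
    if n > N:
        raise ValueError(f"{n} atoms exceed budget {N}; trim first")

    atoms = np.zeros((N, A))
    for i, e in enumerate(m.elements):
        if e not in ATOM_TYPES:
            raise UnsupportedElementError(f"element {e!r} not in vocabulary")
        atoms[i, ATOM_TYPES.index(e)] = 1.0
    atoms[n:, dims.pad_index] = 1.0

    bonds = np.zeros((N, N, B))
    bonds[:, :, NO_BOND] = 1.0
    for i, j, b in m.bond_list:
        if b <= 0 or b >= B:
            raise ValueError(f"bond type {b} outside vocabulary")
        for x, y in ((i, j), (j, i)):
            bonds[x, y, :] = 0.0
            bonds[x, y, b] = 1.0
    return LigandGraph(atoms=atoms, bonds=bonds)


def trim_ligand(m: RawMolecule, max_atoms: int, dims: ModelDims) -> LigandGraph:
    """Trim an oversized ligand to ``max_atoms`` heavy atoms, then encode.

    Atoms are removed one at a time: at each step the atom with the current
    minimum bond degree goes (ties broken by the highest atom index), and
    degrees are recomputed before the next removal.  Survivors keep their
    original relative order.
    """
    if m.n_atoms() == 0:
        raise ValueError("empty molecule")
    keep = list(range(m.n_atoms()))
    bonds = [(i, j) for i, j, _ in m.bond_list]
    while len(keep) > max_atoms:
        alive = set(keep)
        deg = {i: 0 for i in keep}
        for i, j in bonds:
            if i in alive and j in alive:
                deg[i] += 1
                deg[j] += 1
        dmin = min(deg.values())
        victim = max(i for i in keep if deg[i] == dmin)
        keep.remove(victim)

    remap = {old: new for new, old in enumerate(keep)}
    alive = set(keep)
    new_bonds = [(remap[i], remap[j], b) for i, j, b in m.bond_list
                 if i in alive and j in alive]
    trimmed = RawMolecule(
        elements=[m.elements[i] for i in keep],
        bond_list=new_bonds,
        source_id=m.source_id,
        coords=None if m.coords is None else np.asarray(m.coords)[keep],
    )
    return encode_molecule(trimmed, dims)


def standardize_protein(coords: np.ndarray, elements: list[str],
                        ligand_centroid: np.ndarray,
                        dims: ModelDims) -> ProteinCloud:
    """Fix a protein cloud to exactly ``dims.n_protein_atoms`` rows.

    Oversized proteins keep the atoms nearest the ligand centroid (ties by
    lower original index, via stable sort); undersized ones are zero-padded
    with mask 0.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    centroid = np.asarray(ligand_centroid, dtype=np.float64)
    if not np.isfinite(centroid).all():
        raise ValueError("ligand centroid must be finite")

    P = dims.n_protein_atoms
    n = coords.shape[0]
    codes = np.array([PROTEIN_ELEMENT_CODES.get(e, OTHER_ELEMENT_CODE)
                      for e in elements], dtype=np.int64)
    if n > P:
        dist = np.linalg.norm(coords - centroid, axis=1)
        order = np.argsort(dist, kind="stable")[:P]
        order.sort()  # preserve original atom order among the kept
        coords, codes, n = coords[order], codes[order], P

    out_coords = np.zeros((P, 3))
    out_types = np.zeros(P, dtype=np.int64)
    out_mask = np.zeros(P)
    out_coords[:n] = coords
    out_types[:n] = codes
    out_mask[:n] = 1.0
    return ProteinCloud(coords=out_coords, atom_types=out_types, mask=out_mask)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(root_dir: str | Path, dims: ModelDims,
                  on_unsupported: str = "error") -> list[PairedSample]:
    """Preprocess a directory of protein-ligand pairs.

    Each sub-directory must contain one ``.pdb`` protein and one ``.sdf`` or
    ``.mol2`` ligand.  Pairs that fail to parse are logged and skipped;
    output is sorted by pair id.
    """
    root = Path(root_dir)
    subdirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not subdirs:
        raise ValueError(f"no pair sub-directories under {root}")

    samples: list[PairedSample] = []
    n_skipped = 0
    for sub in subdirs:
        try:
            pdb = sorted(sub.glob("*.pdb"))
            lig = sorted(list(sub.glob("*.sdf")) + list(sub.glob("*.mol2")))
            if not pdb or not lig:
                raise ValueError(f"{sub}: missing protein or ligand file")
            mol = load_ligand(lig[0], on_unsupported=on_unsupported)
            centroid = mol.centroid()
            graph = trim_ligand(mol, dims.n_atoms, dims)
            coords, elements = load_protein_pdb(pdb[0])
            cloud = standardize_protein(coords, elements, centroid, dims)
            samples.append(PairedSample(protein=cloud, ligand=graph,
                                        pair_id=sub.name))
        except (ValueError, OSError) as exc:
            n_skipped += 1
            logger.warning("skipping pair %s: %s", sub.name, exc)
    logger.info("built %d pairs (%d skipped)", len(samples), n_skipped)
    if not samples:
        raise ValueError(f"no usable pairs under {root}")
    return sorted(samples, key=lambda s: s.pair_id)


def save_dataset(samples: list[PairedSample], path: str | Path) -> None:
    """Write a preprocessed dataset as one ``.npz`` archive with a manifest."""
    manifest = {
        "format": "liggen-dataset-v1",
        "n_pairs": len(samples),
        "pair_ids": [s.pair_id for s in samples],
    }
    np.savez_compressed(
        path,
        atoms=np.stack([s.ligand.atoms for s in samples]),
        bonds=np.stack([s.ligand.bonds for s in samples]),
        coords=np.stack([s.protein.coords for s in samples]),
        atom_types=np.stack([s.protein.atom_types for s in samples]),
        mask=np.stack([s.protein.mask for s in samples]),
        manifest=np.array(json.dumps(manifest)),
    )


def load_dataset(path: str | Path) -> list[PairedSample]:
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        return [
            PairedSample(
                protein=ProteinCloud(coords=z["coords"][i],
                                     atom_types=z["atom_types"][i],
                                     mask=z["mask"][i]),
                ligand=LigandGraph(atoms=z["atoms"][i], bonds=z["bonds"][i]),
                pair_id=manifest["pair_ids"][i],
            )
            for i in range(manifest["n_pairs"])
        ]


# ---------------------------------------------------------------------------
# synthetic paired data
# ---------------------------------------------------------------------------

def _class_profiles(n_classes: int, n_elements: int, n_relations: int):
    """Deterministic per-class composition profiles.

    Each hidden class concentrates 90% of its atom mass on one element and
    90% of its bond mass on one bond type, with the remainder uniform:
    classes are far apart in composition space and tight within, like
    chemotype families sharing a scaffold chemistry.
    """
    atom_p = np.full((n_classes, n_elements), 0.1 / max(n_elements - 1, 1))
    bond_p = np.full((n_classes, n_relations), 0.1 / max(n_relations - 1, 1))
    for c in range(n_classes):
        atom_p[c, c % n_elements] = 0.9
        bond_p[c, c % n_relations] = 0.9
    atom_p /= atom_p.sum(axis=1, keepdims=True)
    bond_p /= bond_p.sum(axis=1, keepdims=True)
    return atom_p, bond_p


def _class_size_range(cls: int, n_classes: int, N: int) -> tuple[int, int]:
    """Heavy-atom count range for a class: sizes tile [2, N] so that class
    identity also controls molecule size, a joint (size, composition)
    dependence an unconditional generator tends to average away."""
    lo_frac = cls / n_classes
    hi_frac = (cls + 1) / n_classes
    lo = max(2, 2 + int(round(lo_frac * (N - 2))))
    hi = max(lo, 2 + int(round(hi_frac * (N - 2))) - 1)
    return lo, min(hi, N)


def _synthetic_ligand(cls: int, dims: ModelDims, atom_p: np.ndarray,
                      bond_p: np.ndarray, rng: np.random.Generator) -> LigandGraph:
    N = dims.n_atoms
    lo, hi = _class_size_range(cls % atom_p.shape[0], atom_p.shape[0], N)
    n_heavy = int(rng.integers(lo, hi + 1))
    n_elem = dims.n_atom_types - 1
    elem_idx = rng.choice(n_elem, size=n_heavy, p=atom_p[cls])

    atoms = np.zeros((N, dims.n_atom_types))
    atoms[np.arange(n_heavy), elem_idx] = 1.0
    atoms[n_heavy:, dims.pad_index] = 1.0

    bonds = np.zeros((N, N, dims.n_bond_types))
    bonds[:, :, NO_BOND] = 1.0

    def put(i: int, j: int) -> None:
        b = 1 + int(rng.choice(dims.n_relations, p=bond_p[cls]))
        for x, y in ((i, j), (j, i)):
            bonds[x, y, :] = 0.0
            bonds[x, y, b] = 1.0

    for i in range(1, n_heavy):  # random spanning tree keeps graphs connected
        put(i, int(rng.integers(0, i)))
    p_extra = 0.05 + 0.05 * (cls % 3)
    for i in range(n_heavy):
        for j in range(i + 1, n_heavy):
            if bonds[i, j, NO_BOND] == 1.0 and rng.random() < p_extra:
                put(i, j)
    return LigandGraph(atoms=atoms, bonds=bonds)


def _synthetic_protein(cls: int, dims: ModelDims,
                       rng: np.random.Generator) -> ProteinCloud:
    P = dims.n_protein_atoms
    n = int(rng.integers(max(1, P // 2), P + 1))
    center = np.zeros(3)
    center[cls % 3] = 12.0 * (1 + cls // 3)  # class-specific blob offset, angstrom
    coords = rng.normal(loc=center, scale=3.0, size=(n, 3))
    comp = np.full(OTHER_ELEMENT_CODE, 0.4 / (OTHER_ELEMENT_CODE - 1))
    comp[cls % OTHER_ELEMENT_CODE] = 0.6
    comp /= comp.sum()
    codes = 1 + rng.choice(OTHER_ELEMENT_CODE, size=n, p=comp)

    out_coords = np.zeros((P, 3))
    out_types = np.zeros(P, dtype=np.int64)
    out_mask = np.zeros(P)
    out_coords[:n] = coords
    out_types[:n] = codes
    out_mask[:n] = 1.0
    return ProteinCloud(coords=out_coords, atom_types=out_types, mask=out_mask)


def generate_synthetic_dataset(n_pairs: int, dims: ModelDims,
                               n_classes: int = 6,
                               seed: int = 0) -> list[PairedSample]:
    """Generate paired samples with a planted protein-to-ligand dependence.

    Each pair draws a hidden class that shifts the protein blob location and
    element composition *and* sets the ligand's atom/bond composition, so a
    conditional generator can exploit the protein while a non-conditional
    one cannot.  The class is recorded in the pair id (``..._c<k>``).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    atom_p, bond_p = _class_profiles(n_classes, dims.n_atom_types - 1,
                                     dims.n_relations)
    samples = []
    for i in range(n_pairs):
        cls = int(rng.integers(0, n_classes))
        samples.append(PairedSample(
            protein=_synthetic_protein(cls, dims, rng),
            ligand=_synthetic_ligand(cls, dims, atom_p, bond_p, rng),
            pair_id=f"synth{i:05d}_c{cls}",
        ))
    return samples


def synthetic_class_of(sample: PairedSample) -> int:
    """Recover the hidden class planted by the synthetic generator."""
    return int(sample.pair_id.rsplit("_c", 1)[1])
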