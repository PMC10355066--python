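"""Molecule parsing, curation, conformer embedding and atom featurization.

The pipeline consumes tables of SMILES strings (optionally with a crystal
density target in g/cm^3), filters them down to single-fragment, net-neutral
CHON molecules that contain at least one carbon-nitrogen bond and that admit a
3D conformer, and turns each survivor into a heavy-atom molecular graph with
per-atom feature vectors and 3D coordinates.

Hydrogens are explicit only while the conformer is embedded; the stored graph
contains heavy atoms only and carries the hydrogen count as an atom feature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Lipinski

RDLogger.DisableLog("rdApp.*")

FEATURIZER_VERSION = "1"

#: Allowed elements for curation criterion 1.
CHON = frozenset({"C", "H", "O", "N"})

#: Fixed atom-type vocabulary (38 symbols): H, C, N, O first, then common
#: organic / metallic elements alphabetically.  Unknown symbols raise.
ATOM_TYPES: tuple[str, ...] = (
    "H", "C", "N", "O",
    "Ag", "Al", "As", "B", "Ba", "Bi", "Br", "Ca", "Cd", "Cl", "Co", "Cr",
    "Cu", "F", "Fe", "Ge", "Hg", "I", "K", "Li", "Mg", "Mn", "Mo", "Na",
    "Ni", "P", "Pb", "Pd", "Pt", "S", "Sb", "Se", "Si", "Sn",
)
assert len(ATOM_TYPES) == 38

CHIRAL_TYPES = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)  # anything else -> "other" bucket

HYBRIDIZATIONS = (
    Chem.HybridizationType.UNSPECIFIED,
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)  # anything else -> "other" bucket

#: Block sizes of the per-atom feature vector, in concatenation order:
#: atom type, degree, chiral type, attached-H count, hybridization,
#: aromatic flag, scaled atomic mass, H-bond acceptor/donor flags.
FEATURE_BLOCK_SIZES = (38, 6, 4, 6, 8, 1, 1, 2)
ATOM_FEATURE_LENGTH = sum(FEATURE_BLOCK_SIZES)  # 66

#: Atomic-mass scale: mass/100 keeps the feature commensurate with one-hots.
MASS_SCALE = 0.01

_HDONOR = Lipinski.HDonorSmarts
_HACCEPTOR = Lipinski.HAcceptorSmarts


class UnknownElementError(ValueError):
    """An atom's element symbol is outside the fixed 38-symbol vocabulary."""


class EmbeddingFailure(RuntimeError):
    """Distance-geometry conformer generation failed for a molecule."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: id, SMILES, optional crystal density (g/cm^3)."""

    id: str
    smiles: str
    target: float | None = None
    source: str = ""


@dataclass(frozen=True)
class CurationReport:
    n_input: int
    n_accepted: int
    rejections: tuple[tuple[str, str], ...]  # (record id, criterion code)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejections, columns=["id", "criterion"])


@dataclass
class AtomInfo:
    """Chemistry annotations for one heavy atom, the input to featurization."""

    symbol: str
    degree: int
    chiral_tag: int  # index into CHIRAL_TYPES, 3 = other
    num_hs: int
    hybridization: int  # index into HYBRIDIZATIONS, 7 = other
    aromatic: bool
    mass: float
    h_acceptor: bool
    h_donor: bool


@dataclass
class MolecularGraph3D:
    """Heavy-atom molecular graph with 3D coordinates (Angstrom).

    ``atom_features`` is filled by :func:`featurize_atoms`; ``annotations``
    carries the raw chemistry needed to compute it.
    """

    mol_id: str
    atoms: list[str]
    bonds: list[tuple[int, int]]
    coords: np.ndarray  # (n_atoms, 3)
    annotations: list[AtomInfo] = field(default_factory=list)
    atom_features: np.ndarray | None = None  # (n_atoms, 66)
    target: float | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def _check_criteria_123(smiles: str) -> str | None:
    """Return the first failing criterion code among 1-3, or None."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return "ELEMENTS"  # unparseable: reported under the first criterion
    elements = {a.GetSymbol() for a in mol.GetAtoms()}
    if not elements <= CHON:
        return "ELEMENTS"
    has_cn = any(
        {b.GetBeginAtom().GetSymbol(), b.GetEndAtom().GetSymbol()} == {"C", "N"}
        for b in mol.GetBonds()
    )
    if not has_cn:
        return "CN_BOND"
    if len(Chem.GetMolFrags(mol)) > 1 or Chem.GetFormalCharge(mol) != 0:
        return "IONIC_OR_MULTIFRAG"
    return None


def curate(
    records: Sequence[MoleculeRecord], conformer_seed: int = 0
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Apply the four dataset-curation criteria, first failure wins.

    1. elements within {C, H, O, N};
    2. at least one carbon-nitrogen bond of any order;
    3. a single fragment with zero net formal charge (proxy for excluding
       ionic and co-crystal entries);
    4. a 3D conformer can be embedded with the given seed.

    Unparseable SMILES are rejected under ELEMENTS rather than raising, so a
    bad row never aborts a batch.
    """
    accepted: list[MoleculeRecord] = []
    rejections: list[tuple[str, str]] = []
    for rec in records:
        code = _check_criteria_123(rec.smiles)
        if code is None:
            try:
                embed_conformer(rec, seed=conformer_seed)
            except EmbeddingFailure:
                code = "EMBED_FAIL"
        if code is None:
            canonical = Chem.MolToSmiles(Chem.MolFromSmiles(rec.smiles))
            accepted.append(replace(rec, smiles=canonical))
        else:
            rejections.append((rec.id, code))
    report = CurationReport(len(records), len(accepted), tuple(rejections))
    return accepted, report


def deduplicate_against(
    train: Sequence[MoleculeRecord], external_test: Sequence[MoleculeRecord]
) -> list[MoleculeRecord]:
    """Drop training records whose canonical SMILES occur in the external set.

    Keeps an external benchmark unseen: both lists are canonicalized before
    comparison so notation variants of the same molecule are caught.
    """
    test_keys = {
        Chem.MolToSmiles(m)
        for r in external_test
        if (m := Chem.MolFromSmiles(r.smiles)) is not None
    }
    out = []
    for r in train:
        mol = Chem.MolFromSmiles(r.smiles)
        key = Chem.MolToSmiles(mol) if mol is not None else r.smiles
        if key not in test_keys:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Conformer embedding
# ---------------------------------------------------------------------------

def _annotate(mol: Chem.Mol) -> list[AtomInfo]:
    acceptors = {i[0] for i in mol.GetSubstructMatches(_HACCEPTOR)}
    donors = {i[0] for i in mol.GetSubstructMatches(_HDONOR)}
    infos = []
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        chiral = CHIRAL_TYPES.index(tag) if tag in CHIRAL_TYPES else 3
        hyb = atom.GetHybridization()
        hybrid = HYBRIDIZATIONS.index(hyb) if hyb in HYBRIDIZATIONS else 7
        infos.append(
            AtomInfo(
                symbol=atom.GetSymbol(),
                degree=atom.GetDegree(),
                chiral_tag=chiral,
                num_hs=atom.GetTotalNumHs(),
                hybridization=hybrid,
                aromatic=atom.GetIsAromatic(),
                mass=atom.GetMass(),
                h_acceptor=atom.GetIdx() in acceptors,
                h_donor=atom.GetIdx() in donors,
            )
        )
    return infos


def embed_conformer(record: MoleculeRecord, seed: int = 0) -> MolecularGraph3D:
    """Generate one ETKDG conformer and return the heavy-atom graph.

    Hydrogens are added for the distance-geometry embedding and stripped
    afterwards; their count per atom survives as an annotation.  Deterministic
    for a fixed (smiles, seed).

    Raises
    ------
    EmbeddingFailure
        if the distance-geometry embedding does not converge; ``curate``
        consumes this as the EMBED_FAIL criterion.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise EmbeddingFailure(f"unparseable SMILES: {record.smiles!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise EmbeddingFailure(f"ETKDG embedding failed for {record.smiles!r}")
    heavy = Chem.RemoveHs(molh)
    conf = heavy.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(heavy.GetNumAtoms())],
        dtype=float,
    )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in heavy.GetBonds()
    ]
    return MolecularGraph3D(
        mol_id=record.id,
        atoms=[a.GetSymbol() for a in heavy.GetAtoms()],
        bonds=bonds,
        coords=coords,
        annotations=_annotate(heavy),
        target=record.target,
    )


def graph_from_mol(mol: Chem.Mol, mol_id: str, target: float | None = None) -> MolecularGraph3D:
    """Build a graph from an RDKit mol that already carries 3D coordinates
    (e.g. read from an SDF); skips conformer embedding."""
    heavy = Chem.RemoveHs(mol)
    conf = heavy.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(heavy.GetNumAtoms())],
        dtype=float,
    )
    return MolecularGraph3D(
        mol_id=mol_id,
        atoms=[a.GetSymbol() for a in heavy.GetAtoms()],
        bonds=[(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in heavy.GetBonds()],
        coords=coords,
        annotations=_annotate(heavy),
        target=target,
    )


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def _one_hot(index: int, size: int, clamp: bool = True) -> np.ndarray:
    v = np.zeros(size)
    if clamp:
        index = min(index, size - 1)
    v[index] = 1.0
    return v


def atom_feature_vector(info: AtomInfo) -> np.ndarray:
    """66-long feature row for one atom: concatenation of atom-type one-hot
    (38), degree one-hot (6), chiral-type one-hot (4), attached-H one-hot (6),
    hybridization one-hot (8), aromatic flag, atomic mass / 100, and H-bond
    acceptor/donor flags.  Out-of-range ordinals clamp to the final bucket."""
    if info.symbol not in ATOM_TYPES:
        raise UnknownElementError(
            f"element {info.symbol!r} is not in the fixed 38-symbol atom-type vocabulary"
        )
    parts = [
        _one_hot(ATOM_TYPES.index(info.symbol), 38, clamp=False),
        _one_hot(info.degree, 6),
        _one_hot(info.chiral_tag, 4),
        _one_hot(info.num_hs, 6),
        _one_hot(info.hybridization, 8),
        np.array([1.0 if info.aromatic else 0.0]),
        np.array([info.mass * MASS_SCALE]),
        np.array([1.0 if info.h_acceptor else 0.0, 1.0 if info.h_donor else 0.0]),
    ]
    return np.concatenate(parts)


def featurize_atoms(graph: MolecularGraph3D) -> MolecularGraph3D:
    """Fill ``graph.atom_features`` with one 66-long row per heavy atom."""
    graph.atom_features = np.stack(
        [atom_feature_vector(info) for info in graph.annotations]
    )
    return graph


# ---------------------------------------------------------------------------
# Tabular / SDF I/O and the feature cache
# ---------------------------------------------------------------------------

def read_csv(path: str | Path, source: str | None = None) -> list[MoleculeRecord]:
    """Read a ``id,smiles[,density]`` table (comma or tab separated)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols:
        raise ValueError(f"{path}: no 'smiles' column (found {list(df.columns)})")
    id_col = cols.get("id")
    dens_col = cols.get("density", cols.get("target"))
    records = []
    for i, row in df.iterrows():
        rid = str(row[id_col]) if id_col else f"mol{i}"
        target = None
        if dens_col is not None and pd.notna(row[dens_col]):
            target = float(row[dens_col])
        records.append(
            MoleculeRecord(rid, str(row[cols["smiles"]]), target, source or path.name)
        )
    return records


def write_csv(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": r.id, "smiles": r.smiles, "density": r.target} for r in records]
    ).to_csv(path, index=False)


def read_sdf(path: str | Path, source: str | None = None) -> list[MolecularGraph3D]:
    """Read a V2000 SDF with 3D coordinates into graphs (no re-embedding)."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    graphs = []
    for i, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"{path}: skipping unreadable SDF entry {i}")
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
        target = float(mol.GetProp("density")) if mol.HasProp("density") else None
        graphs.append(graph_from_mol(mol, mol_id, target))
    return graphs


def prepare_graphs(
    records: Sequence[MoleculeRecord], conformer_seed: int = 0
) -> list[MolecularGraph3D]:
    """Embed + featurize every record (records must have passed curation)."""
    return [featurize_atoms(embed_conformer(r, conformer_seed)) for r in records]


def cache_key(smiles: str, seed: int) -> str:
    return f"{smiles}|seed={seed}|v={FEATURIZER_VERSION}"


def save_graph_cache(graphs: Iterable[MolecularGraph3D], path: str | Path, seed: int) -> None:
    """JSON cache of featurized graphs keyed by (smiles is not stored per se;
    the key is the mol_id-independent (canonical smiles, seed, version))."""
    payload = {}
    for g in graphs:
        payload[g.mol_id] = {
            "atoms": g.atoms,
            "bonds": [list(b) for b in g.bonds],
            "coords": g.coords.tolist(),
            "features": None if g.atom_features is None else g.atom_features.tolist(),
            "target": g.target,
            "seed": seed,
            "version": FEATURIZER_VERSION,
        }
    Path(path).write_text(json.dumps(payload))


def load_graph_cache(path: str | Path) -> list[MolecularGraph3D]:
    payload = json.loads(Path(path).read_text())
    graphs = []
    for mol_id, d in payload.items():
        graphs.append(
            MolecularGraph3D(
                mol_id=mol_id,
                atoms=d["atoms"],
                bonds=[tuple(b) for b in d["bonds"]],
                coords=np.array(d["coords"], dtype=float),
                atom_features=None if d["features"] is None else np.array(d["features"]),
                target=d["target"],
            )
        )
    return graphs
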