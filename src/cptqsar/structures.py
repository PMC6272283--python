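"""Molecule I/O, charge assignment, conformer preparation and scaffold alignment.

This module prepares a single aligned 3D conformer per compound, the input
expected by the molecular-field stage:

1. parse a molecule record (SDF V2000, MOL2 or SMILES),
2. embed one conformer and minimize it with MMFF94,
3. assign Gasteiger (PEOE) partial charges,
4. locate the common camptothecin scaffold shared by all derivatives, and
5. rigidly superpose each molecule onto the template compound via a
   least-squares (Kabsch) fit on the matched scaffold atoms.

RDKit provides parsing, charges, embedding, minimization and substructure
matching; the alignment bookkeeping and correspondence tie-breaking live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from .errors import (
    ChargeModelError,
    DegenerateAlignmentError,
    MoleculeParseError,
    PreparationError,
    ScaffoldNotFoundError,
    UnsupportedFormatError,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule3D",
    "PrepConfig",
    "ScaffoldCorrespondence",
    "parse_molecule",
    "assign_charges",
    "prepare_conformer",
    "match_scaffold",
    "superpose",
    "write_sdf",
]


@dataclass
class Molecule3D:
    """A single-conformer molecule with optional coordinates and charges.

    Coordinates are in Angstrom, partial charges in elementary charge units.
    The underlying RDKit molecule is kept alongside the plain arrays so that
    substructure matching and force-field operations stay available.
    """

    id: str
    atoms: list[tuple[str, int, int]]  # (element symbol, atomic number, formal charge)
    bonds: list[tuple[int, int, float]]  # (begin, end, bond order)
    coords: np.ndarray | None = None  # (n_atoms, 3) Angstrom
    partial_charges: np.ndarray | None = None  # (n_atoms,) e
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)
    # rigid transform applied by the most recent superposition: x -> R x + t
    transform: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def has_coords(self) -> bool:
        return self.coords is not None

    @property
    def elements(self) -> list[str]:
        return [a[0] for a in self.atoms]

    def total_formal_charge(self) -> int:
        return sum(a[2] for a in self.atoms)

    def copy(self) -> "Molecule3D":
        return replace(
            self,
            atoms=list(self.atoms),
            bonds=list(self.bonds),
            coords=None if self.coords is None else self.coords.copy(),
            partial_charges=(
                None if self.partial_charges is None else self.partial_charges.copy()
            ),
            rdmol=None if self.rdmol is None else Chem.Mol(self.rdmol),
        )

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, mol_id: str) -> "Molecule3D":
        atoms = [
            (a.GetSymbol(), a.GetAtomicNum(), a.GetFormalCharge())
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ]
        coords = None
        if mol.GetNumConformers() > 0:
            coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
        return cls(id=mol_id, atoms=atoms, bonds=bonds, coords=coords, rdmol=Chem.Mol(mol))

    def to_rdkit(self) -> Chem.Mol:
        if self.rdmol is None:
            raise ValueError(f"molecule {self.id!r} carries no RDKit handle")
        mol = Chem.Mol(self.rdmol)
        if self.coords is not None:
            if mol.GetNumConformers() == 0:
                conf = Chem.Conformer(mol.GetNumAtoms())
                mol.AddConformer(conf, assignId=True)
            conf = mol.GetConformer()
            for i, xyz in enumerate(self.coords):
                conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        return mol


@dataclass(frozen=True)
class PrepConfig:
    """Conformer-preparation settings.

    minimization_convergence is the force-norm threshold in kcal/(mol*A);
    the 0.05 default mirrors the convergence criterion used to minimize the
    study compounds. embed_seed makes the distance-geometry embedding (and
    therefore the whole downstream pipeline) deterministic.
    """

    minimization_convergence: float = 0.05
    max_minimization_steps: int = 2000
    embed_seed: int = 1234
    forcefield: str = "mmff"  # "mmff" or "uff"

    def __post_init__(self) -> None:
        if self.minimization_convergence <= 0:
            raise ValueError("minimization_convergence must be > 0")


@dataclass(frozen=True)
class ScaffoldCorrespondence:
    """Atom-to-atom mapping of the common scaffold between template and target."""

    template_id: str
    target_id: str
    pairs: tuple[tuple[int, int], ...]  # (template atom index, target atom index)

    @property
    def n_atoms(self) -> int:
        return len(self.pairs)

    def __post_init__(self) -> None:
        t_idx = [p[0] for p in self.pairs]
        m_idx = [p[1] for p in self.pairs]
        if len(set(t_idx)) != len(t_idx) or len(set(m_idx)) != len(m_idx):
            raise ValueError("correspondence repeats an atom index")


# ---------------------------------------------------------------------------
# parsing


def parse_molecule(record: str, fmt: str, mol_id: str | None = None) -> Molecule3D:
    """Parse one molecule record in the named format.

    ``fmt`` is one of ``"sdf"``, ``"mol"``, ``"mol2"``, ``"smiles"``.  SMILES
    input yields a molecule without coordinates; call :func:`prepare_conformer`
    to embed one.  For SMILES the record may carry a trailing whitespace-
    separated identifier (``.smi`` convention).
    """
    fmt = fmt.lower()
    if fmt in ("sdf", "mol"):
        mol = Chem.MolFromMolBlock(record, removeHs=False)
        if mol is None:
            raise MoleculeParseError(
                f"could not parse SDF/MOL block (id={mol_id!r}); "
                "check the counts line and atom block"
            )
        name = mol_id or mol.GetProp("_Name") or "unnamed"
    elif fmt == "mol2":
        mol = Chem.MolFromMol2Block(record, removeHs=False)
        if mol is None:
            raise MoleculeParseError(f"could not parse MOL2 block (id={mol_id!r})")
        name = mol_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed")
    elif fmt == "smiles":
        parts = record.strip().split()
        if not parts:
            raise MoleculeParseError("empty SMILES record")
        smi = parts[0]
        name = mol_id or (parts[1] if len(parts) > 1 else "unnamed")
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise MoleculeParseError(f"invalid SMILES {smi!r} (id={name!r})")
    else:
        raise UnsupportedFormatError(
            f"unsupported format {fmt!r}; expected sdf, mol, mol2 or smiles"
        )
    mol.SetProp("_Name", name)
    return Molecule3D.from_rdkit(mol, name)


# ---------------------------------------------------------------------------
# charges


def assign_charges(mol: Molecule3D, model: str = "gasteiger") -> Molecule3D:
    """Assign PEOE (Gasteiger) partial charges.

    Charges are computed for the molecule's explicit atoms; contributions of
    implicit hydrogens (if any) are folded into their heavy atom so the vector
    always sums to the net formal charge.
    """
    if model != "gasteiger":
        raise ChargeModelError(f"unknown charge model {model!r}")
    if mol.rdmol is None:
        raise ChargeModelError(f"molecule {mol.id!r} has no structure to charge")
    rd = Chem.Mol(mol.rdmol)
    AllChem.ComputeGasteigerCharges(rd, throwOnParamFailure=False)
    charges = np.empty(rd.GetNumAtoms(), dtype=float)
    for i, atom in enumerate(rd.GetAtoms()):
        q = atom.GetDoubleProp("_GasteigerCharge")
        qh = atom.GetDoubleProp("_GasteigerHCharge") if atom.HasProp("_GasteigerHCharge") else 0.0
        val = q + qh
        if not np.isfinite(val):
            raise ChargeModelError(
                f"non-finite PEOE charge on atom {i} ({atom.GetSymbol()}) "
                f"of molecule {mol.id!r}"
            )
        charges[i] = val
    total = charges.sum()
    if abs(total - mol.total_formal_charge()) > 1e-3:
        raise ChargeModelError(
            f"charges of {mol.id!r} sum to {total:.6f}, expected "
            f"{mol.total_formal_charge()}"
        )
    out = mol.copy()
    out.partial_charges = charges
    return out


# ---------------------------------------------------------------------------
# conformer preparation


def _embed(rd: Chem.Mol, seed: int) -> int:
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    ret = AllChem.EmbedMolecule(rd, params)
    if ret != 0:
        params.useRandomCoords = True
        ret = AllChem.EmbedMolecule(rd, params)
    return ret


def prepare_conformer(mol: Molecule3D, cfg: PrepConfig = PrepConfig()) -> Molecule3D:
    """Embed one conformer and force-field minimize it.

    Hydrogens are made explicit before embedding.  Minimization uses MMFF94
    (UFF as fallback for elements outside MMFF coverage) with the configured
    force tolerance and step cap; whether the minimizer converged is recorded
    on the returned molecule (``converged`` attribute of the RDKit mol prop).
    Deterministic for a fixed ``embed_seed``.
    """
    if mol.rdmol is None:
        raise PreparationError(f"molecule {mol.id!r} has no parsed structure")
    rd = Chem.AddHs(Chem.Mol(mol.rdmol))
    ret = -1
    for attempt in range(3):
        ret = _embed(rd, cfg.embed_seed + attempt)
        if ret == 0:
            break
    if ret != 0:
        raise PreparationError(f"3D embedding failed for {mol.id!r} after retries")

    # minimize on a scratch copy: MMFF setup re-perceives aromaticity in
    # place, which would break later substructure matching on this molecule
    ffmol = Chem.Mol(rd)
    use_mmff = cfg.forcefield == "mmff" and AllChem.MMFFHasAllMoleculeParams(ffmol)
    if use_mmff:
        props = AllChem.MMFFGetMoleculeProperties(ffmol)
        ff = AllChem.MMFFGetMoleculeForceField(ffmol, props)
    else:
        ff = AllChem.UFFGetMoleculeForceField(ffmol)
    ff.Initialize()
    ret = ff.Minimize(
        maxIts=cfg.max_minimization_steps, forceTol=cfg.minimization_convergence
    )
    conf = rd.GetConformer()
    min_conf = ffmol.GetConformer()
    for i in range(rd.GetNumAtoms()):
        conf.SetAtomPosition(i, min_conf.GetAtomPosition(i))
    rd.SetProp("converged", "1" if ret == 0 else "0")
    rd.SetProp("forcefield", "mmff94" if use_mmff else "uff")
    rd.SetDoubleProp("energy_kcal_mol", ff.CalcEnergy())

    out = Molecule3D.from_rdkit(rd, mol.id)
    return out


def forcefield_energy(mol: Molecule3D) -> float:
    """Force-field energy (kcal/mol) of the molecule's current coordinates."""
    rd = mol.to_rdkit()
    if AllChem.MMFFHasAllMoleculeParams(rd):
        props = AllChem.MMFFGetMoleculeProperties(rd)
        ff = AllChem.MMFFGetMoleculeForceField(rd, props)
    else:
        ff = AllChem.UFFGetMoleculeForceField(rd)
    return float(ff.CalcEnergy())


# ---------------------------------------------------------------------------
# scaffold matching


def _best_match(rd: Chem.Mol, query: Chem.Mol, label: str) -> tuple[int, ...]:
    matches = rd.GetSubstructMatches(query, uniquify=False, maxMatches=256)
    if not matches:
        raise ScaffoldNotFoundError(f"scaffold query does not match compound {label!r}")
    # deterministic tie-break between symmetry-equivalent matches: lowest
    # canonical-rank tuple, then lowest atom-index tuple
    ranks = list(Chem.CanonicalRankAtoms(rd, breakTies=False))
    return min(matches, key=lambda m: (tuple(ranks[i] for i in m), m))


def match_scaffold(
    mol: Molecule3D, template: Molecule3D, scaffold_query: str | Chem.Mol
) -> ScaffoldCorrespondence:
    """Map the common-scaffold atoms of ``mol`` onto those of ``template``.

    ``scaffold_query`` is a SMARTS string (or prepared RDKit query molecule)
    describing the substructure shared by every compound.  Both molecules must
    contain the query; symmetric matches are resolved deterministically.
    """
    if isinstance(scaffold_query, str):
        query = Chem.MolFromSmarts(scaffold_query)
        if query is None:
            raise MoleculeParseError(f"invalid scaffold SMARTS {scaffold_query!r}")
    else:
        query = scaffold_query
    if mol.rdmol is None or template.rdmol is None:
        raise ScaffoldNotFoundError("both molecules need parsed structures")
    t_match = _best_match(template.rdmol, query, template.id)
    m_match = _best_match(mol.rdmol, query, mol.id)
    pairs = tuple(zip(t_match, m_match))
    t_sym = template.elements
    m_sym = mol.elements
    for ti, mi in pairs:
        if t_sym[ti] != m_sym[mi]:
            raise ScaffoldNotFoundError(
                f"element mismatch in scaffold mapping {template.id!r}->{mol.id!r}: "
                f"{t_sym[ti]} vs {m_sym[mi]}"
            )
    return ScaffoldCorrespondence(
        template_id=template.id, target_id=mol.id, pairs=pairs
    )


# ---------------------------------------------------------------------------
# rigid superposition


def superpose(
    mol: Molecule3D, template: Molecule3D, corr: ScaffoldCorrespondence
) -> tuple[Molecule3D, float]:
    """Rigidly superpose ``mol`` onto ``template`` using the matched atoms.

    Returns the transformed molecule (all atoms moved by the same rotation +
    translation) and the RMSD (Angstrom) over the matched atoms.  Internal
    geometry is untouched; only a proper rigid motion is applied.
    """
    if mol.coords is None or template.coords is None:
        raise DegenerateAlignmentError("both molecules need 3D coordinates")
    if corr.n_atoms < 3:
        raise DegenerateAlignmentError("need at least 3 matched atoms")
    t_idx = np.array([p[0] for p in corr.pairs])
    m_idx = np.array([p[1] for p in corr.pairs])
    ref = template.coords[t_idx]
    mov = mol.coords[m_idx]
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    a = ref - ref_c
    b = mov - mov_c
    if np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise DegenerateAlignmentError("matched atoms are collinear")
    rot, _ = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = ref_c - R @ mov_c
    # residual rmsd computed directly; the rssd reported by align_vectors
    # loses precision to cancellation near zero
    rmsd = float(np.sqrt(np.mean(np.sum((a - b @ R.T) ** 2, axis=1))))
    out = mol.copy()
    out.coords = mol.coords @ R.T + t
    out.transform = (R, t)
    return out, rmsd


# ---------------------------------------------------------------------------
# output


def write_sdf(mols: list[Molecule3D], path) -> None:
    """Write an aligned ensemble as multi-record SDF.

    The rigid transform applied during superposition (if any) is recorded in
    SDF data fields so an alignment can be audited or re-applied.
    """
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            rd = m.to_rdkit()
            rd.SetProp("_Name", m.id)
            if m.transform is not None:
                R, t = m.transform
                rd.SetProp("alignment_rotation", " ".join(f"{v:.10f}" for v in R.ravel()))
                rd.SetProp("alignment_translation", " ".join(f"{v:.10f}" for v in t))
            if m.partial_charges is not None:
                rd.SetProp(
                    "partial_charges",
                    " ".join(f"{q:.6f}" for q in m.partial_charges),
                )
            writer.write(rd)
    finally:
        writer.close()
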