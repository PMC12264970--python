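"""PDB structure handling and structure-quality features.

A protein–ligand–water structure is represented as a flat list of atoms,
each carrying coordinates, B-factor and a role label (protein / ligand /
water / other), plus the crystallographic resolution when the header
records one. Parsing and serialisation go through gemmi.

The quality features computed per structure are the ones that matter for
binding-site modelling accuracy:

* ``res``     — crystallographic resolution (Å),
* ``lig_bf``  — mean B-factor over ligand atoms (Å²),
* ``n_wat``   — number of water molecules within 5 Å of the ligand,
* ``prot_bf`` — mean B-factor over all atoms of protein residues having
  at least one atom within 5 Å of the ligand (residue-level inclusion).

Distances use ligand heavy atoms only, with an inclusive boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "StructureModel",
    "FeatureVector",
    "parse_structure",
    "structure_to_pdb",
    "compute_features",
    "feature_split",
    "pearson_matrix",
    "WATER_RESNAMES",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL"})

#: standard amino-acid residue names treated as protein
_PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    b_factor: float
    occupancy: float = 1.0
    res_seq: int = 1
    icode: str = ""
    res_name: str = "UNK"
    chain: str = "A"
    role: str = "other"

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError("atom position must be a finite 3-vector")

    @property
    def res_id(self) -> str:
        """Chain-qualified residue identifier, insertion code preserved."""
        return f"{self.chain}:{self.res_seq}{self.icode}"


@dataclass
class StructureModel:
    atoms: list
    resolution: Optional[float] = None

    def positions(self, role: str | None = None, heavy_only: bool = False) -> np.ndarray:
        sel = [
            a.pos
            for a in self.atoms
            if (role is None or a.role == role) and not (heavy_only and a.element == "H")
        ]
        return np.asarray(sel, dtype=float).reshape(-1, 3)

    def ligand_heavy_positions(self) -> np.ndarray:
        return self.positions(role="ligand", heavy_only=True)

    def water_oxygen_positions(self) -> np.ndarray:
        return np.asarray(
            [a.pos for a in self.atoms if a.role == "water" and a.element != "H"],
            dtype=float,
        ).reshape(-1, 3)


def _validate_pdb_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            float(line[60:66])
        except (ValueError, IndexError):
            raise ValueError(f"unparseable coordinate record at line {lineno}: {line!r}")


def parse_structure(pdb_text: str, ligand: str | None = None) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Role assignment: residues named HOH/WAT/SOL are water; ATOM-record
    residues of standard amino acids are protein; the ligand is the
    heteroresidue named by ``ligand`` or, by default, the largest
    non-water heteroresidue (heavy-atom count). Among alternate-location
    conformers the highest-occupancy one is kept. The resolution is read
    from the REMARK 2 record when present; a missing record leaves it as
    None, never zero.
    """
    _validate_pdb_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no model found in PDB input")
    atoms: list[Atom] = []
    het_residues: list[tuple[int, int]] = []  # (heavy count, index into residue list)
    residues = []
    for chain in st[0]:
        for res in chain:
            # altloc: keep the highest-occupancy conformer per atom name
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None or at.occ > prev.occ:
                    by_name[at.name] = at
            resname = res.name.strip().upper()
            is_het = res.het_flag == "H"
            if resname in WATER_RESNAMES:
                role = "water"
            elif not is_het and resname in _PROTEIN_RESNAMES:
                role = "protein"
            elif not is_het:
                role = "protein"  # non-standard polymer residue on an ATOM record
            else:
                role = "other"
            first = len(atoms)
            for at in by_name.values():
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        b_factor=at.b_iso,
                        occupancy=at.occ,
                        res_seq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        res_name=resname,
                        chain=chain.name,
                        role=role,
                    )
                )
            residues.append((resname, first, len(atoms)))
            if role == "other":
                heavy = sum(1 for a in atoms[first:] if a.element != "H")
                het_residues.append((heavy, len(residues) - 1))
    if not atoms:
        raise ValueError("PDB input contains no ATOM/HETATM records")
    # ligand designation
    lig_idx = None
    if ligand is not None:
        for i, (resname, a, b) in enumerate(residues):
            if resname == ligand.strip().upper() and atoms[a].role == "other":
                lig_idx = i
                break
        if lig_idx is None:
            raise ValueError(f"designated ligand residue {ligand!r} not found")
    elif het_residues:
        lig_idx = max(het_residues)[1]
    if lig_idx is not None:
        _, a, b = residues[lig_idx]
        for atom in atoms[a:b]:
            atom.role = "ligand"
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    return StructureModel(atoms=atoms, resolution=resolution)


def structure_to_pdb(structure: StructureModel) -> str:
    """Serialise to PDB text (REMARK 2 resolution, ATOM/HETATM with B-factors)."""
    st = gemmi.Structure()
    st.name = "rbfebench"
    if structure.resolution is not None:
        st.resolution = float(structure.resolution)
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current_key = None
    current_res = None
    for atom in structure.atoms:
        key = (atom.chain, atom.res_seq, atom.icode, atom.res_name)
        if key != current_key:
            ch = chains.get(atom.chain)
            if ch is None:
                ch = gemmi.Chain(atom.chain)
                chains[atom.chain] = ch
            res = gemmi.Residue()
            res.name = atom.res_name
            res.seqid = gemmi.SeqId(atom.res_seq, atom.icode or " ")
            res.het_flag = "A" if atom.role == "protein" else "H"
            ch.add_residue(res)
            current_res = ch[len(ch) - 1]
            current_key = key
        ga = gemmi.Atom()
        ga.name = atom.name
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(*atom.pos)
        ga.occ = atom.occupancy
        ga.b_iso = atom.b_factor
        current_res.add_atom(ga)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


@dataclass
class FeatureVector:
    """The four structure-quality features; ``res`` is None when the
    header lacks a resolution record."""

    res: Optional[float]
    lig_bf: float
    n_wat: int
    prot_bf: float

    def __post_init__(self):
        if self.n_wat < 0:
            raise ValueError("n_wat must be >= 0")
        if self.res is not None and self.res <= 0:
            raise ValueError("resolution must be positive when present")


def compute_features(structure: StructureModel, site_cutoff: float = 5.0) -> FeatureVector:
    """Compute (res, lig_bf, n_wat, prot_bf) for one structure.

    ``prot_bf`` includes *all* atoms of any protein residue with at least
    one atom within ``site_cutoff`` of a ligand heavy atom. Missing
    (NaN) B-factors raise, naming the offending atoms.
    """
    from .waters import binding_site_waters

    lig = structure.ligand_heavy_positions()
    if lig.size == 0:
        raise ValueError("structure has no ligand heavy atoms")
    bad = [a.res_id + "/" + a.name for a in structure.atoms if not np.isfinite(a.b_factor)]
    if bad:
        raise ValueError(f"missing B-factors on atoms: {bad}")
    lig_b = np.array([a.b_factor for a in structure.atoms if a.role == "ligand"])
    # residue-level inclusion for the protein B-factor
    prot_atoms = [a for a in structure.atoms if a.role == "protein"]
    in_site_res: set[str] = set()
    for a in prot_atoms:
        d = np.min(np.linalg.norm(lig - a.pos, axis=1))
        if d <= site_cutoff:
            in_site_res.add(a.res_id)
    prot_b = np.array([a.b_factor for a in prot_atoms if a.res_id in in_site_res])
    n_wat = binding_site_waters(structure, cutoff=site_cutoff).positions.shape[0]
    return FeatureVector(
        res=structure.resolution,
        lig_bf=float(lig_b.mean()) if lig_b.size else float("nan"),
        n_wat=int(n_wat),
        prot_bf=float(prot_b.mean()) if prot_b.size else float("nan"),
    )


def feature_split(
    table: pd.DataFrame,
    feature: str,
    min_diff: float | None = None,
    n_boot: int = 10000,
    seed: int = 0,
):
    """Split pairs by which structure has the higher value of a feature.

    For every pair whose two structure records differ in ``feature`` by at
    least ``min_diff`` (default 0.4 Å for resolution — enough to clear
    measurement noise — and any nonzero difference otherwise), the record
    from the higher-value structure goes to the "higher" class and the
    other to the "lower" class. Returns ``{"higher": AueResult | None,
    "lower": AueResult | None, "n_pairs": int}`` with bootstrap SEs; empty
    classes are None, never zero.
    """
    from .benchmark import add_unsigned_error, aue

    if min_diff is None:
        min_diff = 0.4 if feature == "res" else 0.0
    table = add_unsigned_error(table)
    higher, lower = [], []
    for _, grp in table.groupby("pair_id"):
        if len(grp) != 2 or grp[feature].isna().any():
            continue
        v = grp[feature].to_numpy()
        if abs(v[0] - v[1]) < max(min_diff, 1e-12):
            continue
        hi, lo = (0, 1) if v[0] > v[1] else (1, 0)
        higher.append(grp.iloc[hi]["ue"])
        lower.append(grp.iloc[lo]["ue"])
    out = {"n_pairs": len(higher)}
    out["higher"] = aue(higher, n_boot=n_boot, seed=seed) if higher else None
    out["lower"] = aue(lower, n_boot=n_boot, seed=seed + 1) if lower else None
    return out


def pearson_matrix(
    table: pd.DataFrame,
    columns: Sequence[str] = ("ue", "res", "lig_bf", "n_wat", "prot_bf"),
) -> pd.DataFrame:
    """Pearson correlation matrix of UE and the structural features.

    Requires at least 3 complete records; zero-variance columns yield NaN
    entries and a warning (never a silent 0).
    """
    from .benchmark import add_unsigned_error

    table = add_unsigned_error(table)
    sub = table.loc[:, list(columns)].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete records for a Pearson matrix")
    zero_var = [c for c in columns if np.isclose(sub[c].std(ddof=1), 0.0)]
    if zero_var:
        warnings.warn(
            f"zero-variance columns {zero_var}: correlation undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
    return sub.corr(method="pearson")
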