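"""Processing of HLA class I structures into weighted coarse-grained point clouds.

The peptide binding domain of an HLA class I alpha chain (the alpha-1/alpha-2
"groove", residues 2-180) is reduced to 179 labeled points: one per residue,
placed at the mass-weighted center of its side-chain heavy atoms, carrying the
residue identity and a per-position weight factor describing how strongly that
position shapes peptide binding specificity.

The pipeline is: parse PDB -> :func:`trim_binding_domain` ->
:func:`superpose` onto a common reference -> :func:`coarse_grain` ->
:func:`write_coarse_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.SVDSuperimposer import SVDSuperimposer

__all__ = [
    "RawStructure",
    "CoarseStructure",
    "WeightTable",
    "read_pdb",
    "trim_binding_domain",
    "superpose",
    "coarse_grain",
    "write_coarse_csv",
    "read_coarse_csv",
    "BINDING_DOMAIN_RANGE",
    "STANDARD_AA",
]

#: inclusive residue-number window of the class I peptide binding domain
BINDING_DOMAIN_RANGE = (2, 180)
N_BINDING_RESIDUES = BINDING_DOMAIN_RANGE[1] - BINDING_DOMAIN_RANGE[0] + 1  # 179

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# standard atomic masses of the heavy elements occurring in amino-acid side chains
ATOMIC_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "SE": 78.971}

CSV_COLUMNS = ["chain", "resnum", "resname", "x", "y", "z", "weight"]


@dataclass
class RawStructure:
    """Flat atom-record table for one structure (or one chain of it).

    Parallel arrays, one entry per atom. Coordinates are in Angstroms.
    """

    chain_ids: np.ndarray
    res_nums: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.res_nums = np.asarray(self.res_nums, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if not (len(self.chain_ids) == len(self.res_nums) == len(self.res_names) == n):
            raise ValueError("atom record arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_numbers(self) -> np.ndarray:
        """Sorted unique residue numbers present."""
        return np.unique(self.res_nums)

    def select(self, mask: np.ndarray) -> "RawStructure":
        return RawStructure(
            self.chain_ids[mask],
            self.res_nums[mask],
            self.res_names[mask],
            self.atom_names[mask],
            self.coords[mask],
            name=self.name,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "RawStructure":
        """Apply the rigid motion ``x -> x @ R + t`` to every atom."""
        return replace(self, coords=self.coords @ rotation + translation)

    def ca_coords(self, res_nums: np.ndarray | None = None) -> np.ndarray:
        """C-alpha coordinates ordered by residue number.

        Raises ``ValueError`` naming the first residue lacking a CA atom.
        """
        if res_nums is None:
            res_nums = self.residue_numbers()
        is_ca = self.atom_names == "CA"
        out = np.empty((len(res_nums), 3))
        for i, rn in enumerate(res_nums):
            hit = np.flatnonzero(is_ca & (self.res_nums == rn))
            if hit.size == 0:
                raise ValueError(f"residue {rn} has no CA atom")
            out[i] = self.coords[hit[0]]
        return out


@dataclass
class CoarseStructure:
    """One allele as an ordered cloud of weighted, residue-labeled points.

    A full binding-domain structure has exactly 179 points numbered 2..180;
    the metric itself works on clouds of any size, so strict validation is
    applied only where the 179-residue contract matters (CSV serialization).
    """

    allele_id: str
    chain_ids: np.ndarray
    res_nums: np.ndarray
    res_names: np.ndarray
    coords: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.res_nums)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.res_nums = np.asarray(self.res_nums, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        unknown = set(self.res_names) - STANDARD_AA
        if unknown:
            raise ValueError(f"non-standard residue name(s): {sorted(unknown)}")

    @property
    def n_residues(self) -> int:
        return len(self.res_nums)

    def validate_binding_domain(self) -> None:
        """Enforce the full 179-residue (2..180) contract."""
        lo, hi = BINDING_DOMAIN_RANGE
        expected = np.arange(lo, hi + 1)
        if self.n_residues != N_BINDING_RESIDUES or not np.array_equal(
            self.res_nums, expected
        ):
            raise ValueError(
                f"{self.allele_id!r}: expected residues {lo}..{hi} "
                f"(179 points), got {self.n_residues} residues"
            )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CoarseStructure":
        return replace(self, coords=self.coords @ rotation + translation)


@dataclass
class WeightTable:
    """Per-position weight factors acting as a soft contact threshold.

    Positions absent from the table fall back to ``default_weight`` — a small
    but nonzero value, so non-contact residues still contribute weakly.
    """

    weights: dict[int, float] = field(default_factory=dict)
    default_weight: float = 0.1

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()) or self.default_weight < 0:
            raise ValueError("weights must be non-negative")
        if not self.weights and self.default_weight == 0:
            raise ValueError("at least one weight must be positive")
        if self.weights and max(self.weights.values()) == 0 and self.default_weight == 0:
            raise ValueError("at least one weight must be positive")

    def __getitem__(self, position: int) -> float:
        return self.weights.get(int(position), self.default_weight)

    def lookup(self, positions: np.ndarray) -> np.ndarray:
        return np.array([self[p] for p in positions], dtype=float)

    @classmethod
    def uniform(cls, weight: float = 1.0) -> "WeightTable":
        return cls(weights={}, default_weight=weight)

    @classmethod
    def from_csv(cls, path: str | Path, default_weight: float = 0.1) -> "WeightTable":
        df = pd.read_csv(path, comment="#")
        if not {"position", "weight"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'position' and 'weight'")
        return cls(
            weights=dict(zip(df["position"].astype(int), df["weight"].astype(float))),
            default_weight=default_weight,
        )

    @classmethod
    def default(cls) -> "WeightTable":
        """The shipped contact-position weight table (pocket residues = 1.0)."""
        from .config import default_weight_table_path

        return cls.from_csv(default_weight_table_path())


def read_pdb(path: str | Path, name: str | None = None) -> RawStructure:
    """Parse a PDB file into a :class:`RawStructure`.

    Uses the first model only. Alternate locations other than blank/'A' are
    dropped; insertion codes are rejected because binding-domain numbering
    must be plain integers 2..180. Water and other heteroatoms are skipped.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure(path.stem, str(path)).get_models())
    chain_ids, res_nums, res_names, atom_names, coords = [], [], [], [], []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            if hetflag != " ":
                continue
            if icode.strip():
                raise ValueError(
                    f"{path.name}: residue {resseq}{icode.strip()} carries an "
                    "insertion code; renumber the structure to plain integers"
                )
            for atom in residue:
                if atom.get_altloc() not in (" ", "A"):
                    continue
                chain_ids.append(chain.id)
                res_nums.append(resseq)
                res_names.append(residue.get_resname())
                atom_names.append(atom.get_name())
                coords.append(atom.get_coord())
    if not atom_names:
        raise ValueError(f"{path.name}: no usable ATOM records")
    return RawStructure(
        chain_ids, res_nums, res_names, atom_names, np.array(coords, dtype=float),
        name=name if name is not None else path.stem,
    )


def trim_binding_domain(raw: RawStructure, chain: str = "A") -> RawStructure:
    """Restrict to the 179 binding-domain residues (2..180) of one chain.

    Raises ``ValueError`` listing missing positions if the window is gapped,
    or if the chain is absent.
    """
    on_chain = raw.chain_ids == chain
    if not on_chain.any():
        raise ValueError(f"chain {chain!r} not found (have {sorted(set(raw.chain_ids))})")
    lo, hi = BINDING_DOMAIN_RANGE
    present = set(raw.res_nums[on_chain].tolist())
    missing = [r for r in range(lo, hi + 1) if r not in present]
    if missing:
        raise ValueError(
            f"chain {chain!r} is missing binding-domain residue(s): {missing}"
        )
    keep = on_chain & (raw.res_nums >= lo) & (raw.res_nums <= hi)
    return raw.select(keep)


def superpose(mobile: RawStructure, reference: RawStructure) -> RawStructure:
    """Rigid least-squares fit of ``mobile`` onto ``reference`` over CA atoms.

    Both structures must already be trimmed to the binding domain. The fit
    is the closed-form SVD (Kabsch) solution over the 179 matched C-alpha
    positions, equally weighted; reflections are excluded, so internal
    geometry (chirality included) is preserved exactly.
    """
    lo, hi = BINDING_DOMAIN_RANGE
    res_window = np.arange(lo, hi + 1)
    ref_ca = reference.ca_coords(res_window)
    mob_ca = mobile.ca_coords(res_window)
    sup = SVDSuperimposer()
    sup.set(ref_ca, mob_ca)
    sup.run()
    rot, tran = sup.get_rotran()
    return mobile.transformed(rot, tran)


def _element_of(atom_name: str) -> str:
    """Heavy-atom element from a PDB atom name; '' for hydrogen/deuterium."""
    stripped = atom_name.lstrip("0123456789")
    if not stripped or stripped[0] in ("H", "D"):
        return ""
    if stripped[:2] == "SE":
        return "SE"
    return stripped[0]


def coarse_grain(trimmed: RawStructure, weights: WeightTable) -> CoarseStructure:
    """Collapse each residue to its side-chain center of mass.

    Backbone atoms (N, CA, C, O, OXT) and hydrogens are excluded; remaining
    heavy atoms are averaged with standard atomic masses. Glycine, which has
    no side-chain heavy atoms, is represented by its CA position. The output
    is ordered by residue number and carries the looked-up weight factor.
    """
    res_nums = trimmed.residue_numbers()
    chain_out, names_out, points = [], [], []
    for rn in res_nums:
        at = np.flatnonzero(trimmed.res_nums == rn)
        resname = trimmed.res_names[at[0]]
        if resname not in STANDARD_AA:
            raise ValueError(f"residue {rn}: unknown residue name {resname!r}")
        side, masses = [], []
        for i in at:
            aname = trimmed.atom_names[i]
            if aname in BACKBONE_ATOMS:
                continue
            elem = _element_of(aname)
            if not elem:  # hydrogen
                continue
            if elem not in ATOMIC_MASSES:
                raise ValueError(f"residue {rn}: unexpected element {elem!r} in {aname!r}")
            side.append(trimmed.coords[i])
            masses.append(ATOMIC_MASSES[elem])
        if side:
            m = np.asarray(masses)
            point = (np.asarray(side) * m[:, None]).sum(axis=0) / m.sum()
        elif resname == "GLY":
            ca = np.flatnonzero((trimmed.res_nums == rn) & (trimmed.atom_names == "CA"))
            if ca.size == 0:
                raise ValueError(f"glycine {rn} lacks a CA atom")
            point = trimmed.coords[ca[0]]
        else:
            raise ValueError(f"residue {rn} ({resname}) has no side-chain atoms")
        chain_out.append(trimmed.chain_ids[at[0]])
        names_out.append(resname)
        points.append(point)
    return CoarseStructure(
        allele_id=trimmed.name,
        chain_ids=np.array(chain_out, dtype=object),
        res_nums=res_nums,
        res_names=np.array(names_out, dtype=object),
        coords=np.array(points),
        weights=weights.lookup(res_nums),
    )


def write_coarse_csv(cs: CoarseStructure, path: str | Path) -> None:
    """Serialize a binding-domain cloud as the 179-row, 7-column CSV."""
    cs.validate_binding_domain()
    df = pd.DataFrame(
        {
            "chain": cs.chain_ids,
            "resnum": cs.res_nums,
            "resname": cs.res_names,
            "x": cs.coords[:, 0],
            "y": cs.coords[:, 1],
            "z": cs.coords[:, 2],
            "weight": cs.weights,
        }
    )
    df.to_csv(path, index=False, float_format="%.8g", lineterminator="\n")


def read_coarse_csv(path: str | Path, allele_id: str | None = None) -> CoarseStructure:
    """Read a processed-structure CSV back into a :class:`CoarseStructure`.

    Enforces the 179-row x 7-column contract and reports the offending row
    on unparsable numeric fields.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != CSV_COLUMNS:
        raise ValueError(f"{path.name}: expected columns {CSV_COLUMNS}, got {list(df.columns)}")
    if len(df) != N_BINDING_RESIDUES:
        raise ValueError(f"{path.name}: expected {N_BINDING_RESIDUES} rows, got {len(df)}")
    numeric = {}
    for col in ("resnum", "x", "y", "z", "weight"):
        try:
            numeric[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
            raise ValueError(f"{path.name}: unparsable {col!r} at line {row}") from None
    cs = CoarseStructure(
        allele_id=allele_id if allele_id is not None else path.stem,
        chain_ids=df["chain"].to_numpy(dtype=object),
        res_nums=numeric["resnum"].to_numpy(dtype=int),
        res_names=df["resname"].to_numpy(dtype=object),
        coords=np.column_stack([numeric["x"], numeric["y"], numeric["z"]]),
        weights=numeric["weight"].to_numpy(dtype=float),
    )
    cs.validate_binding_domain()
    return cs
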