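"""Structure input, coarse-graining and ideal B-DNA construction.

Proteins are reduced to one bead per residue, placed on the C-alpha atom.
Bonded terms (bonds, angles, dihedrals) take their reference values from the
input conformation; native contacts are defined by a heavy-atom distance
criterion between residues separated in sequence.  DNA is built as a static,
ideal double helix with three beads per nucleotide (phosphate, sugar, base)
aligned on the Z axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "AtomRecordSet",
    "ChargeScheme",
    "DEFAULT_CHARGE_SCHEME",
    "CGProtein",
    "BDNADuplex",
    "StructureError",
    "StructureParseError",
    "ChainBreakError",
    "load_structure",
    "coarse_grain_protein",
    "build_native_contacts",
    "build_bdna",
    "write_cg_protein",
    "read_cg_protein",
    "write_bdna",
    "read_bdna",
    "write_contacts_tsv",
]


class StructureError(ValueError):
    """Problem with the content of a structure."""


class StructureParseError(StructureError):
    """A PDB record could not be parsed; the message names the line."""


class ChainBreakError(StructureError):
    """Sequential C-alpha distance exceeds the chain-break threshold."""


# --------------------------------------------------------------------------
# Atomic records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    chain_id: str
    res_number: int
    res_name: str
    atom_name: str
    position: tuple[float, float, float]
    element: str = ""


@dataclass
class AtomRecordSet:
    """All ATOM records of a structure, in file order."""

    atoms: list[Atom]
    source: str = "<string>"

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.position):
                raise StructureError(
                    f"non-finite coordinate in {a.chain_id}/{a.res_number}/{a.atom_name}"
                )

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def select_chains(self, chain_ids: Iterable[str]) -> "AtomRecordSet":
        wanted = set(chain_ids)
        return AtomRecordSet(
            [a for a in self.atoms if a.chain_id in wanted],
            source=self.source,
        )

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue number, residue name)."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_number)
            if key not in seen:
                seen.add(key)
                out.append((a.chain_id, a.res_number, a.res_name))
        return out

    def __len__(self) -> int:
        return len(self.atoms)


_COORD_SLICES = (slice(30, 38), slice(38, 46), slice(46, 54))


def load_structure(pdb_content: str, source: str = "<string>") -> AtomRecordSet:
    """Parse ATOM records from PDB-format text.

    HETATM records are skipped; alternate locations other than blank/'A' are
    discarded.  A malformed ATOM record raises :class:`StructureParseError`
    naming the offending line; input without any C-alpha atom raises
    :class:`StructureError` ("not a protein chain").
    """
    atoms: list[Atom] = []
    for lineno, line in enumerate(pdb_content.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise StructureParseError(
                f"{source}, line {lineno}: ATOM record too short ({len(line)} chars)"
            )
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        try:
            name = line[12:16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip() or "A"
            res_number = int(line[22:26])
            xyz = tuple(float(line[s]) for s in _COORD_SLICES)
        except ValueError as exc:
            raise StructureParseError(
                f"{source}, line {lineno}: cannot parse ATOM record ({exc})"
            ) from exc
        element = line[76:78].strip() if len(line) >= 78 else ""
        atoms.append(Atom(chain_id, res_number, res_name, name, xyz, element))
    if not atoms:
        raise StructureParseError(f"{source}: no ATOM records found")
    if not any(a.atom_name == "CA" for a in atoms):
        raise StructureError(f"{source}: no C-alpha atoms — not a protein chain")
    return AtomRecordSet(atoms, source=source)


# --------------------------------------------------------------------------
# Charge scheme
# --------------------------------------------------------------------------

_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


@dataclass(frozen=True)
class ChargeScheme:
    """Residue-type to charge map in units of the elementary charge.

    Charges are restricted to {-1, 0, +1}; the map must cover all twenty
    amino-acid types.  The DNA phosphate bead always carries -1.
    """

    charges: Mapping[str, int]
    phosphate_charge: int = -1

    def __post_init__(self) -> None:
        missing = [aa for aa in _AA3 if aa not in self.charges]
        if missing:
            raise ValueError(f"charge scheme missing residue types: {missing}")
        bad = {r: q for r, q in self.charges.items() if q not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"charges must be in {{-1, 0, +1}}: {bad}")
        if self.phosphate_charge != -1:
            raise ValueError("DNA phosphate bead charge must be -1")

    def charge_of(self, res_name: str) -> int:
        return int(self.charges.get(res_name, 0))


DEFAULT_CHARGE_SCHEME = ChargeScheme(
    {aa: 0 for aa in _AA3}
    | {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1, "HIS": +1}
)


# --------------------------------------------------------------------------
# Coarse-grained protein
# --------------------------------------------------------------------------

@dataclass
class CGProtein:
    """One-bead-per-residue protein model with native topology.

    Bead indices are 0-based; ``res_numbers`` keep the (1-based) PDB
    numbering.  ``contacts`` hold the native-contact pairs with their
    reference distances A_ij measured between beads in the source structure.
    """

    positions: np.ndarray          # (N, 3) Å
    charges: np.ndarray            # (N,) elementary charges
    chain_ids: np.ndarray          # (N,) unicode
    res_numbers: np.ndarray        # (N,) int
    res_names: np.ndarray          # (N,) unicode
    bonds: np.ndarray              # (B, 2) int
    bond_r0: np.ndarray            # (B,) Å
    angles: np.ndarray             # (A, 3) int
    angle_t0: np.ndarray           # (A,) rad
    dihedrals: np.ndarray          # (D, 4) int
    dihedral_p0: np.ndarray        # (D,) rad
    contacts: np.ndarray           # (C, 2) int, i < j
    contact_r0: np.ndarray         # (C,) Å
    repulsion_radii: np.ndarray    # (N,) Å
    label: str = "protein"

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def with_charges(self, charges: np.ndarray, label: str | None = None) -> "CGProtein":
        charges = np.asarray(charges, dtype=float)
        if charges.shape != (self.n_beads,):
            raise ValueError("charge vector has wrong length")
        return replace(self, charges=charges, label=label or self.label)

    def bead_index(self, chain_id: str, res_number: int) -> int:
        hit = np.where(
            (self.chain_ids == chain_id) & (self.res_numbers == res_number)
        )[0]
        if hit.size == 0:
            raise KeyError(f"residue {chain_id}/{res_number} not in model")
        return int(hit[0])

    def validate(self) -> None:
        n = self.n_beads
        for arr, width in ((self.bonds, 2), (self.angles, 3),
                           (self.dihedrals, 4), (self.contacts, 2)):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise StructureError("topology index out of range")
            if arr.ndim != 2 or arr.shape[1] != width:
                raise StructureError("malformed topology array")
        if self.contacts.size:
            bonded = {tuple(sorted(b)) for b in self.bonds.tolist()}
            angled = {(min(a[0], a[2]), max(a[0], a[2])) for a in self.angles.tolist()}
            for i, j in self.contacts.tolist():
                if i == j:
                    raise StructureError("self-contact in native-contact list")
                if tuple(sorted((i, j))) in bonded | angled:
                    raise StructureError("contact pair duplicates a bonded pair")


def _vec_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _vec_dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    sinp = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    return float(np.arctan2(sinp, np.dot(n1, n2)))


def build_native_contacts(
    atoms: AtomRecordSet,
    cutoff: float = 4.5,
    min_seq_sep: int = 3,
) -> list[tuple[int, int, float]]:
    """Native-contact pairs from a heavy-atom distance criterion.

    A residue pair (i, j) — indices into the flattened residue order — is in
    contact iff any heavy-atom pair between the two residues lies within
    ``cutoff`` Å and the sequence separation is at least ``min_seq_sep``
    (pairs on different chains always satisfy the separation requirement).
    The stored distance A_ij is the C-alpha/C-alpha distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_seq_sep < 3:
        raise ValueError("min_seq_sep must be >= 3")
    residues = atoms.residues()
    index_of = {(c, r): k for k, (c, r, _) in enumerate(residues)}
    heavy: list[list[tuple[float, float, float]]] = [[] for _ in residues]
    ca: dict[int, np.ndarray] = {}
    for a in atoms.atoms:
        k = index_of[(a.chain_id, a.res_number)]
        if a.atom_name.startswith("H") or a.element == "H":
            continue
        heavy[k].append(a.position)
        if a.atom_name == "CA":
            ca[k] = np.asarray(a.position)
    contacts: list[tuple[int, int, float]] = []
    coords = [np.asarray(h) for h in heavy]
    for i in range(len(residues)):
        ci, ri, _ = residues[i]
        for j in range(i + 1, len(residues)):
            cj, rj, _ = residues[j]
            if ci == cj and j - i < min_seq_sep:
                continue
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :], axis=-1)
            if d.min() <= cutoff:
                if i not in ca or j not in ca:
                    raise StructureError(
                        f"residue {residues[i if i not in ca else j][:2]} has no C-alpha"
                    )
                contacts.append((i, j, float(np.linalg.norm(ca[i] - ca[j]))))
    return contacts


def coarse_grain_protein(
    atoms: AtomRecordSet,
    scheme: ChargeScheme = DEFAULT_CHARGE_SCHEME,
    contact_cutoff: float = 4.5,
    min_seq_sep: int = 3,
    chain_break_cutoff: float = 4.5,
    on_chain_break: str = "warn",
    repulsion_radius: float = 2.0,
    label: str | None = None,
) -> CGProtein:
    """Reduce a structure to one bead per residue at the C-alpha position.

    Reference bond lengths, angles and dihedrals are measured on the input
    conformation.  Sequential C-alpha distances above ``chain_break_cutoff``
    are treated as chain breaks: bonded terms are not built across the gap
    and a warning (or error, per ``on_chain_break``) is emitted.
    """
    residues = atoms.residues()
    if len(residues) < 4:
        raise StructureError("need at least 4 residues to build dihedrals")
    if on_chain_break not in ("warn", "error"):
        raise ValueError("on_chain_break must be 'warn' or 'error'")

    ca_pos: dict[tuple[str, int], np.ndarray] = {}
    for a in atoms.atoms:
        if a.atom_name == "CA":
            ca_pos.setdefault((a.chain_id, a.res_number), np.asarray(a.position, float))
    for c, r, name in residues:
        if (c, r) not in ca_pos:
            raise StructureError(f"residue {c}/{r} ({name}) is missing its C-alpha atom")

    pos = np.array([ca_pos[(c, r)] for c, r, _ in residues])
    charges = np.array([float(scheme.charge_of(name)) for _, _, name in residues])
    chain_ids = np.array([c for c, _, _ in residues])
    res_numbers = np.array([r for _, r, _ in residues], dtype=int)
    res_names = np.array([name for _, _, name in residues])

    # sequential bonds, broken at chain boundaries and distance gaps
    bonded_next = np.zeros(len(residues), dtype=bool)
    for i in range(len(residues) - 1):
        if chain_ids[i] != chain_ids[i + 1]:
            continue
        d = float(np.linalg.norm(pos[i + 1] - pos[i]))
        if d > chain_break_cutoff:
            msg = (
                f"chain break between residues {chain_ids[i]}/{res_numbers[i]} and "
                f"{chain_ids[i + 1]}/{res_numbers[i + 1]} (C-alpha distance {d:.2f} Å)"
            )
            if on_chain_break == "error":
                raise ChainBreakError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        bonded_next[i] = True

    bonds, bond_r0 = [], []
    angles, angle_t0 = [], []
    dihedrals, dihedral_p0 = [], []
    for i in range(len(residues) - 1):
        if bonded_next[i]:
            bonds.append((i, i + 1))
            bond_r0.append(float(np.linalg.norm(pos[i + 1] - pos[i])))
    for i in range(len(residues) - 2):
        if bonded_next[i] and bonded_next[i + 1]:
            angles.append((i, i + 1, i + 2))
            angle_t0.append(_vec_angle(pos[i], pos[i + 1], pos[i + 2]))
    for i in range(len(residues) - 3):
        if bonded_next[i] and bonded_next[i + 1] and bonded_next[i + 2]:
            dihedrals.append((i, i + 1, i + 2, i + 3))
            dihedral_p0.append(
                _vec_dihedral(pos[i], pos[i + 1], pos[i + 2], pos[i + 3])
            )

    raw_contacts = build_native_contacts(atoms, cutoff=contact_cutoff,
                                         min_seq_sep=min_seq_sep)
    contacts = np.array([(i, j) for i, j, _ in raw_contacts], dtype=int).reshape(-1, 2)
    contact_r0 = np.array([a for _, _, a in raw_contacts], dtype=float)

    protein = CGProtein(
        positions=pos,
        charges=charges,
        chain_ids=chain_ids,
        res_numbers=res_numbers,
        res_names=res_names,
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        bond_r0=np.array(bond_r0, dtype=float),
        angles=np.array(angles, dtype=int).reshape(-1, 3),
        angle_t0=np.array(angle_t0, dtype=float),
        dihedrals=np.array(dihedrals, dtype=int).reshape(-1, 4),
        dihedral_p0=np.array(dihedral_p0, dtype=float),
        contacts=contacts,
        contact_r0=contact_r0,
        repulsion_radii=np.full(len(residues), float(repulsion_radius)),
        label=label or atoms.source,
    )
    protein.validate()
    return protein


# --------------------------------------------------------------------------
# Ideal B-DNA
# --------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# Cylindrical bead placement (radius Å, azimuth offset rad, z offset Å) for
# phosphate/sugar/base groups of an ideal B-form duplex.  Only the relative
# geometry (groove shape, charge spacing) matters at this resolution.
_BEAD_GEOMETRY = {
    "P": (8.9, 0.00, 0.0),
    "S": (7.4, 0.40, 0.0),
    "B": (3.2, 0.85, 0.0),
}
# Azimuthal phase between the two strands of a base pair; sets the relative
# widths of the major and minor grooves.
_STRAND_PHASE = math.radians(140.0)


@dataclass
class BDNADuplex:
    """Static ideal B-DNA at three beads per nucleotide, axis on Z.

    The helical sense is chosen so that a groove-tracking trajectory moving
    toward +Z accumulates *negative* azimuth, matching the sign convention
    used for the rotation-translation coupling slope.
    """

    sequence: str
    rise: float                   # Å per bp
    twist: float                  # degrees per bp
    positions: np.ndarray         # (M, 3) Å
    charges: np.ndarray           # (M,)
    strand: np.ndarray            # (M,) 'A' or 'B'
    nt_index: np.ndarray          # (M,) 0-based along each strand 5'->3'
    kind: np.ndarray              # (M,) 'P', 'S' or 'B'

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    @property
    def z_length(self) -> float:
        """Axial period of the duplex (one rise per base pair)."""
        return self.n_bp * self.rise

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def base_bead_positions(self, strand: str = "A") -> np.ndarray:
        mask = (self.strand == strand) & (self.kind == "B")
        order = np.argsort(self.nt_index[mask])
        return self.positions[mask][order]


def build_bdna(
    sequence: str,
    rise: float = 3.4,
    twist: float = 36.0,
    include_5p_phosphate: bool = True,
) -> BDNADuplex:
    """Build an ideal double-stranded B-DNA aligned on the Z axis.

    Defaults give the canonical helical pitch: 10 bp per full turn, 34 Å of
    axial rise per turn.  Each nucleotide contributes phosphate, sugar and
    base beads; phosphates carry charge -1, all other beads are neutral.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")

    n = len(sequence)
    twist_rad = math.radians(twist)
    rows: list[tuple[str, int, str, float, float, float, float]] = []

    def add_nucleotide(strand: str, idx: int, bp: int, mirror: float) -> None:
        phi0 = -bp * twist_rad + (0.0 if strand == "A" else _STRAND_PHASE)
        z0 = bp * rise
        for kind in ("P", "S", "B"):
            radius, dphi, dz = _BEAD_GEOMETRY[kind]
            phi = phi0 + mirror * dphi
            q = -1.0 if kind == "P" else 0.0
            if kind == "P" and idx == 0 and not include_5p_phosphate:
                q = 0.0
            rows.append(
                (strand, idx, kind,
                 radius * math.cos(phi), radius * math.sin(phi), z0 + dz, q)
            )

    for i in range(n):                      # strand A, 5'->3' along +Z
        add_nucleotide("A", i, i, +1.0)
    for j in range(n):                      # strand B antiparallel
        add_nucleotide("B", j, n - 1 - j, -1.0)

    return BDNADuplex(
        sequence=sequence,
        rise=float(rise),
        twist=float(twist),
        positions=np.array([(x, y, z) for _, _, _, x, y, z, _ in rows]),
        charges=np.array([q for *_, q in rows]),
        strand=np.array([s for s, *_ in rows]),
        nt_index=np.array([i for _, i, *_ in rows], dtype=int),
        kind=np.array([k for _, _, k, *_ in rows]),
    )


def complement(sequence: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(sequence.upper()))


# --------------------------------------------------------------------------
# Plain-text model files
# --------------------------------------------------------------------------

_CG_MAGIC = "#slidescope-cg v1"


def _fmt(x: float) -> str:
    return repr(float(x))


def write_cg_protein(protein: CGProtein, path) -> None:
    """Write a CGProtein to the documented plain-text model format.

    The float formatting round-trips IEEE doubles exactly, so read-back
    reproduces all fields bit-for-bit.
    """
    lines = [f"{_CG_MAGIC} kind=protein label={protein.label}"]
    lines.append(f"beads {protein.n_beads}")
    for i in range(protein.n_beads):
        x, y, z = protein.positions[i]
        lines.append(
            f"{i}\t{protein.chain_ids[i]}\t{protein.res_numbers[i]}\t"
            f"{protein.res_names[i]}\t{_fmt(x)}\t{_fmt(y)}\t{_fmt(z)}\t"
            f"{_fmt(protein.charges[i])}\t{_fmt(protein.repulsion_radii[i])}"
        )
    for name, idx, ref in (
        ("bonds", protein.bonds, protein.bond_r0),
        ("angles", protein.angles, protein.angle_t0),
        ("dihedrals", protein.dihedrals, protein.dihedral_p0),
        ("contacts", protein.contacts, protein.contact_r0),
    ):
        lines.append(f"{name} {len(idx)}")
        for row, r in zip(idx.tolist(), ref.tolist()):
            lines.append("\t".join(str(k) for k in row) + "\t" + _fmt(r))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cg_protein(path) -> CGProtein:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_CG_MAGIC):
        raise StructureParseError(f"{path}: not a slidescope-cg v1 file")
    header = lines[0]
    label = header.split("label=", 1)[1] if "label=" in header else "protein"
    if "kind=protein" not in header:
        raise StructureParseError(f"{path}: not a protein model file")
    pos = 1
    sections: dict[str, list[list[str]]] = {}
    while pos < len(lines):
        name, count = lines[pos].split()
        count = int(count)
        sections[name] = [lines[pos + 1 + k].split("\t") for k in range(count)]
        pos += 1 + count
    beads = sections["beads"]
    n = len(beads)
    protein = CGProtein(
        positions=np.array([[float(b[4]), float(b[5]), float(b[6])] for b in beads]),
        charges=np.array([float(b[7]) for b in beads]),
        chain_ids=np.array([b[1] for b in beads]),
        res_numbers=np.array([int(b[2]) for b in beads], dtype=int),
        res_names=np.array([b[3] for b in beads]),
        bonds=np.array([[int(r[0]), int(r[1])] for r in sections["bonds"]],
                       dtype=int).reshape(-1, 2),
        bond_r0=np.array([float(r[2]) for r in sections["bonds"]]),
        angles=np.array([[int(r[0]), int(r[1]), int(r[2])] for r in sections["angles"]],
                        dtype=int).reshape(-1, 3),
        angle_t0=np.array([float(r[3]) for r in sections["angles"]]),
        dihedrals=np.array(
            [[int(r[0]), int(r[1]), int(r[2]), int(r[3])] for r in sections["dihedrals"]],
            dtype=int).reshape(-1, 4),
        dihedral_p0=np.array([float(r[4]) for r in sections["dihedrals"]]),
        contacts=np.array([[int(r[0]), int(r[1])] for r in sections["contacts"]],
                          dtype=int).reshape(-1, 2),
        contact_r0=np.array([float(r[2]) for r in sections["contacts"]]),
        repulsion_radii=np.array([float(b[8]) for b in beads]),
        label=label,
    )
    if n != protein.n_beads:
        raise StructureParseError(f"{path}: bead count mismatch")
    return protein


def write_bdna(dna: BDNADuplex, path) -> None:
    lines = [f"{_CG_MAGIC} kind=dna sequence={dna.sequence} "
             f"rise={_fmt(dna.rise)} twist={_fmt(dna.twist)}"]
    lines.append(f"beads {dna.n_beads}")
    for i in range(dna.n_beads):
        x, y, z = dna.positions[i]
        lines.append(
            f"{i}\t{dna.strand[i]}\t{dna.nt_index[i]}\t{dna.kind[i]}\t"
            f"{_fmt(x)}\t{_fmt(y)}\t{_fmt(z)}\t{_fmt(dna.charges[i])}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_bdna(path) -> BDNADuplex:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_CG_MAGIC) or "kind=dna" not in lines[0]:
        raise StructureParseError(f"{path}: not a slidescope-cg v1 DNA file")
    fields = dict(tok.split("=", 1) for tok in lines[0].split()[2:])
    count = int(lines[1].split()[1])
    rows = [lines[2 + k].split("\t") for k in range(count)]
    return BDNADuplex(
        sequence=fields["sequence"],
        rise=float(fields["rise"]),
        twist=float(fields["twist"]),
        positions=np.array([[float(r[4]), float(r[5]), float(r[6])] for r in rows]),
        charges=np.array([float(r[7]) for r in rows]),
        strand=np.array([r[1] for r in rows]),
        nt_index=np.array([int(r[2]) for r in rows], dtype=int),
        kind=np.array([r[3] for r in rows]),
    )


def write_contacts_tsv(protein: CGProtein, path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tA_ij\n")
        for (i, j), a in zip(protein.contacts.tolist(), protein.contact_r0.tolist()):
            fh.write(f"{i}\t{j}\t{_fmt(a)}\n")
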