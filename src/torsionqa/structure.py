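"""Structure reading, normalization and residue correspondence.

PDB and mmCIF files are parsed with Biopython into a small in-memory
model (:class:`StructureRecord`) that keeps author numbering, insertion
codes, occupancies and B-factors.  Alternate locations are resolved to
the highest-occupancy conformer.  Residue correspondence between two
structures is established either by author numbering (CASP models share
target numbering) or by per-chain global sequence alignment (templates
from unrelated depositions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import MMCIFParser, PDBParser

from ._geometry import NONSTANDARD_PARENT, STANDARD_AA, THREE_TO_ONE

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureRecord",
    "ResiduePair",
    "StructureError",
    "FormatError",
    "ContentError",
    "PairingError",
    "read_structure",
    "write_pdb",
    "write_mmcif",
    "pair_residues",
]


class StructureError(ValueError):
    """Base class for structure-handling errors."""


class FormatError(StructureError):
    """The input file could not be parsed in the requested format."""


class ContentError(StructureError):
    """The file parsed but contains no usable polymer content."""


class PairingError(StructureError):
    """No residues could be paired between two structures."""


@dataclass
class AtomRecord:
    """A single heavy (or hydrogen) atom.

    ``b_factor`` carries whatever the source column held; for prediction
    files it may be reinterpreted downstream as an RMS coordinate-error
    estimate in Å.
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.position.copy(),
                          self.occupancy, self.b_factor, self.altloc)


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_type: str
    atoms: list[AtomRecord] = field(default_factory=list)
    is_polymer: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def standard_type(self) -> Optional[str]:
        """Standard parent residue type, or None if unmappable."""
        if self.res_type in STANDARD_AA:
            return self.res_type
        return NONSTANDARD_PARENT.get(self.res_type)

    @property
    def one_letter(self) -> str:
        std = self.standard_type
        return THREE_TO_ONE[std] if std else "X"

    def get_atom(self, name: str) -> Optional[AtomRecord]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(self.chain_id, self.seq_number,
                             self.insertion_code, self.res_type,
                             [a.copy() for a in self.atoms], self.is_polymer)


@dataclass
class StructureRecord:
    identifier: str
    chains: dict[str, list[ResidueRecord]]
    source_format: Literal["pdb", "mmcif", "memory"] = "memory"
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        for residues in self.chains.values():
            residues.sort(key=lambda r: (r.seq_number, r.insertion_code))

    def residues(self) -> Iterator[ResidueRecord]:
        for chain in self.chains.values():
            yield from chain

    def polymer_residues(self, chain_id: Optional[str] = None) -> list[ResidueRecord]:
        out = []
        for cid, chain in self.chains.items():
            if chain_id is not None and cid != chain_id:
                continue
            out.extend(r for r in chain if r.is_polymer)
        return out

    def polymer_chain_ids(self) -> list[str]:
        return [cid for cid, ch in self.chains.items()
                if any(r.is_polymer for r in ch)]

    def n_polymer_residues(self) -> int:
        return len(self.polymer_residues())

    def copy(self) -> "StructureRecord":
        return StructureRecord(
            self.identifier,
            {cid: [r.copy() for r in ch] for cid, ch in self.chains.items()},
            self.source_format,
            self.resolution,
        )


@dataclass
class ResiduePair:
    """A target residue matched (or not) with a model/template residue."""

    target_residue: ResidueRecord
    model_residue: Optional[ResidueRecord]
    mutated: bool = False


_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


def _resolve_altlocs(atoms: Sequence) -> list:
    """Keep only the best conformer per atom name.

    Highest occupancy wins; ties break to the lexicographically first
    altloc identifier.
    """
    by_name: dict[str, list] = {}
    for atom in atoms:
        by_name.setdefault(atom.get_name(), []).append(atom)
    chosen = []
    for name, group in by_name.items():
        best = min(
            group,
            key=lambda a: (-(a.get_occupancy() if a.get_occupancy() is not None else 1.0),
                           a.get_altloc()),
        )
        chosen.append(best)
    chosen.sort(key=lambda a: a.get_serial_number() or 0)
    return chosen


def read_structure(path, fmt: Optional[str] = None,
                   identifier: Optional[str] = None) -> StructureRecord:
    """Read a PDB or mmCIF file into a :class:`StructureRecord`.

    The first model of multi-model files is used.  For alternate
    locations only the highest-occupancy conformer is retained.  Waters
    and non-amino-acid heteroatoms are kept but flagged non-polymer.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    fmt = fmt.lower()
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format {fmt!r}")

    parser = PDBParser(QUIET=True) if fmt == "pdb" else MMCIFParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(identifier or path.stem, str(path))
    except Exception as exc:  # Biopython raises assorted exception types
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc

    models = list(bio_structure.get_models())
    if not models:
        raise ContentError(f"{path}: no models in file")

    resolution = None
    header = getattr(bio_structure, "header", None)
    if isinstance(header, dict):
        resolution = header.get("resolution")
        if resolution is not None:
            try:
                resolution = float(resolution)
            except (TypeError, ValueError):
                resolution = None

    chains: dict[str, list[ResidueRecord]] = {}
    for chain in models[0]:
        residues = []
        for res in chain:
            hetflag, seq_number, icode = res.get_id()
            res_type = res.get_resname().strip()
            is_water = hetflag == "W" or res_type in _WATER_NAMES
            is_polymer = (not is_water) and (
                res_type in STANDARD_AA or res_type in NONSTANDARD_PARENT
            )
            atoms = []
            for atom in _resolve_altlocs(list(res.get_unpacked_list())):
                altloc = atom.get_altloc()
                atoms.append(AtomRecord(
                    name=atom.get_name(),
                    element=(atom.element or "").strip() or atom.get_name()[0],
                    position=np.array(atom.get_coord(), dtype=float),
                    occupancy=float(atom.get_occupancy()
                                    if atom.get_occupancy() is not None else 1.0),
                    b_factor=float(atom.get_bfactor()
                                   if atom.get_bfactor() is not None else 0.0),
                    altloc="" if altloc == " " else altloc,
                ))
            residues.append(ResidueRecord(
                chain_id=chain.id,
                seq_number=int(seq_number),
                insertion_code=icode.strip(),
                res_type=res_type,
                atoms=atoms,
                is_polymer=is_polymer,
            ))
        if residues:
            chains[chain.id] = residues

    record = StructureRecord(identifier or path.stem, chains,
                             source_format=fmt, resolution=resolution)
    if record.n_polymer_residues() == 0:
        raise ContentError(f"{path}: no polymer residues")
    for res in record.residues():
        if res.is_polymer and res.res_type not in STANDARD_AA:
            logger.info("nonstandard residue %s %s mapped to %s",
                        res.res_type, res.key, res.standard_type)
    return record


_PDB_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}"
    "{seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _pdb_atom_name(name: str, element: str) -> str:
    # Element columns 13-14: single-letter elements start at column 14.
    if len(name) >= 4 or (len(element) == 2 and name.upper().startswith(element.upper())):
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(structure: StructureRecord, path) -> None:
    """Write a fixed-column PDB file.

    Occupancy and B columns are emitted at PDB precision (two decimals);
    B-factors are clamped to the 999.99 column maximum, with a warning.
    """
    lines = []
    serial = 1
    clamped = 0
    for cid, chain in structure.chains.items():
        last_polymer = None
        for res in chain:
            record = "ATOM" if res.is_polymer and res.res_type in STANDARD_AA else "HETATM"
            for atom in res.atoms:
                b = atom.b_factor
                if b > 999.99:
                    b = 999.99
                    clamped += 1
                lines.append(_PDB_ATOM_FMT.format(
                    record=record, serial=serial,
                    name=_pdb_atom_name(atom.name, atom.element),
                    altloc=atom.altloc or " ",
                    res=res.res_type, chain=cid, seq=res.seq_number,
                    icode=res.insertion_code or " ",
                    x=atom.position[0], y=atom.position[1], z=atom.position[2],
                    occ=atom.occupancy, b=b, element=atom.element.upper(),
                ))
                serial += 1
            if res.is_polymer:
                last_polymer = res
        if last_polymer is not None:
            lines.append(f"TER   {serial:>5d}      {last_polymer.res_type:<3s} "
                         f"{cid:1s}{last_polymer.seq_number:>4d}"
                         f"{last_polymer.insertion_code or ' '}\n")
            serial += 1
    lines.append("END\n")
    if clamped:
        logger.warning("%d B-factor(s) clamped to the 999.99 PDB column maximum",
                       clamped)
    Path(path).write_text("".join(lines))


_MMCIF_HEADER = """\
data_{block}
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
"""


def write_mmcif(structure: StructureRecord, path) -> None:
    """Write a minimal mmCIF atom_site loop (round-trippable by Biopython)."""
    rows = []
    serial = 1
    for cid, chain in structure.chains.items():
        for i, res in enumerate(chain, start=1):
            group = "ATOM" if res.is_polymer and res.res_type in STANDARD_AA else "HETATM"
            icode = res.insertion_code or "?"
            for atom in res.atoms:
                alt = atom.altloc or "."
                x, y, z = atom.position
                rows.append(
                    f"{group} {serial} {atom.element.upper()} {atom.name} {alt} "
                    f"{res.res_type} {cid} 1 {i} {icode} "
                    f"{x:.3f} {y:.3f} {z:.3f} {atom.occupancy:.2f} "
                    f"{min(atom.b_factor, 999.99):.2f} "
                    f"{res.seq_number} {res.res_type} {cid} {atom.name} 1\n"
                )
                serial += 1
    text = _MMCIF_HEADER.format(block=structure.identifier or "structure")
    Path(path).write_text(text + "".join(rows) + "#\n")


def _chain_sequence(residues: Sequence[ResidueRecord]) -> str:
    return "".join(r.one_letter for r in residues)


def _align_chain(target: Sequence[ResidueRecord],
                 other: Sequence[ResidueRecord]) -> dict[int, int]:
    """Map target residue index -> other residue index via global alignment."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    seq_t = _chain_sequence(target)
    seq_o = _chain_sequence(other)
    if not seq_t or not seq_o:
        return {}
    alignment = aligner.align(seq_t, seq_o)[0]
    mapping: dict[int, int] = {}
    for (ts, te), (os_, oe) in zip(*alignment.aligned):
        for k in range(te - ts):
            mapping[ts + k] = os_ + k
    return mapping


def pair_residues(target: StructureRecord, other: StructureRecord,
                  mode: Literal["numbering", "alignment"] = "numbering",
                  ) -> list[ResiduePair]:
    """Pair every target polymer residue with at most one residue of *other*.

    mode="numbering" pairs by (chain_id, seq_number, insertion_code);
    mode="alignment" pairs by per-chain global sequence alignment, which
    tolerates offset or unrelated numbering.  The ``mutated`` flag is set
    when residue types differ (after nonstandard-parent mapping).
    """
    target_chains = target.polymer_chain_ids()
    other_chains = other.polymer_chain_ids()
    if not target_chains or not other_chains:
        raise PairingError("one of the structures has no polymer residues")

    def matching_chain(cid: str) -> Optional[str]:
        if cid in other_chains:
            return cid
        if len(target_chains) == 1 and len(other_chains) == 1:
            return other_chains[0]
        return None

    pairs: list[ResiduePair] = []
    n_matched = 0
    for cid in target_chains:
        t_res = [r for r in target.chains[cid] if r.is_polymer]
        ocid = matching_chain(cid)
        o_res = ([r for r in other.chains[ocid] if r.is_polymer]
                 if ocid is not None else [])
        if mode == "numbering":
            lookup = {(r.seq_number, r.insertion_code): r for r in o_res}
            matches: list[Optional[ResidueRecord]] = [
                lookup.get((r.seq_number, r.insertion_code)) for r in t_res]
        elif mode == "alignment":
            mapping = _align_chain(t_res, o_res) if o_res else {}
            matches = [o_res[mapping[i]] if i in mapping else None
                       for i in range(len(t_res))]
        else:
            raise ValueError(f"unknown pairing mode {mode!r}")
        for t, m in zip(t_res, matches):
            mutated = m is not None and t.standard_type != m.standard_type
            pairs.append(ResiduePair(t, m, mutated))
            if m is not None:
                n_matched += 1
    if n_matched == 0:
        raise PairingError("no residues could be paired")
    return pairs
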