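"""Structure, sequence and secondary-structure ingestion.

Every parser produces a :class:`ProteinRecord`, which keeps an exact
bidirectional map between 0-based sequence indices and author (PDB) residue
numbers.  The distinction matters: deposited crystal structures may start
numbering far above 1 (e.g. a chain whose first residue is author number 22
after a leading hetero-atom entry), while predicted models usually number
contiguously from 1.  All coordinates reported by downstream layers are in
author residue space; internal indices are 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: Three-letter to one-letter amino-acid codes for the 20 standard residues.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is common in crystal structures; treat as Met so
    # active-site detection is not broken by experimental derivatization
    "MSE": "M",
}

#: DSSP 8-state to 3-state reduction: helices to H, strands/bridges to E,
#: everything else (turn, bend, coil, PPII) to C.
SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "P": "C", " ": "C", "-": "C",
}


class StructureParseError(ValueError):
    """Raised when a structure or DSSP file cannot be turned into a record."""


@dataclass
class ProteinRecord:
    """One homolog: sequence, author numbering, C-alpha coordinates, SS3.

    Attributes
    ----------
    id:
        UniProt or PDB identifier.
    group:
        Taxonomic subgroup label (used by the representativeness filter).
    sequence:
        One-letter amino-acid string of length L; never contains the padding
        symbol 'X' (padding exists only inside expansion windows).
    residue_numbers:
        Author residue numbers, strictly increasing, one per sequence position.
    ca_coords:
        (L, 3) array of C-alpha coordinates in Angstrom; rows are NaN where the
        residue has no C-alpha atom.
    ss3:
        Optional 3-state secondary structure string over {H, E, C}, length L.
    """

    id: str
    sequence: str
    residue_numbers: list[int]
    ca_coords: np.ndarray | None = None
    ss3: str | None = None
    group: str = ""
    source: Literal["pdb", "mmcif", "fasta_only"] = "fasta_only"
    _author_to_seq: dict[int, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if len(self.residue_numbers) != L:
            raise ValueError("residue_numbers length must match sequence length")
        if self.ca_coords is not None:
            self.ca_coords = np.asarray(self.ca_coords, dtype=float)
            if self.ca_coords.shape != (L, 3):
                raise ValueError("ca_coords must have shape (L, 3)")
        if self.ss3 is not None and len(self.ss3) != L:
            raise ValueError("ss3 length must match sequence length")
        if any(b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])):
            raise ValueError("residue_numbers must be strictly increasing")
        if "X" in self.sequence:
            raise ValueError("sequence must not contain the padding symbol 'X'")
        self._author_to_seq = {num: i for i, num in enumerate(self.residue_numbers)}

    def __len__(self) -> int:
        return len(self.sequence)

    def seq_to_author(self, index: int) -> int:
        """Author residue number of the residue at 0-based sequence index."""
        return self.residue_numbers[index]

    def author_to_seq(self, resnum: int) -> int:
        """0-based sequence index of the residue with the given author number."""
        try:
            return self._author_to_seq[resnum]
        except KeyError:
            raise KeyError(f"residue number {resnum} not present in {self.id}") from None

    def has_ca(self, index: int) -> bool:
        return self.ca_coords is not None and bool(np.isfinite(self.ca_coords[index]).all())


def _first_polymer_chain(structure: gemmi.Structure, chain_id: str | None) -> gemmi.Chain:
    model = structure[0]  # first model only; NMR ensembles out of scope
    if chain_id is not None:
        for chain in model:
            if chain.name == chain_id:
                return chain
        raise StructureParseError(f"chain {chain_id!r} not found in {structure.name}")
    for chain in model:
        if any(res.name in THREE_TO_ONE for res in chain):
            return chain
    raise StructureParseError(f"no polymer chain with standard residues in {structure.name}")


def parse_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    chain_id: str | None = None,
    record_id: str | None = None,
    group: str = "",
) -> ProteinRecord:
    """Parse a PDB or mmCIF file into a :class:`ProteinRecord`.

    The first polymer chain is selected unless ``chain_id`` is given.
    Hetero-atom entries and waters are excluded from the sequence; residues
    lacking a C-alpha keep their sequence position with a NaN coordinate row.
    Unknown three-letter codes are skipped with a logged warning (MSE maps
    to M).  Alternate locations: the blank or 'A' altloc C-alpha is used.
    """
    path = Path(path)
    try:
        if format == "pdb":
            structure = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot read {path}: {exc}") from exc

    structure.setup_entities()
    chain = _first_polymer_chain(structure, chain_id)

    seq: list[str] = []
    resnums: list[int] = []
    coords: list[tuple[float, float, float]] = []
    for res in chain:
        if res.het_flag == "H" and res.name not in THREE_TO_ONE:
            continue  # waters, ligands, leading het entries
        one = THREE_TO_ONE.get(res.name)
        if one is None:
            log.warning("%s: skipping non-standard residue %s %d", path.name, res.name, res.seqid.num)
            continue
        ca = None
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("", "A", "\0"):
                ca = atom
                break
        seq.append(one)
        resnums.append(res.seqid.num)
        if ca is not None:
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        else:
            coords.append((np.nan, np.nan, np.nan))

    if not seq:
        raise StructureParseError(f"{path}: chain contains zero standard residues")

    src: Literal["pdb", "mmcif"] = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    return ProteinRecord(
        id=record_id or path.stem,
        sequence="".join(seq),
        residue_numbers=resnums,
        ca_coords=np.array(coords, dtype=float),
        group=group,
        source=src,
    )


def parse_dssp(path: str | Path, record: ProteinRecord) -> ProteinRecord:
    """Populate ``record.ss3`` from a classic DSSP text file.

    Residue numbers in the DSSP file are matched against the record's author
    numbering; 8-state codes are reduced to 3 states (H/G/I -> H, E/B -> E,
    others -> C) and residues absent from the file default to coil.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE")) + 1
    except StopIteration:
        raise StructureParseError(f"{path}: not a DSSP file (missing '#  RESIDUE' header)") from None

    ss3 = ["C"] * len(record)
    n_matched = 0
    for ln in lines[start:]:
        if len(ln) < 17:
            continue
        resnum_str = ln[5:10].strip()
        if not resnum_str:
            continue  # chain-break record ('!')
        try:
            resnum = int(resnum_str)
        except ValueError:
            continue
        code = ln[16] if len(ln) > 16 else " "
        try:
            idx = record.author_to_seq(resnum)
        except KeyError:
            continue
        ss3[idx] = SS8_TO_SS3.get(code, "C")
        n_matched += 1

    if n_matched == 0:
        raise StructureParseError(f"{path}: no residues overlap record {record.id}")

    record.ss3 = "".join(ss3)
    return record


def parse_fasta(path: str | Path, group: str = "") -> list[ProteinRecord]:
    """Read a FASTA file into coordinate-free records numbered from 1."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                residue_numbers=list(range(1, len(seq) + 1)),
                group=group,
                source="fasta_only",
            )
        )
    if not records:
        raise StructureParseError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (sequence only; numbering is not preserved)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def reduce_ss8(ss8: str) -> str:
    """Reduce an 8-state DSSP string to the 3-state {H,E,C} alphabet."""
    return "".join(SS8_TO_SS3.get(c, "C") for c in ss8)
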