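"""Read DNA duplexes from PDB coordinate files and organise them for analysis.

A nucleosome entry contains two antiparallel DNA chains wrapped around the
histone octamer.  This module extracts the DNA residues, pairs the strands
positionally into a :class:`DuplexModel`, and labels every basepair with its
superhelix location (SHL): the signed displacement, in basepairs/10, from
the pseudo-dyad basepair at SHL 0.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .templates import COMPLEMENT, RESIDUE_TO_BASE, RING_ATOMS

__all__ = [
    "AtomRecord",
    "NucleotideUnit",
    "BasePairUnit",
    "DuplexModel",
    "read_structure",
    "pair_strands",
    "assign_shl",
    "count_step_classes",
    "load_duplex",
    "write_pdb",
]


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    residue_name: str
    residue_seq: int
    chain_id: str
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class NucleotideUnit:
    base: str
    strand_index: int
    position_in_strand: int
    atoms: dict[str, AtomRecord]
    residue_name: str = ""
    residue_seq: int = 0
    chain_id: str = ""

    def coord(self, name: str) -> np.ndarray | None:
        rec = self.atoms.get(name)
        return None if rec is None else rec.coords

    @property
    def is_purine(self) -> bool:
        return self.base in ("A", "G")


@dataclass
class BasePairUnit:
    nt1: NucleotideUnit
    nt2: NucleotideUnit
    dyad_offset: int | None = None
    shl_label: str | None = None
    half: str | None = None
    watson_crick: bool = True

    @property
    def bases(self) -> tuple[str, str]:
        return self.nt1.base, self.nt2.base


@dataclass
class DuplexModel:
    structure_id: str
    basepairs: list[BasePairUnit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.basepairs)

    @property
    def sequence(self) -> str:
        """Strand-1 base sequence, 5'->3'."""
        return "".join(bp.nt1.base for bp in self.basepairs)

    @property
    def dyad_offsets(self) -> list[int | None]:
        return [bp.dyad_offset for bp in self.basepairs]


def _is_nucleotide(residue: gemmi.Residue) -> bool:
    return residue.name.strip() in RESIDUE_TO_BASE


def read_structure(pdb_source: str | Path) -> dict[str, list[NucleotideUnit]]:
    """Parse PDB text (or a path to it) into DNA nucleotides grouped by chain.

    Protein residues, waters, ions and non-nucleic ligands are skipped.  For
    duplicated atoms only the first alternate location is kept.  A residue
    that carries none of the base ring atoms is dropped with a warning since
    no reference frame can be fitted to it.
    """
    if isinstance(pdb_source, Path) or (
        "\n" not in str(pdb_source) and Path(str(pdb_source)).exists()
    ):
        text = Path(pdb_source).read_text()
    else:
        text = str(pdb_source)
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparseable PDB input: {exc}") from exc
    structure.setup_entities()

    chains: dict[str, list[NucleotideUnit]] = {}
    model = structure[0]
    for chain in model:
        units: list[NucleotideUnit] = []
        for residue in chain:
            if not _is_nucleotide(residue):
                continue
            base = RESIDUE_TO_BASE[residue.name.strip()]
            atoms: dict[str, AtomRecord] = {}
            for atom in residue:
                if atom.name in atoms:
                    continue  # first altloc wins
                atoms[atom.name] = AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    residue_name=residue.name.strip(),
                    residue_seq=residue.seqid.num,
                    chain_id=chain.name,
                    altloc=atom.altloc if atom.altloc != "\0" else "",
                )
            ring = RING_ATOMS[base]
            if not any(name in atoms for name in ring):
                warnings.warn(
                    f"residue {residue.name} {chain.name}{residue.seqid.num} "
                    "has no base ring atoms; excluded"
                )
                continue
            units.append(
                NucleotideUnit(
                    base=base,
                    strand_index=0,
                    position_in_strand=len(units) + 1,
                    atoms=atoms,
                    residue_name=residue.name.strip(),
                    residue_seq=residue.seqid.num,
                    chain_id=chain.name,
                )
            )
        if units:
            chains[chain.name] = units
    return chains


def pair_strands(
    chains: dict[str, list[NucleotideUnit]],
    structure_id: str = "duplex",
    chain_ids: tuple[str, str] | None = None,
) -> DuplexModel:
    """Pair two antiparallel DNA chains positionally into a duplex.

    Basepair k joins strand-1 position k with strand-2 position N+1-k.
    Pairs that are not Watson-Crick complementary are flagged, not dropped.
    """
    if chain_ids is not None:
        missing = [c for c in chain_ids if c not in chains]
        if missing:
            raise ValueError(f"requested chains absent from structure: {missing}")
        names = list(chain_ids)
    else:
        names = list(chains)
        if len(names) != 2:
            raise ValueError(
                f"expected exactly 2 DNA chains, found {len(names)} "
                f"({names}); pass chain_ids to disambiguate"
            )
    strand1, strand2 = chains[names[0]], chains[names[1]]
    if len(strand1) != len(strand2):
        raise ValueError(
            f"strand lengths differ: {len(strand1)} vs {len(strand2)}"
        )
    n = len(strand1)
    pairs: list[BasePairUnit] = []
    for k in range(n):
        nt1 = strand1[k]
        nt2 = strand2[n - 1 - k]
        nt1.strand_index, nt2.strand_index = 1, 2
        wc = COMPLEMENT.get(nt1.base) == nt2.base
        pairs.append(BasePairUnit(nt1=nt1, nt2=nt2, watson_crick=wc))
    return DuplexModel(structure_id=structure_id, basepairs=pairs)


def assign_shl(duplex: DuplexModel, dyad_index: int | None = None) -> DuplexModel:
    """Assign dyad offsets, SHL labels and half labels to every basepair.

    ``dyad_index`` is the 1-based strand-1 position of SHL 0.  By default the
    central basepair is used for odd lengths and the 73rd basepair for the
    146-bp particle, which splits it into a shorter 72-bp 5' half and a
    longer 73-bp 3' half.
    """
    n = duplex.length
    if dyad_index is None:
        dyad_index = 73 if n == 146 else (n + 1) // 2
    if not 1 <= dyad_index <= n:
        raise ValueError(f"dyad_index {dyad_index} outside duplex of length {n}")
    equal_halves = (dyad_index - 1) == (n - dyad_index)
    for pos, bp in enumerate(duplex.basepairs, start=1):
        offset = pos - dyad_index
        bp.dyad_offset = offset
        bp.shl_label = f"{offset / 10:.1f}"
        if offset == 0:
            bp.half = "central"
        elif equal_halves:
            bp.half = "equal"
        else:
            bp.half = "shorter" if offset < 0 else "longer"
    return duplex


def count_step_classes(sequence: str) -> dict[str, int]:
    """Count the ten canonical dinucleotide step classes along a sequence."""
    from .steps import canonical_step_class

    if len(sequence) < 2:
        raise ValueError("sequence must contain at least one dinucleotide step")
    counts: dict[str, int] = {}
    for i in range(len(sequence) - 1):
        label = canonical_step_class(sequence[i : i + 2])
        counts[label] = counts.get(label, 0) + 1
    return counts


def load_duplex(
    pdb_source: str | Path,
    structure_id: str | None = None,
    dyad_index: int | None = None,
    chain_ids: tuple[str, str] | None = None,
) -> DuplexModel:
    """Convenience: read, pair and SHL-label a duplex in one call."""
    if structure_id is None:
        structure_id = Path(str(pdb_source)).stem if Path(str(pdb_source)).exists() else "duplex"
    chains = read_structure(pdb_source)
    duplex = pair_strands(chains, structure_id=structure_id, chain_ids=chain_ids)
    return assign_shl(duplex, dyad_index=dyad_index)


_PDB_BASE_NAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC", "U": "DU"}


def write_pdb(duplex: DuplexModel) -> str:
    """Serialize a duplex as standard PDB ATOM records (two chains).

    Strand 1 is chain A in 5'->3' order; strand 2 is chain B written in its
    own 5'->3' order (reverse basepair order), so the file round-trips
    through :func:`read_structure` / :func:`pair_strands`.
    """
    out = _io.StringIO()
    serial = 1

    def emit(nt: NucleotideUnit, chain: str, resseq: int) -> None:
        nonlocal serial
        resname = _PDB_BASE_NAME.get(nt.base, nt.base)
        for name, rec in nt.atoms.items():
            x, y, z = rec.coords
            atom_field = name if len(name) >= 4 else f" {name:<3s}"
            element = rec.element or name[0]
            out.write(
                f"ATOM  {serial:5d} {atom_field:<4s} {resname:<3s} {chain}"
                f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}\n"
            )
            serial += 1

    for i, bp in enumerate(duplex.basepairs, start=1):
        emit(bp.nt1, "A", i)
    out.write("TER\n")
    for i, bp in enumerate(reversed(duplex.basepairs), start=1):
        emit(bp.nt2, "B", duplex.length + i)
    out.write("TER\nEND\n")
    return out.getvalue()
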