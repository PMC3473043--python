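"""Alignment containers, FASTA/PDB input and per-column statistics.

An :class:`Alignment` stores residues as integer codes into a fixed 21-symbol
alphabet: the 20 standard amino acids in alphabetical one-letter order,
followed by the gap character.  Everything downstream (the binary encodings,
the detectors, the simulator) indexes symbols through this single ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Canonical 21-symbol alphabet: 20 amino acids + gap, gap last.
ALPHABET = AMINO_ACIDS + GAP
N_SYMBOLS = len(ALPHABET)
GAP_CODE = ALPHABET.index(GAP)

_SYMBOL_TO_CODE = {s: i for i, s in enumerate(ALPHABET)}


class AlignmentShapeError(ValueError):
    """Raised when sequences in a putative alignment have unequal lengths."""


class EmptyInputError(ValueError):
    """Raised when an input file contains no records."""


class UndefinedEntropyError(ValueError):
    """Raised when relative entropy is undefined (zero background probability)."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a residue string as codes into :data:`ALPHABET`.

    Input is uppercased; any character outside the canonical 21 symbols
    (ambiguity codes B/Z/X, the rare U/O, '.' gaps, ...) maps to the gap code,
    keeping the alphabet at exactly 21 symbols.
    """
    return np.fromiter(
        (_SYMBOL_TO_CODE.get(c, GAP_CODE) for c in seq.upper()),
        dtype=np.uint8,
        count=len(seq),
    )


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment over the 21-symbol alphabet.

    Attributes
    ----------
    ids : list of str
        Sequence identifiers, in file order.
    rows : ndarray of uint8, shape (n_seq, n_pos)
        Residue codes; ``rows[r, c]`` indexes into :data:`ALPHABET`.
    """

    ids: list[str]
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.uint8)
        if self.rows.ndim != 2:
            raise AlignmentShapeError("alignment rows must form a 2-D matrix")
        if len(self.ids) != self.rows.shape[0]:
            raise AlignmentShapeError(
                f"{len(self.ids)} ids for {self.rows.shape[0]} rows"
            )
        if self.rows.size and self.rows.max() >= N_SYMBOLS:
            raise ValueError("residue code outside the 21-symbol alphabet")

    @property
    def n_seq(self) -> int:
        return self.rows.shape[0]

    @property
    def n_pos(self) -> int:
        return self.rows.shape[1]

    def sequence(self, r: int) -> str:
        """Residue string of row ``r``."""
        return "".join(ALPHABET[c] for c in self.rows[r])

    @classmethod
    def from_sequences(cls, ids: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        """Build an alignment from residue strings, normalizing symbols."""
        if not seqs:
            raise EmptyInputError("no sequences given")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"unequal sequence lengths: {sorted(lengths)}")
        return cls(list(ids), np.stack([encode_sequence(s) for s in seqs]))


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Raises
    ------
    EmptyInputError
        If the file contains no records.
    AlignmentShapeError
        If records have unequal lengths.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Alignment.from_sequences(
        [r.id for r in records], [str(r.seq) for r in records]
    )


def write_fasta(aln: Alignment, path: str | Path) -> None:
    """Write an alignment to FASTA, preserving id order and symbols."""
    records = [
        SeqRecord(Seq(aln.sequence(r)), id=aln.ids[r], description="")
        for r in range(aln.n_seq)
    ]
    SeqIO.write(records, str(path), "fasta")


def relative_entropy(
    aln: Alignment, background: np.ndarray | None = None
) -> np.ndarray:
    """Per-column relative entropy (Kullback-Leibler divergence) in bits.

    For each column, RE = sum_a f_a * log2(f_a / q_a) over the 20 amino
    acids with observed frequency f_a > 0; gaps are excluded from the
    frequencies.  An all-gap column scores 0 by convention.

    Parameters
    ----------
    background : ndarray of shape (20,), optional
        Background amino acid probabilities q; defaults to uniform 1/20.
    """
    if background is None:
        background = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    background = np.asarray(background, dtype=float)
    if background.shape != (len(AMINO_ACIDS),):
        raise ValueError("background must have one probability per amino acid")
    if not np.isclose(background.sum(), 1.0):
        raise ValueError(f"background sums to {background.sum():g}, expected 1")

    out = np.zeros(aln.n_pos)
    for c in range(aln.n_pos):
        col = aln.rows[:, c]
        counts = np.bincount(col[col != GAP_CODE], minlength=len(AMINO_ACIDS))
        total = counts.sum()
        if total == 0:
            continue
        f = counts / total
        nz = f > 0
        if np.any(background[nz] == 0):
            raise UndefinedEntropyError(
                f"column {c + 1}: observed residue has zero background probability"
            )
        out[c] = float(np.sum(f[nz] * np.log2(f[nz] / background[nz])))
    return out


@dataclass
class ContactMap:
    """Boolean residue-contact matrix from structure centroids.

    ``contacts[i, j]`` is true when the centroids of residues ``i`` and ``j``
    lie strictly closer than ``cutoff`` angstroms. ``offset`` records the shift
    applied to the structure's residue numbering so that column ``c``
    (1-based) of an alignment maps to residue number ``c + offset``.
    """

    contacts: np.ndarray
    cutoff: float
    offset: int = 0
    residue_numbers: list[int] = field(default_factory=list)

    @property
    def n_pos(self) -> int:
        return self.contacts.shape[0]


def _residue_centroid(residue: gemmi.Residue, side_chain_only: bool) -> np.ndarray | None:
    backbone = {"N", "CA", "C", "O", "OXT"}
    coords = []
    for atom in residue:
        if atom.is_hydrogen():
            continue
        if atom.altloc not in ("", "\0", "A"):
            continue
        if side_chain_only and atom.name in backbone:
            continue
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords and side_chain_only:
        # Glycine has no side chain: fall back to all heavy atoms.
        return _residue_centroid(residue, side_chain_only=False)
    if not coords:
        return None
    return np.mean(coords, axis=0)


def contact_map(
    structure: str | Path | gemmi.Structure,
    chain: str,
    cutoff: float = 8.0,
    side_chain_only: bool = False,
    offset: int = 0,
) -> ContactMap:
    """Compute a centroid contact map from a PDB structure.

    The centroid of a residue is the unweighted mean of its non-hydrogen atom
    coordinates (all heavy atoms by default; ``side_chain_only`` restricts to
    side-chain atoms, falling back to all heavy atoms for glycine).  Two
    residues are in contact when their centroid distance is strictly below
    ``cutoff``.  Only the first model is used; alternate locations other than
    'A' are ignored.
    """
    if isinstance(structure, (str, Path)):
        structure = gemmi.read_structure(str(structure))
    model = structure[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise KeyError(f"chain {chain!r} not found in structure")

    centroids = []
    numbers = []
    for residue in ch:
        centroid = _residue_centroid(residue, side_chain_only)
        if centroid is None:
            warnings.warn(
                f"residue {residue.seqid.num} {residue.name} has no usable atoms; skipped"
            )
            continue
        centroids.append(centroid)
        numbers.append(residue.seqid.num)
    if len(centroids) < 2:
        raise ValueError(f"chain {chain!r} has fewer than 2 residues with atoms")

    xyz = np.asarray(centroids)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    contacts = dist < cutoff
    np.fill_diagonal(contacts, False)
    return ContactMap(contacts=contacts, cutoff=cutoff, offset=offset,
                      residue_numbers=numbers)
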