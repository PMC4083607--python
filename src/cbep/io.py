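"""Readers and writers for the external formats the epitope pipeline touches.

Covers FASTA antigen sequences, blastpgp ASCII PSSM profiles (the ``-Q``
output dialect), PSIPRED VFORMAT ``.ss2`` secondary-structure files,
DISOPRED plain-text disorder output, Cα coordinates from PDB ``ATOM``
records, and this package's own residue-level epitope annotation TSV.

Every reader validates row counts against the expected chain length and
raises rather than truncating; everything the package itself emits (see
:mod:`cbep.synthdata`) round-trips exactly through the matching reader.
All indices surfaced to users are 1-based inclusive; in memory everything
is 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

__all__ = [
    "STANDARD_AA",
    "PSSM_ALPHABET",
    "FormatError",
    "LengthMismatchError",
    "AntigenRecord",
    "PssmProfile",
    "SecondaryStructureProfile",
    "DisorderProfile",
    "read_fasta",
    "write_fasta",
    "read_pssm",
    "write_pssm",
    "read_ss2",
    "write_ss2",
    "read_disorder",
    "write_disorder",
    "read_ca_coords",
    "write_ca_pdb",
    "read_annotations",
    "write_annotations",
    "attach_annotations",
]

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: blastpgp column order for the 20 substitution-score columns.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Letters retained in sequences but treated as unknown residues
#: (excluded from dipeptide counting, zero physicochemical values).
NONSTANDARD_AA = "BZXUO"

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class LengthMismatchError(FormatError):
    """A per-residue file disagrees with the expected chain length."""


@dataclass
class AntigenRecord:
    """One antigen chain with optional labels, epitope ids and Cα coordinates.

    Parameters
    ----------
    id : str
        Chain identifier.
    sequence : str
        Amino-acid sequence (uppercase one-letter codes).
    labels : ndarray of {0, 1}, optional
        Per-residue antigenic-determinant labels (1 = epitope residue).
    epitope_ids : ndarray of int, optional
        Per-residue epitope membership: 0 = non-epitope, k > 0 = member of
        observed epitope k.
    coords : ndarray of shape (L, 3), optional
        Per-residue Cα coordinates in Å; rows of NaN mark residues without
        a resolved Cα.
    """

    id: str
    sequence: str
    labels: np.ndarray | None = None
    epitope_ids: np.ndarray | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(STANDARD_AA + NONSTANDARD_AA)
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal sequence characters {sorted(bad)}"
            )
        L = len(self.sequence)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (L,):
                raise LengthMismatchError(
                    f"record {self.id!r}: labels length {self.labels.shape} != {L}"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise FormatError(f"record {self.id!r}: labels must be binary")
        if self.epitope_ids is not None:
            self.epitope_ids = np.asarray(self.epitope_ids, dtype=int)
            if self.epitope_ids.shape != (L,):
                raise LengthMismatchError(
                    f"record {self.id!r}: epitope_ids length != {L}"
                )
            if (self.epitope_ids < 0).any():
                raise FormatError(f"record {self.id!r}: epitope ids must be >= 0")
            if self.labels is not None and not np.array_equal(
                self.labels, (self.epitope_ids > 0).astype(int)
            ):
                raise FormatError(
                    f"record {self.id!r}: labels inconsistent with epitope_ids"
                )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (L, 3):
                raise LengthMismatchError(
                    f"record {self.id!r}: coords shape {self.coords.shape} != ({L}, 3)"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def unknown_mask(self) -> np.ndarray:
        """Boolean mask of non-standard (unknown) residues."""
        return np.array([c not in STANDARD_AA for c in self.sequence])


@dataclass
class PssmProfile:
    """Raw blastpgp substitution scores, one 20-vector per residue."""

    scores: np.ndarray  # (L, 20) int, PSSM_ALPHABET column order

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError(f"PSSM must be L x 20, got {self.scores.shape}")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class SecondaryStructureProfile:
    """Per-residue probabilities of helix, coil and strand, each in [0, 1]."""

    probs: np.ndarray  # (L, 3) float, columns (helix, coil, strand)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise FormatError(f"ss profile must be L x 3, got {self.probs.shape}")
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise FormatError("secondary-structure probabilities outside [0, 1]")

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass
class DisorderProfile:
    """Per-residue binary disorder status (1 = disordered)."""

    status: np.ndarray  # (L,) int in {0, 1}

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        if self.status.ndim != 1 or not np.isin(self.status, (0, 1)).all():
            raise FormatError("disorder status must be a binary vector")

    def __len__(self) -> int:
        return self.status.shape[0]


@dataclass
class ProfileSet:
    """All per-chain upstream profiles needed to encode one antigen."""

    pssm: PssmProfile
    ss2: SecondaryStructureProfile
    disorder: DisorderProfile


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[AntigenRecord]:
    """Read antigen chains from a FASTA file.

    Sequences are uppercased; the non-standard letters B/Z/X/U/O are
    retained (downstream feature stages treat them as unknown). Raises
    :class:`FormatError` on an empty file, duplicate identifiers, or any
    other letter.
    """
    path = Path(path)
    records: list[AntigenRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for entry in SeqIO.parse(fh, "fasta"):
            if entry.id in seen:
                raise FormatError(f"{path}: duplicate record id {entry.id!r}")
            seen.add(entry.id)
            records.append(AntigenRecord(id=entry.id, sequence=str(entry.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[AntigenRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# blastpgp ASCII PSSM (-Q dialect)

def read_pssm(path: str | Path, expected_length: int) -> PssmProfile:
    """Read a blastpgp ASCII PSSM.

    Extracts the first 20 numeric columns (log-odds substitution scores in
    the blastpgp alphabet order) of each residue row. Raises
    :class:`LengthMismatchError` if the row count disagrees with
    ``expected_length`` and :class:`FormatError` (with the line number) on
    an unparseable row.
    """
    path = Path(path)
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            # Residue rows start with the 1-based position then the letter.
            if len(parts) < 22 or not parts[0].isdigit():
                continue
            if len(parts[1]) != 1 or not parts[1].isalpha():
                continue
            try:
                scores = [int(tok) for tok in parts[2:22]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable PSSM row") from exc
            if int(parts[0]) != len(rows) + 1:
                raise FormatError(
                    f"{path}:{lineno}: position {parts[0]} out of order"
                )
            rows.append(scores)
    if len(rows) != expected_length:
        raise LengthMismatchError(
            f"{path}: {len(rows)} PSSM rows for a chain of {expected_length} residues"
        )
    return PssmProfile(scores=np.array(rows, dtype=int))


def write_pssm(profile: PssmProfile, sequence: str, path: str | Path) -> None:
    """Write a PSSM in the blastpgp ASCII dialect readable by :func:`read_pssm`."""
    if len(profile) != len(sequence):
        raise LengthMismatchError("PSSM rows != sequence length")
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "  ".join(PSSM_ALPHABET) + "\n")
        for i, (aa, row) in enumerate(zip(sequence, profile.scores), start=1):
            scores = " ".join(f"{int(v):3d}" for v in row)
            pcts = " ".join("  0" for _ in row)
            fh.write(f"{i:5d} {aa} {scores} {pcts}  0.00 0.00\n")


# ---------------------------------------------------------------------------
# PSIPRED VFORMAT .ss2

def read_ss2(path: str | Path, expected_length: int) -> SecondaryStructureProfile:
    """Read a PSIPRED VFORMAT ``.ss2`` file.

    File columns are (coil, helix, strand); the returned profile stores
    (helix, coil, strand).
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: malformed .ss2 row")
            try:
                c, h, e = float(parts[3]), float(parts[4]), float(parts[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed .ss2 row") from exc
            rows.append((h, c, e))
    if len(rows) != expected_length:
        raise LengthMismatchError(
            f"{path}: {len(rows)} .ss2 rows for a chain of {expected_length} residues"
        )
    return SecondaryStructureProfile(probs=np.array(rows, dtype=float))


def write_ss2(
    profile: SecondaryStructureProfile, sequence: str, path: str | Path
) -> None:
    if len(profile) != len(sequence):
        raise LengthMismatchError(".ss2 rows != sequence length")
    states = "HCE"
    with open(path, "w") as fh:
        fh.write("# PSF format result\n\n")
        for i, (aa, (h, c, e)) in enumerate(zip(sequence, profile.probs), start=1):
            state = states[int(np.argmax([h, c, e]))]
            fh.write(f"{i:4d} {aa} {state}   {c:6.3f} {h:6.3f} {e:6.3f}\n")


# ---------------------------------------------------------------------------
# DISOPRED plain output

def read_disorder(path: str | Path, expected_length: int) -> DisorderProfile:
    """Read DISOPRED plain output; ``*`` marks a disordered residue, ``.`` ordered."""
    path = Path(path)
    status: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3 or parts[2] not in ("*", "."):
                raise FormatError(f"{path}:{lineno}: malformed disorder row")
            status.append(1 if parts[2] == "*" else 0)
    if len(status) != expected_length:
        raise LengthMismatchError(
            f"{path}: {len(status)} disorder rows for a chain of "
            f"{expected_length} residues"
        )
    return DisorderProfile(status=np.array(status, dtype=int))


def write_disorder(profile: DisorderProfile, sequence: str, path: str | Path) -> None:
    if len(profile) != len(sequence):
        raise LengthMismatchError("disorder rows != sequence length")
    with open(path, "w") as fh:
        fh.write("# disorder prediction\n")
        for i, (aa, s) in enumerate(zip(sequence, profile.status), start=1):
            mark = "*" if s else "."
            fh.write(f"{i:5d} {aa} {mark} {0.9 if s else 0.1:.2f}\n")


# ---------------------------------------------------------------------------
# PDB Cα coordinates

def read_ca_coords(
    path: str | Path, chain_id: str, expected_length: int | None = None
) -> np.ndarray:
    """Extract per-residue Cα coordinates for one chain from a PDB file.

    Residues are ordered by author residue number, insertion codes broken
    lexicographically; the first altloc wins. Residues without a Cα atom get
    a NaN row and a warning (they are excluded from clustering downstream).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("antigen", str(path))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise FormatError(f"{path}: chain {chain_id!r} not present")
    chain = model[chain_id]
    residues = [r for r in chain if is_aa(r, standard=False) or r.id[0] == " "]
    residues.sort(key=lambda r: (r.id[1], r.id[2]))
    coords = []
    missing = []
    for res in residues:
        if "CA" in res:
            coords.append(res["CA"].get_coord().astype(float))
        else:
            coords.append(np.full(3, np.nan))
            missing.append(res.id[1])
    if missing:
        warnings.warn(
            f"{path}: residues {missing} in chain {chain_id} lack a CA atom; "
            "they will be excluded from clustering",
            stacklevel=2,
        )
    # PDB coordinates carry exactly 3 decimals; rounding undoes the parser's
    # float32 representation error
    arr = np.round(np.asarray(coords, dtype=float).reshape(-1, 3), 3)
    if expected_length is not None and arr.shape[0] != expected_length:
        raise LengthMismatchError(
            f"{path}: chain {chain_id} has {arr.shape[0]} residues, "
            f"expected {expected_length}"
        )
    return arr


def write_ca_pdb(
    sequence: str, coords: np.ndarray, chain_id: str, path: str | Path
) -> None:
    """Write a Cα-only PDB file (one ATOM record per residue)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(sequence), 3):
        raise LengthMismatchError("coords shape != (sequence length, 3)")
    with open(path, "w") as fh:
        serial = 1
        for i, (aa, xyz) in enumerate(zip(sequence, coords), start=1):
            if np.isnan(xyz).any():
                continue
            resname = _THREE_LETTER.get(aa, "UNK")
            fh.write(
                f"ATOM  {serial:5d}  CA  {resname} {chain_id[:1]}{i:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"           C  \n"
            )
            serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Epitope annotation TSV (this package's own format)

def read_annotations(path: str | Path) -> dict[str, dict[int, int]]:
    """Read the epitope annotation TSV.

    Columns: ``chain_id``, ``residue_index`` (1-based), ``epitope_id``
    (k > 0). Returns ``{chain_id: {0-based residue index: epitope id}}``.
    """
    path = Path(path)
    out: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chain_id", "residue_index", "epitope_id"]:
            raise FormatError(f"{path}: unexpected annotation header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: malformed annotation row")
            chain, idx, eid = parts[0], int(parts[1]), int(parts[2])
            if idx < 1 or eid < 1:
                raise FormatError(
                    f"{path}:{lineno}: residue_index and epitope_id must be >= 1"
                )
            out.setdefault(chain, {})[idx - 1] = eid
    return out


def write_annotations(records: list[AntigenRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tresidue_index\tepitope_id\n")
        for rec in records:
            if rec.epitope_ids is None:
                continue
            for i, eid in enumerate(rec.epitope_ids):
                if eid > 0:
                    fh.write(f"{rec.id}\t{i + 1}\t{int(eid)}\n")


def attach_annotations(
    records: list[AntigenRecord], annotations: dict[str, dict[int, int]]
) -> None:
    """Set ``epitope_ids`` and ``labels`` on records in place from an annotation map."""
    for rec in records:
        chain = annotations.get(rec.id, {})
        eids = np.zeros(len(rec), dtype=int)
        for idx, eid in chain.items():
            if idx >= len(rec):
                raise LengthMismatchError(
                    f"annotation index {idx + 1} beyond chain {rec.id!r} "
                    f"of length {len(rec)}"
                )
            eids[idx] = eid
        rec.epitope_ids = eids
        rec.labels = (eids > 0).astype(int)
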