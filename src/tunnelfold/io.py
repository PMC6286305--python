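"""Structure, sequence and table I/O.

PDB here means plain fixed-column ATOM records with MODEL/ENDMDL frame
delimiters — enough to round-trip the coarse models this package builds
(backbone roles N/CA/C/O plus one CB pseudo side-chain per residue).
Radii are written into the B-factor column for inspection but are
re-assigned from the config tables on read, by atom role and residue type.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .config import load_defaults
from .conformer import Conformer, PeptideSequence
from .sasa import PEPTIDE, SphereSet

__all__ = [
    "FormatError",
    "read_structure",
    "write_structure",
    "read_fasta",
    "conformer_to_sphereset",
]

log = logging.getLogger("tunnelfold")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


class FormatError(ValueError):
    pass


def read_fasta(path) -> list[PeptideSequence]:
    """Read peptide sequences from FASTA; the whole chain is annotated as
    the helical region unless overridden later."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return [PeptideSequence.from_string(str(r.seq), id=r.id) for r in records]


def write_structure(frames, path) -> None:
    """Write one or more Conformer/SphereSet frames as fixed-column ATOM
    records; multiple frames become MODEL/ENDMDL blocks."""
    if isinstance(frames, (Conformer, SphereSet)):
        frames = [frames]
    if not frames:
        raise FormatError("nothing to write")
    multi = len(frames) > 1
    lines = []
    for m, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        lines.extend(_frame_lines(frame))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _frame_lines(frame) -> list[str]:
    if isinstance(frame, Conformer):
        roles = frame.roles
        res_idx = frame.residue_index
        coords = frame.coords
        radii = frame.radii
        if frame.sequence is not None:
            resnames = [AA_1TO3[frame.sequence.residues[i - 1].code] for i in res_idx]
        else:
            resnames = ["UNK"] * len(roles)
        chain = "A"
    elif isinstance(frame, SphereSet):
        roles = np.array(["CB" if o == PEPTIDE else "X" for o in frame.owner])
        res_idx = frame.residue_index
        coords = frame.coords
        radii = frame.radii
        resnames = ["UNK" if o == PEPTIDE else "WAL" for o in frame.owner]
        chain = "A"
    else:
        raise FormatError(f"cannot serialize {type(frame).__name__}")

    out = []
    for i in range(len(coords)):
        x, y, z = coords[i]
        if not np.all(np.isfinite(coords[i])):
            raise FormatError("non-finite coordinate")
        name = roles[i] if roles[i] != "X" else "W"
        element = _ELEMENTS.get(str(roles[i]), "C")
        out.append(
            f"ATOM  {i + 1:5d} {name:^4s}{resnames[i]:>4s} {chain}"
            f"{int(res_idx[i]) if res_idx[i] > 0 else 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{radii[i]:6.2f}"
            f"          {element:>2s}"
        )
    return out


def read_structure(path) -> list[Conformer]:
    """Parse ATOM/HETATM records into per-frame Conformers.

    Radii come from the config tables (backbone role table; CB pseudo-atoms
    from the residue side-chain table).  Unknown atom names get the default
    radius with a logged warning.  Raises FormatError with the offending
    line number on malformed records.
    """
    cfg = load_defaults()
    atom_radii = cfg["atom_radii"]
    residues = cfg["residues"]

    frames: list[Conformer] = []
    cur: list[tuple[int, str, np.ndarray, float]] = []

    def flush(frame_id: str):
        if not cur:
            return
        res_idx = np.array([c[0] for c in cur], dtype=int)
        roles = np.array([c[1] for c in cur], dtype="U2")
        coords = np.array([c[2] for c in cur], dtype=float)
        radii = np.array([c[3] for c in cur], dtype=float)
        frames.append(Conformer(frame_id, "unknown", res_idx, roles, coords, radii))
        cur.clear()

    text = Path(path).read_text()
    stem = Path(path).stem
    saw_atoms = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            cur.clear()
        elif rec == "ENDMDL":
            flush(stem)
        elif rec in ("ATOM", "HETATM"):
            saw_atoms = True
            try:
                name = line[12:16].strip()
                resname = line[17:20].strip()
                res_seq = int(line[22:26])
                xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed ATOM record: {exc}") from exc
            if name == "CB" and resname in AA_3TO1:
                radius = float(residues[AA_3TO1[resname]]["sidechain_radius"])
            elif name in atom_radii:
                radius = float(atom_radii[name])
            else:
                radius = float(atom_radii["default"])
                log.warning("%s:%d: unknown atom name %r, default radius %.2f Å",
                            path, lineno, name, radius)
            cur.append((res_seq, name, xyz, radius))
    flush(stem)
    if not saw_atoms:
        raise FormatError(f"{path}: no ATOM records found")
    return frames


def conformer_to_sphereset(conf: Conformer, owner: str = PEPTIDE) -> SphereSet:
    return SphereSet.from_conformer(conf, owner=owner)
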