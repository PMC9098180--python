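"""File formats: XYZ, minimal PDB (ATOM/TER/END), flat config files."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "read_xyz", "write_xyz",
    "PdbAtom", "read_pdb", "write_pdb_cg",
    "RunConfig",
]

_KNOWN_RESNAMES = {"DA", "DC", "DG", "DT", "A", "C", "G", "T", "U"}


class ParseError(ValueError):
    """Malformed file content; message carries the 1-based line number."""


def write_xyz(path, coords: np.ndarray, labels, comment: str = "") -> None:
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(labels) != coords.shape[0]:
        raise ValueError("labels/coordinates length mismatch")
    lines = [str(coords.shape[0]), comment.replace("\n", " ")]
    for lab, (x, y, z) in zip(labels, coords):
        lines.append(f"{lab} {x:.17g} {y:.17g} {z:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path):
    """Returns (coords, labels, comment)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError("line 1: empty XYZ file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"line 1: expected atom count, got {lines[0]!r}") from None
    if len(lines) < n + 2:
        raise ParseError(f"line {len(lines)}: truncated XYZ file "
                         f"({n} atoms declared)")
    comment = lines[1]
    labels, coords = [], []
    for lineno, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"line {lineno}: expected 'label x y z', got {line!r}")
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric coordinate in {line!r}") from None
        labels.append(parts[0])
    return np.array(coords), labels, comment


@dataclass
class PdbAtom:
    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    xyz: np.ndarray
    element: str = ""


def read_pdb(path) -> list[PdbAtom]:
    """Minimal PDB reader: ATOM, TER and END records only."""
    atoms = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("TER", "END", "") or rec == "REMARK":
            continue
        if rec != "ATOM":
            raise ParseError(
                f"line {lineno}: unsupported record {rec!r} "
                "(only ATOM/TER/END are understood)")
        try:
            atom = PdbAtom(
                serial=int(line[6:11]),
                name=line[12:16].strip(),
                resname=line[17:20].strip(),
                chain=line[21:22].strip() or "A",
                resseq=int(line[22:26]),
                xyz=np.array([float(line[30:38]), float(line[38:46]),
                              float(line[46:54])]),
                element=line[76:78].strip(),
            )
        except (ValueError, IndexError):
            raise ParseError(f"line {lineno}: malformed ATOM record") from None
        if atom.resname not in _KNOWN_RESNAMES:
            raise ParseError(
                f"line {lineno}: unknown residue name {atom.resname!r}")
        atoms.append(atom)
    return atoms


def write_pdb_cg(path, conf) -> None:
    """Write a CG conformation as a minimal PDB, one atom per bead."""
    topo = conf.topology
    lines = []
    serial = 0
    for strand in (0, 1):
        seq = topo.sequence if strand == 0 else topo.strand2_sequence
        chain = "AB"[strand]
        for i, base in enumerate(seq):
            for role in topo.ROLES:
                serial += 1
                x, y, z = conf.coords[topo.bead(strand, i, role)]
                lines.append(
                    f"ATOM  {serial:5d} {role:<4s} {'D' + base:>3s} {chain}"
                    f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {role[0]:>2s}")
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Pipeline stage parameters; written verbatim into every output
    directory so each run is reproducible from its own record."""

    system: str = "GAGAGAGAGAGA"  # sequence, or a built-in surface name
    params_file: str = ""          # empty = packaged defaults
    seed: int = 1
    temperature: float = 0.6
    bh_temperature: float = 1.5
    bh_steps: int = 40
    gtol: float = 1e-6
    n_images: int = 15
    k_spring: float = 1.0
    connect_budget: int = 40
    n_levels: int = 30
    out_dir: str = "run_output"

    def to_text(self) -> str:
        lines = ["# flipscape run configuration"]
        for name, val in self.__dict__.items():
            lines.append(f"{name} = {val}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        cfg = cls()
        casts = {name: type(getattr(cfg, name)) for name in cfg.__dict__}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in casts:
                raise ParseError(f"line {lineno}: unknown option {key!r}")
            setattr(cfg, key, casts[key](val))
        return cfg

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())
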