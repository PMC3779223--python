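"""Input/output for domain structures, alignments and report tables.

The pipeline consumes four kinds of input: per-member PDB files (only the
Cα trace is used), a structure-based multiple sequence alignment in gapped
FASTA, a family-label TSV and a GO-annotation TSV.  It emits TSV reports
and a multi-model PDB of the superposed ensemble.

Conventions
-----------
* Residues are indexed 0-based internally; PDB residue numbers survive only
  as labels and are never used to match residues across members — alignment
  columns are the sole source of correspondence.
* Only ``-`` is a gap character; ``.`` is rejected.
* TSVs are tab-separated with a header row; Å and similarity values are
  written with 4 decimal places.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentFormatError,
    AlignmentMismatchError,
    NoCalphaAtomsError,
    PDBFieldError,
    PDBFileMissingError,
)

logger = logging.getLogger(__name__)

#: Sentinel for a gap in an alignment row (rows are int arrays).
GAP: int = -1


@dataclass(frozen=True)
class DomainStructure:
    """One superfamily member: an ordered Cα trace plus metadata.

    Parameters
    ----------
    member_id : str
        Unique identifier within the superfamily (e.g. a SCOP domain id).
    family_id : str
        SCOP-style family label.
    residue_labels : tuple of str
        One label per residue, in chain order (chain, name, author number).
    coords : (n, 3) ndarray
        Cα coordinates in Å, one row per residue, file order.
    go_terms : frozenset of str
        GO term identifiers annotated to this member (possibly empty).
    """

    member_id: str
    family_id: str
    residue_labels: tuple[str, ...]
    coords: np.ndarray
    go_terms: frozenset = frozenset()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise ValueError("coords must be a non-empty (n, 3) array")
        if len(self.residue_labels) != coords.shape[0]:
            raise ValueError("one label per residue required")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite Cα coordinates")
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if d.size and not np.all(d > 0):
            raise ValueError("consecutive Cα atoms at identical positions")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def residues(self) -> list[tuple[str, np.ndarray]]:
        """Ordered (label, Cα coordinate) pairs."""
        return list(zip(self.residue_labels, self.coords))

    def with_coords(self, coords: np.ndarray) -> "DomainStructure":
        """Copy of this structure with replaced coordinates."""
        return DomainStructure(self.member_id, self.family_id,
                               self.residue_labels, coords, self.go_terms)

    def with_go_terms(self, terms: Iterable[str]) -> "DomainStructure":
        return DomainStructure(self.member_id, self.family_id,
                               self.residue_labels, self.coords,
                               frozenset(terms))


@dataclass(frozen=True)
class MultipleAlignment:
    """A gapped multiple alignment mapping columns to residue indices.

    ``rows[m]`` is an int array of length ``n_columns``; entry ``c`` is the
    0-based residue index of member ``m`` in column ``c``, or :data:`GAP`.
    Non-gap indices are strictly increasing along each row and every residue
    appears in exactly one column.
    """

    member_ids: tuple[str, ...]
    rows: Mapping[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.member_ids)) != len(self.member_ids):
            raise AlignmentFormatError("duplicate member ids")
        if set(self.member_ids) != set(self.rows):
            raise AlignmentFormatError("member_ids and rows disagree")
        ncols = {len(r) for r in self.rows.values()}
        if len(ncols) != 1:
            raise AlignmentFormatError("rows have unequal column counts")
        frozen = {}
        for m in self.member_ids:
            row = np.asarray(self.rows[m], dtype=int)
            idx = row[row != GAP]
            if idx.size == 0:
                raise AlignmentFormatError(f"member {m!r} is all gaps")
            if not (np.all(np.diff(idx) == 1) and idx[0] == 0):
                raise AlignmentFormatError(
                    f"member {m!r}: residue indices must enumerate "
                    "0..n-1 in order")
            row.setflags(write=False)
            frozen[m] = row
        object.__setattr__(self, "rows", frozen)
        object.__setattr__(self, "member_ids", tuple(self.member_ids))

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def residue_count(self, member_id: str) -> int:
        row = self.rows[member_id]
        return int(np.sum(row != GAP))

    @classmethod
    def from_sequences(cls, ids: Sequence[str],
                       seqs: Sequence[str]) -> "MultipleAlignment":
        """Build from gapped strings; any non-``-`` character is a residue."""
        rows = {}
        for m, s in zip(ids, seqs):
            row = np.full(len(s), GAP, dtype=int)
            k = 0
            for c, ch in enumerate(s):
                if ch != "-":
                    row[c] = k
                    k += 1
            rows[m] = row
        return cls(tuple(ids), rows)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_pdb_calpha(path, member_id: str, family_id: str = "",
                    go_terms: Iterable[str] = ()) -> DomainStructure:
    """Read the Cα trace of the first model of a PDB file.

    One residue is emitted per residue that carries at least one CA atom,
    in record order.  Alternate locations resolve to the first CA record
    encountered for that residue.  HETATM records never contribute.

    Raises
    ------
    PDBFileMissingError
        If *path* does not exist.
    NoCalphaAtomsError
        If no ATOM record with atom name CA is present in the first model.
    PDBFieldError
        If a coordinate field is unparseable or non-finite.
    """
    path = Path(path)
    if not path.exists():
        raise PDBFileMissingError(f"no such PDB file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFieldError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise NoCalphaAtomsError(f"{path}: no models")
    model = st[0]
    labels: list[str] = []
    xyz: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            if res.het_flag == "H":
                continue
            for atom in res:  # file order; first CA wins (altLoc rule)
                if atom.name == "CA":
                    labels.append(f"{chain.name}/{res.name}{res.seqid.num}"
                                  f"{res.seqid.icode.strip()}")
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    break
    if not xyz:
        raise NoCalphaAtomsError(f"{path}: zero CA atoms in first model")
    coords = np.array(xyz, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise PDBFieldError(f"{path}: non-finite CA coordinate")
    return DomainStructure(member_id, family_id, tuple(labels), coords,
                           frozenset(go_terms))


def _atom_line(serial: int, resname: str, chain: str, resseq: int,
               x: float, y: float, z: float) -> str:
    return (f"ATOM  {serial:>5}  CA  {resname:<3} {chain}{resseq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")


def write_calpha_pdb(path, structure: DomainStructure) -> None:
    """Write a single-chain Cα-only PDB file (one ATOM record per residue)."""
    lines = []
    for i, (x, y, z) in enumerate(structure.coords):
        lines.append(_atom_line(i + 1, "ALA", "A", i + 1, x, y, z))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_superposed_pdb(path, structures: Sequence[DomainStructure],
                         coords_by_member: Mapping[str, np.ndarray]) -> None:
    """Write superposed members as a multi-model PDB (MODEL/ENDMDL each)."""
    lines = []
    for k, s in enumerate(structures, start=1):
        lines.append(f"MODEL     {k:>4}")
        lines.append(f"REMARK   6 MEMBER {s.member_id}")
        for i, (x, y, z) in enumerate(coords_by_member[s.member_id]):
            lines.append(_atom_line(i + 1, "ALA", "A", i + 1, x, y, z))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignment reading / writing
# ---------------------------------------------------------------------------

def read_alignment_fasta(path) -> MultipleAlignment:
    """Read a gapped FASTA alignment ('-' gaps only) into a MultipleAlignment."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: empty alignment file")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignmentFormatError(f"{path}: duplicate headers")
    seqs = [str(r.seq) for r in records]
    if len({len(s) for s in seqs}) != 1:
        raise AlignmentFormatError(f"{path}: rows of unequal length")
    for m, s in zip(ids, seqs):
        if "." in s:
            raise AlignmentFormatError(
                f"{path}: member {m!r} uses '.' as gap; only '-' is accepted")
    return MultipleAlignment.from_sequences(ids, seqs)


def write_alignment_fasta(path, aln: MultipleAlignment,
                          sequences: Mapping[str, str] | None = None) -> None:
    """Write an alignment as gapped FASTA.

    *sequences* optionally maps member ids to their ungapped residue
    strings; absent members are written with ``X`` at every residue
    position (synthetic traces carry no amino-acid identity).
    """
    out = []
    for m in aln.member_ids:
        row = aln.rows[m]
        seq = sequences.get(m) if sequences else None
        chars = []
        for v in row:
            if v == GAP:
                chars.append("-")
            else:
                chars.append(seq[v] if seq else "X")
        out.append(f">{m}\n{''.join(chars)}")
    Path(path).write_text("\n".join(out) + "\n")


def validate_alignment(aln: MultipleAlignment,
                       structures: Sequence[DomainStructure]) -> list[str]:
    """Check alignment/structure consistency; return a list of mismatches.

    Each row's non-gap count must equal the member's residue count.  A
    mismatching member is reported as a human-readable string.  An id-set
    mismatch is a hard error.
    """
    by_id = {s.member_id: s for s in structures}
    if set(by_id) != set(aln.member_ids):
        raise AlignmentMismatchError(
            f"alignment ids {sorted(aln.member_ids)} != structure ids "
            f"{sorted(by_id)}")
    mismatches = []
    for m in aln.member_ids:
        n_aln = aln.residue_count(m)
        n_str = len(by_id[m])
        if n_aln != n_str:
            mismatches.append(
                f"{m}: alignment has {n_aln} residues, structure has {n_str}")
    return mismatches


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_family_labels(path) -> dict[str, str]:
    """Read a TSV with columns member_id, family_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["member_id"], df["family_id"]))


def write_family_labels(path, labels: Mapping[str, str]) -> None:
    pd.DataFrame(sorted(labels.items()),
                 columns=["member_id", "family_id"]).to_csv(
        path, sep="\t", index=False)


def read_annotations(path) -> dict[str, frozenset]:
    """Read a TSV with columns member_id, go_terms (comma-separated ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for m, terms in zip(df["member_id"], df["go_terms"]):
        out[m] = frozenset(t for t in terms.split(",") if t)
    return out


def write_annotations(path, annotations: Mapping[str, Iterable[str]]) -> None:
    rows = [(m, ",".join(sorted(ts)))
            for m, ts in sorted(annotations.items())]
    pd.DataFrame(rows, columns=["member_id", "go_terms"]).to_csv(
        path, sep="\t", index=False)


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.4f}"


def write_matrix_tsv(path, member_ids: Sequence[str],
                     matrix: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\t" + "\t".join(member_ids) + "\n")
        for m, row in zip(member_ids, matrix):
            fh.write(m + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return list(df.index), df.to_numpy(dtype=float)


def write_reports(out_dir, report, semantics=None, structures=None,
                  superposed_coords=None) -> dict[str, Path]:
    """Write the pipeline's report files into *out_dir*.

    Emits ``rmsd_matrix.tsv``, ``tm_matrix.tsv``, ``members.tsv`` (mean
    RMSD, median TM-score, outlier flag, family), and — when GO semantics
    were computed — ``semantics_vs_deviation.tsv``; the member table's
    semantics column is ``NA`` otherwise.  When superposed coordinates are
    given, also writes ``superposed.pdb`` with one MODEL per member.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out_dir / "rmsd_matrix.tsv"
    write_matrix_tsv(p, report.member_ids, report.rmsd_matrix)
    paths["rmsd_matrix"] = p

    p = out_dir / "tm_matrix.tsv"
    write_matrix_tsv(p, report.member_ids, report.tm_matrix)
    paths["tm_matrix"] = p

    sem_scores = semantics.member_scores if semantics is not None else {}
    p = out_dir / "members.tsv"
    with open(p, "w") as fh:
        fh.write("member_id\tfamily_id\tmean_rmsd\tmedian_tm\tis_outlier\t"
                 "go_semantics\n")
        for i, m in enumerate(report.member_ids):
            fam = report.families.get(m, "") if report.families else ""
            fh.write("\t".join([
                m, fam,
                _fmt(report.mean_rmsd[m]),
                _fmt(report.tm_median.get(m, float("nan"))),
                str(int(m in report.outliers)),
                _fmt(sem_scores.get(m)),
            ]) + "\n")
    paths["members"] = p

    if semantics is not None:
        p = out_dir / "semantics_vs_deviation.tsv"
        with open(p, "w") as fh:
            fh.write("member_id\tmean_rmsd\tgo_semantics\tis_outlier\n")
            for m in report.member_ids:
                fh.write("\t".join([
                    m, _fmt(report.mean_rmsd[m]),
                    _fmt(sem_scores.get(m)),
                    str(int(m in report.outliers)),
                ]) + "\n")
        paths["semantics_vs_deviation"] = p

    if superposed_coords is not None and structures is not None:
        p = out_dir / "superposed.pdb"
        write_superposed_pdb(p, structures, superposed_coords)
        paths["superposed"] = p
    return paths
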