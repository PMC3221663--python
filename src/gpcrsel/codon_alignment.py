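"""Codon alignments of concatenated 7TM fragments and subgroup bookkeeping.

This module assembles codon alignments by threading unaligned coding
sequences onto a protein multiple sequence alignment (back-translation with
an enforced translation cross-check), and houses the position indexing
(1-based MSA codon columns mapped to Ballesteros-Weinstein labels, with the
ten binding-cavity "key" positions flagged), subgroup membership, and the
natural-ligand category rules.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._codons import GAP_CODON, STOP_CODONS, CODON_INDEX, translate_codon

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = set("XBZJUO")  # tolerated on read, treated as unknown residues
LIGAND_CATEGORIES = ("small", "lipid", "peptide", "divergent", "orphan")


class AlignmentFormatError(ValueError):
    """Raised for ragged or empty alignments."""


class AlignmentContentError(ValueError):
    """Raised for invalid residues, stop codons, or duplicate labels."""


class BackTranslationError(ValueError):
    """Raised when a CDS does not translate to its aligned protein row."""


class ClassificationError(ValueError):
    """Raised when a subgroup member lacks a ligand annotation."""


@dataclass
class ProteinAlignment:
    """Aligned amino-acid matrix: rows are receptors, columns MSA positions."""

    labels: list[str]
    residues: np.ndarray  # (S, L) array of single characters, '-' for gaps

    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    @property
    def column_count(self) -> int:
        return self.residues.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.residues[self.labels.index(label)]

    def column(self, column_index: int) -> np.ndarray:
        """Residues at 1-based MSA column ``column_index``."""
        return self.residues[:, column_index - 1]


@dataclass
class CodonAlignment:
    """Aligned codon matrix; each cell a codon triplet or the '---' gap."""

    labels: list[str]
    codons: np.ndarray  # (S, L) array of 3-character strings

    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    @property
    def column_count(self) -> int:
        return self.codons.shape[1]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise AlignmentContentError("duplicate sequence labels")
        for row, label in zip(self.codons, self.labels):
            for j, codon in enumerate(row):
                if codon == GAP_CODON:
                    continue
                if codon in STOP_CODONS:
                    raise AlignmentContentError(
                        f"stop codon {codon} in {label} at codon column {j + 1}"
                    )
                if codon not in CODON_INDEX:
                    raise AlignmentContentError(
                        f"invalid codon {codon!r} in {label} at codon column {j + 1}"
                    )

    def to_protein(self) -> ProteinAlignment:
        """Translate back to the amino-acid alignment (gaps preserved)."""
        aa = np.empty(self.codons.shape, dtype="<U1")
        for i in range(self.codons.shape[0]):
            for j in range(self.codons.shape[1]):
                c = self.codons[i, j]
                aa[i, j] = "-" if c == GAP_CODON else translate_codon(c)
        return ProteinAlignment(list(self.labels), aa)

    def subset(self, labels: list[str]) -> "CodonAlignment":
        idx = [self.labels.index(l) for l in labels]
        return CodonAlignment(list(labels), self.codons[idx].copy())

    def integer_matrix(self) -> np.ndarray:
        """(S, L) int matrix of codon state indices; -1 marks gaps/missing."""
        out = np.full(self.codons.shape, -1, dtype=np.int64)
        for i in range(self.codons.shape[0]):
            for j in range(self.codons.shape[1]):
                c = self.codons[i, j]
                if c != GAP_CODON:
                    out[i, j] = CODON_INDEX[c]
        return out


@dataclass
class PositionMap:
    """Mapping of 1-based MSA codon columns to Ballesteros-Weinstein labels."""

    table: pd.DataFrame  # columns: column_index, bw_index, is_key

    def __post_init__(self) -> None:
        bw = self.table["bw_index"].dropna()
        bw = bw[bw.astype(str) != ""]
        if bw.duplicated().any():
            raise ValueError("duplicate Ballesteros-Weinstein labels")

    @property
    def key_columns(self) -> list[int]:
        return sorted(self.table.loc[self.table["is_key"].astype(bool), "column_index"])

    def bw_label(self, column_index: int) -> str | None:
        hit = self.table.loc[self.table["column_index"] == column_index, "bw_index"]
        if hit.empty or pd.isna(hit.iloc[0]) or str(hit.iloc[0]) == "":
            return None
        return str(hit.iloc[0])

    def validate_for(self, alignment: CodonAlignment, n_keys: int = 10) -> None:
        keys = self.key_columns
        if len(keys) != n_keys:
            raise ValueError(f"expected {n_keys} key columns, found {len(keys)}")
        for col in keys:
            if not 1 <= col <= alignment.column_count:
                raise ValueError(f"key column {col} outside alignment (L={alignment.column_count})")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"bw_index": str})
        df["column_index"] = df["column_index"].astype(int)
        df["is_key"] = df["is_key"].astype(int)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SubgroupRecord:
    """One receptor subgroup: members, ligand annotations, and flags."""

    subgroup_id: str
    member_labels: list[str]
    ligands: dict[str, str] = field(default_factory=dict)
    chemical_classes: dict[str, str | None] = field(default_factory=dict)
    orphans: set[str] = field(default_factory=set)
    notes_flags: set[str] = field(default_factory=set)
    ligand_category: str | None = None

    @property
    def orphan_count(self) -> int:
        return len(self.orphans)


def read_protein_alignment(path: str | Path) -> ProteinAlignment:
    """Read an aligned protein FASTA into a residue matrix.

    All records must have the same aligned length; residues are upper-cased
    and '-' gaps preserved. Ragged records raise AlignmentFormatError and
    non-amino-acid symbols AlignmentContentError.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        raise AlignmentContentError("duplicate FASTA labels")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentFormatError(f"ragged alignment lengths {sorted(lengths)}")
    (length,) = lengths
    if length == 0:
        raise AlignmentFormatError("zero-length alignment")
    mat = np.empty((len(records), length), dtype="<U1")
    for i, rec in enumerate(records):
        seq = str(rec.seq).upper()
        for j, ch in enumerate(seq):
            if ch != "-" and ch not in AA_ALPHABET and ch not in AMBIGUOUS_AA:
                raise AlignmentContentError(
                    f"invalid residue {ch!r} in {rec.id} at column {j + 1}"
                )
            mat[i, j] = ch
    return ProteinAlignment(labels, mat)


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read unaligned coding nucleotide sequences keyed by label."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise AlignmentContentError(f"duplicate FASTA label {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def build_codon_alignment(
    aa_alignment: ProteinAlignment, cds_records: dict[str, str]
) -> CodonAlignment:
    """Thread coding sequences onto the protein alignment.

    Each residue column is replaced by its source codon; protein gaps become
    codon gaps. The CDS must translate (standard code) to the ungapped
    protein row — any mismatch raises BackTranslationError naming the label
    and position. Codons containing ambiguous nucleotides become gaps
    (missing data). A trailing stop codon on the CDS is tolerated; internal
    stops are content errors.
    """
    S, L = aa_alignment.residues.shape
    codons = np.full((S, L), GAP_CODON, dtype="<U3")
    for i, label in enumerate(aa_alignment.labels):
        if label not in cds_records:
            raise BackTranslationError(f"no CDS record for {label}")
        cds = cds_records[label].replace("U", "T")
        row = aa_alignment.residues[i]
        ungapped = [j for j in range(L) if row[j] != "-"]
        need = 3 * len(ungapped)
        if len(cds) == need + 3 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        if len(cds) != need:
            raise BackTranslationError(
                f"{label}: CDS length {len(cds)} does not match "
                f"{len(ungapped)} aligned residues"
            )
        for k, j in enumerate(ungapped):
            codon = cds[3 * k : 3 * k + 3]
            if any(b not in "ACGT" for b in codon):
                continue  # ambiguous nucleotide -> missing data
            if codon in STOP_CODONS:
                raise AlignmentContentError(
                    f"internal stop codon {codon} in {label} at residue {k + 1}"
                )
            aa = translate_codon(codon)
            expected = row[j]
            if expected in AMBIGUOUS_AA:
                pass  # unknown residue in the protein row; accept the codon
            elif aa != expected:
                raise BackTranslationError(
                    f"{label}: codon {codon} at residue {k + 1} translates to "
                    f"{aa}, alignment has {expected}"
                )
            codons[i, j] = codon
    return CodonAlignment(list(aa_alignment.labels), codons)


def classify_subgroup(record: SubgroupRecord) -> str:
    """Assign the natural-ligand category of a subgroup.

    Rules, applied in order: all members orphans -> "orphan"; more than two
    orphan members, or non-orphan members spanning more than one chemical
    class (or any class outside small/lipid/peptide) -> "divergent";
    otherwise the unanimous class of the non-orphan members.
    """
    if not record.member_labels:
        raise ClassificationError(f"subgroup {record.subgroup_id} has no members")
    non_orphans = [m for m in record.member_labels if m not in record.orphans]
    if not non_orphans:
        return "orphan"
    if record.orphan_count > 2:
        return "divergent"
    classes = set()
    for m in non_orphans:
        cls = record.chemical_classes.get(m)
        if cls is None or cls == "":
            raise ClassificationError(
                f"subgroup {record.subgroup_id}: member {m} has no ligand annotation"
            )
        classes.add(cls)
    if len(classes) == 1 and classes <= {"small", "lipid", "peptide"}:
        return classes.pop()
    return "divergent"


def load_subgroups(path: str | Path | None = None) -> dict[str, SubgroupRecord]:
    """Load subgroup membership from TSV (packaged fixture by default).

    The packaged table covers 45 curated human class A subgroups (plus
    the overlapping variant "13b"). Ligand categories are filled by
    classify_subgroup.
    """
    if path is None:
        path = importlib.resources.files("gpcrsel").joinpath("data/subgroups.tsv")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    out: dict[str, SubgroupRecord] = {}
    for sg_id, sub in df.groupby("subgroup_id", sort=False):
        rec = SubgroupRecord(subgroup_id=str(sg_id), member_labels=list(sub["label"]))
        for _, row in sub.iterrows():
            label = row["label"]
            rec.ligands[label] = row.get("ligand", "")
            cls = row.get("chemical_class", "")
            rec.chemical_classes[label] = cls if cls else None
            if str(row.get("orphan", "0")) == "1":
                rec.orphans.add(label)
            notes = row.get("notes", "")
            if notes:
                rec.notes_flags.update(n.strip() for n in notes.split(",") if n.strip())
        rec.ligand_category = classify_subgroup(rec)
        out[rec.subgroup_id] = rec
    return out


def category_counts(
    subgroups: dict[str, SubgroupRecord], exclude: tuple[str, ...] = ("13b",)
) -> dict[str, int]:
    """Count subgroups per ligand category (overlapping variants excluded)."""
    counts = {c: 0 for c in LIGAND_CATEGORIES}
    for sg_id, rec in subgroups.items():
        if sg_id in exclude:
            continue
        counts[rec.ligand_category] += 1
    return counts


def load_position_map(path: str | Path | None = None) -> PositionMap:
    """Load the column/BW/key map (packaged Table-style map by default)."""
    if path is None:
        path = importlib.resources.files("gpcrsel").joinpath("data/key_positions.tsv")
    return PositionMap.from_tsv(path)


def write_protein_fasta(path: str | Path, labels: list[str], rows) -> None:
    with open(path, "w") as fh:
        for label, row in zip(labels, rows):
            fh.write(f">{label}\n{''.join(row)}\n")


def write_cds_fasta(path: str | Path, cds: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for label, seq in cds.items():
            fh.write(f">{label}\n{seq}\n")
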