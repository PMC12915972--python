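"""Reading, validation, and canonicalization of miRNA-drug association data.

A prediction task is defined by three inputs: an association table
(miRNA id, drug id pairs labeled resistance or sensitivity), the miRNA
sequences (FASTA or two-column TSV, RNA alphabet), and the drug SMILES
strings (two-column TSV). These are assembled into a single
:class:`AssociationBundle` holding indexed records and the positive pair
set for one task. Resistance and sensitivity are independent tasks and
produce independent bundles.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

_RNA_ALPHABET = set("ACGU")
_CANON_MAP = str.maketrans("acgtuT", "ACGUUU")
_ACCEPTED = set("ACGTUacgtu")


class Task(str, Enum):
    """Association polarity: drug resistance or drug sensitivity."""

    RESISTANCE = "resistance"
    SENSITIVITY = "sensitivity"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class MiRNARecord:
    """A miRNA identifier with its canonicalized RNA sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"miRNA {self.id!r}: empty sequence")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise DataError(
                f"miRNA {self.id!r}: non-RNA characters {sorted(bad)} "
                "(canonicalize first)"
            )


@dataclass(frozen=True)
class DrugRecord:
    """A drug identifier with its SMILES string (parsed downstream)."""

    id: str
    smiles: str

    def __post_init__(self):
        if not self.smiles:
            raise DataError(f"drug {self.id!r}: empty SMILES")


@dataclass
class AssociationBundle:
    """Indexed records plus the positive pair set for one task.

    ``positives`` holds ``(mirna_index, drug_index)`` pairs into the
    ``mirnas`` / ``drugs`` lists. Isolated nodes (referenced by no pair)
    are permitted.
    """

    mirnas: list[MiRNARecord]
    drugs: list[DrugRecord]
    positives: set[tuple[int, int]]
    task: Task
    mirna_index: dict[str, int] = field(init=False, repr=False)
    drug_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.mirna_index = {m.id: i for i, m in enumerate(self.mirnas)}
        self.drug_index = {d.id: j for j, d in enumerate(self.drugs)}
        if len(self.mirna_index) != len(self.mirnas):
            raise DataError("duplicate miRNA ids")
        if len(self.drug_index) != len(self.drugs):
            raise DataError("duplicate drug ids")
        for i, j in self.positives:
            if not (0 <= i < len(self.mirnas) and 0 <= j < len(self.drugs)):
                raise DataError(f"pair index ({i}, {j}) out of range")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def positive_degree(self, side: str) -> dict[int, int]:
        """Count of positive associations per entity on ``side``."""
        n = self.n_mirnas if side == "mirna" else self.n_drugs
        deg = {k: 0 for k in range(n)}
        for i, j in self.positives:
            deg[i if side == "mirna" else j] += 1
        return deg


def canonicalize_sequence(raw: str) -> str:
    """Uppercase and map DNA thymine to uracil; reject ambiguity codes.

    miRBase-derived sequence files mix case and alphabet; downstream
    encoders assume a strict 4-letter RNA alphabet, so ambiguity codes
    (N, R, Y, ...) are rejected rather than imputed. Idempotent.
    """
    if not raw:
        raise DataError("empty sequence")
    for pos, ch in enumerate(raw, start=1):
        if ch not in _ACCEPTED:
            raise DataError(f"invalid character {ch!r} at position {pos}")
    return raw.translate(_CANON_MAP)


_HEADER_TOKENS = {
    "mirna", "mirna_id", "mir", "mir_id", "microrna", "id", "name",
    "drug", "drug_id", "smiles", "sequence", "label",
}


def _looks_like_header(row: list[str]) -> bool:
    return bool(row) and row[0].strip().lower() in _HEADER_TOKENS


def load_association_table(path: str | Path, task: Task | str = Task.RESISTANCE,
                           ) -> tuple[list[tuple[str, str]], int]:
    """Read a ``mirna_id<TAB>drug_id[<TAB>label]`` table.

    Returns the deduplicated (first-seen order) id-pair list and the
    number of duplicate rows dropped. When a label column is present,
    only rows whose label matches ``task`` are kept; unlabeled tables
    are taken to belong entirely to ``task``.
    """
    task = Task(task)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and _looks_like_header(row):
                continue
            if len(row) < 2:
                raise DataError(f"{path}:{lineno}: malformed row "
                                f"(expected >=2 tab-separated columns)")
            mirna_id, drug_id = row[0].strip(), row[1].strip()
            if len(row) >= 3 and row[2].strip():
                label = row[2].strip().lower()
                if label not in (task.value, task.value[:3]):
                    continue
            key = (mirna_id, drug_id)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            pairs.append(key)
    if n_dup:
        logger.info("%s: dropped %d duplicate association rows", path, n_dup)
    return pairs, n_dup


def load_sequences(path: str | Path) -> dict[str, str]:
    """Read miRNA sequences from FASTA or a 2-column TSV (raw, not canonicalized).

    FASTA is detected by a leading ``>``; the record id is the first
    whitespace-delimited token of the header.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.read(1)
    out: dict[str, str] = {}
    if first == ">":
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = str(rec.seq)
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if lineno == 1 and _looks_like_header(row):
                    continue
                if len(row) < 2:
                    raise DataError(f"{path}:{lineno}: malformed sequence row")
                out[row[0].strip()] = row[1].strip()
    return out


def load_smiles(path: str | Path) -> dict[str, str]:
    """Read a ``drug_id<TAB>smiles`` table."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and _looks_like_header(row):
                continue
            if len(row) < 2:
                raise DataError(f"{path}:{lineno}: malformed SMILES row")
            out[row[0].strip()] = row[1].strip()
    return out


def assemble_bundle(sequences: dict[str, str], smiles: dict[str, str],
                    pairs: list[tuple[str, str]], task: Task | str) -> AssociationBundle:
    """Canonicalize records and resolve id pairs into an indexed bundle.

    Pairs that reference a miRNA without a sequence or a drug without a
    SMILES string are dropped with a warning (mirroring the screening
    step that excludes entries absent from the sequence/structure
    databases). An empty resulting positive set is an error.
    """
    task = Task(task)
    mirnas = [MiRNARecord(mid, canonicalize_sequence(seq))
              for mid, seq in sequences.items()]
    drugs = [DrugRecord(did, smi) for did, smi in smiles.items()]
    m_idx = {m.id: i for i, m in enumerate(mirnas)}
    d_idx = {d.id: j for j, d in enumerate(drugs)}
    positives: set[tuple[int, int]] = set()
    for mid, did in pairs:
        if mid not in m_idx:
            logger.warning("dropping pair (%s, %s): no sequence for miRNA", mid, did)
            continue
        if did not in d_idx:
            logger.warning("dropping pair (%s, %s): no SMILES for drug", mid, did)
            continue
        positives.add((m_idx[mid], d_idx[did]))
    if not positives:
        raise DataError("empty positive set after assembling bundle")
    return AssociationBundle(mirnas=mirnas, drugs=drugs, positives=positives, task=task)


def load_bundle(associations: str | Path, sequences: str | Path,
                smiles: str | Path, task: Task | str) -> AssociationBundle:
    """Convenience: load all three files and assemble one task bundle."""
    pairs, _ = load_association_table(associations, task)
    return assemble_bundle(load_sequences(sequences), load_smiles(smiles), pairs, task)


def write_bundle(bundle: AssociationBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle back to the three on-disk formats (round-trippable)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": out_dir / "associations.tsv",
        "sequences": out_dir / "mirnas.fasta",
        "smiles": out_dir / "drugs.tsv",
    }
    with open(paths["associations"], "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tdrug_id\tlabel\n")
        for i, j in sorted(bundle.positives):
            fh.write(f"{bundle.mirnas[i].id}\t{bundle.drugs[j].id}\t"
                     f"{bundle.task.value}\n")
    with open(paths["sequences"], "w", encoding="utf-8") as fh:
        for m in bundle.mirnas:
            fh.write(f">{m.id}\n{m.sequence}\n")
    with open(paths["smiles"], "w", encoding="utf-8") as fh:
        fh.write("drug_id\tsmiles\n")
        for d in bundle.drugs:
            fh.write(f"{d.id}\t{d.smiles}\n")
    return paths
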