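"""Multi-label peptide records: FASTA dialect I/O, residue encoding, splits.

Therapeutic-peptide benchmarks annotate each peptide with one or more of 21
activity classes (antibacterial, anticancer, cell-penetrating, ...).  Records
are stored as FASTA whose header carries the label vector::

    >P0001|100000000000000000001
    KWKLFKKIEK

i.e. ``>ID|b1..b21`` with a 21-character 0/1 string in the order of
:data:`LABEL_NAMES`.  Sequences are single-line, upper-case, over the 20
canonical amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "LABEL_NAMES",
    "PeptideRecord",
    "read_multilabel_fasta",
    "write_multilabel_fasta",
    "encode_residues",
    "train_test_split",
]

#: The 20 canonical residues in alphabetical one-letter order; the encoding
#: of :func:`encode_residues` is the 1-based rank in this string (A=1, C=2, ...).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}

#: The 21 therapeutic activity classes, by standard abbreviation.
LABEL_NAMES = (
    "AAP", "AHIVP", "SBP", "AFP", "ABP", "AHP", "AVP", "ACP", "AIP", "APP",
    "AEP", "BIP", "BBP", "ACVP", "AMRSAP", "CPP", "DPPIP", "ADP", "ATP",
    "THP", "QSP",
)


def validate_sequence(sequence: str, context: str = "sequence") -> None:
    """Raise ``ValueError`` naming the offending residue if not alphabet-valid."""
    if not sequence:
        raise ValueError(f"{context}: empty sequence")
    for ch in sequence:
        if ch not in _AA_INDEX:
            raise ValueError(f"{context}: invalid residue {ch!r}")


@dataclass
class PeptideRecord:
    """One peptide: identifier, residue string and a binary label vector."""

    id: str
    sequence: str
    labels: np.ndarray = field(default_factory=lambda: np.zeros(len(LABEL_NAMES), dtype=np.int8))

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError(f"record {self.id}: labels must be a vector")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError(f"record {self.id}: labels must be 0/1")

    def __eq__(self, other):
        return (
            isinstance(other, PeptideRecord)
            and self.id == other.id
            and self.sequence == other.sequence
            and np.array_equal(self.labels, other.labels)
        )


def _parse_header(description: str, n_labels: int, lineno: int | None = None) -> tuple[str, np.ndarray]:
    where = f" (record {lineno})" if lineno is not None else ""
    if "|" not in description:
        raise ValueError(f"header lacks '|label' field{where}: {description!r}")
    rid, bits = description.rsplit("|", 1)
    if len(bits) != n_labels or any(b not in "01" for b in bits):
        raise ValueError(
            f"label field must be a {n_labels}-character 0/1 string{where}: {bits!r}"
        )
    return rid, np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")


def read_multilabel_fasta(path, n_labels: int = len(LABEL_NAMES)) -> list[PeptideRecord]:
    """Read the label-bearing FASTA dialect into :class:`PeptideRecord` objects.

    File order is preserved.  Raises ``ValueError`` for malformed headers,
    out-of-alphabet residues, or duplicate identifiers.
    """
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        rid, labels = _parse_header(rec.description, n_labels, lineno=i)
        sequence = str(rec.seq)
        validate_sequence(sequence, context=f"record {rid}")
        if rid in seen:
            raise ValueError(f"duplicate record ID: {rid!r}")
        seen.add(rid)
        records.append(PeptideRecord(rid, sequence, labels.astype(np.int8)))
    return records


def write_multilabel_fasta(records: list[PeptideRecord], path) -> None:
    """Write records in the dialect of :func:`read_multilabel_fasta` (round-trip safe)."""
    out = []
    for rec in records:
        validate_sequence(rec.sequence, context=f"record {rec.id}")
        bits = "".join(str(int(b)) for b in rec.labels)
        out.append(SeqRecord(Seq(rec.sequence), id=f"{rec.id}|{bits}", description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(out)


def encode_residues(sequence: str, n: int = 50) -> np.ndarray:
    """Encode a peptide as a length-``n`` integer vector.

    Residues map to their 1-based rank in ``ACDEFGHIKLMNPQRSTVWY`` (A=1,
    C=2, ..., Y=20); shorter sequences are right-padded with 0 and longer
    ones keep their first ``n`` (N-terminal) residues.
    """
    validate_sequence(sequence)
    out = np.zeros(n, dtype=np.int64)
    for i, ch in enumerate(sequence[:n]):
        out[i] = _AA_INDEX[ch]
    return out


def train_test_split(
    records: list[PeptideRecord], fraction: float = 0.8, seed: int = 0
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Random, unstratified, exact and disjoint split (train fraction first)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(fraction * len(records)))
    n_train = min(max(n_train, 1), len(records) - 1)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return [records[i] for i in train_idx], [records[i] for i in test_idx]
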