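"""Multi-label peptide dataset I/O and integer sequence encoding.

Peptides are short chains of the 20 canonical amino acids (5-50 residues by
default), each carrying one or more function labels from a fixed label space.
Sequences are encoded as fixed-length integer vectors: residues map to codes
1..20 in alphabetical single-letter order and the remainder of the vector is
right-padded with 0, so that position ``i`` of the code vector is position
``i`` of the peptide.

Two on-disk dialects are supported:

* multi-label FASTA — header ``>{id}|{label1,label2,...}``, uppercase sequence;
* TSV — columns ``id``, ``sequence``, ``labels`` (comma-separated), with a
  header row.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "AA_TO_CODE",
    "CODE_TO_AA",
    "MAX_SEQ_LEN",
    "MIN_SEQ_LEN",
    "LabelSpace",
    "PeptideRecord",
    "EncodingError",
    "default_label_space",
    "build_label_space",
    "encode_sequence",
    "encode_batch",
    "decode_sequence",
    "read_dataset",
    "write_dataset",
    "read_label_space",
    "write_label_space",
]

#: Canonical amino acids in alphabetical single-letter order; index + 1 = code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_CODE = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
CODE_TO_AA = {i + 1: aa for i, aa in enumerate(AMINO_ACIDS)}

MIN_SEQ_LEN = 5
MAX_SEQ_LEN = 50

#: The 21 therapeutic-peptide classes of the benchmark label space.
DEFAULT_CLASS_NAMES = (
    "AAP",    # antiangiogenic peptide
    "ABP",    # antibacterial peptide
    "ACP",    # anticancer peptide
    "ACVP",   # anticoronavirus peptide
    "ADP",    # antidiabetic peptide
    "AEP",    # antiendotoxin peptide
    "AFP",    # antifungal peptide
    "AHIVP",  # anti-HIV peptide
    "AHP",    # antihypertensive peptide
    "AIP",    # anti-inflammatory peptide
    "AMRSAP", # anti-MRSA peptide
    "APP",    # antiparasitic peptide
    "ATP",    # antitubercular peptide
    "AVP",    # antiviral peptide
    "BBP",    # blood-brain barrier peptide
    "BIP",    # biofilm-inhibitory peptide
    "CPP",    # cell-penetrating peptide
    "DPPIP",  # dipeptidyl peptidase IV inhibitory peptide
    "QSP",    # quorum-sensing peptide
    "SBP",    # surface-binding peptide
    "THP",    # tumor-homing peptide
)


class EncodingError(ValueError):
    """A sequence contains a symbol outside the canonical alphabet."""


@dataclass(frozen=True)
class LabelSpace:
    """An ordered, immutable set of class names defining label-vector indices."""

    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) < 2:
            raise ValueError("a label space needs at least 2 classes")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate class names: {dupes}")
        if any(not n for n in self.names):
            raise ValueError("class names must be non-empty")

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_binary(self, labels: Iterable[str]) -> np.ndarray:
        """Binary label vector from an iterable of class names."""
        vec = np.zeros(self.size, dtype=np.int8)
        unknown = []
        for lab in labels:
            if lab in self.names:
                vec[self.names.index(lab)] = 1
            else:
                unknown.append(lab)
        if unknown:
            raise ValueError(f"labels not in label space: {unknown}")
        return vec

    def to_names(self, vec: Sequence[int]) -> list[str]:
        return [self.names[i] for i, v in enumerate(vec) if v]


def build_label_space(names: Sequence[str]) -> LabelSpace:
    """Construct a :class:`LabelSpace` with a stable index order."""
    return LabelSpace(tuple(names))


def default_label_space() -> LabelSpace:
    """The 21-class therapeutic-peptide label space."""
    return LabelSpace(DEFAULT_CLASS_NAMES)


@dataclass
class PeptideRecord:
    """One peptide with its identifier, sequence and binary label vector."""

    id: str
    sequence: str
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    def validate(self, label_space: LabelSpace | None = None,
                 min_len: int = MIN_SEQ_LEN, max_len: int = MAX_SEQ_LEN,
                 require_label: bool = True) -> None:
        n = len(self.sequence)
        if not (min_len <= n <= max_len):
            raise ValueError(
                f"record {self.id!r}: sequence length {n} outside [{min_len}, {max_len}]")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in AA_TO_CODE:
                raise EncodingError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}")
        labels = np.asarray(self.labels)
        if label_space is not None and labels.shape != (label_space.size,):
            raise ValueError(
                f"record {self.id!r}: label vector length {labels.shape} != {label_space.size}")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError(f"record {self.id!r}: labels must be binary")
        if require_label and labels.sum() == 0:
            raise ValueError(f"record {self.id!r}: at least one label required")


def encode_sequence(sequence: str, max_seq_len: int = MAX_SEQ_LEN, *,
                    truncate: bool = False) -> np.ndarray:
    """Encode a peptide as codes 1..20 right-padded with 0 to ``max_seq_len``.

    Raises
    ------
    EncodingError
        If a character is outside ``ACDEFGHIKLMNPQRSTVWY`` (names the symbol
        and its 1-based position).
    ValueError
        If the sequence is longer than ``max_seq_len`` and ``truncate`` is off.
    """
    if len(sequence) > max_seq_len:
        if not truncate:
            raise ValueError(
                f"sequence length {len(sequence)} exceeds max_seq_len={max_seq_len}")
        sequence = sequence[:max_seq_len]
    codes = np.zeros(max_seq_len, dtype=np.int64)
    for i, ch in enumerate(sequence):
        code = AA_TO_CODE.get(ch)
        if code is None:
            raise EncodingError(f"invalid residue {ch!r} at position {i + 1}")
        codes[i] = code
    return codes


def encode_batch(sequences: Iterable[str], max_seq_len: int = MAX_SEQ_LEN) -> np.ndarray:
    """Encode several peptides into an (N, max_seq_len) integer matrix."""
    return np.stack([encode_sequence(s, max_seq_len) for s in sequences])


def decode_sequence(codes: Sequence[int]) -> str:
    """Inverse of :func:`encode_sequence`: strip the zero pad, map codes back."""
    codes = np.asarray(codes)
    nonzero = np.flatnonzero(codes)
    if nonzero.size == 0:
        return ""
    prefix_len = nonzero[-1] + 1
    prefix = codes[:prefix_len]
    if (prefix == 0).any():
        raise ValueError("zeros interior to the sequence prefix (pad must be a suffix)")
    try:
        return "".join(CODE_TO_AA[int(c)] for c in prefix)
    except KeyError as exc:
        raise ValueError(f"code {exc.args[0]} outside 1..20") from None


# ---------------------------------------------------------------------------
# dataset files


def _parse_header(header: str, line_no: int) -> tuple[str, list[str]]:
    if "|" not in header:
        raise ValueError(f"line {line_no}: FASTA header lacks '|' label separator: {header!r}")
    rid, _, labels = header.partition("|")
    if not rid:
        raise ValueError(f"line {line_no}: empty record id in header {header!r}")
    return rid, [l for l in labels.split(",") if l]


def read_dataset(path: str | Path, format: str, label_space: LabelSpace, *,
                 validate: bool = True, skip_invalid: bool = False) -> list[PeptideRecord]:
    """Read a multi-label peptide dataset in FASTA or TSV dialect.

    With ``skip_invalid`` records failing validation are dropped (counted in
    the raised-free path) instead of aborting the read.
    """
    path = Path(path)
    if format == "fasta":
        records = []
        for seqrec in SeqIO.parse(str(path), "fasta"):
            header = seqrec.description
            rid, label_names = _parse_header(header, 0)
            records.append(PeptideRecord(
                id=rid, sequence=str(seqrec.seq).upper(),
                labels=label_space.to_binary(label_names)))
    elif format == "tsv":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        expected = ["id", "sequence", "labels"]
        if list(df.columns[:3]) != expected:
            raise ValueError(f"TSV header must be {expected}, got {list(df.columns)}")
        records = []
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            label_names = [l for l in row.labels.split(",") if l]
            records.append(PeptideRecord(
                id=row.id, sequence=row.sequence.upper(),
                labels=label_space.to_binary(label_names)))
    else:
        raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'tsv')")

    if validate:
        kept = []
        n_dropped = 0
        for rec in records:
            try:
                rec.validate(label_space)
            except (ValueError, EncodingError):
                if skip_invalid:
                    n_dropped += 1
                    continue
                raise
            kept.append(rec)
        records = kept
        if n_dropped:
            import logging

            logging.getLogger(__name__).warning(
                "dropped %d invalid record(s) while reading %s", n_dropped, path)
    return records


def write_dataset(records: Sequence[PeptideRecord], path: str | Path,
                  format: str, label_space: LabelSpace) -> None:
    """Write records in the FASTA or TSV dialect (deterministic byte output)."""
    path = Path(path)
    if format == "fasta":
        seqrecs = []
        for rec in records:
            header = f"{rec.id}|{','.join(label_space.to_names(rec.labels))}"
            seqrecs.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
        buf = _stdio.StringIO()
        SeqIO.write(seqrecs, buf, "fasta-2line")
        path.write_text(buf.getvalue())
    elif format == "tsv":
        lines = ["id\tsequence\tlabels"]
        for rec in records:
            lines.append(
                f"{rec.id}\t{rec.sequence}\t{','.join(label_space.to_names(rec.labels))}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'tsv')")


def read_label_space(path: str | Path) -> LabelSpace:
    """Label-space file: one class name per line, order = index order."""
    names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return build_label_space(names)


def write_label_space(label_space: LabelSpace, path: str | Path) -> None:
    Path(path).write_text("\n".join(label_space.names) + "\n")
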