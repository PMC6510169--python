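"""Reading, validating and writing protein sequences and labeled datasets.

Sequences are restricted to the 20 standard residues.  Records carrying
ambiguity codes (X, B, Z, and also J, O, U) are rejected at dataset-building
time, mirroring the common curation step of discarding sequences with
ambiguous amino acids before descriptor computation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import ConfigurationError, FastaParseError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Minimum sequence length accepted by default.  Distribution descriptors
#: use 25/50/75% occurrence quantiles, which are degenerate on very short
#: sequences; ten residues is the shortest length at which they are
#: meaningfully distinct.
DEFAULT_MIN_LENGTH = 10

#: Named label schemes for the hierarchical classification task.
LABEL_SCHEMES: dict[str, tuple[str, ...]] = {
    "ion": ("ion", "non-ion"),
    "gating": ("voltage", "ligand"),
    "subtype": ("K", "Ca", "Na", "anion"),
    "six": ("non-ion", "ligand", "K", "Ca", "Na", "anion"),
}


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence with an identifier.

    Attributes
    ----------
    id : str
        Record identifier (FASTA header token before the first whitespace).
    residues : str
        Upper-case residue string over the 20-letter standard alphabet.
    """

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of :func:`validate_sequence`: accepted or rejected with a reason."""

    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


def validate_sequence(residues: str, min_length: int = DEFAULT_MIN_LENGTH) -> ValidationVerdict:
    """Check a candidate residue string against the standard-alphabet rules.

    A sequence is rejected if it is empty, shorter than ``min_length``, or
    contains any character outside ``ACDEFGHIKLMNPQRSTVWY`` — explicitly
    including the ambiguity codes X, B and Z, plus J, O and U.

    Returns a verdict rather than raising, so callers can log and continue.
    """
    if residues == "":
        return ValidationVerdict(False, "empty sequence")
    bad = next((c for c in residues if c not in _ALPHABET_SET), None)
    if bad is not None:
        if bad in "XBZJOU":
            return ValidationVerdict(False, f"ambiguous residue {bad}")
        return ValidationVerdict(False, f"non-standard character {bad!r}")
    if len(residues) < min_length:
        return ValidationVerdict(False, f"shorter than minimum length {min_length}")
    return ValidationVerdict(True)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    Residues are upper-cased; the id is the header token before the first
    whitespace; record order is preserved.  The reader is permissive about
    residue content and duplicate ids — strictness lives in the dataset
    constructor and :func:`validate_sequence`.

    Raises
    ------
    FastaParseError
        If sequence data appears before any ``>`` header, naming the line.
    """
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError("sequence data before any FASTA header", lineno)
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA, wrapping residue lines at ``width`` columns."""
    path = Path(path)
    with path.open("w") as handle:
        for seq in sequences:
            handle.write(f">{seq.id}\n")
            for start in range(0, len(seq.residues), width):
                handle.write(seq.residues[start : start + width] + "\n")


@dataclass
class LabeledDataset:
    """An ordered collection of labeled protein sequences under a label scheme.

    Enforces unique ids and labels drawn from the declared scheme.
    """

    records: list[tuple[ProteinSequence, str]]
    scheme: str = "six"
    labels_allowed: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.scheme not in LABEL_SCHEMES:
            raise ConfigurationError(
                f"unknown label scheme {self.scheme!r}; known: {sorted(LABEL_SCHEMES)}"
            )
        self.labels_allowed = LABEL_SCHEMES[self.scheme]
        seen: set[str] = set()
        for seq, label in self.records:
            if label not in self.labels_allowed:
                raise ConfigurationError(
                    f"label {label!r} not in scheme {self.scheme!r} {self.labels_allowed}"
                )
            if seq.id in seen:
                raise ConfigurationError(f"duplicate sequence id {seq.id!r}")
            seen.add(seq.id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[ProteinSequence]:
        return [seq for seq, _ in self.records]

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.records]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, label in self.records:
            counts[label] = counts.get(label, 0) + 1
        return counts


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV label map with header ``id<TAB>label``."""
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["id", "label"]:
            raise ConfigurationError(
                f"label map {path} must start with a header line 'id\\tlabel'"
            )
        mapping: dict[str, str] = {}
        for row in reader:
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ConfigurationError(f"label map {path}: malformed row {row!r}")
            mapping[row[0].strip()] = row[1].strip()
    return mapping


def write_label_map(labels: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = labels.items() if isinstance(labels, Mapping) else labels
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "label"])
        for seq_id, label in items:
            writer.writerow([seq_id, label])


def load_labeled_dataset(
    fasta_paths: Sequence[str | Path] | Mapping[str, str | Path],
    label_map: str | Path | Mapping[str, str] | None = None,
    scheme: str = "six",
    min_length: int = DEFAULT_MIN_LENGTH,
) -> LabeledDataset:
    """Load and validate a labeled dataset.

    Labels come either from per-class FASTA files (pass a mapping
    ``{label: path}``) or from a TSV/dict label map covering every record of
    the given FASTA files.  Sequences failing :func:`validate_sequence` are
    dropped; a summary log line reports kept/dropped counts per class.

    Raises
    ------
    ConfigurationError
        If a label is missing from the map, or a label falls outside the
        declared scheme.
    """
    allowed = LABEL_SCHEMES.get(scheme)
    if allowed is None:
        raise ConfigurationError(f"unknown label scheme {scheme!r}")

    labeled: list[tuple[ProteinSequence, str]] = []
    if isinstance(fasta_paths, Mapping):
        for label, path in fasta_paths.items():
            if label not in allowed:
                raise ConfigurationError(f"class {label!r} absent from scheme {scheme!r}")
            for seq in read_fasta(path):
                labeled.append((seq, label))
    else:
        if label_map is None:
            raise ConfigurationError("a label map is required with a flat list of FASTA files")
        mapping = label_map if isinstance(label_map, Mapping) else read_label_map(label_map)
        for bad in set(mapping.values()) - set(allowed):
            raise ConfigurationError(f"label {bad!r} absent from scheme {scheme!r}")
        for path in fasta_paths:
            for seq in read_fasta(path):
                if seq.id not in mapping:
                    raise ConfigurationError(f"no label for sequence id {seq.id!r}")
                labeled.append((seq, mapping[seq.id]))

    kept: list[tuple[ProteinSequence, str]] = []
    n_kept: dict[str, int] = {}
    n_dropped: dict[str, int] = {}
    for seq, label in labeled:
        verdict = validate_sequence(seq.residues, min_length=min_length)
        if verdict:
            kept.append((seq, label))
            n_kept[label] = n_kept.get(label, 0) + 1
        else:
            n_dropped[label] = n_dropped.get(label, 0) + 1
            logger.info("dropping %s (%s): %s", seq.id, label, verdict.reason)
    for label in sorted(set(n_kept) | set(n_dropped)):
        logger.info(
            "class %s: kept %d, dropped %d",
            label,
            n_kept.get(label, 0),
            n_dropped.get(label, 0),
        )
    return LabeledDataset(records=kept, scheme=scheme)
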