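"""Labeled peptide sequence I/O and synthetic dataset generation.

Peptides are short sequences over the 20 standard amino acids, each carrying a
binary activity label (1 = anticancer peptide, positive; 0 = non-ACP,
negative).  Real benchmark sets (e.g. the ACP-DL collections) distribute
labels either as a ``|0`` / ``|1`` suffix on the FASTA header or as separate
positive/negative files; both conventions are supported, plus a sidecar TSV.

The synthetic generator produces composition-separable classes: positives are
tilted toward the cationic residues K/R/H (the physicochemical hallmark of
anticancer peptides), negatives toward D/E/S/T.  It exists so that every part
of the pipeline can be exercised without downloading external data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard residues in alphabetical one-letter order.  This order
#: defines the integer rank used by every encoder (A=0 ... Y=19).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)
RESIDUE_RANK = {aa: i for i, aa in enumerate(ALPHABET)}

#: Residue classes used by the synthetic generator.
CATIONIC = "KRH"
ANIONIC_POLAR = "DEST"


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class LabelError(ValueError):
    """A sequence could not be resolved to a binary label."""


class ValidationError(ValueError):
    """A record violates the peptide-record invariants."""


@dataclasses.dataclass(frozen=True)
class PeptideRecord:
    """One labeled peptide sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    sequence : str
        Residue string over the 20-letter alphabet; length >= 1.  The padding
        symbol ``X`` is introduced only inside encoders, never stored here.
    label : int
        1 for ACP (positive), 0 for non-ACP (negative).
    """

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for ch in self.sequence:
            if ch not in ALPHABET_SET:
                raise ValidationError(
                    f"record {self.id!r}: non-standard residue {ch!r}"
                )
        if self.label not in (0, 1):
            raise ValidationError(f"record {self.id!r}: label must be 0 or 1")


@dataclasses.dataclass
class LabeledDataset:
    """An ordered collection of :class:`PeptideRecord` with unique ids."""

    records: list[PeptideRecord]
    name: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices],
            name if name is not None else self.name,
        )


def _parse_header_suffix(header: str) -> tuple[str, int]:
    ident, sep, tail = header.rpartition("|")
    if not sep or tail not in ("0", "1"):
        raise LabelError(
            f"header {header!r}: expected a trailing '|0' or '|1' label token"
        )
    return ident, int(tail)


def read_labeled_fasta(
    path: str | Path,
    label_scheme: str = "header_suffix",
    sidecar: str | Path | None = None,
    name: str | None = None,
) -> LabeledDataset:
    """Read a labeled peptide FASTA file.

    ``label_scheme='header_suffix'`` parses a trailing ``|1`` / ``|0`` token on
    each header; ``'sidecar'`` looks labels up in a two-column tab-separated
    file (id, label) given by *sidecar*.  Sequences are uppercased on read;
    multi-line FASTA is accepted.  An empty file yields an empty dataset.
    """
    path = Path(path)
    if label_scheme not in ("header_suffix", "sidecar"):
        raise ValueError(f"unknown label scheme {label_scheme!r}")
    label_map: dict[str, int] = {}
    if label_scheme == "sidecar":
        if sidecar is None:
            raise LabelError("sidecar label scheme requires a sidecar path")
        for lineno, line in enumerate(Path(sidecar).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1].strip() not in ("0", "1"):
                raise LabelError(f"{sidecar}, line {lineno}: expected 'id<TAB>0|1'")
            label_map[parts[0].strip()] = int(parts[1])

    # Reject non-FASTA leading content explicitly; Bio.SeqIO silently returns
    # nothing for files that do not start with '>'.
    text_head = path.read_text()[:1]
    if text_head and text_head != ">":
        raise FastaParseError(f"{path}, line 1: expected '>' to start a FASTA entry")

    records: list[PeptideRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description.split()[0] if entry.description else entry.id
        if label_scheme == "header_suffix":
            ident, label = _parse_header_suffix(header)
        else:
            ident = header
            if ident not in label_map:
                raise LabelError(f"record {ident!r}: no label in sidecar file")
            label = label_map[ident]
        records.append(PeptideRecord(ident, str(entry.seq).upper(), label))
    return LabeledDataset(records, name=name if name is not None else path.stem)


def read_acp_dl_pair(
    positive_path: str | Path, negative_path: str | Path, name: str = ""
) -> LabeledDataset:
    """Load an ACP-DL-style dataset split into a positive and a negative FASTA.

    Every entry in *positive_path* gets label 1, every entry in *negative_path*
    label 0; ids are taken from the headers (any ``|`` token is kept verbatim).
    """
    records: list[PeptideRecord] = []
    for p, label in ((positive_path, 1), (negative_path, 0)):
        for entry in SeqIO.parse(str(Path(p)), "fasta"):
            records.append(PeptideRecord(entry.id, str(entry.seq).upper(), label))
    return LabeledDataset(records, name=name)


def write_labeled_fasta(dataset: LabeledDataset, path: str | Path) -> None:
    """Write *dataset* with ``|label`` header suffixes; round-trips exactly."""
    ids = [r.id for r in dataset]
    if len(ids) != len(set(ids)):
        raise ValidationError("refusing to write dataset with duplicate ids")
    entries = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.label}", description="")
        for r in dataset
    ]
    SeqIO.write(entries, str(Path(path)), "fasta")


def _tilted_frequencies(favored: str, bias: float) -> np.ndarray:
    """Uniform residue frequencies multiplicatively tilted toward *favored*.

    bias=0 leaves the vector uniform; bias→1 concentrates all mass on the
    favored residues.  The multiplier is 1/(1-bias), renormalized.
    """
    weights = np.ones(20)
    idx = [RESIDUE_RANK[a] for a in favored]
    if bias >= 1.0:
        weights[:] = 0.0
        weights[idx] = 1.0
    else:
        weights[idx] *= 1.0 / (1.0 - bias)
    return weights / weights.sum()


def generate_synthetic_dataset(
    n_pos: int,
    n_neg: int,
    length_range: tuple[int, int] = (10, 40),
    class_bias: float = 0.5,
    seed: int = 0,
    name: str = "synthetic",
) -> LabeledDataset:
    """Generate a labeled synthetic peptide dataset.

    Positive sequences are drawn with residue frequencies tilted toward the
    cationic residues K/R/H by *class_bias*; negatives toward D/E/S/T.  With
    ``class_bias=0`` the two classes are exchangeable (uniform frequencies).
    Lengths are uniform on the closed interval *length_range*, which must lie
    within [5, 60].  Deterministic given *seed*.
    """
    lo, hi = length_range
    if not (5 <= lo <= hi <= 60):
        raise ValueError(f"length_range {length_range} must satisfy 5 <= lo <= hi <= 60")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= class_bias <= 1.0:
        raise ValueError("class_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    freq_pos = _tilted_frequencies(CATIONIC, class_bias)
    freq_neg = _tilted_frequencies(ANIONIC_POLAR, class_bias)
    alphabet = np.array(list(ALPHABET))
    records: list[PeptideRecord] = []
    for label, count, freq in ((1, n_pos, freq_pos), (0, n_neg, freq_neg)):
        tag = "pos" if label else "neg"
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(alphabet, size=length, p=freq))
            records.append(PeptideRecord(f"{tag}{i}", seq, label))
    return LabeledDataset(records, name=name)
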