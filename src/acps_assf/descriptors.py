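"""Peptide descriptor encoding: BPF, OPE, CKSAAGP, AAC and a positional
physicochemical-index feature reduced by mRMR.

Each peptide is represented by the concatenation of five descriptor segments
in a fixed order:

========  =====  ======================================================
segment   width  content
========  =====  ======================================================
BPF       140    one-hot of the first 7 residues (20 coordinates each)
OPE       40     ordinal positional code m*40+l over a length-40 window
CKSAAGP   150    k-spaced residue-group pair frequencies, k = 0..5
AAC       20     residue composition
AAIF      50     mRMR-selected positional physicochemical index values
========  =====  ======================================================

for a 400-dimensional vector.  The first two segments (180 coordinates) are
discrete position codes and are exempted from feature-space perturbation by
the augmentation module; the remaining 220 are real-valued.

Only the AAIF segment is data-dependent: the retained (index, position)
columns are chosen by greedy minimum-redundancy-maximum-relevance selection
on a training set, so the encoder must be fitted before use and the fitted
state can be serialized for reproducible train/test encoding.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import ALPHABET, RESIDUE_RANK, LabeledDataset

# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

BPF_POSITIONS = 7          # one-hot window: first 7 residues
OPE_LENGTH = 40            # length-standardized window for OPE and AAIF
CKSAAGP_KS = (0, 1, 2, 3, 4, 5)
PAD = "X"                  # padding symbol; never stored in records

#: Residue groups for CKSAAGP: aliphatic, aromatic, positively charged,
#: negatively charged, uncharged polar.
GROUPS = ("GAVLMI", "FYW", "KRH", "DE", "STCPNQ")
N_GROUPS = len(GROUPS)
GROUP_OF = {aa: gi for gi, g in enumerate(GROUPS) for aa in g}


@dataclasses.dataclass(frozen=True)
class FeatureLayout:
    """Named contiguous segments of the concatenated feature vector."""

    segments: tuple[tuple[str, int, int], ...]  # (name, offset, width)

    def __post_init__(self) -> None:
        offset = 0
        for name, off, width in self.segments:
            if off != offset or width <= 0:
                raise ValueError("segments must be contiguous and non-empty")
            offset += width

    @property
    def total_width(self) -> int:
        return sum(w for _, _, w in self.segments)

    def segment(self, name: str) -> slice:
        for seg_name, off, width in self.segments:
            if seg_name == name:
                return slice(off, off + width)
        raise KeyError(name)

    @property
    def widths(self) -> dict[str, int]:
        return {name: width for name, _, width in self.segments}

    @property
    def perturbable_mask(self) -> np.ndarray:
        """0/1 mask that is 0 on BPF and OPE, 1 on CKSAAGP, AAC and AAIF."""
        mask = np.ones(self.total_width)
        mask[self.segment("BPF")] = 0.0
        mask[self.segment("OPE")] = 0.0
        return mask


def make_layout(n_aaif: int = 50) -> FeatureLayout:
    return FeatureLayout(
        (
            ("BPF", 0, 20 * BPF_POSITIONS),
            ("OPE", 140, OPE_LENGTH),
            ("CKSAAGP", 180, 25 * len(CKSAAGP_KS)),
            ("AAC", 330, 20),
            ("AAIF", 350, n_aaif),
        )
    )


@dataclasses.dataclass
class FeatureVector:
    """A single encoded peptide with its layout and source record id."""

    values: np.ndarray
    layout: FeatureLayout
    source_id: str

    def segment(self, name: str) -> np.ndarray:
        return self.values[self.layout.segment(name)]


def as_matrix(vectors: Sequence[FeatureVector]) -> np.ndarray:
    return np.stack([v.values for v in vectors])


# ---------------------------------------------------------------------------
# Stateless encoders
# ---------------------------------------------------------------------------

def _validate(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    for ch in sequence:
        if ch not in RESIDUE_RANK:
            raise ValueError(f"non-standard residue {ch!r}")
    return sequence


def _standardize40(sequence: str) -> str:
    """Truncate to 40 residues or right-pad with X to length 40."""
    return sequence[:OPE_LENGTH].ljust(OPE_LENGTH, PAD)


def encode_bpf(sequence: str) -> np.ndarray:
    """One-hot encode the first 7 residues into 140 binary coordinates.

    Position i (0-based) and residue rank m set coordinate 20*i + m.
    Positions past the end of a short sequence stay all-zero.
    """
    _validate(sequence)
    out = np.zeros(20 * BPF_POSITIONS)
    for i, ch in enumerate(sequence[:BPF_POSITIONS]):
        out[20 * i + RESIDUE_RANK[ch]] = 1.0
    return out


def encode_ope(sequence: str) -> np.ndarray:
    """Ordinal positional encoding over a length-40 window.

    The residue of rank m at position l is coded m*40 + l; padding X is -1.
    """
    _validate(sequence)
    out = np.empty(OPE_LENGTH)
    for l, ch in enumerate(_standardize40(sequence)):
        out[l] = -1.0 if ch == PAD else RESIDUE_RANK[ch] * OPE_LENGTH + l
    return out


def encode_cksaagp(sequence: str, k_values: Sequence[int] = CKSAAGP_KS) -> np.ndarray:
    """k-spaced residue-group pair composition.

    For each gap k, the ordered pair (residue i, residue i+k+1) is mapped to
    its group pair; the 25 pair counts are divided by L-(k+1).  Blocks are
    ordered by ascending k, pairs by (G1,G1), (G1,G2) ... (G5,G5).  A block
    with L <= k+1 is all zeros.
    """
    _validate(sequence)
    L = len(sequence)
    groups = np.array([GROUP_OF[ch] for ch in sequence])
    out = np.zeros(N_GROUPS * N_GROUPS * len(k_values))
    for bi, k in enumerate(k_values):
        n_pairs = L - (k + 1)
        if n_pairs <= 0:
            continue
        block = np.zeros((N_GROUPS, N_GROUPS))
        np.add.at(block, (groups[: L - k - 1], groups[k + 1 :]), 1.0)
        out[bi * 25 : (bi + 1) * 25] = block.ravel() / n_pairs
    return out


def encode_aac(sequence: str) -> np.ndarray:
    """Residue composition: count of each of the 20 residues divided by L."""
    _validate(sequence)
    counts = np.zeros(20)
    for ch in sequence:
        counts[RESIDUE_RANK[ch]] += 1.0
    return counts / len(sequence)


# ---------------------------------------------------------------------------
# Physicochemical index table
# ---------------------------------------------------------------------------

_BUNDLED_TABLE = Path(__file__).parent / "data" / "physchem_scales.tsv"


@dataclasses.dataclass
class IndexTable:
    """A named collection of 20-value physicochemical scales.

    Each entry maps every standard residue to one real value (e.g. a
    hydropathy or volume scale).  Values are stored row-per-scale in
    alphabetical residue order.
    """

    names: list[str]
    values: np.ndarray  # (count, 20), residue columns in ALPHABET order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names), 20):
            raise ValueError("index table must be (count, 20)")
        if len(self.names) < 2:
            raise ValueError("index table needs at least 2 scales")

    @property
    def count(self) -> int:
        return len(self.names)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IndexTable":
        """Read a TSV with header 'scale<TAB>A<TAB>C...<TAB>Y' (any residue
        column order; columns are mapped by the header)."""
        lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
        header = lines[0].split("\t")
        residues = header[1:]
        if sorted(residues) != sorted(ALPHABET):
            raise ValueError("TSV header must name all 20 standard residues")
        order = [residues.index(aa) for aa in ALPHABET]
        names, rows = [], []
        for line in lines[1:]:
            parts = line.split("\t")
            names.append(parts[0])
            vals = np.array([float(v) for v in parts[1:]])
            rows.append(vals[order])
        return cls(names, np.stack(rows))

    @classmethod
    def from_aaindex_flat(cls, path: str | Path) -> "IndexTable":
        """Read AAindex1 flat-file format (H / I record lines).

        The I line lists residues as 'A/L R/K N/M ...'; the two following
        lines carry the values row-wise.  Entries with missing values ('NA')
        are skipped.
        """
        names, rows = [], []
        text = Path(path).read_text()
        for entry in text.split("//"):
            lines = entry.strip().splitlines()
            name, data_vals = None, []
            in_data = False
            for line in lines:
                if line.startswith("H "):
                    name = line[2:].strip()
                elif line.startswith("I "):
                    in_data = True
                elif in_data and line.startswith(" "):
                    data_vals.extend(line.split())
            if name is None or len(data_vals) != 20 or "NA" in data_vals:
                continue
            # AAindex I-line residue order, upper row then lower row:
            aaindex_order = "ARNDCQEGHILKMFPSTWYV"
            by_res = dict(zip(aaindex_order, (float(v) for v in data_vals)))
            rows.append(np.array([by_res[aa] for aa in ALPHABET]))
            names.append(name)
        return cls(names, np.stack(rows))

    @classmethod
    def bundled(cls) -> "IndexTable":
        """The packaged 22-scale physicochemical table."""
        return cls.from_tsv(_BUNDLED_TABLE)


def encode_aaindex_positional(sequence: str, table: IndexTable) -> np.ndarray:
    """Positional index values over the length-40 window, flattened index-major.

    Output coordinate j*40 + l holds the value of scale j for the residue at
    position l; padded positions hold 0.  Dimension is ``table.count * 40``
    (531 scales give the classic 21,240-wide raw feature).
    """
    _validate(sequence)
    std = _standardize40(sequence)
    cols = np.zeros((table.count, OPE_LENGTH))
    for l, ch in enumerate(std):
        if ch != PAD:
            cols[:, l] = table.values[:, RESIDUE_RANK[ch]]
    return cols.ravel()


# ---------------------------------------------------------------------------
# mRMR feature selection
# ---------------------------------------------------------------------------

class SelectionError(ValueError):
    """mRMR cannot run (e.g. constant label vector)."""


def _discretize_equal_frequency(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning via quantile edges; constant columns collapse
    to a single bin."""
    edges = np.quantile(column, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, column, side="left")


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats) between two small-cardinality integer codes."""
    nx, ny = int(x.max()) + 1, int(y.max()) + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny) / len(x)
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def _mi_rows(codes: np.ndarray, other: np.ndarray, nb: int, nb_other: int) -> np.ndarray:
    """MI of every row of *codes* with the single code vector *other*."""
    n_rows, n_samples = codes.shape
    cells = nb * nb_other
    flat = codes * nb_other + other[None, :]
    flat += (np.arange(n_rows) * cells)[:, None]
    joint = np.bincount(flat.ravel(), minlength=n_rows * cells)
    joint = joint.reshape(n_rows, nb, nb_other) / n_samples
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return np.where(joint > 0, terms, 0.0).sum(axis=(1, 2))


def mrmr_select(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    n_select: int,
    n_bins: int = 5,
) -> list[int]:
    """Greedy incremental mRMR (MID criterion) over discretized features.

    Each feature column is discretized into *n_bins* equal-frequency bins.
    The first selected column maximizes mutual information with the label;
    each subsequent pick maximizes MI(f; label) minus the mean MI(f; s) over
    the already-selected set.  Ties break toward the lowest column index.
    Returns exactly *n_select* column indices in selection order.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels)
    n_samples, n_features = X.shape
    if n_select > n_features:
        raise ValueError(f"n_select={n_select} exceeds {n_features} columns")
    if len(np.unique(y)) < 2:
        raise SelectionError("labels are constant; relevance is undefined")
    counts = np.bincount(y.astype(int))
    if counts.min() < 2:
        raise SelectionError("need at least 2 samples per class")

    codes = np.empty((n_features, n_samples), dtype=np.int64)
    for j in range(n_features):
        codes[j] = _discretize_equal_frequency(X[:, j], n_bins)
    y_codes = y.astype(np.int64)
    n_classes = int(y_codes.max()) + 1

    relevance = _mi_rows(codes, y_codes, n_bins, n_classes)
    selected: list[int] = []
    remaining = np.ones(n_features, dtype=bool)
    redundancy_sum = np.zeros(n_features)
    for step in range(n_select):
        if step == 0:
            score = relevance.copy()
        else:
            score = relevance - redundancy_sum / step
        score[~remaining] = -np.inf
        pick = int(np.argmax(score))  # argmax returns the lowest tied index
        selected.append(pick)
        remaining[pick] = False
        if step + 1 < n_select:
            redundancy_sum += _mi_rows(codes, codes[pick], n_bins, n_bins)
    return selected


# ---------------------------------------------------------------------------
# Fitted encoder
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EncoderState:
    """Frozen result of fitting the descriptor pipeline on a training set.

    Holds the retained AAIF columns as (scale index, position) pairs together
    with the scale values needed to encode unseen sequences, and the fixed
    :class:`FeatureLayout`.
    """

    layout: FeatureLayout
    table: IndexTable
    aaif_columns: list[tuple[int, int]]  # (scale index into table, position)

    def save(self, path: str | Path) -> None:
        payload = {
            "segments": [list(s) for s in self.layout.segments],
            "scale_names": self.table.names,
            "scale_values": self.table.values.tolist(),
            "aaif_columns": [list(c) for c in self.aaif_columns],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EncoderState":
        payload = json.loads(Path(path).read_text())
        return cls(
            layout=FeatureLayout(
                tuple(tuple(s) for s in payload["segments"])
            ),
            table=IndexTable(payload["scale_names"], np.array(payload["scale_values"])),
            aaif_columns=[tuple(c) for c in payload["aaif_columns"]],
        )

    def encode_sequence(self, sequence: str, source_id: str = "") -> FeatureVector:
        """Encode one sequence as the 140+40+150+20+n_aaif concatenation."""
        std = _standardize40(sequence)
        aaif = np.array(
            [
                0.0 if std[l] == PAD else self.table.values[j, RESIDUE_RANK[std[l]]]
                for j, l in self.aaif_columns
            ]
        )
        values = np.concatenate(
            [
                encode_bpf(sequence),
                encode_ope(sequence),
                encode_cksaagp(sequence),
                encode_aac(sequence),
                aaif,
            ]
        )
        return FeatureVector(values, self.layout, source_id)


def fit_encoder(
    train: LabeledDataset,
    table: IndexTable | None = None,
    n_aaif: int = 50,
    n_bins: int = 5,
) -> EncoderState:
    """Fit the descriptor pipeline on a training set.

    Computes the full positional index matrix on the training sequences, runs
    mRMR against the labels to retain *n_aaif* (scale, position) columns, and
    freezes the layout.  The fitted state is deterministic and reusable on
    unseen sequences.
    """
    if table is None:
        table = IndexTable.bundled()
    n_candidates = table.count * OPE_LENGTH
    if n_candidates < n_aaif:
        raise ValueError(
            f"{n_candidates} candidate index columns < n_aaif={n_aaif}"
        )
    matrix = np.stack(
        [encode_aaindex_positional(r.sequence, table) for r in train]
    )
    cols = mrmr_select(matrix, train.labels, n_select=n_aaif, n_bins=n_bins)
    aaif_columns = [(c // OPE_LENGTH, c % OPE_LENGTH) for c in cols]
    return EncoderState(make_layout(n_aaif), table, aaif_columns)


def encode_dataset(data: LabeledDataset, state: EncoderState) -> list[FeatureVector]:
    """Encode every record with a fitted state, preserving record order."""
    if not isinstance(state, EncoderState):
        raise TypeError("state must be a fitted EncoderState")
    return [state.encode_sequence(r.sequence, r.id) for r in data]
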