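"""K-mer decomposition of RNA sequences into frequency vectors.

A sequence of length m is slid over with a window of width k, giving the
m - k + 1 overlapping k-mers; counting their occurrences over the 4^k
possible words (k = 7 gives a 16,384-word vocabulary) turns each sequence
into a fixed-width numerical descriptor. Rows are normalised to relative
frequencies by default so that a 21-nt miRNA and a kilobase transcript live
on the same scale; similar sequences then have similar frequency profiles.

Columns are ordered lexicographically over A < C < G < U. Windows containing
N are dropped from counting but still consume a position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io_formats import SequenceRecord

__all__ = ["KmerConfig", "FrequencyMatrix", "enumerate_kmers", "split_kmers", "frequency_matrix"]

ALPHABET = ("A", "C", "G", "U")
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class KmerConfig:
    """k-mer counting configuration.

    k defaults to 7, within the 5-9 bp range typical of regulatory binding
    sites; the vocabulary has 4**k words. ``relative=False`` keeps raw counts.
    """

    k: int = 7
    relative: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def vocabulary_size(self) -> int:
        return 4**self.k


def enumerate_kmers(config: KmerConfig) -> dict[str, int]:
    """Bijective map k-mer string -> column index, lexicographic over A<C<G<U.

    For k = 7 this enumerates all 16,384 words, AAAAAAA at column 0 and
    UUUUUUU last.
    """
    k = config.k
    index: dict[str, int] = {}
    # lexicographic order == base-4 counting with digit order A,C,G,U
    for code in range(4**k):
        chars = []
        c = code
        for _ in range(k):
            chars.append(ALPHABET[c % 4])
            c //= 4
        index["".join(reversed(chars))] = code
    return index


def split_kmers(seq: SequenceRecord | str, config: KmerConfig) -> list[str]:
    """All m-k+1 overlapping windows of ``seq`` in 5'->3' order.

    Windows containing N are excluded from the returned list (they carry no
    countable word) but the positions they occupy are not shifted. A sequence
    shorter than k yields an empty list with a warning; the caller's row
    becomes all-zero.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    k = config.k
    if len(s) < k:
        name = seq.id if isinstance(seq, SequenceRecord) else "<anonymous>"
        warnings.warn(f"sequence {name!r} shorter than k={k}; no k-mers", stacklevel=2)
        return []
    return [s[i : i + k] for i in range(len(s) - k + 1) if "N" not in s[i : i + k]]


_LUT = np.full(256, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _LUT[ord(_b)] = _i


def _encode_windows(s: str, k: int) -> np.ndarray:
    """Integer codes of all valid (N-free) windows, vectorised."""
    if len(s) < k:
        return np.empty(0, dtype=np.int64)
    num = _LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(num, k)
    valid = (win >= 0).all(axis=1)  # -1 marks N
    return (np.where(win >= 0, win, 0) @ weights)[valid]


@dataclass
class FrequencyMatrix:
    """N x 4^k sparse matrix of per-sequence k-mer frequencies.

    Rows are ordered all miRNAs first, then all targets, preserving input
    order within each role. ``values`` is CSR; most of the 16,384 columns are
    zero for a 21-nt miRNA, so dense storage would be wasteful.
    """

    values: sp.csr_matrix
    row_ids: list[str]
    config: KmerConfig
    n_mirna: int
    zero_rows: list[str] = field(default_factory=list)

    @property
    def n_target(self) -> int:
        return len(self.row_ids) - self.n_mirna

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, i: int) -> np.ndarray:
        return np.asarray(self.values.getrow(i).todense()).ravel()

    def to_mtx(self, prefix: str | Path) -> None:
        """Export as MatrixMarket plus row/column label files."""
        from scipy.io import mmwrite

        prefix = Path(prefix)
        mmwrite(str(prefix) + ".mtx", self.values)
        with open(str(prefix) + ".rows.txt", "w") as fh:
            fh.write("\n".join(self.row_ids) + "\n")
        index = enumerate_kmers(self.config)
        kmers = sorted(index, key=index.get)
        with open(str(prefix) + ".cols.txt", "w") as fh:
            fh.write("\n".join(kmers) + "\n")


def frequency_matrix(
    records: list[SequenceRecord], config: KmerConfig | None = None
) -> FrequencyMatrix:
    """Count k-mers for every record and stack into the N x 4^k matrix.

    Each row holds the counts of each word divided by the record's number of
    valid windows (``config.relative=False`` skips the division). Rows with
    zero valid windows are all-zero and flagged in ``zero_rows``. Records must
    already be sorted miRNAs-then-targets by the caller; this function
    preserves input order and records where the role boundary falls.
    """
    if not records:
        raise ValueError("need at least one sequence record")
    config = config or KmerConfig()
    roles = [r.role for r in records]
    n_mirna = sum(1 for r in roles if r == "miRNA")
    if any(r == "miRNA" for r in roles[n_mirna:]):
        raise ValueError("records must be ordered: all miRNAs first, then all targets")

    k = config.k
    rows, cols, vals = [], [], []
    zero_rows: list[str] = []
    for i, rec in enumerate(records):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            codes = _encode_windows(rec.sequence, k)
        if codes.size == 0:
            warnings.warn(
                f"sequence {rec.id!r} has no valid k-mers (len {rec.length}, k={k})",
                stacklevel=2,
            )
            zero_rows.append(rec.id)
            continue
        uniq, counts = np.unique(codes, return_counts=True)
        weight = counts / codes.size if config.relative else counts.astype(float)
        rows.extend([i] * len(uniq))
        cols.extend(uniq.tolist())
        vals.extend(weight.tolist())
    values = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(records), config.vocabulary_size)
    )
    return FrequencyMatrix(
        values=values,
        row_ids=[r.id for r in records],
        config=config,
        n_mirna=n_mirna,
        zero_rows=zero_rows,
    )
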