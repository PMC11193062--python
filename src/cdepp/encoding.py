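"""One-hot encoding of aligned nucleotide sequences.

Each alignment column becomes a 4-channel vector (A, C, G, T; U folds to T).
Gaps and ambiguity codes are encoded as all-zeros so they contribute nothing
to the site-wise convolutions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EncodedAlignment", "one_hot_encode", "read_fasta"]

_CHANNEL = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass
class EncodedAlignment:
    """Labelled one-hot alignment of shape (n_taxa, length, 4)."""

    labels: tuple[str, ...]
    data: np.ndarray
    length: int

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if self.data.shape != (len(self.labels), self.length, 4):
            raise ValueError("encoded array shape mismatch")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def row(self, label: str) -> np.ndarray:
        return self.data[self._index[label]]

    def subset(self, labels) -> "EncodedAlignment":
        idx = [self._index[l] for l in labels]
        return EncodedAlignment(tuple(labels), self.data[idx], self.length)


def one_hot_encode(alignment) -> EncodedAlignment:
    """Encode a label->sequence mapping (or iterable of pairs).

    Sequences must share one length; characters outside {A,C,G,T,U} (gaps,
    N, ambiguity codes) map to the all-zeros vector.  Case-insensitive.
    """
    if hasattr(alignment, "items"):
        items = sorted(alignment.items())
    else:
        items = sorted(alignment)
    if not items:
        raise ValueError("empty alignment")
    labels = [lab for lab, _ in items]
    L = len(items[0][1])
    for lab, seq in items:
        if len(seq) != L:
            raise ValueError(
                f"unequal sequence lengths: {lab!r} has {len(seq)}, expected {L}"
            )
    data = np.zeros((len(items), L, 4), dtype=np.float32)
    for r, (_, seq) in enumerate(items):
        for c, ch in enumerate(seq.upper()):
            pos = _CHANNEL.get(ch)
            if pos is not None:
                data[r, c, pos] = 1.0
    return EncodedAlignment(tuple(labels), data, L)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered label->sequence dict."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for lab, seq in seqs.items():
            fh.write(f">{lab}\n{seq}\n")
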