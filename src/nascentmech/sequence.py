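"""DNA sequence utilities: encoding, reverse complement, FASTA I/O."""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
# A=0 C=1 G=2 T=3 N=4
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N to 0..4; any other letter is rejected."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"unsupported character {bad!r} in sequence (only ACGTN allowed)")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def random_sequence(length: int, rng: np.random.Generator, pi=None) -> str:
    """I.i.d. background sequence with base probabilities pi (default uniform)."""
    if pi is None:
        pi = np.full(4, 0.25)
    codes = rng.choice(4, size=length, p=np.asarray(pi, dtype=float))
    return decode(codes)
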