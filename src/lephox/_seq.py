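"""Low-level nucleotide/protein helpers shared across modules."""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = tuple(_standard.stop_codons)
SENSE_CODONS = tuple(sorted(c for c, a in CODON_TO_AA.items() if a != "*"))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

# aa -> synonymous codon list, sorted for reproducibility
SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    SYNONYMOUS.setdefault(CODON_TO_AA[_c], tuple())
SYNONYMOUS = {
    aa: tuple(sorted(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa))
    for aa in SYNONYMOUS
}

# 256-entry byte -> 2-bit code lookup; 255 marks non-ACGT
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes A=0 C=1 G=2 T=3, 255 = other."""
    return _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode()


def translate(seq: str) -> str:
    """Translate an in-frame DNA string; '*' for stops, 'X' for ambiguity."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aas.append(CODON_TO_AA.get(seq[i : i + 3].upper(), "X"))
    return "".join(aas)


def is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq_seqs(path) -> Iterator[str]:
    """Yield read sequences from a 4-line FASTQ file (plain or gzip)."""
    with open_maybe_gzip(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.rstrip()
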