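"""Residue and nucleotide alphabets, background frequencies, codon tables.

Amino acids are encoded 0..19 in the order ``ACDEFGHIKLMNPQRSTVWY``; 20 is
the ambiguity code X (scored as background, log-odds 0) and 21 is the stop
symbol ``*`` (never scored; six-frame segments are split at stops).
"""
from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}
X_CODE = 20
STOP_CODE = 21
N_AA = 20

# Robinson & Robinson amino-acid frequencies (the classic HMMER background),
# normalized to sum exactly to 1.
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


def robinson_background() -> np.ndarray:
    """Robinson-Robinson residue frequencies in AA_LETTERS order."""
    v = np.array([_RR[a] for a in AA_LETTERS], dtype=float)
    return v / v.sum()


def uniform_background() -> np.ndarray:
    return np.full(N_AA, 1.0 / N_AA)


# --- amino-acid string <-> code array -------------------------------------

_AA_ENCODE = np.full(256, X_CODE, dtype=np.uint8)
for _a, _i in AA_INDEX.items():
    _AA_ENCODE[ord(_a)] = _i
    _AA_ENCODE[ord(_a.lower())] = _i
_AA_ENCODE[ord("*")] = STOP_CODE

_AA_DECODE = np.frombuffer((AA_LETTERS + "X*").encode(), dtype=np.uint8)


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string; unknown letters map to X."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _AA_ENCODE[raw]


def decode_protein(codes: np.ndarray) -> str:
    return _AA_DECODE[codes].tobytes().decode("ascii")


# --- nucleotides ----------------------------------------------------------

NT_LETTERS = "ACGT"
_NT_ENCODE = np.full(256, 4, dtype=np.uint8)  # 4 = N / ambiguous
for _i, _b in enumerate(NT_LETTERS):
    _NT_ENCODE[ord(_b)] = _i
    _NT_ENCODE[ord(_b.lower())] = _i

_NT_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_RC_MAP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


def encode_nt(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _NT_ENCODE[raw]


def decode_nt(codes: np.ndarray) -> str:
    return _NT_DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _RC_MAP[codes[::-1]]


def reverse_complement(seq: str) -> str:
    return decode_nt(revcomp_codes(encode_nt(seq)))


def codon_aa_table(code_id: int = 1) -> np.ndarray:
    """64-entry codon-index -> residue-code lookup for an NCBI genetic code.

    Codon index is 16*a + 4*b + c over the ACGT encoding; stops map to
    STOP_CODE.
    """
    table = CodonTable.unambiguous_dna_by_id[code_id]
    out = np.full(64, X_CODE, dtype=np.uint8)
    for i, b1 in enumerate(NT_LETTERS):
        for j, b2 in enumerate(NT_LETTERS):
            for k, b3 in enumerate(NT_LETTERS):
                codon = b1 + b2 + b3
                idx = 16 * i + 4 * j + k
                if codon in table.stop_codons:
                    out[idx] = STOP_CODE
                else:
                    out[idx] = AA_INDEX[table.forward_table[codon]]
    return out


def synonymous_codons(code_id: int = 1) -> dict[str, list[str]]:
    """Residue letter -> list of codons encoding it (for back-translation)."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    out: dict[str, list[str]] = {a: [] for a in AA_LETTERS}
    for codon, aa in table.forward_table.items():
        if set(codon) <= set(NT_LETTERS):
            out[aa].append(codon)
    for aa in out:
        out[aa].sort()
    return out


def stop_codons(code_id: int = 1) -> list[str]:
    return list(CodonTable.unambiguous_dna_by_id[code_id].stop_codons)
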