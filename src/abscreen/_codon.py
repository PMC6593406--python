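"""Low-level nucleotide/peptide encoding helpers shared by the search engine
and the read simulator.

Sequences are held as small unsigned-integer code arrays so that batch
translation and k-mer hashing stay vectorised.  Base codes are 0..3 for
``ACGT`` and 4 for anything else (``N`` etc.).  Amino-acid codes index into
:data:`AA_ALPHABET`; ``X`` (unknown) and ``*`` (stop) are ordinary codes so
translated frames never need special-casing.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

DNA_BASES = "ACGT"
N_CODE = 4

#: Canonical amino-acid alphabet used internally: 20 residues, X, stop.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
AA_CODE = {aa: i for i, aa in enumerate(AA_ALPHABET)}
X_CODE = AA_CODE["X"]
STOP_CODE = AA_CODE["*"]

_BASE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i

_AA_BYTES = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)

# Standard genetic code (table 1).  Code 11 (bacterial) differs only in the
# set of alternative start codons, which local alignment never consults.
_STANDARD = unambiguous_dna_by_id[1]
CODON_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_AA[_stop] = "*"

# Codon lookup in base-5 index space (25*a + 5*b + c); any codon containing a
# non-ACGT base translates to X.
_CODON_LUT = np.full(125, X_CODE, dtype=np.uint8)
for _codon, _aa in CODON_AA.items():
    _a, _b, _c = (_BASE_LUT[ord(ch)] for ch in _codon)
    _CODON_LUT[25 * int(_a) + 5 * int(_b) + int(_c)] = AA_CODE[_aa]

_COMPLEMENT_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_dna(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array (non-ACGT -> 4)."""
    return _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_dna(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on code arrays; works on 1-D or 2-D (per-row)."""
    comp = np.where(codes < 4, 3 - codes, np.uint8(N_CODE)).astype(np.uint8)
    return comp[..., ::-1]


def translate_codes(codes: np.ndarray) -> np.ndarray:
    """Translate encoded nucleotides (1-D or 2-D, frame already applied).

    Trailing bases that do not fill a codon are ignored.  Any codon with a
    non-ACGT base yields ``X``.
    """
    n_codons = codes.shape[-1] // 3
    if n_codons == 0:
        return np.empty(codes.shape[:-1] + (0,), dtype=np.uint8)
    trimmed = codes[..., : 3 * n_codons]
    a = trimmed[..., 0::3].astype(np.int16)
    b = trimmed[..., 1::3].astype(np.int16)
    c = trimmed[..., 2::3].astype(np.int16)
    idx = 25 * a + 5 * b + c
    valid = (a < 4) & (b < 4) & (c < 4)
    idx = np.where(valid, idx, 0)
    out = np.where(valid, _CODON_LUT[idx], np.uint8(X_CODE))
    return out.astype(np.uint8)


def aa_codes_to_str(codes: np.ndarray) -> str:
    return _AA_BYTES[codes].tobytes().decode()


def encode_peptide(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, aa in enumerate(seq):
        out[i] = AA_CODE.get(aa, X_CODE)
    return out
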