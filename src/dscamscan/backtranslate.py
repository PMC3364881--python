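"""Codon-aware back-translation of protein alignments.

Each aligned residue column is replaced by its source codon from the
supplied CDS; alignment gaps become ``---``. The CDS must translate exactly
to the ungapped protein under the standard genetic code (a trailing stop
codon is tolerated), so the codon alignment is always 3x the protein
alignment length.
"""
from __future__ import annotations

from typing import Mapping, Sequence

from Bio.Seq import Seq

from .errors import ValidationError

_GAPS = ("-", ".")


def back_translate(alignment: Sequence[tuple[str, str]],
                   cds: Mapping[str, str]) -> list[tuple[str, str]]:
    out = []
    for sid, row in alignment:
        if sid not in cds:
            raise ValidationError(f"missing CDS for '{sid}'")
        nt = cds[sid].upper().replace("U", "T")
        protein = "".join(c for c in row if c not in _GAPS).upper()
        if len(nt) == 3 * (len(protein) + 1):
            tail = str(Seq(nt[-3:]).translate())
            if tail == "*":
                nt = nt[:-3]
        if len(nt) != 3 * len(protein):
            raise ValidationError(
                f"CDS length for '{sid}' is {len(nt)} nt, expected "
                f"{3 * len(protein)} for {len(protein)} residues")
        translated = str(Seq(nt).translate())
        for pos, (a, b) in enumerate(zip(translated, protein), start=1):
            if a != b and a != "X" and b != "X":
                raise ValidationError(
                    f"CDS/protein mismatch for '{sid}' at position {pos}: "
                    f"codon encodes {a}, alignment has {b}")
        codons = []
        k = 0
        for c in row:
            if c in _GAPS:
                codons.append("---")
            else:
                codons.append(nt[3 * k:3 * k + 3])
                k += 1
        out.append((sid, "".join(codons)))
    return out
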