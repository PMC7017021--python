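"""Fourfold-degenerate codon families derived from the standard genetic code."""

from __future__ import annotations

from Bio.Data import CodonTable

from .seq import NUCLEOTIDES

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _fourfold_families() -> dict:
    """Map codon-family prefix (first two bases) -> amino acid, for the
    families in which every third-position nucleotide is synonymous."""
    fams = {}
    for b1 in NUCLEOTIDES:
        for b2 in NUCLEOTIDES:
            aas = set()
            ok = True
            for b3 in NUCLEOTIDES:
                codon = b1 + b2 + b3
                if codon in _STANDARD.stop_codons:
                    ok = False
                    break
                aas.add(_STANDARD.forward_table[codon])
            if ok and len(aas) == 1:
                fams[b1 + b2] = aas.pop()
    return fams


#: prefix -> amino acid for the eight fourfold families
#: (Ala GCN, Gly GGN, Leu CTN, Pro CCN, Thr ACN, Val GTN, Ser TCN, Arg CGN)
FOURFOLD_FAMILIES = _fourfold_families()

#: all 32 fourfold-degenerate codons
FOURFOLD_CODONS = frozenset(
    pre + b3 for pre in FOURFOLD_FAMILIES for b3 in NUCLEOTIDES
)


def is_fourfold(codon: str) -> bool:
    """True when the codon's third position is fully degenerate."""
    return codon.upper() in FOURFOLD_CODONS
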