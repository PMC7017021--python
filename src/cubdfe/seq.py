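"""Small nucleotide-sequence helpers: complements and the strand-blind
canonical form of a 3-bp mutational context.

Two sites are considered context-compatible when their (context, derived
state) pairs coincide under any of the four strand-blind transforms:
identity, reverse, complement, reverse complement. These form a closed
group, so compatibility is equivalent to equality of canonical forms.
"""

from __future__ import annotations

from functools import lru_cache

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

NUCLEOTIDES = ("A", "C", "G", "T")


def comp(seq: str) -> str:
    """Complement (not reversed)."""
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def context_orbit(context3: str, derived: str | None = None):
    """The four strand-blind images of a (3-bp context, derived allele) pair."""
    d = derived or ""
    return (
        (context3, d),
        (context3[::-1], d),
        (comp(context3), comp(d)),
        (revcomp(context3), comp(d)),
    )


@lru_cache(maxsize=4096)
def canonical_context(context3: str, derived: str | None = None) -> str:
    """Lexicographically minimal strand-blind representation.

    The derived allele (when given) is transformed together with the
    context, so polymorphic states match only when the base change is the
    same up to strand.
    """
    return min(f"{c}|{d}" if d else c for c, d in context_orbit(context3, derived))
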