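"""IUPAC nucleotide-code helpers for single-SNP GBS genotype calls.

Calls live in the alphabet {A, C, G, T} for homozygotes, the six two-base
ambiguity codes {M, R, W, S, Y, K} for heterozygotes, and ``NA`` for missing.
"""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values

NUCLEOTIDES = frozenset("ACGT")

#: the six two-base ambiguity codes (heterozygote calls)
HET_CODES = frozenset(
    code
    for code, bases in ambiguous_dna_values.items()
    if len(bases) == 2
)

MISSING = "NA"

#: frozenset of allele pair -> heterozygote code, e.g. {A,G} -> R
_PAIR_TO_HET = {
    frozenset(ambiguous_dna_values[code]): code for code in HET_CODES
}

#: heterozygote code -> tuple of its two bases
HET_TO_PAIR = {code: tuple(sorted(ambiguous_dna_values[code])) for code in HET_CODES}

CALL_ALPHABET = NUCLEOTIDES | HET_CODES | {MISSING}


def het_code(allele1: str, allele2: str) -> str:
    """Return the IUPAC ambiguity code for a heterozygous allele pair."""
    pair = frozenset((allele1, allele2))
    if len(pair) != 2 or not pair <= NUCLEOTIDES:
        raise ValueError(f"not a heterozygous nucleotide pair: {allele1}/{allele2}")
    return _PAIR_TO_HET[pair]


def is_het(call: str) -> bool:
    return call in HET_CODES


def is_nucleotide(call: str) -> bool:
    return call in NUCLEOTIDES
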