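"""Codon state space for protein-coding sequence models.

The model state space is the set of sense codons under a named genetic code
(61 codons for the universal code); stop codons are excluded.  Precomputed
integer tables describe, for every ordered codon pair, whether the pair
differs at exactly one nucleotide position and, if so, whether that change
is a transition and whether it is synonymous.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@lru_cache(maxsize=None)
def sense_codons(code: str = "universal") -> tuple[str, ...]:
    """Sense codons (alphabetical order) under the named genetic code."""
    table = _codon_table(code)
    all_codons = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    return tuple(c for c in all_codons if c not in table.stop_codons)


@lru_cache(maxsize=None)
def _codon_table(code: str):
    name = {"universal": "Standard"}.get(code, code)
    return CodonTable.unambiguous_dna_by_name[name]


@lru_cache(maxsize=None)
def codon_index(code: str = "universal") -> dict[str, int]:
    return {c: i for i, c in enumerate(sense_codons(code))}


@lru_cache(maxsize=None)
def amino_acids(code: str = "universal") -> tuple[str, ...]:
    table = _codon_table(code)
    return tuple(table.forward_table[c] for c in sense_codons(code))


@lru_cache(maxsize=None)
def change_tables(code: str = "universal"):
    """(single, transition, synonymous) boolean matrices over codon pairs.

    ``single[i, j]`` is True when codons i and j differ at exactly one
    position; the other two matrices are only meaningful where ``single``
    holds.
    """
    codons = sense_codons(code)
    aa = amino_acids(code)
    n = len(codons)
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    synonymous = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(codons[i], codons[j]) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = diffs[0] in _TRANSITIONS
            synonymous[i, j] = aa[i] == aa[j]
    return single, transition, synonymous


def is_stop(codon: str, code: str = "universal") -> bool:
    return codon in _codon_table(code).stop_codons
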