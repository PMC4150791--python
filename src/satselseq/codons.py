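"""Genetic-code arithmetic for saturation-mutagenesis library design.

Degenerate codon expansion (IUPAC nucleotide codes), standard-code
translation, composition of the NNS library (any base at positions 1-2,
C/G at position 3), and synonymous-codon enumeration used to pick silent
positional barcodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

STOP = "*"

#: 20 amino acids plus the stop symbol, the 21-category symbol space used
#: throughout frequency vectors and logos.
AA_SYMBOLS: tuple[str, ...] = tuple(sorted(set(standard_dna_table.forward_table.values()))) + (STOP,)

#: All 64 codons in lexicographic order.
CODONS: tuple[str, ...] = tuple("".join(c) for c in itertools.product("ACGT", repeat=3))

_FORWARD = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _FORWARD[_stop] = STOP

#: Codons considered rare in E. coli. Used for annotation/reporting only,
#: never for filtering; the cutoff for "rare" is a convention and the list
#: is overridable wherever it is consumed.
RARE_CODONS_ECOLI: frozenset[str] = frozenset({"AGG", "AGA", "CGA", "CTA", "ATA", "CCC"})


class InvalidCodonError(ValueError):
    """Raised for malformed codons or degenerate patterns."""


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise InvalidCodonError(
            f"codon must be 3 bases over A/C/G/T, got {codon!r}"
        )
    return codon


def expand_degenerate(pattern: str) -> set[str]:
    """Expand a 3-symbol IUPAC degenerate codon into its codon set.

    The result is the Cartesian product of the three per-symbol base sets,
    e.g. ``"NNS"`` → 32 codons, ``"WRC"`` → {AAC, AGC, TAC, TGC}.
    """
    if len(pattern) != 3:
        raise InvalidCodonError(f"degenerate pattern must have 3 symbols, got {pattern!r}")
    sets = []
    for sym in pattern.upper():
        # Biopython's table also carries the non-IUPAC catch-all "X"
        if sym == "X" or sym not in ambiguous_dna_values:
            raise InvalidCodonError(f"invalid IUPAC nucleotide symbol {sym!r} in {pattern!r}")
        sets.append(ambiguous_dna_values[sym])
    return {"".join(bases) for bases in itertools.product(*sets)}


def translate(codon: str) -> str:
    """Translate an unambiguous codon with the standard genetic code.

    Returns the one-letter amino acid, or ``"*"`` for a stop codon.
    """
    return _FORWARD[_check_codon(codon.upper())]


def synonymous_codons(codon: str) -> set[str]:
    """All codons other than *codon* encoding the same amino acid (or stop).

    May be empty (Met, Trp have a single codon).
    """
    aa = translate(codon)
    codon = codon.upper()
    return {c for c in CODONS if _FORWARD[c] == aa and c != codon}


@dataclass(frozen=True)
class CodonComposition:
    """Codons of a degenerate library grouped by what they encode."""

    entries: dict[str, frozenset[str]]
    aa_count: int = field(init=False)
    stop_count: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "aa_count", sum(1 for aa in self.entries if aa != STOP))
        object.__setattr__(self, "stop_count", len(self.entries.get(STOP, frozenset())))

    @property
    def n_codons(self) -> int:
        return sum(len(s) for s in self.entries.values())

    def to_records(self) -> list[dict]:
        """Long-format records (symbol, codon, rare flag) for TSV export."""
        rows = []
        for aa in sorted(self.entries):
            for codon in sorted(self.entries[aa]):
                rows.append(
                    {"symbol": aa, "codon": codon, "rare_ecoli": codon in RARE_CODONS_ECOLI}
                )
        return rows


def composition(pattern: str) -> CodonComposition:
    """Group the expansion of a degenerate codon by encoded symbol."""
    groups: dict[str, set[str]] = {}
    for codon in expand_degenerate(pattern):
        groups.setdefault(_FORWARD[codon], set()).add(codon)
    return CodonComposition({aa: frozenset(s) for aa, s in groups.items()})


def nns_composition() -> CodonComposition:
    """Composition of the 32-codon NNS expansion.

    NNS covers all 20 amino acids with a single stop codon (TAG); Arg is
    the most redundant residue with three codons (CGC, CGG, AGG).
    """
    return composition("NNS")
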