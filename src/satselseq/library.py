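"""Positional saturation-library design over a reference amplicon.

Each positional library randomizes one loop codon with an NNS degenerate
codon and marks the diversified position with a silent (synonymous) codon
substitution — the positional barcode — immediately 3' of it, so that
pooled amplicon reads can be assigned back to the library they came from.
A covariation library enumerates the Cartesian product of per-position
amino-acid choice sets.

Coordinates are 0-based half-open internally; residue numbers are 1-based
at the interface (hotspot-loop residues 113-123).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import CODONS, InvalidCodonError, expand_degenerate, synonymous_codons, translate

NNS_CODONS: frozenset[str] = frozenset(expand_degenerate("NNS"))

#: Hotspot-recognition loop, residues 113-123 (Leu113..Pro123).
LOOP_PROTEIN = "LYFCEDRKAEP"
LOOP_FIRST_RESIDUE = 113
LOOP_LAST_RESIDUE = 123


class DesignError(ValueError):
    """Raised when a requested library design cannot be realized."""


@dataclass(frozen=True)
class ReferenceAmplicon:
    """The amplified coding window of the deaminase gene.

    The default fixture mimics the real amplicon geometry (99 codons
    covering residues 71-169, i.e. CDS nt 211-507) but carries a synthetic
    coding sequence outside the loop: only the loop residues 113-123 and
    the amplicon frame are meaningful, the flanks are deterministic
    filler. Wild-type codons at barcode slots are chosen so that each
    admits a synonymous variant with third base A or T, i.e. outside the
    NNS codon space, which keeps positional barcodes unambiguous against
    the randomized codon of the neighbouring library.
    """

    cds_window: str
    frame_offset: int = 0
    residue_of_first_codon: int = 71

    def __post_init__(self) -> None:
        if (len(self.cds_window) - self.frame_offset) < 3:
            raise DesignError("amplicon shorter than one codon")
        if any(b not in "ACGT" for b in self.cds_window):
            raise DesignError("amplicon must be uppercase unambiguous DNA")

    @property
    def n_codons(self) -> int:
        return (len(self.cds_window) - self.frame_offset) // 3

    @property
    def last_residue(self) -> int:
        return self.residue_of_first_codon + self.n_codons - 1

    def codon_start(self, residue_index: int) -> int:
        """0-based offset of a residue's codon within the amplicon."""
        if not (self.residue_of_first_codon <= residue_index <= self.last_residue):
            raise DesignError(
                f"residue {residue_index} outside amplicon "
                f"({self.residue_of_first_codon}-{self.last_residue})"
            )
        return self.frame_offset + 3 * (residue_index - self.residue_of_first_codon)

    def codon(self, residue_index: int) -> str:
        start = self.codon_start(residue_index)
        return self.cds_window[start : start + 3]

    def protein(self) -> str:
        return "".join(
            translate(self.cds_window[i : i + 3])
            for i in range(self.frame_offset, self.frame_offset + 3 * self.n_codons, 3)
        )


# Codon choices for the default fixture. Filler codons are common E. coli
# codons; barcode-slot codons (loop + residue 124) use the C/G-ending
# synonym so the silent barcode can take the A/T-ending one.
_FILLER_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGC",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}
_LOOP_CODONS = ("CTG", "TAC", "TTC", "TGC", "GAG", "GAC", "CGC", "AAG", "GCG", "GAG", "CCG")
_FLANK5_PROTEIN = ("SVTDKGQNAHELRIP" * 3)[:42]   # residues 71-112
_FLANK3_PROTEIN = ("TQVNSDHKGAELRIP" * 3)[:45]   # residues 125-169


def default_reference() -> ReferenceAmplicon:
    """Deterministic synthetic amplicon fixture (99 codons, residues 71-169)."""
    seq = (
        "".join(_FILLER_CODON[aa] for aa in _FLANK5_PROTEIN)
        + "".join(_LOOP_CODONS)
        + "GGC"  # residue 124, barcode slot of the Pro123 library
        + "".join(_FILLER_CODON[aa] for aa in _FLANK3_PROTEIN)
    )
    return ReferenceAmplicon(cds_window=seq)


@dataclass(frozen=True)
class PositionalLibrary:
    """One saturation library: NNS site plus silent positional barcode."""

    library_id: str
    residue_index: int
    nns_codon_start: int
    barcode_codon_start: int
    wt_barcode_codon: str
    barcode_codon: str

    def __post_init__(self) -> None:
        if self.barcode_codon == self.wt_barcode_codon:
            raise DesignError("barcode codon must differ from wild type")
        if translate(self.barcode_codon) != translate(self.wt_barcode_codon):
            raise DesignError("barcode codon must be synonymous with wild type")

    @property
    def signature(self) -> tuple[int, str]:
        """(barcode offset, barcode codon) — what the decoder matches."""
        return (self.barcode_codon_start, self.barcode_codon)


def _barcode_candidates(wt_codon: str) -> list[str]:
    """Synonyms ranked: max Hamming distance from wild type, alphabetical ties."""
    def hamming(c: str) -> int:
        return sum(a != b for a, b in zip(c, wt_codon))

    return sorted(synonymous_codons(wt_codon), key=lambda c: (-hamming(c), c))


def design_positional_library(
    ref: ReferenceAmplicon,
    residue_index: int,
    barcode_rule: int = 0,
    barcode_residue: int | None = None,
    library_id: str | None = None,
) -> PositionalLibrary:
    """Design one positional library.

    ``barcode_rule`` is a rank into the synonym candidate list (max Hamming
    distance from wild type, alphabetical tie-break); distinct ranks give
    duplicate libraries at the same position different silent barcodes.
    ``barcode_residue`` overrides the default slot immediately 3' of the
    NNS codon — needed when that neighbour is Met or Trp (no synonym).
    """
    nns_start = ref.codon_start(residue_index)
    slot_residue = barcode_residue if barcode_residue is not None else residue_index + 1
    slot_start = ref.codon_start(slot_residue)
    wt_codon = ref.codon(slot_residue)
    candidates = _barcode_candidates(wt_codon)
    if not candidates:
        raise DesignError(
            f"barcode slot residue {slot_residue} ({translate(wt_codon)}) has no "
            "synonymous codon; override the barcode offset with barcode_residue="
        )
    if barcode_rule >= len(candidates):
        raise DesignError(
            f"barcode_rule={barcode_rule} exhausts the {len(candidates)} synonym(s) "
            f"of {wt_codon} at residue {slot_residue}"
        )
    return PositionalLibrary(
        library_id=library_id or str(residue_index),
        residue_index=residue_index,
        nns_codon_start=nns_start,
        barcode_codon_start=slot_start,
        wt_barcode_codon=wt_codon,
        barcode_codon=candidates[barcode_rule],
    )


def _signature_safe(
    slot_residue: int,
    codon: str,
    taken: set[tuple[int, str]],
    nns_residues: set[int],
    ref: ReferenceAmplicon,
) -> bool:
    # A barcode must be a unique (slot, codon) signature, and must not be an
    # NNS-space codon at a slot that is another library's randomized codon —
    # otherwise a legitimate NNS read from that library mimics this barcode.
    if (ref.codon_start(slot_residue), codon) in taken:
        return False
    if slot_residue in nns_residues and codon in NNS_CODONS:
        return False
    return True


def build_library_panel(
    ref: ReferenceAmplicon,
    residues: range | list[int] | None = None,
    duplicates: dict[int, int] | None = None,
    allow_offset_override: bool = True,
) -> list[PositionalLibrary]:
    """One library per loop residue plus requested duplicates.

    Defaults reproduce the 12-library panel: one library for each hotspot
    loop position 113-123 and a duplicate at Phe115 with a different silent
    barcode. Duplicate barcodes exhaust further synonym ranks at the default
    slot, then (if ``allow_offset_override``) advance the slot downstream to
    the first residue offering a safe unused synonym.
    """
    if residues is None:
        residues = range(LOOP_FIRST_RESIDUE, LOOP_LAST_RESIDUE + 1)
    residues = list(residues)
    if duplicates is None:
        duplicates = {115: 1} if 115 in residues else {}
    nns_residues = set(residues)
    taken: set[tuple[int, str]] = set()
    libraries: list[PositionalLibrary] = []

    def add(residue: int, library_id: str) -> None:
        slot = residue + 1
        while slot <= ref.last_residue:
            wt = ref.codon(slot)
            for codon in _barcode_candidates(wt):
                if _signature_safe(slot, codon, taken, nns_residues, ref):
                    lib = PositionalLibrary(
                        library_id=library_id,
                        residue_index=residue,
                        nns_codon_start=ref.codon_start(residue),
                        barcode_codon_start=ref.codon_start(slot),
                        wt_barcode_codon=wt,
                        barcode_codon=codon,
                    )
                    taken.add(lib.signature)
                    libraries.append(lib)
                    return
            if not allow_offset_override:
                raise DesignError(
                    f"no distinct silent barcode available at residue {slot} for a "
                    f"duplicate library at {residue} (offset override disabled)"
                )
            slot += 1
        raise DesignError(f"no usable barcode slot downstream of residue {residue}")

# base libraries first so each keeps the slot immediately 3' of its NNS
    # codon; duplicates are designed afterwards and absorb any offset override
    for residue in residues:
        add(residue, f"{residue}a" if duplicates.get(residue) else str(residue))
    for residue in residues:
        for k in range(1, duplicates.get(residue, 0) + 1):
            add(residue, f"{residue}{chr(ord('a') + k)}")
    libraries.sort(key=lambda lib: (lib.residue_index, lib.library_id))

    sigs = [lib.signature for lib in libraries]
    if len(set(sigs)) != len(sigs):
        raise DesignError("barcode collision across libraries")
    return libraries


def library_reference(ref: ReferenceAmplicon, lib: PositionalLibrary) -> str:
    """The library's amplicon with its silent barcode applied (NNS slot = WT)."""
    s = lib.barcode_codon_start
    return ref.cds_window[:s] + lib.barcode_codon + ref.cds_window[s + 3 :]


# ---------------------------------------------------------------------------
# Covariation library
# ---------------------------------------------------------------------------

#: Per-position amino-acid choice sets for the covariation library: the
#: wild-type residue at every loop position plus every mutant that exceeded
#: 20% of final-generation counts (F115 F/Y; E117 E/T; D118 D/A/R/P;
#: R119 R/G; K120 K/R; A121 A/R/P; P123 P/R). 384 variants total.
DEFAULT_COVARIATION_SETS: tuple[tuple[int, frozenset[str]], ...] = (
    (113, frozenset("L")),
    (114, frozenset("Y")),
    (115, frozenset("FY")),
    (116, frozenset("C")),
    (117, frozenset("ET")),
    (118, frozenset("DARP")),
    (119, frozenset("RG")),
    (120, frozenset("KR")),
    (121, frozenset("ARP")),
    (122, frozenset("E")),
    (123, frozenset("PR")),
)


@dataclass(frozen=True)
class CovariationSpec:
    """Ordered per-position amino-acid choice sets (wild type always included)."""

    choice_sets: tuple[tuple[int, frozenset[str]], ...] = DEFAULT_COVARIATION_SETS

    def __post_init__(self) -> None:
        for residue, choices in self.choice_sets:
            if not choices:
                raise DesignError(f"empty choice set at residue {residue}")

    @property
    def n_variants(self) -> int:
        return int(np.prod([len(c) for _, c in self.choice_sets]))


def enumerate_covariation(spec: CovariationSpec | None = None) -> list[str]:
    """Full Cartesian product of the choice sets, lexicographic order."""
    spec = spec or CovariationSpec()
    ordered = [sorted(choices) for _, choices in spec.choice_sets]
    return ["".join(combo) for combo in itertools.product(*ordered)]


@dataclass(frozen=True)
class PoolingPlan:
    """Relative pooling amounts for covariation sublibraries."""

    sublibrary_sizes: tuple[int, ...]
    pool_ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sublibrary_sizes) != len(self.pool_ratios):
            raise DesignError("sizes and ratios must have equal length")
        if any(s <= 0 for s in self.sublibrary_sizes) or any(r <= 0 for r in self.pool_ratios):
            raise DesignError("sizes and ratios must be positive")


#: Eight sublibraries pooled 2:2:2:2:1:1:1:1 so that all 384 covariation
#: members end up equally represented (sizes inferred from that equality).
DEFAULT_POOLING = PoolingPlan((64, 64, 64, 64, 32, 32, 32, 32), (2, 2, 2, 2, 1, 1, 1, 1))


def pooling_shares(plan: PoolingPlan) -> np.ndarray:
    """Per-member share of the pooled library, one entry per member.

    A sublibrary of ``size`` members pooled at relative amount ``ratio``
    contributes ``ratio/size`` per member; shares are normalized to sum 1.
    """
    raw = np.concatenate(
        [np.full(size, ratio / size) for size, ratio in zip(plan.sublibrary_sizes, plan.pool_ratios)]
    )
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def panel_manifest(libraries: list[PositionalLibrary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "library_id": lib.library_id,
                "residue_index": lib.residue_index,
                "nns_codon_start": lib.nns_codon_start,
                "barcode_codon_start": lib.barcode_codon_start,
                "wt_barcode_codon": lib.wt_barcode_codon,
                "barcode_codon": lib.barcode_codon,
            }
            for lib in libraries
        ]
    )


def write_manifest(libraries: list[PositionalLibrary], path) -> None:
    panel_manifest(libraries).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> list[PositionalLibrary]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"library_id": str})
    return [
        PositionalLibrary(
            library_id=row.library_id,
            residue_index=int(row.residue_index),
            nns_codon_start=int(row.nns_codon_start),
            barcode_codon_start=int(row.barcode_codon_start),
            wt_barcode_codon=row.wt_barcode_codon,
            barcode_codon=row.barcode_codon,
        )
        for row in df.itertuples()
    ]


def write_panel_fasta(ref: ReferenceAmplicon, libraries: list[PositionalLibrary], path) -> None:
    """FASTA of per-library reference amplicons (silent barcode applied)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(library_reference(ref, lib)),
            id=lib.library_id,
            description=f"residue={lib.residue_index} barcode={lib.barcode_codon}",
        )
        for lib in libraries
    ]
    seqio_write(records, path, "fasta")


def write_covariation_fasta(variants: list[str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(v), id=f"cv{i:04d}", description="") for i, v in enumerate(variants)
    ]
    seqio_write(records, path, "fasta")
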