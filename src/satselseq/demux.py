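"""Read filtering, dual-barcode decoding and codon tabulation.

Amplicon reads carry, 5'→3': a constant sequencing leader, an 8-bp
generational barcode identifying the selection cycle (G0-G3), a constant
12-bp anchor (the amplification touchdown sequence), and the amplicon
payload. Decoding is anchored — the payload is located at a fixed offset
after an exact anchor match, so no alignment is performed; substitution
errors are the only noise handled (indel-producing reads fail the anchor
or barcode match and are rejected).

A read is accepted only if it has a recognized generational barcode and
exactly one positional (silent codon) barcode; the codon at the accepted
library's randomized slot is then tabulated, and mismatches outside the
randomized codon and all barcode slots are tracked to estimate the
off-target substitution rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import CODONS
from .library import NNS_CODONS, PositionalLibrary, ReferenceAmplicon

DEFAULT_LEADER = "TCAG"
DEFAULT_ANCHOR = "GTCACGCTAGGA"

#: Default generational barcodes, pairwise Hamming distance 8.
DEFAULT_GENERATION_BARCODES: dict[str, str] = {
    "G0": "AACCGGTT",
    "G1": "CCAATTGG",
    "G2": "GGTTAACC",
    "G3": "TTGGCCAA",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class GenerationBarcodeSet:
    """Generation label → barcode map plus the constant read scaffold."""

    barcodes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GENERATION_BARCODES))
    leader: str = DEFAULT_LEADER
    anchor: str = DEFAULT_ANCHOR

    def __post_init__(self) -> None:
        seqs = list(self.barcodes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("generation barcodes must be unique")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("generation barcodes must have equal length")
        pairs = [(a, b) for i, a in enumerate(seqs) for b in seqs[i + 1 :]]
        if any(_hamming(a, b) < 2 for a, b in pairs):
            warnings.warn("generation barcodes closer than Hamming distance 2", stacklevel=2)

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes.values())))

    @property
    def payload_offset(self) -> int:
        return len(self.leader) + self.barcode_length + len(self.anchor)


# Reject reasons
TOO_SHORT = "too_short"
NO_GENERATION_BARCODE = "no_generation_barcode"
ORIENTATION = "orientation"
LENGTH_MISMATCH = "length_mismatch"
NO_POSITIONAL_BARCODE = "no_positional_barcode"
MULTIPLE_POSITIONAL_BARCODES = "multiple_positional_barcodes"


@dataclass
class DecodedRead:
    """Per-read decoding outcome: full assignment or one reject reason."""

    read_id: str
    generation: str | None = None
    library_id: str | None = None
    codon: str | None = None
    reject: str | None = None
    off_target_mismatches: int = 0
    comparable_bases: int = 0
    orientation: str = "forward"

    @property
    def accepted(self) -> bool:
        return self.reject is None


def assign_generation(read: str, barcodes: GenerationBarcodeSet, max_mismatch: int = 0) -> str:
    """Match the 8-mer at the expected offset against the barcode map.

    Returns the generation label, or a reject reason. With
    ``max_mismatch`` > 0, nearest-unique semantics apply (ties reject).
    """
    start = len(barcodes.leader)
    end = start + barcodes.barcode_length
    if len(read) < end:
        return TOO_SHORT
    observed = read[start:end]
    if max_mismatch == 0:
        for label, bc in barcodes.barcodes.items():
            if observed == bc:
                return label
        return NO_GENERATION_BARCODE
    dists = {label: _hamming(observed, bc) for label, bc in barcodes.barcodes.items()}
    best = min(dists.values())
    hits = [label for label, d in dists.items() if d == best]
    if best <= max_mismatch and len(hits) == 1:
        return hits[0]
    return NO_GENERATION_BARCODE


def assign_position(
    payload: str,
    libraries: list[PositionalLibrary],
    expected_length: int | None = None,
) -> str:
    """Identify the originating library from its silent codon barcode.

    Exactly one library whose barcode codon appears at its barcode slot
    → that library's id; zero or multiple → reject.
    """
    if expected_length is not None and len(payload) != expected_length:
        return LENGTH_MISMATCH
    hits = [
        lib.library_id
        for lib in libraries
        if payload[lib.barcode_codon_start : lib.barcode_codon_start + 3] == lib.barcode_codon
    ]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        return NO_POSITIONAL_BARCODE
    return MULTIPLE_POSITIONAL_BARCODES


@dataclass
class CountTable:
    """Codon counts per (library, generation) with a rejection ledger.

    Invariant: accepted counts plus rejects equal total_reads.
    """

    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    rejects: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0

    def add(self, library_id: str, generation: str, codon: str) -> None:
        key = (library_id, generation, codon)
        self.counts[key] = self.counts.get(key, 0) + 1
        self.total_reads += 1

    def add_reject(self, reason: str) -> None:
        self.rejects[reason] = self.rejects.get(reason, 0) + 1
        self.total_reads += 1

    def check(self) -> None:
        assert sum(self.counts.values()) + sum(self.rejects.values()) == self.total_reads
        assert all(key[2] in CODONS for key in self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "library": lib,
                "generation": gen,
                "codon": codon,
                "count": n,
                "is_nns": codon in NNS_CODONS,
            }
            for (lib, gen, codon), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["library", "generation", "codon", "count", "is_nns"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        table = cls()
        for row in df.itertuples():
            key = (str(row.library), str(row.generation), row.codon)
            table.counts[key] = table.counts.get(key, 0) + int(row.count)
            table.total_reads += int(row.count)
        return table

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#", dtype={"library": str}))


class Decoder:
    """Anchored dual-barcode decoder over a fixed library panel."""

    def __init__(
        self,
        ref: ReferenceAmplicon,
        libraries: list[PositionalLibrary],
        barcodes: GenerationBarcodeSet | None = None,
        max_barcode_mismatch: int = 0,
    ) -> None:
        sigs = [lib.signature for lib in libraries]
        if len(set(sigs)) != len(sigs):
            raise ValueError("libraries are not pairwise distinguishable")
        self.ref = ref
        self.libraries = libraries
        self.barcodes = barcodes or GenerationBarcodeSet()
        self.max_barcode_mismatch = max_barcode_mismatch
        self._ref_arr = np.frombuffer(ref.cds_window.encode(), dtype=np.uint8)
        # comparable-base mask per library: excludes that library's NNS codon
        # and every library's barcode slot.
        barcode_mask = np.ones(len(ref.cds_window), dtype=bool)
        for lib in libraries:
            barcode_mask[lib.barcode_codon_start : lib.barcode_codon_start + 3] = False
        self._masks = {}
        for lib in libraries:
            m = barcode_mask.copy()
            m[lib.nns_codon_start : lib.nns_codon_start + 3] = False
            self._masks[lib.library_id] = m
        self._by_id = {lib.library_id: lib for lib in libraries}

    def _attempt(self, read_id: str, seq: str) -> tuple[DecodedRead, int]:
        """Decode one orientation; returns (result, stage reached)."""
        gen = assign_generation(seq, self.barcodes, self.max_barcode_mismatch)
        if gen == TOO_SHORT:
            return DecodedRead(read_id, reject=TOO_SHORT), 0
        if gen == NO_GENERATION_BARCODE:
            return DecodedRead(read_id, reject=NO_GENERATION_BARCODE), 1
        a0 = len(self.barcodes.leader) + self.barcodes.barcode_length
        if seq[a0 : a0 + len(self.barcodes.anchor)] != self.barcodes.anchor:
            return DecodedRead(read_id, reject=ORIENTATION), 2
        payload = seq[self.barcodes.payload_offset :]
        lib_id = assign_position(payload, self.libraries, expected_length=len(self.ref.cds_window))
        if lib_id in (LENGTH_MISMATCH, NO_POSITIONAL_BARCODE, MULTIPLE_POSITIONAL_BARCODES):
            return DecodedRead(read_id, generation=gen, reject=lib_id), 3
        lib = self._by_id[lib_id]
        codon = payload[lib.nns_codon_start : lib.nns_codon_start + 3]
        arr = np.frombuffer(payload.encode(), dtype=np.uint8)
        mask = self._masks[lib_id]
        mismatches = int(((arr != self._ref_arr) & mask).sum())
        return (
            DecodedRead(
                read_id,
                generation=gen,
                library_id=lib_id,
                codon=codon,
                off_target_mismatches=mismatches,
                comparable_bases=int(mask.sum()),
            ),
            4,
        )

    def decode(self, read_id: str, seq: str) -> DecodedRead:
        """Try forward then reverse-complement orientation.

        If both fail, the reject reason is taken from whichever orientation
        progressed furthest through the (length, generation barcode, anchor,
        positional barcode) stages, forward winning ties; anchor-stage
        failures are reported as ``orientation``.
        """
        fwd, stage_f = self._attempt(read_id, seq)
        if fwd.accepted:
            return fwd
        rev, stage_r = self._attempt(read_id, reverse_complement(seq))
        if rev.accepted:
            rev.orientation = "reverse"
            return rev
        return fwd if stage_f >= stage_r else rev

    def tabulate(self, reads) -> tuple[CountTable, list[DecodedRead]]:
        """Decode all ``(read_id, sequence)`` pairs into a count table.

        Conservation holds by construction: every read either increments a
        (library, generation, codon) cell or one reject reason.
        """
        table = CountTable()
        ledger = []
        for read_id, seq in reads:
            decoded = self.decode(read_id, seq)
            ledger.append(decoded)
            if decoded.accepted:
                table.add(decoded.library_id, decoded.generation, decoded.codon)
            else:
                table.add_reject(decoded.reject)
        table.check()
        return table, ledger


def off_target_rate(ledger: list[DecodedRead]) -> float:
    """Substitution rate per comparable base over accepted reads.

    Comparable bases exclude the randomized codon, all positional-barcode
    slots and the leader/barcode/anchor scaffold.
    """
    accepted = [r for r in ledger if r.accepted]
    total = sum(r.comparable_bases for r in accepted)
    if total == 0:
        raise ValueError("off-target rate undefined: no comparable bases in ledger")
    return sum(r.off_target_mismatches for r in accepted) / total


def ledger_frame(ledger: list[DecodedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "generation": r.generation or "",
                "library": r.library_id or "",
                "codon": r.codon or "",
                "reject": r.reject or "",
                "off_target_mismatches": r.off_target_mismatches,
                "comparable_bases": r.comparable_bases,
                "orientation": r.orientation,
            }
            for r in ledger
        ]
    )


def qc_summary(table: CountTable, ledger: list[DecodedRead]) -> dict:
    accepted = [r for r in ledger if r.accepted]
    summary = {
        "total_reads": table.total_reads,
        "accepted_reads": len(accepted),
        "rejects": dict(sorted(table.rejects.items())),
        "non_nns_codon_reads": int(
            sum(n for (_, _, codon), n in table.counts.items() if codon not in NNS_CODONS)
        ),
    }
    try:
        summary["off_target_rate"] = off_target_rate(ledger)
    except ValueError:
        summary["off_target_rate"] = None
    return summary


def read_sequences(path):
    """Yield (id, sequence) from FASTQ or FASTA (phred values ignored)."""
    from Bio import SeqIO

    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    for record in SeqIO.parse(str(path), fmt):
        yield record.id, str(record.seq).upper()
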