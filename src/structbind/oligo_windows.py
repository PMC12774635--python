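"""Reference/alternative oligo construction from a genome FASTA.

Window conventions follow SNP-SELEX practice: a 40-bp oligo carries the
variant at its 21st base on the forward strand (20 nt upstream, 19 nt
downstream).  Two symmetric clinical windows are also supported: 41 bp
(20 nt either side) and 81 bp (40 nt either side).  All coordinates are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyfaidx import Fasta

__all__ = [
    "OligoPair",
    "WindowError",
    "WINDOW_MODES",
    "extract_window",
    "apply_variant",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: mode -> (upstream flank, downstream flank); variant offset = upstream + 1
WINDOW_MODES: dict[str, tuple[int, int]] = {
    "selex40": (20, 19),
    "clinical41": (20, 20),
    "clinical81": (40, 40),
}


class WindowError(ValueError):
    """Oligo extraction failed (flank, allele mismatch or bad sequence)."""


@dataclass(frozen=True)
class OligoPair:
    ref_seq: str
    alt_seq: str
    variant_offset: int  # 1-based
    window: tuple[str, int, int]  # chrom, start, end (1-based inclusive)

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError("oligo sequences differ in length")
        diff = [i for i, (a, b) in enumerate(zip(self.ref_seq, self.alt_seq)) if a != b]
        if diff != [self.variant_offset - 1]:
            raise ValueError("sequences must differ exactly at variant_offset")
        for seq in (self.ref_seq, self.alt_seq):
            if not set(seq) <= set("ACGT"):
                raise ValueError("oligo contains non-ACGT characters")


def _validate_base(base: str, name: str) -> str:
    base = base.upper()
    if base not in "ACGT" or len(base) != 1:
        raise WindowError(f"{name} must be a single A/C/G/T base, got {base!r}")
    return base


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase-normalized DNA string."""
    seq = seq.upper()
    if not set(seq) <= set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise WindowError(f"non-ACGT characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def apply_variant(seq: str, offset: int, ref_allele: str, alt_allele: str) -> str:
    """Substitute ``alt_allele`` at 1-based ``offset``, checking the
    reference base currently there."""
    ref_allele = _validate_base(ref_allele, "ref_allele")
    alt_allele = _validate_base(alt_allele, "alt_allele")
    if not (1 <= offset <= len(seq)):
        raise WindowError(f"offset {offset} outside sequence of length {len(seq)}")
    if seq[offset - 1] != ref_allele:
        raise WindowError(
            f"reference mismatch at offset {offset}: sequence has "
            f"{seq[offset - 1]!r}, expected {ref_allele!r}"
        )
    return seq[: offset - 1] + alt_allele + seq[offset:]


def extract_window(
    genome: str | Fasta,
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    mode: str = "selex40",
) -> OligoPair:
    """Extract the forward-strand oligo window around a SNV.

    ``genome`` is a FASTA path or an open :class:`pyfaidx.Fasta`.  The base
    at ``pos`` must equal ``ref_allele``; soft-masked (lowercase) bases are
    uppercased, ambiguity codes rejected.  The variant lands at the mode's
    fixed offset (21st base for 40/41-bp windows, 41st for 81-bp).
    """
    if mode not in WINDOW_MODES:
        raise WindowError(f"unknown mode {mode!r}; choose from {sorted(WINDOW_MODES)}")
    ref_allele = _validate_base(ref_allele, "ref_allele")
    alt_allele = _validate_base(alt_allele, "alt_allele")
    if ref_allele == alt_allele:
        raise WindowError("ref_allele == alt_allele")
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    if chrom not in fa:
        raise WindowError(f"chromosome {chrom!r} not in FASTA")
    up, down = WINDOW_MODES[mode]
    contig_len = len(fa[chrom])
    start, end = pos - up, pos + down
    if start < 1 or end > contig_len:
        raise WindowError(
            f"window [{start}, {end}] truncated by contig {chrom} "
            f"(length {contig_len})"
        )
    seq = str(fa[chrom][start - 1 : end]).upper()
    if not set(seq) <= set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise WindowError(f"ambiguous bases {bad} in window [{start}, {end}]")
    offset = up + 1
    if seq[offset - 1] != ref_allele:
        raise WindowError(
            f"reference-allele mismatch at {chrom}:{pos}: genome has "
            f"{seq[offset - 1]!r}, expected {ref_allele!r}"
        )
    alt_seq = apply_variant(seq, offset, ref_allele, alt_allele)
    return OligoPair(
        ref_seq=seq,
        alt_seq=alt_seq,
        variant_offset=offset,
        window=(chrom, start, end),
    )
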