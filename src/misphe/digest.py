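"""In-silico tryptic digestion with protein-coordinate spans.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) unless the next
residue is proline (P).  Peptides are reported with 1-based inclusive spans
in protein coordinates so that a peptide can be traced back to the residues
it covers — which is what lets a substituted peptide be mapped to the
phenylalanine position it explains.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DigestPeptide", "tryptic_digest", "cleavage_sites"]

STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with its 1-based inclusive span in the protein."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions after which trypsin cuts (K/R not followed by P)."""
    sites = []
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in "KR" and i < n - 1 and sequence[i + 1] != "P":
            sites.append(i)
    return sites


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 2,
    length_range: tuple[int, int] = (7, 52),
) -> list[DigestPeptide]:
    """Digest ``sequence`` with trypsin, allowing up to ``missed_cleavages``.

    Peptides whose length falls outside ``length_range`` (inclusive) are
    dropped.  The empty sequence yields an empty list.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be non-negative")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range: {length_range}")
    if not sequence:
        return []

    # Fragment boundaries: start indices of fully cleaved fragments.
    cuts = cleavage_sites(sequence)
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(sequence)]  # exclusive

    peptides: list[DigestPeptide] = []
    n_frag = len(starts)
    for i in range(n_frag):
        for missed in range(missed_cleavages + 1):
            j = i + missed
            if j >= n_frag:
                break
            start, end = starts[i], ends[j]
            length = end - start
            if lo <= length <= hi:
                peptides.append(
                    DigestPeptide(
                        sequence=sequence[start:end],
                        start=start + 1,
                        end=end,
                        missed_cleavages=missed,
                    )
                )
    return peptides


def validate_protein_sequence(sequence: str, protein_id: str = "?") -> None:
    """Reject sequences containing non-standard residues, naming the offender."""
    if not sequence:
        raise ValueError(f"protein {protein_id}: empty sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_AMINO_ACIDS:
            raise ValueError(
                f"protein {protein_id}: non-standard residue {aa!r} at position {i}"
            )
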