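"""The 20-letter amino-acid alphabet and sequence validation.

Non-standard residue codes (B, J, O, U, X, Z) and gaps are rejected rather
than skipped: a silently dropped window would change every downstream
epitope count.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""Standard residues, alphabetically ordered; index order of all weight tables."""

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

GAP_CHARS = frozenset("-.")


def validate_sequence(seq: str, alphabet: str = AMINO_ACIDS, *, what: str = "sequence") -> str:
    """Return ``seq`` uppercased, or raise ``ValueError`` naming the first bad character."""
    seq = seq.upper()
    allowed = set(alphabet)
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos} in {what}: "
                f"expected one of {alphabet}"
            )
    return seq


def validate_peptide(pep: str, window: int = 9, alphabet: str = AMINO_ACIDS) -> str:
    """Validate a fixed-length peptide (length and alphabet)."""
    if len(pep) != window:
        raise ValueError(f"peptide must have length {window}, got {len(pep)} ({pep!r})")
    return validate_sequence(pep, alphabet, what="peptide")
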