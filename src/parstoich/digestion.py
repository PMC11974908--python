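"""In-silico Lys-C digestion and peptide-to-protein mapping.

Lys-C cleaves C-terminal to lysine, *including* Lys-Pro bonds (unlike
trypsin). Paired with Lys-only SILAC labels this guarantees every internal
peptide carries a label. Positions are 1-based; site-span intervals are
closed on both ends. Ile and Leu are treated as distinct residues (exact
string matching).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_model import AMINO_ACIDS


@dataclass(frozen=True)
class PeptideOccurrence:
    """An exact, cleavage-compatible placement of a peptide in a protein."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_missed: int  # internal (non C-terminal) lysines


def lysc_digest(sequence: str, max_missed: int = 0) -> list:
    """Digest ``sequence`` with Lys-C, allowing up to ``max_missed`` missed cleavages.

    Returns ``(peptide, start, end, n_missed)`` tuples, 1-based inclusive
    coordinates, ordered by start then length. With ``max_missed = 0`` the
    products concatenate back to the input.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not sequence:
        return []
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"illegal residue(s) in sequence: {sorted(bad)!r}")

    # Fully cleaved segment boundaries: cut after every K.
    starts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa == "K":
            starts.append(i + 1)
    ends = starts[1:] + [len(sequence)]

    products = []
    n_seg = len(starts)
    for i in range(n_seg):
        for j in range(i, min(i + max_missed + 1, n_seg)):
            pep = sequence[starts[i] : ends[j]]
            products.append((pep, starts[i] + 1, ends[j], j - i))
    return products


def _n_internal_lysines(peptide: str) -> int:
    n = peptide.count("K")
    if peptide.endswith("K"):
        n -= 1
    return n


def map_peptide(peptide: str, protein_records, max_missed: int | None = None) -> list:
    """Find all exact, Lys-C-compatible occurrences of ``peptide``.

    An occurrence is compatible when it is preceded by K or the protein
    N-terminus and ends at K or the protein C-terminus. ``max_missed``
    optionally caps the internal lysine count; ``None`` means no cap.
    """
    if not peptide:
        return []
    occurrences = []
    for rec in protein_records:
        seq = rec.sequence
        pos = seq.find(peptide)
        while pos != -1:
            start, end = pos + 1, pos + len(peptide)  # 1-based inclusive
            before_ok = start == 1 or seq[start - 2] == "K"
            after_ok = end == len(seq) or seq[end - 1] == "K"
            if before_ok and after_ok:
                n_missed = _n_internal_lysines(peptide)
                if max_missed is None or n_missed <= max_missed:
                    occurrences.append(
                        PeptideOccurrence(
                            protein_id=rec.id,
                            start=start,
                            end=end,
                            n_missed=n_missed,
                        )
                    )
            pos = seq.find(peptide, pos + 1)
    return occurrences


def spans_site(occurrence: PeptideOccurrence, sites) -> bool:
    """True iff any known site on the same protein lies within [start, end]."""
    return any(
        s.protein_id == occurrence.protein_id
        and occurrence.start <= s.position <= occurrence.end
        for s in sites
    )
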