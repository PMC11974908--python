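"""Domain types and typed readers/writers for the stoichiometry pipeline.

The pipeline consumes quantified SILAC peptide pairs (light = enriched,
modified material; heavy = whole-lysate, unmodified material), a titration
design table giving the heavy/light lysate masses behind each mix point,
protein sequences, a reference list of known modified proteins, and a table
of known modification sites used to exclude peptides whose mass would be
shifted by the modification itself.

All occupancies are carried as fractions internally; percent appears only in
reports and summaries. This avoids silent 100x unit errors.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Canonical column names of the peptide quantification TSV.
PEPTIDE_COLUMNS = (
    "sequence",
    "proteins",
    "mix_id",
    "replicate",
    "light_area",
    "heavy_area",
    "light_sn",
    "heavy_sn",
)


class TableFormatError(ValueError):
    """A required column is missing or a table is structurally invalid."""


def _check_sequence(seq: str, context: str) -> str:
    if not seq:
        raise ValueError(f"{context}: empty sequence")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(
            f"{context}: illegal residue(s) {sorted(bad)!r} in sequence"
        )
    return seq


@dataclass(frozen=True)
class PeptidePair:
    """One quantified light/heavy peptide pair in one mix point and replicate.

    Areas are arbitrary detector intensity units; S/N values are the
    per-channel signal-to-noise ratios reported by the quantification
    software. The heavy/light ratio is defined only when ``light_area > 0``.
    """

    sequence: str
    protein_ids: frozenset
    mix_id: str
    replicate_id: str
    light_area: float
    heavy_area: float
    light_sn: float
    heavy_sn: float

    def __post_init__(self):
        _check_sequence(self.sequence, f"peptide {self.sequence!r}")
        if not self.protein_ids:
            raise ValueError(f"peptide {self.sequence!r}: empty protein_ids")
        for name in ("light_area", "heavy_area", "light_sn", "heavy_sn"):
            v = getattr(self, name)
            if not (v == v) or v in (float("inf"), float("-inf")):
                raise ValueError(f"peptide {self.sequence!r}: {name} not finite")
            if v < 0:
                raise ValueError(f"peptide {self.sequence!r}: {name} < 0")
        object.__setattr__(self, "protein_ids", frozenset(self.protein_ids))

    @property
    def hl_ratio(self) -> float:
        """Heavy/light peak-area ratio. Requires a positive light area."""
        if self.light_area <= 0:
            raise ZeroDivisionError(
                f"peptide {self.sequence!r}: H/L undefined for light_area "
                f"{self.light_area}"
            )
        return self.heavy_area / self.light_area


@dataclass(frozen=True)
class MixPoint:
    """One titration point: lysate masses behind a heavy:light mix ratio.

    ``heavy_mass`` is the mass of whole heavy lysate digested; ``light_mass``
    is the mass of light lysate from which the modified proteins were
    enriched. Both in the same unit (conventionally ug). The dimensionless
    mix ratio rho = heavy_mass / light_mass.
    """

    mix_id: str
    heavy_mass: float
    light_mass: float

    def __post_init__(self):
        if self.heavy_mass <= 0 or self.light_mass <= 0:
            raise ValueError(
                f"mix point {self.mix_id!r}: masses must be positive"
            )

    @property
    def ratio(self) -> float:
        return self.heavy_mass / self.light_mass


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein record with empty id")
        _check_sequence(self.sequence, f"protein {self.id!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    """A known modification site: accession, 1-based position, residue letter."""

    protein_id: str
    position: int
    residue: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: position must be >= 1"
            )
        if len(self.residue) != 1 or self.residue not in AMINO_ACIDS:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: bad residue "
                f"{self.residue!r}"
            )


# Flags attached to stoichiometry estimates.
SINGLE_MIX = "SINGLE_MIX"  # occupancy derives from a single mix point
GT_ONE = "GT_ONE"  # occupancy fraction > 1 (never capped)
CORRECTED = "CORRECTED"  # non-specific-binding correction applied


@dataclass
class StoichEstimate:
    """Per-protein occupancy estimate within one replicate.

    ``per_mix_median_ratio[m]`` is the median heavy/light peptide-area ratio
    at mix point ``m``; ``per_mix_stoich[m] = rho_m / per_mix_median_ratio[m]``
    and ``stoich`` is the median of the available per-mix occupancies.
    """

    protein_id: str
    replicate_id: str
    per_mix_median_ratio: dict = field(default_factory=dict)
    per_mix_n_peptides: dict = field(default_factory=dict)
    per_mix_stoich: dict = field(default_factory=dict)
    stoich: float = float("nan")
    flags: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _as_text(stream):
    if isinstance(stream, (str, bytes, os.PathLike)):
        return open(stream, "rt", encoding="utf-8")
    return stream


def read_peptide_table(stream, column_map=None) -> list:
    """Read a tab-separated peptide quantification table.

    Parameters
    ----------
    stream : path or text stream
    column_map : dict, optional
        Maps canonical column names (:data:`PEPTIDE_COLUMNS`) to the names
        used in the file, for foreign exports. Unmapped names are taken as-is.

    Rows with unparsable or negative numerics are rejected with a row-indexed
    warning; the remaining rows are returned. A missing required column is a
    configuration error.
    """
    column_map = dict(column_map or {})
    fh = _as_text(stream)
    try:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn("peptide table is empty", stacklevel=2)
        return []
    rename = {column_map.get(c, c): c for c in PEPTIDE_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise TableFormatError(
            f"peptide table missing required column(s): {sorted(missing)}"
        )
    df = df.rename(columns=rename)
    if df.empty:
        warnings.warn("peptide table has a header but no rows", stacklevel=2)
        return []

    pairs = []
    numeric = ("light_area", "heavy_area", "light_sn", "heavy_sn")
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = {c: getattr(row, c) for c in PEPTIDE_COLUMNS}
        try:
            values = [float(rec[c]) for c in numeric]
            pair = PeptidePair(
                sequence=rec["sequence"].strip().upper(),
                protein_ids=frozenset(
                    p for p in rec["proteins"].split(";") if p
                ),
                mix_id=str(rec["mix_id"]),
                replicate_id=str(rec["replicate"]),
                light_area=values[0],
                heavy_area=values[1],
                light_sn=values[2],
                heavy_sn=values[3],
            )
        except (ValueError, ZeroDivisionError) as exc:
            warnings.warn(
                f"peptide table line {idx}: rejected row ({exc})", stacklevel=2
            )
            continue
        pairs.append(pair)
    return pairs


def write_peptide_table(pairs, stream) -> None:
    """Write pairs as the canonical TSV (inverse of :func:`read_peptide_table`)."""
    close = False
    if isinstance(stream, (str, bytes, os.PathLike)):
        stream, close = open(stream, "wt", encoding="utf-8"), True
    try:
        stream.write("\t".join(PEPTIDE_COLUMNS) + "\n")
        for p in pairs:
            stream.write(
                "\t".join(
                    [
                        p.sequence,
                        ";".join(sorted(p.protein_ids)),
                        p.mix_id,
                        p.replicate_id,
                        repr(p.light_area),
                        repr(p.heavy_area),
                        repr(p.light_sn),
                        repr(p.heavy_sn),
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            stream.close()


def read_fasta(stream) -> list:
    """Read protein records from FASTA; accession = first header token.

    Duplicate accessions and illegal residues are errors.
    """
    fh = _as_text(stream)
    records = []
    seen = set()
    for rec in SeqIO.parse(fh, "fasta"):
        pid = rec.id.split()[0]
        if pid in seen:
            raise ValueError(f"duplicate accession in FASTA: {pid!r}")
        seen.add(pid)
        records.append(ProteinRecord(id=pid, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records, stream, width: int = 60) -> None:
    close = False
    if isinstance(stream, (str, bytes, os.PathLike)):
        stream, close = open(stream, "wt", encoding="utf-8"), True
    try:
        for rec in records:
            stream.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                stream.write(rec.sequence[i : i + width] + "\n")
    finally:
        if close:
            stream.close()


def read_sites(stream, protein_records=None) -> list:
    """Read a TSV of known modification sites (protein_id, position, residue).

    When protein records are supplied, every site is validated against the
    sequence; offending rows are collected and reported in one error.
    """
    fh = _as_text(stream)
    df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    required = ("protein_id", "position", "residue")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"site table missing required column(s): {sorted(missing)}"
        )
    sites = [
        SiteAnnotation(
            protein_id=row.protein_id,
            position=int(row.position),
            residue=row.residue,
        )
        for row in df.itertuples(index=False)
    ]
    if protein_records is not None:
        by_id = {r.id: r.sequence for r in protein_records}
        bad = []
        for s in sites:
            seq = by_id.get(s.protein_id)
            if seq is None:
                continue
            if s.position > len(seq):
                bad.append(f"{s.protein_id}:{s.position} beyond length {len(seq)}")
            elif seq[s.position - 1] != s.residue:
                bad.append(
                    f"{s.protein_id}:{s.position} residue {s.residue!r} != "
                    f"sequence {seq[s.position - 1]!r}"
                )
        if bad:
            raise ValueError("invalid site annotation(s): " + "; ".join(bad))
    return sites


def write_sites(sites, stream) -> None:
    close = False
    if isinstance(stream, (str, bytes, os.PathLike)):
        stream, close = open(stream, "wt", encoding="utf-8"), True
    try:
        stream.write("protein_id\tposition\tresidue\n")
        for s in sites:
            stream.write(f"{s.protein_id}\t{s.position}\t{s.residue}\n")
    finally:
        if close:
            stream.close()


def read_design(stream) -> list:
    """Read the titration design TSV (mix_id, heavy_mass_ug, light_mass_ug)."""
    fh = _as_text(stream)
    df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    required = ("mix_id", "heavy_mass_ug", "light_mass_ug")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"design table missing required column(s): {sorted(missing)}"
        )
    return [
        MixPoint(
            mix_id=row.mix_id,
            heavy_mass=float(row.heavy_mass_ug),
            light_mass=float(row.light_mass_ug),
        )
        for row in df.itertuples(index=False)
    ]


def write_design(mix_points, stream) -> None:
    close = False
    if isinstance(stream, (str, bytes, os.PathLike)):
        stream, close = open(stream, "wt", encoding="utf-8"), True
    try:
        stream.write("mix_id\theavy_mass_ug\tlight_mass_ug\n")
        for m in mix_points:
            stream.write(f"{m.mix_id}\t{m.heavy_mass!r}\t{m.light_mass!r}\n")
    finally:
        if close:
            stream.close()


def read_reference(stream) -> set:
    """Read a reference protein list: one accession per line (or first TSV column)."""
    fh = _as_text(stream)
    out = set()
    for line in fh:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        token = line.split("\t")[0]
        if token and token.lower() not in ("protein_id", "accession"):
            out.add(token)
    return out


def read_term_sets(stream) -> dict:
    """Read an annotation TSV (term_id, protein_id) into term -> set of proteins."""
    fh = _as_text(stream)
    df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    required = ("term_id", "protein_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"term table missing required column(s): {sorted(missing)}"
        )
    terms: dict = {}
    for row in df.itertuples(index=False):
        terms.setdefault(row.term_id, set()).add(row.protein_id)
    return terms
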