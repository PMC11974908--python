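"""Non-specific bead binding, quantified from a mixed-lysate control.

In the control experiment both channels are co-enriched from equal lysate
masses: the light channel is the genuinely modified material, the heavy
channel (modification suppressed by inhibitor) can only be captured
non-specifically. The per-protein heavy/light median therefore measures the
non-specific fraction f_ns directly.

The optional multiplicative correction (occupancy * (1 - f_ns)) is an
extension beyond plain quantification and is off by default.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass

from .io_model import CORRECTED
from .quantify import DEFAULT_SN_THRESHOLD, passes_sn


@dataclass(frozen=True)
class NonspecificEstimate:
    protein_id: str
    f_ns: float  # median heavy/light ratio in the control
    n_peptides: int


def estimate_nonspecific(
    control_pairs,
    reference_proteins,
    sn_threshold: float = DEFAULT_SN_THRESHOLD,
    design=None,
):
    """Per-protein non-specific binding from a co-enrichment control.

    Returns ``(estimates, global_median)``; proteins with no peptide passing
    the S/N gate are absent (their non-specific signal is unmeasurable, not
    zero). When a design table is given, it must describe equal heavy and
    light input masses — the f_ns reading is only meaningful then.
    """
    if design is not None:
        for m in design:
            if m.heavy_mass != m.light_mass:
                raise ValueError(
                    f"control mix point {m.mix_id!r} has unequal masses "
                    f"({m.heavy_mass} vs {m.light_mass}); f_ns requires a "
                    "1:1 co-enrichment"
                )
    reference_proteins = set(reference_proteins)
    groups: dict = {}
    for p in control_pairs:
        if not passes_sn(p, sn_threshold):
            continue
        if p.light_area <= 0:
            continue
        for pid in p.protein_ids:
            if pid in reference_proteins:
                groups.setdefault(pid, []).append(p.hl_ratio)

    estimates = [
        NonspecificEstimate(
            protein_id=pid,
            f_ns=statistics.median(ratios),
            n_peptides=len(ratios),
        )
        for pid, ratios in sorted(groups.items())
    ]
    global_median = (
        statistics.median(e.f_ns for e in estimates) if estimates else None
    )
    return estimates, global_median


def apply_correction(stoich_table, nonspecific_estimates, enabled: bool = False):
    """Optionally deflate occupancies by the per-protein non-specific fraction.

    Disabled (default): returns the table unchanged. Enabled: for proteins
    with an f_ns estimate, corrected = occupancy * (1 - f_ns), floored at 0
    and flagged; f_ns > 1 is physically impossible for a fraction and the
    correction is skipped with a warning for that protein.
    """
    if not enabled:
        return stoich_table
    table = stoich_table.copy()
    by_id = {e.protein_id: e.f_ns for e in nonspecific_estimates}
    if "flags" not in table.columns:
        table["flags"] = ""
    for pid, f_ns in by_id.items():
        if pid not in table.index:
            continue
        if f_ns > 1:
            warnings.warn(
                f"{pid}: f_ns = {f_ns:.3g} > 1, correction skipped",
                stacklevel=2,
            )
            continue
        for col in table.columns:
            if col.startswith("stoich"):
                table.loc[pid, col] = max(table.loc[pid, col] * (1 - f_ns), 0.0)
        prev = table.loc[pid, "flags"]
        table.loc[pid, "flags"] = (
            f"{prev};{CORRECTED}" if prev else CORRECTED
        )
    return table
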