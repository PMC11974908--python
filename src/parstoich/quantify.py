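"""Pipeline core: peptide filtering, median roll-up and occupancy arithmetic.

The measurement model: the light channel holds the modified fraction of each
protein (enriched from ``light_mass`` of lysate), the heavy channel holds
the whole unmodified pool (``heavy_mass`` of lysate digested directly). For
a protein with occupancy ``s`` mixed at ratio ``rho = heavy_mass /
light_mass``, the expected heavy/light peptide-area ratio is ``rho / s``,
so

    occupancy at one mix point  =  rho / median(H/L over the protein's peptides)
    final occupancy             =  median over the available mix points

Medians at both levels make the roll-up robust to individual mis-quantified
peptides and to mix points where one channel is censored by the detector's
dynamic range.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import digestion
from .io_model import GT_ONE, SINGLE_MIX, StoichEstimate

DEFAULT_SN_THRESHOLD = 5.0


@dataclass
class FilterReport:
    """Peptide-filter audit: counts with first-failing-rule attribution."""

    n_input: int = 0
    n_pass: int = 0
    n_fail_sn: int = 0
    n_fail_reference: int = 0
    n_fail_site: int = 0
    n_fail_shared: int = 0

    def check(self) -> None:
        total = (
            self.n_pass
            + self.n_fail_sn
            + self.n_fail_reference
            + self.n_fail_site
            + self.n_fail_shared
        )
        if total != self.n_input:
            raise AssertionError(
                f"filter report not conserved: {total} != {self.n_input}"
            )


@dataclass
class SummaryStats:
    """Distribution summary of final occupancies, in percent."""

    n_proteins: int
    median_pct: float
    mean_pct: float
    min_pct: float
    max_pct: float
    n_gt_5pct: int
    n_lt_1pct: int
    bin_counts: dict = field(default_factory=dict)


def passes_sn(pair, threshold: float = DEFAULT_SN_THRESHOLD, mode: str = "both") -> bool:
    """Signal-to-noise gate: strict ``>`` on the configured channel(s).

    ``mode="both"`` (default) requires both channels above threshold — a
    ratio needs two reliable peaks. ``mode="either"`` accepts one.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if mode == "both":
        return pair.light_sn > threshold and pair.heavy_sn > threshold
    if mode == "either":
        return pair.light_sn > threshold or pair.heavy_sn > threshold
    raise ValueError(f"unknown S/N mode {mode!r}")


def filter_peptides(
    pairs,
    reference_proteins,
    sites=None,
    protein_records=None,
    max_missed: int = 2,
    sn_threshold: float = DEFAULT_SN_THRESHOLD,
    sn_mode: str = "both",
    shared_policy: str = "drop",
):
    """Apply the three retention criteria and return (retained, FilterReport).

    1. S/N above threshold in both channels (strict ``>``).
    2. Every protein the peptide maps to is in the reference list of known
       modified proteins; a peptide mapping to nothing fails here too.
    3. No occurrence of the peptide spans a known modification site (the
       modified form of such a peptide is mass-shifted, so its unmodified
       signal would under-count the light channel). Skipped with a warning
       when sites or sequences are unavailable.

    Shared peptides (mapping to more than one reference protein) are dropped
    under the default ``shared_policy="drop"`` for unambiguous ratio
    attribution, or duplicated to every mapped protein under
    ``"assign-to-all"``.

    Each rejected peptide is attributed to the *first* failing rule, in the
    order S/N, reference, site, shared; the counts are conserved.
    """
    if not reference_proteins:
        raise ValueError("reference protein list must be non-empty")
    if shared_policy not in ("drop", "assign-to-all"):
        raise ValueError(f"unknown shared_policy {shared_policy!r}")
    reference_proteins = set(reference_proteins)

    site_check = sites is not None and protein_records is not None
    if not site_check:
        warnings.warn(
            "site exclusion skipped: known sites and/or protein sequences "
            "not provided",
            stacklevel=2,
        )
    records = list(protein_records) if protein_records is not None else None

    report = FilterReport(n_input=len(pairs))
    retained = []
    occ_cache: dict = {}  # sequences repeat across mix points and replicates
    for pair in pairs:
        if not passes_sn(pair, sn_threshold, sn_mode):
            report.n_fail_sn += 1
            continue

        if records is not None:
            if pair.sequence not in occ_cache:
                occ_cache[pair.sequence] = digestion.map_peptide(
                    pair.sequence, records, max_missed=max_missed
                )
            occurrences = occ_cache[pair.sequence]
            mapped = {o.protein_id for o in occurrences}
            if not mapped:
                report.n_fail_reference += 1
                warnings.warn(
                    f"peptide {pair.sequence!r} maps to no protein record",
                    stacklevel=2,
                )
                continue
        else:
            occurrences = []
            mapped = set(pair.protein_ids)

        if not mapped <= reference_proteins:
            report.n_fail_reference += 1
            continue

        if site_check and any(
            digestion.spans_site(o, sites) for o in occurrences
        ):
            report.n_fail_site += 1
            continue

        if len(mapped) > 1:
            if shared_policy == "drop":
                report.n_fail_shared += 1
                continue
            # assign-to-all: duplicate the pair onto each mapped protein
            for pid in sorted(mapped):
                retained.append(
                    _reassign(pair, frozenset({pid}))
                )
            report.n_pass += 1
            continue

        retained.append(_reassign(pair, frozenset(mapped)))
        report.n_pass += 1

    report.check()
    return retained, report


def _reassign(pair, protein_ids):
    from dataclasses import replace

    return replace(pair, protein_ids=protein_ids)


def compute_mix_ratio(heavy_mass: float, light_mass: float) -> float:
    """Mix ratio rho = heavy lysate mass / light lysate mass (same unit)."""
    if heavy_mass <= 0 or light_mass <= 0:
        raise ValueError("lysate masses must be positive")
    return heavy_mass / light_mass


def protein_median_ratio(pairs) -> tuple:
    """Median heavy/light area ratio over one protein's peptides at one mix.

    Returns ``(median, n_peptides)``; even counts use the midpoint mean.
    Pairs with non-positive light area carry no defined ratio and are
    excluded; with none left the protein is simply absent at this mix point.
    """
    ratios = [p.hl_ratio for p in pairs if p.light_area > 0]
    if not ratios:
        raise ValueError("no pairs with positive light area")
    return statistics.median(ratios), len(ratios)


def stoich_at_mix(mix_ratio: float, median_ratio: float) -> float:
    """Occupancy at one mix point: ``mix_ratio / median_ratio``.

    Values above 1 are returned as-is (flagged downstream, never capped:
    truncation would hide calibration errors).
    """
    if median_ratio <= 0:
        raise ValueError("median H/L ratio must be > 0")
    if mix_ratio <= 0:
        raise ValueError("mix ratio must be > 0")
    return mix_ratio / median_ratio


def combine_across_mixes(per_mix_stoich: dict) -> tuple:
    """Median across mix points; flags SINGLE_MIX and GT_ONE as appropriate."""
    if not per_mix_stoich:
        raise ValueError("no per-mix occupancies to combine")
    values = list(per_mix_stoich.values())
    stoich = statistics.median(values)
    flags = set()
    if len(values) == 1:
        flags.add(SINGLE_MIX)
    if stoich > 1:
        flags.add(GT_ONE)
    return stoich, flags


def estimate_stoichiometries(pairs, mix_points, replicate_id=None) -> list:
    """Roll filtered pairs of one replicate up to per-protein estimates.

    ``pairs`` must already be filtered (each carrying a single protein id);
    ``mix_points`` supplies the rho for every mix_id present. Proteins
    missing from some mix points use the median of the available ones —
    never imputed.
    """
    rho = {m.mix_id: m.ratio for m in mix_points}
    groups: dict = {}
    reps = set()
    for p in pairs:
        if p.mix_id not in rho:
            raise KeyError(f"pair references unknown mix point {p.mix_id!r}")
        if len(p.protein_ids) != 1:
            raise ValueError(
                f"pair {p.sequence!r} still maps to {len(p.protein_ids)} "
                "proteins; filter first"
            )
        (pid,) = p.protein_ids
        reps.add(p.replicate_id)
        groups.setdefault(pid, {}).setdefault(p.mix_id, []).append(p)
    if replicate_id is None:
        replicate_id = reps.pop() if len(reps) == 1 else "+".join(sorted(reps))

    estimates = []
    for pid in sorted(groups):
        est = StoichEstimate(protein_id=pid, replicate_id=replicate_id)
        for mix_id in sorted(groups[pid]):
            try:
                med, n = protein_median_ratio(groups[pid][mix_id])
            except ValueError:
                continue
            if med <= 0:
                continue  # heavy channel fully censored at this mix point
            est.per_mix_median_ratio[mix_id] = med
            est.per_mix_n_peptides[mix_id] = n
            est.per_mix_stoich[mix_id] = stoich_at_mix(rho[mix_id], med)
        if not est.per_mix_stoich:
            continue
        est.stoich, est.flags = combine_across_mixes(est.per_mix_stoich)
        estimates.append(est)
    return estimates


def merge_replicates(estimates_by_replicate: dict):
    """Merge per-replicate estimate lists into one table.

    Returns ``(table, overlap, r)`` where ``table`` is a DataFrame indexed
    by protein id with one ``stoich_<rep>`` column per replicate and a
    merged ``stoich`` column (median across replicates), ``overlap`` is the
    set of proteins present in every replicate, and ``r`` is the Pearson
    correlation of log10 occupancy over the overlap (``None`` when
    undefined).
    """
    if len(estimates_by_replicate) < 2:
        warnings.warn(
            "fewer than 2 replicates: merge is the identity", stacklevel=2
        )
    columns = {}
    for rep, ests in sorted(estimates_by_replicate.items()):
        columns[f"stoich_{rep}"] = pd.Series(
            {e.protein_id: e.stoich for e in ests}, dtype=float
        )
    table = pd.DataFrame(columns)
    table.index.name = "protein_id"
    table = table.sort_index()
    table["stoich"] = table[list(columns)].median(axis=1, skipna=True)

    overlap = set(table.index[table[list(columns)].notna().all(axis=1)])
    r = None
    if len(estimates_by_replicate) >= 2 and len(overlap) >= 2:
        sub = np.log10(table.loc[sorted(overlap), list(columns)].to_numpy())
        # correlation of the first two replicates, matching a scatter plot
        x, y = sub[:, 0], sub[:, 1]
        if np.std(x) > 0 and np.std(y) > 0:
            r = float(np.corrcoef(x, y)[0, 1])
    return table, overlap, r


def summarize(table, bin_edges_pct=None) -> SummaryStats:
    """Distribution summary of final occupancies (input fractions -> percent)."""
    from .enrichment import BIN_LABELS, assign_bin_label

    if isinstance(table, pd.DataFrame):
        values = table["stoich"].dropna().to_numpy(dtype=float)
    else:
        values = np.asarray(list(table), dtype=float)
    if values.size == 0:
        raise ValueError("no occupancies to summarize")
    pct = values * 100.0
    bin_counts = {label: 0 for label in BIN_LABELS}
    for v in pct:
        bin_counts[assign_bin_label(v)] += 1
    return SummaryStats(
        n_proteins=int(pct.size),
        median_pct=float(np.median(pct)),
        mean_pct=float(np.mean(pct)),
        min_pct=float(np.min(pct)),
        max_pct=float(np.max(pct)),
        n_gt_5pct=int(np.sum(pct > 5.0)),
        n_lt_1pct=int(np.sum(pct < 1.0)),
        bin_counts=bin_counts,
    )


def stoich_table_frame(estimates, mix_points) -> pd.DataFrame:
    """Flatten estimates of one replicate into a tidy DataFrame for TSV export."""
    rows = []
    mix_ids = [m.mix_id for m in mix_points]
    for e in estimates:
        row = {
            "protein_id": e.protein_id,
            "replicate": e.replicate_id,
            "stoich": e.stoich,
            "stoich_pct": e.stoich * 100.0,
            "n_peptides": sum(e.per_mix_n_peptides.values()),
            "flags": ";".join(sorted(e.flags)),
        }
        for m in mix_ids:
            row[f"median_ratio_{m}"] = e.per_mix_median_ratio.get(m, math.nan)
            row[f"stoich_{m}"] = e.per_mix_stoich.get(m, math.nan)
            row[f"n_peptides_{m}"] = e.per_mix_n_peptides.get(m, 0)
        rows.append(row)
    return pd.DataFrame(rows)
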