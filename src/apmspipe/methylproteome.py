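"""Methyl-site calling, occupancy, and substrate triangulation.

From peptide-level evidence carrying methyl annotations this module

* maps each modification to an absolute residue position
  (``start_index + offset - 1``, 1-based, initiator Met counted),
* calls sites passing the protein-/peptide-probability gates and
  aggregates per-condition occupancy (modified / total spectra covering
  the site),
* finds preys enriched in the pan-methyl-lysine pull-down, and
* triangulates candidate direct methyltransferase substrates: a protein
  is a candidate iff it co-purifies with the bait in at least two MS
  experiments, is pulled down by the pan-methyl antibody, and carries a
  called methylation site.

Occupancy is printed the way modification tables conventionally are:
percent to one decimal, half rounded away from zero, integer percents
without a decimal ("5%", "50%"), and "ND" when no covering spectra were
observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design_io import (
    Condition,
    CountMatrix,
    MethylState,
    Mod,
    PeptideEvidence,
    SampleManifest,
    ValidationError,
)
from .quantitation import DEFAULT_FLOOR

__all__ = [
    "Occupancy",
    "MethylSite",
    "CandidateTarget",
    "site_occupancy",
    "format_occupancy",
    "map_absolute_position",
    "call_methyl_sites",
    "per_sample_occupancy",
    "panmethyl_enrichment",
    "triangulate_targets",
]


@dataclass(frozen=True)
class Occupancy:
    """Modified vs total spectra covering a site in one condition."""

    n_mod: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_mod < 0 or self.n_total < 0:
            raise ValidationError("occupancy counts must be nonnegative")
        if self.n_mod > self.n_total:
            raise ValidationError("n_mod exceeds n_total")

    @property
    def nd(self) -> bool:
        """Not detected: no spectra covered the site."""
        return self.n_total == 0

    @property
    def percent(self) -> float | None:
        """Percent occupancy rounded half away from zero to one decimal."""
        if self.nd:
            return None
        d = (Decimal(100 * self.n_mod) / Decimal(self.n_total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
        return float(d)

    def __str__(self) -> str:
        return f"{format_occupancy(self)} ({self.n_mod}/{self.n_total})"


def site_occupancy(n_mod: int, n_total: int) -> Occupancy:
    """Occupancy of a site from modified and total spectrum counts."""
    return Occupancy(n_mod=n_mod, n_total=n_total)


def format_occupancy(occ: Occupancy) -> str:
    """"ND" when undetected, else percent with trailing ".0" trimmed."""
    pct = occ.percent
    if pct is None:
        return "ND"
    if pct == int(pct):
        return f"{int(pct)}%"
    return f"{pct}%"


@dataclass(frozen=True)
class MethylSite:
    """A called methylated residue with per-condition occupancy.

    ``position`` is the computed absolute residue index; ``author_label``
    optionally preserves a site name as stated in an external source and
    is never used in computation.
    """

    protein_id: str
    residue: str
    position: int
    state: MethylState
    occ_untreated: tuple[int, int]
    occ_treated: tuple[int, int]
    author_label: str | None = None

    @property
    def untreated(self) -> Occupancy:
        return Occupancy(*self.occ_untreated)

    @property
    def treated(self) -> Occupancy:
        return Occupancy(*self.occ_treated)


@dataclass(frozen=True)
class CandidateTarget:
    protein_id: str
    coip_in_n_experiments: int
    panmethyl_enriched: bool
    has_called_site: bool
    is_direct_candidate: bool


def map_absolute_position(ev: PeptideEvidence, mod: Mod) -> int:
    """Absolute 1-based residue position of a peptide-relative mod."""
    if not ev.coords_consistent:
        raise ValidationError(
            f"evidence for {ev.protein_id} ({ev.peptide_seq}) is coordinate-"
            "inconsistent; check the coords_consistent flag before mapping"
        )
    if mod not in ev.mods:
        raise ValidationError("mod does not belong to this evidence record")
    return ev.start_index + mod.offset - 1


def call_methyl_sites(
    evidence: Sequence[PeptideEvidence],
    manifest: SampleManifest,
    protein_prob_min: float = 0.999,
    peptide_prob_min: float = 0.80,
    author_labels: Mapping[tuple[str, int, MethylState], str] | None = None,
) -> list[MethylSite]:
    """Call methyl sites from probability-gated evidence.

    Both probability gates are inclusive.  Coordinate-inconsistent records
    are excluded (they stay in the parsed evidence with their flag).
    Counts aggregate per (protein, position, state) and per condition,
    summing over samples of each condition; sites undetected in both
    conditions are dropped.
    """
    if not 0.0 < protein_prob_min <= 1.0 or not 0.0 < peptide_prob_min <= 1.0:
        raise ValidationError("probability thresholds must lie in (0, 1]")
    labels = author_labels or {}
    agg: dict[tuple[str, str, int, MethylState], dict[Condition, list[int]]] = {}
    for ev in evidence:
        if not ev.coords_consistent:
            continue
        if ev.protein_prob < protein_prob_min or ev.peptide_prob < peptide_prob_min:
            continue
        if not ev.mods:
            continue
        cond = manifest.condition_of(ev.sample_id)
        for mod in ev.mods:
            pos = ev.start_index + mod.offset - 1
            key = (ev.protein_id, mod.residue, pos, mod.state)
            slot = agg.setdefault(
                key,
                {Condition.UNTREATED: [0, 0], Condition.TREATED: [0, 0]},
            )
            slot[cond][0] += ev.n_mod_spectra
            slot[cond][1] += ev.n_total_spectra
    sites = []
    for (pid, residue, pos, state), conds in sorted(
        agg.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][3].value)
    ):
        u = tuple(conds[Condition.UNTREATED])
        t = tuple(conds[Condition.TREATED])
        if u[1] == 0 and t[1] == 0:
            continue
        sites.append(
            MethylSite(
                protein_id=pid,
                residue=residue,
                position=pos,
                state=state,
                occ_untreated=u,
                occ_treated=t,
                author_label=labels.get((pid, pos, state)),
            )
        )
    return sites


def per_sample_occupancy(
    evidence: Sequence[PeptideEvidence],
    protein_prob_min: float = 0.999,
    peptide_prob_min: float = 0.80,
) -> pd.DataFrame:
    """Per-sample occupancy table for transparency alongside the
    per-condition aggregation of :func:`call_methyl_sites`."""
    rows = []
    for ev in evidence:
        if not ev.coords_consistent:
            continue
        if ev.protein_prob < protein_prob_min or ev.peptide_prob < peptide_prob_min:
            continue
        for mod in ev.mods:
            occ = Occupancy(ev.n_mod_spectra, ev.n_total_spectra)
            rows.append(
                {
                    "protein_id": ev.protein_id,
                    "position": ev.start_index + mod.offset - 1,
                    "residue": mod.residue,
                    "state": mod.state.value,
                    "sample_id": ev.sample_id,
                    "n_mod": ev.n_mod_spectra,
                    "n_total": ev.n_total_spectra,
                    "occupancy": format_occupancy(occ),
                }
            )
    cols = [
        "protein_id",
        "position",
        "residue",
        "state",
        "sample_id",
        "n_mod",
        "n_total",
        "occupancy",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(
        ["protein_id", "position", "state", "sample_id"], kind="mergesort"
    ).reset_index(drop=True)


def panmethyl_enrichment(
    matrix: CountMatrix,
    manifest: SampleManifest,
    ratio_min: float = 1.5,
    floor: float = DEFAULT_FLOOR,
) -> set[str]:
    """Proteins enriched in the pan-methyl pull-down over pooled IgG.

    Keeps proteins whose pan-methyl-sample mean over the floored pooled
    IgG mean is at least ``ratio_min`` (inclusive).
    """
    pan = manifest.pan_methyl_samples()
    if not pan:
        raise ValidationError("manifest has no pan_methyl sample")
    ctrls = manifest.control_samples()
    pan_mean = matrix.group_mean(pan)
    ctrl_mean = matrix.group_mean(ctrls)
    kept = set()
    for pid in matrix.proteins:
        ratio = max(float(pan_mean[pid]), floor) / max(float(ctrl_mean[pid]), floor)
        if ratio >= ratio_min:
            kept.add(pid)
    return kept


def triangulate_targets(
    sites: Sequence[MethylSite],
    panmethyl_set: Iterable[str],
    matrix: CountMatrix,
    manifest: SampleManifest,
    min_experiments: int = 2,
) -> list[CandidateTarget]:
    """Three-way triangulation of candidate direct methylation substrates.

    One record per protein appearing in any evidence stream (count matrix,
    called sites, pan-methyl set).  ``coip_in_n_experiments`` counts the
    distinct MS runs whose bait samples detect the protein (count > 0).
    """
    pan = set(panmethyl_set)
    with_sites = {s.protein_id for s in sites}
    baits = manifest.bait_samples()
    run_of = {sid: manifest.run_of(sid) for sid in baits}
    universe = sorted(set(matrix.proteins) | with_sites | pan)
    sub = matrix.df
    out = []
    for pid in universe:
        runs: set[str] = set()
        if pid in matrix.df.index:
            row = sub.loc[pid]
            runs = {run_of[s] for s in baits if int(row[s]) > 0}
        n_exp = len(runs)
        enriched = pid in pan
        has_site = pid in with_sites
        out.append(
            CandidateTarget(
                protein_id=pid,
                coip_in_n_experiments=n_exp,
                panmethyl_enriched=enriched,
                has_called_site=has_site,
                is_direct_candidate=(
                    n_exp >= min_experiments and enriched and has_site
                ),
            )
        )
    return out
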