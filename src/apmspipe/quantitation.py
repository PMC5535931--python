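"""Spectral-count quantitation primitives.

Semi-quantitative AP-MS compares how many MS/MS spectra map to each prey
protein in bait pull-downs versus isotype (IgG) controls.  This module
provides the four primitives the downstream filters are built from:

* exclusive spectrum counts (shared peptides removed after a minimal
  Occam protein grouping),
* floored fold change of bait over control group means (a 0.1 floor
  substitutes for absent spectra, e.g. in IgG controls),
* a one-sided Fisher exact test per protein on spectra-vs-everything-else
  2x2 tables, and
* Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design_io import CountMatrix, PeptideEvidence, SampleManifest, ValidationError

__all__ = [
    "FoldChangeRecord",
    "ExactTestRecord",
    "occam_group_proteins",
    "compute_exclusive_counts",
    "fold_change_over_control",
    "hypergeom_tail_p",
    "fisher_enrichment",
    "bh_adjust",
]

DEFAULT_FLOOR = 0.1


@dataclass(frozen=True)
class FoldChangeRecord:
    """Floored ratio of bait-group mean to control-group mean spectra."""

    protein_id: str
    bait_mean: float
    control_mean: float
    floor: float
    fold_change: float


@dataclass(frozen=True)
class ExactTestRecord:
    """Fisher exact test of a protein's spectra against the rest.

    ``table`` is ((x_bait, rest_bait), (x_ctrl, rest_ctrl)) where the row
    totals are the summed spectra of the bait and control groups over all
    quantified proteins.
    """

    protein_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    q_value: float


def occam_group_proteins(grouping: Mapping[str, set[str] | frozenset[str]]) -> dict[str, str]:
    """Collapse proteins into minimal groups by their peptide evidence.

    ``grouping`` maps each peptide to the set of proteins it matches.
    Proteins with identical peptide sets merge into one group; a protein
    whose peptide set is strictly contained in another's (subsumed) merges
    into the superset protein's group.  Returns protein -> group id, where
    a merged group id is the "+"-joined sorted member list.
    """
    pep_sets: dict[str, frozenset[str]] = {}
    for pep, prots in grouping.items():
        for p in prots:
            pep_sets.setdefault(p, frozenset())
    tmp: dict[str, set[str]] = {p: set() for p in pep_sets}
    for pep, prots in grouping.items():
        for p in prots:
            tmp[p].add(pep)
    peptide_of = {p: frozenset(s) for p, s in tmp.items()}

    # identical sets merge
    by_set: dict[frozenset[str], list[str]] = {}
    for p, s in peptide_of.items():
        by_set.setdefault(s, []).append(p)

    # subsumption: a set strictly contained in another merges into that
    # superset's group; processed largest-first so chains resolve, ties
    # broken lexicographically for determinism.
    sets = sorted(by_set, key=lambda s: (-len(s), tuple(sorted(s))))
    root_of: dict[frozenset[str], frozenset[str]] = {}
    for s in sets:
        root = s
        for t in sets:
            if len(t) > len(s) and s < t:
                root = root_of[t]
                break
        root_of[s] = root

    groups: dict[str, str] = {}
    merged_members: dict[frozenset[str], list[str]] = {}
    for s, members in by_set.items():
        root = root_of[s]
        merged_members.setdefault(root, []).extend(members)
    for root, members in merged_members.items():
        gid = "+".join(sorted(members))
        for m in members:
            groups[m] = gid
    return groups


def compute_exclusive_counts(
    evidence: Sequence[PeptideEvidence],
    grouping: Mapping[str, set[str] | frozenset[str]],
) -> CountMatrix:
    """Exclusive spectrum counts: drop spectra from peptides shared between
    protein groups.

    After Occam grouping (identical/subsumed peptide sets merged), a
    peptide contributes its ``n_total_spectra`` to a (group, sample) cell
    only if it maps to exactly one group.
    """
    groups = occam_group_proteins(grouping)
    pep_groups: dict[str, set[str]] = {}
    for pep, prots in grouping.items():
        pep_groups[pep] = {groups[p] for p in prots}
    cells: dict[tuple[str, str], int] = {}
    all_groups = sorted(set(groups.values()))
    all_samples: list[str] = []
    for ev in evidence:
        if ev.peptide_seq not in pep_groups:
            raise ValidationError(f"peptide absent from grouping: {ev.peptide_seq!r}")
        if ev.sample_id not in all_samples:
            all_samples.append(ev.sample_id)
        gset = pep_groups[ev.peptide_seq]
        if len(gset) == 1:
            (gid,) = gset
            key = (gid, ev.sample_id)
            cells[key] = cells.get(key, 0) + ev.n_total_spectra
    df = pd.DataFrame(0, index=all_groups, columns=all_samples, dtype=np.int64)
    for (gid, sid), n in cells.items():
        df.loc[gid, sid] = n
    df.index.name = "protein_id"
    return CountMatrix(df=df, count_kind="exclusive_spectra")


def fold_change_over_control(
    matrix: CountMatrix,
    bait_samples: Sequence[str],
    control_samples: Sequence[str],
    floor: float = DEFAULT_FLOOR,
) -> list[FoldChangeRecord]:
    """Per-protein floored fold change of bait mean over control mean.

    Group means (not sums) are used so unequal group sizes do not bias the
    ratio; the floor replaces means below it, so a protein absent from both
    groups has fold change exactly 1.
    """
    if not bait_samples or not control_samples:
        raise ValidationError("bait and control subsets must be non-empty")
    if set(bait_samples) & set(control_samples):
        raise ValidationError("bait and control subsets overlap")
    if floor <= 0:
        raise ValidationError("floor must be positive")
    bait_mean = matrix.group_mean(bait_samples)
    ctrl_mean = matrix.group_mean(control_samples)
    out = []
    for pid in matrix.proteins:
        b, c = float(bait_mean[pid]), float(ctrl_mean[pid])
        fc = max(b, floor) / max(c, floor)
        out.append(
            FoldChangeRecord(
                protein_id=pid, bait_mean=b, control_mean=c, floor=floor, fold_change=fc
            )
        )
    return out


def hypergeom_tail_p(x_bait, n_bait, x_ctrl, n_ctrl):
    """One-sided Fisher p for table [[x_bait, n_bait-x_bait],
    [x_ctrl, n_ctrl-x_ctrl]]: upper hypergeometric tail P(X >= x_bait)
    with population n_bait + n_ctrl, n_bait "bait" slots and
    x_bait + x_ctrl drawn.  Vectorized over array inputs."""
    xb = np.asarray(x_bait)
    xc = np.asarray(x_ctrl)
    p = stats.hypergeom.sf(xb - 1, n_bait + n_ctrl, n_bait, xb + xc)
    p = np.where(np.isnan(p), 1.0, p)  # empty margins: vacuous tail
    return np.clip(p, 0.0, 1.0)


def fisher_enrichment(
    matrix: CountMatrix,
    bait_samples: Sequence[str],
    control_samples: Sequence[str],
) -> list[ExactTestRecord]:
    """One-sided Fisher exact test for bait enrichment, per protein.

    For protein i with x_bait spectra summed over bait samples (group total
    N_bait over all proteins) and x_ctrl over controls (total N_ctrl), the
    2x2 table is [[x_bait, N_bait-x_bait], [x_ctrl, N_ctrl-x_ctrl]] and p
    is the upper hypergeometric tail P(X >= x_bait).  q-values are BH over
    all tested proteins.
    """
    if not bait_samples or not control_samples:
        raise ValidationError("bait and control subsets must be non-empty")
    x_bait = matrix.subset(bait_samples).sum(axis=1).astype(int)
    x_ctrl = matrix.subset(control_samples).sum(axis=1).astype(int)
    n_bait = int(x_bait.sum())
    n_ctrl = int(x_ctrl.sum())
    if n_bait + n_ctrl == 0:
        raise ValidationError("no spectra in matrix")
    xb = x_bait.to_numpy()
    xc = x_ctrl.to_numpy()
    p = hypergeom_tail_p(xb, n_bait, xc, n_ctrl)
    q = bh_adjust(p)
    records = []
    for i, pid in enumerate(matrix.proteins):
        table = (
            (int(xb[i]), n_bait - int(xb[i])),
            (int(xc[i]), n_ctrl - int(xc[i])),
        )
        records.append(
            ExactTestRecord(
                protein_id=pid, table=table, p_value=float(p[i]), q_value=float(q[i])
            )
        )
    return records


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
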