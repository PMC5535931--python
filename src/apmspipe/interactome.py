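"""High-confidence bait interactome construction.

Combines four evidence streams into a per-prey verdict:

* floored fold change of bait over IgG-control spectra (default gate 2.0),
* a one-sided Fisher exact test with BH correction (reported, not gating),
* a probabilistic interaction confidence score (default gate 0.8),
* a contaminant-frequency filter against a reference profile of control
  AP-MS runs.

The confidence score is a two-component Poisson posterior: with prior
probability ``prior_true`` a prey's bait counts are drawn at the bait rate
(its mean bait count, clamped from below by the control rate), otherwise at
the background rate (its mean control count, floored).  The per-replicate
posterior probabilities of the interaction component are averaged over
bait replicates.  This is a deliberately small, fully-specified stand-in
for the heavier replicate-order-statistic interaction scorers used in the
field; the 0.8 default cut-off plays the same screening role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design_io import (
    ENUM_REGISTRY,
    ContaminantProfile,
    CountMatrix,
    SampleManifest,
    ValidationError,
)
from .quantitation import (
    DEFAULT_FLOOR,
    FoldChangeRecord,
    fisher_enrichment,
    fold_change_over_control,
)

__all__ = [
    "Verdict",
    "ScoreModel",
    "EnrichmentRecord",
    "score_interactions",
    "filter_contaminants",
    "build_interactome",
]


class Verdict(str, Enum):
    HIGH_CONFIDENCE = "high_confidence"
    REJECTED = "rejected"


ENUM_REGISTRY["Verdict"] = Verdict


@dataclass(frozen=True)
class ScoreModel:
    """Parameters of the Poisson-mixture confidence score."""

    prior_true: float = 0.5
    count_floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_true < 1.0:
            raise ValidationError("prior_true must lie in (0, 1)")
        if self.count_floor <= 0:
            raise ValidationError("count_floor must be positive")


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-prey statistics and the high-confidence verdict.

    ``high_confidence`` requires fold_change >= fc_threshold, score >=
    score_threshold, and no contaminant flag; p/q and the reference-list
    annotation are carried for reporting.
    """

    protein_id: str
    bait_mean: float
    control_mean: float
    fold_change: float
    p_value: float
    q_value: float
    confidence_score: float
    contaminant_flag: bool
    n_bait_detected: int
    in_reference: bool
    verdict: Verdict


def score_interactions(
    matrix: CountMatrix,
    manifest: SampleManifest,
    model: ScoreModel | None = None,
    bait_samples: Sequence[str] | None = None,
    control_samples: Sequence[str] | None = None,
) -> pd.Series:
    """Per-protein posterior confidence that the bait-prey pair is real.

    For each protein, background rate lam0 = max(mean control count,
    floor) and interaction rate lam1 = max(mean bait count, lam0).  For
    bait replicate count x_j the posterior weight of the interaction
    component is

        r_j = pi * Pois(x_j; lam1) / (pi * Pois(x_j; lam1) + (1-pi) * Pois(x_j; lam0))

    and the score is the mean of r_j over bait replicates.  When the bait
    mean does not exceed the control mean the likelihood ratio is 1 and
    the score equals the prior.
    """
    model = model or ScoreModel()
    baits = list(bait_samples) if bait_samples is not None else manifest.bait_samples()
    ctrls = (
        list(control_samples)
        if control_samples is not None
        else manifest.control_samples()
    )
    if not baits:
        raise ValidationError("no bait replicates")
    if not ctrls:
        raise ValidationError("no control samples")
    x = matrix.subset(baits).to_numpy(dtype=float)  # proteins x replicates
    lam0 = np.maximum(matrix.group_mean(ctrls).to_numpy(), model.count_floor)
    lam1 = np.maximum(np.maximum(x.mean(axis=1), model.count_floor), lam0)
    pi = model.prior_true
    # log-likelihood ratio per replicate, Poisson: x*log(l1/l0) - (l1-l0)
    llr = x * (np.log(lam1) - np.log(lam0))[:, None] - (lam1 - lam0)[:, None]
    r = 1.0 / (1.0 + (1.0 - pi) / pi * np.exp(-llr))
    scores = r.mean(axis=1)
    return pd.Series(scores, index=matrix.proteins, name="confidence_score")


def filter_contaminants(
    bait_means: Mapping[str, float],
    profile: Sequence[ContaminantProfile],
    max_frequency: float = 0.5,
    fc_threshold: float = 2.0,
    floor: float = DEFAULT_FLOOR,
) -> set[str]:
    """Flag frequent background binders that are not differentially enriched.

    A protein is flagged iff (a) it was detected in more than
    ``max_frequency`` of the reference control experiments AND (b) its
    bait mean over the profile's expected background count (floored) is
    below ``fc_threshold``.  Proteins absent from the profile are never
    flagged, and genuinely enriched frequent fliers survive clause (b).
    """
    flagged: set[str] = set()
    for prof in profile:
        if prof.protein_id not in bait_means:
            continue
        if prof.frequency <= max_frequency:
            continue
        expected = max(prof.mean_count, floor)
        fc = max(bait_means[prof.protein_id], floor) / expected
        if fc < fc_threshold:
            flagged.add(prof.protein_id)
    return flagged


def build_interactome(
    matrix: CountMatrix,
    manifest: SampleManifest,
    model: ScoreModel | None = None,
    profile: Sequence[ContaminantProfile] | None = None,
    fc_threshold: float = 2.0,
    score_threshold: float = 0.8,
    reference: Iterable[str] | None = None,
    floor: float = DEFAULT_FLOOR,
    contaminant_max_frequency: float = 0.5,
    q_threshold: float = 0.05,
) -> list[EnrichmentRecord]:
    """Compose fold change, exact test, confidence score and contaminant
    filter into per-prey verdicts.

    All bait samples (both conditions) are compared against all isotype
    controls, mirroring a global bait-vs-IgG screen.  The high-confidence
    verdict requires all four gates: fold change, confidence score, the
    BH-corrected exact test (set ``q_threshold=1`` to disable), and no
    contaminant flag.
    """
    baits = manifest.bait_samples()
    ctrls = manifest.control_samples()
    fc_records = {
        r.protein_id: r
        for r in fold_change_over_control(matrix, baits, ctrls, floor=floor)
    }
    exact = {r.protein_id: r for r in fisher_enrichment(matrix, baits, ctrls)}
    scores = score_interactions(
        matrix, manifest, model=model or ScoreModel(count_floor=floor)
    )
    bait_means = {pid: fc_records[pid].bait_mean for pid in matrix.proteins}
    flagged = (
        filter_contaminants(
            bait_means,
            profile,
            max_frequency=contaminant_max_frequency,
            fc_threshold=fc_threshold,
            floor=floor,
        )
        if profile
        else set()
    )
    detected = (matrix.subset(baits) > 0).sum(axis=1)
    ref = set(reference) if reference is not None else set()
    records = []
    for pid in matrix.proteins:
        fc = fc_records[pid]
        score = float(scores[pid])
        is_contam = pid in flagged
        ok = (
            fc.fold_change >= fc_threshold
            and score >= score_threshold
            and exact[pid].q_value <= q_threshold
            and not is_contam
        )
        records.append(
            EnrichmentRecord(
                protein_id=pid,
                bait_mean=fc.bait_mean,
                control_mean=fc.control_mean,
                fold_change=fc.fold_change,
                p_value=exact[pid].p_value,
                q_value=exact[pid].q_value,
                confidence_score=score,
                contaminant_flag=is_contam,
                n_bait_detected=int(detected[pid]),
                in_reference=pid in ref,
                verdict=Verdict.HIGH_CONFIDENCE if ok else Verdict.REJECTED,
            )
        )
    return records
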