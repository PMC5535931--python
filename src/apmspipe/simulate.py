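"""Synthetic AP-MS study generator with known ground truth.

Emulates the study design every pipeline stage expects: seven bait IPs
split across two treatment conditions (with matched biological pairs),
five isotype (IgG) controls, and one pan-methyl-lysine IP, spread over
five MS runs.  Spectral counts follow a negative-binomial background
(overdispersed, as spectral counts are); a minority of preys are true
interactors whose bait counts are scaled up, some of those additionally
change with treatment; frequent contaminants are elevated everywhere
including controls and appear in the generated contaminant profile; and
methylated peptides carry binomially sampled modified-spectrum counts
with Beta-distributed per-site occupancy.

All randomness flows through one ``numpy.random.Generator`` created from
``config.seed``; the same config yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .design_io import (
    Antibody,
    Condition,
    ContaminantProfile,
    CountMatrix,
    MethylState,
    Mod,
    PeptideEvidence,
    Sample,
    SampleManifest,
    ValidationError,
)

__all__ = ["SimulationConfig", "GroundTruth", "StudyData", "generate_study"]

_AA = np.array(list("ACDEFGHILMNPQSTVWY"))  # no K/R: placed explicitly


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated design: 4 + 3 bait IPs, 5 IgG controls,
    1 pan-methyl IP, 2 matched pairs; low-abundance overdispersed
    background (mean 2 spectra, NB dispersion 10); strong interaction
    (5x) and condition (4x) effects.
    """

    seed: int = 0
    n_proteins: int = 500
    n_true_interactors: int = 20
    n_condition_specific: int = 8
    n_bait_untreated: int = 4
    n_bait_treated: int = 3
    n_controls: int = 5
    n_pairs: int = 2
    background_mean: float = 2.0
    dispersion: float = 10.0
    interaction_effect: float = 5.0
    condition_effect: float = 4.0
    contaminant_fraction: float = 0.05
    contaminant_effect: float = 5.0
    n_methyl_sites: int = 30
    occupancy_alpha: float = 2.0
    occupancy_beta: float = 8.0
    methyl_depth: float = 25.0
    panmethyl_effect: float = 4.0
    n_low_conf_sites: int = 5
    profile_experiments: int = 50

    def __post_init__(self) -> None:
        n_contam = int(round(self.contaminant_fraction * self.n_proteins))
        if self.n_true_interactors + self.n_condition_specific + n_contam > self.n_proteins:
            raise ValidationError(
                "n_true_interactors + n_condition_specific + contaminants exceed n_proteins"
            )
        if self.n_pairs > min(self.n_bait_untreated, self.n_bait_treated):
            raise ValidationError("n_pairs exceeds bait replicates of a condition")
        for name in (
            "background_mean",
            "dispersion",
            "interaction_effect",
            "condition_effect",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.interaction_effect < 1 or self.condition_effect < 1:
            raise ValidationError("effects are multipliers >= 1")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValidationError("contaminant_fraction outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    true_interactors: frozenset[str]
    condition_specific: dict[str, str]  # protein -> "up_in_untreated"/"up_in_treated"
    contaminants: frozenset[str]
    #: (protein, position, residue, state, occ untreated, occ treated)
    methyl_sites: tuple[tuple[str, int, str, MethylState, float, float], ...]


class StudyData(NamedTuple):
    manifest: SampleManifest
    matrix: CountMatrix
    evidence: list[PeptideEvidence]
    profile: list[ContaminantProfile]
    truth: GroundTruth


def _nb(rng: np.random.Generator, mean, k: float, size) -> np.ndarray:
    """Negative binomial with given mean and dispersion k (k -> inf is
    Poisson)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size)


def _build_manifest(cfg: SimulationConfig) -> SampleManifest:
    samples: list[Sample] = []
    n_runs = max(cfg.n_bait_untreated, cfg.n_bait_treated, cfg.n_controls, 1)
    for i in range(cfg.n_bait_untreated):
        pair = f"p{i + 1}" if i < cfg.n_pairs else None
        samples.append(
            Sample(f"ezh2_untx_{i + 1}", Antibody.BAIT, Condition.UNTREATED, pair, f"r{i % n_runs + 1}")
        )
    for i in range(cfg.n_bait_treated):
        pair = f"p{i + 1}" if i < cfg.n_pairs else None
        samples.append(
            Sample(f"ezh2_atra_{i + 1}", Antibody.BAIT, Condition.TREATED, pair, f"r{i % n_runs + 1}")
        )
    for i in range(cfg.n_controls):
        cond = Condition.UNTREATED if i % 2 == 0 else Condition.TREATED
        samples.append(
            Sample(f"igg_{i + 1}", Antibody.ISOTYPE_CONTROL, cond, None, f"r{i % n_runs + 1}")
        )
    samples.append(
        Sample("panmethyl_1", Antibody.PAN_METHYL, Condition.UNTREATED, None, f"r{n_runs}")
    )
    return SampleManifest(tuple(samples))


def generate_study(config: SimulationConfig) -> StudyData:
    """Generate a complete synthetic study: manifest, spectral-count
    matrix, methyl-peptide evidence, contaminant profile, ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    manifest = _build_manifest(cfg)
    proteins = [f"P{i:04d}" for i in range(cfg.n_proteins)]

    order = rng.permutation(cfg.n_proteins)
    true_idx = order[: cfg.n_true_interactors]
    cond_idx = order[
        cfg.n_true_interactors : cfg.n_true_interactors + cfg.n_condition_specific
    ]
    n_contam = int(round(cfg.contaminant_fraction * cfg.n_proteins))
    off = cfg.n_true_interactors + cfg.n_condition_specific
    contam_idx = order[off : off + n_contam]

    true_set = frozenset(proteins[i] for i in true_idx)
    contam_set = frozenset(proteins[i] for i in contam_idx)
    cond_dir = {
        proteins[i]: ("up_in_untreated" if j % 2 == 0 else "up_in_treated")
        for j, i in enumerate(cond_idx)
    }

    baits_u = manifest.bait_samples(Condition.UNTREATED)
    baits_t = manifest.bait_samples(Condition.TREATED)
    ctrls = manifest.control_samples()
    pans = manifest.pan_methyl_samples()
    sample_ids = manifest.sample_ids

    mean = np.full((cfg.n_proteins, len(sample_ids)), cfg.background_mean)
    col = {s: j for j, s in enumerate(sample_ids)}
    bait_cols = [col[s] for s in baits_u + baits_t]
    for i in true_idx:
        mean[i, bait_cols] *= cfg.interaction_effect
    for i in cond_idx:
        # condition-specific preys interact (pass the IgG gate) and change
        # further with treatment in one direction
        mean[i, bait_cols] *= cfg.interaction_effect
    for pid, direction in cond_dir.items():
        i = proteins.index(pid)
        up_cols = [col[s] for s in (baits_u if direction == "up_in_untreated" else baits_t)]
        mean[i, up_cols] *= cfg.condition_effect
    for i in contam_idx:
        mean[i, :] *= cfg.contaminant_effect

    # methylated proteins get elevated pan-methyl pull-down counts
    n_sites = cfg.n_methyl_sites
    carriers = [proteins[i] for i in true_idx] or proteins
    site_proteins = [carriers[j % len(carriers)] for j in range(n_sites)]
    for pid in set(site_proteins):
        i = proteins.index(pid)
        for s in pans:
            mean[i, col[s]] *= cfg.panmethyl_effect

    counts = _nb(rng, mean, cfg.dispersion, mean.shape)
    df = pd.DataFrame(counts.astype(np.int64), index=proteins, columns=sample_ids)
    df.index.name = "protein_id"
    matrix = CountMatrix(df=df, count_kind="total_spectra")

    # --- methyl evidence -----------------------------------------------------
    evidence: list[PeptideEvidence] = []
    truth_sites = []
    used_positions: set[tuple[str, int]] = set()
    for j in range(n_sites):
        pid = site_proteins[j]
        while True:
            pos = int(rng.integers(20, 400))
            if (pid, pos) not in used_positions:
                used_positions.add((pid, pos))
                break
        length = int(rng.integers(8, 21))
        offset = int(rng.integers(1, length + 1))
        start = pos - offset + 1
        if start < 1:
            offset = min(offset, pos)
            start = pos - offset + 1
        residue = "K" if rng.random() < 0.75 else "R"
        state = MethylState(
            rng.choice(["me1", "me2", "me3"] if residue == "K" else ["me1", "me2"])
        )
        seq = rng.choice(_AA, size=length)
        seq[offset - 1] = residue
        peptide = "".join(seq)
        occ_u = float(rng.beta(cfg.occupancy_alpha, cfg.occupancy_beta))
        occ_t = float(rng.beta(cfg.occupancy_alpha, cfg.occupancy_beta))
        truth_sites.append((pid, pos, residue, state, occ_u, occ_t))
        for cond, samples, occ in (
            (Condition.UNTREATED, baits_u, occ_u),
            (Condition.TREATED, baits_t, occ_t),
        ):
            per_sample = cfg.methyl_depth / max(len(samples), 1)
            for sid in samples:
                n_total = int(rng.poisson(per_sample))
                n_mod = int(rng.binomial(n_total, occ)) if n_total else 0
                evidence.append(
                    PeptideEvidence(
                        protein_id=pid,
                        protein_prob=0.9995,
                        peptide_seq=peptide,
                        peptide_prob=float(rng.uniform(0.90, 1.0)),
                        start_index=start,
                        stop_index=start + length - 1,
                        mods=(Mod(offset=offset, residue=residue, state=state),),
                        sample_id=sid,
                        n_mod_spectra=n_mod,
                        n_total_spectra=n_total,
                    )
                )

    # low-confidence decoy sites that the probability gates must remove
    for j in range(cfg.n_low_conf_sites):
        pid = proteins[int(rng.integers(0, cfg.n_proteins))]
        length = int(rng.integers(8, 16))
        offset = int(rng.integers(1, length + 1))
        start = int(rng.integers(1, 300))
        seq = rng.choice(_AA, size=length)
        seq[offset - 1] = "K"
        n_total = int(rng.poisson(5)) + 1
        evidence.append(
            PeptideEvidence(
                protein_id=pid,
                protein_prob=0.9995,
                peptide_seq="".join(seq),
                peptide_prob=float(rng.uniform(0.30, 0.79)),
                start_index=start,
                stop_index=start + length - 1,
                mods=(Mod(offset=offset, residue="K", state=MethylState.ME1),),
                sample_id=baits_u[0],
                n_mod_spectra=int(rng.binomial(n_total, 0.5)),
                n_total_spectra=n_total,
            )
        )

    # --- contaminant profile -------------------------------------------------
    profile: list[ContaminantProfile] = []
    n_exp = cfg.profile_experiments
    for i in sorted(contam_idx):
        n_det = int(rng.binomial(n_exp, 0.85))
        profile.append(
            ContaminantProfile(
                protein_id=proteins[i],
                n_detected=n_det,
                n_experiments=n_exp,
                mean_count=cfg.background_mean * cfg.contaminant_effect,
            )
        )
    # a sprinkle of innocuous low-frequency entries
    others = [i for i in order[off + n_contam :][: max(cfg.n_proteins // 10, 1)]]
    for i in sorted(others):
        profile.append(
            ContaminantProfile(
                protein_id=proteins[i],
                n_detected=int(rng.binomial(n_exp, 0.1)),
                n_experiments=n_exp,
                mean_count=cfg.background_mean,
            )
        )

    truth = GroundTruth(
        true_interactors=true_set,
        condition_specific=cond_dir,
        contaminants=contam_set,
        methyl_sites=tuple(truth_sites),
    )
    return StudyData(manifest, matrix, evidence, profile, truth)
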