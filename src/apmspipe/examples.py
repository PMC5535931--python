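"""Bundled worked example: methyl-peptide evidence from an EZH2 AP-MS
study in HL-60 AML cells.

The evidence mirrors a published methylation-hit table: peptide sequences
as printed (with bold ``**`` markers around the modified lysine and
line-break hyphens, which the parser strips), 1-based protein-relative
coordinates, the methyl state of each annotated lysine, and
modified/total spectrum counts before and after AtRA treatment.  One
histone H3.1 row is coordinate-inconsistent as printed (sequence length
13 vs stated span 28-41); it is retained with its consistency flag set to
False, exactly as a real parsed table would be.

``author_site_labels`` preserves the residue names used in the source for
sites whose stated label differs from (or confirms) the computed
position; labels are annotations only and never enter computation.
"""

from __future__ import annotations

from .design_io import (
    Antibody,
    Condition,
    PeptideEvidence,
    Sample,
    SampleManifest,
    MethylState,
)
from .design_io import _parse_mods  # shared mod grammar

__all__ = [
    "ezh2_example_manifest",
    "ezh2_methyl_evidence",
    "author_site_labels",
]

_UNTX_SAMPLE = "ezh2_untx_1"
_ATRA_SAMPLE = "ezh2_atra_1"

# protein, printed peptide, start, stop, mods, (mod, total) -AtRA, (mod, total) +AtRA
_ROWS: list[tuple[str, str, int, int, str, tuple[int, int], tuple[int, int]]] = [
    # Lys mono-methylation
    ("CBX3", "W**K**DSDEADLVLAK", 142, 154, "K2:me1", (1, 8), (0, 0)),
    ("EZH2", "YSQADAL**K**YVGIER", 728, 741, "K8:me1", (2, 131), (2, 106)),
    ("Histone H1.2", "**K**ASGPPVSELITK", 34, 46, "K1:me1", (2, 96), (1, 20)),
    ("Histone H3.1", "KSAPATGGV**K**PHR", 28, 41, "K10:me1", (0, 18), (1, 6)),
    ("Histone H3.1", "EIAQDF**K**TDLR", 74, 84, "K7:me1", (1, 18), (0, 6)),
    ("MT1X", "MDPNCSCSPVGSCAC-AGSCKC**K**ECKCTSCK", 1, 30, "K22:me1", (1, 1), (0, 0)),
    ("RL36L", "KQSGYGGQT**K**PIFR", 44, 57, "K10:me1", (11, 33), (8, 18)),
    (
        "SUZ12",
        "APQ**K**HGGGGGGGSGPSAGS-GGGGFGGSAAVAAATASGGK",
        2,
        40,
        "K4:me1",
        (2, 154),
        (0, 138),
    ),
    # Lys di-methylation
    ("eEF1A1", "GSF**K**YAWVLDK", 52, 62, "K4:me2", (7, 59), (1, 17)),
    ("eEF1A1", "MDSTEPPYSQ**K**R", 155, 166, "K11:me2", (0, 59), (1, 17)),
    ("Histone H3.1", "**K**SAPATGGVKKPHR", 28, 41, "K1:me2", (1, 18), (3, 6)),
    ("Histone H4", "**K**VLRDNIQGITKPAIR", 21, 36, "K1:me2", (0, 86), (1, 23)),
    ("MYO1D", "S**K**DTCIVISGESGAGKTEASK", 93, 113, "K2:me2", (0, 0), (3, 3)),
    ("RBP56", "GPMTGSSGGDRGGF**K**", 196, 210, "K15:me2", (8, 22), (0, 6)),
    (
        "TR150",
        "DSRPSQAAGDNQGDEA**K**EQ-TFSGGTSQDTK",
        186,
        215,
        "K17:me2",
        (7, 32),
        (0, 0),
    ),
    # Lys tri-methylation
    ("ADT2", "QY**K**GIIDCVVR", 50, 60, "K3:me3", (4, 21), (1, 13)),
    ("HNRPQ", "GGNVGG**K**R", 558, 565, "K7:me3", (1, 4), (1, 6)),
    (
        "MT1X",
        "MDPNCSCSPVGSCACAGSC-**K**CKEC**K**CTSC**K**",
        1,
        30,
        "K20:me3;K25:me3;K30:me3",
        (1, 1),
        (0, 0),
    ),
    ("ALYREF", "AD**K**MDMSLDDIIK", 2, 14, "K3:me3", (0, 27), (1, 19)),
]

#: source-stated residue labels keyed by (protein, computed position, state).
#: Where the source's own convention disagrees with the computed index
#: (e.g. CBX3 "K142" vs computed K143, SUZ12 "K4" vs K5, ADT2 stated both
#: "K51" and "K52"), the computed position is authoritative and the label
#: is carried verbatim.
author_site_labels: dict[tuple[str, int, MethylState], str] = {
    ("CBX3", 143, MethylState.ME1): "K142",
    ("EZH2", 735, MethylState.ME1): "K735",
    ("SUZ12", 5, MethylState.ME1): "K4",
    ("eEF1A1", 55, MethylState.ME2): "K55",
    ("eEF1A1", 165, MethylState.ME2): "K165",
    ("Histone H4", 21, MethylState.ME2): "K20",
    ("ADT2", 52, MethylState.ME3): "K51/K52",
    ("ALYREF", 4, MethylState.ME3): "K4",
}


def ezh2_example_manifest() -> SampleManifest:
    """The 13-sample EZH2 study design: 7 bait IPs across two conditions
    (two matched pairs), 5 IgG controls, 1 pan-methyl-lysine IP, 5 MS runs."""
    samples = [
        Sample("ezh2_untx_1", Antibody.BAIT, Condition.UNTREATED, "p1", "r1"),
        Sample("ezh2_untx_2", Antibody.BAIT, Condition.UNTREATED, "p2", "r2"),
        Sample("ezh2_untx_3", Antibody.BAIT, Condition.UNTREATED, None, "r3"),
        Sample("ezh2_untx_4", Antibody.BAIT, Condition.UNTREATED, None, "r4"),
        Sample("ezh2_atra_1", Antibody.BAIT, Condition.TREATED, "p1", "r1"),
        Sample("ezh2_atra_2", Antibody.BAIT, Condition.TREATED, "p2", "r2"),
        Sample("ezh2_atra_3", Antibody.BAIT, Condition.TREATED, None, "r3"),
        Sample("igg_1", Antibody.ISOTYPE_CONTROL, Condition.UNTREATED, None, "r1"),
        Sample("igg_2", Antibody.ISOTYPE_CONTROL, Condition.UNTREATED, None, "r2"),
        Sample("igg_3", Antibody.ISOTYPE_CONTROL, Condition.UNTREATED, None, "r3"),
        Sample("igg_4", Antibody.ISOTYPE_CONTROL, Condition.TREATED, None, "r4"),
        Sample("igg_5", Antibody.ISOTYPE_CONTROL, Condition.TREATED, None, "r5"),
        Sample("panmethyl_1", Antibody.PAN_METHYL, Condition.UNTREATED, None, "r5"),
    ]
    return SampleManifest(tuple(samples))


def ezh2_methyl_evidence() -> list[PeptideEvidence]:
    """The worked-example methyl evidence: one record per table row and
    condition (19 rows x 2 conditions = 38 records)."""
    records = []
    for protein, seq, start, stop, mods, untx, atra in _ROWS:
        for sample_id, (n_mod, n_total) in (
            (_UNTX_SAMPLE, untx),
            (_ATRA_SAMPLE, atra),
        ):
            records.append(
                PeptideEvidence(
                    protein_id=protein,
                    protein_prob=0.999,
                    peptide_seq=seq,
                    peptide_prob=0.95,
                    start_index=start,
                    stop_index=stop,
                    mods=_parse_mods(mods),
                    sample_id=sample_id,
                    n_mod_spectra=n_mod,
                    n_total_spectra=n_total,
                )
            )
    return records
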