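"""Site occupancy, position mapping, probability gates and triangulation."""

import numpy as np
import pandas as pd
import pytest

from apmspipe.design_io import (
    CountMatrix,
    MethylState,
    Mod,
    PeptideEvidence,
    ValidationError,
)
from apmspipe.examples import ezh2_example_manifest, ezh2_methyl_evidence
from apmspipe.methylproteome import (
    call_methyl_sites,
    format_occupancy,
    map_absolute_position,
    panmethyl_enrichment,
    site_occupancy,
    triangulate_targets,
)


# --- occupancy --------------------------------------------------------------


@pytest.mark.parametrize(
    "n_mod, n_total, text",
    [
        (7, 59, "11.9%"),
        (1, 8, "12.5%"),
        (0, 0, "ND"),
        (3, 6, "50%"),
        (5, 5, "100%"),
        (1, 20, "5%"),
        (11, 33, "33.3%"),
        (7, 32, "21.9%"),  # 21.875 rounds half away from zero
        (0, 18, "0%"),
    ],
)
def test_site_occupancy_formatting(n_mod, n_total, text):
    assert format_occupancy(site_occupancy(n_mod, n_total)) == text


def test_occupancy_invariants():
    occ = site_occupancy(7, 59)
    assert occ.percent == pytest.approx(11.9)
    assert not occ.nd
    assert site_occupancy(0, 0).nd
    with pytest.raises(ValidationError):
        site_occupancy(3, 2)


# --- position mapping -------------------------------------------------------


def test_map_absolute_position_examples():
    ev = PeptideEvidence(
        protein_id="eEF1A1",
        protein_prob=1.0,
        peptide_seq="GSFKYAWVLDK",
        peptide_prob=1.0,
        start_index=52,
        stop_index=62,
        mods=(Mod(4, "K", MethylState.ME2),),
    )
    assert map_absolute_position(ev, ev.mods[0]) == 55
    ev2 = PeptideEvidence(
        protein_id="eEF1A1",
        protein_prob=1.0,
        peptide_seq="MDSTEPPYSQKR",
        peptide_prob=1.0,
        start_index=155,
        stop_index=166,
        mods=(Mod(11, "K", MethylState.ME2),),
    )
    assert map_absolute_position(ev2, ev2.mods[0]) == 165
    ev3 = PeptideEvidence(
        protein_id="X",
        protein_prob=1.0,
        peptide_seq="KAAA",
        peptide_prob=1.0,
        start_index=1,
        stop_index=4,
        mods=(Mod(1, "K", MethylState.ME1),),
    )
    assert map_absolute_position(ev3, ev3.mods[0]) == 1


def test_map_rejects_inconsistent_evidence():
    ev = PeptideEvidence(
        protein_id="H3",
        protein_prob=1.0,
        peptide_seq="KSAPATGGVKPHR",
        peptide_prob=1.0,
        start_index=28,
        stop_index=41,  # span 14 vs length 13
        mods=(Mod(10, "K", MethylState.ME1),),
    )
    assert not ev.coords_consistent
    with pytest.raises(ValidationError, match="coords_consistent"):
        map_absolute_position(ev, ev.mods[0])


def test_position_round_trips_through_random_peptide_windows():
    rng = np.random.default_rng(9)
    for _ in range(50):
        pos = int(rng.integers(5, 500))
        length = int(rng.integers(6, 25))
        offset = int(rng.integers(1, length + 1))
        start = max(1, pos - offset + 1)
        offset = pos - start + 1
        if offset > length:
            continue
        seq = list("A" * length)
        seq[offset - 1] = "K"
        ev = PeptideEvidence(
            protein_id="P",
            protein_prob=1.0,
            peptide_seq="".join(seq),
            peptide_prob=1.0,
            start_index=start,
            stop_index=start + length - 1,
            mods=(Mod(offset, "K", MethylState.ME1),),
        )
        assert map_absolute_position(ev, ev.mods[0]) == pos


# --- site calling -----------------------------------------------------------


def _site_ev(prob_protein, prob_peptide, sample="ezh2_untx_1", n_mod=2, n_total=10):
    return PeptideEvidence(
        protein_id="P",
        protein_prob=prob_protein,
        peptide_seq="AAKAA",
        peptide_prob=prob_peptide,
        start_index=10,
        stop_index=14,
        mods=(Mod(3, "K", MethylState.ME1),),
        sample_id=sample,
        n_mod_spectra=n_mod,
        n_total_spectra=n_total,
    )


@pytest.mark.parametrize(
    "pp, pep, kept",
    [
        (0.999, 0.95, True),
        (0.999, 0.80, True),  # inclusive boundary
        (0.999, 0.50, False),
        (0.99, 0.95, False),  # protein gate
    ],
)
def test_probability_gates_inclusive(manifest13, pp, pep, kept):
    sites = call_methyl_sites([_site_ev(pp, pep)], manifest13)
    assert bool(sites) == kept


def test_site_threshold_monotonicity(study):
    """Raising either probability gate never adds a site."""
    base = {
        (s.protein_id, s.position, s.state)
        for s in call_methyl_sites(study.evidence, study.manifest)
    }
    for kw in ({"peptide_prob_min": 0.95}, {"protein_prob_min": 0.9999}):
        tighter = {
            (s.protein_id, s.position, s.state)
            for s in call_methyl_sites(study.evidence, study.manifest, **kw)
        }
        assert tighter <= base


def test_sites_aggregate_per_condition(manifest13):
    evs = [
        _site_ev(0.999, 0.95, "ezh2_untx_1", 2, 10),
        _site_ev(0.999, 0.95, "ezh2_untx_2", 1, 5),
        _site_ev(0.999, 0.95, "ezh2_atra_1", 0, 4),
    ]
    (site,) = call_methyl_sites(evs, manifest13)
    assert site.occ_untreated == (3, 15)
    assert site.occ_treated == (0, 4)
    assert site.position == 12


def test_all_nd_sites_dropped(manifest13):
    (site_ev,) = [_site_ev(0.999, 0.95, n_mod=0, n_total=0)]
    assert call_methyl_sites([site_ev], manifest13) == []


# --- pan-methyl enrichment --------------------------------------------------


def _pan_matrix(manifest, pan_counts, igg_counts):
    df = pd.DataFrame(
        0, index=list(pan_counts), columns=manifest.sample_ids, dtype=np.int64
    )
    for pid, v in pan_counts.items():
        df.loc[pid, "panmethyl_1"] = v
    for pid, v in igg_counts.items():
        for c in manifest.control_samples():
            df.loc[pid, c] = v
    df.index.name = "protein_id"
    return CountMatrix(df=df, count_kind="total_peptides")


def test_panmethyl_ratio_rules(manifest13):
    m = _pan_matrix(
        manifest13,
        {"KEEP": 3, "DROP": 2, "FLOOR": 1},
        {"KEEP": 2, "DROP": 2, "FLOOR": 0},
    )
    kept = panmethyl_enrichment(m, manifest13)
    # 3 vs 2 -> 1.5 inclusive keep; 2 vs 2 -> 1.0 drop; 1 vs 0 -> 1/0.1 keep
    assert kept == {"KEEP", "FLOOR"}


def test_panmethyl_requires_pan_sample(manifest13, small_matrix):
    from apmspipe.design_io import Antibody, Sample, SampleManifest

    no_pan = SampleManifest(
        tuple(s for s in manifest13.samples if s.antibody is not Antibody.PAN_METHYL)
    )
    with pytest.raises(ValidationError, match="pan_methyl"):
        panmethyl_enrichment(small_matrix, no_pan)


# --- triangulation ----------------------------------------------------------


def test_triangulation_three_clause_rule(manifest13):
    sites = call_methyl_sites(
        [_site_ev(0.999, 0.95, "ezh2_untx_1", 2, 10)], manifest13
    )
    # protein P detected in 3 bait runs; Q in one run only
    df = pd.DataFrame(0, index=["P", "Q"], columns=manifest13.sample_ids, dtype=np.int64)
    df.loc["P", ["ezh2_untx_1", "ezh2_untx_2", "ezh2_atra_3"]] = 4  # runs r1, r2, r3
    df.loc["Q", "ezh2_untx_1"] = 4
    df.index.name = "protein_id"
    m = CountMatrix(df=df)
    targets = {
        t.protein_id: t
        for t in triangulate_targets(sites, {"P", "Q"}, m, manifest13)
    }
    assert targets["P"].coip_in_n_experiments == 3
    assert not targets["Q"].is_direct_candidate  # only 1 run
    # give Q a site too: still not a candidate without >= 2 runs
    assert targets["P"].is_direct_candidate == (
        targets["P"].panmethyl_enriched and targets["P"].has_called_site
    )


def test_triangulation_matches_brute_force(study):
    sites = call_methyl_sites(study.evidence, study.manifest)
    pan = panmethyl_enrichment(study.matrix, study.manifest)
    targets = triangulate_targets(sites, pan, study.matrix, study.manifest)
    with_sites = {s.protein_id for s in sites}
    baits = study.manifest.bait_samples()
    for t in targets:
        if t.protein_id in study.matrix.df.index:
            runs = {
                study.manifest.run_of(s)
                for s in baits
                if study.matrix.df.loc[t.protein_id, s] > 0
            }
        else:
            runs = set()
        expected = (
            len(runs) >= 2
            and t.protein_id in pan
            and t.protein_id in with_sites
        )
        assert t.is_direct_candidate == expected


# --- worked example end to end ---------------------------------------------


def test_worked_example_site_calling():
    manifest = ezh2_example_manifest()
    sites = call_methyl_sites(ezh2_methyl_evidence(), manifest)
    by_key = {(s.protein_id, s.position, s.state): s for s in sites}
    k55 = by_key[("eEF1A1", 55, MethylState.ME2)]
    assert format_occupancy(k55.untreated) == "11.9%"
    assert format_occupancy(k55.treated) == "5.9%"
    # the coordinate-inconsistent H3.1 mono row is excluded from calling
    assert ("Histone H3.1", 37, MethylState.ME1) not in by_key
    # tri-methyl MT1X peptide contributes three distinct sites
    mt1x = [k for k in by_key if k[0] == "MT1X" and k[2] is MethylState.ME3]
    assert sorted(k[1] for k in mt1x) == [20, 25, 30]
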