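import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncdev.config import STAGES
from lncdev.screens import (
    StageProfiles,
    correlate_profiles,
    discordant_pair_screen,
    gaban_olp_switching,
    lineage_switch_screen,
    marker_correlation_screen,
    stage_exclusive_screen,
    term_enrichment,
)
from oracles import hypergeom_tail_enumeration, truth_screen_members


def make_profiles(m: dict, de: dict | None = None, expressed=None, is_ncrna=None):
    mdf = pd.DataFrame(m, index=list(STAGES)).T
    mdf.columns = list(STAGES)
    dedf = (
        pd.DataFrame(de, index=list(STAGES)).T.astype(bool)
        if de is not None
        else (mdf.abs() > 1.0)
    )
    expressed = pd.Series(True, index=mdf.index) if expressed is None else expressed
    return StageProfiles(M=mdf, de=dedf, expressed=expressed, is_ncrna=is_ncrna)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_correlation_identity_and_inversion():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert correlate_profiles(x, x) == pytest.approx((1.0, 1.0))
    r, r2 = correlate_profiles(x, x[::-1])
    assert r == pytest.approx(-1.0) and r2 == pytest.approx(1.0)


def test_correlation_matches_closed_form():
    x = np.array([0.3, -1.2, 2.8, 1.2, 0.5])
    y = np.array([1.1, 0.2, 2.0, -0.4, 0.9])
    r, r2 = correlate_profiles(x, y)
    xc, yc = x - x.mean(), y - y.mean()
    r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
    assert abs(r - r_hand) < 1e-12 and abs(r2 - r_hand**2) < 1e-12


def test_constant_profile_rejected():
    with pytest.raises(ValueError, match="constant"):
        correlate_profiles(np.ones(5), np.arange(5.0))


def test_marker_screen_membership_and_sign_separation():
    tmpl = np.array([0.3, -0.3, 2.8, 1.2, 0.5])
    profiles = make_profiles(
        {
            "Olig1": tmpl,
            "nc_same": tmpl.copy(),
            "nc_inverted": -tmpl,
            "nc_other": np.array([3.0, 2.0, 1.0, 0.5, 0.1]),
        },
        is_ncrna=pd.Series({"Olig1": False, "nc_same": True,
                            "nc_inverted": True, "nc_other": True}),
    )
    pos, neg = marker_correlation_screen(profiles, "Olig1")
    assert pos.members == ["nc_same"]
    assert neg.members == ["nc_inverted"]
    with pytest.raises(ValueError, match="absent or not expressed"):
        marker_correlation_screen(profiles, "missing")


def test_lineage_switch_rules_and_strict_subset():
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = 40
        m = {f"p{i}": rng.normal(0, 2, 5) for i in range(n)}
        profiles = make_profiles(m)
        loose = lineage_switch_screen(profiles, "GABAN", ["OLP", "PMO", "MYO"], strict=False)
        strict = lineage_switch_screen(profiles, "GABAN", ["OLP", "PMO", "MYO"], strict=True)
        assert set(strict.members) <= set(loose.members)
    profiles = make_profiles({
        "up_down": [0.0, 2.0, -2.0, 0.0, 0.0],
        "up_up": [0.0, 2.0, 2.0, 0.0, 0.0],
    })
    res = lineage_switch_screen(profiles, "GABAN", ["OLP"])
    assert res.members == ["up_down"]
    with pytest.raises(ValueError, match="unknown contrast"):
        lineage_switch_screen(profiles, "NOPE", ["OLP"])


def test_stage_exclusive_rules_and_disjointness():
    profiles = make_profiles({
        "only_olp": [0.0, 0.0, 2.0, 0.0, 0.0],
        "olp_and_pmo": [0.0, 0.0, 2.0, -2.0, 0.0],
        "only_pmo": [0.0, 0.0, 0.0, 2.0, 0.0],
    })
    olp = stage_exclusive_screen(profiles, "OLP")
    pmo = stage_exclusive_screen(profiles, "PMO")
    assert olp.members == ["only_olp"]
    assert pmo.members == ["only_pmo"]
    assert not set(olp.members) & set(pmo.members)


def test_switch_screens_are_mutually_exclusive():
    rng = np.random.default_rng(1)
    m = {f"p{i}": rng.normal(0, 2, 5) for i in range(60)}
    profiles = make_profiles(m)
    a = lineage_switch_screen(profiles, "GABAN", ["OLP"])
    b = lineage_switch_screen(profiles, "OLP", ["GABAN"])
    assert not set(a.members) & set(b.members)


def test_screen_membership_matches_truth_derivation():
    rng = np.random.default_rng(2)
    lfc = pd.DataFrame(
        np.where(rng.random((80, 5)) < 0.25, rng.normal(0, 2, (80, 5)), 0.0),
        index=[f"p{i}" for i in range(80)], columns=list(STAGES),
    )
    profiles = StageProfiles(
        M=lfc, de=lfc != 0, expressed=pd.Series(True, index=lfc.index)
    )
    got = set(lineage_switch_screen(profiles, "GABAN", ["OLP"]).members)
    assert got == truth_screen_members(lfc, "lineage_switch", up="GABAN", down="OLP")
    got = set(stage_exclusive_screen(profiles, "OLP").members)
    assert got == truth_screen_members(lfc, "stage_exclusive", contrast="OLP")


def test_discordant_pair_labels():
    profiles = make_profiles({
        "p_nc1": [0.0, 2.0, 0.0, 0.0, 0.0],   # Ecsit-like: ncRNA up at GABAN
        "p_g1": [0.0, -2.0, 0.0, 0.0, 0.0],   # host down -> discordant
        "p_nc2": [0.0, 0.0, 2.0, 0.0, 0.0],   # Sox8-like: both up at OLP
        "p_g2": [0.0, 0.0, 2.0, 0.0, 0.0],
        "p_nc3": [0.0, 0.0, 2.0, 0.0, 0.0],
        "p_g3": [0.0, 0.0, 0.4, 0.0, 0.0],    # host not DE -> no label
    })
    calls = pd.DataFrame({
        "ncrna_id": ["nc1", "nc2", "nc3"],
        "host_gene": ["g1", "g2", "g3"],
        "context_class": ["antisense", "bidirectional", "intronic_sense"],
    })
    pairs = discordant_pair_screen(calls, profiles)
    lab = pairs.set_index("ncrna_id").label
    assert lab["nc1"] == "discordant"
    assert lab["nc2"] == "concordant"
    assert "nc3" not in lab.index
    sw = gaban_olp_switching(make_profiles({"p_sw": [0.0, 2.0, -2.0, 0.0, 0.0]}))
    assert list(sw.probe_id) == ["p_sw"]


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_hypergeometric_fixture_exact_value():
    universe = [f"g{i}" for i in range(20)]
    term = pd.DataFrame({"term_id": "T", "gene_id": universe[:5]})
    gene_list = universe[:5] + universe[10:15]  # k = 5 of K = 5, n = 10
    res = term_enrichment(gene_list, universe, term)
    assert res.p_value.iloc[0] == pytest.approx(3003 / 184756, rel=1e-12)


def test_enrichment_no_surprise_when_list_is_universe():
    universe = [f"g{i}" for i in range(15)]
    term = pd.DataFrame({"term_id": "T", "gene_id": universe[:6]})
    res = term_enrichment(universe, universe, term)
    assert res.p_value.iloc[0] == pytest.approx(1.0)
    assert res.k.iloc[0] == res.term_size.iloc[0]


def test_enrichment_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n_uni = int(rng.integers(5, 13))
        k_term = int(rng.integers(1, n_uni + 1))
        n_list = int(rng.integers(1, n_uni + 1))
        universe = [f"g{i}" for i in range(n_uni)]
        term_genes = universe[:k_term]
        gene_list = list(rng.choice(universe, size=n_list, replace=False))
        k = len(set(gene_list) & set(term_genes))
        res = term_enrichment(gene_list, universe, pd.DataFrame({"term_id": "T", "gene_id": term_genes}))
        expected = hypergeom_tail_enumeration(n_uni, k_term, n_list, k)
        assert res.p_value.iloc[0] == pytest.approx(expected, abs=1e-12)


def test_enrichment_monotone_in_overlap():
    n_uni, k_term, n_list = 100, 20, 30
    ps = [stats.hypergeom.sf(k - 1, n_uni, k_term, n_list) for k in range(0, 21)]
    assert (np.diff(ps) < 1e-15).all()
    # and through the public interface
    universe = [f"g{i}" for i in range(40)]
    term = pd.DataFrame({"term_id": "T", "gene_id": universe[:10]})
    p_small = term_enrichment(universe[:2] + universe[20:28], universe, term).p_value.iloc[0]
    p_big = term_enrichment(universe[:8] + universe[20:22], universe, term).p_value.iloc[0]
    assert p_big < p_small


def test_enrichment_rejects_stray_genes():
    with pytest.raises(ValueError, match="not contained"):
        term_enrichment(["x"], ["a", "b"], pd.DataFrame({"term_id": "T", "gene_id": ["a"]}))
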