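"""Candidate-selection screens over DE results and term enrichment.

Screens operate on stage profiles (the M vector over the five stage-vs-NSC
contrasts plus DE calls) and are pure functions of their inputs.  The
correlation screens use the signed Pearson r with threshold sqrt(0.9): an
R^2 > 0.9 criterion alone is sign-blind, so concordant and anti-correlated
sets are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import STAGES
from .de import adjust_bh

R_THRESHOLD_DEFAULT = np.sqrt(0.9)  # ~0.9487


@dataclass
class StageProfiles:
    """Per-probe M vectors and DE calls over the stage contrasts."""

    M: pd.DataFrame  # probe x contrast
    de: pd.DataFrame  # probe x contrast bool
    expressed: pd.Series  # probe -> bool
    is_ncrna: pd.Series | None = None

    @classmethod
    def from_de_table(cls, table: pd.DataFrame, is_ncrna: pd.Series | None = None):
        m = table.pivot(index="probe_id", columns="contrast", values="M")
        de = table.pivot(index="probe_id", columns="contrast", values="de_call")
        expressed = table.groupby("probe_id")["expressed"].first()
        order = [c for c in STAGES if c in m.columns]
        return cls(M=m[order], de=de[order].astype(bool), expressed=expressed, is_ncrna=is_ncrna)


@dataclass
class ScreenResult:
    name: str
    parameters: dict
    members: list[str]
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)


def correlate_profiles(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and R^2 between two stage profiles.  Constant vectors are
    undefined (ValueError); callers exclude those probes with a flag."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("profiles need >= 3 shared contrasts")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def marker_correlation_screen(
    profiles: StageProfiles,
    marker_id: str,
    r_threshold: float = R_THRESHOLD_DEFAULT,
    ncrna_only: bool = True,
    require_de: bool = True,
) -> tuple[ScreenResult, ScreenResult]:
    """Expressed, differentially expressed ncRNAs whose profile is
    concordant with the marker's (signed r >= threshold); the
    anti-correlated set (r <= -threshold) is returned separately.  The
    candidate pool is the DE ncRNAs (set ``require_de=False`` to correlate
    every expressed profile): a probe with no real change has an
    arbitrary noise profile whose correlation carries no information."""
    if marker_id not in profiles.M.index or not bool(profiles.expressed.get(marker_id, False)):
        raise ValueError(f"marker {marker_id!r} absent or not expressed")
    mvec = profiles.M.loc[marker_id].to_numpy(float)
    rows = []
    for pid, vec in profiles.M.iterrows():
        if pid == marker_id or not bool(profiles.expressed.get(pid, False)):
            continue
        if require_de and not bool(profiles.de.loc[pid].any()):
            continue
        if ncrna_only and profiles.is_ncrna is not None and not bool(profiles.is_ncrna.get(pid, False)):
            continue
        v = vec.to_numpy(float)
        if np.ptp(v) == 0:
            rows.append({"probe_id": pid, "r": np.nan, "r_squared": np.nan, "flag": "constant"})
            continue
        r, r2 = correlate_profiles(mvec, v)
        rows.append({"probe_id": pid, "r": r, "r_squared": r2, "flag": ""})
    tab = pd.DataFrame(rows, columns=["probe_id", "r", "r_squared", "flag"])
    params = {"marker": marker_id, "r_threshold": r_threshold}
    pos = sorted(tab.probe_id[tab.r >= r_threshold])
    neg = sorted(tab.probe_id[tab.r <= -r_threshold])
    return (
        ScreenResult(f"correlated_with_{marker_id}", params, pos, tab[tab.probe_id.isin(pos)]),
        ScreenResult(f"anticorrelated_with_{marker_id}", params, neg, tab[tab.probe_id.isin(neg)]),
    )


def lineage_switch_screen(
    profiles: StageProfiles,
    up_contrast: str,
    down_contrasts: list[str],
    strict: bool = False,
) -> ScreenResult:
    """Probes DE up in ``up_contrast`` and DE down in the first (strict:
    every) ``down_contrasts`` entry — e.g. up in GABAN but down during OL
    differentiation."""
    for c in [up_contrast, *down_contrasts]:
        if c not in profiles.M.columns:
            raise ValueError(f"unknown contrast {c!r}")
    up = profiles.de[up_contrast] & (profiles.M[up_contrast] > 0)
    downs = [profiles.de[c] & (profiles.M[c] < 0) for c in down_contrasts]
    down = (
        np.logical_and.reduce(downs) if strict else downs[0]
    )
    members = sorted(profiles.M.index[up & down])
    return ScreenResult(
        "lineage_switch",
        {"up": up_contrast, "down": list(down_contrasts), "strict": strict},
        members,
    )


def stage_exclusive_screen(profiles: StageProfiles, contrast: str) -> ScreenResult:
    """Probes DE in the named contrast and in no other contrast; up and
    down members are counted separately in the stats table."""
    if contrast not in profiles.M.columns:
        raise ValueError(f"unknown contrast {contrast!r}")
    others = [c for c in profiles.M.columns if c != contrast]
    sel = profiles.de[contrast] & ~profiles.de[others].any(axis=1)
    members = sorted(profiles.M.index[sel])
    signs = np.sign(profiles.M.loc[members, contrast]).astype(int)
    stats_tab = pd.DataFrame(
        {"probe_id": members, "direction": signs.to_numpy()}
    )
    return ScreenResult("stage_exclusive", {"contrast": contrast}, members, stats_tab)


def discordant_pair_screen(
    context_calls: pd.DataFrame,
    profiles: StageProfiles,
    probe_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Label anchored (non-intergenic) ncRNA/host-gene pairs per contrast:
    discordant when both members are DE with opposite signs, concordant when
    both DE with the same sign; otherwise unlabeled.  Also flags transcripts
    whose GABAN and OLP DE signs differ (neuronal-glial switching)."""
    probe_of = probe_of or {}
    rows = []
    for row in context_calls.itertuples():
        if row.context_class == "intergenic" or not row.host_gene:
            continue
        nc_p = probe_of.get(row.ncrna_id, f"p_{row.ncrna_id}")
        host_p = probe_of.get(row.host_gene, f"p_{row.host_gene}")
        if nc_p not in profiles.M.index or host_p not in profiles.M.index:
            continue
        for c in profiles.M.columns:
            nc_de = bool(profiles.de.loc[nc_p, c])
            host_de = bool(profiles.de.loc[host_p, c])
            if not (nc_de and host_de):
                continue
            s_nc = np.sign(profiles.M.loc[nc_p, c])
            s_host = np.sign(profiles.M.loc[host_p, c])
            label = "discordant" if s_nc != s_host else "concordant"
            rows.append(
                {
                    "ncrna_id": row.ncrna_id,
                    "host_gene": row.host_gene,
                    "context_class": row.context_class,
                    "contrast": c,
                    "ncrna_M": float(profiles.M.loc[nc_p, c]),
                    "host_M": float(profiles.M.loc[host_p, c]),
                    "label": label,
                }
            )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "ncrna_id", "host_gene", "context_class", "contrast",
            "ncrna_M", "host_M", "label",
        ],
    )
    return pairs


def gaban_olp_switching(profiles: StageProfiles) -> pd.DataFrame:
    """Transcripts DE at both GABAN and OLP with differing signs (the
    neuronal-vs-glial fate-switch table)."""
    both = profiles.de["GABAN"] & profiles.de["OLP"]
    sg = np.sign(profiles.M["GABAN"])
    so = np.sign(profiles.M["OLP"])
    sel = both & (sg != so)
    return pd.DataFrame(
        {
            "probe_id": profiles.M.index[sel],
            "M_GABAN": profiles.M.loc[sel, "GABAN"].to_numpy(),
            "M_OLP": profiles.M.loc[sel, "OLP"].to_numpy(),
        }
    ).sort_values("probe_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------

def term_enrichment(
    gene_list: list[str],
    universe: list[str],
    term_map: pd.DataFrame,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term with BH
    correction across tested terms; applies identically to GO-style terms
    and miRNA-target sets.  The list fraction k/n per term is reported."""
    genes = set(gene_list)
    uni = set(universe)
    stray = genes - uni
    if stray:
        raise ValueError(f"gene_list not contained in universe: {sorted(stray)[:5]}")
    n_uni = len(uni)
    n_list = len(genes)
    rows = []
    for term, grp in term_map.groupby("term_id", sort=True):
        term_genes = set(grp.gene_id) & uni
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(term_genes & genes)
        # P(X >= k) under sampling n_list of n_uni with big_k successes
        p = float(stats.hypergeom.sf(k - 1, n_uni, big_k, n_list))
        rows.append(
            {
                "term_id": term,
                "k": k,
                "term_size": big_k,
                "list_size": n_list,
                "universe_size": n_uni,
                "list_fraction": k / n_list if n_list else 0.0,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "k", "term_size", "list_size", "universe_size",
            "list_fraction", "p_value",
        ],
    )
    if len(out):
        out["adj_p"] = adjust_bh(out.p_value)
        out["significant"] = out.adj_p < p_cutoff
        out = out.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    else:
        out["adj_p"] = []
        out["significant"] = []
    return out
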