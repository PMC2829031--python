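"""Efficiency-corrected relative expression from qPCR Ct tables and the
TSA-vs-untreated response analysis.

The relative expression ratio follows the standard efficiency-corrected
form ratio = E_target^dCt_target / E_ref^dCt_ref with dCt = mean Ct
(untreated) - mean Ct(treated); significance uses a two-sided fixed-
reallocation randomization test on reference-normalized replicate values.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

ARMS = ("instructive", "stochastic")
TIMEPOINTS = ("24h", "48h")


def relative_expression_ratio(
    target_treated: np.ndarray,
    target_untreated: np.ndarray,
    ref_treated: np.ndarray,
    ref_untreated: np.ndarray,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> float:
    """Treated-vs-untreated fold change of the target, normalized by the
    reference gene."""
    for name, arr in (
        ("target_treated", target_treated),
        ("target_untreated", target_untreated),
        ("ref_treated", ref_treated),
        ("ref_untreated", ref_untreated),
    ):
        if len(np.atleast_1d(arr)) < 1:
            raise ValueError(f"missing Ct values for {name}")
    d_target = float(np.mean(target_untreated) - np.mean(target_treated))
    d_ref = float(np.mean(ref_untreated) - np.mean(ref_treated))
    return e_target**d_target / e_ref**d_ref


def randomization_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
    max_exhaustive: int = 10_000,
) -> float:
    """Two-sided label-randomization p for a difference in group means.

    Exhaustive over all C(n_a+n_b, n_a) partitions when that count is at
    most ``max_exhaustive``; otherwise ``n_perm`` sampled partitions with
    add-one smoothing.  All-equal inputs give p = 1.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("randomization test needs >= 2 values per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    observed = abs(a.mean() - b.mean())
    n, na = len(pooled), len(a)
    total = comb(n, na)
    tol = 1e-12
    if total <= max_exhaustive:
        hits = 0
        idx = set(range(n))
        for pick in combinations(range(n), na):
            sa = pooled[list(pick)]
            sb = pooled[list(idx - set(pick))]
            if abs(sa.mean() - sb.mean()) >= observed - tol:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= observed - tol:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def tsa_response_table(
    ct_table: pd.DataFrame,
    reference: str = "ref18s",
    n_perm: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per gene x arm x timepoint: efficiency-corrected TSA-treated vs
    untreated ratio, randomization p, and significance at ``alpha``; genes
    with significant opposite-sign responses in the two arms (the Neat1
    pattern) are flagged."""
    need = {"gene_id", "condition", "arm", "timepoint", "replicate", "Ct"}
    missing = need - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if reference not in set(ct_table.gene_id):
        raise ValueError(f"reference gene {reference!r} absent from Ct table")
    e_col = ct_table["E"] if "E" in ct_table.columns else pd.Series(2.0, index=ct_table.index)
    tab = ct_table.assign(E=e_col)
    genes = sorted(set(tab.gene_id) - {reference})
    rows = []
    for arm_i, arm in enumerate(ARMS):
        arm_tab = tab[tab.arm == arm]
        if arm_tab.empty:
            continue
        for tp_i, tp in enumerate(TIMEPOINTS):
            cell = arm_tab[arm_tab.timepoint == tp]
            ref_t = cell[(cell.gene_id == reference) & (cell.condition == "treated")]
            ref_u = cell[(cell.gene_id == reference) & (cell.condition == "untreated")]
            if ref_t.empty or ref_u.empty:
                raise ValueError(f"reference gene missing a condition at {arm}/{tp}")
            for g_i, g in enumerate(genes):
                gt = cell[(cell.gene_id == g) & (cell.condition == "treated")]
                gu = cell[(cell.gene_id == g) & (cell.condition == "untreated")]
                if gt.empty or gu.empty:
                    continue
                ratio = relative_expression_ratio(
                    gt.Ct.to_numpy(), gu.Ct.to_numpy(),
                    ref_t.Ct.to_numpy(), ref_u.Ct.to_numpy(),
                    e_target=float(gt.E.iloc[0]), e_ref=float(ref_t.E.iloc[0]),
                )
                # reference-normalized per-replicate values (replicate-paired)
                norm_t = _normalized(gt, ref_t)
                norm_u = _normalized(gu, ref_u)
                p = randomization_test(
                    norm_t, norm_u, n_perm=n_perm,
                    seed=(seed + 1000 * arm_i + 100 * tp_i + g_i) % (2**31),
                )
                rows.append(
                    {
                        "gene_id": g,
                        "arm": arm,
                        "timepoint": tp,
                        "ratio": ratio,
                        "log2_ratio": float(np.log2(ratio)),
                        "p_value": p,
                        "significant": p < alpha,
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "arm", "timepoint", "ratio", "log2_ratio", "p_value", "significant"],
    )
    out["opposite_arms"] = False
    for g in genes:
        sub = out[out.gene_id == g]
        for tp in TIMEPOINTS:
            cell = sub[sub.timepoint == tp]
            if len(cell) == 2 and cell.significant.all():
                signs = np.sign(cell.log2_ratio.to_numpy())
                if signs[0] != signs[1]:
                    out.loc[cell.index, "opposite_arms"] = True
    return out


def _normalized(target: pd.DataFrame, ref: pd.DataFrame) -> np.ndarray:
    """Per-replicate Ct(target) - Ct(reference), paired on replicate id
    where possible, else aligned on sorted order."""
    t = target.sort_values("replicate")
    r = ref.sort_values("replicate")
    if list(t.replicate) == list(r.replicate):
        return t.Ct.to_numpy() - r.Ct.to_numpy()
    return t.Ct.to_numpy() - float(r.Ct.mean())
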