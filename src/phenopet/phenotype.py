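"""Composite z-score phenotyping and group characterisation.

Each behavioural endpoint is standardised *within its own cohort* (sample
SD, ddof=1), the four z-scores are combined into the composite

    z_tot = (z_OF + z_SP + z_WM - z_FST) / 4

(low z_tot = high depression risk: little exploration, low sucrose
preference, few platform crossings, long immobility), and each cohort's
bottom / middle / top deciles of z_tot become the High / Intermediate /
Low Depression Risk groups (HDR / IDR / LDR). Selected groups are then
characterised per endpoint by fixed-effects one-way ANOVA with Tukey's HSD
post hoc.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("HDR", "IDR", "LDR")
UNSELECTED = "unselected"

#: endpoint -> (z column, sign in the composite)
Z_TERMS = {
    "of_center_s": ("z_of", +1),
    "sucrose_pref": ("z_sp", +1),
    "platform_crossings": ("z_wm", +1),
    "fst_immobile_s": ("z_fst", -1),
}


class DegenerateCohortError(ValueError):
    """A cohort has zero within-cohort SD for some endpoint."""


def zscore_within_cohort(values, cohort_ids) -> np.ndarray:
    """Standardise each value against the mean and sample SD of its cohort."""
    values = np.asarray(values, dtype=float)
    cohort_ids = np.asarray(cohort_ids)
    if values.shape != cohort_ids.shape:
        raise ValueError("values and cohort_ids must have the same length")
    out = np.empty_like(values)
    for c in pd.unique(cohort_ids):
        idx = cohort_ids == c
        v = values[idx]
        if v.size < 2:
            raise DegenerateCohortError(f"cohort {c!r} has fewer than 2 animals")
        sd = v.std(ddof=1)
        if sd == 0:
            raise DegenerateCohortError(f"cohort {c!r} has zero within-cohort SD")
        out[idx] = (v - v.mean()) / sd
    return out


def compute_ztot(z_of, z_sp, z_wm, z_fst) -> np.ndarray:
    """Composite score: (z_OF + z_SP + z_WM - z_FST) / 4."""
    arrs = [np.asarray(a, dtype=float) for a in (z_of, z_sp, z_wm, z_fst)]
    for a in arrs:
        if not np.all(np.isfinite(a)):
            raise ValueError("z-scores must be finite")
    return (arrs[0] + arrs[1] + arrs[2] - arrs[3]) / 4.0


def add_zscores(table: pd.DataFrame) -> pd.DataFrame:
    """Append z_of, z_sp, z_wm, z_fst and z_tot columns to a behaviour table."""
    out = table.copy()
    for trait, (zcol, _) in Z_TERMS.items():
        out[zcol] = zscore_within_cohort(out[trait].to_numpy(),
                                         out["cohort_id"].to_numpy())
    out["z_tot"] = compute_ztot(out["z_of"], out["z_sp"], out["z_wm"], out["z_fst"])
    return out


def select_groups(z_tot, cohort_ids, animal_ids, fraction: float = 0.10
                  ) -> pd.DataFrame:
    """Assign HDR / IDR / LDR by per-cohort deciles of the composite score.

    Per cohort of n animals with k = n * fraction (k must be integral and
    >= 1): the k lowest-z_tot animals form HDR, the k highest LDR, and the
    k animals whose ascending ranks straddle the cohort median form IDR
    (ranks 14-16 for n=30, k=3). Ties in z_tot are broken by animal_id so
    assignment is deterministic.

    Returns a DataFrame with columns animal_id, group, rank_in_cohort.
    """
    z_tot = np.asarray(z_tot, dtype=float)
    cohort_ids = np.asarray(cohort_ids)
    animal_ids = np.asarray(animal_ids)
    if len(set(animal_ids)) != len(animal_ids):
        raise ValueError("duplicate animal ids")

    rows = []
    for c in pd.unique(cohort_ids):
        idx = np.flatnonzero(cohort_ids == c)
        n = idx.size
        k_float = n * fraction
        k = int(round(k_float))
        if abs(k_float - k) > 1e-9 or k < 1:
            raise ValueError(
                f"cohort {c!r}: size {n} x fraction {fraction} does not give "
                f"an integer k >= 1")
        order = idx[np.lexsort((animal_ids[idx], z_tot[idx]))]
        group = np.full(n, UNSELECTED, dtype=object)
        group[:k] = "HDR"
        mid = (n - k) // 2
        group[mid:mid + k] = "IDR"
        group[n - k:] = "LDR"
        for rank, (i, g) in enumerate(zip(order, group), start=1):
            rows.append((animal_ids[i], g, rank))
    out = pd.DataFrame(rows, columns=["animal_id", "group", "rank_in_cohort"])
    return out.set_index("animal_id").loc[animal_ids].reset_index()


def phenotype_table(table: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Full phenotyping stage: z-scores, composite, and group assignment."""
    scored = add_zscores(table)
    assign = select_groups(scored["z_tot"].to_numpy(),
                           scored["cohort_id"].to_numpy(),
                           scored["animal_id"].to_numpy(), fraction=fraction)
    return scored.merge(assign, on="animal_id", validate="one_to_one")


# ---------------------------------------------------------------------------
# Group characterisation: one-way ANOVA + Tukey HSD

@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float


@dataclass
class TukeyRow:
    pair: tuple[str, str]
    mean_diff: float
    q: float
    p_adj: float


def _group_arrays(values, group_labels):
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    names = list(pd.unique(group_labels))
    groups = [values[group_labels == g] for g in names]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, arr in zip(names, groups):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return names, groups


def anova_oneway(values, group_labels) -> AnovaResult:
    """Classic fixed-effects one-way ANOVA from sums of squares."""
    names, groups = _group_arrays(values, group_labels)
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    msw = ssw / df_w
    if msw == 0:
        if ssb == 0:
            raise ValueError("zero variance within and between groups: F undefined")
        return AnovaResult(np.inf, df_b, df_w, 0.0, 0.0)
    F = (ssb / df_b) / msw
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p, float(msw))


def tukey_hsd(values, group_labels) -> list[TukeyRow]:
    """All pairwise Tukey(-Kramer) comparisons after a one-way ANOVA.

    q = |mean difference| / sqrt(MSW / n_h) with n_h the harmonic mean of
    the pair's group sizes; adjusted p from the studentized-range
    distribution with k groups and the ANOVA's within df.
    """
    names, groups = _group_arrays(values, group_labels)
    res = anova_oneway(values, group_labels)
    k = len(groups)
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        ga, gb = groups[i], groups[j]
        diff = ga.mean() - gb.mean()
        n_h = 2.0 / (1.0 / ga.size + 1.0 / gb.size)
        se = np.sqrt(res.ms_within / n_h)
        q = abs(diff) / se if se > 0 else np.inf
        p_adj = float(np.clip(stats.studentized_range.sf(q, k, res.df_within),
                              0.0, 1.0))
        rows.append(TukeyRow((a, b), float(diff), float(q), p_adj))
    return rows


def characterize_groups(pheno: pd.DataFrame,
                        traits=tuple(Z_TERMS)) -> pd.DataFrame:
    """ANOVA + Tukey for each behavioural endpoint over the selected animals.

    Only HDR/IDR/LDR rows enter the analysis (matching a design where the
    selected animals are the ones characterised). Returns a tidy table with
    one ANOVA row and one row per Tukey pair for each endpoint.
    """
    sel = pheno[pheno["group"].isin(GROUPS)]
    rows = []
    for trait in traits:
        res = anova_oneway(sel[trait].to_numpy(), sel["group"].to_numpy())
        rows.append({"measure": trait, "test": "anova", "comparison": "omnibus",
                     "statistic": res.F, "df1": res.df_between,
                     "df2": res.df_within, "p": res.p})
        if res.p < 0.05:
            for tk in tukey_hsd(sel[trait].to_numpy(), sel["group"].to_numpy()):
                rows.append({"measure": trait, "test": "tukey",
                             "comparison": f"{tk.pair[0]} vs {tk.pair[1]}",
                             "statistic": tk.q, "df1": np.nan, "df2": np.nan,
                             "p": tk.p_adj, "mean_diff": tk.mean_diff})
    return pd.DataFrame(rows)
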