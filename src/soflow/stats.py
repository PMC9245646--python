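"""Inferential stage: SO vs non-SO contrasts, peak-height mixed models,
and behavior regressions.

Predictors use the unit-step anterior-posterior coding: channels/regions
Fz/F=1, Cz/C=2, Pz/P=3, POz/O=4; distances are absolute index
differences, e.g. D(source, SO channel) in {0..3}. The relative distance
of a sink/source pair with respect to the SO channel is
D(sink, SO) - D(source, SO). Phase is coded prepeak=1 / postpeak=2,
cluster Global=1 / Local=2, coupling noncoupled=1 / coupled=2.

Peak heights are modelled with a linear mixed-effects model (random
intercept per subject, REML); SO-vs-non-SO outflow uses a one-way ANOVA
with Tukey-adjusted post hoc contrasts; word-pair-association (WPA)
improvement ratios are regressed on per-subject mean flow within
distance-defined groups, Bonferroni-corrected within each family (FDR
for the cluster-stratified source x SO-channel grid). Before every test,
values outside mean ± 2 SD of their analysis cell are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .channels import REGION_INDEX, SOURCE_INDEX, region_of

PHASE_CODE = {"pre": 1, "post": 2}
CLUSTER_CODE = {"Global": 1, "Local": 2}
COUPLING_CODE = {False: 1, True: 2}

#: Significance tiers as drawn in the group comparisons.
TIER_STRONG = 0.005
TIER_SIGNIFICANT = 0.05
TIER_MARGINAL = 0.1


def significance_tier(p: float) -> str:
    if p < TIER_STRONG:
        return "strong"
    if p < TIER_SIGNIFICANT:
        return "significant"
    if p < TIER_MARGINAL:
        return "marginal"
    return "ns"


@dataclass
class StatsResult:
    model: str
    coefficients: pd.DataFrame = field(default_factory=pd.DataFrame)
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    correction: str = "none"


def source_index(channel: str) -> int:
    try:
        return SOURCE_INDEX[channel]
    except KeyError:
        raise KeyError(f"unknown source channel {channel!r}") from None


def region_index(region_or_channel: str) -> int:
    if region_or_channel in REGION_INDEX:
        return REGION_INDEX[region_or_channel]
    return REGION_INDEX[region_of(region_or_channel)]


def d_source_so(source: str, so_channel: str) -> int:
    """|index(source) - index(SO channel)|, in {0..3}."""
    return abs(source_index(source) - source_index(so_channel))


def d_sink_so(sink_region: str, so_channel: str) -> int:
    return abs(region_index(sink_region) - source_index(so_channel))


def d_source_sink(source: str, sink_region: str) -> int:
    return abs(region_index(sink_region) - source_index(source))


def relative_distance(sink_region: str, source: str, so_channel: str) -> int:
    """D(sink, SO channel) - D(source, SO channel), signed."""
    return d_sink_so(sink_region, so_channel) - d_source_so(source, so_channel)


def exclude_outliers(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop values outside mean ± 2 SD (computed once); returns (kept, n_dropped)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    mu, sd = values.mean(), values.std(ddof=0)
    keep = (values >= mu - 2 * sd) & (values <= mu + 2 * sd)
    return values[keep], int(np.sum(~keep))


def compare_so_vs_nonso(phase_outflow: dict[str, np.ndarray],
                        non_so_outflow: np.ndarray) -> StatsResult:
    """One-way ANOVA over the five SO phases plus non-SO windows,
    with Tukey-adjusted post hoc contrasts of each phase vs non-SO.

    ``phase_outflow`` maps phase names ("-pi", "-pi/2", "0", "pi/2", "pi")
    to per-subject outflow values; ``non_so_outflow`` is per-subject.
    """
    names = list(phase_outflow) + ["non-SO"]
    groups = [np.asarray(phase_outflow[k], dtype=float) for k in phase_outflow]
    groups.append(np.asarray(non_so_outflow, dtype=float))
    if min(g.size for g in groups) < 3:
        raise ValueError("need at least 3 subjects per condition")
    f_stat, p_anova = scipy.stats.f_oneway(*groups)
    tukey = scipy.stats.tukey_hsd(*groups)
    rows = []
    nonso_idx = len(groups) - 1
    for i, name in enumerate(names[:-1]):
        p = float(tukey.pvalue[i, nonso_idx])
        rows.append({"pair": f"{name} vs non-SO", "p_value": p,
                     "tier": significance_tier(p)})
    coef = pd.DataFrame([{"term": "ANOVA", "estimate": float(f_stat),
                          "p_value": float(p_anova)}])
    return StatsResult(model="so_vs_nonso_anova", coefficients=coef,
                       comparisons=pd.DataFrame(rows), correction="tukey")


def peak_height_lme(peak_table: pd.DataFrame,
                    fixed_terms: list[str],
                    response: str = "peak_height") -> StatsResult:
    """Linear mixed-effects model of flow-peak heights.

    ``peak_table`` is long format with a ``subject`` column, the response,
    and numeric predictor columns (e.g. ``D_source_SO``, ``phase_code``).
    Fits response ~ fixed terms with a random intercept per subject by
    REML and returns the per-term coefficients and p-values.
    """
    if peak_table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a mixed model")
    for term in fixed_terms:
        if peak_table[term].nunique() < 2:
            raise ValueError(f"term {term!r} has fewer than 2 levels")
    design = peak_table[fixed_terms].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(design)), design])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(peak_table[fixed_terms].to_numpy(dtype=float).T)
        pairs = [
            f"{fixed_terms[i]}~{fixed_terms[j]}"
            for i in range(len(fixed_terms)) for j in range(i + 1, len(fixed_terms))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {pairs}")
    formula = f"{response} ~ " + " + ".join(fixed_terms)
    model = smf.mixedlm(formula, peak_table, groups=peak_table["subject"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            # boundary case (random-effect variance ~ 0): the default
            # optimizer can fail; Powell handles the degenerate limit,
            # where the fit coincides with OLS
            fit = model.fit(reml=True, method="powell")
    rows = [{"term": term, "estimate": float(fit.params[term]),
             "p_value": float(fit.pvalues[term])}
            for term in ["Intercept", *fixed_terms]]
    return StatsResult(model="peak_height_lme", coefficients=pd.DataFrame(rows),
                       correction="none")


def wpa_regressions(flow_table: pd.DataFrame, behavior: pd.DataFrame,
                    grouping: str = "D_source_SO",
                    correction: str = "bonferroni") -> StatsResult:
    """Linear regressions of WPA improvement on per-subject mean flow.

    ``flow_table`` is long format (subject, <grouping>, flow) holding
    post-trough peak flow values; ``behavior`` maps subject to
    ``improvement``. Within each level of the grouping column, flow is
    averaged per subject and improvement regressed on it; p-values are
    adjusted across levels by Bonferroni (or ``"fdr_bh"`` for the
    cluster-stratified grid).
    """
    improvement = behavior.set_index("subject")["improvement"]
    rows = []
    for level, sub in flow_table.groupby(grouping):
        per_subject = sub.groupby("subject")["flow"].mean()
        common = per_subject.index.intersection(improvement.index)
        if len(common) < 3:
            rows.append({"group": level, "n": len(common), "r": np.nan,
                         "p_raw": np.nan, "skipped": True})
            continue
        res = scipy.stats.linregress(per_subject[common].to_numpy(),
                                     improvement[common].to_numpy())
        rows.append({"group": level, "n": len(common), "r": float(res.rvalue),
                     "slope": float(res.slope), "p_raw": float(res.pvalue),
                     "skipped": False})
    table = pd.DataFrame(rows)
    tested = table["p_raw"].notna()
    adjusted = np.full(len(table), np.nan)
    if tested.any():
        adjusted[tested.to_numpy()] = multipletests(
            table.loc[tested, "p_raw"].to_numpy(), method=correction)[1]
    table["p_adjusted"] = adjusted
    return StatsResult(model=f"wpa_regression_{grouping}", comparisons=table,
                       correction=correction)
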