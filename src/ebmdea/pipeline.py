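"""Three-stage orchestration and report-table statistics.

Stage 1 scores the raw panel on the global frontier (CRS and VRS, with and
without super-efficiency). Stage 2 fits one stochastic frontier regression
per input to the Stage-1 input contraction gaps and levels every observation
up to the least favorable environment and worst luck. Stage 3 re-scores the
adjusted panel; the global Malmquist index is computed on both panels. All
derived report statistics (weighted means, ranges, rank shifts, stage gaps,
regional and plan-period aggregates, growth rates) are plain functions over
the persisted stage tables, so every summary cell is recomputable.

Super-efficiency scores order the static ranking tables; the slacks fed to
Stage 2 and the scores fed to the Malmquist index come from the plain
(capped) programs, which are always feasible and keep index ratios
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ebm import TechnologySpec, affinity_epsilon_weights, decompose_efficiency, score_panel
from .gml import average_index, compute_gml
from .panel import PanelDataset
from .sfa import SFAModel, adjust_inputs, fit_slack_frontier, jlms_decompose

__all__ = [
    "PipelineConfig",
    "StageTables",
    "StageReport",
    "run_three_stage",
    "weighted_mean",
    "value_range",
    "annual_growth_rate",
    "stage_gap",
    "rank_with_changes",
    "group_aggregate",
]


@dataclass
class PipelineConfig:
    """Run settings; every methodological choice is an explicit, logged field."""

    epsilon_x: float | None = None       # None -> affinity-index procedure
    input_weights: np.ndarray | None = None
    super_efficiency: bool = True        # for the static ranking tables
    bad_output_mode: str = "as-input"
    slack_basis: str = "total-gap"       # "(1-theta)x + s" | "pure-slack"
    recompute_epsilon_stage3: bool = True
    weight_pooling: str = "per-year"     # "per-year" | "pooled"
    grouping: dict | None = None         # unit -> region
    period_blocks: dict | None = None    # block name -> list of years

    def settings(self):
        return {
            "epsilon_x": self.epsilon_x, "super_efficiency": self.super_efficiency,
            "bad_output_mode": self.bad_output_mode, "slack_basis": self.slack_basis,
            "recompute_epsilon_stage3": self.recompute_epsilon_stage3,
            "weight_pooling": self.weight_pooling,
        }


@dataclass
class StageTables:
    """Score tables of one stage: super-efficiency for ranking, capped for GML."""

    cte: pd.DataFrame           # global CRS (super-efficiency per config)
    pte: pd.DataFrame           # global VRS
    se: pd.DataFrame            # cte / pte
    cte_capped: pd.DataFrame    # global CRS, non-super (feeds slacks / GML)
    pte_capped: pd.DataFrame
    contemp_crs: pd.DataFrame   # contemporaneous, non-super (feeds GML)
    contemp_vrs: pd.DataFrame
    epsilon_x: float
    input_weights: np.ndarray
    fallback_count: int


@dataclass
class StageReport:
    stage1: StageTables
    sfa: dict                   # input name -> SFAModel
    sfa_decomp: dict            # input name -> SlackDecomposition
    slack_tables: dict          # input name -> (N,) slack vector (obs order)
    adjusted_panel: PanelDataset
    stage3: StageTables
    gml_before: pd.DataFrame
    gml_after: pd.DataFrame
    summaries: dict
    run_config: dict


def _score_stage(data: PanelDataset, cfg: PipelineConfig):
    """All score tables for one panel (one stage)."""
    labels, Xo, Yo, Bo, Zo, Wo, tidx = data.flatten()
    Xin = np.hstack([Xo, Bo]) if (cfg.bad_output_mode == "as-input"
                                  and Bo.shape[1]) else Xo
    if cfg.epsilon_x is None:
        eps, w = affinity_epsilon_weights(Xin)
    else:
        eps = cfg.epsilon_x
        w = (np.asarray(cfg.input_weights, dtype=float)
             if cfg.input_weights is not None
             else np.full(Xin.shape[1], 1.0 / Xin.shape[1]))

    base = TechnologySpec(epsilon_x=eps, input_weights=w,
                          bad_output_mode=cfg.bad_output_mode)

    def run(frontier, rts, super_):
        spec = replace(base, frontier=frontier, rts=rts, super_efficiency=super_)
        return score_panel(data, spec, return_details=True)

    cte_s, det_cs = run("global", "crs", cfg.super_efficiency)
    pte_s, det_vs = run("global", "vrs", cfg.super_efficiency)
    if cfg.super_efficiency:
        cte_c, det_cc = run("global", "crs", False)
        pte_c, _ = run("global", "vrs", False)
    else:
        cte_c, det_cc = cte_s, det_cs
        pte_c = pte_s
    contemp_crs, _ = run("contemporaneous", "crs", False)
    contemp_vrs, _ = run("contemporaneous", "vrs", False)

    nfall = sum(r.status == "fallback-used"
                for r in list(det_cs.values()) + list(det_vs.values()))
    tables = StageTables(
        cte=cte_s, pte=pte_s, se=decompose_efficiency(cte_s, pte_s),
        cte_capped=cte_c, pte_capped=pte_c,
        contemp_crs=contemp_crs, contemp_vrs=contemp_vrs,
        epsilon_x=eps, input_weights=w, fallback_count=nfall,
    )
    return tables, det_cc


def _stage_slacks(data: PanelDataset, details, basis):
    """Per-input slack vectors in flattened observation order.

    "total-gap" uses the full input contraction (1 - theta) x + s (radial
    shortfall plus non-radial slack); "pure-slack" uses s alone. Taken from
    the capped CRS run, so theta <= 1 and the gap is nonnegative.
    """
    labels, Xo, *_ = data.flatten()
    m = data.n_inputs
    out = np.empty((len(labels), m))
    for kk, (j, t) in enumerate(labels):
        res = details[(data.dmu_ids[j], data.periods[t])]
        s = res.slacks[:m]
        if basis == "total-gap":
            out[kk] = (1.0 - min(res.theta, 1.0)) * Xo[kk, :m] + s
        elif basis == "pure-slack":
            out[kk] = s
        else:
            raise ValueError(f"unknown slack basis: {basis!r}")
    return np.maximum(out, 0.0)


def run_three_stage(data: PanelDataset, config: PipelineConfig | None = None
                    ) -> StageReport:
    """Stage 1 -> SFA adjustment -> Stage 3 -> Malmquist, deterministically."""
    cfg = config or PipelineConfig()

    stage1, det_capped = _score_stage(data, cfg)
    S = _stage_slacks(data, det_capped, cfg.slack_basis)
    _, Xo, Yo, Bo, Zo, Wo, _ = data.flatten()

    models, decomps, slack_tables = {}, {}, {}
    X_adj = np.empty_like(Xo)
    for i, name in enumerate(data.input_names):
        if np.std(S[:, i]) < 1e-5 * float(np.mean(Xo[:, i])):
            # degenerate stage: every unit sits on the frontier for this
            # input, there is nothing to regress and nothing to strip
            model, dec = None, None
            X_adj[:, i] = Xo[:, i]
        else:
            model = fit_slack_frontier(S[:, i], Zo)
            dec = jlms_decompose(S[:, i], Zo, model)
            X_adj[:, i] = adjust_inputs(Xo[:, i], dec.f_hat, dec.v_hat)
        models[name], decomps[name], slack_tables[name] = model, dec, S[:, i]

    adjusted = data.replace_inputs(
        X_adj.reshape(data.n_units, data.n_periods, data.n_inputs))

    cfg3 = cfg if cfg.recompute_epsilon_stage3 else replace(
        cfg, epsilon_x=stage1.epsilon_x, input_weights=stage1.input_weights)
    stage3, _ = _score_stage(adjusted, cfg3)

    gml_before = compute_gml(stage1.cte_capped, stage1.contemp_crs,
                             stage1.pte_capped, stage1.contemp_vrs)
    gml_after = compute_gml(stage3.cte_capped, stage3.contemp_crs,
                            stage3.pte_capped, stage3.contemp_vrs)

    summaries = _summaries(data, stage1, stage3, gml_before, gml_after, cfg)
    return StageReport(
        stage1=stage1, sfa=models, sfa_decomp=decomps,
        slack_tables=slack_tables, adjusted_panel=adjusted, stage3=stage3,
        gml_before=gml_before, gml_after=gml_after, summaries=summaries,
        run_config=cfg.settings(),
    )


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

def weighted_mean(values, weights):
    """Sum(w v) / Sum(w); weights nonnegative and not all zero."""
    v = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal lengths")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    return float(v @ w / w.sum())


def value_range(values):
    """max - min, the 'total distance' between the best and worst unit."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty value list")
    return float(v.max() - v.min())


def annual_growth_rate(v_start, v_end, n_intervals):
    """Compound annual growth rate in percent over n_intervals periods."""
    if v_start <= 0:
        raise ValueError("starting value must be positive")
    if n_intervals < 1:
        raise ValueError("need at least one interval")
    return ((v_end / v_start) ** (1.0 / n_intervals) - 1.0) * 100.0


def stage_gap(stage1_means: pd.Series, stage3_means: pd.Series) -> pd.Series:
    """Stage-1 minus stage-3 efficiency per unit ('promotional effect').

    Positive values mean a favorable external environment flattered the unit.
    """
    if not stage1_means.index.equals(stage3_means.index):
        raise ValueError("unit lists of the two stages do not match")
    return stage1_means - stage3_means


def rank_with_changes(stage1_values: pd.Series, stage3_values: pd.Series
                      ) -> pd.DataFrame:
    """Descending-value ranks in both stages with rise/fall/same labels.

    Ties are broken by unit label order and flagged in the ``tied`` column.
    """
    if not stage1_values.index.equals(stage3_values.index):
        raise ValueError("unit lists of the two stages do not match")

    def ranks(s):
        order = sorted(s.index, key=lambda u: (-s[u], str(u)))
        return pd.Series({u: i + 1 for i, u in enumerate(order)}, name="rank")

    r1 = ranks(stage1_values).reindex(stage1_values.index)
    r3 = ranks(stage3_values).reindex(stage3_values.index)
    label = np.where(r3 < r1, "rise", np.where(r3 > r1, "fall", "same"))
    tied = (stage1_values.duplicated(keep=False)
            | stage3_values.duplicated(keep=False))
    return pd.DataFrame({"stage1": stage1_values, "rank1": r1,
                         "stage3": stage3_values, "rank3": r3,
                         "change": label, "tied": tied})


def group_aggregate(score_table: pd.DataFrame, grouping: dict,
                    weights: pd.DataFrame, period_blocks: dict | None = None,
                    pooling="per-year") -> pd.DataFrame:
    """Weighted mean scores by region and (optionally) named year blocks.

    ``grouping`` maps each unit to a region; ``weights`` is a (J x T) frame
    aligned with ``score_table``. Per-year pooling computes the weighted mean
    within each year and then averages years in the block; pooled weighting
    uses all (unit, year) weights at once.
    """
    unmapped = [u for u in score_table.index if u not in grouping]
    if unmapped:
        raise ValueError(f"units without a region: {unmapped}")
    if not (weights.index.equals(score_table.index)
            and weights.columns.equals(score_table.columns)):
        raise ValueError("weights not aligned with scores")
    blocks = period_blocks or {"all": list(score_table.columns)}
    for name, years in blocks.items():
        missing = [y for y in years if y not in score_table.columns]
        if missing:
            raise ValueError(f"block {name!r} has years outside the panel: {missing}")

    regions = sorted(set(grouping.values()))
    out = pd.DataFrame(index=regions, columns=list(blocks), dtype=float)
    for region in regions:
        units = [u for u in score_table.index if grouping[u] == region]
        for name, years in blocks.items():
            sc = score_table.loc[units, years]
            wt = weights.loc[units, years]
            if pooling == "pooled":
                out.at[region, name] = weighted_mean(sc.to_numpy().ravel(),
                                                     wt.to_numpy().ravel())
            else:
                per_year = [weighted_mean(sc[y], wt[y]) for y in years]
                out.at[region, name] = float(np.mean(per_year))
    return out


def _yearly_weighted(table: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    return pd.Series({y: weighted_mean(table[y], weights[y])
                      for y in table.columns})


def _summaries(data, stage1, stage3, gml_before, gml_after, cfg):
    """Report tables derived from the stage tables (all recomputable)."""
    W = pd.DataFrame(data.W, index=data.dmu_ids, columns=data.periods)
    unit_w = W.mean(axis=1)

    def unit_table(st):
        tab = pd.DataFrame({
            "cte": st.cte.mean(axis=1), "pte": st.pte.mean(axis=1),
            "se": st.se.mean(axis=1)})
        return tab

    u1, u3 = unit_table(stage1), unit_table(stage3)
    annual = {}
    for name, st in (("stage1", stage1), ("stage3", stage3)):
        annual[name] = pd.DataFrame({
            "cte": _yearly_weighted(st.cte, W),
            "pte": _yearly_weighted(st.pte, W),
            "se": _yearly_weighted(st.se, W)})

    n_int = data.n_periods - 1
    growth = {
        stage: {col: annual_growth_rate(annual[stage][col].iloc[0],
                                        annual[stage][col].iloc[-1], n_int)
                for col in ("cte", "pte", "se")} if n_int >= 1 else {}
        for stage in ("stage1", "stage3")
    }

    summaries = {
        "unit_means_stage1": u1,
        "unit_means_stage3": u3,
        "weighted_means_stage1": {c: weighted_mean(u1[c], unit_w) for c in u1},
        "weighted_means_stage3": {c: weighted_mean(u3[c], unit_w) for c in u3},
        "ranges_stage1": {c: value_range(u1[c]) for c in u1},
        "ranges_stage3": {c: value_range(u3[c]) for c in u3},
        "annual": annual,
        "growth_rates_pct": growth,
        "stage_gap": stage_gap(u1["cte"], u3["cte"]),
        "rank_changes": rank_with_changes(u1["cte"], u3["cte"]),
        "gml_unit_means": {
            "before": average_index(gml_before, by="unit", how="arithmetic"),
            "after": average_index(gml_after, by="unit", how="arithmetic"),
        },
        "gml_overall": {
            "before": average_index(gml_before, by=None,
                                    how="arithmetic").iloc[0].to_dict(),
            "after": average_index(gml_after, by=None,
                                   how="arithmetic").iloc[0].to_dict(),
            "before_geometric": average_index(gml_before, by=None,
                                              how="geometric").iloc[0].to_dict(),
            "after_geometric": average_index(gml_after, by=None,
                                             how="geometric").iloc[0].to_dict(),
        },
    }
    if cfg.grouping:
        summaries["regional_stage1"] = group_aggregate(
            stage1.cte, cfg.grouping, W, cfg.period_blocks, cfg.weight_pooling)
        summaries["regional_stage3"] = group_aggregate(
            stage3.cte, cfg.grouping, W, cfg.period_blocks, cfg.weight_pooling)
    return summaries
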