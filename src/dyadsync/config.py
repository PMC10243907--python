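"""End-to-end pipeline configuration and orchestration.

A :class:`PipelineConfig` captures everything a run needs — simulation
block (or recording paths), wavelet/TDDR/lag parameters, band-selection
and test settings, the global seed and the output directory — and is
fully serializable to YAML; a snapshot is written beside the outputs so
every result is reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import pipeline as pl
from . import stats as st
from .io import INSTable, REST_FOR_CONDITION, write_ins_table, write_layout
from .preprocess import TDDRParams, detrend, tddr, trim_edges
from .simulate import (ArtifactSpec, Cohort, CouplingSpec, NoiseSpec,
                       SimulationConfig, generate_cohort)
from .wavelet import MorletParams, ScaleGrid, make_scale_grid

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Reproducible description of one end-to-end analysis run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scale_min: float = 0.3
    scale_max: float = 128.0
    n_scales: int = 106
    omega0: float = 6.0
    tddr: TDDRParams = field(default_factory=TDDRParams)
    trim_s: float = 30.0
    max_lag_s: int = 26
    band: Optional[Tuple[float, float]] = None  # fixed band; None = select
    band_n_perm: int = 1000
    band_percentile: float = 99.0
    alpha: float = 0.05
    validation_n_perm: int = 1000
    validation_area: float = 0.05
    delay_s: float = 6.0
    pairs: Optional[List[Tuple[str, str]]] = None
    scores: Optional[Dict[str, List[float]]] = None  # phase_tag -> per-dyad
    seed: int = 0
    out_dir: Optional[str] = None

    def scale_grid(self) -> ScaleGrid:
        return make_scale_grid(self.scale_min, self.scale_max,
                               self.n_scales, self.omega0)

    def morlet(self) -> MorletParams:
        return MorletParams(omega0=self.omega0)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        sim = dataclasses.asdict(self.simulation)
        sim.pop("channel_labels", None)
        sim["couplings"] = [dataclasses.asdict(c) for c in self.simulation.couplings]
        d = {
            k: getattr(self, k)
            for k in ("scale_min", "scale_max", "n_scales", "omega0", "trim_s",
                      "max_lag_s", "band", "band_n_perm", "band_percentile",
                      "alpha", "validation_n_perm", "validation_area",
                      "delay_s", "pairs", "scores", "seed", "out_dir")
        }
        d["simulation"] = sim
        d["tddr"] = dataclasses.asdict(self.tddr)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        couplings = [
            CouplingSpec(**{**c, "channel_pair": tuple(c["channel_pair"]),
                            "conditions": tuple(c.get("conditions",
                                                      ("CI", "SI", "CC")))})
            for c in sim.pop("couplings", [])
        ]
        noise = NoiseSpec(**sim.pop("noise", {}))
        artifacts = ArtifactSpec(**sim.pop("artifacts", {}))
        sim.pop("channel_labels", None)
        if "conditions" in sim:
            sim["conditions"] = tuple(sim["conditions"])
        sim_cfg = SimulationConfig(couplings=couplings, noise=noise,
                                   artifacts=artifacts, **sim)
        tddr_cfg = TDDRParams(**d.pop("tddr", {}))
        if d.get("band") is not None:
            d["band"] = tuple(d["band"])
        if d.get("pairs") is not None:
            d["pairs"] = [tuple(p) for p in d["pairs"]]
        return cls(simulation=sim_cfg, tddr=tddr_cfg, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _preprocess_recording(rec, trim_s, tddr_params):
    out = trim_edges(rec, trim_s) if trim_s > 0 else rec
    return tddr(detrend(out), tddr_params)


def run_pipeline(config: PipelineConfig, cohort: Optional[Cohort] = None) -> dict:
    """Run the full analysis: simulate (unless a cohort is supplied) ->
    preprocess -> per-scale INS -> band selection -> lagged INS ->
    CI-vs-SI paired tests -> pseudo-dyad validation -> optional score
    correlations.  Returns a result bundle and, if ``out_dir`` is set,
    writes every intermediate table plus a config snapshot.
    """
    t0 = time.time()
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    if cohort is None:
        log.info("simulating cohort: %d dyads, %d channels, conditions %s",
                 sim.n_dyads, sim.n_channels, sim.conditions)
        cohort = generate_cohort(sim)
    conditions = list(cohort.config.conditions)
    for cond in conditions:
        if REST_FOR_CONDITION[cond] not in cohort.layouts:
            raise ValueError(
                f"condition {cond} requires its matched rest "
                f"({REST_FOR_CONDITION[cond]}) in the cohort"
            )

    grid = config.scale_grid()
    params = config.morlet()
    pairs = config.pairs or [
        (la, lc)
        for la in cohort.config.channel_labels
        for lc in cohort.config.channel_labels
    ]

    log.info("preprocessing (trim %.0f s, detrend, TDDR)", config.trim_s)
    prep: Dict[int, Dict[str, tuple]] = {}
    layouts = {}
    for cond, lay in cohort.layouts.items():
        span = lay.span_s()
        layouts[cond] = (lay.shifted(config.trim_s, max_s=span - 2 * config.trim_s)
                         if config.trim_s > 0 else lay)
    for d in cohort.dyad_ids:
        prep[d] = {}
        for cond, (ra, rc) in cohort.recordings[d].items():
            prep[d][cond] = (
                _preprocess_recording(ra, config.trim_s, config.tddr),
                _preprocess_recording(rc, config.trim_s, config.tddr),
            )

    log.info("per-scale INS at lag 0 for %d pairs", len(pairs))
    # per-dyad, per-condition, per-pair per-scale INS increase (lag 0)
    ins0: Dict[int, Dict[str, Dict[tuple, np.ndarray]]] = {}
    rest_avg: Dict[int, Dict[str, Dict[tuple, np.ndarray]]] = {}
    for d in cohort.dyad_ids:
        ins0[d], rest_avg[d] = {}, {}
        for rest_cond in {REST_FOR_CONDITION[c] for c in conditions}:
            ra, rc = prep[d][rest_cond]
            maps = pl.channelwise_ins(ra, rc, grid, params, pairs)
            rest_avg[d][rest_cond] = {
                pr: pl.task_average(m, layouts[rest_cond]) for pr, m in maps.items()
            }
        for cond in conditions:
            ra, rc = prep[d][cond]
            maps = pl.channelwise_ins(ra, rc, grid, params, pairs)
            rest = rest_avg[d][REST_FOR_CONDITION[cond]]
            ins0[d][cond] = {
                pr: pl.ins_increase(pl.task_average(m, layouts[cond]), rest[pr],
                                    cond, REST_FOR_CONDITION[cond])
                for pr, m in maps.items()
            }

    # band selection on pair-averaged per-scale INS across conditions
    if config.band is not None:
        band = tuple(config.band)
        band_result = None
        log.info("using fixed band %s Hz", band)
    else:
        stacked = np.stack([
            np.stack([
                np.mean([ins0[d][cond][pr] for pr in pairs], axis=0)
                for cond in conditions
            ])
            for d in cohort.dyad_ids
        ])  # (n_dyads, n_cond, n_scales)
        band_result = st.permutation_band_selection(
            stacked, grid.frequencies, n_perm=config.band_n_perm,
            percentile=config.band_percentile, seed=config.seed + 1)
        if band_result.merged_bands:
            band = band_result.merged_bands[0]
        else:
            band = (0.02, 0.08)
            log.warning("no band survived the permutation threshold; "
                        "falling back to %s Hz for the lag scan", band)
        log.info("selected bands: %s", band_result.merged_bands)

    log.info("lagged INS over +/- %d s", config.max_lag_s)
    lag_grid = pl.LagGrid(config.max_lag_s)
    tables = []
    for d in cohort.dyad_ids:
        for cond in conditions:
            ra, rc = prep[d][cond]
            rest_cond = REST_FOR_CONDITION[cond]
            rra, rrc = prep[d][rest_cond]
            tables.append(pl.lagged_ins(
                ra, rc, layouts[cond], rra, rrc, layouts[rest_cond],
                grid, lag_grid, params, pairs, dyad_id=d))
    ins_table = INSTable.concat(tables)

    # band-averaged values per (pair, lag) per condition
    banded: Dict[str, Dict[tuple, np.ndarray]] = {c: {} for c in conditions}
    df = ins_table.df
    mask_band = grid.band_mask(*band)
    scale_ok = df["scale_index"].map(lambda k: bool(mask_band[k]))
    dfb = df[scale_ok]
    grouped = dfb.groupby(["condition", "chA", "chC", "lag_s", "dyad"])["value"].mean()
    for (cond, la, lc, lag, d), v in grouped.items():
        banded[cond].setdefault(((la, lc), int(lag)),
                                np.zeros(len(cohort.dyad_ids)))[
            cohort.dyad_ids.index(d)] = v

    results = {
        "band": band,
        "band_result": band_result,
        "ins_table": ins_table,
        "banded": banded,
    }

    if {"CI", "SI"} <= set(conditions):
        log.info("paired CI-vs-SI tests with Bonferroni correction")
        test = st.paired_condition_test(banded["CI"], banded["SI"],
                                        alpha=config.alpha)
        results["group_test"] = test
        # validate the strongest contrast with the pseudo-dyad null
        target = min(test.p_values, key=test.p_values.get)
        (t_pair, t_lag) = target
        log.info("pseudo-dyad validation at pair %s lag %d s", t_pair, t_lag)
        diff = _pseudo_pair_matrix(prep, layouts, cohort.dyad_ids, t_pair,
                                   t_lag, grid, lag_grid, params)
        validation = st.pseudo_pair_permutation(
            lambda assign: float(np.mean(
                [diff[i, j] for i, j in enumerate(assign)])),
            n_dyads=len(cohort.dyad_ids), n_perm=config.validation_n_perm,
            seed=config.seed + 2, two_tailed_area=config.validation_area)
        results["validation"] = {**validation, "target": target}

    if config.scores and "CI" in conditions:
        corr = {}
        ci_layout = layouts["CI"]
        for tag, scores in config.scores.items():
            vals = []
            for d in cohort.dyad_ids:
                ra, rc = prep[d]["CI"]
                # phase INS at the first configured pair
                m = pl.channelwise_ins(ra, rc, grid, params, [pairs[0]])[pairs[0]]
                pooled = pl.pool_phases(
                    pl.phase_average(m, ci_layout, config.delay_s))
                vals.append(pl.band_average(pooled[tag], grid, band))
            corr[tag] = st.score_correlation(vals, scores)
        results["correlations"] = corr

    if config.out_dir:
        _write_outputs(config, results, cohort)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return results


def _pseudo_pair_matrix(prep, layouts, dyad_ids, pair, lag_s, grid,
                        lag_grid, params):
    """CI-minus-SI INS-increase difference for every (A of dyad i,
    C of dyad j) re-pairing at one channel pair and lag, so any
    permutation statistic is a lookup."""
    n = len(dyad_ids)
    diff = np.zeros((n, n))
    for i, di in enumerate(dyad_ids):
        for j, dj in enumerate(dyad_ids):
            vals = {}
            for cond in ("CI", "SI"):
                rest_cond = REST_FOR_CONDITION[cond]
                ra = prep[di][cond][0]
                rc = prep[dj][cond][1]
                rra = prep[di][rest_cond][0]
                rrc = prep[dj][rest_cond][1]
                tbl = pl.lagged_ins(
                    ra, rc, layouts[cond], rra, rrc, layouts[rest_cond],
                    grid, _single_lag_grid(lag_s), params, [pair], dyad_id=0)
                sub = tbl.df[tbl.df["lag_s"] == lag_s]
                per_scale = sub.sort_values("scale_index")["value"].to_numpy()
                vals[cond] = per_scale.mean()
            diff[i, j] = vals["CI"] - vals["SI"]
    return diff


class _single_lag_grid:
    """Lag grid containing a single (possibly nonzero) lag."""

    def __init__(self, lag_s: int):
        self.max_lag_s = abs(int(lag_s))
        self.lags_s = np.array([int(lag_s)])

    def __len__(self):
        return 1


def _write_outputs(config: PipelineConfig, results: dict, cohort) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_snapshot.yaml")
    write_ins_table(results["ins_table"], out / "ins_table.tsv")
    for cond, lay in cohort.layouts.items():
        write_layout(lay, out / f"layout_{cond}.json")
    summary = {"band": list(results["band"])}
    if results.get("band_result") is not None:
        br = results["band_result"]
        summary["selected_bands"] = [list(b) for b in br.merged_bands]
        summary["f_threshold"] = br.threshold
    if "group_test" in results:
        gt = results["group_test"]
        summary["bonferroni_m"] = gt.m
        summary["significant"] = [
            {"pair": list(pair), "lag_s": lag, "t": gt.t_values[(pair, lag)],
             "p": gt.p_values[(pair, lag)]}
            for pair, lag in gt.significant
        ]
    if "validation" in results:
        v = results["validation"]
        summary["validation"] = {
            "target_pair": list(v["target"][0]),
            "target_lag_s": v["target"][1],
            "observed": v["observed"],
            "p_two_tailed": v["p_two_tailed"],
            "significant": bool(v["significant"]),
        }
    if "correlations" in results:
        summary["correlations"] = {
            tag: {"r": r, "p": p}
            for tag, (r, p) in results["correlations"].items()
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
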