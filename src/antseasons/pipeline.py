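"""End-to-end orchestration of the land-cover / temporal-variability study.

The full analysis runs, in order:

1. land-cover PCA -> per-site PC1/PC2 scores;
2. count conditioning -> threshold station counts, sum to site level,
   rarefy every site to the minimum site total;
3. per-site metrics on each rarefied replicate, averaged over replicates —
   functional CV, temporal beta diversity + SCBD (summed by alien status),
   time-series decomposition component variances (absolute and relative) —
   plus richness summaries and the natural log of total pre-rarefaction
   activity;
4. OLS with AICc selection of {PC1, PC2} subsets per response, with a
   Moran's I permutation screen on the selected model's residuals;
5. the between-group species comparison — partition sites into forested /
   developed / excluded thirds by PC1, keep species shared between groups
   above a total-count filter, rarefy each species to its between-group
   minimum, compare relative seasonality variance pairwise (Wilcoxon), and
   measure Loreau-de Mazancourt synchrony by alien status.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .activity import (
    SiteSeries,
    aggregate,
    apply_threshold,
    rarefy_matrix,
    rarefy_species_between_groups,
)
from .config import STATUSES, ConfigurationError, PipelineConfig, SimulationConfig
from .decompose import (
    component_variances,
    fit_tslm,
    loreau_synchrony,
    mean_seasonal_curve,
    standardize_seasonal,
)
from .inference import (
    PairedTestReport,
    RegressionResult,
    SpatialTestResult,
    fit_ols_aicc,
    morans_i_permutation,
    paired_tests,
)
from .landcover import LandcoverScores, pca_scores
from .simulate import simulate_dataset
from .variability import (
    UndefinedMetricError,
    functional_cv,
    hill_q0_extrapolated,
    temporal_beta_diversity,
)

logger = logging.getLogger(__name__)

GROUP_FORESTED = "forested"
GROUP_DEVELOPED = "developed"
GROUP_EXCLUDED = "excluded"


def assign_groups(scores: LandcoverScores, n_per_group: int = 8) -> pd.Series:
    """Partition sites into forested / developed / excluded thirds by PC1.

    The ``n_per_group`` highest-PC1 sites are forested, the lowest are
    developed, the middle excluded. Boundary ties go to the
    lexicographically smaller site id (logged).
    """
    pc1 = scores.pc1
    n = len(pc1)
    if n < 2 * n_per_group:
        raise ConfigurationError(
            f"need >= {2 * n_per_group} sites for two groups of {n_per_group}, got {n}"
        )
    if pc1.duplicated().any():
        logger.info("tied PC1 values: boundary ties broken by site id")
    # mergesort is stable; pre-sort by site id so ties resolve to smaller id
    by_id = pc1.sort_index()
    forested = by_id.sort_values(ascending=False, kind="mergesort").index[:n_per_group]
    remaining = by_id.drop(forested)
    developed = remaining.sort_values(ascending=True, kind="mergesort").index[:n_per_group]
    out = pd.Series(GROUP_EXCLUDED, index=pc1.index, name="group")
    out.loc[forested] = GROUP_FORESTED
    out.loc[developed] = GROUP_DEVELOPED
    return out


def filter_shared_species(
    series_a: SiteSeries,
    series_b: SiteSeries,
    min_total: int = 100,
    inclusive: bool = False,
) -> np.ndarray:
    """Species present in both group series whose combined total passes the
    count filter (strict ``> min_total`` by default; ``>=`` if inclusive)."""
    if not np.array_equal(series_a.species, series_b.species):
        raise KeyError("group series must share a species index")
    tot_a = series_a.matrix.sum(axis=1)
    tot_b = series_b.matrix.sum(axis=1)
    combined = tot_a + tot_b
    passes = combined >= min_total if inclusive else combined > min_total
    keep = (tot_a > 0) & (tot_b > 0) & passes
    retained = series_a.species[keep]
    if retained.size == 0:
        logger.warning("no species retained by the shared-species filter")
    return retained


@dataclass
class GroupComparison:
    """Between-group species-level comparison results."""

    assignment: pd.Series  # site -> forested/developed/excluded
    species_table: pd.DataFrame  # per retained species: status, paired rel. seasonality
    wilcoxon: PairedTestReport | None
    synchrony: pd.DataFrame  # status x group, seasonal-component and raw-series synchrony
    curves: dict[str, pd.DataFrame]  # group -> standardized seasonal curves (species x t)


def run_group_comparison(
    table: pd.DataFrame,
    scores: LandcoverScores,
    status_table: pd.DataFrame,
    pipe: PipelineConfig = PipelineConfig(),
    m: int = 26,
    seed: int | np.random.Generator = 0,
) -> GroupComparison:
    """Species-level forested-vs-developed comparison.

    ``table`` must already be thresholded. For each retained species the two
    group-level series are rarefied to their common minimum total
    ``pipe.n_rarefaction_reps`` times; the relative seasonality variance of
    each group's fit is averaged over replicates, giving one paired value
    per species for the Wilcoxon signed-rank test. Synchrony is computed per
    alien status within each group, both on the species' fitted seasonal
    components and on the raw (replicate-mean) series.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assignment = assign_groups(scores, pipe.n_per_group)
    group_map = {s: g for s, g in assignment.items() if g != GROUP_EXCLUDED}
    grouped = aggregate(table[table["site"].isin(group_map)], level="group", group_map=group_map)
    ser_f, ser_d = grouped[GROUP_FORESTED], grouped[GROUP_DEVELOPED]
    retained = filter_shared_species(ser_f, ser_d, pipe.min_total, pipe.min_total_inclusive)
    status_map = status_table.set_index("species")["status"]

    rows = []
    mean_series: dict[str, dict[str, np.ndarray]] = {GROUP_FORESTED: {}, GROUP_DEVELOPED: {}}
    for sp in retained:
        reps_f, reps_d = rarefy_species_between_groups(
            ser_f.species_series(sp), ser_d.species_series(sp), pipe.n_rarefaction_reps, rng
        )
        rel_f = np.empty(len(reps_f))
        rel_d = np.empty(len(reps_d))
        for r in range(len(reps_f)):
            rel_f[r] = component_variances(
                fit_tslm(reps_f[r], m=m, order=pipe.fourier_order)
            ).relative["seasonal"]
            rel_d[r] = component_variances(
                fit_tslm(reps_d[r], m=m, order=pipe.fourier_order)
            ).relative["seasonal"]
        mean_series[GROUP_FORESTED][sp] = reps_f.mean(axis=0)
        mean_series[GROUP_DEVELOPED][sp] = reps_d.mean(axis=0)
        rows.append(
            {
                "species": sp,
                "status": status_map.get(sp, "uncertain"),
                "rel_seasonality_forested": float(np.nanmean(rel_f)),
                "rel_seasonality_developed": float(np.nanmean(rel_d)),
            }
        )
    species_table = pd.DataFrame(
        rows,
        columns=["species", "status", "rel_seasonality_forested", "rel_seasonality_developed"],
    )

    wilcoxon = None
    if len(species_table) >= 5:
        try:
            wilcoxon = paired_tests(
                species_table["rel_seasonality_forested"].to_numpy(),
                species_table["rel_seasonality_developed"].to_numpy(),
            )
        except ValueError as exc:  # degenerate differences
            logger.warning("paired test unavailable: %s", exc)

    # seasonal components + standardized curves on the replicate-mean series
    seasonal: dict[str, dict[str, np.ndarray]] = {GROUP_FORESTED: {}, GROUP_DEVELOPED: {}}
    curves: dict[str, pd.DataFrame] = {}
    for grp, series_map in mean_series.items():
        curve_rows = {}
        for sp, y in series_map.items():
            d = fit_tslm(y, m=m, order=pipe.fourier_order)
            seasonal[grp][sp] = d.seasonal
            curve_rows[sp] = standardize_seasonal(d, y.sum())
        if curve_rows:
            cdf = pd.DataFrame(curve_rows).T
            cdf.loc["__group_mean__"] = mean_seasonal_curve(cdf.to_numpy())
            curves[grp] = cdf

    sync_rows = []
    for status in STATUSES:
        sp_status = [sp for sp in retained if status_map.get(sp) == status]
        for grp in (GROUP_FORESTED, GROUP_DEVELOPED):
            row = {"status": status, "group": grp, "n_species": len(sp_status)}
            for label, source in (("seasonal", seasonal[grp]), ("raw", mean_series[grp])):
                try:
                    X = np.vstack([source[sp] for sp in sp_status])
                    row[f"synchrony_{label}"] = loreau_synchrony(X)
                except (UndefinedMetricError, ValueError):
                    row[f"synchrony_{label}"] = np.nan
            sync_rows.append(row)
    synchrony = pd.DataFrame(sync_rows)

    return GroupComparison(
        assignment=assignment,
        species_table=species_table,
        wilcoxon=wilcoxon,
        synchrony=synchrony,
        curves=curves,
    )


def _site_metrics(
    series: SiteSeries,
    target: int,
    status_map: pd.Series,
    pipe: PipelineConfig,
    m: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """All per-site responses, averaged over rarefied replicates."""
    reps = rarefy_matrix(series.matrix, target, pipe.n_rarefaction_reps, rng)
    n_rep = reps.shape[0]
    cv = np.empty(n_rep)
    bd = np.empty(n_rep)
    scbd_status = {s: np.empty(n_rep) for s in STATUSES}
    comp = {c: np.empty(n_rep) for c in ("seasonal", "trend", "remainder")}
    rel = {c: np.empty(n_rep) for c in ("seasonal", "trend", "remainder")}
    rarefied_richness = np.empty(n_rep)
    status_arr = np.asarray([status_map.get(sp, "uncertain") for sp in series.species])

    for r in range(n_rep):
        M = reps[r]
        totals = M.sum(axis=0)
        cv[r] = functional_cv(totals)
        bd[r], scbd = temporal_beta_diversity(M)
        for s in STATUSES:
            scbd_status[s][r] = np.nansum(scbd[status_arr == s])
        variances = component_variances(fit_tslm(totals, m=m, order=pipe.fourier_order))
        for c, v in zip(
            ("seasonal", "trend", "remainder"),
            (variances.var_seasonal, variances.var_trend, variances.var_remainder),
        ):
            comp[c][r] = v
        for c, v in variances.relative.items():
            rel[c][r] = v
        rarefied_richness[r] = float((M.sum(axis=1) > 0).sum())

    abund = series.matrix.sum(axis=1)
    out: dict[str, float] = {
        "log_total_activity": float(np.log(series.grand_total)),
        "cv": float(cv.mean()),
        "bd_total": float(bd.mean()),
        "richness_observed": float((abund > 0).sum()),
        "richness_rarefied": float(rarefied_richness.mean()),
        "richness_extrapolated": hill_q0_extrapolated(abund),
    }
    for c in ("seasonal", "trend", "remainder"):
        out[f"var_{c}"] = float(comp[c].mean())
        out[f"rel_{c}"] = float(np.nanmean(rel[c]))
    for s in STATUSES:
        out[f"scbd_{s}"] = float(scbd_status[s].mean())
        sub = abund[status_arr == s]
        out[f"richness_{s}_observed"] = float((sub > 0).sum())
        if sub.sum() > 0:
            out[f"richness_{s}_extrapolated"] = hill_q0_extrapolated(sub)
        else:
            out[f"richness_{s}_extrapolated"] = 0.0
    return out


@dataclass
class ResultBundle:
    """Everything one full analysis run produces."""

    scores: LandcoverScores
    site_table: pd.DataFrame  # one row per site, all responses + PC1/PC2
    regressions: dict[str, RegressionResult]
    regression_table: pd.DataFrame
    moran: dict[str, SpatialTestResult]
    group_comparison: GroupComparison | None
    manifest: dict


#: Responses regressed on the land-cover scores, in output order.
RESPONSES = (
    "log_total_activity",
    "cv",
    "bd_total",
    "var_seasonal",
    "var_trend",
    "var_remainder",
    "rel_seasonal",
    "rel_trend",
    "rel_remainder",
    "richness_observed",
    "richness_rarefied",
    "richness_extrapolated",
    "scbd_native",
    "scbd_alien",
    "scbd_uncertain",
)


def run_full_analysis(
    sim: SimulationConfig | None = None,
    pipe: PipelineConfig = PipelineConfig(),
    *,
    table: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    status_table: pd.DataFrame | None = None,
    analysis_seed: int | None = None,
    include_group_comparison: bool = True,
    include_moran: bool = True,
) -> ResultBundle:
    """Run the whole study from a simulation config or provided tables.

    Either ``sim`` (a synthetic scenario) or all three of ``table``, ``meta``
    and ``status_table`` must be given. ``analysis_seed`` seeds rarefaction
    and permutation draws (defaults to the simulation seed). The two
    optional switches drop the group comparison and the Moran screen for
    fast repeated runs; everything else always executes.
    """
    if sim is not None:
        meta, status_table, _truth, table = simulate_dataset(sim)
        m = sim.period_per_year
        base_seed = sim.seed if analysis_seed is None else analysis_seed
    else:
        if table is None or meta is None or status_table is None:
            raise ConfigurationError(
                "provide either a simulation config or table+meta+status_table"
            )
        m = 26
        base_seed = 0 if analysis_seed is None else analysis_seed

    scores = pca_scores(meta)
    thresholded = apply_threshold(table, pipe.threshold)
    site_series = aggregate(thresholded, level="site")
    status_map = status_table.set_index("species")["status"]

    target = min(s.grand_total for s in site_series.values())
    logger.info("rarefying all sites to the minimum site total (%d individuals)", target)

    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, 101])
    site_rngs = {
        unit: np.random.default_rng(child)
        for unit, child in zip(sorted(site_series), ss.spawn(len(site_series)))
    }
    rows = []
    for unit in sorted(site_series):
        metrics = _site_metrics(site_series[unit], target, status_map, pipe, m, site_rngs[unit])
        rows.append({"site": unit, **metrics})
    site_table = pd.DataFrame(rows).set_index("site")
    site_table["PC1"] = scores.pc1
    site_table["PC2"] = scores.pc2

    regressions: dict[str, RegressionResult] = {}
    moran: dict[str, SpatialTestResult] = {}
    coords = meta.set_index("site").loc[site_table.index, ["x", "y"]].to_numpy()
    moran_rng = np.random.default_rng(np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, 211]))
    for resp in RESPONSES:
        try:
            res = fit_ols_aicc(site_table[resp], site_table[["PC1", "PC2"]], response=resp)
        except (ValueError, ConfigurationError) as exc:
            logger.warning("regression failed for %s: %s", resp, exc)
            continue
        regressions[resp] = res
        if include_moran:
            try:
                moran[resp] = morans_i_permutation(
                    res.residuals, coords, n_perm=pipe.n_permutations, seed=moran_rng
                )
            except ValueError as exc:
                logger.warning("Moran screen failed for %s: %s", resp, exc)

    reg_rows = []
    for resp, res in regressions.items():
        row = {
            "response": resp,
            "selected": res.selected_label,
            "r_squared": res.r_squared,
        }
        for name in ("intercept", "PC1", "PC2"):
            row[f"coef_{name}"] = res.coefficients.get(name, np.nan)
            row[f"p_{name}"] = res.p_values.get(name, np.nan)
        for label, val in res.aicc_table.items():
            row[f"aicc_{label}"] = val
        if resp in moran:
            row["moran_i"] = moran[resp].statistic
            row["moran_p"] = moran[resp].p_value
        reg_rows.append(row)
    regression_table = pd.DataFrame(reg_rows)

    group_comparison = None
    if include_group_comparison and len(site_table) >= 2 * pipe.n_per_group:
        gc_rng = np.random.default_rng(np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, 307]))
        group_comparison = run_group_comparison(
            thresholded, scores, status_table, pipe, m=m, seed=gc_rng
        )

    manifest = {
        "package_version": _pkg_version,
        "analysis_seed": int(base_seed),
        "rarefaction_target": int(target),
        "n_rarefaction_reps": pipe.n_rarefaction_reps,
        "threshold": pipe.threshold,
        "n_sites": int(len(site_table)),
        "simulation_config_digest": sim.digest() if sim is not None else None,
    }
    return ResultBundle(
        scores=scores,
        site_table=site_table,
        regressions=regressions,
        regression_table=regression_table,
        moran=moran,
        group_comparison=group_comparison,
        manifest=manifest,
    )


def analyze_temperature(
    temp: pd.DataFrame, scores: LandcoverScores, m: int = 26
) -> pd.DataFrame:
    """Seasonal absolute variance of per-site temperature series, with the
    same decomposition used for activity, joined with PC1 for regression."""
    rows = []
    for site, sub in temp.groupby("site"):
        sub = sub.sort_values("period")
        for col in ("air_temp", "soil_temp"):
            if col not in sub:
                continue
            d = fit_tslm(sub[col].to_numpy(), m=m, t=sub["period"].to_numpy(dtype=float))
            rows.append(
                {
                    "site": site,
                    "series": col,
                    "var_seasonal": component_variances(d).var_seasonal,
                }
            )
    out = pd.DataFrame(rows)
    out["PC1"] = scores.pc1.reindex(out["site"]).to_numpy()
    return out


def write_results(bundle: ResultBundle, outdir: str | Path) -> None:
    """Write every result table plus the run manifest to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.site_table.to_csv(out / "site_metrics.csv")
    bundle.regression_table.to_csv(out / "regressions.csv", index=False)
    bundle.scores.scores.to_csv(out / "landcover_scores.csv")
    bundle.scores.loadings.to_csv(out / "landcover_loadings.csv")
    if bundle.group_comparison is not None:
        gc = bundle.group_comparison
        gc.assignment.to_csv(out / "group_assignment.csv")
        gc.species_table.to_csv(out / "group_species.csv", index=False)
        gc.synchrony.to_csv(out / "group_synchrony.csv", index=False)
        for grp, cdf in gc.curves.items():
            cdf.to_csv(out / f"seasonal_curves_{grp}.csv")
        if gc.wilcoxon is not None:
            pd.DataFrame([vars(gc.wilcoxon)]).to_csv(out / "group_wilcoxon.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    logger.info("wrote results to %s", out)
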