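"""End-to-end orchestration of the envirotyping study at desk scale.

`run_characterization` sweeps a scenario grid (sites × years × sowing dates
× managements × cultivars), simulates every season, bins the daily RT and GT
indices into 100 °Cd trajectories, clusters them into water (WSP) and heat
(HSP) stress patterns and reports per-site pattern frequencies together
with per-cluster simulated-yield summaries.

`run_testing` takes an independent trial table (site, year, hybrid,
observed yield), simulates the reference cultivar for each trial site-year,
classifies the season into the trained WSP/HSP patterns, regroups the pair
into the four environment categories (ECG), and quantifies how much of the
observed yield variance the classification explains (REML variance
components) plus the hybrid × ECG biplot.

All artifacts are plain CSV/JSON, written sorted, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crop_sim, envirotyping, evalstats, synthetic_data
from .crop_sim import CULTIVAR_PRESETS, SeasonIncompleteError
from .envirotyping import ClusterModel, EcgLabel
from .synthetic_data import SITE_PRESETS, TrialVariance

logger = logging.getLogger("sorgenv")

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "run_characterization",
    "run_testing",
    "CharacterizationResult",
    "TestingResult",
    "gen_trials_from_classification",
]

#: Scenario defaults: four sowing dates around the regional median planting
#: date, and two fertility-density managements (the N label is carried for
#: bookkeeping only; nitrogen is represented through its paired density).
DEFAULT_CONFIG: dict = {
    "weather": {"sites": ["dry_west", "intermediate", "wet_east"], "start_year": 1998, "n_years": 20},
    "soil": "default",
    "cultivars": ["hybrid_1", "hybrid_2"],
    "scenarios": {
        "sowing_dates": ["05-15", "06-01", "06-15", "07-01"],
        "managements": [
            {"density": 28.0, "n_label": 138.0},
            {"density": 14.0, "n_label": 69.0},
        ],
        "init": {"fraction_full_profile": 0.5, "no3_mg_kg": 50.0},
    },
    "clustering": {"k_wsp": 4, "k_hsp": 3, "k_range": [2, 8], "n_init": 25, "bin_width": 100.0},
    "testing": {
        "reference_cultivar": "hybrid_1",
        "sowing_date": "06-01",
        "density": 17.0,
        "nonstress_wsp": None,  # defaults to the highest-mean-RT pattern
        "low_hsp": None,  # defaults to the highest-mean-GT pattern
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, filling unset sections from the defaults."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()


def _site_weather(config: dict, seed: int) -> dict[str, pd.DataFrame]:
    """Synthesize (deterministically) one weather series per configured site."""
    wconf = config["weather"]
    rng = np.random.default_rng(seed)
    series = {}
    for site in sorted(wconf["sites"]):
        site_seed = int(rng.integers(2**31))
        climate = SITE_PRESETS[site]
        series[site] = synthetic_data.gen_weather(
            climate, wconf["start_year"], wconf["n_years"], site_seed
        )
    return series


def _soil(config: dict) -> crop_sim.SoilProfile:
    if config["soil"] == "default":
        return crop_sim.default_soil_profile()
    layers = [crop_sim.SoilLayer(**layer) for layer in config["soil"]["layers"]]
    extra = {k: v for k, v in config["soil"].items() if k != "layers"}
    return crop_sim.SoilProfile(layers=layers, **extra)


def _n_bins(config: dict) -> int:
    ref = CULTIVAR_PRESETS[config["testing"]["reference_cultivar"]]
    return int(np.floor(ref.tt_maturity / config["clustering"]["bin_width"]))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    created: str
    outputs: list = field(default_factory=list)
    version: str = "0.1.0"

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2))


@dataclass
class CharacterizationResult:
    wsp_matrix: pd.DataFrame
    hsp_matrix: pd.DataFrame
    wsp_model: ClusterModel
    hsp_model: ClusterModel
    wsp_frequencies: pd.DataFrame
    hsp_frequencies: pd.DataFrame
    seasons: pd.DataFrame  # meta + simulated yield + WSP/HSP labels
    yield_by_wsp: pd.DataFrame
    yield_by_hsp: pd.DataFrame
    n_failed: int
    manifest: RunManifest


def run_characterization(
    config: dict, seed: int, outdir: str | Path | None = None
) -> CharacterizationResult:
    """Simulate the scenario grid and discover WSP/HSP stress patterns."""
    weather = _site_weather(config, seed)
    profile = _soil(config)
    n_bins = _n_bins(config)
    cconf = config["clustering"]
    sconf = config["scenarios"]
    init = {"fraction_full_profile": sconf["init"]["fraction_full_profile"]}
    start_year = config["weather"]["start_year"]
    n_years = config["weather"]["n_years"]

    rt_rows, gt_rows = [], []
    n_failed = 0
    for site in sorted(weather):
        wx = weather[site]
        for year in range(start_year, start_year + n_years):
            for sowing_md in sconf["sowing_dates"]:
                sowing = f"{year}-{sowing_md}"
                for mgmt in sconf["managements"]:
                    for cultivar in config["cultivars"]:
                        cv = CULTIVAR_PRESETS[cultivar]
                        try:
                            res = crop_sim.simulate_season(
                                wx,
                                profile,
                                cv,
                                {"sowing_date": sowing, "density": mgmt["density"]},
                                init,
                            )
                        except SeasonIncompleteError:
                            n_failed += 1
                            logger.warning(
                                "season incomplete: %s %s sown %s (excluded)",
                                site,
                                cultivar,
                                sowing,
                            )
                            continue
                        meta = {
                            "site": site,
                            "year": year,
                            "sowing": sowing_md,
                            "density": mgmt["density"],
                            "cultivar": cultivar,
                            "yield_kg_ha": res.yield_kg_ha,
                        }
                        rt_rows.append((meta, res.daily))
                        gt_rows.append((meta, res.daily))

    wsp_matrix = envirotyping.build_trajectory_matrix(rt_rows, "rt", n_bins, cconf["bin_width"])
    hsp_matrix = envirotyping.build_trajectory_matrix(gt_rows, "gt", n_bins, cconf["bin_width"])

    def _fit(matrix: pd.DataFrame, k_setting) -> ClusterModel:
        X = envirotyping.trajectory_values(matrix)
        votes: dict = {}
        if k_setting in (None, "auto"):
            lo, hi = cconf["k_range"]
            k, votes = envirotyping.select_k(X, range(lo, hi + 1), seed, cconf["n_init"])
        else:
            k = int(k_setting)
        model = envirotyping.fit_kmeans(X, k, seed, n_init=cconf["n_init"])
        model.index_votes = votes
        return model

    wsp_model = _fit(wsp_matrix, cconf["k_wsp"])
    hsp_model = _fit(hsp_matrix, cconf["k_hsp"])

    meta = wsp_matrix[["site", "year", "sowing", "density", "cultivar", "yield_kg_ha"]]
    wsp_freq = envirotyping.cluster_frequencies(wsp_model.labels, meta, "site", prefix="WSP")
    hsp_freq = envirotyping.cluster_frequencies(hsp_model.labels, meta, "site", prefix="HSP")

    seasons = meta.copy()
    seasons["wsp"] = wsp_model.labels
    seasons["hsp"] = hsp_model.labels
    seasons = seasons.sort_values(["site", "year", "sowing", "density", "cultivar"]).reset_index(drop=True)

    yield_by_wsp = (
        seasons.groupby("wsp")["yield_kg_ha"].agg(["mean", "std", "count"]).reset_index()
    )
    yield_by_hsp = (
        seasons.groupby("hsp")["yield_kg_ha"].agg(["mean", "std", "count"]).reset_index()
    )

    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=seed,
        created=datetime.now(timezone.utc).isoformat(),
    )
    result = CharacterizationResult(
        wsp_matrix=wsp_matrix,
        hsp_matrix=hsp_matrix,
        wsp_model=wsp_model,
        hsp_model=hsp_model,
        wsp_frequencies=wsp_freq,
        hsp_frequencies=hsp_freq,
        seasons=seasons,
        yield_by_wsp=yield_by_wsp,
        yield_by_hsp=yield_by_hsp,
        n_failed=n_failed,
        manifest=manifest,
    )
    if outdir is not None:
        _write_characterization(result, Path(outdir))
    return result


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def _write_characterization(result: CharacterizationResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "wsp_matrix.csv": result.wsp_matrix,
        "hsp_matrix.csv": result.hsp_matrix,
        "wsp_frequencies.csv": result.wsp_frequencies,
        "hsp_frequencies.csv": result.hsp_frequencies,
        "seasons.csv": result.seasons,
        "yield_by_wsp.csv": result.yield_by_wsp,
        "yield_by_hsp.csv": result.yield_by_hsp,
    }
    for name, df in files.items():
        _write_csv(df, outdir / name)
    result.wsp_model.to_json(outdir / "wsp_model.json")
    result.hsp_model.to_json(outdir / "hsp_model.json")
    result.manifest.outputs = sorted(files) + ["wsp_model.json", "hsp_model.json"]
    result.manifest.write(outdir / "manifest.json")


def nonstress_pattern(model: ClusterModel) -> int:
    """The cluster whose centroid has the highest mean index (least stress)."""
    return int(np.argmax(model.centroids.mean(axis=1))) + 1


@dataclass
class TestingResult:
    trials: pd.DataFrame  # trial table + wsp/hsp/ecg labels
    variance: evalstats.VarianceDecomposition | None
    biplot: evalstats.BiplotResult | None
    n_excluded: int


def classify_site_years(
    config: dict,
    site_years: pd.DataFrame,
    wsp_model: ClusterModel,
    hsp_model: ClusterModel,
    seed: int,
) -> pd.DataFrame:
    """Simulate the reference cultivar for each site-year and label it.

    Returns one row per site-year with WSP, HSP and ECG labels.  Site-years
    whose site has no weather coverage are excluded with a log entry.
    """
    weather = _site_weather(config, seed)
    profile = _soil(config)
    n_bins = _n_bins(config)
    tconf = config["testing"]
    cv = CULTIVAR_PRESETS[tconf["reference_cultivar"]]
    init = {"fraction_full_profile": config["scenarios"]["init"]["fraction_full_profile"]}
    nonstress_wsp = tconf["nonstress_wsp"]
    low_hsp = tconf["low_hsp"]
    nonstress_wsp = (
        {nonstress_pattern(wsp_model)} if nonstress_wsp is None else set(nonstress_wsp)
    )
    low_hsp = {nonstress_pattern(hsp_model)} if low_hsp is None else set(low_hsp)

    rows = []
    for _, sy in site_years.drop_duplicates(subset=["site", "year"]).iterrows():
        site, year = sy["site"], int(sy["year"])
        if site not in weather:
            logger.warning("site-year %s-%s has no weather coverage (excluded)", site, year)
            continue
        sowing = f"{year}-{tconf['sowing_date']}"
        try:
            res = crop_sim.simulate_season(
                weather[site],
                profile,
                cv,
                {"sowing_date": sowing, "density": tconf["density"]},
                init,
            )
        except (SeasonIncompleteError, ValueError):
            logger.warning("site-year %s-%s could not be simulated (excluded)", site, year)
            continue
        rt = envirotyping.bin_trajectory(
            res.daily["rt"].to_numpy(), res.daily["tt"].to_numpy(), n_bins=n_bins
        )
        gt = envirotyping.bin_trajectory(
            res.daily["gt"].to_numpy(), res.daily["tt"].to_numpy(), n_bins=n_bins
        )
        wsp = envirotyping.classify_trajectory(rt, wsp_model)
        hsp = envirotyping.classify_trajectory(gt, hsp_model)
        ecg = envirotyping.regroup_ecg(wsp, hsp, nonstress_wsp, low_hsp)
        rows.append(
            {
                "site": site,
                "year": year,
                "wsp": wsp,
                "hsp": hsp,
                "ecg": ecg.value,
                "sim_yield_kg_ha": res.yield_kg_ha,
            }
        )
    return pd.DataFrame(rows, columns=["site", "year", "wsp", "hsp", "ecg", "sim_yield_kg_ha"])


def run_testing(
    config: dict,
    trial_table: pd.DataFrame,
    wsp_model: ClusterModel,
    hsp_model: ClusterModel,
    seed: int,
    outdir: str | Path | None = None,
) -> TestingResult:
    """Classify trial site-years and evaluate the ECG against observed yield."""
    if trial_table.empty:
        return TestingResult(trials=trial_table.copy(), variance=None, biplot=None, n_excluded=0)

    trial_table = trial_table.drop(
        columns=[c for c in ("wsp", "hsp", "ecg", "sim_yield_kg_ha") if c in trial_table.columns]
    )
    labels = classify_site_years(config, trial_table, wsp_model, hsp_model, seed)
    merged = trial_table.merge(labels, on=["site", "year"], how="inner")
    n_excluded = len(trial_table) - len(merged)

    variance = None
    if not merged.empty and merged["site"].nunique() >= 2:
        variance = evalstats.variance_components(merged)

    biplot = None
    if not merged.empty and merged["hybrid"].nunique() >= 3 and merged["ecg"].nunique() >= 2:
        env = merged.assign(env=merged["site"].astype(str) + ":" + merged["year"].astype(str))
        wide = env.pivot_table(index="hybrid", columns="env", values="yield_kg_ha", aggfunc="mean")
        try:
            # tol is absolute, so scale it to the yield magnitude; changes
            # below ~0.1% of the mean yield are agronomically irrelevant.
            tol = 1e-3 * float(np.nanmean(np.abs(wide.to_numpy())) + 1.0)
            completed, _ = evalstats.impute_gaps(wide, rank=2, tol=tol, max_iter=2000)
            env_ecg = env.drop_duplicates("env").set_index("env")["ecg"]
            means = completed.T.groupby(env_ecg).mean().T
            biplot = evalstats.ecg_biplot(means)
        except ValueError as exc:
            logger.warning("biplot skipped: %s", exc)

    result = TestingResult(trials=merged, variance=variance, biplot=biplot, n_excluded=n_excluded)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_csv(merged.sort_values(["site", "year", "hybrid"]), outdir / "trials_classified.csv")
        if variance is not None:
            (outdir / "variance_components.json").write_text(
                json.dumps(variance.to_dict(), indent=2)
            )
        if biplot is not None:
            _write_csv(biplot.scores.reset_index(names="hybrid"), outdir / "biplot_scores.csv")
            _write_csv(biplot.loadings.reset_index(names="ecg"), outdir / "biplot_loadings.csv")
    return result


def gen_trials_from_classification(
    labels: pd.DataFrame,
    hybrids: list[str],
    tv: TrialVariance,
    ecg_means: dict[str, float],
    missing_frac: float,
    seed: int,
) -> pd.DataFrame:
    """Build a synthetic trial table whose yields are driven by the ECG.

    ``labels`` is the site-year classification from
    :func:`classify_site_years`; each observed yield is the grand mean plus
    the fixed mean shift of its ECG category (``ecg_means``, kg ha⁻¹), a
    site effect, a hybrid effect and residual noise.  Used to demonstrate
    that the pipeline recovers an environment signal it is wired to carry.
    """
    rng = np.random.default_rng(seed)
    sites = sorted(labels["site"].unique())
    site_eff = dict(zip(sites, rng.normal(0.0, np.sqrt(tv.sigma2_site), len(sites))))
    hyb_eff = dict(zip(hybrids, rng.normal(0.0, np.sqrt(tv.sigma2_hybrid), len(hybrids))))
    rows = []
    for _, lab in labels.iterrows():
        for hybrid in hybrids:
            if rng.random() < missing_frac:
                continue
            rows.append(
                {
                    "site": lab["site"],
                    "year": int(lab["year"]),
                    "hybrid": hybrid,
                    "yield_kg_ha": tv.grand_mean
                    + ecg_means.get(lab["ecg"], 0.0)
                    + site_eff[lab["site"]]
                    + hyb_eff[hybrid]
                    + rng.normal(0.0, np.sqrt(tv.sigma2_resid)),
                }
            )
    return pd.DataFrame(rows)
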