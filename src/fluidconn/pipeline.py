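"""End-to-end orchestration: signals -> band features -> group statistics.

``run_subject`` turns one subject's regional time series into per-band
features (fluidity via windowed circular correlation, PLI graph metrics with
null-model normalization, alpha peak frequency). ``run_cohort`` assembles the
feature table for a whole (synthetic or loaded) cohort and runs the
statistical layer: per-measure PERMANOVA on age-residualized Mahalanobis
distances, pairwise band-wise post-hocs with FDR, correlation analyses gated
to features that survived the group test, and the LC x cognitive-reserve
quadratic regression. Every run writes a manifest (config, seeds, versions,
analysis ns) from which outputs are byte-identically regenerable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamic import WindowSpec, dfc_matrix, fc_stream, fluidity
from .signals import (
    BROADBAND,
    DEFAULT_BANDS,
    BandSpec,
    RegionTimeSeries,
    alpha_peak_frequency,
    bandpass,
    instantaneous_phase,
)
from .static import normalized_metrics, sfc_graph
from .stats import (
    fdr_adjust,
    fit_lc_reserve_model,
    mahalanobis_distances,
    partial_spearman,
    permanova,
    residualize,
)
from .synthetic import (
    CohortConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_subject_signals,
    subject_seeds,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_subject", "run_cohort", "CohortResult"]

GRAPH_MEASURES = ("av_node_strength", "modularity", "norm_cluster", "norm_path")
SCORE_COLUMNS = ("executive_function", "verbal_memory", "visual_memory")
CLINICAL_COLUMNS = ("updrs", "mfs", "rbdq", "npi")


@dataclass
class RunConfig:
    """Materialized configuration of one cohort run (echoed into the manifest)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    include_broadband: bool = True
    n_null: int = 100
    n_perm: int = 20000
    null_seed: int = 101
    perm_seed: int = 202
    edge_seconds: float = 1.0  # phase-series edges excluded from windowing
    covariates: tuple[str, ...] = ("age",)
    gate_correlations: bool = True
    alpha: float = 0.05
    correlation_sided: str = "two-sided"
    signals_dir: str | None = None  # read signals instead of simulating
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            if "bands" in sim:
                sim["bands"] = tuple(BandSpec(*b) for b in sim["bands"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "cohort" in raw:
            coh = dict(raw["cohort"])
            for key in ("lc_quadratic",):
                if key in coh:
                    coh[key] = tuple(coh[key])
            if "score_links" in coh:
                coh["score_links"] = {
                    k: (v[0], float(v[1])) for k, v in coh["score_links"].items()
                }
            kwargs["cohort"] = CohortConfig(**coh)
        if "window" in raw:
            kwargs["window"] = WindowSpec(**raw["window"])
        if "bands" in raw:
            kwargs["bands"] = tuple(BandSpec(*b) for b in raw["bands"])
        for key in (
            "include_broadband",
            "n_null",
            "n_perm",
            "null_seed",
            "perm_seed",
            "edge_seconds",
            "gate_correlations",
            "alpha",
            "correlation_sided",
            "signals_dir",
            "out_dir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "covariates" in raw:
            kwargs["covariates"] = tuple(raw["covariates"])
        return cls(**kwargs)

    def to_manifest(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        config = encode(self)
        config.pop("out_dir", None)  # output location is not part of the run
        return {"version": __version__, "config": config}


def run_subject(ts: RegionTimeSeries, cfg: RunConfig) -> dict:
    """Per-band features of one subject.

    Per band: band-pass -> phase -> {windowed CCor -> dFC -> fluidity} and
    {PLI graph -> null-normalized graph metrics}; plus broadband fluidity and
    the alpha peak frequency of the raw signal. Stage failures propagate as
    NaN features with a log record, never as fabricated values.
    """
    record: dict = {"subject_id": ts.subject_id}
    bands = list(cfg.bands) + ([BROADBAND] if cfg.include_broadband else [])
    for band in bands:
        suffix = band.name
        try:
            narrow = bandpass(ts, band)
            phases = instantaneous_phase(narrow, on_constant="exclude")
        except Exception as exc:  # configuration errors surface as missing band
            logger.warning("band %s failed for %s: %s", suffix, ts.subject_id, exc)
            record[f"fluidity_{suffix}"] = float("nan")
            continue
        try:
            # drop filter/Hilbert edge transients from the windowed branch
            trim = int(cfg.edge_seconds * phases.fs)
            windowed = phases
            if trim > 0 and phases.n_samples > 2 * trim:
                windowed = dataclasses.replace(
                    phases, phases=phases.phases[:, trim:-trim]
                )
            stream = fc_stream(windowed, cfg.window)
            record[f"fluidity_{suffix}"] = fluidity(dfc_matrix(stream)).value
        except Exception as exc:
            logger.warning("fluidity %s failed for %s: %s", suffix, ts.subject_id, exc)
            record[f"fluidity_{suffix}"] = float("nan")
        if band.name == "broadband":
            continue  # graph metrics are band-specific in this analysis
        try:
            graph = sfc_graph(phases)
            metrics = normalized_metrics(graph, n_null=cfg.n_null, seed=cfg.null_seed)
            record[f"av_node_strength_{suffix}"] = metrics.av_node_strength
            record[f"modularity_{suffix}"] = metrics.modularity
            record[f"norm_cluster_{suffix}"] = metrics.norm_cluster
            record[f"norm_path_{suffix}"] = metrics.norm_path
        except Exception as exc:
            logger.warning("graph %s failed for %s: %s", suffix, ts.subject_id, exc)
            for m in GRAPH_MEASURES:
                record[f"{m}_{suffix}"] = float("nan")
    try:
        record["alpha_peak"] = alpha_peak_frequency(ts)
    except Exception as exc:
        logger.warning("alpha peak failed for %s: %s", ts.subject_id, exc)
        record["alpha_peak"] = float("nan")
    return record


@dataclass
class CohortResult:
    features: pd.DataFrame  # long: one row per subject x band
    cohort: pd.DataFrame  # wide cohort table incl. features
    permanova: pd.DataFrame
    posthoc: pd.DataFrame
    correlations: pd.DataFrame
    lc_model: object
    manifest: dict


def _features_long(wide: pd.DataFrame, band_names: list[str]) -> pd.DataFrame:
    rows = []
    for _, rec in wide.iterrows():
        for band in band_names:
            row = {"subject_id": rec["subject_id"], "band": band}
            for m in ("fluidity",) + GRAPH_MEASURES:
                col = f"{m}_{band}"
                row[m] = rec.get(col, float("nan"))
            rows.append(row)
    out = pd.DataFrame(rows)
    out["provenance"] = f"fluidconn-{__version__}"
    return out


def run_cohort(cfg: RunConfig) -> CohortResult:
    """Full cohort analysis; writes TSV outputs + manifest when configured."""
    groups = []
    for grp, size in cfg.cohort.group_sizes.items():
        groups.extend([grp] * size)
    seeds = subject_seeds(cfg.simulation.seed, len(groups))

    records = []
    if cfg.signals_dir:
        from .io import read_signals

        paths = sorted(Path(cfg.signals_dir).glob("*.tsv"))
        if len(paths) != len(groups):
            raise ValueError("signals_dir file count does not match cohort size")
        for path in paths:
            records.append(run_subject(read_signals(path), cfg))
    else:
        for grp, seed in zip(groups, seeds):
            sim = dataclasses.replace(cfg.simulation, seed=seed, bands=cfg.bands)
            ts = simulate_subject_signals(sim, group=grp)
            rec = run_subject(ts, cfg)
            records.append(rec)
    wide = pd.DataFrame(records)
    wide["group"] = groups
    wide["subject_id"] = [f"{g}-{i:03d}" for i, g in enumerate(groups)]

    cohort = simulate_cohort(cfg.cohort, features=wide.drop(columns=["group"]))
    cohort["group"] = groups  # keep feature/group alignment authoritative
    if len(set(groups)) < 2:
        raise ValueError("need at least 2 groups")

    band_names = [b.name for b in cfg.bands]
    fluidity_bands = band_names + (["broadband"] if cfg.include_broadband else [])
    age = cohort["age"].values

    measure_bands = {"fluidity": fluidity_bands}
    for m in GRAPH_MEASURES:
        measure_bands[m] = band_names

    perm_rows, posthoc_rows, gated = [], [], []
    for measure, bands_for in measure_bands.items():
        cols = [f"{measure}_{b}" for b in bands_for if f"{measure}_{b}" in cohort]
        if not cols:
            continue
        mat = cohort[cols].values.astype(float)
        ok = np.all(np.isfinite(mat), axis=1)
        if ok.sum() < 10:
            logger.warning("skipping %s: too few complete cases", measure)
            continue
        resid = np.column_stack(
            [residualize(mat[ok, j], age[ok]) for j in range(mat.shape[1])]
        )
        try:
            dist = mahalanobis_distances(resid)
        except ValueError as exc:
            logger.warning("skipping %s: %s", measure, exc)
            continue
        res = permanova(
            dist, cohort["group"].values[ok], n_perm=cfg.n_perm, seed=cfg.perm_seed
        )
        perm_rows.append(
            {
                "measure": measure,
                "pseudo_F": res.pseudo_F,
                "p": res.p,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "n": res.n_obs,
                "n_perm": res.n_perm,
            }
        )
        if res.p < cfg.alpha:
            # band-wise pairwise post-hocs on univariate distances
            raw_ps = []
            for col in cols:
                vals = residualize(cohort[col].values.astype(float), age)
                okc = np.isfinite(vals)
                d = np.abs(vals[okc, None] - vals[None, okc])
                sub = permanova(
                    d,
                    cohort["group"].values[okc],
                    n_perm=cfg.n_perm,
                    seed=cfg.perm_seed,
                    pairwise=True,
                )
                for pair, f, pv, _ in sub.pairwise:
                    raw_ps.append(
                        {
                            "measure": measure,
                            "feature": col,
                            "pair": f"{pair[0]} vs {pair[1]}",
                            "F": f,
                            "p": pv,
                        }
                    )
            if raw_ps:
                adj = fdr_adjust(np.array([r["p"] for r in raw_ps]))
                for r, pa in zip(raw_ps, adj):
                    r["p_fdr"] = float(pa)
                    posthoc_rows.append(r)
                for col in cols:
                    if any(
                        r["feature"] == col and r["p_fdr"] < cfg.alpha
                        for r in posthoc_rows
                    ):
                        gated.append(col)

    permanova_df = pd.DataFrame(perm_rows)
    posthoc_df = pd.DataFrame(posthoc_rows)

    if not cfg.gate_correlations:
        gated = sorted(
            {c for m, bs in measure_bands.items() for b in bs
             if (c := f"{m}_{b}") in cohort}
        )
    corr_rows = []
    cov_cols = [c for c in cfg.covariates if c in cohort]
    for feature in gated:
        for target in SCORE_COLUMNS + CLINICAL_COLUMNS:
            if target not in cohort:
                continue
            covs = cohort[cov_cols].values if cov_cols else None
            if target in SCORE_COLUMNS and "premorbid_iq" in cohort:
                covs = (
                    cohort[cov_cols + ["premorbid_iq"]].values
                    if cov_cols
                    else cohort[["premorbid_iq"]].values
                )
            try:
                rho, p = partial_spearman(
                    cohort[feature].values,
                    cohort[target].values,
                    covariates=covs,
                    alternative=cfg.correlation_sided,
                )
            except ValueError as exc:
                logger.warning("correlation %s~%s failed: %s", feature, target, exc)
                continue
            corr_rows.append({"feature": feature, "target": target, "rho": rho, "p": p})
    correlations_df = pd.DataFrame(corr_rows)
    if len(correlations_df):
        correlations_df["p_fdr"] = fdr_adjust(correlations_df["p"].values)

    lc_fit = None
    flu_col = cfg.cohort.fluidity_feature
    if flu_col in cohort and "lc_cr" in cohort:
        try:
            lc_fit = fit_lc_reserve_model(cohort, flu_col, "lc_cr", "premorbid_iq")
        except ValueError as exc:
            logger.warning("LC model skipped: %s", exc)

    manifest = cfg.to_manifest()
    manifest["subject_seeds"] = seeds
    manifest["n_subjects"] = len(groups)
    manifest["gated_features"] = sorted(set(gated))
    manifest["analyses"] = {
        "permanova": len(permanova_df),
        "posthoc": len(posthoc_df),
        "correlations": len(corr_rows),
        "lc_model_n": None if lc_fit is None else lc_fit.n_obs,
    }

    result = CohortResult(
        features=_features_long(wide, fluidity_bands),
        cohort=cohort,
        permanova=permanova_df,
        posthoc=posthoc_df,
        correlations=correlations_df,
        lc_model=lc_fit,
        manifest=manifest,
    )
    if cfg.out_dir:
        _write_outputs(result, cfg.out_dir)
    return result


def _write_outputs(result: CohortResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = lambda df: df.to_csv(sep="\t", index=False, float_format="%.12g")
    (out / "features.tsv").write_text(fmt(result.features))
    (out / "cohort.tsv").write_text(fmt(result.cohort))
    (out / "permanova.tsv").write_text(fmt(result.permanova))
    (out / "posthoc.tsv").write_text(fmt(result.posthoc))
    (out / "correlations.tsv").write_text(fmt(result.correlations))
    if result.lc_model is not None:
        rows = [
            {
                "term": name,
                "coef": result.lc_model.coefficients[name],
                "se": result.lc_model.se[name],
                "t": result.lc_model.t[name],
                "p": result.lc_model.p[name],
            }
            for name in result.lc_model.coefficients
        ]
        head = (
            f"# F({result.lc_model.overall_df[0]},{result.lc_model.overall_df[1]})"
            f"={result.lc_model.overall_F:.6g} p={result.lc_model.overall_p:.6g}"
            f" n={result.lc_model.n_obs}\n"
        )
        (out / "lc_model.tsv").write_text(head + fmt(pd.DataFrame(rows)))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
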