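"""End-to-end orchestration: simulate -> extract -> diagnose -> prognose.

`run_full_study` ties the stages into one reproducible run controlled
by a single configuration object (YAML-serializable) and a master seed.
Every analysis default that a published workflow typically leaves
unstated (threshold method, minimum particle area, box sizes, ties
convention, minimum group fraction) is carried explicitly in the
configuration so deviations are visible in the report.
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
from PIL import Image

from . import diagnostics as dg
from . import morphometry as mm
from . import prep
from . import prognostics as pg
from . import synthetic as syn

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ConfigError",
    "DataError",
    "DegenerateStatisticsError",
    "run_full_study",
    "extract_features",
    "features_table",
    "diagnose",
    "prognose",
    "write_cohort",
    "read_cohort",
]

log = logging.getLogger("cytocluster")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ConfigError(PipelineError):
    pass


class DataError(PipelineError):
    pass


class DegenerateStatisticsError(PipelineError):
    pass


@dataclass
class PipelineConfig:
    """Study-level configuration; nested cohort overrides pass through
    to :class:`cytocluster.synthetic.CohortConfig`."""

    seed: int = 0
    counts: dict[str, int] | None = None
    threshold_method: str = "isodata"
    polarity: str = "dark_foreground"
    connectivity: int = 8
    min_area: int = 64
    box_sizes: tuple[int, ...] = mm.DEFAULT_BOX_SIZES
    # the nine analyzed parameters: eight shape descriptors + field FD
    features: tuple[str, ...] = ("perimeter", "fit_ellipse_major",
                                 "fit_ellipse_minor", "angle", "circularity",
                                 "feret_max", "feret_min", "solidity",
                                 "fractal_dimension")
    combine_features: tuple[str, ...] = ("circularity", "solidity",
                                         "fractal_dimension")
    adjusters: tuple[str, ...] = ("age55", "cytology_flag")
    subsets: tuple[str, ...] = ("all_ec", "em_g1_g3", "em_g2_g3")
    min_group_frac: float = 0.10
    cutpoint_permutations: int = 0
    ties: str = "efron"
    field_size: int = 384
    clusters_per_field_mean: float = 6.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError("config", f"unknown keys: {sorted(bad)}")
        for key in ("box_sizes", "features", "combine_features",
                    "adjusters", "subsets"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def cohort_config(self) -> syn.CohortConfig:
        kwargs: dict = {"seed": self.seed,
                        "field_size": self.field_size,
                        "clusters_per_field_mean": self.clusters_per_field_mean}
        if self.counts is not None:
            kwargs["counts"] = dict(self.counts)
            cyto = {c: syn._DEFAULT_CYTOLOGY[c] for c in kwargs["counts"]}
            ages = {c: syn._DEFAULT_AGES[c] for c in kwargs["counts"]}
            shapes = {c: syn._DEFAULT_SHAPES[c] for c in kwargs["counts"]}
            kwargs.update(cytology_probs=cyto, age_mean_sd=ages,
                          shape_ranges=shapes)
        return syn.default_cohort_config(**kwargs)


def extract_features(
    image: np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[list[mm.ClusterFeatures], float, float]:
    """Measure one field image: per-cluster features, field FD, threshold."""
    config = config or PipelineConfig()
    gray = prep.to_gray8(image)
    res = prep.binarize(gray, method=config.threshold_method,
                        polarity=config.polarity)
    if res.degenerate:
        return [], float("nan"), res.threshold
    labels = prep.label_clusters(res.mask, connectivity=config.connectivity,
                                 min_area=config.min_area)
    clusters = mm.measure_clusters(labels)
    fd = (mm.boxcount_fd(res.mask, sizes=config.box_sizes)
          if res.mask.any() else float("nan"))
    return clusters, fd, res.threshold


def features_table(
    fields_by_patient: dict[str, list[syn.FieldSample]] | dict[str, list[np.ndarray]],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract specimen-level features for a cohort of field images.

    ``fields_by_patient`` maps patient id to its list of field images
    (``FieldSample`` or plain arrays).  Returns (specimen table, long
    per-cluster table).
    """
    config = config or PipelineConfig()
    spec_rows = []
    cluster_rows = []
    for pid, fields in fields_by_patient.items():
        ffs = []
        for i, f in enumerate(fields, start=1):
            img = f.image if isinstance(f, syn.FieldSample) else f
            clusters, fd, thr = extract_features(img, config)
            log.info("extract specimen=%s field=%d method=%s threshold=%s "
                     "clusters=%d", pid, i, config.threshold_method, thr,
                     len(clusters))
            for c in clusters:
                row = {"patient_id": pid, "field_index": i, "label": c.label}
                row.update(c.as_dict())
                cluster_rows.append(row)
            ffs.append(mm.summarize_field(clusters, fd))
        spec = mm.summarize_specimen(ffs, expected_fields=len(fields))
        row = {"patient_id": pid}
        row.update(spec.as_dict())
        row["n_fields_used"] = spec.n_fields_used
        spec_rows.append(row)
    return pd.DataFrame(spec_rows), pd.DataFrame(cluster_rows)


def _auto_orient(score: np.ndarray, label: np.ndarray) -> tuple[np.ndarray, int]:
    """Flip a marker so its ROC is positively oriented (AUC >= 0.5)."""
    auc, _ = dg.delong_variance(score[label], score[~label])
    return (score, 1) if auc >= 0.5 else (-score, -1)


def diagnose(meta: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Diagnostic stage: per-feature logistic + ROC, and combinations.

    ``meta`` must hold histology, age, cytology and the feature columns.
    Raises :class:`DegenerateStatisticsError` when only one diagnostic
    class is present.
    """
    config = config or PipelineConfig()
    trip = [dg.dichotomize(h, a, c) for h, a, c in
            zip(meta["histology"], meta["age"], meta["cytology"])]
    label = np.array([t[0] for t in trip])
    age55 = np.array([t[1] for t in trip], float)
    cyto = np.array([t[2] for t in trip], float)
    if label.all() or not label.any():
        raise DegenerateStatisticsError(
            "diagnose", "only one diagnostic class present in the cohort")
    out: dict = {"n": int(label.size), "n_positive": int(label.sum()),
                 "features": {}, "combined": {}}
    for feat in config.features:
        if feat not in meta.columns:
            continue
        x = meta[feat].to_numpy(float)
        unadj = dg.fit_logistic(label.astype(float), x[:, None], names=[feat])
        adj = dg.fit_logistic(
            label.astype(float),
            np.column_stack([x, age55, cyto]),
            names=[feat, "age55", "cytology_flag"])
        oriented, direction = _auto_orient(x, label)
        roc = dg.roc_curve(oriented, label)
        out["features"][feat] = {
            "or_unadjusted": unadj.odds_ratio[feat],
            "or_unadjusted_ci": [unadj.ci_low[feat], unadj.ci_high[feat]],
            "p_unadjusted": unadj.p_value[feat],
            "or_adjusted": adj.odds_ratio[feat],
            "or_adjusted_ci": [adj.ci_low[feat], adj.ci_high[feat]],
            "p_adjusted": adj.p_value[feat],
            "separation": bool(unadj.separation or adj.separation),
            "auc": roc.auc, "auc_ci": [roc.ci_low, roc.ci_high],
            "cutoff": roc.cutoff * direction,
            "direction": ("higher_in_disease" if direction == 1
                          else "lower_in_disease"),
            "sensitivity": roc.sens_at_cutoff,
            "specificity": roc.spec_at_cutoff,
        }
    cyto_roc = dg.roc_curve(cyto, label)
    out["cytology_auc"] = cyto_roc.auc
    for feat in config.combine_features:
        if feat not in meta.columns:
            continue
        x = meta[feat].to_numpy(float)
        score, fit = dg.combined_score(cyto, x, label)
        auc_c, auc_cyto, p = dg.delong_paired_test(score, cyto, label)
        out["combined"][feat] = {
            "auc_combined": auc_c, "auc_cytology": auc_cyto,
            "p_delong": p, "separation": fit.separation,
        }
    return out


# Risk-group orientation per marker: lower circularity/solidity and
# higher fractal dimension mark the poor-prognosis group.
_CUTPOINT_ORIENTATION = {
    "circularity": "low_risk_below",
    "solidity": "low_risk_below",
    "fractal_dimension": "high_risk_above",
}


def prognose(meta: pd.DataFrame, config: PipelineConfig | None = None,
             rng: np.random.Generator | None = None) -> dict:
    """Prognostic stage: cutpoints, KM/log-rank, and Cox models."""
    config = config or PipelineConfig()
    out: dict = {}
    for subset in config.subsets:
        classes = pg.SUBSET_PRESETS[subset]
        sub = meta[meta["histology"].isin(classes)]
        res: dict = {"n": int(len(sub)), "n_events": int(sub["event"].sum()),
                     "markers": {}}
        out[subset] = res
        if len(sub) < 10 or sub["event"].sum() == 0:
            res["skipped"] = "too few subjects or no events"
            continue
        times = sub["time_months"].to_numpy(float)
        events = sub["event"].to_numpy(bool)
        age55 = (sub["age"].to_numpy(float) >= 55).astype(float)
        endometrioid = sub["histology"].isin(
            ("EM_G1", "EM_G2", "EM_G3")).to_numpy(float)
        for feat in config.combine_features:
            if feat not in sub.columns:
                continue
            x = sub[feat].to_numpy(float)
            entry: dict = {}
            res["markers"][feat] = entry
            try:
                cut = pg.optimal_cutpoint(
                    x, times, events,
                    min_group_frac=config.min_group_frac,
                    orientation=_CUTPOINT_ORIENTATION.get(feat,
                                                          "low_risk_below"),
                    feature_name=feat,
                    n_permutations=config.cutpoint_permutations,
                    rng=rng)
            except ValueError as exc:
                entry["cutpoint_error"] = str(exc)
                continue
            grp = (x <= cut.cutoff).astype(int)
            km = pg.km_estimate(times, events, grp)
            chi, p = pg.logrank_test(times, events, grp)
            entry["cutoff"] = cut.cutoff
            entry["chi_square"] = cut.chi_square
            entry["p_uncorrected"] = cut.p_uncorrected
            entry["p_corrected"] = cut.p_corrected
            entry["n_low"] = cut.n_low
            entry["n_high"] = cut.n_high
            entry["orientation"] = cut.orientation
            entry["logrank_p"] = p
            entry["km"] = {g: tab.reset_index().to_dict(orient="list")
                           for g, tab in km.items()}
            uni = pg.cox_fit(x[:, None], times, events, ties=config.ties,
                             names=[feat])
            entry["cox_univariable"] = _cox_dict(uni, feat)
            adj = pd.DataFrame({feat: x, "age55": age55,
                                "endometrioid": endometrioid,
                                "cluster_count": sub["cluster_count"]})
            drop = [c for c in adj.columns if adj[c].nunique() < 2]
            adj = adj.drop(columns=drop)
            if feat in adj.columns and adj.shape[1] >= 1:
                multi = pg.cox_fit(adj, times, events, ties=config.ties)
                entry["cox_multivariable"] = _cox_dict(multi, feat)
                entry["cox_adjusters"] = [c for c in adj.columns if c != feat]
    return out


def _cox_dict(fit: pg.CoxFit, feat: str) -> dict:
    return {"hr": fit.hazard_ratio[feat],
            "ci": [fit.ci_low[feat], fit.ci_high[feat]],
            "p": fit.p_value[feat],
            "n_events": fit.n_events,
            "monotone_likelihood": fit.monotone_likelihood}


def write_cohort(out_dir: str | Path, cohort: pd.DataFrame,
                 fields: dict[str, list[syn.FieldSample]],
                 write_masks: bool = False) -> Path:
    """Write field PNGs and the cohort CSV; returns the CSV path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    cohort = cohort.copy()
    path_cols: dict[str, list[str]] = {}
    for pid, samples in fields.items():
        for i, fs in enumerate(samples, start=1):
            rel = f"images/{pid}_f{i}.png"
            Image.fromarray(fs.image).save(out_dir / rel)
            if write_masks:
                Image.fromarray((fs.mask * 255).astype(np.uint8)).save(
                    out_dir / f"images/{pid}_f{i}_mask.png")
            path_cols.setdefault(f"field_{i}", []).append(rel)
    for col, vals in path_cols.items():
        cohort[col] = vals
    csv_path = out_dir / "cohort.csv"
    cohort.to_csv(csv_path, index=False)
    return csv_path


def read_cohort(csv_path: str | Path) -> tuple[pd.DataFrame, dict[str, list[np.ndarray]]]:
    """Read a cohort CSV and its referenced field images."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    base = csv_path.parent
    fields: dict[str, list[np.ndarray]] = {}
    cols = sorted(c for c in df.columns if c.startswith("field_"))
    for _, row in df.iterrows():
        fields[row["patient_id"]] = [
            np.asarray(Image.open(base / row[c])) for c in cols]
    return df, fields


def run_full_study(config: PipelineConfig | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Simulate, extract, diagnose, and prognose in one deterministic run.

    Returns the report dict; with ``out_dir`` the report JSON, the
    cohort CSV, and the features CSV are also written.
    """
    config = config or PipelineConfig()
    log.info("run_full_study seed=%d threshold=%s min_area=%d",
             config.seed, config.threshold_method, config.min_area)
    try:
        cohort_cfg = config.cohort_config()
    except ValueError as exc:
        raise ConfigError("config", str(exc)) from exc
    try:
        cohort, fields = syn.generate_cohort(cohort_cfg, images=True)
    except RuntimeError as exc:
        raise DataError("simulate", str(exc)) from exc
    spec_df, cluster_df = features_table(fields, config)
    meta = cohort.drop(columns=[c for c in cohort.columns
                                if c in spec_df.columns and c != "patient_id"])
    meta = meta.merge(spec_df, on="patient_id", validate="1:1")
    diag = diagnose(meta, config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    prog = prognose(meta, config, rng=rng)
    report = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "cohort_summary": {
            "n": int(len(meta)),
            "by_histology": meta["histology"].value_counts().to_dict(),
            "age_mean_by_histology": meta.groupby("histology")["age"]
                                         .mean().round(2).to_dict(),
        },
        "diagnostics": diag,
        "prognostics": prog,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(out_dir, cohort, fields)
        spec_df.to_csv(out_dir / "features.csv", index=False)
        cluster_df.to_csv(out_dir / "clusters.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
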