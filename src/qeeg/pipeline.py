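"""Orchestration: simulate/load -> preprocess -> features -> stats -> report.

A run is described by a :class:`RunConfig` (YAML-serializable).  Exactly one
of ``simulate`` (a cohort spec) or ``input_dir`` (EDF/array files named
``<subject>_<T0|T1>.edf`` plus ``cohort.csv``) must be given.  Outputs are
plain files in ``output_dir``: per-channel features CSV, hemisphere-summary
CSV, statistics CSV, correlations CSV, three Markdown tables mirroring the
usual clinical reporting layout (group x time mean +/- SD with significance
markers), a machine-readable JSON summary, and a run manifest echoing the
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import PipelineError, ValidationError
from .io import (
    EEGRecording,
    REQUIRED_CHANNELS,
    SubjectRecord,
    cohort_frame,
    read_array,
    read_cohort_csv,
    read_edf,
)
from .nonlinear import (
    ApEnConfig,
    LZCConfig,
    epoch_average_apen,
    epoch_average_lzc,
    hemisphere_features,
)
from .preprocess import PreprocessConfig, preprocess
from .simulate import BAND_NAMES, CohortSpec, NIHSSModel, synth_cohort
from .spectral import WelchConfig, epoch_average_rpsd
from .stats import StatReport, analyze_cohort

log = logging.getLogger("qeeg")

FEATURE_CSV_COLUMNS = ("subject_id", "session", "channel", "delta", "theta",
                       "alpha", "beta", "total_power", "lzc", "apen")


@dataclass
class RunConfig:
    """Full description of one pipeline run."""

    simulate: CohortSpec | None = None
    input_dir: str | None = None
    output_dir: str = "qeeg_out"
    seed: int | None = None  # overrides simulate.seed when given
    features: tuple[str, ...] = ("bands", "lzc", "apen")
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    lzc: LZCConfig = field(default_factory=LZCConfig)
    apen: ApEnConfig = field(default_factory=ApEnConfig)
    pooled_t: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulate is None) == (self.input_dir is None):
            raise ValidationError(
                "exactly one of 'simulate' or 'input_dir' must be set")
        bad = set(self.features) - {"bands", "lzc", "apen"}
        if bad:
            raise ValidationError(f"unknown features {sorted(bad)}")

    # -- YAML (de)serialization -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("simulate") is not None:
            sim = d["simulate"]
            sim["band_fractions"] = {
                "|".join(k): [float(x) for x in v]
                for k, v in sim["band_fractions"].items()}
            sim["complexity_level"] = {
                "|".join(k): float(v)
                for k, v in sim["complexity_level"].items()}
        d["features"] = list(self.features)
        d["welch"]["total_band"] = list(d["welch"]["total_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            sim = dict(d["simulate"])
            if "band_fractions" in sim:
                sim["band_fractions"] = {
                    tuple(k.split("|")): tuple(v)
                    for k, v in sim["band_fractions"].items()}
            if "complexity_level" in sim:
                sim["complexity_level"] = {
                    tuple(k.split("|")): float(v)
                    for k, v in sim["complexity_level"].items()}
            if isinstance(sim.get("nihss_model"), dict):
                sim["nihss_model"] = NIHSSModel(**sim["nihss_model"])
            d["simulate"] = CohortSpec(**sim)
        for key, klass in (("preprocess", PreprocessConfig),
                           ("welch", WelchConfig), ("lzc", LZCConfig),
                           ("apen", ApEnConfig)):
            if isinstance(d.get(key), dict):
                sub = d[key]
                if key == "welch" and "total_band" in sub:
                    sub["total_band"] = tuple(sub["total_band"])
                d[key] = klass(**sub)
        if "features" in d:
            d["features"] = tuple(d["features"])
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def load_cohort_dir(input_dir) -> tuple[list[EEGRecording], list[SubjectRecord]]:
    """Read ``cohort.csv`` plus one EDF/array file per subject x session."""
    input_dir = Path(input_dir)
    csv = input_dir / "cohort.csv"
    if not csv.exists():
        raise PipelineError(f"stage 'load': {csv} not found")
    subjects = read_cohort_csv(csv)
    recordings = []
    for s in subjects:
        for sess in ("T0", "T1"):
            stem = input_dir / f"{s.subject_id}_{sess}"
            if stem.with_suffix(".edf").exists():
                rec = read_edf(stem.with_suffix(".edf"))
            elif stem.with_suffix(".json").exists():
                rec = read_array(stem, require=REQUIRED_CHANNELS)
            else:
                raise PipelineError(
                    f"stage 'load': no recording for subject "
                    f"{s.subject_id} session {sess} under {input_dir}")
            recordings.append(rec)
    return recordings, subjects


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def compute_features(recordings: Sequence[EEGRecording],
                     pre_cfg: PreprocessConfig | None = None,
                     welch_cfg: WelchConfig | None = None,
                     lzc_cfg: LZCConfig | None = None,
                     apen_cfg: ApEnConfig | None = None,
                     features: Sequence[str] = ("bands", "lzc", "apen"),
                     channels: Sequence[str] = REQUIRED_CHANNELS
                     ) -> pd.DataFrame:
    """Per subject x session x channel feature table.

    Each recording is preprocessed to its epoch set; band fractions come
    from epoch-averaged Welch PSDs, LZC/ApEn as per-epoch means.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    welch_cfg = welch_cfg or WelchConfig()
    lzc_cfg = lzc_cfg or LZCConfig()
    apen_cfg = apen_cfg or ApEnConfig()
    rows = []
    for rec in recordings:
        try:
            rec.require_channels(channels)
            epochs = preprocess(rec, pre_cfg)
            for ch in channels:
                row = {"subject_id": rec.subject_id, "session": rec.session,
                       "channel": ch}
                if "bands" in features:
                    bp = epoch_average_rpsd(epochs, ch, welch_cfg)
                    row.update(bp.rpsd)
                    row["total_power"] = bp.total_power
                if "lzc" in features:
                    row["lzc"] = epoch_average_lzc(epochs, ch, lzc_cfg)
                if "apen" in features:
                    row["apen"] = epoch_average_apen(epochs, ch, apen_cfg)
                rows.append(row)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage 'features' failed for subject {rec.subject_id} "
                f"session {rec.session}: {exc}") from exc
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _marks(report: StatReport, group: str, feat: str) -> str:
    """Significance markers for a T1 cell: * / ** within-group (vs T0);
    # / ## between-group at T1, shown on the experimental row; keyed to
    FDR q-values."""
    marks = ""
    try:
        q = report.lookup(f"within_{group}", feat).q_fdr
        if q is not None and q < 0.01:
            marks += "**"
        elif q is not None and q < 0.05:
            marks += "*"
    except KeyError:
        pass
    if group == "experimental":
        try:
            q = report.lookup("between_T1", feat).q_fdr
            if q is not None and q < 0.01:
                marks += "##"
            elif q is not None and q < 0.05:
                marks += "#"
        except KeyError:
            pass
    return marks


_LEGEND = ("*q < 0.05, **q < 0.01 vs the same group at T0 (paired t, "
           "BH-FDR); #q < 0.05, ##q < 0.01 vs control at T1 "
           "(independent t, BH-FDR).")


def _group_time_table(hemi: pd.DataFrame, report: StatReport | None,
                      feats: Sequence[str], title: str,
                      percent: bool = False) -> str:
    lines = [f"### {title}", ""]
    lines.append("| Group | Time | " + " | ".join(feats) + " |")
    lines.append("|---" * (len(feats) + 2) + "|")
    for group in ("experimental", "control"):
        for sess in ("T0", "T1"):
            sub = hemi[(hemi["group"] == group) & (hemi["session"] == sess)]
            cells = []
            for feat in feats:
                v = sub[feat].to_numpy(dtype=float)
                scale = 100.0 if percent else 1.0
                cell = f"{scale * v.mean():.1f} ± {scale * v.std(ddof=1):.1f}" \
                    if percent else \
                    f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
                if sess == "T1" and report is not None:
                    cell += _marks(report, group, feat)
                cells.append(cell)
            lines.append(f"| {group} | {sess} | " + " | ".join(cells) + " |")
    lines += ["", _LEGEND, ""]
    return "\n".join(lines)


def make_report_tables(hemi: pd.DataFrame, subjects: Sequence[SubjectRecord],
                       report: StatReport | None) -> dict[str, str]:
    """Three formatted tables: band rPSD, LZC/ApEn, NIHSS.

    Cells are group x time "mean ± SD"; T1 cells carry significance markers
    keyed to q-values (legend included).  Tables for features that were not
    computed are omitted.
    """
    tables = {}
    band_cols = [b for b in BAND_NAMES if b in hemi.columns]
    if band_cols:
        tables["bands"] = _group_time_table(
            hemi, report, band_cols,
            "Relative band power, affected hemisphere (%; mean ± SD)",
            percent=True)
    nl_cols = [c for c in ("lzc", "apen") if c in hemi.columns]
    if nl_cols:
        tables["nonlinear"] = _group_time_table(
            hemi, report, nl_cols,
            "LZC and ApEn, affected hemisphere (mean ± SD)")
    # NIHSS table
    cdf = cohort_frame(subjects)
    lines = ["### NIHSS scores (mean ± SD)", "",
             "| Group | NIHSS T0 | NIHSS T1 | ΔNIHSS |", "|---|---|---|---|"]
    for group in ("experimental", "control"):
        g = cdf[cdf["group"] == group]
        mark = ""
        if report is not None:
            try:
                q = report.lookup(f"within_{group}", "nihss").q_fdr
                mark = "**" if q is not None and q < 0.01 else (
                    "*" if q is not None and q < 0.05 else "")
            except KeyError:
                pass
        lines.append(
            f"| {group} | {g['nihss_t0'].mean():.1f} ± "
            f"{g['nihss_t0'].std(ddof=1):.1f} | {g['nihss_t1'].mean():.1f} ± "
            f"{g['nihss_t1'].std(ddof=1):.1f}{mark} | "
            f"{g['delta_nihss'].mean():.1f} ± "
            f"{g['delta_nihss'].std(ddof=1):.1f} |")
    lines += ["", "*q < 0.05, **q < 0.01 T1 vs T0 within group (paired t).",
              ""]
    tables["nihss"] = "\n".join(lines)
    return tables


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: RunConfig
    subjects: list[SubjectRecord]
    features: pd.DataFrame
    hemisphere: pd.DataFrame
    report: StatReport
    tables: dict[str, str]
    output_dir: Path


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str)
        .encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full chain and write the report bundle."""
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    if config.simulate is not None:
        spec = config.simulate
        if config.seed is not None:
            spec = dataclasses.replace(spec, seed=config.seed)
        log.info("stage simulate: n_per_group=%d seed=%s",
                 spec.n_per_group, spec.seed)
        cohort = synth_cohort(spec)
        recordings, subjects = cohort.recordings, cohort.subjects
    else:
        log.info("stage load: %s", config.input_dir)
        recordings, subjects = load_cohort_dir(config.input_dir)

    log.info("stage features: %d recordings (%s)", len(recordings),
             ",".join(config.features))
    t0 = time.time()
    features = compute_features(recordings, config.preprocess, config.welch,
                                config.lzc, config.apen, config.features)
    log.info("stage features done in %.1f s", time.time() - t0)

    try:
        hemi = hemisphere_features(features, subjects)
        report = analyze_cohort(hemi, subjects, pooled_t=config.pooled_t)
    except Exception as exc:
        raise PipelineError(f"stage 'stats' failed: {exc}") from exc
    tables = make_report_tables(hemi, subjects, report)

    # -- outputs -----------------------------------------------------------
    feat_cols = [c for c in FEATURE_CSV_COLUMNS if c in features.columns]
    features[feat_cols].to_csv(out / "features.csv", index=False)
    hemi.to_csv(out / "hemisphere.csv", index=False)
    report.frame().to_csv(out / "stats.csv", index=False)
    report.correlation_frame().to_csv(out / "correlations.csv", index=False)
    (out / "tables.md").write_text("\n".join(tables.values()))

    summary = {
        "n_subjects": len(subjects),
        "group_means": {},
        "correlations": {c.feature: {"r": c.r, "p": c.p, "n": c.n}
                         for c in report.correlations},
    }
    for (group, sess), sub in hemi.groupby(["group", "session"]):
        summary["group_means"][f"{group}_{sess}"] = {
            c: float(sub[c].mean()) for c in sub.columns
            if sub[c].dtype.kind == "f"}
    (out / "summary.json").write_text(json.dumps(summary, indent=1))

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": (config.seed if config.seed is not None
                 else (config.simulate.seed if config.simulate else None)),
        "runtime_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    log.info("run complete in %.1f s -> %s", time.time() - t_start, out)
    return PipelineResult(config, subjects, features, hemi, report, tables,
                          out)
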