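"""Orchestration of the full multi-dyad analysis.

:func:`run_pipeline` loads (or simulates) a cohort of dyads, builds the
composite arousal series, applies validity masks, removes the lag-1
autocorrelation for the event-locked arousal analyses, and runs the enabled
analyses — vocalisation clustering vs resampled controls, event-locked
arousal vs chance 0, vocalisation likelihood around arousal peaks, ROC/AUC
prediction, partner-arousal quartile splits, and moving-window arousal
stability/coupling — all with permutation-based temporal cluster
correction.  Outputs are delimited-text tables plus a machine-readable
summary; re-running with the same configuration and seed reproduces the
tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CAREGIVER,
    INFANT,
    ROLES,
    ArousalSeries,
    BinGrid,
    Dyad,
    EmptyDataError,
    InsufficientDataError,
    VocaldyadError,
    partner_of,
)
from .coupling import event_locked_stat, windowed_series
from .eventlock import (
    default_lags,
    detect_peaks,
    event_locked_arousal,
    likelihood_profile,
    partner_quartile_profiles,
)
from .events import filter_events, sample_controls_masked
from .io import read_arousal_table, read_event_table, write_dyads
from .preprocess import composite_arousal, remove_autocorrelation
from .stats import mw_hl, permutation_cluster, permutation_cluster_anova, roc_auc_arousal
from .synthetic import get_preset, simulate_cohort

logger = logging.getLogger("vocaldyad")

ALL_ANALYSES = ("clustering", "arousal", "peaks", "roc", "quartiles", "stability", "coupling")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialisable to/from YAML."""

    # inputs: either file paths or a synthetic preset
    arousal_path: str | None = None
    event_path: str | None = None
    preset: str | None = None
    n_dyads: int = 50
    # analysis grids
    bin_half_width_min: float = 21.0
    bin_width_min: float = 2.0
    max_lag_min: int = 20
    window: int = 10
    shift: int = 5
    min_valid: int = 5
    peak_pct: float = 10.0
    # resampling / inference
    n_control_reps: int = 1000
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    min_dyads: int = 8
    # toggles
    analyses: tuple[str, ...] = ALL_ANALYSES
    categories: tuple[str, ...] = ("all", "cry", "speech_like")
    outdir: str = "vocaldyad_out"

    def __post_init__(self) -> None:
        for name in ("n_dyads", "n_control_reps", "n_perm", "window", "shift",
                     "min_valid", "min_dyads"):
            if getattr(self, name) <= 0:
                raise VocaldyadError(f"{name} must be positive")
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise VocaldyadError(f"unknown analyses: {sorted(unknown)}")
        self.analyses = tuple(self.analyses)
        self.categories = tuple(self.categories)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def bin_grid(self) -> BinGrid:
        return BinGrid.default(self.bin_half_width_min, self.bin_width_min)

    def lags(self) -> np.ndarray:
        return default_lags(self.max_lag_min)


def _seed_for(master: int, *labels) -> np.random.SeedSequence:
    """Deterministic per-task seed derived from the master seed and labels."""
    digest = hashlib.blake2s("/".join(map(str, labels)).encode(), digest_size=4).digest()
    return np.random.SeedSequence([int(master), int.from_bytes(digest, "little")])


@dataclass
class PreparedDyad:
    """A dyad plus its AR(1)-residualised ("whitened") arousal series."""

    dyad: Dyad
    whitened: dict[str, ArousalSeries | None] = field(default_factory=dict)

    @property
    def dyad_id(self) -> str:
        return self.dyad.dyad_id


def prepare_dyads(dyads: list[Dyad]) -> list[PreparedDyad]:
    out = []
    for d in dyads:
        whit: dict[str, ArousalSeries | None] = {}
        for role in ROLES:
            try:
                whit[role] = remove_autocorrelation(d.arousal(role))
            except (InsufficientDataError, EmptyDataError, VocaldyadError) as exc:
                logger.warning("dyad %s %s: AR removal failed (%s)", d.dyad_id, role, exc)
                whit[role] = None
        out.append(PreparedDyad(dyad=d, whitened=whit))
    return out


def load_dyads(config: RunConfig) -> list[Dyad]:
    """Load dyads from files or simulate them from the configured preset."""
    if config.preset is not None:
        params = get_preset(config.preset)
        return simulate_cohort(params, config.n_dyads, seed=config.seed)
    if config.arousal_path is None or config.event_path is None:
        raise VocaldyadError("need either a preset or arousal_path + event_path")
    arousal = read_arousal_table(config.arousal_path)
    built: dict[tuple[str, str], ArousalSeries] = {}
    for key, obj in arousal.items():
        built[key] = obj if isinstance(obj, ArousalSeries) else composite_arousal(obj)
    grids = {did: s.grid for (did, _), s in built.items()}
    events = read_event_table(config.event_path, grids=grids)
    dyads = []
    for dyad_id in sorted({did for did, _ in built}):
        inf = built.get((dyad_id, INFANT))
        cg = built.get((dyad_id, CAREGIVER))
        ev = events.get(dyad_id)
        if inf is None or cg is None or ev is None:
            logger.warning("dyad %s: incomplete (missing role or events); skipped", dyad_id)
            continue
        dyads.append(Dyad(dyad_id=dyad_id, infant=inf, caregiver=cg, events=ev))
    return dyads


def _event_contrasts(categories):
    """(speaker, category) pairs; category splits apply to infant events."""
    for speaker in ROLES:
        cats = categories if speaker == INFANT else ("all",)
        for cat in cats:
            yield speaker, cat


def _control_mean_profile(profiles: list[np.ndarray]) -> np.ndarray:
    stacked = np.vstack(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stacked, axis=0)


def _cluster_rows(result, axis_labels, analysis, contrast, category, n) -> list[dict]:
    rows = []
    for i, c in enumerate(result.clusters):
        rows.append(
            {
                "analysis": analysis,
                "contrast": contrast,
                "category": category,
                "cluster": i,
                "start": axis_labels[c.start],
                "stop": axis_labels[c.stop - 1],
                "sign": c.sign,
                "mass": c.mass,
                "p": c.p,
                "n_participants": n,
            }
        )
    return rows


def _bin_frame(analysis, contrast, category, labels, real, control, cluster) -> list[dict]:
    """Tidy per-bin rows for one cohort comparison."""
    n_bins = real.shape[1]
    in_sig = np.zeros(n_bins, dtype=bool)
    for c in cluster.significant():
        in_sig[c.start : c.stop] = True
    rows = []
    for b in range(n_bins):
        r = real[:, b]
        c_ = control[:, b]
        ok = np.isfinite(r) & np.isfinite(c_)
        if ok.sum() >= 2:
            mw = mw_hl(r[ok], c_[ok])
            u, p, hl = mw.u, mw.p, mw.hl
        else:
            u = p = hl = np.nan
        rows.append(
            {
                "analysis": analysis,
                "contrast": contrast,
                "category": category,
                "bin": labels[b],
                "n_participants": int(ok.sum()),
                "real_mean": float(np.nanmean(r)) if np.isfinite(r).any() else np.nan,
                "control_mean": float(np.nanmean(c_)) if np.isfinite(c_).any() else np.nan,
                "u": u,
                "p": p,
                "hl": hl,
                "z": float(cluster.stat[b]) if np.isfinite(cluster.stat[b]) else np.nan,
                "significant_cluster": bool(in_sig[b]),
            }
        )
    return rows


def _collect_real_control(
    prepared,
    per_dyad,
    min_dyads: int,
) -> tuple[np.ndarray, np.ndarray, list[str]] | None:
    """Run ``per_dyad(PreparedDyad) -> (real, control) | None`` over a cohort."""
    reals, ctrls, ids = [], [], []
    for p in prepared:
        got = per_dyad(p)
        if got is None:
            continue
        real, ctrl = got
        reals.append(real)
        ctrls.append(ctrl)
        ids.append(p.dyad_id)
    if len(ids) < min_dyads:
        return None
    return np.vstack(reals), np.vstack(ctrls), ids


# ---------------------------------------------------------------------------
# Individual analyses
# ---------------------------------------------------------------------------

def analyze_clustering(prepared, config: RunConfig):
    """Vocalisation likelihood around vocalisations, real vs control."""
    bins = config.bin_grid()
    labels = bins.labels()
    bin_rows, cluster_rows = [], []
    for ref_s, cat in _event_contrasts(config.categories):
        for tgt_s in ROLES:
            def per_dyad(p, ref_s=ref_s, cat=cat, tgt_s=tgt_s):
                d = p.dyad
                ref = filter_events(d.events, ref_s, cat)
                if len(ref) == 0:
                    return None
                tgt = filter_events(d.events, tgt_s, "all")
                try:
                    controls = sample_controls_masked(
                        d.valid, d.events, ref, config.n_control_reps,
                        seed=_seed_for(config.seed, "clustering", ref_s, cat, tgt_s, p.dyad_id),
                    )
                except InsufficientDataError as exc:
                    logger.warning("dyad %s clustering %s/%s: %s", p.dyad_id, ref_s, cat, exc)
                    return None
                real = likelihood_profile(
                    ref, tgt, bins, d.valid, exclude_ref_epoch=(ref_s == tgt_s)
                ).likelihood
                ctrl = _control_mean_profile(
                    [likelihood_profile(c, tgt, bins, d.valid).likelihood for c in controls]
                )
                return real, ctrl

            got = _collect_real_control(prepared, per_dyad, max(config.min_dyads, 8))
            contrast = f"{ref_s}_voc->{tgt_s}_voc"
            if got is None:
                logger.warning("clustering %s (%s): too few participants; skipped", contrast, cat)
                continue
            real, ctrl, ids = got
            cluster = permutation_cluster(
                real, ctrl, config.n_perm, config.cluster_alpha,
                seed=_seed_for(config.seed, "clustering-perm", ref_s, cat, tgt_s),
            )
            bin_rows += _bin_frame("clustering", contrast, cat, labels, real, ctrl, cluster)
            cluster_rows += _cluster_rows(cluster, labels, "clustering", contrast, cat, len(ids))
    return pd.DataFrame(bin_rows), cluster_rows


def analyze_event_locked_arousal(prepared, config: RunConfig):
    """Mean (whitened) arousal around vocalisations, vs chance level 0."""
    lags = config.lags()
    labels = [str(l) for l in lags]
    bin_rows, cluster_rows = [], []
    for role in ROLES:
        for voc_s, cat in _event_contrasts(config.categories):
            def per_dyad(p, role=role, voc_s=voc_s, cat=cat):
                series = p.whitened[role]
                if series is None:
                    return None
                ev = filter_events(p.dyad.events, voc_s, cat)
                if len(ev) == 0:
                    return None
                traj = event_locked_arousal(series, ev, lags).mean
                return traj, np.zeros_like(traj)

            got = _collect_real_control(prepared, per_dyad, max(config.min_dyads, 8))
            contrast = f"{role}_arousal->{voc_s}_voc"
            if got is None:
                logger.warning("arousal %s (%s): too few participants; skipped", contrast, cat)
                continue
            real, zeros, ids = got
            zeros = np.where(np.isfinite(real), 0.0, np.nan)
            cluster = permutation_cluster(
                real, zeros, config.n_perm, config.cluster_alpha,
                seed=_seed_for(config.seed, "arousal-perm", role, voc_s, cat),
                mode="signflip",
            )
            bin_rows += _bin_frame("arousal", contrast, cat, labels, real, zeros, cluster)
            cluster_rows += _cluster_rows(cluster, labels, "arousal", contrast, cat, len(ids))
    return pd.DataFrame(bin_rows), cluster_rows


def analyze_peaks(prepared, config: RunConfig):
    """Vocalisation likelihood around arousal peaks, real vs control."""
    bins = config.bin_grid()
    labels = bins.labels()
    bin_rows, cluster_rows = [], []
    for role in ROLES:
        for voc_s, cat in _event_contrasts(config.categories):
            def per_dyad(p, role=role, voc_s=voc_s, cat=cat):
                d = p.dyad
                try:
                    peaks = detect_peaks(d.arousal(role), config.peak_pct)
                except (InsufficientDataError, VocaldyadError):
                    return None
                if len(peaks) == 0:
                    return None
                tgt = filter_events(d.events, voc_s, cat)
                try:
                    controls = sample_controls_masked(
                        d.valid, d.events, peaks, config.n_control_reps,
                        seed=_seed_for(config.seed, "peaks", role, voc_s, cat, p.dyad_id),
                    )
                except InsufficientDataError as exc:
                    logger.warning("dyad %s peaks: %s", p.dyad_id, exc)
                    return None
                real = likelihood_profile(peaks, tgt, bins, d.valid).likelihood
                ctrl = _control_mean_profile(
                    [likelihood_profile(c, tgt, bins, d.valid).likelihood for c in controls]
                )
                return real, ctrl

            got = _collect_real_control(prepared, per_dyad, max(config.min_dyads, 8))
            contrast = f"{role}_peak->{voc_s}_voc"
            if got is None:
                logger.warning("peaks %s (%s): too few participants; skipped", contrast, cat)
                continue
            real, ctrl, ids = got
            cluster = permutation_cluster(
                real, ctrl, config.n_perm, config.cluster_alpha,
                seed=_seed_for(config.seed, "peaks-perm", role, voc_s, cat),
            )
            bin_rows += _bin_frame("peaks", contrast, cat, labels, real, ctrl, cluster)
            cluster_rows += _cluster_rows(cluster, labels, "peaks", contrast, cat, len(ids))
    return pd.DataFrame(bin_rows), cluster_rows


def analyze_roc(prepared, config: RunConfig) -> pd.DataFrame:
    """Per-participant AUC of arousal predicting event presence, vs 0.5."""
    rows = []
    for role in ROLES:
        for voc_s, cat in _event_contrasts(config.categories):
            aucs = []
            for p in prepared:
                d = p.dyad
                ev = filter_events(d.events, voc_s, cat)
                try:
                    aucs.append(roc_auc_arousal(d.arousal(role), ev))
                except (InsufficientDataError, VocaldyadError):
                    continue
            if len(aucs) < 2:
                continue
            aucs = np.asarray(aucs)
            test = mw_hl(aucs, np.full(aucs.size, 0.5))
            rows.append(
                {
                    "analysis": "roc",
                    "contrast": f"{role}_arousal->{voc_s}_voc",
                    "category": cat,
                    "n_participants": aucs.size,
                    "mean_auc": float(aucs.mean()),
                    "se_auc": float(aucs.std(ddof=1) / np.sqrt(aucs.size)),
                    "p_vs_chance": test.p,
                }
            )
    return pd.DataFrame(rows)


def analyze_quartiles(prepared, config: RunConfig):
    """Partner arousal around events, split by vocaliser arousal quartile."""
    lags = config.lags()
    labels = [str(l) for l in lags]
    bin_rows, cluster_rows = [], []
    for voc_s in ROLES:
        partner = partner_of(voc_s)
        partner_list, events_list, own_list = [], [], []
        for p in prepared:
            partner_series = p.whitened[partner]
            own_series = p.whitened[voc_s]
            if partner_series is None or own_series is None:
                continue
            partner_list.append(partner_series)
            own_list.append(own_series)
            events_list.append(filter_events(p.dyad.events, voc_s, "all"))
        contrast = f"{partner}_arousal->{voc_s}_voc_by_{voc_s}_arousal"
        if len(partner_list) < max(config.min_dyads, 8):
            logger.warning("quartiles %s: too few participants; skipped", contrast)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            try:
                qp = partner_quartile_profiles(partner_list, events_list, own_list, lags)
            except InsufficientDataError as exc:
                logger.warning("quartiles %s: %s", contrast, exc)
                continue
        if qp.group_means.shape[0] < max(config.min_dyads, 8):
            logger.warning("quartiles %s: too few usable participants; skipped", contrast)
            continue
        cluster = permutation_cluster_anova(
            qp.group_means, config.n_perm, config.cluster_alpha,
            seed=_seed_for(config.seed, "quartiles-perm", voc_s),
        )
        in_sig = np.zeros(lags.size, dtype=bool)
        for c in cluster.significant():
            in_sig[c.start : c.stop] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gmeans = np.nanmean(qp.group_means, axis=0)  # (4, L)
        for b in range(lags.size):
            row = {
                "analysis": "quartiles",
                "contrast": contrast,
                "category": "all",
                "bin": labels[b],
                "n_participants": qp.group_means.shape[0],
                "f": float(qp.f[b]) if np.isfinite(qp.f[b]) else np.nan,
                "p": float(qp.p[b]) if np.isfinite(qp.p[b]) else np.nan,
                "significant_cluster": bool(in_sig[b]),
            }
            for g in range(4):
                row[f"q{g + 1}_mean"] = float(gmeans[g, b]) if np.isfinite(gmeans[g, b]) else np.nan
            bin_rows.append(row)
        cluster_rows += _cluster_rows(
            cluster, labels, "quartiles", contrast, "all", qp.group_means.shape[0]
        )
    return pd.DataFrame(bin_rows), cluster_rows


def analyze_windowed(prepared, config: RunConfig, kind: str):
    """Event-locked moving-window stability or coupling, real vs control."""
    lags = config.lags()
    labels = [str(l) for l in lags]
    bin_rows, cluster_rows = [], []
    roles = ROLES if kind == "stability" else (None,)
    for role in roles:
        for voc_s, cat in _event_contrasts(config.categories):
            def per_dyad(p, role=role, voc_s=voc_s, cat=cat):
                d = p.dyad
                ev = filter_events(d.events, voc_s, cat)
                if len(ev) == 0:
                    return None
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    ws = windowed_series(
                        d, kind, role, config.window, config.shift, config.min_valid
                    )
                if len(ws) == 0 or not np.isfinite(ws.values).any():
                    return None
                real = event_locked_stat(ws, ev, lags).mean
                try:
                    controls = sample_controls_masked(
                        d.valid, d.events, ev, config.n_control_reps,
                        seed=_seed_for(config.seed, kind, role, voc_s, cat, p.dyad_id),
                    )
                except InsufficientDataError as exc:
                    logger.warning("dyad %s %s: %s", p.dyad_id, kind, exc)
                    return None
                ctrl = _control_mean_profile(
                    [event_locked_stat(ws, c, lags).mean for c in controls]
                )
                return real, ctrl

            got = _collect_real_control(prepared, per_dyad, max(config.min_dyads, 8))
            prefix = f"{role}_" if role else "dyad_"
            contrast = f"{prefix}{kind}->{voc_s}_voc"
            if got is None:
                logger.warning("%s %s (%s): too few participants; skipped", kind, contrast, cat)
                continue
            real, ctrl, ids = got
            cluster = permutation_cluster(
                real, ctrl, config.n_perm, config.cluster_alpha,
                seed=_seed_for(config.seed, f"{kind}-perm", role, voc_s, cat),
            )
            bin_rows += _bin_frame(kind, contrast, cat, labels, real, ctrl, cluster)
            cluster_rows += _cluster_rows(cluster, labels, kind, contrast, cat, len(ids))
    return pd.DataFrame(bin_rows), cluster_rows


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "clustering": "likelihood_clustering.tsv",
    "arousal": "arousal_trajectories.tsv",
    "peaks": "peak_likelihood.tsv",
    "roc": "roc_auc.tsv",
    "quartiles": "quartile_anova.tsv",
    "stability": "stability.tsv",
    "coupling": "coupling.tsv",
}


def run_pipeline(config: RunConfig, dyads: list[Dyad] | None = None) -> dict:
    """Run the enabled analyses over a cohort and write the report bundle.

    Returns a dict with the per-analysis DataFrames, the cluster table and
    the summary.  ``dyads`` may be supplied directly (e.g. pre-simulated);
    otherwise they come from the configured files or preset.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if dyads is None:
            dyads = load_dyads(config)
        if len(dyads) < config.min_dyads:
            raise InsufficientDataError(
                f"{len(dyads)} usable dyads; >= {config.min_dyads} required"
            )
        logger.info("cohort: %d dyads, seed=%d", len(dyads), config.seed)
        prepared = prepare_dyads(dyads)

        tables: dict[str, pd.DataFrame] = {}
        cluster_rows: list[dict] = []
        if "clustering" in config.analyses:
            tables["clustering"], cr = analyze_clustering(prepared, config)
            cluster_rows += cr
        if "arousal" in config.analyses:
            tables["arousal"], cr = analyze_event_locked_arousal(prepared, config)
            cluster_rows += cr
        if "peaks" in config.analyses:
            tables["peaks"], cr = analyze_peaks(prepared, config)
            cluster_rows += cr
        if "roc" in config.analyses:
            tables["roc"] = analyze_roc(prepared, config)
        if "quartiles" in config.analyses:
            tables["quartiles"], cr = analyze_quartiles(prepared, config)
            cluster_rows += cr
        if "stability" in config.analyses:
            tables["stability"], cr = analyze_windowed(prepared, config, "stability")
            cluster_rows += cr
        if "coupling" in config.analyses:
            tables["coupling"], cr = analyze_windowed(prepared, config, "coupling")
            cluster_rows += cr

        clusters = pd.DataFrame(
            cluster_rows,
            columns=["analysis", "contrast", "category", "cluster", "start", "stop",
                     "sign", "mass", "p", "n_participants"],
        )
        for name, df in tables.items():
            df.to_csv(outdir / _TABLE_FILES[name], sep="\t", index=False, float_format="%.6g")
        clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False, float_format="%.6g")
        config.to_yaml(outdir / "config_used.yaml")

        summary = {
            "n_dyads": len(dyads),
            "seed": config.seed,
            "analyses": sorted(tables),
            "n_significant_clusters": {
                a: int(((clusters["analysis"] == a) & (clusters["p"] <= config.alpha)).sum())
                for a in sorted(set(clusters["analysis"])) if len(clusters)
            },
            "significant_clusters": [
                {k: (round(v, 6) if isinstance(v, float) else v) for k, v in row.items()}
                for row in cluster_rows
                if row["p"] <= config.alpha
            ],
        }
        if "roc" in tables and len(tables["roc"]):
            summary["mean_auc"] = {
                f"{r.contrast}|{r.category}": round(float(r.mean_auc), 6)
                for r in tables["roc"].itertuples()
            }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {"tables": tables, "clusters": clusters, "summary": summary}
    finally:
        logger.removeHandler(handler)
        handler.close()


def simulate_to_dir(preset: str, n_dyads: int, seed: int, outdir) -> tuple[Path, Path]:
    """CLI helper: simulate a cohort and write arousal + event tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dyads = simulate_cohort(get_preset(preset), n_dyads, seed=seed)
    arousal_path = outdir / "arousal.tsv"
    event_path = outdir / "events.tsv"
    write_dyads(dyads, arousal_path, event_path)
    return arousal_path, event_path
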