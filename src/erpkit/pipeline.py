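"""End-to-end orchestration: simulate -> preprocess -> features -> DTW ->
reliability -> report.

A run is fully determined by one YAML config and a master seed. Every
randomized step (trial subsampling, split-half draws) uses a sub-seed
derived from the master seed and the (subject, session, condition_set,
n_trials, stage) tuple through ``numpy.random.SeedSequence``, and every
derived sub-seed is logged, so any table can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import erp_features as ef
from . import gaze_validity as gv
from . import reliability_stats as rs
from .dtw_latency import dtw_direction_feature
from .preprocess import PreprocConfig, preprocess_session
from .synthetic_data import CohortSpec, DEFAULT_COMPONENTS, simulate_cohort

#: feature columns per condition set (DTW added separately)
FEATURES_BY_SET = {
    "checkerboard": ("P1_latency", "P1_amp", "dtw_direction"),
    "faces_all": (
        "N290_latency",
        "N290_peak_amp",
        "N290_mean_amp",
        "P400_mean_amp",
        "dtw_direction",
    ),
    "faces_upright": (
        "N290_latency",
        "N290_peak_amp",
        "N290_mean_amp",
        "P400_mean_amp",
        "dtw_direction",
    ),
    "faces_inverted": (
        "N290_latency",
        "N290_peak_amp",
        "N290_mean_amp",
        "P400_mean_amp",
        "dtw_direction",
    ),
}

#: DTW analysis window per condition set (P1 window for checkerboards,
#: N290 window for all face sets)
DTW_WINDOWS = {
    "checkerboard": (50.0, 200.0),
    "faces_all": (190.0, 350.0),
    "faces_upright": (190.0, 350.0),
    "faces_inverted": (190.0, 350.0),
}

_SET_CODE = {"checkerboard": 1, "faces_all": 2, "faces_upright": 3, "faces_inverted": 4}
_STAGE_CODE = {"subsample": 1, "split": 2}
_FAMILY_OF_SET = {
    "checkerboard": "checkerboard",
    "faces_all": "faces",
    "faces_upright": "faces",
    "faces_inverted": "faces",
}


def derive_seed(master: int, subject: int, session: int, condition_set: str, n, stage: str) -> int:
    """Deterministic sub-seed for one randomized step (< 2**31)."""
    n_code = -1 if n is None else int(n)
    entropy = (
        int(master),
        int(subject),
        int(session),
        _SET_CODE[condition_set],
        n_code + 2,
        _STAGE_CODE[stage],
    )
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable; unknown keys rejected)."""

    out_dir: str = "erpkit_run"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    dtw_metric: str = "abs"
    min_trials_paired_t: int = 20
    attentive_threshold: float = 60.0
    inclusion_cutoffs: tuple = (1, 10, 20, 30, 40, 50)
    grand_average_min_trials: int = 10
    grand_average_min_abs_amp: float = 1.0
    split_half: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        for key, sub_cls in (("cohort", CohortSpec), ("preproc", PreprocConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(kwargs[key]) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown {key} key(s): {sorted(sub_unknown)}")
                kwargs[key] = sub_cls(**kwargs[key])
        cfg = cls(**kwargs)
        if cfg.dtw_metric not in ("abs", "sq"):
            raise ValueError(f"dtw_metric must be 'abs' or 'sq', got {cfg.dtw_metric!r}")
        # fail on impossible filter settings before any computation
        cfg.preproc.validate_for_fs(500.0)
        return cfg


# ---------------------------------------------------------------------------
# per-session analysis


def _session_waveforms(trialsets, subject, session, master_seed, seed_log):
    """Averaged waveforms per (condition_set, n_trials) for one session."""
    waves = {}
    for cset, grid in ef.TRIAL_GRIDS.items():
        ts = trialsets[_FAMILY_OF_SET[cset]]
        for n in grid:
            sub_seed = derive_seed(master_seed, subject, session, cset, n, "subsample")
            seed_log.append(
                {
                    "subject": subject,
                    "session": session,
                    "condition_set": cset,
                    "n_trials": -1 if n is None else n,
                    "stage": "subsample",
                    "seed": sub_seed,
                }
            )
            idx = _subsample_for_set(ts, cset, n, sub_seed)
            if idx is None or len(idx) == 0:
                continue
            waves[(cset, n)] = ef.average_trials(
                ts,
                idx,
                ef.CONDITION_SET_CHANNELS[cset],
                subject=subject,
                session=session,
                condition_set=cset,
                seed=sub_seed,
            )
    return waves


def _subsample_for_set(ts, cset, n, seed):
    conds = np.asarray(ts.conditions)
    if cset == "faces_all":
        return ef.subsample_trials(ts, n, balance=n is not None, seed=seed)
    if cset in ("faces_upright", "faces_inverted"):
        label = "face_upright" if cset == "faces_upright" else "face_inverted"
        clean = ts.clean_indices()
        pool = clean[conds[clean] == label]
        if n is None:
            return pool
        if len(pool) < n:
            return None
        rng = np.random.default_rng(seed)
        return np.sort(rng.choice(pool, n, replace=False))
    return ef.subsample_trials(ts, n, balance=False, seed=seed)


def run_study(config: RunConfig) -> Path:
    """Simulate a paired-session cohort and run the full analysis.

    Writes features, reliability, internal-consistency, inversion-effect,
    gaze and inclusion tables plus a plain-text report into
    ``config.out_dir`` and returns that path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_data = simulate_cohort(config.cohort, DEFAULT_COMPONENTS, config.seed)
    spec = config.cohort

    seed_log: list = []
    exclusion_log: list = []
    feature_rows: list = []
    gaze_rows: list = []
    clean_counts: dict = {}
    all_waves: dict = {}  # (subject, session) -> {(cset, n): wave}
    half_waves: dict = {}  # (subject, session, half) -> {(cset, n): wave}

    for subject in range(spec.n_subjects):
        for session in range(spec.n_sessions):
            rec, events, gaze, truth = cohort_data.session(subject, session)

            scores = gv.score_trials(
                gaze, events.onsets / rec.fs, events.trial_ids
            )
            att = gv.session_attentiveness(scores, len(events))
            gaze_rows.append(
                {"subject": subject, "session": session, "attentiveness_pct": att}
            )

            trialsets = {
                fam: preprocess_session(rec, events, fam, config.preproc)
                for fam in ("checkerboard", "faces")
            }
            for fam, ts in trialsets.items():
                for row in ts.exclusion_log():
                    exclusion_log.append(
                        {"subject": subject, "session": session, "family": fam, **row}
                    )
                clean_counts[(subject, session, fam)] = ts.n_clean
            conds = np.asarray(trialsets["faces"].conditions)
            clean_f = trialsets["faces"].clean_indices()
            clean_counts[(subject, session, "faces_upright")] = int(
                (conds[clean_f] == "face_upright").sum()
            )
            clean_counts[(subject, session, "faces_inverted")] = int(
                (conds[clean_f] == "face_inverted").sum()
            )

            all_waves[(subject, session)] = _session_waveforms(
                trialsets, subject, session, config.seed, seed_log
            )

            if config.split_half:
                half_waves.update(
                    _split_half_waveforms(
                        trialsets, subject, session, config.seed, seed_log
                    )
                )

    # grand averages per condition set from the all-available-trial averages
    grand = {}
    for cset in ef.TRIAL_GRIDS:
        candidates = [
            w[(cset, None)] for w in all_waves.values() if (cset, None) in w
        ]
        if candidates:
            try:
                grand[cset] = ef.grand_average(
                    candidates,
                    config.grand_average_min_trials,
                    config.grand_average_min_abs_amp,
                )
            except ValueError:
                pass

    # features (+ DTW vs the same-set grand average)
    def _rows_from(waves_by_key, extra_key=None):
        rows = []
        for key, waves in waves_by_key.items():
            for (cset, n), wave in waves.items():
                row = {
                    "subject": wave.subject,
                    "session": wave.session,
                    "condition_set": cset,
                    "n_trials": -1 if n is None else n,
                    "n_trials_used": wave.n_trials,
                    "seed": wave.seed,
                }
                if extra_key:
                    row[extra_key] = key[2]
                row.update(ef.extract_features(wave, condition_set=cset))
                if cset in grand:
                    row["dtw_direction"] = dtw_direction_feature(
                        wave, grand[cset], DTW_WINDOWS[cset], config.dtw_metric
                    )
                rows.append(row)
        return rows

    feature_rows = _rows_from(all_waves)
    features = pd.DataFrame(feature_rows)
    features.to_csv(out / "features.csv", index=False)

    gaze_df = pd.DataFrame(gaze_rows)
    piv = gaze_df.pivot_table(index="subject", columns="session", values="attentiveness_pct")
    gaze_df["highly_attentive"] = gaze_df["subject"].map(
        lambda s: gv.highly_attentive(
            piv.loc[s].get(0, np.nan), piv.loc[s].get(1, np.nan), config.attentive_threshold
        )
    )
    gaze_df.to_csv(out / "gaze_summary.csv", index=False)

    # reliability tables
    rel_tables = []
    for cset, grid in ef.TRIAL_GRIDS.items():
        sub = features[features["condition_set"] == cset]
        if sub.empty:
            continue
        tab = rs.test_retest_table(sub, FEATURES_BY_SET[cset], grid)
        tab.insert(0, "condition_set", cset)
        rel_tables.append(tab)
    reliability = (
        pd.concat(rel_tables, ignore_index=True) if rel_tables else pd.DataFrame()
    )
    reliability.to_csv(out / "test_retest_icc.csv", index=False)

    # inversion effects and their reliability
    up = features[features["condition_set"] == "faces_upright"]
    inv = features[features["condition_set"] == "faces_inverted"]
    inv_feats = [f for f in FEATURES_BY_SET["faces_upright"]]
    inversion = rs.inversion_effect(up, inv, inv_feats)
    inversion.to_csv(out / "inversion_effects.csv", index=False)
    inv_icc = rs.test_retest_table(
        inversion, inv_feats, ef.TRIAL_GRIDS["faces_upright"]
    )
    inv_icc.insert(0, "condition_set", "inversion_effect")
    inv_icc.to_csv(out / "inversion_icc.csv", index=False)

    # paired t-test upright vs inverted (session 0, all trials, >=20 clean each)
    paired = _paired_tests(features, clean_counts, config.min_trials_paired_t, inv_feats)
    with open(out / "paired_t.json", "w") as fh:
        json.dump(paired, fh, indent=2)

    # split-half internal consistency
    if config.split_half and half_waves:
        ic_tables = []
        for session in range(spec.n_sessions):
            wa = {
                k: v for k, v in half_waves.items() if k[1] == session and k[2] == "A"
            }
            wb = {
                k: v for k, v in half_waves.items() if k[1] == session and k[2] == "B"
            }
            fa = pd.DataFrame(_rows_from(wa))
            fb = pd.DataFrame(_rows_from(wb))
            for cset, grid in ef.TRIAL_GRIDS.items():
                sa = fa[fa["condition_set"] == cset] if not fa.empty else fa
                sb = fb[fb["condition_set"] == cset] if not fb.empty else fb
                if sa.empty or sb.empty:
                    continue
                tab = rs.internal_consistency(sa, sb, FEATURES_BY_SET[cset], grid)
                if tab.empty:
                    continue
                tab.insert(0, "session", session)
                tab.insert(0, "condition_set", cset)
                ic_tables.append(tab)
        internal = (
            pd.concat(ic_tables, ignore_index=True) if ic_tables else pd.DataFrame()
        )
        internal.to_csv(out / "internal_consistency_icc.csv", index=False)

    # inclusion rates per family (session 0 counts, like a first-visit tally)
    counts0 = {
        fam: np.array(
            [clean_counts[(s, 0, fam)] for s in range(spec.n_subjects)]
        )
        for fam in ("checkerboard", "faces")
    }
    incl_tables = []
    for fam, counts in counts0.items():
        n_with_data = int((counts > 0).sum())
        tab = inclusion_rates(
            counts,
            config.inclusion_cutoffs,
            {"roster": spec.n_subjects, "with_data": max(n_with_data, 1)},
        )
        tab.insert(0, "family", fam)
        incl_tables.append(tab)
    inclusion = pd.concat(incl_tables, ignore_index=True)
    inclusion.to_csv(out / "inclusion_rates.csv", index=False)

    pd.DataFrame(seed_log).to_csv(out / "seed_log.tsv", sep="\t", index=False)
    pd.DataFrame(
        exclusion_log, columns=["subject", "session", "family", "trial_id", "reason"]
    ).to_csv(out / "excluded_trials.tsv", sep="\t", index=False)

    _write_report(out, config, features, reliability, inclusion, gaze_df, paired)
    return out


def _split_half_waveforms(trialsets, subject, session, master_seed, seed_log):
    """Half-A/half-B averaged waveforms per condition set and trial count."""
    out = {}
    for cset, grid in ef.TRIAL_GRIDS.items():
        ts = trialsets[_FAMILY_OF_SET[cset]]
        for n in grid:
            if n is not None and n % 2:
                continue
            sub_seed = derive_seed(master_seed, subject, session, cset, n, "split")
            seed_log.append(
                {
                    "subject": subject,
                    "session": session,
                    "condition_set": cset,
                    "n_trials": -1 if n is None else n,
                    "stage": "split",
                    "seed": sub_seed,
                }
            )
            idx = _subsample_for_set(ts, cset, n, sub_seed)
            if idx is None or len(idx) < 2:
                continue
            rng = np.random.default_rng(sub_seed + 1)
            drawn = rng.permutation(idx)
            halves = {"A": drawn[0::2], "B": drawn[1::2]}
            for half, h_idx in halves.items():
                if len(h_idx) == 0:
                    continue
                out.setdefault((subject, session, half), {})[(cset, n)] = ef.average_trials(
                    ts,
                    np.sort(h_idx),
                    ef.CONDITION_SET_CHANNELS[cset],
                    subject=subject,
                    session=session,
                    condition_set=cset,
                    seed=sub_seed,
                )
    return out


def _paired_tests(features, clean_counts, min_trials, feature_names):
    """Upright-vs-inverted paired t-tests on session-0 all-trial features."""
    sub = features[(features["session"] == 0) & (features["n_trials"] == -1)]
    up = sub[sub["condition_set"] == "faces_upright"].set_index("subject")
    inv = sub[sub["condition_set"] == "faces_inverted"].set_index("subject")
    eligible = [
        s
        for s in up.index.intersection(inv.index)
        if clean_counts.get((s, 0, "faces_upright"), 0) >= min_trials
        and clean_counts.get((s, 0, "faces_inverted"), 0) >= min_trials
    ]
    out = {}
    for f in feature_names:
        if f not in up.columns or len(eligible) < 2:
            continue
        try:
            out[f] = rs.paired_t(up.loc[eligible, f], inv.loc[eligible, f])
        except ValueError:
            continue
    return out


def inclusion_rates(counts, cutoffs, denominators: dict) -> pd.DataFrame:
    """Percentage of subjects with at least ``cutoff`` clean trials.

    One row per cutoff; one percentage column per denominator (e.g. the
    full simulated roster and the subjects with any usable data).
    Percentages are non-increasing in the cutoff.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty roster")
    if np.any(counts < 0):
        raise ValueError("clean-trial counts must be non-negative")
    rows = []
    for c in cutoffs:
        row = {"cutoff": c}
        n_incl = int((counts >= c).sum())
        for name, denom in denominators.items():
            row[f"pct_{name}"] = 100.0 * n_incl / denom
        rows.append(row)
    return pd.DataFrame(rows)


def _write_report(out, config, features, reliability, inclusion, gaze_df, paired):
    lines = [
        "erpkit run report",
        "=================",
        f"seed: {config.seed}",
        f"subjects: {config.cohort.n_subjects}, sessions: {config.cohort.n_sessions}",
        f"noise_sd: {config.cohort.noise_sd} uV, "
        f"artifact rates: amp={config.cohort.artifact_rate_amp}, "
        f"flat={config.cohort.artifact_rate_flat}",
        "",
        f"feature rows: {len(features)}",
        f"highly attentive subjects: {int(gaze_df['highly_attentive'].sum() // max(config.cohort.n_sessions, 1))}"
        f" of {config.cohort.n_subjects}",
        "",
        "inclusion rates (session 0):",
        inclusion.to_string(index=False),
        "",
    ]
    if not reliability.empty:
        lines += ["test-retest ICC (head):", reliability.head(20).to_string(index=False), ""]
    if paired:
        lines.append("paired upright-vs-inverted t-tests (all trials, session 0):")
        for f, res in paired.items():
            if res.get("defined"):
                lines.append(
                    f"  {f}: t({res['df']}) = {res['t']:.2f}, p = {res['p']:.3f}"
                )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
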