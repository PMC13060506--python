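"""End-to-end trial pipeline: simulate or load inputs, run every analysis
stage, and write the interface files plus a single JSON report.

Stages run in order: synthetic cohort (optional) -> discounting -> demand ->
consumption -> concordance -> adherence selection.  All tabular interfaces
are headered UTF-8 CSV with empty fields for missing values; every exclusion
(nonsystematic screens, nonconverged demand fits, missing days) is counted in
the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adherence import DRINK_COUNT_SPACE, enumerate_models, select_by_bic
from .concordance import (BRAC_POSITIVE_THRESHOLD, build_concordance_matrix,
                          classify_day, fisher_exact_or, nonmissing_2x2,
                          roc_auc)
from .consumption import long_format_export, summarize_all_phases
from .demand import (DemandObservationSet, fit_exponentiated, fitted_pmax,
                     shared_k_span)
from .discounting import (IndifferenceCurve, TitrationSchedule, fit_hyperbolic,
                          johnson_bickel_screen)
from .synthetic import SESSIONS, CohortConfig, CohortData, simulate_cohort

log = logging.getLogger("eftrial")

__all__ = [
    "curves_from_choices",
    "analyze_discounting",
    "analyze_demand",
    "analyze_consumption",
    "analyze_concordance",
    "analyze_adherence",
    "complete_case_filter",
    "run_pipeline",
    "load_cohort",
    "config_hash",
]


def config_hash(config: CohortConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_cohort(in_dir) -> CohortData:
    """Read the four long-format input files written by the generator."""
    d = Path(in_dir)
    return CohortData(
        profiles=pd.read_csv(d / "profiles.csv"),
        choices=pd.read_csv(d / "choices.csv"),
        purchases=pd.read_csv(d / "purchase.csv"),
        daily=pd.read_csv(d / "daily.csv"),
        config=CohortConfig(),
    )


# ---------------------------------------------------------------- discounting

def curves_from_choices(choices: pd.DataFrame,
                        schedule: TitrationSchedule) -> list[IndifferenceCurve]:
    """Replay recorded titration choices into indifference curves.

    The recorded ss_amount of each trial is checked against the replayed
    value, guarding against corrupted or reordered choice files.
    """
    curves = []
    A = schedule.ll_amount
    for (pid, session), g in choices.groupby(["participant", "session"],
                                             sort=True):
        points = []
        for delay in schedule.delays_days:
            trials = g[g.delay_days == delay].sort_values("trial_index")
            if len(trials) != schedule.trials_per_delay:
                raise ValueError(
                    f"{pid}/{session}: {len(trials)} trials at delay {delay}, "
                    f"expected {schedule.trials_per_delay}")
            ss = A / 2.0
            for t, row in enumerate(trials.itertuples(), start=1):
                if abs(row.ss_amount - ss) > 1e-6:
                    raise ValueError(
                        f"{pid}/{session}: ss_amount mismatch at delay {delay} "
                        f"trial {t}")
                ss += (A / 2 ** (t + 1)) * (1 if row.choice == "LL" else -1)
            points.append(ss)
        curves.append(IndifferenceCurve(session=f"{pid}|{session}",
                                        delays_days=schedule.delays_days,
                                        values=tuple(points)))
    return curves


def analyze_discounting(choices: pd.DataFrame,
                        schedule: TitrationSchedule | None = None) -> pd.DataFrame:
    """Per participant-session discounting fits with systematicity flags."""
    schedule = schedule or TitrationSchedule()
    rows = []
    for curve in curves_from_choices(choices, schedule):
        pid, session = curve.session.split("|")
        c1, c2 = johnson_bickel_screen(curve, schedule.ll_amount)
        fit = fit_hyperbolic(curve, schedule=schedule)
        rows.append({"participant": pid, "session": session, "k": fit.k,
                     "ln_k": fit.ln_k, "sse": fit.sse, "criterion1_ok": c1,
                     "criterion2_ok": c2, "boundary_flag": fit.boundary_flag})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- demand

def analyze_demand(purchases: pd.DataFrame) -> pd.DataFrame:
    """Per participant-session demand metrics under a shared k span."""
    grouped = list(purchases.groupby(["participant", "session"], sort=True))
    capped_sets = {}
    for key, g in grouped:
        g = g.sort_values("price")
        obs = DemandObservationSet(tuple(g.price), tuple(g.quantity.astype(int)))
        capped_sets[key] = obs.capped()
    k_span = shared_k_span([s.quantities for s in capped_sets.values()])
    rows = []
    for (pid, session), obs in capped_sets.items():
        fit = fit_exponentiated(obs, k_span)
        rows.append({
            "participant": pid, "session": session,
            "intensity_obs": fit.intensity_obs, "omax_obs": fit.omax_obs,
            "pmax_obs": fit.pmax_obs, "Q0": fit.Q0, "alpha": fit.alpha,
            "ln_alpha": fit.ln_alpha, "k_span": fit.k_span,
            "converged": fit.converged,
            "fitted_pmax": fitted_pmax(fit) if fit.converged else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- consumption

def analyze_consumption(daily: pd.DataFrame,
                        profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phase summaries (calendar-day denominators) and the model frame."""
    summaries = summarize_all_phases(daily)
    summaries = summaries.merge(profiles[["participant", "group"]],
                                on="participant", how="left")
    frame = long_format_export(daily, profiles)
    return summaries, frame


# ---------------------------------------------------------------- concordance

def analyze_concordance(daily: pd.DataFrame,
                        threshold: float = BRAC_POSITIVE_THRESHOLD):
    """3x3 matrix, Fisher exact OR/p on the non-missing 2x2, and ROC AUC."""
    brac_cols = [c for c in daily.columns if c.startswith("brac_")]
    classifications = []
    for row in daily.itertuples():
        samples = [getattr(row, c) for c in brac_cols]
        samples = [s for s in samples if pd.notna(s)]
        reported = None if pd.isna(row.reported_drinks) else int(row.reported_drinks)
        classifications.append(classify_day(samples, reported,
                                            participant=row.participant,
                                            day_index=row.day_index,
                                            threshold=threshold))
    matrix = build_concordance_matrix(classifications)
    or_, p = fisher_exact_or(nonmissing_2x2(matrix))
    pairs = [(c.peak_brac, 0 if c.report_status == "None" else 1)
             for c in classifications
             if c.peak_brac is not None and c.report_status != "Missing"]
    auc = roc_auc([p_ for p_, _ in pairs], [l for _, l in pairs])
    stats = {"odds_ratio": or_, "p_value": p, "auc": auc,
             "threshold": threshold, "n_days_2x2": int(nonmissing_2x2(matrix).sum())}
    return matrix, stats


# ------------------------------------------------------------------ adherence

def missingness_frame(daily: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-day frame with the missing-drink-count indicator and covariates."""
    frame = long_format_export(daily, profiles)
    frame["missing_drink_count"] = frame.reported_drinks.isna().astype(int)
    return frame


def analyze_adherence(daily: pd.DataFrame, profiles: pd.DataFrame):
    frame = missingness_frame(daily, profiles)
    models = enumerate_models(DRINK_COUNT_SPACE)
    return select_by_bic(models, frame, DRINK_COUNT_SPACE.outcome)


# ------------------------------------------------------------------ filtering

def sessions_completed(choices: pd.DataFrame) -> pd.DataFrame:
    """participant x session completion flags derived from the choice records."""
    present = choices.groupby(["participant", "session"]).size().reset_index()
    flags = present.pivot(index="participant", columns="session",
                          values=0).notna()
    for s in SESSIONS:
        if s not in flags.columns:
            flags[s] = False
    return flags[list(SESSIONS)]


def complete_case_filter(cohort: CohortData, mode: str) -> CohortData:
    """Complete-case or intention-to-treat view of a trial dataset.

    complete_case keeps participants with all five sessions.
    intention_to_treat keeps everyone who started the intervention (S2
    completed), masks sessions after their last completed one, and truncates
    daily data at the last day with any submission.
    """
    if mode not in ("complete_case", "intention_to_treat"):
        raise ValueError(f"unknown mode {mode!r}")
    flags = sessions_completed(cohort.choices)

    if mode == "complete_case":
        keep = flags.index[flags.all(axis=1)]
        dropped = len(flags) - len(keep)
        if dropped:
            log.info("complete_case: excluded %d participants without all "
                     "5 sessions", dropped)
        sel_choices = cohort.choices[cohort.choices.participant.isin(keep)]
        sel_daily = cohort.daily[cohort.daily.participant.isin(keep)]
        sel_purch = cohort.purchases[cohort.purchases.participant.isin(keep)]
    else:
        keep = flags.index[flags["S2"]]
        completed = {
            (pid, s)
            for pid in keep
            for s in SESSIONS
            if flags.loc[pid, s]
        }
        key = list(zip(cohort.choices.participant, cohort.choices.session))
        sel_choices = cohort.choices[[k in completed for k in key]]
        key = list(zip(cohort.purchases.participant, cohort.purchases.session))
        sel_purch = cohort.purchases[[k in completed for k in key]]
        daily = cohort.daily[cohort.daily.participant.isin(keep)]
        brac_cols = [c for c in daily.columns if c.startswith("brac_")]
        submitted = daily.reported_drinks.notna()
        for c in brac_cols:
            submitted |= daily[c].notna()
        last = daily.loc[submitted].groupby("participant").day_index.max()
        sel_daily = daily[daily.day_index <= daily.participant.map(last)]

    return CohortData(
        profiles=cohort.profiles[cohort.profiles.participant.isin(keep)].copy(),
        choices=sel_choices.reset_index(drop=True).copy(),
        purchases=sel_purch.reset_index(drop=True).copy(),
        daily=sel_daily.reset_index(drop=True).copy(),
        config=cohort.config,
    )


# -------------------------------------------------------------- orchestration

def _group_session_means(df: pd.DataFrame, profiles: pd.DataFrame,
                         cols: list[str]) -> dict:
    merged = df.merge(profiles[["participant", "group"]], on="participant")
    out: dict = {}
    for (group, session), g in merged.groupby(["group", "session"], sort=True):
        out[f"{group}|{session}"] = {c: float(g[c].mean()) for c in cols}
        out[f"{group}|{session}"]["n"] = int(len(g))
    return out


def run_pipeline(config: CohortConfig | None = None, out_dir=None,
                 in_dir=None, mode: str = "complete_case") -> dict:
    """Run simulate -> analyze -> report end to end.

    Either a CohortConfig (simulation) or an input directory with the four
    CSV files must be given.  Returns the report dict; when ``out_dir`` is
    set, writes every interface file plus report.json.
    """
    if (config is None) == (in_dir is None):
        raise ValueError("provide exactly one of config (simulate) or in_dir")
    if config is not None:
        config.validate()
        cohort = simulate_cohort(config)
    else:
        cohort = load_cohort(in_dir)

    cohort = complete_case_filter(cohort, mode)

    discounting = analyze_discounting(cohort.choices)
    demand = analyze_demand(cohort.purchases)
    summaries, model_frame = analyze_consumption(cohort.daily, cohort.profiles)
    matrix, conc_stats = analyze_concordance(cohort.daily)
    selection = analyze_adherence(cohort.daily, cohort.profiles)

    n_nonsystematic = int((~discounting.criterion1_ok
                           | ~discounting.criterion2_ok).sum())
    n_nonconverged = int((~demand.converged).sum())
    n_missing_days = int(cohort.daily.reported_drinks.isna().sum())
    log.info("exclusion counts: %d nonsystematic curves flagged (kept), "
             "%d nonconverged demand fits, %d missing daily reports",
             n_nonsystematic, n_nonconverged, n_missing_days)

    phase_means: dict = {}
    merged = summaries
    for (group, phase), g in merged.groupby(["group", "phase"], sort=True):
        phase_means[f"{group}|{phase}"] = {
            "drinks_per_day": float(g.drinks_per_day.mean()),
            "drinks_per_reported_day": float(g.drinks_per_reported_day.mean()),
            "drinks_per_drinking_day": float(g.drinks_per_drinking_day.mean()),
            "n": int(len(g)),
        }

    report = {
        "provenance": {
            "package_version": __version__,
            "mode": mode,
            "seed": cohort.config.seed if config is not None else None,
            "config_hash": config_hash(cohort.config) if config is not None else None,
            "n_rows": {"profiles": int(len(cohort.profiles)),
                       "choices": int(len(cohort.choices)),
                       "purchase": int(len(cohort.purchases)),
                       "daily": int(len(cohort.daily))},
        },
        "discounting": _group_session_means(discounting, cohort.profiles,
                                            ["ln_k"]),
        "demand": _group_session_means(
            demand[demand.converged], cohort.profiles,
            ["intensity_obs", "ln_alpha", "omax_obs", "pmax_obs"]),
        "consumption": phase_means,
        "concordance": conc_stats,
        "adherence_selection": {
            "best_terms": list(selection.best.terms),
            "best_bic": selection.best.bic,
            "top5": [{"terms": list(f.terms), "bic": f.bic}
                     for f in selection.ranked[:5]],
            "n_models_fit": len(selection.ranked),
            "n_warnings": len(selection.warnings),
        },
        "exclusions": {
            "nonsystematic_flagged": n_nonsystematic,
            "nonconverged_demand_fits": n_nonconverged,
            "missing_daily_reports": n_missing_days,
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.write(out)
        discounting.to_csv(out / "discounting.csv", index=False)
        demand.to_csv(out / "demand.csv", index=False)
        summaries.to_csv(out / "phase_summaries.csv", index=False)
        model_frame.to_csv(out / "model_frame.csv", index=False)
        matrix.to_csv(out / "concordance_matrix.csv")
        (out / "concordance_stats.json").write_text(
            json.dumps(conc_stats, indent=2, sort_keys=True))
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report
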